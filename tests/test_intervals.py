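import numpy as np
import pytest

import superdna as sd
from superdna.intervals import IntervalSeries, fit_q_exponential_lattice


@pytest.mark.parametrize(
    "seq,cls,expected",
    [
        ("AA", "A", [1]),  # adjacent occurrences: single interval l=1
        ("ACA", "A", [2]),  # one intervening symbol: double interval
        ("ACGTACGT", "A", [4]),
        ("ACGTACGT", "S", [1, 3, 1]),  # C,G adjacent then next segment
        ("GCGC", "S", [1, 1, 1]),
    ],
)
def test_interval_extraction_rules(seq, cls, expected):
    series = sd.extract_intervals(sd.SymbolicSequence.from_string(seq), cls)
    np.testing.assert_array_equal(series.intervals, expected)


def test_full_occupancy_gives_all_ones():
    series = sd.extract_intervals(sd.SymbolicSequence.from_string("A" * 50), "A")
    assert (series.intervals == 1).all()
    assert len(series) == 49  # occurrences - 1


def test_fewer_than_two_occurrences_warns():
    with pytest.warns(UserWarning, match="fewer than 2"):
        series = sd.extract_intervals(sd.SymbolicSequence.from_string("ATTT"), "G")
    assert len(series) == 0


def test_empirical_pdf_normalization(rng):
    series = IntervalSeries("S", rng.geometric(0.3, size=2000), 10_000)
    for binning in ("linear", "logarithmic"):
        pdf = sd.empirical_pdf(series, binning)
        widths = np.diff(pdf.bin_edges)
        assert np.sum(pdf.density * widths) == pytest.approx(1.0, abs=1e-9)


def test_empirical_pdf_single_value():
    pdf = sd.empirical_pdf(IntervalSeries("S", np.full(10, 3), 100), "linear")
    widths = np.diff(pdf.bin_edges)
    mass = pdf.density * widths
    assert mass.sum() == pytest.approx(1.0)
    assert mass.max() == pytest.approx(1.0)  # all mass in one bin


def test_exponential_mle_consistency(rng):
    draws = np.ceil(rng.exponential(10.0, size=20_000)).astype(int)
    series = IntervalSeries("S", draws, 10**6)
    mean = sd.fit_exponential(series)
    assert mean == pytest.approx(10.5, abs=0.3)  # +0.5 from the ceiling
    assert sd.fit_exponential(IntervalSeries("S", [5], 10)) == 5.0


def test_q_exponential_mle_on_gamma_mixture(rng):
    """Continuous draws from the gamma mixture recover q ~ 1 + 1/(alpha+1)."""
    m = sd.model_from_moments(75, 9)
    draws = sd.sample_marginal(m, 200_000, rng)
    q, scale = sd.fit_q_exponential(IntervalSeries("S", np.round(draws * 1000), 10**9))
    # on the near-continuous axis (x1000 grid) the MLE sees the true law
    expected_q = 1 + 1 / (m.alpha + 1)
    assert q == pytest.approx(expected_q, abs=0.005)


def test_q_exponential_mle_exponential_limit(rng):
    draws = rng.exponential(50.0, size=50_000)
    q, scale = sd.fit_q_exponential(IntervalSeries("S", np.round(draws * 100), 10**9))
    assert q < 1.01
    assert scale / 100 == pytest.approx(50.0, rel=0.1)


def test_q_exponential_nll_continuous_at_q_to_1():
    from superdna.intervals import _qexp_nll

    l = np.arange(1.0, 200.0)
    near = _qexp_nll(np.array([1 + 1e-6, 30.0]), l)
    exp_nll = float(np.sum(l / 30.0 + np.log(30.0)))
    assert near == pytest.approx(exp_nll, rel=1e-4)


def test_lattice_fit_recovers_entropic_index(desk_genome):
    """Integer S-intervals of a simulated genome carry the segment-level
    dispersion: the lattice-mixture MLE recovers q = 1 + rho^2."""
    cfg, genome = desk_genome
    st_ = sd.segment_stats(sd.segment_counts(genome), "S")
    q, scale = fit_q_exponential_lattice(sd.extract_intervals(genome, "S"))
    assert q == pytest.approx(1.0 + st_.rho**2, abs=0.01)
    assert scale == pytest.approx(1.0 / st_.xi, rel=0.05)


@pytest.mark.parametrize("hurst,gamma", [(0.8, 0.4), (0.5, 1.0), (0.75, 0.5)])
def test_stretched_exponential_exponent(hurst, gamma):
    assert sd.stretched_exponential_reference(hurst) == pytest.approx(gamma)


def test_mean_interval_inverse_of_fraction(small_genome):
    """Stationarity: the mean interval of a class is ~ 1/xi."""
    cfg, genome = small_genome
    for cls in ("S", "A"):
        series = sd.extract_intervals(genome, cls)
        st_ = sd.segment_stats(sd.segment_counts(genome), cls)
        assert series.mean == pytest.approx(1.0 / st_.xi, rel=0.01)


def test_exponential_gof_accepts_geometric_and_rejects_mixture(rng):
    geo = IntervalSeries("S", rng.geometric(0.5, size=4000), 10**6)
    _, p = sd.exponential_gof(geo, n_boot=200, seed=1)
    assert p > 0.01
    # strongly overdispersed mixture must be rejected
    rates = rng.gamma(4, 0.25 / 4, size=4000)
    mix = IntervalSeries("S", rng.geometric(np.clip(rates, 0.01, 0.99)), 10**6)
    _, p_mix = sd.exponential_gof(mix, n_boot=200, seed=2)
    assert p_mix < 0.01
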