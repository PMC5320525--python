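"""Long-range correlated Gaussian noise with a prescribed Hurst exponent.

The simulator drives its segment-to-segment composition fluctuations with
stationary Gaussian series whose autocorrelation decays algebraically,
C(s) ~ s^(-gamma) with gamma = 2 - 2H.  Series are produced by spectral
synthesis (Fourier filtering): the spectrum of white Gaussian noise is
shaped by f^(-(2H-1)/2), which yields fractional-Gaussian-noise-like
power-law scaling, then inverse transformed and standardized exactly to
zero mean and unit variance.  Cost is O(n log n) and the output is
bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import numpy as np


def _spectral_lrc(n: int, hurst: float, rng: np.random.Generator) -> np.ndarray:
    white = rng.standard_normal(n)
    spectrum = np.fft.rfft(white)
    freq = np.fft.rfftfreq(n)
    exponent = -(2.0 * hurst - 1.0) / 2.0
    with np.errstate(divide="ignore"):
        amp = np.where(freq > 0, freq**exponent, 0.0)
    series = np.fft.irfft(spectrum * amp, n)
    return series


def generate_lrc(
    n: int, hurst: float, seed: int | np.random.Generator, stream: int = 0
) -> np.ndarray:
    """Generate a standardized long-range correlated Gaussian series.

    Parameters
    ----------
    n
        Series length (>= 64).
    hurst
        Target Hurst exponent, 0.5 <= H < 1.  H = 0.5 reduces to white
        noise (apart from removal of the zero-frequency component).
    seed
        Master seed (or an existing generator).
    stream
        Sub-stream index; different streams from the same master seed are
        mutually independent.  The simulator uses this to draw the
        strong/weak, purine-among-weak and purine-among-strong drivers
        independently.

    Returns
    -------
    numpy.ndarray
        Series of length ``n`` with exactly zero mean and unit variance.
    """
    if not 0.5 <= hurst < 1.0:
        raise ValueError(f"hurst must lie in [0.5, 1), got {hurst}")
    if n < 64:
        raise ValueError("n must be >= 64")
    rng = stream_rng(seed, stream)
    series = _spectral_lrc(n, hurst, rng)
    series -= series.mean()
    sd = series.std(ddof=0)
    if sd == 0:
        raise RuntimeError("degenerate spectral synthesis output")
    return series / sd


def stream_rng(seed: int | np.random.Generator, stream: int = 0) -> np.random.Generator:
    """Derive an independent, reproducible generator for a named stream."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=(stream,)))
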