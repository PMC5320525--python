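"""Fixed-length segmentation and local composition statistics.

The model views a chromosome as a concatenation of non-overlapping segments
whose length equals the DNA persistence length (~50 nm, about 150 bp).
Within a segment nucleotides are treated as randomly arranged; between
segments the counts ``n`` of each symbol class fluctuate, and those
segment-to-segment fluctuations carry the long-range structure.  This
module computes the per-segment counts and their summary moments
(mean ``<n>``, standard deviation ``sigma_n``, coefficient of variation
``rho = sigma_n/<n>`` and relative fraction ``xi = <n>/L``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .seqio import ALPHA_DNA, ALPHA_SW, SymbolicSequence, to_sw

#: Default segment length in bp (the DNA persistence length).
DEFAULT_SEGMENT_LENGTH = 150

#: Classes reported for a DNA-alphabet profile.
DNA_CLASSES = ("W", "S", "A", "C", "G", "T")
SW_CLASSES = ("W", "S")


@dataclass
class SegmentProfile:
    """Per-segment symbol-class counts along a sequence.

    ``counts[c]`` is an integer array of length ``n_seg`` holding the count
    of class ``c`` in each segment; the trailing partial segment (if any)
    is discarded, so ``n_seg = floor(N / segment_length)``.
    """

    segment_length: int
    n_seg: int
    counts: dict[str, np.ndarray]
    identifier: str = ""

    def fractions(self, cls: str) -> np.ndarray:
        """Per-segment relative fractions xi = n / L for one class."""
        return self.counts[cls] / self.segment_length

    @property
    def classes(self) -> tuple[str, ...]:
        return tuple(self.counts)


@dataclass
class SegmentStats:
    """Moments of the per-segment counts of a single class."""

    cls: str
    mean_n: float
    sigma_n: float
    segment_length: int

    @property
    def rho(self) -> float:
        """Coefficient of variation sigma_n / <n> (NaN when <n> = 0)."""
        if self.mean_n == 0:
            return float("nan")
        return self.sigma_n / self.mean_n

    @property
    def xi(self) -> float:
        """Relative fraction <n> / L."""
        return self.mean_n / self.segment_length


def segment_counts(
    seq: SymbolicSequence, segment_length: int = DEFAULT_SEGMENT_LENGTH
) -> SegmentProfile:
    """Count symbol classes in consecutive non-overlapping segments.

    For a DNA sequence the counts of A, C, G, T and of the derived strong
    (S = G,C) and weak (W = A,T) classes are all reported; in every segment
    ``n_W + n_S = L`` and ``n_A + n_C + n_G + n_T = L``.
    """
    if segment_length < 1:
        raise ValueError("segment_length must be >= 1")
    n = len(seq)
    if n < segment_length:
        raise ValueError(
            f"sequence length {n} is shorter than one segment ({segment_length} bp)"
        )
    n_seg = n // segment_length
    codes = seq.codes[: n_seg * segment_length].reshape(n_seg, segment_length)

    counts: dict[str, np.ndarray] = {}
    if seq.alphabet == ALPHA_DNA:
        per_code = [
            np.count_nonzero(codes == k, axis=1).astype(np.int64) for k in range(4)
        ]
        n_a, n_c, n_g, n_t = per_code
        counts["W"] = n_a + n_t
        counts["S"] = n_c + n_g
        counts["A"], counts["C"], counts["G"], counts["T"] = n_a, n_c, n_g, n_t
    elif seq.alphabet == ALPHA_SW:
        n_s = np.count_nonzero(codes == 0, axis=1).astype(np.int64)
        counts["W"] = segment_length - n_s
        counts["S"] = n_s
    else:
        raise ValueError(f"unsupported alphabet {seq.alphabet!r}")
    return SegmentProfile(segment_length, n_seg, counts, seq.identifier)


def segment_stats(profile: SegmentProfile, cls: str = "S") -> SegmentStats:
    """Mean and standard deviation of per-segment counts for one class.

    The population (divide-by-``n_seg``) standard deviation is used, which
    keeps ``rho * <n> == sigma_n`` exact and matches the gamma
    moment-matching in :mod:`superdna.superstat`.
    """
    if profile.n_seg < 2:
        raise ValueError("need at least 2 segments for segment statistics")
    c = profile.counts[cls]
    return SegmentStats(
        cls=cls,
        mean_n=float(c.mean()),
        sigma_n=float(c.std(ddof=0)),
        segment_length=profile.segment_length,
    )


def all_segment_stats(profile: SegmentProfile) -> dict[str, SegmentStats]:
    return {cls: segment_stats(profile, cls) for cls in profile.classes}


def binomial_reference(xi: float, segment_length: int = DEFAULT_SEGMENT_LENGTH) -> float:
    """Expected sigma_n for independently placed symbols: sqrt(L xi (1-xi)).

    Randomly shuffled sequences follow this binomial law; genuine genomes
    (and the simulator's output) exceed it because of segment-to-segment
    composition fluctuations.
    """
    if not 0.0 <= xi <= 1.0:
        raise ValueError("xi must lie in [0, 1]")
    return float(np.sqrt(segment_length * xi * (1.0 - xi)))


def count_histogram(
    profile: SegmentProfile, cls: str, bin_width: int = 1
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of per-segment counts with integer bins.

    Returns ``(bin_centers, probability)``; ``bin_width`` > 1 aggregates
    adjacent integer counts for sparse data.
    """
    c = profile.counts[cls]
    lo, hi = int(c.min()), int(c.max())
    edges = np.arange(lo - 0.5, hi + bin_width + 0.5, bin_width)
    hist, edges = np.histogram(c, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, hist / c.size
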