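"""Detrended fluctuation analysis (DFA) and crossover detection.

DFA quantifies long-range correlations in a numeric series: the profile
(cumulative sum of the mean-subtracted series) is split into windows of
size s, a polynomial trend (order 2 by default, "DFA2") is removed in each
window, and the root-mean-square residual defines the fluctuation function
F(s).  For long-range correlated data F(s) ~ s^H with Hurst exponent H;
uncorrelated data give H = 1/2.

Bond-enthalpy tracks of bacterial DNA show two regimes: H ~ 0.5 below and
H ~ 0.8 above a crossover located a few persistence lengths (~150 bp) up;
``detect_crossover`` fits that two-piece power law in log-log coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .seqio import NumericTrack


def _as_array(track: NumericTrack | np.ndarray) -> np.ndarray:
    if isinstance(track, NumericTrack):
        return track.values
    return np.asarray(track, dtype=np.float64)


@dataclass
class FluctuationFunction:
    """DFA fluctuation values F(s) on a grid of window sizes."""

    scales: np.ndarray
    values: np.ndarray
    detrend_order: int = 2

    def log_slope(self, s_min: float | None = None, s_max: float | None = None) -> float:
        return estimate_hurst(self, s_min, s_max)


@dataclass
class CrossoverFit:
    """Two-piece log-log fit of F(s): slopes below/above a breakpoint."""

    h_below: float
    h_above: float
    s_cross: float
    single_regime: bool = False


def profile(track: NumericTrack | np.ndarray) -> np.ndarray:
    """Cumulative sum of the mean-subtracted series (the DFA profile)."""
    y = _as_array(track)
    if y.size < 2:
        raise ValueError("need at least 2 values")
    return np.cumsum(y - y.mean())


def default_scales(n: int, n_scales: int = 20, s_min: int = 8) -> np.ndarray:
    """~20 logarithmically spaced window sizes from s_min up to n/4."""
    s_max = n // 4
    if s_max <= s_min:
        raise ValueError(f"series too short for DFA (length {n})")
    grid = np.geomspace(s_min, s_max, n_scales)
    return np.unique(np.round(grid).astype(np.int64))


def _window_rms(prof: np.ndarray, s: int, order: int) -> float:
    """Mean squared detrending residual over non-overlapping windows.

    Windows are taken from both the start and the end of the profile (the
    standard refinement when the length is not a multiple of s), and the
    squared residuals are averaged over all of them.
    """
    n = prof.size
    n_win = n // s
    x = np.arange(s, dtype=np.float64)
    # Legendre-style centering keeps the Vandermonde well conditioned.
    x -= x.mean()
    vand = np.vander(x, order + 1)
    pinv = np.linalg.pinv(vand)
    total = 0.0
    for seg in (prof[: n_win * s], prof[n - n_win * s :]):
        w = seg.reshape(n_win, s)
        coef = w @ pinv.T
        resid = w - coef @ vand.T
        total += float(np.mean(resid**2))
    return total / 2.0


def fluctuation_function(
    track: NumericTrack | np.ndarray,
    scales: np.ndarray | None = None,
    order: int = 2,
) -> FluctuationFunction:
    """Compute F(s) by polynomial detrending of the profile.

    Scales larger than n/4 (fewer than 4 windows) are skipped.  Windows are
    taken from both ends of the profile so trailing data contribute.
    """
    y = _as_array(track)
    if order < 0:
        raise ValueError("order must be >= 0")
    prof = profile(y)
    if scales is None:
        scales = default_scales(y.size)
    scales = np.asarray(scales, dtype=np.int64)
    kept, values = [], []
    for s in scales:
        if s < order + 2:
            continue
        if s > y.size // 4:
            continue
        kept.append(int(s))
        values.append(np.sqrt(_window_rms(prof, int(s), order)))
    if not kept:
        raise ValueError("no admissible scales (series too short?)")
    return FluctuationFunction(np.array(kept), np.array(values), order)


def estimate_hurst(
    fluct: FluctuationFunction,
    s_min: float | None = None,
    s_max: float | None = None,
) -> float:
    """Least-squares slope of log F(s) vs log s over [s_min, s_max]."""
    s, f = fluct.scales, fluct.values
    mask = np.ones(s.size, dtype=bool)
    if s_min is not None:
        mask &= s >= s_min
    if s_max is not None:
        mask &= s <= s_max
    if mask.sum() < 4:
        raise ValueError("need at least 4 scales in the fitting window")
    slope, _ = np.polyfit(np.log(s[mask]), np.log(f[mask]), 1)
    return float(slope)


def detect_crossover(
    fluct: FluctuationFunction,
    edge_exclude: int = 2,
    min_points: int = 3,
    improvement: float = 0.01,
) -> CrossoverFit:
    """Best two-piece linear fit of log F vs log s.

    Every admissible interior breakpoint (excluding ``edge_exclude`` scales
    at each end) is tried; the one minimizing the total squared residual of
    the two straight lines wins.  If no breakpoint improves on a single
    line by more than ``improvement`` (relative), the result is flagged
    single-regime and both slopes equal the global slope.
    """
    s, f = fluct.scales, fluct.values
    if s.size < 8:
        raise ValueError("need at least 8 scales for crossover detection")
    if np.log10(s[-1] / s[0]) < 1.5:
        raise ValueError("scale range must span at least 1.5 decades")
    ls, lf = np.log(s), np.log(f)

    def ssr(xi: np.ndarray, yi: np.ndarray) -> float:
        coef = np.polyfit(xi, yi, 1)
        return float(np.sum((yi - np.polyval(coef, xi)) ** 2))

    ssr_single = ssr(ls, lf)
    global_slope, _ = np.polyfit(ls, lf, 1)

    best: tuple[float, int] | None = None
    lo = max(min_points - 1, edge_exclude)
    hi = s.size - max(min_points, edge_exclude)
    for i in range(lo, hi):
        # breakpoint between scale i and i+1; both sides include >= min_points
        total = ssr(ls[: i + 1], lf[: i + 1]) + ssr(ls[i:], lf[i:])
        if best is None or total < best[0]:
            best = (total, i)
    # tiny absolute SSR means the data already are a single exact power law
    if best is None or ssr_single < 1e-12 or best[0] > (1.0 - improvement) * ssr_single:
        return CrossoverFit(
            h_below=float(global_slope),
            h_above=float(global_slope),
            s_cross=float(np.sqrt(s[0] * s[-1])),
            single_regime=True,
        )
    _, i = best
    slope_lo, _ = np.polyfit(ls[: i + 1], lf[: i + 1], 1)
    slope_hi, _ = np.polyfit(ls[i:], lf[i:], 1)
    s_cross = float(np.sqrt(s[i] * s[i + 1])) if i + 1 < s.size else float(s[i])
    return CrossoverFit(float(slope_lo), float(slope_hi), s_cross, False)
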