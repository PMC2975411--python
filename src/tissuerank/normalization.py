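"""Invariant-set normalization of arrays against a group baseline.

Each normalization group (arrays of the same or similar tissue) is
normalized against the array whose overall intensity is the group median.
For every other array, an iteratively refined set of probes with small
rank difference to the baseline is selected; a monotone piecewise-linear
curve fitted through running medians of those invariant pairs then maps
the array onto the baseline's intensity scale.

The curve smoother is a running median over windows of the target-sorted
invariant pairs, followed by an isotonic adjustment of the knot targets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import isotonic_regression
from scipy.stats import rankdata

#: reference vector length at which ``min_set_size`` applies un-scaled
_REFERENCE_LENGTH = 4000


@dataclass(frozen=True)
class InvariantSetParams:
    """Tunables of the iterative rank-difference probe selection."""

    initial_fraction: float = 0.05
    shrink_factor: float = 0.9
    max_iterations: int = 30
    min_set_size: int = 200

    def __post_init__(self) -> None:
        if not 0 < self.initial_fraction <= 1:
            raise ValueError("initial_fraction must be in (0, 1]")
        if not 0 < self.shrink_factor < 1:
            raise ValueError("shrink_factor must be in (0, 1)")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be positive")
        if self.min_set_size < 10:
            raise ValueError("min_set_size must be >= 10")

    def scaled_min_set_size(self, n: int) -> int:
        """Scale ``min_set_size`` down proportionally for short vectors."""
        if n >= _REFERENCE_LENGTH:
            return self.min_set_size
        return max(10, int(round(self.min_set_size * n / _REFERENCE_LENGTH)))


@dataclass(frozen=True)
class NormalizationCurve:
    """Monotone piecewise-linear intensity map with linear extrapolation."""

    knots_source: np.ndarray
    knots_target: np.ndarray

    def __post_init__(self) -> None:
        src = np.asarray(self.knots_source, dtype=float)
        tgt = np.asarray(self.knots_target, dtype=float)
        if src.ndim != 1 or src.shape != tgt.shape or src.size < 2:
            raise ValueError("curve needs >= 2 knots of equal length")
        if np.any(np.diff(src) <= 0):
            raise ValueError("knot source coordinates must be strictly increasing")
        if np.any(np.diff(tgt) < 0):
            raise ValueError("knot targets must be non-decreasing")

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return apply_curve(x, self)


def select_baseline(group_values: list[np.ndarray]) -> int:
    """Index of the array whose overall intensity is the group median.

    Overall intensity is the arithmetic mean of the array's values.  For
    even group sizes the lower of the two middle arrays is chosen.
    """
    if not group_values:
        raise ValueError("cannot select a baseline from an empty group")
    means = np.array([float(np.mean(v)) for v in group_values])
    order = np.argsort(means, kind="stable")
    return int(order[(len(order) - 1) // 2])


def find_invariant_set(
    target: np.ndarray,
    baseline: np.ndarray,
    params: InvariantSetParams | None = None,
) -> np.ndarray:
    """Iteratively select probes whose ranks agree between the two arrays.

    At each iteration both vectors are ranked within the surviving set and
    probes with normalized rank difference below the current fraction are
    kept; the fraction then shrinks.  Stops when the set stabilizes, would
    fall below the (length-scaled) minimum size, or the iteration budget
    is exhausted.  Returns probe indices into the original vectors.
    """
    target = np.asarray(target, dtype=float)
    baseline = np.asarray(baseline, dtype=float)
    if target.shape != baseline.shape or target.ndim != 1:
        raise ValueError(
            f"vectors must be 1-D of equal length, got {target.shape} "
            f"and {baseline.shape}"
        )
    params = params or InvariantSetParams()
    n = target.size
    min_size = params.scaled_min_set_size(n)
    if n < min_size:
        raise ValueError(f"vector length {n} below minimum set size {min_size}")

    kept = np.arange(n)
    fraction = params.initial_fraction
    for _ in range(params.max_iterations):
        m = kept.size
        rank_t = rankdata(target[kept])
        rank_b = rankdata(baseline[kept])
        close = np.abs(rank_t - rank_b) / m < fraction
        new_kept = kept[close]
        if new_kept.size < min_size:
            return kept
        if new_kept.size == kept.size:
            kept = new_kept
            break
        kept = new_kept
        fraction *= params.shrink_factor
    return kept


def fit_normalization_curve(
    invariant_target: np.ndarray,
    invariant_baseline: np.ndarray,
    window: int | None = None,
) -> NormalizationCurve:
    """Fit a monotone curve through running medians of invariant pairs.

    Pairs are sorted by target intensity and cut into consecutive windows;
    each window contributes one knot (median target, median baseline).
    Knot targets are isotonically adjusted so the map is non-decreasing.
    Default window: 101 points, or n // 10 for small sets.
    """
    t = np.asarray(invariant_target, dtype=float)
    b = np.asarray(invariant_baseline, dtype=float)
    if t.shape != b.shape or t.ndim != 1:
        raise ValueError("invariant pair vectors must be 1-D of equal length")
    n = t.size
    if window is None:
        window = min(101, max(3, n // 10))
    if n < window:
        raise ValueError(f"{n} pairs cannot fill one window of {window}")

    order = np.argsort(t, kind="stable")
    ts, bs = t[order], b[order]
    edges = np.linspace(0, n, max(2, n // window) + 1).astype(int)
    src = np.array([np.median(ts[lo:hi]) for lo, hi in zip(edges[:-1], edges[1:])])
    tgt = np.array([np.median(bs[lo:hi]) for lo, hi in zip(edges[:-1], edges[1:])])

    tgt = isotonic_regression(tgt).x

    # collapse duplicate source coordinates (heavy ties) by averaging targets
    uniq, inverse = np.unique(src, return_inverse=True)
    if uniq.size < src.size:
        tgt = np.array([tgt[inverse == k].mean() for k in range(uniq.size)])
        src = uniq
    if src.size < 2:
        raise ValueError("invariant pairs collapse to a single knot")
    return NormalizationCurve(knots_source=src, knots_target=tgt)


def apply_curve(target: np.ndarray, curve: NormalizationCurve) -> np.ndarray:
    """Map intensities through the curve; linear extrapolation, floor at 0."""
    x = np.asarray(target, dtype=float)
    src, tgt = curve.knots_source, curve.knots_target
    y = np.interp(x, src, tgt)
    lo_slope = (tgt[1] - tgt[0]) / (src[1] - src[0])
    hi_slope = (tgt[-1] - tgt[-2]) / (src[-1] - src[-2])
    below = x < src[0]
    above = x > src[-1]
    y = np.where(below, tgt[0] + (x - src[0]) * lo_slope, y)
    y = np.where(above, tgt[-1] + (x - src[-1]) * hi_slope, y)
    return np.maximum(y, 0.0)


def normalize_group(
    group: list[np.ndarray],
    params: InvariantSetParams | None = None,
) -> tuple[list[np.ndarray], int]:
    """Normalize every array of a group against its median-intensity baseline.

    Returns the normalized vectors (baseline unchanged) and the baseline
    index.  Works on any intensity vectors: probe-level PM intensities or
    probe-set-level summaries.
    """
    if not group:
        raise ValueError("cannot normalize an empty group")
    params = params or InvariantSetParams()
    baseline_idx = select_baseline(group)
    baseline = np.asarray(group[baseline_idx], dtype=float)
    out: list[np.ndarray] = []
    for i, arr in enumerate(group):
        arr = np.asarray(arr, dtype=float)
        if i == baseline_idx:
            out.append(arr.copy())
            continue
        kept = find_invariant_set(arr, baseline, params)
        curve = fit_normalization_curve(arr[kept], baseline[kept])
        out.append(apply_curve(arr, curve))
    return out, baseline_idx
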