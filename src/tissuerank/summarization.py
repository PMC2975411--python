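"""Probe-level to probe-set-level summarization and detection calls.

Expression values come from a multiplicative model fitted to PM - MM
differences: ``diff[i, j] ~ theta[i] * phi[j]`` with array effects theta
and probe effects phi under the scale convention ``sum(phi**2) == J``
(J = probe count).  Cells with large standardized residuals are marked;
an array (or probe) with marks in more than half of its cells is flagged
as an outlier for the probe set and the model is refit once without it.

Detection calls use a one-sided Wilcoxon signed-rank test of
``PM - MM > 0``: p below ``p_present`` gives Present, below
``p_marginal`` gives Marginal, otherwise Absent.  Calls may also be
supplied externally via a call matrix — this module is the fallback path
when only probe-level data are available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import wilcoxon

from tissuerank.core_model import ABSENT, MARGINAL, PRESENT

_RESIDUAL_Z = 3.0
_CONVERGENCE_TOL = 1e-6
_MAX_ROUNDS = 100


@dataclass
class ProbePairBlock:
    """PM/MM intensities of one probe set: probes x arrays."""

    probe_set_id: str
    pm: np.ndarray
    mm: np.ndarray

    def __post_init__(self) -> None:
        self.pm = np.asarray(self.pm, dtype=float)
        self.mm = np.asarray(self.mm, dtype=float)
        if self.pm.shape != self.mm.shape:
            raise ValueError(
                f"{self.probe_set_id}: pm shape {self.pm.shape} != mm shape "
                f"{self.mm.shape}"
            )
        if self.pm.ndim != 2 or self.pm.shape[0] < 3:
            raise ValueError(
                f"{self.probe_set_id}: need >= 3 probe pairs, got shape "
                f"{self.pm.shape}"
            )
        if np.any(self.pm < 0) or np.any(self.mm < 0):
            raise ValueError(f"{self.probe_set_id}: negative intensities")

    @property
    def n_probes(self) -> int:
        return self.pm.shape[0]

    @property
    def n_arrays(self) -> int:
        return self.pm.shape[1]


@dataclass
class ProbeSetFit:
    """Fitted array effects, probe effects and outlier flags."""

    probe_set_id: str
    expression: np.ndarray
    probe_effects: np.ndarray
    array_outlier_flags: np.ndarray
    probe_outlier_flags: np.ndarray


@dataclass(frozen=True)
class CallParams:
    p_present: float = 0.04
    p_marginal: float = 0.06

    def __post_init__(self) -> None:
        if not 0 < self.p_present < self.p_marginal < 1:
            raise ValueError("need 0 < p_present < p_marginal < 1")


def _als(diff: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Alternating least squares for diff ~ theta phi^T, sum(phi^2) = J."""
    n_probes, n_arrays = diff.shape
    phi = np.ones(n_probes)
    phi *= np.sqrt(n_probes / np.sum(phi**2))
    theta = np.zeros(n_arrays)
    for _ in range(_MAX_ROUNDS):
        theta_new = diff.T @ phi / np.sum(phi**2)
        denom = np.sum(theta_new**2)
        if denom == 0:
            return np.zeros(n_arrays), phi
        phi_new = diff @ theta_new / denom
        norm = np.sqrt(np.sum(phi_new**2))
        if norm == 0:
            return np.zeros(n_arrays), phi
        scale = np.sqrt(n_probes) / norm
        phi_new = phi_new * scale
        theta_new = theta_new / scale
        delta = np.max(np.abs(theta_new - theta)) / (np.max(np.abs(theta_new)) + 1e-300)
        theta, phi = theta_new, phi_new
        if delta < _CONVERGENCE_TOL:
            break
    if np.sum(phi) < 0:  # fix the sign ambiguity of the factorization
        phi, theta = -phi, -theta
    return theta, phi


def _robust_rank1(diff: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Median-based rank-1 fit, insensitive to a minority of bad arrays."""
    col_scale = np.median(diff, axis=0)
    safe = np.where(np.abs(col_scale) > 0, col_scale, 1.0)
    phi = np.median(diff / safe[None, :], axis=1)
    norm = np.sqrt(np.sum(phi**2))
    if norm == 0:
        phi = np.ones(diff.shape[0])
        norm = np.sqrt(float(diff.shape[0]))
    phi = phi * np.sqrt(diff.shape[0]) / norm
    safe_phi = np.where(np.abs(phi) > 0, phi, 1.0)
    theta = np.median(diff / safe_phi[:, None], axis=0)
    return theta, phi


def fit_probe_set(block: ProbePairBlock) -> ProbeSetFit:
    """Fit the multiplicative model to PM - MM and flag outliers.

    Negative differences are kept for fitting; expression values are
    floored at 0 only on output.  After the first fit, arrays/probes with
    more than half of their cells exceeding |z| > 3 are flagged and the
    model is refit once on the remaining cells.
    """
    if block.n_arrays < 2:
        raise ValueError(f"{block.probe_set_id}: need >= 2 arrays")
    diff = block.pm - block.mm
    n_probes, n_arrays = diff.shape

    if not np.any(diff):
        return ProbeSetFit(
            probe_set_id=block.probe_set_id,
            expression=np.zeros(n_arrays),
            probe_effects=np.ones(n_probes) * np.sqrt(1.0),
            array_outlier_flags=np.zeros(n_arrays, dtype=bool),
            probe_outlier_flags=np.zeros(n_probes, dtype=bool),
        )

    # Outliers are detected against a robust median-based rank-1 fit: a
    # grossly corrupted array would otherwise hijack the least-squares fit
    # and hide its own residuals.
    theta_r, phi_r = _robust_rank1(diff)
    resid = diff - np.outer(phi_r, theta_r)
    sd = 1.4826 * float(np.median(np.abs(resid)))
    if sd == 0:
        sd = float(np.std(resid))
    marked = (
        np.abs(resid) > _RESIDUAL_Z * sd
        if sd > 0
        else np.zeros_like(resid, dtype=bool)
    )
    array_flags = marked.sum(axis=0) > n_probes / 2
    probe_flags = marked.sum(axis=1) > n_arrays / 2

    keep_p = ~probe_flags
    keep_a = ~array_flags
    if keep_p.sum() >= 1 and keep_a.sum() >= 2:
        theta_sub, phi_sub = _als(diff[np.ix_(keep_p, keep_a)])
        theta = np.zeros(n_arrays)
        theta[keep_a] = theta_sub
        # flagged arrays still get a value from the clean probe effects
        if (~keep_a).any():
            theta[~keep_a] = diff[np.ix_(keep_p, ~keep_a)].T @ phi_sub / np.sum(
                phi_sub**2
            )
        phi = np.zeros(n_probes)
        phi[keep_p] = phi_sub
        if (~keep_p).any():
            denom = np.sum(theta_sub**2)
            if denom > 0:
                phi[~keep_p] = diff[np.ix_(~keep_p, keep_a)] @ theta_sub / denom
        norm = np.sqrt(np.sum(phi**2))
        if norm > 0:
            scale = np.sqrt(n_probes) / norm
            phi = phi * scale
            theta = theta / scale
    else:
        theta, phi = _als(diff)

    return ProbeSetFit(
        probe_set_id=block.probe_set_id,
        expression=np.maximum(theta, 0.0),
        probe_effects=phi,
        array_outlier_flags=array_flags,
        probe_outlier_flags=probe_flags,
    )


def detection_call(
    pm: np.ndarray, mm: np.ndarray, params: CallParams | None = None
) -> str:
    """Present/Marginal/Absent from a one-sided signed-rank test of PM > MM."""
    params = params or CallParams()
    pm = np.asarray(pm, dtype=float)
    mm = np.asarray(mm, dtype=float)
    if pm.shape != mm.shape or pm.ndim != 1 or pm.size < 3:
        raise ValueError("pm and mm must be 1-D of equal length >= 3")
    d = pm - mm
    if not np.any(d):
        p = 1.0  # degenerate: no signal at all
    else:
        p = float(wilcoxon(d, alternative="greater").pvalue)
    if p < params.p_present:
        return PRESENT
    if p < params.p_marginal:
        return MARGINAL
    return ABSENT


def flag_outlier_arrays(
    per_array_outlier_fraction: np.ndarray | list[float],
    threshold: float = 0.15,
) -> set[int]:
    """Arrays whose probe-set outlier fraction strictly exceeds threshold.

    The fraction for an array is (probe sets flagging it) / (total probe
    sets).  An array at exactly the threshold is kept.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    fractions = np.asarray(per_array_outlier_fraction, dtype=float)
    if np.any(fractions < 0) or np.any(fractions > 1):
        raise ValueError("fractions must lie in [0, 1]")
    return set(np.flatnonzero(fractions > threshold).tolist())


def summarize_blocks(
    blocks: list[ProbePairBlock],
    outlier_threshold: float = 0.15,
    call_params: CallParams | None = None,
) -> tuple[np.ndarray, np.ndarray, set[int], list[str]]:
    """Fit every block; return expression matrix, call matrix, exclusions.

    Returns ``(values, calls, excluded_arrays, probe_set_ids)`` with
    matrices of shape (probe sets x arrays).  Excluded arrays are those
    flagged as outliers in more than ``outlier_threshold`` of probe sets;
    their columns are retained in the matrices so the caller decides what
    to drop.
    """
    if not blocks:
        raise ValueError("no probe-set blocks given")
    n_arrays = blocks[0].n_arrays
    values = np.zeros((len(blocks), n_arrays))
    calls = np.empty((len(blocks), n_arrays), dtype="<U1")
    flag_counts = np.zeros(n_arrays)
    for k, block in enumerate(blocks):
        if block.n_arrays != n_arrays:
            raise ValueError(
                f"{block.probe_set_id}: array count {block.n_arrays} != {n_arrays}"
            )
        fit = fit_probe_set(block)
        values[k] = fit.expression
        flag_counts += fit.array_outlier_flags
        for j in range(n_arrays):
            calls[k, j] = detection_call(block.pm[:, j], block.mm[:, j], call_params)
    fractions = flag_counts / len(blocks)
    excluded = flag_outlier_arrays(fractions, outlier_threshold)
    return values, calls, excluded, [b.probe_set_id for b in blocks]
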