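"""Seeded generators for compendium- and probe-level fixtures.

The compendium generator emulates the statistical structure the pipeline
assumes: lognormal background expression, multiplicative per-study scale
effects, planted tissue-selective genes of known fold, and a stochastic
detection-call process (high probability of Present for planted genes in
their target tissue, a small leak elsewhere, and a value-dependent
logistic call probability for background).

Background call model: P(Present) is logistic in log-value, centred on
each sample's median log-value with slope 1/background_log_sd, so about
half of the background cells in every sample are Present regardless of
the study scale factor.  A fixed 5% of non-Present background cells are
Marginal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from tissuerank.core_model import (
    ABSENT,
    Compendium,
    MARGINAL,
    PRESENT,
    SampleAnnotation,
    validate_compendium,
)
from tissuerank.summarization import ProbePairBlock

_MARGINAL_RATE = 0.05


@dataclass(frozen=True)
class SimulationConfig:
    """Shape and signal parameters of a synthetic compendium."""

    n_tissues: int = 5
    samples_per_tissue: int | tuple[int, ...] = 20
    n_probe_sets: int = 2000
    n_selective_per_tissue: int = 4
    fold_range: tuple[float, float] = (10.0, 50.0)
    p_present_signal: float = 0.9
    p_present_leak: float = 0.005
    background_log_sd: float = 1.0
    group_scale_range: tuple[float, float] = (0.5, 2.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tissues < 1 or self.n_probe_sets < 1:
            raise ValueError("n_tissues and n_probe_sets must be >= 1")
        if self.fold_range[0] <= 1 or self.fold_range[1] < self.fold_range[0]:
            raise ValueError("fold_range must satisfy 1 < low <= high")
        for p in (self.p_present_signal, self.p_present_leak):
            if not 0 <= p <= 1:
                raise ValueError("call probabilities must be in [0, 1]")
        if self.n_selective_per_tissue * self.n_tissues > self.n_probe_sets:
            raise ValueError("more planted genes than probe sets")
        if self.group_scale_range[0] <= 0:
            raise ValueError("group scale factors must be positive")

    def samples_for(self, tissue_index: int) -> int:
        if isinstance(self.samples_per_tissue, int):
            return self.samples_per_tissue
        return self.samples_per_tissue[tissue_index]


@dataclass
class TruthTable:
    """probe_id -> (target tissue, planted fold) for planted genes."""

    planted: dict[str, tuple[str, float]] = field(default_factory=dict)

    def for_tissue(self, tissue: str) -> list[str]:
        return sorted(p for p, (t, _) in self.planted.items() if t == tissue)


def simulate_compendium(config: SimulationConfig) -> tuple[Compendium, TruthTable]:
    """Generate a multi-study, multi-tissue compendium with known truth.

    Fully reproducible from ``config.seed``.  Values are raw (per-group
    scale effects applied); run them through
    :func:`tissuerank.integration.median_transform_compendium` (or the
    full integrate step) before selectivity analysis with theta on the
    median-1 scale.
    """
    rng = np.random.default_rng(config.seed)
    tissues = [f"tissue{k:02d}" for k in range(config.n_tissues)]
    counts = [config.samples_for(k) for k in range(config.n_tissues)]
    n_samples = sum(counts)
    n_probes = config.n_probe_sets
    probe_ids = [f"ps{i:06d}" for i in range(n_probes)]

    sample_ids: list[str] = []
    annotations: list[SampleAnnotation] = []
    tissue_of_sample: list[int] = []
    for k, tissue in enumerate(tissues):
        for j in range(counts[k]):
            sid = f"s{len(sample_ids):05d}"
            sample_ids.append(sid)
            annotations.append(
                SampleAnnotation(
                    sample_id=sid,
                    tissue_label=tissue,
                    normalization_group=f"group_{tissue}",
                    study_id=f"study{k:02d}",
                )
            )
            tissue_of_sample.append(k)
    tissue_of_sample = np.array(tissue_of_sample)

    # one normalization group (= one study scale factor) per tissue
    scales = rng.uniform(*config.group_scale_range, size=config.n_tissues)
    log_bg = rng.normal(0.0, config.background_log_sd, size=(n_probes, n_samples))
    values = np.exp(log_bg) * scales[tissue_of_sample][None, :]

    # plant selective genes on the first probes, round-robin over tissues
    truth = TruthTable()
    planted_target = np.full(n_probes, -1)
    planted_fold = np.zeros(n_probes)
    idx = 0
    for k, tissue in enumerate(tissues):
        for _ in range(config.n_selective_per_tissue):
            fold = rng.uniform(*config.fold_range)
            truth.planted[probe_ids[idx]] = (tissue, fold)
            planted_target[idx] = k
            planted_fold[idx] = fold
            idx += 1
    for i in np.flatnonzero(planted_target >= 0):
        in_target = tissue_of_sample == planted_target[i]
        values[i, in_target] *= planted_fold[i]

    # calls: logistic-in-log-value background, Bernoulli for planted genes
    log_values = np.log(values)
    sample_centre = np.median(log_values, axis=0)
    z = (log_values - sample_centre[None, :]) / config.background_log_sd
    p_present = 1.0 / (1.0 + np.exp(-z))
    for i in np.flatnonzero(planted_target >= 0):
        in_target = tissue_of_sample == planted_target[i]
        p_present[i, in_target] = config.p_present_signal
        p_present[i, ~in_target] = config.p_present_leak

    u = rng.random((n_probes, n_samples))
    calls = np.full((n_probes, n_samples), ABSENT, dtype="<U1")
    calls[u < p_present] = PRESENT
    not_present = u >= p_present
    marginal = not_present & (rng.random((n_probes, n_samples)) < _MARGINAL_RATE)
    calls[marginal] = MARGINAL

    compendium = validate_compendium(probe_ids, sample_ids, values, calls, annotations)
    return compendium, truth


def simulate_probe_level(
    arrays: int,
    probe_sets: int,
    pairs_per_set: int,
    noise_sd: float,
    outlier_arrays: set[int] | None = None,
    seed: int = 0,
    corrupt_fraction: float = 0.2,
) -> tuple[list[ProbePairBlock], np.ndarray]:
    """Rank-1 probe-level blocks with optional planted outlier arrays.

    ``PM = theta_i * phi_j + MM + noise``; designated outlier arrays get
    heavy-tailed corruption of their PM cells in ``corrupt_fraction`` of
    the probe sets.  Returns the blocks and the true array effects theta.
    """
    if pairs_per_set < 3:
        raise ValueError("pairs_per_set must be >= 3")
    outlier_arrays = outlier_arrays or set()
    rng = np.random.default_rng(seed)
    theta = rng.uniform(50.0, 500.0, size=arrays)

    corrupted: dict[int, np.ndarray] = {}
    for a in outlier_arrays:
        n_bad = int(np.ceil(corrupt_fraction * probe_sets))
        corrupted[a] = rng.choice(probe_sets, size=n_bad, replace=False)

    blocks: list[ProbePairBlock] = []
    for s in range(probe_sets):
        phi = rng.uniform(0.5, 2.0, size=pairs_per_set)
        phi *= np.sqrt(pairs_per_set / np.sum(phi**2))
        mm = rng.uniform(20.0, 60.0, size=(pairs_per_set, arrays))
        signal = np.outer(phi, theta)
        noise = rng.normal(0.0, noise_sd, size=signal.shape) if noise_sd > 0 else 0.0
        pm = signal + mm + noise
        for a, bad_sets in corrupted.items():
            if s in bad_sets:
                # heavy-tailed corruption breaks the rank-1 response pattern
                pm[:, a] = mm[:, a] + np.abs(
                    rng.standard_cauchy(pairs_per_set)
                ) * 10 * float(np.mean(theta))
        pm = np.maximum(pm, 0.0)
        blocks.append(ProbePairBlock(probe_set_id=f"ps{s:06d}", pm=pm, mm=mm))
    return blocks, theta


def write_truth_table(path, truth: TruthTable) -> None:
    from pathlib import Path

    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("probe_id\ttissue\tfold\n")
        for pid in sorted(truth.planted):
            tissue, fold = truth.planted[pid]
            fh.write(f"{pid}\t{tissue}\t{fold!r}\n")
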