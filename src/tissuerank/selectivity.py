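"""Tissue-selective gene scoring and permutation significance.

For a target tissue the samples split into an experiment set (size Ne)
and a control set (size Nc).  A sample shows *significant expression* of
a probe set when its detection call is Present and its value is at least
a threshold theta.  With Se and Sc the significant-expression counts in
the two sets, candidates satisfy ``Se >= min_se`` and ``Sc <= max_sc``
and are scored by

    score1 = log10(((Se + a) / Ne) / ((Sc + a) / Nc))        (a > 0 small)
    score2 = log10(Ee / Ec)
    score  = w1 * score1 + w2 * score2

where Ee is the mean value over the Se significant experiment samples
and Ec the mean of the Se largest control values.  Probe sets with
score2 <= 0 are excluded.  Significance comes from joint permutation of
each probe set's (value, call) pairs across all samples, re-splitting
into sets of the same sizes, and counting permutations whose score
reaches the observed one.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from tissuerank.core_model import Compendium, PRESENT, TissuePartition, partition_by_tissue


@dataclass(frozen=True)
class SelectivityConfig:
    """Every tunable of the candidate-selection and scoring stage."""

    theta: float = 1.0
    min_se: int = 1
    max_sc: int = 0
    w1: float = 1.0
    w2: float = 1.0
    pseudocount: float = 0.1
    n_permutations: int = 1_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.theta < 0:
            raise ValueError("theta must be >= 0")
        if self.min_se < 1:
            raise ValueError("min_se must be >= 1")
        if self.max_sc < 0:
            raise ValueError("max_sc must be >= 0")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")


@dataclass
class SelectivityResult:
    """Per-probe-set scoring record."""

    probe_id: str
    Se: int
    Sc: int
    Ee: float
    Ec: float
    fold: float
    score1: float
    score2: float
    score: float
    p_value: float | None = None
    #: count of permutations reaching the score; 0 means below resolution
    exceed_count: int | None = None

    def p_value_string(self, n_permutations: int) -> str:
        if self.p_value is None:
            return "-"
        if self.exceed_count == 0:
            return f"<{1.0 / n_permutations:g}"
        return f"{self.p_value:.6g}"


def is_significant(value: float, call: str, theta: float) -> bool:
    """True iff the call is Present and the value is at least theta."""
    return call == PRESENT and value >= theta


def significance_mask(
    values: np.ndarray, calls: np.ndarray, theta: float
) -> np.ndarray:
    """Vectorized is_significant over arrays of any matching shape."""
    return (np.asarray(calls) == PRESENT) & (np.asarray(values) >= theta)


def count_significant(
    values: np.ndarray,
    calls: np.ndarray,
    partition: TissuePartition,
    theta: float,
) -> tuple[int, int]:
    """(Se, Sc): significant-expression counts in experiment/control sets."""
    sig = significance_mask(values, calls, theta)
    exp_idx = np.fromiter(partition.experiment_index, dtype=int)
    ctl_idx = np.fromiter(partition.control_index, dtype=int)
    return int(sig[exp_idx].sum()), int(sig[ctl_idx].sum())


def candidate_filter(Se: int, Sc: int, config: SelectivityConfig) -> bool:
    """Keep probe sets with Se >= min_se and Sc <= max_sc (both inclusive)."""
    return Se >= config.min_se and Sc <= config.max_sc


def expression_means(
    values: np.ndarray,
    calls: np.ndarray,
    partition: TissuePartition,
    theta: float,
) -> tuple[float, float]:
    """(Ee, Ec): experiment mean over significant samples, top-Se control mean.

    Ec averages the Se largest control values (all controls if Se > Nc).
    Requires Se >= 1.
    """
    values = np.asarray(values, dtype=float)
    sig = significance_mask(values, calls, theta)
    exp_idx = np.fromiter(partition.experiment_index, dtype=int)
    ctl_idx = np.fromiter(partition.control_index, dtype=int)
    sig_exp = exp_idx[sig[exp_idx]]
    se = sig_exp.size
    if se == 0:
        raise ValueError("Se = 0: expression means undefined; filter first")
    ee = float(values[sig_exp].mean())
    ctl_values = values[ctl_idx]
    k = min(se, ctl_values.size)
    top = np.partition(ctl_values, ctl_values.size - k)[ctl_values.size - k :]
    ec = float(top.mean())
    return ee, ec


def score1(Se: int, Sc: int, Ne: int, Nc: int, alpha: float = 0.1) -> float:
    """Log10 contrast of smoothed significant-expression frequencies."""
    if Ne < 1 or Nc < 1:
        raise ValueError("Ne and Nc must be >= 1")
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    return float(np.log10(((Se + alpha) / Ne) / ((Sc + alpha) / Nc)))


def score2(Ee: float, Ec: float) -> float:
    """Log10 fold of experiment mean over top-Se control mean."""
    if Ee <= 0 or Ec <= 0:
        raise ValueError(f"means must be positive, got Ee={Ee}, Ec={Ec}")
    return float(np.log10(Ee / Ec))


def priority_score(s1: float, s2: float, w1: float = 1.0, w2: float = 1.0) -> float:
    return w1 * s1 + w2 * s2


def raw_priority_score(
    values: np.ndarray,
    calls: np.ndarray,
    partition: TissuePartition,
    config: SelectivityConfig,
) -> float:
    """Priority score without candidate filtering, -inf when degenerate.

    Degenerate means Se = 0 or a non-positive mean — the same convention
    used for permuted replicates, so a row's actual score is exchangeable
    with its permutation scores under a signal-free null.
    """
    se, sc = count_significant(values, calls, partition, config.theta)
    if se == 0:
        return float("-inf")
    ee, ec = expression_means(values, calls, partition, config.theta)
    if ee <= 0 or ec <= 0:
        return float("-inf")
    s1 = score1(se, sc, partition.n_experiment, partition.n_control, config.pseudocount)
    return priority_score(s1, score2(ee, ec), config.w1, config.w2)


def _probe_rng(seed: int, probe_id: str) -> np.random.Generator:
    """Seed-stable per-probe substream, independent of evaluation order."""
    return np.random.default_rng([seed, zlib.crc32(probe_id.encode("utf-8"))])


def score_probe(
    values: np.ndarray,
    calls: np.ndarray,
    partition: TissuePartition,
    config: SelectivityConfig,
    probe_id: str = "",
) -> SelectivityResult | None:
    """Score one probe-set row; None if it fails the filters.

    Applies the candidate filter (Se >= min_se, Sc <= max_sc) and drops
    rows with score2 <= 0 or a non-positive control mean.
    """
    se, sc = count_significant(values, calls, partition, config.theta)
    if not candidate_filter(se, sc, config):
        return None
    ee, ec = expression_means(values, calls, partition, config.theta)
    if ee <= 0 or ec <= 0:
        return None
    s2 = score2(ee, ec)
    if s2 <= 0:
        return None
    s1 = score1(se, sc, partition.n_experiment, partition.n_control, config.pseudocount)
    return SelectivityResult(
        probe_id=probe_id,
        Se=se,
        Sc=sc,
        Ee=ee,
        Ec=ec,
        fold=ee / ec,
        score1=s1,
        score2=s2,
        score=priority_score(s1, s2, config.w1, config.w2),
    )


def rank_tissue(
    compendium: Compendium,
    tissue: str,
    config: SelectivityConfig,
) -> list[SelectivityResult]:
    """Score every probe set for one tissue; return survivors ranked.

    The result contains exactly the probe sets passing the candidate
    filter with score2 > 0, sorted by priority score descending with ties
    broken by probe id.  Permutation p-values are not computed here; see
    :func:`attach_p_values`.
    """
    partition = partition_by_tissue(compendium, tissue)
    exp_idx = np.fromiter(partition.experiment_index, dtype=int)
    ctl_idx = np.fromiter(partition.control_index, dtype=int)
    sig = significance_mask(compendium.values, compendium.calls, config.theta)
    se_all = sig[:, exp_idx].sum(axis=1)
    sc_all = sig[:, ctl_idx].sum(axis=1)
    candidates = np.flatnonzero((se_all >= config.min_se) & (sc_all <= config.max_sc))

    results: list[SelectivityResult] = []
    for i in candidates:
        res = score_probe(
            compendium.values[i],
            compendium.calls[i],
            partition,
            config,
            probe_id=compendium.probe_ids[i],
        )
        if res is not None:
            results.append(res)
    results.sort(key=lambda r: (-r.score, r.probe_id))
    return results


def permutation_scores(
    values: np.ndarray,
    calls: np.ndarray,
    partition: TissuePartition,
    config: SelectivityConfig,
    rng: np.random.Generator,
    n_permutations: int | None = None,
    batch: int = 512,
) -> np.ndarray:
    """Priority scores of jointly permuted (value, call) rows.

    Each permutation shuffles the per-sample pairs and re-splits into
    experiment/control sets of the original sizes.  Degenerate
    permutations (Se = 0 or a non-positive mean) score -inf.  Vectorized
    in batches of permutations.
    """
    n_perm = config.n_permutations if n_permutations is None else n_permutations
    values = np.asarray(values, dtype=float)
    sig = significance_mask(values, calls, config.theta).astype(float)
    n = values.size
    ne, nc = partition.n_experiment, partition.n_control
    alpha, w1, w2 = config.pseudocount, config.w1, config.w2

    out = np.empty(n_perm)
    done = 0
    while done < n_perm:
        b = min(batch, n_perm - done)
        # each row of `perm` is an independent permutation of sample positions
        perm = np.argsort(rng.random((b, n)), axis=1)
        exp_pos = perm[:, :ne]
        ctl_pos = perm[:, ne:]
        se = sig[exp_pos].sum(axis=1)
        sig_vals = values * sig
        ee_sum = sig_vals[exp_pos].sum(axis=1)
        ctl_vals = values[ctl_pos]
        ctl_sorted = np.sort(ctl_vals, axis=1)[:, ::-1]
        csum = np.cumsum(ctl_sorted, axis=1)
        scores = np.full(b, -np.inf)
        ok = se >= 1
        if ok.any():
            se_ok = se[ok].astype(int)
            k = np.minimum(se_ok, nc)
            ee = ee_sum[ok] / se_ok
            ec = csum[ok, k - 1] / k
            valid = (ee > 0) & (ec > 0)
            s = np.full(ok.sum(), -np.inf)
            if valid.any():
                sc = sig[ctl_pos[ok]].sum(axis=1)
                s1 = np.log10(
                    ((se[ok] + alpha) / ne) / ((sc + alpha) / nc)
                )
                with np.errstate(divide="ignore", invalid="ignore"):
                    s2 = np.where(valid, np.log10(ee / ec), -np.inf)
                s = np.where(valid, w1 * s1 + w2 * s2, -np.inf)
            scores[ok] = s
        out[done : done + b] = scores
        done += b
    return out


def permutation_pvalue(
    values: np.ndarray,
    calls: np.ndarray,
    partition: TissuePartition,
    actual_score: float,
    config: SelectivityConfig,
    rng: np.random.Generator,
) -> tuple[float, int]:
    """Fraction of permutations scoring >= the actual priority score.

    Returns ``(p, exceed_count)`` with ``p = exceed_count /
    n_permutations``; an exceed count of 0 means the p-value is below the
    resolution 1/n_permutations and should be reported as such.
    """
    scores = permutation_scores(values, calls, partition, config, rng)
    exceed = int(np.count_nonzero(scores >= actual_score))
    return exceed / config.n_permutations, exceed


def attach_p_values(
    compendium: Compendium,
    tissue: str,
    results: list[SelectivityResult],
    config: SelectivityConfig,
) -> list[SelectivityResult]:
    """Compute permutation p-values for ranked results, in place.

    Each probe set uses a substream derived from the config seed and its
    id, so results do not depend on evaluation order.
    """
    partition = partition_by_tissue(compendium, tissue)
    index = {pid: i for i, pid in enumerate(compendium.probe_ids)}
    for res in results:
        i = index[res.probe_id]
        rng = _probe_rng(config.seed, res.probe_id)
        p, exceed = permutation_pvalue(
            compendium.values[i],
            compendium.calls[i],
            partition,
            res.score,
            config,
            rng,
        )
        res.p_value = p
        res.exceed_count = exceed
    return results


def write_results(path, results: list[SelectivityResult], config: SelectivityConfig) -> None:
    """Write ranked results as TSV, scores at 4 d.p."""
    from pathlib import Path

    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write(
            "probe_id\tSe\tSc\tEe\tEc\tfold\tscore1\tscore2\tscore\tp_value\n"
        )
        for r in results:
            fh.write(
                f"{r.probe_id}\t{r.Se}\t{r.Sc}\t{r.Ee:.4f}\t{r.Ec:.4f}"
                f"\t{r.fold:.4f}\t{r.score1:.4f}\t{r.score2:.4f}\t{r.score:.4f}"
                f"\t{r.p_value_string(config.n_permutations)}\n"
            )
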