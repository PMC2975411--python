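"""Domain types, tab-separated I/O, validation and tissue partitioning.

File dialect (all three tables): tab-separated, UTF-8, '.' decimal point,
no quoting.  Matrix files carry a header row of sample ids and a first
column of probe-set ids.  The annotation table has the header
``sample_id\ttissue\tgroup\tstudy``.

Detection calls use the single-letter Affymetrix convention ``P`` / ``M``
/ ``A`` (Present / Marginal / Absent); full words are accepted
case-insensitively on input.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

PRESENT = "P"
MARGINAL = "M"
ABSENT = "A"

CALL_ALPHABET = (PRESENT, MARGINAL, ABSENT)

_CALL_SYNONYMS = {
    "p": PRESENT,
    "present": PRESENT,
    "m": MARGINAL,
    "marginal": MARGINAL,
    "a": ABSENT,
    "absent": ABSENT,
}


class FormatError(ValueError):
    """Malformed file layout (wrong cell count, bad header)."""


class MatrixValueError(ValueError):
    """A cell failed to parse (non-numeric, negative, unknown call symbol)."""


class StructuralError(ValueError):
    """Dimension mismatch between parallel tables."""


class MembershipError(ValueError):
    """Sample sets of matrix and annotation table disagree."""


class PartitionError(ValueError):
    """A tissue partition would leave one side empty."""


@dataclass(frozen=True)
class SampleAnnotation:
    """Per-sample metadata: tissue label, normalization group, study."""

    sample_id: str
    tissue_label: str
    normalization_group: str
    study_id: str = ""

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValueError("sample_id must be non-empty")
        if not self.tissue_label.strip():
            raise ValueError(f"tissue_label empty for sample {self.sample_id!r}")
        if not self.normalization_group.strip():
            raise ValueError(
                f"normalization_group empty for sample {self.sample_id!r}"
            )


@dataclass
class Compendium:
    """Probe-set x sample expression values with parallel detection calls.

    ``values`` is a non-negative float matrix, ``calls`` a matrix over
    ``{P, M, A}``; both are probe x sample with rows/columns matching
    ``probe_ids`` / ``sample_ids``.  A transcript with an Absent call may
    still carry a positive expression value — the two matrices are
    independent measurements.
    """

    probe_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    calls: np.ndarray
    annotations: list[SampleAnnotation]

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def annotation_for(self, sample_id: str) -> SampleAnnotation:
        return self.annotations[self.sample_ids.index(sample_id)]

    def tissue_labels(self) -> list[str]:
        return [a.tissue_label for a in self.annotations]


@dataclass(frozen=True)
class TissuePartition:
    """Experiment/control split of sample positions for one tissue."""

    tissue: str
    experiment_index: tuple[int, ...]
    control_index: tuple[int, ...]

    @property
    def n_experiment(self) -> int:
        return len(self.experiment_index)

    @property
    def n_control(self) -> int:
        return len(self.control_index)

    def __post_init__(self) -> None:
        exp = set(self.experiment_index)
        ctl = set(self.control_index)
        if exp & ctl:
            raise ValueError("experiment and control indices overlap")
        if not exp:
            raise PartitionError(f"no samples labelled {self.tissue!r}")
        if not ctl:
            raise PartitionError(f"tissue {self.tissue!r} covers every sample")


# ---------------------------------------------------------------------------
# readers / writers


def _read_table(path: str | Path) -> tuple[list[str], list[str], list[list[str]]]:
    """Split a matrix TSV into header sample ids, probe ids and body cells."""
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise FormatError(f"{path}: empty file")
    header = lines[0].split("\t")
    if len(header) < 2:
        raise FormatError(f"{path}: header must name at least one sample")
    sample_ids = [s.strip() for s in header[1:]]
    n = len(sample_ids)
    probe_ids: list[str] = []
    rows: list[list[str]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        cells = line.split("\t")
        if len(cells) != n + 1:
            raise FormatError(
                f"{path}: line {lineno} has {len(cells)} cells, expected {n + 1}"
            )
        probe_ids.append(cells[0].strip())
        rows.append(cells[1:])
    dupes = _duplicates(probe_ids)
    if dupes:
        raise MatrixValueError(f"{path}: duplicate probe ids {sorted(dupes)}")
    return sample_ids, probe_ids, rows


def _duplicates(items: Iterable[str]) -> set[str]:
    seen: set[str] = set()
    dup: set[str] = set()
    for item in items:
        if item in seen:
            dup.add(item)
        seen.add(item)
    return dup


def read_expression_matrix(
    path: str | Path,
) -> tuple[list[str], list[str], np.ndarray]:
    """Read a probe x sample expression TSV.

    Returns ``(probe_ids, sample_ids, values)`` preserving file order.
    Raises :class:`FormatError` on layout problems and
    :class:`MatrixValueError` on negative or non-numeric cells, naming the
    offending location.
    """
    sample_ids, probe_ids, rows = _read_table(path)
    values = np.empty((len(probe_ids), len(sample_ids)), dtype=float)
    for i, row in enumerate(rows):
        for j, cell in enumerate(row):
            try:
                v = float(cell)
            except ValueError:
                raise MatrixValueError(
                    f"{path}: non-numeric cell {cell!r} at probe "
                    f"{probe_ids[i]!r}, sample {sample_ids[j]!r}"
                ) from None
            if not np.isfinite(v) or v < 0:
                raise MatrixValueError(
                    f"{path}: invalid value {cell!r} at probe "
                    f"{probe_ids[i]!r}, sample {sample_ids[j]!r} (must be >= 0)"
                )
            values[i, j] = v
    return probe_ids, sample_ids, values


def write_expression_matrix(
    path: str | Path,
    probe_ids: Sequence[str],
    sample_ids: Sequence[str],
    values: np.ndarray,
) -> None:
    """Write a probe x sample matrix; floats use shortest round-trip form."""
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("probe_id\t" + "\t".join(sample_ids) + "\n")
        for pid, row in zip(probe_ids, values):
            fh.write(pid + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def read_call_matrix(path: str | Path) -> tuple[list[str], list[str], np.ndarray]:
    """Read a probe x sample detection-call TSV (alphabet P/M/A)."""
    sample_ids, probe_ids, rows = _read_table(path)
    calls = np.empty((len(probe_ids), len(sample_ids)), dtype="<U1")
    for i, row in enumerate(rows):
        for j, cell in enumerate(row):
            symbol = _CALL_SYNONYMS.get(cell.strip().lower())
            if symbol is None:
                raise MatrixValueError(
                    f"{path}: unknown call symbol {cell!r} at probe "
                    f"{probe_ids[i]!r}, sample {sample_ids[j]!r}"
                )
            calls[i, j] = symbol
    return probe_ids, sample_ids, calls


def write_call_matrix(
    path: str | Path,
    probe_ids: Sequence[str],
    sample_ids: Sequence[str],
    calls: np.ndarray,
) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("probe_id\t" + "\t".join(sample_ids) + "\n")
        for pid, row in zip(probe_ids, calls):
            fh.write(pid + "\t" + "\t".join(row) + "\n")


def read_annotations(path: str | Path) -> list[SampleAnnotation]:
    """Read the sample annotation TSV (sample_id, tissue, group, study)."""
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise FormatError(f"{path}: empty file")
    header = [c.strip().lower() for c in lines[0].split("\t")]
    if header[:3] != ["sample_id", "tissue", "group"]:
        raise FormatError(
            f"{path}: expected header 'sample_id\\ttissue\\tgroup\\tstudy', "
            f"got {lines[0]!r}"
        )
    annotations: list[SampleAnnotation] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        cells = line.split("\t")
        if len(cells) < 3:
            raise FormatError(f"{path}: line {lineno} has fewer than 3 cells")
        study = cells[3].strip() if len(cells) > 3 else ""
        annotations.append(
            SampleAnnotation(
                sample_id=cells[0].strip(),
                tissue_label=cells[1].strip(),
                normalization_group=cells[2].strip(),
                study_id=study,
            )
        )
    dupes = _duplicates(a.sample_id for a in annotations)
    if dupes:
        raise MembershipError(f"{path}: duplicate sample ids {sorted(dupes)}")
    return annotations


def write_annotations(path: str | Path, annotations: Sequence[SampleAnnotation]) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("sample_id\ttissue\tgroup\tstudy\n")
        for a in annotations:
            fh.write(
                f"{a.sample_id}\t{a.tissue_label}\t{a.normalization_group}"
                f"\t{a.study_id}\n"
            )


# ---------------------------------------------------------------------------
# validation / partitioning


def validate_compendium(
    probe_ids: Sequence[str],
    sample_ids: Sequence[str],
    values: np.ndarray,
    calls: np.ndarray,
    annotations: Sequence[SampleAnnotation],
) -> Compendium:
    """Check all invariants and return a consistently ordered Compendium.

    Annotation rows are reordered to match matrix column order; matrix
    column order itself is preserved.
    """
    values = np.asarray(values, dtype=float)
    calls = np.asarray(calls, dtype="<U1")
    shape = (len(probe_ids), len(sample_ids))
    if values.shape != shape:
        raise StructuralError(
            f"values shape {values.shape} does not match declared {shape}"
        )
    if calls.shape != shape:
        raise StructuralError(
            f"calls shape {calls.shape} does not match values shape {values.shape}"
        )
    if np.any(values < 0):
        i, j = np.argwhere(values < 0)[0]
        raise MatrixValueError(
            f"negative value at probe {probe_ids[i]!r}, sample {sample_ids[j]!r}"
        )
    bad = ~np.isin(calls, CALL_ALPHABET)
    if np.any(bad):
        i, j = np.argwhere(bad)[0]
        raise MatrixValueError(
            f"unknown call {calls[i, j]!r} at probe {probe_ids[i]!r}, "
            f"sample {sample_ids[j]!r}"
        )
    dupes = _duplicates(probe_ids)
    if dupes:
        raise MatrixValueError(f"duplicate probe ids {sorted(dupes)}")
    by_id = {a.sample_id: a for a in annotations}
    if len(by_id) != len(annotations):
        raise MembershipError("duplicate sample ids in annotations")
    matrix_set = set(sample_ids)
    missing = sorted(matrix_set - set(by_id))
    extra = sorted(set(by_id) - matrix_set)
    if missing or extra:
        raise MembershipError(
            f"sample sets disagree: in matrix but unannotated {missing}, "
            f"annotated but absent from matrix {extra}"
        )
    ordered = [by_id[s] for s in sample_ids]
    return Compendium(
        probe_ids=list(probe_ids),
        sample_ids=list(sample_ids),
        values=values,
        calls=calls,
        annotations=ordered,
    )


def partition_by_tissue(compendium: Compendium, tissue: str) -> TissuePartition:
    """Split sample positions into experiment (== tissue) and control sets.

    Matching is exact string equality after whitespace trimming.
    """
    wanted = tissue.strip()
    experiment = tuple(
        i
        for i, a in enumerate(compendium.annotations)
        if a.tissue_label.strip() == wanted
    )
    control = tuple(
        i
        for i, a in enumerate(compendium.annotations)
        if a.tissue_label.strip() != wanted
    )
    return TissuePartition(
        tissue=wanted, experiment_index=experiment, control_index=control
    )


def partition_from_labels(labels: Sequence[str], tissue: str) -> TissuePartition:
    """Partition directly from a list of tissue labels (no Compendium needed)."""
    wanted = tissue.strip()
    experiment = tuple(i for i, t in enumerate(labels) if t.strip() == wanted)
    control = tuple(i for i, t in enumerate(labels) if t.strip() != wanted)
    return TissuePartition(
        tissue=wanted, experiment_index=experiment, control_index=control
    )
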