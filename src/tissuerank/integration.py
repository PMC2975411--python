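"""Merging normalized groups into one compendium on a common median scale.

Profiles from different normalization groups have different medians, so
every retained profile is divided by its own median before integration;
the integrated dataset then has one shared profile median, 1.00.  The
sample median is the standard convention: middle element for odd counts,
midpoint mean for even counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from tissuerank.core_model import (
    Compendium,
    PRESENT,
    SampleAnnotation,
    StructuralError,
    validate_compendium,
)


class DegenerateProfileError(ValueError):
    """A profile whose median is not positive cannot be median-scaled."""


@dataclass
class GroupData:
    """One normalized group awaiting integration."""

    probe_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    calls: np.ndarray | None = None
    excluded: set[int] | None = None


def median_transform(profile: np.ndarray) -> np.ndarray:
    """Divide a profile by its median so the output median is 1.00."""
    profile = np.asarray(profile, dtype=float)
    med = float(np.median(profile))
    if med <= 0:
        raise DegenerateProfileError(
            f"profile median {med} is not positive (n={profile.size}, "
            f"min={profile.min() if profile.size else 'n/a'})"
        )
    return profile / med


def integrate(
    groups: Sequence[GroupData],
    annotations: Sequence[SampleAnnotation],
) -> Compendium:
    """Drop excluded samples, median-scale the rest, merge into a Compendium.

    All groups must share one probe-id list in identical order.  Groups
    lacking a call matrix contribute all-Present calls (external calls are
    the primary input path; this keeps value-only groups usable).
    """
    if not groups:
        raise ValueError("no groups to integrate")
    probe_ids = groups[0].probe_ids
    for g in groups[1:]:
        if g.probe_ids != probe_ids:
            divergent = next(
                (a for a, b in zip(probe_ids, g.probe_ids) if a != b),
                "<length mismatch>",
            )
            raise StructuralError(
                f"probe-id mismatch between groups, first divergence at "
                f"{divergent!r}"
            )

    columns: list[np.ndarray] = []
    call_columns: list[np.ndarray] = []
    sample_ids: list[str] = []
    for g in groups:
        excluded = g.excluded or set()
        for j, sid in enumerate(g.sample_ids):
            if j in excluded:
                continue
            columns.append(median_transform(g.values[:, j]))
            if g.calls is not None:
                call_columns.append(g.calls[:, j])
            else:
                call_columns.append(np.full(len(probe_ids), PRESENT, dtype="<U1"))
            sample_ids.append(sid)

    values = np.column_stack(columns)
    calls = np.column_stack(call_columns)
    kept = set(sample_ids)
    kept_annotations = [a for a in annotations if a.sample_id in kept]
    return validate_compendium(probe_ids, sample_ids, values, calls, kept_annotations)


def median_transform_compendium(compendium: Compendium) -> Compendium:
    """Return a copy with every sample column divided by its own median."""
    values = np.column_stack(
        [median_transform(compendium.values[:, j]) for j in range(compendium.n_samples)]
    )
    return Compendium(
        probe_ids=list(compendium.probe_ids),
        sample_ids=list(compendium.sample_ids),
        values=values,
        calls=compendium.calls.copy(),
        annotations=list(compendium.annotations),
    )


def write_provenance(
    path: str | Path,
    group_sizes: dict[str, int],
    baselines: dict[str, str],
    exclusions: dict[str, list[str]],
) -> None:
    """Plain-text sidecar: per-group sizes, chosen baselines, exclusions."""
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("# integration provenance\n")
        for name in sorted(group_sizes):
            fh.write(
                f"group\t{name}\tsize\t{group_sizes[name]}"
                f"\tbaseline\t{baselines.get(name, '-')}"
                f"\texcluded\t{','.join(exclusions.get(name, [])) or '-'}\n"
            )
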