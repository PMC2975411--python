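import numpy as np
import pytest

from tissuerank.core_model import (
    SampleAnnotation,
    partition_from_labels,
    validate_compendium,
)


@pytest.fixture
def small_compendium():
    """4 probes x 6 samples, two tissues, hand-checkable."""
    probe_ids = ["p1", "p2", "p3", "p4"]
    sample_ids = [f"s{i}" for i in range(6)]
    values = np.array(
        [
            [5.0, 4.0, 6.0, 0.2, 0.1, 0.3],  # brain-selective
            [1.0, 1.0, 1.0, 1.0, 1.0, 1.0],  # flat
            [0.1, 0.2, 0.1, 3.0, 4.0, 5.0],  # liver-selective
            [2.0, 2.0, 2.0, 2.0, 2.0, 2.0],  # flat, high
        ]
    )
    calls = np.array(
        [
            ["P", "P", "P", "A", "A", "A"],
            ["P", "P", "P", "P", "P", "P"],
            ["A", "A", "A", "P", "P", "P"],
            ["P", "P", "P", "P", "P", "P"],
        ]
    )
    annotations = [
        SampleAnnotation(f"s{i}", "brain" if i < 3 else "liver", "g1", "st1")
        for i in range(6)
    ]
    return validate_compendium(probe_ids, sample_ids, values, calls, annotations)


@pytest.fixture
def partition_10_90():
    return partition_from_labels(["t"] * 10 + ["c"] * 90, "t")
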