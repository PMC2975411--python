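"""Bundled reference tables.

``compendium_profile_counts.tsv`` records, per tissue, how many public
expression profiles were curated for the reference compendium and how
many survived outlier-array exclusion.  It is used for bookkeeping checks
(total compendium size, number of excluded arrays).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def load_profile_counts() -> pd.DataFrame:
    """Tissue-level profile counts: columns tissue, n_selected, n_integrated."""
    ref = resources.files("tissuerank.data").joinpath("compendium_profile_counts.tsv")
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")
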