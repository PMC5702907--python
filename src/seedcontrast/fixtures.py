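"""Loaders for the packaged in-paper table fixtures.

``table1``: tissue-specific and differentially accumulated metabolites
(compound, class, endosperm/embryo log2 ratio, FDR, tissue-specific flag).
``table2``: the 64 z-score differential proteins with their log2 ratios.
``table3``: folding/chaperone proteins with tissue specificity.
``results_counts``: the per-tissue detection and list-size counts printed in
the results text, used as inputs to the set-arithmetic checks.
"""

from __future__ import annotations

from importlib import resources
from io import StringIO

import pandas as pd


def _read(name: str, **kwargs) -> pd.DataFrame:
    text = resources.files("seedcontrast.data").joinpath(name).read_text()
    return pd.read_csv(StringIO(text), sep="\t", **kwargs)


def load_table1() -> pd.DataFrame:
    """Metabolite contrast fixture; NA log2_ratio marks tissue-specific rows."""
    return _read("table1.tsv", na_values=["NA"])


def load_table2() -> pd.DataFrame:
    """Differential-protein fixture (64 rows, endosperm/embryo log2 ratios)."""
    return _read("table2.tsv")


def load_table3() -> pd.DataFrame:
    """Chaperone/folding protein fixture with tissue specificity labels."""
    return _read("table3.tsv", na_values=["NA"])


def load_results_counts() -> dict:
    """Printed per-tissue detection/list-size counts as a key -> int map."""
    df = _read("results_counts.tsv")
    return dict(zip(df["key"], df["value"].astype(int)))
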