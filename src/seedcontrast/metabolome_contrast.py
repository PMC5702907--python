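"""Dry-weight-normalized metabolite contrasts between seed compartments.

Per-mg peak areas are converted to per-seed abundances through the seed mass
model (tissue dry-weight fractions x whole-seed dry mass), tissue-specific
metabolites are called from replicate detection counts, and common
metabolites are tested with an equal-variance t-test under FDR control.

A metabolite record table has columns ``name``, ``class``, ``tissue``,
``replicate`` and ``peak_area_per_mg`` (NaN = not detected).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from seedcontrast.proteomics_quant import FeaturePartition, partition_features

RECORD_COLUMNS = ["name", "class", "tissue", "replicate", "peak_area_per_mg"]


@dataclass(frozen=True)
class SeedMassModel:
    """Per-seed dry-mass fractions used to scale per-mg abundances.

    Defaults reflect a cereal seed whose embryo is 2% of whole-seed dry
    weight with the endosperm accounting for the remaining 98%.
    """

    embryo_fraction: float = 0.02
    endosperm_fraction: float = 0.98
    seed_dw_mg: float = 25.0

    def __post_init__(self):
        if self.embryo_fraction < 0 or self.endosperm_fraction < 0:
            raise ValueError("tissue fractions must be >= 0")
        if abs(self.embryo_fraction + self.endosperm_fraction - 1.0) > 1e-9:
            raise ValueError("tissue fractions must sum to 1")
        if self.seed_dw_mg <= 0:
            raise ValueError("seed_dw_mg must be positive")

    def fraction_of(self, tissue: str) -> float:
        try:
            return {"embryo": self.embryo_fraction,
                    "endosperm": self.endosperm_fraction}[tissue]
        except KeyError:
            raise ValueError(f"unknown tissue {tissue!r}") from None

    def tissue_mass_mg(self, tissue: str) -> float:
        return self.fraction_of(tissue) * self.seed_dw_mg


def per_seed_normalize(
    records: pd.DataFrame, mass: SeedMassModel
) -> pd.DataFrame:
    """Scale per-mg peak areas to per-seed abundances.

    ``per_seed = peak_area_per_mg * tissue_fraction * seed_dw_mg``, so the
    per-seed log2 tissue ratio equals the per-mg ratio shifted by
    ``log2(endosperm_fraction / embryo_fraction)``.
    """
    out = records.copy()
    out["per_seed_area"] = [
        area * mass.tissue_mass_mg(tissue)
        for area, tissue in zip(out["peak_area_per_mg"], out["tissue"])
    ]
    return out


def call_tissue_specific(
    records: pd.DataFrame, min_detections: int = 2
) -> FeaturePartition:
    """Partition metabolites into embryo-specific/endosperm-specific/common.

    A metabolite counts as detected in a tissue when at least
    ``min_detections`` replicates there carry a non-missing area; metabolites
    detected in exactly one tissue are tissue-specific.
    """
    detected = {}
    for tissue in ("embryo", "endosperm"):
        sub = records[records["tissue"] == tissue]
        counts = sub.groupby("name")["peak_area_per_mg"].count()
        detected[tissue] = set(counts[counts >= min_detections].index)
    return partition_features(detected["embryo"], detected["endosperm"])


def differential_metabolites(
    per_seed: pd.DataFrame,
    common=None,
    alpha: float = 0.05,
    fdr_method: str = "bh",
) -> pd.DataFrame:
    """Equal-variance t-test + FDR on per-seed abundances of common features.

    Positive log2 ratios mark endosperm-favored accumulation.  Metabolites
    with zero variance in both tissues are untestable and excluded from the
    FDR family.  ``fdr_method`` is ``bh`` (step-up) or ``by``.
    """
    if fdr_method not in ("bh", "by"):
        raise ValueError("fdr_method must be 'bh' or 'by'")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if common is None:
        common = call_tissue_specific(per_seed).common

    rows = []
    for name in sorted(common):
        sub = per_seed[per_seed["name"] == name]
        x = sub.loc[sub["tissue"] == "endosperm", "per_seed_area"].dropna()
        y = sub.loc[sub["tissue"] == "embryo", "per_seed_area"].dropna()
        if len(x) < 2 or len(y) < 2:
            continue
        mean_x, mean_y = x.mean(), y.mean()
        if x.var(ddof=1) + y.var(ddof=1) == 0:
            continue  # untestable: flat in both groups
        t, p = stats.ttest_ind(x, y, equal_var=True)
        log2_ratio = (
            np.log2(mean_x / mean_y) if mean_x > 0 and mean_y > 0 else np.nan
        )
        rows.append(
            {
                "feature_id": name,
                "log2_ratio": log2_ratio,
                "t": float(t),
                "p": float(p),
                "mean_endosperm": float(mean_x),
                "mean_embryo": float(mean_y),
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "feature_id", "log2_ratio", "t", "p",
            "mean_endosperm", "mean_embryo",
        ],
    )
    if len(out):
        method = "fdr_bh" if fdr_method == "bh" else "fdr_by"
        out["p_adj"] = multipletests(out["p"], method=method)[1]
        out["significant"] = out["p_adj"] < alpha
    else:
        out["p_adj"] = pd.Series(dtype=float)
        out["significant"] = pd.Series(dtype=bool)
    return out
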