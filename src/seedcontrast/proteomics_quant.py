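"""Label-free peptide-ion to protein quantification and tissue contrasts.

The quantification rollup proceeds in four steps: (1) drop peptide ions that
are shared between proteins or irreproducibly detected, (2) collapse repeated
detections of an ion within one biological sample by area summation,
(3) sum ion areas per protein to obtain per-replicate protein abundances, and
(4) contrast tissue means on the log2 scale.  Downstream, common proteins are
classified as tissue-favored against per-sign median thresholds and tested
for differential accumulation with a z-score on the log2 ratios.

Tables are plain :class:`pandas.DataFrame` objects.  A peptide-ion table has
columns ``ion_id``, ``protein_ids`` (``;``-separated identifiers), ``tissue``,
``replicate`` and ``area`` (NaN = not detected).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

ION_COLUMNS = ["ion_id", "protein_ids", "tissue", "replicate", "area"]

TISSUE_A = "embryo"
TISSUE_B = "endosperm"


# ---------------------------------------------------------------------------
# feature partitioning (generic: proteins, probes, metabolites)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeaturePartition:
    """Specific-A / specific-B / common decomposition of two detected sets."""

    specific_a: frozenset
    specific_b: frozenset
    common: frozenset

    @property
    def union(self) -> frozenset:
        return self.specific_a | self.specific_b | self.common

    @property
    def n_union(self) -> int:
        return len(self.union)

    @property
    def shared_percent(self) -> float:
        """Percentage of the union detected in both tissues."""
        if not self.union:
            return float("nan")
        return 100.0 * len(self.common) / len(self.union)

    def counts(self) -> dict:
        return {
            "specific_a": len(self.specific_a),
            "specific_b": len(self.specific_b),
            "common": len(self.common),
            "union": self.n_union,
        }


def partition_features(detected_a, detected_b) -> FeaturePartition:
    """Partition two detected feature sets into specific and common subsets.

    Inclusion-exclusion holds exactly:
    ``|union| = |A| + |B| - |common|``.
    """
    a = frozenset(detected_a)
    b = frozenset(detected_b)
    return FeaturePartition(
        specific_a=a - b,
        specific_b=b - a,
        common=a & b,
    )


# ---------------------------------------------------------------------------
# peptide-ion filtering
# ---------------------------------------------------------------------------

@dataclass
class FilterReport:
    """Row counts removed per filtering reason."""

    n_input_rows: int = 0
    n_nonspecific_rows: int = 0
    n_irreproducible_rows: int = 0
    n_retained_rows: int = 0
    n_nonspecific_ions: int = 0
    n_irreproducible_ion_tissues: int = 0

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def _split_proteins(protein_ids: str) -> list:
    return [p for p in str(protein_ids).split(";") if p]


def validate_ion_table(table: pd.DataFrame, n_replicates: int = 3) -> None:
    missing = [c for c in ION_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"peptide-ion table missing columns: {missing}")
    reps = table["replicate"]
    if len(table) and ((reps < 1) | (reps > n_replicates)).any():
        bad = sorted(reps[(reps < 1) | (reps > n_replicates)].unique().tolist())
        raise ValueError(
            f"replicate indices {bad} outside 1..{n_replicates}"
        )
    areas = table["area"]
    if len(table) and (areas.dropna() < 0).any():
        raise ValueError("negative peptide-ion areas are not allowed")


def filter_peptide_ions(
    table: pd.DataFrame,
    min_detections: int = 2,
    n_replicates: int = 3,
) -> tuple[pd.DataFrame, FilterReport]:
    """Keep ions specific to a single protein and reproducibly detected.

    An ion is retained within a tissue when it maps to exactly one protein and
    has at least ``min_detections`` non-missing areas among that tissue's
    replicates.  Filtering is applied per tissue independently, so an ion may
    survive in one tissue and be dropped in the other.
    """
    if min_detections > n_replicates:
        raise ValueError(
            f"min_detections ({min_detections}) exceeds "
            f"n_replicates ({n_replicates})"
        )
    validate_ion_table(table, n_replicates=n_replicates)
    report = FilterReport(n_input_rows=len(table))

    n_prot = table["protein_ids"].map(lambda s: len(_split_proteins(s)))
    if len(table) and (n_prot == 0).any():
        raise ValueError("every peptide ion must map to >=1 protein")
    specific = table[n_prot == 1].copy()
    report.n_nonspecific_rows = len(table) - len(specific)
    report.n_nonspecific_ions = table.loc[n_prot > 1, "ion_id"].nunique()

    detected = specific["area"].notna()
    n_det = (
        detected.groupby([specific["ion_id"], specific["tissue"]])
        .transform("sum")
    )
    keep = n_det >= min_detections
    report.n_irreproducible_rows = int((~keep).sum())
    grp = specific.groupby(["ion_id", "tissue"], sort=False)["area"]
    report.n_irreproducible_ion_tissues = int(
        (grp.count() < min_detections).sum()
    )
    out = specific[keep].reset_index(drop=True)
    report.n_retained_rows = len(out)
    return out, report


def sum_within_sample(table: pd.DataFrame) -> pd.DataFrame:
    """Collapse repeated detections of an ion within one biological sample.

    Rows sharing (ion_id, protein_ids, tissue, replicate) are merged with
    their areas summed; all-missing groups stay missing.  Order-independent.
    """
    if table.empty:
        return table.copy()
    out = (
        table.groupby(
            ["ion_id", "protein_ids", "tissue", "replicate"], sort=True
        )["area"]
        .sum(min_count=1)
        .reset_index()
    )
    return out[ION_COLUMNS]


def rollup_protein_abundance(table: pd.DataFrame) -> pd.DataFrame:
    """Sum ion areas into per-(protein, tissue, replicate) abundances.

    Expects a table already ion-filtered (single-protein ions) and
    sample-summed.  Returns columns ``protein_id``, ``tissue``, ``replicate``,
    ``abundance`` (exp scale) and ``log2_abundance``.  Proteins without a
    single detected replicate in either tissue are excluded with a warning.
    """
    work = table.copy()
    n_prot = work["protein_ids"].map(lambda s: len(_split_proteins(s)))
    if len(work) and (n_prot != 1).any():
        raise ValueError("rollup requires single-protein ions; filter first")
    work["protein_id"] = work["protein_ids"]
    rolled = (
        work.groupby(["protein_id", "tissue", "replicate"], sort=True)["area"]
        .sum(min_count=1)
        .reset_index()
        .rename(columns={"area": "abundance"})
    )
    detected_any = (
        rolled["abundance"].notna().groupby(rolled["protein_id"]).transform("any")
    )
    n_dropped = rolled.loc[~detected_any, "protein_id"].nunique()
    if n_dropped:
        warnings.warn(
            f"{n_dropped} protein(s) without any detected replicate excluded",
            stacklevel=2,
        )
        rolled = rolled[detected_any].reset_index(drop=True)
    with np.errstate(divide="ignore"):
        rolled["log2_abundance"] = np.log2(rolled["abundance"])
    return rolled


def protein_tissue_means(
    rollup: pd.DataFrame, mode: str = "mean-of-raw"
) -> pd.DataFrame:
    """Per-protein per-tissue mean abundance on the exp scale.

    ``mean-of-raw`` averages the exp-scale replicate abundances (arithmetic
    mean); ``mean-of-log`` averages the per-replicate log2 abundances and
    exponentiates back (geometric mean).  Missing replicates are excluded
    from the mean, never imputed as zero.
    """
    if mode == "mean-of-raw":
        means = rollup.groupby(["protein_id", "tissue"])["abundance"].mean()
    elif mode == "mean-of-log":
        means = (
            rollup.groupby(["protein_id", "tissue"])["log2_abundance"]
            .mean()
            .pipe(lambda s: np.power(2.0, s))
        )
    else:
        raise ValueError(f"unknown ratio mode: {mode!r}")
    wide = means.unstack("tissue")
    wide.index.name = "feature_id"
    return wide


def detected_features(rollup: pd.DataFrame) -> dict:
    """Map tissue -> set of proteins with >=1 detected replicate there."""
    det = rollup[rollup["abundance"].notna()]
    return {
        tissue: set(grp["protein_id"])
        for tissue, grp in det.groupby("tissue")
    }


# ---------------------------------------------------------------------------
# ratio table and contrast statistics
# ---------------------------------------------------------------------------

def tissue_log2_ratio(
    tissue_means: pd.DataFrame,
    numerator: str = TISSUE_B,
    denominator: str = TISSUE_A,
) -> pd.DataFrame:
    """log2(mean numerator-tissue / mean denominator-tissue) per feature.

    Features missing a mean, or with a non-positive mean, in either tissue
    are excluded with a warning.  Positive ratios indicate higher abundance
    in the numerator tissue (endosperm-favored under the default orientation).
    """
    for t in (numerator, denominator):
        if t not in tissue_means.columns:
            raise ValueError(f"tissue {t!r} absent from the means table")
    num = tissue_means[numerator]
    den = tissue_means[denominator]
    ok = num.notna() & den.notna() & (num > 0) & (den > 0)
    n_bad = int((~ok & (num.notna() & den.notna())).sum())
    if n_bad:
        warnings.warn(
            f"{n_bad} feature(s) with non-positive tissue mean excluded",
            stacklevel=2,
        )
    ratios = np.log2(num[ok]) - np.log2(den[ok])
    out = pd.DataFrame(
        {"feature_id": ratios.index, "log2_ratio": ratios.to_numpy()}
    )
    return out.reset_index(drop=True)


def favored_by_median(ratios: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Classify features as tissue-favored against per-sign medians.

    Within the positive-ratio subset, features strictly above that subset's
    median are endosperm-favored; within the negative-ratio subset, features
    strictly below that subset's median are embryo-favored.  Everything else
    is ``none``.  Both medians are returned (NaN when a subset is empty).
    """
    out = ratios.copy()
    r = out["log2_ratio"]
    pos = r[r > 0]
    neg = r[r < 0]
    pos_median = float(pos.median()) if len(pos) else float("nan")
    neg_median = float(neg.median()) if len(neg) else float("nan")
    cls = np.full(len(out), "none", dtype=object)
    if len(pos):
        cls[(r > 0) & (r > pos_median)] = "endosperm-favored"
    if len(neg):
        cls[(r < 0) & (r < neg_median)] = "embryo-favored"
    out["favored_class"] = cls
    thresholds = {"positive_median": pos_median, "negative_median": neg_median}
    return out, thresholds


def zscore_differential(
    ratios: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Standardize log2 ratios and flag two-sided normal-tail outliers.

    ``z = (r - mean(r)) / sd(r)`` with the sample standard deviation
    (ddof=1) over all input ratios; ``p`` is the two-sided standard-normal
    tail probability and ``significant`` means ``p < alpha``.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    r = ratios["log2_ratio"].to_numpy(dtype=float)
    if len(r) < 3:
        raise ValueError("z-score differential requires >=3 ratios")
    sd = r.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate input: all ratios identical (sd = 0)")
    out = ratios.copy()
    out["z"] = (r - r.mean()) / sd
    out["p"] = 2.0 * stats.norm.sf(np.abs(out["z"]))
    out["significant"] = out["p"] < alpha
    return out


def shapiro_normality(ratios) -> tuple[float, float]:
    """Shapiro-Wilk normality diagnostic (W, p) for 3 <= n <= 5000.

    Reported as a diagnostic only; no downstream step is gated on it.
    """
    r = np.asarray(ratios, dtype=float)
    if not 3 <= len(r) <= 5000:
        raise ValueError(
            f"Shapiro-Wilk requires 3 <= n <= 5000, got n={len(r)}"
        )
    res = stats.shapiro(r)
    return float(res.statistic), float(res.pvalue)
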