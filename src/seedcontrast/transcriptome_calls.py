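"""Probe-level presence consensus, differential testing and correlation.

Consumes normalized probe matrices (intensities already log-scale) together
with per-sample P/M/A detection calls; normalization internals are out of
scope.  Marginal (M) calls count as not-present.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

VALID_CALLS = frozenset("PMA")

CALL_RULES = ("majority", "all", "any")


@dataclass
class ProbeMatrix:
    """Normalized intensities + presence calls + the sample design map.

    ``intensities`` and ``calls`` are probe x sample frames with identical
    axes; ``design`` maps each sample to (tissue, replicate).
    """

    intensities: pd.DataFrame
    calls: pd.DataFrame
    design: pd.DataFrame  # columns: sample, tissue, replicate

    def __post_init__(self):
        if not self.intensities.index.equals(self.calls.index):
            raise ValueError("intensity and call matrices disagree on probes")
        if list(self.intensities.columns) != list(self.calls.columns):
            raise ValueError("intensity and call matrices disagree on samples")
        for col in ("sample", "tissue", "replicate"):
            if col not in self.design.columns:
                raise ValueError(f"design table missing column {col!r}")
        if set(self.design["sample"]) != set(self.intensities.columns):
            raise ValueError("design samples do not match matrix columns")
        bad = set(np.unique(self.calls.to_numpy())) - VALID_CALLS
        if bad:
            raise ValueError(f"unknown presence-call symbols: {sorted(bad)}")
        sizes = self.design.groupby("tissue")["sample"].size()
        if sizes.nunique() != 1:
            raise ValueError("tissues must have equal replicate counts")

    @property
    def tissues(self) -> list:
        return sorted(self.design["tissue"].unique())

    def samples_of(self, tissue: str) -> list:
        return self.design.loc[self.design["tissue"] == tissue, "sample"].tolist()


def consensus_detection(matrix: ProbeMatrix, rule: str = "majority") -> dict:
    """Per-tissue detected probe sets under a presence-call consensus rule.

    ``majority``: P in more than half of the tissue's replicates (>=2 of 3);
    ``all``: P in every replicate; ``any``: P in at least one.  Probes absent
    in both tissues are dropped from every returned set.
    """
    if rule not in CALL_RULES:
        raise ValueError(f"unknown consensus rule {rule!r}; use {CALL_RULES}")
    detected = {}
    for tissue in matrix.tissues:
        calls = matrix.calls[matrix.samples_of(tissue)]
        n_present = (calls == "P").sum(axis=1)
        n = calls.shape[1]
        if rule == "majority":
            mask = n_present * 2 > n
        elif rule == "all":
            mask = n_present == n
        else:
            mask = n_present >= 1
        detected[tissue] = set(calls.index[mask])
    return detected


def ttest_bonferroni(
    matrix: ProbeMatrix,
    probes=None,
    alpha: float = 0.01,
    tissue_num: str = "endosperm",
    tissue_den: str = "embryo",
) -> pd.DataFrame:
    """Equal-variance two-sample t-test per probe with Bonferroni control.

    ``probes`` restricts testing (typically probes detected in >=1 tissue);
    Bonferroni ``m`` counts only testable probes (pooled variance > 0).
    Untestable probes are returned flagged but carry no p-values and do not
    inflate ``m``.  ``direction`` names the tissue with the larger mean.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if probes is None:
        probes = list(matrix.intensities.index)
    probes = [p for p in matrix.intensities.index if p in set(probes)]
    x = matrix.intensities.loc[probes, matrix.samples_of(tissue_num)].to_numpy()
    y = matrix.intensities.loc[probes, matrix.samples_of(tissue_den)].to_numpy()
    if x.shape[1] < 2 or y.shape[1] < 2:
        raise ValueError("need >=2 replicates per group")

    mean_num = x.mean(axis=1)
    mean_den = y.mean(axis=1)
    pooled = x.var(axis=1, ddof=1) + y.var(axis=1, ddof=1)
    testable = pooled > 0

    t = np.full(len(probes), np.nan)
    p_raw = np.full(len(probes), np.nan)
    if testable.any():
        res = stats.ttest_ind(x[testable].T, y[testable].T, equal_var=True)
        t[testable] = res.statistic
        p_raw[testable] = res.pvalue
    m = int(testable.sum())
    p_adj = np.minimum(1.0, p_raw * m)

    out = pd.DataFrame(
        {
            "probe_id": probes,
            "t": t,
            "p_raw": p_raw,
            "p_adj": p_adj,
            f"mean_{tissue_num}": mean_num,
            f"mean_{tissue_den}": mean_den,
            "direction": np.where(mean_num >= mean_den, tissue_num, tissue_den),
            "testable": testable,
            "significant": p_adj < alpha,
        }
    )
    out.attrs["m"] = m
    out.attrs["alpha"] = alpha
    return out.reset_index(drop=True)


def strong_de_filter(
    de: pd.DataFrame,
    matrix: ProbeMatrix,
    detected_universe=None,
) -> pd.DataFrame:
    """Keep significant probes strongly expressed in their favored tissue.

    A differential probe survives when its mean intensity in the
    higher-mean tissue strictly exceeds the median of the per-probe mean
    intensities over all detected probes (the global expression median).
    """
    if detected_universe is None:
        detected_universe = list(matrix.intensities.index)
    pool = matrix.intensities.loc[sorted(detected_universe)].mean(axis=1)
    global_median = float(pool.median())
    sig = de[de["significant"]].copy()
    mean_cols = {
        c.removeprefix("mean_"): c for c in de.columns if c.startswith("mean_")
    }
    high_mean = np.array(
        [row[mean_cols[row["direction"]]] for _, row in sig.iterrows()]
    )
    out = sig[high_mean > global_median] if len(sig) else sig
    out = out.reset_index(drop=True)
    out.attrs["global_median"] = global_median
    return out


def pearson_correlation(x, y) -> tuple[float, float]:
    """Product-moment correlation with its two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("vectors must have equal length")
    if len(x) < 3:
        raise ValueError("correlation requires length >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("undefined correlation: zero-variance input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
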