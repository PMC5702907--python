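"""Hypergeometric over-representation testing with Benjamini-Yekutieli FDR.

Annotations are flat term -> locus sets; no ontology-graph propagation is
performed.  Only terms with at least one study hit enter the test family by
default (configurable), matching standard over-representation practice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class AnnotationMap:
    """Flat term annotations: term id -> set of annotated loci."""

    terms: dict  # term id -> set of loci
    labels: dict = field(default_factory=dict)

    def restricted_to(self, background) -> "AnnotationMap":
        bg = set(background)
        return AnnotationMap(
            terms={t: s & bg for t, s in self.terms.items()},
            labels=dict(self.labels),
        )


def hypergeom_pvalue(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail probability of >= k annotated hits in a draw of n.

    Exact hypergeometric survival probability
    ``P = sum_{i=k}^{min(n,K)} C(K,i) C(N-K,n-i) / C(N,n)`` computed in
    log space by scipy, stable for large backgrounds.
    """
    if not (0 <= k <= min(n, K)):
        raise ValueError(f"invalid counts: k={k}, n={n}, K={K}, N={N}")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def by_adjust(pvals) -> np.ndarray:
    """Benjamini-Yekutieli step-up adjustment (arbitrary dependence).

    With m tests and harmonic sum c(m) = sum_{k=1..m} 1/k, sorted p-values
    p_(i) receive q_(i) = min_{j>=i} min(1, m * c(m) * p_(j) / j); results
    are returned in the original order.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    c_m = np.sum(1.0 / np.arange(1, m + 1))
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    scaled = np.minimum(1.0, m * c_m * ranked / np.arange(1, m + 1))
    q_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(m)
    out[order] = q_sorted
    return out


def hypergeom_enrich(
    study,
    background,
    ann: AnnotationMap,
    alpha: float = 0.05,
    include_zero_hit_terms: bool = False,
) -> pd.DataFrame:
    """Over-representation of annotation terms in a study set.

    Each term annotated to >=1 study locus (or every term when
    ``include_zero_hit_terms``) is tested with the exact upper-tail
    hypergeometric probability against the background, then BY-adjusted.
    ``enriched`` means adjusted p < alpha.
    """
    study = set(study)
    background = set(background)
    if not background:
        raise ValueError("background must be non-empty")
    offenders = study - background
    if offenders:
        raise ValueError(
            "study loci outside the background: "
            + ", ".join(sorted(map(str, offenders))[:10])
        )
    restricted = ann.restricted_to(background)
    N, n = len(background), len(study)
    rows = []
    for term in sorted(restricted.terms):
        annotated = restricted.terms[term]
        K = len(annotated)
        k = len(annotated & study)
        if k == 0 and not include_zero_hit_terms:
            continue
        if K == 0:
            continue
        rows.append(
            {
                "term": term,
                "label": ann.labels.get(term, ""),
                "k": k,
                "n": n,
                "K": K,
                "N": N,
                "p": hypergeom_pvalue(k, n, K, N),
            }
        )
    out = pd.DataFrame(rows, columns=["term", "label", "k", "n", "K", "N", "p"])
    if len(out):
        out["p_adj"] = by_adjust(out["p"].to_numpy())
        out["enriched"] = out["p_adj"] < alpha
    else:
        out["p_adj"] = pd.Series(dtype=float)
        out["enriched"] = pd.Series(dtype=bool)
    return out.sort_values("p", kind="mergesort").reset_index(drop=True)
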