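"""Pairing of probe sets with proteins and mRNA-protein ratio concordance."""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from seedcontrast.transcriptome_calls import pearson_correlation

_LOCUS_RE = re.compile(r"^(Os\d{2}g\d{5,7})(?:\.(\d+))?$")


def normalize_locus(protein_id: str) -> str:
    """Strip the isoform suffix from a locus.isoform protein identifier.

    ``Os02g06410.1 -> Os02g06410``; already-bare loci pass through unchanged
    (idempotent).  Malformed identifiers raise ``ValueError``.
    """
    m = _LOCUS_RE.match(str(protein_id))
    if not m:
        raise ValueError(f"malformed protein/locus identifier: {protein_id!r}")
    return m.group(1)


@dataclass
class PairingReport:
    """Exclusions applied while building unique probe/protein pairs."""

    isoform_collisions: list = field(default_factory=list)
    loci_multi_probe: list = field(default_factory=list)
    loci_no_probe: list = field(default_factory=list)

    def counts(self) -> dict:
        return {
            "isoform_collisions": len(self.isoform_collisions),
            "loci_multi_probe": len(self.loci_multi_probe),
            "loci_no_probe": len(self.loci_no_probe),
        }


def pair_probe_protein(
    protein_ratios: pd.DataFrame,
    probe_map: pd.DataFrame,
    probe_ratios: pd.DataFrame,
) -> tuple[pd.DataFrame, PairingReport]:
    """Build a bijection between loci and probe sets for ratio comparison.

    ``protein_ratios`` needs columns ``protein_id`` and ``log2_ratio`` (an
    optional ``abundance`` column resolves isoform collisions in favor of the
    more abundant isoform); ``probe_map`` maps ``probe_id`` to ``locus``
    (many-to-many allowed); ``probe_ratios`` holds the candidate probes
    (columns ``probe_id``, ``log2_ratio``).

    Proteins are collapsed to loci; loci matched by zero or by more than one
    candidate probe are removed, so each retained locus pairs with exactly
    one probe and vice versa.
    """
    report = PairingReport()

    prot = protein_ratios.copy()
    prot["locus"] = prot["protein_id"].map(normalize_locus)
    if "abundance" not in prot.columns:
        prot["abundance"] = 0.0
    # deterministic collision resolution: highest abundance, then id order
    prot = prot.sort_values(
        ["locus", "abundance", "protein_id"],
        ascending=[True, False, True],
        kind="mergesort",
    )
    dup = prot.duplicated("locus", keep="first")
    report.isoform_collisions = sorted(prot.loc[dup, "protein_id"].tolist())
    prot = prot[~dup]

    candidates = set(probe_ratios["probe_id"])
    pmap = probe_map[probe_map["probe_id"].isin(candidates)]
    probes_per_locus = pmap.groupby("locus")["probe_id"].apply(sorted).to_dict()

    mrna_ratio = probe_ratios.set_index("probe_id")["log2_ratio"]
    rows = []
    for _, row in prot.iterrows():
        probes = probes_per_locus.get(row["locus"], [])
        if len(probes) == 0:
            report.loci_no_probe.append(row["locus"])
        elif len(probes) > 1:
            report.loci_multi_probe.append(row["locus"])
        else:
            rows.append(
                {
                    "locus": row["locus"],
                    "probe_id": probes[0],
                    "protein_id": row["protein_id"],
                    "mrna_log2_ratio": float(mrna_ratio[probes[0]]),
                    "protein_log2_ratio": float(row["log2_ratio"]),
                }
            )
    pairs = pd.DataFrame(
        rows,
        columns=[
            "locus", "probe_id", "protein_id",
            "mrna_log2_ratio", "protein_log2_ratio",
        ],
    )
    # one probe may map to several loci; enforce probe uniqueness too
    dup_probe = pairs.duplicated("probe_id", keep=False)
    if dup_probe.any():
        report.loci_multi_probe.extend(pairs.loc[dup_probe, "locus"].tolist())
        pairs = pairs[~dup_probe]
    return pairs.reset_index(drop=True), report


def concordance(pairs: pd.DataFrame) -> dict:
    """Summarize mRNA-vs-protein ratio agreement over the pair table.

    Returns the Pearson r of the two ratio vectors (None when a vector is
    degenerate), the sign-quadrant counts (keys like ``+/+`` meaning protein
    ratio positive / mRNA ratio positive; zero ratios land in ``boundary``)
    and the per-pair table itself.
    """
    if len(pairs) < 3:
        raise ValueError("concordance requires >= 3 pairs")
    prot = pairs["protein_log2_ratio"].to_numpy(dtype=float)
    mrna = pairs["mrna_log2_ratio"].to_numpy(dtype=float)
    quadrants = {
        "+/+": int(((prot > 0) & (mrna > 0)).sum()),
        "+/-": int(((prot > 0) & (mrna < 0)).sum()),
        "-/+": int(((prot < 0) & (mrna > 0)).sum()),
        "-/-": int(((prot < 0) & (mrna < 0)).sum()),
        "boundary": int(((prot == 0) | (mrna == 0)).sum()),
    }
    try:
        r, p = pearson_correlation(prot, mrna)
    except ValueError:
        r, p = None, None
    return {"r": r, "p": p, "quadrants": quadrants, "n_pairs": len(pairs),
            "pairs": pairs}
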