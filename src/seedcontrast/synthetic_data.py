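"""Generators for every pipeline input, with planted ground truth.

Each generator is deterministic under a fixed ``rng_seed`` and returns its
ground truth as a sidecar table so that downstream recovery can be asserted
rather than inferred.  Intensities are log-normal: Gaussian effects on the
log2 scale, exponentiated to positive exp-scale areas.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from seedcontrast.metabolome_contrast import SeedMassModel
from seedcontrast.seq_phylo import DistanceMatrix, PhyloTree
from seedcontrast.transcriptome_calls import ProbeMatrix

TISSUES = ("embryo", "endosperm")

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# internal log2-scale location constants for generated abundances
_BASE_LOG2_MEAN = 20.0
_BASE_LOG2_SD = 2.0
_PROBE_BASE_MEAN = 8.0
_PROBE_BASE_SD = 2.0
_METAB_BASE_MEAN = 10.0
_METAB_BASE_SD = 1.5


@dataclass(frozen=True)
class OmicsScenario:
    """Parameters of the synthetic two-tissue three-replicate design."""

    n_features_common: int = 50
    n_specific_a: int = 10          # embryo-specific features
    n_specific_b: int = 5           # endosperm-specific features
    n_replicates: int = 3
    tissue_effect_sd: float = 2.0   # log2 scale
    noise_sd: float = 0.3           # log2 scale
    ion_multiplicity: float = 3.0   # mean peptide ions per protein
    dropout_rate: float = 0.1
    shared_ion_rate: float = 0.05
    rng_seed: int = 0

    def __post_init__(self):
        for f in ("n_features_common", "n_specific_a", "n_specific_b",
                  "n_replicates"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        for f in ("dropout_rate", "shared_ion_rate"):
            if not 0.0 <= getattr(self, f) <= 1.0:
                raise ValueError(f"{f} must lie in [0, 1]")
        for f in ("tissue_effect_sd", "noise_sd"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be >= 0")
        if self.ion_multiplicity < 1:
            raise ValueError("ion_multiplicity must be >= 1")

    def with_seed(self, seed: int) -> "OmicsScenario":
        return replace(self, rng_seed=seed)


def _feature_frame(scenario: OmicsScenario, rng, prefix="") -> pd.DataFrame:
    """Feature ids, memberships and planted log2 tissue effects.

    Ids follow the ``OsNNgNNNNN`` locus convention so that downstream
    identifier handling is exercised.  The tissue effect is the planted
    endosperm-minus-embryo log2 difference (0 for non-common features).
    """
    n = (scenario.n_features_common + scenario.n_specific_a
         + scenario.n_specific_b)
    ids = [f"Os{(i % 12) + 1:02d}g{(i + 1) * 10:05d}" for i in range(n)]
    membership = (
        ["common"] * scenario.n_features_common
        + ["embryo_specific"] * scenario.n_specific_a
        + ["endosperm_specific"] * scenario.n_specific_b
    )
    base = rng.normal(_BASE_LOG2_MEAN, _BASE_LOG2_SD, size=n)
    effect = np.where(
        np.array(membership) == "common",
        rng.normal(0.0, scenario.tissue_effect_sd, size=n),
        0.0,
    )
    return pd.DataFrame(
        {
            "feature_id": [prefix + i for i in ids],
            "membership": membership,
            "base_log2": base,
            "tissue_effect_log2": effect,
        }
    )


def _present_in(membership: str, tissue: str) -> bool:
    if membership == "common":
        return True
    if membership == "embryo_specific":
        return tissue == "embryo"
    return tissue == "endosperm"


def _tissue_log2_mean(row, tissue: str) -> float:
    half = row["tissue_effect_log2"] / 2.0
    return row["base_log2"] + (half if tissue == "endosperm" else -half)


# ---------------------------------------------------------------------------
# peptide-ion tables
# ---------------------------------------------------------------------------

def gen_peptide_ion_table(
    scenario: OmicsScenario,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Synthetic peptide-ion quantification table plus protein ground truth.

    Proteins receive 1 + Poisson(multiplicity - 1) peptide ions with
    log-normal areas around the planted per-tissue protein level; each
    tissue x replicate detection drops out independently (missing area) and
    a fraction of ions is additionally assigned a second protein so the
    specificity filter has work to do.
    """
    rng = np.random.default_rng(scenario.rng_seed)
    truth = _feature_frame(scenario, rng)
    truth["protein_id"] = truth["feature_id"] + ".1"

    protein_ids = truth["protein_id"].tolist()
    rows = []
    for _, prot in truth.iterrows():
        n_ions = 1 + rng.poisson(scenario.ion_multiplicity - 1.0)
        for ion_idx in range(n_ions):
            ion_id = f"{prot['protein_id']}|ion{ion_idx + 1}"
            assigned = [prot["protein_id"]]
            if len(protein_ids) > 1 and rng.random() < scenario.shared_ion_rate:
                other = prot["protein_id"]
                while other == prot["protein_id"]:
                    other = protein_ids[rng.integers(len(protein_ids))]
                assigned.append(other)
            ion_offset = rng.normal(0.0, 1.0)
            for tissue in TISSUES:
                present = _present_in(prot["membership"], tissue)
                mu = _tissue_log2_mean(prot, tissue) + ion_offset
                for rep in range(1, scenario.n_replicates + 1):
                    detected = present and rng.random() >= scenario.dropout_rate
                    area = (
                        float(2.0 ** (mu + rng.normal(0.0, scenario.noise_sd)))
                        if detected
                        else np.nan
                    )
                    rows.append(
                        {
                            "ion_id": ion_id,
                            "protein_ids": ";".join(assigned),
                            "tissue": tissue,
                            "replicate": rep,
                            "area": area,
                        }
                    )
    table = pd.DataFrame(
        rows, columns=["ion_id", "protein_ids", "tissue", "replicate", "area"]
    )
    return table, truth


# ---------------------------------------------------------------------------
# probe matrices
# ---------------------------------------------------------------------------

def gen_probe_matrix(
    scenario: OmicsScenario,
    ambiguous_rate: float = 0.02,
) -> tuple[ProbeMatrix, pd.DataFrame]:
    """Synthetic probe intensity matrix with P/M/A calls and ground truth.

    Intensities are log2 scale.  Probes present in a tissue receive a P call
    per replicate unless dropped out (then M/A); probes absent from a tissue
    get background intensity and A calls, with an occasional ambiguous M.
    """
    rng = np.random.default_rng(scenario.rng_seed)
    truth = _feature_frame(scenario, rng, prefix="probe:")
    truth["probe_id"] = [
        f"Affx.{i + 1:05d}_at" for i in range(len(truth))
    ]
    truth["locus"] = truth["feature_id"].str.removeprefix("probe:")
    # rescale proteome-level constants down to array scale
    truth["base_log2"] = (
        _PROBE_BASE_MEAN
        + (truth["base_log2"] - _BASE_LOG2_MEAN) * _PROBE_BASE_SD / _BASE_LOG2_SD
    )

    samples, design_rows = [], []
    for tissue in TISSUES:
        for rep in range(1, scenario.n_replicates + 1):
            sample = f"{tissue}_{rep}"
            samples.append(sample)
            design_rows.append(
                {"sample": sample, "tissue": tissue, "replicate": rep}
            )
    design = pd.DataFrame(design_rows)

    inten = np.zeros((len(truth), len(samples)))
    calls = np.full((len(truth), len(samples)), "A", dtype=object)
    for i, (_, probe) in enumerate(truth.iterrows()):
        for s, srow in enumerate(design_rows):
            tissue = srow["tissue"]
            if _present_in(probe["membership"], tissue):
                mu = _tissue_log2_mean(probe, tissue)
                inten[i, s] = mu + rng.normal(0.0, scenario.noise_sd)
                if rng.random() >= scenario.dropout_rate:
                    calls[i, s] = "P"
                elif rng.random() < 0.5:
                    calls[i, s] = "M"
            else:
                inten[i, s] = 3.0 + rng.normal(0.0, scenario.noise_sd)
                if rng.random() < ambiguous_rate:
                    calls[i, s] = "M"
    matrix = ProbeMatrix(
        intensities=pd.DataFrame(
            inten, index=truth["probe_id"].tolist(), columns=samples
        ),
        calls=pd.DataFrame(
            calls, index=truth["probe_id"].tolist(), columns=samples
        ),
        design=design,
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# metabolite tables
# ---------------------------------------------------------------------------

def gen_metabolite_table(
    scenario: OmicsScenario,
    mass: SeedMassModel | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Synthetic per-mg metabolite peak-area table plus ground truth.

    Areas are generated on a per-mg-dry-weight basis; the planted tissue
    effect is the per-mg endosperm-minus-embryo log2 difference.  The mass
    model does not influence the per-mg areas but is recorded in the truth
    table attrs so tests can assert the per-seed shift property.
    """
    if mass is None:
        mass = SeedMassModel()
    rng = np.random.default_rng(scenario.rng_seed)
    truth = _feature_frame(scenario, rng, prefix="met:")
    truth["name"] = [f"metabolite_{i + 1:03d}" for i in range(len(truth))]
    truth["base_log2"] = (
        _METAB_BASE_MEAN
        + (truth["base_log2"] - _BASE_LOG2_MEAN) * _METAB_BASE_SD / _BASE_LOG2_SD
    )
    classes = ["Amino acids", "Carbohydrate", "Organic acids", "Sugar alcohol",
               "Apolar", "Other"]

    rows = []
    for idx, (_, met) in enumerate(truth.iterrows()):
        klass = classes[idx % len(classes)]
        for tissue in TISSUES:
            present = _present_in(met["membership"], tissue)
            mu = _tissue_log2_mean(met, tissue)
            for rep in range(1, scenario.n_replicates + 1):
                detected = present and rng.random() >= scenario.dropout_rate
                area = (
                    float(2.0 ** (mu + rng.normal(0.0, scenario.noise_sd)))
                    if detected
                    else np.nan
                )
                rows.append(
                    {
                        "name": met["name"],
                        "class": klass,
                        "tissue": tissue,
                        "replicate": rep,
                        "peak_area_per_mg": area,
                    }
                )
    table = pd.DataFrame(
        rows, columns=["name", "class", "tissue", "replicate",
                       "peak_area_per_mg"]
    )
    table.attrs["seed_mass_model"] = mass
    truth.attrs["seed_mass_model"] = mass
    return table, truth


# ---------------------------------------------------------------------------
# probe -> locus maps and annotations (integration / enrichment plumbing)
# ---------------------------------------------------------------------------

def gen_probe_locus_map(probe_truth: pd.DataFrame) -> pd.DataFrame:
    """Two-column probe_id -> locus map matching a generated probe matrix."""
    return probe_truth[["probe_id", "locus"]].copy()


def gen_annotation_map(loci, n_terms: int, rng_seed: int,
                       mean_term_size: float = 10.0) -> dict:
    """Random flat term -> locus-set annotations over a locus universe."""
    rng = np.random.default_rng(rng_seed)
    loci = sorted(loci)
    terms = {}
    for t in range(n_terms):
        size = min(len(loci), 1 + rng.poisson(mean_term_size))
        chosen = rng.choice(len(loci), size=size, replace=False)
        terms[f"TERM:{t + 1:04d}"] = {loci[i] for i in chosen}
    return terms


# ---------------------------------------------------------------------------
# sequence families along a tree
# ---------------------------------------------------------------------------

def random_tree(n_taxa: int, rng_seed: int,
                min_branch: float = 0.05, max_branch: float = 0.5) -> PhyloTree:
    """Random unrooted binary tree with uniform branch lengths."""
    if n_taxa < 3:
        raise ValueError("need >= 3 taxa")
    rng = np.random.default_rng(rng_seed)

    def bl():
        return float(rng.uniform(min_branch, max_branch))

    leaves = [f"T{i + 1}" for i in range(n_taxa)]
    # start from a 3-leaf star, then attach remaining leaves to random edges
    edges = [(leaves[0], "_i0", bl()), (leaves[1], "_i0", bl()),
             (leaves[2], "_i0", bl())]
    next_internal = 1
    for leaf in leaves[3:]:
        idx = int(rng.integers(len(edges)))
        a, b, ln = edges.pop(idx)
        u = f"_i{next_internal}"
        next_internal += 1
        split = float(rng.uniform(0.2, 0.8))
        edges.extend(
            [(a, u, ln * split), (u, b, ln * (1 - split)), (leaf, u, bl())]
        )
    return PhyloTree(edges=edges, leaves=leaves)


def star_tree(n_taxa: int, branch_length: float = 0.3) -> PhyloTree:
    leaves = [f"T{i + 1}" for i in range(n_taxa)]
    return PhyloTree(
        edges=[(leaf, "_c", branch_length) for leaf in leaves], leaves=leaves
    )


def gen_protein_family(
    tree: PhyloTree,
    seq_length: int,
    subst_rate: float,
    rng_seed: int,
) -> dict:
    """Evolve equal-length ungapped sequences along a tree.

    Uniform substitution model: on a branch of length t each site mutates
    with probability ``1 - exp(-subst_rate * t)`` to a residue drawn
    uniformly from the 19 alternatives.  Returns leaf id -> sequence.
    """
    if seq_length < 1:
        raise ValueError("seq_length must be >= 1")
    if subst_rate < 0:
        raise ValueError("subst_rate must be >= 0")
    rng = np.random.default_rng(rng_seed)
    adj = tree.adjacency()
    root = tree.nodes[0]
    root_seq = [AMINO_ACIDS[i] for i in rng.integers(20, size=seq_length)]

    seqs = {}

    def evolve(seq, node, parent):
        if node in set(tree.leaves):
            seqs[node] = "".join(seq)
        for child, ln in adj[node]:
            if child == parent:
                continue
            p_sub = 1.0 - np.exp(-subst_rate * ln)
            child_seq = list(seq)
            hits = np.flatnonzero(rng.random(seq_length) < p_sub)
            for site in hits:
                alternatives = AMINO_ACIDS.replace(child_seq[site], "")
                child_seq[site] = alternatives[rng.integers(19)]
            evolve(child_seq, child, node)

    evolve(root_seq, root, None)
    return seqs
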