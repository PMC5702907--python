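"""End-to-end orchestration of the tissue-contrast stages.

Every stage writes its intermediate table as TSV into the output directory
so single stages can be re-run and audited; the run report collects partition
counts (with an inclusion-exclusion check), ratio-table summaries, favored
thresholds, differential lists, pairing/concordance, enrichment tables and
the Newick tree.  The same configuration always produces a byte-identical
report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from seedcontrast import enrichment as enr
from seedcontrast import metabolome_contrast as metab
from seedcontrast import omics_integration as integ
from seedcontrast import proteomics_quant as prot
from seedcontrast import seq_phylo as phylo
from seedcontrast import synthetic_data as synth
from seedcontrast import transcriptome_calls as trans
from seedcontrast.metabolome_contrast import SeedMassModel
from seedcontrast.synthetic_data import OmicsScenario

log = logging.getLogger("seedcontrast.pipeline")


@dataclass
class RunConfig:
    """Thresholds, scenario parameters and switches for a pipeline run."""

    seed: int = 0
    scenario: dict = field(default_factory=dict)
    embryo_fraction: float = 0.02
    endosperm_fraction: float = 0.98
    seed_dw_mg: float = 25.0
    min_detections: int = 2
    call_rule: str = "majority"
    ratio_mode: str = "mean-of-raw"
    fdr_method: str = "bh"
    alpha_protein: float = 0.05
    alpha_transcript: float = 0.01
    alpha_metabolite: float = 0.05
    alpha_enrichment: float = 0.05
    n_enrichment_terms: int = 20
    phylo_n_taxa: int = 8
    phylo_seq_length: int = 200
    phylo_subst_rate: float = 0.5

    def __post_init__(self):
        for a in ("alpha_protein", "alpha_transcript", "alpha_metabolite",
                  "alpha_enrichment"):
            if not 0 < getattr(self, a) < 1:
                raise ValueError(f"{a} must lie in (0, 1)")
        if self.call_rule not in trans.CALL_RULES:
            raise ValueError(f"unknown call rule {self.call_rule!r}")
        if self.ratio_mode not in ("mean-of-raw", "mean-of-log"):
            raise ValueError(f"unknown ratio mode {self.ratio_mode!r}")
        if self.fdr_method not in ("bh", "by"):
            raise ValueError(f"unknown fdr method {self.fdr_method!r}")

    def scenario_obj(self) -> OmicsScenario:
        return OmicsScenario(**{"rng_seed": self.seed, **self.scenario})

    def mass_model(self) -> SeedMassModel:
        return SeedMassModel(
            embryo_fraction=self.embryo_fraction,
            endosperm_fraction=self.endosperm_fraction,
            seed_dw_mg=self.seed_dw_mg,
        )

    def to_yaml(self, path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


def _partition_entry(partition: prot.FeaturePartition) -> dict:
    counts = partition.counts()
    n_a = counts["specific_a"] + counts["common"]
    n_b = counts["specific_b"] + counts["common"]
    counts["inclusion_exclusion_ok"] = (
        counts["union"] == n_a + n_b - counts["common"]
    )
    return counts


def _round(x, nd=6):
    if x is None:
        return None
    return round(float(x), nd)


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Run every stage on generated inputs and return the run report."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scenario = config.scenario_obj()
    mass = config.mass_model()
    report = {"seed": config.seed}

    # --- simulate -----------------------------------------------------------
    ion_table, protein_truth = synth.gen_peptide_ion_table(scenario)
    probe_matrix, probe_truth = synth.gen_probe_matrix(scenario)
    metab_table, metab_truth = synth.gen_metabolite_table(scenario, mass)
    probe_map = synth.gen_probe_locus_map(probe_truth)
    ion_table.to_csv(out / "peptide_ions.tsv", sep="\t", index=False)
    protein_truth.to_csv(out / "protein_truth.tsv", sep="\t", index=False)
    probe_truth.to_csv(out / "probe_truth.tsv", sep="\t", index=False)
    metab_table.to_csv(out / "metabolites_per_mg.tsv", sep="\t", index=False)
    log.info("simulate: %d ion rows, %d probes, %d metabolite rows",
             len(ion_table), len(probe_matrix.intensities), len(metab_table))

    # --- proteome -----------------------------------------------------------
    filtered, filter_report = prot.filter_peptide_ions(
        ion_table, min_detections=config.min_detections,
        n_replicates=scenario.n_replicates,
    )
    summed = prot.sum_within_sample(filtered)
    rollup = prot.rollup_protein_abundance(summed)
    rollup.to_csv(out / "protein_abundance.tsv", sep="\t", index=False)
    detected = prot.detected_features(rollup)
    prot_partition = prot.partition_features(
        detected.get("embryo", set()), detected.get("endosperm", set())
    )
    means = prot.protein_tissue_means(rollup, mode=config.ratio_mode)
    common_means = means.loc[sorted(prot_partition.common)]
    ratios = prot.tissue_log2_ratio(common_means)
    favored, thresholds = prot.favored_by_median(ratios)
    report_proteome = {
        "filter": filter_report.as_dict(),
        "partition": _partition_entry(prot_partition),
        "favored_counts": {
            k: int(v)
            for k, v in favored["favored_class"].value_counts().items()
        },
        "favored_thresholds": {k: _round(v) for k, v in thresholds.items()},
    }
    if len(ratios) >= 3 and ratios["log2_ratio"].std(ddof=1) > 0:
        z = prot.zscore_differential(ratios, alpha=config.alpha_protein)
        z.to_csv(out / "protein_ratio_table.tsv", sep="\t", index=False)
        w, p_shapiro = prot.shapiro_normality(z["log2_ratio"])
        report_proteome["zscore_significant"] = int(z["significant"].sum())
        report_proteome["zscore_significant_ids"] = sorted(
            z.loc[z["significant"], "feature_id"].tolist()
        )
        report_proteome["shapiro"] = {
            "W": _round(w), "p": _round(p_shapiro)
        }
        protein_ratio_table = z
    else:
        favored.to_csv(out / "protein_ratio_table.tsv", sep="\t", index=False)
        protein_ratio_table = favored
    report["proteome"] = report_proteome
    log.info("proteome: %d/%d/%d specific-a/specific-b/common proteins",
             *[report_proteome["partition"][k]
               for k in ("specific_a", "specific_b", "common")])

    # --- transcriptome ------------------------------------------------------
    detected_probes = trans.consensus_detection(probe_matrix, rule=config.call_rule)
    probe_partition = prot.partition_features(
        detected_probes.get("embryo", set()),
        detected_probes.get("endosperm", set()),
    )
    tested = sorted(probe_partition.union)
    de = trans.ttest_bonferroni(
        probe_matrix, probes=tested, alpha=config.alpha_transcript
    )
    de.to_csv(out / "transcript_de.tsv", sep="\t", index=False)
    strong = trans.strong_de_filter(de, probe_matrix, detected_universe=tested)
    mean_embryo = probe_matrix.intensities[
        probe_matrix.samples_of("embryo")].mean(axis=1)
    mean_endo = probe_matrix.intensities[
        probe_matrix.samples_of("endosperm")].mean(axis=1)
    common_probes = sorted(probe_partition.common)
    r_trans, p_trans = trans.pearson_correlation(
        mean_embryo.loc[common_probes], mean_endo.loc[common_probes]
    )
    report["transcriptome"] = {
        "partition": _partition_entry(probe_partition),
        "n_tested": int(de.attrs["m"]),
        "n_de": int(de["significant"].sum()),
        "n_strong_de": len(strong),
        "pearson_r": _round(r_trans),
        "pearson_p": _round(p_trans),
    }

    # --- metabolome ---------------------------------------------------------
    per_seed = metab.per_seed_normalize(metab_table, mass)
    per_seed.to_csv(out / "metabolites_per_seed.tsv", sep="\t", index=False)
    met_partition = metab.call_tissue_specific(
        metab_table, min_detections=config.min_detections
    )
    met_diff = metab.differential_metabolites(
        per_seed, common=met_partition.common,
        alpha=config.alpha_metabolite, fdr_method=config.fdr_method,
    )
    met_diff.to_csv(out / "metabolite_differential.tsv", sep="\t", index=False)
    report["metabolome"] = {
        "partition": _partition_entry(met_partition),
        "n_tested": len(met_diff),
        "n_differential": int(met_diff["significant"].sum())
        if len(met_diff) else 0,
    }

    # --- integration --------------------------------------------------------
    protein_ratios = protein_ratio_table.rename(
        columns={"feature_id": "protein_id"}
    )[["protein_id", "log2_ratio"]].copy()
    mrna_ratios = (mean_endo - mean_embryo).loc[common_probes]
    probe_ratio_df = mrna_ratios.rename("log2_ratio").reset_index()
    probe_ratio_df.columns = ["probe_id", "log2_ratio"]
    pairs, pairing_report = integ.pair_probe_protein(
        protein_ratios, probe_map, probe_ratio_df
    )
    pairs.to_csv(out / "probe_protein_pairs.tsv", sep="\t", index=False)
    report_integration = {
        "n_pairs": len(pairs),
        "exclusions": pairing_report.counts(),
    }
    if len(pairs) >= 3:
        conc = integ.concordance(pairs)
        report_integration["concordance"] = {
            "r": _round(conc["r"]),
            "quadrants": conc["quadrants"],
        }
    report["integration"] = report_integration

    # --- enrichment ---------------------------------------------------------
    background = {integ.normalize_locus(p) for p in prot_partition.union}
    study = {
        integ.normalize_locus(p)
        for p in (
            set(favored.loc[favored["favored_class"] == "embryo-favored",
                            "feature_id"])
            | prot_partition.specific_a
        )
    }
    ann = enr.AnnotationMap(
        terms=synth.gen_annotation_map(
            background, config.n_enrichment_terms, rng_seed=config.seed + 1
        )
    )
    enriched = enr.hypergeom_enrich(
        study, background, ann, alpha=config.alpha_enrichment
    )
    enriched.to_csv(out / "enrichment.tsv", sep="\t", index=False)
    report["enrichment"] = {
        "n_terms_tested": len(enriched),
        "n_enriched": int(enriched["enriched"].sum()) if len(enriched) else 0,
        "study_size": len(study),
        "background_size": len(background),
    }

    # --- phylogeny ----------------------------------------------------------
    true_tree = synth.random_tree(config.phylo_n_taxa, rng_seed=config.seed + 2)
    family = synth.gen_protein_family(
        true_tree, config.phylo_seq_length, config.phylo_subst_rate,
        rng_seed=config.seed + 3,
    )
    aln = phylo.AlignedProteinSet(
        ids=tuple(sorted(family)), seqs=tuple(family[k] for k in sorted(family))
    )
    dmat = phylo.blosum62_distance(aln)
    tree = phylo.neighbor_joining(dmat)
    newick = phylo.write_newick(tree)
    (out / "family.newick").write_text(newick + "\n")
    ng_hits = {
        sid: [pos for pos, _ctx in phylo.find_ng_cleavage(seq)]
        for sid, seq in sorted(family.items())
    }
    report["phylogeny"] = {
        "n_taxa": len(aln),
        "newick": newick,
        "ng_motif_positions": ng_hits,
    }

    report_text = json.dumps(report, sort_keys=True, indent=2)
    (out / "report.json").write_text(report_text + "\n")
    return report
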