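# seedcontrast

Tissue-contrast analysis of seed embryo/endosperm multi-omics data:
label-free peptide-ion → protein quantification rollup, presence/absence
transcript contrasts, dry-weight-normalized metabolite contrasts,
mRNA–protein concordance, hypergeometric term enrichment with
Benjamini–Yekutieli FDR, and BLOSUM62/neighbor-joining phylogeny — plus a
synthetic-data generator so the whole pipeline is testable offline.

## Package layout

| module | contents |
| --- | --- |
| `seedcontrast.proteomics_quant` | ion specificity/reproducibility filter, within-sample summation, protein rollup, feature partitioning, log2 ratios, median-based favored classes, z-score differential, Shapiro diagnostic |
| `seedcontrast.transcriptome_calls` | `ProbeMatrix`, P/M/A consensus detection, pooled-variance t-test with Bonferroni control, strong-expression filter, Pearson correlation |
| `seedcontrast.metabolome_contrast` | `SeedMassModel` (per-seed dry-mass fractions), per-seed normalization, tissue-specific calls, equal-variance t-test with BH/BY FDR |
| `seedcontrast.omics_integration` | locus normalization, unique probe/protein pairing, ratio concordance |
| `seedcontrast.enrichment` | exact hypergeometric over-representation, Benjamini–Yekutieli adjustment |
| `seedcontrast.seq_phylo` | BLOSUM62 distances, neighbor joining, Newick output, NG cleavage-motif scan |
| `seedcontrast.synthetic_data` | scenario-driven generators for every input, with planted ground truth sidecars |
| `seedcontrast.pipeline` | `RunConfig` + `run_pipeline` end-to-end orchestration |
| `seedcontrast.fixtures` | loaders for the packaged reference tables (below) |

Packaged data (`src/seedcontrast/data/`): `table1.tsv` (metabolite
contrasts), `table2.tsv` (64 differential proteins), `table3.tsv`
(chaperone/folding proteins), `results_counts.tsv` (printed per-tissue
detection counts used by the set-arithmetic checks), `blosum62.tsv`.

## CLI

```bash
seedcontrast simulate   --seed 1 --out sim/            # synthetic inputs + truth
seedcontrast quantify   sim/peptide_ions.tsv --out quant/ \
                        --min-detections 2 --alpha 0.05 --ratio-mode mean-of-raw
seedcontrast transcripts sim/probe_intensities.tsv sim/probe_calls.tsv \
                        sim/probe_design.tsv --out tr/ --call-rule majority --alpha 0.01
seedcontrast metabolites sim/metabolites_per_mg.tsv --out met/ --fdr-method bh
seedcontrast integrate  quant/protein_ratio_table.tsv sim/probe_locus_map.tsv \
                        tr/probe_ratios.tsv --out pairs/
seedcontrast enrich     study.txt annotation.tsv --background background.txt --out enrich.tsv
seedcontrast phylo      alignment.fasta --out tree.newick --scan-ng
seedcontrast run        --config config.yaml --seed 1 --out run/   # everything
```

`run` executes every stage on generated inputs, persists all intermediates
as TSV in the output directory, and writes a deterministic `report.json`
(same config ⇒ byte-identical report).

### Table formats

* **Peptide-ion table** (TSV): `ion_id`, `protein_ids` (`;`-separated),
  `tissue` (`embryo`/`endosperm`), `replicate` (1..3), `area` (blank =
  undetected).
* **Probe matrix**: intensity and call TSVs (probe × sample) plus a design
  TSV (`sample`, `tissue`, `replicate`); calls are `P`/`M`/`A`.
* **Metabolite table** (TSV): `name`, `class`, `tissue`, `replicate`,
  `peak_area_per_mg`.
* **Probe map** (TSV): `probe_id`, `locus`; protein ids are
  `OsNNgNNNNN.K`, loci are the same without the isoform suffix.

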