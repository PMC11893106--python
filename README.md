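# pgcgrn

Paired single-nucleus RNA + ATAC (multiome) analysis of primordial germ
cell (PGC) sex determination, as a reusable, tested Python library.

During fetal gonad development, bipotential PGCs commit to the oogenic or
spermatogenic fate in response to their chromosomal sex and to signals from
the somatic supporting cells. A multiome experiment measures, in the same
nuclei, gene expression and chromatin accessibility across both sexes and
several embryonic stages — and asks which genes and peaks diverge between
XX and XY germ cells, which accessible elements drive which genes, which
transcription factors (TFs) sit upstream, and which ligand-receptor
signals the soma sends. `pgcgrn` implements that full analytical chain:

* **QC and sex filtering** — depth/mitochondrial/nucleosome-signal/TSS-
  enrichment gates; chrY confirmation combining a rank-based module score
  of the Y-linked genes (*Kdm5d*, *Eif2s3y*, *Uty*, *Ddx3y*) with fragment
  counts over chrY:1-90,000,000.
* **Population selection** — per-cell marker rules (e.g. *Ddx4*+/*Pou5f1*+
  nuclei without somatic markers are PGCs).
* **Embedding and clustering** — log-normalization + PCA for RNA, TF-IDF +
  LSI for ATAC, a weighted joint embedding, Leiden clustering on a
  shared-nearest-neighbor graph, and cluster composition tables.
* **Differential testing** — Seurat-style marker tests: percent-expressed
  and log-fold-change gates, Wilcoxon rank-sum (exact for tiny groups),
  Benjamini-Hochberg adjustment.
* **Peak-to-gene links** — for each peak-gene pair within 500 kb, the
  correlation r across cells is scored as z = (r − mean)/SD against the
  same gene's correlations with GC/accessibility/width-matched background
  peaks; links accepted at p < 0.05 and z > 0.
* **Motifs** — JASPAR PFM parsing, log-odds PWM scanning of peak sequences,
  GC-matched hypergeometric motif enrichment, and chromVAR-style
  bias-corrected per-cell motif-activity deviations.
* **GRN inference** — candidate TFs must be differentially expressed,
  germline-enriched, motif-enriched in linked peaks, and show positive
  motif activity; their targets are the linked DEGs whose peaks carry the
  motif, with full (motif, peak, link) provenance and TF x TF
  cross-regulation.
* **Cell-cell communication** — a CellphoneDB-style permutation screen of
  ligand-receptor pairs (minimum-subunit complexes, cluster-label
  shuffling, add-one p-values) between supporting cells and PGCs.

Since the original sequencing data are not needed to test any of this, the
package ships a first-class synthetic-data generator
(`pgcgrn.simulate`) that produces paired count matrices, fragments, peak
sequences and metadata with *planted, recoverable ground truth*: chrY
structure, stage-growing DE genes and DA peaks, latent-factor peak-gene
couplings, a planted TF->motif->peak->gene circuit, sex-specific
ligand-receptor pairs, and deliberately failed nuclei. Every statistical
claim in the test suite is a recovery or calibration statement against
that truth. See `docs/methods.md` for models, parameters and limitations.

## Worked example

```python
from pgcgrn import GeneratorConfig, generate_dataset, pipeline

cfg = GeneratorConfig(seed=1)                 # 2 sexes x 3 stages x 400 nuclei
dataset, truth = generate_dataset(cfg)
metrics = pipeline.recovery_metrics(1, cfg)   # full analysis + truth comparison
for k in ("sex_accuracy_pct", "de_sensitivity", "de_fdr", "link_sensitivity",
          "planted_motif_rank", "selected_tfs", "tf_target_coverage",
          "cluster_ari_sex"):
    print(k, metrics[k])
```

prints (seed 1):

```
sex_accuracy_pct 100.0
de_sensitivity 1.0
de_fdr 0.0
link_sensitivity 1.0
planted_motif_rank 1.0
selected_tfs ['TFAP2C']
tf_target_coverage 1.0
cluster_ari_sex 1.0
```

meaning: every surviving nucleus was assigned its true chromosomal sex;
all 64 truly sex-different genes at E13.5 were recovered with no false
calls; all 50 planted peak-gene links were found; the planted
TFAP2C motif ranked first among the eight motifs in the linked-peak
enrichment; TFAP2C — and no decoy TF — was selected as a candidate
regulator and reached all of its linked target genes; and the joint
RNA+ATAC clustering of E13.5 germ cells split them perfectly by sex.

A small CLI covers dataset generation and the communication screen:

```bash
pgcgrn simulate --out sim/ --seed 1
pgcgrn commscreen --data-dir sim/ \
    --pairs src/pgcgrn/data/lr_pairs.tsv --nperm 1000 --seed 1
```

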