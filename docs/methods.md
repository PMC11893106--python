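# Methods

`pgcgrn` re-implements, as a tested library, the statistical core of a paired
single-nucleus RNA + ATAC (multiome) analysis of primordial germ cell (PGC)
sex determination in the fetal mouse gonad: quality control and chrY-based
sex filtering, marker-rule population selection, per-modality and joint
embeddings with graph clustering, Wilcoxon differential expression and
accessibility, peak-to-gene linkage against a matched-background null,
motif enrichment and per-cell motif activity, a candidate-TF /
target-prediction flow, and a permutation ligand-receptor screen. Because
the real dataset is not required, a synthetic-data module generates paired
matrices with planted, recoverable structure; every claim the test suite
makes is a claim about recovering that planted structure.

## The synthetic multiome

The generator emulates two sexes (XX, XY) at three embryonic stages (E11.5,
E12.5, E13.5), each group containing germ cells (default 50%), supporting
cells (25%) and other somatic cells (25%). Default 400 nuclei per sex x
stage group, so ~200 germ cells per sex at each stage and ~400 cells per
sex at the final stage.

**Count model.** RNA counts are gamma-Poisson (negative binomial) draws on
per-cell depth x per-gene relative rate, with per-gene dispersion theta ~
U(5, 50); ATAC counts likewise with theta ~ U(10, 50) and low per-peak
rates (mostly 0/1/2 counts). Per-cell depths are log-normal around the
configured means (defaults: 5,000 RNA counts, 3,000 fragments). Rates are
renormalized per cell, so planted effects act on composition as they do in
real libraries. Mitochondrial genes receive a per-cell fraction of the RNA
depth (mean 5%).

**The toy genome** has three autosomes (genes tiled every 100 kb, about the
gene density of the mouse genome, each gene with two exons, an intron and a
strand), a chrY carrying the four Y-linked genes (*Kdm5d*, *Eif2s3y*,
*Uty*, *Ddx3y*) and 21 peaks inside chrY:1-90,000,000, and a chrM for the
mitochondrial genes. Peaks (default 2,000; widths 300-1,000 bp) never
overlap one another: ~30% sit on gene promoters, planted link peaks sit
10-200 kb from their target gene's TSS, the rest are uniform. Peak
sequences are random with per-peak GC drawn around 0.45; planted motif
instances are exact consensus insertions at non-overlapping offsets, which
guarantees recall at the 80%-of-maximum PWM score threshold.

**Planted structure.**

* chrY genes and peaks have zero rate in XX nuclei; Y-gene expression is
  high in XY nuclei (mean ~6 counts) so the rank-based module score
  separates the sexes cleanly. 2% of nuclei carry the wrong dataset sex
  label, exercising the sex filter; its accuracy is scored on survivors
  against the true sex.
* DE genes follow a nested stage schedule (defaults 10/35/60) with
  multiplicative 2^1.5 effects in germ cells of the up-regulated sex from
  the stage a gene enters the set; DA peaks follow the same logic
  (20/60/120). Planted DE genes keep at least one link-window (500 kb) of
  genomic separation so that candidate peak-gene pairs that are not planted
  links are genuinely uncorrelated (see "link truth" below).
* Each of the 50 planted links couples one DA peak to one DE gene through a
  shared per-cell log-normal latent factor (sigma 0.9), giving Pearson
  r ~ 0.4-0.6 on normalized values within a sex x stage group.
* One causal TF (TFAP2C/*Tfap2c*) is germ-restricted, XX-up DE at the final
  stage, and its consensus is planted in all XX-side link peaks and in the
  promoter peak of a second TF gene (*Tcfl5*), wiring one TF->TF edge. The
  remaining motifs are decoys planted in random peaks that are neither DA,
  link peaks, nor TF promoters — otherwise a decoy can acquire planted
  wiring by coincidence and the truth tables would be wrong, not the
  caller.
* Three ligand-receptor pairs (including one multi-subunit receptor
  complex) are active in one sex only: ligand high in that sex's supporting
  cells, receptor in germ cells; in the other sex the ligand is expressed
  in <10% of senders, so the CellphoneDB-style expression gate excludes the
  pair there.
* 5% of nuclei are planted QC failures (low RNA depth, high mitochondrial
  fraction, low ATAC depth, or all-mononucleosomal fragments).

Fragments are generated per ATAC count inside the peak, with a
sub-nucleosomal (mean 80 bp) / mono-nucleosomal (mean 200 bp) length
mixture (65/35), and aggregate back to the count matrix exactly.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: doublets, ambient RNA, batch and replicate
effects, realistic genome sequence composition, UMI-level errors, motif
redundancy between TF family members, trans-chromosomal regulation, and
continuous differentiation trajectories (stages are discrete). Marker genes
are perfectly compartment-restricted, so population selection is cleaner
than in tissue.

## Statistical components

**QC.** n_count thresholds are strict inequalities (RNA in (1000, 25000),
percent.mt < 25, ATAC in (1000, 100000)); nucleosome signal is
(# fragments with length in [147, 294]) / (# fragments shorter than 147),
defined as +inf when the denominator is zero so such cells fail the < 2
gate; TSS enrichment is per-bp fragment-midpoint coverage in TSS +/- 1 kb
over two 100 bp background windows just outside it (0/0 reported as 0,
x/0 as +inf). Mitochondrial genes are removed from the matrix after QC.

**Module scores.** Two flavors: the binned-control score (genes binned into
24 expression bins, 100 controls per set gene sampled with replacement,
score = mean(set) - mean(pooled unique controls)) and the rank-based score
(per-cell average ranks by decreasing expression, clipped at r_max + 1,
U-statistic rescaled to [0, 1]; r_max default 1500). Sex assignment scores
the four Y-linked genes with the rank score and combines it with the chrY
fragment count: an XY-labeled cell is removed when it has zero chrY
fragments or a score below mean - 1 SD of the XY final-stage reference; an
XX-labeled cell when it has any chrY fragment or a score above mean + 1 SD
of the XX reference. The literal "above one SD of the XY mean" reading
would remove most true XY cells, so the thresholds are implemented as
reference-consistent bounds and exposed via `n_sd`.

**Embeddings and clustering.** RNA: log-normalize (scale factor 10^4), PCA
on scaled genes (default 18 components, deterministic sign convention).
ATAC: TF-IDF (log1p(10^4 x TF x IDF)) + truncated SVD, with component 1
dropped by default because it tracks depth (the per-component |correlation|
with depth is reported). The joint embedding centers each modality's
coordinate block, divides it by its total standard deviation, scales by
sqrt(weight) and concatenates. Block-level rather than per-dimension
standardization is deliberate: z-scoring every component equally weights
pure-noise dimensions and, on generator output, collapsed a sex separation
that either single modality resolved perfectly. Clustering is Leiden
(RB-configuration modularity, resolution 0.3) on a shared-nearest-neighbor
graph (k = 20, Jaccard weights, pruned below 1/15), with cluster ids
relabeled by size; the weight-0/1 limits of the joint embedding reproduce
single-modality clusterings exactly.

**Differential testing.** Features pass to a two-sided Wilcoxon rank-sum
test only if max(pct_1, pct_2) >= min_pct and |log2FC| >= the threshold,
where log2FC uses de-normalized group means with pseudocount 1 (gene
defaults 0.25/0.25; peak defaults 0.001/0.1). Exact enumeration is used
when the two groups have <= 20 cells in total; otherwise a tie-corrected
normal approximation with continuity correction. BH adjustment uses m =
all input features, not just gate survivors: the fold-change gate
preferentially passes features whose p-value is already small, and
adjusting over survivors alone was measured to call ~half of the surviving
null features significant on null data. Constant features get p = 1.

**Peak-gene links.** Candidates are peak-midpoint-to-TSS distances within
500 kb on the same chromosome. For each pair, Pearson r across cells is
compared with the correlations of the same gene against 200 background
peaks matched to the query peak in z-scored (GC, mean accessibility,
width) space; z = (r - null mean)/null SD, with an upper-tail Student-t
p-value (199 df — the correct reference for a statistic studentized by a
200-draw SD estimate; the normal tail was measurably anti-conservative).
A link is accepted when p < 0.05 and z > 0. Zero-variance features and
degenerate nulls drop the pair with a recorded reason. In the pipeline the
matching features are computed on the cells being analyzed, so the null
shares their depth structure. Spearman correlation is available via
`method=`.

**Motifs.** JASPAR-format PFMs (parsed with Biopython) become log-odds
PWMs with a background-split pseudocount of 0.8. Scanning slides the PWM
over both strands; a hit is any window scoring >= 80% of the motif's
maximal achievable score (deterministic, recall-guaranteed on consensus
insertions; N scores as background). Enrichment is a hypergeometric
upper-tail test of query hits in the query+background universe with BH
over motifs. Motif activity follows the bias-corrected deviation scheme on
raw counts: expected motif counts from the motif's share of total
accessibility times cell depth; 50 background peak sets drawn from each
peak's 50 nearest matched neighbors give the bias correction and z-scores;
per-group "motif activity" is the mean z over the group. Motifs whose
peaks have zero total counts are dropped with a warning.

**GRN flow.** A TF is selected for a group when it is differentially
expressed toward that group's sex, germline-enriched (germ vs soma marker
test at the gene defaults), its motif is enriched (BH p < 0.05) in the
peaks linked to the group's DEGs, and its mean motif-activity z over the
group is positive. Predicted targets are linked DEGs whose accepted link
peaks carry the motif; coverage divides by the number of DEGs with at
least one accepted link (one denominator, stated explicitly, since
published coverage fractions mix denominators). Cross-regulation A->B
requires A's motif in a peak accepted-linked to B's gene or inside B's
TSS +/- 3 kb; self-edges are kept on the diagonal and reported separately.
Every reported edge carries a (motif, peak, link) witness row.

**Ligand-receptor screen.** CellphoneDB statistical-method conventions:
complex expression is the minimum subunit cluster mean; pairs require
every ligand subunit expressed in >= 10% of sender cells and every
receptor subunit in >= 10% of receivers; the score is the mean of ligand
and receptor cluster means; p is the add-one permutation tail over 1,000
cluster-label shuffles (so p >= 1/1001); significance at p < 0.05. The
tool's published defaults are used for the two parameters the source
analysis does not state (n_perm, expression fraction).

## Problem sizes and determinism

The default evaluation runs at 1,000 genes x 2,000 peaks x ~2,500 nuclei
(planted) and 200 cells per group (null calibration), sizes at which the
full pipeline completes in well under a minute per seed on one CPU while
leaving every test adequately powered. All randomness flows through
explicit integer seeds (generator, control-gene sampling, background sets,
permutations, Leiden); fixed seeds give byte-identical written datasets
and identical analysis output. Write -> read round trips are exact,
including float metadata (written with `%.17g`, parsed with round-trip
precision).

## Known limitations

* The joint embedding is a weighted concatenation, not weighted-nearest-
  neighbor integration; it preserves the clustering logic but not the
  per-cell modality weighting of the latter.
* Pseudotime/trajectory analysis, doublet and ambient-RNA removal, and
  regularized NB normalization are out of scope; log-normalization stands
  in for the latter and is config-switchable in principle at the call
  sites.
* The Wilcoxon exact path enumerates combinations and is intended for
  n <= 20; larger groups use the asymptotic test.
* Motif redundancy is not collapsed; each PFM is scored independently.
* The hypergeometric over-representation test treats gene sets as
  unweighted and ignores set overlap.
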