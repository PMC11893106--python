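"""Synthetic paired snRNA/snATAC multiome generator with planted ground truth.

The generator emulates the structure of a fetal-gonad multiome time course:
two sexes (XX, XY) sampled at three embryonic stages, each containing a germ
cell (PGC) compartment and two somatic compartments (supporting cells and
other soma). Into this scaffold it plants recoverable signal:

* chrY-restricted genes (*Kdm5d*, *Eif2s3y*, *Uty*, *Ddx3y*) and 21 chrY
  peaks present only in XY nuclei, supporting chrY-based sex filtering;
* compartment marker genes (*Ddx4*/*Pou5f1* for germ cells, *Wt1*/*Runx1*/
  *Sox9* for supporting cells, and exclusion markers for other soma);
* differentially expressed genes and differentially accessible peaks between
  XX and XY germ cells whose count grows with stage;
* peak-gene links realised as a shared per-cell log-normal latent factor that
  couples a peak's accessibility rate to its target gene's expression rate;
* a TF circuit: one causal TF whose motif consensus is planted into the
  accessible, XX-up, gene-linked peaks (including a peak linked to a second
  TF gene, giving one TF -> TF cross-regulatory edge);
* ligand-receptor pairs active in one sex only, sent from supporting cells
  and received by germ cells;
* a configurable fraction of failed nuclei violating the QC thresholds and a
  small fraction of sex-mislabeled nuclei to exercise the sex filter.

Counts are negative binomial (gamma-Poisson) with per-gene/per-peak
dispersion on per-cell depth x per-feature rate. Fragments are generated per
ATAC count with a bimodal sub-/mono-nucleosomal length mixture and aggregate
back to the peak counts exactly. All randomness flows from ``config.seed``.
"""
from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .types import GroundTruth, MultiomeDataset

# -- fixed toy-genome layout ------------------------------------------------

AUTOSOMES = ("chr1", "chr2", "chr3")
CHRY = "chrY"
CHRM = "chrM"
CHRY_REGION = (1, 90_000_000)          # chrY interval that holds the sexing peaks
GENE_SPACING = 100_000                 # bp between consecutive gene TSSs

MITO_GENES = ["mt-Nd1", "mt-Nd2", "mt-Co1", "mt-Co2", "mt-Co3",
              "mt-Atp6", "mt-Cytb", "mt-Nd4", "mt-Nd5", "mt-Rnr1"]
CHRY_GENES = ["Kdm5d", "Eif2s3y", "Uty", "Ddx3y"]
GERM_MARKERS = ["Ddx4", "Pou5f1"]
SUPPORTING_MARKERS = ["Wt1", "Runx1", "Sox9", "Tspan8"]
SOMA_MARKERS = ["Foxl2", "Insl3", "Plvap", "Pecam1", "Mafb",
                "Pdgfra", "Nr2f2", "Krt19"]
STAGE_PROGRAM_SIZE = 20                # germ-cell genes ramping up with stage

_BASES = np.array(list("ACGT"))
_RC = str.maketrans("ACGTN", "TGCAN")


def _data_path(name: str):
    return importlib.resources.files("pgcgrn.data").joinpath(name)


def load_tf_motif_map() -> pd.DataFrame:
    """Shipped motif_id <-> TF gene mapping (columns motif_id, tf_name, gene_id)."""
    with importlib.resources.as_file(_data_path("tf_motif_map.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def default_motif_file() -> str:
    """Path-like handle to the shipped JASPAR-format toy motif set."""
    return str(_data_path("tf_motif_map.tsv")).replace("tf_motif_map.tsv", "motifs.jaspar")


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic multiome; defaults define the study conditions."""

    n_cells_per_group: int = 400          # nuclei per sex x stage group
    stages: tuple = ("E11.5", "E12.5", "E13.5")
    sexes: tuple = ("XX", "XY")
    n_genes: int = 1000
    n_peaks: int = 2000
    frac_germ: float = 0.5
    frac_supporting: float = 0.25
    n_chrY_genes: int = 4
    n_chrY_peaks: int = 21
    n_motifs: int = 8
    n_de_genes_per_stage: tuple = (10, 35, 60)
    n_da_peaks_per_stage: tuple = (20, 60, 120)
    n_links: int = 50
    link_window: int = 500_000
    effect_size_logfc: float = 1.5        # planted |log2 FC| for DE genes and DA peaks
    link_coupling_sigma: float = 0.9      # latent-factor scale; gives Pearson r ~ 0.3-0.6
    sequencing_depth_rna: float = 5000.0  # mean RNA counts per nucleus
    sequencing_depth_atac: float = 3000.0 # mean fragments per nucleus
    mito_frac_mean: float = 0.05
    n_lr_pairs_true: int = 3
    frac_failed: float = 0.05             # nuclei violating QC thresholds
    frac_sex_mislabeled: float = 0.02     # nuclei carried in the wrong-sex dataset
    n_replicates: int = 2
    n_decoy_motif_sites: int = 60         # random peaks seeded with each decoy motif
    seed: int = 0

    def __post_init__(self):
        for name in ("n_cells_per_group", "n_genes", "n_peaks", "n_motifs",
                     "n_replicates"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if len(self.stages) < 2:
            raise ValueError("at least 2 stages are required (trajectory undefined)")
        if len(set(self.stages)) != len(self.stages):
            raise ValueError("stages must be distinct and ordered")
        if not (0 < self.frac_germ < 1) or not (0 <= self.frac_supporting < 1):
            raise ValueError("compartment fractions must lie in (0,1)")
        if self.frac_germ + self.frac_supporting >= 1:
            raise ValueError("frac_germ + frac_supporting must be < 1")
        if len(self.n_de_genes_per_stage) != len(self.stages) or \
           len(self.n_da_peaks_per_stage) != len(self.stages):
            raise ValueError("per-stage DE/DA counts must match the number of stages")
        if list(self.n_de_genes_per_stage) != sorted(self.n_de_genes_per_stage) or \
           list(self.n_da_peaks_per_stage) != sorted(self.n_da_peaks_per_stage):
            raise ValueError("DE/DA counts must be non-decreasing across stages")
        if self.link_window <= 0 or self.effect_size_logfc < 0:
            raise ValueError("link_window must be positive, effect size non-negative")
        if self.n_links > max(self.n_da_peaks_per_stage) and self.n_links > 0:
            raise ValueError("n_links cannot exceed the final-stage DA peak count")

    @classmethod
    def null(cls, **overrides) -> "GeneratorConfig":
        """A configuration with no planted effects (calibration null)."""
        base = dict(
            n_cells_per_group=200,
            n_de_genes_per_stage=(0,) * 3,
            n_da_peaks_per_stage=(0,) * 3,
            n_links=0,
            effect_size_logfc=0.0,
            n_lr_pairs_true=0,
            frac_sex_mislabeled=0.0,
        )
        base.update(overrides)
        return cls(**base)


# -- helpers ----------------------------------------------------------------

def _lognormal_depth(rng, mean, sigma, n):
    return mean * np.exp(rng.normal(-0.5 * sigma**2, sigma, n))


def _fragment_lengths(rng, n, mono_only=False):
    """Bimodal sub- (mean 80 bp) / mono-nucleosomal (mean 200 bp) lengths."""
    mono = np.clip(np.round(rng.normal(200, 25, n)), 147, 294).astype(np.int64)
    if mono_only:
        return mono
    sub = np.clip(np.round(rng.normal(80, 15, n)), 30, 146).astype(np.int64)
    take_sub = rng.random(n) < 0.65
    return np.where(take_sub, sub, mono)


def _nb_counts(rng, rate, theta):
    """Gamma-Poisson draw; ``rate`` is feature x cell, ``theta`` per feature."""
    shape = np.broadcast_to(theta[:, None], rate.shape)
    lam = rng.gamma(shape, np.where(rate > 0, rate, 1.0) / shape)
    lam = np.where(rate > 0, lam, 0.0)
    return rng.poisson(lam).astype(np.int32)


def _random_sequence(rng, length, gc):
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_BASES[rng.choice(4, size=length, p=p)])


def reverse_complement(seq: str) -> str:
    return seq.translate(_RC)[::-1]


# -- generator --------------------------------------------------------------

def generate_dataset(config: GeneratorConfig) -> tuple[MultiomeDataset, GroundTruth]:
    """Draw one synthetic multiome and the ground truth it was built from."""
    rng = np.random.default_rng(config.seed)
    cfg = config
    stages = list(cfg.stages)
    n_stage = len(stages)

    # ---- gene table -------------------------------------------------------
    tf_map = load_tf_motif_map().iloc[: cfg.n_motifs]
    tf_genes = tf_map["gene_id"].tolist()
    lr_table = read_lr_pairs_fixture()
    lr_genes = sorted({g for _, row in lr_table.iterrows()
                       for g in row["ligand"].split(";") + row["receptor"].split(";")})

    chry_genes = list(CHRY_GENES[: cfg.n_chrY_genes]) + [
        f"chrY_gene_{i}" for i in range(len(CHRY_GENES), cfg.n_chrY_genes)]
    named = (MITO_GENES + chry_genes + GERM_MARKERS + SUPPORTING_MARKERS +
             SOMA_MARKERS + tf_genes + lr_genes)
    named = list(dict.fromkeys(named))  # preserve order, drop duplicates
    n_named = len(named)
    n_filler = cfg.n_genes - n_named
    if n_filler < max(cfg.n_de_genes_per_stage) + STAGE_PROGRAM_SIZE + 10:
        raise ValueError("n_genes too small for the planted structure")
    fillers = [f"gene_{i:04d}" for i in range(n_filler)]
    gene_ids = named + fillers
    G = len(gene_ids)
    gidx = {g: i for i, g in enumerate(gene_ids)}

    gene_meta = pd.DataFrame(index=pd.Index(gene_ids, name="gene_id"))
    gene_meta["is_mito"] = [g in MITO_GENES for g in gene_ids]
    gene_meta["is_chrY"] = [g in chry_genes for g in gene_ids]
    marker_of = {}
    for g in GERM_MARKERS:
        marker_of[g] = "germ"
    for g in SUPPORTING_MARKERS:
        marker_of[g] = "supporting"
    for g in SOMA_MARKERS:
        marker_of[g] = "other-soma"
    gene_meta["is_marker_of"] = [marker_of.get(g, "") for g in gene_ids]

    # positions: nuclear genes tile the autosomes, 100 kb apart
    nuclear = [g for g in gene_ids if g not in MITO_GENES and g not in chry_genes]
    chroms, tss, strands, gstart, gend = {}, {}, {}, {}, {}
    ex_starts, ex_ends = {}, {}
    per_chrom = int(np.ceil(len(nuclear) / len(AUTOSOMES)))
    for i, g in enumerate(nuclear):
        chrom = AUTOSOMES[i // per_chrom]
        pos = GENE_SPACING * (i % per_chrom + 1)
        strand = "+" if i % 2 == 0 else "-"
        glen = int(rng.integers(5_000, 20_000))
        if strand == "+":
            s, e = pos, pos + glen
        else:
            s, e = pos - glen, pos
        # two exons of 30% of the body each, one intron between
        e1 = int(0.3 * glen)
        chroms[g], tss[g], strands[g] = chrom, pos, strand
        gstart[g], gend[g] = s, e
        ex_starts[g], ex_ends[g] = f"{s},{e - e1}", f"{s + e1},{e}"
    for k, g in enumerate(chry_genes):
        chroms[g], tss[g], strands[g] = CHRY, 1_000_000 * (k + 1), "+"
        gstart[g], gend[g] = tss[g], tss[g] + 10_000
        ex_starts[g], ex_ends[g] = f"{gstart[g]},{gend[g]-3000}", f"{gstart[g]+3000},{gend[g]}"
    for k, g in enumerate(MITO_GENES):
        chroms[g], tss[g], strands[g] = CHRM, 100 + 1_000 * k, "+"
        gstart[g], gend[g] = tss[g], tss[g] + 900
        ex_starts[g], ex_ends[g] = f"{gstart[g]}", f"{gend[g]}"
    for col, d in (("chrom", chroms), ("tss", tss), ("strand", strands),
                   ("start", gstart), ("end", gend),
                   ("exon_starts", ex_starts), ("exon_ends", ex_ends)):
        gene_meta[col] = [d[g] for g in gene_ids]
    gene_meta["tss"] = gene_meta["tss"].astype(np.int64)
    chrom_len = {c: GENE_SPACING * (per_chrom + 2) for c in AUTOSOMES}

    # ---- planted DE genes -------------------------------------------------
    n_de_final = max(cfg.n_de_genes_per_stage)
    de_pool = fillers[STAGE_PROGRAM_SIZE:]
    causal_tf, target_tf = (tf_genes[0], tf_genes[1]) if len(tf_genes) >= 2 else (None, None)
    de_genes, de_sex = [], []
    if n_de_final:
        n_pick = n_de_final - (2 if causal_tf else 0)
        # planted DE genes keep >= link_window genomic separation (from each
        # other and from the TF circuit genes) so that a planted link peak's
        # neighborhood never contains a second planted gene: candidate pairs
        # that are not planted links stay genuinely null
        taken = [(chroms[t], tss[t]) for t in (causal_tf, target_tf) if t]
        shuffled = list(rng.permutation(de_pool))
        picked = []
        for g in shuffled:
            if len(picked) == n_pick:
                break
            if all(c != chroms[g] or abs(t - tss[g]) > cfg.link_window
                   for c, t in taken):
                picked.append(g)
                taken.append((chroms[g], tss[g]))
        for g in shuffled:                       # fallback when space runs out
            if len(picked) == n_pick:
                break
            if g not in picked:
                picked.append(g)
        # alternate sexes through the nested stage sets so each stage is balanced
        for i, g in enumerate(picked):
            de_genes.append(g)
            de_sex.append("XX" if i % 2 == 0 else "XY")
        if causal_tf:
            # the TF circuit genes join the final-stage set, XX-up
            de_genes += [causal_tf, target_tf]
            de_sex += ["XX", "XX"]
    stage_program = fillers[:STAGE_PROGRAM_SIZE]

    # ---- peak table -------------------------------------------------------
    n_chry_peaks = cfg.n_chrY_peaks
    n_auto_peaks = cfg.n_peaks - n_chry_peaks
    peak_ids = [f"peak_{i:05d}" for i in range(cfg.n_peaks)]
    pidx = {p: i for i, p in enumerate(peak_ids)}
    p_chrom = np.empty(cfg.n_peaks, dtype=object)
    p_start = np.zeros(cfg.n_peaks, dtype=np.int64)
    p_width = rng.integers(300, 1000, cfg.n_peaks).astype(np.int64)

    # planted links: DA peaks placed 10-200 kb from their target gene's TSS
    n_links = cfg.n_links
    link_peaks, link_genes = [], []
    if n_links:
        xx_de = [g for g, s in zip(de_genes, de_sex) if s == "XX" and g != causal_tf]
        xy_de = [g for g, s in zip(de_genes, de_sex) if s == "XY"]
        n_half = n_links // 2
        lg = ([target_tf] + [g for g in xx_de if g != target_tf])[:n_half] + xy_de[: n_links - n_half]
        if len(lg) < n_links:
            raise ValueError("not enough DE genes to carry the planted links")
        link_genes = lg
        link_peaks = [f"peak_{i:05d}" for i in range(n_links)]
    # peaks never overlap each other (a fragment belongs to exactly one peak)
    from bisect import bisect_left, insort
    occupied: dict[str, list[tuple[int, int]]] = {}

    def free(chrom, s, e):
        spans = occupied.setdefault(chrom, [])
        j = bisect_left(spans, (s, e))
        for nb in (j - 1, j):
            if 0 <= nb < len(spans):
                a, b = spans[nb]
                if s < b and e > a:
                    return False
        return True

    def claim(chrom, s, e):
        insort(occupied.setdefault(chrom, []), (s, e))

    # promoter peaks on ~30% of genes (placed first: their position is fixed)
    i0 = len(link_peaks)
    n_prom = int(0.3 * n_auto_peaks)
    prom_genes = list(rng.choice(nuclear, size=n_prom, replace=False))
    if target_tf and n_links:
        # the circuit target TF always carries a promoter peak (cross-regulation
        # is detectable through the promoter window as well as through links)
        if target_tf in prom_genes:
            prom_genes.remove(target_tf)
        else:
            prom_genes.pop()
        prom_genes.insert(0, target_tf)
    for j, g in enumerate(prom_genes):
        i = i0 + j
        p_chrom[i] = chroms[g]
        p_start[i] = tss[g] - p_width[i] // 2
        claim(chroms[g], int(p_start[i]), int(p_start[i] + p_width[i]))

    for i, (p, g) in enumerate(zip(link_peaks, link_genes)):
        for _ in range(100):
            offset = int(rng.integers(10_000, 200_000)) * (1 if rng.random() < 0.5 else -1)
            pos = int(np.clip(tss[g] + offset, 1000, chrom_len[chroms[g]] - 2000))
            if free(chroms[g], pos, pos + int(p_width[i])):
                break
        p_chrom[i], p_start[i] = chroms[g], pos
        claim(chroms[g], pos, pos + int(p_width[i]))

    for i in range(i0 + n_prom, n_auto_peaks):
        for _ in range(100):
            c = AUTOSOMES[int(rng.integers(len(AUTOSOMES)))]
            pos = int(rng.integers(1000, chrom_len[c] - 2000))
            if free(c, pos, pos + int(p_width[i])):
                break
        p_chrom[i], p_start[i] = c, pos
        claim(c, pos, pos + int(p_width[i]))
    for k in range(n_chry_peaks):
        i = n_auto_peaks + k
        lo, hi = CHRY_REGION
        for _ in range(100):
            pos = int(rng.integers(lo, hi - 1000))
            if free(CHRY, pos, pos + int(p_width[i])):
                break
        p_chrom[i], p_start[i] = CHRY, pos
        claim(CHRY, pos, pos + int(p_width[i]))
    p_end = p_start + p_width
    peak_meta = pd.DataFrame(
        {"chrom": p_chrom, "start": p_start, "end": p_end},
        index=pd.Index(peak_ids, name="peak_id"),
    )
    chry_peak_ids = peak_ids[n_auto_peaks:]

    # planted DA peaks: the link peaks plus extra autosomal peaks, sexes balanced
    n_da_final = max(cfg.n_da_peaks_per_stage)
    da_peaks = list(link_peaks)
    da_sex = ["XX" if g in set(de_genes) and de_sex[de_genes.index(g)] == "XX" else "XY"
              for g in link_genes]
    extra = [p for p in peak_ids[:n_auto_peaks] if p not in set(link_peaks)]
    extra = list(rng.choice(extra, size=n_da_final - len(da_peaks), replace=False)) \
        if n_da_final > len(da_peaks) else []
    for i, p in enumerate(extra):
        da_peaks.append(p)
        da_sex.append("XX" if i % 2 == 0 else "XY")

    # ---- cells ------------------------------------------------------------
    comps = ["germ", "supporting", "other-soma"]
    rows = []
    for sex in cfg.sexes:
        for stage in stages:
            n = cfg.n_cells_per_group
            n_germ = int(round(cfg.frac_germ * n))
            n_supp = int(round(cfg.frac_supporting * n))
            comp = (["germ"] * n_germ + ["supporting"] * n_supp +
                    ["other-soma"] * (n - n_germ - n_supp))
            for c in comp:
                rows.append((sex, stage, c))
    n_normal = len(rows)
    n_failed = int(round(cfg.frac_failed * n_normal))
    fail_modes = []
    for k in range(n_failed):
        sex = cfg.sexes[int(rng.integers(len(cfg.sexes)))]
        stage = stages[int(rng.integers(n_stage))]
        comp = comps[int(rng.integers(3))]
        rows.append((sex, stage, comp))
        fail_modes.append(("low_rna", "high_mito", "low_atac", "mono_fragments")[k % 4])
    N = len(rows)
    cell_ids = [f"cell_{i:05d}" for i in range(N)]
    cell_meta = pd.DataFrame(rows, columns=["sex", "stage", "compartment"],
                             index=pd.Index(cell_ids, name="cell_id"))
    cell_meta = cell_meta[["sex", "stage", "compartment"]]
    cell_meta.insert(2, "replicate",
                     [f"r{int(r) + 1}" for r in rng.integers(0, cfg.n_replicates, N)])
    cell_meta["true_sex"] = cell_meta["sex"]
    cell_meta["qc_ok"] = [True] * n_normal + [False] * n_failed
    cell_meta["qc_fail_mode"] = [""] * n_normal + fail_modes
    # sex mislabeling: the dataset label (column "sex") disagrees with truth
    if cfg.frac_sex_mislabeled > 0:
        n_flip = int(round(cfg.frac_sex_mislabeled * n_normal))
        flip = rng.choice(n_normal, size=n_flip, replace=False)
        other = {"XX": "XY", "XY": "XX"}
        lab = cell_meta["sex"].to_numpy(object)
        for i in flip:
            lab[i] = other[lab[i]]
        cell_meta["sex"] = lab

    true_sex = cell_meta["true_sex"].to_numpy()
    stage_of = cell_meta["stage"].to_numpy()
    comp_of = cell_meta["compartment"].to_numpy()
    is_germ = comp_of == "germ"
    stage_rank = np.array([stages.index(s) for s in stage_of])

    # ---- RNA rates --------------------------------------------------------
    w = np.exp(rng.normal(0.0, 1.0, G))          # baseline relative expression
    W0 = w.sum()

    def weight_for(target_counts: float) -> float:
        # weight giving ~target mean counts/cell at the configured depth
        # (approximate: later overrides shift the column total only slightly)
        return target_counts / cfg.sequencing_depth_rna * W0

    for g in de_genes:
        w[gidx[g]] = weight_for(float(rng.uniform(1.0, 4.0)))
    for g in GERM_MARKERS + SUPPORTING_MARKERS + SOMA_MARKERS + chry_genes:
        w[gidx[g]] = weight_for(6.0)
    for g in tf_genes:
        w[gidx[g]] = weight_for(4.0)

    rate = np.tile(w[:, None], (1, N))

    # compartment-restricted genes
    for g in GERM_MARKERS:
        rate[gidx[g], ~is_germ] = 0.0
    for g in SUPPORTING_MARKERS:
        rate[gidx[g], comp_of != "supporting"] = 0.0
    for g in SOMA_MARKERS:
        rate[gidx[g], comp_of != "other-soma"] = 0.0
    for g in tf_genes:
        if g == "Rreb1":
            continue                      # Rreb1 is broadly expressed (not germline-enriched)
        rate[gidx[g], ~is_germ] = 0.0
    for g in chry_genes:
        rate[gidx[g], true_sex == "XX"] = 0.0

    # stage program: germ-cell genes ramping 1x/2x/4x across stages
    ramp = 2.0 ** stage_rank
    for g in stage_program:
        rate[gidx[g], is_germ] *= ramp[is_germ]

    # planted DE: multiplicative 2^logfc in germ cells of the up-sex,
    # active from the stage at which the gene enters the nested DE set
    fc = 2.0 ** cfg.effect_size_logfc
    true_de_rows = []
    for s_i, n_active in enumerate(cfg.n_de_genes_per_stage):
        for g, sx in zip(de_genes[:n_active], de_sex[:n_active]):
            true_de_rows.append((g, stages[s_i], sx, cfg.effect_size_logfc))
    gene_stage_entry = {}
    for s_i, n_active in enumerate(cfg.n_de_genes_per_stage):
        for g in de_genes[:n_active]:
            gene_stage_entry.setdefault(g, s_i)
    for g, sx in zip(de_genes, de_sex):
        active = is_germ & (true_sex == sx) & (stage_rank >= gene_stage_entry[g])
        rate[gidx[g], active] *= fc
    # chrY genes are genuinely sex-different at every stage; record them as truth
    for g in chry_genes:
        for st in stages:
            true_de_rows.append((g, st, "XY", np.inf))
    true_de = pd.DataFrame(true_de_rows, columns=["gene", "stage", "sex_up", "logfc"])

    # ligand-receptor planting
    lr_rows = []
    true_pairs = lr_table.iloc[: cfg.n_lr_pairs_true]
    planted_lr_sex = {}
    for k, (_, row) in enumerate(true_pairs.iterrows()):
        sx = "XY" if k == 2 else "XX"
        planted_lr_sex[row["pair_id"]] = sx
        lr_rows.append((row["pair_id"], row["ligand"], row["receptor"],
                        "supporting", "germ", sx))
        for g in row["ligand"].split(";"):
            sender = (comp_of == "supporting") & (true_sex == sx)
            rate[gidx[g], :] = weight_for(0.02)
            rate[gidx[g], sender] = weight_for(4.0)
        for g in row["receptor"].split(";"):
            rate[gidx[g], :] = weight_for(0.2)
            rate[gidx[g], is_germ] = weight_for(4.0)
    for _, row in lr_table.iloc[cfg.n_lr_pairs_true:].iterrows():
        for g in row["ligand"].split(";") + row["receptor"].split(";"):
            if g in marker_of:            # marker genes keep their compartment pattern
                continue
            rate[gidx[g], :] = weight_for(1.0)
    true_lr = pd.DataFrame(lr_rows, columns=["pair_id", "ligand", "receptor",
                                             "sender", "receiver", "sex"])

    # ---- ATAC rates -------------------------------------------------------
    P = cfg.n_peaks
    v = np.exp(rng.normal(0.0, 0.8, P))
    arate = np.tile(v[:, None], (1, N))
    for p in chry_peak_ids:
        arate[pidx[p], true_sex == "XX"] = 0.0
    true_da_rows = []
    da_stage_entry = {}
    for s_i, n_active in enumerate(cfg.n_da_peaks_per_stage):
        for p, sx in zip(da_peaks[:n_active], da_sex[:n_active]):
            true_da_rows.append((p, stages[s_i], sx, cfg.effect_size_logfc))
        for p in da_peaks[:n_active]:
            da_stage_entry.setdefault(p, s_i)
    for p, sx in zip(da_peaks, da_sex):
        active = is_germ & (true_sex == sx) & (stage_rank >= da_stage_entry[p])
        arate[pidx[p], active] *= fc
    for p in chry_peak_ids:
        for st in stages:
            true_da_rows.append((p, st, "XY", np.inf))
    true_da = pd.DataFrame(true_da_rows, columns=["peak", "stage", "sex_up", "logfc"])

    # link coupling: shared log-normal latent factor per (peak, gene) pair
    sig = cfg.link_coupling_sigma
    for p, g in zip(link_peaks, link_genes):
        f = rng.normal(0.0, 1.0, N)
        boost = np.exp(sig * f - 0.5 * sig**2)
        rate[gidx[g], :] *= boost
        arate[pidx[p], :] *= boost
    true_links = pd.DataFrame({"peak": link_peaks, "gene": link_genes})

    # ---- depths and counts ------------------------------------------------
    d_rna = _lognormal_depth(rng, cfg.sequencing_depth_rna, 0.25, N)
    d_atac = _lognormal_depth(rng, cfg.sequencing_depth_atac, 0.25, N)
    mito_frac = np.clip(rng.normal(cfg.mito_frac_mean, 0.015, N), 0.005, 0.2)
    for i in range(n_failed):
        c = n_normal + i
        mode = fail_modes[i]
        if mode == "low_rna":
            d_rna[c] = rng.uniform(200, 900)
        elif mode == "high_mito":
            mito_frac[c] = rng.uniform(0.35, 0.6)
        elif mode == "low_atac":
            d_atac[c] = rng.uniform(100, 800)

    is_mito = gene_meta["is_mito"].to_numpy(bool)
    rate_n = rate.copy()
    col_nonmito = rate_n[~is_mito].sum(axis=0)
    col_mito = rate_n[is_mito].sum(axis=0)
    col_mito[col_mito == 0] = 1.0
    rate_n[~is_mito] *= (1.0 - mito_frac) / col_nonmito
    rate_n[is_mito] *= mito_frac / col_mito
    rna_rate = rate_n * d_rna

    acol = arate.sum(axis=0)
    atac_rate = arate / acol * d_atac

    theta_g = rng.uniform(5.0, 50.0, G)
    theta_p = rng.uniform(10.0, 50.0, P)
    rna_counts = _nb_counts(rng, rna_rate, theta_g)
    atac_counts = _nb_counts(rng, atac_rate, theta_p)

    # ---- fragments --------------------------------------------------------
    coo = sp.coo_matrix(atac_counts)
    rep_peak = np.repeat(coo.row, coo.data)
    rep_cell = np.repeat(coo.col, coo.data)
    n_frag = rep_peak.size
    mono_cells = {n_normal + i for i, m in enumerate(fail_modes) if m == "mono_fragments"}
    lengths = _fragment_lengths(rng, n_frag)
    if mono_cells:
        mask = np.isin(rep_cell, list(mono_cells))
        lengths[mask] = _fragment_lengths(rng, int(mask.sum()), mono_only=True)
    widths = p_width[rep_peak]
    lengths = np.minimum(lengths, widths - 1)
    starts = p_start[rep_peak] + np.floor(
        rng.random(n_frag) * (widths - lengths)).astype(np.int64)
    fragments = pd.DataFrame({
        "cell": np.array(cell_ids, dtype=object)[rep_cell],
        "chrom": p_chrom[rep_peak],
        "start": starts,
        "end": starts + lengths,
    })
    fragments = fragments.sort_values(["cell", "chrom", "start"],
                                      kind="mergesort").reset_index(drop=True)

    # ---- peak sequences and motif planting --------------------------------
    gc_target = np.clip(rng.normal(0.45, 0.08, P), 0.25, 0.65)
    seqs = {p: _random_sequence(rng, int(p_width[i]), gc_target[i])
            for i, p in enumerate(peak_ids)}
    from .motifs import read_jaspar  # local import to avoid a cycle
    with importlib.resources.as_file(_data_path("motifs.jaspar")) as mp:
        motif_models = read_jaspar(str(mp))[: cfg.n_motifs]
    planted_rows = []
    used = {p: [] for p in peak_ids}

    def plant(motif, peak):
        cons = motif.consensus
        L = len(cons)
        width = len(seqs[peak])
        if width <= L:
            return
        for _ in range(30):
            off = int(rng.integers(0, width - L))
            if all(off + L <= a or off >= b for a, b in used[peak]):
                s = seqs[peak]
                seqs[peak] = s[:off] + cons + s[off + L:]
                used[peak].append((off, off + L))
                planted_rows.append((motif.motif_id, peak, off, "+"))
                return

    causal_motif = motif_models[0] if motif_models else None
    xx_link_peaks = [p for p, sx in zip(da_peaks[:n_links], da_sex[:n_links]) if sx == "XX"]
    if n_links and causal_motif is not None:
        for p in xx_link_peaks:
            plant(causal_motif, p)
        if target_tf:
            plant(causal_motif, peak_ids[i0])     # the target TF's promoter peak
    # decoy motifs stay out of DA/link peaks and TF promoters so that no
    # decoy can acquire the planted regulatory wiring by construction
    avoid = set(link_peaks) | set(chry_peak_ids) | set(da_peaks)
    # keep decoy motifs away from the TF genes' own promoter peaks so decoy
    # cross-regulation edges cannot arise by construction
    tf_tss = {tss[g] for g in tf_genes if g in tss}
    for i, p in enumerate(peak_ids):
        if p_chrom[i] in AUTOSOMES:
            mid = (p_start[i] + p_end[i]) // 2
            if any(abs(mid - t) < 5000 for t in tf_tss):
                avoid.add(p)
    decoy_pool = [p for p in peak_ids if p not in avoid]
    for m in motif_models[1:]:
        picks = rng.choice(decoy_pool, size=min(cfg.n_decoy_motif_sites, len(decoy_pool)),
                           replace=False)
        for p in picks:
            plant(m, p)
    planted = pd.DataFrame(planted_rows, columns=["motif_id", "peak", "offset", "strand"])

    gc_actual = np.array([
        (seqs[p].count("G") + seqs[p].count("C")) / len(seqs[p]) for p in peak_ids])
    peak_meta["gc_fraction"] = gc_actual

    tf_targets = {}
    if n_links and causal_motif is not None:
        tf_targets[causal_motif.motif_id] = {
            g for p, g in zip(link_peaks, link_genes) if p in set(xx_link_peaks)}

    dataset = MultiomeDataset(
        rna_counts=sp.csr_matrix(rna_counts),
        atac_counts=sp.csr_matrix(atac_counts),
        fragments=fragments,
        cell_meta=cell_meta,
        gene_meta=gene_meta,
        peak_meta=peak_meta,
        peak_seqs=seqs,
    )
    dataset.validate()
    truth = GroundTruth(
        true_de=true_de,
        true_da=true_da,
        true_links=true_links,
        true_tf_targets=tf_targets,
        planted_motif_positions=planted,
        true_lr=true_lr,
        sex_of_cell=cell_meta["true_sex"].rename("sex"),
    )
    return dataset, truth


def read_lr_pairs_fixture() -> pd.DataFrame:
    """The shipped toy ligand-receptor pair list."""
    with importlib.resources.as_file(_data_path("lr_pairs.tsv")) as p:
        return pd.read_csv(p, sep="\t")
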