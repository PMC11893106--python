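"""Per-cell QC metrics, cell/peak filtering, module scores and sex assignment.

The QC metrics and thresholds follow the usual single-nucleus multiome
conventions: RNA depth between 1,000 and 25,000 counts, mitochondrial
fraction below 25%, ATAC depth between 1,000 and 100,000, nucleosome signal
below 2 and TSS enrichment above 1 (all strict inequalities). Sex is called
from a rank-based module score of the four Y-linked genes (*Kdm5d*,
*Eif2s3y*, *Uty*, *Ddx3y*) combined with the fragment count over the chrY
peak region (chrY:1-90,000,000).
"""
from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import rankdata

from .types import MultiomeDataset

CHRY_REGION = ("chrY", 1, 90_000_000)
_STANDARD_CHROM = re.compile(r"^chr(\d+|[XYM])$")


@dataclass
class QCThresholds:
    """Strict-inequality QC gates; a cell is kept iff every condition holds."""
    rna_min: float = 1000
    rna_max: float = 25_000
    mt_max: float = 25.0
    atac_min: float = 1000
    atac_max: float = 100_000
    nucleosome_signal_max: float = 2.0
    tss_enrichment_min: float = 1.0


@dataclass
class MarkerRule:
    """Per-cell population rule: required genes expressed, exclusion genes absent."""
    label: str
    require_expressed: list
    require_absent: list
    expressed_threshold: int = 1      # raw count strictly greater than this
    absent_threshold: int = 1         # raw count strictly smaller than this

    def __post_init__(self):
        if set(self.require_expressed) & set(self.require_absent):
            raise ValueError("require_expressed and require_absent overlap")


def pgc_rule() -> MarkerRule:
    """Germ-cell selection: Ddx4+/Pou5f1+ nuclei without somatic marker signal."""
    return MarkerRule(
        label="PGC",
        require_expressed=["Ddx4", "Pou5f1"],
        require_absent=["Foxl2", "Runx1", "Sox9", "Insl3", "Wt1", "Plvap",
                        "Mafb", "Pdgfra", "Nr2f2", "Tspan8", "Krt19"],
    )


def supporting_rule() -> MarkerRule:
    """Supporting-cell selection: Wt1+ nuclei without germ/endothelial/interstitial signal."""
    return MarkerRule(
        label="supporting",
        require_expressed=["Wt1"],
        require_absent=["Ddx4", "Pou5f1", "Plvap", "Pecam1", "Pdgfra", "Nr2f2"],
    )


def compute_qc(dataset: MultiomeDataset, mito_genes=None,
               tss_flank: int = 2000, tss_background: int = 100) -> pd.DataFrame:
    """Per-cell QC table: n_count_rna, percent_mt, n_count_atac,
    nucleosome_signal and tss_enrichment.

    ``tss_flank`` is the total width of the central TSS window (TSS +/-
    tss_flank/2); the background is two windows of ``tss_background`` bp
    immediately outside it. Enrichment is the ratio of per-bp fragment
    midpoint coverage, central over background; 0/0 is reported as 0 and
    x/0 as +inf.
    """
    cells = dataset.cell_ids
    n_count_rna = np.asarray(dataset.rna_counts.sum(axis=0)).ravel()
    if mito_genes is None:
        mito_mask = dataset.gene_meta.get(
            "is_mito", pd.Series(False, index=dataset.gene_ids)).to_numpy(bool)
    else:
        mito_mask = dataset.gene_ids.isin(mito_genes)
    mito_counts = np.asarray(dataset.rna_counts[mito_mask].sum(axis=0)).ravel()
    with np.errstate(divide="ignore", invalid="ignore"):
        percent_mt = np.where(n_count_rna > 0, 100.0 * mito_counts / n_count_rna, 0.0)
    n_count_atac = np.asarray(dataset.atac_counts.sum(axis=0)).ravel()

    frags = dataset.fragments
    cell_codes = cells.get_indexer(frags["cell"])
    lengths = (frags["end"] - frags["start"]).to_numpy()
    short = np.bincount(cell_codes[lengths < 147], minlength=len(cells)).astype(float)
    mono = np.bincount(cell_codes[(lengths >= 147) & (lengths <= 294)],
                       minlength=len(cells)).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        nucleosome_signal = np.where(short > 0, mono / short, np.inf)

    half = tss_flank // 2
    mid = ((frags["start"] + frags["end"]) // 2).to_numpy()
    dist = np.full(len(frags), np.inf)
    for chrom, gm in dataset.gene_meta.groupby("chrom"):
        tss = np.sort(gm["tss"].to_numpy())
        sel = (frags["chrom"] == chrom).to_numpy()
        if not sel.any() or len(tss) == 0:
            continue
        pos = mid[sel]
        j = np.searchsorted(tss, pos)
        d_right = np.where(j < len(tss), np.abs(tss[np.minimum(j, len(tss) - 1)] - pos), np.inf)
        d_left = np.where(j > 0, np.abs(pos - tss[np.maximum(j - 1, 0)]), np.inf)
        dist[sel] = np.minimum(d_left, d_right)
    in_center = dist <= half
    in_flank = (dist > half) & (dist <= half + tss_background)
    c_center = np.bincount(cell_codes[in_center], minlength=len(cells)).astype(float)
    c_flank = np.bincount(cell_codes[in_flank], minlength=len(cells)).astype(float)
    rate_center = c_center / (2 * half)
    rate_flank = c_flank / (2 * tss_background)
    with np.errstate(divide="ignore", invalid="ignore"):
        tss_enrichment = np.where(
            c_flank > 0, rate_center / rate_flank,
            np.where(c_center > 0, np.inf, 0.0))

    return pd.DataFrame({
        "n_count_rna": n_count_rna,
        "percent_mt": percent_mt,
        "n_count_atac": n_count_atac,
        "nucleosome_signal": nucleosome_signal,
        "tss_enrichment": tss_enrichment,
    }, index=cells)


def filter_cells(qc: pd.DataFrame, thresholds: QCThresholds | None = None
                 ) -> tuple[pd.Index, pd.Series]:
    """Apply the strict QC gates; returns (kept cells, per-condition failure tally)."""
    t = thresholds or QCThresholds()
    conds = {
        "rna_min": qc["n_count_rna"] > t.rna_min,
        "rna_max": qc["n_count_rna"] < t.rna_max,
        "mt_max": qc["percent_mt"] < t.mt_max,
        "atac_min": qc["n_count_atac"] > t.atac_min,
        "atac_max": qc["n_count_atac"] < t.atac_max,
        "nucleosome_signal_max": qc["nucleosome_signal"] < t.nucleosome_signal_max,
        "tss_enrichment_min": qc["tss_enrichment"] > t.tss_enrichment_min,
    }
    keep = np.ones(len(qc), dtype=bool)
    tally = {}
    for name, ok in conds.items():
        ok = ok.to_numpy()
        tally[name] = int((~ok).sum())
        keep &= ok
    return qc.index[keep], pd.Series(tally, name="n_failed")


def filter_peaks(peak_meta: pd.DataFrame, width_min: int = 20,
                 width_max: int = 10_000, blacklist: pd.DataFrame | None = None
                 ) -> pd.Index:
    """Keep peaks with 20 < width < 10,000 bp on standard chromosomes and
    outside an optional blacklist (BED-like frame with chrom/start/end)."""
    width = peak_meta["end"] - peak_meta["start"]
    keep = (width > width_min) & (width < width_max)
    keep &= peak_meta["chrom"].map(lambda c: bool(_STANDARD_CHROM.match(str(c))))
    if blacklist is not None and len(blacklist):
        for chrom, bl in blacklist.groupby("chrom"):
            sel = (peak_meta["chrom"] == chrom).to_numpy()
            if not sel.any():
                continue
            s = peak_meta.loc[sel, "start"].to_numpy()[:, None]
            e = peak_meta.loc[sel, "end"].to_numpy()[:, None]
            bs = bl["start"].to_numpy()[None, :]
            be = bl["end"].to_numpy()[None, :]
            overlap = ((s < be) & (e > bs)).any(axis=1)
            idx = np.flatnonzero(sel)[overlap]
            keep.iloc[idx] = False
    return peak_meta.index[keep.to_numpy(bool)]


def _dense(norm_expr) -> np.ndarray:
    return norm_expr.toarray() if sp.issparse(norm_expr) else np.asarray(norm_expr)


def module_score_binned(norm_expr, gene_ids: pd.Index, gene_set,
                        n_bins: int = 24, n_ctrl_per_gene: int = 100,
                        seed: int = 0) -> np.ndarray:
    """Expression-binned control module score (mean of set genes minus mean of
    bin-matched control genes, per cell)."""
    gene_set = list(gene_set)
    if not gene_set:
        raise ValueError("empty gene set")
    gene_ids = pd.Index(gene_ids)
    missing = set(gene_set) - set(gene_ids)
    if missing:
        raise KeyError(f"genes not in matrix: {sorted(missing)[:3]}")
    X = _dense(norm_expr)
    rng = np.random.default_rng(seed)
    avg = X.mean(axis=1)
    order = rankdata(avg, method="average")
    bins = np.minimum((order - 1) * n_bins // len(avg), n_bins - 1).astype(int)
    pos = gene_ids.get_indexer(gene_set)
    ctrl: set[int] = set()
    for g in pos:
        pool = np.flatnonzero(bins == bins[g])
        ctrl.update(rng.choice(pool, size=n_ctrl_per_gene, replace=True).tolist())
    set_score = X[pos].mean(axis=0)
    ctrl_score = X[sorted(ctrl)].mean(axis=0)
    return set_score - ctrl_score


def module_score_rank(norm_expr, gene_ids: pd.Index, gene_set,
                      r_max: int = 1500) -> np.ndarray:
    """Rank-based (Mann-Whitney U) module score in [0, 1] per cell.

    Genes are ranked per cell by decreasing expression (average ranks on
    ties); ranks beyond ``r_max`` are clipped to ``r_max + 1``.
    """
    gene_set = list(gene_set)
    if not gene_set:
        raise ValueError("empty gene set")
    if r_max < len(gene_set):
        raise ValueError("r_max must be at least the size of the gene set")
    gene_ids = pd.Index(gene_ids)
    pos = gene_ids.get_indexer(gene_set)
    if (pos < 0).any():
        raise KeyError("gene set contains genes absent from the matrix")
    X = _dense(norm_expr)
    ranks = rankdata(-X, axis=0, method="average")
    clipped = np.minimum(ranks, r_max + 1)
    k = len(gene_set)
    u = clipped[pos].sum(axis=0) - k * (k + 1) / 2
    return 1.0 - u / (k * r_max)


def chry_fragment_counts(fragments: pd.DataFrame, cells: pd.Index,
                         region=CHRY_REGION) -> pd.Series:
    """Per-cell count of fragments overlapping the chrY sexing region."""
    chrom, lo, hi = region
    sel = (fragments["chrom"] == chrom) & \
          (fragments["start"] < hi) & (fragments["end"] > lo)
    codes = cells.get_indexer(fragments.loc[sel, "cell"])
    counts = np.bincount(codes[codes >= 0], minlength=len(cells))
    return pd.Series(counts, index=cells, name="chrY_fragment_count")


@dataclass
class SexCallResult:
    calls: pd.DataFrame          # cell_id-indexed: score, chrY_fragment_count, call
    threshold_male: float
    threshold_female: float


def assign_sex(scores: pd.Series, chry_frag: pd.Series, cell_meta: pd.DataFrame,
               reference_stage: str = "E13.5", n_sd: float = 1.0) -> SexCallResult:
    """chrY-based sex confirmation against same-assay reference distributions.

    The latest-stage cells of each labeled sex serve as reference. A cell in
    a male (XY-labeled) dataset is removed when it has zero chrY fragments or
    a chrY module score below mean - ``n_sd``*SD of the XY reference; a cell
    in a female dataset is removed when it has any chrY fragment or a score
    above mean + ``n_sd``*SD of the XX reference. Survivors are called XY/XX.
    """
    scores = scores.reindex(cell_meta.index)
    chry_frag = chry_frag.reindex(cell_meta.index).fillna(0)
    ref_xy = scores[(cell_meta["sex"] == "XY") & (cell_meta["stage"] == reference_stage)]
    ref_xx = scores[(cell_meta["sex"] == "XX") & (cell_meta["stage"] == reference_stage)]
    if len(ref_xy) < 2 or len(ref_xx) < 2:
        raise ValueError("need at least 2 reference cells per sex to estimate an SD")
    t_m = float(ref_xy.mean() - n_sd * ref_xy.std(ddof=1))
    t_f = float(ref_xx.mean() + n_sd * ref_xx.std(ddof=1))
    call = np.empty(len(cell_meta), dtype=object)
    labeled_xy = (cell_meta["sex"] == "XY").to_numpy()
    frag = chry_frag.to_numpy()
    sc = scores.to_numpy()
    rm_male = labeled_xy & ((frag == 0) | (sc < t_m))
    rm_female = ~labeled_xy & ((frag >= 1) | (sc > t_f))
    call[labeled_xy] = "XY"
    call[~labeled_xy] = "XX"
    call[rm_male | rm_female] = "removed"
    calls = pd.DataFrame({
        "chrY_module_score": sc,
        "chrY_fragment_count": frag.astype(int),
        "call": call,
    }, index=cell_meta.index)
    return SexCallResult(calls=calls, threshold_male=t_m, threshold_female=t_f)


def select_population(rna_counts, gene_ids: pd.Index, cells: pd.Index,
                      rules: list[MarkerRule]) -> dict[str, pd.Index]:
    """Apply marker rules to raw counts; returns {label: selected cells}."""
    gene_ids = pd.Index(gene_ids)
    X = rna_counts.tocsr() if sp.issparse(rna_counts) else sp.csr_matrix(rna_counts)
    out: dict[str, pd.Index] = {}
    for rule in rules:
        for g in rule.require_expressed + rule.require_absent:
            if g not in gene_ids:
                raise KeyError(f"rule {rule.label!r} references unknown gene {g!r}")
        keep = np.ones(X.shape[1], dtype=bool)
        for g in rule.require_expressed:
            keep &= np.asarray(X[gene_ids.get_loc(g)].todense()).ravel() > rule.expressed_threshold
        for g in rule.require_absent:
            keep &= np.asarray(X[gene_ids.get_loc(g)].todense()).ravel() < rule.absent_threshold
        out[rule.label] = pd.Index(cells)[keep]
    return out
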