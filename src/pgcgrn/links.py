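"""Peak-to-gene linkage against a matched-background null, plus peak annotation.

A candidate (peak, gene) pair is any peak whose midpoint lies within a
window (default 500 kb) of the gene's TSS on the same chromosome. For each
pair the Pearson correlation r between normalized accessibility and
normalized expression across cells is compared with the correlations of the
same gene against background peaks matched to the query peak in (GC content,
mean accessibility, width) feature space; the resulting z-score gets a
one-sided upper-tail p-value (Student-t, since the null SD is estimated from
finitely many background peaks), and a link is accepted when p < 0.05 and
z > 0.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import rankdata
from scipy.stats import t as t_dist
from sklearn.neighbors import NearestNeighbors


def peak_features(peak_meta: pd.DataFrame, atac_counts=None) -> pd.DataFrame:
    """Per-peak matching features: gc_fraction, mean accessibility, width."""
    feat = pd.DataFrame(index=peak_meta.index)
    feat["gc_fraction"] = peak_meta["gc_fraction"].astype(float)
    if atac_counts is not None:
        feat["mean_accessibility"] = np.log1p(
            np.asarray(atac_counts.mean(axis=1)).ravel())
    else:
        feat["mean_accessibility"] = 0.0
    feat["width"] = (peak_meta["end"] - peak_meta["start"]).astype(float)
    return feat


def _zscore_features(features: pd.DataFrame) -> np.ndarray:
    F = features.to_numpy(dtype=float)
    sd = F.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    return (F - F.mean(axis=0)) / sd


def match_background_peaks(query_peak: str, features: pd.DataFrame,
                           n_background: int = 200, seed: int = 0) -> list[str]:
    """The ``n_background`` peaks nearest to the query in z-scored feature
    space (Euclidean), excluding the query; ties broken by peak id."""
    Z = _zscore_features(features)
    q = features.index.get_loc(query_peak)
    d = np.sqrt(((Z - Z[q]) ** 2).sum(axis=1))
    order = pd.DataFrame({"dist": d, "peak_id": features.index}) \
        .drop(index=q).sort_values(["dist", "peak_id"], kind="mergesort")
    if len(order) < n_background:
        warnings.warn(f"only {len(order)} background peaks available")
        return order["peak_id"].tolist()
    return order["peak_id"].head(n_background).tolist()


def background_pools(features: pd.DataFrame, n_background: int = 200) -> np.ndarray:
    """Matched-background pool for every peak at once: an integer array of
    shape (n_peaks, n_background) of row positions, nearest first."""
    Z = _zscore_features(features)
    n = len(features)
    k = min(n_background + 1, n)
    nn = NearestNeighbors(n_neighbors=k).fit(Z)
    _, idx = nn.kneighbors(Z)
    pools = np.empty((n, k - 1), dtype=np.int64)
    for i in range(n):
        row = idx[i][idx[i] != i][: k - 1]
        if len(row) < k - 1:                       # self not returned: drop the farthest
            row = np.concatenate([row, idx[i][-1:]])[: k - 1]
        pools[i] = row
    return pools


def candidate_pairs(peak_meta: pd.DataFrame, gene_meta: pd.DataFrame,
                    window_bp: int = 500_000) -> pd.DataFrame:
    """All (peak, gene) pairs with |peak midpoint - TSS| <= window on the
    same chromosome; distance signed by gene strand."""
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    genes = gene_meta
    no_tss = genes["tss"].isna()
    if no_tss.any():
        warnings.warn(f"skipping {int(no_tss.sum())} genes without a TSS")
        genes = genes[~no_tss]
    rows = []
    for chrom, gm in genes.groupby("chrom"):
        pm = peak_meta[peak_meta["chrom"] == chrom]
        if pm.empty:
            continue
        mid = ((pm["start"] + pm["end"]) // 2).to_numpy()
        tss = gm["tss"].to_numpy()
        strand = np.where(gm["strand"].to_numpy() == "-", -1, 1)
        delta = mid[:, None] - tss[None, :]
        hit = np.abs(delta) <= window_bp
        pi, gi = np.nonzero(hit)
        rows.append(pd.DataFrame({
            "peak_id": pm.index.to_numpy()[pi],
            "gene_id": gm.index.to_numpy()[gi],
            "distance": delta[pi, gi] * strand[gi],
        }))
    if not rows:
        return pd.DataFrame(columns=["peak_id", "gene_id", "distance"])
    return pd.concat(rows, ignore_index=True)


def _standardize_rows(X) -> tuple[np.ndarray, np.ndarray]:
    D = X.toarray() if sp.issparse(X) else np.asarray(X, dtype=float)
    mu = D.mean(axis=1, keepdims=True)
    sd = D.std(axis=1, ddof=0)
    ok = sd > 0
    Z = (D - mu) / np.where(sd > 0, sd, 1.0)[:, None]
    Z[~ok] = 0.0
    return Z, ok


def link_peaks(atac_norm, rna_norm, pairs: pd.DataFrame,
               peak_ids: pd.Index, gene_ids: pd.Index,
               features: pd.DataFrame, n_background: int = 200,
               alpha: float = 0.05, method: str = "pearson",
               seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Correlation linkage with a matched-background null.

    Returns (links, dropped): ``links`` has one row per testable pair with
    r, z, p_value and the accepted flag (p < alpha and z > 0); ``dropped``
    lists pairs excluded for zero variance or a degenerate null.
    """
    peak_ids = pd.Index(peak_ids)
    gene_ids = pd.Index(gene_ids)
    A = atac_norm.toarray() if sp.issparse(atac_norm) else np.asarray(atac_norm, float)
    R = rna_norm.toarray() if sp.issparse(rna_norm) else np.asarray(rna_norm, float)
    if A.shape[1] != R.shape[1]:
        raise ValueError("modalities must share one cell order")
    if method == "spearman":
        A = rankdata(A, axis=1)
        R = rankdata(R, axis=1)
    elif method != "pearson":
        raise ValueError("method must be 'pearson' or 'spearman'")
    n_cells = A.shape[1]
    Za, ok_a = _standardize_rows(A)
    Zr, ok_r = _standardize_rows(R)

    genes_needed = pd.Index(pairs["gene_id"].unique())
    gpos_map = {g: i for i, g in enumerate(genes_needed)}
    g_rows = gene_ids.get_indexer(genes_needed)
    if (g_rows < 0).any():
        raise KeyError("pairs reference genes absent from the matrix")
    corr = Za @ Zr[g_rows].T / n_cells              # peak x needed-gene

    pools = background_pools(features.loc[peak_ids], n_background)
    p_pos = peak_ids.get_indexer(pairs["peak_id"])
    g_pos = np.array([gpos_map[g] for g in pairs["gene_id"]])
    if (p_pos < 0).any():
        raise KeyError("pairs reference peaks absent from the matrix")

    dropped_mask = ~(ok_a[p_pos] & ok_r[g_rows][g_pos])
    reasons = np.where(dropped_mask, "zero variance", "")

    r_obs = corr[p_pos, g_pos]
    null = corr[pools[p_pos], g_pos[:, None]]
    null_mean = null.mean(axis=1)
    null_sd = null.std(axis=1, ddof=1)
    degen = (null_sd == 0) & ~dropped_mask
    reasons = np.where(degen, "degenerate null", reasons)
    dropped_mask |= degen

    with np.errstate(divide="ignore", invalid="ignore"):
        z = (r_obs - null_mean) / np.where(null_sd > 0, null_sd, np.nan)
    # upper-tail p with Student-t reference: the null SD is estimated from
    # n_background draws, so the normal tail would be slightly anti-conservative
    p = t_dist.sf(z, df=max(null.shape[1] - 1, 1))
    links = pd.DataFrame({
        "peak_id": pairs["peak_id"].to_numpy(),
        "gene_id": pairs["gene_id"].to_numpy(),
        "r": r_obs,
        "z": z,
        "p_value": p,
        "accepted": (p < alpha) & (z > 0),
    })
    dropped = links.loc[dropped_mask, ["peak_id", "gene_id"]].copy()
    dropped["reason"] = reasons[dropped_mask]
    links = links.loc[~dropped_mask].reset_index(drop=True)
    return links, dropped


# -- genomic feature annotation --------------------------------------------

CATEGORIES = ["promoter", "5'UTR", "3'UTR", "exon", "intron",
              "downstream", "distal_intergenic"]


def _gene_intervals(gene_meta: pd.DataFrame, tss_region=(-3000, 3000),
                    utr5: int = 150, utr3: int = 200, downstream: int = 3000):
    """Category -> {chrom: [(start, end)]} interval map from the toy gene model."""
    out = {c: {} for c in CATEGORIES[:-1]}

    def add(cat, chrom, s, e):
        if e > s:
            out[cat].setdefault(chrom, []).append((int(s), int(e)))

    for g, row in gene_meta.iterrows():
        chrom, strand = row["chrom"], row.get("strand", "+")
        tss = row["tss"]
        add("promoter", chrom, tss + tss_region[0], tss + tss_region[1])
        s, e = row.get("start", tss), row.get("end", tss)
        if strand == "+":
            add("5'UTR", chrom, s, s + utr5)
            add("3'UTR", chrom, e - utr3, e)
            add("downstream", chrom, e, e + downstream)
        else:
            add("5'UTR", chrom, e - utr5, e)
            add("3'UTR", chrom, s, s + utr3)
            add("downstream", chrom, s - downstream, s)
        ex_s = str(row.get("exon_starts", "")).split(",")
        ex_e = str(row.get("exon_ends", "")).split(",")
        exons = [(int(a), int(b)) for a, b in zip(ex_s, ex_e) if a and b]
        for a, b in exons:
            add("exon", chrom, a, b)
        for (a1, b1), (a2, b2) in zip(exons, exons[1:]):
            add("intron", chrom, b1, a2)
    return out


def annotate_peaks(peak_meta: pd.DataFrame, gene_meta: pd.DataFrame,
                   tss_region=(-3000, 3000)) -> tuple[pd.DataFrame, pd.Series]:
    """Assign each peak one genomic category with fixed priority
    promoter > 5'UTR > 3'UTR > exon > intron > downstream > distal_intergenic.

    Returns (per-peak table, category percentages summing to 100).
    """
    if len(gene_meta) == 0:
        cats = pd.Series("distal_intergenic", index=peak_meta.index)
    else:
        ivals = _gene_intervals(gene_meta, tss_region=tss_region)
        cats = pd.Series("distal_intergenic", index=peak_meta.index, dtype=object)
        assigned = np.zeros(len(peak_meta), dtype=bool)
        starts = peak_meta["start"].to_numpy()
        ends = peak_meta["end"].to_numpy()
        chroms = peak_meta["chrom"].to_numpy()
        for cat in CATEGORIES[:-1]:
            for chrom, spans in ivals[cat].items():
                sel = (chroms == chrom) & ~assigned
                if not sel.any():
                    continue
                s = starts[sel][:, None]
                e = ends[sel][:, None]
                a = np.array([x for x, _ in spans])[None, :]
                b = np.array([y for _, y in spans])[None, :]
                hit = ((s < b) & (e > a)).any(axis=1)
                idx = np.flatnonzero(sel)[hit]
                cats.iloc[idx] = cat
                assigned[idx] = True
    table = pd.DataFrame({"category": cats})
    pct = (table["category"].value_counts(normalize=True) * 100.0) \
        .reindex(CATEGORIES, fill_value=0.0)
    return table, pct
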