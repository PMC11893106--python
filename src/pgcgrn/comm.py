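"""Permutation-based ligand-receptor screen between cell clusters.

Follows the CellphoneDB statistical-method conventions: a complex's
expression in a cluster is the minimum over its subunits of the cluster
mean (a complex is only as present as its weakest subunit); a pair is tested
only when every ligand subunit is expressed in at least ``min_frac`` of the
sender cluster and every receptor subunit in at least ``min_frac`` of the
receiver cluster; the interaction score is the arithmetic mean of the ligand
and receptor cluster means; and the p-value is the add-one permutation tail
probability of that score under random cluster labels.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp


@dataclass
class LRPair:
    pair_id: str
    ligand: tuple                 # ligand subunit gene ids
    receptor: tuple               # receptor subunit gene ids
    pathway_label: str = ""

    def __post_init__(self):
        self.ligand = tuple(self.ligand)
        self.receptor = tuple(self.receptor)
        if not self.ligand or not self.receptor:
            raise ValueError("subunit lists must be non-empty")


def pairs_from_table(table: pd.DataFrame) -> list[LRPair]:
    """Build LRPair objects from a pair-list frame (;-separated subunits)."""
    return [LRPair(pair_id=row["pair_id"],
                   ligand=tuple(row["ligand"].split(";")),
                   receptor=tuple(row["receptor"].split(";")),
                   pathway_label=row.get("pathway_label", ""))
            for _, row in table.iterrows()]


def _cluster_mask(clusters: pd.Series, name) -> np.ndarray:
    return (clusters == name).to_numpy()


def lr_mean(norm_expr, gene_ids: pd.Index, clusters: pd.Series, pair: LRPair,
            sender, receiver, min_frac: float = 0.10):
    """Observed interaction score for one pair, or (None, reason) if excluded."""
    gene_ids = pd.Index(gene_ids)
    X = norm_expr.tocsr() if sp.issparse(norm_expr) else sp.csr_matrix(norm_expr)
    s_mask = _cluster_mask(clusters, sender)
    r_mask = _cluster_mask(clusters, receiver)
    for g in pair.ligand + pair.receptor:
        if g not in gene_ids:
            return None, "missing gene"

    def complex_value(subunits, mask):
        means, fracs = [], []
        for g in subunits:
            row = np.asarray(X[gene_ids.get_loc(g)].todense()).ravel()[mask]
            means.append(row.mean())
            fracs.append((row > 0).mean())
        return min(means), min(fracs)

    lig_val, lig_frac = complex_value(pair.ligand, s_mask)
    rec_val, rec_frac = complex_value(pair.receptor, r_mask)
    if lig_frac < min_frac:
        return None, "ligand below expression fraction"
    if rec_frac < min_frac:
        return None, "receptor below expression fraction"
    return (lig_val + rec_val) / 2.0, ""


def permutation_test(norm_expr, gene_ids: pd.Index, clusters: pd.Series,
                     pairs: list[LRPair], sender, receiver,
                     n_perm: int = 1000, seed: int = 0,
                     min_frac: float = 0.10, alpha: float = 0.05
                     ) -> pd.DataFrame:
    """Label-shuffling permutation test of ligand-receptor interaction scores.

    The null is built by permuting cluster labels over cells ``n_perm``
    times; p = (1 + #{null >= observed}) / (1 + n_perm). Pairs excluded by
    the expression-fraction gate (or missing genes) are reported with the
    exclusion reason and no p-value. Clusters with fewer than 3 cells
    exclude all their pairs.
    """
    gene_ids = pd.Index(gene_ids)
    X = norm_expr.tocsr() if sp.issparse(norm_expr) else sp.csr_matrix(norm_expr)
    clusters = pd.Series(clusters)
    rng = np.random.default_rng(seed)
    n_cells = len(clusters)
    s_mask = _cluster_mask(clusters, sender)
    r_mask = _cluster_mask(clusters, receiver)
    small = s_mask.sum() < 3 or r_mask.sum() < 3

    genes_needed = sorted({g for p in pairs for g in p.ligand + p.receptor
                           if g in gene_ids})
    gpos = {g: i for i, g in enumerate(genes_needed)}
    D = np.asarray(X[gene_ids.get_indexer(genes_needed)].todense()) \
        if genes_needed else np.zeros((0, n_cells))

    rows = []
    observed = {}
    for pair in pairs:
        if small:
            rows.append((pair.pair_id, sender, receiver, np.nan, np.nan, False,
                         "cluster too small", pair.pathway_label))
            continue
        val, reason = lr_mean(norm_expr, gene_ids, clusters, pair,
                              sender, receiver, min_frac)
        if val is None:
            rows.append((pair.pair_id, sender, receiver, np.nan, np.nan, False,
                         reason, pair.pathway_label))
        else:
            observed[pair.pair_id] = val
            rows.append((pair.pair_id, sender, receiver, val, np.nan, False,
                         "", pair.pathway_label))
    out = pd.DataFrame(rows, columns=["pair_id", "sender", "receiver",
                                      "mean_expr", "p_value", "significant",
                                      "reason", "pathway_label"])
    if not observed:
        return out

    tested = [p for p in pairs if p.pair_id in observed]
    exceed = {p.pair_id: 0 for p in tested}
    idx = np.arange(n_cells)
    for _ in range(n_perm):
        perm = rng.permutation(idx)
        ps = perm[s_mask]          # cells holding the sender label after shuffle
        pr = perm[r_mask]
        s_means = D[:, ps].mean(axis=1)
        r_means = D[:, pr].mean(axis=1)
        for p in tested:
            lig = min(s_means[gpos[g]] for g in p.ligand)
            rec = min(r_means[gpos[g]] for g in p.receptor)
            if (lig + rec) / 2.0 >= observed[p.pair_id] - 1e-12:
                exceed[p.pair_id] += 1
    for p in tested:
        pv = (1 + exceed[p.pair_id]) / (1 + n_perm)
        out.loc[out["pair_id"] == p.pair_id, "p_value"] = pv
        out.loc[out["pair_id"] == p.pair_id, "significant"] = pv < alpha
    return out


def count_and_overlap(results: dict, pathway_labels: pd.Series | None = None
                      ) -> dict:
    """Summarize per-group screens: significant counts, per-pathway counts,
    and per-stage (XX-only, shared, XY-only) partitions of significant pairs.

    ``results`` maps (sex, stage) -> permutation_test result frame.
    """
    counts = {}
    pathway_counts = {}
    sig_sets = {}
    for key, df in results.items():
        sig = df[df["significant"].fillna(False).astype(bool)]
        counts[key] = int(len(sig))
        sig_sets[key] = set(sig["pair_id"])
        lab = sig["pathway_label"] if "pathway_label" in sig.columns else \
            sig["pair_id"].map(pathway_labels or {})
        pathway_counts[key] = lab.value_counts().to_dict()
    overlaps = {}
    stages = sorted({stage for (_, stage) in results})
    for stage in stages:
        xx = sig_sets.get(("XX", stage), set())
        xy = sig_sets.get(("XY", stage), set())
        overlaps[stage] = {
            "XX_only": sorted(xx - xy),
            "shared": sorted(xx & xy),
            "XY_only": sorted(xy - xx),
        }
    return {"counts": counts, "pathway_counts": pathway_counts,
            "overlaps": overlaps}
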