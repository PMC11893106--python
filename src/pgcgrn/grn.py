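"""Candidate-TF selection, target-gene prediction and cross-regulation.

The analytical flow mirrors how differential accessibility, peak-to-gene
links and motif statistics are combined to nominate regulators of germ-cell
sex determination: a TF is a candidate for a group (one sex at one stage)
when its gene is differentially expressed toward that sex, shows germline-
enriched expression, its motif is enriched in the peaks linked to the
group's DEGs, and its per-cell motif activity (mean deviation z over the
group) is positive. Predicted targets of a candidate are the linked DEGs
whose accepted link peaks carry the motif; coverage is the fraction of
linked DEGs reached. Every reported TF -> gene edge keeps its
(motif, peak, link) witness.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .differential import bh_adjust, find_markers
from .motifs import DeviationMatrix, HitMatrix


@dataclass
class CandidateTF:
    tf_name: str
    gene_id: str
    motif_id: str
    is_de: bool
    germline_enriched: bool
    motif_enriched: bool
    mean_motif_activity_z: float
    enrichment_p: float
    selected: bool


@dataclass
class GRNResult:
    targets: dict[str, set]                # tf gene -> predicted target genes
    coverage: dict[str, float]             # tf gene -> fraction of linked DEGs
    tf_cross: pd.DataFrame                 # TF x TF binary adjacency
    provenance: pd.DataFrame               # tf, target, motif, peak witnesses


def germline_enrichment(norm_expr, germ_cells, soma_cells, feature_ids,
                        alpha: float = 0.05, logfc_threshold: float = 0.25,
                        min_pct: float = 0.25) -> set:
    """Genes with significantly higher expression in germ cells than soma."""
    table = find_markers(norm_expr, germ_cells, soma_cells, feature_ids,
                         min_pct=min_pct, logfc_threshold=logfc_threshold,
                         alpha=alpha, group_labels=("germ", "soma"))
    hit = table[(table["p_adj"] < alpha) & (table["log2fc"] > logfc_threshold)]
    return set(hit.index)


def select_candidate_tfs(de_table: pd.DataFrame, enrichment_table: pd.DataFrame,
                         deviations: DeviationMatrix, germline_set: set,
                         group_cells, tf_map: pd.DataFrame,
                         group_label: str, alpha: float = 0.05
                         ) -> list[CandidateTF]:
    """Apply the candidate conjunction for one group (sex x stage).

    ``de_table`` is a find_markers result for the group's comparison (the
    group itself listed in ``group_up``); ``tf_map`` maps motif_id -> tf_name,
    gene_id. Motifs without a mapped gene are excluded. The returned list is
    ordered by motif-enrichment p-value; ``selected`` marks TFs passing all
    four requirements.
    """
    activity = deviations.group_activity(group_cells)
    out = []
    for _, row in tf_map.iterrows():
        motif_id, gene = row["motif_id"], row["gene_id"]
        if not isinstance(gene, str) or not gene:
            continue
        is_de = bool(
            gene in de_table.index
            and de_table.loc[gene, "significant"]
            and de_table.loc[gene, "group_up"] == group_label)
        enriched = bool(
            motif_id in enrichment_table.index
            and enrichment_table.loc[motif_id, "p_adj"] < alpha)
        p_enr = float(enrichment_table.loc[motif_id, "p_value"]) \
            if motif_id in enrichment_table.index else 1.0
        mean_z = float(activity.get(motif_id, np.nan))
        out.append(CandidateTF(
            tf_name=row["tf_name"], gene_id=gene, motif_id=motif_id,
            is_de=is_de,
            germline_enriched=gene in germline_set,
            motif_enriched=enriched,
            mean_motif_activity_z=mean_z,
            enrichment_p=p_enr,
            selected=bool(is_de and gene in germline_set and enriched
                          and mean_z > 0),
        ))
    return sorted(out, key=lambda c: (c.enrichment_p, c.motif_id))


def predict_targets(motif_id: str, hits: HitMatrix, links: pd.DataFrame,
                    deg_set: set) -> tuple[set, float, pd.DataFrame]:
    """Linked DEGs reachable through a motif-bearing accepted-link peak.

    ``links`` must already be restricted to accepted links; ``deg_set`` is
    the set of DEGs that have at least one accepted link. Returns
    (targets, coverage, witnesses) where every witness row is one
    (motif, peak, gene) triple supporting an edge.
    """
    if not deg_set:
        raise ValueError("deg_set is empty; coverage is undefined")
    motif_peaks = set(hits.motif_peaks(motif_id))
    sub = links[links["peak_id"].isin(motif_peaks) & links["gene_id"].isin(deg_set)]
    targets = set(sub["gene_id"])
    witnesses = sub[["peak_id", "gene_id"]].copy()
    witnesses.insert(0, "motif_id", motif_id)
    return targets, len(targets) / len(deg_set), witnesses


def tf_cross_regulation(tfs: list[CandidateTF], hits: HitMatrix,
                        links: pd.DataFrame, peak_meta: pd.DataFrame,
                        gene_meta: pd.DataFrame, promoter_window: int = 3000
                        ) -> pd.DataFrame:
    """TF x TF adjacency: edge A->B when A's motif hits a peak accepted-linked
    to B's gene or lying in B's promoter window (TSS +/- promoter_window).

    Self-edges are computed but reported on the diagonal so callers can
    treat them separately.
    """
    names = [t.tf_name for t in tfs]
    adj = pd.DataFrame(False, index=names, columns=names)
    links_acc = links[links["accepted"]] if "accepted" in links.columns else links
    mid = ((peak_meta["start"] + peak_meta["end"]) // 2)
    for a in tfs:
        a_peaks = set(hits.motif_peaks(a.motif_id))
        if not a_peaks:
            continue
        linked = links_acc[links_acc["peak_id"].isin(a_peaks)]
        for b in tfs:
            if b.gene_id not in gene_meta.index:
                raise KeyError(f"TF gene {b.gene_id} absent from gene_meta")
            hit_link = (linked["gene_id"] == b.gene_id).any()
            row = gene_meta.loc[b.gene_id]
            prom = peak_meta.index[
                (peak_meta["chrom"] == row["chrom"])
                & (np.abs(mid - row["tss"]) <= promoter_window)]
            hit_prom = bool(a_peaks & set(prom))
            adj.loc[a.tf_name, b.tf_name] = bool(hit_link or hit_prom)
    return adj


def overrepresentation(genes, universe, gene_sets: dict[str, set]) -> pd.DataFrame:
    """Hypergeometric over-representation of ``genes`` within ``universe``
    for each gene set; BH-adjusted over sets."""
    if not gene_sets:
        raise ValueError("gene_sets is empty")
    genes = set(genes)
    universe = set(universe)
    if not genes <= universe:
        raise ValueError("query genes must be a subset of the universe")
    M, n = len(universe), len(genes)
    rows = []
    for name, s in gene_sets.items():
        K = len(s & universe)
        if K == 0:
            continue
        k = len(s & genes)
        p = float(hypergeom.sf(k - 1, M, K, n))
        rows.append((name, k, K, p))
    out = pd.DataFrame(rows, columns=["gene_set", "k", "K", "p_value"]) \
        .set_index("gene_set")
    if len(out):
        out["p_adj"] = bh_adjust(out["p_value"].to_numpy())
        out["significant"] = out["p_adj"] < 0.05
    return out.sort_values("p_value", kind="mergesort")
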