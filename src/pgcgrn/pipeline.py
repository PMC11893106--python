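"""End-to-end flows: preprocessing, recovery evaluation and null calibration.

These functions chain the package's modules the way the analysis is meant to
be run on a paired multiome: QC filtering -> chrY sex confirmation ->
marker-based population selection -> differential expression/accessibility
between sexes -> peak-to-gene linkage within each sex -> motif enrichment on
linked peaks -> per-cell motif activity -> candidate-TF selection and target
prediction -> ligand-receptor screen -> joint-embedding clustering. On
synthetic data with planted truth they additionally measure recovery.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score, roc_auc_score

from . import comm, differential, embed, grn, links, motifs, qc
from .simulate import (GeneratorConfig, default_motif_file, generate_dataset,
                       load_tf_motif_map, read_lr_pairs_fixture)
from .types import GroundTruth, MultiomeDataset


def preprocess(dataset: MultiomeDataset) -> dict:
    """QC filtering, mito-gene removal, sex confirmation, population selection.

    Returns a dict with the filtered dataset (sex-confirmed survivors only),
    normalized matrices, QC table, sex calls and the PGC/supporting cell sets.
    """
    qc_table = qc.compute_qc(dataset)
    kept, tally = qc.filter_cells(qc_table)
    ds = dataset.subset_cells(kept)
    ds = ds.subset_genes(ds.gene_ids[~ds.gene_meta["is_mito"].to_numpy(bool)])

    norm_rna = embed.lognormalize(ds.rna_counts)
    chry_genes = ds.gene_ids[ds.gene_meta["is_chrY"].to_numpy(bool)]
    scores = pd.Series(qc.module_score_rank(norm_rna, ds.gene_ids, chry_genes),
                       index=ds.cell_ids)
    frags = qc.chry_fragment_counts(ds.fragments, ds.cell_ids)
    sex_res = qc.assign_sex(scores, frags, ds.cell_meta)
    surviving = sex_res.calls.index[sex_res.calls["call"] != "removed"]
    ds = ds.subset_cells(surviving)
    calls = sex_res.calls.loc[surviving, "call"]

    pops = qc.select_population(ds.rna_counts, ds.gene_ids, ds.cell_ids,
                                [qc.pgc_rule(), qc.supporting_rule()])
    return {
        "dataset": ds,
        "qc": qc_table,
        "qc_tally": tally,
        "sex_calls": sex_res,
        "called_sex": calls,
        "norm_rna": embed.lognormalize(ds.rna_counts),
        "norm_atac": embed.lognormalize(ds.atac_counts),
        "pgc": pops["PGC"],
        "supporting": pops["supporting"],
    }


def _positions(index: pd.Index, items) -> np.ndarray:
    return index.get_indexer(pd.Index(items))


def recovery_metrics(seed: int, config: GeneratorConfig | None = None,
                     n_perm_lr: int = 1000) -> dict:
    """Generate a planted dataset, run the full analysis and measure recovery."""
    cfg = config or GeneratorConfig(seed=seed)
    if config is not None and config.seed != seed:
        cfg = GeneratorConfig(**{**config.__dict__, "seed": seed})
    dataset, truth = generate_dataset(cfg)
    pp = preprocess(dataset)
    ds: MultiomeDataset = pp["dataset"]
    calls = pp["called_sex"]
    meta = ds.cell_meta
    final = cfg.stages[-1]

    truth_sex = truth.sex_of_cell.loc[ds.cell_ids]
    sex_acc = float((calls == truth_sex).mean()) * 100.0

    pgc = pp["pgc"]
    stage3 = ds.cell_ids[(meta["stage"] == final).to_numpy()]
    pgc3 = pgc.intersection(stage3)
    cells_by_sex = {s: pgc3.intersection(calls.index[calls == s]) for s in ("XX", "XY")}

    # differential expression and accessibility between sexes at the final stage
    idx_xx = _positions(ds.cell_ids, cells_by_sex["XX"])
    idx_xy = _positions(ds.cell_ids, cells_by_sex["XY"])
    de = differential.find_markers(pp["norm_rna"], idx_xx, idx_xy, ds.gene_ids,
                                   group_labels=("XX", "XY"))
    da = differential.find_markers(pp["norm_atac"], idx_xx, idx_xy, ds.peak_ids,
                                   min_pct=0.001, logfc_threshold=0.1,
                                   group_labels=("XX", "XY"))
    de_sig = de[de["significant"]]
    da_sig = da[da["significant"]]
    truth_de3 = set(truth.true_de.loc[truth.true_de["stage"] == final, "gene"])
    called = set(de_sig.index)
    de_sens = len(called & truth_de3) / len(truth_de3) if truth_de3 else np.nan
    de_fdr = len(called - truth_de3) / len(called) if called else 0.0

    # peak-to-gene links within each sex (DA peaks x DEGs of that sex);
    # matching features are computed on the analyzed cells so that the
    # background shares their depth structure
    accepted = {}
    n_acc_false = n_acc_total = 0
    true_pairs = set(zip(truth.true_links["peak"], truth.true_links["gene"]))
    n_recovered = 0
    for sx in ("XX", "XY"):
        peaks_sx = da_sig.index[da_sig["group_up"] == sx]
        genes_sx = de_sig.index[de_sig["group_up"] == sx]
        if not len(peaks_sx) or not len(genes_sx):
            accepted[sx] = pd.DataFrame(columns=["peak_id", "gene_id", "accepted"])
            continue
        pairs = links.candidate_pairs(ds.peak_meta.loc[peaks_sx],
                                      ds.gene_meta.loc[genes_sx],
                                      cfg.link_window)
        idx = _positions(ds.cell_ids, cells_by_sex[sx])
        feats_sx = links.peak_features(ds.peak_meta, ds.atac_counts[:, idx])
        tab, _ = links.link_peaks(pp["norm_atac"][:, idx], pp["norm_rna"][:, idx],
                                  pairs, ds.peak_ids, ds.gene_ids, feats_sx)
        acc = tab[tab["accepted"]]
        accepted[sx] = acc
        for p, g in zip(acc["peak_id"], acc["gene_id"]):
            n_acc_total += 1
            if (p, g) in true_pairs:
                n_recovered += 1
            else:
                n_acc_false += 1
    link_sens = n_recovered / len(true_pairs) if true_pairs else np.nan
    link_false_frac = n_acc_false / n_acc_total if n_acc_total else 0.0

    # motif enrichment in XX-linked peaks against GC-matched background
    motif_models = motifs.read_jaspar(default_motif_file())[: cfg.n_motifs]
    hits = motifs.scan_peaks(ds.peak_seqs, motif_models)
    tf_map = load_tf_motif_map().iloc[: cfg.n_motifs]
    causal_motif = tf_map.iloc[0]["motif_id"]
    query = pd.Index(accepted["XX"]["peak_id"].unique())
    cells3 = pgc3
    idx3 = _positions(ds.cell_ids, cells3)
    feats3 = links.peak_features(ds.peak_meta, ds.atac_counts[:, idx3])
    motif_rank = np.nan
    enrich = None
    if len(query):
        pools = links.background_pools(feats3, 200)
        qpos = _positions(ds.peak_ids, query)
        bg = pd.Index(ds.peak_ids[np.unique(pools[qpos])]).difference(query)
        enrich = motifs.motif_enrichment(query, bg, hits)
        motif_rank = int(enrich.index.get_loc(causal_motif)) + 1

    # per-cell motif activity on final-stage germ cells
    dev = motifs.chromvar_deviations(ds.atac_counts[:, idx3], hits, feats3,
                                     cells3, seed=cfg.seed)
    sex3 = calls.loc[cells3]
    z_row = dev.z.loc[causal_motif]
    act_xx = float(z_row[cells_by_sex["XX"]].mean())
    act_xy = float(z_row[cells_by_sex["XY"]].mean())
    auc = float(roc_auc_score((sex3 == "XX").to_numpy(int), z_row.to_numpy())) \
        if sex3.nunique() == 2 else np.nan

    # candidate-TF selection and target prediction for the XX group
    soma3 = stage3.difference(pgc)
    germset = grn.germline_enrichment(pp["norm_rna"],
                                      _positions(ds.cell_ids, pgc3),
                                      _positions(ds.cell_ids, soma3),
                                      ds.gene_ids)
    selected = []
    coverage = np.nan
    cross_ok = np.nan
    if enrich is not None:
        cands = grn.select_candidate_tfs(de, enrich, dev, germset,
                                         cells_by_sex["XX"], tf_map, "XX")
        selected = [c.tf_name for c in cands if c.selected]
        deg_linked = set(de_sig.index[de_sig["group_up"] == "XX"]) & \
            set(accepted["XX"]["gene_id"])
        if deg_linked:
            _, coverage, _ = grn.predict_targets(causal_motif, hits,
                                                 accepted["XX"], deg_linked)
        adj = grn.tf_cross_regulation(cands, hits, accepted["XX"],
                                      ds.peak_meta, ds.gene_meta)
        a_name = tf_map.iloc[0]["tf_name"]
        b_name = tf_map.iloc[1]["tf_name"]
        cross_ok = float(bool(adj.loc[a_name, b_name]) and
                         not bool(adj.loc[b_name, a_name]))

    # ligand-receptor screen per sex at the final stage
    lr_pairs = comm.pairs_from_table(read_lr_pairs_fixture())
    lr_results = {}
    for sx in ("XX", "XY"):
        cells_sx = ds.cell_ids[((meta["stage"] == final).to_numpy()) &
                               (calls == sx).to_numpy()]
        labels = pd.Series("other", index=cells_sx)
        labels[labels.index.isin(pp["supporting"])] = "supporting"
        labels[labels.index.isin(pgc)] = "PGC"
        idx = _positions(ds.cell_ids, cells_sx)
        lr_results[(sx, final)] = comm.permutation_test(
            pp["norm_rna"][:, idx], ds.gene_ids, labels, lr_pairs,
            sender="supporting", receiver="PGC",
            n_perm=n_perm_lr, seed=cfg.seed)
    lr_ok = 1.0
    for _, row in truth.true_lr.iterrows():
        for sx in ("XX", "XY"):
            res = lr_results[(sx, final)]
            sig = res.loc[res["pair_id"] == row["pair_id"], "significant"]
            sig = bool(sig.iloc[0]) if len(sig) else False
            if (sx == row["sex"]) != sig:
                lr_ok = 0.0

    # joint-embedding clustering of final-stage germ cells vs the true sex
    idx3 = _positions(ds.cell_ids, cells3)
    rna_emb = embed.pca_embed(pp["norm_rna"][:, idx3], cells3,
                              n_dims=min(18, len(cells3) - 1))
    n_lsi = min(30, len(cells3) - 1)
    atac_emb = embed.tfidf_lsi(ds.atac_counts[:, idx3], cells3, n_dims=n_lsi)
    joint = embed.joint_embedding(rna_emb, atac_emb)
    clust = embed.cluster_graph(joint, k_neighbors=min(20, len(cells3) - 1),
                                resolution=0.3, seed=cfg.seed)
    ari = float(adjusted_rand_score(truth_sex.loc[cells3], clust.labels))

    return {
        "sex_accuracy_pct": sex_acc,
        "n_cells_after_filtering": int(ds.n_cells),
        "de_sensitivity": float(de_sens),
        "de_fdr": float(de_fdr),
        "n_de_called": int(len(called)),
        "link_sensitivity": float(link_sens),
        "link_false_fraction": float(link_false_frac),
        "n_links_accepted": int(n_acc_total),
        "planted_motif_rank": float(motif_rank),
        "motif_activity_xx_minus_xy": act_xx - act_xy,
        "motif_activity_auc": auc,
        "selected_tfs": selected,
        "tf_selection_exact": float(selected == [tf_map.iloc[0]["tf_name"]]),
        "tf_target_coverage": float(coverage),
        "tf_cross_edge_ok": float(cross_ok),
        "lr_sex_specific": lr_ok,
        "cluster_ari_sex": ari,
    }


def null_metrics(seed: int, config: GeneratorConfig | None = None,
                 n_splits: int = 20, n_perm_lr: int = 200,
                 n_lr_decoys: int = 60) -> dict:
    """Generate a no-effect dataset and measure error control of every screen."""
    cfg = config or GeneratorConfig.null(seed=seed)
    dataset, _ = generate_dataset(cfg)
    pp = preprocess(dataset)
    ds = pp["dataset"]
    rng = np.random.default_rng(seed)
    calls = pp["called_sex"]

    # type-I error of the marker test over random splits of XX germ cells
    pgc_xx = pp["pgc"].intersection(calls.index[calls == "XX"])
    pos = _positions(ds.cell_ids, pgc_xx)
    n_called = n_tested = 0
    for _ in range(n_splits):
        perm = rng.permutation(pos)
        half = len(perm) // 2
        tab = differential.find_markers(pp["norm_rna"], perm[:half], perm[half:],
                                        ds.gene_ids)
        n_called += int(tab["significant"].sum())
        n_tested += len(ds.gene_ids)     # every input gene is a tested hypothesis
    de_type1 = n_called / n_tested

    # raw Wilcoxon calibration on one split, no gates
    perm = rng.permutation(pos)
    half = len(perm) // 2
    pvals = differential.wilcoxon_test(pp["norm_rna"], perm[:half], perm[half:])
    informative = np.ptp(pp["norm_rna"][:, pos].toarray(), axis=1) > 0
    wilcoxon_frac05 = float((pvals[informative] < 0.05).mean())

    # accepted-link fraction among all candidate pairs (XX germ cells)
    feats = links.peak_features(ds.peak_meta, ds.atac_counts[:, pos])
    pairs = links.candidate_pairs(ds.peak_meta, ds.gene_meta, cfg.link_window)
    tab, dropped = links.link_peaks(pp["norm_atac"][:, pos], pp["norm_rna"][:, pos],
                                    pairs, ds.peak_ids, ds.gene_ids, feats)
    link_frac = float(tab["accepted"].mean()) if len(tab) else 0.0

    # motif deviation z-means over all cells
    motif_models = motifs.read_jaspar(default_motif_file())[: cfg.n_motifs]
    hits = motifs.scan_peaks(ds.peak_seqs, motif_models)
    feats_all = links.peak_features(ds.peak_meta, ds.atac_counts)
    dev = motifs.chromvar_deviations(ds.atac_counts, hits, feats_all, ds.cell_ids,
                                     seed=seed)
    max_abs_z_mean = float(dev.z.mean(axis=1).abs().max())

    # ligand-receptor null: random gene pairs, compartment clusters, XX cells
    fillers = [g for g in ds.gene_ids if g.startswith("gene_")]
    decoys = []
    for i in range(n_lr_decoys):
        lig, rec = rng.choice(fillers, size=2, replace=False)
        decoys.append(comm.LRPair(pair_id=f"null_{i}", ligand=(lig,),
                                  receptor=(rec,), pathway_label="null"))
    cells_xx = ds.cell_ids[(calls == "XX").to_numpy()]
    labels = pd.Series("other", index=cells_xx)
    labels[labels.index.isin(pp["supporting"])] = "supporting"
    labels[labels.index.isin(pp["pgc"])] = "PGC"
    idx = _positions(ds.cell_ids, cells_xx)
    res = comm.permutation_test(pp["norm_rna"][:, idx], ds.gene_ids, labels,
                                decoys, "supporting", "PGC",
                                n_perm=n_perm_lr, seed=seed)
    tested = res[res["p_value"].notna()]
    lr_frac = float(tested["significant"].mean()) if len(tested) else 0.0

    return {
        "de_type1_after_bh": float(de_type1),
        "wilcoxon_frac_p_below_05": wilcoxon_frac05,
        "link_accept_fraction": link_frac,
        "n_candidate_pairs": int(len(tab)),
        "max_abs_motif_z_mean": max_abs_z_mean,
        "z_mean_bound": 3.0 / np.sqrt(ds.n_cells),
        "lr_null_significant_fraction": lr_frac,
        "n_lr_tested": int(len(tested)),
    }
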