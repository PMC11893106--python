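"""Candidate-TF selection logic, target prediction and over-representation."""
from math import comb

import numpy as np
import pandas as pd
import pytest

from pgcgrn import grn, motifs


def _hits(peak_ids, cols):
    df = pd.DataFrame(False, index=pd.Index(peak_ids, name="peak_id"),
                      columns=list(cols))
    return motifs.HitMatrix(hits=df,
                            positions=pd.DataFrame(columns=["motif_id", "peak_id",
                                                            "offset", "strand",
                                                            "score"]),
                            threshold_fraction=0.8, pseudocount=0.8)


def test_germline_enrichment_restricted_gene():
    rng = np.random.default_rng(0)
    n = 40
    germ_only = np.log1p(np.concatenate([rng.poisson(5.0, n), np.zeros(n)]))
    flat = np.log1p(rng.poisson(2.0, 2 * n).astype(float))
    X = np.vstack([germ_only, flat])
    out = grn.germline_enrichment(X, np.arange(n), np.arange(n, 2 * n),
                                  ["germ_gene", "flat"])
    assert out == {"germ_gene"}
    identical = np.vstack([flat, flat])
    assert grn.germline_enrichment(identical, np.arange(n), np.arange(n, 2 * n),
                                   ["a", "b"]) == set()


def _selection_fixture(mean_z_a=2.0):
    de = pd.DataFrame({
        "significant": [True, True, False],
        "group_up": ["XX", "XX", "XX"],
        "log2fc": [1.0, 1.0, 0.0],
    }, index=pd.Index(["Tfa", "Tfb", "Tfc"], name="feature_id"))
    enrich = pd.DataFrame({
        "p_value": [1e-8, 1e-6, 0.5],
        "p_adj": [1e-7, 1e-5, 0.6],
    }, index=pd.Index(["MA", "MB", "MC"], name="motif_id"))
    cells = pd.Index(["c0", "c1"])
    z = pd.DataFrame([[mean_z_a] * 2, [-1.0] * 2, [0.5] * 2],
                     index=["MA", "MB", "MC"], columns=cells)
    dev = motifs.DeviationMatrix(raw=z, deviations=z, z=z,
                                 n_background_sets=1, seed=0)
    tf_map = pd.DataFrame({
        "motif_id": ["MA", "MB", "MC", "MD"],
        "tf_name": ["TFA", "TFB", "TFC", "TFD"],
        "gene_id": ["Tfa", "Tfb", "Tfc", ""],
    })
    return de, enrich, dev, cells, tf_map


def test_candidate_selection_requires_all_four_flags():
    de, enrich, dev, cells, tf_map = _selection_fixture()
    out = grn.select_candidate_tfs(de, enrich, dev, {"Tfa", "Tfb", "Tfc"},
                                   cells, tf_map, "XX")
    by_name = {c.tf_name: c for c in out}
    assert by_name["TFA"].selected                      # all four conditions hold
    # DE + enriched + germline but negative chromatin-binding score: rejected
    assert by_name["TFB"].is_de and by_name["TFB"].motif_enriched
    assert not by_name["TFB"].selected
    assert not by_name["TFC"].selected                  # not DE, not enriched
    assert "TFD" not in by_name                         # unmapped motif excluded
    assert [c.tf_name for c in out[:2]] == ["TFA", "TFB"]   # ordered by p


def test_predict_targets_set_logic():
    hm = _hits([f"p{i}" for i in range(8)], ["MA"])
    hm.hits.loc[["p0", "p2"], "MA"] = True
    links = pd.DataFrame({
        "peak_id": ["p0", "p1", "p2", "p3"],
        "gene_id": ["g0", "g1", "g2", "g3"],
        "accepted": [True] * 4,
    })
    deg = {"g0", "g1", "g2", "g3", "g4"}
    targets, cov, wit = grn.predict_targets("MA", hm, links, deg)
    assert targets == {"g0", "g2"}
    assert cov == pytest.approx(2 / 5)
    # every edge carries a re-validating witness
    for _, w in wit.iterrows():
        assert hm.hits.loc[w["peak_id"], "MA"]
        assert ((links["peak_id"] == w["peak_id"]) &
                (links["gene_id"] == w["gene_id"])).any()
    # motif hitting no linked peak
    hm.hits[:] = False
    t2, c2, _ = grn.predict_targets("MA", hm, links, deg)
    assert t2 == set() and c2 == 0.0
    with pytest.raises(ValueError, match="empty"):
        grn.predict_targets("MA", hm, links, set())


def test_target_sets_grow_when_link_threshold_relaxes():
    hm = _hits(["p0", "p1"], ["MA"])
    hm.hits[:] = True
    links = pd.DataFrame({
        "peak_id": ["p0", "p1"], "gene_id": ["g0", "g1"],
        "p_value": [0.01, 0.04], "accepted": [True, True],
    })
    strict = links[links["p_value"] < 0.02]
    t_strict, _, _ = grn.predict_targets("MA", hm, strict, {"g0", "g1"})
    t_loose, _, _ = grn.predict_targets("MA", hm, links, {"g0", "g1"})
    assert t_strict <= t_loose


def test_cross_regulation_edges_and_self_edges():
    pm = pd.DataFrame({"chrom": ["chr1", "chr1"], "start": [1000, 49_000],
                       "end": [1500, 49_500], "gc_fraction": 0.5},
                      index=pd.Index(["p0", "p1"], name="peak_id"))
    gm = pd.DataFrame({"chrom": ["chr1", "chr1"], "tss": [200_000, 50_000],
                       "strand": ["+", "+"]},
                      index=pd.Index(["Tfa", "Tfb"], name="gene_id"))
    hm = _hits(["p0", "p1"], ["MA", "MB"])
    hm.hits.loc["p0", "MA"] = True      # A's motif in a peak linked to B's gene
    hm.hits.loc["p1", "MB"] = True      # B's motif in B's own promoter region
    links = pd.DataFrame({"peak_id": ["p0"], "gene_id": ["Tfb"],
                          "accepted": [True]})
    tfs = [grn.CandidateTF("TFA", "Tfa", "MA", True, True, True, 1.0, 1e-5, True),
           grn.CandidateTF("TFB", "Tfb", "MB", True, True, False, 1.0, 0.5, False)]
    adj = grn.tf_cross_regulation(tfs, hm, links, pm, gm)
    assert adj.loc["TFA", "TFB"]
    assert not adj.loc["TFB", "TFA"]                   # reverse edge absent
    assert adj.loc["TFB", "TFB"]                       # self-edge on the diagonal
    assert not adj.loc["TFA", "TFA"]
    # a TF with no motif hits anywhere has out-degree zero
    hm.hits["MA"] = False
    adj2 = grn.tf_cross_regulation(tfs, hm, links, pm, gm)
    assert adj2.loc["TFA"].sum() == 0


def test_overrepresentation_exact_tail_and_degenerate_cases():
    universe = {f"g{i}" for i in range(20)}
    query = {"g0", "g1", "g2", "g3", "g4"}
    sets = {"hit": {"g0", "g1", "g2", "g3"}, "none": {"x1", "x2"}}
    out = grn.overrepresentation(query, universe, sets)
    M, K, n = 20, 4, 5
    expected = sum(comb(K, k) * comb(M - K, n - k) for k in range(4, 5)) / comb(M, n)
    assert out.loc["hit", "p_value"] == pytest.approx(expected)
    assert "none" not in out.index                     # zero overlap: skipped
    # query == universe -> every drawn set is fully contained, p = 1
    out2 = grn.overrepresentation(universe, universe, {"s": {"g0", "g1"}})
    assert out2.loc["s", "p_value"] == pytest.approx(1.0)
    with pytest.raises(ValueError):
        grn.overrepresentation({"zz"}, universe, sets)
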