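"""Peak-gene candidate pairs, background matching, linkage and annotation."""
import numpy as np
import pandas as pd
import pytest

from pgcgrn import links


def _peaks(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end"],
                        index=pd.Index([f"p{i}" for i in range(len(rows))],
                                       name="peak_id"))


def test_candidate_pairs_window_and_chromosome():
    pm = _peaks([("chr1", 599_750, 600_250),      # midpoint 600,000
                 ("chr2", 100, 600)])
    gm = pd.DataFrame({"chrom": ["chr1"], "tss": [100_000], "strand": ["+"]},
                      index=pd.Index(["g0"], name="gene_id"))
    pairs = links.candidate_pairs(pm, gm, window_bp=500_000)
    # boundary |600,000 - 100,000| = 500,000 is included; chr2 peak is not
    assert len(pairs) == 1
    assert pairs.iloc[0]["peak_id"] == "p0"
    assert pairs.iloc[0]["distance"] == 500_000
    gm_minus = gm.assign(strand="-")
    assert links.candidate_pairs(pm, gm_minus).iloc[0]["distance"] == -500_000


def test_background_matching_is_nearest_neighbor_with_id_ties():
    feats = pd.DataFrame({
        "gc_fraction": [0.50, 0.52, 0.48, 0.60, 0.70, 0.30, 0.51, 0.49, 0.55, 0.45],
        "mean_accessibility": 0.0,
        "width": 500.0,
    }, index=pd.Index([f"p{i}" for i in range(10)], name="peak_id"))
    got = links.match_background_peaks("p0", feats, n_background=3)
    # brute force in z-scored feature space (only gc varies)
    z = (feats["gc_fraction"] - feats["gc_fraction"].mean()) / feats["gc_fraction"].std(ddof=0)
    d = (z - z["p0"]).abs().drop("p0").sort_values(kind="mergesort")
    assert got == list(d.index[:3])
    # identical features: tie-break by peak id order
    flat = feats.copy()
    flat["gc_fraction"] = 0.5
    assert links.match_background_peaks("p3", flat, n_background=4) == \
        ["p0", "p1", "p2", "p4"]
    assert got[0] == d.index[0]       # the nearest neighbor is always included


def test_background_gc_is_closer_than_random(small_data):
    ds, _ = small_data
    feats = links.peak_features(ds.peak_meta, ds.atac_counts)
    rng = np.random.default_rng(0)
    gc = feats["gc_fraction"]
    diffs_bg, diffs_rand = [], []
    for q in rng.choice(feats.index, 15, replace=False):
        bg = links.match_background_peaks(q, feats, n_background=50)
        rand = rng.choice(feats.index.drop(q), 50, replace=False)
        diffs_bg.append(np.abs(gc[bg] - gc[q]).mean())
        diffs_rand.append(np.abs(gc[rand] - gc[q]).mean())
    assert np.mean(diffs_bg) <= np.mean(diffs_rand)


def _toy_link_setup(rng, n_cells=80, n_peaks=30):
    atac = rng.normal(size=(n_peaks, n_cells))
    gene = atac[0].copy()                    # gene identical to peak 0
    rna = np.vstack([gene, rng.normal(size=(1, n_cells))])
    peak_ids = pd.Index([f"p{i}" for i in range(n_peaks)], name="peak_id")
    gene_ids = pd.Index(["g0", "g1"], name="gene_id")
    feats = pd.DataFrame({"gc_fraction": rng.uniform(0.4, 0.6, n_peaks),
                          "mean_accessibility": rng.uniform(0, 1, n_peaks),
                          "width": 500.0}, index=peak_ids)
    pairs = pd.DataFrame({"peak_id": ["p0", "p1"], "gene_id": ["g0", "g1"],
                          "distance": [0, 0]})
    return atac, rna, pairs, peak_ids, gene_ids, feats


def test_link_peaks_perfect_coupling_and_affine_invariance():
    rng = np.random.default_rng(1)
    atac, rna, pairs, peak_ids, gene_ids, feats = _toy_link_setup(rng)
    tab, dropped = links.link_peaks(atac, rna, pairs, peak_ids, gene_ids, feats,
                                    n_background=20)
    row = tab.set_index("peak_id").loc["p0"]
    assert row["r"] == pytest.approx(1.0)
    assert row["z"] > 0 and row["accepted"]
    # affine rescaling of the accessibility leaves z unchanged
    tab2, _ = links.link_peaks(atac * 5.0 + 3.0, rna, pairs, peak_ids, gene_ids,
                               feats, n_background=20)
    assert np.allclose(tab["z"].to_numpy(), tab2["z"].to_numpy())


def test_link_peaks_degenerate_cases():
    rng = np.random.default_rng(2)
    atac, rna, pairs, peak_ids, gene_ids, feats = _toy_link_setup(rng)
    atac[1] = 0.0                              # zero-variance peak
    tab, dropped = links.link_peaks(atac, rna, pairs, peak_ids, gene_ids, feats,
                                    n_background=20)
    assert "p1" in set(dropped["peak_id"])
    assert (dropped.set_index("peak_id").loc["p1", "reason"] == "zero variance")
    # constant backgrounds -> degenerate null
    atac2 = np.zeros((5, 40))
    atac2[0] = rng.normal(size=40)
    rna2 = atac2[:1].copy()
    pairs2 = pd.DataFrame({"peak_id": ["p0"], "gene_id": ["g0"], "distance": [0]})
    feats2 = pd.DataFrame({"gc_fraction": 0.5, "mean_accessibility": 0.0,
                           "width": 500.0},
                          index=pd.Index([f"p{i}" for i in range(5)], name="peak_id"))
    tab2, dropped2 = links.link_peaks(atac2, rna2, pairs2, feats2.index,
                                      pd.Index(["g0"]), feats2, n_background=3)
    assert list(dropped2["reason"]) == ["degenerate null"]
    assert len(tab2) == 0


def test_annotation_priority_and_percentages():
    gm = pd.DataFrame({
        "chrom": ["chr1"], "tss": [50_000], "strand": ["+"],
        "start": [50_000], "end": [70_000],
        "exon_starts": ["50000,64000"], "exon_ends": ["56000,70000"],
    }, index=pd.Index(["g0"], name="gene_id"))
    pm = _peaks([
        ("chr1", 49_500, 50_500),       # spans the TSS -> promoter
        ("chr1", 54_000, 54_500),       # inside exon 1 (beyond the 5'UTR)
        ("chr1", 60_000, 60_500),       # intron
        ("chr1", 69_900, 70_100),       # 3'UTR end of the gene
        ("chr1", 71_000, 71_500),       # within 3 kb downstream
        ("chr1", 2_000_000, 2_000_500), # far away
    ])
    table, pct = links.annotate_peaks(pm, gm)
    assert list(table["category"]) == ["promoter", "exon", "intron", "3'UTR",
                                       "downstream", "distal_intergenic"]
    assert pct.sum() == pytest.approx(100.0)
    # no gene model at all -> everything distal
    table2, _ = links.annotate_peaks(pm, gm.iloc[:0])
    assert set(table2["category"]) == {"distal_intergenic"}
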