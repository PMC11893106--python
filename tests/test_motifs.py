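"""PFM parsing, PWM scanning, enrichment and motif-activity deviations."""
from math import comb

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from pgcgrn import motifs
from pgcgrn.links import peak_features
from pgcgrn.simulate import default_motif_file, reverse_complement


def test_jaspar_round_trip_and_uniform_logodds(tmp_path):
    models = motifs.read_jaspar(default_motif_file())
    assert len(models) == 8
    out = tmp_path / "copy.jaspar"
    motifs.write_jaspar(models, out)
    models2 = motifs.read_jaspar(out)
    for a, b in zip(models, models2):
        assert a.motif_id == b.motif_id and np.array_equal(a.pfm, b.pfm)
    # uniform counts mean no information: all log-odds zero
    uni = motifs.MotifModel("U0", "UNI", np.full((4, 5), 25.0))
    assert np.allclose(uni.log_odds(), 0.0)


def test_logodds_matches_hand_arithmetic():
    pfm = np.array([[8, 0, 5, 3], [0, 8, 5, 3], [2, 1, 0, 2], [0, 1, 0, 2]],
                   dtype=float)
    m = motifs.MotifModel("T", "T", pfm)
    p00 = (8 + 0.8 * 0.25) / (10 + 0.8)
    assert m.log_odds()[0, 0] == pytest.approx(np.log2(p00 / 0.25))
    p30 = (0 + 0.8 * 0.25) / (10 + 0.8)
    assert m.log_odds()[3, 0] == pytest.approx(np.log2(p30 / 0.25))


def test_malformed_jaspar_raises(tmp_path):
    bad = tmp_path / "bad.jaspar"
    bad.write_text(">M1\tX\nA [ 1 2 ]\nC [ 1 ]\n")
    with pytest.raises(ValueError, match="malformed"):
        motifs.read_jaspar(bad)


def _brute_force_hits(seq, model, threshold_fraction=0.8):
    lo = model.log_odds()
    thr = threshold_fraction * model.max_score()
    L = model.length
    code = {c: i for i, c in enumerate("ACGT")}
    found = []
    for strand, s in (("+", seq), ("-", reverse_complement(seq))):
        for off in range(len(s) - L + 1):
            score = sum(lo[code[c], j] if c in code else 0.0
                        for j, c in enumerate(s[off:off + L]))
            if score >= thr:
                pos = off if strand == "+" else len(seq) - off - L
                found.append((pos, strand))
    return sorted(set(found))


def test_scan_matches_brute_force_and_consensus_rules():
    models = motifs.read_jaspar(default_motif_file())[:1]
    m = models[0]
    rng = np.random.default_rng(0)
    bases = np.array(list("ACGT"))
    seqs = {}
    for i in range(3):
        s = "".join(rng.choice(bases, size=120))
        if i == 0:
            s = s[:40] + m.consensus + s[40 + m.length:]   # guaranteed site
        seqs[f"p{i}"] = s
    seqs["pN"] = "N" * 100
    seqs["short"] = "ACG"
    hm = motifs.scan_peaks(seqs, models)
    assert bool(hm.hits.loc["p0", m.motif_id])
    assert not hm.hits.loc["pN", m.motif_id]       # N scores as background
    assert not hm.hits.loc["short", m.motif_id]    # shorter than the motif
    for pid, s in seqs.items():
        if pid == "short":
            continue
        expected = {(pos, strand) for pos, strand in _brute_force_hits(s, m)}
        got = hm.positions[hm.positions["peak_id"] == pid]
        got_set = set()
        for _, r in got.iterrows():
            pos = r["offset"] if r["strand"] == "+" else len(s) - r["offset"] - m.length
            got_set.add((r["offset"], r["strand"]) if r["strand"] == "+"
                        else (r["offset"], "-"))
        # compare via hit presence per (offset, strand) on the forward coordinates
        fwd = {(pos, st) for pos, st in expected if st == "+"}
        got_fwd = {(r["offset"], "+") for _, r in got.iterrows() if r["strand"] == "+"}
        assert fwd == got_fwd
        assert bool(len(expected)) == bool(hm.hits.loc[pid, m.motif_id])


def test_scan_is_strand_symmetric():
    models = motifs.read_jaspar(default_motif_file())[:3]
    rng = np.random.default_rng(1)
    bases = np.array(list("ACGT"))
    seqs = {f"p{i}": "".join(rng.choice(bases, size=80)) for i in range(6)}
    seqs["p0"] = seqs["p0"][:10] + models[0].consensus + seqs["p0"][10 + models[0].length:]
    rc = {k: reverse_complement(v) for k, v in seqs.items()}
    h1 = motifs.scan_peaks(seqs, models)
    h2 = motifs.scan_peaks(rc, models)
    assert h1.hits.equals(h2.hits)


def test_enrichment_exact_hypergeometric_tail():
    peak_ids = [f"q{i}" for i in range(10)] + [f"b{i}" for i in range(100)]
    hit = np.zeros((110, 1), dtype=bool)
    hit[:8, 0] = True                    # 8 of 10 query peaks carry the motif
    hit[10:30, 0] = True                 # 20 of 100 background peaks do
    hm = motifs.HitMatrix(
        hits=pd.DataFrame(hit, index=pd.Index(peak_ids, name="peak_id"),
                          columns=["M1"]),
        positions=pd.DataFrame(columns=["motif_id", "peak_id", "offset",
                                        "strand", "score"]),
        threshold_fraction=0.8, pseudocount=0.8)
    out = motifs.motif_enrichment(peak_ids[:10], peak_ids[10:], hm)
    M, K, n = 110, 28, 10
    expected = sum(comb(K, k) * comb(M - K, n - k) for k in range(8, n + 1)) / comb(M, n)
    assert out.loc["M1", "p_value"] == pytest.approx(expected)
    assert out.loc["M1", "fold_enrichment"] == pytest.approx(0.8 / 0.2)
    # equal rates: no enrichment signal
    hit2 = np.zeros((30, 1), dtype=bool)
    hit2[:2, 0] = True
    hit2[10:14, 0] = True
    hm2 = motifs.HitMatrix(
        hits=pd.DataFrame(hit2, index=pd.Index([f"x{i}" for i in range(30)],
                                               name="peak_id"), columns=["M1"]),
        positions=hm.positions, threshold_fraction=0.8, pseudocount=0.8)
    out2 = motifs.motif_enrichment([f"x{i}" for i in range(10)],
                                   [f"x{i}" for i in range(10, 30)], hm2)
    assert out2.loc["M1", "fold_enrichment"] == pytest.approx(1.0)
    assert out2.loc["M1", "p_value"] >= 0.5


def _dev_setup(rng, n_peaks=40, n_cells=30):
    counts = sp.csr_matrix(rng.poisson(2.0, size=(n_peaks, n_cells)).astype(np.int32))
    peak_ids = pd.Index([f"p{i}" for i in range(n_peaks)], name="peak_id")
    feats = pd.DataFrame({"gc_fraction": rng.uniform(0.4, 0.6, n_peaks),
                          "mean_accessibility": np.asarray(counts.mean(axis=1)).ravel(),
                          "width": 500.0}, index=peak_ids)
    return counts, peak_ids, feats


def test_deviations_all_peak_motif_is_exactly_zero():
    rng = np.random.default_rng(3)
    counts, peak_ids, feats = _dev_setup(rng)
    hits = motifs.HitMatrix(
        hits=pd.DataFrame(True, index=peak_ids, columns=["ALL"]),
        positions=pd.DataFrame(columns=["motif_id", "peak_id", "offset",
                                        "strand", "score"]),
        threshold_fraction=0.8, pseudocount=0.8)
    cells = pd.Index([f"c{i}" for i in range(counts.shape[1])])
    dev = motifs.chromvar_deviations(counts, hits, feats, cells,
                                     n_background_sets=10, seed=0)
    # observed = expected when the motif spans every peak: X = d_c, E = d_c
    assert np.allclose(dev.raw.loc["ALL"].to_numpy(), 0.0, atol=1e-12)


def test_deviations_are_cell_equivariant():
    rng = np.random.default_rng(4)
    counts, peak_ids, feats = _dev_setup(rng)
    hit = rng.random(len(peak_ids)) < 0.3
    hits = motifs.HitMatrix(
        hits=pd.DataFrame({"M": hit}, index=peak_ids),
        positions=pd.DataFrame(columns=["motif_id", "peak_id", "offset",
                                        "strand", "score"]),
        threshold_fraction=0.8, pseudocount=0.8)
    cells = pd.Index([f"c{i}" for i in range(counts.shape[1])])
    dev = motifs.chromvar_deviations(counts, hits, feats, cells,
                                     n_background_sets=15, seed=0)
    perm = np.random.default_rng(5).permutation(counts.shape[1])
    dev_p = motifs.chromvar_deviations(counts[:, perm], hits, feats, cells[perm],
                                       n_background_sets=15, seed=0)
    assert np.allclose(dev.z.loc["M", cells[perm]].to_numpy(),
                       dev_p.z.loc["M"].to_numpy())


def test_zero_count_motif_is_dropped():
    rng = np.random.default_rng(6)
    counts, peak_ids, feats = _dev_setup(rng)
    counts = counts.tolil()
    counts[0] = 0
    counts = counts.tocsr()
    hits_df = pd.DataFrame(False, index=peak_ids, columns=["DEAD", "OK"])
    hits_df.iloc[0, 0] = True
    hits_df.iloc[1:5, 1] = True
    hits = motifs.HitMatrix(hits=hits_df,
                            positions=pd.DataFrame(columns=["motif_id", "peak_id",
                                                            "offset", "strand",
                                                            "score"]),
                            threshold_fraction=0.8, pseudocount=0.8)
    cells = pd.Index([f"c{i}" for i in range(counts.shape[1])])
    with pytest.warns(UserWarning, match="zero-count"):
        dev = motifs.chromvar_deviations(counts, hits, feats, cells,
                                         n_background_sets=5, seed=0)
    assert list(dev.z.index) == ["OK"]
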