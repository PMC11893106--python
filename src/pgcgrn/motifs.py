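"""Motif models, PWM scanning, GC-matched enrichment and per-cell motif activity.

Position frequency matrices are read from JASPAR-format text. Scanning uses
a log-odds PWM over both strands with a threshold expressed as a fraction of
the maximal achievable score (default 80%), which is deterministic and
guarantees that an exact consensus site is always recovered. Enrichment is a
hypergeometric upper-tail test of query-peak hits against a (typically
GC-matched) background universe. Per-cell motif activity follows the
bias-corrected deviation scheme: observed minus expected accessibility in a
motif's peaks, corrected and scaled by deviations of matched background peak
sets.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from Bio import motifs as bio_motifs
from scipy.stats import hypergeom

from .differential import bh_adjust
from .links import background_pools

_CODE = {c: i for i, c in enumerate("ACGT")}


@dataclass
class MotifModel:
    """A TF binding motif as a 4 x L count matrix with A,C,G,T rows."""
    motif_id: str
    name: str
    pfm: np.ndarray                                 # 4 x L non-negative counts
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self):
        self.pfm = np.asarray(self.pfm, dtype=float)
        if self.pfm.shape[0] != 4 or self.pfm.shape[1] < 4:
            raise ValueError("PFM must be 4 x L with L >= 4")
        if (self.pfm < 0).any():
            raise ValueError("PFM counts must be non-negative")

    @property
    def length(self) -> int:
        return self.pfm.shape[1]

    def probabilities(self, pseudocount: float = 0.8) -> np.ndarray:
        """Column-normalized probabilities with a background-split pseudocount."""
        counts = self.pfm + pseudocount * self.background[:, None]
        return counts / counts.sum(axis=0, keepdims=True)

    def log_odds(self, pseudocount: float = 0.8) -> np.ndarray:
        """log2 odds versus the background distribution."""
        return np.log2(self.probabilities(pseudocount) / self.background[:, None])

    @property
    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.pfm.argmax(axis=0))

    def max_score(self, pseudocount: float = 0.8) -> float:
        return float(self.log_odds(pseudocount).max(axis=0).sum())


def read_jaspar(path, background=None) -> list[MotifModel]:
    """Read JASPAR-format PFMs (header '>ID name', bracketed count rows)."""
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    out = []
    try:
        with open(path) as handle:
            records = bio_motifs.parse(handle, "jaspar")
        for rec in records:
            pfm = np.array([list(rec.counts[b]) for b in "ACGT"], dtype=float)
            out.append(MotifModel(motif_id=rec.matrix_id or rec.name,
                                  name=rec.name or rec.matrix_id,
                                  pfm=pfm, background=bg.copy()))
    except Exception as exc:
        raise ValueError(f"malformed JASPAR file {path}: {exc}") from exc
    with open(path) as handle:
        has_content = any(line.strip() for line in handle)
    if has_content and not out:
        raise ValueError(f"malformed JASPAR file {path}: no motifs parsed")
    return out


def write_jaspar(motif_list: list[MotifModel], path) -> None:
    with open(path, "w") as f:
        for m in motif_list:
            f.write(f">{m.motif_id}\t{m.name}\n")
            for i, base in enumerate("ACGT"):
                row = " ".join(f"{int(round(x)):>3}" for x in m.pfm[i])
                f.write(f"{base}  [ {row} ]\n")


@dataclass
class HitMatrix:
    """Binary peak x motif indicator plus the scan parameters that made it."""
    hits: pd.DataFrame                 # bool, index peak_id, columns motif_id
    positions: pd.DataFrame            # motif_id, peak_id, offset, strand, score
    threshold_fraction: float
    pseudocount: float

    def motif_peaks(self, motif_id: str) -> pd.Index:
        return self.hits.index[self.hits[motif_id].to_numpy(bool)]


_ENC_TABLE = np.full(256, 4, dtype=np.int8)
for _c, _i in _CODE.items():
    _ENC_TABLE[ord(_c)] = _i


def _encode(seq: str) -> np.ndarray:
    return _ENC_TABLE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def scan_peaks(peak_seqs: dict[str, str], motif_list: list[MotifModel],
               threshold_fraction: float = 0.8, pseudocount: float = 0.8
               ) -> HitMatrix:
    """Slide each PWM over both strands of every peak sequence.

    A window is a hit when its log-odds score reaches ``threshold_fraction``
    of the motif's maximal achievable score. N bases score as background
    (log-odds 0); sequences shorter than the motif yield no hit. Offsets are
    0-based relative to the peak start on the forward strand.
    """
    peak_ids = list(peak_seqs)
    codes = {p: _encode(s.upper()) for p, s in peak_seqs.items()}
    hits = np.zeros((len(peak_ids), len(motif_list)), dtype=bool)
    pos_rows = []
    for j, m in enumerate(motif_list):
        lo = m.log_odds(pseudocount)
        lo_ext = np.vstack([lo, np.zeros((1, m.length))])          # row 4 = N
        # reverse strand: complement rows (A<->T, C<->G) and reverse columns
        lo_rc = lo[::-1, ::-1]
        lo_rc_ext = np.vstack([lo_rc, np.zeros((1, m.length))])
        thr = threshold_fraction * m.max_score(pseudocount)
        L = m.length
        col = np.arange(L)
        for i, p in enumerate(peak_ids):
            c = codes[p]
            if len(c) < L:
                continue
            win = np.lib.stride_tricks.sliding_window_view(c, L)
            fwd = lo_ext[win, col].sum(axis=1)
            rev = lo_rc_ext[win, col].sum(axis=1)
            for strand, scores in (("+", fwd), ("-", rev)):
                for off in np.flatnonzero(scores >= thr):
                    pos_rows.append((m.motif_id, p, int(off), strand,
                                     float(scores[off])))
                    hits[i, j] = True
    hits_df = pd.DataFrame(hits, index=pd.Index(peak_ids, name="peak_id"),
                           columns=[m.motif_id for m in motif_list])
    positions = pd.DataFrame(pos_rows, columns=["motif_id", "peak_id",
                                                "offset", "strand", "score"])
    return HitMatrix(hits=hits_df, positions=positions,
                     threshold_fraction=threshold_fraction, pseudocount=pseudocount)


def motif_enrichment(query_peaks, background_peaks, hits: HitMatrix) -> pd.DataFrame:
    """Hypergeometric motif enrichment of query peaks within a
    query+background universe; BH-adjusted, sorted by p-value."""
    query = pd.Index(query_peaks)
    background = pd.Index(background_peaks)
    universe = query.union(background)
    H = hits.hits.loc[universe]
    bg_only = universe.difference(query)
    M = len(universe)
    n = len(query)
    rows = []
    for motif_id in H.columns:
        K = int(H[motif_id].sum())
        k = int(H.loc[query, motif_id].sum())
        bg_k = int(H.loc[bg_only, motif_id].sum())
        p = float(hypergeom.sf(k - 1, M, K, n))
        q_rate = k / n if n else 0.0
        bg_rate = bg_k / len(bg_only) if len(bg_only) else 0.0
        fold = np.inf if (bg_rate == 0 and q_rate > 0) else \
            (q_rate / bg_rate if bg_rate > 0 else 1.0)
        rows.append((motif_id, n, k, K, q_rate, bg_rate, fold, p))
    out = pd.DataFrame(rows, columns=["motif_id", "n_query", "k_query",
                                      "k_universe", "query_rate",
                                      "background_rate", "fold_enrichment",
                                      "p_value"]).set_index("motif_id")
    out["p_adj"] = bh_adjust(out["p_value"].to_numpy())
    out["enriched"] = out["p_adj"] < 0.05
    return out.sort_values("p_value", kind="mergesort")


@dataclass
class DeviationMatrix:
    """Per-cell motif activity: raw and bias-corrected deviations, z-scores."""
    raw: pd.DataFrame              # motif x cell, (observed - expected)/expected
    deviations: pd.DataFrame       # motif x cell, bias-corrected deviation
    z: pd.DataFrame                # motif x cell deviation z-score
    n_background_sets: int
    seed: int

    def group_activity(self, cells: pd.Index | list) -> pd.Series:
        """Mean deviation z over a cell group ('motif activity')."""
        return self.z[list(cells)].mean(axis=1)


def chromvar_deviations(atac_counts, hits: HitMatrix, features: pd.DataFrame,
                        cells: pd.Index, n_background_sets: int = 50,
                        n_background_pool: int = 50, seed: int = 0
                        ) -> DeviationMatrix:
    """Bias-corrected per-cell motif accessibility deviations.

    For motif m and cell c, the expected count is the motif's share of total
    accessibility times the cell's depth; the raw deviation is
    (observed - expected)/expected. Each of ``n_background_sets`` iterations
    swaps every motif peak for one drawn from its matched background pool
    (GC, accessibility, width) and recomputes the deviation; the mean and SD
    of these background deviations give the bias correction and the z-score.
    Runs on raw counts. Motifs whose peaks carry zero total counts are
    dropped with a warning.
    """
    A = atac_counts.tocsr() if sp.issparse(atac_counts) else sp.csr_matrix(atac_counts)
    peak_ids = hits.hits.index
    if A.shape[0] != len(peak_ids):
        raise ValueError("atac_counts rows must match the hit matrix peaks")
    H = sp.csr_matrix(hits.hits.to_numpy(dtype=float))      # peak x motif
    a = np.asarray(A.sum(axis=1)).ravel().astype(float)      # per-peak totals
    d = np.asarray(A.sum(axis=0)).ravel().astype(float)      # per-cell depths
    total = a.sum()
    motif_ids = list(hits.hits.columns)

    motif_tot = H.T @ a
    keep = motif_tot > 0
    if not keep.all():
        dropped = [m for m, k in zip(motif_ids, keep) if not k]
        warnings.warn(f"dropping motifs with zero-count peaks: {dropped}")
        H = H[:, keep]
        motif_ids = [m for m, k in zip(motif_ids, keep) if k]
        motif_tot = motif_tot[keep]

    X = (H.T @ A).toarray()
    E = np.outer(motif_tot / total, d)
    with np.errstate(divide="ignore", invalid="ignore"):
        Y = np.where(E > 0, (X - E) / E, 0.0)

    pools = background_pools(features.loc[peak_ids], n_background_pool)
    rng = np.random.default_rng(seed)
    n_peaks = len(peak_ids)
    bg = np.empty((n_background_sets,) + Y.shape)
    for b in range(n_background_sets):
        swap = pools[np.arange(n_peaks), rng.integers(0, pools.shape[1], n_peaks)]
        a_b = a[swap]
        A_b = A[swap]
        X_b = (H.T @ A_b).toarray()
        tot_b = H.T @ a_b
        E_b = np.outer(tot_b / total, d)
        with np.errstate(divide="ignore", invalid="ignore"):
            bg[b] = np.where(E_b > 0, (X_b - E_b) / E_b, 0.0)
    mean_bg = bg.mean(axis=0)
    sd_bg = bg.std(axis=0, ddof=1)
    corrected = Y - mean_bg
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd_bg > 0, corrected / sd_bg, 0.0)
    cells = pd.Index(cells)
    return DeviationMatrix(
        raw=pd.DataFrame(Y, index=motif_ids, columns=cells),
        deviations=pd.DataFrame(corrected, index=motif_ids, columns=cells),
        z=pd.DataFrame(z, index=motif_ids, columns=cells),
        n_background_sets=n_background_sets, seed=seed)
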