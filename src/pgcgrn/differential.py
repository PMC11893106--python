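"""Differential testing for genes and peaks.

The procedure mirrors the standard single-cell marker test: features are
pre-filtered on the fraction of expressing cells (``min_pct``) and on an
absolute log2 fold change computed from de-normalized group means with a
pseudocount, survivors are tested with a two-sided Wilcoxon rank-sum test
(exact enumeration for small groups, tie-corrected normal approximation
otherwise), and p-values are Benjamini-Hochberg adjusted within the
comparison. Gene-level defaults are min_pct 0.25 / log2FC 0.25; peak-level
comparisons conventionally use min_pct 0.001 / log2FC 0.1.
"""
from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import norm, rankdata
from statsmodels.stats.multitest import multipletests

EXACT_MAX_N = 20


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _group_dense(X, idx):
    sub = X[:, idx]
    return sub.toarray() if sp.issparse(sub) else np.asarray(sub, dtype=float)


def fold_change_and_pct(norm_expr, cells_a, cells_b, pseudocount: float = 1.0
                        ) -> pd.DataFrame:
    """Per-feature log2 fold change of de-normalized means and expressing fractions.

    log2fc = log2((mean_A(e^x - 1) + pc) / (mean_B(e^x - 1) + pc)); pct_g is
    the fraction of group-g cells with a non-zero value.
    """
    a_idx = np.asarray(cells_a)
    b_idx = np.asarray(cells_b)
    if a_idx.size == 0 or b_idx.size == 0:
        raise ValueError("both groups must be non-empty")
    if np.intersect1d(a_idx, b_idx).size:
        raise ValueError("groups must be disjoint")
    A = _group_dense(norm_expr, a_idx)
    B = _group_dense(norm_expr, b_idx)
    mean_a = np.expm1(A).mean(axis=1)
    mean_b = np.expm1(B).mean(axis=1)
    log2fc = np.log2((mean_a + pseudocount) / (mean_b + pseudocount))
    return pd.DataFrame({
        "log2fc": log2fc,
        "pct_1": (A > 0).mean(axis=1),
        "pct_2": (B > 0).mean(axis=1),
    })


def _exact_two_sided(values_a: np.ndarray, values_b: np.ndarray) -> float:
    """Exact two-sided rank-sum p by enumeration of all group assignments.

    Two-sided via the symmetric statistic |U - n_a n_b / 2|; ties handled by
    average ranks of the pooled sample.
    """
    na, nb = len(values_a), len(values_b)
    pooled = np.concatenate([values_a, values_b])
    ranks = rankdata(pooled)
    mu = na * nb / 2.0
    u_obs = ranks[:na].sum() - na * (na + 1) / 2.0
    d_obs = abs(u_obs - mu)
    n = na + nb
    count = 0
    total = 0
    for comb in combinations(range(n), na):
        u = ranks[list(comb)].sum() - na * (na + 1) / 2.0
        count += abs(u - mu) >= d_obs - 1e-9
        total += 1
    return count / total


def wilcoxon_test(norm_expr, cells_a, cells_b, features=None) -> np.ndarray:
    """Two-sided Mann-Whitney p-value per feature (rows of ``norm_expr``).

    Exact enumeration when n_A + n_B <= 20, else tie-corrected normal
    approximation with continuity correction. Constant features get p = 1.
    """
    a_idx = np.asarray(cells_a)
    b_idx = np.asarray(cells_b)
    if len(a_idx) < 3 or len(b_idx) < 3:
        raise ValueError("each group needs at least 3 cells")
    A = _group_dense(norm_expr, a_idx)
    B = _group_dense(norm_expr, b_idx)
    if features is not None:
        A, B = A[features], B[features]
    na, nb = A.shape[1], B.shape[1]
    n = na + nb
    X = np.concatenate([A, B], axis=1)
    constant = np.ptp(X, axis=1) == 0

    if n <= EXACT_MAX_N:
        p = np.array([
            1.0 if constant[i] else _exact_two_sided(A[i], B[i])
            for i in range(X.shape[0])])
        return p

    ranks = rankdata(X, axis=1)
    u = ranks[:, :na].sum(axis=1) - na * (na + 1) / 2.0
    mu = na * nb / 2.0
    # tie correction per feature
    tie_term = np.zeros(X.shape[0])
    for i in range(X.shape[0]):
        _, counts = np.unique(X[i], return_counts=True)
        tie_term[i] = (counts**3 - counts).sum()
    var = na * nb / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    sd = np.sqrt(var)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (u - mu - np.sign(u - mu) * 0.5) / sd
    p = np.where(sd > 0, 2.0 * norm.sf(np.abs(z)), 1.0)
    return np.minimum(p, 1.0)


def find_markers(norm_expr, cells_a, cells_b, feature_ids,
                 min_pct: float = 0.25, logfc_threshold: float = 0.25,
                 alpha: float = 0.05, pseudocount: float = 1.0,
                 group_labels=("group1", "group2")) -> pd.DataFrame:
    """Marker table between two cell groups.

    Features are pre-filtered to max(pct_1, pct_2) >= min_pct and
    |log2fc| >= logfc_threshold; the Wilcoxon test and BH adjustment run on
    the survivors only. ``group_up`` names the group with the higher mean.
    """
    if min_pct < 0 or logfc_threshold < 0:
        raise ValueError("thresholds must be non-negative")
    fc = fold_change_and_pct(norm_expr, cells_a, cells_b, pseudocount)
    fc.index = pd.Index(feature_ids, name="feature_id")
    keep = (np.maximum(fc["pct_1"], fc["pct_2"]) >= min_pct) & \
           (fc["log2fc"].abs() >= logfc_threshold)
    surv = np.flatnonzero(keep.to_numpy())
    out = fc.iloc[surv].copy()
    if len(surv) == 0:
        out["p_value"] = np.array([], dtype=float)
        out["p_adj"] = np.array([], dtype=float)
        out["group_up"] = np.array([], dtype=object)
        out["significant"] = np.array([], dtype=bool)
        return out
    p = wilcoxon_test(norm_expr, cells_a, cells_b, features=surv)
    out["p_value"] = p
    # BH over all input features (filtered features count as untested p = 1):
    # adjusting only over gate survivors would be anti-conservative because
    # the fold-change gate preferentially passes features with small p
    padded = np.concatenate([p, np.ones(len(fc) - len(p))])
    out["p_adj"] = bh_adjust(padded)[: len(p)]
    out["group_up"] = np.where(out["log2fc"] > 0, group_labels[0], group_labels[1])
    out["significant"] = out["p_adj"] < alpha
    return out.sort_values("p_value", kind="mergesort")
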