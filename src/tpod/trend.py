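"""Williams trend test prefilter with a fold-change gate.

Williams' procedure compares the monotone-amalgamated top-dose mean with the
control mean, pooling adjacent violating dose means by weighted isotonic
regression (PAVA).  Published critical-value tables are replaced here by a
permutation null (sample labels permuted across concentration groups), which
is exact at the small replicate numbers typical of these designs.  A gene
passes the prefilter when the permutation p-value is below ``alpha`` and the
largest linear-scale fold change of any dose group vs control is at least
``fc_cut`` (default 1.5-fold).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic_data import DoseDesign
from .deg import NormalizedMatrix

__all__ = ["pava", "williams_stat", "williams_test", "williams_test_matrix",
           "TREND_FC_CUTOFF", "TREND_ALPHA"]

#: Linear-scale fold-change gate of the prefilter.
TREND_FC_CUTOFF = 1.5
#: Permutation p-value threshold of the prefilter.
TREND_ALPHA = 0.05


def pava(means, weights=None, direction: int = 1) -> np.ndarray:
    """Weighted pool-adjacent-violators (isotonic) fit of group means.

    ``direction=+1`` fits a non-decreasing sequence, ``-1`` non-increasing.
    Pooling preserves the weighted mean.
    """
    y = np.asarray(means, dtype=float)
    if weights is None:
        weights = np.ones_like(y)
    w = np.asarray(weights, dtype=float)
    if len(y) < 1 or (w <= 0).any():
        raise ValueError("need >= 1 group with positive weights")
    if direction == -1:
        return -pava(-y, w, 1)

    # classic stack algorithm: blocks of (sum_w, sum_wy)
    vals, wts, sizes = [], [], []
    for yi, wi in zip(y, w):
        vals.append(yi)
        wts.append(wi)
        sizes.append(1)
        while len(vals) > 1 and vals[-2] > vals[-1]:
            wv = wts[-2] + wts[-1]
            vv = (wts[-2] * vals[-2] + wts[-1] * vals[-1]) / wv
            sz = sizes[-2] + sizes[-1]
            vals = vals[:-2] + [vv]
            wts = wts[:-2] + [wv]
            sizes = sizes[:-2] + [sz]
    return np.repeat(vals, sizes)


def _pava_rows(Y: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Vectorized non-decreasing isotonic fit applied independently per row.

    ``Y`` is (n_rows, k); ``w`` is (k,) group weights shared by all rows.
    Uses the exact minimax characterization of the isotonic regression:
    ``fit_i = max_{a<=i} min_{b>=i} mean_w(Y[a..b])``; with the handful of
    dose groups of these designs the (rows, k, k) segment-mean tensor is
    cheap and the result is exact, not iterative.
    """
    Y = np.asarray(Y, dtype=float)
    n, k = Y.shape
    w = np.asarray(w, dtype=float)
    cw = np.concatenate([[0.0], np.cumsum(w)])
    cy = np.concatenate([np.zeros((n, 1)), np.cumsum(Y * w, axis=1)], axis=1)
    # segment means M[:, a, b] for a <= b
    wseg = cw[None, 1:] - cw[:-1, None]                  # (k, k): W[a..b]
    with np.errstate(divide="ignore", invalid="ignore"):
        M = (cy[:, None, 1:] - cy[:, :-1, None]) / wseg[None, :, :]
    # invalid segments (a > b) must not affect the min/max
    tri = np.tril(np.ones((k, k), dtype=bool), -1)       # a > b
    M[:, tri] = np.nan
    # min over b >= i (suffix min along b), then max over a <= i
    suff = np.fmin.accumulate(M[:, :, ::-1], axis=2)[:, :, ::-1]
    fit = np.fmax.accumulate(
        np.where(np.isnan(suff), -np.inf, suff), axis=1)
    # fit_i = max_{a<=i} min_{b>=i} M[a..b]
    out = fit.diagonal(axis1=1, axis2=2).copy()
    return out


def _group_indicator(concs: np.ndarray):
    """Group index per sample plus the ordered unique concentrations."""
    uniq = np.unique(concs)
    gidx = np.searchsorted(uniq, concs)
    return gidx, uniq


def williams_stat(expr, design: DoseDesign = None, direction: int = 1,
                  concentrations=None) -> float:
    """Williams t-bar for one gene.

    ``t = (amalgamated top-dose mean - control mean) /
    sqrt(s2 * (1/n_top + 1/n_0))`` with ``s2`` the pooled within-group
    variance.  ``direction=-1`` is evaluated by negating the data, so
    ``williams_stat(x, -1) == williams_stat(-x, +1)``.
    """
    y = np.asarray(expr, dtype=float)
    if direction == -1:
        return williams_stat(-y, design, 1, concentrations)
    concs = (np.asarray(concentrations, float) if concentrations is not None
             else np.array([c for c in design.concentrations
                            for _ in range(design.n_replicates)]))
    gidx, uniq = _group_indicator(concs)
    k = len(uniq)
    n_g = np.bincount(gidx, minlength=k).astype(float)
    if n_g[0] < 2 or n_g[-1] < 2:
        raise ValueError("need >= 2 replicates in control and top dose")
    means = np.bincount(gidx, weights=y, minlength=k) / n_g
    ss = np.bincount(gidx, weights=y ** 2, minlength=k) - n_g * means ** 2
    dfw = len(y) - k
    s2 = ss.sum() / dfw if dfw > 0 else 0.0
    # control mean stays un-amalgamated; isotonic fit over the dose groups
    amalg = pava(means[1:], n_g[1:], 1)
    num = amalg[-1] - means[0]
    if s2 <= 0:
        return math.inf if num > 0 else (0.0 if num == 0 else -math.inf)
    return float(num / math.sqrt(s2 * (1.0 / n_g[-1] + 1.0 / n_g[0])))


def _stats_matrix(Y: np.ndarray, gidx: np.ndarray, k: int):
    """Williams t-bar for each row of Y, both directions. Returns (t_up, t_dn)."""
    n = Y.shape[1]
    n_g = np.bincount(gidx, minlength=k).astype(float)
    M = np.zeros((k, n))
    M[gidx, np.arange(n)] = 1.0 / n_g[gidx]
    means = Y @ M.T                               # rows x k group means
    ss = (Y ** 2) @ (M.T * n_g) - n_g * means ** 2
    dfw = n - k
    s2 = ss.sum(axis=1) / dfw
    scale = np.sqrt(np.clip(s2, 0, None) * (1.0 / n_g[-1] + 1.0 / n_g[0]))
    up = _pava_rows(means[:, 1:], n_g[1:])[:, -1] - means[:, 0]
    dn = means[:, 0] - (-_pava_rows(-means[:, 1:], n_g[1:]))[:, -1]
    with np.errstate(divide="ignore", invalid="ignore"):
        t_up = np.where(scale > 0, up / scale,
                        np.where(up > 0, np.inf, np.where(up < 0, -np.inf, 0)))
        t_dn = np.where(scale > 0, dn / scale,
                        np.where(dn > 0, np.inf, np.where(dn < 0, -np.inf, 0)))
    return t_up, t_dn, means, n_g


def williams_test_matrix(norm: NormalizedMatrix, n_permutations: int = 10_000,
                         seed: int = 0, fc_cut: float = TREND_FC_CUTOFF,
                         alpha: float = TREND_ALPHA) -> pd.DataFrame:
    """Permutation Williams trend test for every gene of a normalized matrix.

    Permutations of the sample labels are shared across genes; for each gene
    the direction with the larger |t| is kept and its one-sided permutation
    p-value is Bonferroni-doubled.  The fold-change gate uses linear-scale
    group means (2**mean of log2 values) vs control.
    """
    if n_permutations < 999:
        raise ValueError("need >= 999 permutations")
    Y = norm.log2.to_numpy(float)
    concs = norm.concentrations()
    gidx, uniq = _group_indicator(concs)
    k = len(uniq)
    n = Y.shape[1]

    n_distinct = (math.factorial(n)
                  // math.prod(math.factorial(int((gidx == j).sum()))
                               for j in range(k)))
    if n_distinct < n_permutations:
        warnings.warn("fewer distinct permutations than requested; "
                      "sampling with replacement", stacklevel=2)

    t_up, t_dn, means, n_g = _stats_matrix(Y, gidx, k)
    use_up = np.abs(t_up) >= np.abs(t_dn)
    t_obs = np.where(use_up, t_up, t_dn)
    direction = np.where(use_up, 1, -1)

    rng = np.random.default_rng(seed)
    exceed = np.zeros(Y.shape[0], dtype=np.int64)
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        pu, pdn, _, _ = _stats_matrix(Y[:, perm], gidx, k)
        t_perm = np.where(use_up, pu, pdn)
        exceed += t_perm >= t_obs
    p_one = (1.0 + exceed) / (1.0 + n_permutations)
    p = np.minimum(1.0, 2.0 * p_one)

    lin = np.exp2(means)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = lin[:, 1:] / lin[:, [0]]
    max_fc = np.maximum(ratio, 1.0 / ratio).max(axis=1)
    max_fc = np.maximum(max_fc, 1.0)

    out = pd.DataFrame({
        "gene_id": norm.log2.index.to_numpy(),
        "direction": direction,
        "stat": t_obs,
        "p": p,
        "max_fc": max_fc,
    })
    out["passes"] = (out["p"] < alpha) & (out["max_fc"] >= fc_cut)
    return out


def williams_test(expr, design: DoseDesign, n_permutations: int = 10_000,
                  seed: int = 0, fc_cut: float = TREND_FC_CUTOFF,
                  alpha: float = TREND_ALPHA, gene_id: str = "gene",
                  concentrations=None) -> pd.Series:
    """Single-gene permutation Williams test; returns one TrendRecord row."""
    y = np.asarray(expr, dtype=float)[None, :]
    concs = (np.asarray(concentrations, float) if concentrations is not None
             else np.array([c for c in design.concentrations
                            for _ in range(design.n_replicates)]))
    sheet = pd.DataFrame({"sample_id": [f"s{i}" for i in range(len(concs))],
                          "concentration_uM": concs,
                          "replicate": "r"})
    norm = NormalizedMatrix(
        log2=pd.DataFrame(y, index=[gene_id],
                          columns=sheet["sample_id"].to_numpy()),
        size_factors=pd.Series(np.ones(len(concs)),
                               index=sheet["sample_id"].to_numpy()),
        pseudocount=1.0, samples=sheet)
    return williams_test_matrix(norm, n_permutations, seed, fc_cut,
                                alpha).iloc[0]
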