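"""Normalization and negative-binomial differential expression.

Implements median-of-ratios size factors, log2 normalization, and a
per-gene negative-binomial GLM Wald test for the top-concentration vs
control contrast with a ``~ replicate + condition`` design.  Dispersions are
estimated by method of moments per gene, a mean-dispersion trend is fitted
across genes, and gene-wise estimates are shrunk toward the trend.  This is a
deliberately simplified NB-GLM pipeline, not a DESeq2 clone: no Cox-Reid
adjustment and no fold-change shrinkage.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .synthetic_data import CountMatrix

__all__ = [
    "NormalizedMatrix",
    "size_factors",
    "normalize_log2",
    "estimate_dispersions",
    "nb_test",
    "call_degs",
    "Q_CUTOFF",
    "LFC_CUTOFF",
]

LN2 = math.log(2.0)

#: FDR threshold for DEG calls.
Q_CUTOFF = 0.05
#: |log2 fold change| threshold: a 1.5-fold change, log2(1.5) = 0.585.
LFC_CUTOFF = math.log2(1.5)


@dataclass
class NormalizedMatrix:
    """log2-scale normalized expression with per-sample size factors."""

    log2: pd.DataFrame
    size_factors: pd.Series
    pseudocount: float
    samples: pd.DataFrame

    def concentrations(self) -> np.ndarray:
        return self.samples["concentration_uM"].to_numpy(float)


def size_factors(counts: CountMatrix) -> pd.Series:
    """Median-of-ratios per-sample size factors, geometric mean 1.

    Per sample: the median over all-positive genes of count / geometric-mean
    reference, rescaled so the factors have geometric mean 1.
    """
    x = counts.counts.to_numpy(float)
    pos = (x > 0).all(axis=1)
    if not pos.any():
        raise ValueError("no gene expressed in all samples; cannot normalize")
    logx = np.log(x[pos])
    ref = logx.mean(axis=1, keepdims=True)      # log geometric mean per gene
    sf = np.exp(np.median(logx - ref, axis=0))
    sf /= np.exp(np.mean(np.log(sf)))
    return pd.Series(sf, index=counts.counts.columns, name="size_factor")


def normalize_log2(counts: CountMatrix, factors: pd.Series = None,
                   pseudocount: float = 1.0) -> NormalizedMatrix:
    """Elementwise ``log2(count / size_factor + pseudocount)``."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    if factors is None:
        factors = size_factors(counts)
    if (factors <= 0).any():
        raise ValueError("size factors must be positive")
    norm = np.log2(counts.counts / factors.to_numpy(float)[None, :]
                   + pseudocount)
    return NormalizedMatrix(log2=norm, size_factors=factors,
                            pseudocount=pseudocount, samples=counts.samples)


# ---------------------------------------------------------------------------
# Dispersion estimation
# ---------------------------------------------------------------------------

def _design_matrix(samples: pd.DataFrame, condition: np.ndarray) -> np.ndarray:
    """Intercept + replicate dummies + condition indicator."""
    reps = pd.get_dummies(samples["replicate"], drop_first=True)
    X = np.column_stack([np.ones(len(samples)), reps.to_numpy(float),
                         condition.astype(float)])
    return X


def estimate_dispersions(norm_counts: np.ndarray, groups: np.ndarray,
                         prior_df: float = 6.0,
                         n_params: int = None) -> np.ndarray:
    """Trended, shrunken method-of-moments NB dispersions.

    Gene-wise: with within-group means mu_ig, the moment estimator
    ``phi_g = sum((y - mu)^2 - mu) / sum(mu^2)`` (df-corrected).  A trend
    ``phi(mu) = a0 + a1 / mu`` is fitted across genes by least squares on the
    positive estimates, and gene-wise values are shrunk toward the trend on
    the log scale with a weight equivalent to ``prior_df`` residual degrees
    of freedom.
    """
    n_genes, n = norm_counts.shape
    uniq = np.unique(groups)
    mu = np.zeros_like(norm_counts)
    # residual df of the downstream GLM (replicate terms included), not just
    # the group count: under-counting the model's parameters biases the
    # moment estimator low and makes the Wald test anticonservative
    df = n - (n_params if n_params is not None else len(uniq))
    for gval in uniq:
        m = groups == gval
        mu[:, m] = norm_counts[:, m].mean(axis=1, keepdims=True)
    resid2 = (norm_counts - mu) ** 2
    num = resid2.sum(axis=1) * (n / max(df, 1)) - mu.sum(axis=1)
    den = (mu ** 2).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        phi_raw = num / den
    mean_expr = norm_counts.mean(axis=1)

    ok = (phi_raw > 0) & (mean_expr > 0) & np.isfinite(phi_raw)
    floor = 1e-8
    if ok.sum() >= 10:
        A = np.column_stack([np.ones(ok.sum()), 1.0 / mean_expr[ok]])
        coef, *_ = np.linalg.lstsq(A, phi_raw[ok], rcond=None)
        a0, a1 = max(coef[0], floor), max(coef[1], 0.0)
    else:
        a0, a1 = max(np.nanmedian(phi_raw[ok]) if ok.any() else 0.1, floor), 0.0
    with np.errstate(divide="ignore"):
        trend = a0 + a1 / np.where(mean_expr > 0, mean_expr, np.inf)
    trend = np.clip(trend, floor, None)

    # shrink on the log scale toward the trend
    w = df / (df + prior_df)
    phi = np.where(ok, np.exp(w * np.log(np.clip(phi_raw, floor, None))
                              + (1 - w) * np.log(trend)), trend)
    return np.clip(phi, floor, 10.0)


# ---------------------------------------------------------------------------
# Wald test
# ---------------------------------------------------------------------------

def nb_test(counts: CountMatrix, treat_conc: float = None,
            control_conc: float = 0.0,
            factors: pd.Series = None) -> pd.DataFrame:
    """Per-gene NB-GLM Wald test of condition (treatment vs control).

    Fits, for every gene with any nonzero count in the contrast samples, a
    negative-binomial GLM with log link, design ``~ replicate + condition``
    and log size-factor offset.  The two-sided Wald p-value for the condition
    coefficient uses a moderated-t reference whose degrees of freedom are the
    moment-estimator residual df plus the dispersion-shrinkage prior df
    (limma-style): a plain normal reference is mildly anticonservative at 3
    replicates per arm and the raw residual-df t is badly conservative.  BH
    adjustment across tested genes.

    Returns a DataFrame with columns gene_id, log2fc, p, q, is_deg (the flag
    is filled by :func:`call_degs` at the default thresholds).
    """
    samples = counts.samples
    if treat_conc is None:
        treat_conc = float(samples["concentration_uM"].max())
    mask = samples["concentration_uM"].isin([control_conc, treat_conc])
    if mask.sum() < 4:
        raise ValueError("need >= 2 samples per contrast arm")
    sub = samples[mask].reset_index(drop=True)
    cond = (sub["concentration_uM"] == treat_conc).to_numpy()
    if cond.sum() < 2 or (~cond).sum() < 2:
        raise ValueError("need >= 2 samples per contrast arm")

    y_all = counts.counts.loc[:, sub["sample_id"]].to_numpy(float)
    if factors is None:
        factors = size_factors(counts)
    sf = factors.loc[sub["sample_id"]].to_numpy(float)
    offset = np.log(sf)
    X = _design_matrix(sub, cond)

    groups = np.where(cond, 1, 0)
    prior_df = 6.0
    phi = estimate_dispersions(y_all / sf[None, :], groups,
                               prior_df=prior_df)
    # moderated-t reference: the shrunken dispersion carries roughly
    # (moment df + prior df) degrees of freedom, limma-style
    df_mod = (len(sub) - len(np.unique(groups))) + prior_df

    gene_ids = counts.gene_ids.to_numpy()
    n_genes = len(gene_ids)
    lfc = np.full(n_genes, np.nan)
    pvals = np.full(n_genes, np.nan)
    nonzero = y_all.sum(axis=1) > 0

    for gi in np.nonzero(nonzero)[0]:
        y = y_all[gi]
        fam = sm.families.NegativeBinomial(alpha=float(phi[gi]))
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.GLM(y, X, family=fam, offset=offset).fit(maxiter=100)
            beta = res.params[-1]
            se = res.bse[-1]
            if not np.isfinite(beta) or not np.isfinite(se) or se == 0:
                continue
            lfc[gi] = beta / LN2
            pvals[gi] = 2.0 * stats.t.sf(abs(beta / se), df_mod)
        except Exception:
            continue

    tested = np.isfinite(pvals)
    q = np.full(n_genes, np.nan)
    if tested.any():
        q[tested] = multipletests(pvals[tested], method="fdr_bh")[1]
    out = pd.DataFrame({"gene_id": gene_ids, "log2fc": lfc,
                        "p": pvals, "q": q})
    # deterministic report order: by p, ties broken by gene_id
    out = out.sort_values(["p", "gene_id"], kind="mergesort",
                          na_position="last").reset_index(drop=True)
    return call_degs(out)


def call_degs(records: pd.DataFrame, q_cut: float = Q_CUTOFF,
              lfc_cut: float = LFC_CUTOFF) -> pd.DataFrame:
    """Flag records with q < ``q_cut`` and |log2FC| >= ``lfc_cut`` as DEGs."""
    out = records.copy()
    out["is_deg"] = ((out["q"] < q_cut)
                     & (out["log2fc"].abs() >= lfc_cut)).fillna(False)
    return out
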