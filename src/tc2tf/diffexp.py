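"""Per-gene genotype x time linear model with empirical-Bayes moderation.

The model is the saturated cell-means parameterization over (genotype, time)
cells; the quantity of interest at each non-zero time t is the interaction
contrast

    C_t = (I_ko,t - I_ko,0) - (I_wt,t - I_wt,0),

which is zero whenever the stimulus response is identical in both genotypes.
Per-gene residual variances are shrunk toward an ensemble prior (d0, s0^2)
estimated by method of moments on log variances, giving a moderated t with
d + d0 degrees of freedom; p-values are Benjamini-Hochberg adjusted within
each time point and genes pass at adjusted p < alpha.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from tc2tf.preprocess import ExpressionDataset


@dataclass
class LinearFit:
    """Cell means and pooled residual variance per gene.

    ``means`` has a (genotype, time_h) MultiIndex on columns; ``s2`` is the
    pooled within-cell variance with ``df`` residual degrees of freedom
    (identical across genes for a complete design); ``cell_counts`` maps each
    cell to its sample count.
    """

    means: pd.DataFrame
    s2: pd.Series
    df: int
    cell_counts: dict[tuple[str, float], int]


@dataclass
class VariancePrior:
    """Ensemble prior for residual variances: s_g^2 ~ s0^2 * d0 / chi^2_d0."""

    d0: float       # prior degrees of freedom; may be math.inf
    s0_sq: float    # prior variance


def fit_cell_means(dataset: ExpressionDataset) -> LinearFit:
    """Fit the saturated cell-means model row by row.

    Cell means are per-cell sample means; the residual variance pools the
    within-cell sums of squares over all cells, with df = sum(n_cell - 1).
    """
    design = dataset.design
    cells = sorted(set(zip(design["genotype"], design["time_h"])),
                   key=lambda c: (c[0], c[1]))
    columns_of: dict[tuple[str, float], list[str]] = {}
    for gt, t in cells:
        mask = (design["genotype"] == gt) & (design["time_h"] == t)
        cols = design.loc[mask, "sample_id"].tolist()
        if not cols:
            raise ValueError(f"cell (genotype={gt}, time_h={t}) has 0 samples")
        columns_of[(gt, t)] = cols

    X = dataset.values
    means = pd.DataFrame(index=X.index,
                         columns=pd.MultiIndex.from_tuples(
                             cells, names=["genotype", "time_h"]),
                         dtype=float)
    rss = np.zeros(len(X))
    df = 0
    for cell, cols in columns_of.items():
        block = X[cols].to_numpy()
        m = block.mean(axis=1)
        means[cell] = m
        rss += ((block - m[:, None]) ** 2).sum(axis=1)
        df += len(cols) - 1
    if df <= 0:
        raise ValueError("no residual degrees of freedom (all cells have a "
                         "single sample)")
    s2 = pd.Series(rss / df, index=X.index, name="s2")
    counts = {cell: len(cols) for cell, cols in columns_of.items()}
    return LinearFit(means=means, s2=s2, df=df, cell_counts=counts)


def interaction_contrast(fit: LinearFit, t: float
                         ) -> tuple[pd.Series, float]:
    """The genotype x time interaction contrast at time t and its scale.

    Returns (C_t per gene, v_c) where v_c = sum of 1/n over the four cells
    entering the contrast, so var(C_t) = sigma^2 * v_c.
    """
    t = float(t)
    if t == 0:
        raise ValueError("contrast at t=0 is identically zero")
    for cell in [("ko", t), ("ko", 0.0), ("wt", t), ("wt", 0.0)]:
        if cell not in fit.cell_counts:
            raise ValueError(f"cell {cell} not in design")
    c = ((fit.means[("ko", t)] - fit.means[("ko", 0.0)])
         - (fit.means[("wt", t)] - fit.means[("wt", 0.0)]))
    v_c = sum(1.0 / fit.cell_counts[cell]
              for cell in [("ko", t), ("ko", 0.0), ("wt", t), ("wt", 0.0)])
    return c.rename("contrast"), v_c


def estimate_variance_prior(s2: np.ndarray | pd.Series, df: int,
                            tol: float = 1e-8) -> VariancePrior:
    """Method-of-moments fit of (d0, s0^2) from an ensemble of variances.

    Works on e_g = log s_g^2: the excess of var(e) over trigamma(df/2) is
    matched to trigamma(d0/2) by monotone root finding (d0 = inf when the
    excess is at or below tolerance), and s0^2 follows from mean(e) with the
    digamma bias corrections.
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = s2[np.isfinite(s2)]
    if len(s2) < 50:
        raise ValueError("need >= 50 genes to estimate the variance prior")
    if np.all(s2 <= 0):
        raise ValueError("degenerate variance ensemble (all zero)")
    e = np.log(s2[s2 > 0])
    var_e = float(np.var(e, ddof=1))
    excess = var_e - float(special.polygamma(1, df / 2.0))
    mean_e = float(np.mean(e))
    if excess <= tol:
        d0 = math.inf
        log_s0 = mean_e - special.digamma(df / 2.0) + math.log(df / 2.0)
    else:
        # trigamma is strictly decreasing; bracket the root generously
        f = lambda x: special.polygamma(1, x) - excess
        lo, hi = 1e-6, 1e6
        x = optimize.brentq(f, lo, hi)
        d0 = 2.0 * x
        log_s0 = (mean_e + special.digamma(d0 / 2.0)
                  - special.digamma(df / 2.0) + math.log(df / d0))
    return VariancePrior(d0=d0, s0_sq=float(np.exp(log_s0)))


def posterior_variances(fit: LinearFit, prior: VariancePrior) -> pd.Series:
    """Moderated variances: (d0 s0^2 + d s^2) / (d0 + d)."""
    if math.isinf(prior.d0):
        return pd.Series(prior.s0_sq, index=fit.s2.index, name="s2_post")
    s2_post = (prior.d0 * prior.s0_sq + fit.df * fit.s2) / (prior.d0 + fit.df)
    return s2_post.rename("s2_post")


def moderated_stats(fit: LinearFit, t: float,
                    prior: VariancePrior | None = None) -> pd.DataFrame:
    """Moderated t, F = t^2 and two-sided p for the interaction contrast at t.

    With ``prior=None`` the prior is estimated from the fit's variance
    ensemble. A prior with d0 = 0 reproduces the ordinary t exactly; d0 = inf
    uses the normal reference.
    """
    if prior is None:
        prior = estimate_variance_prior(fit.s2.to_numpy(), fit.df)
    contrast, v_c = interaction_contrast(fit, t)
    if prior.d0 == 0:
        s2_post = fit.s2
        df_total = float(fit.df)
    else:
        s2_post = posterior_variances(fit, prior)
        df_total = fit.df + prior.d0
    se = np.sqrt(s2_post * v_c)
    tstat = contrast / se
    if math.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(tstat))
    else:
        p = 2.0 * stats.t.sf(np.abs(tstat), df_total)
    return pd.DataFrame({
        "gene_id": fit.means.index, "time_h": float(t),
        "contrast": contrast.to_numpy(), "s2_post": s2_post.to_numpy(),
        "t": tstat.to_numpy(), "df": df_total, "p": p,
    }).reset_index(drop=True)


def bh_adjust(p: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    q_(i) = min_{j >= i} (p_(j) * m / j), clipped at 1.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be one-dimensional")
    if len(p) == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def select_significant(fit: LinearFit, times: list[float] | None = None,
                       alpha: float = 0.05,
                       prior: VariancePrior | None = None,
                       bh_scope: str = "per_time") -> pd.DataFrame:
    """Interaction statistics at every non-zero time with BH selection.

    BH is applied within each time point's gene ensemble by default
    (``bh_scope='per_time'``) or across all tests (``'global'``). Returns the
    full tidy table with a ``significant`` column (adjusted p < alpha).
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must lie in (0, 1]")
    if bh_scope not in ("per_time", "global"):
        raise ValueError("bh_scope must be 'per_time' or 'global'")
    if times is None:
        times = sorted({t for _, t in fit.means.columns if t != 0})
    if prior is None:
        prior = estimate_variance_prior(fit.s2.to_numpy(), fit.df)
    tables = [moderated_stats(fit, t, prior=prior) for t in times]
    if bh_scope == "per_time":
        for tab in tables:
            tab["q"] = bh_adjust(tab["p"].to_numpy())
        out = pd.concat(tables, ignore_index=True)
    else:
        out = pd.concat(tables, ignore_index=True)
        out["q"] = bh_adjust(out["p"].to_numpy())
    out["significant"] = out["q"] < alpha
    return out
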