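"""Empirical-Bayes moderated two-group differential expression.

The gene-wise pooled variances s2_g (d = n1 + n2 - 2 df each) are shrunk
toward a prior s0^2 with d0 prior df, both estimated by matching the first
two moments of log s2_g to the log chi-square model: if s2_g ~ s0^2 *
F(d, d0) then e_g = log s2_g - psi(d/2) + log(d/2) has mean log s0^2 +
psi(d0/2) - log(d0/2) and excess variance psi'(d0/2) beyond psi'(d/2).
The moderated t uses the posterior variance (d0 s0^2 + d s2_g)/(d0 + d)
with d0 + d degrees of freedom. When the genes' variances show no excess
spread, d0 is infinite, every gene is tested against the pooled common
variance (the average of the gene variances) and the reference becomes
normal; with exactly equal gene variances this collapses to the ordinary
two-sample t.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .containers import ExpressionMatrix, TMEScoreError

__all__ = ["DEGResult", "moderated_t_test", "bh_adjust", "select_degs", "trigamma_inverse"]


@dataclass
class DEGResult:
    """Per-gene DE table plus the fitted variance-prior hyperparameters."""

    table: pd.DataFrame  # gene-indexed: log_fc, t_mod, df_total, p, fdr
    d0: float
    s0_sq: float

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# d0={self.d0!r} s0_sq={self.s0_sq!r}\n")
            self.table.to_csv(fh, sep="\t", index_label="gene")


def trigamma_inverse(x: float, tol: float = 1e-10, max_iter: int = 100) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x <= 0:
        return np.inf
    y = 0.5 + 1.0 / x  # good starting value since trigamma(y) ~ 1/y for large y
    for _ in range(max_iter):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < tol * y:
            break
    return float(y)


def _fit_variance_prior(s2: np.ndarray, d: float) -> tuple[float, float]:
    """Moment-match (d0, s0^2) on log pooled variances with d df each."""
    s2 = s2[s2 > 0]
    if s2.size == 0:
        return np.inf, 1.0
    if s2.size < 2:
        return np.inf, float(np.exp(np.mean(np.log(s2))))
    z = np.log(s2)
    e = z - special.digamma(d / 2.0) + np.log(d / 2.0)
    evar = np.var(e, ddof=1) - special.polygamma(1, d / 2.0)
    if evar <= 0:
        # no excess dispersion: infinite prior df; the common variance is
        # the plain average of the gene variances
        return np.inf, float(np.mean(s2))
    d0 = 2.0 * trigamma_inverse(evar)
    s0_sq = float(np.exp(np.mean(e) + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_sq


def moderated_t_test(expr, groups) -> DEGResult:
    """Moderated two-sample t-test per gene.

    Parameters
    ----------
    expr : ExpressionMatrix (log2 scale) or DataFrame, genes x samples.
    groups : array-like of two labels aligned to the samples.
        ``log_fc`` is mean(second sorted level) - mean(first sorted level).
    """
    if isinstance(expr, ExpressionMatrix):
        values = expr.values
    else:
        values = expr if isinstance(expr, pd.DataFrame) else pd.DataFrame(expr)
    g = pd.Series(np.asarray(groups))
    levels = sorted(g.unique().tolist())
    if len(levels) != 2:
        raise TMEScoreError(f"need exactly two groups, got {levels}")
    mask_b = (g == levels[1]).to_numpy()
    mask_a = ~mask_b
    n1, n2 = int(mask_a.sum()), int(mask_b.sum())
    if n1 < 2 or n2 < 2:
        raise TMEScoreError("both groups need >=2 samples")

    X = values.to_numpy(float)
    m_a = X[:, mask_a].mean(axis=1)
    m_b = X[:, mask_b].mean(axis=1)
    log_fc = m_b - m_a
    d = float(n1 + n2 - 2)
    ss = ((X[:, mask_a] - m_a[:, None]) ** 2).sum(axis=1) + (
        (X[:, mask_b] - m_b[:, None]) ** 2
    ).sum(axis=1)
    s2 = ss / d

    d0, s0_sq = _fit_variance_prior(s2, d)
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)  # complete shrinkage to the prior
        df_total = np.inf
    else:
        s2_post = (d0 * s0_sq + d * s2) / (d0 + d)
        df_total = d0 + d

    denom = np.sqrt(s2_post) * np.sqrt(1.0 / n1 + 1.0 / n2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = np.where(denom > 0, log_fc / denom, 0.0)
    # identical values in both groups: no evidence, not infinite evidence
    degenerate = (s2 == 0) & (log_fc == 0)
    t_mod = np.where(degenerate, 0.0, t_mod)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t_mod))
    else:
        p = 2.0 * stats.t.sf(np.abs(t_mod), df=df_total)
    p = np.where(degenerate, 1.0, p)

    table = pd.DataFrame(
        {
            "log_fc": log_fc,
            "t_mod": t_mod,
            "df_total": df_total,
            "p": p,
            "fdr": bh_adjust(p),
        },
        index=values.index,
    )
    return DEGResult(table=table, d0=d0, s0_sq=s0_sq)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment.

    q_(i) = min_{j >= i} m * p_(j) / j, capped at 1, in the input order.
    """
    p = np.asarray(pvalues, float)
    if p.ndim != 1:
        p = p.ravel()
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or p.min() < 0 or p.max() > 1:
        raise TMEScoreError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranks = np.arange(1, m + 1)
    terms = p[order] * m / ranks
    q_sorted = np.minimum.accumulate(terms[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def select_degs(result: DEGResult, fdr_threshold: float = 0.01) -> list[str]:
    """Genes with fdr < threshold, sorted by |t_mod| descending."""
    tab = result.table
    hits = tab[tab["fdr"] < fdr_threshold]
    hits = hits.reindex(hits["t_mod"].abs().sort_values(ascending=False).index)
    return hits.index.tolist()
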