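"""Immune-cell abundance estimation from bulk expression.

Two complementary routes:

* :class:`NuSVRDeconvolver` — support-vector regression of each bulk sample
  on a reference signature matrix (genes x cell types, linear scale),
  returning per-sample cell-type fractions with fit quality and a
  permutation p-value. This is the classic nu-SVR deconvolution scheme used
  with LM22-style leukocyte references.
* :func:`ssgsea_scores` — single-sample gene-set enrichment (rank-weighted
  ECDF difference), used both for set-based cell scoring and for the
  immune/stromal summary in :func:`estimate_scores`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.svm import NuSVR

from .containers import ExpressionMatrix, GeneSetCollection, TMEScoreError, warn

__all__ = [
    "CellFractions",
    "NuSVRDeconvolver",
    "nusvr_deconvolve",
    "read_signature",
    "ssgsea_scores",
    "estimate_scores",
]


@dataclass
class CellFractions:
    """Samples x cell-types deconvolution output with per-sample QC."""

    fractions: pd.DataFrame  # samples x cell types
    rmse: pd.Series
    pearson_r: pd.Series
    p_value: pd.Series
    n_permutations: int
    params: dict = field(default_factory=dict)

    @property
    def sample_ids(self) -> pd.Index:
        return self.fractions.index

    @property
    def cell_types(self) -> pd.Index:
        return self.fractions.columns

    def to_tsv(self, path) -> None:
        out = self.fractions.copy()
        out["rmse"] = self.rmse
        out["pearson_r"] = self.pearson_r
        out["p_value"] = self.p_value
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        out.to_csv(path, sep="\t", index_label="sample_id")
        sidecar = dict(self.params, n_permutations=self.n_permutations)
        Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2))


def read_signature(path) -> pd.DataFrame:
    """Read a genes x cell-types reference signature matrix (TSV)."""
    sig = pd.read_csv(path, sep="\t", index_col=0)
    _validate_signature(sig)
    return sig


def _validate_signature(sig: pd.DataFrame) -> None:
    if sig.shape[1] < 2:
        raise TMEScoreError("signature matrix needs >=2 cell types")
    arr = sig.to_numpy(float)
    if not np.all(np.isfinite(arr)) or arr.min() < 0:
        raise TMEScoreError("signature values must be finite and non-negative")
    if (arr.sum(axis=1) == 0).any():
        raise TMEScoreError("signature matrix contains all-zero gene rows")
    if sig.index.has_duplicates or sig.columns.has_duplicates:
        raise TMEScoreError("signature gene ids / cell types must be unique")


class NuSVRDeconvolver(BaseEstimator, TransformerMixin):
    """nu-SVR bulk deconvolution against a cell-type reference.

    Per sample the mixture is restricted to genes shared with the reference,
    the reference is standardised globally (one mean/SD over all its
    entries, which preserves proportionality of the regression weights to
    the underlying fractions) and the mixture column by its own mean/SD. A
    linear nu-SVR is fit for each nu on the grid; negative coefficients are
    clipped to zero and renormalised to a simplex; the nu minimising the
    reconstruction RMSE wins (ties toward smaller nu). Significance comes
    from a shared permutation null: gene-permuted mixture columns are fit
    the same way and the p-value is the fraction of null Pearson r at or
    above the observed one.

    Parameters
    ----------
    nu_grid : sequence of float, default (0.25, 0.5, 0.75)
    n_permutations : int, default 1000
    C : float, default 1.0
        Soft-margin constant of the nu-SVR.
    random_state : int, default 0
    """

    def __init__(self, nu_grid=(0.25, 0.5, 0.75), n_permutations=1000, C=1.0, random_state=0):
        self.nu_grid = nu_grid
        self.n_permutations = n_permutations
        self.C = C
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y=None) -> "NuSVRDeconvolver":
        """Store the reference signature matrix (genes x cell types)."""
        sig = X if isinstance(X, pd.DataFrame) else pd.DataFrame(X)
        _validate_signature(sig)
        self.signature_ = sig.astype(float)
        return self

    def _fit_one(self, Xz: np.ndarray, yz: np.ndarray):
        """Return (fractions, rmse, r) for one standardised mixture."""
        best = None
        for nu in self.nu_grid:
            model = NuSVR(kernel="linear", nu=nu, C=self.C)
            model.fit(Xz, yz)
            w = model.coef_.ravel().copy()
            w[w < 0] = 0.0
            if w.sum() <= 0:
                continue
            f = w / w.sum()
            recon = Xz @ f
            rmse = float(np.sqrt(np.mean((recon - yz) ** 2)))
            r = float(np.corrcoef(recon, yz)[0, 1])
            if best is None or rmse < best[1]:  # strict: ties keep smaller nu
                best = (f, rmse, r)
        return best

    def transform(self, X) -> CellFractions:
        """Deconvolve a linear-scale mixture matrix (genes x samples)."""
        if isinstance(X, ExpressionMatrix):
            if X.scale != "linear":
                raise TMEScoreError("deconvolution expects linear-scale mixtures")
            mix = X.values
        else:
            mix = X if isinstance(X, pd.DataFrame) else pd.DataFrame(X)
        sig = self.signature_
        shared = sig.index.intersection(mix.index)
        coverage = len(shared) / sig.shape[0]
        if coverage < 0.5:
            raise TMEScoreError(
                f"only {len(shared)}/{sig.shape[0]} ({coverage:.0%}) signature genes "
                "present in the mixture (<50%)"
            )
        if coverage < 0.8:
            warn(f"signature gene coverage is {coverage:.0%} (<80%)")
        Xs = sig.loc[shared].to_numpy(float)
        Xz = (Xs - Xs.mean()) / Xs.std(ddof=1)
        M = mix.loc[shared].to_numpy(float)

        n_samples = M.shape[1]
        k = sig.shape[1]
        fractions = np.zeros((n_samples, k))
        rmse = np.full(n_samples, np.nan)
        rvals = np.full(n_samples, np.nan)
        flagged = []
        for j in range(n_samples):
            y = M[:, j]
            sd = y.std(ddof=1)
            if sd == 0:
                flagged.append(j)
                continue
            yz = (y - y.mean()) / sd
            fit = self._fit_one(Xz, yz)
            if fit is None:
                flagged.append(j)
                continue
            fractions[j], rmse[j], rvals[j] = fit
        if flagged:
            warn(f"{len(flagged)} sample(s) had no positive coefficients; zero rows flagged")

        rng = np.random.default_rng(self.random_state)
        null_r = np.empty(self.n_permutations)
        for b in range(self.n_permutations):
            src = M[:, rng.integers(n_samples)]
            perm = rng.permutation(src)
            sd = perm.std(ddof=1)
            if sd == 0:
                null_r[b] = 1.0
                continue
            fit = self._fit_one(Xz, (perm - perm.mean()) / sd)
            null_r[b] = fit[2] if fit is not None else -np.inf
        if self.n_permutations > 0:
            pvals = np.array([np.mean(null_r >= r) if np.isfinite(r) else 1.0 for r in rvals])
        else:
            pvals = np.full(n_samples, np.nan)
        pvals = np.where(np.isnan(rvals), 1.0, pvals)

        samples = mix.columns
        return CellFractions(
            fractions=pd.DataFrame(fractions, index=samples, columns=sig.columns),
            rmse=pd.Series(rmse, index=samples),
            pearson_r=pd.Series(rvals, index=samples),
            p_value=pd.Series(pvals, index=samples),
            n_permutations=self.n_permutations,
            params={"nu_grid": list(self.nu_grid), "C": self.C, "seed": self.random_state},
        )


def nusvr_deconvolve(
    mixture: ExpressionMatrix,
    sig: pd.DataFrame,
    nu_grid=(0.25, 0.5, 0.75),
    n_permutations: int = 1000,
    seed: int = 0,
) -> CellFractions:
    """Functional wrapper over :class:`NuSVRDeconvolver`."""
    est = NuSVRDeconvolver(nu_grid=nu_grid, n_permutations=n_permutations, random_state=seed)
    return est.fit(sig).transform(mixture)


# ---------------------------------------------------------------------------
# ssGSEA and immune/stromal summary scores
# ---------------------------------------------------------------------------

def _ssgsea_one(ranks: np.ndarray, in_set: np.ndarray, alpha: float) -> float:
    """Enrichment of one set in one sample from the gene ranks.

    Genes are walked in decreasing-rank order; the score is the sum over
    positions of (cumulative rank^alpha-weighted hit mass - cumulative
    uniform miss mass).
    """
    order = np.argsort(-ranks, kind="mergesort")
    hit = in_set[order]
    w = np.abs(ranks[order]) ** alpha
    hit_w = np.where(hit, w, 0.0)
    denom_hit = hit_w.sum()
    if denom_hit == 0:
        return 0.0
    p_hit = np.cumsum(hit_w) / denom_hit
    n_miss = len(ranks) - int(in_set.sum())
    if n_miss == 0:
        p_miss = np.zeros(len(ranks))
    else:
        p_miss = np.cumsum(~hit) / n_miss
    return float(np.sum(p_hit - p_miss))


def ssgsea_scores(
    expr: ExpressionMatrix,
    sets: GeneSetCollection,
    alpha: float = 0.25,
    rescale: bool = False,
) -> pd.DataFrame:
    """Single-sample gene-set enrichment scores (samples x sets).

    Ranks are computed within each sample (average ranks for ties), so the
    score is invariant under any strictly increasing transform of a
    sample's expression. ``rescale=True`` divides all scores by the global
    (max - min) across the matrix, a normalised variant used by some tools.
    The result carries ``.attrs['method'] = 'ssgsea'``.
    """
    genes = expr.gene_ids
    gene_pos = {g: i for i, g in enumerate(genes)}
    memberships = {}
    for name, members in sets.items():
        mask = np.zeros(len(genes), bool)
        idx = [gene_pos[g] for g in members if g in gene_pos]
        if not idx:
            raise TMEScoreError(f"gene set {name!r} has no members in the expression matrix")
        mask[idx] = True
        memberships[name] = mask

    X = expr.values.to_numpy(float)
    out = np.empty((expr.n_samples, len(memberships)))
    for j in range(expr.n_samples):
        ranks = rankdata(X[:, j])
        for si, mask in enumerate(memberships.values()):
            out[j, si] = _ssgsea_one(ranks, mask, alpha)
    result = pd.DataFrame(out, index=expr.sample_ids, columns=list(memberships))
    if rescale:
        span = result.to_numpy().max() - result.to_numpy().min()
        if span > 0:
            result = result / span
    result.attrs["method"] = "ssgsea"
    return result


def estimate_scores(
    expr: ExpressionMatrix,
    immune_set: list[str],
    stromal_set: list[str],
    alpha: float = 0.25,
) -> pd.DataFrame:
    """Immune/stromal infiltration summary (ESTIMATE-style).

    ImmuneScore and StromalScore are ssGSEA enrichments of the two sets;
    ESTIMATEScore is their per-sample sum.
    """
    if set(immune_set) & set(stromal_set):
        warn("immune and stromal sets overlap; scores computed anyway")
    sets = GeneSetCollection({"ImmuneScore": list(immune_set), "StromalScore": list(stromal_set)})
    scores = ssgsea_scores(expr, sets, alpha=alpha)
    scores["ESTIMATEScore"] = scores["ImmuneScore"] + scores["StromalScore"]
    scores.attrs["method"] = "estimate"
    return scores
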