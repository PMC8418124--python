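"""TME-score construction: SVM-RFE signature selection, gene-cluster PCA
and the oriented principal-component score.

The final per-sample score is

    TME-score = sum_i PC1_i - sum_j PC1_j

where the sums run over gene clusters whose oriented first-principal-
component sample score associates with increased hazard (HR > 1, the "i"
set) or decreased hazard (HR < 1, the "j" set) in a univariate Cox fit.
Each cluster's PC1 is oriented so that it correlates positively with the
cluster's mean z-scored expression, removing PCA's sign ambiguity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .clustering import consensus_cluster
from .containers import ExpressionMatrix, TMEScoreError, warn
from .survival import SurvivalData, cox_fit, optimal_cutpoint

__all__ = [
    "svm_rfe_rank",
    "select_signature",
    "cluster_signature_genes",
    "PC1Fit",
    "fit_pc1",
    "assign_direction_sets",
    "TMEScoreModel",
    "tme_score",
    "cyt_score",
    "gep_score",
    "TMEScorer",
]


def _expr_frame(expr) -> pd.DataFrame:
    if isinstance(expr, ExpressionMatrix):
        return expr.values
    return expr if isinstance(expr, pd.DataFrame) else pd.DataFrame(expr)


# ---------------------------------------------------------------------------
# SVM-RFE
# ---------------------------------------------------------------------------

def svm_rfe_rank(
    X: pd.DataFrame,
    labels,
    step_fraction: float = 0.1,
    C: float = 1.0,
    seed: int = 0,
) -> list[str]:
    """Recursive feature elimination with a linear soft-margin SVM.

    ``X`` is samples x genes. Each round trains an SVM on the surviving
    genes, ranks them by squared weight and eliminates the lowest
    ``ceil(step_fraction * remaining)`` (one at a time once 20 or fewer
    remain). Returns genes from rank 1 (eliminated last) downward.
    """
    X = X if isinstance(X, pd.DataFrame) else pd.DataFrame(X)
    y = np.asarray(labels)
    if len(np.unique(y)) != 2:
        raise TMEScoreError("svm_rfe_rank needs exactly two classes")
    mu = X.mean(axis=0)
    sd = X.std(axis=0).replace(0.0, 1.0)
    Z = (X - mu) / sd

    remaining = list(Z.columns)
    eliminated: list[str] = []
    while len(remaining) > 1:
        clf = SVC(kernel="linear", C=C)
        clf.fit(Z[remaining].to_numpy(), y)
        w2 = (clf.coef_.ravel()) ** 2
        n_drop = 1 if len(remaining) <= 20 else int(np.ceil(step_fraction * len(remaining)))
        n_drop = min(n_drop, len(remaining) - 1)
        drop_idx = np.argsort(w2, kind="mergesort")[:n_drop]
        for idx in sorted(drop_idx, reverse=True):
            eliminated.append(remaining.pop(idx))
    eliminated.extend(remaining)
    return eliminated[::-1]  # rank 1 first


def select_signature(
    ranked: list[str],
    X: pd.DataFrame,
    labels,
    candidate_sizes=None,
    cv_folds: int = 5,
    C: float = 1.0,
    seed: int = 0,
) -> tuple[list[str], pd.DataFrame]:
    """Pick the top-m prefix of an RFE ranking maximising CV accuracy.

    Stratified ``cv_folds``-fold accuracy of a linear SVM is estimated for
    each candidate size; ties go to the smaller size. Returns the selected
    gene list and the size/accuracy table.
    """
    X = X if isinstance(X, pd.DataFrame) else pd.DataFrame(X)
    y = np.asarray(labels)
    if candidate_sizes is None:
        candidate_sizes = [m for m in range(10, 301, 10) if m <= len(ranked)] or [len(ranked)]
    candidate_sizes = sorted(set(int(m) for m in candidate_sizes))
    if candidate_sizes[0] < 1 or candidate_sizes[-1] > len(ranked):
        raise TMEScoreError("candidate sizes must lie within [1, len(ranked)]")

    counts = pd.Series(y).value_counts()
    folds = cv_folds
    if counts.min() < folds:
        folds = max(2, int(counts.min()))
        warn(f"select_signature: smallest class has {counts.min()} samples; refolded to {folds} folds")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(np.zeros(len(y)), y))

    rows = []
    best_m, best_acc = None, -1.0
    for m in candidate_sizes:
        genes = ranked[:m]
        Xm = X[genes].to_numpy()
        correct = 0
        for train, test in splits:
            clf = SVC(kernel="linear", C=C)
            clf.fit(Xm[train], y[train])
            correct += int((clf.predict(Xm[test]) == y[test]).sum())
        acc = correct / len(y)
        rows.append({"size": m, "cv_accuracy": acc})
        if acc > best_acc:  # strict: ties keep the smaller earlier size
            best_m, best_acc = m, acc
    return list(ranked[:best_m]), pd.DataFrame(rows).set_index("size")


# ---------------------------------------------------------------------------
# Gene clusters, directions and PC1
# ---------------------------------------------------------------------------

def cluster_signature_genes(
    expr,
    k_values=(2, 3, 4, 5, 6),
    n_resamples: int = 50,
    seed: int = 0,
):
    """Consensus-cluster the signature genes (1 - Pearson, hierarchical).

    ``expr`` is genes x samples over the signature genes. Returns
    (per-gene labels Series, ConsensusResult).
    """
    values = _expr_frame(expr)
    if values.shape[0] < 2 and max(k_values) > 1:
        raise TMEScoreError("need >=2 signature genes to cluster")
    res = consensus_cluster(
        values.to_numpy(float),
        k_values=k_values,
        n_resamples=n_resamples,
        base="hierarchical",
        distance="one_minus_pearson",
        seed=seed,
    )
    labels = pd.Series(res.labels[res.selected_k], index=values.index)
    return labels, res


@dataclass
class PC1Fit:
    """Oriented first principal axis over one gene cluster."""

    genes: list[str]
    loadings: np.ndarray        # unit vector, orientation applied
    mean: np.ndarray            # training per-gene mean
    sd: np.ndarray              # training per-gene SD
    explained_ratio: float

    def score(self, values: pd.DataFrame, standardize: str = "cohort") -> pd.Series:
        """PC1 sample scores for a genes x samples matrix.

        ``standardize='cohort'`` re-z-scores genes within the given matrix
        (the default when projecting an external cohort); ``'train'`` uses
        the stored training mean/SD.
        """
        present = [g for g in self.genes if g in values.index]
        missing = [g for g in self.genes if g not in values.index]
        w = self.loadings
        mean, sd = self.mean, self.sd
        if missing:
            keep = np.array([g in values.index for g in self.genes])
            w = self.loadings[keep]
            norm = np.linalg.norm(w)
            if norm == 0:
                raise TMEScoreError("all informative loadings missing for a gene cluster")
            w = w / norm
            mean, sd = self.mean[keep], self.sd[keep]
            warn(f"PC1 projection: {len(missing)} gene(s) missing; loadings renormalised")
        sub = values.loc[present].to_numpy(float)
        if standardize == "cohort":
            mu = sub.mean(axis=1)
            sigma = sub.std(axis=1, ddof=1)
            sigma[sigma == 0] = 1.0
        elif standardize == "train":
            mu, sigma = mean, sd
        else:
            raise TMEScoreError(f"unknown standardize mode {standardize!r}")
        Z = (sub - mu[:, None]) / sigma[:, None]
        return pd.Series(Z.T @ w, index=values.columns)


def fit_pc1(expr) -> PC1Fit:
    """Fit the oriented PC1 of one gene cluster (genes x samples).

    Genes are z-scored over the training samples; the first right singular
    vector of the samples x genes matrix gives the loadings, sign-fixed so
    the sample score correlates positively with the cluster's mean z-scored
    expression. Zero-variance genes are dropped with a warning.
    """
    values = _expr_frame(expr)
    if values.shape[1] < 3:
        raise TMEScoreError("fit_pc1 needs >=3 samples")
    arr = values.to_numpy(float)
    sd = arr.std(axis=1, ddof=1)
    keep = sd > 0
    if not keep.all():
        warn(f"fit_pc1: dropped {int((~keep).sum())} zero-variance gene(s)")
    if not keep.any():
        raise TMEScoreError("all genes have zero variance")
    arr = arr[keep]
    genes = [g for g, k in zip(values.index, keep) if k]
    mu = arr.mean(axis=1)
    sigma = arr.std(axis=1, ddof=1)
    Z = ((arr - mu[:, None]) / sigma[:, None]).T  # samples x genes

    if Z.shape[1] == 1:
        loadings = np.array([1.0])
        explained = 1.0
    else:
        _, s, Vt = np.linalg.svd(Z, full_matrices=False)
        loadings = Vt[0]
        explained = float(s[0] ** 2 / (s**2).sum())
    score = Z @ loadings
    orient = np.corrcoef(score, Z.mean(axis=1))[0, 1] if Z.shape[1] > 1 else 1.0
    if np.isfinite(orient) and orient < 0:
        loadings = -loadings
    return PC1Fit(genes=genes, loadings=loadings, mean=mu, sd=sigma, explained_ratio=explained)


def assign_direction_sets(
    cluster_labels: pd.Series,
    expr,
    surv: SurvivalData,
) -> tuple[dict[str, str], dict[str, PC1Fit], pd.DataFrame]:
    """Fit each gene cluster's PC1 and call its hazard direction.

    Returns (direction per cluster in {"i", "j"}, PC1 fits, Cox summary).
    A cluster whose PC1 score has HR > 1 goes to "i"; HR <= 1 (including
    exactly 1) to "j".
    """
    values = _expr_frame(expr)
    directions: dict[str, str] = {}
    pc1_fits: dict[str, PC1Fit] = {}
    rows = []
    for cl in sorted(pd.Series(cluster_labels).unique()):
        name = str(cl)
        genes = cluster_labels.index[cluster_labels == cl].tolist()
        fit = fit_pc1(values.loc[genes])
        score = fit.score(values, standardize="train")
        cox = cox_fit(surv, score.to_numpy()[:, None])
        hr = float(cox.summary["hr"].iloc[0])
        directions[name] = "i" if hr > 1.0 else "j"
        pc1_fits[name] = fit
        rows.append({"cluster": name, "n_genes": len(genes), "hr": hr,
                     "p": float(cox.summary["p"].iloc[0]), "direction": directions[name]})
    if len(set(directions.values())) == 1:
        warn(f"all gene clusters assigned direction {next(iter(directions.values()))!r}; "
             "the other direction set is empty")
    return directions, pc1_fits, pd.DataFrame(rows).set_index("cluster")


# ---------------------------------------------------------------------------
# The fitted model and scoring
# ---------------------------------------------------------------------------

@dataclass
class TMEScoreModel:
    """Serializable fitted TME scorer.

    ``gene_clusters`` partitions ``signature_genes``; each cluster carries
    an oriented PC1 and a hazard direction. ``standardize`` controls how an
    external cohort is z-scored before projection ("cohort": within the new
    cohort, the default; "train": with stored training parameters).
    """

    signature_genes: list[str]
    gene_clusters: dict[str, list[str]]
    direction: dict[str, str]
    pc1: dict[str, PC1Fit]
    cutoff: float | None = None
    standardize: str = "cohort"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        clustered = [g for genes in self.gene_clusters.values() for g in genes]
        if sorted(clustered) != sorted(self.signature_genes):
            raise TMEScoreError("gene clusters must partition the signature genes")
        if not self.gene_clusters:
            raise TMEScoreError("model needs at least one gene cluster")
        for cl in self.gene_clusters:
            if self.direction.get(cl) not in ("i", "j"):
                raise TMEScoreError(f"cluster {cl!r} lacks a direction in {{'i','j'}}")

    def to_json(self, path=None) -> str:
        payload = {
            "signature_genes": self.signature_genes,
            "gene_clusters": self.gene_clusters,
            "direction": self.direction,
            "pc1": {
                cl: {
                    "genes": fit.genes,
                    "loadings": fit.loadings.tolist(),
                    "mean": fit.mean.tolist(),
                    "sd": fit.sd.tolist(),
                    "explained_ratio": fit.explained_ratio,
                }
                for cl, fit in self.pc1.items()
            },
            "cutoff": self.cutoff,
            "standardize": self.standardize,
            "provenance": self.provenance,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).parent.mkdir(parents=True, exist_ok=True)
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "TMEScoreModel":
        if isinstance(source, Path) or (
            isinstance(source, str) and not source.lstrip().startswith("{")
        ):
            payload = json.loads(Path(source).read_text())
        else:
            payload = json.loads(source)
        pc1 = {
            cl: PC1Fit(
                genes=rec["genes"],
                loadings=np.array(rec["loadings"], float),
                mean=np.array(rec["mean"], float),
                sd=np.array(rec["sd"], float),
                explained_ratio=rec["explained_ratio"],
            )
            for cl, rec in payload["pc1"].items()
        }
        return cls(
            signature_genes=payload["signature_genes"],
            gene_clusters=payload["gene_clusters"],
            direction=payload["direction"],
            pc1=pc1,
            cutoff=payload["cutoff"],
            standardize=payload["standardize"],
            provenance=payload.get("provenance", {}),
        )


def tme_score(expr, model: TMEScoreModel, standardize: str | None = None) -> pd.DataFrame:
    """Score samples with a fitted model.

    Returns a frame indexed by sample id with ``tme_score``, ``group``
    (high/low against the model cutoff; absent if the model has none) and
    one ``PC1_<cluster>`` column per gene cluster. Requires >= 80% of the
    signature genes in the input; missing genes' loadings are dropped and
    renormalised with a warning.
    """
    values = _expr_frame(expr)
    present = [g for g in model.signature_genes if g in values.index]
    coverage = len(present) / len(model.signature_genes)
    if coverage < 0.8:
        missing = [g for g in model.signature_genes if g not in values.index]
        raise TMEScoreError(
            f"signature coverage {coverage:.0%} < 80%; missing genes: {missing[:10]}"
            + ("..." if len(missing) > 10 else "")
        )
    mode = standardize or model.standardize
    out = pd.DataFrame(index=values.columns)
    total = pd.Series(0.0, index=values.columns)
    for cl, fit in model.pc1.items():
        s = fit.score(values, standardize=mode)
        out[f"PC1_{cl}"] = s
        total = total + s if model.direction[cl] == "i" else total - s
    out.insert(0, "tme_score", total)
    if model.cutoff is not None:
        out.insert(1, "group", np.where(total > model.cutoff, "high", "low"))
    return out


def cyt_score(expr, markers=("GZMA", "PRF1"), pseudocount: float = 0.01) -> pd.DataFrame:
    """Cytolytic activity: geometric mean of the two cytolytic markers.

    Expects linear (TPM-like) expression; a small pseudocount keeps zero
    counts finite.
    """
    if isinstance(expr, ExpressionMatrix) and expr.scale != "linear":
        raise TMEScoreError("cyt_score expects linear-scale expression")
    values = _expr_frame(expr)
    for mk in markers:
        if mk not in values.index:
            raise TMEScoreError(f"cytolytic marker {mk!r} absent from the expression matrix")
    logs = np.log(values.loc[list(markers)].to_numpy(float) + pseudocount)
    out = pd.DataFrame({"CYT": np.exp(logs.mean(axis=0))}, index=values.columns)
    out.attrs["method"] = "cyt"
    return out


def gep_score(expr, gep_genes, max_missing: int = 0) -> pd.DataFrame:
    """T-cell-inflamed gene-expression profile: mean log2 expression of the
    18-gene panel (unweighted)."""
    if isinstance(expr, ExpressionMatrix) and expr.scale != "log2":
        raise TMEScoreError("gep_score expects log2-scale expression")
    values = _expr_frame(expr)
    gep_genes = list(gep_genes)
    missing = [g for g in gep_genes if g not in values.index]
    if len(missing) > max_missing:
        raise TMEScoreError(
            f"{len(missing)} of {len(gep_genes)} GEP genes missing "
            f"(tolerance {max_missing}): {missing}"
        )
    present = [g for g in gep_genes if g in values.index]
    out = pd.DataFrame({"GEP": values.loc[present].mean(axis=0)}, index=values.columns)
    out.attrs["method"] = "gep"
    return out


# ---------------------------------------------------------------------------
# Estimator
# ---------------------------------------------------------------------------

class TMEScorer(BaseEstimator):
    """End-to-end TME-score learner (sklearn-style).

    ``fit`` takes log2-scale expression (samples x genes DataFrame), a
    survival table and per-sample TME-phenotype labels, then runs:
    moderated DE between the two phenotypes -> univariate Cox screen ->
    top-``top_pool`` candidate pool -> consensus clustering of patients on
    the pool (the two "TME gene clusters") -> SVM-RFE ranking against those
    cluster labels -> CV-accuracy signature-size selection -> gene-side
    consensus clusters -> per-cluster PC1 with hazard directions -> TME
    score and a maximally selected survival cutoff.

    Parameters
    ----------
    deg_fdr : float, default 0.01
        BH-adjusted p threshold for DEGs.
    screen_p : float, default 0.05
        Univariate Cox screening threshold ("representative" DEGs).
    top_pool : int, default 300
        Size of the candidate pool handed to SVM-RFE.
    candidate_sizes : sequence of int, optional
        Signature sizes scanned for CV accuracy (default 10..300 step 10).
    gene_k_values : sequence of int, default (2, 3, 4, 5, 6)
        k scanned for the gene-side consensus clustering.
    consensus_resamples : int, default 50
        Resamples for both consensus clusterings inside fit.
    pooled_direction_pca : bool, default False
        If set, refit one PC1 per pooled direction set (i and j) instead of
        per gene cluster.
    cutpoint_minprop : float, default 0.1
    rfe_step : float, default 0.1
    cv_folds : int, default 5
    random_state : int, default 0
    """

    def __init__(
        self,
        deg_fdr: float = 0.01,
        screen_p: float = 0.05,
        top_pool: int = 300,
        candidate_sizes=None,
        gene_k_values=(2, 3, 4, 5, 6),
        consensus_resamples: int = 50,
        pooled_direction_pca: bool = False,
        cutpoint_minprop: float = 0.1,
        rfe_step: float = 0.1,
        cv_folds: int = 5,
        random_state: int = 0,
    ):
        self.deg_fdr = deg_fdr
        self.screen_p = screen_p
        self.top_pool = top_pool
        self.candidate_sizes = candidate_sizes
        self.gene_k_values = gene_k_values
        self.consensus_resamples = consensus_resamples
        self.pooled_direction_pca = pooled_direction_pca
        self.cutpoint_minprop = cutpoint_minprop
        self.rfe_step = rfe_step
        self.cv_folds = cv_folds
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y, phenotype=None) -> "TMEScorer":
        from .de import moderated_t_test, select_degs  # local import avoids cycle at module load

        X = X if isinstance(X, pd.DataFrame) else pd.DataFrame(X)
        if phenotype is None:
            raise TMEScoreError("TMEScorer.fit requires per-sample phenotype labels")
        phenotype = np.asarray(phenotype)
        surv = y if isinstance(y, SurvivalData) else SurvivalData(
            np.asarray(y["os_time"], float), np.asarray(y["os_event"], int)
        )
        if len(surv) != X.shape[0]:
            raise TMEScoreError("survival data must align with samples")
        seed = int(self.random_state)

        # 1) DEGs between the two TME phenotypes
        deg_res = moderated_t_test(X.T, phenotype)
        degs = select_degs(deg_res, self.deg_fdr)
        if len(degs) < 10:
            raise TMEScoreError(f"only {len(degs)} DEGs at FDR {self.deg_fdr}; cannot build a signature")
        self.deg_result_ = deg_res
        self.degs_ = degs

        # 2) univariate Cox screen (per-SD hazard ratios)
        from .survival import univariate_screen as _screen

        screen = _screen(X[degs].T, surv, threshold=self.screen_p)
        representative = screen.index[screen["representative"]].tolist()
        if len(representative) < 10:
            warn("fewer than 10 representative DEGs; falling back to the full DEG list")
            representative = degs
        self.screen_table_ = screen

        # 3) candidate pool: top |t_mod| among representative DEGs
        pool = [g for g in degs if g in set(representative)][: self.top_pool]
        self.pool_ = pool

        # 4) patient-side "TME gene clusters" on the pool
        pool_z = (X[pool] - X[pool].mean()) / X[pool].std().replace(0.0, 1.0)
        gene_cluster_res = consensus_cluster(
            pool_z.to_numpy(float), k_values=(2,),
            n_resamples=self.consensus_resamples, base="pam",
            distance="euclidean", seed=seed + 1,
        )
        sample_gene_clusters = gene_cluster_res.labels[2]
        self.sample_gene_clusters_ = pd.Series(sample_gene_clusters, index=X.index)

        # 5) SVM-RFE + size selection against the gene-cluster labels
        ranked = svm_rfe_rank(X[pool], sample_gene_clusters, step_fraction=self.rfe_step, seed=seed + 2)
        signature, acc = select_signature(
            ranked, X[pool], sample_gene_clusters,
            candidate_sizes=self.candidate_sizes, cv_folds=self.cv_folds, seed=seed + 3,
        )
        self.ranking_ = ranked
        self.accuracy_table_ = acc
        self.signature_genes_ = signature

        # 6) gene-side clusters, directions, PC1
        expr_sig = X[signature].T  # genes x samples
        labels, gene_side_res = cluster_signature_genes(
            expr_sig, k_values=self.gene_k_values,
            n_resamples=self.consensus_resamples, seed=seed + 4,
        )
        directions, pc1_fits, direction_table = assign_direction_sets(labels, expr_sig, surv)
        if self.pooled_direction_pca:
            pooled_labels = pd.Series(
                [directions[str(labels[g])] for g in labels.index], index=labels.index
            )
            directions, pc1_fits, direction_table = assign_direction_sets(
                pooled_labels, expr_sig, surv
            )
            labels = pooled_labels
        self.gene_cluster_labels_ = labels
        self.direction_table_ = direction_table

        clusters = {str(cl): labels.index[labels == cl].tolist() for cl in sorted(labels.unique())}
        model = TMEScoreModel(
            signature_genes=signature,
            gene_clusters=clusters,
            direction=directions,
            pc1=pc1_fits,
            cutoff=None,
            standardize="cohort",
            provenance={
                "seed": seed, "deg_fdr": self.deg_fdr, "screen_p": self.screen_p,
                "top_pool": self.top_pool, "n_degs": len(degs),
                "n_representative": len(representative),
                "gene_side_k": int(gene_side_res.selected_k),
            },
        )

        # 7) training scores and survival-based dichotomisation
        scores = tme_score(expr_sig, model, standardize="train")
        cut = optimal_cutpoint(
            scores["tme_score"].to_numpy(), surv, minprop=self.cutpoint_minprop
        )
        model.cutoff = cut.cutoff
        self.cutpoint_ = cut
        self.model_ = model
        self.scores_ = tme_score(expr_sig, model, standardize="train")
        return self

    def predict(self, X: pd.DataFrame) -> pd.Series:
        """Per-sample TME score for new samples (samples x genes)."""
        X = X if isinstance(X, pd.DataFrame) else pd.DataFrame(X)
        return tme_score(X.T, self.model_)["tme_score"]

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        X = X if isinstance(X, pd.DataFrame) else pd.DataFrame(X)
        return tme_score(X.T, self.model_)

    def predict_group(self, X: pd.DataFrame) -> pd.Series:
        return self.transform(X)["group"]
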