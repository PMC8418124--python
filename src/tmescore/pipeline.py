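"""Discovery-pipeline orchestration with reproducible run records.

``run_discovery`` executes the full chain — simulate/load -> preprocess ->
deconvolve -> consensus-PAM phenotypes -> moderated DE -> Cox screen ->
SVM-RFE signature -> directions/PC1 -> TME score -> survival cutoff — and
writes every stage's intermediates, parameters and seeds to the run
directory. ``run_apply`` projects a fitted model onto a new cohort.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .batch import batch_correct
from .clustering import ConsensusCluster
from .containers import ClinicalTable, ExpressionMatrix, TMEScoreError, warn
from .deconvolution import NuSVRDeconvolver, read_signature
from .io import load_dataset
from .preprocess import fpkm_to_tpm, log2_transform
from .signature import TMEScoreModel, TMEScorer, tme_score
from .survival import SurvivalData, cox_fit, logrank_test, optimal_cutpoint, roc_auc
from .synthetic import SimulationConfig, generate_cohort, generate_reference, truth_metrics

__all__ = ["PipelineConfig", "DiscoveryResult", "StageError", "run_discovery", "run_apply"]


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Everything a discovery run needs, with full seed capture."""

    # inputs: either a simulation or file paths
    simulation: SimulationConfig | None = None
    expression_path: str | None = None
    clinical_path: str | None = None
    signature_path: str | None = None
    expression_scale: str = "linear"   # scale of the input file (linear FPKM/TPM)

    # preprocessing
    tpm_rescale: bool = True
    log2_pseudocount: float = 1.0
    apply_batch_correction: bool = True

    # deconvolution
    nu_grid: tuple = (0.25, 0.5, 0.75)
    n_permutations: int = 1000

    # phenotype consensus clustering
    k_values: tuple = (2, 3, 4, 5, 6)
    n_resamples: int = 1000
    item_fraction: float = 0.8

    # signature construction
    deg_fdr: float = 0.01
    screen_p: float = 0.05
    top_pool: int = 300
    candidate_sizes: tuple | None = None
    gene_k_values: tuple = (2, 3, 4, 5, 6)
    cutpoint_minprop: float = 0.1

    seed: int = 0

    @classmethod
    def benchmark(cls, seed: int = 17) -> "PipelineConfig":
        """The default synthetic benchmark profile (fast consensus)."""
        return cls(
            simulation=SimulationConfig(seed=seed),
            n_permutations=20,
            n_resamples=50,
            seed=seed,
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        if self.simulation is not None:
            d["simulation"] = self.simulation.to_dict()
        for key in ("nu_grid", "k_values", "gene_k_values"):
            d[key] = list(d[key])
        if d["candidate_sizes"] is not None:
            d["candidate_sizes"] = list(d["candidate_sizes"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if d.get("simulation") is not None:
            d["simulation"] = SimulationConfig.from_dict(d["simulation"])
        for key in ("nu_grid", "k_values", "gene_k_values", "candidate_sizes"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class DiscoveryResult:
    model: TMEScoreModel
    scores: pd.DataFrame
    phenotype_labels: pd.Series
    fractions: pd.DataFrame
    reports: dict
    scorer: TMEScorer
    truth: object | None = None


class _RunLog:
    def __init__(self, out_dir: Path | None):
        self.path = out_dir / "run_log.jsonl" if out_dir else None
        if self.path is not None:
            self.path.parent.mkdir(parents=True, exist_ok=True)
            self.path.write_text("")

    def record(self, stage: str, seconds: float, **params) -> None:
        if self.path is None:
            return
        entry = {"stage": stage, "wall_seconds": round(seconds, 3), **params}
        with open(self.path, "a") as fh:
            fh.write(json.dumps(entry, default=str) + "\n")


def _stage(name: str):
    class _Ctx:
        def __enter__(self):
            self.t0 = time.time()
            return self

        def __exit__(self, exc_type, exc, tb):
            self.seconds = time.time() - self.t0
            if exc is not None and not isinstance(exc, StageError):
                raise StageError(f"stage '{name}' failed: {exc}") from exc
            return False

    return _Ctx()


def run_discovery(config: PipelineConfig, out_dir=None) -> DiscoveryResult:
    out = Path(out_dir) if out_dir is not None else None
    log = _RunLog(out)
    if out is not None:
        config.to_yaml(out / "config.yaml")
    truth = None

    with _stage("inputs") as st:
        if config.simulation is not None:
            expr_linear, clinical, truth = generate_cohort(config.simulation)
            signature = generate_reference(config.simulation)
        else:
            if config.expression_path is None or config.clinical_path is None:
                raise TMEScoreError("need expression_path and clinical_path (or a simulation config)")
            expr_linear, clinical = load_dataset(
                config.expression_path, config.clinical_path, scale=config.expression_scale
            )
            if config.signature_path is None:
                raise TMEScoreError("need a signature_path for deconvolution")
            signature = read_signature(config.signature_path)
        if clinical is None or "os_time" not in clinical.frame:
            raise TMEScoreError("inputs lack survival columns (os_time/os_event)")
    log.record("inputs", st.seconds, n_samples=expr_linear.n_samples, n_genes=expr_linear.n_genes)

    with _stage("preprocess") as st:
        if config.tpm_rescale:
            expr_linear = fpkm_to_tpm(expr_linear)
        expr_log = log2_transform(expr_linear, pseudocount=config.log2_pseudocount)
        batch = expr_linear.cohort
        if config.apply_batch_correction and batch is not None and batch.nunique() > 1:
            expr_log = batch_correct(expr_log, batch.to_numpy())
    log.record("preprocess", st.seconds, batch_corrected=bool(
        config.apply_batch_correction and batch is not None and batch.nunique() > 1))

    with _stage("deconvolution") as st:
        deconv = NuSVRDeconvolver(
            nu_grid=config.nu_grid,
            n_permutations=config.n_permutations,
            random_state=config.seed + 11,
        ).fit(signature)
        cf = deconv.transform(expr_linear)
        if out is not None:
            cf.to_tsv(out / "cell_fractions.tsv")
    log.record("deconvolution", st.seconds, nu_grid=list(config.nu_grid),
               n_permutations=config.n_permutations, seed=config.seed + 11)

    with _stage("phenotype_clustering") as st:
        fz = (cf.fractions - cf.fractions.mean()) / cf.fractions.std().replace(0.0, 1.0)
        cc = ConsensusCluster(
            k_values=config.k_values,
            n_resamples=config.n_resamples,
            item_fraction=config.item_fraction,
            base="pam",
            distance="euclidean",
            random_state=config.seed + 21,
        ).fit(fz.to_numpy())
        phenotype = pd.Series(cc.labels_ + 1, index=cf.sample_ids, name="tme_cluster")
        if out is not None:
            phenotype.to_frame().to_csv(out / "tme_clusters.tsv", sep="\t")
            (out / "consensus_diagnostics.json").write_text(json.dumps({
                "selected_k": int(cc.selected_k_),
                "delta_area": {str(k): v for k, v in cc.delta_area_.items()},
            }, indent=2))
    log.record("phenotype_clustering", st.seconds, selected_k=int(cc.selected_k_),
               n_resamples=config.n_resamples, seed=config.seed + 21)

    with _stage("signature") as st:
        surv = SurvivalData.from_clinical(clinical)
        scorer = TMEScorer(
            deg_fdr=config.deg_fdr,
            screen_p=config.screen_p,
            top_pool=config.top_pool,
            candidate_sizes=config.candidate_sizes,
            gene_k_values=config.gene_k_values,
            consensus_resamples=config.n_resamples,
            cutpoint_minprop=config.cutpoint_minprop,
            random_state=config.seed + 31,
        )
        scorer.fit(expr_log.values.T, surv, phenotype=phenotype.to_numpy())
        model = scorer.model_
        model.provenance["pipeline_seed"] = config.seed
        scores = scorer.scores_
        if out is not None:
            model.to_json(out / "model.json")
            scores.to_csv(out / "tme_scores.tsv", sep="\t", index_label="sample_id")
            scorer.deg_result_.to_tsv(out / "deg_table.tsv")
            scorer.screen_table_.to_csv(out / "cox_screen.tsv", sep="\t")
    log.record("signature", st.seconds, n_degs=len(scorer.degs_),
               signature_size=len(scorer.signature_genes_), seed=config.seed + 31)

    with _stage("reports") as st:
        group = scores["group"].to_numpy()
        reports: dict = {
            "n_samples": int(expr_linear.n_samples),
            "n_degs": len(scorer.degs_),
            "signature_size": len(scorer.signature_genes_),
            "selected_k": int(cc.selected_k_),
            "cutoff": float(model.cutoff),
            "directions": dict(model.direction),
        }
        if len(np.unique(group)) == 2:
            chi2, df, p = logrank_test(surv, group)
            reports["logrank_chi2"] = float(chi2)
            reports["logrank_p"] = float(p)
        score_z = (scores["tme_score"] - scores["tme_score"].mean()) / scores["tme_score"].std()
        covs = pd.DataFrame({"tme_score": score_z})
        reports["cox_univariate"] = cox_fit(surv, covs).summary.loc["tme_score"].to_dict()
        if batch is not None and batch.nunique() > 1:
            covs_multi = covs.copy()
            for lev in sorted(batch.unique())[1:]:
                covs_multi[f"batch_{lev}"] = (batch == lev).astype(float).to_numpy()
            reports["cox_multivariate"] = cox_fit(surv, covs_multi).summary.loc["tme_score"].to_dict()
        if truth is not None:
            reports["truth"] = truth_metrics(
                truth,
                phenotype_labels=phenotype.to_numpy(),
                fractions=cf.fractions,
                deg_ids=scorer.degs_,
                signature_genes=scorer.signature_genes_,
                scores=scores["tme_score"],
            )
            med = scores["tme_score"].groupby(truth.phenotype.to_numpy()).median()
            reports["truth"]["median_score_short_survival"] = float(med.loc[1])
            reports["truth"]["median_score_long_survival"] = float(med.loc[2])
        if out is not None:
            (out / "reports.json").write_text(json.dumps(reports, indent=2, default=float))
    log.record("reports", st.seconds)

    return DiscoveryResult(
        model=model, scores=scores, phenotype_labels=phenotype,
        fractions=cf.fractions, reports=reports, scorer=scorer, truth=truth,
    )


def run_apply(
    model: TMEScoreModel,
    expr: ExpressionMatrix,
    clinical: ClinicalTable | None = None,
    refit_cutoff: bool = False,
    minprop: float = 0.1,
) -> tuple[pd.DataFrame, dict]:
    """Score an external cohort with a fitted model.

    With survival data and ``refit_cutoff`` the high/low split uses a
    cohort-specific maximally selected cutoff instead of the trained one.
    """
    values = expr.values if isinstance(expr, ExpressionMatrix) else expr
    scores = tme_score(values, model)
    report: dict = {"n_samples": int(scores.shape[0]), "cutoff": float(model.cutoff)
                    if model.cutoff is not None else None}
    if clinical is not None:
        surv = SurvivalData.from_clinical(clinical.subset(scores.index))
        if refit_cutoff:
            cut = optimal_cutpoint(scores["tme_score"].to_numpy(), surv, minprop=minprop)
            scores["group"] = np.where(scores["tme_score"] > cut.cutoff, "high", "low")
            report["cutoff"] = cut.cutoff
            report["cutoff_refit"] = True
        if scores["group"].nunique() == 2:
            chi2, df, p = logrank_test(surv, scores["group"].to_numpy())
            report["logrank_chi2"] = float(chi2)
            report["logrank_p"] = float(p)
        else:
            warn("run_apply: single score group; no log-rank test")
    return scores, report
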