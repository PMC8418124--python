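"""Synthetic multi-cohort benchmark generator with known ground truth.

The generator emulates the statistical structure the analysis assumes:

* a marker-structured cell-type reference (LM22-like, but 8 types by
  default) on linear scale;
* per-sample cell-type fractions drawn from one of two Dirichlet
  distributions — the two latent TME phenotypes, one tilted toward
  "suppressive-like" cell types;
* bulk expression = reference profiles x fractions, with multiplicative
  log-normal noise, planted differentially expressed background genes and
  additive log-scale batch shifts, rescaled to TPM;
* exponential survival whose hazard depends on the phenotype, with
  uniform censoring calibrated to a requested censoring fraction.

All outputs are pure functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .containers import ClinicalTable, ExpressionMatrix, TMEScoreError
from .survival import roc_auc

__all__ = ["SimulationConfig", "SyntheticTruth", "generate_reference", "generate_cohort", "truth_metrics"]


@dataclass
class SimulationConfig:
    """Knobs of the synthetic benchmark (defaults = the study conditions).

    Expression effect sizes are in log2 units; ``noise_sd`` is the SD of
    the multiplicative log-normal noise in natural-log units (0.2 ~ 20%
    coefficient of variation). Survival times are in days.
    """

    n_samples: int = 400
    n_cell_types: int = 8
    markers_per_type: int = 40
    n_background_genes: int = 1680
    reference_background_genes: int = 80
    marker_high_mean: float = 6.0
    marker_high_sd: float = 0.5
    marker_low_mean: float = 1.0
    marker_low_sd: float = 0.5
    alpha_phenotype1: Sequence[float] | None = None
    alpha_phenotype2: Sequence[float] | None = None
    n_planted_degs: int = 100
    deg_effect: float = 2.0
    noise_sd: float = 0.2
    batch_count: int = 2
    batch_shift: float = 1.0
    baseline_hazard: float = 1.0 / 1000.0
    phenotype_beta: float = float(np.log(2.0))
    weibull_shape: float = 1.0
    censoring: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_samples", "n_cell_types", "markers_per_type", "n_background_genes",
                     "n_planted_degs", "batch_count"):
            if getattr(self, name) <= 0:
                raise TMEScoreError(f"{name} must be positive")
        if not 0 <= self.censoring < 1:
            raise TMEScoreError("censoring fraction must be in [0, 1)")
        if self.n_planted_degs > self.n_background_genes:
            raise TMEScoreError("planted DEGs exceed the number of background genes")
        if self.reference_background_genes > self.n_background_genes:
            raise TMEScoreError("reference background genes exceed total background genes")
        k = self.n_cell_types
        if self.alpha_phenotype1 is None:
            self.alpha_phenotype1 = tuple(np.geomspace(8.0, 1.0, k))
        if self.alpha_phenotype2 is None:
            self.alpha_phenotype2 = tuple(np.geomspace(8.0, 1.0, k)[::-1])
        a1, a2 = np.asarray(self.alpha_phenotype1, float), np.asarray(self.alpha_phenotype2, float)
        if len(a1) != k or len(a2) != k or (a1 <= 0).any() or (a2 <= 0).any():
            raise TMEScoreError("phenotype Dirichlet concentrations must be positive, length n_cell_types")
        self.alpha_phenotype1 = tuple(float(v) for v in a1)
        self.alpha_phenotype2 = tuple(float(v) for v in a2)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["alpha_phenotype1"] = list(self.alpha_phenotype1)
        d["alpha_phenotype2"] = list(self.alpha_phenotype2)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        return cls(**d)


@dataclass
class SyntheticTruth:
    true_fractions: pd.DataFrame   # samples x cell types, simplex rows
    phenotype: pd.Series           # per sample in {1, 2}
    planted_deg_ids: list[str]
    batch: pd.Series
    true_beta: float

    def to_json_dict(self) -> dict:
        return {
            "phenotype": self.phenotype.astype(int).to_dict(),
            "batch": self.batch.astype(str).to_dict(),
            "planted_deg_ids": self.planted_deg_ids,
            "true_beta": self.true_beta,
            "true_fractions": {
                "index": self.true_fractions.index.tolist(),
                "columns": self.true_fractions.columns.tolist(),
                "values": self.true_fractions.to_numpy().tolist(),
            },
        }


def _gene_names(config: SimulationConfig) -> tuple[list[str], list[str]]:
    markers = [
        f"CT{t + 1}_M{m + 1}"
        for t in range(config.n_cell_types)
        for m in range(config.markers_per_type)
    ]
    background = [f"BG{i + 1}" for i in range(config.n_background_genes)]
    return markers, background


def _full_profiles(config: SimulationConfig, seed: int) -> pd.DataFrame:
    """Linear-scale per-gene per-cell-type expression profiles (all genes)."""
    rng = np.random.default_rng(seed)
    markers, background = _gene_names(config)
    k = config.n_cell_types
    log2_vals = rng.normal(
        config.marker_low_mean, config.marker_low_sd, size=(len(markers), k)
    )
    for t in range(k):
        rows = slice(t * config.markers_per_type, (t + 1) * config.markers_per_type)
        log2_vals[rows, t] = rng.normal(
            config.marker_high_mean, config.marker_high_sd, size=config.markers_per_type
        )
    bg = rng.normal(config.marker_low_mean, config.marker_low_sd, size=len(background))
    bg_vals = np.repeat(bg[:, None], k, axis=1)  # flat across types
    values = np.exp2(np.vstack([log2_vals, bg_vals]))
    cell_types = [f"CellType{t + 1}" for t in range(k)]
    return pd.DataFrame(values, index=markers + background, columns=cell_types)


def generate_reference(config: SimulationConfig, seed: int | None = None) -> pd.DataFrame:
    """LM22-like signature matrix: all markers plus a small flat panel.

    Real deconvolution references are compact differential panels, so only
    ``reference_background_genes`` of the flat background genes are
    included alongside every marker gene.
    """
    seed = config.seed if seed is None else seed
    profiles = _full_profiles(config, seed)
    markers, background = _gene_names(config)
    keep = markers + background[: config.reference_background_genes]
    return profiles.loc[keep]


def _calibrate_censoring(rates: np.ndarray, frac: float) -> float:
    """c such that P(U(0,c) < T) = frac on average over the sample rates."""

    def censored_prob(c: float) -> float:
        lam_c = rates * c
        return float(np.mean((1.0 - np.exp(-lam_c)) / lam_c))

    lo, hi = 1e-9, 1.0
    while censored_prob(hi) > frac:
        hi *= 2.0
        if hi > 1e12:
            break
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if censored_prob(mid) > frac:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_cohort(
    config: SimulationConfig, seed: int | None = None
) -> tuple[ExpressionMatrix, ClinicalTable, SyntheticTruth]:
    """Simulate one multi-batch cohort with ground truth.

    The "biology" — cell-type profiles and the planted DEG set — is fixed
    by ``config.seed``; the optional ``seed`` argument redraws only the
    samples (phenotypes, fractions, noise, batches, survival), so cohorts
    generated with different ``seed`` are held-out replicates of the same
    underlying system.
    """
    sample_seed = config.seed if seed is None else seed
    bio_rng = np.random.default_rng(config.seed + 1)
    rng = np.random.default_rng(sample_seed + 2)
    profiles = _full_profiles(config, config.seed)
    n = config.n_samples
    k = config.n_cell_types
    samples = [f"S{i + 1:04d}" for i in range(n)]
    markers, background = _gene_names(config)
    planted = list(bio_rng.choice(background, size=config.n_planted_degs, replace=False))
    planted_idx = [len(markers) + background.index(g) for g in planted]

    phenotype = rng.integers(1, 3, size=n)
    a1 = np.asarray(config.alpha_phenotype1)
    a2 = np.asarray(config.alpha_phenotype2)
    fractions = np.empty((n, k))
    for i in range(n):
        fractions[i] = rng.dirichlet(a1 if phenotype[i] == 1 else a2)

    expr = profiles.to_numpy() @ fractions.T  # genes x samples, linear
    if config.noise_sd > 0:
        expr = expr * np.exp(rng.normal(0.0, config.noise_sd, size=expr.shape))

    expr[np.ix_(planted_idx, np.flatnonzero(phenotype == 1))] *= 2.0 ** config.deg_effect

    batch = rng.integers(0, config.batch_count, size=n)
    if config.batch_count > 1 and config.batch_shift != 0:
        expr = expr * 2.0 ** (config.batch_shift * batch[None, :])

    expr = expr / expr.sum(axis=0, keepdims=True) * 1e6  # TPM rescale

    rates = config.baseline_hazard * np.exp(config.phenotype_beta * (phenotype == 1))
    raw_t = rng.exponential(1.0 / rates)
    if config.weibull_shape != 1.0:
        # T = (E / lambda)^(1/shape) keeps the phenotype effect proportional-hazards
        raw_t = (raw_t * rates) ** (1.0 / config.weibull_shape) / rates
    if config.censoring > 0:
        c_max = _calibrate_censoring(rates, config.censoring)
        cens = rng.uniform(0.0, c_max, size=n)
        os_time = np.minimum(raw_t, cens)
        os_event = (raw_t <= cens).astype(int)
    else:
        os_time, os_event = raw_t, np.ones(n, int)
    os_time = np.maximum(os_time, 1e-6)

    gene_ids = markers + background
    em = ExpressionMatrix(
        pd.DataFrame(expr, index=gene_ids, columns=samples),
        scale="linear",
        cohort=pd.Series([f"batch{b}" for b in batch], index=samples),
    )
    clinical = ClinicalTable(
        pd.DataFrame(
            {"os_time": os_time, "os_event": os_event, "cohort": [f"batch{b}" for b in batch]},
            index=pd.Index(samples, name="sample_id"),
        )
    )
    truth = SyntheticTruth(
        true_fractions=pd.DataFrame(fractions, index=samples, columns=profiles.columns),
        phenotype=pd.Series(phenotype, index=samples),
        planted_deg_ids=planted,
        batch=pd.Series([f"batch{b}" for b in batch], index=samples),
        true_beta=config.phenotype_beta,
    )
    return em, clinical, truth


def truth_metrics(
    truth: SyntheticTruth,
    phenotype_labels=None,
    fractions: pd.DataFrame | None = None,
    deg_ids: Sequence[str] | None = None,
    signature_genes: Sequence[str] | None = None,
    beta_hat: float | None = None,
    scores: pd.Series | None = None,
) -> dict:
    """Recovery metrics of pipeline outputs against the planted truth."""
    report: dict = {}
    if phenotype_labels is not None:
        labels = pd.Series(np.asarray(phenotype_labels), index=truth.phenotype.index) \
            if len(phenotype_labels) == len(truth.phenotype) else None
        if labels is None:
            raise TMEScoreError("phenotype labels misaligned with truth")
        report["phenotype_ari"] = float(adjusted_rand_score(truth.phenotype.to_numpy(), labels.to_numpy()))
    if fractions is not None:
        if not fractions.index.equals(truth.true_fractions.index):
            fractions = fractions.reindex(truth.true_fractions.index)
            if fractions.isna().any().any():
                raise TMEScoreError("fraction sample ids misaligned with truth")
        common = truth.true_fractions.columns.intersection(fractions.columns)
        diff = fractions[common].to_numpy() - truth.true_fractions[common].to_numpy()
        report["fraction_mae"] = float(np.abs(diff).mean())
    if deg_ids is not None:
        found = set(deg_ids)
        planted = set(truth.planted_deg_ids)
        report["deg_recall"] = len(found & planted) / len(planted)
        report["deg_precision"] = len(found & planted) / len(found) if found else 1.0
    if signature_genes is not None:
        planted = set(truth.planted_deg_ids)
        report["signature_planted_recall"] = len(set(signature_genes) & planted) / len(planted)
    if beta_hat is not None:
        report["cox_beta_error"] = float(abs(beta_hat - truth.true_beta))
    if scores is not None:
        s = pd.Series(scores)
        if not s.index.equals(truth.phenotype.index):
            s = s.reindex(truth.phenotype.index)
        report["score_phenotype_auc"] = roc_auc(s.to_numpy(), (truth.phenotype == 1).to_numpy())
    return report
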