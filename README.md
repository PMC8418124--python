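# tmescore

Tumor-microenvironment (TME) phenotyping and prognostic scoring from bulk
tumor transcriptomes.

Bulk RNA profiles of solid tumors mix malignant cells with infiltrating
immune and stromal cells, and the composition of that infiltrate carries
prognostic and immunotherapy-response information. `tmescore` implements a
complete, tested pipeline for turning a genes × samples expression matrix
plus survival annotation into a per-patient **TME-score**:

1. **Deconvolution** — per-sample immune-cell fractions by ν-support-vector
   regression of the mixture on an LM22-like reference signature matrix
   (linear kernel, ν-grid search, negative weights clipped to a simplex,
   permutation p-values), plus ssGSEA and immune/stromal summary scores.
2. **TME phenotypes** — consensus clustering (Partitioning Around Medoids
   over item subsamples) of the cell-fraction profiles; the number of
   clusters is chosen from the consensus-CDF delta-area curve.
3. **Signature extraction** — empirical-Bayes moderated-*t* differential
   expression between the two phenotypes (BH FDR < 0.01), univariate Cox
   screening of the DEGs (per-SD hazard ratios), and SVM-RFE ranking with
   cross-validated selection of the signature size.
4. **TME-score** — signature genes are consensus-clustered (1 − Pearson);
   each gene cluster contributes its oriented first principal component
   score; clusters whose PC1 associates with increased hazard (HR > 1)
   form the *i* set and the rest the *j* set, and

       TME-score = Σ PC1_i − Σ PC1_j

   Patients are dichotomised at a maximally selected log-rank cutpoint
   (Kaplan–Meier curves, log-rank tests, uni/multivariate Cox reports).
5. **Immune readouts** — cytolytic activity (CYT, geometric mean of GZMA
   and PRF1 TPM) and the T-cell-inflamed GEP mean for immunotherapy
   contexts.

Because public cohorts cannot be bundled, the package ships a first-class
synthetic-cohort generator (`tmescore.synthetic`) that emulates the assumed
data structure — marker-structured reference, two latent infiltration
phenotypes with Dirichlet-tilted mixing, planted DEGs, batch shifts, and
phenotype-linked exponential survival — with full ground truth, so every
stage is testable for recovery, not just for running.

## Worked example

```python
from tmescore import PipelineConfig, SimulationConfig, run_discovery

config = PipelineConfig(
    simulation=SimulationConfig(n_samples=200, seed=11),
    n_permutations=20, n_resamples=50, seed=11,
)
result = run_discovery(config, out_dir="runs/demo")
r = result.reports
print(f"selected k (phenotypes): {r['selected_k']}")
print(f"DEGs (FDR < 0.01)      : {r['n_degs']}")
print(f"signature size         : {r['signature_size']}")
print(f"score cutoff           : {r['cutoff']:.3f}")
print(f"log-rank p (high/low)  : {r['logrank_p']:.2e}")
print(f"HR per SD of TME-score : {r['cox_univariate']['hr']:.2f}")
print(f"phenotype ARI vs truth : {r['truth']['phenotype_ari']:.3f}")
print(f"score-vs-phenotype AUC : {r['truth']['score_phenotype_auc']:.3f}")
```

prints

```
selected k (phenotypes): 2
DEGs (FDR < 0.01)      : 1406
signature size         : 10
score cutoff           : 5.309
log-rank p (high/low)  : 2.28e-03
HR per SD of TME-score : 1.28
phenotype ARI vs truth : 1.000
score-vs-phenotype AUC : 1.000
```

The run recovers both planted phenotypes exactly (ARI = 1.0), the learned
score separates them perfectly (AUC = 1.0), and the high-score group has
significantly shorter survival (log-rank p ≈ 2×10⁻³; hazard ratio 1.28 per
SD of the score) — the sign convention places the short-survival phenotype
on the high side of the score. All intermediates (cell fractions, cluster
labels, DEG table, model JSON, scores, JSON-lines run log with per-stage
seeds) land in `runs/demo/`.

The same pipeline is available from the shell:

```bash
tmescorer simulate  --out data/            # synthetic cohort + truth
tmescorer run-all   --out runs/demo --seed 11
tmescorer apply     --expr data/expression.tsv --model runs/demo/model.json \
                    --clinical data/clinical.tsv --out scores.tsv --refit-cutoff
```

Estimator-style classes (`NuSVRDeconvolver`, `PAM`, `ConsensusCluster`,
`TMEScorer`) expose the sklearn `fit`/`transform`/`predict` surface for
composition with sklearn tooling; the module-level functions
(`nusvr_deconvolve`, `pam_cluster`, `moderated_t_test`, `cox_fit`,
`optimal_cutpoint`, `tme_score`, …) are thin wrappers over the same code.

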