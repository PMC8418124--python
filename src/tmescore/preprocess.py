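"""Pre-analysis normalisation: TPM conversion, log transform, quantile
normalisation and multi-cohort merging."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import ClinicalTable, ExpressionMatrix, TMEScoreError, warn

__all__ = ["fpkm_to_tpm", "log2_transform", "log2_inverse", "quantile_normalize", "merge_cohorts"]


def fpkm_to_tpm(m: ExpressionMatrix) -> ExpressionMatrix:
    """Rescale each sample so its values sum to 1e6 (FPKM -> TPM).

    TPM is the within-sample renormalisation of FPKM: tpm_gj =
    fpkm_gj / sum_g fpkm_gj * 1e6, which makes columns comparable across
    samples.
    """
    if m.scale != "linear":
        raise TMEScoreError("fpkm_to_tpm expects linear-scale input")
    sums = m.values.sum(axis=0)
    zero = sums[sums <= 0]
    if len(zero):
        raise TMEScoreError(f"all-zero sample columns: {zero.index.tolist()[:5]}")
    out = m.values.div(sums, axis=1) * 1e6
    return m.with_values(out, "linear")


def log2_transform(m: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    if m.scale != "linear":
        raise TMEScoreError("log2_transform expects linear-scale input")
    if pseudocount <= 0 and (m.values.to_numpy() == 0).any():
        raise TMEScoreError("pseudocount must be > 0 when zeros are present")
    out = np.log2(m.values + pseudocount)
    return m.with_values(out, "log2")


def log2_inverse(m: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    if m.scale != "log2":
        raise TMEScoreError("log2_inverse expects log2-scale input")
    out = np.exp2(m.values) - pseudocount
    return m.with_values(out.clip(lower=0.0), "linear")


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample onto the common (mean) quantile distribution.

    Each column's sorted values are replaced by the across-column mean of
    order statistics; tied values within a column receive the mean of their
    tied positions' reference values, so ties stay tied.
    """
    if m.n_samples < 2:
        warn("quantile_normalize: single sample, returned unchanged")
        return m.with_values(m.values.copy())
    X = m.values.to_numpy(float)
    ref = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        col = X[:, j]
        order = np.argsort(col, kind="mergesort")
        sorted_vals = col[order]
        # group ties (consecutive equal values in sorted order)
        boundaries = np.flatnonzero(np.diff(sorted_vals) != 0) + 1
        starts = np.concatenate([[0], boundaries])
        ends = np.concatenate([boundaries, [len(col)]])
        new_sorted = np.empty_like(sorted_vals)
        for s, e in zip(starts, ends):
            new_sorted[s:e] = ref[s:e].mean()
        out[order, j] = new_sorted
    return m.with_values(pd.DataFrame(out, index=m.gene_ids, columns=m.sample_ids))


def merge_cohorts(
    cohorts: list[tuple[ExpressionMatrix, ClinicalTable | None]],
    names: list[str] | None = None,
) -> tuple[ExpressionMatrix, ClinicalTable]:
    """Concatenate cohorts on the gene intersection, tagging samples with
    their cohort label. The caller is expected to batch-correct afterwards.
    """
    if len(cohorts) < 2:
        raise TMEScoreError("merge_cohorts needs >=2 cohorts")
    if names is None:
        names = [f"cohort{i + 1}" for i in range(len(cohorts))]
    scale = cohorts[0][0].scale
    genes = cohorts[0][0].gene_ids
    for m, _ in cohorts[1:]:
        if m.scale != scale:
            raise TMEScoreError("cannot merge cohorts with mixed scales")
        genes = genes.intersection(m.gene_ids)
    if len(genes) == 0:
        raise TMEScoreError("empty gene intersection across cohorts")
    genes = [g for g in cohorts[0][0].gene_ids if g in set(genes)]  # preserve order

    seen: set[str] = set()
    expr_parts, clin_parts, cohort_labels = [], [], []
    for name, (m, clin) in zip(names, cohorts):
        vals = m.values.loc[genes]
        renamed = {}
        for s in vals.columns:
            sid = str(s)
            if sid in seen:
                warn(f"duplicate sample id {sid!r} across cohorts; suffixed with {name!r}")
                sid = f"{sid}_{name}"
            renamed[s] = sid
            seen.add(sid)
        vals = vals.rename(columns=renamed)
        expr_parts.append(vals)
        cohort_labels.extend([name] * vals.shape[1])
        if clin is not None:
            cf = clin.frame.copy()
            cf.index = [renamed.get(s, s) for s in cf.index]
            cf["cohort"] = name
            clin_parts.append(cf)
    values = pd.concat(expr_parts, axis=1)
    cohort = pd.Series(cohort_labels, index=values.columns)
    merged_expr = ExpressionMatrix(values, scale, cohort)
    merged_clin = ClinicalTable(pd.concat(clin_parts)) if clin_parts else None
    if merged_clin is None:
        raise TMEScoreError("merge_cohorts: no clinical tables supplied")
    return merged_expr, merged_clin
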