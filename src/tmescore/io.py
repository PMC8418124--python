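"""Reading and writing the tabular interchange formats.

Expression: delimited text (TSV/CSV, gzip-transparent), genes in rows by
default with the first column holding gene ids and the header holding sample
ids. Clinical: TSV with mandatory columns ``sample_id``, ``os_time``,
``os_event``. Gene sets: GMT.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .containers import ClinicalTable, ExpressionMatrix, TMEScoreError, warn

__all__ = ["load_dataset", "read_expression", "read_clinical", "write_expression"]


def _sep_for(path) -> str:
    name = str(path)
    if name.endswith(".gz"):
        name = name[:-3]
    return "," if name.endswith(".csv") else "\t"


def read_expression(path, layout: str = "genes_in_rows", scale: str = "linear") -> ExpressionMatrix:
    """Parse an expression table into an :class:`ExpressionMatrix`.

    Duplicate gene ids are collapsed to the row with the highest mean
    expression (common microarray probe-collapse convention); duplicate
    sample ids are an error. Non-numeric cells raise with the offending
    location named.
    """
    if layout not in ("genes_in_rows", "genes_in_columns"):
        raise TMEScoreError(f"unknown layout {layout!r}")
    try:
        raw = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    except pd.errors.EmptyDataError as exc:
        raise TMEScoreError(f"{path}: empty file") from exc
    if raw.shape[0] == 0 or raw.shape[1] == 0:
        raise TMEScoreError(f"{path}: no data rows/columns")
    if layout == "genes_in_columns":
        raw = raw.T
    # locate non-numeric cells before coercing
    coerced = raw.apply(pd.to_numeric, errors="coerce")
    bad = coerced.isna() & ~raw.isna()
    bad |= raw.isna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise TMEScoreError(
            f"{path}: non-numeric cell at gene {raw.index[i]!r}, sample {raw.columns[j]!r}"
        )
    if coerced.columns.has_duplicates:
        dups = coerced.columns[coerced.columns.duplicated()].unique().tolist()
        raise TMEScoreError(f"{path}: duplicate sample ids {dups[:5]}")
    if coerced.index.has_duplicates:
        # keep, per duplicated gene id, the row with the highest mean
        order = coerced.mean(axis=1).groupby(coerced.index, sort=False).idxmax()
        means = coerced.mean(axis=1)
        keep = np.zeros(len(coerced), bool)
        best: dict = {}
        for pos, (g, m) in enumerate(zip(coerced.index, means)):
            if g not in best or m > means.iloc[best[g]]:
                best[g] = pos
        keep[list(best.values())] = True
        coerced = coerced.iloc[keep]
        warn(f"{path}: collapsed duplicate gene ids to highest-mean rows")
    coerced.index = coerced.index.astype(str)
    coerced.columns = coerced.columns.astype(str)
    return ExpressionMatrix(coerced.astype(float), scale=scale)


def read_clinical(path) -> ClinicalTable:
    try:
        raw = pd.read_csv(path, sep=_sep_for(path))
    except pd.errors.EmptyDataError as exc:
        raise TMEScoreError(f"{path}: empty file") from exc
    if "sample_id" not in raw.columns:
        raise TMEScoreError(f"{path}: clinical table must have a 'sample_id' column")
    raw["sample_id"] = raw["sample_id"].astype(str)
    if raw["sample_id"].duplicated().any():
        dups = raw.loc[raw["sample_id"].duplicated(), "sample_id"].tolist()
        raise TMEScoreError(f"{path}: duplicate sample ids {dups[:5]}")
    return ClinicalTable(raw.set_index("sample_id"))


def load_dataset(
    expr_path,
    clinical_path=None,
    layout: str = "genes_in_rows",
    scale: str = "linear",
) -> tuple[ExpressionMatrix, ClinicalTable | None]:
    """Load an expression matrix and (optionally) its clinical table.

    Samples present in both tables are aligned by id; unmatched samples on
    either side are dropped with a warning naming them.
    """
    expr = read_expression(expr_path, layout=layout, scale=scale)
    if clinical_path is None:
        return expr, None
    clin = read_clinical(clinical_path)
    shared = expr.sample_ids.intersection(clin.sample_ids)
    if len(shared) == 0:
        raise TMEScoreError("no samples shared between expression and clinical tables")
    only_e = expr.sample_ids.difference(clin.sample_ids)
    only_c = clin.sample_ids.difference(expr.sample_ids)
    if len(only_e) or len(only_c):
        warn(
            f"dropping unmatched samples: {len(only_e)} expression-only "
            f"{list(only_e[:3])}, {len(only_c)} clinical-only {list(only_c[:3])}"
        )
    shared = [s for s in expr.sample_ids if s in set(shared)]
    return expr.subset_samples(shared), clin.subset(shared)


def write_expression(m: ExpressionMatrix, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    m.values.to_csv(path, sep=_sep_for(path), index_label="gene")
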