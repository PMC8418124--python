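"""Core data containers shared across the package.

Expression data is carried as a pandas DataFrame (genes in rows, samples in
columns) inside a light wrapper that tracks the measurement scale, because
several stages are scale-sensitive: deconvolution and the CYT readout expect
linear TPM-like values, while clustering, differential expression and the
signature score operate on log2 values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "ClinicalTable",
    "GeneSetCollection",
    "TMEScoreError",
]


class TMEScoreError(ValueError):
    """Raised for validation and input-contract failures."""


@dataclass
class ExpressionMatrix:
    """Genes x samples numeric matrix with a declared scale.

    Parameters
    ----------
    values : DataFrame
        Genes in rows (index = gene ids), samples in columns.
    scale : {"linear", "log2"}
        Declared measurement scale. Linear values must be non-negative.
    cohort : Series, optional
        Per-sample cohort label, indexed by sample id.
    """

    values: pd.DataFrame
    scale: str = "linear"
    cohort: pd.Series | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        if self.scale not in ("linear", "log2"):
            raise TMEScoreError(f"scale must be 'linear' or 'log2', got {self.scale!r}")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise TMEScoreError(f"duplicate gene ids: {dups[:5]}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise TMEScoreError(f"duplicate sample ids: {dups[:5]}")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise TMEScoreError("expression values must be numeric")
        if not np.all(np.isfinite(arr)):
            bad = np.argwhere(~np.isfinite(arr))[0]
            raise TMEScoreError(
                "non-finite expression value at gene "
                f"{self.values.index[bad[0]]!r}, sample {self.values.columns[bad[1]]!r}"
            )
        if self.scale == "linear" and arr.size and arr.min() < 0:
            raise TMEScoreError("linear-scale expression must be non-negative")
        if self.cohort is not None:
            self.cohort = pd.Series(self.cohort)
            if not self.cohort.index.equals(self.values.columns):
                self.cohort = self.cohort.reindex(self.values.columns)
            if self.cohort.isna().any():
                raise TMEScoreError("cohort labels missing for some samples")

    # -- convenience -----------------------------------------------------
    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def with_values(self, values: pd.DataFrame, scale: str | None = None) -> "ExpressionMatrix":
        """Return a new matrix sharing cohort labels but with new values."""
        cohort = None
        if self.cohort is not None:
            cohort = self.cohort.reindex(values.columns)
        return ExpressionMatrix(values, scale or self.scale, cohort)

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        return self.with_values(self.values.loc[:, list(sample_ids)])


@dataclass
class ClinicalTable:
    """Per-sample survival annotation (overall survival in days).

    ``frame`` is indexed by sample id and must contain ``os_time`` (> 0) and
    ``os_event`` (0/1); any further columns are treated as covariates. An
    optional ``cohort`` column is preserved through merges.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        if not isinstance(self.frame, pd.DataFrame):
            self.frame = pd.DataFrame(self.frame)
        if self.frame.index.has_duplicates:
            raise TMEScoreError("duplicate sample ids in clinical table")
        for col in ("os_time", "os_event"):
            if col not in self.frame.columns:
                raise TMEScoreError(f"clinical table missing mandatory column {col!r}")
        t = pd.to_numeric(self.frame["os_time"], errors="coerce")
        if t.isna().any() or (t <= 0).any():
            bad = self.frame.index[t.isna() | (t <= 0)].tolist()
            raise TMEScoreError(f"os_time must be positive and numeric; offending samples: {bad[:5]}")
        e = pd.to_numeric(self.frame["os_event"], errors="coerce")
        if e.isna().any() or not set(np.unique(e)).issubset({0, 1}):
            raise TMEScoreError("os_event must be 0/1")
        self.frame = self.frame.copy()
        self.frame["os_time"] = t.astype(float)
        self.frame["os_event"] = e.astype(int)

    @property
    def sample_ids(self) -> pd.Index:
        return self.frame.index

    @property
    def os_time(self) -> np.ndarray:
        return self.frame["os_time"].to_numpy(float)

    @property
    def os_event(self) -> np.ndarray:
        return self.frame["os_event"].to_numpy(int)

    def subset(self, sample_ids) -> "ClinicalTable":
        return ClinicalTable(self.frame.loc[list(sample_ids)])


@dataclass
class GeneSetCollection:
    """Named gene sets with GMT semantics (name, description, members)."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if len(members) == 0:
                raise TMEScoreError(f"gene set {name!r} is empty")
        for name in self.sets:
            self.descriptions.setdefault(name, "")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def __iter__(self):
        return iter(self.sets)

    def items(self):
        return self.sets.items()

    @classmethod
    def from_gmt(cls, path) -> "GeneSetCollection":
        sets: dict[str, list[str]] = {}
        descriptions: dict[str, str] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line:
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise TMEScoreError(f"{path}:{lineno}: GMT line needs name, description, >=1 member")
                name, desc, *members = parts
                members = [m for m in members if m]
                if name in sets:
                    raise TMEScoreError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
                if not members:
                    raise TMEScoreError(f"{path}:{lineno}: gene set {name!r} has no members")
                sets[name] = members
                descriptions[name] = desc
        return cls(sets, descriptions)

    def to_gmt(self, path) -> None:
        with open(path, "w") as fh:
            for name, members in self.sets.items():
                fh.write("\t".join([name, self.descriptions.get(name, "")] + list(members)) + "\n")


def warn(message: str) -> None:
    """Package-level warning helper (single category for easy filtering)."""
    warnings.warn(message, UserWarning, stacklevel=3)
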