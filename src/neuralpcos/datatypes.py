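"""Core in-memory containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CASE = "case"
CONTROL = "control"
VALID_CLASSES = frozenset({CASE, CONTROL})
VALID_SCALES = frozenset({"log2", "counts"})


class DataError(ValueError):
    """Input data violates a contract (wrong scale, missing genes, bad counts...)."""


class ConfigurationError(ValueError):
    """A parameter value is outside its allowed range."""


@dataclass
class ExpressionMatrix:
    """Genes x samples expression with per-sample class and batch labels.

    Attributes
    ----------
    values
        DataFrame indexed by gene id, columns are sample ids. Log2 intensities
        or raw counts depending on ``scale``.
    classes
        Per-sample labels, each ``"case"`` or ``"control"``, indexed like the
        columns of ``values``.
    batches
        Per-sample batch labels (strings), same index.
    scale
        ``"log2"`` or ``"counts"``.
    """

    values: pd.DataFrame
    classes: pd.Series
    batches: pd.Series
    scale: str = "log2"

    def __post_init__(self) -> None:
        if self.scale not in VALID_SCALES:
            raise ConfigurationError(f"scale must be one of {sorted(VALID_SCALES)}, got {self.scale!r}")
        if self.values.index.duplicated().any():
            raise DataError("duplicate gene ids")
        if self.values.columns.duplicated().any():
            raise DataError("duplicate sample ids")
        self.classes = pd.Series(self.classes).reindex(self.values.columns)
        self.batches = pd.Series(self.batches).reindex(self.values.columns).astype(str)
        if self.classes.isna().any():
            raise DataError("class labels missing for some samples")
        bad = set(self.classes.unique()) - VALID_CLASSES
        if bad:
            raise DataError(f"invalid class labels: {sorted(bad)}")
        if self.scale == "log2" and not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise DataError("non-finite values in log2-scale matrix")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def case_mask(self) -> np.ndarray:
        return (self.classes == CASE).to_numpy()

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        missing = [g for g in gene_ids if g not in self.values.index]
        if missing:
            raise DataError(f"genes absent from matrix: {missing[:5]}{'...' if len(missing) > 5 else ''}")
        return ExpressionMatrix(
            values=self.values.loc[list(gene_ids)].copy(),
            classes=self.classes.copy(),
            batches=self.batches.copy(),
            scale=self.scale,
        )

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(
            values=self.values.copy(),
            classes=self.classes.copy(),
            batches=self.batches.copy(),
            scale=self.scale,
        )


@dataclass
class NormalizationRanges:
    """Per-gene min/max computed on training data, for min-max normalization."""

    min: pd.Series
    max: pd.Series

    def __post_init__(self) -> None:
        self.min = pd.Series(self.min, dtype=float)
        self.max = pd.Series(self.max, dtype=float)
        if not self.min.index.equals(self.max.index):
            raise ConfigurationError("min and max must cover the same genes")
        if (self.max < self.min).any():
            raise ConfigurationError("max < min for some gene")

    def to_dict(self) -> dict:
        return {
            "gene_ids": list(self.min.index),
            "min": [float(v) for v in self.min],
            "max": [float(v) for v in self.max],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NormalizationRanges":
        idx = pd.Index(d["gene_ids"])
        return cls(min=pd.Series(d["min"], index=idx), max=pd.Series(d["max"], index=idx))
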