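"""Core data containers shared across the pipeline.

All matrices follow the genes x samples orientation of the on-disk TSV
formats (first column ``gene_id``, one column per sample).  The sklearn-style
estimators transpose internally to the samples x features convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np
import pandas as pd

UNANNOTATED = "unannotated"


class ParameterError(ValueError):
    """A parameter violated a documented precondition."""


def _check_unique(index: pd.Index, what: str) -> None:
    if index.has_duplicates:
        dups = index[index.duplicated()].unique().tolist()
        raise ParameterError(f"duplicate {what}: {dups[:5]}")


@dataclass
class CountMatrix:
    """Gene x sample non-negative integer counts with condition labels.

    Parameters
    ----------
    counts
        DataFrame indexed by gene id, columns are sample ids.
    conditions
        Series mapping sample id -> condition label; must cover every sample.
    """

    counts: pd.DataFrame
    conditions: pd.Series

    def __post_init__(self) -> None:
        _check_unique(self.counts.index, "gene_ids")
        _check_unique(self.counts.columns, "sample_ids")
        missing = self.counts.columns.difference(self.conditions.index)
        if len(missing):
            raise ParameterError(
                f"samples without condition label: {missing.tolist()[:5]}"
            )
        values = self.counts.to_numpy()
        if not np.isfinite(values).all():
            raise ParameterError("counts must be finite")
        if (values < 0).any():
            raise ParameterError("counts must be non-negative")
        self.conditions = self.conditions.loc[self.counts.columns]

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def subset_genes(self, genes) -> "CountMatrix":
        return CountMatrix(self.counts.loc[genes].copy(), self.conditions.copy())

    def subset_samples(self, samples) -> "CountMatrix":
        return CountMatrix(
            self.counts.loc[:, samples].copy(),
            self.conditions.loc[samples].copy(),
        )


@dataclass
class ExpressionMatrix:
    """Real-valued gene x sample expression with transform provenance."""

    values: pd.DataFrame
    transform_tag: str = "raw"  # one of raw | cpm | log2cpm1
    provenance: list[dict[str, Any]] = field(default_factory=list)
    conditions: pd.Series | None = None

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "gene_ids")
        _check_unique(self.values.columns, "sample_ids")
        if self.transform_tag not in {"raw", "cpm", "log2cpm1"}:
            raise ParameterError(f"unknown transform_tag {self.transform_tag!r}")
        if self.conditions is not None:
            self.conditions = self.conditions.loc[self.values.columns]

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns


@dataclass
class GeneAnnotation:
    """Total gene -> biotype lookup; unannotated genes map to a sentinel."""

    biotypes: Mapping[str, str]

    def biotype(self, gene_id: str) -> str:
        return self.biotypes.get(gene_id, UNANNOTATED)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "GeneAnnotation":
        return cls(dict(zip(frame["gene_id"], frame["biotype"])))


@dataclass
class ConditionedExpression:
    """Expression split by the two conditions, identical gene order."""

    expr1: pd.DataFrame
    expr2: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.expr1.index.equals(self.expr2.index):
            raise ParameterError("conditions must share an identical gene set/order")
        if self.n1 < 4 or self.n2 < 4:
            raise ParameterError(
                f"need >=4 samples per condition (got {self.n1}, {self.n2}); "
                "the Fisher-Z variance 1/(n-3) requires n > 3"
            )

    @property
    def n1(self) -> int:
        return self.expr1.shape[1]

    @property
    def n2(self) -> int:
        return self.expr2.shape[1]

    @property
    def gene_ids(self) -> pd.Index:
        return self.expr1.index

    @classmethod
    def from_expression(
        cls, expr: ExpressionMatrix, cond1: str, cond2: str
    ) -> "ConditionedExpression":
        if expr.conditions is None:
            raise ParameterError("expression matrix carries no condition labels")
        s1 = expr.conditions.index[expr.conditions == cond1]
        s2 = expr.conditions.index[expr.conditions == cond2]
        if len(s1) == 0 or len(s2) == 0:
            raise ParameterError(f"no samples for condition {cond1!r} or {cond2!r}")
        return cls(expr.values.loc[:, s1], expr.values.loc[:, s2])
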