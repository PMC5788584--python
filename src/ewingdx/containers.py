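"""Core in-memory containers shared across the pipeline.

Two datasets flow through the package: a labeled log2 expression matrix
(genes x samples, with a sample->entity annotation) used by the
transcriptome-wide marker screen, and a tissue-microarray (TMA) scoring
table holding one immunoreactivity score (IRS, 0-12) per sample and
marker, used by the cut-off search and the diagnostic workflow.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

REFERENCE_ENTITY = "Ewing sarcoma"

#: panel scored on the TMA, in display order
DEFAULT_MARKERS = ("ATP1A1", "BCL11B", "GLG1", "CD99")


class ValidationError(ValueError):
    """Raised when an input dataset or configuration violates its contract."""


@dataclass
class LabeledExpressionMatrix:
    """A genes x samples matrix of log2 expression values with entity labels.

    Parameters
    ----------
    values
        DataFrame indexed by unique gene ids, columns are sample ids,
        cells are log2-scale expression intensities (RMA-like).
    entities
        Series mapping every sample id (index) to its entity label.
    truth
        Optional Series mapping gene ids to a planted-class label
        (``background``, ``full_marker``, ``er_only``, ``p_only``) when
        the matrix was simulated; ``None`` for real data.
    """

    values: pd.DataFrame
    entities: pd.Series
    truth: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique()
            raise ValidationError(f"duplicate gene ids: {list(dupes[:5])}")
        if self.values.isna().any().any():
            raise ValidationError("expression matrix contains missing values")
        missing = self.values.columns.difference(self.entities.index)
        if len(missing):
            raise ValidationError(f"samples lack entity annotation: {list(missing[:5])}")
        self.entities = self.entities.loc[self.values.columns]
        counts = self.entities.value_counts()
        small = counts[counts < 2]
        if len(small):
            raise ValidationError(
                f"entities with fewer than 2 samples: {list(small.index)}"
            )
        if self.truth is not None and not self.truth.index.equals(self.values.index):
            self.truth = self.truth.reindex(self.values.index)
            if self.truth.isna().any():
                raise ValidationError("truth annotation does not cover all genes")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def entity_names(self) -> list[str]:
        # insertion order of first appearance, deterministic
        return list(dict.fromkeys(self.entities))

    def samples_of(self, entity: str) -> pd.DataFrame:
        cols = self.entities.index[self.entities == entity]
        if not len(cols):
            raise ValidationError(f"unknown entity: {entity!r}")
        return self.values[cols]


@dataclass
class TMADataset:
    """Per-sample entity labels and integer IRS values for a marker panel.

    ``scores`` is indexed by sample id with one column per marker; every
    cell is an integer IRS in [0, 12].  ``is_reference`` flags samples of
    the reference entity (Ewing sarcoma by default): these define the
    positive class for sensitivity, everything else - including
    Ewing-like sarcomas - counts toward specificity.
    """

    scores: pd.DataFrame
    entities: pd.Series
    reference_entity: str = REFERENCE_ENTITY

    def __post_init__(self) -> None:
        if not self.scores.index.equals(self.entities.index):
            self.entities = self.entities.reindex(self.scores.index)
            if self.entities.isna().any():
                raise ValidationError("every sample needs an entity label")
        if self.scores.isna().any().any():
            raise ValidationError("every sample needs an IRS for every marker")
        arr = self.scores.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ValidationError("IRS values must be integers")
            self.scores = self.scores.astype(int)
            arr = self.scores.to_numpy()
        if arr.min() < 0 or arr.max() > 12:
            raise ValidationError("IRS values must lie in [0, 12]")

    @property
    def markers(self) -> list[str]:
        return list(self.scores.columns)

    @property
    def is_reference(self) -> pd.Series:
        return self.entities == self.reference_entity

    @property
    def n_samples(self) -> int:
        return len(self.scores)

    def irs(self, marker: str) -> np.ndarray:
        if marker not in self.scores.columns:
            raise ValidationError(f"unknown marker: {marker!r}")
        return self.scores[marker].to_numpy()


@dataclass(frozen=True)
class Performance:
    """Confusion counts of a diagnostic rule against the reference entity."""

    tp: int
    fn: int
    tn: int
    fp: int

    @property
    def sensitivity(self) -> float:
        pos = self.tp + self.fn
        return self.tp / pos if pos else float("nan")

    @property
    def specificity(self) -> float:
        neg = self.tn + self.fp
        return self.tn / neg if neg else float("nan")

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.tn + self.fp

    def as_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fn": self.fn,
            "tn": self.tn,
            "fp": self.fp,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
        }


def round_half_up_percent(fraction: float) -> int:
    """Round a fraction to integer percent, halves away from zero.

    Reports follow the convention of printed operating characteristics
    (e.g. 15/17 = 88.2% -> 88, 37/47 = 78.7% -> 79).
    """
    import math

    return int(math.floor(fraction * 100 + 0.5))
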