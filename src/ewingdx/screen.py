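"""Transcriptome-wide two-criterion marker screen.

For a reference entity (Ewing sarcoma) against every other entity in a
labeled log2 expression matrix, the screen computes

1. the pairwise expression ratio (ER) of every gene as the difference
   of entity medians on the log2 scale, thresholded on the *minimum*
   over all comparison entities (``min log2 ER > 2``, i.e. at least
   4-fold over every other entity), and
2. an unpaired two-tailed equal-variance Student's t-test per pairwise
   comparison, Bonferroni-adjusted, requiring the adjusted p to clear
   alpha in *every* comparison (``max adjusted p < 0.05``).

The intersection of the two gene lists is the set of candidate
diagnostic markers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import LabeledExpressionMatrix, ValidationError

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScreenThresholds:
    """Thresholds and conventions of the two-criterion screen.

    ``er_min`` is in log2 units (default 2, i.e. 4-fold); both
    inequalities are strict.  ``family_policy`` sets the Bonferroni
    family size: ``per_comparison_genes`` (default) multiplies each raw
    p by the number of genes, applied within each pairwise comparison;
    ``genes_times_entities`` multiplies by genes x comparisons.
    ``input_scale`` declares the matrix scale: ``log2`` (RMA-like,
    default) computes the ER as a median difference; ``linear`` takes
    log2 of the median ratio instead.
    """

    er_min: float = 2.0
    alpha: float = 0.05
    family_policy: str = "per_comparison_genes"
    input_scale: str = "log2"

    def __post_init__(self) -> None:
        if self.er_min <= 0:
            raise ValidationError("er_min must be positive")
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must lie in (0, 1)")
        if self.family_policy not in ("per_comparison_genes", "genes_times_entities"):
            raise ValidationError(f"unknown family policy {self.family_policy!r}")
        if self.input_scale not in ("log2", "linear"):
            raise ValidationError(f"unknown input scale {self.input_scale!r}")


@dataclass
class ERTable:
    """Per-gene, per-comparison-entity log2 expression ratios."""

    per_entity: pd.DataFrame  # genes x comparison entities
    min_log2_er: pd.Series
    reference: str


@dataclass
class PValueTable:
    """Raw and Bonferroni-adjusted p-values per pairwise comparison."""

    raw: pd.DataFrame  # genes x comparison entities
    adjusted: pd.DataFrame
    max_adjusted: pd.Series
    family_size: int
    reference: str


@dataclass
class ScreenResult:
    """Gene lists of the two criteria and their intersection."""

    er_pass: list[str]
    p_pass: list[str]
    intersection: list[str]
    er_table: ERTable
    p_table: PValueTable
    thresholds: ScreenThresholds

    def summary(self) -> dict:
        return {
            "n_er_pass": len(self.er_pass),
            "n_p_pass": len(self.p_pass),
            "n_intersection": len(self.intersection),
            "intersection": list(self.intersection),
            "er_min": self.thresholds.er_min,
            "alpha": self.thresholds.alpha,
            "family_policy": self.thresholds.family_policy,
            "family_size": self.p_table.family_size,
        }


def median_by_entity(matrix: LabeledExpressionMatrix) -> pd.DataFrame:
    """Median log2 expression per (gene, entity).

    Standard sample median: for even counts, the mean of the two
    central order statistics.
    """
    return matrix.values.T.groupby(matrix.entities, sort=False).median().T


def log2_expression_ratios(medians: pd.DataFrame, reference: str,
                           input_scale: str = "log2") -> ERTable:
    """Log2 ER of the reference entity over each comparison entity.

    On the log2 scale the ER is simply the difference of medians
    (reference minus entity); for linear-scale input it is the log2 of
    the median ratio.  Antisymmetric under swapping reference and
    comparison entity.
    """
    if reference not in medians.columns:
        raise ValidationError(f"reference entity {reference!r} not in median table")
    others = [e for e in medians.columns if e != reference]
    if input_scale == "log2":
        er = medians[others].rsub(medians[reference], axis=0)
    else:
        er = np.log2(medians[others].rdiv(medians[reference], axis=0))
    return ERTable(per_entity=er, min_log2_er=er.min(axis=1), reference=reference)


def _ttest_vs_reference(ref: np.ndarray, ent: np.ndarray) -> np.ndarray:
    """Equal-variance two-sample t-test per gene (rows); two-tailed p.

    Degenerate genes (zero pooled variance) get p = 1 when the group
    means agree and p = 0 otherwise, with a log note.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(ref, ent, axis=1, equal_var=True)
    p = np.asarray(res.pvalue, dtype=float)
    bad = ~np.isfinite(p)
    if bad.any():
        same = np.isclose(ref[bad].mean(axis=1), ent[bad].mean(axis=1))
        p[bad] = np.where(same, 1.0, 0.0)
        if (~same).any():
            log.warning("%d gene(s) with zero pooled variance and unequal means; "
                        "p set to 0", int((~same).sum()))
    return p


def pairwise_tests(matrix: LabeledExpressionMatrix, reference: str,
                   thresholds: ScreenThresholds | None = None) -> PValueTable:
    """Raw and Bonferroni-adjusted p-values, reference vs every entity."""
    thresholds = thresholds or ScreenThresholds()
    entity_names = matrix.entity_names
    if reference not in entity_names:
        raise ValidationError(f"reference entity {reference!r} absent from matrix")
    others = [e for e in entity_names if e != reference]
    if not others:
        raise ValidationError("need at least one comparison entity")

    ref_vals = matrix.samples_of(reference).to_numpy()
    raw = {}
    for entity in others:
        raw[entity] = _ttest_vs_reference(ref_vals, matrix.samples_of(entity).to_numpy())
    raw_df = pd.DataFrame(raw, index=matrix.gene_ids)

    n_genes = len(matrix.gene_ids)
    if thresholds.family_policy == "per_comparison_genes":
        family = n_genes
    else:
        family = n_genes * len(others)
    adjusted = (raw_df * family).clip(upper=1.0)
    return PValueTable(raw=raw_df, adjusted=adjusted,
                       max_adjusted=adjusted.max(axis=1),
                       family_size=family, reference=reference)


def two_criterion_screen(matrix: LabeledExpressionMatrix, reference: str,
                         thresholds: ScreenThresholds | None = None) -> ScreenResult:
    """Run both criteria and intersect the passing gene lists.

    ``er_pass``: genes whose minimum log2 ER over all comparison
    entities strictly exceeds ``er_min``.  ``p_pass``: genes whose
    Bonferroni-adjusted p is strictly below ``alpha`` in every pairwise
    comparison.  All lists follow input gene order.
    """
    thresholds = thresholds or ScreenThresholds()
    medians = median_by_entity(matrix)
    er = log2_expression_ratios(medians, reference, thresholds.input_scale)
    pvals = pairwise_tests(matrix, reference, thresholds)

    er_mask = er.min_log2_er > thresholds.er_min
    p_mask = pvals.max_adjusted < thresholds.alpha
    er_pass = list(matrix.gene_ids[er_mask])
    p_pass = list(matrix.gene_ids[p_mask])
    both = set(er_pass) & set(p_pass)
    intersection = [g for g in matrix.gene_ids if g in both]
    log.info("screen: %d ER-passing, %d test-passing, %d intersection",
             len(er_pass), len(p_pass), len(intersection))
    return ScreenResult(er_pass=er_pass, p_pass=p_pass, intersection=intersection,
                        er_table=er, p_table=pvals, thresholds=thresholds)


def volcano_table(er: ERTable, pvals: PValueTable, entity: str,
                  thresholds: ScreenThresholds | None = None) -> pd.DataFrame:
    """Per-gene (log2 ER, adjusted p, pass flag) for one comparison.

    The pass flag marks genes clearing both thresholds in this single
    pairwise comparison, as plotted in a volcano plot.
    """
    thresholds = thresholds or ScreenThresholds()
    if entity not in er.per_entity.columns:
        raise ValidationError(f"entity {entity!r} absent from ER table")
    if entity not in pvals.adjusted.columns:
        raise ValidationError(f"entity {entity!r} absent from p-value table")
    out = pd.DataFrame({
        "log2_er": er.per_entity[entity],
        "adjusted_p": pvals.adjusted[entity],
    })
    out["passes"] = (out["log2_er"] > thresholds.er_min) & \
        (out["adjusted_p"] < thresholds.alpha)
    return out
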