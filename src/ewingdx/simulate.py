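"""Synthetic inputs for the marker-discovery pipeline.

Two generators stand in for the study data that cannot be shipped:

* :func:`generate_expression_cohort` builds a multi-entity log2
  expression matrix (RMA-like scale) with *planted* marker genes of
  three classes - genes passing only the expression-ratio criterion,
  genes passing only the significance criterion, and true markers
  passing both - so the two-criterion screen has a known answer.
* :func:`generate_tma_fixture` builds a deterministic tissue-microarray
  scoring table whose per-stratum composition follows the published
  TMA (47 Ewing sarcoma, 17 Ewing-like sarcoma, 110 other tumors; 174
  samples in 12 strata) and whose per-marker IRS assignments are
  calibrated so that every published operating characteristic (CD99
  sensitivity, OR/AND-rule specificity, ...) is reproduced exactly by
  counting.  :func:`sample_tma` adds grade-preserving jitter for
  property tests.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import (
    DEFAULT_MARKERS,
    REFERENCE_ENTITY,
    LabeledExpressionMatrix,
    TMADataset,
    ValidationError,
)

# ---------------------------------------------------------------------------
# rosters
# ---------------------------------------------------------------------------

#: the 20 comparison entities of the expression screen (morphological
#: mimics and entities of differential-diagnostic relevance)
DEFAULT_COMPARISON_ENTITIES = (
    "CIC-DUX4 sarcoma",
    "BCOR-CCNB3 sarcoma",
    "EWSR1-NFATc2 sarcoma",
    "Alveolar rhabdomyosarcoma",
    "Embryonal rhabdomyosarcoma",
    "Neuroblastoma",
    "Ganglioneuroblastoma",
    "Osteosarcoma",
    "Synovial sarcoma",
    "Leiomyosarcoma",
    "Liposarcoma",
    "Nephroblastoma",
    "Alveolar soft part sarcoma",
    "Malignant fibrous histiocytoma",
    "MPNST",
    "DLBCL",
    "MALT lymphoma",
    "Burkitt lymphoma",
    "Extraskeletal myxoid chondrosarcoma",
    "Clear cell sarcoma",
)


@dataclass(frozen=True)
class EntityRoster:
    """Entities of a cohort with per-entity sample counts."""

    entries: tuple[tuple[str, int], ...]
    reference_entity: str = REFERENCE_ENTITY

    def __post_init__(self) -> None:
        names = [name for name, _ in self.entries]
        if len(set(names)) != len(names):
            raise ValidationError("entity names must be unique")
        if names.count(self.reference_entity) != 1:
            raise ValidationError(
                f"reference entity {self.reference_entity!r} must appear exactly once"
            )
        for name, n in self.entries:
            if n < 2:
                raise ValidationError(f"entity {name!r} needs >= 2 samples, got {n}")

    @property
    def total(self) -> int:
        return sum(n for _, n in self.entries)

    @property
    def names(self) -> list[str]:
        return [name for name, _ in self.entries]

    def size_of(self, entity: str) -> int:
        for name, n in self.entries:
            if name == entity:
                return n
        raise ValidationError(f"unknown entity: {entity!r}")


def default_expression_roster() -> EntityRoster:
    """21-entity roster: reference n=50, each comparison entity n=15.

    A desk-scale surrogate for the published 768-tumor cohort that keeps
    every pairwise t-test well powered at the planted effect sizes.
    """
    entries = [(REFERENCE_ENTITY, 50)]
    entries += [(name, 15) for name in DEFAULT_COMPARISON_ENTITIES]
    return EntityRoster(tuple(entries))


# ---------------------------------------------------------------------------
# planted expression cohort
# ---------------------------------------------------------------------------

FULL_MARKER_IDS = ("ATP1A1", "BCL11B", "GLG1")


def _entity_tag(name: str, idx: int) -> str:
    """Short unique sample-id prefix: roster position + name stem."""
    stem = "".join(c for c in name.upper() if c.isalnum())[:8]
    return f"E{idx:02d}{stem}"


@dataclass(frozen=True)
class ClassEffect:
    """Per-class planted effect: log2 shift in the reference entity and
    the within-entity spread of reference samples for that class."""

    log2_shift: float
    within_entity_sd: float


@dataclass(frozen=True)
class PlantedDesign:
    """Design of the planted screening cohort.

    Defaults reproduce the published Venn structure: of ``n_genes``
    measured genes, 51 clear the minimum log2 expression-ratio > 2
    criterion (48 ``er_only`` + 3 full markers), 10 clear the
    Bonferroni-corrected significance criterion (7 ``p_only`` + the
    same 3), and exactly the 3 full markers clear both.

    ``er_only`` genes are strongly overexpressed on the median but too
    heterogeneous for significance: their reference samples follow a
    symmetric contamination model - most samples near the shifted mean
    (sd 0.5) with an equal number of extreme outliers at +/- 2 x
    ``within_entity_sd`` - which keeps the sample variance near
    ``within_entity_sd**2`` (t-test non-significant) while the median
    stays tightly at the shift (ratio criterion stable for any seed).
    """

    n_genes: int = 19_702
    roster: EntityRoster = field(default_factory=default_expression_roster)
    n_full_markers: int = 3
    n_er_only: int = 48
    n_p_only: int = 7
    full_marker_effect: ClassEffect = ClassEffect(4.5, 0.5)
    er_only_effect: ClassEffect = ClassEffect(3.0, 4.0)
    p_only_effect: ClassEffect = ClassEffect(1.2, 0.15)
    background_sd: float = 0.5
    baseline_mean: float = 6.0
    er_only_outlier_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        for n in (self.n_full_markers, self.n_er_only, self.n_p_only):
            if n < 0:
                raise ValidationError("class counts must be non-negative")
        if self.n_full_markers + self.n_er_only + self.n_p_only >= self.n_genes:
            raise ValidationError("class counts must sum to less than n_genes")
        if self.n_er_only and self.er_only_effect.log2_shift <= 2:
            raise ValidationError("er_only log2 shift must exceed 2")
        if self.n_p_only and self.p_only_effect.log2_shift >= 2:
            raise ValidationError("p_only log2 shift must stay below 2")
        if self.full_marker_effect.log2_shift <= 2:
            raise ValidationError("full-marker log2 shift must exceed 2 with margin")


def generate_expression_cohort(design: PlantedDesign) -> LabeledExpressionMatrix:
    """Simulate a labeled log2 expression cohort with planted markers.

    Background genes are N(baseline, background_sd^2) in every entity.
    Planted genes additionally receive their class's log2 shift in the
    reference entity only.  Fully reproducible from ``design.seed``.
    """
    rng = np.random.default_rng(design.seed)
    roster = design.roster

    sample_ids: list[str] = []
    entity_labels: list[str] = []
    for idx, (name, n) in enumerate(roster.entries):
        tag = _entity_tag(name, idx)
        sample_ids += [f"{tag}_{i + 1:03d}" for i in range(n)]
        entity_labels += [name] * n
    entities = pd.Series(entity_labels, index=sample_ids, name="entity")
    n_samples = len(sample_ids)

    values = rng.normal(design.baseline_mean, design.background_sd,
                        size=(design.n_genes, n_samples))

    # deterministic planted positions: spread through the gene list
    n_planted = design.n_full_markers + design.n_er_only + design.n_p_only
    planted_pos = rng.choice(design.n_genes, size=n_planted, replace=False)
    full_pos = planted_pos[: design.n_full_markers]
    er_pos = planted_pos[design.n_full_markers:
                         design.n_full_markers + design.n_er_only]
    p_pos = planted_pos[design.n_full_markers + design.n_er_only:]

    ref_mask = entities.to_numpy() == roster.reference_entity
    ref_cols = np.flatnonzero(ref_mask)
    n_ref = len(ref_cols)

    def plant_normal(pos: np.ndarray, eff: ClassEffect) -> None:
        shifted = rng.normal(design.baseline_mean + eff.log2_shift,
                             eff.within_entity_sd, size=(len(pos), n_ref))
        values[np.ix_(pos, ref_cols)] = shifted

    plant_normal(full_pos, design.full_marker_effect)
    plant_normal(p_pos, design.p_only_effect)

    # er_only: symmetric contamination around the shift (see class docstring)
    if len(er_pos):
        eff = design.er_only_effect
        n_out = int(round(design.er_only_outlier_fraction * n_ref))
        n_out -= n_out % 2  # symmetric pairs keep the mean centred
        core = rng.normal(design.baseline_mean + eff.log2_shift, 0.5,
                          size=(len(er_pos), n_ref))
        for row, pos in enumerate(er_pos):
            out_cols = rng.choice(n_ref, size=n_out, replace=False)
            half = n_out // 2
            core[row, out_cols[:half]] += 2.0 * eff.within_entity_sd
            core[row, out_cols[half:]] -= 2.0 * eff.within_entity_sd
        values[np.ix_(er_pos, ref_cols)] = core

    gene_ids = np.array([f"g{i + 1:05d}" for i in range(design.n_genes)], dtype=object)
    for gid, pos in zip(FULL_MARKER_IDS, full_pos):
        gene_ids[pos] = gid

    truth = np.full(design.n_genes, "background", dtype=object)
    truth[full_pos] = "full_marker"
    truth[er_pos] = "er_only"
    truth[p_pos] = "p_only"

    return LabeledExpressionMatrix(
        values=pd.DataFrame(values, index=pd.Index(gene_ids, name="gene"),
                            columns=sample_ids),
        entities=entities,
        truth=pd.Series(truth, index=pd.Index(gene_ids, name="gene"), name="class"),
    )


# ---------------------------------------------------------------------------
# calibrated TMA fixture
# ---------------------------------------------------------------------------

EWING_LIKE_ENTITY = "Ewing-like sarcoma"

#: the published TMA composition: 12 strata, 174 samples
DEFAULT_TMA_ROSTER = EntityRoster(
    (
        (REFERENCE_ENTITY, 47),
        ("Alveolar Soft Part Sarcoma", 3),
        (EWING_LIKE_ENTITY, 17),
        ("Ganglioneuroblastoma", 7),
        ("Leiomyosarcoma", 5),
        ("Liposarcoma", 19),
        ("Malignant Fibrous Histiocytoma", 3),
        ("Nephroblastoma", 21),
        ("Neuroblastoma", 16),
        ("Osteosarcoma", 15),
        ("Rhabdomyosarcoma", 11),
        ("Synovial sarcoma", 10),
    )
)

#: representative IRS per staining grade; all values are attainable
#: percentage x intensity products and sit away from the cut-offs 2 and 9
DEFAULT_IRS_VALUES = {"high": 12, "moderate": 6, "low": 2, "negative": 0}


@dataclass(frozen=True)
class GroupCounts:
    """Marker-event counts for one TMA group (sizes, not probabilities).

    ``both_high``/``bcl11b_only``/``glg1_only`` partition the samples
    with BCL11B and/or GLG1 IRS above the high cut-off (9);
    ``atp1a1_high`` counts ATP1A1 IRS > 9; ``cd99_positive`` counts
    CD99 IRS above the screening cut-off (2), stained at the group's
    ``cd99_level`` ("high" or "moderate")."""

    both_high: int
    bcl11b_only: int
    glg1_only: int
    atp1a1_high: int
    cd99_positive: int
    cd99_level: str = "high"


@dataclass(frozen=True)
class TMACalibration:
    """Deterministic per-group event counts for the TMA fixture.

    The defaults are calibrated so that direct counting on the fixture
    reproduces every published operating characteristic:

    * CD99 > 2 sensitivity 47/47 = 100%
    * OR-rule (BCL11B > 9 or GLG1 > 9): sensitivity 37/47 -> 79%,
      specificity 122/127 = 96.1%
    * AND-rule (both > 9): specificity 126/127 = 99.2%
    * ATP1A1 > 9 specificity 114/127 -> 90%
    * Ewing-like CD99-positive fraction 15/17 -> 88%, with no
      Ewing-like sample high for both BCL11B and GLG1.
    """

    roster: EntityRoster = DEFAULT_TMA_ROSTER
    ewing: GroupCounts = GroupCounts(both_high=20, bcl11b_only=10, glg1_only=7,
                                     atp1a1_high=30, cd99_positive=47,
                                     cd99_level="high")
    ewing_like: GroupCounts = GroupCounts(both_high=0, bcl11b_only=1, glg1_only=1,
                                          atp1a1_high=0, cd99_positive=15,
                                          cd99_level="high")
    other: GroupCounts = GroupCounts(both_high=1, bcl11b_only=1, glg1_only=1,
                                     atp1a1_high=13, cd99_positive=60,
                                     cd99_level="moderate")
    ewing_like_entity: str = EWING_LIKE_ENTITY
    irs_values: tuple[tuple[str, int], ...] = tuple(DEFAULT_IRS_VALUES.items())
    markers: tuple[str, ...] = DEFAULT_MARKERS
    high_cutoff: int = 9
    cd99_cutoff: int = 2

    def irs_of(self, grade: str) -> int:
        return dict(self.irs_values)[grade]

    def group_sizes(self) -> dict[str, int]:
        ref = self.roster.reference_entity
        sizes = {"ewing": 0, "ewing_like": 0, "other": 0}
        for name, n in self.roster.entries:
            if name == ref:
                sizes["ewing"] += n
            elif name == self.ewing_like_entity:
                sizes["ewing_like"] += n
            else:
                sizes["other"] += n
        return sizes

    def __post_init__(self) -> None:
        sizes = self.group_sizes()
        for group, counts in (("ewing", self.ewing),
                              ("ewing_like", self.ewing_like),
                              ("other", self.other)):
            size = sizes[group]
            n_bg_high = counts.both_high + counts.bcl11b_only + counts.glg1_only
            for label, k in (("BCL11B/GLG1-high", n_bg_high),
                             ("ATP1A1-high", counts.atp1a1_high),
                             ("CD99-positive", counts.cd99_positive)):
                if not 0 <= k <= size:
                    raise ValidationError(
                        f"{group}: {label} count {k} exceeds stratum size {size}"
                    )
            if counts.both_high > n_bg_high:  # pragma: no cover - arithmetic guard
                raise ValidationError("both-high count exceeds either-high count")
            if counts.cd99_level not in dict(self.irs_values):
                raise ValidationError(f"unknown CD99 grade {counts.cd99_level!r}")
        if self.irs_of("high") <= self.high_cutoff:
            raise ValidationError("'high' IRS must exceed the high cut-off")


def _group_scores(counts: GroupCounts, size: int, cal: TMACalibration) -> np.ndarray:
    """IRS assignment for one group, shape (size, 4) in marker order
    ATP1A1, BCL11B, GLG1, CD99.  The first samples of the group carry
    the events, nested consistently: both-high first, then BCL11B-only,
    then GLG1-only.  Non-event samples show "low" (IRS 2) background
    staining regardless of entity, so no marker separates the groups
    below the calibrated cut-offs."""
    high = cal.irs_of("high")
    scores = np.full((size, 4), cal.irs_of("low"), dtype=int)

    k = counts.both_high
    scores[:k, 1] = high
    scores[:k, 2] = high
    scores[k:k + counts.bcl11b_only, 1] = high
    k += counts.bcl11b_only
    scores[k:k + counts.glg1_only, 2] = high

    scores[: counts.atp1a1_high, 0] = high

    cd99_val = cal.irs_of(counts.cd99_level)
    scores[: counts.cd99_positive, 3] = cd99_val
    scores[counts.cd99_positive:, 3] = cal.irs_of("negative")
    return scores


def generate_tma_fixture(calibration: TMACalibration | None = None) -> TMADataset:
    """Deterministic TMA dataset satisfying every calibrated event count.

    No sampling is involved: within each group the first samples (in
    roster order) carry the events; all non-event marker values show
    entity-independent "low" background staining (CD99-negative
    samples are "negative").
    """
    cal = calibration or TMACalibration()
    sizes = cal.group_sizes()
    group_tables = {
        "ewing": _group_scores(cal.ewing, sizes["ewing"], cal),
        "ewing_like": _group_scores(cal.ewing_like, sizes["ewing_like"], cal),
        "other": _group_scores(cal.other, sizes["other"], cal),
    }
    cursor = {g: 0 for g in group_tables}

    rows, sample_ids, entity_labels = [], [], []
    ref = cal.roster.reference_entity
    for idx, (name, n) in enumerate(cal.roster.entries):
        if name == ref:
            group = "ewing"
        elif name == cal.ewing_like_entity:
            group = "ewing_like"
        else:
            group = "other"
        start = cursor[group]
        rows.append(group_tables[group][start:start + n])
        cursor[group] = start + n
        tag = _entity_tag(name, idx)
        sample_ids += [f"{tag}_{i + 1:03d}" for i in range(n)]
        entity_labels += [name] * n

    scores = pd.DataFrame(np.vstack(rows), index=pd.Index(sample_ids, name="sample_id"),
                          columns=list(cal.markers))
    entities = pd.Series(entity_labels, index=scores.index, name="entity")
    return TMADataset(scores=scores, entities=entities, reference_entity=ref)


def sample_tma(calibration: TMACalibration | None = None, *, seed: int = 0,
               noise: float = 0.0) -> TMADataset:
    """Stochastic variant of the fixture with grade-preserving jitter.

    Each IRS is perturbed by rounded Gaussian noise but clipped to the
    band delimited by the calibrated cut-offs (2 and 9) that contains
    its fixture value, so no jitter ever moves a sample across a
    calibrated event cut-off; with ``noise == 0`` the fixture is
    returned unchanged.
    """
    if noise < 0:
        raise ValidationError("noise must be non-negative")
    cal = calibration or TMACalibration()
    base = generate_tma_fixture(cal)
    if noise == 0:
        return base
    rng = np.random.default_rng(seed)
    values = base.scores.to_numpy().astype(float)
    jittered = np.rint(values + rng.normal(0.0, noise, size=values.shape)).astype(int)

    cuts = sorted({cal.cd99_cutoff, cal.high_cutoff})
    edges = [0, *[c for c in cuts if 0 < c < 12], 12]
    lo = np.zeros_like(values, dtype=int)
    hi = np.full_like(lo, 12)
    for a, b in itertools.pairwise([-1, *edges[1:-1], 12]):
        band = (values > a) & (values <= b)
        lo[band] = a + 1
        hi[band] = b
    jittered = np.clip(jittered, lo, hi)
    scores = pd.DataFrame(jittered, index=base.scores.index,
                          columns=base.scores.columns)
    return TMADataset(scores=scores, entities=base.entities,
                      reference_entity=base.reference_entity)
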