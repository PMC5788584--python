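"""Exhaustive marker-combination and cut-off search.

Enumerates every non-empty subset of the marker panel, every integer
cut-off assignment from a grid, and every requested combiner (OR -
"and/or" rules - and AND - "both high" rules), evaluates sensitivity
and specificity for each, and selects the best rule under a
specificity floor.  Selection is lexicographic: rules clearing the
floor, then maximum sensitivity, then maximum discriminability, then
fewest markers, then smallest cut-offs.

Discriminability - the separation between rule-positive and
rule-negative samples - is the mean over rule atoms of
``mean(IRS - c | called positive) - mean(IRS - c | called negative)``
on that atom's marker; it is 0 when either side is empty.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

from .containers import Performance, TMADataset, ValidationError
from .ihc import _performance_from_calls

log = logging.getLogger(__name__)

DEFAULT_GRID = range(-1, 13)


@dataclass(frozen=True, order=True)
class MarkerCutoff:
    """One rule atom: a sample fires iff its IRS on ``marker`` is
    strictly greater than ``cutoff`` (-1 = always, 12 = never)."""

    marker: str
    cutoff: int

    def __post_init__(self) -> None:
        if not -1 <= self.cutoff <= 12:
            raise ValidationError(f"cutoff must be in [-1, 12], got {self.cutoff}")


@dataclass(frozen=True)
class DiagnosticRule:
    """A set of marker/cut-off atoms combined by OR (default) or AND."""

    atoms: tuple[MarkerCutoff, ...]
    combiner: str = "OR"

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValidationError("a rule needs at least one atom")
        markers = [a.marker for a in self.atoms]
        if len(set(markers)) != len(markers):
            raise ValidationError("markers within a rule must be distinct")
        if self.combiner not in ("OR", "AND"):
            raise ValidationError(f"combiner must be OR or AND, got {self.combiner!r}")

    def describe(self) -> str:
        sep = " or " if self.combiner == "OR" else " and "
        return sep.join(f"{a.marker} > {a.cutoff}" for a in self.atoms)

    def sort_key(self) -> tuple:
        return (len(self.atoms), tuple(sorted((a.marker, a.cutoff) for a in self.atoms)),
                self.combiner)

    def as_dict(self) -> dict:
        return {"atoms": [{"marker": a.marker, "cutoff": a.cutoff} for a in self.atoms],
                "combiner": self.combiner}


@dataclass(frozen=True)
class SearchCriteria:
    """Selection criteria: specificity floor (strict, default > 0.95),
    then sensitivity, discriminability, parsimony, smallest cut-offs.

    A floor >= 1 is permitted and unsatisfiable (specificity never
    strictly exceeds 1), making the search report no best rule.
    """

    specificity_floor: float = 0.95

    def __post_init__(self) -> None:
        if self.specificity_floor <= 0:
            raise ValidationError("specificity floor must be positive")


@dataclass
class EvaluatedRule:
    rule: DiagnosticRule
    performance: Performance
    discriminability: float


@dataclass
class SearchReport:
    """All evaluated rules plus the selected best rule (or None)."""

    evaluated: list[EvaluatedRule]
    best: EvaluatedRule | None
    n_rules_evaluated: int
    criteria: SearchCriteria

    def as_dict(self, max_rules: int | None = 100) -> dict:
        ranked = sorted(
            self.evaluated,
            key=lambda ev: (-ev.performance.sensitivity, -ev.discriminability,
                            *ev.rule.sort_key()),
        )
        if max_rules is not None:
            ranked = ranked[:max_rules]
        return {
            "n_rules_evaluated": self.n_rules_evaluated,
            "specificity_floor": self.criteria.specificity_floor,
            "best": None if self.best is None else {
                "rule": self.best.rule.as_dict(),
                "description": self.best.rule.describe(),
                "performance": self.best.performance.as_dict(),
                "discriminability": self.best.discriminability,
            },
            "rules": [
                {"rule": ev.rule.as_dict(), "performance": ev.performance.as_dict(),
                 "discriminability": ev.discriminability}
                for ev in ranked
            ],
        }


def _rule_calls(tma: TMADataset, rule: DiagnosticRule) -> np.ndarray:
    fires = [tma.irs(a.marker) > a.cutoff for a in rule.atoms]
    op = np.logical_or if rule.combiner == "OR" else np.logical_and
    calls = fires[0]
    for f in fires[1:]:
        calls = op(calls, f)
    return calls


def evaluate_rule(tma: TMADataset, rule: DiagnosticRule) -> Performance:
    """Confusion counts of a rule: OR fires on any atom, AND on all."""
    return _performance_from_calls(_rule_calls(tma, rule),
                                   tma.is_reference.to_numpy())


def discriminability(tma: TMADataset, rule: DiagnosticRule) -> float:
    """Mean signed IRS margin separation between called-positive and
    called-negative samples; 0 if either side is empty."""
    calls = _rule_calls(tma, rule)
    n_pos = int(calls.sum())
    if n_pos == 0 or n_pos == len(calls):
        log.debug("degenerate rule %s: one side empty", rule.describe())
        return 0.0
    total = 0.0
    for atom in rule.atoms:
        margin = tma.irs(atom.marker).astype(float) - atom.cutoff
        total += margin[calls].mean() - margin[~calls].mean()
    return total / len(rule.atoms)


def n_enumerated_rules(n_markers: int, grid_size: int, n_combiners: int) -> int:
    """Closed-form size of the enumeration space:
    |combiners| x sum_k C(m, k) * g^k over non-empty subset sizes k."""
    from math import comb

    return n_combiners * sum(
        comb(n_markers, k) * grid_size ** k for k in range(1, n_markers + 1)
    )


def enumerate_rules(markers: Sequence[str], grid: Sequence[int] = DEFAULT_GRID,
                    combiners: Sequence[str] = ("OR", "AND")) -> Iterator[DiagnosticRule]:
    """Yield every rule exactly once, in deterministic order
    (subset size, then lexicographic subsets, cut-offs, combiners)."""
    if not markers:
        raise ValidationError("need at least one marker")
    grid = list(grid)
    if not grid:
        raise ValidationError("cut-off grid must not be empty")
    markers = list(markers)
    for k in range(1, len(markers) + 1):
        for subset in itertools.combinations(sorted(markers), k):
            for cutoffs in itertools.product(grid, repeat=k):
                for combiner in combiners:
                    yield DiagnosticRule(
                        atoms=tuple(MarkerCutoff(m, c) for m, c in zip(subset, cutoffs)),
                        combiner=combiner,
                    )


def exhaustive_search(tma: TMADataset, markers: Sequence[str],
                      criteria: SearchCriteria | None = None,
                      grid: Sequence[int] = DEFAULT_GRID,
                      combiners: Sequence[str] = ("OR", "AND"),
                      keep_evaluated: bool = True) -> SearchReport:
    """Evaluate every enumerated rule and select the best one.

    Best = among rules with specificity strictly above the floor, the
    one maximizing (sensitivity, discriminability), tie-broken by
    fewest markers, then lexicographically smallest (marker, cut-off)
    atoms, then OR before AND.  ``None`` if no rule clears the floor.
    """
    criteria = criteria or SearchCriteria()
    is_ref = tma.is_reference.to_numpy()
    if not is_ref.any() or is_ref.all():
        raise ValidationError("need at least one reference and one other sample")

    grid = list(grid)
    # precomputed atom calls: marker -> cutoff -> boolean sample vector
    atom_calls = {
        m: {c: tma.irs(m) > c for c in grid} for m in dict.fromkeys(markers)
    }

    evaluated: list[EvaluatedRule] = []
    best: EvaluatedRule | None = None
    best_key: tuple | None = None
    n_rules = 0
    for rule in enumerate_rules(markers, grid, combiners):
        n_rules += 1
        fires = [atom_calls[a.marker][a.cutoff] for a in rule.atoms]
        op = np.logical_or if rule.combiner == "OR" else np.logical_and
        calls = fires[0]
        for f in fires[1:]:
            calls = op(calls, f)
        perf = _performance_from_calls(calls, is_ref)

        n_pos = perf.tp + perf.fp
        if n_pos == 0 or n_pos == perf.n:
            disc = 0.0
        else:
            disc = 0.0
            for atom in rule.atoms:
                margin = tma.irs(atom.marker).astype(float) - atom.cutoff
                disc += margin[calls].mean() - margin[~calls].mean()
            disc /= len(rule.atoms)

        ev = EvaluatedRule(rule=rule, performance=perf, discriminability=disc)
        if keep_evaluated:
            evaluated.append(ev)
        if perf.specificity > criteria.specificity_floor:
            key = (-perf.sensitivity, -disc, *rule.sort_key())
            if best_key is None or key < best_key:
                best, best_key = ev, key

    log.info("search: %d rules evaluated, best = %s", n_rules,
             best.rule.describe() if best else "none")
    return SearchReport(evaluated=evaluated, best=best,
                        n_rules_evaluated=n_rules, criteria=criteria)
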