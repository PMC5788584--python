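"""Independent brute-force reimplementations used as test oracles.

Everything here is written with explicit Python loops and textbook
formulas, deliberately avoiding the vectorized code paths of the
package, so that agreement between the two is informative.
"""

from __future__ import annotations

import itertools
import math
import statistics

from scipy.stats import t as t_dist


def ttest_equal_variance_p(a: list[float], b: list[float]) -> float:
    """Two-tailed equal-variance two-sample t-test, textbook formula."""
    n1, n2 = len(a), len(b)
    m1 = sum(a) / n1
    m2 = sum(b) / n2
    ss1 = sum((x - m1) ** 2 for x in a)
    ss2 = sum((x - m2) ** 2 for x in b)
    df = n1 + n2 - 2
    sp2 = (ss1 + ss2) / df
    if sp2 == 0:
        return 1.0 if m1 == m2 else 0.0
    t_stat = (m1 - m2) / math.sqrt(sp2 * (1 / n1 + 1 / n2))
    return 2 * t_dist.sf(abs(t_stat), df)


def brute_force_screen(values: dict[str, dict[str, list[float]]], reference: str,
                       er_min: float = 2.0, alpha: float = 0.05,
                       family_policy: str = "per_comparison_genes"):
    """Loop-based two-criterion screen.

    ``values``: gene id -> entity -> list of sample values.  Returns
    (er_pass, p_pass, intersection) in gene insertion order.
    """
    genes = list(values)
    entities = list(values[genes[0]])
    others = [e for e in entities if e != reference]
    n_genes = len(genes)
    family = n_genes if family_policy == "per_comparison_genes" \
        else n_genes * len(others)

    er_pass, p_pass = [], []
    for gene in genes:
        ref_median = statistics.median(values[gene][reference])
        min_er = min(ref_median - statistics.median(values[gene][e]) for e in others)
        if min_er > er_min:
            er_pass.append(gene)
        worst = 0.0
        for e in others:
            raw = ttest_equal_variance_p(values[gene][reference], values[gene][e])
            worst = max(worst, min(1.0, family * raw))
        if worst < alpha:
            p_pass.append(gene)
    intersection = [g for g in genes if g in er_pass and g in p_pass]
    return er_pass, p_pass, intersection


def naive_rule_performance(samples: list[dict], atoms: list[tuple[str, int]],
                           combiner: str) -> tuple[int, int, int, int]:
    """Per-sample loop evaluation of a rule.

    ``samples``: list of {"is_reference": bool, "irs": {marker: value}}.
    Returns (tp, fn, tn, fp).
    """
    tp = fn = tn = fp = 0
    for s in samples:
        fires = [s["irs"][m] > c for m, c in atoms]
        positive = any(fires) if combiner == "OR" else all(fires)
        if s["is_reference"]:
            tp += positive
            fn += not positive
        else:
            fp += positive
            tn += not positive
    return tp, fn, tn, fp


def naive_discriminability(samples: list[dict], atoms: list[tuple[str, int]],
                           combiner: str) -> float:
    pos, neg = [], []
    for s in samples:
        fires = [s["irs"][m] > c for m, c in atoms]
        (pos if (any(fires) if combiner == "OR" else all(fires)) else neg).append(s)
    if not pos or not neg:
        return 0.0
    total = 0.0
    for m, c in atoms:
        mp = sum(s["irs"][m] - c for s in pos) / len(pos)
        mn = sum(s["irs"][m] - c for s in neg) / len(neg)
        total += mp - mn
    return total / len(atoms)


def naive_exhaustive_search(samples: list[dict], markers: list[str],
                            grid: list[int], combiners: list[str],
                            floor: float):
    """Re-enumerate every rule, evaluate naively, sort naively.

    Returns (best_atoms, best_combiner, n_rules) where best_atoms is a
    sorted tuple of (marker, cutoff) pairs, or (None, None, n_rules).
    """
    candidates = []
    n_rules = 0
    for k in range(1, len(markers) + 1):
        for subset in itertools.combinations(sorted(markers), k):
            for cutoffs in itertools.product(grid, repeat=k):
                for combiner in combiners:
                    n_rules += 1
                    atoms = list(zip(subset, cutoffs))
                    tp, fn, tn, fp = naive_rule_performance(samples, atoms, combiner)
                    if tn + fp == 0 or tp + fn == 0:
                        continue
                    spec = tn / (tn + fp)
                    if spec > floor:
                        sens = tp / (tp + fn)
                        disc = naive_discriminability(samples, atoms, combiner)
                        candidates.append(
                            (-sens, -disc, len(atoms),
                             tuple(sorted(atoms)), combiner))
    if not candidates:
        return None, None, n_rules
    best = sorted(candidates)[0]
    return best[3], best[4], n_rules
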