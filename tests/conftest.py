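"""Shared fixtures: the calibrated TMA fixture, a small planted cohort,
and random-dataset builders for the oracle-equivalence tests."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ewingdx import (LabeledExpressionMatrix, PlantedDesign, TMADataset,
                     generate_expression_cohort, generate_tma_fixture)


@pytest.fixture(scope="session")
def tma() -> TMADataset:
    """The deterministic 174-sample TMA fixture (default calibration)."""
    return generate_tma_fixture()


@pytest.fixture(scope="session")
def default_cohort() -> LabeledExpressionMatrix:
    """The full default planted cohort (19,702 genes, 21 entities, seed 0)."""
    return generate_expression_cohort(PlantedDesign(seed=0))


def small_design(seed: int = 0, n_genes: int = 400) -> PlantedDesign:
    """Desk-scale planted design for fast unit tests (same class counts)."""
    return PlantedDesign(n_genes=n_genes, seed=seed)


def make_matrix(values: dict[str, dict[str, list[float]]]) -> LabeledExpressionMatrix:
    """Build a LabeledExpressionMatrix from gene -> entity -> samples."""
    genes = list(values)
    entities = list(values[genes[0]])
    cols, labels = [], []
    for e in entities:
        n = len(values[genes[0]][e])
        for i in range(n):
            cols.append(f"{e}_{i}")
            labels.append(e)
    data = {
        f"{e}_{i}": [values[g][e][i] for g in genes]
        for e in entities for i in range(len(values[genes[0]][e]))
    }
    frame = pd.DataFrame(data, index=genes)[cols]
    return LabeledExpressionMatrix(values=frame,
                                   entities=pd.Series(labels, index=cols))


def random_small_tma(rng: np.random.Generator, n_samples: int = 20,
                     markers: tuple[str, ...] = ("BCL11B", "GLG1")) -> TMADataset:
    """A random tiny TMA with at least one reference and one other sample."""
    n_ref = int(rng.integers(1, n_samples))
    labels = ["Ewing sarcoma"] * n_ref + ["Other tumor"] * (n_samples - n_ref)
    scores = pd.DataFrame(
        rng.integers(0, 13, size=(n_samples, len(markers))),
        index=[f"s{i:02d}" for i in range(n_samples)], columns=list(markers))
    return TMADataset(scores=scores,
                      entities=pd.Series(labels, index=scores.index))


def tma_as_records(tma: TMADataset) -> list[dict]:
    """Convert a TMADataset to the plain-record form the oracles use."""
    is_ref = tma.is_reference
    return [
        {"is_reference": bool(is_ref[sid]),
         "irs": {m: int(tma.scores.at[sid, m]) for m in tma.markers}}
        for sid in tma.scores.index
    ]
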