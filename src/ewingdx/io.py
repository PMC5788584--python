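"""Readers and writers for the package's plain-text formats.

Expression cohorts travel as a genes x samples TSV (gene ids in the
first column, sample ids in the header) plus a two-column sample
annotation TSV (sample_id, entity) and an optional gene-truth TSV.
TMA datasets travel as a wide CSV (sample_id, entity, one IRS column
per marker); a long per-core CSV (sample_id, entity, marker,
core_index, percent_positive, intensity_grade) is accepted as input
and aggregated to the wide form.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import LabeledExpressionMatrix, TMADataset, ValidationError
from .ihc import aggregate_cores, score_assessment


class ParseError(ValidationError):
    """A file violated its format contract; the message names the spot."""


# --------------------------------------------------------------------------
# expression matrices
# --------------------------------------------------------------------------

def write_expression(matrix: LabeledExpressionMatrix, matrix_path: str | Path,
                     annotation_path: str | Path,
                     truth_path: str | Path | None = None) -> None:
    matrix.values.to_csv(matrix_path, sep="\t", index_label="gene")
    matrix.entities.rename_axis("sample_id").to_frame("entity").to_csv(
        annotation_path, sep="\t")
    if truth_path is not None and matrix.truth is not None:
        matrix.truth.rename_axis("gene").to_frame("class").to_csv(
            truth_path, sep="\t")


def read_expression(matrix_path: str | Path, annotation_path: str | Path,
                    truth_path: str | Path | None = None) -> LabeledExpressionMatrix:
    """Read and validate a TSV expression matrix plus its annotation."""
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    if values.index.has_duplicates:
        dupes = values.index[values.index.duplicated()].unique()
        raise ParseError(f"{matrix_path}: duplicate gene id(s): {list(dupes[:5])}")
    non_numeric = values.select_dtypes(exclude="number").columns
    bad_cells = values.isna() | ~values.map(np.isreal) if len(non_numeric) else values.isna()
    if bad_cells.any().any():
        gene = bad_cells.any(axis=1).idxmax()
        col = bad_cells.loc[gene].idxmax()
        raise ParseError(
            f"{matrix_path}: non-numeric or blank cell at gene {gene!r}, sample {col!r}"
        )

    ann = pd.read_csv(annotation_path, sep="\t")
    if not {"sample_id", "entity"} <= set(ann.columns):
        raise ParseError(f"{annotation_path}: needs columns sample_id, entity")
    entities = ann.set_index("sample_id")["entity"]
    missing = values.columns.difference(entities.index)
    if len(missing):
        raise ParseError(
            f"{annotation_path}: no entity annotation for sample(s) {list(missing[:5])}"
        )

    truth = None
    if truth_path is not None:
        tr = pd.read_csv(truth_path, sep="\t")
        if not {"gene", "class"} <= set(tr.columns):
            raise ParseError(f"{truth_path}: needs columns gene, class")
        truth = tr.set_index("gene")["class"]
    try:
        return LabeledExpressionMatrix(values=values, entities=entities, truth=truth)
    except ValidationError as err:
        raise ParseError(f"{matrix_path}: {err}") from err


# --------------------------------------------------------------------------
# TMA datasets
# --------------------------------------------------------------------------

def write_tma(tma: TMADataset, path: str | Path) -> None:
    out = tma.scores.copy()
    out.insert(0, "entity", tma.entities)
    out.rename_axis("sample_id").to_csv(path)


def read_tma(path: str | Path, reference_entity: str = "Ewing sarcoma") -> TMADataset:
    """Read a wide TMA CSV; IRS cells are coerced to integers in [0, 12]."""
    df = pd.read_csv(path)
    if "sample_id" not in df.columns or "entity" not in df.columns:
        raise ParseError(f"{path}: needs columns sample_id, entity")
    df = df.set_index("sample_id")
    entities = df.pop("entity")
    markers = list(df.columns)
    if not markers:
        raise ParseError(f"{path}: no marker columns found")
    for marker in markers:
        col = pd.to_numeric(df[marker], errors="coerce")
        bad = col.isna() | (col != col.round()) | (col < 0) | (col > 12)
        if bad.any():
            sample = bad.idxmax()
            raise ParseError(
                f"{path}: invalid IRS {df.loc[sample, marker]!r} for sample "
                f"{sample!r}, marker {marker!r} (need integer 0-12)"
            )
        df[marker] = col.astype(int)
    return TMADataset(scores=df, entities=entities, reference_entity=reference_entity)


LONG_TMA_COLUMNS = ("sample_id", "entity", "marker", "core_index",
                    "percent_positive", "intensity_grade")


def read_tma_long(path: str | Path, reference_entity: str = "Ewing sarcoma",
                  aggregation: str = "median") -> TMADataset:
    """Read a long per-core CSV and aggregate cores per (sample, marker).

    Each row is one scored core: the raw percentage of positive cells
    and the intensity grade are turned into a per-core IRS, and the
    1-3 cores of a sample are combined with :func:`aggregate_cores`.
    """
    df = pd.read_csv(path)
    missing = set(LONG_TMA_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing column(s) {sorted(missing)}")
    try:
        df["irs"] = [
            score_assessment(float(p), int(i))
            for p, i in zip(df["percent_positive"], df["intensity_grade"])
        ]
    except (ValidationError, ValueError) as err:
        raise ParseError(f"{path}: {err}") from err

    agg = (
        df.groupby(["sample_id", "marker"], sort=False)["irs"]
        .apply(lambda s: aggregate_cores(list(s), method=aggregation))
        .unstack("marker")
    )
    entities = df.drop_duplicates("sample_id").set_index("sample_id")["entity"]
    if agg.isna().any().any():
        gene = agg.isna().any(axis=1).idxmax()
        raise ParseError(f"{path}: sample {gene!r} lacks cores for some marker")
    return TMADataset(scores=agg.astype(int), entities=entities.loc[agg.index],
                      reference_entity=reference_entity)


# --------------------------------------------------------------------------
# config / reports
# --------------------------------------------------------------------------

def load_config_file(path: str | Path) -> dict:
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def dump_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
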