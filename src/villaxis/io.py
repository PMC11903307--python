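"""Readers and writers for the on-disk bundle formats.

Transcripts travel as a plain CSV (x, y, gene, cell_id, nuclear); the
cell-by-gene matrix as MatrixMarket ``.mtx`` plus ``cells.csv`` / ``genes.csv``
sidecars; polyline annotations and polygon gates as labelme-style JSON
(``shapes`` with ``label``, ``points`` and ``shape_type``).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .core_data import (
    TRANSCRIPT_COLUMNS,
    CellTable,
    PolylineAnnotation,
    SampleBundle,
    SchemaError,
    validate_transcripts,
)

META_COLUMNS = ["x", "y", "nuclear_count", "cell_type", "cluster",
                "sample_id", "replicate_id"]


def write_transcripts(transcripts: pd.DataFrame, path) -> None:
    validate_transcripts(transcripts)
    out = transcripts[TRANSCRIPT_COLUMNS].copy()
    out["nuclear"] = out["nuclear"].astype(int)
    out.to_csv(path, index=False)


def read_transcripts(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"gene": str, "cell_id": str}, keep_default_na=False)
    missing = [c for c in TRANSCRIPT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    try:
        df["x"] = df["x"].astype(float)
        df["y"] = df["y"].astype(float)
    except ValueError as exc:  # report offending line (1-based, after header)
        for i, (x, y) in enumerate(zip(df["x"], df["y"])):
            try:
                float(x), float(y)
            except (TypeError, ValueError):
                raise SchemaError(f"{path}: malformed coordinates on data line {i + 1}") from exc
        raise
    df["nuclear"] = df["nuclear"].astype(int).astype(bool)
    return validate_transcripts(df[TRANSCRIPT_COLUMNS])


def write_cell_table(cells: CellTable, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    mat = scipy.sparse.csr_matrix(cells.counts.to_numpy())
    scipy.io.mmwrite(str(directory / "counts.mtx"), mat)
    pd.Series(cells.genes, name="gene").to_csv(directory / "genes.csv", index=False)
    cells.meta.rename_axis("cell_id").to_csv(directory / "cells.csv")


def read_cell_table(directory) -> CellTable:
    directory = Path(directory)
    mat = scipy.io.mmread(str(directory / "counts.mtx")).toarray().astype(np.int64)
    genes = pd.read_csv(directory / "genes.csv")["gene"].astype(str)
    meta = pd.read_csv(directory / "cells.csv", index_col="cell_id",
                       keep_default_na=False)
    meta.index = meta.index.astype(str)
    for col in ("x", "y"):
        meta[col] = meta[col].astype(float)
    if "nuclear_count" in meta:
        meta["nuclear_count"] = meta["nuclear_count"].astype(int)
    counts = pd.DataFrame(mat, index=meta.index, columns=pd.Index(genes, name="gene"))
    return CellTable(counts, meta)


def _shapes_to_json(shapes: list) -> dict:
    return {"version": "5.0.0", "flags": {}, "shapes": shapes,
            "imagePath": "", "imageData": None}


def write_polylines(annotations: dict, path) -> None:
    shapes = [
        {"label": ann.name, "points": np.asarray(ann.vertices, float).tolist(),
         "shape_type": "linestrip", "flags": {}}
        for ann in annotations.values()
    ]
    Path(path).write_text(json.dumps(_shapes_to_json(shapes), indent=1))


def read_polylines(path) -> dict:
    data = json.loads(Path(path).read_text())
    out = {}
    for shape in data.get("shapes", []):
        if shape.get("shape_type") not in ("linestrip", "line", "polyline"):
            continue
        out[shape["label"]] = PolylineAnnotation(shape["label"],
                                                 np.asarray(shape["points"], float))
    if not out:
        raise SchemaError(f"{path}: no polyline shapes found")
    return out


def write_gates(gates: dict, path) -> None:
    """Write named gate polygons (name -> (n, 2) vertex array) as labelme JSON."""
    shapes = [
        {"label": name, "points": np.asarray(vertices, float).tolist(),
         "shape_type": "polygon", "flags": {}}
        for name, vertices in gates.items()
    ]
    Path(path).write_text(json.dumps(_shapes_to_json(shapes), indent=1))


def read_gates(path) -> dict:
    data = json.loads(Path(path).read_text())
    out = {}
    for shape in data.get("shapes", []):
        if shape.get("shape_type") != "polygon":
            continue
        pts = np.asarray(shape["points"], float)
        if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
            raise SchemaError(f"{path}: gate {shape.get('label')!r} is not a polygon")
        out[shape["label"]] = pts
    if not out:
        raise SchemaError(f"{path}: no polygon shapes found")
    return out


def write_bundle(bundle: SampleBundle, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_transcripts(bundle.transcripts, directory / "transcripts.csv")
    write_cell_table(bundle.cells, directory)
    if bundle.annotations:
        write_polylines(bundle.annotations, directory / "annotations.json")
    if bundle.villus_labels is not None:
        vl = bundle.villus_labels.rename("villus_id").rename_axis("cell_id")
        vl.to_csv(directory / "villus_labels.csv")


def read_bundle(directory) -> SampleBundle:
    directory = Path(directory)
    transcripts = read_transcripts(directory / "transcripts.csv")
    cells = read_cell_table(directory)
    annotations = {}
    if (directory / "annotations.json").exists():
        annotations = read_polylines(directory / "annotations.json")
    villus_labels = None
    if (directory / "villus_labels.csv").exists():
        vl = pd.read_csv(directory / "villus_labels.csv", index_col="cell_id",
                         keep_default_na=False)
        vl.index = vl.index.astype(str)
        villus_labels = pd.to_numeric(vl["villus_id"], errors="coerce")
    return SampleBundle(transcripts, cells, annotations, villus_labels,
                        sample_id=directory.name)
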