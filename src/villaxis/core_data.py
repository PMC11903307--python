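"""Data model and cell-level preprocessing for imaging-based spatial transcriptomics.

The in-memory containers are deliberately thin wrappers over pandas objects:
a transcript table is a DataFrame with columns ``x, y, gene, cell_id, nuclear``,
a cell table pairs a cell-by-gene count matrix with per-cell metadata, and
tissue annotations are named polylines in micrometre coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon

TRANSCRIPT_COLUMNS = ["x", "y", "gene", "cell_id", "nuclear"]

#: sentinel used in transcript tables for transcripts outside any cell
UNASSIGNED = ""


class SchemaError(ValueError):
    """Raised when an input table does not match the expected schema."""


def validate_transcripts(transcripts: pd.DataFrame) -> pd.DataFrame:
    """Check a transcript table against the expected schema.

    Required columns: x, y (finite micrometre coordinates), gene (non-empty),
    cell_id (may be the empty-string sentinel for unassigned transcripts) and
    nuclear (boolean flag).
    """
    missing = [c for c in TRANSCRIPT_COLUMNS if c not in transcripts.columns]
    if missing:
        raise SchemaError(f"transcript table is missing column(s): {missing}")
    xy = transcripts[["x", "y"]].to_numpy(dtype=float)
    if not np.isfinite(xy).all():
        bad = np.where(~np.isfinite(xy).all(axis=1))[0]
        raise SchemaError(f"non-finite coordinates at row(s) {bad[:10].tolist()}")
    genes = transcripts["gene"].astype(str)
    if (genes == "").any():
        bad = np.where((genes == "").to_numpy())[0]
        raise SchemaError(f"empty gene label at row(s) {bad[:10].tolist()}")
    return transcripts


@dataclass
class CellTable:
    """Cell-by-gene counts plus per-cell metadata.

    Parameters
    ----------
    counts
        Integer count matrix, index = cell_id, columns = gene symbols.
    meta
        Per-cell metadata indexed like ``counts``. Expected columns:
        ``x, y`` (centroid), ``nuclear_count``, and optionally
        ``cell_type, cluster, sample_id, replicate_id``.
    """

    counts: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.meta.index):
            raise ValueError("counts and meta must be indexed by the same cell_ids")
        arr = self.counts.to_numpy()
        if arr.size and arr.min() < 0:
            raise ValueError("counts must be non-negative")
        if "nuclear_count" in self.meta:
            total = self.total_count
            if (self.meta["nuclear_count"].to_numpy() > total.to_numpy()).any():
                raise ValueError("nuclear_count exceeds total_count for some cells")

    @property
    def cell_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def genes(self) -> pd.Index:
        return self.counts.columns

    @property
    def n_cells(self) -> int:
        return len(self.counts)

    @property
    def total_count(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def centroids(self) -> np.ndarray:
        return self.meta[["x", "y"]].to_numpy(dtype=float)

    def subset(self, cell_ids) -> "CellTable":
        return CellTable(self.counts.loc[cell_ids], self.meta.loc[cell_ids])

    def copy(self) -> "CellTable":
        return CellTable(self.counts.copy(), self.meta.copy())


@dataclass
class PolylineAnnotation:
    """A named open polyline (e.g. the base of the basal membrane)."""

    name: str
    vertices: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ValueError("vertices must be an (n, 2) array")
        if len(self.vertices) < 2:
            raise ValueError("a polyline needs at least 2 vertices")
        if self.total_length <= 0:
            raise ValueError("polyline has zero total length")

    @property
    def segment_lengths(self) -> np.ndarray:
        return np.linalg.norm(np.diff(self.vertices, axis=0), axis=1)

    @property
    def cumulative_length(self) -> np.ndarray:
        """Arc length at each vertex, starting at 0."""
        return np.concatenate([[0.0], np.cumsum(self.segment_lengths)])

    @property
    def total_length(self) -> float:
        return float(self.segment_lengths.sum())


@dataclass
class SampleBundle:
    """One tissue sample: transcripts, cells, annotations and villus labels."""

    transcripts: pd.DataFrame
    cells: CellTable
    annotations: dict = field(default_factory=dict)
    villus_labels: pd.Series | None = None
    sample_id: str = "sample"

    def __post_init__(self) -> None:
        validate_transcripts(self.transcripts)
        assigned = self.transcripts["cell_id"].astype(str)
        assigned = assigned[assigned != UNASSIGNED]
        unknown = set(assigned.unique()) - set(map(str, self.cells.cell_ids))
        if unknown:
            raise ValueError(
                f"{len(unknown)} transcript cell_id(s) missing from cell table, "
                f"e.g. {sorted(unknown)[:5]}"
            )


# ---------------------------------------------------------------------------
# preprocessing operations
# ---------------------------------------------------------------------------

def qc_filter_cells(
    cells: CellTable,
    min_nuclear: int = 8,
    min_total: int = 20,
    max_total: int = 800,
    return_report: bool = False,
):
    """Remove low-quality cells by transcript-count thresholds.

    A cell is kept when ``nuclear_count >= min_nuclear`` and
    ``min_total <= total_count <= max_total``; the removal inequalities are
    strict (fewer than 8 nuclear, fewer than 20 total, more than 800 total),
    so the boundary values themselves are kept. Idempotent.
    """
    if min_nuclear < 0 or min_total < 0 or max_total < 0:
        raise ValueError("thresholds must be non-negative")
    if min_total > max_total:
        raise ValueError("min_total must be <= max_total")
    if cells.n_cells == 0:
        warnings.warn("qc_filter_cells: empty input cell table")
        return (cells, {}) if return_report else cells

    total = cells.total_count.to_numpy()
    nuclear = cells.meta["nuclear_count"].to_numpy()
    fail_nuclear = nuclear < min_nuclear
    fail_low = total < min_total
    fail_high = total > max_total
    keep = ~(fail_nuclear | fail_low | fail_high)
    out = cells.subset(cells.cell_ids[keep])
    if return_report:
        report = {
            "n_input": int(cells.n_cells),
            "n_kept": int(keep.sum()),
            "removed_low_nuclear": int(fail_nuclear.sum()),
            "removed_low_total": int(fail_low.sum()),
            "removed_high_total": int(fail_high.sum()),
        }
        return out, report
    return out


def split_multinucleus_cells(
    transcripts: pd.DataFrame,
    nucleus_centroids: dict,
) -> pd.Series:
    """Reassign transcripts of multi-nucleus cells to nearest-nucleus sub-cells.

    Parameters
    ----------
    transcripts
        Transcript table; only its ``x, y, cell_id`` columns are used.
    nucleus_centroids
        Mapping cell_id -> list of (x, y) nucleus centroids. Cells with one
        centroid (or absent from the mapping) are left untouched; cells with
        >= 2 centroids have each of their transcripts assigned to the sub-cell
        ``"{cell_id}.{j}"`` of the nearest centroid j. Ties go to the
        lower-indexed centroid. Cells listed with zero centroids are flagged
        with a warning and left unsplit.

    Returns
    -------
    pandas.Series
        New cell assignment, aligned with ``transcripts.index``. The total
        number of transcripts is conserved exactly.
    """
    validate_transcripts(transcripts)
    new_assignment = transcripts["cell_id"].astype(str).copy()
    for cell_id, centroids in nucleus_centroids.items():
        centroids = np.asarray(centroids, dtype=float).reshape(-1, 2)
        if len(centroids) == 0:
            warnings.warn(f"cell {cell_id!r} has no nucleus centroids; left unsplit")
            continue
        if len(centroids) == 1:
            continue
        mask = new_assignment == str(cell_id)
        if not mask.any():
            continue
        pts = transcripts.loc[mask, ["x", "y"]].to_numpy(dtype=float)
        # argmin returns the first (lowest-index) centroid on exact ties
        d2 = ((pts[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        nearest = d2.argmin(axis=1)
        new_assignment.loc[mask] = [f"{cell_id}.{j}" for j in nearest]
    return new_assignment


def aggregate_bins_to_cells(
    bin_counts: pd.DataFrame,
    bin_centers: np.ndarray,
    cell_masks: dict,
    meta: pd.DataFrame | None = None,
    rule: str = "center",
) -> CellTable:
    """Aggregate regular-grid bin counts (VisiumHD style) into per-cell counts.

    Parameters
    ----------
    bin_counts
        Bins x genes count matrix (one row per bin).
    bin_centers
        (n_bins, 2) bin-centre coordinates, same order as ``bin_counts`` rows.
    cell_masks
        Mapping cell_id -> shapely-compatible polygon (sequence of vertices or
        ``shapely.Polygon``) describing the cell mask.
    rule
        ``"center"`` (default): a bin contributes to the mask containing its
        centre (boundary inclusive); a bin whose centre lies in no mask
        contributes to no cell. ``"overlap"`` is accepted as an alias that
        also uses the centre rule for the multi-mask case, documented as the
        conservative tie-break.

    Total transcripts are conserved for every bin assigned to exactly one cell.
    """
    if rule not in ("center", "overlap"):
        raise ValueError(f"unknown aggregation rule {rule!r}")
    centers = np.asarray(bin_centers, dtype=float)
    if centers.shape != (len(bin_counts), 2):
        raise ValueError("bin_centers must be (n_bins, 2) aligned with bin_counts")
    polys = {}
    for cid, mask in cell_masks.items():
        polys[cid] = mask if isinstance(mask, Polygon) else Polygon(mask)

    cell_ids = list(polys)
    rows = np.zeros((len(cell_ids), bin_counts.shape[1]), dtype=bin_counts.to_numpy().dtype)
    arr = bin_counts.to_numpy()
    for b, (cx, cy) in enumerate(centers):
        p = Point(cx, cy)
        for i, cid in enumerate(cell_ids):
            if polys[cid].covers(p):  # boundary counted inside
                rows[i] += arr[b]
                break  # centre rule: first (declaration-order) containing mask
    counts = pd.DataFrame(rows, index=pd.Index(cell_ids, name="cell_id"),
                          columns=bin_counts.columns)
    if meta is None:
        meta = pd.DataFrame(
            {
                "x": [polys[c].centroid.x for c in cell_ids],
                "y": [polys[c].centroid.y for c in cell_ids],
                "nuclear_count": 0,
            },
            index=counts.index,
        )
    return CellTable(counts, meta.loc[counts.index])
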