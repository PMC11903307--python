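"""Immune allocation plots (IMAPs).

An IMAP positions every cell in a 2-D plane spanned by its crypt–villus
value (x) and a biexponential transform of its clipped epithelial-distance
z-score (y). Weighted Gaussian kernel density estimates over this plane
visualize where a population, a gene's transcripts, or a signature
concentrates; manually drawn polygon gates (villus top, crypt, muscularis)
partition the plane for per-region statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from scipy.stats import gaussian_kde, rankdata
from shapely.geometry import Polygon

from .core_data import CellTable


def biexponential_transform(values, w: float = 0.5) -> np.ndarray:
    """Biexponential (arcsinh) scale: linear near 0, logarithmic in the tails.

    ``T(v) = asinh(v / w)`` with width parameter ``w > 0``; strictly
    increasing, odd and invertible (`biexponential_inverse`).
    """
    if w <= 0:
        raise ValueError("width parameter w must be > 0")
    return np.arcsinh(np.asarray(values, dtype=float) / w)


def biexponential_inverse(values, w: float = 0.5) -> np.ndarray:
    if w <= 0:
        raise ValueError("width parameter w must be > 0")
    return np.sinh(np.asarray(values, dtype=float)) * w


def imap_coordinates(axes: pd.DataFrame, w: float = 0.5,
                     x_column: str = "crypt_villus_display") -> pd.DataFrame:
    """Per-cell IMAP coordinates: (crypt–villus, T(epithelial_clipped)).

    ``x_column`` selects which crypt–villus variant is used for the x axis
    (display-rescaled by default; the z-score column is also accepted).
    """
    for col in (x_column, "epithelial_clipped"):
        if col not in axes.columns:
            raise ValueError(f"axis column {col!r} missing; compute axes first")
    out = pd.DataFrame({
        "imap_x": axes[x_column].to_numpy(dtype=float),
        "imap_y": biexponential_transform(axes["epithelial_clipped"], w),
    }, index=axes.index)
    if not np.isfinite(out.to_numpy()).all():
        raise ValueError("non-finite IMAP coordinates; check axis inputs")
    return out


@dataclass
class IMAPField:
    """Weighted KDE density evaluated on a regular grid over the IMAP plane."""

    grid_x: np.ndarray
    grid_y: np.ndarray
    density: np.ndarray          # shape (len(grid_y), len(grid_x))
    bandwidth: float
    weight_label: str = ""

    def integral(self) -> float:
        dx = self.grid_x[1] - self.grid_x[0]
        dy = self.grid_y[1] - self.grid_y[0]
        return float(self.density.sum() * dx * dy)


def weighted_kde(
    points: pd.DataFrame,
    weights=None,
    bandwidth=None,
    grid_size: int = 128,
    padding: float = 0.25,
    weight_label: str = "",
):
    """Gaussian KDE over IMAP coordinates with optional per-cell weights.

    Weights are normalized to sum to one; all-equal weights reproduce the
    unweighted density exactly. Bandwidth defaults to Scott's rule on the
    weighted cloud; a scalar bandwidth is the *absolute* standard deviation
    of an isotropic Gaussian kernel (degenerate point clouds included).
    Returns ``(IMAPField, per_point_density)``.
    """
    xy = points[["imap_x", "imap_y"]].to_numpy(dtype=float).T
    if xy.shape[1] < 2:
        raise ValueError("need at least 2 points for a density estimate")
    if weights is not None:
        weights = np.asarray(weights, dtype=float)
        if (weights < 0).any():
            raise ValueError("weights must be non-negative")
        if weights.sum() <= 0:
            raise ValueError("all-zero weights: nothing to weight the density by")
        weights = weights / weights.sum()
    if np.isscalar(bandwidth) and not isinstance(bandwidth, str):
        h = float(bandwidth)
        if h <= 0:
            raise ValueError("bandwidth must be > 0")
        w = weights if weights is not None else np.full(xy.shape[1],
                                                        1.0 / xy.shape[1])

        def kde(query):
            query = np.atleast_2d(query)
            diff = query[:, :, None] - xy[:, None, :]   # (2, n_query, n_points)
            sq = (diff ** 2).sum(axis=0)
            return (w * np.exp(-sq / (2 * h ** 2))).sum(axis=1) / (
                2 * np.pi * h ** 2)

        kde.factor = h
    else:
        kde = gaussian_kde(xy, bw_method=bandwidth, weights=weights)

    span_x = xy[0].max() - xy[0].min() or 1.0
    span_y = xy[1].max() - xy[1].min() or 1.0
    gx = np.linspace(xy[0].min() - padding * span_x,
                     xy[0].max() + padding * span_x, grid_size)
    gy = np.linspace(xy[1].min() - padding * span_y,
                     xy[1].max() + padding * span_y, grid_size)
    mesh = np.meshgrid(gx, gy)
    density = kde(np.vstack([m.ravel() for m in mesh])).reshape(grid_size,
                                                                grid_size)
    field = IMAPField(gx, gy, density, bandwidth=float(kde.factor),
                      weight_label=weight_label)
    return field, kde(xy)


class GateSet:
    """Named simple polygons in IMAP coordinates, in priority order."""

    def __init__(self, polygons: dict):
        self.polygons = {}
        for name, vertices in polygons.items():
            poly = vertices if isinstance(vertices, Polygon) else Polygon(vertices)
            if not poly.is_valid:
                raise ValueError(f"gate {name!r} is not a simple polygon")
            if name in self.polygons:
                raise ValueError(f"duplicate gate name {name!r}")
            self.polygons[name] = poly

    @property
    def names(self) -> list:
        return list(self.polygons)

    def __len__(self) -> int:
        return len(self.polygons)


def assign_gates(points: pd.DataFrame, gates: GateSet) -> pd.Series:
    """Assign each IMAP point to a gate (boundary counts as inside).

    Overlapping gates are resolved by declaration order; points outside all
    gates are labelled ``"none"``.
    """
    pts = shapely.points(points[["imap_x", "imap_y"]].to_numpy(dtype=float))
    labels = np.full(len(points), "none", dtype=object)
    unassigned = np.ones(len(points), dtype=bool)
    for name, poly in gates.polygons.items():
        inside = shapely.covers(poly, pts) & unassigned
        labels[inside] = name
        unassigned &= ~inside
    return pd.Series(labels, index=points.index, name="gate")


def log_normalize(counts: pd.DataFrame, target_sum: float | None = None) -> pd.DataFrame:
    """Scale each cell to the median total count of the population, then log1p."""
    totals = counts.sum(axis=1).to_numpy(dtype=float)
    if target_sum is None:
        positive = totals[totals > 0]
        target_sum = float(np.median(positive)) if len(positive) else 1.0
    scale = np.divide(target_sum, totals, out=np.zeros_like(totals),
                      where=totals > 0)
    return np.log1p(counts.mul(scale, axis=0))


def gate_statistics(
    cells: CellTable,
    labels: pd.Series,
    genes=None,
    groups: pd.Series | None = None,
):
    """Per-gate cell counts, mean log-normalized expression and fractions.

    ``groups`` (optional, e.g. a perturbation or population label) yields
    per-group gate fractions that sum to 1 over gates plus the ``none``
    bucket. Empty gates are reported with count 0 and NaN means.
    """
    labels = labels.reindex(cells.cell_ids)
    gate_names = sorted(labels.dropna().unique().tolist())
    if "none" not in gate_names:
        gate_names.append("none")
    genes = list(genes) if genes is not None else list(cells.genes)
    logn = log_normalize(cells.counts[genes])

    counts, means = {}, {}
    for g in gate_names:
        mask = (labels == g).to_numpy()
        counts[g] = int(mask.sum())
        means[g] = logn.loc[mask].mean(axis=0) if mask.any() else pd.Series(
            np.nan, index=genes)
    summary = pd.DataFrame({
        "n_cells": pd.Series(counts),
    })
    mean_expr = pd.DataFrame(means).T  # gates x genes

    if groups is None:
        fractions = summary["n_cells"] / max(summary["n_cells"].sum(), 1)
        fractions = fractions.rename("fraction").to_frame().T
        fractions.index = ["all"]
    else:
        groups = groups.reindex(cells.cell_ids)
        rows = {}
        for grp in pd.unique(groups.dropna()):
            sub = labels[groups == grp]
            n = len(sub)
            rows[grp] = {g: float((sub == g).sum()) / n if n else np.nan
                         for g in gate_names}
        fractions = pd.DataFrame(rows).T[gate_names]
    return summary, mean_expr, fractions


def signature_score(
    cells: CellTable,
    signature,
    max_rank: int = 1500,
) -> pd.Series:
    """Rank-based per-cell signature enrichment score in [0, 1].

    Genes are ranked per cell by descending count (ties get average ranks)
    and ranks are truncated at ``max_rank``. The rank-sum of the signature
    genes, shifted by its minimum n(n+1)/2, is normalized by the maximum
    attainable shifted rank-sum, so a signature occupying the top n ranks
    scores exactly 1 and a signature entirely beyond ``max_rank`` scores
    exactly 0. The score is monotone non-increasing in any signature gene's
    rank.
    """
    signature = list(signature)
    if not signature:
        raise ValueError("empty signature")
    missing = [g for g in signature if g not in cells.genes]
    if missing:
        raise ValueError(f"signature genes not in panel: {missing}")
    arr = cells.counts.to_numpy(dtype=float)
    # average ranks of descending counts, per cell
    ranks = rankdata(-arr, axis=1, method="average")
    ranks = np.minimum(ranks, max_rank)
    sig_cols = [cells.genes.get_loc(g) for g in signature]
    n = len(signature)
    u = ranks[:, sig_cols].sum(axis=1) - n * (n + 1) / 2
    u_max = n * max_rank - n * (n + 1) / 2
    score = np.clip(1.0 - u / u_max, 0.0, 1.0)
    return pd.Series(score, index=cells.cell_ids, name="signature_score")
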