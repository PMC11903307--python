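"""Per-cell anatomical coordinate axes.

Three axes locate each cell in the small-intestine architecture:

* **longitudinal** — arc-length fraction of the nearest point on the
  basal-membrane polyline, in [0, 1];
* **crypt–villus** — Euclidean distance to the basal membrane, z-scored
  within each segmented villus (geometric variant), or predicted from
  transcriptional-neighbourhood latent factors where morphology is poor
  (predicted variant, spatially smoothed);
* **epithelial** — mean distance to the k nearest epithelial cells divided
  by the mean distance to the k nearest cells of any type (a ratio >= 1:
  the any-type candidate set contains the epithelial candidates), z-scored
  and clipped at an upper bound.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from scipy.spatial import cKDTree
from shapely.geometry import LineString
from sklearn.decomposition import NMF
from sklearn.neighbors import KNeighborsRegressor

from .core_data import CellTable, PolylineAnnotation


@dataclass
class AxisSet:
    """Per-cell axis values assembled into one frame.

    Columns: ``longitudinal``, ``crypt_villus_raw`` (µm),
    ``crypt_villus`` (per-villus z-score), ``crypt_villus_display``
    (per-sample min–max rescale of the z-scores to [0, 1]),
    ``epithelial_raw`` (ratio >= 1), ``epithelial`` (z-score) and
    ``epithelial_clipped``.
    """

    values: pd.DataFrame

    def __getitem__(self, key: str) -> pd.Series:
        return self.values[key]


def longitudinal_axis(cells: CellTable, basal: PolylineAnnotation) -> pd.Series:
    """Arc-length fraction along the basal membrane of each cell's nearest point."""
    line = LineString(basal.vertices)
    if line.length <= 0:
        raise ValueError("degenerate zero-length basal polyline")
    pts = shapely.points(cells.centroids)
    frac = shapely.line_locate_point(line, pts) / line.length
    return pd.Series(np.clip(frac, 0.0, 1.0), index=cells.cell_ids,
                     name="longitudinal")


def _zscore_by_group(values: np.ndarray, groups: np.ndarray,
                     sd_floor: float) -> np.ndarray:
    """Population-s.d. z-score within groups; degenerate groups map to 0."""
    out = np.full(len(values), np.nan)
    for g in pd.unique(groups):
        if pd.isna(g):
            continue
        mask = groups == g
        v = values[mask]
        if len(v) < 2:
            warnings.warn(f"villus {g!r} has a single cell; z-score set to 0")
            out[mask] = 0.0
            continue
        sd = v.std()  # population s.d.
        out[mask] = 0.0 if sd < sd_floor else (v - v.mean()) / sd
    return out


def crypt_villus_axis_geometric(
    cells: CellTable,
    basal: PolylineAnnotation,
    villus_labels: pd.Series,
    sd_floor: float = 1e-9,
) -> pd.DataFrame:
    """Distance to the basal membrane, z-scored within each segmented villus.

    Returns a frame with ``crypt_villus_raw`` (µm), ``crypt_villus``
    (z-score; NaN for cells outside any villus) and ``crypt_villus_display``
    (min–max rescale of the z-scores to [0, 1] over the sample).
    """
    line = LineString(basal.vertices)
    raw = shapely.distance(shapely.points(cells.centroids), line)
    groups = villus_labels.reindex(cells.cell_ids).to_numpy()
    z = _zscore_by_group(raw, groups, sd_floor)
    finite = np.isfinite(z)
    display = np.full(len(z), np.nan)
    if finite.any():
        lo, hi = z[finite].min(), z[finite].max()
        display[finite] = (z[finite] - lo) / (hi - lo) if hi > lo else 0.5
    return pd.DataFrame(
        {"crypt_villus_raw": raw, "crypt_villus": z,
         "crypt_villus_display": display},
        index=cells.cell_ids,
    )


@dataclass
class NeighborhoodEmbedding:
    """Non-negative latent factors of summed k-NN neighbourhood counts."""

    loadings: pd.DataFrame        # cells x factors, all >= 0
    components: np.ndarray        # factors x genes
    reconstruction_err: float


def neighborhood_counts(
    cells: CellTable,
    k: int = 10,
    restrict_types=None,
) -> pd.DataFrame:
    """Sum transcript counts over each cell's k nearest neighbours.

    Neighbour candidates may be restricted to a set of cell types (e.g.
    epithelial and stromal) so that the embedding is insensitive to shifting
    immune composition; the query cells are always all cells. Self is
    excluded from its own neighbourhood. If fewer than k candidates exist,
    all are used with a warning.
    """
    xy = cells.centroids
    if restrict_types is not None:
        cand_mask = cells.meta["cell_type"].isin(list(restrict_types)).to_numpy()
    else:
        cand_mask = np.ones(cells.n_cells, dtype=bool)
    cand_idx = np.where(cand_mask)[0]
    if len(cand_idx) == 0:
        raise ValueError("no neighbour candidates after type restriction")
    k_eff = min(k, len(cand_idx) - 1 if cand_mask.all() else len(cand_idx))
    if k_eff < k:
        warnings.warn(f"only {k_eff} neighbour candidates available; using all")
    if k_eff < 1:
        raise ValueError("need at least one neighbour candidate besides self")
    tree = cKDTree(xy[cand_idx])
    # query one extra so self can be dropped when it is its own candidate
    dist, nbr = tree.query(xy, k=k_eff + 1)
    counts = cells.counts.to_numpy()
    out = np.zeros_like(counts, dtype=np.int64)
    for i in range(cells.n_cells):
        idx = cand_idx[nbr[i]]
        idx = idx[idx != i][:k_eff]
        out[i] = counts[idx].sum(axis=0)
    return pd.DataFrame(out, index=cells.cell_ids, columns=cells.genes)


def neighborhood_factors(
    neighborhood: pd.DataFrame,
    n_factors: int = 15,
    seed: int = 0,
    max_iter: int = 500,
) -> NeighborhoodEmbedding:
    """Non-negative matrix factorization of the neighbourhood count matrix."""
    model = NMF(n_components=n_factors, init="nndsvda", random_state=seed,
                max_iter=max_iter, tol=1e-5)
    w = model.fit_transform(neighborhood.to_numpy(dtype=float))
    return NeighborhoodEmbedding(
        loadings=pd.DataFrame(w, index=neighborhood.index),
        components=model.components_,
        reconstruction_err=float(model.reconstruction_err_),
    )


class CryptVillusRegressor:
    """Supervised map from neighbourhood latent factors to an axis value.

    A pluggable regressor (default: k-NN on the factor space, deterministic)
    with post-hoc spatial smoothing: each prediction is replaced by the mean
    prediction over the cell's ``smoothing_k`` nearest spatial neighbours
    (including itself; ``smoothing_k=1`` is the identity).
    """

    def __init__(self, regressor=None, smoothing_k: int = 150,
                 min_labelled: int = 20):
        self.regressor = regressor
        self.smoothing_k = smoothing_k
        self.min_labelled = min_labelled

    def get_params(self, deep: bool = True) -> dict:
        return {"regressor": self.regressor, "smoothing_k": self.smoothing_k,
                "min_labelled": self.min_labelled}

    def set_params(self, **params) -> "CryptVillusRegressor":
        for key, value in params.items():
            setattr(self, key, value)
        return self

    def fit(self, factors: np.ndarray, labels: np.ndarray) -> "CryptVillusRegressor":
        factors = np.asarray(factors, dtype=float)
        labels = np.asarray(labels, dtype=float)
        if len(labels) < self.min_labelled:
            raise ValueError(
                f"need >= {self.min_labelled} labelled cells, got {len(labels)}")
        self.regressor_ = (self.regressor if self.regressor is not None
                           else KNeighborsRegressor(n_neighbors=10))
        self.regressor_.fit(factors, labels)
        return self

    def predict(self, factors: np.ndarray,
                coords: np.ndarray | None = None) -> np.ndarray:
        raw = np.asarray(self.regressor_.predict(np.asarray(factors, float)))
        if coords is None or self.smoothing_k <= 1:
            return raw
        coords = np.asarray(coords, dtype=float)
        k = min(self.smoothing_k, len(coords))
        tree = cKDTree(coords)
        _, nbr = tree.query(coords, k=k)
        if k == 1:
            nbr = nbr[:, None]
        return raw[nbr].mean(axis=1)


def crypt_villus_axis_predicted(
    embedding: NeighborhoodEmbedding,
    labels: pd.Series,
    coords: pd.DataFrame | np.ndarray,
    smoothing_k: int = 150,
    regressor=None,
    holdout_fraction: float = 0.2,
    seed: int = 0,
):
    """Predict crypt–villus values for all cells from neighbourhood factors.

    ``labels`` holds axis values on the labelled subset (index = cell_id).
    Returns ``(predictions, metrics)`` where metrics reports held-out RMSE
    and Spearman correlation on a random label split.
    """
    from scipy.stats import spearmanr

    factors = embedding.loadings
    labelled = labels.dropna()
    labelled = labelled[labelled.index.isin(factors.index)]
    coords = np.asarray(coords, dtype=float)

    model = CryptVillusRegressor(regressor=regressor, smoothing_k=smoothing_k)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(labelled))
    n_hold = max(1, int(holdout_fraction * len(labelled)))
    hold_idx = labelled.index[perm[:n_hold]]
    train_idx = labelled.index[perm[n_hold:]]

    model.fit(factors.loc[train_idx].to_numpy(), labelled.loc[train_idx].to_numpy())
    hold_pred = model.predict(factors.loc[hold_idx].to_numpy())
    resid = hold_pred - labelled.loc[hold_idx].to_numpy()
    rho = spearmanr(hold_pred, labelled.loc[hold_idx].to_numpy()).statistic
    metrics = {"holdout_rmse": float(np.sqrt(np.mean(resid ** 2))),
               "holdout_spearman": float(rho), "n_holdout": int(n_hold)}

    model.fit(factors.loc[labelled.index].to_numpy(), labelled.to_numpy())
    pred = model.predict(factors.to_numpy(), coords=coords)
    return pd.Series(pred, index=factors.index, name="crypt_villus_predicted"), metrics


def epithelial_axis(
    cells: CellTable,
    epithelial_types=("Enterocyte", "Goblet", "Progenitor_enterocyte"),
    k_epi: int = 5,
    k_any: int = 5,
    clip_upper: float = 3.0,
    eps: float = 1e-12,
) -> pd.DataFrame:
    """Relative distance to the epithelial lining.

    raw = mean distance to the ``k_epi`` nearest epithelial cells divided by
    the mean distance to the ``k_any`` nearest cells of any type (self
    excluded from both queries). The ratio is >= 1 whenever ``k_any <= k_epi``
    candidates overlap, z-scored over the sample and clipped at
    ``clip_upper``.
    """
    xy = cells.centroids
    is_epi = cells.meta["cell_type"].isin(list(epithelial_types)).to_numpy()
    epi_idx = np.where(is_epi)[0]
    if len(epi_idx) < k_epi:
        raise ValueError(f"need >= {k_epi} epithelial cells, got {len(epi_idx)}")
    if cells.n_cells <= k_any:
        raise ValueError(f"need > {k_any} cells in total")

    epi_tree = cKDTree(xy[epi_idx])
    any_tree = cKDTree(xy)

    d_epi, n_epi = epi_tree.query(xy, k=min(k_epi + 1, len(epi_idx)))
    mean_epi = np.empty(cells.n_cells)
    for i in range(cells.n_cells):
        d = d_epi[i][epi_idx[n_epi[i]] != i][:k_epi]
        mean_epi[i] = d.mean()

    d_any, n_any = any_tree.query(xy, k=k_any + 1)
    mean_any = np.empty(cells.n_cells)
    for i in range(cells.n_cells):
        d = d_any[i][n_any[i] != i][:k_any]
        mean_any[i] = d.mean()

    if (mean_any <= eps).any():
        warnings.warn("cells with duplicate coordinates: denominator floored")
    raw = mean_epi / np.maximum(mean_any, eps)
    sd = raw.std()
    z = (raw - raw.mean()) / sd if sd > 0 else np.zeros_like(raw)
    clipped = np.minimum(z, clip_upper)
    return pd.DataFrame(
        {"epithelial_raw": raw, "epithelial": z, "epithelial_clipped": clipped},
        index=cells.cell_ids,
    )


def compute_axes(
    cells: CellTable,
    basal: PolylineAnnotation,
    villus_labels: pd.Series,
    epithelial_types=("Enterocyte", "Goblet", "Progenitor_enterocyte"),
    k_epi: int = 5,
    k_any: int = 5,
    clip_upper: float = 3.0,
) -> AxisSet:
    """Convenience wrapper computing all three axes into one AxisSet."""
    lon = longitudinal_axis(cells, basal)
    cv = crypt_villus_axis_geometric(cells, basal, villus_labels)
    epi = epithelial_axis(cells, epithelial_types, k_epi=k_epi, k_any=k_any,
                          clip_upper=clip_upper)
    return AxisSet(pd.concat([lon, cv, epi], axis=1))
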