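"""Spatial neighbour graphs, cell-type interaction scores and proximity stats.

The tissue "connectome" is a cell-type x cell-type matrix of spatial
contacts: edges of a spatial neighbour graph (k-NN by default) are tallied
by the type pair they join, averaged across biological replicates, and
normalized either to the matrix maximum (for edge display with a score
threshold) or per row (for heat maps). Nearest-cell-type distances and
Kolmogorov–Smirnov comparisons of their distributions quantify condition
differences in physical proximity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import Delaunay, cKDTree

from .core_data import CellTable
from .gradients import spearman_with_pvalue


def spatial_neighbor_graph(
    coords: np.ndarray,
    method: str = "knn",
    param: float = 6,
) -> nx.Graph:
    """Undirected spatial neighbour graph over cells.

    ``knn`` (default, k = ``param``, symmetrized), ``delaunay``
    (degenerate inputs fall back to knn with a warning) or ``radius``.
    Nodes are integer positions 0..n-1.
    """
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    if n < 2:
        raise ValueError("need at least 2 cells")
    graph = nx.Graph()
    graph.add_nodes_from(range(n))

    if method == "knn":
        k = min(int(param), n - 1)
        tree = cKDTree(coords)
        _, nbr = tree.query(coords, k=k + 1)
        for i in range(n):
            for j in nbr[i]:
                if j != i:
                    graph.add_edge(i, int(j))
    elif method == "delaunay":
        try:
            tri = Delaunay(coords)
        except Exception:
            warnings.warn("degenerate geometry for Delaunay; using knn fallback")
            return spatial_neighbor_graph(coords, "knn", param=6)
        for simplex in tri.simplices:
            for a in range(3):
                graph.add_edge(int(simplex[a]), int(simplex[(a + 1) % 3]))
    elif method == "radius":
        tree = cKDTree(coords)
        pairs = tree.query_pairs(r=float(param))
        graph.add_edges_from(pairs)
        if graph.number_of_edges() == 0:
            warnings.warn("radius graph has no edges; consider a larger radius")
    else:
        raise ValueError(f"unknown graph method {method!r}")
    return graph


@dataclass
class InteractionMatrix:
    """Cell-type interaction scores with raw and normalized variants."""

    raw: pd.DataFrame          # symmetric edge tallies, replicate-averaged
    max_normalized: pd.DataFrame
    row_normalized: pd.DataFrame
    threshold: float
    replicates: list

    def strong_edges(self) -> list:
        """Type pairs whose max-normalized score exceeds the threshold."""
        out = []
        types = self.max_normalized.index
        for i, a in enumerate(types):
            for b in types[i:]:
                if self.max_normalized.loc[a, b] > self.threshold:
                    out.append((a, b, float(self.max_normalized.loc[a, b])))
        return out


def _edge_tally(graph: nx.Graph, types: np.ndarray,
                all_types: list) -> pd.DataFrame:
    code = {t: i for i, t in enumerate(all_types)}
    mat = np.zeros((len(all_types), len(all_types)))
    if graph.number_of_edges():
        edges = np.asarray(graph.edges(), dtype=int)
        a = np.vectorize(code.__getitem__)(types[edges[:, 0]])
        b = np.vectorize(code.__getitem__)(types[edges[:, 1]])
        np.add.at(mat, (a, b), 1)
        np.add.at(mat, (b, a), (a != b))
    return pd.DataFrame(mat, index=all_types, columns=all_types)


def interaction_scores(
    graphs,
    cell_types,
    threshold: float = 0.1,
) -> InteractionMatrix:
    """Replicate-averaged cell-type interaction matrix from neighbour graphs.

    Parameters
    ----------
    graphs
        One graph or a dict replicate_id -> graph.
    cell_types
        Matching array (or dict of arrays) of per-node type labels.
    threshold
        Max-normalized score above which a connection counts as present
        (the "top fraction of connections" display rule).
    """
    if isinstance(graphs, nx.Graph):
        graphs = {"R1": graphs}
        cell_types = {"R1": cell_types}
    replicate_ids = list(graphs)
    all_types = sorted({str(t) for rep in replicate_ids
                        for t in np.asarray(cell_types[rep], dtype=object)})

    per_rep = []
    for rep in replicate_ids:
        types = np.asarray(cell_types[rep], dtype=object).astype(str)
        graph = graphs[rep]
        if len(types) != graph.number_of_nodes():
            raise ValueError(f"replicate {rep}: every node needs a type label")
        missing = [t for t in all_types if t not in set(types)]
        if missing:
            warnings.warn(f"replicate {rep}: type(s) {missing} absent; "
                          "zero rows/columns used")
        per_rep.append(_edge_tally(graph, types, all_types))
    raw = sum(per_rep) / len(per_rep)

    peak = raw.to_numpy().max()
    max_norm = raw / peak if peak > 0 else raw.copy()
    row_sums = raw.sum(axis=1)
    row_norm = raw.div(row_sums.replace(0, np.nan), axis=0).fillna(0.0)
    return InteractionMatrix(raw, max_norm, row_norm, threshold, replicate_ids)


def nearest_type_distances(
    cells: CellTable,
    target_types=None,
) -> pd.DataFrame:
    """Per-cell Euclidean distance to the nearest cell of each target type.

    Self-excluded: a cell of type B queried for B gets the distance to the
    *other* nearest B cell. Types absent from the sample give a column of
    infinity with a warning.
    """
    xy = cells.centroids
    types = cells.meta["cell_type"].astype(str)
    if target_types is None:
        target_types = sorted(types.unique())
    out = pd.DataFrame(index=cells.cell_ids, dtype=float)
    for t in target_types:
        member_idx = np.where((types == t).to_numpy())[0]
        if len(member_idx) == 0:
            warnings.warn(f"cell type {t!r} absent; distances set to inf")
            out[t] = np.inf
            continue
        tree = cKDTree(xy[member_idx])
        k = min(2, len(member_idx))
        dist, nbr = tree.query(xy, k=k)
        dist = np.atleast_2d(dist.T).T
        nbr = np.atleast_2d(nbr.T).T
        col = np.empty(cells.n_cells)
        for i in range(cells.n_cells):
            cand_global = member_idx[nbr[i]]
            valid = dist[i][cand_global != i]
            col[i] = valid[0] if len(valid) else np.inf
        out[t] = col
    return out


def expression_distance_correlation(
    score: pd.Series,
    distances: pd.DataFrame,
    samples: pd.Series | None = None,
) -> pd.DataFrame:
    """Spearman correlation of an expression score with nearest-type distances.

    Negative rho means the score is higher when cells are NEAR the target
    type (small distance). With ``samples`` given, the coefficient is
    computed per sample and the mean across samples is reported.
    """
    score = score.astype(float)
    if len(score) < 10:
        raise ValueError("need at least 10 cells")
    if score.std() == 0:
        raise ValueError("zero-variance score: correlation undefined")
    if samples is None:
        samples = pd.Series("all", index=score.index)
    samples = samples.reindex(score.index)

    rows = []
    for target in distances.columns:
        rhos = []
        for _, idx in samples.groupby(samples).groups.items():
            d = distances.loc[idx, target].to_numpy(dtype=float)
            s = score.loc[idx].to_numpy()
            finite = np.isfinite(d)
            if finite.sum() < 3:
                continue
            rho, _ = spearman_with_pvalue(s[finite], d[finite])
            if np.isfinite(rho):
                rhos.append(rho)
        rows.append((target, float(np.mean(rhos)) if rhos else np.nan,
                     len(rhos)))
    return pd.DataFrame(rows, columns=["target_type", "rho", "n_samples"])


def compare_proximity_distributions(
    distances_a,
    distances_b,
    cutoff_d: float = 0.08,
) -> dict:
    """Two-sample Kolmogorov–Smirnov comparison of proximity distributions.

    D = sup |ECDF_A - ECDF_B| with the asymptotic p-value; conditions are
    flagged ``different`` when D exceeds ``cutoff_d``.
    """
    a = np.asarray(distances_a, dtype=float)
    b = np.asarray(distances_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both samples need at least 2 values")
    res = stats.ks_2samp(a, b, method="asymp")
    return {"D": float(res.statistic), "p": float(res.pvalue),
            "different": bool(res.statistic > cutoff_d),
            "cutoff": cutoff_d}
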