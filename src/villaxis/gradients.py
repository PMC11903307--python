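"""Gene–axis gradient screening and trend fitting.

The screen rank-correlates every sufficiently expressed gene with a per-cell
anatomical axis (Spearman rho with average ranks; large-sample t
approximation for p-values) and classifies genes as positively / negatively
correlated at a configurable |rho| threshold. Trends along an axis are
summarized either by a moving average over sorted cells (convolved trend) or
by a penalized cubic B-spline (a generalized additive model with one smooth
term), z-scaled for comparison across genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import interpolate, stats
from statsmodels.stats.multitest import multipletests

from .core_data import CellTable
from .imap import log_normalize


def expression_fraction_filter(
    counts: pd.DataFrame,
    min_fraction: float = 0.05,
) -> list:
    """Genes detected (count > 0) in at least ``min_fraction`` of cells."""
    if len(counts) == 0:
        raise ValueError("empty cell subset")
    frac = (counts.to_numpy() > 0).mean(axis=0)
    return [g for g, f in zip(counts.columns, frac) if f >= min_fraction]


def spearman_with_pvalue(x: np.ndarray, y: np.ndarray):
    """Spearman rho (average ranks) with the large-sample t approximation."""
    n = len(x)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    sx, sy = rx.std(), ry.std()
    if sx == 0 or sy == 0:
        return np.nan, np.nan
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * np.sqrt((n - 2) / (1 - rho ** 2))
    p = 2 * stats.t.sf(abs(t), df=n - 2)
    return rho, float(p)


def axis_correlation_screen(
    counts: pd.DataFrame,
    axis: pd.Series,
    genes=None,
    threshold: float = 0.05,
    axis_name: str = "axis",
) -> pd.DataFrame:
    """Spearman screen of each gene against an axis.

    Returns one row per gene with ``rho``, ``p``, ``class`` in
    {positive, negative, none} (|rho| against ``threshold``; zero-variance
    genes are ``none`` with undefined rho) and ``n_cells``.
    """
    if len(counts) < 3:
        raise ValueError("need at least 3 cells for a rank correlation")
    axis_vals = axis.reindex(counts.index).to_numpy(dtype=float)
    if not np.isfinite(axis_vals).all():
        raise ValueError("axis contains non-finite values")
    genes = list(genes) if genes is not None else list(counts.columns)

    axis_ranks = stats.rankdata(axis_vals)
    n = len(axis_ranks)
    results = []
    for gene in genes:
        g = counts[gene].to_numpy(dtype=float)
        rho, p = spearman_with_pvalue(axis_ranks, g)
        if np.isnan(rho):
            cls = "none"
        elif rho > threshold:
            cls = "positive"
        elif rho < -threshold:
            cls = "negative"
        else:
            cls = "none"
        results.append((gene, axis_name, rho, p, cls, n))
    return pd.DataFrame(results, columns=["gene", "axis", "rho", "p",
                                          "class", "n_cells"])


@dataclass
class TrendCurve:
    """A fitted expression trend along an axis."""

    grid: np.ndarray
    fitted: np.ndarray
    z_scaled: np.ndarray
    method: str
    smoothing: dict

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"axis": self.grid, "fitted": self.fitted,
                             "z": self.z_scaled})


def _z_scale(values: np.ndarray) -> np.ndarray:
    sd = values.std()
    if sd <= 1e-9 * (abs(values.mean()) + 1.0):
        return np.zeros_like(values)  # degenerate (numerically) constant curve
    return (values - values.mean()) / sd


def convolved_trend(
    counts: pd.Series | np.ndarray,
    axis: pd.Series | np.ndarray,
    window: int,
) -> TrendCurve:
    """Moving average of counts over cells sorted by axis value.

    Each position averages exactly ``window`` consecutive sorted cells,
    centred where possible and clamped at the array edges, so ``window=1``
    returns the raw sorted counts and ``window=n`` a constant curve at the
    global mean. The grid is the sorted axis values.
    """
    y = np.asarray(counts, dtype=float)
    x = np.asarray(axis, dtype=float)
    n = len(y)
    if not 1 <= window <= n:
        raise ValueError(f"window must be in [1, {n}]")
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    half = (window - 1) // 2
    starts = np.clip(np.arange(n) - half, 0, n - window)
    csum = np.concatenate([[0.0], np.cumsum(ys)])
    fitted = (csum[starts + window] - csum[starts]) / window
    return TrendCurve(xs, fitted, _z_scale(fitted), "convolution",
                      {"window": window})


def additive_trend(
    counts: pd.Series | np.ndarray,
    axis: pd.Series | np.ndarray,
    n_knots: int = 8,
    grid_size: int = 100,
    lambdas=None,
) -> TrendCurve:
    """Penalized cubic B-spline fit of counts on an axis (a 1-smooth GAM).

    The design is a cubic B-spline basis on ``n_knots`` interior quantile
    knots; a second-difference penalty on the coefficients is tuned by
    generalized cross-validation over a log-spaced lambda grid. The fitted
    curve is evaluated on a uniform grid over the axis range and z-scaled.
    Linear signals lie in the penalty null space and are reproduced exactly.
    """
    y = np.asarray(counts, dtype=float)
    x = np.asarray(axis, dtype=float)
    if len(y) < 3 * n_knots:
        raise ValueError(f"need >= {3 * n_knots} cells for {n_knots} knots")
    lo, hi = x.min(), x.max()
    if hi <= lo:
        raise ValueError("axis is constant")
    interior = np.quantile(x, np.linspace(0, 1, n_knots)[1:-1])
    knots = np.concatenate([[lo] * 4, interior, [hi] * 4])
    n_coef = len(knots) - 4
    design = interpolate.BSpline.design_matrix(np.clip(x, lo, hi), knots,
                                               3).toarray()
    # second-difference penalty; null space contains constants and linears
    d2 = np.diff(np.eye(n_coef), n=2, axis=0)
    bt_b = design.T @ design
    n = len(y)

    if lambdas is None:
        lambdas = np.logspace(-8, 6, 29)
    best = None
    zeros = np.zeros(d2.shape[0])
    for lam in lambdas:
        # augmented least squares: min ||B c - y||^2 + lam ||D c||^2
        aug = np.vstack([design, np.sqrt(lam) * d2])
        rhs = np.concatenate([y, zeros])
        coef, *_ = np.linalg.lstsq(aug, rhs, rcond=None)
        try:
            hat_trace = np.trace(np.linalg.solve(bt_b + lam * (d2.T @ d2),
                                                 bt_b))
        except np.linalg.LinAlgError:
            continue
        resid = y - design @ coef
        denom = max(n - hat_trace, 1e-8)
        gcv = n * (resid @ resid) / denom ** 2
        if best is None or gcv < best[0]:
            best = (gcv, lam, coef)
    if best is None:
        warnings.warn("singular spline design at all penalties; "
                      "falling back to heavy smoothing")
        lam = float(lambdas[-1])
        aug = np.vstack([design, np.sqrt(lam) * d2])
        coef, *_ = np.linalg.lstsq(aug, np.concatenate([y, zeros]), rcond=None)
        best = (np.inf, lam, coef)
    _, lam, coef = best

    grid = np.linspace(lo, hi, grid_size)
    grid_design = interpolate.BSpline.design_matrix(grid, knots, 3).toarray()
    fitted = grid_design @ coef
    return TrendCurve(grid, fitted, _z_scale(fitted), "additive_model",
                      {"n_knots": n_knots, "lambda": float(lam)})


def rank_de_genes(
    cells: CellTable,
    group_a,
    group_b,
    n_top: int = 15,
    genes=None,
) -> pd.DataFrame:
    """Wilcoxon rank-sum differential expression between two cell groups.

    Two-sided Mann–Whitney U on log-normalized counts per gene, with
    Benjamini–Hochberg adjustment; genes constant across both groups get
    p = 1. Rows are ordered by the signed standardized statistic (genes
    highest in ``group_a`` first), which is how signature gene lists are
    built; ``n_top`` rows carry ``in_top = True``.
    """
    ids_a = pd.Index(group_a)
    ids_b = pd.Index(group_b)
    if len(ids_a) < 3 or len(ids_b) < 3:
        raise ValueError("both groups need at least 3 cells")
    genes = list(genes) if genes is not None else list(cells.genes)
    logn = log_normalize(cells.counts[genes])
    a = logn.loc[ids_a].to_numpy()
    b = logn.loc[ids_b].to_numpy()
    n1, n2 = len(ids_a), len(ids_b)

    rows = []
    for j, gene in enumerate(genes):
        va, vb = a[:, j], b[:, j]
        if va.std() == 0 and vb.std() == 0 and va.mean() == vb.mean():
            rows.append((gene, 0.0, n1 * n2 / 2.0, 1.0))
            continue
        # exact p for small tie-free groups, asymptotic otherwise
        res = stats.mannwhitneyu(va, vb, alternative="two-sided",
                                 method="auto")
        mu = n1 * n2 / 2.0
        # tie-corrected standard deviation of U under the null
        combined = np.concatenate([va, vb])
        _, tie_counts = np.unique(combined, return_counts=True)
        n = n1 + n2
        tie_term = ((tie_counts ** 3 - tie_counts).sum() / (n * (n - 1))
                    if n > 1 else 0.0)
        sd = np.sqrt(n1 * n2 / 12.0 * ((n + 1) - tie_term))
        z = (res.statistic - mu) / sd if sd > 0 else 0.0
        rows.append((gene, float(z), float(res.statistic), float(res.pvalue)))
    table = pd.DataFrame(rows, columns=["gene", "z", "U", "p"])
    table["p_adj"] = multipletests(table["p"], method="fdr_bh")[1]
    table = table.sort_values("z", ascending=False, kind="stable",
                              ignore_index=True)
    table["in_top"] = np.arange(len(table)) < n_top
    return table
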