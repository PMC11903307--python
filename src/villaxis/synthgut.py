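"""Synthetic small-intestine tissue with known ground truth.

The generator emulates the features of a rolled-intestine spatial
transcriptomics sample that the downstream analyses depend on, in a flat
(unrolled) layout: a straight basal membrane at ``y = 0``, a band of
muscularis below it, and a row of villi above it. Epithelial cells line each
villus boundary (a half-ellipse), lamina propria cells fill the interior, and
muscularis cells sit in the band. Per-cell anatomical axes — longitudinal
position, normalized crypt–villus height and distance to the epithelial
lining — are recorded analytically from placement, so axis-recovery tests
have a noiseless reference.

Gene counts follow a log-linear model on the true axes,
``count ~ Poisson(exp(b0 + b_cv*cv + b_epi*epi + b_long*long))``, with
designated null genes having all slopes exactly zero. A pooled-perturbation
scenario adds pseudogene barcode counts to a subset of CD8 T cells (one
sgRNA per cell, landing on a low-expression panel gene) plus an optional
goblet-cell bleed-over contamination and an optional positional shift of one
sgRNA population toward the villus top.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import LineString

from .core_data import CellTable, PolylineAnnotation, SampleBundle

RATE_CAP = 1e6


@dataclass
class GeneModel:
    """Log-linear expression model for one gene.

    ``b0`` is the log baseline rate; ``b_cv``, ``b_epi`` and ``b_long`` are
    slopes on the normalized crypt–villus, epithelial and longitudinal axes.
    ``cell_types=None`` means expressed in every cell type; otherwise the gene
    is off (rate 0) outside the listed types. ``b0 = -inf`` switches the gene
    off entirely.
    """

    gene: str
    b0: float
    b_cv: float = 0.0
    b_epi: float = 0.0
    b_long: float = 0.0
    cell_types: tuple | None = None


def default_gene_models() -> list:
    """The default 30-gene panel: axis gradients, markers and null genes."""
    ln = np.log
    models = [
        # epithelial genes with crypt–villus gradients (villus-tip vs crypt)
        GeneModel("Apoa4", ln(10), b_cv=2.0, cell_types=("Enterocyte",)),
        GeneModel("Ada", ln(5), b_cv=1.5, cell_types=("Enterocyte",)),
        GeneModel("Slc2a2", ln(6), b_cv=1.0, cell_types=("Enterocyte",)),
        GeneModel("Olfm4", ln(20), b_cv=-2.0, cell_types=("Progenitor_enterocyte",)),
        GeneModel("Lgr5", ln(5), b_cv=-1.5, cell_types=("Progenitor_enterocyte",)),
        GeneModel("Epcam", ln(15), cell_types=("Enterocyte", "Goblet",
                                               "Progenitor_enterocyte")),
        GeneModel("Muc2", ln(30), cell_types=("Goblet",)),
        GeneModel("Reg3b", ln(6), b_long=1.0, cell_types=("Enterocyte",)),
        GeneModel("Il15", ln(4), b_cv=0.5, cell_types=("Enterocyte",)),
        # CD8 T cell markers and axis-graded effector/progenitor genes
        GeneModel("Cd8a", ln(8), cell_types=("CD8_T",)),
        GeneModel("Cd8b1", ln(8), cell_types=("CD8_T",)),
        GeneModel("Cd3e", ln(8), cell_types=("CD8_T", "CD4_T")),
        GeneModel("Gzmb", ln(3), b_cv=1.0, cell_types=("CD8_T",)),
        GeneModel("Gzma", ln(3), b_cv=1.0, cell_types=("CD8_T",)),
        GeneModel("Itgae", ln(3), b_epi=-1.0, cell_types=("CD8_T",)),
        GeneModel("Tcf7", ln(3), b_cv=-1.0, cell_types=("CD8_T",)),
        GeneModel("Slamf6", ln(3), b_cv=-1.0, cell_types=("CD8_T",)),
        GeneModel("Klrg1", ln(3), b_cv=-0.8, cell_types=("CD8_T",)),
        GeneModel("Il18r1", ln(3), b_cv=-0.8, cell_types=("CD8_T",)),
        GeneModel("Klf2", ln(3), b_cv=-0.5, cell_types=("CD8_T",)),
        # stromal / muscle
        GeneModel("Col1a1", ln(20), cell_types=("Fibroblast",)),
        GeneModel("Myh11", ln(20), cell_types=("Smooth_muscle",)),
        GeneModel("Cxcl9", ln(4), b_cv=-1.0, cell_types=("Fibroblast",)),
        GeneModel("Cxcl10", ln(4), b_cv=-1.0, cell_types=("Fibroblast",)),
        GeneModel("Tgfb1", ln(5), b_cv=-0.5, cell_types=("Fibroblast",)),
        GeneModel("Cd19", ln(8), cell_types=("B_cell",)),
        GeneModel("Cd4", ln(8), cell_types=("CD4_T",)),
        # flat null genes in CD8 T cells (zero slope by construction)
        *[GeneModel(f"Null{i:02d}", ln(5), cell_types=("CD8_T",))
          for i in range(1, 9)],
        # barcode landing genes: present in the panel, off everywhere
        GeneModel("Muc5ac", -np.inf),
        GeneModel("Neurog3", -np.inf),
        GeneModel("Fer1l6", -np.inf),
    ]
    return models


@dataclass
class PerturbationDesign:
    """Pooled sgRNA design: one low-expression landing gene per sgRNA."""

    sgrnas: dict = field(default_factory=lambda: {
        "sgCd19": ("Muc5ac", 7),
        "sgThy1": ("Neurog3", 8),
        "sgCxcr3": ("Fer1l6", 8),
    })
    fraction: float = 0.10               # of target cells receiving each sgRNA
    target_cell_type: str = "CD8_T"
    contamination_rate: float = 0.05     # of goblet cells with bleed-over counts
    contamination_gene: str = "Fer1l6"
    barcode_rate: float = 2.0            # extra counts ~ Poisson(rate*sites/8)
    shift_sgrna: str | None = None       # sgRNA population resampled upward
    shift_quantile: float = 0.7          # lower bound of the target height band

    def __post_init__(self) -> None:
        landings = [lg for lg, _ in self.sgrnas.values()]
        if len(set(landings)) != len(landings):
            raise ValueError("duplicate barcode landing genes across sgRNAs")
        for name, (_, sites) in self.sgrnas.items():
            if sites not in (7, 8):
                raise ValueError(f"{name}: hybridization sites must be 7 or 8")
        if not 0 <= self.fraction <= 1 / max(len(self.sgrnas), 1):
            raise ValueError("per-sgRNA fraction must fit within the target pool")
        if not 0 <= self.contamination_rate <= 1:
            raise ValueError("contamination_rate must be in [0, 1]")


@dataclass
class SyntheticConfig:
    n_villi: int = 10
    villus_height: float = 300.0         # µm
    villus_width: float = 80.0           # µm
    villus_gap: float = 20.0             # µm between adjacent villi
    crypt_depth: float = 50.0            # µm; base band counted as crypt region
    muscularis_thickness: float = 40.0   # µm below the basal membrane
    cells_per_villus: dict = field(default_factory=lambda: {
        "epithelial": 160, "lamina_propria": 260, "muscularis": 80})
    cell_type_frequencies: dict = field(default_factory=lambda: {
        "epithelial": {"Enterocyte": 0.65, "Goblet": 0.15,
                       "Progenitor_enterocyte": 0.20},
        "lamina_propria": {"CD8_T": 0.40, "CD4_T": 0.12, "B_cell": 0.18,
                           "Fibroblast": 0.22, "DC": 0.08},
        "muscularis": {"Smooth_muscle": 0.60, "Fibroblast": 0.25,
                       "CD8_T": 0.15},
    })
    gene_models: list = field(default_factory=default_gene_models)
    perturbation_design: PerturbationDesign | None = None
    nuclear_fraction: float = 0.6        # chance a transcript falls in the nucleus
    transcript_jitter: float = 4.0       # µm spread of transcripts around centroid
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("villus_height", "villus_width", "crypt_depth",
                     "muscularis_thickness"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.villus_gap < 0:
            raise ValueError("villi overlap: villus_gap must be >= 0")
        for comp, freqs in self.cell_type_frequencies.items():
            if abs(sum(freqs.values()) - 1.0) > 1e-9:
                raise ValueError(f"{comp} cell-type frequencies must sum to 1")

    @property
    def pitch(self) -> float:
        return self.villus_width + self.villus_gap

    @property
    def total_length(self) -> float:
        return self.n_villi * self.pitch


@dataclass
class GroundTruth:
    """Per-cell true axes/labels and per-gene true slopes."""

    cells: pd.DataFrame   # longitudinal, crypt_villus, epithelial_dist, ...
    genes: pd.DataFrame   # b0, b_cv, b_epi, b_long, cell_types per gene


def _villus_boundary(cx: float, width: float, height: float,
                     n: int = 200) -> np.ndarray:
    """Half-ellipse villus lining from left base over the tip to right base."""
    t = np.linspace(np.pi, 0.0, n)
    return np.column_stack([cx + (width / 2) * np.cos(t), height * np.sin(t)])


def generate_tissue(config: SyntheticConfig, seed: int | None = None):
    """Place cells in the flat villus geometry and record true axes.

    Returns
    -------
    (truth_cells, annotations)
        ``truth_cells`` is the per-cell ground-truth frame (positions,
        compartment, cell type, villus id and the three true axes);
        ``annotations`` holds the basal-membrane polyline.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    half_w = config.villus_width / 2
    boundaries = [
        _villus_boundary(i * config.pitch + config.pitch / 2,
                         config.villus_width, config.villus_height)
        for i in range(config.n_villi)
    ]
    boundary_lines = [LineString(b) for b in boundaries]
    all_boundaries = shapely.union_all(boundary_lines)

    rows = []
    for v in range(config.n_villi):
        cx = v * config.pitch + config.pitch / 2
        n_epi = config.cells_per_villus.get("epithelial", 0)
        n_lp = config.cells_per_villus.get("lamina_propria", 0)
        n_mus = config.cells_per_villus.get("muscularis", 0)

        # epithelial cells exactly on the boundary curve -> epithelial dist 0
        t = rng.uniform(0.02, np.pi - 0.02, n_epi)
        ex = cx + half_w * np.cos(t)
        ey = config.villus_height * np.sin(t)
        for x, y in zip(ex, ey):
            rows.append((x, y, "epithelial", v, 0.0))

        # lamina propria cells uniform in a shrunken half-ellipse interior
        margin = 0.88
        rho = np.sqrt(rng.uniform(0, 1, n_lp))
        th = rng.uniform(0.0, np.pi, n_lp)
        lx = cx + rho * half_w * margin * np.cos(th)
        ly = np.maximum(rho * config.villus_height * margin * np.sin(th), 1.0)
        for x, y in zip(lx, ly):
            rows.append((x, y, "lamina_propria", v, np.nan))

        # muscularis band below the basal membrane
        mx = rng.uniform(v * config.pitch, (v + 1) * config.pitch, n_mus)
        my = rng.uniform(-config.muscularis_thickness, 0.0, n_mus)
        for x, y in zip(mx, my):
            rows.append((x, y, "muscularis", np.nan, np.nan))

    truth = pd.DataFrame(rows, columns=["x", "y", "compartment", "villus_id",
                                        "epithelial_dist"])
    truth.index = pd.Index([f"c{i:05d}" for i in range(len(truth))],
                           name="cell_id")

    # true axes are exact functions of placement
    truth["longitudinal"] = np.clip(truth["x"] / config.total_length, 0.0, 1.0)
    truth["crypt_villus"] = truth["y"] / config.villus_height
    need = truth["epithelial_dist"].isna()
    pts = shapely.points(truth.loc[need, ["x", "y"]].to_numpy())
    truth.loc[need, "epithelial_dist"] = shapely.distance(pts, all_boundaries)
    truth["epithelial_norm"] = truth["epithelial_dist"] / half_w

    # cell types per compartment
    types = np.empty(len(truth), dtype=object)
    for comp, freqs in config.cell_type_frequencies.items():
        mask = (truth["compartment"] == comp).to_numpy()
        labels = list(freqs)
        types[mask] = rng.choice(labels, size=mask.sum(), p=list(freqs.values()))
    truth["cell_type"] = types
    truth["cluster"] = truth["cell_type"]
    truth["sgrna"] = ""

    basal = PolylineAnnotation(
        "basal_membrane",
        np.column_stack([np.linspace(0, config.total_length, 5), np.zeros(5)]),
    )
    return truth, {"basal_membrane": basal}


def generate_expression(
    truth_cells: pd.DataFrame,
    gene_models: list,
    noise: str = "poisson",
    nb_dispersion: float = 10.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw the cell-by-gene count matrix from the log-linear axis model.

    ``truth_cells`` needs columns ``crypt_villus``, ``epithelial_norm``,
    ``longitudinal`` and ``cell_type``. Returns an integer DataFrame
    (cells x genes). Rates exceeding an overflow cap are clipped with a
    warning.
    """
    if noise not in ("poisson", "negative_binomial"):
        raise ValueError(f"unknown noise model {noise!r}")
    rng = np.random.default_rng(seed)
    cv = truth_cells["crypt_villus"].to_numpy(dtype=float)
    epi = truth_cells["epithelial_norm"].to_numpy(dtype=float)
    lon = truth_cells["longitudinal"].to_numpy(dtype=float)
    ctype = truth_cells["cell_type"].to_numpy()

    counts = np.zeros((len(truth_cells), len(gene_models)), dtype=np.int64)
    for j, gm in enumerate(gene_models):
        if not np.isfinite(gm.b0):
            continue  # gene off: all-zero column
        log_rate = gm.b0 + gm.b_cv * cv + gm.b_epi * epi + gm.b_long * lon
        rate = np.exp(log_rate)
        if (rate > RATE_CAP).any():
            warnings.warn(f"{gm.gene}: expression rate capped at {RATE_CAP:g}")
            rate = np.minimum(rate, RATE_CAP)
        if gm.cell_types is not None:
            rate = np.where(np.isin(ctype, gm.cell_types), rate, 0.0)
        if noise == "poisson":
            counts[:, j] = rng.poisson(rate)
        else:
            r = nb_dispersion
            p = r / (r + rate)
            draw = np.where(rate > 0, rng.negative_binomial(r, np.minimum(p, 1.0)), 0)
            counts[:, j] = draw
    return pd.DataFrame(counts, index=truth_cells.index,
                        columns=pd.Index([gm.gene for gm in gene_models],
                                         name="gene"))


def inject_perturbation_barcodes(
    counts: pd.DataFrame,
    truth_cells: pd.DataFrame,
    design: PerturbationDesign,
    gene_models: list,
    villus_height: float = 300.0,
    seed: int = 0,
):
    """Add pseudogene barcode counts and record true perturbation labels.

    Each perturbed cell (sampled from the target type at ``design.fraction``
    per sgRNA, disjoint across sgRNAs) receives ``1 + Poisson`` counts of its
    sgRNA's landing gene. A ``contamination_rate`` fraction of goblet cells
    receives spurious counts of ``contamination_gene`` (bleed-over scenario).
    If ``shift_sgrna`` is set, those cells are repositioned into the upper
    villus band (height quantile above ``shift_quantile``), updating the true
    axes so gate-enrichment tests have a known displacement.

    Returns updated ``(counts, truth_cells)`` copies.
    """
    for sg, (landing, _) in design.sgrnas.items():
        if landing not in counts.columns:
            raise ValueError(f"landing gene {landing!r} for {sg} not in panel")
        gm = next((g for g in gene_models if g.gene == landing), None)
        if gm is not None and np.isfinite(gm.b0):
            raise ValueError(f"landing gene {landing!r} overlaps an expressed gene")

    rng = np.random.default_rng(seed)
    counts = counts.copy()
    truth_cells = truth_cells.copy()
    truth_cells["sgrna"] = ""

    targets = truth_cells.index[truth_cells["cell_type"] == design.target_cell_type]
    targets = targets.to_numpy()
    rng.shuffle(targets)
    n_per = int(round(design.fraction * len(targets)))
    cursor = 0
    for sg, (landing, sites) in design.sgrnas.items():
        chosen = targets[cursor:cursor + n_per]
        cursor += n_per
        if len(chosen) == 0:
            continue
        truth_cells.loc[chosen, "sgrna"] = sg
        extra = rng.poisson(design.barcode_rate * sites / 8.0, size=len(chosen))
        counts.loc[chosen, landing] += 1 + extra  # >= 1 barcode count guaranteed

    goblets = truth_cells.index[truth_cells["cell_type"] == "Goblet"].to_numpy()
    if design.contamination_rate > 0 and len(goblets):
        n_cont = int(round(design.contamination_rate * len(goblets)))
        contaminated = rng.choice(goblets, size=n_cont, replace=False)
        counts.loc[contaminated, design.contamination_gene] += 1 + rng.poisson(
            1.0, size=n_cont)

    if design.shift_sgrna is not None:
        shifted = truth_cells.index[truth_cells["sgrna"] == design.shift_sgrna]
        if len(shifted):
            new_cv = rng.uniform(design.shift_quantile, 0.98, size=len(shifted))
            truth_cells.loc[shifted, "y"] = new_cv * villus_height
            truth_cells.loc[shifted, "crypt_villus"] = new_cv
    return counts, truth_cells


def realize_transcripts(
    counts: pd.DataFrame,
    truth_cells: pd.DataFrame,
    nuclear_fraction: float = 0.6,
    jitter: float = 4.0,
    seed: int = 0,
):
    """Scatter per-cell counts into point transcripts around each centroid.

    Returns ``(transcripts, nuclear_count)``: the transcript table and the
    per-cell number of nuclear-flagged transcripts.
    """
    rng = np.random.default_rng(seed)
    arr = counts.to_numpy()
    genes = counts.columns.to_numpy()
    cells = counts.index.to_numpy()
    cx = truth_cells["x"].to_numpy()
    cy = truth_cells["y"].to_numpy()

    per_cell_total = arr.sum(axis=1)
    n_tx = int(per_cell_total.sum())
    cell_rep = np.repeat(np.arange(len(cells)), per_cell_total)
    gene_rep = np.concatenate([
        np.repeat(genes, arr[i]) for i in range(len(cells))
    ]) if n_tx else np.array([], dtype=object)
    x = cx[cell_rep] + rng.normal(0, jitter, n_tx)
    y = cy[cell_rep] + rng.normal(0, jitter, n_tx)
    nuclear = rng.random(n_tx) < nuclear_fraction
    transcripts = pd.DataFrame({
        "x": x, "y": y, "gene": gene_rep,
        "cell_id": cells[cell_rep], "nuclear": nuclear,
    })
    nuclear_count = pd.Series(
        np.bincount(cell_rep, weights=nuclear, minlength=len(cells)).astype(int),
        index=counts.index, name="nuclear_count")
    return transcripts, nuclear_count


def simulate(config: SyntheticConfig, sample_id: str = "sample",
             replicate_id: str = "R1", seed: int | None = None):
    """Run the full generator: tissue, expression, barcodes, transcripts.

    Returns ``(SampleBundle, GroundTruth)``. Identical ``config`` and seed
    yield identical outputs.
    """
    base = config.seed if seed is None else seed
    truth_cells, annotations = generate_tissue(config, seed=base)
    counts = generate_expression(truth_cells, config.gene_models,
                                 seed=base + 1)
    if config.perturbation_design is not None:
        counts, truth_cells = inject_perturbation_barcodes(
            counts, truth_cells, config.perturbation_design,
            config.gene_models, villus_height=config.villus_height,
            seed=base + 2)
    transcripts, nuclear_count = realize_transcripts(
        counts, truth_cells, config.nuclear_fraction,
        config.transcript_jitter, seed=base + 3)

    meta = pd.DataFrame({
        "x": truth_cells["x"], "y": truth_cells["y"],
        "nuclear_count": nuclear_count,
        "cell_type": truth_cells["cell_type"],
        "cluster": truth_cells["cluster"],
        "sample_id": sample_id, "replicate_id": replicate_id,
    })
    cells = CellTable(counts, meta)
    villus_labels = truth_cells["villus_id"]
    bundle = SampleBundle(transcripts, cells, annotations, villus_labels,
                          sample_id=sample_id)
    gene_truth = pd.DataFrame(
        [(gm.gene, gm.b0, gm.b_cv, gm.b_epi, gm.b_long,
          ",".join(gm.cell_types) if gm.cell_types else "")
         for gm in config.gene_models],
        columns=["gene", "b0", "b_cv", "b_epi", "b_long", "cell_types"],
    ).set_index("gene")
    return bundle, GroundTruth(truth_cells, gene_truth)
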