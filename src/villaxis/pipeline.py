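"""End-to-end pipeline tying the analysis stages together.

Stages run in dependency order (simulate/load -> qc -> axes -> imap ->
gradients -> proximity -> perturb); every numeric output is a CSV/TSV in the
output directory, written with fixed float formatting so identical seeds
yield byte-identical files. The resolved configuration and seed are
snapshotted alongside the outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import axes as axes_mod
from . import gradients as grad_mod
from . import imap as imap_mod
from . import io
from . import perturb as perturb_mod
from . import proximity as prox_mod
from . import synthgut
from .core_data import qc_filter_cells

log = logging.getLogger("villaxis")

FLOAT_FORMAT = "%.10g"

DEFAULT_GATES = {
    # IMAP x is the display-rescaled crypt–villus value in [0, 1]; IMAP y is
    # asinh of the clipped epithelial z-score (negative near the epithelium).
    "top": [[0.75, -3.0], [1.01, -3.0], [1.01, 3.0], [0.75, 3.0]],
    "crypt": [[-0.01, -3.0], [0.25, -3.0], [0.25, 3.0], [-0.01, 3.0]],
}

DEFAULT_CONFIG = {
    "seed": 0,
    "stages": {"simulate": True, "qc": True, "axes": True, "imap": True,
               "gradients": True, "proximity": True, "perturb": True},
    "qc": {"min_nuclear": 8, "min_total": 20, "max_total": 800},
    "axes": {"k_epi": 5, "k_any": 5, "clip_upper": 3.0,
             "neighborhood_k": 10, "n_factors": 15, "smoothing_k": 150},
    "imap": {"width": 0.5, "weight_gene": "Gzmb"},
    "gradients": {"subset_cell_type": "CD8_T", "min_fraction": 0.05,
                  "rho_threshold": 0.05},
    "proximity": {"graph": "knn", "graph_param": 6,
                  "interaction_threshold": 0.1, "ks_cutoff": 0.08},
    "perturb": {"marker_min": 3, "contaminant": "Muc2", "contaminant_max": 1,
                "required_clusters": ["CD8_T"]},
}


def _merge(base: dict, override: dict | None) -> dict:
    out = {k: (v.copy() if isinstance(v, dict) else v) for k, v in base.items()}
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, float_format=FLOAT_FORMAT)


def run_pipeline(
    out_dir,
    config: dict | None = None,
    bundle=None,
    seed: int | None = None,
) -> dict:
    """Run the pipeline into ``out_dir`` and return stage artifacts.

    Without an input ``bundle`` the synthetic generator supplies the sample
    (with the pooled-perturbation scenario enabled so every downstream stage
    has work to do). A failing stage raises with the stage name.
    """
    cfg = _merge(DEFAULT_CONFIG, config)
    if seed is not None:
        cfg["seed"] = int(seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stages = cfg["stages"]
    artifacts: dict = {"config": cfg}
    timings = {}

    def stage(name):
        def wrap(fn):
            if not stages.get(name, True):
                return
            t0 = time.perf_counter()
            try:
                fn()
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            timings[name] = round(time.perf_counter() - t0, 3)
            log.info("stage %s done in %.2fs", name, timings[name])
        return wrap

    truth = None

    @stage("simulate")
    def _simulate():
        nonlocal bundle, truth
        if bundle is None:
            sim_cfg = synthgut.SyntheticConfig(
                seed=cfg["seed"],
                perturbation_design=synthgut.PerturbationDesign(),
            )
            bundle, truth = synthgut.simulate(sim_cfg, seed=cfg["seed"])
            io.write_bundle(bundle, out_dir / "bundle")
            _write(truth.cells, out_dir / "ground_truth.csv")

    if bundle is None and not stages.get("simulate", True):
        raise ValueError("no input bundle and the simulate stage is disabled")

    cells = None

    @stage("qc")
    def _qc():
        nonlocal cells
        cells, report = qc_filter_cells(bundle.cells, return_report=True,
                                        **cfg["qc"])
        (out_dir / "qc_report.json").write_text(json.dumps(report, indent=1))

    if cells is None:
        cells = bundle.cells

    axis_set = None

    @stage("axes")
    def _axes():
        nonlocal axis_set
        acfg = cfg["axes"]
        axis_set = axes_mod.compute_axes(
            cells, bundle.annotations["basal_membrane"], bundle.villus_labels,
            k_epi=acfg["k_epi"], k_any=acfg["k_any"],
            clip_upper=acfg["clip_upper"])
        _write(axis_set.values, out_dir / "axes.csv")

    coords = gate_labels = None

    @stage("imap")
    def _imap():
        nonlocal coords, gate_labels
        icfg = cfg["imap"]
        scored = axis_set.values.dropna(subset=["crypt_villus_display"])
        coords = imap_mod.imap_coordinates(scored, w=icfg["width"])
        gates = imap_mod.GateSet(DEFAULT_GATES)
        gate_labels = imap_mod.assign_gates(coords, gates)
        weight_gene = icfg["weight_gene"]
        weights = (cells.counts.loc[coords.index, weight_gene]
                   if weight_gene in cells.genes else None)
        p14 = cells.meta.loc[coords.index, "cell_type"] == "CD8_T"
        if weights is not None and weights[p14].sum() > 0:
            field, _ = imap_mod.weighted_kde(
                coords[p14.to_numpy()], weights=weights[p14].to_numpy(),
                weight_label=weight_gene)
            np.savetxt(out_dir / "imap_density.tsv", field.density,
                       delimiter="\t", fmt=FLOAT_FORMAT)
        out = coords.copy()
        out["gate"] = gate_labels
        _write(out, out_dir / "imap.csv")
        io.write_gates(DEFAULT_GATES, out_dir / "gates.json")

    @stage("gradients")
    def _gradients():
        gcfg = cfg["gradients"]
        subset_ids = cells.cell_ids[
            cells.meta["cell_type"] == gcfg["subset_cell_type"]]
        sub_counts = cells.counts.loc[subset_ids]
        keep = grad_mod.expression_fraction_filter(sub_counts,
                                                   gcfg["min_fraction"])
        tables = []
        for axis_name in ("crypt_villus", "epithelial", "longitudinal"):
            axis = axis_set.values.loc[subset_ids, axis_name].dropna()
            tables.append(grad_mod.axis_correlation_screen(
                sub_counts.loc[axis.index], axis, genes=keep,
                threshold=gcfg["rho_threshold"], axis_name=axis_name))
        _write(pd.concat(tables, ignore_index=True),
               out_dir / "gradients.csv")

    @stage("proximity")
    def _proximity():
        pcfg = cfg["proximity"]
        graph = prox_mod.spatial_neighbor_graph(
            cells.centroids, pcfg["graph"], pcfg["graph_param"])
        interactions = prox_mod.interaction_scores(
            graph, cells.meta["cell_type"].to_numpy(),
            threshold=pcfg["interaction_threshold"])
        long_rows = interactions.raw.stack().rename("raw").to_frame()
        long_rows["max_norm"] = interactions.max_normalized.stack()
        long_rows["row_norm"] = interactions.row_normalized.stack()
        long_rows.index.names = ["type_a", "type_b"]
        _write(long_rows, out_dir / "interactions.csv")
        distances = prox_mod.nearest_type_distances(cells)
        _write(distances, out_dir / "distances.csv")

    @stage("perturb")
    def _perturb():
        pcfg = cfg["perturb"]
        design = perturb_mod.BarcodeDesign()
        calls = perturb_mod.call_perturbed_cells(
            cells, design, marker_min=pcfg["marker_min"],
            contaminant=pcfg["contaminant"],
            contaminant_max=pcfg["contaminant_max"],
            required_clusters=pcfg["required_clusters"])
        _write(calls, out_dir / "calls.csv")
        called = calls[calls["called"]]
        if called["sgrna"].nunique() >= 2 and (
                called.groupby("sgrna").size() >= 3).all():
            de = perturb_mod.perturbation_de(cells, calls)
            de.to_csv(out_dir / "de_stats.csv", index=False,
                      float_format=FLOAT_FORMAT)

    snapshot = {"config": cfg, "timings": timings}
    (out_dir / "config_snapshot.json").write_text(
        json.dumps(snapshot, indent=1, default=_json_default))
    artifacts.update({"cells": cells, "axes": axis_set, "bundle": bundle,
                      "truth": truth, "timings": timings})
    return artifacts


def _json_default(obj):
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")
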