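import numpy as np
import pandas as pd
import pytest

import villaxis as vx


@pytest.fixture(scope="session")
def default_sample():
    """Default-sized synthetic sample (10 villi, ~5,000 cells) with barcodes."""
    cfg = vx.SyntheticConfig(perturbation_design=vx.PerturbationDesign())
    bundle, truth = vx.simulate(cfg, seed=11)
    return bundle, truth


@pytest.fixture(scope="session")
def small_sample():
    """Three-villus sample kept small for fast unit tests."""
    cfg = vx.SyntheticConfig(
        n_villi=3,
        cells_per_villus={"epithelial": 50, "lamina_propria": 80,
                          "muscularis": 25},
        perturbation_design=vx.PerturbationDesign(),
    )
    bundle, truth = vx.simulate(cfg, seed=7)
    return bundle, truth


@pytest.fixture(scope="session")
def default_axes(default_sample):
    from villaxis import axes

    bundle, _ = default_sample
    return axes.compute_axes(bundle.cells,
                             bundle.annotations["basal_membrane"],
                             bundle.villus_labels)


def make_cell_table(counts: dict, meta: dict | None = None) -> vx.CellTable:
    """Build a small CellTable from a gene -> per-cell-count mapping."""
    counts = pd.DataFrame(counts)
    counts.index = pd.Index([f"c{i}" for i in range(len(counts))],
                            name="cell_id")
    counts.columns = counts.columns.rename("gene")
    base = {
        "x": np.arange(len(counts), dtype=float),
        "y": np.zeros(len(counts)),
        "nuclear_count": 0,
        "cell_type": "T",
        "cluster": "T",
    }
    base.update(meta or {})
    return vx.CellTable(counts, pd.DataFrame(base, index=counts.index))
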