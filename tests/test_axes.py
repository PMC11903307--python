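import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

import villaxis as vx
from conftest import make_cell_table
from villaxis import axes
from villaxis.core_data import PolylineAnnotation


def dense_longitudinal_oracle(vertices, points, n_samples=10_000):
    """Arc-length fraction via dense sampling along the polyline."""
    verts = np.asarray(vertices, float)
    seg = np.linalg.norm(np.diff(verts, axis=0), axis=1)
    cum = np.concatenate([[0], np.cumsum(seg)])
    total = cum[-1]
    s = np.linspace(0, total, n_samples)
    seg_idx = np.clip(np.searchsorted(cum, s, side="right") - 1,
                      0, len(seg) - 1)
    frac = (s - cum[seg_idx]) / seg[seg_idx]
    samples = verts[seg_idx] + frac[:, None] * np.diff(verts, axis=0)[seg_idx]
    out = []
    for p in np.asarray(points, float):
        d = np.linalg.norm(samples - p, axis=1)
        out.append(s[d.argmin()] / total)
    return np.array(out)


def _cells_at(xy, **meta):
    xy = np.asarray(xy, float)
    table = make_cell_table({"g": np.zeros(len(xy), dtype=int)}, meta)
    table.meta["x"] = xy[:, 0]
    table.meta["y"] = xy[:, 1]
    return table


class TestLongitudinal:
    def test_projection_endpoints_and_midpoint(self):
        basal = PolylineAnnotation("b", [(0, 0), (10, 0)])
        cells = _cells_at([(0, 1), (5, 2), (10, 3)])
        lon = axes.longitudinal_axis(cells, basal)
        np.testing.assert_allclose(lon.to_numpy(), [0.0, 0.5, 1.0])

    def test_matches_dense_sampling_oracle(self):
        rng = np.random.default_rng(4)
        verts = [(0, 0), (5, 3), (9, 1), (15, 6)]
        pts = rng.uniform([0, -2], [15, 8], size=(50, 2))
        cells = _cells_at(pts)
        lon = axes.longitudinal_axis(cells, PolylineAnnotation("b", verts))
        oracle = dense_longitudinal_oracle(verts, pts)
        np.testing.assert_allclose(lon.to_numpy(), oracle, atol=1e-3)

    def test_invariant_to_rigid_translation(self):
        rng = np.random.default_rng(5)
        verts = np.array([(0., 0.), (7., 2.), (12., 0.)])
        pts = rng.uniform(0, 12, size=(20, 2))
        lon1 = axes.longitudinal_axis(_cells_at(pts),
                                      PolylineAnnotation("b", verts))
        shift = np.array([100.0, -50.0])
        lon2 = axes.longitudinal_axis(_cells_at(pts + shift),
                                      PolylineAnnotation("b", verts + shift))
        np.testing.assert_allclose(lon1.to_numpy(), lon2.to_numpy(),
                                   atol=1e-12)


class TestCryptVillusGeometric:
    def test_known_zscores(self):
        basal = PolylineAnnotation("b", [(0, 0), (10, 0)])
        cells = _cells_at([(1, 1), (2, 2), (3, 3)])
        labels = pd.Series([0, 0, 0], index=cells.cell_ids)
        out = axes.crypt_villus_axis_geometric(cells, basal, labels)
        np.testing.assert_allclose(out["crypt_villus_raw"], [1, 2, 3])
        sd = np.sqrt(2.0 / 3.0)  # population s.d. of {1,2,3}
        np.testing.assert_allclose(out["crypt_villus"],
                                   [-1 / sd, 0, 1 / sd], atol=1e-12)

    def test_zero_variance_villus_maps_to_zero(self):
        basal = PolylineAnnotation("b", [(0, 0), (10, 0)])
        cells = _cells_at([(1, 2), (5, 2), (9, 2)])
        labels = pd.Series([0, 0, 0], index=cells.cell_ids)
        out = axes.crypt_villus_axis_geometric(cells, basal, labels)
        np.testing.assert_allclose(out["crypt_villus"], 0.0)

    def test_per_villus_zscore_moments(self, default_sample, default_axes):
        bundle, _ = default_sample
        z = default_axes.values["crypt_villus"]
        for villus, idx in bundle.villus_labels.dropna().groupby(
                bundle.villus_labels).groups.items():
            vals = z.loc[idx]
            assert abs(vals.mean()) < 1e-9
            np.testing.assert_allclose(vals.std(ddof=0), 1.0, atol=1e-9)

    def test_recovers_truth_per_villus(self, default_sample, default_axes):
        bundle, truth = default_sample
        z = default_axes.values["crypt_villus"]
        for villus, idx in bundle.villus_labels.dropna().groupby(
                bundle.villus_labels).groups.items():
            rho = spearmanr(z.loc[idx],
                            truth.cells.loc[idx, "crypt_villus"]).statistic
            assert rho > 0.95


class TestNeighborhoodEmbedding:
    def test_k1_neighborhood_equals_nearest_neighbor_row(self):
        counts = np.eye(4, dtype=int)
        cells = make_cell_table(
            {f"g{j}": counts[:, j] for j in range(4)})
        cells.meta["x"] = [0.0, 1.0, 5.0, 6.0]
        cells.meta["y"] = 0.0
        nbr = axes.neighborhood_counts(cells, k=1)
        np.testing.assert_array_equal(
            nbr.to_numpy(),
            np.array([[0, 1, 0, 0], [1, 0, 0, 0],
                      [0, 0, 0, 1], [0, 0, 1, 0]]))

    def test_rank_one_matrix_recovered_by_single_factor(self):
        rng = np.random.default_rng(6)
        u = rng.uniform(1, 2, 30)[:, None]
        v = rng.uniform(0, 3, 8)[None, :]
        mat = pd.DataFrame(u * v)
        emb = axes.neighborhood_factors(mat, n_factors=1, seed=0)
        recon = emb.loadings.to_numpy() @ emb.components
        rel_err = np.linalg.norm(recon - mat.to_numpy()) / np.linalg.norm(mat)
        assert rel_err < 1e-6
        assert (emb.loadings.to_numpy() >= 0).all()

    def test_cell_order_permutation_leaves_loadings_unchanged(self):
        rng = np.random.default_rng(7)
        mat = pd.DataFrame(rng.uniform(0, 5, size=(40, 6)),
                           index=[f"c{i}" for i in range(40)])
        emb = axes.neighborhood_factors(mat, n_factors=3, seed=0)
        perm = rng.permutation(40)
        emb_p = axes.neighborhood_factors(mat.iloc[perm], n_factors=3, seed=0)
        aligned = emb_p.loadings.loc[mat.index]
        # factors may come out permuted; match columns by best correlation
        a = emb.loadings.to_numpy()
        b = aligned.to_numpy()
        for j in range(3):
            sims = [np.corrcoef(a[:, j], b[:, k])[0, 1] for k in range(3)]
            assert max(sims) > 0.999


class TestPredictedAxis:
    def test_memorizing_regressor_reproduces_labels(self):
        rng = np.random.default_rng(8)
        w = pd.DataFrame(rng.uniform(0, 1, size=(50, 4)),
                         index=[f"c{i}" for i in range(50)])
        emb = axes.NeighborhoodEmbedding(w, np.zeros((4, 1)), 0.0)
        labels = pd.Series(rng.uniform(0, 1, 50), index=w.index)
        from sklearn.neighbors import KNeighborsRegressor

        model = axes.CryptVillusRegressor(
            regressor=KNeighborsRegressor(n_neighbors=1), smoothing_k=1)
        model.fit(w.to_numpy(), labels.to_numpy())
        np.testing.assert_allclose(model.predict(w.to_numpy()),
                                   labels.to_numpy())

    def test_smoothing_k1_is_identity(self):
        rng = np.random.default_rng(9)
        w = rng.uniform(0, 1, size=(30, 3))
        y = rng.uniform(0, 1, 30)
        coords = rng.uniform(0, 100, size=(30, 2))
        model = axes.CryptVillusRegressor(smoothing_k=1, min_labelled=10)
        model.fit(w, y)
        np.testing.assert_allclose(model.predict(w, coords=coords),
                                   model.predict(w))

    def test_too_few_labels_rejected(self):
        model = axes.CryptVillusRegressor(min_labelled=20)
        with pytest.raises(ValueError, match="labelled"):
            model.fit(np.zeros((5, 2)), np.zeros(5))

    def test_cross_sample_recovery(self):
        cfg = vx.SyntheticConfig()
        bundle_a, _ = vx.simulate(cfg, sample_id="A", seed=31)
        bundle_b, truth_b = vx.simulate(cfg, sample_id="B", seed=32)
        epi_stromal = ("Enterocyte", "Goblet", "Progenitor_enterocyte",
                       "Fibroblast", "Smooth_muscle")
        nbr_a = axes.neighborhood_counts(bundle_a.cells, k=10,
                                         restrict_types=epi_stromal)
        nbr_b = axes.neighborhood_counts(bundle_b.cells, k=10,
                                         restrict_types=epi_stromal)
        joint = pd.concat([nbr_a, nbr_b], keys=["A", "B"])
        emb = axes.neighborhood_factors(joint, n_factors=15, seed=0)
        geom = axes.crypt_villus_axis_geometric(
            bundle_a.cells, bundle_a.annotations["basal_membrane"],
            bundle_a.villus_labels)
        labels = pd.Series(np.nan, index=joint.index)
        labels.loc[[("A", c) for c in geom.index]] = geom[
            "crypt_villus"].to_numpy()
        offset = np.array([1e6, 0.0])  # keep samples spatially disjoint
        coords = np.vstack([bundle_a.cells.centroids,
                            bundle_b.cells.centroids + offset])
        pred, metrics = axes.crypt_villus_axis_predicted(
            emb, labels, coords, smoothing_k=150, seed=0)
        in_villus = truth_b.cells["compartment"] != "muscularis"
        rho = spearmanr(pred.loc["B"][in_villus],
                        truth_b.cells.loc[in_villus, "crypt_villus"]).statistic
        assert rho > 0.8
        assert metrics["holdout_spearman"] > 0.8


class TestEpithelialAxis:
    def test_all_epithelial_neighbourhood_gives_unit_ratio(self):
        # 6 epithelial cells on a tight cluster; the probe cell's 5 nearest
        # of any type are exactly the 5 nearest epithelial cells
        xy = [(0, 0)] + [(np.cos(a), np.sin(a))
                         for a in np.linspace(0, 2 * np.pi, 6)[:-1]]
        cells = _cells_at(xy, cell_type="Enterocyte")
        out = axes.epithelial_axis(cells, epithelial_types=("Enterocyte",))
        np.testing.assert_allclose(out["epithelial_raw"].iloc[0], 1.0)

    def test_raw_ratio_matches_brute_force_on_toy_layout(self):
        rng = np.random.default_rng(10)
        xy = rng.uniform(0, 50, size=(30, 2))
        types = np.where(np.arange(30) < 12, "Enterocyte", "CD8_T")
        cells = _cells_at(xy, cell_type=types)
        out = axes.epithelial_axis(cells, epithelial_types=("Enterocyte",))
        d = np.linalg.norm(xy[:, None] - xy[None, :], axis=2)
        np.fill_diagonal(d, np.inf)
        epi_cols = np.where(types == "Enterocyte")[0]
        for i in range(30):
            mean_epi = np.sort(d[i, epi_cols])[:5].mean()
            mean_any = np.sort(d[i])[:5].mean()
            np.testing.assert_allclose(out["epithelial_raw"].iloc[i],
                                       mean_epi / mean_any, rtol=1e-12)
        assert (out["epithelial_raw"] >= 1.0).all()

    def test_epithelial_cells_score_below_lamina_propria(
            self, default_sample, default_axes):
        _, truth = default_sample
        z = default_axes.values["epithelial"]
        mean_epi = z[truth.cells["compartment"] == "epithelial"].mean()
        mean_lp = z[truth.cells["compartment"] == "lamina_propria"].mean()
        assert mean_epi < mean_lp

    def test_clipping_bound_respected(self, default_axes):
        assert (default_axes.values["epithelial_clipped"] <= 3.0).all()
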