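import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from conftest import make_cell_table
from villaxis import imap


def ray_casting_oracle(point, vertices):
    """Independent even-odd point-in-polygon test (boundary inclusive)."""
    x, y = point
    verts = np.asarray(vertices, float)
    n = len(verts)
    inside = False
    for i in range(n):
        x1, y1 = verts[i]
        x2, y2 = verts[(i + 1) % n]
        # on-segment check for boundary inclusivity
        cross = (x2 - x1) * (y - y1) - (y2 - y1) * (x - x1)
        if (abs(cross) < 1e-12
                and min(x1, x2) - 1e-12 <= x <= max(x1, x2) + 1e-12
                and min(y1, y2) - 1e-12 <= y <= max(y1, y2) + 1e-12):
            return True
        if (y1 > y) != (y2 > y):
            x_int = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            if x < x_int:
                inside = not inside
    return inside


class TestBiexponential:
    def test_odd_function_through_origin(self):
        assert imap.biexponential_transform(0.0, w=0.5) == 0.0
        v = imap.biexponential_transform([-2.0, 2.0], w=0.5)
        np.testing.assert_allclose(v[0], -v[1])

    def test_analytic_inverse_point(self):
        w = 0.7
        np.testing.assert_allclose(
            imap.biexponential_transform(w * np.sinh(1.0), w=w), 1.0,
            atol=1e-14)

    def test_numeric_roundtrip(self):
        rng = np.random.default_rng(12)
        v = rng.uniform(-10, 10, 100)
        back = imap.biexponential_inverse(
            imap.biexponential_transform(v, w=0.5), w=0.5)
        np.testing.assert_allclose(back, v, atol=1e-10)

    def test_strictly_increasing(self):
        v = np.linspace(-5, 5, 101)
        t = imap.biexponential_transform(v, w=0.3)
        assert (np.diff(t) > 0).all()

    def test_invalid_width_rejected(self):
        with pytest.raises(ValueError):
            imap.biexponential_transform(1.0, w=0.0)


class TestIMAPCoordinates:
    def _axes_frame(self, cv, epi):
        return pd.DataFrame({"crypt_villus_display": cv,
                             "epithelial_clipped": epi},
                            index=[f"c{i}" for i in range(len(cv))])

    def test_zero_epithelial_maps_to_zero_y(self):
        coords = imap.imap_coordinates(self._axes_frame([0.5], [0.0]))
        np.testing.assert_allclose(coords.iloc[0], [0.5, 0.0])

    def test_monotone_in_epithelial(self):
        epi = np.linspace(-3, 3, 50)
        coords = imap.imap_coordinates(self._axes_frame(np.zeros(50), epi))
        assert (np.diff(coords["imap_y"]) > 0).all()

    def test_missing_axes_rejected(self):
        with pytest.raises(ValueError, match="epithelial_clipped"):
            imap.imap_coordinates(pd.DataFrame({"crypt_villus_display": [1.0]}))


class TestWeightedKDE:
    def _points(self, xy):
        xy = np.asarray(xy, float)
        return pd.DataFrame({"imap_x": xy[:, 0], "imap_y": xy[:, 1]})

    def test_equal_weights_match_unweighted(self):
        rng = np.random.default_rng(13)
        pts = self._points(rng.normal(size=(200, 2)))
        _, d_unweighted = imap.weighted_kde(pts)
        _, d_equal = imap.weighted_kde(pts, weights=np.full(200, 3.7))
        np.testing.assert_allclose(d_equal, d_unweighted, atol=1e-12)

    def test_single_positive_weight_gives_single_gaussian(self):
        pts = self._points([(0, 0), (5, 5), (9, 1)])
        w = np.array([0.0, 1.0, 0.0])
        field, dens = imap.weighted_kde(pts, weights=w, bandwidth=1.0)
        assert dens.argmax() == 1
        # density at the weighted point equals the 2-D Gaussian peak
        np.testing.assert_allclose(dens[1], 1 / (2 * np.pi), rtol=1e-10)

    def test_two_point_mixture_matches_closed_form(self):
        h = 0.8
        pts = self._points([(0, 0), (2, 0)])
        _, dens = imap.weighted_kde(pts, bandwidth=h)
        # equal-weight mixture of two isotropic Gaussians with s.d. h
        def mixture(x, y):
            g1 = np.exp(-((x - 0) ** 2 + y ** 2) / (2 * h ** 2))
            g2 = np.exp(-((x - 2) ** 2 + y ** 2) / (2 * h ** 2))
            return (g1 + g2) / (2 * 2 * np.pi * h ** 2)
        np.testing.assert_allclose(dens[0], mixture(0, 0), rtol=1e-10)

    def test_mass_normalization_on_sample(self, default_axes):
        scored = default_axes.values.dropna(subset=["crypt_villus_display"])
        coords = imap.imap_coordinates(scored)
        field, _ = imap.weighted_kde(coords)
        assert abs(field.integral() - 1.0) < 0.01

    def test_zero_weights_rejected(self):
        pts = self._points([(0, 0), (1, 1)])
        with pytest.raises(ValueError, match="zero"):
            imap.weighted_kde(pts, weights=np.zeros(2))


class TestGates:
    unit_square = [(0, 0), (1, 0), (1, 1), (0, 1)]

    def _pts(self, xy):
        xy = np.asarray(xy, float)
        return pd.DataFrame({"imap_x": xy[:, 0], "imap_y": xy[:, 1]})

    def test_inside_edge_and_outside(self):
        gates = imap.GateSet({"sq": self.unit_square})
        labels = imap.assign_gates(
            self._pts([(0.5, 0.5), (1.0, 0.5), (2.0, 2.0)]), gates)
        assert list(labels) == ["sq", "sq", "none"]

    def test_priority_is_declaration_order(self):
        gates = imap.GateSet({"first": self.unit_square,
                              "second": [(0.5, -1), (2, -1), (2, 2), (0.5, 2)]})
        labels = imap.assign_gates(self._pts([(0.75, 0.5)]), gates)
        assert list(labels) == ["first"]

    def test_self_intersecting_polygon_rejected(self):
        bowtie = [(0, 0), (1, 1), (1, 0), (0, 1)]
        with pytest.raises(ValueError, match="simple"):
            imap.GateSet({"bad": bowtie})

    def test_matches_ray_casting_oracle_on_random_points(self):
        rng = np.random.default_rng(14)
        pts = rng.uniform(-0.5, 1.5, size=(200, 2))
        pentagon = [(0.1, 0.0), (0.9, 0.1), (1.0, 0.8), (0.5, 1.2), (0.0, 0.7)]
        triangle = [(0.4, -0.4), (1.4, 0.2), (0.6, 0.6)]
        gates = imap.GateSet({"pent": pentagon, "tri": triangle})
        labels = imap.assign_gates(self._pts(pts), gates)
        for p, got in zip(pts, labels):
            if ray_casting_oracle(p, pentagon):
                expected = "pent"
            elif ray_casting_oracle(p, triangle):
                expected = "tri"
            else:
                expected = "none"
            assert got == expected


class TestGateStatistics:
    def test_all_in_one_gate(self):
        cells = make_cell_table({"g": [1, 2, 3]})
        labels = pd.Series(["top"] * 3, index=cells.cell_ids)
        _, _, fractions = imap.gate_statistics(cells, labels)
        assert fractions.loc["all", "top"] == 1.0

    def test_six_four_split(self):
        cells = make_cell_table({"g": np.ones(10, int)})
        labels = pd.Series(["a"] * 6 + ["b"] * 4, index=cells.cell_ids)
        summary, _, fractions = imap.gate_statistics(cells, labels)
        assert summary.loc["a", "n_cells"] == 6
        np.testing.assert_allclose(fractions.loc["all", ["a", "b"]], [0.6, 0.4])

    def test_group_fractions_sum_to_one_including_none(self):
        cells = make_cell_table({"g": np.ones(9, int)})
        labels = pd.Series(["a", "b", "none"] * 3, index=cells.cell_ids)
        groups = pd.Series(["p", "q", "p"] * 3, index=cells.cell_ids)
        _, _, fractions = imap.gate_statistics(cells, labels, groups=groups)
        np.testing.assert_allclose(fractions.sum(axis=1), 1.0)

    def test_shifted_population_enriches_top_gate(self, default_axes):
        import villaxis as vx
        from villaxis import axes as axes_mod

        cfg = vx.SyntheticConfig(perturbation_design=vx.PerturbationDesign(
            shift_sgrna="sgCxcr3", contamination_rate=0.0))
        bundle, truth = vx.simulate(cfg, seed=17)
        aset = axes_mod.compute_axes(bundle.cells,
                                     bundle.annotations["basal_membrane"],
                                     bundle.villus_labels)
        scored = aset.values.dropna(subset=["crypt_villus_display"])
        coords = imap.imap_coordinates(scored)
        gates = imap.GateSet({"top": [(0.75, -3), (1.01, -3), (1.01, 3),
                                      (0.75, 3)]})
        labels = imap.assign_gates(coords, gates)
        sg = truth.cells["sgrna"].reindex(coords.index)
        top_shifted = (labels[sg == "sgCxcr3"] == "top").mean()
        top_control = (labels[sg == "sgCd19"] == "top").mean()
        assert top_shifted > top_control


class TestSignatureScore:
    def test_top_ranked_signature_scores_one(self):
        counts = {f"g{i}": [10 - i] for i in range(10)}
        cells = make_cell_table(counts)
        score = imap.signature_score(cells, ["g0", "g1", "g2"], max_rank=8)
        np.testing.assert_allclose(score.iloc[0], 1.0)

    def test_signature_beyond_max_rank_scores_zero(self):
        counts = {f"g{i}": [100 - i] for i in range(10)}
        cells = make_cell_table(counts)
        score = imap.signature_score(cells, ["g8", "g9"], max_rank=5)
        np.testing.assert_allclose(score.iloc[0], 0.0)

    def test_matches_hand_computed_rank_formula(self):
        # one cell, 10-gene panel, 3-gene signature with a tie
        counts = {"a": [9], "b": [7], "c": [7], "d": [5], "e": [4],
                  "f": [3], "g": [2], "h": [2], "i": [1], "j": [0]}
        cells = make_cell_table(counts)
        ranks = rankdata([-9, -7, -7, -5, -4, -3, -2, -2, -1, 0])
        sig_ranks = ranks[[0, 3, 5]]  # a, d, f
        n, r_max = 3, 9
        u = np.minimum(sig_ranks, r_max).sum() - n * (n + 1) / 2
        expected = 1 - u / (n * r_max - n * (n + 1) / 2)
        score = imap.signature_score(cells, ["a", "d", "f"], max_rank=r_max)
        np.testing.assert_allclose(score.iloc[0], expected)

    def test_monotone_when_signature_gene_count_increases(self):
        rng = np.random.default_rng(15)
        base = rng.integers(0, 20, 12)
        low = make_cell_table({f"g{i}": [int(base[i])] for i in range(12)})
        bumped = base.copy()
        bumped[3] += 15
        high = make_cell_table({f"g{i}": [int(bumped[i])] for i in range(12)})
        sig = ["g3", "g7"]
        assert (imap.signature_score(high, sig, max_rank=10).iloc[0]
                >= imap.signature_score(low, sig, max_rank=10).iloc[0])

    def test_bounds_and_empty_signature(self, small_sample):
        bundle, _ = small_sample
        score = imap.signature_score(bundle.cells, ["Gzmb", "Tcf7"],
                                     max_rank=20)
        assert score.between(0, 1).all()
        with pytest.raises(ValueError):
            imap.signature_score(bundle.cells, [])
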