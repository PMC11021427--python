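"""Transition estimation, Markov projection, allocation and driver
screening."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from habscape.change import (
    TransitionMatrix,
    allocate_change,
    net_change,
    project_demand,
    screen_drivers,
    suitability,
    transition_matrix,
)
from habscape.raster import ContinuousRaster, GridTransform, Legend

from conftest import TWO_CLASS_LEGEND, make_categorical


class TestTransitionMatrix:
    def test_identical_maps_give_identity(self, seven_class_landcover):
        tm = transition_matrix(seven_class_landcover, seven_class_landcover, 30)
        np.testing.assert_allclose(tm.probs, np.eye(7))

    def test_single_flip_probability(self):
        a = np.array([[1, 1], [1, 1]])
        b = np.array([[2, 1], [1, 1]])
        tm = transition_matrix(
            make_categorical(a, legend=TWO_CLASS_LEGEND),
            make_categorical(b, legend=TWO_CLASS_LEGEND),
            30,
        )
        i, j = tm.legend.codes.index(1), tm.legend.codes.index(2)
        assert tm.probs[i, j] == pytest.approx(0.25)

    def test_absent_class_gets_identity_row(self):
        legend = Legend([(1, "a"), (2, "b"), (3, "absent")])
        a = make_categorical(np.array([[1, 2]]), legend=legend)
        b = make_categorical(np.array([[1, 2]]), legend=legend)
        tm = transition_matrix(a, b, 30)
        k = tm.legend.codes.index(3)
        assert tm.probs[k, k] == 1.0
        assert np.isfinite(tm.probs).all()

    def test_row_normalization_invariant(self, seven_class_landcover):
        from habscape.synthetic import SyntheticConfig, evolve_landcover

        tm0 = TransitionMatrix.from_rows(
            seven_class_landcover.legend, {1: {6: 0.3}}
        )
        evolved = evolve_landcover(seven_class_landcover, tm0, seed=2)
        est = transition_matrix(seven_class_landcover, evolved, 30)
        np.testing.assert_allclose(est.probs.sum(axis=1), 1.0)


class TestNetChange:
    def test_identical_maps_all_zero(self, seven_class_landcover):
        changes = net_change(seven_class_landcover, seven_class_landcover)
        assert all(v == 0.0 for v in changes.values())

    def test_single_30m_cell_flip_is_009_ha(self):
        a = make_categorical(np.array([[1, 1], [1, 1]]), legend=TWO_CLASS_LEGEND)
        b = make_categorical(np.array([[2, 1], [1, 1]]), legend=TWO_CLASS_LEGEND)
        changes = net_change(a, b)
        assert changes[1] == pytest.approx(-0.09)
        assert changes[2] == pytest.approx(0.09)

    def test_conservation_on_fully_valid_maps(self, seven_class_landcover):
        from habscape.synthetic import evolve_landcover

        tm = TransitionMatrix.from_rows(seven_class_landcover.legend, {1: {6: 0.5}})
        evolved = evolve_landcover(seven_class_landcover, tm, seed=8)
        assert sum(net_change(seven_class_landcover, evolved).values()) == (
            pytest.approx(0.0, abs=1e-9)
        )


class TestProjectDemand:
    def test_zero_steps_returns_input(self):
        tm = TransitionMatrix(TWO_CLASS_LEGEND, np.array([[0.9, 0.1], [0.2, 0.8]]))
        comp = {1: 0.3, 2: 0.7}
        assert project_demand(tm, comp, 0) == pytest.approx(comp)

    def test_identity_matrix_fixes_composition(self):
        tm = TransitionMatrix(TWO_CLASS_LEGEND, np.eye(2))
        comp = {1: 0.25, 2: 0.75}
        assert project_demand(tm, comp, 5) == pytest.approx(comp)

    def test_two_step_hand_computation(self):
        tm = TransitionMatrix(TWO_CLASS_LEGEND, np.array([[0.9, 0.1], [0.2, 0.8]]))
        out = project_demand(tm, {1: 1.0, 2: 0.0}, 2)
        assert out[1] == pytest.approx(0.83)
        assert out[2] == pytest.approx(0.17)

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(0, 2**31 - 1), st.integers(0, 6))
    def test_simplex_preserved_for_random_stochastic_matrices(self, seed, n):
        rng = np.random.default_rng(seed)
        k = 4
        probs = rng.dirichlet(np.ones(k), size=k)
        legend = Legend([(i + 1, f"c{i}") for i in range(k)])
        tm = TransitionMatrix(legend, probs)
        comp = dict(zip(legend.codes, rng.dirichlet(np.ones(k))))
        out = project_demand(tm, comp, n)
        vals = np.array(list(out.values()))
        assert (vals >= -1e-12).all()
        assert vals.sum() == pytest.approx(1.0)


def _surface(values):
    values = np.asarray(values, dtype=float)
    return ContinuousRaster(
        values, transform=GridTransform(0, values.shape[0] * 30.0, 30.0)
    )


class TestSuitability:
    def test_single_covariate_is_minmax_normalized(self):
        cov = _surface([[0.0, 5.0], [10.0, 2.5]])
        out = suitability([cov], [1.0])
        np.testing.assert_allclose(out.values, [[0.0, 0.5], [1.0, 0.25]])

    def test_zero_weights_give_uniform_half(self):
        cov = _surface([[0.0, 5.0], [10.0, 2.5]])
        out = suitability([cov], [0.0])
        np.testing.assert_allclose(out.values, 0.5)

    def test_constant_covariate_contributes_half(self):
        flat = _surface(np.full((2, 2), 3.0))
        ramp = _surface([[0.0, 1.0], [2.0, 3.0]])
        out = suitability([flat, ramp], [1.0, 1.0])
        # flat adds a constant 0.5; after rescaling the ramp's ordering rules
        expected = (np.array([[0.0, 1.0], [2.0, 3.0]]) / 3.0)
        np.testing.assert_allclose(out.values, expected)

    def test_equal_weights_hand_surface(self):
        a = _surface([[0, 1, 2], [3, 4, 5], [6, 7, 8]])
        b = _surface([[8, 7, 6], [5, 4, 3], [2, 1, 0]])
        out = suitability([a, b], [1.0, 1.0])
        np.testing.assert_allclose(out.values, 0.5)


class TestAllocateChange:
    def test_identity_matrix_leaves_map_unchanged(self, seven_class_landcover):
        tm = TransitionMatrix(seven_class_landcover.legend, np.eye(7))
        out = allocate_change(seven_class_landcover, tm, seed=1)
        np.testing.assert_array_equal(out.values, seven_class_landcover.values)

    def test_top_suitability_cells_convert(self):
        vals = np.ones((5, 4), dtype=int)
        lc = make_categorical(vals, legend=TWO_CLASS_LEGEND)
        tm = TransitionMatrix(TWO_CLASS_LEGEND, np.array([[0.5, 0.5], [0.0, 1.0]]))
        ranking = np.arange(20, dtype=float).reshape(5, 4)
        surf = ContinuousRaster(ranking, transform=lc.transform)
        out = allocate_change(lc, tm, {(1, 2): surf}, seed=0)
        converted = out.values == 2
        assert converted.sum() == 10
        assert set(ranking[converted]) == set(range(10, 20))

    def test_composition_error_at_most_one_cell_per_transition(
        self, seven_class_landcover
    ):
        tm = TransitionMatrix.from_rows(
            seven_class_landcover.legend,
            {1: {6: 0.13, 7: 0.07}, 2: {6: 0.2}, 4: {6: 0.33, 7: 0.11}},
        )
        counts_before = seven_class_landcover.class_counts()
        out = allocate_change(seven_class_landcover, tm, seed=3)
        counts_after = out.class_counts()
        codes = tm.legend.codes
        idx = {c: i for i, c in enumerate(codes)}
        expected = np.zeros(len(codes))
        for c in codes:
            expected += counts_before.get(c, 0) * tm.probs[idx[c]]
        for c in codes:
            # K transitions feed each class; each may be off by <= 1 cell
            assert abs(counts_after.get(c, 0) - expected[idx[c]]) <= len(codes)

    def test_infeasible_demand_converts_all_donors(self):
        lc = make_categorical(
            np.array([[1, 2], [2, 2]]), legend=TWO_CLASS_LEGEND
        )
        tm = TransitionMatrix(TWO_CLASS_LEGEND, np.array([[0.0, 1.0], [0.0, 1.0]]))
        out = allocate_change(lc, tm, seed=0)
        assert (out.values == 2).all()


class TestScreenDrivers:
    def test_mask_identical_covariate_flagged(self):
        rng = np.random.default_rng(0)
        mask_vals = rng.integers(0, 2, size=(32, 32))
        mask = make_categorical(
            mask_vals + 1, legend=Legend([(1, "stable"), (2, "changed")])
        )
        cov = ContinuousRaster(mask_vals.astype(float), transform=mask.transform)
        report = screen_drivers({"selfsame": cov}, mask)
        assert report.values["selfsame"] == pytest.approx(1.0)
        assert report.influential["selfsame"]

    def test_independent_covariate_not_flagged(self):
        rng = np.random.default_rng(1)
        mask_vals = rng.integers(0, 2, size=(64, 64))
        mask = make_categorical(
            mask_vals + 1, legend=Legend([(1, "stable"), (2, "changed")])
        )
        cov = ContinuousRaster(
            rng.permutation(mask_vals.astype(float).ravel()).reshape(64, 64),
            transform=mask.transform,
        )
        report = screen_drivers({"noise": cov}, mask)
        assert report.values["noise"] < 0.1
        assert not report.influential["noise"]

    def test_constant_covariate_scores_zero(self):
        mask = make_categorical(
            np.array([[1, 2], [2, 1]]), legend=Legend([(1, "s"), (2, "c")])
        )
        cov = ContinuousRaster(np.full((2, 2), 7.0), transform=mask.transform)
        assert screen_drivers({"flat": cov}, mask).values["flat"] == 0.0
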