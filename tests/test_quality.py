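"""Habitat-quality core: decay kernels, degradation, half-saturation
transform, six-level classification."""

import numpy as np
import pandas as pd
import pytest

from habscape.quality import (
    HQParams,
    SensitivityTable,
    ThreatSpec,
    classify_hq,
    decay_factor,
    degradation,
    load_sensitivity,
    load_threat_specs,
    mean_hq,
    quality,
    resolve_half_saturation,
)
from habscape.raster import ContinuousRaster, GridTransform, Legend
from habscape.synthetic import SyntheticConfig, generate_landcover, generate_threat_layers

from _oracles import degradation_bruteforce
from conftest import make_categorical

LINEAR = ThreatSpec("t", max_dist_km=0.3, weight=1.0, decay="linear")
EXPONENTIAL = ThreatSpec("t", max_dist_km=0.3, weight=1.0, decay="exponential")


def binary_layer(mask, template):
    return make_categorical(
        np.asarray(mask, dtype=np.int64),
        legend=Legend([(0, "absent"), (1, "present")]),
        nodata=-1,
    )


def simple_sensitivity(habitat=1.0, s=1.0, threats=("t",)):
    frame = pd.DataFrame(
        {"habitat": [habitat], **{name: [s] for name in threats}},
        index=pd.Index(["class 1"], name="lulc"),
    )
    return SensitivityTable(frame)


class TestShippedTables:
    def test_seven_threats_with_expected_kinds(self):
        specs = load_threat_specs()
        assert len(specs) == 7
        kinds = {s.name: s.decay for s in specs}
        assert kinds["Agriculture land"] == "linear"
        assert kinds["Mining land"] == "exponential"
        weights = {s.name: s.weight for s in specs}
        assert weights["Agriculture land"] == pytest.approx(0.82)
        assert max(s.max_dist_km for s in specs) == 10

    def test_sensitivity_rows_cover_default_legend(self):
        sens = load_sensitivity()
        assert sens.habitat("Zagros forest") == 1.0
        assert sens.habitat("Build up area") == 0.0
        assert sens.sensitivity("Rangeland/fair", "Main roads") == pytest.approx(0.73)
        assert set(sens.threat_names) == {s.name for s in load_threat_specs()}


class TestDecay:
    @pytest.mark.parametrize("spec", [LINEAR, EXPONENTIAL])
    def test_unity_at_source(self, spec):
        assert decay_factor(0.0, spec) == 1.0

    def test_linear_reaches_zero_at_max_distance(self):
        assert decay_factor(LINEAR.max_dist_m, LINEAR) == 0.0
        assert decay_factor(LINEAR.max_dist_m / 2, LINEAR) == pytest.approx(0.5)

    def test_exponential_value_and_cutoff(self):
        d = EXPONENTIAL.max_dist_m / 2
        assert decay_factor(d, EXPONENTIAL) == pytest.approx(np.exp(-2.99 / 2))
        assert decay_factor(EXPONENTIAL.max_dist_m * 1.001, EXPONENTIAL) == 0.0

    @pytest.mark.parametrize("spec", [LINEAR, EXPONENTIAL])
    def test_monotone_nonincreasing(self, spec):
        d = np.linspace(0, spec.max_dist_m * 1.5, 50)
        vals = decay_factor(d, spec)
        assert (np.diff(vals) <= 1e-12).all()


class TestDegradation:
    def test_zero_without_threat_cells(self):
        lc = make_categorical(np.ones((8, 8), dtype=int))
        layer = binary_layer(np.zeros((8, 8)), lc)
        D = degradation(lc, {"t": layer}, [LINEAR], simple_sensitivity())
        np.testing.assert_allclose(D.values, 0.0)

    def test_zero_where_sensitivity_zero(self):
        lc = make_categorical(np.ones((8, 8), dtype=int))
        layer = binary_layer(np.eye(8), lc)
        D = degradation(lc, {"t": layer}, [LINEAR], simple_sensitivity(s=0.0))
        np.testing.assert_allclose(D.values, 0.0)

    def test_single_threat_half_distance_gives_half(self):
        # one threat pixel; a cell 5 cells away with d_rmax = 10 cells
        lc = make_categorical(np.ones((1, 11), dtype=int))
        mask = np.zeros((1, 11))
        mask[0, 0] = 1
        spec = ThreatSpec("t", max_dist_km=0.3, weight=1.0, decay="linear")
        D = degradation(lc, {"t": binary_layer(mask, lc)}, [spec],
                        simple_sensitivity())
        assert D.values[0, 5] == pytest.approx(0.5, rel=1e-6)
        assert D.values[0, 10] == pytest.approx(0.0, abs=1e-9)

    def test_weight_normalization_scale_invariance(self, seven_class_landcover):
        cfg = SyntheticConfig(n_rows=64, n_cols=64, seed=7)
        layers = generate_threat_layers(seven_class_landcover, cfg)
        specs = load_threat_specs()
        sens = load_sensitivity()
        scaled = [
            ThreatSpec(s.name, s.max_dist_km, s.weight * 3.7, s.decay)
            for s in specs
        ]
        a = degradation(seven_class_landcover, layers, specs, sens)
        b = degradation(seven_class_landcover, layers, scaled, sens)
        np.testing.assert_allclose(a.values, b.values, rtol=1e-12)

    def test_adding_a_threat_cell_never_decreases_degradation(self):
        lc = make_categorical(np.ones((12, 12), dtype=int))
        mask = np.zeros((12, 12))
        mask[2, 2] = 1
        base = degradation(lc, {"t": binary_layer(mask, lc)}, [LINEAR],
                           simple_sensitivity())
        mask2 = mask.copy()
        mask2[9, 9] = 1
        more = degradation(lc, {"t": binary_layer(mask2, lc)}, [LINEAR],
                           simple_sensitivity())
        assert (more.values - base.values >= -1e-12).all()

    def test_matches_bruteforce_on_mixed_threats(self):
        cfg = SyntheticConfig(n_rows=24, n_cols=24, seed=13)
        lc = generate_landcover(cfg)
        layers = generate_threat_layers(lc, cfg)
        specs = load_threat_specs()
        sens = load_sensitivity()
        subset = {k: layers[k] for k in ("Agriculture land", "Mining land")}
        fast = degradation(lc, subset, specs, sens)
        slow = degradation_bruteforce(lc, subset, specs, sens)
        np.testing.assert_allclose(fast.values, slow, rtol=1e-6, atol=1e-9)

    def test_missing_spec_or_sensitivity_raises(self):
        lc = make_categorical(np.ones((4, 4), dtype=int))
        layer = binary_layer(np.eye(4), lc)
        with pytest.raises(KeyError):
            degradation(lc, {"mystery": layer}, [LINEAR], simple_sensitivity())


class TestHalfSaturation:
    def test_auto_is_half_of_max(self):
        D = ContinuousRaster(np.array([[0.2, 1.0], [0.4, 0.0]]))
        assert resolve_half_saturation(D, HQParams()) == pytest.approx(0.5)

    def test_user_value_passes_through(self):
        D = ContinuousRaster(np.array([[0.2]]))
        assert resolve_half_saturation(D, HQParams(half_saturation=0.3)) == 0.3

    def test_degradation_free_landscape_falls_back(self):
        D = ContinuousRaster(np.zeros((3, 3)))
        assert resolve_half_saturation(D, HQParams()) == 0.5

    def test_invalid_user_value_rejected(self):
        with pytest.raises(ValueError):
            HQParams(half_saturation=-1.0)


class TestQuality:
    def test_closed_forms_over_shipped_table(self):
        """Q = H at D = 0, Q = H/2 at D = K, for every land-cover class."""
        sens = load_sensitivity()
        legend = Legend([(i + 1, n) for i, n in enumerate(sens.frame.index)])
        K = 0.37
        for code, name in legend:
            lc = make_categorical(np.full((1, 2), code), legend=legend)
            D = ContinuousRaster(np.array([[0.0, K]]), transform=lc.transform)
            qr = quality(lc, D, sens, HQParams(half_saturation=K))
            H = sens.habitat(name)
            assert qr.quality.values[0, 0] == pytest.approx(H)
            assert qr.quality.values[0, 1] == pytest.approx(H / 2)

    def test_built_up_is_non_habitat_everywhere(self):
        sens = load_sensitivity()
        legend = Legend([(7, "Build up area")])
        lc = make_categorical(np.full((2, 2), 7), legend=legend)
        D = ContinuousRaster(np.array([[0.0, 0.1], [5.0, 50.0]]),
                             transform=lc.transform)
        qr = quality(lc, D, sens, HQParams(half_saturation=1.0))
        np.testing.assert_allclose(qr.quality.values, 0.0)

    def test_strictly_decreasing_in_degradation(self):
        lc = make_categorical(np.ones((1, 5), dtype=int))
        D = ContinuousRaster(np.array([[0.0, 0.1, 0.5, 1.0, 3.0]]),
                             transform=lc.transform)
        qr = quality(lc, D, simple_sensitivity(), HQParams(half_saturation=0.5))
        q = qr.quality.values[0]
        assert (np.diff(q) < 0).all()
        assert ((q >= 0) & (q <= 1)).all()


class TestClassifyAndMean:
    def test_all_zero_quality_is_no_habitat(self):
        Q = ContinuousRaster(np.zeros((4, 4)))
        raster, table = classify_hq(Q)
        assert (raster.values == 0).all()
        row = table.set_index("class").loc["No habitat"]
        assert row["cells"] == 16

    @pytest.mark.parametrize(
        "value, expected",
        [(0.2, "Poor"), (0.6, "Moderate"), (0.61, "Relatively good"),
         (1.0, "Good"), (1e-9, "Poor")],
    )
    def test_boundary_convention(self, value, expected):
        raster, _ = classify_hq(ContinuousRaster(np.array([[value]])))
        assert raster.legend.name(int(raster.values[0, 0])) == expected

    def test_hand_raster_areas(self):
        Q = ContinuousRaster(
            np.array([[0.0, 0.1, 0.3], [0.5, 0.7, 0.9], [0.9, 0.5, 0.0]]),
            transform=GridTransform(0, 90, 30.0),
        )
        _, table = classify_hq(Q)
        areas = table.set_index("class")["area_ha"]
        assert areas["No habitat"] == pytest.approx(0.18)
        assert areas["Good"] == pytest.approx(0.18)
        assert areas["Moderate"] == pytest.approx(0.18)
        assert table["area_ha"].sum() == pytest.approx(9 * 0.09)

    def test_mean_hq_values(self):
        Q = ContinuousRaster(np.array([[0.0, 1.0], [0.25, 0.75]]))
        assert mean_hq(Q) == pytest.approx(0.5)
        assert mean_hq(Q, mask=np.array([[True, True], [False, False]])) == (
            pytest.approx(0.5)
        )
        with pytest.raises(ValueError):
            mean_hq(Q, mask=np.zeros((2, 2), dtype=bool))
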