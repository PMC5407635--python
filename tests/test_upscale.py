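"""Regional upscaling: grid prediction, zonal statistics, totals,
deviation classification, CO2-equivalent accounting, yield validation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from soiln2o import emulate as em
from soiln2o import upscale as up
from soiln2o.synthgen import PREDICTORS, GridSet, PredictorGrid


def mk_gridset(values_by_name, codes, variant="MT1",
               region_index=("R0", "R1")):
    gs = GridSet(variant=variant)
    for name, vals in values_by_name.items():
        gs.layers[name] = PredictorGrid(
            name=name, values=np.asarray(vals, float), cellsize=1.0,
            origin=(0.0, 0.0), region_codes=np.asarray(codes),
            region_index=tuple(region_index), variant=variant)
    return gs


@pytest.fixture(scope="module")
def toy_model():
    rng = np.random.default_rng(3)
    tab = pd.DataFrame({n: rng.uniform(0, 10, 400) for n in PREDICTORS})
    tab["n2o"] = 0.4 * tab["soc_stock"] + 0.1 * tab["clay"]
    return em.fit(tab, em.RFHyper(n_trees=40, seed=0)), tab


class TestPredictGrid:
    def test_constant_grid_equals_record_prediction(self, toy_model):
        model, tab = toy_model
        rec = tab.iloc[[5]]
        codes = np.zeros((4, 4), int)
        gs = mk_gridset({n: np.full((4, 4), rec[n].iloc[0])
                         for n in PREDICTORS}, codes)
        flux = up.predict_grid(model, gs)
        np.testing.assert_allclose(flux, model.predict(rec)[0])

    def test_masked_cells_yield_nodata(self, toy_model):
        model, tab = toy_model
        codes = np.zeros((3, 3), int)
        codes[0, 0] = -1
        gs = mk_gridset({n: np.full((3, 3), 5.0) for n in PREDICTORS}, codes)
        flux = up.predict_grid(model, gs)
        assert np.isnan(flux[0, 0]) and np.isfinite(flux[1:]).all()

    def test_matches_percell_loop_oracle(self, toy_model):
        model, _ = toy_model
        rng = np.random.default_rng(1)
        shape = (5, 6)
        codes = np.zeros(shape, int)
        gs = mk_gridset({n: rng.uniform(0, 10, shape) for n in PREDICTORS},
                        codes)
        flux = up.predict_grid(model, gs)
        for i in range(shape[0]):
            for j in range(shape[1]):
                rec = pd.DataFrame({n: [gs[n].values[i, j]]
                                    for n in PREDICTORS})
                assert flux[i, j] == model.predict(rec)[0]

    def test_misaligned_layers_rejected(self, toy_model):
        model, _ = toy_model
        vals = {n: np.zeros((3, 3)) for n in PREDICTORS}
        gs = mk_gridset(vals, np.zeros((3, 3), int))
        gs.layers["clay"] = PredictorGrid("clay", np.zeros((2, 2)), 1.0,
                                          (0, 0), np.zeros((2, 2), int),
                                          ("R0",), "MT1")
        with pytest.raises(ValueError, match="shape"):
            up.predict_grid(model, gs)


class TestZonalMean:
    def test_constant_region(self):
        flux = np.full((4, 4), 2.5)
        codes = np.zeros((4, 4), int)
        assert up.zonal_mean(flux, codes, ("R0",)) == {"R0": 2.5}

    def test_two_cells(self):
        flux = np.array([[1.0, 3.0]])
        codes = np.zeros((1, 2), int)
        assert up.zonal_mean(flux, codes, ("R0",))["R0"] == 2.0

    def test_empty_region_missing_not_zero(self):
        flux = np.array([[1.0, np.nan]])
        codes = np.array([[0, 1]])
        out = up.zonal_mean(flux, codes, ("R0", "R1"))
        assert "R1" not in out and out["R0"] == 1.0

    def test_matches_bruteforce_average(self):
        rng = np.random.default_rng(2)
        flux = rng.uniform(0, 5, (10, 12))
        codes = rng.integers(0, 4, (10, 12))
        out = up.zonal_mean(flux, codes, ("A", "B", "C", "D"))
        for i, rid in enumerate(("A", "B", "C", "D")):
            assert out[rid] == pytest.approx(flux[codes == i].mean(),
                                             rel=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            up.zonal_mean(np.zeros((2, 2)), np.zeros((3, 3), int), ("R0",))


class TestDirectTotal:
    def test_single_point_total(self):
        df = pd.DataFrame({"region_id": ["R0"], "n2o": [2.0]})
        ests, total, excl = up.direct_total(df, {"R0": 1000.0})
        # 2 kg/ha x 1000 ha = 2000 kg = 2e-6 Tg
        assert ests["R0"].total_n2o_n == pytest.approx(2000.0 / 1e9)
        assert excl == []

    def test_pointless_region_excluded_and_logged(self):
        df = pd.DataFrame({"region_id": ["R0"], "n2o": [2.0]})
        ests, total, excl = up.direct_total(df, {"R0": 10.0, "R9": 99.0})
        assert "R9" in excl and "R9" not in ests

    def test_regional_totals_add_up(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame({"region_id": rng.choice(["A", "B", "C"], 60),
                           "n2o": rng.uniform(0.5, 4, 60)})
        areas = {"A": 1e5, "B": 2e5, "C": 3e5}
        ests, total, _ = up.direct_total(df, areas)
        assert total == pytest.approx(
            sum(e.total_n2o_n for e in ests.values()), rel=1e-12)

    def test_negative_area_rejected(self):
        df = pd.DataFrame({"region_id": ["R0"], "n2o": [2.0]})
        with pytest.raises(ValueError):
            up.direct_total(df, {"R0": -5.0})


class TestVarStatistic:
    @pytest.mark.parametrize("mt,lcs,expect", [
        (1.0, 1.0, 0.0), (1.2, 1.0, 20.0), (0.5, 1.0, -50.0)])
    def test_printed_examples(self, mt, lcs, expect):
        assert up.var_statistic(mt, lcs) == pytest.approx(expect)

    @given(mt=st.floats(0.0, 10.0), lcs=st.floats(0.01, 10.0))
    @settings(max_examples=60, derandomize=True)
    def test_matches_formula(self, mt, lcs):
        assert up.var_statistic(mt, lcs) == (mt - lcs) / lcs * 100.0

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            up.var_statistic(1.0, 0.0)


class TestClassifyVar:
    def comps(self, vals):
        return [up.RegionalComparison(f"R{i}", 1.0, 1.0, v)
                for i, v in enumerate(vals)]

    def test_all_zero_within(self):
        out = up.classify_var(self.comps([0.0] * 5))
        assert out["outside_inner"] == 0 and out["within"] == 5

    def test_mixed_bands(self):
        out = up.classify_var(self.comps([10.0, -30.0, 60.0]))
        assert out["outside_inner"] == 2
        assert out["beyond_outer"] == 1
        assert out["flagged"] == ["R2"]

    def test_partition_and_bruteforce_counts(self):
        rng = np.random.default_rng(7)
        vals = rng.uniform(-100, 100, 200)
        out = up.classify_var(self.comps(vals))
        assert out["within"] + out["outside_inner"] == out["total"] == 200
        assert out["outside_inner"] == int((np.abs(vals) > 20).sum())
        assert out["beyond_outer"] == int((np.abs(vals) > 50).sum())
        assert out["beyond_outer"] <= out["outside_inner"]


class TestToCo2eq:
    def test_printed_survey_totals(self):
        # 0.41 Tg N2O-N -> ~170.7 Tg CO2eq (printed 170.6 from the
        # unrounded total)
        assert up.to_co2eq(0.41) == pytest.approx(170.6, abs=0.2)

    def test_zero(self):
        assert up.to_co2eq(0.0) == 0.0

    def test_unit_mass_conversion(self):
        assert up.to_co2eq(1.0) == pytest.approx(44.0 / 28.0 * 265.0)
        assert up.to_co2eq(1.0) == pytest.approx(416.43, abs=0.005)

    @given(a=st.floats(0, 1e3), b=st.floats(0, 1e3))
    @settings(max_examples=60, derandomize=True)
    def test_linearity_to_rounding(self, a, b):
        assert up.to_co2eq(a + b) == pytest.approx(
            up.to_co2eq(a) + up.to_co2eq(b), rel=1e-12, abs=1e-12)

    def test_invalid_gwp_rejected(self):
        with pytest.raises(ValueError):
            up.to_co2eq(1.0, gwp=0.0)


class TestYieldCompare:
    def test_identical_vectors_zero_error(self):
        sim = pd.DataFrame({"region_id": ["A", "B"], "crop": ["potato"] * 2,
                            "yield_c": [3.0, 4.0]})
        rep = pd.DataFrame({"region_id": ["A", "B"], "crop": ["potato"] * 2,
                            "fresh_yield": [3.0 / 0.45 / 0.22,
                                            4.0 / 0.45 / 0.22]})
        out = up.yield_compare(sim, rep, {"potato": 0.78})
        assert out.rmse == pytest.approx(0.0, abs=1e-12)
        assert out.mae == pytest.approx(0.0, abs=1e-12)

    def test_moisture_carbon_hand_conversion(self):
        # fresh 10 Mg at 14% moisture -> 10 x 0.86 x 0.45 = 3.87 Mg C
        sim = pd.DataFrame({"region_id": ["A"], "crop": ["winter_wheat"],
                            "yield_c": [0.0]})
        rep = pd.DataFrame({"region_id": ["A"], "crop": ["winter_wheat"],
                            "fresh_yield": [10.0]})
        out = up.yield_compare(sim, rep, {"winter_wheat": 0.14})
        assert out.mae == pytest.approx(3.87)

    def test_definitional_residuals(self):
        sim = pd.DataFrame({"region_id": ["A", "B"], "crop": ["potato"] * 2,
                            "yield_c": [1.0, -1.0]})
        rep = pd.DataFrame({"region_id": ["A", "B"], "crop": ["potato"] * 2,
                            "fresh_yield": [0.0, 0.0]})
        out = up.yield_compare(sim, rep, {"potato": 0.0})
        assert out.mae == pytest.approx(1.0)
        assert out.rmse == pytest.approx(1.0)
        sim2 = sim.assign(yield_c=[0.0, 2.0])
        out2 = up.yield_compare(sim2, rep, {"potato": 0.0})
        assert out2.mae == pytest.approx(1.0)
        assert out2.rmse == pytest.approx(np.sqrt(2.0))

    def test_no_matches_rejected(self):
        sim = pd.DataFrame({"region_id": ["A"], "crop": ["potato"],
                            "yield_c": [1.0]})
        rep = pd.DataFrame({"region_id": ["B"], "crop": ["cotton"],
                            "fresh_yield": [1.0]})
        with pytest.raises(ValueError, match="matched"):
            up.yield_compare(sim, rep, {"potato": 0.0, "cotton": 0.0})
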