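"""Meta-model: training table, split, fit/evaluate, permutation importance."""

import numpy as np
import pandas as pd
import pytest

from soiln2o import emulate as em
from soiln2o.synthgen import PREDICTORS


def random_table(n, seed=0, target="linear"):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({name: rng.uniform(0, 10, n) for name in PREDICTORS})
    if target == "linear":
        df["n2o"] = 0.3 * df["soc_stock"] + 0.1 * df["clay"]
    elif target == "copy":
        df["n2o"] = df["soc_stock"]
    else:
        df["n2o"] = rng.uniform(0, 5, n)
    return df


class TestBuildTable:
    def test_complete_points_give_full_records(self, small_world,
                                               small_results):
        pts = small_world["points"][:10]
        tab = em.build_table(pts, small_world["derived"], small_results,
                             small_world["weathers"])
        assert len(tab) == 10
        assert set(PREDICTORS) | {"n2o"} <= set(tab.columns)
        assert tab[list(PREDICTORS) + ["n2o"]].notna().all().all()

    def test_rain_equals_bruteforce_resummation(self, small_world,
                                                small_results):
        p = small_world["points"][0]
        tab = em.build_table([p], small_world["derived"], small_results,
                             small_world["weathers"])
        w = small_world["weathers"][p.point_id]
        res = small_results[p.point_id]
        years = res.reported_years
        wy = w.dates.year.to_numpy()
        expect = np.mean([w.precip[wy == y].sum() for y in years])
        assert tab.loc[0, "rain"] == pytest.approx(expect, rel=1e-12)

    def test_missing_inputs_error_names_point(self, small_world,
                                              small_results):
        p = small_world["points"][0]
        with pytest.raises(ValueError, match=p.point_id):
            em.build_table([p], {}, small_results, small_world["weathers"])

    def test_ensemble_target_overrides_deterministic(self, small_world,
                                                     small_results):
        p = small_world["points"][0]
        tab = em.build_table([p], small_world["derived"], small_results,
                             small_world["weathers"],
                             targets={p.point_id: 1.234})
        assert tab.loc[0, "n2o"] == 1.234


class TestSplit:
    def test_75_25_sizes(self):
        tr, te = em.split(random_table(100), 0.75, seed=1)
        assert len(tr) == 75 and len(te) == 25

    def test_disjoint_exhaustive(self):
        tab = random_table(37)
        tab["i"] = np.arange(37)
        tr, te = em.split(tab, 0.75, seed=2)
        assert set(tr["i"]) | set(te["i"]) == set(range(37))
        assert set(tr["i"]) & set(te["i"]) == set()

    def test_seeded_partition_stable(self):
        tab = random_table(40)
        a1 = em.split(tab, seed=5)[0]
        a2 = em.split(tab, seed=5)[0]
        pd.testing.assert_frame_equal(a1, a2)

    def test_too_few_records_rejected(self):
        with pytest.raises(ValueError):
            em.split(random_table(3))


class TestFit:
    def test_recovers_copied_predictor(self):
        """Target equal to one predictor is learnable to held-out R^2>0.99."""
        tab = random_table(5000, seed=3, target="copy")
        tr, te = em.split(tab, 0.75, seed=0)
        model = em.fit(tr, em.RFHyper(n_trees=100, seed=0))
        _, ve = em.evaluate(model, te)
        assert ve > 99.0

    def test_single_record_rejected(self):
        with pytest.raises(ValueError):
            em.fit(random_table(1))

    def test_constant_target_rejected(self):
        tab = random_table(50)
        tab["n2o"] = 2.0
        with pytest.raises(ValueError, match="constant"):
            em.fit(tab)

    def test_save_load_roundtrip(self, tmp_path):
        tab = random_table(200, seed=5)
        tr, te = em.split(tab, seed=0)
        model = em.fit(tr, em.RFHyper(n_trees=20, seed=3))
        path = tmp_path / "emulator.joblib"
        model.save(str(path))
        loaded = em.Emulator.load(str(path))
        np.testing.assert_array_equal(model.predict(te), loaded.predict(te))
        assert loaded.hyper.seed == 3

    def test_seeded_determinism(self):
        tab = random_table(300, seed=4)
        tr, te = em.split(tab, seed=0)
        p1 = em.fit(tr, em.RFHyper(n_trees=50, seed=7)).predict(te)
        p2 = em.fit(tr, em.RFHyper(n_trees=50, seed=7)).predict(te)
        np.testing.assert_array_equal(p1, p2)


class TestEvaluate:
    def test_perfect_predictions(self):
        tab = random_table(200, seed=1, target="copy")
        model = em.fit(tab, em.RFHyper(n_trees=30, seed=0,
                                       bootstrap=False))
        rmse, ve = em.evaluate(model, tab)
        assert rmse == pytest.approx(0.0, abs=1e-9)
        assert ve == pytest.approx(100.0, abs=1e-6)

    def test_mean_predictor_explains_nothing(self):
        tab = random_table(100, seed=2, target="random")

        class MeanModel:
            features = tuple(PREDICTORS)

            def predict(self, df):
                return np.full(len(df), tab["n2o"].mean())

        rmse, ve = em.evaluate(MeanModel(), tab)
        assert ve == pytest.approx(0.0, abs=1e-9)
        assert rmse == pytest.approx(tab["n2o"].std(ddof=0), rel=1e-12)

    def test_agrees_with_bruteforce_formula(self):
        tab = random_table(150, seed=6)
        tr, te = em.split(tab, seed=0)
        model = em.fit(tr, em.RFHyper(n_trees=40, seed=0))
        rmse, ve = em.evaluate(model, te)
        pred = model.predict(te)
        y = te["n2o"].to_numpy()
        mse = np.mean((pred - y) ** 2)
        assert rmse == pytest.approx(np.sqrt(mse), rel=1e-12)
        assert ve == pytest.approx(100 * (1 - mse / np.var(y)), rel=1e-12)

    def test_empty_data_rejected(self):
        model = em.fit(random_table(20), em.RFHyper(n_trees=10))
        with pytest.raises(ValueError):
            em.evaluate(model, random_table(20).iloc[:0])


class TestImportance:
    def test_identity_permutation_is_exactly_zero(self):
        tab = random_table(200, seed=1)
        model = em.fit(tab, em.RFHyper(n_trees=30, seed=0))
        imp = em.importance(model, tab, n_permutations=2, seed=0,
                            permuter=lambda rng, n: np.arange(n))
        assert all(v == 0.0 for v in imp.values())

    def test_copied_predictor_ranks_first(self):
        tab = random_table(800, seed=2, target="copy")
        tr, te = em.split(tab, seed=0)
        model = em.fit(tr, em.RFHyper(n_trees=60, seed=0))
        imp = em.importance(model, te, n_permutations=3, seed=0)
        assert max(imp, key=imp.get) == "soc_stock"

    def test_too_few_records_rejected(self):
        tab = random_table(30)
        model = em.fit(tab, em.RFHyper(n_trees=10))
        with pytest.raises(ValueError):
            em.importance(model, tab.iloc[:5])

    def test_missing_predictor_rejected(self):
        tab = random_table(40)
        model = em.fit(tab, em.RFHyper(n_trees=10))
        with pytest.raises(ValueError, match="missing"):
            model.predict(tab.drop(columns=["clay"]))

    def test_agrees_with_sklearn_permutation_importance(self):
        """Independent cross-check: our %IncMSE ranking matches sklearn's
        permutation importance (MSE-increase scoring) on a structured
        table."""
        from scipy.stats import spearmanr
        from sklearn.inspection import permutation_importance
        rng = np.random.default_rng(4)
        tab = pd.DataFrame({name: rng.uniform(0, 10, 600)
                            for name in PREDICTORS})
        tab["n2o"] = (2.0 * tab["soc_stock"] + 1.0 * tab["clay"]
                      + 0.4 * tab["rain"])
        tr, te = em.split(tab, seed=0)
        model = em.fit(tr, em.RFHyper(n_trees=60, seed=0))
        ours = em.importance(model, te, n_permutations=5, seed=0)
        ref = permutation_importance(
            model.model, te[list(PREDICTORS)].to_numpy(),
            te["n2o"].to_numpy(), n_repeats=5, random_state=0,
            scoring="neg_mean_squared_error")
        rho, _ = spearmanr([ours[p] for p in PREDICTORS],
                           ref.importances_mean)
        assert rho >= 0.8
        assert max(ours, key=ours.get) == \
            PREDICTORS[int(np.argmax(ref.importances_mean))] == "soc_stock"

    def test_ranking_stable_across_seeds(self):
        """Spearman rank correlation of importance across 5 RF seeds >= 0.8
        on a table whose target loads on every predictor with distinct
        weights (well-separated true ranking)."""
        from scipy.stats import spearmanr
        rng = np.random.default_rng(9)
        tab = pd.DataFrame({name: rng.uniform(0, 10, 1200)
                            for name in PREDICTORS})
        weights = np.linspace(1.0, 0.05, len(PREDICTORS))
        tab["n2o"] = sum(w * tab[p] for w, p in zip(weights, PREDICTORS))
        tr, te = em.split(tab, seed=0)
        ranks = []
        for s in range(5):
            model = em.fit(tr, em.RFHyper(n_trees=80, seed=s))
            imp = em.importance(model, te, n_permutations=3, seed=s)
            ranks.append([imp[p] for p in PREDICTORS])
        for i in range(1, 5):
            rho, _ = spearmanr(ranks[0], ranks[i])
            assert rho >= 0.8
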