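import numpy as np
import pandas as pd
import pytest
import shapely
from scipy import optimize, stats

from rangeshift import models
from rangeshift.grid import GridSpec
from rangeshift.occurrence_prep import StudyArea


@pytest.fixture(scope="module")
def rect_area():
    return StudyArea(polygon=shapely.box(0.5, 40.5, 3.5, 43.5), buffer_km=0.0, alpha=np.inf)


@pytest.fixture(scope="module")
def grid():
    return GridSpec(nrows=40, ncols=40, xmin=0.0, ymin=40.0, cellsize=0.1)


def synth_pb(seed=0, n_pres=300, n_bg=900, informative=True):
    """1-predictor presence/background with a monotone generative effect."""
    r = np.random.default_rng(seed)
    Xb = r.uniform(0, 1, (n_bg, 1))
    if informative:
        Xp = r.beta(4, 1.5, (n_pres, 1))
    else:
        Xp = r.uniform(0, 1, (n_pres, 1))
    return Xp, Xb


class TestMakeBackground:
    def test_containment(self, rect_area, grid):
        pts = models.make_background(rect_area, grid, n=500, seed=1)
        assert shapely.contains_xy(
            rect_area.polygon.buffer(1e-9), pts["lon"].to_numpy(), pts["lat"].to_numpy()
        ).all()

    def test_deterministic(self, rect_area, grid):
        a = models.make_background(rect_area, grid, n=200, seed=7)
        b = models.make_background(rect_area, grid, n=200, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_uniform_density(self, rect_area, grid):
        pts = models.make_background(rect_area, grid, n=30_000, seed=3)
        # equal-area quadrats: 3x3 degree box split into 0.5-degree cells
        qx = ((pts["lon"] - 0.5) // 0.5).astype(int)
        qy = ((pts["lat"] - 40.5) // 0.5).astype(int)
        counts = np.bincount(qy * 6 + qx, minlength=36)
        assert stats.chisquare(counts).pvalue > 0.01

    def test_degenerate_area_error(self, grid):
        empty = StudyArea(polygon=shapely.box(50, 50, 51, 51), buffer_km=0, alpha=1)
        with pytest.raises(ValueError):
            models.make_background(empty, grid, n=10, seed=0)


class TestSpatialBlocks:
    def test_square_corners_one_per_block(self):
        pres = pd.DataFrame({"lon": [0.0, 0.0, 1.0, 1.0], "lat": [0.0, 1.0, 0.0, 1.0]})
        bg = pd.DataFrame({"lon": [0.5], "lat": [0.5]})
        pf, _ = models.spatial_blocks(pres, bg)
        assert sorted(pf) == [1, 2, 3, 4]

    @pytest.mark.parametrize("seed", range(5))
    def test_balanced_when_divisible_by_four(self, seed):
        r = np.random.default_rng(seed)
        pres = pd.DataFrame({"lon": r.uniform(0, 10, 40), "lat": r.uniform(0, 10, 40)})
        bg = pd.DataFrame({"lon": r.uniform(0, 10, 100), "lat": r.uniform(0, 10, 100)})
        pf, _ = models.spatial_blocks(pres, bg)
        counts = np.bincount(pf)[1:]
        assert counts.max() - counts.min() <= 1

    def test_translation_invariance(self):
        r = np.random.default_rng(2)
        pres = pd.DataFrame({"lon": r.uniform(0, 5, 20), "lat": r.uniform(40, 45, 20)})
        bg = pd.DataFrame({"lon": r.uniform(0, 5, 50), "lat": r.uniform(40, 45, 50)})
        pf1, bf1 = models.spatial_blocks(pres, bg)
        shift = 3.7
        pf2, bf2 = models.spatial_blocks(pres + shift, bg + shift)
        np.testing.assert_array_equal(pf1, pf2)
        np.testing.assert_array_equal(bf1, bf2)

    def test_too_few_presences_error(self):
        pres = pd.DataFrame({"lon": [0.0, 0.0, 0.0], "lat": [0.0, 1.0, 2.0]})
        bg = pd.DataFrame({"lon": [0.5], "lat": [0.5]})
        with pytest.raises(ValueError):
            models.spatial_blocks(pres, bg)


class TestFitMaxent:
    def test_huge_regularization_constant_prediction(self):
        Xp, Xb = synth_pb()
        m = models.fit_maxent(Xp, Xb, feature_classes=("L",), reg_mult=1e6)
        assert np.all(m.coef == 0.0)
        preds = m.predict(Xb)
        assert np.allclose(preds, preds[0])

    def test_linear_only_matches_direct_optimization(self):
        """Independent oracle: optimize the same penalized weighted deviance
        with a split-variable L1 formulation via L-BFGS-B."""
        Xp, Xb = synth_pb(n_pres=150, n_bg=400)
        lam0, rm, bgw = 0.05, 1.5, 100.0
        m = models.fit_maxent(Xp, Xb, feature_classes=("L",), reg_mult=rm, lambda0=lam0, bg_weight=bgw)
        F = np.vstack([m.feature_map.transform(Xp), m.feature_map.transform(Xb)])
        y = np.concatenate([np.ones(len(Xp)), np.zeros(len(Xb))])
        w = np.concatenate([np.ones(len(Xp)), np.full(len(Xb), bgw)])
        npres = len(Xp)
        k = F.shape[1]

        def objective(theta):
            b0, bp, bn = theta[0], theta[1 : 1 + k], theta[1 + k :]
            eta = b0 + F @ (bp - bn)
            nll = np.logaddexp(0.0, eta) - y * eta
            # liblinear penalizes the intercept via its synthetic bias feature
            return (w * nll).sum() / npres + lam0 * (bp.sum() + bn.sum() + abs(b0))

        x0 = np.zeros(1 + 2 * k)
        bounds = [(None, None)] + [(0, None)] * (2 * k)
        res = optimize.minimize(objective, x0, method="L-BFGS-B", bounds=bounds,
                                options={"maxiter": 5000, "ftol": 1e-14, "gtol": 1e-10})
        oracle_coef = res.x[1 : 1 + k] - res.x[1 + k :]
        np.testing.assert_allclose(m.coef, oracle_coef, atol=1e-3)

    def test_monotone_prediction_with_linear_features(self):
        Xp, Xb = synth_pb()
        m = models.fit_maxent(Xp, Xb, feature_classes=("L",), reg_mult=1.0)
        xs = np.linspace(0, 1, 50)[:, None]
        preds = m.predict(xs)
        assert np.all(np.diff(preds) >= -1e-12)
        assert np.all((preds >= 0) & (preds <= 1))

    def test_too_few_presences_error(self):
        _, Xb = synth_pb()
        with pytest.raises(ValueError):
            models.fit_maxent(Xb[:1], Xb, feature_classes=("L",))

    def test_bad_reg_mult_and_features(self):
        Xp, Xb = synth_pb()
        with pytest.raises(ValueError):
            models.fit_maxent(Xp, Xb, feature_classes=("L",), reg_mult=0.0)
        with pytest.raises(ValueError):
            models.fit_maxent(Xp, Xb, feature_classes=())

    def test_hinge_predictions_in_unit_interval(self):
        Xp, Xb = synth_pb(seed=4)
        m = models.fit_maxent(Xp, Xb, feature_classes=("L", "Q", "H"), reg_mult=1.0)
        for X in (Xp, Xb, np.linspace(-0.5, 1.5, 30)[:, None]):
            p = m.predict(X)
            assert np.all(np.isfinite(p))
            assert np.all((p >= 0) & (p <= 1))


class TestTuneMaxent:
    @pytest.fixture(scope="class")
    def folds_data(self):
        r = np.random.default_rng(1)
        Xp, Xb = synth_pb(seed=1, n_pres=200, n_bg=400)
        pf = r.integers(1, 5, len(Xp))
        bf = r.integers(1, 5, len(Xb))
        return Xp, Xb, pf, bf

    def test_single_candidate_returned(self, folds_data):
        Xp, Xb, pf, bf = folds_data
        fc, rm, board = models.tune_maxent(
            Xp, Xb, pf, bf, feature_combos=(("L",),), reg_mults=np.array([2.0])
        )
        assert fc == ("L",) and rm == 2.0 and len(board) == 1

    def test_leaderboard_length(self, folds_data):
        Xp, Xb, pf, bf = folds_data
        _, _, board = models.tune_maxent(
            Xp, Xb, pf, bf,
            feature_combos=(("L",), ("L", "Q")),
            reg_mults=np.array([1.0, 5.0, 9.0]),
        )
        assert len(board) == 6

    def test_default_grid_is_7_by_91(self):
        assert len(models.FEATURE_CLASS_COMBOS) == 7
        reg = np.round(np.arange(1.0, 10.0 + 1e-9, 0.1), 1)
        assert len(reg) == 91

    def test_winner_minimizes_omission(self, folds_data):
        Xp, Xb, pf, bf = folds_data
        fc, rm, board = models.tune_maxent(
            Xp, Xb, pf, bf,
            feature_combos=(("L",), ("Q",)),
            reg_mults=np.array([1.0, 4.0]),
        )
        best_row = board.iloc[0]
        assert best_row["mean_omission"] == board["mean_omission"].min()
        assert "".join(fc) == best_row["feature_classes"]


class TestTreeModels:
    def make_data(self, seed=0, with_noise=True):
        r = np.random.default_rng(seed)
        n_p, n_b = 200, 500
        xb = r.uniform(0, 1, (n_b, 2))
        xp = np.column_stack([r.beta(4, 1.5, n_p), r.beta(1.5, 4, n_p)])
        if with_noise:
            xp = np.column_stack([xp, r.uniform(0, 1, n_p)])
            xb = np.column_stack([xb, r.uniform(0, 1, n_b)])
        pf = r.integers(1, 5, n_p)
        bf = r.integers(1, 5, n_b)
        return xp, xb, pf, bf

    @pytest.mark.parametrize("algorithm", ["RF", "BRT"])
    def test_predictions_in_unit_interval(self, algorithm):
        xp, xb, pf, bf = self.make_data()
        m = models.fit_tree_model(algorithm, xp, xb, pf, bf, nperm=3,
                                  variable_names=["good", "also_good", "noise"])
        p = m.predict(np.vstack([xp, xb]))
        assert np.all((p >= 0) & (p <= 1))

    def test_noise_predictor_removed_most_seeds(self):
        removed = 0
        for seed in range(10):
            xp, xb, pf, bf = self.make_data(seed)
            m = models.fit_tree_model("RF", xp, xb, pf, bf, nperm=5, seed=seed,
                                      variable_names=["good", "also_good", "noise"])
            if "noise" not in m.variable_names:
                removed += 1
        assert removed >= 9

    def test_single_predictor_still_returned(self):
        xp, xb, pf, bf = self.make_data()
        m = models.fit_tree_model("RF", xp[:, :1], xb[:, :1], pf, bf, nperm=3,
                                  variable_names=["only"])
        assert m.variable_names == ["only"]

    def test_importance_normalized(self):
        xp, xb, pf, bf = self.make_data()
        m = models.fit_tree_model("BRT", xp, xb, pf, bf, nperm=3,
                                  variable_names=["a", "b", "c"])
        vals = np.array(list(m.importance.values()))
        assert (vals >= 0).all()
        assert vals.sum() == pytest.approx(100.0, abs=0.5)

    def test_unknown_algorithm_rejected(self):
        xp, xb, pf, bf = self.make_data()
        with pytest.raises(ValueError):
            models.fit_tree_model("XGB", xp, xb, pf, bf)


class TestPermutationImportance:
    def test_unused_variable_near_zero(self):
        r = np.random.default_rng(0)
        Xp = np.column_stack([r.beta(5, 1, 300), r.uniform(0, 1, 300)])
        Xb = r.uniform(0, 1, (600, 2))
        est = models._fit_est("RF", {"n_estimators": 150, "min_samples_leaf": 5}, Xp[:, :1], Xb[:, :1], 0)

        class OneVarModel(models.SuitabilityModel):
            variable_names = ["used", "unused"]

            def predict(self, X):
                return est.predict_proba(X[:, :1])[:, 1]

        imp = models.permutation_importance(OneVarModel(), Xp, Xb, nperm=10, seed=1)
        assert imp["unused"] == pytest.approx(0.0, abs=1e-9)

    def test_duplicate_informative_variables_split_importance(self):
        # a symmetric learner must credit near-duplicate variables equally
        # (an L1 model would concentrate on one twin, so use a forest)
        r = np.random.default_rng(3)
        sig_p = r.beta(5, 1, 400)
        sig_b = r.uniform(0, 1, 800)
        Xp = np.column_stack([sig_p, sig_p])
        Xb = np.column_stack([sig_b, sig_b])
        est = models._fit_est("RF", {"n_estimators": 300, "min_samples_leaf": 5}, Xp, Xb, 0)
        m = models.TreeModel(est, ["v1", "v2"], np.arange(2))
        imp = models.permutation_importance(m, Xp, Xb, nperm=20, seed=2)
        assert abs(imp["v1"] - imp["v2"]) < 10.0

    def test_nperm_one_reproducible(self):
        r = np.random.default_rng(0)
        Xp = r.beta(5, 1, (200, 2))
        Xb = r.uniform(0, 1, (400, 2))
        m = models.fit_maxent(Xp, Xb, feature_classes=("L",), variable_names=["a", "b"])
        i1 = models.permutation_importance(m, Xp, Xb, nperm=1, seed=42)
        i2 = models.permutation_importance(m, Xp, Xb, nperm=1, seed=42)
        assert i1 == i2


class TestBootstrapEnsemble:
    def test_uncertainty_shape_and_prediction_range(self):
        Xp, Xb = synth_pb(seed=5, n_pres=150, n_bg=300)
        m = models.fit_bootstrap_ensemble(Xp, Xb, n_members=5, seed=1)
        p = m.predict(Xb)
        u = m.uncertainty(Xb)
        assert p.shape == u.shape == (len(Xb),)
        assert np.all((p >= 0) & (p <= 1))
        assert np.all(u >= 0)

    def test_deterministic(self):
        Xp, Xb = synth_pb(seed=5, n_pres=100, n_bg=200)
        a = models.fit_bootstrap_ensemble(Xp, Xb, n_members=3, seed=9).predict(Xb)
        b = models.fit_bootstrap_ensemble(Xp, Xb, n_members=3, seed=9).predict(Xb)
        np.testing.assert_array_equal(a, b)


class TestSerialization:
    def test_roundtrip_with_sidecar(self, tmp_path):
        Xp, Xb = synth_pb(seed=6, n_pres=100, n_bg=200)
        m = models.fit_maxent(Xp, Xb, feature_classes=("L",), variable_names=["x"])
        m.importance = {"x": 100.0}
        path = tmp_path / "model.pkl"
        models.save_model(m, path)
        back = models.load_model(path)
        np.testing.assert_array_equal(back.predict(Xb), m.predict(Xb))
        import json

        sidecar = json.loads((tmp_path / "model.pkl.json").read_text())
        assert sidecar["algorithm"] == "maxent"
        assert sidecar["variable_names"] == ["x"]
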