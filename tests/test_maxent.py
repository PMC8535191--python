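"""Maximum-entropy core: feature expansion, fitting, prediction, importance."""

import numpy as np
import pytest

from cliffsdm import MaxentModel, predict, response_curve
from cliffsdm.maxent import (FeatureSpec, build_feature_specs, expand_features,
                             fit, percent_contribution, permutation_importance)


@pytest.fixture(scope="module")
def toy_data():
    """Two informative variables: presences favor high v0, mid v1."""
    rng = np.random.default_rng(0)
    bg = rng.uniform(0, 10, size=(2000, 2))
    eta = 1.5 * bg[:, 0] - 0.8 * (bg[:, 1] - 5.0) ** 2
    p = np.exp(eta - eta.max())
    idx = rng.choice(len(bg), size=300, p=p / p.sum())
    return bg[idx], bg


class TestFeatureExpansion:
    def test_feature_counts_by_class(self):
        bg = np.random.default_rng(1).uniform(size=(100, 3))
        assert len(build_feature_specs(["a", "b"], "LQ", bg[:, :2])) == 4
        assert len(build_feature_specs(["a", "b", "c"], "LP", bg)) == 6
        n_h = len(build_feature_specs(["a"], "H", bg[:, :1], n_hinge_knots=50))
        assert n_h <= 100  # 50 forward + 50 reverse, minus duplicate knots

    def test_constant_variable_flagged_and_degraded(self):
        bg = np.column_stack([np.full(50, 3.0), np.arange(50.0)])
        with pytest.warns(UserWarning, match="constant"):
            specs = build_feature_specs(["const", "v"], "LQH", bg * 0 + bg)
        # const keeps only its L feature (which scales to 0)
        assert [s.label for s in specs if s.variables == ("const",)] == ["L(const)"]
        feats = expand_features(bg, ["const", "v"], specs,
                                bg.min(axis=0), bg.max(axis=0))
        assert np.all(feats[:, 0] == 0.0)

    def test_hinge_knots_strictly_interior(self):
        bg = np.random.default_rng(2).uniform(size=(200, 1))
        specs = build_feature_specs(["v"], "H", bg)
        assert all(0.0 < s.knot < 1.0 for s in specs)

    def test_product_requires_two_distinct_variables(self):
        with pytest.raises(ValueError):
            FeatureSpec("P", ("a", "a"))


class TestFitting:
    def test_extreme_rm_shrinks_to_uniform(self, toy_data):
        pres, bg = toy_data
        m = fit(pres, bg, ["v0", "v1"], "LQ", rm=1e6)
        assert np.all(m.beta == 0.0)
        raw = m.raw_score(bg)
        assert raw == pytest.approx(np.full(len(bg), 1.0 / len(bg)))
        # cloglog of the uniform model is 1 - exp(-1) everywhere
        assert m.cloglog(bg) == pytest.approx(np.full(len(bg), 1 - np.exp(-1.0)))

    def test_raw_normalizes_over_background(self, toy_data):
        pres, bg = toy_data
        m = fit(pres, bg, ["v0", "v1"], "LQ", rm=1.0)
        assert m.raw_score(bg).sum() == pytest.approx(1.0, abs=1e-9)

    def test_objective_monotone_nonincreasing(self, toy_data):
        pres, bg = toy_data
        m = fit(pres, bg, ["v0", "v1"], "LQH", rm=1.0, n_hinge_knots=10)
        assert np.all(np.diff(m.objective_trace) <= 1e-12)

    def test_shrinkage_monotone_in_rm(self, toy_data):
        pres, bg = toy_data
        norms = [np.abs(fit(pres, bg, ["v0", "v1"], "LQ", rm=rm).beta).sum()
                 for rm in (0.5, 1.0, 2.0, 4.0)]
        assert all(a >= b - 1e-8 for a, b in zip(norms, norms[1:]))

    def test_separating_feature_stays_finite(self):
        rng = np.random.default_rng(3)
        bg = np.column_stack([np.repeat([0.0, 1.0], 100), rng.uniform(size=200)])
        pres = bg[bg[:, 0] == 1.0][:50]
        m = fit(pres, bg, ["flag", "noise"], "L", rm=1.0)
        assert np.all(np.isfinite(m.beta))
        assert m.beta[0] > 0

    def test_recovery_of_generating_model(self, stack, true_model, training_data):
        """Fitted eta correlates >= 0.95 with the generating eta over the region."""
        m = fit(training_data["pres"], training_data["bg"], stack.variables,
                "LQ", rm=1.0)
        r = np.corrcoef(true_model.eta(stack), m.eta(training_data["region"]))[0, 1]
        assert r >= 0.95

    def test_no_feature_variation_rejected(self):
        flat = np.full((50, 1), 2.0)
        with pytest.warns(UserWarning, match="constant"):
            with pytest.raises(ValueError, match="variation"):
                fit(flat[:10], flat, ["v"], "L")

    def test_json_round_trip(self, toy_data, tmp_path):
        pres, bg = toy_data
        m = fit(pres, bg, ["v0", "v1"], "LQH", rm=1.0, n_hinge_knots=8)
        m2 = MaxentModel.from_json(m.to_json(tmp_path / "m.json"))
        assert m2.cloglog(bg[:50]) == pytest.approx(m.cloglog(bg[:50]), abs=1e-12)


class TestPrediction:
    def test_grid_prediction_matches_cell_scores(self, stack, training_data):
        m = fit(training_data["pres"], training_data["bg"], stack.variables,
                "LQ", rm=1.0)
        g = predict(m, stack, "cloglog")
        r, c = 10, 10
        raw_vals = np.array([[stack.grids[v].values[r, c] for v in m.variables]])
        assert g.values[r, c] == pytest.approx(float(m.cloglog(raw_vals)[0]))
        vals = g.values[g.values != g.nodata]
        assert np.all((vals > 0) & (vals < 1))

    def test_missing_variable_named(self, stack, training_data):
        from cliffsdm.grids import ScenarioStack
        m = fit(training_data["pres"], training_data["bg"], stack.variables,
                "L", rm=1.0)
        partial = ScenarioStack(grids={"bio9": stack.grids["bio9"]})
        with pytest.raises(ValueError, match="dist_cliffs"):
            predict(m, partial)

    def test_response_curve_decreasing_in_distance(self, stack, training_data):
        xs, ys = response_curve("dist_cliffs", training_data["pres"],
                                training_data["bg"], stack.variables,
                                classes="LQ", rm=1.0, n_points=50)
        assert len(xs) == len(ys) == 50
        assert ys[0] > ys[-1]
        assert np.sum(np.diff(ys) > 1e-6) <= 2   # monotone up to optimizer noise

    def test_response_curve_flat_for_uninformative_variable(self):
        rng = np.random.default_rng(4)
        bg = np.column_stack([rng.uniform(0, 1, 1000), rng.uniform(0, 1, 1000)])
        pres = bg[rng.choice(1000, 200, p=np.full(1000, 1e-3))]
        xs, ys = response_curve("noise", pres, bg, ["noise", "other"],
                                classes="LQ", rm=1.0, n_points=30)
        assert ys.max() - ys.min() < 0.25


class TestImportance:
    def make_model(self, beta, sds=None):
        specs = [FeatureSpec("L", ("a",)), FeatureSpec("L", ("b",))]
        beta = np.asarray(beta, dtype=float)
        return MaxentModel(
            variables=["a", "b"], specs=specs, beta=beta,
            lambdas=np.zeros(2), vmin=np.zeros(2), vmax=np.ones(2), rm=1.0,
            log_z=0.0, entropy=1.0,
            feature_sd_bg=np.ones(2) if sds is None else np.asarray(sds),
            m_presences=10, n_background=100, iterations=1, converged=True)

    def test_zero_coefficient_variable_has_zero_importance(self):
        rng = np.random.default_rng(5)
        m = self.make_model([2.0, 0.0])
        pres = rng.uniform(0.5, 1.0, size=(40, 2))
        bg = rng.uniform(0.0, 1.0, size=(400, 2))
        imp = permutation_importance(m, pres, bg, seed=0, n_perm=5)
        assert imp["b"] == 0.0
        assert imp["a"] == pytest.approx(100.0)

    def test_dominant_variable_ranks_first(self, stack, training_data):
        m = fit(training_data["pres"], training_data["bg"], stack.variables,
                "LQ", rm=1.0)
        imp = permutation_importance(m, training_data["pres"],
                                     training_data["bg"][:1000], seed=0, n_perm=3)
        assert max(imp, key=imp.get) == "dist_cliffs"
        assert imp["dist_cliffs"] > 50.0

    def test_contribution_symmetric_for_identical_features(self):
        m = self.make_model([1.5, 1.5])
        pc = percent_contribution(m)
        assert pc["a"] == pytest.approx(50.0)
        assert pc["b"] == pytest.approx(50.0)

    def test_contribution_single_loaded_variable(self):
        pc = percent_contribution(self.make_model([0.7, 0.0]))
        assert pc["a"] == pytest.approx(100.0)
        assert sum(pc.values()) == pytest.approx(100.0)
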