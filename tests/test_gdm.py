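"""Generalized dissimilarity modeling: splines, fitting, significance, maps."""

import numpy as np
import pandas as pd
import pytest

from betascape.gdm import (
    GDMModel,
    ISplineBasis,
    beta_map,
    build_site_pairs,
    fit_gdm,
    gdm_deviance,
    ispline_eval,
    predict_dissimilarity,
    predictor_significance,
    transform_env,
)
from betascape.raster import RasterGrid


def m_spline_value(x, q1, q2, q3):
    """Order-2 M-spline on the triple (q1, q2, q3), integrating to 1."""
    if q3 == q1:
        return 0.0
    if q1 <= x < q2:
        return 2.0 * (x - q1) / ((q2 - q1) * (q3 - q1))
    if q2 <= x < q3:
        return 2.0 * (q3 - x) / ((q3 - q2) * (q3 - q1))
    return 0.0


def quadrature_ispline(knots, x):
    """Oracle: numerically integrate each M-spline from the minimum knot."""
    padded = np.concatenate([[knots[0]], knots, [knots[-1]]])
    out = np.zeros(len(knots))
    for i in range(len(knots)):
        q1, q2, q3 = padded[i], padded[i + 1], padded[i + 2]
        grid = np.linspace(knots[0], min(max(x, knots[0]), knots[-1]), 20001)
        vals = np.array([m_spline_value(t, q1, q2, q3) for t in grid])
        out[i] = np.trapezoid(vals, grid)
        if x >= knots[-1]:
            out[i] = 1.0
    return out


class TestISpline:
    def test_zero_at_min_knot(self):
        knots = np.array([0.0, 5.0, 10.0])
        assert np.allclose(ispline_eval(knots, [0.0]), 0.0)
        assert np.allclose(ispline_eval(knots, [-3.0]), 0.0)  # clamped

    def test_one_at_max_knot(self):
        knots = np.array([0.0, 5.0, 10.0])
        assert np.allclose(ispline_eval(knots, [10.0]), 1.0)
        assert np.allclose(ispline_eval(knots, [99.0]), 1.0)

    def test_agrees_with_quadrature_oracle(self):
        knots = np.array([1.0, 4.0, 9.0])
        for x in np.linspace(1.0, 9.0, 9):
            vals = ispline_eval(knots, [x])[0]
            oracle = quadrature_ispline(knots, x)
            assert np.allclose(vals, oracle, atol=1e-6)

    def test_monotone_nondecreasing(self):
        knots = np.array([0.0, 2.0, 3.0, 10.0])
        xs = np.linspace(-1, 11, 200)
        V = ispline_eval(knots, xs)
        assert (np.diff(V, axis=0) >= -1e-12).all()

    def test_constant_predictor_raises(self):
        with pytest.raises(ValueError, match="constant predictor"):
            ispline_eval(np.array([2.0, 2.0, 2.0]), [2.0])

    def test_basis_from_site_values_percentiles(self):
        sv = pd.DataFrame({"a": np.arange(101.0)})
        basis = ISplineBasis.from_site_values(sv, n_splines=3)
        assert np.allclose(basis.knots["a"], [0, 50, 100])


def toy_env(n, rng, n_vars=1):
    env = pd.DataFrame({"site": np.arange(n)})
    for k in range(n_vars):
        env[f"x{k}"] = rng.uniform(0, 10, n)
    return env


def pairs_from_eta(env, predictors, beta_by_pred, intercept, richness=None):
    """Generate noise-free d = 1 - exp(-eta) from a known spline model."""
    n = len(env)
    basis = ISplineBasis.from_site_values(env[predictors], n_splines=3)
    i_idx, j_idx = np.triu_indices(n, 1)
    eta = np.full(i_idx.size, intercept)
    for p in predictors:
        I = basis.evaluate(p, env[p].to_numpy())
        eta = eta + np.abs(I[i_idx] - I[j_idx]) @ beta_by_pred[p]
    d = 1 - np.exp(-eta)
    D = np.zeros((n, n))
    D[i_idx, j_idx] = d
    D += D.T
    rich = richness if richness is not None else np.ones(n)
    return build_site_pairs(D, env, rich, predictors=predictors), basis


class TestSitePairs:
    def test_pair_count(self):
        rng = np.random.default_rng(0)
        env = toy_env(7, rng)
        D = np.zeros((7, 7))
        pairs = build_site_pairs(D, env, np.ones(7))
        assert pairs.n_pairs == 21

    def test_equal_richness_unit_weights(self):
        env = toy_env(4, np.random.default_rng(1))
        pairs = build_site_pairs(np.zeros((4, 4)), env, np.full(4, 12))
        assert np.allclose(pairs.w, 1.0)

    def test_richness_weight_formula(self):
        env = toy_env(3, np.random.default_rng(2))
        pairs = build_site_pairs(np.zeros((3, 3)), env, np.array([10, 30, 50]))
        # pairs in i<j order: (0,1), (0,2), (1,2)
        assert np.allclose(pairs.w, [(10 + 30) / 100, (10 + 50) / 100, (30 + 50) / 100])

    def test_zero_richness_raises(self):
        env = toy_env(3, np.random.default_rng(3))
        with pytest.raises(ValueError, match="richness"):
            build_site_pairs(np.zeros((3, 3)), env, np.array([0, 1, 2]))


class TestFitGDM:
    def test_null_data_gives_null_model(self):
        rng = np.random.default_rng(4)
        n = 10
        env = toy_env(n, rng)
        env["x0"] = np.arange(n, dtype=float)  # varying predictor, constant response
        D = np.full((n, n), 0.4)
        np.fill_diagonal(D, 0)
        pairs = build_site_pairs(D, env, np.ones(n), predictors=["x0"])
        model = fit_gdm(pairs)
        assert np.allclose(model.coefficients["x0"], 0.0, atol=1e-6)
        assert model.pct_deviance_explained == pytest.approx(0.0, abs=1e-4)

    def test_generative_inversion_exact(self):
        rng = np.random.default_rng(5)
        env = toy_env(40, rng)
        beta_true = np.array([0.4, 0.9, 0.2])
        pairs, _ = pairs_from_eta(env, ["x0"], {"x0": beta_true}, intercept=0.1)
        model = fit_gdm(pairs)
        assert model.importance()["x0"] == pytest.approx(beta_true.sum(), abs=1e-3)
        assert model.intercept == pytest.approx(0.1, abs=1e-3)
        assert model.model_deviance <= 1e-6 * model.null_deviance

    def test_optimum_beats_random_search(self):
        rng = np.random.default_rng(6)
        env = toy_env(6, rng, n_vars=2)
        D = np.zeros((6, 6))
        iu = np.triu_indices(6, 1)
        D[iu] = rng.uniform(0.1, 0.9, iu[0].size)
        D += D.T
        pairs = build_site_pairs(D, env, np.ones(6), predictors=["x0", "x1"])
        model = fit_gdm(pairs)
        basis = model.basis
        from betascape.gdm import _design_matrix

        X = _design_matrix(pairs, basis)
        draws = rng.exponential(0.5, size=(10_000, X.shape[1]))
        etas = draws @ X.T
        mus = 1 - np.exp(-etas)
        devs = [gdm_deviance(pairs.d, mu, pairs.w) for mu in mus]
        assert model.model_deviance <= min(devs) + 1e-9

    def test_coefficients_nonnegative(self):
        rng = np.random.default_rng(7)
        env = toy_env(12, rng, n_vars=2)
        D = np.zeros((12, 12))
        iu = np.triu_indices(12, 1)
        D[iu] = rng.uniform(0, 1, iu[0].size)
        D += D.T
        pairs = build_site_pairs(D, env, np.ones(12), predictors=["x0", "x1"])
        model = fit_gdm(pairs)
        for c in model.coefficients.values():
            assert (c >= 0).all()
        assert model.intercept >= 0

    def test_duplicated_predictor_never_hurts_deviance(self):
        rng = np.random.default_rng(8)
        env = toy_env(15, rng)
        pairs, _ = pairs_from_eta(env, ["x0"], {"x0": np.array([0.3, 0.5, 0.1])}, 0.2)
        base = fit_gdm(pairs)
        env2 = env.copy()
        env2["x0dup"] = env2["x0"]
        D = np.zeros((15, 15))
        iu = np.triu_indices(15, 1)
        D[iu] = pairs.d
        D += D.T
        pairs2 = build_site_pairs(D, env2, np.ones(15), predictors=["x0", "x0dup"])
        dup = fit_gdm(pairs2)
        assert dup.model_deviance <= base.model_deviance + 1e-6

    def test_invariance_to_pair_order_and_predictor_names(self):
        rng = np.random.default_rng(9)
        env = toy_env(10, rng)
        pairs, _ = pairs_from_eta(env, ["x0"], {"x0": np.array([0.2, 0.4, 0.3])}, 0.15)
        m1 = fit_gdm(pairs)
        env_renamed = env.rename(columns={"x0": "zz"})
        D = np.zeros((10, 10))
        iu = np.triu_indices(10, 1)
        D[iu] = pairs.d
        D += D.T
        m2 = fit_gdm(build_site_pairs(D, env_renamed, np.ones(10), predictors=["zz"]))
        assert m1.pct_deviance_explained == pytest.approx(m2.pct_deviance_explained, abs=1e-9)

    def test_d_outside_unit_interval_rejected(self):
        env = toy_env(3, np.random.default_rng(10))
        D = np.full((3, 3), 1.5)
        np.fill_diagonal(D, 0)
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            build_site_pairs(D, env, np.ones(3))


class TestPredict:
    def test_identity_pair_gives_intercept_mu(self):
        rng = np.random.default_rng(11)
        env = toy_env(10, rng)
        pairs, _ = pairs_from_eta(env, ["x0"], {"x0": np.array([0.3, 0.2, 0.4])}, 0.25)
        model = fit_gdm(pairs)
        # pair of identical sites: duplicate site 0
        env2 = pd.concat([env.iloc[[0]], env.iloc[[0]]]).reset_index(drop=True)
        env2["site"] = [0, 1]
        p2 = build_site_pairs(np.zeros((2, 2)), env2, np.ones(2), predictors=["x0"])
        mu = predict_dissimilarity(model, p2)
        assert mu[0] == pytest.approx(1 - np.exp(-model.intercept), abs=1e-12)

    def test_monotone_in_predictor_difference(self):
        rng = np.random.default_rng(12)
        env = toy_env(30, rng)
        pairs, _ = pairs_from_eta(env, ["x0"], {"x0": np.array([0.5, 0.5, 0.5])}, 0.1)
        model = fit_gdm(pairs)
        base = env["x0"].iloc[0]
        mus = []
        for delta in np.linspace(0, 5, 8):
            env2 = pd.DataFrame({"site": [0, 1], "x0": [base, base + delta]})
            p2 = build_site_pairs(np.zeros((2, 2)), env2, np.ones(2), predictors=["x0"])
            mus.append(predict_dissimilarity(model, p2)[0])
        assert (np.diff(mus) >= -1e-12).all()

    def test_unseen_predictor_raises(self):
        rng = np.random.default_rng(13)
        env = toy_env(10, rng)
        pairs, _ = pairs_from_eta(env, ["x0"], {"x0": np.array([0.1, 0.1, 0.1])}, 0.1)
        model = fit_gdm(pairs)
        env2 = toy_env(4, rng)
        env2["other"] = 1.0
        p2 = build_site_pairs(np.zeros((4, 4)), env2, np.ones(4), predictors=["other"])
        with pytest.raises(KeyError, match="other"):
            predict_dissimilarity(model, p2)

    def test_hand_evaluated_link(self):
        env = pd.DataFrame({"site": [0, 1], "x0": [0.0, 10.0]})
        basis = ISplineBasis(knots={"x0": np.array([0.0, 5.0, 10.0])}, n_splines=3)
        model = GDMModel(
            basis=basis,
            intercept=0.2,
            coefficients={"x0": np.array([0.3, 0.4, 0.5])},
            null_deviance=1.0,
            model_deviance=0.5,
            converged=True,
            n_iter=1,
            predictor_names=["x0"],
        )
        p = build_site_pairs(np.zeros((2, 2)), env, np.ones(2), predictors=["x0"])
        # splines span 0 -> 1 across the full range, so |delta I| = (1,1,1)
        assert predict_dissimilarity(model, p)[0] == pytest.approx(
            1 - np.exp(-(0.2 + 1.2)), abs=1e-12
        )


class TestSignificance:
    def test_zero_coefficient_importance_is_zero(self):
        rng = np.random.default_rng(14)
        env = toy_env(12, rng, n_vars=2)
        env["x1"] = rng.uniform(0, 10, 12)  # pure noise
        pairs, _ = pairs_from_eta(env, ["x0"], {"x0": np.array([0.6, 0.6, 0.6])}, 0.1)
        D = np.zeros((12, 12))
        iu = np.triu_indices(12, 1)
        D[iu] = pairs.d
        D += D.T
        both = build_site_pairs(D, env, np.ones(12), predictors=["x0", "x1"])
        model = fit_gdm(both)
        imp = model.importance()
        if np.allclose(model.coefficients["x1"], 0):
            assert imp["x1"] == pytest.approx(0.0, abs=1e-9)

    def test_driver_kept_noise_not(self):
        rng = np.random.default_rng(15)
        env = toy_env(25, rng)
        env["noise"] = rng.uniform(0, 10, 25)
        pairs, _ = pairs_from_eta(env, ["x0"], {"x0": np.array([0.8, 0.8, 0.8])}, 0.1)
        D = np.zeros((25, 25))
        iu = np.triu_indices(25, 1)
        D[iu] = np.clip(pairs.d + rng.normal(0, 0.02, pairs.d.size), 0, 1)
        D += D.T
        both = build_site_pairs(D, env, np.ones(25), predictors=["x0", "noise"])
        summary = predictor_significance(both, n_perm=49, seed=1)
        table = summary.table.set_index("predictor")
        assert bool(table.loc["x0", "keep"])
        assert table.loc["x0", "importance"] > table.loc["noise", "importance"]

    def test_invalid_n_perm(self):
        rng = np.random.default_rng(16)
        env = toy_env(6, rng)
        pairs, _ = pairs_from_eta(env, ["x0"], {"x0": np.array([0.1, 0.1, 0.1])}, 0.1)
        with pytest.raises(ValueError, match="n_perm"):
            predictor_significance(pairs, n_perm=0)


class TestTransformAndMap:
    def make_model(self, knots=(0.0, 50.0, 100.0), coefs=(0.2, 0.3, 0.5), name="x0"):
        return GDMModel(
            basis=ISplineBasis(knots={name: np.array(knots)}, n_splines=3),
            intercept=0.1,
            coefficients={name: np.array(coefs)},
            null_deviance=1.0,
            model_deviance=0.5,
            converged=True,
            n_iter=1,
            predictor_names=[name],
        )

    def grid(self, vals):
        vals = np.asarray(vals, dtype=float)
        return RasterGrid(vals, (1.0, 0, 0.0, 0, -1.0, float(vals.shape[0])))

    def test_constant_raster_constant_transform(self):
        model = self.make_model()
        out = transform_env(model, {"x0": self.grid(np.full((4, 4), 50.0))})
        from betascape.gdm import ispline_eval

        expected = ispline_eval(np.array([0.0, 50.0, 100.0]), [50.0])[0] @ np.array(
            [0.2, 0.3, 0.5]
        )
        assert np.allclose(out["x0"].values, expected)

    def test_transform_bounded_by_importance(self):
        model = self.make_model()
        rng = np.random.default_rng(17)
        out = transform_env(model, {"x0": self.grid(rng.uniform(-10, 120, (5, 5)))})
        assert (out["x0"].values >= -1e-12).all()
        assert (out["x0"].values <= 1.0 + 1e-12).all()  # sum of coefs = 1.0

    def test_pixelwise_match_to_direct_evaluation(self):
        model = self.make_model()
        vals = np.linspace(0, 100, 16).reshape(4, 4)
        out = transform_env(model, {"x0": self.grid(vals)})
        direct = (
            ispline_eval(np.array([0.0, 50.0, 100.0]), vals.ravel())
            @ np.array([0.2, 0.3, 0.5])
        ).reshape(4, 4)
        assert np.allclose(out["x0"].values, direct)

    def test_missing_raster_for_kept_predictor_raises(self):
        model = self.make_model()
        with pytest.raises(KeyError, match="x0"):
            transform_env(model, {"unrelated": self.grid(np.zeros((4, 4)))})

    def test_beta_map_channels_span_full_range(self):
        rng = np.random.default_rng(18)
        layers = {f"l{k}": self.grid(rng.uniform(0, 1, (8, 8))) for k in range(3)}
        rgb, valid, _ = beta_map(layers)
        for k in range(3):
            chan = rgb[valid, k]
            assert chan.min() == 0 and chan.max() == 255

    def test_beta_map_deterministic_and_identity_on_equal_pixels(self):
        grad = np.tile(np.linspace(0, 1, 8), (8, 1))
        layers = {"a": self.grid(grad), "b": self.grid(grad), "c": self.grid(grad * 2)}
        rgb1, valid, _ = beta_map(layers)
        rgb2, _, _ = beta_map(layers)
        assert np.array_equal(rgb1, rgb2)
        # identical input pixels (same column) -> identical colors
        assert np.array_equal(rgb1[0], rgb1[5])
        # hue varies only along the gradient: columns differ, rows do not
        assert not np.array_equal(rgb1[:, 0], rgb1[:, 7])

    def test_fewer_than_three_layers_padded_with_warning(self):
        rng = np.random.default_rng(19)
        layers = {"a": self.grid(rng.uniform(0, 1, (6, 6)))}
        with pytest.warns(UserWarning, match="padding"):
            rgb, valid, _ = beta_map(layers)
        assert rgb.shape == (6, 6, 3)

    def test_model_text_round_trip(self):
        model = self.make_model()
        back = GDMModel.from_text(model.to_text())
        assert back.intercept == model.intercept
        assert np.allclose(back.coefficients["x0"], model.coefficients["x0"])
        assert np.allclose(back.basis.knots["x0"], model.basis.knots["x0"])
        assert back.null_deviance == model.null_deviance
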