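import numpy as np
import pytest
from scipy.special import expit

from ecostab.raster import RasterGrid
from ecostab.sampling import FactorSpec
from ecostab.stability import (
    SeparationError,
    factor_contributions,
    fit_logistic,
    predict_esi,
)

from conftest import make_grid, make_stack


def simulate(beta0, beta, n, seed):
    rng = np.random.default_rng(seed)
    z = rng.random((n, len(beta)))
    p = expit(beta0 + z @ np.asarray(beta))
    y = (rng.random(n) < p).astype(int)
    return z, y


class TestFitLogistic:
    def test_intercept_only_matches_closed_form(self):
        # MLE of the intercept-only model is the empirical log-odds ln(3)
        model = fit_logistic(np.empty((4, 0)), [1, 1, 1, 0])
        assert model.beta0 == pytest.approx(np.log(3.0), abs=1e-8)
        assert model.converged

    def test_matches_statsmodels_mle(self):
        """Independent cross-check of coefficients, SEs and log-likelihood."""
        sm = pytest.importorskip("statsmodels.api")
        z, y = simulate(0.5, [1.0, -2.0, 0.0], n=2000, seed=1)
        model = fit_logistic(z, y)
        ref = sm.Logit(y, sm.add_constant(z)).fit(disp=0)
        np.testing.assert_allclose(model.coefficients, ref.params, rtol=1e-6)
        np.testing.assert_allclose(model.se, ref.bse, rtol=1e-4)
        assert model.loglik == pytest.approx(ref.llf, rel=1e-8)

    def test_loglik_nondecreasing_over_iterations(self):
        z, y = simulate(-0.5, [2.0, 1.0], n=500, seed=2)
        model = fit_logistic(z, y)
        trace = np.array(model.loglik_trace)
        assert (np.diff(trace) >= -1e-10).all()

    def test_uninformative_factor_stays_within_wald_band(self):
        # the second factor does not enter the truth: |beta| < 3 se
        z, y = simulate(0.3, [1.5, 0.0], n=5000, seed=3)
        model = fit_logistic(z, y)
        assert abs(model.beta[1]) < 3 * model.se[2]

    def test_separation_raises_naming_factor(self):
        z = np.linspace(0, 1, 40).reshape(-1, 1)
        y = (z.ravel() > 0.5).astype(int)
        specs = [FactorSpec("X7", "aspect", "X7", 0, 1)]
        with pytest.raises(SeparationError, match="X7"):
            fit_logistic(z, y, factor_specs=specs)

    def test_collinear_design_raises(self):
        rng = np.random.default_rng(4)
        a = rng.random(100)
        z = np.column_stack([a, 2 * a])
        y = (rng.random(100) < expit(a)).astype(int)
        with pytest.raises(np.linalg.LinAlgError, match="singular"):
            fit_logistic(z, y)

    def test_single_label_rejected(self):
        with pytest.raises(ValueError, match="both labels"):
            fit_logistic(np.empty((5, 0)), [1, 1, 1, 1, 1])

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="samples"):
            fit_logistic(np.random.default_rng(0).random((3, 2)), [0, 1, 0])

    def test_serialization_roundtrip(self, tmp_path):
        from ecostab.stability import StabilityModel

        z, y = simulate(0.2, [1.0], n=200, seed=5)
        model = fit_logistic(z, y, landscape_id=3,
                             factor_specs=[FactorSpec("X1", "gdp", "X1", 0, 1)])
        p = tmp_path / "model.json"
        model.save(p)
        back = StabilityModel.load(p)
        assert back.landscape_id == 3
        np.testing.assert_allclose(back.coefficients, model.coefficients)
        assert back.factor_specs == model.factor_specs


def model_with(beta0, beta, specs=None):
    from ecostab.stability import StabilityModel

    beta = np.asarray(beta, dtype=float)
    specs = specs or [FactorSpec(f"X{i+1}", f"x{i+1}", f"X{i+1}", 0.0, 1.0) for i in range(len(beta))]
    return StabilityModel(
        landscape_id=1, beta0=beta0, beta=beta, se=np.ones(len(beta) + 1),
        loglik=0.0, converged=True, n_samples=10, n_iter=1, factor_specs=specs,
    )


class TestPredictESI:
    def _mask(self, shape):
        return make_grid(np.ones(shape, dtype=np.uint8))

    def test_zero_coefficients_give_half(self):
        model = model_with(0.0, [0.0, 0.0])
        factors = make_stack([np.random.default_rng(0).random((3, 3))] * 2, ["X1", "X2"])
        esi = predict_esi(model, factors, self._mask((3, 3)))
        np.testing.assert_allclose(esi.values.values, 0.5)

    def test_unit_factor_value(self):
        # beta0=0, beta1=1, Z1=1 -> 1/(1+e^-1)
        model = model_with(0.0, [1.0])
        factors = make_stack([np.ones((2, 2))], ["X1"])
        esi = predict_esi(model, factors, self._mask((2, 2)))
        np.testing.assert_allclose(esi.values.values, 0.7310585786300049, rtol=1e-12)

    def test_extreme_linear_predictor_saturates_without_overflow(self):
        model = model_with(-1000.0, [0.0])
        factors = make_stack([np.ones((2, 2))], ["X1"])
        esi = predict_esi(model, factors, self._mask((2, 2)))
        v = esi.values.values
        assert np.isfinite(v).all()
        assert (v > 0).all() and (v < 1e-200).all()
        model = model_with(1000.0, [0.0])
        v = predict_esi(model, factors, self._mask((2, 2))).values.values
        assert (v < 1).all()

    def test_matches_scalar_evaluation_everywhere(self):
        """Oracle equivalence: map evaluation equals per-pixel scalar Eq."""
        import math

        rng = np.random.default_rng(6)
        beta0, beta = 0.4, [1.2, -2.0, 0.7]
        specs = [FactorSpec(f"X{i+1}", "f", f"X{i+1}", 2.0, 8.0) for i in range(3)]
        model = model_with(beta0, beta, specs)
        raw = [rng.uniform(2, 8, (4, 5)) for _ in range(3)]
        factors = make_stack(raw, ["X1", "X2", "X3"])
        esi = predict_esi(model, factors, self._mask((4, 5))).values.values
        for r in range(4):
            for c in range(5):
                eta = beta0 + sum(
                    b * (raw[i][r, c] - 2.0) / 6.0 for i, b in enumerate(beta)
                )
                expect = math.exp(eta) / (1 + math.exp(eta))
                assert abs(esi[r, c] - expect) <= 1e-12 * expect

    def test_respects_landscape_mask(self):
        model = model_with(0.0, [0.0])
        factors = make_stack([np.ones((2, 2))], ["X1"])
        mask_vals = np.array([[1, 0], [0, 1]], dtype=np.uint8)
        esi = predict_esi(model, factors, make_grid(mask_vals)).values.values
        assert np.isnan(esi[0, 1]) and np.isnan(esi[1, 0])
        assert esi[0, 0] == 0.5

    def test_missing_factor_layer_errors(self):
        model = model_with(0.0, [1.0])
        factors = make_stack([np.ones((2, 2))], ["X9"])
        with pytest.raises(KeyError, match="X1"):
            predict_esi(model, factors, self._mask((2, 2)))


class TestFactorContributions:
    def test_sorted_by_magnitude(self):
        model = model_with(0.0, [2.0, -0.5])
        df = factor_contributions(model)
        assert list(df["factor"]) == ["X1", "X2"]
        assert list(df["coefficient"]) == [2.0, -0.5]
        assert list(df["sign"]) == [1, -1]

    def test_zero_ties_break_by_factor_code(self):
        model = model_with(0.0, [0.0, 0.0, 0.0])
        df = factor_contributions(model)
        assert list(df["factor"]) == ["X1", "X2", "X3"]

    def test_planted_sign_recovered(self):
        # temperature planted positive: recovered contribution sign positive
        z, y = simulate(0.0, [1.8], n=4000, seed=7)
        specs = [FactorSpec("X4", "temperature", "X4", 0, 1)]
        model = fit_logistic(z, y, factor_specs=specs)
        df = factor_contributions(model)
        assert df.loc[0, "factor"] == "X4"
        assert df.loc[0, "sign"] == 1

    def test_unconverged_model_rejected(self):
        model = model_with(0.0, [1.0])
        model.converged = False
        with pytest.raises(ValueError, match="converged"):
            factor_contributions(model)

    def test_odds_ratio_view(self):
        model = model_with(0.0, [1.0, -1.0])
        df = factor_contributions(model, metric="odds_ratio")
        np.testing.assert_allclose(sorted(df["odds_ratio"]), [np.exp(-1), np.e])
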