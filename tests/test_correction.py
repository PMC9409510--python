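import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

from radibias.correction import (
    NoiseBiasCorrector,
    build_observations,
    correct_study,
    fit_model,
    model_zoo,
    select_model,
    transfer_correct,
)
from radibias.features.extract import estimate_noise
from radibias.volumetrics import ImageVolume, VOIMask


class TestNoiseEstimate:
    def _vol(self, grid):
        return ImageVolume(grid=np.asarray(grid, float), spacing=(1, 1, 1))

    def test_identical_frames_give_zero_sd(self):
        a = self._vol(np.ones((2, 1, 1)))
        mask = VOIMask(np.ones((2, 1, 1), bool), (1, 1, 1))
        sd, cov = estimate_noise(a, a, mask)
        assert sd == 0.0 and cov == 0.0

    def test_hand_arithmetic(self):
        a = self._vol([[[1.0]], [[3.0]]])
        b = self._vol([[[2.0]], [[2.0]]])
        mask = VOIMask(np.ones((2, 1, 1), bool), (1, 1, 1))
        sd, cov = estimate_noise(a, b, mask)
        assert sd == pytest.approx(np.sqrt(2))
        assert cov == pytest.approx(np.sqrt(2) / 2.0)

    def test_scaling_homogeneity(self, rng):
        a = self._vol(rng.uniform(1, 2, (4, 4, 4)))
        b = self._vol(rng.uniform(1, 2, (4, 4, 4)))
        mask = VOIMask(np.ones((4, 4, 4), bool), (1, 1, 1))
        sd1, cov1 = estimate_noise(a, b, mask)
        c = 3.7
        a2 = self._vol(c * a.grid)
        b2 = self._vol(c * b.grid)
        sd2, cov2 = estimate_noise(a2, b2, mask)
        assert sd2 == pytest.approx(c * sd1)
        assert cov2 == pytest.approx(cov1)


class TestModelZoo:
    def test_zoo_has_fifteen_forms(self):
        zoo = model_zoo()
        assert len(zoo) == 15
        assert len({m.name for m in zoo}) == 15

    def test_every_model_finite_at_zero(self):
        x = np.array([0.0, 0.5, 1.0])
        for m in model_zoo():
            p0 = np.asarray(m.init(x, np.array([1.0, 0.8, 0.5])), float)
            p0[~np.isfinite(p0)] = 1.0
            if m.bounds is not None:
                lb, ub = m.bounds(x, np.array([1.0, 0.8, 0.5]))
                p0 = np.clip(p0, np.asarray(lb) + 1e-6, np.asarray(ub) - 1e-6)
            with np.errstate(all="ignore"):
                y = m.func(x, *p0)
            assert np.all(np.isfinite(y)), m.name

    def test_power2_with_unit_exponent_is_linear_slope(self):
        zoo = {m.name: m for m in model_zoo()}
        x = np.linspace(0, 3, 7)
        np.testing.assert_allclose(
            zoo["power_2"].func(x, 2.5, 1.0), zoo["linear_slope"].func(x, 2.5)
        )

    def test_alt_double_exp2_parameterisation_differs(self):
        std = {m.name: m for m in model_zoo(False)}["double_exponential_2"]
        alt = {m.name: m for m in model_zoo(True)}["double_exponential_2"]
        x = np.array([0.5, 1.0])
        assert not np.allclose(std.func(x, 2.0, 0.5), alt.func(x, 2.0, 0.5))


class TestLinearFits:
    def test_exact_slope_only(self):
        x = np.linspace(0.1, 2, 10)
        zoo = {m.name: m for m in model_zoo()}
        fit = fit_model(x, 2.0 * x, np.ones(10), zoo["linear_slope"])
        assert fit.params[0] == pytest.approx(2.0, abs=1e-12)
        assert fit.wrss == pytest.approx(0.0, abs=1e-20)

    def test_exact_intercept_only(self):
        x = np.linspace(0.1, 2, 10)
        zoo = {m.name: m for m in model_zoo()}
        fit = fit_model(x, x + 0.3, np.ones(10), zoo["linear_intercept"])
        assert fit.params[0] == pytest.approx(0.3, abs=1e-12)

    def test_weighted_fit_matches_normal_equations(self, rng):
        # implementation (statsmodels WLS) vs closed-form normal equations
        x = rng.uniform(0, 3, 25)
        y = 1.7 * x - 0.4 + rng.normal(0, 0.2, 25)
        w = rng.uniform(0.5, 2.0, 25)
        zoo = {m.name: m for m in model_zoo()}
        fit = fit_model(x, y, w, zoo["linear"])
        A = np.column_stack([x, np.ones_like(x)])
        coef = np.linalg.solve(A.T @ (w[:, None] * A), A.T @ (w * y))
        np.testing.assert_allclose(fit.params, coef, atol=1e-10)


class TestNonlinearFits:
    @pytest.mark.parametrize(
        "name,params",
        [
            ("exponential_1", (2.0, 1.5)),
            ("reciprocal", (0.5, 0.2)),
            ("logistic", (2.0, 1.5, 2.0)),
            ("power_2", (1.2, 0.7)),
            ("rational_1", (3.0, 0.8)),
        ],
    )
    def test_parameter_recovery_at_one_percent_noise(self, name, params):
        # 9 tumors x 4 durations = 36 design points
        zoo = {m.name: m for m in model_zoo()}
        model = zoo[name]
        rng = np.random.default_rng(hash(name) % 2**31)
        x = np.sort(rng.uniform(0.05, 3.0, 36))
        y_clean = model.func(x, *params)
        y = y_clean + rng.normal(0, 0.01 * np.abs(y_clean).mean(), 36)
        fit = fit_model(x, y, np.ones(36), model, seed=1)
        assert fit.converged
        np.testing.assert_allclose(fit.params, params, rtol=0.1)

    def test_aic_selection_invariant_to_zoo_order(self, rng):
        x = np.linspace(0.1, 3, 36)
        y = 1.0 / (0.5 + 0.2 * x) + rng.normal(0, 0.01, 36)
        w = np.ones(36)
        fits = [fit_model(x, y, w, m, seed=2) for m in model_zoo()]
        best_fwd = select_model(fits).model_name
        best_rev = select_model(fits[::-1]).model_name
        assert best_fwd == best_rev


class TestEstimatorInterface:
    def test_sklearn_contract(self):
        est = NoiseBiasCorrector(mode="multiplicative", random_state=3)
        cloned = clone(est)
        assert cloned.get_params()["mode"] == "multiplicative"
        est.set_params(mode="additive")
        assert est.mode == "additive"

    def test_fit_predict_roundtrip(self, rng):
        x = np.linspace(0.1, 2, 20)
        y = 0.8 * x
        est = NoiseBiasCorrector(models=("linear_slope", "linear")).fit(x[:, None], y)
        assert est.best_model_ == "linear_slope"  # fewer parameters at equal fit
        np.testing.assert_allclose(est.predict(x[:, None]), y, atol=1e-10)

    def test_zero_bias_fit_leaves_values_unchanged(self):
        x = np.linspace(0.1, 2, 12)
        est = NoiseBiasCorrector(models=("linear_slope",)).fit(x, np.zeros(12))
        rf = np.array([1.0, 2.0, 3.0])
        np.testing.assert_allclose(est.correct(rf, np.array([0.5, 1.0, 1.5])), rf, atol=1e-12)


def _closed_loop_tables(slope=0.8, n_tumors=9, n_reps=5):
    """Feature and noise tables with bias injected exactly as rf_diff = slope*sd_diff."""
    rng = np.random.default_rng(11)
    durations = (5.0, 10.0, 30.0, 120.0)
    refs = 1.0 + 0.7 * np.arange(n_tumors)
    feat_rows, noise_rows = [], []
    for t, ref in enumerate(refs):
        feat_rows.append(
            dict(tumor_label=f"t{t}", duration_s=2400.0, replicate="reference",
                 feature_id="f", value=ref)
        )
        for d in durations:
            sd_diff = (1.0 + 0.05 * t) / np.sqrt(d)
            noise_rows.append(
                dict(tumor_label=f"t{t}", duration_s=d, protocol="EARL1",
                     sd_diff=sd_diff, cov_diff=sd_diff / ref)
            )
            for r in range(1, n_reps + 1):
                feat_rows.append(
                    dict(tumor_label=f"t{t}", duration_s=d, replicate=str(r),
                         feature_id="f", value=ref - slope * sd_diff)
                )
    return pd.DataFrame(feat_rows), pd.DataFrame(noise_rows)


class TestClosedLoopCorrection:
    def test_exact_linear_bias_recovered(self):
        feats, noise = _closed_loop_tables()
        fits, before_after, correctors = correct_study(feats, noise, ["f"])
        add = before_after[before_after["mode"] == "additive"]
        assert np.allclose(add["sdm_after"], 1.0, atol=1e-9)
        assert (add["sdm_after"] >= add["sdm_before"] - 1e-12).all()

    def test_observations_bookkeeping(self):
        feats, noise = _closed_loop_tables()
        obs = build_observations(feats, noise, "f")
        assert len(obs) == 36
        np.testing.assert_allclose(obs["rf_diff"], 0.8 * obs["sd_diff"], atol=1e-12)

    def test_transfer_to_identical_protocol_matches_native(self):
        feats, noise = _closed_loop_tables()
        _, before_after, correctors = correct_study(feats, noise, ["f"])
        transfer = transfer_correct(correctors, feats, noise, ["f"])
        add = transfer[transfer["mode"] == "additive"]
        native = before_after[before_after["mode"] == "additive"]
        np.testing.assert_allclose(
            add.sort_values("duration_s")["sdm_after_transfer"].to_numpy(),
            native.sort_values("duration_s")["sdm_after"].to_numpy(),
            atol=1e-12,
        )
        assert add["pct_increase"].iloc[0] == pytest.approx(
            100.0
            * (add["sdm_after_transfer"].iloc[0] - add["sdm_before"].iloc[0])
            / add["sdm_before"].iloc[0]
        )


def test_aic_prefers_the_generating_model():
    """Reciprocal-generated data: AIC selects reciprocal as the modal winner.

    The richer nested forms (rational_2 reproduces the reciprocal exactly with
    one spare parameter; the sum of two exponentials has two) legitimately
    out-score it in the chi-square exceedance fraction of seeds (~16% and ~13%
    respectively), so the expected recovery rate sits near 70-75%, not at 100%.
    """
    from collections import Counter

    zoo = model_zoo()
    x = np.linspace(0.1, 3.0, 36)
    winners = Counter()
    for seed in range(50):
        rng = np.random.default_rng(seed)
        y = 1.0 / (0.5 + 0.2 * x) + rng.normal(0, 0.01, 36)
        fits = [fit_model(x, y, np.ones(36), m, seed=seed) for m in zoo]
        winners[select_model(fits).model_name] += 1
    assert winners.most_common(1)[0][0] == "reciprocal"
    assert winners["reciprocal"] >= 30  # 60%, margin below the measured 73%
    assert set(winners) <= {"reciprocal", "rational_2", "sum_two_exponentials"}
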