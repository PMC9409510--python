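"""Noise-bias regression: model zoo, AIC selection, feature correction, transfer.

The local noise level of a replicate pair is estimated from their difference
image (SD_diff: SD of difference voxels in the VOI; COV_diff: SD_diff divided
by the VOI mean of the replicate average). Feature bias is then regressed on
noise in one of two modes:

* additive: RF_diff = RF_long - RF_short  against  SD_diff;
* multiplicative: RF_ratio = RF_long / RF_short  against  COV_diff;

using the replicate variability of the feature as weights. Fifteen candidate
regression forms (linear, exponential, sigmoid, power-law, rational) are
fitted per feature and mode; the lowest-AIC converged fit predicts the ideal
feature value, and the SDM is recomputed to verify that the bias was reduced.

:class:`NoiseBiasCorrector` is a scikit-learn compatible estimator (it
supports ``get_params``/``set_params``, ``clone`` and sklearn model
selection); the module-level helpers are thin wrappers around it.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator, RegressorMixin

from .features.extract import estimate_noise
from .robustness import categorize, compute_sdm

__all__ = [
    "ModelForm",
    "RegressionFit",
    "model_zoo",
    "fit_model",
    "select_model",
    "NoiseBiasCorrector",
    "estimate_noise",
    "build_observations",
    "correct_study",
    "transfer_correct",
]

_EXP_CLIP = 700.0


def _safe_exp(z):
    return np.exp(np.clip(z, -_EXP_CLIP, _EXP_CLIP))


@dataclass(frozen=True)
class ModelForm:
    name: str
    n_params: int
    func: Callable
    init: Callable  # (x, y) -> p0
    bounds: Callable | None = None  # (x, y) -> (lb, ub)
    linear: bool = False


@dataclass
class RegressionFit:
    model_name: str
    params: tuple[float, ...]
    mode: str
    aic: float
    n_points: int
    converged: bool
    wrss: float = float("nan")


def _loglin_rate(x, y):
    """Rate guess from log-linearised endpoints; falls back to 1/span."""
    span = max(x.max() - x.min(), 1e-12)
    y0, y1 = y[np.argmin(x)], y[np.argmax(x)]
    if y0 * y1 > 0 and abs(y0) > 0:
        r = abs(np.log(abs(y1 / y0))) / span
        if np.isfinite(r) and r > 0:
            return min(r, 1e3)
    return 1.0 / span


def model_zoo(alt_double_exp2: bool = False) -> list[ModelForm]:
    """The fifteen candidate regression forms.

    ``alt_double_exp2`` switches the second double-exponential from the
    exp((a/b)(1 - e^{bx})) parameterisation to exp(a*b*(1 - e^{bx})).
    """

    def inf_bounds(n):
        return lambda x, y: ([-np.inf] * n, [np.inf] * n)

    def f_dexp2(x, a, b):
        b = np.where(np.abs(b) < 1e-9, 1e-9, b)
        scale = a * b if alt_double_exp2 else a / b
        return _safe_exp(scale * (1.0 - _safe_exp(b * x)))

    zoo = [
        ModelForm("linear_slope", 1, lambda x, a: a * x,
                  lambda x, y: (1.0,), linear=True),
        ModelForm("linear_intercept", 1, lambda x, b: x + b,
                  lambda x, y: (0.0,), linear=True),
        ModelForm("linear", 2, lambda x, a, b: a * x + b,
                  lambda x, y: (1.0, 0.0), linear=True),
        ModelForm("exponential_1", 2, lambda x, a, b: a * _safe_exp(-b * x),
                  lambda x, y: (y[np.argmin(x)] or np.max(np.abs(y)) or 1.0,
                                _loglin_rate(x, y))),
        ModelForm("exponential_2", 2, lambda x, a, b: _safe_exp(a * (x - b)),
                  lambda x, y: (_loglin_rate(x, y), float(np.median(x)))),
        ModelForm(
            "sum_two_exponentials", 4,
            lambda x, a, b, c, d: a * _safe_exp(-b * x) + c * _safe_exp(-d * x),
            lambda x, y: (0.5 * (y[np.argmin(x)] or 1.0), _loglin_rate(x, y),
                          0.5 * (y[np.argmin(x)] or 1.0), 2.0 * _loglin_rate(x, y)),
        ),
        ModelForm(
            "reciprocal", 2, lambda x, a, b: 1.0 / (a + b * x), _recip_init
        ),
        ModelForm(
            "double_exponential_1", 3,
            lambda x, a, b, c: a * _safe_exp(-_safe_exp(-b * (x - c))),
            lambda x, y: (y[np.argmax(x)] or np.max(np.abs(y)) or 1.0,
                          _loglin_rate(x, y), float(np.median(x))),
        ),
        ModelForm(
            "double_exponential_2", 2, f_dexp2,
            lambda x, y: (_loglin_rate(x, y), _loglin_rate(x, y)),
        ),
        ModelForm(
            "logistic", 3,
            lambda x, a, b, c: a / (1.0 + b * _safe_exp(-c * x)),
            lambda x, y: (y[np.argmax(x)] or 1.0, 1.0, _loglin_rate(x, y)),
            bounds=lambda x, y: ([-np.inf, 1e-9, -np.inf], [np.inf, np.inf, np.inf]),
        ),
        ModelForm(
            "generalized_logistic", 4,
            lambda x, a, b, c, d: a
            * np.power(
                np.maximum(1.0 + (b - 1.0) * _safe_exp(-c * (x - d)), 1e-12),
                1.0 / (1.0 - b),
            ),
            lambda x, y: (y[np.argmax(x)] or 1.0, 2.0, _loglin_rate(x, y),
                          float(np.median(x))),
            bounds=lambda x, y: ([-np.inf, 1.0 + 1e-6, -np.inf, -np.inf],
                                 [np.inf, 100.0, np.inf, np.inf]),
        ),
        ModelForm(
            "power_1", 2,
            lambda x, a, b: a * (1.0 - np.power(np.maximum(b, 1e-12), x)),
            lambda x, y: (y[np.argmax(x)] or 1.0, 0.5),
            bounds=lambda x, y: ([-np.inf, 1e-9], [np.inf, 20.0]),
        ),
        ModelForm(
            "power_2", 2,
            lambda x, a, b: a * np.power(np.maximum(x, 0.0), b),
            _power_init,
            bounds=lambda x, y: ([-np.inf, 0.0], [np.inf, 20.0]),
        ),
        ModelForm(
            "rational_1", 2,
            lambda x, a, b: a * x / (b + x),
            lambda x, y: (y[np.argmax(x)] or 1.0, float(np.median(x)) or 1.0),
            bounds=lambda x, y: ([-np.inf, 1e-9], [np.inf, np.inf]),
        ),
        ModelForm(
            "rational_2", 3,
            lambda x, a, b, c: (a + b * x) / (1.0 + c * x),
            lambda x, y: (y[np.argmin(x)], _slope_init(x, y), 0.1),
            bounds=lambda x, y: ([-np.inf, -np.inf, 0.0], [np.inf, np.inf, np.inf]),
        ),
    ]
    return zoo


def _slope_init(x, y) -> float:
    span = max(x.max() - x.min(), 1e-12)
    return float((y[np.argmax(x)] - y[np.argmin(x)]) / span)


def _recip_init(x, y):
    ok = np.abs(y) > 1e-12
    if ok.sum() >= 2:
        A = np.column_stack([np.ones(ok.sum()), x[ok]])
        coef, *_ = np.linalg.lstsq(A, 1.0 / y[ok], rcond=None)
        if np.all(np.isfinite(coef)) and abs(coef[0]) > 1e-12:
            return tuple(coef)
    return (1.0, 0.1)


def _power_init(x, y):
    ok = (x > 0) & (y > 0)
    if ok.sum() >= 2:
        A = np.column_stack([np.ones(ok.sum()), np.log(x[ok])])
        coef, *_ = np.linalg.lstsq(A, np.log(y[ok]), rcond=None)
        if np.all(np.isfinite(coef)):
            return (
                float(np.exp(np.clip(coef[0], -300.0, 300.0))),
                float(np.clip(coef[1], 0.0, 20.0)),
            )
    return (1.0, 1.0)


def _wrss(model: ModelForm, params, x, y, w) -> float:
    with np.errstate(all="ignore"):
        r = y - model.func(x, *params)
        val = float(np.sum(w * r * r))
    return val if np.isfinite(val) else float("inf")


def _aic(wrss: float, n: int, n_params: int) -> float:
    return n * float(np.log(max(wrss, 1e-300) / n)) + 2.0 * (n_params + 1)


def _fit_linear(model: ModelForm, x, y, w):
    if model.name == "linear_slope":
        res = sm.WLS(y, x[:, None], weights=w).fit()
        return (float(res.params[0]),)
    if model.name == "linear_intercept":
        # weighted normal equation for y = x + b has the closed-form root
        return (float(np.average(y - x, weights=w)),)
    res = sm.WLS(y, sm.add_constant(x), weights=w).fit()
    return (float(res.params[1]), float(res.params[0]))  # (slope, intercept)


def fit_model(
    x: np.ndarray,
    y: np.ndarray,
    w: np.ndarray,
    model: ModelForm,
    mode: str = "additive",
    seed: int = 0,
    max_restarts: int = 5,
) -> RegressionFit:
    """Weighted fit of one model form; non-convergence is reported, not raised."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    w = np.asarray(w, dtype=np.float64)
    n = len(x)
    if n < model.n_params + 1:
        return RegressionFit(model.name, (), mode, float("inf"), n, False)
    if model.linear:
        params = _fit_linear(model, x, y, w)
        wrss = _wrss(model, params, x, y, w)
        return RegressionFit(model.name, params, mode, _aic(wrss, n, model.n_params), n, True, wrss)

    rng = np.random.default_rng(seed)
    sigma = 1.0 / np.sqrt(w)
    bounds = model.bounds(x, y) if model.bounds is not None else None
    p0_base = np.asarray(model.init(x, y), dtype=np.float64)
    p0_base[~np.isfinite(p0_base)] = 1.0
    best: tuple[float, tuple[float, ...]] | None = None
    for attempt in range(max_restarts + 1):
        p0 = p0_base if attempt == 0 else p0_base * rng.lognormal(0.0, 0.5, p0_base.size) + rng.normal(0.0, 0.1, p0_base.size)
        try:
            with np.errstate(all="ignore"), warnings.catch_warnings():
                warnings.simplefilter("ignore")
                if bounds is not None:
                    lb, ub = np.asarray(bounds[0]), np.asarray(bounds[1])
                    p0c = np.clip(p0, lb + 1e-9, ub - 1e-9)
                    popt, _ = curve_fit(
                        model.func, x, y, p0=p0c, sigma=sigma, bounds=(lb, ub),
                        method="trf", maxfev=5000,
                    )
                else:
                    popt, _ = curve_fit(
                        model.func, x, y, p0=p0, sigma=sigma, method="lm", maxfev=5000
                    )
        except (RuntimeError, ValueError, TypeError):
            continue
        if not np.all(np.isfinite(popt)):
            continue
        wrss = _wrss(model, popt, x, y, w)
        if not np.isfinite(wrss):
            continue
        if best is None or wrss < best[0]:
            best = (wrss, tuple(float(p) for p in popt))
        if best is not None:
            break  # jittered restarts only when earlier attempts failed
    if best is None:
        return RegressionFit(model.name, (), mode, float("inf"), n, False)
    wrss, params = best
    return RegressionFit(model.name, params, mode, _aic(wrss, n, model.n_params), n, True, wrss)


def select_model(fits: Sequence[RegressionFit]) -> RegressionFit:
    converged = [f for f in fits if f.converged and np.isfinite(f.aic)]
    if not converged:
        raise RuntimeError("no regression model converged")
    return min(converged, key=lambda f: f.aic)


class NoiseBiasCorrector(RegressorMixin, BaseEstimator):
    """AIC-selected regression of feature bias on a local noise estimate.

    Parameters
    ----------
    mode : {"additive", "multiplicative"}
        Additive mode regresses RF_diff on SD_diff and corrects by adding the
        prediction; multiplicative mode regresses RF_ratio on COV_diff and
        corrects by multiplying.
    models : sequence of str or None
        Subset of model-zoo names to consider (None = full zoo).
    max_restarts : int
        Jittered re-initialisations per nonlinear model before giving up.
    alt_double_exp2 : bool
        Alternative parameterisation of the second double-exponential form.
    random_state : int
        Seed for restart jitter.
    """

    def __init__(
        self,
        mode: str = "additive",
        models: tuple[str, ...] | None = None,
        max_restarts: int = 5,
        alt_double_exp2: bool = False,
        random_state: int = 0,
    ):
        self.mode = mode
        self.models = models
        self.max_restarts = max_restarts
        self.alt_double_exp2 = alt_double_exp2
        self.random_state = random_state

    def fit(self, X, y, sample_weight=None):
        x = np.asarray(X, dtype=np.float64)
        if x.ndim == 2:
            if x.shape[1] != 1:
                raise ValueError("expected a single noise column")
            x = x[:, 0]
        y = np.asarray(y, dtype=np.float64)
        w = (
            np.ones_like(y)
            if sample_weight is None
            else np.asarray(sample_weight, dtype=np.float64)
        )
        if np.any(w <= 0) or not np.all(np.isfinite(w)):
            raise ValueError("weights must be positive and finite")
        zoo = model_zoo(self.alt_double_exp2)
        if self.models is not None:
            zoo = [m for m in zoo if m.name in set(self.models)]
        self._zoo_ = {m.name: m for m in zoo}
        fits = [
            fit_model(x, y, w, m, self.mode, seed=self.random_state,
                      max_restarts=self.max_restarts)
            for m in zoo
        ]
        self.fits_ = {f.model_name: f for f in fits}
        best = select_model(fits)
        self.best_model_ = best.model_name
        self.params_ = best.params
        self.aic_ = best.aic
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        x = np.asarray(X, dtype=np.float64)
        if x.ndim == 2:
            x = x[:, 0]
        model = self._zoo_[self.best_model_]
        with np.errstate(all="ignore"):
            return np.asarray(model.func(x, *self.params_), dtype=np.float64)

    def correct(self, rf_short, noise):
        """Predicted reference-equivalent value for noisy feature values."""
        pred = self.predict(np.asarray(noise, dtype=np.float64))
        rf_short = np.asarray(rf_short, dtype=np.float64)
        if self.mode == "additive":
            return rf_short + pred
        return rf_short * pred


# ------------------------------------------------------------- study-level


def _feature_seed(feature_id: str, seed: int) -> int:
    return (zlib.crc32(feature_id.encode()) ^ seed) & 0x7FFFFFFF


def build_observations(
    features: pd.DataFrame, noise: pd.DataFrame, feature_id: str,
    weight_floor_quantile: float = 0.05,
) -> pd.DataFrame:
    """Per (tumor, duration) bias observations for one feature.

    rf_short is the median over replicates, rf_long the reference value;
    weights are inverse replicate variances with the SD floored at the given
    quantile of all SDs for the feature (separately per mode).
    """
    sub = features[features["feature_id"] == feature_id]
    ref = sub[sub["replicate"] == "reference"].set_index("tumor_label")["value"]
    noisy = sub[sub["replicate"] != "reference"]
    rows = []
    for (tumor, duration), grp in noisy.groupby(["tumor_label", "duration_s"]):
        vals = grp["value"].to_numpy()
        rf_long = float(ref.loc[tumor])
        rf_short = float(np.median(vals))
        with np.errstate(all="ignore"):
            ratios = np.where(vals != 0, rf_long / vals, np.nan)
        rows.append(
            {
                "tumor_label": tumor,
                "duration_s": duration,
                "rf_short": rf_short,
                "rf_long": rf_long,
                "rf_diff": rf_long - rf_short,
                "rf_ratio": rf_long / rf_short if rf_short != 0 else np.nan,
                "sd_add": float(np.std(vals, ddof=1)),
                "sd_mul": (
                    float(np.nanstd(ratios, ddof=1))
                    if np.isfinite(ratios).sum() >= 2
                    else np.nan
                ),
            }
        )
    obs = pd.DataFrame(rows).merge(noise, on=["tumor_label", "duration_s"], how="inner")
    for col, wcol in (("sd_add", "w_add"), ("sd_mul", "w_mul")):
        sds = obs[col].to_numpy(dtype=np.float64)
        finite = sds[np.isfinite(sds)]
        floor = np.nanquantile(finite, weight_floor_quantile) if finite.size else np.nan
        floor = max(floor, 1e-12) if np.isfinite(floor) else 1e-12
        obs[wcol] = 1.0 / np.maximum(sds, floor) ** 2
    return obs


def _sdm_table(values: pd.DataFrame, ref: pd.Series, ddof: int) -> dict[float, float]:
    out = {}
    for duration, grp in values.groupby("duration_s"):
        pivot = grp.pivot_table(index="tumor_label", columns="replicate",
                                values="value", aggfunc="first")
        r = ref.reindex(pivot.index).to_numpy()
        sdm, _, _ = compute_sdm(r, pivot.to_numpy(), ddof=ddof)
        out[float(duration)] = sdm
    return out


def correct_study(
    features: pd.DataFrame,
    noise: pd.DataFrame,
    correctable_ids: Sequence[str],
    sdm_ddof: int = 1,
    seed: int = 0,
    alt_double_exp2: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[tuple[str, str], NoiseBiasCorrector]]:
    """Fit both correction modes for every correctable feature and re-score SDM.

    Returns (fits table, before/after SDM table, fitted correctors keyed by
    (feature_id, mode)). Features whose short-scan median is 0 anywhere fall
    back to the additive mode only.
    """
    fit_rows: list[dict] = []
    ba_rows: list[dict] = []
    correctors: dict[tuple[str, str], NoiseBiasCorrector] = {}
    for fid in correctable_ids:
        obs = build_observations(features, noise, fid)
        sub = features[features["feature_id"] == fid]
        ref = sub[sub["replicate"] == "reference"].set_index("tumor_label")["value"]
        noisy = sub[sub["replicate"] != "reference"].merge(
            noise, on=["tumor_label", "duration_s"], how="left"
        )
        sdm_before = _sdm_table(noisy, ref, sdm_ddof)
        modes = [("additive", "rf_diff", "sd_diff", "w_add")]
        if (obs["rf_short"] != 0).all() and np.isfinite(obs["rf_ratio"]).all():
            modes.append(("multiplicative", "rf_ratio", "cov_diff", "w_mul"))
        for mode, ycol, xcol, wcol in modes:
            o = obs.dropna(subset=[ycol, xcol, wcol])
            if len(o) < 3:
                continue
            est = NoiseBiasCorrector(
                mode=mode, random_state=_feature_seed(fid, seed),
                alt_double_exp2=alt_double_exp2,
            )
            try:
                est.fit(o[xcol].to_numpy(), o[ycol].to_numpy(), o[wcol].to_numpy())
            except RuntimeError:
                continue
            correctors[(fid, mode)] = est
            fit_rows.append(
                {
                    "feature_id": fid,
                    "mode": mode,
                    "model_name": est.best_model_,
                    "params": ";".join(f"{p:.10g}" for p in est.params_),
                    "aic": est.aic_,
                    "n_points": len(o),
                }
            )
            corrected = noisy.copy()
            corrected["value"] = est.correct(
                corrected["value"].to_numpy(), corrected[xcol].to_numpy()
            )
            sdm_after = _sdm_table(corrected, ref, sdm_ddof)
            for duration in sorted(sdm_before):
                ba_rows.append(
                    {
                        "feature_id": fid,
                        "mode": mode,
                        "duration_s": duration,
                        "sdm_before": sdm_before[duration],
                        "sdm_after": sdm_after[duration],
                        "category_before": categorize(sdm_before[duration]),
                        "category_after": categorize(sdm_after[duration]),
                    }
                )
    return pd.DataFrame(fit_rows), pd.DataFrame(ba_rows), correctors


def transfer_correct(
    correctors_a: dict[tuple[str, str], NoiseBiasCorrector],
    features_b: pd.DataFrame,
    noise_b: pd.DataFrame,
    feature_ids: Sequence[str],
    sdm_ddof: int = 1,
) -> pd.DataFrame:
    """Apply protocol A's fitted correctors to protocol B's data.

    Reports, per feature, mode and duration, the SDM before correction and
    after correction with the transferred parameters, plus the percentage SDM
    increase 100*(post - pre)/pre.
    """
    rows: list[dict] = []
    for fid in feature_ids:
        sub = features_b[features_b["feature_id"] == fid]
        ref = sub[sub["replicate"] == "reference"].set_index("tumor_label")["value"]
        noisy = sub[sub["replicate"] != "reference"].merge(
            noise_b, on=["tumor_label", "duration_s"], how="left"
        )
        sdm_before = _sdm_table(noisy, ref, sdm_ddof)
        for mode, xcol in (("additive", "sd_diff"), ("multiplicative", "cov_diff")):
            est = correctors_a.get((fid, mode))
            if est is None:
                continue
            corrected = noisy.copy()
            corrected["value"] = est.correct(
                corrected["value"].to_numpy(), corrected[xcol].to_numpy()
            )
            sdm_after = _sdm_table(corrected, ref, sdm_ddof)
            for duration in sorted(sdm_before):
                pre = sdm_before[duration]
                post = sdm_after[duration]
                rows.append(
                    {
                        "feature_id": fid,
                        "mode": mode,
                        "duration_s": duration,
                        "sdm_before": pre,
                        "sdm_after_transfer": post,
                        "pct_increase": 100.0 * (post - pre) / pre,
                    }
                )
    return pd.DataFrame(rows)
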