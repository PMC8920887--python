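"""Linear models for log K_sa / log k_e vs physicochemical predictors.

A partition model is a straight line ``log K_sa = slope * x + intercept``
fitted by (optionally weighted) least squares.  The 1/Y^2 weighting reflects
that uncertainty on log K_sa grows as volatility falls: less volatile
compounds are harder to measure in the vapor phase, so high-y points get
down-weighted.

Also here: 95% prediction intervals for new observations, the
high-confidence-data (HCD) filter that keeps only estimates with standard
deviation below one log unit, and repeated k-fold cross-validation for
comparing predictive performance between candidate models.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats as sps

from .chem_registry import Chemical, Predictor

__all__ = [
    "Weighting",
    "Response",
    "ParameterEstimate",
    "PartitionModel",
    "CVResult",
    "HCDFilterResult",
    "fit_weighted_line",
    "prediction_interval",
    "hcd_filter",
    "repeated_kfold_cv",
    "model_to_json",
    "model_from_json",
]


class Weighting(str, Enum):
    NONE = "NONE"
    INVERSE_Y2 = "INVERSE_Y2"


class Response(str, Enum):
    LOG_KSA = "LOG_KSA"
    LOG_KE = "LOG_KE"


@dataclass(frozen=True)
class ParameterEstimate:
    """One chemical's estimated log-scale kinetic parameter with uncertainty."""

    chemical: Chemical
    response: Response
    value: float
    sd: Optional[float] = None
    source: str = "this-study"

    def __post_init__(self) -> None:
        if self.sd is not None and self.sd < 0:
            raise ValueError("sd must be nonnegative")


@dataclass(frozen=True)
class HCDFilterResult:
    """Partition of estimates by the one-log-unit uncertainty rule."""

    retained: tuple[ParameterEstimate, ...]
    dropped: tuple[ParameterEstimate, ...]
    missing_sd: tuple[ParameterEstimate, ...]


@dataclass
class PartitionModel:
    """A fitted log-parameter vs predictor line with interval machinery.

    Stores the design information (x values and weights) needed to compute
    prediction intervals for future observations.
    """

    response: Response
    predictor: Predictor
    slope: float
    intercept: float
    n: int
    adj_r2: float
    rmse: float
    weighting: Weighting
    slope_se: float = float("nan")
    residual_scale: float = float("nan")  # sqrt(weighted SSE / (n-2))
    x_: Optional[np.ndarray] = field(default=None, repr=False)
    w_: Optional[np.ndarray] = field(default=None, repr=False)
    cv: Optional["CVResult"] = field(default=None, repr=False)

    def predict(self, x):
        return self.slope * np.asarray(x, dtype=float) + self.intercept


@dataclass
class CVResult:
    """Summary of a repeated k-fold cross-validation run."""

    k: int
    repeats: int
    seed: int
    mean_r2: float
    mean_rmse: float
    mean_mae: float
    per_resample: list[dict]
    final_model: Optional[PartitionModel] = None


def _weights(y: np.ndarray, weighting: Weighting) -> np.ndarray:
    if weighting is Weighting.INVERSE_Y2:
        if np.any(y == 0):
            raise ValueError("1/Y^2 weighting undefined for y = 0")
        return 1.0 / y**2
    return np.ones_like(y)


def fit_weighted_line(
    points: Sequence[tuple[float, float]],
    weighting: Weighting | str = Weighting.NONE,
    response: Response = Response.LOG_KSA,
    predictor: Predictor = Predictor.BP_TEST,
) -> PartitionModel:
    """Fit ``y = intercept + slope*x`` minimising the (weighted) sum of squares.

    With INVERSE_Y2 weighting each point carries weight 1/y_i^2.  Reported
    fit metrics: adjusted R^2 = 1 - (1-R^2)(n-1)/(n-2) from the weighted fit,
    and RMSE = sqrt(mean(unweighted squared residuals)) so models with
    different weightings stay comparable on a common scale.
    """
    weighting = Weighting(weighting)
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (x, y) pairs")
    if pts.shape[0] < 3:
        raise ValueError("need at least 3 points")
    x, y = pts[:, 0], pts[:, 1]
    if np.ptp(x) == 0:
        raise ValueError("predictor has zero variance; line undefined")
    w = _weights(y, weighting)

    X = sm.add_constant(x)
    res = sm.WLS(y, X, weights=w).fit()
    intercept, slope = float(res.params[0]), float(res.params[1])

    n = len(x)
    resid = y - (intercept + slope * x)
    rmse = float(np.sqrt(np.mean(resid**2)))
    adj_r2 = 1.0 - (1.0 - res.rsquared) * (n - 1) / (n - 2)
    residual_scale = float(np.sqrt(np.sum(w * resid**2) / (n - 2)))

    return PartitionModel(
        response=response,
        predictor=predictor,
        slope=slope,
        intercept=intercept,
        n=n,
        adj_r2=float(adj_r2),
        rmse=rmse,
        weighting=weighting,
        slope_se=float(res.bse[1]),
        residual_scale=residual_scale,
        x_=x.copy(),
        w_=w.copy(),
    )


def prediction_interval(model: PartitionModel, x0: float, level: float = 0.95) -> tuple[float, float]:
    """Interval expected to contain a fraction ``level`` of future observations at x0.

    Uses the t distribution with n-2 degrees of freedom and the weighted
    leverage; the variance of a new observation is s^2 * (1/w0 + 1/W +
    (x0 - xbar_w)^2 / S_xx_w).  For 1/Y^2-weighted fits the new point's
    weight w0 is evaluated at the predicted value (its own y is unknown).
    The interval is narrowest at the weighted mean of x and widens with
    leverage.
    """
    if not (0.0 < level < 1.0):
        raise ValueError("level must be in (0, 1)")
    if model.x_ is None or model.w_ is None:
        raise ValueError("model lacks retained design data; refit before intervals")
    x, w = model.x_, model.w_
    n = model.n
    W = float(np.sum(w))
    xbar = float(np.sum(w * x) / W)
    sxx = float(np.sum(w * (x - xbar) ** 2))
    yhat = model.slope * x0 + model.intercept
    if model.weighting is Weighting.INVERSE_Y2:
        w0 = 1.0 / yhat**2 if yhat != 0 else np.inf
    else:
        w0 = 1.0
    se = model.residual_scale * np.sqrt(1.0 / w0 + 1.0 / W + (x0 - xbar) ** 2 / sxx)
    tcrit = sps.t.ppf(0.5 + level / 2.0, n - 2)
    return (yhat - tcrit * se, yhat + tcrit * se)


def hcd_filter(estimates: Sequence[ParameterEstimate], sd_limit: float = 1.0) -> HCDFilterResult:
    """Keep only estimates whose log-scale SD is strictly below ``sd_limit``.

    One log-unit SD already spans an order of magnitude in concentration,
    so the conservative default retains only sd < 1.0.  Estimates without an
    SD cannot demonstrate low uncertainty and are set aside separately.
    """
    retained, dropped, missing = [], [], []
    for e in estimates:
        if e.sd is None or not np.isfinite(e.sd):
            missing.append(e)
        elif e.sd < sd_limit:
            retained.append(e)
        else:
            dropped.append(e)
    return HCDFilterResult(tuple(retained), tuple(dropped), tuple(missing))


def _score_heldout(y_true: np.ndarray, y_pred: np.ndarray) -> dict:
    err = y_true - y_pred
    sse = float(np.sum(err**2))
    sst = float(np.sum((y_true - np.mean(y_true)) ** 2))
    return {
        "r2": 1.0 - sse / sst if sst > 0 else float("nan"),
        "rmse": float(np.sqrt(np.mean(err**2))),
        "mae": float(np.mean(np.abs(err))),
    }


def repeated_kfold_cv(
    points: Sequence[tuple[float, float]],
    k: int = 10,
    repeats: int = 10,
    weighting: Weighting | str = Weighting.NONE,
    seed: int = 0,
    response: Response = Response.LOG_KSA,
    predictor: Predictor = Predictor.BP_TEST,
) -> CVResult:
    """Repeated k-fold cross-validation of the straight-line model.

    Each repeat shuffles the points with the seeded generator and splits them
    into k folds whose sizes differ by at most one; each fold in turn is held
    out, the line is fitted to the rest, and held-out R^2 / RMSE / MAE are
    recorded.  Reported metrics are means over all k*repeats resamples
    (held-out R^2 is NaN for single-point folds and excluded from the mean).
    The returned ``final_model`` is refit on all points: cross-validation
    estimates performance, the full fit supplies the coefficients.
    """
    weighting = Weighting(weighting)
    pts = np.asarray(points, dtype=float)
    n = pts.shape[0]
    if k < 2:
        raise ValueError("k must be >= 2")
    if n < k:
        raise ValueError(f"n = {n} < k = {k}; use a smaller k")
    rng = np.random.default_rng(seed)
    per_resample = []
    for rep in range(repeats):
        order = rng.permutation(n)
        folds = np.array_split(order, k)
        for fold_i, heldout in enumerate(folds):
            train = np.setdiff1d(order, heldout)
            m = fit_weighted_line(pts[train], weighting, response, predictor)
            scores = _score_heldout(pts[heldout, 1], m.predict(pts[heldout, 0]))
            scores.update({"repeat": rep, "fold": fold_i, "n_heldout": int(len(heldout))})
            per_resample.append(scores)
    r2s = np.array([s["r2"] for s in per_resample])
    result = CVResult(
        k=k,
        repeats=repeats,
        seed=seed,
        mean_r2=float(np.nanmean(r2s)) if np.any(np.isfinite(r2s)) else float("nan"),
        mean_rmse=float(np.mean([s["rmse"] for s in per_resample])),
        mean_mae=float(np.mean([s["mae"] for s in per_resample])),
        per_resample=per_resample,
    )
    final = fit_weighted_line(pts, weighting, response, predictor)
    final.cv = result
    result.final_model = final
    return result


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def model_to_json(model: PartitionModel) -> str:
    """Serialize a fitted model (and its CV summary, if any) to JSON."""
    payload = {
        "response": model.response.value,
        "predictor": model.predictor.value,
        "slope": model.slope,
        "intercept": model.intercept,
        "n": model.n,
        "adj_r2": model.adj_r2,
        "rmse": model.rmse,
        "weighting": model.weighting.value,
        "residual_scale": model.residual_scale,
    }
    if model.cv is not None:
        payload["cv"] = {
            "k": model.cv.k,
            "repeats": model.cv.repeats,
            "seed": model.cv.seed,
            "mean_r2": model.cv.mean_r2,
            "mean_rmse": model.cv.mean_rmse,
            "mean_mae": model.cv.mean_mae,
        }
    return json.dumps(payload, indent=2)


def model_from_json(text: str) -> PartitionModel:
    """Rebuild a model from its JSON form (without design data or per-fold detail)."""
    d = json.loads(text)
    model = PartitionModel(
        response=Response(d["response"]),
        predictor=Predictor(d["predictor"]),
        slope=d["slope"],
        intercept=d["intercept"],
        n=d["n"],
        adj_r2=d["adj_r2"],
        rmse=d["rmse"],
        weighting=Weighting(d["weighting"]),
        residual_scale=d.get("residual_scale", float("nan")),
    )
    if "cv" in d:
        c = d["cv"]
        model.cv = CVResult(
            k=c["k"], repeats=c["repeats"], seed=c["seed"],
            mean_r2=c["mean_r2"], mean_rmse=c["mean_rmse"], mean_mae=c["mean_mae"],
            per_resample=[], final_model=model,
        )
    return model
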