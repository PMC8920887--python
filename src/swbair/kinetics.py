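"""Uptake kinetics: curve fitting for equilibrium amount, K_sa, R_s and k_e.

Passive uptake into silicone follows first-order kinetics toward an
equilibrium amount N_s-eq = C_a * V_s * K_sa.  Two interchangeable curve
shapes are fitted to (time, amount) data:

* ``FIRST_ORDER`` -- N(t) = N_s-eq * (1 - exp(-k_e t)), the generative form
  of the rate-constant air-equivalency equations;
* ``MM`` -- a rectangular hyperbola N(t) = Vmax * t / (Km + t), whose plateau
  Vmax plays the role of N_s-eq.  This is the conventional fitting form for
  uptake curves in the passive-sampling literature and the default here.

Fits can use a robust loss (iteratively reweighted least squares with a Tukey
bisquare weight) so single aberrant observations do not dominate N_s-eq.
Derived quantities: K_sa = N_s-eq / V_s / C_a; the sampling rate R_s as the
initial (kinetic-phase) slope divided by C_a; and k_e = R_s / (V_s * K_sa),
with first-order propagation of uncertainty throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import NamedTuple, Optional, Sequence

import numpy as np
from scipy import optimize, stats

from .chem_registry import Chemical, SamplerSpec

__all__ = [
    "ModelForm",
    "EquilibriumStatus",
    "ValueSD",
    "UptakeObservation",
    "UptakeSeries",
    "KineticFit",
    "FitFailureError",
    "InsufficientDataError",
    "predict_uptake_first_order",
    "predict_uptake_mm",
    "fit_uptake",
    "compute_ksa",
    "estimate_sampling_rate",
    "derive_ke",
    "propagate_quotient_sd",
    "log10_with_sd",
]

#: Tukey bisquare tuning constant (95% efficiency under Gaussian errors).
TUKEY_C = 4.685

#: Default kinetic-window cutoff: observations where the fitted curve is below
#: this fraction of N_s-eq are treated as the linear uptake phase.
KINETIC_FRACTION = 0.25


class ModelForm(str, Enum):
    MM = "MM"
    FIRST_ORDER = "FIRST_ORDER"


class EquilibriumStatus(str, Enum):
    """How far along the uptake curve the experiment got.

    EQUILIBRIUM: last timepoint at >= 90% of the fitted plateau.
    CURVILINEAR: 50-90% (intermediate phase).
    KINETIC_ONLY: < 50%, only the linear phase observed.
    """

    EQUILIBRIUM = "EQUILIBRIUM"
    CURVILINEAR = "CURVILINEAR"
    KINETIC_ONLY = "KINETIC_ONLY"


class FitFailureError(RuntimeError):
    """Nonlinear fit failed to converge from every starting point."""


class InsufficientDataError(ValueError):
    """Too few quantified observations for the requested operation."""


class ValueSD(NamedTuple):
    """A point estimate with its standard deviation (sd may be NaN if unknown)."""

    value: float
    sd: float


@dataclass(frozen=True)
class UptakeObservation:
    """One sampler pulled from the chamber: time (days) and amount found (ng)."""

    t: float
    amount_ng: float
    replicate: str = "1"
    below_lod: bool = False

    def __post_init__(self) -> None:
        if self.t < 0:
            raise ValueError("time must be nonnegative")
        if self.amount_ng < 0:
            raise ValueError("amount must be nonnegative")


@dataclass(frozen=True)
class UptakeSeries:
    """Replicate-labelled uptake observations for one chemical under one exposure."""

    chemical: Chemical
    sampler: SamplerSpec
    ca_ng_per_l: float
    observations: tuple[UptakeObservation, ...]

    def __post_init__(self) -> None:
        if not self.ca_ng_per_l > 0:
            raise ValueError("exposure concentration must be positive")
        object.__setattr__(self, "observations", tuple(self.observations))

    def quantified(self) -> list[UptakeObservation]:
        return [o for o in self.observations if not o.below_lod]


@dataclass(frozen=True)
class KineticFit:
    """Everything derived from one uptake curve fit.

    ``km_or_ke`` is the second curve parameter: the half-saturation time Km
    (days) for MM fits, or the first-order rate k_e (per day) for FIRST_ORDER
    fits.  ``ke_per_day`` is always the dissipation rate on the first-order
    scale, derived via R_s for MM fits.
    """

    model_form: ModelForm
    sqrt_time_used: bool
    ns_eq_ng: ValueSD
    km_or_ke: ValueSD
    rs_l_per_day: ValueSD
    ksa: ValueSD
    ke_per_day: ValueSD
    log_ksa: ValueSD
    log_ke: ValueSD
    equilibrium_status: EquilibriumStatus
    n_obs: int
    density_g_per_ml: float
    robust: bool = True


# ---------------------------------------------------------------------------
# Forward models
# ---------------------------------------------------------------------------

def predict_uptake_first_order(t, ns_eq: float, ke: float):
    """Amount in sampler at time t (days) under first-order uptake.

    N(t) = ns_eq * (1 - exp(-ke * t)); monotone, bounded above by ns_eq.
    """
    t = np.asarray(t, dtype=float)
    if not ns_eq > 0 or not ke > 0 or np.any(t < 0):
        raise ValueError("require ns_eq > 0, ke > 0, t >= 0")
    return ns_eq * -np.expm1(-ke * t)


def predict_uptake_mm(t, vmax: float, km: float):
    """Rectangular-hyperbola uptake: N(t) = vmax * t / (km + t)."""
    t = np.asarray(t, dtype=float)
    if not vmax > 0 or not km > 0 or np.any(t < 0):
        raise ValueError("require vmax > 0, km > 0, t >= 0")
    return vmax * t / (km + t)


def _curve(model_form: ModelForm):
    if model_form is ModelForm.FIRST_ORDER:
        return lambda t, a, b: a * -np.expm1(-b * t)
    return lambda t, a, b: a * t / (b + t)


def _jacobian(model_form: ModelForm):
    if model_form is ModelForm.FIRST_ORDER:
        def jac(t, a, b):
            e = np.exp(-b * t)
            return np.column_stack([1.0 - e, a * t * e])
    else:
        def jac(t, a, b):
            return np.column_stack([t / (b + t), -a * t / (b + t) ** 2])
    return jac


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _initial_guesses(t: np.ndarray, y: np.ndarray, model_form: ModelForm) -> list[tuple[float, float]]:
    """Coarse deterministic multi-start grid over (plateau, timescale)."""
    ymax = float(np.max(y))
    tmax = float(np.max(t))
    # time at which y first exceeds half its maximum: a half-rise estimate
    above = t[y >= 0.5 * ymax]
    t_half = float(above.min()) if above.size else 0.5 * tmax
    t_half = max(t_half, 1e-3)
    guesses = []
    for a_mult in (1.0, 1.5, 3.0):
        for th in (t_half, 0.25 * tmax, tmax):
            a0 = max(a_mult * ymax, 1e-12)
            if model_form is ModelForm.FIRST_ORDER:
                b0 = math.log(2.0) / max(th, 1e-3)
            else:
                b0 = max(th, 1e-3)
            guesses.append((a0, b0))
    # drop duplicate starts (the timescale guesses often coincide)
    seen, unique = set(), []
    for g in guesses:
        key = (round(g[0], 9), round(g[1], 9))
        if key not in seen:
            seen.add(key)
            unique.append(g)
    return unique


def _ls_fit(t, y, model_form, p0, sigma=None):
    f = _curve(model_form)
    popt, pcov = optimize.curve_fit(
        f, t, y, p0=p0, sigma=sigma, absolute_sigma=False,
        jac=_jacobian(model_form),
        bounds=([1e-12, 1e-9], [np.inf, np.inf]), maxfev=20000,
    )
    resid = y - f(t, *popt)
    return popt, pcov, float(np.sum(resid**2))


def _fit_best_start(t, y, model_form, sigma=None):
    best = None
    errs = []
    for p0 in _initial_guesses(t, y, model_form):
        try:
            popt, pcov, sse = _ls_fit(t, y, model_form, p0, sigma=sigma)
        except (RuntimeError, ValueError, optimize.OptimizeWarning) as exc:  # non-convergence
            errs.append(str(exc))
            continue
        if best is None or sse < best[2]:
            best = (popt, pcov, sse)
    if best is None:
        raise FitFailureError(
            f"uptake fit did not converge from any start ({len(errs)} attempts); "
            f"last error: {errs[-1] if errs else 'none'}"
        )
    return best


def _tukey_weights(resid: np.ndarray) -> np.ndarray:
    s = np.median(np.abs(resid - np.median(resid))) / 0.6745
    if s <= 0:
        s = np.std(resid)
    if s <= 0:
        return np.ones_like(resid)
    u = resid / (TUKEY_C * s)
    w = np.where(np.abs(u) < 1.0, (1.0 - u**2) ** 2, 0.0)
    # never let all weights vanish
    if np.all(w < 1e-12):
        w = np.ones_like(resid)
    return np.maximum(w, 1e-8)


def fit_uptake(
    series: UptakeSeries,
    model_form: ModelForm | str = ModelForm.MM,
    robust: bool = True,
    sqrt_time: bool = False,
    kinetic_fraction: float = KINETIC_FRACTION,
) -> KineticFit:
    """Fit an uptake curve and derive K_sa, R_s and k_e with uncertainties.

    Below-LOD observations are excluded.  With ``robust`` the curve is refit
    by iteratively reweighted least squares using Tukey bisquare weights
    (deterministic; initialized from the plain least-squares solution).  With
    ``sqrt_time`` the curve is fitted against sqrt(t) instead of t — a
    variance-stabilising device for series that never reach equilibrium — and
    the result is capped at CURVILINEAR status since the plateau is then an
    extrapolation.

    Parameter SDs come from the Gauss-Newton covariance at the solution;
    a degenerate covariance yields NaN SDs (such estimates are excluded by
    the high-confidence-data filter downstream).
    """
    model_form = ModelForm(model_form)
    obs = series.quantified()
    times = sorted({o.t for o in obs})
    if len(obs) < 4 or len(times) < 2:
        raise InsufficientDataError(
            f"need >= 4 quantified observations over >= 2 distinct times, "
            f"got {len(obs)} over {len(times)}"
        )
    if len(obs) < 3 + 1:  # parameters + 1
        raise InsufficientDataError("fewer points than parameters + 1")

    t_raw = np.array([o.t for o in obs], dtype=float)
    y = np.array([o.amount_ng for o in obs], dtype=float)
    x = np.sqrt(t_raw) if sqrt_time else t_raw

    popt, pcov, _ = _fit_best_start(x, y, model_form)

    if robust:
        f = _curve(model_form)
        w_prev = None
        for _ in range(20):
            resid = y - f(x, *popt)
            w = _tukey_weights(resid)
            if w_prev is not None and np.allclose(w, w_prev, rtol=0, atol=1e-8):
                break
            w_prev = w
            sigma = 1.0 / np.sqrt(w)
            try:
                # warm start from the current solution; the multistart already
                # located the basin on the unweighted problem
                new_popt, new_pcov, _ = _ls_fit(x, y, model_form, tuple(popt), sigma=sigma)
            except (RuntimeError, ValueError, optimize.OptimizeWarning):
                break  # keep the last successful solution
            converged = np.allclose(new_popt, popt, rtol=1e-6, atol=0.0)
            popt, pcov = new_popt, new_pcov
            if converged:
                break

    perr = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else np.array([np.nan, np.nan])
    ns_eq = ValueSD(float(popt[0]), float(perr[0]))
    km_or_ke = ValueSD(float(popt[1]), float(perr[1]))

    # equilibrium status from the fitted fraction reached at the last timepoint
    f = _curve(model_form)
    frac_last = float(f(np.max(x), *popt) / popt[0])
    if sqrt_time:
        status = EquilibriumStatus.CURVILINEAR if frac_last >= 0.5 else EquilibriumStatus.KINETIC_ONLY
    elif frac_last >= 0.9:
        status = EquilibriumStatus.EQUILIBRIUM
    elif frac_last >= 0.5:
        status = EquilibriumStatus.CURVILINEAR
    else:
        status = EquilibriumStatus.KINETIC_ONLY

    ksa = compute_ksa(ns_eq, series.sampler, series.ca_ng_per_l)
    vs = series.sampler.volume_l

    if model_form is ModelForm.FIRST_ORDER and not sqrt_time:
        ke = ValueSD(km_or_ke.value, km_or_ke.sd)
        rs = ValueSD(ke.value * vs * ksa.value,
                     _product_sd(ke, ksa) * vs)
    else:
        rs = _sampling_rate_with_fallback(series, popt, model_form, sqrt_time, kinetic_fraction)
        ke = derive_ke(rs, series.sampler, ksa)

    log_ksa = log10_with_sd(ksa)
    log_ke = log10_with_sd(ke)

    return KineticFit(
        model_form=model_form,
        sqrt_time_used=sqrt_time,
        ns_eq_ng=ns_eq,
        km_or_ke=km_or_ke,
        rs_l_per_day=rs,
        ksa=ksa,
        ke_per_day=ke,
        log_ksa=log_ksa,
        log_ke=log_ke,
        equilibrium_status=status,
        n_obs=len(obs),
        density_g_per_ml=series.sampler.density_g_per_ml,
        robust=robust,
    )


def _product_sd(a: ValueSD, b: ValueSD) -> float:
    """First-order SD of a*b assuming independence."""
    rel = math.hypot(a.sd / a.value if a.value else 0.0,
                     b.sd / b.value if b.value else 0.0)
    return abs(a.value * b.value) * rel


def _sampling_rate_with_fallback(series, popt, model_form, sqrt_time, kinetic_fraction):
    """R_s from the kinetic-window slope; analytic initial slope if the window is thin."""
    f = _curve(model_form)
    obs = series.quantified()
    t_raw = np.array([o.t for o in obs], dtype=float)
    x = np.sqrt(t_raw) if sqrt_time else t_raw
    fitted = f(x, *popt)
    in_window = [o for o, fv in zip(obs, fitted) if fv < kinetic_fraction * popt[0]]
    if len(in_window) >= 3:
        try:
            return estimate_sampling_rate(series, window=[o.t for o in in_window])
        except InsufficientDataError:
            pass
    # too few points in the linear phase: use the analytic initial slope of
    # the fitted curve (ns_eq*ke for first-order, vmax/km for the hyperbola)
    a = ValueSD(float(popt[0]), float("nan"))
    b = ValueSD(float(popt[1]), float("nan"))
    if model_form is ModelForm.FIRST_ORDER:
        slope0 = a.value * b.value
    else:
        slope0 = a.value / b.value
    return ValueSD(slope0 / series.ca_ng_per_l, float("nan"))


def compute_ksa(ns_eq: ValueSD | float, sampler: SamplerSpec, ca: float) -> ValueSD:
    """K_sa = (N_s-eq / V_s) / C_a, dimensionless (volume basis).

    C_a and V_s are treated as exact; the SD comes from sd(N_s-eq) alone.
    """
    if isinstance(ns_eq, (int, float)):
        ns_eq = ValueSD(float(ns_eq), 0.0)
    if not ns_eq.value > 0 or not ca > 0:
        raise ValueError("ns_eq and ca must be positive")
    scale = 1.0 / (sampler.volume_l * ca)
    return ValueSD(ns_eq.value * scale, ns_eq.sd * scale)


def estimate_sampling_rate(series: UptakeSeries, window: Optional[Sequence[float]] = None) -> ValueSD:
    """Sampling rate R_s (L air cleared per day) from the linear uptake phase.

    Ordinary least-squares slope of amount vs time over the kinetic window
    (intercept fitted, not forced through zero), divided by the exposure
    concentration.  ``window`` is the collection of time values to include;
    by default all quantified observations are used.
    """
    obs = series.quantified()
    if window is not None:
        win = set(float(w) for w in window)
        obs = [o for o in obs if float(o.t) in win]
    if len(obs) < 3:
        raise InsufficientDataError(
            f"kinetic window holds {len(obs)} quantified points; need >= 3"
        )
    t = np.array([o.t for o in obs], dtype=float)
    y = np.array([o.amount_ng for o in obs], dtype=float)
    if np.unique(t).size < 2:
        raise InsufficientDataError("kinetic window spans a single timepoint")
    res = stats.linregress(t, y)
    return ValueSD(res.slope / series.ca_ng_per_l, res.stderr / series.ca_ng_per_l)


def derive_ke(rs: ValueSD | float, sampler: SamplerSpec, ksa: ValueSD | float) -> ValueSD:
    """Dissipation rate k_e = R_s / (V_s * K_sa), per day.

    Substituting this k_e back into the first-order air-equivalency equation
    reproduces the sampling-rate form exactly.  Uncertainty by first-order
    propagation on the quotient (V_s exact).
    """
    if isinstance(rs, (int, float)):
        rs = ValueSD(float(rs), 0.0)
    if isinstance(ksa, (int, float)):
        ksa = ValueSD(float(ksa), 0.0)
    denom = ValueSD(sampler.volume_l * ksa.value, sampler.volume_l * ksa.sd)
    return propagate_quotient_sd(rs, denom)


def propagate_quotient_sd(x: ValueSD, y: ValueSD) -> ValueSD:
    """First-order propagation of uncertainty for x/y (independent errors).

    Relative variance of the quotient is the sum of the relative variances.
    NaN SDs propagate to a NaN result SD.
    """
    if not x.value > 0 or not y.value > 0:
        raise ValueError("propagate_quotient_sd requires positive values")
    if (x.sd < 0) or (y.sd < 0):
        raise ValueError("standard deviations must be nonnegative")
    q = x.value / y.value
    rel = math.hypot(x.sd / x.value, y.sd / y.value)
    return ValueSD(q, q * rel)


def log10_with_sd(x: ValueSD) -> ValueSD:
    """Delta-method transform to log10 scale: sd_log = sd / (x * ln 10)."""
    if not x.value > 0:
        raise ValueError("log10 requires a positive value")
    if x.sd < 0:
        raise ValueError("standard deviation must be nonnegative")
    return ValueSD(math.log10(x.value), x.sd / (x.value * math.log(10.0)))
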