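"""Simulated chamber exposures and calibration tables with known ground truth.

The generator mirrors the vapor-generator / exposure-chamber design used for
wristband uptake calibration: each chemical is exposed at a constant air
concentration, 5-6 samplers are withdrawn over a 3-14 day window (log-spaced,
dense early, because volatile compounds approach equilibrium within hours),
and the whole time series is repeated to give three true replicates.

Amounts follow the first-order generative model
N(t) = C_a * V_s * K_sa * (1 - exp(-k_e t)) with independent multiplicative
lognormal noise of mean 1 and a chosen coefficient of variation, matching the
strictly-positive, roughly-proportional error behavior of chromatographic
quantitation.  Amounts below the detection limit are censored and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Union

import numpy as np

from .chem_registry import Chemical, SamplerSpec
from .kinetics import UptakeObservation, UptakeSeries
from .model_building import ParameterEstimate, Response

__all__ = [
    "ChemicalTruth",
    "ChamberScenario",
    "default_timepoints",
    "simulate_uptake_series",
    "simulate_calibration_table",
]


def default_timepoints(n: int = 6, start_days: float = 0.25, end_days: float = 14.0) -> tuple[float, ...]:
    """Log-spaced withdrawal times over the study window (days)."""
    return tuple(np.geomspace(start_days, end_days, n))


@dataclass(frozen=True)
class ChemicalTruth:
    """Ground-truth kinetics for one simulated chemical."""

    chemical: Chemical
    ksa: float
    ke_per_day: float
    ca_ng_per_l: float

    def __post_init__(self) -> None:
        if not (self.ksa > 0 and self.ke_per_day > 0 and self.ca_ng_per_l > 0):
            raise ValueError("ksa, ke and ca must all be positive")


@dataclass(frozen=True)
class ChamberScenario:
    """One simulated exposure campaign: truth set, schedule, noise and censoring."""

    truths: tuple[ChemicalTruth, ...]
    sampler: SamplerSpec = field(default_factory=SamplerSpec)
    timepoints: tuple[float, ...] = field(default_factory=default_timepoints)
    n_replicate_series: int = 3
    noise_cv: float = 0.0
    lod_ng: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        tp = tuple(float(t) for t in self.timepoints)
        if any(t <= 0 for t in tp) or any(b <= a for a, b in zip(tp, tp[1:])):
            raise ValueError("timepoints must be strictly increasing and positive")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be nonnegative")
        if self.n_replicate_series < 1:
            raise ValueError("need at least one replicate series")
        object.__setattr__(self, "truths", tuple(self.truths))
        object.__setattr__(self, "timepoints", tp)


def _lognormal_factors(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Multiplicative noise with mean exactly 1 and coefficient of variation cv."""
    if cv == 0:
        return np.ones(size)
    sigma2 = np.log1p(cv**2)
    mu = -0.5 * sigma2
    return rng.lognormal(mean=mu, sigma=np.sqrt(sigma2), size=size)


def simulate_uptake_series(scenario: ChamberScenario) -> list[UptakeSeries]:
    """Generate one UptakeSeries per chemical, replicates pooled as repeated measures.

    Identical seeds give bit-identical output.  Observations whose noisy
    amount falls below ``lod_ng`` are flagged ``below_lod`` with the bound as
    their recorded amount.
    """
    rng = np.random.default_rng(scenario.seed)
    vs = scenario.sampler.volume_l
    out = []
    t = np.asarray(scenario.timepoints)
    for truth in scenario.truths:
        ns_eq = truth.ca_ng_per_l * vs * truth.ksa
        clean = ns_eq * -np.expm1(-truth.ke_per_day * t)
        observations = []
        for rep in range(1, scenario.n_replicate_series + 1):
            eps = _lognormal_factors(rng, scenario.noise_cv, t.size)
            amounts = clean * eps
            for ti, amt in zip(t, amounts):
                censored = bool(amt < scenario.lod_ng)
                observations.append(UptakeObservation(
                    t=float(ti),
                    amount_ng=float(scenario.lod_ng if censored else amt),
                    replicate=str(rep),
                    below_lod=censored,
                ))
        out.append(UptakeSeries(
            chemical=truth.chemical,
            sampler=scenario.sampler,
            ca_ng_per_l=truth.ca_ng_per_l,
            observations=tuple(observations),
        ))
    return out


SdAssignment = Union[None, Sequence[float], Callable[[np.random.Generator, int], np.ndarray]]


def simulate_calibration_table(
    n_chem: int,
    predictor_range: tuple[float, float],
    true_slope: float,
    true_intercept: float,
    residual_sd: float,
    sd_assignment: SdAssignment = None,
    seed: int = 0,
    response: Response = Response.LOG_KSA,
) -> tuple[list[ParameterEstimate], np.ndarray]:
    """Draw a synthetic calibration dataset for regression / CV / filter testing.

    Predictor values are uniform over ``predictor_range``; responses are
    ``true_slope*x + true_intercept`` plus Gaussian noise of ``residual_sd``.
    ``sd_assignment`` attaches per-estimate SDs: a sequence of length
    ``n_chem``, a callable ``(rng, n) -> array``, or None (no SDs attached).
    Returns the estimates and the predictor vector.

    Estimate placeholders carry synthetic Chemical identities (benzene's CAS
    reused; only the predictor/response values matter downstream).
    """
    if n_chem < 5:
        raise ValueError("need at least 5 chemicals")
    rng = np.random.default_rng(seed)
    x = rng.uniform(predictor_range[0], predictor_range[1], size=n_chem)
    y = true_slope * x + true_intercept + rng.normal(0.0, residual_sd, size=n_chem)
    if sd_assignment is None:
        sds = [None] * n_chem
    elif callable(sd_assignment):
        sds = list(np.asarray(sd_assignment(rng, n_chem), dtype=float))
    else:
        sds = list(np.asarray(sd_assignment, dtype=float))
        if len(sds) != n_chem:
            raise ValueError("sd_assignment sequence length must equal n_chem")
    estimates = []
    for i in range(n_chem):
        chem = Chemical(
            name=f"synthetic-{i:03d}", cas="71-43-2", abbreviation=f"S{i:03d}",
            voc_class="VOC", mw=100.0, bp_test=float(x[i]),
        )
        estimates.append(ParameterEstimate(
            chemical=chem, response=response, value=float(y[i]),
            sd=None if sds[i] is None else float(sds[i]),
            source="synthetic",
        ))
    return estimates, x
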