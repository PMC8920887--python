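"""Air-equivalent concentrations from sampler amounts via rate-constant equations.

The central relation converts the amount N (ng) found in a silicone sampler
worn for t days into the air concentration it is equivalent to under standard
indoor conditions (25 degC, 50% RH, low wind):

    C_a = N / (V_s * K_sa * (1 - exp(-k_e * t)))            (dissipation form)
    C_a = N / (V_s * K_sa * (1 - exp(-R_s * t / (V_s * K_sa))))   (sampling-rate form)

The two are identical when R_s = k_e * V_s * K_sa.  When no rate parameter is
available the equilibrium assumption C_a = N / (V_s * K_sa) is used with an
explicit warning; it is a lower bound on the finite-time estimate.

K_sa comes from a registry of published high-confidence-data (HCD) models
regressing log K_sa on boiling point (TEST or OPERA QSAR) or log K_oa, with
the recommended fallback BP-TEST -> BP-OPERA applied per chemical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .chem_registry import (
    Chemical,
    Predictor,
    PredictorUnavailableError,
    SamplerSpec,
    resolve_predictor,
)
from .model_building import Response

__all__ = [
    "DeploymentRecord",
    "ModelRegistryEntry",
    "AirEquivalencyResult",
    "ModelComparison",
    "builtin_ksa_models",
    "predict_log_ksa",
    "air_equivalent_conc",
    "air_equivalent_conc_rs",
    "compare_model_pair",
    "spearman_rank_correlation",
]

#: Above this predicted log K_sa the air route loses relevancy: uptake is
#: increasingly dominated by direct/dermal contact and equilibrium is never
#: approached during a normal deployment.
LOG_KSA_RELEVANCY_LIMIT = 6.0


@dataclass(frozen=True)
class DeploymentRecord:
    """A worn-sampler measurement: amount found, sampler, and days worn."""

    chemical: Chemical
    amount_ng: float
    sampler: SamplerSpec
    t_days: float

    def __post_init__(self) -> None:
        if self.amount_ng < 0:
            raise ValueError("amount must be nonnegative")
        if not self.t_days > 0:
            raise ValueError("deployment time must be positive")


@dataclass(frozen=True)
class ModelRegistryEntry:
    """A published straight-line model: response = slope * predictor + intercept."""

    id: str
    response: Response
    predictor: Predictor
    slope: float
    intercept: float
    provenance: str = ""


@dataclass
class AirEquivalencyResult:
    """Per-chemical air-equivalent concentration with full provenance."""

    chemical: Chemical
    ca_ng_per_l: float
    ksa_used: float
    model_id: Optional[str]
    ke_used: Optional[float]
    ke_source: str  # "registry model" | "user value" | "equilibrium-assumption"
    fraction_equilibrated: float
    warnings: list[str] = field(default_factory=list)

    @property
    def ca_ug_per_m3(self) -> float:
        """Output-formatting convenience: 1 ng/L = 1000 ug/m^3."""
        return self.ca_ng_per_l * 1000.0


def builtin_ksa_models() -> dict[str, ModelRegistryEntry]:
    """The three published cross-validated HCD log K_sa models.

    All were fitted on the 29-chemical high-confidence dataset (VOCs and
    SVOCs, 1/Y^2 weighting) and take a single physicochemical input:
    boiling point in degC from the TEST or OPERA QSAR, or log K_oa.
    """
    entries = [
        ModelRegistryEntry("bp_test_cv", Response.LOG_KSA, Predictor.BP_TEST,
                           slope=0.020, intercept=0.527, provenance="HCD CV model, BP-TEST input"),
        ModelRegistryEntry("bp_opera_cv", Response.LOG_KSA, Predictor.BP_OPERA,
                           slope=0.019, intercept=0.829, provenance="HCD CV model, BP-OPERA input"),
        ModelRegistryEntry("log_koa_cv", Response.LOG_KSA, Predictor.LOG_KOA,
                           slope=0.867, intercept=0.190, provenance="HCD CV model, log K_oa input"),
    ]
    return {e.id: e for e in entries}


def predict_log_ksa(
    chemical: Chemical,
    model_id: str,
    registry: Optional[dict[str, ModelRegistryEntry]] = None,
) -> tuple[float, str]:
    """Predict log K_sa for a chemical; returns ``(value, model_id_used)``.

    When the BP-TEST model is requested for a chemical without a TEST boiling
    point, the prediction switches to the matching BP-OPERA model (fallback
    recorded in the returned id).  Extending the fallback to the log K_oa
    model is deliberate user opt-in, not automatic.
    """
    registry = registry if registry is not None else builtin_ksa_models()
    entry = registry[model_id]
    if entry.predictor is Predictor.BP_TEST and chemical.bp_test is None:
        if "bp_opera_cv" in registry and chemical.bp_opera is not None:
            fallback = registry["bp_opera_cv"]
            x, _ = resolve_predictor(chemical, fallback.predictor)
            return fallback.slope * x + fallback.intercept, fallback.id
        raise PredictorUnavailableError(
            f"predictor unavailable: {chemical.name} lacks BP-TEST and no OPERA fallback"
        )
    x, _ = resolve_predictor(chemical, entry.predictor)
    return entry.slope * x + entry.intercept, entry.id


def _check_positive(**kwargs) -> None:
    for name, v in kwargs.items():
        if not v > 0:
            raise ValueError(f"{name} must be positive, got {v}")


def air_equivalent_conc(
    record: DeploymentRecord,
    ksa: float,
    ke: Optional[float] = None,
    model_id: Optional[str] = None,
    ke_source: Optional[str] = None,
) -> AirEquivalencyResult:
    """Air-equivalent concentration (ng/L) from the dissipation-rate form.

    With ``ke`` given: C_a = N / (V_s * K_sa * (1 - exp(-ke * t))).  With
    ``ke`` absent the equilibrium assumption is applied (fraction equilibrated
    taken as 1) and a warning recorded: for chemicals far from equilibrium
    this understates the true air concentration.
    """
    vs = record.sampler.volume_l
    _check_positive(ksa=ksa, volume_l=vs, t_days=record.t_days)
    warnings = []
    if ke is not None:
        _check_positive(ke=ke)
        frac = -math.expm1(-ke * record.t_days)
        source = ke_source or "user value"
    else:
        frac = 1.0
        source = "equilibrium-assumption"
        warnings.append(
            "no dissipation rate supplied; equilibrium assumed — C_a is a lower bound"
        )
        if math.log10(ksa) > LOG_KSA_RELEVANCY_LIMIT:
            warnings.append(
                f"log K_sa = {math.log10(ksa):.2f} > {LOG_KSA_RELEVANCY_LIMIT:g}: "
                "equilibrium unlikely within deployment and air-route relevancy reduced"
            )
    ca = record.amount_ng / (vs * ksa * frac)
    return AirEquivalencyResult(
        chemical=record.chemical,
        ca_ng_per_l=ca,
        ksa_used=ksa,
        model_id=model_id,
        ke_used=ke,
        ke_source=source,
        fraction_equilibrated=frac,
        warnings=warnings,
    )


def air_equivalent_conc_rs(
    record: DeploymentRecord,
    ksa: float,
    rs: float,
    model_id: Optional[str] = None,
) -> AirEquivalencyResult:
    """Air-equivalent concentration from the sampling-rate form.

    Algebraically identical to the dissipation form with
    k_e = R_s / (V_s * K_sa).
    """
    _check_positive(rs=rs)
    ke = rs / (record.sampler.volume_l * ksa)
    result = air_equivalent_conc(record, ksa, ke=ke, model_id=model_id,
                                 ke_source="sampling-rate value")
    return result


@dataclass
class ModelComparison:
    """Per-chemical air-equivalency under two K_sa models, with agreement metrics."""

    model_a: str
    model_b: str
    table: pd.DataFrame  # columns: chemical, log_ksa_a, log_ksa_b, ca_a, ca_b, fold_difference
    spearman_r: float
    n_within_twofold: int
    excluded: list[str]


def compare_model_pair(
    chemicals: Iterable[Chemical],
    model_a_id: str,
    model_b_id: str,
    amount_ng: float,
    sampler: SamplerSpec,
    t_days: float,
    ke_policy: str = "equilibrium",
    ke_values: Optional[dict[str, float]] = None,
    registry: Optional[dict[str, ModelRegistryEntry]] = None,
) -> ModelComparison:
    """Compare air-equivalency estimates from two K_sa models chemical by chemical.

    Every chemical gets the same amount, sampler and deployment time, so the
    comparison isolates the effect of the K_sa model choice.  ``ke_policy``
    is ``"equilibrium"`` (default) or ``"user"`` with per-chemical rates in
    ``ke_values`` (keyed by chemical name).  Reports the fold-difference
    10**|delta log10 C_a| per chemical, the count agreeing within twofold,
    and the Spearman rank correlation across chemicals.
    """
    registry = registry if registry is not None else builtin_ksa_models()
    rows, excluded = [], []
    for chem in chemicals:
        try:
            la, ida = predict_log_ksa(chem, model_a_id, registry)
            lb, idb = predict_log_ksa(chem, model_b_id, registry)
        except PredictorUnavailableError:
            excluded.append(chem.name)
            continue
        record = DeploymentRecord(chem, amount_ng, sampler, t_days)
        ke = None
        if ke_policy == "user":
            if not ke_values or chem.name not in ke_values:
                excluded.append(chem.name)
                continue
            ke = ke_values[chem.name]
        ra = air_equivalent_conc(record, 10.0**la, ke=ke, model_id=ida)
        rb = air_equivalent_conc(record, 10.0**lb, ke=ke, model_id=idb)
        fold = 10.0 ** abs(math.log10(ra.ca_ng_per_l) - math.log10(rb.ca_ng_per_l)) \
            if amount_ng > 0 else 1.0
        rows.append({
            "chemical": chem.name,
            "log_ksa_a": la, "log_ksa_b": lb,
            "ca_a": ra.ca_ng_per_l, "ca_b": rb.ca_ng_per_l,
            "fold_difference": fold,
        })
    if len(rows) < 3:
        raise ValueError(f"only {len(rows)} chemicals comparable under both models; need >= 3")
    table = pd.DataFrame(rows)
    r = spearman_rank_correlation(table["ca_a"].to_numpy(), table["ca_b"].to_numpy())
    return ModelComparison(
        model_a=model_a_id,
        model_b=model_b_id,
        table=table,
        spearman_r=r,
        n_within_twofold=int((table["fold_difference"] <= 2.0).sum()),
        excluded=excluded,
    )


def spearman_rank_correlation(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman's r: Pearson correlation of average-tie ranks."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length vectors of at least 3 values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman correlation undefined for a constant vector")
    return float(sps.spearmanr(x, y).statistic)
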