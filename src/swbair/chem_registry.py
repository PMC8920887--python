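"""Chemical identities, physicochemical predictors, and the built-in calibration set.

The registry holds, per chemical: CAS number, volatility class (VOC/SVOC),
molecular weight, boiling-point estimates from two QSAR systems (TEST and
OPERA), the octanol-air partition coefficient (log K_oa), vapor pressure at
25 degC, and the chamber exposure concentration used during uptake
experiments.  Missing values are represented as ``None``, never imputed.

Predictor resolution implements the recommended fallback ordering for
air-equivalency work: when a TEST boiling point is requested but absent,
the OPERA boiling point is returned with an explicit provenance tag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from typing import Optional, Sequence

import pandas as pd

__all__ = [
    "Predictor",
    "Chemical",
    "SamplerSpec",
    "PredictorUnavailableError",
    "validate_cas",
    "load_builtin_chemicals",
    "resolve_predictor",
    "read_chemical_table",
    "write_chemical_table",
]

#: Default silicone density (g/mL).  Typical PDMS wristband values fall in
#: 1.1-1.2 g/mL; every K_sa-bearing output records the density actually used
#: because K_sa scales as 1/V_s.
DEFAULT_SILICONE_DENSITY_G_PER_ML = 1.10

#: Mass of a regular-size silicone wristband in grams.
DEFAULT_WRISTBAND_MASS_G = 4.76


class Predictor(str, Enum):
    """Physicochemical predictors usable on the x-axis of partition models."""

    BP_TEST = "BP_TEST"
    BP_OPERA = "BP_OPERA"
    LOG_KOA = "LOG_KOA"
    LOG_VP = "LOG_VP"


class PredictorUnavailableError(KeyError):
    """Raised when a chemical has no value (nor admissible fallback) for a predictor."""


def validate_cas(cas: str) -> bool:
    """Check a CAS registry number: ``digits-digits-digit`` plus check digit.

    The check digit is the weighted sum of the other digits (weights 1, 2, 3,
    ... from the right) modulo 10.
    """
    parts = cas.split("-")
    if len(parts) != 3:
        return False
    a, b, c = parts
    if not (a.isdigit() and b.isdigit() and c.isdigit()):
        return False
    if len(b) != 2 or len(c) != 1 or not (2 <= len(a) <= 7):
        return False
    digits = a + b
    checksum = sum(int(d) * w for d, w in zip(reversed(digits), range(1, len(digits) + 1)))
    return checksum % 10 == int(c)


@dataclass(frozen=True)
class Chemical:
    """One chemical with identity and physicochemical predictor values.

    ``exposure_conc`` is an ordered tuple because some chemicals were exposed
    at two concentrations in separate chamber runs; uptake series declare
    which one applies.
    """

    name: str
    cas: str
    abbreviation: str
    voc_class: str  # "VOC" or "SVOC"
    mw: float
    bp_exp: Optional[float] = None
    bp_test: Optional[float] = None
    bp_opera: Optional[float] = None
    log_koa: Optional[float] = None
    vp_mmhg: Optional[float] = None
    exposure_conc: tuple[float, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not validate_cas(self.cas):
            raise ValueError(f"invalid CAS number {self.cas!r} for {self.name}")
        if self.voc_class not in ("VOC", "SVOC"):
            raise ValueError(f"voc_class must be VOC or SVOC, got {self.voc_class!r}")
        if not self.mw > 0:
            raise ValueError(f"mw must be positive, got {self.mw}")
        if self.vp_mmhg is not None and not self.vp_mmhg > 0:
            raise ValueError(f"vp_mmhg must be positive, got {self.vp_mmhg}")
        for bp in (self.bp_exp, self.bp_test, self.bp_opera):
            if bp is not None and not (-200.0 < bp < 600.0):
                raise ValueError(f"boiling point {bp} degC outside (-200, 600)")

    @property
    def model_predictable(self) -> bool:
        """True when at least one of BP-TEST, BP-OPERA, log K_oa is present."""
        return any(v is not None for v in (self.bp_test, self.bp_opera, self.log_koa))


@dataclass(frozen=True)
class SamplerSpec:
    """Silicone sampler geometry: mass and density determine volume.

    The sampler volume V_s enters both the partition coefficient
    (K_sa = N_s-eq / V_s / C_a) and the air-equivalency denominator.
    """

    mass_g: float = DEFAULT_WRISTBAND_MASS_G
    density_g_per_ml: float = DEFAULT_SILICONE_DENSITY_G_PER_ML

    def __post_init__(self) -> None:
        if not self.mass_g > 0:
            raise ValueError("sampler mass must be positive")
        if not self.density_g_per_ml > 0:
            raise ValueError("silicone density must be positive")

    @property
    def volume_l(self) -> float:
        """Silicone volume in liters (mass / density / 1000)."""
        return self.mass_g / self.density_g_per_ml / 1000.0


# ---------------------------------------------------------------------------
# Built-in calibration set
# ---------------------------------------------------------------------------

_COLUMNS = [
    "name", "cas", "abbrev", "class", "mw",
    "bp_exp_c", "bp_test_c", "bp_opera_c", "log_koa", "vp_mmhg",
    "exposure_ng_per_l",
]


def _parse_exposure(cell) -> tuple[float, ...]:
    if cell is None or (isinstance(cell, float) and math.isnan(cell)) or cell == "":
        return ()
    return tuple(float(part) for part in str(cell).split(";"))


def _row_to_chemical(row: pd.Series) -> Chemical:
    def opt(col: str) -> Optional[float]:
        v = row[col]
        return None if pd.isna(v) else float(v)

    return Chemical(
        name=str(row["name"]),
        cas=str(row["cas"]),
        abbreviation=str(row["abbrev"]),
        voc_class=str(row["class"]),
        mw=float(row["mw"]),
        bp_exp=opt("bp_exp_c"),
        bp_test=opt("bp_test_c"),
        bp_opera=opt("bp_opera_c"),
        log_koa=opt("log_koa"),
        vp_mmhg=opt("vp_mmhg"),
        exposure_conc=_parse_exposure(row["exposure_ng_per_l"]),
    )


def read_chemical_table(path) -> list[Chemical]:
    """Read a chemical property table (comma-delimited, canonical header)."""
    df = pd.read_csv(path, dtype={"cas": str, "exposure_ng_per_l": str},
                     float_precision="round_trip")
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"chemical table missing columns: {missing}")
    return [_row_to_chemical(row) for _, row in df.iterrows()]


def write_chemical_table(chemicals: Sequence[Chemical], path) -> None:
    """Write chemicals in the canonical delimited schema (round-trip stable)."""
    records = []
    for c in chemicals:
        records.append({
            "name": c.name,
            "cas": c.cas,
            "abbrev": c.abbreviation,
            "class": c.voc_class,
            "mw": repr(c.mw),
            "bp_exp_c": "" if c.bp_exp is None else repr(c.bp_exp),
            "bp_test_c": "" if c.bp_test is None else repr(c.bp_test),
            "bp_opera_c": "" if c.bp_opera is None else repr(c.bp_opera),
            "log_koa": "" if c.log_koa is None else repr(c.log_koa),
            "vp_mmhg": "" if c.vp_mmhg is None else repr(c.vp_mmhg),
            "exposure_ng_per_l": ";".join(repr(x) for x in c.exposure_conc),
        })
    pd.DataFrame.from_records(records, columns=_COLUMNS).to_csv(path, index=False)


def load_builtin_chemicals() -> list[Chemical]:
    """Load the packaged 22-chemical calibration set (14 VOCs, 8 SVOCs).

    These are the chemicals exposed in the chamber uptake experiments, with
    boiling points from the TEST and OPERA QSAR systems, log K_oa, vapor
    pressure, and the chamber exposure concentrations.
    """
    ref = resources.files("swbair.data").joinpath("table1_chemicals.csv")
    with resources.as_file(ref) as path:
        return read_chemical_table(path)


def resolve_predictor(chemical: Chemical, predictor: Predictor) -> tuple[float, str]:
    """Return ``(value, provenance)`` for a predictor, applying the fallback rule.

    Provenance is ``"primary"`` when the requested predictor is present.  A
    request for BP_TEST on a chemical lacking it falls back to BP_OPERA and is
    tagged ``"fallback:BP_OPERA"`` -- never a silent substitution.  LOG_VP is
    computed as log10 of the stored vapor pressure (mm Hg).
    """
    predictor = Predictor(predictor)
    if predictor is Predictor.BP_TEST:
        if chemical.bp_test is not None:
            return chemical.bp_test, "primary"
        if chemical.bp_opera is not None:
            return chemical.bp_opera, "fallback:BP_OPERA"
        raise PredictorUnavailableError(
            f"predictor unavailable: {chemical.name} has neither BP-TEST nor BP-OPERA"
        )
    if predictor is Predictor.BP_OPERA:
        if chemical.bp_opera is not None:
            return chemical.bp_opera, "primary"
    elif predictor is Predictor.LOG_KOA:
        if chemical.log_koa is not None:
            return chemical.log_koa, "primary"
    elif predictor is Predictor.LOG_VP:
        if chemical.vp_mmhg is not None:
            return math.log10(chemical.vp_mmhg), "primary"
    raise PredictorUnavailableError(
        f"predictor unavailable: {chemical.name} has no {predictor.value}"
    )
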