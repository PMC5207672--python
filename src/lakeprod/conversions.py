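"""Unit and quantity conversions for lake-productivity work.

Chlorophyll-a from ethanol-extract absorbance, O2 solubility and
percent-saturation handling, practical salinity from conductivity,
O2-to-carbon flux conversion via a photosynthetic quotient, and the simple
carbon-budget bookkeeping (growth rate, turnover, annual fixation) used when
relating daily primary production to a standing stock.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import seawater
from .constants import (
    CHLA_COEF_UG_PER_ML,
    O2_MOLAR_MASS,
    C_MOLAR_MASS,
    PSS78_VALID_SALINITY,
    SOLUBILITY_VALID_T,
    SOLUBILITY_VALID_S,
)

__all__ = [
    "ChlaReading",
    "PamTransient",
    "CarbonBudget",
    "chla_from_absorbance",
    "o2_saturation_concentration",
    "percent_saturation_to_concentration",
    "salinity_from_conductivity",
    "oxygen_to_carbon",
    "carbon_to_oxygen",
    "o2_rate_mass_to_molar",
    "carbon_budget",
    "quantum_yield",
]


class ExtrapolationWarning(UserWarning):
    """A value was computed outside the validity range of its empirical fit."""


@dataclass(frozen=True)
class ChlaReading:
    """A spectrophotometric chlorophyll-a reading on an ethanol extract.

    Absorbances are for a 1-cm path; ``a750`` is the turbidity blank.
    ``extract_volume`` is the ethanol volume (mL), ``filtered_volume`` the
    lake-water volume pushed through the filter (mL).
    """

    a665: float
    a750: float
    extract_volume: float
    filtered_volume: float

    def __post_init__(self):
        if self.a665 < 0 or self.a750 < 0:
            raise ValueError("absorbances must be non-negative")
        if self.extract_volume <= 0 or self.filtered_volume <= 0:
            raise ValueError("extract and filtered volumes must be positive")


@dataclass(frozen=True)
class PamTransient:
    """A dark-adapted PAM fluorescence transient (basal F0, saturating Fmax)."""

    f0: float
    fmax: float

    def __post_init__(self):
        if self.fmax <= 0:
            raise ValueError("fmax must be positive")
        if not (0 <= self.f0 <= self.fmax):
            raise ValueError("need 0 <= f0 <= fmax for a dark-adapted transient")


@dataclass(frozen=True)
class CarbonBudget:
    """Daily production set against a standing stock of autotroph carbon.

    ``growth_rate`` is the exponential rate mu = ln(1 + P/B) in d-1;
    ``daily_turnover`` the simple percentage 100*P/B; ``annual_fixation``
    assumes the daily rate holds year-round.
    """

    daily_production: float  # g C m-2 d-1
    standing_stock: float    # g C m-2
    growth_rate: float = field(init=False)      # d-1
    daily_turnover: float = field(init=False)   # % of stock
    annual_fixation: float = field(init=False)  # g C m-2 yr-1
    doubling_time: float = field(init=False)    # d

    def __post_init__(self):
        if self.standing_stock <= 0:
            raise ValueError("standing stock must be positive")
        if self.daily_production < 0:
            raise ValueError("daily production must be non-negative")
        pb = self.daily_production / self.standing_stock
        object.__setattr__(self, "growth_rate", math.log1p(pb))
        object.__setattr__(self, "daily_turnover", 100.0 * pb)
        object.__setattr__(self, "annual_fixation", 365.0 * self.daily_production)
        object.__setattr__(
            self, "doubling_time",
            math.inf if pb == 0 else math.log(2.0) / math.log1p(pb))


def chla_from_absorbance(reading: ChlaReading) -> tuple[float, float]:
    """Chlorophyll-a from a 665/750-nm ethanol-extract absorbance pair.

    Returns ``(extract, in_lake)``: the extract concentration in ug mL-1
    (11.904 ug mL-1 per unit of A665 - A750) and the in-lake concentration
    in ug L-1 after accounting for extract and filtered volumes.

    A negative absorbance difference (blank above sample, possible in turbid
    field extracts) is clamped to zero with a warning.
    """
    diff = reading.a665 - reading.a750
    if diff < 0:
        warnings.warn(
            "A665 < A750: negative pigment difference clamped to zero",
            ExtrapolationWarning, stacklevel=2)
        diff = 0.0
    extract = CHLA_COEF_UG_PER_ML * diff  # ug per mL of extract
    in_lake = extract * reading.extract_volume / reading.filtered_volume * 1000.0
    return extract, in_lake


def absorbance_for_chla(in_lake_ug_l: float, extract_volume: float,
                        filtered_volume: float) -> float:
    """Inverse of :func:`chla_from_absorbance`: the A665-A750 difference that
    yields a given in-lake concentration (ug L-1). Used to build fixtures."""
    extract = in_lake_ug_l / 1000.0 * filtered_volume / extract_volume
    return extract / CHLA_COEF_UG_PER_ML


def o2_saturation_concentration(temperature: float, salinity: float,
                                fit: str = "garcia-gordon") -> float:
    """Equilibrium O2 concentration (mg L-1) at 1 atm.

    ``fit`` selects the solubility parameterization: ``"garcia-gordon"``
    (default; Benson–Krause coefficients) or ``"weiss"``. Both agree to
    well under 2% over the warm saline range of interest.
    """
    t = np.asarray(temperature, dtype=float)
    s = np.asarray(salinity, dtype=float)
    if np.any(t < SOLUBILITY_VALID_T[0]) or np.any(t > SOLUBILITY_VALID_T[1]):
        raise ValueError(f"temperature outside {SOLUBILITY_VALID_T} degC")
    if np.any(s < SOLUBILITY_VALID_S[0]) or np.any(s > SOLUBILITY_VALID_S[1]):
        raise ValueError(f"salinity outside {SOLUBILITY_VALID_S} psu")
    if fit == "garcia-gordon":
        out = seawater.o2_solubility_garcia_gordon(t, s)
    elif fit == "weiss":
        out = seawater.o2_solubility_weiss(t, s)
    else:
        raise ValueError(f"unknown solubility fit {fit!r}")
    return out if out.ndim else float(out)


def percent_saturation_to_concentration(percent, temperature, salinity,
                                        fit: str = "garcia-gordon"):
    """Convert an O2 reading in % air saturation to mg L-1 at (T, S)."""
    pct = np.asarray(percent, dtype=float)
    if np.any(pct < 0):
        raise ValueError("percent saturation must be non-negative")
    out = pct / 100.0 * o2_saturation_concentration(temperature, salinity, fit=fit)
    return out if np.ndim(out) else float(out)


def salinity_from_conductivity(conductivity_ms_cm: float,
                               temperature: float) -> float:
    """Practical salinity (PSS-78, zero pressure) from conductivity in mS cm-1.

    Values outside the PSS-78 validity range [2, 42] psu — routine for
    hypersaline lakes — are still returned but raise an
    :class:`ExtrapolationWarning`.
    """
    if np.any(np.asarray(conductivity_ms_cm) <= 0):
        raise ValueError("conductivity must be positive")
    t = np.asarray(temperature, dtype=float)
    if np.any(t < 0) or np.any(t > 40):
        raise ValueError("temperature outside [0, 40] degC")
    s = seawater.practical_salinity_pss78(conductivity_ms_cm, temperature)
    lo, hi = PSS78_VALID_SALINITY
    if np.any(s < lo) or np.any(s > hi):
        warnings.warn(
            f"practical salinity outside the PSS-78 validity range [{lo}, {hi}]"
            " — value is an extrapolation", ExtrapolationWarning, stacklevel=2)
    return s if np.ndim(s) else float(s)


def oxygen_to_carbon(o2_flux: float, pq: float = 1.0) -> float:
    """Convert an O2 flux (g O2 m-2 d-1) to carbon (g C m-2 d-1).

    ``pq`` is the photosynthetic quotient, the molar ratio of O2 evolved to
    CO2 fixed (1 for nitrate-free carbohydrate synthesis).
    """
    if pq <= 0:
        raise ValueError("photosynthetic quotient must be positive")
    return o2_flux / O2_MOLAR_MASS / pq * C_MOLAR_MASS


def carbon_to_oxygen(c_flux: float, pq: float = 1.0) -> float:
    """Inverse of :func:`oxygen_to_carbon` with the same quotient."""
    if pq <= 0:
        raise ValueError("photosynthetic quotient must be positive")
    return c_flux / C_MOLAR_MASS * pq * O2_MOLAR_MASS


def o2_rate_mass_to_molar(rate_mg):
    """mg O2 (per whatever basis) -> umol O2 on the same basis."""
    return np.multiply(rate_mg, 1000.0 / O2_MOLAR_MASS)


def carbon_budget(daily_production: float, standing_stock: float) -> CarbonBudget:
    """Relate daily carbon fixation P to a standing stock B.

    Returns a :class:`CarbonBudget` with mu = ln(1 + P/B) (d-1), the daily
    turnover 100*P/B (%), the annual fixation 365*P and the doubling time
    ln 2 / mu.
    """
    return CarbonBudget(daily_production, standing_stock)


def quantum_yield(transient: PamTransient) -> float:
    """Dark-adapted PSII quantum yield Qy = (Fmax - F0)/Fmax, in [0, 1]."""
    return (transient.fmax - transient.f0) / transient.fmax
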