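"""Physical seawater relations used throughout the package.

All functions are scalar-or-array (numpy broadcasting) implementations of the
standard published fits used in limnology and oceanography:

* oxygen solubility — Garcia & Gordon (1992) combined fit with the
  Benson & Krause coefficients (micromol per kg, converted to mg per litre
  with the EOS-80 surface density), and the older Weiss (1970) ml-per-litre
  fit as an independent alternative;
* practical salinity — PSS-78 from conductivity at zero pressure;
* density — EOS-80 one-atmosphere equation of state;
* Schmidt number — Wanninkhof (2014) polynomial for O2, linearly
  interpolated in salinity between the fresh- and sea-water fits.

They are valid for the oxic surface layer of warm saline lakes: roughly
T in [-2, 40] degC and S in [0, 60] (the solubility fits) and the PSS-78
validity range S in [2, 42] (values outside are extrapolations and are
flagged by the caller in :mod:`lakeprod.conversions`).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "density_eos80",
    "o2_solubility_garcia_gordon",
    "o2_solubility_weiss",
    "practical_salinity_pss78",
    "schmidt_number_o2",
    "R35_MS_CM",
]

#: Conductivity of the PSS-78 reference (S=35, 15 degC, 0 dbar), mS/cm.
R35_MS_CM = 42.914

# mg of O2 per ml of O2 at STP (ideal-gas molar volume 22.392 l/mol for O2)
_MG_PER_ML_O2 = 1.42905


def density_eos80(temperature, salinity):
    """Seawater density at atmospheric pressure (kg m-3), EOS-80.

    UNESCO (1983) one-atmosphere international equation of state.
    """
    t = np.asarray(temperature, dtype=float)
    s = np.asarray(salinity, dtype=float)
    rho_w = (999.842594 + 6.793952e-2 * t - 9.095290e-3 * t**2
             + 1.001685e-4 * t**3 - 1.120083e-6 * t**4 + 6.536332e-9 * t**5)
    a = (8.24493e-1 - 4.0899e-3 * t + 7.6438e-5 * t**2
         - 8.2467e-7 * t**3 + 5.3875e-9 * t**4)
    b = -5.72466e-3 + 1.0227e-4 * t - 1.6546e-6 * t**2
    c = 4.8314e-4
    return rho_w + a * s + b * s**1.5 + c * s**2


# Garcia & Gordon (1992) combined fit, Benson & Krause coefficients.
_GG_A = (5.80871, 3.20291, 4.17887, 5.10006, -9.86643e-2, 3.80369)
_GG_B = (-7.01577e-3, -7.70028e-3, -1.13864e-2, -9.51519e-3)
_GG_C0 = -2.75915e-7


def o2_solubility_garcia_gordon(temperature, salinity):
    """Equilibrium O2 concentration (mg L-1) of air-saturated water.

    Garcia & Gordon (1992) combined fit with Benson & Krause coefficients
    (yields micromol per kg), converted to mg per litre using the EOS-80
    density at (T, S). Moist air at 1 atm total pressure.
    """
    t = np.asarray(temperature, dtype=float)
    s = np.asarray(salinity, dtype=float)
    ts = np.log((298.15 - t) / (273.15 + t))  # scaled temperature
    ln_c = sum(a * ts**i for i, a in enumerate(_GG_A))
    ln_c = ln_c + s * sum(b * ts**i for i, b in enumerate(_GG_B))
    ln_c = ln_c + _GG_C0 * s**2
    umol_kg = np.exp(ln_c)
    mg_kg = umol_kg * 31.9988e-3
    return mg_kg * density_eos80(t, s) / 1000.0


def o2_solubility_weiss(temperature, salinity):
    """Equilibrium O2 concentration (mg L-1), Weiss (1970) fit.

    Independent of the Garcia–Gordon fit: different functional form
    (Van't Hoff / Setchenow in absolute temperature), different source data,
    native units ml(STP) per litre. Kept as a cross-check and as a
    selectable alternative solubility model.
    """
    tk = np.asarray(temperature, dtype=float) + 273.15
    s = np.asarray(salinity, dtype=float)
    ln_c = (-173.4292 + 249.6339 * (100.0 / tk) + 143.3483 * np.log(tk / 100.0)
            - 21.8492 * (tk / 100.0)
            + s * (-0.033096 + 0.014259 * (tk / 100.0)
                   - 0.0017000 * (tk / 100.0) ** 2))
    return np.exp(ln_c) * _MG_PER_ML_O2


# PSS-78 coefficient tables (UNESCO 1981).
_PSS_A = (0.0080, -0.1692, 25.3851, 14.0941, -7.0261, 2.7081)
_PSS_B = (0.0005, -0.0056, -0.0066, -0.0375, 0.0636, -0.0144)
_PSS_C = (0.6766097, 2.00564e-2, 1.104259e-4, -6.9698e-7, 1.0031e-9)
_PSS_K = 0.0162


def practical_salinity_pss78(conductivity_ms_cm, temperature):
    """Practical salinity (PSS-78) from conductivity (mS cm-1) at 0 dbar.

    ``conductivity_ms_cm`` is the in-situ conductivity, not a
    temperature-compensated specific conductance.
    """
    t = np.asarray(temperature, dtype=float)
    r = np.asarray(conductivity_ms_cm, dtype=float) / R35_MS_CM
    rt_t = sum(c * t**i for i, c in enumerate(_PSS_C))
    rt = r / rt_t  # pressure correction Rp = 1 at the surface
    x = np.sqrt(rt)
    s = sum(a * x**i for i, a in enumerate(_PSS_A))
    ds = ((t - 15.0) / (1.0 + _PSS_K * (t - 15.0))
          * sum(b * x**i for i, b in enumerate(_PSS_B)))
    return s + ds


# Wanninkhof (2014) Schmidt-number polynomials for O2.
_SC_FRESH = (1745.1, -124.34, 4.8055, -0.10115, 0.00086842)
_SC_SEA35 = (1920.4, -135.6, 5.2122, -0.10939, 0.00093777)


def schmidt_number_o2(temperature, salinity=0.0):
    """Schmidt number of O2 in water at (T, S).

    Wanninkhof (2014) 4th-order polynomials for fresh water and S=35
    seawater, interpolated (and beyond S=35, extrapolated) linearly in
    salinity — the standard practice for brackish and hypersaline systems
    in the absence of a dedicated fit.
    """
    t = np.asarray(temperature, dtype=float)
    s = np.asarray(salinity, dtype=float)
    sc0 = sum(c * t**i for i, c in enumerate(_SC_FRESH))
    sc35 = sum(c * t**i for i, c in enumerate(_SC_SEA35))
    return sc0 + (sc35 - sc0) * s / 35.0
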