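"""Photosynthesis–irradiance (P–I) curves with photoinhibition.

Rates are extracted from closed-flask O2 incubations (photosynthetic oxygen
evolution, PSOE) by linear regression of concentration on time, normalised
to chlorophyll, and fitted against irradiance with the three-parameter
exponential photoinhibition model of Platt:

    P(I) = Ps * (1 - exp(-alpha*I/Ps)) * exp(-beta*I/Ps)

where Ps is the capacity parameter (the "Pmax" of the printed model), alpha
the light-limited initial slope and beta >= 0 the photoinhibition slope. The
same machinery applies unchanged to PAM rETR-vs-irradiance data (units tag
"umol electrons m-2 s-1").

Fitting follows the statsmodels shape: :class:`PlattModel` wraps the
observations, ``fit()`` returns a :class:`PlattResults` with estimates,
standard errors, diagnostics and a ``summary()`` table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .constants import O2_MOLAR_MASS

__all__ = [
    "IncubationSeries",
    "PIDataset",
    "PICurve",
    "PlattModel",
    "PlattResults",
    "psoe_rate",
    "platt_p",
    "fit_platt",
    "derived_indices",
]

#: default R-squared below which an incubation is flagged nonlinear
DEFAULT_MIN_R2 = 0.95


@dataclass(frozen=True)
class IncubationSeries:
    """O2 concentration vs time in one flask at constant irradiance.

    times in h, o2_conc in mg L-1, irradiance in umol photons m-2 s-1
    (0 = dark flask), chla of the incubated sample in ug L-1.
    """

    times: np.ndarray
    o2_conc: np.ndarray
    irradiance: float
    chla: float

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        o = np.asarray(self.o2_conc, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "o2_conc", o)
        if t.shape != o.shape or t.ndim != 1 or len(t) < 3:
            raise ValueError("need >= 3 matched (time, O2) points")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if t[-1] - t[0] < 1.0:
            raise ValueError("incubation must span at least 1 h")
        if self.irradiance < 0:
            raise ValueError("irradiance must be non-negative")


@dataclass(frozen=True)
class PIDataset:
    """Chlorophyll-specific rates observed across an irradiance gradient.

    ``rates`` in umol O2 (mg chl a)-1 h-1 for PSOE data, or umol electrons
    m-2 s-1 for PAM rETR; ``dark_rate`` (respiration, <= 0) in the same units.
    """

    irradiances: np.ndarray
    rates: np.ndarray
    dark_rate: float = 0.0
    units: str = "umol O2 mg chla-1 h-1"

    def __post_init__(self):
        i = np.asarray(self.irradiances, dtype=float)
        r = np.asarray(self.rates, dtype=float)
        object.__setattr__(self, "irradiances", i)
        object.__setattr__(self, "rates", r)
        if i.shape != r.shape or i.ndim != 1:
            raise ValueError("irradiances and rates must be 1-d and same length")
        if len(np.unique(i[i > 0])) < 5:
            raise ValueError("need >= 5 distinct positive irradiances "
                             "for a 3-parameter fit")
        if self.dark_rate > 0:
            raise ValueError("dark (respiration) rate must be <= 0")


@dataclass(frozen=True)
class PICurve:
    """Parameters of the Platt photoinhibition model, with a units tag."""

    p_s: float
    alpha: float
    beta: float
    units: str = "umol O2 mg chla-1 h-1"

    def __post_init__(self):
        if self.p_s <= 0:
            raise ValueError("p_s must be positive")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.beta < 0:
            raise ValueError("beta must be non-negative")

    def __call__(self, irradiance):
        return platt_p(self, irradiance)


def platt_p(curve: PICurve, irradiance):
    """Evaluate P(I) = Ps (1 - e^(-alpha I/Ps)) e^(-beta I/Ps)."""
    i = np.asarray(irradiance, dtype=float)
    if np.any(i < 0):
        raise ValueError("irradiance must be non-negative")
    out = _platt(i, curve.p_s, curve.alpha, curve.beta)
    return out if np.ndim(out) else float(out)


def _platt(i, p_s, alpha, beta):
    return p_s * (1.0 - np.exp(-alpha * i / p_s)) * np.exp(-beta * i / p_s)


@dataclass(frozen=True)
class RateEstimate:
    """A chlorophyll-specific PSOE rate with its linearity diagnostic."""

    rate: float          # umol O2 mg chla-1 h-1
    rate_mg: float       # mg O2 mg chla-1 h-1
    slope_se: float      # mg O2 L-1 h-1
    r_squared: float
    nonlinear: bool
    irradiance: float


def psoe_rate(series: IncubationSeries, min_r2: float = DEFAULT_MIN_R2
              ) -> RateEstimate:
    """Chlorophyll-specific oxygen-evolution rate from one flask.

    OLS slope of O2 (mg L-1) on time (h), normalised by the sample's
    chlorophyll and converted to umol O2 (mg chl a)-1 h-1. The R-squared of
    the regression is the linearity diagnostic; below ``min_r2`` the flask
    is flagged nonlinear (substrate exhaustion or bubble formation).
    """
    if series.chla <= 0:
        raise ValueError("chla must be positive to normalise the rate")
    res = stats.linregress(series.times, series.o2_conc)
    slope = res.slope  # mg O2 L-1 h-1
    chla_mg_l = series.chla / 1000.0
    rate_mg = slope / chla_mg_l                      # mg O2 mg chla-1 h-1
    rate_umol = rate_mg * 1000.0 / O2_MOLAR_MASS     # umol O2 mg chla-1 h-1
    r2 = 1.0 if np.allclose(series.o2_conc, series.o2_conc[0]) \
        else float(res.rvalue**2)
    return RateEstimate(rate=float(rate_umol), rate_mg=float(rate_mg),
                        slope_se=float(res.stderr), r_squared=r2,
                        nonlinear=r2 < min_r2, irradiance=series.irradiance)


class PlattModel:
    """Nonlinear least-squares Platt fit of a :class:`PIDataset`.

    Initialisation: alpha from the slope through the three lowest-light
    points, Ps from the maximum observed rate, beta from the high-light
    decline (0 if none). On convergence failure the fit restarts from five
    jittered starting points (deterministic seed).
    """

    def __init__(self, data: PIDataset, subtract_dark: bool = False):
        self.data = data
        rates = data.rates.copy()
        if subtract_dark:
            rates = rates - data.dark_rate  # dark_rate <= 0: raises light rates
        self.endog = rates
        self.exog = data.irradiances
        if np.allclose(rates, rates[0]):
            raise ValueError("rates are all equal; P-I fit is unidentified")

    # -- starting values ---------------------------------------------------
    def start_params(self) -> np.ndarray:
        i, r = self.exog, self.endog
        order = np.argsort(i)
        i_s, r_s = i[order], r[order]
        low = slice(0, 3)
        di = i_s[low][-1] - i_s[low][0]
        alpha0 = (r_s[low][-1] - r_s[low][0]) / di if di > 0 else 0.0
        if alpha0 <= 0:
            alpha0 = max(r_s.max() / max(i_s[i_s > 0].min(), 1.0), 1e-6)
        ps0 = float(r_s.max())
        # photoinhibition start: log-decline from the peak to the brightest flask
        k = int(np.argmax(r_s))
        beta0 = 0.0
        if k < len(i_s) - 1 and r_s[-1] > 0 and r_s[k] > r_s[-1]:
            beta0 = ps0 * math.log(r_s[k] / r_s[-1]) / (i_s[-1] - i_s[k])
        return np.array([max(ps0, 1e-9), alpha0, max(beta0, 0.0)])

    def fit(self, n_restarts: int = 5, seed: int = 0) -> "PlattResults":
        p0 = self.start_params()
        rng = np.random.default_rng(seed)
        bounds = ([1e-12, 1e-12, 0.0], [np.inf, np.inf, np.inf])
        attempt_starts = [p0] + [
            p0 * rng.lognormal(0.0, 0.3, size=3) for _ in range(n_restarts)]
        best = None
        for start in attempt_starts:
            start = np.clip(start, bounds[0], None)
            try:
                popt, pcov = optimize.curve_fit(
                    _platt, self.exog, self.endog, p0=start, bounds=bounds,
                    maxfev=20000)
            except RuntimeError:
                continue
            resid = self.endog - _platt(self.exog, *popt)
            ssr = float(resid @ resid)
            if best is None or ssr < best[2]:
                best = (popt, pcov, ssr)
        if best is None:
            raise RuntimeError(
                "Platt fit failed to converge after restarts; check that the "
                "dataset spans light limitation and saturation")
        popt, pcov, ssr = best
        dof = max(len(self.endog) - 3, 1)
        resid_se = math.sqrt(ssr / dof)
        bse = np.sqrt(np.clip(np.diag(pcov), 0.0, None))
        curve = PICurve(p_s=float(popt[0]), alpha=float(popt[1]),
                        beta=float(popt[2]), units=self.data.units)
        return PlattResults(model=self, curve=curve, bse=bse,
                            resid_se=resid_se, ssr=ssr, converged=True)


@dataclass
class PlattResults:
    """Fitted Platt curve with uncertainties and derived light indices."""

    model: PlattModel
    curve: PICurve
    bse: np.ndarray
    resid_se: float
    ssr: float
    converged: bool

    @property
    def params(self) -> np.ndarray:
        return np.array([self.curve.p_s, self.curve.alpha, self.curve.beta])

    def predict(self, irradiance):
        return platt_p(self.curve, irradiance)

    @property
    def resid(self) -> np.ndarray:
        return self.model.endog - self.predict(self.model.exog)

    def indices(self) -> dict:
        return derived_indices(self.curve)

    def summary(self) -> str:
        names = ["Ps", "alpha", "beta"]
        idx = self.indices()
        lines = [
            f"Platt P-I fit ({self.curve.units}), "
            f"n = {len(self.model.endog)}",
            f"{'param':<8}{'estimate':>12}{'std err':>12}",
        ]
        for name, est, se in zip(names, self.params, self.bse):
            lines.append(f"{name:<8}{est:>12.4g}{se:>12.4g}")
        lines += [
            f"residual SE {self.resid_se:.4g}",
            f"Ik = {idx['ik']:.4g}  Im = {idx['i_m']:.4g}  "
            f"realized Pmax = {idx['p_max_realized']:.4g}  "
            f"half-saturation = {idx['half_saturation']:.4g}",
        ]
        return "\n".join(lines)


def fit_platt(data: PIDataset, subtract_dark: bool = False,
              n_restarts: int = 5, seed: int = 0) -> PlattResults:
    """Convenience wrapper around :class:`PlattModel`."""
    return PlattModel(data, subtract_dark=subtract_dark).fit(
        n_restarts=n_restarts, seed=seed)


def derived_indices(curve: PICurve) -> dict:
    """Light indices of a fitted curve.

    ik = Ps/alpha (light-saturation parameter); i_m the irradiance of the
    realized maximum, (Ps/alpha) ln((alpha+beta)/beta) (unbounded when
    beta = 0); p_max_realized the closed-form maximum
    Ps (alpha/(alpha+beta)) (beta/(alpha+beta))^(beta/alpha); and the
    half-saturation irradiance, the root of P(I) = p_max_realized/2 on
    [0, i_m] found by bisection (for beta = 0 the closed form
    Ps ln 2 / alpha).
    """
    ps, a, b = curve.p_s, curve.alpha, curve.beta
    ik = ps / a
    if b == 0:
        return {
            "ik": ik,
            "i_m": math.inf,
            "p_max_realized": ps,
            "half_saturation": ps * math.log(2.0) / a,
        }
    i_m = ik * math.log((a + b) / b)
    p_max = ps * (a / (a + b)) * (b / (a + b)) ** (b / a)
    half = optimize.brentq(
        lambda i: platt_p(curve, i) - p_max / 2.0, 0.0, i_m, xtol=1e-10)
    return {"ik": ik, "i_m": i_m, "p_max_realized": p_max,
            "half_saturation": float(half)}
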