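"""Underwater PAR attenuation and the time-resolved light field.

The light climate of a turbid lake is summarised by a single diffuse
attenuation coefficient Kd (m-1), estimated by log-linear regression of a
discrete PAR-depth profile, and a Beer–Lambert light field

    I(z, t) = I(z_ref, t) * exp(-Kd * (z - z_ref))

anchored to a continuously logged PAR series at a fixed reference depth
(a sensor just below the surface, 0.3 m by default). The model/results split
follows the statsmodels convention: :class:`AttenuationModel` holds the
profile data, ``fit()`` returns a :class:`LightField` carrying the estimate,
its standard error and the evaluation methods.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

from .constants import DEFAULT_LIGHT_THRESHOLD, DEFAULT_REFERENCE_DEPTH

__all__ = [
    "ParProfile",
    "ParSeries",
    "AttenuationModel",
    "LightField",
    "fit_kd",
    "photic_depth",
]


@dataclass(frozen=True)
class ParProfile:
    """A discrete PAR-depth profile (depths m, irradiance umol m-2 s-1)."""

    depths: np.ndarray
    irradiance: np.ndarray

    def __post_init__(self):
        z = np.asarray(self.depths, dtype=float)
        i = np.asarray(self.irradiance, dtype=float)
        object.__setattr__(self, "depths", z)
        object.__setattr__(self, "irradiance", i)
        if z.shape != i.shape or z.ndim != 1:
            raise ValueError("depths and irradiance must be 1-d and same length")
        if len(z) < 3:
            raise ValueError("need at least 3 points to fit an attenuation slope")
        if np.any(np.diff(z) <= 0):
            raise ValueError("depths must be strictly increasing")
        if np.any(z < 0):
            raise ValueError("depths must be non-negative")


@dataclass(frozen=True)
class ParSeries:
    """A PAR time series at a fixed reference depth.

    ``times`` are hours of the local day (fractional); irradiance in
    umol photons m-2 s-1.
    """

    times: np.ndarray
    irradiance: np.ndarray
    reference_depth: float = DEFAULT_REFERENCE_DEPTH

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        i = np.asarray(self.irradiance, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "irradiance", i)
        if t.shape != i.shape or t.ndim != 1:
            raise ValueError("times and irradiance must be 1-d and same length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if np.any(i < 0):
            raise ValueError("irradiance must be non-negative")

    def daylight_window(self, threshold: float = DEFAULT_LIGHT_THRESHOLD
                        ) -> tuple[float, float]:
        """(dawn, dusk): first and last times the series exceeds ``threshold``."""
        above = np.nonzero(self.irradiance > threshold)[0]
        if len(above) == 0:
            raise ValueError("series never exceeds the light threshold")
        return float(self.times[above[0]]), float(self.times[above[-1]])


class AttenuationModel:
    """Log-linear Beer–Lambert attenuation model for a PAR-depth profile.

    ln I(z) = ln I0 - Kd * z, estimated by ordinary least squares.
    """

    def __init__(self, profile: ParProfile):
        if np.any(profile.irradiance <= 0):
            raise ValueError("log-regression needs strictly positive irradiance")
        self.profile = profile

    def fit(self, series: ParSeries | None = None) -> "LightField":
        """OLS fit; attach ``series`` to make the result a full light field."""
        z = self.profile.depths
        y = np.log(self.profile.irradiance)
        res = sm.OLS(y, sm.add_constant(z)).fit()
        kd = -res.params[1]
        kd_se = res.bse[1]
        if not kd > 0:
            raise ValueError(
                f"fitted attenuation coefficient {kd:.3g} m-1 is not positive "
                "(profile does not attenuate)")
        return LightField(kd=float(kd), kd_se=float(kd_se), series=series,
                          surface_irradiance=float(np.exp(res.params[0])),
                          rsquared=float(res.rsquared))


@dataclass
class LightField:
    """A fitted attenuation coefficient plus (optionally) a reference series.

    ``irradiance_at`` answers I(z, t) queries by linear interpolation of the
    reference series in time and Beer–Lambert scaling in depth.
    """

    kd: float
    kd_se: float = 0.0
    series: ParSeries | None = None
    surface_irradiance: float = field(default=float("nan"))
    rsquared: float = field(default=float("nan"))

    def __post_init__(self):
        if not self.kd > 0:
            raise ValueError("kd must be positive")

    def photic_depth(self, fraction: float = 0.01) -> float:
        """Depth where irradiance falls to ``fraction`` of its subsurface value."""
        return photic_depth(self.kd, fraction)

    def irradiance_at(self, depth, time):
        """I(z, t) in umol photons m-2 s-1.

        ``time`` must lie within the span of the reference series (no
        extrapolation). Depths above the reference sensor extrapolate upward
        with the same Kd.
        """
        if self.series is None:
            raise ValueError("light field has no reference PAR series attached")
        z = np.asarray(depth, dtype=float)
        t = np.asarray(time, dtype=float)
        if np.any(z < 0):
            raise ValueError("depth must be non-negative")
        t0, t1 = self.series.times[0], self.series.times[-1]
        if np.any(t < t0) or np.any(t > t1):
            raise ValueError(
                f"time outside the reference-series span [{t0}, {t1}]")
        i_ref = np.interp(t, self.series.times, self.series.irradiance)
        out = i_ref * np.exp(-self.kd * (z - self.series.reference_depth))
        return out if np.ndim(out) else float(out)

    def summary(self) -> str:
        lines = [
            "Beer-Lambert attenuation fit",
            f"  Kd            {self.kd:.3f} m-1 (SE {self.kd_se:.3f})",
            f"  1% PAR depth  {self.photic_depth(0.01):.3f} m",
        ]
        if np.isfinite(self.rsquared):
            lines.append(f"  R-squared     {self.rsquared:.4f}")
        if self.series is not None:
            lines.append(f"  reference depth {self.series.reference_depth} m, "
                         f"{len(self.series.times)} samples")
        return "\n".join(lines)


def fit_kd(profile: ParProfile) -> tuple[float, float]:
    """Convenience wrapper: (Kd, standard error) from a discrete profile."""
    f = AttenuationModel(profile).fit()
    return f.kd, f.kd_se


def photic_depth(kd: float, fraction: float) -> float:
    """Depth at which PAR is reduced to ``fraction`` of the subsurface value."""
    if not kd > 0:
        raise ValueError("kd must be positive")
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    return -np.log(fraction) / kd
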