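"""Synthetic-data generators with known ground truth.

Every input the analysis pipeline consumes can be generated here, so that
each estimation stage has a forward model to invert against:

* a smooth half-sine diel PAR series at the reference depth (tropical day
  length, configurable noise);
* exponentially attenuated PAR-depth profiles with multiplicative
  log-normal noise;
* a diel O2 record produced by forward-Euler integration of the mixed-layer
  budget dO2/dt = (GPP(t) - R)/z_mix - F/z_mix, with GPP(t) distributed
  proportionally to instantaneous PAR (so the metabolism inversion test does
  not depend on the P-I module), R constant and F the same gas-flux
  operation the inversion uses;
* P-I rate datasets drawn from the Platt curve with additive Gaussian noise;
* multi-lake ion tables with planted cluster structure and an EcoPlate OD
  matrix constructed to hit prescribed class-utilisation percentages.

All generators are deterministic under a fixed seed. Default parameters
mirror the study conditions: Kd = 6.79 m-1, chl a = 612 ug L-1, P-I
parameters (Ps, alpha, beta) = (271, 3.31, 0.109) in umol O2 mg chl-1 h-1,
daily GPP/R near 20/18 g O2 m-2 d-1, 5-min O2 sampling, ~12-h tropical day.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .community import BLANK_SUBSTRATE, ecoplate_class_map
from .conversions import absorbance_for_chla, o2_saturation_concentration
from .light import ParProfile, ParSeries
from .metabolism import GasExchangeSpec, O2DielSeries, gas_flux
from .pe_curves import PICurve, PIDataset, platt_p

__all__ = [
    "SimulationSpec",
    "DEFAULT_PI_TRUTH",
    "gen_diel_par",
    "gen_par_profile",
    "gen_o2_diel",
    "gen_pi_dataset",
    "gen_incubation_table",
    "gen_ion_table",
    "gen_ecoplate",
    "gen_chla_readings",
    "gen_fixtures",
]

#: P-I truth used throughout: the study's mean PSOE parameters.
DEFAULT_PI_TRUTH = PICurve(p_s=271.0, alpha=3.31, beta=0.109)


@dataclass(frozen=True)
class SimulationSpec:
    """Study conditions for the synthetic generators.

    PAR is the series at the reference sensor depth (0.3 m); ``par_max`` is
    its noon value, ~260 umol photons m-2 s-1 (a ~2000 umol surface noon
    attenuated by exp(-0.3*Kd) at Kd = 6.79). GPP/R magnitudes bracket the
    free-water estimates of a dense tropical cyanobacterial lake.
    """

    seed: int = 0
    day_length: float = 12.0     # h
    par_max: float = 260.0       # umol photons m-2 s-1 at the reference depth
    kd: float = 6.79             # m-1
    chla: float = 612.0          # ug L-1
    gpp_true: float = 20.0       # g O2 m-2 d-1
    resp_true: float = 18.0      # g O2 m-2 d-1
    k600: float = 0.5            # m d-1
    z_mix: float = 1.0           # m
    temperature: float = 31.0    # degC
    salinity: float = 52.0       # psu
    dt_min: float = 5.0          # native O2 logger step, minutes
    par_noise_cv: float = 0.0    # log-normal CV on PAR
    o2_noise_sd: float = 0.0     # mg L-1 Gaussian sensor noise
    reference_depth: float = 0.3

    def __post_init__(self):
        if self.day_length <= 0 or self.day_length > 24:
            raise ValueError("day_length must be in (0, 24] h")
        for name in ("par_max", "kd", "chla", "gpp_true", "resp_true",
                     "k600", "z_mix", "dt_min"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def dawn(self) -> float:
        return (24.0 - self.day_length) / 2.0

    @property
    def dusk(self) -> float:
        return self.dawn + self.day_length

    def rng(self, stream: int = 0) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


def _half_sine(times: np.ndarray, spec: SimulationSpec) -> np.ndarray:
    """Half-sine irradiance over [dawn, dusk], zero at night."""
    tod = np.mod(times, 24.0)
    phase = (tod - spec.dawn) / spec.day_length
    par = spec.par_max * np.sin(np.pi * np.clip(phase, 0.0, 1.0))
    return np.where((phase > 0) & (phase < 1), par, 0.0)


def gen_diel_par(spec: SimulationSpec, n_hours: float = 24.0) -> ParSeries:
    """A diel PAR series at the reference depth (half-sine day).

    Optional multiplicative log-normal noise with CV ``par_noise_cv``.
    """
    dt = spec.dt_min / 60.0
    times = np.arange(0.0, n_hours + dt / 2, dt)
    par = _half_sine(times, spec)
    if spec.par_noise_cv > 0:
        sigma = np.sqrt(np.log(1.0 + spec.par_noise_cv**2))
        par = par * spec.rng(1).lognormal(-sigma**2 / 2, sigma, size=par.shape)
    return ParSeries(times=times, irradiance=par,
                     reference_depth=spec.reference_depth)


def gen_par_profile(spec: SimulationSpec, surface_par: float = 1000.0,
                    depths: np.ndarray | None = None,
                    noise_cv: float = 0.0) -> ParProfile:
    """An attenuated PAR-depth profile, optionally with log-normal noise."""
    z = np.asarray(depths if depths is not None
                   else np.linspace(0.1, 1.0, 10), dtype=float)
    par = surface_par * np.exp(-spec.kd * z)
    if noise_cv > 0:
        sigma = np.sqrt(np.log(1.0 + noise_cv**2))
        par = par * spec.rng(2).lognormal(-sigma**2 / 2, sigma, size=par.shape)
    return ParProfile(depths=z, irradiance=par)


def gen_o2_diel(spec: SimulationSpec, n_hours: float = 24.0
                ) -> tuple[O2DielSeries, dict]:
    """Forward-model a diel O2 record; return it with its truth record.

    Forward Euler at the native logger step: the O2 increment over each
    interval is ((GPP(t) - R) - F)/z_mix * dt with GPP(t) proportional to
    the instantaneous half-sine PAR (integrating to ``gpp_true`` per day), R
    constant and F the package's own gas-flux operation evaluated at the
    interval's left endpoint. The series starts at air saturation.
    """
    gas = GasExchangeSpec(model="constant_k600", k600=spec.k600)
    dt_d = spec.dt_min / 60.0 / 24.0
    if spec.z_mix <= 0:
        raise ValueError("z_mix must be positive")
    k = gas.piston_velocity(spec.temperature, spec.salinity)
    if k * dt_d / spec.z_mix > 0.5:
        raise ValueError("time step too large for k600/z_mix: Euler unstable")
    dt_h = spec.dt_min / 60.0
    times = np.arange(0.0, n_hours + dt_h / 2, dt_h)
    par = _half_sine(times, spec)
    # distribute the daily GPP total proportionally to instantaneous PAR;
    # the half-sine integrates to (2/pi)*par_max*(day_length/24) in day units
    gpp_rate = (spec.gpp_true * par / ((2.0 / np.pi) * spec.par_max
                                       * (spec.day_length / 24.0))
                if spec.par_max > 0 else par * 0.0)
    o2 = np.empty_like(times)
    o2[0] = o2_saturation_concentration(spec.temperature, spec.salinity)
    for n in range(len(times) - 1):
        f = gas_flux(o2[n], spec.temperature, spec.salinity, gas)
        o2[n + 1] = o2[n] + ((gpp_rate[n] - spec.resp_true) - f) / spec.z_mix * dt_d
    if spec.o2_noise_sd > 0:
        o2 = o2 + spec.rng(3).normal(0.0, spec.o2_noise_sd, size=o2.shape)
        o2 = np.clip(o2, 0.0, None)
    series = O2DielSeries(times=times, o2=o2, temperature=spec.temperature,
                          salinity=spec.salinity,
                          mixed_layer_depth=spec.z_mix)
    truth = {"gpp": spec.gpp_true, "resp": spec.resp_true,
             "nep": spec.gpp_true - spec.resp_true, "k600": spec.k600,
             "dawn": spec.dawn, "dusk": spec.dusk}
    return series, truth


def gen_pi_dataset(truth: PICurve = DEFAULT_PI_TRUTH,
                   irradiances: np.ndarray | None = None,
                   noise_sd: float = 0.0, seed: int = 0) -> PIDataset:
    """Rates on the Platt curve at given irradiances plus Gaussian noise."""
    i = np.asarray(irradiances if irradiances is not None
                   else np.linspace(0.0, 1100.0, 12), dtype=float)
    rng = np.random.default_rng([seed, 4])
    rates = platt_p(truth, i)
    if noise_sd > 0:
        rates = rates + rng.normal(0.0, noise_sd, size=i.shape)
    return PIDataset(irradiances=i, rates=rates, units=truth.units)


def gen_incubation_table(chla: float = 612.0, slopes_mg_l_h=(0.5, 0.3, 0.1),
                         irradiances=(800.0, 200.0, 50.0),
                         duration_h: float = 4.0, dt_h: float = 1.0 / 3.0,
                         noise_sd: float = 0.0, seed: int = 0) -> pd.DataFrame:
    """Flask O2-vs-time series with known linear slopes (mg O2 L-1 h-1)."""
    rng = np.random.default_rng([seed, 5])
    times = np.arange(0.0, duration_h + dt_h / 2, dt_h)
    rows = []
    for fid, (slope, irr) in enumerate(zip(slopes_mg_l_h, irradiances), 1):
        o2 = 5.0 + slope * times
        if noise_sd > 0:
            o2 = o2 + rng.normal(0.0, noise_sd, size=times.shape)
        for t, c in zip(times, o2):
            rows.append({"flask_id": fid, "time_h": t, "o2_mg_l": c,
                         "par_umol_m2_s": irr, "chla_ug_l": chla})
    return pd.DataFrame(rows)


#: cluster centres for the planted ion-table design: a seawater-like brine,
#: a soda-lake water and a dilute athalassohaline lake (mg L-1)
_ION_CENTERS = {
    "brine": (22000.0, 1300.0, 100.0, 2.0, 250.0, 27500.0, 14000.0),
    "soda": (5000.0, 300.0, 10.0, 5.0, 2000.0, 1500.0, 9000.0),
    "dilute": (500.0, 50.0, 30.0, 40.0, 150.0, 600.0, 400.0),
}


def gen_ion_table(n_per_cluster: int = 5, spread: float = 0.02,
                  seed: int = 0) -> pd.DataFrame:
    """Multi-lake ion table with three planted clusters.

    Cluster centres are separated by far more than ten times the
    within-cluster spread (``spread`` is a relative SD), so a flat cut at
    k = 3 must recover the planting exactly. The true assignment is in the
    ``planted`` column (drop it before clustering).
    """
    rng = np.random.default_rng([seed, 6])
    rows = []
    from .community import ION_VARIABLES
    for name, center in _ION_CENTERS.items():
        for i in range(n_per_cluster):
            jitter = rng.normal(1.0, spread, size=len(center))
            vals = np.abs(np.asarray(center) * jitter)
            row = {"label": f"{name}-{i+1}", "planted": name}
            row.update(dict(zip(ION_VARIABLES, vals)))
            rows.append(row)
    return pd.DataFrame(rows).set_index("label")


def gen_ecoplate(class_percent: dict | None = None, awcd_value: float = 0.482,
                 blank_od: float = 0.05, n_replicates: int = 3,
                 time_h: float = 96.0) -> pd.DataFrame:
    """An EcoPlate OD table constructed to hit given class percentages.

    Within each chemical class the prescribed share of the plate total
    (31 * ``awcd_value``) is spread evenly over the class's wells; the blank
    OD is added back so that blank correction recovers the construction.
    Defaults reproduce an oxic-layer profile dominated by carbohydrates and
    amino acids.
    """
    class_percent = class_percent or {
        "amines": 1.1, "amino acids": 26.5, "carbohydrates": 47.6,
        "carboxylic acids": 15.2, "phenolic compounds": 0.4, "polymers": 9.2}
    total = abs(sum(class_percent.values()) - 100.0)
    if total > 0.5:
        raise ValueError("class percentages must sum to 100")
    cmap = ecoplate_class_map()
    total_od = 31.0 * awcd_value
    rows = []
    for rep in range(1, n_replicates + 1):
        for substrate, cls in cmap.items():
            n_class = int((cmap == cls).sum())
            corrected = class_percent.get(cls, 0.0) / 100.0 * total_od / n_class
            rows.append({"replicate": rep, "substrate": substrate,
                         "time_h": time_h, "od590": corrected + blank_od})
        rows.append({"replicate": rep, "substrate": BLANK_SUBSTRATE,
                     "time_h": time_h, "od590": blank_od})
    return pd.DataFrame(rows)


def gen_chla_readings(in_lake_ug_l=(612.0, 524.0, 875.0),
                      extract_volume: float = 3.0,
                      filtered_volume: float = 5.0) -> pd.DataFrame:
    """Absorbance pairs whose chlorophyll works back to given lake values."""
    rows = []
    for c in in_lake_ug_l:
        diff = absorbance_for_chla(c, extract_volume, filtered_volume)
        rows.append({"a665": diff + 0.02, "a750": 0.02,
                     "extract_volume_ml": extract_volume,
                     "filtered_volume_ml": filtered_volume,
                     "expected_ug_l": c})
    return pd.DataFrame(rows)


def gen_fixtures(outdir: str | Path, seed: int = 0) -> dict[str, Path]:
    """Write the bundled small CSV fixtures; returns name -> path.

    Deterministic under ``seed``: PAR profile (noiseless, Kd = 6.79), diel
    PAR series, ion table with three planted clusters, EcoPlate matrix and
    chl-a absorbance readings.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spec = SimulationSpec(seed=seed)
    paths = {}

    profile = gen_par_profile(spec)
    paths["par_profile"] = outdir / "par_profile.csv"
    pd.DataFrame({"depth_m": profile.depths,
                  "par_umol_m2_s": profile.irradiance}
                 ).to_csv(paths["par_profile"], index=False)

    series = gen_diel_par(spec)
    paths["par_series"] = outdir / "par_series.csv"
    pd.DataFrame({"time_h": series.times,
                  "par_umol_m2_s": series.irradiance}
                 ).to_csv(paths["par_series"], index=False)

    paths["ion_table"] = outdir / "ion_table.csv"
    gen_ion_table(seed=seed).to_csv(paths["ion_table"])

    paths["ecoplate"] = outdir / "ecoplate.csv"
    gen_ecoplate().to_csv(paths["ecoplate"], index=False)

    paths["chla_readings"] = outdir / "chla_readings.csv"
    gen_chla_readings().to_csv(paths["chla_readings"], index=False)
    return paths
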