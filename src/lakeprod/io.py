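"""CSV readers/writers and run configuration.

All file formats are plain comma-separated text with a header row, UTF-8,
decimal point, times either as fractional hours of the local day or as
ISO-8601 timestamps (converted to hours since the first record's midnight;
no timezone arithmetic). Readers sort by time and reject duplicate
timestamps by name.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .community import EcoplatePlate
from .conversions import percent_saturation_to_concentration
from .light import ParProfile, ParSeries
from .metabolism import O2DielSeries
from .pe_curves import IncubationSeries, PIDataset

__all__ = [
    "read_timeseries",
    "read_par_profile",
    "read_par_series",
    "read_o2_series",
    "read_pi_dataset",
    "read_incubations",
    "read_water_samples",
    "read_ecoplate",
    "RunConfig",
]


def _times_to_hours(values: pd.Series) -> np.ndarray:
    """Fractional hours of the local day from numeric or ISO-8601 input."""
    if pd.api.types.is_numeric_dtype(values):
        return values.to_numpy(dtype=float)
    ts = pd.to_datetime(values, format="ISO8601")
    origin = ts.iloc[0].normalize()
    return ((ts - origin).dt.total_seconds() / 3600.0).to_numpy()


def read_timeseries(path: str | Path, column_map: dict[str, str]
                    ) -> pd.DataFrame:
    """Read a time-stamped CSV into a frame with parsed, sorted time.

    ``column_map`` maps semantic names to file columns and must contain
    ``"time"``; the returned frame has a float ``time_h`` column plus the
    other mapped columns under their semantic names. Duplicate timestamps
    raise with the offending timestamp named.
    """
    if "time" not in column_map:
        raise ValueError("column_map must map 'time'")
    df = pd.read_csv(path)
    missing = set(column_map.values()) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    out = pd.DataFrame({name: df[col] for name, col in column_map.items()})
    raw_time = out.pop("time")
    out.insert(0, "time_h", _times_to_hours(raw_time))
    out = out.sort_values("time_h", kind="stable").reset_index(drop=True)
    dup = out["time_h"].duplicated()
    if dup.any():
        t_bad = out.loc[dup.idxmax(), "time_h"]
        raise ValueError(f"{path}: duplicated timestamp at t = {t_bad} h")
    return out


def read_par_profile(path: str | Path) -> ParProfile:
    """Profile CSV with columns depth_m, par_umol_m2_s."""
    df = pd.read_csv(path).sort_values("depth_m")
    return ParProfile(depths=df["depth_m"].to_numpy(float),
                      irradiance=df["par_umol_m2_s"].to_numpy(float))


def read_par_series(path: str | Path, reference_depth: float = 0.3,
                    time_col: str = "time_h",
                    par_col: str = "par_umol_m2_s") -> ParSeries:
    df = read_timeseries(path, {"time": time_col, "par": par_col})
    return ParSeries(times=df["time_h"].to_numpy(),
                     irradiance=df["par"].to_numpy(),
                     reference_depth=reference_depth)


def read_o2_series(path: str | Path, mixed_layer_depth: float,
                   o2_col: str = "o2_mg_l", o2_units: str = "mg_l",
                   time_col: str = "time_h", temp_col: str = "temp_c",
                   sal_col: str = "sal_psu",
                   sensor_depth: float = 0.15) -> O2DielSeries:
    """Logger CSV -> diel series; ``o2_units`` is ``"mg_l"`` or ``"pct_sat"``.

    Percent-saturation input is converted to mg L-1 through the solubility
    fit at the per-sample temperature and salinity.
    """
    df = read_timeseries(path, {"time": time_col, "o2": o2_col,
                                "temp": temp_col, "sal": sal_col})
    o2 = df["o2"].to_numpy(float)
    temp = df["temp"].to_numpy(float)
    sal = df["sal"].to_numpy(float)
    if o2_units == "pct_sat":
        o2 = percent_saturation_to_concentration(o2, temp, sal)
    elif o2_units != "mg_l":
        raise ValueError(f"unknown o2 units {o2_units!r}")
    return O2DielSeries(times=df["time_h"].to_numpy(), o2=o2,
                        temperature=temp, salinity=sal,
                        mixed_layer_depth=mixed_layer_depth,
                        sensor_depth=sensor_depth)


def read_pi_dataset(path: str | Path) -> PIDataset:
    """Rate-vs-irradiance CSV with columns par_umol_m2_s, rate (any tag)."""
    df = pd.read_csv(path)
    dark = 0.0
    if "dark_rate" in df.columns:
        dark = float(df["dark_rate"].iloc[0])
    return PIDataset(irradiances=df["par_umol_m2_s"].to_numpy(float),
                     rates=df["rate"].to_numpy(float), dark_rate=dark)


def read_incubations(path: str | Path) -> list[IncubationSeries]:
    """Flask CSV (flask_id, time_h, o2_mg_l, par_umol_m2_s, chla_ug_l)."""
    df = pd.read_csv(path)
    out = []
    for _, grp in df.groupby("flask_id"):
        grp = grp.sort_values("time_h")
        out.append(IncubationSeries(
            times=grp["time_h"].to_numpy(float),
            o2_conc=grp["o2_mg_l"].to_numpy(float),
            irradiance=float(grp["par_umol_m2_s"].iloc[0]),
            chla=float(grp["chla_ug_l"].iloc[0])))
    return out


def read_water_samples(path: str | Path) -> pd.DataFrame:
    """Ion-composition CSV (label + the 7 chemistry columns)."""
    df = pd.read_csv(path)
    label_col = "label" if "label" in df.columns else df.columns[0]
    return df.set_index(label_col)


def read_ecoplate(path: str | Path) -> EcoplatePlate:
    """EcoPlate CSV (replicate, substrate, time_h, od590)."""
    return EcoplatePlate(readings=pd.read_csv(path))


@dataclass
class RunConfig:
    """Validated configuration of an end-to-end synthetic pipeline run.

    Physically meaningful parameters that the analysis cannot default —
    the respiration integration depth of the bottle route and the mixed-layer
    depth of the free-water route — are required and checked up front.
    """

    resp_depth: float = None            # m; required, no silent default
    z_mix: float = None                 # m; required, no silent default
    seed: int = 0
    outdir: str = "results"
    z_max: float = 1.5
    dz: float = 0.1
    dt_min: float = 10.0
    light_threshold: float = 1.0
    chla: float = 612.0
    kd: float = 6.79
    p_s: float = 271.0
    alpha: float = 3.31
    beta: float = 0.109
    resp_volumetric: float = 0.6        # mg O2 L-1 h-1, dark incubation
    k600: float = 0.5
    gpp_true: float = 20.0
    resp_true: float = 18.0
    verbosity: int = 1

    def __post_init__(self):
        if self.resp_depth is None:
            raise ValueError(
                "resp_depth is required: the depth over which the volumetric "
                "dark respiration is integrated has no defensible default")
        if self.z_mix is None:
            raise ValueError("z_mix (mixed-layer depth) is required")
        if self.resp_depth <= 0 or self.z_mix <= 0:
            raise ValueError("resp_depth and z_mix must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dc_fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)
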