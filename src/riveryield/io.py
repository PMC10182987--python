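"""CSV schemas and readers/writers shared by the pipeline commands."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .load_estimation import CFS_TO_M3S, StationLoad

UNITS_COLUMNS = ["unit_id", "tohuc_id", "area_km2", "closed_basin"]
CORRECTIONS_COLUMNS = ["unit_id", "corrected_tohuc_id", "note"]
STATIONS_COLUMNS = ["station_id", "unit_id", "reported_area_km2"]
OBSERVATIONS_COLUMNS = [
    "station_id",
    "date",
    "flow",
    "flow_unit",
    "concentration",
    "constituent",
]

#: station-load record schema (mirrors the shared-dataset field names)
STATION_LOAD_COLUMNS = [
    "Station ID",
    "Constituent",
    "NHDplus derived drainage area",
    "USGS reported drainage area",
    "Drainage area data source flag",
    "Carbon load",
    "Number of observations",
    "Data period",
    "Regression model",
    "R-square(%)",
    "Exclusion reason",
]


def read_units(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"unit_id": str, "tohuc_id": str})
    missing = set(UNITS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"units file {path} missing columns {sorted(missing)}")
    return df


def read_corrections(path: str | Path | None) -> pd.DataFrame | None:
    if path is None or not Path(path).exists():
        return None
    return pd.read_csv(path, dtype={"unit_id": str, "corrected_tohuc_id": str})


def read_stations(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"station_id": str, "unit_id": str})
    missing = {"station_id", "unit_id"} - set(df.columns)
    if missing:
        raise ValueError(f"stations file {path} missing columns {sorted(missing)}")
    if "reported_area_km2" not in df.columns:
        df["reported_area_km2"] = np.nan
    return df


def read_observations(path: str | Path, flow_unit_default: str = "m3s") -> pd.DataFrame:
    """Long observation table; converts flows to m3 s-1 when flagged cfs."""
    df = pd.read_csv(path, dtype={"station_id": str, "constituent": str})
    missing = {"station_id", "date", "flow"} - set(df.columns)
    if missing:
        raise ValueError(f"observations file {path} missing columns {sorted(missing)}")
    df["date"] = pd.to_datetime(df["date"])
    if "flow_unit" not in df.columns:
        df["flow_unit"] = flow_unit_default
    df["flow_unit"] = df["flow_unit"].fillna(flow_unit_default)
    is_cfs = df["flow_unit"].str.lower().isin({"cfs", "ft3s"})
    df.loc[is_cfs, "flow"] = df.loc[is_cfs, "flow"] * CFS_TO_M3S
    df.loc[is_cfs, "flow_unit"] = "m3s"
    if "constituent" not in df.columns:
        df["constituent"] = ""
    df["constituent"] = df["constituent"].fillna("")
    return df


def split_observations(
    obs: pd.DataFrame,
) -> tuple[dict[str, pd.DataFrame], dict[tuple[str, str], pd.DataFrame]]:
    """Split the long table into per-station flow and per-(station,
    constituent) concentration series."""
    flows: dict[str, pd.DataFrame] = {}
    concs: dict[tuple[str, str], pd.DataFrame] = {}
    for sid, grp in obs.groupby("station_id"):
        flow = (
            grp[["date", "flow"]]
            .dropna(subset=["flow"])
            .drop_duplicates(subset="date")
            .sort_values("date")
            .reset_index(drop=True)
        )
        flows[str(sid)] = flow
        with_conc = grp.dropna(subset=["concentration"])
        for constituent, cgrp in with_conc.groupby("constituent"):
            if constituent == "":
                continue
            concs[(str(sid), str(constituent))] = (
                cgrp[["date", "concentration"]].sort_values("date").reset_index(drop=True)
            )
    return flows, concs


def station_loads_frame(
    loads: list[StationLoad],
    derived_areas: dict[str, float],
    reported_areas: dict[str, float],
) -> pd.DataFrame:
    rows = []
    for sl in loads:
        reported = reported_areas.get(sl.station_id, np.nan)
        rows.append(
            {
                "Station ID": sl.station_id,
                "Constituent": sl.constituent,
                "NHDplus derived drainage area": derived_areas.get(sl.station_id, np.nan),
                "USGS reported drainage area": reported,
                "Drainage area data source flag": 0 if pd.isna(reported) else 1,
                "Carbon load": sl.mean_daily_load,
                "Number of observations": sl.n_obs,
                "Data period": ""
                if sl.excluded
                else f"{sl.period_start}-{sl.period_end}",
                "Regression model": sl.model_id,
                "R-square(%)": sl.r_square_pct,
                "Exclusion reason": sl.exclusion_reason,
            }
        )
    return pd.DataFrame(rows, columns=STATION_LOAD_COLUMNS)


def write_csv(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path
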