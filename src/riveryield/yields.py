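"""Inter-station net carbon yield.

The yield of the region controlled between a station and its immediate
upstream stations is the incremental load divided by the incremental
drainage area,

    Y = (F_down - sum F_up) / (A_down - sum A_up)   [kgC km-2 yr-1],

with Y = F/A for a station with no gauge upstream. Negative yields are
legitimate: the incremental area removed more carbon (burial, outgassing)
than it contributed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .leveling import NO_DATA, RegionAssignment, downstream_station_path
from .network import NetworkGraph

STATUS_OK = "ok"
STATUS_INVALID_AREA = "non-positive incremental area"
STATUS_INCOMPLETE = "incomplete"


@dataclass
class RegionYield:
    region_id: str  # downstream station id
    level: int
    f_down: float  # kgC yr-1
    f_up_sum: float
    a_down: float  # km2
    a_up_sum: float
    yield_value: float  # kgC km-2 yr-1; nan when invalid
    status: str = STATUS_OK
    member_units: set[str] = field(default_factory=set)

    @property
    def incremental_area(self) -> float:
        return self.a_down - self.a_up_sum


def immediate_upstream_stations(
    graph: NetworkGraph, stations: pd.DataFrame, station_id: str
) -> set[str]:
    """Stations whose first downstream station is ``station_id``."""
    row = stations.loc[stations["station_id"] == station_id]
    if row.empty:
        raise KeyError(f"unknown station {station_id!r}")
    out: set[str] = set()
    for other in stations.itertuples(index=False):
        sid = str(other.station_id)
        if sid == station_id:
            continue
        path = downstream_station_path(graph, stations, str(other.unit_id))
        # path[0] is the station itself; path[1] its nearest downstream gauge
        if len(path) >= 2 and path[1] == station_id:
            out.add(sid)
    return out


def compute_region_yield(
    station_id: str,
    loads: dict[str, float],
    areas: dict[str, float],
    upstream_stations: set[str],
    level: int = 0,
) -> RegionYield:
    """Yield of the region drained by ``station_id`` net of its upstream gauges.

    ``loads`` are annual loads in kgC yr-1, ``areas`` drainage areas in km2.
    Missing upstream loads flag the region ``incomplete``; a non-positive
    incremental area flags it invalid. Neither emits a yield value.
    """
    f_down = loads.get(station_id, np.nan)
    a_down = areas[station_id]
    missing = [s for s in upstream_stations if s not in loads or not np.isfinite(loads[s])]
    if not np.isfinite(f_down) or missing:
        return RegionYield(
            station_id, level, f_down, np.nan, a_down, np.nan, np.nan, STATUS_INCOMPLETE
        )
    f_up = float(sum(loads[s] for s in upstream_stations))
    a_up = float(sum(areas[s] for s in upstream_stations))
    if a_down <= a_up:
        return RegionYield(
            station_id, level, f_down, f_up, a_down, a_up, np.nan, STATUS_INVALID_AREA
        )
    y = (f_down - f_up) / (a_down - a_up)
    return RegionYield(station_id, level, f_down, f_up, a_down, a_up, y)


def compute_all_region_yields(
    graph: NetworkGraph,
    stations: pd.DataFrame,
    loads: dict[str, float],
    areas: dict[str, float],
    levels: dict[str, int],
    assignments: list[RegionAssignment] | None = None,
    granularity: str = "per_region",
) -> dict[str, RegionYield]:
    """One RegionYield per station with a load, keyed by station id.

    ``granularity="per_level"`` pools all same-level regions of one
    drainage tree into a single yield value (the incremental-area-weighted
    mean of the per-region yields), written back onto each member region.
    """
    members: dict[str, set[str]] = {}
    if assignments is not None:
        for a in assignments:
            if a.region_id != NO_DATA:
                members.setdefault(a.region_id, set()).add(a.unit_id)

    out: dict[str, RegionYield] = {}
    for row in stations.itertuples(index=False):
        sid = str(row.station_id)
        if sid not in loads or not np.isfinite(loads.get(sid, np.nan)):
            continue
        ups = immediate_upstream_stations(graph, stations, sid)
        ry = compute_region_yield(sid, loads, areas, ups, level=levels.get(sid, 0))
        ry.member_units = members.get(sid, set())
        out[sid] = ry

    if granularity == "per_level":
        _pool_per_level(graph, stations, out)
    elif granularity != "per_region":
        raise ValueError(f"unknown granularity {granularity!r}")
    return out


def _pool_per_level(
    graph: NetworkGraph, stations: pd.DataFrame, region_yields: dict[str, RegionYield]
) -> None:
    unit_of = {
        str(r.station_id): str(r.unit_id) for r in stations.itertuples(index=False)
    }
    tree_of = {
        sid: graph.downstream_path(unit_of[sid])[-1] for sid in region_yields
    }
    groups: dict[tuple[str, int], list[str]] = {}
    for sid, ry in region_yields.items():
        if ry.status == STATUS_OK:
            groups.setdefault((tree_of[sid], ry.level), []).append(sid)
    for sids in groups.values():
        dF = sum(region_yields[s].f_down - region_yields[s].f_up_sum for s in sids)
        dA = sum(region_yields[s].incremental_area for s in sids)
        pooled = dF / dA
        for s in sids:
            region_yields[s].yield_value = pooled


def build_yield_table(
    units: pd.DataFrame,
    assignments: list[RegionAssignment],
    region_yields_by_constituent: dict[str, dict[str, RegionYield]],
) -> pd.DataFrame:
    """Per-unit yield records mirroring the shared-dataset schema.

    One row per unit: id, (corrected) downstream link, area, and one yield
    column per constituent — blank (NaN) for no-data units and for regions
    flagged invalid or incomplete.
    """
    region_of = {a.unit_id: a.region_id for a in assignments}
    rows = []
    for row in units.itertuples(index=False):
        uid = str(row.unit_id)
        rec = {
            "HUC12 ID": uid,
            "ToHUC": str(row.tohuc_id),
            "Area": float(row.area_km2),
        }
        region = region_of.get(uid, NO_DATA)
        for constituent, ry_map in region_yields_by_constituent.items():
            ry = ry_map.get(region) if region != NO_DATA else None
            value = ry.yield_value if ry is not None and ry.status == STATUS_OK else np.nan
            rec[f"{constituent} yield"] = value
        rows.append(rec)
    return pd.DataFrame(rows)


def summarize_yield_sign(yield_table: pd.DataFrame) -> pd.DataFrame:
    """Counts and total areas of positive / zero / negative / no-data units.

    Strictly positive and exactly zero yields are tallied separately, so
    the "greater than 0" class is unambiguous.
    """
    rows = []
    for col in [c for c in yield_table.columns if c.endswith(" yield")]:
        constituent = col[: -len(" yield")]
        v = yield_table[col]
        area = yield_table["Area"]
        for label, mask in [
            ("positive", v > 0),
            ("zero", v == 0),
            ("negative", v < 0),
            ("no_data", v.isna()),
        ]:
            rows.append(
                {
                    "constituent": constituent,
                    "class": label,
                    "n_units": int(mask.sum()),
                    "total_area_km2": float(area[mask].sum()),
                }
            )
    return pd.DataFrame(rows)
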