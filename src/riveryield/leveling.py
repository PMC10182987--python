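"""Station leveling and unit-to-region assignment.

A station's level counts the gauges below it: level 1 stations have no
station anywhere downstream; a level-(n+1) station is an immediate
upstream station of a level-n one. Every catchment unit is assigned to
the region of the nearest station on its downstream walk (a unit hosting
a station belongs to that station's own region); units with no station
downstream, or inside a closed-basin drainage, are no-data.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .network import NetworkGraph

NO_DATA = "NO_DATA"

# no-data reason codes
REASON_CLOSED = "closed_basin"
REASON_DOWNSTREAM = "downstream_of_outlet"
REASON_NO_STATION = "no_station"


@dataclass(frozen=True)
class RegionAssignment:
    unit_id: str
    region_id: str  # station id or NO_DATA
    no_data_reason: str = ""


def _station_by_unit(stations: pd.DataFrame) -> dict[str, str]:
    by_unit: dict[str, str] = {}
    for row in stations.itertuples(index=False):
        uid = str(row.unit_id)
        if uid in by_unit:
            raise ValueError(
                f"two stations on unit {uid!r} ({by_unit[uid]}, {row.station_id}); "
                "co-located gauges must be merged upstream of leveling"
            )
        by_unit[uid] = str(row.station_id)
    return by_unit


def downstream_station_path(
    graph: NetworkGraph, stations: pd.DataFrame, unit_id: str
) -> list[str]:
    """Stations met on the downstream walk from ``unit_id``, in order.

    A station hosted on ``unit_id`` itself comes first. The list is empty
    when no station lies on the path.
    """
    by_unit = _station_by_unit(stations)
    return [by_unit[u] for u in graph.downstream_path(unit_id) if u in by_unit]


def assign_station_levels(graph: NetworkGraph, stations: pd.DataFrame) -> dict[str, int]:
    """level(S) = 1 + number of stations strictly downstream of S."""
    by_unit = _station_by_unit(stations)
    levels: dict[str, int] = {}
    for row in stations.itertuples(index=False):
        path = graph.downstream_path(str(row.unit_id))
        downstream = [u for u in path[1:] if u in by_unit]
        levels[str(row.station_id)] = 1 + len(downstream)
    return levels


def assign_regions(
    graph: NetworkGraph, stations: pd.DataFrame, excluded_set: set[str]
) -> list[RegionAssignment]:
    """Map every unit to its controlling region (or no-data with a reason).

    region(unit) = first station on the unit's downstream walk. Units in
    the closed-basin excluded set are no-data regardless of stations
    downstream. A unit with an empty station path is no-data: reason
    ``downstream_of_outlet`` when a station exists somewhere upstream of
    it (between the most downstream gauge and the outlet), else
    ``no_station``.
    """
    by_unit = _station_by_unit(stations)
    station_units = set(by_unit)
    out: list[RegionAssignment] = []
    # units with >=1 station upstream (for the downstream_of_outlet reason)
    has_station_above: set[str] = set()
    for su in station_units:
        has_station_above.update(graph.downstream_path(su))
    for unit_id in graph.units:
        if unit_id in excluded_set:
            out.append(RegionAssignment(unit_id, NO_DATA, REASON_CLOSED))
            continue
        path = graph.downstream_path(unit_id)
        first = next((u for u in path if u in station_units), None)
        if first is None:
            reason = (
                REASON_DOWNSTREAM if unit_id in has_station_above else REASON_NO_STATION
            )
            out.append(RegionAssignment(unit_id, NO_DATA, reason))
        else:
            out.append(RegionAssignment(unit_id, by_unit[first]))
    return out


def assignments_frame(assignments: list[RegionAssignment], levels: dict[str, int]) -> pd.DataFrame:
    """Diagnostic table: unit_id, region_id, level, no_data_reason."""
    return pd.DataFrame(
        {
            "unit_id": [a.unit_id for a in assignments],
            "region_id": [a.region_id for a in assignments],
            "level": [levels.get(a.region_id, pd.NA) for a in assignments],
            "no_data_reason": [a.no_data_reason for a in assignments],
        }
    )
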