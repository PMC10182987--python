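"""Catchment drainage topology: graph building, upstream tracing, areas.

Each catchment unit carries a single downstream link (the ``tohuc``
attribute of the Watershed Boundary Dataset). Units draining to the sea
point at the :data:`OCEAN` sentinel; endorheic units are flagged closed
and carry the :data:`CLOSED` sentinel. The link table, after applying an
explicit corrections table, must form a forest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

#: downstream-link sentinel for units draining to the sea
OCEAN = "OCEAN"
#: downstream-link sentinel for closed (endorheic) basins
CLOSED = "CLOSED"
TERMINALS = frozenset({OCEAN, CLOSED})


@dataclass
class ValidationReport:
    corrections_applied: list[tuple[str, str, str]] = field(default_factory=list)
    defects: list[str] = field(default_factory=list)


@dataclass
class NetworkGraph:
    """Validated drainage forest with precomputed accumulations.

    ``parent`` maps unit -> downstream unit (or a terminal sentinel);
    ``children`` is the reverse adjacency. Unit areas are km2.
    """

    parent: dict[str, str]
    children: dict[str, list[str]]
    area: dict[str, float]
    closed_basin: dict[str, bool]
    report: ValidationReport
    _drainage_area: dict[str, float] = field(default_factory=dict, repr=False)

    @property
    def units(self) -> list[str]:
        return list(self.parent)

    def __contains__(self, unit_id: str) -> bool:
        return unit_id in self.parent

    def is_headwater(self, unit_id: str) -> bool:
        return len(self.children.get(unit_id, [])) == 0

    def downstream_path(self, unit_id: str) -> list[str]:
        """Units on the walk from ``unit_id`` (inclusive) to a terminal."""
        if unit_id not in self.parent:
            raise KeyError(f"unknown unit {unit_id!r}")
        path = [unit_id]
        nxt = self.parent[unit_id]
        while nxt not in TERMINALS:
            path.append(nxt)
            nxt = self.parent[nxt]
        return path


def build_graph(units: pd.DataFrame, corrections: pd.DataFrame | None = None) -> NetworkGraph:
    """Assemble and validate the drainage graph from a unit table.

    Parameters
    ----------
    units
        Columns ``unit_id``, ``tohuc_id``, ``area_km2``, ``closed_basin``
        (truthy flag). Closed-basin units may carry any link; it is
        normalized to the CLOSED sentinel.
    corrections
        Optional columns ``unit_id``, ``corrected_tohuc_id``; applied to
        the link column before validation, mirroring the manual repair of
        defective downstream links against flowlines.

    Raises
    ------
    ValueError
        On duplicate unit ids, a dangling link, or a residual cycle; the
        message names the offending units.
    """
    if units["unit_id"].duplicated().any():
        dupes = units.loc[units["unit_id"].duplicated(), "unit_id"].tolist()
        raise ValueError(f"duplicate unit ids: {dupes}")
    report = ValidationReport()

    parent: dict[str, str] = {}
    area: dict[str, float] = {}
    closed: dict[str, bool] = {}
    for row in units.itertuples(index=False):
        uid = str(row.unit_id)
        parent[uid] = str(row.tohuc_id)
        area[uid] = float(row.area_km2)
        closed[uid] = bool(row.closed_basin)
        if area[uid] <= 0:
            raise ValueError(f"unit {uid} has nonpositive area {area[uid]}")

    if corrections is not None and len(corrections):
        for row in corrections.itertuples(index=False):
            uid = str(row.unit_id)
            if uid not in parent:
                raise ValueError(f"correction targets unknown unit {uid!r}")
            new = str(row.corrected_tohuc_id)
            note = str(getattr(row, "note", ""))
            report.corrections_applied.append((uid, new, note))
            parent[uid] = new

    for uid in parent:
        if closed[uid]:
            parent[uid] = CLOSED

    dangling = [u for u, p in parent.items() if p not in TERMINALS and p not in parent]
    if dangling:
        report.defects.extend(f"dangling link at {u} -> {parent[u]}" for u in dangling)
        raise ValueError(f"dangling downstream link(s) at units {dangling}")

    g = nx.DiGraph()
    g.add_nodes_from(parent)
    g.add_edges_from((u, p) for u, p in parent.items() if p not in TERMINALS)
    if not nx.is_directed_acyclic_graph(g):
        cycle = sorted({u for u, _ in nx.find_cycle(g)})
        report.defects.append(f"cycle among {cycle}")
        raise ValueError(f"cycle in drainage links among units {cycle}")

    children: dict[str, list[str]] = {u: [] for u in parent}
    for u, p in parent.items():
        if p not in TERMINALS:
            children[p].append(u)

    graph = NetworkGraph(
        parent=parent, children=children, area=area, closed_basin=closed, report=report
    )
    # post-order accumulation: drainage_area(u) = area(u) + sum over children
    acc: dict[str, float] = {}
    for u in nx.topological_sort(g):  # upstream before downstream
        acc[u] = area[u] + sum(acc[c] for c in children[u])
    graph._drainage_area = acc
    return graph


def upstream_units(graph: NetworkGraph, unit_id: str) -> set[str]:
    """All units whose downstream walk passes through ``unit_id``, plus itself."""
    if unit_id not in graph:
        raise KeyError(f"unknown unit {unit_id!r}")
    out = {unit_id}
    stack = list(graph.children[unit_id])
    while stack:
        u = stack.pop()
        out.add(u)
        stack.extend(graph.children[u])
    return out


def drainage_area(graph: NetworkGraph, unit_id: str) -> float:
    """Total area (km2) of the unit's upstream set, itself included."""
    if unit_id not in graph:
        raise KeyError(f"unknown unit {unit_id!r}")
    return graph._drainage_area[unit_id]


def station_drainage_area(
    graph: NetworkGraph, station: pd.Series | dict
) -> tuple[float, str]:
    """Drainage area controlling a station, honoring the headwater rule.

    A station inside a headwater unit only controls a fraction of it, so
    the reported (gauge-record) drainage area is substituted when
    available; otherwise the accumulated area is returned with flag
    ``"derived"`` (an overestimate for headwaters, logged as such). The
    flag is ``"reported"`` only when the substitution happened.
    """
    import logging

    unit_id = str(station["unit_id"])
    if unit_id not in graph:
        raise KeyError(f"station unit {unit_id!r} not in graph")
    reported = station.get("reported_area_km2", None)
    has_reported = reported is not None and pd.notna(reported)
    if graph.is_headwater(unit_id):
        if has_reported:
            return float(reported), "reported"
        logging.getLogger(__name__).warning(
            "headwater station on unit %s has no reported area; "
            "whole-unit area likely overestimates its drainage",
            unit_id,
        )
    return drainage_area(graph, unit_id), "derived"


def closed_basin_excluded_set(graph: NetworkGraph) -> set[str]:
    """Closed-basin units plus everything draining into one.

    These units are excluded from yield accounting on the assumption that
    closed watersheds do not exchange water or carbon with other basins.
    """
    excluded: set[str] = set()
    for u, is_closed in graph.closed_basin.items():
        if is_closed:
            excluded |= upstream_units(graph, u)
    return excluded
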