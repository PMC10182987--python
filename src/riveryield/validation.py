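"""Internal consistency checks for derived areas and estimated loads.

Two procedures: (1) regression of network-derived drainage areas on
gauge-record reported areas, read against the 1:1 line; (2) the
inversed-load analysis — for pairs of a sparsely sampled upstream gauge
below a densely sampled downstream gauge, the upstream load implied by
pure area scaling, F_down * (A_up / A_down), is compared with the
rating-curve estimate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .network import NetworkGraph
from .yields import immediate_upstream_stations

DEFAULT_MAX_UP_OBS = 20
DEFAULT_MIN_DOWN_OBS = 30


@dataclass
class AreaComparison:
    slope: float
    intercept: float
    r_square: float
    n: int


def compare_drainage_areas(stations: pd.DataFrame) -> AreaComparison:
    """Least-squares fit of derived on reported drainage area.

    Expects columns ``derived_area_km2`` and ``reported_area_km2``; rows
    lacking either are ignored. Requires at least 3 complete rows.
    """
    df = stations.dropna(subset=["derived_area_km2", "reported_area_km2"])
    if len(df) < 3:
        raise ValueError(f"need >= 3 stations with both areas, got {len(df)}")
    res = stats.linregress(df["reported_area_km2"], df["derived_area_km2"])
    return AreaComparison(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_square=float(res.rvalue**2),
        n=len(df),
    )


def select_validation_pairs(
    graph: NetworkGraph,
    stations: pd.DataFrame,
    n_obs: dict[str, int],
    areas: dict[str, float],
    loads: dict[str, float],
    max_up_obs: int = DEFAULT_MAX_UP_OBS,
    min_down_obs: int = DEFAULT_MIN_DOWN_OBS,
    adjacent_only: bool = True,
) -> pd.DataFrame:
    """Upstream/downstream station pairs for the inversed-load check.

    A pair qualifies when the upstream station has ``max_up_obs`` or fewer
    observations, the downstream station ``min_down_obs`` or more, and the
    upstream gauge drains into the downstream one. With ``adjacent_only``
    (default) only immediate upstream stations pair with a downstream
    gauge; otherwise any ancestor/descendant station pair qualifies. A
    downstream station may appear in several pairs.
    """
    from .leveling import downstream_station_path

    rows = []
    for down in stations.itertuples(index=False):
        d_id = str(down.station_id)
        if d_id not in loads or n_obs.get(d_id, 0) < min_down_obs:
            continue
        if adjacent_only:
            candidates = immediate_upstream_stations(graph, stations, d_id)
        else:
            candidates = set()
            for up in stations.itertuples(index=False):
                u_id = str(up.station_id)
                if u_id == d_id:
                    continue
                path = downstream_station_path(graph, stations, str(up.unit_id))
                if d_id in path[1:]:
                    candidates.add(u_id)
        for u_id in sorted(candidates):
            if u_id not in loads or n_obs.get(u_id, 0) > max_up_obs:
                continue
            rows.append(
                {
                    "upstream_station_id": u_id,
                    "downstream_station_id": d_id,
                    "n_obs_up": n_obs[u_id],
                    "n_obs_down": n_obs[d_id],
                    "A_up": areas[u_id],
                    "A_down": areas[d_id],
                    "F_up_est": loads[u_id],
                    "F_down_est": loads[d_id],
                    "F_up_inversed": inverse_upstream_load(
                        loads[d_id], areas[u_id], areas[d_id]
                    ),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "upstream_station_id",
            "downstream_station_id",
            "n_obs_up",
            "n_obs_down",
            "A_up",
            "A_down",
            "F_up_est",
            "F_down_est",
            "F_up_inversed",
        ],
    )


def inverse_upstream_load(f_down: float, a_up: float, a_down: float) -> float:
    """Upstream load implied by area scaling: F_down * (A_up / A_down)."""
    if a_down <= 0:
        raise ValueError("downstream drainage area must be positive")
    return f_down * (a_up / a_down)


@dataclass
class PairConsistency:
    pearson_r: float | None  # None when variance is degenerate
    slope: float | None
    n_pairs: int
    table: pd.DataFrame


def pair_consistency_report(
    pairs: pd.DataFrame, log_scale: bool = False
) -> PairConsistency:
    """Correlation and slope of estimated vs. inversed upstream loads.

    ``log_scale`` applies ln to both load columns first (requires them
    positive). Degenerate variance yields ``pearson_r = slope = None``.
    """
    if len(pairs) < 3:
        raise ValueError(f"need >= 3 pairs, got {len(pairs)}")
    x = pairs["F_up_inversed"].to_numpy(dtype=float)
    y = pairs["F_up_est"].to_numpy(dtype=float)
    if log_scale:
        if np.any(x <= 0) or np.any(y <= 0):
            raise ValueError("log scale requires strictly positive loads")
        x, y = np.log(x), np.log(y)
    if np.std(x) == 0 or np.std(y) == 0:
        return PairConsistency(None, None, len(pairs), pairs)
    res = stats.linregress(x, y)
    return PairConsistency(
        pearson_r=float(res.rvalue), slope=float(res.slope), n_pairs=len(pairs), table=pairs
    )
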