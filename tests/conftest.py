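import numpy as np
import pandas as pd
import pytest

from riveryield import network, synthetic


# ---------------------------------------------------------------- oracles
# Brute-force path-walk helpers, independent of riveryield.network's
# traversal/accumulation code: they use only the raw parent-pointer table.

def parent_map(units: pd.DataFrame) -> dict[str, str]:
    return {
        str(r.unit_id): str(r.tohuc_id) for r in units.itertuples(index=False)
    }


def walk_downstream(parents: dict[str, str], unit: str) -> list[str]:
    """Units on the downstream walk from ``unit`` inclusive, by pointer chasing."""
    path = [unit]
    seen = {unit}
    nxt = parents[unit]
    while nxt in parents:
        if nxt in seen:
            raise AssertionError(f"cycle through {nxt}")
        path.append(nxt)
        seen.add(nxt)
        nxt = parents[nxt]
    return path


def brute_upstream_sets(units: pd.DataFrame) -> dict[str, set[str]]:
    """upstream[u] = every unit whose downstream walk passes through u."""
    parents = parent_map(units)
    out: dict[str, set[str]] = {u: set() for u in parents}
    for u in parents:
        for node in walk_downstream(parents, u):
            out[node].add(u)
    return out


def brute_drainage_areas(units: pd.DataFrame) -> dict[str, float]:
    parents = parent_map(units)
    areas = {str(r.unit_id): float(r.area_km2) for r in units.itertuples(index=False)}
    acc = dict.fromkeys(parents, 0.0)
    for u in parents:
        for node in walk_downstream(parents, u):
            acc[node] += areas[u]
    return acc


# ---------------------------------------------------------------- fixtures

def _nested_watershed_rows():
    # Nine-station nested watershed: outlet unit H1 below station S1;
    # five branches with stations S11..S15; S121 above S12, S131/S132
    # above S13; plus a closed basin H2 fed by C1.
    rows = [("H1", network.OCEAN, 80.0, 0), ("U1", "H1", 120.0, 0)]
    for i in range(11, 16):
        rows.append((f"M{i}", "U1", 60.0 + i, 0))
        rows.append((f"U{i}", f"M{i}", 90.0 + i, 0))
    rows += [
        ("M121", "U12", 40.0, 0),
        ("U121", "M121", 55.0, 0),
        ("U131", "U13", 35.0, 0),
        ("U132", "U13", 45.0, 0),
        ("H2", network.CLOSED, 70.0, 1),
        ("C1", "H2", 25.0, 0),
    ]
    return rows


@pytest.fixture(scope="session")
def nested_watershed_units() -> pd.DataFrame:
    return pd.DataFrame(
        _nested_watershed_rows(), columns=["unit_id", "tohuc_id", "area_km2", "closed_basin"]
    )


@pytest.fixture(scope="session")
def nested_watershed_stations() -> pd.DataFrame:
    placements = [
        ("S1", "U1"),
        ("S11", "U11"),
        ("S12", "U12"),
        ("S13", "U13"),
        ("S14", "U14"),
        ("S15", "U15"),
        ("S121", "U121"),
        ("S131", "U131"),
        ("S132", "U132"),
    ]
    return pd.DataFrame(
        [(s, u, np.nan) for s, u in placements],
        columns=["station_id", "unit_id", "reported_area_km2"],
    )


@pytest.fixture(scope="session")
def nested_watershed_graph(nested_watershed_units):
    return network.build_graph(nested_watershed_units)


def random_forest(seed: int, n_units: int = 300, n_closed: int = 1) -> pd.DataFrame:
    spec = synthetic.SyntheticNetworkSpec(
        n_units=n_units,
        n_roots=max(1, n_units // 100),
        n_closed_basins=n_closed,
        seed=seed,
    )
    return synthetic.generate_network(spec)
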