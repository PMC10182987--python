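"""Synthetic watershed generator.

Produces the three inputs the pipeline consumes — a catchment-unit table
with downstream links, station placements, and paired flow/concentration
observations — together with a ground-truth per-unit yield field whose
induced station loads are exactly mass-balanced. Unit areas are lognormal
with a default mean of ~104 km2, matching the average size of the HUC12
population the generator emulates. No spatial geometry is attempted: only
tree structure and area scale matter to the analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import load_estimation, models, network
from .load_estimation import SECONDS_PER_DAY, _decorrelating_center

#: lognormal log-sd of unit areas
DEFAULT_AREA_LOG_SD = 1.0
#: log-mean chosen so E[area] = exp(mu + sd^2/2) = 104 km2
DEFAULT_AREA_LOG_MEAN = float(np.log(104.0) - DEFAULT_AREA_LOG_SD**2 / 2.0)


@dataclass(frozen=True)
class SyntheticNetworkSpec:
    """Parameters of a random drainage forest."""

    n_units: int = 500
    n_roots: int = 3
    n_closed_basins: int = 1
    area_log_mean: float = DEFAULT_AREA_LOG_MEAN
    area_log_sd: float = DEFAULT_AREA_LOG_SD
    max_children: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_units < 1:
            raise ValueError("n_units must be >= 1")
        if self.n_roots < 1:
            raise ValueError("n_roots must be >= 1")
        if self.n_closed_basins >= self.n_units:
            raise ValueError("n_closed_basins must be < n_units")
        if self.n_roots + self.n_closed_basins > self.n_units:
            raise ValueError("n_roots + n_closed_basins exceeds n_units")
        if self.max_children < 1:
            raise ValueError("max_children must be >= 1")
        if self.area_log_sd < 0:
            raise ValueError("area_log_sd must be >= 0")


@dataclass(frozen=True)
class ObservationGeneratorSpec:
    """Parameters of a station's simulated flow and sampling record.

    Concentrations are derived from a simulated ln-load that follows the
    chosen rating-curve model exactly (plus Gaussian noise of SD ``sigma``
    on the ln scale), so a noise-free record is recovered to machine
    precision by refitting the same model.
    """

    model_id: int = 4
    coefficients: tuple[float, ...] = (10.0, 1.0, 0.3, 0.2)
    sigma: float = 0.3
    flow_log_mean: float = 3.0  # ln(m3 s-1); ~20 m3/s median flow
    flow_log_sd: float = 0.8
    flow_seasonal_amplitude: float = 0.5
    n_days: int = 3653  # ten years of daily flow
    n_samples: int = 40
    start_year: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model_id not in models.MODEL_TERMS:
            raise ValueError(f"model_id must be in 1..9, got {self.model_id}")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if not (2 <= self.n_samples <= self.n_days):
            raise ValueError("need 2 <= n_samples <= n_days")
        if len(self.coefficients) != models.n_coefficients(self.model_id):
            raise ValueError(
                f"model {self.model_id} takes "
                f"{models.n_coefficients(self.model_id)} coefficients"
            )


def generate_network(spec: SyntheticNetworkSpec) -> pd.DataFrame:
    """Random drainage forest as a catchment-unit table.

    The first ``n_roots`` units drain to the ocean sentinel and the next
    ``n_closed_basins`` are closed; every later unit attaches to a
    uniformly chosen existing unit with fewer than ``max_children``
    upstream neighbours, so the result is acyclic by construction.
    """
    rng = np.random.default_rng(spec.seed)
    ids = [f"U{i:05d}" for i in range(spec.n_units)]
    tohuc: list[str] = []
    closed: list[bool] = []
    child_count = np.zeros(spec.n_units, dtype=int)
    for i in range(spec.n_units):
        if i < spec.n_roots:
            tohuc.append(network.OCEAN)
            closed.append(False)
        elif i < spec.n_roots + spec.n_closed_basins:
            tohuc.append(network.CLOSED)
            closed.append(True)
        else:
            eligible = np.flatnonzero(child_count[:i] < spec.max_children)
            parent = int(rng.choice(eligible))
            child_count[parent] += 1
            tohuc.append(ids[parent])
            closed.append(False)
    areas = rng.lognormal(spec.area_log_mean, spec.area_log_sd, size=spec.n_units)
    return pd.DataFrame(
        {
            "unit_id": ids,
            "tohuc_id": tohuc,
            "area_km2": areas,
            "closed_basin": np.array(closed, dtype=int),
        }
    )


def place_stations(
    units: pd.DataFrame,
    n_stations: int,
    seed: int = 0,
    report_prob: float = 0.7,
) -> pd.DataFrame:
    """Place at most one station per eligible (non-closed-draining) unit.

    Headwater placements get a reported drainage area strictly smaller
    than the hosting unit's area (the gauge controls only part of the
    unit); interior placements carry the exact accumulated area as their
    reported value with probability ``report_prob``, else no record.
    """
    graph = network.build_graph(units)
    excluded = network.closed_basin_excluded_set(graph)
    eligible = sorted(u for u in graph.units if u not in excluded)
    if n_stations > len(eligible):
        raise ValueError(
            f"n_stations={n_stations} exceeds {len(eligible)} eligible units"
        )
    rng = np.random.default_rng(seed)
    chosen = sorted(rng.choice(eligible, size=n_stations, replace=False).tolist())
    rows = []
    for k, uid in enumerate(chosen):
        if graph.is_headwater(uid):
            reported = graph.area[uid] * rng.uniform(0.2, 0.8)
        elif rng.random() < report_prob:
            reported = network.drainage_area(graph, uid)
        else:
            reported = np.nan
        rows.append(
            {
                "station_id": f"S{k:04d}",
                "unit_id": uid,
                "reported_area_km2": reported,
            }
        )
    return pd.DataFrame(rows, columns=["station_id", "unit_id", "reported_area_km2"])


def simulate_observations(
    spec: ObservationGeneratorSpec,
    target_annual_load: float | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Daily flow series and sparse same-day concentration samples.

    Daily flows are lognormal with a sinusoidal annual component in the
    log. On each of ``n_samples`` distinct sampled days, ln(load) is the
    model's linear predictor at that day's centered covariates plus
    N(0, sigma^2) noise; concentration is back-computed as
    load / (86400 * Q), in mgC L-1 for Q in m3 s-1 and load in gC day-1.

    When ``target_annual_load`` (kgC yr-1) is given, the generated loads
    are rescaled so the expected whole-record mean of the bias-corrected
    rating-curve prediction equals the target; at sigma = 0 the refitted
    annual load matches the target to machine precision.
    """
    rng = np.random.default_rng(spec.seed)
    dates = pd.date_range(f"{spec.start_year}-01-01", periods=spec.n_days, freq="D")
    dtime = load_estimation.decimal_time(dates)
    frac = dtime - np.floor(dtime)
    ln_q = (
        spec.flow_log_mean
        + spec.flow_seasonal_amplitude * np.sin(2.0 * np.pi * frac)
        + rng.normal(0.0, spec.flow_log_sd, size=spec.n_days)
    )
    flow = np.exp(ln_q)
    flow_df = pd.DataFrame({"date": dates, "flow": flow})

    idx = np.sort(rng.choice(spec.n_days, size=spec.n_samples, replace=False))
    c_lnq = _decorrelating_center(ln_q[idx])
    c_dt = _decorrelating_center(dtime[idx])
    lp_samples = models.linear_predictor(
        spec.model_id, np.asarray(spec.coefficients), ln_q[idx] - c_lnq, dtime[idx] - c_dt
    )
    ln_load = lp_samples + rng.normal(0.0, spec.sigma, size=spec.n_samples)

    if target_annual_load is not None:
        lp_all = models.linear_predictor(
            spec.model_id, np.asarray(spec.coefficients), ln_q - c_lnq, dtime - c_dt
        )
        expected_daily = float(np.mean(np.exp(lp_all))) * np.exp(spec.sigma**2 / 2.0)
        target_daily = target_annual_load * 1000.0 / load_estimation.DAYS_PER_YEAR
        ln_load = ln_load + np.log(target_daily / expected_daily)

    conc = np.exp(ln_load) / (SECONDS_PER_DAY * flow[idx])
    samples_df = pd.DataFrame({"date": dates[idx], "concentration": conc})
    return flow_df, samples_df


def generate_true_yields(
    units: pd.DataFrame,
    seed: int = 0,
    mean: float = 5000.0,
    sd: float = 3000.0,
) -> pd.Series:
    """Gaussian per-unit true yield field (kgC km-2 yr-1), negatives allowed.

    The default scale puts most units in the low thousands of
    kgC km-2 yr-1 with a few percent net-removal (negative) units.
    """
    rng = np.random.default_rng(seed)
    values = rng.normal(mean, sd, size=len(units))
    return pd.Series(values, index=units["unit_id"].astype(str), name="true_yield")


def induce_station_loads(
    graph: network.NetworkGraph,
    stations: pd.DataFrame,
    yields: pd.Series,
) -> dict[str, float]:
    """Ground-truth annual load (kgC yr-1) each station would observe.

    load(s) = sum over the station's upstream units of yield * area, with
    a headwater station's partial unit contributing yield * reported_area
    instead of the whole unit.
    """
    excluded = network.closed_basin_excluded_set(graph)
    out: dict[str, float] = {}
    for row in stations.itertuples(index=False):
        uid = str(row.unit_id)
        if uid in excluded:
            raise ValueError(f"station {row.station_id} drains to a closed basin")
        reported = getattr(row, "reported_area_km2", np.nan)
        if graph.is_headwater(uid) and pd.notna(reported):
            load = float(yields[uid]) * float(reported)
        else:
            load = sum(
                float(yields[u]) * graph.area[u] for u in network.upstream_units(graph, uid)
            )
        out[str(row.station_id)] = float(load)
    return out


@dataclass
class SyntheticDataset:
    """Bundle of generated pipeline inputs plus the hidden truth."""

    units: pd.DataFrame
    stations: pd.DataFrame
    observations: pd.DataFrame  # long table: station_id, date, flow, concentration, constituent
    true_yields: pd.DataFrame  # unit_id, constituent, true_yield
    true_loads: pd.DataFrame  # station_id, constituent, annual_load_kgc_yr
    seed: int = 0


def simulate_dataset(
    n_units: int = 300,
    n_stations: int = 25,
    seed: int = 0,
    constituents: tuple[str, ...] = ("POC", "DOC"),
    sigma: float = 0.3,
    n_days: int = 3653,
    n_samples_range: tuple[int, int] = (15, 60),
    yield_mean: float = 5000.0,
    yield_sd: float = 3000.0,
) -> SyntheticDataset:
    """Generate a complete, internally consistent pipeline input set.

    Each station gets one daily flow record and, per constituent, a sparse
    concentration record whose underlying loads are scaled to the load
    induced by that constituent's true yield field — so rating-curve
    estimates can be checked against network mass balance end to end.
    """
    rng = np.random.default_rng(seed)
    net_spec = SyntheticNetworkSpec(
        n_units=n_units,
        n_roots=max(1, n_units // 150),
        n_closed_basins=1 if n_units >= 10 else 0,
        seed=int(rng.integers(2**31 - 1)),
    )
    units = generate_network(net_spec)
    graph = network.build_graph(units)
    stations = place_stations(units, n_stations, seed=int(rng.integers(2**31 - 1)))

    yield_rows = []
    load_rows = []
    obs_frames = []
    for constituent in constituents:
        yfield = generate_true_yields(
            units, seed=int(rng.integers(2**31 - 1)), mean=yield_mean, sd=yield_sd
        )
        for uid, val in yfield.items():
            yield_rows.append(
                {"unit_id": uid, "constituent": constituent, "true_yield": val}
            )
        true_loads = induce_station_loads(graph, stations, yfield)
        for sid, load in true_loads.items():
            load_rows.append(
                {
                    "station_id": sid,
                    "constituent": constituent,
                    "annual_load_kgc_yr": load,
                }
            )

    for row in stations.itertuples(index=False):
        sid = str(row.station_id)
        station_seed = int(rng.integers(2**31 - 1))
        n_samples = int(rng.integers(n_samples_range[0], n_samples_range[1] + 1))
        flow_df = None
        for j, constituent in enumerate(constituents):
            truth = next(
                r["annual_load_kgc_yr"]
                for r in load_rows
                if r["station_id"] == sid and r["constituent"] == constituent
            )
            if truth <= 0:
                continue  # a net-negative station load has no lognormal record
            spec = ObservationGeneratorSpec(
                model_id=4,
                coefficients=(8.0, 1.0 + 0.1 * j, 0.3, 0.2),
                sigma=sigma,
                n_days=n_days,
                n_samples=n_samples,
                seed=station_seed,  # same flow record for both constituents
            )
            flow_df, samples = simulate_observations(spec, target_annual_load=truth)
            samples = samples.assign(
                station_id=sid, constituent=constituent, flow=np.nan, flow_unit="m3s"
            )
            samples = samples.merge(
                flow_df.rename(columns={"flow": "day_flow"}), on="date", how="left"
            )
            samples["flow"] = samples["day_flow"]
            obs_frames.append(
                samples[
                    ["station_id", "date", "flow", "flow_unit", "concentration", "constituent"]
                ]
            )
        if flow_df is not None:
            flow_rows = flow_df.assign(
                station_id=sid, flow_unit="m3s", concentration=np.nan, constituent=""
            )
            obs_frames.append(
                flow_rows[
                    ["station_id", "date", "flow", "flow_unit", "concentration", "constituent"]
                ]
            )

    observations = (
        pd.concat(obs_frames, ignore_index=True)
        if obs_frames
        else pd.DataFrame(
            columns=["station_id", "date", "flow", "flow_unit", "concentration", "constituent"]
        )
    )
    return SyntheticDataset(
        units=units,
        stations=stations,
        observations=observations,
        true_yields=pd.DataFrame(yield_rows),
        true_loads=pd.DataFrame(load_rows),
        seed=seed,
    )
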