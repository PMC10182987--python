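"""End-to-end orchestration of the load/yield workflow over CSV files.

Each ``cmd_*`` function is one pipeline stage operating on the paths in a
:class:`~riveryield.config.PipelineConfig`; the CLI wraps these directly.
All stages are deterministic for a fixed config and seed.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io, leveling, load_estimation, network, synthetic, validation, yields
from .config import PipelineConfig

logger = logging.getLogger(__name__)


def cmd_simulate(config: PipelineConfig) -> dict[str, Path]:
    """Write a complete synthetic input set (units, stations, observations,
    true yields/loads) to the configured paths."""
    ds = synthetic.simulate_dataset(
        n_units=config.n_units,
        n_stations=config.n_stations,
        seed=config.seed,
        constituents=config.constituents,
        sigma=config.sigma,
        n_days=config.n_days,
    )
    paths = {
        "units": io.write_csv(ds.units, config.units_path),
        "stations": io.write_csv(ds.stations, config.stations_path),
        "observations": io.write_csv(ds.observations, config.observations_path),
        "true_yields": io.write_csv(ds.true_yields, config.out_path("true_yields.csv")),
        "true_loads": io.write_csv(ds.true_loads, config.out_path("true_loads.csv")),
    }
    logger.info("simulated %d units, %d stations", len(ds.units), len(ds.stations))
    return paths


def _load_graph(config: PipelineConfig) -> network.NetworkGraph:
    units = io.read_units(config.units_path)
    corrections = io.read_corrections(config.corrections_path)
    return network.build_graph(units, corrections)


def cmd_build_network(config: PipelineConfig) -> dict[str, Path]:
    """Validate the drainage graph and write per-station drainage areas."""
    graph = _load_graph(config)
    stations = io.read_stations(config.stations_path)
    rows = []
    for _, st in stations.iterrows():
        area, flag = network.station_drainage_area(graph, st)
        rows.append(
            {
                "station_id": st["station_id"],
                "unit_id": st["unit_id"],
                "drainage_area_km2": area,
                "area_source": flag,
            }
        )
    report_lines = [
        *(f"correction applied: {u} -> {t} ({note})" for u, t, note in graph.report.corrections_applied),
        *(f"defect: {d}" for d in graph.report.defects),
        f"units: {len(graph.units)}",
        f"closed-basin excluded units: {len(network.closed_basin_excluded_set(graph))}",
    ]
    report_path = config.out_path("network_report.txt")
    report_path.parent.mkdir(parents=True, exist_ok=True)
    report_path.write_text("\n".join(report_lines) + "\n")
    return {
        "station_areas": io.write_csv(
            pd.DataFrame(rows), config.out_path("station_areas.csv")
        ),
        "network_report": report_path,
    }


def cmd_fit_loads(config: PipelineConfig) -> dict[str, Path]:
    """Estimate per-station, per-constituent loads (station-load CSV).

    Every station x constituent with any concentration record appears in
    the output; stations failing the minimum-observation filter or with
    no fittable model carry a null load and a reason code.
    """
    graph = _load_graph(config)
    stations = io.read_stations(config.stations_path)
    obs = io.read_observations(config.observations_path, config.flow_unit)
    flows, concs = io.split_observations(obs)

    derived_areas: dict[str, float] = {}
    reported_areas: dict[str, float] = {}
    for _, st in stations.iterrows():
        sid = str(st["station_id"])
        derived_areas[sid], _ = network.station_drainage_area(graph, st)
        reported_areas[sid] = st.get("reported_area_km2", np.nan)

    results: list[load_estimation.StationLoad] = []
    for (sid, constituent), conc in sorted(concs.items()):
        flow = flows.get(sid)
        if flow is None or flow.empty:
            logger.warning("station %s has concentrations but no flow record", sid)
            continue
        results.append(
            load_estimation.estimate_station_load(
                flow, conc, station_id=sid, constituent=constituent, min_obs=config.min_obs
            )
        )
    frame = io.station_loads_frame(results, derived_areas, reported_areas)
    exclusions = frame[frame["Exclusion reason"] != ""][
        ["Station ID", "Constituent", "Number of observations", "Exclusion reason"]
    ]
    return {
        "station_loads": io.write_csv(frame, config.out_path("station_loads.csv")),
        "exclusions": io.write_csv(exclusions, config.out_path("exclusions.csv")),
    }


def _annual_loads(frame: pd.DataFrame, constituent: str) -> dict[str, float]:
    sub = frame[(frame["Constituent"] == constituent) & (frame["Exclusion reason"] == "")]
    return {
        str(r["Station ID"]): float(r["Carbon load"])
        * load_estimation.DAYS_PER_YEAR
        / 1000.0
        for _, r in sub.iterrows()
        if np.isfinite(r["Carbon load"])
    }


def cmd_compute_yields(config: PipelineConfig) -> dict[str, Path]:
    """Allocate net yields to inter-station regions (per-unit yield CSV)."""
    units = io.read_units(config.units_path)
    corrections = io.read_corrections(config.corrections_path)
    graph = network.build_graph(units, corrections)
    stations = io.read_stations(config.stations_path)
    loads_frame = pd.read_csv(config.out_path("station_loads.csv"), dtype={"Station ID": str})
    loads_frame["Exclusion reason"] = loads_frame["Exclusion reason"].fillna("")

    excluded = network.closed_basin_excluded_set(graph)
    levels = leveling.assign_station_levels(graph, stations)
    assignments = leveling.assign_regions(graph, stations, excluded)

    areas = {
        str(st["station_id"]): network.station_drainage_area(graph, st)[0]
        for _, st in stations.iterrows()
    }
    by_constituent: dict[str, dict[str, yields.RegionYield]] = {}
    diag_rows = []
    for constituent in config.constituents:
        loads = _annual_loads(loads_frame, constituent)
        sub_stations = stations[stations["station_id"].isin(loads)].reset_index(drop=True)
        if sub_stations.empty:
            by_constituent[constituent] = {}
            continue
        sub_levels = leveling.assign_station_levels(graph, sub_stations)
        sub_assignments = leveling.assign_regions(graph, sub_stations, excluded)
        ry = yields.compute_all_region_yields(
            graph,
            sub_stations,
            loads,
            areas,
            sub_levels,
            assignments=sub_assignments,
            granularity=config.yield_granularity,
        )
        by_constituent[constituent] = ry
        for sid, r in sorted(ry.items()):
            diag_rows.append(
                {
                    "constituent": constituent,
                    "region_id": sid,
                    "level": r.level,
                    "F_down": r.f_down,
                    "F_up_sum": r.f_up_sum,
                    "A_down": r.a_down,
                    "A_up_sum": r.a_up_sum,
                    "yield": r.yield_value,
                    "status": r.status,
                }
            )

    # per-constituent region structure may differ; the shared table uses
    # each constituent's own assignment through its RegionYield members
    table_rows = _merge_yield_tables(units, graph, stations, excluded, by_constituent, config)
    diag = pd.DataFrame(
        diag_rows,
        columns=[
            "constituent",
            "region_id",
            "level",
            "F_down",
            "F_up_sum",
            "A_down",
            "A_up_sum",
            "yield",
            "status",
        ],
    )
    assign_frame = leveling.assignments_frame(assignments, levels)
    return {
        "yields": io.write_csv(table_rows, config.out_path("yields.csv")),
        "region_diagnostics": io.write_csv(diag, config.out_path("region_diagnostics.csv")),
        "assignments": io.write_csv(assign_frame, config.out_path("assignments.csv")),
    }


def _merge_yield_tables(
    units: pd.DataFrame,
    graph: network.NetworkGraph,
    stations: pd.DataFrame,
    excluded: set[str],
    by_constituent: dict[str, dict[str, yields.RegionYield]],
    config: PipelineConfig,
) -> pd.DataFrame:
    out = None
    for constituent, ry in by_constituent.items():
        sub_stations = stations[
            stations["station_id"].isin(ry.keys())
        ].reset_index(drop=True)
        assignments = leveling.assign_regions(graph, sub_stations, excluded)
        tbl = yields.build_yield_table(units, assignments, {constituent: ry})
        col = f"{constituent} yield"
        if col not in tbl.columns:
            tbl[col] = np.nan
        out = tbl if out is None else out.assign(**{col: tbl[col]})
    if out is None:
        out = yields.build_yield_table(units, leveling.assign_regions(graph, stations.iloc[0:0], excluded), {})
        for constituent in config.constituents:
            out[f"{constituent} yield"] = np.nan
    return out


def cmd_validate(config: PipelineConfig) -> dict[str, Path]:
    """Drainage-area comparison and inversed-load consistency report."""
    graph = _load_graph(config)
    stations = io.read_stations(config.stations_path)
    loads_frame = pd.read_csv(config.out_path("station_loads.csv"), dtype={"Station ID": str})
    loads_frame["Exclusion reason"] = loads_frame["Exclusion reason"].fillna("")

    lines = []
    area_df = pd.DataFrame(
        {
            "station_id": stations["station_id"],
            "derived_area_km2": [
                network.drainage_area(graph, str(u)) for u in stations["unit_id"]
            ],
            "reported_area_km2": stations["reported_area_km2"],
        }
    )
    try:
        cmp = validation.compare_drainage_areas(area_df)
        lines.append(
            "drainage-area regression (derived on reported): "
            f"slope={cmp.slope:.6g} intercept={cmp.intercept:.6g} "
            f"R2={cmp.r_square:.6g} n={cmp.n}"
        )
    except ValueError as exc:
        lines.append(f"drainage-area comparison skipped: {exc}")

    areas = {
        str(st["station_id"]): network.station_drainage_area(graph, st)[0]
        for _, st in stations.iterrows()
    }
    pair_frames = []
    for constituent in config.constituents:
        loads = _annual_loads(loads_frame, constituent)
        sub = loads_frame[loads_frame["Constituent"] == constituent]
        n_obs = {
            str(r["Station ID"]): int(r["Number of observations"]) for _, r in sub.iterrows()
        }
        sub_stations = stations[stations["station_id"].isin(loads)].reset_index(drop=True)
        pairs = validation.select_validation_pairs(
            graph,
            sub_stations,
            n_obs,
            areas,
            loads,
            max_up_obs=config.max_up_obs,
            min_down_obs=config.min_down_obs,
        )
        pairs.insert(0, "constituent", constituent)
        pair_frames.append(pairs)
        try:
            rep = validation.pair_consistency_report(pairs)
            lines.append(
                f"{constituent}: {rep.n_pairs} pairs, "
                f"pearson_r={rep.pearson_r:.4f} slope={rep.slope:.4f}"
            )
        except ValueError as exc:
            lines.append(f"{constituent}: pair consistency skipped: {exc}")

    pairs_all = pd.concat(pair_frames, ignore_index=True) if pair_frames else pd.DataFrame()
    summary_path = config.out_path("validation_summary.txt")
    summary_path.parent.mkdir(parents=True, exist_ok=True)
    summary_path.write_text("\n".join(lines) + "\n")
    return {
        "pairs": io.write_csv(pairs_all, config.out_path("validation_pairs.csv")),
        "summary": summary_path,
    }


def run_all(config: PipelineConfig) -> dict[str, Path]:
    """simulate -> build-network -> fit-loads -> compute-yields -> validate."""
    out: dict[str, Path] = {}
    out.update(cmd_simulate(config))
    out.update(cmd_build_network(config))
    out.update(cmd_fit_loads(config))
    out.update(cmd_compute_yields(config))
    out.update(cmd_validate(config))
    return out
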