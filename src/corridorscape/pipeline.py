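"""End-to-end pipeline: landscape -> nodes -> conductance -> corridors ->
metrics -> priority index -> group statistics.

A :class:`PipelineConfig` either embeds a synthetic-landscape configuration
or points at raster/vector input files; :func:`run_pipeline` executes every
stage, writes the stage outputs (GeoJSON layers, CSV tables, ASCII-grid
rasters) under an output directory, and returns a manifest — inputs,
parameters, per-stage record counts, and the seed — that suffices to
reproduce every output byte for byte. The manifest deliberately records no
wall-clock information.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import shapely

from . import __version__
from .conductance import ConductanceLookup, EXAMPLE_LOOKUP, biomass_modifier, build_conductance, resample_categorical
from .errors import ConfigError, CorridorscapeError, StatsInputError
from .grid import Raster
from .groupstats import class_comparisons, spearman
from .io import check_aligned, read_config, read_raster, read_vector, write_raster, write_vector
from .metrics import corridor_metrics, node_metrics
from .nodes import NodeThresholds, clean_reserves, extract_end_patches, identify_start_nodes
from .pathfinding import batch_corridors, build_graph
from .priority import FeatureSpec, prioritize
from .synthetic import LandscapeConfig, SyntheticLandscape, generate_landscape

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "end_point_table"]

#: corridor-level variables compared across priority classes
COMPARISON_VARIABLES = [
    "length_km", "elev_range_m", "protection_pct", "n_pas", "n_kbas", "mean_biomass",
]
#: variable pairs for the Spearman correlation report
SPEARMAN_PAIRS = [
    ("n_pas", "length_km"),
    ("n_kbas", "length_km"),
    ("protection_pct", "length_km"),
    ("protection_pct", "mean_biomass"),
]


@dataclass
class PipelineConfig:
    """Everything one pipeline run depends on.

    Exactly one of ``landscape`` (synthetic mode) or ``input_paths`` (file
    mode, with keys dem/landcover/biomass/integrity/reserves/kbas/countries)
    must be set. All analysis thresholds carry their standard defaults:
    5 km2 minimum node area, 500 m lowland / 1500 m highland mean-elevation
    cuts, 100 Mt C biomass cap, k = 5 nearest end points, 1000 m corridor
    buffer, 3 retained components, class cuts at 2 and 4.
    """

    landscape: LandscapeConfig | None = None
    input_paths: dict[str, str] | None = None
    thresholds: NodeThresholds = field(default_factory=NodeThresholds)
    lookup: ConductanceLookup = field(default_factory=lambda: EXAMPLE_LOOKUP)
    resample_target_cell: float | None = None
    connectivity: int = 8
    k: int = 5
    buffer_half_width: float = 1000.0
    feature_spec: FeatureSpec = field(default_factory=FeatureSpec)
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.landscape is None) == (self.input_paths is None):
            raise ConfigError("set exactly one of landscape (synthetic) or input_paths")
        if self.input_paths is not None:
            required = {"dem", "landcover", "biomass", "integrity",
                        "reserves", "kbas", "countries"}
            missing = required - set(self.input_paths)
            if missing:
                raise ConfigError(f"input_paths missing keys: {sorted(missing)}")
            absent = [p for p in self.input_paths.values() if not Path(p).exists()]
            if absent:
                raise ConfigError(f"input file(s) not found: {absent}")
        if self.k < 1:
            raise ConfigError("k must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = read_config(path)
        kwargs: dict[str, Any] = {}
        if "landscape" in raw:
            kwargs["landscape"] = LandscapeConfig(**raw["landscape"])
        if "input_paths" in raw:
            kwargs["input_paths"] = dict(raw["input_paths"])
        if "thresholds" in raw:
            kwargs["thresholds"] = NodeThresholds(**raw["thresholds"])
        if "lookup" in raw:
            kwargs["lookup"] = ConductanceLookup.from_csv(raw["lookup"])
        for key in ("resample_target_cell", "connectivity", "k",
                    "buffer_half_width", "alpha", "seed"):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)

    def to_manifest_dict(self) -> dict[str, Any]:
        d: dict[str, Any] = {
            "landscape": dataclasses.asdict(self.landscape) if self.landscape else None,
            "input_paths": self.input_paths,
            "thresholds": dataclasses.asdict(self.thresholds),
            "lookup": {str(k): v for k, v in sorted(self.lookup.values.items())},
            "forest_classes": sorted(self.lookup.forest_classes),
            "resample_target_cell": self.resample_target_cell,
            "connectivity": self.connectivity,
            "k": self.k,
            "buffer_half_width": self.buffer_half_width,
            "alpha": self.alpha,
            "seed": self.seed,
        }
        return d


@dataclass
class PipelineResult:
    manifest: dict
    reserves_clean: pd.DataFrame
    start_nodes: pd.DataFrame
    end_patches: pd.DataFrame
    end_points: pd.DataFrame
    corridor_table: pd.DataFrame
    priority_table: pd.DataFrame
    stats_report: pd.DataFrame
    screen_report: pd.DataFrame


def end_point_table(end_patches: pd.DataFrame) -> pd.DataFrame:
    """Flatten patch seed points into one row per end point."""
    rows = []
    epid = 0
    for _, patch in end_patches.iterrows():
        for pt in patch["seed_points"]:
            rows.append({"end_point_id": epid, "patch_id": patch["patch_id"], "point": pt})
            epid += 1
    return pd.DataFrame.from_records(rows, columns=["end_point_id", "patch_id", "point"])


def _load_inputs(config: PipelineConfig) -> SyntheticLandscape:
    if config.landscape is not None:
        return generate_landscape(dataclasses.replace(config.landscape, seed=config.seed))
    p = config.input_paths
    dem = read_raster(p["dem"])
    landcover = read_raster(p["landcover"])
    biomass = read_raster(p["biomass"])
    integrity = read_raster(p["integrity"])
    check_aligned({"dem": dem, "landcover": landcover,
                   "biomass": biomass, "integrity": integrity})
    return SyntheticLandscape(
        dem=dem,
        landcover=landcover.with_data(np.asarray(landcover.data, dtype=np.int64)),
        biomass=biomass,
        integrity=integrity,
        reserves=read_vector(p["reserves"], required=["id", "status", "designation",
                                                      "marine", "reported_area"]),
        kbas=read_vector(p["kbas"], required=["id"]),
        countries=read_vector(p["countries"], required=["id"]),
        config=LandscapeConfig(seed=config.seed),
    )


def _write_table(table: pd.DataFrame, path: Path, geometry_cols: tuple[str, ...] = ()) -> None:
    """CSV without geometry columns; stable float formatting for reproducibility."""
    drop = [c for c in geometry_cols if c in table.columns]
    table.drop(columns=drop).to_csv(path, index=False, float_format="%.10g")


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> PipelineResult:
    """Execute every stage and write the result bundle under ``out_dir``.

    Any stage failure is re-raised annotated with the stage name; outputs
    of completed stages stay on disk.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict[str, Any] = {}
    stage = "load-inputs"
    try:
        scape = _load_inputs(config)
        counts["n_reserves_raw"] = len(scape.reserves)

        stage = "nodes"
        land = scape.dem.extent_polygon
        reserves_clean = clean_reserves(scape.reserves, land=land)
        start_nodes = identify_start_nodes(reserves_clean, scape.dem, config.thresholds)
        end_patches = extract_end_patches(
            scape.landcover, scape.integrity, scape.dem, scape.biomass,
            config.thresholds, reserves_clean=reserves_clean,
        )
        end_points = end_point_table(end_patches)
        counts["n_reserves_clean"] = len(reserves_clean)
        counts["n_start_nodes"] = len(start_nodes)
        counts["n_end_patches"] = len(end_patches)
        counts["n_end_points"] = len(end_points)
        _write_table(start_nodes, out / "start_nodes.csv", ("geometry", "point"))
        _write_table(end_patches, out / "end_patches.csv",
                     ("geometry", "point", "seed_points"))
        if len(start_nodes):
            write_vector(
                start_nodes.assign(geometry=start_nodes["geometry"]).drop(columns=["point"]),
                out / "start_nodes.geojson",
            )
        if len(end_points):
            write_vector(
                end_points.assign(geometry=end_points["point"]).drop(columns=["point"]),
                out / "end_points.geojson",
            )
        if len(start_nodes) == 0 or len(end_points) == 0:
            raise CorridorscapeError(
                f"no corridors can be routed: {len(start_nodes)} start node(s), "
                f"{len(end_points)} end point(s)"
            )

        stage = "conductance"
        landcover = scape.landcover
        if config.resample_target_cell is not None:
            landcover = resample_categorical(landcover, config.resample_target_cell)
        modifier = biomass_modifier(scape.biomass)
        surface = build_conductance(landcover, config.lookup, modifier)
        write_raster(surface.raster, out / "conductance.asc")

        stage = "corridors"
        graph = build_graph(surface, connectivity=config.connectivity)
        paths, pairing = batch_corridors(graph, start_nodes, end_points, k=config.k)
        counts["n_paths_expected"] = int(
            len(start_nodes) * min(config.k, len(end_points))
        )
        counts["n_paths_ok"] = len(paths)
        counts["n_paths_unreachable"] = int((pairing["status"] == "unreachable").sum())
        _write_table(pairing, out / "pairing.csv")

        stage = "metrics"
        corridor_table = corridor_metrics(
            paths, pairing, scape.dem, scape.biomass, reserves_clean,
            scape.kbas, scape.countries, half_width=config.buffer_half_width,
        )
        corridor_table = corridor_table.merge(
            end_points[["end_point_id", "patch_id"]], on="end_point_id", how="left"
        )
        start_metrics, end_metrics = node_metrics(
            start_nodes, end_patches, scape.dem, reserves_clean, scape.biomass
        )
        _write_table(corridor_table, out / "corridor_metrics.csv", ("geometry", "buffer"))
        _write_table(start_metrics, out / "start_node_metrics.csv")
        _write_table(end_metrics, out / "end_patch_metrics.csv")
        ok_lines = corridor_table.loc[corridor_table["status"] == "ok"]
        if len(ok_lines):
            write_vector(
                ok_lines[["corridor_id", "start_id", "end_point_id",
                          "accumulated_cost", "geometry"]],
                out / "corridors.geojson",
            )

        stage = "prioritize"
        ok = corridor_table.loc[corridor_table["status"] == "ok"].reset_index(drop=True)
        model, priority_table, screen_report = prioritize(
            ok, start_nodes, end_patches, config.feature_spec
        )
        priority_table = priority_table.reset_index()
        counts["n_corridors_prioritized"] = len(priority_table)
        cls_counts = priority_table["priority_class"].value_counts()
        counts["class_counts"] = {
            c: int(cls_counts.get(c, 0)) for c in ("low", "medium", "high")
        }
        counts["variance_explained_3pc"] = float(model.variance_explained)
        _write_table(priority_table, out / "priority.csv")
        _write_table(screen_report, out / "collinearity_screen.csv")
        loadings = pd.DataFrame(
            model.loadings,
            index=model.feature_names,
            columns=[f"pc{j + 1}" for j in range(model.loadings.shape[1])],
        )
        loadings.insert(0, "variable", loadings.index)
        _write_table(loadings.reset_index(drop=True), out / "pca_loadings.csv")

        stage = "stats"
        merged = ok.merge(
            priority_table[["corridor_id", "index", "priority_class"]], on="corridor_id"
        )
        try:
            stats_report = class_comparisons(
                merged, "priority_class", COMPARISON_VARIABLES, alpha=config.alpha
            )
        except StatsInputError as exc:
            log.warning("class comparisons skipped: %s", exc)
            stats_report = pd.DataFrame(
                columns=["variable", "test", "group_a", "group_b",
                         "statistic", "p", "p_adjusted"]
            )
        corr_rows = []
        for a, b in SPEARMAN_PAIRS:
            try:
                rho, p = spearman(merged[a], merged[b])
            except StatsInputError:
                continue
            corr_rows.append({"variable": f"{a}~{b}", "test": "spearman",
                              "group_a": None, "group_b": None,
                              "statistic": rho, "p": p, "p_adjusted": None})
        if corr_rows:
            # rebuild from records rather than concat: the correlation rows
            # carry no group labels, and all-NA columns make concat fragile
            stats_report = pd.DataFrame.from_records(
                stats_report.to_dict("records") + corr_rows,
                columns=["variable", "test", "group_a", "group_b",
                         "statistic", "p", "p_adjusted"],
            )
        _write_table(stats_report, out / "stats_report.csv")
    except CorridorscapeError as exc:
        raise type(exc)(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "package": "corridorscape",
        "version": __version__,
        "config": config.to_manifest_dict(),
        "counts": counts,
    }
    with (out / "manifest.json").open("w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    return PipelineResult(
        manifest=manifest,
        reserves_clean=reserves_clean,
        start_nodes=start_nodes,
        end_patches=end_patches,
        end_points=end_points,
        corridor_table=corridor_table,
        priority_table=priority_table,
        stats_report=stats_report,
        screen_report=screen_report,
    )
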