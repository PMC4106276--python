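"""Pipeline orchestration: simulate -> krige -> sample surfaces at plant
locations -> correlograms -> pairwise Mantel tests -> path network.

Every randomized stage receives a sub-seed derived from the master seed and
the stage name, logged in the run manifest together with SHA-256 digests of
every output file, so a rerun with the same configuration is byte-identical
and tampering is detectable.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
import time
import zlib
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.interpolate import RegularGridInterpolator

from . import geostat, mantel as mantel_mod, pathnet, synth

__all__ = ["RunConfig", "run_pipeline", "sample_surface_at", "derive_seed",
           "default_edge_spec"]

log = logging.getLogger("meadowpath")

ENV_VARS = ["elevation", "soil_moisture", "vpd"]
ANALYSIS_VARS = [
    "elevation", "soil_moisture", "vpd",
    "rosette_diameter", "stalk_number", "stalk_diameter", "fruit_number",
    "line", "rosette_herbivory", "stalk_herbivory",
    "goldenrod_density", "dandelion_density",
]


@dataclass
class RunConfig:
    """Settings of one pipeline run; defaults follow the study conventions
    (2.5 m lags, 10,000 permutations, 100,000 posterior draws, 90% CIs,
    alpha 0.05, 0.5 m prediction raster on a 40 x 50 m domain)."""

    seed: int = 0
    outdir: str = "results/run"
    domain_width: float = 40.0
    domain_height: float = 50.0
    lag_width: float = 2.5
    n_perm: int = 10000
    n_draws: int = 100000
    n_boot: int = 1000
    ci_level: float = 0.90
    alpha: float = 0.05
    raster_cell: float = 0.5
    surface_cell: float = 1.0
    grid: geostat.ParameterGrid = dc_field(default_factory=geostat.ParameterGrid.default)
    loo_mode: str = "shared"
    plants_csv: str | None = None  # optional pre-existing inputs
    env_csv: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        grid_cfg = raw.pop("grid", None)
        cfg = cls(**raw)
        if grid_cfg:
            cfg.grid = geostat.ParameterGrid(
                phi_support=np.asarray(grid_cfg["phi_support"], dtype=float),
                tau2rel_support=np.asarray(grid_cfg["tau2rel_support"], dtype=float),
            )
        return cfg


def derive_seed(master: int, stage: str) -> int:
    """Deterministic per-stage sub-seed: CRC-32 of the stage name keyed by
    the master seed, folded below 2^31."""
    return (zlib.crc32(stage.encode(), master & 0xFFFFFFFF)) & 0x7FFFFFFF


def sample_surface_at(points, surface: geostat.PredictiveSummary,
                      mode: str = "bilinear") -> np.ndarray:
    """Evaluate a kriged raster at arbitrary points.

    The raster's locations must form a regular grid.  ``bilinear`` (default)
    interpolates the predictive mean; ``nearest`` snaps to the closest node.
    Points outside the raster by more than one cell are rejected.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    xs = np.unique(surface.locations[:, 0])
    ys = np.unique(surface.locations[:, 1])
    vals = surface.mean.reshape(len(ys), len(xs))
    cell = max(
        np.diff(xs).max() if len(xs) > 1 else 0.0,
        np.diff(ys).max() if len(ys) > 1 else 0.0,
    )
    bad = (
        (pts[:, 0] < xs[0] - cell) | (pts[:, 0] > xs[-1] + cell)
        | (pts[:, 1] < ys[0] - cell) | (pts[:, 1] > ys[-1] + cell)
    )
    if np.any(bad):
        raise ValueError(f"points outside raster bounds: {np.where(bad)[0].tolist()}")
    interp = RegularGridInterpolator(
        (ys, xs), vals,
        method="linear" if mode == "bilinear" else "nearest",
        bounds_error=False, fill_value=None,
    )
    return interp(np.column_stack([pts[:, 1], pts[:, 0]]))


def default_edge_spec() -> list[tuple[str, str, bool, str | None]]:
    """Reconstruction of the full hypothesis network tested by the analysis:
    directed abiotic -> biotic influences with ecologically predetermined
    directions, plus one undirected (simple-correlation) pair.
    """
    return [
        ("elevation", "soil_moisture", True, "-"),
        ("elevation", "rosette_diameter", True, "-"),
        ("elevation", "stalk_number", True, "-"),
        ("elevation", "fruit_number", True, "-"),
        ("soil_moisture", "stalk_number", True, "+"),
        ("rosette_diameter", "stalk_number", True, "+"),
        ("rosette_diameter", "fruit_number", True, "+"),
        ("stalk_number", "fruit_number", True, "+"),
        ("stalk_herbivory", "fruit_number", True, "-"),
        ("dandelion_density", "rosette_herbivory", True, "+"),
        ("vpd", "goldenrod_density", True, "+"),
        ("rosette_herbivory", "stalk_herbivory", False, None),
    ]


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g", lineterminator="\n")


def run_pipeline(config: RunConfig, edge_spec=None) -> Path:
    """Execute all stages in order and return the run directory.

    Stage failures abort the run with the stage name and cause.  The
    manifest (``manifest.json``) records the configuration, each stage's
    sub-seed and timing, and a SHA-256 digest of every output file.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    domain = synth.Domain(config.domain_width, config.domain_height)
    manifest: dict = {"seed": config.seed, "stages": {}, "files": {}}
    t_all = time.time()

    def stage(name):
        def deco(fn):
            t0 = time.time()
            log.info("stage %s: start", name)
            try:
                fn()
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            manifest["stages"][name] = {
                "seed": derive_seed(config.seed, name),
                "seconds": round(time.time() - t0, 3),
            }
            log.info("stage %s: done in %.1fs", name, time.time() - t0)
        return deco

    state: dict = {}

    @stage("simulate")
    def _simulate():
        if config.plants_csv and config.env_csv:
            for p in (config.plants_csv, config.env_csv):
                if not Path(p).exists():
                    raise FileNotFoundError(f"missing input file: {p}")
            state["plants"] = pd.read_csv(config.plants_csv)
            state["env"] = pd.read_csv(config.env_csv)
            return
        truth = synth.default_truth_config(seed=derive_seed(config.seed, "simulate"))
        plants, env, surfaces, truth = synth.generate_study(
            truth, domain, cell=config.surface_cell
        )
        state["plants"] = plants
        state["env"] = env
        _write_csv(plants[[c for c in synth.PLANT_COLUMNS]], out / "plants.csv")
        _write_csv(env, out / "env_sites.csv")
        (out / "truth.json").write_text(truth.to_json() + "\n")

    @stage("krige")
    def _krige():
        xs = np.arange(0, domain.width + config.raster_cell / 2, config.raster_cell)
        ys = np.arange(0, domain.height + config.raster_cell / 2, config.raster_cell)
        gx, gy = np.meshgrid(xs, ys)
        raster_pts = np.column_stack([gx.ravel(), gy.ravel()])
        env = state["env"]
        state["surfaces"] = {}
        for var in ENV_VARS:
            field = geostat.SpatialField(
                env[["x", "y"]].to_numpy(), env[var].to_numpy(), var
            )
            table = geostat.log_marginal_posterior(field, config.grid)
            draws = geostat.sample_posterior(
                table, config.n_draws, seed=derive_seed(config.seed, f"krige:{var}")
            )
            pred = geostat.krige_predict(field, draws, raster_pts)
            state["surfaces"][var] = pred
            _write_csv(
                pd.DataFrame(
                    {"x": raster_pts[:, 0], "y": raster_pts[:, 1],
                     "pred_mean": pred.mean, "pred_var": pred.variance}
                ),
                out / f"surface_{var}.csv",
            )
            _write_csv(table.to_frame()[["phi", "tau2rel", "mass"]],
                       out / f"posterior_{var}.csv")
            loo = geostat.loo_validate(field, config.grid, mode=config.loo_mode,
                                       ci_level=config.ci_level)
            _write_csv(loo, out / f"loo_{var}.csv")

    @stage("sample_surfaces")
    def _sample():
        plants = state["plants"]
        pts = plants[["x", "y"]].to_numpy()
        table = plants[[c for c in synth.PLANT_COLUMNS]].copy()
        for var in ENV_VARS:
            table[var] = sample_surface_at(pts, state["surfaces"][var])
        state["analysis"] = table
        _write_csv(table, out / "plants_with_env.csv")

    @stage("correlogram")
    def _correlograms():
        table = state["analysis"]
        geo = mantel_mod.euclidean_dmat(table[["x", "y"]].to_numpy(), "space")
        state["geo"] = geo
        ranges = {}
        for var in ANALYSIS_VARS:
            col = table[var].to_numpy() if var != "line" else table["line"].astype(str).to_numpy()
            dm = (
                mantel_mod.euclidean_dmat(col, var)
                if var == "line"
                else mantel_mod.euclidean_dmat(mantel_mod.standardize(col, var), var)
            )
            cg = mantel_mod.correlogram(
                dm, geo, lag_width=config.lag_width,
                n_perm=config.n_perm,
                seed=derive_seed(config.seed, f"correlogram:{var}"),
                alpha=config.alpha,
            )
            ranges[var] = cg.range_m
            bins = cg.bins.copy()
            _write_csv(bins, out / f"correlogram_{var}.csv")
        state["ranges"] = ranges
        (out / "ranges.json").write_text(json.dumps(ranges, indent=2, sort_keys=True) + "\n")

    @stage("mantel")
    def _mantel_pairs():
        table = state["analysis"]
        rows = []
        for va, vb in itertools.combinations(ANALYSIS_VARS, 2):
            da = _var_dmat(table, va)
            db = _var_dmat(table, vb)
            res = mantel_mod.mantel(
                da, db, n_perm=config.n_perm,
                seed=derive_seed(config.seed, f"mantel:{va}:{vb}"),
                tail="two-sided",
            )
            ci = mantel_mod.bootstrap_ci(
                da, db, n_boot=max(config.n_boot, 100), level=config.ci_level,
                seed=derive_seed(config.seed, f"boot:{va}:{vb}"),
            )
            rows.append({"var_a": va, "var_b": vb, "r": res.r,
                         "p_value": res.p_value, "ci_lo": ci[0], "ci_hi": ci[1]})
        _write_csv(pd.DataFrame(rows), out / "mantel_pairs.csv")

    @stage("path")
    def _path():
        table = state["analysis"]
        spec = edge_spec if edge_spec is not None else default_edge_spec()
        hyps = pathnet.build_hypotheses(ANALYSIS_VARS, spec)
        tbl = table.copy()
        tbl["line"] = tbl["line"].astype(str)
        net = pathnet.evaluate_network(
            tbl, hyps, state["ranges"],
            n_perm=config.n_perm, n_boot=config.n_boot,
            ci_level=config.ci_level, alpha=config.alpha,
            seed=derive_seed(config.seed, "path"),
        )
        pathnet.export_network(net, out / "network.json")
        _write_csv(net.to_frame(), out / "network_edges.csv")

    for path in sorted(out.glob("*.csv")) + sorted(out.glob("*.json")):
        if path.name != "manifest.json":
            manifest["files"][path.name] = _digest(path)
    manifest["total_seconds"] = round(time.time() - t_all, 3)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return out


def _var_dmat(table: pd.DataFrame, var: str):
    if var == "line":
        return mantel_mod.euclidean_dmat(table["line"].astype(str).to_numpy(), "line")
    return mantel_mod.euclidean_dmat(
        mantel_mod.standardize(table[var].to_numpy(), var), var
    )
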