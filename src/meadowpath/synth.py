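"""Synthetic meadow generator with known ground truth.

Emulates the statistical structure of a densely mapped meadow population:
spatially autocorrelated environmental surfaces (Gaussian random fields
with exponential correlation), habitat-driven plant placement (inhomogeneous
point process via rejection sampling), spatially clustered inbred-line
labels (nearest-founder assignment with distance-decay mixing), and plant
traits produced by a declared acyclic causal graph over the dataset columns.

The default configuration mirrors the study geometry the analysis modules
assume: a 40 x 50 m domain, 234 plants, 71 environmental sample sites,
counts of herbivory holes and of neighboring goldenrod/dandelion plants
within a 15 cm radius.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field, asdict

import networkx as nx
import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator
from scipy.spatial.distance import cdist

from .geostat import GPParams, SpatialField, simulate_gp

__all__ = [
    "Domain",
    "TruthConfig",
    "GridSurface",
    "simulate_grf",
    "simulate_plant_locations",
    "assign_lines",
    "simulate_traits",
    "neighbor_counts",
    "generate_study",
    "default_truth_config",
]

COUNT_COLUMNS = (
    "stalk_number",
    "fruit_number",
    "rosette_herbivory",
    "stalk_herbivory",
    "goldenrod_density",
    "dandelion_density",
)

PLANT_COLUMNS = (
    "x",
    "y",
    "rosette_diameter",
    "stalk_number",
    "stalk_diameter",
    "fruit_number",
    "line",
    "rosette_herbivory",
    "stalk_herbivory",
    "goldenrod_density",
    "dandelion_density",
)

ENV_VARIABLES = ("elevation", "soil_moisture", "vpd")


@dataclass(frozen=True)
class Domain:
    """Rectangular study area, origin at (0, 0), in meters."""

    width: float = 40.0
    height: float = 50.0

    def __post_init__(self) -> None:
        if not (self.width > 0 and self.height > 0):
            raise ValueError("domain width and height must be positive")

    def contains(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(pts)
        return (
            (pts[:, 0] >= 0)
            & (pts[:, 0] <= self.width)
            & (pts[:, 1] >= 0)
            & (pts[:, 1] <= self.height)
        )


@dataclass
class TruthConfig:
    """Full generative specification; echoed alongside every dataset.

    edge_list entries are (source, target, sign, effect) with sign in
    {"+", "-"} and effect the absolute standardized effect size; directed
    edges must form a DAG.  bidirectional entries are (var_a, var_b, sign,
    effect) pairs coupled through a shared latent rather than a direction.
    """

    surface_params: dict = dc_field(default_factory=dict)
    intensity_link: dict = dc_field(
        default_factory=lambda: {"elevation": -0.8, "soil_moisture": 0.8}
    )
    n_plants: int = 234
    n_env_sites: int = 71
    n_lines: int = 12
    dispersal_scale: float = 8.0
    edge_list: list = dc_field(default_factory=list)
    bidirectional: list = dc_field(default_factory=list)
    base_values: dict = dc_field(default_factory=dict)
    noise_sd: dict = dc_field(default_factory=dict)
    count_scale: dict = dc_field(default_factory=dict)
    line_effects: dict = dc_field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_plants < 10:
            raise ValueError("n_plants must be >= 10")
        if self.dispersal_scale <= 0:
            raise ValueError("dispersal_scale must be positive")
        for src, tgt, sign, eff in self.edge_list:
            if sign not in ("+", "-"):
                raise ValueError(f"edge sign must be '+' or '-', got {sign!r}")
            if not np.isfinite(eff):
                raise ValueError(f"edge effect for {src}->{tgt} is not finite")

    def signed_effects(self) -> list[tuple[str, str, float]]:
        return [
            (s, t, eff if sign == "+" else -eff)
            for s, t, sign, eff in self.edge_list
        ]

    def to_json(self) -> str:
        d = asdict(self)
        d["surface_params"] = {
            k: {"beta": p.beta, "sigma2": p.sigma2, "phi": p.phi, "tau2_rel": p.tau2_rel}
            for k, p in self.surface_params.items()
        }
        return json.dumps(d, indent=2, sort_keys=True)


@dataclass
class GridSurface:
    """A surface realized on a regular grid, interpolable to any point."""

    xs: np.ndarray
    ys: np.ndarray
    values: np.ndarray  # (len(ys), len(xs)) grid of values
    name: str = ""

    def at(self, pts: np.ndarray) -> np.ndarray:
        interp = RegularGridInterpolator(
            (self.ys, self.xs), self.values, bounds_error=False, fill_value=None
        )
        pts = np.atleast_2d(pts)
        return interp(np.column_stack([pts[:, 1], pts[:, 0]]))


def default_truth_config(seed: int = 0) -> TruthConfig:
    """Study-shaped default: 40 x 50 m, 234 plants, 71 env sites.

    The causal graph carries four signed true edges — elevation lowers soil
    moisture, larger rosettes carry more stalks, stalk herbivory lowers
    fruit set, dandelion neighbors raise rosette herbivory — with every
    other column causally unlinked (available as declared null edges for
    recovery tests).  Effect sizes are on the standardized-parent scale.
    """
    surface_params = {
        "elevation": GPParams(beta=1700.0, sigma2=4.0, phi=8.0, tau2_rel=0.05),
        "soil_moisture_resid": GPParams(beta=0.0, sigma2=1.0, phi=5.0, tau2_rel=0.1),
        "vpd": GPParams(beta=1.2, sigma2=0.04, phi=6.0, tau2_rel=0.1),
        "rosette_field": GPParams(beta=0.0, sigma2=1.0, phi=6.0, tau2_rel=0.2),
        "herbivory_field": GPParams(beta=0.0, sigma2=1.0, phi=4.0, tau2_rel=0.2),
        "dandelion_field": GPParams(beta=0.0, sigma2=1.0, phi=4.0, tau2_rel=0.2),
    }
    edge_list = [
        ("elevation", "soil_moisture", "-", 1.5),
        ("rosette_diameter", "stalk_number", "+", 0.9),
        ("stalk_herbivory", "fruit_number", "-", 0.8),
        ("dandelion_density", "rosette_herbivory", "+", 0.8),
    ]
    base_values = {
        "soil_moisture": 30.0,
        "rosette_diameter": 6.0,
        "stalk_number": 3.0,
        "stalk_diameter": 2.5,
        "fruit_number": 8.0,
        "rosette_herbivory": 4.0,
        "stalk_herbivory": 3.0,
        "goldenrod_density": 1.5,
        "dandelion_density": 1.5,
    }
    noise_sd = {
        "soil_moisture": 2.0,
        "rosette_diameter": 1.0,
        "stalk_number": 0.8,
        "stalk_diameter": 0.4,
        "fruit_number": 2.0,
        "rosette_herbivory": 1.2,
        "stalk_herbivory": 1.0,
        "goldenrod_density": 1.2,
        "dandelion_density": 1.2,
    }
    count_scale = {
        "stalk_number": 1.5,
        "fruit_number": 3.0,
        "rosette_herbivory": 2.0,
        "stalk_herbivory": 1.5,
        "goldenrod_density": 1.2,
        "dandelion_density": 1.2,
    }
    return TruthConfig(
        surface_params=surface_params,
        edge_list=edge_list,
        base_values=base_values,
        noise_sd=noise_sd,
        count_scale=count_scale,
        line_effects={"rosette_diameter": 0.6},
        seed=seed,
    )


def simulate_grf(locations, params: GPParams, seed=None) -> SpatialField:
    """Gaussian random field values at the locations.

    Multivariate normal with mean beta and covariance
    sigma^2 exp(-h/phi) off-diagonal, sigma^2 (1 + tau2_rel) on the
    diagonal.  Identical seeds reproduce identical values.
    """
    locations = np.atleast_2d(np.asarray(locations, dtype=float))
    if len(locations) < 1:
        raise ValueError("need at least one location")
    values = simulate_gp(locations, params, seed=seed)
    return SpatialField(locations, values)


def simulate_grid_surface(domain: Domain, params: GPParams, seed=None,
                          cell: float = 1.0, name: str = "") -> GridSurface:
    """GRF realized on a regular grid over the domain (bilinear thereafter)."""
    xs = np.arange(0.0, domain.width + cell / 2, cell)
    ys = np.arange(0.0, domain.height + cell / 2, cell)
    gx, gy = np.meshgrid(xs, ys)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    fld = simulate_grf(pts, params, seed=seed)
    return GridSurface(xs, ys, fld.values.reshape(len(ys), len(xs)), name)


def simulate_plant_locations(domain: Domain, intensity_surface: GridSurface,
                             n_target: int, seed=None) -> np.ndarray:
    """Place plants by rejection sampling proportional to a gridded intensity.

    Candidate points are uniform over the domain and accepted with
    probability intensity / max intensity, until exactly ``n_target``
    points are accepted.
    """
    if n_target == 0:
        return np.zeros((0, 2))
    rng = np.random.default_rng(seed)
    peak = float(np.max(intensity_surface.values))
    if not peak > 0 or np.any(intensity_surface.values < 0):
        raise ValueError("intensity surface must be nonnegative with a positive peak")
    pts = []
    while len(pts) < n_target:
        k = max(4 * (n_target - len(pts)), 64)
        cand = rng.uniform((0, 0), (domain.width, domain.height), size=(k, 2))
        lam = np.maximum(intensity_surface.at(cand), 0.0)
        accept = rng.uniform(0, peak, size=k) < lam
        pts.extend(cand[accept])
    return np.array(pts[:n_target])


def assign_lines(locations, n_lines: int, dispersal_scale: float, seed=None) -> np.ndarray:
    """Spatially clustered categorical line labels (1..n_lines).

    ``n_lines`` founder plants are chosen among the locations; every plant
    takes its nearest founder's line with probability exp(-d / dispersal
    scale) and otherwise a uniformly random line.  Founders are at distance
    zero from themselves, so every line occurs at least once.
    """
    locations = np.atleast_2d(np.asarray(locations, dtype=float))
    n = len(locations)
    if n_lines < 1:
        raise ValueError("n_lines must be >= 1")
    if n_lines > n:
        raise ValueError(f"n_lines={n_lines} exceeds number of plants {n}")
    rng = np.random.default_rng(seed)
    founders = rng.choice(n, size=n_lines, replace=False)
    d = cdist(locations, locations[founders])
    nearest = np.argmin(d, axis=1)
    d_near = d[np.arange(n), nearest]
    keep = rng.uniform(size=n) < np.exp(-d_near / dispersal_scale)
    labels = np.where(keep, nearest + 1, rng.integers(1, n_lines + 1, size=n))
    labels[founders] = np.arange(1, n_lines + 1)
    return labels.astype(int)


def _causal_order(edges: list[tuple[str, str, float]]) -> list[str]:
    g = nx.DiGraph()
    for s, t, _ in edges:
        g.add_edge(s, t)
    try:
        return list(nx.topological_sort(g))
    except nx.NetworkXUnfeasible:
        cycle = nx.find_cycle(g)
        path = " -> ".join(e[0] for e in cycle) + f" -> {cycle[-1][1]}"
        raise ValueError(f"directed edges contain a cycle: {path}") from None


def simulate_traits(locations, fields: dict, truth: TruthConfig, seed=None) -> pd.DataFrame:
    """Generate the per-plant dataset from the declared causal structure.

    Variables are built in topological order of the directed edge list.
    Each variable starts from its base value, plus its exogenous spatial
    field contribution (if ``fields`` carries one under its name), plus the
    sum of signed effects times the standardized parent, plus Gaussian
    noise, plus a shared latent per bidirectional pair.  Count columns pass
    through a rounding link floored at zero; all other columns stay
    continuous.  Line labels, when present in ``fields`` under ``"line"``,
    contribute a per-line random intercept to variables named in
    ``truth.line_effects``.
    """
    locations = np.atleast_2d(np.asarray(locations, dtype=float))
    n = len(locations)
    rng = np.random.default_rng(seed)
    effects = truth.signed_effects()
    order = _causal_order(effects)
    all_vars = list(
        dict.fromkeys(
            order
            + [v for v in truth.base_values]
            + [v for pair in truth.bidirectional for v in pair[:2]]
            + [v for v in fields if v != "line"]
        )
    )
    parents: dict[str, list[tuple[str, float]]] = {v: [] for v in all_vars}
    for s, t, eff in effects:
        if t not in parents:
            raise ValueError(f"edge target {t!r} is not a dataset column")
        parents[t].append((s, eff))

    cols: dict[str, np.ndarray] = {}
    # exogenous environmental inputs evaluated at the plant locations
    for name, fld in fields.items():
        if name == "line":
            continue
        cols[name] = np.asarray(fld.at(locations) if hasattr(fld, "at") else fld, dtype=float)

    line_labels = fields.get("line")
    line_intercepts: dict[str, np.ndarray] = {}
    if line_labels is not None:
        line_labels = np.asarray(line_labels)
        uniq = np.unique(line_labels)
        for var, sd in truth.line_effects.items():
            per_line = rng.normal(0.0, sd, size=len(uniq))
            lut = dict(zip(uniq, per_line))
            line_intercepts[var] = np.array([lut[l] for l in line_labels])

    shared_latents = []
    for a, b, sign, eff in truth.bidirectional:
        z = rng.standard_normal(n)
        shared_latents.append((a, z, eff))
        shared_latents.append((b, z, eff if sign == "+" else -eff))

    for var in all_vars:
        val = np.full(n, truth.base_values.get(var, 0.0))
        if var in cols:  # exogenous field contribution under the same name
            val = val + cols[var]
        for par, eff in parents[var]:
            if par not in cols:
                raise ValueError(f"edge source {par!r} is not a dataset column")
            pv = cols[par].astype(float)
            sd = pv.std(ddof=1)
            z = (pv - pv.mean()) / sd if sd > 0 else np.zeros(n)
            scale = truth.count_scale.get(var, 1.0)
            val = val + eff * scale * z
        for name, z, eff in shared_latents:
            if name == var:
                val = val + eff * z
        if var in line_intercepts:
            val = val + line_intercepts[var]
        sd = truth.noise_sd.get(var, 0.0)
        if sd > 0:
            val = val + rng.normal(0.0, sd, size=n)
        if var in COUNT_COLUMNS:
            # rounding link, floored at zero; children condition on the
            # observed (integer) counts, not the latent linear predictor
            val = np.maximum(np.rint(val), 0).astype(int)
        cols[var] = val

    df = pd.DataFrame({"x": locations[:, 0], "y": locations[:, 1]})
    for var in all_vars:
        df[var] = cols[var]
    if line_labels is not None:
        df["line"] = line_labels
    return df


def neighbor_counts(focal, neighbors, radius: float) -> np.ndarray:
    """Neighbors within a closed ball of ``radius`` meters around each focal point."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    focal = np.atleast_2d(np.asarray(focal, dtype=float))
    neighbors = np.asarray(neighbors, dtype=float).reshape(-1, 2)
    if len(neighbors) == 0:
        return np.zeros(len(focal), dtype=int)
    d = cdist(focal, neighbors)
    return (d <= radius).sum(axis=1).astype(int)


def generate_study(config: TruthConfig, domain: Domain = Domain(), cell: float = 1.0):
    """End-to-end synthetic study: plants, environmental sites, ground truth.

    Returns ``(plants, env_sites, surfaces, config)`` where ``plants`` is
    the per-plant table (default 234 rows), ``env_sites`` the environmental
    samples at 71 random locations, and ``surfaces`` the true gridded
    environmental surfaces.  Fully deterministic under ``config.seed``.
    """
    master = np.random.SeedSequence(config.seed)
    seeds = master.spawn(10)
    rng_sites = np.random.default_rng(seeds[0])

    surfaces: dict[str, GridSurface] = {}
    names = sorted(config.surface_params)
    surf_seeds = seeds[1].spawn(len(names))
    for i, name in enumerate(names):
        surfaces[name] = simulate_grid_surface(
            domain, config.surface_params[name], seed=surf_seeds[i], cell=cell, name=name
        )

    elev = surfaces["elevation"]
    # soil moisture = base + signed effect * standardized elevation + own GRF residual
    sm_effect = next(
        (eff for s, t, eff in default_edges_signed(config) if (s, t) == ("elevation", "soil_moisture")),
        0.0,
    )
    elev_z = (elev.values - elev.values.mean()) / elev.values.std(ddof=1)
    sm_values = (
        config.base_values.get("soil_moisture", 0.0)
        + sm_effect * elev_z
        + surfaces["soil_moisture_resid"].values
        if "soil_moisture_resid" in surfaces
        else np.full_like(elev.values, config.base_values.get("soil_moisture", 0.0))
    )
    surfaces["soil_moisture"] = GridSurface(elev.xs, elev.ys, sm_values, "soil_moisture")

    # plant placement from the habitat intensity surface
    link = config.intensity_link
    sm_z = (sm_values - sm_values.mean()) / sm_values.std(ddof=1)
    log_lam = link.get("elevation", 0.0) * elev_z + link.get("soil_moisture", 0.0) * sm_z
    intensity = GridSurface(elev.xs, elev.ys, np.exp(log_lam), "intensity")
    plant_xy = simulate_plant_locations(domain, intensity, config.n_plants, seed=seeds[2])

    lines = assign_lines(plant_xy, config.n_lines, config.dispersal_scale, seed=seeds[3])

    plant_fields: dict = {"line": lines}
    plant_fields["elevation"] = surfaces["elevation"].at(plant_xy)
    plant_fields["vpd"] = surfaces["vpd"].at(plant_xy) if "vpd" in surfaces else None
    if plant_fields["vpd"] is None:
        plant_fields.pop("vpd")
    for extra, col in (
        ("rosette_field", "rosette_diameter"),
        ("herbivory_field", "rosette_herbivory"),
        ("dandelion_field", "dandelion_density"),
    ):
        if extra in surfaces:
            z = surfaces[extra]
            zz = z.at(plant_xy)
            plant_fields[col] = (zz - zz.mean()) / zz.std(ddof=1)
    # soil moisture at plants is regenerated causally from elevation inside
    # simulate_traits, sharing the residual surface for spatial coherence
    plant_fields["soil_moisture"] = (
        surfaces["soil_moisture_resid"].at(plant_xy)
        if "soil_moisture_resid" in surfaces
        else np.zeros(len(plant_xy))
    )

    plants = simulate_traits(plant_xy, plant_fields, config, seed=seeds[4])
    ordered = [c for c in PLANT_COLUMNS if c in plants.columns]
    plants = plants[ordered + [c for c in plants.columns if c not in ordered]]

    env_xy = rng_sites.uniform((0, 0), (domain.width, domain.height),
                               size=(config.n_env_sites, 2))
    env_sites = pd.DataFrame(
        {
            "x": env_xy[:, 0],
            "y": env_xy[:, 1],
            "elevation": surfaces["elevation"].at(env_xy),
            "soil_moisture": surfaces["soil_moisture"].at(env_xy),
            "vpd": surfaces["vpd"].at(env_xy) if "vpd" in surfaces else 0.0,
        }
    )
    return plants, env_sites, surfaces, config


def default_edges_signed(config: TruthConfig) -> list[tuple[str, str, float]]:
    return config.signed_effects()
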