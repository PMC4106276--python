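"""Calibration and recovery experiments over synthetic ground truth.

These functions tie the generator to the inference modules: each one
simulates data whose truth is known, runs the corresponding estimator, and
returns the recovery or calibration rate.  They back both the test suite
and the reproduction script; problem sizes are arguments so callers choose
their compute budget explicitly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import geostat, mantel as mantel_mod, pathnet, synth

__all__ = [
    "phi_recovery_rate",
    "mantel_type1_error",
    "correlogram_range_recovery",
    "correlogram_null_first_bin_rate",
    "loo_calibration",
    "network_recovery",
    "NULL_EDGES",
]


def _seeds(master: int, k: int) -> list[int]:
    ss = np.random.SeedSequence(master)
    return [int(s.generate_state(1)[0] & 0x7FFFFFFF) for s in ss.spawn(k)]


def phi_recovery_rate(
    n_reps: int = 20,
    n: int = 150,
    truth: geostat.GPParams = geostat.GPParams(beta=0.0, sigma2=1.0, phi=5.0, tau2_rel=0.25),
    grid: geostat.ParameterGrid | None = None,
    domain: tuple[float, float] = (40.0, 50.0),
    seed: int = 0,
) -> float:
    """Fraction of replicates whose marginal posterior mode of phi lands
    within one grid cell of the truth's nearest grid value."""
    grid = grid or geostat.ParameterGrid.default()
    true_idx = int(np.argmin(np.abs(np.log(grid.phi_support) - np.log(truth.phi))))
    hits = 0
    for s in _seeds(seed, n_reps):
        rng = np.random.default_rng(s)
        loc = rng.uniform((0, 0), domain, size=(n, 2))
        fld = synth.simulate_grf(loc, truth, seed=rng.integers(2**31))
        table = geostat.log_marginal_posterior(fld, grid)
        mode = table.marginal_phi_mode()
        mode_idx = int(np.argmin(np.abs(grid.phi_support - mode)))
        hits += abs(mode_idx - true_idx) <= 1
    return hits / n_reps


def mantel_type1_error(
    n_sims: int = 500, n: int = 30, n_perm: int = 999, alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Rejection rate of the simple Mantel test on independent variables."""
    rejections = 0
    for s in _seeds(seed, n_sims):
        rng = np.random.default_rng(s)
        da = mantel_mod.euclidean_dmat(rng.standard_normal(n))
        db = mantel_mod.euclidean_dmat(rng.standard_normal(n))
        res = mantel_mod.mantel(da, db, n_perm=n_perm, seed=int(rng.integers(2**31)))
        rejections += res.p_value <= alpha
    return rejections / n_sims


def correlogram_range_recovery(
    n_seeds: int = 20,
    n: int = 234,
    phi: float = 4.0,
    band: tuple[float, float] = (6.0, 24.0),
    n_perm: int = 999,
    domain: tuple[float, float] = (40.0, 50.0),
    seed: int = 0,
) -> float:
    """Fraction of GRF realizations (effective range 3 phi) whose estimated
    correlogram range falls inside ``band`` meters."""
    params = geostat.GPParams(beta=0.0, sigma2=1.0, phi=phi, tau2_rel=0.1)
    hits = 0
    for s in _seeds(seed, n_seeds):
        rng = np.random.default_rng(s)
        loc = rng.uniform((0, 0), domain, size=(n, 2))
        fld = synth.simulate_grf(loc, params, seed=int(rng.integers(2**31)))
        geo = mantel_mod.euclidean_dmat(loc)
        dm = mantel_mod.euclidean_dmat(mantel_mod.standardize(fld.values))
        cg = mantel_mod.correlogram(dm, geo, n_perm=n_perm,
                                    seed=int(rng.integers(2**31)))
        if cg.range_m is not None and band[0] <= cg.range_m <= band[1]:
            hits += 1
    return hits / n_seeds


def correlogram_null_first_bin_rate(
    n_sims: int = 500, n: int = 234, n_perm: int = 999, alpha: float = 0.05,
    domain: tuple[float, float] = (40.0, 50.0), seed: int = 0,
) -> float:
    """First-bin significance rate for spatially unstructured (i.i.d.) data;
    should sit near the nominal alpha."""
    hits = 0
    for s in _seeds(seed, n_sims):
        rng = np.random.default_rng(s)
        loc = rng.uniform((0, 0), domain, size=(n, 2))
        geo = mantel_mod.euclidean_dmat(loc)
        dm = mantel_mod.euclidean_dmat(mantel_mod.standardize(rng.standard_normal(n)))
        cg = mantel_mod.correlogram(dm, geo, max_lag=2.5, n_perm=n_perm,
                                    seed=int(rng.integers(2**31)), min_pairs=1)
        hits += bool(cg.bins["p_value"].iloc[0] <= alpha)
    return hits / n_sims


def loo_calibration(
    n_reps: int = 4,
    n: int = 100,
    truth: geostat.GPParams = geostat.GPParams(beta=2.0, sigma2=1.0, phi=5.0, tau2_rel=0.25),
    grid: geostat.ParameterGrid | None = None,
    domain: tuple[float, float] = (40.0, 50.0),
    seed: int = 0,
) -> dict:
    """Pooled LOO calibration on model-simulated data.

    Returns the pooled mean and SD of standardized residuals and the
    empirical coverage of central 90% predictive intervals.
    """
    grid = grid or geostat.ParameterGrid.default()
    frames = []
    for s in _seeds(seed, n_reps):
        rng = np.random.default_rng(s)
        loc = rng.uniform((0, 0), domain, size=(n, 2))
        fld = synth.simulate_grf(loc, truth, seed=int(rng.integers(2**31)))
        frames.append(geostat.loo_validate(fld, grid, mode="refit", ci_level=0.90))
    pooled = pd.concat(frames, ignore_index=True)
    return {
        "resid_mean": float(pooled["std_resid"].mean()),
        "resid_sd": float(pooled["std_resid"].std(ddof=1)),
        "coverage90": float(pooled["covered"].mean()),
        "n_points": len(pooled),
    }


# Hypothesized edges that are causally absent from the default generator:
# each is declared with a direction and sign, so a correct analysis should
# fail to retain them.
NULL_EDGES = [
    ("elevation", "fruit_number", True, "-"),
    ("elevation", "stalk_herbivory", True, "+"),
    ("vpd", "rosette_diameter", True, "-"),
    ("vpd", "stalk_number", True, "+"),
    ("vpd", "goldenrod_density", True, "+"),
    ("soil_moisture", "stalk_diameter", True, "+"),
    ("soil_moisture", "rosette_herbivory", True, "-"),
    ("goldenrod_density", "fruit_number", True, "-"),
    ("goldenrod_density", "rosette_herbivory", True, "+"),
    ("stalk_diameter", "fruit_number", True, "+"),
]


def network_recovery(
    n_seeds: int = 10,
    n_perm: int = 999,
    n_boot: int = 100,
    corr_perm: int = 299,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Network recovery against the default generator truth.

    For each seed a full synthetic study is generated, autocorrelation
    ranges are estimated per variable, and a hypothesis set of the four
    true signed edges plus the declared null edges is evaluated.  A seed
    succeeds when all true edges are retained with the correct sign and at
    least 90% of the null edges are not retained.
    """
    truth_cfg = synth.default_truth_config()
    true_edges = [(s_, t_, True, sign) for s_, t_, sign, _ in truth_cfg.edge_list]
    edge_spec = true_edges + NULL_EDGES
    variables = sorted(
        {e[0] for e in edge_spec} | {e[1] for e in edge_spec}
    )
    per_seed = []
    for s in _seeds(seed, n_seeds):
        cfg = synth.default_truth_config(seed=s)
        plants, env, surfaces, cfg = synth.generate_study(cfg)
        rng = np.random.default_rng(s)
        geo = mantel_mod.euclidean_dmat(plants[["x", "y"]].to_numpy(), "space")
        ranges = {}
        for var in variables:
            dm = mantel_mod.euclidean_dmat(
                mantel_mod.standardize(plants[var].to_numpy(), var), var
            )
            cg = mantel_mod.correlogram(dm, geo, n_perm=corr_perm,
                                        seed=int(rng.integers(2**31)), alpha=alpha)
            ranges[var] = cg.range_m
        hyps = pathnet.build_hypotheses(variables, edge_spec)
        net = pathnet.evaluate_network(
            plants, hyps, ranges, n_perm=n_perm, n_boot=n_boot,
            alpha=alpha, seed=int(rng.integers(2**31)),
        )
        by_pair = {(e.source, e.target): e for e in net.edges}
        true_ok = all(
            by_pair[(s_, t_)].retained and by_pair[(s_, t_)].sign == sign
            for s_, t_, sign, _ in cfg.edge_list
        )
        n_null_kept = sum(by_pair[(a, b)].retained for a, b, _, _ in NULL_EDGES)
        null_ok = (1 - n_null_kept / len(NULL_EDGES)) >= 0.90
        per_seed.append(
            {"true_edges_ok": true_ok, "null_kept": n_null_kept,
             "success": true_ok and null_ok}
        )
    df = pd.DataFrame(per_seed)
    return {
        "success_rate": float(df["success"].mean()),
        "true_edge_rate": float(df["true_edges_ok"].mean()),
        "null_retention_rate": float(df["null_kept"].sum() / (len(NULL_EDGES) * n_seeds)),
        "per_seed": per_seed,
    }
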