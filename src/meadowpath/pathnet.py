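"""Mantel path analysis: evaluate a pre-declared hypothesis network of
directed and bidirectional relations among variables with partial Mantel
tests, conditioning on the other linked variables and on geographic space
whenever either endpoint is spatially autocorrelated.

Directionality is declarative metadata: the Mantel statistic is symmetric,
so an arrow encodes prior ecological knowledge (relief drives moisture,
stalks drive fruit set), not a statistical asymmetry.

A dissimilarity matrix built from a single variable is sign-blind: if
y = -x the two Euclidean distance matrices coincide and the Mantel r is +1,
so a negative association raises the Mantel statistic exactly like a
positive one.  Each edge is therefore tested one-tailed "greater" on the
partial Mantel statistic when a sign is declared (two-tailed otherwise),
while the reported sign of the relationship comes from the value-scale
partial Pearson correlation of the standardized variables, residualized on
the same conditioning variables.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .mantel import bootstrap_ci, euclidean_dmat, partial_mantel, standardize

__all__ = [
    "PathHypothesis",
    "PathEdge",
    "PathNetwork",
    "build_hypotheses",
    "evaluate_network",
    "export_network",
    "load_network",
]


@dataclass(frozen=True)
class PathHypothesis:
    """One edge of the hypothesis graph, with its conditioning set."""

    source: str
    target: str
    directed: bool = True
    expected_sign: str | None = None  # "+", "-", or None
    conditioning: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.source == self.target:
            raise ValueError(f"self-edge on {self.source!r}")
        if self.directed and self.expected_sign not in ("+", "-"):
            raise ValueError(
                f"directed edge {self.source}->{self.target} needs an expected sign"
            )
        if self.source in self.conditioning or self.target in self.conditioning:
            raise ValueError("conditioning set must exclude the edge endpoints")


@dataclass
class PathEdge:
    """One evaluated hypothesis: the partial Mantel statistic ``r`` with
    its permutation p-value and bootstrap CI, and the value-scale partial
    correlation ``value_r`` carrying the sign of the relationship."""

    source: str
    target: str
    directed: bool
    r: float
    p_value: float
    ci90: tuple[float, float]
    sign: str
    space_included: bool
    conditioning: tuple[str, ...]
    retained: bool
    value_r: float = float("nan")


@dataclass
class PathNetwork:
    """Machine-readable interaction network: nodes with autocorrelation
    ranges, and all tested edges (retained ones satisfy p <= alpha)."""

    nodes: dict  # variable -> autocorrelation range in meters, or None
    edges: list  # list[PathEdge], every tested hypothesis
    alpha: float = 0.05

    @property
    def retained_edges(self) -> list:
        return [e for e in self.edges if e.retained]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "source": e.source,
                    "target": e.target,
                    "directed": e.directed,
                    "r": e.r,
                    "p_value": e.p_value,
                    "ci_lo": e.ci90[0],
                    "ci_hi": e.ci90[1],
                    "sign": e.sign,
                    "value_r": e.value_r,
                    "space_included": e.space_included,
                    "conditioning": ";".join(e.conditioning),
                    "retained": e.retained,
                }
                for e in self.edges
            ]
        )


def build_hypotheses(variables, edge_spec, conditioning_mode: str = "adjacent"):
    """Compile a declarative edge list into testable hypotheses.

    ``edge_spec`` entries are (source, target, directed, sign) tuples or
    dicts with those keys.  The conditioning set of an edge is, by default,
    every variable adjacent to either endpoint elsewhere in the hypothesis
    graph (``"adjacent"``); ``"all"`` conditions on all other variables.
    """
    if conditioning_mode not in ("adjacent", "all"):
        raise ValueError(f"unknown conditioning mode {conditioning_mode!r}")
    variables = list(variables)
    parsed = []
    seen = set()
    for e in edge_spec:
        if isinstance(e, dict):
            src, tgt = e["source"], e["target"]
            directed = bool(e.get("directed", True))
            sign = e.get("sign")
        else:
            src, tgt, directed, sign = e
        for v in (src, tgt):
            if v not in variables:
                raise ValueError(f"unknown variable {v!r} in edge {src}->{tgt}")
        key = frozenset((src, tgt))
        if key in seen:
            raise ValueError(f"duplicate edge between {src!r} and {tgt!r}")
        seen.add(key)
        parsed.append((src, tgt, directed, sign))

    adjacency: dict[str, set] = {v: set() for v in variables}
    for src, tgt, *_ in parsed:
        adjacency[src].add(tgt)
        adjacency[tgt].add(src)

    hypotheses = []
    for src, tgt, directed, sign in parsed:
        if conditioning_mode == "all":
            cond = [v for v in variables if v not in (src, tgt)]
        else:
            cond = sorted(
                (adjacency[src] | adjacency[tgt]) - {src, tgt}
            )
        hypotheses.append(
            PathHypothesis(
                source=src,
                target=tgt,
                directed=directed,
                expected_sign=sign,
                conditioning=tuple(cond),
            )
        )
    return hypotheses


def _dmat_for(values, name: str):
    arr = np.asarray(values)
    if not np.issubdtype(arr.dtype, np.number):
        return euclidean_dmat(arr, name)
    return euclidean_dmat(standardize(arr, name), name)


def _partial_value_corr(data: pd.DataFrame, source: str, target: str,
                        conditioning) -> float:
    """Signed partial Pearson correlation on the value scale.

    Numeric conditioning variables enter standardized; categorical ones as
    dummy indicators.  Returns NaN when either endpoint is categorical
    (no value-scale sign exists for a label variable).
    """
    cols = []
    for v in (source, target):
        arr = data[v].to_numpy()
        if not np.issubdtype(np.asarray(arr).dtype, np.number):
            return float("nan")
        cols.append(standardize(arr, v))
    design = [np.ones(len(data))]
    for c in conditioning:
        arr = data[c].to_numpy()
        if np.issubdtype(np.asarray(arr).dtype, np.number):
            design.append(standardize(arr, c))
        else:
            dummies = pd.get_dummies(pd.Series(arr), drop_first=True)
            design.extend(dummies.to_numpy(dtype=float).T)
    x = np.column_stack(design)
    resid = []
    for y in cols:
        coef, *_ = np.linalg.lstsq(x, y, rcond=None)
        resid.append(y - x @ coef)
    denom = np.linalg.norm(resid[0]) * np.linalg.norm(resid[1])
    if denom == 0:
        return float("nan")
    return float(resid[0] @ resid[1] / denom)


def evaluate_network(
    data: pd.DataFrame,
    hypotheses,
    ranges: dict,
    coords=None,
    n_perm: int = 10000,
    n_boot: int = 1000,
    ci_level: float = 0.90,
    alpha: float = 0.05,
    seed=None,
) -> PathNetwork:
    """Test every hypothesis with a partial Mantel test and assemble the network.

    ``data`` holds one column per variable (the ``line`` column, or any
    non-numeric column, enters as a 0/1 mismatch matrix; numeric columns are
    standardized before Euclidean distances).  ``ranges`` maps each variable
    to its correlogram autocorrelation range (meters) or None; the geographic
    distance matrix joins the partials of an edge iff either endpoint has a
    non-None range.  Coordinates default to the ``x``/``y`` columns.
    Variables with zero spread are dropped with a warning, silently removing
    the hypotheses that touch them.
    """
    if coords is None:
        coords = data[["x", "y"]].to_numpy()
    coords = np.asarray(coords, dtype=float)
    rng = np.random.default_rng(seed)

    needed = sorted(
        {h.source for h in hypotheses}
        | {h.target for h in hypotheses}
        | {c for h in hypotheses for c in h.conditioning}
    )
    dmats = {}
    dropped = set()
    for var in needed:
        if var not in data.columns:
            raise ValueError(f"variable {var!r} missing from the dataset")
        try:
            dmats[var] = _dmat_for(data[var].to_numpy(), var)
        except ValueError:
            warnings.warn(f"variable {var!r} has zero spread; dropping it")
            dropped.add(var)
    geo = euclidean_dmat(coords, "space")

    edges = []
    for h in hypotheses:
        if h.source in dropped or h.target in dropped:
            continue
        cond = [c for c in h.conditioning if c not in dropped]
        partials = [dmats[c] for c in cond]
        space = (ranges.get(h.source) is not None) or (ranges.get(h.target) is not None)
        if space:
            partials = partials + [geo]
        tail = "greater" if h.expected_sign in ("+", "-") else "two-sided"
        sub_seed = int(rng.integers(0, 2**31 - 1))
        res = partial_mantel(
            dmats[h.source], dmats[h.target], partials,
            n_perm=n_perm, seed=sub_seed, tail=tail,
        )
        ci = bootstrap_ci(
            dmats[h.source], dmats[h.target], [dmats[c] for c in cond] + ([geo] if space else []),
            n_boot=n_boot, level=ci_level, seed=sub_seed + 1,
        )
        value_r = _partial_value_corr(data, h.source, h.target, cond)
        sign = ("+" if value_r >= 0 else "-") if np.isfinite(value_r) else (
            "+" if res.r >= 0 else "-"
        )
        edges.append(
            PathEdge(
                source=h.source,
                target=h.target,
                directed=h.directed,
                r=res.r,
                p_value=res.p_value,
                ci90=ci,
                sign=sign,
                value_r=value_r,
                space_included=space,
                conditioning=tuple(cond),
                retained=res.p_value <= alpha,
            )
        )
    nodes = {v: ranges.get(v) for v in needed if v not in dropped}
    return PathNetwork(nodes=nodes, edges=edges, alpha=alpha)


def export_network(net: PathNetwork, path) -> None:
    """Write the network to JSON; :func:`load_network` round-trips it."""
    payload = {
        "alpha": net.alpha,
        "nodes": net.nodes,
        "edges": [
            {**asdict(e), "ci90": list(e.ci90), "conditioning": list(e.conditioning)}
            for e in net.edges
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_network(path) -> PathNetwork:
    with open(path) as fh:
        payload = json.load(fh)
    edges = [
        PathEdge(
            source=e["source"],
            target=e["target"],
            directed=e["directed"],
            r=e["r"],
            p_value=e["p_value"],
            ci90=tuple(e["ci90"]),
            sign=e["sign"],
            value_r=e.get("value_r", float("nan")),
            space_included=e["space_included"],
            conditioning=tuple(e["conditioning"]),
            retained=e["retained"],
        )
        for e in payload["edges"]
    ]
    return PathNetwork(nodes=payload["nodes"], edges=edges, alpha=payload["alpha"])
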