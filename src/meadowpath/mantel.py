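"""Distance-matrix inference: simple and partial Mantel permutation tests,
piecewise Mantel correlograms, autocorrelation-range detection and bootstrap
confidence intervals.

All statistics operate on the n(n-1)/2 upper-triangle entries of symmetric
dissimilarity matrices.  Permutation null distributions come from joint
row/column relabelings, which preserve the multiset of off-diagonal entries
— so each permuted statistic reduces to a dot product with a pre-normalized
reference vector.  P-values use the add-one estimator
(exceedances + 1) / (n_perm + 1), which is never exactly zero.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "DistanceMatrix",
    "MantelResult",
    "CorrelogramResult",
    "standardize",
    "euclidean_dmat",
    "mantel",
    "partial_mantel",
    "correlogram",
    "autocorr_range",
    "bootstrap_ci",
]

_PERM_CHUNK = 256  # permutations vectorized per block


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative dissimilarity matrix with zero diagonal."""

    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.all(np.isfinite(v)):
            raise ValueError(f"non-finite entries in distance matrix {self.label!r}")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError(f"distance matrix {self.label!r} is not symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValueError(f"distance matrix {self.label!r} has nonzero diagonal")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def condensed(self) -> np.ndarray:
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]


@dataclass
class MantelResult:
    r: float
    p_value: float
    n_perm: int
    tail: str
    ci90: tuple[float, float] | None = None
    partials: list[str] = dc_field(default_factory=list)


@dataclass
class CorrelogramResult:
    """Per-lag-bin Mantel statistics and the derived autocorrelation range."""

    bins: pd.DataFrame  # lower, upper, midpoint, n_pairs, mantel_r, p_value, significant, usable
    range_m: float | None
    truncated: bool = False
    lag_width: float = 2.5
    alpha: float = 0.05


def _as_square(d) -> np.ndarray:
    if isinstance(d, DistanceMatrix):
        return d.values
    return DistanceMatrix(np.asarray(d, dtype=float)).values


def standardize(values, name: str = "") -> np.ndarray:
    """Center to mean 0 and scale to sample SD 1 (ddof = 1)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError(f"need at least 2 values to standardize {name!r}")
    sd = v.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError(f"variable {name!r} has zero spread; cannot standardize")
    return (v - v.mean()) / sd


def euclidean_dmat(data, label: str = "") -> DistanceMatrix:
    """Euclidean dissimilarity over one or more columns, or coordinates.

    A 1-d numeric column yields absolute differences; an (n, k) array the
    k-dimensional Euclidean distance (coordinates in meters give geographic
    distance).  Categorical (non-numeric) labels yield the 0/1 mismatch
    matrix: 0 for same label, 1 otherwise.
    """
    arr = np.asarray(data)
    if arr.ndim == 1 and not np.issubdtype(arr.dtype, np.number):
        same = arr[:, None] == arr[None, :]
        return DistanceMatrix(1.0 - same.astype(float), label)
    arr = np.asarray(arr, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    if arr.ndim != 2:
        raise ValueError("data must be 1-d or 2-d")
    if len(arr) < 3:
        raise ValueError(f"need at least 3 units, got {len(arr)}")
    return DistanceMatrix(squareform(pdist(arr)), label)


def _normalize(x: np.ndarray) -> np.ndarray:
    """Center and scale to unit norm, so corr(a, b) = a_hat . b_hat."""
    c = x - x.mean()
    nrm = np.linalg.norm(c)
    if nrm == 0:
        raise ValueError("zero variance over off-diagonal entries")
    return c / nrm


def _permuted_dots(b_sq, refs, n_perm, rng):
    """Statistics of permuted relabelings of ``b_sq`` against reference vectors.

    ``refs`` is a (k, n_pairs) array of unit-norm centered references; the
    permuted condensed vector of b shares the observed mean and norm, so the
    per-permutation correlation with each reference is a single dot product.
    Returns the observed statistics and exceedance counts for each tail.
    """
    n = b_sq.shape[0]
    iu_i, iu_j = np.triu_indices(n, k=1)
    b_cond = b_sq[iu_i, iu_j]
    mean, nrm = b_cond.mean(), np.linalg.norm(b_cond - b_cond.mean())
    obs = refs @ ((b_cond - mean) / nrm)
    ge = np.zeros(len(refs), dtype=int)
    le = np.zeros(len(refs), dtype=int)
    abs_ge = np.zeros(len(refs), dtype=int)
    done = 0
    while done < n_perm:
        k = min(_PERM_CHUNK, n_perm - done)
        perms = np.argsort(rng.random((k, n)), axis=1)
        gathered = b_sq[perms[:, iu_i], perms[:, iu_j]]  # (k, n_pairs)
        stats = ((gathered - mean) / nrm) @ refs.T  # (k, n_refs)
        ge += np.sum(stats >= obs[None, :] - 1e-12, axis=0)
        le += np.sum(stats <= obs[None, :] + 1e-12, axis=0)
        abs_ge += np.sum(np.abs(stats) >= np.abs(obs)[None, :] - 1e-12, axis=0)
        done += k
    return obs, ge, le, abs_ge


def _p_from_counts(obs, ge, le, abs_ge, n_perm, tail):
    if tail == "greater":
        cnt = ge
    elif tail == "less":
        cnt = le
    elif tail == "two-sided":
        cnt = abs_ge
    else:
        raise ValueError(f"unknown tail {tail!r}")
    return (cnt + 1.0) / (n_perm + 1.0)


def _exact_p(a_hat, b_sq, obs, tail):
    """Full enumeration over all n! joint relabelings (n <= 7)."""
    n = b_sq.shape[0]
    iu_i, iu_j = np.triu_indices(n, k=1)
    b_cond = b_sq[iu_i, iu_j]
    mean, nrm = b_cond.mean(), np.linalg.norm(b_cond - b_cond.mean())
    stats = []
    for perm in itertools.permutations(range(n)):
        p = np.array(perm)
        stats.append(a_hat @ ((b_sq[p[iu_i], p[iu_j]] - mean) / nrm))
    stats = np.array(stats)
    if tail == "greater":
        cnt = np.sum(stats >= obs - 1e-12)
    elif tail == "less":
        cnt = np.sum(stats <= obs + 1e-12)
    else:
        cnt = np.sum(np.abs(stats) >= abs(obs) - 1e-12)
    return cnt / len(stats)


def mantel(dA, dB, n_perm: int = 10000, seed=None, tail: str = "greater",
           exact: bool = False) -> MantelResult:
    """Simple Mantel test between two distance matrices.

    r is the Pearson correlation of the upper-triangle entries; the
    permutation null jointly relabels rows and columns of ``dB``.  With
    ``exact=True`` (n <= 7) all n! relabelings are enumerated and the
    p-value is the exact tail proportion.
    """
    a_sq, b_sq = _as_square(dA), _as_square(dB)
    if a_sq.shape != b_sq.shape:
        raise ValueError("distance matrices must have matching size")
    n = a_sq.shape[0]
    iu = np.triu_indices(n, k=1)
    a_hat = _normalize(a_sq[iu])
    b_hat = _normalize(b_sq[iu])
    r = float(a_hat @ b_hat)
    if exact:
        if n > 7:
            raise ValueError("exact enumeration only supported for n <= 7")
        p = _exact_p(a_hat, b_sq, r, tail)
        return MantelResult(r=r, p_value=p, n_perm=math.factorial(n), tail=tail)
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    obs, ge, le, abs_ge = _permuted_dots(b_sq, a_hat[None, :], n_perm, rng)
    p = float(_p_from_counts(obs, ge, le, abs_ge, n_perm, tail)[0])
    return MantelResult(r=r, p_value=p, n_perm=n_perm, tail=tail)


def _residualize(y: np.ndarray, x_cols: list[np.ndarray]) -> np.ndarray:
    """Residuals of y on the partial columns plus an intercept.

    A partial that is constant (collinear with the intercept only) is
    harmless and ignored; collinearity among the centered partials is an
    error.
    """
    centered = []
    for c in x_cols:
        cc = c - c.mean()
        if np.linalg.norm(cc) > 1e-10 * np.sqrt(len(c)):
            centered.append(cc)
    if len(centered) > 1:
        cond = np.linalg.cond(np.column_stack(centered))
        if cond > 1e10:
            raise ValueError(
                f"collinear conditioning matrices (condition number {cond:.3g})"
            )
    x = np.column_stack([np.ones_like(y)] + centered)
    coef, *_ = np.linalg.lstsq(x, y, rcond=None)
    return y - x @ coef


def partial_mantel(dA, dB, partials, n_perm: int = 10000, seed=None,
                   tail: str = "greater",
                   method: str = "permute_residuals") -> MantelResult:
    """Partial Mantel test of dA ~ dB conditioned on the partial matrices.

    Upper triangles of dA and dB are each residualized by least squares on
    the partials (intercept included); r is the Pearson correlation of the
    residuals.  The default null permutes the residualized dB matrix
    (rows/columns jointly); ``method="permute_raw"`` instead permutes the
    raw dB and re-residualizes per permutation.  With an empty partial
    list the result equals the simple Mantel test.
    """
    a_sq, b_sq = _as_square(dA), _as_square(dB)
    part_sq = [_as_square(p) for p in partials]
    if any(p.shape != a_sq.shape for p in part_sq) or a_sq.shape != b_sq.shape:
        raise ValueError("all matrices must share the same size")
    n = a_sq.shape[0]
    iu = np.triu_indices(n, k=1)
    part_cols = [p[iu] for p in part_sq]
    ra = _residualize(a_sq[iu], part_cols)
    rb = _residualize(b_sq[iu], part_cols)
    a_hat = _normalize(ra)
    r = float(a_hat @ _normalize(rb))
    rng = np.random.default_rng(seed)
    if method == "permute_residuals":
        rb_sq = np.zeros_like(b_sq)
        rb_sq[iu] = rb
        rb_sq += rb_sq.T
        obs, ge, le, abs_ge = _permuted_dots(rb_sq, a_hat[None, :], n_perm, rng)
        p = float(_p_from_counts(obs, ge, le, abs_ge, n_perm, tail)[0])
    elif method == "permute_raw":
        ge = le = abs_ge = 0
        for _ in range(n_perm):
            perm = rng.permutation(n)
            rb_p = _residualize(b_sq[np.ix_(perm, perm)][iu], part_cols)
            stat = a_hat @ _normalize(rb_p)
            ge += stat >= r - 1e-12
            le += stat <= r + 1e-12
            abs_ge += abs(stat) >= abs(r) - 1e-12
        cnt = {"greater": ge, "less": le, "two-sided": abs_ge}[tail]
        p = (cnt + 1.0) / (n_perm + 1.0)
    else:
        raise ValueError(f"unknown method {method!r}")
    return MantelResult(
        r=r, p_value=p, n_perm=n_perm, tail=tail,
        partials=[getattr(pm, "label", "") for pm in partials],
    )


def correlogram(dData, dGeo, lag_width: float = 2.5, max_lag: float | None = None,
                n_perm: int = 10000, seed=None, alpha: float = 0.05,
                min_pairs: int = 20) -> CorrelogramResult:
    """Piecewise Mantel correlogram over half-open geographic lag bins.

    For each bin [k w, (k+1) w) the statistic is the negated Mantel
    correlation between ``dData`` and the bin's 0/1 pair-indicator matrix,
    so positive values read as positive spatial autocorrelation (pairs
    within the bin are more similar than average).  Per-bin one-tailed
    (greater) p-values come from joint relabelings of ``dData`` shared
    across bins.  Bins with fewer than ``min_pairs`` pairs are flagged
    unusable and excluded from range detection.
    """
    if lag_width <= 0:
        raise ValueError("lag_width must be positive")
    data_sq, geo_sq = _as_square(dData), _as_square(dGeo)
    if data_sq.shape != geo_sq.shape:
        raise ValueError("data and geographic matrices must match")
    n = data_sq.shape[0]
    iu = np.triu_indices(n, k=1)
    g = geo_sq[iu]
    if max_lag is None:
        max_lag = g.max() / 2.0
    if max_lag < lag_width:
        raise ValueError("max_lag smaller than one lag width: no bins")
    n_bins = int(np.ceil(max_lag / lag_width - 1e-9))
    edges = np.arange(n_bins + 1) * lag_width
    rows = []
    refs, ref_bins = [], []
    for k in range(n_bins):
        lo, hi = edges[k], edges[k + 1]
        ind = ((g >= lo) & (g < hi)).astype(float)
        npairs = int(ind.sum())
        rows.append(
            {
                "lower": lo,
                "upper": hi,
                "midpoint": (lo + hi) / 2.0,
                "n_pairs": npairs,
                "mantel_r": np.nan,
                "p_value": np.nan,
                "significant": False,
                "usable": npairs >= min_pairs,
            }
        )
        if 0 < npairs < len(ind):  # indicator has variance
            refs.append(-_normalize(ind))  # negated: positive = autocorrelation
            ref_bins.append(k)
    if refs:
        rng = np.random.default_rng(seed)
        obs, ge, le, abs_ge = _permuted_dots(data_sq, np.array(refs), n_perm, rng)
        p = _p_from_counts(obs, ge, le, abs_ge, n_perm, "greater")
        for j, k in enumerate(ref_bins):
            rows[k]["mantel_r"] = float(obs[j])
            rows[k]["p_value"] = float(p[j])
            rows[k]["significant"] = bool(p[j] <= alpha)
    bins = pd.DataFrame(rows)
    result = CorrelogramResult(bins=bins, range_m=None, lag_width=lag_width, alpha=alpha)
    result.range_m = autocorr_range(result, alpha)
    return result


def autocorr_range(result: CorrelogramResult, alpha: float = 0.05) -> float | None:
    """Autocorrelation range from the correlogram's significance profile.

    Returns the midpoint of the last bin in the initial consecutive run of
    significant (p <= alpha), positive-statistic, usable bins starting at
    lag zero; None when the first usable bin is not significant.  If every
    usable bin is significant the last midpoint is returned and the result
    is marked truncated (the true range may exceed the tested lags).
    """
    usable = result.bins[result.bins["usable"]].reset_index(drop=True)
    if len(usable) == 0:
        return None
    last = None
    for _, row in usable.iterrows():
        ok = (
            np.isfinite(row["p_value"])
            and row["p_value"] <= alpha
            and row["mantel_r"] > 0
        )
        if not ok:
            break
        last = row["midpoint"]
    else:
        result.truncated = True
    return None if last is None else float(last)


def bootstrap_ci(dA, dB, partials=(), n_boot: int = 1000, level: float = 0.90,
                 seed=None) -> tuple[float, float]:
    """Nonparametric bootstrap percentile CI for the (partial) Mantel r.

    Sample units are resampled with replacement; both matrices (and any
    partials) are rebuilt by row/column subsetting and the statistic is
    recomputed.  Degenerate resamples (zero off-diagonal variance) are
    redrawn, up to a cap of 10x n_boot attempts.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    a_sq, b_sq = _as_square(dA), _as_square(dB)
    part_sq = [_as_square(p) for p in partials]
    n = a_sq.shape[0]
    iu = np.triu_indices(n, k=1)
    rng = np.random.default_rng(seed)
    stats_out = []
    attempts = 0
    while len(stats_out) < n_boot and attempts < 10 * n_boot:
        attempts += 1
        idx = rng.integers(0, n, size=n)
        sel = np.ix_(idx, idx)
        a_c, b_c = a_sq[sel][iu], b_sq[sel][iu]
        try:
            ra = _residualize(a_c, [p[sel][iu] for p in part_sq])
            rb = _residualize(b_c, [p[sel][iu] for p in part_sq])
            stats_out.append(float(_normalize(ra) @ _normalize(rb)))
        except (ValueError, np.linalg.LinAlgError):
            continue  # degenerate resample: redraw
    if len(stats_out) < n_boot:
        raise RuntimeError("too many degenerate bootstrap resamples")
    lo, hi = np.percentile(stats_out, [50 * (1 - level), 100 - 50 * (1 - level)])
    return float(lo), float(hi)
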