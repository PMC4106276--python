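# Methods

## Hierarchical spatial model and discrete-posterior kriging

The geostatistical model is a stationary Gaussian spatial process with an
exponential correlation function:

    Y_i | S ~ N(β + S(x_i), τ²),    S(x) ~ GP(0, σ² exp(−h/Φ)).

The covariance of the observations is σ² exp(−h_ij/Φ) off the diagonal and
σ²(1 + τ²rel) on it, with τ²rel = τ²/σ² the relative nugget. The effective
range — the distance at which correlation falls to exp(−3) ≈ 5% — is 3Φ.

Inference is the discrete-posterior scheme of model-based geostatistics:
(Φ, τ²rel) live on a finite grid with flat priors, while the trend β (flat
prior) and the partial sill σ² (reciprocal prior, p(σ²) ∝ 1/σ²) are
marginalized analytically. Writing V = R + τ²rel·I for the correlation
matrix including the relative nugget, the closed-form log marginal at a
grid point is

    log p(y | Φ, τ²rel) = −((n−1)/2) log 2π − ½ log|V| − ½ log(1ᵀV⁻¹1)
                          + log Γ((n−1)/2) + ((n−1)/2) log 2
                          − ((n−1)/2) log S²,

with S² the generalized-least-squares residual sum of squares. The
conditional laws used for posterior draws are σ² | grid ~ S²/χ²_{n−1} and
β | σ² ~ N(β̂, σ²/(1ᵀV⁻¹1)). The test suite verifies this closed form
against two-dimensional numerical quadrature over (β, σ²) on a small
dataset, and against a naive Cholesky evaluation.

Gridding Φ and τ²rel but not σ² and β is a deliberate design choice: the
reciprocal/flat priors admit exact marginalization, which is both more
accurate and cheaper than adding grid dimensions; the conditional draws
recover the full joint posterior when needed.

**Numerics.** For each Φ the correlation matrix is eigendecomposed once and
every quadratic form in V⁻¹ is evaluated across the whole τ²rel support
from the same eigenbasis (eigenvalues clamped at 1e−12, the spectral
analogue of diagonal jitter). Simulation and per-draw prediction use
Cholesky factorization with an escalating jitter policy: 1e−10 σ² growing
tenfold to at most 1e−6 σ², then failure with a condition diagnostic.

**Defaults.** Φ grid: 20 log-spaced values on [0.5, 25] m; τ²rel grid: 0 to
1 in steps of 0.05; prediction raster 0.5 m; 100,000 posterior draws;
configurable throughout. The default grid resolves Φ to a factor ≈ 1.23 per
cell; the posterior for the range parameter of an exponential covariance is
intrinsically broad at moderate n (only σ²/Φ is well identified under
infill asymptotics), so modal-Φ scatter across replicates spans a few grid
cells at n ≈ 150 even though the posterior itself is exactly computed.

**Prediction** at new locations is the conditional Gaussian per posterior
draw — mean β + rᵀV⁻¹(y − β1), variance σ²(1 + τ²rel − rᵀV⁻¹r) — combined
by the law of total variance across draws. With τ²rel = 0 prediction at a
datum reproduces the observation exactly.

**Leave-one-out validation** refits the discrete posterior for each held-out
point (mode `refit`, default) and evaluates the predictive as the exact
mixture of per-grid-point Student-t distributions (df = n−1) obtained by
marginalizing σ² and β — the same integral a large draw ensemble
approximates, computed without Monte-Carlo error. A `shared` mode reuses
the full-data posterior to restrict the grid first and is used for the
routine per-variable LOO in the pipeline. Outputs include standardized
residuals and the probability integral transform, from which interval
coverage is read directly.

## Mantel machinery

All Mantel statistics are Pearson correlations over the n(n−1)/2
upper-triangle entries of symmetric dissimilarity matrices. Variables are
standardized (mean 0, sample SD 1) before Euclidean distances; categorical
line labels become a 0/1 mismatch matrix. Permutation nulls jointly relabel
rows and columns; because a relabeling permutes the multiset of off-diagonal
entries, each permuted statistic is a single dot product against a
pre-normalized reference vector, and permutations are processed in
vectorized blocks. P-values use (exceedances + 1)/(n_perm + 1); for n ≤ 7
an exact mode enumerates all n! relabelings.

**Partial Mantel tests** residualize both unfolded matrices on the
conditioning matrices (intercept included), correlate the residuals, and
permute the residualized second matrix (the alternative — permute the raw
matrix and re-residualize per permutation — is available as an option). A
constant conditioning matrix is collinear with the intercept and harmless;
collinearity among the centered partials is an error. With no partials the
result equals the simple Mantel test exactly, permutation stream included.

**Correlograms** use half-open lag bins [k·w, (k+1)·w) of width 2.5 m by
default, up to half the maximum pairwise distance. The bin statistic is the
negated Mantel correlation between the data dissimilarity and the bin's
pair-indicator matrix, so positive values read as positive spatial
autocorrelation. One shared set of data-matrix relabelings serves all bins;
per-bin p-values are one-tailed (greater). Bins with fewer than 20 pairs
are excluded from range detection. The autocorrelation range is the
midpoint of the last bin in the initial consecutive run of significant
(p ≤ 0.05), positive bins; none if the first bin is not significant; if
every usable bin is significant the result carries a truncation flag, since
the true range may exceed the tested lags.

**Bootstrap confidence intervals** resample sample units with replacement,
rebuild all matrices by row/column subsetting, recompute the (partial)
Mantel statistic, and take percentile bounds (90% by default). Degenerate
resamples are redrawn up to a cap.

**Tails.** Simple screening correlations are two-tailed. Correlogram bins
and hypothesized network edges are one-tailed greater. No multiple-testing
correction is applied across bins or edges, matching the per-test P = 0.05
convention of this analysis style; a correction can be layered on by the
caller.

## Path analysis

Hypotheses are declared as (source, target, directed, expected sign) edges.
Each edge's conditioning set defaults to the variables adjacent to either
endpoint elsewhere in the hypothesis graph; a mode conditioning on all
other variables is available. Geographic distance joins the partials of an
edge if and only if either endpoint's correlogram shows a non-null
autocorrelation range, making the space-inclusion rule a pure, auditable
function of the correlogram results.

A dissimilarity matrix built from one variable is sign-blind: y = −x yields
the identical distance matrix and Mantel r = +1. A one-tailed test "in the
declared negative direction" on the Mantel statistic would therefore never
fire for a true negative relationship. Signed edges are instead tested
one-tailed greater on the partial Mantel statistic, and the sign reported
for the edge comes from the value-scale partial Pearson correlation of the
standardized variables residualized on the same conditioning set (dummy
coding for categorical conditioners); it is exported as `value_r` alongside
the Mantel coefficient. Direction remains declarative metadata — the
statistic is symmetric.

Edges with p ≤ 0.05 are retained; zero-variance variables are dropped with
a warning rather than failing the network. The network serializes to JSON
and round-trips losslessly.

## Synthetic meadow generator

The generator emulates the statistical structure this analysis assumes,
with the study-shaped defaults: a 40 × 50 m domain, 234 plants, 71
environmental sites.

- **Surfaces** (elevation, soil-moisture residual, vapor pressure deficit,
  plus latent trait fields) are Gaussian random fields with exponential
  correlation, simulated exactly on a 1 m grid and interpolated bilinearly
  to any point. Elevation uses Φ = 8 m, σ² = 4 (≈ meters of relief over the
  meadow); the others Φ = 4–6 m.
- **Plant placement** follows an inhomogeneous point process: intensity
  exp(−0.8·z(elevation) + 0.8·z(soil moisture)) on the grid, realized by
  rejection sampling, so plants concentrate in low, moist ground.
- **Inbred lines**: 12 founder plants are chosen; every plant takes its
  nearest founder's label with probability exp(−d/8 m) and a uniformly
  random line otherwise. Founders guarantee every line occurs; the decay
  scale produces short-range label clustering (correlogram range of a few
  meters) without simulating genetics.
- **Traits** follow a declared acyclic causal graph, built in topological
  order: each variable is its base value, plus its exogenous field
  contribution, plus signed effects times the standardized parent, plus
  Gaussian noise; count variables (stalks, fruits, herbivory holes,
  neighbor densities) are rounded and floored at zero, and children
  condition on the observed counts. Bidirectional relations are generated
  as shared latent noise. The default truth carries four signed edges —
  elevation ⊣ soil moisture, rosette diameter → stalk number, stalk
  herbivory ⊣ fruit number, dandelion density → rosette herbivory — and
  leaves every other column causally unlinked, providing declared null
  edges for recovery experiments.
- **Neighbor counts** use a closed ball (distance ≤ radius, 15 cm
  convention); the default generator draws neighbor-density counts from the
  causal model directly rather than simulating neighbor point patterns.

Effect sizes and noise SDs are chosen for statistical power of the recovery
experiments, not calibrated to any real meadow: no field magnitudes are
available to fit. What the generator does **not** emulate: plant demography
or genetics, insect movement, anisotropy, non-stationary trends,
measurement protocols. Passing tests therefore demonstrate that the
inference machinery recovers the structure of data generated by its own
model class at realistic sizes — not that any particular field system obeys
that model.

## Pipeline and reproducibility

`run_pipeline` executes simulate → krige → sample surfaces at plant
locations (bilinear on the prediction raster; nearest-node mode available)
→ correlograms → pairwise Mantel tests → path network. Every randomized
stage receives a sub-seed derived as CRC-32 of the stage name keyed by the
master seed (logged, below 2³¹), making runs byte-identical under a fixed
master seed; the manifest records per-stage seeds and timings and a SHA-256
digest of every output file, so tampering is detectable by re-hashing.

## Problem sizes in tests and the reproduction script

Calibration and recovery experiments use: 20 replicates at n = 150 for Φ
recovery; 500 null simulations × 999 permutations (n = 30) for Mantel
type-I error; 20 GRF realizations at n = 234 (Φ = 4 m) plus 400 null
simulations for correlogram range recovery and first-bin calibration; 4
replicates at n = 100 with per-fold posterior refits for LOO calibration;
10 full synthetic studies (999 permutations per edge, 100 bootstrap
resamples) for network recovery. These sizes give Monte-Carlo error
comfortably inside the asserted bands while keeping a full run to minutes
on a single core.

## Known limitations

- Only the exponential correlation family, isotropic, with a constant
  trend; no full MCMC (the discrete posterior is the model).
- The range parameter Φ is weakly identified at moderate n; the posterior
  mode scatters across neighboring grid cells even with exact computation.
- The matrix-subsetting bootstrap for Mantel CIs duplicates units (zero
  distances) in resamples; it is the conventional choice but can be
  mildly biased for strong dependence.
- Mantel statistics on univariate Euclidean distances cannot distinguish
  the sign of a relationship; signs are value-scale quantities here.
- The correlogram range estimator is resolution-limited to lag midpoints
  and sensitive to the per-bin significance rule near the range.
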