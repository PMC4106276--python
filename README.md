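# meadowpath

Integrated spatial analysis of plant-community structure: **Bayesian
kriging** of environmental surfaces under a hierarchical Gaussian spatial
process, **piecewise Mantel correlograms** and simple/partial **Mantel
permutation tests**, and **Mantel path analysis** that assembles a directed
abiotic–biotic interaction network with geographic space as a conditioning
variable. Because field data of this kind are rarely deposited, the package
ships a **synthetic-meadow generator** with known ground truth (a 40 × 50 m
domain, 234 plants, 71 environmental sample sites by default) so every
stage can be validated against the structure that produced the data.

It is written for ecologists and biostatisticians who study how topography,
microclimate, limited dispersal, herbivory and neighbor density jointly
shape the distribution and performance of a mapped plant population.

## The models

**Geostatistics.** Observations of a surface variable follow the hierarchy

    Y_i | S ~ N(β + S(x_i), τ²)
    S(x)    ~ GP(0, σ² R(h; Φ)),   R(h; Φ) = exp(−h / Φ)

with constant trend β, partial sill σ², nugget τ² (reported as the relative
nugget τ²rel = τ²/σ²), and correlation scale Φ; the effective range of
spatial autocorrelation is 3Φ (correlation ≈ 5%). Inference puts flat
priors on a discrete (Φ, τ²rel) grid, a flat prior on β and a reciprocal
prior on σ², marginalizing β and σ² analytically at every grid point.
Predictive surfaces mix conditional Gaussian kriging over posterior draws
(100,000 by default) and are validated by leave-one-out cross-validation.

**Distance-matrix inference.** Variables are standardized, converted to
Euclidean dissimilarity matrices (inbred-line labels to a 0/1 mismatch
matrix), and compared with Mantel permutation tests (10,000 joint
row/column relabelings by default, p = (exceedances + 1)/(n_perm + 1)).
The piecewise Mantel correlogram tests 2.5 m lag bins one at a time; the
autocorrelation range is the midpoint of the last bin in the initial run of
significant, positive bins. Partial Mantel tests residualize both matrices
on the conditioning matrices (including geographic distance — "space")
before correlating.

**Path analysis.** A pre-declared hypothesis network (directions fixed by
ecological knowledge: relief drives moisture, stalks drive fruit set) is
evaluated edge by edge with partial Mantel tests, conditioning on the other
linked variables and adding space whenever either endpoint is spatially
autocorrelated. Note that a univariate distance matrix is sign-blind
(y = −x gives Mantel r = +1), so edges are tested one-tailed "greater" on
the Mantel statistic and the reported sign comes from the value-scale
partial Pearson correlation.

## Worked example

```sh
python analysis/01_simulate.py --seed 0
python analysis/02_krige.py --seed 0 --draws 20000 --cell 1.0
python analysis/03_correlograms.py --seed 0 --perms 2000
python analysis/04_mantel_pairs.py --seed 0 --perms 2000 --boot 200
python analysis/05_path_network.py --seed 0 --perms 2000 --boot 200
```

Step 02 reports, per environmental variable, the posterior modal Φ and the
LOO calibration, e.g.

    soil_moisture: modal phi = 7.27 m (autocorrelation range ~21.8 m);
    LOO std-resid mean +0.018, SD 0.926, 90% coverage 0.92

(standardized residuals near mean 0 / SD 1 and ~90% interval coverage mean
the predictive distribution is well calibrated). Step 03 prints each
variable's autocorrelation range — here elevation 8.75 m, line 6.25 m,
several traits none — and step 05 prints the retained network:

    4 of 12 hypothesized edges retained at P <= 0.05:
      elevation -> soil_moisture: - r=0.527 (0.45, 0.59) p=0.0005 | space
      rosette_diameter -> stalk_number: + r=0.672 (0.60, 0.73) p=0.0005 | space
      stalk_herbivory -> fruit_number: - r=0.476 (0.40, 0.54) p=0.0005
      dandelion_density -> rosette_herbivory: + r=0.497 (0.43, 0.58) p=0.0005

These are exactly the four causal edges the generator planted (see
`results/study/truth.json`), with correct signs, 90% bootstrap CIs in
parentheses, and `| space` marking edges whose test conditioned on
geographic distance; the eight hypothesized-but-false edges were pruned.

The same pipeline runs end to end with one command (also available as the
`meadowpath` console script with `simulate`, `krige`, `correlogram`,
`mantel` and `path` subcommands):

```sh
meadowpath all --seed 0 --outdir results/run
```

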