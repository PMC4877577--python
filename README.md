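# gwlasso

Geographically weighted logistic lasso regression for area-based health
indices.

## The problem

Health policy planners rank administrative areas (municipalities, districts)
by indices built from census covariates — weighted sums whose weights come
from a logistic regression of a binary health outcome (e.g. "screening rate
above the national median") on area characteristics.  Classical indices
assume the same weights and the same covariate set everywhere, ignoring both
spatial correlation between neighbouring areas and the fact that different
regions may have different drivers of low coverage.

`gwlasso` drops that homogeneity assumption.  It fits a **geographically
weighted logistic lasso (GWL)**: at every sampled location *i* a local
logistic model

&nbsp;&nbsp;&nbsp;&nbsp;logit μ_j = **x**_j ᵀ **β**_i

is estimated from all observations, weighted by a Gaussian distance-decay
kernel *w_ij* = exp(−½ (d_ij/θ)²), with an L1 penalty λ‖**β**_i‖₁ on the
slopes so each location selects its own sparse covariate set.  The bandwidth
θ and penalty λ are chosen jointly by leave-one-out cross-validation
(held-out binomial deviance), in a two-stage procedure: stage one scans a
(θ, λ) grid with each unit excluded from its own local fit; stage two refits
every location at the selected pair, producing an N × (p+1) sparse
coefficient matrix.

Downstream, the package builds a Gordon-style **coverage index**
ind_i = k · Σ_{m selected} exp(β̂_im) x_im — odds-ratio weights on the
covariates the lasso retained — with the constant k calibrated so the
household-weighted national average of the index matches a known population
rate; validates the index against external rate series by Spearman
correlation; and co-clusters the coefficient matrix with a Gaussian latent
block model to find groups of areas sharing a predictor profile.

A synthetic-data generator with known spatially smooth, sparse coefficient
surfaces (Gaussian-process draws) makes the whole pipeline testable without
any census data.

## Worked example

```python
import numpy as np
from gwlasso import (SimulationConfig, generate_dataset, pairwise_distances,
                     auto_lambda_grid, HyperGrid, select_hyperparameters,
                     fit_gwl, compute_index)

config = SimulationConfig(n=100, p=6, n_active=2, seed=11)
dataset, truth = generate_dataset(config)
D = pairwise_distances(dataset.coords).D

thetas = np.array([1.0, 3.0, 9.0])
lambdas = auto_lambda_grid(dataset, thetas[-1], T=8, D=D)
params, cv = select_hyperparameters(dataset, HyperGrid(thetas, lambdas), D=D)
field = fit_gwl(dataset, params, D=D)
index = compute_index(field.B, dataset, target_average=0.1018)
```

prints (via the obvious `print` statements):

```
selected bandwidth theta = 3, penalty lambda = 0.03364
held-out deviance at the optimum: 123.6
coefficient field: (100, 7), median covariates retained per unit: 4
covariate x5: correlation(true surface, estimate) = 0.86
covariate x6: correlation(true surface, estimate) = 0.73
k = 0.2688; household-weighted index mean = 0.1018
```

Reading: cross-validation picked the middle bandwidth (the data really are
spatially heterogeneous — the global-model limit loses), a typical unit keeps
4 of the 6 candidate covariates, both truly active coefficient surfaces are
recovered with high spatial correlation, and the index is calibrated exactly
to the requested 10.18% household-weighted average, with k the score-to-index
scale factor.

The same pipeline is available from the shell:

```sh
gwlasso simulate --n 100 --p 6 --active 2 --seed 11 --out data.csv
gwlasso fit --input data.csv --outcome-col outcome --households-col households \
            --theta-grid 1,3,9 --lambda-grid auto:8 --out coef.csv --cv-out cv.csv
gwlasso index --input data.csv --outcome-col outcome --households-col households \
              --coef coef.csv --target-average 0.1018 --out index.csv
gwlasso cocluster --coef coef.csv --g 3 --seed 1 --out clusters.csv
gwlasso validate --index index.csv --external rates.csv --out table.csv
```

## Layout

| module | contents |
|---|---|
| `gwlasso.kernel` | pairwise distances (Euclidean/Manhattan/Minkowski/haversine), Gaussian kernel weights |
| `gwlasso.solver` | weighted elastic-net logistic coordinate descent, λ_max, warm-started paths |
| `gwlasso.estimation` | LOO-CV grid/golden-section selection of (θ, λ), final coefficient field |
| `gwlasso.index` | median binarization, standardization, coverage index + k, Spearman validation |
| `gwlasso.cocluster` | Gaussian/Bernoulli latent block model via classification EM |
| `gwlasso.simulate` | synthetic datasets with known GP coefficient surfaces |
| `gwlasso.io` / `gwlasso.cli` | CSV/GeoJSON/metadata readers-writers, `gwlasso` command |

See `docs/methods.md` for the statistical details and design choices.
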