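# Methods

## The model

`pottsmix` treats a spatial transcriptomic experiment as *L* tissue sections
measuring a common set of *P* genes on *N₁ … N_L* cells with known 2-D
coordinates. Two latent labelings are inferred jointly: a cell type
`c_i ∈ {1..C}` per cell and a spatial domain `z_i ∈ {1..R}` per cell. The
hierarchical structure is

1. `x_i | c_i = c ~ Normal(mu_c, Sigma)` — the *J*-dimensional expression
   features of a cell are Gaussian around a type-specific mean, with a single
   covariance `Sigma` shared across types;
2. `c_i | z_i = r ~ Categorical(pi_r)` — the cell type is drawn from the
   composition of the domain the cell sits in;
3. `z^(l) ~ Potts(V^(l), beta)` — the domain labels follow a homogeneous
   Potts model on the per-section kNN graph, with mass function
   `Pr(z) = exp(beta * sum_{i~i'} 1[z_i = z_{i'}]) / Z(beta)`.

A domain is therefore defined by its cell-type composition, not by
homogeneous expression — this is what lets domains containing several
distinct cell types be segmented correctly.

Priors: per feature *j*, the type means are exchangeable with
`mu_{cj} | lambda_j ~ Normal(m_j, lambda_j)` and a Gamma(shape `a`, rate `b`)
prior on the precision `1/lambda_j` (a normal–gamma hierarchy). Under this
parameterization `lambda_j` is the between-type variance of feature *j*: a
large posterior `lambda_j` literally means the feature spreads the type
means far apart, i.e. is informative for clustering. `Sigma` gets an
inverse-Wishart prior, each `pi_r` a symmetric Dirichlet, and
`beta ~ Uniform(0, beta_max)` with `beta_max = 4`: zero means spatial
neighbors carry no information, the upper bound corresponds to extremely
smooth domain boundaries.

## Inference

One systematic scan per iteration:

| step | update | kernel |
|---|---|---|
| 1 | `c` | independent categorical draws, `p(c_i=c) ∝ N(x_i; mu_c, Sigma) * pi_{c, z_i}` |
| 2 | `mu, lambda, Sigma` | conjugate normal / gamma / inverse-Wishart draws |
| 3 | `pi` | per-domain Dirichlet(alpha + n_cr) |
| 4 | `z` | one Swendsen–Wang sweep per section |
| 5 | `beta` | exchange-algorithm Metropolis–Hastings |

**Swendsen–Wang with a field.** Bonds are placed on each monochromatic edge
with probability `1 − exp(−beta)`; the connected clusters of the bond graph
then draw a common new label with probability proportional to
`prod_{i in cluster} pi_{c_i, r}`. With `beta = 0` this reduces to
independent draws from the composition field; with a uniform field it is the
classic pure-Potts SW kernel. Connected components are found with a
union-find compiled by numba; this is the sampler's hot loop.

**Exchange step for beta.** The conditional of `beta` contains the
intractable partition function `Z(beta)`. A Gaussian random-walk proposal
(sd 0.1) reflected into `[0, beta_max]` is accepted with the exchange ratio
`exp((beta' − beta) (S(z) − S(w)))`, where `S` is the monochromatic-edge
count and `w` is an auxiliary configuration simulated at `beta'` by 10
pure-Potts SW sweeps warm-started from the current `z`; the partition
functions cancel. The auxiliary draw is approximate (a perfect sampler is
not used); its adequacy is verified empirically by parameter recovery
(posterior mean 0.99 ± 0.05 for truth 1.0 on a 15×15 lattice) and by
credible-interval calibration over independent Potts draws. With multiple
sections, `beta` is updated from the first section's configuration only; all
other parameters are shared across sections.

**Label switching.** The posterior is invariant to permuting type or domain
labels, so raw draws cannot be averaged. After burn-in, the type chain and
the domain chain are relabeled independently: the pivot starts as the draw
with the highest stored (unnormalized) log joint; every draw is mapped onto
the pivot by the permutation maximizing contingency-table agreement
(Hungarian assignment); the pivot is then refreshed to the per-cell marginal
mode and the pass repeats until total disagreement stops improving (cap 100
passes). The per-draw permutations are applied consistently to the label
vectors, the rows of `mu` and `pi` (types), and the columns of `pi`
(domains). Point estimates: per-cell marginal posterior modes for labels
(ties to the smaller label), posterior means for `pi` (columns
renormalized), `beta`, and `lambda`.

## Preprocessing

Counts are library-size normalized per cell to a common target (default: the
median library size — scale-free and platform-independent), log2(x+1)
transformed, and reduced to the top *J* = 20 principal components of the
gene-centered matrix. Genes are centered but not unit-scaled before PCA:
the features are already on a common log scale. PCA uses a deterministic
full SVD with the sign convention that each component's largest-magnitude
loading is positive, so outputs are bit-reproducible. For multi-section
runs the default alignment standardizes each feature within each section
(location/scale batch correction); a user-supplied alignment callable (e.g.
Harmony) can be plugged in instead via `align_sections(...,
method="external-hook")` — alignment quality is orthogonal to the model's
correctness at the scales tested here, so no integration method is
reimplemented. The spatial graph links each cell to its *k* = 6 nearest
neighbors (near the typical contact number of cells in a 2-D monolayer),
union-symmetrized; distance ties break toward the smaller cell index.
Sensitivity to *k* has not been systematically mapped and *k* is exposed as
a flag.

## Default hyperparameters

| parameter | default | meaning |
|---|---|---|
| `J` | 20 | PCA features |
| `k` | 6 | spatial nearest neighbors |
| `beta_max` | 4 | upper bound of the uniform prior on `beta` |
| `dirichlet_alpha` | 1 | flat prior on compositions |
| `m_j` | per-feature global mean | prior location of type means |
| `lambda_shape`, `lambda_rate` | 2, 1 | gamma prior on `1/lambda_j` (prior mean `lambda` = 1) |
| `wishart_df`, scale | `J + 2`, identity | weakly-informative prior on `Sigma` |
| `n_iter`, `burn_in` | 10 000, 5 000 | chain length (4 000 / 2 000 used in the benchmark scripts) |
| `inner_sweeps` | 10 | auxiliary SW sweeps per exchange step |

All are exposed through `RunConfig` / the CLI. Initialization is k-means on
the features for `c`, k-means on neighborhood-averaged features for `z`,
empirical moments for `mu`/`Sigma`, smoothed empirical composition for `pi`,
and `beta = 1`. Empty clusters simply draw their parameters from the prior;
redundant clusters are allowed to die, which is what makes over-specified
C or R behave gracefully.

## The simulator

The generator emulates a layered cortical tissue: ~1127 cells placed
uniformly in a 5000 × 1000 rectangle, four vertical bands as true domains
(boundaries at width × {0.25, 0.5, 0.75}); additional sections shift each
interior boundary independently by Uniform(±10% of width). Four scenarios
set the domain compositions over four cell types, each domain missing a
different type: I — one type per domain; II — dominant type 0.90, two others
0.05; III — 0.50/0.25/0.25; IV — three types at 1/3 each. Rare-type variants
add 6 or 10 rare types splitting 30% of cells equally (majors keep the
scenario-III 2:1:1 ratio), either dispersed uniformly or each confined to
one domain.

Counts follow the splat recipe: per-gene base means Gamma(0.6, rate 0.3);
per (gene, type) a DE factor LogNormal(location `de_facloc`, scale 0.4) with
probability `de_prob`, up/down with equal probability (down = reciprocal);
type mean profiles normalized to proportions; per-cell library sizes
LogNormal(7.0, 0.3) (≈ 1100 counts per cell, the scale of a few-hundred-gene
in-situ panel); BCV-style overdispersion `bcv = (0.1 + 1/sqrt(mu)) *
sqrt(df/chi2_df)` with df = 60 via gamma mixing; Poisson counts. Baseline:
200 genes, `de_prob` 0.2, `de_facloc` 1.1 (three-fold median change).

**Fidelity caveat.** The original benchmark estimated the splat base
parameters (library size, BCV trend) from real STARmap cells; those
estimates are not public, so this simulator ships generic defaults. Under
them the synthetic data are somewhat cleaner than the calibrated version:
cell types remain nearly separable even at 1.5-fold DE, so benchmark ARIs
here sit at or above the published medians (notably the weak-DE robustness
setting: domain ARI ≈ 0.98 where the calibrated simulation gave 0.90). The
generator also omits splat features the benchmark did not vary: expression
outlier genes, dropout, batch factors, and path/trajectory structure, and
it synthesizes uniform cell positions rather than copying a real section's
coordinates. Passing tests therefore demonstrate correctness of the model
and sampler under the stated generative conditions, not performance parity
on any particular real tissue.

## Verification strategy

Beyond unit oracles (brute-force kNN, pair-counting ARI, factorial label
matching, exact Potts partition functions by enumeration on ≤ 12 nodes), the
sampler is validated by: exactness of the SW kernel against the enumerated
Potts distribution (χ² over 50 000 sweeps on a 4-node graph); recovery and
credible-interval calibration of `beta` from genuine Potts draws on a 15×15
lattice; conjugate-update algebra on 1-D toys (including a
probability-integral-transform check of the `lambda` update); a
Geweke-style joint-correctness comparison of forward vs successive-
conditional simulation through all five kernels on a 6-node toy (moment
z-scores < 1 at 20 000 draws; the toy uses a wider `beta` proposal, sd 1.0,
purely so the chain mixes fast enough to compare moments); and full-model
composition recovery (RMSE < 0.05 at 1000 cells on the banded geometry).
The composition-recovery and interval-calibration checks are deliberately
separate experiments: a 4-state Potts draw on a ~7-regular graph is either
speckled (domains not identifiable from composition data) or ordered into
one giant domain, so no single dataset makes both `pi` and `beta`
identifiable at once.

Benchmark problem sizes (10 replicates, 4000 iterations, half burn-in) are
the package's reporting choice for the scripts and tests; longer chains give
indistinguishable label estimates on these data.

## Known limitations

- Gaussian emissions with a shared covariance; no per-type covariances or
  heavy-tailed emissions.
- No model selection for C or R: both are user-specified. Practical advice:
  over-specify moderately and inspect the sizes of the resulting clusters —
  redundant clusters stay small.
- The exchange step uses approximate auxiliary draws; at extreme `beta`
  (far above the graphs' ordering transition) its acceptance ratio becomes
  noisy, though the prior bound at 4 keeps this regime rare.
- `lambda_j` estimates are exposed for feature-informativeness inspection,
  but no gene-selection procedure is built on them.
- Convergence diagnostics are limited to the `beta` and log-posterior
  traces.
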