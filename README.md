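# pottsmix

Joint **cell type clustering** and **spatial domain segmentation** for
single-cell-resolution spatial transcriptomics (STARmap, MERFISH, seqFISH+,
osmFISH, high-resolution Visium treated as pseudo-cells), in one Bayesian
hierarchical model fitted by MCMC. Both tasks inform each other: knowing the
cell types sharpens the domain boundaries, and knowing the domains sharpens
the type assignments. The package also ships a splat-style count simulator
that reproduces layered-tissue benchmark designs, and the evaluation metrics
(ARI, NMI, label matching, rare-type F1/MCC, composition RMSE) used to score
them.

## Model

For cell *i* on tissue section *l*, with low-dimensional expression features
*x*ᵢ⁽ˡ⁾ (top-*J* principal components of the normalized, log-transformed
counts):

```
x_i | c_i = c   ~  Normal(mu_c, Sigma)            (expression | cell type)
c_i | z_i = r   ~  Categorical(pi_r)              (cell type | spatial domain)
z^(l)           ~  Potts(V^(l), beta)             (domains on the kNN graph)
```

A spatial domain is a tissue region with a distinctive **cell type
composition** `pi_r` (a column of the C x R matrix `pi`), not a region of
homogeneous expression. The Potts model over the per-section k-nearest-
neighbor graph `V^(l)` smooths the domain labels of neighboring cells, with
interaction strength `beta` *inferred from the data* under a Uniform(0, 4)
prior. Conjugate priors everywhere else: per-feature normal–gamma on the
type means (the feature scale `lambda_j` measures the between-type spread of
feature *j*, i.e. how informative it is), inverse-Wishart on the shared
covariance `Sigma`, Dirichlet on each `pi_r`.

Inference is a systematic-scan Gibbs sampler with two special moves:
Swendsen–Wang cluster updates for the domain labels (fast mixing), and an
exchange-algorithm (double Metropolis–Hastings) step for `beta` that cancels
the intractable Potts partition function with an auxiliary configuration.
Label switching is resolved post hoc by iterative pivot relabeling with
optimal assignment (ECR-style), separately for the type and domain chains.
Multiple tissue sections are fitted jointly: `mu`, `Sigma`, `lambda`, `pi`
are shared, each section has its own graph, and `beta` is updated from the
first section.

## Worked example

```sh
pottsmix simulate --scenario III --cells 1127 --genes 200 --seed 1 --out demo/data
pottsmix run --manifest demo/data/manifest.csv --c 4 --r 4 \
    --iters 4000 --burnin 2000 --seed 1 --out demo/fit
pottsmix evaluate --pred demo/fit/labels.csv --truth demo/data/truth_labels.csv \
    --metrics ari,nmi
```

which prints (numbers from this exact invocation):

```
    scale metric    value
cell_type    ari 1.000000
cell_type    nmi 1.000000
   domain    ari 0.976643
   domain    nmi 0.962786
```

The simulated tissue has four vertical band domains, each a 2:1:1 mixture of
three of four cell types. A cell-type ARI of 1.0 means every cell was
assigned to its true type; a domain ARI of 0.98 means the four bands were
recovered with small errors along the band boundaries, where mixed
neighborhoods make the domain genuinely ambiguous. `demo/fit/` also contains
the estimated composition matrix (`pi.csv`), the `beta` and log-posterior
traces (`beta_trace.csv`), the per-feature informativeness estimates
(`lambda.csv`), and a config snapshot + seed for bit-identical reruns.

The same workflow runs on real data: point the manifest at per-section
expression (Matrix Market `.mtx` with `.genes.tsv`/`.barcodes.tsv` sidecars,
or dense CSV with genes in rows) and a coordinates CSV
(`cell_id,x,y`).

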