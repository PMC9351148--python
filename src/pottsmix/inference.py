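"""Gibbs/Metropolis-Hastings sampler, label-switching correction, summaries.

The sampler performs a systematic scan per iteration:

  1. cell-type labels c   -- independent categorical draws given z and the
                             Gaussian likelihood,
  2. mu, lambda, Sigma    -- conjugate normal / gamma / inverse-Wishart draws,
  3. compositions pi      -- per-domain Dirichlet draws,
  4. domain labels z      -- one Swendsen-Wang sweep per section, with the
                             cell-type composition acting as an external field,
  5. interaction beta     -- exchange-algorithm (double Metropolis-Hastings)
                             step that cancels the intractable Potts partition
                             function with an auxiliary configuration; in
                             multi-section runs beta is informed by the first
                             section only.

Post-burn-in draws are relabeled with an iterative pivot-based relabeling
(ECR-style optimal assignment against the highest-posterior draw) separately
for the cell-type and domain chains, then summarized by per-cell marginal
posterior modes and posterior means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.optimize import linear_sum_assignment
from scipy.stats import invwishart

from .graph import NeighborGraph
from .model import (
    HyperParams,
    ModelState,
    gaussian_loglik_matrix,
    monochromatic_edge_count,
)
from .preprocess import FeatureMatrix

__all__ = [
    "MCMCSamples",
    "FitResult",
    "sample_cell_labels",
    "sample_gaussian_params",
    "sample_compositions",
    "sample_domain_labels_sw",
    "sample_beta",
    "run_mcmc",
    "relabel_ecr",
    "summarize_posterior",
]


# ---------------------------------------------------------------------------
# Gibbs kernels
# ---------------------------------------------------------------------------

def _categorical_rows(logp: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One categorical draw per row of a matrix of unnormalized log masses."""
    # Gumbel-max: exact, vectorized, and safe with -inf entries
    g = -np.log(-np.log(rng.random(logp.shape)))
    return np.argmax(logp + g, axis=1).astype(np.int64)


def sample_cell_labels(
    features: FeatureMatrix | np.ndarray,
    state: ModelState,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw each c_i given z_i: p(c_i=c) prop. to Normal(x_i; mu_c, Sigma) * pi_{c, z_i}."""
    X = features.features if isinstance(features, FeatureMatrix) else np.asarray(features)
    loglik = gaussian_loglik_matrix(X, state.mu, state.Sigma)
    with np.errstate(divide="ignore"):
        logpi = np.log(state.pi)  # C x R
    logp = loglik + logpi[:, state.z].T
    return _categorical_rows(logp, rng)


def sample_gaussian_params(
    features: FeatureMatrix | np.ndarray,
    c: np.ndarray,
    hyper: HyperParams,
    rng: np.random.Generator,
    Sigma: np.ndarray,
    lam: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Conjugate draws of (mu, lambda, Sigma) given the cell-type allocation.

    mu_c | Sigma, lambda is multivariate normal with precision
    n_c Sigma^{-1} + diag(1/lambda); the mean precision tau_j = 1/lambda_j is
    gamma; Sigma | mu is inverse-Wishart on the pooled residuals. Types with
    no assigned cells draw their mean from the prior.
    """
    X = features.features if isinstance(features, FeatureMatrix) else np.asarray(features)
    n, J = X.shape
    C = hyper.C
    m0 = hyper.mean_prior_location
    tau = 1.0 / lam

    Sigma_inv = np.linalg.inv(Sigma)
    counts = np.bincount(c, minlength=C).astype(float)
    sums = np.zeros((C, J))
    np.add.at(sums, c, X)

    mu = np.empty((C, J))
    for ct in range(C):
        prec = counts[ct] * Sigma_inv + np.diag(tau)
        b = Sigma_inv @ sums[ct] + tau * m0
        L = np.linalg.cholesky(prec)
        mean = np.linalg.solve(prec, b)
        # draw ~ N(mean, prec^{-1})
        mu[ct] = mean + np.linalg.solve(L.T, rng.standard_normal(J))

    shape = hyper.lambda_shape + 0.5 * C
    rate = hyper.lambda_rate + 0.5 * ((mu - m0[None, :]) ** 2).sum(axis=0)
    tau_new = rng.gamma(shape, 1.0 / rate)
    lam_new = 1.0 / tau_new

    resid = X - mu[c]
    S = resid.T @ resid
    df_post = hyper.wishart_df + n
    scale_post = hyper.wishart_scale + S
    Sigma_new = invwishart.rvs(df=df_post, scale=scale_post, random_state=rng)
    Sigma_new = np.atleast_2d(Sigma_new)
    return mu, lam_new, Sigma_new


def sample_compositions(
    c: np.ndarray,
    z: np.ndarray,
    hyper: HyperParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw each column pi_r ~ Dirichlet(alpha + n_{.r}); empty domains draw the prior."""
    counts = np.zeros((hyper.C, hyper.R))
    np.add.at(counts, (c, z), 1.0)
    g = rng.gamma(counts + hyper.dirichlet_alpha)
    return g / g.sum(axis=0, keepdims=True)


# ---------------------------------------------------------------------------
# Swendsen-Wang machinery
# ---------------------------------------------------------------------------

@njit(cache=True)
def _union_find(n: int, bi: np.ndarray, bj: np.ndarray) -> np.ndarray:
    """Compacted connected-component label per node for the given bond edges."""
    parent = np.arange(n)
    for e in range(bi.shape[0]):
        x = bi[e]
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        y = bj[e]
        while parent[y] != y:
            parent[y] = parent[parent[y]]
            y = parent[y]
        if x < y:
            parent[y] = x
        elif y < x:
            parent[x] = y
    comp = np.empty(n, dtype=np.int64)
    label_of_root = np.full(n, -1, dtype=np.int64)
    n_comp = 0
    for i in range(n):
        r = i
        while parent[r] != r:
            r = parent[r]
        if label_of_root[r] < 0:
            label_of_root[r] = n_comp
            n_comp += 1
        comp[i] = label_of_root[r]
    return comp


def _sw_sweep(
    z: np.ndarray,
    graph: NeighborGraph,
    beta: float,
    log_field: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """One Swendsen-Wang sweep leaving the Potts-plus-field distribution invariant.

    Bonds are placed on monochromatic edges with probability 1 - exp(-beta);
    each resulting cluster draws a common new label with probability
    proportional to exp(sum of its members' log field weights). A zero field
    gives the pure Potts sweep.
    """
    n = graph.n_nodes
    R = log_field.shape[1]
    if graph.n_edges and beta > 0:
        i, j = graph.edge_arrays()
        same = z[i] == z[j]
        u = rng.random(graph.n_edges)
        bond = same & (u < -np.expm1(-beta))
        bi, bj = i[bond], j[bond]
    else:
        if graph.n_edges:
            rng.random(graph.n_edges)  # keep the random stream aligned
        bi = bj = np.empty(0, dtype=np.int64)
    comp = _union_find(n, bi, bj)
    n_comp = comp.max() + 1 if n else 0
    comp_logw = np.empty((n_comp, R))
    for r in range(R):
        comp_logw[:, r] = np.bincount(comp, weights=log_field[:, r], minlength=n_comp)
    new_labels = _categorical_rows(comp_logw, rng)
    return new_labels[comp]


def sample_domain_labels_sw(
    c: np.ndarray,
    z: np.ndarray,
    graphs: list[NeighborGraph],
    section_slices: list[slice],
    state: ModelState,
    rng: np.random.Generator,
) -> np.ndarray:
    """One SW sweep of the domain labels per section.

    The external field on cell i is pi_{c_i, r}: a cluster takes label r with
    probability proportional to the product of its members' composition
    entries.
    """
    with np.errstate(divide="ignore"):
        logpi = np.log(state.pi)  # C x R
    z_new = z.copy()
    for graph, sl in zip(graphs, section_slices):
        log_field = logpi[c[sl], :]
        # clusters with all -inf rows cannot occur: Dirichlet draws are a.s. positive
        z_new[sl] = _sw_sweep(z[sl], graph, state.beta, log_field, rng)
    return z_new


def _reflect(x: float, lo: float, hi: float) -> float:
    width = hi - lo
    while x < lo or x > hi:
        if x < lo:
            x = 2 * lo - x
        if x > hi:
            x = 2 * hi - x
    return x


def sample_beta(
    z_first: np.ndarray,
    graph_first: NeighborGraph,
    state: ModelState,
    hyper: HyperParams,
    rng: np.random.Generator,
    inner_sweeps: int = 10,
    proposal_sd: float = 0.1,
) -> tuple[float, bool]:
    """Exchange-algorithm update of the Potts interaction parameter.

    A random-walk proposal reflected into [0, beta_max] is accepted with the
    exchange ratio exp((beta' - beta) * (S(z) - S(w))), where S is the
    monochromatic-edge count and w is an auxiliary configuration simulated at
    beta' by ``inner_sweeps`` pure-Potts SW sweeps warm-started from z. The
    intractable partition functions cancel. Returns (new beta, accepted).
    """
    beta = float(state.beta)
    prop = _reflect(beta + proposal_sd * rng.standard_normal(), 0.0, hyper.beta_max)
    zeros = np.zeros((graph_first.n_nodes, hyper.R))
    w = z_first.copy()
    for _ in range(inner_sweeps):
        w = _sw_sweep(w, graph_first, prop, zeros, rng)
    s_real = monochromatic_edge_count(z_first, graph_first)
    s_aux = monochromatic_edge_count(w, graph_first)
    log_alpha = (prop - beta) * (s_real - s_aux)
    if np.log(rng.random()) < log_alpha:
        return prop, True
    return beta, False


# ---------------------------------------------------------------------------
# Samples containers
# ---------------------------------------------------------------------------

@dataclass
class MCMCSamples:
    """Post-burn-in posterior draws, ready for relabeling and summarization."""

    c_draws: np.ndarray  # draws x cells
    z_draws: np.ndarray  # draws x cells
    pi_draws: np.ndarray  # draws x C x R
    beta_draws: np.ndarray  # draws
    lam_draws: np.ndarray  # draws x J
    mu_draws: np.ndarray  # draws x C x J
    log_post_draws: np.ndarray  # draws (unnormalized; Potts partition omitted)
    C: int
    R: int
    beta_accept_rate: float = float("nan")

    def __post_init__(self) -> None:
        lengths = {
            arr.shape[0]
            for arr in (
                self.c_draws,
                self.z_draws,
                self.pi_draws,
                self.beta_draws,
                self.lam_draws,
                self.mu_draws,
                self.log_post_draws,
            )
        }
        if len(lengths) != 1:
            raise ValueError("inconsistent number of draws across fields")

    @property
    def n_draws(self) -> int:
        return self.c_draws.shape[0]


@dataclass
class FitResult:
    """Point summaries of the posterior: labels, compositions, beta, lambda."""

    c_hat: np.ndarray
    z_hat: np.ndarray
    pi_hat: np.ndarray
    beta_hat: float
    lam_hat: np.ndarray


def _log_prior(state: ModelState, hyper: HyperParams) -> float:
    from scipy.special import gammaln, multigammaln

    m0 = hyper.mean_prior_location
    J = hyper.J
    lp = float(
        np.sum(
            -0.5 * np.log(2 * np.pi * state.lam)[None, :]
            - 0.5 * (state.mu - m0[None, :]) ** 2 / state.lam[None, :]
        )
    )
    # gamma prior on the mean precisions tau_j = 1/lambda_j
    a, b = hyper.lambda_shape, hyper.lambda_rate
    tau = 1.0 / state.lam
    lp += float(np.sum(a * np.log(b) - gammaln(a) + (a - 1) * np.log(tau) - b * tau))
    # inverse-Wishart on Sigma
    nu = hyper.wishart_df
    S0 = hyper.wishart_scale
    L = np.linalg.cholesky(state.Sigma)
    logdet_sigma = 2.0 * np.sum(np.log(np.diag(L)))
    sign, logdet_s0 = np.linalg.slogdet(S0)
    tr = float(np.trace(np.linalg.solve(state.Sigma, S0)))
    lp += (
        0.5 * nu * logdet_s0
        - 0.5 * nu * J * np.log(2.0)
        - multigammaln(0.5 * nu, J)
        - 0.5 * (nu + J + 1) * logdet_sigma
        - 0.5 * tr
    )
    # symmetric Dirichlet on each composition column
    alpha = hyper.dirichlet_alpha
    const = gammaln(hyper.C * alpha) - hyper.C * gammaln(alpha)
    logpi = np.log(np.clip(state.pi, 1e-300, None))
    lp += float(hyper.R * const + (alpha - 1.0) * logpi.sum())
    return lp


def log_joint_unnormalized(
    X: np.ndarray,
    state: ModelState,
    hyper: HyperParams,
    graphs: list[NeighborGraph],
    section_slices: list[slice],
) -> float:
    """Unnormalized log joint density (the Potts partition term is omitted)."""
    diff = X - state.mu[state.c]
    J = X.shape[1]
    L = np.linalg.cholesky(state.Sigma)
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    Sigma_inv = np.linalg.inv(state.Sigma)
    quad = float(np.sum((diff @ Sigma_inv) * diff))
    ll = -0.5 * (X.shape[0] * (J * np.log(2 * np.pi) + logdet) + quad)
    with np.errstate(divide="ignore"):
        lp_c = float(np.sum(np.log(np.clip(state.pi[state.c, state.z], 1e-300, None))))
    potts = sum(
        state.beta * monochromatic_edge_count(state.z[sl], g)
        for g, sl in zip(graphs, section_slices)
    )
    return float(ll + lp_c + potts + _log_prior(state, hyper))


def section_slices_of(section_of_cell: np.ndarray) -> list[slice]:
    """Contiguous per-section slices; cells must be grouped by section."""
    sections = np.unique(section_of_cell)
    slices = []
    for sec in sections:
        idx = np.flatnonzero(section_of_cell == sec)
        if not np.array_equal(idx, np.arange(idx[0], idx[-1] + 1)):
            raise ValueError("cells must be ordered contiguously by section")
        slices.append(slice(int(idx[0]), int(idx[-1]) + 1))
    return slices


def run_mcmc(
    features: FeatureMatrix,
    graphs: list[NeighborGraph],
    hyper: HyperParams,
    n_iter: int = 10_000,
    burn_in: int = 5_000,
    seed: int | np.random.Generator = 0,
    inner_sweeps: int = 10,
    initial_state: ModelState | None = None,
    callback=None,
) -> MCMCSamples:
    """Run the full systematic-scan sampler and store post-burn-in draws.

    Fixed seed implies bit-identical draws. In multi-section runs the Gaussian
    parameters, lambda, and pi are shared across sections while beta is
    updated from the first section's configuration only.
    """
    if n_iter <= burn_in:
        raise ValueError("n_iter must exceed burn_in")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    X = features.features
    slices = section_slices_of(features.section_of_cell)
    if len(graphs) != len(slices):
        raise ValueError("one neighbor graph per section is required")

    if initial_state is None:
        from .model import initialize_state

        state = initialize_state(features, graphs, hyper, rng)
    else:
        state = initial_state.copy()

    n_store = n_iter - burn_in
    n = X.shape[0]
    c_draws = np.empty((n_store, n), dtype=np.int16)
    z_draws = np.empty((n_store, n), dtype=np.int16)
    pi_draws = np.empty((n_store, hyper.C, hyper.R))
    beta_draws = np.empty(n_store)
    lam_draws = np.empty((n_store, hyper.J))
    mu_draws = np.empty((n_store, hyper.C, hyper.J))
    log_post = np.empty(n_store)
    n_accept = 0

    for it in range(n_iter):
        state.c = sample_cell_labels(features, state, rng)
        state.mu, state.lam, state.Sigma = sample_gaussian_params(
            features, state.c, hyper, rng, state.Sigma, state.lam
        )
        state.pi = sample_compositions(state.c, state.z, hyper, rng)
        state.z = sample_domain_labels_sw(state.c, state.z, graphs, slices, state, rng)
        state.beta, accepted = sample_beta(
            state.z[slices[0]], graphs[0], state, hyper, rng, inner_sweeps=inner_sweeps
        )
        n_accept += accepted
        if it >= burn_in:
            k = it - burn_in
            c_draws[k] = state.c
            z_draws[k] = state.z
            pi_draws[k] = state.pi
            beta_draws[k] = state.beta
            lam_draws[k] = state.lam
            mu_draws[k] = state.mu
            lp = log_joint_unnormalized(X, state, hyper, graphs, slices)
            if not np.isfinite(lp):
                raise FloatingPointError(
                    f"non-finite log-posterior at iteration {it}: beta={state.beta}, "
                    f"lam range=({state.lam.min()}, {state.lam.max()})"
                )
            log_post[k] = lp
        if callback is not None:
            callback(it, state)

    return MCMCSamples(
        c_draws=c_draws,
        z_draws=z_draws,
        pi_draws=pi_draws,
        beta_draws=beta_draws,
        lam_draws=lam_draws,
        mu_draws=mu_draws,
        log_post_draws=log_post,
        C=hyper.C,
        R=hyper.R,
        beta_accept_rate=n_accept / n_iter,
    )


# ---------------------------------------------------------------------------
# Label-switching correction (iterative pivot relabeling) and summaries
# ---------------------------------------------------------------------------

def _best_permutation(draw: np.ndarray, pivot: np.ndarray, K: int) -> np.ndarray:
    """Permutation m (old -> new) maximizing agreement of m[draw] with pivot."""
    table = np.bincount(draw.astype(np.int64) * K + pivot.astype(np.int64), minlength=K * K)
    table = table.reshape(K, K)
    row, col = linear_sum_assignment(-table)
    perm = np.empty(K, dtype=np.int64)
    perm[row] = col
    return perm


def _relabel_chain(
    draws: np.ndarray, log_post: np.ndarray, K: int, max_iter: int = 100
) -> tuple[np.ndarray, np.ndarray]:
    """Iteratively relabel a label chain against a pivot allocation.

    Returns the relabeled draws and the per-draw permutations (old -> new)
    relative to the input. The pivot starts as the highest-log-posterior draw
    and is updated to the per-cell marginal mode after each pass; iteration
    stops when the total disagreement with the pivot stops improving.
    """
    n_draws, n = draws.shape
    labels = draws.astype(np.int64).copy()
    perms = np.tile(np.arange(K, dtype=np.int64), (n_draws, 1))
    pivot = labels[int(np.argmax(log_post))].copy()
    prev = np.inf
    for _ in range(max_iter):
        total = 0
        for d in range(n_draws):
            perm = _best_permutation(labels[d], pivot, K)
            labels[d] = perm[labels[d]]
            perms[d] = perm[perms[d]]
            total += int(np.sum(labels[d] != pivot))
        if total >= prev:
            break
        prev = total
        # updated pivot: per-cell marginal mode of the relabeled chain
        counts = np.zeros((K, n), dtype=np.int64)
        for kk in range(K):
            counts[kk] = np.sum(labels == kk, axis=0)
        pivot = counts.argmax(axis=0)
    return labels, perms


def relabel_ecr(samples: MCMCSamples) -> MCMCSamples:
    """Resolve label switching for the cell-type and domain chains independently.

    The per-draw permutation found for the cell-type chain is applied to the
    labels, the rows of mu and the rows of pi; the domain-chain permutation is
    applied to the labels and the columns of pi.
    """
    c_lab, c_perms = _relabel_chain(samples.c_draws, samples.log_post_draws, samples.C)
    z_lab, z_perms = _relabel_chain(samples.z_draws, samples.log_post_draws, samples.R)
    pi = samples.pi_draws.copy()
    mu = samples.mu_draws.copy()
    for d in range(samples.n_draws):
        cp = np.argsort(c_perms[d])  # new index -> old index
        zp = np.argsort(z_perms[d])
        pi[d] = pi[d][cp][:, zp]
        mu[d] = mu[d][cp]
    return MCMCSamples(
        c_draws=c_lab.astype(samples.c_draws.dtype),
        z_draws=z_lab.astype(samples.z_draws.dtype),
        pi_draws=pi,
        beta_draws=samples.beta_draws.copy(),
        lam_draws=samples.lam_draws.copy(),
        mu_draws=mu,
        log_post_draws=samples.log_post_draws.copy(),
        C=samples.C,
        R=samples.R,
        beta_accept_rate=samples.beta_accept_rate,
    )


def _marginal_mode(draws: np.ndarray, K: int) -> np.ndarray:
    counts = np.zeros((K, draws.shape[1]), dtype=np.int64)
    for kk in range(K):
        counts[kk] = np.sum(draws == kk, axis=0)
    return counts.argmax(axis=0)  # ties -> smaller label


def summarize_posterior(samples: MCMCSamples) -> FitResult:
    """Point estimates from (relabeled) draws.

    Labels are per-cell marginal posterior modes (ties break to the smaller
    label); pi is the posterior mean with columns renormalized; beta and
    lambda are posterior means.
    """
    c_hat = _marginal_mode(samples.c_draws, samples.C)
    z_hat = _marginal_mode(samples.z_draws, samples.R)
    pi_hat = samples.pi_draws.mean(axis=0)
    pi_hat = pi_hat / pi_hat.sum(axis=0, keepdims=True)
    return FitResult(
        c_hat=c_hat,
        z_hat=z_hat,
        pi_hat=pi_hat,
        beta_hat=float(samples.beta_draws.mean()),
        lam_hat=samples.lam_draws.mean(axis=0),
    )
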