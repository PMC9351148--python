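"""Model state, priors, and log-density kernels.

The hierarchical model: expression features of a cell are Gaussian around a
cell-type-specific mean with a covariance shared across types,

    x_i | c_i = c       ~  Normal(mu_c, Sigma),
    c_i | z_i = r       ~  Categorical(pi_r),
    z^(l)               ~  Potts(V^(l), beta),

where pi_r is the cell-type composition of spatial domain r and the Potts
model over the per-section neighbor graph V^(l) encourages neighboring cells
to share a domain label. Conjugate priors: per-feature normal--gamma on the
type means (mu_{cj} | lambda_j ~ Normal(m_j, lambda_j) with the precision
1/lambda_j gamma-distributed), inverse-Wishart on Sigma, Dirichlet on each
pi_r, and a uniform prior on beta over [0, beta_max].

The feature scale lambda_j is the prior variance of the type means on feature
j: a larger lambda_j means a larger between-type spread, i.e. a more
informative feature for discriminating cell types.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from sklearn.cluster import KMeans

from .graph import NeighborGraph
from .preprocess import FeatureMatrix

__all__ = [
    "HyperParams",
    "ModelState",
    "loglik_cell",
    "gaussian_loglik_matrix",
    "potts_log_potential",
    "monochromatic_edge_count",
    "potts_log_partition_exact",
    "initialize_state",
]


@dataclass
class HyperParams:
    """Prior and dimension hyperparameters.

    C, R, J are the numbers of cell types, spatial domains, and features.
    ``beta_max`` bounds the uniform prior on the Potts interaction parameter
    (default 4). ``dirichlet_alpha`` is the symmetric Dirichlet concentration
    for the domain compositions. ``mean_prior_location`` is the per-feature
    prior location of the type means (default: per-feature global mean at
    initialization). ``lambda_shape``/``lambda_rate`` parameterize the gamma
    prior on the mean precision 1/lambda_j. ``wishart_df``/``wishart_scale``
    parameterize the inverse-Wishart prior on Sigma.
    """

    C: int
    R: int
    J: int
    beta_max: float = 4.0
    dirichlet_alpha: float = 1.0
    mean_prior_location: np.ndarray | None = None
    lambda_shape: float = 2.0
    lambda_rate: float = 1.0
    wishart_df: float | None = None
    wishart_scale: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.C < 1 or self.R < 1 or self.J < 1:
            raise ValueError("C, R, J must all be >= 1")
        if self.beta_max <= 0:
            raise ValueError("beta_max must be positive")
        if self.dirichlet_alpha <= 0:
            raise ValueError("dirichlet_alpha must be positive")
        if self.lambda_shape <= 0 or self.lambda_rate <= 0:
            raise ValueError("lambda hyperparameters must be positive")
        if self.mean_prior_location is None:
            self.mean_prior_location = np.zeros(self.J)
        self.mean_prior_location = np.asarray(self.mean_prior_location, dtype=float)
        if self.mean_prior_location.shape != (self.J,):
            raise ValueError("mean_prior_location must have length J")
        if self.wishart_df is None:
            self.wishart_df = float(self.J + 2)
        if self.wishart_df <= self.J - 1:
            raise ValueError("wishart_df must exceed J - 1")
        if self.wishart_scale is None:
            self.wishart_scale = np.eye(self.J)
        self.wishart_scale = np.asarray(self.wishart_scale, dtype=float)
        if self.wishart_scale.shape != (self.J, self.J):
            raise ValueError("wishart_scale must be J x J")

    @property
    def lambda_prior_mean(self) -> float:
        """Prior mean of lambda_j = 1/tau_j (finite for lambda_shape > 1)."""
        if self.lambda_shape <= 1:
            return self.lambda_rate / self.lambda_shape  # fallback: 1/mean precision
        return self.lambda_rate / (self.lambda_shape - 1.0)


@dataclass
class ModelState:
    """One MCMC configuration of all unknowns.

    Labels ``c`` (cell types, 0..C-1) and ``z`` (domains, 0..R-1) are stored
    0-based internally; external interfaces are 1-based.
    """

    c: np.ndarray
    z: np.ndarray
    mu: np.ndarray  # C x J
    Sigma: np.ndarray  # J x J, SPD
    lam: np.ndarray  # J, positive
    pi: np.ndarray  # C x R, columns sum to 1
    beta: float

    def validate(self, hyper: HyperParams) -> None:
        C, R, J = hyper.C, hyper.R, hyper.J
        if self.mu.shape != (C, J) or self.Sigma.shape != (J, J):
            raise ValueError("parameter shape mismatch")
        if self.pi.shape != (C, R):
            raise ValueError("pi must be C x R")
        if not np.allclose(self.pi.sum(axis=0), 1.0, atol=1e-10):
            raise ValueError("pi columns must sum to 1")
        if np.any(self.pi < -1e-12):
            raise ValueError("pi entries must be non-negative")
        if self.lam.shape != (J,) or np.any(self.lam <= 0):
            raise ValueError("lam must be J positive reals")
        if not (0.0 <= self.beta <= hyper.beta_max):
            raise ValueError("beta outside [0, beta_max]")
        if np.any(self.c < 0) or np.any(self.c >= C):
            raise ValueError("cell-type label out of range")
        if np.any(self.z < 0) or np.any(self.z >= R):
            raise ValueError("domain label out of range")
        if not np.allclose(self.Sigma, self.Sigma.T, atol=1e-8):
            raise ValueError("Sigma must be symmetric")
        try:
            np.linalg.cholesky(self.Sigma)
        except np.linalg.LinAlgError as err:
            raise ValueError("Sigma must be positive-definite") from err

    def copy(self) -> "ModelState":
        return ModelState(
            c=self.c.copy(),
            z=self.z.copy(),
            mu=self.mu.copy(),
            Sigma=self.Sigma.copy(),
            lam=self.lam.copy(),
            pi=self.pi.copy(),
            beta=float(self.beta),
        )


def gaussian_loglik_matrix(X: np.ndarray, mu: np.ndarray, Sigma: np.ndarray) -> np.ndarray:
    """Log Normal(x_i; mu_c, Sigma) for every cell i and type c -> (N, C)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    mu = np.atleast_2d(np.asarray(mu, dtype=float))
    J = X.shape[1]
    try:
        factor = cho_factor(Sigma, lower=True)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError("Sigma is singular or not positive-definite") from err
    logdet = 2.0 * np.sum(np.log(np.diag(factor[0])))
    const = -0.5 * (J * np.log(2.0 * np.pi) + logdet)
    Sigma_inv = cho_solve(factor, np.eye(J))
    out = np.empty((X.shape[0], mu.shape[0]))
    for c in range(mu.shape[0]):
        diff = X - mu[c]
        out[:, c] = const - 0.5 * np.sum((diff @ Sigma_inv) * diff, axis=1)
    return out


def loglik_cell(x: np.ndarray, c: int, state: ModelState) -> float:
    """Log density of one cell's feature vector under its type's Gaussian."""
    return float(gaussian_loglik_matrix(np.atleast_2d(x), state.mu[c : c + 1], state.Sigma)[0, 0])


def monochromatic_edge_count(z: np.ndarray, graph: NeighborGraph) -> int:
    """Number of graph edges whose two endpoints share a domain label."""
    if graph.n_edges == 0:
        return 0
    i, j = graph.edge_arrays()
    return int(np.sum(z[i] == z[j]))


def potts_log_potential(z: np.ndarray, graph: NeighborGraph, beta: float) -> float:
    """beta times the monochromatic-edge count (log of the unnormalized mass)."""
    z = np.asarray(z)
    if z.shape[0] != graph.n_nodes:
        raise ValueError("labels must cover all graph nodes")
    return float(beta) * monochromatic_edge_count(z, graph)


def potts_log_partition_exact(graph: NeighborGraph, beta: float, R: int, max_nodes: int = 12) -> float:
    """Exact log partition function by enumeration of all R^n configurations.

    Test oracle; feasible only for tiny graphs (guarded at ``max_nodes``).
    """
    n = graph.n_nodes
    if n > max_nodes:
        raise ValueError(f"exact enumeration refused for n_nodes={n} > {max_nodes}")
    i, j = graph.edge_arrays() if graph.n_edges else (np.empty(0, int), np.empty(0, int))
    terms = np.empty(R**n)
    for idx, config in enumerate(product(range(R), repeat=n)):
        zc = np.asarray(config)
        terms[idx] = beta * np.sum(zc[i] == zc[j]) if len(i) else 0.0
    m = terms.max()
    return float(m + np.log(np.exp(terms - m).sum()))


def _seed_from(rng: np.random.Generator) -> int:
    return int(rng.integers(0, 2**31 - 1))


def neighborhood_average(features: np.ndarray, graph: NeighborGraph) -> np.ndarray:
    """Average of each cell's features with those of its graph neighbors."""
    n = graph.n_nodes
    acc = features.copy()
    deg = np.ones(n)
    if graph.n_edges:
        i, j = graph.edge_arrays()
        np.add.at(acc, i, features[j])
        np.add.at(acc, j, features[i])
        np.add.at(deg, i, 1.0)
        np.add.at(deg, j, 1.0)
    return acc / deg[:, None]


def initialize_state(
    features: FeatureMatrix,
    graphs: list[NeighborGraph],
    hyper: HyperParams,
    rng: np.random.Generator,
) -> ModelState:
    """Deterministic-given-seed initialization of the MCMC state.

    Cell types are initialized by k-means on the features; domains by k-means
    on neighborhood-averaged features (per section, stacked). Gaussian
    parameters are set to empirical within-cluster moments, lambda to its
    prior mean, pi to the smoothed empirical composition, and beta to 1.
    """
    X = features.features
    n, J = X.shape
    if J != hyper.J:
        raise ValueError("feature dimension does not match hyper.J")

    if hyper.C == 1:
        c = np.zeros(n, dtype=np.int64)
    else:
        km = KMeans(n_clusters=hyper.C, n_init=10, random_state=_seed_from(rng))
        c = km.fit_predict(X).astype(np.int64)

    smooth = np.empty_like(X)
    sections = features.sections
    if len(graphs) != len(sections):
        raise ValueError("one neighbor graph per section is required")
    for graph, sec in zip(graphs, sections):
        mask = features.section_of_cell == sec
        if int(mask.sum()) != graph.n_nodes:
            raise ValueError(f"graph for section {sec} does not match cell count")
        smooth[mask] = neighborhood_average(X[mask], graph)
    if hyper.R == 1:
        z = np.zeros(n, dtype=np.int64)
    else:
        km_z = KMeans(n_clusters=hyper.R, n_init=10, random_state=_seed_from(rng))
        z = km_z.fit_predict(smooth).astype(np.int64)

    mu = np.empty((hyper.C, J))
    global_mean = X.mean(axis=0)
    for ct in range(hyper.C):
        mask = c == ct
        mu[ct] = X[mask].mean(axis=0) if mask.any() else global_mean
    resid = X - mu[c]
    Sigma = (resid.T @ resid) / max(n - 1, 1) + 1e-6 * np.eye(J)

    lam = np.full(J, hyper.lambda_prior_mean)
    counts = np.zeros((hyper.C, hyper.R))
    np.add.at(counts, (c, z), 1.0)
    pi = counts + hyper.dirichlet_alpha
    pi /= pi.sum(axis=0, keepdims=True)

    state = ModelState(c=c, z=z, mu=mu, Sigma=Sigma, lam=lam, pi=pi, beta=1.0)
    state.validate(hyper)
    return state
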