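"""Synthetic spatial transcriptomic experiments.

Generates layered tissue layouts (four vertical cortical-layer-like bands in
a 5000 x 1000 rectangle), scenario-specific cell-type compositions per
domain, and gamma-Poisson expression counts that follow the splat generative
recipe: per-gene base means from a gamma distribution, log-normal
differential-expression (DE) factors per (gene, type), log-normal library
sizes, BCV-style mean-variance overdispersion through gamma mixing, and
Poisson counts. Multi-section experiments shift the interior band boundaries
uniformly (up to 10% of the tissue width by default); rare-cell-type and
gene-exclusion variants are supported.

Scenarios (4 domains, 4 major types; each domain lacks one distinct type):
  I   one type per domain,
  II  dominant type with probability 0.90, two others 0.05 each,
  III dominant 0.50, two others 0.25 each,
  IV  the three present types equally likely (1/3 each).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .preprocess import CountMatrix

__all__ = [
    "SimulationConfig",
    "RareConfig",
    "SimulationTruth",
    "layout_domains",
    "scenario_composition",
    "assign_types",
    "assign_types_rare",
    "simulate_counts_splat",
    "exclude_genes",
    "simulate_experiment",
]

TISSUE_WIDTH = 5000.0
TISSUE_HEIGHT = 1000.0
N_DOMAINS = 4
N_MAJOR_TYPES = 4


@dataclass
class RareConfig:
    """Rare-cell-type setting: 4 major types hold 70% of cells (2:1:1 within
    each domain, as in scenario III); the rare types split the remaining 30%
    equally, either dispersed uniformly or each confined to one domain."""

    n_rare: int = 6
    major_fraction: float = 0.70
    rare_pattern: str = "random"  # or "domain_specific"

    def __post_init__(self) -> None:
        if self.n_rare not in (6, 10):
            warnings.warn(f"n_rare={self.n_rare} differs from the studied settings (6, 10)")
        if self.rare_pattern not in ("random", "domain_specific"):
            raise ValueError("rare_pattern must be 'random' or 'domain_specific'")


@dataclass
class SimulationConfig:
    """Simulation settings; the defaults are the baseline study conditions
    (200 genes, de_prob 0.2, de_facloc 1.1, ~1127 cells per section)."""

    n_genes: int = 200
    de_prob: float = 0.2
    de_facloc: float = 1.1
    de_facscale: float = 0.4
    scenario: str = "I"
    n_cells_per_section: int = 1127
    n_sections: int = 1
    boundary_shift_fraction: float = 0.10
    rare_config: RareConfig | None = None
    genes_retained: int | None = None
    seed: int = 0
    # splat base parameters: generic defaults on the scale of targeted
    # in-situ panels (a few hundred genes, ~1e3 counts per cell)
    mean_shape: float = 0.6
    mean_rate: float = 0.3
    lib_loc: float = 7.0
    lib_scale: float = 0.3
    bcv_common: float = 0.1
    bcv_df: float = 60.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.de_prob <= 1.0:
            raise ValueError("de_prob must be in [0, 1]")
        if self.de_facloc < 0:
            raise ValueError("de_facloc must be non-negative")
        if self.n_sections < 1:
            raise ValueError("n_sections must be >= 1")
        if self.scenario not in ("I", "II", "III", "IV"):
            raise ValueError("scenario must be one of I, II, III, IV")


@dataclass
class SimulationTruth:
    """Ground truth bundle: counts, coordinates, true labels and composition."""

    counts: CountMatrix
    coords: np.ndarray  # total cells x 2, ordered by section
    true_c: np.ndarray  # 0-based cell-type labels
    true_z: np.ndarray  # 0-based domain labels
    true_pi: np.ndarray  # C x R, columns sum to 1
    de_gene_flags: np.ndarray  # genes x types: +1 up, -1 down, 0 none
    config: SimulationConfig = field(repr=False, default=None)


def _band_boundaries(shift: float, rng: np.random.Generator | None) -> np.ndarray:
    base = TISSUE_WIDTH * np.array([0.25, 0.5, 0.75])
    if rng is None or shift == 0:
        return base
    b = base + rng.uniform(-shift, shift, size=3)
    if np.any(np.diff(b) <= 0) or b[0] <= 0 or b[-1] >= TISSUE_WIDTH:
        warnings.warn("boundary shift caused band inversion; clamping")
        b = np.clip(np.sort(b), 1.0, TISSUE_WIDTH - 1.0)
    return b


def layout_domains(
    n_cells: int,
    L: int,
    shift_fraction: float,
    seed: int | np.random.Generator,
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Uniform cell positions and band-membership domain labels per section.

    The first section uses the baseline equal-quarter boundaries
    (1250/2500/3750 for width 5000); each later section shifts every interior
    boundary independently by Uniform(-s, +s) with s = shift_fraction * width.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    shift = shift_fraction * TISSUE_WIDTH
    coords, labels = [], []
    for sec in range(L):
        xy = np.column_stack(
            [rng.uniform(0, TISSUE_WIDTH, n_cells), rng.uniform(0, TISSUE_HEIGHT, n_cells)]
        )
        b = _band_boundaries(shift, rng if sec > 0 else None)
        z = np.searchsorted(b, xy[:, 0], side="right")
        coords.append(xy)
        labels.append(z.astype(np.int64))
    return coords, labels


def scenario_composition(scenario: str) -> np.ndarray:
    """True C x R composition matrix of the four main scenarios.

    Domain r's dominant type is r; its missing type is (r + 1) mod 4, so each
    domain lacks a different type.
    """
    C = R = 4
    pi = np.zeros((C, R))
    for r in range(R):
        missing = (r + 1) % C
        present = [t for t in range(C) if t != missing]
        if scenario == "I":
            pi[r, r] = 1.0
        elif scenario == "II":
            for t in present:
                pi[t, r] = 0.90 if t == r else 0.05
        elif scenario == "III":
            for t in present:
                pi[t, r] = 0.50 if t == r else 0.25
        elif scenario == "IV":
            for t in present:
                pi[t, r] = 1.0 / 3.0
        else:
            raise ValueError(f"unknown scenario {scenario!r}")
    return pi


def _draw_types(true_z: np.ndarray, pi: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    probs = pi[:, true_z].T  # cells x C
    u = rng.random(len(true_z))
    cum = np.cumsum(probs, axis=1)
    return (u[:, None] > cum).sum(axis=1).astype(np.int64)


def assign_types(
    true_z: np.ndarray, scenario: str, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw each cell's type from its domain's scenario composition."""
    pi = scenario_composition(scenario)
    return _draw_types(true_z, pi, rng), pi


def assign_types_rare(
    true_z: np.ndarray, rare_config: RareConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Scenario-III major types plus equally sized rare types.

    Major types fill ``major_fraction`` of cells with a 2:1:1 within-domain
    ratio; rare types split the remainder equally overall. In the
    domain-specific pattern each rare type is confined to a single domain
    (rare type t lives in domain t mod 4), and its within-domain share is
    inflated so its overall share stays (1 - major_fraction) / n_rare.
    """
    n_rare = rare_config.n_rare
    C = N_MAJOR_TYPES + n_rare
    R = N_DOMAINS
    rare_total = 1.0 - rare_config.major_fraction
    major = scenario_composition("III")
    pi = np.zeros((C, R))
    if rare_config.rare_pattern == "random":
        share = rare_total / n_rare
        pi[:N_MAJOR_TYPES] = major * rare_config.major_fraction
        pi[N_MAJOR_TYPES:, :] = share
    else:
        # overall share per rare type = rare_total/n_rare; domains hold ~1/R of
        # cells each, so the within-domain share is R times the overall share
        share = rare_total / n_rare * R
        for t in range(n_rare):
            pi[N_MAJOR_TYPES + t, t % R] = share
        rare_mass = pi[N_MAJOR_TYPES:].sum(axis=0)
        if np.any(rare_mass >= 1.0):
            raise ValueError("rare types exceed a domain's capacity; reduce n_rare")
        pi[:N_MAJOR_TYPES] = major * (1.0 - rare_mass)[None, :]
    pi = pi / pi.sum(axis=0, keepdims=True)
    return _draw_types(true_z, pi, rng), pi


def simulate_counts_splat(
    true_c: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
    n_types: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Gamma-Poisson counts with log-normal DE factors and library sizes.

    Per gene: base mean ~ Gamma(mean_shape, rate=mean_rate). Per (gene, type):
    with probability de_prob the gene is DE with a log-normal factor
    (log-location de_facloc, log-scale de_facscale), up- or down-regulated
    with equal probability (down means the reciprocal factor). Type-specific
    mean profiles are normalized to proportions and scaled by log-normal
    per-cell library sizes; BCV-style overdispersion enters through gamma
    mixing of the Poisson rate with a per-gene chi-square df adjustment.

    Returns (counts genes x cells, de_gene_flags genes x types).
    """
    n_types = int(n_types if n_types is not None else true_c.max() + 1)
    G, n = config.n_genes, len(true_c)
    base = rng.gamma(config.mean_shape, 1.0 / config.mean_rate, size=G)

    is_de = rng.random((G, n_types)) < config.de_prob
    up = rng.random((G, n_types)) < 0.5
    raw = rng.lognormal(config.de_facloc, config.de_facscale, size=(G, n_types))
    factors = np.ones((G, n_types))
    factors[is_de & up] = raw[is_de & up]
    factors[is_de & ~up] = 1.0 / raw[is_de & ~up]
    flags = np.zeros((G, n_types), dtype=np.int8)
    flags[is_de & up] = 1
    flags[is_de & ~up] = -1

    type_means = base[:, None] * factors
    props = type_means / type_means.sum(axis=0, keepdims=True)
    lib = rng.lognormal(config.lib_loc, config.lib_scale, size=n)
    mu = props[:, true_c] * lib[None, :]

    chi = rng.chisquare(config.bcv_df, size=G)
    bcv = (config.bcv_common + 1.0 / np.sqrt(np.clip(mu, 1e-12, None))) * np.sqrt(
        config.bcv_df / chi
    )[:, None]
    shape = 1.0 / bcv**2
    mixed = rng.gamma(shape, mu / shape)
    counts = rng.poisson(mixed).astype(np.int64)
    return counts, flags


def exclude_genes(
    counts: CountMatrix, n_retained: int, rng: np.random.Generator
) -> tuple[CountMatrix, np.ndarray]:
    """Retain a uniformly random gene subset (seed-reproducible).

    Returns the reduced matrix and the sorted indices of the retained genes.
    """
    if n_retained <= 0:
        raise ValueError("n_retained must be positive")
    if n_retained > counts.n_genes:
        raise ValueError("n_retained exceeds the number of genes")
    if n_retained == counts.n_genes:
        return counts, np.arange(counts.n_genes)
    keep = np.sort(rng.choice(counts.n_genes, size=n_retained, replace=False))
    reduced = CountMatrix(
        counts=counts.counts[keep],
        gene_ids=[counts.gene_ids[i] for i in keep],
        cell_ids=list(counts.cell_ids),
        section_of_cell=counts.section_of_cell.copy(),
    )
    return reduced, keep


def simulate_experiment(config: SimulationConfig) -> SimulationTruth:
    """End-to-end generation of one synthetic experiment from a single seed."""
    rng = np.random.default_rng(config.seed)
    coords_list, z_list = layout_domains(
        config.n_cells_per_section, config.n_sections, config.boundary_shift_fraction, rng
    )
    coords = np.vstack(coords_list)
    true_z = np.concatenate(z_list)
    if config.rare_config is not None:
        true_c, true_pi = assign_types_rare(true_z, config.rare_config, rng)
    else:
        true_c, true_pi = assign_types(true_z, config.scenario, rng)
    n_types = true_pi.shape[0]
    counts, flags = simulate_counts_splat(true_c, config, rng, n_types=n_types)

    section_of_cell = np.concatenate(
        [np.full(config.n_cells_per_section, sec + 1) for sec in range(config.n_sections)]
    )
    cell_ids = [
        f"s{sec}_c{i}"
        for sec in range(1, config.n_sections + 1)
        for i in range(config.n_cells_per_section)
    ]
    gene_ids = [f"gene{g}" for g in range(config.n_genes)]
    cm = CountMatrix(
        counts=counts, gene_ids=gene_ids, cell_ids=cell_ids, section_of_cell=section_of_cell
    )
    if config.genes_retained is not None:
        cm, keep = exclude_genes(cm, config.genes_retained, rng)
        flags = flags[keep]
    return SimulationTruth(
        counts=cm,
        coords=coords,
        true_c=true_c,
        true_z=true_z,
        true_pi=true_pi,
        de_gene_flags=flags,
        config=config,
    )
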