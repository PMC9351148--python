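"""Expression preprocessing: normalization, log transform, PCA features, alignment.

Raw counts from one or more tissue sections are turned into a common set of
low-dimensional expression features: library-size normalization, log2(x+1)
transform, principal components of the gene-centered matrix, and an optional
per-section alignment step for multi-section experiments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "CountMatrix",
    "FeatureMatrix",
    "normalize_log_transform",
    "extract_features",
    "align_sections",
]


@dataclass
class CountMatrix:
    """Gene-by-cell expression counts across one or more tissue sections.

    Parameters
    ----------
    counts
        Non-negative integer matrix of shape (n_genes, n_cells).
    gene_ids
        Unique gene identifiers, length n_genes.
    cell_ids
        Cell identifiers, length n_cells.
    section_of_cell
        1-based section index per cell, length n_cells.
    """

    counts: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    section_of_cell: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.section_of_cell = np.asarray(self.section_of_cell, dtype=int)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D genes x cells matrix")
        n_genes, n_cells = self.counts.shape
        if n_genes == 0 or n_cells == 0:
            raise ValueError("counts matrix is empty")
        if len(self.gene_ids) != n_genes:
            raise ValueError("gene_ids length does not match counts rows")
        if len(self.cell_ids) != n_cells:
            raise ValueError("cell_ids length does not match counts columns")
        if len(set(self.gene_ids)) != n_genes:
            raise ValueError("duplicate gene_ids")
        if self.section_of_cell.shape != (n_cells,):
            raise ValueError("section_of_cell length does not match cells")
        if np.any(self.counts < 0):
            raise ValueError("negative entries in counts")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    @property
    def n_sections(self) -> int:
        return int(self.section_of_cell.max())

    def library_sizes(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=0)).ravel()


@dataclass
class FeatureMatrix:
    """Low-dimensional expression features, cells x J, with section bookkeeping."""

    features: np.ndarray
    section_of_cell: np.ndarray
    cell_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.section_of_cell = np.asarray(self.section_of_cell, dtype=int)
        if self.features.ndim != 2:
            raise ValueError("features must be 2-D (cells x J)")
        if not np.all(np.isfinite(self.features)):
            raise ValueError("non-finite feature values")
        if self.section_of_cell.shape[0] != self.features.shape[0]:
            raise ValueError("section_of_cell length does not match cells")
        if not self.cell_ids:
            self.cell_ids = [f"cell{i}" for i in range(self.features.shape[0])]

    @property
    def n_cells(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    @property
    def sections(self) -> np.ndarray:
        return np.unique(self.section_of_cell)


def normalize_log_transform(
    counts: CountMatrix, target_sum: float | None = None
) -> np.ndarray:
    """Library-size normalize each cell and apply log2(x + 1).

    Each cell's counts are rescaled so its total equals ``target_sum``
    (default: the median library size over non-empty cells), then
    log2-transformed after adding a pseudo-count of one. All-zero cells pass
    through as all-zero columns.
    """
    mat = counts.counts.astype(float)
    lib = mat.sum(axis=0)
    nonempty = lib > 0
    if target_sum is None:
        if not np.any(nonempty):
            raise ValueError("all cells are empty; cannot pick a target sum")
        target_sum = float(np.median(lib[nonempty]))
    if target_sum <= 0:
        raise ValueError("target_sum must be positive")
    scale = np.ones_like(lib)
    scale[nonempty] = target_sum / lib[nonempty]
    return np.log2(mat * scale[None, :] + 1.0)


def _fix_signs(components: np.ndarray, scores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # sign convention: the largest-magnitude gene loading of each component is positive
    for j in range(components.shape[0]):
        idx = int(np.argmax(np.abs(components[j])))
        if components[j, idx] < 0:
            components[j] *= -1.0
            scores[:, j] *= -1.0
    return components, scores


def extract_features(
    normalized: np.ndarray,
    section_of_cell: Sequence[int] | np.ndarray | None = None,
    J: int = 20,
    cell_ids: Sequence[str] | None = None,
) -> FeatureMatrix:
    """Project cells onto the top-J principal components of the gene-centered matrix.

    ``normalized`` is genes x cells (e.g. the output of
    :func:`normalize_log_transform`). Genes are centered but not unit-scaled.
    If J exceeds the matrix rank it is reduced with a warning.
    """
    normalized = np.asarray(normalized, dtype=float)
    n_genes, n_cells = normalized.shape
    if J < 1:
        raise ValueError("J must be positive")
    J = min(J, n_genes, n_cells)
    X = normalized.T  # cells x genes
    Xc = X - X.mean(axis=0, keepdims=True)
    # deterministic full SVD; sizes here are desk scale
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    tol = s.max(initial=0.0) * max(Xc.shape) * np.finfo(float).eps
    rank = int(np.sum(s > tol))
    if rank == 0:
        warnings.warn("input matrix has rank 0; features are all-zero")
        rank = 1
    if J > rank:
        warnings.warn(f"requested J={J} exceeds matrix rank {rank}; reducing to rank")
        J = rank
    scores = U[:, :J] * s[:J]
    comps, scores = _fix_signs(Vt[:J].copy(), scores.copy())
    if section_of_cell is None:
        section_of_cell = np.ones(n_cells, dtype=int)
    return FeatureMatrix(
        features=scores,
        section_of_cell=np.asarray(section_of_cell, dtype=int),
        cell_ids=list(cell_ids) if cell_ids is not None else [],
    )


def align_sections(
    features: FeatureMatrix,
    method: str = "standardize",
    external_hook: Callable[[np.ndarray, np.ndarray], np.ndarray] | None = None,
) -> FeatureMatrix:
    """Align expression features across tissue sections.

    method="none" returns the input unchanged; "standardize" centers and
    unit-scales every feature within each section (a simple location/scale
    batch correction); "external-hook" applies a user-supplied alignment
    routine (e.g. Harmony) with the contract that output shape equals input
    shape.
    """
    if method == "none":
        return features
    if method == "external-hook":
        if external_hook is None:
            raise ValueError("method 'external-hook' requires an external_hook callable")
        out = np.asarray(external_hook(features.features, features.section_of_cell), dtype=float)
        if out.shape != features.features.shape:
            raise ValueError("external hook changed the feature matrix shape")
        return FeatureMatrix(out, features.section_of_cell, list(features.cell_ids))
    if method != "standardize":
        raise ValueError(f"unknown alignment method: {method!r}")
    out = features.features.copy()
    for sec in features.sections:
        mask = features.section_of_cell == sec
        if mask.sum() < 2:
            raise ValueError(
                f"section {sec} has fewer than 2 cells; cannot standardize"
            )
        block = out[mask]
        mean = block.mean(axis=0)
        std = block.std(axis=0)
        std[std == 0] = 1.0
        out[mask] = (block - mean) / std
    return FeatureMatrix(out, features.section_of_cell, list(features.cell_ids))
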