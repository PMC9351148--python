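"""I/O plumbing, run configuration, and the end-to-end fitting pipeline.

The on-disk contract: a manifest CSV with columns ``section_id``,
``expr_path``, ``coords_path`` (paths relative to the manifest), expression
as Matrix Market (``.mtx`` with ``<stem>.genes.tsv`` / ``<stem>.barcodes.tsv``
sidecars) or dense CSV (genes in rows, header = cell ids), coordinates as CSV
with columns ``cell_id``, ``x``, ``y``. The pipeline intersects cells between
expression and coordinates within each section and genes across sections,
then runs preprocess -> neighbor graph -> initialize -> MCMC -> relabel ->
summarize and writes all outputs with a config snapshot for bit-identical
reruns.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import io as spio
from scipy import sparse

from .evaluate import ari, composition_rmse, matching_permutation, match_labels, nmi, rare_type_scores
from .graph import build_knn_graph
from .inference import FitResult, relabel_ecr, run_mcmc, summarize_posterior
from .model import HyperParams
from .preprocess import CountMatrix, align_sections, extract_features, normalize_log_transform
from .simulate import SimulationTruth

logger = logging.getLogger("pottsmix")

__all__ = [
    "RunConfig",
    "read_inputs",
    "run_pipeline",
    "write_simulation",
    "evaluate_labels",
]


@dataclass
class RunConfig:
    """Everything needed to reproduce one fit."""

    manifest: str
    out_dir: str
    C: int = 4
    R: int = 4
    J: int = 20
    k: int = 6
    n_iter: int = 10_000
    burn_in: int = 5_000
    seed: int = 0
    beta_max: float = 4.0
    alignment: str = "auto"  # none | standardize | auto (standardize iff L > 1)
    dirichlet_alpha: float = 1.0
    lambda_shape: float = 2.0
    lambda_rate: float = 1.0
    target_sum: float | None = None
    inner_sweeps: int = 10

    def __post_init__(self) -> None:
        if self.C < 1 or self.R < 1:
            raise ValueError("C and R must be >= 1")
        if self.n_iter <= self.burn_in:
            raise ValueError("n_iter must exceed burn_in")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _read_expression(path: Path) -> tuple[np.ndarray, list[str], list[str]]:
    """Read one section's genes x cells counts from MTX (+sidecars) or CSV."""
    if path.suffix == ".mtx":
        mat = spio.mmread(path)
        if sparse.issparse(mat):
            mat = mat.toarray()
        mat = np.asarray(mat)
        stem = path.with_suffix("")
        genes_path = Path(str(stem) + ".genes.tsv")
        cells_path = Path(str(stem) + ".barcodes.tsv")
        if not genes_path.exists():
            genes_path = path.parent / "genes.tsv"
        if not cells_path.exists():
            cells_path = path.parent / "barcodes.tsv"
        genes = pd.read_csv(genes_path, header=None, sep="\t")[0].astype(str).tolist()
        cells = pd.read_csv(cells_path, header=None, sep="\t")[0].astype(str).tolist()
        return mat, genes, cells
    df = pd.read_csv(path, index_col=0)
    return df.to_numpy(), [str(g) for g in df.index], [str(c) for c in df.columns]


def read_inputs(manifest_path: str | Path) -> tuple[CountMatrix, pd.DataFrame]:
    """Load all sections listed in a manifest into one CountMatrix + coordinates.

    Cells are intersected between expression and coordinates by cell id
    (dropped cells are logged); genes are intersected across sections; cells
    are ordered contiguously by section.
    """
    manifest_path = Path(manifest_path)
    manifest = pd.read_csv(manifest_path)
    required = {"section_id", "expr_path", "coords_path"}
    if not required.issubset(manifest.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")
    base = manifest_path.parent

    sections = []
    common_genes: set[str] | None = None
    for _, row in manifest.iterrows():
        mat, genes, cells = _read_expression(base / str(row["expr_path"]))
        coords = pd.read_csv(base / str(row["coords_path"]))
        coords["cell_id"] = coords["cell_id"].astype(str)
        keep = [i for i, cid in enumerate(cells) if cid in set(coords["cell_id"])]
        dropped = len(cells) - len(keep)
        if dropped:
            logger.warning(
                "section %s: dropped %d cells without coordinates", row["section_id"], dropped
            )
        if not keep:
            raise ValueError(f"section {row['section_id']}: no cells with coordinates")
        cells = [cells[i] for i in keep]
        mat = mat[:, keep]
        coords = coords.set_index("cell_id").loc[cells].reset_index()
        sections.append((row["section_id"], mat, genes, cells, coords))
        common_genes = set(genes) if common_genes is None else common_genes & set(genes)

    if not common_genes:
        raise ValueError("zero genes shared across sections")
    gene_order = [g for g in sections[0][2] if g in common_genes]

    blocks, cell_ids, section_of_cell, coord_frames = [], [], [], []
    for sec_idx, (sec_id, mat, genes, cells, coords) in enumerate(sections, start=1):
        gidx = [genes.index(g) for g in gene_order]
        blocks.append(mat[gidx, :])
        cell_ids.extend(cells)
        section_of_cell.extend([sec_idx] * len(cells))
        coords = coords.copy()
        coords["section_id"] = sec_id
        coord_frames.append(coords)
    counts = CountMatrix(
        counts=np.hstack(blocks).astype(np.int64),
        gene_ids=gene_order,
        cell_ids=cell_ids,
        section_of_cell=np.asarray(section_of_cell),
    )
    coords_df = pd.concat(coord_frames, ignore_index=True)
    return counts, coords_df


def write_expression(counts: CountMatrix, path: Path) -> None:
    """Write genes x cells counts as MTX (+sidecars) or dense CSV by extension."""
    if path.suffix == ".mtx":
        spio.mmwrite(str(path), sparse.coo_matrix(counts.counts))
        stem = path.with_suffix("")
        pd.Series(counts.gene_ids).to_csv(Path(str(stem) + ".genes.tsv"), index=False, header=False)
        pd.Series(counts.cell_ids).to_csv(
            Path(str(stem) + ".barcodes.tsv"), index=False, header=False
        )
    else:
        pd.DataFrame(counts.counts, index=counts.gene_ids, columns=counts.cell_ids).to_csv(path)


def write_simulation(truth: SimulationTruth, out_dir: str | Path, fmt: str = "csv") -> Path:
    """Write a simulated experiment in the same formats the pipeline reads.

    Produces a manifest plus per-section expression and coordinate files and
    the truth CSVs (labels, composition matrix, DE flags). Returns the
    manifest path.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts = truth.counts
    rows = []
    for sec in range(1, counts.n_sections + 1):
        mask = counts.section_of_cell == sec
        idx = np.flatnonzero(mask)
        sub = CountMatrix(
            counts=counts.counts[:, idx],
            gene_ids=counts.gene_ids,
            cell_ids=[counts.cell_ids[i] for i in idx],
            section_of_cell=np.ones(len(idx), dtype=int),
        )
        expr_name = f"section{sec}_expr." + ("mtx" if fmt == "mtx" else "csv")
        write_expression(sub, out / expr_name)
        coords_name = f"section{sec}_coords.csv"
        pd.DataFrame(
            {
                "cell_id": sub.cell_ids,
                "section_id": sec,
                "x": truth.coords[idx, 0],
                "y": truth.coords[idx, 1],
            }
        ).to_csv(out / coords_name, index=False)
        rows.append({"section_id": sec, "expr_path": expr_name, "coords_path": coords_name})
    manifest = out / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)

    pd.DataFrame(
        {
            "cell_id": counts.cell_ids,
            "section_id": counts.section_of_cell,
            "cell_type": truth.true_c + 1,
            "domain": truth.true_z + 1,
        }
    ).to_csv(out / "truth_labels.csv", index=False)
    pd.DataFrame(
        truth.true_pi,
        index=[f"type{c + 1}" for c in range(truth.true_pi.shape[0])],
        columns=[f"domain{r + 1}" for r in range(truth.true_pi.shape[1])],
    ).to_csv(out / "true_pi.csv")
    pd.DataFrame(
        truth.de_gene_flags,
        index=counts.gene_ids,
        columns=[f"type{c + 1}" for c in range(truth.de_gene_flags.shape[1])],
    ).to_csv(out / "de_gene_flags.csv")
    return manifest


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------

def fit_counts(
    counts: CountMatrix,
    coords_df: pd.DataFrame,
    config: RunConfig,
) -> tuple[FitResult, "object"]:
    """Preprocess, build graphs, and run the sampler on in-memory inputs.

    Returns the posterior summary and the relabeled samples.
    """
    normalized = normalize_log_transform(counts, target_sum=config.target_sum)
    features = extract_features(
        normalized, counts.section_of_cell, J=config.J, cell_ids=counts.cell_ids
    )
    n_sections = len(features.sections)
    method = config.alignment
    if method == "auto":
        method = "standardize" if n_sections > 1 else "none"
    features = align_sections(features, method=method)

    graphs = []
    for sec in features.sections:
        mask = features.section_of_cell == sec
        xy = coords_df.loc[np.flatnonzero(mask), ["x", "y"]].to_numpy()
        graphs.append(build_knn_graph(xy, k=config.k, section_id=int(sec)))

    hyper = HyperParams(
        C=config.C,
        R=config.R,
        J=features.n_features,
        beta_max=config.beta_max,
        dirichlet_alpha=config.dirichlet_alpha,
        mean_prior_location=features.features.mean(axis=0),
        lambda_shape=config.lambda_shape,
        lambda_rate=config.lambda_rate,
    )
    samples = run_mcmc(
        features,
        graphs,
        hyper,
        n_iter=config.n_iter,
        burn_in=config.burn_in,
        seed=config.seed,
        inner_sweeps=config.inner_sweeps,
    )
    samples = relabel_ecr(samples)
    return summarize_posterior(samples), samples


def run_simulation_replicate(
    scenario: str,
    seed: int,
    de_facloc: float = 1.1,
    n_iter: int = 4000,
    burn_in: int = 2000,
    n_sections: int = 1,
) -> dict:
    """One replicate of the simulation study: simulate, fit, score.

    Generates a baseline synthetic section (200 genes, de_prob 0.2, ~1127
    cells) for the given scenario, fits the model with C = R = 4, and returns
    the domain and cell-type ARIs against the simulation truth together with
    the matched composition RMSE.
    """
    from .simulate import SimulationConfig, simulate_experiment

    truth = simulate_experiment(
        SimulationConfig(
            scenario=scenario, de_facloc=de_facloc, seed=seed, n_sections=n_sections
        )
    )
    coords_df = pd.DataFrame({"x": truth.coords[:, 0], "y": truth.coords[:, 1]})
    config = RunConfig(
        manifest="",
        out_dir="",
        C=truth.true_pi.shape[0],
        R=truth.true_pi.shape[1],
        n_iter=n_iter,
        burn_in=burn_in,
        seed=seed,
    )
    fit, _ = fit_counts(truth.counts, coords_df, config)
    cmap = matching_permutation(fit.c_hat, truth.true_c)
    zmap = matching_permutation(fit.z_hat, truth.true_z)
    C, R = truth.true_pi.shape
    perm_c = np.arange(C)
    perm_z = np.arange(R)
    for p, t in cmap.items():
        if 0 <= t < C:
            perm_c[t] = p
    for p, t in zmap.items():
        if 0 <= t < R:
            perm_z[t] = p
    return {
        "ari_domain": ari(fit.z_hat, truth.true_z),
        "ari_celltype": ari(fit.c_hat, truth.true_c),
        "composition_rmse": composition_rmse(
            fit.pi_hat, truth.true_pi, perm_c=perm_c, perm_z=perm_z
        ),
        "beta_hat": fit.beta_hat,
    }


def run_pipeline(config: RunConfig) -> FitResult:
    """Full disk-to-disk run: read manifest, fit, write labels/pi/traces/log."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    snapshot = config.to_yaml()
    (out / "config.yaml").write_text(snapshot)
    config_hash = hashlib.sha256(snapshot.encode()).hexdigest()

    counts, coords_df = read_inputs(config.manifest)
    fit, samples = fit_counts(counts, coords_df, config)

    pd.DataFrame(
        {
            "cell_id": counts.cell_ids,
            "section_id": counts.section_of_cell,
            "cell_type": fit.c_hat + 1,
            "domain": fit.z_hat + 1,
        }
    ).to_csv(out / "labels.csv", index=False)
    pd.DataFrame(
        fit.pi_hat,
        index=[f"type{c + 1}" for c in range(config.C)],
        columns=[f"domain{r + 1}" for r in range(config.R)],
    ).to_csv(out / "pi.csv")
    pd.DataFrame(
        {
            "draw": np.arange(samples.n_draws),
            "beta": samples.beta_draws,
            "log_post": samples.log_post_draws,
        }
    ).to_csv(out / "beta_trace.csv", index=False)
    pd.DataFrame({"feature": np.arange(1, len(fit.lam_hat) + 1), "lambda": fit.lam_hat}).to_csv(
        out / "lambda.csv", index=False
    )
    log = {
        "seed": config.seed,
        "config_sha256": config_hash,
        "beta_hat": fit.beta_hat,
        "beta_accept_rate": samples.beta_accept_rate,
        "n_cells": counts.n_cells,
        "n_genes": counts.n_genes,
        "n_sections": counts.n_sections,
    }
    (out / "run_log.yaml").write_text(yaml.safe_dump(log, sort_keys=True))
    logger.info("run complete: %s", log)
    return fit


def evaluate_labels(
    pred_path: str | Path,
    truth_path: str | Path,
    metrics: list[str],
    pred_pi: str | Path | None = None,
    truth_pi: str | Path | None = None,
    rare_type_ids: list[int] | None = None,
) -> pd.DataFrame:
    """Compare predicted and true label tables (joined on cell_id)."""
    pred = pd.read_csv(pred_path).set_index("cell_id")
    truth = pd.read_csv(truth_path).set_index("cell_id")
    joined = pred.join(truth, lsuffix="_pred", rsuffix="_true", how="inner")
    if joined.empty:
        raise ValueError("no shared cell ids between pred and truth")
    rows = []
    for scale, pcol, tcol in (
        ("cell_type", "cell_type_pred", "cell_type_true"),
        ("domain", "domain_pred", "domain_true"),
    ):
        if pcol not in joined.columns or tcol not in joined.columns:
            continue
        p = joined[pcol].to_numpy()
        t = joined[tcol].to_numpy()
        if "ari" in metrics:
            rows.append({"scale": scale, "metric": "ari", "value": ari(p, t)})
        if "nmi" in metrics:
            rows.append({"scale": scale, "metric": "nmi", "value": nmi(p, t)})
        if scale == "cell_type" and rare_type_ids and ({"f1", "mcc"} & set(metrics)):
            matched = match_labels(p, t)
            scores = rare_type_scores(matched, t, rare_type_ids)
            for m in ("f1", "mcc"):
                if m in metrics:
                    rows.append({"scale": scale, "metric": m, "value": scores[m]})
    if "rmse" in metrics and pred_pi is not None and truth_pi is not None:
        ph = pd.read_csv(pred_pi, index_col=0).to_numpy()
        pt = pd.read_csv(truth_pi, index_col=0).to_numpy()
        cmap = matching_permutation(
            joined["cell_type_pred"].to_numpy(), joined["cell_type_true"].to_numpy()
        )
        zmap = matching_permutation(
            joined["domain_pred"].to_numpy(), joined["domain_true"].to_numpy()
        )
        perm_c = _perm_array(cmap, ph.shape[0])
        perm_z = _perm_array(zmap, ph.shape[1])
        rows.append(
            {
                "scale": "composition",
                "metric": "rmse",
                "value": composition_rmse(ph, pt, perm_c=perm_c, perm_z=perm_z),
            }
        )
    return pd.DataFrame(rows)


def _perm_array(mapping: dict, K: int) -> np.ndarray:
    """Row/column order so that pi_hat[perm] aligns with the truth's indexing.

    mapping sends 1-based predicted labels to matched 1-based truth labels;
    entries of the result are the predicted indices matched to each truth
    index (identity where unmatched).
    """
    perm = np.arange(K)
    for p_label, t_label in mapping.items():
        p_idx, t_idx = int(p_label) - 1, int(t_label) - 1
        if 0 <= t_idx < K and 0 <= p_idx < K:
            perm[t_idx] = p_idx
    return perm
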