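"""Bootstrap cluster alignment between two clustered expression matrices.

Each dataset is normalized by the per-cell median of its non-zero entries
(robust to outlier genes), log1p-transformed, and restricted to the shared
gene set. Cluster-to-cluster Euclidean distances are bootstrapped by
resampling cells with replacement to cluster size; a query cluster's nearest
reference cluster is called a significant match when its distance
distribution lies more than ``sigma`` standard deviations below the
runner-up's distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AlignmentError, DataError

logger = logging.getLogger(__name__)


@dataclass
class ClusteredMatrix:
    """Genes x cells non-negative expression with per-cell cluster labels."""

    values: np.ndarray  # (n_genes, n_cells)
    gene_ids: list[str]
    cell_ids: list[str]
    cluster_labels: dict[str, str]  # cell id -> cluster

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DataError("expression matrix must be 2-D (genes x cells)")
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise DataError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if np.any(self.values < 0):
            raise DataError("expression matrix has negative entries")
        missing = [c for c in self.cell_ids if c not in self.cluster_labels]
        if missing:
            raise DataError(f"{len(missing)} cells lack a cluster label")

    @property
    def clusters(self) -> list[str]:
        return sorted(set(self.cluster_labels[c] for c in self.cell_ids))

    def cluster_columns(self) -> dict[str, np.ndarray]:
        """Column indices per cluster."""
        out: dict[str, list[int]] = {}
        for j, c in enumerate(self.cell_ids):
            out.setdefault(self.cluster_labels[c], []).append(j)
        return {k: np.array(v) for k, v in out.items()}


@dataclass
class AlignmentResult:
    """Per (query, reference) bootstrap distance summaries and match calls."""

    distance_mean: pd.DataFrame  # query clusters x reference clusters
    distance_sd: pd.DataFrame
    matches: dict[str, list[str]] = field(default_factory=dict)
    sigma: float = 1.6
    n_boot: int = 1000
    significance_rule: str = "nearest-vs-runner-up z-separation"


def nonzero_median_normalize(matrix: ClusteredMatrix, log_transform: bool = True) -> ClusteredMatrix:
    """Scale each cell by the median of its non-zero entries, then log1p.

    Cells with no non-zero entry are dropped (with a logged count).
    """
    vals = matrix.values
    keep: list[int] = []
    scaled_cols = []
    for j in range(vals.shape[1]):
        col = vals[:, j]
        nz = col[col > 0]
        if nz.size == 0:
            continue
        keep.append(j)
        scaled_cols.append(col / np.median(nz))
    n_dropped = vals.shape[1] - len(keep)
    if n_dropped:
        logger.warning("dropped %d all-zero cells during normalization", n_dropped)
    out = np.column_stack(scaled_cols) if scaled_cols else np.empty((vals.shape[0], 0))
    if log_transform:
        out = np.log1p(out)
    cell_ids = [matrix.cell_ids[j] for j in keep]
    return ClusteredMatrix(
        values=out,
        gene_ids=list(matrix.gene_ids),
        cell_ids=cell_ids,
        cluster_labels={c: matrix.cluster_labels[c] for c in cell_ids},
    )


def _dedupe_genes(matrix: ClusteredMatrix) -> ClusteredMatrix:
    seen: dict[str, int] = {}
    idx = []
    for i, g in enumerate(matrix.gene_ids):
        if g not in seen:
            seen[g] = i
            idx.append(i)
    if len(idx) == len(matrix.gene_ids):
        return matrix
    return ClusteredMatrix(
        values=matrix.values[idx, :],
        gene_ids=[matrix.gene_ids[i] for i in idx],
        cell_ids=list(matrix.cell_ids),
        cluster_labels=dict(matrix.cluster_labels),
    )


def restrict_to_shared_genes(
    query: ClusteredMatrix, reference: ClusteredMatrix
) -> tuple[ClusteredMatrix, ClusteredMatrix]:
    """Intersect de-duplicated gene sets, order-matched."""
    query = _dedupe_genes(query)
    reference = _dedupe_genes(reference)
    shared = sorted(set(query.gene_ids) & set(reference.gene_ids))
    if len(shared) < 2:
        raise AlignmentError(f"only {len(shared)} shared genes; need >= 2")
    qi = {g: i for i, g in enumerate(query.gene_ids)}
    ri = {g: i for i, g in enumerate(reference.gene_ids)}
    q_idx = [qi[g] for g in shared]
    r_idx = [ri[g] for g in shared]
    q = ClusteredMatrix(query.values[q_idx, :], shared, list(query.cell_ids),
                        dict(query.cluster_labels))
    r = ClusteredMatrix(reference.values[r_idx, :], shared, list(reference.cell_ids),
                        dict(reference.cluster_labels))
    return q, r


def align_clusters(
    query: ClusteredMatrix,
    reference: ClusteredMatrix,
    n_boot: int = 1000,
    sigma: float = 1.6,
    seed: int = 0,
    normalize: bool = True,
) -> AlignmentResult:
    """Bootstrap Euclidean distances between all cluster pairs and call matches.

    Per replicate, each cluster's cells are resampled with replacement to the
    cluster's own size and mean profiles compared. Size-1 clusters are
    excluded with a warning.
    """
    if normalize:
        query = nonzero_median_normalize(query)
        reference = nonzero_median_normalize(reference)
    query, reference = restrict_to_shared_genes(query, reference)

    q_cols = {k: v for k, v in query.cluster_columns().items() if len(v) >= 2}
    r_cols = {k: v for k, v in reference.cluster_columns().items() if len(v) >= 2}
    for name, cols in (("query", query.cluster_columns()), ("reference", reference.cluster_columns())):
        for k, v in cols.items():
            if len(v) < 2:
                logger.warning("excluding size-1 %s cluster %r", name, k)
    if not q_cols or not r_cols:
        raise AlignmentError("no clusters with >= 2 cells to align")

    q_names = sorted(q_cols)
    r_names = sorted(r_cols)
    rng = np.random.default_rng(seed)
    dists = np.zeros((n_boot, len(q_names), len(r_names)))
    for b in range(n_boot):
        q_profiles = {}
        for k in q_names:
            cols = q_cols[k]
            samp = rng.choice(cols, size=len(cols), replace=True)
            q_profiles[k] = query.values[:, samp].mean(axis=1)
        r_profiles = {}
        for k in r_names:
            cols = r_cols[k]
            samp = rng.choice(cols, size=len(cols), replace=True)
            r_profiles[k] = reference.values[:, samp].mean(axis=1)
        for a, qk in enumerate(q_names):
            for c, rk in enumerate(r_names):
                dists[b, a, c] = np.linalg.norm(q_profiles[qk] - r_profiles[rk])

    mean = pd.DataFrame(dists.mean(axis=0), index=q_names, columns=r_names)
    sd = pd.DataFrame(dists.std(axis=0, ddof=1), index=q_names, columns=r_names)

    matches: dict[str, list[str]] = {}
    for qk in q_names:
        row_mean = mean.loc[qk]
        order = row_mean.sort_values().index
        best = order[0]
        if len(order) == 1:
            matches[qk] = [str(best)]
            continue
        runner = order[1]
        spread = float(np.hypot(sd.loc[qk, best], sd.loc[qk, runner]))
        if spread == 0:
            z = np.inf if row_mean[runner] > row_mean[best] else 0.0
        else:
            z = (row_mean[runner] - row_mean[best]) / spread
        matches[qk] = [str(best)] if z > sigma else []
    return AlignmentResult(
        distance_mean=mean,
        distance_sd=sd,
        matches=matches,
        sigma=sigma,
        n_boot=n_boot,
    )
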