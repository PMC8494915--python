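"""DIO vectors and their cosine / Ward.D2 hierarchical clustering.

The DIO (difference between input and output) vector of a residue pair is
the per-time-step residual ``input − output`` left by the apo-trained
autoencoder.  Pairs whose fluctuation pattern the apo model knows
reconstruct to near-zero DIO; holo-specific patterns leave structured
residuals.  Residue pairs of one apo+holo combination are clustered
jointly on the cosine dissimilarity of their DIO vectors with the Ward.D2
agglomeration criterion, and the tree is cut at a range of cluster counts
(default 2..9) to watch holo-specific groups separate from the apo bulk.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform

__all__ = [
    "DIOMatrix",
    "Dendrogram",
    "compute_dio",
    "dio_nonzero_frequency",
    "stack_dio",
    "cosine_distance_matrix",
    "ward_d2_cluster",
    "cut_tree",
    "scan_cuts",
]

logger = logging.getLogger(__name__)

#: sign convention for DIO; recorded in artifact metadata
DIO_SIGN = "input_minus_output"


@dataclass
class DIOMatrix:
    """Signed per-pair reconstruction residuals, same shape as the features."""

    pairs: list[tuple[int, int]]
    values: np.ndarray  # (n_pairs, n_steps), Å, signed
    source: str = ""  # e.g. "apo1", "holo2"
    pair_molecules: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != len(self.pairs):
            raise ValueError("values shape does not match pair list")

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


@dataclass
class Dendrogram:
    """Agglomeration record: scipy linkage matrix plus leaf labels."""

    linkage: np.ndarray  # (n_leaves - 1, 4)
    leaves: list[tuple[tuple[int, int], str]]  # (pair, source)

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    @property
    def merges(self) -> list[tuple[int, int, float, int]]:
        return [(int(a), int(b), float(h), int(n)) for a, b, h, n in self.linkage]


def compute_dio(features, output: np.ndarray, source: str = "") -> DIOMatrix:
    """Elementwise ``input − output`` residual of an inspected feature matrix."""
    X = np.asarray(features.values, dtype=float)
    Y = np.asarray(output, dtype=float)
    if X.shape != Y.shape:
        raise ValueError(f"shape mismatch: input {X.shape} vs output {Y.shape}")
    return DIOMatrix(
        pairs=list(features.pairs),
        values=X - Y,
        source=source,
        pair_molecules=list(getattr(features, "pair_molecules", [])),
    )


def dio_nonzero_frequency(dio: DIOMatrix, eps: float = 1e-6) -> np.ndarray:
    """Per-pair fraction of time steps with ``|DIO| > eps`` (Å)."""
    if eps < 0:
        raise ValueError("eps must be >= 0")
    return (np.abs(dio.values) > eps).mean(axis=1)


def stack_dio(*dios: DIOMatrix) -> tuple[np.ndarray, list[tuple[tuple[int, int], str]]]:
    """Row-stack several DIO matrices, keeping (pair, source) leaf labels."""
    rows = np.vstack([d.values for d in dios])
    labels = [(pair, d.source) for d in dios for pair in d.pairs]
    return rows, labels


def cosine_distance_matrix(rows: np.ndarray) -> np.ndarray:
    """Pairwise cosine dissimilarity ``1 − u·v/(‖u‖‖v‖)``, in [0, 2].

    Zero-norm rows (pairs the autoencoder reconstructs exactly) have no
    direction: they are placed at distance 0 from one another and at the
    maximum distance 2 from every nonzero row, and their count is logged.
    """
    X = np.asarray(rows, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D array with at least 2 rows")
    norms = np.linalg.norm(X, axis=1)
    zero = norms == 0.0
    if zero.any():
        logger.info("cosine_distance_matrix: %d zero-norm rows", int(zero.sum()))
    safe = np.where(zero, 1.0, norms)
    unit = X / safe[:, None]
    D = 1.0 - unit @ unit.T
    D[zero[:, None] & zero[None, :]] = 0.0
    D[zero[:, None] ^ zero[None, :]] = 2.0
    np.fill_diagonal(D, 0.0)
    np.clip(D, 0.0, 2.0, out=D)
    return 0.5 * (D + D.T)


def ward_d2_cluster(
    dissimilarity: np.ndarray,
    leaves: list[tuple[tuple[int, int], str]] | None = None,
) -> Dendrogram:
    """Agglomerative clustering under the Ward.D2 criterion.

    Successively merges the cluster pair minimising the Lance–Williams
    update ``d(i∪j,k) = sqrt(((n_i+n_k) d_ik² + (n_j+n_k) d_jk²
    − n_k d_ij²) / (n_i+n_j+n_k))`` on the (possibly non-Euclidean) input
    dissimilarities — the behaviour of R ``hclust(method="ward.D2")``.
    Heights are on the dissimilarity scale.
    """
    D = np.asarray(dissimilarity, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("dissimilarity must be square")
    if not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("dissimilarity must be symmetric")
    Z = sch.linkage(squareform(D, checks=False), method="ward")
    if leaves is None:
        leaves = [((i, i), "") for i in range(D.shape[0])]
    elif len(leaves) != D.shape[0]:
        raise ValueError("leaf labels do not match matrix size")
    return Dendrogram(linkage=Z, leaves=leaves)


def cut_tree(dendrogram: Dendrogram, k: int) -> np.ndarray:
    """Cluster label per leaf at exactly ``k`` clusters; cuts nest across k."""
    n = dendrogram.n_leaves
    if not (1 <= k <= n):
        raise ValueError(f"k must be in [1, {n}], got {k}")
    return sch.cut_tree(dendrogram.linkage, n_clusters=k).ravel()


def scan_cuts(
    dendrogram: Dendrogram,
    k_range: tuple[int, int] = (2, 9),
    sources: list[str] | None = None,
) -> dict[int, dict]:
    """Cut the tree at each k in ``k_range`` and tally apo/holo composition.

    Returns ``{k: {"labels": array, "composition": DataFrame}}`` where the
    composition table counts leaves per cluster by source tag.
    """
    k_min, k_max = k_range
    if not (2 <= k_min <= k_max <= dendrogram.n_leaves):
        raise ValueError(f"invalid k_range {k_range} for {dendrogram.n_leaves} leaves")
    if sources is None:
        sources = [src for (_, src) in dendrogram.leaves]
    out: dict[int, dict] = {}
    for k in range(k_min, k_max + 1):
        labels = cut_tree(dendrogram, k)
        comp = (
            pd.DataFrame({"cluster": labels, "source": sources})
            .value_counts()
            .rename("n_pairs")
            .reset_index()
            .sort_values(["cluster", "source"])
            .reset_index(drop=True)
        )
        out[k] = {"labels": labels, "composition": comp}
    return out
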