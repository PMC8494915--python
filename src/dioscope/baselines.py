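"""Comparison analyses: DCCM, DCCM-network betweenness, mean/variance.

These are the conventional trajectory analyses the DIO method is
benchmarked against: the dynamic cross-correlation matrix (DCCM) of Cα
displacements, a residue ranking by betweenness centrality on the
thresholded DCCM network, and a PCA-like summary of each residue pair's
distance series by its mean and variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .md_features import TrajectoryFrames, _kabsch, _select_atom_indices

__all__ = ["DCCM", "compute_dccm", "betweenness_ranking", "pair_mean_variance"]


@dataclass
class DCCM:
    """Normalised displacement covariance: symmetric, unit diagonal, in [−1, 1]."""

    matrix: np.ndarray
    resids: np.ndarray
    selection: str = "CA"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.resids, columns=self.resids)


def compute_dccm(
    frames: TrajectoryFrames, selection: str = "CA", superpose: bool = True
) -> DCCM:
    """Dynamic cross-correlation of the selected atoms' displacements.

    ``C_ij = ⟨Δr_i·Δr_j⟩ / sqrt(⟨Δr_i²⟩⟨Δr_j²⟩)`` with Δr the deviation
    from the time-average position after superposition onto the average
    structure.  Zero-variance entries are set to 0 with a warning.
    """
    if frames.n_frames < 2:
        raise ValueError("DCCM needs at least 2 frames")
    idx = _select_atom_indices(frames, selection)
    if len(idx) == 0:
        raise ValueError(f"no atoms match selection {selection!r}")
    X = frames.coords[:, idx, :]
    if superpose:
        ref = X.mean(axis=0)
        X = np.stack([_kabsch(f, ref) for f in X])
    dX = X - X.mean(axis=0)  # (frames, atoms, 3)
    cov = np.einsum("tid,tjd->ij", dX, dX) / dX.shape[0]
    var = np.diag(cov).copy()
    zero = var <= 0.0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} zero-variance atoms; their correlations set to 0")
    denom = np.sqrt(np.where(zero, 1.0, var))
    C = cov / denom[:, None] / denom[None, :]
    C[zero, :] = 0.0
    C[:, zero] = 0.0
    np.fill_diagonal(C, np.where(zero, 0.0, 1.0))
    np.clip(C, -1.0, 1.0, out=C)
    return DCCM(matrix=C, resids=frames.atoms["resid"].values[idx], selection=selection)


def betweenness_ranking(
    dccm: DCCM, edge_threshold: float = 0.5, top_m: int | None = None
) -> pd.DataFrame:
    """Residues ranked by betweenness centrality on the |C| ≥ threshold graph.

    Edges connect residue pairs whose absolute correlation reaches the
    threshold; centrality is shortest-path betweenness on the unweighted
    graph.  Returns all residues sorted by centrality (ties by residue
    number), truncated to ``top_m`` when given.
    """
    if not (0.0 < edge_threshold < 1.0):
        raise ValueError("edge_threshold must be in (0, 1)")
    C = dccm.matrix
    resids = [int(r) for r in dccm.resids]
    G = nx.Graph()
    G.add_nodes_from(resids)
    n = len(resids)
    for i in range(n):
        for j in range(i + 1, n):
            if abs(C[i, j]) >= edge_threshold:
                G.add_edge(resids[i], resids[j])
    bc = nx.betweenness_centrality(G, normalized=True)
    table = pd.DataFrame(
        sorted(bc.items(), key=lambda kv: (-kv[1], kv[0])),
        columns=["residue", "betweenness"],
    )
    table["empty_graph"] = G.number_of_edges() == 0
    if top_m is not None:
        table = table.head(top_m).reset_index(drop=True)
    return table


def pair_mean_variance(features) -> pd.DataFrame:
    """Mean and unbiased variance of each pair's distance series."""
    X = np.asarray(features.values, dtype=float)
    if X.shape[1] < 2:
        raise ValueError("need at least 2 time steps")
    return pd.DataFrame(
        {
            "pair_i": [p[0] for p in features.pairs],
            "pair_j": [p[1] for p in features.pairs],
            "mean": X.mean(axis=1),
            "variance": X.var(axis=1, ddof=1),
        }
    )
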