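"""Morphometric similarity networks.

A subject's network has the 68 atlas regions as nodes; the edge between two
regions is the Pearson correlation of their 7-element morphometric feature
profiles after each feature has been z-scored across regions.  Optional
density thresholding keeps only the strongest edges by absolute weight;
degree, normalised nodal strength (mean surviving edge weight) and global
strength (mean of nodal strengths) are the derived node/graph metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import DK_REGIONS, FEATURES, N_REGIONS
from .synthetic import MorphometryTable

__all__ = [
    "MSNGraph",
    "zscore_across_regions",
    "build_msn",
    "vectorize_edges",
    "edges_to_matrix",
    "threshold_by_density",
    "nodal_strength",
    "build_msn_for_table",
]

def _triu(n: int) -> tuple[np.ndarray, np.ndarray]:
    return np.triu_indices(n, k=1)


def zscore_across_regions(values: np.ndarray, subject_id: str = "?") -> np.ndarray:
    """Z-score each feature column across the 68 regions (mean 0, SD 1).

    Uses the population SD; a constant feature column is a hard error since
    it would make every inter-regional correlation undefined.
    """
    values = np.asarray(values, dtype=float)
    if values.shape != (N_REGIONS, len(FEATURES)):
        raise ValueError(f"expected shape {(N_REGIONS, len(FEATURES))}, got {values.shape}")
    mu = values.mean(axis=0)
    sd = values.std(axis=0)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        raise ValueError(
            f"feature {FEATURES[zero[0]]!r} is constant across regions for subject {subject_id!r}"
        )
    return (values - mu) / sd


@dataclass
class MSNGraph:
    """One subject's similarity network.

    ``weights`` is the symmetric 68x68 Pearson correlation matrix (the
    diagonal is stored as zero and excluded from every metric); ``mask``
    marks surviving edges (all off-diagonal entries when unthresholded).
    """

    subject_id: str
    weights: np.ndarray
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    density: float | str = "unthresholded"
    node_labels: tuple[str, ...] = DK_REGIONS

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        n = self.weights.shape[0]
        if self.weights.shape != (n, n):
            raise ValueError("weights must be square")
        if len(self.node_labels) != n:
            self.node_labels = tuple(f"node{i}" for i in range(n))
        if self.mask is None:
            self.mask = ~np.eye(n, dtype=bool)

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def degree(self) -> np.ndarray:
        return self.mask.sum(axis=1)

    def edge_frame(self) -> pd.DataFrame:
        i, j = _triu(self.n_nodes)
        labels = np.asarray(self.node_labels)
        return pd.DataFrame({
            "region_i": labels[i],
            "region_j": labels[j],
            "weight": self.weights[i, j],
            "surviving": self.mask[i, j],
        })

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.weights, index=list(self.node_labels),
                     columns=list(self.node_labels)).to_csv(path)


def build_msn(normalized: np.ndarray, subject_id: str = "?") -> MSNGraph:
    """Unthresholded MSN from a z-scored 68x7 matrix.

    Edge (i, j) is the Pearson correlation of the regions' 7-long feature
    vectors.  A region with zero variance across its 7 features would yield
    undefined correlations and is rejected.
    """
    normalized = np.asarray(normalized, dtype=float)
    if normalized.shape != (N_REGIONS, len(FEATURES)):
        raise ValueError(f"expected shape {(N_REGIONS, len(FEATURES))}, got {normalized.shape}")
    row_sd = normalized.std(axis=1)
    zero = np.flatnonzero(row_sd == 0)
    if zero.size:
        raise ValueError(
            f"region {DK_REGIONS[zero[0]]!r} has a constant feature profile for "
            f"subject {subject_id!r}; its correlations are undefined"
        )
    weights = np.corrcoef(normalized)
    np.fill_diagonal(weights, 0.0)
    weights = np.clip(weights, -1.0, 1.0)
    weights = (weights + weights.T) / 2.0
    return MSNGraph(subject_id=subject_id, weights=weights)


def vectorize_edges(g: MSNGraph) -> np.ndarray:
    """Upper-triangle (i < j) edge weights in fixed node order.

    Length p(p-1)/2, i.e. 2278 on the 68-region atlas.
    """
    return g.weights[_triu(g.n_nodes)].copy()


def edges_to_matrix(edges: np.ndarray) -> np.ndarray:
    """Inverse of :func:`vectorize_edges` (zero diagonal)."""
    edges = np.asarray(edges, dtype=float)
    p = int(round((1 + np.sqrt(1 + 8 * edges.size)) / 2))
    if p * (p - 1) // 2 != edges.size:
        raise ValueError(f"edge vector length {edges.size} is not triangular")
    m = np.zeros((p, p))
    m[_triu(p)] = edges
    return m + m.T


def threshold_by_density(g: MSNGraph, density: float) -> MSNGraph:
    """Keep the round-half-even(density * n_edges) edges largest in |weight|.

    Signed weights are retained; ties are broken deterministically by
    (|weight| descending, i, j), so lower densities always select a subset
    of the edges kept at higher densities.
    """
    if not (0.0 < density <= 1.0):
        raise ValueError(f"density must lie in (0, 1], got {density}")
    i, j = _triu(g.n_nodes)
    w = np.abs(g.weights[i, j])
    k = int(np.rint(density * w.size))
    order = np.lexsort((j, i, -w))  # |w| desc, then i, then j
    keep = order[:k]
    mask = np.zeros((g.n_nodes, g.n_nodes), dtype=bool)
    mask[i[keep], j[keep]] = True
    mask |= mask.T
    return MSNGraph(subject_id=g.subject_id, weights=g.weights.copy(),
                    mask=mask, density=density, node_labels=g.node_labels)


def nodal_strength(g: MSNGraph) -> tuple[np.ndarray, float]:
    """Normalised nodal strength and global strength.

    strength_i = sum of node i's surviving edge weights / degree_i; the
    global value is the mean nodal strength across the network.  A node
    left with no surviving edge has no defined strength and is an error.
    """
    degree = g.degree
    if np.any(degree == 0):
        node = int(np.flatnonzero(degree == 0)[0])
        raise ValueError(f"node {g.node_labels[node]!r} has zero degree after thresholding")
    sums = np.where(g.mask, g.weights, 0.0).sum(axis=1)
    strength = sums / degree
    return strength, float(strength.mean())


def build_msn_for_table(morpho: MorphometryTable, density: float | None = None) -> list[MSNGraph]:
    """MSNs for every subject of a (harmonised) morphometry table."""
    vals = morpho.values_array()
    graphs = []
    for sid, block in zip(morpho.subject_ids, vals):
        g = build_msn(zscore_across_regions(block, subject_id=sid), subject_id=sid)
        if density is not None:
            g = threshold_by_density(g, density)
        graphs.append(g)
    return graphs
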