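"""Structural connectome summaries: node strength, group consistency, density.

Connectomes are weighted undirected adjacency matrices (symmetric,
nonnegative, zero diagonal); weights are streamline counts or comparable
tract-strength measures.  A region's strength ``s`` is its weighted degree
(row sum).  The group connectome keeps edges present in more than a given
fraction of subjects and averages the nonzero subject weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ConnectomeMatrix",
    "GroupConnectome",
    "node_strength",
    "group_connectome",
    "edge_density",
]


@dataclass
class ConnectomeMatrix:
    """Symmetric nonnegative weighted adjacency with zero diagonal."""

    weights: np.ndarray
    region_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.all(np.isfinite(w)):
            raise ValueError("adjacency must be finite")
        if not np.allclose(w, w.T, rtol=0, atol=1e-10):
            i, j = np.unravel_index(np.argmax(np.abs(w - w.T)), w.shape)
            raise ValueError(f"adjacency is asymmetric at ({i}, {j})")
        if np.any(np.diag(w) != 0):
            raise ValueError("adjacency diagonal must be zero")
        if np.any(w < 0):
            raise ValueError("adjacency weights must be nonnegative")
        self.weights = w
        if not self.region_ids:
            self.region_ids = [f"region_{i:02d}" for i in range(w.shape[0])]
        if len(self.region_ids) != w.shape[0]:
            raise ValueError("region_ids length must match matrix size")

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]


@dataclass
class GroupConnectome(ConnectomeMatrix):
    """A group-consistency connectome, remembering the threshold used."""

    consistency: float = 0.75


def node_strength(a: ConnectomeMatrix | np.ndarray) -> np.ndarray:
    """Per-region strength s_i = sum_j A_ij (weighted degree)."""
    if not isinstance(a, ConnectomeMatrix):
        a = ConnectomeMatrix(a)
    return a.weights.sum(axis=1)


def group_connectome(
    matrices, consistency: float = 0.75
) -> GroupConnectome:
    """Group connectome over subjects at a strict consistency threshold.

    An edge is retained iff it is nonzero in strictly more than
    ``consistency`` of the subjects; its weight is the mean over the
    subjects in which it is nonzero (zeros excluded from the average).
    """
    mats = [m.weights if isinstance(m, ConnectomeMatrix) else np.asarray(m, float) for m in matrices]
    if len(mats) < 2:
        raise ValueError("group_connectome needs at least 2 subjects")
    shapes = {m.shape for m in mats}
    if len(shapes) != 1:
        raise ValueError(f"subject connectome shapes differ: {sorted(shapes)}")
    stack = np.stack(mats)
    present = (stack > 0).sum(axis=0)
    keep = present / stack.shape[0] > consistency
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_nonzero = np.where(present > 0, stack.sum(axis=0) / np.maximum(present, 1), 0.0)
    weights = np.where(keep, mean_nonzero, 0.0)
    np.fill_diagonal(weights, 0.0)
    region_ids = (
        list(matrices[0].region_ids) if isinstance(matrices[0], ConnectomeMatrix) else []
    )
    return GroupConnectome(weights, region_ids=region_ids, consistency=consistency)


def edge_density(g: ConnectomeMatrix | np.ndarray) -> float:
    """Fraction of possible (undirected) edges that are nonzero."""
    if not isinstance(g, ConnectomeMatrix):
        g = ConnectomeMatrix(g)
    n = g.n_regions
    iu = np.triu_indices(n, 1)
    return float((g.weights[iu] > 0).sum() / (n * (n - 1) / 2))
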