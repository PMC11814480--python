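"""Global graph-theory measures of weighted structural connectomes.

A connectome is a symmetric non-negative weight matrix (default 84
nodes, one per cortical/subcortical atlas region). Five whole-network
measures summarize it:

- **edge density** — nonzero edges / possible edges;
- **characteristic path length** — mean shortest-path distance over
  connected node pairs, with edge length 1/weight;
- **clustering coefficient** — mean nodal weighted clustering (Onnela:
  geometric mean of triangle weights normalized by the network max);
- **assortativity** — Pearson correlation of endpoint strengths
  (weighted degrees) over edges;
- **global efficiency** — mean inverse shortest-path distance, with
  disconnected pairs contributing 0.

Degenerate quantities (path length of an edgeless graph, assortativity
of a strength-regular graph) are reported as NaN rather than 0: they
are undefined, not null.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

from .errors import ValidationError

__all__ = ["Connectome", "GlobalMetrics", "global_metrics", "METRIC_NAMES"]

METRIC_NAMES = (
    "density",
    "char_path_length",
    "clustering_coeff",
    "assortativity",
    "global_efficiency",
)

_SYMMETRY_TOL = 1e-12


@dataclass
class Connectome:
    """Symmetric weighted network on ``n`` nodes with zero diagonal."""

    weights: np.ndarray
    labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        W = np.asarray(self.weights, dtype=float)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValidationError("weights must be a square matrix")
        if W.shape[0] < 3:
            raise ValidationError("a connectome needs at least 3 nodes")
        if not np.isfinite(W).all():
            raise ValidationError("weights must be finite")
        if np.abs(W - W.T).max() > _SYMMETRY_TOL:
            raise ValidationError("weights must be symmetric")
        if (W < 0).any():
            raise ValidationError("weights must be non-negative")
        if np.abs(np.diag(W)).max() > 0:
            raise ValidationError("diagonal must be zero")
        self.weights = W
        if self.labels is None:
            self.labels = tuple(f"node{i:03d}" for i in range(W.shape[0]))
        elif len(self.labels) != W.shape[0]:
            raise ValidationError("label count must match node count")
        else:
            self.labels = tuple(self.labels)

    @property
    def n(self) -> int:
        return self.weights.shape[0]

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.weights, columns=list(self.labels)).to_csv(
            path, sep="\t", index=False, float_format="%.17g"
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Connectome":
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
        return cls(weights=df.to_numpy(dtype=float), labels=tuple(df.columns))


@dataclass(frozen=True)
class GlobalMetrics:
    density: float
    char_path_length: float
    clustering_coeff: float
    assortativity: float
    global_efficiency: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


def _shortest_distances(W: np.ndarray) -> np.ndarray:
    """All-pairs shortest-path distances with edge length 1/weight."""
    i, j = np.nonzero(np.triu(W, k=1))
    lengths = csr_matrix((1.0 / W[i, j], (i, j)), shape=W.shape)
    return dijkstra(lengths, directed=False)


def _assortativity(W: np.ndarray, weighted: bool) -> float:
    """Pearson correlation of endpoint strengths over edges (both
    orientations), NaN when endpoint strengths have zero variance."""
    s = W.sum(axis=1) if weighted else (W > 0).sum(axis=1).astype(float)
    i, j = np.nonzero(np.triu(W, k=1))
    if i.size < 2:
        return float("nan")
    x = np.concatenate([s[i], s[j]])
    y = np.concatenate([s[j], s[i]])
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def global_metrics(c: Connectome, weighted: bool = True) -> GlobalMetrics:
    """Compute the five global network measures of a connectome.

    ``weighted=False`` switches clustering and assortativity to their
    binary-graph variants (distances still use 1/weight, which for a
    0/1 matrix reduces to hop counts). Uniform rescaling of all weights
    leaves density, clustering and assortativity unchanged.
    """
    W = c.weights
    n = c.n
    n_edges = int(np.count_nonzero(np.triu(W, k=1)))
    density = n_edges / (n * (n - 1) / 2.0)

    if n_edges == 0:
        return GlobalMetrics(
            density=0.0,
            char_path_length=float("nan"),
            clustering_coeff=0.0,
            assortativity=float("nan"),
            global_efficiency=0.0,
        )

    D = _shortest_distances(W)
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(D) & off
    char_path_length = float(D[finite].mean()) if finite.any() else float("nan")
    inv = np.zeros_like(D)
    inv[finite] = 1.0 / D[finite]
    global_efficiency = float(inv[off].sum() / (n * (n - 1)))

    G = nx.from_numpy_array(W)
    clustering = nx.clustering(G, weight="weight" if weighted else None)
    clustering_coeff = float(np.mean(list(clustering.values())))

    return GlobalMetrics(
        density=float(density),
        char_path_length=char_path_length,
        clustering_coeff=clustering_coeff,
        assortativity=_assortativity(W, weighted),
        global_efficiency=global_efficiency,
    )
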