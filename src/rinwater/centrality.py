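"""Residue Centrality Analysis (RCA) and Betweenness Centrality Analysis (BCA).

Both methods score every node of a RIN and standardize the raw scores into
Z-scores over all nodes of the same network (waters included in wet RINs —
one shared normalization population per analysis). A node with Z ≥ 2 is
called central.

RCA: raw_i = L(G − i) − L(G), the change in average shortest path length when
node i and its incident edges are removed. L averages over connected node
pairs only; pairs split across components are excluded from both numerator
and denominator, so removal-induced disconnection enters through the changed
pair set. Positive raw (and Z) means removal lengthens communication.

BCA: raw_i is unnormalized Brandes betweenness — the number of shortest
paths between other node pairs passing through i, each pair's paths
fractionally weighted. The normalization choice cancels in Z-scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import networkx as nx
import numpy as np
from scipy.sparse import csr_array
from scipy.sparse.csgraph import shortest_path

from .rin import RIN

__all__ = [
    "CentralityResult",
    "CentralNodeSet",
    "average_shortest_path_length",
    "rca",
    "bca",
    "zscore",
    "central_nodes",
    "CENTRAL_Z_THRESHOLD",
]

#: Default Z cutoff defining a central node.
CENTRAL_Z_THRESHOLD = 2.0


@dataclass
class CentralityResult:
    """Per-node raw centrality and Z-score for one method on one RIN."""

    method: str  # "RCA" or "BCA"
    rin_metadata: dict
    labels: list[str]
    raw: dict[str, float]
    z: dict[str, float]
    node_kind: dict[str, str] = field(default_factory=dict)
    node_chain: dict[str, str] = field(default_factory=dict)

    def central(self, threshold: float = CENTRAL_Z_THRESHOLD) -> "CentralNodeSet":
        return central_nodes(self, threshold)

    def z_of(self, label: str) -> float:
        return self.z[label]

    def to_frame(self):
        """Tidy per-node table: label, kind, chain, raw, z."""
        import pandas as pd

        return pd.DataFrame(
            {
                "label": self.labels,
                "kind": [self.node_kind.get(l, "") for l in self.labels],
                "chain": [self.node_chain.get(l, "") for l in self.labels],
                "raw": [self.raw[l] for l in self.labels],
                "z": [self.z[l] for l in self.labels],
            }
        )


@dataclass(frozen=True)
class CentralNodeSet:
    threshold: float
    labels: frozenset[str]

    def __contains__(self, label: str) -> bool:
        return label in self.labels

    def __iter__(self):
        return iter(sorted(self.labels))

    def __len__(self) -> int:
        return len(self.labels)


def _adjacency(g: nx.Graph, order: list) -> csr_array:
    m = nx.to_scipy_sparse_array(g, nodelist=order, dtype=np.int8, format="csr")
    return m


def _avg_connected_pairs(dist: np.ndarray) -> float:
    """Mean finite off-diagonal distance; 0 when no pair is connected."""
    n = dist.shape[0]
    if n < 2:
        return 0.0
    iu = np.triu_indices(n, k=1)
    d = dist[iu]
    finite = np.isfinite(d)
    if not finite.any():
        return 0.0
    return float(d[finite].mean())


def average_shortest_path_length(rin: RIN | nx.Graph) -> float:
    """Average shortest path length over connected node pairs.

    Pairs in different components are excluded from numerator and
    denominator; a graph with no connected pair yields 0.
    """
    g = rin.graph if isinstance(rin, RIN) else rin
    if g.number_of_nodes() < 2:
        raise ValueError("average shortest path length needs >= 2 nodes")
    order = list(g.nodes)
    adj = _adjacency(g, order)
    dist = shortest_path(adj, method="D", unweighted=True, directed=False)
    return _avg_connected_pairs(dist)


def rca(rin: RIN | nx.Graph) -> CentralityResult:
    """Node-removal centrality: effect of each removal on the average
    shortest path length, Z-scored over all nodes."""
    g = rin.graph if isinstance(rin, RIN) else rin
    if g.number_of_nodes() < 3:
        raise ValueError("RCA needs >= 3 nodes")
    order = list(g.nodes)
    n = len(order)
    adj = _adjacency(g, order).toarray()
    base = _avg_connected_pairs(
        shortest_path(csr_array(adj), method="D", unweighted=True, directed=False)
    )
    raw = np.empty(n)
    keep = np.ones(n, dtype=bool)
    for i in range(n):
        keep[i] = False
        sub = adj[np.ix_(keep, keep)]
        d = shortest_path(csr_array(sub), method="D", unweighted=True, directed=False)
        raw[i] = _avg_connected_pairs(d) - base
        keep[i] = True
    return _finish(rin, "RCA", order, raw)


def bca(rin: RIN | nx.Graph) -> CentralityResult:
    """Unnormalized betweenness centrality, Z-scored over all nodes."""
    g = rin.graph if isinstance(rin, RIN) else rin
    if g.number_of_nodes() < 3:
        raise ValueError("BCA needs >= 3 nodes")
    bet = nx.betweenness_centrality(g, normalized=False)
    order = list(g.nodes)
    raw = np.array([bet[v] for v in order], dtype=float)
    return _finish(rin, "BCA", order, raw)


def _finish(rin: RIN | nx.Graph, method: str, order: list, raw: np.ndarray) -> CentralityResult:
    z = _zscore_array(raw)
    g = rin.graph if isinstance(rin, RIN) else rin
    meta = dict(rin.metadata) if isinstance(rin, RIN) else {}
    meta["z_population_size"] = len(order)
    return CentralityResult(
        method=method,
        rin_metadata=meta,
        labels=list(order),
        raw={v: float(r) for v, r in zip(order, raw)},
        z={v: float(s) for v, s in zip(order, z)},
        node_kind={v: g.nodes[v].get("kind", "") for v in order},
        node_chain={v: g.nodes[v].get("chain", "") for v in order},
    )


def _zscore_array(x: np.ndarray) -> np.ndarray:
    mu = x.mean()
    sigma = x.std(ddof=0)
    if sigma == 0.0 or not np.isfinite(sigma):
        return np.zeros_like(x)
    return (x - mu) / sigma


def zscore(values: Mapping[str, float], population: list[str] | None = None) -> dict[str, float]:
    """Standardize values over a population (mean 0, population SD 1).

    Zero spread maps everything to 0. ``population`` defaults to all keys;
    a key outside the population is an error.
    """
    pop = list(values.keys()) if population is None else list(population)
    if not pop:
        raise ValueError("empty population")
    missing = [p for p in pop if p not in values]
    if missing:
        raise KeyError(f"values missing for population members: {missing[:3]}")
    extra = set(values) - set(pop)
    if extra:
        raise KeyError(f"labels outside population: {sorted(extra)[:3]}")
    x = np.array([values[p] for p in pop], dtype=float)
    z = _zscore_array(x)
    return {p: float(v) for p, v in zip(pop, z)}


def central_nodes(result: CentralityResult, threshold: float = CENTRAL_Z_THRESHOLD) -> CentralNodeSet:
    """Nodes with Z ≥ threshold (inclusive)."""
    return CentralNodeSet(
        threshold=threshold,
        labels=frozenset(l for l, v in result.z.items() if v >= threshold),
    )
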