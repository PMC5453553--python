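"""Network statistics: node in/out-strength and density.

All statistics operate on a weighted directed adjacency ``W`` whose entry
(j, k) is the weight of the edge j -> k (item j at t-1 to item k at t);
diagonal entries are the autoregressive self-loops.  Weights may be sparse
regression coefficients (exact zeros from the lasso) or significance-
thresholded fixed effects from the multilevel comparator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: density definitions
EDGES_EXCL_AR = "edges_excl_ar"   # E / (V (V-1)), self-loops not counted
EDGES_INCL_AR = "edges_incl_ar"   # nonzero incl. diagonal / V^2
AVG_SPARSE = "avg_sparse"         # mean |w| over the nonzero (remaining) edges
AVG_ALL = "avg_all"               # mean |w| over all V^2 entries
DENSITY_DEFS = (EDGES_EXCL_AR, EDGES_INCL_AR, AVG_SPARSE, AVG_ALL)


@dataclass
class DirectedNetwork:
    W: np.ndarray
    node_names: list[str] | None = None
    weight_semantics: str = "regression-weight"

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        if self.W.ndim != 2 or self.W.shape[0] != self.W.shape[1]:
            raise ValueError("W must be square")
        if not np.isfinite(self.W).all():
            raise ValueError("W must be finite")
        if self.node_names is None:
            self.node_names = [f"node_{i + 1}" for i in range(self.W.shape[0])]

    @property
    def n_nodes(self) -> int:
        return self.W.shape[0]

    def to_networkx(self):
        """Signed weighted DiGraph (self-loops included), for plotting/export."""
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(self.node_names)
        for j in range(self.n_nodes):
            for k in range(self.n_nodes):
                w = self.W[j, k]
                if w != 0:
                    g.add_edge(self.node_names[j], self.node_names[k],
                               weight=w, sign=int(np.sign(w)))
        return g

    def edge_list(self, stable: np.ndarray | None = None) -> pd.DataFrame:
        rows = []
        for j in range(self.n_nodes):
            for k in range(self.n_nodes):
                w = self.W[j, k]
                if w != 0:
                    rows.append({
                        "source": self.node_names[j],
                        "target": self.node_names[k],
                        "weight": w,
                        "sign": int(np.sign(w)),
                        "stable": bool(stable[j, k]) if stable is not None else True,
                    })
        return pd.DataFrame(rows, columns=["source", "target", "weight", "sign", "stable"])


@dataclass
class StrengthTable:
    """Per-node strength (sum of absolute weights, self-loops excluded)."""

    in_strength: np.ndarray
    out_strength: np.ndarray
    node_names: list[str]

    def summary(self) -> pd.DataFrame:
        rows = {}
        for label, v in (("in_strength", self.in_strength), ("out_strength", self.out_strength)):
            rows[label] = {
                "mean": float(np.mean(v)),
                "sd": float(np.std(v, ddof=1)) if len(v) > 1 else 0.0,
                "median": float(np.median(v)),
                "min": float(np.min(v)),
                "max": float(np.max(v)),
            }
        return pd.DataFrame(rows).T

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "node": self.node_names,
            "in_strength": self.in_strength,
            "out_strength": self.out_strength,
        })


def strengths(net: DirectedNetwork) -> StrengthTable:
    """in(k) = sum_{j != k} |W_jk|; out(j) = sum_{k != j} |W_jk|."""
    W = np.abs(net.W.copy())
    np.fill_diagonal(W, 0.0)
    return StrengthTable(in_strength=W.sum(axis=0), out_strength=W.sum(axis=1),
                         node_names=list(net.node_names))


def density(net: DirectedNetwork, definition: str = EDGES_EXCL_AR) -> float:
    """One of the four density statistics; 'nonzero' means |w| > 0 exactly."""
    W = net.W
    V = net.n_nodes
    if V < 2:
        raise ValueError("density needs at least 2 nodes")
    off = ~np.eye(V, dtype=bool)
    if definition == EDGES_EXCL_AR:
        return float((W[off] != 0).sum() / (V * (V - 1)))
    if definition == EDGES_INCL_AR:
        return float((W != 0).sum() / V**2)
    if definition == AVG_SPARSE:
        nz = W[W != 0]
        return float(np.abs(nz).mean()) if nz.size else 0.0
    if definition == AVG_ALL:
        return float(np.abs(W).mean())
    raise ValueError(f"unknown density definition: {definition!r}")


@dataclass
class DensityReport:
    density_edges_excl_ar: float
    density_edges_incl_ar: float
    density_avg_sparse: float
    density_avg_all: float

    @classmethod
    def from_network(cls, net: DirectedNetwork) -> "DensityReport":
        return cls(*(density(net, d) for d in DENSITY_DEFS))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "definition": list(DENSITY_DEFS),
            "density": [self.density_edges_excl_ar, self.density_edges_incl_ar,
                        self.density_avg_sparse, self.density_avg_all],
        })
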