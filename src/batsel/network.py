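"""Coexpression networks from thresholded Pearson correlation.

Gene pairs are linked when their expression correlation exceeds a fixed
threshold tau (default 0.8, strict inequality).  Building one network per
biological state (normal vs tumor samples) and taking the symmetric
difference of the edge sets yields the differential coexpression network:
pairs coexpressed in exactly one state.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .io import ExpressionMatrix

__all__ = [
    "GeneNetwork",
    "pearson_matrix",
    "threshold_network",
    "differential_network",
]


def pearson_matrix(
    x: ExpressionMatrix, sample_subset: int | None = None
) -> np.ndarray:
    """Gene-gene Pearson correlation matrix.

    ``sample_subset`` restricts to samples of one class label (0 or 1).
    Zero-variance genes produce NaN rows/columns (flagged, never silently
    zero); the diagonal is exactly 1 for well-defined genes.
    """
    if x.missing_mask.any():
        raise ValueError("expression matrix has missing values; impute first")
    values = x.values
    if sample_subset is not None:
        if x.labels is None:
            raise ValueError("sample_subset requires labels")
        values = values[:, x.labels == sample_subset]
    if values.shape[1] < 3:
        raise ValueError(
            f"need at least 3 samples for correlation, got {values.shape[1]}"
        )
    sd = values.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.corrcoef(values)
    R = np.clip(R, -1.0, 1.0)
    flat = sd == 0
    R[flat, :] = np.nan
    R[:, flat] = np.nan
    np.fill_diagonal(R, np.where(flat, np.nan, 1.0))
    return R


@dataclass
class GeneNetwork:
    """Undirected gene graph; edges carry the correlation that created them.

    Edges are stored once (networkx undirected semantics); ``tau`` and
    ``mode`` record the thresholding rule.  Differential networks
    additionally tag each edge with the state it came from.
    """

    graph: nx.Graph
    tau: float
    mode: str

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    def edge_set(self) -> set[tuple[str, str]]:
        return {tuple(sorted((a, b))) for a, b in self.graph.edges}

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def to_edgelist_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("gene_a\tgene_b\tr\tstate\n")
            for a, b in sorted(self.edge_set()):
                d = self.graph.edges[a, b]
                state = d.get("state", "")
                fh.write(f"{a}\t{b}\t{d['weight']!r}\t{state}\n")

    def to_graphml(self, path) -> None:
        nx.write_graphml(self.graph, path)


def threshold_network(
    R: np.ndarray,
    gene_ids: list[str],
    tau: float = 0.8,
    mode: str = "absolute",
) -> GeneNetwork:
    """Link gene pairs whose correlation is strictly bigger than tau.

    ``mode='absolute'`` uses |r| > tau (sign-agnostic coexpression,
    the default); ``mode='signed'`` uses r > tau.  Undefined (NaN)
    correlations never produce an edge.
    """
    R = np.asarray(R, dtype=float)
    if R.shape[0] != R.shape[1]:
        raise ValueError("correlation matrix must be square")
    if R.shape[0] != len(gene_ids):
        raise ValueError("gene_ids length must match matrix size")
    if not 0 <= tau <= 1:
        raise ValueError(f"tau must be in [0, 1], got {tau}")
    if mode not in ("absolute", "signed"):
        raise ValueError(f"mode must be 'absolute' or 'signed', got {mode!r}")
    if not np.allclose(R, R.T, equal_nan=True):
        raise ValueError("correlation matrix must be symmetric")

    g = nx.Graph()
    g.add_nodes_from(gene_ids)
    n = len(gene_ids)
    for i in range(n):
        for j in range(i + 1, n):
            r = R[i, j]
            if np.isnan(r):
                continue
            stat = abs(r) if mode == "absolute" else r
            if stat > tau:
                a, b = sorted((gene_ids[i], gene_ids[j]))
                g.add_edge(a, b, weight=float(r))
    return GeneNetwork(graph=g, tau=tau, mode=mode)


def differential_network(
    net_a: GeneNetwork,
    net_b: GeneNetwork,
    state_a: str = "normal",
    state_b: str = "tumor",
) -> GeneNetwork:
    """Edges coexpressed in exactly one state (symmetric difference).

    Each differential edge is annotated with the state whose network
    contained it.  Node sets must agree.
    """
    nodes_a = set(net_a.graph.nodes)
    nodes_b = set(net_b.graph.nodes)
    if nodes_a != nodes_b:
        only_a = sorted(nodes_a - nodes_b)
        only_b = sorted(nodes_b - nodes_a)
        raise ValueError(
            f"node sets differ: only in first={only_a}, only in second={only_b}"
        )
    edges_a = net_a.edge_set()
    edges_b = net_b.edge_set()
    g = nx.Graph()
    g.add_nodes_from(nodes_a)
    for a, b in sorted(edges_a - edges_b):
        g.add_edge(a, b, weight=net_a.graph.edges[a, b]["weight"], state=state_a)
    for a, b in sorted(edges_b - edges_a):
        g.add_edge(a, b, weight=net_b.graph.edges[a, b]["weight"], state=state_b)
    return GeneNetwork(graph=g, tau=net_a.tau, mode=net_a.mode)
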