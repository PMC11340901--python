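"""Haplotype collapsing and minimum-spanning networks for maternal markers.

Mitochondrial (or W-linked) haplotypes are collapsed over the retained
variant sites, and nodes are connected in a minimum-spanning network (MSN):
the union of every minimum spanning tree, i.e. all edges that join distinct
components of the graph formed by strictly shorter edges.  Edge weights are
Hamming distances in mutational steps.  An optional distance cutoff can
split the network into components, approximating a statistical-parsimony
connection limit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .genotype_io import GenotypeIOError, GenotypeTable


@dataclass
class HaplotypeNode:
    node_id: int
    haplotype: np.ndarray  # allele indices over variant sites, -1 missing
    samples: list
    metadata: pd.DataFrame | None = None

    @property
    def multiplicity(self) -> int:
        return len(self.samples)


@dataclass
class HaplotypeNetwork:
    nodes: list
    edges: pd.DataFrame  # node_a, node_b, weight
    graph: nx.Graph

    @property
    def components(self) -> list:
        return [sorted(c) for c in nx.connected_components(self.graph)]

    def to_tsvs(self, node_path, edge_path) -> None:
        rows = [
            {
                "node": n.node_id,
                "multiplicity": n.multiplicity,
                "samples": ",".join(map(str, n.samples)),
            }
            for n in self.nodes
        ]
        pd.DataFrame(rows).to_csv(node_path, sep="\t", index=False)
        self.edges.to_csv(edge_path, sep="\t", index=False)

    def to_graphml(self, path) -> None:
        nx.write_graphml(self.graph, str(path))


def collapse_haplotypes(
    table: GenotypeTable,
    samples: list[str],
    max_missing: float = 0.05,
    sample_sheet: pd.DataFrame | None = None,
) -> list[HaplotypeNode]:
    """Merge samples with identical haploid calls at all retained variant
    sites; samples missing more than ``max_missing`` of the sites are
    excluded."""
    idx = table.sample_index(samples)
    variant = np.flatnonzero(table.is_biallelic_snp())
    g = table.gt[variant][:, idx, 0]  # haploid: first slot
    keep_samples = []
    haps = []
    for j, s in enumerate(samples):
        h = g[:, j]
        if len(variant) and np.mean(h < 0) > max_missing:
            continue
        keep_samples.append(s)
        haps.append(h)
    nodes: list[HaplotypeNode] = []
    for s, h in zip(keep_samples, haps):
        for n in nodes:
            if np.array_equal(n.haplotype, h):
                n.samples.append(s)
                break
        else:
            nodes.append(HaplotypeNode(len(nodes), h.copy(), [s]))
    for n in nodes:
        if sample_sheet is not None:
            n.metadata = sample_sheet[sample_sheet["sample_id"].isin(n.samples)]
    if not nodes:
        raise GenotypeIOError("no samples left after the missingness filter")
    return nodes


def hamming_distance(a: np.ndarray, b: np.ndarray) -> int:
    """Mutational steps between two haplotypes; sites missing in either are
    ignored and the count is rescaled to the full number of sites (rounded)."""
    ok = (a >= 0) & (b >= 0)
    n = len(a)
    compared = int(ok.sum())
    if n == 0:
        return 0
    if compared == 0:
        return n  # maximally conservative
    d = int((a[ok] != b[ok]).sum())
    return int(round(d * n / compared))


def minimum_spanning_network(dist: np.ndarray, max_distance: float | None = None):
    """Edges of the minimum-spanning network for a symmetric distance matrix.

    An edge (i, j) belongs to the MSN iff i and j lie in different connected
    components of the graph containing all strictly shorter edges — this is
    exactly the union of all minimum spanning trees.
    """
    k = dist.shape[0]
    pairs = [(dist[i, j], i, j) for i in range(k) for j in range(i + 1, k)]
    if max_distance is not None:
        pairs = [p for p in pairs if p[0] <= max_distance]
    pairs.sort()
    parent = list(range(k))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    edges = []
    i = 0
    while i < len(pairs):
        w = pairs[i][0]
        tie_class = []
        while i < len(pairs) and pairs[i][0] == w:
            tie_class.append(pairs[i])
            i += 1
        accepted = [
            (a, b) for _, a, b in tie_class if find(a) != find(b)
        ]  # against components from strictly shorter edges only
        for a, b in accepted:
            edges.append((a, b, w))
        for a, b in accepted:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[ra] = rb
    return edges


def build_network(
    nodes: list[HaplotypeNode], max_distance: float | None = None
) -> HaplotypeNetwork:
    """Mutation-weighted minimum-spanning network over haplotype nodes."""
    k = len(nodes)
    dist = np.zeros((k, k), dtype=float)
    for i in range(k):
        for j in range(i + 1, k):
            dist[i, j] = dist[j, i] = hamming_distance(
                nodes[i].haplotype, nodes[j].haplotype
            )
    edges = minimum_spanning_network(dist, max_distance)
    g = nx.Graph()
    for n in nodes:
        g.add_node(
            n.node_id,
            multiplicity=n.multiplicity,
            samples=",".join(map(str, n.samples)),
        )
    for a, b, w in edges:
        g.add_edge(a, b, weight=float(w))
    df = pd.DataFrame(edges, columns=["node_a", "node_b", "weight"])
    return HaplotypeNetwork(nodes=nodes, edges=df, graph=g)
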