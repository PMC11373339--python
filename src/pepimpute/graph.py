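"""Peptide-only graph built from protein-peptide membership.

Peptides are nodes; two peptides are connected if they share at least one
parent protein.  Each protein therefore contributes a clique over its
peptides, and proteins linked by shared (non-unique) peptides merge into a
single connected component.  Self-edges are not stored: the attention
layer of the model adds self-connections internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datamodel import PeptideDataset

__all__ = ["PeptideGraph", "build_peptide_graph", "connected_components", "graph_stats"]


@dataclass
class PeptideGraph:
    node_ids: list
    edges: set  # unordered pairs (i, j), i < j, row indices

    def __post_init__(self):
        n = len(self.node_ids)
        canon = set()
        for i, j in self.edges:
            if i == j:
                raise ValueError("self-edges are not stored")
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"edge ({i},{j}) out of range")
            canon.add((min(i, j), max(i, j)))
        self.edges = canon

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def neighbors(self, i: int) -> set:
        return {b if a == i else a for a, b in self.edges if i in (a, b)}

    def adjacency_lists(self) -> list:
        adj = [[] for _ in range(self.n_nodes)]
        for a, b in self.edges:
            adj[a].append(b)
            adj[b].append(a)
        return adj

    def directed_edge_arrays(self, include_self_loops: bool = True):
        """(src, dst) index arrays with both directions per edge, sorted by
        destination; used to drive the attention layer."""
        src, dst = [], []
        for a, b in self.edges:
            src += [a, b]
            dst += [b, a]
        if include_self_loops:
            src += list(range(self.n_nodes))
            dst += list(range(self.n_nodes))
        src = np.asarray(src, dtype=np.intp)
        dst = np.asarray(dst, dtype=np.intp)
        order = np.lexsort((src, dst))
        return src[order], dst[order]

    def write_edge_list(self, path):
        with open(path, "w") as fh:
            fh.write("peptide_a\tpeptide_b\n")
            for a, b in sorted(self.edges):
                fh.write(f"{self.node_ids[a]}\t{self.node_ids[b]}\n")


def build_peptide_graph(ds: PeptideDataset, max_edges_per_protein: int | None = None, seed: int = 0) -> PeptideGraph:
    """Full-clique construction: every protein's peptide set is fully
    connected; edges are deduplicated across proteins.

    ``max_edges_per_protein`` optionally subsamples each protein's clique
    edges uniformly at random (seeded) as a memory escape hatch for
    proteins with very many peptides; off by default.
    """
    members: dict = {}
    for i, groups in enumerate(ds.protein_groups):
        for acc in groups:
            members.setdefault(acc, []).append(i)
    rng = np.random.default_rng(seed)
    edges: set = set()
    for acc in sorted(members):
        peps = members[acc]
        clique = [(peps[a], peps[b]) for a in range(len(peps)) for b in range(a + 1, len(peps))]
        if max_edges_per_protein is not None and len(clique) > max_edges_per_protein:
            keep = rng.choice(len(clique), size=max_edges_per_protein, replace=False)
            clique = [clique[k] for k in keep]
        for i, j in clique:
            edges.add((min(i, j), max(i, j)))
    return PeptideGraph(list(ds.peptide_ids), edges)


def connected_components(g: PeptideGraph) -> list:
    """Partition of node ids into connected components (BFS)."""
    adj = g.adjacency_lists()
    seen = np.zeros(g.n_nodes, dtype=bool)
    comps = []
    for start in range(g.n_nodes):
        if seen[start]:
            continue
        stack = [start]
        seen[start] = True
        comp = []
        while stack:
            u = stack.pop()
            comp.append(u)
            for v in adj[u]:
                if not seen[v]:
                    seen[v] = True
                    stack.append(v)
        comps.append({g.node_ids[u] for u in comp})
    return comps


def graph_stats(g: PeptideGraph) -> dict:
    """Descriptive summary: node/edge counts, component-size histogram, and
    the largest single-protein clique contribution (max component degree)."""
    comps = connected_components(g)
    sizes = sorted(len(c) for c in comps)
    hist: dict = {}
    for s in sizes:
        hist[s] = hist.get(s, 0) + 1
    degrees = np.zeros(g.n_nodes, dtype=int)
    for a, b in g.edges:
        degrees[a] += 1
        degrees[b] += 1
    return {
        "n_nodes": g.n_nodes,
        "n_edges": g.n_edges,
        "n_components": len(comps),
        "component_size_histogram": hist,
        "max_component_size": sizes[-1] if sizes else 0,
        "max_degree": int(degrees.max()) if g.n_nodes else 0,
    }
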