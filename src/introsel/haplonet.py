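"""Haplotype collapsing and median-joining genealogy networks.

Phased chromosomes (modern, population-tagged, plus the ALTAI and
DENISOVA archaic rows) over a set of biallelic SNPs are collapsed into
distinct haplotypes, then connected into a median-joining network:
inferred intermediate haplotypes (coordinate-wise majority medians of
node triplets, the L1/Hamming Steiner points of binary sequences) are
added whenever they reduce the total connection cost, and unobserved
nodes that no longer reduce cost are pruned. With epsilon = 0 the
result is the sparsest network; tie-breaking is lexicographic on
canonical node labels so output is deterministic.

Sites are binary (0 = ancestral, 1 = derived) with uniform weights;
rows containing missing calls are excluded (and counted), never
imputed.
"""

from __future__ import annotations

import itertools
import json
from collections.abc import Sequence
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .types import GeneModel  # noqa: F401  (shared coordinate conventions)


@dataclass
class Haplotype:
    """One distinct haplotype sequence with its carrier chromosomes."""

    sequence: tuple[int, ...]
    carriers: tuple[str, ...] = ()
    is_median: bool = False

    def __post_init__(self) -> None:
        if any(s not in (0, 1) for s in self.sequence):
            raise ValueError("haplotype states must be 0/1")
        if not self.is_median and not self.carriers:
            raise ValueError("observed haplotypes must have carriers")
        if self.is_median and self.carriers:
            raise ValueError("median vectors carry no chromosomes")

    @property
    def count(self) -> int:
        return len(self.carriers)

    @property
    def label(self) -> str:
        return "".join(map(str, self.sequence))


@dataclass
class HapNetwork:
    """Nodes plus Hamming-weighted edges of the genealogy network."""

    nodes: list[Haplotype]
    edges: list[tuple[str, str, int]]  # (label, label, hamming distance)
    excluded_rows: list[str] = field(default_factory=list)

    @property
    def total_cost(self) -> int:
        return sum(w for _, _, w in self.edges)

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        for h in self.nodes:
            g.add_node(h.label, count=h.count, carriers=h.carriers, is_median=h.is_median)
        for u, v, w in self.edges:
            g.add_edge(u, v, weight=w)
        return g


def hamming(a: Sequence[int], b: Sequence[int]) -> int:
    if len(a) != len(b):
        raise ValueError("sequence length mismatch")
    return int(sum(x != y for x, y in zip(a, b)))


def collapse_haplotypes(
    matrix: np.ndarray | Sequence[Sequence[int]],
    labels: Sequence[str],
) -> tuple[list[Haplotype], list[str]]:
    """Merge identical chromosome rows into haplotypes.

    Entries must be 0, 1, or negative/NaN for missing; rows with any
    missing site are excluded and their labels returned for reporting.
    """
    arr = np.asarray(matrix, dtype=float)
    if arr.ndim != 2:
        raise ValueError("phased matrix must be 2-dimensional")
    if arr.shape[0] != len(labels):
        raise ValueError("row labels must align with the matrix")
    groups: dict[tuple[int, ...], list[str]] = {}
    excluded: list[str] = []
    for row, label in zip(arr, labels):
        if np.any(np.isnan(row)) or np.any(row < 0):
            excluded.append(label)
            continue
        if not np.all(np.isin(row, (0.0, 1.0))):
            raise ValueError(f"row {label} contains non-binary states")
        groups.setdefault(tuple(int(x) for x in row), []).append(label)
    haplotypes = [
        Haplotype(sequence=seq, carriers=tuple(carriers))
        for seq, carriers in sorted(groups.items())
    ]
    return haplotypes, excluded


def _majority_median(a: tuple[int, ...], b: tuple[int, ...], c: tuple[int, ...]) -> tuple[int, ...]:
    """Coordinate-wise majority of three binary sequences."""
    return tuple(1 if (x + y + z) >= 2 else 0 for x, y, z in zip(a, b, c))


def _mst_cost(sequences: list[tuple[int, ...]]) -> int:
    if len(sequences) <= 1:
        return 0
    g = nx.Graph()
    for i, j in itertools.combinations(range(len(sequences)), 2):
        g.add_edge(i, j, weight=hamming(sequences[i], sequences[j]))
    return int(
        sum(d["weight"] for _, _, d in nx.minimum_spanning_edges(g, algorithm="kruskal"))
    )


def _canonical_mst_edges(sequences: list[tuple[int, ...]]) -> list[tuple[int, int, int]]:
    """Kruskal MST with deterministic lexicographic tie-breaks on
    (weight, endpoint sequences)."""
    order = sorted(
        (
            (hamming(sequences[i], sequences[j]),) + tuple(sorted((sequences[i], sequences[j]))) + (i, j)
            for i, j in itertools.combinations(range(len(sequences)), 2)
        )
    )
    parent = list(range(len(sequences)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    edges = []
    for item in order:
        w, i, j = item[0], item[-2], item[-1]
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
            edges.append((i, j, w))
    return edges


def build_mj_network(haplotypes: Sequence[Haplotype], epsilon: int = 0) -> HapNetwork:
    """Median-joining network over observed haplotypes.

    Iteratively adds the majority median of the node triplet that most
    reduces the minimum-spanning cost (with epsilon = 0 only strictly
    cost-reducing medians are retained; a positive epsilon also accepts
    medians within ``epsilon`` of the current cost, yielding denser
    candidate sets). Unobserved nodes whose removal does not increase
    the cost are pruned. Edges form a deterministic minimum spanning
    tree with lexicographic tie-breaks.
    """
    haplotypes = list(haplotypes)
    if not haplotypes:
        raise ValueError("at least one haplotype is required")
    lengths = {len(h.sequence) for h in haplotypes}
    if len(lengths) != 1:
        raise ValueError("haplotype sequences must share one length")
    observed = {h.sequence: h for h in haplotypes}
    if len(observed) != len(haplotypes):
        raise ValueError("duplicate haplotype sequences in input")

    nodes: list[tuple[int, ...]] = sorted(observed)
    cost = _mst_cost(nodes)
    while True:
        node_set = set(nodes)
        best: tuple[int, tuple[int, ...]] | None = None
        for tri in itertools.combinations(nodes, 3):
            med = _majority_median(*tri)
            if med in node_set:
                continue
            new_cost = _mst_cost(nodes + [med])
            # epsilon = 0 keeps only strictly cost-reducing medians;
            # epsilon > 0 also tolerates medians within epsilon of the
            # current cost (denser candidate network)
            if new_cost < cost or (epsilon > 0 and new_cost <= cost + epsilon):
                candidate = (new_cost, med)
                if best is None or candidate < best:
                    best = candidate
        if best is None:
            break
        cost = best[0]
        nodes = sorted(nodes + [best[1]])

    # prune unobserved nodes that no longer reduce cost
    changed = True
    while changed:
        changed = False
        for seq in sorted(nodes):
            if seq in observed:
                continue
            without = [s for s in nodes if s != seq]
            if _mst_cost(without) <= cost:
                nodes = without
                cost = _mst_cost(nodes)
                changed = True
                break

    node_objs = [
        observed.get(seq, Haplotype(sequence=seq, is_median=True)) for seq in nodes
    ]
    idx_edges = _canonical_mst_edges(nodes)
    labels = [h.label for h in node_objs]
    edges = sorted((min(labels[i], labels[j]), max(labels[i], labels[j]), w) for i, j, w in idx_edges)
    return HapNetwork(nodes=node_objs, edges=edges)


# ---------------------------------------------------------------------------
# export / import


def export_network(network: HapNetwork, path: str | Path, format: str = "json") -> Path:
    """Lossless export of nodes, edges and carrier annotations.

    ``json`` writes one file; ``tsv`` writes an edge list plus a node
    attribute table (``<stem>.nodes.tsv``).
    """
    path = Path(path)
    if format == "json":
        payload = {
            "nodes": [
                {
                    "label": h.label,
                    "sequence": list(h.sequence),
                    "carriers": list(h.carriers),
                    "count": h.count,
                    "is_median": h.is_median,
                }
                for h in network.nodes
            ],
            "edges": [[u, v, w] for u, v, w in network.edges],
        }
        path.write_text(json.dumps(payload, indent=2, sort_keys=True))
    elif format == "tsv":
        with path.open("w") as fh:
            fh.write("node_a\tnode_b\thamming\n")
            for u, v, w in network.edges:
                fh.write(f"{u}\t{v}\t{w}\n")
        nodes_path = path.with_suffix(".nodes.tsv")
        with nodes_path.open("w") as fh:
            fh.write("label\tcount\tis_median\tcarriers\n")
            for h in network.nodes:
                fh.write(f"{h.label}\t{h.count}\t{int(h.is_median)}\t{','.join(h.carriers)}\n")
    else:
        raise ValueError(f"unknown export format {format!r}")
    return path


def import_network(path: str | Path) -> HapNetwork:
    """Round-trip reader for the JSON export."""
    payload = json.loads(Path(path).read_text())
    nodes = [
        Haplotype(
            sequence=tuple(n["sequence"]),
            carriers=tuple(n["carriers"]),
            is_median=n["is_median"],
        )
        for n in payload["nodes"]
    ]
    edges = [(u, v, int(w)) for u, v, w in payload["edges"]]
    return HapNetwork(nodes=nodes, edges=edges)
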