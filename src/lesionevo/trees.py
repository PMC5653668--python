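"""Rooted clone trees for multi-lesion tumor phylogenies.

A clone tree is rooted at a germline node representing normal epithelium.
Every other node is a subclone created by acquiring one mutation cluster;
the edge into a node carries that cluster (and any loss-of-heterozygosity
feature groups placed with it).  Tumor samples label the node whose genotype
they match: all upstream alterations present, all downstream absent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Hashable, Iterable

import dendropy
import networkx as nx

GERMLINE = "germline"


@dataclass
class CloneTree:
    """Rooted subclone hierarchy.

    Parameters
    ----------
    parent
        Maps each cluster id to its parent node: either :data:`GERMLINE` or
        another cluster id.  The edge parent -> cluster carries that cluster.
    sample_labels
        Maps node (cluster id or GERMLINE) to sample names attached there.
    loh_groups
        Maps cluster id to LOH feature-group ids acquired on the same edge.
    """

    parent: dict[Hashable, Hashable]
    sample_labels: dict[Hashable, list[str]] = field(default_factory=dict)
    loh_groups: dict[Hashable, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        g = self.graph()
        if not nx.is_arborescence(g):
            raise ValueError("parent map does not describe a rooted tree")
        roots = [n for n in g if g.in_degree(n) == 0]
        if roots != [GERMLINE]:
            raise ValueError(f"tree must be rooted at {GERMLINE!r}, found {roots}")

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_node(GERMLINE)
        for child, par in self.parent.items():
            g.add_edge(par, child)
        return g

    @property
    def clusters(self) -> list[Hashable]:
        return sorted(self.parent, key=str)

    @property
    def samples(self) -> list[str]:
        return sorted(s for ss in self.sample_labels.values() for s in ss)

    def children(self, node: Hashable) -> list[Hashable]:
        return sorted((c for c, p in self.parent.items() if p == node), key=str)

    def path_from_root(self, node: Hashable) -> list[Hashable]:
        """Clusters acquired on the path germline -> node, inclusive."""
        path: list[Hashable] = []
        while node != GERMLINE:
            path.append(node)
            node = self.parent[node]
        return path[::-1]

    def subtree_nodes(self, node: Hashable) -> set[Hashable]:
        out = {node}
        stack = [node]
        while stack:
            for c in self.children(stack.pop()):
                out.add(c)
                stack.append(c)
        return out

    def subtree_samples(self, node: Hashable) -> set[str]:
        return {
            s for n in self.subtree_nodes(node) for s in self.sample_labels.get(n, [])
        }

    def cluster_presence(self, samples: Iterable[str] | None = None) -> dict:
        """Truth presence pattern per cluster: samples at or below its node."""
        samples = list(samples) if samples is not None else self.samples
        return {
            c: tuple(s in self.subtree_samples(c) for s in samples)
            for c in self.parent
        }

    def ancestor_pairs(self) -> set[tuple[Hashable, Hashable]]:
        """All (ancestor cluster, descendant cluster) pairs, both non-germline."""
        pairs = set()
        for c in self.parent:
            for anc in self.path_from_root(c)[:-1]:
                pairs.add((anc, c))
        return pairs

    # -- serialization -----------------------------------------------------

    def to_newick(self) -> str:
        """Newick string; edge labels carry cluster and feature-group ids."""
        taxa = dendropy.TaxonNamespace()
        dtree = dendropy.Tree(taxon_namespace=taxa)

        def label(node: Hashable) -> str:
            if node == GERMLINE:
                base = GERMLINE
            else:
                feats = self.loh_groups.get(node, [])
                base = f"cluster_{node}" + ("|" + "|".join(map(str, feats)) if feats else "")
            samples = self.sample_labels.get(node, [])
            return base + ("@" + "+".join(samples) if samples else "")

        dnodes = {GERMLINE: dtree.seed_node}
        dtree.seed_node.label = label(GERMLINE)
        for c in nx.topological_sort(self.graph()):
            if c == GERMLINE:
                continue
            node = dnodes[self.parent[c]].new_child()
            node.label = label(c)
            dnodes[c] = node
        return dtree.as_string(
            schema="newick",
            suppress_rooting=True,
            suppress_leaf_node_labels=False,
        ).strip()

    def to_json(self) -> str:
        return json.dumps(
            {
                "parent": {str(c): str(p) for c, p in self.parent.items()},
                "sample_labels": {
                    str(n): list(ss) for n, ss in self.sample_labels.items()
                },
                "loh_groups": {
                    str(n): list(map(str, gg)) for n, gg in self.loh_groups.items()
                },
            },
            indent=2,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "CloneTree":
        d = json.loads(text)
        return cls(
            parent=dict(d["parent"].items()),
            sample_labels={n: list(ss) for n, ss in d.get("sample_labels", {}).items()},
            loh_groups={n: list(gg) for n, gg in d.get("loh_groups", {}).items()},
        )


def compare_trees(a: CloneTree, b: CloneTree) -> dict:
    """Concordance of the ancestor--descendant relations of two clone trees.

    Both trees must be built over the same sample set.  Shared pairs are
    ancestor->descendant cluster pairs present in both; conflicting pairs are
    reversed between the trees; concordance is |shared| / |union of pairs|
    (1.0 for identical trees, and defined as 1.0 when neither tree has pairs).
    """
    if set(a.samples) != set(b.samples):
        raise ValueError("trees are labeled with different sample sets")
    pa, pb = a.ancestor_pairs(), b.ancestor_pairs()
    shared = pa & pb
    conflicting = {(x, y) for (x, y) in pa if (y, x) in pb}
    union = pa | pb
    return {
        "shared_pairs": sorted(shared, key=str),
        "conflicting_pairs": sorted(conflicting, key=str),
        "concordance": len(shared) / len(union) if union else 1.0,
    }
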