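"""Subclonal hierarchy inference from cluster cellularities.

The lineage precedence rule states that an ancestor alteration's cellularity
must be at least its descendant's in every tumor sample (within tolerance).
All rooted trees over the mutation clusters — with the ubiquitous cluster
fixed on the edge out of the germline root — are scored by how well their
ancestor/descendant pairs satisfy precedence, minus violations of per-sample
cellularity sum consistency (children cannot jointly exceed their parent).
At the cluster counts seen per patient (<= ~7) the search is exhaustive; a
seeded hill-climb covers larger instances and doubles as an independent
search route for cross-checking.

An exhaustive maximum-parsimony oracle over sample-labeled binary trees
(Fitch counting on presence characters, germline fixed all-absent) provides
the cross-method comparison; the two analyses agree when every clade of the
parsimony tree is nested in or disjoint from every subtree sample set of the
cellularity-based tree.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Hashable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .cellularity import MutationCluster
from .trees import GERMLINE, CloneTree, compare_trees  # noqa: F401 (re-export)

MAX_EXHAUSTIVE_CLUSTERS = 8
MAX_EXHAUSTIVE_SAMPLES = 8


@dataclass(frozen=True)
class PrecedenceMatrix:
    """Pairwise ancestor->descendant feasibility from cellularity profiles."""

    allowed: pd.DataFrame  # bool, index=ancestor cluster, columns=descendant
    tolerance: float


def precedence_matrix(
    clusters: Sequence[MutationCluster], tolerance: float = 0.05
) -> PrecedenceMatrix:
    """Allowed[a, d] iff cellularity of a >= that of d - tolerance in every sample."""
    ids = [cl.cluster_id for cl in clusters]
    mles = {cl.cluster_id: cl.mle_vector() for cl in clusters}
    allowed = pd.DataFrame(False, index=ids, columns=ids)
    for a, d in itertools.permutations(ids, 2):
        allowed.loc[a, d] = bool(np.all(mles[a] >= mles[d] - tolerance))
    return PrecedenceMatrix(allowed=allowed, tolerance=tolerance)


# ---------------------------------------------------------------------------
# tree scoring


def _ancestor_pairs(parent: dict) -> list[tuple]:
    pairs = []
    for c in parent:
        p = parent[c]
        while p != GERMLINE:
            pairs.append((p, c))
            p = parent[p]
    return pairs


def _score_tree(
    parent: dict,
    matrix: PrecedenceMatrix,
    mles: dict[Hashable, np.ndarray],
    tolerance: float,
) -> float:
    """Satisfied precedence constraints plus cellularity-sum consistency.

    Each ancestor/descendant pair contributes 1 minus the summed per-sample
    precedence violation beyond tolerance; each node loses the amount by
    which its children's cellularity sum exceeds its own (per sample, beyond
    tolerance).  Grading violations by magnitude keeps noise-scale
    cellularity fluctuations from outweighing tree structure, while hard
    violations (e.g. a private cluster forced above a shared one) dominate.
    """
    score = 0.0
    for a, d in _ancestor_pairs(parent):
        violation = np.sum(np.maximum(0.0, mles[d] - mles[a] - tolerance))
        score += 1.0 - float(violation)
    children: dict = {}
    for c, p in parent.items():
        children.setdefault(p, []).append(c)
    n_samples = len(next(iter(mles.values()))) if mles else 0
    for node, kids in children.items():
        parent_mle = np.ones(n_samples) if node == GERMLINE else mles[node]
        kid_sum = np.sum([mles[k] for k in kids], axis=0)
        score -= float(np.sum(np.maximum(0.0, kid_sum - parent_mle - tolerance)))
    return score


def _enumerate_parent_maps(cluster_ids: list, ubiquitous) -> list[dict]:
    """All rooted trees with the ubiquitous cluster as the root's only child.

    The remaining clusters form a tree rooted at the ubiquitous cluster;
    labeled trees on k nodes are enumerated via Pruefer sequences.
    """
    k = len(cluster_ids)
    if k == 1:
        return [{ubiquitous: GERMLINE}]
    others = [c for c in cluster_ids if c != ubiquitous]
    nodes = [ubiquitous, *others]
    maps = []
    if k == 2:
        seqs: list[tuple] = [()]
    else:
        seqs = itertools.product(range(k), repeat=k - 2)
    for seq in seqs:
        tree = nx.from_prufer_sequence(list(seq))
        parent = {ubiquitous: GERMLINE}
        for u, v in nx.bfs_edges(tree, 0):  # node 0 = ubiquitous = root
            parent[nodes[v]] = nodes[u]
        maps.append(parent)
    return maps


def _attach_samples(parent: dict, clusters: Sequence[MutationCluster]) -> CloneTree:
    """Label each sample at the deepest cluster called present in it."""
    samples = clusters[0].samples if clusters else []
    present_in = {
        s: {cl.cluster_id for cl in clusters if cl.pattern[clusters[0].samples.index(s)]}
        for s in samples
    }

    def depth(c) -> int:
        d = 0
        while c != GERMLINE:
            c = parent[c]
            d += 1
        return d

    labels: dict = {}
    for s in samples:
        cands = present_in[s]
        node = max(cands, key=depth) if cands else GERMLINE
        labels.setdefault(node, []).append(s)
    return CloneTree(parent=dict(parent), sample_labels=labels)


def search_trees(
    matrix: PrecedenceMatrix,
    clusters: Sequence[MutationCluster],
    ubiquitous_cluster: str,
    tolerance: float | None = None,
    max_exhaustive: int = MAX_EXHAUSTIVE_CLUSTERS,
    seed: int = 0,
    n_restarts: int = 50,
) -> list[CloneTree]:
    """All co-optimal clone trees under the precedence-based fitness.

    Exhaustive for up to ``max_exhaustive`` clusters, otherwise seeded
    hill-climbing with restarts.  Within the co-optimal set, trees are
    ordered lexicographically by their parent maps for reproducibility.
    """
    ids = [cl.cluster_id for cl in clusters]
    if ubiquitous_cluster not in ids:
        raise ValueError(f"unknown ubiquitous cluster {ubiquitous_cluster!r}")
    ubiq = next(cl for cl in clusters if cl.cluster_id == ubiquitous_cluster)
    if not all(ubiq.pattern):
        raise ValueError(
            "ubiquitous cluster is absent from some samples; no tree can "
            "attach it to the root edge"
        )
    tol = matrix.tolerance if tolerance is None else tolerance
    mles = {cl.cluster_id: cl.mle_vector() for cl in clusters}

    if len(ids) <= max_exhaustive:
        candidates = _enumerate_parent_maps(ids, ubiquitous_cluster)
        scored = [
            (_score_tree(p, matrix, mles, tol), p) for p in candidates
        ]
        best = max(s for s, _ in scored)
        optimal = [p for s, p in scored if s == best]
    else:
        optimal = _hill_climb(ids, ubiquitous_cluster, matrix, mles, tol,
                              seed, n_restarts)
    optimal.sort(key=lambda p: sorted((str(c), str(p[c])) for c in p))
    return [_attach_samples(p, list(clusters)) for p in optimal]


def _hill_climb(ids, ubiquitous, matrix, mles, tol, seed, n_restarts):
    rng = np.random.default_rng(seed)
    others = [c for c in ids if c != ubiquitous]
    best_score, best_set, best_keys = -np.inf, [], set()
    for _ in range(n_restarts):
        parent = {ubiquitous: GERMLINE}
        order = list(rng.permutation(others))
        placed = [ubiquitous]
        for c in order:
            parent[c] = placed[int(rng.integers(len(placed)))]
            placed.append(c)
        score = _score_tree(parent, matrix, mles, tol)
        improved = True
        while improved:
            improved = False
            for c in others:
                descendants = _descendants(parent, c)
                for new_p in ids:
                    if new_p == c or new_p in descendants or parent[c] == new_p:
                        continue
                    trial = dict(parent)
                    trial[c] = new_p
                    s = _score_tree(trial, matrix, mles, tol)
                    if s > score:
                        parent, score = trial, s
                        improved = True
        key = tuple(sorted((str(c), str(parent[c])) for c in parent))
        if score > best_score:
            best_score, best_set, best_keys = score, [parent], {key}
        elif score == best_score and key not in best_keys:
            best_set.append(parent)
            best_keys.add(key)
    return best_set


def _descendants(parent: dict, node) -> set:
    out = set()
    changed = True
    while changed:
        changed = False
        for c, p in parent.items():
            if (p == node or p in out) and c not in out:
                out.add(c)
                changed = True
    return out


# ---------------------------------------------------------------------------
# post-hoc LOH feature placement


def place_loh_features(tree: CloneTree, groups) -> tuple[CloneTree, list]:
    """Attach LOH feature groups to tree edges by their presence patterns.

    Matched groups go to their bound cluster's edge.  An unmatched group is
    placed on the deepest edge whose subtree sample set equals the group's
    carrier samples; groups with no consistent edge are returned unplaced
    (homoplasy candidates).
    """
    loh_groups = {c: list(g) for c, g in tree.loh_groups.items()}
    unplaced = []
    for group in groups:
        carriers = {
            s for s, present in zip(group.samples, group.pattern) if present
        }
        target = None
        if group.matched_cluster is not None and group.matched_cluster in tree.parent:
            target = group.matched_cluster
        else:
            depth = {
                c: len(tree.path_from_root(c)) for c in tree.parent
            }
            matches = [
                c for c in tree.parent if tree.subtree_samples(c) == carriers
            ]
            if matches:
                target = max(matches, key=lambda c: depth[c])
        if target is None:
            unplaced.append(group)
        else:
            loh_groups.setdefault(target, []).append(group.group_id)
    placed = CloneTree(
        parent=dict(tree.parent),
        sample_labels={n: list(s) for n, s in tree.sample_labels.items()},
        loh_groups=loh_groups,
    )
    return placed, unplaced


# ---------------------------------------------------------------------------
# maximum-parsimony oracle over sample trees


@dataclass(frozen=True)
class ParsimonyTree:
    """A rooted binary sample tree with its parsimony score."""

    topology: tuple  # nested tuples of sample names
    score: int

    def clades(self) -> list[frozenset]:
        out = []

        def walk(node) -> frozenset:
            if isinstance(node, str):
                return frozenset([node])
            clade = frozenset().union(*(walk(c) for c in node))
            out.append(clade)
            return clade

        walk(self.topology)
        return out


def _rooted_topologies(leaves: list[str]):
    """All rooted binary leaf-labeled topologies, by stepwise leaf insertion."""
    if len(leaves) == 1:
        yield leaves[0]
        return

    def insert(node, leaf):
        # yield every topology obtained by attaching leaf on an edge of node
        yield (node, leaf)
        if not isinstance(node, str):
            left, right = node
            for sub in insert(left, leaf):
                yield (sub, right)
            for sub in insert(right, leaf):
                yield (left, sub)

    def build(current, remaining):
        if not remaining:
            yield current
            return
        leaf, rest = remaining[0], remaining[1:]
        for topo in insert(current, leaf):
            yield from build(topo, rest)

    yield from build(leaves[0], leaves[1:])


def _fitch_score(topology, states: dict[str, int]) -> int:
    """Minimum state changes with the root constrained to state 0."""
    changes = 0

    def walk(node) -> set:
        nonlocal changes
        if isinstance(node, str):
            return {states[node]}
        left, right = (walk(c) for c in node)
        inter = left & right
        if inter:
            return inter
        changes += 1
        return left | right

    root_set = walk(topology)
    if 0 not in root_set:
        changes += 1
    return changes


def parsimony_oracle(
    presence: pd.DataFrame, max_samples: int = MAX_EXHAUSTIVE_SAMPLES
) -> list[ParsimonyTree]:
    """Exhaustive maximum parsimony over rooted sample trees.

    ``presence`` is a characters x samples boolean matrix (rows may be
    mutations, clusters, or LOH features).  Trees are rooted binary with
    samples as leaves and a germline root constrained to the all-absent
    state; Fitch counting scores each binary character.  Returns every
    minimum-score tree.
    """
    samples = list(presence.columns)
    if len(samples) > max_samples:
        raise ValueError(
            f"{len(samples)} samples exceeds the exhaustive bound "
            f"{max_samples}; use the heuristic clone-tree search instead"
        )
    characters = [
        {s: int(bool(v)) for s, v in row.items()} for _, row in presence.iterrows()
    ]
    best: list[ParsimonyTree] = []
    best_score = np.inf
    for topo in _rooted_topologies(samples):
        score = sum(_fitch_score(topo, ch) for ch in characters)
        if score < best_score:
            best_score, best = score, [ParsimonyTree(topo, score)]
        elif score == best_score:
            best.append(ParsimonyTree(topo, score))
    return best


def clone_tree_compatible(tree: CloneTree, parsimony: ParsimonyTree) -> bool:
    """Hierarchy compatibility between the two analyses.

    True when every clade of the parsimony sample tree is nested within, or
    disjoint from, every subtree sample set of the clone tree (and vice
    versa, which follows by symmetry of the check).
    """
    clone_sets = [
        frozenset(tree.subtree_samples(c)) for c in tree.parent
    ]
    for clade in parsimony.clades():
        for cs in clone_sets:
            if clade & cs and not (clade <= cs or cs <= clade):
                return False
    return True
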