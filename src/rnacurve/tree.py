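"""UPGMA clustering, Newick serialization, and cluster-purity checks."""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np

from .similarity import DistanceMatrix


@dataclass(frozen=True)
class TreeNode:
    """Node of a rooted binary ultrametric tree.

    ``height`` is half the merge distance; leaves sit at height 0.
    """

    height: float
    label: Optional[str] = None
    children: tuple["TreeNode", ...] = ()

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> tuple[str, ...]:
        if self.is_leaf:
            return (self.label,)
        return tuple(l for c in self.children for l in c.leaves())


@dataclass(frozen=True)
class ClusterTree:
    root: TreeNode
    labels: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if not self.labels:
            object.__setattr__(self, "labels", tuple(sorted(self.root.leaves())))

    def nodes(self) -> list[TreeNode]:
        out, stack = [], [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return out

    def leaf_depths(self) -> dict[str, float]:
        """Root-to-leaf path lengths (equal for an ultrametric tree)."""
        depths: dict[str, float] = {}

        def walk(node: TreeNode, acc: float) -> None:
            if node.is_leaf:
                depths[node.label] = acc
                return
            for child in node.children:
                walk(child, acc + (node.height - child.height))

        walk(self.root, 0.0)
        return depths


def _min_leaf(node: TreeNode) -> str:
    return min(node.leaves())


def upgma(m: DistanceMatrix) -> ClusterTree:
    """Average-linkage (size-weighted) agglomerative clustering.

    The closest pair is merged at node height = distance / 2; ties are
    broken by the lexicographically smallest pair of cluster
    representatives (each cluster represented by its smallest leaf
    label), so the result is independent of input label order.
    """
    if len(m) < 2:
        raise ValueError("need at least 2 labels")
    # DistanceMatrix guarantees symmetry, zero diagonal, finite non-negative
    clusters: dict[int, TreeNode] = {
        i: TreeNode(height=0.0, label=lab) for i, lab in enumerate(m.labels)
    }
    sizes = {i: 1 for i in clusters}
    dist: dict[frozenset[int], float] = {}
    for i in range(len(m)):
        for j in range(i + 1, len(m)):
            dist[frozenset((i, j))] = float(m.values[i, j])

    next_id = len(m.labels)
    while len(clusters) > 1:
        best_key, best_d, best_reps = None, None, None
        for key, d in dist.items():
            a, b = sorted(key)
            reps = tuple(sorted((_min_leaf(clusters[a]), _min_leaf(clusters[b]))))
            if best_d is None or d < best_d or (d == best_d and reps < best_reps):
                best_key, best_d, best_reps = key, d, reps
        a, b = sorted(best_key)
        merged = TreeNode(height=best_d / 2.0, children=(clusters[a], clusters[b]))
        size_a, size_b = sizes[a], sizes[b]
        # size-weighted average linkage
        for other in clusters:
            if other in (a, b):
                continue
            da = dist.pop(frozenset((a, other)))
            db = dist.pop(frozenset((b, other)))
            dist[frozenset((next_id, other))] = (size_a * da + size_b * db) / (size_a + size_b)
        dist.pop(best_key)
        del clusters[a], clusters[b], sizes[a], sizes[b]
        clusters[next_id] = merged
        sizes[next_id] = size_a + size_b
        next_id += 1

    (root,) = clusters.values()
    return ClusterTree(root=root)


def _fmt_branch(length: float) -> str:
    return f"{length:.10g}"


def to_newick(t: ClusterTree) -> str:
    """Newick text with branch lengths; children ordered by smallest leaf."""

    def render(node: TreeNode, parent_height: Optional[float]) -> str:
        if node.is_leaf:
            body = node.label
        else:
            kids = sorted(node.children, key=_min_leaf)
            body = "(" + ",".join(render(c, node.height) for c in kids) + ")"
        if parent_height is None:
            return body
        return f"{body}:{_fmt_branch(parent_height - node.height)}"

    return render(t.root, None) + ";"


def _monophyletic(leafsets: list[frozenset[str]], family_leaves: frozenset[str], removed: frozenset[str]) -> bool:
    kept = family_leaves - removed
    if not kept:
        return False
    if len(kept) == 1:
        return True
    return any(ls - removed == kept for ls in leafsets)


def cluster_purity(t: ClusterTree, truth: Mapping[str, str]) -> tuple[int, list[str]]:
    """Count monophyletic families and find the minimal misplaced set.

    ``truth`` maps every leaf label to its family.  Returns the number
    of families whose leaves form a monophyletic subtree in ``t`` as-is,
    plus the minimal list of leaves whose removal restores monophyly of
    all families (exhaustive up to 3 removals, greedy beyond).
    """
    leaves = set(t.root.leaves())
    unknown = leaves - set(truth)
    if unknown:
        raise KeyError(f"unknown leaf labels: {sorted(unknown)}")
    families: dict[str, set[str]] = {}
    for leaf in leaves:
        families.setdefault(truth[leaf], set()).add(leaf)
    leafsets = [frozenset(n.leaves()) for n in t.nodes() if not n.is_leaf]

    fam_sets = {fam: frozenset(members) for fam, members in families.items()}

    def failing(removed: frozenset[str]) -> list[str]:
        return [fam for fam, fl in fam_sets.items() if not _monophyletic(leafsets, fl, removed)]

    clean = len(fam_sets) - len(failing(frozenset()))
    bad_families = failing(frozenset())
    if not bad_families:
        return clean, []

    candidates = sorted(l for fam in bad_families for l in fam_sets[fam])
    for size in range(1, min(3, len(candidates)) + 1):
        for combo in itertools.combinations(candidates, size):
            if not failing(frozenset(combo)):
                return clean, list(combo)

    # greedy fallback for larger defects
    removed: set[str] = set()
    while failing(frozenset(removed)):
        remaining = [c for c in candidates if c not in removed]
        if not remaining:
            break
        best = min(remaining, key=lambda c: (len(failing(frozenset(removed | {c}))), c))
        removed.add(best)
    return clean, sorted(removed)


def ultrametric_violation(t: ClusterTree) -> float:
    """Max spread of root-to-leaf path lengths (0 for a perfect tree)."""
    depths = list(t.leaf_depths().values())
    return float(np.max(depths) - np.min(depths))
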