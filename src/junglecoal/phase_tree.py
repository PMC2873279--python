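"""Random-phase concatenation, neighbor-joining and consensus support.

Diploid phase across loci is unknown, so an individual is represented by a
random choice of one haplotype copy per locus, concatenated.  NJ trees are
built from per-draw p-distance matrices; clade support is the proportion of
draws in which the clade appears in the tree rooted at the outgroup, and the
average-difference tree is NJ on the p-distances averaged over draws (p_a).
"""
from __future__ import annotations

import itertools
import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .locus_io import LocusCatalog
from .popgen_stats import encode

logger = logging.getLogger(__name__)


class TreeNode:
    """Rooted view of an (un)rooted tree; children carry branch lengths."""

    __slots__ = ("name", "children", "support")

    def __init__(self, name: str | None = None):
        self.name = name
        self.children: list[tuple["TreeNode", float]] = []
        self.support: float | None = None

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf():
            return [self]
        out = []
        for c, _ in self.children:
            out.extend(c.leaves())
        return out

    def leaf_names(self) -> frozenset[str]:
        return frozenset(l.name for l in self.leaves())

    def walk(self):
        yield self
        for c, _ in self.children:
            yield from c.walk()

    def newick(self, include_support: bool = True) -> str:
        def fmt(node: TreeNode, blen: float | None) -> str:
            if node.is_leaf():
                s = node.name
            else:
                inner = ",".join(fmt(c, b) for c, b in node.children)
                label = ""
                if include_support and node.support is not None:
                    label = f"{node.support:g}"
                s = f"({inner}){label}"
            if blen is not None:
                s += f":{blen:.6g}"
            return s

        return fmt(self, None) + ";"


def nj_tree(dist: np.ndarray, labels: list[str]) -> TreeNode:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    Joins the lowest-index pair among Q-minimizers; branch lengths are clamped
    at zero.  On a tree-additive matrix the generating topology and branch
    lengths are recovered exactly.  Returns an unrooted tree represented with
    a trifurcating root.
    """
    dist = np.asarray(dist, dtype=float)
    r = len(labels)
    if dist.shape != (r, r):
        raise ValueError("distance matrix shape does not match labels")
    if r < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")
    if not np.allclose(dist, dist.T) or (dist < 0).any():
        raise ValueError("distance matrix must be symmetric and non-negative")
    nodes = [TreeNode(lbl) for lbl in labels]
    D = dist.copy()
    active = list(range(r))
    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        R = sub.sum(axis=1)
        Q = (m - 2) * sub - R[:, None] - R[None, :]
        np.fill_diagonal(Q, np.inf)
        # lowest-index pair among minimizers (row-major argmin is exactly that)
        i, j = divmod(int(np.argmin(Q)), m)
        if i > j:
            i, j = j, i
        d_ij = sub[i, j]
        b_i = 0.5 * d_ij + (R[i] - R[j]) / (2 * (m - 2))
        b_j = d_ij - b_i
        b_i, b_j = max(b_i, 0.0), max(b_j, 0.0)
        parent = TreeNode()
        parent.children = [(nodes[active[i]], b_i), (nodes[active[j]], b_j)]
        new_d = 0.5 * (sub[i, :] + sub[j, :] - d_ij)
        ai, aj = active[i], active[j]
        D = np.pad(D, ((0, 1), (0, 1)))
        for k_pos, k in enumerate(active):
            D[-1, k] = D[k, -1] = max(new_d[k_pos], 0.0)
        D[-1, -1] = 0.0
        nodes.append(parent)
        active = [k for k in active if k not in (ai, aj)] + [len(nodes) - 1]
    # final three-point resolution
    i, j, k = active
    d_ij, d_ik, d_jk = D[i, j], D[i, k], D[j, k]
    root = TreeNode()
    root.children = [
        (nodes[i], max(0.5 * (d_ij + d_ik - d_jk), 0.0)),
        (nodes[j], max(0.5 * (d_ij + d_jk - d_ik), 0.0)),
        (nodes[k], max(0.5 * (d_ik + d_jk - d_ij), 0.0)),
    ]
    return root


def _edges(tree: TreeNode):
    """(parent, child_position, child, length) for every edge."""
    for node in tree.walk():
        for pos, (child, blen) in enumerate(node.children):
            yield node, pos, child, blen


def root_at_outgroup(tree: TreeNode, outgroups: set[str]) -> TreeNode | None:
    """Re-root at the edge separating all outgroups from all ingroups.

    Returns None when no such edge exists (the outgroups are not monophyletic
    in the unrooted tree).
    """
    all_leaves = tree.leaf_names()
    outgroups = frozenset(outgroups) & all_leaves
    if not outgroups:
        return None
    ingroups = all_leaves - outgroups
    if not ingroups:
        return None
    for parent, pos, child, blen in _edges(tree):
        below = child.leaf_names()
        if below == outgroups or below == ingroups:
            new_root = TreeNode()
            detached = _reroot_above(tree, parent, pos)
            new_root.children = [(child, blen / 2), (detached, blen / 2)]
            return new_root
    return None


def _reroot_above(tree: TreeNode, parent: TreeNode, pos: int) -> TreeNode:
    """Detach ``parent.children[pos]`` and re-hang the rest of the tree from
    ``parent``; returns the re-hung structure."""
    path = _path_to(tree, parent)
    parent.children = [c for k, c in enumerate(parent.children) if k != pos]
    # reverse edges along the path root -> parent
    for node, via in reversed(list(zip(path[:-1], path[1:]))):
        for k, (child, blen) in enumerate(node.children):
            if child is via:
                node.children.pop(k)
                via.children.append((node, blen))
                break
    # drop a now-degree-1 old root by splicing (root had >= 2 children)
    return _splice_unary(parent)


def _path_to(tree: TreeNode, target: TreeNode) -> list[TreeNode]:
    def rec(node):
        if node is target:
            return [node]
        for c, _ in node.children:
            p = rec(c)
            if p is not None:
                return [node] + p
        return None

    path = rec(tree)
    if path is None:
        raise ValueError("target not in tree")
    return path


def _splice_unary(node: TreeNode) -> TreeNode:
    for k, (child, blen) in enumerate(node.children):
        if not child.is_leaf() and len(child.children) == 1:
            gchild, gblen = child.children[0]
            node.children[k] = (gchild, blen + gblen)
    for k, (child, _) in enumerate(node.children):
        node.children[k] = (_splice_unary(child), node.children[k][1])
    if len(node.children) == 1 and node.name is None:
        child, blen = node.children[0]
        return child
    return node


def rooted_clades(rooted: TreeNode) -> set[frozenset[str]]:
    """Leaf sets of all internal nodes of a rooted tree (excluding the root
    and trivial single-leaf clades)."""
    out = set()
    for node in rooted.walk():
        if node is rooted or node.is_leaf():
            continue
        out.add(node.leaf_names())
    return out


def is_monophyletic(rooted: TreeNode, clade: set[str]) -> bool:
    target = frozenset(clade)
    if len(target) == 1:
        return target <= rooted.leaf_names()
    return target in rooted_clades(rooted) or target == rooted.leaf_names()


def unrooted_bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial splits of an unrooted tree, stored as the child-side set."""
    all_leaves = tree.leaf_names()
    out = set()
    for _, _, child, _ in _edges(tree):
        below = child.leaf_names()
        if 1 < len(below) < len(all_leaves) - 1:
            out.add(min(below, all_leaves - below, key=sorted))
    return out


@dataclass
class ConcatenationDraw:
    """One random phase draw: chosen copy index per (individual, locus)."""

    choices: dict[str, dict[str, int]]
    draw_index: int


@dataclass
class SupportResult:
    supports: dict[str, float]
    p_a: pd.DataFrame
    reps: int
    clade_counts: Counter
    unrooted_failures: int = 0


class _EncodedCatalog:
    """Per-(individual, locus) encoded sequences for fast draw assembly."""

    def __init__(self, catalog: LocusCatalog, individuals: list[str] | None = None):
        self.individuals = individuals or [
            s.individual_id
            for s in catalog.samples
            if any(locus.copies_of(s.individual_id) for locus in catalog.loci)
        ]
        self.catalog = catalog
        self.locus_ids = [l.locus_id for l in catalog.loci]
        self.offsets = np.cumsum([0] + [l.length for l in catalog.loci])
        self.total_len = int(self.offsets[-1])
        self.copies: dict[tuple[str, str], list[np.ndarray]] = {}
        for locus in catalog.loci:
            for ind, copy, seq in locus.sequences:
                key = (ind, locus.locus_id)
                lst = self.copies.setdefault(key, [None, None])
                lst[copy] = encode(seq)

    def draw(self, rng: np.random.Generator, draw_index: int = 0) -> ConcatenationDraw:
        choices: dict[str, dict[str, int]] = {}
        for ind in self.individuals:
            ploidy = self.catalog.sample(ind).ploidy
            per_locus = {}
            for lid in self.locus_ids:
                lst = self.copies.get((ind, lid))
                if lst is None:
                    continue
                present = [c for c in (0, 1) if lst[c] is not None]
                if ploidy == 1 or len(present) == 1:
                    per_locus[lid] = present[0]
                else:
                    per_locus[lid] = int(rng.integers(0, 2))
            choices[ind] = per_locus
        return ConcatenationDraw(choices, draw_index)

    def matrix(self, draw: ConcatenationDraw) -> np.ndarray:
        """(n_individuals, total_len) uint8 matrix; 255 marks gap/N/missing."""
        M = np.full((len(self.individuals), self.total_len), 255, dtype=np.uint8)
        for i, ind in enumerate(self.individuals):
            for j, lid in enumerate(self.locus_ids):
                copy = draw.choices[ind].get(lid)
                if copy is None:
                    continue
                lo, hi = self.offsets[j], self.offsets[j + 1]
                M[i, lo:hi] = self.copies[(ind, lid)][copy]
        return M


def p_distance_matrix(M: np.ndarray) -> np.ndarray:
    """Pairwise p-distances over sites valid in both rows (pairwise deletion)."""
    n = M.shape[0]
    D = np.zeros((n, n))
    valid = M != 255
    for i in range(n):
        vi, mi = valid[i], M[i]
        for j in range(i + 1, n):
            both = vi & valid[j]
            sites = int(both.sum())
            if sites == 0:
                raise ValueError(f"no comparable sites between rows {i} and {j}")
            D[i, j] = D[j, i] = int(((mi != M[j]) & both).sum()) / sites
    return D


def random_concatenate(
    catalog: LocusCatalog, rng: np.random.Generator
) -> ConcatenationDraw:
    """One uniform random choice of haplotype copy per (individual, locus)."""
    return _EncodedCatalog(catalog).draw(rng)


def resample_support(
    catalog: LocusCatalog,
    reps: int = 1000,
    focal_clades: dict[str, set[str]] | None = None,
    outgroup_labels: set[str] | tuple[str, ...] = (),
    rng: np.random.Generator | None = None,
    rooted: bool = True,
) -> SupportResult:
    """Phase-resampling clade support and the p_a average-distance matrix.

    Per draw: concatenate randomly chosen copies, build the p-distance matrix,
    NJ, root at the outgroup and record every clade of the rooted tree.
    Support of a clade is its occurrence proportion over draws.  With
    ``rooted=False`` unrooted bipartitions are scored instead.
    """
    if rng is None:
        rng = np.random.default_rng()
    outgroup_labels = set(outgroup_labels)
    if rooted and not outgroup_labels:
        raise ValueError("rooted support scoring requires outgroup labels")
    enc = _EncodedCatalog(catalog)
    labels = enc.individuals
    if rooted and not outgroup_labels & set(labels):
        raise ValueError("no outgroup individual present in the catalog")
    focal_clades = focal_clades or {}
    counts: Counter = Counter()
    p_sum = np.zeros((len(labels), len(labels)))
    failures = 0
    for rep in range(reps):
        draw = enc.draw(rng, rep)
        D = p_distance_matrix(enc.matrix(draw))
        p_sum += D
        tree = nj_tree(D, labels)
        if rooted:
            rtree = root_at_outgroup(tree, outgroup_labels)
            if rtree is None:
                failures += 1
                logger.warning("draw %d: outgroup not separable; scored as absent", rep)
                continue
            counts.update(rooted_clades(rtree))
        else:
            counts.update(unrooted_bipartitions(tree))
    supports = {}
    for name, clade in focal_clades.items():
        key = frozenset(clade)
        if not rooted:
            all_l = frozenset(labels)
            key = min(key, all_l - key, key=sorted)
        supports[name] = counts.get(key, 0) / reps
    p_a = pd.DataFrame(p_sum / reps, index=labels, columns=labels)
    return SupportResult(supports, p_a, reps, counts, failures)


def average_difference_tree(
    p_a: pd.DataFrame,
    support: SupportResult | None = None,
    outgroup_labels: set[str] | tuple[str, ...] = (),
) -> TreeNode:
    """NJ tree on the averaged p_a distances, annotated with draw supports.

    When outgroups are given the tree is returned rooted at the outgroup edge
    and each internal node carries the proportion of draws containing its
    clade (from ``support.clade_counts``).
    """
    labels = list(p_a.index)
    tree = nj_tree(p_a.values, labels)
    if outgroup_labels:
        rtree = root_at_outgroup(tree, set(outgroup_labels))
        if rtree is not None:
            tree = rtree
    if support is not None:
        for node in tree.walk():
            if node.is_leaf() or node is tree:
                continue
            node.support = support.clade_counts.get(node.leaf_names(), 0) / support.reps
    return tree
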