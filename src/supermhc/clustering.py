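"""WPGMA clustering of the RDI matrix and supertype labeling.

Supertypes are groups of molecules with overlapping binding
repertoires.  They are obtained by agglomerative clustering of the
RDI matrix under WPGMA linkage (weighted pair-group method using
arithmetic averages): when clusters P' and P'' merge into P, the
distance from P to any other cluster Q is the plain average
``(d(P', Q) + d(P'', Q)) / 2``, regardless of cluster sizes.  Cutting
the resulting tree at a fixed height (default 0.7, which excludes
negative and weak rank correlations) yields disjoint clusters;
clusters with at least ``min_size`` members become named "main"
supertypes, everything else falls into a single "diverse" pool.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .rdi import DissimilarityMatrix

#: Default tree-cut height on the RDI scale.
DEFAULT_CUT = 0.7
DIVERSE_LABEL = "diverse"


@dataclass
class ClusterTree:
    """Binary merge tree over molecules.

    ``merges[k] = (left, right, height)`` creates internal node
    ``n + k``; ids below ``n`` are leaves into ``leaves``.  WPGMA
    heights are nondecreasing along any leaf-to-root path.
    """

    leaves: list[str]
    merges: list[tuple[int, int, float]]

    def n_leaves(self) -> int:
        return len(self.leaves)

    def members(self, node: int) -> list[str]:
        """Leaf names under a node id, in leaf order."""
        n = self.n_leaves()
        out: list[str] = []
        stack = [node]
        while stack:
            v = stack.pop()
            if v < n:
                out.append(self.leaves[v])
            else:
                left, right, _ = self.merges[v - n]
                stack.extend((right, left))
        return out

    def to_linkage(self) -> np.ndarray:
        """SciPy-style linkage array (for dendrogram plotting)."""
        n = self.n_leaves()
        sizes = {i: 1 for i in range(n)}
        z = np.zeros((len(self.merges), 4))
        for k, (left, right, h) in enumerate(self.merges):
            size = sizes[left] + sizes[right]
            sizes[n + k] = size
            z[k] = (left, right, h, size)
        return z

    def to_newick(self) -> str:
        """Ultrametric Newick string; leaf-to-node distance is height/2."""
        n = self.n_leaves()
        heights = {i: 0.0 for i in range(n)}
        for k, (_, _, h) in enumerate(self.merges):
            heights[n + k] = h

        def emit(node: int, parent_h: float) -> str:
            blen = (parent_h - heights[node]) / 2.0
            if node < n:
                return f"{self.leaves[node]}:{blen:.6g}"
            left, right, h = self.merges[node - n]
            return (f"({emit(left, h)},{emit(right, h)}):{blen:.6g}")

        root = n + len(self.merges) - 1
        left, right, h = self.merges[-1]
        return f"({emit(left, h)},{emit(right, h)});" if self.merges else \
            f"({self.leaves[0]});"


@dataclass
class SupertypeAssignment:
    """molecule -> cluster label partition with named main clusters."""

    labels: dict[str, str]
    main_clusters: list[str]
    diverse: list[str] = field(default_factory=list)

    def members(self, label: str) -> list[str]:
        return [m for m, lab in self.labels.items() if lab == label]

    def to_dict(self) -> dict:
        return {"labels": self.labels, "main_clusters": self.main_clusters,
                "diverse": self.diverse}

    @classmethod
    def from_dict(cls, d: dict) -> "SupertypeAssignment":
        return cls(labels=dict(d["labels"]),
                   main_clusters=list(d["main_clusters"]),
                   diverse=list(d["diverse"]))


def wpgma_tree(matrix: DissimilarityMatrix) -> ClusterTree:
    """Agglomerate under WPGMA linkage.

    Requires a complete (no-NA) symmetric matrix.  Ties in the
    minimum-distance pair are broken by the lexicographic order of the
    concatenated sorted member names, making the tree deterministic
    and invariant to input ordering.
    """
    names = matrix.molecules
    d0 = np.asarray(matrix.values, dtype=float)
    n = len(names)
    if n < 2:
        raise ValueError("clustering needs at least two molecules")
    if not np.all(np.isfinite(d0)):
        raise ValueError(
            "the dissimilarity matrix has missing (NA) entries; raise "
            "min_overlap, or drop the molecules with sparse overlap, "
            "before clustering"
        )
    if not np.allclose(d0, d0.T):
        raise ValueError("the dissimilarity matrix must be symmetric")

    # Active clusters: id -> (sort key = sorted member names, distances).
    dist: dict[frozenset, float] = {}
    active: dict[int, tuple[str, ...]] = {}
    for i in range(n):
        active[i] = (names[i],)
        for j in range(i + 1, n):
            dist[frozenset((i, j))] = d0[i, j]

    merges: list[tuple[int, int, float]] = []
    next_id = n
    while len(active) > 1:
        best = None
        for pair, dv in dist.items():
            i, j = sorted(pair)
            tie_key = tuple(sorted(active[i] + active[j]))
            cand = (dv, tie_key, i, j)
            if best is None or cand < best:
                best = cand
        dv, _, i, j = best
        merged_members = tuple(sorted(active[i] + active[j]))
        for k in active:
            if k in (i, j):
                continue
            dist[frozenset((next_id, k))] = (
                dist.pop(frozenset((i, k))) + dist.pop(frozenset((j, k)))
            ) / 2.0
        dist.pop(frozenset((i, j)))
        del active[i], active[j]
        active[next_id] = merged_members
        merges.append((i, j, dv))
        next_id += 1
    return ClusterTree(leaves=list(names), merges=merges)


def cut_tree(tree: ClusterTree, height: float = DEFAULT_CUT
             ) -> list[list[str]]:
    """Partition the leaves at a cut height.

    Clusters are the maximal subtrees all of whose internal merge
    heights are strictly below ``height``; a merge exactly at the
    threshold does not join.  Returns member-name lists sorted for
    determinism (clusters by size descending, then by first name).
    """
    if height < 0:
        raise ValueError("cut height must be nonnegative")
    n = tree.n_leaves()
    parent = list(range(n + len(tree.merges)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    # WPGMA heights are nondecreasing in merge order, so a single pass
    # of unions below the cut produces the maximal subtrees.
    for k, (left, right, h) in enumerate(tree.merges):
        if h < height:
            node = n + k
            parent[find(left)] = node
            parent[find(right)] = node

    groups: dict[int, list[str]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(tree.leaves[i])
    clusters = [sorted(g) for g in groups.values()]
    clusters.sort(key=lambda g: (-len(g), g[0]))
    return clusters


def label_supertypes(partition: list[list[str]],
                     isotype_of: dict[str, str],
                     min_size: int = 2) -> SupertypeAssignment:
    """Name main supertypes by majority isotype; pool the rest as diverse.

    Clusters of size >= ``min_size`` become main clusters named
    ``main<ISOTYPE>`` (e.g. ``mainDR``); when one isotype yields
    several main clusters they get ordinal suffixes ordered by cluster
    size descending, ties by first member name (``mainDQ1``,
    ``mainDQ2``).  All remaining molecules form the single diverse
    cluster.
    """
    mains = [sorted(c) for c in partition if len(c) >= min_size]
    mains.sort(key=lambda g: (-len(g), g[0]))
    by_isotype: dict[str, list[list[str]]] = {}
    for c in mains:
        isos = sorted(isotype_of[m] for m in c)
        majority = max(set(isos), key=lambda x: (isos.count(x), x))
        by_isotype.setdefault(majority, []).append(c)

    labels: dict[str, str] = {}
    main_labels: list[str] = []
    for isotype in sorted(by_isotype):
        clusters = by_isotype[isotype]
        for k, c in enumerate(clusters, start=1):
            label = f"main{isotype}" if len(clusters) == 1 \
                else f"main{isotype}{k}"
            main_labels.append(label)
            for m in c:
                labels[m] = label
    diverse = sorted(
        m for c in partition for m in c if m not in labels
    )
    for m in diverse:
        labels[m] = DIVERSE_LABEL
    return SupertypeAssignment(labels=labels, main_clusters=main_labels,
                               diverse=diverse)


def write_assignment(assignment: SupertypeAssignment,
                     path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("molecule\tcluster_label\tis_main\n")
        for mol in sorted(assignment.labels):
            lab = assignment.labels[mol]
            fh.write(f"{mol}\t{lab}\t{int(lab in assignment.main_clusters)}\n")


def read_assignment(path: str | Path) -> SupertypeAssignment:
    labels: dict[str, str] = {}
    mains: set[str] = set()
    with Path(path).open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            row = dict(zip(header, line.rstrip("\n").split("\t")))
            labels[row["molecule"]] = row["cluster_label"]
            if row["is_main"] == "1":
                mains.add(row["cluster_label"])
    diverse = sorted(m for m, lab in labels.items() if lab not in mains)
    return SupertypeAssignment(labels=labels, main_clusters=sorted(mains),
                               diverse=diverse)
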