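"""Distance phylogeny of matched isolates: p-distance NJ with bootstrap.

The chain mirrors the classic distance workflow for 16S isolate sets:
columns containing gaps or missing data are removed (complete deletion),
pairwise p-distances (proportion of differing sites) are computed,
a neighbor-joining tree is built, and branch support is estimated by
bootstrap resampling of alignment columns with a majority-rule consensus
in which bipartitions reproduced in fewer than half the replicates are
collapsed.

Trees are lightweight node structures with Newick export; bipartitions
are normalized to the side not containing the lexicographically smallest
taxon, which makes them behave as clades of the tree rooted at that
reference taxon (two bipartitions are compatible iff nested or disjoint).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

GAP_CHARS = frozenset("-?")


@dataclass
class MultipleAlignment:
    """An aligned character matrix over DNA plus gap '-' and missing '?'."""

    taxa: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.rows):
            raise ValueError("taxa and rows differ in length")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxon labels")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError("alignment rows differ in length")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def matrix(self) -> np.ndarray:
        """Rows as a uint8 character matrix."""
        return np.frombuffer("".join(self.rows).encode(), dtype=np.uint8
                             ).reshape(self.n_taxa, self.n_columns)

    @classmethod
    def from_fasta(cls, path: str | Path) -> "MultipleAlignment":
        taxa, rows = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            taxa.append(rec.id)
            rows.append(str(rec.seq).upper())
        return cls(taxa=taxa, rows=rows)

    def take_columns(self, cols: Sequence[int]) -> "MultipleAlignment":
        mat = self.matrix()[:, list(cols)]
        return MultipleAlignment(
            taxa=list(self.taxa),
            rows=[row.tobytes().decode() for row in mat])


def complete_deletion(msa: MultipleAlignment) -> MultipleAlignment:
    """Drop every column where any row holds '-' or '?'.

    Raises if no column survives (distances would be undefined).
    """
    mat = msa.matrix()
    bad = np.zeros(msa.n_columns, dtype=bool)
    for ch in GAP_CHARS:
        bad |= (mat == ord(ch)).any(axis=0)
    keep = np.flatnonzero(~bad)
    if keep.size == 0:
        raise ValueError("complete deletion removed every column")
    return msa.take_columns(keep)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with ordered taxa."""

    taxa: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.taxa), len(self.taxa)):
            raise ValueError("matrix shape does not match taxa")
        if not np.isfinite(v).all():
            raise ValueError("non-finite distances")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix not symmetric")
        self.values = v


def p_distance(msa: MultipleAlignment) -> DistanceMatrix:
    """Proportion of differing sites per pair; characters compare by
    equality, so ambiguity codes count as differences unless identical."""
    if msa.n_columns < 1:
        raise ValueError("alignment has no columns")
    mat = msa.matrix()
    n = msa.n_taxa
    d = np.zeros((n, n))
    for i in range(n):
        diff = (mat[i] != mat[i + 1:]).mean(axis=1) if i + 1 < n else []
        d[i, i + 1:] = diff
        d[i + 1:, i] = diff
    return DistanceMatrix(taxa=list(msa.taxa), values=d)


@dataclass
class TreeNode:
    """Tree node; ``length`` is the branch to the parent."""

    name: str | None = None
    length: float = 0.0
    support: int | None = None
    children: list["TreeNode"] = field(default_factory=list)

    def leaves(self) -> list[str]:
        if not self.children:
            return [self.name]  # type: ignore[list-item]
        out: list[str] = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def newick(self, with_support: bool = True) -> str:
        return self._newick(with_support) + ";"

    def _newick(self, with_support: bool) -> str:
        if not self.children:
            return f"{self.name}:{self.length:.6f}"
        inner = ",".join(c._newick(with_support) for c in self.children)
        label = ""
        if with_support and self.support is not None:
            label = str(self.support)
        return f"({inner}){label}:{self.length:.6f}"


@dataclass
class PhyloTree:
    """Unrooted tree held at an arbitrary internal node."""

    root: TreeNode
    taxa: list[str]

    def newick(self, with_support: bool = True) -> str:
        return self.root.newick(with_support)

    def bipartitions(self) -> dict[frozenset, float]:
        """Nontrivial bipartitions, each as the side excluding the
        lexicographically smallest taxon, mapped to branch length."""
        ref = min(self.taxa)
        all_taxa = frozenset(self.taxa)
        out: dict[frozenset, float] = {}

        def walk(node: TreeNode) -> frozenset:
            if not node.children:
                return frozenset([node.name])
            below = frozenset().union(*(walk(c) for c in node.children))
            side = all_taxa - below if ref in below else below
            if 2 <= len(side) <= len(all_taxa) - 2:
                # parallel edges (root splits) can repeat: keep max length
                out[side] = max(out.get(side, 0.0), node.length)
            return below

        for child in self.root.children:
            walk(child)
        return out

    def leaf_branch_lengths(self) -> dict[str, float]:
        out: dict[str, float] = {}

        def walk(node: TreeNode) -> None:
            if not node.children:
                out[node.name] = node.length  # type: ignore[index]
            for c in node.children:
                walk(c)

        walk(self.root)
        return out


@dataclass
class SupportedTree:
    """Consensus tree with per-bipartition bootstrap support (percent)."""

    tree: PhyloTree
    supports: dict[frozenset, int]
    n_replicates: int

    def newick(self) -> str:
        return self.tree.newick(with_support=True)

    def bipartition_table(self) -> pd.DataFrame:
        rows = [{"bipartition": "|".join(sorted(side)),
                 "support_percent": sup}
                for side, sup in sorted(self.supports.items(),
                                        key=lambda kv: (-kv[1], sorted(kv[0])))]
        return pd.DataFrame(rows, columns=["bipartition", "support_percent"])


def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    At each step the pair minimizing Q = (n-2) d_ij - r_i - r_j is joined;
    exact Q ties resolve to the lexicographically smallest pair of cluster
    labels (a cluster is labeled by its smallest leaf).  Negative branch
    lengths are clamped to zero.
    """
    n = len(dm.taxa)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    d = dm.values.astype(float).copy()
    nodes = [TreeNode(name=t) for t in dm.taxa]
    keys = list(dm.taxa)  # smallest leaf label per active cluster

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        # floating-point Q is not exactly symmetric; use the upper triangle
        q[np.tril_indices(m)] = np.inf
        qmin = q.min()
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                if q[i, j] == qmin:
                    pair = tuple(sorted((keys[i], keys[j])))
                    if best is None or pair < best[0]:
                        best = (pair, i, j)
        _, i, j = best  # type: ignore[misc]
        dij = d[i, j]
        li = dij / 2.0 + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        nodes[i].length = max(li, 0.0)
        nodes[j].length = max(lj, 0.0)
        parent = TreeNode(children=[nodes[i], nodes[j]])
        dnew = (d[i] + d[j] - dij) / 2.0
        keep = [k for k in range(m) if k not in (i, j)]
        d = np.vstack([d[keep][:, keep],
                       dnew[keep][None, :]])
        d = np.hstack([d, np.append(dnew[keep], 0.0)[:, None]])
        nodes = [nodes[k] for k in keep] + [parent]
        keys = [keys[k] for k in keep] + [min(keys[i], keys[j])]

    a, b, c = nodes
    dab, dac, dbc = d[0, 1], d[0, 2], d[1, 2]
    a.length = max((dab + dac - dbc) / 2.0, 0.0)
    b.length = max((dab + dbc - dac) / 2.0, 0.0)
    c.length = max((dac + dbc - dab) / 2.0, 0.0)
    center = TreeNode(children=[a, b, c])
    return PhyloTree(root=center, taxa=list(dm.taxa))


def _compatible(a: frozenset, b: frozenset) -> bool:
    # both sides exclude the reference taxon -> clade logic applies
    return a <= b or b <= a or not (a & b)


def majority_rule_consensus(bip_counts: Counter, taxa: Sequence[str],
                            n_reps: int, threshold: float = 0.5,
                            bip_lengths: dict | None = None,
                            leaf_lengths: dict | None = None,
                            ) -> SupportedTree:
    """Greedy majority-rule consensus from tallied bipartitions.

    Bipartitions with replicate frequency >= ``threshold`` are added in
    order of decreasing frequency (ties broken on the sorted taxon sets)
    when compatible with those already accepted; everything below the
    threshold is collapsed.
    """
    taxa = sorted(taxa)
    ref = taxa[0]
    leaf_lengths = leaf_lengths or {}
    accepted: dict[frozenset, int] = {}
    ordered = sorted(bip_counts.items(),
                     key=lambda kv: (-kv[1], sorted(kv[0])))
    for side, count in ordered:
        if count / n_reps < threshold:
            continue
        if all(_compatible(side, other) for other in accepted):
            accepted[side] = int(round(100.0 * count / n_reps))

    # assemble the clade hierarchy rooted at the reference taxon
    clades = sorted(accepted, key=len, reverse=True)
    root = TreeNode(children=[
        TreeNode(name=ref, length=leaf_lengths.get(ref, 0.0) / max(n_reps, 1))])
    node_of: dict[frozenset, TreeNode] = {}

    def parent_of(side: frozenset) -> TreeNode:
        best = None
        for other in clades:
            if side < other and (best is None or len(other) < len(best)):
                best = other
        return node_of[best] if best is not None else root

    bip_lengths = bip_lengths or {}
    for side in clades:
        mean_len = (bip_lengths.get(side, 0.0) / bip_counts[side]
                    if bip_counts.get(side) else 0.0)
        node = TreeNode(support=accepted[side], length=mean_len)
        node_of[side] = node
    for side in clades:
        parent_of(side).children.append(node_of[side])
    for taxon in taxa[1:]:
        leaf = TreeNode(name=taxon,
                        length=leaf_lengths.get(taxon, 0.0) / max(n_reps, 1))
        best = None
        for other in clades:
            if taxon in other and (best is None or len(other) < len(best)):
                best = other
        (node_of[best] if best is not None else root).children.append(leaf)
    tree = PhyloTree(root=root, taxa=list(taxa))
    return SupportedTree(tree=tree, supports=dict(accepted),
                         n_replicates=n_reps)


def bootstrap_consensus(msa: MultipleAlignment, n_reps: int = 1000,
                        collapse_threshold: float = 0.50,
                        seed: int = 0, max_redraws: int = 100,
                        ) -> SupportedTree:
    """Column-bootstrap NJ trees and return their majority-rule consensus.

    Each replicate resamples alignment columns with replacement, applies
    complete deletion, computes p-distances and a NJ tree, and its
    bipartitions are tallied.  Replicates whose resampled columns are all
    removed by complete deletion are redrawn up to ``max_redraws`` times.
    """
    if msa.n_taxa < 4:
        raise ValueError("bootstrap consensus needs at least 4 taxa")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    counts: Counter = Counter()
    bip_lengths: dict[frozenset, float] = {}
    leaf_lengths: dict[str, float] = {t: 0.0 for t in msa.taxa}
    ncol = msa.n_columns
    for _ in range(n_reps):
        tree = None
        for _try in range(max_redraws):
            cols = rng.integers(0, ncol, size=ncol)
            try:
                rep = complete_deletion(msa.take_columns(cols))
            except ValueError:
                continue
            tree = neighbor_joining(p_distance(rep))
            break
        if tree is None:
            raise RuntimeError(
                "could not draw a replicate with surviving columns")
        for side, length in tree.bipartitions().items():
            counts[side] += 1
            bip_lengths[side] = bip_lengths.get(side, 0.0) + length
        for taxon, length in tree.leaf_branch_lengths().items():
            leaf_lengths[taxon] += length
    return majority_rule_consensus(counts, msa.taxa, n_reps,
                                   collapse_threshold,
                                   bip_lengths=bip_lengths,
                                   leaf_lengths=leaf_lengths)
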