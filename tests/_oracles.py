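"""Independent brute-force oracles shared by the test suite.

Everything here deliberately avoids the package's implementation paths:
segment enumeration instead of the scanning aligner, explicit path-length
computation on known trees instead of NJ, dense linear algebra instead of
the Woodbury-profiled REML solver.
"""

from __future__ import annotations

import collections

import numpy as np

_COMP = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def brute_force_align(query: str, subject: str, reward: int = 2,
                      penalty: int = -3):
    """Enumerate every contiguous diagonal segment on both strands.

    Returns ``(score, length, matches, strand, q_start, s_start)`` of the
    best segment under the tie-break order: score, length, matches,
    '+' strand first, subject start, query start; or ``None`` when no
    segment scores positively.
    """
    best = None
    best_key = None
    for strand, q in (("+", query), ("-", revcomp(query))):
        nq, ns = len(q), len(subject)
        for qs in range(nq):
            for ss in range(ns):
                score = matches = 0
                limit = min(nq - qs, ns - ss)
                for ln in range(1, limit + 1):
                    a, b = q[qs + ln - 1], subject[ss + ln - 1]
                    if a == b and a in "ACGT":
                        score += reward
                        matches += 1
                    else:
                        score += penalty
                    if score <= 0:
                        continue
                    key = (-score, -ln, -matches, strand != "+", ss, qs)
                    if best_key is None or key < best_key:
                        best_key = key
                        best = (score, ln, matches, strand, qs, ss)
    return best


def random_additive_tree(n_taxa: int, rng: np.random.Generator):
    """Random unrooted binary tree with positive branch lengths.

    Returns ``(taxa, D, bipartitions)`` where ``D`` is the exact additive
    path-length matrix and ``bipartitions`` the set of nontrivial splits,
    each given as the frozenset side not containing the smallest taxon.
    """
    taxa = [f"t{i:02d}" for i in range(n_taxa)]
    adj: dict[str, dict[str, float]] = collections.defaultdict(dict)
    active = list(taxa)
    nxt = 0
    while len(active) > 2:
        i, j = sorted(rng.choice(len(active), size=2, replace=False))
        a, b = active[j], active[i]
        new = f"internal{nxt}"
        nxt += 1
        for leaf, length in ((a, rng.uniform(0.05, 1.0)),
                             (b, rng.uniform(0.05, 1.0))):
            adj[leaf][new] = length
            adj[new][leaf] = length
        active = [x for x in active if x not in (a, b)] + [new]
    length = rng.uniform(0.05, 1.0)
    adj[active[0]][active[1]] = length
    adj[active[1]][active[0]] = length

    def distances_from(u: str) -> dict[str, float]:
        dist = {u: 0.0}
        stack = [u]
        while stack:
            x = stack.pop()
            for y, w in adj[x].items():
                if y not in dist:
                    dist[y] = dist[x] + w
                    stack.append(y)
        return dist

    D = np.zeros((n_taxa, n_taxa))
    for ii, u in enumerate(taxa):
        du = distances_from(u)
        for jj, v in enumerate(taxa):
            D[ii, jj] = du[v]
    D = (D + D.T) / 2.0

    ref = min(taxa)
    all_taxa = frozenset(taxa)
    splits = set()
    for u in adj:
        for v in adj[u]:
            if u < v:
                # component containing u once edge (u, v) is removed
                seen = {u}
                stack = [u]
                while stack:
                    x = stack.pop()
                    for y in adj[x]:
                        if (x, y) == (u, v):
                            continue
                        if y not in seen:
                            seen.add(y)
                            stack.append(y)
                side = frozenset(t for t in seen if t in all_taxa)
                side = all_taxa - side if ref in side else side
                if 2 <= len(side) <= n_taxa - 2:
                    splits.add(side)
    return taxa, D, splits


def tree_path_distances(tree) -> np.ndarray:
    """Leaf-to-leaf path lengths of a package ``PhyloTree``, in taxa order."""
    adj: dict[str, dict[str, float]] = collections.defaultdict(dict)
    counter = [0]

    def build(node) -> str:
        name = node.name or f"__internal{counter[0]}"
        counter[0] += 1
        for child in node.children:
            cname = build(child)
            adj[name][cname] = child.length
            adj[cname][name] = child.length
        return name

    build(tree.root)

    def distances_from(u: str) -> dict[str, float]:
        dist = {u: 0.0}
        stack = [u]
        while stack:
            x = stack.pop()
            for y, w in adj[x].items():
                if y not in dist:
                    dist[y] = dist[x] + w
                    stack.append(y)
        return dist

    n = len(tree.taxa)
    D = np.zeros((n, n))
    for ii, u in enumerate(tree.taxa):
        du = distances_from(u)
        for jj, v in enumerate(tree.taxa):
            D[ii, jj] = du[v]
    return D


def gls_lsmean(data, cell, sigma2_block, sigma2_e):
    """LS-mean of one genotype x isolate cell by dense GLS.

    Builds the full marginal covariance ``V`` explicitly and computes
    ``x' (X'V^-1X)^-1 X'V^-1 y`` with sum-to-zero contrasts — an
    independent route to the package's Woodbury-based solver.
    """
    g_levels = sorted(data["genotype"].unique())
    i_levels = sorted(data["isolate"].unique())
    b_levels = sorted(data["block"].unique())

    def code(levels, value):
        row = np.zeros(len(levels) - 1)
        if value == levels[-1]:
            row[:] = -1.0
        else:
            row[levels.index(value)] = 1.0
        return row

    def design_row(g, i):
        parts = [np.ones(1)]
        if len(g_levels) > 1:
            parts.append(code(g_levels, g))
        if len(i_levels) > 1:
            parts.append(code(i_levels, i))
        if len(g_levels) > 1 and len(i_levels) > 1:
            parts.append(np.outer(code(g_levels, g),
                                  code(i_levels, i)).ravel())
        return np.concatenate(parts)

    X = np.array([design_row(g, i)
                  for g, i in zip(data["genotype"], data["isolate"])])
    y = data["response"].to_numpy(float)
    Z = np.array([[1.0 if b == lb else 0.0 for lb in b_levels]
                  for b in data["block"]])
    V = sigma2_e * np.eye(len(y)) + sigma2_block * (Z @ Z.T)
    Vi = np.linalg.inv(V)
    A = X.T @ Vi @ X
    beta = np.linalg.solve(A, X.T @ Vi @ y)
    x = design_row(*cell)
    cov = np.linalg.inv(A)
    return float(x @ beta), float(np.sqrt(x @ cov @ x))
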