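"""Independent brute-force oracles used by the test suite.

Everything here recomputes quantities from first principles (BFS over the
genome operation graph, exhaustive enumeration of mappings / refinements /
matchings, quadratic alignment DP) without calling the implementation paths
it is used to check.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

# ---------------------------------------------------------------------------
# signed gene orders: state = frozenset of adjacencies over extremities


def genome_state(genome) -> frozenset:
    """Adjacency-set state of a Genome, derived directly from gene order."""
    adjs = set()
    for chrom in genome.chromosomes:
        seq = chrom.genes
        pairs = list(zip(seq, seq[1:]))
        if chrom.circular:
            pairs.append((seq[-1], seq[0]))
        for x, y in pairs:
            ex = (abs(x), 1 if x > 0 else 0)  # extremity by which x is left
            ey = (abs(y), 0 if y > 0 else 1)
            adjs.add(frozenset((ex, ey)))
    return frozenset(adjs)


def dcj_neighbors(state: frozenset, genes) -> set[frozenset]:
    """All genomes one DCJ operation away (own enumeration)."""
    bound = set(itertools.chain.from_iterable(state))
    telos = [
        (g, e) for g in sorted(genes) for e in (0, 1) if (g, e) not in bound
    ]
    adjs = sorted(state, key=sorted)
    out = set()
    for p, q in itertools.combinations(adjs, 2):
        (a, b), (c, d) = sorted(p), sorted(q)
        rest = state - {p, q}
        out.add(rest | {frozenset((a, c)), frozenset((b, d))})
        out.add(rest | {frozenset((a, d)), frozenset((b, c))})
    for p in adjs:
        a, b = sorted(p)
        rest = state - {p}
        out.add(rest)  # split into two telomeres
        for t in telos:
            out.add(rest | {frozenset((a, t))})
            out.add(rest | {frozenset((b, t))})
    for t, u in itertools.combinations(telos, 2):
        out.add(state | {frozenset((t, u))})
    out.discard(state)
    return out


def bfs_dcj_distance(a, b) -> int:
    """Bidirectional BFS shortest path in the DCJ operation graph."""
    genes = a.genes
    sa, sb = genome_state(a), genome_state(b)
    if sa == sb:
        return 0
    front_a, front_b = {sa: 0}, {sb: 0}
    layer_a, layer_b = [sa], [sb]
    while True:
        if len(layer_a) <= len(layer_b):
            layer, seen, other = layer_a, front_a, front_b
        else:
            layer, seen, other = layer_b, front_b, front_a
        nxt = []
        best = None
        for s in layer:
            for t in dcj_neighbors(s, genes):
                if t in other:
                    cand = seen[s] + 1 + other[t]
                    best = cand if best is None else min(best, cand)
                if t not in seen:
                    seen[t] = seen[s] + 1
                    nxt.append(t)
        if best is not None:
            return best
        layer[:] = nxt


def all_genome_states(genes) -> list[frozenset]:
    """Every genome on the gene set = every partial matching of extremities."""
    exts = [(g, e) for g in sorted(genes) for e in (0, 1)]

    def rec(remaining):
        if not remaining:
            yield frozenset()
            return
        first, rest = remaining[0], remaining[1:]
        for sub in rec(rest):  # first stays a telomere
            yield sub
        for i, other in enumerate(rest):
            pair = frozenset((first, other))
            for sub in rec(rest[:i] + rest[i + 1 :]):
                yield sub | {pair}

    return list(rec(exts))


def state_dcj_distance(s1: frozenset, s2: frozenset, genes) -> int:
    """DCJ distance between two adjacency-set states by direct component
    counting (used only to score exhaustive median enumeration)."""
    pa, pb = {}, {}
    for pm, s in ((pa, s1), (pb, s2)):
        for adj in s:
            x, y = tuple(adj)
            pm[x] = y
            pm[y] = x
    exts = [(g, e) for g in sorted(genes) for e in (0, 1)]
    visited = set()
    cycles = odd = 0
    for e0 in exts:
        if e0 in visited or (e0 in pa and e0 in pb):
            continue
        side = "B" if e0 not in pa else "A"
        cur, edges = e0, 0
        while True:
            visited.add(cur)
            edges += 1
            pm = pa if side == "A" else pb
            if cur in pm and pm[cur] not in visited:
                cur = pm[cur]
                side = "B" if side == "A" else "A"
            else:
                break
        odd += edges % 2
    for e0 in exts:
        if e0 in visited:
            continue
        cur, side = e0, "A"
        while cur not in visited:
            visited.add(cur)
            pm = pa if side == "A" else pb
            cur = pm[cur]
            side = "B" if side == "A" else "A"
        cycles += 1
    return len(exts) // 2 - cycles - odd // 2


def exhaustive_median_score(a, b, c) -> int:
    genes = a.genes
    states = [genome_state(g) for g in (a, b, c)]
    best = None
    for m in all_genome_states(genes):
        score = sum(state_dcj_distance(m, s, genes) for s in states)
        best = score if best is None else min(best, score)
    return best


# ---------------------------------------------------------------------------
# reconciliation: exhaustive minimum over ancestry-respecting mappings


def brute_min_duploss_cost(gene_tree, species_tree, species_of) -> int:
    """Minimum dup+loss cost over all ancestry-respecting mappings.

    Each internal gene node may map to any ancestor-or-equal of the LCA of
    its children's images (anything else violates ancestry), enumerated
    exhaustively; events and per-edge losses follow the standard rules for an
    arbitrary mapping: a node is a duplication unless it maps exactly to the
    LCA of its children's images and shares no image with a child; losses on
    an edge are the species steps skipped, minus one below a speciation.
    """
    sp_nodes = list(species_tree.preorder_node_iter())
    parent = {id(s): s.parent_node for s in sp_nodes}
    depth = {}
    for s in sp_nodes:
        depth[id(s)] = 0 if s.parent_node is None else depth[id(s.parent_node)] + 1
    leaf_of = {l.taxon.label: l for l in species_tree.leaf_node_iter()}

    def lca(u, v):
        while depth[id(u)] > depth[id(v)]:
            u = parent[id(u)]
        while depth[id(v)] > depth[id(u)]:
            v = parent[id(v)]
        while u is not v:
            u, v = parent[id(u)], parent[id(v)]
        return u

    def ancestors_or_self(s):
        out = []
        while s is not None:
            out.append(s)
            s = parent[id(s)]
        return out

    gnodes = list(gene_tree.postorder_node_iter())
    internal = [n for n in gnodes if not n.is_leaf()]
    fixed = {
        id(n): leaf_of[species_of(n.taxon.label)] for n in gnodes if n.is_leaf()
    }

    best = [None]

    def cost_of(M):
        dups = losses = 0
        for n in internal:
            k1, k2 = n.child_nodes()
            l = lca(M[id(k1)], M[id(k2)])
            is_dup = (
                M[id(n)] is M[id(k1)]
                or M[id(n)] is M[id(k2)]
                or M[id(n)] is not l
            )
            dups += is_dup
            for c in (k1, k2):
                steps = depth[id(M[id(c)])] - depth[id(M[id(n)])]
                losses += steps - (0 if is_dup else 1)
        return dups + losses

    def rec(i, M):
        if i == len(internal):
            c = cost_of(M)
            best[0] = c if best[0] is None else min(best[0], c)
            return
        n = internal[i]
        k1, k2 = n.child_nodes()
        base = lca(M[id(k1)], M[id(k2)])
        for s in ancestors_or_self(base):
            M[id(n)] = s
            rec(i + 1, M)
        del M[id(n)]

    # internal nodes are in postorder, so children are assigned before parents
    rec(0, dict(fixed))
    return best[0]


# ---------------------------------------------------------------------------
# exhaustive binary refinements of a multiset of subtrees


def all_rooted_shapes(items):
    """All rooted binary tree shapes (nested 2-tuples) over ``items``."""
    if len(items) == 1:
        yield items[0]
        return
    if len(items) == 2:
        yield (items[0], items[1])
        return

    def insert_everywhere(t, x):
        yield (t, x)
        if isinstance(t, tuple) and len(t) == 2 and not isinstance(t, str):
            a, b = t
            for ia in insert_everywhere(a, x):
                yield (ia, b)
            for ib in insert_everywhere(b, x):
                yield (a, ib)

    for t in all_rooted_shapes(items[:-1]):
        yield from insert_everywhere(t, items[-1])


# ---------------------------------------------------------------------------
# tree distances from branch lengths (additive matrices)


def additive_matrix(tree, leaf_label) -> pd.DataFrame:
    leaves = list(tree.leaf_node_iter())
    labels = [leaf_label(l) for l in leaves]
    dist_from_root = {}

    def walk(node, acc):
        dist_from_root[id(node)] = acc
        for c in node.child_nodes():
            walk(c, acc + (c.edge.length or 0.0))

    walk(tree.seed_node, 0.0)
    ancestors = {}
    for l in leaves:
        a = set()
        x = l
        while x is not None:
            a.add(id(x))
            x = x.parent_node
        ancestors[id(l)] = a
    n = len(leaves)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            x = leaves[i]
            while id(x) not in ancestors[id(leaves[j])]:
                x = x.parent_node
            d[i, j] = d[j, i] = (
                dist_from_root[id(leaves[i])]
                + dist_from_root[id(leaves[j])]
                - 2 * dist_from_root[id(x)]
            )
    return pd.DataFrame(d, index=labels, columns=labels)


# ---------------------------------------------------------------------------
# quadratic affine-gap local alignment DP (gap of length L costs
# open + L * extend, matching the homology module's convention)


def sw_score(a, b, score_fn, gap_open, gap_extend) -> float:
    n, m = len(a), len(b)
    NEG = float("-inf")
    M = np.zeros((n + 1, m + 1))
    X = np.full((n + 1, m + 1), NEG)  # gap in b (consuming a)
    Y = np.full((n + 1, m + 1), NEG)  # gap in a (consuming b)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            X[i, j] = max(
                M[i - 1, j] - gap_open - gap_extend, X[i - 1, j] - gap_extend
            )
            Y[i, j] = max(
                M[i, j - 1] - gap_open - gap_extend, Y[i, j - 1] - gap_extend
            )
            s = score_fn(a[i - 1], b[j - 1])
            M[i, j] = max(
                0.0, s + max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            )
            best = max(best, M[i, j], X[i, j], Y[i, j])
    return best
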