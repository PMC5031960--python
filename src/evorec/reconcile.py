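"""Gene-tree / species-tree reconciliation under duplication+loss parsimony.

The pipeline implemented here turns one gene tree with bootstrap supports
into a final event-annotated tree with per-node event support:

1. contract weakly supported branches (several thresholds), giving unrooted
   non-binary trees;
2. enumerate every rooting (one per branch);
3. resolve each polytomy into minimum duplication+loss binary refinements by
   dynamic programming over the species tree (cost-vector method),
   tie-breaking with NJ-style joins on the family distance matrix;
4. reconcile and score every candidate, keep those not rejected by the SH
   test against the best likelihood and having minimal reconciliation cost;
5. build a greedy (extended majority-rule) consensus, pick the retained tree
   closest to it, and compute per-node support as the frequency of candidate
   replicates sharing both the clade and the inferred event.

A node of a reconciled binary tree is a duplication iff one of its children
maps to the same species node (LCA criterion); losses are counted per gene
edge as the number of skipped species branches, with the usual free first
step below a speciation parent, and can be grafted onto the tree as labeled
pseudo-leaves.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from .treebuild import (
    SiteLikelihoods,
    assign_branch_lengths_ols,
    felsenstein_loglik,
    protein_distance_matrix,
    sh_filter,
)
from .trees import clone, leaf_label, rf_distance, species_of

__all__ = [
    "Reconciliation",
    "CandidateTree",
    "lca_reconcile",
    "graft_losses",
    "contract_low_support",
    "enumerate_rootings",
    "resolve_polytomies_min_cost",
    "generate_candidates",
    "select_best",
    "consensus_extended_majority",
    "final_tree_and_support",
    "family_report",
]

_INF = float("inf")

DEFAULT_THRESHOLDS = (20, 30, 40, 50, 60, 70, 80, 90)
MAX_CANDIDATES = 2000


class _SpeciesIndex:
    """Parent/depth index over a rooted binary species tree with LCA."""

    def __init__(self, species_tree: dendropy.Tree):
        self.tree = species_tree
        self.parent = {}
        self.depth = {}
        self.by_label = {}
        for node in species_tree.preorder_node_iter():
            self.depth[id(node)] = (
                0 if node.parent_node is None else self.depth[id(node.parent_node)] + 1
            )
            self.parent[id(node)] = node.parent_node
            if node.is_leaf():
                self.by_label[node.taxon.label] = node
        self.postorder = list(species_tree.postorder_node_iter())

    def species(self, label: str) -> dendropy.Node:
        code = species_of(label)
        try:
            return self.by_label[code]
        except KeyError:
            raise ValueError(
                f"gene-tree leaf {label!r}: species code {code!r} "
                "not in the species tree"
            ) from None

    def lca(self, u, v):
        du, dv = self.depth[id(u)], self.depth[id(v)]
        while du > dv:
            u = self.parent[id(u)]
            du -= 1
        while dv > du:
            v = self.parent[id(v)]
            dv -= 1
        while u is not v:
            u = self.parent[id(u)]
            v = self.parent[id(v)]
        return u

    def path_down(self, top, bottom):
        """Species nodes from just below ``top`` down to ``bottom``
        (inclusive, top-down order)."""
        path = []
        node = bottom
        while node is not top:
            path.append(node)
            node = self.parent[id(node)]
            if node is None:
                raise ValueError("path_down: top is not an ancestor of bottom")
        return list(reversed(path))

    @staticmethod
    def sibling(node):
        return [c for c in node.parent_node.child_nodes() if c is not node][0]

    @staticmethod
    def branch_name(node) -> str:
        if node.is_leaf():
            return node.taxon.label
        return "+".join(sorted(l.taxon.label for l in node.leaf_iter()))


@dataclass
class Reconciliation:
    """LCA reconciliation of a rooted gene tree against a species tree."""

    mapping: dict  # gene node -> species node
    events: dict  # internal gene node -> "duplication" | "speciation"
    losses: list  # (species-tree branch name, count), aggregated
    loss_branches: dict  # gene child node -> [lost species nodes, top-down]
    dup_count: int
    loss_count: int

    @property
    def cost(self) -> int:
        return self.dup_count + self.loss_count


def lca_reconcile(
    gene_tree: dendropy.Tree, species_tree: dendropy.Tree | _SpeciesIndex
) -> Reconciliation:
    """Map each gene node to the LCA of its children's species images and
    count duplications and losses.

    Losses along a gene edge (u, v) are the species branches skipped between
    M(u) and M(v): every step down the species path loses the sibling branch,
    except that the first step below a speciation parent is free (covered by
    u's other gene child).
    """
    sidx = (
        species_tree
        if isinstance(species_tree, _SpeciesIndex)
        else _SpeciesIndex(species_tree)
    )
    mapping, events = {}, {}
    for node in gene_tree.postorder_node_iter():
        if node.is_leaf():
            mapping[node] = sidx.species(leaf_label(node))
        else:
            kids = node.child_nodes()
            m = mapping[kids[0]]
            for c in kids[1:]:
                m = sidx.lca(m, mapping[c])
            mapping[node] = m
            events[node] = (
                "duplication"
                if any(mapping[c] is m for c in kids)
                else "speciation"
            )
    loss_branches: dict = {}
    loss_count = 0
    for node in gene_tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        u, v = node.parent_node, node
        path = sidx.path_down(mapping[u], mapping[v])
        steps = path[1:] if events[u] == "speciation" else path
        lost = [sidx.sibling(s) for s in steps]
        if lost:
            loss_branches[v] = lost
            loss_count += len(lost)
    dup_count = sum(1 for e in events.values() if e == "duplication")
    agg: dict[str, int] = {}
    for lost in loss_branches.values():
        for s in lost:
            name = sidx.branch_name(s)
            agg[name] = agg.get(name, 0) + 1
    return Reconciliation(
        mapping=mapping,
        events=events,
        losses=sorted(agg.items()),
        loss_branches=loss_branches,
        dup_count=dup_count,
        loss_count=loss_count,
    )


def annotate_events(gene_tree: dendropy.Tree, rec: Reconciliation) -> None:
    """Stamp ``node.event`` labels from a reconciliation onto the tree."""
    for node, event in rec.events.items():
        node.event = event


def graft_losses(
    gene_tree: dendropy.Tree, species_tree: dendropy.Tree
) -> tuple[dendropy.Tree, Reconciliation]:
    """Copy of the gene tree with one ``LOST_<branch>`` pseudo-leaf grafted
    per inferred loss, plus the reconciliation that produced them.

    Grafted nodes are speciation points inserted along the gene edge where
    the corresponding species branch was skipped; the original topology is
    otherwise unchanged.
    """
    sidx = _SpeciesIndex(species_tree)
    out = clone(gene_tree)
    rec = lca_reconcile(out, sidx)
    annotate_events(out, rec)
    tns = out.taxon_namespace
    for child, lost in list(rec.loss_branches.items()):
        edge_len = child.edge.length
        seg = None if edge_len is None else edge_len / (len(lost) + 1)
        upper = child.parent_node
        for s in lost:  # top-down along the edge
            mid = dendropy.Node()
            mid.event = "speciation"
            mid.edge.length = seg
            loss_leaf = dendropy.Node()
            loss_leaf.taxon = tns.require_taxon(label=f"LOST_{sidx.branch_name(s)}")
            loss_leaf.is_loss = True
            loss_leaf.edge.length = 0.0
            upper.remove_child(child)
            mid.add_child(child)
            mid.add_child(loss_leaf)
            upper.add_child(mid)
            upper = mid
        child.edge.length = seg
    return out, rec


def contract_low_support(gene_tree: dendropy.Tree, threshold: float) -> dendropy.Tree:
    """Collapse every internal branch with bootstrap support < threshold.

    Returns an unrooted, possibly non-binary copy; leaf branches are never
    collapsed.  Internal branches without a support value are kept.
    """
    out = clone(gene_tree)
    out.is_rooted = False
    targets = [
        node
        for node in out.preorder_node_iter()
        if not node.is_leaf()
        and node.parent_node is not None
        and getattr(node, "support", None) is not None
        and node.support < threshold
    ]
    for node in targets:
        parent = node.parent_node
        for child in node.child_nodes():
            node.remove_child(child)
            parent.add_child(child)
        parent.remove_child(node)
    return out


def enumerate_rootings(unrooted: dendropy.Tree) -> list[dendropy.Tree]:
    """One rooted tree per branch of the unrooted tree.

    Rooting "at a node" is realized by rooting on an incident branch; branch
    enumeration covers every reconciliation-distinct rooting without
    duplicates.
    """
    if sum(1 for _ in unrooted.leaf_node_iter()) < 3:
        raise ValueError("rooting enumeration needs >= 3 leaves")
    n_edges = sum(1 for n in unrooted.preorder_node_iter() if n.parent_node is not None)
    out = []
    for k in range(n_edges):
        t = clone(unrooted)
        node = [n for n in t.preorder_node_iter() if n.parent_node is not None][k]
        edge = node.edge
        if edge.length is not None:
            t.reroot_at_edge(edge, length1=edge.length / 2, length2=edge.length / 2)
        else:
            t.reroot_at_edge(edge)
        t.is_rooted = True
        out.append(t)
    return out


# ---------------------------------------------------------------------------
# minimum-cost polytomy resolution (cost-vector DP over the species tree)


def _copy_subtree(node: dendropy.Node) -> dendropy.Node:
    """Structural copy of a gene subtree sharing taxon objects."""
    new = dendropy.Node()
    new.taxon = node.taxon
    new.edge.length = node.edge.length
    for attr in ("event", "support"):
        if getattr(node, attr, None) is not None:
            setattr(new, attr, getattr(node, attr))
    for child in node.child_nodes():
        new.add_child(_copy_subtree(child))
    return new


class _LinDist:
    """NJ-style tie-breaking between partial lineages (None = loss filler)."""

    def __init__(self, dist: pd.DataFrame | None):
        self.dist = dist

    @staticmethod
    def key(lineage):
        if lineage is None:
            return (1, "")
        return (0, min(leaf_label(l) for l in lineage.leaf_iter()))

    def between(self, a, b) -> float:
        if self.dist is None or a is None or b is None:
            return _INF
        la = [leaf_label(l) for l in a.leaf_iter()]
        lb = [leaf_label(l) for l in b.leaf_iter()]
        return float(np.mean([[self.dist.loc[x, y] for y in lb] for x in la]))

    def closest_pair(self, lineages) -> tuple[int, int]:
        best = None
        for i, j in itertools.combinations(range(len(lineages)), 2):
            cand = (self.between(lineages[i], lineages[j]),
                    self.key(lineages[i]), self.key(lineages[j]))
            if best is None or cand < best[0]:
                best = (cand, (i, j))
        return best[1]

    def closest_cross_pair(self, left, right) -> tuple[int, int]:
        best = None
        for i, j in itertools.product(range(len(left)), range(len(right))):
            cand = (self.between(left[i], right[j]),
                    self.key(left[i]), self.key(right[j]))
            if best is None or cand < best[0]:
                best = (cand, (i, j))
        return best[1]


def _join_nodes(a, b, event):
    if a is None and b is None:
        return None
    if a is None or b is None:
        return a if b is None else b
    node = dendropy.Node()
    node.event = event
    node.edge.length = 0.0
    for x in (a, b):
        if x.edge.length is None:
            x.edge.length = 0.0
        node.add_child(x)
    return node


def _resolve_polytomy(children, sidx: _SpeciesIndex, lindist: _LinDist, limit: int):
    """Minimum dup+loss assemblies of already-binary subtrees into one
    lineage rooted at their joint species image.

    DP state C[s][k]: minimal cost of presenting k gene lineages at species
    node s given every polytomy child mapped at or below s.  At a speciation
    node, ``a`` child-side lineage pairs speciate, ``b``/``c`` unpaired
    lineages pass through at one loss each, and the count is then adjusted to
    k with duplications (surplus) or losses (deficit).  Returns
    ``(list of up to limit root nodes, minimal cost)``.
    """
    K = len(children)
    images = {}
    for ch in children:
        m = None
        leaves = [ch] if ch.is_leaf() else list(ch.leaf_iter())
        for leaf in leaves:
            s = sidx.species(leaf_label(leaf))
            m = s if m is None else sidx.lca(m, s)
        images[id(ch)] = m
    root_s = images[id(children[0])]
    for ch in children[1:]:
        root_s = sidx.lca(root_s, images[id(ch)])
    mapped: dict[int, list] = {}
    for ch in children:
        mapped.setdefault(id(images[id(ch)]), []).append(ch)

    has_below: dict[int, bool] = {}
    C: dict[int, list] = {}
    choice: dict[tuple, list] = {}
    for s in sidx.postorder:
        m = len(mapped.get(id(s), []))
        kids = s.child_nodes()
        if not kids:
            has_below[id(s)] = m > 0
            C[id(s)] = [
                _INF if (k == 0 and m > 0) else abs(k - m) for k in range(K + 1)
            ]
            continue
        s1, s2 = kids
        has_below[id(s)] = m > 0 or has_below[id(s1)] or has_below[id(s2)]
        vec = []
        for k in range(K + 1):
            if k == 0 and has_below[id(s)]:
                vec.append(_INF)
                choice[(id(s), k)] = []
                continue
            best, args = _INF, []
            for a in range(K + 1):
                for b in range(K + 1 - a):
                    c1 = C[id(s1)][a + b]
                    if c1 == _INF:
                        continue
                    for c in range(K + 1 - a):
                        c2 = C[id(s2)][a + c]
                        if c2 == _INF:
                            continue
                        cost = c1 + c2 + b + c + abs(a + b + c + m - k)
                        if cost < best:
                            best, args = cost, [(a, b, c)]
                        elif cost == best:
                            args.append((a, b, c))
            vec.append(best)
            choice[(id(s), k)] = args
        C[id(s)] = vec

    def fresh_mapped(s):
        return [_copy_subtree(ch) for ch in mapped.get(id(s), [])]

    def adjust(lineages, k):
        lineages = list(lineages)
        while len(lineages) > k:
            i, j = lindist.closest_pair(lineages)
            b = lineages.pop(j)
            a = lineages.pop(i)
            lineages.append(_join_nodes(a, b, "duplication"))
        while len(lineages) < k:
            lineages.append(None)
        return lineages

    def build(s, k, limit):
        """Up to ``limit`` alternative length-k lineage lists at s; node
        objects are fresh copies, never shared across alternatives."""
        kids = s.child_nodes()
        if not kids:
            return [adjust(fresh_mapped(s), k)]
        s1, s2 = kids
        out = []
        for (a, b, c) in choice[(id(s), k)]:
            for left in build(s1, a + b, limit):
                for right in build(s2, a + c, limit):
                    # copy: lineage objects must never be shared or mutated
                    # across alternative assemblies
                    lc = [None if x is None else _copy_subtree(x) for x in left]
                    rc = [None if x is None else _copy_subtree(x) for x in right]
                    paired = []
                    for _ in range(a):
                        i, j = lindist.closest_cross_pair(lc, rc)
                        paired.append(
                            _join_nodes(lc.pop(i), rc.pop(j), "speciation")
                        )
                    out.append(adjust(paired + lc + rc + fresh_mapped(s), k))
                    if len(out) >= limit:
                        return out
        return out

    assemblies = build(root_s, 1, limit)
    roots = []
    for lineages in assemblies:
        if lineages and lineages[0] is not None:
            roots.append(lineages[0])
    return roots, C[id(root_s)][1]


def _first_polytomy(tree):
    for node in tree.postorder_node_iter():
        if not node.is_leaf() and len(node.child_nodes()) > 2:
            return node
    return None


def resolve_polytomies_min_cost(
    tree: dendropy.Tree,
    species_tree: dendropy.Tree,
    dist: pd.DataFrame | None = None,
    max_solutions: int = 32,
) -> list[dendropy.Tree]:
    """Binary refinements of a rooted non-binary tree attaining the minimum
    dup+loss reconciliation cost, up to ``max_solutions`` of them.

    Each polytomy is resolved independently by the cost-vector DP (costs are
    additive across polytomies); ties beyond the requested number of
    solutions are broken by NJ-style joins on ``dist``.  Contracting the
    inserted zero-length branches of any returned tree recovers the input.
    """
    if max_solutions < 1:
        raise ValueError("max_solutions must be >= 1")
    sidx = _SpeciesIndex(species_tree)
    lindist = _LinDist(dist)
    first = clone(tree)
    first.is_rooted = True
    work, done = [first], []
    while work:
        t = work.pop()
        poly = _first_polytomy(t)
        if poly is None:
            done.append(t)
            continue
        children = list(poly.child_nodes())
        for ch in children:
            poly.remove_child(ch)
        poly_index = next(
            i for i, n in enumerate(t.preorder_node_iter()) if n is poly
        )
        roots, _ = _resolve_polytomy(children, sidx, lindist, max_solutions)
        for root in roots:
            t2 = clone(t)
            poly2 = list(t2.preorder_node_iter())[poly_index]
            root_copy = _copy_subtree(root)
            if root_copy.is_leaf():
                # polytomy resolved to a single leaf lineage: absorb label
                poly2.taxon = root_copy.taxon
            for ch in list(root_copy.child_nodes()):
                root_copy.remove_child(ch)
                poly2.add_child(ch)
            if getattr(root_copy, "event", None) is not None:
                poly2.event = root_copy.event
            work.append(t2)
        excess = len(done) + len(work) - max_solutions
        if excess > 0:
            work = work[:-excess] if excess < len(work) else work[:0]
    return done[:max_solutions]


# ---------------------------------------------------------------------------
# candidate generation, selection, consensus, final supports


@dataclass
class CandidateTree:
    """One rooted binary candidate with provenance and scores."""

    tree: dendropy.Tree
    origin: tuple  # (support_threshold, root_index, refinement_index)
    reconciliation: Reconciliation
    site_loglik: SiteLikelihoods | None
    multiplicity: int = 1

    @property
    def loglik(self) -> float:
        return self.site_loglik.total if self.site_loglik is not None else float("nan")

    @property
    def cost(self) -> int:
        return self.reconciliation.cost


def _topology_key(tree) -> str:
    def rec(node):
        if node.is_leaf():
            return leaf_label(node)
        return "(" + ",".join(sorted(rec(c) for c in node.child_nodes())) + ")"

    return rec(tree.seed_node)


def generate_candidates(
    tree_with_supports: dendropy.Tree,
    species_tree: dendropy.Tree,
    alignment: dict[str, str],
    thresholds=DEFAULT_THRESHOLDS,
    max_solutions: int = 32,
    subs_model="poisson",
    gamma_categories: int = 4,
    max_candidates: int = MAX_CANDIDATES,
) -> list[CandidateTree]:
    """Threshold x rooting x minimal-refinement candidate sweep.

    Candidates are deduplicated by rooted topology (multiplicity retained);
    each unique topology gets OLS branch lengths from the family distance
    matrix, an LCA reconciliation and a per-site log-likelihood.
    """
    dist = protein_distance_matrix(alignment)
    sidx = _SpeciesIndex(species_tree)
    seen: dict[str, CandidateTree] = {}
    overflow = False
    for thr in thresholds:
        contracted = contract_low_support(tree_with_supports, thr)
        for ri, rooted in enumerate(enumerate_rootings(contracted)):
            refinements = resolve_polytomies_min_cost(
                rooted, species_tree, dist=dist, max_solutions=max_solutions
            )
            for fi, bin_tree in enumerate(refinements):
                key = _topology_key(bin_tree)
                if key in seen:
                    seen[key].multiplicity += 1
                    continue
                if len(seen) >= max_candidates:
                    overflow = True
                    continue
                assign_branch_lengths_ols(bin_tree, dist)
                rec = lca_reconcile(bin_tree, sidx)
                annotate_events(bin_tree, rec)
                sl = felsenstein_loglik(
                    bin_tree,
                    alignment,
                    subs_model=subs_model,
                    gamma_categories=gamma_categories,
                )
                seen[key] = CandidateTree(bin_tree, (thr, ri, fi), rec, sl)
    if overflow:
        warnings.warn(
            f"candidate cap {max_candidates} reached; keeping the first "
            "unique topologies (costs of later duplicates still counted)"
        )
    return list(seen.values())


def select_best(
    candidates: list[CandidateTree],
    alpha: float = 0.05,
    n_rell: int = 1000,
    seed: int = 0,
) -> list[CandidateTree]:
    """Retain candidates passing the SH test against the best likelihood AND
    attaining the minimum reconciliation cost among the SH survivors."""
    if not candidates:
        raise ValueError("no candidates to select from")
    kept_idx = sh_filter(
        [c.site_loglik for c in candidates], n_rell=n_rell, seed=seed, alpha=alpha
    )
    survivors = [candidates[i] for i in kept_idx]
    min_cost = min(c.cost for c in survivors)
    return [c for c in survivors if c.cost == min_cost]


def consensus_extended_majority(trees: list[dendropy.Tree]) -> dendropy.Tree:
    """Greedy (extended majority-rule) consensus of rooted trees.

    Clades are added in order of decreasing frequency (ties: larger clades,
    then lexicographic) while compatible with those already accepted; every
    clade with frequency > 50% is necessarily included.
    """
    if not trees:
        raise ValueError("no trees to form a consensus of")
    leafsets = {frozenset(leaf_label(l) for l in t.leaf_node_iter()) for t in trees}
    if len(leafsets) != 1:
        raise ValueError("consensus requires a common leaf set")
    all_leaves = leafsets.pop()
    counts: dict[frozenset, int] = {}
    for t in trees:
        for node in t.preorder_node_iter():
            if node.is_leaf() or node.parent_node is None:
                continue
            below = frozenset(leaf_label(l) for l in node.leaf_iter())
            if 2 <= len(below) < len(all_leaves):
                counts[below] = counts.get(below, 0) + 1
    ordered = sorted(
        counts.items(), key=lambda kv: (-kv[1], -len(kv[0]), sorted(kv[0]))
    )
    accepted: list[frozenset] = []
    for clade, _freq in ordered:
        if all(
            clade <= other or other <= clade or not (clade & other)
            for other in accepted
        ):
            accepted.append(clade)
    # assemble the tree: parent of each clade = smallest accepted superset
    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.is_rooted = True
    nodes: dict[frozenset, dendropy.Node] = {frozenset(all_leaves): tree.seed_node}
    for clade in sorted(accepted, key=len, reverse=True):
        nodes[clade] = dendropy.Node()
    units = sorted(accepted, key=len, reverse=True) + [
        frozenset((l,)) for l in sorted(all_leaves)
    ]
    for unit in units:
        supersets = [c for c in nodes if unit < c]
        parent = min(supersets, key=len)
        if len(unit) == 1:
            leaf = dendropy.Node()
            leaf.taxon = tns.require_taxon(label=next(iter(unit)))
            nodes[parent].add_child(leaf)
        else:
            nodes[parent].add_child(nodes[unit])
    return tree


def final_tree_and_support(
    best: list[CandidateTree],
    all_candidates: list[CandidateTree],
    alignment: dict[str, str] | None = None,
    n_boot: int = 100,
    seed: int = 0,
) -> tuple[dendropy.Tree, Reconciliation]:
    """Pick the retained tree closest (Robinson-Foulds) to the consensus of
    the retained set and attach per-node event supports.

    Node support = fraction of candidate replicates (with multiplicity) that
    contain the node's clade with the same event label; stored as
    ``node.event_support``.  If an alignment is given, clade bootstrap values
    are recomputed on the final topology into ``node.support``.
    """
    if not best:
        raise ValueError("empty best-tree set")
    consensus = consensus_extended_majority([c.tree for c in best])
    ranked = sorted(
        best, key=lambda c: (rf_distance(c.tree, consensus), -c.loglik)
    )
    final = ranked[0]
    tree = final.tree
    # replicate frequencies of (clade, event) pairs
    weights: dict[tuple, int] = {}
    total = 0
    for cand in all_candidates:
        total += cand.multiplicity
        for node, event in cand.reconciliation.events.items():
            below = frozenset(leaf_label(l) for l in node.leaf_iter())
            key = (below, event)
            weights[key] = weights.get(key, 0) + cand.multiplicity
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        below = frozenset(leaf_label(l) for l in node.leaf_iter())
        event = final.reconciliation.events.get(node)
        node.event_support = weights.get((below, event), 0) / total
    if alignment is not None:
        from .treebuild import bootstrap_supports

        boot_tree = bootstrap_supports(alignment, n_reps=n_boot, seed=seed)
        from .trees import bipartitions as _bips

        ref = {}
        anchor = min(leaf_label(l) for l in tree.leaf_node_iter())
        all_leaves = frozenset(leaf_label(l) for l in tree.leaf_node_iter())
        for node in boot_tree.preorder_node_iter():
            if node.is_leaf() or node.parent_node is None:
                continue
            below = frozenset(leaf_label(l) for l in node.leaf_iter())
            side = all_leaves - below if anchor in below else below
            if getattr(node, "support", None) is not None:
                ref[side] = node.support
        for node in tree.preorder_node_iter():
            if node.is_leaf() or node.parent_node is None:
                continue
            below = frozenset(leaf_label(l) for l in node.leaf_iter())
            side = all_leaves - below if anchor in below else below
            if side in ref:
                node.support = ref[side]
    return tree, final.reconciliation


def family_report(
    families: dict[str, tuple[dendropy.Tree, Reconciliation]],
    species: list[str],
) -> pd.DataFrame:
    """Per-family homolog counts per species plus dup/loss totals."""
    rows = []
    for fam in sorted(families):
        tree, rec = families[fam]
        counts = {sp: 0 for sp in species}
        for leaf in tree.leaf_node_iter():
            if getattr(leaf, "is_loss", False):
                continue
            sp = species_of(leaf_label(leaf))
            if sp in counts:
                counts[sp] += 1
        row = {"family": fam, **counts,
               "duplications": rec.dup_count, "losses": rec.loss_count}
        rows.append(row)
    columns = ["family", *species, "duplications", "losses"]
    return pd.DataFrame(rows, columns=columns)
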