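"""Gene-tree construction and scoring.

Distance/NJ engine with nonparametric bootstrap supports, ordinary
least-squares branch-length fitting for candidate topologies, per-site
log-likelihood by Felsenstein's pruning algorithm under a reversible
amino-acid model with discrete-Gamma rates, and a Shimodaira-Hasegawa test
(RELL resampling) for filtering candidate trees against the best one.

Alignments are ``{label: gapped protein string}`` mappings of equal lengths;
distance matrices are pandas DataFrames indexed by the same labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .model import (
    AMINO_ACIDS,
    P_DISTANCE_CAP,
    ProteinModel,
    correct_p_distance,
    gamma_category_rates,
)
from .trees import bipartitions, leaf_label

__all__ = [
    "protein_distance_matrix",
    "neighbor_joining",
    "bootstrap_supports",
    "assign_branch_lengths_ols",
    "SiteLikelihoods",
    "felsenstein_loglik",
    "sh_filter",
]

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


def _check_alignment(alignment: dict[str, str], min_seqs: int = 2) -> int:
    if len(alignment) < min_seqs:
        raise ValueError(f"alignment needs >= {min_seqs} sequences")
    lengths = {len(s) for s in alignment.values()}
    if len(lengths) != 1:
        raise ValueError("aligned sequences must have equal length")
    return lengths.pop()


def protein_distance_matrix(alignment: dict[str, str]) -> pd.DataFrame:
    """Corrected pairwise distances (substitutions/site).

    Columns with a gap in either sequence are excluded from the comparison;
    the p-distance is corrected by the 20-state formula in
    :func:`evorec.model.correct_p_distance`.  A pair with no shared ungapped
    column gets the saturation-cap distance with a warning.
    """
    _check_alignment(alignment, min_seqs=3)
    labels = list(alignment)
    arrs = {l: np.frombuffer(alignment[l].encode(), dtype="S1") for l in labels}
    ungapped = {l: a != b"-" for l, a in arrs.items()}
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            li, lj = labels[i], labels[j]
            shared = ungapped[li] & ungapped[lj]
            m = int(shared.sum())
            if m == 0:
                warnings.warn(
                    f"no shared ungapped columns for {li!r}/{lj!r}; "
                    "distance set to the saturation cap"
                )
                dist = correct_p_distance(P_DISTANCE_CAP)
            else:
                p = float((arrs[li][shared] != arrs[lj][shared]).sum()) / m
                dist = correct_p_distance(p)
            d[i, j] = d[j, i] = dist
    return pd.DataFrame(d, index=labels, columns=labels)


def neighbor_joining(dist: pd.DataFrame) -> dendropy.Tree:
    """Saitou-Nei neighbor joining; unrooted (trifurcating root) binary tree.

    Negative branch lengths are clamped to zero; joins with tied Q criterion
    pick the smallest (row, column) index pair, so the output is a
    deterministic function of the matrix.
    """
    d = np.asarray(dist, dtype=float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T):
        raise ValueError("distance matrix must be square and symmetric")
    if np.any(d < 0):
        raise ValueError("distance matrix must be nonnegative")
    n = d.shape[0]
    if n < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")
    tns = dendropy.TaxonNamespace()
    nodes = []
    for label in dist.index:
        node = dendropy.Node()
        node.taxon = tns.require_taxon(label=str(label))
        nodes.append(node)
    d = d.copy()
    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                if best is None or q[i, j] < q[best[0], best[1]] - 1e-12:
                    best = (i, j)
        i, j = best
        li = 0.5 * sub[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = sub[i, j] - li
        parent = dendropy.Node()
        ni, nj = nodes[active[i]], nodes[active[j]]
        parent.add_child(ni)
        parent.add_child(nj)
        ni.edge.length = max(li, 0.0)
        nj.edge.length = max(lj, 0.0)
        # distances from the new node to the remaining ones
        d = np.pad(d, ((0, 1), (0, 1)))
        k_new = d.shape[0] - 1
        for t, k in enumerate(active):
            if t in (i, j):
                continue
            val = 0.5 * (sub[i, t] + sub[j, t] - sub[i, j])
            d[k_new, k] = d[k, k_new] = max(val, 0.0)
        nodes.append(parent)
        active = [k for t, k in enumerate(active) if t not in (i, j)] + [k_new]
    # final trifurcation: three-point formulas
    a, b, c = active
    tree = dendropy.Tree(taxon_namespace=tns)
    root = tree.seed_node
    for k in (a, b, c):
        root.add_child(nodes[k])
    nodes[a].edge.length = max(0.5 * (d[a, b] + d[a, c] - d[b, c]), 0.0)
    nodes[b].edge.length = max(0.5 * (d[a, b] + d[b, c] - d[a, c]), 0.0)
    nodes[c].edge.length = max(0.5 * (d[a, c] + d[b, c] - d[a, b]), 0.0)
    tree.is_rooted = False
    return tree


def _resampled_alignment(alignment: dict[str, str], cols: np.ndarray):
    return {l: "".join(s[c] for c in cols) for l, s in alignment.items()}


def bootstrap_supports(
    alignment: dict[str, str], n_reps: int = 100, seed: int = 0
) -> dendropy.Tree:
    """NJ point-estimate tree with nonparametric bootstrap supports.

    Columns are resampled with replacement ``n_reps`` times; each internal
    branch of the point tree gets ``node.support`` = percentage of replicate
    NJ trees containing its bipartition.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    length = _check_alignment(alignment, min_seqs=3)
    if length < 2:
        raise ValueError("alignment must have >= 2 columns")
    tree = neighbor_joining(protein_distance_matrix(alignment))
    counts: dict[frozenset, int] = {}
    rng = np.random.default_rng(seed)
    for _ in range(n_reps):
        cols = rng.integers(length, size=length)
        rep_tree = neighbor_joining(
            protein_distance_matrix(_resampled_alignment(alignment, cols))
        )
        for bp in bipartitions(rep_tree):
            counts[bp] = counts.get(bp, 0) + 1
    all_leaves = frozenset(leaf_label(l) for l in tree.leaf_node_iter())
    anchor = min(all_leaves)
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        below = frozenset(leaf_label(l) for l in node.leaf_iter())
        side = all_leaves - below if anchor in below else below
        if 2 <= len(side) <= len(all_leaves) - 2:
            node.support = round(100.0 * counts.get(side, 0) / n_reps)
    return tree


def assign_branch_lengths_ols(tree: dendropy.Tree, dist: pd.DataFrame) -> None:
    """Fit branch lengths to pairwise distances by nonnegative least squares.

    Modifies the tree in place.  Used to put comparable branch lengths on
    candidate topologies whose contracted/refined branches lost theirs.
    """
    leaves = [n for n in tree.leaf_node_iter()]
    edges = [n for n in tree.preorder_node_iter() if n.parent_node is not None]
    edge_index = {id(n): k for k, n in enumerate(edges)}

    def path_edges(u, v):
        anc_u = []
        x = u
        while x is not None:
            anc_u.append(x)
            x = x.parent_node
        anc_set = {id(x) for x in anc_u}
        path = []
        x = v
        while id(x) not in anc_set:
            path.append(x)
            x = x.parent_node
        mrca = x
        x = u
        while id(x) != id(mrca):
            path.append(x)
            x = x.parent_node
        return path

    rows, targets = [], []
    for i in range(len(leaves)):
        for j in range(i + 1, len(leaves)):
            row = np.zeros(len(edges))
            for node in path_edges(leaves[i], leaves[j]):
                row[edge_index[id(node)]] = 1.0
            rows.append(row)
            targets.append(dist.loc[leaf_label(leaves[i]), leaf_label(leaves[j])])
    solution, _ = nnls(np.array(rows), np.array(targets))
    for node, value in zip(edges, solution):
        node.edge.length = float(value)


@dataclass
class SiteLikelihoods:
    """Per-site log-likelihoods of one tree; ``total`` is their sum."""

    site_loglik: np.ndarray

    @property
    def total(self) -> float:
        return float(self.site_loglik.sum())

    def __len__(self) -> int:
        return len(self.site_loglik)


def _leaf_conditionals(seq: str) -> np.ndarray:
    L = len(seq)
    out = np.zeros((L, 20))
    for i, aa in enumerate(seq):
        k = _AA_INDEX.get(aa)
        if k is None:  # gap or ambiguity: uninformative site
            out[i, :] = 1.0
        else:
            out[i, k] = 1.0
    return out


def felsenstein_loglik(
    tree: dendropy.Tree,
    alignment: dict[str, str],
    subs_model: str | ProteinModel = "poisson",
    gamma_categories: int = 4,
    gamma_alpha: float = 1.0,
) -> SiteLikelihoods:
    """Pruning-algorithm per-site log-likelihood.

    Unrooted trees are evaluated from their seed node: under a reversible
    model the likelihood is invariant to root placement (pulley principle).
    Rates follow the discrete-Gamma approximation with ``gamma_categories``
    equal-probability categories (1 = homogeneous).
    """
    model = (
        subs_model
        if isinstance(subs_model, ProteinModel)
        else ProteinModel.named(subs_model)
    )
    length = _check_alignment(alignment)
    rates = gamma_category_rates(gamma_alpha, gamma_categories)
    site_lik = np.zeros(length)
    for rate in rates:
        partials = {}
        for node in tree.postorder_node_iter():
            if node.is_leaf():
                label = leaf_label(node)
                if label not in alignment:
                    raise ValueError(f"leaf {label!r} has no sequence")
                cond = _leaf_conditionals(alignment[label])
            else:
                cond = np.ones((length, 20))
                for child in node.child_nodes():
                    t = (child.edge.length or 0.0) * rate
                    P = model.transition_matrix(t)
                    cond = cond * (partials.pop(id(child)) @ P.T)
            partials[id(node)] = cond
        root_cond = partials[id(tree.seed_node)]
        site_lik += (root_cond * model.freqs[None, :]).sum(axis=1) / len(rates)
    return SiteLikelihoods(np.log(site_lik))


def sh_filter(
    candidates: list[SiteLikelihoods],
    n_rell: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> list[int]:
    """Shimodaira-Hasegawa test via RELL resampling with centering.

    Returns the indices of candidates whose SH p-value against the
    maximum-likelihood candidate is >= ``alpha``.  The best candidate is
    always retained; with a single candidate the test is vacuous.
    """
    if len(candidates) == 1:
        return [0]
    n_sites = {len(c) for c in candidates}
    if len(n_sites) != 1:
        raise ValueError("candidates must share the site count")
    S = n_sites.pop()
    L = np.stack([c.site_loglik for c in candidates])  # M x S
    totals = L.sum(axis=1)
    T = totals.max() - totals  # observed deficits
    rng = np.random.default_rng(seed)
    weights = rng.multinomial(S, np.full(S, 1.0 / S), size=n_rell)  # B x S
    resampled = L @ weights.T.astype(float)  # M x B
    centered = resampled - resampled.mean(axis=1, keepdims=True)
    D = centered.max(axis=0)[None, :] - centered  # M x B
    pvals = (D >= T[:, None]).mean(axis=1)
    return [i for i in range(len(candidates)) if pvals[i] >= alpha]
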