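"""Synthetic data with known evolutionary histories.

Three generators drive the test benches for both analysis tracks:

* :func:`simulate_gene_family` grows a gene family along a fixed species tree
  under a continuous-time birth-death process (birth = duplication, death =
  loss, branch length as exposure), pruning extinct lineages but logging every
  event, so downstream reconciliation can be scored against the truth.
* :func:`evolve_sequences` evolves gap-free protein sequences down a gene tree
  under a reversible substitution model.
* :func:`simulate_genome_evolution` diverges signed gene orders from a common
  ancestor by a known number of uniformly random DCJ operations per branch.

Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

import itertools
import math
from collections import defaultdict
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .model import AMINO_ACIDS, ProteinModel, gamma_category_rates
from .rearrange import (
    Genome,
    adjacency_set,
    apply_operation,
    genome_from_adjacencies,
    random_operation,
)
from .trees import species_of  # noqa: F401  (part of the module's public surface)

__all__ = [
    "SimulatedFamily",
    "SimulatedGenomeSet",
    "simulate_gene_family",
    "evolve_sequences",
    "simulate_genome_evolution",
    "replay_event_counts",
    "random_genome",
    "random_binary_tree",
    "branch_key",
]


def branch_key(species_node) -> str:
    """Stable identifier of the species-tree branch above ``species_node``."""
    if species_node.is_leaf():
        return species_node.taxon.label
    return "+".join(sorted(l.taxon.label for l in species_node.leaf_iter()))


@dataclass
class SimulatedFamily:
    """A gene family with full ground truth.

    ``gene_tree_true`` carries true event labels on internal nodes
    (``node.event``); extinct lineages are pruned from it but every birth and
    death is retained in ``event_log`` (births carry a ``surviving`` flag set
    after pruning).  ``true_dup_count`` counts duplication nodes present in
    the pruned tree; ``true_loss_count`` counts death events.
    """

    gene_tree_true: dendropy.Tree | None
    sequences: dict[str, str] = field(default_factory=dict)
    true_dup_count: int = 0
    true_loss_count: int = 0
    locus_map: dict[str, tuple[str, str, str]] = field(default_factory=dict)
    event_log: list[dict] = field(default_factory=list)
    seed: int | None = None

    @property
    def empty(self) -> bool:
        return self.gene_tree_true is None


def replay_event_counts(event_log) -> tuple[int, int]:
    """Recount (surviving duplications, losses) from the event log."""
    dups = sum(
        1 for e in event_log if e["type"] == "duplication" and e.get("surviving")
    )
    losses = sum(1 for e in event_log if e["type"] == "loss")
    return dups, losses


def simulate_gene_family(
    species_tree: dendropy.Tree,
    birth_rate: float,
    death_rate: float,
    root_copies: int = 1,
    seed: int = 0,
) -> SimulatedFamily:
    """Birth-death gene family along a species tree.

    Rates are events per unit of species-tree branch length.  An all-extinct
    family is returned as an explicit empty result, not an exception.
    """
    if birth_rate < 0 or death_rate < 0:
        raise ValueError("rates must be nonnegative")
    if root_copies < 1:
        raise ValueError("root_copies must be >= 1")
    rng = np.random.default_rng(seed)
    tns = dendropy.TaxonNamespace()
    event_log: list[dict] = []
    event_ids = itertools.count()
    gene_counter: dict[str, int] = defaultdict(int)
    total_rate = birth_rate + death_rate

    def new_leaf(taxon_code: str, elapsed: float) -> dendropy.Node:
        gene_counter[taxon_code] += 1
        node = dendropy.Node()
        node.taxon = tns.require_taxon(
            label=f"{taxon_code}.g{gene_counter[taxon_code]}"
        )
        node.edge.length = elapsed
        return node

    def lineage(snode, remaining: float, elapsed: float):
        """Evolve one gene lineage toward ``snode``; returns a pruned gene
        subtree node (edge length set) or None if the lineage went extinct."""
        dt = rng.exponential(1.0 / total_rate) if total_rate > 0 else math.inf
        if dt < remaining:
            here = branch_key(snode)
            if rng.random() < (birth_rate / total_rate):
                ev = next(event_ids)
                event_log.append(
                    {"type": "duplication", "id": ev, "branch": here,
                     "surviving": False}
                )
                left = lineage(snode, remaining - dt, 0.0)
                right = lineage(snode, remaining - dt, 0.0)
                return _join(left, right, elapsed + dt, "duplication", ev)
            event_log.append({"type": "loss", "branch": here})
            return None
        arrived = elapsed + remaining
        if snode.is_leaf():
            return new_leaf(snode.taxon.label, arrived)
        kids = [lineage(c, c.edge.length or 0.0, 0.0) for c in snode.child_nodes()]
        return _join(kids[0], kids[1], arrived, "speciation", None)

    def _join(left, right, edge_len, event, event_id):
        if left is None and right is None:
            return None
        if left is None or right is None:
            survivor = left if right is None else right
            survivor.edge.length = (survivor.edge.length or 0.0) + edge_len
            return survivor
        node = dendropy.Node()
        node.event = event
        if event_id is not None:
            node.event_id = event_id
        node.edge.length = edge_len
        node.add_child(left)
        node.add_child(right)
        return node

    root_s = species_tree.seed_node
    copies = []
    for _ in range(root_copies):
        copies.append(lineage(root_s, 0.0, 0.0))
    # chain the root copies with zero-length duplication nodes
    current = None
    for sub in copies:
        if current is None:
            current = sub
        else:
            ev = next(event_ids)
            event_log.append(
                {"type": "duplication", "id": ev, "branch": branch_key(root_s),
                 "surviving": False}
            )
            current = _join(current, sub, 0.0, "duplication", ev)
    if current is None:
        return SimulatedFamily(
            None,
            true_loss_count=sum(1 for e in event_log if e["type"] == "loss"),
            event_log=event_log,
            seed=seed,
        )
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = current
    tree.is_rooted = True
    current.edge.length = None
    surviving_ids = {
        getattr(n, "event_id", None)
        for n in tree.preorder_node_iter()
        if getattr(n, "event", None) == "duplication"
    }
    dup_count = 0
    for e in event_log:
        if e["type"] == "duplication" and e["id"] in surviving_ids:
            e["surviving"] = True
            dup_count += 1
    loss_count = sum(1 for e in event_log if e["type"] == "loss")
    locus_map = {}
    for leaf in tree.leaf_node_iter():
        label = leaf.taxon.label
        sp, local = label.split(".", 1)
        locus_map[label] = (sp, local, "i1")
    return SimulatedFamily(
        tree,
        true_dup_count=dup_count,
        true_loss_count=loss_count,
        locus_map=locus_map,
        event_log=event_log,
        seed=seed,
    )


def evolve_sequences(
    tree: dendropy.Tree,
    length: int,
    subs_model: str | ProteinModel = "poisson",
    seed: int = 0,
    gamma_alpha: float | None = None,
    gamma_categories: int = 4,
) -> dict[str, str]:
    """Markov substitution along branches; returns leaf label -> protein.

    With ``gamma_alpha`` set, each site draws one of ``gamma_categories``
    discrete-Gamma rate multipliers (mean 1); otherwise all sites evolve at
    rate 1.  Gap-free: every sequence has exactly ``length`` residues.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    model = (
        subs_model
        if isinstance(subs_model, ProteinModel)
        else ProteinModel.named(subs_model)
    )
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise ValueError("negative branch length")
    rng = np.random.default_rng(seed)
    if gamma_alpha is not None:
        rates = gamma_category_rates(gamma_alpha, gamma_categories)
        site_rates = rates[rng.integers(len(rates), size=length)]
    else:
        site_rates = np.ones(length)
    distinct_rates = np.unique(site_rates)
    root_states = rng.choice(20, size=length, p=model.freqs)
    states = {id(tree.seed_node): root_states}
    out = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            t = node.edge.length or 0.0
            parent = states[id(node.parent_node)]
            cur = parent.copy()
            if t > 0:
                for r in distinct_rates:
                    P = model.transition_matrix(t * r)
                    sel = site_rates == r
                    for s in np.unique(parent[sel]):
                        idx = np.flatnonzero(sel & (parent == s))
                        cur[idx] = rng.choice(20, size=idx.size, p=P[s])
            states[id(node)] = cur
        if node.is_leaf():
            seq = states[id(node)]
            out[node.taxon.label] = "".join(AMINO_ACIDS[s] for s in seq)
    return out


@dataclass
class SimulatedGenomeSet:
    """Genomes diverged from a known ancestor by logged DCJ operations."""

    ancestor: Genome
    leaves: dict[str, Genome]
    ops_applied: dict[str, list]
    seed: int


def simulate_genome_evolution(
    ancestor: Genome,
    species_tree: dendropy.Tree,
    ops_per_branch: int | dict[str, int],
    seed: int = 0,
) -> SimulatedGenomeSet:
    """Apply uniformly random valid DCJ operations along each branch.

    ``ops_per_branch`` is either one integer for every branch or a mapping
    from :func:`branch_key` to an integer.  DCJ preserves gene content, so
    every leaf genome carries the ancestor's gene multiset.
    """
    if not ancestor.chromosomes:
        raise ValueError("ancestor genome is empty")
    rng = np.random.default_rng(seed)
    genes = ancestor.genes

    def k_for(node) -> int:
        if isinstance(ops_per_branch, dict):
            return int(ops_per_branch.get(branch_key(node), 0))
        return int(ops_per_branch)

    if isinstance(ops_per_branch, int) and ops_per_branch < 0:
        raise ValueError("ops_per_branch must be >= 0")
    states = {id(species_tree.seed_node): adjacency_set(ancestor)}
    ops_applied: dict[str, list] = {}
    leaves: dict[str, Genome] = {}
    for node in species_tree.preorder_node_iter():
        if node.parent_node is not None:
            adjs = states[id(node.parent_node)]
            log = []
            for _ in range(k_for(node)):
                op = random_operation(adjs, genes, rng)
                adjs = apply_operation(adjs, op)
                log.append(op)
            states[id(node)] = adjs
            ops_applied[branch_key(node)] = log
            if node.is_leaf():
                leaves[node.taxon.label] = genome_from_adjacencies(
                    node.taxon.label, genes, adjs
                )
    return SimulatedGenomeSet(ancestor, leaves, ops_applied, seed)


def random_genome(
    name: str,
    n_genes: int,
    rng,
    max_chromosomes: int = 2,
    circular_prob: float = 0.3,
) -> Genome:
    """Random signed gene order over genes 1..n (uniform helper for tests
    and oracles, not a biological model)."""
    from .rearrange import Chromosome

    order = rng.permutation(n_genes) + 1
    signs = rng.choice([-1, 1], size=n_genes)
    genes = list(order * signs)
    n_chrom = int(rng.integers(1, min(max_chromosomes, n_genes) + 1))
    cuts = sorted(rng.choice(np.arange(1, n_genes), size=n_chrom - 1, replace=False))
    pieces = np.split(np.array(genes), cuts)
    chroms = tuple(
        Chromosome(tuple(int(g) for g in piece), bool(rng.random() < circular_prob))
        for piece in pieces
    )
    return Genome(name, chroms)


def random_binary_tree(labels, rng, min_bl: float = 0.05, max_bl: float = 0.4):
    """Random rooted binary tree over ``labels`` with uniform branch lengths
    (random sequential joins; used for NJ-consistency style checks)."""
    tns = dendropy.TaxonNamespace()
    nodes = []
    for lab in labels:
        n = dendropy.Node()
        n.taxon = tns.require_taxon(label=lab)
        n.edge.length = float(rng.uniform(min_bl, max_bl))
        nodes.append(n)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        right = nodes.pop(j)
        left = nodes.pop(i)
        parent = dendropy.Node()
        parent.add_child(left)
        parent.add_child(right)
        parent.edge.length = float(rng.uniform(min_bl, max_bl))
        nodes.append(parent)
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = nodes[0]
    tree.seed_node.edge.length = None
    tree.is_rooted = True
    return tree
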