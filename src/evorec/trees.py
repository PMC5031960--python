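"""Shared tree plumbing: species tree, newick/NHX I/O, bipartition utilities.

Trees are :class:`dendropy.Tree` objects throughout.  Gene-tree leaves are
labeled ``species.geneid`` (e.g. ``rha.g3``); species-tree leaves carry bare
taxon codes.  Event labels (``"duplication"``/``"speciation"``) and event
supports live in plain node attributes (``node.event``, ``node.event_support``)
and are serialized as NHX tags.
"""

from __future__ import annotations

import dendropy

DEFAULT_TAXA = ("the", "tom", "cof", "rha", "cra", "rsa")

# Six eudicots: Theobroma (rosid outgroup), Solanum (non-Gentianales asterid),
# then the Gentianales: Coffea sister to the three Rauvolfioideae.  The
# branching order within (rha, cra, rsa) is not fixed by the framework and is
# a documented, overridable assumption; branch lengths are expected amino-acid
# substitutions per site.
DEFAULT_SPECIES_NEWICK = (
    "(the:0.25,(tom:0.20,(cof:0.15,(rha:0.10,(cra:0.08,rsa:0.08):0.04)"
    ":0.05):0.07):0.05);"
)


def parse_tree(newick: str, rooted: bool = True) -> dendropy.Tree:
    tree = dendropy.Tree.get(
        data=newick,
        schema="newick",
        suppress_internal_node_taxa=True,
        rooting="force-rooted" if rooted else "force-unrooted",
    )
    return tree


def species_tree(newick: str | None = None) -> dendropy.Tree:
    """Rooted binary species tree (default: the six-taxon eudicot frame)."""
    tree = parse_tree(newick or DEFAULT_SPECIES_NEWICK, rooted=True)
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        if len(node.child_nodes()) != 2:
            raise ValueError("species tree must be rooted and binary")
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        raise ValueError("species tree taxon codes must be unique")
    return tree


def species_of(label: str) -> str:
    """Species code of a gene label (``rha.g3`` -> ``rha``)."""
    return label.split(".", 1)[0]


def leaf_label(node) -> str:
    return node.taxon.label if node.taxon is not None else node.label


def leaf_labels(tree) -> list[str]:
    return [leaf_label(n) for n in tree.leaf_node_iter()]


def to_newick(tree, **kwargs) -> str:
    return tree.as_string(
        schema="newick", suppress_rooting=True, **kwargs
    ).strip()


def clades(tree, trivial: bool = False) -> list[frozenset]:
    """Leaf-label set below every internal node (rooted view), with
    multiplicity collapsed to a list in preorder."""
    out = []
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        below = frozenset(leaf_label(l) for l in node.leaf_iter())
        if trivial or len(below) >= 2:
            out.append(below)
    return out


def bipartitions(tree) -> set[frozenset]:
    """Nontrivial unrooted bipartitions, each canonicalized as the side not
    containing the lexicographically smallest leaf."""
    all_leaves = frozenset(leaf_labels(tree))
    anchor = min(all_leaves)
    out = set()
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        below = frozenset(leaf_label(l) for l in node.leaf_iter())
        side = all_leaves - below if anchor in below else below
        if 2 <= len(side) <= len(all_leaves) - 2:
            out.add(side)
    return out


def rf_distance(t1, t2) -> int:
    """Unrooted Robinson-Foulds (symmetric bipartition difference)."""
    if frozenset(leaf_labels(t1)) != frozenset(leaf_labels(t2)):
        raise ValueError("trees are on different leaf sets")
    return len(bipartitions(t1) ^ bipartitions(t2))


def build_tree(root_children, taxon_namespace=None) -> dendropy.Tree:
    """Assemble a dendropy tree from a nested tuple/str structure.

    Strings are leaves; tuples are internal nodes.  Mostly used in tests.
    """
    tns = taxon_namespace or dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)

    def attach(parent, spec):
        if isinstance(spec, str):
            node = dendropy.Node()
            node.taxon = tns.require_taxon(label=spec)
            parent.add_child(node)
            return
        node = dendropy.Node()
        parent.add_child(node)
        for child in spec:
            attach(node, child)

    for child in root_children:
        attach(tree.seed_node, child)
    tree.is_rooted = True
    return tree


def _nhx_node(node, include_events: bool, include_supports: bool) -> str:
    if node.is_leaf():
        body = leaf_label(node)
    else:
        body = (
            "(" + ",".join(
                _nhx_node(c, include_events, include_supports)
                for c in node.child_nodes()
            ) + ")"
        )
        if include_supports and getattr(node, "support", None) is not None:
            body += f"{node.support:g}"
    if node.edge.length is not None:
        body += f":{node.edge.length:.6g}"
    tags = []
    event = getattr(node, "event", None)
    if include_events and event is not None:
        tags.append("D=Y" if event == "duplication" else "D=N")
    ev_sup = getattr(node, "event_support", None)
    if include_events and ev_sup is not None:
        tags.append(f"B={ev_sup:.3f}")
    if tags:
        body += "[&&NHX:" + ":".join(tags) + "]"
    return body


def to_nhx(tree, include_events: bool = True, include_supports: bool = True) -> str:
    """Newick with NHX tags: ``D=Y/N`` duplication flag, ``B=`` event support."""
    return _nhx_node(tree.seed_node, include_events, include_supports) + ";"


def clone(tree) -> dendropy.Tree:
    """Deep-copy a tree (shared taxon namespace), preserving custom node
    attributes such as ``event``."""
    return tree.clone(depth=1)
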