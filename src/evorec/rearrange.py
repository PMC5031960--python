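"""Genome rearrangement analysis on signed gene orders.

Implements the double-cut-and-join (DCJ) model: a genome is a set of
chromosomes (linear or circular) of signed genes; a DCJ operation cuts up to
two adjacencies and rejoins the four (or fewer) exposed extremities.  The
module provides the adjacency graph between two genomes, the DCJ distance
d = N - (C + I/2) where C counts cycles and I odd paths, an optimal greedy
sorting scenario, and median-genome inference for three-way ancestor
reconstruction.  It also carries the duplicate-pair dating utilities used to
restrict rearrangement analysis to orthologs: Nei-Gojobori (NG86) Ks/Ka
estimation and a Ks/similarity classifier separating speciation-derived
orthologs from older out-paralogs.

Gene orders follow GRIMM conventions: signed integers, ``$`` terminates a
linear chromosome and ``@`` a circular one.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, replace

from Bio.Data import CodonTable

__all__ = [
    "Chromosome",
    "Genome",
    "AdjacencyGraph",
    "DcjOperation",
    "GenePair",
    "build_adjacency_graph",
    "dcj_distance",
    "dcj_sort",
    "apply_operation",
    "enumerate_operations",
    "random_operation",
    "dcj_median",
    "infer_ancestor",
    "ks_ng86",
    "classify_pairs",
    "read_grimm",
    "write_grimm",
    "genome_from_adjacencies",
    "adjacency_set",
]

# An extremity is (gene, 0) for the tail or (gene, 1) for the head.
TAIL, HEAD = 0, 1


class GeneContentError(ValueError):
    """Raised when two genomes do not share the same unsigned gene content."""


class CapabilityError(RuntimeError):
    """Raised when an exact computation is requested above its size cap."""


@dataclass(frozen=True)
class Chromosome:
    genes: tuple[int, ...]
    circular: bool = False

    def __post_init__(self):
        if not self.genes:
            raise ValueError("empty chromosome")
        if any(g == 0 for g in self.genes):
            raise ValueError("gene identifiers must be nonzero signed integers")


@dataclass(frozen=True)
class Genome:
    """Signed gene order: each unsigned gene id appears exactly once."""

    name: str
    chromosomes: tuple[Chromosome, ...]

    def __post_init__(self):
        object.__setattr__(self, "chromosomes", tuple(self.chromosomes))
        genes = [abs(g) for c in self.chromosomes for g in c.genes]
        if len(genes) != len(set(genes)):
            raise ValueError(f"genome {self.name!r}: duplicated gene identifiers")

    @property
    def genes(self) -> frozenset[int]:
        return frozenset(abs(g) for c in self.chromosomes for g in c.genes)

    @property
    def n_genes(self) -> int:
        return sum(len(c.genes) for c in self.chromosomes)


# ---------------------------------------------------------------------------
# adjacency representation


def _ext_in(g: int) -> tuple[int, int]:
    """Extremity by which a signed gene is entered reading left to right."""
    return (abs(g), TAIL if g > 0 else HEAD)


def _ext_out(g: int) -> tuple[int, int]:
    return (abs(g), HEAD if g > 0 else TAIL)


def adjacency_set(genome: Genome) -> frozenset[frozenset]:
    """Adjacencies of a genome as frozensets of two extremities.

    Telomeres are implicit: an extremity absent from every adjacency is a
    telomere.
    """
    adjs = set()
    for chrom in genome.chromosomes:
        seq = chrom.genes
        for x, y in zip(seq, seq[1:]):
            adjs.add(frozenset((_ext_out(x), _ext_in(y))))
        if chrom.circular:
            adjs.add(frozenset((_ext_out(seq[-1]), _ext_in(seq[0]))))
    return frozenset(adjs)


def _partner_map(adjs) -> dict:
    partner = {}
    for adj in adjs:
        x, y = tuple(adj)
        partner[x] = y
        partner[y] = x
    return partner


def genome_from_adjacencies(name: str, genes, adjs) -> Genome:
    """Rebuild a canonical Genome from an adjacency set over ``genes``.

    Linear chromosomes are read off between telomeres, circular ones from the
    leftover cycles; each chromosome is put in its lexicographically minimal
    signed representation and chromosomes are sorted, so equal adjacency sets
    always produce identical objects.
    """
    partner = _partner_map(adjs)
    genes = sorted(genes)
    exts = [(g, e) for g in genes for e in (TAIL, HEAD)]
    seen_genes = set()
    chroms = []
    for t in exts:  # linear chromosomes start at telomeres
        if t in partner or t[0] in seen_genes:
            continue
        seq = []
        cur = t
        while True:
            g, end = cur
            seq.append(g if end == TAIL else -g)
            seen_genes.add(g)
            out = (g, 1 - end)
            if out in partner:
                cur = partner[out]
            else:
                break
        rev = tuple(-g for g in reversed(seq))
        chroms.append(Chromosome(min(tuple(seq), rev), False))
    for e0 in exts:  # remaining genes sit on circular chromosomes
        if e0[0] in seen_genes:
            continue
        seq = []
        cur = e0
        while cur[0] not in seen_genes:
            g, end = cur
            seq.append(g if end == TAIL else -g)
            seen_genes.add(g)
            cur = partner[(g, 1 - end)]
        variants = []
        for s in (tuple(seq), tuple(-g for g in reversed(seq))):
            for i in range(len(s)):
                variants.append(s[i:] + s[:i])
        chroms.append(Chromosome(min(variants), True))
    chroms.sort(key=lambda c: (c.circular, c.genes))
    return Genome(name, tuple(chroms))


def _check_content(a: Genome, b: Genome) -> frozenset[int]:
    if a.genes != b.genes:
        diff = sorted(a.genes ^ b.genes)
        raise GeneContentError(
            f"genomes {a.name!r} and {b.name!r} differ in gene content: {diff}"
        )
    return a.genes


# ---------------------------------------------------------------------------
# adjacency graph and distance


@dataclass(frozen=True)
class AdjacencyGraph:
    """Component census of the adjacency graph between two genomes.

    Vertices are the adjacencies and telomeres of both genomes; every
    extremity is an edge joining its element in genome A to its element in
    genome B.  ``cycles`` (C) and ``odd_paths`` (I) give the DCJ distance
    d = N - (C + I/2).
    """

    n_genes: int
    cycles: int
    odd_paths: int
    even_paths: int

    @property
    def distance(self) -> int:
        assert self.odd_paths % 2 == 0
        return self.n_genes - self.cycles - self.odd_paths // 2


def _component_counts(pa: dict, pb: dict, genes) -> tuple[int, int, int]:
    exts = [(g, e) for g in sorted(genes) for e in (TAIL, HEAD)]
    visited = set()
    cycles = odd = even = 0
    # paths first: an endpoint is an extremity telomeric in one genome
    for e0 in exts:
        if e0 in visited or (e0 in pa and e0 in pb):
            continue
        side = "B" if e0 not in pa else "A"  # e0's other element is expandable
        # walk edge by edge; an extremity IS an edge of the adjacency graph
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
        if edges % 2:
            odd += 1
        else:
            even += 1
    for e0 in exts:  # leftovers are cycles
        if e0 in visited:
            continue
        cur, side = e0, "A"
        while cur not in visited:
            visited.add(cur)
            pm = pa if side == "A" else pb
            cur = pm[cur]
            side = "B" if side == "A" else "A"
        cycles += 1
    return cycles, odd, even


def build_adjacency_graph(a: Genome, b: Genome) -> AdjacencyGraph:
    genes = _check_content(a, b)
    pa = _partner_map(adjacency_set(a))
    pb = _partner_map(adjacency_set(b))
    cycles, odd, even = _component_counts(pa, pb, genes)
    return AdjacencyGraph(len(genes), cycles, odd, even)


def dcj_distance(a: Genome, b: Genome) -> int:
    """Minimum number of DCJ operations transforming ``a`` into ``b``."""
    return build_adjacency_graph(a, b).distance


def _distance_from_maps(pa: dict, pb: dict, genes) -> int:
    cycles, odd, _ = _component_counts(pa, pb, genes)
    return len(genes) - cycles - odd // 2


# ---------------------------------------------------------------------------
# operations


@dataclass(frozen=True)
class DcjOperation:
    """Cut the adjacencies in ``removed`` and form those in ``added``.

    Extremities freed by a cut but not re-joined become telomeres, so both
    tuples may have fewer than two entries (a join of two telomeres removes
    nothing; splitting an adjacency adds nothing).
    """

    removed: tuple[frozenset, ...]
    added: tuple[frozenset, ...]


def apply_operation(adjs: frozenset, op: DcjOperation) -> frozenset:
    cur = set(adjs)
    for adj in op.removed:
        cur.remove(adj)
    bound = set(itertools.chain.from_iterable(cur))
    for adj in op.added:
        if adj & bound:
            raise ValueError("operation joins an extremity that is not free")
        cur.add(adj)
    return frozenset(cur)


def enumerate_operations(adjs: frozenset, genes) -> list[DcjOperation]:
    """All distinct DCJ operations applicable to an adjacency set."""
    adj_list = sorted(adjs, key=sorted)
    partner = _partner_map(adjs)
    telos = [
        (g, e) for g in sorted(genes) for e in (TAIL, HEAD) if (g, e) not in partner
    ]
    ops = []
    for p, q in itertools.combinations(adj_list, 2):
        (a, b), (c, d) = sorted(p), sorted(q)
        ops.append(
            DcjOperation((p, q), (frozenset((a, c)), frozenset((b, d))))
        )
        ops.append(
            DcjOperation((p, q), (frozenset((a, d)), frozenset((b, c))))
        )
    for p in adj_list:
        a, b = sorted(p)
        for t in telos:
            ops.append(DcjOperation((p,), (frozenset((a, t)),)))
            ops.append(DcjOperation((p,), (frozenset((b, t)),)))
        ops.append(DcjOperation((p,), ()))  # split into two telomeres
    for t, u in itertools.combinations(telos, 2):
        ops.append(DcjOperation((), (frozenset((t, u)),)))
    return ops


def random_operation(adjs: frozenset, genes, rng) -> DcjOperation:
    """Uniformly random valid DCJ operation (``rng``: numpy Generator)."""
    ops = enumerate_operations(adjs, genes)
    return ops[int(rng.integers(len(ops)))]


def dcj_sort(a: Genome, b: Genome) -> list[DcjOperation]:
    """Optimal DCJ scenario from ``a`` to ``b`` (greedy adjacency repair).

    Every target adjacency of ``b`` absent from the current genome is formed
    by one cut-and-join; a final pass splits adjacencies whose extremities are
    telomeric in ``b``.  Each step reduces the distance by exactly one, so the
    scenario length equals ``dcj_distance(a, b)``.
    """
    genes = _check_content(a, b)
    cur = set(adjacency_set(a))
    partner = _partner_map(cur)
    target = adjacency_set(b)
    ops = []

    def element(e):
        return frozenset((e, partner[e])) if e in partner else None

    def do(removed, added):
        op = DcjOperation(tuple(removed), tuple(added))
        for adj in removed:
            cur.remove(adj)
            x, y = tuple(adj)
            del partner[x], partner[y]
        for adj in added:
            cur.add(adj)
            x, y = tuple(adj)
            partner[x] = y
            partner[y] = x
        ops.append(op)

    for adj in sorted(target, key=sorted):
        p, q = sorted(adj)
        u, v = element(p), element(q)
        if u is not None and u == v:
            continue  # already in place
        removed = [x for x in {u, v} if x is not None]
        leftovers = set(itertools.chain(*removed)) - {p, q}
        added = [frozenset((p, q))]
        if len(leftovers) == 2:
            added.append(frozenset(leftovers))
        do(removed, added)
    target_partner = _partner_map(target)
    for g in sorted(genes):
        for e in (TAIL, HEAD):
            ext = (g, e)
            if ext not in target_partner and ext in partner:
                do([frozenset((ext, partner[ext]))], [])
    assert frozenset(cur) == target
    return ops


# ---------------------------------------------------------------------------
# median / ancestor inference

EXACT_MEDIAN_MAX_GENES = 6


def _all_matchings(exts: list):
    """Yield all adjacency sets (partial perfect matchings) on extremities."""
    if not exts:
        yield ()
        return
    first, rest = exts[0], exts[1:]
    for sub in _all_matchings(rest):  # first is a telomere
        yield sub
    for i, other in enumerate(rest):
        pair = frozenset((first, other))
        for sub in _all_matchings(rest[:i] + rest[i + 1 :]):
            yield (pair,) + sub


def median_lower_bound(a: Genome, b: Genome, c: Genome) -> int:
    dab = dcj_distance(a, b)
    dac = dcj_distance(a, c)
    dbc = dcj_distance(b, c)
    return -((dab + dac + dbc) // -2)  # ceil


def dcj_median(
    a: Genome, b: Genome, c: Genome, mode: str = "heuristic"
) -> tuple[Genome, int]:
    """Genome minimizing d(m,a)+d(m,b)+d(m,c); a parsimony ancestor.

    ``exact`` mode searches the full genome space (all matchings of gene
    extremities) with early termination at the pairwise lower bound
    ceil((d(a,b)+d(a,c)+d(b,c))/2); it is capped at
    ``EXACT_MEDIAN_MAX_GENES`` genes.  ``heuristic`` mode hill-climbs over
    single DCJ moves from each input genome and keeps the best.
    """
    genes = _check_content(a, b)
    _check_content(a, c)
    maps = [_partner_map(adjacency_set(g)) for g in (a, b, c)]

    def total(pm):
        return sum(_distance_from_maps(pm, m, genes) for m in maps)

    lb = median_lower_bound(a, b, c)
    if mode == "exact":
        if len(genes) > EXACT_MEDIAN_MAX_GENES:
            raise CapabilityError(
                f"exact median capped at {EXACT_MEDIAN_MAX_GENES} genes "
                f"(got {len(genes)}); use mode='heuristic'"
            )
        exts = [(g, e) for g in sorted(genes) for e in (TAIL, HEAD)]
        best_adjs, best = None, None
        for adjs in _all_matchings(exts):
            score = total(_partner_map(adjs))
            if best is None or score < best:
                best_adjs, best = frozenset(adjs), score
                if best == lb:
                    break
        return genome_from_adjacencies("median", genes, best_adjs), best
    if mode != "heuristic":
        raise ValueError(f"unknown median mode {mode!r}")
    best_adjs, best = None, None
    for g in (a, b, c):
        adjs = adjacency_set(g)
        score = total(_partner_map(adjs))
        improved = True
        while improved:
            improved = False
            for op in enumerate_operations(adjs, genes):
                nxt = apply_operation(adjs, op)
                s = total(_partner_map(nxt))
                if s < score:
                    adjs, score, improved = nxt, s, True
                    break
            if score == lb:
                break
        if best is None or score < best:
            best_adjs, best = adjs, score
        if best == lb:
            break
    return genome_from_adjacencies("median", genes, best_adjs), best


def infer_ancestor(leaves: dict[str, Genome], mode: str = "heuristic"):
    """Median-based ancestor of three leaf genomes.

    Returns ``(ancestor, branch_counts)`` where ``branch_counts[name]`` is the
    DCJ distance from the inferred ancestor to that leaf.
    """
    if len(leaves) != 3:
        raise ValueError("ancestor inference requires exactly three genomes")
    names = sorted(leaves)
    a, b, c = (leaves[n] for n in names)
    median, _ = dcj_median(a, b, c, mode=mode)
    counts = {n: dcj_distance(median, leaves[n]) for n in names}
    return replace(median, name="ancestor"), counts


# ---------------------------------------------------------------------------
# GRIMM format


def write_grimm(genomes) -> str:
    lines = []
    for g in genomes:
        lines.append(f">{g.name}")
        for chrom in g.chromosomes:
            body = " ".join(f"{x:+d}" for x in chrom.genes)
            lines.append(f"{body} {'@' if chrom.circular else '$'}")
    return "\n".join(lines) + "\n"


def read_grimm(text: str) -> list[Genome]:
    genomes = []
    name, chroms = None, []
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith(">"):
            if name is not None:
                genomes.append(Genome(name, tuple(chroms)))
            name, chroms = line[1:].strip(), []
            continue
        if name is None:
            raise ValueError("GRIMM gene order before any '>' header")
        if line.endswith("$"):
            circular = False
        elif line.endswith("@"):
            circular = True
        else:
            raise ValueError(f"chromosome line must end with '$' or '@': {raw!r}")
        genes = tuple(int(tok) for tok in line[:-1].split())
        chroms.append(Chromosome(genes, circular))
    if name is not None:
        genomes.append(Genome(name, tuple(chroms)))
    return genomes


# ---------------------------------------------------------------------------
# Ks estimation (NG86) and ortholog / out-paralog classification

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]
_STOPS = set(_STANDARD_TABLE.stop_codons)
_BASES = "ACGT"


def _translate(codon: str):
    return None if codon in _STOPS else _STANDARD_TABLE.forward_table[codon]


def _syn_sites(codon: str) -> float:
    """Synonymous site count of one codon: per position, the fraction of the
    three possible point mutations that preserve the amino acid (mutations to
    stop codons count as nonsynonymous)."""
    aa = _translate(codon)
    s = 0.0
    for pos in range(3):
        syn = 0
        for base in _BASES:
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1 :]
            if alt not in _STOPS and _translate(alt) == aa:
                syn += 1
        s += syn / 3.0
    return s


def _pathway_differences(c1: str, c2: str) -> tuple[float, float]:
    """Average synonymous/nonsynonymous difference counts over all mutational
    pathways between two codons, skipping pathways through stop codons."""
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    totals = []
    for order in itertools.permutations(diff_pos):
        cur, sd, nd, ok = c1, 0, 0, True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in _STOPS:
                ok = False
                break
            if _translate(cur) == _translate(nxt):
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            totals.append((sd, nd))
    if not totals:  # every path crosses a stop; count all as nonsynonymous
        return 0.0, float(len(diff_pos))
    sd = sum(t[0] for t in totals) / len(totals)
    nd = sum(t[1] for t in totals) / len(totals)
    return sd, nd


@dataclass
class KsResult:
    ks: float | None
    ka: float | None
    syn_sites: float
    nonsyn_sites: float
    syn_diffs: float
    nonsyn_diffs: float
    saturated_s: bool = False
    saturated_n: bool = False


def _jc_correct(p: float) -> float | None:
    arg = 1.0 - 4.0 * p / 3.0
    if arg <= 0.0:
        return None
    return -0.75 * math.log(arg)


def ks_ng86(cds_a: str, cds_b: str) -> KsResult:
    """Nei-Gojobori (1986) Ks/Ka with Jukes-Cantor correction.

    Sites are counted per sequence and averaged; differences are averaged over
    all mutational pathways per codon.  Saturation (correction argument <= 0)
    yields ``ks`` (or ``ka``) of ``None`` with the corresponding flag set.
    """
    cds_a, cds_b = cds_a.upper(), cds_b.upper()
    if len(cds_a) != len(cds_b):
        raise ValueError("coding sequences differ in length")
    if len(cds_a) % 3:
        raise ValueError("coding sequence length is not a multiple of 3")
    codons_a = [cds_a[i : i + 3] for i in range(0, len(cds_a), 3)]
    codons_b = [cds_b[i : i + 3] for i in range(0, len(cds_b), 3)]
    for codon in itertools.chain(codons_a, codons_b):
        if any(b not in _BASES for b in codon):
            raise ValueError(f"non-ACGT base in codon {codon!r}")
        if codon in _STOPS:
            raise ValueError(f"internal stop codon {codon!r}")
    s_a = sum(_syn_sites(c) for c in codons_a)
    s_b = sum(_syn_sites(c) for c in codons_b)
    S = 0.5 * (s_a + s_b)
    N = len(cds_a) - S
    Sd = Nd = 0.0
    for ca, cb in zip(codons_a, codons_b):
        sd, nd = _pathway_differences(ca, cb)
        Sd += sd
        Nd += nd
    ps = Sd / S if S > 0 else 0.0
    pn = Nd / N if N > 0 else 0.0
    ks, ka = _jc_correct(ps), _jc_correct(pn)
    return KsResult(
        ks=ks,
        ka=ka,
        syn_sites=S,
        nonsyn_sites=N,
        syn_diffs=Sd,
        nonsyn_diffs=Nd,
        saturated_s=ks is None,
        saturated_n=ka is None,
    )


@dataclass
class GenePair:
    """A candidate homologous gene pair between (or within) genomes."""

    gene_a: str
    gene_b: str
    similarity: float  # percent amino-acid identity
    ks: float | None  # None = saturated/undefined
    classification: str = "unassigned"


def classify_pairs(pairs, ks_cut: float, sim_cut: float) -> list[GenePair]:
    """Label pairs as speciation-derived orthologs or older out-paralogs.

    A pair is an ortholog iff its Ks is defined and <= ``ks_cut`` and its
    similarity >= ``sim_cut``; anything else (including Ks-saturated pairs)
    is an out-paralog, to be discarded before single-copy rearrangement
    analysis.
    """
    out = []
    for p in pairs:
        ortholog = p.ks is not None and p.ks <= ks_cut and p.similarity >= sim_cut
        out.append(replace(p, classification="ortholog" if ortholog else "out_paralog"))
    return out
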