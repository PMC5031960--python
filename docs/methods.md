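# Methods

This note documents the models, algorithms, defaults and deliberate design
choices behind `evorec`, and what the synthetic benchmarks do and do not
demonstrate about real data.

## Synthetic data generators

**Gene families** (`evorec.simulate.simulate_gene_family`). A gene family is
grown along a fixed rooted binary species tree by a continuous-time
birth–death process per lineage: events occur at rate λ (birth = duplication)
and μ (death = loss) per unit of species-tree branch length, so branch length
is the exposure. At a speciation node every surviving lineage splits into
both descendant branches. Extinct lineages are pruned from the emitted tree
(unary nodes suppressed, branch lengths merged) but every event stays in the
log; `true_dup_count` counts duplication nodes *surviving in the pruned
tree* and `true_loss_count` counts death events. These definitions coincide
with parsimony reconciliation counts exactly in the duplication-only regime
(μ = 0), which is the regime used for event-recovery benchmarks; with μ > 0
a duplication whose one side went fully extinct is invisible to any
tree-based method, so simulator truth and attainable inference deliberately
differ. `root_copies = k` seeds the family with k copies joined by k−1
zero-length duplication nodes at the root. An all-extinct family is an
explicit empty result, not an exception.

Default species tree: `(the,(tom,(cof,(rha,(cra,rsa)))))` with branch
lengths 0.04–0.25 expected substitutions/site. The branching order within
the Rauvolfioideae triple `(rha,(cra,rsa))` is an assumption, not settled
phylogeny, and every entry point accepts a user newick instead.

**Sequences** (`evolve_sequences`). Protein sequences evolve gap-free down
the gene tree under a reversible amino-acid model; the root sequence is
drawn from the stationary frequencies and each branch applies the transition
matrix `P(t) = exp(Qt)`. The built-in default model is the
uniform-exchangeability ("poisson") 20-state model, normalized to one
expected substitution per unit branch length; any empirical matrix (LG, WAG,
…) can be plugged in from a PAML-format `.dat` file via
`ProteinModel.from_paml` — the package ships no transcribed empirical matrix
on purpose, since a silently mistyped 190-entry table is worse than an
explicit simple default. Optional discrete-Gamma rate heterogeneity uses
mean-of-bin category rates (4 categories by default).

**Genomes** (`simulate_genome_evolution`). A signed gene order diverges
along each species-tree branch by exactly `ops_per_branch` DCJ operations
drawn uniformly from the set of all valid operations (adjacency/adjacency,
adjacency/telomere, telomere join, adjacency split). DCJ preserves gene
content, so every leaf genome carries the ancestor's genes. Defaults used in
the benchmarks — 30 genes, 2–3 operations per branch — mirror the
"handful of large rearrangements" regime of desk-scale ancestral
reconstruction: short random walks on genomes of this size almost never
cancel, so the simulated operation count is almost always the true distance.

**What the simulations do not model:** insertions/deletions and alignment
error (sequences are gap-free), codon-level selection, incomplete lineage
sorting, gene conversion, tandem-array dynamics, and unequal gene content
between genomes. A method that passes these benchmarks is verified as an
implementation of its model; performance on real data additionally depends
on all of the above.

## Homolog screen

BLAST's seeded heuristic is replaced by exact Smith–Waterman local alignment
(Biopython `PairwiseAligner`, BLOSUM62 by default), which is affordable at
desk scale and removes the database-size-dependent e-value from the screen;
the operative filters are percent identity ≥ 35 and query coverage ≥ 0.5.
Definitions the screen depends on, stated explicitly because conventions
vary: identity = identical columns / aligned columns with gaps in the
denominator; coverage = aligned query span / query length; a gap of length L
costs `gap_open + L·gap_extend` (defaults 11/1). Subject overhang beyond the
aligned span is trimmed. `X` is tolerated and scored 0. Ties between
co-optimal alignments take Biopython's first enumeration path, so results
are deterministic. One isoform per locus is retained (highest score, then
longest, then smallest id); subjects missing from the locus map become
singleton loci with a warning.

## Tree building and scoring

Distances are corrected p-distances on pairwise-ungapped columns,
`d = −(19/20) ln(1 − (20/19) p)`, with p clamped at 0.93 (the correction
diverges at 19/20); a pair with no shared ungapped columns gets the cap with
a warning. NJ is the Saitou–Nei agglomeration with negative branch lengths
clamped to zero and ties broken by the smallest row index, making the tree a
deterministic function of the matrix. Bootstrap supports resample columns
with replacement and count bipartition recovery across replicate NJ trees.

Candidate topologies produced downstream lose branch lengths on contracted
or refined edges, so each candidate's lengths are re-fit from the family
distance matrix by nonnegative least squares over the edge–path incidence
system; likelihoods are then computed by Felsenstein pruning under the same
substitution model with discrete-Gamma(4) rates (shape fixed at 1.0 by
default — candidates are *ranked*, not parameter-estimated, so a shared
coarse shape is sufficient and keeps candidates comparable). Under a
reversible model the likelihood is root-invariant; unrooted trees are
evaluated from their seed node, and the test suite asserts re-rooting
invariance to 1e-8.

The SH test uses RELL: site log-likelihood vectors are resampled (1000
multinomial replicates by default), centered per candidate, and the p-value
of each candidate's observed deficit to the best tree is the fraction of
replicates whose centered max-difference exceeds it. The best tree always
survives; α = 0 retains everything. The AU test is intentionally out of
scope (multiscale bootstrap complexity disproportionate to its filtering
role here).

## Reconciliation pipeline

`lca_reconcile` implements the standard LCA mapping with unit-cost
duplications and losses; loss counting per gene edge subtracts one step
below a speciation parent. The exhaustive-mapping oracle in the test suite
confirms that this equals the minimum over all ancestry-respecting mappings.
Losses can be grafted as `LOST_<branch>` pseudo-leaves at the species
position where the lineage disappeared.

Branches under each support threshold (default sweep 20–90 in steps of 10)
are contracted; every branch of the resulting unrooted tree is tried as a
root (rooting *at a node* is subsumed by rooting on an incident branch);
every polytomy is refined to binary at minimum duplication+loss cost by the
cost-vector dynamic program: `C[s][k]` is the minimal cost of presenting `k`
lineages at species node `s`, with speciation pairing, loss pass-through,
and duplication/loss count adjustment as transitions. The DP is exact (the
test suite checks it against exhaustive refinement enumeration up to degree
6); when more co-optimal refinements exist than requested, construction
tie-breaks by NJ-style joins on the family distance matrix, so output is
deterministic given the matrix. Candidates are deduplicated by rooted
topology with multiplicity retained, so replicate frequencies weight
distinct outcomes by how often the sweep produced them.

Selection keeps SH survivors (α = 0.05 by default; the combination rule —
SH first, then minimal cost among survivors — is a documented package choice)
with minimal reconciliation cost. The final tree is the retained candidate
closest in Robinson–Foulds distance to the greedy extended majority-rule
consensus of the retained set (ties: higher likelihood). Per-node event
support is the fraction of all candidate replicates (with multiplicity)
containing the same clade with the same event label; clade bootstrap values
are recomputed on the final topology when an alignment is supplied.

## DCJ track

Genomes are single-copy signed gene orders (GRIMM conventions: `$` linear,
`@` circular). The adjacency graph is walked directly over extremities;
`d = N − (C + I/2)`. Sorting is the greedy adjacency-repair algorithm (form
each target adjacency with one cut-and-join, then split extra adjacencies at
target telomeres); every step reduces the distance by exactly one, which the
tests assert per prefix. The exact median enumerates adjacency-set matchings
with early termination at the pairwise lower bound and is capped at 6 genes
(the test suite verifies it against a full scan of the genome space);
beyond the cap, a first-improvement hill-climb from each input genome is
used — on the 30-gene/2-ops benchmark it recovers the true ancestor at DCJ
distance 0 in ≈98% of runs, which is the regression baseline. Requesting
the exact mode above the cap raises a capability error (CLI exit code 2).

Ks uses NG86 pathway counting (sites averaged across the two sequences,
differences averaged over stop-free mutational pathways) with the
Jukes–Cantor correction; `pS ≥ 3/4` is reported as saturated/undefined.
Ortholog/out-paralog classification takes explicit Ks and similarity cuts:
no published defaults exist for these thresholds, so they must be supplied
(pairs with undefined Ks are always out-paralogs, and the benchmarks verify
clean separation of a bimodal synthetic Ks mixture).

## Pipelines, determinism and problem sizes

All stage seeds derive arithmetically from the single configured seed; no
stage reads the clock or global RNG state, and manifests record seeds and
per-stage counts, so re-running a config is bit-identical (asserted by
digest comparison in the tests). Default benchmark sizes — families of ~6–12
genes with 200–500-residue alignments, 100 bootstrap replicates, 100-instance
oracle batches, 20 median triples on 5 genes, 30-gene genomes — were chosen
as the smallest sizes at which every oracle comparison is still exhaustive
and recovery rates are stable across seeds.

## Known limitations

* Duplication and loss costs are unit-weighted; no transfer (DTL) events,
  no probabilistic reconciliation, no NNI/SPR search.
* The likelihood engine ranks candidate topologies; it does not optimize
  branch lengths or model parameters by maximum likelihood.
* The exact DCJ median is exponential and capped at 6 genes; the heuristic
  carries no optimality guarantee beyond the pairwise lower bound.
* Gene orders must be single-copy; tandem arrays and unassigned paralogs
  must be collapsed or dropped upstream.
* The uniform-exchangeability default substitution model is adequate for
  simulation-consistent inference but is not a fitted empirical model for
  real proteins; plug in an empirical matrix for real data.
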