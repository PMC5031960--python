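"""End-to-end orchestration of the two analysis tracks.

``run_family_pipeline`` drives simulate -> screen -> build -> reconcile for a
batch of synthetic gene families and writes per-family NHX trees, a family
report TSV and a JSON manifest.  ``run_rearrange_pipeline`` drives the
genome-structure track: simulated (or user-supplied) gene orders, pairwise
DCJ distance matrix, optional median ancestor with per-branch operation
counts.  Both are deterministic functions of their configuration: re-running
with the same config produces bit-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .homology import dedup_isoforms, screen_homologs
from .rearrange import dcj_distance, infer_ancestor, read_grimm, write_grimm
from .reconcile import (
    DEFAULT_THRESHOLDS,
    family_report,
    final_tree_and_support,
    generate_candidates,
    select_best,
)
from .simulate import (
    evolve_sequences,
    random_genome,
    simulate_gene_family,
    simulate_genome_evolution,
)
from .treebuild import bootstrap_supports
from .trees import parse_tree, species_tree, to_nhx

__all__ = ["PipelineConfig", "run_family_pipeline", "run_rearrange_pipeline"]


@dataclass
class PipelineConfig:
    """Flat configuration for both pipelines; ``seed`` is mandatory."""

    seed: int
    species_newick: str | None = None  # None = built-in six-taxon tree
    # family track
    n_families: int = 4
    birth_rate: float = 0.25
    death_rate: float = 0.1
    root_copies: int = 1
    seq_length: int = 300
    min_identity: float = 35.0
    min_coverage: float = 0.5
    bootstrap_reps: int = 100
    thresholds: tuple = DEFAULT_THRESHOLDS
    alpha: float = 0.05
    n_rell: int = 1000
    max_solutions: int = 16
    # rearrangement track
    n_genes: int = 30
    ops_per_branch: int = 2
    median_mode: str = "heuristic"
    grimm_path: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "seed" not in raw:
            raise ValueError("config must set a seed (stochastic stages)")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "thresholds" in raw:
            raw["thresholds"] = tuple(raw["thresholds"])
        return cls(**raw)

    def species(self):
        return species_tree(self.species_newick)


def _write(path: Path, text: str) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(text)


def _fasta(seqs: dict[str, str]) -> str:
    return "".join(f">{k}\n{seqs[k]}\n" for k in sorted(seqs))


def run_family_pipeline(config: PipelineConfig, outdir) -> dict:
    """Simulate families, screen, build, reconcile; write a report bundle.

    Per family: FASTA of surviving sequences, true and inferred NHX trees,
    plus a family-report TSV and manifest.  Families whose screen retains
    fewer than three sequences are reported but skipped for tree building.
    Returns the manifest dict.
    """
    outdir = Path(outdir)
    st = config.species()
    taxa = sorted(l.taxon.label for l in st.leaf_node_iter())
    manifest = {
        "tool": "evorec",
        "version": __version__,
        "seed": config.seed,
        "stage_counts": {},
        "families": {},
    }
    finals = {}
    truth = {}
    for i in range(config.n_families):
        fam_name = f"fam{i + 1:03d}"
        fam_seed = config.seed + 1000 * (i + 1)
        fam = simulate_gene_family(
            st,
            config.birth_rate,
            config.death_rate,
            root_copies=config.root_copies,
            seed=fam_seed,
        )
        info = {"seed": fam_seed, "empty": fam.empty}
        if fam.empty:
            manifest["families"][fam_name] = info
            continue
        seqs = evolve_sequences(
            fam.gene_tree_true, config.seq_length, seed=fam_seed + 1
        )
        info["n_genes"] = len(seqs)
        info["true_dup"] = fam.true_dup_count
        info["true_loss"] = fam.true_loss_count
        truth[fam_name] = (fam.true_dup_count, fam.true_loss_count)
        _write(outdir / f"{fam_name}.faa", _fasta(seqs))
        _write(outdir / f"{fam_name}.true.nhx", to_nhx(fam.gene_tree_true) + "\n")
        # homolog screen against the family's first gene as query
        query_id = sorted(seqs)[0]
        hits = screen_homologs(
            seqs[query_id],
            seqs,
            min_identity=config.min_identity,
            min_coverage=config.min_coverage,
            query_id=query_id,
        )
        hits = dedup_isoforms(hits, fam.locus_map)
        kept = {h.subject_id: seqs[h.subject_id] for h in hits}
        info["n_screened"] = len(kept)
        if len(kept) < 3:
            info["skipped"] = "fewer than 3 sequences after screening"
            manifest["families"][fam_name] = info
            continue
        boot = bootstrap_supports(kept, n_reps=config.bootstrap_reps,
                                  seed=fam_seed + 2)
        cands = generate_candidates(
            boot, st, kept,
            thresholds=config.thresholds,
            max_solutions=config.max_solutions,
        )
        best = select_best(cands, alpha=config.alpha, n_rell=config.n_rell,
                           seed=fam_seed + 3)
        tree, rec = final_tree_and_support(
            best, cands, alignment=kept, n_boot=config.bootstrap_reps,
            seed=fam_seed + 4
        )
        info["n_candidates"] = len(cands)
        info["n_best"] = len(best)
        info["inferred_dup"] = rec.dup_count
        info["inferred_loss"] = rec.loss_count
        _write(outdir / f"{fam_name}.final.nhx", to_nhx(tree) + "\n")
        finals[fam_name] = (tree, rec)
        manifest["families"][fam_name] = info
    report = family_report(finals, taxa)
    _write(outdir / "family_report.tsv", report.to_csv(sep="\t", index=False))
    manifest["stage_counts"] = {
        "families_simulated": config.n_families,
        "families_reconciled": len(finals),
        "total_inferred_dup": int(sum(r.dup_count for _, r in finals.values())),
        "total_inferred_loss": int(sum(r.loss_count for _, r in finals.values())),
        "total_true_dup": int(sum(d for d, _ in truth.values())),
        "total_true_loss": int(sum(l for _, l in truth.values())),
    }
    _write(outdir / "manifest.json", json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def run_rearrange_pipeline(config: PipelineConfig, outdir) -> dict:
    """Genome-structure track: distances, median ancestor, branch counts.

    With ``grimm_path`` set, genomes are read from that file; otherwise a
    random ancestor of ``n_genes`` genes is evolved along a three-leaf star
    by ``ops_per_branch`` random DCJ operations per branch.  Writes the
    pairwise distance TSV, the genomes (and inferred ancestor) in GRIMM
    format, and a manifest; returns the manifest.
    """
    outdir = Path(outdir)
    rng = np.random.default_rng(config.seed)
    manifest = {"tool": "evorec", "version": __version__, "seed": config.seed}
    if config.grimm_path:
        genomes = {g.name: g for g in read_grimm(Path(config.grimm_path).read_text())}
        truth_ops = None
    else:
        ancestor = random_genome("ancestor", config.n_genes, rng)
        star = parse_tree("(gA:1,gB:1,gC:1);")
        star.is_rooted = True
        sim = simulate_genome_evolution(
            ancestor, star, config.ops_per_branch, seed=config.seed + 7
        )
        genomes = sim.leaves
        truth_ops = {k: len(v) for k, v in sim.ops_applied.items()}
        _write(outdir / "true_ancestor.grimm", write_grimm([ancestor]))
    if len(genomes) < 2:
        raise ValueError("rearrangement pipeline needs >= 2 genomes")
    names = sorted(genomes)
    _write(outdir / "genomes.grimm", write_grimm([genomes[n] for n in names]))
    lines = ["genome_a\tgenome_b\tdcj_distance"]
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            lines.append(f"{a}\t{b}\t{dcj_distance(genomes[a], genomes[b])}")
    _write(outdir / "distances.tsv", "\n".join(lines) + "\n")
    manifest["n_genomes"] = len(names)
    manifest["true_ops_per_branch"] = truth_ops
    if len(names) == 3:
        ancestor_hat, counts = infer_ancestor(genomes, mode=config.median_mode)
        _write(outdir / "ancestor.grimm", write_grimm([ancestor_hat]))
        count_lines = ["branch\toperations"]
        count_lines += [f"{n}\t{counts[n]}" for n in names]
        _write(outdir / "branch_counts.tsv", "\n".join(count_lines) + "\n")
        manifest["branch_counts"] = counts
        manifest["median_score"] = int(sum(counts.values()))
    _write(outdir / "manifest.json", json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
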