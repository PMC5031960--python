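"""Homolog screening by exact local alignment.

Reproduces a BLAST-style homolog screen at desk scale with exact
Smith-Waterman affine-gap alignment instead of the seeded heuristic: the
operative filters are percent identity (default >= 35, computed over aligned
columns with gaps in the denominator) and query coverage (default >= 0.5 of
the query length).  Subject sequence extending beyond the aligned span is
trimmed.  Scoring defaults to BLOSUM62 with NCBI-style affine gaps (a gap of
length L costs ``gap_open + L * gap_extend``; default 11/1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices

__all__ = ["HomologHit", "local_align", "screen_homologs", "dedup_isoforms"]


@dataclass
class HomologHit:
    query_id: str
    subject_id: str
    percent_identity: float  # identical / aligned columns, gaps included, in %
    query_coverage: float  # aligned query span / query length
    alignment: tuple[str, str]  # gapped (query, subject) strings, local span
    score: float
    trimmed_subject: str  # subject subsequence within the aligned span


@lru_cache(maxsize=None)
def _aligner(matrix: str, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    m = substitution_matrices.load(matrix)
    m = m.copy()
    if "X" in m.alphabet:  # unknown residue tolerated, scored 0
        i = m.alphabet.index("X")
        m[i, :] = 0.0
        m[:, i] = 0.0
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = m
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def local_align(
    a: str,
    b: str,
    matrix: str = "BLOSUM62",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
    query_id: str = "query",
    subject_id: str = "subject",
) -> HomologHit:
    """Optimal local alignment of query ``a`` against subject ``b``.

    Ties between co-optimal alignments are broken deterministically by taking
    the first alignment in Biopython's enumeration order (leftmost-upper
    path).  A best score of 0 yields an empty alignment with identity 0.
    """
    if not a or not b:
        raise ValueError("sequences must be nonempty")
    aligner = _aligner(matrix, gap_open, gap_extend)
    alignments = aligner.align(a.upper(), b.upper())
    if alignments.score <= 0:
        return HomologHit(query_id, subject_id, 0.0, 0.0, ("", ""), 0.0, "")
    aln = alignments[0]
    ga, gb = str(aln[0]), str(aln[1])
    columns = len(ga)
    identical = sum(1 for x, y in zip(ga, gb) if x == y and x != "-")
    qa_start, qa_end = int(aln.coordinates[0][0]), int(aln.coordinates[0][-1])
    sb_start, sb_end = int(aln.coordinates[1][0]), int(aln.coordinates[1][-1])
    return HomologHit(
        query_id=query_id,
        subject_id=subject_id,
        percent_identity=100.0 * identical / columns if columns else 0.0,
        query_coverage=(qa_end - qa_start) / len(a),
        alignment=(ga, gb),
        score=float(aln.score),
        trimmed_subject=b[sb_start:sb_end],
    )


def screen_homologs(
    query: str,
    db: dict[str, str],
    min_identity: float = 35.0,
    min_coverage: float = 0.5,
    matrix: str = "BLOSUM62",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
    query_id: str = "query",
) -> list[HomologHit]:
    """Hits passing both identity and coverage thresholds, trimmed to the
    aligned span, sorted by descending score (ties by subject id)."""
    if not 0 <= min_coverage <= 1:
        raise ValueError("min_coverage must be in [0, 1]")
    hits = []
    for subject_id in sorted(db):
        hit = local_align(
            query,
            db[subject_id],
            matrix=matrix,
            gap_open=gap_open,
            gap_extend=gap_extend,
            query_id=query_id,
            subject_id=subject_id,
        )
        if hit.percent_identity >= min_identity and hit.query_coverage >= min_coverage:
            hits.append(hit)
    hits.sort(key=lambda h: (-h.score, h.subject_id))
    return hits


def dedup_isoforms(hits, locus_map) -> list[HomologHit]:
    """Retain a single isoform per genetic locus.

    ``locus_map`` maps gene id -> (species, locus_id, isoform_id).  Within a
    locus the highest-scoring hit wins; ties go to the longer trimmed subject,
    then the lexicographically smallest id.  Subjects missing from the map are
    treated as their own singleton locus with a warning.
    """
    best: dict[tuple, HomologHit] = {}
    for hit in hits:
        if hit.subject_id in locus_map:
            species, locus, _ = locus_map[hit.subject_id]
            key = (species, locus)
        else:
            warnings.warn(
                f"subject {hit.subject_id!r} absent from locus map; "
                "treated as its own locus"
            )
            key = ("?", hit.subject_id)
        cur = best.get(key)
        if cur is None or (
            (-hit.score, -len(hit.trimmed_subject), hit.subject_id)
            < (-cur.score, -len(cur.trimmed_subject), cur.subject_id)
        ):
            best[key] = hit
    keep = {id(h) for h in best.values()}
    return [h for h in hits if id(h) in keep]
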