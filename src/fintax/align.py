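"""Pairwise DNA alignment primitives.

Two engines back the package:

* an affine-gap dynamic-programming aligner (Biopython ``PairwiseAligner``)
  with megablast-like scores — match +2, mismatch −3, gap open −5,
  gap extend −2 (the opening column scores −5, each further column −2) —
  used by the similarity-search engine and the chunk-homolog scan;
* a unit-cost global edit alignment (edlib) used where only an identity
  percentage against a threshold is needed (greedy 97% clustering,
  cluster consensus), because it is orders of magnitude faster.

Identity is defined everywhere as matching columns / alignment columns,
with gap columns counted; terminal free gaps of a semi-global alignment
are not alignment columns.  ``N`` matches nothing (scores as a mismatch,
including against another ``N``).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import edlib
from Bio import Align
from Bio.Align import substitution_matrices

from .records import DNA_ALPHABET

MATCH_SCORE = 2.0
MISMATCH_SCORE = -3.0
GAP_OPEN_SCORE = -5.0
GAP_EXTEND_SCORE = -2.0

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

MODES = ("local", "semi-global", "global")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _check_dna(seq: str, label: str) -> str:
    if not seq:
        raise ValueError(f"{label} sequence must be non-empty")
    seq = seq.upper()
    bad = set(seq) - DNA_ALPHABET
    if bad:
        raise ValueError(f"{label} sequence has characters outside ACGTN: {sorted(bad)}")
    return seq


def _substitution_matrix() -> substitution_matrices.Array:
    m = substitution_matrices.Array("ACGTN", dims=2)
    for a in "ACGTN":
        for b in "ACGTN":
            m[a, b] = MATCH_SCORE if (a == b and a != "N") else MISMATCH_SCORE
    return m


@lru_cache(maxsize=None)
def _aligner(mode: str) -> Align.PairwiseAligner:
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    al = Align.PairwiseAligner()
    al.substitution_matrix = _substitution_matrix()
    al.open_gap_score = GAP_OPEN_SCORE
    al.extend_gap_score = GAP_EXTEND_SCORE
    if mode == "local":
        al.mode = "local"
    else:
        al.mode = "global"
        if mode == "semi-global":
            # Subject overhangs (gap columns in the query row at either end)
            # are free: the query aligns end-to-end into a subject infix.
            al.open_left_deletion_score = 0.0
            al.extend_left_deletion_score = 0.0
            al.open_right_deletion_score = 0.0
            al.extend_right_deletion_score = 0.0
    return al


@dataclass(frozen=True)
class AlignmentResult:
    """Outcome of one pairwise alignment (plus-strand coordinates)."""

    identity: float  # percent, matching columns / alignment columns
    coverage: float  # percent of the query inside the aligned interval
    score: float
    subject_start: int  # 0-based half-open on the subject
    subject_end: int
    query_start: int
    query_end: int
    mismatches: int
    gap_opens: int
    gaps: int
    columns: int


def pairwise_alignment(query: str, subject: str, mode: str = "local") -> AlignmentResult:
    """Optimal affine-gap alignment of *query* against *subject*.

    ``local``: Smith–Waterman, one best interval per subject (the
    single-HSP analogue).  ``semi-global``: the query is aligned
    end-to-end into a subject infix.  ``global``: both end-to-end.
    """
    query = _check_dna(query, "query")
    subject = _check_dna(subject, "subject")
    aln = _aligner(mode).align(subject, query)[0]
    c = aln.counts()
    internal_gaps = (
        c.open_internal_insertions
        + c.extend_internal_insertions
        + c.open_internal_deletions
        + c.extend_internal_deletions
    )
    gap_opens = c.open_internal_insertions + c.open_internal_deletions
    if mode == "global":
        terminal_gaps = c.gaps - internal_gaps
        terminal_opens = (
            c.open_left_insertions
            + c.open_left_deletions
            + c.open_right_insertions
            + c.open_right_deletions
        )
        gaps = internal_gaps + terminal_gaps
        gap_opens += terminal_opens
    else:
        # Local alignments have no terminal gaps; semi-global terminal
        # subject overhangs are free and not alignment columns.
        gaps = internal_gaps
    columns = c.identities + c.mismatches + gaps
    blocks = aln.aligned[0]  # subject blocks, excluding all gap columns
    if len(blocks):
        subject_start, subject_end = int(blocks[0][0]), int(blocks[-1][-1])
        qblocks = aln.aligned[1]
        query_start, query_end = int(qblocks[0][0]), int(qblocks[-1][-1])
    else:  # empty alignment (possible in local mode)
        subject_start = subject_end = query_start = query_end = 0
    if mode != "local":
        query_start, query_end = 0, len(query)
        if mode == "global":
            subject_start, subject_end = 0, len(subject)
    identity = 100.0 * c.identities / columns if columns else 0.0
    coverage = 100.0 * (query_end - query_start) / len(query)
    return AlignmentResult(
        identity=identity,
        coverage=coverage,
        score=float(aln.score),
        subject_start=subject_start,
        subject_end=subject_end,
        query_start=query_start,
        query_end=query_end,
        mismatches=int(c.mismatches),
        gap_opens=int(gap_opens),
        gaps=int(gaps),
        columns=int(columns),
    )


def _cigar_columns(cigar: str) -> int:
    total = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            total += int(num)
            num = ""
    return total


def global_identity(a: str, b: str) -> float:
    """Percent identity of the optimal unit-cost global alignment of a and b."""
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    res = edlib.align(a, b, mode="NW", task="path")
    columns = _cigar_columns(res["cigar"])
    return 100.0 * (columns - res["editDistance"]) / columns


def edit_distance(a: str, b: str, k: int | None = None) -> int:
    """Global edit distance; returns k+1 if the distance exceeds *k*."""
    res = edlib.align(a, b, mode="NW", task="distance", k=-1 if k is None else k)
    d = res["editDistance"]
    return (k + 1) if (k is not None and d == -1) else d


def global_alignment_cigar(query: str, target: str) -> tuple[int, str]:
    """Edit distance and CIGAR of the unit-cost global alignment (query vs target)."""
    res = edlib.align(query, target, mode="NW", task="path")
    return res["editDistance"], res["cigar"]
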