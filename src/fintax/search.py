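"""BLAST-like similarity search over reference and background sequences.

The engine mirrors the search strategy of a megablast/blastn workflow at
desk scale: best local hit per subject, a query-coverage gate at 80%,
at most *max_targets* hits ordered by score, recursive widening of
*max_targets* while the top-score stratum is still saturated at high
identity, and a sensitive-mode rerun (shorter seed) when the fast pass
finds nothing.  An adapter for an external BLASTN binary can implement
the same contract; everything in this package runs on the internal pure
engine so no external binary is required.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from .align import pairwise_alignment, reverse_complement

COVERAGE_MIN = 80.0
FAST_WORD_SIZE = 28
SENSITIVE_WORD_SIZE = 11
INITIAL_MAX_TARGETS = 10
MAX_TARGETS_STEP = 50
SCORE_DECIMALS = 1


class HitTableParseError(ValueError):
    """Raised when a BLAST-tabular row cannot be parsed."""


@dataclass(frozen=True)
class SimilarityHit:
    """One query-vs-subject local alignment result.

    Subject coordinates are 0-based half-open on the plus strand;
    ``strand`` records the orientation of the query match.
    """

    query_id: str
    subject_id: str
    identity: float
    query_coverage: float
    score: float
    subject_start: int
    subject_end: int
    query_start: int = 0
    query_end: int = 0
    mismatches: int = 0
    gap_opens: int = 0
    length: int = 0
    strand: str = "+"
    subject_is_fish: bool = False
    evalue: float = 0.0  # parsed from external tables, unused internally

    def __post_init__(self) -> None:
        if self.subject_start >= self.subject_end:
            raise ValueError("subject_start must be < subject_end")
        if self.identity >= 100.0 and (self.mismatches or self.gap_opens):
            raise ValueError("identity 100 implies no mismatches and no gap opens")

    @property
    def rounded_score(self) -> float:
        return round(self.score, SCORE_DECIMALS)


@dataclass(frozen=True)
class DbEntry:
    entry_id: str
    sequence: str
    is_fish: bool = True
    species: str = ""


class SequenceDatabase:
    """An in-memory searchable set of reference/background sequences."""

    def __init__(self, entries: Iterable[DbEntry]):
        self.entries: list[DbEntry] = list(entries)
        ids = [e.entry_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate entry ids in database")
        self._by_id = {e.entry_id: e for e in self.entries}
        self._kmer_cache: dict[int, list[set[str]]] = {}

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, entry_id: str) -> bool:
        return entry_id in self._by_id

    def __getitem__(self, entry_id: str) -> DbEntry:
        return self._by_id[entry_id]

    def species_of(self, entry_id: str) -> str:
        return self._by_id[entry_id].species

    def _kmer_sets(self, k: int) -> list[set[str]]:
        if k not in self._kmer_cache:
            self._kmer_cache[k] = [
                {e.sequence[i : i + k] for i in range(len(e.sequence) - k + 1)}
                for e in self.entries
            ]
        return self._kmer_cache[k]


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def search_topk(
    query: str,
    db: SequenceDatabase,
    max_targets: int = INITIAL_MAX_TARGETS,
    query_id: str = "query",
    word_size: int | None = None,
    min_coverage: float = COVERAGE_MIN,
) -> list[SimilarityHit]:
    """Best local hit per subject, coverage-gated, top *max_targets* by score.

    Both query strands are searched; each subject contributes its single
    best interval.  With *word_size* set, subjects sharing no exact
    word-size-mer with either query strand are skipped (the seeded
    fast/sensitive modes); without it the scan is exhaustive.
    """
    if max_targets < 1:
        raise ValueError("max_targets must be >= 1")
    query = query.upper()
    rc = reverse_complement(query)
    seeds = None
    if word_size is not None:
        seeds = (_kmers(query, word_size), _kmers(rc, word_size))
        subject_kmers = db._kmer_sets(word_size)
    hits: list[SimilarityHit] = []
    for idx, entry in enumerate(db.entries):
        if seeds is not None:
            km = subject_kmers[idx]
            if km.isdisjoint(seeds[0]) and km.isdisjoint(seeds[1]):
                continue
        best = None
        best_strand = "+"
        for strand, q in (("+", query), ("-", rc)):
            res = pairwise_alignment(q, entry.sequence, mode="local")
            if best is None or res.score > best.score:
                best, best_strand = res, strand
        if best is None or best.score <= 0:
            continue
        coverage = round(best.coverage, 3)
        if coverage < min_coverage:
            continue
        hits.append(
            SimilarityHit(
                query_id=query_id,
                subject_id=entry.entry_id,
                identity=round(best.identity, 3),
                query_coverage=coverage,
                score=best.score,
                subject_start=best.subject_start,
                subject_end=best.subject_end,
                query_start=best.query_start,
                query_end=best.query_end,
                mismatches=best.mismatches,
                gap_opens=best.gap_opens,
                length=best.columns,
                strand=best_strand,
                subject_is_fish=entry.is_fish,
            )
        )
    hits.sort(key=lambda h: (-h.rounded_score, h.subject_id))
    return hits[:max_targets]


def top_score_stratum(hits: Sequence[SimilarityHit]) -> list[SimilarityHit]:
    """All hits sharing the maximum (rounded) score."""
    if not hits:
        return []
    top = max(h.rounded_score for h in hits)
    return [h for h in hits if h.rounded_score == top]


def recursive_top_hits(
    query: str,
    db: SequenceDatabase,
    species_threshold: float = 99.0,
    query_id: str = "query",
    word_size: int | None = None,
) -> tuple[list[SimilarityHit], bool]:
    """Top-score stratum with recursive widening of ``max_target_seqs``.

    Starting at 10 targets: while the returned list is full, every score
    equals the maximum and every identity is >= *species_threshold*, the
    search is repeated with the target count increased by 50, until a
    lower-score hit appears or the database is exhausted.  Returns the
    maximum-score hits and a flag that is True unless the database ran
    out while the scores were still uniform.
    """
    k = INITIAL_MAX_TARGETS
    while True:
        hits = search_topk(query, db, max_targets=k, query_id=query_id, word_size=word_size)
        if not hits:
            return [], True
        stratum = top_score_stratum(hits)
        if len(stratum) < len(hits):
            return stratum, True  # a lower-score hit bounds the stratum
        if len(hits) < k:
            # database exhausted while all scores were still uniform
            return stratum, False
        if any(h.identity < species_threshold for h in stratum):
            return stratum, True
        if k >= len(db):
            return stratum, False
        k += MAX_TARGETS_STEP


def search_with_fallback(
    query: str,
    db: SequenceDatabase,
    species_threshold: float = 99.0,
    query_id: str = "query",
) -> tuple[list[SimilarityHit], bool]:
    """Seeded fast search, rerun in sensitive mode when nothing is found.

    The fast pass requires an exact shared 28-mer (megablast analogue);
    the sensitive rerun requires an 11-mer (blastn analogue).  Returns
    the possibly-empty top-score stratum only after both modes.
    """
    hits, saturated = recursive_top_hits(
        query, db, species_threshold, query_id=query_id, word_size=FAST_WORD_SIZE
    )
    if hits:
        return hits, saturated
    return recursive_top_hits(
        query, db, species_threshold, query_id=query_id, word_size=SENSITIVE_WORD_SIZE
    )


# --- BLAST tabular interchange (outfmt "6 std qcovhsp") -------------------

_STD_COLUMNS = 12


def parse_hit_table(path, fish_ids: set[str] | frozenset[str] = frozenset()) -> list[SimilarityHit]:
    """Read a 12-column BLAST tabular file (optional 13th qcovhsp column).

    1-based inclusive subject coordinates are converted to 0-based
    half-open; reversed subject coordinates mark a minus-strand hit.
    """
    hits: list[SimilarityHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < _STD_COLUMNS:
                raise HitTableParseError(
                    f"line {lineno}: expected >= {_STD_COLUMNS} columns, got {len(fields)}"
                )
            try:
                (qseqid, sseqid, pident, length, mismatch, gapopen,
                 qstart, qend, sstart, send, evalue, bitscore) = fields[:_STD_COLUMNS]
                identity = float(pident)
                length_i = int(length)
                mismatch_i = int(mismatch)
                gapopen_i = int(gapopen)
                qstart_i, qend_i = int(qstart), int(qend)
                sstart_i, send_i = int(sstart), int(send)
                evalue_f = float(evalue)
                score = float(bitscore)
                qcov = float(fields[_STD_COLUMNS]) if len(fields) > _STD_COLUMNS else 100.0
            except ValueError as exc:
                raise HitTableParseError(f"line {lineno}: {exc}") from exc
            if sstart_i <= send_i:
                strand, s0, s1 = "+", sstart_i - 1, send_i
            else:
                strand, s0, s1 = "-", send_i - 1, sstart_i
            hits.append(
                SimilarityHit(
                    query_id=qseqid,
                    subject_id=sseqid,
                    identity=identity,
                    query_coverage=qcov,
                    score=score,
                    subject_start=s0,
                    subject_end=s1,
                    query_start=qstart_i - 1,
                    query_end=qend_i,
                    mismatches=mismatch_i,
                    gap_opens=gapopen_i,
                    length=length_i,
                    strand=strand,
                    subject_is_fish=sseqid in fish_ids,
                    evalue=evalue_f,
                )
            )
    return hits


def write_hit_table(hits: Sequence[SimilarityHit], path) -> None:
    """Write hits as BLAST tabular (outfmt "6 std qcovhsp")."""
    with open(path, "w") as fh:
        for h in hits:
            if h.strand == "+":
                sstart, send = h.subject_start + 1, h.subject_end
            else:
                sstart, send = h.subject_end, h.subject_start + 1
            fh.write(
                "\t".join(
                    [
                        h.query_id,
                        h.subject_id,
                        f"{h.identity:.3f}",
                        str(h.length),
                        str(h.mismatches),
                        str(h.gap_opens),
                        str(h.query_start + 1),
                        str(h.query_end),
                        str(sstart),
                        str(send),
                        f"{h.evalue:.2g}",
                        f"{h.rounded_score:.1f}",
                        f"{h.query_coverage:.3f}",
                    ]
                )
                + "\n"
            )


def resolve_fish_flags(hits: Sequence[SimilarityHit], db: SequenceDatabase) -> list[SimilarityHit]:
    """Set ``subject_is_fish`` on parsed hits from a database's entries."""
    out = []
    for h in hits:
        if h.subject_id not in db:
            raise KeyError(f"hit references unknown subject {h.subject_id!r}")
        out.append(replace(h, subject_is_fish=db[h.subject_id].is_fish))
    return out
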