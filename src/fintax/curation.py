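"""Taxonomy validation of reference-sequence regions and the background database.

Public reference sequences can be chimeric: part of a deposited sequence
may originate from a different species than its label.  What matters for
metabarcoding is whether such heterospecific segments overlap the marker
region, so validation runs on 100-bp chunks rather than whole sequences.
For each chunk, homologs elsewhere in the database with >99% identity are
collected; a chunk corroborated by the same species from independent
authors is homospecific, a chunk matched only by several other species
from independent authors is flagged heterospecific, and anything else
stays unknown.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

from .align import global_identity, pairwise_alignment, reverse_complement
from .records import (
    ChunkStatus,
    GeneChunk,
    ReferenceRecord,
    authors_disjoint,
    normalize_author,
    split_gene_into_chunks,
)

HOMOLOG_IDENTITY_MIN = 99.0  # strict: identity must exceed this
HOMOLOG_COVERAGE_MIN = 80.0
BACKGROUND_CLUSTER_IDENTITY = 97.0


@dataclass(frozen=True)
class ChunkHomolog:
    species: str
    authors: frozenset[str]
    identity: float


def _best_local_identity(chunk_seq: str, subject: str) -> tuple[float, float]:
    """(identity, coverage) of the best local hit of the chunk on either strand."""
    best = pairwise_alignment(chunk_seq, subject, mode="local")
    rc = pairwise_alignment(reverse_complement(chunk_seq), subject, mode="local")
    if rc.score > best.score:
        best = rc
    return best.identity, best.coverage


def collect_chunk_homologs(
    record: ReferenceRecord,
    chunk: GeneChunk,
    db: Sequence[ReferenceRecord],
    search: Callable[[str, str], tuple[float, float]] | None = None,
) -> list[ChunkHomolog]:
    """Database records matching a chunk at >99% identity and >=80% coverage.

    *db* must not contain the record itself; records sharing any accession
    with the query record are skipped (they are not independent evidence).
    *search* maps (chunk sequence, subject sequence) to (identity,
    coverage) and defaults to the internal local aligner.
    """
    if search is None:
        search = _best_local_identity
    chunk_seq = record.sequence[chunk.start : chunk.end]
    own_accessions = set(record.accessions)
    homologs: list[ChunkHomolog] = []
    for other in db:
        if other.record_id == record.record_id or own_accessions & set(other.accessions):
            continue
        identity, coverage = search(chunk_seq, other.sequence)
        if identity > HOMOLOG_IDENTITY_MIN and coverage >= HOMOLOG_COVERAGE_MIN:
            homologs.append(ChunkHomolog(other.species, other.authors, identity))
    return homologs


def _author_components(author_sets: Iterable[frozenset[str]]) -> int:
    """Number of connected components of author sets under name overlap."""
    normalized = [frozenset(normalize_author(a) for a in s) for s in author_sets]
    parent = list(range(len(normalized)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(normalized)):
        for j in range(i + 1, len(normalized)):
            if normalized[i] & normalized[j]:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[ri] = rj
    return len({find(i) for i in range(len(normalized))})


def classify_chunk(
    record_species: str,
    record_authors: frozenset[str] | set[str],
    homologs: Sequence[ChunkHomolog],
) -> ChunkStatus:
    """Label a chunk from its >99%-identity homologs.

    homospecific: at least one same-species homolog whose authors are
    disjoint from the record's (independent corroboration).
    heterospecific: no same-species homolog at all, and the independent
    other-species homologs span >=2 distinct species contributed by >=2
    disjoint author groups.  Everything else is unknown.
    """
    same_species = [h for h in homologs if h.species == record_species]
    if any(authors_disjoint(h.authors, record_authors) for h in same_species):
        return ChunkStatus.HOMOSPECIFIC
    if same_species:
        return ChunkStatus.UNKNOWN  # only same-author corroboration
    independent = [
        h
        for h in homologs
        if h.species != record_species and authors_disjoint(h.authors, record_authors)
    ]
    if len({h.species for h in independent}) >= 2:
        if _author_components([h.authors for h in independent]) >= 2:
            return ChunkStatus.HETEROSPECIFIC
    return ChunkStatus.UNKNOWN


def validate_reference_set(
    db: Sequence[ReferenceRecord],
    search: Callable[[str, str], tuple[float, float]] | None = None,
) -> list[ReferenceRecord]:
    """Populate chunk statuses for every record in *db*.

    Each record's sequence is tiled with 100-bp chunks and every chunk is
    classified against the rest of the database.  Classification of each
    chunk is independent of record iteration order.
    """
    validated: list[ReferenceRecord] = []
    for record in db:
        chunks: list[GeneChunk] = []
        for start, end in split_gene_into_chunks(len(record.sequence)):
            chunk = GeneChunk(start, end)
            homologs = collect_chunk_homologs(record, chunk, db, search=search)
            status = classify_chunk(record.species, record.authors, homologs)
            chunks.append(chunk.with_status(status))
        validated.append(
            ReferenceRecord(
                record_id=record.record_id,
                accessions=record.accessions,
                sequence=record.sequence,
                gene=record.gene,
                lineage=record.lineage,
                authors=record.authors,
                is_fish=record.is_fish,
                chunks=chunks,
            )
        )
    return validated


def build_background_db(
    seqs: Sequence[tuple[str, str, str]],
    fish_taxa: set[str] | frozenset[str],
    identity: float = BACKGROUND_CLUSTER_IDENTITY,
) -> list[tuple[str, str, str]]:
    """Greedy centroid clustering of non-fish sequences.

    *seqs* are ``(id, sequence, taxon)`` triples.  Fish-taxon entries are
    removed first; the rest are sorted by decreasing length then id (so
    results do not depend on input order) and clustered greedily: a
    sequence joins the first centroid with global identity >= *identity*
    percent, otherwise it founds a new centroid.  Returns the centroids.
    """
    survivors = [s for s in seqs if s[2] not in fish_taxa]
    survivors.sort(key=lambda s: (-len(s[1]), s[0]))
    centroids: list[tuple[str, str, str]] = []
    for entry in survivors:
        joined = False
        for cid, cseq, _ in centroids:
            if global_identity(entry[1], cseq) >= identity:
                joined = True
                break
        if not joined:
            centroids.append(entry)
    return centroids
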