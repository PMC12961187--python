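"""End-to-end orchestration: reads -> ASVs -> annotation -> result matrix."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .annotate import (
    AnnotationResult,
    SummaryTables,
    Taxonomy,
    annotate_asv,
    summarize_tables,
)
from .asv import ASV, illumina_asvs, nanopore_asvs
from .curation import validate_reference_set
from .matrix import ResultMatrix, SampleRole, build_matrix
from .records import GeneChunk, ReferenceRecord
from .search import DbEntry, SequenceDatabase, search_with_fallback


def reference_database(
    records: Sequence[ReferenceRecord],
    background: Sequence[tuple[str, str, str]] = (),
) -> SequenceDatabase:
    """Searchable database over fish references plus background centroids."""
    entries = [
        DbEntry(r.record_id, r.sequence, is_fish=True, species=r.species) for r in records
    ]
    entries.extend(
        DbEntry(bid, seq, is_fish=False, species=taxon) for bid, seq, taxon in background
    )
    return SequenceDatabase(entries)


def hetero_chunk_map(records: Sequence[ReferenceRecord]) -> dict[str, list[GeneChunk]]:
    return {r.record_id: list(r.chunks) for r in records}


def taxonomy_from_records(records: Sequence[ReferenceRecord]) -> Taxonomy:
    return Taxonomy({r.species: r.lineage for r in records})


@dataclass
class PipelineResult:
    asvs: list[ASV]
    annotations: list[AnnotationResult]
    tables: SummaryTables
    matrix: ResultMatrix


def annotate_asvs(
    asvs: Sequence[ASV],
    db: SequenceDatabase,
    taxonomy: Taxonomy,
    hetero_map: Mapping[str, Sequence[GeneChunk]] | None = None,
    threshold: float = 99.0,
    hetero_filter: bool = True,
) -> list[AnnotationResult]:
    species_map = {e.entry_id: e.species for e in db.entries}
    results = []
    for asv in asvs:
        hits, _ = search_with_fallback(asv.sequence, db, threshold, query_id=asv.asv_id)
        results.append(
            annotate_asv(
                asv,
                hits,
                taxonomy,
                species_map,
                hetero_map=hetero_map,
                threshold=threshold,
                hetero_filter=hetero_filter,
            )
        )
    return results


def run_workflow(
    reads_by_sample: Mapping[str, Sequence[str]],
    manifest: Sequence[SampleRole],
    reference: Sequence[ReferenceRecord],
    background: Sequence[tuple[str, str, str]] = (),
    platform: str = "illumina",
    species_identity: float = 99.0,
    hetero_filter: bool = True,
    validate_reference: bool = False,
    asvs: Sequence[ASV] | None = None,
) -> PipelineResult:
    """Run the full analysis for one multi-sample dataset.

    *reference* records should already carry chunk statuses; pass
    ``validate_reference=True`` to (re)validate here.  Pre-made ASVs (the
    reanalysis path) skip read processing entirely via *asvs*.
    """
    if validate_reference:
        reference = validate_reference_set(reference)
    db = reference_database(reference, background)
    taxonomy = taxonomy_from_records(reference)
    hetero = hetero_chunk_map(reference)

    if asvs is None:
        if platform == "illumina":
            asvs = illumina_asvs(reads_by_sample)
        elif platform == "nanopore":
            asvs = nanopore_asvs(reads_by_sample)
        else:
            raise ValueError("platform must be 'illumina' or 'nanopore'")
    asvs = list(asvs)

    annotations = annotate_asvs(
        asvs, db, taxonomy, hetero_map=hetero,
        threshold=species_identity, hetero_filter=hetero_filter,
    )
    counts = {a.asv_id: a.counts for a in asvs}
    md5s = {a.asv_id: a.md5 for a in asvs}
    tables = summarize_tables(annotations, counts, md5s)
    matrix = build_matrix(tables.species, manifest, members=tables.members)
    return PipelineResult(asvs=asvs, annotations=annotations, tables=tables, matrix=matrix)
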