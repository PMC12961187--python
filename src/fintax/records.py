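"""Domain records of the curated reference database.

A reference record is one mitochondrial gene sequence with its taxonomic
lineage, contributing authors and (after validation) a tiling of 100-bp
chunks, each labelled homospecific / heterospecific / unknown.  This module
also holds the bookkeeping operations that act on plain records: merging
identical sequences, the 100-bp chunking rule, and grid deduplication of
species occurrence coordinates.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

from .genes import is_canonical_gene

logger = logging.getLogger(__name__)

DNA_ALPHABET = frozenset("ACGTN")

CHUNK_SIZE = 100

_NONBINOMIAL_QUALIFIERS = {"sp", "spp", "cf", "aff", "x", "hybrid", "gen"}
_EPITHET_RE = re.compile(r"^[a-z][a-z-]*$")
_GENUS_RE = re.compile(r"^[A-Z][A-Za-z-]*$")


class ChunkStatus(str, Enum):
    HOMOSPECIFIC = "homospecific"
    HETEROSPECIFIC = "heterospecific"
    UNKNOWN = "unknown"


def species_is_binomial(species: str) -> bool:
    """True iff *species* is a plain ``Genus epithet`` binomial.

    Qualifiers such as "sp.", "cf." or "aff." mark a name as not formally
    described and therefore nonbinomial.
    """
    tokens = species.split()
    if len(tokens) != 2:
        return False
    genus, epithet = tokens
    stripped = epithet.rstrip(".").casefold()
    if stripped in _NONBINOMIAL_QUALIFIERS:
        return False
    return bool(_GENUS_RE.match(genus)) and bool(_EPITHET_RE.match(epithet))


@dataclass(frozen=True)
class TaxonLineage:
    """Ranked lineage from (optionally) superclass down to species."""

    species: str
    genus: str = ""
    family: str = ""
    order: str = ""
    higher: str = ""

    def __post_init__(self) -> None:
        if not self.species:
            raise ValueError("species must be non-empty")
        if not self.genus and self.is_binomial:
            object.__setattr__(self, "genus", self.species.split()[0])

    @property
    def is_binomial(self) -> bool:
        return species_is_binomial(self.species)


@dataclass(frozen=True)
class GeneChunk:
    """A 100-bp validation window on a reference sequence (0-based, half-open)."""

    start: int
    end: int
    status: ChunkStatus = ChunkStatus.UNKNOWN

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid chunk interval ({self.start}, {self.end})")

    def with_status(self, status: ChunkStatus) -> "GeneChunk":
        return GeneChunk(self.start, self.end, status)


@dataclass
class ReferenceRecord:
    """One curated mitochondrial gene sequence."""

    record_id: str
    accessions: tuple[str, ...]
    sequence: str
    gene: str
    lineage: TaxonLineage
    authors: frozenset[str] = frozenset()
    is_fish: bool = True
    chunks: list[GeneChunk] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValueError("sequence must be non-empty")
        bad = set(self.sequence) - DNA_ALPHABET
        if bad:
            raise ValueError(f"sequence of {self.record_id} has non-DNA characters {sorted(bad)}")
        self.accessions = tuple(self.accessions)
        if not self.accessions:
            raise ValueError("record needs at least one accession")
        if len(set(self.accessions)) != len(self.accessions):
            raise ValueError("accessions must be unique within a record")
        if not is_canonical_gene(self.gene):
            raise ValueError(f"gene {self.gene!r} is not canonical")
        self.authors = frozenset(self.authors)

    @property
    def species(self) -> str:
        return self.lineage.species

    def heterospecific_chunks(self) -> list[GeneChunk]:
        return [c for c in self.chunks if c.status is ChunkStatus.HETEROSPECIFIC]


def normalize_author(name: str) -> str:
    """Case-fold an author name and strip punctuation around initials."""
    cleaned = re.sub(r"[.,;]", " ", name.casefold())
    return " ".join(cleaned.split())


def authors_disjoint(a: Iterable[str], b: Iterable[str]) -> bool:
    """True when two author-name sets share no (normalized) name."""
    return not ({normalize_author(x) for x in a} & {normalize_author(x) for x in b})


def split_gene_into_chunks(length: int) -> list[tuple[int, int]]:
    """Tile a gene of *length* bp into 100-bp validation chunks.

    Chunks start at multiples of 100; when the final chunk would be shorter
    than 100 bp it is taken as the final 100 bp of the sequence instead
    (so the last two chunks may overlap).  Genes shorter than 100 bp yield
    a single whole-gene chunk.
    """
    if length < 1:
        raise ValueError("length must be positive")
    if length < CHUNK_SIZE:
        return [(0, length)]
    chunks = [(s, s + CHUNK_SIZE) for s in range(0, length - CHUNK_SIZE + 1, CHUNK_SIZE)]
    if length % CHUNK_SIZE != 0:
        chunks.append((length - CHUNK_SIZE, length))
    return chunks


def merge_identical_sequences(records: Sequence[ReferenceRecord]) -> list[ReferenceRecord]:
    """Merge records with identical (sequence, gene, species) triples.

    Accession lists and author sets are unioned; total accession count is
    conserved.  Identical sequences of the same species under *different*
    gene labels stay separate (a warning is logged, since one of the
    annotations is presumably wrong).
    """
    groups: dict[tuple[str, str, str], list[ReferenceRecord]] = {}
    order: list[tuple[str, str, str]] = []
    for rec in records:
        key = (rec.sequence, rec.gene, rec.species)
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(rec)

    seen_genes: dict[tuple[str, str], set[str]] = {}
    for seq, gene, species in order:
        seen_genes.setdefault((seq, species), set()).add(gene)
    for (seq, species), genes in seen_genes.items():
        if len(genes) > 1:
            logger.warning(
                "identical sequence of %s carries conflicting gene labels %s; kept separate",
                species,
                sorted(genes),
            )

    merged: list[ReferenceRecord] = []
    for key in order:
        group = groups[key]
        first = group[0]
        if len(group) == 1:
            merged.append(first)
            continue
        accessions: list[str] = []
        for rec in group:
            for acc in rec.accessions:
                if acc not in accessions:
                    accessions.append(acc)
        authors = frozenset().union(*(rec.authors for rec in group))
        merged.append(
            ReferenceRecord(
                record_id=first.record_id,
                accessions=tuple(accessions),
                sequence=first.sequence,
                gene=first.gene,
                lineage=first.lineage,
                authors=authors,
                is_fish=first.is_fish,
            )
        )
    return merged


@dataclass(frozen=True)
class HabitatProfile:
    """FishBase-style habitat descriptors for one species.

    ``demers_pelag`` is single-valued; salinity and climate zone may carry
    several values per species.
    """

    demers_pelag: str = "unknown"
    salinity: frozenset[str] = frozenset()
    climate_zone: frozenset[str] = frozenset()

    DEMERS_PELAG_VALUES = (
        "Bathydemersal",
        "Bathypelagic",
        "Benthopelagic",
        "Demersal",
        "Pelagic",
        "Pelagic-neritic",
        "Pelagic-oceanic",
        "Reef-associated",
    )
    SALINITY_VALUES = ("Freshwater", "Brackish water", "Saltwater")
    CLIMATE_ZONE_VALUES = (
        "Subtropical",
        "Temperate",
        "Tropical",
        "Boreal",
        "Deep-water",
        "High altitude",
        "Polar",
    )

    def __post_init__(self) -> None:
        if self.demers_pelag != "unknown" and self.demers_pelag not in self.DEMERS_PELAG_VALUES:
            raise ValueError(f"unknown DemersPelag value {self.demers_pelag!r}")
        object.__setattr__(self, "salinity", frozenset(self.salinity))
        object.__setattr__(self, "climate_zone", frozenset(self.climate_zone))

    @property
    def is_unknown(self) -> bool:
        return self.demers_pelag == "unknown" and not self.salinity and not self.climate_zone


UNKNOWN_HABITAT = HabitatProfile()


@dataclass(frozen=True)
class OccurrenceRecord:
    """A georeferenced observation of a species."""

    species: str
    latitude: float
    longitude: float

    @property
    def in_range(self) -> bool:
        return (
            math.isfinite(self.latitude)
            and math.isfinite(self.longitude)
            and -90.0 <= self.latitude <= 90.0
            and -180.0 <= self.longitude <= 180.0
        )


def dedup_occurrences(
    records: Sequence[OccurrenceRecord], tolerance_deg: float = 1.0
) -> list[OccurrenceRecord]:
    """Deduplicate occurrences within each species on a degree grid.

    Within a species, at most one record is kept per
    ``(floor(lat/tol), floor(lon/tol))`` cell (first record wins), i.e.
    coordinates are deduplicated within a tolerance of *tolerance_deg*
    degrees.  Out-of-range coordinates are skipped with a warning.
    """
    if tolerance_deg <= 0:
        raise ValueError("tolerance_deg must be positive")
    seen: set[tuple[str, int, int]] = set()
    kept: list[OccurrenceRecord] = []
    for rec in records:
        if not rec.in_range:
            logger.warning(
                "skipping out-of-range occurrence of %s at (%s, %s)",
                rec.species,
                rec.latitude,
                rec.longitude,
            )
            continue
        cell = (
            rec.species,
            math.floor(rec.latitude / tolerance_deg),
            math.floor(rec.longitude / tolerance_deg),
        )
        if cell in seen:
            continue
        seen.add(cell)
        kept.append(rec)
    return kept
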