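"""Species-level taxonomy assignment of ASVs.

Each ASV's saturated top-score hit stratum is turned into one of five
outcomes:

* ``unassigned`` — no hits in either database;
* ``nonfish`` — the stratum comes from the background (off-target)
  database;
* ``higher_taxon`` — fish hits below the species-identity threshold are
  reported as the lowest common ancestor of the top-hit species;
* ``species`` — a single species survives at or above the threshold;
* ``species_complex`` — several species remain indistinguishable at this
  marker and are reported jointly.

Above the threshold, two filters sharpen ambiguous strata: nonbinomial
species are dropped when a binomial alternative exists, and species whose
every supporting hit falls into heterospecific reference regions are
dropped for lack of trustworthy evidence.  If the filters remove every
candidate, the unfiltered set is reported with a low-confidence flag
rather than discarding the ASV.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Sequence

import pandas as pd

from .asv import ASV, md5_of_sequence  # noqa: F401  (md5 re-exported here)
from .records import ChunkStatus, GeneChunk, TaxonLineage, species_is_binomial
from .search import SimilarityHit

SPECIES_IDENTITY_THRESHOLD = 99.0
HETERO_OVERLAP_FRAC = 0.5

COMPLEX_SEPARATOR = "/"


class Category(str, Enum):
    SPECIES = "species"
    SPECIES_COMPLEX = "species_complex"
    HIGHER_TAXON = "higher_taxon"
    NONFISH = "nonfish"
    UNASSIGNED = "unassigned"


class DataIntegrityError(KeyError):
    """A hit references a subject unknown to the reference index."""


_RANKS = ("genus", "family", "order", "higher")


class Taxonomy:
    """Species -> ranked lineage lookup with LCA queries."""

    def __init__(self, lineages: Mapping[str, TaxonLineage] | Sequence[TaxonLineage]):
        if isinstance(lineages, Mapping):
            self._by_species = dict(lineages)
        else:
            self._by_species = {lin.species: lin for lin in lineages}

    def __contains__(self, species: str) -> bool:
        return species in self._by_species

    def lineage(self, species: str) -> TaxonLineage:
        try:
            return self._by_species[species]
        except KeyError as exc:
            raise KeyError(f"species {species!r} not in taxonomy") from exc

    def species(self) -> list[str]:
        return sorted(self._by_species)

    def is_binomial(self, species: str) -> bool:
        if species in self._by_species:
            return self._by_species[species].is_binomial
        return species_is_binomial(species)

    def ancestors(self, species: str) -> dict[str, str]:
        lin = self.lineage(species)
        return {
            "genus": lin.genus,
            "family": lin.family,
            "order": lin.order,
            "higher": lin.higher,
        }


def lowest_common_ancestor(
    species: Sequence[str], taxonomy: Taxonomy
) -> tuple[str, str]:
    """Deepest rank shared by all *species* among genus/family/order/higher.

    A single species reports its genus.  Unknown species raise KeyError.
    """
    if not species:
        raise ValueError("need at least one species")
    tables = [taxonomy.ancestors(sp) for sp in species]
    for rank in _RANKS:
        names = {t[rank] for t in tables}
        if len(names) == 1 and "" not in names:
            return names.pop(), rank
    return "root", "root"


def overlaps_heterospecific(
    hit: SimilarityHit,
    chunks: Sequence[GeneChunk],
    frac: float = HETERO_OVERLAP_FRAC,
) -> bool:
    """True when >= *frac* of the hit's subject interval is heterospecific.

    Heterospecific chunks may overlap each other (the final-100-bp rule),
    so covered length is measured on their union.
    """
    intervals = sorted(
        (c.start, c.end) for c in chunks if c.status is ChunkStatus.HETEROSPECIFIC
    )
    if not intervals:
        return False
    covered = 0
    cursor = hit.subject_start
    for start, end in intervals:
        lo = max(start, cursor, hit.subject_start)
        hi = min(end, hit.subject_end)
        if hi > lo:
            covered += hi - lo
            cursor = hi
    span = hit.subject_end - hit.subject_start
    return span > 0 and covered >= frac * span


@dataclass(frozen=True)
class AnnotationResult:
    """Outcome of the assignment algorithm for one ASV."""

    asv_id: str
    category: Category
    taxa: tuple[str, ...]
    best_identity: float | None
    evidence: tuple[SimilarityHit, ...]
    notes: tuple[str, ...] = ()
    rank: str = ""  # populated for higher_taxon results

    def __post_init__(self) -> None:
        if self.category is Category.SPECIES and len(self.taxa) != 1:
            raise ValueError("species result carries exactly one taxon")
        if self.category is Category.SPECIES_COMPLEX:
            if len(self.taxa) < 2 or len(set(self.taxa)) != len(self.taxa):
                raise ValueError("complex needs >=2 distinct members")
            if list(self.taxa) != sorted(self.taxa):
                raise ValueError("complex members must be sorted")
        if self.category is Category.UNASSIGNED and self.evidence:
            raise ValueError("unassigned result cannot carry evidence")

    @property
    def label(self) -> str:
        return COMPLEX_SEPARATOR.join(self.taxa) if self.taxa else ""


@dataclass(frozen=True)
class SpeciesComplex:
    """Species indistinguishable at this marker, reported jointly."""

    members: tuple[str, ...]
    asv_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError("complex needs >=2 members")
        object.__setattr__(self, "members", tuple(sorted(self.members)))

    @property
    def label(self) -> str:
        return COMPLEX_SEPARATOR.join(self.members)


def annotate_asv(
    asv: ASV,
    hits: Sequence[SimilarityHit],
    taxonomy: Taxonomy,
    species_map: Mapping[str, str],
    hetero_map: Mapping[str, Sequence[GeneChunk]] | None = None,
    threshold: float = SPECIES_IDENTITY_THRESHOLD,
    hetero_filter: bool = True,
    hetero_overlap_frac: float = HETERO_OVERLAP_FRAC,
) -> AnnotationResult:
    """Assign one ASV from its top-score hit stratum.

    *species_map* maps subject ids to species (fish references) or taxon
    labels (background entries); *hetero_map* maps fish reference ids to
    their validated chunks.  *threshold* is the species-level identity
    threshold in percent (adjustable; default 99).
    """
    if not hits:
        return AnnotationResult(asv.asv_id, Category.UNASSIGNED, (), None, ())

    notes: list[str] = []
    for h in hits:
        if h.subject_id not in species_map:
            raise DataIntegrityError(f"hit references unknown reference id {h.subject_id!r}")

    fish_hits = [h for h in hits if h.subject_is_fish]
    bg_hits = [h for h in hits if not h.subject_is_fish]
    if not fish_hits:
        best = bg_hits[0]
        return AnnotationResult(
            asv.asv_id,
            Category.NONFISH,
            (species_map[best.subject_id],),
            max(h.identity for h in bg_hits),
            tuple(hits),
        )
    if bg_hits:
        notes.append("score-tie-with-nonfish")

    best_identity = max(h.identity for h in fish_hits)
    if best_identity < threshold:
        species = sorted({species_map[h.subject_id] for h in fish_hits})
        name, rank = lowest_common_ancestor(species, taxonomy)
        return AnnotationResult(
            asv.asv_id,
            Category.HIGHER_TAXON,
            (name,),
            best_identity,
            tuple(hits),
            tuple(notes),
            rank=rank,
        )

    support: dict[str, list[SimilarityHit]] = {}
    for h in fish_hits:
        if h.identity >= threshold:
            support.setdefault(species_map[h.subject_id], []).append(h)
    candidates = set(support)

    binomial = {sp for sp in candidates if taxonomy.is_binomial(sp)}
    if binomial and binomial != candidates:
        notes.append("nonbinomial-filtered")
        candidates = binomial

    if hetero_filter and hetero_map is not None:
        surviving = set()
        for sp in candidates:
            sp_hits = support[sp]
            all_hetero = all(
                overlaps_heterospecific(
                    h, hetero_map.get(h.subject_id, ()), frac=hetero_overlap_frac
                )
                for h in sp_hits
            )
            if all_hetero:
                notes.append("heterospecific-filtered")
            else:
                surviving.add(sp)
        candidates = surviving

    if not candidates:
        notes.append("all-filtered-fallback")
        candidates = set(support)

    taxa = tuple(sorted(candidates))
    category = Category.SPECIES if len(taxa) == 1 else Category.SPECIES_COMPLEX
    return AnnotationResult(
        asv.asv_id, category, taxa, best_identity, tuple(hits), tuple(notes)
    )


@dataclass
class SummaryTables:
    """The three result tables plus the unassigned remainder.

    ``species``: one row per species or species-complex label, read counts
    aggregated over member ASVs per sample.  ``higher`` and ``nonfish``:
    one row per ASV with its MD5.  ``unassigned``: per-ASV counts with no
    taxon.  Total reads are conserved across the four tables.
    """

    species: pd.DataFrame
    higher: pd.DataFrame
    nonfish: pd.DataFrame
    unassigned: pd.DataFrame
    members: dict[str, tuple[str, ...]]

    def total_reads(self) -> int:
        total = int(self.species.sum().sum()) if not self.species.empty else 0
        for df in (self.higher, self.nonfish, self.unassigned):
            if not df.empty:
                total += int(df[self.sample_columns(df)].sum().sum())
        return total

    @staticmethod
    def sample_columns(df: pd.DataFrame) -> list[str]:
        meta = {"asv_id", "md5", "taxon", "rank"}
        return [c for c in df.columns if c not in meta]


def summarize_tables(
    results: Sequence[AnnotationResult],
    counts: Mapping[str, Mapping[str, int]],
    md5s: Mapping[str, str] | None = None,
) -> SummaryTables:
    """Assemble species / higher-taxon / nonfish / unassigned tables.

    *counts* maps asv_id -> per-sample read counts; *md5s* maps asv_id ->
    sequence digest for the per-ASV tables.
    """
    samples = sorted({s for c in counts.values() for s in c})
    md5s = dict(md5s or {})

    species_rows: dict[str, dict[str, int]] = {}
    members: dict[str, tuple[str, ...]] = {}
    per_asv_rows = {Category.HIGHER_TAXON: [], Category.NONFISH: [], Category.UNASSIGNED: []}

    for res in results:
        asv_counts = counts.get(res.asv_id, {})
        if res.category in (Category.SPECIES, Category.SPECIES_COMPLEX):
            row = species_rows.setdefault(res.label, {s: 0 for s in samples})
            for s, n in asv_counts.items():
                row[s] += n
            members[res.label] = res.taxa
        else:
            entry = {
                "asv_id": res.asv_id,
                "md5": md5s.get(res.asv_id, ""),
                "taxon": res.taxa[0] if res.taxa else "",
                "rank": res.rank,
            }
            for s in samples:
                entry[s] = asv_counts.get(s, 0)
            per_asv_rows[res.category].append(entry)

    species_df = pd.DataFrame.from_dict(species_rows, orient="index", columns=samples)
    species_df = species_df.fillna(0).astype(int)
    species_df.index.name = "taxon"

    def as_df(rows: list[dict]) -> pd.DataFrame:
        cols = ["asv_id", "md5", "taxon", "rank", *samples]
        return pd.DataFrame(rows, columns=cols)

    return SummaryTables(
        species=species_df,
        higher=as_df(per_asv_rows[Category.HIGHER_TAXON]),
        nonfish=as_df(per_asv_rows[Category.NONFISH]),
        unassigned=as_df(per_asv_rows[Category.UNASSIGNED]),
        members=members,
    )
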