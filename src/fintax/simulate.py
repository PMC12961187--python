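"""Synthetic data with known ground truth for every pipeline stage.

The generator emulates the shapes of real inputs — reference sets with
corroborating same-species records from independent author pools and
planted chimeric (heterospecific) segments, background contaminants,
taxonomies, habitat/occurrence tables, and multi-sample read sets for
accurate-short-read and noisy-long-read platforms — while keeping the
truth (templates, planted intervals, per-sample compositions) explicit so
expected outputs of every downstream module are computable exactly.

Species sequences derive from a random root by *stratified* substitution:
one substitution is placed in every window of ``1/rate`` bases, at a
random in-window position.  Compared to uniform placement this guarantees
that any 100-bp chunk of two species at >=5% divergence differs at several
positions, so identity-threshold logic behaves the same for every seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .records import (
    HabitatProfile,
    OccurrenceRecord,
    ReferenceRecord,
    TaxonLineage,
)

BASES = np.array(list("ACGT"))

ILLUMINA_ERROR_RATE = 0.001
NANOPORE_ERROR_RATE = 0.03
# share of nanopore errors that are substitutions / insertions / deletions
NANOPORE_ERROR_MIX = (0.4, 0.3, 0.3)

_EPITHETS = (
    "alpha", "bravo", "charlie", "delta", "echo", "foxtrot", "golf",
    "hotel", "india", "juliett", "kilo", "lima", "mike", "november",
    "oscar", "papa", "quebec", "romeo", "sierra", "tango", "uniform",
)
_GENERA = ("Aquaticus", "Benthicus", "Currensis", "Dulcis", "Estuarius", "Fluvius")
_FAMILIES = ("Alphidae", "Betidae", "Gammidae")
_ORDERS = ("Primoformes", "Secundoformes")
_HIGHER = "Actinopterygii"


@dataclass
class FixtureTruth:
    """Ground truth that fully determines expected downstream outputs."""

    templates: dict[str, str] = field(default_factory=dict)
    planted_chimeras: list[tuple[str, tuple[int, int], tuple[str, ...]]] = field(
        default_factory=list
    )
    sample_compositions: dict[str, dict[str, int]] = field(default_factory=dict)
    seed: int = 0


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


def random_sequence(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(BASES, size=length))


def mutate_stratified(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Substitute one base per window of ``1/rate`` bases (interior jitter)."""
    if not 0 < rate < 0.5:
        raise ValueError("rate must be in (0, 0.5)")
    out = list(seq)
    step = max(2, round(1.0 / rate))
    for start in range(0, len(seq) - step + 1, step):
        pos = start + int(rng.integers(0, step))
        old = out[pos]
        choices = [b for b in "ACGT" if b != old]
        out[pos] = choices[int(rng.integers(0, 3))]
    return "".join(out)


def mutate_uniform(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Independent per-base substitution at *rate* (an error process)."""
    out = list(seq)
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    for pos in hits:
        old = out[pos]
        choices = [b for b in "ACGT" if b != old]
        out[pos] = choices[int(rng.integers(0, 3))]
    return "".join(out)


def _species_name(i: int) -> str:
    return f"{_GENERA[(i // 2) % len(_GENERA)]} {_EPITHETS[i % len(_EPITHETS)]}"


def default_lineage(species: str, i: int) -> TaxonLineage:
    return TaxonLineage(
        species=species,
        genus=species.split()[0],
        family=_FAMILIES[(i // 4) % len(_FAMILIES)],
        order=_ORDERS[(i // 8) % len(_ORDERS)],
        higher=_HIGHER,
    )


def author_pool(k: int) -> frozenset[str]:
    return frozenset({f"Author {k}A", f"Author {k}B"})


def make_reference_db(
    n_species: int = 6,
    gene_length: int = 600,
    divergence: float = 0.1,
    n_records_per_species: int = 2,
    n_author_pools: int = 4,
    seed: int = 0,
) -> tuple[list[ReferenceRecord], FixtureTruth]:
    """A reference set with independent-author corroboration built in.

    Species sequences are mutated from a shared root at ``divergence/2``
    each, giving pairwise divergence close to *divergence*.  Record ``j``
    of a species is the species sequence plus a short random tail of
    ``4*j`` bases, with authors drawn from pool ``j`` — so records of one
    species are distinct sequences (no merging) from disjoint author
    sets, and every chunk of every record has an exact independent
    same-species homolog.
    """
    if not 0 < divergence < 0.5:
        raise ValueError("divergence must be in (0, 0.5)")
    if n_records_per_species > n_author_pools:
        raise ValueError("need at least as many author pools as records per species")
    rng = _rng(seed)
    root = random_sequence(gene_length, rng)
    truth = FixtureTruth(seed=seed)
    records: list[ReferenceRecord] = []
    acc = 0
    for i in range(n_species):
        species = _species_name(i)
        seq = mutate_stratified(root, divergence / 2.0, rng)
        truth.templates[species] = seq
        lineage = default_lineage(species, i)
        for j in range(n_records_per_species):
            acc += 1
            tail = random_sequence(4 * j, rng) if j else ""
            records.append(
                ReferenceRecord(
                    record_id=f"ref{i:02d}_{j}",
                    accessions=(f"ACC{acc:05d}",),
                    sequence=seq + tail,
                    gene="12S rRNA",
                    lineage=lineage,
                    authors=author_pool(j),
                    is_fish=True,
                )
            )
    return records, truth


def plant_chimera(
    record: ReferenceRecord, donor_sequence: str, interval: tuple[int, int]
) -> ReferenceRecord:
    """Replace *interval* of the record with the matching donor segment."""
    start, end = interval
    if not (0 <= start < end <= len(record.sequence)):
        raise ValueError(f"interval {interval} out of bounds for {record.record_id}")
    if end > len(donor_sequence):
        raise ValueError("donor sequence does not cover the interval")
    new_seq = record.sequence[:start] + donor_sequence[start:end] + record.sequence[end:]
    return replace(record, sequence=new_seq, chunks=[])


def simulate_reads(
    composition: Mapping[str, Mapping[str, int]],
    templates: Mapping[str, str],
    platform: str = "illumina",
    error_rate: float | None = None,
    seed: int = 0,
) -> dict[str, list[tuple[str, str]]]:
    """Per-sample reads ``(read_id, sequence)`` from known compositions.

    *composition* maps sample -> species -> read count.  Illumina reads
    carry independent per-base substitutions only; Nanopore reads carry a
    mixed substitution/insertion/deletion process at the stated per-base
    rate over the full-length amplicon.
    """
    if platform not in ("illumina", "nanopore"):
        raise ValueError("platform must be 'illumina' or 'nanopore'")
    if error_rate is None:
        error_rate = ILLUMINA_ERROR_RATE if platform == "illumina" else NANOPORE_ERROR_RATE
    if error_rate < 0:
        raise ValueError("error_rate must be >= 0")
    rng = _rng(seed)
    out: dict[str, list[tuple[str, str]]] = {}
    for sample in composition:
        reads: list[tuple[str, str]] = []
        for species in sorted(composition[sample]):
            template = templates[species]
            for r in range(composition[sample][species]):
                if platform == "illumina":
                    seq = mutate_uniform(template, error_rate, rng)
                else:
                    seq = _nanopore_noise(template, error_rate, rng)
                reads.append((f"{sample}_{species.replace(' ', '_')}_{r}", seq))
        out[sample] = reads
    return out


def _nanopore_noise(template: str, rate: float, rng: np.random.Generator) -> str:
    p_sub, p_ins, p_del = (rate * m for m in NANOPORE_ERROR_MIX)
    out: list[str] = []
    for base in template:
        u = rng.random()
        if u < p_ins:
            out.append("ACGT"[int(rng.integers(0, 4))])
            out.append(base)
        elif u < p_ins + p_del:
            continue
        elif u < p_ins + p_del + p_sub:
            choices = [b for b in "ACGT" if b != base]
            out.append(choices[int(rng.integers(0, 3))])
        else:
            out.append(base)
    return "".join(out)


def make_background_contaminants(
    kinds: Sequence[str] = ("human", "frog", "bird"),
    seed: int = 0,
    length: int = 300,
) -> list[tuple[str, str, str]]:
    """Divergent non-fish marker stand-ins ``(id, sequence, taxon)``.

    Independent random sequences sit near 25% pairwise identity, far
    below any fish template, emulating off-target amplification sources.
    """
    rng = _rng(seed)
    return [
        (f"bg_{kind}", random_sequence(length, rng), kind) for kind in kinds
    ]


def make_habitat_table(species: Sequence[str], seed: int = 0) -> dict[str, HabitatProfile]:
    rng = _rng(seed)
    table: dict[str, HabitatProfile] = {}
    for sp in species:
        dp = HabitatProfile.DEMERS_PELAG_VALUES[int(rng.integers(0, 8))]
        sal = {HabitatProfile.SALINITY_VALUES[int(rng.integers(0, 3))]}
        if rng.random() < 0.3:
            sal.add(HabitatProfile.SALINITY_VALUES[int(rng.integers(0, 3))])
        cz = {HabitatProfile.CLIMATE_ZONE_VALUES[int(rng.integers(0, 7))]}
        table[sp] = HabitatProfile(demers_pelag=dp, salinity=frozenset(sal), climate_zone=frozenset(cz))
    return table


def make_occurrences(
    species: Sequence[str], n_per_species: int = 20, seed: int = 0,
    lat_range: tuple[float, float] = (20.0, 40.0),
    lon_range: tuple[float, float] = (120.0, 140.0),
) -> list[OccurrenceRecord]:
    rng = _rng(seed)
    recs = []
    for sp in species:
        lats = rng.uniform(*lat_range, size=n_per_species)
        lons = rng.uniform(*lon_range, size=n_per_species)
        recs.extend(OccurrenceRecord(sp, float(a), float(o)) for a, o in zip(lats, lons))
    return recs


# --- presets ---------------------------------------------------------------


@dataclass
class ChimeraPreset:
    """A reference set with one planted heterospecific segment.

    The host species' first record carries a 150-bp segment copied from
    two donor species that share it verbatim (as closely related species
    do); clean host records and per-donor record pairs provide the
    independent-author corroboration needed for confident labels.
    """

    records: list[ReferenceRecord]
    truth: FixtureTruth
    host_species: str
    donor_species: tuple[str, str]
    host_record_id: str
    interval: tuple[int, int]


def preset_chimera(seed: int = 0, gene_length: int = 600,
                   interval: tuple[int, int] = (300, 450)) -> ChimeraPreset:
    records, truth = make_reference_db(
        n_species=3,
        gene_length=gene_length,
        divergence=0.1,
        n_records_per_species=2,
        n_author_pools=4,
        seed=seed,
    )
    host, donor_a, donor_b = sorted(truth.templates)
    # third record of the host species from a fourth author pool carries
    # the chimera; donors share the planted segment verbatim
    start, end = interval
    donor_segment = truth.templates[donor_a][start:end]
    shared_b = (
        truth.templates[donor_b][:start] + donor_segment + truth.templates[donor_b][end:]
    )
    truth.templates[donor_b] = shared_b
    updated: list[ReferenceRecord] = []
    for rec in records:
        if rec.species == donor_b:
            base = shared_b + rec.sequence[gene_length:]
            rec = replace(rec, sequence=base)
        updated.append(rec)
    host_idx = [i for i, s in enumerate(sorted(truth.templates)) if s == host][0]
    host_lineage = next(r.lineage for r in updated if r.species == host)
    chimeric = ReferenceRecord(
        record_id="chimera_0",
        accessions=("ACCCHIM1",),
        sequence=truth.templates[host],
        gene="12S rRNA",
        lineage=host_lineage,
        authors=author_pool(3),
        is_fish=True,
    )
    chimeric = plant_chimera(
        chimeric,
        truth.templates[host][:start] + donor_segment + truth.templates[host][end:],
        interval,
    )
    updated.append(chimeric)
    truth.planted_chimeras.append(("chimera_0", interval, (donor_a, donor_b)))
    del host_idx
    return ChimeraPreset(
        records=updated,
        truth=truth,
        host_species=host,
        donor_species=(donor_a, donor_b),
        host_record_id="chimera_0",
        interval=interval,
    )


@dataclass
class NanoporePreset:
    """Long-read end-to-end scenario: K well-separated templates."""

    records: list[ReferenceRecord]
    truth: FixtureTruth
    reads_by_sample: dict[str, list[tuple[str, str]]]


def preset_nanopore(
    seed: int = 0,
    n_species: int = 5,
    marker_length: int = 170,
    reads_per_species: int = 50,
    error_rate: float = NANOPORE_ERROR_RATE,
) -> NanoporePreset:
    records, truth = make_reference_db(
        n_species=n_species,
        gene_length=marker_length,
        divergence=0.12,
        n_records_per_species=2,
        seed=seed,
    )
    composition = {"sample1": {sp: reads_per_species for sp in truth.templates}}
    truth.sample_compositions = {s: dict(c) for s, c in composition.items()}
    reads = simulate_reads(
        composition, truth.templates, platform="nanopore", error_rate=error_rate, seed=seed + 1
    )
    return NanoporePreset(records=records, truth=truth, reads_by_sample=reads)


@dataclass
class MultisamplePreset:
    """Multi-sample short-read design with controls and replicates."""

    records: list[ReferenceRecord]
    background: list[tuple[str, str, str]]
    truth: FixtureTruth
    reads_by_sample: dict[str, list[tuple[str, str]]]
    manifest: list  # list[SampleRole]; imported lazily to avoid cycle
    novel_species: str
    habitat: dict[str, HabitatProfile]
    occurrences: list[OccurrenceRecord]


def preset_multisample(seed: int = 0, marker_length: int = 170) -> MultisamplePreset:
    from .matrix import SampleRole

    records, truth = make_reference_db(
        n_species=6,
        gene_length=marker_length,
        divergence=0.12,
        n_records_per_species=2,
        seed=seed,
    )
    species = sorted(truth.templates)
    spA, spB, spC, spD, spE, spF = species
    rng = _rng(seed + 7)
    # an unreferenced relative of spA: ~2.5% away, below the 99% species
    # threshold but well inside genus-level similarity
    novel = mutate_stratified(truth.templates[spA], 0.025, rng)
    background = make_background_contaminants(("human", "frog"), seed=seed + 3, length=marker_length)

    read_templates = dict(truth.templates)
    read_templates["novel"] = novel
    read_templates["human"] = background[0][1]

    composition = {
        "siteA": {spA: 300, spB: 200, "novel": 60},
        "siteB": {spB: 150, spC: 220, "human": 50},
        "rep1": {spD: 150, spE: 25},
        "rep2": {spD: 140},
        "positive": {spF: 100},
        "negative": {spA: 6},
    }
    truth.sample_compositions = {s: dict(c) for s, c in composition.items()}
    reads = simulate_reads(
        composition, read_templates, platform="illumina",
        error_rate=ILLUMINA_ERROR_RATE, seed=seed + 11,
    )
    manifest = [
        SampleRole("siteA"),
        SampleRole("siteB"),
        SampleRole("rep1", replicate_group="repA"),
        SampleRole("rep2", replicate_group="repA"),
        SampleRole("positive", role="positive_control"),
        SampleRole("negative", role="negative_control"),
    ]
    habitat = make_habitat_table(species, seed=seed + 5)
    occurrences = make_occurrences(species, seed=seed + 6)
    return MultisamplePreset(
        records=records,
        background=background,
        truth=truth,
        reads_by_sample=reads,
        manifest=manifest,
        novel_species=novel,
        habitat=habitat,
        occurrences=occurrences,
    )
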