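"""File formats: FASTA/FASTQ, TSV sidecars, chunk BED, count tables.

Reference input is a FASTA (record id = record_id) plus a TSV sidecar
with columns record_id, accessions (semicolon-joined), species, genus,
family, order, gene_raw, authors (semicolon-joined), is_fish (0/1).
Validated chunk statuses travel as a BED-like TSV
(record_id, start, end, status).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .asv import ASV
from .genes import normalize_gene_name
from .matrix import SampleRole
from .records import (
    ChunkStatus,
    GeneChunk,
    HabitatProfile,
    OccurrenceRecord,
    ReferenceRecord,
    TaxonLineage,
)

SIDECAR_COLUMNS = [
    "record_id", "accessions", "species", "genus", "family", "order",
    "gene_raw", "authors", "is_fish",
]


def read_fasta(path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(entries: Iterable[tuple[str, str]], path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in entries]
    SeqIO.write(records, str(path), "fasta")


def read_fastq(path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fastq")]


def write_fastq(reads: Iterable[tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")


def read_reference(fasta_path, sidecar_path) -> list[ReferenceRecord]:
    """Reference FASTA + TSV sidecar -> records with canonical gene names."""
    seqs = dict(read_fasta(fasta_path))
    meta = pd.read_csv(sidecar_path, sep="\t", dtype=str).fillna("")
    missing = set(SIDECAR_COLUMNS) - set(meta.columns)
    if missing:
        raise ValueError(f"sidecar missing columns {sorted(missing)}")
    records = []
    for row in meta.itertuples(index=False):
        gene = normalize_gene_name(row.gene_raw)
        if gene is None:
            raise ValueError(f"{row.record_id}: unknown gene name {row.gene_raw!r}")
        if row.record_id not in seqs:
            raise ValueError(f"{row.record_id} not present in FASTA")
        records.append(
            ReferenceRecord(
                record_id=row.record_id,
                accessions=tuple(a for a in row.accessions.split(";") if a),
                sequence=seqs[row.record_id],
                gene=gene,
                lineage=TaxonLineage(
                    species=row.species, genus=row.genus,
                    family=row.family, order=row.order,
                ),
                authors=frozenset(a for a in row.authors.split(";") if a),
                is_fish=row.is_fish == "1",
            )
        )
    return records


def write_reference(records: Sequence[ReferenceRecord], fasta_path, sidecar_path) -> None:
    write_fasta([(r.record_id, r.sequence) for r in records], fasta_path)
    rows = [
        {
            "record_id": r.record_id,
            "accessions": ";".join(r.accessions),
            "species": r.lineage.species,
            "genus": r.lineage.genus,
            "family": r.lineage.family,
            "order": r.lineage.order,
            "gene_raw": r.gene,
            "authors": ";".join(sorted(r.authors)),
            "is_fish": "1" if r.is_fish else "0",
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=SIDECAR_COLUMNS).to_csv(sidecar_path, sep="\t", index=False)


def write_chunk_bed(records: Sequence[ReferenceRecord], path) -> None:
    """Chunk statuses as a BED-like TSV (record_id, start, end, status)."""
    with open(path, "w") as fh:
        for rec in records:
            for chunk in rec.chunks:
                fh.write(f"{rec.record_id}\t{chunk.start}\t{chunk.end}\t{chunk.status.value}\n")


def read_chunk_bed(path) -> dict[str, list[GeneChunk]]:
    out: dict[str, list[GeneChunk]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            rid, start, end, status = line.rstrip("\n").split("\t")
            out.setdefault(rid, []).append(
                GeneChunk(int(start), int(end), ChunkStatus(status))
            )
    return out


def read_manifest(path) -> list[SampleRole]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    return [
        SampleRole(
            sample_id=row.sample_id,
            role=row.role or "sample",
            replicate_group=row.replicate_group or None,
        )
        for row in df.itertuples(index=False)
    ]


def write_manifest(manifest: Sequence[SampleRole], path) -> None:
    pd.DataFrame(
        [
            {
                "sample_id": m.sample_id,
                "role": m.role,
                "replicate_group": m.replicate_group or "",
            }
            for m in manifest
        ]
    ).to_csv(path, sep="\t", index=False)


def write_habitat(table: Mapping[str, HabitatProfile], path) -> None:
    rows = [
        {
            "species": sp,
            "demers_pelag": prof.demers_pelag,
            "salinity": ";".join(sorted(prof.salinity)),
            "climate_zone": ";".join(sorted(prof.climate_zone)),
        }
        for sp, prof in sorted(table.items())
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_habitat(path) -> dict[str, HabitatProfile]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    return {
        row.species: HabitatProfile(
            demers_pelag=row.demers_pelag or "unknown",
            salinity=frozenset(v for v in row.salinity.split(";") if v),
            climate_zone=frozenset(v for v in row.climate_zone.split(";") if v),
        )
        for row in df.itertuples(index=False)
    }


def write_occurrences(records: Sequence[OccurrenceRecord], path) -> None:
    pd.DataFrame(
        [{"species": r.species, "lat": r.latitude, "lon": r.longitude} for r in records]
    ).to_csv(path, sep="\t", index=False)


def read_occurrences(path) -> list[OccurrenceRecord]:
    df = pd.read_csv(path, sep="\t")
    return [
        OccurrenceRecord(row.species, float(row.lat), float(row.lon))
        for row in df.itertuples(index=False)
    ]


def write_asv_fasta(asvs: Sequence[ASV], fasta_path, counts_path=None) -> None:
    """ASV FASTA with ``>asv_<n>;size=<total>`` headers + count TSV."""
    write_fasta([(f"{a.asv_id};size={a.total}", a.sequence) for a in asvs], fasta_path)
    if counts_path is not None:
        samples = sorted({s for a in asvs for s in a.counts})
        rows = [
            {"asv_id": a.asv_id, **{s: a.counts.get(s, 0) for s in samples}}
            for a in asvs
        ]
        pd.DataFrame(rows, columns=["asv_id", *samples]).to_csv(counts_path, sep="\t", index=False)


def read_asv_fasta(fasta_path, counts_path=None) -> list[ASV]:
    """Read pre-made ASV/OTU FASTA (reanalysis input path).

    Headers may carry ``;size=<n>``; without a count table each ASV gets
    that total (default 1) under a single ``"sample"`` column.
    """
    counts: dict[str, dict[str, int]] = {}
    if counts_path is not None:
        df = pd.read_csv(counts_path, sep="\t")
        for row in df.to_dict(orient="records"):
            asv_id = str(row.pop("asv_id"))
            counts[asv_id] = {str(k): int(v) for k, v in row.items() if int(v) > 0}
    asvs = []
    for name, seq in read_fasta(fasta_path):
        asv_id, _, attrs = name.partition(";")
        size = 1
        for part in attrs.split(";"):
            if part.startswith("size="):
                size = int(part[5:])
        asvs.append(
            ASV(asv_id=asv_id, sequence=seq, counts=counts.get(asv_id, {"sample": size}))
        )
    return asvs


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
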