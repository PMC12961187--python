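"""Multi-sample result matrices with control and replicate badges.

Rows are species (or species complexes), columns are the samples of a
manifest, cells are read counts.  Three badges prompt manual inspection:
``P`` — detected in a positive control, ``N`` — detected in a negative
control, ``S`` — detected in only a single replicate.  Badges only flag;
nothing is removed automatically.  Habitat profiles and occurrence
proximity can be attached per row member to support manual filtering.
"""

from __future__ import annotations

import csv
import io as _io
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd

from .annotate import COMPLEX_SEPARATOR, SummaryTables, Taxonomy
from .records import HabitatProfile, OccurrenceRecord, UNKNOWN_HABITAT

ROLES = ("sample", "positive_control", "negative_control")


@dataclass(frozen=True)
class SampleRole:
    sample_id: str
    role: str = "sample"
    replicate_group: str | None = None

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"role must be one of {ROLES}")
        if self.replicate_group is not None and self.role != "sample":
            raise ValueError("replicate_group applies only to role=sample")


@dataclass
class ResultMatrix:
    """Species-by-sample abundance table with P/N/S badges."""

    counts: pd.DataFrame  # rows: species/complex labels; cols: manifest order
    badges: dict[str, frozenset[str]]
    manifest: tuple[SampleRole, ...]
    members: dict[str, tuple[str, ...]] = field(default_factory=dict)
    habitat: dict[str, HabitatProfile] = field(default_factory=dict)

    @property
    def labels(self) -> list[str]:
        return list(self.counts.index)

    def row_members(self, label: str) -> tuple[str, ...]:
        return self.members.get(label, tuple(label.split(COMPLEX_SEPARATOR)))


def _compute_badges(
    counts: pd.DataFrame, manifest: Sequence[SampleRole], scope: str = "global"
) -> dict[str, frozenset[str]]:
    positives = [m.sample_id for m in manifest if m.role == "positive_control"]
    negatives = [m.sample_id for m in manifest if m.role == "negative_control"]
    plain = [m.sample_id for m in manifest if m.role == "sample"]
    groups: dict[str, list[str]] = {}
    for m in manifest:
        if m.role == "sample" and m.replicate_group:
            groups.setdefault(m.replicate_group, []).append(m.sample_id)

    badges: dict[str, frozenset[str]] = {}
    for label in counts.index:
        row = counts.loc[label]
        flags = set()
        if any(row[s] > 0 for s in positives):
            flags.add("P")
        if any(row[s] > 0 for s in negatives):
            flags.add("N")
        if scope == "global":
            detected = [s for s in plain if row[s] > 0]
            if len(detected) == 1:
                grp = next(
                    (m.replicate_group for m in manifest if m.sample_id == detected[0]),
                    None,
                )
                if grp is not None and len(groups.get(grp, [])) >= 2:
                    flags.add("S")
        elif scope == "group":
            for members in groups.values():
                if len(members) >= 2 and sum(row[s] > 0 for s in members) == 1:
                    flags.add("S")
                    break
        else:
            raise ValueError("scope must be 'global' or 'group'")
        badges[label] = frozenset(flags)
    return badges


def build_matrix(
    per_sample_results: Mapping[str, Mapping[str, int]] | pd.DataFrame,
    manifest: Sequence[SampleRole],
    members: Mapping[str, tuple[str, ...]] | None = None,
    habitat: Mapping[str, HabitatProfile] | None = None,
    scope: str = "global",
) -> ResultMatrix:
    """Assemble the species-by-sample matrix and compute badges.

    *per_sample_results* is either ``sample -> {label: count}`` or a
    species table DataFrame (rows labels, columns samples).  Every result
    sample must appear in the manifest; manifest samples without results
    get zero columns.
    """
    ids = [m.sample_id for m in manifest]
    if len(set(ids)) != len(ids):
        raise ValueError("manifest sample_ids must be unique")
    if isinstance(per_sample_results, pd.DataFrame):
        table = per_sample_results.copy()
        unknown = set(table.columns) - set(ids)
    else:
        unknown = set(per_sample_results) - set(ids)
        labels = sorted({lab for res in per_sample_results.values() for lab in res})
        table = pd.DataFrame(0, index=labels, columns=list(per_sample_results))
        for sample, res in per_sample_results.items():
            for lab, n in res.items():
                table.loc[lab, sample] = n
    if unknown:
        raise ValueError(f"results reference samples not in manifest: {sorted(unknown)}")
    for sid in ids:
        if sid not in table.columns:
            table[sid] = 0
    table = table[ids].fillna(0).astype(int)
    table.index.name = "taxon"
    badges = _compute_badges(table, manifest, scope=scope)
    return ResultMatrix(
        counts=table,
        badges=badges,
        manifest=tuple(manifest),
        members=dict(members or {}),
        habitat=dict(habitat or {}),
    )


def annotate_habitat(
    members: Sequence[str], habitat_table: Mapping[str, HabitatProfile]
) -> dict[str, HabitatProfile]:
    """Per-member habitat profiles; species absent from the table map to unknown."""
    return {sp: habitat_table.get(sp, UNKNOWN_HABITAT) for sp in members}


def _wrapped_lon_diff(a: float, b: float) -> float:
    d = abs(a - b) % 360.0
    return min(d, 360.0 - d)


def occurrence_proximity(
    species: str,
    site: tuple[float, float],
    radius_deg: float,
    occurrences: Iterable[OccurrenceRecord],
) -> tuple[bool, int]:
    """Occurrence records of *species* within a box radius of *site*.

    Distance is the maximum of |Δlat| and the wrapped |Δlon| in degrees
    (consistent with the 1° dedup grid), so longitudes near ±180 are
    neighbours.
    """
    if radius_deg <= 0:
        raise ValueError("radius_deg must be positive")
    lat, lon = site
    n = 0
    for rec in occurrences:
        if rec.species != species:
            continue
        if abs(rec.latitude - lat) <= radius_deg and _wrapped_lon_diff(rec.longitude, lon) <= radius_deg:
            n += 1
    return n > 0, n


def filter_matrix(
    matrix: ResultMatrix,
    row_pred: Callable[[str, frozenset[str]], bool] | None = None,
    member_pred: Callable[[str, HabitatProfile], bool] | None = None,
    scope: str = "global",
) -> ResultMatrix:
    """Drop rows (or complex members) failing a predicate.

    *row_pred* receives ``(label, badges)``; *member_pred* receives
    ``(species, habitat profile)`` and shrinks complexes — a row whose
    members are all dropped is removed.  The input matrix is unchanged;
    the operation is idempotent for any fixed predicate pair.
    """
    keep_rows: list[str] = []
    new_members: dict[str, tuple[str, ...]] = {}
    relabel: dict[str, str] = {}
    for label in matrix.labels:
        if row_pred is not None and not row_pred(label, matrix.badges[label]):
            continue
        members = matrix.row_members(label)
        if member_pred is not None:
            members = tuple(
                sp for sp in members if member_pred(sp, matrix.habitat.get(sp, UNKNOWN_HABITAT))
            )
            if not members:
                continue
        new_label = COMPLEX_SEPARATOR.join(members)
        keep_rows.append(label)
        relabel[label] = new_label
        new_members[new_label] = members

    counts = matrix.counts.loc[keep_rows].rename(index=relabel)
    badges = {relabel[lab]: matrix.badges[lab] for lab in keep_rows}
    return ResultMatrix(
        counts=counts,
        badges=badges,
        manifest=matrix.manifest,
        members=new_members,
        habitat=dict(matrix.habitat),
    )


def export_csv(matrix: ResultMatrix) -> str:
    """Serialize the matrix as CSV text (badges joined with ';')."""
    buf = _io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    samples = list(matrix.counts.columns)
    writer.writerow(["taxon", "badges", *samples])
    for label in matrix.labels:
        badge_str = ";".join(sorted(matrix.badges[label]))
        writer.writerow([label, badge_str, *(int(v) for v in matrix.counts.loc[label])])
    return buf.getvalue()


def parse_csv(text: str, manifest: Sequence[SampleRole] | None = None) -> ResultMatrix:
    """Parse :func:`export_csv` output back into a matrix (lossless)."""
    reader = csv.reader(_io.StringIO(text))
    header = next(reader)
    samples = header[2:]
    if manifest is None:
        manifest = tuple(SampleRole(s) for s in samples)
    labels: list[str] = []
    badges: dict[str, frozenset[str]] = {}
    rows: list[list[int]] = []
    for row in reader:
        if not row:
            continue
        labels.append(row[0])
        badges[row[0]] = frozenset(b for b in row[1].split(";") if b)
        rows.append([int(v) for v in row[2:]])
    counts = pd.DataFrame(rows, index=labels, columns=samples).astype(int)
    counts.index.name = "taxon"
    return ResultMatrix(counts=counts, badges=badges, manifest=tuple(manifest))


# --- comparison against a published taxon list ----------------------------

CATEGORIES = ("Single", "Multiple", "Clades", "Diff", "Undetected")


@dataclass(frozen=True)
class ResultRows:
    """Name-level view of an analysis result for comparisons."""

    singles: frozenset[str]
    complexes: tuple[tuple[str, ...], ...]
    clades: frozenset[str]

    @classmethod
    def from_tables(cls, tables: SummaryTables) -> "ResultRows":
        singles = set()
        complexes = []
        for label, members in tables.members.items():
            if len(members) == 1:
                singles.add(members[0])
            else:
                complexes.append(tuple(members))
        clades = set(tables.higher["taxon"]) if not tables.higher.empty else set()
        return cls(frozenset(singles), tuple(complexes), frozenset(clades))

    @property
    def complex_members(self) -> frozenset[str]:
        return frozenset(sp for cx in self.complexes for sp in cx)


def _species_in_clade(species: str, clade: str, taxonomy: Taxonomy) -> bool:
    if species not in taxonomy:
        return False
    return clade in set(taxonomy.ancestors(species).values())


def compare_to_published(
    rows: ResultRows,
    published: Sequence[tuple[str, str]],
    taxonomy: Taxonomy,
    assignments: Mapping[str, str] | None = None,
) -> dict[str, str]:
    """Categorize each published taxon against the analysis rows.

    *published* entries are ``(name, level)`` with level ``"species"`` or
    ``"clade"``.  Outcomes: exact species row -> ``Single``; member of a
    complex -> ``Multiple``; a higher-taxon row containing it ->
    ``Clades``; present as a different taxon -> ``Diff`` (decidable only
    through *assignments*, an optional published-name -> observed-label
    map from read provenance); absent -> ``Undetected``.  Every taxon
    receives exactly one category.
    """
    out: dict[str, str] = {}
    for name, level in published:
        if level not in ("species", "clade"):
            raise ValueError(f"published level must be species or clade, got {level!r}")
        if level == "species":
            if name in rows.singles:
                out[name] = "Single"
            elif name in rows.complex_members:
                out[name] = "Multiple"
            elif any(_species_in_clade(name, clade, taxonomy) for clade in rows.clades):
                out[name] = "Clades"
            elif assignments and assignments.get(name):
                out[name] = "Diff"
            else:
                out[name] = "Undetected"
        else:
            in_clade_singles = {
                sp for sp in rows.singles if _species_in_clade(sp, name, taxonomy)
            }
            in_clade_complexes = [
                cx
                for cx in rows.complexes
                if all(_species_in_clade(sp, name, taxonomy) for sp in cx)
            ]
            if in_clade_singles:
                out[name] = "Single"
            elif in_clade_complexes:
                out[name] = "Multiple"
            elif name in rows.clades:
                out[name] = "Clades"
            elif assignments and assignments.get(name):
                out[name] = "Diff"
            else:
                out[name] = "Undetected"
    return out
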