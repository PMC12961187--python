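"""Amplicon sequence variant (ASV) generation.

Two read paths produce ASVs with per-sample counts:

* accurate short reads (Illumina): exact dereplication followed by a
  simple abundance-skew denoiser — a unique sequence within a small edit
  distance of a much more abundant one is treated as its error shadow
  and absorbed;
* noisy long reads (Nanopore): greedy length-sorted clustering at 97%
  identity, per-cluster plurality consensus, then consensus re-clustering
  rounds until the ASV set is stable.  Raw noisy reads rarely sit within
  97% of each other even when they share a template, so the consensus
  polish loop is what collapses each template's read cloud into a single
  clean ASV.

Pre-made ASV/OTU FASTA input can bypass this module entirely (reanalysis
path); see :mod:`fintax.pipeline`.
"""

from __future__ import annotations

import hashlib
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .align import edit_distance, global_alignment_cigar, global_identity

DEFAULT_MIN_ABUNDANCE = 2
DEFAULT_MAX_DIST = 1
DEFAULT_SKEW = 8.0
NANOPORE_CLUSTER_IDENTITY = 97.0
POLISH_ROUNDS = 5


def md5_of_sequence(sequence: str) -> str:
    """Lowercase hex MD5 of the uppercased sequence bytes."""
    if not sequence:
        raise ValueError("sequence must be non-empty")
    return hashlib.md5(sequence.upper().encode("ascii")).hexdigest()


@dataclass
class ASV:
    """A denoised/consensus amplicon variant with per-sample read counts."""

    asv_id: str
    sequence: str
    counts: dict[str, int]
    md5: str = ""

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        digest = md5_of_sequence(self.sequence)
        if self.md5 and self.md5 != digest:
            raise ValueError("stored md5 does not match sequence")
        self.md5 = digest
        if self.total < 1:
            raise ValueError("ASV must have total count >= 1")

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass
class ReadCluster:
    """A greedy cluster of noisy reads around a centroid read."""

    centroid: str
    members: list[str]
    member_indices: list[int] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.members)


def dereplicate(reads: Sequence[str]) -> list[tuple[str, int]]:
    """Unique sequences with exact-match abundances.

    Sorted by abundance descending, then sequence ascending.
    """
    counter = Counter(r.upper() for r in reads)
    return sorted(counter.items(), key=lambda kv: (-kv[1], kv[0]))


def dereplicate_samples(
    reads_by_sample: Mapping[str, Sequence[str]],
) -> list[tuple[str, dict[str, int]]]:
    """Dereplicate across samples, keeping per-sample counts."""
    per_seq: dict[str, dict[str, int]] = {}
    for sample, reads in reads_by_sample.items():
        for read in reads:
            seq = read.upper()
            per_seq.setdefault(seq, {})
            per_seq[seq][sample] = per_seq[seq].get(sample, 0) + 1
    items = [(seq, counts) for seq, counts in per_seq.items()]
    items.sort(key=lambda kv: (-sum(kv[1].values()), kv[0]))
    return items


def _merge_counts(into: dict[str, int], other: Mapping[str, int]) -> None:
    for k, v in other.items():
        into[k] = into.get(k, 0) + v


def denoise_simple(
    uniques: Sequence[tuple[str, int]],
    min_abundance: int = DEFAULT_MIN_ABUNDANCE,
    max_dist: int = DEFAULT_MAX_DIST,
    skew: float = DEFAULT_SKEW,
    sample_counts: Mapping[str, Mapping[str, int]] | None = None,
) -> list[ASV]:
    """Absorb error shadows of abundant sequences; the rest become ASVs.

    A unique within *max_dist* edits of an accepted ASV at least *skew*
    times more abundant is absorbed into it.  Uniques at or above
    *min_abundance* otherwise found new ASVs.  Sub-threshold orphans are
    attached to the nearest accepted ASV (or become ASVs themselves when
    none exists), so total abundance is conserved exactly.

    *sample_counts* optionally maps sequence -> per-sample counts; without
    it all reads are booked under a single ``"sample"`` column.
    """
    ordered = sorted(uniques, key=lambda kv: (-kv[1], kv[0]))

    def counts_for(seq: str, abundance: int) -> dict[str, int]:
        if sample_counts is None:
            return {"sample": abundance}
        return dict(sample_counts[seq])

    accepted: list[dict] = []  # {"seq", "abundance", "counts"}
    leftovers: list[tuple[str, int]] = []
    for seq, abundance in ordered:
        parent = None
        for cand in accepted:
            if cand["abundance"] >= skew * abundance and edit_distance(seq, cand["seq"], k=max_dist) <= max_dist:
                parent = cand
                break
        if parent is not None:
            parent["abundance"] += abundance
            _merge_counts(parent["counts"], counts_for(seq, abundance))
        elif abundance >= min_abundance:
            accepted.append({"seq": seq, "abundance": abundance, "counts": counts_for(seq, abundance)})
        else:
            leftovers.append((seq, abundance))

    for seq, abundance in leftovers:
        if accepted:
            nearest = min(accepted, key=lambda cand: (edit_distance(seq, cand["seq"]), cand["seq"]))
            nearest["abundance"] += abundance
            _merge_counts(nearest["counts"], counts_for(seq, abundance))
        else:
            accepted.append({"seq": seq, "abundance": abundance, "counts": counts_for(seq, abundance)})

    accepted.sort(key=lambda cand: (-cand["abundance"], cand["seq"]))
    return [
        ASV(asv_id=f"asv_{i + 1}", sequence=cand["seq"], counts=cand["counts"])
        for i, cand in enumerate(accepted)
    ]


def nanopore_cluster(
    reads: Sequence[str], identity: float = NANOPORE_CLUSTER_IDENTITY
) -> list[ReadCluster]:
    """Greedy centroid clustering of noisy reads.

    Reads are sorted by decreasing length (ties by sequence) and each
    read joins the first existing centroid with global identity >=
    *identity* percent, else founds a new cluster.  Deterministic given
    the sort.
    """
    order = sorted(range(len(reads)), key=lambda i: (-len(reads[i]), reads[i]))
    clusters: list[ReadCluster] = []
    for idx in order:
        seq = reads[idx].upper()
        placed = False
        for cluster in clusters:
            if global_identity(seq, cluster.centroid) >= identity:
                cluster.members.append(seq)
                cluster.member_indices.append(idx)
                placed = True
                break
        if not placed:
            clusters.append(ReadCluster(centroid=seq, members=[seq], member_indices=[idx]))
    return clusters


def _parse_cigar(cigar: str):
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            yield int(num), ch
            num = ""


def consensus_from(centroid: str, members: Sequence[str]) -> str:
    """Plurality consensus of *members* aligned globally to *centroid*.

    Per centroid column the plurality base wins (ties resolved toward the
    centroid base, then alphabetically); a plurality of deletions removes
    the column.  Insertions between columns are kept only when present in
    more than half of the members (plurality insertion string).
    """
    if not members:
        raise ValueError("cluster must be non-empty")
    if len(members) == 1:
        return members[0]
    n = len(centroid)
    column_votes: list[Counter] = [Counter() for _ in range(n)]
    insertion_votes: list[Counter] = [Counter() for _ in range(n + 1)]
    for member in members:
        _, cigar = global_alignment_cigar(member, centroid)
        t = 0  # centroid position
        q = 0  # member position
        pending_ins: dict[int, list[str]] = {}
        for count, op in _parse_cigar(cigar):
            if op in "=X":
                for _ in range(count):
                    column_votes[t][member[q]] += 1
                    t += 1
                    q += 1
            elif op == "D":  # centroid base absent from member
                for _ in range(count):
                    column_votes[t]["-"] += 1
                    t += 1
            elif op == "I":  # member bases absent from centroid
                pending_ins.setdefault(t, []).append(member[q : q + count])
                q += count
            else:  # pragma: no cover - edlib emits only =XID
                raise ValueError(f"unexpected CIGAR op {op!r}")
        for pos, pieces in pending_ins.items():
            insertion_votes[pos]["".join(pieces)] += 1

    half = len(members) / 2.0
    out: list[str] = []
    for t in range(n + 1):
        ins = insertion_votes[t]
        if ins and sum(ins.values()) > half:
            best = max(ins.items(), key=lambda kv: (kv[1], kv[0]))
            # plurality inserted string, ties toward lexicographically larger
            top_count = best[1]
            candidates = sorted(s for s, c in ins.items() if c == top_count)
            out.append(candidates[0])
        if t == n:
            break
        votes = column_votes[t]
        if not votes:
            out.append(centroid[t])
            continue
        top_count = max(votes.values())
        tied = {b for b, c in votes.items() if c == top_count}
        if centroid[t] in tied:
            winner = centroid[t]
        else:
            winner = sorted(tied)[0]
        if winner != "-":
            out.append(winner)
    return "".join(out)


def cluster_consensus(cluster: ReadCluster) -> str:
    """Consensus sequence of one read cluster (singletons return the read)."""
    return consensus_from(cluster.centroid, cluster.members)


REASSIGN_RELAXATION = 10.0  # percentage points below the cluster threshold


def nanopore_asvs(
    reads_by_sample: Mapping[str, Sequence[str]],
    identity: float = NANOPORE_CLUSTER_IDENTITY,
    min_size: int | None = None,
    polish_rounds: int = POLISH_ROUNDS,
) -> list[ASV]:
    """Full Nanopore path: cluster, consensus polish loop, abundance floor.

    Greedy clustering of raw noisy reads at *identity* seeds a set of
    candidate consensi which are then refined iteratively: candidates
    within *identity* percent of each other are merged (largest first),
    every read is re-assigned to its highest-identity candidate provided
    it clears the threshold relaxed by 10 points (room for the read's
    own errors on top of residual consensus noise; reads clearing no
    candidate stay as their own singleton candidates), and each
    candidate's consensus is recomputed from its assigned reads.  The
    loop runs up to *polish_rounds* times or until assignments are
    stable.  Candidates attracting fewer than *min_size* reads (default
    ``max(2, 1% of reads)``) are finally dropped as unpolishable noise.
    """
    reads: list[str] = []
    provenance: list[str] = []
    for sample, sample_reads in reads_by_sample.items():
        for read in sample_reads:
            reads.append(read.upper())
            provenance.append(sample)
    if not reads:
        return []
    if min_size is None:
        min_size = max(2, math.ceil(0.01 * len(reads)))
    floor = identity - REASSIGN_RELAXATION

    clusters = nanopore_cluster(reads, identity=identity)
    groups = [
        {"consensus": cluster_consensus(c), "indices": list(c.member_indices)}
        for c in clusters
    ]

    for _ in range(polish_rounds):
        groups.sort(key=lambda g: (-len(g["indices"]), g["consensus"]))
        # merge candidates that have converged onto the same variant
        merged: list[dict] = []
        for g in groups:
            target = None
            for m in merged:
                if global_identity(g["consensus"], m["consensus"]) >= identity:
                    target = m
                    break
            if target is None:
                merged.append({"consensus": g["consensus"], "indices": list(g["indices"])})
            else:
                target["indices"].extend(g["indices"])
        # re-assign every read to its best multi-read candidate; pure
        # singletons cannot attract (a read is always 100% identical to
        # the candidate it founded, which would freeze the partition)
        eligible = [j for j, m in enumerate(merged) if len(m["indices"]) >= 2] or list(
            range(len(merged))
        )
        assignment: list[int | None] = []
        for idx, read in enumerate(reads):
            best_j, best_ident = None, floor
            for j in eligible:
                ident = global_identity(read, merged[j]["consensus"])
                if ident > best_ident:
                    best_j, best_ident = j, ident
            assignment.append(best_j)
        new_groups = [
            {"consensus": m["consensus"], "indices": []} for m in merged
        ]
        orphans: list[int] = []
        for idx, j in enumerate(assignment):
            if j is None:
                orphans.append(idx)
            else:
                new_groups[j]["indices"].append(idx)
        new_groups = [g for g in new_groups if g["indices"]]
        new_groups.extend({"consensus": reads[i], "indices": [i]} for i in orphans)
        for g in new_groups:
            if len(g["indices"]) > 1:
                g["consensus"] = consensus_from(
                    g["consensus"], [reads[i] for i in g["indices"]]
                )
        stable = {tuple(sorted(g["indices"])) for g in new_groups} == {
            tuple(sorted(g["indices"])) for g in groups
        }
        groups = new_groups
        if stable:
            break

    kept = [g for g in groups if len(g["indices"]) >= min_size] or groups
    kept.sort(key=lambda g: (-len(g["indices"]), g["consensus"]))
    asvs = []
    for i, g in enumerate(kept):
        counts: dict[str, int] = {}
        for idx in g["indices"]:
            counts[provenance[idx]] = counts.get(provenance[idx], 0) + 1
        asvs.append(ASV(asv_id=f"asv_{i + 1}", sequence=g["consensus"], counts=counts))
    return asvs


def illumina_asvs(
    reads_by_sample: Mapping[str, Sequence[str]],
    min_abundance: int = DEFAULT_MIN_ABUNDANCE,
    max_dist: int = DEFAULT_MAX_DIST,
    skew: float = DEFAULT_SKEW,
) -> list[ASV]:
    """Full Illumina path: cross-sample dereplication plus denoising."""
    uniques = dereplicate_samples(reads_by_sample)
    totals = [(seq, sum(counts.values())) for seq, counts in uniques]
    per_seq = {seq: counts for seq, counts in uniques}
    return denoise_simple(
        totals,
        min_abundance=min_abundance,
        max_dist=max_dist,
        skew=skew,
        sample_counts=per_seq,
    )
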