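import pytest

from fintax.align import global_identity, pairwise_alignment
from fintax.curation import (
    ChunkHomolog,
    build_background_db,
    classify_chunk,
    collect_chunk_homologs,
    validate_reference_set,
)
from fintax.records import ChunkStatus, GeneChunk, ReferenceRecord, TaxonLineage

A1, A2, A3, A4 = (frozenset({f"Author {k}"}) for k in "1234")


def make_record(record_id, seq, species="Aquaticus alpha", accessions=None, authors=A1):
    return ReferenceRecord(
        record_id=record_id,
        accessions=accessions or (record_id.upper(),),
        sequence=seq,
        gene="12S rRNA",
        lineage=TaxonLineage(species),
        authors=authors,
    )


def mutate_at(seq, positions):
    out = list(seq)
    for p in positions:
        out[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[p]]
    return "".join(out)


class TestCollectChunkHomologs:
    def test_exact_copy_found_at_full_identity(self, random_dna):
        seq = random_dna(200)
        rec = make_record("q", seq)
        other = make_record("s", random_dna(30) + seq[:100] + random_dna(30),
                            species="Aquaticus bravo", authors=A2)
        homologs = collect_chunk_homologs(rec, GeneChunk(0, 100), [other])
        assert len(homologs) == 1
        assert homologs[0].identity == pytest.approx(100.0)

    def test_98_percent_copy_excluded(self, random_dna):
        seq = random_dna(200)
        rec = make_record("q", seq)
        diverged = mutate_at(seq[:100], [30, 60])  # 98% over the chunk
        other = make_record("s", diverged, species="Aquaticus bravo", authors=A2)
        assert collect_chunk_homologs(rec, GeneChunk(0, 100), [other]) == []

    def test_three_planted_copies_yield_two_homologs(self, random_dna):
        # identities verified against the package aligner itself (oracle route)
        seq = random_dna(200)
        rec = make_record("q", seq)
        chunk = GeneChunk(0, 100)
        exact = seq[:100] + random_dna(100)
        near = seq[:100] + mutate_at(random_dna(100), [50])  # mutation outside the chunk match
        far = mutate_at(seq[:100], [30, 60]) + random_dna(100)  # 2% inside the chunk
        db = [
            make_record("s1", exact, species="Aquaticus bravo", authors=A2),
            make_record("s2", near, species="Aquaticus charlie", authors=A3),
            make_record("s3", far, species="Aquaticus delta", authors=A4),
        ]
        expected = []
        for other in db:
            res = pairwise_alignment(seq[:100], other.sequence, mode="local")
            if res.identity > 99.0 and res.coverage >= 80.0:
                expected.append(other.record_id)
        homologs = collect_chunk_homologs(rec, chunk, db)
        assert len(homologs) == len(expected) == 2

    def test_shared_accession_records_skipped(self, random_dna):
        seq = random_dna(120)
        rec = make_record("q", seq, accessions=("ACC1", "ACC2"))
        twin = make_record("s", seq, accessions=("ACC2",), authors=A2)
        assert collect_chunk_homologs(rec, GeneChunk(0, 100), [twin]) == []

    def test_empty_db_gives_empty_list(self, random_dna):
        rec = make_record("q", random_dna(120))
        assert collect_chunk_homologs(rec, GeneChunk(0, 100), []) == []


SP = "Aquaticus alpha"


@pytest.mark.parametrize(
    "homologs,expected",
    [
        # same species, independent author -> corroborated
        ([("Aquaticus alpha", A2)], ChunkStatus.HOMOSPECIFIC),
        # same species but same author cannot corroborate
        ([("Aquaticus alpha", A1)], ChunkStatus.UNKNOWN),
        # no evidence at all
        ([], ChunkStatus.UNKNOWN),
        # a single other species is insufficient
        ([("Aquaticus bravo", A2)], ChunkStatus.UNKNOWN),
        # two other species from two independent authors -> heterospecific
        ([("Aquaticus bravo", A2), ("Aquaticus charlie", A3)], ChunkStatus.HETEROSPECIFIC),
        # other species but from the record's own author
        ([("Aquaticus bravo", A1), ("Aquaticus charlie", A1)], ChunkStatus.UNKNOWN),
        # two other species but a single contributing author
        ([("Aquaticus bravo", A2), ("Aquaticus charlie", A2)], ChunkStatus.UNKNOWN),
        # same-species homolog exists (same author), so never heterospecific
        (
            [("Aquaticus alpha", A1), ("Aquaticus bravo", A2), ("Aquaticus charlie", A3)],
            ChunkStatus.UNKNOWN,
        ),
        # homospecific takes precedence over heterospecific evidence
        (
            [("Aquaticus alpha", A2), ("Aquaticus bravo", A3), ("Aquaticus charlie", A4)],
            ChunkStatus.HOMOSPECIFIC,
        ),
        # overlapping author sets form one group only
        (
            [("Aquaticus bravo", frozenset({"Author 2", "Author 3"})),
             ("Aquaticus charlie", frozenset({"Author 3", "Author 4"}))],
            ChunkStatus.UNKNOWN,
        ),
        # one species under several authors is still one species
        ([("Aquaticus bravo", A2), ("Aquaticus bravo", A3)], ChunkStatus.UNKNOWN),
        # three homologs, two species, two author groups
        (
            [("Aquaticus bravo", A2), ("Aquaticus charlie", A3), ("Aquaticus delta", A2)],
            ChunkStatus.HETEROSPECIFIC,
        ),
    ],
)
def test_classify_chunk_truth_table(homologs, expected):
    hl = [ChunkHomolog(sp, authors, 99.5) for sp, authors in homologs]
    assert classify_chunk(SP, A1, hl) is expected


def test_homospecific_and_heterospecific_mutually_exclusive():
    # enumerating every branch above, no homolog set can yield both labels;
    # spot-check that adding a same-species independent homolog to a
    # heterospecific set flips it to homospecific
    hetero = [ChunkHomolog("Aquaticus bravo", A2, 99.5), ChunkHomolog("Aquaticus charlie", A3, 99.5)]
    assert classify_chunk(SP, A1, hetero) is ChunkStatus.HETEROSPECIFIC
    assert classify_chunk(SP, A1, hetero + [ChunkHomolog(SP, A4, 99.5)]) is ChunkStatus.HOMOSPECIFIC


class TestValidateReferenceSet:
    def test_single_record_all_unknown(self, random_dna):
        rec = make_record("only", random_dna(250))
        (validated,) = validate_reference_set([rec])
        assert [c.status for c in validated.chunks] == [ChunkStatus.UNKNOWN] * 3
        assert [(c.start, c.end) for c in validated.chunks] == [(0, 100), (100, 200), (150, 250)]

    def test_duplicated_record_under_two_authors_all_homospecific(self, random_dna):
        seq = random_dna(300)
        r1 = make_record("r1", seq, authors=A1)
        r2 = make_record("r2", seq, authors=A2)
        for rec in validate_reference_set([r1, r2]):
            assert all(c.status is ChunkStatus.HOMOSPECIFIC for c in rec.chunks)

    def test_order_independence(self, random_dna):
        seq = random_dna(300)
        recs = [
            make_record("r1", seq, authors=A1),
            make_record("r2", seq, authors=A2),
            make_record("r3", random_dna(300), species="Aquaticus bravo", authors=A3),
        ]
        fwd = {r.record_id: [c.status for c in r.chunks] for r in validate_reference_set(recs)}
        rev = {r.record_id: [c.status for c in r.chunks] for r in validate_reference_set(recs[::-1])}
        assert fwd == rev


class TestBackgroundDb:
    def test_identical_sequences_one_centroid(self, random_dna):
        seq = random_dna(150)
        seqs = [(f"s{i}", seq, "human") for i in range(5)]
        assert len(build_background_db(seqs, set())) == 1

    def test_divergent_sequences_stay_apart(self, random_dna):
        seqs = [(f"s{i}", random_dna(150), "human") for i in range(3)]
        assert len(build_background_db(seqs, set())) == 3

    def test_fish_taxa_removed_first(self, random_dna):
        seqs = [("f", random_dna(150), "Aquaticus alpha"), ("h", random_dna(150), "human")]
        centroids = build_background_db(seqs, {"Aquaticus alpha"})
        assert [c[0] for c in centroids] == ["h"]

    def test_two_seed_families_collapse_to_two_centroids(self, random_dna):
        # oracle: all pairwise identities + a simulated greedy pass
        from oracles import simulate_greedy_clustering

        def mutate_pct(seq, k):
            out = list(seq)
            step = len(seq) // k
            for i in range(k):
                p = i * step
                out[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[p]]
            return "".join(out)

        seed_a, seed_b = random_dna(200), random_dna(200)
        family = [seed_a, seed_b]
        for i in range(1, 5):
            family.append(mutate_pct(seed_a, 2))  # 1% divergence
            family.append(mutate_pct(seed_b, 2))
        seqs = [(f"s{i:02d}", s, "human") for i, s in enumerate(family)]
        ordered = sorted(seqs, key=lambda s: (-len(s[1]), s[0]))
        expected = simulate_greedy_clustering(
            [s[1] for s in ordered], global_identity, 97.0
        )
        centroids = build_background_db(seqs, set())
        assert len(centroids) == expected == 2

    def test_centroid_count_invariant_under_duplication(self, random_dna):
        seqs = [(f"s{i}", random_dna(150), "human") for i in range(4)]
        base = build_background_db(seqs, set())
        for i in range(4):
            dup = seqs + [("dup", seqs[i][1], "human")]
            assert len(build_background_db(dup, set())) == len(base)
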