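import hashlib

import pytest

from fintax.annotate import (
    Category,
    DataIntegrityError,
    Taxonomy,
    annotate_asv,
    lowest_common_ancestor,
    md5_of_sequence,
    overlaps_heterospecific,
    summarize_tables,
)
from fintax.asv import ASV
from fintax.records import ChunkStatus, GeneChunk, TaxonLineage
from fintax.search import SimilarityHit


def lineage(species, genus, family="Alphidae", order="Primoformes", higher="Actinopterygii"):
    return TaxonLineage(species, genus, family, order, higher)


TAXONOMY = Taxonomy(
    [
        lineage("Aquaticus alpha", "Aquaticus"),
        lineage("Aquaticus bravo", "Aquaticus"),
        lineage("Aquaticus sp.", "Aquaticus"),
        lineage("Benthicus charlie", "Benthicus"),
        lineage("Currensis delta", "Currensis", family="Betidae", order="Secundoformes"),
    ]
)

SPECIES_MAP = {
    "refA": "Aquaticus alpha",
    "refA2": "Aquaticus alpha",
    "refB": "Aquaticus bravo",
    "refSp": "Aquaticus sp.",
    "refC": "Benthicus charlie",
    "refD": "Currensis delta",
    "bg_human": "human",
}


def hit(subject, identity=100.0, score=300.0, fish=True, start=0, end=150):
    mism = 0 if identity >= 100 else 1
    return SimilarityHit(
        "asv_1", subject, identity, 100.0, score, start, end,
        mismatches=mism, subject_is_fish=fish,
    )


ASV1 = ASV("asv_1", "ACGT" * 30, {"s1": 10})

HETERO = {"refB": [GeneChunk(0, 100, ChunkStatus.HETEROSPECIFIC),
                   GeneChunk(100, 200, ChunkStatus.HETEROSPECIFIC)]}


def annotate(hits, **kw):
    kw.setdefault("hetero_map", HETERO)
    return annotate_asv(ASV1, hits, TAXONOMY, SPECIES_MAP, **kw)


class TestDecisionTable:
    def test_no_hits_unassigned(self):
        res = annotate([])
        assert res.category is Category.UNASSIGNED
        assert res.evidence == () and res.taxa == ()

    def test_background_only_is_nonfish(self):
        res = annotate([hit("bg_human", fish=False)])
        assert res.category is Category.NONFISH
        assert res.taxa == ("human",)

    def test_subthreshold_single_species_reports_genus(self):
        res = annotate([hit("refA", identity=96.0)])
        assert res.category is Category.HIGHER_TAXON
        assert res.taxa == ("Aquaticus",) and res.rank == "genus"

    def test_subthreshold_cross_genus_reports_family(self):
        res = annotate([hit("refA", identity=96.0), hit("refC", identity=96.0)])
        assert res.category is Category.HIGHER_TAXON
        assert res.taxa == ("Alphidae",) and res.rank == "family"

    def test_single_species_at_full_identity(self):
        res = annotate([hit("refA")])
        assert res.category is Category.SPECIES
        assert res.taxa == ("Aquaticus alpha",)
        assert res.best_identity == 100.0

    def test_two_species_tie_is_a_complex(self):
        res = annotate([hit("refA", identity=99.5), hit("refC", identity=99.5)])
        assert res.category is Category.SPECIES_COMPLEX
        assert res.taxa == ("Aquaticus alpha", "Benthicus charlie")

    def test_nonbinomial_dropped_when_binomial_coexists(self):
        res = annotate([hit("refSp"), hit("refA")])
        assert res.category is Category.SPECIES
        assert res.taxa == ("Aquaticus alpha",)
        assert "nonbinomial-filtered" in res.notes

    def test_nonbinomials_alone_are_kept(self):
        res = annotate([hit("refSp")])
        assert res.category is Category.SPECIES
        assert res.taxa == ("Aquaticus sp.",)
        assert "nonbinomial-filtered" not in res.notes

    def test_heterospecific_species_excluded(self):
        res = annotate([hit("refA"), hit("refB")])  # refB hit sits in hetero chunks
        assert res.category is Category.SPECIES
        assert res.taxa == ("Aquaticus alpha",)
        assert "heterospecific-filtered" in res.notes

    def test_all_filtered_falls_back_flagged(self):
        res = annotate([hit("refB")])
        assert res.category is Category.SPECIES
        assert res.taxa == ("Aquaticus bravo",)
        assert "all-filtered-fallback" in res.notes

    def test_filter_can_be_disabled(self):
        res = annotate([hit("refA"), hit("refB")], hetero_filter=False)
        assert res.category is Category.SPECIES_COMPLEX
        assert res.taxa == ("Aquaticus alpha", "Aquaticus bravo")

    def test_fish_background_tie_classified_fish_with_flag(self):
        res = annotate([hit("refA"), hit("bg_human", fish=False)])
        assert res.category is Category.SPECIES
        assert "score-tie-with-nonfish" in res.notes

    def test_threshold_is_adjustable(self):
        hits = [hit("refA", identity=99.5)]
        assert annotate(hits, threshold=99.0).category is Category.SPECIES
        assert annotate(hits, threshold=99.6).category is Category.HIGHER_TAXON

    def test_unknown_reference_id_is_an_error(self):
        with pytest.raises(DataIntegrityError):
            annotate([hit("ghost")])

    def test_every_asv_gets_exactly_one_category(self):
        scenarios = [
            [],
            [hit("bg_human", fish=False)],
            [hit("refA", identity=96.0)],
            [hit("refA")],
            [hit("refA"), hit("refC")],
            [hit("refSp"), hit("refA")],
            [hit("refB")],
            [hit("refA"), hit("bg_human", fish=False)],
        ]
        for hits in scenarios:
            res = annotate(hits)
            assert isinstance(res.category, Category)

    def test_threshold_monotonicity(self):
        # raising the species threshold never moves an ASV from
        # higher_taxon back to species level
        hits = [hit("refA", identity=99.2)]
        was_higher = False
        for thr in (98.0, 99.0, 99.3, 99.8):
            cat = annotate(hits, threshold=thr).category
            if was_higher:
                assert cat is Category.HIGHER_TAXON
            was_higher = cat is Category.HIGHER_TAXON

    def test_hetero_filter_only_shrinks_the_complex(self):
        hits = [hit("refA"), hit("refB"), hit("refC")]
        with_filter = set(annotate(hits).taxa)
        without = set(annotate(hits, hetero_filter=False).taxa)
        assert with_filter <= without


class TestLCA:
    def test_shared_genus(self):
        assert lowest_common_ancestor(
            ["Aquaticus alpha", "Aquaticus bravo"], TAXONOMY
        ) == ("Aquaticus", "genus")

    def test_single_species_reports_its_genus(self):
        assert lowest_common_ancestor(["Benthicus charlie"], TAXONOMY) == ("Benthicus", "genus")

    def test_cross_order_reports_shared_higher_clade(self):
        assert lowest_common_ancestor(
            ["Aquaticus alpha", "Currensis delta"], TAXONOMY
        ) == ("Actinopterygii", "higher")

    def test_unknown_species_raises(self):
        with pytest.raises(KeyError):
            lowest_common_ancestor(["Ghostus nemo"], TAXONOMY)


class TestHeteroOverlap:
    CHUNKS = [GeneChunk(0, 100, ChunkStatus.HETEROSPECIFIC),
              GeneChunk(100, 200, ChunkStatus.HETEROSPECIFIC)]

    def test_fully_covered_hit(self):
        assert overlaps_heterospecific(hit("refB", start=0, end=170), self.CHUNKS)

    def test_disjoint_hit(self):
        chunks = [GeneChunk(900, 1000, ChunkStatus.HETEROSPECIFIC)]
        assert not overlaps_heterospecific(hit("refB", start=0, end=170), chunks)

    def test_exact_half_coverage_is_boundary_inclusive(self):
        chunks = [GeneChunk(100, 200, ChunkStatus.HETEROSPECIFIC)]
        assert overlaps_heterospecific(hit("refB", start=50, end=250), chunks)
        assert not overlaps_heterospecific(hit("refB", start=50, end=251), chunks)

    def test_overlapping_chunks_not_double_counted(self):
        chunks = [GeneChunk(100, 200, ChunkStatus.HETEROSPECIFIC),
                  GeneChunk(150, 250, ChunkStatus.HETEROSPECIFIC)]
        # union covers 100-250 = 150 of a 300-wide hit -> exactly half
        assert overlaps_heterospecific(hit("refB", start=0, end=300), chunks)


class TestMd5:
    def test_matches_independent_digest(self):
        assert md5_of_sequence("ACGT") == hashlib.md5(b"ACGT").hexdigest()

    def test_case_insensitive(self):
        assert md5_of_sequence("acgt") == md5_of_sequence("ACGT")

    def test_distinct_sequences_distinct_digests(self):
        assert md5_of_sequence("ACGT") != md5_of_sequence("ACGA")


class TestSummaries:
    def make_results(self):
        from fintax.annotate import AnnotationResult

        r1 = AnnotationResult("asv_1", Category.SPECIES, ("Aquaticus alpha",), 100.0, (hit("refA"),))
        r2 = AnnotationResult("asv_2", Category.SPECIES, ("Aquaticus alpha",), 100.0, (hit("refA2"),))
        r3 = AnnotationResult("asv_3", Category.HIGHER_TAXON, ("Aquaticus",), 96.0,
                              (hit("refA", identity=96.0),), rank="genus")
        r4 = AnnotationResult("asv_4", Category.NONFISH, ("human",), 100.0,
                              (hit("bg_human", fish=False),))
        r5 = AnnotationResult("asv_5", Category.UNASSIGNED, (), None, ())
        return [r1, r2, r3, r4, r5]

    COUNTS = {
        "asv_1": {"s1": 10, "s2": 0},
        "asv_2": {"s1": 5},
        "asv_3": {"s2": 7},
        "asv_4": {"s1": 2},
        "asv_5": {"s2": 1},
    }

    def test_same_species_asvs_aggregate(self):
        tables = summarize_tables(self.make_results(), self.COUNTS)
        assert tables.species.loc["Aquaticus alpha", "s1"] == 15

    def test_per_asv_tables_keep_md5(self):
        md5s = {"asv_3": md5_of_sequence("ACGT")}
        tables = summarize_tables(self.make_results(), self.COUNTS, md5s)
        row = tables.higher.iloc[0]
        assert row["asv_id"] == "asv_3"
        assert len(row["md5"]) == 32

    def test_read_count_conservation(self):
        tables = summarize_tables(self.make_results(), self.COUNTS)
        total_in = sum(sum(c.values()) for c in self.COUNTS.values())
        assert tables.total_reads() == total_in == 25
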