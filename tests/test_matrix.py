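import itertools

import pytest

from fintax.annotate import Taxonomy
from fintax.matrix import (
    ResultRows,
    SampleRole,
    annotate_habitat,
    build_matrix,
    compare_to_published,
    export_csv,
    filter_matrix,
    occurrence_proximity,
    parse_csv,
)
from fintax.records import HabitatProfile, OccurrenceRecord, TaxonLineage, UNKNOWN_HABITAT

MANIFEST = [
    SampleRole("r1", replicate_group="g"),
    SampleRole("r2", replicate_group="g"),
    SampleRole("pos", role="positive_control"),
    SampleRole("neg", role="negative_control"),
]


def matrix_for(pattern):
    r1, r2, pos, neg = pattern
    results = {
        "r1": {"Aquaticus alpha": 10 * r1},
        "r2": {"Aquaticus alpha": 10 * r2},
        "pos": {"Aquaticus alpha": 10 * pos},
        "neg": {"Aquaticus alpha": 10 * neg},
    }
    return build_matrix(results, MANIFEST)


class TestBadges:
    def test_exhaustive_truth_table(self):
        # every detection pattern over {2 replicates, 1 positive, 1 negative}
        for pattern in itertools.product((0, 1), repeat=4):
            r1, r2, pos, neg = pattern
            badges = matrix_for(pattern).badges["Aquaticus alpha"]
            assert ("P" in badges) == bool(pos), pattern
            assert ("N" in badges) == bool(neg), pattern
            assert ("S" in badges) == (r1 + r2 == 1), pattern

    def test_both_replicates_no_badges(self):
        assert matrix_for((1, 1, 0, 0)).badges["Aquaticus alpha"] == frozenset()

    def test_detection_elsewhere_suppresses_global_s(self):
        manifest = MANIFEST + [SampleRole("plain")]
        results = {
            "r1": {"Aquaticus alpha": 5},
            "r2": {},
            "pos": {},
            "neg": {},
            "plain": {"Aquaticus alpha": 5},
        }
        m_global = build_matrix(results, manifest, scope="global")
        assert "S" not in m_global.badges["Aquaticus alpha"]
        m_group = build_matrix(results, manifest, scope="group")
        assert "S" in m_group.badges["Aquaticus alpha"]

    def test_unknown_sample_rejected(self):
        with pytest.raises(ValueError):
            build_matrix({"ghost": {"Aquaticus alpha": 1}}, MANIFEST)

    def test_columns_follow_manifest_order_with_zero_fill(self):
        m = build_matrix({"r1": {"Aquaticus alpha": 3}}, MANIFEST)
        assert list(m.counts.columns) == ["r1", "r2", "pos", "neg"]
        assert m.counts.loc["Aquaticus alpha", "neg"] == 0


class TestCsvRoundTrip:
    def test_single_cell(self):
        m = build_matrix({"r1": {"Aquaticus alpha": 3}}, [SampleRole("r1")])
        back = parse_csv(export_csv(m))
        assert back.counts.equals(m.counts)
        assert back.badges == m.badges

    def test_label_with_comma_is_quoted(self):
        m = build_matrix({"r1": {"Aquaticus alpha, sensu lato": 3}}, [SampleRole("r1")])
        text = export_csv(m)
        assert '"Aquaticus alpha, sensu lato"' in text
        back = parse_csv(text)
        assert list(back.counts.index) == ["Aquaticus alpha, sensu lato"]

    def test_random_matrix_round_trip(self, rng):
        labels = [f"Species {chr(97 + i)}" for i in range(20)]
        samples = [f"s{i}" for i in range(6)]
        manifest = [SampleRole(s) for s in samples[:4]] + [
            SampleRole(samples[4], role="positive_control"),
            SampleRole(samples[5], role="negative_control"),
        ]
        results = {
            s: {lab: int(rng.integers(0, 50)) for lab in labels} for s in samples
        }
        m = build_matrix(results, manifest)
        back = parse_csv(export_csv(m))
        assert back.counts.equals(m.counts)
        assert back.badges == m.badges


class TestFilters:
    def make_matrix(self):
        habitat = {
            "Aquaticus alpha": HabitatProfile("Demersal", frozenset({"Freshwater"}), frozenset()),
            "Aquaticus bravo": HabitatProfile("Pelagic", frozenset({"Saltwater"}), frozenset()),
        }
        results = {"r1": {"Aquaticus alpha/Aquaticus bravo": 10, "Benthicus charlie": 5}}
        manifest = [SampleRole("r1"), SampleRole("neg", role="negative_control")]
        m = build_matrix(results, manifest,
                         members={"Aquaticus alpha/Aquaticus bravo": ("Aquaticus alpha", "Aquaticus bravo")},
                         habitat=habitat)
        return m

    def test_empty_predicate_is_identity(self):
        m = self.make_matrix()
        out = filter_matrix(m)
        assert out.counts.equals(m.counts)
        assert out.badges == m.badges

    def test_member_filter_shrinks_complex(self):
        m = self.make_matrix()
        out = filter_matrix(m, member_pred=lambda sp, prof: "Freshwater" in prof.salinity)
        assert "Aquaticus alpha" in out.counts.index
        assert "Aquaticus alpha/Aquaticus bravo" not in out.counts.index
        # unknown habitat members fail the predicate, dropping their row
        assert "Benthicus charlie" not in out.counts.index

    def test_row_filter_drops_badged_rows(self):
        results = {"r1": {"Aquaticus alpha": 5}, "neg": {"Aquaticus alpha": 2, "Benthicus charlie": 1}}
        manifest = [SampleRole("r1"), SampleRole("neg", role="negative_control")]
        m = build_matrix(results, manifest)
        out = filter_matrix(m, row_pred=lambda label, badges: "N" not in badges)
        assert list(out.counts.index) == []
        assert m.counts.shape[0] == 2  # original unchanged

    def test_idempotent(self):
        m = self.make_matrix()
        pred = lambda sp, prof: "Freshwater" in prof.salinity
        once = filter_matrix(m, member_pred=pred)
        twice = filter_matrix(once, member_pred=pred)
        assert once.counts.equals(twice.counts)
        assert once.badges == twice.badges


class TestHabitatAndOccurrence:
    def test_unknown_species_get_unknown_profile(self):
        table = {"Aquaticus alpha": HabitatProfile("Demersal")}
        out = annotate_habitat(["Aquaticus alpha", "Ghostus nemo"], table)
        assert out["Ghostus nemo"] is UNKNOWN_HABITAT
        assert out["Aquaticus alpha"].demers_pelag == "Demersal"

    def test_record_at_site_counts(self):
        occ = [OccurrenceRecord("Aquaticus alpha", 10.0, 20.0)]
        assert occurrence_proximity("Aquaticus alpha", (10.0, 20.0), 1.0, occ) == (True, 1)

    def test_no_records(self):
        assert occurrence_proximity("Aquaticus alpha", (0.0, 0.0), 1.0, []) == (False, 0)

    def test_longitude_wraps_at_antimeridian(self):
        occ = [OccurrenceRecord("Aquaticus alpha", 0.0, 179.5)]
        assert occurrence_proximity("Aquaticus alpha", (0.0, -179.8), 1.0, occ) == (True, 1)
        assert occurrence_proximity("Aquaticus alpha", (0.0, -170.0), 1.0, occ) == (False, 0)


class TestCompareToPublished:
    TAX = Taxonomy(
        [
            TaxonLineage("Aquaticus alpha", "Aquaticus", "Alphidae", "Primoformes", "Actinopterygii"),
            TaxonLineage("Aquaticus bravo", "Aquaticus", "Alphidae", "Primoformes", "Actinopterygii"),
            TaxonLineage("Benthicus charlie", "Benthicus", "Alphidae", "Primoformes", "Actinopterygii"),
            TaxonLineage("Currensis delta", "Currensis", "Betidae", "Secundoformes", "Actinopterygii"),
        ]
    )
    ROWS = ResultRows(
        singles=frozenset({"Aquaticus alpha"}),
        complexes=(("Aquaticus bravo", "Benthicus charlie"),),
        clades=frozenset({"Currensis"}),
    )

    def test_five_categories(self):
        published = [
            ("Aquaticus alpha", "species"),
            ("Aquaticus bravo", "species"),
            ("Currensis delta", "species"),
            ("Ghostus nemo", "species"),
            ("Aquaticus", "clade"),
        ]
        out = compare_to_published(self.ROWS, published, self.TAX)
        assert out == {
            "Aquaticus alpha": "Single",
            "Aquaticus bravo": "Multiple",
            "Currensis delta": "Clades",
            "Ghostus nemo": "Undetected",
            "Aquaticus": "Single",  # a species inside the clade was resolved
        }

    def test_diff_requires_assignment_evidence(self):
        published = [("Ghostus nemo", "species")]
        out = compare_to_published(
            self.ROWS, published, self.TAX, assignments={"Ghostus nemo": "Aquaticus alpha"}
        )
        assert out == {"Ghostus nemo": "Diff"}

    def test_partition_property(self):
        published = [
            ("Aquaticus alpha", "species"),
            ("Aquaticus bravo", "species"),
            ("Benthicus charlie", "species"),
            ("Currensis delta", "species"),
            ("Ghostus nemo", "species"),
            ("Currensis", "clade"),
            ("Betidae", "clade"),
        ]
        out = compare_to_published(self.ROWS, published, self.TAX)
        assert set(out) == {name for name, _ in published}
        assert all(cat in ("Single", "Multiple", "Clades", "Diff", "Undetected")
                   for cat in out.values())

    def test_bad_level_rejected(self):
        with pytest.raises(ValueError):
            compare_to_published(self.ROWS, [("x", "genus")], self.TAX)
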