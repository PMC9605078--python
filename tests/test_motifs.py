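"""Motif database and scanner: placements, frequencies, table regressions."""

import json

import pytest
from hypothesis import given
from hypothesis import strategies as st

from pepsilico import (
    ACE_INHIBITOR,
    ANTIOXIDATIVE,
    MotifDB,
    distinct_motif_count,
    load_motif_db,
    parse_peptide,
    scan_motifs,
)
from pepsilico.fixtures import load_fixture, parse_spans
from pepsilico.motifs import MotifDBError

from conftest import RESIDUES, brute_force_scan


class TestMotifDB:
    def test_bundled_db_covers_all_published_fragments(self, motif_db):
        ace = {str(r.fragment) for r in motif_db.fragments(ACE_INHIBITOR)}
        assert len(ace) >= 30
        anti = {str(r.fragment) for r in motif_db.fragments(ANTIOXIDATIVE)}
        assert anti == {"WPL", "GPP", "MM"}

    def test_fragment_lengths_restricted_to_di_tripeptides(self):
        with pytest.raises(MotifDBError, match="length"):
            MotifDB.from_records(
                [{"fragment": "GPPG", "activity": ACE_INHIBITOR, "name": ""}]
            )

    def test_duplicate_fragment_activity_rejected(self):
        rows = [
            {"fragment": "GP", "activity": ACE_INHIBITOR, "name": "a"},
            {"fragment": "GP", "activity": ACE_INHIBITOR, "name": "b"},
        ]
        with pytest.raises(MotifDBError, match="duplicate"):
            MotifDB.from_records(rows)

    def test_same_fragment_different_activity_allowed(self, motif_db):
        assert motif_db.lookup("MM", ANTIOXIDATIVE) is not None
        assert motif_db.lookup("MM", ACE_INHIBITOR) is not None

    def test_empty_db_valid(self):
        db = MotifDB([])
        assert len(db) == 0
        profile = scan_motifs(parse_peptide("GPGP"), db, ACE_INHIBITOR)
        assert profile.a == 0 and profile.frequency == 0

    def test_load_from_json(self, tmp_path):
        path = tmp_path / "db.json"
        path.write_text(
            json.dumps([{"fragment": "GP", "activity": ACE_INHIBITOR, "name": "x"}])
        )
        assert len(load_motif_db(path)) == 1

    def test_unknown_activity_rejected(self, motif_db):
        with pytest.raises(MotifDBError, match="unknown activity"):
            scan_motifs(parse_peptide("GP"), motif_db, "antimicrobial")


class TestScanExamples:
    def test_antioxidative_scan_gpgmmgp(self, motif_db):
        # True coordinates: the printed (5-6) cell is a known +1 shift.
        profile = scan_motifs(parse_peptide("GPGMMGP"), motif_db, ANTIOXIDATIVE)
        assert [(str(o.motif.fragment), o.span) for o in profile.occurrences] == [
            ("MM", (4, 5))
        ]

    def test_antioxidative_scan_gppgpqwpldf(self, motif_db):
        profile = scan_motifs(parse_peptide("GPPGPQWPLDF"), motif_db, ANTIOXIDATIVE)
        hits = {(str(o.motif.fragment), o.span) for o in profile.occurrences}
        assert hits == {("GPP", (1, 3)), ("WPL", (7, 9))}

    def test_ace_scan_apdmafpr_counts_placements(self, motif_db):
        profile = scan_motifs(parse_peptide("APDMAFPR"), motif_db, ACE_INHIBITOR)
        hits = {(str(o.motif.fragment), o.span) for o in profile.occurrences}
        assert hits == {
            ("AP", (1, 2)),
            ("DM", (3, 4)),
            ("AF", (5, 6)),
            ("AFP", (5, 7)),
            ("FP", (6, 7)),
            ("PR", (7, 8)),
        }
        assert profile.a == 6 and profile.frequency == pytest.approx(0.75)

    def test_ace_scan_gpgmmgp_repeated_gp(self, motif_db):
        profile = scan_motifs(parse_peptide("GPGMMGP"), motif_db, ACE_INHIBITOR)
        assert profile.a == 7  # GP placed twice
        assert distinct_motif_count(profile) == 6
        assert profile.frequency == pytest.approx(1.0)

    def test_richest_ace_profile(self, motif_db):
        profile = scan_motifs(parse_peptide("GPPGASGPLGIAGSM"), motif_db, ACE_INHIBITOR)
        assert distinct_motif_count(profile) == 17
        assert profile.a == 18

    def test_occurrences_sorted_by_start_then_length(self, motif_db):
        profile = scan_motifs(parse_peptide("GPPGPQWPLDF"), motif_db, ACE_INHIBITOR)
        keys = [(o.start, o.end - o.start) for o in profile.occurrences]
        assert keys == sorted(keys)


def _expected_from_fixture(fixture, sequence, loc_key, multi):
    expected = set()
    for row in fixture.rows:
        if row["sequence"] != sequence or row["fragment"] == "_":
            continue
        cell = row[f"{loc_key}_corrected"] or row[loc_key]
        for start, end in parse_spans(cell):
            expected.add((row["fragment"], start, end))
    return expected


class TestTableRegressions:
    """Scanning the 11 study peptides reproduces every published
    (fragment, location) cell, modulo the annotated printed errata."""

    @pytest.mark.parametrize("table,activity_key", [("table2", "location"), ("table3", "location")])
    def test_antioxidative_profiles(self, motif_db, table, activity_key):
        fixture = load_fixture(table)
        for sequence in {row["sequence"] for row in fixture.rows}:
            profile = scan_motifs(parse_peptide(sequence), motif_db, ANTIOXIDATIVE)
            got = {(str(o.motif.fragment), o.start, o.end) for o in profile.occurrences}
            assert got == _expected_from_fixture(fixture, sequence, activity_key, False), sequence

    @pytest.mark.parametrize("table", ["table4", "table5"])
    def test_ace_profiles(self, motif_db, table):
        fixture = load_fixture(table)
        for sequence in {row["sequence"] for row in fixture.rows}:
            profile = scan_motifs(parse_peptide(sequence), motif_db, ACE_INHIBITOR)
            got = {(str(o.motif.fragment), o.start, o.end) for o in profile.occurrences}
            assert got == _expected_from_fixture(fixture, sequence, "locations", True), sequence

    def test_motif_names_carried_through(self, motif_db):
        profile = scan_motifs(parse_peptide("GPPGPQWPLDF"), motif_db, ACE_INHIBITOR)
        names = {str(o.motif.fragment): o.motif.name for o in profile.occurrences}
        assert names["GP"] == "ACE inhibitor from Alaskan pollack skin"
        assert names["GPP"] == "ACE inhibitor from wheat gliadin"


class TestScannerProperties:
    @given(
        seq=st.text(alphabet=RESIDUES, min_size=1, max_size=40),
        frags=st.lists(
            st.text(alphabet=RESIDUES, min_size=2, max_size=3),
            min_size=1,
            max_size=15,
            unique=True,
        ),
    )
    def test_equivalence_with_brute_force_oracle(self, seq, frags):
        db = MotifDB.from_records(
            [{"fragment": f, "activity": ACE_INHIBITOR, "name": ""} for f in frags]
        )
        profile = scan_motifs(parse_peptide(seq), db, ACE_INHIBITOR)
        got = {(str(o.motif.fragment), o.start, o.end) for o in profile.occurrences}
        assert got == brute_force_scan(seq, frags)

    @given(seq=st.text(alphabet=RESIDUES, min_size=2, max_size=40))
    def test_reported_spans_match_fragment_text(self, seq, motif_db):
        profile = scan_motifs(parse_peptide(seq), motif_db, ACE_INHIBITOR)
        for occ in profile.occurrences:
            assert seq[occ.start - 1 : occ.end] == str(occ.motif.fragment)

    def test_oracle_equivalence_on_many_random_peptides(self, motif_db):
        # Large-batch agreement check with a fixed generator seed.
        import numpy as np

        rng = np.random.default_rng(20220928)
        frags = [str(r.fragment) for r in motif_db.fragments(ACE_INHIBITOR)]
        letters = np.array(list(RESIDUES))
        for _ in range(1000):
            seq = "".join(rng.choice(letters, size=rng.integers(2, 20)))
            profile = scan_motifs(parse_peptide(seq), motif_db, ACE_INHIBITOR)
            got = {(str(o.motif.fragment), o.start, o.end) for o in profile.occurrences}
            assert got == brute_force_scan(seq, frags)
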