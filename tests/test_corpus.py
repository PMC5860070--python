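"""Corpus data model, canonical-format round trips and the DAT adapter."""

import datetime
import io

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from annotrail.corpus import (
    EntryVersion,
    ReleaseTimeline,
    VersionedCorpus,
    parse_uniprot_dat,
    read_corpus,
    read_grouping,
    write_corpus,
)
from annotrail.errors import ConfigError, IntegrityError, ParseError
from annotrail.sentencise import extract_sentences

D1 = datetime.date(2001, 1, 1)
D2 = datetime.date(2002, 1, 1)


class TestTypes:
    def test_timeline_rejects_duplicate_releases(self):
        with pytest.raises(IntegrityError):
            ReleaseTimeline("D", (("r1", D1), ("r1", D2)))

    def test_timeline_rejects_decreasing_dates(self):
        with pytest.raises(IntegrityError):
            ReleaseTimeline("D", (("r1", D2), ("r2", D1)))

    def test_timeline_rejects_empty(self):
        with pytest.raises(IntegrityError):
            ReleaseTimeline("D", ())

    def test_entry_must_resolve_in_timeline(self):
        tl = ReleaseTimeline("D", (("r1", D1),))
        with pytest.raises(IntegrityError):
            VersionedCorpus([tl], [EntryVersion("D", "r9", "A", "x.")])
        with pytest.raises(IntegrityError):
            VersionedCorpus([tl], [EntryVersion("E", "r1", "A", "x.")])

    def test_duplicate_entry_version_rejected(self):
        tl = ReleaseTimeline("D", (("r1", D1),))
        ev = EntryVersion("D", "r1", "A", "x.")
        with pytest.raises(IntegrityError):
            VersionedCorpus([tl], [ev, ev])

    def test_default_grouping_is_identity(self):
        tl = ReleaseTimeline("D", (("r1", D1),))
        corpus = VersionedCorpus([tl])
        assert corpus.groups == {"D": "D"}


class TestCanonicalFormat:
    def test_empty_corpus_timeline_only(self, tmp_path):
        path = tmp_path / "c.tsv"
        path.write_text("T\tD\tr1\t2001-01-01\n")
        corpus = read_corpus(path)
        assert corpus.entries == ()
        assert corpus.timeline("D").release_ids == ("r1",)

    def test_singleton_record(self, tmp_path):
        path = tmp_path / "c.tsv"
        path.write_text("T\tD\tr1\t2001-01-01\nE\tD\tr1\tA\tx.\n")
        corpus = read_corpus(path)
        assert corpus.entries == (EntryVersion("D", "r1", "A", "x."),)

    def test_json_lines_dialect(self, tmp_path):
        path = tmp_path / "c.jsonl"
        path.write_text(
            '{"database": "D", "release": "r1", "date": "2001-01-01"}\n'
            '{"database": "D", "release": "r1", "entry": "A", "text": "x."}\n'
        )
        corpus = read_corpus(path)
        assert corpus.entries == (EntryVersion("D", "r1", "A", "x."),)

    def test_text_escaping_round_trip(self, tmp_path):
        tl = ReleaseTimeline("D", (("r1", D1),))
        tricky = "line one.\nline\ttwo with \\backslash."
        corpus = VersionedCorpus([tl], [EntryVersion("D", "r1", "A", tricky)])
        path = tmp_path / "c.tsv"
        write_corpus(corpus, path)
        assert read_corpus(path) == corpus

    def test_malformed_record_names_line(self, tmp_path):
        path = tmp_path / "c.tsv"
        path.write_text("T\tD\tr1\t2001-01-01\nX\tbogus\n")
        with pytest.raises(ParseError, match="line 2"):
            read_corpus(path)

    def test_unknown_release_is_integrity_error(self, tmp_path):
        path = tmp_path / "c.tsv"
        path.write_text("T\tD\tr1\t2001-01-01\nE\tD\tr9\tA\tx.\n")
        with pytest.raises(IntegrityError):
            read_corpus(path)

    def test_writes_are_byte_identical(self, tmp_path):
        tl = ReleaseTimeline("D", (("r1", D1), ("r2", D2)))
        corpus = VersionedCorpus(
            [tl],
            [
                EntryVersion("D", "r2", "B", "b."),
                EntryVersion("D", "r1", "A", "a."),
            ],
        )
        p1, p2 = tmp_path / "1.tsv", tmp_path / "2.tsv"
        write_corpus(corpus, p1)
        write_corpus(corpus, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_record_order_irrelevant(self, tmp_path):
        lines = [
            "T\tD\tr1\t2001-01-01",
            "E\tD\tr1\tB\tb.",
            "E\tD\tr1\tA\ta.",
        ]
        p1, p2 = tmp_path / "1.tsv", tmp_path / "2.tsv"
        p1.write_text("\n".join(lines) + "\n")
        p2.write_text("\n".join([lines[0], lines[2], lines[1]]) + "\n")
        assert read_corpus(p1) == read_corpus(p2)

    @given(
        st.lists(
            st.tuples(
                st.sampled_from(["D1", "D2", "D3"]),
                st.integers(0, 2),
                st.sampled_from(["A", "B", "C", "Δ-entry"]),
                st.text(
                    alphabet=st.characters(blacklist_categories=("Cs",)),
                    max_size=40,
                ),
            ),
            max_size=12,
            unique_by=lambda t: (t[0], t[1], t[2]),
        )
    )
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_round_trip_property(self, rows):
        timelines = [
            ReleaseTimeline(
                db,
                tuple(
                    (f"r{i}", D1 + datetime.timedelta(days=30 * i))
                    for i in range(3)
                ),
            )
            for db in ("D1", "D2", "D3")
        ]
        corpus = VersionedCorpus(
            timelines,
            [EntryVersion(db, f"r{r}", e, text) for db, r, e, text in rows],
        )
        buf = io.StringIO()
        write_corpus(corpus, buf)
        buf.seek(0)
        assert read_corpus(buf) == corpus


DAT_EXAMPLE = """\
ID   PAX6_HUMAN
AC   O18381; Q9W5Z2;
DE   Paired box protein.
CC   -!- FUNCTION: May be a transcription factor with important functions
CC       in eye and nasal development.
SQ   SEQUENCE
//
"""


class TestUniprotDatAdapter:
    def test_worked_example_text(self):
        entries = parse_uniprot_dat(DAT_EXAMPLE, "SwissProt", "r1")
        assert len(entries) == 1
        ev = entries[0]
        assert ev.entry_id == "O18381"
        assert ev.text == (
            "May be a transcription factor with important functions in eye "
            "and nasal development."
        )

    def test_entry_without_cc_has_empty_text(self):
        dat = "ID   X\nAC   P00001;\nDE   Something.\n//\n"
        entries = parse_uniprot_dat(dat, "SP", "r1")
        assert entries == [EntryVersion("SP", "r1", "P00001", "")]

    def test_two_topics_stay_separate(self):
        dat = (
            "AC   P00002;\n"
            "CC   -!- FUNCTION: Binds DNA and regulates\n"
            "CC       transcription of target genes\n"
            "CC   -!- SUBCELLULAR LOCATION: Nucleus.\n"
            "//\n"
        )
        entries = parse_uniprot_dat(dat, "SP", "r1")
        text = entries[0].text
        assert "\n\n" in text
        per_block = [extract_sentences(b) for b in text.split("\n\n")]
        assert extract_sentences(text) == [s for b in per_block for s in b]
        assert len(extract_sentences(text)) == 2

    def test_topic_filter(self):
        dat = (
            "AC   P00003;\n"
            "CC   -!- FUNCTION: Binds DNA.\n"
            "CC   -!- SUBCELLULAR LOCATION: Nucleus.\n"
            "//\n"
        )
        entries = parse_uniprot_dat(dat, "SP", "r1", topics={"FUNCTION"})
        assert entries[0].text == "Binds DNA."

    def test_missing_ac_skipped_with_warning(self, caplog):
        dat = "ID   X\nCC   -!- FUNCTION: Something.\n//\nAC   P1;\n//\n"
        with caplog.at_level("WARNING"):
            entries = parse_uniprot_dat(dat, "SP", "r1")
        assert [e.entry_id for e in entries] == ["P1"]
        assert any("no AC line" in r.message for r in caplog.records)

    def test_truncated_final_entry_raises(self):
        dat = "AC   P1;\n//\nAC   P2;\nCC   -!- FUNCTION: Lost.\n"
        with pytest.raises(ParseError):
            parse_uniprot_dat(dat, "SP", "r1")

    def test_entry_order_permutation_same_set(self):
        a = "AC   P1;\nCC   -!- FUNCTION: One.\n//\n"
        b = "AC   P2;\nCC   -!- FUNCTION: Two.\n//\n"
        assert set(parse_uniprot_dat(a + b, "SP", "r1")) == set(
            parse_uniprot_dat(b + a, "SP", "r1")
        )


class TestGrouping:
    def test_yaml_mapping(self, tmp_path):
        p = tmp_path / "g.yml"
        p.write_text("SwissProt: UniProtKB\nTrEMBL: UniProtKB\nInterPro: InterPro\n")
        assert read_grouping(p) == {
            "SwissProt": "UniProtKB",
            "TrEMBL": "UniProtKB",
            "InterPro": "InterPro",
        }

    def test_flat_key_value(self, tmp_path):
        p = tmp_path / "g.cfg"
        p.write_text("# comment\nSwissProt = UniProtKB\nTrEMBL = UniProtKB\n")
        assert read_grouping(p) == {
            "SwissProt": "UniProtKB",
            "TrEMBL": "UniProtKB",
        }

    def test_empty_config_rejected(self, tmp_path):
        p = tmp_path / "g.cfg"
        p.write_text("\n")
        with pytest.raises(ConfigError):
            read_grouping(p)
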