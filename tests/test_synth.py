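"""Synthetic-ecosystem generator: determinism, soundness, edit process."""

import datetime
import io
import random

import pytest

from annotrail.corpus import write_corpus
from annotrail.errors import ConfigError
from annotrail.index import build_index
from annotrail.patterns import pattern_summary
from annotrail.synth import (
    BackgroundRates,
    DatabaseSpec,
    GroundTruth,
    PlantCounts,
    PlantedInstance,
    SynthConfig,
    edit_sentence,
    generate,
    verify_ground_truth,
)


def small_config(**kwargs) -> SynthConfig:
    defaults = dict(
        seed=42,
        databases=(
            DatabaseSpec("D1", 5, datetime.date(2001, 1, 1), 365, 8),
            DatabaseSpec("D2", 5, datetime.date(2001, 1, 1), 365, 8),
        ),
    )
    defaults.update(kwargs)
    return SynthConfig(**defaults)


class TestGenerate:
    def test_inert_corpus_is_pattern_free(self):
        corpus, truth = generate(small_config())
        idx = build_index(corpus)
        for db in ("D1", "D2"):
            s = pattern_summary(idx, db)
            assert (s.missing_origin, s.transient, s.possibly_transient) == (0, 0, 0)
        assert truth.planted == ()

    def test_everything_born_at_release_one_persists(self):
        corpus, _ = generate(small_config())
        idx = build_index(corpus)
        for db in ("D1", "D2"):
            tl = idx.timeline(db)
            assert idx.sentences_at(db, tl.release_ids[0]) == idx.sentences_at(
                db, tl.latest
            )

    def test_planted_transient_recovered_exactly(self):
        from annotrail.patterns import detect_transient

        cfg = small_config(seed=42, planted=PlantCounts(transient=5))
        corpus, truth = generate(cfg)
        idx = build_index(corpus)
        got = {
            e.sentence for db in ("D1", "D2") for e in detect_transient(idx, db)
        }
        assert got == truth.sentences("transient")

    def test_byte_identical_across_runs(self):
        cfg = small_config(
            background=BackgroundRates(birth=0.2, copy=0.2, removal=0.1, edit=0.05),
            planted=PlantCounts(2, 2, 2, 2),
        )
        bufs = []
        for _ in range(2):
            corpus, truth = generate(cfg)
            buf = io.StringIO()
            write_corpus(corpus, buf)
            bufs.append((buf.getvalue(), truth))
        assert bufs[0][0] == bufs[1][0]
        assert bufs[0][1] == bufs[1][1]

    def test_infeasible_planting_rejected(self):
        cfg = SynthConfig(
            seed=1,
            databases=(DatabaseSpec("D1", 2, datetime.date(2001, 1, 1), 365, 4),),
            planted=PlantCounts(missing_origin=1),
        )
        with pytest.raises(ConfigError):
            generate(cfg)

    def test_bad_rates_rejected(self):
        with pytest.raises(ConfigError):
            BackgroundRates(birth=1.5)

    @pytest.mark.parametrize("seed", range(20))
    def test_soundness_on_random_configs(self, seed):
        rng = random.Random(seed)
        n_rel = rng.randint(3, 6)
        cfg = SynthConfig(
            seed=seed,
            databases=tuple(
                DatabaseSpec(
                    f"D{i}",
                    n_rel,
                    datetime.date(2000 + i, 1, 1),
                    rng.choice([180, 365]),
                    rng.randint(2, 6),
                )
                for i in range(rng.randint(1, 3))
            ),
            background=BackgroundRates(
                birth=rng.random() * 0.3,
                copy=rng.random() * 0.3,
                removal=rng.random() * 0.2,
                edit=rng.random() * 0.1,
            ),
            planted=PlantCounts(
                transient=rng.randint(0, 3),
                possibly_transient=rng.randint(0, 3),
                missing_origin=rng.randint(0, 3),
                cross_db_missing_origin=0,
            ),
        )
        corpus, truth = generate(cfg)
        assert verify_ground_truth(corpus, truth).ok


class TestEditSentence:
    def test_never_returns_input(self):
        rng = random.Random(0)
        for _ in range(50):
            s = "the protein binds dna replication in the nucleus (statement 3)."
            assert edit_sentence(s, rng) != s

    def test_deterministic_under_fixed_state(self):
        s = "the enzyme regulates gene expression during development."
        assert edit_sentence(s, random.Random(9)) == edit_sentence(
            s, random.Random(9)
        )

    def test_single_token_rejected(self):
        with pytest.raises(ConfigError):
            edit_sentence("lonely.", random.Random(0))

    def test_edited_copies_break_exact_match_recovery(self):
        """With forced edits on cross-database copies, exact matching finds
        none of the planted cross-database instances."""
        from annotrail.crossdb import cross_missing_origin

        cfg = small_config(
            seed=13,
            databases=(
                DatabaseSpec("D1", 8, datetime.date(2000, 1, 1), 365, 10),
                DatabaseSpec("D2", 8, datetime.date(2000, 1, 1), 365, 10),
            ),
            planted=PlantCounts(cross_db_missing_origin=8),
            force_edit_cross_copies=True,
        )
        corpus, truth = generate(cfg)
        idx = build_index(corpus)
        grouping = {"D1": "G1", "D2": "G2"}
        got = {
            c.sentence
            for s, t in (("G1", "G2"), ("G2", "G1"))
            for c in cross_missing_origin(idx, grouping, s, t)
        }
        assert got & truth.sentences("cross_db_missing_origin") == set()
        assert all(p.edited_in_target for p in truth.by_label("cross_db_missing_origin"))


class TestVerifyGroundTruth:
    def _planted(self):
        cfg = small_config(seed=3, planted=PlantCounts(transient=2))
        return generate(cfg)

    def test_generator_output_clean(self):
        corpus, truth = self._planted()
        assert verify_ground_truth(corpus, truth).violations == ()

    def test_deleted_occurrence_detected(self):
        corpus, truth = self._planted()
        inst = truth.by_label("transient")[0]
        db, entry, rid, sentence = inst.occurrences[0]
        from annotrail.corpus import EntryVersion, VersionedCorpus

        mutated_entries = [
            EntryVersion(e.database, e.release_id, e.entry_id, "")
            if (e.database, e.entry_id, e.release_id) == (db, entry, rid)
            else e
            for e in corpus.entries
        ]
        mutated = VersionedCorpus(corpus.timelines.values(), mutated_entries)
        report = verify_ground_truth(mutated, truth)
        assert len(report.violations) == 1
        assert "missing occurrence" in report.violations[0]

    def test_fictitious_tuple_detected(self):
        corpus, truth = self._planted()
        fake = PlantedInstance(
            label="transient",
            sentence="xq-planted fabricated sentence never realized.",
            occurrences=(
                ("D1", "D1_E0000", "D1_r01", "xq-planted fabricated sentence never realized."),
            ),
        )
        report = verify_ground_truth(corpus, GroundTruth(truth.planted + (fake,)))
        assert len(report.violations) == 1

    def test_jsonl_round_trip(self, tmp_path):
        _, truth = self._planted()
        p = tmp_path / "truth.jsonl"
        truth.write_jsonl(p)
        assert GroundTruth.read_jsonl(p) == truth


def test_config_yaml_round_trip(tmp_path):
    p = tmp_path / "cfg.yml"
    p.write_text(
        """
seed: 42
databases:
  - {label: D1, n_releases: 5, start_date: 2001-01-01, period_days: 365, n_entries: 8}
  - {label: D2, n_releases: 5, start_date: 2001-01-01, period_days: 365, n_entries: 8}
planted: {transient: 2}
background: {birth: 0.1}
"""
    )
    cfg = SynthConfig.from_yaml(p)
    assert cfg.seed == 42
    assert cfg.planted.transient == 2
    assert cfg.background.birth == 0.1
    assert cfg.databases[1].label == "D2"
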