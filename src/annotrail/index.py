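"""Occurrence index: sentence ↔ (database, entry, release) with presence runs.

The index is the backbone of every measure and detector.  It stores two
views of the same extraction:

* a **multiplicity map** ``(database, release, sentence) → slot count`` in
  which duplicate sentences within one entry are counted once per slot —
  this is what "total sentences" (the redundant count) sums over; and
* a **binary presence** relation per (sentence, database, entry) over
  release ordinals — this is what lifetimes (:class:`PresenceRun`) are
  computed from: a run models entry *membership* over time, so a sentence
  is simply present or absent in an entry at a release.

An entry absent from a release (deleted, or not yet created) contributes no
occurrences there, so deletion terminates all of its runs.

The index persists to a single-file SQLite database with tables
``releases(database, release_id, ordinal, date)``, ``sentences(id, key)``
and ``occurrences(sentence_id, database, entry_id, release_ordinal,
slot_count)``.
"""

from __future__ import annotations

import sqlite3
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable

from .corpus import ReleaseTimeline, VersionedCorpus
from .errors import UnknownDatabaseError
from .sentencise import extract_sentences, split_sentences

__all__ = [
    "Occurrence",
    "PresenceRun",
    "OccurrenceIndex",
    "build_index",
    "occurrences_of",
    "presence_runs",
    "sentence_multiplicity",
    "save_index",
    "load_index",
]


@dataclass(frozen=True, order=True)
class Occurrence:
    """One sentence sitting in one entry at one release (binary)."""

    sentence: str
    database: str
    entry_id: str
    release_id: str


@dataclass(frozen=True, order=True)
class PresenceRun:
    """Maximal contiguous interval of releases a sentence spends in an entry.

    ``start_idx``/``end_idx`` are ordinals into the database's timeline.
    ``censored`` is true iff the run touches the latest release, in which
    case its true end is unobservable.
    """

    database: str
    entry_id: str
    sentence: str
    start_idx: int
    end_idx: int
    censored: bool

    @property
    def length(self) -> int:
        return self.end_idx - self.start_idx + 1


class OccurrenceIndex:
    """Bidirectional sentence ↔ occurrence map over a versioned corpus."""

    def __init__(self, timelines: dict[str, ReleaseTimeline]):
        self._timelines = dict(timelines)
        # (db, ordinal) -> Counter{sentence: slot_count}
        self._slots: dict[tuple[str, int], Counter] = {
            (db, i): Counter()
            for db, tl in self._timelines.items()
            for i in range(len(tl))
        }
        # sentence -> (db, entry) -> sorted-on-demand set of ordinals
        self._presence: dict[str, dict[tuple[str, str], set[int]]] = {}
        # db -> lifetime sentence set
        self._db_sentences: dict[str, set[str]] = {db: set() for db in self._timelines}
        # (sentence, db, entry, ordinal) -> slot count, recorded only when > 1
        self._entry_counts: dict[tuple[str, str, str, int], int] = {}

    # -- construction -----------------------------------------------------

    @classmethod
    def from_corpus(
        cls,
        corpus: VersionedCorpus,
        splitter: Callable[[str], list[str]] = split_sentences,
        min_chars: int = 0,
    ) -> "OccurrenceIndex":
        idx = cls(corpus.timelines)
        for ev in corpus.entries:
            ordinal = corpus.timelines[ev.database].ordinal(ev.release_id)
            keys = extract_sentences(ev.text, splitter=splitter, min_chars=min_chars)
            if not keys:
                continue
            slot = idx._slots[(ev.database, ordinal)]
            for key in keys:
                slot[key] += 1
            per_entry = Counter(keys)
            for key, count in per_entry.items():
                idx._presence.setdefault(key, {}).setdefault(
                    (ev.database, ev.entry_id), set()
                ).add(ordinal)
                idx._db_sentences[ev.database].add(key)
                if count > 1:
                    idx._entry_counts[
                        (key, ev.database, ev.entry_id, ordinal)
                    ] = count
        return idx

    # -- basic queries -----------------------------------------------------

    @property
    def databases(self) -> tuple[str, ...]:
        return tuple(sorted(self._timelines))

    def timeline(self, database: str) -> ReleaseTimeline:
        try:
            return self._timelines[database]
        except KeyError:
            raise UnknownDatabaseError(f"unknown database {database!r}") from None

    def _ordinal(self, database: str, release_id: str) -> int:
        return self.timeline(database).ordinal(release_id)

    def multiplicity(self, database: str, release_id: str, sentence: str) -> int:
        """Entry-slot count of ``sentence`` at one release (within-entry
        duplicates counted)."""
        return self._slots[(database, self._ordinal(database, release_id))].get(
            sentence, 0
        )

    def release_counter(self, database: str, release_id: str) -> Counter:
        """The full multiplicity map of one release (do not mutate)."""
        return self._slots[(database, self._ordinal(database, release_id))]

    def total_sentences(self, database: str, release_id: str) -> int:
        return sum(self.release_counter(database, release_id).values())

    def sentences_at(self, database: str, release_id: str) -> set[str]:
        return set(self.release_counter(database, release_id))

    def lifetime_sentences(self, database: str) -> set[str]:
        if database not in self._timelines:
            raise UnknownDatabaseError(f"unknown database {database!r}")
        return set(self._db_sentences[database])

    def sentences(self) -> set[str]:
        return set(self._presence)

    def occurrences_of(
        self, sentence: str, database: str | None = None
    ) -> set[Occurrence]:
        """Exact support set of a sentence; ∅ for an unseen sentence."""
        if database is not None and database not in self._timelines:
            raise UnknownDatabaseError(f"unknown database {database!r}")
        out: set[Occurrence] = set()
        for (db, entry), ordinals in self._presence.get(sentence, {}).items():
            if database is not None and db != database:
                continue
            tl = self._timelines[db]
            for i in ordinals:
                out.add(Occurrence(sentence, db, entry, tl.release_id(i)))
        return out

    def entry_presence(self, sentence: str, database: str) -> dict[str, set[int]]:
        """entry_id → set of release ordinals where the sentence is present."""
        self.timeline(database)
        return {
            entry: set(ordinals)
            for (db, entry), ordinals in self._presence.get(sentence, {}).items()
            if db == database
        }

    def presence_runs(
        self, sentence: str, database: str, entry_id: str
    ) -> list[PresenceRun]:
        """Maximal runs of ``sentence`` in ``entry_id``, sorted; [] if absent."""
        tl = self.timeline(database)
        ordinals = sorted(
            self._presence.get(sentence, {}).get((database, entry_id), ())
        )
        last = len(tl) - 1
        runs: list[PresenceRun] = []
        for i in ordinals:
            if runs and i == runs[-1].end_idx + 1:
                prev = runs[-1]
                runs[-1] = PresenceRun(
                    database, entry_id, sentence, prev.start_idx, i, i == last
                )
            else:
                runs.append(
                    PresenceRun(database, entry_id, sentence, i, i, i == last)
                )
        return runs

    def all_runs(self, database: str) -> Iterable[PresenceRun]:
        """Every presence run of every (sentence, entry) pair in a database."""
        self.timeline(database)
        for sentence, by_entry in self._presence.items():
            for (db, entry), _ in by_entry.items():
                if db == database:
                    yield from self.presence_runs(sentence, database, entry)

    def __eq__(self, other) -> bool:
        if not isinstance(other, OccurrenceIndex):
            return NotImplemented
        return (
            self._timelines == other._timelines
            and {k: c for k, c in self._slots.items() if c}
            == {k: c for k, c in other._slots.items() if c}
            and self._presence == other._presence
            and self._entry_counts == other._entry_counts
        )

    # -- persistence -------------------------------------------------------

    def save(self, path: str | Path) -> None:
        con = sqlite3.connect(path)
        try:
            cur = con.cursor()
            cur.executescript(
                """
                DROP TABLE IF EXISTS releases;
                DROP TABLE IF EXISTS sentences;
                DROP TABLE IF EXISTS occurrences;
                CREATE TABLE releases(
                    "database" TEXT, release_id TEXT, ordinal INTEGER, date TEXT,
                    PRIMARY KEY ("database", ordinal));
                CREATE TABLE sentences(id INTEGER PRIMARY KEY, key TEXT UNIQUE);
                CREATE TABLE occurrences(
                    sentence_id INTEGER, "database" TEXT, entry_id TEXT,
                    release_ordinal INTEGER, slot_count INTEGER);
                """
            )
            for db in sorted(self._timelines):
                tl = self._timelines[db]
                cur.executemany(
                    "INSERT INTO releases VALUES (?,?,?,?)",
                    [
                        (db, rid, i, date.isoformat())
                        for i, (rid, date) in enumerate(tl.releases)
                    ],
                )
            sent_ids: dict[str, int] = {}
            for sid, key in enumerate(sorted(self._presence), start=1):
                sent_ids[key] = sid
                cur.execute("INSERT INTO sentences VALUES (?,?)", (sid, key))
            rows = []
            for key, by_entry in self._presence.items():
                sid = sent_ids[key]
                for (db, entry), ordinals in by_entry.items():
                    for i in sorted(ordinals):
                        rows.append(
                            (
                                sid,
                                db,
                                entry,
                                i,
                                self._entry_counts.get((key, db, entry, i), 1),
                            )
                        )
            cur.executemany("INSERT INTO occurrences VALUES (?,?,?,?,?)", rows)
            con.commit()
        finally:
            con.close()

    @classmethod
    def load(cls, path: str | Path) -> "OccurrenceIndex":
        import datetime

        con = sqlite3.connect(path)
        try:
            cur = con.cursor()
            by_db: dict[str, list[tuple[int, str, str]]] = {}
            for db, rid, i, date in cur.execute(
                'SELECT "database", release_id, ordinal, date FROM releases'
            ):
                by_db.setdefault(db, []).append((i, rid, date))
            timelines = {
                db: ReleaseTimeline(
                    db,
                    tuple(
                        (rid, datetime.date.fromisoformat(date))
                        for _, rid, date in sorted(rows)
                    ),
                )
                for db, rows in by_db.items()
            }
            idx = cls(timelines)
            keys = dict(cur.execute("SELECT id, key FROM sentences"))
            for sid, db, entry, i, slots in cur.execute(
                'SELECT sentence_id, "database", entry_id, release_ordinal,'
                " slot_count FROM occurrences"
            ):
                key = keys[sid]
                idx._slots[(db, i)][key] += slots
                idx._presence.setdefault(key, {}).setdefault((db, entry), set()).add(i)
                idx._db_sentences[db].add(key)
                if slots != 1:
                    idx._entry_counts[(key, db, entry, i)] = slots
            return idx
        finally:
            con.close()


# ---------------------------------------------------------------------------
# Functional surface (thin wrappers over the methods)


def build_index(
    corpus: VersionedCorpus,
    splitter: Callable[[str], list[str]] = split_sentences,
    min_chars: int = 0,
) -> OccurrenceIndex:
    """Extract every entry's sentences and build the occurrence index."""
    return OccurrenceIndex.from_corpus(corpus, splitter=splitter, min_chars=min_chars)


def occurrences_of(
    index: OccurrenceIndex, sentence: str, database: str | None = None
) -> set[Occurrence]:
    return index.occurrences_of(sentence, database)


def presence_runs(
    index: OccurrenceIndex, sentence: str, database: str, entry_id: str
) -> list[PresenceRun]:
    return index.presence_runs(sentence, database, entry_id)


def sentence_multiplicity(
    index: OccurrenceIndex, database: str, release_id: str, sentence: str
) -> int:
    return index.multiplicity(database, release_id, sentence)


def save_index(index: OccurrenceIndex, path: str | Path) -> None:
    index.save(path)


def load_index(path: str | Path) -> OccurrenceIndex:
    return OccurrenceIndex.load(path)
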