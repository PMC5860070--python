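"""Versioned-annotation corpus data model and I/O.

A *versioned corpus* is the raw material of all reuse analysis: for every
database it carries a dated release calendar (:class:`ReleaseTimeline`) and,
for every release in which an entry existed, one :class:`EntryVersion`
holding that entry's plain-text annotation block.  Entry deletion between
releases is represented simply by the absence of the record — there are no
tombstones; downstream code treats absence as removal.

Release dates are upper bounds on when a sentence entered an entry: a
database is developed continuously but published periodically, so the best
statement one can make is "this sentence was present by the date of release
*r*".

Two interchange dialects are supported on disk, line-delimited and freely
mixable per file:

* tab-separated records::

      T <tab> database <tab> release_id <tab> ISO-8601 date
      E <tab> database <tab> release_id <tab> entry_id <tab> text

  with tabs, newlines and backslashes in ``text`` escaped as ``\\t``,
  ``\\n`` and ``\\\\``;

* JSON lines with keys ``{"database","release","date"}`` for timeline
  records and ``{"database","release","entry","text"}`` for entry records.

An adapter for UniProtKB-style DAT flat files harvests CC comment blocks
into :class:`EntryVersion` records (:func:`parse_uniprot_dat`).
"""

from __future__ import annotations

import datetime
import io
import json
import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, TextIO

import yaml

from .errors import ConfigError, IntegrityError, ParseError, UnknownReleaseError

logger = logging.getLogger(__name__)

__all__ = [
    "ReleaseTimeline",
    "EntryVersion",
    "VersionedCorpus",
    "read_corpus",
    "write_corpus",
    "parse_uniprot_dat",
    "read_grouping",
]


@dataclass(frozen=True)
class ReleaseTimeline:
    """Ordered, dated release calendar of one database.

    Release ordering is positional (sequence order), not date order: dates
    may tie, and within a database the publication sequence is what defines
    "the next release".  Dates are used only when comparing databases.
    """

    database: str
    releases: tuple[tuple[str, datetime.date], ...]

    def __post_init__(self):
        if not self.database:
            raise IntegrityError("timeline requires a non-empty database id")
        if not self.releases:
            raise IntegrityError(
                f"timeline for {self.database!r} must list at least one release"
            )
        ids = [r for r, _ in self.releases]
        if len(set(ids)) != len(ids):
            raise IntegrityError(
                f"duplicate release ids in timeline for {self.database!r}"
            )
        dates = [d for _, d in self.releases]
        if any(b < a for a, b in zip(dates, dates[1:])):
            raise IntegrityError(
                f"release dates for {self.database!r} must be non-decreasing"
            )
        object.__setattr__(
            self, "_ordinals", {rid: i for i, (rid, _) in enumerate(self.releases)}
        )

    def __len__(self) -> int:
        return len(self.releases)

    def ordinal(self, release_id: str) -> int:
        try:
            return self._ordinals[release_id]
        except KeyError:
            raise UnknownReleaseError(
                f"release {release_id!r} not in timeline of {self.database!r}"
            ) from None

    def __contains__(self, release_id: str) -> bool:
        return release_id in self._ordinals

    def release_id(self, ordinal: int) -> str:
        return self.releases[ordinal][0]

    def date(self, release_id: str) -> datetime.date:
        return self.releases[self.ordinal(release_id)][1]

    def date_at(self, ordinal: int) -> datetime.date:
        return self.releases[ordinal][1]

    @property
    def latest(self) -> str:
        return self.releases[-1][0]

    @property
    def release_ids(self) -> tuple[str, ...]:
        return tuple(r for r, _ in self.releases)


@dataclass(frozen=True)
class EntryVersion:
    """One entry's annotation text in one database release."""

    database: str
    release_id: str
    entry_id: str
    text: str

    def __post_init__(self):
        if not self.entry_id:
            raise IntegrityError("entry_id must be non-empty")
        if not self.database or not self.release_id:
            raise IntegrityError("database and release_id must be non-empty")


class VersionedCorpus:
    """Timelines plus entry versions; the unit all modules consume.

    Every database referenced by an entry must have a timeline, and the
    entry's release must appear in it.  Each database belongs to exactly
    one *group* (default: its own name); grouping collapses sibling
    databases — e.g. Swiss-Prot + TrEMBL into UniProtKB — for
    cross-database analysis.
    """

    def __init__(
        self,
        timelines: Iterable[ReleaseTimeline],
        entries: Iterable[EntryVersion] = (),
        groups: Mapping[str, str] | None = None,
    ):
        self.timelines: dict[str, ReleaseTimeline] = {}
        for tl in timelines:
            if tl.database in self.timelines:
                raise IntegrityError(f"duplicate timeline for {tl.database!r}")
            self.timelines[tl.database] = tl
        self._entries: dict[tuple[str, str, str], EntryVersion] = {}
        for ev in entries:
            self.add_entry(ev)
        self.groups: dict[str, str] = {db: db for db in self.timelines}
        if groups:
            for db, grp in groups.items():
                if db in self.groups:
                    self.groups[db] = grp

    def add_entry(self, ev: EntryVersion) -> None:
        tl = self.timelines.get(ev.database)
        if tl is None:
            raise IntegrityError(
                f"entry {ev.entry_id!r} references database {ev.database!r} "
                "with no timeline"
            )
        if ev.release_id not in tl:
            raise IntegrityError(
                f"entry {ev.entry_id!r} references unknown release "
                f"{ev.release_id!r} of {ev.database!r}"
            )
        key = (ev.database, ev.release_id, ev.entry_id)
        if key in self._entries:
            raise IntegrityError(f"duplicate entry version {key}")
        self._entries[key] = ev

    @property
    def entries(self) -> tuple[EntryVersion, ...]:
        return tuple(self._entries.values())

    @property
    def databases(self) -> tuple[str, ...]:
        return tuple(sorted(self.timelines))

    def timeline(self, database: str) -> ReleaseTimeline:
        return self.timelines[database]

    def sorted_entries(self) -> list[EntryVersion]:
        """Entries sorted by (database, release ordinal, entry) — the
        byte-stable write order."""
        return sorted(
            self._entries.values(),
            key=lambda e: (
                e.database,
                self.timelines[e.database].ordinal(e.release_id),
                e.entry_id,
            ),
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, VersionedCorpus):
            return NotImplemented
        return (
            self.timelines == other.timelines
            and self._entries == other._entries
            and self.groups == other.groups
        )

    def __repr__(self) -> str:
        return (
            f"<VersionedCorpus databases={len(self.timelines)} "
            f"entry_versions={len(self._entries)}>"
        )


# ---------------------------------------------------------------------------
# Canonical format I/O


def _escape(text: str) -> str:
    return text.replace("\\", "\\\\").replace("\t", "\\t").replace("\n", "\\n")


def _unescape(text: str) -> str:
    out = []
    it = iter(range(len(text)))
    i = 0
    while i < len(text):
        c = text[i]
        if c == "\\" and i + 1 < len(text):
            nxt = text[i + 1]
            if nxt == "t":
                out.append("\t")
                i += 2
                continue
            if nxt == "n":
                out.append("\n")
                i += 2
                continue
            if nxt == "\\":
                out.append("\\")
                i += 2
                continue
        out.append(c)
        i += 1
    return "".join(out)


def _parse_date(value: str, lineno: int) -> datetime.date:
    try:
        return datetime.date.fromisoformat(value)
    except ValueError:
        raise ParseError(f"bad ISO date {value!r}", lineno) from None


def read_corpus(
    path: str | Path | TextIO, groups: Mapping[str, str] | None = None
) -> VersionedCorpus:
    """Read a corpus from the canonical line-delimited format.

    Record order in the file is irrelevant to the result; timeline release
    order follows the order of T records per database.
    """
    if hasattr(path, "read"):
        stream, name = path, getattr(path, "name", "<stream>")
    else:
        stream, name = open(path, encoding="utf-8"), str(path)
    timeline_rows: dict[str, list[tuple[str, datetime.date]]] = {}
    entry_rows: list[tuple[int, EntryVersion]] = []
    try:
        for lineno, line in enumerate(stream, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.lstrip().startswith("{"):
                kind, row = _parse_json_record(line, lineno)
            else:
                kind, row = _parse_tsv_record(line, lineno)
            if kind == "T":
                db, rid, date = row
                timeline_rows.setdefault(db, []).append((rid, date))
            else:
                entry_rows.append((lineno, row))
    finally:
        if stream is not path:
            stream.close()

    timelines = []
    for db, rels in timeline_rows.items():
        try:
            timelines.append(ReleaseTimeline(db, tuple(rels)))
        except IntegrityError as exc:
            raise ParseError(f"bad timeline in {name}: {exc}") from exc
    corpus = VersionedCorpus(timelines, groups=groups)
    for lineno, ev in entry_rows:
        try:
            corpus.add_entry(ev)
        except IntegrityError as exc:
            raise IntegrityError(f"{name}, line {lineno}: {exc}") from exc
    return corpus


def _parse_tsv_record(line: str, lineno: int):
    fields = line.split("\t")
    tag = fields[0]
    if tag == "T":
        if len(fields) != 4:
            raise ParseError("T record needs 4 tab-separated fields", lineno)
        _, db, rid, date = fields
        return "T", (db, rid, _parse_date(date, lineno))
    if tag == "E":
        if len(fields) != 5:
            raise ParseError("E record needs 5 tab-separated fields", lineno)
        _, db, rid, eid, text = fields
        try:
            return "E", EntryVersion(db, rid, eid, _unescape(text))
        except IntegrityError as exc:
            raise ParseError(str(exc), lineno) from exc
    raise ParseError(f"unknown record tag {tag!r}", lineno)


def _parse_json_record(line: str, lineno: int):
    try:
        obj = json.loads(line)
    except json.JSONDecodeError as exc:
        raise ParseError(f"bad JSON record: {exc}", lineno) from exc
    if not isinstance(obj, dict):
        raise ParseError("JSON record must be an object", lineno)
    if "entry" in obj:
        try:
            return "E", EntryVersion(
                obj["database"], obj["release"], obj["entry"], obj.get("text", "")
            )
        except (KeyError, IntegrityError) as exc:
            raise ParseError(f"bad entry record: {exc}", lineno) from exc
    try:
        return "T", (
            obj["database"],
            obj["release"],
            _parse_date(obj["date"], lineno),
        )
    except KeyError as exc:
        raise ParseError(f"timeline record missing key {exc}", lineno) from exc


def write_corpus(corpus: VersionedCorpus, path: str | Path | TextIO) -> None:
    """Write the canonical tab-separated dialect, byte-stable.

    Timelines first (databases sorted, releases in sequence order), then
    entries sorted by (database, release ordinal, entry id).
    """
    if hasattr(path, "write"):
        _write_corpus_stream(corpus, path)
        return
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        _write_corpus_stream(corpus, fh)


def _write_corpus_stream(corpus: VersionedCorpus, fh: TextIO) -> None:
    for db in sorted(corpus.timelines):
        for rid, date in corpus.timelines[db].releases:
            fh.write(f"T\t{db}\t{rid}\t{date.isoformat()}\n")
    for ev in corpus.sorted_entries():
        fh.write(
            f"E\t{ev.database}\t{ev.release_id}\t{ev.entry_id}\t{_escape(ev.text)}\n"
        )


# ---------------------------------------------------------------------------
# UniProtKB DAT adapter

_CC_TOPIC_RE = re.compile(r"^-!-\s*[A-Z][A-Z0-9 /:_-]*?:\s*")


def parse_uniprot_dat(
    stream: TextIO | str,
    database: str,
    release_id: str,
    topics: set[str] | None = None,
) -> list[EntryVersion]:
    """Harvest CC comment blocks from a UniProtKB-style DAT flat file.

    Each entry (terminated by a ``//`` line) becomes one
    :class:`EntryVersion` whose text is the concatenation of its CC topic
    blocks: the ``CC`` line prefix and the ``-!- TOPIC:`` marker are
    stripped, continuation lines are joined with single spaces, and blocks
    are separated by a blank line so sentence splitting never fuses
    statements across topics.  Entries with no CC text get ``text == ""``.

    ``topics`` optionally restricts harvesting to the named CC topics
    (e.g. ``{"FUNCTION"}``); by default all topics are kept.

    Entries lacking an AC line are skipped with a warning; a truncated
    final entry (content after the last ``//``) raises :class:`ParseError`.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    out: list[EntryVersion] = []
    accession: str | None = None
    blocks: list[tuple[str, list[str]]] = []  # (topic, fragments)
    pending = False
    last_line = 0

    def flush(lineno: int) -> None:
        nonlocal accession, blocks, pending
        if accession is None:
            logger.warning(
                "%s:%s entry ending at line %d has no AC line; skipped",
                database,
                release_id,
                lineno,
            )
        else:
            kept = [
                " ".join(frags)
                for topic, frags in blocks
                if topics is None or topic in topics
            ]
            out.append(EntryVersion(database, release_id, accession, "\n\n".join(kept)))
        accession, blocks, pending = None, [], False

    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if line.strip():
            last_line = lineno
        if line.startswith("//"):
            flush(lineno)
            continue
        pending = pending or bool(line.strip())
        if line.startswith("AC"):
            if accession is None:
                acc = line[2:].strip().split(";")[0].strip()
                if acc:
                    accession = acc
        elif line.startswith("CC"):
            body = line[2:].strip()
            if not body or body.startswith("---") or body.startswith("==="):
                continue  # copyright rule blocks in real DAT files
            m = _CC_TOPIC_RE.match(body)
            if m:
                topic = body[3 : body.index(":")].strip(" -!")
                blocks.append((topic, []))
                rest = body[m.end() :].strip()
                if rest:
                    blocks[-1][1].append(rest)
            elif blocks:
                blocks[-1][1].append(body)
            else:
                # continuation with no topic start: treat as its own block
                blocks.append(("", [body]))
    if pending:
        raise ParseError(
            f"truncated final entry (content after last '//')", last_line
        )
    return out


# ---------------------------------------------------------------------------
# Grouping config


def read_grouping(path: str | Path) -> dict[str, str]:
    """Read a database → group-label map.

    Accepts YAML mappings (``SwissProt: UniProtKB``) and flat ``key = value``
    or ``key<TAB>value`` lines.
    """
    text = Path(path).read_text(encoding="utf-8")
    try:
        obj = yaml.safe_load(text)
    except yaml.YAMLError:
        obj = None
    if isinstance(obj, dict) and all(
        isinstance(k, str) and isinstance(v, str) for k, v in obj.items()
    ):
        return dict(obj)
    mapping: dict[str, str] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" in line:
            key, _, value = line.partition("=")
        elif "\t" in line:
            key, _, value = line.partition("\t")
        else:
            raise ConfigError(f"{path}:{lineno}: cannot parse grouping line {line!r}")
        mapping[key.strip()] = value.strip()
    if not mapping:
        raise ConfigError(f"{path}: empty grouping config")
    return mapping
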