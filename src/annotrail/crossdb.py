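"""Cross-database sharing and the cross-database missing-origin search.

Databases are first collapsed into *groups* (e.g. Swiss-Prot + TrEMBL →
UniProtKB) and every sentence that has ever occurred anywhere is assigned
the exact set of groups it has ever appeared in — the *combination
partition*.  Lifetime occurrence is used deliberately: content flows
between databases over years, and the interesting shared sentences are
often no longer present in the latest releases.

Timing between databases is inherently fuzzy.  A database is developed
continuously but released periodically, so a sentence's true arrival (or
departure) is only known up to the half-open interval between consecutive
releases.  The cross-database missing-origin search therefore works on
:class:`DateInterval` arithmetic and is a *candidate generator*: when the
relevant intervals strictly order, a candidate is flagged ``ordered``;
when they merely overlap, ``ambiguous``.  No verdict is forced — release
calendars alone cannot prove the direction of copying.
"""

from __future__ import annotations

import datetime
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence, TextIO

from .corpus import ReleaseTimeline
from .errors import ConfigError
from .index import OccurrenceIndex

__all__ = [
    "CombinationPartition",
    "DateInterval",
    "CrossPatternCandidate",
    "shared_partition",
    "date_intervals",
    "cross_missing_origin",
    "write_partition_tsv",
    "write_candidates_jsonl",
]


@dataclass(frozen=True)
class DateInterval:
    """The half-open date window one release is 'current' for.

    ``[start, end)`` where ``end`` is the next release's date, or ``None``
    (open) for the latest release.  Consecutive intervals abut without
    overlap.
    """

    database: str
    release_id: str
    start: datetime.date
    end: datetime.date | None

    def strictly_before(self, other: "DateInterval") -> bool:
        return self.end is not None and self.end <= other.start

    def to_json_obj(self) -> dict:
        return {
            "database": self.database,
            "release": self.release_id,
            "start": self.start.isoformat(),
            "end": self.end.isoformat() if self.end is not None else None,
        }


@dataclass(frozen=True)
class CombinationPartition:
    """Sentence counts per exact group-combination (disjoint classes)."""

    classes: Mapping[frozenset, int]

    @property
    def total(self) -> int:
        return sum(self.classes.values())

    def sorted_items(self) -> list[tuple[tuple[str, ...], int]]:
        """(sorted group labels, count), count-descending then label order."""
        items = [
            (tuple(sorted(groups)), count) for groups, count in self.classes.items()
        ]
        return sorted(items, key=lambda kv: (-kv[1], kv[0]))


@dataclass(frozen=True)
class CrossPatternCandidate:
    sentence: str
    source_group: str
    target_group: str
    source_last_seen: DateInterval
    target_first_seen: DateInterval
    target_still_present: bool
    direction_confidence: str  # "ordered" | "ambiguous"

    def to_json_obj(self) -> dict:
        return {
            "sentence": self.sentence,
            "source_group": self.source_group,
            "target_group": self.target_group,
            "source_last_seen": self.source_last_seen.to_json_obj(),
            "target_first_seen": self.target_first_seen.to_json_obj(),
            "target_still_present": self.target_still_present,
            "direction_confidence": self.direction_confidence,
        }


def _as_indexes(indexes) -> list[OccurrenceIndex]:
    if isinstance(indexes, OccurrenceIndex):
        return [indexes]
    return list(indexes)


def _group_members(
    indexes: list[OccurrenceIndex], grouping: Mapping[str, str]
) -> dict[str, list[tuple[OccurrenceIndex, str]]]:
    members: dict[str, list[tuple[OccurrenceIndex, str]]] = {}
    for idx in indexes:
        for db in idx.databases:
            if db not in grouping:
                raise ConfigError(f"database {db!r} missing from grouping map")
            members.setdefault(grouping[db], []).append((idx, db))
    return members


def shared_partition(
    indexes: OccurrenceIndex | Iterable[OccurrenceIndex],
    grouping: Mapping[str, str],
) -> CombinationPartition:
    """Partition all lifetime-unique sentences by the exact set of groups
    they have ever occurred in."""
    idxs = _as_indexes(indexes)
    members = _group_members(idxs, grouping)
    if len(members) < 2:
        raise ConfigError("shared_partition needs at least 2 groups after grouping")
    membership: dict[str, set[str]] = {}
    for group, dbs in members.items():
        for idx, db in dbs:
            for sentence in idx.lifetime_sentences(db):
                membership.setdefault(sentence, set()).add(group)
    classes: dict[frozenset, int] = {}
    for groups in membership.values():
        key = frozenset(groups)
        classes[key] = classes.get(key, 0) + 1
    return CombinationPartition(classes)


def date_intervals(timeline: ReleaseTimeline) -> list[DateInterval]:
    """One half-open currency interval per release; the last is open."""
    out = []
    for i, (rid, date) in enumerate(timeline.releases):
        end = (
            timeline.releases[i + 1][1] if i + 1 < len(timeline.releases) else None
        )
        out.append(DateInterval(timeline.database, rid, date, end))
    return out


def _group_presence_intervals(
    members: list[tuple[OccurrenceIndex, str]], sentence: str
) -> list[DateInterval]:
    """Every release interval of every member database holding the sentence,
    sorted by (start, database, release ordinal)."""
    hits: list[tuple[datetime.date, str, int, DateInterval]] = []
    for idx, db in members:
        tl = idx.timeline(db)
        intervals = date_intervals(tl)
        presence = idx.entry_presence(sentence, db)
        ordinals = set().union(*presence.values()) if presence else set()
        for i in sorted(ordinals):
            hits.append((intervals[i].start, db, i, intervals[i]))
    hits.sort(key=lambda h: (h[0], h[1], h[2]))
    return [h[3] for h in hits]


def cross_missing_origin(
    indexes: OccurrenceIndex | Iterable[OccurrenceIndex],
    grouping: Mapping[str, str],
    source_group: str,
    target_group: str,
) -> list[CrossPatternCandidate]:
    """Candidates for the missing-origin pattern played out *between* groups.

    A sentence qualifies iff (i) its first dated appearance in the source
    group precedes, by interval ordering, its first appearance in the
    target group (interval overlap → candidate kept but flagged
    ``ambiguous``; a target interval that closes before the source's first
    opens is rejected outright); (ii) it is absent from the latest release
    of every source-group database; and (iii) some target release whose
    interval starts at or after the source's last-containing interval
    still holds it.  The earliest qualifying target first-seen interval is
    the one reported.
    """
    idxs = _as_indexes(indexes)
    members = _group_members(idxs, grouping)
    for grp in (source_group, target_group):
        if grp not in members:
            raise ConfigError(f"group {grp!r} has no databases in the given indexes")
    src, tgt = members[source_group], members[target_group]

    src_sentences: set[str] = set()
    for idx, db in src:
        src_sentences |= idx.lifetime_sentences(db)
    tgt_sentences: set[str] = set()
    for idx, db in tgt:
        tgt_sentences |= idx.lifetime_sentences(db)

    out: list[CrossPatternCandidate] = []
    for sentence in sorted(src_sentences & tgt_sentences):
        # (ii) absent from every source database's latest release
        if any(
            sentence in idx.sentences_at(db, idx.timeline(db).latest)
            for idx, db in src
        ):
            continue
        src_iv = _group_presence_intervals(src, sentence)
        tgt_iv = _group_presence_intervals(tgt, sentence)
        src_first, src_last = src_iv[0], max(src_iv, key=lambda iv: iv.start)
        tgt_first = tgt_iv[0]
        # no time travel: target cannot have closed before source opened
        if tgt_first.end is not None and tgt_first.end <= src_first.start:
            continue
        # (iii) survivor at/after the source's last-containing interval
        if not any(iv.start >= src_last.start for iv in tgt_iv):
            continue
        confidence = (
            "ordered" if src_first.strictly_before(tgt_first) else "ambiguous"
        )
        still_present = any(
            sentence in idx.sentences_at(db, idx.timeline(db).latest)
            for idx, db in tgt
        )
        out.append(
            CrossPatternCandidate(
                sentence=sentence,
                source_group=source_group,
                target_group=target_group,
                source_last_seen=src_last,
                target_first_seen=tgt_first,
                target_still_present=still_present,
                direction_confidence=confidence,
            )
        )
    return out


def write_partition_tsv(
    partition: CombinationPartition, path: str | Path | TextIO
) -> None:
    own = not hasattr(path, "write")
    fh = open(path, "w", encoding="utf-8", newline="\n") if own else path
    try:
        fh.write("group_combination\tcount\n")
        for groups, count in partition.sorted_items():
            fh.write(f"{'; '.join(groups)}\t{count}\n")
    finally:
        if own:
            fh.close()


def write_candidates_jsonl(
    candidates: Sequence[CrossPatternCandidate], path: str | Path | TextIO
) -> None:
    own = not hasattr(path, "write")
    fh = open(path, "w", encoding="utf-8", newline="\n") if own else path
    try:
        for cand in sorted(candidates, key=lambda c: c.sentence):
            fh.write(json.dumps(cand.to_json_obj(), sort_keys=True) + "\n")
    finally:
        if own:
            fh.close()
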