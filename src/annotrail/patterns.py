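"""Within-database propagation-pattern detectors.

Three temporal signatures of annotation flow, each defined over the
presence runs of a sentence in a database's entries:

* **transient** — the sentence sat in some entry for exactly one release
  and was then removed (the run has length 1 and is not censored).
  Transience is unobservable when the single occurrence is in the latest
  release, so single-release databases reject the query outright.
* **possibly transient** — the sentence is new in the latest release for
  some entry (a censored run of length 1): its removal-or-persistence
  cannot yet be observed.  Treated as an unclassifiable remainder, not a
  pattern of its own: a sentence already transient elsewhere is *not*
  additionally labelled possibly transient.
* **missing origin** — the sentence debuts in an origin entry (or a set
  of entries, if the debut is simultaneous), propagates to entries that
  debut strictly later, and is then removed from *all* origin entries
  while at least one later entry still holds it.  This is the signature
  of a failed update: the source of a statement corrected or retracted
  it, but the copies did not follow.

Counting is sentence-level: a sentence contributes at most once per label
per database — exhibiting a pattern in a single entry suffices.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, TextIO

from .errors import UnobservablePatternError
from .index import OccurrenceIndex, PresenceRun

__all__ = [
    "PatternEvidence",
    "PatternSummary",
    "detect_transient",
    "detect_possibly_transient",
    "detect_missing_origin",
    "pattern_summary",
    "write_evidence_jsonl",
    "write_summary_tsv",
]

LABELS = ("missing_origin", "transient", "possibly_transient")


@dataclass(frozen=True)
class PatternEvidence:
    """One sentence's witness for one pattern label in one database."""

    label: str
    sentence: str
    database: str
    witness_runs: tuple[PresenceRun, ...]
    origin_entries: frozenset[str] | None = None
    removal_release: int | None = None
    surviving_entries: frozenset[str] | None = None

    def to_json_obj(self, index: OccurrenceIndex) -> dict:
        tl = index.timeline(self.database)
        obj = {
            "label": self.label,
            "sentence": self.sentence,
            "database": self.database,
            "witness_runs": [
                {
                    "entry": r.entry_id,
                    "start_release": tl.release_id(r.start_idx),
                    "end_release": tl.release_id(r.end_idx),
                    "censored": r.censored,
                }
                for r in self.witness_runs
            ],
        }
        if self.label == "missing_origin":
            obj["origin_entries"] = sorted(self.origin_entries)
            obj["removal_release"] = tl.release_id(self.removal_release)
            obj["surviving_entries"] = sorted(self.surviving_entries)
        return obj


@dataclass(frozen=True)
class PatternSummary:
    database: str
    missing_origin: int
    transient: int
    possibly_transient: int


def _transient_sentences(index: OccurrenceIndex, database: str) -> dict[str, PatternEvidence]:
    evidences: dict[str, PatternEvidence] = {}
    for sentence in sorted(index.lifetime_sentences(database)):
        best: PresenceRun | None = None
        for entry in sorted(index.entry_presence(sentence, database)):
            for run in index.presence_runs(sentence, database, entry):
                if run.length == 1 and not run.censored:
                    if best is None or (run.start_idx, run.entry_id) < (
                        best.start_idx,
                        best.entry_id,
                    ):
                        best = run
        if best is not None:
            evidences[sentence] = PatternEvidence(
                "transient", sentence, database, (best,)
            )
    return evidences


def detect_transient(index: OccurrenceIndex, database: str) -> list[PatternEvidence]:
    """Sentences with a completed single-release stay in some entry.

    One evidence per sentence, witnessing the earliest qualifying run.
    Rejects single-release databases, where transience is unobservable.
    """
    if len(index.timeline(database)) < 2:
        raise UnobservablePatternError(
            f"{database!r} has a single release; transience is unobservable"
        )
    return list(_transient_sentences(index, database).values())


def detect_possibly_transient(
    index: OccurrenceIndex, database: str
) -> list[PatternEvidence]:
    """Sentences new in the latest release (censored length-1 run) that are
    not already transient elsewhere in the database."""
    n_releases = len(index.timeline(database))
    transient = (
        set(_transient_sentences(index, database)) if n_releases >= 2 else set()
    )
    evidences: list[PatternEvidence] = []
    for sentence in sorted(index.lifetime_sentences(database)):
        if sentence in transient:
            continue
        best: PresenceRun | None = None
        for entry in sorted(index.entry_presence(sentence, database)):
            for run in index.presence_runs(sentence, database, entry):
                if run.length == 1 and run.censored:
                    if best is None or run.entry_id < best.entry_id:
                        best = run
        if best is not None:
            evidences.append(
                PatternEvidence("possibly_transient", sentence, database, (best,))
            )
    return evidences


def detect_missing_origin(
    index: OccurrenceIndex, database: str
) -> list[PatternEvidence]:
    """Sentences whose whole debut (origin) set later drops them while a
    strictly-later entry still carries them.

    Formally, with f the earliest release ordinal at which the sentence
    occurs anywhere in the database and O the entries holding it at f:
    the label applies iff some ordinal m > f has (i) no entry of O holding
    the sentence at m, (ii) some entry of O holding it at m − 1, and
    (iii) some entry outside O, whose own first occurrence is after f,
    holding it at m.  Only the first qualifying removal m is witnessed;
    later dynamics never retract the label.  Requires ≥ 3 releases.
    """
    tl = index.timeline(database)
    if len(tl) < 3:
        raise UnobservablePatternError(
            f"{database!r} has {len(tl)} release(s); the missing-origin "
            "appear/propagate/remove sequence needs at least 3"
        )
    evidences: list[PatternEvidence] = []
    for sentence in sorted(index.lifetime_sentences(database)):
        presence = index.entry_presence(sentence, database)
        f = min(min(s) for s in presence.values())
        origin = {e for e, s in presence.items() if f in s}
        secondaries = {
            e for e, s in presence.items() if e not in origin and min(s) > f
        }
        if not secondaries:
            continue
        witness_m = None
        for m in range(f + 1, len(tl)):
            if any(m in presence[e] for e in origin):
                continue
            if not any(m - 1 in presence[e] for e in origin):
                continue
            survivors = {e for e in secondaries if m in presence[e]}
            if survivors:
                witness_m = (m, survivors)
                break
        if witness_m is None:
            continue
        m, survivors = witness_m
        runs: list[PresenceRun] = []
        for e in sorted(origin):
            runs.extend(
                r
                for r in index.presence_runs(sentence, database, e)
                if r.end_idx == m - 1
            )
        for e in sorted(survivors):
            runs.extend(
                r
                for r in index.presence_runs(sentence, database, e)
                if r.start_idx <= m <= r.end_idx
            )
        evidences.append(
            PatternEvidence(
                "missing_origin",
                sentence,
                database,
                tuple(runs),
                origin_entries=frozenset(origin),
                removal_release=m,
                surviving_entries=frozenset(survivors),
            )
        )
    return evidences


def pattern_summary(index: OccurrenceIndex, database: str) -> PatternSummary:
    """Distinct-sentence counts per label under the precedence rule."""
    n = len(index.timeline(database))
    transient = detect_transient(index, database) if n >= 2 else []
    possibly = detect_possibly_transient(index, database)
    missing = detect_missing_origin(index, database) if n >= 3 else []
    return PatternSummary(
        database=database,
        missing_origin=len(missing),
        transient=len(transient),
        possibly_transient=len(possibly),
    )


def write_evidence_jsonl(
    evidences: Sequence[PatternEvidence],
    index: OccurrenceIndex,
    path: str | Path | TextIO,
) -> None:
    own = not hasattr(path, "write")
    fh = open(path, "w", encoding="utf-8", newline="\n") if own else path
    try:
        for ev in sorted(evidences, key=lambda e: (e.database, e.label, e.sentence)):
            fh.write(json.dumps(ev.to_json_obj(index), sort_keys=True) + "\n")
    finally:
        if own:
            fh.close()


def write_summary_tsv(
    summaries: Sequence[PatternSummary], path: str | Path | TextIO
) -> None:
    own = not hasattr(path, "write")
    fh = open(path, "w", encoding="utf-8", newline="\n") if own else path
    try:
        fh.write("database\tmissing_origin\ttransient\tpossibly_transient\n")
        for s in sorted(summaries, key=lambda s: s.database):
            fh.write(
                f"{s.database}\t{s.missing_origin}\t{s.transient}"
                f"\t{s.possibly_transient}\n"
            )
    finally:
        if own:
            fh.close()
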