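"""Per-release reuse measures.

Three counts characterise sentence redundancy in one database release:

* **total** — the redundant count of all sentence slots (every occurrence,
  including within-entry duplicates);
* **unique** — the number of distinct sentence strings;
* **singleton** — the number of strings occurring exactly once.

``unique / total`` near 1 means little reuse; heavily redundant databases
(large, computationally generated ones in particular) push it toward 0.
The lifetime-unique count is the size of the union of the distinct-key
sets across all releases of a database — sentences that have *ever*
appeared, whether or not they survive to the latest release.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, TextIO

from .errors import UndefinedRatioError
from .index import OccurrenceIndex

__all__ = [
    "VersionCounts",
    "version_counts",
    "lifetime_unique",
    "reuse_percentages",
    "top_reused",
    "write_version_report",
]


@dataclass(frozen=True)
class VersionCounts:
    database: str
    release_id: str
    total: int
    unique: int
    singleton: int

    def __post_init__(self):
        assert 0 <= self.singleton <= self.unique <= self.total
        assert (self.unique == 0) == (self.total == 0)


def version_counts(
    index: OccurrenceIndex, database: str, release_id: str
) -> VersionCounts:
    """Total / unique / singleton sentence counts of one release."""
    counter = index.release_counter(database, release_id)
    return VersionCounts(
        database=database,
        release_id=release_id,
        total=sum(counter.values()),
        unique=len(counter),
        singleton=sum(1 for c in counter.values() if c == 1),
    )


def lifetime_unique(index: OccurrenceIndex, database: str) -> int:
    """Distinct sentences over the whole lifetime of the database."""
    return len(index.lifetime_sentences(database))


def reuse_percentages(
    index: OccurrenceIndex, database: str, release_id: str
) -> tuple[float, float]:
    """(unique, singleton) as percentages of the total; full precision."""
    vc = version_counts(index, database, release_id)
    if vc.total == 0:
        raise UndefinedRatioError(
            f"{database}/{release_id} has no sentences; percentages undefined"
        )
    return 100.0 * vc.unique / vc.total, 100.0 * vc.singleton / vc.total


def top_reused(
    index: OccurrenceIndex, database: str, release_id: str, k: int
) -> list[tuple[str, int]]:
    """The k most-multiplied sentences of a release.

    Descending by multiplicity, ties broken lexicographically on the key so
    the ranking is reproducible.  Fewer than k keys → shorter list.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    counter = index.release_counter(database, release_id)
    ranked = sorted(counter.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked[:k]


def write_version_report(
    index: OccurrenceIndex,
    path: str | Path | TextIO,
    databases: Sequence[str] | None = None,
) -> None:
    """TSV of per-release counts and percentages for every release.

    Columns: database, release, date, total, unique, singleton,
    unique_pct, singleton_pct.  Empty releases print empty percentage
    fields rather than dividing by zero.
    """
    dbs = sorted(databases) if databases is not None else list(index.databases)
    own = not hasattr(path, "write")
    fh = open(path, "w", encoding="utf-8", newline="\n") if own else path
    try:
        fh.write(
            "database\trelease\tdate\ttotal\tunique\tsingleton"
            "\tunique_pct\tsingleton_pct\n"
        )
        for db in dbs:
            tl = index.timeline(db)
            for rid, date in tl.releases:
                vc = version_counts(index, db, rid)
                if vc.total:
                    upct, spct = reuse_percentages(index, db, rid)
                    pcts = f"{upct:.6g}\t{spct:.6g}"
                else:
                    pcts = "\t"
                fh.write(
                    f"{db}\t{rid}\t{date.isoformat()}\t{vc.total}"
                    f"\t{vc.unique}\t{vc.singleton}\t{pcts}\n"
                )
    finally:
        if own:
            fh.close()
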