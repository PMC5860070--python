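"""Shared fixtures: tiny hand-built corpora and a brute-force pattern oracle.

The oracle (`oracle_labels`) is a direct, independent transcription of the
pattern definitions over a raw presence matrix, evaluated without runs,
indexes or any package machinery — detectors are checked against it
exhaustively on small matrices.
"""

from __future__ import annotations

import datetime

import pytest

from annotrail.corpus import EntryVersion, ReleaseTimeline, VersionedCorpus

PROBE = "the probe sentence under test."


def make_timeline(db: str, n: int, start_year: int = 2001, period_days: int = 365):
    base = datetime.date(start_year, 1, 1)
    return ReleaseTimeline(
        db,
        tuple(
            (f"r{i + 1}", base + datetime.timedelta(days=i * period_days))
            for i in range(n)
        ),
    )


def corpus_from_matrix(
    presence: dict[str, set[int]],
    n_releases: int,
    db: str = "D",
    sentence: str = PROBE,
    start_year: int = 2001,
) -> VersionedCorpus:
    """Corpus holding one probe sentence according to a presence matrix.

    ``presence`` maps entry id → set of release ordinals at which the
    entry's text contains the sentence; every entry exists (possibly with
    empty text) at every release.
    """
    tl = make_timeline(db, n_releases, start_year)
    entries = [
        EntryVersion(
            db,
            tl.release_id(i),
            entry,
            sentence if i in ordinals else "",
        )
        for entry, ordinals in presence.items()
        for i in range(n_releases)
    ]
    return VersionedCorpus([tl], entries)


def _runs(ordinals: set[int]) -> list[tuple[int, int]]:
    runs, start, prev = [], None, None
    for i in sorted(ordinals):
        if start is None:
            start = prev = i
        elif i == prev + 1:
            prev = i
        else:
            runs.append((start, prev))
            start = prev = i
    if start is not None:
        runs.append((start, prev))
    return runs


def oracle_labels(presence: dict[str, set[int]], n_releases: int) -> set[str]:
    """Pattern labels of one sentence, straight from the definitions.

    transient: some entry holds the sentence for exactly one release that
    is not the latest.  possibly_transient: some entry's only-latest-release
    stay, unless already transient.  missing_origin: with f the earliest
    occurrence and O the entries holding it at f, some m > f has no O-entry
    holding it, an O-entry holding it at m-1, and a strictly-later-debuting
    non-O entry holding it at m.
    """
    occupied = {e: s for e, s in presence.items() if s}
    labels: set[str] = set()
    if not occupied:
        return labels
    last = n_releases - 1
    transient = any(
        a == b and b != last for s in occupied.values() for a, b in _runs(s)
    )
    if transient and n_releases >= 2:
        labels.add("transient")
    if not transient and any(
        a == b == last for s in occupied.values() for a, b in _runs(s)
    ):
        labels.add("possibly_transient")
    if n_releases >= 3:
        f = min(min(s) for s in occupied.values())
        origin = {e for e, s in occupied.items() if f in s}
        for m in range(f + 1, n_releases):
            if any(m in occupied[e] for e in origin):
                continue
            if not any(m - 1 in occupied[e] for e in origin):
                continue
            if any(
                m in s
                for e, s in occupied.items()
                if e not in origin and min(s) > f
            ):
                labels.add("missing_origin")
                break
    return labels


@pytest.fixture
def fig2_corpus() -> VersionedCorpus:
    """The published InterPro timeline: a sentence debuts in IPR004086 in
    2001, propagates to IPR005430 in 2002, is removed from the origin in
    2003 and survives in the secondary for another release."""
    sentence = (
        "pyelonephritogenic e.coli specifically invade the uroepithelium by "
        "expressing between 100 and 300 pili on their cell surface"
    )
    return corpus_from_matrix(
        {"IPR004086": {0, 1}, "IPR005430": {1, 2}},
        n_releases=4,
        db="InterPro",
        sentence=sentence,
    )


@pytest.fixture
def fig3_corpora() -> tuple[VersionedCorpus, VersionedCorpus]:
    """Two-database reconstruction of the published cross-database case:
    the sentence appears in PRINTS around 1999, percolates into InterPro
    in 2000, later disappears from PRINTS while persisting in InterPro —
    a missing origin visible only across both databases."""
    sentence = "this fingerprint discriminates the family from related sequences."
    prints = corpus_from_matrix(
        {"PR_FP1": {0, 1}},
        n_releases=4,
        db="PRINTS",
        sentence=sentence,
        start_year=1999,
    )
    interpro_tl = ReleaseTimeline(
        "InterPro",
        tuple(
            (f"ip{i + 1}", datetime.date(2000 + i, 6, 1)) for i in range(9)
        ),
    )
    interpro_entries = [
        EntryVersion(
            "InterPro",
            interpro_tl.release_id(i),
            "IPR001055",
            sentence,  # present from 2000 onwards, censored
        )
        for i in range(9)
    ] + [
        EntryVersion(
            "InterPro",
            interpro_tl.release_id(i),
            "IPR018298",
            sentence if i >= 8 else "",
        )
        for i in range(9)
    ]
    return prints, VersionedCorpus([interpro_tl], interpro_entries)
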