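"""Synthetic versioned-corpus generator with planted ground truth.

Real multi-database annotation ecosystems cannot be redistributed, so all
detector validation runs against synthetic ecosystems that emulate their
dynamics: several databases with regular (deliberately unsynchronised)
release calendars, entries whose annotation blocks are drawn from a shared
template pool (creating realistic reuse), and per-release background
processes — sentence birth, intra-database copying with a one-release lag,
removal, and provenance-breaking edits.

On top of the background, the generator *plants* instances of the
propagation patterns and emits machine-checkable :class:`GroundTruth`.
Planted sentences carry a reserved token prefix that the background
processes can never produce, so recovery metrics are exact rather than
probabilistic: a detector is correct iff its output equals the planted
set.

Generation is a pure function of the config (including the seed): the same
config yields byte-identical corpora.
"""

from __future__ import annotations

import datetime
import random
from dataclasses import dataclass, field
from pathlib import Path
import yaml

from .corpus import EntryVersion, ReleaseTimeline, VersionedCorpus
from .errors import ConfigError
from .sentencise import extract_sentences

__all__ = [
    "DatabaseSpec",
    "BackgroundRates",
    "PlantCounts",
    "SynthConfig",
    "PlantedInstance",
    "GroundTruth",
    "ValidationReport",
    "generate",
    "edit_sentence",
    "verify_ground_truth",
]

#: Reserved token opening every planted sentence; the background template
#: pool never contains it, so planted keys cannot collide with background.
PLANT_PREFIX = "xq-planted"

_SUBJECTS = (
    "the protein", "this enzyme", "the domain", "this family", "the receptor",
    "the kinase", "the transporter", "this motif", "the complex", "the channel",
)
_VERBS = (
    "binds", "regulates", "catalyzes", "mediates", "inhibits", "activates",
    "stabilizes", "transports", "phosphorylates", "recognizes",
)
_OBJECTS = (
    "dna replication", "signal transduction", "atp hydrolysis",
    "membrane transport", "gene expression", "ion flux", "protein folding",
    "cell adhesion", "lipid metabolism", "vesicle fusion",
)
_CONTEXTS = (
    "in the nucleus", "during development", "in response to stress",
    "in eukaryotes", "at the cell surface", "in the cytoplasm",
    "under anaerobic conditions", "in muscle tissue", "in the retina",
    "across the inner membrane",
)

#: Fixed synonym table used by the background edit process.
SYNONYMS = {
    "protein": "polypeptide",
    "enzyme": "catalyst",
    "domain": "module",
    "family": "superfamily",
    "receptor": "sensor",
    "binds": "associates",
    "regulates": "modulates",
    "catalyzes": "drives",
    "mediates": "enables",
    "inhibits": "suppresses",
    "activates": "stimulates",
    "stabilizes": "maintains",
    "transports": "shuttles",
    "nucleus": "nucleoplasm",
    "development": "morphogenesis",
    "stress": "insult",
    "expression": "transcription",
    "marker": "tag",
    "instance": "case",
}


@dataclass(frozen=True)
class DatabaseSpec:
    label: str
    n_releases: int
    start_date: datetime.date
    period_days: int
    n_entries: int


@dataclass(frozen=True)
class BackgroundRates:
    """Per-release, per-entry event probabilities."""

    birth: float = 0.0
    copy: float = 0.0
    removal: float = 0.0
    edit: float = 0.0

    def __post_init__(self):
        for name in ("birth", "copy", "removal", "edit"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"background rate {name}={p} not in [0, 1]")


@dataclass(frozen=True)
class PlantCounts:
    transient: int = 0
    possibly_transient: int = 0
    missing_origin: int = 0
    cross_db_missing_origin: int = 0

    def __post_init__(self):
        for name in (
            "transient",
            "possibly_transient",
            "missing_origin",
            "cross_db_missing_origin",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"planted count {name} must be >= 0")


@dataclass(frozen=True)
class SynthConfig:
    seed: int
    databases: tuple[DatabaseSpec, ...]
    vocabulary_size: int = 120
    background: BackgroundRates = field(default_factory=BackgroundRates)
    planted: PlantCounts = field(default_factory=PlantCounts)
    initial_sentences_per_entry: int = 3
    #: shift even-numbered databases' calendars by half a period so
    #: cross-database intervals order strictly; False forces coincident
    #: calendars (overlapping intervals → ambiguous candidates).
    offset_calendars: bool = True
    #: pass target-side copies of cross-db plants through edit_sentence,
    #: demonstrating that edits break exact-match provenance.
    force_edit_cross_copies: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SynthConfig":
        obj = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        if not isinstance(obj, dict):
            raise ConfigError(f"{path}: synthesis config must be a mapping")
        try:
            dbs = tuple(
                DatabaseSpec(
                    label=d["label"],
                    n_releases=int(d["n_releases"]),
                    start_date=datetime.date.fromisoformat(str(d["start_date"])[:10]),
                    period_days=int(d.get("period_days", 365)),
                    n_entries=int(d["n_entries"]),
                )
                for d in obj["databases"]
            )
            return cls(
                seed=int(obj["seed"]),
                databases=dbs,
                vocabulary_size=int(obj.get("vocabulary_size", 120)),
                background=BackgroundRates(**obj.get("background", {})),
                planted=PlantCounts(**obj.get("planted", {})),
                initial_sentences_per_entry=int(
                    obj.get("initial_sentences_per_entry", 3)
                ),
                offset_calendars=bool(obj.get("offset_calendars", True)),
                force_edit_cross_copies=bool(
                    obj.get("force_edit_cross_copies", False)
                ),
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ConfigError(f"{path}: bad synthesis config: {exc}") from exc


@dataclass(frozen=True)
class PlantedInstance:
    """One planted pattern instance with its exact realization.

    ``occurrences`` lists every (database, entry, release_id, sentence)
    tuple the plant put into the corpus; for edited cross-database copies
    the per-occurrence sentence differs from the canonical ``sentence``.
    """

    label: str
    sentence: str
    occurrences: tuple[tuple[str, str, str, str], ...]
    origin_entries: tuple[str, ...] = ()
    removal_release: str | None = None
    source_database: str | None = None
    target_database: str | None = None
    edited_in_target: bool = False

    def to_json_obj(self) -> dict:
        return {
            "label": self.label,
            "sentence": self.sentence,
            "occurrences": [list(o) for o in self.occurrences],
            "origin_entries": list(self.origin_entries),
            "removal_release": self.removal_release,
            "source_database": self.source_database,
            "target_database": self.target_database,
            "edited_in_target": self.edited_in_target,
        }


@dataclass(frozen=True)
class GroundTruth:
    planted: tuple[PlantedInstance, ...]

    def by_label(self, label: str) -> list[PlantedInstance]:
        return [p for p in self.planted if p.label == label]

    def sentences(self, label: str) -> set[str]:
        return {p.sentence for p in self.by_label(label)}

    def write_jsonl(self, path: str | Path) -> None:
        import json

        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            for inst in self.planted:
                fh.write(json.dumps(inst.to_json_obj(), sort_keys=True) + "\n")

    @classmethod
    def read_jsonl(cls, path: str | Path) -> "GroundTruth":
        import json

        planted = []
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                if not line.strip():
                    continue
                obj = json.loads(line)
                planted.append(
                    PlantedInstance(
                        label=obj["label"],
                        sentence=obj["sentence"],
                        occurrences=tuple(tuple(o) for o in obj["occurrences"]),
                        origin_entries=tuple(obj.get("origin_entries", ())),
                        removal_release=obj.get("removal_release"),
                        source_database=obj.get("source_database"),
                        target_database=obj.get("target_database"),
                        edited_in_target=obj.get("edited_in_target", False),
                    )
                )
        return cls(tuple(planted))


@dataclass(frozen=True)
class ValidationReport:
    violations: tuple[str, ...]

    @property
    def ok(self) -> bool:
        return not self.violations


# ---------------------------------------------------------------------------


def edit_sentence(sentence: str, rng: random.Random) -> str:
    """Apply one provenance-breaking token substitution.

    Replaces a token drawn from the fixed synonym table (falling back to a
    deterministic ``-alt`` variant of a random token when none matches), so
    the result always differs from the input while staying a single
    normalized sentence.  Deterministic under a fixed rng state.
    """
    tokens = sentence.split(" ")
    if len(tokens) < 2:
        raise ConfigError("edit_sentence needs a sentence of >= 2 tokens")
    candidates = [
        i for i, t in enumerate(tokens) if t.strip(".,;:!?") in SYNONYMS
    ]
    if candidates:
        i = rng.choice(candidates)
        bare = tokens[i].strip(".,;:!?")
        suffix = tokens[i][len(bare) :]
        tokens[i] = SYNONYMS[bare] + suffix
    else:
        i = rng.randrange(len(tokens))
        bare = tokens[i].strip(".,;:!?")
        suffix = tokens[i][len(bare) :]
        tokens[i] = bare + "-alt" + suffix
    edited = " ".join(tokens)
    assert edited != sentence
    return edited


def _vocabulary(size: int) -> list[str]:
    vocab = []
    i = 0
    while len(vocab) < size:
        s = _SUBJECTS[i % len(_SUBJECTS)]
        v = _VERBS[(i // len(_SUBJECTS)) % len(_VERBS)]
        o = _OBJECTS[(i * 7 + 3) % len(_OBJECTS)]
        c = _CONTEXTS[(i * 11 + 5) % len(_CONTEXTS)]
        vocab.append(f"{s} {v} {o} {c} (statement {i}).")
        i += 1
    return vocab


class _DbState:
    """Per-database evolving annotation: entry → ordinal → sentence list."""

    def __init__(self, spec: DatabaseSpec):
        self.spec = spec
        self.entries = [f"{spec.label}_E{j:04d}" for j in range(spec.n_entries)]
        self.texts: dict[str, list[list[str]]] = {
            e: [[] for _ in range(spec.n_releases)] for e in self.entries
        }

    def plant(self, entry: str, ordinal: int, sentence: str) -> None:
        self.texts[entry][ordinal].append(sentence)


def _plant_sentence(label: str, k: int) -> str:
    return f"{PLANT_PREFIX} {label.replace('_', ' ')} marker instance number {k}."


def generate(config: SynthConfig) -> tuple[VersionedCorpus, GroundTruth]:
    """Generate a synthetic ecosystem and its ground truth.

    Raises :class:`ConfigError` for infeasible planting requests (e.g. a
    missing-origin plant in a database with fewer than 3 releases).
    """
    if not config.databases:
        raise ConfigError("at least one database is required")
    labels = [d.label for d in config.databases]
    if len(set(labels)) != len(labels):
        raise ConfigError("database labels must be unique")
    rng = random.Random(config.seed)
    vocab = _vocabulary(config.vocabulary_size)

    states: dict[str, _DbState] = {}
    timelines: dict[str, ReleaseTimeline] = {}
    for i, spec in enumerate(config.databases):
        if spec.n_releases < 1 or spec.n_entries < 1 or spec.period_days < 1:
            raise ConfigError(f"bad database spec for {spec.label!r}")
        start = spec.start_date
        if config.offset_calendars and i % 2 == 1:
            start = start + datetime.timedelta(days=spec.period_days // 2)
        releases = tuple(
            (
                f"{spec.label}_r{t + 1:02d}",
                start + datetime.timedelta(days=t * spec.period_days),
            )
            for t in range(spec.n_releases)
        )
        timelines[spec.label] = ReleaseTimeline(spec.label, releases)
        states[spec.label] = _DbState(spec)

    # background evolution (planting happens afterwards and is never
    # touched by background processes)
    for spec in config.databases:
        st = states[spec.label]
        for e in st.entries:
            st.texts[e][0] = [
                rng.choice(vocab) for _ in range(config.initial_sentences_per_entry)
            ]
        _evolve_background_from_initial(st, vocab, config.background, rng)

    planted: list[PlantedInstance] = []
    serial = 0

    def next_sentence(label: str) -> str:
        nonlocal serial
        serial += 1
        return _plant_sentence(label, serial)

    # --- transient: one completed single-release stay ----------------------
    for _ in range(config.planted.transient):
        eligible = [d for d in config.databases if d.n_releases >= 2]
        if not eligible:
            raise ConfigError("transient planting needs a database with >= 2 releases")
        spec = rng.choice(eligible)
        st = states[spec.label]
        entry = rng.choice(st.entries)
        r = rng.randrange(spec.n_releases - 1)  # never the latest release
        s = next_sentence("transient")
        st.plant(entry, r, s)
        tl = timelines[spec.label]
        planted.append(
            PlantedInstance(
                label="transient",
                sentence=s,
                occurrences=((spec.label, entry, tl.release_id(r), s),),
            )
        )

    # --- possibly transient: new in the latest release ---------------------
    for _ in range(config.planted.possibly_transient):
        spec = rng.choice(config.databases)
        st = states[spec.label]
        entry = rng.choice(st.entries)
        r = spec.n_releases - 1
        s = next_sentence("possibly_transient")
        st.plant(entry, r, s)
        tl = timelines[spec.label]
        planted.append(
            PlantedInstance(
                label="possibly_transient",
                sentence=s,
                occurrences=((spec.label, entry, tl.release_id(r), s),),
            )
        )

    # --- missing origin: debut, propagate, remove --------------------------
    for _ in range(config.planted.missing_origin):
        eligible = [
            d for d in config.databases if d.n_releases >= 3 and d.n_entries >= 2
        ]
        if not eligible:
            raise ConfigError(
                "missing-origin planting needs a database with >= 3 releases "
                "and >= 2 entries"
            )
        spec = rng.choice(eligible)
        st = states[spec.label]
        origin, secondary = rng.sample(st.entries, 2)
        f = rng.randrange(spec.n_releases - 2)
        m = rng.randrange(f + 2, spec.n_releases)
        s = next_sentence("missing_origin")
        tl = timelines[spec.label]
        occs = []
        for t in range(f, m):  # origin holds f .. m-1 (run length >= 2)
            st.plant(origin, t, s)
            occs.append((spec.label, origin, tl.release_id(t), s))
        for t in range(f + 1, spec.n_releases):  # secondary debuts at f+1, censored
            st.plant(secondary, t, s)
            occs.append((spec.label, secondary, tl.release_id(t), s))
        planted.append(
            PlantedInstance(
                label="missing_origin",
                sentence=s,
                occurrences=tuple(occs),
                origin_entries=(origin,),
                removal_release=tl.release_id(m),
            )
        )

    # --- cross-database missing origin --------------------------------------
    for _ in range(config.planted.cross_db_missing_origin):
        if len(config.databases) < 2:
            raise ConfigError("cross-database planting needs >= 2 databases")
        src_spec, tgt_spec = rng.sample(list(config.databases), 2)
        plan = _plan_cross_plant(
            timelines[src_spec.label],
            timelines[tgt_spec.label],
            rng,
            want_overlap=not config.offset_calendars,
        )
        if plan is None:
            raise ConfigError(
                f"calendars of {src_spec.label!r}/{tgt_spec.label!r} leave no "
                "room for a cross-database missing-origin plant"
            )
        f, j = plan
        src_st, tgt_st = states[src_spec.label], states[tgt_spec.label]
        src_entry = rng.choice(src_st.entries)
        tgt_entry = rng.choice(tgt_st.entries)
        s = next_sentence("cross_db_missing_origin")
        tgt_sentence = s
        edited = False
        if config.force_edit_cross_copies:
            tgt_sentence = edit_sentence(s, rng)
            edited = True
        src_tl, tgt_tl = timelines[src_spec.label], timelines[tgt_spec.label]
        occs = []
        for t in (f, f + 1):  # source run of length 2, removed before latest
            src_st.plant(src_entry, t, s)
            occs.append((src_spec.label, src_entry, src_tl.release_id(t), s))
        for t in range(j, tgt_spec.n_releases):  # target persists to the end
            tgt_st.plant(tgt_entry, t, tgt_sentence)
            occs.append(
                (tgt_spec.label, tgt_entry, tgt_tl.release_id(t), tgt_sentence)
            )
        planted.append(
            PlantedInstance(
                label="cross_db_missing_origin",
                sentence=s,
                occurrences=tuple(occs),
                origin_entries=(src_entry,),
                removal_release=src_tl.release_id(f + 2),
                source_database=src_spec.label,
                target_database=tgt_spec.label,
                edited_in_target=edited,
            )
        )

    # --- assemble the corpus -------------------------------------------------
    entries: list[EntryVersion] = []
    for spec in config.databases:
        st = states[spec.label]
        tl = timelines[spec.label]
        for e in st.entries:
            for t in range(spec.n_releases):
                text = "\n".join(st.texts[e][t])
                entries.append(EntryVersion(spec.label, tl.release_id(t), e, text))
    corpus = VersionedCorpus(timelines.values(), entries)
    truth = GroundTruth(tuple(planted))
    report = verify_ground_truth(corpus, truth)
    if not report.ok:  # pragma: no cover - generator self-check
        raise AssertionError(
            "generator emitted unrealizable ground truth: "
            + "; ".join(report.violations)
        )
    return corpus, truth


def _evolve_background_from_initial(
    state: _DbState, vocab: list[str], rates: BackgroundRates, rng: random.Random
) -> None:
    spec = state.spec
    for t in range(1, spec.n_releases):
        prev_snapshot = {e: list(state.texts[e][t - 1]) for e in state.entries}
        for e in state.entries:
            current = list(prev_snapshot[e])
            if rates.removal:
                current = [s for s in current if rng.random() >= rates.removal]
            if rates.edit:
                current = [
                    edit_sentence(s, rng)
                    if len(s.split(" ")) >= 2 and rng.random() < rates.edit
                    else s
                    for s in current
                ]
            if rates.birth and rng.random() < rates.birth:
                current.append(rng.choice(vocab))
            if rates.copy and rng.random() < rates.copy and len(state.entries) > 1:
                donor = rng.choice([x for x in state.entries if x != e])
                pool = prev_snapshot[donor]
                if pool:
                    current.append(rng.choice(pool))
            state.texts[e][t] = current


def _plan_cross_plant(
    src_tl: ReleaseTimeline,
    tgt_tl: ReleaseTimeline,
    rng: random.Random,
    want_overlap: bool = False,
) -> tuple[int, int] | None:
    """Pick (source debut ordinal f, target debut ordinal j) such that the
    planted instance satisfies the cross-database candidate conditions.

    Source holds the sentence at f and f+1 and must be silent afterwards
    (so f + 2 <= last source ordinal).  In ordered mode the target debut
    interval must start at or after the source's last-containing interval
    start (>= date of f+1), which also makes the first-seen intervals
    strictly order.  In overlap mode the target debut interval overlaps
    the source's first-seen interval (ambiguous direction) while some
    later target release still satisfies the survivor condition.  Either
    way the target run has length >= 2.
    """
    feasible: list[tuple[int, int]] = []
    for f in range(len(src_tl) - 2):
        d_first, d_last = src_tl.date_at(f), src_tl.date_at(f + 1)
        for j in range(len(tgt_tl) - 1):  # run length >= 2 → j <= last-1
            t_j = tgt_tl.date_at(j)
            if want_overlap:
                survivor = any(
                    tgt_tl.date_at(k) >= d_last for k in range(j, len(tgt_tl))
                )
                if d_first <= t_j < d_last and survivor:
                    feasible.append((f, j))
                    break
            elif t_j >= d_last:
                feasible.append((f, j))
                break
    if not feasible:
        return None
    return rng.choice(feasible)


def verify_ground_truth(
    corpus: VersionedCorpus, truth: GroundTruth
) -> ValidationReport:
    """Check that every planted tuple is realized, exactly.

    For each sentence string a planted instance mentions, its actual
    occurrence set in the corpus (recomputed by sentence extraction) must
    equal the set the ground truth claims.  Violations are reported as
    strings; an empty report means the generator is self-consistent.
    """
    actual: dict[str, set[tuple[str, str, str]]] = {}
    claimed: dict[str, set[tuple[str, str, str]]] = {}
    for inst in truth.planted:
        for db, entry, rid, sentence in inst.occurrences:
            claimed.setdefault(sentence, set()).add((db, entry, rid))
    if claimed:
        for ev in corpus.entries:
            for key in set(extract_sentences(ev.text)):
                if key in claimed:
                    actual.setdefault(key, set()).add(
                        (ev.database, ev.entry_id, ev.release_id)
                    )
    violations: list[str] = []
    for sentence in sorted(claimed):
        got = actual.get(sentence, set())
        want = claimed[sentence]
        for miss in sorted(want - got):
            violations.append(f"missing occurrence {miss} of {sentence!r}")
        for extra in sorted(got - want):
            violations.append(f"unclaimed occurrence {extra} of {sentence!r}")
    return ValidationReport(tuple(violations))
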