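# Methods

This note records the model behind `annotrail`, the choices made where the
design was genuinely open, and what the validation strategy does and does
not establish.

## Data model

A *versioned corpus* couples per-database release calendars with one plain
text annotation block per (database, release, entry). Releases are ordered
positionally within a database — dates may tie, and the publication
sequence, not the calendar, defines "the next release". Dates matter only
across databases, where they are the sole timing signal. A sentence's date
is always an upper bound: databases are developed continuously but
published periodically, so presence in release *r* means "present by
*r*'s date", with the slack set by the release frequency.

Entry deletion is represented by absence of the record, not tombstones.
Downstream, an entry missing from a release contributes no sentence
occurrences there, so deletion terminates all of the entry's presence
runs. This is a modelling choice: a deleted entry's annotation really is
gone from the published product.

## Sentence identity

Sentences are compared by exact equality of a minimal normal form:
lower-case (simple per-character mapping, not aggressive case-folding, for
locale independence) with whitespace runs collapsed to single spaces.
Nothing else — no stemming, stop-word removal or punctuation change. Exact
matching is deliberately blunt: it misses edited copies (see the edit
demonstration below) but a match is very strong evidence of shared
history.

Segmentation is the one underdetermined step, and every count downstream
is sensitive to it. The default splitter breaks after `.`/`!`/`?` followed
by whitespace and an alphanumeric, except when the preceding token is a
curated abbreviation or a single letter (genus initials: *E. coli*,
*B. subtilis*). Paragraph breaks are hard boundaries, which is why the DAT
adapter joins comment-topic blocks with a blank line — independent topic
statements must never fuse into one sentence. Splitting runs before
lower-casing because capitalization is a segmentation cue. The splitter is
pluggable (`extract_sentences(text, splitter=...)`) for users who prefer a
different segmenter; published counts from other tooling will differ
unless the segmenter matches.

Within-entry duplicate sentences are counted per slot in the multiplicity
map (they are real redundancy mass) but presence in an entry is binary for
run computation (runs model membership over time). This distinction is
isolated behind the index so either convention can be audited.

## Pattern definitions and numerical choices

All three within-database patterns are functions of maximal presence runs,
with sentence-level counting: one label per sentence per database, however
many entries exhibit it; the earliest qualifying run is the recorded
witness.

- *Transient*: some run has length 1 and does not touch the latest release.
  Requires ≥ 2 releases (otherwise unobservable, and the query is rejected
  rather than answered vacuously).
- *Possibly transient*: some censored run of length 1. Precedence: a
  sentence already transient elsewhere is not additionally counted here —
  the class is the "cannot classify yet" remainder, so the two labels are
  disjoint by construction.
- *Missing origin*: with *f* the sentence's earliest ordinal in the
  database and *O* the entries holding it at *f* (a simultaneous debut set
  is treated as a joint origin, since release granularity cannot
  distinguish a single source within it), the label applies iff some
  *m* > *f* has no *O*-entry holding the sentence, some *O*-entry holding
  it at *m* − 1, and some entry outside *O* that debuted strictly after
  *f* holding it at *m*. Entries debuting at *f* are origin members, never
  propagation targets. Only the first qualifying removal is witnessed;
  later re-introductions do not retract the label. Detection requires ≥ 3
  releases; the degenerate case where the secondary debuts exactly at the
  removal release is counted, as the definition admits it.

Ranking ties in `top_reused` break lexicographically; all report writers
sort their rows — every output is deterministic and diff-stable.

Cross-database detection is a candidate generator, not a classifier.
Each release is assigned the half-open date interval to its successor
(open for the latest). A candidate requires: first source interval not
after the first target interval (strict ordering → `ordered`, overlap →
`ambiguous`, reversed → rejected), absence from every source-group
database's latest release, and a target release holding the sentence
whose interval starts at or after the source's last-containing interval.
Group membership uses lifetime occurrence, because cross-database flows
span years and the interesting shared sentences are often already gone
from the latest releases.

## Synthetic ecosystems

The generator emulates the dynamics the detectors target: entries seeded
from a shared template pool (3 sentences per entry by default, from a
120-template pool — enough to create within- and cross-database reuse at
realistic density without swamping small corpora), then per-release
background processes with configurable per-entry probabilities: birth of a
pool sentence, copy of a random sentence from another entry's *previous*
release (lag 1, the smallest observable propagation), removal, and a
synonym-substitution edit that breaks exact-match identity. All defaults
are zero so the inert corpus is exactly static.

Planted instances are constructed to satisfy the corresponding detector
definition and *only* that definition: origin runs of length ≥ 2 (so a
missing-origin plant is never also transient), secondary runs censored,
cross-database source runs removed before the source's latest release and
target runs persisting to the end. Planted sentences open with a reserved
token the template pool cannot produce, so recovery is exact set equality
rather than a statistical estimate. Release calendars are regular;
alternate databases are offset by half a period so cross-database
intervals order strictly (`offset_calendars=False` forces coincident
calendars and hence `ambiguous` candidates). Generation is a pure function
of the config, and `verify_ground_truth` re-extracts every claimed
occurrence from the emitted corpus — the generator self-checks on emit.

What the synthetic corpora do *not* model: natural-language variety and
sentence-length distributions, entry birth/death, coordinated
cross-database release schedules, or the heavy-tailed reuse distributions
of real resources (where a single sentence can occur millions of times).
Passing the planted-recovery tests therefore shows the detectors implement
their definitions exactly on clean signals; it does not estimate their
yield or error rate on real archives, where segmentation choices and
editing dominate.

## Validation strategy and problem sizes

- Detectors are checked against an independent brute-force transcription
  of the definitions, exhaustively over all binary presence matrices of up
  to 3 entries × 4 releases (4,096 matrices) — small enough to enumerate,
  large enough to contain every qualitative configuration of debut,
  propagation, removal and censoring.
- Planted-pattern recovery runs on a 2-database × 12-release × 200-entry
  ecosystem with background off and 160 plants; precision and recall are
  exact set comparisons.
- Conservation invariants (singleton ≤ unique ≤ total, multiplicity sums,
  partition totals) run over 100 randomly configured small ecosystems with
  all background processes active.
- The published single-database and cross-database timeline narratives are
  encoded as fixtures and must classify as described, including the
  cross-database case being invisible to either database alone.
- The edit limitation is asserted, not hidden: with forced edits on
  cross-database copies, exact-match recovery of the planted instances is
  zero.

These sizes keep the full suite and the acceptance script in the
tens-of-seconds range while exercising every code path; all stochastic
pieces are seeded and derandomised.

## Known limitations

- Exact matching misses every edited copy; recall against real archives is
  unknowable from within this framework (by design).
- The segmenter is heuristic; counts are comparable only under a fixed
  segmenter.
- Cross-database direction inference rests entirely on release dates;
  overlapping intervals are surfaced as `ambiguous` rather than resolved.
- The in-memory index holds the full corpus; archives larger than memory
  are out of scope (the SQLite persistence is a cache/interchange format,
  not an out-of-core engine).
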