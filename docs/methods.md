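# Methods

This note records the definitions the toolkit implements, the conventions
chosen where the task description leaves room, and what the synthetic
test bed does and does not establish.

## Standoff representation

A document is a text plus two annotation layers. The given layer (`.a1`)
holds typed entity mentions (`T` lines: id, type, start/end offsets,
surface string) and `Equiv` relations (`*` lines) marking local aliases.
The target layer (`.a2`) holds event triggers (`T` lines in the same id
space), events (`E` lines: type:trigger followed by role:filler pairs) and
`Negation`/`Speculation` modifications (`M` lines). Conventions adopted:

* Offsets are 0-based, end-exclusive, over Unicode code points.
* Type names with internal spaces (e.g. *Gene or gene product*) are
  serialized with underscores, since fields are whitespace-delimited.
* Repeated same-role arguments carry numeric suffixes in serialization
  (`Theme`, `Theme2`, ...); the suffix is presentation only and is
  stripped (`role_base`) before any semantic use.
* `Equiv` lines are accepted in either file but always belong to the
  given layer; the relation is closed symmetrically and transitively
  (union-find) and never contains events.
* Both `\n` and `\r\n` input line endings are accepted; output is `\n`.
* Parsing is strict: a surface string that disagrees with the text at its
  offsets is an error. A lenient flag downgrades exactly this check to a
  warning, to tolerate normalization differences in third-party data.
  Dangling references and event-argument cycles are always errors.

## Type systems

The CG schema has 18 entity types (organism- to molecule-level) and six
event categories (anatomical, pathological, molecular, general,
regulation, planned); the PC schema has 4 entity types and three
categories (simple, general, regulation). Role multiplicity follows the
task tables' notation — bare = exactly one, `?` optional, `+` one or
more, `*` zero or more — with one documented reading: an *additional*
(non-core) argument printed without a marker is treated as optional,
because a mandatory argument would contradict the additional/core
distinction itself. The chemical-modification families are expanded to
the concrete types that appear in the tasks' per-type result breakdowns
(CG: Acetylation, Glycosylation, Ubiquitination, Dephosphorylation, DNA
methylation, DNA demethylation alongside Phosphorylation; PC additionally
Deacetylation, Methylation, Demethylation, Deubiquitination). `Breakdown`
is categorized as anatomical, following the schema table rather than the
result-table row ordering; the category is metadata and is overridable.

Filler categories (which entity types satisfy *Molecule*, *Anatomy*,
*Site*, the location roles, ...) are not exhaustively enumerated anywhere
authoritative. The shipped tables are a documented best effort — e.g. CG
*Anatomy* covers all anatomical entity rows plus *Pathological formation*
and *Cancer*, CG *Molecule* covers the five molecular entity types — and
are exportable/overridable through the YAML schema dialect. Accordingly,
filler-category findings are reported as warnings, while structural
findings (unknown types, unlicensed roles, multiplicity violations, event
fillers where only entities are licensed, `Equiv` over events) are errors.

## Matching criteria

*Word-level span relaxation.* A token is a maximal alphanumeric run;
spans are snapped outward to the tokens they overlap. The default
`approximate` rule accepts a predicted trigger iff its first and last
token indices each differ from the gold ones by at most 1 — a symmetric
reading of "up to one word on each side". The historical official tooling
used an asymmetric containment-in-extended-gold-span rule; both it
(`containment`) and exact offsets (`strict`) are available as
configuration, so results can be compared across conventions.

*Recursive matching.* The core match relation is computed as the greatest
fixed point: start from all (gold, predicted) pairs with equal type and
matching triggers, and repeatedly delete pairs whose core arguments
cannot be aligned under the current relation. Alignment demands a perfect
per-role bijection between filler multisets (brute force over the handful
of same-role slots), with entity fillers equal modulo `Equiv` class and
event fillers required to be in the relation. On acyclic event graphs —
which the format guarantees — the fixed point coincides with direct
recursion, verified against a memoized recursive reference
implementation; the fixed-point formulation additionally stays
well-defined if cycle checking is disabled. The top-level (primary)
match additionally requires all non-core arguments to align.

*Deduplication.* Before scoring, structurally identical events (same
type, trigger span, and argument multiset, compared through the merge
itself) are merged on both sides, so duplicated predictions cannot
inflate precision; this mirrors the duplicate elimination the core-target
reduction performs.

*Single partial penalty.* Among the unmatched residue, a (gold,
predicted) pair matches partially iff types and triggers agree and one
side's role-normalized argument multiset is a strict sub-multiset of the
other, all shared arguments aligning. Pairs are selected by a maximum
bipartite matching; because different maximum matchings can disagree on
which side each pair waives, the selection is made canonical: the
lexicographically smallest maximum matching in ascending (gold id, pred
id) order, computed greedily with a feasibility check. For each selected
pair, extra predicted arguments waive the gold false negative; missing
ones waive the predicted false positive. Modifications are scored exactly
as under the primary criteria (the relaxation is defined for event
arguments).

*Counting.* Matching is set-based (a gold event is matched if ≥1
prediction matches it and vice versa); SPP is the only stage with an
explicit assignment. A modification is matched iff a same-type
modification exists on the other side whose target events match at top
level. Counts are pooled micro-style over documents into per-type rows,
category subtotals, an event `Sub-total`, a `Modification total`, and a
grand `TOTAL` that includes modifications. Rows with no instances on
either side are omitted. Percentages are printed to two decimals, rounded
half away from zero; zero-denominator ratios are 0 by convention, and F
is computed from unrounded P and R.

## Significance testing

The statistic is the grand-total F difference under the chosen criteria
(primary by default). Because scoring is document-local, each document
contributes a fixed (gold matched, gold total, predicted matched,
predicted total) tuple per system; a permutation swaps the tuples of the
two systems per document with probability ½ (stratified shuffling, the
standard formulation for corpus-level F). The default repetition count is
9,999 and the p-value uses the add-one estimator (r+1)/(R+1), which is
valid at finite R. Swap decisions are drawn in doc-id-sorted order from a
single seeded generator, so results are reproducible across platforms. An
exhaustive 2^n enumeration is provided for small corpora as a reference.

## Synthetic corpora

The generator emits "token soup": whitespace-separated pseudo-words, each
entity mention and trigger covering exactly one word with padding words
between mentions (so a one-token trigger shift is always possible and
unambiguous). Events are drawn from the schema with all role constraints
satisfied; regulation-family events take event-valued Themes up to a
configurable nesting depth. Defaults: 20 documents, Poisson(10) events
per document, nesting depth 3, regulation probability 0.3, and rates of
one modification per ~13 events (0.075), Equiv membership 0.05, and
non-core arguments 0.06 per event — chosen to loosely track the scale of
the published corpus statistics (the CG data has roughly one modification
per 13 events and one Equiv relation per 19, with ~6% of events carrying
non-core arguments). Everything is deterministic given the seed.

Perturbation plans apply seeded edits in a fixed order: event deletion
(with cascading deletion of referring events — re-pointing would invent
events the plan did not specify), duplication (an exact copy, removed
again by the scorer's deduplication and used as a regression test for
it), retyping within the same role signature, one-token trigger shifts,
argument drops and spurious additions (fillers drawn from the existing
given layer, since predictions may not add entities), Equiv-sibling
swaps, and modification flips. Deletion and duplication have exact
expected confusion counts (reported alongside the predictions); the other
operations are flagged context-dependent.

What the synthetic bed does *not* emulate: natural trigger
lexicalizations, sentence structure, the empirical type distribution of
the real CG/PC corpora, discontinuous or overlapping mention spans, and
cross-sentence annotation artifacts. Passing tests therefore establish
the correctness of the scoring machinery on schema-conformant input, not
system performance on real text; real corpora downloaded from the task
homepage are read by the same code paths (use the lenient flag if their
normalization differs).

## Numerical and procedural choices

* Rounding: two decimals, half away from zero, via exact decimal
  arithmetic on the repr of the float.
* The oracle scorer refuses documents with more than 15 events; its SPP
  search is exhaustive and intended for fixture scale only.
* Problem sizes in the test suite and acceptance script (hundreds of
  single-document fixtures of ~5 events at depth ≤3, corpora of ≤10
  documents for exhaustive permutation enumeration) were chosen as the
  smallest scales at which every code path — nesting, Equiv, SPP
  directionality, modification scoring — is exercised across both tasks
  and all four criteria settings.
* Significance comparisons between Monte-Carlo and exhaustive p-values
  use a three-standard-error band plus one repetition's resolution.

## Known limitations

* Normalization (`N`) lines, attribute types beyond Negation and
  Speculation, and discontinuous spans are not supported.
* Filler-category membership is a best-effort table (see above); strict
  category validation of real corpora may produce spurious warnings.
* Whether the official grand total weights modifications exactly like
  event rows is inferred from the published tables' layout
  (`Modification total` preceding `Total`); this reading is implemented.
* Per-type significance testing, macro-averaging, and bootstrap intervals
  are out of scope.
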