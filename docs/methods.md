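# Methods

## Cleavage model

A protease rule is a set of *site patterns* and *exception patterns* in
Schechter–Berger nomenclature. A pattern maps positions P4…P1 (N-terminal
side) and P1′…P4′ (C-terminal side) to allowed residue sets; the scissile
bond is P1–P1′. For a candidate between-residue index *i* (0-based, the
bond between `seq[i-1]` and `seq[i]`), a pattern holds iff every
constrained position exists in the sequence and carries an allowed
residue; the bond is cleaved iff some site pattern holds and no exception
pattern does. Consequences of this definition:

- **Sites are strictly internal** (1 ≤ i ≤ len−1): terminal "cleavage" is
  impossible by construction.
- **Out-of-range context is a non-match.** In sequential mode each enzyme
  digests the previous round's fragments independently, so a P2 or P2′
  constraint that would reach past a fragment terminus simply fails. This
  is the conservative choice — truncated context can suppress but never
  create a site — and it is a documented divergence risk versus tools that
  re-evaluate context on the intact parent.
- **Exhaustive digestion** (no missed cleavages): fragments are the
  maximal runs between consecutive sites and tile the parent exactly.
  Digestion kinetics, structural accessibility and partial hydrolysis are
  out of scope.

Rules are compiled to zero-width regular expressions
(fixed-width lookbehind/lookahead), which makes the 60,840-combination
screens fast while keeping the rule file declarative.

Ambiguity codes B, Z, X, U are accepted in input sequences under the
default `never-cleave` policy: they satisfy no constrained position, so an
ambiguous P1/P1′ never cleaves. The `error` policy rejects them instead.

### The bundled library

`data/enzymes.yaml` defines exactly 40 enzymatic proteases (chemical
cleavage agents are deliberately excluded) in PeptideCutter-style rules,
including the trypsin/chymotrypsin families, Asp-N and Lys-N
endopeptidases, the caspase family, thermolysin, papain, ficin,
enterokinase, proline endopeptidase and others. Published specificities
were simplified where the literature rule is context-dependent beyond
P4/P4′ (e.g. trypsin's conditional K–P cleavage override is dropped; only
blocking exceptions are kept). The file is the single source of truth:
replacing it changes the library, and no bit-compatibility with any
external digestion tool is promised.

## Combination screening

Depth-*k* combinations are ordered tuples with distinct consecutive
entries — the only convention under which a 40-enzyme library yields
40·39 = 1,560 pairs and 40·39² = 60,840 triples. Enumeration is
lexicographic by name tuple, so results are independent of library file
order. Per combination, all substrates are sequentially digested,
products outside the inclusive 5–30 residue window are dropped, the rest
are pooled across substrates and deduplicated by sequence, and each unique
peptide's multi-label prediction increments every class it is called
positive for. Per-class winners break ties toward the lexicographically
smallest enzyme tuple (an all-zero class is flagged `no positives`).

Digestion results are memoized by (enzyme, fragment sequence) — sound
because site finding is deterministic — which reduces the screen to one
digest per unique fragment rather than one per combination. A dedicated
test asserts the memoized path agrees with the reference
coordinate-tracking `sequential_digest`. Prediction results are likewise
memoized per sequence, sound because the predictor contract requires
purity; a test asserts screen serialization is byte-identical under
reordered evaluation.

Two counting conventions coexist deliberately: per-combination counts
(`ScreenResult.counts`, the basis of "best combination per class") and
pooled per-class totals across all combinations
(`ScreenResult.class_totals()`). They answer different questions and are
reported separately.

## Filter cascade

Retention is the conjunction of four independent predicates, so the
outcome is order-free; the audit trail records the first failing gate in
the fixed evaluation order toxicity → bitterness → plasma → intestinal.
Boundary semantics follow the most explicit published phrasing in each
case and are all config-overridable (`WorkflowConfig`):

| gate | rule | default |
|---|---|---|
| toxicity | exclude if called toxic | — |
| bitterness | exclude strictly above | 333 |
| plasma half-life | retain at or above (inclusive) | 800 s |
| intestinal half-life | retain strictly above | 1.0 s |
| pose energy | retain at or below (inclusive) | −30 kcal/mol |

The plasma boundary is stated both exclusively ("exceeding 800 s") and
inclusively ("800 s or greater") in the source material; the inclusive
reading is adopted. Class confirmation uses an all-positive consensus
across named platforms by default, with an m-of-n generalization;
score-threshold gates default to strict inequality ("exceeding") with a
`greater-or-equal` option.

Pose energies are externally supplied (docking + MD re-scoring are out of
scope); the package only applies the cutoff and ranks retained poses
ascending by mean energy with deterministic (sequence, pose) tie-breaks.
The bundled `reported_poses.tsv` / `reported_candidates.tsv` transcribe
the published tomato-peel candidate tables and serve as worked-example
inputs only — none of their energies is recomputed here.

## Predictors

`BioactivityPredictor` is a pure, total contract: one prediction per input
peptide, scores in [0, 1] with calls consistent against the backend's
threshold, and no hidden state (enforced in the seeded backend by hashing
(seed, class, sequence), so predictions are independent of call order).
The table-backed adapter replays external server output from a long-format
TSV and, in strict mode, refuses unknown peptides. The
composition-heuristic baseline scores clipped linear functions of residue
group fractions (cationic, hydrophobic, aromatic, small, acidic, proline,
length ≤ 10); it exists so the pipeline runs end to end offline and is
explicitly **not** a reimplementation of any trained multi-label model —
per-combination counts obtained with it characterize the pipeline, not
real bioactivity.

## Synthetic fixtures

The generator emulates the *shape* of the study inputs, not their
content: 60 expression rows (default) with three replicate columns,
multiplicative replicate noise (sd 5% of the base intensity), log-normal
base abundances (σ = 1.2 around 500 arbitrary units, a microarray-like
dynamic range), ~90% annotated rows so a top-50 annotated selection has
headroom, and protein sequences drawn i.i.d. from Swiss-Prot average
residue frequencies with lengths ~N(300, 120²) clipped to [60, 600].
Optional planted motifs guarantee specific cleavage contexts (e.g. `KRP`
for a trypsin-vetoed bond). Mock score/safety tables cover every peptide
the fixture can yield at digestion depth ≤ 2 under the bundled library, so
strict table-backed screening cannot miss a key. Everything is a pure
function of the seed; equal seeds give byte-identical files.

What passing tests on these fixtures do **not** show: real proteome
composition (domain structure, repeats, signal peptides), probe-to-protein
mapping ambiguity, real predictor behaviour, or the published
per-combination counts — those depend on the trained external models and
the original expression dataset and are documented as out of reach
offline.

## Numerical and design choices

- Sample (n−1) standard deviation for replicate spread, matching
  triplicate error-bar convention; expression is ranked untransformed.
- Selection ties at the boundary break by ascending accession, making
  top-N independent of input row order.
- Coordinates are 0-based half-open everywhere; a fragment's sequence
  always equals `parent[start:end]`, through any number of sequential
  rounds.
- Problem sizes in `scripts/acceptance.py`: the full 1,560-pair screen
  runs over all 50 selected substrates; the depth-3 comparison
  (60,840 combinations) is restricted to the five most abundant
  substrates, the same restriction the motivating study applied to its
  triple-enzyme analysis.

## Known limitations

- Rule fidelity: specificities are simplified published rules; enzymes
  like ficin, bromelain and papain have broad, substrate-dependent
  preferences that no position pattern captures fully.
- No missed cleavages or partial digestion; yields are upper bounds on
  what a real hydrolysis would release.
- The composition baseline is intentionally crude; swap in a table-backed
  adapter over real server output for any scientific claim.
- Sequential-mode context truncation can under-cleave relative to tools
  that retain parent context (documented above).
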