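# Methods

## Scope and model

The package discovers a *bow-tie* process model around an index
hospitalization: a directed graph of diagnostic event classes observed in
a 730-day look-back window, a central index node, and a second directed
graph for a 365-day follow-up window. Nodes are meta-code classes (220
CCS-style groupings of ICD-10 codes), edges are directly-follows
relations at day granularity. Timing between events is deliberately not
modeled; only order and window membership matter.

## Data structuration

Raw episodes arrive as one delimited table covering inpatient and
outpatient activity; fields that do not apply to a setting stay blank.
Rules, in order:

- Timestamps are normalized to days (`yyyy-mm-dd`); configurable input
  dialects are converted at parse time. Rows with unparseable mandatory
  fields are dropped and reported with their row number.
- Episodes with no spell linkage are removed and counted.
- A spell (continuous stay) becomes exactly one coded event, dated at
  admission, labeled with the primary diagnosis of its first episode;
  other diagnoses recorded during the stay are discarded. A spell whose
  episodes disagree on the patient is an integrity error.
- Stays with neither a discharge date nor a length of stay are flagged
  day-care; a discharge date earlier than admission is treated as
  missing rather than fatal (degenerate-input choice).
- The index is each patient's earliest spell inside the study period
  whose primary diagnosis matches an index prefix (`A40`/`A41` by
  default). The age filter is strict (`age > 13`): a 13-year-old at
  index is excluded, a 14-year-old kept. Later index-matching admissions
  stay in the trace as ordinary post-index events, which is what makes
  recurrence statistics computable.
- Same-day events are ordered deterministically by (offset, input order,
  class label); day granularity leaves no better key.

Meta-code lookup uses longest-prefix semantics, so specific entries
(`N39.0` → UTI, `S72.0` → hip fracture, `R65.2` → septicemia) override
their broader families. Codes outside the table map to a sentinel
`UNMAPPED` class by default; an error policy is available. The bundled
table is a fixture authored for this package in the style of the AHRQ
Clinical Classifications Software, with exactly 220 classes; analysts
holding the full CCS release can substitute it via
`ClassMapping.from_csv`.

## Replay fitness

A model is scored by event-pooled replay fitness. Each trace side is
projected onto the model's node set; the first projected event replays,
and each subsequent projected event replays iff the pair
(previous projected class → current class) is a model edge. The score is
the ratio of replayed events to *all* events on that side, so excluding
a class from the model forfeits all of its events — node membership is
part of the optimization, not free. Consequences:

- the score is always in [0, 1]; 0 for the empty model, exactly 1 for
  the complete succession graph;
- adding an edge between existing nodes can never lower the exact score
  (tested as a property); adding a *node* can, because its events enter
  the projection without their successions — which is why search moves
  that introduce a node also wire it up (below);
- the "previous" event for the edge check is the previous projected
  event, not the previous replayed one.

Self-loops are legal edges (recurrent admissions for the same class are
clinically meaningful). A trace-averaged variant that gives every
patient equal weight is available behind a flag; the default pooling
weights long histories more. Scoring runs on an integer-compiled form of
the log with vectorized numpy lookups; a plain reference replayer with
identical semantics is kept in the API (`replay_trace`) and the two are
cross-checked against an independent oracle in the tests.

Monte Carlo scoring (sampling traces without replacement, redrawn each
iteration) is available for logs too large to score exactly; at desk
scale the default is exact scoring, and `sample_size >= n_traces`
degenerates to it.

## Search

Tabu search over feasible models under hard size caps (pre 25/40, post
15/25; the index node and its join edges sit outside both budgets):

- **Initialization**: node count drawn uniformly from the feasible
  range, nodes sampled without replacement weighted by distinct-patient
  support, then an edge subset weighted by succession support.
- **Moves**: add node, remove node (dropping incident edges), add edge,
  remove edge, swap node. Because a bare node strictly hurts the score,
  add/swap immediately attach the incoming node's highest-support
  candidate successions within the edge budget, evicting strictly weaker
  non-incident edges when the budget is full. This keeps every
  single-move neighbor feasible and makes node growth competitive;
  without it, every path to a larger node set passes through a
  score-decreasing intermediate and the search stalls at small node
  sets.
- **Selection**: up to 30 neighbors sampled per iteration (exhaustive
  when fewer exist); best non-tabu neighbor becomes current even when
  worse than the incumbent; tabu stores canonical model signatures for a
  tenure of 50 iterations, with aspiration for neighbors beating the
  global best. Ties break toward fewer edges, then fewer nodes, then
  lexicographic signature, so runs are reproducible bit for bit under a
  seed. A strict hill-climb mode exists behind a flag.
- **Stopping**: 25 consecutive iterations without improving the global
  solution, or 500 iterations total. The full per-iteration
  (current, global) score history is returned for audit.

The two halves are discovered in independent runs (with decorrelated
seed streams) and joined afterwards: for each patient, the last
discovered pre-index class contributes an entry edge into the index node
and the first discovered post-index class an exit edge, both weighted by
distinct patients. Whether link weights should count direct successions
or any-order co-occurrence is not fixed by the output format; this
package counts replay traversals (direct successions), documented here
as its choice.

No global-optimality guarantee exists (the problem is combinatorial);
on instances small enough to enumerate every feasible model, the test
suite checks the search never exceeds and does attain the exhaustive
optimum.

## Synthetic cohorts

The generator emulates the statistical shape of a national
hospital-activity extract, not any real prevalence:

- **Sequences**: pre-index histories are first-order Markov walks over
  the non-index classes; an optional `pre_to_index` distribution draws
  the class of the final pre-index admission (the bow-tie's entry
  edges), and `index_to_post` seeds the follow-up walk. Pre and post are
  independent given the index, matching the two independent discovery
  runs. Transitions at or above `dominance_threshold` are the *planted*
  edges that recovery experiments target.
- **Dates**: the index admission is uniform in the study year (2016);
  event days are uniform draws without replacement inside each window,
  sorted — order statistics rather than explicit inter-admission gaps,
  since day-level order is all discovery consumes. The true
  inter-admission time distribution is unknown; uniform-in-window is an
  assumption and is flagged for sensitivity work.
- **Records**: each event becomes an inpatient stay (LOS 1–14, ~10%
  gaining a second same-spell episode) or an outpatient attendance
  (blank discharge/LOS/admission-method) with probability 0.3; every
  patient gets exactly one inpatient index admission. Ages are uniform
  on 14–95 with a configurable fraction (default 5%) aged ≤ 13 to
  exercise the cohort filter. Codes are representative ICD-10 codes of
  each class from the bundled table, so structuration round-trips.
- **Noise and artifacts**: with probability `noise_rate` an event's
  class is replaced uniformly at random (ground truth keeps the
  pre-noise path). Artifact injection blanks discharge/LOS on a stay,
  orphans an episode (never an index admission — the cohort anchor must
  survive), or appends a duplicate same-timestamp episode carrying a
  secondary diagnosis; injected counts are returned for accounting.
- **Reproducibility**: one RNG stream per patient derived from
  (seed, patient index), so growing the cohort leaves earlier patients
  byte-identical.

The reference demo (`sepsis_demo_spec`) plants a 10-class bow-tie with
six dominant pre-index transitions (probabilities 0.6–0.7, including a
recurrent-UTI self-loop) and gives the three pathway entry classes
elevated starting mass (0.2 each). These strengths were chosen so the
planted pathway is *identifiable*: with 40 edge slots against ~100
observed successions, weaker planting leaves the replay-optimal model
free to drop a planted-edge source node entirely (verified by full
node-subset enumeration), at which point no optimizer could recover the
ground truth. Default cohort sizes are 500 patients for recovery
experiments and 120 for repeated-run property checks — sizes at which
the planted structure is comfortably above sampling noise. The follow-up
period is deliberately unstructured (uniform transitions), mirroring the
expectation that post-index events show recurrence rather than linkage.

What passing tests on these cohorts do **not** show: recovery under
real-world coding drift, true inter-admission timing, demographic
structure, or prevalence — the generator makes no attempt at any of
those.

## Known limitations

- Replay fitness counts skipped (non-node) events in the denominator;
  published variants of replay fitness differ on this point, and scores
  are comparable only within one convention.
- The tabu tenure (50) and neighbor sample size (30) are design
  defaults; the stopping rules (25/500) and size caps (25/40, 15/25)
  are fixed by the method definition.
- Spell resolution trusts the extract's spell identifiers; no stay
  reconstruction from overlapping dates is attempted.
- No statistical disclosure control is applied — outputs are intended
  for synthetic or already-cleared data.
- Mortality records are out of scope by design; traces end at the
  follow-up window regardless of vital status.
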