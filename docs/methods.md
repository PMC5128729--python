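# Methods

This note documents the models, default parameters, and design choices
behind `medagg`, and what the simulator's results do and do not show about
a real deployment.

## System model

The simulator is **single-process and turn-based**. Nodes, the broker,
and tuple centres are in-memory objects; message delivery is ordered and
reliable by construction. Timing behaviour of a real network (latency,
concurrent writes to a tuple centre, node churn mid-operation) is out of
scope: "blocking" tuple reads are modelled by the caller re-polling, and
the peers' answer deadline is modelled by the host closing the collection
window and treating silent invitees as rejecting (default window:
100 scheduler ticks, a bookkeeping value rather than wall-clock time).

## Discovery

Keyword matching is deliberately naive: case-normalized exact string
equality, with a subscription matching a publication when the
subscription's keyword set is a **subset** of the publication's. The
subscriber names a topic; publishers may be more specific. Subset (rather
than equality or overlap) keeps the matching direction consistent with
condition evaluation during negotiation, where the host's keywords must
be a subset of the peer's. Publications are retained, so a subscription
arriving later is immediately answered with all previously published
matches; we chose retained-publication semantics because discovery of
*existing* data is the primary use case. No stemming, synonyms, or
ontology alignment is attempted; semantic schema matching between
heterogeneous databases is explicitly a non-goal.

## Tuple centre

The coordination substrate is a multiset of logic tuples with `out`, `rd`
(read), and `in` (consume) plus *reactions* — trigger/guard/effect
records that fire atomically with the triggering operation. We did not
re-implement a first-order-logic reaction language: the negotiation needs
reaction *semantics* (state flips when the last `hello` arrives), not
Prolog syntax, and data-described reactions keep every firing inspectable
in the event log. Numerical/operational choices:

- tie-break among multiple matching tuples: insertion order, so every
  run replays deterministically;
- reaction cascades are depth-bounded (default 100); exceeding the bound
  raises an error signalling a non-terminating script;
- every primitive call and firing is appended to a JSON-lines event log.

## Negotiation

The session state machine has five states — Started, Active, Renegotiate,
Failure, Success — with transitions Started→Active,
Active→{Renegotiate, Failure, Success}, Renegotiate→{Active, Failure}.
Choices where the protocol description is open:

- **Keyword clause**: read as non-strict (⊆). A strict-subset reading
  would forbid a peer whose keyword set equals the host's, which
  contradicts the evaluation setup where every node carries the same
  two keywords.
- **Count clause** (`N ≥ 0`): read as "the requested count is
  non-negative" rather than a constraint on the peer's remaining
  capacity.
- **Acceptance policy**: a real deployment puts a human in the loop; the
  simulator replaces them with a deterministic policy — accept iff the
  capability-containment clauses hold and the proposed k-anonymity
  parameter is at least the peer's configured minimum (`AgentPolicy.min_k`,
  default 1).
- **Quota allocation** (not specified by the protocol): when offers
  exceed the requested N, quotas are proportional floors
  `⌊N·Ñ_a/ΣÑ⌋` with the remainder distributed one-by-one in
  descending-offer order, ties broken by agent id. Deterministic,
  and Σ quotas = min(N, ΣÑ) with quota_a ≤ Ñ_a always.
- **Renegotiation policy**: the host may widen every bounded numeric
  range by a relaxation factor (default 0.1 of the range width per
  round) and/or drop rejecting invitees (default: drop); at most
  `max_rounds` (default 3) renegotiations.
- **Host contribution**: the host's own database contributes through an
  internal answer, symmetric with the peers', but moves no data between
  nodes.
- **Success vs. waiting**: Success triggers when every invitee is
  finished *and* the requested N was obtained. All invitees finished
  with a shortfall leaves the session quiescently Active, open for new
  publishers announced by the broker (`join_agent`) — this keeps the
  observable edge set exactly the five transitions above.
- **Removal tuple**: dropping an agent during renegotiation writes
  `removedAgent(AgentId)`, an extension tuple shape of this
  implementation.

## Privacy pipeline

Order is fixed: pseudonymize → generalize → sign; nothing leaves a node
without all three.

- **Pseudonyms** are HMAC-SHA256 digests of the patient identifier under
  a shared study key: deterministic (so two nodes contributing the same
  patient update one research-database row instead of creating a
  duplicate) and one-way without the key. Key distribution is assumed,
  not modelled.
- **Signatures** are HMAC-SHA256 over the serialized record bundle under
  the signing node's key; verification succeeds iff the payload is
  unmodified and the key matches. This is a self-contained
  integrity/authenticity contract between nodes that share pairwise
  keys; certificate-authority infrastructure is out of scope.
- **Generalization** uses per-attribute binary interval hierarchies.
  Defaults for the neonatal schema: body weight over [0, 5000] g with 5
  levels (leaf width 156.25 g), gestational age over [20, 44] weeks with
  3 levels (leaf 3 weeks), postnatal age over [0, 32] days with 3 levels
  (leaf 4 days), gender {M, F} with a single generalization step. The
  default quasi-identifier set is {body weight, gestational age,
  postnatal age, gender}; the default k is 2; both are negotiable in the
  study condition.
- **Level selection** is a uniform-per-attribute greedy lift from the
  leaves: while any equivalence class is smaller than k, lift the
  attribute currently at the deepest level (ties by QID order) one
  level — the smallest marginal widening at each step. Because the lift
  path does not depend on k, raising k only moves the stopping point
  further along the same path, so intervals are monotone in k (they
  only widen or stay equal). The price is that the chosen assignment is
  minimal *along that path*, not globally minimal over all uniform level
  assignments; a globally optimal search can violate monotonicity when
  cost ties swap levels between attributes, and we prioritized the
  monotonicity guarantee. Records that cannot reach a class of size ≥ k
  even at the root (i.e. fewer than k records in total) are suppressed.
- Each node generalizes its own contribution under globally agreed
  trees, which preserves the k-property of that contribution.
  Composition of multiple independently released contributions is a
  strictly weaker guarantee than coordinated distributed anonymization;
  defending the combined release against composition attacks is out of
  scope and should be kept in mind when interpreting results.
- The research database audits whether generalized intervals **overlap**
  the requested ranges (containment can be destroyed by widening a
  boundary value's interval); non-overlapping intervals are ingested but
  logged as violations for audit.

## Synthetic data

No public deposit of the underlying neonatal TDM collection exists, so
the generator emulates it; its defaults are the simulator's study
conditions. 8922 complete records (the usable-record count we
standardize on, since the source's partial counts cannot all be
reconciled), keywords {"Gentamicin", "neonates"}, attributes:

| attribute        | distribution                                | range        |
|------------------|---------------------------------------------|--------------|
| gestational age  | truncated normal, mean 34 w, sd 4 w         | [24, 42] w   |
| body weight      | normal around 3300 − 150·(40 − GA) g, sd 300 g, clipped | [400, 5000] g |
| postnatal age    | uniform integer days                        | [0, 28] d    |
| gender           | Bernoulli(1/2)                              | {M, F}       |
| concentration    | log-normal (μ=1.0, σ=0.6 on log scale), mg/L| ≥ 0          |

The GA-linked body-weight mean (~150 g per gestational week, ~900 g at 24
weeks, ~3300 g at term) gives the positive GA–BW correlation any birth
cohort shows. Decoy datasets carry only age (uniform in [18, 100] years)
and gender under keywords like {"Malaria", "adults"}. Everything is
deterministic per seed; `missing_rate > 0` optionally punches holes to
exercise the incomplete-record rules.

What this emulation does *not* reproduce: the real data's clinical
statistics (dosing regimens, correlated sampling times, repeated
measurements per patient), multi-database schema extensions, or genuinely
shared patients across institutions. Passing tests therefore demonstrate
protocol and pipeline correctness — counts conserved, classes ≥ k,
signatures sound — not clinical fidelity.

## Record matching and partitioning

Range constraints are inclusive at both ends, consistent with the ≤/≥
comparisons of capability evaluation. A wildcard ("any") bound matches
every value, but a record *missing* a value for any conditioned
attribute never matches — including under a wildcard — mirroring the
discard-incomplete-records rule at query time. Units are fixed by
configuration (grams, weeks, days, mg/L), not hard-coded semantics.
"Split approximately equally" is operationalized as a balanced random
partition: part sizes differ by at most one (8922 records over 10 nodes
gives parts of 892–893), deterministic per seed.

## Evaluations

- **Consistency**: for a condition and a partition of the pool into
  1/3/5/10 agents, the per-agent offered counts from a full negotiation
  must sum exactly to the central query count. The acceptance run does
  50 seeded trials cycling through the 20-condition bank. The bank's
  exact contents are not prescribed anywhere beyond one example; ours is
  a JSON fixture whose first entry is that example (body weight
  2000–3000 g, gestational age 38–42 weeks, any gender, any
  concentration, N = 6000) and whose other 19 vary body-weight,
  gestational-age and gender combinations within the generator's ranges.
- **Timing**: `local_time`/`distributed_time` implement the
  collection-time model; wall-clock system run times are
  hardware-dependent inputs (`t_run`), never asserted numbers. Month
  conversion uses the mean Gregorian month (30.44 days).
- **Fairness**: 10 agents × 892 records, 200 runs per simulation. Each
  run a uniformly chosen agent hosts a uniformly chosen bank condition;
  transfers are accounted at the record-count level (the metric is about
  counts; running the anonymization pipeline per run would not change
  them). The reported metric is m(R) = meanₐ |obtainedₐ − providedₐ| / R;
  normalizing by the number of runs R turns "the gap converges" into a
  testable decreasing-in-R statement even though cumulative transfers
  grow. Conservation Σ(obtained − provided) = 0 holds exactly by
  construction of the accounting (each transferred record has one
  provider and one receiver; the host's own matches move nowhere).
  Each run builds a fresh database; reusing published RSDBs (which the
  metadata republication would enable) would reduce transfers and is a
  variant we did not simulate.
- **State machine**: exhaustive enumeration of every ≤3-agent,
  ≤2-round session over all per-round behaviour assignments
  (accept/reject/silent), driven through the real protocol code.

Problem sizes in the default test and acceptance runs (full 8922-record
pool for consistency, 20 seeds × 200 runs for fairness, 500-record
privacy audits, 1000 random evaluation pairs) were chosen so the whole
evaluation completes in about a minute on one CPU while keeping the
statistical checks well-powered.

## Known limitations

- No network transport, concurrency, or adversarial behaviour; agents
  are honest-but-curious at most.
- The k-anonymity guarantee is per contribution, not for the composed
  research database (see above).
- Uniform-level generalization sacrifices utility compared to local
  recoding or multidimensional partitioning schemes.
- Keyword discovery has no semantics; two communities using different
  vocabulary will not find each other.
- De-generalization (recovering utility as the database grows) is not
  implemented.
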