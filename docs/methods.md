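# Methods

This note documents the models and procedures the package implements, the
design choices that were genuinely open, and what the synthetic data does
and does not establish.

## Data model

Raw input is three delimited tables. The *event* table has one row per
timestamped clinical event (`subject_id, hadm_id, timestamp, event_id,
event_value, category`); the *admission* table carries
`admit_time, discharge_time, death_time, admission_type` per `hadm_id`;
the *vocabulary* maps `event_id` to a label, a category (admission, lab,
procedure, prescription, comorbidity, diagnosis) and an optional
root-to-leaf hierarchy path of event ids. Timestamps are treated as
timezone-naive local times, as is conventional for de-identified hospital
extracts.

### Cleaning

A record is kept only if its `hadm_id` exists and its timestamp lies in
`[admit_time, min(discharge_time, death_time)]`. Records after discharge
or death are entry errors; using the *earlier* of discharge and death is
deliberate — a record timed after death but before administrative
discharge is still an error.

### Sequence construction

Rows are ordered by (time bucket, input row order, event id) and grouped
per patient or per admission. Two element conventions are supported:

* `element-per-event` (default): each record becomes its own singleton
  element, so events with identical bucketed timestamps still emit
  ordered elements, in input row order. This is the convention that turns
  three same-timestamp rows into the sequence `(2), (6185), (30)`.
* `itemset-per-bucket`: records sharing a bucket merge into one sorted,
  de-duplicated itemset — the standard sequence-mining semantics.

Time bucketing is `none`, `day` (calendar-date truncation) or `admission`
(one bucket per stay). Granularity rollup replaces each event id with its
hierarchy ancestor at a requested depth; ids without a path pass through
with a warning rather than failing, since real vocabularies are ragged.

## Closed sequential pattern mining

A sequence *contains* a pattern when the pattern's elements can be mapped,
in order and at strictly increasing positions, onto sequence elements of
which they are subsets (gaps allowed). Support is the number of containing
sequences; the absolute threshold is `ceil(rate × n)`, i.e. "support rate
≥ rate". A frequent pattern is **closed** iff no super-pattern has equal
support; because support is anti-monotone, it suffices to search for the
equal-support super-pattern among the frequent set itself.

The miner grows patterns depth-first in a canonical order — append a new
singleton element with any frequent item, or extend the last element with
an item strictly greater than its current maximum — which generates every
pattern exactly once. Support is recounted by containment scan restricted
to the parent pattern's supporting sequences (sound by anti-monotonicity).
A post-filter removes patterns absorbed by an equal-support super-pattern.
This favors transparency over the fastest known data structures; the
correctness contract is exact agreement with
`brute_force_closed_patterns`, which enumerates *all* sub-patterns of all
database sequences (guarded to ≤ 64 total events) and recounts support
independently. Results are sorted by descending support, then total item
count, then lexicographic elements, so outputs are comparable across
implementations. Mining wall time is recorded but never asserted — it is
hardware-dependent.

Note a threshold-independence consequence used by the tests: closedness
does not reference the threshold, so the closed frequent set at a higher
support rate is exactly a subset of the set at any lower rate.

## Pathway graph and cohort selection

Mined patterns merge into a staged graph: node (stage *s*, label *L*)
accumulates the support of every pattern whose *s*-th element bears *L*,
and links join consecutive stages. Nodes are keyed by (stage, label) —
not label alone — so an event recurring at two positions yields two
nodes, preserving Sankey stage semantics. Link weights are summed pattern
supports; distinct-patient counts would be an alternative reading, and the
choice is recorded here rather than inferred. Stage-0 node mass therefore
equals the total support of all merged patterns, a conservation law the
tests assert.

Cohort selection treats each pathway event as a singleton element and
matches gap-allowed; the empty pathway matches every sequence. Labels are
emitted per the database's unit (patient or admission), matching the unit
mining ran on. By construction `|matched|` equals the miner's
`pattern_support` for the same chain, and appending an event can only
shrink the cohort.

## Attention-LSTM predictor

The tensor is admissions × days × features: day *t*, feature *f* holds
the summed event value (an occurrence count for binary events) of event
*f* on hospital day *t*. Stays longer than `max_len` (default 15) days
are truncated to the first `max_len` days by default; dropping such stays
entirely is available as `overflow="drop"` since both readings of
"too-long sequences" are defensible and the choice materially changes the
sample. Shorter stays are zero-padded with a {0,1} prefix mask.

Per day *k* the attention vector is `a_k = softmax(W_k · x_k)` and the
recurrence input is `x_k ⊙ a_k`. Design choices:

* `W_k` is a separate F × F matrix per day (`per-timestep`, default),
  with a `shared` option; the per-day form follows the indexed formula
  literally and lets early-stay attention differ from late-stay attention.
* Attention weights initialize at zero, i.e. exactly uniform attention,
  so any learned preference is signal, not initialization noise.
* Masked days contribute zero attention and pass hidden/cell state
  through unchanged, so predictions are provably invariant to padded-day
  values (asserted by perturbation tests).
* Inputs are standardized per feature using statistics of the *training*
  split's unmasked entries (stored with the model); label leakage through
  normalization is thereby excluded.

The recurrence is an LSTM (default 128 units; forget-gate bias 1) with a
sigmoid output head, trained with binary cross-entropy and Adam
(lr 0.001, β₁ 0.9, β₂ 0.999, ε 1e-8), batch 64 for 10 epochs by default
(256/20 is the alternative preset). A plain tanh-RNN cell is available;
on the synthetic task the RNN never beats the LSTM by more than noise,
mirroring the expected ordering of the two architectures. The network and
its gradients are written directly in numpy — at these sizes (T ≤ 15,
F ≤ 251) dense matmuls dominate and a framework adds nothing but opacity —
and the backward pass is verified against central finite differences for
both cells and both weight-sharing modes.

Data are split 0.7/0.15/0.15 into train/validation/test. Splits are
label-stratified (per-class seeded shuffle apportioned by cumulative
rounding): with small synthetic cohorts an unstratified split too often
starves a split of positives. AUROC is the rank-based concordance
probability (ties one half, via `sklearn.metrics.roc_auc_score`; the test
oracle is an explicit pairwise count); F1 uses a fixed 0.5 threshold,
recorded in the config.

## Synthetic data generator

The generator emulates *occurrence and ordering* semantics of an ICU-style
EHR extract, not clinical value distributions. Per patient: 1–2 contiguous
admissions (configurable), stay length uniform on a configurable range
(default 3–10 days), noise events Poisson per day (default mean 2) drawn
uniformly from the non-causal, non-admission vocabulary, and each
admission emits its admission-type event on day 0. Planted pathways are
assigned to distinct increasing days of the first admission so day
bucketing preserves their order. Outcomes are Bernoulli with log-odds
`intercept + Σ weight × 1[event in day-window]`.

Two invariants make the generator a usable oracle: noise never draws
pathway or causal event ids, so a pathway is contained iff planted; and
outcome signal enters only through planted events, so the causal feature
set is known exactly.

Default study conditions: the Emergency → Troponin T → CABG pathway
planted at rate 0.30; outcome driven by CABG with weight 6.0 and
intercept −3.0. The strong-signal scenario (one causal lab feature among
20, planted in half the patients, weight 6.0, intercept −3.0) is sized so
the Bayes-optimal AUROC is ≈ 0.95: per-admission outcome probabilities
are sigmoid(±3) ≈ {0.953, 0.047}, giving concordance
0.953² + 0.953·0.047 ≈ 0.953. A weight of 2 with centered intercept would
cap *any* model at ≈ 0.88, leaving no headroom to demonstrate recovery at
a 0.9 bar; the larger effect makes "the model found the signal" a
falsifiable claim rather than a coin flip.

What passing tests on this data do **not** show: robustness to
irregular/multimodal visit timing, correlated comorbidity structure,
numeric lab trajectories, missingness mechanisms, or label noise — all
present in real EHRs and all outside the generator's scope.

## Problem sizes and numerical choices

Test and acceptance workloads are sized for a single CPU: miner–oracle
equivalence uses 200 random databases of ≤ 8 sequences over a 5-symbol
alphabet; the anti-monotonicity database uses 500 single-admission
patients at reduced noise (0.6 events/day, 3–6 day stays) because the
closed-pattern lattice grows combinatorially with event density at 3%
support; pathway recovery uses 1000 patients; signal recovery uses 2000
admissions × 10 days × 20 features with 64 LSTM units over three seeds.
Attention row sums are checked to 1e-6 (softmax in float64); gradient
checks use central differences at 1e-6 with a 1e-5 relative tolerance;
standardization floors the per-feature deviation at 1e-6.

## Known limitations

* The miner's support recount is quadratic-ish in dense databases; very
  low support rates on long event-dense sequences are expensive (by
  design the package favors verifiable exactness over speed).
* `evaluate` requires both classes in the test set; AUROC is undefined
  otherwise and the package raises rather than guessing.
* Merged-graph link weights are summed supports, not distinct-patient
  counts; patterns sharing sequences double-count in node mass.
* The per-timestep attention (`W_k` per day) costs T·F² parameters and
  can overfit very small cohorts; use `attention_weight_sharing="shared"`
  there.
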