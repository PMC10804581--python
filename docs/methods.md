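# Methods

## Data model

A treatment log is a set of treatment processes (one per patient stay).
A process is a time-ordered sequence of treatment days; a day is a
non-empty bag of activity tokens sharing one timestamp *t*, the 1-based
day index within the stay.  Duplicate activities within a day are kept as
separate tokens (bag-of-activities, mirroring bag-of-words LDA).  The
timestamp universe |T| defaults to the largest observed timestamp; an
optional cap buckets long-stay tails (`max_timestamp`), since the count
arrays `q` and `m` are indexed by *t* and |T| bounds memory.  Calendar
dates must be converted to day indices by the caller (earliest date per
patient → day 1); the reader otherwise accepts delimited text or JSON
lines with columns `patient_id`, `day`, `activity`.

## The temporal model and its sampler

Three coupled Dirichlet-multinomial blocks: day-topic mixtures θ_d
(symmetric prior α), topic-timestamp distributions φ_k (prior δ), and
per-(topic, timestamp) activity distributions ϕ_{k,t} (prior β).
Collapsing θ, φ, ϕ leaves a Gibbs sampler over per-token topic
assignments driven by the counts n[d,k], q[k,t], m[k,t,a].  Design
choices that matter:

- **Current-token exclusion.**  The full conditional removes the token
  being resampled from all three count structures.  This is the only
  convention consistent with the collapsed joint: the test suite checks,
  on random tiny states, that the conditional equals the normalised ratio
  of collapsed joints of the K single-token completions to 1e-10.
- **Final estimates use full counts** (no exclusion): θ̂, φ̂, ϕ̂ are the
  smoothed count ratios of the final state.  An optional estimator
  averages the ratios over thinned post-burn-in states (off by default —
  it lowers variance but is vulnerable to label switching).
- **Determinism.**  Tokens are visited in fixed corpus order; each sweep
  consumes exactly one uniform per token (inverse-CDF categorical draw),
  so runs are bit-reproducible given the seed.  The sweep inner loop is a
  numba-jitted kernel; a pure-Python conditional is the reference
  implementation and a test asserts the kernel reproduces it token for
  token.
- **Defaults:** α = 1.0, β = 0.01, 2000 iterations (the standard setting
  for treatment-day topic models), burn-in 500.  δ has no established
  value; the default is 0.1 and the choice is inconsequential for the
  identifiability property below (verified at δ ∈ {0.1, 1, 10, 50}).
- **Counts storage** is dense (K × |T| × |A| int64); at the vocabulary
  and stay lengths this package targets (|A| ≈ 40, |T| ≈ 20) that is a
  few hundred kilobytes.
- **Topic presentation order.**  Raw sampler labels are arbitrary; for
  reporting, topics are ordered by their φ-mean timestamp Σ_t t·φ_{k,t},
  so "topic 0" is the earliest-stay phase.

The LDA baseline is the same machinery without the timestamp block.  With
|T| = 1 the temporal conditional's time factor is exactly 1.0 in IEEE
arithmetic and both samplers consume the identical RNG stream, so their
trajectories agree bitwise — a strong end-to-end oracle for both
implementations.

## Identifiability: what the likelihood does and does not pin down

Every token of a day shares the day's timestamp, and ϕ is indexed by
(topic, timestamp).  Apply any permutation of topic labels to **all**
tokens at one timestamp: the day factor is invariant (each day lives at
one timestamp; the Dirichlet-multinomial is symmetric), the activity
factor is invariant (the (k, t) cells are carried along with their
counts), and the timestamp factor changes only through the symmetric
row-sum normaliser Σ_k lnΓ(q_k· + |T|δ).  Hence configurations that
relabel topics independently per timestamp — subject only to keeping the
per-topic totals balanced — have essentially equal posterior probability.
Two practical consequences, both reproduced in the test suite:

1. **Topic identity does not transfer across timestamps.**  A phase that
   spans several hospital days is recovered *per day*, but which sampler
   label serves it on day 3 versus day 4 is arbitrary.  Globally-matched
   recovery of φ and of time-marginal activity distributions is therefore
   only meaningful when each phase occupies a single timestamp (the
   regime used by the pathway-recovery tests).  The sampler's preferred
   mode in multi-day-phase regimes assigns each timestamp wholly to one
   topic: a chain initialised at the generating configuration moves to
   the timestamp-ownership mode and stays there.
2. **Training perplexity does not decrease with K.**  Since ϕ̂ is
   per-(topic, timestamp), a one-topic model already predicts each token
   with its timestamp's empirical activity mixture; extra topics only
   spread θ̂'s prior mass onto cells irrelevant for the day.  On
   model-generated corpora the perplexity curve is flat-to-increasing in
   K across every generator design and δ we examined, so the
   first-inflection selection rule has no signal there.  The rule is
   implemented as specified — interior K maximising the second difference
   p(K−1) − 2p(K) + p(K+1), falling back (flagged) to the smallest grid
   value when no curvature exceeds tolerance — and is exercised on
   hand-constructed curves; on real logs whose days mix phases in ways
   this generative family does not capture, the curve may behave
   differently.

The per-timestamp relabelling property is itself a unit test (the joint
changes by exactly the row-sum term).  The comparison metric
`time_resolved_error` respects the property: it Hungarian-matches topics
*per timestamp* (equally generous to LDA, whose slices are constant in
t), then averages per-(k, t) total-variation distances weighted by the
realised topic-timestamp distribution.  Under that metric the temporal
model's advantage on drifting activity distributions is real and large,
and is what the acceptance comparison measures.

## Synthetic data

The generator draws from the model's own structure so every stage is
testable without clinical data.  Defaults, chosen once as the study
conditions:

- **Scenarios** shaped like oncology courses: 37 distinct activities
  (a realistic order-catalogue size for one service line), K ∈ {3, 4}
  care phases, stays uniform on (5, 11)–(9, 17) days (means ≈ 8–13),
  8 activities per day, 400 processes.
- **Activity structure:** activities split into K contiguous blocks;
  phase k puts `separation` = 0.8 of its mass uniformly on its own block.
  `time_drift` moves the within-block mass from the block's first half to
  its second half across the phase's own window (drift 0.8 ⇒ TV ≈ 0.6
  between a phase's early and late profiles) for the drifting scenarios.
- **Phase schedule:** the stay is tiled by K contiguous windows; the mean
  day mixture gives `theta_concentration` = 0.8 to the window's phase.
  Each day draws θ_d ~ Dirichlet(κ · profile) with κ = 1.0, so most days
  are dominated by one phase — matching how treatment days read in
  practice (a day is usually devoted to one kind of care) — while the
  dominant phase varies day to day.  Deterministic θ is available
  (κ = None).
- **Two modes.**  `"day-timestamp"` (default) respects the data
  definition: days are 1..LOS, one timestamp per day; the true φ is then
  *induced* by the realised (z, t) pairs and reported with the ground
  truth.  `"model-faithful"` follows the likelihood factorisation
  literally: each token draws its own t ~ φ_z and becomes a single-token
  day.  The two stories (one timestamp per day vs per-token timestamps)
  are in genuine tension in this model family; both are provided rather
  than resolved.

What the generator does **not** emulate: activity co-occurrence beyond
the block structure, comorbidity-driven heterogeneity between patients,
readmissions, and calendar effects.  Passing recovery tests on this
family therefore demonstrates correctness of the inference machinery
under the model's own assumptions, not performance on real EMR data.

`recovery_report` matches topics with a single global permutation
(Hungarian assignment on time-marginal activity TV, exact for any K) and
reports per-topic TVs for the activity marginals and φ, plus θ error.
The θ error is reported as the mean absolute error over (day, topic)
entries (`theta_mae`): with 8 tokens per day even an oracle knowing the
true per-token topics incurs a full-vector L1 error around 0.3 from
multinomial noise alone, so the per-entry error (oracle ≈ 0.08) is the
informative scale; the full per-day L1 is also reported (`theta_l1`).

## Evaluation and pathway extraction

- **Top activities per topic** are ranked by the φ-weighted time marginal
  ϕ̄_k(a) = Σ_t φ_{k,t} ϕ_{k,t,a}; ties break toward smaller activity
  ids; per-timestamp rankings are also exposed.
- **NKQM@N** = mean over topics of Σ_{j≤N} score(j)/log₂(j+1) divided by
  Z_N = Σ_{j≤N} 2/log₂(j+1), the ideal all-2 ranking — base-2 logs and
  ideal-DCG normalisation follow the NDCG convention, bounding the score
  to [0, 1].  Three raters combine by majority vote; a three-way split
  (one each of 0, 1, 2) resolves to the median 1.
- **Pathway extraction:** for each day t up to the horizon (default:
  ceil of mean length of stay), the topic probability vector is the
  renormalised mean of θ̂ over days observed at t; a day with no
  observations gets a flagged uniform row and a warning.  An alternative
  φ-based view (p(k | t) ∝ φ_{k,t}) is exposed as `mode="phi_time"`.
  Columns are presented in φ-mean-timestamp order and the dominant-topic
  sequence breaks ties toward the earlier phase.

## Numerical and testing notes

- Perplexity uses the predictive p(a | d) = Σ_k θ̂_{d,k} ϕ̂_{k,t_d,a};
  with positive priors it is finite and ≥ 1, and it is invariant to topic
  relabelling.  Held-out perplexity folds in θ for unseen days by a short
  Gibbs run with φ̂, ϕ̂ frozen.
- The sampled-vs-enumerated posterior check uses an 8-token corpus with
  α = 1, δ = β = 0.5: priors chosen so the 256-state posterior is neither
  near-uniform (where 200k samples cannot beat TV 0.02 even for a correct
  sampler) nor bimodal-sticky (where the Monte-Carlo floor depends on
  mode-hopping luck).
- Problem sizes in the test and acceptance harnesses (150–400 processes,
  150–500 sweeps) were chosen so each statistical check has clear margin
  over its Monte-Carlo noise while the whole suite stays interactive on a
  single CPU.
- Model artifacts are single JSON files (schema-versioned); floats
  round-trip exactly via shortest-repr.

## Known limitations

- Cross-timestamp topic identity is unidentified (see above); treat φ̂
  and time-marginal topic summaries with care unless phases are
  single-timestamp.
- Hyperparameters are fixed (no slice-sampled or fixed-point prior
  optimisation); timestamps are discrete day indices, not continuous
  times.
- The CLI covers the common pipeline only; programmatic use is the
  primary interface.
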