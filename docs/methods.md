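# Methods

## The model

A vesicle release site holds at most one releasable vesicle.  Its state
σ(t) ∈ {0, 1} changes only two ways: an AP arriving at `t_AP,i` while
σ = 1 releases the vesicle with probability `P_r|a(t_AP,i)` (σ → 0), and an
unavailable site refills exactly once per inter-release period, after a
random availability time `T_a` with CDF `F` and mean `τ_a` (σ → 1).  The
two bookkeeping rules that define a *correct* simulation are (a) no
release without availability and (b) once available, the site stays
available until released.  Most published simulation bugs violate (b).

**Availability Model 1 (AM1).**  `T_a` is drawn once, at the release, and
later spikes do not disturb it.  The refill probability between two
consecutive observation times `a < b` (elapsed since the release) is the
Bayes conditional `(F(b) − F(a)) / (1 − F(a))`.

**Availability Model 2 (AM2).**  While unavailable, the clock re-anchors
at every spike: the refill probability over a gap θ is simply `F(θ)`.

For exponential `F` the conditional equals `F(b − a)` and the two models
coincide; for any other law they do not, and the package treats them as
distinct simulation targets.

**Release models.**  `P_r|a(t)` is either a constant or the standard
facilitation law: rest value `Q`, jump `P → P + S(1 − P)` at each spike,
exponential decay toward `Q` with time constant `τ_f` between spikes.  A
release-independent depression variant steps down by `D·(P − floor)` and
recovers identically.  `P_r|a(t)` depends only on the spike times, so the
per-spike sequence is precomputed once and shared across trials.

## Default study conditions

| parameter | default | meaning |
|---|---|---|
| `τ_a` | 0.5 s | mean availability time |
| `P_r|a` | 0.6 | constant release probability given availability |
| `Q`, `S` | 0.4, 0.2 | facilitation rest probability and jump fraction |
| `τ_f` | 0.1 s | facilitation recovery time constant |
| f grid | 5–150 Hz (step 5) | periodic-drive frequencies for error surfaces |
| K, H | 20 (first-release), 100 (totals) | spikes per train |
| Z | 10,000 (CLI default), up to 100,000 in the test suite | trials |

All times are seconds; no unit conversion layer exists.  Every simulation
starts from a forced release at t = 0 (the site is empty at the start), so
AP times must be strictly positive; `start_available=True` selects the
fully-stocked initial condition instead, which is the one the closed-form
mean model assumes.

## Algorithms and conventions

* **Correct AM1**, three equivalent forms: draw `T_a` once per release
  (`resample_at_release`, works for any distribution, one variate per
  release); flip a per-spike coin against the Bayes conditional while
  unavailable (`per_spike_conditional`); or take the next event of a
  pre-generated rate-1/τ_a Poisson stream (`pregenerated_poisson`,
  exponential only).  A spike arriving exactly at the scheduled
  availability instant finds the vesicle available (`>=` tie-break).
* **Correct AM2**: identical to the first form except the refill clock is
  re-drawn at every spike that finds the site empty, anchored at that
  spike.
* **Flawed variants** (namespaced, warn on use, kept as regression
  anchors): `am1_i11`/`am1_i12` compare `P_a(t|t_s)·P_r|a` (resp. two
  separate coins) against fresh uniforms every spike with no persistent
  availability state — algebraically identical laws, over-releasing;
  `am1_i2` keeps a persistent flag but uses the unconditional `F(t − t_s)`
  where the Bayes conditional belongs, making too many vesicles available
  after multi-spike gaps (the 0.4/0.7 worked example: 82% instead of 70%);
  `am2_i1` anchors `F` at the previous spike with no persistent state,
  under-releasing.  The flawed-AM2 form is described in its source only as
  "analogous" to the first flawed AM1 form; the adopted reading
  (previous-spike anchor, no flag) reproduces the documented
  under-estimation and is the natural transcription.
* **Implied availability for i11.**  The single-coin variant has no
  explicit availability state; its trajectory records `U < P_a` as the
  implied availability (coupled to the same uniform as the release event,
  so release ⟹ available).  This makes the trajectory validator fail on
  i11/i12 — by design: the validator enforces exactly the contract these
  algorithms break.
* **Binomial fast paths.**  Refills are drawn before releases within a
  spike.  Exponential: one binomial refill draw on the unavailable pool
  with `1 − e^{−θ/τ_a}` plus one release draw — valid because
  memorylessness makes the refill probability common to all unavailable
  trials regardless of release history.  General AM2: the same with
  `F(θ)`.  General AM1: the unavailable pool is partitioned into cohorts
  by release spike; each cohort gets one binomial draw with its own Bayes
  conditional; a cohort is refilled wholesale and pruned once its
  conditional reaches 1 − 1e−12 (bounds memory on long trains).  Counts
  are conservation-checked at every spike.
* **Time-stepped comparator.**  Per-step refill coin with probability
  `Δt/τ_a` after each release.  `Δt ≥ τ_a` is rejected; `Δt > τ_a/50`
  warns.  Step uniforms are drawn in batches of 512 from the trial's
  stream and compared vectorised; the consumed-draw count reported is the
  number of step comparisons actually resolved, matching the sequential
  algorithm's consumption (the unconsumed batch tail is discarded, so the
  stream is deterministic per seed but not identical to a strictly
  sequential draw order).
* **Seeding.**  Multi-trial drivers give trial *j* its own PCG64 stream
  seeded `seed + j`, so enlarging a trial count never re-randomises
  earlier trials.  Uniforms are drawn on (0, 1); an exact 0.0 is nudged to
  the smallest positive double before `log`.
* **Facilitation jump convention.**  The piecewise law assigns the jumped
  value at the spike instant but does not say whether that spike's own
  release decision sees it.  Default: the decision at spike *i* uses the
  pre-jump value, so an isolated spike releases with probability `Q`,
  consistent with `Q` as the rest/steady-state probability;
  `jump_applies_to_current_spike=True` selects the other convention.
  Both are tested.

## Analytic oracles

Until the first release there is a single release anchor (t = 0), so the
first-release law of *every* variant — correct or flawed, any availability
distribution — follows from chaining the per-spike coin probabilities the
algorithm actually uses; mass conservation (probabilities + never-released
residual = 1) holds to 1e−12.  The no-stopping marginal release law uses,
for the correct models, the forward recursion equal to the closed-form
mean availability times `P_r|a` (exponential only), and for the flawed
variants an exact renewal decomposition over the last-release spike index
(O(K²)); both are cross-validated against simulation and, for K ≤ 6,
against exhaustive enumeration of every outcome branch.

**Relative error convention.**  Error surfaces report
`|test − correct| / correct`, undefined (flagged, NaN) where the reference
probability is zero.  On the standard grid the exact maxima are: flawed
AM1 (i11) absolute 0.0698, flawed AM1 (i2) absolute 0.1048 (at low
frequency, as expected — slow refill makes the unconditional-CDF bug
worst there); at 150 Hz the maximum relative errors are 358% (i11) and
479% (i2), rising with spike index.  Estimating these surfaces from 10⁵
trials instead of the exact recursions adds Monte-Carlo noise of order
±20 percentage points to the relative-error maximum, since the reference
probabilities at 150 Hz are of order 0.01.

## What the synthetic data does and does not capture

All inputs are generated: periodic trains `t_i = i/f` and fixed-count
homogeneous Poisson trains.  These exercise everything the algorithms
depend on (inter-spike-interval structure, refill-clock anchoring), but
real spike trains are neither periodic nor Poisson (bursting,
rate-modulated), real synapses have multiple, possibly correlated release
sites, and calcium-dependent refill dynamics are not modelled — `τ_a` is
a phenomenological constant.  Passing tests therefore certify the
*algorithms* against their *conceptual models*, not the models against
biology.

## Numerical choices

* CDFs use `expm1`/`log1p` forms; the Bayes conditional is clipped to
  [0, 1] against round-off and raises a dedicated error when conditioning
  on a zero-probability event (`F(a) = 1`).
* Custom distributions invert their CDF by bisection with a doubling
  upper bracket, tolerance 1e−10.
* The Rayleigh law is parameterised by its **mean** (scale
  = mean·√(2/π)), so `make_rayleigh(0.5)` has mean availability 0.5 s.
* Statistical agreement tests use two-sample KS at α = 0.001 on
  first-release indices (conservative under discreteness) or simultaneous
  ±4.5 SE binomial bands on per-spike fractions; *dis*agreement tests
  (AM1 vs AM2 under Rayleigh; mean model vs non-exponential AM1) require
  a z-score above 3 somewhere.
* Desk-scale problem sizes in the test suite: equivalence checks at
  Z = 10⁵, the worked-example simulation at 10⁶, release totals and
  Rayleigh comparisons at 10⁴, the time-stepped convergence check at
  3×10⁴ with Δt = τ_a/1000.

## Known limitations

* Multi-vesicle sites, correlated sites, spontaneous release,
  time-varying `τ_a` and frequency-dependent recovery (time-varying
  `τ_f`) are out of scope; release-independent depression is supported
  only as a static release-probability model.
* The binomial fast paths require release probabilities independent of
  each trial's release history (true for both release models here); they
  are invalid for history-dependent release.
* The no-stopping analytic marginal law is exponential-only; for other
  distributions use the simulators (the first-release law, however, is
  exact for any distribution).
* Per-trial loops are pure Python and scale linearly; they are the
  reference implementation, not the fast path.
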