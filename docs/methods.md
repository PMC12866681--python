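# Methods

## Model

The probability that the observer reports "right" for a stimulus with
interaural time difference `ITD` (µs, negative = left ear leading) and level
difference `ILD` (dB, negative = left ear louder) is modeled as an additive
probit with lapses:

```
p_R = Φ(α_ILD·ILD + α_ITD·ITD + β) · (1 − γ) + γ/2 + δ
```

* `α_ILD` (1/dB) and `α_ITD` (1/µs): cue sensitivities.  Their ratio
  `TITR = α_ILD / α_ITD` has units (1/dB)/(1/µs) = µs/dB and is the ITD
  needed to offset a 1 dB ILD of opposite sign, from
  `α_ILD·1 − α_ITD·TITR = 0`.  The ratio is dimensionally forced in this
  orientation; it is invariant under joint rescaling of (α_ILD, α_ITD, β).
* `β`: ear bias, a shift of the perceptual midline on the probit axis.
* `γ ∈ [0, 1)`: lapse rate, the fraction of responses made independently of
  the stimulus.
* `δ`: spout bias, the side preference on lapsed trials.  We impose
  `|δ| ≤ γ/2`; without this constraint the predicted probability can leave
  [0, 1] for extreme stimuli.  With it, `p_R ∈ [γ/2 + δ, 1 − γ/2 + δ] ⊆
  [0, 1]` always, with no post-hoc clamping.  The constraint is a modeling
  choice of this package: a guessing-trial bias cannot logically exceed the
  share of guessing trials.

The model is additive: no ITD × ILD interaction term.  Residual diagnostics
(observed minus predicted right-fraction per condition, plus a
row/column sign-pattern check) are the tool for judging whether that
assumption holds on a given data set.

## Task structure and trial schema

The stimulus grid is finite; the default is ITD ∈ {0, ±60, ±80} µs ×
ILD ∈ {0, ±1, ±4} dB with (0, 0) excluded — 24 conditions.  Conditions with
strictly conflicting cue signs (8 of the 24) are *probe* trials: no correct
side exists, the subject is always rewarded, and these trials carry the
cue-trading information.  All others (16), including single-cue conditions,
are *honesty* trials, rewarded only for the side of the nonzero cue(s).
Trial containers enforce this contract at construction so that malformed
logs cannot enter the analysis silently.

Session quality control uses honesty trials only (probe trials are correct
by construction and would inflate the metric): a session is kept when its
honesty accuracy is ≥ 0.75.  The boundary is inclusive by default — the
protocol this mirrors describes the criterion both as "above 75 %" and as
"reached or exceeded 75 %", and we follow the inclusive reading — with a
flag (`inclusive=False`) for the strict alternative.  Sessions without any
honesty trial have undefined accuracy and are excluded with a warning.

Both honesty and probe trials enter the response tables and the fit: the
per-condition (n_right, n_total) counts over the full grid are the
sufficient statistics.  Cells never presented are recorded as absent, not as
zero-probability.

## Fitting

The likelihood is the binomial product over presented cells (identical MLE
to the per-trial Bernoulli product, cheaper by a factor of the cell
occupancy); binomial coefficients are dropped, so the reported negative
log-likelihood is ≥ 0.  Predicted probabilities are clipped at
`eps = 1e-12` inside the likelihood only, to keep log(0) out of degenerate
evaluations; a warning is raised if the clip is active on a cell whose
counts contradict it.

Optimization is bounded L-BFGS-B in the coordinates
`(α_ILD, α_ITD, β, γ, δ/(γ/2))`: the δ-fraction coordinate turns the
coupled constraint `|δ| ≤ γ/2` into a fixed box `[−1, 1]`, and the box on
γ is `[0, 0.99]`.  We chose box constraints in natural coordinates over a
smooth unconstrained transform (logistic γ, tanh δ): the objective is
identical on the feasible set, bound-hitting is directly observable (used
for the separation flags below), and there is no gradient vanishing at the
γ → 0 boundary where many real observers sit.  Magnitude caps
|α_ILD| ≤ 5 /dB, |α_ITD| ≤ 0.5 /µs, |β| ≤ 10 keep separated data sets
(responses perfectly predicted by the stimulus) finite.  Convergence
tolerances: `ftol = 1e-12` (relative objective change), `gtol = 1e-8`,
500 iterations, with the optimizer status reported as the `converged` flag.
The tight `ftol` costs little here and pins the optimum closely enough for
the grid-search equivalence check in the test suite.

Sixteen deterministic starts are used: a probit-regression warm start
(weighted least squares on probit-transformed cell frequencies) plus a
fixed 15-point lattice covering both cue-sign quadrants, weak/strong
sensitivity, bias-only and high-lapse regimes.  The best final value wins;
ties cannot occur in practice and would resolve to the first minimizer.

Identifiability handling, by flag rather than by error where data (not
design) are at fault:

* design with a single presented ITD or ILD level → hard error (the
  corresponding α is structurally unidentifiable);
* responses all on one side, or a sensitivity at its bound → `separation`;
* cue model beating the best stimulus-blind constant-probability model by
  fewer than 3 log-likelihood units → `titr_unidentifiable` (the data carry
  no usable cue signal, e.g. a near-pure guesser);
* fitted α_ITD = 0 → `titr_undefined`; negative fitted ratio →
  `negative_titr` (reported, not excluded, unless another flag fires).

Flagged animals are listed but excluded from cohort statistics, with a log
line.

## Synthetic cohorts

The generator is the package's validation instrument, not a fixture.  Per
trial it draws the class (probe with probability 0.18, matching the
observed ≈ 82 %/18 % honesty/probe split of the 4:1 interleaving), then a
condition uniformly within the class subset, then a Bernoulli response from
the model, then the reward per the task contract.  Defaults: 17 sessions ×
240 trials per animal — 4080 trials, matching the ≈ 4070-trial per-animal
average of the emulated schedule; the protocol's alternative "≈ 200 trials
per session" phrasing is available through `trials_per_session`.  Probe
scheduling is an independent per-trial Bernoulli draw by default
("randomly interleaved"); a fixed one-probe-per-block schedule is available
via `schedule="block"`.  Uniform condition frequencies within class are an
assumption — real schedules show unequal cell totals, but the published
per-condition frequencies do not determine a schedule.

The nine-observer reference cohort anchors its generating trading ratios at
the cohort statistics the analysis is meant to recover — minimum
3.9 µs/dB (animal 9), median 18.7, maximum 27.1 (animal 1) — with six
filler ratios (8, 12, 16, 21, 24, 26) chosen not to move the median.  ITD
sensitivities are fixed per animal at 0.013–0.018 /µs so the ±60/±80 µs
stimuli fall in the informative part of the psychometric range; lapse rates
0.05–0.15 and small biases put expected honesty accuracy at roughly
0.78–0.86, inside the 75–95 % band where the reliability criterion
operates (occasional session exclusions are therefore expected and
exercised).  α_ILD follows as TITR × α_ITD.

What the generator does **not** emulate: per-condition presentation
imbalance, session-to-session drift in motivation or attention (available
only as an explicit lapse-jitter option), reaction times, training history,
and any pulse-rate dependence (the pps field is a pass-through label).
Passing recovery tests therefore demonstrate estimator correctness under
the idealized task structure, not robustness to every behavioral
nuisance in real animals.

## Validation

* **Parameter recovery** (primary): 50 replicates of simulate → QC → fit →
  summarize on the reference cohort.  Median absolute relative error of the
  recovered per-animal TITR ≤ 10 % (measured ≈ 4.5 %), recovered cohort
  median within 10 % of the generating 18.7 µs/dB (measured within 1 %).
  The weakest animal is the 3.9 µs/dB observer, whose small α_ILD carries
  the largest relative uncertainty (≈ 11 % median error) — an estimator
  property, not a defect.
* **Oracle equivalence**: on ten random ~500-trial instances the optimizer
  matches an exhaustive 5-D grid search within one final grid step in every
  parameter and 1e-3 in negative log-likelihood.  The oracle refines by
  tracking the sublevel set `{NLL ≤ best + Δ}` with Δ shrinking from 50 to
  1e-6: re-boxing onto a likelihood region rather than a single argmin is
  what keeps narrow correlated valleys (e.g. γ–β–δ trade-offs) inside the
  lattice until it resolves them.
* **Invariants**: probability bounds and monotonicity in each cue, point
  symmetry `p(ITD, ILD) + p(−ITD, −ILD) = 1` at zero biases, maximum
  likelihood dominance over the generating parameters, count conservation
  in response tables, byte-identical pipeline reports under fixed seeds.

## Numerical and reporting conventions

* Cohort median: midpoint convention for even counts; quartiles by linear
  interpolation.
* Across-animal curve SEM: sample SD over contributing animals divided by
  √(n animals) — the animal, not the trial, is the unit of replication;
  undefined (NaN) for a single animal.
* Heatmap exports: ILD rows descending, ITD columns ascending, right-response
  fraction per cell; long-format tables carry the raw counts.
* All randomness flows from explicit integer seeds through
  `numpy.random.SeedSequence` spawning; replicate and per-animal streams
  are independent and reproducible.

## Known limitations

No confidence intervals on fitted parameters (bootstrap or profile
likelihood would be natural extensions); no alternative link functions; the
signal-vs-guessing flag threshold (3 log-likelihood units) is a heuristic,
not a calibrated test; the generator's uniform condition schedule is an
idealization of real presentation statistics.
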