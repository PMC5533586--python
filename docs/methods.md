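# Methods

This note documents the task model, the learning models, the estimation
machinery, and the design decisions taken where the published description
of the paradigm leaves the implementation open. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Task environment

A schedule is an ordered list of phases, each with per-option delay
distributions and a session count. The default design is the study's:
a 3-session initial baseline, then the four shift types (HV upshift,
HV downshift, LV upshift, LV downshift), each a 5-session shift phase
followed by a 5-session return to baseline — 43 sessions of 60 completed
trials. Delay distributions are Normal in seconds: baseline mean 10 s for
both options with σ_HV = 4 s and σ_LV = 1 s; upshifts move the shifted
option's mean to 5 s and downshifts to 20 s, σ unchanged.

Decisions taken where the design is under-specified:

* **Negative draws.** A Normal with mean 5 s and σ 4 s has ~11% mass below
  zero, and a delay cannot be negative. Draws below 0 are rejected and
  redrawn, so the realized distribution is the Normal truncated at zero.
  The induced upward mean bias is negligible at baseline (μ/σ ≥ 2.5) and
  small (~0.3 s) during the HV upshift; the delay-generator tests compare
  against a rejection-sampling oracle rather than the untruncated mean.
* **Initial baseline length.** The study advanced animals on a stability
  criterion; the simulator fixes 3 sessions, which reproduces the printed
  43-session total deterministically.
* **Counterbalancing.** Shift orders are assigned by a cyclic 4×4 Latin
  square cycled over the cohort (agent *i* gets row *i* mod 4) — the study
  states counterbalancing without giving the scheme.
* **Session length.** A session is exactly 60 completed choice trials; the
  45-minute wall-clock alternative termination is not modeled. Response
  windows, inter-trial intervals and satiety are likewise out of scope.
* **Precision.** Delays are recorded at millisecond precision (3 decimals)
  at draw time, so CSV logs round-trip bit-exactly and re-fitting a
  written log reproduces in-memory results.

## Learning models

Four nested models. Outcome value is hyperbolic in the delay,
`V = 1/(1+kD)`, bounded in (0, 1]. (The source description prints the
denominator with a minus sign, which is singular/negative for `kD ≥ 1` —
including its own fitted `k ≈ 0.3` at the 10 s baseline delay — and
contradicts the hyperbolic-discounting literature it builds on; this
package uses the standard `1 + kD` form.)

Per completed trial, with `δ = V − Q` for the chosen option:

* `RW`: `Q ← Q + α·δ`, α constant.
* `PH`: as RW, plus `α ← η·|δ| + (1−η)·α`.
* `RW_EU`: `Q ← Q + α·δ/(ω·exp(σ′))`, α constant, and
  `σ′ ← σ′ + α_risk·(δ² − σ′)`.
* `FULL`: both mechanisms, with the divisor also applied to the surprise
  input of the learning-rate update:
  `α ← η·|δ|/(ω·exp(σ′)) + (1−η)·α`.

Choice is softmax in the two Q values with inverse temperature β,
computed as a logistic of `β·(Q_HV − Q_LV)` per side so neither
probability underflows.

Interpretation and initialization decisions:

* The uncertainty term is a **divisor** (`δ/(ω·exp(σ′))`): expected
  uncertainty shrinks the impact of prediction errors, and ω ≥ 1 scales
  individual sensitivity to it. The alternative operator reading
  (multiplication) would make uncertain options learn *faster*, the
  opposite of the mechanism the models encode.
* `σ′` is tracked **per option**, mirroring per-option Q and α.
* Initial values: `Q₀ = 0.5` for both options (midpoint of the attainable
  value range), `σ′₀ = 0`, and both options share the initial learning
  rate α₀ before updating independently.
* Within a trial the update order is fixed: value update, then (where
  applicable) learning-rate update, both using the pre-trial `σ′`; `σ′`
  updates last. Only the chosen option's state changes.

With α, α_risk ∈ [0,1], divisor ≥ 1 and V ∈ (0,1], every update is a
convex combination, so Q, α and σ′ remain in [0,1] without clipping — a
property the test suite asserts over random trajectories. The reductions
`PH(η=0) ≡ RW`, `RW_EU(α_risk=0, ω=1) ≡ RW` and
`FULL(α_risk=0, ω=1) ≡ PH` hold bit-for-bit and are tested end-to-end.

## Synthetic cohorts

The generator emulates the study conditions: 8 agents per group, the full
43-session schedule, choices sampled from the model's own softmax, delays
from the active phase's distribution for the chosen option, learning
contiguous across sessions. Group defaults are the published best-fitting
model and group-mean parameters (control/sham → FULL; basolateral-amygdala
lesion → RW_EU; orbitofrontal lesion → PH). Per-agent seeds derive
deterministically from a cohort master seed and are written to a
provenance sidecar, so any cohort regenerates bit-identically.

What the generator does **not** emulate: session- or side-bias effects,
response latencies, satiety, reward-port behavior, and any choice noise
beyond softmax. Omissions are off by default; an optional
condition-dependent initiation-omission probability exists for
demonstrating the qualitative omission pattern (more omissions in
downshifts) but no generative omission model is published. Passing tests
on these cohorts therefore certify the pipeline's correctness under the
models' own assumptions, not the realism of the models for rat behavior.

Cohort heterogeneity: by default all agents share the group-mean
parameters. An option draws per-agent parameters from a Normal centred on
the mean with sd = SEM·√8 (undoing the standard-error scaling of the
published n = 8 groups), truncated to each parameter's legal range by
rejection.

## Fitting

Per agent and model, the negative log likelihood of the observed choices
is minimized under bounds k ∈ [0,10], α₀ ∈ [0,1], β ∈ [0,100], η ∈ [0,1],
α_risk ∈ [0,1], ω ∈ [1,20]. The [0,1] bounds are part of the model
definition and ω ≥ 1 is its published lower bound; the upper bounds on k,
β and ω are numerical-stability choices wide enough to contain any
plausible fit. Omitted trials contribute neither to the likelihood nor to
state updates; state is never reset across sessions; `n` in BIC is the
agent's completed-trial count, and the group-level BIC is the sum over
agents (the published group values are consistent with summation, which is
recorded here as an inference).

The per-trial likelihood recurrence cannot be vectorized across trials,
so the inner loop is numba-compiled; a naive pure-Python per-trial
evaluation of the same equations lives alongside it and in the tests,
which require agreement to 1e−9.

Optimization is multi-start (default 20 starts, tolerance 1e−6,
deterministic in the settings seed): a seeded Sobol screen of 100× as many
candidate points is evaluated directly (cheap relative to one optimizer
run) and L-BFGS-B is launched from the best `n_starts`. When several
models are fit to the same log, each model is additionally warm-started
from the embedded optima of the models it nests (e.g. the RW solution with
η = 0 for PH), which guarantees that a richer model never scores a worse
likelihood than a model it contains, beyond optimizer tolerance — the
screen alone was observed to miss such basins. If the likelihood is flat
in β up to its upper bound (saturated, near-deterministic choices), β is
reported at the bound and a warning is raised, since value-scale
parameters are then unidentifiable; the recovery report flags `k`
accordingly when most of a cohort's fits are in this regime.

## Known limitations: identifiability at the published parameter scales

Two structural facts dominate recovery behavior at the study's trial
count (T = 2580 per agent), and the package's own recovery experiments
quantify both:

* Because δ is bounded in [−1,1] and baseline delay noise moves V by only
  ~0.08, `σ′` equilibrates near δ² ≈ 0.006, so `exp(σ′)` stays within 1%
  of 1. The uncertainty divisor therefore acts almost exactly like the
  constant ω — a rescaling of α that plain RW absorbs — and the
  likelihood advantage of the uncertainty models over RW on data they
  themselves generated is small relative to the BIC penalty. Group-BIC
  model recovery consequently tends to select RW for cohorts generated
  from the richer models at the published parameter values.
* The FULL likelihood has a k–β ridge and boundary-attracting basins for
  α₀/η/α_risk whose depth differences are on the order of the expected
  overfitting margin (~p/2 nats), so per-agent maximum-likelihood
  estimates of k scatter widely and their cohort mean is biased upward
  with substantial seed-to-seed spread; β recovers to ~10% and η via its
  cross-agent dispersion. RW-generated cohorts, by contrast, recover all
  three parameters to a few percent — the machinery, not the data, is the
  difference.

These are properties of the model family at its published parameter
scales, not of the estimator: truth-started polishing finds the same
optima as the multi-start search, and the likelihood implementation is
verified against an independent oracle.

## Behavioral statistics

* **Baseline history** per option: running min, mean and max of all delays
  experienced for that option in baseline phases strictly before the
  current trial. Shift-phase delays never enter the history, and histories
  pool across all prior baseline phases (they do not reset after shifts).
* **Outcome classification**: a delay inside the closed interval
  [min, max] is *expected*, outside it *unexpected*; with fewer than two
  prior baseline observations the trial is *unclassifiable* and excluded.
* **Win/loss**: a delay shorter than the running baseline mean is a win,
  longer is a loss, equal is excluded. (The source's Methods sentence
  literally labels longer-than-mean delays wins, while its Results define
  win-stay as repetition after better-than-average outcomes; a shorter
  wait is the better outcome, so the default follows the Results reading
  and `win_rule="long"` provides the literal one for sensitivity
  analysis.)
* **Win-stay/lose-shift**: each completed trial over all baseline and
  shift phases is paired with the next choice (stay = same option);
  win-stays and lose-shifts score 1, win-shifts and lose-stays 0; cells
  are split by outcome class and converted to probabilities by dividing
  the score sum by the cell count. A pair whose next attempted choice
  ended in a choice omission is dropped; an intervening initiation
  omission does not break a pair (no choice was made).
* **Preference**: per-session HV-choice fraction over completed trials,
  with omission counts by type. The maximal shift response is the largest
  absolute session-minus-baseline difference in preference for the shifted
  option within a shift phase (signed), referenced to the mean over the
  immediately preceding baseline phase.

## Problem sizes

The test suite simulates full 43-session cohorts where the check is about
the study design (recovery, sign properties) and 9-session miniatures
(1 session per phase) where only the mechanics are under test. The
acceptance script draws 10,000 delays per generator and runs one
8-agent simulate-and-refit cycle of the FULL model.
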