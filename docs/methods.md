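# Methods

`attnstates` estimates coexisting attentional states during a sustained
attention to response task (SART) from two observation streams — thought-probe
immersion reports and response-time variability — using hidden Markov models
(HMMs), and links the two with classical inferential statistics. Because no
public trial-level dataset accompanies the design it targets, the package
ships a first-class synthetic cohort generator whose defaults encode the study
conditions; every analysis stage is validated against that generative ground
truth and against independent oracles.

## The generative model

A participant's attention is modelled as a first-order Markov chain over
`K = 4` latent states, advanced once per trial (1.5 s per trial: 350 ms digit,
1150 ms ISI). The default states and their signatures:

| state | probe signature | RT mean (s) | RT CV | omit | commit |
|---|---|---|---|---|---|
| `tut` | task-unrelated thought at 75–100 %, task focus ≤ 25 % | 0.33 | 0.43 | .08 | .60 |
| `unfocused` | every channel at 0–25 % | 0.32 | 0.18 | .03 | .45 |
| `task_focused` | task focus at 75–100 %, the rest ≈ 0 % | 0.31 | 0.09 | .01 | .25 |
| `mixed` | task focus ≈ 50 % plus task-related thought at 25–50 % | 0.30 | 0.13 | .02 | .35 |

Self-transition probabilities are ≈ 0.99 per trial (mean dwell ≈ 100 trials
≈ 2.5 min). This is a substantive choice, not a nuisance default: thought
probes are ~45 trials apart, so per-trial persistence much below ~0.99 makes
consecutive probes effectively independent and destroys the temporal signal a
probe-level HMM needs. The initial distribution is the chain's stationary
distribution (≈ .31/.23/.25/.20).

RTs on correct go trials are lognormal with state-specific mean and
coefficient of variation (CV), so the sliding-window RTV statistic directly
reflects the state's CV. The CV ladder spans a steady task-focused state, a
behaviourally similar mixed state, a middling unfocused state and a highly
variable TUT state; behaviourally the two steady states are near-twins, which
is why the behavioural (RTV) model supports fewer states than the
self-report model.

**Probe emissions.** Given the state, the four immersion channels
(task-focused, task-related, external, task-unrelated) are conditionally
independent categoricals over the five levels 0/25/50/75/100 %. Reports are
constrained to a total of at most 100 %: draws exceeding the budget are
rejected and redrawn (up to 100 attempts, then the largest channels are
stepped down a level at a time). Rejection preserves conditional independence
as closely as any budget rule can; a flag disables the cap to exercise the
cleaning path.

**Calibrating the default emissions.** The emission profiles were set once
against two structural requirements: the four states must be the BIC-optimal
description of a 28 × 20-probe cohort, and their signatures must match the
archetypes above. Rather than trial-and-error simulation, the profiles were
tuned with an exact design metric: for each pair of states, the
Kullback–Leibler cost (nats per probe, computed over the full 625-pattern
grid after cap-rejection renormalisation) of replacing the pair by its
product-of-marginals merge. A K−1-state model pays this cost; four states are
identifiable at n = 560 when the weakest pair's total cost exceeds the BIC
penalty of the extra state (≈ 73 nats). The final profiles have a weakest-pair
margin of ≈ 85 nats. Two lessons from this exercise are worth recording:
(i) contrasts concentrated in a single channel are nearly invisible, because
the merged state's channel marginals absorb them — each state pair must
differ on at least two channels simultaneously; (ii) the ≤ 100 % budget pulls
high-immersion profiles toward the origin, so nominal separation overstates
post-cap separation.

**Seeding.** One master seed; per-participant generators derive from
`numpy.random.SeedSequence(master).spawn(n)`. Identical (model, design, seed)
reproduce byte-identical tables.

## Preprocessing

* **Correct-go RT stream** — non-target trials with a correct response;
  target trials never contribute, even when (incorrectly) responded to.
* **Pre-probe windows** — mean RT and RTV (sample SD / mean, `ddof = 1`) over
  the five correct-go RTs immediately before each probe. A window is invalid
  if fewer than five such RTs exist or the go trial immediately preceding the
  probe was answered incorrectly; invalid windows are dropped from the
  regression with a logged count.
* **Sliding RTV series** — RTV over every window of five consecutive
  correct-go RTs, advancing one correct-go trial per step; this is the
  behavioural HMM's observation sequence.
* **Cleaning** — probes totalling > 100 % have all four channels set missing,
  then imputed per participant and channel by linear interpolation over probe
  order, rounded to the nearest legal level (boundary gaps take the nearest
  probe's value). Because rounding can push an imputed total back over 100,
  the largest channels are stepped down until legal — this makes cleaning
  idempotent. Totals of exactly 100 are legal (single-channel 100 % reports
  exist by design). The interpolation rule is configurable; it is one of
  several defensible readings of interpolating over-budget responses.
* **Classification** — mind-blank (all channels 0), single thought (exactly
  one channel ≥ 25), coexistence (≥ 2 non-zero channels); flags for 50/50
  splits and any-100 % reports. The three categories partition the full
  5⁴ grid.
* **Bimodality diagnostic** — Sarle's bimodality coefficient of each
  participant's correct-go RTs (> 0.555 suggests bimodal responding). It is a
  diagnostic only; no automatic exclusion, since the analogous exclusions in
  practice are judgment calls a pipeline should surface, not make.

## Hidden Markov models

Both models share one estimation core: scaled forward–backward in linear
space (per-step normalisation; per-time-point max-shift of log emission
likelihoods prevents underflow), batched across sequences by padding with an
activity mask, and Baum–Welch EM with the E-step pooled over sequences.
Multi-sequence handling is the statistically proper one — shared parameters,
independent sequences — with a `concatenate` switch that joins all
participants into one chain for fidelity with analyses that concatenated
before fitting; the boundary transitions that concatenation invents are the
reason the multi-sequence E-step is the default.

* **Emissions** — product-categorical (4 channels × 5 levels) for probe
  sequences; univariate Gaussian for RTV. Emission probabilities are floored
  at 1e-10 during EM and renormalised on output.
* **Initialisation** — categorical: Dirichlet(1) draws per state and channel;
  Gaussian: means from K quantile groups of the pooled data with small
  jitter, SDs at the pooled SD. Transitions start sticky (diagonal 0.8),
  initial distribution uniform. Default 20 restarts (5 in the orchestrated
  pipeline, where eight model sizes × two streams are fitted), tolerance 1e-6
  relative, max 500 iterations (300 in the pipeline).
* **Monotonicity** — the log-likelihood trace is checked on every iteration;
  a decrease beyond 1e-8 relative raises immediately. Restarts that collapse
  a state (no posterior mass) are re-initialised.
* **Selection** — BIC = −2 logL + p ln(n_obs) with
  p = (K−1) + K(K−1) + K·4·(5−1) (categorical) or 2K (Gaussian) and n_obs the
  total number of observation vectors. Self-report models use minimum BIC
  over K = 1..8; RTV models use the elbow rule (largest second difference of
  a monotonically decreasing BIC curve), falling back to min-BIC with a
  warning when the curve is not monotone.
* **Decoding** — posterior (gamma) and Viterbi paths; ties in the Viterbi
  argmax break toward the lowest state index. Occupancy counts Viterbi visits
  by default; posterior-mass occupancy is available.
* **Label matching** — fitted states are aligned to reference states by
  minimum-L1 optimal assignment on emission parameters
  (`scipy.optimize.linear_sum_assignment`); interpretive names
  (tut / unfocused / task_focused / mixed) come from expected immersion
  levels per channel and are reported alongside neutral indices.

## Downstream statistics

* **Per-state RTV** — mean pre-probe RTV over probes decoded into each state,
  per participant; compared with a repeated-measures one-way ANOVA
  (listwise-complete participants, subject term removed from the error;
  η² = SS_state / SS_total) and Tukey HSD on the pooled cells. A
  between-participants one-way ANOVA is available as a fallback.
* **Occupancy correlations** — Pearson r between every self-report-state and
  RTV-state occupancy pair across participants, with Benjamini–Hochberg
  adjustment over the full grid as one family; zero-variance occupancies are
  reported missing and excluded from the family.
* **Moderated regression** — pooled valid pre-probe windows; RTV on centered
  task-focus, centered TUT and their product. Immersion codes are rescaled to
  level units (0–4) before centering, so raw slopes are per 25 % immersion;
  standardised betas are unit-free. VIF per predictor (1/(1−R²_j)); simple
  slopes at moderator mean ± 1 SD with delta-method standard errors from the
  coefficient covariance and t-tests on residual df. Task-related and
  external channels stay out of the default regression (their upper immersion
  levels are too rare to support linear terms, mirroring the design the
  pipeline follows).
* **Power utilities** — the a-priori sample sizes the design quotes:
  correlation (r = 0.5, α = .05, power .80 → n ≈ 28.25) via the exact-r
  convention (critical r from the t distribution on n−2 df; Fisher-z power
  with the r/(2(n−1)) bias correction), and the four-group one-way ANOVA
  (f = 0.3 → n ≈ 31.27 per group) via the noncentral-F solver
  (`statsmodels.FTestAnovaPower`). Four groups is the only group count
  consistent with the quoted per-group n, which fixes `k_groups = 4` as the
  default.

## What the synthetic cohort does and does not establish

The generator reproduces the study's structure: sample sizes, design
geometry, probe spacing, the ≤ 100 % budget, four self-report states
recoverable by BIC at n = 560, and a behavioural state ladder whose extremes
match the reported RTV-state structure (≈ 0.09–0.18–0.43 with SDs rising in
proportion). It does **not** reproduce, and the tests make no claims about:

* **Effect sizes.** The latent state determines both the probe emissions and
  the RT distribution exactly, so state–behaviour coupling is far tighter
  than in real data: variance explained by the regression and the per-state
  RTV ANOVA run several times higher than real cohorts show. Passing tests
  demonstrate pipeline correctness, not realism of effect magnitudes.
* **Report-category rates.** Conditionally independent channels under a hard
  budget inflate single-thought reports relative to observed rates
  (~36 % vs ~14 %); the ordering (coexistence > single > mind-blank) is
  preserved. Capturing the observed coexistence rate would need within-state
  channel dependence, which the product-categorical emission family — chosen
  to match the estimation model — cannot express.
* **Sequential RT structure.** No autocorrelation, fatigue drift or
  participant-level heterogeneity beyond the latent chain.
* **The RTV elbow.** On the synthetic cohort the elbow rule selects two
  behavioural states, not three: the BIC drop from one to two states (the
  highly variable TUT state against everything else) dominates the second
  difference, and the near-twin steady states merge. This is a property of
  the elbow criterion under a single dominant contrast, reported as-is; the
  three-state Gaussian structure itself is validated directly by the
  parameter-recovery checks.

## Numerical and design choices

* Sample SD (`ddof = 1`) throughout; RTV undefined (invalid) on windows with
  a zero mean — impossible with positive RTs.
* "More than 100 %" means strictly greater: totals of exactly 100 are legal
  reports.
* Probe placement is uniform over feasible positions given the 15-trial
  spacing, by forward feasibility filtering; with 45-trial blocks and one
  probe per block every block admits a position.
* BIC's n_obs counts observation vectors (one probe = one vector), matching
  the likelihood's units.
* EM convergence: relative improvement < 1e-6. Gaussian SDs floored at 1e-6.
* The elbow rule needs ≥ 3 fitted sizes and a decreasing curve; otherwise
  min-BIC with a warning.
* The pipeline derives stage seeds from the run seed via `SeedSequence`, so
  any stage can be replayed in isolation; artifacts are written with a
  17-significant-digit float format and re-read with round-trip parsing, so
  write→read→recompute is bit-stable and two runs with one seed produce
  byte-identical CSV/JSON artifacts (the run report additionally records
  wall-clock timings).

## Problem sizes used by the checks

Exhaustive-enumeration oracles run at K ≤ 3, T ≤ 6 (200 instances);
categorical parameter recovery at 200 sequences × 100 points with selection
consistency over 20 replicate cohorts scanning K = 1..6; Gaussian recovery at
100 × 200; null calibration of the interaction test over 2,000 replicates at
n = 285 and of the occupancy-correlation FDR over 1,000 replicate cohorts;
the orchestrated-pipeline determinism check uses a 5-participant, 8-block
cohort with K = 1..3. These sizes were chosen so the full suite exercises
every claim at meaningful scale while remaining comfortably runnable on a
single CPU.
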