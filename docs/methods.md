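# Methods

This note documents the statistical procedures `vsdd` implements, the
assumptions of its synthetic-data generator, the defaults that matter, and
the design choices made where the design was genuinely open. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Task and data model

One behavioral trial: a first option with value `V1 ∈ {1..6}` is shown for
1000 ms; releasing a held button during this period commits to the option
(`chosen = 1`, with release latency `RT`), otherwise a second option
(`V2 ∈ {1..6}`) follows. Times are real-valued milliseconds with 0 at
first-option onset; spike times may be negative (pre-onset baseline).
Analysis windows are half-open `[t, t + L)` and labeled by their start
`t` — this avoids double-counting boundary spikes and matches the
convention that a signal latency is the start of its first qualifying
window. Trial and spike tables travel as plain CSV (UTF-8, comma, `.`
decimal, header mandatory, absent values empty); readers validate all
record invariants and referential integrity rather than assuming them.

One deliberate asymmetry: the trial reader enforces "latency present iff
chosen" for the decision task, so second-option response latencies do not
live in the same table; `fit_latency_regression(which='second')` operates
on whatever records the caller supplies with a latency and a second-option
value.

## Behavioral models

* Choice logistic: `P = logistic(β₀ + β₁·V1)`, maximum likelihood by IRLS
  (statsmodels GLM/Binomial) with a 25-iteration cap. Overtrained behavior
  frequently produces (quasi-)separation; this is reported via
  `converged=False` plus a diagnostic, never raised, and detected both
  from IRLS non-convergence and from unbounded estimates (|β| > 50 or
  non-finite standard errors).
* Indifference point (risk-attitude index): `−β₀/β₁`, defined only for a
  converged fit with nonzero slope.
* History logistic: `Pₜ = logistic(β₀ + β₁·V2ₜ₋₁ + β₂·V1ₜ)`; the first
  trial of each session is dropped (no predecessor), so n = trials −
  sessions. Sessions never share history.
* Latency chronometry: OLS of `RT` on option value. A constant response is
  returned as a flat line with `r² = 0` rather than NaN.
* Session-level inference: models are fit per session; the across-session
  mean ± SEM of the slope is reported with a two-sided Wilcoxon
  signed-rank test of per-session slopes against zero.

## Firing-rate primitives

Spike density functions replace each spike with a Gaussian kernel
(σ = 30 ms default), normalized so each spike contributes unit area in
seconds; a single spike peaks at 1000/(σ√(2π)) ≈ 13.30 Hz at σ = 30 ms.
Windowed rates are half-open counts divided by window duration.

The motor-control comparison measures, per neuron and task, the
peri-release modulation (mean rate in a release-aligned window, default
[−200, +200) ms, minus the pre-onset baseline rate, default [−200, 0) ms;
both windows are configuration parameters, not hard-coded). Unchosen
trials receive surrogate release times resampled with replacement from the
session's chosen-trial releases (seeded). Per-neuron significance is a
two-sided Wilcoxon signed-rank over trials; the population comparison is a
paired two-sided Wilcoxon signed-rank across neurons, run separately for
neurons with positive and negative decision-task modulation.

## Sliding-window model comparison

For each neuron and window, trial rates `F` are fit to the value model
`F = β₀ + β₁·V1` and the choice model `F = β₀ + β₁·C` by closed-form
simple OLS; the statistic is `ΔR² = R²_value − R²_choice`. The null
distribution reassigns the *baseline-window* firing rates (default
[−200, 0) ms) randomly across trials and fits both models to the shuffled
baselines — a no-signal ΔR² distribution sharing the trial count and the
V/C design of the window under test. Decisions at two-sided level α
(default 0.05):

* value-modulated: observed ΔR² strictly exceeds the null in more than
  (1 − α/2)·n_shuffle repetitions *and* the value model's F-test p < α;
* choice-modulated: the mirror image (fewer than (α/2)·n_shuffle
  exceedances, significant choice fit);
* intermediate: neither tail *and* both fits significant;
* otherwise unlabeled. Ties between observed and null ΔR² count as
  non-exceeding (conservative).

Each window draws a fresh permutation substream keyed by (seed, neuron,
window start), so results are reproducible per window and invariant to
which other neurons are analyzed. Whether the null should instead share
one permutation set across windows is not determined by the procedure's
definition; the per-window choice affects only the window-to-window
correlation of the null, not its marginal law.

A signal requires the same label across consecutive windows spanning the
equivalent of 40 windows at the 1-ms reference step. The step is
configuration-exposed (desk-scale analyses use 10 ms; the 1-ms original is
supported but ~100× slower); at step `s` the run requirement is
`ceil(40/s)` windows, preserving the run duration. The intermediate label,
like the others, requires its gate (both fits significant) in *every*
window of the run, the stricter of the two possible readings. Windows need
at least 10 trials (F-test validity). The signal latency is the start time
of the first window of the run; note that a window starting at `t` covers
`[t, t + 150)`, so with strong signals detection legitimately begins up to
one window length before the underlying epoch onset, and the first
qualifying window's *end* (`latency + 150`) is the earliest time the
detector has seen epoch-overlapping evidence.

Transition probabilities among value/intermediate/choice signals are
computed over neurons exhibiting both kinds of a pair, ordered by
first-segment latency; latency ties contribute half to each direction and
are flagged. The transition time is the later signal's latency.

## Ridge analyses with max-statistic FWER

Predictors are standardized (zero mean, unit variance) before
penalization — the penalty is otherwise scale-inconsistent — and the
intercept is unpenalized, giving the closed form
`β = (XᵀX + λI)⁻¹ Xᵀ(F − F̄)` on the standardized design. The default
penalty is λ = 1 (deterministic); `gcv_lambda` offers generalized
cross-validation for users who want a data-driven penalty. Constant
predictor columns get coefficient 0 with a warning.

Per-coefficient significance permutes the response across trials and
refits: `p = (1 + #{|β_perm| ≥ |β_obs|}) / (1 + n_perm)`. The population
question — in which windows does the proportion of neurons with p < α
exceed chance — uses a max-statistic permutation procedure: each
permutation reshuffles every neuron's rates across trials (one trial
permutation applied to all windows, a dataset-level shuffle), the
proportion is recomputed per window on the shuffled data, and its maximum
across windows enters the null; a window is significant iff its observed
proportion strictly exceeds the empirical (1 − α) quantile (method
"higher") of that null. The same permutation ensemble supplies both the
observed p-values and the shuffled-data replicates: permutation k's
p-value is computed against the other permutations via rank counts. This
keeps the otherwise nested permutation cost linear while preserving
exchangeability; the observed and null p-value grids differ by one step
(1/(n_perm+1) vs 1/n_perm), a negligible asymmetry at n_perm ≥ 200 that
the family-wise calibration test bounds empirically.

Model-specific designs: the value+RT model is restricted to chosen trials
(RT exists only there); the history model drops each session's first
trial.

## Stimulation-effect statistics

Per site and value, `Δ = choice-rate(stim) − choice-rate(control)`;
per-site significance is a Pearson chi-square on the 2×2 table without
continuity correction (df = 1); a zero margin makes the test undefined and
it is reported absent. The |Δ| profile across values uses the site as the
unit: one-way F-test across the six value groups plus a Welch-t contrast
of value 4 against the pooled rest.

The distribution-width test operationalizes "width" as the σ of a
maximum-likelihood Gaussian fit to the site Δs after centering — i.e. the
population SD — avoiding histogram-binning arbitrariness. The chance-level
width shuffles stimulation/control labels within every site (preserving
per-site trial counts and value composition) and recomputes the Δs. The
label shuffle is realized by its exact distributional equivalent: the
number of chosen trials landing in the stimulated half is hypergeometric
given the site's margins, which vectorizes the null; the equivalence to
explicit label permutation is verified in a test. Significance follows the
exceedance convention (observed width larger than the null in more than
(1 − α/2)·n_shuffle repetitions); a two-tailed Monte Carlo p-value is also
reported.

Latency controls compute per-site mean release-latency differences
(stim − control), a population Wilcoxon signed-rank against zero, and the
Pearson correlation between latency and choice effects at value 4. The
early/late-half consistency of Δ per site is reported descriptively (sign
agreement), with no test.

## Synthetic-data generator

The generator defines the conditions under which every recovery and
calibration claim is made:

* Behavior: `V1, V2` i.i.d. uniform on {1..6}; choice Bernoulli with logit
  `β₀ + β₁·V1 + β_prev·V2ₜ₋₁` (no history term on trial 1). Defaults
  β₀ = −4.8, β₁ = 1.2 (indifference at value 4), β_prev = −0.3 (weak
  negative carry-over). Latency = 400 − 20·V1 ms plus Gaussian noise
  (SD 30 ms), truncated positive, present only on chosen trials; the
  −20 ms/value slope matches the chronometric effect size typical of this
  task, and 300 trials per session matches recording-session lengths.
* Neurons: inhomogeneous Poisson on [−400, 1000) ms with piecewise-constant
  rate `baseline + value_gain·(V1 − 3.5)·[value epoch] +
  choice_gain·C·[choice epoch]`, clipped at 0. Defaults: 10 Hz baseline,
  4 Hz/value-unit gain on [150, 500), 8 Hz choice gain on [500, 1000).
  Value coding is centered at 3.5 so the baseline equals the grand-mean
  rate, decoupling baseline and gain in recovery tests. The hard epoch
  switch gives an unambiguous ground-truth latency; real transitions are
  gradual, so passing recovery tests demonstrates correct detection of
  present signals, not the shape of real ramps. The neuron conditions on
  the realized choice from the behavioral model (not on private choice
  noise), matching the analyses' conditioning structure.
* Stimulation sites: a random half of trials receives an additive logit
  shift (default ±1.5). The site psychometric is steeper (logit 4·(V−4)):
  overtrained subjects choose near-deterministically away from the medium
  value, so a logit shift moves choice almost exclusively at the
  indifference value — the phenomenon the width and |Δ| tests target.
  900 trials per site matches stimulation-session lengths.

One configured seed governs all randomness; every stochastic stage derives
an independent substream keyed by (stage name, unit id), so per-unit
results are invariant to the composition of the population.

What the generator does not emulate: aborted/error trials, eye movements,
inter-trial-interval structure, non-Poisson spiking variability (real
spike counts are often over-dispersed), gradual value-to-choice morphing,
session-to-session drift, and any spatial organization of stimulation
sites. Calibration results (mislabel rates, FWER, width-test levels)
therefore certify the procedures under exchangeable, Poisson, stationary
conditions; on real data the same procedures remain valid permutation
tests but their power and the latency bias depend on effect shapes the
generator does not model.

## Numerical choices and problem sizes

* Simple-regression R² is computed from centered sums of squares; a
  constant response gives R² = 0 with p = 1, a constant predictor is a
  degenerate-design error. R² is clipped to [0, 1] against round-off.
* Monte Carlo tie-breaks are conservative throughout (ties do not count
  as exceedances; a proportion equal to the null quantile is not
  significant).
* The ridge closed form is verified against an independent gradient-based
  numerical minimizer to 1e-8 on random small designs.
* Desk-scale defaults used by the test suite and the acceptance script:
  10-ms classifier step with 200 shuffles (the 1-ms/1000-shuffle original
  is configuration-reachable), 200 ridge permutations, populations of
  30–200 simulated neurons, 20–56 sites, 50–100 replicate populations for
  calibration claims. These sizes give binomial standard errors small
  enough for the stated tolerances while keeping a full run in the
  minutes range on one CPU.

## Known limitations

* The latency of a detected signal is the start of its first qualifying
  window and is therefore biased early by up to one window length for
  sharp-onset signals; consumers needing onset times should add the
  window length (see the sliding-window section).
* Ridge coefficient significance via response permutation tests the
  global null for that neuron-window, not a per-coefficient conditional
  null; with strongly dependent predictors a significant value
  coefficient can partly reflect shared variance.
* The width test's Gaussian-σ width is one of several defensible width
  measures (FWHM, IQR); σ was chosen for its histogram-free ML estimator.
* The IRLS separation diagnostic is heuristic (estimate magnitude and SE
  finiteness); it reports, rather than certifies, separation.
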