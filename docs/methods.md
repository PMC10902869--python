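# Methods

`seqbias` simulates and analyses a two-environment, two-alternative
forced-choice (2AFC) orientation-discrimination study: observers report
whether a grating embedded in noise is tilted clockwise (+45°) or
counterclockwise (−45°) of vertical, first in a *neutral* environment where
the orientation sequence is serially counterbalanced (repetition
probability 0.5), then in a *repeating* environment where the orientation
repeats with probability 0.8. The package's purpose is to quantify how
choice history biases adapt to that sequential regularity and, via reverse
correlation on target-absent trials, to separate a stimulus-independent
decision bias from a stimulus-dependent sensitivity modulation (a
perceptual confirmation bias).

## Session design

A session is 12 blocks of 100 trials: six neutral blocks followed by six
repeating blocks (the order is fixed to keep the neutral blocks as a
carry-over-free baseline). Six Michelson contrasts (0, 0.02, 0.04, 0.06,
0.12, 0.18) are crossed with the two orientations.

* **Neutral environment.** The 12 conditions are sequenced as an Eulerian
  circuit on the complete directed multigraph over conditions (self-loops
  included), randomised by shuffling adjacency lists and the circulant
  shifts used for the remainder edges. Over the 599 transitions of a
  600-trial environment every ordered condition pair occurs 4 or 5 times
  (counts differ by at most one; exact balance is impossible because 599 is
  not divisible by 144). This yields repetition probability 0.5 and zero
  lag-1 autocorrelation by construction. Sessions shorter than
  `n_conditions² + 1` trials cannot be counterbalanced and fall back to a
  balanced random permutation.
* **Repeating environment.** Orientations follow a two-state Markov chain
  with repetition probability `p_rep = 0.8`; the whole sequence is
  resampled (seed incremented, up to `max_iter = 10 000` times) until the
  empirical repetition frequency is within ±0.02 of the target. Contrasts
  are a balanced permutation drawn independently of the chain. Block
  boundaries do not reset the chain; the chain restarts only at the
  environment switch.
* **0%-contrast trials.** The latent orientation of a 0%-contrast trial is
  defined (condition identity in the neutral environment, chain state in
  the repeating one) even though no grating is shown. The rewarded response
  is uniform random in the neutral environment — making above-chance
  accuracy there impossible — and equals the latent chain orientation in
  the repeating environment, so exploiting the regularity pays.

## Stimuli and orientation energy

Stimuli are sinusoidal gratings (1 cycle/°, random phase, Michelson
contrast as above) summed with Gaussian white noise that is smoothed with a
0.08° SD kernel, standardised, and scaled so that the smoothed-noise
luminance SD equals `0.5 × noise_contrast` (noise contrast 0.3) relative to
the mean-gray background; the composite is windowed by a raised-cosine
circular aperture (radius 5°, 0.5° edge) and clipped to [0, 1]. The
`noise_contrast` convention (SD relative to background) is a recorded
configuration choice. The default raster is 240 × 240 px (24 px/°, ≥ 4
samples per cycle at 1.4 c/°); batch pipelines default to 64 × 64
(6.4 px/°), which preserves all tested energy properties.

Orientation content is measured with a quadrature Gabor bank: orientations
−89°…90° in 1° steps × spatial frequencies 0.6–1.4 c/° in 0.1 c/° steps
(the target frequency ± 0.4 c/°). Each cell holds an even and an odd
filter — aperture-windowed sinusoids sharing the stimulus envelope (no
extra Gaussian taper, keeping bandwidth comparable across frequencies) —
made zero-mean and unit-norm. The energy of an image in a cell is the
quadrature magnitude `sqrt(c² + s²)` of the mean-subtracted raster's
projections on the filter pair: phase-invariant, offset-invariant, and
monotone in grating contrast. Because each filter is a windowed sinusoid,
the pair of projections equals one complex-exponential inner product, which
is evaluated separably per axis; this exact identity (verified against
explicitly constructed filters in the tests) avoids materialising the
1620-filter bank at full resolution.

## Generative observer

The observer responds clockwise with probability

    P(cw) = γ_cw + (1 − γ_cw − γ_ccw) · σ(η),
    η = β₀ + β_c·(signed contrast)
        + Σ_{k=1..7} w_stim[k]·s_{t−k} + Σ_{k=1..7} w_choice[k]·r_{t−k}
        + energy term (0%-contrast trials only),

with stimuli and responses coded ±1, lapse rates as asymptotes (the
standard psychometric convention; the fitting side treats them the same
way), and history lags zero-padded at the start of each environment. On
0%-contrast trials an optional prediction-dependent gain acts on the
z-scored class-mean orientation energies of the noise: writing `E⁺`/`E⁻`
for the energy of the predicted/unpredicted orientation class (the
prediction being the previous trial's latent orientation),

    η += prev · energy_beta · (gain_consistent·E⁺ − gain_inconsistent·E⁻).

With equal gains this reduces exactly to the prediction-free sensitivity
`energy_beta·(z_cw − z_ccw)`; a gain asymmetry amplifies evidence
consistent with the prediction, i.e. a perceptual confirmation bias. This
additive-in-log-odds combination with channel gains is the package's own
modelling choice (used for synthetic data and recovery testing only); no
claim is made that real observers combine the terms this way.

Cohort defaults (all configurable): slope 20 log-odds per unit contrast
(≈ 95% asymptotic accuracy at contrast 0.18, matching a well-performing
participant), lapse rates 0.025 each, lag-1 kernels of 0.1 in the neutral
environment rising to stim/choice kernels (0.4, 0.2, 0.1)/(0.2, 0.1) in the
repeating environment (adapted observer, magnitudes in the range seen for
individual participants), `energy_beta = 1`, and repeating-environment
gains 1.25/0.75. Per-participant idiosyncrasy is injected as Gaussian
jitter on the intercept (SD 0.2) and lag-1 kernels (SD 0.15).

## History regression

Per participant and environment, responses are fit with a lasso-regularised
logistic model containing the signed-contrast slope, an intercept, lapse
rates, and 7 lags of previous-stimulus and previous-choice regressors. The
objective is the mean negative log-likelihood plus `λ·Σ|w_history|` with
`λ = 0.001`; the penalty applies to the 14 history columns only (the
high-dimensional block), leaving slope, intercept and lapses unpenalised.
λ is applied per observation on ±1-coded history columns and the raw
signed-contrast column (internally rescaled to unit SD for conditioning
only); this convention is recorded in the fit metadata.

Numerical choices:

* Inner solver: FISTA with soft-thresholding, per-candidate backtracking,
  adaptive restart; deterministic zero initialisation, objective tolerance
  1e-8, at most 10⁴ iterations.
* Lapse rates: bounded grid 0–0.2 in steps of 0.01, searched coarse-to-fine
  (0.04-step pass, then 0.01-step refinement around the optimum), all
  candidates solved as one batched problem. Selection is by penalised
  likelihood **with a parsimony tie-break**: among pairs within 2
  log-likelihood units of the optimum (an AIC-equivalent margin for the two
  lapse parameters) the smallest total lapse wins. The likelihood surface
  is a flat ridge trading lapses against slope; without the tie-break,
  boundary noise at 600 trials/environment systematically overestimates
  lapses, inflates the contrast slope, and — because current and previous
  stimuli are correlated in the repeating environment — leaks a ≈ −0.05
  bias into the lag-1 previous-correct weight. The package's own recovery
  simulation (below) was used to calibrate this choice; with it the
  null-observer recovery bias is ≈ −0.03 and the generating-case bias
  ≈ −0.02.
* Missed responses are dropped row-wise but occupy history-lag positions
  with a 0-coded choice regressor (config-switchable).
* Separation/non-convergence is flagged (`converged=False`, weights in the
  standardised space exceeding 30); flagged fits are not summarised.

Derived quantities, all under ±1 coding: previous-correct weight
`w_stim[k] + w_choice[k]` (equal to the weight of an explicit
previous-correct-choice regressor — asserted by a reparameterised refit in
the tests), previous-incorrect weight `w_choice[k] − w_stim[k]`, and
adaptation = repeating minus neutral previous-correct weight. Accuracy
tables use "low contrast" = contrast < 0.06, i.e. {0, 0.02, 0.04}.
Participant exclusion mirrors the study rules: ≥ 65% overall accuracy,
≤ 5% missed responses (60 of 1200), ≥ 65% accuracy in each environment.

`recovery_simulation` reproduces the regularisation check: responses are
simulated from known parameters on the (autocorrelated) repeating
sequences, the lasso regression is refit on each of 100 simulated sets, and
the distribution and bias of the recovered weights are reported.

## Reverse correlation

Restricted to 0%-contrast trials (asserted at input). Per participant,
energies are z-scored per (orientation, SF, previous stimulus, environment)
cell with the sample SD (ddof = 1); zero-variance cells are dropped and
logged. Each cell × condition is fit with a 2-parameter logistic
`P(cw) = σ(β₀ + β₁·z)` by Newton–Raphson (vectorised across the 1620
cells, identical to per-cell maximum likelihood); separation is flagged,
estimates truncated at |β| = 10 and excluded from summaries. Pooled β₀ and
β₁ estimates are then filtered with Tukey fences (1.5 × IQR,
linear-interpolation quartiles — the convention is recorded in the output)
per (previous stimulus, environment) pool; pools smaller than 4 are left
unfiltered with a warning. Summaries per participant and condition: β₀
averaged over all cells (it is stimulus-independent); β₁ averaged within
the clockwise (1°–89°) and counterclockwise (−89°–−1°) orientation classes
over all SFs, the 0° and 90° cells belonging to neither class. The history
effect on sensitivity per environment is the sensitivity to clockwise
energy after a clockwise previous stimulus minus that after a
counterclockwise one. Flipping all orientation, response and
previous-stimulus labels negates the bias summaries and swaps the
sensitivity classes exactly (a tested symmetry).

The spatial-frequency range follows the 0.6–1.4 c/° grid of the summary
averaging; a wider 0.6–2.5 c/° range appears in one description of the
filter pool but contradicts the "target frequency ± 0.4 c/°" definition
used everywhere else, so the narrower range is implemented and the
discrepancy flagged here rather than resolved.

## Group statistics

Paired t-tests (bias split by previous stimulus), 2×2 and 2×2×2
repeated-measures ANOVAs (bias and sensitivity by previous stimulus ×
environment (× energy class)), Welch two-sample tests, Spearman/Pearson
correlations, and ordinary least-squares trajectory fits
(intercept = starting level at the environment's first step, slope =
per-step change) for learning-rate summaries. All ANOVA factors are
two-level, so every effect is a 1-df within-subject contrast and F = t²
exactly; sphericity is trivially satisfied and no correction is applied.
Numerically null contrasts (scores below 1e-10 of the data scale) report
F = 0 rather than a 0/0 ratio. Bayes factors are out of scope. Trajectory
inputs come from per-block refits of the history model (trial-resolved
state-space estimation is outside this package); outputs are labelled
accordingly.

## Synthetic-data scope

The generator emulates the study's design statistics (trial counts,
transition structure, contrast marginals, reward rules), a psychometric
observer with lapses and history kernels, and noise stimuli whose energy
profiles drive choices on target-absent trials. It does **not** emulate
reaction times, missed responses, learning dynamics within an environment
(kernels switch discretely at the environment boundary), nonstationary
attention, or gamma/monitor characteristics. Passing tests therefore
demonstrate that the analysis code recovers known generative structure at
the study's scale — not that real observers satisfy the generative
assumptions.

## Problem sizes used in tests and the acceptance script

Sequence statistics are checked at the design scale (600 trials per
environment); chance-level accuracy at 10⁵ trials; history recovery with
100 simulated response sets per observer on a 600-trial repeating
sequence; the reverse-correlation sign-recovery check runs 100 seeds of an
all-0%-contrast session (600 target-absent trials per environment, i.e.
≈ 300 per previous-stimulus condition — the scale at which the per-seed
effect estimate is clearly separated from its own sampling noise), and the
decision-bias dissociation 20 seeds of the standard mixed-contrast
session. Batch rasters are 64 × 64.

## Known limitations

* The counterbalancing scheme balances first-order transitions only, as
  specified; higher-order balance is not attempted.
* Lapse estimation at 600 trials/environment is intrinsically noisy; the
  parsimony tie-break trades a small lapse underestimation for unbiased
  history weights.
* The per-bin logistic fits ignore correlations between neighbouring
  energy cells; summaries average over strongly correlated estimates, so
  their across-cell dispersion understates the true uncertainty (group
  inference uses across-participant variability instead).
* `energy_beta` and the gain asymmetry of the synthetic observer are
  modelling constants of the generator, not estimates of any real
  observer.
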