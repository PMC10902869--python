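# seqbias

Simulation and analysis of **choice-history-bias adaptation** in
two-alternative forced-choice (2AFC) orientation discrimination.

Observers judging whether a noisy grating is tilted clockwise or
counterclockwise of vertical do not rely on the current stimulus alone:
their decisions are pulled toward recent stimuli and choices, and these
history biases adapt when the environment contains sequential structure
(e.g. stimuli that tend to repeat). `seqbias` provides, for researchers in
visual psychophysics and perceptual decision-making, a tested pipeline to

- **generate session designs**: a serially counterbalanced *neutral*
  environment (orientation repetition probability 0.5, every ordered
  condition pair equally frequent up to ±1) followed by a *repeating*
  environment whose orientations follow a Markov chain with repetition
  probability 0.8 ± 0.02, with six Michelson contrasts (including 0%) and
  the study's reward rules for target-absent trials;
- **render stimuli and measure orientation energy**: gratings in smoothed
  white noise inside a raised-cosine aperture, decomposed by a quadrature
  Gabor bank (orientations −89°…90° in 1° steps × spatial frequencies
  0.6–1.4 c/°), energy `E(θ, f) = sqrt(c² + s²)`;
- **simulate observers**: a generative psychometric model
  `P(cw) = γ_cw + (1 − γ_cw − γ_ccw)·σ(β₀ + β_c·x_t + Σ_k w_stim[k]·s_{t−k}
  + Σ_k w_choice[k]·r_{t−k} + energy term)` with lapse asymptotes, 7-lag
  history kernels, and an optional prediction-dependent gain on noise
  orientation-energy channels (a perceptual confirmation bias);
- **fit the history model**: lasso-regularised logistic regression
  (λ = 0.001 on the 14 history weights), lapse rates by bounded grid
  search, and derived summaries — previous-correct weight
  `w_stim[k] + w_choice[k]`, previous-incorrect weight
  `w_choice[k] − w_stim[k]`, adaptation = repeating − neutral —
  plus conditioned psychometric curves, accuracy tables, exclusion rules,
  and the 100-simulation parameter-recovery check;
- **reverse-correlate** choices on 0%-contrast trials: per-cell logistic
  fits `P(cw) = σ(β₀ + β₁·Z[E(S)])` conditioned on previous stimulus ×
  environment, Tukey 1.5×IQR outlier filtering, and summaries separating
  stimulus-independent bias (β₀) from stimulus-dependent sensitivity (β₁)
  and its history modulation;
- **run group statistics**: paired/Welch t-tests, 2×2(×2) within-subject
  ANOVAs (all factors two-level, F = t²), rank/product-moment correlations,
  and linear trajectory fits for learning-rate summaries.

See `docs/methods.md` for the model details, conventions and limitations.

## Worked example

```python
from seqbias import (build_session, lag1_params, simulate_session,
                     build_design_matrix, fit_lasso_logistic,
                     derive_history_summaries)

design = build_session(seed=3)          # 6 neutral + 6 repeating blocks
print("repeating repetition frequency:",
      round(design.repeating.repetition_frequency(), 3))

observer = {                            # adapted observer: larger kernels
    "neutral":   lag1_params(0.1, 0.1, slope=20.0),   # in the repeating
    "repeating": lag1_params(0.4, 0.2, slope=20.0),   # environment
}
data = simulate_session(observer, design, seed=3, participant_id="obs01")
print("overall accuracy:", round(data["is_correct"].mean(), 3))

fits = {env: fit_lasso_logistic(build_design_matrix(data, env))
        for env in ("neutral", "repeating")}
summary = derive_history_summaries(fits["neutral"], fits["repeating"])
print(summary.loc[summary.lag <= 3].round(3).to_string(index=False))
```

prints

```
repeating repetition frequency: 0.803
overall accuracy: 0.749
 lag  prev_correct_neutral  prev_incorrect_neutral  prev_correct_repeating  prev_incorrect_repeating  adaptation
   1                 0.217                  -0.036                   0.568                    -0.346       0.351
   2                -0.066                   0.277                   0.157                     0.157       0.223
   3                -0.085                  -0.311                  -0.142                     0.153      -0.057
```

The generated repeating sequence repeats orientations 80.3% of the time.
The fitted lag-1 previous-correct weight rises from 0.22 (neutral) to 0.57
(repeating) — an adaptation of 0.35 log-odds, close to the generating
kernels (0.2 → 0.6): the observer learns to repeat rewarded choices when
the environment makes repetition likely. Single-session estimates carry a
standard error of roughly 0.15, visible in the noisier higher lags.

A full synthetic cohort (design → stimuli → behavior → exclusions → fits →
reverse correlation → group statistics, with a hashed manifest) runs via

```sh
seqbias run-all --seed 1 --out-dir out/
```

and the individual stages are exposed as `seqbias simulate design`,
`seqbias simulate observer`, `seqbias energy`, `seqbias fit-history`,
`seqbias revcorr`, `seqbias stats`, and `seqbias fixtures`.

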