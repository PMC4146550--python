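# Methods

## Signal path

Continuous EEG (microvolts, channels × samples, 0-based sample indexing)
enters as a `Recording`; epochs are cut on half-open windows `[t0, t1)` in
milliseconds relative to a cue marker, with the onset sample included at
`t0 = 0`. Markers whose window would leave the recording are excluded and
reported, never zero-padded — padding would bias the covariance estimates
everything downstream depends on.

Acquisition-rate data are low-pass filtered at 45 Hz (zero-phase order-5
Butterworth, applied before decimation as the anti-alias step) and brought
to 100 Hz; marker indices rescale with rounding down, which at 100 Hz is
negligible against multi-second trials. All subsequent band-pass filters
are order-5 Butterworth in second-order sections — direct-form transfer
functions are numerically unreliable with a 0.2 Hz edge at 100 Hz. The
online path is strictly causal (`sosfilt`, verified by a prefix-equality
property test); offline analyses may use zero-phase forward-backward
filtering. Continuous filtering of the stream is the default; per-epoch
filtering is possible but inherits edge transients.

## Feature extraction

**CSP.** Per-trial spatial covariance is trace-normalized before class
averaging, so trials with large amplitude (artifacts, drifting gain) do not
dominate; `1e-8 · tr(C) · I` is added per class covariance, which makes the
generalized eigendecomposition safe in the realistic rank-deficient regime
of 16 channels and few trials. Eigenvalues are clipped to [0, 1] and
sorted descending; exact ties break by the dominant-channel index of the
eigenvector so the decomposition is deterministic. Patterns are the
pseudoinverse of the filter matrix (columns = scalp patterns); since the
overall sign of a filter/pattern pair is arbitrary, it is normalized so the
largest-magnitude pattern coefficient is positive. Six components (three
per end of the spectrum) are kept by default; the count is configurable and
should stay well below the trial count per class.

**Slow potentials.** Mean amplitude per channel over a discriminative
interval of the 0.2–4 Hz signal, after subtracting the per-channel mean of
the 300 ms pre-cue baseline. The default intervals (oscillatory
500–4500 ms, slow 2000–5000 ms within a 5 s trial) suit the synthetic
generator's ramp-to-trial-end readiness potential; on real data they are
per-user choices, and `ssauc_map` (signed scaled AUC, `2·(AUC − 0.5)`,
positive where class-2 values are larger) is the screening tool for picking
them. An automatic max-ssAUC interval search is deliberately not wired into
the default path: interval choice on real patient data was a judgment call,
and the config keeps it explicit.

## Classification and adaptation

Shrinkage LDA uses the analytic Ledoit–Wolf coefficient computed on
class-centered pooled residuals, shrinking toward ν I with ν = tr(Σ)/d.
The per-trial supervised update is

    μ_y ← (1 − η) μ_y + η x
    Σ   ← (1 − η) Σ + η (x − μ̄)(x − μ̄)ᵀ,   μ̄ = (μ₁ + μ₂)/2 after the update

with η = 0.03 by default; w and b are recomputed from the updated moments,
so bias correction is implicit. γ stays frozen after initial training:
re-estimating shrinkage from a one-sample update is not meaningful, and
freezing keeps the update O(d²). Adaptation is a CopyTask-only operation —
the FreeMode runner asserts that no update ever happens there.

The meta-combination divides each branch score by the standard deviation of
its training-set scores before the weighted sum; without this the weights
would silently encode the arbitrary scale difference between log-variance
and microvolt features. Default weights are proportional to
`max(0, CV accuracy − 0.5)` per branch (equal weights if neither branch
beats chance); `active_output` can pin a single branch instead. The
decision gate maps the accumulated trial output to the negative action
below −θ, the positive action above +θ, and *noDecision* on the closed
interval `[−θ, θ]` (boundary inclusive, so θ = 0 still gates an exactly-zero
output). θ can be calibrated on CopyTask outcomes as the smallest value
reaching a target precision (default 0.8) on decided trials.

## Online engine

The classifier is evaluated on a sliding 1 s window every 100 ms inside the
trial (the feedback rate is a free choice; continuous feedback needs some
rate, and 10 Hz updates on a 1 s window are conventional for band-power
feedback). The trial-level output is the *mean* of frame scores; sum and
decaying-integral accumulation are plausible alternatives but change only a
monotone scaling at fixed trial length. CopyTask correctness is the sign of
the accumulated output — the threshold applies only to FreeMode actions.
Illegal FreeMode actions (placing into a full column) are dropped and
logged rather than remapped, keeping control errors visible. Default trial
length is 5 s; inter-trial pause defaults to 3 s in the generator, and all
reported ITRs divide by the full session span so pauses and noDecision
trials cost bitrate.

## Evaluation

The chance-level test is the exact one-sided binomial tail
P(X ≥ k | n, 0.5); a Pearson χ² (1 df) against the 50/50 split is computed
alongside as a cross-check, since at block sizes of 20–100 trials the exact
test is strictly preferable. Cross-validation is stratified 5-fold with
*all* supervised steps (CSP and LDA) refitted inside each training fold;
the shuffled-label suite verifies the absence of leakage. ITR accuracy is
computed over decided trials while time includes everything — the choice is
documented rather than hidden because the alternative (all-trial accuracy)
is also computed trivially from the session log. Spectral screening uses
Welch periodograms (256-sample windows by default) and integrates 8–12 Hz
for the alpha topography.

## Synthetic generator

The generator emulates exactly the signal classes the pipeline targets, on
a 16-channel motor grid with Gaussian-bump mixing columns centered on C3
and C4 (no forward head model — unnecessary for testing filters, CSP and
LDA):

- pink (1/f-amplitude) background noise, 5 µV per channel by default;
- two band-limited sources (default 8–12 Hz) whose in-band variance drops
  by `erd_depth` (default 0.5) during trials of the matching class and
  rebounds by `rebound_gain` (default 1.5) for 1 s starting 500 ms after
  trial end;
- a 0-to-−5 µV linear ramp over the contralateral motor channel from cue
  onset to trial end (low-frequency by construction);
- optional per-trial rotation of the mixing columns in their common plane
  (`drift_rate` degrees/trial), emulating session nonstationarity;
- `snr` is the in-band source-to-background variance ratio at the peak
  channel (default 1).

Defaults: 50 trials per class, 5 s trials, 3 s pauses, 100 Hz. The
scripted-user variant expresses each intended class with probability
`controllability` and the opposite class otherwise, so controllability 0.5
conveys no information and 1.0 is a perfectly reliable user. The generator
does **not** model ocular/muscular artifacts, volume conduction, or
atypical patient spectra beyond a `no_idle_rhythm` switch in the screening
generator; passing tests therefore demonstrate correctness of the
processing chain on its declared signal model, not performance on real
patient EEG.

Null-calibration checks use 30-trial sessions because the exact binomial
0.05 cutoff at n = 30 rejects at 4.94% — the closest attainable nominal
rate to 5% among desk-scale session lengths (binomial discreteness makes,
e.g., n = 20 reject at only 2.07%).

## Connect-4 baseline

The game is the standard 6 × 7 board; the two-action interface advances a
wrapping cursor or drops a coin. The computer opponent plays an immediate
winning column if one exists, else blocks an opponent's immediate win
(lowest-index threat if there are several — a double threat cannot be
parried, which is the only way a random player beats it), else a uniformly
random legal column. The baseline simulation plays 10,000 games between
this heuristic and a uniformly random player, alternating who moves first.

This opponent is a *reconstruction*: immediate-win/block policies are the
canonical minimal heuristic, but measured outcomes are sensitive to the
exact policy. Under this reconstruction the random player wins ≈ 4% and
draws are rare (< 1%); exploratory variants (a block-only opponent raises
random-player wins to ≈ 10%, a two-action random player changes little)
show that no immediate-threat policy yields a large draw fraction on a 6 × 7
board. Reported percentages are therefore what the implemented policy
actually produces, not a calibration target.

## Problem sizes

Test and acceptance runs use desk-scale sizes chosen once: 10,000 simulated
games, 40–100 trials per synthetic session, 20 seeds for seed-averaged
properties, 100 sessions for null calibration. These sizes put Monte-Carlo
error comfortably below the asserted margins (e.g. ±0.5% on a 10⁴-game
percentage) while keeping the whole suite fast.

## Known limitations

- The synthetic signal model is linear and stationary within its declared
  envelopes; real EEG nonstationarity is richer than a rotating mixing
  column.
- The slow-potential branch's default interval assumes a ramp-shaped
  readiness potential; biphasic potentials would need a different interval.
- Branch weights are fixed after calibration; the original workflow allowed
  manual recalibration between blocks, which the config supports
  (refit + session-to-session JSON transfer) but no automation is provided.
- The game heuristic is a reconstruction (see above); engine-level results
  should be read with that caveat.
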