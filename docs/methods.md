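# Methods

This note records the modelling assumptions, parameter choices, and design
decisions behind the package, and what the synthetic-data tests do and do
not establish about real recordings.

## The two-phase state model

The affective state is a scalar first-order system with two regimes.
During stimulus input the state rises toward the saturation value S with
time constant τ_BROADCAST; without input it decays with τ_PERSIST. The
rectified drive (S − x₀)⁺ enforces saturation: a puff arriving while the
state already exceeds S cannot push it higher. Both regimes have exact
closed-form solutions, so simulation is evaluated analytically per phase —
there is no integration error, and phase continuity holds to machine
precision. The canonical input schedule is eight 250 ms steps at 3 s
spacing followed by a 50 s free decay.

Fitting uses bounded trust-region least squares (`scipy.optimize.least_squares`)
with per-parameter bounds [0, 100] over the concatenation of all condition
traces. Masked samples (NaN) are excluded from the residual; behavioral
fits mask 750 ms after each puff onset to remove the reflexive blink. The
cost surface is nonconvex in the time constants, so the fit multi-starts
from a log-spaced grid of τ values (default 10 starts) and keeps the best
residual; after convergence, any parameter that can be moved to a bound
without worsening the residual is snapped there and flagged, so degenerate
directions (e.g. S → 0 on a flat trace) are reported at the bound rather
than at an arbitrary equivalent point. Optimizer tolerances are xtol =
ftol = 1e-12; these choices are implementation-defined.

Model comparison quantifies the variance explained by the condition-varying
parameter: 1 − MSE_model / MSE_null, where the null model shares every
parameter across conditions. The statistic may be negative when the free
parameter does not help.

## Synthetic sessions

The generator produces the structures the analyses assume, with every
planted quantity stored in a ground-truth record. All randomness derives
from one integer seed split into named substreams
(`SeedSequence([seed, crc32(name)])`), so outputs are bit-identical for
identical configuration and seed, and adding a new consumer never perturbs
existing streams.

**Events.** Series of 8 × 250 ms puffs at 3 s intervals; 45–90 s uniform
gaps between series; condition labels pre → drug (→ post). The default
first series begins at t = 150 s, leaving a 2-minute pre-assay baseline
epoch for spectral normalization.

**Units.** Each unit carries an archetype kernel: zero until a latency,
saturating rise (1 − e^(−t/τ_rise)) for the drive duration, then *exact*
exponential decay. The piecewise form (rather than a difference of
exponentials) was chosen so that rise and decay times are closed-form
checkable — the trace after the peak is a pure exponential, and persistent
archetypes inherit the condition's τ_PERSIST as their decay constant.
Defaults:

| archetype          | latency | τ_rise | drive | decay        | share |
|--------------------|---------|--------|-------|--------------|-------|
| fast_transient     | 20 ms   | 30 ms  | 250 ms| 40 ms        | 40%   |
| fast_persistent    | 20 ms   | 50 ms  | 250 ms| τ_PERSIST    | 5%    |
| delayed_persistent | 250 ms  | 250 ms | 750 ms| τ_PERSIST    | 5%    |
| suppressed (dip)   | 50 ms   | 80 ms  | 200 ms| 100 ms       | 10%   |
| unmodulated        | —       | —      | —     | —            | 40%   |

Rates are baseline + kernels convolved with the event train + i.i.d.
Gaussian noise, rectified at zero. Persistent units (10% of the
population, so they exactly fill the top decile used in recovery checks)
additionally receive slow baseline fluctuations: an Ornstein–Uhlenbeck
latent with condition-specific timescale (defaults pre 0.5 s, drug 0.1 s,
post 0.4 s), mixed between one latent shared across the persistent
subnetwork (weight = the condition's coupling gain; defaults 0.8 / 0.3 /
0.7) and private latents. This plants both the baseline intrinsic
timescale and the within-subnetwork coupling as condition-dependent,
recoverable quantities. Default τ_PERSIST is 10 s (pre), 1 s (drug), 8 s
(post); effect sizes (kernel amplitudes ~8–12 Hz over ~4–8 Hz baselines,
closure saturation S = 0.6) are generator choices pitched at realistic
single-unit and eyelid scales, not measured values.

**LFP.** Each channel is 1/f^χ background (χ = 2 by default) made by
spectral shaping of white noise, plus planted narrowband oscillations
gated to condition epochs with smooth 1 s ramps, plus evoked
spectrotemporal factors after each puff — positive factors add band-limited
bursts scaled by per-channel loadings; negative factors multiplicatively
attenuate the background's own band component, so power genuinely
decreases — plus shared lagged narrowband components for phase-coupled
channel pairs. The default coupled pair's amplitude is set near the
background's beta-band standard deviation so that the planted coupling
drop moves PLV off its ceiling.

**Eye traces.** closure(t) = the model's affective component driven by the
trial's actual puff times + a raised-cosine reflexive blink kernel after
each puff + Gaussian noise, clipped to [0, 1]. State is reset at each
series; with ≥ 45 s gaps the carried-over state is below 1.5% of S even at
τ_PERSIST = 10 s.

**What the generator does not emulate.** Poisson spike statistics,
bursting, slow drifts and electrode artifacts, behavioral state changes
(arousal, sleep), pharmacokinetic ramps (conditions switch sharply),
habituation across trials, and heterogeneous per-unit persistence within a
condition. Passing recovery tests therefore shows the analyses are
correct and well-calibrated under their stated assumptions — not that real
recordings satisfy those assumptions.

## Analysis conventions

* All windows are half-open [start, stop) in seconds relative to an
  alignment event; this avoids double-counting boundary samples.
* Multitaper spectrograms use ⌊2·TBW⌋ − 1 DPSS tapers (3 at TBW 2; 59 at
  TBW 30), mean detrending per window only, frequency axis truncated to
  1–100 Hz by default; frequency-bin resolution follows the window length.
* Double z-scoring: per frequency against a 2-minute session baseline,
  then per frequency against each event's 1.5 s pre-onset segment.
  Zero-variance frequencies are flagged and excluded, not imputed.
* Band envelopes: zero-phase (forward–backward) fifth-order Butterworth,
  squared magnitude of the analytic signal; canonical bands delta 1–4,
  theta 4–8, alpha 8–12, beta 12–30, low-gamma 30–50, high-gamma 65–95 Hz.
* Sign-split NMF: the signed z-scored response matrix is split into
  positive and |negative| parts, each factored with Frobenius loss and
  deterministic NNDSVD initialization (the seed only breaks solver ties).
  Held-out loadings are refit by non-negative least squares against fixed
  templates — an interpretation choice, since projecting without the
  non-negativity constraint would be equally defensible. The factor count
  is the grid point with the maximum discrete second difference of held-out
  explained variance (EV(0) = 0; ties to smaller k; the last grid point is
  never an elbow) — a deterministic surrogate for reading an elbow off the
  curve. Loading contrasts (infusion − mean of pre/post) exclude channels
  below a 0.1 mean reference loading per factor and are tested by a
  hierarchical bootstrap over participants then channels when a grouping is
  supplied (percentile p, floored at 1/n_boot), else a paired t-test.
* Cluster permutation: one-sample t per (time, frequency) cell on paired
  difference maps, two-sided forming threshold at α = 0.01, 4-neighbour
  connectivity within sign (signs never merge), cluster mass = Σt, null =
  maximum |mass| over random whole-event sign flips,
  p = (1 + #{null ≥ observed}) / (1 + n_perm), n_perm ≥ 100 enforced.
  An unpaired variant (label-shuffle two-sample t) is available. Regional
  minimum p-values are BH-corrected; flagged regions report all clusters
  with raw p < 0.01.
* Coding dimensions: w = (mean_target − mean_reference) / √(var_target +
  var_reference) across events, zero for zero-pooled-variance sites,
  normalized to unit L2 norm (units) or unit Σ|w| (channels). The d′ trace
  uses the *average* of variances, √((v₁+v₂)/2), while the weight formula
  uses the *sum* — both conventions are kept deliberately as given, and the
  rise/decay d′ uses the summed-variance form for consistency with the
  weights. In pipelines the persistent dimension is trained on
  first-puff events: in these synthetic sessions later puffs carry the
  accumulated state, which would otherwise dominate the event-to-event
  variance term and shrink persistent units' weights.
* Emotion-like dimension: 1 s window starting 5 s after each pre-condition
  series vs a 750 ms window ending 250 ms before it, restricted to
  puff-modulated units, orthogonalized (Gram–Schmidt / thin QR) against the
  fast per-puff dimension built from the last four series (200 ms post vs
  200 ms pre each puff), then unit-normalized.
* Unit screening: paired t-tests over five canonical window pairs, flagged
  at any uncorrected p < 0.01. Response clustering: per-unit z-score →
  PCA (≤ 20 components) → Ward agglomerative clustering with silhouette
  model selection — a deterministic stand-in for neighbor-graph embedding
  pipelines, whose exact output is seed- and implementation-sensitive while
  downstream analyses only need archetype separation. Clusters are ordered
  by decay-to-25%-of-peak time.
* Rise/decay: d′ traces from the first two puffs per series; rise = first
  time at 25% of peak, decay = first post-peak return to 25%; clusters with
  peak d′ < 1.3 or peak latency > 750 ms are excluded; regional values are
  cluster-fraction-weighted; CIs bootstrap puff replicates (1000 draws).
* Intrinsic timescale: biased (divide-by-N) autocorrelation of the
  mean-subtracted series — smoother than the unbiased estimator for
  fitting — then a·e^(−lag/b)+c fit from the peak to 2.5 s beyond it,
  initialized at (1, 0.2, 0). Non-convergent fits and b < 2·dt (white-noise
  regime) are flagged for exclusion.
* PLV: zero-phase band-pass (phase-preserving), analytic phase difference,
  |circular mean| in sliding 5 s windows. Subnetwork coupling restricts
  edges to sites above the 90th percentile of |persistent weight| (the
  top/bottom-decile per-participant variant is exposed) and either z-scores
  drug windows against preinfusion per edge or normalizes mean coupling to
  preinfusion.
* Oscillations: multitaper PSDs (TBW 30, 59 tapers, 30 s windows, 15 s
  stride) averaged within 3-minute segments; the aperiodic component is an
  iteratively masked straight line in log10–log10 space (mask > 2.5
  residual SDs above the fit, refit, three iterations — no knee term, which
  suffices for the power-law backgrounds generated here). Peaks above a
  0.15 log10-unit prominence floor (calibrated against the false-positive
  budget on pure-1/f channels) are clustered greedily, tallest first, when
  center ± half-bandwidth intervals overlap ≥ 80% of the smaller interval;
  clusters in < 40% of segments are dropped; peak centers are refined to
  the residual-power centroid over the half-prominence span, which removes
  the upward bias the steep background slope imposes on the raw argmax.
  Drug clusters with no baseline cluster within 2 Hz are new-frequency;
  overlapping ones are amplified only at one-sided rank-sum p < 0.001.

## Problem sizes

The test suite and `scripts/acceptance.py` size their simulations for a
single CPU: sessions of 4–16 trials with 30–50 units, 100-run Monte-Carlo
batches for calibration properties in the suite, and 20–30-run batches in
the acceptance script (which reports the run counts it used alongside each
value). These are the package's own choices of demonstration scale; all
statistical tolerances are stated per batch size in the tests themselves.

## Known limitations

* The NMF elbow heuristic assumes factors of comparable strength; a single
  dominant component can pull the maximum-curvature point to small k (it
  does so legitimately on sessions with one strong evoked pattern).
* The aperiodic fit has no knee/Lorentzian term, so backgrounds with a
  genuine knee would bias flattened spectra at low frequencies.
* The sign-flip cluster null is exact only under symmetric per-event null
  distributions; strongly skewed noise would miscalibrate it.
* The behavioral and neural fits share one optimizer; heavily masked traces
  (blink mask ≥ inter-puff interval) leave the broadcast phase constrained
  mostly by the unmasked tail and widen τ_BROADCAST uncertainty.
* Mixed-effects loading statistics are replaced by the hierarchical
  bootstrap; with very few participants (< 4) its percentile p-values are
  coarse.
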