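# Methods

This package analyses two-alternative saccadic orienting to paired fearful
and neutral faces under transient unilateral amygdala disruption, and ships
a synthetic-experiment generator with known ground truth so that every
analysis stage can be validated by recovery. This note records the models,
the estimation machinery, the generator's assumptions, and the numerical
choices, in enough detail to reproduce or challenge any of them.

## Task structure and trial table

A trial presents a fearful and a neutral face at ±5.3° eccentricity for
1000 ms after a 1750 ± 250 ms jittered fixation. Factors: Instruction
(Yield: look at the face that captures attention; Oppose: look away from
it), Disruption (None, Ipsilateral or Contralateral to the fearful face),
and the fearful face's Hemifield (L/R, randomised per trial, modelled only
as a confound). The behavioural readouts are the binary choice (fearful vs
neutral target) and the saccade latency in ms. Trials enter analysis only
with QC flag `valid`: fixation stable in the 100 ms before stimulus onset,
latency in [100, 1000] ms.

## Saccade detection and QC

Velocity is obtained by Savitzky–Golay differentiation (window 11 samples,
order 2) of the 1 kHz horizontal gaze trace. Candidate movements are
contiguous samples with |velocity| ≥ 5°/s, trimmed to the sign-consistent
segment around the velocity peak (velocity noise adjacent to a movement has
random sign; without trimming, noise merged onto the movement biases the
onset early). A candidate becomes a saccade only if it jointly satisfies:
amplitude ≥ 0.5°, duration ≥ 20 ms, and a preceding-fixation criterion —
no sample in the 50 ms before onset displaced more than 0.5° from the
window median (the median reference avoids penalising the candidate for
the onset sample's own noise). Onset is the last sample below the velocity
threshold; direction is the sign of net displacement; the first saccade
after stimulus onset scores the trial. The 5°/s threshold is unusually low
for saccades and is exposed as a parameter. The fixation-adequacy trial
check (pre-stimulus window SD ≤ 0.5°, no sample beyond 1°) is an automatic
surrogate for a manual screening step and is likewise configurable.

At the generator's default noise (0.1° SD), detection recovers ≥ 99% of
onsets within ±10 ms and produces no false saccades on fixation-only
traces; both properties are regression-tested.

## The three behavioural models

All three are hierarchical Bayesian models over the QC'd trial table with
sum-to-zero (deviation) factor coding, so "marginalising" the Hemifield
confound is equal-weight averaging over its levels and main effects remain
interpretable under imbalance. Participants contribute random intercepts
(centred parameterisation) with half-Normal(1) priors on the group SDs.

**Shifted lognormal latency.** latency_s = δ + exp(ε), ε ~ N(μ, σ²), with
μ a full factorial in Instruction × Disruption(3) × Emotion-of-target plus
the Hemifield confound column and a participant intercept. σ and δ carry
intercepts and participant intercepts only. σ uses a log link. δ ("the
earliest possible response") uses a smooth bounded link
δ_s = ub_s · logistic(q), ub_s = 0.95 × participant s's fastest valid
latency: the bound keeps the shift below every observed latency, and the
logistic shape removes the hard likelihood wall that a truncated log link
creates (that wall defeats both Laplace initialisation and any sampler
without gradients). Priors: intercept N(log 0.25 s, 1), other fixed
effects N(0, 1), log σ intercept N(−1, 1), q N(0, 1.5).

**Bernoulli choice.** Fear-choice rate θ with logit link, full factorial
in Instruction × Disruption(3) × binarized Latency plus Hemifield
confound and participant intercepts; fixed effects N(0, 1). Binarized
Latency is a median split computed within each Instruction × Disruption ×
Hemifield cell (hence orthogonal to those factors); values strictly below
the cell median are Early, values at or above it Late (deterministic tie
rule, so an odd cell's median observation goes to Late).

**Hierarchical drift-diffusion.** Choice and latency jointly, with the
Wiener first-passage likelihood: drift v and start point z (logit link)
vary over Instruction × Disruption(3) × Hemifield (full factorial);
boundary separation a and non-decision time t0 (log links) over
Instruction × Disruption-presence — disruption laterality and hemifield
are defined relative to the fearful face, which is unknown before stimulus
onset, so the pre-stimulus parameters a and t0 cannot depend on them. The
upper boundary codes orientation to the fearful face. The diffusion
coefficient is fixed at 1 (scaling convention); there are no inter-trial
variability parameters. t0 is bounded above by 0.95 × the minimum latency
among the trials it applies to (each participant × instruction × presence
group); bounding by the participant's global minimum instead would exclude
true parameter sets in which a participant's fastest trials come from a
lower-t0 condition. Priors: v and z-logit coefficients N(0, 1); log a
coefficients N(0, 0.5); log t0 intercept N(log 0.18 s, 0.5), other
coefficients N(0, 0.5).

### Wiener first-passage density

The defective density is evaluated with the classical small-time and
large-time series, switching per evaluation to whichever needs fewer terms
at truncation tolerance 1e−10 (terms capped at 120); the two expansions
agree to better than 1e−8 across the tested parameter grid. The upper
boundary density uses the exact mirror identity
f_upper(t | v, a, z) = f_lower(t | −v, a, 1−z). The sampler's hot path is
a numba-compiled kernel returning per-parameter-set log-likelihood sums;
it matches the pure-numpy implementation to ~1e−12. Two simulators back
the generator and the oracle tests: `exact_hybrid` (closed-form boundary
probability plus inverse-CDF sampling of the conditional density on an
8192-point grid extended until the neglected tail is < 1e−9) and
Euler–Maruyama with per-step Brownian-bridge boundary-crossing correction
(without the bridge term, first-passage times carry an O(√dt) late-hitting
bias of several milliseconds at dt = 1e−4 s).

### Posterior sampling

No gradient-based sampler is used; posteriors are drawn with block
differential-evolution MCMC, the standard family for hierarchical
evidence-accumulation models. An ensemble of walkers (default 96; 64/32
in reduced settings) is updated block-wise: one block per fixed-effect
group, one per participant (all of that participant's intercepts jointly,
evaluated against only that participant's trials via partial-posterior
terms), plus "ridge" blocks that move an intercept together with its
random intercepts, a joint (location, spread, shift) intercept block for
the lognormal model, and joint (v, z) / (a, t0) coefficient blocks for the
drift-diffusion model — each extra block targets an empirically slow
posterior direction. Proposals are γ × (difference of two opposite-half
walkers) with γ = 2.38/√(2d) per block, adapted toward 25% acceptance
during burn-in only, and a 10% chance of γ = 1 mode jumps. Hierarchical
scale parameters are excluded from DE updates and resampled exactly by
univariate slice sampling from their conditional given the centred
intercepts (the conditional involves no data, so the scale–intercept
funnel never slows the ensemble). Initialisation is a MAP search (L-BFGS
with batched central finite differences) with the scales clamped — the
joint mode of a centred hierarchy sits at the degenerate sd → 0 apex —
followed by per-axis curvature scaling validated by unit-step probes.

Convergence is enforced on the reported parameters (fixed effects and
intercepts, from which every planned contrast is computed): R-hat ≤ 1.01
and bulk ESS ≥ 400 by default, with automatic chain extension. R-hat is
computed over four superchains (walkers grouped round-robin, draws ordered
step-major): walker-level split R-hat is structurally inflated for short
ensemble chains — on an exact Gaussian target it reads ≈ 1.25 at a healthy
pooled ESS — whereas superchain R-hat still detects non-stationarity and
ensemble disagreement. ESS uses walkers as chains. Failure raises a
ConvergenceError rather than returning draws.

The validation suite fits twenty replicate cohorts per model (6
participants × ~180 trials, the study's scale) with reduced-draw settings
— 48 walkers × 400–600 sweeps for the latency and choice models, 32 × 300–
450 for the drift-diffusion model, with thresholds R-hat ≤ 1.10–1.15 and
ESS ≥ 40–60 — chosen so a full recovery study completes in one sitting;
interval-endpoint Monte-Carlo noise at these ESS values is well under the
interval widths being checked.

### Contrasts

Cell predictions are formed per posterior draw at the average participant
(random intercepts at zero) on each quantity's reporting scale: latency as
δ + exp(μ_cell + σ²/2) in ms (posterior-predictive mean differencing), θ
as a rate, z via its inverse logit, a and t0 via exp. Hemifield is
marginalised by equal-weight averaging before any differencing, and
contrasts that reference a hemifield level directly are rejected. Each
planned contrast reports the posterior mean, the 2.5/97.5-percentile
interval, and P(effect), the posterior mass strictly on the side of zero
matching the sign of the mean.

## Face difference images

Trial-wise attended-minus-neglected difference images (assumed
pre-registered to a common frame) are analysed with an ordinary
least-squares cell-means model over Disruption(3) × Latency(2) with a
centred orientation-side confound column, independently per pixel. Emitted
maps: per-disruption Early−Late t, the 3-contrast omnibus F over those
differences, and the 2-df Disruption × Latency interaction F. Family-wise
error over pixels uses a permutation max-statistic null — Early/Late
labels exchanged within Disruption × side blocks, the trial being the
exchangeable unit — in place of random-field theory, whose smoothness
estimation is not reproducible here; permutation control is exact under
exchangeability. Inference is restricted to an upper-half-face mask before
thresholding; pixels outside the mask are never suprathreshold.

## Induced time-frequency analysis

Preprocessing: bipolar difference of the two most distal contacts, 0.1 Hz
two-pass 5th-order Butterworth high-pass (zero phase), epochs −2 to +4 s.
Power uses fixed-length sliding windows at 25 ms steps, with window
centres on an absolute grid (multiples of 25 ms) so images are pixelwise
comparable across trials and conditions: 1–48 Hz with a 400 ms Hanning
taper on a 2.5 Hz frequency grid; 52–148 Hz with 200 ms DPSS multitapers
(time-half-bandwidth 2, 3 tapers, ±10 Hz smoothing) on a 4 Hz grid. Each
window is projected onto complex exponentials at exactly the requested
frequencies, which accommodates the non-integer samples-per-step at
1024 Hz.

Trial images are robust-averaged per condition and participant: Tukey
bisquare weights (tuning 4.685, ≤ 20 iterations) on residuals standardised
by 1.4826 × MAD. For strictly positive inputs the residuals are formed on
the log scale — trialwise spectral power is strongly right-skewed, and
weighting raw-power residuals clips the right tail and biases condition
averages (and hence percent-change amplitudes) by ~10%; log-scale
residuals are near-symmetric and remove most of that bias. The weighted
mean itself is taken on the power scale. Condition averages are rescaled
to percent change over the −600 to −200 ms per-frequency baseline
(baseline statistics on the condition average, not per trial), then
smoothed with a Gaussian kernel of 3×2 (low band) or 4×2 (high band)
frequency × time pixels FWHM, truncated at 4 SD, before statistics.

Inference is a within-subject 2 × 2 pixelwise ANOVA with factors Recording
side (re fearful face) and Emotion of the oriented target; the interaction
F(1, n−1) is the squared one-sample t of each participant's double
difference, with a max-F permutation null from within-participant sign
flips of that double difference, masked to 0–400 ms post-stimulus. Note
that in this side × emotion coding, "the saccade went contralateral to the
recording site" is exactly the interaction pattern: (Contra-to-fear, fear
target) and (Ipsi-to-fear, neutral target) are the contralateral cells.

## The synthetic generator

The generator emulates the study's structure with effect sizes seeded from
its headline estimates: start-point shift Δz = −0.104 between
disruption-laterality cells under Yield (around z = 0.48 Yield / 0.42
Oppose baselines, matching the reported 48%/42% fear-choice rates),
non-decision time +19 ms under disruption (t0 = 0.18 s baseline), boundary
separation +0.194 under Oppose (a = 0.9 baseline), drift 0, latency
effects of −17 ms (Emotion), +32 ms (Disruption presence) and +17 ms
(Yield laterality × emotion interaction) on the response scale, a +0.11
Early−Late fear-preference rate effect, and an induced 99 Hz gamma burst
(Gaussian envelope centred 80 ms, SD 25.5 ms, so ±2 SD spans ≈ 29–131 ms)
on contralateral-orientation trials. The lognormal latency scale
(μ0 = log 0.185 s, σ = 0.22, δ = 80 ms; mean ≈ 270 ms, SD ≈ 42 ms) is
calibrated to the study's reported posterior latencies and contrast
uncertainties, which imply a trial-level SD near 50 ms. Participant
intercept deviations are Normal(0, 0.1) on each parameter's link scale.
All randomness flows from one master seed through counter-keyed
substreams, so regenerating a subset of trials never shifts other trials'
draws.

Burst amplitude is specified in percent change of baseline power at the
burst's centre frequency and converted to a raw sinusoid amplitude by an
exact first-moment calibration: the expected multitaper background power
at that frequency is computed from the generator's 1/f spectral shaping
and the taper transfer functions, and the phase-averaged burst power from
the taper-weighted envelope; no simulation or fitting is involved.

Oppose trials are generated from their own drift-diffusion parameter cell
rather than an explicit countermanding race, mirroring how the behavioural
models treat instruction. Eye traces are minimum-jerk displacements
(default 40 ms) in Gaussian fixation noise; LFP background is 1/f noise;
face images are smooth Gaussian noise fields with an elliptical
scleral-region offset on Early trials. None of these claim fidelity to
real waveform shapes, spectra beyond 1/f, or facial morphology — passing
recovery tests therefore certifies the analysis machinery (detection
accuracy, estimator calibration, error control), not robustness to
real-data pathologies such as blinks, electrode artefacts, registration
error, or non-stationary noise. The inter-trial interval beyond fixation
jitter is likewise a free parameter with no claimed fidelity.

## Known limitations

- With drift and start point both free per condition cell, a choice-rate
  difference is partially absorbed by drift at this study's size (~1200
  trials): posterior means of Δz shrink toward roughly half the generating
  value while intervals still cover it. This is inherent to the model
  class, not an implementation defect.
- Discarding latencies above 1000 ms truncates the slow tail without a
  truncation term in the likelihood; the boundary-separation parameter
  absorbs most of the bias (its Oppose effect underestimates the
  generating +0.194). The bias is differential (larger a ⇒ more
  truncation) and would affect any untruncated-likelihood fit of
  truncated data.
- Ensemble MCMC without gradients pays a steep price in high dimensions;
  the block structure and Gibbs scale updates recover acceptable mixing,
  but fits are minutes, not seconds, and the walker-level chains are too
  short for conventional per-chain diagnostics (hence superchain R-hat).
- The permutation nulls treat trials (facepix) and participants (tfr) as
  the exchangeable units; with few participants the sign-flip null is
  discrete (2^n patterns), which makes the test conservative rather than
  invalid.
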