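# amygaze

Analysis toolkit for saccadic orienting to facial threat under transient
unilateral amygdala disruption — and a synthetic-experiment generator with
known ground truth that makes every stage of the analysis testable.

## The problem

In the underlying experimental paradigm, a participant fixates centrally;
a fearful and a neutral face then appear simultaneously at ±5.3°
eccentricity, and the participant either looks at the face that captures
attention ("Yield") or away from it ("Oppose"), while one amygdala may be
transiently disrupted ipsi- or contralateral to the fearful face. The
behavioural readouts per trial are the binary orientation choice and the
saccade latency; a bipolar amygdala LFP channel and the face images
themselves provide electrophysiological and stimulus-feature correlates.
Clinical data of this kind are scarce, imbalanced, and not publicly
depositable, so the package is built for two audiences: analysts fitting
the models to their own recordings, and methodologists who need the whole
pipeline validated by parameter recovery on synthetic cohorts.

## What's inside

- **`synth`** — generates complete experiments (trial tables,
  drift-diffusion behaviour, 1 kHz eye traces, LFP epochs with an induced
  gamma burst, face difference images), each object carrying its ground
  truth.
- **`gaze`** — horizontal saccade detection (velocity ≥ 5°/s, amplitude
  ≥ 0.5°, preceding fixation ≥ 50 ms, duration ≥ 20 ms) and trial QC
  (bad fixation / latency < 100 ms / absent by 1000 ms).
- **`wiener`** — the drift-diffusion core: first-passage density
  f(t | v, a, z, t₀) via small/large-time series, defective choice
  probabilities, log-likelihood, and exact-hybrid / bridge-corrected Euler
  simulators.
- **`bayes`** — three hierarchical Bayesian models (shifted-lognormal
  latency; Bernoulli choice with a within-cell median split; joint Wiener
  drift-diffusion with v, z per Instruction × Disruption × Hemifield and
  a, t₀ per Instruction × Disruption presence), fitted by block
  differential-evolution MCMC with Gibbs scale updates, plus planned
  posterior contrasts: mean, 95% credible interval, P(effect).
- **`facepix`** — pixelwise OLS on attended-minus-neglected face
  difference images with permutation max-statistic family-wise error
  control inside an upper-face mask.
- **`tfr`** — induced time-frequency analysis of the amygdala channel:
  Hanning (1–48 Hz) and DPSS multitaper (52–148 Hz) spectrograms at 25 ms
  steps, robust trial averaging, percent-change baseline rescaling, and a
  within-subject 2 × 2 (Recording side × Emotion) pixelwise ANOVA with
  permutation FWE.

The fitting classes follow scikit-learn conventions (`fit`,
`get_params`, fitted attributes with trailing underscores) and compose
with its tooling; module-level functions are thin wrappers. A `amygaze`
CLI exposes `simulate`, `detect`, `fit`, `contrast`, `facepix` and `tfr`
subcommands.

## Worked example

Simulate a six-participant experiment at the study's effect sizes, detect
saccades from the rendered eye traces, QC the trials, and fit the joint
drift-diffusion model:

```python
from amygaze import synth, gaze, bayes

# 1. simulate a six-participant experiment at the study's effect sizes
truth = synth.default_ground_truth()
design = synth.make_design(synth.DesignSpec(n_participants=6,
                                            trials_per_block=30, seed=1))
trials = synth.simulate_behaviour(design, truth, seed=1)

# 2. render eye traces, detect saccades, apply QC
traces = [synth.synth_eye_trace(rec, noise_sd_deg=0.1, seed=1)
          for _, rec in trials.iterrows()]
table, qc = gaze.build_trial_table(traces, trials)
print(f"QC: {qc['remaining']} of {qc['acquired']} trials remain ({qc['by_code']})")

# 3. fit the joint drift-diffusion model and report planned contrasts
cfg = bayes.SamplerConfig(n_walkers=32, n_burn=150, n_draws=200,
                          max_extensions=1, extension_steps=150,
                          rhat_max=1.15, ess_min=40, seed=1)
ddm = bayes.WienerDDMModel(sampler=cfg).fit(table)
for name in ("z_yield_laterality", "t0_disruption_main", "a_instruction_main"):
    r = ddm.planned_contrasts()[name]
    print(f"{name}: {r.mean:+.3f}  95% CI ({r.ci_low:+.3f}, {r.ci_high:+.3f})"
          f"  P(effect)={r.p_effect:.3f}")
```

Output:

```
QC: 1036 of 1080 trials remain ({'absent': 44})
z_yield_laterality: -0.088  95% CI (-0.163, -0.013)  P(effect)=0.994
t0_disruption_main: +0.026  95% CI (+0.017, +0.036)  P(effect)=1.000
a_instruction_main: +0.119  95% CI (+0.058, +0.188)  P(effect)=1.000
```

Reading the numbers: the generator injected a start-point bias shift of
−0.104 between disruption-laterality cells under Yield, +19 ms of
non-decision time under disruption, and +0.194 boundary separation under
Oppose. The fitted posterior recovers a credibly negative bias shift whose
interval covers the injected value, a +26 ms (CI 17–36 ms) non-decision
slowing, and increased response caution under Oppose — the boundary effect
is partly attenuated because latencies beyond 1000 ms are discarded by QC
(see `docs/methods.md`, Known limitations).

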