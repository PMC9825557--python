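"""Synthetic two-alternative face-orienting experiments with known ground truth.

Emulates the structure of a clinical saccadic-orienting study: participants
fixate centrally (1750 ms +/- 250 ms jitter), then a fearful and a neutral
face appear at +/-5.3 deg horizontal eccentricity for 1000 ms and the
participant orients toward one of them ("Yield") or away from the face that
captures attention ("Oppose"), in blocks of 50 trials, while one amygdala
may be transiently disrupted ipsilateral or contralateral to the fearful
face.  Behaviour is generated by a condition-dependent drift-diffusion
process; eye traces, local field potential epochs and face difference
images are rendered from the behavioural records.

Every generated object carries its ground truth so downstream stages
(saccade detection, Bayesian model fitting, pixelwise and time-frequency
inference) can be tested by parameter and signal recovery.  All randomness
flows from a single master seed through per-trial counter-keyed substreams,
so subsetting trials never shifts other trials' draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .wiener import WienerParams, simulate_ddm

INSTRUCTIONS = ("Yield", "Oppose")
DISRUPTIONS = ("None", "Ipsi", "Contra")
HEMIFIELDS = ("L", "R")
EMOTIONS = ("fear", "neutral")

# sampling rates of the synthetic recordings
EYE_FS = 1000.0  # Hz
LFP_FS = 1024.0  # Hz
EPOCH_TSPAN = (-2.0, 4.0)  # s relative to stimulus onset

__all__ = [
    "DesignSpec",
    "GroundTruth",
    "LognormalTruth",
    "ChoiceTruth",
    "BurstSpec",
    "ImageParams",
    "EyeTrace",
    "LfpEpoch",
    "default_ground_truth",
    "make_design",
    "simulate_behaviour",
    "simulate_latency_cohort",
    "simulate_choice_cohort",
    "synth_eye_trace",
    "synth_lfp_epoch",
    "synth_lfp_cohort",
    "synth_face_pair",
    "synth_face_cohort",
    "default_sclera_mask",
    "upper_face_mask",
    "inject_qc_defects",
    "trial_rng",
]


def trial_rng(master_seed: int, *key: int) -> np.random.Generator:
    """Counter-keyed substream: independent of draws made for other keys."""
    ss = np.random.SeedSequence(entropy=int(master_seed), spawn_key=tuple(int(k) for k in key))
    return np.random.default_rng(ss)


# stream identifiers for substream keys
_STREAM_DESIGN = 1
_STREAM_BEHAVIOUR = 2
_STREAM_EYE = 3
_STREAM_LFP = 4
_STREAM_FACE = 5
_STREAM_SUBJECT = 6


# ---------------------------------------------------------------------------
# design
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DesignSpec:
    """Factorial trial design of one synthetic experiment."""

    n_participants: int = 6
    blocks_per_condition: int = 1
    trials_per_block: int = 50
    fixation_ms: float = 1750.0
    jitter_ms: float = 250.0
    eccentricity_deg: float = 5.3
    presentation_ms: float = 1000.0
    instruction_levels: tuple = INSTRUCTIONS
    disruption_levels: tuple = DISRUPTIONS
    hemifield_levels: tuple = HEMIFIELDS
    seed: int = 0

    def __post_init__(self):
        if self.n_participants <= 0 or self.blocks_per_condition <= 0 or self.trials_per_block <= 0:
            raise ValueError("participant, block and trial counts must be positive")
        if self.jitter_ms < 0:
            raise ValueError("jitter_ms must be >= 0")
        for name in ("instruction_levels", "disruption_levels", "hemifield_levels"):
            levels = getattr(self, name)
            if len(levels) == 0 or len(set(levels)) != len(levels):
                raise ValueError(f"{name} must be a non-empty set of unique labels")


def make_design(spec: DesignSpec) -> pd.DataFrame:
    """Enumerate trials: one block per Instruction x Disruption condition
    (times ``blocks_per_condition``), fearful-face hemifield randomised
    uniformly per trial, fixation duration jittered uniformly.

    Deterministic given ``spec.seed``.
    """
    rows = []
    for p in range(spec.n_participants):
        block = 0
        for instr in spec.instruction_levels:
            for disr in spec.disruption_levels:
                for _ in range(spec.blocks_per_condition):
                    for trial in range(spec.trials_per_block):
                        rng = trial_rng(spec.seed, _STREAM_DESIGN, p, block, trial)
                        hemi = spec.hemifield_levels[int(rng.integers(len(spec.hemifield_levels)))]
                        fix = spec.fixation_ms + spec.jitter_ms * (2.0 * rng.random() - 1.0)
                        rows.append((p, block, trial, instr, disr, hemi, fix))
                    block += 1
    return pd.DataFrame(
        rows,
        columns=["participant", "block", "trial", "instruction", "disruption",
                 "hemifield_fear", "fixation_ms"],
    )


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LognormalTruth:
    """Population-level shifted-lognormal latency truth (seconds).

    Cell means are ``delta_s + exp(mu0 + dmu_cell + sigma**2 / 2)`` at the
    average participant; ``mu_effects`` maps
    (instruction, disruption, emotion-of-target) cells to log-scale offsets.
    """

    mu0: float = float(np.log(0.185))
    sigma: float = 0.22
    delta_s: float = 0.08
    mu_effects: dict = field(default_factory=dict)
    subject_sd_mu: float = 0.1

    def cell_mu(self, instruction: str, disruption: str, emotion: str) -> float:
        return self.mu0 + self.mu_effects.get((instruction, disruption, emotion), 0.0)

    def cell_mean_s(self, instruction: str, disruption: str, emotion: str) -> float:
        return self.delta_s + float(
            np.exp(self.cell_mu(instruction, disruption, emotion) + self.sigma**2 / 2)
        )


@dataclass(frozen=True)
class ChoiceTruth:
    """Population-level Bernoulli fear-preference truth.

    ``theta`` maps (instruction, disruption, latency-class) to the
    fear-choice rate at the average participant.
    """

    theta: dict = field(default_factory=dict)
    base_rate: float = 0.45
    subject_sd_logit: float = 0.1

    def cell_theta(self, instruction: str, disruption: str, latclass: str) -> float:
        return self.theta.get((instruction, disruption, latclass), self.base_rate)


@dataclass(frozen=True)
class BurstSpec:
    """Induced gamma burst injected into LFP epochs on contralateral-orientation
    trials: Gaussian-windowed sinusoid, amplitude expressed as percent of
    baseline power at the centre frequency so time-frequency percent-change
    units match directly."""

    center_freq_hz: float = 99.0
    t_center_s: float = 0.080
    t_sigma_s: float = 0.0255  # +/- 2 sigma spans roughly 29-131 ms
    amplitude_pct: float = 100.0


@dataclass(frozen=True)
class GroundTruth:
    """Everything the generator needs, and every recovery test's reference."""

    wiener: dict  # (instruction, disruption, hemifield) -> WienerParams
    subject_sd: dict = field(default_factory=lambda: {"v": 0.1, "z": 0.1, "a": 0.1, "t0": 0.1})
    lognormal: LognormalTruth = field(default_factory=LognormalTruth)
    choice: ChoiceTruth = field(default_factory=ChoiceTruth)
    lfp_burst: BurstSpec = field(default_factory=BurstSpec)
    lfp_noise_alpha: float = 1.0  # 1/f exponent of the background
    sclera_effect: float = 1.0

    def __post_init__(self):
        for cell, p in self.wiener.items():
            if not isinstance(p, WienerParams):
                raise ValueError(f"wiener[{cell}] is not a WienerParams")


def _interaction_pattern(disruption: str, emotion: str) -> float:
    """+1/-1 pattern whose (Contra-Ipsi) x (fear-neutral) double difference
    equals 4."""
    if disruption == "None":
        return 0.0
    s_d = 1.0 if disruption == "Contra" else -1.0
    s_e = 1.0 if emotion == "fear" else -1.0
    return s_d * s_e


def default_ground_truth(
    delta_z: float = -0.104,
    delta_t0_s: float = 0.019,
    delta_a: float = 0.194,
    latency_interaction_ms: float = 17.0,
    emotion_main_ms: float = -17.0,
    disruption_main_ms: float = 32.0,
    choice_latency_rate: float = 0.11,
    subject_sd: float = 0.1,
    symmetric: bool = False,
) -> GroundTruth:
    """Study-condition effect sizes for the generator.

    Defaults are seeded from the headline point estimates of the modelled
    study: a start-point bias shift of -0.104 between disruption-laterality
    cells under Yield, +19 ms of non-decision time under disruption,
    +0.194 boundary separation under Oppose, a +17 ms laterality-by-emotion
    latency interaction under Yield, a -17 ms emotion main effect, a +32 ms
    disruption-presence main effect, and a +0.11 Early-vs-Late fear-
    preference rate effect.  ``symmetric=True`` zeroes every effect and
    centres the start point (null / calibration cohorts).
    """
    if symmetric:
        base = WienerParams(v=0.0, a=0.9, z=0.5, t0=0.18)
        wiener = {(i, d, h): base for i in INSTRUCTIONS for d in DISRUPTIONS for h in HEMIFIELDS}
        return GroundTruth(
            wiener=wiener,
            subject_sd={"v": subject_sd, "z": subject_sd, "a": subject_sd, "t0": subject_sd},
            lognormal=LognormalTruth(subject_sd_mu=subject_sd),
            choice=ChoiceTruth(base_rate=0.5, subject_sd_logit=subject_sd),
            sclera_effect=0.0,
        )

    wiener = {}
    z_none = {"Yield": 0.48, "Oppose": 0.42}
    z_lat = {"Yield": delta_z, "Oppose": 0.072}
    for instr in INSTRUCTIONS:
        a = 0.9 + (delta_a if instr == "Oppose" else 0.0)
        for disr in DISRUPTIONS:
            t0 = 0.18 + (delta_t0_s if disr != "None" else 0.0)
            z = z_none[instr]
            if disr == "Ipsi":
                z = z - z_lat[instr] / 2.0
            elif disr == "Contra":
                z = z + z_lat[instr] / 2.0
            for hemi in HEMIFIELDS:
                wiener[(instr, disr, hemi)] = WienerParams(v=0.0, a=a, z=z, t0=t0)

    # latency truth: sum-coded main effects plus the Yield laterality x emotion
    # interaction, all specified on the response (ms) scale and mapped onto the
    # log-location scale through the local derivative of the cell mean
    ln0 = LognormalTruth(subject_sd_mu=subject_sd)
    dmean_dmu = float(np.exp(ln0.mu0 + ln0.sigma**2 / 2))  # s per mu unit
    mu_eff = {}
    for instr in INSTRUCTIONS:
        for disr in DISRUPTIONS:
            for emo in EMOTIONS:
                eff_s = 0.0
                eff_s += (emotion_main_ms / 2.0) * (1.0 if emo == "fear" else -1.0) / 1000.0
                eff_s += (disruption_main_ms / 2.0) * (1.0 if disr != "None" else -1.0) / 1000.0
                if instr == "Yield":
                    eff_s += (latency_interaction_ms / 4.0) * _interaction_pattern(disr, emo) / 1000.0
                mu_eff[(instr, disr, emo)] = eff_s / dmean_dmu
    lognormal = replace(ln0, mu_effects=mu_eff)

    theta = {}
    for instr in INSTRUCTIONS:
        base = 0.48 if instr == "Yield" else 0.42
        for disr in DISRUPTIONS:
            for lc in ("Early", "Late"):
                theta[(instr, disr, lc)] = base + (choice_latency_rate / 2.0) * (
                    1.0 if lc == "Early" else -1.0
                )
    choice = ChoiceTruth(theta=theta, base_rate=0.45, subject_sd_logit=subject_sd)

    return GroundTruth(
        wiener=wiener,
        subject_sd={"v": subject_sd, "z": subject_sd, "a": subject_sd, "t0": subject_sd},
        lognormal=lognormal,
        choice=choice,
    )


# ---------------------------------------------------------------------------
# behaviour
# ---------------------------------------------------------------------------

def _logit(p):
    return np.log(p) - np.log1p(-p)


def _inv_logit(x):
    return 1.0 / (1.0 + np.exp(-x))


def subject_deviations(truth: GroundTruth, n_participants: int, seed: int) -> pd.DataFrame:
    """Zero-mean Normal subject intercept deviations, one row per participant,
    columns per drift-diffusion parameter on its link scale
    (identity for v, logit for z, log for a and t0)."""
    rng = trial_rng(seed, _STREAM_SUBJECT)
    dev = {p: rng.normal(0.0, truth.subject_sd[p], size=n_participants)
           for p in ("v", "z", "a", "t0")}
    return pd.DataFrame(dev)


def _subject_params(base: WienerParams, dev_row) -> WienerParams:
    return WienerParams(
        v=float(base.v + dev_row["v"]),
        a=float(base.a * np.exp(dev_row["a"])),
        z=float(_inv_logit(_logit(base.z) + dev_row["z"])),
        t0=float(base.t0 * np.exp(dev_row["t0"])),
    )


def simulate_behaviour(design: pd.DataFrame, truth: GroundTruth, seed: int = 0) -> pd.DataFrame:
    """Sample each trial's (choice, latency) from the participant- and
    condition-specific drift-diffusion process.

    Returns the design table augmented with ``choice`` ('fear'/'neutral'),
    ``latency_ms`` (= t0 + first-passage time, so always above t0), saccade
    ``direction`` ('left'/'right') and a ``qc_true`` label ('valid', or
    'absent' for latencies beyond 1000 ms).  Trial order and count are
    preserved.
    """
    cells = set(zip(design["instruction"], design["disruption"], design["hemifield_fear"]))
    missing = [c for c in cells if c not in truth.wiener]
    if missing:
        raise ValueError(f"ground truth lacks parameters for conditions: {missing}")
    devs = subject_deviations(truth, int(design["participant"].max()) + 1, seed)
    out = design.copy()
    out["choice"] = ""
    out["latency_ms"] = np.nan
    for (p, instr, disr, hemi), idx in out.groupby(
        ["participant", "instruction", "disruption", "hemifield_fear"], sort=False
    ).groups.items():
        params = _subject_params(truth.wiener[(instr, disr, hemi)], devs.iloc[int(p)])
        rng = trial_rng(seed, _STREAM_BEHAVIOUR, int(p),
                        list(truth.wiener).index((instr, disr, hemi)))
        ch, rt = simulate_ddm(params, len(idx), seed=rng, method="exact_hybrid")
        out.loc[idx, "choice"] = np.where(ch == 1, "fear", "neutral")
        out.loc[idx, "latency_ms"] = rt * 1000.0
    fear_right = out["hemifield_fear"] == "R"
    to_fear = out["choice"] == "fear"
    out["direction"] = np.where(fear_right == to_fear, "right", "left")
    out["qc_true"] = np.where(out["latency_ms"] > 1000.0, "absent",
                              np.where(out["latency_ms"] < 100.0, "too_fast", "valid"))
    return out


def simulate_latency_cohort(design: pd.DataFrame, truth: GroundTruth, seed: int = 0) -> pd.DataFrame:
    """Cohort whose latencies are drawn directly from the shifted-lognormal
    truth (choice assigned uniformly): the reference data set for latency-
    model parameter recovery, where the generating family and the fitted
    family coincide."""
    ln = truth.lognormal
    rng_subj = trial_rng(seed, _STREAM_SUBJECT, 1)
    n_subj = int(design["participant"].max()) + 1
    eta = rng_subj.normal(0.0, ln.subject_sd_mu, size=n_subj)
    out = design.copy()
    n = len(out)
    rng = trial_rng(seed, _STREAM_BEHAVIOUR, 99)
    out["choice"] = np.where(rng.random(n) < 0.5, "fear", "neutral")
    mu = np.array([
        ln.cell_mu(i, d, e) for i, d, e in zip(out["instruction"], out["disruption"], out["choice"])
    ]) + eta[out["participant"].to_numpy()]
    lat_s = ln.delta_s + np.exp(rng.normal(mu, ln.sigma))
    out["latency_ms"] = lat_s * 1000.0
    fear_right = out["hemifield_fear"] == "R"
    to_fear = out["choice"] == "fear"
    out["direction"] = np.where(fear_right == to_fear, "right", "left")
    out["qc_true"] = "valid"
    return out


def simulate_choice_cohort(design: pd.DataFrame, truth: GroundTruth, seed: int = 0) -> pd.DataFrame:
    """Cohort whose choices are drawn from the Bernoulli fear-preference truth
    conditional on an Early/Late latency class (median split within each
    Instruction x Disruption x Hemifield cell of lognormal latencies)."""
    ln = truth.lognormal
    ch = truth.choice
    out = design.copy()
    n = len(out)
    rng = trial_rng(seed, _STREAM_BEHAVIOUR, 98)
    lat_s = ln.delta_s + np.exp(rng.normal(ln.mu0, ln.sigma, size=n))
    out["latency_ms"] = lat_s * 1000.0
    med = out.groupby(["instruction", "disruption", "hemifield_fear"])["latency_ms"].transform("median")
    out["latency_class"] = np.where(out["latency_ms"] < med, "Early", "Late")
    n_subj = int(design["participant"].max()) + 1
    eta = trial_rng(seed, _STREAM_SUBJECT, 2).normal(0.0, ch.subject_sd_logit, size=n_subj)
    logit_theta = np.array([
        _logit(ch.cell_theta(i, d, lc))
        for i, d, lc in zip(out["instruction"], out["disruption"], out["latency_class"])
    ]) + eta[out["participant"].to_numpy()]
    out["choice"] = np.where(rng.random(n) < _inv_logit(logit_theta), "fear", "neutral")
    fear_right = out["hemifield_fear"] == "R"
    to_fear = out["choice"] == "fear"
    out["direction"] = np.where(fear_right == to_fear, "right", "left")
    out["qc_true"] = "valid"
    return out


# ---------------------------------------------------------------------------
# eye traces
# ---------------------------------------------------------------------------

@dataclass
class EyeTrace:
    """1 kHz horizontal gaze trace for one trial (degrees, rightward positive)."""

    x_deg: np.ndarray
    stim_onset_ms: float
    fs: float = EYE_FS
    truth_onset_ms: float | None = None  # ground-truth saccade onset re stimulus
    truth_direction: str | None = None

    @property
    def times_ms(self) -> np.ndarray:
        return np.arange(len(self.x_deg)) * 1000.0 / self.fs


def _min_jerk(tau: np.ndarray) -> np.ndarray:
    tau = np.clip(tau, 0.0, 1.0)
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def synth_eye_trace(
    record,
    noise_sd_deg: float = 0.1,
    sac_duration_ms: float = 40.0,
    seed: int = 0,
    eccentricity_deg: float = 5.3,
    pre_ms: float = 500.0,
    post_ms: float = 1300.0,
) -> EyeTrace:
    """Render one trial's gaze trace: Gaussian fixation noise plus, for
    responding trials, a minimum-jerk sigmoidal displacement to the chosen
    face's eccentricity starting at the record's latency.

    ``record`` needs fields participant/block/trial (for seeding),
    ``latency_ms``, ``direction`` and ``qc_true``; a ``qc_true`` of
    'absent' renders no saccade, 'bad_fixation' adds a slow pre-stimulus
    drift beyond the fixation tolerance.
    """
    if noise_sd_deg < 0:
        raise ValueError("noise_sd_deg must be >= 0")
    rng = trial_rng(seed, _STREAM_EYE, int(record["participant"]),
                    int(record["block"]), int(record["trial"]))
    n = int(round((pre_ms + post_ms) * EYE_FS / 1000.0))
    t = np.arange(n) * 1000.0 / EYE_FS - pre_ms  # ms re stimulus onset
    x = rng.normal(0.0, noise_sd_deg, size=n) if noise_sd_deg > 0 else np.zeros(n)
    qc = record["qc_true"]
    onset = None
    direction = None
    if qc != "absent" and np.isfinite(record["latency_ms"]):
        onset = float(record["latency_ms"])
        direction = str(record["direction"])
        sign = 1.0 if direction == "right" else -1.0
        x = x + sign * eccentricity_deg * _min_jerk((t - onset) / sac_duration_ms)
    if qc == "bad_fixation":
        # slow pre-stimulus drift: violates the 100 ms fixation window
        drift = np.clip((t + pre_ms) / pre_ms, 0, 1) * 1.6
        x = x + np.where(t < 0, drift, 1.6)
    return EyeTrace(x_deg=x, stim_onset_ms=pre_ms, truth_onset_ms=onset,
                    truth_direction=direction)


def inject_qc_defects(table: pd.DataFrame, frac_bad_fixation: float = 0.05,
                      frac_absent: float = 0.05, frac_too_fast: float = 0.03,
                      seed: int = 0) -> pd.DataFrame:
    """Relabel a random subset of trials with known QC defects (ground truth
    for quality-control accounting tests).  'too_fast' trials get a latency
    of 60-95 ms; 'absent' trials lose their saccade."""
    out = table.copy()
    rng = trial_rng(seed, 7)
    u = rng.random(len(out))
    lab = np.asarray(out["qc_true"], dtype=object)
    valid = lab == "valid"
    lab[valid & (u < frac_bad_fixation)] = "bad_fixation"
    lab[valid & (u >= frac_bad_fixation) & (u < frac_bad_fixation + frac_absent)] = "absent"
    fast = valid & (u >= frac_bad_fixation + frac_absent) & (
        u < frac_bad_fixation + frac_absent + frac_too_fast)
    lab[fast] = "too_fast"
    out["qc_true"] = lab
    out.loc[fast, "latency_ms"] = rng.uniform(60.0, 95.0, size=int(fast.sum()))
    return out


# ---------------------------------------------------------------------------
# LFP epochs
# ---------------------------------------------------------------------------

@dataclass
class LfpEpoch:
    """One bipolar amygdala-channel epoch, -2 to +4 s at 1024 Hz."""

    samples: np.ndarray
    fs: float = LFP_FS
    tmin: float = EPOCH_TSPAN[0]
    trigger: str = "stimulus"
    recording_side: str = "Contra"  # re fearful face
    emotion: str = "fear"           # of the oriented target
    participant: int = 0

    @property
    def times(self) -> np.ndarray:
        return self.tmin + np.arange(len(self.samples)) / self.fs

    @property
    def contralateral_orientation(self) -> bool:
        """The saccade went contralateral to the recording side iff the
        oriented face sat opposite the electrode: (Contra re fear, fear
        target) or (Ipsi re fear, neutral target)."""
        return (self.recording_side == "Contra") == (self.emotion == "fear")


def _pink_shaping(n: int, fs: float, alpha: float) -> np.ndarray:
    """rFFT amplitude shaping of the 1/f^alpha background (unit white input)."""
    f = np.fft.rfftfreq(n, 1.0 / fs)
    shape = np.empty_like(f)
    f0 = max(f[1], 0.5)
    shape[0] = 0.0
    shape[1:] = (np.maximum(f[1:], f0)) ** (-alpha / 2.0)
    return shape


def pink_noise(n: int, fs: float, rng: np.random.Generator, alpha: float = 1.0) -> np.ndarray:
    spec = (rng.standard_normal(n // 2 + 1) + 1j * rng.standard_normal(n // 2 + 1))
    spec *= _pink_shaping(n, fs, alpha)
    return np.fft.irfft(spec, n=n)


def noise_psd_rfft(n: int, fs: float, alpha: float = 1.0) -> np.ndarray:
    """Expected |rFFT|^2 profile of the generated background (arbitrary power
    scale; percent-change analyses are invariant to the overall scale)."""
    return 2.0 * _pink_shaping(n, fs, alpha) ** 2


def synth_lfp_epoch(record_labels: dict, truth: GroundTruth, seed: int = 0,
                    amplitude: float | None = None) -> LfpEpoch:
    """One epoch of 1/f background plus, on contralateral-orientation trials,
    a Gaussian-windowed sinusoid at the burst frequency with random phase
    (induced, not phase-locked).

    ``record_labels`` carries participant / trial / cell keys plus
    ``recording_side`` ('Ipsi'/'Contra' re fearful face) and ``emotion`` of
    the oriented target.  ``amplitude`` is the raw sinusoid amplitude in
    background units; by default it is calibrated so that the measured
    high-band percent change at the burst peak equals
    ``truth.lfp_burst.amplitude_pct``.
    """
    n = int(round((EPOCH_TSPAN[1] - EPOCH_TSPAN[0]) * LFP_FS))
    rng = trial_rng(seed, _STREAM_LFP, int(record_labels.get("participant", 0)),
                    int(record_labels.get("trial", 0)), int(record_labels.get("cell", 0)))
    x = pink_noise(n, LFP_FS, rng, truth.lfp_noise_alpha)
    epoch = LfpEpoch(samples=x, recording_side=str(record_labels["recording_side"]),
                     emotion=str(record_labels["emotion"]),
                     participant=int(record_labels.get("participant", 0)))
    if epoch.contralateral_orientation and truth.lfp_burst.amplitude_pct != 0:
        if amplitude is None:
            amplitude = calibrated_burst_amplitude(truth)
        b = truth.lfp_burst
        t = epoch.times
        phase = rng.uniform(0, 2 * np.pi)
        env = np.exp(-((t - b.t_center_s) ** 2) / (2 * b.t_sigma_s**2))
        epoch.samples = x + amplitude * env * np.cos(2 * np.pi * b.center_freq_hz * t + phase)
    return epoch


def calibrated_burst_amplitude(truth: GroundTruth) -> float:
    """Sinusoid amplitude that produces ``amplitude_pct`` percent change at
    the burst's peak time-frequency bin of the high-band spectrogram.

    Exact first-moment calibration: the expected multitaper power of the
    background at the centre frequency is computed from the generator's
    spectral shaping, and the deterministic burst power (phase-averaged,
    envelope included) from the taper transfer functions.  No simulation or
    fitting is involved.
    """
    from .tfr import HIGH_BAND, _dpss_tapers  # settings live with tfr

    b = truth.lfp_burst
    fs = LFP_FS
    nwin = int(round(HIGH_BAND.window_s * fs))
    tapers = _dpss_tapers(nwin, HIGH_BAND.bandwidth_hz, fs)
    k = tapers.shape[0]
    nseg = int(round((EPOCH_TSPAN[1] - EPOCH_TSPAN[0]) * fs))
    # expected background power at f0: sum_m S[m] |W_k(f0 - f_m)|^2 / nseg^2
    psd = noise_psd_rfft(nseg, fs, truth.lfp_noise_alpha)
    fgrid = np.fft.rfftfreq(nseg, 1.0 / fs)
    tseg = np.arange(nwin) / fs
    stride = 8  # frequency subsampling of the (smooth) shaping profile
    exps = np.exp(2j * np.pi * np.outer(fgrid[::stride], tseg))
    p_noise = 0.0
    for w in tapers:
        wk = w * np.exp(-2j * np.pi * b.center_freq_hz * tseg)
        wf = np.abs(exps @ wk) ** 2
        p_noise += np.sum(psd[::stride] * wf) * stride / nseg**2
    p_noise /= k
    # unit-amplitude burst power at (f0, t_center), phase-averaged
    tw = tseg - tseg.mean()
    env = np.exp(-(tw**2) / (2 * b.t_sigma_s**2))
    p_sig = 0.0
    for w in tapers:
        s_dc = np.abs(np.sum(w * env)) ** 2
        s_2f = np.abs(np.sum(w * env * np.exp(-4j * np.pi * b.center_freq_hz * tseg))) ** 2
        p_sig += (s_dc + s_2f) / 4.0
    p_sig /= k
    return float(np.sqrt((b.amplitude_pct / 100.0) * p_noise / p_sig))


def synth_lfp_cohort(n_subjects: int, trials_per_cell: int, truth: GroundTruth,
                     seed: int = 0) -> list:
    """Balanced 2 x 2 (Recording side re fearful face x Emotion of target)
    epoch set per subject — the input of the time-frequency pipeline."""
    amp = (calibrated_burst_amplitude(truth) if truth.lfp_burst.amplitude_pct != 0 else 0.0)
    epochs = []
    for s in range(n_subjects):
        for ci, (side, emo) in enumerate(
            [(sd, em) for sd in ("Ipsi", "Contra") for em in EMOTIONS]
        ):
            for tr in range(trials_per_cell):
                epochs.append(synth_lfp_epoch(
                    {"participant": s, "trial": tr, "cell": ci,
                     "recording_side": side, "emotion": emo},
                    truth, seed=seed, amplitude=amp))
    return epochs


# ---------------------------------------------------------------------------
# face difference images
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ImageParams:
    height: int = 48
    width: int = 48
    noise_sd: float = 1.0
    smooth_sigma_px: float = 1.5


def default_sclera_mask(params: ImageParams) -> np.ndarray:
    """Two elliptical eye-white regions in the upper half of the face frame."""
    h, w = params.height, params.width
    yy, xx = np.mgrid[0:h, 0:w]
    mask = np.zeros((h, w), dtype=bool)
    for cx in (w * 0.32, w * 0.68):
        mask |= (((yy - h * 0.35) / (h * 0.06)) ** 2 + ((xx - cx) / (w * 0.10)) ** 2) <= 1.0
    return mask


def upper_face_mask(params: ImageParams) -> np.ndarray:
    mask = np.zeros((params.height, params.width), dtype=bool)
    mask[: params.height // 2, :] = True
    return mask


def synth_face_pair(record_labels: dict, image_params: ImageParams, seed: int = 0,
                    sclera_effect: float = 1.0, mask: np.ndarray | None = None) -> np.ndarray:
    """Attended-minus-neglected difference image for one trial: a smooth
    zero-mean noise field plus a scleral-region signal present on Early
    trials, emulating greater scleral exposure of the attended fearful eye
    region driving rapid orientation."""
    from scipy.ndimage import gaussian_filter

    if mask is None:
        mask = default_sclera_mask(image_params)
    if not mask.any():
        raise ValueError("empty sclera mask")
    rng = trial_rng(seed, _STREAM_FACE, int(record_labels.get("participant", 0)),
                    int(record_labels.get("trial", 0)), int(record_labels.get("cell", 0)))
    field_ = rng.standard_normal((image_params.height, image_params.width))
    if image_params.smooth_sigma_px > 0:
        field_ = gaussian_filter(field_, image_params.smooth_sigma_px)
        field_ *= image_params.noise_sd / max(field_.std(), 1e-12)
    img = field_
    latclass = record_labels.get("latency_class", "Early")
    if sclera_effect != 0 and latclass == "Early":
        img = img + sclera_effect * mask.astype(float)
    return img


def synth_face_cohort(n_trials_per_cell: int, image_params: ImageParams,
                      truth: GroundTruth, seed: int = 0):
    """Difference-image set over Disruption(3) x Latency(2) cells with an
    orientation-side label; returns (stack, labels DataFrame, sclera mask)."""
    mask = default_sclera_mask(image_params)
    rows, imgs = [], []
    trial = 0
    rng = trial_rng(seed, _STREAM_FACE, 999)
    for ci, disr in enumerate(DISRUPTIONS):
        for latclass in ("Early", "Late"):
            for _ in range(n_trials_per_cell):
                labels = {"participant": 0, "trial": trial, "cell": ci,
                          "latency_class": latclass}
                imgs.append(synth_face_pair(labels, image_params, seed=seed,
                                            sclera_effect=truth.sclera_effect, mask=mask))
                rows.append((trial, disr, latclass, "L" if rng.random() < 0.5 else "R"))
                trial += 1
    labels = pd.DataFrame(rows, columns=["trial", "disruption", "latency_class", "side"])
    return np.stack(imgs), labels, mask
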