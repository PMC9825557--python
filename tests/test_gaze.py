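"""Saccade detection criteria and trial quality control."""

import numpy as np
import pytest

from amygaze import synth
from amygaze.gaze import SaccadeDetector, build_trial_table, detect_saccades
from amygaze.synth import EyeTrace


def make_trace(movements, n_ms=1800, stim_onset_ms=500, noise_sd=0.0, seed=0,
               duration_ms=40.0):
    """Trace with minimum-jerk movements given as (onset_ms, amplitude_deg)."""
    rng = np.random.default_rng(seed)
    t = np.arange(n_ms, dtype=float)
    x = rng.normal(0, noise_sd, n_ms) if noise_sd > 0 else np.zeros(n_ms)
    for onset, amp in movements:
        x += amp * synth._min_jerk((t - onset) / duration_ms)
    return EyeTrace(x_deg=x, stim_onset_ms=stim_onset_ms)


META = {"participant": 0, "block": 0, "instruction": "Yield", "disruption": "None",
        "hemifield_fear": "L"}


class TestDetectionCriteria:
    def test_amplitude_threshold_enforced(self):
        assert detect_saccades(make_trace([(700, 0.4)])) == []
        assert len(detect_saccades(make_trace([(700, 0.8)]))) == 1

    def test_duration_threshold_enforced(self):
        fast = make_trace([(700, 5.3)], duration_ms=8.0)
        det = SaccadeDetector(min_duration_ms=20.0)
        assert det.detect(fast) == []
        slow = make_trace([(700, 5.3)], duration_ms=40.0)
        assert len(det.detect(slow)) == 1

    def test_velocity_threshold_enforced(self):
        # 0.55 deg spread over 400 ms peaks below 5 deg/s
        creeping = make_trace([(700, 0.55)], duration_ms=400.0)
        assert detect_saccades(creeping) == []
        quick = make_trace([(700, 0.55)], duration_ms=60.0)
        assert len(detect_saccades(quick)) == 1

    def test_preceding_fixation_enforced(self):
        two_close = make_trace([(700, 2.0), (770, 2.0)])  # 30 ms fixation gap
        found = detect_saccades(two_close)
        assert len(found) == 1 and found[0].onset_ms < 750
        two_far = make_trace([(700, 2.0), (900, 2.0)])
        assert len(detect_saccades(two_far)) == 2

    def test_flat_noisy_trace_yields_nothing(self):
        assert detect_saccades(make_trace([], noise_sd=0.05, seed=3)) == []

    def test_onset_recovered_within_5ms(self):
        trace = make_trace([(750, 5.3)], noise_sd=0.1, seed=4)
        sac = detect_saccades(trace)
        assert len(sac) == 1
        assert abs(sac[0].onset_ms - 750.0) <= 5.0
        assert sac[0].direction == "right"
        assert sac[0].amplitude_deg == pytest.approx(5.3, abs=0.3)

    def test_tightening_criteria_never_adds_saccades(self):
        traces = [make_trace([(700, 5.3)], noise_sd=0.1, seed=s) for s in range(10)]
        base = SaccadeDetector()
        n_base = sum(len(base.detect(tr)) for tr in traces)
        for kwargs in (dict(min_velocity_deg_s=20), dict(min_amplitude_deg=1.5),
                       dict(min_fixation_ms=100), dict(min_duration_ms=35)):
            tight = SaccadeDetector(**kwargs)
            assert sum(len(tight.detect(tr)) for tr in traces) <= n_base

    def test_nonuniform_or_short_traces_rejected(self):
        with pytest.raises(ValueError, match="1 kHz"):
            detect_saccades(EyeTrace(x_deg=np.zeros(500), stim_onset_ms=100, fs=500.0))
        with pytest.raises(ValueError, match="short"):
            detect_saccades(EyeTrace(x_deg=np.zeros(20), stim_onset_ms=5))


class TestTrialScoring:
    def test_low_latency_flagged_too_fast(self):
        trace = make_trace([(590, 5.3)])  # 90 ms after stimulus
        det = SaccadeDetector()
        rec = det.score_trial(trace, det.detect(trace), META)
        assert rec["qc_flag"] == "too_fast"
        assert rec["latency_ms"] == pytest.approx(90, abs=5)

    def test_no_response_within_second_is_absent(self):
        det = SaccadeDetector()
        trace = make_trace([], n_ms=1800)
        rec = det.score_trial(trace, det.detect(trace), META)
        assert rec["qc_flag"] == "absent" and rec["choice"] == "none"
        late = make_trace([(1600, 5.3)], n_ms=2000)  # 1100 ms after stimulus
        rec = det.score_trial(late, det.detect(late), META)
        assert rec["qc_flag"] == "absent"

    def test_direction_and_hemifield_define_choice(self):
        det = SaccadeDetector()
        leftward = make_trace([(750, -5.3)])
        rec = det.score_trial(leftward, det.detect(leftward), META)  # fear on L
        assert rec["choice"] == "fear" and rec["qc_flag"] == "valid"
        rec2 = det.score_trial(leftward, det.detect(leftward),
                               dict(META, hemifield_fear="R"))
        assert rec2["choice"] == "neutral"

    def test_unstable_prestimulus_fixation_rejected(self):
        rec_meta = {"participant": 0, "block": 0, "trial": 0, "latency_ms": 250.0,
                    "direction": "right", "qc_true": "bad_fixation"}
        trace = synth.synth_eye_trace(rec_meta, seed=2)
        det = SaccadeDetector()
        rec = det.score_trial(trace, det.detect(trace), META)
        assert rec["qc_flag"] == "bad_fixation"

    def test_scoring_is_pure(self):
        det = SaccadeDetector()
        trace = make_trace([(750, 5.3)], noise_sd=0.1, seed=5)
        sacc = det.detect(trace)
        assert det.score_trial(trace, sacc, META) == det.score_trial(trace, sacc, META)

    def test_missing_metadata_raises(self):
        det = SaccadeDetector()
        trace = make_trace([(750, 5.3)])
        with pytest.raises(ValueError, match="metadata"):
            det.score_trial(trace, det.detect(trace), {"participant": 0})


class TestTrialTable:
    def test_qc_accounting_is_exact(self, truth):
        design = synth.make_design(synth.DesignSpec(n_participants=2,
                                                    trials_per_block=10, seed=31))
        table = synth.inject_qc_defects(
            synth.simulate_latency_cohort(design, truth, seed=31),
            frac_bad_fixation=0.1, frac_absent=0.1, frac_too_fast=0.05, seed=31)
        traces = [synth.synth_eye_trace(r, seed=31) for _, r in table.iterrows()]
        scored, summary = build_trial_table(traces, table)
        assert summary["remaining"] == summary["acquired"] - summary["rejected"]
        assert summary["acquired"] == len(table)
        truth_counts = table["qc_true"].value_counts().to_dict()
        got_counts = scored["qc_flag"].value_counts().to_dict()
        assert got_counts == truth_counts
        assert (scored["qc_flag"].to_numpy() == table["qc_true"].to_numpy()).all()

    def test_duplicate_trial_ids_raise(self, truth):
        design = synth.make_design(synth.DesignSpec(n_participants=1,
                                                    trials_per_block=3, seed=1))
        table = synth.simulate_latency_cohort(design, truth, seed=1)
        table["trial"] = 0
        traces = [synth.synth_eye_trace(r, seed=1) for _, r in table.iterrows()]
        with pytest.raises(ValueError, match="duplicate"):
            build_trial_table(traces[:6], table.head(6))
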