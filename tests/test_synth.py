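"""Synthetic experiment generator: design, behaviour, traces, LFP, images."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binomtest

from amygaze import synth
from amygaze.synth import DesignSpec, ImageParams


class TestDesign:
    def test_trial_count_and_levels(self):
        design = synth.make_design(DesignSpec(n_participants=1, blocks_per_condition=1,
                                              trials_per_block=50, seed=0))
        assert len(design) == 50 * 6  # 2 instructions x 3 disruptions
        assert set(design["instruction"]) == set(synth.INSTRUCTIONS)
        assert set(design["disruption"]) == set(synth.DISRUPTIONS)
        one_block = design[design["block"] == 0]
        assert len(one_block) == 50
        assert one_block["instruction"].nunique() == 1

    def test_fixation_jitter_within_printed_range(self):
        design = synth.make_design(DesignSpec(n_participants=2, seed=1))
        assert design["fixation_ms"].between(1500, 2000).all()

    def test_same_seed_reproduces_exactly(self):
        a = synth.make_design(DesignSpec(seed=5))
        b = synth.make_design(DesignSpec(seed=5))
        pd.testing.assert_frame_equal(a, b)
        c = synth.make_design(DesignSpec(seed=6))
        assert not a["hemifield_fear"].equals(c["hemifield_fear"])

    def test_fearful_side_marginally_balanced(self):
        design = synth.make_design(DesignSpec(n_participants=6, seed=2))
        k = int((design["hemifield_fear"] == "L").sum())
        assert binomtest(k, len(design), 0.5).pvalue > 0.01

    @pytest.mark.parametrize("kwargs", [
        dict(trials_per_block=0), dict(jitter_ms=-1), dict(n_participants=0),
        dict(hemifield_levels=("L", "L")),
    ])
    def test_invalid_specs_raise(self, kwargs):
        with pytest.raises(ValueError):
            DesignSpec(**kwargs)


class TestBehaviour:
    def test_record_count_conserved_and_fields_complete(self, behaviour_table, small_design):
        assert len(behaviour_table) == len(small_design)
        assert set(behaviour_table["choice"]) <= {"fear", "neutral"}
        assert behaviour_table["latency_ms"].notna().all()

    def test_latencies_exceed_subject_nondecision_time(self, behaviour_table, truth):
        devs = synth.subject_deviations(truth, 2, 7)
        for (p, instr, disr, hemi), grp in behaviour_table.groupby(
                ["participant", "instruction", "disruption", "hemifield_fear"]):
            t0 = truth.wiener[(instr, disr, hemi)].t0 * np.exp(devs["t0"][p])
            assert (grp["latency_ms"] > t0 * 1000).all()

    def test_symmetric_truth_gives_unbiased_choice(self, symmetric_truth):
        design = synth.make_design(DesignSpec(n_participants=2, trials_per_block=420, seed=3))
        beh = synth.simulate_behaviour(design, symmetric_truth, seed=3)
        k = int((beh["choice"] == "fear").sum())
        assert binomtest(k, len(beh), 0.5).pvalue > 0.01
        k_side = int((beh["direction"] == "left").sum())
        assert binomtest(k_side, len(beh), 0.5).pvalue > 0.01

    def test_lowered_start_point_reduces_fear_choice(self, truth):
        design = synth.make_design(DesignSpec(n_participants=4, trials_per_block=170, seed=4))
        beh = synth.simulate_behaviour(design, truth, seed=4)
        yield_ = beh[beh["instruction"] == "Yield"]
        rate = yield_.groupby("disruption")["choice"].apply(lambda c: (c == "fear").mean())
        assert rate["Contra"] < rate["Ipsi"]

    def test_determinism(self, small_design, truth):
        a = synth.simulate_behaviour(small_design, truth, seed=42)
        b = synth.simulate_behaviour(small_design, truth, seed=42)
        pd.testing.assert_frame_equal(a, b)

    def test_missing_condition_parameters_raise(self, small_design):
        sparse = synth.GroundTruth(wiener={})
        with pytest.raises(ValueError, match="lacks parameters"):
            synth.simulate_behaviour(small_design, sparse, seed=0)


class TestEyeTraces:
    record = {"participant": 0, "block": 0, "trial": 0, "latency_ms": 250.0,
              "direction": "right", "qc_true": "valid"}

    def test_absent_trial_has_no_displacement(self):
        rec = dict(self.record, qc_true="absent")
        tr = synth.synth_eye_trace(rec, noise_sd_deg=0.05, seed=1)
        assert np.abs(tr.x_deg).max() < 0.5

    def test_noiseless_trace_is_exact_sigmoid(self):
        tr = synth.synth_eye_trace(self.record, noise_sd_deg=0.0, seed=1)
        t = tr.times_ms - tr.stim_onset_ms
        expected = 5.3 * synth._min_jerk((t - 250.0) / 40.0)
        np.testing.assert_allclose(tr.x_deg, expected)
        assert tr.truth_onset_ms == 250.0

    def test_deterministic_given_seed(self):
        a = synth.synth_eye_trace(self.record, seed=9)
        b = synth.synth_eye_trace(self.record, seed=9)
        np.testing.assert_array_equal(a.x_deg, b.x_deg)

    def test_negative_noise_raises(self):
        with pytest.raises(ValueError):
            synth.synth_eye_trace(self.record, noise_sd_deg=-0.1)


class TestLfp:
    def test_epoch_spans_six_seconds(self, truth):
        ep = synth.synth_lfp_epoch({"recording_side": "Contra", "emotion": "fear"},
                                   truth, seed=0, amplitude=0.1)
        assert len(ep.samples) == int(6 * 1024)
        assert ep.times[0] == pytest.approx(-2.0)

    @pytest.mark.parametrize("side,emotion,expected", [
        ("Contra", "fear", True), ("Contra", "neutral", False),
        ("Ipsi", "fear", False), ("Ipsi", "neutral", True),
    ])
    def test_contralateral_orientation_coding(self, side, emotion, expected, truth):
        ep = synth.synth_lfp_epoch({"recording_side": side, "emotion": emotion},
                                   truth, seed=0, amplitude=0.0)
        assert ep.contralateral_orientation is expected

    def test_burst_raises_power_only_on_contralateral_trials(self, truth):
        sel = slice(int((2 + 0.03) * 1024), int((2 + 0.13) * 1024))
        burst_var, none_var = [], []
        for i in range(30):
            on = synth.synth_lfp_epoch({"trial": i, "recording_side": "Contra",
                                        "emotion": "fear"}, truth, seed=2)
            off = synth.synth_lfp_epoch({"trial": i, "recording_side": "Contra",
                                         "emotion": "neutral"}, truth, seed=2)
            burst_var.append(np.var(on.samples[sel]))
            none_var.append(np.var(off.samples[sel]))
        assert np.mean(burst_var) > np.mean(none_var)

    def test_zero_amplitude_matches_background_statistics(self, truth):
        quiet = dataclasses.replace(truth, lfp_burst=dataclasses.replace(
            truth.lfp_burst, amplitude_pct=0.0))
        ep = synth.synth_lfp_epoch({"recording_side": "Contra", "emotion": "fear"},
                                   quiet, seed=3)
        ep2 = synth.synth_lfp_epoch({"recording_side": "Contra", "emotion": "neutral"},
                                    quiet, seed=3)
        assert np.var(ep.samples) == pytest.approx(np.var(ep2.samples), rel=0.5)


class TestFaceImages:
    params = ImageParams(height=32, width=32)

    def test_zero_effect_gives_zero_mean_noise(self):
        imgs = [synth.synth_face_pair({"trial": i}, self.params, seed=1, sclera_effect=0.0)
                for i in range(40)]
        assert abs(np.mean(imgs)) < 0.05

    def test_early_trials_carry_scleral_signal(self):
        mask = synth.default_sclera_mask(self.params)
        img = synth.synth_face_pair({"trial": 0, "latency_class": "Early"},
                                    self.params, seed=2, sclera_effect=3.0)
        late = synth.synth_face_pair({"trial": 0, "latency_class": "Late"},
                                     self.params, seed=2, sclera_effect=3.0)
        assert img[mask].mean() - img[~mask].mean() > 2.0
        assert abs(late[mask].mean() - late[~mask].mean()) < 1.0

    def test_same_seed_identical_image(self):
        a = synth.synth_face_pair({"trial": 3}, self.params, seed=4)
        b = synth.synth_face_pair({"trial": 3}, self.params, seed=4)
        np.testing.assert_array_equal(a, b)

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError, match="mask"):
            synth.synth_face_pair({}, self.params, mask=np.zeros((32, 32), bool))

    def test_sclera_mask_sits_in_upper_face(self):
        mask = synth.default_sclera_mask(self.params)
        upper = synth.upper_face_mask(self.params)
        assert mask.any()
        assert not (mask & ~upper).any()
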