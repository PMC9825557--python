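"""Horizontal saccade detection at 1 kHz and trial quality control.

Saccades are detected on the Savitzky-Golay-smoothed velocity trace and
must jointly satisfy four criteria: initial velocity >= 5 deg/s, amplitude
>= 0.5 deg, preceding fixation >= 50 ms, duration >= 20 ms.  Trials are
scored by their first post-stimulus saccade and rejected when fixation was
inadequate in the 100 ms before stimulus onset, latency was implausibly
low (< 100 ms), or no response arrived within 1000 ms (absent).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter
from sklearn.base import BaseEstimator

from .synth import EyeTrace

__all__ = [
    "Saccade",
    "SaccadeDetector",
    "detect_saccades",
    "score_trial",
    "build_trial_table",
]


@dataclass(frozen=True)
class Saccade:
    onset_ms: float
    offset_ms: float
    amplitude_deg: float
    peak_velocity_deg_s: float
    direction: str  # 'left' | 'right'

    def __post_init__(self):
        if self.offset_ms <= self.onset_ms:
            raise ValueError("saccade offset must follow onset")
        if self.amplitude_deg < 0:
            raise ValueError("amplitude must be >= 0")

    @property
    def duration_ms(self) -> float:
        return self.offset_ms - self.onset_ms


class SaccadeDetector(BaseEstimator):
    """Threshold-crossing saccade detector with the study's QC rules.

    Parameters mirror the printed detection criteria; the velocity trace is
    obtained by Savitzky-Golay differentiation (window 11 samples, order 2).
    The preceding-fixation criterion is operationalised as: no sample in the
    ``min_fixation_ms`` window before onset displaced more than
    ``min_amplitude_deg`` from the onset position.  Pre-stimulus fixation
    adequacy (trial QC) requires the 100 ms window before stimulus onset to
    have SD <= ``fixation_sd_deg`` and no sample beyond
    ``fixation_range_deg`` from centre.
    """

    def __init__(self, min_velocity_deg_s: float = 5.0, min_amplitude_deg: float = 0.5,
                 min_fixation_ms: float = 50.0, min_duration_ms: float = 20.0,
                 sg_window: int = 11, sg_order: int = 2,
                 fixation_sd_deg: float = 0.5, fixation_range_deg: float = 1.0,
                 max_latency_ms: float = 1000.0, min_latency_ms: float = 100.0):
        self.min_velocity_deg_s = min_velocity_deg_s
        self.min_amplitude_deg = min_amplitude_deg
        self.min_fixation_ms = min_fixation_ms
        self.min_duration_ms = min_duration_ms
        self.sg_window = sg_window
        self.sg_order = sg_order
        self.fixation_sd_deg = fixation_sd_deg
        self.fixation_range_deg = fixation_range_deg
        self.max_latency_ms = max_latency_ms
        self.min_latency_ms = min_latency_ms

    def fit(self, X=None, y=None):
        """No-op: the detector has no data-dependent state."""
        return self

    # -- detection ---------------------------------------------------------

    def velocity(self, trace: EyeTrace) -> np.ndarray:
        """Smoothed velocity in deg/s."""
        self._check_trace(trace)
        return savgol_filter(trace.x_deg, self.sg_window, self.sg_order,
                             deriv=1, delta=1.0 / trace.fs)

    def _check_trace(self, trace: EyeTrace) -> None:
        if abs(trace.fs - 1000.0) > 1e-6:
            raise ValueError(f"trace must be uniformly sampled at 1 kHz, got fs={trace.fs}")
        if len(trace.x_deg) < max(self.sg_window, 100):
            raise ValueError("trace shorter than the minimum analysable window")
        if not (0 <= trace.stim_onset_ms <= trace.times_ms[-1]):
            raise ValueError("stimulus onset outside the trace")

    def detect(self, trace: EyeTrace) -> list:
        """All saccades satisfying the four criteria, ordered by onset."""
        x = np.asarray(trace.x_deg, dtype=float)
        v = self.velocity(trace)
        ms = 1000.0 / trace.fs
        supra = np.abs(v) >= self.min_velocity_deg_s
        saccades = []
        # contiguous suprathreshold runs are candidate movements
        starts = np.flatnonzero(supra & ~np.roll(supra, 1))
        ends = np.flatnonzero(supra & ~np.roll(supra, -1))
        if supra[0]:
            starts = np.concatenate([[0], starts[starts != 0]])
        if supra[-1]:
            ends = np.concatenate([ends[ends != len(supra) - 1], [len(supra) - 1]])
        for i0, i1 in zip(starts, ends):
            # trim the run to the sign-consistent segment around its velocity
            # peak: noise excursions merged onto a movement have random sign
            ipk = i0 + int(np.argmax(np.abs(v[i0:i1 + 1])))
            s = np.sign(v[ipk])
            j0 = ipk
            while j0 > i0 and np.sign(v[j0 - 1]) == s:
                j0 -= 1
            j1 = ipk
            while j1 < i1 and np.sign(v[j1 + 1]) == s:
                j1 += 1
            onset = max(j0 - 1, 0)       # last sample below threshold
            offset = min(j1 + 1, len(x) - 1)  # first sample back below
            duration = (offset - onset) * ms
            if duration < self.min_duration_ms:
                continue
            amplitude = abs(x[offset] - x[onset])
            if amplitude < self.min_amplitude_deg:
                continue
            nfix = int(round(self.min_fixation_ms / ms))
            w0 = onset - nfix
            if w0 < 0:
                continue  # cannot verify the preceding fixation
            w = x[w0:onset]
            if np.any(np.abs(w - np.median(w)) > self.min_amplitude_deg):
                continue
            peak = float(np.abs(v[ipk]))
            direction = "right" if x[offset] - x[onset] > 0 else "left"
            saccades.append(Saccade(onset_ms=onset * ms, offset_ms=offset * ms,
                                    amplitude_deg=float(amplitude),
                                    peak_velocity_deg_s=peak, direction=direction))
        return saccades

    # -- trial scoring -----------------------------------------------------

    def adequate_fixation(self, trace: EyeTrace) -> bool:
        """Fixation stability in the 100 ms before stimulus onset."""
        i_stim = int(round(trace.stim_onset_ms * trace.fs / 1000.0))
        w = trace.x_deg[max(i_stim - 100, 0):i_stim]
        if len(w) == 0:
            return False
        return bool(w.std() <= self.fixation_sd_deg
                    and np.all(np.abs(w) <= self.fixation_range_deg))

    def score_trial(self, trace: EyeTrace, saccades: list, trial_meta) -> dict:
        """Score one trial from its detected saccades and condition labels.

        The first saccade with onset after stimulus onset defines latency
        and direction; direction plus the fearful face's hemifield define
        the choice.  QC codes: bad_fixation, too_fast (< 100 ms), absent
        (none within 1000 ms), else valid.
        """
        required = ("participant", "block", "instruction", "disruption", "hemifield_fear")
        try:
            meta = {k: trial_meta[k] for k in required}
        except (KeyError, TypeError) as err:
            raise ValueError(f"missing trial metadata: {err}") from err
        rec = dict(meta, choice="none", latency_ms=np.nan, qc_flag="valid")
        if not self.adequate_fixation(trace):
            rec["qc_flag"] = "bad_fixation"
            return rec
        post = [s for s in saccades if s.onset_ms > trace.stim_onset_ms]
        if not post:
            rec["qc_flag"] = "absent"
            return rec
        first = post[0]
        latency = first.onset_ms - trace.stim_onset_ms
        if latency > self.max_latency_ms:
            rec["qc_flag"] = "absent"
            return rec
        rec["latency_ms"] = latency
        toward_fear = (first.direction == "right") == (meta["hemifield_fear"] == "R")
        rec["choice"] = "fear" if toward_fear else "neutral"
        if latency < self.min_latency_ms:
            rec["qc_flag"] = "too_fast"
        return rec

    def build_trial_table(self, traces, meta: pd.DataFrame):
        """Score every (trace, metadata) pair into the analysable trial table.

        Returns ``(table, qc_summary)`` where the summary accounts exactly:
        remaining = acquired - rejected, with per-code rejection counts.
        """
        ids = list(zip(meta["participant"], meta["block"], meta.get("trial", range(len(meta)))))
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate trial identifiers")
        if len(traces) != len(meta):
            raise ValueError("one trace per trial required")
        rows = []
        for trace, (_, m) in zip(traces, meta.iterrows()):
            rows.append(self.score_trial(trace, self.detect(trace), m))
        table = pd.DataFrame(rows)
        table.insert(2, "trial", meta.get("trial", pd.Series(range(len(meta)))).to_numpy())
        counts = table["qc_flag"].value_counts().to_dict()
        acquired = len(table)
        rejected = int(sum(v for k, v in counts.items() if k != "valid"))
        summary = {
            "acquired": acquired,
            "rejected": rejected,
            "remaining": acquired - rejected,
            "by_code": {k: int(v) for k, v in counts.items() if k != "valid"},
        }
        return table, summary


# -- thin functional wrappers ----------------------------------------------

def detect_saccades(trace: EyeTrace, criteria: dict | None = None) -> list:
    return SaccadeDetector(**(criteria or {})).detect(trace)


def score_trial(trace: EyeTrace, saccades: list, trial_meta, criteria: dict | None = None) -> dict:
    return SaccadeDetector(**(criteria or {})).score_trial(trace, saccades, trial_meta)


def build_trial_table(traces, meta: pd.DataFrame, criteria: dict | None = None):
    return SaccadeDetector(**(criteria or {})).build_trial_table(traces, meta)
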