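"""File interchange: trial tables (CSV), recordings (HDF5), images (PNG),
QC summaries and contrast reports (JSON), experiment configs (YAML)."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .synth import DesignSpec, EyeTrace, LfpEpoch, default_ground_truth

TRIAL_COLUMNS = ["participant", "block", "trial", "instruction", "disruption",
                 "hemifield_fear", "choice", "latency_ms", "qc_flag"]

__all__ = [
    "read_trial_table",
    "write_trial_table",
    "write_qc_summary",
    "write_traces_h5",
    "read_traces_h5",
    "write_epochs_h5",
    "read_epochs_h5",
    "write_image_png",
    "write_contrast_report",
    "load_experiment_config",
]


def write_trial_table(table: pd.DataFrame, path) -> None:
    cols = [c for c in TRIAL_COLUMNS if c in table.columns]
    extra = [c for c in table.columns if c not in cols]
    table[cols + extra].to_csv(path, index=False)


def read_trial_table(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = {"participant", "instruction", "disruption", "hemifield_fear"} - set(table.columns)
    if missing:
        raise ValueError(f"trial table lacks columns {sorted(missing)}")
    return table


def write_qc_summary(summary: dict, path) -> None:
    Path(path).write_text(json.dumps(summary, indent=2) + "\n")


def write_traces_h5(traces, meta: pd.DataFrame, path) -> None:
    """One group per trial keyed participant/block/trial."""
    with h5py.File(path, "w") as f:
        for trace, (_, m) in zip(traces, meta.iterrows()):
            g = f.create_group(f"p{int(m['participant'])}/b{int(m['block'])}/t{int(m['trial'])}")
            g.create_dataset("x_deg", data=trace.x_deg)
            g.attrs["stim_onset_ms"] = trace.stim_onset_ms
            g.attrs["fs"] = trace.fs


def read_traces_h5(path):
    out = []
    with h5py.File(path, "r") as f:
        def visit(name, obj):
            if isinstance(obj, h5py.Group) and "x_deg" in obj:
                out.append(EyeTrace(x_deg=obj["x_deg"][()],
                                    stim_onset_ms=float(obj.attrs["stim_onset_ms"]),
                                    fs=float(obj.attrs["fs"])))
        f.visititems(visit)
    return out


def write_epochs_h5(epochs, path) -> None:
    with h5py.File(path, "w") as f:
        for i, ep in enumerate(epochs):
            g = f.create_group(f"epoch{i:05d}")
            g.create_dataset("samples", data=ep.samples)
            for k in ("fs", "tmin", "trigger", "recording_side", "emotion", "participant"):
                g.attrs[k] = getattr(ep, k)


def read_epochs_h5(path):
    out = []
    with h5py.File(path, "r") as f:
        for name in sorted(f):
            g = f[name]
            out.append(LfpEpoch(samples=g["samples"][()], fs=float(g.attrs["fs"]),
                                tmin=float(g.attrs["tmin"]), trigger=str(g.attrs["trigger"]),
                                recording_side=str(g.attrs["recording_side"]),
                                emotion=str(g.attrs["emotion"]),
                                participant=int(g.attrs["participant"])))
    return out


def write_image_png(img: np.ndarray, path) -> None:
    from PIL import Image

    lo, hi = np.nanmin(img), np.nanmax(img)
    scaled = np.zeros_like(img) if hi == lo else (img - lo) / (hi - lo)
    Image.fromarray((255 * scaled).astype(np.uint8)).save(path)


def write_contrast_report(report: dict, path) -> None:
    """Nested {model: {contrast: ContrastResult}} to JSON."""
    out = {}
    for model, contrasts in report.items():
        out[model] = {
            name: {"mean": c.mean, "ci_low": c.ci_low, "ci_high": c.ci_high,
                   "p_effect": c.p_effect, "scale": c.scale}
            for name, c in contrasts.items()
        }
    Path(path).write_text(json.dumps(out, indent=2) + "\n")


def read_lfp_edf(path, channels=None):
    """Load contacts from an EDF recording as ``(array, sampling rate)``.

    ``channels``: names of the two most distal contacts (default: first
    two).  Requires mne.
    """
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    picks = channels if channels is not None else raw.ch_names[:2]
    data = raw.get_data(picks=picks)
    return data, float(raw.info["sfreq"])


def load_experiment_config(path):
    """YAML with optional ``design`` (DesignSpec fields) and ``effects``
    (default_ground_truth keyword arguments) sections."""
    cfg = yaml.safe_load(Path(path).read_text()) or {}
    design = DesignSpec(**(cfg.get("design") or {}))
    truth = default_ground_truth(**(cfg.get("effects") or {}))
    return design, truth
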