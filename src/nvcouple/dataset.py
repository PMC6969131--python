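"""Dataset container: one directory per cohort.

Layout::

    <root>/manifest.json
    <root>/probe_layout.json
    <root>/<subject>/recording.h5     # fNIRS intensities + ground truth, EEG
    <root>/<subject>/events.tsv       # stimulus schedule (BIDS-style)
    <root>/<subject>/params.json      # generative parameters

HDF5 datasets are written without timestamps so that re-running with the
same master seed reproduces the dataset byte-for-byte.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import h5py
import numpy as np

from .paradigm import StimulusSchedule, read_events, write_events


def _write_ds(grp, name, data):
    grp.create_dataset(name, data=data, track_times=False)


def _as_str(x) -> str:
    return x.decode() if isinstance(x, bytes) else str(x)


def write_subject(root, subject_id, params, schedule, rec_nirs=None, rec_eeg=None) -> Path:
    """Write one subject's recordings, schedule and parameters."""
    sub = Path(root) / subject_id
    sub.mkdir(parents=True, exist_ok=True)
    write_events(schedule, sub / "events.tsv")
    with open(sub / "params.json", "w") as fh:
        json.dump(asdict(params), fh, indent=1, sort_keys=True)
    with h5py.File(sub / "recording.h5", "w", track_order=False) as f:
        if rec_nirs is not None:
            g = f.create_group("nirs")
            g.attrs["sampling_rate_hz"] = rec_nirs.sampling_rate_hz
            g.attrs["t_start_s"] = rec_nirs.t_start_s
            g.attrs["wavelengths_nm"] = list(rec_nirs.wavelengths_nm)
            g.attrs["channel_ids"] = [c.encode() for c in rec_nirs.channel_ids]
            _write_ds(g, "intensity", rec_nirs.intensity)
            if rec_nirs.ground_truth_hbo_uM is not None:
                _write_ds(g, "ground_truth_hbo_uM", rec_nirs.ground_truth_hbo_uM)
                _write_ds(g, "ground_truth_hb_uM", rec_nirs.ground_truth_hb_uM)
        if rec_eeg is not None:
            g = f.create_group("eeg")
            g.attrs["sampling_rate_hz"] = rec_eeg.sampling_rate_hz
            g.attrs["t_start_s"] = rec_eeg.t_start_s
            g.attrs["labels"] = [c.encode() for c in rec_eeg.labels]
            _write_ds(g, "voltage", np.asarray(rec_eeg.voltage, np.float32))
    return sub


def read_subject(root, subject_id):
    """Read one subject back: (params dict, schedule, nirs or None, eeg or None)."""
    from .synthetic import RawEEGRecording, RawIntensityRecording

    sub = Path(root) / subject_id
    with open(sub / "params.json") as fh:
        params = json.load(fh)
    schedule = read_events(sub / "events.tsv")
    rec_nirs = rec_eeg = None
    with h5py.File(sub / "recording.h5", "r") as f:
        if "nirs" in f:
            g = f["nirs"]
            rec_nirs = RawIntensityRecording(
                sampling_rate_hz=float(g.attrs["sampling_rate_hz"]),
                wavelengths_nm=tuple(int(w) for w in g.attrs["wavelengths_nm"]),
                channel_ids=[_as_str(c) for c in g.attrs["channel_ids"]],
                intensity=g["intensity"][()],
                t_start_s=float(g.attrs["t_start_s"]),
                ground_truth_hbo_uM=g["ground_truth_hbo_uM"][()]
                if "ground_truth_hbo_uM" in g
                else None,
                ground_truth_hb_uM=g["ground_truth_hb_uM"][()]
                if "ground_truth_hb_uM" in g
                else None,
            )
        if "eeg" in f:
            g = f["eeg"]
            rec_eeg = RawEEGRecording(
                sampling_rate_hz=float(g.attrs["sampling_rate_hz"]),
                labels=tuple(_as_str(c) for c in g.attrs["labels"]),
                voltage=np.asarray(g["voltage"][()], float),
                t_start_s=float(g.attrs["t_start_s"]),
            )
    return params, schedule, rec_nirs, rec_eeg


def write_manifest(root, manifest: dict) -> None:
    with open(Path(root) / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)


def read_manifest(root) -> dict:
    with open(Path(root) / "manifest.json") as fh:
        manifest = json.load(fh)
    for rec in manifest["subjects"]:
        if not (Path(root) / rec["path"]).exists():
            raise FileNotFoundError(f"missing subject directory: {rec['path']}")
    return manifest
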