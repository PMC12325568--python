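"""Persistence: HDF5 recording container with JSON sidecar, event TSVs,
CSV spectra, and an EDF/BDF read path for real BioSemi-family data."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .montage import Montage, default_montage
from .simulate import Recording, ResponseSpec

__all__ = ["save_recording", "load_recording", "read_raw_edf",
           "spectrum_to_frame", "save_spectrum_csv"]


def save_recording(rec: Recording, path) -> Path:
    """Write a recording to ``<path>.h5`` plus a ``<path>.json`` sidecar.

    The HDF5 file holds the channels x samples array; the sidecar carries
    everything needed to reconstruct provenance: sampling rate, channel
    labels, events, condition labels, the ground-truth response parameters
    and the seed.
    """
    import h5py

    path = Path(path)
    h5_path = path.with_suffix(".h5")
    with h5py.File(h5_path, "w") as f:
        f.create_dataset("data_uv", data=rec.data, compression="gzip")
        f.attrs["fs_hz"] = rec.fs_hz
    sidecar = {
        "fs_hz": rec.fs_hz,
        "channel_labels": rec.montage.labels,
        "events": [[t, d, lab] for (t, d, lab) in rec.events],
        "labels": rec.labels,
        "bad_channels": rec.bad_channels,
        "seed": rec.seed,
        "ground_truth": asdict(rec.ground_truth) if rec.ground_truth else None,
    }
    h5_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return h5_path


def load_recording(path, montage: Montage | None = None) -> Recording:
    import h5py

    h5_path = Path(path).with_suffix(".h5")
    sidecar = json.loads(h5_path.with_suffix(".json").read_text())
    with h5py.File(h5_path, "r") as f:
        data = f["data_uv"][()]
        fs = float(f.attrs["fs_hz"])
    montage = montage or default_montage()
    if sidecar["channel_labels"] != montage.labels:
        raise ValueError("sidecar channel labels do not match the montage")
    gt = sidecar.get("ground_truth")
    if gt is not None:
        gt["oddball_harmonic_weights"] = tuple(gt["oddball_harmonic_weights"])
        gt = ResponseSpec(**gt)
    return Recording(data=data, fs_hz=fs, montage=montage,
                     events=[tuple(e) for e in sidecar["events"]],
                     ground_truth=gt, seed=sidecar.get("seed"),
                     labels=sidecar.get("labels", {}),
                     bad_channels=sidecar.get("bad_channels", []))


def read_raw_edf(path, montage: Montage | None = None) -> Recording:
    """Read an EDF/BDF (BioSemi-family) file into a Recording (data in uV).

    Channels not present in the 64-channel montage (EXG, status...) are
    dropped; annotations become events.
    """
    import mne

    path = str(path)
    reader = mne.io.read_raw_bdf if path.lower().endswith(".bdf") else mne.io.read_raw_edf
    raw = reader(path, preload=True, verbose="ERROR")
    montage = montage or default_montage()
    keep = [ch for ch in raw.ch_names if ch in set(montage.labels)]
    raw.pick(keep)
    if raw.ch_names != montage.labels:
        raise ValueError("EDF channels do not cover the 64-channel montage "
                         f"(got {len(raw.ch_names)})")
    data = raw.get_data() * 1e6  # volts -> microvolts
    events = [(float(on), float(du), str(desc))
              for on, du, desc in zip(raw.annotations.onset,
                                      raw.annotations.duration,
                                      raw.annotations.description)]
    return Recording(data=data, fs_hz=float(raw.info["sfreq"]), montage=montage,
                     events=events, labels={"source": path})


def spectrum_to_frame(spec) -> pd.DataFrame:
    """Wide bin_hz x channel DataFrame of an amplitude or SNR spectrum."""
    cols = spec.channel_labels or [f"ch{i}" for i in range(spec.amplitudes.shape[0])]
    return pd.DataFrame(spec.amplitudes.T, columns=cols,
                        index=pd.Index(spec.frequencies_hz, name="bin_hz"))


def save_spectrum_csv(spec, path) -> None:
    spectrum_to_frame(spec).to_csv(path)
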