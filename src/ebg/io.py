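"""Readers and writers for recordings, epochs, TFR maps and reports.

Synthetic recordings are written as BrainVision (.vhdr/.vmrk/.eeg,
IEEE float32 multiplexed) — readable by any EEG toolchain — with events
also exported as a BIDS-style TSV (onset_sample, condition, trial_id).
EDF+ and BrainVision files are read back through MNE.  Epoch sets, lead
fields and time-frequency maps are stored in HDF5 with their axes.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .headmodel import LeadField
from .preproc import EpochSet
from .simulate import GroundTruth, RawRecording
from .timefreq import TimeFrequencyMap

__all__ = [
    "write_brainvision", "read_raw", "write_events_tsv", "read_events_tsv",
    "save_epochs_h5", "load_epochs_h5", "save_tfr_h5", "load_tfr_h5",
    "save_ground_truth", "save_leadfield_h5", "load_leadfield_h5",
]


def write_brainvision(recording: RawRecording, basename) -> Path:
    """Write .vhdr/.vmrk/.eeg; returns the header path.

    Data are stored as multiplexed IEEE float32 microvolts (unit
    resolution), stimulus markers at the event onsets.
    """
    base = Path(basename)
    base.parent.mkdir(parents=True, exist_ok=True)
    stem = base.name
    vhdr, vmrk, eeg = (base.with_suffix(s) for s in (".vhdr", ".vmrk", ".eeg"))

    n_ch = recording.n_channels
    with open(vhdr, "w", newline="\r\n") as fh:
        fh.write("Brain Vision Data Exchange Header File Version 1.0\n\n")
        fh.write("[Common Infos]\n")
        fh.write(f"DataFile={stem}.eeg\nMarkerFile={stem}.vmrk\n")
        fh.write("DataFormat=BINARY\nDataOrientation=MULTIPLEXED\n")
        fh.write(f"NumberOfChannels={n_ch}\n")
        fh.write(f"SamplingInterval={1e6 / recording.fs:.6f}\n\n")
        fh.write("[Binary Infos]\nBinaryFormat=IEEE_FLOAT_32\n\n")
        fh.write("[Channel Infos]\n")
        for i, name in enumerate(recording.ch_names, start=1):
            fh.write(f"Ch{i}={name},,1,µV\n")
    with open(vmrk, "w", newline="\r\n") as fh:
        fh.write("Brain Vision Data Exchange Marker File, Version 1.0\n\n")
        fh.write("[Common Infos]\n")
        fh.write(f"DataFile={stem}.eeg\n\n")
        fh.write("[Marker Infos]\n")
        fh.write("Mk1=New Segment,,1,1,0,00000000000000000000\n")
        for j, (_, ev) in enumerate(recording.events.iterrows(), start=2):
            # BrainVision marker positions are 1-based samples
            fh.write(f"Mk{j}=Stimulus,{ev['condition']},"
                     f"{int(ev['onset_sample']) + 1},1,0\n")
    recording.data.T.astype("<f4").tofile(eeg)
    return vhdr


def read_raw(path) -> RawRecording:
    """Read a BrainVision (.vhdr) or EDF (.edf) recording via MNE."""
    import warnings

    import mne

    path = Path(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if path.suffix.lower() == ".vhdr":
            raw = mne.io.read_raw_brainvision(path, preload=True, verbose="error")
        elif path.suffix.lower() == ".edf":
            raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        else:
            raise ValueError(f"unsupported recording format: {path.suffix}")
        events, event_id = mne.events_from_annotations(raw, verbose="error")
    inv = {v: k for k, v in event_id.items()}
    rows = []
    tid = 0
    for onset, _, code in events:
        name = inv[code].split("/")[-1]
        if name.startswith("Stimulus"):
            name = name.split(",")[-1]
        if name in ("Odor", "Air"):
            rows.append((int(onset), name, tid))
            tid += 1
    ev = pd.DataFrame(rows, columns=["onset_sample", "condition", "trial_id"])
    data = raw.get_data() * 1e6  # MNE volts -> microvolts
    return RawRecording(data, float(raw.info["sfreq"]),
                        tuple(raw.ch_names), ev)


def write_events_tsv(events: pd.DataFrame, path) -> None:
    events.to_csv(path, sep="\t", index=False)


def read_events_tsv(path) -> pd.DataFrame:
    ev = pd.read_csv(path, sep="\t")
    need = {"onset_sample", "condition", "trial_id"}
    if not need.issubset(ev.columns):
        raise ValueError(f"events TSV must have columns {sorted(need)}")
    return ev


def _write_str_array(grp, name, values) -> None:
    grp.create_dataset(name, data=np.array([str(v) for v in values],
                                           dtype=h5py.string_dtype()))


def save_epochs_h5(epochs: EpochSet, path) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("data", data=epochs.data, compression="gzip")
        fh.create_dataset("times", data=epochs.times)
        fh.attrs["fs"] = epochs.fs
        _write_str_array(fh, "ch_names", epochs.ch_names)
        _write_str_array(fh, "labels", epochs.labels)
        fh.create_dataset("trial_ids", data=epochs.trial_ids)
        fh.create_dataset("reject_mask", data=epochs.reject_mask)
        _write_str_array(fh, "reject_reason", epochs.reject_reason)


def load_epochs_h5(path) -> EpochSet:
    with h5py.File(path, "r") as fh:
        return EpochSet(
            fh["data"][()], fh["times"][()], float(fh.attrs["fs"]),
            tuple(s.decode() for s in fh["ch_names"][()]),
            np.array([s.decode() for s in fh["labels"][()]], dtype=object),
            fh["trial_ids"][()], fh["reject_mask"][()].astype(bool),
            np.array([s.decode() for s in fh["reject_reason"][()]],
                     dtype=object))


def save_tfr_h5(tfr: TimeFrequencyMap, path) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("power", data=tfr.power, compression="gzip")
        fh.create_dataset("freqs", data=tfr.freqs)
        fh.create_dataset("times", data=tfr.times)
        _write_str_array(fh, "ch_names", tfr.ch_names)
        _write_str_array(fh, "labels", tfr.labels)
        fh.attrs["normalization"] = tfr.normalization
        fh.attrs["fs"] = tfr.fs
        if tfr.coefficients is not None:
            fh.create_dataset("coefficients", data=tfr.coefficients,
                              compression="gzip")


def load_tfr_h5(path) -> TimeFrequencyMap:
    with h5py.File(path, "r") as fh:
        coefs = fh["coefficients"][()] if "coefficients" in fh else None
        return TimeFrequencyMap(
            fh["power"][()], fh["freqs"][()], fh["times"][()],
            tuple(s.decode() for s in fh["ch_names"][()]),
            np.array([s.decode() for s in fh["labels"][()]], dtype=object),
            str(fh.attrs["normalization"]), coefs, float(fh.attrs["fs"]))


def save_ground_truth(gt: GroundTruth, h5_path, json_path=None) -> None:
    with h5py.File(h5_path, "w") as fh:
        fh.create_dataset("ob_positions", data=gt.ob_positions)
        fh.create_dataset("ob_timecourses", data=gt.ob_timecourses)
        fh.create_dataset("ob_amplitudes", data=gt.ob_amplitudes)
        fh.create_dataset("cortical_amplitudes", data=gt.cortical_amplitudes)
        fh.create_dataset("epoch_times", data=gt.epoch_times)
        _write_str_array(fh, "labels", gt.labels)
        fh.attrs["seed"] = gt.seed
    if json_path is not None:
        side = {
            "seed": int(gt.seed),
            "n_trials": int(len(gt.labels)),
            "artifacts": gt.artifacts.to_dict(orient="records"),
        }
        Path(json_path).write_text(json.dumps(side, indent=2))


def save_leadfield_h5(lf: LeadField, path) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("gain", data=lf.gain)
        fh.create_dataset("source_positions", data=lf.source_positions)
        _write_str_array(fh, "labels", lf.labels)
        fh.attrs["reference_scheme"] = lf.reference_scheme


def load_leadfield_h5(path) -> LeadField:
    with h5py.File(path, "r") as fh:
        return LeadField(
            fh["gain"][()], fh["source_positions"][()],
            tuple(s.decode() for s in fh["labels"][()]),
            str(fh.attrs["reference_scheme"]))
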