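"""Default electrode montages for EBG recordings.

The EBG montage is a standard 10-20 scalp set (64 or 32 channels) plus four
electrodes in a curved row across the nasal bridge just above the eyebrows
(EBG1-EBG4) and the two mastoids (M1/M2) used as the recording reference.
Standard scalp positions come from the 10-20 template shipped with MNE and
are projected radially onto the model scalp sphere; the EBG electrodes are
placed relative to the nasion landmark.
"""

from __future__ import annotations

import warnings
from functools import lru_cache

import numpy as np

from .headmodel import ElectrodeMontage, ShellHeadModel, build_head_model

__all__ = [
    "EBG_LABELS", "MASTOID_LABELS", "FRONTAL_LABELS",
    "default_ebg_montage", "read_sfp", "write_sfp",
]

EBG_LABELS = ("EBG1", "EBG2", "EBG3", "EBG4")
MASTOID_LABELS = ("M1", "M2")
# channels considered "frontal" for blink detection scope
FRONTAL_LABELS = EBG_LABELS + ("Fp1", "Fpz", "Fp2")

_SCALP_64 = (
    "Fp1", "Fpz", "Fp2", "AF7", "AF3", "AFz", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO7", "PO3", "POz", "PO4", "PO8", "O1", "Oz", "O2", "Iz", "F9", "F10",
)
_SCALP_32 = (
    "Fp1", "Fpz", "Fp2", "AF3", "AF4", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6", "T7", "C3", "Cz", "C4", "T8",
    "CP5", "CP1", "CP2", "CP6", "P7", "P3", "Pz", "P4", "P8",
    "PO3", "PO4", "O1", "O2",
)


@lru_cache(maxsize=1)
def _template_positions() -> tuple[dict, dict]:
    """Standard 10-20 positions (mm) and fiducials from the MNE template."""
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            mont = mne.channels.make_standard_montage("colin27_1020")
        except ValueError:  # older template name
            mont = mne.channels.make_standard_montage("standard_1020")
    pos = mont.get_positions()
    ch = {k: np.asarray(v) * 1e3 for k, v in pos["ch_pos"].items()}
    fid = {"Nasion": np.asarray(pos["nasion"]) * 1e3,
           "LPA": np.asarray(pos["lpa"]) * 1e3,
           "RPA": np.asarray(pos["rpa"]) * 1e3}
    return ch, fid


def default_ebg_montage(
    n_scalp: int = 64,
    model: ShellHeadModel | None = None,
    reference_scheme: str = "mastoid-average",
) -> ElectrodeMontage:
    """Scalp + EBG + mastoid montage projected onto the model scalp sphere.

    Parameters
    ----------
    n_scalp
        64 or 32 standard 10-20 scalp channels (the two cohort sizes used
        for EBG recordings).
    """
    if model is None:
        model = build_head_model()
    if n_scalp == 64:
        scalp = _SCALP_64
    elif n_scalp == 32:
        scalp = _SCALP_32
    else:
        raise ValueError("n_scalp must be 64 or 32")
    ch, fid = _template_positions()

    labels = list(scalp) + list(EBG_LABELS) + list(MASTOID_LABELS)
    positions = [ch[l] for l in scalp]

    # EBG row: lateral offsets across the nasal bridge, slightly above the
    # nasion, then projected radially to the scalp sphere.
    nas = fid["Nasion"]
    for dx in (-30.0, -12.0, 12.0, 30.0):
        positions.append(nas + np.array([dx, 0.0, 8.0]))
    positions.extend([ch["M1"], ch["M2"]])

    mont = ElectrodeMontage(tuple(labels), np.asarray(positions),
                            fiducials=fid, reference_scheme=reference_scheme)
    return mont.projected_to_sphere(model)


def read_sfp(path) -> ElectrodeMontage:
    """Read a whitespace-delimited label/x/y/z electrode position file.

    Rows labelled Nasion/LPA/RPA (case-insensitive) are stored as fiducials.
    """
    labels, positions, fiducials = [], [], {}
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts or parts[0].startswith("#"):
                continue
            if len(parts) != 4:
                raise ValueError(f"malformed electrode row: {line!r}")
            name, xyz = parts[0], np.array([float(v) for v in parts[1:]])
            key = {"nasion": "Nasion", "lpa": "LPA", "rpa": "RPA"}.get(name.lower())
            if key is not None:
                fiducials[key] = xyz
            else:
                labels.append(name)
                positions.append(xyz)
    return ElectrodeMontage(tuple(labels), np.asarray(positions), fiducials=fiducials)


def write_sfp(path, montage: ElectrodeMontage) -> None:
    with open(path, "w") as fh:
        for name, xyz in montage.fiducials.items():
            fh.write(f"{name}\t{xyz[0]:.4f}\t{xyz[1]:.4f}\t{xyz[2]:.4f}\n")
        for name, xyz in zip(montage.labels, montage.positions):
            fh.write(f"{name}\t{xyz[0]:.4f}\t{xyz[1]:.4f}\t{xyz[2]:.4f}\n")
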