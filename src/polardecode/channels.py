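"""32-channel 10-10 montage used throughout the pipeline.

The recording montage is a standard 32-electrode cap (10-10 positions,
ground at AFz which is not recorded).  Helper index sets identify the
frontal channels used for ocular-artifact scoring and the sensorimotor
channels (C3/Cz/C4 and their immediate neighbours) where movement-related
activity is strongest.
"""

from __future__ import annotations

import numpy as np

CHANNELS: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6",
    "T7", "C3", "Cz", "C4", "T8",
    "TP9", "CP5", "CP1", "CP2", "CP6", "TP10",
    "P7", "P3", "Pz", "P4", "P8",
    "PO9", "O1", "Oz", "O2", "PO10",
)

N_CHANNELS = len(CHANNELS)

FRONTAL = ("Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8")
MOTOR = ("C3", "Cz", "C4")
MOTOR_NEIGHBOURS = ("FC5", "FC1", "FC2", "FC6", "CP5", "CP1", "CP2", "CP6")


def channel_index(name: str) -> int:
    """Index of a channel label in the montage (case sensitive)."""
    try:
        return CHANNELS.index(name)
    except ValueError as err:
        raise KeyError(f"unknown channel label {name!r}") from err


def indices(names) -> np.ndarray:
    return np.array([channel_index(n) for n in names], dtype=int)


def montage_positions() -> np.ndarray:
    """3-D electrode positions (m) from the standard 10-05 head model.

    Returns an (n_channels, 3) array in the order of :data:`CHANNELS`.
    """
    import warnings

    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        montage = mne.channels.make_standard_montage("standard_1005")
    pos = montage.get_positions()["ch_pos"]
    return np.array([pos[name] for name in CHANNELS])
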