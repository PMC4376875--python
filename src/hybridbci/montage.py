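"""Electrode montage for a 32-channel 10-20 cap plus mastoid references.

Channel order follows the BioSemi 32-electrode layout. Topography helpers
return per-channel gains in [0, 1] (maximum 1) used to spatially weight the
simulated evoked components: the P300 is largest over parieto-central sites,
the early target-locked negativity and the steady-state flicker response over
parieto-occipital/occipital sites.
"""

from __future__ import annotations

import numpy as np

SCALP_CHANNELS: tuple[str, ...] = (
    "Fp1", "AF3", "F7", "F3", "FC1", "FC5", "T7", "C3",
    "CP1", "CP5", "P7", "P3", "Pz", "PO3", "O1", "Oz",
    "O2", "PO4", "P4", "P8", "CP6", "CP2", "C4", "T8",
    "FC6", "FC2", "F4", "F8", "AF4", "Fp2", "Fz", "Cz",
)

MASTOID_CHANNELS: tuple[str, ...] = ("M1", "M2")

ALL_CHANNELS: tuple[str, ...] = SCALP_CHANNELS + MASTOID_CHANNELS

_PARIETOCENTRAL = {
    "Pz": 1.0, "Cz": 0.9, "CP1": 0.85, "CP2": 0.85, "P3": 0.7, "P4": 0.7,
    "C3": 0.55, "C4": 0.55, "PO3": 0.5, "PO4": 0.5, "FC1": 0.4, "FC2": 0.4,
    "CP5": 0.4, "CP6": 0.4, "P7": 0.3, "P8": 0.3, "O1": 0.3, "Oz": 0.35,
    "O2": 0.3, "Fz": 0.3, "F3": 0.2, "F4": 0.2, "FC5": 0.2, "FC6": 0.2,
    "T7": 0.15, "T8": 0.15, "F7": 0.1, "F8": 0.1, "AF3": 0.1, "AF4": 0.1,
    "Fp1": 0.05, "Fp2": 0.05,
}

_OCCIPITAL = {
    "Oz": 1.0, "O1": 0.8, "O2": 0.8, "PO3": 0.6, "PO4": 0.6, "Pz": 0.4,
    "P3": 0.3, "P4": 0.3, "P7": 0.25, "P8": 0.25, "CP1": 0.15, "CP2": 0.15,
    "CP5": 0.1, "CP6": 0.1, "Cz": 0.1, "C3": 0.05, "C4": 0.05, "T7": 0.05,
    "T8": 0.05, "FC1": 0.02, "FC2": 0.02, "FC5": 0.02, "FC6": 0.02,
    "Fz": 0.02, "F3": 0.01, "F4": 0.01, "F7": 0.01, "F8": 0.01,
    "AF3": 0.01, "AF4": 0.01, "Fp1": 0.0, "Fp2": 0.0,
}

_FRONTAL = {
    "Fp1": 1.0, "Fp2": 1.0, "AF3": 0.8, "AF4": 0.8, "F7": 0.5, "F8": 0.5,
    "F3": 0.5, "F4": 0.5, "Fz": 0.4, "FC1": 0.2, "FC2": 0.2, "FC5": 0.2,
    "FC6": 0.2,
}


def _gains(table: dict[str, float]) -> np.ndarray:
    return np.array([table.get(ch, 0.0) for ch in SCALP_CHANNELS])


def parietocentral_topography() -> np.ndarray:
    """Gain profile peaking at Pz, used for the P300 component."""
    return _gains(_PARIETOCENTRAL)


def occipital_topography() -> np.ndarray:
    """Gain profile peaking at Oz, used for SSVEP and the early negativity."""
    return _gains(_OCCIPITAL)


def frontal_topography() -> np.ndarray:
    """Gain profile peaking at the frontopolar sites, used for ocular artifacts."""
    return _gains(_FRONTAL)
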