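"""EEG preprocessing: referencing, zero-phase filtering, epoching, rejection.

The processing chain mirrors standard offline ERP/SSVEP practice: re-reference
the scalp channels to the mastoid mean, filter with zero-phase (forward plus
backward) Butterworth designs, cut stimulus-locked epochs, optionally drop the
highest-amplitude epochs per run, and decimate band-limited data to the
analysis rate. The canonical parameter sets are 0.5-20 Hz order 3 with 128 Hz
epochs for the ERP/P300 path, and a 0.2 Hz order-4 high-pass with 256 Hz data
for the SSVEP path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import signal

from .montage import MASTOID_CHANNELS
from .simulate import Recording


@dataclass
class EpochSet:
    """Stimulus-locked epochs (epoch x channel x sample) with labels and indexing.

    ``window`` is (t_start, t_end) in seconds relative to flash onset; both
    endpoint samples are included, so the epoch length at rate fs is
    floor((t_end - t_start) * fs) + 1. ``index`` has one row per epoch with
    columns trial, panel, icon, repetition; ``labels`` is True for epochs of
    the cued icon on the cued panel. ``trial_targets`` maps each trial to its
    cued (icon, panel).
    """

    epochs: np.ndarray
    window: tuple[float, float]
    labels: np.ndarray
    index: pd.DataFrame
    trial_targets: pd.DataFrame
    sampling_rate: float
    channel_labels: list[str]
    run_id: str | int | None = None

    def __len__(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_channels(self) -> int:
        return self.epochs.shape[1]

    @property
    def n_samples(self) -> int:
        return self.epochs.shape[2]

    def select(self, mask: np.ndarray) -> "EpochSet":
        """Subset of epochs given a boolean or integer index array."""
        return replace(
            self,
            epochs=self.epochs[mask],
            labels=self.labels[mask],
            index=self.index.iloc[mask].reset_index(drop=True),
        )

    def target_panel_only(self) -> "EpochSet":
        """Keep only epochs from each trial's cued panel (two-panel designs)."""
        cued = self.trial_targets.set_index("trial")["target_panel"]
        mask = (
            self.index["panel"].to_numpy()
            == cued.loc[self.index["trial"]].to_numpy()
        )
        return self.select(mask)


def epoch_length(window: tuple[float, float], sampling_rate: float) -> int:
    """Number of samples per epoch, both endpoints included."""
    t_start, t_end = window
    return int(math.floor((t_end - t_start) * sampling_rate)) + 1


def reference_to_mastoids(
    raw: Recording, mastoids: tuple[str, str] = MASTOID_CHANNELS
) -> Recording:
    """Subtract the mastoid mean from every scalp channel; drop the mastoids."""
    labels = raw.channel_labels
    for m in mastoids:
        if m not in labels:
            raise ValueError(f"mastoid channel {m!r} missing from recording")
    m_idx = [labels.index(m) for m in mastoids]
    keep = [i for i in range(len(labels)) if i not in m_idx]
    reference = raw.data[m_idx].mean(axis=0)
    return Recording(
        data=raw.data[keep] - reference,
        channel_labels=[labels[i] for i in keep],
        sampling_rate=raw.sampling_rate,
        events=raw.events,
    )


def _apply_zero_phase(rec: Recording, sos: np.ndarray, low_edge: float) -> Recording:
    # reflective padding scaled to the filter's characteristic length: the
    # default (a few filter orders) is far too short for sub-hertz cutoffs,
    # whose edge transients ring for seconds
    padlen = min(rec.n_samples - 1, int(round(3 * rec.sampling_rate / low_edge)))
    filtered = signal.sosfiltfilt(sos, rec.data, axis=1, padlen=padlen)
    return Recording(
        data=filtered,
        channel_labels=list(rec.channel_labels),
        sampling_rate=rec.sampling_rate,
        events=rec.events,
    )


def bandpass_zero_phase(
    rec: Recording, low: float = 0.5, high: float = 20.0, order: int = 3
) -> Recording:
    """Zero-phase Butterworth band-pass (applied forward and backward)."""
    nyq = rec.sampling_rate / 2
    if not (0 < low < high < nyq):
        raise ValueError(f"band edges must satisfy 0 < {low} < {high} < {nyq}")
    sos = signal.butter(order, [low, high], btype="bandpass", fs=rec.sampling_rate, output="sos")
    return _apply_zero_phase(rec, sos, low_edge=low)


def highpass_zero_phase(rec: Recording, cutoff: float = 0.2, order: int = 4) -> Recording:
    """Zero-phase Butterworth high-pass (applied forward and backward)."""
    if not (0 < cutoff < rec.sampling_rate / 2):
        raise ValueError("cutoff must lie strictly between 0 and Nyquist")
    sos = signal.butter(order, cutoff, btype="highpass", fs=rec.sampling_rate, output="sos")
    return _apply_zero_phase(rec, sos, low_edge=cutoff)


def resample(obj: Recording | EpochSet, target_rate: float):
    """Integer-factor decimation of already band-limited data.

    Event times are stored in seconds and therefore need no rescaling; epoch
    tensors keep sample 0 (the window start) so the endpoint convention is
    preserved.
    """
    factor = obj.sampling_rate / target_rate
    if abs(factor - round(factor)) > 1e-9:
        raise ValueError(
            f"target rate {target_rate} must divide the source rate {obj.sampling_rate}"
        )
    factor = int(round(factor))
    if factor == 1:
        return obj
    if isinstance(obj, Recording):
        return Recording(
            data=obj.data[:, ::factor],
            channel_labels=list(obj.channel_labels),
            sampling_rate=target_rate,
            events=obj.events,
        )
    return replace(obj, epochs=obj.epochs[:, :, ::factor], sampling_rate=target_rate)


def extract_epochs(
    rec: Recording, window: tuple[float, float], run_id: str | int | None = None
) -> EpochSet:
    """Cut one epoch per flash per panel, labelled target/non-target.

    An epoch is target iff its icon and panel match the trial's cue.
    """
    fs = rec.sampling_rate
    n_len = epoch_length(window, fs)
    flashes = rec.events.flashes
    targets = rec.events.trial_targets()
    tmap = targets.set_index("trial")

    starts = np.round((flashes["onset"].to_numpy() + window[0]) * fs).astype(int)
    if starts.min() < 0 or (starts.max() + n_len) > rec.n_samples:
        raise ValueError("epoch window falls outside the recording for some flash")

    n_ch = rec.data.shape[0]
    epochs = np.empty((len(flashes), n_ch, n_len))
    for i, s in enumerate(starts):
        epochs[i] = rec.data[:, s : s + n_len]

    index = flashes[["trial", "panel", "icon", "repetition"]].reset_index(drop=True)
    cued_icon = tmap.loc[index["trial"], "target_icon"].to_numpy()
    cued_panel = tmap.loc[index["trial"], "target_panel"].to_numpy()
    labels = (index["icon"].to_numpy() == cued_icon) & (
        index["panel"].to_numpy() == cued_panel
    )
    return EpochSet(
        epochs=epochs,
        window=window,
        labels=labels,
        index=index,
        trial_targets=targets,
        sampling_rate=fs,
        channel_labels=list(rec.channel_labels),
        run_id=run_id,
    )


def peak_to_peak_scores(epochs: EpochSet) -> np.ndarray:
    """Per-epoch max over channels of the within-epoch peak-to-peak amplitude."""
    return np.ptp(epochs.epochs, axis=2).max(axis=1)


def reject_high_amplitude(epochs: EpochSet, fraction: float = 0.10) -> EpochSet:
    """Drop the ceil(fraction * n) epochs with the largest peak-to-peak amplitude.

    Intended to run per experimental run, as a cheap ocular-artifact guard in
    the ERP-averaging path. Ties at the cut boundary are resolved by removing
    the earlier epoch first.
    """
    if not (0 <= fraction < 1):
        raise ValueError("fraction must lie in [0, 1)")
    n = len(epochs)
    n_remove = math.ceil(fraction * n)
    if n_remove == 0:
        return epochs
    scores = peak_to_peak_scores(epochs)
    # sort by descending score, ascending original index among ties
    order = np.lexsort((np.arange(n), -scores))
    keep = np.sort(order[n_remove:])
    return epochs.select(keep)
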