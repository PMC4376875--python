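"""Synthetic multichannel EEG generator.

Builds a run-length recording as the sum of three spatially weighted parts:

* background noise — per-channel Gaussian noise with a 1/f**beta amplitude
  spectrum, mixed through a seeded random spatial smearing matrix to give
  realistic inter-channel correlation;
* target-locked ERPs — for every flash of the cued icon, an early occipital
  negativity plus a P300 bump (Gaussian-windowed deflections scaled by their
  channel topographies) time-locked to flash onset;
* flicker responses — for every panel with an active flicker frequency f, a
  sum over harmonics k in {1, 2, 3} of A_k sin(2 pi k f t + phi) gated to
  [flicker_onset, trial_end], scaled by the occipital topography, with the
  attended panel's amplitudes multiplied by the subject's attention gain.

Mastoid channels carry noise only. Generation is bit-reproducible given the
seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .montage import ALL_CHANNELS, SCALP_CHANNELS, frontal_topography
from .paradigm import EventLog, ParadigmConfig
from .profiles import SubjectProfile


@dataclass
class Recording:
    """Multichannel EEG (channels x samples, microvolts) with its event log."""

    data: np.ndarray
    channel_labels: list[str]
    sampling_rate: float
    events: EventLog

    def __post_init__(self) -> None:
        if len(self.channel_labels) != len(set(self.channel_labels)):
            raise ValueError("duplicate channel labels")
        if self.data.shape[0] != len(self.channel_labels):
            raise ValueError("data row count must equal channel count")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def channel(self, label: str) -> np.ndarray:
        return self.data[self.channel_labels.index(label)]


def one_over_f_noise(
    n_channels: int, n_samples: int, exponent: float, rng: np.random.Generator
) -> np.ndarray:
    """Gaussian noise with amplitude spectrum ~ 1/f**(exponent/2), unit variance."""
    n_freq = n_samples // 2 + 1
    freqs = np.fft.rfftfreq(n_samples)
    shaping = np.zeros(n_freq)
    shaping[1:] = freqs[1:] ** (-exponent / 2.0)
    spectrum = (
        rng.standard_normal((n_channels, n_freq))
        + 1j * rng.standard_normal((n_channels, n_freq))
    ) * shaping
    noise = np.fft.irfft(spectrum, n=n_samples, axis=1)
    std = noise.std(axis=1, keepdims=True)
    std[std == 0] = 1.0
    return noise / std


def spatial_smearing_matrix(
    n_channels: int, rng: np.random.Generator, strength: float = 0.5
) -> np.ndarray:
    """Row-normalized mixing matrix: identity plus random positive cross-talk.

    Rows have unit L2 norm so mixing independent unit-variance noise leaves
    each channel's variance at 1.
    """
    mix = np.eye(n_channels) + strength * rng.uniform(0, 1, (n_channels, n_channels))
    return mix / np.linalg.norm(mix, axis=1, keepdims=True)


def _gaussian_bump(t: np.ndarray, amplitude: float, latency: float, width: float) -> np.ndarray:
    return amplitude * np.exp(-0.5 * ((t - latency) / width) ** 2)


def erp_template(profile: SubjectProfile, sampling_rate: float, duration: float = 0.8):
    """Noiseless target-ERP template: (scalp channels x samples) array.

    The template spans [0, duration) s after flash onset and is the sum of the
    early negativity and the P300, each weighted by its own topography.
    """
    t = np.arange(int(round(duration * sampling_rate))) / sampling_rate
    neg = -_gaussian_bump(
        t, profile.early_negativity_amplitude,
        profile.early_negativity_latency, profile.early_negativity_width,
    )
    p300 = _gaussian_bump(t, profile.p300_amplitude, profile.p300_latency, profile.p300_width)
    return (
        np.outer(profile.early_negativity_topography, neg)
        + np.outer(profile.p300_topography, p300)
    )


def simulate_recording(
    schedule: EventLog,
    profile: SubjectProfile,
    config: ParadigmConfig,
    seed: int,
    tail: float = 0.5,
) -> Recording:
    """Render a full-run synthetic EEG recording for one subject.

    Raises if any requested flicker frequency's 3rd harmonic reaches the
    Nyquist frequency of the configured sampling rate.
    """
    fs = config.sampling_rate
    if config.flicker_freq_per_panel is not None:
        for f in config.flicker_freq_per_panel:
            if 3 * f >= fs / 2:
                raise ValueError(
                    f"3rd harmonic of {f} Hz exceeds the Nyquist frequency {fs / 2} Hz"
                )

    rng = np.random.default_rng(seed)
    n_samples = int(round((schedule.run_duration + tail) * fs))
    n_all = len(ALL_CHANNELS)
    n_scalp = len(SCALP_CHANNELS)

    data = np.zeros((n_all, n_samples))
    if profile.noise_scale > 0:
        mix = spatial_smearing_matrix(n_all, rng)
        data += profile.noise_scale * (
            mix @ one_over_f_noise(n_all, n_samples, profile.noise_spectral_exponent, rng)
        )
    else:
        # keep the rng stream aligned so signal draws do not depend on noise_scale
        spatial_smearing_matrix(n_all, rng)
        one_over_f_noise(n_all, n_samples, profile.noise_spectral_exponent, rng)

    scalp = data[:n_scalp]

    # --- target-locked ERPs ---------------------------------------------
    if config.oddball_present:
        template = erp_template(profile, fs)
        tlen = template.shape[1]
        targets = schedule.trials.set_index("trial")
        for row in schedule.flashes.itertuples(index=False):
            trow = targets.loc[row.trial]
            is_target = (
                row.icon == trow["target_icon"] and row.panel == trow["target_panel"]
            )
            gain = 1.0 if is_target else profile.nontarget_erp_gain
            if gain == 0.0:
                continue
            start = int(round(row.onset * fs))
            stop = min(start + tlen, n_samples)
            scalp[:, start:stop] += gain * template[:, : stop - start]

    # --- flicker (SSVEP) responses --------------------------------------
    if config.flicker_freq_per_panel is not None:
        topo = profile.ssvep_topography
        for trow in schedule.trials.itertuples(index=False):
            start = int(round(trow.flicker_onset * fs))
            stop = min(int(round(trow.trial_end * fs)), n_samples)
            t = np.arange(start, stop) / fs
            for panel, freq in enumerate(config.flicker_freq_per_panel):
                phi = rng.uniform(0, 2 * np.pi)
                amps = np.asarray(profile.ssvep_harmonic_amplitudes[freq], dtype=float)
                if panel == trow.target_panel:
                    amps = amps * profile.attention_gain
                wave = np.zeros_like(t)
                for k, a_k in enumerate(amps, start=1):
                    if a_k:
                        wave += a_k * np.sin(2 * np.pi * k * freq * t + phi)
                if wave.any():
                    scalp[:, start:stop] += np.outer(topo, wave)

    # --- optional ocular artifacts (square frontal transients) ----------
    if profile.artifact_rate > 0:
        n_events = rng.poisson(profile.artifact_rate * n_samples / fs)
        onsets = rng.uniform(0, n_samples / fs - 0.3, size=n_events)
        topo = frontal_topography()
        width = int(round(0.2 * fs))
        for onset in np.sort(onsets):
            start = int(round(onset * fs))
            scalp[:, start : start + width] += np.outer(
                topo, np.full(min(width, n_samples - start), profile.artifact_amplitude)
            )

    return Recording(
        data=data,
        channel_labels=list(ALL_CHANNELS),
        sampling_rate=fs,
        events=schedule,
    )
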