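"""Synthetic subject profiles: evoked-response amplitudes, topographies, noise.

A profile collects everything subject-specific that the generator needs:
the target-locked ERP (an early parieto-occipital negativity between 100 and
200 ms plus a parieto-central P300 around 350 ms, both Gaussian-windowed
deflections), per-frequency amplitudes of the flicker response at harmonics
1-3 (subjects differ in which harmonic responds most strongly, and some
harmonics may be absent), an attention gain for the attended panel in the
two-panel design, and the 1/f-type background-noise level.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .montage import occipital_topography, parietocentral_topography
from .paradigm import STIMULATION_FREQUENCIES


def _default_ssvep_amps() -> dict[float, tuple[float, float, float]]:
    # strong responder: clear fundamental, weaker 2nd/3rd harmonics, at every
    # stimulation frequency usable on a 60 Hz screen
    return {f: (2.0, 1.2, 0.6) for f in STIMULATION_FREQUENCIES}


@dataclass(frozen=True)
class SubjectProfile:
    """Generative parameters of one synthetic subject.

    Amplitudes are in microvolts; latencies and widths in seconds (widths are
    Gaussian standard deviations). Topographies are per-scalp-channel gains in
    [0, 1] with at least one channel at 1. ``attention_gain`` multiplies the
    flicker amplitudes of the attended panel relative to unattended panels.
    ``noise_scale`` is the per-channel standard deviation of the background
    noise, whose spectrum falls off as 1/f**noise_spectral_exponent.
    """

    p300_amplitude: float = 8.0
    p300_latency: float = 0.350
    p300_width: float = 0.060
    p300_topography: np.ndarray = field(default_factory=parietocentral_topography)
    early_negativity_amplitude: float = 3.0
    early_negativity_latency: float = 0.150
    early_negativity_width: float = 0.030
    early_negativity_topography: np.ndarray = field(default_factory=occipital_topography)
    ssvep_harmonic_amplitudes: dict[float, tuple[float, float, float]] = field(
        default_factory=_default_ssvep_amps
    )
    ssvep_topography: np.ndarray = field(default_factory=occipital_topography)
    attention_gain: float = 2.0
    noise_scale: float = 8.0
    noise_spectral_exponent: float = 1.0
    nontarget_erp_gain: float = 0.0
    artifact_rate: float = 0.0
    artifact_amplitude: float = 100.0

    def __post_init__(self) -> None:
        for name in ("p300_amplitude", "early_negativity_amplitude", "noise_scale"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.attention_gain < 1:
            raise ValueError("attention_gain must be >= 1")
        for topo_name in ("p300_topography", "early_negativity_topography", "ssvep_topography"):
            topo = np.asarray(getattr(self, topo_name))
            if topo.min() < 0 or topo.max() > 1 or not np.isclose(topo.max(), 1.0):
                raise ValueError(f"{topo_name} gains must lie in [0, 1] with max 1")
        for amps in self.ssvep_harmonic_amplitudes.values():
            if len(amps) != 3 or min(amps) < 0:
                raise ValueError("harmonic amplitudes are non-negative triplets")

    def scaled(self, factor: float) -> "SubjectProfile":
        """Profile with every signal amplitude multiplied by ``factor``."""
        return replace(
            self,
            p300_amplitude=self.p300_amplitude * factor,
            early_negativity_amplitude=self.early_negativity_amplitude * factor,
            ssvep_harmonic_amplitudes={
                f: tuple(a * factor for a in amps)
                for f, amps in self.ssvep_harmonic_amplitudes.items()
            },
        )

    @classmethod
    def strong(cls) -> "SubjectProfile":
        """High-SNR reference subject (the defaults)."""
        return cls()

    @classmethod
    def silent(cls, **kw) -> "SubjectProfile":
        """No evoked activity at all: background noise only."""
        return cls(
            p300_amplitude=0.0,
            early_negativity_amplitude=0.0,
            ssvep_harmonic_amplitudes={f: (0.0, 0.0, 0.0) for f in STIMULATION_FREQUENCIES},
            **kw,
        )


def sample_profiles(n_subjects: int, seed: int) -> list[SubjectProfile]:
    """Draw a cohort of subject profiles around the strong-responder defaults.

    Inter-subject variability follows what multi-subject flicker recordings
    show: the relative weight of the three harmonics varies widely (the
    fundamental is not always the strongest), and ERP latency/amplitude and
    noise level vary moderately.
    """
    rng = np.random.default_rng(seed)
    base = SubjectProfile.strong()
    profiles = []
    for _ in range(n_subjects):
        # harmonic mix: Dirichlet weights, total amplitude lognormal around base
        amps = {}
        for f in STIMULATION_FREQUENCIES:
            total = sum(base.ssvep_harmonic_amplitudes[f])
            total *= rng.lognormal(mean=0.0, sigma=0.25)
            w = rng.dirichlet((2.0, 1.5, 1.0))
            amps[f] = tuple(total * wi for wi in w)
        profiles.append(
            replace(
                base,
                p300_amplitude=base.p300_amplitude * rng.lognormal(0.0, 0.2),
                p300_latency=float(np.clip(rng.normal(0.350, 0.030), 0.25, 0.45)),
                early_negativity_amplitude=(
                    base.early_negativity_amplitude * rng.lognormal(0.0, 0.3)
                ),
                early_negativity_latency=float(rng.uniform(0.110, 0.190)),
                ssvep_harmonic_amplitudes=amps,
                attention_gain=float(rng.uniform(1.6, 2.4)),
                noise_scale=base.noise_scale * rng.lognormal(0.0, 0.15),
            )
        )
    return profiles
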