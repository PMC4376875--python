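"""SSVEP analysis: narrowband power, spectra, MEC filtering, SNR detection.

The power of a single-channel signal Y = [y_1 .. y_ns] at a frequency f is
estimated by projection onto a sine/cosine pair:

    P(Y, f) = (mean_i y_i cos(2 pi i f / f_s))**2
            + (mean_i y_i sin(2 pi i f / f_s))**2

which for a unit-amplitude sinusoid over an integer number of cycles equals
0.25 (amplitude**2 / 4).

Frequency detection uses the Minimum Energy Combination (MEC) spatial filter:
the candidate sinusoids (all stimulation frequencies and their first three
harmonics) are projected out of the segment, the residual's channel
covariance is eigendecomposed, and the components with the smallest residual
noise energy are retained (scaled by 1/sqrt(eigenvalue)). A candidate
frequency is scored by the mean signal-to-noise ratio over the retained
components and harmonics, where the noise power at a frequency is the mean
narrowband power over the nearest off-target frequency bins. The candidate
with the highest score is the winner frequency.

A trained variant keeps the per-harmonic SNRs as a 3-D feature vector and
learns per-subject harmonic weights with a linear SVM, since subjects differ
in which harmonics respond.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import GridSearchCV, LeaveOneOut
from sklearn.svm import SVC

DEFAULT_C_GRID = np.logspace(-5, 2, 15)


# ---------------------------------------------------------------------------
# power and spectra
# ---------------------------------------------------------------------------

def power_at(y: np.ndarray, f: float, fs: float) -> float:
    """Narrowband power (microvolts squared) of a 1-D signal at frequency f."""
    y = np.asarray(y, dtype=float)
    n_s = y.size
    if n_s < 2:
        raise ValueError("signal must contain at least 2 samples")
    if f >= fs / 2:
        raise ValueError("frequency of interest must be below Nyquist")
    i = np.arange(1, n_s + 1)
    phase = 2 * np.pi * i * f / fs
    return float((y @ np.cos(phase) / n_s) ** 2 + (y @ np.sin(phase) / n_s) ** 2)


@dataclass(frozen=True)
class PowerEstimate:
    """Narrowband power at harmonic k of a stimulation frequency."""

    P: float
    f: float
    harmonic: int
    f_s: float
    n_s: int
    channel: str | None = None

    def __post_init__(self) -> None:
        if self.P < 0:
            raise ValueError("power must be non-negative")


def harmonic_powers(
    y: np.ndarray, f_stim: float, fs: float, harmonics: int = 3, channel: str | None = None
) -> list[PowerEstimate]:
    """Power at harmonics 1..harmonics of the stimulation frequency."""
    return [
        PowerEstimate(
            P=power_at(y, k * f_stim, fs), f=k * f_stim, harmonic=k,
            f_s=fs, n_s=len(y), channel=channel,
        )
        for k in range(1, harmonics + 1)
    ]


def amplitude_spectrum(y: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """One-sided FFT amplitude spectrum: (frequency grid, magnitudes in microvolts)."""
    y = np.asarray(y, dtype=float)
    if y.size < 2:
        raise ValueError("signal must contain at least 2 samples")
    n = y.size
    mags = np.abs(np.fft.rfft(y)) * 2.0 / n
    mags[0] /= 2.0
    if n % 2 == 0:
        mags[-1] /= 2.0
    return np.fft.rfftfreq(n, d=1.0 / fs), mags


def mean_amplitude_spectrum(trials: list[np.ndarray], fs: float):
    """Trial-averaged amplitude spectrum (magnitudes averaged across trials)."""
    spectra = [amplitude_spectrum(y, fs) for y in trials]
    freqs = spectra[0][0]
    for f, _ in spectra[1:]:
        if f.shape != freqs.shape:
            raise ValueError("all trials must share one segment length")
    return freqs, np.mean([m for _, m in spectra], axis=0)


# ---------------------------------------------------------------------------
# minimum energy combination
# ---------------------------------------------------------------------------

def sinusoid_basis(freqs, harmonics: int, n_s: int, fs: float) -> np.ndarray:
    """(n_s x 2*len(freqs)*harmonics) matrix of sin/cos columns at k*f."""
    i = np.arange(1, n_s + 1)
    cols = []
    for f in freqs:
        for k in range(1, harmonics + 1):
            if k * f >= fs / 2:
                raise ValueError(f"harmonic {k} of {f} Hz exceeds Nyquist")
            phase = 2 * np.pi * i * (k * f) / fs
            cols.append(np.sin(phase))
            cols.append(np.cos(phase))
    return np.column_stack(cols)


@dataclass
class MecFilter:
    """Spatial filter minimizing residual noise energy at the candidate frequencies."""

    weights: np.ndarray             # channels x components, 1/sqrt(eigenvalue)-scaled
    eigenvalues: np.ndarray         # ascending, of the retained spectrum
    retained_noise_ratio: float     # cumulative share of residual energy kept
    freqs: tuple[float, ...]
    harmonics: int

    @property
    def n_components(self) -> int:
        return self.weights.shape[1]

    def apply(self, segment: np.ndarray) -> np.ndarray:
        """Filtered component signals (components x samples)."""
        return self.weights.T @ segment


def fit_mec(
    segment: np.ndarray,
    freqs,
    fs: float,
    harmonics: int = 3,
    retain: float = 0.10,
) -> MecFilter:
    """Fit the Minimum Energy Combination filter on one analysis segment.

    ``segment`` is channels x samples. The SSVEP subspace (all candidate
    frequencies and their harmonics) is removed by least squares; the filter
    keeps the eigenvectors of the residual covariance whose cumulative
    eigenvalue share is at most ``retain`` (at least one component), each
    scaled by 1/sqrt(eigenvalue). Near-zero eigenvalues (below 1e-12 of the
    largest) are discarded as rank deficiency.
    """
    segment = np.asarray(segment, dtype=float)
    if segment.ndim != 2 or segment.shape[0] < 2:
        raise ValueError("segment must be channels x samples with >= 2 channels")
    n_s = segment.shape[1]
    if n_s / fs <= 1.0 / min(freqs):
        raise ValueError("segment must span more than one period of the lowest frequency")

    basis = sinusoid_basis(freqs, harmonics, n_s, fs)
    coefs, *_ = np.linalg.lstsq(basis, segment.T, rcond=None)
    residual = segment - (basis @ coefs).T

    cov = residual @ residual.T / n_s
    eigvals, eigvecs = np.linalg.eigh(cov)          # ascending
    valid = eigvals > 1e-12 * eigvals.max()
    eigvals, eigvecs = eigvals[valid], eigvecs[:, valid]

    total = eigvals.sum()
    share = np.cumsum(eigvals) / total
    n_comp = max(1, int(np.searchsorted(share, retain, side="right")))
    n_comp = min(n_comp, eigvals.size)

    weights = eigvecs[:, :n_comp] / np.sqrt(eigvals[:n_comp])
    return MecFilter(
        weights=weights,
        eigenvalues=eigvals[:n_comp],
        retained_noise_ratio=float(share[n_comp - 1]),
        freqs=tuple(freqs),
        harmonics=harmonics,
    )


# ---------------------------------------------------------------------------
# SNR scoring and detection
# ---------------------------------------------------------------------------

def snr_at(
    y: np.ndarray,
    f: float,
    fs: float,
    exclude: tuple[float, ...] = (),
    n_noise_bins: int = 8,
) -> float:
    """Signal power at f divided by the mean power over nearby noise bins.

    Noise bins are the ``n_noise_bins`` off-target frequencies nearest to f,
    spaced at the segment's frequency resolution fs/n_s, excluding f itself
    and any frequency in ``exclude`` (the other candidate harmonics). A zero
    noise estimate yields +inf with a warning.
    """
    y = np.asarray(y, dtype=float)
    n_s = y.size
    df = fs / n_s
    excluded = np.asarray((f,) + tuple(exclude), dtype=float)

    noise_freqs: list[float] = []
    m = 1
    while len(noise_freqs) < n_noise_bins:
        for cand in (f - m * df, f + m * df):
            if len(noise_freqs) >= n_noise_bins:
                break
            if cand <= 0 or cand >= fs / 2:
                continue
            if np.min(np.abs(excluded - cand)) < df / 2:
                continue
            noise_freqs.append(cand)
        m += 1
        if m > 10 * n_noise_bins + int(fs / df):
            raise ValueError("could not find enough noise bins below Nyquist")

    signal_power = power_at(y, f, fs)
    noise_power = float(np.mean([power_at(y, nf, fs) for nf in noise_freqs]))
    if noise_power == 0.0:
        warnings.warn("zero noise-power estimate; SNR reported as +inf")
        return np.inf
    return signal_power / noise_power


@dataclass
class SnrFeature:
    """Per-(trial, candidate-frequency) SNR triplet for harmonics 1-3."""

    trial: int
    frequency: float
    snr: np.ndarray                # one value per harmonic, component-averaged
    n_components: int
    n_repetitions: int | None = None
    attended: bool | None = None

    def __post_init__(self) -> None:
        self.snr = np.asarray(self.snr, dtype=float)
        if (self.snr < 0).any():
            raise ValueError("SNR values must be non-negative")


def harmonic_snrs(
    segment: np.ndarray,
    f_candidate: float,
    all_candidates,
    fs: float,
    harmonics: int = 3,
    mec: MecFilter | None = None,
) -> np.ndarray:
    """Component-averaged SNR per harmonic of one candidate frequency."""
    if mec is None:
        mec = fit_mec(segment, all_candidates, fs, harmonics=harmonics)
    components = mec.apply(segment)
    exclude = tuple(
        k * f for f in all_candidates for k in range(1, harmonics + 1)
    )
    out = np.empty(harmonics)
    for k in range(1, harmonics + 1):
        f_k = k * f_candidate
        excl = tuple(e for e in exclude if e != f_k)
        out[k - 1] = np.mean([snr_at(c, f_k, fs, exclude=excl) for c in components])
    return out


def score_frequency(
    segment: np.ndarray,
    f_candidate: float,
    all_candidates,
    fs: float,
    harmonics: int = 3,
    mec: MecFilter | None = None,
) -> float:
    """Mean SNR over spatial components and harmonics of one candidate."""
    return float(
        np.mean(harmonic_snrs(segment, f_candidate, all_candidates, fs, harmonics, mec))
    )


def detect_ssvep(
    segment: np.ndarray,
    candidates,
    fs: float,
    harmonics: int = 3,
    attended: float | None = None,
) -> dict:
    """Winner frequency = candidate with the highest mean-SNR score.

    Ties break to the lower frequency (flagged). When the attended frequency
    is known, ``correct`` reports whether the winner matches it.
    """
    candidates = sorted(candidates)
    if len(candidates) < 2:
        raise ValueError("need at least two candidate frequencies")
    mec = fit_mec(segment, candidates, fs, harmonics=harmonics)
    scores = {
        f: score_frequency(segment, f, candidates, fs, harmonics, mec)
        for f in candidates
    }
    best = max(scores.values())
    winners = [f for f in candidates if scores[f] == best]
    tie = len(winners) > 1
    if tie:
        warnings.warn(f"tied SSVEP scores at {winners}; choosing {winners[0]} Hz")
    winner = winners[0]
    result = {"winner": winner, "scores": scores, "tie": tie}
    if attended is not None:
        result["correct"] = int(winner == attended)
    return result


# ---------------------------------------------------------------------------
# subject-trained harmonic weighting
# ---------------------------------------------------------------------------

@dataclass
class HarmonicWeightModel:
    """Linear model over the 3-D per-harmonic SNR feature space."""

    weights: np.ndarray
    bias: float
    C: float
    grid: np.ndarray = field(repr=False, default=None)

    def decision(self, snr_triplets: np.ndarray) -> np.ndarray:
        return np.atleast_2d(snr_triplets) @ self.weights + self.bias

    def pick_winner(self, features: list[SnrFeature]) -> float:
        """Candidate whose SNR triplet yields the highest model output."""
        outputs = self.decision(np.vstack([f.snr for f in features]))
        order = np.lexsort((np.array([f.frequency for f in features]), -outputs))
        return features[order[0]].frequency


def train_harmonic_weighting(
    features: list[SnrFeature],
    seed: int,
    grid: np.ndarray = DEFAULT_C_GRID,
) -> HarmonicWeightModel:
    """Learn per-subject harmonic weights from labelled SNR features.

    Each (trial, candidate) pair is one training sample, labelled by whether
    the candidate was the attended frequency; the regularization strength is
    chosen by leave-one-out cross-validation over a logarithmic line search.
    """
    X = np.vstack([f.snr for f in features])
    y = np.array([bool(f.attended) for f in features])
    if y.all() or not y.any():
        raise ValueError("training features must contain both classes")
    if np.allclose(X.var(axis=0), 0):
        raise ValueError("degenerate SNR features: zero variance in every harmonic")
    del seed  # the SMO solver is deterministic; kept for interface stability
    search = GridSearchCV(
        SVC(kernel="linear"),
        {"C": grid},
        cv=LeaveOneOut(),
        scoring="accuracy",
        n_jobs=None,
    )
    search.fit(X, y)
    best = search.best_estimator_
    return HarmonicWeightModel(
        weights=best.coef_.ravel().copy(),
        bias=float(best.intercept_[0]),
        C=float(search.best_params_["C"]),
        grid=np.asarray(grid),
    )
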