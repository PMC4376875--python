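"""Hybrid decision fusion, accuracy/ITR curves, and experiment workflows.

An icon of the two-panel speller is identified only when both decisions are
right: the P300 decoder picks which of the 6 icons of the attended panel was
attended, and the SSVEP detector picks which of the 2 panels. The fused
correctness is the logical AND, so fused accuracy is bounded by both
marginals.

Communication speed is summarized by the information transfer rate. The
bitrate per symbol for accuracy p over N symbols is

    B = log2(N) + p*log2(p) + (1 - p)*log2((1 - p) / (N - 1))

and the rate in bits per minute over N_c communicated symbols with per-symbol
times t_i is

    I = B * N_c / sum(t_i) * 60.

N is 6 for P300-only, 2 for SSVEP-only and 12 for the hybrid decision, and the
per-symbol time is the stimulation time 1.5 * N_r seconds (cue and pauses
excluded; an overhead term can be added for realistic-rate reporting).

This module also drives the three synthetic experiment designs end-to-end:
ERP averaging plus condition correlations and P300 cross-validation (design
1), harmonic-power tables with and without oddball flashes (design 2), and
the full hybrid detection/ITR evaluation (design 3).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import erp as erp_mod
from . import p300 as p300_mod
from . import ssvep as ssvep_mod
from .paradigm import ParadigmConfig, STIMULATION_FREQUENCIES, make_schedule
from .preprocessing import (
    EpochSet,
    bandpass_zero_phase,
    extract_epochs,
    highpass_zero_phase,
    reference_to_mastoids,
    reject_high_amplitude,
    resample,
)
from .profiles import SubjectProfile
from .simulate import Recording, simulate_recording

SEQUENCE_DURATION = 1.5          # nominal seconds per flashing sequence (6 x 0.250)
MODALITY_SYMBOLS = {"p300": 6, "ssvep": 2, "hybrid": 12}


# ---------------------------------------------------------------------------
# information transfer rate
# ---------------------------------------------------------------------------

def bitrate(p: float, N: int) -> float:
    """Bits per symbol at accuracy p over N symbols (Wolpaw definition).

    The p -> 0 and p -> 1 limits are evaluated by continuity (x*log2(x) -> 0).
    B is convex in p with a minimum of exactly 0 at chance level p = 1/N, so
    it is non-negative over the whole domain (below-chance accuracies map to
    small positive values, not to negative ones).
    """
    if N < 2:
        raise ValueError("need at least 2 symbols")
    if not (0 <= p <= 1):
        raise ValueError("accuracy must lie in [0, 1]")
    b = np.log2(N)
    if p > 0:
        b += p * np.log2(p)
    if p < 1:
        b += (1 - p) * np.log2((1 - p) / (N - 1))
    return float(b)


def itr(p: float, N: int, times) -> float:
    """Information transfer rate in bits per minute.

    ``times`` lists the seconds spent communicating each of the N_c symbols.
    """
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        raise ValueError("need at least one communicated symbol")
    if (times <= 0).any():
        raise ValueError("symbol times must be positive")
    return bitrate(p, N) * times.size / times.sum() * 60.0


# ---------------------------------------------------------------------------
# fusion and curves
# ---------------------------------------------------------------------------

def fuse(p300_row, ssvep_row) -> int:
    """Icon correctness: both decisions of the same (trial, N_r) must be right."""
    for key in ("trial", "n_r"):
        if p300_row[key] != ssvep_row[key]:
            raise ValueError(f"rows disagree on {key}")
    return int(bool(p300_row["correct"]) and bool(ssvep_row["correct"]))


def build_detection_table(
    p300_rows: pd.DataFrame, ssvep_rows: pd.DataFrame, subject=None
) -> pd.DataFrame:
    """Merge per-trial P300 and SSVEP correctness and fuse them per (trial, N_r)."""
    keys = ["test_run", "trial", "n_r"]
    merged = p300_rows[keys + ["correct"]].rename(columns={"correct": "p300_correct"}).merge(
        ssvep_rows[keys + ["correct"]].rename(columns={"correct": "ssvep_correct"}),
        on=keys,
        validate="one_to_one",
    )
    merged["icon_correct"] = merged["p300_correct"] & merged["ssvep_correct"]
    merged["icon_correct"] = merged["icon_correct"].astype(int)
    merged["stimulation_time"] = SEQUENCE_DURATION * merged["n_r"]
    if subject is not None:
        merged.insert(0, "subject", subject)
    return merged


def accuracy_itr_curves(
    table: pd.DataFrame, modality: str, overhead: float = 0.0
) -> pd.DataFrame:
    """Accuracy and ITR per repetition count for one modality.

    ``overhead`` adds fixed non-stimulation seconds (cue, pauses) per trial
    for realistic-rate reporting; the default counts stimulation time only.
    """
    if modality not in MODALITY_SYMBOLS:
        raise ValueError(f"unknown modality {modality!r}")
    col = {"p300": "p300_correct", "ssvep": "ssvep_correct", "hybrid": "icon_correct"}[modality]
    N = MODALITY_SYMBOLS[modality]
    rows = []
    for n_r, group in table.groupby("n_r"):
        p = float(group[col].mean())
        times = np.full(len(group), SEQUENCE_DURATION * n_r + overhead)
        rows.append(
            {
                "n_r": int(n_r),
                "modality": modality,
                "accuracy": p,
                "itr": itr(p, N, times),
                "n_trials": len(group),
            }
        )
    return pd.DataFrame(rows).sort_values("n_r").reset_index(drop=True)


# ---------------------------------------------------------------------------
# canonical preprocessing paths
# ---------------------------------------------------------------------------

def p300_path(rec: Recording, run_id=None) -> EpochSet:
    """ERP-classification path: mastoid reference, 0.5-20 Hz, 0-600 ms, 128 Hz."""
    rec = bandpass_zero_phase(reference_to_mastoids(rec), 0.5, 20.0, order=3)
    epochs = extract_epochs(rec, (0.0, 0.6), run_id=run_id)
    return resample(epochs, 128.0)


def erp_path(rec: Recording, run_id=None, reject_fraction: float = 0.10) -> EpochSet:
    """ERP-averaging path: 0.5-20 Hz, -200..800 ms epochs, per-run 10% rejection."""
    rec = bandpass_zero_phase(reference_to_mastoids(rec), 0.5, 20.0, order=3)
    epochs = extract_epochs(rec, (-0.2, 0.8), run_id=run_id)
    return reject_high_amplitude(epochs, reject_fraction)


def ssvep_path(rec: Recording) -> Recording:
    """SSVEP path: mastoid reference, 0.2 Hz high-pass (order 4), 256 Hz."""
    rec = highpass_zero_phase(reference_to_mastoids(rec), 0.2, order=4)
    return resample(rec, 256.0)


def ssvep_trial_segment(rec: Recording, trial_row, n_r: int) -> np.ndarray:
    """Analysis segment of one trial: 1.5*N_r seconds from oddball onset."""
    fs = rec.sampling_rate
    start = int(round(trial_row.oddball_onset * fs))
    stop = start + int(round(SEQUENCE_DURATION * n_r * fs))
    if stop > rec.n_samples:
        raise ValueError("requested segment extends past the recording")
    return rec.data[:, start:stop]


def detect_run_ssvep(
    rec: Recording,
    candidates=(12.0, 15.0),
    n_r_values=range(1, 11),
    run_label=None,
    harmonics: int = 3,
) -> pd.DataFrame:
    """Per-trial SSVEP winner-frequency correctness for each repetition count.

    ``rec`` must already be on the SSVEP path (referenced, high-passed,
    downsampled). The attended frequency of a trial is its cued panel's
    flicker frequency.
    """
    freqs = rec.events.config.flicker_freq_per_panel
    rows = []
    for trial_row in rec.events.trials.itertuples(index=False):
        attended = freqs[int(trial_row.target_panel)]
        for n_r in n_r_values:
            segment = ssvep_trial_segment(rec, trial_row, n_r)
            res = ssvep_mod.detect_ssvep(
                segment, candidates, rec.sampling_rate, harmonics=harmonics,
                attended=attended,
            )
            rows.append(
                {
                    "test_run": run_label,
                    "trial": int(trial_row.trial),
                    "n_r": int(n_r),
                    "correct": res["correct"],
                    "winner": res["winner"],
                    "attended": attended,
                }
            )
    return pd.DataFrame(rows)


def ssvep_run_features(
    rec: Recording,
    candidates=(12.0, 15.0),
    n_r: int = 2,
    harmonics: int = 3,
) -> list[ssvep_mod.SnrFeature]:
    """Per-(trial, candidate) harmonic-SNR features for the trained variant."""
    freqs = rec.events.config.flicker_freq_per_panel
    candidates = sorted(candidates)
    features = []
    for trial_row in rec.events.trials.itertuples(index=False):
        attended = freqs[int(trial_row.target_panel)]
        segment = ssvep_trial_segment(rec, trial_row, n_r)
        mec = ssvep_mod.fit_mec(segment, candidates, rec.sampling_rate, harmonics=harmonics)
        for f in candidates:
            snrs = ssvep_mod.harmonic_snrs(
                segment, f, candidates, rec.sampling_rate, harmonics, mec
            )
            features.append(
                ssvep_mod.SnrFeature(
                    trial=int(trial_row.trial),
                    frequency=f,
                    snr=snrs,
                    n_components=mec.n_components,
                    n_repetitions=n_r,
                    attended=(f == attended),
                )
            )
    return features


# ---------------------------------------------------------------------------
# experiment workflows
# ---------------------------------------------------------------------------

def _simulate_runs(
    config: ParadigmConfig, profile: SubjectProfile, n_runs: int, seed: int
) -> list[Recording]:
    rng = np.random.default_rng(seed)
    recs = []
    for _ in range(n_runs):
        s_sched, s_rec = rng.integers(0, 2**31 - 1, size=2)
        schedule = make_schedule(config, int(s_sched))
        recs.append(simulate_recording(schedule, profile, config, int(s_rec)))
    return recs


def run_experiment1(
    profile: SubjectProfile,
    seed: int,
    conditions: dict[str, float | None] | None = None,
    n_runs_per_condition: int = 3,
    n_r_values=range(1, 11),
    config_kw: dict | None = None,
    decoder_kw: dict | None = None,
) -> dict:
    """Design 1: flicker's effect on the target ERP and its decoding.

    For each condition (pure oddball plus one hybrid condition per flicker
    frequency) simulates ``n_runs_per_condition`` runs, averages the target
    ERP on the averaging path, correlates conditions pairwise per channel,
    and cross-validates the P300 decoder by run.
    """
    if conditions is None:
        conditions = {"oddball": None}
        conditions.update(
            {f"hybrid-{f:g}": f for f in np.round(STIMULATION_FREQUENCIES, 2)}
        )
    config_kw = config_kw or {}
    decoder_kw = decoder_kw or {}
    rng = np.random.default_rng(seed)

    erps, correctness = [], []
    for cond, freq in conditions.items():
        config = ParadigmConfig.experiment1(flicker_freq=freq, **config_kw)
        recs = _simulate_runs(config, profile, n_runs_per_condition, int(rng.integers(2**31 - 1)))
        # averaging path: per-run rejection, then pool target epochs across runs
        pooled = [erp_path(r, run_id=i) for i, r in enumerate(recs)]
        waveforms = [erp_mod.average_target_erp(e, condition=cond) for e in pooled]
        n_tot = sum(w.n_epochs_used for w in waveforms)
        mean_wave = sum(w.waveform * w.n_epochs_used for w in waveforms) / n_tot
        erps.append(
            erp_mod.ErpAverage(
                waveform=mean_wave,
                n_epochs_used=n_tot,
                condition=cond,
                window=pooled[0].window,
                sampling_rate=pooled[0].sampling_rate,
                channel_labels=pooled[0].channel_labels,
            )
        )
        if n_runs_per_condition == 3:
            epoch_runs = [p300_path(r, run_id=i) for i, r in enumerate(recs)]
            table = p300_mod.crossvalidate_runs(
                epoch_runs, "3-fold-by-run", seed=int(rng.integers(2**31 - 1)),
                n_r_values=n_r_values, **decoder_kw,
            )
            table.insert(0, "condition", cond)
            correctness.append(table)

    return {
        "erps": erps,
        "correlations": erp_mod.condition_pair_correlations(erps),
        "p300_correctness": (
            pd.concat(correctness, ignore_index=True) if correctness else None
        ),
    }


def run_experiment2(
    profile: SubjectProfile,
    seed: int,
    frequencies=STIMULATION_FREQUENCIES,
    harmonics: int = 3,
    config_kw: dict | None = None,
) -> pd.DataFrame:
    """Design 2: per-trial Oz power at harmonics 1-3, pure-SSVEP vs hybrid runs.

    One run per (frequency, stimulation type) cell; per trial the power is
    measured over the flicker-on interval at channel Oz. Returns a tidy table
    (frequency, type, trial, harmonic, power).
    """
    config_kw = config_kw or {}
    rng = np.random.default_rng(seed)
    rows = []
    for freq in frequencies:
        for oddball in (False, True):
            config = ParadigmConfig.experiment2(freq, oddball=oddball, **config_kw)
            [rec] = _simulate_runs(config, profile, 1, int(rng.integers(2**31 - 1)))
            rec = reference_to_mastoids(rec)
            oz = rec.channel("Oz")
            fs = rec.sampling_rate
            for trial_row in rec.events.trials.itertuples(index=False):
                start = int(round(trial_row.flicker_onset * fs))
                stop = int(round((trial_row.trial_end - config.post_pause) * fs))
                for est in ssvep_mod.harmonic_powers(
                    oz[start:stop], freq, fs, harmonics=harmonics, channel="Oz"
                ):
                    rows.append(
                        {
                            "frequency": freq,
                            "type": "hybrid" if oddball else "pure",
                            "trial": int(trial_row.trial),
                            "harmonic": est.harmonic,
                            "power": est.P,
                        }
                    )
    return pd.DataFrame(rows)


def run_experiment3(
    profile: SubjectProfile,
    seed: int,
    n_runs: int = 8,
    n_r_values=range(1, 11),
    candidates: tuple[float, float] = (12.0, 15.0),
    subject=None,
    config_kw: dict | None = None,
    decoder_kw: dict | None = None,
) -> dict:
    """Design 3: full hybrid evaluation (train on 2 runs, test on the rest).

    Returns the merged detection table plus accuracy/ITR curves for the three
    modalities.
    """
    config_kw = config_kw or {}
    decoder_kw = decoder_kw or {}
    config = ParadigmConfig.experiment3(flicker_freqs=candidates, **config_kw)
    recs = _simulate_runs(config, profile, n_runs, seed)

    epoch_runs = [p300_path(r, run_id=i) for i, r in enumerate(recs)]
    p300_rows = p300_mod.crossvalidate_runs(
        epoch_runs, "train-2-test-6", seed=seed, n_r_values=n_r_values, **decoder_kw
    )

    ssvep_rows = []
    for k, rec in enumerate(recs[2:], start=2):
        ssvep_rows.append(
            detect_run_ssvep(
                ssvep_path(rec), candidates=candidates, n_r_values=n_r_values,
                run_label=k,
            )
        )
    ssvep_rows = pd.concat(ssvep_rows, ignore_index=True)

    table = build_detection_table(p300_rows, ssvep_rows, subject=subject)
    curves = pd.concat(
        [accuracy_itr_curves(table, m) for m in ("p300", "ssvep", "hybrid")],
        ignore_index=True,
    )
    return {
        "detection_table": table,
        "curves": curves,
        "p300_rows": p300_rows,
        "ssvep_rows": ssvep_rows,
    }


def run_experiment(design: int, profile: SubjectProfile, seed: int, **kw):
    """Dispatch to the three experiment workflows by design number."""
    if design == 1:
        return run_experiment1(profile, seed, **kw)
    if design == 2:
        return run_experiment2(profile, seed, **kw)
    if design == 3:
        return run_experiment3(profile, seed, **kw)
    raise ValueError("design must be 1, 2 or 3")
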