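"""Linear P300 decoding with repetition averaging and run-level evaluation.

Single-flash epochs (0-600 ms at 128 Hz) are flattened to channel-by-sample
feature vectors and a linear support-vector machine separates target from
non-target flashes; the regularization strength is chosen by an inner
stratified 10-fold cross-validation over a logarithmic line search. At test
time the epochs of each icon are averaged over the first N_r repetitions, the
icon with the highest decision value is the detected target, and a trial is
correct when that icon matches the cue. Evaluation is blocked by experimental
run: either a 3-fold cross-validation over 3 runs (single-panel design) or
train-on-2 / test-on-6 (two-panel design).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.svm import SVC

from .preprocessing import EpochSet

DEFAULT_C_GRID = np.logspace(-5, 2, 15)


def featurize(epochs: EpochSet) -> np.ndarray:
    """Flatten epochs to (n_epochs, n_channels * n_samples) feature vectors.

    Channel blocks are concatenated in the EpochSet's channel order; for the
    canonical 0-600 ms window at 128 Hz this gives 32 x 77 = 2464 features.
    """
    n = len(epochs)
    return epochs.epochs.reshape(n, epochs.n_channels * epochs.n_samples)


@dataclass
class DecoderModel:
    """Trained linear target/non-target classifier."""

    weights: np.ndarray
    bias: float
    C: float
    n_channels: int
    n_samples: int
    window: tuple[float, float]
    sampling_rate: float
    grid: np.ndarray = field(repr=False, default=None)
    inner_folds: int = 10
    inner_cv_accuracy: float | None = None

    def decision(self, X: np.ndarray) -> np.ndarray:
        return np.atleast_2d(X) @ self.weights + self.bias


def train_decoder(
    train_epochs: EpochSet,
    seed: int,
    grid: np.ndarray = DEFAULT_C_GRID,
    inner_folds: int = 10,
) -> DecoderModel:
    """Fit the linear SVM on single-flash epochs with an inner C line search.

    The linear kernel is precomputed once and shared across the grid search,
    and the primal weight vector is recovered from the support-vector dual
    coefficients (w = X_sv' alpha), so the stored model scores plain feature
    vectors.
    """
    y = np.asarray(train_epochs.labels, dtype=bool)
    if y.all() or not y.any():
        raise ValueError("training set must contain target and non-target epochs")
    X = featurize(train_epochs)
    gram = X @ X.T
    search = GridSearchCV(
        SVC(kernel="precomputed"),
        {"C": np.asarray(grid)},
        cv=StratifiedKFold(n_splits=inner_folds, shuffle=True, random_state=seed),
        scoring="accuracy",
        n_jobs=None,
    )
    search.fit(gram, y)
    best = search.best_estimator_
    weights = X[best.support_].T @ best.dual_coef_.ravel()
    return DecoderModel(
        weights=weights,
        bias=float(best.intercept_[0]),
        C=float(search.best_params_["C"]),
        n_channels=train_epochs.n_channels,
        n_samples=train_epochs.n_samples,
        window=train_epochs.window,
        sampling_rate=train_epochs.sampling_rate,
        grid=np.asarray(grid),
        inner_folds=inner_folds,
        inner_cv_accuracy=float(search.best_score_),
    )


@dataclass
class TrialScore:
    """Decision outcome of one trial at one repetition count."""

    trial: int
    n_r: int
    scores: dict[int, float]        # per-icon decision value
    detected_icon: int
    cued_icon: int
    correct: int
    tie: bool = False


def score_trial(model: DecoderModel, trial_epochs: EpochSet, n_r: int) -> TrialScore:
    """Score one trial: average each icon's first-N_r epochs, pick the argmax.

    ``trial_epochs`` must hold the epochs of a single trial on the cued panel.
    Ties between icons break to the lowest icon id (flagged).
    """
    idx = trial_epochs.index
    trials = idx["trial"].unique()
    if len(trials) != 1:
        raise ValueError("trial_epochs must contain exactly one trial")
    trial = int(trials[0])
    cued = trial_epochs.trial_targets.set_index("trial").loc[trial, "target_icon"]

    icons = sorted(idx["icon"].unique())
    scores: dict[int, float] = {}
    for icon in icons:
        mask = (idx["icon"] == icon) & (idx["repetition"] <= n_r)
        if not mask.any():
            raise ValueError(f"no epochs for icon {icon} within the first {n_r} repetitions")
        mean_epoch = trial_epochs.epochs[mask.to_numpy()].mean(axis=0)
        scores[int(icon)] = float(model.decision(mean_epoch.reshape(1, -1))[0])

    best = max(scores.values())
    winners = [i for i in icons if scores[i] == best]
    tie = len(winners) > 1
    if tie:
        warnings.warn(f"tied decoder scores for icons {winners}; choosing {winners[0]}")
    detected = int(winners[0])
    return TrialScore(
        trial=trial,
        n_r=n_r,
        scores=scores,
        detected_icon=detected,
        cued_icon=int(cued),
        correct=int(detected == cued),
        tie=tie,
    )


def _evaluate_run(
    model: DecoderModel, run: EpochSet, n_r_values, run_label
) -> list[dict]:
    """Correctness of every trial of one test run at every repetition count."""
    run = run.target_panel_only()
    rows = []
    for trial in run.index["trial"].unique():
        trial_set = run.select((run.index["trial"] == trial).to_numpy())
        for n_r in n_r_values:
            ts = score_trial(model, trial_set, n_r)
            rows.append(
                {
                    "test_run": run_label,
                    "trial": int(trial),
                    "n_r": int(n_r),
                    "correct": ts.correct,
                    "detected_icon": ts.detected_icon,
                    "cued_icon": ts.cued_icon,
                }
            )
    return rows


def _concatenate(runs: list[EpochSet]) -> EpochSet:
    """Stack runs into one EpochSet, offsetting trial ids to keep them unique."""
    ref = runs[0]
    indices, targets = [], []
    offset = 0
    for r in runs:
        idx = r.index.copy()
        idx["trial"] = idx["trial"] + offset
        tt = r.trial_targets.copy()
        tt["trial"] = tt["trial"] + offset
        indices.append(idx)
        targets.append(tt)
        offset += int(r.trial_targets["trial"].max()) + 1
    return EpochSet(
        epochs=np.concatenate([r.epochs for r in runs], axis=0),
        window=ref.window,
        labels=np.concatenate([np.asarray(r.labels, dtype=bool) for r in runs]),
        index=pd.concat(indices, ignore_index=True),
        trial_targets=pd.concat(targets, ignore_index=True),
        sampling_rate=ref.sampling_rate,
        channel_labels=list(ref.channel_labels),
        run_id="concatenated",
    )


def crossvalidate_runs(
    runs: list[EpochSet],
    scheme: str,
    seed: int,
    n_r_values=range(1, 11),
    grid: np.ndarray = DEFAULT_C_GRID,
    inner_folds: int = 10,
) -> pd.DataFrame:
    """Run-blocked evaluation of P300 decoding.

    ``scheme`` is ``"3-fold-by-run"`` (every run tested once, trained on the
    other two; requires 3 runs) or ``"train-2-test-6"`` (first two runs train,
    the rest test). Returns one row per (test run, trial, N_r) with the trial
    correctness. Training always uses each trial's cued-panel epochs.
    """
    rows: list[dict] = []
    if scheme == "3-fold-by-run":
        if len(runs) != 3:
            raise ValueError("3-fold-by-run requires exactly 3 runs")
        for k, test_run in enumerate(runs):
            train = _concatenate([r for i, r in enumerate(runs) if i != k])
            model = train_decoder(
                train.target_panel_only(), seed=seed + k, grid=grid, inner_folds=inner_folds
            )
            rows += _evaluate_run(model, test_run, n_r_values, run_label=k)
    elif scheme == "train-2-test-6":
        if len(runs) < 3:
            raise ValueError("train-2-test-6 requires at least 3 runs (2 train + tests)")
        train = _concatenate(runs[:2])
        model = train_decoder(
            train.target_panel_only(), seed=seed, grid=grid, inner_folds=inner_folds
        )
        for k, test_run in enumerate(runs[2:], start=2):
            rows += _evaluate_run(model, test_run, n_r_values, run_label=k)
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    return pd.DataFrame(rows)
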