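"""Stimulation paradigm: trial structure and flash scheduling.

A *trial* (stimulation cycle) of the hybrid speller runs: a 2 s cue, a 1 s
pause, flicker onset, oddball onset 500 ms later, 10 *flashing sequences*
in which each of the 6 icons of a panel is highlighted once in random order
for a uniformly random 200-300 ms, and a 1 s post-stimulation pause. A *run*
is 12 consecutive trials, cueing every selectable icon an equal number of
times in random order (twice for the single-panel designs, once for the
two-panel design).

With two panels the flash streams are scheduled independently per panel:
each panel draws its own icon orders and flash durations, so the streams
are not onset-synchronized (an optional config flag forces shared flash
timing while keeping independent orders).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: screen refresh rate (Hz) from which the usable flicker frequencies derive
REFRESH_RATE = 60.0
#: flicker frequencies realisable on a 60 Hz screen: 60/7, 60/6, 60/5, 60/4
STIMULATION_FREQUENCIES = (REFRESH_RATE / 7, 10.0, 12.0, 15.0)

FLASH_COLUMNS = ["onset", "duration", "icon", "panel", "repetition", "trial"]
TRIAL_COLUMNS = [
    "trial", "target_icon", "target_panel",
    "cue_onset", "flicker_onset", "oddball_onset", "trial_end",
]


@dataclass(frozen=True)
class ParadigmConfig:
    """Parameters of one experimental run of the hybrid speller paradigm."""

    n_icons_per_panel: int = 6
    n_panels: int = 1
    flicker_freq_per_panel: tuple[float, ...] | None = None
    oddball_present: bool = True
    n_repetitions: int = 10
    flash_duration_range: tuple[float, float] = (0.200, 0.300)
    cue_duration: float = 2.0
    pre_flicker_pause: float = 1.0
    flicker_lead: float = 0.5
    post_pause: float = 1.0
    n_trials_per_run: int = 12
    sampling_rate: float = 1024.0
    synchronize_panels: bool = False

    def __post_init__(self) -> None:
        lo, hi = self.flash_duration_range
        if not (0 < lo < hi):
            raise ValueError("flash_duration_range must satisfy 0 < low < high")
        if self.n_panels < 1 or self.n_icons_per_panel < 1:
            raise ValueError("need at least one panel and one icon per panel")
        freqs = self.flicker_freq_per_panel
        if freqs is not None:
            if len(freqs) != self.n_panels:
                raise ValueError("one flicker frequency per panel required")
            if len(set(freqs)) != len(freqs):
                raise ValueError("flicker frequencies must be distinct across panels")

    @property
    def n_icons(self) -> int:
        """Total number of selectable icons across panels."""
        return self.n_icons_per_panel * self.n_panels

    @property
    def mean_sequence_duration(self) -> float:
        """Expected duration of one flashing sequence (6 x 0.250 s = 1.5 s)."""
        lo, hi = self.flash_duration_range
        return self.n_icons_per_panel * (lo + hi) / 2

    @property
    def mean_trial_duration(self) -> float:
        """Expected trial duration: cue + pause + flicker lead + flashing + post pause."""
        return (
            self.cue_duration
            + self.pre_flicker_pause
            + self.flicker_lead
            + self.n_repetitions * self.mean_sequence_duration
            + self.post_pause
        )

    # -- canonical experiment designs -------------------------------------

    @classmethod
    def experiment1(cls, flicker_freq: float | None = None, **kw) -> "ParadigmConfig":
        """Single panel, oddball always on; ``flicker_freq`` None = pure oddball."""
        freqs = None if flicker_freq is None else (flicker_freq,)
        return cls(n_panels=1, flicker_freq_per_panel=freqs, oddball_present=True, **kw)

    @classmethod
    def experiment2(cls, flicker_freq: float, oddball: bool, **kw) -> "ParadigmConfig":
        """Single panel, flicker always on; oddball flashes present only in hybrid runs."""
        return cls(
            n_panels=1, flicker_freq_per_panel=(flicker_freq,),
            oddball_present=oddball, **kw,
        )

    @classmethod
    def experiment3(cls, flicker_freqs: tuple[float, float] = (12.0, 15.0), **kw) -> "ParadigmConfig":
        """Two panels flickering at distinct frequencies, both with oddball streams."""
        return cls(
            n_panels=2, flicker_freq_per_panel=tuple(flicker_freqs),
            oddball_present=True, **kw,
        )


@dataclass
class EventLog:
    """Complete stimulation timeline of one run.

    ``trials`` has one row per trial (cue target and the trial's landmark
    times); ``flashes`` one row per icon highlight with its onset, duration,
    icon id (0-based within panel), panel id, repetition index (1-based) and
    trial index.
    """

    trials: pd.DataFrame
    flashes: pd.DataFrame
    config: ParadigmConfig = field(repr=False, default=None)

    @property
    def run_duration(self) -> float:
        """Total run length in seconds (end of the last trial)."""
        return float(self.trials["trial_end"].iloc[-1])

    def trial_targets(self) -> pd.DataFrame:
        return self.trials[["trial", "target_icon", "target_panel"]].copy()

    def to_tsv(self, flashes_path, trials_path) -> None:
        self.flashes.to_csv(flashes_path, sep="\t", index=False)
        self.trials.to_csv(trials_path, sep="\t", index=False)


def make_schedule(config: ParadigmConfig, seed: int) -> EventLog:
    """Draw one full run timeline (cue order, flash orders, flash durations).

    Every selectable icon is cued ``n_trials_per_run / n_icons`` times in
    randomized order; that ratio must be a whole number. Within a trial each
    panel runs ``n_repetitions`` flashing sequences back-to-back, each a
    random permutation of its icons with independent uniform durations.
    """
    rng = np.random.default_rng(seed)
    if config.n_trials_per_run % config.n_icons != 0:
        raise ValueError(
            f"{config.n_trials_per_run} trials cannot cue {config.n_icons} icons "
            "a whole number of times each"
        )
    cues_per_icon = config.n_trials_per_run // config.n_icons
    # cue targets as (panel, icon) pairs, each repeated cues_per_icon times
    targets = [
        (panel, icon)
        for panel in range(config.n_panels)
        for icon in range(config.n_icons_per_panel)
    ] * cues_per_icon
    order = rng.permutation(len(targets))
    targets = [targets[i] for i in order]

    lo, hi = config.flash_duration_range
    trial_rows = []
    flash_rows = []
    t = 0.0
    for trial, (target_panel, target_icon) in enumerate(targets):
        cue_onset = t
        flicker_onset = cue_onset + config.cue_duration + config.pre_flicker_pause
        oddball_onset = flicker_onset + config.flicker_lead
        panel_ends = []
        shared = None  # shared durations when panels are onset-synchronized
        for panel in range(config.n_panels):
            n_flashes = config.n_repetitions * config.n_icons_per_panel
            if config.synchronize_panels:
                if shared is None:
                    shared = rng.uniform(lo, hi, size=n_flashes)
                durations = shared
            else:
                durations = rng.uniform(lo, hi, size=n_flashes)
            onsets = oddball_onset + np.concatenate(([0.0], np.cumsum(durations[:-1])))
            pos = 0
            for rep in range(1, config.n_repetitions + 1):
                for icon in rng.permutation(config.n_icons_per_panel):
                    flash_rows.append(
                        (onsets[pos], durations[pos], int(icon), panel, rep, trial)
                    )
                    pos += 1
            panel_ends.append(onsets[-1] + durations[-1])
        trial_end = max(panel_ends) + config.post_pause
        trial_rows.append(
            (trial, target_icon, target_panel,
             cue_onset, flicker_onset, oddball_onset, trial_end)
        )
        t = trial_end

    trials = pd.DataFrame(trial_rows, columns=TRIAL_COLUMNS)
    flashes = pd.DataFrame(flash_rows, columns=FLASH_COLUMNS)
    return EventLog(trials=trials, flashes=flashes, config=config)
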