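"""Target-ERP averaging and between-condition waveform correlations.

For each experimental condition (pure oddball, or hybrid with one of the four
flicker frequencies) the target-flash-locked epochs are averaged per channel.
Condition similarity is then quantified per channel by the Pearson correlation
across time between the two conditions' average waveforms, for all condition
pairs, each pair classed as oddball-vs-hybrid or hybrid-vs-hybrid.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .preprocessing import EpochSet

ODDBALL_CONDITION = "oddball"
CONDITIONS = ("oddball", "hybrid-8.57", "hybrid-10", "hybrid-12", "hybrid-15")


@dataclass
class ErpAverage:
    """Per-channel mean target ERP of one condition."""

    waveform: np.ndarray            # channels x samples, microvolts
    n_epochs_used: int
    condition: str
    window: tuple[float, float]
    sampling_rate: float
    channel_labels: list[str]

    def __post_init__(self) -> None:
        if self.n_epochs_used <= 0:
            raise ValueError("an ERP average needs at least one epoch")
        if not np.isfinite(self.waveform).all():
            raise ValueError("ERP waveform contains non-finite values")


def average_target_erp(epochs: EpochSet, condition: str = "unspecified") -> ErpAverage:
    """Sample-wise mean over the target-labelled epochs only."""
    mask = np.asarray(epochs.labels, dtype=bool)
    if not mask.any():
        raise ValueError("no target epochs to average")
    return ErpAverage(
        waveform=epochs.epochs[mask].mean(axis=0),
        n_epochs_used=int(mask.sum()),
        condition=condition,
        window=epochs.window,
        sampling_rate=epochs.sampling_rate,
        channel_labels=list(epochs.channel_labels),
    )


def pair_class(cond_a: str, cond_b: str) -> str:
    """'oddball-hybrid' when exactly one member is the pure-oddball condition."""
    n_odd = (cond_a == ODDBALL_CONDITION) + (cond_b == ODDBALL_CONDITION)
    return "oddball-hybrid" if n_odd == 1 else "hybrid-hybrid"


def condition_pair_correlations(erps: list[ErpAverage]) -> pd.DataFrame:
    """Per-channel Pearson r between average ERPs for every condition pair.

    Returns a tidy table (channel, condition_a, condition_b, pair, pair_class,
    r). A zero-variance waveform on a channel makes r undefined; it is
    reported as NaN, never as 0.
    """
    if len(erps) < 2:
        raise ValueError("need at least two conditions")
    ref = erps[0]
    for e in erps[1:]:
        if e.window != ref.window or e.sampling_rate != ref.sampling_rate:
            raise ValueError("all ERP averages must share one window and rate")
        if e.channel_labels != ref.channel_labels:
            raise ValueError("all ERP averages must share one channel set")

    rows = []
    for ea, eb in combinations(erps, 2):
        a, b = ea.waveform, eb.waveform
        a_c = a - a.mean(axis=1, keepdims=True)
        b_c = b - b.mean(axis=1, keepdims=True)
        denom = np.sqrt((a_c**2).sum(axis=1) * (b_c**2).sum(axis=1))
        # a constant waveform has no variance: r is undefined there, not 0
        degenerate = (np.ptp(a, axis=1) == 0) | (np.ptp(b, axis=1) == 0) | (denom == 0)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(~degenerate, (a_c * b_c).sum(axis=1) / denom, np.nan)
        for ch, r_ch in zip(ref.channel_labels, r):
            rows.append(
                {
                    "channel": ch,
                    "condition_a": ea.condition,
                    "condition_b": eb.condition,
                    "pair": f"{ea.condition}|{eb.condition}",
                    "pair_class": pair_class(ea.condition, eb.condition),
                    "r": r_ch,
                }
            )
    return pd.DataFrame(rows)
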