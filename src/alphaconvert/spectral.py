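"""Time-frequency decomposition and ERD/ERS normalization.

Power is computed by convolution with 6-cycle Morlet wavelets (2-25 Hz),
magnitude-squared per trial and averaged across trials; event-related
(de)synchronization is the percent change of the trial-averaged power
relative to the mean power in a pre-stimulus baseline window, per
frequency and channel: ``ERD = 100 * (P - Pb) / Pb`` (negative values =
desynchronization).  Bins closer to an epoch edge than half the wavelet
support are flagged invalid.

Trial selection before the spectral analysis follows the equal-trial rule:
both congruence conditions are subsampled to the smaller correct-trial
count, and a subject with fewer than two correct trials in either condition
is excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    DegenerateBaselineError,
    RereferenceError,
    SupportError,
)
from .synthgen import EpochArray

DEFAULT_FREQS = np.arange(2.0, 25.0 + 1e-9, 0.25)
BASELINE_WINDOWS_MS = {"encoding": (-2100.0, -1600.0), "memory": (-600.0, -100.0)}

# analysis windows for the band features: (freq Hz, (start, end) ms)
BAND_WINDOWS = {
    ("alpha", "encoding"): (8.5, (500.0, 1000.0)),
    ("alpha", "memory"): (8.5, (500.0, 1000.0)),
    ("beta", "encoding"): (15.75, (400.0, 900.0)),
    ("beta", "memory"): (16.25, (500.0, 1000.0)),
}


@dataclass
class BaselineWindow:
    start: float  # ms relative to onset
    end: float

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"baseline start {self.start} must precede end {self.end}")


@dataclass
class TFRGrid:
    freqs: np.ndarray
    times: np.ndarray  # ms relative to onset
    channels: Sequence[str]
    power: np.ndarray  # (n_freqs, n_times, n_channels), >= 0
    valid: np.ndarray  # (n_freqs, n_times) bool, False near edges
    n_trials_averaged: int


@dataclass
class ERDGrid:
    freqs: np.ndarray
    times: np.ndarray
    channels: Sequence[str]
    values: np.ndarray  # percent change; negative = desynchronization
    valid: np.ndarray
    baseline: BaselineWindow


@dataclass
class MatchResult:
    """Outcome of the equal-trial-count rule for one subject."""

    selected: dict  # condition -> list of retained trial indices
    excluded: bool
    reason: str | None = None

    @property
    def n_retained(self) -> int:
        return 0 if self.excluded else sum(len(v) for v in self.selected.values())


def common_average_reference(epoch: EpochArray) -> EpochArray:
    """Subtract the instantaneous mean across channels from every channel."""
    if epoch.data.shape[0] < 2:
        raise RereferenceError("common average reference needs at least 2 channels")
    data = epoch.data - epoch.data.mean(axis=0, keepdims=True)
    return replace(epoch, data=data)


def match_trial_counts(
    trials_by_condition: dict, seed: int | None = 0, min_trials: int = 2
) -> MatchResult:
    """Retain an identical number of trials per congruence condition.

    Both conditions keep ``min(n_A, n_B)`` trials; the larger condition is
    subsampled uniformly without replacement (seeded).  A subject with fewer
    than ``min_trials`` trials in either condition is flagged excluded
    rather than raising.
    """
    conds = list(trials_by_condition)
    if len(conds) < 2:
        return MatchResult(selected={}, excluded=True, reason="missing condition")
    counts = {c: len(v) for c, v in trials_by_condition.items()}
    if min(counts.values()) < min_trials:
        worst = min(counts, key=counts.get)
        return MatchResult(
            selected={},
            excluded=True,
            reason=f"condition {worst!r} has {counts[worst]} < {min_trials} correct trials",
        )
    k = min(counts.values())
    rng = np.random.default_rng(seed)
    selected = {}
    for c, idx in trials_by_condition.items():
        idx = list(idx)
        if len(idx) > k:
            keep = rng.choice(len(idx), size=k, replace=False)
            idx = [idx[i] for i in sorted(keep)]
        selected[c] = idx
    return MatchResult(selected=selected, excluded=False)


def retained_trial_counts(trials: pd.DataFrame, seed: int = 0) -> pd.Series:
    """Per-subject retained trial count after the equal-trial rule.

    Pools correctly recognized memory-phase trials by condition and applies
    :func:`match_trial_counts`; excluded subjects get NaN.
    """
    mem = trials[(trials["phase"] == "memory") & trials["correct"] & trials["responded"]]
    out = {}
    for sid, sub in mem.groupby("subject_id", sort=False):
        by_cond = {c: sub.index[sub["condition"] == c].tolist() for c in ("SCF", "SIF")}
        res = match_trial_counts(by_cond, seed=seed)
        out[sid] = np.nan if res.excluded else res.n_retained
    return pd.Series(out, name="n_retained")


def _half_support_s(freq: float, n_cycles: float) -> float:
    # half the wavelet support, taken as (n_cycles / freq) / 2 seconds
    return 0.5 * n_cycles / freq


def morlet_tfr(epoch: EpochArray, freqs: np.ndarray | None = None, n_cycles: float = 6.0) -> TFRGrid:
    """Morlet time-frequency power, averaged over trials after per-trial |.|^2."""
    from mne.time_frequency import tfr_array_morlet  # deferred: mne import is slow

    freqs = np.asarray(DEFAULT_FREQS if freqs is None else freqs, dtype=float)
    times = epoch.times_ms()
    span_s = (times[-1] - times[0]) / 1000.0
    too_long = [f for f in freqs if 2.0 * _half_support_s(f, n_cycles) >= span_s]
    if too_long:
        raise SupportError(
            f"epoch of {span_s:.2f}s cannot hold {n_cycles}-cycle wavelets at "
            f"frequencies {too_long} Hz"
        )
    data = epoch.data.transpose(2, 0, 1)  # (n_trials, n_channels, n_samples)
    power = tfr_array_morlet(
        data,
        sfreq=epoch.sampling_rate,
        freqs=freqs,
        n_cycles=n_cycles,
        output="power",
        zero_mean=True,
    )  # (n_trials, n_channels, n_freqs, n_times)
    avg = power.mean(axis=0).transpose(1, 2, 0)  # (freq, time, channel)

    valid = np.ones((freqs.size, times.size), dtype=bool)
    for i, f in enumerate(freqs):
        half_ms = 1000.0 * _half_support_s(f, n_cycles)
        valid[i] = (times >= times[0] + half_ms) & (times <= times[-1] - half_ms)
    return TFRGrid(
        freqs=freqs,
        times=times,
        channels=list(epoch.channels),
        power=avg,
        valid=valid,
        n_trials_averaged=epoch.n_trials,
    )


def erd(tfr: TFRGrid, baseline: BaselineWindow) -> ERDGrid:
    """Percent power change relative to the mean baseline power per freq x channel."""
    in_base = (tfr.times >= baseline.start) & (tfr.times <= baseline.end)
    if not in_base.any():
        raise DegenerateBaselineError(
            f"baseline [{baseline.start}, {baseline.end}] ms contains no time bins"
        )
    bad = [float(f) for i, f in enumerate(tfr.freqs) if not tfr.valid[i, in_base].all()]
    if bad:
        raise DegenerateBaselineError(
            f"baseline bins are edge-contaminated at frequencies {bad} Hz; "
            "use a longer epoch or restrict the frequency grid"
        )
    base = tfr.power[:, in_base, :].mean(axis=1, keepdims=True)
    if np.any(base <= 0):
        raise DegenerateBaselineError("zero baseline power at some frequency/channel")
    values = 100.0 * (tfr.power - base) / base
    return ERDGrid(
        freqs=tfr.freqs,
        times=tfr.times,
        channels=tfr.channels,
        values=values,
        valid=tfr.valid,
        baseline=baseline,
    )


def band_window_mean(grid: ERDGrid, freq: float, window_ms: tuple, channel: int | None = None):
    """Mean ERD at the grid frequency nearest ``freq`` over a time window."""
    fi = int(np.argmin(np.abs(grid.freqs - freq)))
    w0, w1 = window_ms
    sel = (grid.times >= w0) & (grid.times <= w1) & grid.valid[fi]
    if not sel.any():
        raise DegenerateBaselineError(f"no valid bins at {freq} Hz within {window_ms} ms")
    block = grid.values[fi][sel]
    return float(block.mean()) if channel is None else float(block[:, channel].mean())
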