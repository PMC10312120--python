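"""Transient beta-burst detection in single-trial time-frequency power.

A time-frequency point is marked when its power exceeds the within-trial
mean + 2 SD of its frequency row (computed over the full epoch time axis),
and a contiguous supra-threshold run within a row is kept only if it lasts
at least one cycle (1/frequency). Marked points are clustered into burst
events by 4-connectivity (adjacent in time OR frequency, not diagonal), and
six parameters are read from each trial: the event count in the analysis
window and, for the event containing the globally highest-power point, its
peak power, peak time, peak frequency, frequency range and time range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .containers import TFRSet
from .synthetic import SyntheticGroundTruth

__all__ = [
    "BurstEvent",
    "BurstParams",
    "burst_mask",
    "cluster_events",
    "burst_parameters",
    "trial_burst_params",
    "params_table",
    "recover_injected",
]


@dataclass
class BurstEvent:
    """One connected supra-threshold component of a single-trial TFR."""

    points: list[tuple[int, int]]  # (freq bin, time bin)
    peak_power: float
    peak_freq: float  # Hz
    peak_time: float  # seconds
    freq_range: float  # Hz (max - min member frequency)
    time_range: float  # seconds (max - min member time)
    peak_point: tuple[int, int]


@dataclass
class BurstParams:
    """Per-trial six-tuple; the five peak parameters are NaN when n_events=0."""

    n_events: int
    peak_power: float = np.nan
    peak_time: float = np.nan
    peak_freq: float = np.nan
    freq_range: float = np.nan
    time_range: float = np.nan


def burst_mask(tfr_trial: np.ndarray, freqs: np.ndarray,
               times: np.ndarray) -> np.ndarray:
    """Supra-threshold mask for one trial's freqs x times power grid.

    Thresholds are per frequency row: within-trial mean + 2 * within-trial
    SD (sample SD, ddof=1) over the full time axis; marks are strict
    exceedances, so a constant row yields no marks. Runs shorter than one
    cycle (1/f seconds) are then cleared row by row.
    """
    tfr_trial = np.asarray(tfr_trial, dtype=float)
    if tfr_trial.shape[1] < 2:
        raise ValueError("need at least 2 time points per frequency row")
    mu = tfr_trial.mean(axis=1, keepdims=True)
    sd = tfr_trial.std(axis=1, ddof=1, keepdims=True)
    mask = tfr_trial > mu + 2 * sd
    dt = float(times[1] - times[0])
    for i, f in enumerate(freqs):
        row = mask[i]
        if not row.any():
            continue
        min_bins = int(np.ceil((1.0 / f) / dt - 1e-9))
        # clear contiguous runs shorter than one cycle of this frequency
        edges = np.flatnonzero(np.diff(np.r_[0, row.astype(int), 0]))
        for start, stop in zip(edges[::2], edges[1::2]):
            if stop - start < min_bins:
                row[start:stop] = False
    return mask


def cluster_events(mask: np.ndarray, tfr_trial: np.ndarray,
                   freqs: np.ndarray, times: np.ndarray) -> list[BurstEvent]:
    """Connected components of the mask under 4-connectivity, one event each."""
    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    labels, n = ndimage.label(mask, structure=structure)
    events: list[BurstEvent] = []
    for lab in range(1, n + 1):
        fi, ti = np.nonzero(labels == lab)
        powers = tfr_trial[fi, ti]
        # tie-break at equal power: earliest time, then lowest frequency
        order = np.lexsort((fi, ti, -powers))
        best = order[0]
        events.append(
            BurstEvent(
                points=list(zip(fi.tolist(), ti.tolist())),
                peak_power=float(powers[best]),
                peak_freq=float(freqs[fi[best]]),
                peak_time=float(times[ti[best]]),
                freq_range=float(freqs[fi.max()] - freqs[fi.min()]),
                time_range=float(times[ti.max()] - times[ti.min()]),
                peak_point=(int(fi[best]), int(ti[best])),
            )
        )
    return events


def burst_parameters(events: list[BurstEvent],
                     window: tuple[float, float] | None = None) -> BurstParams:
    """Six burst parameters for one trial.

    An event belongs to the analysis window if its peak point lies inside it
    (closed interval). Among the retained events, the maximal event is the
    one containing the highest-power point; its five parameters are
    extracted. With no events everything except the count is NaN.
    """
    if window is not None:
        events = [e for e in events
                  if window[0] - 1e-12 <= e.peak_time <= window[1] + 1e-12]
    if not events:
        return BurstParams(n_events=0)
    best = max(
        events,
        key=lambda e: (e.peak_power, -e.peak_time, -e.peak_freq),
    )
    return BurstParams(
        n_events=len(events),
        peak_power=best.peak_power,
        peak_time=best.peak_time,
        peak_freq=best.peak_freq,
        freq_range=best.freq_range,
        time_range=best.time_range,
    )


def trial_burst_params(
    tfr_set: TFRSet,
    channel: str,
    window: tuple[float, float] = (-0.7, 0.0),
) -> tuple[list[BurstParams], list[list[BurstEvent]]]:
    """Detect bursts on every trial of one channel and extract parameters.

    Thresholding uses the full TFR time axis of each trial; the window is
    applied only when counting events and picking the maximal one.
    """
    tfrs = tfr_set.channel(channel)
    params: list[BurstParams] = []
    all_events: list[list[BurstEvent]] = []
    for tr in range(tfrs.shape[0]):
        mask = burst_mask(tfrs[tr], tfr_set.freqs, tfr_set.times)
        events = cluster_events(mask, tfrs[tr], tfr_set.freqs, tfr_set.times)
        all_events.append(events)
        params.append(burst_parameters(events, window=window))
    return params, all_events


def params_table(params: list[BurstParams], window: str = "pretarget"):
    """Per-trial burst parameters as a DataFrame (times in ms, freqs in Hz),
    ready for CSV export."""
    import pandas as pd

    return pd.DataFrame({
        "trial": np.arange(len(params)),
        "window": window,
        "n_events": [p.n_events for p in params],
        "peak_power": [p.peak_power for p in params],
        "peak_time_ms": [p.peak_time * 1e3 for p in params],
        "peak_freq_hz": [p.peak_freq for p in params],
        "freq_range_hz": [p.freq_range for p in params],
        "time_range_ms": [p.time_range * 1e3 for p in params],
    })


def recover_injected(
    events_per_trial: list[list[BurstEvent]],
    ground_truth: SyntheticGroundTruth,
    channel: str,
    window: str = "pretarget",
    tol_freq: float = 2.0,
    tol_time: float = 0.100,
) -> tuple[float | None, float]:
    """Score detected events against injected bursts.

    An injected burst counts as recovered when some detected event's peak in
    the same trial lies within ``tol_freq`` Hz and ``tol_time`` s of the
    burst's centre. Recall = recovered / injected (None when nothing was
    injected); precision = events matched to some injection / all events.
    """
    truths = [r for r in ground_truth.records_in(window) if r.channel == channel]
    n_events = sum(len(ev) for ev in events_per_trial)
    matched_events = 0
    recovered = 0
    by_trial: dict[int, list] = {}
    for r in truths:
        by_trial.setdefault(r.trial, []).append(r)
    for tr, events in enumerate(events_per_trial):
        recs = by_trial.get(tr, [])
        hit_recs = set()
        for e in events:
            ok = False
            for k, r in enumerate(recs):
                if (abs(e.peak_freq - r.freq) <= tol_freq
                        and abs(e.peak_time - r.t_center) <= tol_time):
                    ok = True
                    hit_recs.add(k)
            matched_events += ok
        recovered += len(hit_recs)
    recall = None if not truths else recovered / len(truths)
    precision = 1.0 if n_events == 0 else matched_events / n_events
    return recall, precision
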