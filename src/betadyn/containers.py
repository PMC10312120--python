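"""Core in-memory containers for epoched two-channel data and derived spectra.

The pipeline operates on trial-epoched virtual-channel time series (here:
"motor" and "auditory" cortex), time-locked either to target onset
(``pretarget`` window) or to cue onset (``precue`` window), with one reaction
time per trial.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np


class SchemaError(ValueError):
    """A container or file violates the expected layout; names the field."""


@dataclass
class EpochSet:
    """Trials x channels x samples of epoched signal.

    Parameters
    ----------
    data
        Array of shape ``(n_trials, n_channels, n_samples)``.
    fs
        Sampling rate in Hz.
    t0
        Time of the first sample in seconds, relative to the locking event
        (target onset for ``pretarget`` epochs, cue onset for ``precue``).
    ch_names
        Channel names, e.g. ``("motor", "auditory")``.
    window
        Label of the analysis window these epochs belong to.
    rts
        Optional per-trial reaction times in milliseconds (all > 0).
    """

    data: np.ndarray
    fs: float
    t0: float
    ch_names: tuple[str, ...]
    window: str = "pretarget"
    rts: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x samples")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if len(self.ch_names) != self.data.shape[1]:
            raise SchemaError("ch_names length does not match data channels")
        if self.rts is not None:
            self.rts = np.asarray(self.rts, dtype=float)
            if self.rts.shape != (self.n_trials,):
                raise SchemaError("rts length does not match number of trials")
            if np.any(self.rts <= 0):
                raise ValueError("rts must be strictly positive")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        """Time axis in seconds, strictly increasing with spacing 1/fs."""
        return self.t0 + np.arange(self.n_samples) / self.fs

    def channel(self, name: str) -> np.ndarray:
        """Return the trials x samples array for one named channel."""
        try:
            idx = self.ch_names.index(name)
        except ValueError:
            raise KeyError(f"no channel named {name!r}") from None
        return self.data[:, idx, :]

    def copy(self, **changes) -> "EpochSet":
        out = replace(self, **changes)
        if "data" not in changes:
            out.data = self.data.copy()
        if "rts" not in changes and self.rts is not None:
            out.rts = self.rts.copy()
        return out

    def crop(self, tmin: float, tmax: float) -> "EpochSet":
        """Return samples with ``tmin <= t < tmax`` (half-open window)."""
        t = self.times
        eps = 0.5 / self.fs
        sel = (t >= tmin - eps) & (t < tmax - eps)
        if not np.any(sel):
            raise ValueError("crop window contains no samples")
        return self.copy(data=self.data[:, :, sel], t0=float(t[sel][0]))


@dataclass
class SpectrumSet:
    """Single-trial Fourier coefficients and log-power on a regular grid.

    ``coefs`` has shape (trials, channels, freqs); ``log_power`` is the
    natural log of |coef|^2. ``freqs`` spacing equals 1/pad_to exactly.
    """

    coefs: np.ndarray
    log_power: np.ndarray
    freqs: np.ndarray
    ch_names: tuple[str, ...]
    floored: bool = False  # True if any zero-power bin was floored before log

    @property
    def df(self) -> float:
        return float(self.freqs[1] - self.freqs[0])

    def power(self) -> np.ndarray:
        return np.abs(self.coefs) ** 2

    def channel_index(self, name: str) -> int:
        return self.ch_names.index(name)


@dataclass
class TFRSet:
    """Trials x channels x frequencies x times of (optionally normalized) power."""

    power: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    ch_names: tuple[str, ...]
    norm_factors: np.ndarray | None = None  # per-channel, set after normalization

    def __post_init__(self) -> None:
        self.power = np.asarray(self.power, dtype=float)
        if self.power.ndim != 4:
            raise ValueError("power must be trials x channels x freqs x times")
        if self.power.shape[2] != len(self.freqs):
            raise SchemaError("freqs length mismatch")
        if self.power.shape[3] != len(self.times):
            raise SchemaError("times length mismatch")

    @property
    def n_trials(self) -> int:
        return self.power.shape[0]

    def channel(self, name: str) -> np.ndarray:
        return self.power[:, self.ch_names.index(name), :, :]
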