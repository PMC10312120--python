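"""Spectral analysis: 1/f flattening, single-trial Fourier spectra, and
sliding-window time-frequency representations (TFRs).

The analysis chain mirrors a standard pretarget-interval workflow: the raw
epochs are differentiated once to flatten the aperiodic 1/f background, then
single-trial spectra are computed with a Hanning taper zero-padded to 2 s
(0.5 Hz resolution), and a 250-ms sliding-window TFR is evaluated on a
13-30 Hz x (-750..+250 ms) grid.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import fft as spfft
from scipy.signal import get_window

from .containers import EpochSet, SpectrumSet, TFRSet

BETA_BAND = (13.0, 30.0)

__all__ = [
    "BETA_BAND",
    "differentiate",
    "fourier_spectra",
    "tfr",
    "normalize_tfr",
    "band_power_timecourse",
]


def differentiate(epochs: EpochSet) -> EpochSet:
    """First temporal derivative of each trace, in signal units per second.

    Differencing multiplies the power spectrum by ~(2*pi*f)^2 and thereby
    flattens a 1/f^2 background; it is the default 1/f-removal step applied
    before all spectral, burst and instantaneous-frequency analyses.

    The output is one sample shorter and its time axis sits on the midpoints
    of the original sample intervals.
    """
    if epochs.n_samples < 2:
        raise ValueError("differentiate requires at least 2 samples")
    d = np.diff(epochs.data, axis=-1) * epochs.fs
    return EpochSet(
        data=d,
        fs=epochs.fs,
        t0=epochs.t0 + 0.5 / epochs.fs,
        ch_names=epochs.ch_names,
        window=epochs.window,
        rts=None if epochs.rts is None else epochs.rts.copy(),
    )


def fourier_spectra(
    epochs: EpochSet,
    window: tuple[float, float] = (-0.7, 0.0),
    pad_to: float = 2.0,
    fmax: float = 30.0,
    taper: bool = True,
) -> SpectrumSet:
    """Single-trial Fourier spectra of one analysis window.

    A Hanning taper is applied across the window and the tapered segment is
    zero-padded to ``pad_to`` seconds, giving a frequency resolution of
    exactly ``1/pad_to`` Hz (0.5 Hz for the default 2 s). Log-power is the
    natural log of |coef|^2; zero-power bins are floored at the smallest
    positive float with a warning.

    Set ``taper=False`` for the plain (rectangular-window) FFT variant.
    """
    cropped = epochs.crop(*window)
    n = cropped.n_samples
    if n == 0:
        raise ValueError("empty analysis window")
    n_pad = int(round(pad_to * epochs.fs))
    if n_pad < n:
        raise ValueError("pad_to must be at least the window length")
    x = cropped.data
    if taper:
        x = x * get_window("hann", n, fftbins=False)
    coefs = spfft.rfft(x, n=n_pad, axis=-1)
    freqs = spfft.rfftfreq(n_pad, d=1.0 / epochs.fs)
    keep = freqs <= fmax + 1e-12
    coefs = coefs[..., keep]
    freqs = freqs[keep]
    power = np.abs(coefs) ** 2
    floored = bool(np.any(power == 0))
    if floored:
        warnings.warn("zero-power bins floored before log", RuntimeWarning)
        power = np.where(power == 0, np.finfo(float).tiny, power)
    return SpectrumSet(
        coefs=coefs,
        log_power=np.log(power),
        freqs=freqs,
        ch_names=epochs.ch_names,
        floored=floored,
    )


def default_foi() -> np.ndarray:
    """13..30 Hz in 0.5 Hz steps (35 bins)."""
    return np.arange(13.0, 30.0 + 1e-9, 0.5)


def default_toi() -> np.ndarray:
    """-750..+250 ms in 20 ms steps (51 time points)."""
    return np.arange(-0.75, 0.25 + 1e-9, 0.02)


def tfr(
    epochs: EpochSet,
    foi: np.ndarray | None = None,
    toi: np.ndarray | None = None,
    window: float = 0.25,
) -> TFRSet:
    """Hanning-tapered short-time Fourier power on an exact (foi x toi) grid.

    Implemented as multiplication in the frequency domain: for each frequency
    f the full epoch is convolved (via FFT) with a Hanning-windowed complex
    exponential of length ``window`` seconds, and |.|^2 is read out at the
    requested time points. This is numerically the same as a windowed FFT
    evaluated at f for each window position.

    Epochs must extend at least ``window/2`` beyond the toi extremes;
    otherwise the estimate would silently mix in zero-padding and an error is
    raised instead.
    """
    foi = default_foi() if foi is None else np.asarray(foi, dtype=float)
    toi = default_toi() if toi is None else np.asarray(toi, dtype=float)
    fs = epochs.fs
    t = epochs.times
    half = window / 2.0
    eps = 0.5 / fs
    if toi.min() - half < t[0] - eps or toi.max() + half > t[-1] + eps:
        raise ValueError(
            "toi +/- window/2 exceeds the epoch span; supply longer epochs"
        )

    n_win = int(round(window * fs))
    if n_win < 2:
        raise ValueError("window too short")
    n = epochs.n_samples
    nfft = spfft.next_fast_len(n + n_win)
    X = spfft.fft(epochs.data, n=nfft, axis=-1)  # (trials, ch, nfft)

    taper = get_window("hann", n_win, fftbins=False)
    # map each toi to the sample index of the window centre
    centre_idx = np.round((toi - t[0]) * fs).astype(int)
    win_t = (np.arange(n_win) - (n_win - 1) / 2.0) / fs

    power = np.empty(
        (epochs.n_trials, epochs.n_channels, len(foi), len(toi)), dtype=float
    )
    for i, f in enumerate(foi):
        kernel = taper * np.exp(-2j * np.pi * f * win_t)
        K = spfft.fft(kernel, n=nfft)
        conv = spfft.ifft(X * K, axis=-1)
        # sample 'full' convolution so the kernel is centred on each toi
        idx = centre_idx + (n_win - 1) // 2
        power[:, :, i, :] = np.abs(conv[..., idx]) ** 2
    return TFRSet(power=power, freqs=foi, times=toi, ch_names=epochs.ch_names)


def normalize_tfr(tfr_set: TFRSet) -> TFRSet:
    """Divide each channel by its grand-mean power over trials x freqs x times.

    After normalization the grand mean per channel is exactly 1, making power
    comparable across channels with different source depths / signal scales.
    """
    factors = tfr_set.power.mean(axis=(0, 2, 3))
    if np.any(factors <= 0):
        raise ValueError("degenerate input: non-positive mean power")
    out = tfr_set.power / factors[None, :, None, None]
    return TFRSet(
        power=out,
        freqs=tfr_set.freqs.copy(),
        times=tfr_set.times.copy(),
        ch_names=tfr_set.ch_names,
        norm_factors=factors,
    )


def band_power_timecourse(
    tfr_set: TFRSet, band: tuple[float, float] = BETA_BAND
) -> np.ndarray:
    """Mean power over the frequency rows inside ``band`` (inclusive).

    Returns an array of shape (trials, channels, times).
    """
    sel = (tfr_set.freqs >= band[0] - 1e-9) & (tfr_set.freqs <= band[1] + 1e-9)
    if not np.any(sel):
        raise ValueError("band contains no TFR frequency bins")
    return tfr_set.power[:, :, sel, :].mean(axis=2)
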