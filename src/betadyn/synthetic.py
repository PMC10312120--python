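"""Synthetic two-channel epoch generator with full ground truth.

Emulates the statistical structure the analysis pipeline assumes in real
pretarget MEG data:

* 1/f^alpha background activity (frequency-domain amplitude shaping of
  Gaussian white noise),
* transient beta bursts (Hanning-windowed sinusoids, Poisson counts per
  trial) with controllable amplitude, frequency and duration,
* a directed, lagged motor -> auditory coupling in the beta band, and
* reaction times generated as a noisy linear function of motor beta power,
  auditory beta frequency and coupling strength.

Every injected burst, per-trial coupling strength and RT-model coefficient is
recorded in a :class:`SyntheticGroundTruth`, so each pipeline stage can be
validated by parameter recovery without any recorded data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
import yaml

from .containers import EpochSet

__all__ = [
    "SimConfig",
    "BurstRecord",
    "SyntheticGroundTruth",
    "SimDataset",
    "generate_noise",
    "inject_bursts",
    "couple_channels",
    "generate_rts",
    "make_dataset",
]

RT_FLOOR_MS = 100.0  # physiological floor; RTs are clipped here, never negative


@dataclass
class SimConfig:
    """Generator settings; defaults reproduce the study's design.

    ``n_trials`` defaults to 600 (ten blocks of 60 trials, pooled over cue
    conditions). The RT model is
    ``RT = b0 + bP*z(P) + bF*z(F) + bC*z(C) + eps`` with P the trial's motor
    beta power, F its auditory beta frequency and C its motor->auditory
    coupling gain; coefficients are in ms per z-unit.
    """

    n_trials: int = 600
    fs: float = 300.0
    epoch_span: tuple[float, float] = (-1.0, 0.4)
    precue_span: tuple[float, float] = (-1.0, 0.4)
    noise_exponent: float = 1.0
    burst_rate: float = 2.0  # Poisson mean bursts per trial, per channel
    burst_freq_range: tuple[float, float] = (13.0, 30.0)
    burst_cycles: tuple[float, float] = (2.0, 6.0)
    burst_amp: float = 5.0  # amplitude in units of the background SD
    coupling_gain: float = 0.8
    coupling_lag: float = 0.02  # seconds, motor leads auditory
    rt_coefs: tuple[float, float, float, float] = (500.0, 30.0, 20.0, 20.0)
    rt_noise_sd: float = 50.0  # ms
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.fs <= 2 * self.burst_freq_range[1]:
            raise ValueError("fs must exceed twice the upper burst frequency")
        lo, hi = self.burst_freq_range
        if not (0 < lo < hi < self.fs / 2):
            raise ValueError("burst_freq_range must lie inside (0, fs/2)")
        if self.rt_noise_sd < 0:
            raise ValueError("rt_noise_sd must be >= 0")
        if self.epoch_span[1] <= self.epoch_span[0]:
            raise ValueError("epoch_span must be increasing")

    def to_yaml(self, path) -> None:
        d = asdict(self)
        for k in ("epoch_span", "precue_span", "burst_freq_range",
                  "burst_cycles", "rt_coefs"):
            d[k] = list(d[k])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if not isinstance(d, dict):
            raise ValueError("config YAML must be a mapping")
        for k in ("epoch_span", "precue_span", "burst_freq_range",
                  "burst_cycles", "rt_coefs"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


@dataclass
class BurstRecord:
    trial: int
    channel: str
    t_center: float  # seconds relative to locking event
    freq: float  # Hz
    duration: float  # seconds
    amplitude: float
    window: str = "pretarget"


@dataclass
class SyntheticGroundTruth:
    """Everything needed to score the pipeline by parameter recovery."""

    burst_records: list[BurstRecord]
    rt_features: dict[str, np.ndarray]  # keys "P", "F", "C", per trial
    rt_coefs: tuple[float, float, float, float]
    seed: int

    def records_in(self, window: str) -> list[BurstRecord]:
        return [r for r in self.burst_records if r.window == window]

    def to_json(self, path) -> None:
        obj = {
            "burst_records": [asdict(r) for r in self.burst_records],
            "rt_features": {k: np.asarray(v).tolist()
                            for k, v in self.rt_features.items()},
            "rt_coefs": list(self.rt_coefs),
            "seed": int(self.seed),
        }
        with open(path, "w") as fh:
            json.dump(obj, fh)

    @classmethod
    def from_json(cls, path) -> "SyntheticGroundTruth":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(
            burst_records=[BurstRecord(**r) for r in obj["burst_records"]],
            rt_features={k: np.asarray(v) for k, v in obj["rt_features"].items()},
            rt_coefs=tuple(obj["rt_coefs"]),
            seed=obj["seed"],
        )


@dataclass
class SimDataset:
    pretarget: EpochSet
    precue: EpochSet
    rts: np.ndarray
    ground_truth: SyntheticGroundTruth


def generate_noise(
    n_trials: int,
    n_samples: int,
    fs: float,
    exponent: float = 1.0,
    seed: int = 0,
    n_channels: int = 1,
) -> np.ndarray:
    """1/f^exponent background noise, globally scaled to unit SD.

    White Gaussian noise is shaped in the frequency domain by f^(-exponent/2)
    (the DC bin is zeroed), which gives an expected power spectrum
    proportional to 1/f^exponent while keeping Gaussian statistics and
    uniformly distributed phases. Returns (n_trials, n_channels, n_samples).
    """
    if n_trials < 1 or fs <= 0:
        raise ValueError("n_trials and fs must be positive")
    if n_samples < 64:
        raise ValueError("n_samples must be >= 64")
    if exponent < 0:
        raise ValueError("exponent must be >= 0")
    rng = np.random.default_rng(seed)
    w = rng.standard_normal((n_trials, n_channels, n_samples))
    W = np.fft.rfft(w, axis=-1)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    shape = np.zeros_like(freqs)
    shape[1:] = freqs[1:] ** (-exponent / 2.0)
    W *= shape
    x = np.fft.irfft(W, n=n_samples, axis=-1)
    x -= x.mean(axis=-1, keepdims=True)
    sd = x.std()
    if sd > 0:
        x /= sd
    return x


def _burst_waveform(t: np.ndarray, t_center: float, freq: float,
                    duration: float, amplitude: float, phase: float) -> np.ndarray:
    """Hanning-windowed sinusoid A*w(t)*sin(2*pi*f*t + phi), zero outside."""
    rel = t - (t_center - duration / 2.0)
    inside = (rel >= 0) & (rel <= duration)
    w = np.zeros_like(t)
    win = 0.5 * (1 - np.cos(2 * np.pi * rel[inside] / duration))
    w[inside] = amplitude * win * np.sin(2 * np.pi * freq * t[inside] + phase)
    return w


def inject_bursts(
    epochs: EpochSet,
    rate: float,
    freq_range: tuple[float, float] = (13.0, 30.0),
    cycles_range: tuple[float, float] = (2.0, 6.0),
    amp: float = 5.0,
    seed: int = 0,
    channels: tuple[str, ...] | None = None,
    freq_per_trial: dict[str, np.ndarray] | None = None,
    center_span: tuple[float, float] | None = None,
) -> tuple[EpochSet, list[BurstRecord]]:
    """Add Poisson-distributed beta bursts in place and record each injection.

    Per trial and channel the burst count is drawn Poisson(rate). Each burst
    is a Hanning-windowed sinusoid with uniform random phase, frequency drawn
    uniformly from ``freq_range`` (or fixed per trial via ``freq_per_trial``,
    keyed by channel name), duration drawn uniformly in cycles and converted
    through 1/f, and centre placed uniformly so the burst fits inside
    ``center_span`` (default: the whole epoch).
    """
    if freq_range[1] >= epochs.fs / 2:
        raise ValueError("burst frequencies must be below Nyquist")
    t = epochs.times
    span = center_span if center_span is not None else (t[0], t[-1])
    max_dur = cycles_range[1] / freq_range[0]
    if max_dur > span[1] - span[0]:
        raise ValueError("burst duration exceeds the placement span")
    rng = np.random.default_rng(seed)
    out = epochs.copy()
    records: list[BurstRecord] = []
    channels = epochs.ch_names if channels is None else channels
    for ch in channels:
        ci = epochs.ch_names.index(ch)
        counts = rng.poisson(rate, size=epochs.n_trials)
        for tr in range(epochs.n_trials):
            for _ in range(counts[tr]):
                if freq_per_trial is not None and ch in freq_per_trial:
                    f = float(freq_per_trial[ch][tr])
                else:
                    f = rng.uniform(*freq_range)
                cyc = rng.uniform(*cycles_range)
                dur = cyc / f
                lo, hi = span[0] + dur / 2, span[1] - dur / 2
                tc = rng.uniform(lo, hi) if hi > lo else (lo + hi) / 2
                phase = rng.uniform(0, 2 * np.pi)
                out.data[tr, ci, :] += _burst_waveform(t, tc, f, dur, amp, phase)
                records.append(BurstRecord(tr, ch, tc, f, dur, amp,
                                           window=epochs.window))
    return out, records


def _beta_bandpass(x: np.ndarray, fs: float,
                   band: tuple[float, float]) -> np.ndarray:
    # local import: instfreq owns the zero-phase FIR design
    from .instfreq import bandpass_array

    return bandpass_array(x, fs, band)


def couple_channels(
    epochs: EpochSet,
    gain: float | np.ndarray,
    lag: float = 0.02,
    band: tuple[float, float] = (13.0, 30.0),
    src: str = "motor",
    dst: str = "auditory",
) -> EpochSet:
    """Add a lagged, band-limited copy of ``src`` into ``dst``.

    ``dst += gain * delay(bandpass(src), lag)``; ``gain`` may be a per-trial
    array (stored in the ground truth as the coupling strength C). The lag is
    rounded to whole samples and the delayed trace is zero-padded at the
    epoch start.
    """
    t = epochs.times
    if lag >= t[-1] - t[0]:
        raise ValueError("lag must be shorter than the epoch")
    if not (0 < band[0] < band[1] < epochs.fs / 2):
        raise ValueError("band must lie inside (0, fs/2)")
    gain = np.asarray(gain, dtype=float)
    if gain.ndim == 1 and gain.shape[0] != epochs.n_trials:
        raise ValueError("per-trial gain length must match trial count")
    out = epochs.copy()
    src_bp = _beta_bandpass(epochs.channel(src), epochs.fs, band)
    shift = int(round(lag * epochs.fs))
    delayed = np.zeros_like(src_bp)
    if shift < src_bp.shape[-1]:
        delayed[:, shift:] = src_bp[:, : src_bp.shape[-1] - shift]
    g = gain[:, None] if gain.ndim == 1 else gain
    out.data[:, epochs.ch_names.index(dst), :] += g * delayed
    return out


def _zscore(v: np.ndarray) -> np.ndarray:
    sd = v.std(ddof=0)
    if sd == 0:
        raise ValueError("degenerate input: feature has zero variance")
    return (v - v.mean()) / sd


def generate_rts(
    features: dict[str, np.ndarray],
    rt_coefs: tuple[float, float, float, float],
    rt_noise_sd: float,
    seed: int = 0,
) -> np.ndarray:
    """RT_i = b0 + bP*z(P_i) + bF*z(F_i) + bC*z(C_i) + eps_i, clipped at 100 ms."""
    b0, bP, bF, bC = rt_coefs
    n = len(next(iter(features.values())))
    rt = np.full(n, b0, dtype=float)
    for coef, key in ((bP, "P"), (bF, "F"), (bC, "C")):
        if coef != 0:
            rt += coef * _zscore(np.asarray(features[key], dtype=float))
    rng = np.random.default_rng(seed)
    if rt_noise_sd > 0:
        rt += rng.normal(0, rt_noise_sd, size=n)
    return np.clip(rt, RT_FLOOR_MS, None)


def _auditory_trial_freqs(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-trial auditory beta frequency: the trial's 'frequency state'."""
    lo, hi = cfg.burst_freq_range
    centre, sd = (lo + hi) / 2.0, (hi - lo) / 6.0
    return np.clip(rng.normal(centre, sd, size=cfg.n_trials), lo + 1, hi - 1)


def make_dataset(cfg: SimConfig) -> SimDataset:
    """Compose noise, bursts, coupling and RTs into a full two-channel dataset.

    The pretarget epochs carry the three RT-relevant features: P (measured
    mean beta-band power of the motor channel in the -700..0 ms window),
    F (the trial's auditory burst frequency) and C (the trial's
    motor->auditory coupling gain). The precue epochs are generated
    independently from the same burst statistics, with constant coupling, so
    pretarget-vs-precue contrasts are null by construction unless configured
    otherwise.
    """
    root = np.random.default_rng(cfg.seed)
    seeds = root.integers(0, 2**31 - 1, size=8)
    n_samples = int(round((cfg.epoch_span[1] - cfg.epoch_span[0]) * cfg.fs))
    records: list[BurstRecord] = []

    def build(window: str, t0: float, seed_off: int, trial_freqs, gains):
        noise = generate_noise(cfg.n_trials, n_samples, cfg.fs,
                               cfg.noise_exponent, seed=int(seeds[seed_off]),
                               n_channels=2)
        ep = EpochSet(noise, cfg.fs, t0, ("motor", "auditory"), window=window)
        ep, recs = inject_bursts(
            ep, cfg.burst_rate, cfg.burst_freq_range, cfg.burst_cycles,
            cfg.burst_amp, seed=int(seeds[seed_off + 1]),
            freq_per_trial={"auditory": trial_freqs},
        )
        records.extend(recs)
        if cfg.coupling_gain != 0:
            ep = couple_channels(ep, gains, cfg.coupling_lag,
                                 cfg.burst_freq_range)
        return ep

    rng_feat = np.random.default_rng(int(seeds[4]))
    freqs_pre = _auditory_trial_freqs(cfg, rng_feat)
    bC = cfg.rt_coefs[3]
    if bC != 0 and cfg.coupling_gain != 0:
        gains = rng_feat.uniform(0, 2 * cfg.coupling_gain, size=cfg.n_trials)
    else:
        gains = np.full(cfg.n_trials, cfg.coupling_gain)
    pretarget = build("pretarget", cfg.epoch_span[0], 0, freqs_pre, gains)

    rng_cue = np.random.default_rng(int(seeds[5]))
    freqs_cue = _auditory_trial_freqs(cfg, rng_cue)
    precue = build("precue", cfg.precue_span[0], 2, freqs_cue,
                   np.full(cfg.n_trials, cfg.coupling_gain))

    # P: mean beta-band power of the motor channel in the analysis window
    # (band-pass the full epoch first: the filter needs the longer support)
    motor_bp = _beta_bandpass(pretarget.channel("motor"), cfg.fs,
                              cfg.burst_freq_range)
    t = pretarget.times
    in_win = (t >= -0.7 - 0.5 / cfg.fs) & (t < -0.5 / cfg.fs)
    P = (motor_bp[:, in_win] ** 2).mean(axis=-1)
    features = {"P": P, "F": freqs_pre, "C": gains}
    rts = generate_rts(features, cfg.rt_coefs, cfg.rt_noise_sd,
                       seed=int(seeds[6]))
    pretarget.rts = rts

    gt = SyntheticGroundTruth(
        burst_records=records,
        rt_features={k: np.asarray(v, dtype=float) for k, v in features.items()},
        rt_coefs=cfg.rt_coefs,
        seed=cfg.seed,
    )
    return SimDataset(pretarget=pretarget, precue=precue, rts=rts,
                      ground_truth=gt)
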