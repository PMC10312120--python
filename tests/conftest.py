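import numpy as np
import pytest

from betadyn.containers import EpochSet

FS = 300.0


@pytest.fixture
def tone_epochs():
    """Single-trial 20 Hz unit sinusoid on the standard epoch grid."""
    t = -1.0 + np.arange(420) / FS
    data = np.sin(2 * np.pi * 20.0 * t)[None, None, :]
    return EpochSet(data=data, fs=FS, t0=-1.0, ch_names=("motor",))


@pytest.fixture
def two_channel_noise():
    """Deterministic 1/f noise epochs on two channels (40 trials)."""
    from betadyn.synthetic import generate_noise

    data = generate_noise(40, 420, FS, exponent=1.0, seed=7, n_channels=2)
    return EpochSet(data=data, fs=FS, t0=-1.0, ch_names=("motor", "auditory"))


def loglog_slope(x: np.ndarray, fs: float, fmin: float = 2.0,
                 fmax: float = 100.0) -> float:
    """Independent spectral-slope oracle: Welch spectrum + linear fit."""
    from scipy.signal import welch

    f, p = welch(x, fs=fs, nperseg=x.shape[-1], axis=-1)
    pm = p.reshape(-1, p.shape[-1]).mean(axis=0)
    sel = (f >= fmin) & (f <= fmax)
    return float(np.polyfit(np.log(f[sel]), np.log(pm[sel]), 1)[0])
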