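"""Directed auditory-motor coupling in the beta band.

Two estimators, both computed from the single-trial Fourier coefficients of
the spectral module:

* pairwise phase consistency (PPC) — the unbiased average over all trial
  pairs of the cosine of their phase-difference difference; and
* bivariate nonparametric Granger causality — the trial-averaged
  cross-spectral density matrix is factorized into a minimum-phase transfer
  function and a noise covariance with Wilson's iterative algorithm, from
  which frequency-resolved directed influences are read out without fitting
  an autoregressive model.

Connectivity is not defined on single trials, so reaction-time effects are
assessed by estimating both measures separately on the slow and fast halves
of a median split.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import EpochSet
from .spectral import fourier_spectra
from .stats import median_split

__all__ = [
    "FactorizationResult",
    "ConnectivitySpectrum",
    "ppc",
    "ppc_from_coefs",
    "cross_spectral_density",
    "spectral_factorization",
    "granger_spectrum",
    "granger_from_coefs",
    "split_connectivity",
]


@dataclass
class FactorizationResult:
    H: np.ndarray  # (nfreq, 2, 2) minimum-phase transfer function
    Sigma: np.ndarray  # (2, 2) real noise covariance
    converged: bool
    n_iter: int
    residual: float  # relative reconstruction error ||S - H Sigma H*|| / ||S||


@dataclass
class ConnectivitySpectrum:
    freqs: np.ndarray
    ppc: np.ndarray
    gc_src_to_dst: np.ndarray  # e.g. motor -> auditory
    gc_dst_to_src: np.ndarray


def ppc(phase_diffs: np.ndarray, axis: int = 0) -> np.ndarray:
    """Pairwise phase consistency of trial-wise phase differences.

    PPC = (2 / (N(N-1))) * sum_{j<k} cos(theta_j - theta_k), evaluated via
    the equivalent closed form (|sum_j e^{i theta_j}|^2 - N) / (N(N-1)).
    Unbiased: its expectation is 0 for uniform phases at any N >= 2.
    """
    theta = np.asarray(phase_diffs)
    n = theta.shape[axis]
    if n < 2:
        raise ValueError("PPC needs at least 2 trials")
    resultant = np.abs(np.exp(1j * theta).sum(axis=axis)) ** 2
    return (resultant - n) / (n * (n - 1))


def ppc_from_coefs(coefs_a: np.ndarray, coefs_b: np.ndarray) -> np.ndarray:
    """PPC spectrum from trial x frequency Fourier coefficients of two channels."""
    theta = np.angle(coefs_a * np.conj(coefs_b))
    return ppc(theta, axis=0)


def cross_spectral_density(coefs: np.ndarray, smooth_bins: int = 1) -> np.ndarray:
    """Trial-averaged 2x2 cross-spectral density matrix per frequency.

    ``coefs`` is trials x 2 channels x freqs. The CSD is optionally smoothed
    with a +/- ``smooth_bins`` moving average along frequency (raw 0.5 Hz
    trial-averaged spectra can be ill-conditioned for the factorization).
    """
    S = np.einsum("tcf,tdf->fcd", coefs, np.conj(coefs)) / coefs.shape[0]
    if smooth_bins > 0:
        k = 2 * smooth_bins + 1
        kernel = np.ones(k) / k
        padded = np.concatenate(
            [S[smooth_bins:0:-1], S, S[-2:-smooth_bins - 2:-1]], axis=0
        )
        S = np.stack(
            [np.convolve(padded[:, i, j], kernel, mode="valid")
             for i in range(2) for j in range(2)],
            axis=-1,
        ).reshape(-1, 2, 2)
    # enforce exact Hermitian symmetry
    return 0.5 * (S + np.conj(np.transpose(S, (0, 2, 1))))


def _plus_operator(g: np.ndarray) -> np.ndarray:
    """Causal part of a two-sided spectral matrix function.

    ``g`` has shape (N, 2, 2) on the full FFT frequency grid. Its lag-domain
    coefficients are kept for non-negative lags only; the zero-lag (Hermitian)
    coefficient gamma0 is split as tril(gamma0, -1) + diag(gamma0)/2 so the
    causal factor's zero-lag term stays lower-triangular.
    """
    N = g.shape[0]
    gam = np.fft.ifft(g, axis=0)
    gamp = np.zeros_like(gam)
    g0 = gam[0]
    gamp[0] = np.tril(g0, -1) + np.diag(np.diag(g0)) / 2.0
    half = N // 2
    gamp[1:half + 1] = gam[1:half + 1]
    return np.fft.fft(gamp, axis=0)


def spectral_factorization(
    S: np.ndarray,
    tol: float = 1e-9,
    max_iter: int = 100,
) -> FactorizationResult:
    """Wilson's iterative factorization S(f) = H(f) Sigma H(f)*.

    ``S`` is (nfreq, 2, 2) Hermitian PSD on a uniform one-sided grid from 0
    to Nyquist inclusive. H is minimum-phase with H(0) lower-triangular (the
    zero-lag coefficient of the causal factor is kept lower-triangular each
    iteration). Iterates until the maximum relative change of the factor
    drops below ``tol`` or ``max_iter`` is reached; convergence status and
    the relative reconstruction residual are reported.
    """
    S = np.asarray(S, dtype=complex)
    nfreq = S.shape[0]
    if S.shape[1:] != (2, 2):
        raise ValueError("S must be (nfreq, 2, 2)")
    herm_err = np.abs(S - np.conj(np.transpose(S, (0, 2, 1)))).max()
    if herm_err > 1e-8 * (np.abs(S).max() + 1e-300):
        raise ValueError("S must be Hermitian at every frequency")
    eigs = np.linalg.eigvalsh(S)
    if eigs.min() < -1e-10 * max(eigs.max(), 1e-300):
        raise ValueError("S must be positive semidefinite at every frequency")

    N = 2 * (nfreq - 1)
    # two-sided extension: S(-f) = conj(S(f)) for a real vector process
    S2 = np.concatenate([S, np.conj(S[-2:0:-1])], axis=0)

    gam0 = np.real(np.fft.ifft(S2, axis=0)[0])
    # tiny ridge keeps the Cholesky well-posed for rank-deficient inputs
    ridge = 1e-12 * np.trace(gam0) / 2.0
    L = np.linalg.cholesky(gam0 + ridge * np.eye(2))
    psi = np.broadcast_to(L.astype(complex), (N, 2, 2)).copy()

    def inv2(M):
        a, b = M[:, 0, 0], M[:, 0, 1]
        c, d = M[:, 1, 0], M[:, 1, 1]
        det = a * d - b * c
        out = np.empty_like(M)
        out[:, 0, 0], out[:, 0, 1] = d / det, -b / det
        out[:, 1, 0], out[:, 1, 1] = -c / det, a / det
        return out

    I2 = np.eye(2)
    converged = False
    n_iter = 0
    best = np.inf
    stalled = 0
    for n_iter in range(1, max_iter + 1):
        psi_inv = inv2(psi)
        g = psi_inv @ S2 @ np.conj(np.transpose(psi_inv, (0, 2, 1))) + I2
        gp = _plus_operator(g)
        psi_new = psi @ gp
        num = np.abs(psi_new - psi).max()
        den = np.abs(psi).max()
        psi = psi_new
        change = num / den
        if change < tol:
            converged = True
            break
        # stop early once the update has hit its numerical floor: noisy
        # estimated spectra plateau well above tol and further iterations
        # only repeat the same fixed point
        if change < 0.5 * best:
            best = change
            stalled = 0
        else:
            stalled += 1
            if stalled >= 8:
                break

    A0 = np.real(np.fft.ifft(psi, axis=0)[0])
    Sigma = A0 @ A0.T
    H = psi[:nfreq] @ np.linalg.inv(A0)
    recon = H @ Sigma @ np.conj(np.transpose(H, (0, 2, 1)))
    residual = float(np.linalg.norm(recon - S) / np.linalg.norm(S))
    return FactorizationResult(H=H, Sigma=Sigma, converged=converged,
                               n_iter=n_iter, residual=residual)


def granger_spectrum(
    S: np.ndarray, H: np.ndarray, Sigma: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Frequency-resolved directed influences from a factorized CSD.

    For channels (x, y) = (0, 1):
    ``G_x->y(f) = ln[ S_yy / (S_yy - (Sigma_xx - Sigma_xy^2/Sigma_yy) |H_yx|^2) ]``
    and symmetrically for the reverse direction. Numerical negatives below
    1e-12 are clipped to zero.
    """
    Syy = np.real(S[:, 1, 1])
    Sxx = np.real(S[:, 0, 0])
    if np.any(Syy == 0) or np.any(Sxx == 0):
        raise ValueError("zero diagonal spectral power")
    sig_x_cond = Sigma[0, 0] - Sigma[0, 1] ** 2 / Sigma[1, 1]
    sig_y_cond = Sigma[1, 1] - Sigma[0, 1] ** 2 / Sigma[0, 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        g_xy = np.log(Syy / (Syy - sig_x_cond * np.abs(H[:, 1, 0]) ** 2))
        g_yx = np.log(Sxx / (Sxx - sig_y_cond * np.abs(H[:, 0, 1]) ** 2))
    g_xy = np.where(np.abs(g_xy) < 1e-12, 0.0, g_xy)
    g_yx = np.where(np.abs(g_yx) < 1e-12, 0.0, g_yx)
    return np.clip(g_xy, 0, None), np.clip(g_yx, 0, None)


def granger_from_coefs(
    coefs: np.ndarray,
    smooth_bins: int = 1,
    tol: float = 1e-9,
    max_iter: int = 100,
) -> tuple[np.ndarray, np.ndarray, FactorizationResult]:
    """Directed spectra from trials x 2 x freqs coefficients on the full grid."""
    S = cross_spectral_density(coefs, smooth_bins=smooth_bins)
    fac = spectral_factorization(S, tol=tol, max_iter=max_iter)
    g_xy, g_yx = granger_spectrum(S, fac.H, fac.Sigma)
    return g_xy, g_yx, fac


def split_connectivity(
    epochs: EpochSet,
    window: tuple[float, float] = (-0.7, 0.0),
    pad_to: float = 2.0,
    band: tuple[float, float] = (13.0, 30.0),
    src: str = "motor",
    dst: str = "auditory",
    smooth_bins: int = 1,
) -> dict[str, ConnectivitySpectrum]:
    """PPC and Granger spectra for the fast and slow halves of a median split.

    The Fourier coefficients are computed once on the full 0..Nyquist grid
    (Wilson's factorization needs the whole spectrum); the returned spectra
    are restricted to ``band``. Keys: ``"fast"``, ``"slow"``.
    """
    if epochs.rts is None:
        raise ValueError("epochs carry no reaction times")
    fast, slow = median_split(epochs.rts)
    if len(fast) < 2 or len(slow) < 2:
        raise ValueError("each median-split half needs at least 2 trials")
    spec = fourier_spectra(epochs, window=window, pad_to=pad_to,
                           fmax=epochs.fs / 2)
    si = spec.ch_names.index(src)
    di = spec.ch_names.index(dst)
    band_sel = (spec.freqs >= band[0] - 1e-9) & (spec.freqs <= band[1] + 1e-9)
    out = {}
    for name, idx in (("fast", fast), ("slow", slow)):
        coefs = spec.coefs[idx][:, [si, di], :]
        p = ppc_from_coefs(coefs[:, 0, :], coefs[:, 1, :])
        g_sd, g_ds, _ = granger_from_coefs(coefs, smooth_bins=smooth_bins)
        out[name] = ConnectivitySpectrum(
            freqs=spec.freqs[band_sel],
            ppc=p[band_sel],
            gc_src_to_dst=g_sd[band_sel],
            gc_dst_to_src=g_ds[band_sel],
        )
    return out
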