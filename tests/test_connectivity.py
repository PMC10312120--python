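"""Connectivity tests: PPC estimator, Wilson factorization, directed
spectra, median-split estimation."""

import numpy as np
import pytest

from betadyn.connectivity import (granger_from_coefs, granger_spectrum, ppc,
                                  ppc_from_coefs, spectral_factorization,
                                  split_connectivity)
from betadyn.containers import EpochSet
from betadyn.spectral import fourier_spectra
from betadyn.synthetic import couple_channels, generate_noise

from conftest import FS

NFREQ = 301  # 0..150 Hz at 0.5 Hz

AR1 = np.array([[0.55, 0.0], [0.4, 0.55]])
AR2 = np.array([[-0.8, 0.0], [0.0, -0.8]])
ARSIG = np.array([[1.0, 0.2], [0.2, 0.7]])


def ar2_transfer(f, a1=AR1, a2=AR2, fs=FS):
    z = np.exp(-2j * np.pi * f / fs)
    return np.linalg.inv(np.eye(2) - a1 * z - a2 * z * z)


def ar2_spectrum(freqs, a1=AR1, a2=AR2, sig=ARSIG):
    H = np.stack([ar2_transfer(f, a1, a2) for f in freqs])
    return H @ sig @ np.conj(np.transpose(H, (0, 2, 1)))


def simulate_var2(n_trials, n_samples, seed, a1=AR1, a2=AR2, sig=ARSIG,
                  burn=200):
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(sig)
    e = rng.standard_normal((n_trials, n_samples + burn, 2)) @ L.T
    x = np.zeros_like(e)
    for t in range(2, n_samples + burn):
        x[:, t] = x[:, t - 1] @ a1.T + x[:, t - 2] @ a2.T + e[:, t]
    return x[:, burn:, :].transpose(0, 2, 1)


class TestPpc:
    def test_identical_phases(self):
        assert ppc(np.full(10, 0.8)) == pytest.approx(1.0)

    def test_antiphase_pair(self):
        assert ppc(np.array([0.0, np.pi])) == pytest.approx(-1.0)

    def test_single_trial_rejected(self):
        with pytest.raises(ValueError):
            ppc(np.array([0.3]))

    def test_matches_pairwise_definition(self):
        """Closed form equals the explicit sum over trial pairs."""
        rng = np.random.default_rng(1)
        theta = rng.uniform(0, 2 * np.pi, 40)
        n = len(theta)
        brute = np.mean([np.cos(theta[j] - theta[k])
                         for j in range(n) for k in range(j + 1, n)])
        assert ppc(theta) == pytest.approx(brute, abs=1e-12)

    def test_null_mean_near_zero(self):
        rng = np.random.default_rng(2)
        vals = [ppc(rng.uniform(0, 2 * np.pi, 100)) for _ in range(300)]
        se = np.std(vals) / np.sqrt(len(vals))
        assert abs(np.mean(vals)) < 3 * se

    @pytest.mark.parametrize("n", [10, 50, 200])
    def test_unbiased_across_sample_sizes(self, n):
        """Mean PPC under fixed von Mises phase locking (kappa = 1, true
        PPC = (I1/I0)^2 ~ 0.1993) does not depend on trial count."""
        rng = np.random.default_rng(100 + n)
        vals = [ppc(rng.vonmises(0.0, 1.0, n)) for _ in range(400)]
        se = np.std(vals) / np.sqrt(len(vals))
        assert np.mean(vals) == pytest.approx(0.1993, abs=max(4 * se, 0.01))


class TestSpectralFactorization:
    def test_white_noise_identity_transfer(self):
        S = np.broadcast_to(ARSIG, (NFREQ, 2, 2)).astype(complex).copy()
        fac = spectral_factorization(S)
        assert fac.converged
        np.testing.assert_allclose(fac.Sigma, ARSIG, atol=1e-6)
        np.testing.assert_allclose(fac.H, np.broadcast_to(np.eye(2),
                                                          (NFREQ, 2, 2)),
                                   atol=1e-6)

    def test_ar2_reconstruction(self):
        freqs = np.linspace(0, FS / 2, NFREQ)
        S = ar2_spectrum(freqs)
        fac = spectral_factorization(S)
        assert fac.converged
        assert fac.residual < 1e-6

    def test_random_stable_model_sweep(self):
        """Twenty random stable bivariate AR(2) spectra all factorize with
        relative reconstruction residual below 1e-6."""
        rng = np.random.default_rng(3)
        freqs = np.linspace(0, FS / 2, NFREQ)
        done = 0
        while done < 20:
            a1 = rng.normal(0, 0.3, (2, 2))
            a2 = rng.normal(0, 0.2, (2, 2))
            companion = np.block([[a1, a2], [np.eye(2), np.zeros((2, 2))]])
            if np.abs(np.linalg.eigvals(companion)).max() > 0.95:
                continue
            w = rng.normal(0, 1, (2, 2))
            sig = w @ w.T + 0.1 * np.eye(2)
            fac = spectral_factorization(ar2_spectrum(freqs, a1, a2, sig))
            assert fac.residual < 1e-6
            done += 1

    def test_non_hermitian_rejected(self):
        S = np.broadcast_to(np.array([[1.0, 1.0], [0.0, 1.0]]),
                            (NFREQ, 2, 2)).astype(complex)
        with pytest.raises(ValueError):
            spectral_factorization(S.copy())

    def test_non_psd_rejected(self):
        S = np.broadcast_to(np.array([[1.0, 0.0], [0.0, -1.0]]),
                            (NFREQ, 2, 2)).astype(complex)
        with pytest.raises(ValueError):
            spectral_factorization(S.copy())


class TestGrangerSpectrum:
    def test_independent_white_channels_near_zero(self):
        """500 trials of independent noise: both directions < 0.01."""
        x = generate_noise(500, 420, FS, 0.0, seed=4, n_channels=2)
        ep = EpochSet(x, FS, -1.0, ("x", "y"))
        spec = fourier_spectra(ep, window=(-0.7, 0.0), pad_to=2.0, fmax=FS / 2)
        gxy, gyx, _ = granger_from_coefs(spec.coefs)
        assert gxy.max() < 0.01
        assert gyx.max() < 0.01

    def test_amplitude_scaling_invariance(self):
        freqs = np.linspace(0, FS / 2, NFREQ)
        S = ar2_spectrum(freqs)
        D = np.diag([10.0, 1.0])
        S_scaled = D @ S @ D
        g = []
        for s in (S, S_scaled):
            fac = spectral_factorization(s)
            g.append(granger_spectrum(s, fac.H, fac.Sigma))
        np.testing.assert_allclose(g[0][0], g[1][0], atol=1e-6)
        np.testing.assert_allclose(g[0][1], g[1][1], atol=1e-6)

    def test_nonparametric_matches_fitted_ar_oracle(self):
        """Nonparametric estimate within 10% of the parametric Granger from
        a pooled least-squares VAR(2) fit, at the spectral peak."""
        x = simulate_var2(300, 420, seed=5)
        ep = EpochSet(x, FS, -1.0, ("x", "y"))
        spec = fourier_spectra(ep, window=(-1.0, 0.4), pad_to=2.0, fmax=FS / 2)
        gxy, _, _ = granger_from_coefs(spec.coefs)

        X = x.transpose(0, 2, 1)
        Y = X[:, 2:, :].reshape(-1, 2)
        Z = np.concatenate([X[:, 1:-1, :], X[:, :-2, :]], axis=2).reshape(-1, 4)
        B, *_ = np.linalg.lstsq(Z, Y, rcond=None)
        a1h, a2h = B[:2].T, B[2:].T
        resid = Y - Z @ B
        sigh = resid.T @ resid / len(Y)
        H = np.stack([ar2_transfer(f, a1h, a2h) for f in spec.freqs])
        S = H @ sigh @ np.conj(np.transpose(H, (0, 2, 1)))
        sxc = sigh[0, 0] - sigh[0, 1] ** 2 / sigh[1, 1]
        syy = np.real(S[:, 1, 1])
        g_par = np.log(syy / (syy - sxc * np.abs(H[:, 1, 0]) ** 2))
        peak = int(np.argmax(g_par))
        assert gxy[peak] == pytest.approx(g_par[peak], rel=0.10)

    def test_lagged_coupling_gives_directional_ordering(self):
        x = generate_noise(80, 420, FS, 1.0, seed=6, n_channels=2)
        ep = couple_channels(EpochSet(x, FS, -1.0, ("motor", "auditory")),
                             gain=0.8, lag=0.02)
        spec = fourier_spectra(ep, window=(-0.7, 0.0), pad_to=2.0, fmax=FS / 2)
        g_m2a, g_a2m, _ = granger_from_coefs(spec.coefs)
        bsel = (spec.freqs >= 13) & (spec.freqs <= 30)
        peak = np.argmax(g_m2a[bsel] + g_a2m[bsel])
        assert g_m2a[bsel][peak] > g_a2m[bsel][peak]

    def test_coupling_raises_beta_ppc(self):
        x = generate_noise(80, 420, FS, 1.0, seed=7, n_channels=2)
        ep0 = EpochSet(x, FS, -1.0, ("motor", "auditory"))
        ep1 = couple_channels(ep0, gain=0.8, lag=0.02)
        out = {}
        for name, e in (("uncoupled", ep0), ("coupled", ep1)):
            spec = fourier_spectra(e, window=(-0.7, 0.0), pad_to=2.0)
            bsel = (spec.freqs >= 13) & (spec.freqs <= 30)
            out[name] = ppc_from_coefs(spec.coefs[:, 0, :],
                                       spec.coefs[:, 1, :])[bsel].mean()
        assert out["coupled"] > out["uncoupled"]


class TestSplitConnectivity:
    def _epochs(self, seed=8, n=40):
        x = generate_noise(n, 420, FS, 1.0, seed=seed, n_channels=2)
        rng = np.random.default_rng(seed)
        return EpochSet(x, FS, -1.0, ("motor", "auditory"),
                        rts=rng.uniform(300, 700, n))

    def test_duplicated_trials_identical_halves(self):
        ep = self._epochs(n=20)
        dup = EpochSet(np.concatenate([ep.data, ep.data]), FS, -1.0,
                       ("motor", "auditory"),
                       rts=np.r_[np.full(20, 300.0), np.full(20, 700.0)])
        out = split_connectivity(dup)
        np.testing.assert_allclose(out["fast"].ppc, out["slow"].ppc,
                                   atol=1e-12)
        np.testing.assert_allclose(out["fast"].gc_src_to_dst,
                                   out["slow"].gc_src_to_dst, atol=1e-9)

    def test_requires_rts(self):
        ep = self._epochs()
        ep.rts = None
        with pytest.raises(ValueError):
            split_connectivity(ep)

    def test_beta_readout_grid(self):
        out = split_connectivity(self._epochs())
        assert out["fast"].freqs[0] == 13.0
        assert out["fast"].freqs[-1] == 30.0
        assert len(out["fast"].freqs) == 35
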