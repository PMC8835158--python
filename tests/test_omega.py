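"""Cross-spectral estimation and omega eigenvalue-entropy complexity."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eegdyn.montage import generic_montage
from eegdyn.omega import (DEFAULT_BANDS, BandDefinition, CrossSpectra,
                          band_omega, cross_spectra, omega_from_matrix,
                          omega_per_bin, omega_pipeline)
from eegdyn.preprocess import EpochSet
from eegdyn.synth import SyncGenParams, synthesize_synchronized
from eegdyn.preprocess import epoch as cut_epochs


def _random_psd(rng, k, complex_=True):
    a = rng.standard_normal((k, k))
    if complex_:
        a = a + 1j * rng.standard_normal((k, k))
    return a @ a.conj().T


class TestOmegaFromMatrix:
    def test_rank_one_is_exactly_one(self, rng):
        v = rng.standard_normal(30) + 1j * rng.standard_normal(30)
        assert omega_from_matrix(np.outer(v, v.conj())) == pytest.approx(
            1.0, abs=1e-9)

    def test_identity_is_channel_count(self):
        assert omega_from_matrix(np.eye(30)) == pytest.approx(30.0, abs=1e-9)
        assert omega_from_matrix(np.eye(7)) == pytest.approx(7.0, abs=1e-9)

    def test_two_equal_modes_give_two(self):
        c = np.diag([0.5, 0.5] + [0.0] * 8)
        assert omega_from_matrix(c) == pytest.approx(2.0, abs=1e-12)

    def test_zero_trace_rejected(self):
        with pytest.raises(ValueError):
            omega_from_matrix(np.zeros((5, 5)))

    def test_non_hermitian_rejected(self, rng):
        a = rng.standard_normal((6, 6))
        with pytest.raises(ValueError):
            omega_from_matrix(a + np.triu(np.ones((6, 6)), 1))

    def test_matches_entropy_oracle(self, rng):
        for _ in range(100):
            c = _random_psd(rng, int(rng.integers(2, 12)))
            lam = np.linalg.eigvalsh(c)
            lam = lam[lam > 0]
            p = lam / lam.sum()
            expect = np.exp(-(p * np.log(p)).sum())
            assert omega_from_matrix(c) == pytest.approx(expect, abs=1e-9)

    def test_scale_invariant(self, rng):
        c = _random_psd(rng, 8)
        assert omega_from_matrix(c) == pytest.approx(
            omega_from_matrix(37.5 * c), abs=1e-9)


class TestCrossSpectra:
    def _epochs(self, data, fs=250.0):
        return EpochSet(data, fs, generic_montage(data.shape[2]))

    def test_common_sinusoid_rank_one(self):
        fs = 250.0
        t = np.arange(500) / fs
        sig = np.sin(2 * np.pi * 10 * t)
        data = np.tile(sig[None, :, None], (4, 1, 6))
        sp = cross_spectra(self._epochs(data))
        bin10 = np.argmin(np.abs(sp.freqs_hz - 10.0))
        lam = np.linalg.eigvalsh(sp.matrices[bin10])
        assert lam[-2] < 1e-6 * lam[-1]

    def test_hermitian(self, rng):
        data = rng.standard_normal((5, 500, 6))
        sp = cross_spectra(self._epochs(data))
        err = np.abs(sp.matrices - np.conj(np.transpose(
            sp.matrices, (0, 2, 1)))).max()
        assert err < 1e-10 * np.abs(sp.matrices).max()

    def test_matches_naive_dft_oracle(self, rng):
        data = rng.standard_normal((3, 100, 2))
        ep = EpochSet(data, 50.0, generic_montage(2))
        sp = cross_spectra(ep)
        taper = np.hanning(100)
        n_bins = sp.freqs_hz.size
        expect = np.zeros((n_bins, 2, 2), dtype=complex)
        freqs = np.fft.rfftfreq(100, d=1 / 50.0)
        pos = freqs > 0
        for e in range(3):
            u = np.array([np.fft.rfft(taper * data[e, :, c]) for c in range(2)]).T
            u = u[pos]
            for f in range(n_bins):
                expect[f] += np.outer(u[f], u[f].conj()) / 3
        assert np.allclose(sp.matrices, expect, atol=1e-10)

    def test_resolution_is_half_hz_for_two_second_epochs(self, rng):
        ep = self._epochs(rng.standard_normal((3, 500, 4)))
        sp = cross_spectra(ep)
        assert np.allclose(np.diff(sp.freqs_hz), 0.5)

    def test_correlation_normalization_removes_power_differences(self, rng):
        # one common source with wildly different per-channel gains:
        # trace-normalized omega sees an uneven eigenvalue spread only
        # through the gains; correlation-normalized omega is exactly 1
        gains = np.array([1.0, 10.0, 0.1, 5.0])
        data = rng.standard_normal((6, 500, 1)) * gains[None, None, :]
        sp = cross_spectra(EpochSet(data, 250.0, generic_montage(4)))
        om_corr = omega_per_bin(sp, normalize="correlation")
        assert np.allclose(om_corr, 1.0, atol=1e-6)
        with pytest.raises(ValueError):
            omega_per_bin(sp, normalize="bogus")


class TestBandOmega:
    def _spectra(self, freqs, omegas_target):
        # diagonal matrices whose omega is exactly the requested value:
        # eigenvalues (1,...,1,eps on the rest) are hard to invert, so use
        # m equal modes for integer targets
        mats = []
        for w in omegas_target:
            m = int(w)
            d = np.zeros(8)
            d[:m] = 1.0 / m
            mats.append(np.diag(d))
        return CrossSpectra(freqs_hz=np.asarray(freqs, dtype=float),
                            matrices=np.array(mats))

    def test_constant_bins(self):
        sp = self._spectra([1.0, 1.5, 2.0], [2, 2, 2])
        assert band_omega(sp, BandDefinition("b", 0.5, 3.0)) == pytest.approx(2.0)

    def test_mean_of_two_and_four(self):
        sp = self._spectra([10.0, 11.0], [2, 4])
        assert band_omega(sp, BandDefinition("b", 9.0, 12.0)) == pytest.approx(3.0)

    def test_empty_band_raises(self):
        sp = self._spectra([1.0], [2])
        with pytest.raises(ValueError):
            band_omega(sp, BandDefinition("b", 5.0, 6.0))

    def test_half_open_edges(self):
        sp = self._spectra([12.5, 13.0, 13.5], [2, 4, 4])
        alpha2 = next(b for b in DEFAULT_BANDS if b.name == "alpha2")
        beta1 = next(b for b in DEFAULT_BANDS if b.name == "beta1")
        assert band_omega(sp, alpha2) == pytest.approx(2.0)  # 13 Hz excluded
        assert band_omega(sp, beta1) == pytest.approx(4.0)   # 13 Hz included


class TestOmegaPipeline:
    def test_single_mode_recording_near_one(self):
        rec = synthesize_synchronized(SyncGenParams(
            n_channels=7, n_modes=1, duration_s=60.0, seed=3))
        table = omega_pipeline(cut_epochs(rec, 2.0), scopes=("global",))
        alpha = table[table.band == "alpha1"].omega.iloc[0]
        assert alpha <= 1.3

    def test_independent_channels_near_k(self, rng):
        data = rng.standard_normal((150, 500, 7))
        ep = EpochSet(data, 250.0, generic_montage(7))
        table = omega_pipeline(ep, scopes=("global",))
        assert np.all(np.abs(table.omega - 7) / 7 < 0.10)

    def test_shape_and_bounds(self, small_cohort):
        from eegdyn.preprocess import preprocess
        ep = preprocess(small_cohort.subjects[0].recording)
        table = omega_pipeline(ep)
        assert len(table) == 21  # 7 bands x 3 scopes
        for r in table.itertuples():
            k = 30 if r.scope == "global" else 7
            assert 1.0 <= r.omega <= k


class TestSynchronizationControl:
    def test_omega_increases_with_modes(self):
        vals = {}
        for n_modes in (2, 6):
            got = []
            for rep in range(8):
                rec = synthesize_synchronized(SyncGenParams(
                    n_channels=7, n_modes=n_modes, duration_s=40.0,
                    seed=100 + rep))
                sp = cross_spectra(cut_epochs(rec, 2.0))
                om = omega_per_bin(sp)
                sel = (sp.freqs_hz >= 8) & (sp.freqs_hz <= 12)
                got.append(om[sel].mean())
            vals[n_modes] = np.mean(got)
        assert vals[2] < vals[6]

    def test_balanced_modes_match_count(self):
        rec = synthesize_synchronized(SyncGenParams(
            n_channels=8, n_modes=4, duration_s=240.0, seed=9))
        sp = cross_spectra(cut_epochs(rec, 2.0))
        sel = (sp.freqs_hz >= 8) & (sp.freqs_hz <= 12)
        got = omega_per_bin(sp)[sel].mean()
        assert got == pytest.approx(4.0, rel=0.15)


@settings(deadline=None, max_examples=20, derandomize=True)
@given(st.integers(min_value=0, max_value=2 ** 31 - 1),
       st.floats(min_value=0.05, max_value=0.9))
def test_omega_decreases_with_common_mode_share(seed, rho_low):
    """More shared variance -> fewer effective modes -> lower omega."""
    rng = np.random.default_rng(seed)
    k = 6
    common = rng.standard_normal(2000)
    indep = rng.standard_normal((2000, k))
    rho_high = min(0.95, rho_low + 0.1)
    oms = []
    for rho in (rho_low, rho_high):
        x = np.sqrt(rho) * common[:, None] + np.sqrt(1 - rho) * indep
        c = x.T @ x
        oms.append(omega_from_matrix(c))
    assert oms[1] < oms[0]
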