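"""GFP, TAAHC clustering, backfitting, GEV and label statistics."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eegdyn.montage import generic_montage
from eegdyn.microstate import (TAAHC, backfit, compute_gev, compute_gfp,
                               find_gfp_peaks, microstate_bandpass,
                               order_classes, segment_stats,
                               spatial_correlation, taahc_cluster,
                               transition_matrix)
from eegdyn.preprocess import EpochSet


class TestGFP:
    def test_constant_topography_is_zero(self):
        assert compute_gfp(np.full((10, 8), 3.3)).max() == 0.0

    def test_two_channel_unit(self):
        assert compute_gfp(np.array([[1.0, -1.0]]))[0] == pytest.approx(1.0)

    def test_matches_formula_oracle(self, rng):
        x = rng.standard_normal((50, 30))
        expect = np.array([
            np.sqrt(sum((v - row.mean()) ** 2 for v in row) / row.size)
            for row in x])
        assert np.allclose(compute_gfp(x), expect, atol=1e-12)


class TestGFPPeaks:
    def test_monotone_has_none(self):
        assert find_gfp_peaks(np.arange(10.0)).size == 0

    def test_alternating(self):
        assert find_gfp_peaks(np.array([1, 3, 1, 3, 1.0])).tolist() == [1, 3]

    def test_matches_scan_oracle(self, rng):
        t = np.linspace(0, 6 * np.pi, 300)
        v = np.abs(np.sin(t)) + 0.1 * rng.standard_normal(300)
        expect = [i for i in range(1, 299) if v[i] > v[i - 1] and v[i] > v[i + 1]]
        assert find_gfp_peaks(v).tolist() == expect


class TestMicrostateBandpass:
    @pytest.mark.parametrize("freq,kind", [(10.0, "pass"), (30.0, "stop"),
                                           (1.0, "stop")])
    def test_band_response(self, freq, kind):
        fs, mont = 250.0, generic_montage(3)
        t = np.arange(500) / fs
        sig = np.tile(np.sin(2 * np.pi * freq * t)[:, None], (1, 3))
        ep = EpochSet(np.tile(sig, (4, 1, 1)), fs, mont)
        out = microstate_bandpass(ep)
        core = out.epochs[0, 100:400, 0]
        rms_in = np.sqrt((sig[100:400, 0] ** 2).mean())
        rms_out = np.sqrt((core ** 2).mean())
        if kind == "pass":
            assert rms_out / rms_in > 10 ** (-1 / 20)  # within 1 dB
        else:
            assert rms_out / rms_in < 10 ** (-20 / 20)  # >= 20 dB down


def _orthogonal_protos(k=12, n=4):
    """Mutually orthogonal zero-mean unit-norm maps (orthogonal to ones)."""
    rng = np.random.default_rng(7)
    basis = np.column_stack([np.ones(k), rng.standard_normal((k, n))])
    q, _ = np.linalg.qr(basis)
    return q[:, 1:n + 1].T


class TestTAAHC:
    def test_noise_free_recovery_up_to_sign(self, rng):
        protos = _orthogonal_protos()
        idx = rng.integers(0, 4, 80)
        signs = rng.choice([-1.0, 1.0], 80)
        amps = 1 + rng.random(80)
        maps = signs[:, None] * amps[:, None] * protos[idx]
        centers = taahc_cluster(maps, n_clusters=4)
        r = np.abs(spatial_correlation(centers, protos))
        assert sorted(r.argmax(axis=1)) == [0, 1, 2, 3]
        assert r.max(axis=1) == pytest.approx(np.ones(4), abs=1e-9)

    def test_polarity_ignored(self, rng):
        protos = _orthogonal_protos()
        maps = protos[rng.integers(0, 4, 60)] * (1 + rng.random(60))[:, None]
        a = TAAHC(4).fit(maps)
        b = TAAHC(4).fit(-maps)
        assert np.array_equal(a.labels_, b.labels_)
        assert np.allclose(np.abs(np.sum(a.cluster_centers_
                                         * b.cluster_centers_, axis=1)), 1.0)

    def test_noisy_recovery(self, prototypes, rng):
        idx = rng.integers(0, 4, 60)
        maps = prototypes[idx] + 0.15 * rng.standard_normal((60, 30))
        maps *= rng.choice([-1.0, 1.0], 60)[:, None]
        centers = taahc_cluster(maps, n_clusters=4)
        aligned, _ = order_classes(centers, prototypes)
        r = np.abs(np.sum(aligned * prototypes, axis=1))
        assert np.all(r >= 0.95)

    def test_too_few_maps_raises(self):
        with pytest.raises(ValueError):
            taahc_cluster(np.ones((3, 8)), n_clusters=4)

    def test_gev_one_for_exact_maps(self):
        protos = _orthogonal_protos()
        model = TAAHC(4).fit(np.repeat(protos, 5, axis=0))
        assert model.gev_ == pytest.approx(1.0, abs=1e-12)


class TestOrderClasses:
    def test_inverts_shuffle(self, templates, rng):
        perm = rng.permutation(4)
        ordered, cols = order_classes(templates[perm], templates)
        assert np.allclose(ordered, templates, atol=1e-12)
        assert np.array_equal(perm[cols], np.arange(4))

    def test_sign_flip_invariant(self, templates):
        ordered, cols = order_classes(-templates, templates)
        assert np.array_equal(cols, np.arange(4))
        assert np.allclose(ordered, templates, atol=1e-12)

    def test_matches_exhaustive_oracle(self, rng):
        protos = _unit_rows(rng.standard_normal((4, 10)))
        templ = _unit_rows(rng.standard_normal((4, 10)))
        _, cols = order_classes(protos, templ)
        r = np.abs(spatial_correlation(templ, protos))
        best = max(itertools.permutations(range(4)),
                   key=lambda p: sum(r[i, p[i]] for i in range(4)))
        assert tuple(cols) == best


def _unit_rows(x):
    x = x - x.mean(axis=1, keepdims=True)
    return x / np.linalg.norm(x, axis=1, keepdims=True)


def _epochset_from(data, fs=250.0):
    data = data - data.mean(axis=2, keepdims=True)
    return EpochSet(data, fs, generic_montage(data.shape[2]),
                    epoch_length_s=data.shape[1] / fs)


class TestBackfit:
    def _noise_free_epochs(self, prototypes, rng, n_ep=3, n_t=250):
        planted = rng.integers(0, 4, (n_ep, n_t))
        amp = 1.0 + np.abs(np.sin(np.linspace(0, 20, n_t)))  # varying GFP
        data = prototypes[planted] * amp[None, :, None]
        return _epochset_from(data), planted

    def test_recovers_planted_labels_at_peaks(self, prototypes, rng):
        ep, planted = self._noise_free_epochs(prototypes, rng)
        labels = backfit(ep, prototypes)
        for e in range(ep.n_epochs):
            g = compute_gfp(ep.epochs[e])
            for p in find_gfp_peaks(g):
                assert labels[e, p] == planted[e, p]

    def test_sign_flip_leaves_labels(self, prototypes, rng):
        ep, _ = self._noise_free_epochs(prototypes, rng)
        flipped = _epochset_from(-ep.epochs)
        assert np.array_equal(backfit(ep, prototypes),
                              backfit(flipped, prototypes))

    def test_peak_assignment_matches_bruteforce(self, prototypes, rng):
        data = rng.standard_normal((2, 250, 30))
        ep = _epochset_from(data)
        labels = backfit(ep, prototypes)
        for e in range(2):
            g = compute_gfp(ep.epochs[e])
            for p in find_gfp_peaks(g):
                r = [abs(float(spatial_correlation(ep.epochs[e, p], proto)))
                     for proto in prototypes]
                assert labels[e, p] == int(np.argmax(r))


class TestGEV:
    def test_exact_prototypes_give_one(self, prototypes, rng):
        idx = rng.integers(0, 4, (2, 100))
        data = prototypes[idx] * (1 + rng.random((2, 100, 1)))
        ep = _epochset_from(data)
        assert compute_gev(ep, idx, prototypes) == pytest.approx(1.0, abs=1e-12)

    def test_orthogonal_assignment_gives_zero(self):
        protos = _orthogonal_protos()
        data = np.tile(protos[0], (1, 50, 1))
        ep = _epochset_from(data)
        labels = np.full((1, 50), 1)  # orthogonal prototype assigned
        assert compute_gev(ep, labels, protos) == pytest.approx(0.0, abs=1e-12)

    def test_matches_summation_oracle(self, prototypes, rng):
        data = rng.standard_normal((2, 80, 30))
        ep = _epochset_from(data)
        labels = rng.integers(0, 4, (2, 80))
        num = den = 0.0
        for e in range(2):
            for t in range(80):
                v = ep.epochs[e, t]
                g = np.sqrt(((v - v.mean()) ** 2).mean())
                r = float(spatial_correlation(v, prototypes[labels[e, t]]))
                num += (g * r) ** 2
                den += g ** 2
        assert compute_gev(ep, labels, prototypes) == pytest.approx(
            num / den, abs=1e-12)


class TestSegmentStats:
    def test_forty_sample_epoch(self):
        labels = np.array([[0] * 10 + [1] * 10 + [0] * 10 + [1] * 10])
        st_ = segment_stats(labels, 100.0)
        assert st_.contribution_pct[0] == pytest.approx(50.0)
        assert st_.contribution_pct[1] == pytest.approx(50.0)
        # interior segments: one of class B(1) and one of class A(0), 100 ms each
        assert st_.duration_ms[0] == pytest.approx(100.0)
        assert st_.duration_ms[1] == pytest.approx(100.0)

    def test_occurrence_counts_complete_segments(self):
        # 5 complete A-segments inside 1 s at 100 Hz, separated by B
        row = [1] * 5 + ([0] * 10 + [1] * 9) * 5
        assert len(row) == 100
        st_ = segment_stats(np.array([row]), 100.0)
        assert st_.occurrence_per_s[0] == pytest.approx(5.0)

    def test_montecarlo_duration_recovery(self):
        from eegdyn.synth import MicrostateGenParams, sample_state_sequence
        p = MicrostateGenParams(mean_duration_ms=80.0, seed=5)
        labels = sample_state_sequence(p, 200.0, 250.0)
        st_ = segment_stats(labels.reshape(-1, 500), 250.0)
        n_segments = st_.occurrence_per_s.sum() * 200.0
        assert n_segments >= 1000
        mean_dur = float(np.nanmean(st_.duration_ms))
        assert mean_dur == pytest.approx(80.0, abs=5.0)


class TestTransitions:
    def test_forced_alternation(self):
        labels = np.array([[0] * 5 + [1] * 5 + [0] * 5 + [1] * 5])
        t = transition_matrix(labels, 4)
        assert t[0, 1] == 1.0 and t[1, 0] == 1.0
        assert t.sum() == pytest.approx(2.0)

    def test_twelve_informative_cells(self):
        t = transition_matrix(np.arange(4).repeat(10)[None, :], 4)
        off_diag = ~np.eye(4, dtype=bool)
        assert off_diag.sum() == 12
        assert np.all(np.diag(t) == 0)

    def test_matches_pair_counting_oracle(self, rng):
        labels = rng.integers(0, 4, (3, 200))
        t = transition_matrix(labels, 4)
        counts = np.zeros((4, 4))
        for row in labels:
            segs = [row[0]]
            for v in row[1:]:
                if v != segs[-1]:
                    segs.append(v)
            for a, b in zip(segs[:-1], segs[1:]):
                counts[a, b] += 1
        expect = counts / np.where(counts.sum(1, keepdims=True) == 0, 1,
                                   counts.sum(1, keepdims=True))
        assert np.allclose(t, expect, atol=1e-12)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.integers(min_value=0, max_value=2 ** 31 - 1))
def test_label_statistics_invariants(seed):
    """Contributions sum to 100; transition rows sum to 1 or are zero."""
    rng = np.random.default_rng(seed)
    labels = rng.integers(0, 4, (rng.integers(1, 4), rng.integers(10, 300)))
    st_ = segment_stats(labels, 250.0)
    assert st_.contribution_pct.sum() == pytest.approx(100.0, abs=1e-6)
    rows = st_.transitions.sum(axis=1)
    assert np.all((np.abs(rows - 1) < 1e-9) | (rows == 0))


def test_statistics_invariant_to_scale_and_sign(prototypes, rng):
    data = rng.standard_normal((2, 250, 30))
    ep = _epochset_from(data)
    ep_scaled = _epochset_from(-3.7 * data)
    la, lb = backfit(ep, prototypes), backfit(ep_scaled, prototypes)
    assert np.array_equal(la, lb)
    assert compute_gev(ep, la, prototypes) == pytest.approx(
        compute_gev(ep_scaled, lb, prototypes), abs=1e-12)
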