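"""Inverted encoding model: per-equation oracles, identities, closed loop."""

import numpy as np
import pytest

import expectdecode as ed
from expectdecode.iem import (
    BasisSet,
    analytic_shrinkage_intensity,
    center,
    channel_responses,
    decode_orientation,
    decoding_accuracy,
    estimate_noise,
    fit_forward,
    reconstruct,
    spatial_filter,
)
from conftest import single_timepoint_dataset


def random_spd(rng, p):
    A = rng.standard_normal((p, p))
    return A @ A.T + p * np.eye(p)


class TestBasis:
    def test_rectification_and_preferred_values(self):
        resp = channel_responses([0.0])[:, 0]
        assert resp[0] == 1.0
        assert resp[2] == 0.0 and resp[3] == 0.0  # channels >= 45 deg away
        assert resp[1] > 0.0
        assert resp[1] == pytest.approx(resp[4], rel=1e-12)
        assert channel_responses([36.0])[1, 0] == pytest.approx(1.0)

    def test_offpeak_value_matches_formula(self):
        # channel at 0 deg responding to 36 deg: cos(72 deg)^4
        expected = np.cos(np.deg2rad(72.0)) ** 4  # 0.009121...
        assert channel_responses([36.0])[0, 0] == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.00912, abs=5e-6)

    def test_channel_sum_invariant_under_36deg_shift(self, rng):
        theta = rng.uniform(0, 180, 50)
        s0 = channel_responses(theta).sum(axis=0)
        s1 = channel_responses((theta + 36.0) % 180.0).sum(axis=0)
        np.testing.assert_allclose(s0, s1, atol=1e-12)


class TestCenter:
    def test_constant_row_zeroed_and_idempotent(self, rng):
        M = np.vstack([np.full(10, 3.7), rng.standard_normal(10)])
        C = center(M)
        np.testing.assert_allclose(C[0], 0.0, atol=1e-12)
        np.testing.assert_allclose(center(C), C, atol=1e-12)
        assert np.abs(center(rng.standard_normal((6, 40))).mean(axis=1)).max() < 1e-12


class TestFitForward:
    def test_rank_one_exact_recovery(self, rng):
        w_true = rng.standard_normal(7)
        c = center(rng.standard_normal((1, 30)))
        B = np.outer(w_true, c[0])
        W = fit_forward(B, c)
        np.testing.assert_allclose(W[:, 0], w_true, atol=1e-12)

    def test_matches_least_squares_oracle(self, rng):
        """Per-channel result equals one-regressor LS via np.linalg.lstsq."""
        B = center(rng.standard_normal((6, 50)))
        C = center(rng.standard_normal((5, 50)))
        W = fit_forward(B, C)
        for i in range(5):
            expected, *_ = np.linalg.lstsq(C[i][:, None], B.T, rcond=None)
            np.testing.assert_allclose(W[:, i], expected[0], atol=1e-10)

    def test_zero_channel_raises_naming_channel(self):
        B = np.zeros((3, 10))
        C = np.zeros((5, 10))
        C[0] = np.linspace(-1, 1, 10)
        with pytest.raises(ValueError, match=r"\[1, 2, 3, 4\]"):
            fit_forward(B, C)


class TestEstimateNoise:
    def test_noiseless_degenerate_falls_back_to_identity(self, rng):
        w = rng.standard_normal(4)
        c = center(rng.standard_normal((1, 20)))[0]
        B = np.outer(w, c)
        nm = estimate_noise(B, w, c)
        assert nm.degenerate
        np.testing.assert_allclose(nm.shrunk_cov, np.eye(4))
        v = spatial_filter(w, nm.shrunk_cov)
        np.testing.assert_allclose(v, w / (w @ w), atol=1e-12)

    def test_iid_noise_recovers_identity(self, rng):
        """n=1e4 unit-variance residuals: shrunk cov within 0.1 of I."""
        B = rng.standard_normal((8, 10_000))
        nm = estimate_noise(B, np.zeros(8), np.zeros(10_000))
        assert np.linalg.norm(nm.shrunk_cov - np.eye(8)) < 0.1

    def test_shrinkage_in_unit_interval(self, rng):
        for _ in range(100):
            X = rng.standard_normal((5, 12))
            assert 0.0 <= analytic_shrinkage_intensity(X) <= 1.0

    def test_shrinkage_matches_sklearn(self, rng):
        """Analytic intensity agrees with the Ledoit-Wolf reference."""
        from sklearn.covariance import ledoit_wolf_shrinkage

        X = center(rng.standard_normal((6, 200)))
        ours = analytic_shrinkage_intensity(X)
        ref = ledoit_wolf_shrinkage(X.T, assume_centered=True)
        assert ours == pytest.approx(ref, abs=1e-10)

    def test_too_few_presentations_raises(self):
        with pytest.raises(ValueError, match="two training"):
            estimate_noise(np.ones((3, 1)), np.ones(3), np.ones(1))


class TestSpatialFilter:
    def test_identity_covariance_reduction(self, rng):
        w = rng.standard_normal(6)
        np.testing.assert_allclose(spatial_filter(w, np.eye(6)), w / (w @ w))

    def test_hand_computed_2x2_case(self):
        # w=(1,0), cov=diag(2,1): cov^-1 w = (0.5, 0); w' cov^-1 w = 0.5
        v = spatial_filter(np.array([1.0, 0.0]), np.diag([2.0, 1.0]))
        np.testing.assert_allclose(v, [1.0, 0.0])
        # cross-check by independent solve
        ref = np.linalg.solve(np.diag([2.0, 1.0]), [1.0, 0.0])
        np.testing.assert_allclose(v, ref / ([1.0, 0.0] @ ref))

    def test_unit_gain_identity_over_random_instances(self, rng):
        """v' w = 1 for random SPD covariances (the filter's defining identity)."""
        for _ in range(100):
            p = rng.integers(2, 9)
            w = rng.standard_normal(p)
            cov = random_spd(rng, p)
            assert spatial_filter(w, cov) @ w == pytest.approx(1.0, abs=1e-10)


class TestReconstructDecode:
    def test_orthogonal_weights_identity_reconstruction(self, rng):
        W, _ = np.linalg.qr(rng.standard_normal((8, 5)))
        c = rng.uniform(0, 1, 5)
        V = W / np.einsum("pk,pk->k", W, W)[None, :]
        np.testing.assert_allclose(reconstruct(V, W @ c), c, atol=1e-12)
        np.testing.assert_allclose(reconstruct(V, np.zeros(8)), 0.0)

    def test_matches_triple_loop_oracle(self, rng):
        V = rng.standard_normal((6, 5))
        B = rng.standard_normal((6, 9))
        out = reconstruct(V, B)
        oracle = np.zeros((5, 9))
        for i in range(5):
            for j in range(9):
                for p in range(6):
                    oracle[i, j] += V[p, i] * B[p, j]
        np.testing.assert_allclose(out, oracle, atol=1e-12)

    @pytest.mark.parametrize(
        "c_hat, expected",
        [
            ([0.0, 1.0, 0.0, 0.0, 0.0], 36.0),   # one-hot preferred channel
            ([1.0, 1.0, 0.0, 0.0, 0.0], 18.0),   # symmetric midpoint
        ],
    )
    def test_phasor_decode_cases(self, c_hat, expected):
        assert decode_orientation(np.array(c_hat)) == pytest.approx(expected)

    def test_equal_weights_undefined(self):
        assert np.isnan(decode_orientation(np.ones(5)))

    def test_accuracy_extremes_and_null(self, rng):
        theta = rng.uniform(0, 180, 200)
        assert decoding_accuracy(theta, theta)[0] == pytest.approx(1.0)
        assert decoding_accuracy((theta + 90.0) % 180.0, theta)[0] == pytest.approx(-1.0)
        dec = rng.uniform(0, 180, 100_000)
        pres = rng.uniform(0, 180, 100_000)
        r, _ = decoding_accuracy(dec, pres)
        assert abs(r) < 0.02

    def test_accuracy_invariant_under_common_rotation(self, rng):
        theta = rng.uniform(0, 180, 50)
        dec = rng.uniform(0, 180, 50)
        r0, _ = decoding_accuracy(dec, theta)
        r1, _ = decoding_accuracy((dec + 77.7) % 180.0, (theta + 77.7) % 180.0)
        assert r0 == pytest.approx(r1, abs=1e-12)

    def test_all_undefined_raises(self):
        with pytest.raises(ValueError, match="no defined"):
            decoding_accuracy([np.nan, np.nan], [10.0, 20.0])


class TestPipeline:
    def test_oracle_equivalence_small_instance(self, rng):
        """Every intermediate matrix matches naive per-formula implementations."""
        n_sensors, n_trials = 4, 40
        theta = rng.uniform(0, 180, n_trials)
        X = rng.standard_normal((n_trials, n_sensors))
        est = ed.InvertedEncodingDecoder().fit(X, theta)

        basis = BasisSet()
        B = X.T - X.T.mean(axis=1, keepdims=True)
        C = channel_responses(theta, basis)
        C = C - C.mean(axis=1, keepdims=True)
        for i in range(5):
            ci = C[i]
            wi = (1.0 / (ci @ ci)) * (B @ ci)               # one-regressor LS
            np.testing.assert_allclose(est.weights_[:, i], wi, atol=1e-8)
            eps = B - np.outer(wi, ci)
            raw = eps @ eps.T / (n_trials - 1)
            np.testing.assert_allclose(est.noise_models_[i].raw_cov, raw, atol=1e-8)
            lam = est.noise_models_[i].shrinkage
            shrunk = (1 - lam) * raw + lam * np.mean(np.diag(raw)) * np.eye(n_sensors)
            np.testing.assert_allclose(est.noise_models_[i].shrunk_cov, shrunk,
                                       atol=1e-8)
            vi = np.linalg.inv(shrunk) @ wi / (wi @ np.linalg.inv(shrunk) @ wi)
            np.testing.assert_allclose(est.filters_[:, i], vi, atol=1e-8)
        np.testing.assert_allclose(
            est.transform(X), (est.filters_.T @ B).T, atol=1e-8
        )

    def test_filter_weight_unit_gain_after_fit(self, rng, small_schedule):
        ds = single_timepoint_dataset(small_schedule, n_sensors=8, seed=3)
        est = ed.InvertedEncodingDecoder().fit(
            ds.data[:, :, 0], ds.schedule["target_orientation_deg"]
        )
        gains = np.einsum("pk,pk->k", est.filters_, est.weights_)
        np.testing.assert_allclose(gains, 1.0, atol=1e-10)

    def test_high_snr_closed_loop(self, small_schedule):
        """High-SNR recovery: r > 0.9, per-trial error bounded by the basis's
        intrinsic phasor aliasing (~5 deg), zero-mean."""
        ds = single_timepoint_dataset(small_schedule, n_sensors=32, snr=1e3,
                                      seed=4)
        res = ed.crossvalidated_decode(ds, k=10, seed=0)
        theta = small_schedule["target_orientation_deg"].to_numpy()
        assert res.accuracy["all"][0] > 0.9
        err = (res.decoded_deg[:, 0] - theta + 90.0) % 180.0 - 90.0
        assert np.abs(err).max() < 8.0
        assert abs(err.mean()) < 1.0

    def test_equivariance_under_36deg_rotation(self, rng):
        """Shifting every orientation label by the channel spacing shifts
        every decode by exactly the same amount (the basis is 36-deg
        shift-covariant, so the whole chain is a channel permutation)."""
        n = 80
        theta = rng.uniform(0, 180, n)
        W = rng.standard_normal((16, 5))
        X = (W @ channel_responses(theta)).T + 0.3 * rng.standard_normal((n, 16))
        dec0 = ed.InvertedEncodingDecoder().fit(X, theta).predict(X)
        for delta in (36.0, 72.0):
            dec1 = ed.InvertedEncodingDecoder().fit(X, (theta + delta) % 180.0).predict(X)
            diff = (dec1 - dec0 - delta + 90.0) % 180.0 - 90.0
            assert np.abs(diff).max() < 1e-8

    def test_permuted_labels_decode_at_chance(self, small_schedule):
        accs = []
        for seed in range(20):
            ds = single_timepoint_dataset(small_schedule, n_sensors=16, snr=2.0,
                                          seed=seed)
            rng = np.random.default_rng(seed)
            shuffled = ds.schedule.copy()
            shuffled["target_orientation_deg"] = rng.permutation(
                shuffled["target_orientation_deg"].to_numpy()
            )
            ds_perm = ed.EpochedDataset(
                data=ds.data, sampling_rate_hz=ds.sampling_rate_hz,
                epoch_window_ms=ds.epoch_window_ms,
                sensor_labels=ds.sensor_labels, schedule=shuffled,
            )
            res = ed.crossvalidated_decode(ds_perm, k=10, seed=seed)
            accs.append(res.accuracy["all"][0])
        assert abs(np.mean(accs)) < 0.05

    def test_determinism(self, small_schedule):
        ds = single_timepoint_dataset(small_schedule, n_sensors=8, seed=1)
        a = ed.crossvalidated_decode(ds, k=10, seed=5)
        b = ed.crossvalidated_decode(ds, k=10, seed=5)
        np.testing.assert_array_equal(a.decoded_deg, b.decoded_deg)
        np.testing.assert_array_equal(a.accuracy["all"], b.accuracy["all"])

    def test_too_few_trials_raises(self, small_schedule):
        ds = single_timepoint_dataset(small_schedule.iloc[:5], n_sensors=4, seed=0)
        with pytest.raises(ValueError, match="folds"):
            ed.crossvalidated_decode(ds, k=10)
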