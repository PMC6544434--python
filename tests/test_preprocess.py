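import numpy as np
import pytest

from xmv1 import preprocess, synthetic
from xmv1.datatypes import RoiTraceSet

FR = 31.5


class TestSubtractNeuropil:
    def test_zero_neuropil_identity(self):
        tr = RoiTraceSet(F=np.full((2, 10), 5.0), F_np=np.zeros((2, 10)))
        assert np.array_equal(preprocess.subtract_neuropil(tr), tr.F)

    def test_paper_coefficient(self):
        tr = RoiTraceSet(F=np.full((1, 4), 10.0), F_np=np.full((1, 4), 10.0))
        assert np.allclose(preprocess.subtract_neuropil(tr, 0.7), 3.0)

    def test_weight_bounds(self):
        tr = RoiTraceSet(F=np.ones((1, 4)), F_np=np.ones((1, 4)))
        with pytest.raises(ValueError):
            preprocess.subtract_neuropil(tr, 1.5)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            RoiTraceSet(F=np.ones((2, 10)), F_np=np.ones((2, 9)))


class TestEstimateBaseline:
    def test_constant_trace(self):
        F = np.full((1, int(25 * FR)), 7.0)
        F_c0, flagged = preprocess.estimate_baseline(F, FR)
        assert np.allclose(F_c0, 7.0)
        assert flagged == []

    def test_notch_shared_by_neighborhood(self):
        # oracle: brute-force min over truncated 5-block windows
        n_blocks = 8
        spb = int(round(5 * FR))
        F = np.full((1, n_blocks * spb), 10.0)
        F[0, 3 * spb: 3 * spb + spb // 2] = 2.0  # deep notch in block 3
        F_c0, _ = preprocess.estimate_baseline(F, FR, gaussian_sigma=0.05)
        from scipy.ndimage import gaussian_filter1d
        sm = gaussian_filter1d(F, 0.05 * FR, axis=1)
        block_min = [sm[0, b * spb:(b + 1) * spb].min() for b in range(n_blocks)]
        expected = [
            min(block_min[max(0, b - 2):min(n_blocks, b + 3)])
            for b in range(n_blocks)
        ]
        assert np.allclose(F_c0[0], expected)
        # notch shared by blocks 1..5
        assert np.all(F_c0[0, 1:6] < 5.0)
        assert F_c0[0, 0] > 5.0 and F_c0[0, 7] > 5.0

    def test_rising_staircase_nondecreasing(self):
        spb = int(round(5 * FR))
        F = np.concatenate([np.full(spb, v) for v in [1, 2, 3, 4, 5, 6, 7]])[None]
        F_c0, _ = preprocess.estimate_baseline(F, FR)
        assert np.all(np.diff(F_c0[0]) >= 0)

    def test_nonpositive_baseline_flagged(self):
        F = np.full((2, int(25 * FR)), 5.0)
        F[1] = -1.0
        _, flagged = preprocess.estimate_baseline(F, FR)
        assert flagged == [1]


class TestDff:
    def test_equal_gives_zero(self):
        assert np.allclose(preprocess.dff(np.full((1, 5), 3.0), np.full((1, 5), 3.0)), 0.0)

    def test_double_gives_one(self):
        assert np.allclose(preprocess.dff(np.full((1, 5), 6.0), np.full((1, 5), 3.0)), 1.0)

    def test_nonpositive_baseline_names_roi(self):
        with pytest.raises(ValueError, match=r"\[1\]"):
            preprocess.dff(np.ones((2, 5)), np.array([[1.0] * 5, [0.0] * 5]))

    def test_baseline_idempotence(self):
        # re-normalising an already-normalised constant-baseline trace
        F = np.full((1, int(30 * FR)), 4.0)
        F[0, 100:110] += 1.0
        F_c0, _ = preprocess.estimate_baseline(F, FR)
        base = preprocess.expand_baseline(F_c0, F.shape[1], FR)
        f1 = preprocess.dff(F, base)
        g = f1 + 1.0  # shift to positive baseline 1
        G_c0, _ = preprocess.estimate_baseline(g, FR)
        base2 = preprocess.expand_baseline(G_c0, g.shape[1], FR)
        f2 = preprocess.dff(g, base2)
        assert np.abs(f2 - f1).max() < 1e-10


class TestDeconvolve:
    def test_constant_maps_to_c_over_tau(self):
        f = np.full((1, 50), 3.0)
        assert np.allclose(preprocess.deconvolve(f, tau=2.0, frame_rate=FR), 1.5)

    def test_exponential_is_in_nullspace(self):
        t = np.arange(200) / FR
        f = np.exp(-t / 2.0)[None]
        r = preprocess.deconvolve(f, tau=2.0, frame_rate=FR)
        # finite-difference error only
        assert np.abs(r[0, :-1]).max() < 0.01

    def test_impulse_train_roundtrip(self):
        # oracle: numeric forward-convolution then deconvolution
        rng = np.random.default_rng(3)
        rates = np.zeros((1, 500))
        rates[0, rng.choice(450, 12, replace=False) + 10] = rng.uniform(1, 5, 12)
        tr = synthetic.rates_to_fluorescence(rates, tau_rise=0.0, noise_sd=0.0,
                                             frame_rate=FR)
        f = tr.F / 100.0 - 1.0
        r = preprocess.deconvolve(f, tau=2.0, frame_rate=FR)
        # forward difference advances the estimate by exactly one frame
        recovered = r[0, :-1]
        expected = rates[0, 1:] * 0.1  # A * rate
        impulses = expected > 0
        assert np.allclose(recovered[impulses], expected[impulses], rtol=2e-3)
        # off-impulse residual is the finite-difference discretisation error
        assert np.abs(recovered[~impulses]).max() < 1e-3
        assert np.corrcoef(recovered, expected)[0, 1] > 0.999

    def test_linearity_exact(self, rng):
        f1 = rng.standard_normal((2, 100))
        f2 = rng.standard_normal((2, 100))
        lhs = preprocess.deconvolve(3.0 * f1 - 2.0 * f2, 2.0, FR)
        rhs = 3.0 * preprocess.deconvolve(f1, 2.0, FR) - 2.0 * preprocess.deconvolve(f2, 2.0, FR)
        assert np.allclose(lhs, rhs, atol=1e-12)

    def test_bad_tau(self):
        with pytest.raises(ValueError):
            preprocess.deconvolve(np.ones((1, 5)), tau=0)


class TestSmooth:
    def test_constant_unchanged(self):
        r = np.full((1, 100), 2.5)
        assert np.allclose(preprocess.smooth(r, frame_rate=FR), 2.5)

    def test_impulse_plateau(self):
        w = int(round(0.190 * FR))
        r = np.zeros((1, 101))
        r[0, 50] = 1.0
        sm = preprocess.smooth(r, frame_rate=FR)
        assert np.isclose(sm[0].max(), 1.0 / w)
        assert np.sum(np.isclose(sm[0], 1.0 / w)) == w

    def test_white_noise_variance_reduction(self, rng):
        w = int(round(0.190 * FR))
        x = rng.standard_normal((1, 200_000))
        sm = preprocess.smooth(x, frame_rate=FR)
        ratio = sm.var() / x.var()
        assert abs(ratio - 1.0 / w) < 0.02 / w * 5

    def test_too_short_window(self):
        with pytest.raises(ValueError):
            preprocess.smooth(np.ones((1, 10)), window=0.001, frame_rate=FR)


class TestEpochAndAverage:
    def test_blank_self_subtracts_to_zero(self, clean_dataset):
        ds = clean_dataset
        from xmv1 import preprocess as pp
        dec = pp.run(ds.traces)
        prof = pp.epoch_and_average(dec.r, ds.trials, FR)
        assert np.abs(prof.profiles["blank"]).max() < 1e-10

    def test_loud_on_profile_peaks_early(self, clean_dataset):
        ds = clean_dataset
        dec = preprocess.run(ds.traces)
        prof = preprocess.epoch_and_average(dec.r, ds.trials, FR)
        idx = [i for i, l in enumerate(ds.truth_labels) if l == "loud_ON"]
        assert idx, "fixture must contain a loud_ON cell"
        trace = prof.profiles["down_ramp"][idx[0]]
        # block starts 0.5 s before onset; peak within 0.5 s of onset
        t_peak = np.argmax(trace) / FR - 0.5
        assert 0.0 <= t_peak <= 0.5

    def test_all_trials_invalid_flags_missing(self, clean_dataset):
        ds = clean_dataset
        trials = ds.trials.copy()
        trials.loc[trials.stimulus == "down_ramp", "valid"] = False
        dec = preprocess.run(ds.traces)
        prof = preprocess.epoch_and_average(dec.r, trials, FR)
        assert "down_ramp" in prof.missing
        assert "down_ramp" not in prof.profiles

    def test_n_trials_used_bounded(self, small_dataset):
        ds = small_dataset
        dec = preprocess.run(ds.traces)
        prof = preprocess.epoch_and_average(dec.r, ds.trials, FR)
        for stim, n in prof.n_trials_used.items():
            assert n <= 10


class TestRoundTrip:
    def test_noiseless_roundtrip_correlation(self, clean_dataset):
        ds = clean_dataset
        dec = preprocess.run(ds.traces)
        truth = preprocess.smooth(ds.truth_rates * 0.1 / FR, frame_rate=FR)
        for i in range(ds.traces.n_roi):
            if truth[i].std() == 0:
                continue
            c = np.corrcoef(dec.r[i, :-1], truth[i, 1:])[0, 1]
            assert c > 0.99
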