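"""FBCSP chain: filter bank, CSP, features, MI/MIBIF, NBPW, end-to-end."""

import numpy as np
import pytest
import scipy.linalg
from hypothesis import given, settings, strategies as st
from scipy import signal as sig

from mibci import fbcsp
from mibci.fbcsp import (CspModel, classify_window, design_filter_bank,
                         apply_filter_bank, estimate_mi, extract_features,
                         fit_csp, fit_csp_single, fit_nbpw, posterior_nbpw,
                         predict_nbpw, select_features_mibif, train_pipeline)


class TestFilterBankDesign:
    def test_default_grid_is_17_overlapped_bands(self):
        spec = design_filter_bank()
        assert spec.n_bands == 17
        assert spec.bands[0] == (4.0, 8.0)
        assert spec.bands[-1] == (36.0, 40.0)
        for (lo1, hi1), (lo2, hi2) in zip(spec.bands, spec.bands[1:]):
            assert 4.0 <= lo1 < hi1 <= 40.0
            assert lo2 - lo1 == pytest.approx(2.0)
            assert hi1 - lo2 == pytest.approx(2.0)  # 2 Hz overlap step

    def test_infeasible_grid_rejected(self):
        with pytest.raises(fbcsp.FilterBankError):
            design_filter_bank(n_bands=10)

    def test_designs_stable_at_512(self):
        spec = design_filter_bank(fs=512.0)
        for sos in spec.sos:
            _, p, _ = sig.sos2zpk(sos)
            assert np.max(np.abs(p)) < 1.0


class TestFilterBankApplication:
    def test_tone_lands_in_matching_bands(self):
        spec = design_filter_bank()
        fs = spec.fs
        t = np.arange(int(4 * fs)) / fs
        tone = np.sin(2 * np.pi * 10.0 * t)[None, :]
        banded = apply_filter_bank(tone, spec)
        power = (banded[:, 0, :] ** 2).mean(axis=1)
        in_band = [i for i, (lo, hi) in enumerate(spec.bands) if lo <= 10 <= hi]
        assert int(np.argmax(power)) in in_band
        # 10 Hz lies deep in the last band's stopband
        atten_db = 10 * np.log10(power[-1] / power.max())
        assert atten_db <= -spec.attenuation_db

    def test_zero_in_zero_out_and_linearity(self, rng):
        spec = design_filter_bank()
        x = rng.standard_normal((2, 2048))
        y = rng.standard_normal((2, 2048))
        zero = apply_filter_bank(np.zeros((2, 2048)), spec)
        assert np.all(zero == 0)
        lin = apply_filter_bank(2.0 * x - 3.0 * y, spec)
        ref = 2.0 * apply_filter_bank(x, spec) - 3.0 * apply_filter_bank(y, spec)
        assert np.allclose(lin, ref, atol=1e-8)

    def test_short_window_rejected(self):
        spec = design_filter_bank()
        with pytest.raises(ValueError, match="warm-up"):
            apply_filter_bank(np.zeros((2, 20)), spec)


def random_psd(rng, n):
    m = rng.standard_normal((n, n))
    return m @ m.T + 0.1 * np.eye(n)


class TestCsp:
    def test_equal_covariances_give_half_eigenvalues(self, rng):
        c = random_psd(rng, 6)
        w, lam = fit_csp_single(c, c)
        assert np.allclose(lam, 0.5, atol=1e-10)

    def test_2x2_closed_form(self):
        w, lam = fit_csp_single(np.diag([4.0, 1.0]), np.diag([1.0, 4.0]))
        assert np.allclose(lam, [0.8, 0.2])
        # axis-aligned filters for diagonal covariances
        assert np.allclose(np.abs(w) > 1e-12, np.eye(2, dtype=bool))

    @settings(derandomize=True, deadline=None, max_examples=30)
    @given(n=st.integers(3, 8), seed=st.integers(0, 10_000))
    def test_matches_brute_force_generalized_eig(self, n, seed):
        """Whitening-based CSP vs scipy's generalized eigensolver, 1e-8."""
        rng = np.random.default_rng(seed)
        a, b = random_psd(rng, n), random_psd(rng, n)
        w, lam = fit_csp_single(a, b)
        ref = np.sort(scipy.linalg.eigh(a, a + b, eigvals_only=True))[::-1]
        assert np.allclose(lam, ref, atol=1e-8)
        assert np.allclose(w @ (a + b) @ w.T, np.eye(n), atol=1e-8)
        # filters diagonalize the first class covariance to its eigenvalues
        assert np.allclose(w @ a @ w.T, np.diag(lam), atol=1e-8)

    def test_non_pd_sum_rejected(self):
        z = np.zeros((3, 3))
        with pytest.raises(ValueError, match="positive definite"):
            fit_csp_single(z, z)

    def test_too_many_pairs_rejected(self, rng):
        a, b = random_psd(rng, 4), random_psd(rng, 4)
        with pytest.raises(ValueError, match="pairs"):
            fit_csp(a, b, m=3)


class TestFeatures:
    def _model(self, rng, n_bands=17, n_ch=8, m=2):
        covs = np.stack([
            np.stack([random_psd(rng, n_ch), random_psd(rng, n_ch)])
            for _ in range(n_bands)
        ])
        return fit_csp(covs[:, 0], covs[:, 1], m=m)

    def test_dimension_is_bands_times_2m(self, rng):
        spec = design_filter_bank()
        csp = self._model(rng)
        x = rng.standard_normal((8, 1024))
        f = extract_features(x, csp, spec)
        assert f.shape == (17 * 4,)
        assert np.all(np.isfinite(f))

    def test_scale_invariance(self, rng):
        spec = design_filter_bank()
        csp = self._model(rng)
        x = rng.standard_normal((8, 1024))
        f1 = extract_features(x, csp, spec)
        f2 = extract_features(123.4 * x, csp, spec)
        assert np.allclose(f1, f2, atol=1e-9)

    def test_equal_variance_gives_log_inverse_2m(self):
        # identity covariance on whitening filters -> all variances equal
        m = 2
        csp = CspModel(filters=np.eye(8)[None], eigenvalues=np.full((1, 8), .5),
                       m=m)
        covs = np.eye(8)[None, None]
        f = fbcsp.features_from_covs(covs, csp)
        assert np.allclose(f, np.log(1.0 / (2 * m)))


class TestMutualInformation:
    def test_separated_classes_approach_one_bit(self, rng):
        y = np.array(["left", "right"] * 100, dtype=object)
        x = np.where(y == "left", -10.0, 10.0) + 0.01 * rng.standard_normal(200)
        mi = estimate_mi(x[:, None], y)
        assert mi[0] > 0.95

    def test_independent_feature_near_zero(self, rng):
        y = np.array(["left", "right"] * 100, dtype=object)
        x = rng.standard_normal(200)
        assert estimate_mi(x[:, None], y)[0] < 0.05

    def test_permutation_destroys_information(self, rng):
        y = np.array(["left", "right"] * 100, dtype=object)
        x = np.where(y == "left", -2.0, 2.0) + 0.5 * rng.standard_normal(200)
        informative = estimate_mi(x[:, None], y)[0]
        permuted = [
            estimate_mi(x[:, None], y[rng.permutation(200)])[0]
            for _ in range(20)
        ]
        assert informative > 0.8
        assert np.median(permuted) < 0.05

    def test_monotone_rescaling_tolerance(self, rng):
        y = np.array(["left", "right"] * 100, dtype=object)
        x = np.where(y == "left", -1.0, 1.0) + 0.8 * rng.standard_normal(200)
        base = estimate_mi(x[:, None], y)[0]
        affine = estimate_mi((3.0 * x + 7.0)[:, None], y)[0]
        cbrt = estimate_mi(np.cbrt(x)[:, None], y)[0]
        arctan = estimate_mi(np.arctan(x)[:, None], y)[0]
        assert abs(affine - base) < 1e-9  # Parzen MI is affine-equivariant
        # mild monotone warping stays within the estimator tolerance;
        # heavy tail-stretching (e.g. cubing) is a documented limitation
        assert abs(cbrt - base) < 0.05
        assert abs(arctan - base) < 0.05

    def test_single_class_rejected(self):
        y = np.array(["left"] * 10, dtype=object)
        with pytest.raises(ValueError):
            estimate_mi(np.zeros((10, 1)), y)


class TestMibif:
    def test_partner_closure_size(self):
        m, d = 2, 68
        mi = np.zeros(d)
        mi[[0, 4, 8, 12]] = [4, 3, 2, 1]  # top filters of four bands
        sel = select_features_mibif(mi, k=4, m=m)
        assert 4 <= len(sel) <= 8
        for idx in (0, 4, 8, 12):
            assert idx in sel.selected
            assert fbcsp.csp_pair_partner(idx, m) in sel.selected

    def test_all_equal_takes_lowest_indices(self):
        sel = select_features_mibif(np.ones(20), k=3, m=2)
        assert set(sel.ranked[:3]) == {0, 1, 2}

    def test_k_equals_dimension_noop_closure(self):
        sel = select_features_mibif(np.arange(8.0), k=8, m=2)
        assert list(sel.selected) == list(range(8))

    def test_k_out_of_range(self):
        with pytest.raises(ValueError):
            select_features_mibif(np.ones(5), k=6, m=1)

    def test_pair_partner_involution(self):
        for m in (1, 2, 3):
            for idx in range(6 * 2 * m):
                p = fbcsp.csp_pair_partner(idx, m)
                assert fbcsp.csp_pair_partner(p, m) == idx
                assert p // (2 * m) == idx // (2 * m)  # same band


class TestNbpw:
    def test_two_kernel_hand_oracle(self):
        """One training point per class at -1/+1, h=1, test at 0.5."""
        x = np.array([[-1.0], [1.0]])
        y = np.array(["left", "right"], dtype=object)
        model = fit_nbpw(x, y, bandwidths=[1.0])
        phi = lambda z: np.exp(-0.5 * z ** 2) / np.sqrt(2 * np.pi)
        expected_right = phi(0.5) / (phi(0.5) + phi(1.5))
        cls, p = predict_nbpw(model, np.array([0.5]))
        assert cls == "right"
        assert p == pytest.approx(expected_right, abs=1e-8)

    def test_five_point_kernel_sum_oracle(self):
        """Explicit Parzen arithmetic on a 5-point training set, 2 features."""
        xl = np.array([[0.0, 1.0], [0.2, 0.8], [-0.1, 1.2]])
        xr = np.array([[1.0, -1.0], [1.3, -0.7]])
        x = np.vstack([xl, xr])
        y = np.array(["left"] * 3 + ["right"] * 2, dtype=object)
        h = np.array([0.5, 0.7])
        model = fit_nbpw(x, y, bandwidths=h)
        q = np.array([0.4, 0.1])

        def lik(train):
            dens = np.ones(1)
            for j in range(2):
                z = (q[j] - train[:, j]) / h[j]
                dens *= np.mean(np.exp(-0.5 * z ** 2)
                                / (np.sqrt(2 * np.pi) * h[j]))
            return dens[0]

        num_l, num_r = lik(xl) * (3 / 5), lik(xr) * (2 / 5)
        expected = {"left": num_l / (num_l + num_r),
                    "right": num_r / (num_l + num_r)}
        post = posterior_nbpw(model, q)
        assert post["left"] == pytest.approx(expected["left"], abs=1e-8)
        assert post["left"] + post["right"] == pytest.approx(1.0, abs=1e-12)

    def test_mirror_symmetric_training_gives_half(self):
        x = np.array([[-2.0], [-1.0], [1.0], [2.0]])
        y = np.array(["left", "left", "right", "right"], dtype=object)
        model = fit_nbpw(x, y)
        post = posterior_nbpw(model, np.array([0.0]))
        assert post["left"] == pytest.approx(0.5, abs=1e-12)

    def test_non_finite_input_rejected(self):
        model = fit_nbpw(np.array([[0.0], [0.1], [1.0], [1.1]]),
                         np.array(["left", "left", "right", "right"],
                                  dtype=object))
        with pytest.raises(ValueError, match="finite"):
            predict_nbpw(model, np.array([np.nan]))

    @settings(derandomize=True, deadline=None, max_examples=20)
    @given(seed=st.integers(0, 10_000))
    def test_posteriors_normalized(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal((12, 3))
        y = np.array(["left", "right"] * 6, dtype=object)
        model = fit_nbpw(x, y)
        post = posterior_nbpw(model, rng.standard_normal(3))
        assert sum(post.values()) == pytest.approx(1.0, abs=1e-12)


class TestPipeline:
    def test_resubstitution_accuracy_on_strong_erd(self, strong_session):
        eps = strong_session["epochs"]
        pipe = train_pipeline(eps, window=(3.0, 2.0))
        s0 = eps.time_to_sample(3.0)
        hits = 0
        for trial, label in zip(eps.data, eps.labels):
            cls, _ = classify_window(pipe, trial[:, s0:s0 + 1024],
                                     mode="zero-phase")
            hits += cls == label
        assert hits / eps.n_trials >= 0.95

    def test_end_to_end_scale_invariance(self, strong_session):
        eps = strong_session["epochs"]
        pipe = train_pipeline(eps, window=(3.0, 2.0))
        s0 = eps.time_to_sample(3.0)
        w = eps.data[0][:, s0:s0 + 1024]
        c1, p1 = classify_window(pipe, w)
        c2, p2 = classify_window(pipe, 10.0 * w)
        assert c1 == c2
        assert p1 == pytest.approx(p2, abs=1e-9)

    def test_training_features_reproduced_zero_phase(self, strong_session):
        """Feature extraction on a raw training window agrees with the stored
        training-time features when the same zero-phase filtering is used.

        Training filters the full 7 s trial before slicing, so residual
        differences come only from filter edge effects at the window cut."""
        eps = strong_session["epochs"]
        pipe = train_pipeline(eps, window=(3.0, 2.0))
        s0 = eps.time_to_sample(3.0)
        trial = eps.data[0]
        f_win = extract_features(trial[:, s0:s0 + 1024], pipe.csp, pipe.spec,
                                 mode="zero-phase")
        banded = apply_filter_bank(trial[None], pipe.spec)
        covs = fbcsp.trial_covariances(banded, s0, s0 + 1024)
        f_train = fbcsp.features_from_covs(covs, pipe.csp)[0]
        sel = pipe.selection.selected
        assert np.corrcoef(f_win[sel], f_train[sel])[0, 1] > 0.99

    def test_pipeline_json_round_trip(self, strong_session):
        eps = strong_session["epochs"]
        pipe = train_pipeline(eps, window=(3.0, 2.0))
        back = fbcsp.TrainedPipeline.from_json(pipe.to_json())
        s0 = eps.time_to_sample(3.0)
        w = eps.data[5][:, s0:s0 + 1024]
        assert classify_window(pipe, w) == classify_window(back, w)

    def test_window_outside_trial_rejected(self, tiny_session):
        with pytest.raises(ValueError, match="window"):
            train_pipeline(tiny_session["epochs"], window=(6.0, 2.0))
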