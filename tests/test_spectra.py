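import json

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from leafspec import (SpectralPreprocessor, Spectrum, average_replicates,
                      qc_spectrum, savgol_second_derivative, snv)
from leafspec.spectra import interpolate_masked, preprocess_chain

WL = np.arange(350.0, 2501.0)


def spec(values, wl=WL, **kw):
    return Spectrum(wl, np.asarray(values, dtype=float), **kw)


class TestSpectrumQC:
    def test_clean_spectrum_unchanged(self):
        s = qc_spectrum(spec(np.full(WL.size, 0.3)))
        assert not s.mask.any()
        assert set(s.qc_flags) == {"ok"}

    def test_single_negative_cell_masked(self):
        r = np.full(WL.size, 0.3)
        r[WL == 2499] = -0.01
        s = qc_spectrum(spec(r))
        assert s.mask.sum() == 1
        assert s.qc_flags[WL == 2499] == "negative_removed"
        assert np.all(s.reflectance[~s.mask] == 0.3)

    def test_all_negative_rejected(self):
        with pytest.raises(ValueError):
            qc_spectrum(spec(np.full(WL.size, -0.1)))

    def test_nonmonotone_grid_rejected(self):
        with pytest.raises(ValueError):
            Spectrum(np.array([500.0, 499.0, 501.0]), np.zeros(3))


class TestReplicateAveraging:
    def test_identical_replicates_average_to_themselves(self):
        rng = np.random.default_rng(0)
        r = rng.uniform(0.05, 0.5, WL.size)
        mean = average_replicates([spec(r)] * 9)
        np.testing.assert_allclose(mean.reflectance, r, rtol=1e-14)

    def test_two_value_mean(self):
        mean = average_replicates([spec(np.full(WL.size, 0.2)),
                                   spec(np.full(WL.size, 0.4))])
        np.testing.assert_allclose(mean.reflectance, 0.3)

    def test_masked_cell_excluded_hand_example(self):
        # three replicates, one masked (negative) at a single wavelength:
        # the mean there is over the remaining two
        wl = np.arange(500.0, 510.0)
        r1, r2, r3 = np.full(10, 0.2), np.full(10, 0.4), np.full(10, 0.9)
        r3[4] = -0.1
        reps = [qc_spectrum(Spectrum(wl, r)) for r in (r1, r2, r3)]
        mean = average_replicates(reps)
        assert mean.reflectance[4] == pytest.approx((0.2 + 0.4) / 2)
        assert mean.reflectance[0] == pytest.approx((0.2 + 0.4 + 0.9) / 3)

    def test_cell_masked_everywhere_stays_masked_then_interpolates(self):
        wl = np.arange(500.0, 510.0)
        r = np.full(10, 0.3)
        r[4] = -1.0
        reps = [qc_spectrum(Spectrum(wl, r.copy())) for _ in range(3)]
        mean = average_replicates(reps)
        assert mean.mask[4]
        with pytest.warns(UserWarning, match="interpolating"):
            filled = interpolate_masked(mean)
        assert filled.reflectance[4] == pytest.approx(0.3)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            average_replicates([spec(np.full(WL.size, 0.3)),
                                Spectrum(WL[:-1], np.full(WL.size - 1, 0.3))])

    def test_replicate_averaging_shrinks_noise_by_sqrt_n(self):
        # 9 replicates with sd sigma -> mean spectrum sd ~ sigma/3
        rng = np.random.default_rng(42)
        sigma, trials = 0.01, 1000
        errs = rng.normal(0, sigma, size=(trials, 9)).mean(axis=1)
        assert np.std(errs) == pytest.approx(sigma / 3.0, rel=0.1)


class TestSNV:
    @given(st.integers(0, 2 ** 31 - 1))
    def test_output_standardised(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.uniform(0, 1, 211)
        z = snv(x)
        assert abs(z.mean()) < 1e-12
        assert abs(z.std(ddof=1) - 1.0) < 1e-12

    def test_three_point_example_n_minus_one_convention(self):
        np.testing.assert_allclose(snv(np.array([1.0, 2.0, 3.0])),
                                   [-1.0, 0.0, 1.0], atol=1e-14)

    def test_constant_row_rejected(self):
        with pytest.raises(ValueError):
            snv(np.full(50, 0.3))


class TestSavgolSecondDerivative:
    def test_quadratic_maps_to_constant_2a(self):
        x = np.arange(100.0)
        a, b, c = 0.37, -1.2, 5.0
        d2 = savgol_second_derivative(a * x ** 2 + b * x + c, window=15)
        np.testing.assert_allclose(d2, 2 * a, atol=1e-8)

    def test_linear_maps_to_zero(self):
        d2 = savgol_second_derivative(3.0 * np.arange(60.0) + 1.0, window=11)
        np.testing.assert_allclose(d2, 0.0, atol=1e-9)

    def test_impulse_matches_bruteforce_local_polyfit(self):
        # window 5 on a length-5 row: every output point comes from the same
        # quadratic least-squares fit to all five samples
        row = np.array([0.0, 0.0, 1.0, 0.0, 0.0])
        x = np.arange(5.0)
        coeffs = np.polyfit(x, row, 2)  # brute-force oracle
        expected = np.full(5, 2 * coeffs[0])
        got = savgol_second_derivative(row, window=5, polyorder=2)
        np.testing.assert_allclose(got, expected, atol=1e-12)

    @pytest.mark.parametrize("window,polyorder", [(4, 2), (5, 5), (5, 1)])
    def test_invalid_settings_rejected(self, window, polyorder):
        with pytest.raises(ValueError):
            savgol_second_derivative(np.zeros(50), window=window,
                                     polyorder=polyorder)

    def test_row_shorter_than_window_rejected(self):
        with pytest.raises(ValueError):
            savgol_second_derivative(np.zeros(7), window=15)


class TestPreprocessingChain:
    def _matrix(self, n=12, seed=0):
        rng = np.random.default_rng(seed)
        base = 0.2 + 0.2 * np.sin(WL / 300.0)
        return base + rng.normal(0, 0.01, size=(n, WL.size))

    def test_training_columns_centred(self):
        X = self._matrix()
        prep = SpectralPreprocessor(wavelengths=WL).fit(X)
        out = prep.transform(X)
        assert np.abs(out.mean(axis=0)).max() < 1e-10

    def test_subset_to_modelling_range_before_transforms(self):
        X = self._matrix()
        prep = SpectralPreprocessor(wavelengths=WL).fit(X)
        assert prep.wavelengths_.min() >= 450.0
        assert prep.wavelengths_.max() <= 2500.0

    def test_refit_equals_replay_on_training_set(self):
        X = self._matrix()
        prep = SpectralPreprocessor(wavelengths=WL)
        via_fit_transform = prep.fit_transform(X)
        via_replay = prep.transform(X)
        np.testing.assert_array_equal(via_fit_transform, via_replay)

    def test_test_row_equal_to_training_row_maps_identically(self):
        X = self._matrix()
        prep = SpectralPreprocessor(wavelengths=WL).fit(X)
        dup = prep.transform(X[3][None, :])
        np.testing.assert_allclose(dup[0], prep.transform(X)[3], atol=1e-12)

    def test_serialise_roundtrip_bit_identical(self):
        X = self._matrix()
        prep = SpectralPreprocessor(wavelengths=WL).fit(X)
        replay = SpectralPreprocessor.from_json(prep.to_json())
        np.testing.assert_array_equal(replay.transform(X), prep.transform(X))
        # and the state survives a second serialisation unchanged
        assert json.loads(replay.to_json()) == json.loads(prep.to_json())

    def test_preprocessing_state_records_the_declared_order(self):
        X = self._matrix()
        prep = SpectralPreprocessor(wavelengths=WL).fit(X)
        steps = [s["step"] for s in prep.preprocessing_state_]
        assert steps == ["subset", "snv", "savgol_d2", "autoscale", "mean_center"]

    def test_functional_wrapper(self):
        X = self._matrix()
        out, prep = preprocess_chain(X, wavelengths=WL, train_index=range(6))
        assert out.shape[0] == X.shape[0]
        assert out[:6].mean(axis=0) == pytest.approx(0.0, abs=1e-10)
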