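import numpy as np
import pytest

from leafspec import SyntheticConfig, metrics, simulate_study
from leafspec.validation import (Dataset, build_dataset, loo_cv,
                                 repeated_split, select_stress_dates,
                                 stress_holdout)


class TestMetrics:
    def test_perfect_prediction(self):
        m = metrics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert m.r_squared == pytest.approx(1.0)
        assert m.rmse == 0.0

    def test_constant_offset_keeps_correlation_but_not_rmse(self):
        # diagnostic of the squared-Pearson convention: a biased but
        # perfectly correlated prediction still has R2 = 1
        obs = np.array([1.0, 2.0, 3.0, 4.0])
        m = metrics(obs, obs + 2.5)
        assert m.r_squared == pytest.approx(1.0)
        assert m.rmse == pytest.approx(2.5)
        assert m.r2_sse < 1.0  # the SSE convention penalises the bias

    def test_four_point_hand_example(self):
        obs = np.array([1.0, 3.0, 2.0, 5.0])
        pred = np.array([1.5, 2.5, 2.5, 4.5])
        # direct formula evaluation (independent arithmetic oracle)
        r_num = np.sum((obs - obs.mean()) * (pred - pred.mean()))
        r_den = np.sqrt(np.sum((obs - obs.mean()) ** 2)
                        * np.sum((pred - pred.mean()) ** 2))
        expected_r2 = (r_num / r_den) ** 2
        expected_rmse = np.sqrt(np.mean((pred - obs) ** 2))
        m = metrics(obs, pred)
        assert m.r_squared == pytest.approx(expected_r2, abs=1e-12)
        assert m.rmse == pytest.approx(expected_rmse, abs=1e-12)

    def test_zero_variance_flagged_undefined(self):
        m = metrics([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert m.undefined and np.isnan(m.r_squared)

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            metrics([1.0, 2.0], [1.0, 2.0, 3.0])


class TestStressDateSelection:
    def test_argmax_of_pair_variance(self):
        # per-date psi variances {0.01, 0.01, 0.17, 0.0} give pair scores
        # {0.01, 0.09, 0.085}: the middle consecutive pair must win
        per_date_var = [0.01, 0.01, 0.17, 0.0]
        psi, dates = [], []
        for d, v in enumerate(per_date_var):
            half = np.sqrt(v / 2.0)  # two points at +/-half: ddof=1 var = v
            psi.extend([-0.5 - half, -0.5 + half])
            dates.extend([d, d])
        assert select_stress_dates(psi, dates) == (1, 2)

    def test_tie_resolves_to_earlier_pair(self):
        psi = [-0.4, -0.6, -0.4, -0.6, -0.4, -0.6]
        dates = [0, 0, 1, 1, 2, 2]
        assert select_stress_dates(psi, dates) == (0, 1)

    def test_requires_three_dates(self):
        with pytest.raises(ValueError):
            select_stress_dates([-0.4, -0.5, -0.6, -0.7], [0, 0, 1, 1])


@pytest.fixture(scope="module")
def noise_free_dataset(small_noise_free_study):
    return build_dataset(small_noise_free_study, trait_source="true")


class TestLOO:
    def test_one_fit_and_prediction_per_observation(self, noise_free_dataset):
        res = loo_cv(noise_free_dataset, "vcmax", max_components=5)
        n = len(noise_free_dataset.y["vcmax"])
        assert len(res.runs) == n
        assert res.predicted.shape == (n,)
        assert all(r.n_train == n - 1 and r.n_test == 1 for r in res.runs)

    def test_noise_free_injective_mapping_recovered(self, noise_free_dataset):
        res = loo_cv(noise_free_dataset, "vcmax", max_components=5)
        assert res.pooled.r_squared > 0.99

    def test_deterministic(self, noise_free_dataset):
        r1 = loo_cv(noise_free_dataset, "vcmax", max_components=3)
        r2 = loo_cv(noise_free_dataset, "vcmax", max_components=3)
        np.testing.assert_array_equal(r1.predicted, r2.predicted)

    def test_too_few_observations_rejected(self, noise_free_dataset):
        ds = noise_free_dataset
        tiny = Dataset(X=ds.X[:4], wavelengths=ds.wavelengths,
                       y={k: v[:4] for k, v in ds.y.items()},
                       psi_pd=ds.psi_pd[:4], date_index=ds.date_index[:4],
                       tree_id=ds.tree_id[:4])
        with pytest.raises(ValueError):
            loo_cv(tiny, "vcmax")


class TestRepeatedSplit:
    def test_summary_reproducible_under_seed(self, noise_free_dataset):
        a = repeated_split(noise_free_dataset, "vcmax", n_reps=5, seed=3,
                           max_components=4)
        b = repeated_split(noise_free_dataset, "vcmax", n_reps=5, seed=3,
                           max_components=4)
        assert a.summary == b.summary
        np.testing.assert_array_equal(a.predicted, b.predicted)

    def test_noise_free_splits_near_perfect(self, noise_free_dataset):
        res = repeated_split(noise_free_dataset, "vcmax", n_reps=5, seed=1,
                             max_components=4)
        assert all(r.r_squared > 0.98 for r in res.runs)

    def test_train_test_partition(self, noise_free_dataset):
        res = repeated_split(noise_free_dataset, "vcmax", n_reps=3, seed=2,
                             max_components=3)
        n = len(noise_free_dataset.y["vcmax"])
        assert all(r.n_train + r.n_test == n for r in res.runs)

    def test_invalid_fraction_rejected(self, noise_free_dataset):
        with pytest.raises(ValueError):
            repeated_split(noise_free_dataset, "vcmax", train_fraction=1.2)

    def test_mean_r2_improves_with_training_fraction(self, default_dataset):
        # the training-fraction sweep: more calibration data gives better
        # mean held-out performance (one adjacent-pair violation tolerated
        # as sampling noise).  The sd of per-repetition R2 is not required
        # to shrink: it reflects the held-out sample size, which falls as
        # the training fraction grows.
        fractions = [0.5, 0.6, 0.7, 0.8, 0.9]
        means = []
        for f in fractions:
            res = repeated_split(default_dataset, "vcmax", train_fraction=f,
                                 n_reps=12, seed=17, max_components=8)
            means.append(res.summary["mean_r2"])
        mean_viol = int(np.sum(np.diff(means) < -1e-6))
        assert mean_viol <= 1


class TestStressHoldout:
    def test_holds_out_the_stress_pair(self, default_dataset, default_study):
        res = stress_holdout(default_dataset, "vcmax", seed=0)
        peak = default_study.config.stress_peak_date_index
        assert res.held_out_dates == (peak, peak + 1)
        assert res.runs[0].n_train + res.runs[0].n_test == len(
            default_dataset.y["vcmax"])

    def test_trains_only_on_calm_dates(self, default_dataset):
        res = stress_holdout(default_dataset, "vcmax", seed=0)
        held = np.array(res.runs[0].held_out)
        held_dates = default_dataset.date_index[held]
        assert set(held_dates) == set(res.held_out_dates)


class TestLeakFreeCanary:
    def test_test_only_artifact_cannot_improve_training_rmsep(
            self, default_dataset):
        """Poisoning held-out spectra with a perfectly informative artefact
        must leave the training-fold RMSEP curve bit-identical."""
        ds = default_dataset
        res = stress_holdout(ds, "vcmax", seed=0)
        held = np.array(res.runs[0].held_out)
        X_poison = ds.X.copy()
        # overwrite a SWIR region of the held-out rows with the trait value
        X_poison[held, 1800:1810] = ds.y["vcmax"][held, None] / 200.0
        poisoned = Dataset(X=X_poison, wavelengths=ds.wavelengths, y=ds.y,
                           psi_pd=ds.psi_pd, date_index=ds.date_index,
                           tree_id=ds.tree_id)
        res_p = stress_holdout(poisoned, "vcmax", seed=0)
        np.testing.assert_array_equal(res.runs[0].rmsep_curve,
                                      res_p.runs[0].rmsep_curve)
        assert res.runs[0].n_components == res_p.runs[0].n_components
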