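"""Tests for leave-one-out and bootstrap forecasting."""

import numpy as np
import pytest

from habitatdyn.calibrate import CalibrationResult, fit
from habitatdyn.models import VARIANTS, ModelParams, simulate
from habitatdyn.predict import (
    LOO_SCHEMES,
    BootstrapConfig,
    PredictionResult,
    bootstrap_predict,
    compare_predictions,
    loo_predict,
    loo_weights,
    update_with_data,
)


def _calibration(params, subject="s"):
    return CalibrationResult(
        variant=VARIANTS["D"], params=params, rss=0.01,
        sse_per_habitat=np.zeros(3), aicc=0.0, ccc=1.0, T=21, k=5,
        n_starts=1, converged_fraction=1.0, subject_id=subject)


PARAMS = ModelParams(k1=1.5, k2=0.5, d12=0.3, d21=0, d13=0, d23=0.2, theta=200)


def _series_from(params, subject="s", noise=None, seed=0):
    days = np.arange(7) * 1.5
    traj = simulate(VARIANTS["D"], params, [30, 15, 5], days)
    if noise:
        rng = np.random.default_rng(seed)
        traj = traj * (1 + rng.normal(0, noise, traj.shape))
    from habitatdyn.habitats import HabitatSeries
    return HabitatSeries(subject, "control", days, np.clip(traj, 0, None))


class TestLooWeights:
    def test_identical_cohort_uniform(self):
        w = loo_weights("initial_total_volume", [50.0], [[50.0]] * 4)
        np.testing.assert_allclose(w, 0.25)

    def test_exact_match_dominates(self):
        w = loo_weights("initial_total_volume", [50.0], [[50.0], [500.0], [900.0]])
        assert w[0] > 0.999

    def test_inverse_distance_arithmetic(self):
        w = loo_weights("initial_HVHC_volume", [0.0], [[1.0], [2.0], [4.0]])
        np.testing.assert_allclose(w, [4 / 7, 2 / 7, 1 / 7], atol=1e-5)

    def test_sum_one_and_permutation_equivariance(self):
        rng = np.random.default_rng(0)
        summaries = [rng.uniform(0, 1, 3) for _ in range(6)]
        heldout = rng.uniform(0, 1, 3)
        w = loo_weights("initial_composition", heldout, summaries)
        assert w.sum() == pytest.approx(1.0)
        perm = rng.permutation(6)
        w2 = loo_weights("initial_composition", heldout,
                         [summaries[i] for i in perm])
        np.testing.assert_allclose(w2, w[perm])

    def test_empty_cohort(self):
        with pytest.raises(ValueError, match="at least one"):
            loo_weights("initial_total_volume", [1.0], [])


class TestLooPredict:
    def test_identical_cohort_params_reduce_to_simulation(self):
        heldout = _series_from(PARAMS)
        cohort = [(_calibration(PARAMS, f"c{i}"), _series_from(PARAMS, f"c{i}"))
                  for i in range(4)]
        expected = simulate(VARIANTS["D"], PARAMS, heldout.volumes[0], heldout.days)
        for scheme in LOO_SCHEMES:
            pred = loo_predict(scheme, heldout, cohort)
            np.testing.assert_allclose(pred.mean, expected, rtol=1e-12)
            assert pred.sse_per_habitat is not None

    def test_cohort_mean_params_predict_well(self):
        rng = np.random.default_rng(1)
        cohort = []
        for i in range(6):
            p = ModelParams(k1=1.5 + rng.normal(0, 0.1), k2=0.5, d12=0.3,
                            d21=0, d13=0, d23=0.2, theta=200)
            cohort.append((_calibration(p, f"c{i}"), _series_from(p, f"c{i}")))
        heldout = _series_from(PARAMS)  # truth at the cohort center
        pred = loo_predict("initial_total_volume", heldout, cohort)
        assert np.all(pred.sse_per_habitat < 0.05)

    def test_variant_mismatch(self):
        a = _calibration(PARAMS)
        b = CalibrationResult(
            variant=VARIANTS["A"], params=ModelParams(
                k1=1, k2=0.5, d12=0.1, d21=0.01, d13=0.01, d23=0.1, theta=100),
            rss=0.01, sse_per_habitat=np.zeros(3), aicc=0.0, ccc=1.0,
            T=21, k=7, n_starts=1, converged_fraction=1.0)
        heldout = _series_from(PARAMS)
        with pytest.raises(ValueError, match="mix variants"):
            loo_predict("initial_total_volume", heldout,
                        [(a, heldout), (b, heldout)])


class TestBootstrapPredict:
    def test_zero_variance_cohort_collapses(self):
        heldout = _series_from(PARAMS)
        cohort = [_calibration(PARAMS, f"c{i}") for i in range(4)]
        pred = bootstrap_predict(cohort, heldout.volumes[0], heldout.days,
                                 BootstrapConfig(n_b=20, seed=0), heldout=heldout)
        np.testing.assert_allclose(pred.upper - pred.lower, 0, atol=1e-9)
        expected = simulate(VARIANTS["D"], PARAMS, heldout.volumes[0], heldout.days)
        np.testing.assert_allclose(pred.mean, expected, rtol=1e-9)

    def test_nb_one_mean_is_single_draw(self):
        heldout = _series_from(PARAMS)
        rng = np.random.default_rng(2)
        cohort = []
        for i in range(4):
            p = ModelParams(k1=1.5 + rng.normal(0, 0.2), k2=0.5, d12=0.3,
                            d21=0, d13=0, d23=0.2, theta=200)
            cohort.append(_calibration(p, f"c{i}"))
        pred = bootstrap_predict(cohort, heldout.volumes[0], heldout.days,
                                 BootstrapConfig(n_b=1, seed=3), heldout=heldout)
        np.testing.assert_array_equal(pred.mean, pred.extra["curves"][0])

    def test_seeded_determinism_and_band_brackets_mean(self):
        heldout = _series_from(PARAMS)
        rng = np.random.default_rng(4)
        cohort = [_calibration(ModelParams(
            k1=max(1.5 + rng.normal(0, 0.3), 0.05), k2=0.5, d12=0.3,
            d21=0, d13=0, d23=0.2, theta=200), f"c{i}") for i in range(6)]
        cfg = BootstrapConfig(n_b=50, seed=9)
        a = bootstrap_predict(cohort, heldout.volumes[0], heldout.days, cfg)
        b = bootstrap_predict(cohort, heldout.volumes[0], heldout.days, cfg)
        np.testing.assert_array_equal(a.mean, b.mean)
        assert np.all(a.lower <= a.mean + 1e-9) and np.all(a.mean <= a.upper + 1e-9)

    def test_monte_carlo_se_shrinks_with_nb(self):
        """Pointwise-mean Monte-Carlo SE scales as 1/sqrt(n_b)."""
        heldout = _series_from(PARAMS)
        rng = np.random.default_rng(5)
        cohort = [_calibration(ModelParams(
            k1=max(1.5 + rng.normal(0, 0.3), 0.05), k2=0.5, d12=0.3,
            d21=0, d13=0, d23=0.2, theta=200), f"c{i}") for i in range(6)]
        ses = {}
        for n_b in (50, 200):
            pred = bootstrap_predict(cohort, heldout.volumes[0], heldout.days,
                                     BootstrapConfig(n_b=n_b, seed=11))
            curves = pred.extra["curves"]
            ses[n_b] = np.mean(curves.std(axis=0) / np.sqrt(n_b))
        ratio = ses[50] / ses[200]
        assert 1.5 < ratio < 2.7  # ideal 2.0 for a 4x sample increase

    def test_small_cohort_errors(self):
        heldout = _series_from(PARAMS)
        with pytest.raises(ValueError, match=">= 2"):
            bootstrap_predict([_calibration(PARAMS)], heldout.volumes[0],
                              heldout.days)


class TestUpdateWithData:
    def _setup(self, seed=0):
        rng = np.random.default_rng(seed)
        heldout = _series_from(PARAMS, noise=0.05, seed=seed)
        cohort = [_calibration(ModelParams(
            k1=max(1.5 + rng.normal(0, 0.2), 0.05), k2=0.5, d12=0.3,
            d21=0, d13=0, d23=0.2, theta=200), f"c{i}") for i in range(6)]
        boot = bootstrap_predict(cohort, heldout.volumes[0], heldout.days,
                                 BootstrapConfig(n_b=40, seed=seed), heldout=heldout)
        return heldout, boot

    def test_one_visit_is_pure_bootstrap(self):
        heldout, boot = self._setup()
        upd = update_with_data(boot, heldout, 1)
        np.testing.assert_array_equal(upd.mean, boot.mean)
        assert upd.extra["w"] == 0.0

    def test_all_visits_is_pure_individual_fit(self):
        heldout, boot = self._setup()
        upd = update_with_data(boot, heldout, heldout.n_visits, n_starts=10, seed=6)
        direct = fit(VARIANTS["D"], heldout, n_starts=10, seed=6)
        expected = simulate(VARIANTS["D"], direct.params, heldout.volumes[0],
                            heldout.days)
        np.testing.assert_allclose(upd.mean, expected, rtol=1e-9)
        assert upd.extra["w"] == 1.0
        assert any("retrospective" in f for f in upd.extra["flags"])

    def test_blend_is_convex_combination(self):
        heldout, boot = self._setup(seed=3)
        mid = update_with_data(boot, heldout, 4, n_starts=10, seed=8)
        w = mid.extra["w"]
        assert w == pytest.approx(3 / 6)
        individual = fit(VARIANTS["D"], heldout.truncate(4), n_starts=10, seed=8)
        curve = simulate(VARIANTS["D"], individual.params, heldout.volumes[0],
                         heldout.days)
        np.testing.assert_allclose(mid.mean, (1 - w) * boot.mean + w * curve,
                                   rtol=1e-9)
        # withheld-visit error is reported
        assert mid.sse_per_habitat is not None and np.all(mid.sse_per_habitat >= 0)

    def test_invalid_visits(self):
        heldout, boot = self._setup()
        with pytest.raises(ValueError, match="n_visits"):
            update_with_data(boot, heldout, 0)


class TestComparePredictions:
    def _fake(self, sse, subject):
        days = np.arange(3.0)
        z = np.zeros((3, 3))
        return PredictionResult(days=days, mean=z, lower=z, upper=z,
                                sse_per_habitat=np.asarray(sse, dtype=float),
                                method="m", subject_id=subject)

    def test_identical_methods_not_significant(self):
        a = [self._fake([1, 2, 3], f"s{i}") for i in range(8)]
        b = [self._fake([1, 2, 3], f"s{i}") for i in range(8)]
        report = compare_predictions({"m1": a, "m2": b})
        assert not report.significant.any()

    def test_shifted_sse_significant(self):
        rng = np.random.default_rng(0)
        base = [rng.uniform(1, 2, 3) for _ in range(8)]
        a = [self._fake(s, f"s{i}") for i, s in enumerate(base)]
        b = [self._fake(s + 100.0, f"s{i}") for i, s in enumerate(base)]
        report = compare_predictions({"m1": a, "m2": b})
        pairwise = report[report.comparison == "m1 vs m2"]
        assert pairwise.significant.all()

    def test_unmatched_subjects_error(self):
        a = [self._fake([1, 1, 1], "s1")]
        b = [self._fake([1, 1, 1], "s2")]
        with pytest.raises(ValueError, match="different subjects"):
            compare_predictions({"m1": a, "m2": b})
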