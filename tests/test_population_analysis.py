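"""Accuracy metrics, spread, subsampling, decay fits, group statistics."""

import numpy as np
import pandas as pd
import pytest

import prfdecode as p
from prfdecode.decoding import DecodedTrajectory
from tests.conftest import uniform_population


def as_decoded(positions, run_ids=None, method="ML"):
    if run_ids is None:
        run_ids = np.zeros(len(positions), dtype=int)
    return DecodedTrajectory(np.asarray(positions, float), run_ids, method)


class TestPredictionAccuracy:
    def test_perfect_and_mirrored(self):
        rng = np.random.default_rng(0)
        pos = rng.uniform(-3, 3, size=(50, 2))
        truth = p.VolumeSeries(pos, np.zeros(50, dtype=int))
        acc = p.prediction_accuracy(truth, as_decoded(pos))
        assert (acc.r_horizontal, acc.r_vertical) == (1.0, 1.0)
        mirrored = pos * np.array([-1.0, 1.0])
        acc = p.prediction_accuracy(truth, as_decoded(mirrored))
        assert acc.r_horizontal == pytest.approx(-1.0)
        assert acc.r_vertical == pytest.approx(1.0)

    def test_noise_attenuation_matches_closed_form(self):
        """Adding noise with the truth's SD attenuates r to 1/sqrt(2)."""
        rng = np.random.default_rng(1)
        pos = rng.normal(0, 1.5, size=(1440, 2))
        noisy = pos + rng.normal(0, 1.5, size=pos.shape)
        truth = p.VolumeSeries(pos, np.zeros(1440, dtype=int))
        acc = p.prediction_accuracy(truth, as_decoded(noisy))
        assert acc.r_horizontal == pytest.approx(1 / np.sqrt(2), abs=0.03)
        assert acc.r_vertical == pytest.approx(1 / np.sqrt(2), abs=0.03)

    def test_zero_variance_prediction_warns(self):
        pos = np.random.default_rng(2).uniform(-1, 1, (10, 2))
        truth = p.VolumeSeries(pos, np.zeros(10, dtype=int))
        with pytest.warns(UserWarning):
            acc = p.prediction_accuracy(truth, as_decoded(np.zeros((10, 2))))
        assert np.isnan(acc.r_horizontal)


class TestFisherZ:
    def test_values(self):
        assert p.fisher_z(0.0) == 0.0
        assert p.fisher_z(0.75) == pytest.approx(0.97296, abs=1e-5)

    def test_antisymmetry(self):
        for r in (0.1, 0.5, 0.9):
            assert p.fisher_z(-r) == pytest.approx(-p.fisher_z(r))

    def test_domain(self):
        with pytest.raises(ValueError):
            p.fisher_z(1.0)


class TestCenterSpread:
    def _fits(self, centers):
        return [
            p.FitResult(p.PRFParams(0, 1, x, y, 1.0, 1.0), 0.5, 0.0)
            for x, y in centers
        ]

    def test_hand_computed(self):
        assert p.center_spread(self._fits([(0, 0), (0, 0)])) == (0.0, 0.0)
        sd_x, sd_y = p.center_spread(self._fits([(-1, 0), (1, 0)]))
        assert sd_x == pytest.approx(np.sqrt(2))  # n-1 denominator
        assert sd_y == 0.0

    def test_requires_two(self):
        with pytest.raises(ValueError):
            p.center_spread(self._fits([(0, 0)]))

    def test_ffalike_population_narrow_vertical(self):
        preset = [pr for pr in p.make_area_presets() if pr.name == "FFAlike"][0]
        pop = p.sample_population(preset, seed=4)
        fits = self._fits(pop.mu)
        sd_x, sd_y = p.center_spread(fits)
        assert sd_y < sd_x


@pytest.fixture(scope="module")
def small_set(volumes3, spec):
    pop = uniform_population(40, 1.0, 0.3, seed=31)
    series = p.simulate_responses(pop, volumes3, spec, seed=32)
    return series, volumes3


@pytest.fixture(scope="module")
def gt_setup(volumes3, spec):
    from tests.test_decoding import population_fits

    pop = uniform_population(60, 1.2, 0.3, seed=41)
    series = p.simulate_responses(pop, volumes3, spec, seed=42)
    fits = population_fits(pop, 0.3)
    return fits, series, volumes3


class TestSubsampleAccuracy:
    def test_full_pool_equals_full_accuracy(self, small_set):
        series, volumes = small_set
        full = p.cross_validate(series, volumes, "ml")
        full_acc = p.prediction_accuracy(volumes, full)
        # pool size: rerun the internal selection to count eligible voxels
        sub = p.subsample_accuracy(
            series, volumes, n_voxels=self._pool_size(series, volumes), n_repeats=1, seed=0
        )
        assert sub.r_horizontal == pytest.approx(full_acc.r_horizontal, abs=1e-12)
        assert sub.r_vertical == pytest.approx(full_acc.r_vertical, abs=1e-12)

    @staticmethod
    def _pool_size(series, volumes):
        import warnings

        opts = p.DecodingOptions()
        sel = []
        for run in volumes.runs:
            train = volumes.run_ids != run
            fits = p.fit_voxels(
                series.amplitudes[:, train], volumes.subset(train), opts.fit, opts.spec
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                p.select_voxels(fits, opts.fit)
            sel.append([f.selected for f in fits])
        return int(np.any(sel, axis=0).sum())

    def test_deterministic_under_seed(self, small_set):
        series, volumes = small_set
        a = p.subsample_accuracy(series, volumes, 10, 3, seed=5)
        b = p.subsample_accuracy(series, volumes, 10, 3, seed=5)
        assert (a.r_horizontal, a.r_vertical) == (b.r_horizontal, b.r_vertical)

    def test_more_voxels_help_on_average(self, small_set):
        series, volumes = small_set
        few = p.subsample_accuracy(series, volumes, 5, 5, seed=6)
        many = p.subsample_accuracy(series, volumes, 30, 5, seed=6)
        assert many.r_horizontal > few.r_horizontal
        assert many.r_vertical > few.r_vertical

    def test_oversized_request_rejected(self, small_set):
        series, volumes = small_set
        with pytest.raises(ValueError):
            p.subsample_accuracy(series, volumes, 1000, 1, seed=0)


class TestDistanceExclusion:
    def test_zero_threshold_equals_full_decoding(self, gt_setup, spec):
        fits, series, volumes = gt_setup
        curve = p.distance_exclusion_curve(fits, series, volumes, [0.0, 1.0])
        table = p.build_likelihood_table(fits, p.DecodingGrid(), spec)
        pred = p.decode_ml_batch(series.amplitudes.T, table)
        r_full = np.corrcoef(volumes.positions[:, 0], pred[:, 0])[0, 1]
        assert curve.iloc[0]["r_horizontal"] == pytest.approx(r_full, abs=1e-12)
        assert curve.iloc[0]["n_skipped"] == 0

    def test_huge_threshold_skips_everything(self, gt_setup):
        fits, series, volumes = gt_setup
        curve = p.distance_exclusion_curve(fits, series, volumes, [0.0, 50.0])
        last = curve.iloc[-1]
        assert last["n_used"] == 0
        assert np.isnan(last["r_horizontal"])

    def test_accuracy_declines_with_threshold(self, gt_setup):
        fits, series, volumes = gt_setup
        curve = p.distance_exclusion_curve(
            fits, series, volumes, np.arange(0, 4.1, 1.0)
        )
        rs = curve["r_horizontal"].to_numpy()
        assert rs[0] > rs[-1]

    def test_thresholds_must_start_at_zero(self, gt_setup):
        fits, series, volumes = gt_setup
        with pytest.raises(ValueError):
            p.distance_exclusion_curve(fits, series, volumes, [0.5, 1.0])


class TestExponentialDecayFit:
    def test_exact_recovery(self):
        d = np.arange(0, 4.01, 0.5)
        y = 0.7 * np.exp(-d / 1.5) + 0.05
        fit = p.fit_exponential_decay(
            pd.DataFrame({"threshold": d, "r_horizontal": y})
        )
        assert fit.tau == pytest.approx(1.5, abs=1e-6)
        assert fit.amplitude == pytest.approx(0.7, abs=1e-6)
        assert fit.baseline == pytest.approx(0.05, abs=1e-6)
        assert fit.identifiable

    def test_flat_curve_flagged(self):
        d = np.arange(0, 4.01, 0.5)
        fit = p.fit_exponential_decay(
            pd.DataFrame({"threshold": d, "r_horizontal": np.full_like(d, 0.4)})
        )
        assert not fit.identifiable
        assert abs(fit.amplitude) < 1e-2

    def test_scaling_equivariance(self):
        d = np.arange(0, 4.01, 0.5)
        y = 0.6 * np.exp(-d / 2.0) + 0.1
        f1 = p.fit_exponential_decay(pd.DataFrame({"threshold": d, "r_horizontal": y}))
        f2 = p.fit_exponential_decay(
            pd.DataFrame({"threshold": d, "r_horizontal": 2 * y})
        )
        assert f2.tau == pytest.approx(f1.tau, rel=1e-4)
        assert f2.amplitude == pytest.approx(2 * f1.amplitude, rel=1e-4)
        assert f2.baseline == pytest.approx(2 * f1.baseline, rel=1e-4)


class TestGroupStats:
    def test_anova_hand_computed(self):
        gs = p.one_way_f([[1, 2, 3], [4, 5, 6]])
        assert gs.statistic == pytest.approx(13.5)
        assert gs.df == (1, 4)

    def test_anova_all_equal(self):
        gs = p.one_way_f([[2.0, 2.0], [2.0, 2.0]])
        assert gs.statistic == 0.0

    def test_anova_matches_independent_sums_of_squares(self):
        """scipy-based F equals a direct sums-of-squares computation."""
        rng = np.random.default_rng(0)
        for _ in range(10):
            groups = [rng.normal(size=rng.integers(3, 8)) for _ in range(4)]
            gs = p.one_way_f(groups)
            allv = np.concatenate(groups)
            grand = allv.mean()
            ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
            ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
            f_oracle = (ss_between / (len(groups) - 1)) / (
                ss_within / (len(allv) - len(groups))
            )
            assert gs.statistic == pytest.approx(f_oracle, abs=1e-8)

    def test_paired_t_hand_computed(self):
        gs = p.paired_t([1.0, 2.0, 3.0], [0.0, 0.0, 0.0])
        assert gs.statistic == pytest.approx(2 * np.sqrt(3), abs=1e-4)
        assert gs.df == (2,)

    def test_paired_t_zero_variance_flagged(self):
        gs = p.paired_t([1.0, 1.0, 1.0, 1.0], [0.0, 0.0, 0.0, 0.0])
        assert gs.flag == "zero-variance differences"
        assert np.isinf(gs.statistic)

    def test_paired_t_identical_inputs(self):
        gs = p.paired_t([1.0, 2.0], [1.0, 2.0])
        assert gs.statistic == 0.0

    def test_ci_hand_computed(self):
        lo, hi = p.ci_across_subjects([0.0, 1.0])
        half = 12.7062 * (np.std([0.0, 1.0], ddof=1) / np.sqrt(2))
        assert lo == pytest.approx(0.5 - half, abs=1e-4)
        assert hi == pytest.approx(0.5 + half, abs=1e-4)

    def test_ci_contains_mean_and_degenerate(self):
        lo, hi = p.ci_across_subjects([0.3, 0.5, 0.7])
        assert lo < 0.5 < hi
        lo, hi = p.ci_across_subjects([0.4, 0.4, 0.4])
        assert lo == pytest.approx(0.4)
        assert hi - lo == pytest.approx(0.0, abs=1e-12)
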