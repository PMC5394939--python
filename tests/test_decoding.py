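"""ML grid decoder, kernel SVR and leave-one-run-out cross-validation."""

import numpy as np
import pytest
from scipy import stats
from sklearn.metrics.pairwise import rbf_kernel

import prfdecode as p
from prfdecode.synthetic_population import noiseless_responses
from tests.conftest import uniform_population


def population_fits(pop, noise_floor=1e-6):
    """FitResults carrying a population's ground-truth parameters."""
    return [
        p.FitResult(
            params=p.PRFParams(
                C0=pop.C0[i],
                C1=pop.C1[i],
                mu_x=pop.mu[i, 0],
                mu_y=pop.mu[i, 1],
                sigma=pop.sigma[i],
                sigma_noise=max(pop.sigma_noise[i], noise_floor),
            ),
            fit_r=1.0,
            log_likelihood=0.0,
            selected=True,
        )
        for i in range(pop.n_voxels)
    ]


def brute_force_ml(activity, table):
    """Independent oracle: full Gaussian log-pdf summed per grid point."""
    lls = stats.norm.logpdf(
        activity[None, :], loc=table.rhat.T, scale=table.sigma_noise[None, :]
    ).sum(axis=1)
    return table.grid.positions[int(np.argmax(lls))]


class TestLikelihoodTable:
    def test_row_peaks_nearest_center(self, spec):
        pop = uniform_population(5, 0.8, 0.1, seed=1, extent=2.0)
        grid = p.DecodingGrid()
        table = p.build_likelihood_table(population_fits(pop), grid, spec)
        for i in range(5):
            peak = grid.positions[np.argmax(table.rhat[i])]
            # raster jitter of the binary indicator can move the flat
            # peak by one cell; require agreement within one cell step
            assert np.linalg.norm(peak - pop.mu[i]) <= 0.12

    def test_zero_gain_row_is_baseline(self, spec):
        pop = uniform_population(1, 1.0, 0.1, seed=2)
        pop.C1[:] = 0.0
        pop.C0[:] = 4.2
        table = p.build_likelihood_table(
            population_fits(pop), p.DecodingGrid(), spec
        )
        assert np.allclose(table.rhat, 4.2)

    def test_quadrature_refinement_changes_little(self):
        """Halving the pixel size leaves table entries nearly unchanged:
        the binary indicator's raster jitter bounds the worst entry at a
        few percent and the typical entry far below that."""
        pop = uniform_population(4, 0.9, 0.1, seed=3, extent=2.0)
        grid = p.DecodingGrid(n_x=12, n_y=12)
        t1 = p.build_likelihood_table(
            population_fits(pop), grid, p.StimulusSpec(pixel_size=0.1)
        )
        t2 = p.build_likelihood_table(
            population_fits(pop), grid, p.StimulusSpec(pixel_size=0.05)
        )
        rel = np.abs(t1.rhat - t2.rhat) / np.abs(t2.rhat).max()
        assert rel.max() < 0.05
        assert np.median(rel) < 0.005

    def test_empty_fits_rejected(self, spec):
        with pytest.raises(ValueError):
            p.build_likelihood_table([], p.DecodingGrid(), spec)


class TestDecodeML:
    def test_self_consistency_at_grid_points(self, spec):
        """Noiseless activity generated at a grid point decodes to it."""
        pop = uniform_population(50, 1.0, 0.2, seed=4)
        grid = p.DecodingGrid()
        table = p.build_likelihood_table(population_fits(pop, 0.2), grid, spec)
        rng = np.random.default_rng(0)
        for g in rng.choice(grid.n_points, 10, replace=False):
            pos = p.decode_ml(table.rhat[:, g], table)
            assert np.allclose(pos, grid.positions[g])

    def test_matches_brute_force_oracle(self, spec):
        """The vectorized decoder equals an exhaustive per-point scan of
        full Gaussian log-likelihoods on random instances."""
        rng = np.random.default_rng(7)
        pop = uniform_population(10, 1.0, 0.5, seed=5)
        pop.sigma_noise[:] = rng.uniform(0.2, 1.0, 10)
        table = p.build_likelihood_table(
            population_fits(pop, 0.0), p.DecodingGrid(), spec
        )
        for _ in range(20):
            activity = rng.normal(0.5, 1.0, size=10)
            assert np.allclose(
                p.decode_ml(activity, table), brute_force_ml(activity, table)
            )

    def test_voxel_permutation_invariance(self, spec):
        pop = uniform_population(20, 1.0, 0.3, seed=6)
        table = p.build_likelihood_table(
            population_fits(pop, 0.3), p.DecodingGrid(), spec
        )
        rng = np.random.default_rng(1)
        activity = rng.normal(size=20)
        perm = rng.permutation(20)
        t2 = p.LikelihoodTable(
            rhat=table.rhat[perm], sigma_noise=table.sigma_noise[perm], grid=table.grid
        )
        assert p.decode_ml(activity, table) == p.decode_ml(activity[perm], t2)

    def test_rejects_bad_activity(self, spec):
        pop = uniform_population(3, 1.0, 0.3, seed=8)
        table = p.build_likelihood_table(
            population_fits(pop, 0.3), p.DecodingGrid(), spec
        )
        with pytest.raises(ValueError):
            p.decode_ml(np.array([1.0, np.nan, 0.0]), table)
        with pytest.raises(ValueError):
            p.decode_ml(np.zeros(5), table)


class TestSVR:
    def test_kernel_is_one_at_zero_distance(self):
        Z = np.random.default_rng(0).normal(size=(4, 7))
        K = rbf_kernel(Z, gamma=1.0 / 7)
        assert np.allclose(np.diag(K), 1.0)

    def test_voxel_duplication_leaves_kernel_unchanged(self):
        """Doubling every voxel doubles ||r1-r2||^2 and N alike."""
        Z = np.random.default_rng(1).normal(size=(6, 10))
        K1 = rbf_kernel(Z, gamma=1.0 / 10)
        K2 = rbf_kernel(np.hstack([Z, Z]), gamma=1.0 / 20)
        assert np.allclose(K1, K2)

    def test_low_noise_in_sample_correlation(self, volumes3, spec):
        pop = uniform_population(40, 1.0, 0.1, seed=9)
        series = p.simulate_responses(pop, volumes3, spec, seed=10)
        model = p.train_svr(series.amplitudes, volumes3)
        pred = model.train_predictions
        for axis in range(2):
            r = np.corrcoef(volumes3.positions[:, axis], pred[:, axis])[0, 1]
            assert r > 0.9

    def test_predict_reproduces_training_predictions(self, volumes3, spec):
        pop = uniform_population(10, 1.0, 0.3, seed=11)
        series = p.simulate_responses(pop, volumes3, spec, seed=12)
        model = p.train_svr(series.amplitudes, volumes3)
        out = p.predict_svr(model, series.amplitudes)
        assert np.allclose(out.positions, model.train_predictions)

    def test_constant_targets_predict_constant(self):
        rng = np.random.default_rng(2)
        activity = rng.normal(size=(5, 30))
        positions = p.VolumeSeries(
            np.full((30, 2), 1.3), np.zeros(30, dtype=int)
        )
        model = p.train_svr(activity, positions)
        out = p.predict_svr(model, rng.normal(size=(5, 10)))
        assert np.allclose(out.positions, 1.3, atol=0.1 + 1e-9)  # epsilon tube

    def test_prediction_continuity(self, volumes3, spec):
        """An O(eps) amplitude perturbation moves predictions by O(eps)."""
        pop = uniform_population(8, 1.0, 0.2, seed=13)
        series = p.simulate_responses(pop, volumes3, spec, seed=14)
        model = p.train_svr(series.amplitudes, volumes3)
        a = series.amplitudes[:, :5].copy()
        base = p.predict_svr(model, a).positions
        a[3, 2] += 1e-4
        moved = p.predict_svr(model, a).positions
        assert np.abs(moved - base).max() < 1e-2

    def test_dimension_mismatch_rejected(self, volumes3, spec):
        pop = uniform_population(5, 1.0, 0.2, seed=15)
        series = p.simulate_responses(pop, volumes3, spec, seed=16)
        model = p.train_svr(series.amplitudes, volumes3)
        with pytest.raises(ValueError):
            p.predict_svr(model, np.zeros((6, 4)))


class TestCrossValidate:
    def test_every_volume_predicted_once(self, volumes3, clean_series):
        decoded = p.cross_validate(clean_series, volumes3, "ml")
        assert decoded.n_volumes == volumes3.n_volumes
        assert np.all(np.isfinite(decoded.positions))
        assert decoded.skipped_runs == []

    def test_identical_runs_decode_identically(self, short_schedule, spec):
        """With two byte-identical runs and no noise, the held-out
        predictions equal self-decoding of the training run."""
        tr = p.simulate_trajectory(p.TrajectoryConfig(seed=17), 240 * 60)
        one = p.frames_to_volumes(tr, short_schedule, 1)
        positions = np.vstack([one.positions, one.positions])
        runs = np.repeat([0, 1], one.n_volumes)
        volumes = p.VolumeSeries(positions, runs)
        pop = uniform_population(25, 1.0, 0.0, seed=18)
        clean = noiseless_responses(pop, volumes, spec)
        clean += np.random.default_rng(0).normal(0, 1e-3, clean.shape[0])[:, None]
        series = p.VoxelTimeSeriesSet(clean, runs)
        decoded = p.cross_validate(series, volumes, "ml")
        half = one.n_volumes
        assert np.allclose(decoded.positions[:half], decoded.positions[half:])

    def test_voxel_order_irrelevant_for_ml(self, volumes3, clean_series):
        perm = np.random.default_rng(3).permutation(clean_series.n_voxels)
        shuffled = clean_series.subset_voxels(perm)
        a = p.cross_validate(clean_series, volumes3, "ml")
        b = p.cross_validate(shuffled, volumes3, "ml")
        assert np.allclose(a.positions, b.positions)

    def test_requires_two_runs(self, clean_series, volumes3):
        mask = volumes3.run_ids == 0
        with pytest.raises(ValueError):
            p.cross_validate(
                clean_series.subset_volumes(mask), volumes3.subset(mask), "ml"
            )
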