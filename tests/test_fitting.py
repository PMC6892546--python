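import numpy as np
import pytest

from dnmodel import (
    ConstantDataError,
    DNParams,
    FitBounds,
    GridRanges,
    ResamplingError,
    SeedingError,
    dn_response,
    fit_biphasic_electrode,
    fit_contrast_family,
    fit_timecourse,
    grid_fit,
    resample_fit,
    scaled_shifted_fit,
    search_fit,
    step_stimulus,
    variance_explained,
)
from dnmodel.estimators import BiphasicDNModel, DNTimecourseModel
from dnmodel.fitting import GridEvaluator
from dnmodel.model import contrast_family_metrics
from dnmodel.synthetic import simulate_contrast_psths


@pytest.fixture(scope="module")
def two_contrast(epoch_grid):
    stim = step_stimulus(0.5, epoch_grid)
    return [stim, stim.scaled(0.3)]


@pytest.fixture(scope="module")
def evaluator(two_contrast):
    return GridEvaluator(two_contrast)


class TestVarianceExplained:
    def test_perfect_and_affine(self, rng):
        d = rng.standard_normal(200)
        assert variance_explained(d, d) == pytest.approx(1.0)
        assert variance_explained(3 * d + 5, d) == pytest.approx(1.0)

    def test_orthogonal(self):
        assert variance_explained([1, -1, 1, -1], [1, 1, -1, -1]) == pytest.approx(0.0, abs=1e-12)

    def test_constant_data_rejected(self):
        with pytest.raises(ConstantDataError):
            variance_explained([1.0, 2.0, 3.0], [4.0, 4.0, 4.0])


class TestGridFit:
    def test_default_grid_has_ten_thousand_nodes(self, evaluator):
        assert evaluator.n_nodes == 10_000

    def test_recovers_interior_node_and_gain(self, two_contrast, evaluator):
        """Data generated at a grid node are seeded at exactly that node."""
        axes = GridRanges().axes()
        node = DNParams(tau1=axes["tau1"][2], tau2=axes["tau2"][4],
                        n=axes["n"][3], sigma=axes["sigma"][5], gain=2.0)
        data = [dn_response(s, node).values / 2.0 * 2.0 for s in two_contrast]
        gf = grid_fit(data, two_contrast, evaluator=evaluator)
        assert np.allclose(
            gf.seed, [node.tau1, node.tau2, node.n, node.sigma], atol=1e-12
        )
        assert gf.gain == pytest.approx(2.0, abs=1e-6)
        assert gf.r2 == pytest.approx(1.0, abs=1e-9)

    def test_constant_zero_data_raises(self, two_contrast, evaluator):
        zeros = [np.zeros(s.grid.n) for s in two_contrast]
        with pytest.raises(SeedingError):
            grid_fit(zeros, two_contrast, evaluator=evaluator)


class TestSearchFit:
    truth = DNParams(tau1=0.15, tau2=0.25, n=2.5, sigma=0.15, shift=0.002, gain=2.0)

    def test_noiseless_two_contrast_recovery(self, two_contrast):
        """Two contrast levels break the n/sigma trade-off: exact recovery."""
        data = [dn_response(s, self.truth).values for s in two_contrast]
        fr = fit_timecourse(data, two_contrast)
        assert fr.r2 >= 0.999
        for name in ("tau1", "tau2", "n", "sigma"):
            rel = abs(getattr(fr.params, name) - getattr(self.truth, name))
            assert rel / getattr(self.truth, name) < 0.10, name

    def test_shift_stays_within_bounds(self, two_contrast):
        data = [dn_response(s, self.truth).values for s in two_contrast]
        fr = fit_timecourse(data, two_contrast)
        assert 0.0001 - 1e-12 <= fr.params.shift <= 0.1 + 1e-12

    def test_seed_outside_bounds_rejected(self, two_contrast):
        data = [dn_response(s, self.truth).values for s in two_contrast]
        with pytest.raises(ValueError):
            search_fit(data, two_contrast, seed=np.array([2.0, 0.1, 2.0, 0.1]))

    def test_refit_from_optimum_is_fixed_point(self, two_contrast):
        data = [dn_response(s, self.truth).values for s in two_contrast]
        fr = fit_timecourse(data, two_contrast)
        theta = np.array([fr.params.tau1, fr.params.tau2, fr.params.n,
                          fr.params.sigma, fr.params.shift])
        fr2 = search_fit(data, two_contrast, seed=theta)
        assert abs(fr2.sse - fr.sse) < 1e-8

    def test_search_improves_on_grid_seed(self, two_contrast, evaluator):
        """Seeding dominance: the refined objective never exceeds the seed's."""
        data = [dn_response(s, self.truth).values for s in two_contrast]
        gf = grid_fit(data, two_contrast, evaluator=evaluator)
        seed_params = DNParams(tau1=gf.seed[0], tau2=gf.seed[1], n=gf.seed[2],
                               sigma=gf.seed[3], gain=gf.gain)
        seed_pred = np.concatenate(
            [dn_response(s, seed_params).values for s in two_contrast]
        )
        seed_sse = float(np.sum((np.concatenate(data) - seed_pred) ** 2))
        fr = fit_timecourse(data, two_contrast)
        assert fr.sse <= seed_sse + 1e-12
        assert np.allclose(fr.seed_used, gf.seed)

    def test_noisy_recovery_of_tau1(self, two_contrast, evaluator, rng):
        """Median tau1 over repeated noisy fits lands within 20% of truth."""
        clean = [dn_response(s, self.truth).values for s in two_contrast]
        peak = max(c.max() for c in clean)
        estimates = []
        for _ in range(20):
            noisy = [c + rng.normal(0, peak / 10, c.shape) for c in clean]
            seed, _, _ = evaluator.best(np.concatenate(noisy))
            fr = search_fit(noisy, two_contrast, seed)
            estimates.append(fr.params.tau1)
        assert abs(np.median(estimates) - self.truth.tau1) / self.truth.tau1 < 0.2


FAMILY_TRUTH = DNParams(tau1=0.04, tau2=0.1, n=3.0, sigma=0.1, shift=0.01, gain=1.0)


@pytest.fixture(scope="module")
def family():
    return simulate_contrast_psths(FAMILY_TRUTH, duration=0.2)


@pytest.fixture(scope="module")
def fitted(family):
    psths, stims, contrasts = family
    return fit_contrast_family(psths, contrasts)


class TestContrastFamily:
    truth = FAMILY_TRUTH

    def test_noiseless_recovery(self, fitted):
        assert fitted.r2 >= 0.999
        for name in ("tau1", "tau2", "n", "sigma"):
            rel = abs(getattr(fitted.params, name) - getattr(self.truth, name))
            assert rel / getattr(self.truth, name) < 0.10, name

    def test_fitted_model_contrast_dynamics(self, fitted):
        """Fitted peaks grow and arrive earlier as contrast increases."""
        m = contrast_family_metrics(fitted.params, np.arange(1, 10) / 10, duration=0.2)
        assert np.all(np.diff(m.peak_amp_by_contrast) >= -1e-9)
        assert np.all(np.diff(m.peak_time_by_contrast) <= 1e-9)

    def test_zero_contrast_predicts_zero(self, family, fitted):
        _, stims, _ = family
        pred = dn_response(stims[0].scaled(0.0), fitted.params).values
        assert not np.any(pred)

    def test_contrast_domain_checked(self, family):
        psths, stims, contrasts = family
        with pytest.raises(ValueError):
            fit_contrast_family(psths, contrasts + 1.0)


class TestBiphasicFit:
    def test_weight_ordering_recovered(self, step_500):
        fits = {}
        for w in (0.8, 0.1):
            truth = DNParams(tau1=0.03, w=w, tau2=0.12, n=2.0, sigma=0.15,
                             shift=0.005, gain=3.0)
            data = dn_response(step_500, truth).values
            fits[w] = fit_biphasic_electrode(data, step_500)
        assert fits[0.8].params.w > fits[0.1].params.w

    def test_four_seeds_scored_and_n_fixed(self, step_500):
        truth = DNParams(tau1=0.03, w=0.5, tau2=0.12, n=2.0, sigma=0.15, gain=2.0)
        est = BiphasicDNModel().fit(step_500, dn_response(step_500, truth).values)
        assert len(est.seed_scores_) == 4
        assert est.params_.n == 2.0


class TestScaledShifted:
    def test_identity(self, step_500):
        ref = dn_response(step_500, DNParams(tau1=0.05, tau2=0.1, n=2.0, sigma=0.3)).values
        scale, shift, r2 = scaled_shifted_fit(ref, ref, dt=0.001)
        assert (scale, shift) == (1.0, 0.0)
        assert r2 == pytest.approx(1.0)

    def test_recovers_constructed_scale_and_delay(self, step_500):
        ref = dn_response(step_500, DNParams(tau1=0.05, tau2=0.1, n=2.0, sigma=0.3)).values
        tgt = np.zeros_like(ref)
        tgt[10:] = 0.5 * ref[:-10]
        scale, shift, r2 = scaled_shifted_fit(ref, tgt, dt=0.001)
        assert scale == pytest.approx(0.5, abs=1e-12)
        assert shift == pytest.approx(0.010, abs=1e-12)
        assert r2 == pytest.approx(1.0)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            scaled_shifted_fit(np.zeros(100), np.ones(100))


class TestResampling:
    truth = DNParams(tau1=0.1, tau2=0.15, n=2.0, sigma=0.1, shift=0.003, gain=5.0)

    def test_identical_electrodes_zero_width_ci(self, step_500):
        clean = dn_response(step_500, self.truth).values
        res = resample_fit(np.tile(clean, (6, 1)), step_500,
                           "bootstrap_electrodes", n_draws=25, rng_seed=0)
        assert np.max(res.ci_high - res.ci_low) == 0.0

    def test_loo_fold_count_and_generalization_gap(self, step_500, rng):
        clean = dn_response(step_500, self.truth).values
        trials = clean + rng.normal(0, 1.0, (6, step_500.grid.n))
        res = resample_fit(trials, step_500, "loo_trials")
        assert len(res.fits) == 6 and res.cv_r2.shape == (6,)
        assert res.cv_r2.mean() <= res.train_r2.mean()

    def test_determinism_under_seed(self, step_500, rng):
        clean = dn_response(step_500, self.truth).values
        data = clean + np.random.default_rng(7).normal(0, 0.5, (4, step_500.grid.n))
        a = resample_fit(data, step_500, "bootstrap_electrodes", n_draws=8, rng_seed=3)
        b = resample_fit(data, step_500, "bootstrap_electrodes", n_draws=8, rng_seed=3)
        assert np.array_equal(a.predictions, b.predictions)
        assert [f.params for f in a.fits] == [f.params for f in b.fits]

    def test_too_few_units_rejected(self, step_500):
        with pytest.raises(ResamplingError):
            resample_fit(np.ones((1, step_500.grid.n)), step_500, "loo_trials")


class TestEstimatorInterface:
    def test_sklearn_params_roundtrip(self):
        est = DNTimecourseModel(maxfev=123)
        assert est.get_params()["maxfev"] == 123
        est.set_params(maxfev=456)
        assert est.maxfev == 456

    def test_fit_predict_score(self, step_500):
        truth = DNParams(tau1=0.1, tau2=0.15, n=2.0, sigma=0.1, gain=2.0)
        data = dn_response(step_500, truth).values
        est = DNTimecourseModel().fit(step_500, data)
        pred = est.predict(step_500)
        assert pred.shape == data.shape
        assert est.score(step_500, data) == pytest.approx(est.r2_, abs=1e-9)
        assert est.converged_
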