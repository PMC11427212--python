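"""Tests for the curve-collapse calibration stage."""

import numpy as np
import pytest

from rlsense.calibrate import (
    EPS_DELTA_LAMBDA,
    REFERENCE_MH_OPTIMA,
    REFERENCE_NM_OPTIMA,
    CollapseDataset,
    calibrate,
    collapse_objective,
    compute_general_k,
    fit_exponential,
    fit_k_linearity,
    normalize_and_refit,
    optimize_metropolis_hastings,
    optimize_nelder_mead,
    reconstruct_and_score,
)
from rlsense.errors import DataError, FitError
from rlsense.model import CalibratedModel, OpticalProperties, REFERENCE_MODEL, forward_delta_lambda
from rlsense.synth import GeneratorConfig, study_collapse_dataset, study_sample_grid


def _model_dataset(dE_max=35.0, n=15, model=REFERENCE_MODEL, ops=None):
    """Dataset built directly from the forward model (no generator, no noise)."""
    if ops is None:
        ops = [s.op for s in study_sample_grid()]
    ids, msp, mua, de, dl = [], [], [], [], []
    dE = np.linspace(0.0, dE_max, n)
    for i, op in enumerate(ops):
        ids += [f"s{i}"] * n
        msp += [op.mu_s_prime] * n
        mua += [op.mu_a] * n
        de += list(dE)
        dl += list(forward_delta_lambda(op, dE, model))
    return CollapseDataset(np.array(ids), np.array(msp), np.array(mua), np.array(de), np.array(dl))


class TestFitExponential:
    def test_exact_recovery(self):
        x = np.arange(0.0, 55.0, 5.0)
        y = -2.0 * np.exp(-0.034 * x) + 2.0
        curve = fit_exponential(x, y)
        assert curve.a == pytest.approx(2.0, abs=1e-6)
        assert curve.b == pytest.approx(0.034, abs=1e-6)
        assert curve.c == pytest.approx(2.0, abs=1e-6)

    def test_saturating_growth_shape(self):
        # amplitude 1.13, rate 0.034: the through-origin saturating form
        x = np.linspace(0.0, 63.4, 25)
        y = 1.13 * (1.0 - np.exp(-0.034 * x))
        curve = fit_exponential(x, y)
        assert curve.a == pytest.approx(1.13, abs=1e-6)
        assert curve.c == pytest.approx(1.13, abs=1e-6)
        assert curve.b == pytest.approx(0.034, abs=1e-6)

    def test_constant_ordinate_unidentifiable(self):
        with pytest.raises(FitError):
            fit_exponential(np.arange(10.0), np.ones(10))

    def test_deterministic_repeats(self):
        rng = np.random.default_rng(2)
        x = np.linspace(0, 40, 30)
        y = 1.1 * (1 - np.exp(-0.03 * x)) + rng.normal(0, 0.01, 30)
        c1, c2 = fit_exponential(x, y), fit_exponential(x, y)
        assert (c1.a, c1.b, c1.c) == (c2.a, c2.b, c2.c)

    def test_too_few_points(self):
        with pytest.raises(DataError):
            fit_exponential([0, 1, 2], [0, 1, 2])


class TestCollapseObjective:
    def test_exact_collapse_on_the_ray(self):
        data = _model_dataset()
        obj, curve = collapse_objective(1.0, REFERENCE_MODEL.r, data)
        assert obj <= 1e-9
        assert curve.b == pytest.approx(REFERENCE_MODEL.b, rel=1e-6)

    def test_minimum_lies_on_the_ray(self):
        data = _model_dataset()
        on_ray = collapse_objective(1.0, 0.36, data)[0]
        off = [collapse_objective(1.0, ratio, data)[0] for ratio in (0.1, 0.25, 0.5, 0.8)]
        assert all(o > on_ray + 1e-8 for o in off)

    def test_ray_invariance_exact(self, noiseless):
        data, _ = noiseless
        rng = np.random.default_rng(0)
        noisy = data.delta_lambda_p * (1 + rng.normal(0, 0.05, data.delta_lambda_p.size))
        noisy_data = CollapseDataset(
            data.sample_ids, data.mu_s_prime, data.mu_a, data.delta_E, np.abs(noisy)
        )
        for c in (0.1, 3.0, 42.0):
            o1, _ = collapse_objective(1.7, 0.9, noisy_data)
            o2, _ = collapse_objective(c * 1.7, c * 0.9, noisy_data)
            assert o2 == pytest.approx(o1, abs=1e-10)


class TestNelderMead:
    def test_recovers_truth_ratio(self, noiseless, nm_scale_optima):
        _, truth = noiseless
        for opt in nm_scale_optima:
            assert opt.objective < 1e-6
            assert opt.ratio == pytest.approx(truth.truth_model.r, abs=1e-3)

    def test_scale_pattern_same_r2_different_magnitudes(self, nm_scale_optima):
        r2 = [o.r_squared for o in nm_scale_optima]
        assert max(r2) - min(r2) < 1e-6
        ratios = [o.ratio for o in nm_scale_optima]
        assert max(ratios) - min(ratios) < 1e-2
        k1s = sorted(o.k1 for o in nm_scale_optima)
        assert k1s[-1] / k1s[0] > 10  # magnitudes follow the initial scales

    def test_restart_from_minimizer_does_not_worsen(self, noiseless, nm_scale_optima):
        data, _ = noiseless
        best = nm_scale_optima[0]
        again = optimize_nelder_mead(data, best.k1, best.k2)
        assert again.objective <= best.objective + 1e-12


class TestMetropolisHastings:
    def test_seeded_determinism(self, noiseless):
        data, _ = noiseless
        a = optimize_metropolis_hastings(data, 1.0, 1.0, n_iter=300, seed=5)
        b = optimize_metropolis_hastings(data, 1.0, 1.0, n_iter=300, seed=5)
        assert (a.k1, a.k2, a.objective) == (b.k1, b.k2, b.objective)
        assert a.history == b.history

    def test_literal_rule_never_accepts_worsening(self, noiseless):
        data, _ = noiseless
        rng = np.random.default_rng(1)
        noisy = CollapseDataset(
            data.sample_ids,
            data.mu_s_prime,
            data.mu_a,
            data.delta_E,
            np.abs(data.delta_lambda_p * (1 + rng.normal(0, 0.05, len(data)))),
        )
        res = optimize_metropolis_hastings(noisy, 10.0, 10.0, n_iter=800, seed=6)
        assert len(res.history) > 1, "chain should accept some improving moves"
        assert np.all(np.diff(res.history) <= 0)

    def test_long_run_recovers_ratio(self, noiseless, mh_optimum):
        _, truth = noiseless
        assert mh_optimum.ratio == pytest.approx(truth.truth_model.r, abs=0.02)

    def test_seed_required(self, noiseless):
        data, _ = noiseless
        with pytest.raises(Exception):
            optimize_metropolis_hastings(data, 1.0, 1.0, n_iter=10, seed=None)

    def test_standard_rule_available(self, noiseless):
        data, _ = noiseless
        res = optimize_metropolis_hastings(
            data, 1.0, 1.0, n_iter=200, seed=7, literal_rule=False, temperature=0.05
        )
        assert res.optimizer == "metropolis-hastings-standard"
        assert 0 <= res.objective <= 1


class TestKLinearity:
    def test_published_nelder_mead_optima(self):
        assert fit_k_linearity(REFERENCE_NM_OPTIMA) == pytest.approx(0.36009, abs=5e-5)

    def test_published_metropolis_optima(self):
        assert fit_k_linearity(REFERENCE_MH_OPTIMA) == pytest.approx(0.35982, abs=5e-5)

    def test_single_pair_is_the_ratio(self):
        assert fit_k_linearity([(1.0, 0.36)]) == pytest.approx(0.36, rel=1e-12)


class TestNormalizeAndRefit:
    def test_max_normalized_ordinate_is_one(self, noiseless):
        data, _ = noiseless
        y = data.delta_lambda_p * (1.0 + 0.36 * data.mu_a) / data.mu_s_prime
        assert np.max(y / np.max(y)) == 1.0

    def test_rate_invariant_to_normalization(self, noiseless):
        data, _ = noiseless
        y = data.delta_lambda_p * (1.0 + 0.36 * data.mu_a) / data.mu_s_prime
        raw_curve = fit_exponential(data.delta_E, y)
        _, b_norm = normalize_and_refit(data, 1.0, 0.36)
        assert b_norm == pytest.approx(raw_curve.b, abs=1e-9)

    def test_amplitude_at_extended_energy_span(self):
        # span to dE = 63.4 mJ: normalized amplitude 1/(1-exp(-0.034*63.4)) = 1.131
        data = _model_dataset(dE_max=63.4, n=25)
        curve, b = normalize_and_refit(data, 1.0, REFERENCE_MODEL.r)
        expected = 1.0 / (1.0 - np.exp(-0.034 * 63.4))
        assert curve.a == pytest.approx(expected, abs=2e-3)
        assert curve.c == pytest.approx(expected, abs=2e-3)
        assert round(curve.a, 2) == 1.13
        assert b == pytest.approx(0.034, rel=1e-4)


class TestGeneralK:
    def test_exact_recovery_zero_dispersion(self, noiseless):
        data, truth = noiseless
        k, kpp, n_exc = compute_general_k(data, truth.truth_model.r, truth.truth_model.b)
        assert k == pytest.approx(truth.truth_model.k, abs=1e-6)
        assert np.std(kpp) < 1e-9 * k
        assert n_exc >= 10  # the ten (0, 0) threshold anchors are excluded, not errors

    def test_noisy_mean_within_two_percent(self):
        data = _model_dataset(n=20)  # 200 points
        rng = np.random.default_rng(11)
        mask = data.delta_lambda_p > EPS_DELTA_LAMBDA
        noisy = CollapseDataset(
            data.sample_ids[mask],
            data.mu_s_prime[mask],
            data.mu_a[mask],
            data.delta_E[mask],
            data.delta_lambda_p[mask] * (1 + rng.normal(0, 0.05, int(mask.sum()))),
        )
        k, _, _ = compute_general_k(noisy, REFERENCE_MODEL.r, REFERENCE_MODEL.b)
        assert k == pytest.approx(REFERENCE_MODEL.k, rel=0.02)

    def test_no_eligible_points_is_an_error(self):
        data = _model_dataset()
        tiny = CollapseDataset(
            data.sample_ids, data.mu_s_prime, data.mu_a, data.delta_E,
            np.zeros_like(data.delta_lambda_p),
        )
        with pytest.raises(DataError):
            compute_general_k(tiny, 0.36, 0.034)


class TestReconstruction:
    def test_noiseless_reconstruction_is_perfect(self, noiseless):
        data, truth = noiseless
        score = reconstruct_and_score(data, truth.truth_model)
        assert score.average == pytest.approx(1.0, abs=1e-12)
        assert all(v == pytest.approx(1.0, abs=1e-12) for v in score.per_sample.values())

    def test_saturation_hurts_low_absorption_samples_most(self):
        """Gain saturation far above threshold pulls down reconstruction R^2,
        most strongly for samples with small mu_a/mu_s' (lowest thresholds)."""
        data, truth = study_collapse_dataset(
            seed=9,
            config=GeneratorConfig(seed=9, sigma_lambda=0.0, saturation=(0.35, 25.0)),
        )
        score = reconstruct_and_score(data, truth.truth_model)
        assert score.average < 1.0 - 1e-4
        ratios, r2s = [], []
        for sid, r2 in score.per_sample.items():
            t = truth.samples[sid]
            ratios.append(t.op.mu_a / t.op.mu_s_prime)
            r2s.append(r2)
        rank_corr = np.corrcoef(
            np.argsort(np.argsort(ratios)), np.argsort(np.argsort(r2s))
        )[0, 1]
        assert rank_corr > 0.5


class TestCalibratePipeline:
    def test_noiseless_identifiability(self, noiseless):
        data, truth = noiseless
        res = calibrate(data)
        assert res.r == pytest.approx(truth.truth_model.r, rel=1e-3)
        assert res.b == pytest.approx(truth.truth_model.b, rel=1e-3)
        assert res.k == pytest.approx(truth.truth_model.k, rel=1e-3)
        assert res.reconstruction.average == pytest.approx(1.0, abs=1e-9)

    def test_mild_noise_reconstruction(self):
        data, _ = study_collapse_dataset(seed=13, multiplicative=0.01)
        res = calibrate(data)
        assert res.reconstruction.average >= 0.93
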