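import numpy as np
import pytest

from ztlkinetics import (
    DegradationParams,
    IdentifiabilityError,
    LightSchedule,
    NoiseSpec,
    PhotocycleDegradationModel,
    ProteinTimecourse,
    bootstrap_ci,
    fit_degradation,
    gen_protein_timecourse,
    profile_objective,
    recovery_experiment,
)


def noiseless_ld(params, times=None, c0=1.0):
    times = np.arange(12.0, 24.01, 1.0) if times is None else times
    return gen_protein_timecourse(
        params, LightSchedule.ld(), c0, times, NoiseSpec(protein_cv=0.0, n_replicates=1)
    )


def noiseless_ll(params, times=None):
    times = np.arange(0.0, 12.01, 1.0) if times is None else times
    return gen_protein_timecourse(
        params, None, 1.0, times, NoiseSpec(protein_cv=0.0, n_replicates=1),
        condition="LL",
    )


class TestFitDegradation:
    def test_noiseless_ll_recovers_light_rate(self):
        truth = DegradationParams(0.14, 0.8, 0.7)
        tc = noiseless_ll(truth)
        res = fit_degradation(tc, DegradationParams(0.3, 0.8, 0.7), ("k1",))
        assert res.estimates["k1"] == pytest.approx(0.14, rel=1e-6)
        assert res.converged

    def test_noiseless_ld_recovers_reversion_rate(self):
        truth = DegradationParams(0.14, 0.8, 0.15)
        tc = noiseless_ld(truth)
        res = fit_degradation(tc, truth.with_updates(k3=0.5), ("k3",))
        assert res.estimates["k3"] == pytest.approx(0.15, rel=1e-6)

    def test_joint_dark_and_reversion_rates_from_clean_data(self):
        truth = DegradationParams(0.14, 0.8, 0.7)
        tc = noiseless_ld(truth, times=np.arange(12.0, 24.01, 0.5))
        res = fit_degradation(tc, DegradationParams(0.14, 0.5, 0.3), ("k2", "k3"))
        assert res.estimates["k2"] == pytest.approx(0.8, rel=1e-4)
        assert res.estimates["k3"] == pytest.approx(0.7, rel=1e-3)

    def test_ll_refuses_dark_parameters(self):
        tc = noiseless_ll(DegradationParams(0.14, 0.8, 0.7))
        for free in (("k3",), ("k2",), ("k1", "k3")):
            with pytest.raises(IdentifiabilityError):
                fit_degradation(tc, DegradationParams(0.14, 0.8, 0.7), free)

    def test_degenerate_equal_rates_flagged_nonidentifiable(self):
        truth = DegradationParams(0.8, 0.8, 0.09)
        tc = noiseless_ld(truth)
        with pytest.warns(RuntimeWarning, match="non-identifiable"):
            res = fit_degradation(tc, truth, ("k3",))
        assert not res.converged
        assert "flat" in res.message

    def test_pooling_invariance_under_replicate_duplication(self):
        truth = DegradationParams(0.14, 0.8, 0.15)
        tc = gen_protein_timecourse(
            truth, LightSchedule.ld(), 1.0, np.arange(12.0, 24.01, 1.0),
            NoiseSpec(seed=4),
        )
        doubled = ProteinTimecourse(
            tc.species, tc.condition,
            np.concatenate([tc.times, tc.times]),
            np.concatenate([tc.levels, tc.levels]),
            np.concatenate([tc.replicates, tc.replicates + 10]),
        )
        a = fit_degradation(tc, truth, ("k3",), seed=0)
        b = fit_degradation(doubled, truth, ("k3",), seed=0)
        assert b.estimates["k3"] == pytest.approx(a.estimates["k3"], rel=1e-6)

    def test_objective_never_worse_than_initial_guess(self):
        truth = DegradationParams(0.14, 0.8, 0.15)
        tc = gen_protein_timecourse(
            truth, LightSchedule.ld(), 1.0, np.arange(12.0, 24.01, 1.0),
            NoiseSpec(seed=8),
        )
        start = truth.with_updates(k3=2.0)
        res = fit_degradation(tc, start, ("k3",), seed=8)
        prof = profile_objective(tc, start, "k3", [2.0])
        assert res.objective <= prof["objective"].iloc[0] + 1e-12

    def test_estimates_respect_bounds(self):
        truth = DegradationParams(0.14, 0.8, 0.15)
        tc = gen_protein_timecourse(
            truth, LightSchedule.ld(), 1.0, np.arange(12.0, 24.01, 1.0),
            NoiseSpec(seed=2),
        )
        res = fit_degradation(tc, truth, ("k1", "k2", "k3"), seed=2)
        for v in res.estimates.values():
            assert 0.0 <= v <= 10.0


class TestEstimatorProtocol:
    def test_get_set_params_and_predict(self):
        est = PhotocycleDegradationModel(free=("k3",), condition="LD")
        assert est.get_params()["k3"] == 0.7
        t = np.arange(0.0, 12.01, 1.0)
        truth = DegradationParams(0.14, 0.8, 0.15)
        from ztlkinetics import prr5_analytic

        y = prr5_analytic(t, 1.0, truth)
        est.set_params(k1=0.14, k2=0.8, k3=0.4).fit(t, y)
        assert est.estimates_["k3"] == pytest.approx(0.15, rel=1e-6)
        np.testing.assert_allclose(est.predict(t), y, rtol=1e-5)


class TestBootstrap:
    @pytest.fixture
    def fitted(self, g80r_params, dark_times):
        tc = gen_protein_timecourse(
            g80r_params, LightSchedule.ld(), 1.0, dark_times, NoiseSpec(seed=7)
        )
        return tc, fit_degradation(tc, g80r_params, ("k3",), seed=7)

    def test_same_seed_identical_cis(self, fitted):
        tc, res = fitted
        a = bootstrap_ci(tc, res, n_boot=120, seed=5)
        b = bootstrap_ci(tc, res, n_boot=120, seed=5)
        assert a.ci == b.ci

    def test_ci_brackets_estimate(self, fitted):
        tc, res = fitted
        out = bootstrap_ci(tc, res, n_boot=120, seed=5)
        lo, hi = out.ci["k3"]
        assert lo <= res.estimates["k3"] <= hi

    def test_zero_noise_ci_collapses(self, g80r_params, dark_times):
        tc = gen_protein_timecourse(
            g80r_params, LightSchedule.ld(), 1.0, dark_times,
            NoiseSpec(protein_cv=0.0),
        )
        res = fit_degradation(tc, g80r_params, ("k3",))
        out = bootstrap_ci(tc, res, n_boot=100, seed=1)
        lo, hi = out.ci["k3"]
        assert hi - lo < 1e-6

    def test_single_replicate_falls_back_to_residual(self, g80r_params, dark_times):
        tc = gen_protein_timecourse(
            g80r_params, LightSchedule.ld(), 1.0, dark_times,
            NoiseSpec(seed=2, n_replicates=1),
        )
        res = fit_degradation(tc, g80r_params, ("k3",))
        with pytest.warns(RuntimeWarning, match="residual"):
            out = bootstrap_ci(tc, res, n_boot=100, seed=3, method="case")
        assert np.isfinite(out.ci["k3"]).all()

    def test_residual_bootstrap_coverage_near_nominal(self, g80r_params, dark_times):
        # 30 outer repetitions at 95% CIs; binomial slack for n=30 at ~90-95%
        covered = 0
        seeds = np.random.SeedSequence(123).generate_state(30) % 2**31
        for s in seeds:
            tc = gen_protein_timecourse(
                g80r_params, LightSchedule.ld(), 1.0, dark_times,
                NoiseSpec(seed=int(s)),
            )
            res = fit_degradation(tc, g80r_params, ("k3",), n_starts=1)
            out = bootstrap_ci(tc, res, n_boot=200, seed=int(s), method="residual")
            lo, hi = out.ci["k3"]
            covered += lo <= 0.15 <= hi
        assert covered / 30 >= 0.8


class TestProfileObjective:
    def test_flat_under_continuous_light(self):
        tc = noiseless_ll(DegradationParams(0.14, 0.8, 0.7))
        prof = profile_objective(
            tc, DegradationParams(0.14, 0.8, 0.7), "k3", [0.05, 0.5, 5.0], free=("k1",)
        )
        assert prof["objective"].max() - prof["objective"].min() < 1e-12

    def test_unimodal_around_truth_with_rate_contrast(self, g80r_params):
        tc = gen_protein_timecourse(
            g80r_params, LightSchedule.ld(), 1.0, np.arange(12.0, 24.01, 1.0),
            NoiseSpec(seed=6),
        )
        grid = np.linspace(0.05, 0.5, 10)
        prof = profile_objective(tc, g80r_params, "k3", grid)
        i = int(prof["objective"].idxmin())
        assert 0.1 <= prof["k3"].iloc[i] <= 0.25
        assert np.all(np.diff(prof["objective"].to_numpy()[: i + 1]) <= 1e-12)
        assert np.all(np.diff(prof["objective"].to_numpy()[i:]) >= -1e-12)

    def test_single_point_grid(self, g80r_params, dark_times):
        tc = gen_protein_timecourse(
            g80r_params, LightSchedule.ld(), 1.0, dark_times, NoiseSpec(seed=1)
        )
        prof = profile_objective(tc, g80r_params, "k3", 0.15)
        assert len(prof) == 1


class TestRecoveryExperiment:
    def test_zero_noise_gives_zero_bias_and_rmse(self, g80r_params):
        out = recovery_experiment(
            g80r_params, noise=NoiseSpec(protein_cv=0.0), n_seeds=3, seed=0
        )
        row = out.summary.loc["k3"]
        assert row["bias"] == pytest.approx(0.0, abs=1e-6)
        assert row["rel_rmse"] == pytest.approx(0.0, abs=1e-6)
        assert out.n_failed == 0

    def test_median_relative_error_below_ten_percent(self, wt_params, g80r_params):
        for truth in (wt_params, g80r_params):
            out = recovery_experiment(truth, n_seeds=25, seed=3)
            vals = out.estimates["k3"].to_numpy()
            med_err = np.median(np.abs(vals - truth.k3) / truth.k3)
            assert med_err < 0.10
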