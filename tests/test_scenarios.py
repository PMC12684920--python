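"""Scenario application, MSE metric, grid survey and loess smoothing."""

import numpy as np
import pandas as pd
import pytest

import rootga as rg
from rootga.profiles import EmissionProfile
from rootga.scenarios import (
    SurveySpec,
    builtin_scenarios,
    grid_survey,
    half_decade_grid,
    loess_smooth,
    mse,
    reverify_top,
    run_scenario,
)

from conftest import rel_l2


class TestRunScenario:
    def test_identity_scenario_is_bit_identical_to_baseline(self, params, continuum_baseline):
        prof, _ = run_scenario(params, rg.ScenarioConfig())
        assert np.array_equal(prof.cyt, continuum_baseline.cyt)

    def test_unknown_solver_rejected(self, params):
        with pytest.raises(ValueError):
            run_scenario(params, solver="magic")

    def test_ga3ox_lof_differs_from_wildtype(self, params, continuum_baseline):
        prof, _ = run_scenario(params, builtin_scenarios()["ga3ox_lof"])
        assert not np.allclose(prof.ga4(), continuum_baseline.ga4())
        # no GA3ox anywhere: no GA4 is ever synthesized
        assert np.max(prof.ga4()) < 1e-9

    def test_superposition_in_linear_regime_only(self, params, continuum_baseline):
        # far below saturation the two GA12 sources superpose; at baseline
        # the Michaelis–Menten chain breaks additivity
        eps = 1e-3
        both, _ = run_scenario(params, rg.ScenarioConfig(s_qcz_factor=eps, d_phloem_factor=eps))
        only_s, _ = run_scenario(params, rg.ScenarioConfig(s_qcz_factor=eps, d_phloem_factor=0.0))
        only_d, _ = run_scenario(params, rg.ScenarioConfig(s_qcz_factor=0.0, d_phloem_factor=eps))
        lin_err = rel_l2(both.x, only_s.ga4() + only_d.ga4(), both.ga4())
        assert lin_err < 0.01

        base_s, _ = run_scenario(params, rg.ScenarioConfig(d_phloem_factor=0.0))
        base_d, _ = run_scenario(params, rg.ScenarioConfig(s_qcz_factor=0.0))
        nonlin_err = rel_l2(continuum_baseline.x, base_s.ga4() + base_d.ga4(),
                            continuum_baseline.ga4())
        assert nonlin_err > lin_err


class TestMse:
    def test_exact_samples_give_zero(self):
        pred = EmissionProfile(x=np.linspace(0, 500, 100),
                               ratio=np.linspace(0.6, 1.0, 100))
        obs = EmissionProfile(x=pred.x[::7], ratio=pred.ratio[::7])
        assert mse(pred, obs) == 0.0

    def test_constant_offset_gives_square(self):
        pred = EmissionProfile(x=np.linspace(0, 500, 100),
                               ratio=np.full(100, 0.8))
        obs = EmissionProfile(x=np.array([10.0, 99.0, 444.0]),
                              ratio=np.full(3, 0.8 + 0.02))
        assert mse(pred, obs) == pytest.approx(0.02**2, rel=1e-12)

    def test_three_point_worked_example(self):
        pred = EmissionProfile(x=np.array([0.0, 1.0, 2.0]),
                               ratio=np.array([1.0, 1.2, 1.4]))
        obs = EmissionProfile(x=np.array([0.0, 1.0, 2.0]),
                              ratio=np.array([1.1, 1.2, 1.3]))
        assert mse(pred, obs) == pytest.approx(0.006667, abs=1e-6)

    def test_uncovered_nucleus_is_an_error(self):
        pred = EmissionProfile(x=np.linspace(0, 100, 10), ratio=np.full(10, 1.0))
        obs = EmissionProfile(x=np.array([200.0]), ratio=np.array([1.0]))
        with pytest.raises(ValueError, match="range"):
            mse(pred, obs)

    def test_empty_observed_is_an_error(self):
        pred = EmissionProfile(x=np.linspace(0, 100, 10), ratio=np.full(10, 1.0))
        obs = EmissionProfile(x=np.array([]), ratio=np.array([]))
        with pytest.raises(ValueError):
            mse(pred, obs)


class TestGridSurvey:
    def test_single_point_grid(self, params, continuum_baseline):
        sup, cat = params.supply, params.catabolism
        spec = SurveySpec((sup.s_qcz,), (sup.d_phloem,), (cat.delta12,),
                          (cat.delta9,), (cat.delta4,))
        target = rg.generate_emission_dataset(
            params, noise=rg.NoiseModel(sigma_ratio=0.0), n_nuclei=50, seed=0,
            profile=continuum_baseline,
        )
        df = grid_survey(spec, target, params)
        assert len(df) == 1
        assert df.loc[0, "mse"] == pytest.approx(0.0, abs=1e-10)

    def test_noise_free_on_grid_truth_ranks_first(self, params, continuum_baseline):
        sup, cat = params.supply, params.catabolism
        spec = SurveySpec(
            s_qcz=(0.5 * sup.s_qcz, sup.s_qcz, 2 * sup.s_qcz),
            d_phloem=(0.5 * sup.d_phloem, sup.d_phloem, 2 * sup.d_phloem),
            delta12=(cat.delta12,), delta9=(cat.delta9,),
            delta4=(0.5 * cat.delta4, cat.delta4, 2 * cat.delta4),
        )
        target = rg.generate_emission_dataset(
            params, noise=rg.NoiseModel(sigma_ratio=0.0), n_nuclei=200, seed=1,
            profile=continuum_baseline,
        )
        df = grid_survey(spec, target, params)
        top = df.iloc[0]
        assert (top["s_qcz"], top["d_phloem"], top["delta4"]) == (
            sup.s_qcz, sup.d_phloem, cat.delta4)
        assert top["mse"] == pytest.approx(0.0, abs=1e-9)

    def test_deterministic_ordering_on_rerun(self, params, continuum_baseline):
        sup, cat = params.supply, params.catabolism
        spec = SurveySpec((sup.s_qcz,), (0.5 * sup.d_phloem, sup.d_phloem),
                          (cat.delta12,), (cat.delta9,), (cat.delta4, 2 * cat.delta4))
        target = rg.generate_emission_dataset(
            params, noise=rg.NoiseModel(sigma_ratio=0.02), n_nuclei=100, seed=5,
            profile=continuum_baseline,
        )
        df1 = grid_survey(spec, target, params)
        df2 = grid_survey(spec, target, params)
        pd.testing.assert_frame_equal(df1, df2)

    def test_solver_failure_recorded_and_excluded(self, params, continuum_baseline,
                                                  monkeypatch):
        import rootga.scenarios as sc_mod

        real = sc_mod.solve_steady
        bad_point = 123.456

        def flaky(p, scenario=None, **kw):
            if p.supply.d_phloem == bad_point:
                raise RuntimeError("synthetic failure")
            return real(p, scenario, **kw)

        monkeypatch.setattr(sc_mod, "solve_steady", flaky)
        sup, cat = params.supply, params.catabolism
        spec = SurveySpec((sup.s_qcz,), (sup.d_phloem, bad_point),
                          (cat.delta12,), (cat.delta9,), (cat.delta4,))
        target = rg.generate_emission_dataset(
            params, noise=rg.NoiseModel(sigma_ratio=0.0), n_nuclei=50, seed=2,
            profile=continuum_baseline,
        )
        df = grid_survey(spec, target, params)
        failed = df[~df["ok"]]
        assert len(failed) == 1
        assert "synthetic failure" in failed.iloc[0]["error"]
        assert failed.iloc[0]["rank"] == -1

    def test_half_decade_grid_shape(self):
        g = half_decade_grid(1.0)
        assert len(g) == 5
        assert g[2] == pytest.approx(1.0)
        assert g[4] / g[0] == pytest.approx(100.0)

    def test_reverify_top_scores_with_discrete_solver(self, params, continuum_baseline,
                                                      discrete_baseline):
        sup, cat = params.supply, params.catabolism
        spec = SurveySpec((sup.s_qcz,), (sup.d_phloem,), (cat.delta12,),
                          (cat.delta9,), (cat.delta4,))
        target = rg.generate_emission_dataset(
            params, noise=rg.NoiseModel(sigma_ratio=0.0), n_nuclei=100, seed=3,
            profile=continuum_baseline,
        )
        ranked = grid_survey(spec, target, params)
        out = reverify_top(ranked, target, params, k=1,
                           discrete_solver=lambda p, s: discrete_baseline)
        assert len(out) == 1
        # discrete and continuum scores agree to the cross-model error scale
        assert out.loc[0, "mse_discrete"] < 0.01


class TestLoess:
    def test_reproduces_exact_line(self):
        rng = np.random.default_rng(0)
        x = np.sort(rng.uniform(0, 10, 60))
        y = 2.0 * x - 1.0
        fit = loess_smooth(x, y, span=0.5)
        assert fit["fit"].to_numpy() == pytest.approx(y[np.argsort(x)], abs=1e-8)

    def test_constant_data_ci_shrinks_with_n(self):
        rng = np.random.default_rng(1)
        widths = []
        for n in (30, 300):
            x = np.sort(rng.uniform(0, 10, n))
            y = np.full(n, 3.0) + rng.normal(0, 0.1, n)
            fit = loess_smooth(x, y)
            widths.append(np.mean(fit["hi"] - fit["lo"]))
            assert np.all(fit["hi"] > fit["lo"])
        assert widths[1] < widths[0]

    def test_smooths_noisy_sine_below_noise_floor(self):
        rng = np.random.default_rng(7)
        x = np.sort(rng.uniform(0, 2 * np.pi, 200))
        truth = np.sin(x)
        y = truth + rng.normal(0, 0.3, x.size)
        fit = loess_smooth(x, y, span=0.3)
        rmse_fit = np.sqrt(np.mean((fit["fit"].to_numpy() - truth) ** 2))
        rmse_raw = np.sqrt(np.mean((y - truth) ** 2))
        assert rmse_fit < rmse_raw

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            loess_smooth(np.arange(5.0), np.arange(5.0))
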