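"""Correlation grouping, stage-1 screening, stage-2 shrinkage fitting."""

import warnings

import numpy as np
import pandas as pd
import pytest

from lekdemog.config import SelectionConfig
from lekdemog.exposure import StageDesign, build_stage_model
from lekdemog.mcmc import MCMCConfig, adaptive_metropolis
from lekdemog.selection import (
    ScaleVariant,
    exposure_fitter,
    fit_stage2,
    group_covariates,
    screen_stage1,
)
from lekdemog.synthetic import gen_encounter_histories


def correlated_frame(seed=0, n=2000):
    rng = np.random.default_rng(seed)
    a = rng.standard_normal(n)
    b = 0.9 * a + np.sqrt(1 - 0.9**2) * rng.standard_normal(n)
    # c targets corr(b, c) = 0.75 and corr(a, c) = 0.5: linked to b above
    # the grouping threshold but to a below it
    c = -0.921 * a + 1.579 * b + 0.526 * rng.standard_normal(n)
    d = rng.standard_normal(n)
    return pd.DataFrame({"a": a, "b": b, "c": c, "d": d})


class TestGroupCovariates:
    def test_independent_columns_are_singletons(self):
        rng = np.random.default_rng(1)
        frame = pd.DataFrame(rng.standard_normal((500, 3)),
                             columns=list("xyz"))
        groups = group_covariates(frame, threshold=0.65)
        assert groups == [["x"], ["y"], ["z"]]

    def test_transitive_chain_merges(self):
        frame = correlated_frame()
        corr = frame.corr().abs()
        assert corr.loc["a", "b"] >= 0.65
        assert corr.loc["b", "c"] >= 0.65
        assert corr.loc["a", "c"] < 0.65
        groups = group_covariates(frame, threshold=0.65)
        assert groups == [["a", "b", "c"], ["d"]]

    def test_extreme_threshold_gives_singletons(self):
        frame = correlated_frame()
        groups = group_covariates(frame, threshold=0.999)
        assert all(len(g) == 1 for g in groups)

    def test_partition_is_disjoint_and_exhaustive(self):
        frame = correlated_frame(seed=2)
        groups = group_covariates(frame, threshold=0.5)
        flat = [c for g in groups for c in g]
        assert sorted(flat) == sorted(frame.columns)
        assert len(flat) == len(set(flat))

    def test_invariant_to_column_order(self):
        frame = correlated_frame(seed=3)
        g1 = group_covariates(frame, threshold=0.65)
        g2 = group_covariates(frame[["d", "c", "b", "a"]], threshold=0.65)
        assert {frozenset(g) for g in g1} == {frozenset(g) for g in g2}

    def test_constant_column_rejected(self):
        frame = pd.DataFrame({"x": np.arange(10.0), "k": np.ones(10)})
        with pytest.raises(ValueError, match="constant"):
            group_covariates(frame)


def scale_signal_histories(seed, n_units=250, effect=0.35):
    """Nest histories where one covariate acts at its 370-m scale only;
    the 75-m and 1451-m variants are correlated stand-ins."""
    rng = np.random.default_rng(seed)
    design = StageDesign(stage="nest", mains=("x_370",))
    coeffs = {"intercept": 3.2, "x_370": effect}
    from lekdemog.synthetic import ExposureTruth

    truth = ExposureTruth(stage="nest", coefficients=coeffs, n_units=n_units,
                          horizon=38)
    frame = gen_encounter_histories(truth, stage="nest", design=design,
                                    seed=seed)
    z = frame["x_370"].to_numpy()
    w = 0.6
    frame["x_75"] = w * z + np.sqrt(1 - w**2) * rng.standard_normal(len(frame))
    frame["x_1451"] = w * z + np.sqrt(1 - w**2) * rng.standard_normal(len(frame))
    return frame


SCREEN_MCMC = MCMCConfig(iterations=4000, burn_in=2000, thin=2, chains=2,
                         seed=0)


class TestScreenStage1:
    def test_single_candidate_single_scale_passes_through(self):
        frame = scale_signal_histories(seed=5)
        fitter = exposure_fitter(frame, "nest", SCREEN_MCMC)
        variants = {"x": [ScaleVariant(370.0, "x_370")]}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = screen_stage1([["x"]], variants, fitter)
        assert res.chosen["x"].column == "x_370"
        assert res.retained == ["x"]
        assert res.pd_values["x"] > 0.9

    def test_scale_specific_signal_selected_at_true_scale(self):
        frame = scale_signal_histories(seed=6)
        fitter = exposure_fitter(frame, "nest", SCREEN_MCMC)
        variants = {"x": [ScaleVariant(75.0, "x_75"),
                          ScaleVariant(370.0, "x_370"),
                          ScaleVariant(1451.0, "x_1451")]}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = screen_stage1([["x"]], variants, fitter)
        assert res.chosen["x"].scale == 370.0
        assert "x" in res.retained


class TestFitStage2:
    def test_lambda_within_support_and_off_bounds(self, nest_histories):
        fitter_cfg = MCMCConfig(iterations=6000, burn_in=3000, thin=2,
                                chains=4, seed=7)
        design = StageDesign(
            stage="nest",
            mains=("sagebrush", "annual_forb_grass", "vpd"))
        from lekdemog.selection import ScreenResult

        screen = ScreenResult(chosen={}, pd_values={}, retained=[],
                              confounded=[], groups=[])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit, report = fit_stage2(
                ["sagebrush", "annual_forb_grass", "vpd"], nest_histories,
                "nest", screen, mcmc_config=fitter_cfg, extra_design=design)
        lam = report.lambda_summary
        assert 0.01 < lam["q2.5"] < lam["q97.5"] < 10.0

    def test_shrinkage_reduces_null_coefficient_error(self):
        # sparse truth: with shrinkage, null coefficients have smaller RMSE
        # than under a flat prior (paired on the same dataset)
        rng = np.random.default_rng(8)
        from lekdemog.exposure import exposure_loglik
        from lekdemog.synthetic import ExposureTruth

        names = tuple(f"c{i}" for i in range(8))
        coeffs = {"intercept": 3.2, "c0": 0.4, "c1": -0.35}
        coeffs.update({n: 0.0 for n in names[2:]})
        truth = ExposureTruth(stage="nest", coefficients=coeffs, n_units=150)
        design = StageDesign(stage="nest", mains=names)
        frame = gen_encounter_histories(truth, stage="nest", design=design,
                                        seed=9)
        model = build_stage_model("nest", frame, design=design)

        def flat_logpost(params):
            return exposure_loglik(params, model.X, model.t, model.y) \
                - 0.5 * np.sum((params / 10.0) ** 2)

        cfg = MCMCConfig(iterations=6000, burn_in=3000, thin=2, chains=2,
                         seed=10)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            from lekdemog.exposure import fit_stage_model

            shrunk = fit_stage_model(model, cfg)
            flat_draws, _ = adaptive_metropolis(
                flat_logpost, np.r_[3.2, np.zeros(8)], cfg)
        nulls = slice(3, 9)  # columns c2..c7 in the coefficient vector
        shrunk_means = shrunk.beta_draws.mean(axis=(0, 1))[nulls]
        flat_means = flat_draws.mean(axis=(0, 1))[nulls]
        assert np.sqrt(np.mean(shrunk_means**2)) < \
            np.sqrt(np.mean(flat_means**2))

    def test_monotone_shrinkage_with_lambda(self, nest_histories):
        # at pinned Λ values on a fixed dataset, posterior magnitudes of
        # non-intercept coefficients shrink monotonically toward zero
        model = build_stage_model("nest", nest_histories)
        from lekdemog.exposure import exposure_loglik

        mags = []
        for lam in (0.1, 3.0, 30.0):
            def logpost(params, lam=lam):
                beta = params
                return (exposure_loglik(beta, model.X, model.t, model.y)
                        - 0.5 * (beta[0] / 10.0) ** 2
                        - lam * np.sum(np.abs(beta[1:])))

            cfg = MCMCConfig(iterations=4000, burn_in=2000, thin=2,
                             chains=2, seed=11)
            draws, _ = adaptive_metropolis(
                logpost, np.r_[3.4, np.zeros(model.n_coefficients - 1)], cfg)
            mags.append(float(np.mean(np.abs(
                draws.mean(axis=(0, 1))[1:]))))
        assert mags[0] > mags[1] > mags[2]

    def test_empty_retained_set_rejected(self, nest_histories):
        from lekdemog.selection import ScreenResult

        screen = ScreenResult(chosen={}, pd_values={}, retained=[],
                              confounded=[], groups=[])
        with pytest.raises(ValueError, match="empty"):
            fit_stage2([], nest_histories, "nest", screen)

    def test_report_serializes_with_bracket_notation(self, nest_histories):
        from lekdemog.selection import ScreenResult, SelectionReport

        screen = ScreenResult(
            chosen={"sagebrush": ScaleVariant(75.0, "sagebrush")},
            pd_values={"sagebrush": 0.9}, retained=["sagebrush"],
            confounded=[], groups=[["sagebrush"]])
        report = SelectionReport(
            screen=screen, final_covariates=["sagebrush"],
            lambda_summary={"mean": 7.0, "sd": 1.0, "q2.5": 4.0,
                            "q50": 7.0, "q97.5": 9.9},
            config=SelectionConfig())
        text = report.to_json()
        assert '"sagebrush"' in text
        brackets = report.bracket_notation(
            [75.0, 167.0, 260.0, 370.0, 439.0, 1451.0])
        assert brackets["sagebrush"] == "sagebrush[1]"
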