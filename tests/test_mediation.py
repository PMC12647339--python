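import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

import famstress as fs
from famstress.mediation import (
    NaturalModelSpec,
    _LogitMediator,
    _LogitOutcome,
    bootstrap_cis,
    expand_and_impute,
    fit_mediator_model,
    fit_natural_model,
    fit_outcome_imputation_model,
    natural_effects,
    pool_over_imputations,
    proportion_mediated,
)


def null_everything_params(n=50_000, seed=0):
    """All structural coefficients zero except intercepts."""
    p = fs.default_params(n_children=n, seed=seed)
    zero_conf = {k: 0.0 for k in fs.CONFOUNDERS}
    return p.replace(
        alpha_x=fs.LogisticEq(intercept=-0.4, conf=zero_conf),
        alpha_m1=fs.LogisticEq(intercept=-1.0, conf=zero_conf),
        alpha_m2=fs.LogisticEq(intercept=-0.8, conf=zero_conf),
        alpha_y=fs.LogisticEq(intercept=-2.2, conf=zero_conf),
    )


def analysis_from(params):
    cohort = fs.generate_cohort(params)
    return fs.derive_analysis_set(cohort, cutoffs=cohort.cutoffs)


def one_confounder_dataset(n=3000, seed=0):
    """Binary-confounder DGP used for the g-formula equivalence check."""
    rng = np.random.default_rng(seed)
    c = (rng.random(n) < 0.4).astype(float)
    x = (rng.random(n) < expit(-0.5 + 0.9 * c)).astype(float)
    m1 = (rng.random(n) < expit(-1.0 + 0.8 * x + 0.5 * c)).astype(float)
    m2 = (rng.random(n) < expit(-0.7 + 0.5 * x + 0.6 * m1 - 0.4 * c)).astype(float)
    y = (rng.random(n) < expit(-1.5 + 0.7 * x + 0.5 * m1 + 0.6 * m2 + 0.5 * c)).astype(float)
    return pd.DataFrame(
        {"X": x, "M1": m1, "M2": m2, "Y": y, "c": c, "weight": 1.0}
    )


class TestProportionMediated:
    def test_nie_one_gives_zero(self):
        assert proportion_mediated(1.7, 1.0) == 0.0
        assert proportion_mediated(0.4, 1.0) == 0.0

    def test_nde_one_gives_full_mediation(self):
        assert proportion_mediated(1.0, 2.0) == pytest.approx(1.0)
        assert proportion_mediated(1.0, 1.3) == pytest.approx(1.0)

    def test_printed_formula_value(self):
        # direct evaluation at the published rounded estimates
        assert proportion_mediated(2.02, 1.06) == pytest.approx(0.1062, abs=5e-5)

    def test_undefined_when_denominator_zero(self):
        assert proportion_mediated(2.0, 0.5) is None


class TestOutcomeModel:
    def test_null_data_coefficients_near_zero(self):
        a = analysis_from(null_everything_params(seed=101))
        spec = NaturalModelSpec()
        model = fit_outcome_imputation_model(a, spec)
        for name, coef, se in zip(model.columns[1:], model.params[1:], model.bse[1:]):
            assert abs(coef) < 3.5 * se, name

    def test_recovers_structural_x_coefficient(self, analysis_20k, calibrated_params):
        model = fit_outcome_imputation_model(analysis_20k)
        i = model.columns.index("X")
        assert abs(model.params[i] - calibrated_params.alpha_y.x) < 3 * model.bse[i]

    def test_saturated_mode_equals_cell_means(self):
        df = one_confounder_dataset(n=2000, seed=3)
        spec = NaturalModelSpec(confounders=("c",), saturated=True)
        model = fit_outcome_imputation_model(df, spec)
        for (x, m1, m2, c), grp in df.groupby(["X", "M1", "M2", "c"]):
            pred = model.predict(x, m1, m2, np.array([[c]]))
            assert pred[0] == pytest.approx(grp["Y"].mean(), rel=1e-12)

    def test_missing_values_rejected(self, analysis_20k):
        broken = analysis_20k.copy()
        broken.loc[0, "Y"] = np.nan
        with pytest.raises(ValueError, match="missing"):
            fit_outcome_imputation_model(broken)


class TestMediatorModel:
    def test_null_data_coefficients_near_zero(self):
        a = analysis_from(null_everything_params(seed=103))
        model = fit_mediator_model(a)
        for name, coef, se in zip(model.columns[1:], model.params[1:], model.bse[1:]):
            assert abs(coef) < 3.5 * se, name

    def test_recovers_structural_x_coefficient(self, analysis_20k, calibrated_params):
        model = fit_mediator_model(analysis_20k)
        i = model.columns.index("X")
        assert abs(model.params[i] - calibrated_params.alpha_m1.x) < 3 * model.bse[i]

    def test_saturated_mode_equals_cell_means(self):
        df = one_confounder_dataset(n=2000, seed=4)
        spec = NaturalModelSpec(confounders=("c",), saturated=True)
        model = fit_mediator_model(df, spec)
        for (x, c), grp in df.groupby(["X", "c"]):
            pred = model.predict(x, np.array([[c]]))
            assert pred[0] == pytest.approx(grp["M1"].mean(), rel=1e-12)


class TestExpandAndImpute:
    def _tiny(self):
        return pd.DataFrame(
            {
                "X": [0.0, 1.0, 0.0, 1.0],
                "M1": [0.0, 1.0, 1.0, 0.0],
                "M2": [0.0, 0.0, 1.0, 1.0],
                "Y": [0.0, 1.0, 0.0, 1.0],
                "weight": 1.0,
            }
        )

    def test_outcome_ignoring_m1_is_constant_in_x1(self):
        spec = NaturalModelSpec(confounders=())
        outcome = _LogitOutcome(np.array([-1.0, 0.8, 0.0, 0.5]), np.full(4, np.nan), spec)
        mediator = _LogitMediator(np.array([-0.5, 0.7]), np.full(2, np.nan), spec)
        ex = expand_and_impute(self._tiny(), outcome, mediator, spec)
        wide = ex.pivot_table(index=["row_id", "x0"], columns="x1", values="yhat")
        assert np.allclose(wide[0.0], wide[1.0])

    def test_degenerate_mediator_reduces_to_m1_zero(self):
        spec = NaturalModelSpec(confounders=())
        outcome = _LogitOutcome(np.array([-1.0, 0.8, 0.6, 0.5]), np.full(4, np.nan), spec)
        mediator = _LogitMediator(np.array([-800.0, 0.0]), np.full(2, np.nan), spec)
        df = self._tiny()
        ex = expand_and_impute(df, outcome, mediator, spec)
        for _, row in ex.iterrows():
            m2 = df.loc[df.index == row.row_id, "M2"].iloc[0]
            expected = expit(-1.0 + 0.8 * row.x0 + 0.5 * m2)
            assert row.yhat == pytest.approx(expected, rel=1e-9)

    def test_expansion_shape_and_x2_pinned(self, analysis_20k):
        sub = analysis_20k.head(500)
        spec = NaturalModelSpec()
        ex = expand_and_impute(
            sub, fit_outcome_imputation_model(sub, spec), fit_mediator_model(sub, spec), spec
        )
        assert len(ex) == 4 * len(sub)
        merged = ex.merge(sub["X"], left_on="row_id", right_index=True)
        assert (merged["x2"] == merged["X"]).all()

    def test_matches_exhaustive_g_formula(self):
        # dual route: saturated-model expansion vs hand-rolled tabulation
        df = one_confounder_dataset(n=3000, seed=5)
        spec = NaturalModelSpec(confounders=("c",), saturated=True)
        ex = expand_and_impute(
            df, fit_outcome_imputation_model(df, spec), fit_mediator_model(df, spec), spec
        )

        p_m1 = {
            (x, c): grp["M1"].mean() for (x, c), grp in df.groupby(["X", "c"])
        }
        p_y = {
            key: grp["Y"].mean() for key, grp in df.groupby(["X", "M1", "M2", "c"])
        }
        checked = 0
        for _, row in ex.sample(400, random_state=0).iterrows():
            src = df.loc[int(row.row_id)]
            expected = sum(
                (p_m1[(row.x1, src.c)] if m1 == 1 else 1 - p_m1[(row.x1, src.c)])
                * p_y[(row.x0, m1, src.M2, src.c)]
                for m1 in (0.0, 1.0)
            )
            assert row.yhat == pytest.approx(expected, rel=1e-10)
            checked += 1
        assert checked == 400


class TestFitNaturalModel:
    def test_decomposition_identity_exact(self, analysis_20k):
        fit = natural_effects(analysis_20k.head(4000))
        assert fit.or_te == pytest.approx(fit.or_nde * fit.or_nie_joint, rel=1e-12)
        assert fit.or_nie_joint == pytest.approx(fit.or_nie_m1 * fit.or_nie_m2, rel=1e-12)

    def test_null_mediated_paths_give_unit_joint_nie(self, calibrated_params):
        p = calibrated_params.replace(
            n_children=50_000,
            seed=7,
            alpha_m1=dataclasses.replace(calibrated_params.alpha_m1, x=0.0),
            alpha_m2=dataclasses.replace(calibrated_params.alpha_m2, x=0.0),
        )
        fit = natural_effects(analysis_from(p))
        assert 0.97 <= fit.or_nie_joint <= 1.03

    def test_null_direct_path_gives_unit_nde(self, calibrated_params):
        p = calibrated_params.replace(
            n_children=50_000,
            seed=8,
            alpha_y=dataclasses.replace(calibrated_params.alpha_y, x=0.0),
        )
        fit = natural_effects(analysis_from(p))
        assert 0.95 <= fit.or_nde <= 1.05

    def test_recovery_against_oracle(self, calibrated_params, analysis_20k):
        oracle = fs.oracle_effects(calibrated_params, n_mc=300_000, seed=19)
        fit = natural_effects(analysis_20k)
        # single cohort of n=20,000: allow 3 x empirical sampling SD
        tol = {"or_te": 0.27, "or_nde": 0.27, "or_nie_m1": 0.03, "or_nie_m2": 0.03,
               "or_nie_joint": 0.04}
        for k, target in oracle.as_dict().items():
            assert abs(np.log(fit.effects()[k]) - np.log(target)) < tol[k], k

    def test_weights_change_estimates(self, analysis_20k):
        sub = analysis_20k.head(4000).copy()
        base = natural_effects(sub)
        rng = np.random.default_rng(0)
        sub["weight"] = rng.lognormal(0, 0.8, len(sub))
        weighted = natural_effects(sub)
        assert weighted.or_te != pytest.approx(base.or_te, rel=1e-6)


class TestBootstrap:
    def test_constant_estimator_zero_width(self, analysis_20k):
        spec = NaturalModelSpec(n_boot=25, seed=1)
        const = {k: 1.5 for k in ("or_te", "or_nde", "or_nie_m1", "or_nie_m2", "or_nie_joint")}
        cis = bootstrap_cis(analysis_20k.head(200), spec, estimator=lambda df, rng: const)
        for lo, hi in cis.values():
            assert lo == hi == 1.5

    def test_same_seed_identical(self, analysis_20k):
        sub = analysis_20k.head(800)
        spec = NaturalModelSpec(n_boot=10, seed=33)
        assert bootstrap_cis(sub, spec) == bootstrap_cis(sub, spec)

    def test_too_many_failures_raise(self, analysis_20k):
        def flaky(df, rng):
            raise RuntimeError("boom")

        spec = NaturalModelSpec(n_boot=10, seed=2)
        with pytest.raises(RuntimeError, match="replicates failed"):
            bootstrap_cis(analysis_20k.head(100), spec, estimator=flaky)

    def test_nominal_coverage_scaled_down(self, calibrated_params):
        # reduced-scale coverage simulation for the or_nde percentile CI
        oracle = fs.oracle_effects(calibrated_params, n_mc=200_000, seed=55)
        n_sims, covered = 60, 0
        spec = NaturalModelSpec(n_boot=80, seed=0)
        for s in range(n_sims):
            a = analysis_from(calibrated_params.replace(n_children=600, seed=9000 + s))
            cis = bootstrap_cis(a, dataclasses.replace(spec, seed=s))
            lo, hi = cis["or_nde"]
            covered += lo <= oracle.or_nde <= hi
        rate = covered / n_sims
        # binomial 99% bounds around 0.95 at 60 sims
        half = 2.576 * np.sqrt(0.95 * 0.05 / n_sims)
        assert 0.95 - half <= rate <= 1.0


class TestPooling:
    def _fit(self, theta1):
        theta = {"const": -2.0, "x0": theta1, "x1": 0.05, "x2": 0.1}
        from famstress.mediation import _fit_from_theta

        return _fit_from_theta(dict(theta))

    def test_identical_fits_pool_to_same(self):
        fits = [self._fit(0.6)] * 3
        pooled = pool_over_imputations(fits)
        assert pooled.theta == pytest.approx(fits[0].theta)
        assert pooled.m_imputations == 3

    def test_mean_of_theta(self):
        pooled = pool_over_imputations([self._fit(0.6), self._fit(0.8)])
        assert pooled.theta["x0"] == pytest.approx(0.7)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pool_over_imputations([])

    def test_mismatched_specs_rejected(self):
        from famstress.mediation import _fit_from_theta

        a = _fit_from_theta({"const": 0.0, "x0": 0.1, "x1": 0.0, "x2": 0.0})
        b = _fit_from_theta({"const": 0.0, "x0": 0.1, "x1": 0.0, "x2": 0.0, "extra": 1.0})
        with pytest.raises(ValueError, match="mismatched"):
            pool_over_imputations([a, b])

    def test_pooled_close_to_complete_data_fit(self, analysis_20k):
        from famstress.missing import chained_impute

        complete = analysis_20k.head(5000).reset_index(drop=True)
        full_fit = natural_effects(complete)
        degraded = complete.copy()
        rng = np.random.default_rng(3)
        for col in ["M1", "M2", "Y"]:
            degraded.loc[rng.random(len(degraded)) < 0.10, col] = np.nan
        model_cols = ["X", "M1", "M2", "Y", *fs.CONFOUNDERS]
        imp = chained_impute(degraded[model_cols], m=5, n_iterations=5, seed=4)
        fits = [
            natural_effects(d.assign(weight=1.0)) for d in imp.datasets
        ]
        pooled = pool_over_imputations(fits)
        tol = {"or_te": 0.15, "or_nde": 0.15, "or_nie_m1": 0.05, "or_nie_m2": 0.05,
               "or_nie_joint": 0.06}
        for k, v in pooled.log_effects().items():
            assert abs(v - full_fit.log_effects()[k]) < tol[k], k
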