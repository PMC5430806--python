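"""Standardization, OLS model suite, VIF, pruning and mediation checks."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from motenet import (compute_vif, fit_fertility_model,
                     fit_fertility_with_pruning, fit_joint_model,
                     fit_sickness_model, mediation_check, two_sd_standardize)
from motenet.errors import CollinearityError, DegenerateDataError

RNG = np.random.default_rng(777)


def _frame(n=120, n_camps=3, seed=7):
    rng = np.random.default_rng(seed)
    camp = np.repeat([f"c{i}" for i in range(n_camps)], n // n_camps)
    df = pd.DataFrame({
        "camp": camp,
        "age": rng.uniform(17, 75, len(camp)),
        "z_degree": rng.normal(size=len(camp)),
        "z_betweenness": rng.normal(size=len(camp)),
        "z_closeness": rng.normal(size=len(camp)),
        "settled": rng.integers(0, 2, len(camp)),
        "mobile": rng.integers(0, 2, len(camp)),
        "belongings": rng.lognormal(1, 0.5, len(camp)),
        "n_dependents": rng.poisson(3, len(camp)),
    })
    df["residual"] = (0.8 * df["z_closeness"]
                      + rng.normal(scale=1.5, size=len(camp)))
    df["sickness_count"] = rng.integers(0, 3, len(camp))
    return df


class TestTwoSD:
    def test_definitional_rescaling(self):
        df = pd.DataFrame({"x": [8.0, 10.0, 12.0]})   # mean 10, sd 2
        out = two_sd_standardize(df, ["x"])
        assert out["x"].tolist() == [-0.5, 0.0, 0.5]

    def test_binary_columns_untouched(self):
        df = pd.DataFrame({"b": [0, 1, 1, 0]})
        out = two_sd_standardize(df, ["b"])
        assert out["b"].tolist() == [0, 1, 1, 0]

    def test_zero_variance_continuous_rejected(self):
        with pytest.raises(DegenerateDataError, match="x"):
            two_sd_standardize(pd.DataFrame({"x": [2.0, 2.0, 2.0]}), ["x"])

    def test_age_center_override(self):
        df = pd.DataFrame({"age": [30.0, 40.0, 50.0]})
        out = two_sd_standardize(df, ["age"], age_center=36.0)
        assert out["age"].iloc[1] == pytest.approx((40 - 36) / (2 * 10.0))

    def test_coefficients_rescale_exactly(self):
        # beta on a 2-SD standardized predictor equals 2*SD*(raw beta)
        rng = np.random.default_rng(3)
        x = rng.normal(10, 3, 80)
        y = 1.3 * x + rng.normal(size=80)
        raw = sm.OLS(y, sm.add_constant(x)).fit().params[1]
        xs = two_sd_standardize(pd.DataFrame({"x": x}), ["x"])["x"]
        std = sm.OLS(y, sm.add_constant(xs.to_numpy())).fit().params[1]
        assert std == pytest.approx(2 * np.std(x, ddof=1) * raw, abs=1e-10)


class TestFertilityModel:
    def test_planted_effect_recovered_in_sample(self):
        df = _frame()
        res = fit_fertility_model(df, "closeness")
        # generative slope 0.8 per z unit = 1.6 per 2-SD unit
        assert res.beta("closeness") == pytest.approx(
            1.6, abs=4 * res._row("closeness")["se"])
        assert res.p("closeness") < 0.001
        lo, hi = res.ci("closeness")
        assert lo <= res.beta("closeness") <= hi

    def test_shifting_outcome_moves_only_intercept(self):
        df = _frame()
        r1 = fit_fertility_model(df, "betweenness")
        r2 = fit_fertility_model(df.assign(residual=df["residual"] + 5.0),
                                 "betweenness")
        assert r2.beta("const") == pytest.approx(r1.beta("const") + 5.0)
        assert r2.beta("betweenness") == pytest.approx(
            r1.beta("betweenness"), abs=1e-10)

    def test_camp_fixed_effects_absorb_camp_shifts(self):
        df = _frame()
        shifted = df.copy()
        shifted.loc[shifted["camp"] == "c1", "residual"] += 7.0
        b0 = fit_fertility_model(df, "closeness").beta("closeness")
        b1 = fit_fertility_model(shifted, "closeness").beta("closeness")
        assert b1 == pytest.approx(b0, abs=1e-10)

    def test_rank_deficient_design_rejected(self):
        df = _frame()
        df["camp"] = "only_one"          # no camp variation
        df["z_degree"] = df["z_closeness"]
        with pytest.raises(CollinearityError):
            fit_joint_model(df, measures=("degree", "closeness"))


class TestPruning:
    def test_insignificant_interaction_removed(self):
        df = _frame(seed=21)             # no planted interaction
        res = fit_fertility_with_pruning(df, "closeness")
        assert res.interaction_retained is False
        assert not any(t.endswith(":age") for t in res.terms["term"])

    def test_strong_interaction_retained(self):
        rng = np.random.default_rng(5)
        df = _frame(n=240, seed=5)
        zc = df["z_closeness"]
        s_age = (df["age"] - df["age"].mean()) / (2 * df["age"].std(ddof=1))
        s_zc = (zc - zc.mean()) / (2 * zc.std(ddof=1))
        df["residual"] = 3.0 * s_zc * s_age + rng.normal(scale=0.5, size=len(df))
        res = fit_fertility_with_pruning(df, "closeness")
        assert res.interaction_retained is True
        assert res.p("closeness:age") < 0.001

    def test_threshold_one_never_prunes(self):
        df = _frame(seed=9)
        res = fit_fertility_with_pruning(df, "degree", threshold=1.0)
        assert res.interaction_retained is True


class TestVIF:
    def test_orthogonal_predictors_have_unit_vif(self):
        X = pd.DataFrame({"a": [1, 1, -1, -1], "b": [1, -1, 1, -1]},
                         dtype=float)
        vif = compute_vif(X)
        assert vif["a"] == pytest.approx(1.0)
        assert vif["b"] == pytest.approx(1.0)

    def test_duplicate_predictor_is_infinite(self):
        x = np.arange(10.0)
        vif = compute_vif(pd.DataFrame({"a": x, "b": x}))
        assert np.isinf(vif["a"])

    def test_matches_auxiliary_regression_oracle(self):
        rng = np.random.default_rng(11)
        X = pd.DataFrame(rng.normal(size=(50, 3)), columns=list("abc"))
        X["c"] += 0.9 * X["a"]
        vif = compute_vif(X)
        for col in "abc":
            others = np.column_stack(
                [np.ones(50)] + [X[o] for o in "abc" if o != col])
            bh, *_ = np.linalg.lstsq(others, X[col], rcond=None)
            resid = X[col] - others @ bh
            r2 = 1 - resid @ resid / ((X[col] - X[col].mean()) ** 2).sum()
            assert vif[col] == pytest.approx(1 / (1 - r2), abs=1e-10)


class TestJointModel:
    def test_orthogonal_predictors_match_single_models(self):
        rng = np.random.default_rng(13)
        n = 64
        # exactly orthogonal, zero-mean predictors in one camp
        from scipy.linalg import qr
        Q, _ = qr(rng.normal(size=(n, 3)), mode="economic")
        Q -= Q.mean(axis=0)
        df = pd.DataFrame(Q, columns=["z_degree", "z_betweenness",
                                      "z_closeness"])
        # re-orthogonalize after centering
        Q2, _ = qr(df.to_numpy(), mode="economic")
        df[["z_degree", "z_betweenness", "z_closeness"]] = Q2 - Q2.mean(0)
        df["camp"] = "c"
        df["age"] = rng.uniform(20, 60, n)
        df["residual"] = rng.normal(size=n)
        joint = fit_joint_model(df)
        for m in ("degree", "betweenness", "closeness"):
            single = fit_fertility_model(df, m)
            assert joint.beta(m) == pytest.approx(single.beta(m), abs=1e-9)
        assert all(v == pytest.approx(1.0, abs=1e-9)
                   for v in joint.vif.values())

    def test_vif_breach_aborts_when_asked(self):
        rng = np.random.default_rng(17)
        df = _frame(seed=17)
        df["z_degree"] = 0.93 * df["z_betweenness"] + 0.37 * rng.normal(
            size=len(df))
        vifs = fit_joint_model(df, vif_mode="warn").vif
        assert max(vifs.values()) > 2.5    # fixture really does breach
        with pytest.raises(CollinearityError):
            fit_joint_model(df, vif_mode="abort")


class TestSicknessAndMediation:
    def test_constant_outcome_rejected(self):
        df = _frame()
        df["sickness_count"] = 1
        with pytest.raises(DegenerateDataError):
            fit_sickness_model(df, "closeness")

    def test_identical_models_have_zero_attenuation(self):
        df = _frame()
        m = fit_sickness_model(df, "closeness")
        med = mediation_check(m, m, "closeness")
        assert med.attenuation == pytest.approx(0.0)

    def test_sample_mismatch_rejected(self):
        df = _frame()
        m1 = fit_sickness_model(df, "closeness")
        m2 = fit_sickness_model(df.iloc[:-6], "closeness")
        with pytest.raises(ValueError):
            mediation_check(m1, m2, "closeness")

    def test_dependents_channel_attenuates_coefficient(self):
        rng = np.random.default_rng(23)
        df = _frame(n=300, seed=23)
        # sickness driven only by dependents; dependents track betweenness
        df["n_dependents"] = np.round(
            3 + 2 * df["z_betweenness"] + rng.normal(scale=0.5, size=len(df))
        ).clip(0)
        lam = np.exp(-1.2 + 0.35 * df["n_dependents"])
        df["sickness_count"] = np.minimum(2, rng.poisson(lam))
        without = fit_sickness_model(df, "betweenness")
        with_ = fit_sickness_model(df, "betweenness", include_dependents=True)
        med = mediation_check(without, with_, "betweenness")
        assert med.significant_without
        assert abs(med.beta_with) < abs(med.beta_without)
        assert med.attenuation > 0.5

    def test_poisson_family_agrees_on_sign(self):
        df = _frame(n=300, seed=29)
        rng = np.random.default_rng(29)
        lam = np.exp(-0.3 + 0.8 * (df["z_closeness"] / 2))
        df["sickness_count"] = np.minimum(2, rng.poisson(lam))
        ols = fit_sickness_model(df, "closeness")
        pois = fit_sickness_model(df, "closeness", family="poisson")
        assert np.sign(ols.beta("closeness")) == np.sign(
            pois.beta("closeness")) == 1.0
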