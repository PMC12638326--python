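"""Association models: oracle equivalence, planted-effect recovery, guards."""

import numpy as np
import pandas as pd
import pytest

from wmbrainage import assoc, synth
from wmbrainage.imgio import RISK_FACTORS

from _oracle import ols_oracle


def _small_frame(n=50, seed=0):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "age": rng.uniform(45, 83, n),
            "sex": rng.integers(0, 2, n),
            "scanner": rng.integers(0, 3, n),
            "apoe_e4_count": rng.choice([0, 1, 2], n),
            "education_college": rng.integers(0, 2, n),
            "health_status": rng.choice(["healthy", "unhealthy"], n),
        }
    )
    for k in RISK_FACTORS:
        df[k] = (rng.random(n) < 0.25).astype(float)
    # pin the first rows so every VRS category occurs for both sexes and
    # the design stays full rank at small n
    patterns = [0, 1, 2, 3, 4, 0, 1, 2, 3, 4]
    for i, cnt in enumerate(patterns):
        for j, k in enumerate(RISK_FACTORS):
            df.loc[i, k] = float(j < cnt)
        df.loc[i, "sex"] = int(i >= 5)
    count = df[list(RISK_FACTORS)].sum(axis=1)
    capped = np.minimum(count, 3)
    for lv in (1, 2, 3):
        df[f"vrs_{lv}"] = (capped == lv).astype(float)
    df["wmbag"] = rng.normal(0, 3, n)
    df["speed"] = rng.normal(0, 1, n)
    df["executive"] = rng.normal(0, 1, n)
    df["memory"] = rng.normal(0, 1, n)
    df["global_cognition"] = df[["speed", "executive", "memory"]].mean(axis=1)
    return df


def _check_against_oracle(result, df, outcome, terms):
    sub = df[[outcome, *terms]].dropna()
    oracle = ols_oracle(sub[terms].to_numpy(float), sub[outcome].to_numpy(float))
    got = result.terms.loc[terms]
    np.testing.assert_allclose(got["beta"].to_numpy(), oracle["beta"][1:], atol=1e-8)
    np.testing.assert_allclose(got["ci_low"].to_numpy(), oracle["ci_low"][1:], atol=1e-8)
    np.testing.assert_allclose(got["ci_high"].to_numpy(), oracle["ci_high"][1:], atol=1e-8)
    np.testing.assert_allclose(got["p"].to_numpy(), oracle["p"][1:], atol=1e-8)


class TestOracleEquivalence:
    """Every model matches the independent normal-equations solver."""

    def test_model_1a(self):
        df = _small_frame()
        res = assoc.fit_model_1a(df)
        _check_against_oracle(res, df, "wmbag", ["vrs_1", "vrs_2", "vrs_3", *assoc.DEFAULT_COVARIATES])

    def test_model_1b(self):
        df = _small_frame(seed=1)
        res = assoc.fit_model_1b(df)
        data = df.copy()
        for k in (1, 2, 3):
            data[f"vrs_{k}_x_sex"] = data[f"vrs_{k}"] * data["sex"]
        terms = ["vrs_1", "vrs_2", "vrs_3", *assoc.DEFAULT_COVARIATES,
                 "vrs_1_x_sex", "vrs_2_x_sex", "vrs_3_x_sex"]
        _check_against_oracle(res, data, "wmbag", terms)

    def test_model_2a_and_2bf(self):
        df = _small_frame(seed=2)
        res = assoc.fit_model_2a(df)
        _check_against_oracle(res, df, "wmbag", [*RISK_FACTORS, *assoc.DEFAULT_COVARIATES])
        for k, r in assoc.fit_models_2b_f(df).items():
            data = df.copy()
            data[f"{k}_x_sex"] = data[k] * data["sex"]
            _check_against_oracle(
                r, data, "wmbag", [*RISK_FACTORS, *assoc.DEFAULT_COVARIATES, f"{k}_x_sex"]
            )

    def test_ancova_and_cognition(self):
        df = _small_frame(seed=3)
        res = assoc.ancova_group_difference(df)
        data = df.copy()
        data["group"] = (data["health_status"] == "unhealthy").astype(float)
        _check_against_oracle(res, data, "wmbag", ["group", *assoc.DEFAULT_COVARIATES])
        table, results = assoc.cognition_regressions(df)
        for outcome, r in results.items():
            _check_against_oracle(
                r, df, outcome, ["wmbag", *assoc.DEFAULT_COVARIATES, "education_college"]
            )


class TestRecovery:
    def test_ancova_recovers_planted_group_offset(self):
        cfg = synth.SynthConfig(n_participants=2000, seed=21, unhealthy_fraction=0.3)
        records, truth = synth.simulate_cohort(cfg)
        df = records.copy()
        df["wmbag"] = truth["true_gap"]
        res = assoc.ancova_group_difference(df)
        assert abs(res.beta("group") - cfg.unhealthy_extra_gap) < 3 * res.se("group")

    def test_covariate_free_ancova_equals_t_test_difference(self):
        df = _small_frame(seed=4)
        res = assoc.ancova_group_difference(df, covariates=())
        means = df.groupby("health_status")["wmbag"].mean()
        assert res.beta("group") == pytest.approx(means["unhealthy"] - means["healthy"])

    def test_noise_free_gap_recovers_planted_betas_exactly(self):
        cfg = synth.SynthConfig(
            n_participants=800,
            seed=22,
            gap_noise_sd=0.0,
            sex_obesity_interaction=0.0,
            unhealthy_fraction=0.0,
        )
        records, truth = synth.simulate_cohort(cfg)
        df = records.copy()
        df["wmbag"] = truth["true_gap"]
        res = assoc.fit_model_2a(df)
        for k in RISK_FACTORS:
            assert res.beta(k) == pytest.approx(cfg.risk_age_offsets[k], abs=1e-8), k

    def test_model_1b_sex_recode_flips_interaction_signs(self):
        df = _small_frame(n=120, seed=5)
        res = assoc.fit_model_1b(df)
        flipped = df.copy()
        flipped["sex"] = 1 - flipped["sex"]
        res_f = assoc.fit_model_1b(flipped)
        for k in (1, 2, 3):
            t = f"vrs_{k}_x_sex"
            assert res_f.beta(t) == pytest.approx(-res.beta(t), abs=1e-8)
        # dummy main effects now refer to the other sex at the reference
        # level, but fit quality is unchanged
        assert res.sm_result.rsquared == pytest.approx(res_f.sm_result.rsquared)

    def test_vrs_level_sex_contrast_delta_method(self):
        df = _small_frame(n=200, seed=6)
        res = assoc.fit_model_1b(df)
        c = assoc.vrs_level_sex_contrast(res, 3)
        assert c["difference"] == pytest.approx(
            res.beta("sex") + res.beta("vrs_3_x_sex")
        )
        assert c["se"] > 0 and 0 <= c["p"] <= 1


class TestGuards:
    def test_constant_dummy_rejected_with_name(self):
        df = _small_frame(seed=7)
        df["vrs_3"] = 0.0
        with pytest.raises(ValueError, match="vrs_3"):
            assoc.fit_model_1a(df)

    def test_zero_prevalence_factor_rejected(self):
        df = _small_frame(seed=8)
        df["diabetes"] = 0.0
        with pytest.raises(ValueError, match="diabetes"):
            assoc.fit_model_2a(df)

    def test_single_sex_level_rejected(self):
        df = _small_frame(seed=9)
        df["sex"] = 1
        with pytest.raises(ValueError, match="sex"):
            assoc.fit_models_2b_f(df)

    def test_empty_group_rejected(self):
        df = _small_frame(seed=10)
        df["health_status"] = "healthy"
        with pytest.raises(ValueError, match="two groups"):
            assoc.ancova_group_difference(df)

    def test_missing_outcome_skipped_with_warning(self):
        df = _small_frame(seed=11).drop(columns=["memory"])
        with pytest.warns(UserWarning, match="memory"):
            table, _ = assoc.cognition_regressions(df)
        assert "memory" not in set(table["outcome"])

    def test_complete_case_accounting(self):
        df = _small_frame(n=100, seed=12)
        df.loc[:9, "apoe_e4_count"] = np.nan
        res = assoc.fit_model_2a(df)
        assert res.n_used == 90


class TestCalibration:
    def test_null_interaction_p_values_uniform(self):
        """With no planted interactions, 2b-f interaction tests reject at
        the nominal rate over replicates."""
        rejections = 0
        R = 120
        for r in range(R):
            rng = np.random.default_rng(1000 + r)
            n = 150
            df = pd.DataFrame(
                {
                    "age": rng.uniform(45, 83, n),
                    "sex": rng.integers(0, 2, n),
                    "scanner": rng.integers(0, 3, n),
                    "apoe_e4_count": rng.choice([0, 1, 2], n),
                    "obesity": rng.integers(0, 2, n).astype(float),
                }
            )
            df["wmbag"] = rng.normal(0, 1, n)  # independent of everything
            data, inter = assoc._with_interactions(df, [("obesity", "sex")])
            res = assoc._fit_ols(
                data, "wmbag", ["obesity", *assoc.DEFAULT_COVARIATES, *inter], "null"
            )
            rejections += res.p("obesity_x_sex") < 0.05
        rate = rejections / R
        se = np.sqrt(0.05 * 0.95 / R)
        assert abs(rate - 0.05) < 3.5 * se
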