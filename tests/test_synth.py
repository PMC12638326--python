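"""Cohort generator: determinism, planted effects, maps, splits."""

import numpy as np
import pandas as pd
import pytest

from wmbrainage import synth
from wmbrainage.imgio import MAP_NAMES, RISK_FACTORS

from _oracle import ols_oracle


def _cfg(**kw):
    return synth.SynthConfig(**kw)


class TestSimulateCohort:
    def test_deterministic_under_seed(self):
        cfg = _cfg(n_participants=50, seed=11)
        r1, t1 = synth.simulate_cohort(cfg)
        r2, t2 = synth.simulate_cohort(_cfg(n_participants=50, seed=11))
        pd.testing.assert_frame_equal(r1, r2)
        pd.testing.assert_frame_equal(t1, t2)

    def test_no_risk_null_case(self):
        cfg = _cfg(
            n_participants=500,
            seed=2,
            risk_prevalences={k: 0.0 for k in RISK_FACTORS},
            unhealthy_fraction=0.0,
        )
        _, truth = synth.simulate_cohort(cfg)
        # only the Gaussian noise term remains
        assert abs(truth["true_gap"].mean()) < 4 * cfg.gap_noise_sd / np.sqrt(500)

    def test_forced_single_factor_offset(self):
        cfg = _cfg(
            n_participants=40,
            seed=3,
            risk_prevalences={**{k: 0.0 for k in RISK_FACTORS}, "diabetes": 1.0},
            risk_age_offsets={**{k: 0.0 for k in RISK_FACTORS}, "diabetes": 1.39},
            gap_noise_sd=0.0,
            sex_obesity_interaction=0.0,
            unhealthy_fraction=0.0,
        )
        _, truth = synth.simulate_cohort(cfg)
        assert np.allclose(truth["true_gap"], 1.39)

    def test_empirical_prevalence_matches_configuration(self):
        cfg = _cfg(n_participants=2000, seed=7)
        records, _ = synth.simulate_cohort(cfg)
        p = cfg.risk_prevalences["hypertension"]
        se = np.sqrt(p * (1 - p) / 2000)
        assert abs(records["hypertension"].mean() - p) < 3 * se

    def test_ages_within_range(self, default_cohort):
        cfg, records, _ = default_cohort
        lo, hi = cfg.age_range
        assert records["age"].between(lo, hi).all()

    def test_offset_recovery_oracle(self, default_cohort):
        """Regressing true_gap on the factor indicators recovers each
        planted offset within 3 s.e. (male-only obesity damage appears
        as its marginal male-fraction share in this no-interaction fit)."""
        cfg = _cfg(n_participants=5000, seed=5, gap_noise_sd=1.0)
        records, truth = synth.simulate_cohort(cfg)
        X = np.column_stack(
            [truth[f"true_{k}"].to_numpy() for k in RISK_FACTORS]
            + [records["sex"].to_numpy()]
        )
        fit = ols_oracle(X, truth["true_gap"].to_numpy())
        p_male_obese = records.loc[truth["true_obesity"] == 1, "sex"].mean()
        expected = [
            cfg.risk_age_offsets[k]
            + (cfg.sex_obesity_interaction * p_male_obese if k == "obesity" else 0.0)
            for k in RISK_FACTORS
        ]
        for i, (k, exp) in enumerate(zip(RISK_FACTORS, expected)):
            assert abs(fit["beta"][i + 1] - exp) < 3 * fit["se"][i + 1], k

    def test_invalid_configs_rejected(self):
        with pytest.raises(synth.ConfigError):
            _cfg(risk_prevalences={**synth._default_prevalences(), "diabetes": 1.4})
        with pytest.raises(synth.ConfigError):
            _cfg(age_range=(80.0, 45.0))
        with pytest.raises(synth.ConfigError):
            _cfg(grid_shape=(0, 8, 8))


class TestRenderMaps:
    def test_fa_decreases_with_effective_age(self):
        cfg = _cfg(
            n_participants=2,
            seed=1,
            noise_sd_map={m: 0.0 for m in MAP_NAMES},
            shared_noise_sd=0.0,
        )
        rec = {"participant_id": "S00000", "timepoint": "baseline", "age": 55.0}
        young = synth.render_maps(rec, {"participant_id": "S00000", "true_gap": 0.0}, cfg)
        old = synth.render_maps(rec | {"age": 75.0}, {"participant_id": "S00000", "true_gap": 0.0}, cfg)
        assert old.volumes["FA"].mean() < young.volumes["FA"].mean()
        assert old.volumes["MD"].mean() > young.volumes["MD"].mean()

    def test_rendering_deterministic(self):
        cfg = _cfg(n_participants=2, seed=4)
        rec = {"participant_id": "S00001", "timepoint": "baseline", "age": 60.0}
        tru = {"participant_id": "S00001", "true_gap": 1.0}
        a = synth.render_maps(rec, tru, cfg)
        b = synth.render_maps(rec, tru, cfg)
        for m in MAP_NAMES:
            np.testing.assert_array_equal(a.volumes[m], b.volumes[m])

    def test_mismatched_ids_rejected(self):
        cfg = _cfg(n_participants=2, seed=4)
        with pytest.raises(ValueError, match="mismatch"):
            synth.render_maps(
                {"participant_id": "S00001", "age": 60.0},
                {"participant_id": "S00002", "true_gap": 0.0},
                cfg,
            )

    def test_md_voxel_mean_slope_recovers_configured_slope(self):
        cfg = _cfg(n_participants=500, seed=6, grid_shape=(12, 14, 12))
        records, truth = synth.simulate_cohort(cfg)
        vols = synth.render_cohort(records, truth, cfg)
        a_eff = records["age"].to_numpy() + truth["true_gap"].to_numpy()
        means = vols["MD"].mean(axis=(1, 2, 3)).astype(np.float64)
        fit = ols_oracle(a_eff, means)
        assert abs(fit["beta"][1] - cfg.map_age_slopes["MD"]) < 2 * fit["se"][1]

    def test_within_participant_maps_correlated(self):
        cfg = _cfg(n_participants=80, seed=8, grid_shape=(12, 14, 12))
        records, truth = synth.simulate_cohort(cfg)
        vols = synth.render_cohort(records, truth, cfg)
        # residual map means after removing the age trend correlate
        # across maps through the shared participant field
        a_eff = records["age"].to_numpy() + truth["true_gap"].to_numpy()
        res = {}
        for m in ("FA", "MD"):
            y = vols[m].mean(axis=(1, 2, 3)).astype(np.float64)
            fit = ols_oracle(a_eff, y)
            res[m] = y - (fit["beta"][0] + fit["beta"][1] * a_eff)
        assert abs(np.corrcoef(res["FA"], res["MD"])[0, 1]) > 0.2


class TestCognition:
    def test_null_paths_make_cognition_independent_of_factors(self):
        cfg = _cfg(
            n_participants=2000,
            seed=9,
            cognition_paths=synth.CognitionPaths(
                b={}, c_prime={}, age_beta=0.0, sex_beta=0.0, edu_beta=0.0
            ),
        )
        records, truth = synth.simulate_cohort(cfg)
        cog, _ = synth.simulate_cognition(records, truth, cfg)
        fit = ols_oracle(truth["true_diabetes"].to_numpy(), cog["symbol_digit"].to_numpy())
        assert abs(fit["beta"][1] / fit["se"][1]) < 2

    def test_noise_free_limit_equals_linear_predictor(self):
        paths = synth.CognitionPaths(domain_noise_sd=0.0, test_noise_sd=0.0)
        cfg = _cfg(n_participants=30, seed=10, cognition_paths=paths)
        records, truth = synth.simulate_cohort(cfg)
        cog, lat = synth.simulate_cognition(records, truth, cfg)
        # symbol digit is an unreversed speed test: raw = 20 + 5 * latent
        np.testing.assert_allclose(
            cog["symbol_digit"].to_numpy(),
            20.0 + 5.0 * lat["latent_speed"].to_numpy(),
            atol=1e-10,
        )
        # reaction time is reversed: raw = 550 - 100 * latent
        np.testing.assert_allclose(
            cog["reaction_time"].to_numpy(),
            550.0 - 100.0 * lat["latent_speed"].to_numpy(),
            atol=1e-9,
        )

    def test_implied_indirect_effect_arithmetic(self):
        # planted a = 1.39 (diabetes offset), b = 0.02 -> a*b = 0.0278
        cfg = _cfg(
            n_participants=10,
            cognition_paths=synth.CognitionPaths(b={"speed": 0.02}),
        )
        implied = cfg.risk_age_offsets["diabetes"] * cfg.cognition_paths.b["speed"]
        assert implied == pytest.approx(0.0278)


class TestLongitudinal:
    def test_zero_fraction_empty(self, default_cohort):
        cfg, records, truth = default_cohort
        import dataclasses

        cfg0 = dataclasses.replace(cfg, longitudinal_fraction=0.0)
        fu, ft = synth.make_longitudinal_subset(records, truth, cfg0)
        assert len(fu) == 0 and len(ft) == 0

    def test_zero_interval_sd_degenerate(self, default_cohort):
        cfg, records, truth = default_cohort
        import dataclasses

        cfg0 = dataclasses.replace(cfg, interval_years=(2.25, 0.0))
        fu, _ = synth.make_longitudinal_subset(records, truth, cfg0)
        base = records.set_index("participant_id").loc[fu["participant_id"], "age"]
        np.testing.assert_allclose(fu["age"].to_numpy() - base.to_numpy(), 2.25)

    def test_subset_size_binomial(self, default_cohort):
        cfg, records, truth = default_cohort
        fu, _ = synth.make_longitudinal_subset(records, truth, cfg)
        p = cfg.longitudinal_fraction  # 1409/11168 analogue
        n = len(records)
        se = np.sqrt(p * (1 - p) * n)
        assert abs(len(fu) - p * n) < 3 * se

    def test_risk_factors_carried_forward(self, default_cohort):
        cfg, records, truth = default_cohort
        fu, _ = synth.make_longitudinal_subset(records, truth, cfg)
        base = records.set_index("participant_id")
        for k in RISK_FACTORS:
            np.testing.assert_array_equal(
                fu[k].to_numpy(), base.loc[fu["participant_id"], k].to_numpy()
            )


class TestSplits:
    def test_all_train_when_single_fraction(self):
        cfg = _cfg(n_participants=50, seed=3, unhealthy_fraction=0.0)
        records, _ = synth.simulate_cohort(cfg)
        labels = synth.make_splits(records, (1.0, 0.0, 0.0), seed=0)
        assert (labels == "train").all()

    def test_unhealthy_forced_into_test(self):
        cfg = _cfg(n_participants=300, seed=3, unhealthy_fraction=0.2)
        records, _ = synth.simulate_cohort(cfg)
        labels = synth.make_splits(records, seed=0)
        unhealthy = records["health_status"] == "unhealthy"
        assert (labels[unhealthy] == "test").all()
        assert unhealthy.sum() > 0

    def test_exact_proportions(self):
        cfg = _cfg(n_participants=1000, seed=3, unhealthy_fraction=0.0)
        records, _ = synth.simulate_cohort(cfg)
        labels = synth.make_splits(records, (0.6, 0.2, 0.2), seed=0)
        counts = labels.value_counts()
        assert counts["train"] == 600 and counts["validation"] == 200 and counts["test"] == 200

    def test_bad_fractions_rejected(self, default_cohort):
        _, records, _ = default_cohort
        with pytest.raises(synth.ConfigError, match="sum to 1"):
            synth.make_splits(records, (0.5, 0.2, 0.2), seed=0)

    def test_split_deterministic(self, default_cohort):
        _, records, _ = default_cohort
        a = synth.make_splits(records, seed=5)
        b = synth.make_splits(records, seed=5)
        pd.testing.assert_series_equal(a, b)
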