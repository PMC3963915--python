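import numpy as np
import pandas as pd
import pytest

from cordmediate.birth_outcomes import classify_sga_cohort
from cordmediate.exposure import classify_exposure, impute_below_lod
from cordmediate.synthetic_cohort import (
    MEDIATOR_GENE,
    MEDIATOR_TRANSCRIPT,
    SimulationConfig,
    SyntheticTruth,
    generate_cohort,
    generate_expression,
    generate_qpcr,
    generate_reference_curves,
)

ZERO_NOISE = SimulationConfig(
    residual_bw_sd=0.0,
    beta_as_per_iqr=0.0,
    mediator_bw_effect_girls=0.0,
    mediator_bw_effect_boys=0.0,
    n_missing_birthweight=0,
    n_missing_maternal_as=0,
    seed=1,
)


class TestConfig:
    def test_theoretical_iqr_matches_lognormal_closed_form(self):
        cfg = SimulationConfig()
        # Q3 - Q1 of LogNormal(ln 0.56, ln 3.25)
        from scipy import stats

        dist = stats.lognorm(s=np.log(3.25), scale=0.56)
        assert cfg.as_iqr_theoretical == pytest.approx(dist.ppf(0.75) - dist.ppf(0.25), rel=1e-12)
        assert cfg.as_iqr_theoretical == pytest.approx(0.99, abs=0.01)

    @pytest.mark.parametrize(
        "bad",
        [
            {"n_subjects": 0},
            {"as_gsd": 0.9},
            {"maternal_cord_log_corr": 1.3},
            {"ga_weeks": (10, 11), "ga_probs": (0.5, 0.5)},
            {"residual_bw_sd": -1.0},
        ],
    )
    def test_invalid_configs_rejected(self, bad):
        with pytest.raises(ValueError):
            SimulationConfig(**bad).validate()


class TestGenerateCohort:
    def test_zero_noise_birth_weight_equals_linear_predictor(self):
        cohort, truth = generate_cohort(ZERO_NOISE)
        assert np.array_equal(
            cohort["birth_weight_g"].to_numpy(), truth.linear_predictor
        )

    def test_fixed_seed_is_byte_identical(self, default_config):
        c1, t1 = generate_cohort(default_config)
        c2, t2 = generate_cohort(default_config)
        assert c1.to_csv() == c2.to_csv()
        assert t1 == t2

    def test_censoring_flags_exactly_below_lod(self):
        cfg = SimulationConfig(as_lod=0.5, seed=5)  # high LOD to force censoring
        cohort, truth = generate_cohort(cfg)
        assert np.array_equal(
            cohort["as_cord_below_lod"].to_numpy(), truth.latent_as < 0.5
        )
        assert cohort["as_cord_below_lod"].sum() > 0

    def test_cord_maternal_log_correlation_matches_target(self):
        rs = []
        for seed in range(200):
            cfg = SimulationConfig(seed=seed, n_missing_maternal_as=0)
            cohort, _ = generate_cohort(cfg)
            lc = np.log(cohort["as_cord_ugL"])
            lm = np.log(cohort["as_maternal_ugL"])
            rs.append(np.corrcoef(lc, lm)[0, 1])
        assert np.mean(rs) == pytest.approx(0.82, abs=0.05)

    def test_planted_coefficients_recovered_from_true_design(self):
        cohort, truth = generate_cohort(ZERO_NOISE.replace(beta_as_per_iqr=-47.0))
        cfg = ZERO_NOISE
        X = np.column_stack(
            [
                np.ones(len(cohort)),
                cohort["ga_weeks"] - 40.0,
                (cohort["sex"] == "boy").astype(float),
                cohort["smoking"],
                (cohort["parity"] == 0).astype(float),
                (cohort["parity"] == 1).astype(float),
                truth.latent_as / cfg.as_iqr_theoretical,
            ]
        )
        beta, *_ = np.linalg.lstsq(X, cohort["birth_weight_g"].to_numpy(), rcond=None)
        planted = [cfg.bw_intercept, cfg.beta_ga, cfg.beta_sex_boys, cfg.beta_smoking,
                   cfg.beta_parity_0, cfg.beta_parity_1, -47.0]
        assert np.allclose(beta, planted, atol=1e-8)

    def test_missingness_counts_honoured(self, default_cohort):
        cohort, _ = default_cohort
        assert cohort["birth_weight_g"].isna().sum() == 6
        assert cohort["as_maternal_ugL"].isna().sum() == 6

    def test_nonpositive_n_rejected(self):
        with pytest.raises(ValueError):
            generate_cohort(SimulationConfig(n_subjects=-3))


class TestTruthSerialization:
    def test_round_trip_unchanged(self, default_cohort, tmp_path):
        _, truth = default_cohort
        path = tmp_path / "truth.json"
        truth.to_json(path)
        again = SyntheticTruth.from_json(path)
        assert again == truth


class TestGenerateExpression:
    def test_zero_noise_mediator_contrast_is_exactly_planted(self):
        cfg = SimulationConfig(
            expression_noise_sd=0.0, probe_noise_sd=0.0, seed=2,
            n_missing_birthweight=0,
        )
        cohort, truth = generate_cohort(cfg)
        matrix = generate_expression(cohort, truth, cfg)
        values = impute_below_lod(cohort["as_cord_ugL"], cfg.as_lod, cohort["as_cord_below_lod"])
        labels = classify_exposure(pd.Series(values, index=cohort.index)).labels
        med = matrix.values.loc[MEDIATOR_TRANSCRIPT] if MEDIATOR_TRANSCRIPT in matrix.values.index else None
        row = matrix.annotation.index[matrix.annotation["gene_symbol"] == MEDIATOR_GENE][0]
        med = matrix.values.loc[row]
        diff = med[labels == "high"].mean() - med[labels == "low"].mean()
        assert diff == pytest.approx(0.30, abs=1e-12)

    def test_null_gene_type_one_error_calibrated(self):
        cfg = SimulationConfig(
            n_null_genes=2000, mediator_log2fc_high_as=0.0,
            replicate_probe_fraction=0.0, unreliable_fraction=0.0, seed=3,
        )
        cohort, truth = generate_cohort(cfg)
        matrix = generate_expression(cohort, truth, cfg)
        values = impute_below_lod(cohort["as_cord_ugL"], cfg.as_lod, cohort["as_cord_below_lod"])
        labels = classify_exposure(pd.Series(values, index=cohort.index)).labels
        from cordmediate.transcriptome import welch_t_arrays

        hi = matrix.values.loc[:, labels == "high"].to_numpy()
        lo = matrix.values.loc[:, labels == "low"].to_numpy()
        null_rows = matrix.annotation["gene_symbol"] != MEDIATOR_GENE
        _, _, p, _ = welch_t_arrays(hi[null_rows.to_numpy()], lo[null_rows.to_numpy()], axis=1)
        rate = float((p < 0.05).mean())
        assert 0.035 < rate < 0.065  # 3 binomial SDs around 0.05

    def test_unreliable_feature_count_binomial(self):
        cfg = SimulationConfig(
            n_null_genes=1000, unreliable_fraction=0.05,
            replicate_probe_fraction=0.0, seed=4,
        )
        cohort, truth = generate_cohort(cfg)
        matrix = generate_expression(cohort, truth, cfg)
        failing = (~matrix.reliable()).any(axis=1).sum()
        assert 29 <= failing <= 71  # 50 +- 3 * sqrt(1000 * .05 * .95)

    def test_every_gene_in_a_panel_and_mediator_unique(self, default_config, default_cohort):
        cohort, truth = default_cohort
        matrix = generate_expression(cohort, truth, default_config)
        assert (matrix.annotation["panels"].str.len() > 0).all()
        assert (matrix.annotation["gene_symbol"] == MEDIATOR_GENE).sum() == 1
        med_row = matrix.annotation[matrix.annotation["gene_symbol"] == MEDIATOR_GENE]
        assert med_row["panels"].iloc[0] == "embryonal_growth"
        assert med_row["transcript"].iloc[0] == MEDIATOR_TRANSCRIPT

    def test_replicate_probes_share_transcript(self, default_config, default_cohort):
        cohort, truth = default_cohort
        matrix = generate_expression(cohort, truth, default_config)
        sizes = matrix.annotation.groupby("transcript").size()
        assert sizes.max() == 2 and sizes.min() == 1


class TestReferenceCurves:
    def test_zero_noise_p10_equals_deterministic_predictor(self):
        cfg = ZERO_NOISE.replace(expression_noise_sd=0.0, curve_sim_size=500)
        curves = generate_reference_curves(cfg)
        for sex, sexeff in (("boy", cfg.beta_sex_boys), ("girl", 0.0)):
            for week in cfg.ga_weeks:
                expected_vals = []
                for parity, beta_p in ((0, cfg.beta_parity_0), (1, cfg.beta_parity_1), (2, 0.0)):
                    for smoke, beta_s in ((0, 0.0), (1, cfg.beta_smoking)):
                        expected_vals.append(
                            cfg.bw_intercept + cfg.beta_ga * (week - 40) + sexeff + beta_p + beta_s
                        )
                p10 = curves.p10(sex, week)
                # zero-noise BW is discrete over covariate cells; P10 must be
                # one of the attainable predictor values for that (sex, week)
                assert any(p10 == pytest.approx(v, abs=1e-9) for v in expected_vals)

    def test_curves_monotone_and_round_trip(self, tmp_path, default_config):
        cfg = default_config.replace(curve_sim_size=2000)
        curves = generate_reference_curves(cfg)
        path = tmp_path / "c.csv"
        curves.to_csv(path)
        from cordmediate.birth_outcomes import GrowthCurveTable

        again = GrowthCurveTable.from_csv(path)
        pd.testing.assert_frame_equal(curves.table, again.table)

    def test_sga_prevalence_near_ten_percent_by_construction(self):
        cfg = SimulationConfig(seed=6, curve_sim_size=20000)
        curves = generate_reference_curves(cfg)
        flags = []
        for seed in range(4):
            cohort, _ = generate_cohort(cfg.replace(seed=100 + seed))
            sga = classify_sga_cohort(cohort, curves).dropna()
            flags.append(sga.to_numpy(dtype=bool))
        rate = np.concatenate(flags).mean()
        assert rate == pytest.approx(0.10, abs=0.035)


class TestGenerateQpcr:
    def test_empty_subset_gives_valid_header(self, default_config, default_cohort):
        cohort, truth = default_cohort
        cq = generate_qpcr(cohort, truth, 0, default_config)
        assert list(cq.columns) == ["sample_id", "target", "cq", "efficiency"]
        assert len(cq) == 0

    def test_subset_larger_than_cohort_rejected(self, default_config, default_cohort):
        cohort, truth = default_cohort
        with pytest.raises(ValueError):
            generate_qpcr(cohort, truth, len(cohort) + 1, default_config)

    def test_noise_free_cq_inverts_to_planted_expression(self):
        cfg = SimulationConfig(seed=7, qpcr_noise_sd=0.0, qpcr_second_transcript_noise=0.0)
        cohort, truth = generate_cohort(cfg)
        cq = generate_qpcr(cohort, truth, 30, cfg)
        from cordmediate.qpcr_confirm import relative_quantify

        fc = relative_quantify(cq, ["GNB2L1", "RPLP0", "RPL13A"])
        ref = sorted(fc.index)[0]
        pos = cohort.index.get_indexer(fc.index)
        ref_pos = cohort.index.get_loc(ref)
        planted = truth.mediator_log2[pos] - truth.mediator_log2[ref_pos]
        assert np.allclose(fc["NM_001159920"].to_numpy(), planted, atol=1e-10)

    def test_extreme_mode_picks_exposure_tails(self, default_config, default_cohort):
        cohort, truth = default_cohort
        cq = generate_qpcr(cohort, truth, 30, default_config, mode="extremes")
        subset = cq["sample_id"].unique()
        as_sub = cohort.loc[subset, "as_cord_ugL"].sort_values()
        rest = cohort.drop(index=subset)["as_cord_ugL"]
        assert as_sub.iloc[:15].max() < rest.min()
        assert as_sub.iloc[15:].min() > rest.max()
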