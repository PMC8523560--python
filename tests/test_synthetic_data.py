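"""Generators: determinism, planted-effect arithmetic and round-trip identities."""

import numpy as np
import pandas as pd
import pytest

from azasynergy import (
    MedianEffectFit,
    ProteomeSimConfig,
    ScreenSimConfig,
    SlamSimConfig,
    call_affected,
    combination_index,
    filter_protein_groups,
    fit_median_effect,
    gen_combination,
    gen_dose_response,
    gen_protein_groups,
    gen_screen_counts,
    gen_slamseq_counts,
    viability_to_fa,
)


class TestScreenGenerator:
    def test_deterministic_given_seed(self):
        cfg = ScreenSimConfig(n_genes=15, seed=42)
        m1, t1 = gen_screen_counts(cfg)
        m2, t2 = gen_screen_counts(cfg)
        pd.testing.assert_frame_equal(m1.counts, m2.counts)
        pd.testing.assert_frame_equal(t1, t2)

    def test_adding_genes_preserves_existing_counts(self):
        # planted fractions pinned to 0 so only the RNG sub-streams are probed
        small, _ = gen_screen_counts(
            ScreenSimConfig(n_genes=10, frac_depleted=0, frac_enriched=0, seed=9)
        )
        big, _ = gen_screen_counts(
            ScreenSimConfig(n_genes=20, frac_depleted=0, frac_enriched=0, seed=9)
        )
        # first 10 genes draw from the same per-gene sub-streams
        np.testing.assert_array_equal(
            small.counts.to_numpy(), big.counts.to_numpy()[: len(small.counts)]
        )

    def test_planted_ratio_recovered_by_recount(self):
        """Mean treated/control ratio of planted shRNAs within 10% of 2^-2,
        checked by an independent recount of the emitted matrix."""
        cfg = ScreenSimConfig(
            n_genes=20,
            frac_depleted=0.2,
            frac_enriched=0.0,
            effect_log2fc=2.0,
            frac_active_shrnas=1.0,
            baseline_mean=500.0,
            seed=7,
        )
        matrix, truth = gen_screen_counts(cfg)
        planted = truth.index[truth["label"] == "depleted"]
        rows = matrix.genes.isin(planted).to_numpy()
        ctrl = matrix.counts.loc[rows, matrix.sample_ids("control")].to_numpy()
        trt = matrix.counts.loc[rows, matrix.sample_ids("treated")].to_numpy()
        ratio = trt.mean() / ctrl.mean()
        assert ratio == pytest.approx(2.0**-2, rel=0.10)

    def test_column_sums_scale_with_baseline_mean(self):
        cfg1 = ScreenSimConfig(n_genes=150, baseline_mean=200.0, seed=3)
        cfg2 = ScreenSimConfig(n_genes=150, baseline_mean=600.0, seed=3)
        s1 = gen_screen_counts(cfg1)[0].counts.sum(axis=0).to_numpy()
        s2 = gen_screen_counts(cfg2)[0].counts.sum(axis=0).to_numpy()
        np.testing.assert_allclose(s2 / s1, 3.0, rtol=0.05)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            ScreenSimConfig(baseline_mean=0.0)
        with pytest.raises(ValueError):
            ScreenSimConfig(baseline_mean=float("nan"))
        with pytest.raises(ValueError):
            ScreenSimConfig(frac_depleted=0.7, frac_enriched=0.7)
        with pytest.raises(ValueError):
            ScreenSimConfig(dispersion=0.0)


class TestDoseResponseGenerator:
    def test_half_effect_at_median_dose(self):
        df = gen_dose_response(m=2.3, Dm=1.7, doses=[1.7], n_replicates=1, noise_sd=0)
        assert df["pct_live"].iloc[0] == pytest.approx(50.0)

    def test_closed_form_fraction_affected(self):
        # m=1, Dm=1, D=3 -> fa = 3/4 -> 25% live
        df = gen_dose_response(m=1.0, Dm=1.0, doses=[3.0], n_replicates=1, noise_sd=0)
        assert df["pct_live"].iloc[0] == pytest.approx(25.0)

    def test_noise_free_round_trip_recovers_parameters(self):
        m_true, dm_true = 1.8, 0.4
        df = gen_dose_response(
            m=m_true, Dm=dm_true, doses=[0.1, 0.2, 0.4, 0.8, 1.6], n_replicates=2, noise_sd=0
        )
        df["fa"] = 1 - df["pct_live"] / 100.0
        fit = fit_median_effect(df, "d")
        assert fit.m == pytest.approx(m_true, abs=1e-9)
        assert fit.Dm == pytest.approx(dm_true, abs=1e-9)

    def test_noise_truncated_to_physical_bounds(self):
        df = gen_dose_response(
            m=1.0, Dm=1.0, doses=[0.001, 1000.0], n_replicates=50, noise_sd=30.0, seed=1
        )
        assert df["pct_live"].between(0, 100).all()

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            gen_dose_response(m=0, Dm=1, doses=[1])
        with pytest.raises(ValueError):
            gen_dose_response(m=1, Dm=1, doses=[-1])


class TestCombinationGenerator:
    def test_sham_combination_matches_double_dose_effect(self):
        fit = MedianEffectFit("d", 1.6, 0.9, 1.0, 5)
        for d in (0.2, 0.9, 2.0):
            combo = gen_combination(fit, fit, [(d, d)], target_ci=1.0)
            fa_2d = (2 * d / 0.9) ** 1.6 / (1 + (2 * d / 0.9) ** 1.6)
            assert combo["fa_true"].iloc[0] == pytest.approx(fa_2d, abs=1e-9)

    def test_closed_form_pair(self):
        # DxA = 1, DxB = 2 at fa = 0.5: 0.5/1 + 0.5/2 = 0.75
        a = MedianEffectFit("a", 1.0, 1.0, 1.0, 5)
        b = MedianEffectFit("b", 1.0, 2.0, 1.0, 5)
        combo = gen_combination(a, b, [(0.5, 0.5)], target_ci=0.75)
        assert combo["fa_true"].iloc[0] == pytest.approx(0.5, abs=1e-9)

    def test_round_trip_recovers_target_ci(self, rng):
        for _ in range(20):
            a = MedianEffectFit("a", rng.uniform(0.5, 3), rng.uniform(0.2, 5), 1.0, 5)
            b = MedianEffectFit("b", rng.uniform(0.5, 3), rng.uniform(0.2, 5), 1.0, 5)
            target = rng.uniform(0.3, 1.8)
            pairs = [(rng.uniform(0.05, 2), rng.uniform(0.05, 2)) for _ in range(4)]
            combo = gen_combination(a, b, pairs, target_ci=target)
            for _, row in combo.iterrows():
                res = combination_index(
                    a, b, row.dose_a_um, row.dose_b_um, row.fa_true
                )
                assert res.ci == pytest.approx(target, abs=1e-6)

    def test_invalid_target_rejected(self):
        fit = MedianEffectFit("d", 1.0, 1.0, 1.0, 5)
        with pytest.raises(ValueError):
            gen_combination(fit, fit, [(1, 1)], target_ci=0.0)


class TestSlamseqGenerator:
    def test_deterministic_given_seed(self):
        cfg = SlamSimConfig(n_genes=8, seed=5)
        t1, _ = gen_slamseq_counts(cfg)
        t2, _ = gen_slamseq_counts(cfg)
        pd.testing.assert_frame_equal(t1, t2)

    def test_unlabelled_conversion_tail_matches_binomial(self):
        """With no labelled reads, the k>=2 fraction equals the background
        binomial tail 1-(1-p)^n - n p (1-p)^(n-1)."""
        cfg = SlamSimConfig(
            n_genes=40,
            utrs_per_gene=1,
            reads_per_utr_mean=2000.0,
            frac_labeled=0.0,
            p_conversion_background=0.01,
            p_conversion_labeled=0.05,
            seed=2,
        )
        table, _ = gen_slamseq_counts(cfg)
        n, p = cfg.n_t_sites, cfg.p_conversion_background
        expected = 1 - (1 - p) ** n - n * p * (1 - p) ** (n - 1)
        observed = table.loc[table["k"] >= 2, "n_reads"].sum() / table["n_reads"].sum()
        assert observed == pytest.approx(expected, rel=0.15)

    def test_degenerate_probabilities_saturate_conversions(self):
        cfg = SlamSimConfig(
            n_genes=3,
            utrs_per_gene=1,
            reads_per_utr_mean=100.0,
            frac_labeled=1.0,
            p_conversion_labeled=1.0,
            p_conversion_background=0.0,
            seed=1,
        )
        table, _ = gen_slamseq_counts(cfg)
        assert (table["k"] == cfg.n_t_sites).all()

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError):
            SlamSimConfig(p_conversion_background=0.5, p_conversion_labeled=0.1)
        with pytest.raises(ValueError):
            SlamSimConfig(frac_labeled=1.5)


class TestProteomeGenerator:
    def test_deterministic_given_seed(self):
        cfg = ProteomeSimConfig(n_proteins=30, seed=8)
        r1, _ = gen_protein_groups(cfg)
        r2, _ = gen_protein_groups(cfg)
        pd.testing.assert_frame_equal(r1, r2)

    def test_all_reverse_filters_to_nothing(self):
        cfg = ProteomeSimConfig(
            n_proteins=50, frac_reverse=1.0, frac_contaminant=0.0, frac_onlysite=0.0, seed=1
        )
        records, _ = gen_protein_groups(cfg)
        result = filter_protein_groups(records)
        assert len(result.retained) == 0

    def test_clean_config_recovers_planted_fraction(self):
        cfg = ProteomeSimConfig(
            n_proteins=600,
            frac_contaminant=0.0,
            frac_reverse=0.0,
            frac_onlysite=0.0,
            frac_background=0.0,
            psm_mean=50.0,
            frac_affected=0.3,
            reduction_factor=0.1,
            seed=6,
        )
        records, truth = gen_protein_groups(cfg)
        result = filter_protein_groups(records)
        assert len(result.retained) >= 0.99 * len(records)
        call_affected(result, records)
        frac_called = len(result.affected) / len(result.retained)
        assert frac_called == pytest.approx(0.3, abs=0.05)
        # direction of calls matches the planted truth
        assert set(result.affected) <= set(truth.index[truth["affected"]])

    def test_null_reduction_false_calls_match_poisson_oracle(self, rng):
        """With reduction_factor=1 the 75% rule only fires on Poisson noise;
        the observed rate must match a Monte-Carlo oracle on raw Poisson
        draws within a factor of 2 (both rates are tiny)."""
        psm_mean, n_reps = 10.0, 3
        cfg = ProteomeSimConfig(
            n_proteins=4000,
            frac_contaminant=0.0,
            frac_reverse=0.0,
            frac_onlysite=0.0,
            frac_background=0.0,
            psm_mean=psm_mean,
            frac_affected=0.5,
            reduction_factor=1.0,
            seed=13,
        )
        records, _ = gen_protein_groups(cfg)
        result = call_affected(filter_protein_groups(records), records)
        observed_rate = len(result.affected) / len(result.retained)

        # independent Monte-Carlo oracle on the same Poisson null
        n_mc = 200_000
        dmso = rng.poisson(psm_mean, size=(n_mc, n_reps))
        trt = rng.poisson(psm_mean, size=(n_mc, n_reps))
        ok = (dmso > 0).all(axis=1)
        red = 1 - trt[ok].mean(axis=1) / dmso[ok].mean(axis=1)
        oracle_rate = (red >= 0.75).mean()
        assert observed_rate <= max(2 * oracle_rate, 2e-3)
        assert oracle_rate <= max(2 * observed_rate, 2e-3)
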