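import math

import numpy as np
import pandas as pd
import pytest

from itraqstat import (
    SimDesign,
    anova_across_workflows,
    cv_distribution,
    cv_vs_spectral_count,
    generate_psm_table,
    log2_sd_distribution,
    quantify_proteins,
    summarize_variation,
    technical_cv,
    workflow_cv,
)
from itraqstat.replicate_stats import cohort_summary, consistent_fraction


def quant_frame(rows):
    """Tidy quant rows: (protein, wr, tr, channel, ratio[, sc])."""
    return pd.DataFrame(
        [
            {
                "protein_id": pid,
                "workflow_rep": wr,
                "technical_rep": tr,
                "spectral_count": sc,
                "channel": ch,
                "ratio": r,
                "n_peptide_ratios": sc,
            }
            for (pid, wr, tr, ch, r, sc) in rows
        ]
    )


def single_channel_quants(ratios_by_wr, pid="P1", ch=115, sc=10):
    rows = []
    for wr, ratios in ratios_by_wr.items():
        for tr, r in enumerate(ratios, start=1):
            rows.append((pid, wr, tr, ch, r, sc))
    return quant_frame(rows)


class TestWorkflowCv:
    def test_constant_ratios_zero_cv(self):
        q = single_channel_quants({1: [1.0], 2: [1.0], 3: [1.0]})
        out = workflow_cv(q)
        assert out["cv"].iloc[0] == 0.0

    def test_hand_computed_cv(self):
        # per-workflow means 0.9, 1.0, 1.1 -> sample SD 0.1, mean 1.0
        q = single_channel_quants({1: [0.9], 2: [1.0], 3: [1.1]})
        assert workflow_cv(q)["cv"].iloc[0] == pytest.approx(0.1, rel=1e-12)

    def test_technical_reps_averaged_before_cv(self):
        q = single_channel_quants({1: [0.8, 1.0], 2: [1.0, 1.0], 3: [1.2, 1.0]})
        assert workflow_cv(q)["cv"].iloc[0] == pytest.approx(0.1, rel=1e-12)

    def test_min_workflow_reps_excludes(self):
        q = single_channel_quants({1: [1.0]})
        assert workflow_cv(q, min_workflow_reps=2).empty

    def test_cv_scale_invariant(self):
        q = single_channel_quants({1: [0.9, 1.1], 2: [1.3], 3: [0.7, 1.0, 1.2]})
        q2 = q.assign(ratio=q["ratio"] * 7.3)
        assert workflow_cv(q2)["cv"].iloc[0] == pytest.approx(
            workflow_cv(q)["cv"].iloc[0], rel=1e-12
        )

    def test_replicate_relabeling_invariant(self):
        q = single_channel_quants({1: [0.9, 1.1], 2: [1.3, 0.8], 3: [1.0, 1.2]})
        relabeled = q.assign(workflow_rep=q["workflow_rep"].map({1: 3, 2: 1, 3: 2}))
        assert workflow_cv(relabeled)["cv"].iloc[0] == pytest.approx(
            workflow_cv(q)["cv"].iloc[0], rel=1e-12
        )


class TestTechnicalCv:
    def test_identical_runs_zero_cv(self):
        q = single_channel_quants({1: [2.0, 2.0]})
        assert technical_cv(q)["cv"].iloc[0] == 0.0

    def test_hand_computed_cv(self):
        # {1.0, 2.0}: SD = sqrt(2)/2, mean = 1.5 -> CV ~= 0.4714
        q = single_channel_quants({1: [1.0, 2.0]})
        assert technical_cv(q)["cv"].iloc[0] == pytest.approx(
            math.sqrt(2) / 2 / 1.5, rel=1e-12
        )

    def test_single_run_excluded(self):
        q = single_channel_quants({1: [1.0]})
        assert technical_cv(q).empty

    def test_parameter_recovery_quick(self):
        design = SimDesign(n_proteins=800, seed=23)
        quants = quantify_proteins(generate_psm_table(design))
        s_t = technical_cv(quants)["cv"].mean()
        assert s_t == pytest.approx(0.10, abs=0.02)


class TestCvDistribution:
    def test_quantile_conventions(self):
        dist = cv_distribution([0.1, 0.2, 0.3, 0.4])
        assert dist.quantile(0.75, mode="linear") == pytest.approx(0.325)
        assert dist.quantile(0.75, mode="nearest_rank") == pytest.approx(0.3)

    def test_all_equal_cvs(self):
        dist = cv_distribution([0.2, 0.2, 0.2])
        for q in (0.1, 0.5, 0.9):
            assert dist.quantile(q) == 0.2

    def test_uniform_sample_quantile(self):
        rng = np.random.default_rng(4)
        dist = cv_distribution(rng.uniform(0, 1, 1000))
        assert dist.quantile(0.9) == pytest.approx(0.9, abs=0.05)

    def test_fraction_below_inverts_quantile(self):
        rng = np.random.default_rng(5)
        dist = cv_distribution(rng.uniform(0, 1, 500))
        thr = dist.quantile(0.75)
        assert dist.fraction_below(thr) == pytest.approx(0.75, abs=0.01)

    def test_histogram_counts_sum(self):
        dist = cv_distribution([0.01, 0.02, 0.3, 0.55])
        assert dist.counts.sum() == 4


class TestCvVsSpectralCount:
    def test_direct_bin_assignment(self):
        table = pd.DataFrame({"cv": [0.1, 0.3], "total_sc": [100, 2]})
        out = cv_vs_spectral_count(table, [0, 10, 1000])
        assert out["mean_cv"].tolist() == [0.3, 0.1]

    def test_single_bin_is_overall_mean(self):
        table = pd.DataFrame({"cv": [0.1, 0.2, 0.6], "total_sc": [5, 50, 500]})
        out = cv_vs_spectral_count(table, [0, 1000])
        assert out["mean_cv"].iloc[0] == pytest.approx(0.3)

    def test_noisier_low_count_proteins_give_negative_trend(self):
        # spectrum-level noise dominates at low SC -> CV falls with SC
        design = SimDesign(
            n_proteins=600, seed=31, s_b=0.02, s_t=0.02, s_psm=0.5
        )
        quants = quantify_proteins(generate_psm_table(design))
        wcv = workflow_cv(quants)
        from scipy.stats import spearmanr

        rho = spearmanr(wcv["total_sc"], wcv["cv"]).statistic
        assert rho < -0.1


class TestLog2Sd:
    def test_constant_ratios(self):
        q = single_channel_quants({1: [2.0], 2: [2.0], 3: [2.0]})
        assert log2_sd_distribution(q)["sd_log2"].iloc[0] == 0.0

    def test_hand_computed(self):
        q = single_channel_quants({1: [1.0], 2: [4.0]})
        assert log2_sd_distribution(q)["sd_log2"].iloc[0] == pytest.approx(
            math.sqrt(2), rel=1e-12
        )

    def test_delta_method_limit(self):
        # SD(log2 r) ~= CV/ln2 for small CV
        rng = np.random.default_rng(6)
        cv = 0.04
        rows = {}
        sigma = math.sqrt(math.log1p(cv * cv))
        for wr in (1, 2, 3, 4, 5, 6, 7, 8):
            rows[wr] = [float(np.exp(rng.normal(0, sigma)))]
        q = single_channel_quants(rows)
        sd = log2_sd_distribution(q)["sd_log2"].iloc[0]
        observed_cv = workflow_cv(q)["cv"].iloc[0]
        assert sd == pytest.approx(observed_cv / math.log(2), rel=0.05)


class TestAnova:
    def test_identical_groups_consistent_by_convention(self):
        q = single_channel_quants({1: [1.0, 1.0], 2: [1.0, 1.0], 3: [1.0, 1.0]})
        out = anova_across_workflows(q)
        assert out["p_value"].iloc[0] == 1.0
        assert bool(out["consistent"].iloc[0])

    def test_zero_variance_different_means_inconsistent(self):
        q = single_channel_quants({1: [1.0, 1.0], 2: [2.0, 2.0]})
        out = anova_across_workflows(q)
        assert out["p_value"].iloc[0] == 0.0

    def test_extreme_separation_rejected(self):
        q = single_channel_quants({1: [1.0, 1.0, 1.0], 2: [5.0, 5.0, 5.0001]})
        out = anova_across_workflows(q)
        assert out["p_value"].iloc[0] < 0.05
        assert not bool(out["consistent"].iloc[0])

    def test_matches_statsmodels_oracle(self):
        # independent route: ordinary least squares ANOVA table
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        rng = np.random.default_rng(7)
        ratios = {wr: list(rng.lognormal(0, 0.1, size=3)) for wr in (1, 2, 3)}
        q = single_channel_quants(ratios)
        p_ours = anova_across_workflows(q)["p_value"].iloc[0]
        df = pd.DataFrame(
            [(wr, r) for wr, rs in ratios.items() for r in rs],
            columns=["wr", "ratio"],
        )
        fit = ols("ratio ~ C(wr)", data=df).fit()
        p_sm = sm.stats.anova_lm(fit, typ=1)["PR(>F)"].iloc[0]
        assert p_ours == pytest.approx(p_sm, rel=1e-9)

    def test_insufficient_replication_skipped(self):
        q = single_channel_quants({1: [1.0, 1.1], 2: [1.2]})
        assert anova_across_workflows(q).empty

    def test_consistent_fraction(self):
        q = pd.concat(
            [
                single_channel_quants({1: [1.0, 1.0], 2: [1.0, 1.0]}, pid="A"),
                single_channel_quants({1: [1.0, 1.0], 2: [9.0, 9.0]}, pid="B"),
            ]
        )
        out = anova_across_workflows(q)
        assert consistent_fraction(out) == 0.5


class TestVarianceSummary:
    def test_generator_consistency(self):
        # RMS workflow CV ~= sqrt(s_b^2 + s_t^2/m) on generator output
        design = SimDesign(n_proteins=2000, seed=41)
        quants = quantify_proteins(generate_psm_table(design))
        wcv = workflow_cv(quants)
        rms = math.sqrt(np.mean(wcv["cv"] ** 2))
        predicted = math.sqrt(design.s_b**2 + design.s_t**2 / design.n_technical_reps)
        assert rms == pytest.approx(predicted, rel=0.10)

    def test_summary_fields(self, small_sim_psms):
        quants = quantify_proteins(small_sim_psms)
        s = summarize_variation(quants)
        assert set(s.per_channel_cv) == {115, 116, 117}
        assert s.s_b > 0 and s.s_t > 0
        qs = s.cumulative_cv_quantiles
        assert qs[0.5] <= qs[0.75] <= qs[0.9]  # monotone quantile map
        assert all("quantified" in k for k in s.n_proteins_used)

    def test_two_replicate_cohort_noisier_under_coupled_dropout(self):
        design = SimDesign(
            n_proteins=1500,
            seed=43,
            s_psm=0.5,
            detection_prob=0.75,
            detection_abundance_slope=0.35,
        )
        quants = quantify_proteins(generate_psm_table(design))
        cs = cohort_summary(quants)
        two = cs[cs["n_workflow_reps"] == 2]["mean_cv"].mean()
        three = cs[cs["n_workflow_reps"] == 3]["mean_cv"].mean()
        assert three <= two
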