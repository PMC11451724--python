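"""DR/AL pair grid, Bonferroni tallies, and cross-lab correlations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from drlifespan import (
    DietPairAnalysis,
    PairResult,
    bonferroni_threshold,
    cross_lab_correlation,
    delta_correlation,
    lab_summary_correlation,
    pair_grid,
    simulate_dataset,
    summarize_pairs,
)
from drlifespan.fixtures import STUDY_FLIES_PER_LAB, load_table3, table3_pair_results


class TestBonferroni:
    def test_study_grid_threshold(self):
        thr = bonferroni_threshold(0.05, 64)
        assert thr == 0.00078125
        assert float(f"{thr:.2g}") == 0.00078

    @pytest.mark.parametrize("alpha,m,expected", [(0.05, 1, 0.05), (0.05, 10, 0.005)])
    def test_direct_division(self, alpha, m, expected):
        assert bonferroni_threshold(alpha, m) == pytest.approx(expected)

    def test_monotone_decreasing_in_m(self):
        thrs = [bonferroni_threshold(0.05, m) for m in (1, 2, 8, 64, 640)]
        assert all(b < a for a, b in zip(thrs, thrs[1:]))

    def test_contracts(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)
        with pytest.raises(ValueError):
            bonferroni_threshold(1.5, 10)


class TestPublishedGrid:
    """Tallies recomputed from the packaged 64-pair log-rank fixture."""

    @pytest.fixture(scope="module")
    def summary(self):
        return summarize_pairs(table3_pair_results(), alpha=0.05)

    def test_grid_shape(self):
        df = load_table3()
        assert len(df) == 64
        assert df.groupby(["lab", "cohort"]).size().eq(8).all()

    def test_significant_counts(self, summary):
        assert summary.n_significant_dr == 17
        assert summary.n_significant_al == 5
        assert summary.bonferroni_threshold == 0.00078125

    def test_oregon_r_nominal_tally(self, summary):
        assert summary.nominal_counts["genotype"]["Oregon-R"] == 12

    def test_second_lab_protocol2_cohort(self):
        results = [r for r in table3_pair_results()
                   if r.lab == "lab2" and r.cohort == "4"]
        assert len(results) == 8
        thr = bonferroni_threshold(0.05, 64)
        dr = sum(r.p_value <= thr and r.direction == "DR" for r in results)
        assert dr == 4

    def test_wdahomey_males_never_significant(self):
        thr = bonferroni_threshold(0.05, 64)
        rows = [r for r in table3_pair_results()
                if r.genotype == "wDahomey" and r.sex == "M"]
        assert len(rows) == 8  # 2 labs x 4 cohorts
        assert sum(r.p_value <= thr for r in rows) == 0

    def test_rollups_sum_to_global(self, summary):
        total = summary.n_significant_dr + summary.n_significant_al
        for roll in (summary.per_genotype, summary.per_sex,
                     summary.per_lab, summary.per_cohort):
            assert sum(roll.values()) == total

    def test_study_scale_constants(self):
        assert sum(STUDY_FLIES_PER_LAB.values()) == 15_935


class TestPairGrid:
    def test_identical_arms_give_p_one_and_no_direction(self):
        times = [3.0, 5.0, 8.0, 12.0, 20.0]
        rows = []
        for diet in ("DR", "AL"):
            for i, t in enumerate(times):
                rows.append(dict(lab="lab1", cohort="1", genotype="w1118",
                                 sex="F", diet=diet, time_days=t, event=1))
        res = pair_grid(pd.DataFrame(rows))
        assert len(res) == 1
        r = res[0]
        assert r.p_value == pytest.approx(1.0)
        assert r.direction == "none"
        assert r.delta_l == 0.0

    def test_all_censored_arm_not_computable(self):
        rows = [dict(lab="lab1", cohort="1", genotype="w1118", sex="F",
                     diet="DR", time_days=t, event=0) for t in (5.0, 6.0)]
        rows += [dict(lab="lab1", cohort="1", genotype="w1118", sex="F",
                      diet="AL", time_days=t, event=1) for t in (5.0, 6.0)]
        r = pair_grid(pd.DataFrame(rows))[0]
        assert np.isnan(r.p_value)
        assert r.direction == "none"

    def test_missing_arm_skipped_with_warning(self, caplog):
        rows = [dict(lab="lab1", cohort="1", genotype="w1118", sex="F",
                     diet="DR", time_days=5.0, event=1)]
        with caplog.at_level("WARNING"):
            res = pair_grid(pd.DataFrame(rows))
        assert res == []
        assert "missing a diet arm" in caplog.text

    def test_direction_antisymmetric_under_diet_swap(self, small_sim):
        base = pair_grid(small_sim)
        swapped_df = small_sim.copy()
        swapped_df["diet"] = swapped_df["diet"].map({"DR": "AL", "AL": "DR"})
        swapped = pair_grid(swapped_df)
        flip = {"DR": "AL", "AL": "DR", "none": "none"}
        for a, b in zip(base, swapped):
            assert a.stratum == b.stratum
            assert b.direction == flip[a.direction]
            if np.isfinite(a.delta_l):
                assert b.delta_l == pytest.approx(-a.delta_l)
            assert b.p_value == pytest.approx(a.p_value, abs=1e-12)

    def test_effect_localised_to_one_genotype(self):
        # diet helps only Oregon-R; significant pairs should concentrate there
        hits_or, hits_other = 0, 0
        for seed in range(12):
            # null generator, then a DR lifespan benefit applied to Oregon-R only
            df = simulate_dataset(
                seed=seed, flies_per_cell=40, cohort_frailty_sd=0.0,
                censor_rate=0.0, beta={},
            )
            scale = np.where(
                (df.genotype == "Oregon-R") & (df.diet == "DR"), 1.25, 1.0
            )
            df = df.assign(time_days=df.time_days * scale)
            for r in pair_grid(df):
                if r.p_value < 0.01:
                    if r.genotype == "Oregon-R":
                        hits_or += 1
                    else:
                        hits_other += 1
        assert hits_or > 5 * max(hits_other, 1)


class TestSummaries:
    def test_counts_are_pure_function_of_p_and_direction(self):
        results = [
            PairResult("lab1", "1", "g", "F", 1e-5, "DR"),
            PairResult("lab1", "1", "g", "M", 1e-5, "AL"),
            PairResult("lab1", "2", "g", "F", 0.04, "DR"),
            PairResult("lab1", "2", "g", "M", 0.9, "none"),
        ]
        s = summarize_pairs(results, alpha=0.05)
        assert s.bonferroni_threshold == 0.0125
        assert s.n_significant_dr == 1 and s.n_significant_al == 1
        assert s.nominal_counts["sex"] == {"F": 2, "M": 1}

    def test_empty_results_rejected(self):
        with pytest.raises(ValueError):
            summarize_pairs([])


class TestCorrelations:
    def test_perfect_concordance_and_discordance(self):
        x = np.arange(10.0)
        assert cross_lab_correlation(x, x).rho == pytest.approx(1.0)
        assert cross_lab_correlation(x, x[::-1]).rho == pytest.approx(-1.0)

    def test_ties_match_rank_then_pearson_oracle(self):
        x = np.array([3.0, 1.0, 4.0, 1.0, 5.0, 9.0, 2.0, 6.0, 5.0, 3.5])
        y = np.array([2.0, 7.0, 1.0, 8.0, 2.0, 8.0, 1.0, 9.0, 0.5, 6.0])
        res = cross_lab_correlation(x, y)
        rx, ry = stats.rankdata(x), stats.rankdata(y)  # average ranks
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert res.rho == pytest.approx(oracle, abs=1e-12)
        t = oracle * np.sqrt((10 - 2) / (1 - oracle**2))
        assert res.p_value == pytest.approx(2 * stats.t.sf(abs(t), 8), abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            cross_lab_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            cross_lab_correlation([1.0, 2.0], [1.0, 2.0])

    def test_delta_duplicated_lab_gives_rho_one(self, small_sim):
        grid = pair_grid(small_sim)
        lab1 = [r for r in grid if r.lab == "lab1"]
        res = delta_correlation(lab1, lab1)
        assert res.rho == pytest.approx(1.0)

    def test_delta_unmatched_strata_dropped_with_warning(self, small_sim, caplog):
        grid = pair_grid(small_sim)
        lab1 = [r for r in grid if r.lab == "lab1"]
        lab2 = [r for r in grid if r.lab == "lab2"]
        with caplog.at_level("WARNING"):
            res = delta_correlation(lab1, lab2[:-3])
        assert res.n == len(lab2) - 3
        assert "unmatched" in caplog.text

    def test_lab_median_correlation_positive_on_default_sim(self, small_sim):
        # shared genotype/sex/cohort effects should dominate the scatter
        res = lab_summary_correlation(small_sim)
        assert res.n == 64
        assert res.rho > 0.5 and res.p_value < 1e-3
        # mean-longevity variant runs and is also strongly positive
        assert lab_summary_correlation(small_sim, summary="mean").rho > 0.5


def test_model_style_wrapper_summary(small_sim):
    res = DietPairAnalysis(small_sim).fit()
    assert res.pair_summary.n_pairs == 64
    text = res.summary()
    assert "64 pairs" in text
    assert "cross-lab longevity correlation" in text
    frame = res.as_frame()
    assert len(frame) == 64 and "delta_l" in frame.columns
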