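from itertools import combinations, permutations, product

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from dfhm.stats import (
    bonferroni_posthoc,
    dunn_bonferroni,
    friedman_test,
    log_transform,
    median_split,
    mixed_anova,
    shapiro_gate,
    signed_rank_z,
    wilcoxon_signed_rank,
)


class TestShapiroGate:
    def test_detects_heavy_tails(self):
        rng = np.random.default_rng(1)
        hits = sum(
            shapiro_gate(rng.standard_cauchy(21))[0] == "non-normal"
            for _ in range(100)
        )
        assert hits >= 80

    def test_size_under_normality(self):
        rng = np.random.default_rng(2)
        hits = sum(
            shapiro_gate(rng.standard_normal(21))[0] == "normal" for _ in range(100)
        )
        assert 88 <= hits <= 100  # nominal 95%

    def test_small_and_degenerate_samples_rejected(self):
        with pytest.raises(ValueError):
            shapiro_gate([1.0, 2.0])
        with pytest.raises(ValueError):
            shapiro_gate([3.0] * 10)


class TestLogTransform:
    def test_known_values(self):
        np.testing.assert_allclose(
            log_transform([1.0, np.e, np.e**2]), [0.0, 1.0, 2.0]
        )

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            log_transform([1.0, 0.0])

    def test_normalizes_lognormal_planning_times(self):
        """Log-normal planning times pass the normality gate after the log
        transform in >= 90% of seeded replicates at n = 21."""
        rng = np.random.default_rng(3)
        hits = 0
        for _ in range(100):
            pt = rng.lognormal(np.log(18.0), 0.6, size=21)
            hits += shapiro_gate(log_transform(pt))[0] == "normal"
        assert hits >= 90


class TestWilcoxon:
    def test_z_matches_published_convention(self):
        # T = 26 over n = 21 pairs → z = −3.11, r = |z|/√42 = 0.48
        z = signed_rank_z(26.0, 21)
        assert round(z, 2) == -3.11
        assert round(abs(z) / np.sqrt(42), 2) == 0.48

    def test_full_report_on_synthetic_pairs(self):
        rng = np.random.default_rng(4)
        a = rng.normal(57.5, 6.0, 21)
        b = a + rng.normal(5.0, 4.0, 21)
        rep = wilcoxon_signed_rank(a, b)
        assert rep.p < 0.05
        assert 0 <= rep.effect_size <= 1
        assert rep.extras["n_pairs"] == 21

    def test_matches_scipy_approximation(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0, 1, 30)
        b = a + rng.normal(0.3, 1, 30)
        rep = wilcoxon_signed_rank(a, b)
        ref = sps.wilcoxon(b, a, method="approx", correction=False)
        assert rep.statistic == pytest.approx(ref.statistic)
        assert abs(rep.extras["z"]) == pytest.approx(abs(ref.zstatistic), abs=1e-9)
        assert rep.p == pytest.approx(ref.pvalue, abs=1e-9)

    def test_normal_approximation_close_to_exact_enumeration(self):
        """At n = 8 the normal-approximation p is within 0.05 of the exact p
        from enumerating all 2^8 sign assignments, in the decision-relevant
        regime of a real paired shift."""
        rng = np.random.default_rng(6)
        for _ in range(5):
            d = rng.normal(0.8, 1.0, 8)
            while np.any(d == 0):
                d = rng.normal(0.4, 1.0, 8)
            rep = wilcoxon_signed_rank(np.zeros(8), d)
            ranks = sps.rankdata(np.abs(d))
            T_obs = rep.statistic
            count = 0
            total = 2**8
            for signs in product([0, 1], repeat=8):
                r_plus = sum(r for r, s in zip(ranks, signs) if s)
                T = min(r_plus, ranks.sum() - r_plus)
                if T <= T_obs:
                    count += 1
            p_exact = count / total
            assert abs(rep.p - p_exact) < 0.05

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([1.0] * 6, [1.0] * 6)  # all differences zero


class TestMedianSplit:
    def test_21_distinct_scores_split_10_11(self):
        rng = np.random.default_rng(7)
        scores = rng.choice(np.arange(20, 70), size=21, replace=False)
        labels, med = median_split(scores)
        assert (labels == "lower").sum() == 10
        assert (labels == "higher").sum() == 11

    def test_tie_at_median_goes_higher(self):
        labels, med = median_split([40, 43, 50])
        assert med == 43
        assert labels.tolist() == ["lower", "higher", "higher"]

    def test_constant_scores_warn(self):
        with pytest.warns(UserWarning, match="empty lower"):
            labels, _ = median_split([5, 5, 5])
        assert (labels == "higher").all()

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            median_split([])


def make_mixed_table(n_subjects=21, k=3, seed=0, effect=0.0):
    rng = np.random.default_rng(seed)
    rows = []
    groups = ["lower"] * (n_subjects // 2) + ["higher"] * (n_subjects - n_subjects // 2)
    for s in range(n_subjects):
        base = rng.normal(60, 5)
        for j in range(k):
            shift = effect * j if groups[s] == "higher" else 0.0
            rows.append(
                {
                    "subject": s,
                    "group": groups[s],
                    "condition": f"c{j}",
                    "value": base + shift + rng.normal(0, 3),
                }
            )
    return pd.DataFrame(rows)


class TestMixedANOVA:
    def test_interaction_df_for_study_design(self):
        rep = mixed_anova(make_mixed_table(21, 3, seed=1))
        assert rep.df == (2, 38)
        assert rep.extras["effects"]["within"]["df"] == (2, 38)
        assert rep.extras["effects"]["between"]["df"] == (1, 19)

    def test_partial_eta_squared_identity(self):
        rep = mixed_anova(make_mixed_table(21, 3, seed=2))
        F = rep.statistic
        df1, df2 = rep.df
        assert rep.effect_size == pytest.approx(F * df1 / (F * df1 + df2), rel=1e-9)

    def test_hand_computed_tiny_dataset(self):
        """4 subjects × 2 groups × 2 levels: every SS term equals the explicit
        mean-decomposition computed by hand."""
        y = np.array([[1.0, 3.0], [2.0, 6.0], [5.0, 5.0], [4.0, 8.0]])
        groups = np.array(["a", "a", "b", "b"])
        rows = [
            {"subject": s, "group": groups[s], "condition": f"c{j}", "value": y[s, j]}
            for s in range(4)
            for j in range(2)
        ]
        rep = mixed_anova(pd.DataFrame(rows))
        grand = y.mean()
        subj = y.mean(axis=1)
        ss_total = ((y - grand) ** 2).sum()
        ss_bs = 2 * ((subj - grand) ** 2).sum()
        ga, gb = y[:2].mean(), y[2:].mean()
        ss_group = 2 * (2 * (ga - grand) ** 2 + 2 * (gb - grand) ** 2)
        lvl = y.mean(axis=0)
        ss_cond = 4 * ((lvl - grand) ** 2).sum()
        cell_a, cell_b = y[:2].mean(axis=0), y[2:].mean(axis=0)
        ss_inter = 2 * (
            ((cell_a - ga - lvl + grand) ** 2).sum()
            + ((cell_b - gb - lvl + grand) ** 2).sum()
        )
        ss = rep.extras["ss"]
        assert ss["total"] == pytest.approx(ss_total, abs=1e-10)
        assert ss["between_subjects"] == pytest.approx(ss_bs, abs=1e-10)
        assert ss["group"] == pytest.approx(ss_group, abs=1e-10)
        assert ss["condition"] == pytest.approx(ss_cond, abs=1e-10)
        assert ss["interaction"] == pytest.approx(ss_inter, abs=1e-10)

    def test_sum_of_squares_identity_on_random_data(self):
        rep = mixed_anova(make_mixed_table(13, 4, seed=3, effect=1.0))
        ss = rep.extras["ss"]
        lhs = ss["total"]
        rhs = (
            ss["group"]
            + ss["error_between"]
            + ss["condition"]
            + ss["interaction"]
            + ss["error_within"]
        )
        assert lhs == pytest.approx(rhs, abs=1e-10)

    def test_matches_pingouin_on_balanced_data(self):
        pg = pytest.importorskip("pingouin")
        df = make_mixed_table(20, 3, seed=4, effect=2.0)
        rep = mixed_anova(df)
        ref = pg.mixed_anova(
            data=df, dv="value", within="condition", between="group", subject="subject"
        ).set_index("Source")
        eff = rep.extras["effects"]
        assert eff["between"]["F"] == pytest.approx(ref.loc["group", "F"], rel=1e-6)
        assert eff["within"]["F"] == pytest.approx(ref.loc["condition", "F"], rel=1e-6)
        assert eff["interaction"]["F"] == pytest.approx(
            ref.loc["Interaction", "F"], rel=1e-6
        )

    def test_incomplete_design_rejected(self):
        df = make_mixed_table(8, 3, seed=5)
        df = df.drop(index=df.index[0])
        with pytest.raises(ValueError, match="incomplete|every subject"):
            mixed_anova(df)


class TestBonferroniPosthoc:
    def test_adjustment_and_cap(self):
        # m = 3 comparisons for 3 levels
        df = make_mixed_table(10, 3, seed=6)
        table = bonferroni_posthoc(df)
        assert len(table) == 3
        assert np.all(table["p_adj"] >= table["p_raw"])
        assert np.all(table["p_adj"] <= 1.0)
        np.testing.assert_allclose(
            table["p_adj"], np.minimum(1.0, table["p_raw"] * 3)
        )

    def test_null_simulation_type_i_control(self):
        n_reps = 200
        hits = 0
        for rep in range(n_reps):
            df = make_mixed_table(12, 3, seed=100 + rep, effect=0.0)
            table = bonferroni_posthoc(df)
            hits += (table["p_adj"] < 0.05).any()
        # family-wise error controlled at 5%, within binomial noise
        assert hits / n_reps <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / n_reps)

    def test_single_level_rejected(self):
        df = make_mixed_table(6, 3, seed=7)
        with pytest.raises(ValueError):
            bonferroni_posthoc(df[df["condition"] == "c0"])


class TestFriedman:
    def test_df_is_levels_minus_one(self):
        rng = np.random.default_rng(8)
        rep = friedman_test(rng.normal(size=(10, 3)))
        assert rep.df == (2,)

    def test_identical_columns_give_zero(self):
        y = np.tile(np.arange(6, dtype=float)[:, None], (1, 3))
        rep = friedman_test(y)
        assert rep.statistic == 0.0
        assert rep.p == 1.0

    def test_matches_scipy_on_tie_free_data(self):
        rng = np.random.default_rng(13)
        y = rng.normal(size=(9, 4))
        rep = friedman_test(y)
        chi2, p = sps.friedmanchisquare(*(y[:, j] for j in range(4)))
        assert rep.statistic == pytest.approx(chi2, rel=1e-9)
        assert rep.p == pytest.approx(p, rel=1e-9)

    def test_exact_permutation_oracle_n5_k3(self):
        """The χ² approximation p is within 0.05 of the exact p from all
        (3!)^5 within-row permutations."""
        rng = np.random.default_rng(9)
        y = rng.normal(size=(5, 3)) + np.array([0.0, 0.5, 1.0])
        rep = friedman_test(y)
        perms = list(permutations(range(3)))
        stats = []
        for combo in product(perms, repeat=5):
            m = np.vstack([y[i, list(p)] for i, p in enumerate(combo)])
            stats.append(friedman_test(m).statistic)
        stats = np.asarray(stats)
        p_exact = (stats >= rep.statistic - 1e-12).mean()
        assert abs(rep.p - p_exact) < 0.05

    def test_missing_entries_rejected(self):
        y = np.ones((4, 3))
        y[0, 0] = np.nan
        with pytest.raises(ValueError):
            friedman_test(y)


class TestDunnBonferroni:
    def test_two_levels_single_comparison_no_adjustment(self):
        rng = np.random.default_rng(10)
        table = dunn_bonferroni(rng.normal(size=(8, 2)))
        assert len(table) == 1
        assert table["p_adj"].iloc[0] == pytest.approx(table["p_raw"].iloc[0])

    def test_null_familywise_error(self):
        rng = np.random.default_rng(11)
        hits = 0
        n_reps = 200
        for _ in range(n_reps):
            table = dunn_bonferroni(rng.normal(size=(10, 3)))
            hits += (table["p_adj"] < 0.05).any()
        rate = hits / n_reps
        assert rate <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / n_reps)

    def test_outlying_level_has_smallest_adjusted_p(self):
        rng = np.random.default_rng(12)
        y = rng.normal(size=(12, 3))
        y[:, 2] += 5.0  # one clearly shifted level
        table = dunn_bonferroni(y)
        involving = table[(table["level_a"] == 2) | (table["level_b"] == 2)]
        others = table[(table["level_a"] != 2) & (table["level_b"] != 2)]
        assert involving["p_adj"].max() <= others["p_adj"].min()


class TestParameterRecoveryPattern:
    def test_directional_pattern_over_replicates(self):
        """Cohorts drawn with the default group parameters show (a) a
        significant planning-task > memory-task workload contrast in most
        replicates, and (b) a learning-phase index decline concentrated in
        the higher-WM group."""
        from dfhm.cohort import CohortSpec, generate_cohort

        n_reps = 200
        sig_direction = 0
        decline_higher = 0
        decline_lower = 0
        for rep in range(n_reps):
            records = generate_cohort(CohortSpec(seed=5000 + rep))
            toh = np.array([r.index["toh_whole"] for r in records])
            aos = np.array([r.index["aospan_whole"] for r in records])
            w = wilcoxon_signed_rank(aos, toh)
            if w.p < 0.05 and toh.mean() > aos.mean():
                sig_direction += 1
            for grp, counter in (("higher", "h"), ("lower", "l")):
                sel = [r for r in records if r.wm_group == grp]
                first = np.mean([r.index["toh_learning_5"] for r in sel])
                last = np.mean([r.index["toh_learning_7"] for r in sel])
                if last < first:
                    if grp == "higher":
                        decline_higher += 1
                    else:
                        decline_lower += 1
        assert sig_direction > n_reps / 2
        assert decline_higher > decline_lower
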