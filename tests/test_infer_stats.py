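import itertools

import numpy as np
import pandas as pd
import pytest

from shamtrack.data_io import ParticipantSession
from shamtrack.infer_stats import (
    BONFERRONI_3,
    delta_rt,
    mixed_anova,
    paired_t,
    pearson_corr,
    repeated_anova_2x2,
    run_inferential_battery,
    sensitivity_rt_correlations,
    welch_t,
    wilcoxon_signed_rank,
)


def make_session(block_rts, pid="p1", cond="active"):
    rows = []
    for block, rts in block_rts.items():
        for j, rt in enumerate(rts):
            rows.append((block, j + 1, 1, float(rt)))
    # pad block 1 to the required 100 trials with correct=0 fillers
    n1 = len(block_rts.get(1, []))
    for j in range(n1, 100):
        rows.append((1, j + 1, 0, 500.0))
    return ParticipantSession(
        participant_id=pid, current_mA=2.0, condition=cond, session_order=1,
        responses=np.array(["yes"] * 32, dtype=object),
        confidence=np.full(32, 5.0),
        rt_trials=pd.DataFrame(rows, columns=["block", "trial_index", "correct", "rt_ms"]),
        side_effects={k: 1 for k in ("headache", "tingling", "itching", "burning", "pain")},
    )


class TestDeltaRT:
    def test_baseline_subtracted_per_block(self):
        s = make_session({1: [500] * 5, 2: [510] * 5, 3: [520] * 5, 4: [505] * 5})
        assert delta_rt(s) == {2: 10.0, 3: 20.0, 4: 5.0}

    def test_identical_blocks_give_zero(self):
        s = make_session({b: [480, 500, 520] for b in (1, 2, 3, 4)})
        assert delta_rt(s) == {2: 0.0, 3: 0.0, 4: 0.0}

    @pytest.mark.parametrize("rts", [[3.0, 1, 2], [4.0, 1, 3, 2]])
    def test_median_convention_matches_sort_oracle(self, rts):
        s = make_session({1: [0.0, 0.0], 2: rts, 3: [1.0], 4: [1.0]})
        srt = sorted(rts)
        n = len(srt)
        oracle = srt[n // 2] if n % 2 else (srt[n // 2 - 1] + srt[n // 2]) / 2
        assert delta_rt(s)[2] == oracle - 0.0

    def test_block_with_no_correct_trials_flagged_nan(self):
        s = make_session({1: [500] * 5, 2: [], 3: [510], 4: [520]})
        d = delta_rt(s)
        assert np.isnan(d[2]) and d[3] == 10.0


class TestTTests:
    def test_paired_identical_samples_degenerate(self):
        res = paired_t(np.arange(5.0), np.arange(5.0))
        assert res.statistic == 0.0 and res.p_value == 1.0 and res.degenerate

    def test_paired_hand_example(self):
        x = np.array([10.0, 12, 9, 11])
        y = np.array([9.0, 10, 9, 10])
        d = x - y  # [1, 2, 0, 1]; mean 1, sd sqrt(2/3)
        t_oracle = 1.0 / (np.sqrt(2 / 3) / 2)
        res = paired_t(x, y)
        assert res.statistic == pytest.approx(t_oracle, abs=1e-12)
        assert res.effect_size == pytest.approx(1.0 / np.sqrt(2 / 3), abs=1e-12)
        assert res.alpha_adjusted is None
        res_one = paired_t(x, y, tails="one", alpha_adjusted=BONFERRONI_3)
        assert res_one.p_value == res_one.extras["p_one_tailed"]
        assert res_one.alpha_adjusted == pytest.approx(0.05 / 3)

    def test_welch_df_hand_arithmetic(self):
        x = np.array([1.0, 2, 3, 4, 5])
        y = np.array([2.0, 4, 6])
        vx, vy = x.var(ddof=1), y.var(ddof=1)
        se2 = vx / 5 + vy / 3
        df_oracle = se2**2 / ((vx / 5) ** 2 / 4 + (vy / 3) ** 2 / 2)
        res = welch_t(x, y)
        assert res.df == pytest.approx(df_oracle, abs=1e-10)
        assert res.statistic == pytest.approx((x.mean() - y.mean()) / np.sqrt(se2), abs=1e-12)

    def test_zero_variance_everywhere_rejected(self):
        with pytest.raises(ValueError):
            welch_t(np.ones(4), np.full(4, 2.0))


def anova_frame(values_by_cell, n):
    """Long frame for subjects 0..n-1 with cells keyed (between, within)."""
    rows = []
    for i in range(n):
        for (grp, cond), vals in values_by_cell.items():
            rows.append((f"s{grp}{i}", grp, cond, vals[i]))
    return pd.DataFrame(rows, columns=["participant_id", "current_mA", "condition", "peak_r"])


class TestMixedAnova:
    def test_all_equal_gives_zero_f(self):
        df = anova_frame({(g, c): [1.0] * 4 for g in (1.0, 2.0)
                          for c in ("active", "sham")}, 4)
        res = mixed_anova(df)
        assert all(r.statistic == 0.0 and r.p_value == 1.0 for r in res.values())

    def test_pure_between_shift_loads_only_between(self):
        base = [0.1, 0.2, 0.3, 0.4]
        df = anova_frame({
            (1.0, "active"): base, (1.0, "sham"): base,
            (2.0, "active"): [b + 1 for b in base], (2.0, "sham"): [b + 1 for b in base],
        }, 4)
        res = mixed_anova(df)
        assert res["between"].statistic > 10
        assert res["within"].statistic == pytest.approx(0.0, abs=1e-20)
        assert res["interaction"].statistic == pytest.approx(0.0, abs=1e-20)

    def test_matches_manual_sums_of_squares_on_8_subject_fixture(self):
        rng = np.random.default_rng(42)
        df = anova_frame({(g, c): list(rng.normal(size=4))
                          for g in (1.0, 2.0) for c in ("active", "sham")}, 4)
        res = mixed_anova(df)
        # manual balanced two-way mixed ANOVA decomposition
        y = df.pivot_table(index=["participant_id", "current_mA"],
                           columns="condition", values="peak_r")
        groups = y.index.get_level_values("current_mA").to_numpy()
        m = y.to_numpy()  # (8 subjects, 2 conditions)
        grand = m.mean()
        subj_means = m.mean(axis=1)
        cond_means = m.mean(axis=0)
        n_s, n_c = m.shape
        ss_between = 0.0
        for g in (1.0, 2.0):
            ss_between += n_c * (groups == g).sum() * (subj_means[groups == g].mean() - grand) ** 2
        ss_subj_within = n_c * np.sum(
            [(subj_means[i] - subj_means[groups == groups[i]].mean()) ** 2 for i in range(n_s)]
        )
        ss_cond = n_s * np.sum((cond_means - grand) ** 2)
        cell = np.vstack([m[groups == g].mean(axis=0) for g in (1.0, 2.0)])
        grp_mean = np.array([m[groups == g].mean() for g in (1.0, 2.0)])
        ss_inter = 0.0
        for gi, g in enumerate((1.0, 2.0)):
            for ci in range(n_c):
                ss_inter += (groups == g).sum() * (
                    cell[gi, ci] - grp_mean[gi] - cond_means[ci] + grand) ** 2
        ss_err_within = 0.0
        for i in range(n_s):
            gi = 0 if groups[i] == 1.0 else 1
            for ci in range(n_c):
                ss_err_within += (m[i, ci] - subj_means[i] - cell[gi, ci] + grp_mean[gi]) ** 2
        f_between = (ss_between / 1) / (ss_subj_within / (n_s - 2))
        f_cond = (ss_cond / 1) / (ss_err_within / (n_s - 2))
        f_inter = (ss_inter / 1) / (ss_err_within / (n_s - 2))
        assert res["between"].statistic == pytest.approx(f_between, abs=1e-10)
        assert res["within"].statistic == pytest.approx(f_cond, abs=1e-10)
        assert res["interaction"].statistic == pytest.approx(f_inter, abs=1e-10)

    def test_matches_pingouin_on_random_data(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(7)
        df = anova_frame({(g, c): list(rng.normal(size=6))
                          for g in (1.0, 2.0) for c in ("active", "sham")}, 6)
        res = mixed_anova(df)
        ref = pg.mixed_anova(data=df, dv="peak_r", within="condition",
                             subject="participant_id", between="current_mA"
                             ).set_index("Source")
        assert res["between"].statistic == pytest.approx(ref.loc["current_mA", "F"], abs=1e-9)
        assert res["within"].statistic == pytest.approx(ref.loc["condition", "F"], abs=1e-9)
        assert res["interaction"].statistic == pytest.approx(ref.loc["Interaction", "F"], abs=1e-9)
        assert res["between"].effect_size == pytest.approx(ref.loc["current_mA", "np2"], abs=1e-9)

    def test_incomplete_design_rejected(self):
        df = anova_frame({(1.0, "active"): [1, 2], (1.0, "sham"): [1, 2]}, 2)
        with pytest.raises(ValueError):
            mixed_anova(df)


def rm_frame(cells, n):
    rows = []
    for i in range(n):
        for (cond, ref), vals in cells.items():
            rows.append((f"s{i}", cond, ref, vals[i]))
    return pd.DataFrame(rows, columns=["participant_id", "condition", "reference", "peak_r"])


class TestRepeatedAnova2x2:
    def test_all_equal_gives_zero_f(self):
        cells = {(c, r): [2.0] * 5 for c in ("active", "sham")
                 for r in ("congruent", "incongruent")}
        res = repeated_anova_2x2(rm_frame(cells, 5))
        assert all(r.statistic == 0.0 for r in res.values())

    def test_pure_congruence_effect_loads_only_congruence(self):
        base = [0.25, 0.5, 0.75, 1.0, 1.25]  # dyadic: contrasts are exact
        cells = {("active", "congruent"): [b + 1 for b in base],
                 ("active", "incongruent"): base,
                 ("sham", "congruent"): [b + 1 for b in base],
                 ("sham", "incongruent"): base}
        res = repeated_anova_2x2(rm_frame(cells, 5))
        assert res["reference"].p_value < 1e-6
        assert res["condition"].statistic == pytest.approx(0.0, abs=1e-18)
        assert res["interaction"].statistic == pytest.approx(0.0, abs=1e-18)

    def test_matches_manual_sums_of_squares(self):
        rng = np.random.default_rng(8)
        cells = {(c, r): list(rng.normal(size=6)) for c in ("active", "sham")
                 for r in ("congruent", "incongruent")}
        res = repeated_anova_2x2(rm_frame(cells, 6))
        m = np.array([cells[(c, r)] for c in ("active", "sham")
                      for r in ("congruent", "incongruent")]).T  # (6, 4): a-cong, a-inc, s-cong, s-inc
        n = m.shape[0]
        A = (m[:, :2].mean(axis=1) - m[:, 2:].mean(axis=1))  # condition contrast
        B = (m[:, [0, 2]].mean(axis=1) - m[:, [1, 3]].mean(axis=1))  # congruence
        AB = (m[:, 0] - m[:, 1]) - (m[:, 2] - m[:, 3])
        for key, c in (("condition", A), ("reference", B), ("interaction", AB)):
            t = c.mean() / (c.std(ddof=1) / np.sqrt(n))
            assert res[key].statistic == pytest.approx(t**2, abs=1e-10)
            assert res[key].df == (1.0, float(n - 1))
            assert res[key].effect_size == pytest.approx(
                t**2 / (t**2 + n - 1), abs=1e-12)


class TestWilcoxon:
    def test_identical_pairs_degenerate(self):
        res = wilcoxon_signed_rank(np.arange(6.0), np.arange(6.0))
        assert res.degenerate and res.p_value == 1.0

    def test_n6_exact_p_matches_enumeration(self):
        a = np.array([12.0, 9, 14, 7, 10.5, 15])  # distinct |differences|
        b = np.array([10.0, 10, 10, 10, 10, 10])
        res = wilcoxon_signed_rank(a, b)
        d = a - b
        ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
        w_obs = ranks[d > 0].sum()
        # two-sided exact p by full enumeration of 2^6 sign assignments
        total = 0
        extreme = 0
        mu = ranks.sum() / 2
        for signs in itertools.product([0, 1], repeat=6):
            w = sum(r for r, s in zip(ranks, signs) if s)
            total += 1
            if abs(w - mu) >= abs(w_obs - mu) - 1e-12:
                extreme += 1
        assert res.extras["method"] == "exact"
        assert res.p_value == pytest.approx(extreme / total, abs=1e-12)

    def test_antisymmetry_of_z(self):
        rng = np.random.default_rng(11)
        a = rng.normal(1, 1, 30)
        b = rng.normal(0, 1, 30)
        z1 = wilcoxon_signed_rank(a, b).statistic
        z2 = wilcoxon_signed_rank(b, a).statistic
        assert z1 == pytest.approx(-z2, abs=1e-12)

    def test_large_sample_uses_normal_approximation(self):
        rng = np.random.default_rng(12)
        a = rng.normal(0.7, 1, 40)
        b = rng.normal(0, 1, 40)
        res = wilcoxon_signed_rank(a, b)
        assert res.extras["method"] == "normal_approx"
        assert res.statistic > 2 and res.p_value < 0.05


class TestPearson:
    def test_exact_linear_relation(self):
        x = np.arange(10.0)
        res = pearson_corr(x, 3 * x + 2)
        assert res.statistic == pytest.approx(1.0, abs=1e-12)

    def test_constant_variable_flagged(self):
        res = pearson_corr(np.ones(10), np.arange(10.0))
        assert res.degenerate and np.isnan(res.statistic)

    def test_stratified_rt_correlations_flag_small_strata(self):
        sens = pd.DataFrame({
            "participant_id": ["a", "b", "a", "b"],
            "current_mA": [2.0] * 4,
            "condition": ["active"] * 2 + ["sham"] * 2,
            "reference": ["congruent"] * 4,
            "peak_r": [0.5, 0.7, 0.4, 0.6],
        })
        drt = pd.DataFrame({
            "participant_id": ["a", "b", "a", "b"],
            "condition": ["active", "active", "sham", "sham"],
            "delta_rt_ms": [5.0, 10.0, 1.0, 2.0],
        })
        out = sensitivity_rt_correlations(sens, drt)
        assert all(r.degenerate for r in out.values())  # n = 2 < 3 per stratum


class TestTypeICalibrationSmoke:
    def test_battery_runs_on_synthetic_study(self, small_study):
        from shamtrack.protocol import protocols_for_strength
        from shamtrack.sensitivity import sensitivity_table

        records, _ = small_study
        protos = {s: protocols_for_strength(s) for s in (1.0, 2.0)}
        stats = run_inferential_battery(records, sensitivity_table(records, protos))
        for key in ("delta_rt_paired_t_2mA_block3", "mixed_anova_between",
                    "rm_anova_congruence", "side_effect_wilcoxon_itching_2mA",
                    "peak_r_paired_t_active_vs_sham",
                    "sensitivity_rt_corr_2mA_active"):
            assert key in stats
        d = stats["rm_anova_congruence"].to_dict()
        assert isinstance(d["statistic"], float) and 0 <= d["p_value"] <= 1
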