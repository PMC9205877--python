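"""Cleaning, tables, ANOVA, effect sizes, screening, correlations, power."""

import numpy as np
import pandas as pd
import pytest

from coopddm import stats as gs
from coopddm.stats import (
    CleaningError,
    affect_ttests,
    clean_trials,
    cohens_d_paired,
    cooperation_table,
    correlate,
    mixed_logit_cooperation,
    rm_anova_2x2,
    sample_size_cooperation,
    select_features,
    stimulation_effect_per_subject,
)


def _mini_log(n_invalid=0):
    rows = []
    k = 0
    for sid in ("s01", "s02"):
        for cond in ("tvns", "sham"):
            for i in range(10):
                rows.append({
                    "subject_id": sid, "session_index": 1 if cond == "tvns" else 2,
                    "stim_condition": cond, "trial_index": i + 1,
                    "opponent_id": "human_random", "opponent_class": "human" if i % 2 else "computer",
                    "opponent_policy": "random", "decision_order": "subject_first",
                    "subject_choice": "cooperate" if i % 2 else "deceive",
                    "opponent_choice": "cooperate", "subject_rt_s": 0.8,
                    "opponent_rt_s": 2.0, "points_subject": 20, "cumulative_points": 0,
                    "valid": k >= n_invalid,
                })
                k += 1
    return pd.DataFrame(rows)


class TestCleaning:
    def test_counts_and_identity(self):
        log = _mini_log(n_invalid=1)
        valid, report = clean_trials(log)
        assert len(valid) == len(log) - 1
        assert report.n_excluded.sum() == 1
        log2 = _mini_log(0)
        valid2, report2 = clean_trials(log2)
        pd.testing.assert_frame_equal(valid2, log2)
        assert report2.n_excluded.sum() == 0

    def test_empty_cell_raises_naming_it(self):
        log = _mini_log()
        log.loc[(log.subject_id == "s01") & (log.stim_condition == "sham"), "valid"] = False
        with pytest.raises(CleaningError, match="s01/sham"):
            clean_trials(log)


class TestCooperationTable:
    def test_saturation_and_recount_oracle(self, small_valid):
        coop, rt = cooperation_table(small_valid)
        # brute-force recount, plain python loops
        for row in coop.sample(8, random_state=0).itertuples():
            n = c = 0
            for t in small_valid.itertuples():
                if (t.subject_id == row.subject_id and t.stim_condition == row.stim_condition
                        and t.opponent_class == row.opponent_class):
                    n += 1
                    c += t.subject_choice == "cooperate"
            assert row.n_valid == n
            assert row.percent_cooperation == pytest.approx(100.0 * c / n)

    def test_all_cooperate_gives_100(self):
        log = _mini_log()
        log["subject_choice"] = "cooperate"
        valid, _ = clean_trials(log)
        coop, _ = cooperation_table(valid)
        assert (coop.percent_cooperation == 100.0).all()

    def test_alternating_gives_50(self):
        log = _mini_log()
        log["opponent_class"] = "human"
        log["subject_choice"] = ["cooperate", "deceive"] * (len(log) // 2)
        valid, _ = clean_trials(log)
        coop, _ = cooperation_table(valid)
        assert (coop.percent_cooperation == 50.0).all()


def brute_force_rm_anova(wide):
    """Textbook within-subject sums-of-squares decomposition for a 2x2
    design; wide columns are (level1, level2) cell means per subject."""
    y = wide.to_numpy(dtype=float)
    n = y.shape[0]
    a_means = np.stack([y[:, :2].mean(1), y[:, 2:].mean(1)], 1)  # factor 1
    b_means = np.stack([y[:, [0, 2]].mean(1), y[:, [1, 3]].mean(1)], 1)
    grand = y.mean()
    subj = y.mean(1)
    out = {}
    for name, cellm, other in (("f1", a_means, b_means), ("f2", b_means, a_means)):
        ss_eff = 2 * n * ((cellm.mean(0) - grand) ** 2).sum()
        ss_err = 2 * ((cellm - cellm.mean(0)[None, :] - subj[:, None] + grand) ** 2).sum()
        F = (ss_eff / 1) / (ss_err / (n - 1))
        out[name] = F
    inter = (y[:, 3] - y[:, 2]) - (y[:, 1] - y[:, 0])  # interaction contrast per subject
    ss_int = n * inter.mean() ** 2
    ss_interr = ((inter - inter.mean()) ** 2).sum()
    out["f1:f2"] = ss_int / (ss_interr / (n - 1))
    return out


class TestAnova:
    @staticmethod
    def _table(y):
        rows = []
        for i, subj in enumerate(y):
            for j, (c1, c2) in enumerate([("sham", "computer"), ("sham", "human"),
                                          ("tvns", "computer"), ("tvns", "human")]):
                rows.append({"subject_id": f"s{i}", "stim_condition": c1,
                             "opponent_class": c2, "dv": subj[j]})
        return pd.DataFrame(rows)

    def test_null_table_gives_zero_f(self):
        y = [[40, 44, 40, 44], [35, 38, 35, 38], [50, 52, 50, 52], [45, 40, 45, 40]]
        table = self._table(y)
        out = rm_anova_2x2(table, "dv")
        stim = out[out.effect == "stim_condition"].iloc[0]
        assert stim.F == pytest.approx(0.0, abs=1e-10)
        assert stim.p == pytest.approx(1.0)

    def test_matches_brute_force_sums_of_squares(self):
        rng = np.random.default_rng(0)
        y = rng.normal(40, 8, size=(5, 4))
        table = self._table(y.tolist())
        out = rm_anova_2x2(table, "dv").set_index("effect")
        oracle = brute_force_rm_anova(pd.DataFrame(
            y, columns=pd.MultiIndex.from_product([["sham", "tvns"], ["computer", "human"]])))
        assert out.loc["stim_condition", "F"] == pytest.approx(oracle["f1"], rel=1e-8)
        assert out.loc["opponent_class", "F"] == pytest.approx(oracle["f2"], rel=1e-8)
        assert out.loc["stim_condition:opponent_class", "F"] == pytest.approx(oracle["f1:f2"], rel=1e-8)

    def test_subject_label_permutation_invariance(self):
        rng = np.random.default_rng(1)
        y = rng.normal(40, 8, size=(6, 4))
        t1 = self._table(y.tolist())
        perm = rng.permutation(6)
        relabel = {f"s{i}": f"s{perm[i]}" for i in range(6)}
        t2 = t1.assign(subject_id=t1.subject_id.map(relabel))
        pd.testing.assert_frame_equal(rm_anova_2x2(t1, "dv"), rm_anova_2x2(t2, "dv"))

    def test_missing_cell_rejected(self):
        t = self._table([[1, 2, 3, 4]] * 4).iloc[:-1]
        with pytest.raises(ValueError):
            rm_anova_2x2(t, "dv")


class TestCohensD:
    def test_hand_computed_four_pairs(self):
        x = np.array([10.0, 12.0, 9.0, 14.0])
        y = np.array([8.0, 11.0, 10.0, 9.0])
        d = x - y  # [2, 1, -1, 5] -> mean 1.75, sd 2.5
        assert cohens_d_paired(x, y) == pytest.approx(1.75 / 2.5)

    def test_null_and_degenerate(self):
        x = np.array([1.0, 2.0, 3.0])
        assert cohens_d_paired(x, x) == 0.0
        assert np.isposinf(cohens_d_paired(x + 2.0, x))
        assert np.isneginf(cohens_d_paired(x - 2.0, x))


class TestFeatureScreen:
    def test_orthogonal_predictors_all_retained(self):
        X = pd.DataFrame(np.eye(6)[:, :4], columns=list("abcd"))
        kept, report = select_features(X)
        assert list(kept.columns) == list("abcd") and report.empty

    def test_duplicate_column_dropped_once(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(50)
        X = pd.DataFrame({"a": x, "b": x.copy(), "c": rng.standard_normal(50)})
        kept, report = select_features(X)
        assert len(report) == 1 and set(kept.columns) >= {"c"}
        assert len(kept.columns) == 2

    def test_r2_at_065_retained(self):
        """The screen is strict > 0.7 on R^2: a pair at R^2 = 0.65 passes."""
        n = 400
        rng = np.random.default_rng(1)
        x = rng.standard_normal(n)
        x -= x.mean()
        e = rng.standard_normal(n)
        e -= e.mean()
        e -= e @ x / (x @ x) * x  # orthogonalise
        r = np.sqrt(0.65)
        y = r * (x / x.std()) + np.sqrt(1 - 0.65) * (e / e.std())
        X = pd.DataFrame({"x": x, "y": y})
        assert abs(np.corrcoef(x, y)[0, 1] ** 2 - 0.65) < 1e-12
        kept, report = select_features(X)
        assert list(kept.columns) == ["x", "y"] and report.empty


class TestCorrelate:
    def test_monotone_gives_spearman_one(self):
        x = np.array([1.0, 2.0, 5.0, 9.0])
        assert correlate(x, np.exp(x), "spearman").coefficient == pytest.approx(1.0)

    def test_ties_match_rank_then_pearson_oracle(self):
        x = np.array([1.0, 2.0, 2.0, 3.0, 5.0, 5.0, 5.0, 8.0])
        y = np.array([3.0, 3.0, 1.0, 4.0, 6.0, 6.0, 2.0, 9.0])
        from scipy.stats import rankdata, pearsonr

        oracle = pearsonr(rankdata(x), rankdata(y))[0]
        assert correlate(x, y, "spearman").coefficient == pytest.approx(oracle, rel=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            correlate([1.0, 2.0, 3.0], [4.0, 4.0, 4.0])


class TestSampleSize:
    def test_minimality(self):
        n = sample_size_cooperation(6.0, 10.0, alpha=0.05, power=0.95)
        from coopddm.stats import _paired_t_power

        es = 0.6
        assert _paired_t_power(n, es, 0.05) >= 0.95
        assert _paired_t_power(n - 1, es, 0.05) < 0.95

    def test_monotone_in_effect_size(self):
        n1 = sample_size_cooperation(5.0, 10.0)
        n2 = sample_size_cooperation(10.0, 10.0)
        assert n2 <= n1

    def test_zero_effect_rejected(self):
        with pytest.raises(ValueError):
            sample_size_cooperation(0.0, 10.0)

    def test_matches_monte_carlo_power(self):
        """Power at the returned n agrees with a 1e5-replicate paired-t
        simulation within one percentage point."""
        from scipy import stats as sps

        es, alpha, target = 0.8, 0.05, 0.9
        n = sample_size_cooperation(8.0, 10.0, alpha=alpha, power=target)
        rng = np.random.default_rng(0)
        draws = rng.standard_normal((100_000, n)) + es
        t = draws.mean(1) / (draws.std(1, ddof=1) / np.sqrt(n))
        crit = sps.t.ppf(1 - alpha / 2, n - 1)
        mc_power = np.mean(np.abs(t) > crit)
        from coopddm.stats import _paired_t_power

        assert abs(mc_power - _paired_t_power(n, es, alpha)) < 0.01


class TestAffect:
    @staticmethod
    def _profiles(pos1, pos2):
        n = len(pos1)
        return pd.DataFrame({
            "subject_id": [f"s{i}" for i in range(n)],
            "condition_order": ["tvns_first"] * n,
            "panas_positive_session1": pos1, "panas_positive_session2": pos2,
            "panas_negative_session1": pos1, "panas_negative_session2": pos2,
        })

    def test_identical_scores_give_p_one(self):
        out = affect_ttests(self._profiles([17, 18, 19, 20], [17, 18, 19, 20]))
        assert (out.t == 0).all() and (out.p == 1.0).all()

    def test_antisymmetry_under_session_swap(self):
        p = self._profiles([17.0, 20.0, 15.0, 22.0], [18.0, 17.0, 16.0, 19.0])
        out1 = affect_ttests(p)
        swapped = p.assign(condition_order="sham_first")
        out2 = affect_ttests(swapped)
        np.testing.assert_allclose(out1.t.to_numpy(), -out2.t.to_numpy())
        np.testing.assert_allclose(out1.p.to_numpy(), out2.p.to_numpy())

    def test_matches_hand_computed_paired_t(self):
        from scipy.stats import ttest_rel

        p = self._profiles([17.0, 20.0, 15.0, 22.0], [18.0, 17.0, 16.0, 19.0])
        out = affect_ttests(p).set_index("scale")
        t, pv = ttest_rel([17.0, 20.0, 15.0, 22.0], [18.0, 17.0, 16.0, 19.0])
        assert out.loc["positive", "t"] == pytest.approx(t)
        assert out.loc["positive", "p"] == pytest.approx(pv)

    def test_missing_session_rejected(self):
        p = self._profiles([17, 18, 19, 20], [17, 18, 19, 20]).drop(
            columns=["panas_positive_session2"])
        with pytest.raises(ValueError):
            affect_ttests(p)


class TestStimulationEffect:
    def test_recount_and_shape(self, small_valid):
        coop, _ = cooperation_table(small_valid)
        eff = stimulation_effect_per_subject(coop)
        assert len(eff) == small_valid.subject_id.nunique()
        means = coop.groupby(["subject_id", "stim_condition"]).percent_cooperation.mean()
        for sid in eff.index:
            assert eff[sid] == pytest.approx(means[sid, "tvns"] - means[sid, "sham"])

    def test_identical_conditions_give_zero(self):
        log = _mini_log()
        valid, _ = clean_trials(log)
        coop, _ = cooperation_table(valid)
        eff = stimulation_effect_per_subject(coop)
        np.testing.assert_allclose(eff.to_numpy(), 0.0)


class TestMixedModelSmoke:
    def test_runs_on_small_study_and_reports_all_interactions(self, small_study, small_valid):
        mm = mixed_logit_cooperation(small_valid, small_study.profiles, small_study.likability)
        terms = set(mm.coef.index)
        assert "stimulation" in terms and "stimulation:neuroticism" in terms
        retained_nonstim = [t for t in terms
                            if ":" not in t and t not in ("intercept", "stimulation")]
        for t in retained_nonstim:
            assert f"stimulation:{t}" in terms
        assert mm.result.sigma >= 0
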