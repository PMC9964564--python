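"""Inferential layer: Lilliefors screen, RM-ANOVA, pairwise comparisons."""

import numpy as np
import pytest
from scipy import stats as sps

from kinevar import StudyTable, lilliefors_test, pairwise_comparisons, rm_anova
from reference import naive_rm_anova_ss


def make_table(values, metric="sd"):
    values = np.asarray(values, dtype=float)
    labels = [f"C{j}" for j in range(values.shape[1])]
    return StudyTable(values=values, metric_name=metric, condition_labels=labels)


class TestLilliefors:
    def test_statistic_matches_manual_ecdf_computation(self):
        # symmetric 4-point sample: max gap against the fitted normal,
        # recomputed here by explicit enumeration of ECDF steps
        x = np.array([-1.5, -0.5, 0.5, 1.5])
        z = (np.sort(x) - x.mean()) / x.std(ddof=1)
        cdf = sps.norm.cdf(z)
        gaps = []
        for i in range(4):
            gaps.append(abs((i + 1) / 4 - cdf[i]))
            gaps.append(abs(cdf[i] - i / 4))
        expected = max(gaps)
        result = lilliefors_test(x)
        assert result.statistic == pytest.approx(expected, abs=1e-12)

    def test_statistic_agrees_with_statsmodels(self):
        from statsmodels.stats.diagnostic import lilliefors as sm_lilliefors

        x = np.random.default_rng(3).standard_normal(25)
        d_sm, _ = sm_lilliefors(x, dist="norm")
        assert lilliefors_test(x).statistic == pytest.approx(d_sm, abs=1e-10)

    def test_size_under_the_null(self):
        # rejection rate at alpha=0.05 should be ~0.05 when sampling from
        # the null (normal) distribution
        rng = np.random.default_rng(11)
        rejections = sum(
            lilliefors_test(rng.standard_normal(21)).p < 0.05 for _ in range(1000)
        )
        assert 0.03 <= rejections / 1000 <= 0.07

    def test_power_against_uniform(self):
        rng = np.random.default_rng(5)
        rejections = sum(
            lilliefors_test(rng.uniform(size=200)).p < 0.05 for _ in range(100)
        )
        assert rejections >= 95

    def test_zero_variance_sample_is_an_error(self):
        with pytest.raises(ValueError, match="zero-variance"):
            lilliefors_test(np.ones(10))


class TestRmAnova:
    def test_identical_columns_give_zero_f(self):
        col = np.random.default_rng(0).normal(size=8)
        result = rm_anova(make_table(np.column_stack([col, col, col])))
        assert result.F == pytest.approx(0.0, abs=1e-20)
        assert result.pes == pytest.approx(0.0, abs=1e-20)

    def test_two_conditions_equal_squared_paired_t(self, rng):
        values = rng.normal(size=(12, 2))
        values[:, 1] += 0.4
        result = rm_anova(make_table(values))
        t_stat, p_t = sps.ttest_rel(values[:, 0], values[:, 1])
        assert result.F == pytest.approx(t_stat**2, abs=1e-10)
        assert result.p == pytest.approx(p_t, abs=1e-10)

    def test_study_shape_degrees_of_freedom(self, rng):
        result = rm_anova(make_table(rng.normal(size=(21, 5))))
        assert (result.df_effect, result.df_error) == (4.0, 80.0)

    def test_sum_of_squares_match_bruteforce_two_way_fit(self, rng):
        values = rng.normal(size=(6, 4)) + rng.normal(size=(6, 1))
        result = rm_anova(make_table(values))
        ss_subj, ss_cond, ss_err = naive_rm_anova_ss(values)
        assert result.ss_subjects == pytest.approx(ss_subj, abs=1e-10)
        assert result.ss_conditions == pytest.approx(ss_cond, abs=1e-10)
        assert result.ss_error == pytest.approx(ss_err, abs=1e-10)

    def test_agrees_with_statsmodels_anovarm(self, rng):
        import pandas as pd
        from statsmodels.stats.anova import AnovaRM

        values = rng.normal(size=(10, 4))
        values += np.array([0.0, 0.2, 0.1, -0.3])
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(10), 4),
                "condition": np.tile(np.arange(4), 10),
                "y": values.ravel(),
            }
        )
        sm_res = AnovaRM(long, "y", "subject", within=["condition"]).fit()
        f_sm = float(sm_res.anova_table["F Value"].iloc[0])
        assert rm_anova(make_table(values)).F == pytest.approx(f_sm, rel=1e-8)

    def test_invariant_to_subject_constants(self, rng):
        values = rng.normal(size=(9, 3))
        shifted = values + rng.normal(size=(9, 1)) * 50
        assert rm_anova(make_table(shifted)).F == pytest.approx(
            rm_anova(make_table(values)).F, rel=1e-8
        )

    def test_pes_identity(self, rng):
        result = rm_anova(make_table(rng.normal(size=(15, 4))))
        identity = (
            result.F * result.df_effect / (result.F * result.df_effect + result.df_error)
        )
        assert result.pes == pytest.approx(identity, abs=1e-10)
        assert 0 <= result.pes <= 1

    def test_type_one_error_calibration(self):
        rng = np.random.default_rng(99)
        rejections = 0
        for _ in range(1000):
            values = rng.normal(size=(12, 4)) + rng.normal(size=(12, 1))
            if rm_anova(make_table(values)).p < 0.05:
                rejections += 1
        assert 0.03 <= rejections / 1000 <= 0.07

    def test_incomplete_matrix_rejected(self):
        values = np.random.default_rng(0).normal(size=(5, 3))
        values[2, 1] = np.nan
        with pytest.raises(ValueError, match="complete"):
            make_table(values)


class TestPairwise:
    def test_five_conditions_make_ten_pairs(self, rng):
        out = pairwise_comparisons(make_table(rng.normal(size=(10, 5))))
        assert len(out) == 10

    def test_bonferroni_definition(self, rng):
        table = make_table(rng.normal(size=(10, 5)))
        out = pairwise_comparisons(table, correction="bonferroni")
        np.testing.assert_allclose(
            out["p_adjusted"], np.minimum(1.0, 10 * out["p_raw"]), atol=1e-14
        )

    def test_zero_variance_pair_isolated(self, rng):
        values = rng.normal(size=(8, 3))
        values[:, 2] = values[:, 0]  # identical columns -> zero-variance diff
        out = pairwise_comparisons(make_table(values))
        bad = out[out["error"] != ""]
        good = out[out["error"] == ""]
        assert len(bad) == 1 and "zero-variance" in bad["error"].iloc[0]
        assert good["p_raw"].notna().all()

    def test_deviant_condition_power(self):
        # one condition with 10x the noise SD: its pairs should light up
        from kinevar.pipeline import build_study_table, compute_metrics_table
        from kinevar.synthetic import TaskSimSpec, gen_study

        specs = {
            "HoS": TaskSimSpec(condition="HoS", noise_sd=0.004),
            "ARelax": TaskSimSpec(condition="ARelax", noise_sd=0.004),
            "A90": TaskSimSpec(condition="A90", noise_sd=0.04),
        }
        hits = 0
        for rep in range(20):
            study = gen_study(
                n_participants=6, trials_per_condition=1,
                condition_specs=specs, seed=3000 + rep,
            )
            per_trial, _ = compute_metrics_table_sd_only(study)
            table = build_study_table(
                per_trial_to_cells(per_trial), "sd", conditions=list(specs)
            )
            out = pairwise_comparisons(table)
            flagged = set(out.loc[out["significant"], "pair"])
            expected = {"HoS vs A90", "ARelax vs A90"}
            unexpected = {"HoS vs ARelax"}
            if expected <= flagged and not (unexpected & flagged):
                hits += 1
        assert hits >= 18


def compute_metrics_table_sd_only(study):
    """SD-only metric pass (skips the entropy/DFA cost for power sims)."""
    import pandas as pd

    from kinevar import RunConfig, preprocess_trial, std_dev

    rows = []
    for trial in study:
        rd = preprocess_trial(trial, RunConfig())
        rows.append({**trial.provenance(), "sd": std_dev(rd.values)})
    return pd.DataFrame(rows), []


def per_trial_to_cells(per_trial):
    return per_trial.groupby(["participant", "condition", "site"], as_index=False)[
        ["sd"]
    ].mean()
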