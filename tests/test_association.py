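"""Matched splitting, edge-wise GLMs, FDR, effect sizes, RRMSE."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import dynconn as dc
from dynconn.association import (
    fdr_correct,
    fit_connection_glm,
    matched_split,
    partial_r_from_result,
    rrmse_class,
    rrmse_on_test,
    run_association,
    trait_nuisance_correlation,
)


def _random_tindex(n_subjects, n_conn, seed, index=None):
    rng = np.random.default_rng(seed)
    idx = index if index is not None else [f"s{i:04d}" for i in range(n_subjects)]
    cols = [f"{k + 1}_{k + 2}" for k in range(n_conn)]
    table = pd.DataFrame(
        np.abs(rng.normal(3.0, 1.0, (n_subjects, n_conn))), index=idx, columns=cols
    )
    table.index.name = "subject_id"
    return table


class TestMatchedSplit:
    def test_paper_scale_split_sizes(self):
        table = _random_tindex(818, 10, seed=0)
        split = matched_split(table, seed=1)
        assert len(split.train_ids) == 613
        assert len(split.test_ids) == 205
        assert not set(split.train_ids) & set(split.test_ids)
        assert (split.match_pvalues > 0.05).all()

    def test_identical_rows_accepted_first_draw(self):
        table = _random_tindex(40, 6, seed=1)
        table.iloc[:, :] = 2.5
        split = matched_split(table, seed=2)
        assert split.n_resamples_used == 1

    def test_deterministic_given_seed(self):
        table = _random_tindex(60, 8, seed=3)
        a = matched_split(table, seed=9)
        b = matched_split(table, seed=9)
        assert a.train_ids == b.train_ids and a.test_ids == b.test_ids

    def test_gradient_table_blocked_split_fails_but_random_matches(self):
        """A T-index rank-correlated with subject order defeats a blocked
        assignment yet random partitions still match."""
        n = 120
        table = _random_tindex(n, 5, seed=4)
        table.iloc[:, :] += np.linspace(0, 6, n)[:, None]
        blocked_p = stats.mannwhitneyu(
            table.iloc[:90, 0], table.iloc[90:, 0]
        ).pvalue
        assert blocked_p < 0.05
        split = matched_split(table, seed=5)
        assert (split.match_pvalues > 0.05).all()

    def test_unmatchable_raises_with_worst_connection(self):
        table = _random_tindex(40, 3, seed=6)
        with pytest.raises(RuntimeError, match="worst-matched connection"):
            # alpha so high no draw can satisfy it
            matched_split(table, match_alpha=0.9999, max_resamples=5, seed=0)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            matched_split(_random_tindex(6, 3, seed=0))


class TestConnectionGlm:
    def test_planted_dominant_signal(self, small_phenotypes):
        phen = small_phenotypes
        rng = np.random.default_rng(0)
        t = -0.5 * phen["conscientiousness"] + 0.1 * rng.standard_normal(len(phen)) + 20
        res = fit_connection_glm(t, phen)
        assert res.params["conscientiousness"] < 0
        assert res.pvalues["conscientiousness"] < 1e-6

    def test_single_predictor_matches_pearson_test(self):
        rng = np.random.default_rng(1)
        x = pd.DataFrame({"x": rng.normal(size=80)}, index=range(80))
        y = pd.Series(0.3 * x["x"] + rng.normal(size=80), index=x.index)
        res = fit_connection_glm(y, x, predictors=["x"])
        r, p = stats.pearsonr(x["x"], y)
        assert res.pvalues["x"] == pytest.approx(p, rel=1e-9)

    def test_null_pvalues_uniform(self, small_phenotypes):
        """Raw trait p-values under the null pass a KS test for uniformity."""
        phen = small_phenotypes.iloc[:80]
        rng = np.random.default_rng(2)
        pvals = []
        for _ in range(400):
            t = pd.Series(rng.normal(size=len(phen)), index=phen.index)
            res = fit_connection_glm(t, phen)
            pvals.append(res.pvalues["extraversion"])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_collinear_design_named(self, small_phenotypes):
        phen = small_phenotypes.copy()
        phen["age_copy"] = phen["age"]
        t = pd.Series(np.arange(len(phen), dtype=float), index=phen.index)
        with pytest.raises(ValueError, match="age"):
            fit_connection_glm(t, phen, predictors=["age", "age_copy"])

    def test_missing_t_dropped(self, small_phenotypes):
        phen = small_phenotypes
        rng = np.random.default_rng(3)
        t = pd.Series(rng.normal(size=len(phen)) + 5, index=phen.index)
        t.iloc[:10] = np.nan
        res = fit_connection_glm(t, phen)
        assert int(res.nobs) == len(phen) - 10


class TestFdrCorrect:
    def test_hand_worked_step_up(self):
        np.testing.assert_allclose(fdr_correct([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_equal_pvalues_unchanged(self):
        np.testing.assert_allclose(fdr_correct([0.001] * 105), [0.001] * 105)

    def test_monotone_and_dominates_raw(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(size=105)
        q = fdr_correct(p)
        assert (q >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_readjustment_never_decreases(self):
        # step-up re-adjustment can only inflate already-adjusted values;
        # tied families are exact fixed points
        rng = np.random.default_rng(5)
        q = fdr_correct(rng.uniform(size=50))
        assert (fdr_correct(q) >= q - 1e-15).all()
        np.testing.assert_allclose(fdr_correct([0.03] * 7), [0.03] * 7)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_correct([0.5, 1.2])

    def test_global_null_family_error_control(self):
        """Fraction of 105-test families with any BH discovery stays near alpha."""
        rng = np.random.default_rng(6)
        hits = sum(
            (fdr_correct(rng.uniform(size=105)) < 0.05).any() for _ in range(1000)
        )
        assert hits / 1000 <= 0.07


class TestEffectSize:
    def test_t_statistic_identity(self, small_phenotypes):
        phen = small_phenotypes
        rng = np.random.default_rng(7)
        t = pd.Series(
            5 - 0.05 * phen["neuroticism"] + rng.normal(size=len(phen)), index=phen.index
        )
        res = fit_connection_glm(t, phen)
        for name in res.params.index:
            r = partial_r_from_result(res, name)
            tt, df = float(res.tvalues[name]), float(res.df_resid)
            assert r**2 == pytest.approx(tt**2 / (tt**2 + df), abs=1e-10)

    def test_orthogonal_predictor_near_zero(self, small_phenotypes):
        phen = small_phenotypes
        rng = np.random.default_rng(8)
        t = pd.Series(rng.normal(size=len(phen)) + 4, index=phen.index)
        assert dc.effect_size_partial_r(t, phen, "openness") < 0.12

    def test_no_covariates_equals_pearson(self):
        rng = np.random.default_rng(9)
        x = pd.DataFrame({"x": rng.normal(size=100)})
        y = pd.Series(0.4 * x["x"] + rng.normal(size=100))
        r, _ = stats.pearsonr(x["x"], y)
        assert dc.effect_size_partial_r(y, x, "x", predictors=["x"]) == pytest.approx(
            abs(r), abs=1e-10
        )

    def test_planted_partial_r_recovered(self, small_phenotypes):
        """Direct regression oracle: T built to carry partial r = 0.13 at n = 613."""
        target = 0.13
        phen = pd.concat([small_phenotypes] * 2).iloc[:613]
        phen.index = [f"r{i}" for i in range(len(phen))]
        z = (phen["conscientiousness"] - 34.5) / 5.9
        lam = target / np.sqrt(1 - target**2)
        estimates = []
        for seed in range(50):
            rng = np.random.default_rng(100 + seed)
            t = pd.Series(10 - lam * z + rng.standard_normal(len(phen)), index=phen.index)
            estimates.append(dc.effect_size_partial_r(t, phen, "conscientiousness"))
        assert np.median(estimates) == pytest.approx(target, abs=0.05)


class TestRrmse:
    def test_perfect_predictions(self, small_phenotypes):
        phen = small_phenotypes
        t = pd.Series(
            10 + 0.1 * phen["age"].to_numpy(), index=phen.index
        )
        res = fit_connection_glm(t.iloc[:300], phen.iloc[:300], predictors=["age"])
        rrmse, klass = rrmse_on_test(res, phen.iloc[300:], t.iloc[300:])
        assert rrmse == pytest.approx(0.0, abs=1e-10)
        assert klass == "excellent"

    def test_class_boundaries(self):
        assert rrmse_class(0.05) == "excellent"
        assert rrmse_class(0.14) == "good"
        assert rrmse_class(0.25) == "fair"
        assert rrmse_class(0.35) == "poor"

    def test_intercept_only_closed_form(self):
        """Intercept-only model: RRMSE -> sd/mean of the test values."""
        rng = np.random.default_rng(10)
        n = 4000
        x = pd.DataFrame({"z": rng.normal(size=n)})
        t = pd.Series(np.abs(rng.normal(10, 1.5, size=n)))
        res = fit_connection_glm(t.iloc[:2000], x.iloc[:2000], predictors=[])
        rrmse, _ = rrmse_on_test(res, x.iloc[2000:], t.iloc[2000:])
        expected = t.iloc[2000:].std() / t.iloc[2000:].mean()
        assert rrmse == pytest.approx(expected, rel=0.05)

    def test_nonpositive_mean_rejected(self, small_phenotypes):
        phen = small_phenotypes
        t = pd.Series(np.ones(len(phen)), index=phen.index)
        t += 0.001 * np.arange(len(phen))
        res = fit_connection_glm(t.iloc[:300], phen.iloc[:300])
        with pytest.raises(ValueError, match="non-positive"):
            rrmse_on_test(res, phen.iloc[300:], -t.iloc[300:])


class TestTraitNuisance:
    def test_identity_and_negation(self, small_phenotypes):
        phen = small_phenotypes.assign(m=lambda d: d["conscientiousness"])
        r, _ = trait_nuisance_correlation(phen, "conscientiousness", "m")
        assert r == pytest.approx(1.0)
        phen["m"] = -phen["m"]
        r, _ = trait_nuisance_correlation(phen, "conscientiousness", "m")
        assert r == pytest.approx(-1.0)

    def test_independent_columns_small_r(self, small_phenotypes):
        r, p = trait_nuisance_correlation(small_phenotypes, "conscientiousness", "motion_rms")
        assert abs(r) < 0.15

    def test_constant_column_rejected(self, small_phenotypes):
        phen = small_phenotypes.assign(c=1.0)
        with pytest.raises(ValueError, match="constant"):
            trait_nuisance_correlation(phen, "conscientiousness", "c")


class TestRunAssociation:
    def test_tidy_output_and_family_structure(self, small_phenotypes):
        phen = small_phenotypes.iloc[:80]
        table = _random_tindex(80, 6, seed=11, index=list(phen.index))
        split, assoc = run_association(table, phen, seed=12)
        assert set(assoc["trait"]) == set(dc.TRAIT_COLUMNS)
        assert len(assoc) == 6 * 5
        # FDR applied within each trait family of 6 connections
        for trait, grp in assoc.groupby("trait"):
            np.testing.assert_allclose(
                np.sort(grp["p_fdr"]), np.sort(fdr_correct(grp["p"].to_numpy()))
            )
        assert (assoc["p_fdr"] >= assoc["p"] - 1e-15).all()
        assert assoc["effect_size"].between(0, 1).all()
        assert (assoc["rrmse"] >= 0).all()

    def test_models_fitted_on_train_rows_only(self, small_phenotypes):
        """Reported coefficients equal a manual refit restricted to train rows."""
        phen = small_phenotypes.iloc[:80]
        table = _random_tindex(80, 3, seed=13, index=list(phen.index))
        split, assoc = run_association(table, phen, seed=14)
        conn = table.columns[0]
        manual = fit_connection_glm(table.loc[split.train_ids, conn], phen.loc[split.train_ids])
        row = assoc[(assoc.connection == conn) & (assoc.trait == "openness")].iloc[0]
        assert row["beta"] == pytest.approx(float(manual.params["openness"]), rel=1e-12)
        assert row["p"] == pytest.approx(float(manual.pvalues["openness"]), rel=1e-12)
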