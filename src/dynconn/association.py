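"""Trait-connectivity association with matched train/test generalization.

Subjects are split 75/25 into train and test sets, re-drawn until no
connection's T-index distribution differs between the two sets by
Mann-Whitney U test (distribution matching). Per connection, an ordinary
least squares GLM regresses the T-index on the five personality traits plus
nuisance covariates (age, sex, education, handedness, intelligence); trait
p-values are Benjamini-Hochberg corrected across the family of connections
within each trait; effect sizes are absolute partial correlations (via the
t-statistic identity r^2 = t^2 / (t^2 + df)); and out-of-sample fit on the
untouched test set is scored by relative root-mean-square error,

    RRMSE = RMSE(observed, predicted) / mean(observed),

classed excellent (< 0.1), good (< 0.2), fair (< 0.3), poor otherwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .synthetic import COVARIATE_COLUMNS, TRAIT_COLUMNS

logger = logging.getLogger(__name__)

__all__ = [
    "SplitAssignment",
    "matched_split",
    "fit_connection_glm",
    "fdr_correct",
    "effect_size_partial_r",
    "rrmse_on_test",
    "rrmse_class",
    "trait_nuisance_correlation",
    "run_association",
]

RRMSE_THRESHOLDS = ((0.1, "excellent"), (0.2, "good"), (0.3, "fair"))


@dataclass
class SplitAssignment:
    """Accepted train/test partition with its per-connection match p-values."""

    train_ids: list[str]
    test_ids: list[str]
    match_pvalues: pd.Series
    n_resamples_used: int


def matched_split(
    tindex: pd.DataFrame,
    train_frac: float = 0.75,
    match_alpha: float = 0.05,
    max_resamples: int = 1000,
    seed: int = 0,
) -> SplitAssignment:
    """Draw random train/test partitions until every connection matches.

    A candidate partition (|train| = floor(train_frac * n)) is accepted when
    the Mann-Whitney U test comparing train vs test T-index values exceeds
    ``match_alpha`` for every connection. Deterministic given ``seed``.
    """
    n = tindex.shape[0]
    if n < 8:
        raise ValueError("need at least 8 subjects for a meaningful split")
    if tindex.isna().all(axis=0).any():
        bad = tindex.columns[tindex.isna().all(axis=0)].tolist()
        raise ValueError(f"connections with no valid T-index values: {bad}")
    n_train = int(np.floor(train_frac * n))
    if n_train < 4 or n - n_train < 4:
        raise ValueError("train_frac leaves too few subjects in one partition")

    rng = np.random.default_rng(seed)
    values = tindex.to_numpy(dtype=float)
    ids = np.asarray(tindex.index)
    worst_p, worst_conn = np.inf, None
    for attempt in range(1, max_resamples + 1):
        perm = rng.permutation(n)
        tr, te = perm[:n_train], perm[n_train:]
        if np.ptp(values[tr], axis=0).min() == 0 and np.ptp(values[te], axis=0).min() == 0:
            # fully tied columns: U test p-value is 1 by convention
            pvals = np.ones(values.shape[1])
        else:
            res = stats.mannwhitneyu(values[tr], values[te], axis=0, nan_policy="omit")
            pvals = np.atleast_1d(res.pvalue)
        if np.nanmin(pvals) > match_alpha:
            return SplitAssignment(
                train_ids=list(ids[np.sort(tr)]),
                test_ids=list(ids[np.sort(te)]),
                match_pvalues=pd.Series(pvals, index=tindex.columns, name="match_p"),
                n_resamples_used=attempt,
            )
        k = int(np.nanargmin(pvals))
        if pvals[k] < worst_p:
            worst_p, worst_conn = float(pvals[k]), tindex.columns[k]
    raise RuntimeError(
        f"no matched split found in {max_resamples} resamples; "
        f"worst-matched connection {worst_conn!r} (p = {worst_p:.2g})"
    )


def _default_predictors(phenotypes: pd.DataFrame) -> list[str]:
    standard = [c for c in TRAIT_COLUMNS + COVARIATE_COLUMNS if c in phenotypes.columns]
    if standard:
        return standard
    return [c for c in phenotypes.columns if c != "motion_rms"]


def _design_matrix(phenotypes: pd.DataFrame, predictors: list[str]) -> pd.DataFrame:
    X = sm.add_constant(phenotypes[predictors].astype(float), has_constant="add")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        collinear = []
        for col in predictors:
            others = X.drop(columns=[col]).to_numpy()
            beta, *_ = np.linalg.lstsq(others, X[col].to_numpy(), rcond=None)
            resid = X[col].to_numpy() - others @ beta
            if np.linalg.norm(resid) < 1e-8 * max(1.0, np.linalg.norm(X[col].to_numpy())):
                collinear.append(col)
        raise ValueError(f"design matrix rank-deficient; collinear columns: {collinear or 'const'}")
    return X


def fit_connection_glm(
    t_values: pd.Series,
    phenotypes: pd.DataFrame,
    predictors: list[str] | None = None,
) -> sm.regression.linear_model.RegressionResultsWrapper:
    """OLS of one connection's T-index on traits + nuisance covariates.

    Subjects with a missing T-index are dropped (complete-case). Returns the
    statsmodels results object (coefficients, two-sided t-test p-values).
    """
    predictors = predictors or _default_predictors(phenotypes)
    y = pd.Series(t_values).astype(float)
    keep = y.notna()
    if keep.sum() < len(predictors) + 3:
        raise ValueError("too few complete cases for the requested design")
    if keep.sum() < len(y):
        logger.info("dropping %d subjects with missing T-index", int((~keep).sum()))
    X = _design_matrix(phenotypes.loc[y.index[keep]], predictors)
    return sm.OLS(y[keep].to_numpy(), X).fit()


def fdr_correct(raw_pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment within one family of tests."""
    p = np.asarray(raw_pvalues, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def effect_size_partial_r(
    t_values: pd.Series,
    phenotypes: pd.DataFrame,
    predictor: str,
    predictors: list[str] | None = None,
) -> float:
    """|partial correlation| between the T-index and one predictor.

    Computed from the fitted GLM through r = t / sqrt(t^2 + df), controlling
    for every other predictor in the design.
    """
    res = fit_connection_glm(t_values, phenotypes, predictors=predictors)
    return abs(partial_r_from_result(res, predictor))


def partial_r_from_result(res, predictor: str) -> float:
    """Signed partial correlation of one coefficient via the t-statistic."""
    t = float(res.tvalues[predictor])
    df = float(res.df_resid)
    return t / np.sqrt(t * t + df)


def rrmse_class(rrmse: float) -> str:
    for cut, label in RRMSE_THRESHOLDS:
        if rrmse < cut:
            return label
    return "poor"


def rrmse_on_test(
    train_result,
    test_phenotypes: pd.DataFrame,
    test_t_values: pd.Series,
) -> tuple[float, str]:
    """Out-of-sample RRMSE of a train-fitted GLM on held-out subjects.

    Predictions use the train coefficients with the test subjects' phenotypes;
    RRMSE normalizes the RMSE by the mean observed test T-index.
    """
    y = pd.Series(test_t_values).astype(float)
    keep = y.notna()
    y = y[keep]
    cols = [c for c in train_result.model.exog_names if c != "const"]
    X = sm.add_constant(test_phenotypes.loc[y.index, cols].astype(float), has_constant="add")
    pred = np.asarray(train_result.predict(X[train_result.model.exog_names]))
    mean_obs = float(y.mean())
    if mean_obs <= 0:
        raise ValueError("mean observed T-index is non-positive; RRMSE undefined")
    rrmse = float(np.sqrt(np.mean((y.to_numpy() - pred) ** 2)) / mean_obs)
    return rrmse, rrmse_class(rrmse)


def trait_nuisance_correlation(
    phenotypes: pd.DataFrame, trait: str, nuisance_column: str
) -> tuple[float, float]:
    """Pearson correlation (r, two-sided p) between a trait and a nuisance measure."""
    x = phenotypes[trait].astype(float).to_numpy()
    y = phenotypes[nuisance_column].astype(float).to_numpy()
    if x.size < 3:
        raise ValueError("need at least 3 subjects")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant column")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def run_association(
    tindex: pd.DataFrame,
    phenotypes: pd.DataFrame,
    train_frac: float = 0.75,
    match_alpha: float = 0.05,
    max_resamples: int = 1000,
    fdr_alpha: float = 0.05,
    pooled_fdr: bool = False,
    seed: int = 0,
) -> tuple[SplitAssignment, pd.DataFrame]:
    """Full association stage: matched split, per-connection GLMs, FDR, RRMSE.

    Returns the split and a tidy frame with one row per (connection, trait):
    coefficient, raw and FDR-adjusted p, |partial r| effect size, significance
    flag, and the connection's test-set RRMSE and class. The FDR family is the
    set of connections within each trait (``pooled_fdr=True`` pools all
    trait-connection tests into one family instead).
    """
    split = matched_split(
        tindex,
        train_frac=train_frac,
        match_alpha=match_alpha,
        max_resamples=max_resamples,
        seed=seed,
    )
    predictors = _default_predictors(phenotypes)
    traits = [c for c in TRAIT_COLUMNS if c in predictors]
    rows = []
    for conn in tindex.columns:
        i, j = (int(v) for v in conn.split("_"))
        res = fit_connection_glm(
            tindex.loc[split.train_ids, conn], phenotypes.loc[split.train_ids], predictors
        )
        rrmse, klass = rrmse_on_test(
            res, phenotypes.loc[split.test_ids], tindex.loc[split.test_ids, conn]
        )
        for trait in traits:
            rows.append(
                {
                    "connection": conn,
                    "node_i": i,
                    "node_j": j,
                    "trait": trait,
                    "beta": float(res.params[trait]),
                    "p": float(res.pvalues[trait]),
                    "effect_size": abs(partial_r_from_result(res, trait)),
                    "rrmse": rrmse,
                    "rrmse_class": klass,
                }
            )
    table = pd.DataFrame(rows)
    if pooled_fdr:
        table["p_fdr"] = fdr_correct(table["p"].to_numpy())
    else:
        table["p_fdr"] = np.nan
        for trait in traits:
            mask = table["trait"] == trait
            table.loc[mask, "p_fdr"] = fdr_correct(table.loc[mask, "p"].to_numpy())
    table["significant"] = table["p_fdr"] < fdr_alpha
    order = [
        "connection", "node_i", "node_j", "trait", "beta", "p", "p_fdr",
        "effect_size", "significant", "rrmse", "rrmse_class",
    ]
    return split, table[order]
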