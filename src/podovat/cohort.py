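"""Cohort statistics: group comparisons, ANCOVA, matching, regression.

Implements the statistical workflow of the post-nephrectomy cohort
analysis: Levene-gated t tests for continuous variables, rank-sum tests
for ordinal histopathology scores, Pearson chi-square for nominal data,
ANCOVA with estimated marginal means (BMI and age as covariates), 1:1
nearest-neighbour propensity matching on BMI, and standardized linear
regression of renal compensation (ΔeGFR and relative ΔeGFR) on the
morphometric predictors with four prespecified adjustment sets.

Conventions: SDs use the n−1 convention; VAT enters regression models
log-transformed; every model variable is z-scored to mean 0 / unit
variance, so the unadjusted standardized β equals the Pearson
correlation; missing follow-up is handled by complete-case exclusion,
never imputation; no multiple-testing correction is applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "GroupComparison",
    "AncovaResult",
    "MatchResult",
    "RegressionResult",
    "DiagnosticReport",
    "MODEL_COVARIATES",
    "delta_egfr",
    "compare_groups",
    "ancova_emm",
    "propensity_match",
    "standardized_regression",
    "residual_diagnostics",
    "zscore",
]

#: Adjustment sets of the four prespecified regression models.
MODEL_COVARIATES: dict[str, tuple[str, ...]] = {
    "unadjusted": (),
    "1": ("log_vat", "bmi"),
    "2": ("log_vat", "hypertension", "diabetes", "age", "sex_female"),
    "3": ("height_adj_kidney_volume", "egfr_baseline"),
    "4": (
        "score_mesangial_expansion",
        "score_interstitial_fibrosis",
        "score_arteriolar_hyalinosis",
        "score_intimal_fibrosis",
        "score_tubular_atrophy",
    ),
}


def delta_egfr(baseline, followup) -> tuple:
    """Absolute and relative eGFR change from baseline to follow-up.

    ``delta = followup - baseline`` (signed; negative means loss) and
    ``relative = 100 * delta / baseline`` in %.  Accepts scalars or
    arrays; baseline must be strictly positive.
    """
    baseline_arr = np.asarray(baseline, dtype=float)
    followup_arr = np.asarray(followup, dtype=float)
    if np.any(baseline_arr <= 0):
        raise ValueError("baseline eGFR must be > 0")
    delta = followup_arr - baseline_arr
    relative = 100.0 * delta / baseline_arr
    if np.isscalar(baseline) and np.isscalar(followup):
        return float(delta), float(relative)
    return delta, relative


def zscore(values: np.ndarray) -> np.ndarray:
    """Standardize to mean 0 and unit variance (SD with ddof=1)."""
    values = np.asarray(values, dtype=float)
    sd = values.std(ddof=1)
    if sd == 0:
        raise ValueError("cannot standardize a constant column")
    return (values - values.mean()) / sd


@dataclass
class GroupComparison:
    mode: str
    test_name: str
    statistic: float
    p_value: float
    group_summaries: pd.DataFrame
    levene_p: Optional[float] = None


def compare_groups(values, group, mode: str = "continuous",
                   levene_alpha: float = 0.05) -> GroupComparison:
    """Two-group comparison with the test chosen by measurement level.

    ``continuous``: Levene's test (center='mean') gates between the
    pooled-variance and the unequal-variance (Welch) t test at
    ``levene_alpha``.  ``ordinal``: Wilcoxon rank-sum (Mann-Whitney U,
    mid-rank ties).  ``nominal``: Pearson chi-square on the
    contingency table, without continuity correction.
    """
    values = np.asarray(values)
    group = np.asarray(group)
    if values.shape != group.shape:
        raise ValueError("values and group must have equal length")
    keep = ~pd.isna(values)
    values, group = values[keep], group[keep]
    levels = np.unique(group)
    if levels.size != 2:
        raise ValueError(f"expected exactly 2 groups, got {levels.size}")
    a = values[group == levels[0]]
    b = values[group == levels[1]]
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")

    if mode == "continuous":
        if min(a.size, b.size) < 2:
            raise ValueError("continuous comparison needs >= 2 observations per group")
        a = a.astype(float)
        b = b.astype(float)
        _, levene_p = stats.levene(a, b, center="mean")
        equal_var = levene_p >= levene_alpha
        stat, p = stats.ttest_ind(a, b, equal_var=equal_var)
        name = "t (pooled)" if equal_var else "t (Welch)"
        summary = pd.DataFrame({
            "group": levels, "n": [a.size, b.size],
            "mean": [a.mean(), b.mean()],
            "sd": [a.std(ddof=1), b.std(ddof=1)],
        })
        return GroupComparison("continuous", name, float(stat), float(p), summary, float(levene_p))
    if mode == "ordinal":
        a = a.astype(float)
        b = b.astype(float)
        stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        summary = pd.DataFrame({
            "group": levels, "n": [a.size, b.size],
            "median": [np.median(a), np.median(b)],
            "q1": [np.percentile(a, 25), np.percentile(b, 25)],
            "q3": [np.percentile(a, 75), np.percentile(b, 75)],
        })
        return GroupComparison("ordinal", "Wilcoxon rank-sum", float(stat), float(p), summary)
    if mode == "nominal":
        table = pd.crosstab(group, values)
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        return GroupComparison("nominal", "chi-square", float(chi2), float(p),
                               table.reset_index())
    raise ValueError(f"unknown mode {mode!r}")


@dataclass
class AncovaResult:
    emms: pd.DataFrame  # group, emm, ci_low, ci_high
    p_group: float
    p_covariates: dict[str, float]
    model: object = field(repr=False)


def ancova_emm(df: pd.DataFrame, outcome: str, group: str,
               covariates: Sequence[str] = ("bmi", "age")) -> AncovaResult:
    """ANCOVA ``outcome ~ group + covariates`` with estimated marginal means.

    EMMs are model predictions per group at the covariate grand means,
    with 95% confidence intervals from the coefficient covariance; the
    group p-value is the Wald test of the group term.
    """
    cols = [outcome, group, *covariates]
    data = df[cols].dropna()
    X = pd.DataFrame({group: data[group].astype(float)})
    for cov in covariates:
        X[cov] = data[cov].astype(float)
    X = sm.add_constant(X)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        for col in [group, *covariates]:
            reduced = X.drop(columns=col)
            if np.linalg.matrix_rank(reduced.to_numpy()) == np.linalg.matrix_rank(X.to_numpy()):
                raise ValueError(f"design matrix is rank deficient: column {col!r} is collinear")
        raise ValueError("design matrix is rank deficient")
    fit = sm.OLS(data[outcome].astype(float), X).fit()

    grand = {cov: float(data[cov].astype(float).mean()) for cov in covariates}
    rows = []
    for level in sorted(data[group].unique()):
        point = pd.DataFrame(
            {"const": [1.0], group: [float(level)], **{c: [grand[c]] for c in covariates}}
        )[X.columns]
        pred = fit.get_prediction(point)
        ci = pred.conf_int(alpha=0.05)[0]
        rows.append({"group": level, "emm": float(pred.predicted_mean[0]),
                     "ci_low": float(ci[0]), "ci_high": float(ci[1])})
    return AncovaResult(
        emms=pd.DataFrame(rows),
        p_group=float(fit.pvalues[group]),
        p_covariates={c: float(fit.pvalues[c]) for c in covariates},
        model=fit,
    )


@dataclass
class MatchResult:
    pairs: list[tuple]  # (treated index, control index)
    matched: pd.DataFrame
    balance_before: GroupComparison
    balance_after: GroupComparison


def propensity_match(df: pd.DataFrame, group: str = "vo",
                     covariates: Sequence[str] = ("bmi",),
                     seed: int = 0) -> MatchResult:
    """1:1 nearest-neighbour propensity matching without replacement.

    A logistic model of group membership on the score covariates (BMI
    by default) yields propensity scores; members of the smaller group,
    taken in a seeded random order, each greedily claim the nearest
    unused partner from the larger group (no caliper, ties broken by
    the shuffled order).  Yields ``min(n_treated, n_control)`` pairs
    and t-test balance checks on the first covariate before and after.
    """
    data = df.dropna(subset=[group, *covariates])
    g = data[group].astype(int).to_numpy()
    if (g == 1).sum() < 1 or (g == 0).sum() < 1:
        raise ValueError("both groups must be non-empty for matching")
    X = sm.add_constant(data[list(covariates)].astype(float))
    ps = sm.Logit(g, X).fit(disp=0).predict(X)
    ps = np.asarray(ps)

    rng = np.random.default_rng(seed)
    treated = np.flatnonzero(g == 1)
    controls = np.flatnonzero(g == 0)
    # iterate the limiting group so every pair is a genuine nearest match
    small, large = ((treated, controls) if treated.size <= controls.size
                    else (controls, treated))
    order = small[rng.permutation(small.size)]
    pool = list(large)
    pairs: list[tuple] = []
    for s in order:
        if not pool:
            break
        j = int(np.argmin(np.abs(ps[pool] - ps[s])))
        partner = pool.pop(j)
        t, c = (s, partner) if g[s] == 1 else (partner, s)
        pairs.append((data.index[t], data.index[c]))
    matched_idx = [i for pair in pairs for i in pair]
    matched = data.loc[matched_idx]

    bal_col = covariates[0]
    before = compare_groups(data[bal_col].to_numpy(), g, mode="continuous")
    after = compare_groups(matched[bal_col].to_numpy(),
                           matched[group].astype(int).to_numpy(), mode="continuous")
    return MatchResult(pairs=pairs, matched=matched,
                       balance_before=before, balance_after=after)


@dataclass
class RegressionResult:
    standardized_beta: float
    p_value: float
    model_id: str
    predictor: str
    outcome: str
    n: int
    fit: object = field(repr=False, default=None)


def _prepare_outcome(df: pd.DataFrame, outcome: str) -> pd.Series:
    if outcome in df.columns:
        return df[outcome].astype(float)
    if outcome in ("delta_egfr", "relative_delta_egfr"):
        sub = df.dropna(subset=["egfr_baseline", "egfr_12m"])
        delta, rel = delta_egfr(sub["egfr_baseline"].to_numpy(),
                                sub["egfr_12m"].to_numpy())
        return pd.Series(delta if outcome == "delta_egfr" else rel, index=sub.index)
    raise KeyError(f"unknown outcome {outcome!r}")


def standardized_regression(df: pd.DataFrame, predictor: str,
                            outcome: str = "delta_egfr",
                            model: str = "unadjusted") -> RegressionResult:
    """OLS of a z-scored outcome on z-scored predictor + adjustment set.

    ``model`` selects one of the prespecified adjustment sets in
    :data:`MODEL_COVARIATES` ('unadjusted', '1'..'4').  VAT enters as
    log(VAT) before standardization.  All variables (including binary
    and ordinal adjusters) are z-scored with ddof=1, so the returned
    coefficient is the standardized β — for the unadjusted model it
    equals the Pearson correlation between outcome and predictor.
    Complete-case analysis over the model's columns.
    """
    if model not in MODEL_COVARIATES:
        raise ValueError(f"unknown model {model!r}; choose from {sorted(MODEL_COVARIATES)}")
    covariates = MODEL_COVARIATES[model]
    work = df.copy()
    if "log_vat" in covariates and "log_vat" not in work.columns:
        work["log_vat"] = np.log(work["vat_cm2"].astype(float))
    y = _prepare_outcome(work, outcome)
    cols = [predictor, *covariates]
    data = work.loc[y.index, cols].astype(float).join(y.rename("_y")).dropna()
    n, p = data.shape[0], len(cols) + 1
    if n <= p:
        raise ValueError(f"n = {n} observations cannot identify {p} parameters")
    Z = pd.DataFrame({c: zscore(data[c].to_numpy()) for c in cols}, index=data.index)
    fit = sm.OLS(zscore(data["_y"].to_numpy()), sm.add_constant(Z)).fit()
    return RegressionResult(
        standardized_beta=float(fit.params[predictor]),
        p_value=float(fit.pvalues[predictor]),
        model_id=model, predictor=predictor, outcome=outcome, n=n, fit=fit,
    )


@dataclass
class DiagnosticReport:
    table: pd.DataFrame  # fitted, residual, theoretical normal quantile
    max_residual_index: int
    tercile_spread_ratio: float
    heteroscedastic: bool
    loo_beta_delta: Optional[float] = None


def residual_diagnostics(fit, spread_flag_ratio: float = 2.0) -> DiagnosticReport:
    """Tabular residual diagnostics for a fitted OLS model.

    Returns residual-vs-fitted values with theoretical normal
    quantiles, flags the largest-|residual| observation, compares the
    residual spread (SD) between the lowest and highest fitted-value
    terciles, and reports how much the first non-intercept coefficient
    moves when the model is refitted without the worst point
    (leave-one-out sensitivity).
    """
    fitted = np.asarray(fit.fittedvalues, dtype=float)
    resid = np.asarray(fit.resid, dtype=float)
    order = np.argsort(np.argsort(resid))
    n = resid.size
    theo = stats.norm.ppf((order + 0.5) / n)
    table = pd.DataFrame({"fitted": fitted, "residual": resid, "normal_quantile": theo})
    worst = int(np.argmax(np.abs(resid)))

    terciles = np.quantile(fitted, [1 / 3, 2 / 3])
    lo = resid[fitted <= terciles[0]]
    hi = resid[fitted >= terciles[1]]
    if lo.size >= 2 and hi.size >= 2 and min(lo.std(ddof=1), hi.std(ddof=1)) > 0:
        ratio = max(lo.std(ddof=1), hi.std(ddof=1)) / min(lo.std(ddof=1), hi.std(ddof=1))
    else:
        ratio = 1.0

    loo_delta = None
    exog = np.asarray(fit.model.exog, dtype=float)
    endog = np.asarray(fit.model.endog, dtype=float)
    if exog.shape[1] >= 2 and n - 1 > exog.shape[1]:
        keep = np.ones(n, dtype=bool)
        keep[worst] = False
        refit = sm.OLS(endog[keep], exog[keep]).fit()
        loo_delta = float(refit.params[1] - fit.params[1])
    return DiagnosticReport(
        table=table,
        max_residual_index=worst,
        tercile_spread_ratio=float(ratio),
        heteroscedastic=bool(ratio > spread_flag_ratio),
        loo_beta_delta=loo_delta,
    )
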