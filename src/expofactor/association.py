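"""Association models for exposome factor scores.

Standardized linear regression (with adjusted-R^2 change when the
factor scores enter), binary logistic regression with Wald CIs,
Bonferroni-corrected demographic contrasts with Cohen's d, and a
site/family random-intercept sensitivity model.  All models use
listwise deletion and report the n actually used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats


@dataclass
class RegressionResult:
    beta: pd.Series
    se: pd.Series
    pvalues: pd.Series
    r2: float
    adj_r2: float
    n: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"beta": self.beta, "se": self.se, "p": self.pvalues})


@dataclass
class DeltaR2Result:
    adj_r2_base: float
    adj_r2_full: float
    delta: float
    ratio: float
    n: int


@dataclass
class LogisticResult:
    odds_ratio: pd.Series
    ci_low: pd.Series
    ci_high: pd.Series
    pvalues: pd.Series
    n: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"OR": self.odds_ratio, "ci_low": self.ci_low,
             "ci_high": self.ci_high, "p": self.pvalues}
        )


@dataclass
class ContrastResult:
    mean_1: float
    mean_2: float
    t_stat: float
    p_raw: float
    p_adjusted: float
    cohens_d: float
    n_1: int
    n_2: int


@dataclass
class MixedResult:
    fixed_effects: pd.Series
    se: pd.Series
    var_site: float
    var_family: float
    var_residual: float
    n: int


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    if sd <= 0:
        raise ValueError("zero-variance column cannot be standardized")
    return (x - x.mean()) / sd


def _design(y, predictors: pd.DataFrame, covariates: pd.DataFrame | None,
            standardize: bool):
    X = predictors.copy()
    if covariates is not None:
        overlap = set(X.columns) & set(covariates.columns)
        if overlap:
            raise ValueError(f"predictors duplicated in covariates: {sorted(overlap)}")
        X = pd.concat([X, covariates], axis=1)
    frame = pd.concat([pd.Series(np.asarray(y, float), index=X.index, name="_y"), X],
                      axis=1).dropna()
    yv = frame["_y"].to_numpy()
    Xv = frame.drop(columns="_y")
    if standardize:
        yv = _zscore(yv)
        Xv = Xv.apply(lambda c: _zscore(c.to_numpy()) if c.nunique() > 1 else c)
    Xd = sm.add_constant(Xv.to_numpy(float), has_constant="add")
    rank = np.linalg.matrix_rank(Xd)
    if rank < Xd.shape[1]:
        # name the columns involved in the deficiency
        bad = []
        base = sm.add_constant(np.empty((len(frame), 0)))
        cols_so_far = base
        for name in Xv.columns:
            cand = np.column_stack([cols_so_far, Xv[name].to_numpy(float)])
            if np.linalg.matrix_rank(cand) == cols_so_far.shape[1]:
                bad.append(name)
            else:
                cols_so_far = cand
        raise ValueError(f"design matrix rank-deficient; collinear columns: {bad}")
    return yv, Xd, list(Xv.columns), len(frame)


def standardized_linear_model(y, predictors: pd.DataFrame,
                              covariates: pd.DataFrame | None = None
                              ) -> RegressionResult:
    """OLS on z-scored outcome and predictors -> standardized betas."""
    yv, Xd, names, n = _design(y, predictors, covariates, standardize=True)
    fit = sm.OLS(yv, Xd).fit()
    idx = ["const"] + names
    return RegressionResult(
        beta=pd.Series(fit.params, index=idx).drop("const"),
        se=pd.Series(fit.bse, index=idx).drop("const"),
        pvalues=pd.Series(fit.pvalues, index=idx).drop("const"),
        r2=float(fit.rsquared),
        adj_r2=float(fit.rsquared_adj),
        n=n,
    )


def delta_r2(y, base_covariates: pd.DataFrame, added_predictors: pd.DataFrame
             ) -> DeltaR2Result:
    """Adjusted-R^2 change when predictors join a covariate-only model.

    Both fits use the intersection of listwise-complete rows, so the
    comparison is on identical data.
    """
    overlap = set(base_covariates.columns) & set(added_predictors.columns)
    if overlap:
        raise ValueError(f"added predictors already in base model: {sorted(overlap)}")
    frame = pd.concat(
        [pd.Series(np.asarray(y, float), index=added_predictors.index, name="_y"),
         base_covariates, added_predictors], axis=1).dropna()
    yv = frame["_y"]
    base_cols = list(base_covariates.columns)
    if base_cols:
        base = standardized_linear_model(yv, frame[base_cols])
        adj_base = base.adj_r2
    else:
        adj_base = 0.0
    full = standardized_linear_model(
        yv, frame[list(added_predictors.columns)],
        frame[base_cols] if base_cols else None)
    adj_full = full.adj_r2
    ratio = adj_full / adj_base if adj_base > 0 else np.inf
    return DeltaR2Result(adj_base, adj_full, adj_full - adj_base, ratio,
                         n=len(frame))


def logistic_model(binary_y, predictors: pd.DataFrame,
                   covariates: pd.DataFrame | None = None) -> LogisticResult:
    """ML logistic regression; OR = exp(beta) with Wald 95% CIs."""
    yv, Xd, names, n = _design(binary_y, predictors, covariates,
                               standardize=False)
    classes = np.unique(yv)
    if classes.size != 2:
        raise ValueError("outcome must have exactly two classes")
    yb = (yv == classes.max()).astype(float)
    fit = sm.Logit(yb, Xd).fit(disp=0, maxiter=200)
    params = pd.Series(fit.params, index=["const"] + names)
    if np.any(np.abs(params.drop("const")) > 15):
        raise ValueError(
            "separation detected (diverging coefficient); consider a "
            "penalized fit")
    se = pd.Series(fit.bse, index=["const"] + names)
    z = stats.norm.ppf(0.975)
    return LogisticResult(
        odds_ratio=np.exp(params.drop("const")),
        ci_low=np.exp(params.drop("const") - z * se.drop("const")),
        ci_high=np.exp(params.drop("const") + z * se.drop("const")),
        pvalues=pd.Series(fit.pvalues, index=["const"] + names).drop("const"),
        n=n,
    )


def group_contrast(score, group, m_comparisons: int = 7) -> ContrastResult:
    """Welch t-test with pooled-SD Cohen's d and Bonferroni adjustment.

    d is signed group1 - group2 where group1 is the higher group label.
    """
    score = np.asarray(score, float)
    group = np.asarray(group)
    mask = ~np.isnan(score)
    score, group = score[mask], group[mask]
    labels = np.unique(group)
    if labels.size != 2:
        raise ValueError("group label must have exactly two levels")
    x1 = score[group == labels[1]]
    x2 = score[group == labels[0]]
    if len(x1) < 2 or len(x2) < 2:
        raise ValueError("both groups need at least 2 observations")
    t_res = stats.ttest_ind(x1, x2, equal_var=False)
    n1, n2 = len(x1), len(x2)
    pooled = np.sqrt(((n1 - 1) * x1.var(ddof=1) + (n2 - 1) * x2.var(ddof=1))
                     / (n1 + n2 - 2))
    d = (x1.mean() - x2.mean()) / pooled if pooled > 0 else 0.0
    p_adj = min(1.0, m_comparisons * float(t_res.pvalue))
    return ContrastResult(
        mean_1=float(x1.mean()), mean_2=float(x2.mean()),
        t_stat=float(t_res.statistic), p_raw=float(t_res.pvalue),
        p_adjusted=p_adj, cohens_d=float(d), n_1=n1, n_2=n2,
    )


def cluster_random_intercept_model(y, predictors: pd.DataFrame,
                                   site_id, family_id) -> MixedResult:
    """Linear mixed model with site and family random intercepts (REML).

    Families are treated as nested within site: the site grouping
    carries a random intercept and family enters as a variance
    component within site.
    """
    frame = predictors.copy()
    frame["_y"] = np.asarray(y, float)
    frame["_site"] = np.asarray(site_id)
    frame["_family"] = np.asarray(family_id)
    frame = frame.dropna()
    pred_cols = list(predictors.columns)
    formula = "_y ~ " + (" + ".join(f"Q('{c}')" for c in pred_cols) or "1")
    model = sm.MixedLM.from_formula(
        formula, groups="_site", re_formula="1",
        vc_formula={"family": "0 + C(_family)"}, data=frame,
    )
    try:
        fit = model.fit(reml=True, method="powell", maxiter=2000)
    except Exception as exc:  # pragma: no cover - rare numeric failure
        raise RuntimeError(f"mixed model failed to converge: {exc}") from exc
    if not fit.converged:
        raise RuntimeError("mixed model failed to converge; "
                           f"loglike trace ended at {fit.llf:.4f}")
    params = fit.fe_params.copy()
    params.index = ["const"] + pred_cols
    se = fit.bse_fe.copy()
    se.index = ["const"] + pred_cols
    var_site = float(np.asarray(fit.cov_re)[0, 0])
    var_family = float(fit.vcomp[0]) if len(fit.vcomp) else 0.0
    return MixedResult(
        fixed_effects=params.drop("const"), se=se.drop("const"),
        var_site=var_site, var_family=var_family,
        var_residual=float(fit.scale), n=len(frame),
    )
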