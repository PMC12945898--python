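"""Association analyses: correlations, random-intercept models, part R².

The inferential stage relates the subject-level accumulation measures
(EEA, SEA, DDM drift) to criterion scores while respecting nesting
(subjects within families, families within sites) through linear mixed
models with random intercepts.  The unique contribution of a predictor set
is quantified as semipartial (part) marginal R²: the marginal R² of the
full model minus that of the model with the set removed, with a percentile
bootstrap over top-level groups for the confidence interval.

Marginal R² follows the fixed-effects-variance convention:

    R²_marginal = var(X beta) / (var(X beta) + sum(variance components)
                                 + residual variance)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.tools.sm_exceptions import ConvergenceWarning


@dataclass
class Correlation:
    r: float
    n: int
    p: float


def pearson_r(x, y) -> Correlation:
    """Product-moment correlation over complete pairs.

    Zero variance in either variable makes the estimate undefined
    (returned as NaN).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        return Correlation(float("nan"), n, float("nan"))
    r, p = sps.pearsonr(x, y)
    return Correlation(float(r), n, float(p))


@dataclass
class MixedFit:
    """Random-intercept model fit: fixed effects plus variance components."""

    outcome: str
    predictors: list[str]
    groups: list[str]
    fe_params: pd.Series
    vc: dict[str, float]  # group label -> intercept variance
    resid_var: float
    fitted_fixed: np.ndarray
    marginal_r2: float
    singular: bool
    n: int


def _ols_fit(df: pd.DataFrame, outcome: str, predictors: list[str],
             groups: list[str]) -> MixedFit:
    X = sm.add_constant(df[predictors], has_constant="add")
    res = sm.OLS(df[outcome], X).fit()
    fitted = np.asarray(X @ res.params)
    var_f = float(np.var(fitted))
    resid = float(res.scale)
    return MixedFit(
        outcome=outcome, predictors=list(predictors), groups=list(groups),
        fe_params=res.params, vc={g: 0.0 for g in groups},
        resid_var=resid, fitted_fixed=fitted,
        marginal_r2=var_f / (var_f + resid) if var_f + resid > 0 else 0.0,
        singular=False, n=len(df),
    )


def fit_random_intercept_model(df: pd.DataFrame, outcome: str,
                               predictors, groups=()) -> MixedFit:
    """REML fit of ``outcome ~ predictors + (1 | g)`` for each factor g.

    Grouping factors with fewer than two observed levels are dropped (the
    random intercept is not identified); with no usable factors the model
    degenerates to ordinary least squares.  A variance component driven to
    zero is reported as 0 with ``singular=True``.
    """
    predictors = list(predictors)
    groups = [g for g in groups
              if g in df.columns and df[g].nunique() >= 2]
    cols = [outcome] + predictors + groups
    data = df[cols].dropna().reset_index(drop=True)
    if not groups:
        return _ols_fit(data, outcome, predictors, groups)

    endog = data[outcome].to_numpy(dtype=float)
    exog = sm.add_constant(data[predictors], has_constant="add")
    if len(groups) == 1:
        model = MixedLM(endog, np.asarray(exog), groups=data[groups[0]])
    else:
        # crossed/nested factors via variance components on a single group
        vcf = {g: f"0 + C({g})" for g in groups}
        model = MixedLM.from_formula(
            f"{outcome} ~ " + " + ".join(predictors) if predictors
            else f"{outcome} ~ 1",
            data=data,
            groups=np.ones(len(data)),
            vc_formula=vcf,
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", UserWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        try:
            res = model.fit(reml=True, maxiter=200)
        except Exception:
            try:
                res = model.fit(reml=True, method="powell", maxiter=500)
            except Exception:
                # degenerate design (e.g. as many groups as rows): report
                # the fixed effects from OLS with components pinned at 0
                fallback = _ols_fit(data, outcome, predictors, groups)
                fallback.singular = True
                return fallback

    names = ["const"] + predictors
    fe = pd.Series(np.asarray(res.fe_params)[: len(names)], index=names)
    fitted = np.asarray(sm.add_constant(data[predictors],
                                        has_constant="add") @ fe)
    if len(groups) == 1:
        raw = float(np.asarray(res.cov_re)[0, 0]) if res.cov_re.size else 0.0
        vc_vals = {groups[0]: raw}
    else:
        vc_vals = {g: float(res.vcomp[i]) for i, g in enumerate(groups)}
    vc_vals = {g: max(v, 0.0) for g, v in vc_vals.items()}
    singular = any(v <= 1e-10 for v in vc_vals.values())
    resid = float(res.scale)
    var_f = float(np.var(fitted))
    denom = var_f + sum(vc_vals.values()) + resid
    return MixedFit(
        outcome=outcome, predictors=predictors, groups=groups,
        fe_params=fe, vc=vc_vals, resid_var=resid, fitted_fixed=fitted,
        marginal_r2=var_f / denom if denom > 0 else 0.0,
        singular=singular, n=len(data),
    )


@dataclass
class PartR2:
    estimate: float
    lo: float
    hi: float
    n_boot: int
    floored: bool = False


def _part_r2_point(df, outcome, predictors, part, groups) -> tuple[float, bool]:
    part = [part] if isinstance(part, str) else list(part)
    missing = [p for p in part if p not in predictors]
    if missing:
        raise ValueError(f"{missing} not among the model predictors")
    full = fit_random_intercept_model(df, outcome, predictors, groups)
    reduced_preds = [p for p in predictors if p not in part]
    reduced = fit_random_intercept_model(df, outcome, reduced_preds, groups)
    diff = full.marginal_r2 - reduced.marginal_r2
    return (max(diff, 0.0), diff < 0.0)


def part_r2(df: pd.DataFrame, outcome: str, predictors, part,
            groups=(), n_boot: int = 1000, seed=None,
            resample: str = "groups") -> PartR2:
    """Semipartial marginal R² of ``part`` with a bootstrap 95% CI.

    The point estimate is the drop in marginal R² when ``part`` is removed
    from the full model (floored at 0 when refit noise makes it negative).
    The bootstrap resamples top-level groups (the first factor in
    ``groups``) to respect nesting; ``resample="subjects"`` switches to
    plain row resampling.
    """
    predictors = list(predictors)
    est, floored = _part_r2_point(df, outcome, predictors, part, groups)
    rng = np.random.default_rng(seed)
    boots = []
    group_col = groups[0] if (groups and resample == "groups"
                              and groups[0] in df.columns) else None
    for _ in range(n_boot):
        if group_col is not None:
            levels = df[group_col].unique()
            pick = rng.choice(levels, size=len(levels), replace=True)
            parts = [df[df[group_col] == lv] for lv in pick]
            samp = pd.concat(parts, ignore_index=True)
        else:
            samp = df.sample(n=len(df), replace=True,
                             random_state=int(rng.integers(2**31 - 1)))
        try:
            b, _ = _part_r2_point(samp, outcome, predictors, part, groups)
        except Exception:
            continue
        boots.append(b)
    if boots:
        lo, hi = np.percentile(boots, [2.5, 97.5])
    else:
        lo = hi = float("nan")
    return PartR2(est, float(lo), float(hi), len(boots), floored)


def correlation_table(measures: pd.DataFrame,
                      target: str = "v_mean") -> pd.DataFrame:
    """Correlations of EEA and SEA with the DDM drift, per task."""
    rows = []
    for task, sub in measures.groupby("task"):
        for pred in ("EEA", "SEA"):
            c = pearson_r(sub[pred], sub[target])
            rows.append({"task": task, "predictor": pred, "target": target,
                         "r": c.r, "n": c.n, "p": c.p})
    return pd.DataFrame(rows)


def association_table(data: pd.DataFrame, criteria, groups=(),
                      predictors=("EEA", "SEA"), n_boot: int = 1000,
                      seed=None) -> pd.DataFrame:
    """Variance explained in each criterion by each predictor (with CIs).

    ``data`` holds one row per subject with the predictors, the criterion
    columns and any nesting columns; both predictors enter each mixed
    model simultaneously and each one's unique contribution is its
    semipartial marginal R².
    """
    rng = np.random.default_rng(seed)
    rows = []
    predictors = list(predictors)
    for crit in criteria:
        for pred in predictors:
            pr = part_r2(data, crit, predictors, pred, groups,
                         n_boot=n_boot, seed=rng)
            rows.append(
                {
                    "criterion": crit,
                    "predictor": pred,
                    "part_r2": pr.estimate,
                    "ci_lo": pr.lo,
                    "ci_hi": pr.hi,
                    "n_boot": pr.n_boot,
                }
            )
    return pd.DataFrame(rows)
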