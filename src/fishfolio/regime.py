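"""Pre/post regime-shift revenue responses and the diversity regressions.

For each community the response to the regime shift is the percent change in
mean annual real revenue between a pre window (1980-1989 by default; the
shift year belongs to the pre period) and a post window (1990-1999).  The
same percent change on total pounds landed gives the catch response.

Two regressions relate the revenue response to portfolio structure:

* a log-linear model, pct_change ~ log(diversity), where diversity is the
  revenue-weighted reciprocal Simpson index over the pre window; and
* an interaction model, pct_change ~ diversity + turnover +
  diversity:turnover, with standardized effect sizes obtained by refitting
  on z-scored covariates (interaction = product of the z-scores).

A supplementary check regresses revenue change on catch change, price change
and their product.  All fits are ordinary least squares (statsmodels) with
two-sided t-test p-values and no multiple-testing correction.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .metrics import community_turnover, diversity_table


@dataclasses.dataclass
class RegressionResult:
    """A fitted OLS model in portable form."""

    formula: str
    coefficients: dict
    std_effects: dict
    r_squared: float
    p_values: dict
    n: int
    residual_sd: float
    conf_int: dict  # 95% CI per coefficient, (lo, hi)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def percent_change(pre_values, post_values) -> float:
    """100 * (mean(post) - mean(pre)) / mean(pre); the pre mean must be positive."""
    pre = np.asarray(pre_values, dtype=float)
    post = np.asarray(post_values, dtype=float)
    pre_mean = pre.mean()
    if pre_mean <= 0:
        raise ValueError("pre-period mean must be positive")
    return float(100.0 * (post.mean() - pre_mean) / pre_mean)


def build_responses(
    records: pd.DataFrame,
    pre,
    post,
    communities=None,
    turnover_value: str = "pounds",
    jaccard_variant: str = "ruzicka",
    weighting: str = "weighted",
) -> pd.DataFrame:
    """Assemble the per-community response table feeding the regressions.

    One row per community: mean pre/post revenue, percent changes in revenue
    and catch, pre-window diversity, and pre-vs-post turnover.  Communities
    with zero pre-window catch get NaN for ``pct_change_catch`` only and are
    flagged in ``catch_excluded``.
    """
    pre = [int(y) for y in pre]
    post = [int(y) for y in post]
    if communities is None:
        communities = sorted(records["community"].unique())
    wanted = set(communities)
    groups = {c: g for c, g in records.groupby("community") if c in wanted}
    missing = wanted - groups.keys()
    if missing:
        raise ValueError(f"no records for communities: {sorted(missing)[:5]}")

    div = diversity_table(records, pre, communities=communities).set_index("community")
    div_col = "weighted_reciprocal" if weighting == "weighted" else "pooled_reciprocal"

    ann_rev = (
        records.groupby(["community", "year"])["revenue_real"].sum().unstack("year")
    )
    ann_lbs = records.groupby(["community", "year"])["pounds"].sum().unstack("year")

    rows = []
    for c in communities:
        rev_pre = ann_rev.loc[c].reindex(pre).fillna(0.0).to_numpy()
        rev_post = ann_rev.loc[c].reindex(post).fillna(0.0).to_numpy()
        lbs_pre = ann_lbs.loc[c].reindex(pre).fillna(0.0).to_numpy()
        lbs_post = ann_lbs.loc[c].reindex(post).fillna(0.0).to_numpy()
        catch_excluded = lbs_pre.mean() <= 0
        if turnover_value == "pounds" and (lbs_pre.sum() <= 0 or lbs_post.sum() <= 0):
            turnover = np.nan  # no catch in a period: composition undefined
        else:
            turnover = community_turnover(
                groups[c], pre, post, community=c,
                value=turnover_value, variant=jaccard_variant,
            ).jaccard
        rows.append(
            {
                "community": c,
                "mean_rev_pre": rev_pre.mean(),
                "mean_rev_post": rev_post.mean(),
                "pct_change_revenue": percent_change(rev_pre, rev_post),
                "pct_change_catch": (
                    np.nan if catch_excluded else percent_change(lbs_pre, lbs_post)
                ),
                "catch_excluded": catch_excluded,
                "diversity": div.loc[c, div_col],
                "turnover": turnover,
            }
        )
    return pd.DataFrame(rows)


def _package(res, names, std_effects) -> RegressionResult:
    ci = res.conf_int(alpha=0.05)
    return RegressionResult(
        formula="",
        coefficients={k: float(res.params[k]) for k in names},
        std_effects=std_effects,
        r_squared=float(res.rsquared),
        p_values={k: float(res.pvalues[k]) for k in names},
        n=int(res.nobs),
        residual_sd=float(np.sqrt(res.mse_resid)) if res.df_resid > 0 else 0.0,
        conf_int={k: (float(ci.loc[k, 0]), float(ci.loc[k, 1])) for k in names},
    )


def fit_loglinear(responses: pd.DataFrame) -> RegressionResult:
    """OLS of revenue percent change on log(diversity)."""
    df = responses.dropna(subset=["pct_change_revenue", "diversity"])
    if len(df) < 3:
        raise ValueError("need at least 3 communities")
    if (df["diversity"] <= 0).any():
        raise ValueError("diversity must be positive for the log transform")
    X = pd.DataFrame({"log_diversity": np.log(df["diversity"].to_numpy())})
    X = sm.add_constant(X)
    y = df["pct_change_revenue"].to_numpy()
    res = sm.OLS(y, X).fit()
    if res.df_resid < 0 or np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("rank-deficient design")
    sd_x = df["diversity"].pipe(np.log).std(ddof=1)
    out = _package(res, ["const", "log_diversity"], {"log_diversity": float(res.params["log_diversity"] * sd_x)})
    out.formula = "pct_change_revenue ~ log(diversity)"
    return out


def fit_interaction(
    responses: pd.DataFrame, log_covariates: bool = False, grid_size: int = 25
):
    """OLS of revenue change on diversity, turnover and their interaction.

    Returns (RegressionResult, surface) where ``surface`` is a long-format
    DataFrame of model predictions on a grid bounded by the observed
    covariate ranges.  With ``log_covariates`` the model uses log(diversity)
    and log(turnover + eps), eps = half the smallest positive turnover
    (turnover can be exactly zero).  If turnover is numerically constant the
    model falls back to diversity only, with a warning.
    """
    df = responses.dropna(subset=["pct_change_revenue", "diversity", "turnover"]).copy()
    if len(df) < 5:
        raise ValueError("need at least 5 communities")
    d = df["diversity"].to_numpy(float)
    t = df["turnover"].to_numpy(float)
    if log_covariates:
        pos = t[t > 0]
        eps = (pos.min() / 2.0) if pos.size else 1e-6
        d = np.log(d)
        t = np.log(t + eps)
        d_name, t_name = "log_diversity", "log_turnover"
    else:
        d_name, t_name = "diversity", "turnover"
    y = df["pct_change_revenue"].to_numpy(float)

    if np.std(t) < 1e-12:
        warnings.warn(
            "turnover is constant; dropping turnover and interaction terms",
            RuntimeWarning,
        )
        X = sm.add_constant(pd.DataFrame({d_name: d}))
        res = sm.OLS(y, X).fit()
        out = _package(res, ["const", d_name], {d_name: float(res.params[d_name] * np.std(d, ddof=1))})
        out.formula = f"pct_change_revenue ~ {d_name} (turnover degenerate)"
        return out, pd.DataFrame()

    inter = d * t
    X = sm.add_constant(pd.DataFrame({d_name: d, t_name: t, f"{d_name}:{t_name}": inter}))
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("collinear design: diversity, turnover and product are rank-deficient")
    res = sm.OLS(y, X).fit()

    zd = (d - d.mean()) / d.std(ddof=1)
    zt = (t - t.mean()) / t.std(ddof=1)
    Xz = sm.add_constant(
        pd.DataFrame({d_name: zd, t_name: zt, f"{d_name}:{t_name}": zd * zt})
    )
    resz = sm.OLS(y, Xz).fit()
    std_effects = {k: float(resz.params[k]) for k in (d_name, t_name, f"{d_name}:{t_name}")}

    names = ["const", d_name, t_name, f"{d_name}:{t_name}"]
    out = _package(res, names, std_effects)
    out.formula = f"pct_change_revenue ~ {d_name} * {t_name}"

    dg = np.linspace(d.min(), d.max(), grid_size)
    tg = np.linspace(t.min(), t.max(), grid_size)
    DD, TT = np.meshgrid(dg, tg)
    pred = (
        res.params["const"]
        + res.params[d_name] * DD
        + res.params[t_name] * TT
        + res.params[f"{d_name}:{t_name}"] * DD * TT
    )
    surface = pd.DataFrame(
        {d_name: DD.ravel(), t_name: TT.ravel(), "predicted_pct_change": pred.ravel()}
    )
    return out, surface


def fit_catch_price_product(revenue_change, catch_change, price_change) -> RegressionResult:
    """OLS of revenue change on catch change, price change and their product.

    ``price_change`` may be a scalar (a statewide price shift applied to all
    communities); a scalar is constant across rows, so the price main effect
    and the product are then unidentifiable and the model reduces to the
    catch term with a warning.
    """
    yv = np.asarray(revenue_change, dtype=float)
    cv = np.asarray(catch_change, dtype=float)
    pv = np.broadcast_to(np.asarray(price_change, dtype=float), yv.shape).astype(float)
    if not (yv.shape == cv.shape == pv.shape):
        raise ValueError("inputs must align")
    keep = np.isfinite(yv) & np.isfinite(cv) & np.isfinite(pv)
    yv, cv, pv = yv[keep], cv[keep], pv[keep]

    if np.std(pv) < 1e-12:
        warnings.warn(
            "price change is constant across communities; fitting catch term only",
            RuntimeWarning,
        )
        X = sm.add_constant(pd.DataFrame({"catch_change": cv}))
        names = ["const", "catch_change"]
    else:
        X = sm.add_constant(
            pd.DataFrame(
                {"catch_change": cv, "price_change": pv, "catch_change:price_change": cv * pv}
            )
        )
        names = ["const", "catch_change", "price_change", "catch_change:price_change"]
    if len(yv) <= X.shape[1]:
        raise ValueError(f"too few rows ({len(yv)}) for {X.shape[1]} parameters")
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("collinear design")
    res = sm.OLS(yv, X).fit()
    std = {
        k: float(res.params[k] * np.std(X[k].to_numpy(), ddof=1))
        for k in names
        if k != "const"
    }
    out = _package(res, names, std)
    out.formula = "revenue_change ~ catch_change * price_change"
    return out
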