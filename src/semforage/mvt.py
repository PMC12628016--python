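"""Statistical tests of marginal-value-theorem adherence.

Implements the behavioral battery run on scored fluency data: paired Wilcoxon
comparisons of switching vs clustering IRT ratios at each switch-relative
position, the pre-switch-gap -> fluency optimality regression, the IRT -> IRS
mixed model, the −1 vs −2 ramping test, and the Spearman correlation battery
with Benjamini–Hochberg correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests

from .errors import DataError, DegenerateTestError

__all__ = [
    "PositionTestResult",
    "RegressionResult",
    "MixedModelResult",
    "paired_wilcoxon",
    "test_position",
    "ramping_test",
    "optimality_regression",
    "irt_irs_model",
    "correlation_battery",
    "POSITIONS",
]

POSITIONS = ("-2", "-1", "+1", "+2")
EXACT_THRESHOLD = 25  # exact signed-rank null at or below this many pairs


@dataclass
class PositionTestResult:
    position: str
    switch_subset: str
    metric: str
    statistic: float          # W+ : sum of ranks of positive differences
    p: float
    n: int                    # pairs used (zeros removed)
    mean_a: float             # condition A (e.g. switching) mean
    mean_b: float             # condition B (e.g. clustering at position) mean
    se_a: float
    se_b: float


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    F: float
    df: tuple[int, int]
    p: float


@dataclass
class MixedModelResult:
    coef_irt: float
    se_irt: float
    p_irt: float
    coef_rank: float
    intercept: float
    vc_participant: float
    vc_cue: float
    resid_var: float
    marginal_r2: float
    fallback_ols: bool


def paired_wilcoxon(a, b, exact_threshold: int = EXACT_THRESHOLD):
    """Two-sided paired Wilcoxon signed-rank test.

    Pairs with an undefined value are dropped listwise, zero differences are
    removed before ranking, and the exact null distribution is used for up to
    ``exact_threshold`` untied pairs (normal approximation with continuity
    correction otherwise).  Returns ``(W_plus, p, n_used)``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    keep = ~(np.isnan(a) | np.isnan(b))
    d = a[keep] - b[keep]
    d = d[d != 0.0]
    n = len(d)
    if n == 0:
        raise DegenerateTestError("all paired differences are zero or missing")
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    has_ties = len(np.unique(np.abs(d))) < n
    if n <= exact_threshold and not has_ties:
        method = "exact"
        res = stats.wilcoxon(d, zero_method="wilcox", method=method)
    else:
        res = stats.wilcoxon(d, zero_method="wilcox", method="approx",
                             correction=True)
    return w_plus, float(res.pvalue), n


def _per_participant_position_means(scored: pd.DataFrame, anchors: pd.DataFrame,
                                    metric: str, switch_subset: str) -> pd.DataFrame:
    """Participant x position means of a metric, response -> cue -> participant.

    ``switch_subset`` restricts anchors to fast or slow governing switches.
    Returns a wide frame with one column per position plus a 'S' column for
    the switching responses themselves.
    """
    if switch_subset not in ("all", "fast", "slow"):
        raise ValueError("switch_subset must be all, fast, or slow")
    anc = anchors
    if switch_subset != "all":
        anc = anc[anc["switch_speed"] == switch_subset]
    vals = scored.loc[anc["row"], metric].to_numpy()
    tidy = anc[["participant", "cue", "position"]].copy()
    tidy["value"] = vals
    by_cue = (tidy.groupby(["participant", "position", "cue"])["value"].mean()
              .groupby(["participant", "position"]).mean())
    return by_cue.unstack("position")


def test_position(scored: pd.DataFrame, anchors: pd.DataFrame,
                  metric: str = "irtr", switch_subset: str = "all",
                  exact_threshold: int = EXACT_THRESHOLD) -> list[PositionTestResult]:
    """Paired Wilcoxon of the switching metric vs the clustering metric at
    each switch-relative position (−2, −1, +1, +2), across participants."""
    wide = _per_participant_position_means(scored, anchors, metric, switch_subset)
    if "S" not in wide.columns:
        raise DegenerateTestError("no switching responses in subset")
    results = []
    for pos in POSITIONS:
        if pos not in wide.columns:
            continue
        sub = wide[["S", pos]].dropna()
        if len(sub) < 2:
            continue
        w, p, n = paired_wilcoxon(sub["S"], sub[pos], exact_threshold)
        results.append(PositionTestResult(
            position=pos, switch_subset=switch_subset, metric=metric,
            statistic=w, p=p, n=n,
            mean_a=float(sub["S"].mean()), mean_b=float(sub[pos].mean()),
            se_a=float(sub["S"].sem()), se_b=float(sub[pos].sem())))
    return results


def ramping_test(scored: pd.DataFrame, anchors: pd.DataFrame,
                 metric: str = "irtr", switch_subset: str = "all",
                 exact_threshold: int = EXACT_THRESHOLD) -> PositionTestResult:
    """Paired Wilcoxon of the metric at position −1 vs −2: does the last
    clustering response before a switch run slower than the one before it?"""
    wide = _per_participant_position_means(scored, anchors, metric, switch_subset)
    for pos in ("-1", "-2"):
        if pos not in wide.columns:
            raise DegenerateTestError(f"no responses at position {pos}")
    sub = wide[["-1", "-2"]].dropna()
    if len(sub) < 2:
        raise DegenerateTestError("fewer than 2 participants with both "
                                  "positions defined")
    w, p, n = paired_wilcoxon(sub["-1"], sub["-2"], exact_threshold)
    return PositionTestResult(position="-1 vs -2", switch_subset=switch_subset,
                              metric=metric, statistic=w, p=p, n=n,
                              mean_a=float(sub["-1"].mean()),
                              mean_b=float(sub["-2"].mean()),
                              se_a=float(sub["-1"].sem()),
                              se_b=float(sub["-2"].sem()))


def optimality_regression(summaries: pd.DataFrame) -> RegressionResult:
    """OLS of fluency on the pre-switch gap.

    Under the MVT, participants whose pre-switch IRT sits close to their
    long-term IRT exploit clusters optimally and retrieve more responses, so
    the slope is expected to be negative.
    """
    sub = summaries[["pre_switch_gap", "polyft_fluency"]].dropna()
    if len(sub) < 3:
        raise DataError("need >= 3 participants with a defined pre-switch gap")
    x = sub["pre_switch_gap"].to_numpy()
    y = sub["polyft_fluency"].to_numpy()
    if np.ptp(x) == 0.0:
        raise DegenerateTestError("pre-switch gap has zero variance")
    n = len(x)
    if np.ptp(y) == 0.0:
        return RegressionResult(slope=0.0, intercept=float(y[0]),
                                r_squared=0.0, F=0.0, df=(1, n - 2), p=1.0)
    fit = stats.linregress(x, y)
    r2 = fit.rvalue ** 2
    f = r2 * (n - 2) / (1 - r2) if r2 < 1 else np.inf
    return RegressionResult(slope=float(fit.slope),
                            intercept=float(fit.intercept),
                            r_squared=float(r2), F=float(f),
                            df=(1, n - 2), p=float(fit.pvalue))


def irt_irs_model(scored: pd.DataFrame,
                  transition_subset: str = "clustering") -> MixedModelResult:
    """Linear mixed model IRS ~ IRT + response rank, with random intercepts
    for participant and cue (crossed, fitted by REML).

    Falls back to fixed-effects OLS (with the ``fallback_ols`` flag set) when
    the mixed fit is singular or fails to converge.  The reported R² is the
    marginal R²: fixed-effects variance over total variance.
    """
    if transition_subset not in ("clustering", "switching"):
        raise ValueError("transition_subset must be clustering or switching")
    sub = scored[(scored["transition"] == transition_subset)
                 & scored["irt"].notna() & scored["irs"].notna()].copy()
    if sub["participant"].nunique() < 2 or sub["cue"].nunique() < 2:
        raise DataError("need >= 2 participants and >= 2 cues with data")
    sub = sub.rename(columns={"response_index": "rank"})
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm(
                "irs ~ irt + rank", data=sub,
                groups=np.ones(len(sub)),
                vc_formula={"participant": "0 + C(participant)",
                            "cue": "0 + C(cue)"})
            fit = None
            for method in ("bfgs", "lbfgs", "powell"):
                fit = model.fit(reml=True, method=method, maxiter=200)
                if fit.converged:
                    break
        if fit is None or not fit.converged:
            raise np.linalg.LinAlgError("mixed model did not converge")
        fixed = fit.fe_params
        vcs = dict(zip(model.exog_vc.names, np.asarray(fit.vcomp)))
        fixed_pred = fit.predict(sub)
        var_fixed = float(np.var(fixed_pred))
        vc_p = float(vcs.get("participant", 0.0))
        vc_c = float(vcs.get("cue", 0.0))
        resid = float(fit.scale)
        total = var_fixed + vc_p + vc_c + resid
        return MixedModelResult(
            coef_irt=float(fixed["irt"]), se_irt=float(fit.bse_fe["irt"]),
            p_irt=float(fit.pvalues["irt"]), coef_rank=float(fixed["rank"]),
            intercept=float(fixed["Intercept"]), vc_participant=vc_p,
            vc_cue=vc_c, resid_var=resid,
            marginal_r2=var_fixed / total if total > 0 else np.nan,
            fallback_ols=False)
    except (np.linalg.LinAlgError, ValueError) as exc:
        warnings.warn(f"mixed model failed ({exc}); falling back to OLS")
        X = sm.add_constant(sub[["irt", "rank"]])
        ols = sm.OLS(sub["irs"], X).fit()
        return MixedModelResult(
            coef_irt=float(ols.params["irt"]), se_irt=float(ols.bse["irt"]),
            p_irt=float(ols.pvalues["irt"]), coef_rank=float(ols.params["rank"]),
            intercept=float(ols.params["const"]), vc_participant=0.0,
            vc_cue=0.0, resid_var=float(ols.mse_resid),
            marginal_r2=float(ols.rsquared), fallback_ols=True)


def correlation_battery(counts: pd.DataFrame, scores: pd.DataFrame,
                        alpha: float = 0.05,
                        alternative: str = "two-sided") -> pd.DataFrame:
    """Spearman correlations of every count column with every score column,
    Benjamini–Hochberg-adjusted within the declared family.

    ``counts`` and ``scores`` must share a ``participant`` column; missing
    values are dropped pairwise.  ``alternative`` may be 'two-sided' (primary
    protocol) or 'greater'/'less' (one-tailed replication protocol).
    Constant columns yield an undefined correlation reported as missing.
    """
    merged = counts.merge(scores, on="participant")
    count_cols = [c for c in counts.columns if c != "participant"]
    score_cols = [c for c in scores.columns if c != "participant"]
    rows = []
    for cc in count_cols:
        for sc in score_cols:
            sub = merged[[cc, sc]].dropna()
            if len(sub) < 4 or sub[cc].nunique() < 2 or sub[sc].nunique() < 2:
                rows.append(dict(count=cc, score=sc, n=len(sub),
                                 rho=np.nan, p=np.nan))
                continue
            rho, p = stats.spearmanr(sub[cc], sub[sc],
                                     alternative=alternative)
            rows.append(dict(count=cc, score=sc, n=len(sub),
                             rho=float(rho), p=float(p)))
    out = pd.DataFrame(rows)
    defined = out["p"].notna()
    out["p_fdr"] = np.nan
    if defined.any():
        _, p_adj, _, _ = multipletests(out.loc[defined, "p"], alpha=alpha,
                                       method="fdr_bh")
        out.loc[defined, "p_fdr"] = p_adj
    out["significant"] = out["p_fdr"] < alpha
    return out
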