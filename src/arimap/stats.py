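"""Arrhythmia-outcome statistics over animal-level summaries.

Covers the univariate association battery used for early ischemic VF work:
Friedman + Bonferroni-corrected Wilcoxon tests for repeated measurements,
univariate logistic / linear / Cox regressions with Wald intervals, ROC
analysis with the Youden-optimal cutoff, Kaplan-Meier curves with the
log-rank test, and a 2x2 chi-square for occlusion-site incidence.

Repeated time-points enter regressions either pooled (one row per animal per
time-point, animal-level clustering flagged as a limitation, the default) or
as one per-animal maximum over the analysis period; neither mode claims the
other is wrong, so every report carries its mode.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter, KaplanMeierFitter
from scipy import stats as sps
from scipy.stats import rankdata

__all__ = [
    "AssocResult",
    "RocResult",
    "SurvivalFit",
    "compare_repeated",
    "univariate_logistic",
    "univariate_linear",
    "roc_analysis",
    "cox_univariate",
    "km_logrank",
    "site_chisquare",
    "outcome_associations",
]

logger = logging.getLogger(__name__)

PHASE_1A_PERIOD = (1.0, 10.0)


@dataclass
class AssocResult:
    """One univariate association: OR, HR or slope B with a Wald 95% CI."""

    estimate: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int
    scale: str = "OR"           # "OR" | "HR" | "B"
    flag: Optional[str] = None  # e.g. "separation", "degenerate"


@dataclass
class RocResult:
    auc: float
    p_value: float
    thresholds: pd.DataFrame       # cutoff, sensitivity, specificity
    optimal_cutoff: float          # Youden-optimal, rule "x > cutoff" = event
    sens_at_cutoff: float
    spec_at_cutoff: float
    n_events: int
    n_nonevents: int


@dataclass
class SurvivalFit:
    curves: Dict[str, pd.DataFrame]  # group -> (time, survival)
    statistic: float                 # log-rank chi-square, 1 df
    p_value: float


# -- repeated measurements ----------------------------------------------------


def compare_repeated(values: pd.DataFrame, baseline=None) -> dict:
    """Friedman test plus pairwise Wilcoxon-vs-baseline with Bonferroni.

    ``values`` has one row per animal and one column per time-point; animals
    with any missing value are dropped listwise.  The Bonferroni multiplier
    equals the number of pairwise tests performed.
    """
    values = values.dropna(axis=0, how="any")
    if values.shape[1] < 3:
        raise ValueError("need >= 3 time-points for the Friedman test")
    if values.shape[0] < 5:
        warnings.warn("fewer than 5 animals: repeated-measures tests are low powered")
    cols = list(values.columns)
    baseline = cols[0] if baseline is None else baseline
    arrs = [values[c].to_numpy(dtype=float) for c in cols]
    if all(np.allclose(a, arrs[0]) for a in arrs[1:]):
        friedman_stat, friedman_p = 0.0, 1.0
    else:
        friedman_stat, friedman_p = sps.friedmanchisquare(*arrs)
    pairs = [c for c in cols if c != baseline]
    m = len(pairs)
    rows = []
    for c in pairs:
        diff = values[c] - values[baseline]
        if np.allclose(diff, 0.0):
            stat, p = 0.0, 1.0
        else:
            stat, p = sps.wilcoxon(values[c], values[baseline])
        rows.append({"time_point": c, "statistic": float(stat),
                     "p_raw": float(p), "p_bonferroni": float(min(1.0, p * m))})
    return {
        "friedman_statistic": float(friedman_stat),
        "friedman_p": float(friedman_p),
        "n": int(values.shape[0]),
        "pairwise": pd.DataFrame(rows),
    }


# -- regressions --------------------------------------------------------------


def _as_xy(outcome, covariate) -> Tuple[np.ndarray, np.ndarray]:
    y = np.asarray(outcome, dtype=float)
    x = np.asarray(covariate, dtype=float)
    keep = np.isfinite(y) & np.isfinite(x)
    return y[keep], x[keep]


def univariate_logistic(outcome, covariate) -> AssocResult:
    """Maximum-likelihood logistic fit of a binary outcome on one covariate.

    Reports the odds ratio per unit of the covariate with its Wald 95% CI
    (symmetric on the log-odds scale).  Complete or quasi-complete separation
    is flagged rather than silently reported.
    """
    y, x = _as_xy(outcome, covariate)
    if len(np.unique(y)) < 2:
        raise ValueError("outcome must contain both classes")
    if np.ptp(x) == 0:
        raise ValueError("covariate has zero variance")
    X = sm.add_constant(x)
    flag = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        except Exception:
            return AssocResult(np.nan, np.nan, np.nan, np.nan, len(y), "OR",
                               flag="separation")
    beta = res.params[1]
    se = np.sqrt(np.diag(res.cov_params()))[1]
    if not np.isfinite(se) or abs(beta) * np.std(x) > 30:
        return AssocResult(np.nan, np.nan, np.nan, np.nan, len(y), "OR",
                           flag="separation")
    lo, hi = beta - 1.959963984540054 * se, beta + 1.959963984540054 * se
    return AssocResult(float(np.exp(beta)), float(np.exp(lo)), float(np.exp(hi)),
                       float(res.pvalues[1]), len(y), "OR", flag)


def univariate_linear(y, x) -> AssocResult:
    """Ordinary least squares slope B with its 95% confidence interval."""
    yv, xv = _as_xy(y, x)
    if len(yv) < 3:
        raise ValueError("need n >= 3 for the linear fit")
    if np.ptp(xv) == 0:
        raise ValueError("covariate has zero variance")
    res = sm.OLS(yv, sm.add_constant(xv)).fit()
    lo, hi = res.conf_int()[1]
    return AssocResult(float(res.params[1]), float(lo), float(hi),
                       float(res.pvalues[1]), len(yv), "B")


# -- ROC ----------------------------------------------------------------------


def roc_analysis(outcome, covariate, higher_is_event: bool = True) -> RocResult:
    """Empirical ROC with the Youden-optimal cutoff.

    The AUC is the pairwise concordance (Mann-Whitney) statistic with ties
    counted 0.5, computed from ranks; its p-value comes from the asymptotic
    normal rank test.  Cutoffs follow the "covariate > c predicts event"
    convention over all observed values; the optimal cutoff maximizes
    Youden's J = sensitivity + specificity - 1, ties resolved toward the
    lower cutoff.
    """
    y, x = _as_xy(outcome, covariate)
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome classes are required")
    if not higher_is_event:
        x = -x
    events = x[y == 1]
    nonevents = x[y == 0]
    n1, n0 = len(events), len(nonevents)
    ranks = rankdata(x)
    u1 = float(np.sum(ranks[y == 1])) - n1 * (n1 + 1) / 2.0
    auc = u1 / (n1 * n0)
    if np.ptp(x) == 0:
        p = 1.0
    else:
        p = float(sps.mannwhitneyu(events, nonevents, alternative="two-sided",
                                   method="asymptotic").pvalue)
    cutoffs = np.unique(x)
    sens = np.array([(events > c).mean() for c in cutoffs])
    spec = np.array([(nonevents <= c).mean() for c in cutoffs])
    j = sens + spec - 1.0
    best = int(np.flatnonzero(j == j.max())[0])  # ties -> lowest cutoff
    table = pd.DataFrame({"cutoff": cutoffs, "sensitivity": sens, "specificity": spec})
    return RocResult(float(auc), p, table, float(cutoffs[best]),
                     float(sens[best]), float(spec[best]), n1, n0)


# -- survival -----------------------------------------------------------------


def cox_univariate(time, event, covariate) -> AssocResult:
    """Cox partial-likelihood hazard ratio per unit covariate (Efron ties)."""
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=float)
    x = np.asarray(covariate, dtype=float)
    if e.sum() < 1:
        raise ValueError("at least one event is required")
    if np.ptp(x) == 0:
        return AssocResult(np.nan, np.nan, np.nan, np.nan, len(t), "HR",
                           flag="degenerate")
    df = pd.DataFrame({"time": t, "event": e, "x": x})
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            cph.fit(df, duration_col="time", event_col="event")
        except Exception:
            return AssocResult(np.nan, np.nan, np.nan, np.nan, len(t), "HR",
                               flag="degenerate")
    s = cph.summary.loc["x"]
    return AssocResult(float(s["exp(coef)"]),
                       float(s["exp(coef) lower 95%"]),
                       float(s["exp(coef) upper 95%"]),
                       float(s["p"]), len(t), "HR")


def logrank_statistic(time, event, group) -> Tuple[float, float]:
    """Two-sample log-rank chi-square (1 df) and its p-value.

    Sums observed-minus-expected events over distinct event times with the
    hypergeometric variance at each.
    """
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=bool)
    g = np.asarray(group)
    labels = np.unique(g)
    if len(labels) != 2:
        raise ValueError("exactly two groups are required")
    in1 = g == labels[1]
    o_minus_e = 0.0
    var = 0.0
    for tt in np.unique(t[e]):
        at_risk = t >= tt
        n_t = at_risk.sum()
        n1_t = (at_risk & in1).sum()
        d_t = (e & (t == tt)).sum()
        d1_t = (e & (t == tt) & in1).sum()
        o_minus_e += d1_t - d_t * n1_t / n_t
        if n_t > 1:
            var += d_t * (n1_t / n_t) * (1 - n1_t / n_t) * (n_t - d_t) / (n_t - 1)
    if var == 0:
        return 0.0, 1.0
    stat = o_minus_e ** 2 / var
    return float(stat), float(sps.chi2.sf(stat, 1))


def km_logrank(time, event, group) -> SurvivalFit:
    """Kaplan-Meier curves per group plus the two-sample log-rank test."""
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=bool)
    g = np.asarray(group)
    curves = {}
    for lab in np.unique(g):
        sel = g == lab
        if sel.sum() == 0:
            raise ValueError(f"group {lab!r} is empty")
        kmf = KaplanMeierFitter()
        kmf.fit(t[sel], e[sel])
        sf = kmf.survival_function_
        curves[str(lab)] = pd.DataFrame(
            {"time": sf.index.to_numpy(dtype=float),
             "survival": sf.iloc[:, 0].to_numpy(dtype=float)})
    stat, p = logrank_statistic(t, e, g)
    return SurvivalFit(curves, stat, p)


def site_chisquare(site, vf) -> dict:
    """Pearson chi-square (no continuity correction) for VF incidence by site."""
    table = pd.crosstab(pd.Series(site, name="site"), pd.Series(vf, name="vf"))
    if table.shape != (2, 2) or (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("need a full 2x2 table with nonempty margins")
    chi2, p, dof, _ = sps.chi2_contingency(table.to_numpy(), correction=False)
    return {"chi2": float(chi2), "p": float(p), "dof": int(dof), "table": table}


# -- orchestration ------------------------------------------------------------

_MAPPING_COVARIATES = ("at_max", "dor", "aric_mean", "aric_min", "aric_max")
_ECG_COVARIATES = ("rr", "qtp_min", "qtp_c_min", "qt_max", "qtc_max", "tpe", "tpe_c")


def outcome_associations(
    summaries: pd.DataFrame,
    cohort: pd.DataFrame,
    covariates: Sequence[str] = _MAPPING_COVARIATES + _ECG_COVARIATES,
    period: Tuple[float, float] = PHASE_1A_PERIOD,
    mode: str = "pooled",
) -> pd.DataFrame:
    """Univariate logistic screens of VF against each map/ECG covariate.

    ``mode='pooled'`` uses one row per animal per time-point inside
    ``period`` (repeated measures pooled; animal-level clustering is noted,
    not modeled).  ``mode='per_animal_max'`` reduces to one maximum per
    animal first.  Returns a tidy results table.
    """
    if mode not in ("pooled", "per_animal_max"):
        raise ValueError("mode must be 'pooled' or 'per_animal_max'")
    df = summaries.merge(cohort[["animal", "vf"]], on="animal", how="inner")
    df = df[(df["time_point"] >= period[0]) & (df["time_point"] <= period[1])]
    rows = []
    for cov in covariates:
        if cov not in df.columns:
            continue
        if mode == "pooled":
            sub = df[["animal", "vf", cov]].dropna()
            y, x = sub["vf"].astype(float), sub[cov]
        else:
            sub = (df[["animal", "vf", cov]].dropna()
                   .groupby("animal").agg(vf=("vf", "first"), val=(cov, "max")))
            y, x = sub["vf"].astype(float), sub["val"]
        try:
            res = univariate_logistic(y, x)
        except ValueError as exc:
            logger.warning("logistic screen skipped for %s: %s", cov, exc)
            continue
        rows.append({
            "analysis": "logistic", "covariate": cov, "mode": mode,
            "estimate": res.estimate, "ci_low": res.ci_low, "ci_high": res.ci_high,
            "p": res.p_value, "n": res.n, "scale": res.scale,
            "note": res.flag or "repeated time-points pooled; clustering not modeled"
            if mode == "pooled" else res.flag or "per-animal maximum over period",
        })
    return pd.DataFrame(rows)
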