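"""Behavioural endpoint analyses.

The five endpoints, in the configuration the study design prescribes:

1. SMS-Mind slopes  — pooled covariate residualization of post-meditation
   State Mindfulness scores (on pre-score, sleepiness, age, sex), one
   least-squares slope per participant over the six session days, one-way
   ANOVA on the slopes between groups.
2. SMS-Body slopes  — same procedure on the Body subscale.
3. DASS-21 change   — ANCOVA on follow-up-minus-baseline difference scores
   with age and sex as covariates.
4. BCT task change  — same ANCOVA on breath-counting task accuracy changes.
5. BCT probe change — Wilcoxon rank-sum on the discrete probe-accuracy
   changes (exact enumeration for combined n <= 12, normal approximation
   with tie correction otherwise).

Raw p-values are Benjamini-Hochberg adjusted across the five tests and each
t-based statistic is converted to Cohen's d via d = t * sqrt(1/n1 + 1/n2).
Partial correlations and one-sample t-tests used for the brain-behaviour
follow-ups live here as well.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

EXACT_RANKSUM_MAX_N = 12


@dataclass
class StatResult:
    """One test's statistic, p-value and effect size."""

    statistic: float
    df: float
    raw_p: float
    effect_size: float | None = None
    test_kind: str = ""
    tail: str = "two"


@dataclass(frozen=True)
class MultipleTestingConfig:
    m: int = 5
    q: float = 0.05

    def __post_init__(self):
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if not 0 < self.q < 1:
            raise ValueError("q must be in (0, 1)")


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=0)
    return (x - x.mean()) / sd if sd > 0 else x - x.mean()


def residualize_sms(cohort: pd.DataFrame, subscale: str = "mind") -> pd.DataFrame:
    """Pooled covariate residualization of post-meditation SMS scores.

    Regresses the post scores of all subject-timepoints on the matching pre
    score, the session's sleepiness rating, age and sex (standardized, with
    intercept) and returns a long table (subject_id, group, timepoint,
    residual).  Subjects with incomplete 6-timepoint data are dropped
    listwise with a log message; constant covariates are dropped with a
    warning.
    """
    pre_cols = [f"sms_{subscale}_pre_{t}" for t in range(6)]
    post_cols = [f"sms_{subscale}_post_{t}" for t in range(6)]
    sss_cols = [f"sss_{t}" for t in range(6)]
    needed = pre_cols + post_cols + sss_cols + ["age", "sex"]
    complete = cohort[needed].notna().all(axis=1)
    if (~complete).any():
        logger.info("residualize_sms: dropping %d subjects with incomplete data",
                    int((~complete).sum()))
    data = cohort.loc[complete]

    n = len(data)
    post = data[post_cols].to_numpy(dtype=float).ravel()        # subject-major
    pre = data[pre_cols].to_numpy(dtype=float).ravel()
    sss = data[sss_cols].to_numpy(dtype=float).ravel()
    age = np.repeat(data["age"].to_numpy(dtype=float), 6)
    sex = np.repeat(data["sex"].to_numpy(dtype=float), 6)

    cols, names = [np.ones_like(post)], ["intercept"]
    for name, x in (("pre", pre), ("sss", sss), ("age", age), ("sex", sex)):
        if np.ptp(x) == 0:
            warnings.warn(f"constant covariate '{name}' dropped", stacklevel=2)
            continue
        cols.append(_standardize(x))
        names.append(name)
    X = np.column_stack(cols)
    beta, *_ = np.linalg.lstsq(X, post, rcond=None)
    resid = post - X @ beta
    return pd.DataFrame({
        "subject_id": np.repeat(data["subject_id"].to_numpy(), 6),
        "group": np.repeat(data["group"].to_numpy(), 6),
        "timepoint": np.tile(np.arange(6), n),
        "residual": resid,
    })


@dataclass
class SlopeResult:
    subject_id: str
    group: str
    slope: float
    intercept: float
    n_timepoints: int


def fit_subject_slopes(residuals: pd.DataFrame, session_days) -> list:
    """Per-subject least-squares slope of the residuals on days since baseline.

    Subjects with fewer than 3 usable timepoints are excluded and logged.
    """
    days = np.asarray(session_days, dtype=float)
    out = []
    for sid, grp in residuals.groupby("subject_id", sort=False):
        y = grp.sort_values("timepoint")["residual"].to_numpy(dtype=float)
        d = days[grp.sort_values("timepoint")["timepoint"].to_numpy()]
        ok = np.isfinite(y)
        if ok.sum() < 3:
            logger.info("fit_subject_slopes: excluding %s (%d timepoints)", sid, ok.sum())
            continue
        slope, intercept = np.polyfit(d[ok], y[ok], 1)
        out.append(SlopeResult(subject_id=sid, group=str(grp["group"].iloc[0]),
                               slope=float(slope), intercept=float(intercept),
                               n_timepoints=int(ok.sum())))
    return out


def _cohen_d_from_t(t: float, n1: int, n2: int) -> float:
    return float(t * np.sqrt(1.0 / n1 + 1.0 / n2))


def compare_slopes(slopes_a, slopes_b) -> StatResult:
    """One-way ANOVA on per-subject slopes between the two groups.

    Cohen's d is derived from the equivalent two-sample comparison,
    d = t * sqrt(1/n1 + 1/n2) with t = sqrt(F) signed by the direction of
    the group-mean difference (group A minus group B).
    """
    a = np.asarray(slopes_a, dtype=float)
    b = np.asarray(slopes_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 subjects per group")
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a.mean() == b.mean():
        return StatResult(statistic=0.0, df=a.size + b.size - 2, raw_p=1.0,
                          effect_size=0.0, test_kind="anova_on_slopes")
    f, p = stats.f_oneway(a, b)
    sign = np.sign(a.mean() - b.mean()) or 1.0
    t_equiv = sign * np.sqrt(max(f, 0.0))
    return StatResult(statistic=float(f), df=float(a.size + b.size - 2),
                      raw_p=float(p), effect_size=_cohen_d_from_t(t_equiv, a.size, b.size),
                      test_kind="anova_on_slopes")


def ancova_difference_scores(diff_scores, group, covariates) -> StatResult:
    """Group effect in the linear model diff ~ group + covariates.

    ``group`` is a 0/1 (or boolean) indicator; covariates a (n, k) array
    (age and sex in the endpoint battery), standardized internally.
    """
    y = np.asarray(diff_scores, dtype=float)
    g = np.asarray(group, dtype=float)
    n = y.size
    n1 = int(g.sum())
    n2 = n - n1
    cols = [np.ones(n), g]
    names = ["intercept", "group"]
    if covariates is not None:
        Z = np.atleast_2d(np.asarray(covariates, dtype=float))
        if Z.shape[0] != n:
            Z = Z.T
        for j in range(Z.shape[1]):
            cols.append(_standardize(Z[:, j]))
            names.append(f"cov_{j}")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(f"singular model matrix; collinear columns among {names}")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = n - X.shape[1]
    if dof <= 0:
        raise ValueError("no residual degrees of freedom")
    sigma2 = (resid**2).sum() / dof
    var_g = sigma2 * np.linalg.inv(X.T @ X)[1, 1]
    # degenerate: the model fits exactly (e.g. all diffs equal) -> no evidence
    scale = max(float(np.abs(y).max()), 1.0)
    if np.sqrt(var_g) < 1e-10 * scale:
        if abs(beta[1]) < 1e-10 * scale:
            return StatResult(statistic=0.0, df=float(dof), raw_p=1.0,
                              effect_size=0.0, test_kind="ancova_diff")
        t_inf = float(np.inf * np.sign(beta[1]))
        return StatResult(statistic=t_inf, df=float(dof), raw_p=0.0,
                          effect_size=_cohen_d_from_t(np.sign(beta[1]) * 1e6, n1, n2),
                          test_kind="ancova_diff")
    t = float(beta[1] / np.sqrt(var_g))
    p = float(2 * stats.t.sf(abs(t), dof))
    return StatResult(statistic=t, df=float(dof), raw_p=p,
                      effect_size=_cohen_d_from_t(t, n1, n2), test_kind="ancova_diff")


def _ranksum_exact(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact rank-sum p by enumerating all label assignments.

    Midranks handle ties; the p-value is the probability, over all
    C(n1+n2, n1) assignments of the pooled values to the first group, of a
    rank sum at least as far from its null mean as observed.
    """
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n1 = x.size
    n = pooled.size
    w_obs = ranks[:n1].sum()
    mu = n1 * (n + 1) / 2.0
    dev = abs(w_obs - mu)
    count = 0
    for idx in combinations(range(n), n1):
        if abs(ranks[list(idx)].sum() - mu) >= dev - 1e-12:
            count += 1
    return count / comb(n, n1)


def ranksum_probe(diff_a, diff_b) -> StatResult:
    """Two-sided Wilcoxon rank-sum between the groups' difference scores.

    Exact enumeration for combined n <= 12, normal approximation with tie
    correction otherwise; all-tied data gives p = 1.
    """
    a = np.asarray(diff_a, dtype=float)
    b = np.asarray(diff_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("need at least 3 per group")
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    w = float(ranks[:a.size].sum())
    if np.ptp(pooled) == 0:
        return StatResult(statistic=w, df=float(a.size + b.size), raw_p=1.0,
                          test_kind="ranksum")
    if a.size + b.size <= EXACT_RANKSUM_MAX_N:
        p = _ranksum_exact(a, b)
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        p = float(res.pvalue)
    # rank-biserial r as the effect size for the nonparametric endpoint
    u = w - a.size * (a.size + 1) / 2.0
    r_rb = 1.0 - 2.0 * u / (a.size * b.size)
    return StatResult(statistic=w, df=float(a.size + b.size), raw_p=float(min(p, 1.0)),
                      effect_size=float(r_rb), test_kind="ranksum")


def bh_fdr(raw_p, config: MultipleTestingConfig | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    The family size defaults to the number of p-values supplied; a
    :class:`MultipleTestingConfig` with a larger ``m`` widens the family
    (extra tests assumed non-significant).
    """
    p = np.asarray(raw_p, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("raw_p must be a non-empty 1-D sequence")
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    m = config.m if config is not None else p.size
    if m < p.size:
        raise ValueError("family size m cannot be smaller than the number of p-values")
    if m == p.size:
        return multipletests(p, method="fdr_bh")[1]
    # widen the family: pad with p = 1 placeholders, adjust, return the originals
    padded = np.concatenate([p, np.ones(m - p.size)])
    return multipletests(padded, method="fdr_bh")[1][: p.size]


def partial_correlation(x, y, covariates=None) -> StatResult:
    """Pearson partial correlation via residuals of covariate regressions.

    r is the Pearson correlation of the residuals of x and y after
    regressing each on the covariates (with intercept); df = n - 2 - k and
    the two-sided p comes from t = r * sqrt(df / (1 - r^2)).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if covariates is None:
        Z = np.ones((n, 1))
        k = 0
    else:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != n:
            C = C.T
        k = C.shape[1]
        Z = np.column_stack([np.ones(n), C])
    df = n - 2 - k
    if df <= 0:
        raise ValueError(f"not enough observations: n={n}, covariates k={k}")
    rx = x - Z @ np.linalg.lstsq(Z, x, rcond=None)[0]
    ry = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
    r = float(np.corrcoef(rx, ry)[0, 1])
    return partial_correlation_from_r(r, df)


def partial_correlation_from_r(r: float, df: int) -> StatResult:
    """Two-sided p for a (partial) correlation at the given residual df."""
    if not -1.0 <= r <= 1.0:
        raise ValueError("r must be in [-1, 1]")
    if df <= 0:
        raise ValueError("df must be positive")
    if abs(r) == 1.0:
        return StatResult(statistic=np.inf * np.sign(r), df=float(df), raw_p=0.0,
                          effect_size=r, test_kind="partial_correlation")
    t = r * np.sqrt(df / (1.0 - r * r))
    p = float(2 * stats.t.sf(abs(t), df))
    return StatResult(statistic=float(t), df=float(df), raw_p=p, effect_size=r,
                      test_kind="partial_correlation")


def one_sample_t(values, mu0: float = 0.0, tail: str = "two") -> StatResult:
    """One-sample t-test with Cohen's d = (mean - mu0) / sd."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need n >= 2")
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance")
    t = float((v.mean() - mu0) / (sd / np.sqrt(v.size)))
    df = v.size - 1
    if tail == "two":
        p = float(2 * stats.t.sf(abs(t), df))
    elif tail == "greater":
        p = float(stats.t.sf(t, df))
    elif tail == "less":
        p = float(stats.t.cdf(t, df))
    else:
        raise ValueError("tail must be 'two', 'greater' or 'less'")
    return StatResult(statistic=t, df=float(df), raw_p=p,
                      effect_size=float((v.mean() - mu0) / sd),
                      test_kind="one_sample_t", tail=tail)


def blinding_checks(ratings_experimental: dict, ratings_control: dict,
                    sham_displayed=None, sham_actual=None) -> pd.DataFrame:
    """Participant-blinding verification.

    ``ratings_*`` map question names (NF-meditation correspondence, perceived
    utility, performance; 0-5 integer scales) to per-subject rating vectors;
    each question gets a two-sided rank-sum between groups.  If the sham
    group's displayed scores and their actual block PSC are supplied (from
    the NF session logs), their Pearson correlation is appended — effective
    blinding predicts no group differences and no sham/actual correlation.
    """
    rows = []
    for question in ratings_experimental:
        res = ranksum_probe(ratings_experimental[question], ratings_control[question])
        rows.append({"check": f"ratings_{question}", "statistic": res.statistic,
                     "raw_p": res.raw_p, "test_kind": res.test_kind})
    if sham_displayed is not None and sham_actual is not None:
        x = np.asarray(sham_displayed, dtype=float)
        y = np.asarray(sham_actual, dtype=float)
        r, p = stats.pearsonr(x, y)
        rows.append({"check": "sham_vs_actual_correlation", "statistic": float(r),
                     "raw_p": float(p), "test_kind": "pearson"})
    return pd.DataFrame.from_records(rows)


ENDPOINT_NAMES = ("sms_mind_slope", "sms_body_slope", "dass_change",
                  "bct_task_change", "bct_probe_change")


def run_endpoints(cohort: pd.DataFrame, session_days=(0.0, 3.0, 4.0, 5.0, 6.0, 7.0),
                  fdr_q: float = 0.05) -> pd.DataFrame:
    """Run the five behavioural tests and BH-adjust across them (m = 5).

    Returns the endpoint table with exactly five rows: endpoint, test_kind,
    statistic, df, raw_p, bh_adjusted_p, cohen_d.  Group contrasts are
    experimental minus control throughout.
    """
    counts = cohort["group"].value_counts()
    if counts.min() < 3 or set(counts.index) != {"experimental", "control"}:
        raise ValueError("need >= 3 subjects in each of experimental and control")
    is_exp = (cohort["group"] == "experimental").to_numpy()
    covs = cohort[["age", "sex"]].to_numpy(dtype=float)

    rows = []
    for subscale, name in (("mind", "sms_mind_slope"), ("body", "sms_body_slope")):
        resid = residualize_sms(cohort, subscale)
        slopes = fit_subject_slopes(resid, session_days)
        s_exp = [s.slope for s in slopes if s.group == "experimental"]
        s_con = [s.slope for s in slopes if s.group == "control"]
        res = compare_slopes(s_exp, s_con)
        rows.append((name, res))

    dass_diff = (cohort["dass_followup"] - cohort["dass_baseline"]).to_numpy(dtype=float)
    rows.append(("dass_change", ancova_difference_scores(dass_diff, is_exp, covs)))

    task_diff = (cohort["bct_task_followup"] - cohort["bct_task_baseline"]).to_numpy(dtype=float)
    rows.append(("bct_task_change", ancova_difference_scores(task_diff, is_exp, covs)))

    probe_diff = (cohort["bct_probe_followup"] - cohort["bct_probe_baseline"]).to_numpy(dtype=float)
    rows.append(("bct_probe_change",
                 ranksum_probe(probe_diff[is_exp], probe_diff[~is_exp])))

    raw_p = [r.raw_p for _, r in rows]
    adj = bh_fdr(raw_p, MultipleTestingConfig(m=5, q=fdr_q))
    table = pd.DataFrame({
        "endpoint": [name for name, _ in rows],
        "test_kind": [r.test_kind for _, r in rows],
        "statistic": [r.statistic for _, r in rows],
        "df": [r.df for _, r in rows],
        "raw_p": raw_p,
        "bh_adjusted_p": adj,
        "cohen_d": [r.effect_size for _, r in rows],
    })
    return table
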