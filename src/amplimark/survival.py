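"""Kaplan-Meier estimation, log-rank tests, Cox models and the per-gene
outlier-vs-normal survival screen.

The screen must test thousands of binary group indicators (one per gene and
direction) against the same follow-up data, so the two-sample log-rank
statistic and the univariate Cox model on a binary indicator are implemented
here as vectorised computations over the shared risk table. Both are
unit-tested against lifelines, which also provides the Kaplan-Meier
estimator and the multivariate (Table-3-style) Cox fit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from scipy import stats

from .outliers import OutlierMatrixPair

MAX_ABS_COEF = 15.0  # |log HR| cap signalling a monotone partial likelihood


@dataclass
class KMCurve:
    """Product-limit survival curve with Greenwood-based 95% CI and at-risk counts."""

    times: np.ndarray
    survival: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    at_risk: np.ndarray
    _fitter: KaplanMeierFitter

    def survival_at(self, t: float) -> float:
        """Step-function value S(t); 1 before the first event."""
        return float(self._fitter.predict(t))


@dataclass
class CoxResult:
    """Per-covariate estimates from a proportional-hazards fit (Efron ties)."""

    summary: pd.DataFrame  # coef, hazard_ratio, ci_lower, ci_upper, p
    overall_p: float  # likelihood-ratio test of the full model
    n: int
    n_events: int


def _check_surv(times, events) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.size == 0:
        raise ValueError("empty survival sample")
    if (t < 0).any():
        raise ValueError("negative survival times")
    if not np.isin(e, (0, 1)).all():
        raise ValueError("event flags must be 0/1")
    return t, e


def km_estimate(times, events) -> KMCurve:
    """Kaplan-Meier product-limit estimate; samples censored at an event time
    are counted at risk for that time (the usual convention)."""
    t, e = _check_surv(times, events)
    kmf = KaplanMeierFitter()
    kmf.fit(t, e)
    surv = kmf.survival_function_["KM_estimate"]
    ci = kmf.confidence_interval_
    at_risk = kmf.event_table["at_risk"].reindex(surv.index).to_numpy()
    return KMCurve(
        times=surv.index.to_numpy(),
        survival=surv.to_numpy(),
        ci_lower=ci.iloc[:, 0].to_numpy(),
        ci_upper=ci.iloc[:, 1].to_numpy(),
        at_risk=at_risk,
        _fitter=kmf,
    )


def _risk_table(times: np.ndarray, events: np.ndarray, member: np.ndarray):
    """Aggregate the cohort into per-distinct-event-time counts.

    member is (n_samples, G) binary group-1 membership. Returns, at each of
    the K distinct event times: d (total deaths), n (at risk), and per group
    d1 (K, G) deaths in group 1 and n1 (K, G) group-1 members at risk.
    """
    order = np.argsort(times, kind="mergesort")
    t = times[order]
    e = events[order]
    m = member[order]
    n_samples = t.size
    # suffix counts of group-1 members (at risk at time >= t[i])
    suffix = np.cumsum(m[::-1], axis=0)[::-1]
    starts = np.flatnonzero(np.r_[True, t[1:] != t[:-1]])  # first index of each distinct time
    d_all = np.add.reduceat(e, starts)
    has_event = d_all > 0
    ev_starts = starts[has_event]
    d = d_all[has_event].astype(float)
    n = (n_samples - ev_starts).astype(float)
    n1 = suffix[ev_starts].astype(float)
    d1 = np.add.reduceat(m * e[:, None], starts, axis=0)[has_event].astype(float)
    return d, n, d1, n1


def logrank_many(times, events, member: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two-sample log-rank chi-square (1 df) for every column of a binary
    membership matrix, sharing one risk table across all columns.

    Returns (statistic, p) arrays of length G. A column whose groups never
    overlap in risk contributes variance 0 and gets statistic 0, p 1.
    """
    t, e = _check_surv(times, events)
    member = np.asarray(member)
    if member.ndim == 1:
        member = member[:, None]
    d, n, d1, n1 = _risk_table(t, e, member)
    frac = n1 / n[:, None]
    o_minus_e = (d1 - d[:, None] * frac).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(n > 1, (n - d) / (n - 1), 0.0)
    var = (d[:, None] * frac * (1 - frac) * corr[:, None]).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        stat = np.where(var > 0, o_minus_e**2 / var, 0.0)
    p = stats.chi2.sf(stat, df=1)
    p = np.where(var > 0, p, 1.0)
    return stat, p


def log_rank_test(times_a, events_a, times_b, events_b) -> tuple[float, float]:
    """Standard two-group log-rank test; returns (chi-square statistic, p)."""
    ta, ea = _check_surv(times_a, events_a)
    tb, eb = _check_surv(times_b, events_b)
    times = np.r_[ta, tb]
    events = np.r_[ea, eb]
    member = np.r_[np.ones(ta.size, dtype=int), np.zeros(tb.size, dtype=int)]
    stat, p = logrank_many(times, events, member)
    return float(stat[0]), float(p[0])


def cox_binary_many(times, events, member: np.ndarray, max_iter: int = 50, tol: float = 1e-10):
    """Univariate Cox PH fit of a binary indicator, vectorised over columns.

    Newton-Raphson on the Efron partial likelihood; for a 0/1 covariate the
    risk-set sums reduce to closed forms in the per-time counts, so every
    column is fitted simultaneously. Returns (coef, se, loglik, loglik0)
    arrays. Columns with a monotone likelihood (complete separation) are
    capped at |coef| = 15 and get se = inf.
    """
    t, e = _check_surv(times, events)
    member = np.asarray(member, dtype=float)
    if member.ndim == 1:
        member = member[:, None]
    d, n, d1, n1 = _risk_table(t, e, member)
    K, G = d1.shape
    n0 = n[:, None] - n1
    d0 = d[:, None] - d1
    max_d = int(d.max()) if K else 1
    beta = np.zeros(G)

    def efron_terms(theta: np.ndarray):
        """loglik, score and information summed over event times and Efron steps."""
        ll = (np.log(theta) * d1).sum(axis=0)
        u = d1.sum(axis=0).astype(float)
        info = np.zeros(G)
        r_num = n1 * theta  # risk-set sum of x*exp(bx) per (K, G)
        r_den = n0 + r_num
        e_num = d1 * theta  # tied-set sum of x*exp(bx)
        e_den = d0 + e_num
        for l in range(max_d):
            rows = d > l
            frac = (l / d[rows])[:, None]
            den = r_den[rows] - frac * e_den[rows]
            num = r_num[rows] - frac * e_num[rows]
            a = num / den
            ll -= np.log(den).sum(axis=0)
            u -= a.sum(axis=0)
            info += (a * (1 - a)).sum(axis=0)  # x binary: E[x^2] = E[x]
        return ll, u, info

    ll0 = efron_terms(np.ones((K, G)))[0]
    ll = ll0.copy()
    for _ in range(max_iter):
        theta = np.exp(beta)[None, :] * np.ones((K, 1))
        ll, u, info = efron_terms(theta)
        with np.errstate(invalid="ignore", divide="ignore"):
            step = np.where(info > 0, u / info, 0.0)
        step = np.clip(step, -2.0, 2.0)
        beta = np.clip(beta + step, -MAX_ABS_COEF, MAX_ABS_COEF)
        if np.max(np.abs(u)) < tol or np.max(np.abs(step)) < 1e-12:
            break
    theta = np.exp(beta)[None, :] * np.ones((K, 1))
    ll, u, info = efron_terms(theta)
    with np.errstate(invalid="ignore", divide="ignore"):
        se = np.where(info > 0, 1.0 / np.sqrt(info), np.inf)
    se = np.where(np.abs(beta) >= MAX_ABS_COEF, np.inf, se)
    return beta, se, ll, ll0


def cox_binary(times, events, indicator) -> dict:
    """Univariate Cox PH fit on one binary indicator.

    Returns coef, hazard_ratio, Wald 95% CI and p, and the likelihood-ratio p.
    """
    ind = np.asarray(indicator, dtype=int)
    if ind.min() == ind.max():
        raise ValueError("indicator is constant")
    beta, se, ll, ll0 = cox_binary_many(times, events, ind[:, None])
    b, s = float(beta[0]), float(se[0])
    z = b / s if np.isfinite(s) and s > 0 else 0.0
    lr = 2 * (ll[0] - ll0[0])
    return {
        "coef": b,
        "hazard_ratio": float(np.exp(b)),
        "ci_lower": float(np.exp(b - 1.96 * s)),
        "ci_upper": float(np.exp(b + 1.96 * s)),
        "p": float(2 * stats.norm.sf(abs(z))),
        "lr_p": float(stats.chi2.sf(lr, df=1)),
    }


GRADE_BASELINE = "intermediate"


def build_cox_design(clinical: pd.DataFrame, covariates: Sequence[str]) -> pd.DataFrame:
    """Assemble the regression design from the clinical table.

    ``grade`` expands to two indicators (grade_low, grade_high) against the
    intermediate-grade baseline; other covariates enter as numeric columns.
    Rows with any missing covariate are dropped (complete-case analysis).
    """
    cols: dict[str, pd.Series] = {}
    for cov in covariates:
        if cov == "grade":
            g = clinical["grade"]
            cols["grade_low"] = (g == "low").astype(float).where(g.notna())
            cols["grade_high"] = (g == "high").astype(float).where(g.notna())
        else:
            cols[cov] = pd.to_numeric(clinical[cov], errors="coerce")
    design = pd.DataFrame(cols, index=clinical.index)
    design["time"] = clinical["time"].astype(float)
    design["event"] = clinical["event"].astype(int)
    return design.dropna()


def cox_fit(clinical: pd.DataFrame, covariates: Sequence[str]) -> CoxResult:
    """Multivariate Cox proportional-hazards fit with Efron tie handling.

    ``clinical`` must carry ``time`` and ``event`` columns plus the requested
    covariates (``grade`` is expanded to low/high indicators against the
    intermediate baseline). Constant covariates raise; non-convergence
    propagates lifelines' diagnostic error.
    """
    design = build_cox_design(clinical, covariates)
    if design["event"].sum() == 0:
        raise ValueError("no events in the fitted data")
    value_cols = [c for c in design.columns if c not in ("time", "event")]
    for c in value_cols:
        if design[c].nunique() < 2:
            raise ValueError(f"constant covariate: {c}")
    cph = CoxPHFitter()
    cph.fit(design, duration_col="time", event_col="event")
    summ = cph.summary
    out = pd.DataFrame(
        {
            "coef": summ["coef"],
            "hazard_ratio": summ["exp(coef)"],
            "ci_lower": np.exp(summ["coef lower 95%"]),
            "ci_upper": np.exp(summ["coef upper 95%"]),
            "p": summ["p"],
        }
    )
    overall = cph.log_likelihood_ratio_test().p_value
    return CoxResult(summary=out, overall_p=float(overall), n=int(design.shape[0]),
                     n_events=int(design["event"].sum()))


def outlier_survival_screen(
    pair: OutlierMatrixPair,
    clinical: pd.DataFrame,
    alpha: float = 0.05,
    min_outliers: int | None = None,
) -> pd.DataFrame:
    """Per-gene log-rank screen of outlier vs normal samples.

    For every gene with at least ``min_outliers`` outliers (high and low
    directions screened separately), the outlier sample class is compared to
    the normal class by log-rank test; the hazard ratio comes from a
    univariate Cox fit on the outlier indicator. Associations with log-rank
    p < alpha are retained.

    Returns a DataFrame with columns gene_id, direction, n_outlier,
    hazard_ratio, hr_ci_lower, hr_ci_upper, logrank_stat, p_value.
    """
    if min_outliers is None:
        min_outliers = pair.config.min_outliers
    rows = []
    for direction, mat in (("high", pair.b_high), ("low", pair.b_low)):
        if mat.shape[0] == 0:
            continue
        sample_ids = list(mat.columns)
        missing = [s for s in sample_ids if s not in clinical.index]
        if missing:
            raise ValueError(f"samples missing from clinical table: {missing[:10]}")
        clin = clinical.loc[sample_ids]
        times = clin["time"].to_numpy(dtype=float)
        events = clin["event"].to_numpy(dtype=int)
        counts = mat.sum(axis=1)
        tested = mat.loc[(counts >= min_outliers) & (counts < mat.shape[1])]
        if tested.shape[0] == 0:
            continue
        member = tested.to_numpy().T  # samples x genes
        stat, p = logrank_many(times, events, member)
        hit = p < alpha
        if not hit.any():
            continue
        beta, se, _, _ = cox_binary_many(times, events, member[:, hit])
        genes = tested.index[hit]
        for i, g in enumerate(genes):
            rows.append(
                {
                    "gene_id": g,
                    "direction": direction,
                    "n_outlier": int(counts[g]),
                    "hazard_ratio": float(np.exp(beta[i])),
                    "hr_ci_lower": float(np.exp(beta[i] - 1.96 * se[i])),
                    "hr_ci_upper": float(np.exp(beta[i] + 1.96 * se[i])),
                    "logrank_stat": float(stat[np.flatnonzero(hit)[i]]),
                    "p_value": float(p[np.flatnonzero(hit)[i]]),
                }
            )
    cols = ["gene_id", "direction", "n_outlier", "hazard_ratio",
            "hr_ci_lower", "hr_ci_upper", "logrank_stat", "p_value"]
    return pd.DataFrame(rows, columns=cols)
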