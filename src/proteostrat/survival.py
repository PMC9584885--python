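"""Clinical endpoints, survival models, and functional phenotype summaries.

Endpoints follow the usual leukemia-cohort conventions: time to next
treatment (TTNT) runs from sample collection to treatment initiation,
with untreated patients — including those who die untreated — censored
at last contact; time to first treatment (TTFT) runs from diagnosis;
overall survival (OS) runs from collection to death.  Kaplan-Meier
estimation and the log-rank test are delegated to lifelines; the Cox
proportional-hazards model is fitted here by Newton-Raphson on the
partial likelihood with Efron (default) or Breslow tie handling, which
also exposes the score test whose two-group Breslow form equals the
log-rank statistic.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

__all__ = [
    "build_endpoint",
    "km_curve",
    "logrank",
    "CoxResult",
    "cox_fit",
    "cox_score_test",
    "lymphocyte_growth",
    "viability_normalize",
    "classify_nuclei",
    "group_rank_tests",
]

ENDPOINT_ORIGIN = {"TTNT": "collection_day", "TTFT": "diagnosis_day",
                   "OS": "collection_day"}


def build_endpoint(records: pd.DataFrame, endpoint: str) -> pd.DataFrame:
    """Construct (time, event) pairs from a clinical record table.

    ``records`` carries per-sample day offsets: ``collection_day``,
    ``diagnosis_day``, ``treatment_day`` (NaN if never treated),
    ``death_day`` (NaN if alive), ``last_contact_day``.  Patients with
    no follow-up at all are excluded (count logged via a warning);
    treatment before the origin raises with the offending sample ids.
    """
    endpoint = endpoint.upper()
    if endpoint not in ENDPOINT_ORIGIN:
        raise ValueError(f"unknown endpoint {endpoint!r}")
    origin_col = ENDPOINT_ORIGIN[endpoint]
    rows = []
    excluded = []
    bad = []
    for sample, rec in records.iterrows():
        origin = rec[origin_col]
        treatment = rec.get("treatment_day", np.nan)
        death = rec.get("death_day", np.nan)
        last = rec.get("last_contact_day", np.nan)
        if np.isnan(treatment) and np.isnan(death) and np.isnan(last):
            excluded.append(sample)
            continue
        if endpoint in ("TTNT", "TTFT"):
            if not np.isnan(treatment):
                if treatment < origin:
                    bad.append(sample)
                    continue
                time, event = treatment - origin, 1
            else:
                # untreated (possibly deceased): censored at last contact
                cens = last if not np.isnan(last) else death
                if np.isnan(cens):
                    excluded.append(sample)
                    continue
                time, event = cens - origin, 0
        else:  # OS
            if not np.isnan(death):
                time, event = death - origin, 1
            else:
                if np.isnan(last):
                    excluded.append(sample)
                    continue
                time, event = last - origin, 0
        rows.append((sample, float(time), int(event)))
    if bad:
        raise ValueError(
            f"treatment precedes the {endpoint} origin for samples: "
            f"{bad[:5]}")
    if excluded:
        warnings.warn(f"{len(excluded)} sample(s) excluded from {endpoint} "
                      "(no follow-up)")
    out = pd.DataFrame(rows, columns=["sample_id", "time_days", "event"]
                       ).set_index("sample_id")
    out.attrs["endpoint"] = endpoint
    out.attrs["n_excluded"] = len(excluded)
    return out


def km_curve(times, events) -> tuple[pd.DataFrame, float | None]:
    """Kaplan-Meier product-limit estimate plus median survival.

    Returns a step-function table (time, survival) and the median
    (earliest time with S <= 0.5; None if never reached).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("need at least one observation")
    if (times < 0).any():
        raise ValueError("negative times")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    sf = kmf.survival_function_
    curve = pd.DataFrame({"time": sf.index.to_numpy(dtype=float),
                          "survival": sf.iloc[:, 0].to_numpy(dtype=float)})
    below = curve[curve["survival"] <= 0.5]
    median = float(below["time"].iloc[0]) if not below.empty else None
    return curve, median


def logrank(groups: list[pd.DataFrame]) -> tuple[float, int, float]:
    """Standard O - E log-rank over >= 2 endpoint tables.

    Each table needs ``time_days`` and ``event`` columns; returns
    (chi-square, df, p).
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for g in groups:
        if len(g) == 0:
            raise ValueError("a group has zero samples")
    times = np.concatenate([g["time_days"].to_numpy(dtype=float)
                            for g in groups])
    events = np.concatenate([g["event"].to_numpy(dtype=int) for g in groups])
    labels = np.concatenate([np.full(len(g), i)
                             for i, g in enumerate(groups)])
    res = multivariate_logrank_test(times, labels, events)
    return (float(res.test_statistic), len(groups) - 1, float(res.p_value))


@dataclass
class CoxResult:
    """Wald summaries of a fitted proportional-hazards model."""

    table: pd.DataFrame          # coef, hr, ci_lower, ci_upper, se, p
    log_likelihood: float
    ties: str
    converged: bool
    warnings: list


def _cox_loglik_grad_hess(beta: np.ndarray, X: np.ndarray, time: np.ndarray,
                          event: np.ndarray, ties: str):
    """Partial log likelihood with gradient and Hessian (Efron/Breslow)."""
    order = np.argsort(-time, kind="mergesort")  # decreasing time
    Xo, to, eo = X[order], time[order], event[order]
    n, p = Xo.shape
    eta = Xo @ beta
    w = np.exp(eta)
    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    # cumulative risk-set sums while walking down in time
    S0 = 0.0
    S1 = np.zeros(p)
    S2 = np.zeros((p, p))
    i = 0
    while i < n:
        j = i
        while j < n and to[j] == to[i]:
            j += 1
        for idx in range(i, j):
            S0 += w[idx]
            S1 += w[idx] * Xo[idx]
            S2 += w[idx] * np.outer(Xo[idx], Xo[idx])
        dead = [idx for idx in range(i, j) if eo[idx] == 1]
        d = len(dead)
        if d:
            sx = Xo[dead].sum(axis=0)
            ll += float(eta[dead].sum())
            grad += sx
            if ties == "breslow" or d == 1:
                for _ in range(d):
                    ll -= math.log(S0)
                    grad -= S1 / S0
                    hess -= S2 / S0 - np.outer(S1, S1) / S0**2
            elif ties == "efron":
                wd = w[dead].sum()
                S1d = (w[dead, None] * Xo[dead]).sum(axis=0)
                S2d = np.einsum("k,ki,kj->ij", w[dead], Xo[dead], Xo[dead])
                for r in range(d):
                    f = r / d
                    denom = S0 - f * wd
                    num1 = S1 - f * S1d
                    num2 = S2 - f * S2d
                    ll -= math.log(denom)
                    grad -= num1 / denom
                    hess -= num2 / denom - np.outer(num1, num1) / denom**2
            else:
                raise ValueError(f"unknown ties method {ties!r}")
        i = j
    return ll, grad, hess


def cox_fit(covariates: pd.DataFrame, endpoint: pd.DataFrame,
            ties: str = "efron", max_iter: int = 50,
            tol: float = 1e-9) -> CoxResult:
    """Cox proportional hazards by Newton-Raphson.

    ``covariates`` is samples x p; ``endpoint`` provides ``time_days``
    and ``event``.  Monotone likelihood (perfect separation) is flagged
    with a warning and the last iterate reported; a constant covariate
    raises.
    """
    cov = covariates.loc[endpoint.index]
    X = cov.to_numpy(dtype=float)
    time = endpoint["time_days"].to_numpy(dtype=float)
    event = endpoint["event"].to_numpy(dtype=int)
    if event.sum() < 1:
        raise ValueError("need at least one event")
    const = [c for c in cov.columns if cov[c].nunique() < 2]
    if const:
        raise ValueError(f"constant covariate(s): {const}")
    p = X.shape[1]
    beta = np.zeros(p)
    converged = False
    warns: list[str] = []
    ll_prev = -np.inf
    for _ in range(max_iter):
        ll, grad, hess = _cox_loglik_grad_hess(beta, X, time, event, ties)
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            warns.append("singular Hessian; stopping early")
            break
        beta_new = beta - step
        if np.abs(beta_new).max() > 50:
            warns.append("monotone likelihood suspected "
                         "(coefficient diverging); result flagged")
            warnings.warn(warns[-1])
            beta = beta_new
            break
        beta = beta_new
        if abs(ll - ll_prev) < tol:
            converged = True
            break
        ll_prev = ll
    if np.abs(beta).max() > 10 and not any("monotone" in w for w in warns):
        warns.append("monotone likelihood suspected "
                     "(|coefficient| > 10); result flagged")
        warnings.warn(warns[-1])
    ll, grad, hess = _cox_loglik_grad_hess(beta, X, time, event, ties)
    try:
        cov_beta = np.linalg.inv(-hess)
    except np.linalg.LinAlgError:
        warns.append("singular information matrix; using pseudo-inverse")
        warnings.warn(warns[-1])
        cov_beta = np.linalg.pinv(-hess)
    se = np.sqrt(np.clip(np.diag(cov_beta), 0, None))
    z = beta / se
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    zcrit = stats.norm.ppf(0.975)
    table = pd.DataFrame({
        "coef": beta, "hr": np.exp(beta), "se": se,
        "ci_lower": np.exp(beta - zcrit * se),
        "ci_upper": np.exp(beta + zcrit * se),
        "p": pvals,
    }, index=cov.columns)
    return CoxResult(table=table, log_likelihood=float(ll), ties=ties,
                     converged=converged, warnings=warns)


def cox_score_test(covariates: pd.DataFrame, endpoint: pd.DataFrame,
                   ties: str = "breslow") -> tuple[float, float]:
    """Score (Rao) test at beta = 0; for one binary covariate with
    Breslow ties and no tied event times this equals the log-rank
    chi-square."""
    cov = covariates.loc[endpoint.index]
    X = cov.to_numpy(dtype=float)
    time = endpoint["time_days"].to_numpy(dtype=float)
    event = endpoint["event"].to_numpy(dtype=int)
    p = X.shape[1]
    _, grad, hess = _cox_loglik_grad_hess(np.zeros(p), X, time, event, ties)
    stat = float(grad @ np.linalg.solve(-hess, grad))
    return stat, float(stats.chi2.sf(stat, p))


# ---------------------------------------------------------------------------
# functional phenotypes

def lymphocyte_growth(series: pd.DataFrame, min_points: int = 4
                      ) -> pd.DataFrame:
    """Per-sample slope of log10 lymphocyte count per day (OLS).

    Samples with fewer than ``min_points`` time points are excluded and
    listed in the result attrs; non-positive counts raise.
    """
    if (series["count"] <= 0).any():
        raise ValueError("non-positive lymphocyte counts")
    rows = []
    excluded = []
    for sample, sub in series.groupby("sample_id"):
        if len(sub) < min_points:
            excluded.append(sample)
            continue
        slope = np.polyfit(sub["day"].to_numpy(dtype=float),
                           np.log10(sub["count"].to_numpy(dtype=float)),
                           1)[0]
        rows.append((sample, float(slope)))
    out = pd.DataFrame(rows, columns=["sample_id", "growth_rate"]
                       ).set_index("sample_id")
    out.attrs["excluded"] = excluded
    return out


def viability_normalize(plate: pd.DataFrame) -> pd.DataFrame:
    """Percent-alive per well normalized to the solvent-control mean.

    For every sample the mean percent alive over its solvent wells is
    the 100% reference; wells with zero cells get a missing value with
    a warning.  Scale-invariant in the cell counts.
    """
    plate = plate.copy()
    zero = plate["n_cells"] == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} well(s) with zero cells; "
                      "viability set to missing")
    with np.errstate(invalid="ignore", divide="ignore"):
        plate["pct_alive"] = np.where(
            zero, np.nan, 100.0 * plate["n_alive"] / plate["n_cells"])
    out = []
    for sample, sub in plate.groupby("sample_id"):
        solvent = sub[sub["is_solvent_control"] == 1]["pct_alive"].dropna()
        if solvent.empty:
            raise ValueError(f"no solvent-control wells for sample {sample!r}")
        ref = solvent.mean()
        treated = sub.copy()
        treated["viability_pct"] = 100.0 * treated["pct_alive"] / ref
        out.append(treated)
    return pd.concat(out, axis=0)


def classify_nuclei(areas, threshold: float = 23.8) -> float:
    """Fraction of cells alive by the nuclear-area rule (alive = area
    strictly greater than the threshold; condensed nuclei are dead)."""
    areas = np.asarray(areas, dtype=float)
    if areas.size == 0:
        raise ValueError("empty area list")
    if (areas <= 0).any():
        raise ValueError("areas must be positive")
    return float((areas > threshold).mean())


def group_rank_tests(values, groups) -> float:
    """Two-sided rank-sum p for 2 groups, Kruskal-Wallis for more.

    Uses the exact rank-sum null when both groups have <= 10
    observations and there are no ties, the tie-corrected normal
    approximation otherwise.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    uniq = pd.unique(groups)
    if len(uniq) < 2:
        raise ValueError("need at least two groups")
    samples = [values[groups == g] for g in uniq]
    for s in samples:
        if s.size == 0:
            raise ValueError("a group is empty")
    if len(uniq) == 2:
        a, b = samples
        small = a.size <= 10 and b.size <= 10
        no_ties = np.unique(np.concatenate([a, b])).size == a.size + b.size
        method = "exact" if (small and no_ties) else "asymptotic"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
        return float(res.pvalue)
    res = stats.kruskal(*samples)
    return float(res.pvalue)
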