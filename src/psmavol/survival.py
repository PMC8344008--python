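"""Survival analysis plan: Cox regression, Kaplan–Meier, maximally
selected rank statistics, Martingale diagnostics, rank correlations.

Conventions, fixed for reproducibility:

* all continuous covariates are natural-log transformed before Cox
  regression and Martingale analysis; volumetric response enters Cox as
  the log of the baseline/interim volume ratio;
* Cox partial likelihood with Efron tie handling (lifelines default);
* the standardized two-sample log-rank statistic uses the hypergeometric
  variance; without tied event times it coincides with the Cox score test
  at beta = 0;
* Martingale residuals use the Breslow baseline cumulative hazard, so they
  sum to zero exactly for any risk score (including the null model, where
  they reduce to event minus the Nelson–Aalen estimate);
* median splits send ties to the low group;
* cutoff finding scans midpoints between consecutive distinct covariate
  values whose induced groups both hold at least ``min_prop`` of patients,
  and returns the cutoff maximizing |standardized log-rank| (smallest on
  ties); significance, if requested, comes from a permutation null of the
  maximal statistic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats

from .errors import DegenerateModelError, InputError


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CovariateEffect:
    name: str
    hazard_ratio: float
    ci_lower: float
    ci_upper: float
    p_value: float
    coef: float
    se: float


@dataclass(frozen=True)
class CoxResult:
    """Proportional-hazards fit summary."""

    effects: tuple[CovariateEffect, ...]
    lrt_p_value: float
    n_used: int
    n_dropped: int
    n_events: int

    def effect(self, name: str) -> CovariateEffect:
        for e in self.effects:
            if e.name == name:
                return e
        raise KeyError(name)


@dataclass(frozen=True)
class KMGroupSummary:
    label: str
    n: int
    n_events: int
    median_months: float  # NaN when the curve never reaches 0.5


@dataclass(frozen=True)
class KMLogrankResult:
    groups: tuple[KMGroupSummary, KMGroupSummary]
    logrank_statistic: float  # chi-square, 1 df
    logrank_p: float
    hazard_ratio: float
    hr_ci: tuple[float, float]
    hr_p: float


@dataclass(frozen=True)
class CutoffResult:
    covariate: str
    cutoff: float
    statistic: float  # maximal standardized log-rank statistic (signed)
    n_low: int
    n_high: int
    p_value: float = float("nan")  # permutation p of max|z|, if computed


# ---------------------------------------------------------------------------
# core rank statistics (hand-rolled; shared by log-rank, maxstat, score test)
# ---------------------------------------------------------------------------

def logrank_z(
    durations: np.ndarray, events: np.ndarray, group: np.ndarray
) -> float:
    """Standardized two-sample log-rank statistic (O - E)/sqrt(V) for the
    ``group == True`` sample, hypergeometric variance."""
    durations = np.asarray(durations, dtype=float)
    events = np.asarray(events, dtype=bool)
    group = np.asarray(group, dtype=bool)
    if group.all() or not group.any():
        raise InputError("both groups must be nonempty")
    event_times = np.unique(durations[events])
    o_minus_e = 0.0
    var = 0.0
    for t in event_times:
        at_risk = durations >= t
        n = int(at_risk.sum())
        n1 = int((at_risk & group).sum())
        d = int((events & (durations == t)).sum())
        d1 = int((events & (durations == t) & group).sum())
        if n == 0:
            continue
        e1 = d * n1 / n
        o_minus_e += d1 - e1
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var <= 0:
        return 0.0
    return o_minus_e / math.sqrt(var)


def cox_score_test(
    durations: np.ndarray, events: np.ndarray, covariate: np.ndarray
) -> tuple[float, float]:
    """Cox partial-likelihood score test at beta = 0.

    Returns (score z, chi-square); with untied event times on a binary
    covariate this equals the log-rank statistic exactly.
    """
    durations = np.asarray(durations, dtype=float)
    events = np.asarray(events, dtype=bool)
    x = np.asarray(covariate, dtype=float)
    u = 0.0
    info = 0.0
    for t in np.unique(durations[events]):
        at_risk = durations >= t
        xr = x[at_risk]
        d_idx = events & (durations == t)
        d = int(d_idx.sum())
        mean_r = xr.mean()
        u += x[d_idx].sum() - d * mean_r
        info += d * (np.mean(xr**2) - mean_r**2)
    if info <= 0:
        raise DegenerateModelError("no covariate variation in any risk set")
    z = u / math.sqrt(info)
    return z, z * z


# ---------------------------------------------------------------------------
# Cox regression (lifelines-backed)
# ---------------------------------------------------------------------------

def cox_fit(
    cohort: pd.DataFrame,
    covariates: Sequence[str],
    duration_col: str = "os_months",
    event_col: str = "event",
    log_transform: bool | Sequence[str] = True,
) -> CoxResult:
    """Cox proportional-hazards fit (Efron ties) on selected covariates.

    ``log_transform`` may be True (log every covariate), False, or the list
    of columns to log. Rows with any missing covariate are dropped
    (complete-case) and the dropped count reported. Boolean covariates are
    never log-transformed.
    """
    covariates = list(covariates)
    missing_cols = [c for c in covariates + [duration_col, event_col] if c not in cohort]
    if missing_cols:
        raise InputError(f"columns not in cohort: {missing_cols}")
    df = cohort[covariates + [duration_col, event_col]].copy()
    n_total = len(df)
    df = df.dropna()
    n_dropped = n_total - len(df)

    if log_transform is True:
        to_log = [c for c in covariates if df[c].dtype != bool]
    elif log_transform is False:
        to_log = []
    else:
        to_log = list(log_transform)
    for c in to_log:
        bad = df.index[df[c] <= 0]
        if len(bad):
            raise InputError(
                f"covariate {c!r} must be > 0 for log transform; offending rows: {list(bad[:5])}"
            )
        df[c] = np.log(df[c].astype(float))
    for c in covariates:
        if df[c].dtype == bool:
            df[c] = df[c].astype(float)
        if float(np.var(df[c])) == 0.0:
            raise DegenerateModelError(f"covariate {c!r} is constant; HR undefined")

    n_events = int(df[event_col].sum())
    if n_events < 2:
        raise DegenerateModelError(f"need >= 2 events, got {n_events}")

    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col=duration_col, event_col=event_col)
    except Exception as exc:  # lifelines ConvergenceError and kin
        raise DegenerateModelError(f"Cox fit failed: {exc}") from exc
    summ = cph.summary
    effects = tuple(
        CovariateEffect(
            name=str(name),
            hazard_ratio=float(row["exp(coef)"]),
            ci_lower=float(row["exp(coef) lower 95%"]),
            ci_upper=float(row["exp(coef) upper 95%"]),
            p_value=float(row["p"]),
            coef=float(row["coef"]),
            se=float(row["se(coef)"]),
        )
        for name, row in summ.iterrows()
    )
    lrt_p = float(cph.log_likelihood_ratio_test().p_value)
    return CoxResult(effects, lrt_p, len(df), n_dropped, n_events)


# ---------------------------------------------------------------------------
# Kaplan–Meier / log-rank
# ---------------------------------------------------------------------------

def km_median(durations: np.ndarray, events: np.ndarray) -> float:
    """Kaplan–Meier median: earliest time with S(t) <= 0.5 (NaN if never)."""
    kmf = KaplanMeierFitter()
    kmf.fit(durations, events)
    med = kmf.median_survival_time_
    return float("nan") if np.isinf(med) else float(med)


def km_logrank(
    cohort: pd.DataFrame,
    group_flag: str | np.ndarray,
    duration_col: str = "os_months",
    event_col: str = "event",
    labels: tuple[str, str] = ("low", "high"),
) -> KMLogrankResult:
    """KM medians per group, two-sided log-rank p, and the binary-group
    Cox hazard ratio (high vs low)."""
    grp = cohort[group_flag] if isinstance(group_flag, str) else pd.Series(group_flag)
    grp = np.asarray(grp, dtype=bool)
    t = cohort[duration_col].to_numpy(float)
    e = cohort[event_col].to_numpy(bool)
    if grp.all() or not grp.any():
        raise InputError("both groups must be nonempty")

    summaries = []
    for flag, label in ((False, labels[0]), (True, labels[1])):
        m = grp == flag
        summaries.append(
            KMGroupSummary(label, int(m.sum()), int(e[m].sum()), km_median(t[m], e[m]))
        )
    lr = logrank_test(t[grp], t[~grp], e[grp], e[~grp])
    df = pd.DataFrame({"_t": t, "_e": e, "_g": grp.astype(float)})
    try:
        fit = cox_fit(df, ["_g"], duration_col="_t", event_col="_e", log_transform=False)
        eff = fit.effect("_g")
        hr, ci, hr_p = eff.hazard_ratio, (eff.ci_lower, eff.ci_upper), eff.p_value
    except DegenerateModelError:
        hr, ci, hr_p = float("nan"), (float("nan"), float("nan")), float("nan")
    return KMLogrankResult(
        groups=(summaries[0], summaries[1]),
        logrank_statistic=float(lr.test_statistic),
        logrank_p=float(lr.p_value),
        hazard_ratio=hr,
        hr_ci=ci,
        hr_p=hr_p,
    )


def median_binarize(values: pd.Series | np.ndarray) -> np.ndarray:
    """High group = value > median (midpoint convention); ties go low."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)] if np.isnan(v).any() else v
    if v.size < 2:
        raise InputError("need >= 2 values to binarize")
    med = float(np.median(v))
    full = np.asarray(values, dtype=float)
    flag = full > med
    if flag.all() or not flag.any():
        raise DegenerateModelError("median split is degenerate (all values equal a side)")
    return flag


# ---------------------------------------------------------------------------
# maximally selected rank statistics
# ---------------------------------------------------------------------------

def maxstat_cutoff(
    cohort: pd.DataFrame,
    covariate: str,
    duration_col: str = "os_months",
    event_col: str = "event",
    min_prop: float = 0.1,
    n_permutations: int = 0,
    seed: int | None = None,
) -> CutoffResult:
    """Best survival cutoff by maximally selected standardized log-rank.

    Candidate cutoffs are midpoints between consecutive distinct sorted
    covariate values; a candidate is admissible when both induced groups
    contain at least ``min_prop`` of the patients. The returned cutoff
    maximizes the absolute standardized log-rank statistic (smallest cutoff
    on exact ties). With ``n_permutations > 0`` a permutation p-value for
    max|z| is attached (the adjustment for having scanned many cutoffs).
    """
    x = cohort[covariate].to_numpy(float)
    t = cohort[duration_col].to_numpy(float)
    e = cohort[event_col].to_numpy(bool)
    keep = ~np.isnan(x)
    x, t, e = x[keep], t[keep], e[keep]
    n = x.size
    if n < 4:
        raise InputError("need >= 4 patients for cutoff finding")

    def _scan(xv: np.ndarray) -> tuple[float, float] | None:
        distinct = np.unique(xv)
        best: tuple[float, float] | None = None  # (|z|, cutoff) -> stores (z, cutoff)
        best_abs = -1.0
        for lo, hi in zip(distinct[:-1], distinct[1:]):
            cut = 0.5 * (lo + hi)
            high = xv > cut
            n_high = int(high.sum())
            if n_high < min_prop * n or (n - n_high) < min_prop * n:
                continue
            z = logrank_z(t, e, high)
            if abs(z) > best_abs + 1e-15:
                best_abs = abs(z)
                best = (z, cut)
        return best

    found = _scan(x)
    if found is None:
        raise InputError("fewer than 2 distinct values in the admissible range")
    z, cut = found

    p = float("nan")
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        obs = abs(z)
        exceed = 0
        for _ in range(n_permutations):
            perm = _scan(rng.permutation(x))
            if perm is not None and abs(perm[0]) >= obs:
                exceed += 1
        p = (exceed + 1) / (n_permutations + 1)

    n_high = int((x > cut).sum())
    return CutoffResult(
        covariate=covariate, cutoff=float(cut), statistic=float(z),
        n_low=n - n_high, n_high=n_high, p_value=p,
    )


# ---------------------------------------------------------------------------
# Martingale residuals
# ---------------------------------------------------------------------------

def breslow_cumulative_hazard(
    durations: np.ndarray, events: np.ndarray, risk_scores: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Breslow baseline cumulative hazard at the distinct event times.

    ``H0(t) = sum_{event times s <= t} d_s / sum_{j at risk at s} r_j``.
    With unit risk scores this is the Nelson–Aalen estimator.
    """
    durations = np.asarray(durations, dtype=float)
    events = np.asarray(events, dtype=bool)
    r = np.asarray(risk_scores, dtype=float)
    times = np.unique(durations[events])
    increments = np.empty(times.size)
    for k, s in enumerate(times):
        d = int((events & (durations == s)).sum())
        denom = r[durations >= s].sum()
        increments[k] = d / denom
    return times, np.cumsum(increments)


def martingale_residuals(
    cohort: pd.DataFrame,
    fit: CoxResult | None = None,
    covariates: Sequence[str] | None = None,
    duration_col: str = "os_months",
    event_col: str = "event",
    log_transform: bool | Sequence[str] = True,
) -> pd.Series:
    """Per-patient martingale residuals, ``event_i - r_i * H0(t_i)``.

    With ``fit=None`` the null model is used (unit risk scores, Nelson–Aalen
    cumulative hazard). With a fitted :class:`CoxResult`, risk scores come
    from its coefficients applied to ``covariates`` (same log convention as
    the fit). Residuals sum to zero exactly by the Breslow construction.
    """
    t = cohort[duration_col].to_numpy(float)
    e = cohort[event_col].to_numpy(bool)
    n = t.size
    if fit is None:
        r = np.ones(n)
    else:
        if covariates is None:
            covariates = [eff.name for eff in fit.effects]
        X = cohort[list(covariates)].copy()
        if log_transform is True:
            to_log = [c for c in covariates if X[c].dtype != bool]
        elif log_transform is False:
            to_log = []
        else:
            to_log = list(log_transform)
        for c in to_log:
            X[c] = np.log(X[c].astype(float))
        for c in covariates:
            if X[c].dtype == bool:
                X[c] = X[c].astype(float)
        beta = np.array([fit.effect(c).coef for c in covariates])
        r = np.exp(X.to_numpy(float) @ beta)
    times, H0 = breslow_cumulative_hazard(t, e, r)
    idx = np.searchsorted(times, t, side="right") - 1
    H_at_t = np.where(idx >= 0, H0[np.clip(idx, 0, None)], 0.0)
    resid = e.astype(float) - r * H_at_t
    return pd.Series(resid, index=cohort.index, name="martingale_residual")


# ---------------------------------------------------------------------------
# rank correlation / group comparison
# ---------------------------------------------------------------------------

def correlate_and_compare(
    cohort: pd.DataFrame,
    tv_decline_col: str = "tv_decline_pct",
    psa_decline_col: str = "psa_decline_pct",
    psa_responder_col: str = "psa_responder",
) -> dict:
    """Spearman rho between volumetric and biochemical decline, and a
    Wilcoxon rank-sum comparison of volumetric decline by PSA-responder
    status (exact p for group sizes <= 10, normal approximation above)."""
    cols = [tv_decline_col, psa_decline_col, psa_responder_col]
    absent = [c for c in cols if c not in cohort]
    if absent:
        raise InputError(f"columns not in cohort: {absent}")
    d = cohort[cols].dropna()
    if len(d) < 3:
        raise InputError("need >= 3 complete pairs")
    rho, rho_p = stats.spearmanr(d[tv_decline_col], d[psa_decline_col])
    resp = d[psa_responder_col].astype(bool)
    out = {
        "spearman_rho": float(rho),
        "spearman_p": float(rho_p),
        "n_pairs": int(len(d)),
    }
    if resp.any() and (~resp).any():
        a = d.loc[resp, tv_decline_col]
        b = d.loc[~resp, tv_decline_col]
        method = "exact" if min(len(a), len(b)) <= 10 else "asymptotic"
        mw = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
        out.update(
            {
                "wilcoxon_p": float(mw.pvalue),
                "median_decline_psa_responders": float(a.median()),
                "median_decline_psa_nonresponders": float(b.median()),
            }
        )
    else:
        out.update(
            {
                "wilcoxon_p": float("nan"),
                "median_decline_psa_responders": float("nan"),
                "median_decline_psa_nonresponders": float("nan"),
            }
        )
    return out


# ---------------------------------------------------------------------------
# the full analysis plan
# ---------------------------------------------------------------------------

def _cox_to_dict(res: CoxResult) -> dict:
    return {
        "covariates": {
            e.name: {
                "hr": e.hazard_ratio,
                "ci_lower": e.ci_lower,
                "ci_upper": e.ci_upper,
                "p": e.p_value,
            }
            for e in res.effects
        },
        "lrt_p": res.lrt_p_value,
        "n_used": res.n_used,
        "n_dropped": res.n_dropped,
        "n_events": res.n_events,
    }


def _km_to_dict(res: KMLogrankResult) -> dict:
    return {
        "groups": [
            {"label": g.label, "n": g.n, "events": g.n_events, "median_months": g.median_months}
            for g in res.groups
        ],
        "logrank_p": res.logrank_p,
        "hr_high_vs_low": res.hazard_ratio,
        "hr_ci": list(res.hr_ci),
        "hr_p": res.hr_p,
    }


def run_paper_analysis(
    cohort: pd.DataFrame,
    alpha: float = 0.05,
    maxstat_covariates: Sequence[str] = ("mean_suv_max_baseline", "tlq_baseline"),
    seed: int = 0,
) -> dict:
    """Execute the full statistical plan on a cohort table.

    Univariable Cox for the baseline PET burden metrics; multivariable Cox
    adjusted for PSA and LDH; KM by median split of baseline PSMA-TV, TLQ
    and meanSUVmax; volumetric response (as log baseline/interim ratio and
    as binary flag) against OS in the full cohort and after excluding the
    low-expression subgroup — the analysis' headline contrast; the
    decline-vs-PSA rank statistics; cutoff finding; null-model Martingale
    residuals. Degenerate sub-models are recorded, not fatal.
    """
    report: dict = {"n_patients": int(len(cohort)), "alpha": alpha, "models": {}}
    models = report["models"]

    def _try(key: str, fn):
        try:
            models[key] = fn()
        except (DegenerateModelError, InputError) as exc:
            models[key] = {"status": "degenerate", "reason": str(exc)}

    for cov in ("tv_baseline_ml", "tlq_baseline", "mean_suv_max_baseline", "tv_interim_ml", "tlq_interim"):
        if cov in cohort:
            _try(f"uni_cox_{cov}", lambda c=cov: _cox_to_dict(cox_fit(cohort, [c])))
            _try(
                f"multi_cox_{cov}",
                lambda c=cov: _cox_to_dict(cox_fit(cohort, [c, "psa_baseline", "ldh"])),
            )

    for cov in ("tv_baseline_ml", "tlq_baseline", "mean_suv_max_baseline"):
        if cov in cohort:
            def _km(c=cov):
                flag = median_binarize(cohort[c])
                return _km_to_dict(km_logrank(cohort, flag))
            _try(f"km_median_{cov}", _km)

    # volumetric response: continuous (log ratio) and binary, full cohort
    resp_df = cohort.dropna(subset=["tv_ratio"])
    _try(
        "uni_cox_tv_response_full",
        lambda: _cox_to_dict(cox_fit(resp_df, ["tv_ratio"], log_transform=["tv_ratio"])),
    )
    _try(
        "multi_cox_tv_response_full",
        lambda: _cox_to_dict(
            cox_fit(resp_df, ["tv_ratio", "psa_baseline", "ldh"])
        ),
    )
    _try(
        "km_tv_responder_full",
        lambda: _km_to_dict(km_logrank(cohort, cohort["tv_responder"].astype(bool))),
    )

    # headline contrast: exclude the low-expression subgroup and refit
    if "low_expression" in cohort:
        sub = resp_df.loc[~resp_df["low_expression"].astype(bool)]
        report["n_low_expression"] = int(cohort["low_expression"].astype(bool).sum())
        _try(
            "uni_cox_tv_response_high_expr",
            lambda: _cox_to_dict(cox_fit(sub, ["tv_ratio"], log_transform=["tv_ratio"])),
        )
        _try(
            "multi_cox_tv_response_high_expr",
            lambda: _cox_to_dict(cox_fit(sub, ["tv_ratio", "psa_baseline", "ldh"])),
        )

    # expression within responders (median split), as in the subgroup analysis
    responders = cohort.loc[cohort["tv_responder"].astype(bool)]
    def _km_expr_resp():
        flag = median_binarize(responders["mean_suv_max_baseline"])
        return _km_to_dict(km_logrank(responders, flag))
    if len(responders) >= 4:
        _try("km_mean_suv_max_in_responders", _km_expr_resp)

    _try("correlation", lambda: correlate_and_compare(cohort))

    for cov in maxstat_covariates:
        if cov in responders and len(responders) >= 6:
            _try(
                f"maxstat_{cov}_in_responders",
                lambda c=cov: {
                    "cutoff": (r := maxstat_cutoff(responders, c, seed=seed)).cutoff,
                    "statistic": r.statistic,
                    "n_low": r.n_low,
                    "n_high": r.n_high,
                },
            )

    resid = martingale_residuals(cohort)
    models["martingale_null"] = {
        "sum": float(resid.sum()),
        "min": float(resid.min()),
        "max": float(resid.max()),
    }
    report["martingale_residuals"] = [float(v) for v in resid]
    report["median_os_months"] = km_median(
        cohort["os_months"].to_numpy(float), cohort["event"].to_numpy(bool)
    )
    return report
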