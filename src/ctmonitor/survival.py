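"""Survival endpoints stratified by ctDNA dynamics.

PFS and OS run from the start of checkpoint-inhibitor treatment to
progression/death, right-censored at last follow-up; all times are in
weeks. Kaplan-Meier curves and log-rank tests come from ``lifelines``;
univariate Cox hazard ratios from ``statsmodels`` PHReg with Breslow tie
handling. Durable clinical benefit (DCB) is at least stable disease
lasting 26 weeks from treatment start.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats
from statsmodels.duration.hazard_regression import PHReg

__all__ = [
    "KMCurve",
    "LogrankResult",
    "CoxResult",
    "kaplan_meier",
    "logrank_test",
    "cox_univariate",
    "durable_clinical_benefit",
    "dcb_rate",
    "mann_whitney_u",
    "stratified_endpoint_report",
]

DCB_THRESHOLD_WEEKS = 26.0


@dataclass(frozen=True)
class KMCurve:
    """Product-limit estimate: step-function support points and the median.

    ``median_weeks`` is the earliest time at which survival drops to 0.5
    or below, ``None`` when the curve never reaches 0.5 ("not reached").
    """

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    median_weeks: float | None


@dataclass(frozen=True)
class LogrankResult:
    statistic: float
    df: int
    p_value: float


@dataclass(frozen=True)
class CoxResult:
    hazard_ratio: float
    ci_lower: float
    ci_upper: float
    p_value: float
    log_hr: float
    se: float
    converged: bool


def kaplan_meier(records: Sequence[tuple[float, int]]) -> KMCurve:
    """Kaplan-Meier product-limit estimator from (time, event) pairs."""
    if len(records) == 0:
        raise ValueError("kaplan_meier requires at least one record")
    times = np.asarray([t for t, _ in records], dtype=float)
    events = np.asarray([e for _, e in records], dtype=int)
    if np.any(times < 0):
        raise ValueError("times must be non-negative")

    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    sf = kmf.survival_function_
    table = kmf.event_table
    median = kmf.median_survival_time_
    return KMCurve(
        times=sf.index.to_numpy(dtype=float),
        survival=sf.iloc[:, 0].to_numpy(dtype=float),
        at_risk=table["at_risk"].to_numpy(dtype=float),
        median_weeks=None if math.isinf(median) else float(median),
    )


def logrank_test(groups: Sequence[Sequence[tuple[float, int]]]) -> LogrankResult:
    """Mantel-Cox log-rank test across two or more groups."""
    if len(groups) < 2:
        raise ValueError("logrank_test needs at least two groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("every group must be non-empty")
    times, events, labels = [], [], []
    for i, g in enumerate(groups):
        for t, e in g:
            times.append(t)
            events.append(e)
            labels.append(i)
    res = multivariate_logrank_test(times, labels, events)
    return LogrankResult(
        statistic=float(res.test_statistic),
        df=len(groups) - 1,
        p_value=float(res.p_value),
    )


def cox_univariate(
    records: Sequence[tuple[float, int]],
    binary_covariate: Sequence[int],
) -> CoxResult:
    """Univariate Cox proportional-hazards fit for a 0/1 covariate.

    Breslow tie handling; 95% CI as ``exp(beta +/- 1.96 SE)``. Monotone
    partial likelihoods (complete separation of event times between the
    groups) are returned flagged ``converged=False`` rather than raised.
    """
    times = np.asarray([t for t, _ in records], dtype=float)
    events = np.asarray([e for _, e in records], dtype=int)
    x = np.asarray(binary_covariate, dtype=float)
    if len(x) != len(times):
        raise ValueError("covariate length must match records")
    if len(set(x)) < 2:
        raise ValueError("both covariate levels must be present")
    for level in (0, 1):
        if events[x == level].sum() < 1:
            raise ValueError(f"covariate level {level} has no events")

    model = PHReg(times, x[:, None], status=events, ties="breslow")
    import warnings

    with np.errstate(all="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore")  # non-convergence is flagged, not raised
        try:
            res = model.fit(disp=False)
            beta = float(res.params[0])
            se = float(res.bse[0])
            p = float(res.pvalues[0])
        except Exception:
            beta, se, p = math.nan, math.nan, math.nan

    # Monotone likelihood shows up as a runaway coefficient or blown-up SE.
    converged = np.isfinite(beta) and np.isfinite(se) and abs(beta) < 15 and se < 50
    if not converged:
        return CoxResult(math.nan, math.nan, math.nan, math.nan, beta, se, False)
    return CoxResult(
        hazard_ratio=math.exp(beta),
        ci_lower=math.exp(beta - 1.96 * se),
        ci_upper=math.exp(beta + 1.96 * se),
        p_value=p,
        log_hr=beta,
        se=se,
        converged=True,
    )


def durable_clinical_benefit(
    pfs_weeks: float,
    pfs_event: int,
    threshold_weeks: float = DCB_THRESHOLD_WEEKS,
) -> Literal["true", "false", "indeterminate"]:
    """DCB status: progression-free for at least ``threshold_weeks``.

    Patients censored before the threshold are ``indeterminate`` — their
    benefit duration is unknown — and are dropped from rate denominators.
    """
    if pfs_weeks < 0:
        raise ValueError("pfs_weeks must be non-negative")
    if pfs_weeks >= threshold_weeks:
        return "true"
    if pfs_event == 1:
        return "false"
    return "indeterminate"


def dcb_rate(
    pfs_weeks: Sequence[float],
    pfs_event: Sequence[int],
    threshold_weeks: float = DCB_THRESHOLD_WEEKS,
) -> tuple[float | None, int]:
    """DCB rate among evaluable (non-indeterminate) patients.

    Returns (rate or None when nobody is evaluable, evaluable n).
    """
    calls = [
        durable_clinical_benefit(t, e, threshold_weeks)
        for t, e in zip(pfs_weeks, pfs_event)
    ]
    evaluable = [c for c in calls if c != "indeterminate"]
    if not evaluable:
        return None, 0
    return sum(c == "true" for c in evaluable) / len(evaluable), len(evaluable)


def mann_whitney_u(
    sample_a: Sequence[float], sample_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Exact enumeration when the pooled sample is small (<= 16) and tie-free;
    otherwise the normal approximation with tie and continuity correction.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    no_ties = len(np.unique(pooled)) == pooled.size
    method = "exact" if (pooled.size <= 16 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.statistic), min(1.0, float(res.pvalue))


def _group_records(df: pd.DataFrame, time_col: str, event_col: str):
    return list(zip(df[time_col].tolist(), df[event_col].astype(int).tolist()))


def _endpoint_block(df: pd.DataFrame, group_col: str) -> dict:
    """KM medians, pairwise log-rank, Cox HR and DCB rates for one grouping."""
    out: dict = {"groups": {}, "pfs": {}, "os": {}}
    groups = [g for g in df[group_col].dropna().unique()]
    for g in sorted(groups):
        sub = df[df[group_col] == g]
        block = {"n": int(len(sub))}
        for ep in ("pfs", "os"):
            curve = kaplan_meier(_group_records(sub, f"{ep}_weeks", f"{ep}_event"))
            block[f"median_{ep}_weeks"] = curve.median_weeks
        rate, n_eval = dcb_rate(sub["pfs_weeks"], sub["pfs_event"])
        block["dcb_rate"] = rate
        block["dcb_evaluable_n"] = n_eval
        out["groups"][str(g)] = block

    if len(groups) >= 2:
        for ep in ("pfs", "os"):
            recs = [
                _group_records(df[df[group_col] == g], f"{ep}_weeks", f"{ep}_event")
                for g in sorted(groups)
            ]
            lr = logrank_test(recs)
            out[ep]["logrank_p"] = lr.p_value
            out[ep]["logrank_statistic"] = lr.statistic
        if len(groups) == 2 and set(map(str, groups)) == {"decrease", "no_decrease"}:
            # decrease coded 1 so HR < 1 means decrease does better
            x = (df[group_col] == "decrease").astype(int).tolist()
            for ep in ("pfs", "os"):
                try:
                    cox = cox_univariate(
                        _group_records(df, f"{ep}_weeks", f"{ep}_event"), x
                    )
                except ValueError:
                    continue
                if cox.converged:
                    out[ep]["hr_decrease"] = cox.hazard_ratio
                    out[ep]["hr_ci"] = [cox.ci_lower, cox.ci_upper]
                    out[ep]["hr_p"] = cox.p_value
                else:
                    out[ep]["hr_decrease"] = None
            # DCB-rate comparison between the two arms
            a = df[df[group_col] == "decrease"]
            b = df[df[group_col] == "no_decrease"]
            a_flags = _dcb_flags(a)
            b_flags = _dcb_flags(b)
            if a_flags and b_flags:
                _, p = mann_whitney_u(a_flags, b_flags)
                out["dcb_comparison_p"] = p
    return out


def _dcb_flags(df: pd.DataFrame) -> list[float]:
    flags = []
    for t, e in zip(df["pfs_weeks"], df["pfs_event"]):
        call = durable_clinical_benefit(t, int(e))
        if call != "indeterminate":
            flags.append(1.0 if call == "true" else 0.0)
    return flags


def stratified_endpoint_report(
    clinical: pd.DataFrame, dynamics: pd.DataFrame
) -> dict:
    """Full endpoint report joining clinical outcomes onto dynamics calls.

    Reproduces the standard comparison structure: the four-level dynamics
    categories; the binary decrease/no-decrease split excluding
    ctDNA-negative patients; and the binary split including negatives
    crossed with PD-L1 TPS >= 1% vs < 1%.
    """
    df = clinical.merge(dynamics, on="patient_id", how="inner")
    df = df[df["category"] != "excluded"].copy()

    report: dict = {
        "n_patients": int(len(df)),
        "four_level": _endpoint_block(df, "category"),
        "binary_exclude_negative": _endpoint_block(df, "group_exclude_negative"),
        "binary_include_negative": _endpoint_block(df, "group_include_negative"),
        "tps_strata": {},
    }
    if "tps_stratum" in df.columns:
        known = df[df["tps_stratum"].isin(["<1%", "1-49%", ">=50%"])]
        strata = {
            "tps_ge_1": known[known["tps_stratum"].isin(["1-49%", ">=50%"])],
            "tps_lt_1": known[known["tps_stratum"] == "<1%"],
        }
        for name, sub in strata.items():
            if len(sub) == 0:
                continue
            report["tps_strata"][name] = _endpoint_block(
                sub, "group_include_negative"
            )
    return report
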