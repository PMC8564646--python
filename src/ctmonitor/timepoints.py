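"""Follow-up timepoint evaluation from longitudinal ctDNA series.

Responding patients often show a transient ctDNA spike in the first one to
two weeks of checkpoint-inhibitor treatment (tumor DNA released by dying
cells) before levels fall; sampling too early therefore misclassifies
responders as increasing. This module characterizes that spike and scores
candidate follow-up weeks by how cleanly a 30%-change rule separates
responders (decreasing) from non-responders (non-decreasing).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import pandas as pd

from .dynamics import TimepointMeasurement, classify_dynamics

__all__ = [
    "Observation",
    "LongitudinalSeries",
    "detect_spike",
    "interpolate_at_week",
    "separation_by_timepoint",
]

DEFAULT_CANDIDATE_WEEKS = (1.0, 2.0, 4.0, 6.0)


@dataclass(frozen=True)
class Observation:
    week: float
    copies_per_ml: float | None
    status: str  # positive | negative | invalid


@dataclass(frozen=True)
class LongitudinalSeries:
    """Week-indexed ctDNA trajectory for one patient, plus the response label."""

    patient_id: str
    observations: tuple[Observation, ...]
    response_label: Literal["responder", "non-responder"] | None = None

    def __post_init__(self) -> None:
        weeks = [o.week for o in self.observations]
        if any(w < 0 for w in weeks):
            raise ValueError("weeks must be non-negative")
        if weeks != sorted(set(weeks)):
            raise ValueError("observation weeks must be strictly increasing")
        if not weeks or weeks[0] != 0:
            raise ValueError("a baseline (week 0) observation is required")

    @property
    def baseline(self) -> Observation:
        return self.observations[0]


def detect_spike(
    series: LongitudinalSeries,
    spike_window_weeks: float = 2.0,
    threshold: float = 0.30,
) -> Literal["spike", "no_spike", "unevaluable"]:
    """Flag an early on-treatment ctDNA spike.

    A spike is any observation within ``spike_window_weeks`` of baseline
    exceeding the baseline level by more than ``threshold`` (fractional).
    Baseline-negative patients, and patients with no sample inside the
    window, are unevaluable.
    """
    base = series.baseline
    if base.status != "positive" or not base.copies_per_ml:
        return "unevaluable"
    in_window = [
        o
        for o in series.observations[1:]
        if o.week <= spike_window_weeks and o.copies_per_ml is not None
    ]
    if not in_window:
        return "unevaluable"
    for o in in_window:
        if (o.copies_per_ml - base.copies_per_ml) / base.copies_per_ml > threshold:
            return "spike"
    return "no_spike"


def interpolate_at_week(
    series: LongitudinalSeries, target_week: float, max_gap_weeks: float = 1.0
) -> Observation | None:
    """Nearest observation within ``max_gap_weeks`` of the target week.

    Distance ties break toward the earlier observation; ``None`` when no
    observation falls inside the gap.
    """
    best: Observation | None = None
    best_dist = None
    for o in series.observations:
        dist = abs(o.week - target_week)
        if dist > max_gap_weeks:
            continue
        if best is None or dist < best_dist:  # strict: first (earlier) wins ties
            best, best_dist = o, dist
    return best


def separation_by_timepoint(
    cohort: Sequence[LongitudinalSeries],
    candidate_weeks: Sequence[float] = DEFAULT_CANDIDATE_WEEKS,
    threshold: float = 0.30,
    max_gap_weeks: float = 1.0,
) -> tuple[pd.DataFrame, float | None]:
    """Score candidate follow-up weeks by responder/non-responder separation.

    For each candidate week, every patient with an evaluable baseline and
    an observation within the alignment gap is classified against baseline
    with the change rule; the table reports the fraction of responders
    called decreasing and of non-responders called non-decreasing. The
    recommended week maximizes the sum of the two fractions (ties to the
    earlier week); ``None`` when either response group is empty throughout.
    """
    rows = []
    for week in candidate_weeks:
        resp_dec = resp_n = nonresp_nodec = nonresp_n = 0
        for series in cohort:
            if series.response_label is None:
                continue
            obs = interpolate_at_week(series, week, max_gap_weeks)
            if obs is None or obs.status == "invalid":
                continue
            base = series.baseline
            if base.status == "invalid":
                continue
            m0 = TimepointMeasurement(
                series.patient_id, "t0", base.status, base.copies_per_ml
            )
            m1 = TimepointMeasurement(
                series.patient_id, f"w{week:g}", obs.status, obs.copies_per_ml
            )
            call = classify_dynamics(m0, m1, threshold)
            if series.response_label == "responder":
                resp_n += 1
                resp_dec += call.category == "decreasing"
            else:
                nonresp_n += 1
                nonresp_nodec += call.category != "decreasing"
        rows.append(
            {
                "week": week,
                "responders_n": resp_n,
                "responder_decrease_frac": resp_dec / resp_n if resp_n else None,
                "nonresponders_n": nonresp_n,
                "nonresponder_nondecrease_frac": (
                    nonresp_nodec / nonresp_n if nonresp_n else None
                ),
            }
        )
    table = pd.DataFrame(rows)

    scored = table.dropna(
        subset=["responder_decrease_frac", "nonresponder_nondecrease_frac"]
    )
    if scored.empty:
        return table, None
    score = (
        scored["responder_decrease_frac"]
        + scored["nonresponder_nondecrease_frac"]
    )
    best_idx = score.idxmax()  # idxmax keeps the first (earliest) maximum
    return table, float(scored.loc[best_idx, "week"])
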