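"""Two-timepoint ctDNA dynamics classification.

A patient's mutant-copy level at baseline (t0) and the 4-6 week follow-up
(t1) is reduced to one of four categories at a relative-change threshold
(default 30%, matching the assay's technical coefficient of variation):

* ``decreasing`` — more than a 30% drop in copies/mL, or loss of a
  previously positive signal (change -100%);
* ``increasing`` — more than a 30% rise, or new detection at t1 in a
  baseline-negative patient;
* ``stable``     — absolute change within the threshold (the boundary
  value itself is stable);
* ``negative``   — the tumor mutation undetectable in plasma at both
  timepoints.

Samples with ``invalid`` status (insufficient informative droplets) exclude
the patient; they carry no information and must not be read as negative.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import pandas as pd

__all__ = [
    "TimepointMeasurement",
    "DynamicsCall",
    "relative_change",
    "classify_dynamics",
    "group_binary",
    "threshold_sweep",
    "classify_table",
]

DEFAULT_THRESHOLD = 0.30

Category = Literal["decreasing", "stable", "increasing", "negative"]


@dataclass(frozen=True)
class TimepointMeasurement:
    """One quantified sample for a patient at t0 or t1."""

    patient_id: str
    timepoint: str
    status: str  # positive | negative | invalid
    copies_per_ml: float | None = None

    def __post_init__(self) -> None:
        if self.status not in ("positive", "negative", "invalid"):
            raise ValueError(f"unknown status {self.status!r}")
        if self.status == "positive":
            if self.copies_per_ml is None or self.copies_per_ml < 0:
                raise ValueError("positive measurement needs copies_per_ml >= 0")


@dataclass(frozen=True)
class DynamicsCall:
    patient_id: str
    category: Category
    relative_change: float | None
    threshold_used: float


def relative_change(c0: float, c1: float) -> float:
    """Signed fractional change ``(c1 - c0) / c0`` from a positive baseline."""
    if c0 <= 0:
        raise ValueError("baseline copies/mL must be positive")
    if c1 < 0:
        raise ValueError("follow-up copies/mL must be non-negative")
    return (c1 - c0) / c0


def classify_dynamics(
    m0: TimepointMeasurement,
    m1: TimepointMeasurement,
    threshold: float = DEFAULT_THRESHOLD,
) -> DynamicsCall:
    """Classify one patient's t0->t1 ctDNA change.

    Baseline-negative patients who become positive at t1 are called
    ``increasing`` (new detection); positive-to-negative is a ``decreasing``
    call with change -1.0 (a valid negative bounds t1 below the limit of
    detection). A change whose magnitude equals the threshold exactly is
    ``stable``; decrease/increase require strict exceedance.
    """
    if m0.patient_id != m1.patient_id:
        raise ValueError("measurements belong to different patients")
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    if m0.status == "invalid" or m1.status == "invalid":
        raise ValueError(
            f"patient {m0.patient_id}: invalid measurement cannot be classified"
        )

    pid = m0.patient_id
    if m0.status == "negative" and m1.status == "negative":
        return DynamicsCall(pid, "negative", None, threshold)
    if m0.status == "negative":  # new detection at t1
        return DynamicsCall(pid, "increasing", None, threshold)
    if m1.status == "negative":
        return DynamicsCall(pid, "decreasing", -1.0, threshold)

    r = relative_change(m0.copies_per_ml, m1.copies_per_ml)
    if r < -threshold:
        category: Category = "decreasing"
    elif r > threshold:
        category = "increasing"
    else:
        category = "stable"
    return DynamicsCall(pid, category, r, threshold)


def group_binary(
    calls: Iterable[DynamicsCall],
    convention: Literal["exclude_negative", "include_negative"] = "exclude_negative",
) -> tuple[dict[str, str], set[str]]:
    """Collapse four-level calls to decrease / no_decrease.

    Under ``exclude_negative`` (the head-to-head survival comparison),
    ctDNA-negative patients are set aside; under ``include_negative`` (the
    PD-L1-stratified comparison) they join the no-decrease arm.

    Returns ``(labels, excluded)`` where ``labels`` maps patient_id to
    ``"decrease"`` or ``"no_decrease"``.
    """
    if convention not in ("exclude_negative", "include_negative"):
        raise ValueError(f"unknown grouping convention {convention!r}")
    labels: dict[str, str] = {}
    excluded: set[str] = set()
    for call in calls:
        if call.category == "decreasing":
            labels[call.patient_id] = "decrease"
        elif call.category == "negative" and convention == "exclude_negative":
            excluded.add(call.patient_id)
        else:
            labels[call.patient_id] = "no_decrease"
    return labels, excluded


def threshold_sweep(
    measurements: Sequence[tuple[TimepointMeasurement, TimepointMeasurement]],
    thresholds: Sequence[float] = (0.30, 0.40, 0.50),
) -> dict[float, list[DynamicsCall]]:
    """Re-classify the cohort at each threshold (e.g. 30/40/50%).

    A larger threshold can only move patients out of the decreasing (or
    increasing) set into stable, so the decreasing sets are nested.
    """
    for t in thresholds:
        if not 0 < t < 1:
            raise ValueError(f"threshold {t} outside (0, 1)")
    return {
        t: [classify_dynamics(m0, m1, threshold=t) for m0, m1 in measurements]
        for t in thresholds
    }


def classify_table(
    quant: pd.DataFrame,
    threshold: float = DEFAULT_THRESHOLD,
    t0_label: str = "t0",
    t1_label: str = "t1",
) -> pd.DataFrame:
    """Classify a quantification table (one row per patient x timepoint).

    Returns one row per patient with the category, relative change, and the
    binary grouping under both conventions; patients missing a timepoint or
    with an invalid sample appear with category ``excluded`` and a reason.
    """
    rows = []
    for pid, grp in quant.groupby("patient_id", sort=True):
        by_tp = {r.timepoint: r for r in grp.itertuples()}
        if t0_label not in by_tp or t1_label not in by_tp:
            rows.append(_excluded_row(pid, threshold, "missing timepoint"))
            continue
        r0, r1 = by_tp[t0_label], by_tp[t1_label]
        if r0.status == "invalid" or r1.status == "invalid":
            rows.append(_excluded_row(pid, threshold, "invalid measurement"))
            continue
        m0 = _measurement(r0)
        m1 = _measurement(r1)
        call = classify_dynamics(m0, m1, threshold)
        rows.append(
            {
                "patient_id": str(pid),
                "category": call.category,
                "relative_change": call.relative_change,
                "threshold": threshold,
                "exclusion_reason": None,
            }
        )
    table = pd.DataFrame(rows)

    kept = table[table["category"] != "excluded"]
    calls = [
        DynamicsCall(r.patient_id, r.category, r.relative_change, threshold)
        for r in kept.itertuples()
    ]
    for convention in ("exclude_negative", "include_negative"):
        labels, _ = group_binary(calls, convention)
        table[f"group_{convention}"] = table["patient_id"].map(labels)
    return table


def _measurement(row) -> TimepointMeasurement:
    return TimepointMeasurement(
        patient_id=str(row.patient_id),
        timepoint=str(row.timepoint),
        status=row.status,
        copies_per_ml=row.copies_per_ml if row.status == "positive" else None,
    )


def _excluded_row(pid, threshold: float, reason: str) -> dict:
    return {
        "patient_id": str(pid),
        "category": "excluded",
        "relative_change": None,
        "threshold": threshold,
        "exclusion_reason": reason,
    }
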