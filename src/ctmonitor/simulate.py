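"""Synthetic droplet-level and cohort-level ctDNA monitoring data.

The generator emulates the statistical structure the monitoring analysis
assumes, so every pipeline stage is testable end-to-end:

* **Droplet level** — each droplet of a well is independently positive with
  the Poisson occupancy probability ``1 - exp(-conc * V_d)`` (plus an
  optional false-positive rate), giving binomial counts from which the
  quantifier should recover the planted concentration.
* **Patient level** — lognormal baseline mutant copies/mL and five kinetic
  archetypes: complete and partial responders (optional early spike around
  week 1 — tumor DNA released by dying cells — then exponential decay, with
  complete responders clearing below the detection limit), stable disease
  (flat), progressive disease (exponential growth), and baseline
  ctDNA-negative patients. Every observation carries multiplicative
  lognormal technical noise at the assay's 30% coefficient of variation.
* **Cohort level** — archetype-dependent exponential PFS, OS built as PFS
  plus an exponential remainder, administrative censoring, and a PD-L1
  tumor proportion score drawn independently of the ctDNA dynamics.

All randomness flows through seeds derived from a single
``numpy.random.SeedSequence``; identical seeds give identical tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ddpcr import AssayConstants, WellDropletCount
from .timepoints import LongitudinalSeries, Observation

__all__ = [
    "AssaySimConfig",
    "CohortSimConfig",
    "simulate_droplet_counts",
    "simulate_patient_series",
    "simulate_cohort",
]

ARCHETYPES = ("CR", "PR", "SD", "PD", "ctDNA_negative")

#: Default sampling schedule in weeks: dense early (to capture the spike and
#: the 4-6 week evaluation window), then every 6 weeks.
DEFAULT_SAMPLING_WEEKS = (0.0, 1.0, 2.0, 4.0, 6.0, 12.0, 18.0, 24.0)


@dataclass(frozen=True)
class AssaySimConfig:
    """Forward model of a single ddPCR well."""

    true_mut_conc: float  # copies per µL reaction
    true_wt_conc: float
    n_droplets: int = 15_000
    droplet_volume: float = 8.5e-4  # µL
    false_positive_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_mut_conc < 0 or self.true_wt_conc < 0:
            raise ValueError("concentrations must be non-negative")
        if not 0 <= self.false_positive_rate <= 1e-3:
            raise ValueError("false_positive_rate must lie in [0, 0.001]")
        if self.n_droplets < 1:
            raise ValueError("n_droplets must be >= 1")


@dataclass(frozen=True)
class CohortSimConfig:
    """Cohort generator settings; defaults describe the study conditions.

    Archetype proportions put 31% of patients baseline ctDNA-negative and
    ~30% in the responder (CR/PR) arm; PD-L1 TPS frequencies follow the
    typical advanced-adenocarcinoma distribution (34% <1%, 17% 1-49%,
    35% >=50%, 14% unavailable). Group medians (weeks) place responders at
    ~43-week PFS / ~125-week OS against ~6 / ~29 for non-responders, with
    baseline-negative patients intermediate.
    """

    n_patients: int = 100
    archetype_mix: Mapping[str, float] = field(
        default_factory=lambda: {
            "CR": 0.05,
            "PR": 0.25,
            "SD": 0.14,
            "PD": 0.25,
            "ctDNA_negative": 0.31,
        }
    )
    baseline_log_mean: float = math.log(200.0)  # lognormal copies/mL plasma
    baseline_log_sd: float = 1.2
    wildtype_log_mean: float = math.log(2500.0)  # background ccfDNA copies/mL
    wildtype_log_sd: float = 0.4
    spike_probability: float = 0.70
    spike_amplitude: float = 2.0  # fold-change over baseline at the spike
    spike_week: float = 1.0
    decay_rate: Mapping[str, float] = field(
        default_factory=lambda: {"CR": 0.50, "PR": 0.65}
    )  # per-week multiplicative factor after the spike window
    growth_rate: float = 1.2  # per-week factor for progressive disease
    technical_cv: float = 0.30
    median_pfs_by_group: Mapping[str, float] = field(
        default_factory=lambda: {
            "CR": 60.0,
            "PR": 43.0,
            "SD": 8.0,
            "PD": 5.0,
            "ctDNA_negative": 20.0,
        }
    )
    median_os_by_group: Mapping[str, float] = field(
        default_factory=lambda: {
            "CR": 150.0,
            "PR": 125.0,
            "SD": 30.0,
            "PD": 25.0,
            "ctDNA_negative": 60.0,
        }
    )
    censor_week: float = 160.0
    tps_probs: Mapping[str, float] = field(
        default_factory=lambda: {
            "<1%": 0.34,
            "1-49%": 0.17,
            ">=50%": 0.35,
            "unavailable": 0.14,
        }
    )
    sampling_weeks: Sequence[float] = DEFAULT_SAMPLING_WEEKS
    n_droplets: int = 15_000
    lod_copies_per_ml: float = 10.0  # below this a sample reads negative
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.archetype_mix.values()) - 1.0) > 1e-9:
            raise ValueError("archetype_mix proportions must sum to 1")
        if abs(sum(self.tps_probs.values()) - 1.0) > 1e-9:
            raise ValueError("tps_probs must sum to 1")
        if self.technical_cv < 0:
            raise ValueError("technical_cv must be non-negative")
        for g, m in self.median_pfs_by_group.items():
            if m <= 0:
                raise ValueError(f"median PFS for {g} must be positive")
            os_m = self.median_os_by_group.get(g)
            if os_m is None or os_m <= 0:
                raise ValueError(f"median OS for {g} must be positive")
            if os_m < m:
                raise ValueError(
                    f"group {g}: median OS ({os_m}) below median PFS ({m})"
                )
        if self.censor_week < 0:
            raise ValueError("censor_week must be non-negative")


def simulate_droplet_counts(
    config: AssaySimConfig,
    patient_id: str = "sim",
    timepoint: str = "t0",
) -> WellDropletCount:
    """Draw one well's droplet counts from the Poisson occupancy model."""
    rng = np.random.default_rng(config.seed)
    counts = []
    for conc in (config.true_mut_conc, config.true_wt_conc):
        p_occ = -math.expm1(-conc * config.droplet_volume)
        p = p_occ + (1.0 - p_occ) * config.false_positive_rate
        counts.append(int(rng.binomial(config.n_droplets, p)))
    return WellDropletCount(
        patient_id=patient_id,
        timepoint=timepoint,
        mutant_positive=counts[0],
        wildtype_positive=counts[1],
        total_droplets=config.n_droplets,
    )


def _noise_factor(rng: np.random.Generator, cv: float) -> float:
    """Multiplicative lognormal noise with unit mean and the given CV."""
    if cv == 0:
        return 1.0
    sigma2 = math.log1p(cv**2)
    return float(rng.lognormal(-sigma2 / 2.0, math.sqrt(sigma2)))


def _true_level(
    config: CohortSimConfig,
    archetype: str,
    baseline: float,
    spiked: bool,
    week: float,
) -> float:
    """Noise-free mutant copies/mL at a given week for one archetype."""
    if archetype == "ctDNA_negative":
        return 0.0
    if archetype == "SD":
        return baseline
    if archetype == "PD":
        return baseline * config.growth_rate**week
    # responders: optional spike, then exponential decay
    decay = config.decay_rate[archetype]
    peak = config.spike_amplitude if spiked else 1.0
    if week <= 0:
        return baseline
    if spiked and week <= config.spike_week:
        # linear rise to the spike peak on the log scale
        return baseline * peak ** (week / config.spike_week)
    return baseline * peak * decay ** (week - config.spike_week)


def simulate_patient_series(
    config: CohortSimConfig,
    archetype: str,
    patient_seed: int,
    patient_id: str = "sim",
) -> tuple[LongitudinalSeries, dict]:
    """Simulate one patient's week-indexed ctDNA trajectory.

    Returns the series plus a truth record (baseline, spike flag, rates)
    for parameter-recovery tests.
    """
    if archetype not in ARCHETYPES:
        raise ValueError(f"unknown archetype {archetype!r}")
    rng = np.random.default_rng(patient_seed)
    baseline = float(rng.lognormal(config.baseline_log_mean, config.baseline_log_sd))
    spiked = bool(
        archetype in ("CR", "PR") and rng.random() < config.spike_probability
    )

    observations = []
    for week in config.sampling_weeks:
        level = _true_level(config, archetype, baseline, spiked, week)
        observed = level * _noise_factor(rng, config.technical_cv)
        if observed < config.lod_copies_per_ml:
            observations.append(Observation(week, None, "negative"))
        else:
            observations.append(Observation(week, observed, "positive"))
    series = LongitudinalSeries(
        patient_id=patient_id,
        observations=tuple(observations),
        response_label=(
            "responder" if archetype in ("CR", "PR") else "non-responder"
        ),
    )
    truth = {
        "patient_id": patient_id,
        "archetype": archetype,
        "baseline_copies_per_ml": baseline,
        "spiked": spiked,
    }
    return series, truth


def _draw_survival(
    config: CohortSimConfig, archetype: str, rng: np.random.Generator
) -> tuple[float, int, float, int]:
    """Exponential PFS and OS (PFS plus exponential remainder), censored."""
    m_pfs = config.median_pfs_by_group[archetype]
    m_os = config.median_os_by_group[archetype]
    pfs = float(rng.exponential(m_pfs / math.log(2)))
    remainder_median = m_os - m_pfs
    if remainder_median > 0:
        os_time = pfs + float(rng.exponential(remainder_median / math.log(2)))
    else:
        os_time = pfs
    c = config.censor_week
    pfs_event, os_event = 1, 1
    if pfs > c:
        pfs, pfs_event = c, 0
    if os_time > c:
        os_time, os_event = c, 0
    return pfs, pfs_event, os_time, os_event


def _recist_label(archetype: str, rng: np.random.Generator) -> str:
    if archetype != "ctDNA_negative":
        return archetype
    # baseline-negative patients span the clinical spectrum, skewed to PD
    return str(rng.choice(["PD", "SD", "PR"], p=[0.70, 0.15, 0.15]))


def simulate_cohort(
    config: CohortSimConfig,
    constants: AssayConstants | None = None,
) -> dict:
    """Generate a linked synthetic cohort: droplet, series and clinical tables.

    Returns a dict with

    * ``droplets`` — per-well counts at t0 and t1 (the follow-up sample,
      drawn at week 4 or 6), ready for the quantifier;
    * ``series`` — long-format weekly trajectories with response labels;
    * ``clinical`` — PFS/OS with event flags, RECIST label, TPS stratum;
    * ``truth`` — the planted per-patient parameters.
    """
    constants = constants or AssayConstants()
    ss = np.random.SeedSequence(config.seed)
    cohort_rng = np.random.default_rng(ss.spawn(1)[0])
    patient_seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(config.n_patients + 1)[1:]]

    names = list(config.archetype_mix)
    probs = [config.archetype_mix[a] for a in names]
    archetypes = cohort_rng.choice(names, size=config.n_patients, p=probs)
    tps_names = list(config.tps_probs)
    tps = cohort_rng.choice(
        tps_names, size=config.n_patients, p=[config.tps_probs[t] for t in tps_names]
    )

    # back-calculation factor: copies/mL plasma -> copies/µL reaction
    to_rxn = (
        constants.plasma_volume
        * constants.eluate_in_reaction
        / (constants.reaction_volume * constants.eluate_volume)
    )

    droplet_rows, series_rows, clinical_rows, truth_rows = [], [], [], []
    for i in range(config.n_patients):
        pid = f"P{i:04d}"
        archetype = str(archetypes[i])
        series, truth = simulate_patient_series(
            config, archetype, patient_seeds[i], patient_id=pid
        )
        rng = np.random.default_rng(patient_seeds[i] + 1)

        t1_week = float(rng.choice([4.0, 6.0]))
        wt_cpml = float(
            rng.lognormal(config.wildtype_log_mean, config.wildtype_log_sd)
        )
        for tp, week in (("t0", 0.0), ("t1", t1_week)):
            obs = next(o for o in series.observations if o.week == week)
            mut_cpml = obs.copies_per_ml or 0.0
            well = simulate_droplet_counts(
                AssaySimConfig(
                    true_mut_conc=mut_cpml * to_rxn,
                    true_wt_conc=wt_cpml * to_rxn,
                    n_droplets=config.n_droplets,
                    droplet_volume=constants.droplet_volume,
                    seed=int(rng.integers(2**31)),
                ),
                patient_id=pid,
                timepoint=tp,
            )
            droplet_rows.append(
                {
                    "patient_id": pid,
                    "timepoint": tp,
                    "well_id": f"{pid}-{tp}-w1",
                    "mutant_positive": well.mutant_positive,
                    "wildtype_positive": well.wildtype_positive,
                    "total_droplets": well.total_droplets,
                }
            )

        for o in series.observations:
            series_rows.append(
                {
                    "patient_id": pid,
                    "week": o.week,
                    "copies_per_ml": o.copies_per_ml,
                    "status": o.status,
                    "response_label": series.response_label,
                }
            )

        pfs, pfs_event, os_time, os_event = _draw_survival(config, archetype, rng)
        clinical_rows.append(
            {
                "patient_id": pid,
                "pfs_weeks": pfs,
                "pfs_event": pfs_event,
                "os_weeks": os_time,
                "os_event": os_event,
                "recist_response": _recist_label(archetype, rng),
                "tps_stratum": str(tps[i]),
            }
        )
        truth.update(t1_week=t1_week, wildtype_copies_per_ml=wt_cpml, tps=str(tps[i]))
        truth_rows.append(truth)

    return {
        "droplets": pd.DataFrame(droplet_rows),
        "series": pd.DataFrame(series_rows),
        "clinical": pd.DataFrame(clinical_rows),
        "truth": pd.DataFrame(truth_rows),
        "config": config,
    }
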