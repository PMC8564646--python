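"""Droplet digital PCR quantification of mutant ctDNA.

Converts raw droplet counts (mutant- and wildtype-channel positives out of
the accepted droplets of a well) into Poisson-corrected template
concentrations, absolute mutant copies per mL of plasma, and variant allele
frequency, and applies the sample positivity rules used for tumor-informed
ctDNA monitoring:

* a sample is **positive** when at least 3 mutant-positive droplets are seen;
* it is **negative** only when fewer than 3 mutant droplets are seen *and*
  at least 330 informative (mutant + wildtype positive) droplets were
  counted, which bounds the analytical sensitivity below 1%;
* anything else is **invalid** — too few informative droplets to claim a
  negative — and must be treated as missing downstream, never as negative.

The Poisson correction accounts for droplets holding more than one template:
with ``k`` of ``N`` droplets positive, the mean occupancy is
``lambda = -ln(1 - k/N)`` copies per droplet, and concentration is
``lambda / V_d`` for droplet volume ``V_d``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

__all__ = [
    "WellDropletCount",
    "AssayConstants",
    "QuantResult",
    "SaturationError",
    "poisson_concentration",
    "merge_wells",
    "copies_per_ml_plasma",
    "variant_allele_frequency",
    "call_sample_status",
    "limit_of_detection",
    "quantify_sample",
    "quantify_table",
]

#: Minimum mutant-positive droplets to call a sample positive.
MIN_MUTANT_DROPLETS = 3
#: Minimum informative (mutant + wildtype positive) droplets to call negative.
MIN_INFORMATIVE_DROPLETS = 330

# Nominal accepted-droplet range of the QX200 generator; counts outside it
# are suspicious but not fatal.
_PLAUSIBLE_DROPLETS = (10_000, 20_000)


class SaturationError(ValueError):
    """All droplets positive: the template concentration is unbounded."""


@dataclass(frozen=True)
class WellDropletCount:
    """Raw droplet counts for one ddPCR well (mutant + wildtype channels)."""

    patient_id: str
    timepoint: str
    mutant_positive: int
    wildtype_positive: int
    total_droplets: int

    def __post_init__(self) -> None:
        if self.total_droplets < 1:
            raise ValueError("total_droplets must be >= 1")
        if not (0 <= self.mutant_positive <= self.total_droplets):
            raise ValueError("mutant_positive must lie in [0, total_droplets]")
        if not (0 <= self.wildtype_positive <= self.total_droplets):
            raise ValueError("wildtype_positive must lie in [0, total_droplets]")

    @property
    def informative_droplets(self) -> int:
        return self.mutant_positive + self.wildtype_positive

    def validate_droplet_range(self) -> None:
        """Warn when the accepted-droplet count is outside the plausible range."""
        lo, hi = _PLAUSIBLE_DROPLETS
        if not lo <= self.total_droplets <= hi:
            warnings.warn(
                f"well for {self.patient_id}/{self.timepoint}: "
                f"{self.total_droplets} accepted droplets outside the "
                f"expected {lo}-{hi} range",
                stacklevel=2,
            )


@dataclass(frozen=True)
class AssayConstants:
    """Volumes linking the ddPCR reaction back to the plasma draw.

    ``droplet_volume`` is the QX200 nominal 0.85 nL. ``eluate_in_reaction``
    is the share of the 52 µL ccfDNA eluate pipetted into the 20 µL
    reaction; ``plasma_volume`` the mL of plasma extracted.
    """

    droplet_volume: float = 8.5e-4  # µL
    reaction_volume: float = 20.0  # µL
    eluate_volume: float = 52.0  # µL
    eluate_in_reaction: float = 13.0  # µL
    plasma_volume: float = 2.0  # mL

    def __post_init__(self) -> None:
        for name in (
            "droplet_volume",
            "reaction_volume",
            "eluate_volume",
            "eluate_in_reaction",
            "plasma_volume",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.eluate_in_reaction > self.eluate_volume:
            raise ValueError("eluate_in_reaction cannot exceed eluate_volume")
        if self.reaction_volume < self.eluate_in_reaction:
            raise ValueError("reaction_volume must hold the eluate aliquot")


@dataclass(frozen=True)
class QuantResult:
    """Quantification outcome for one patient sample (merged wells)."""

    patient_id: str
    timepoint: str
    lambda_mut: float
    conc_mut: float  # copies per µL reaction
    conc_wt: float  # copies per µL reaction
    copies_per_ml: float  # mutant copies per mL plasma
    vaf: float | None  # mutant fraction; None when no template seen
    informative_droplets: int
    status: str  # positive | negative | invalid
    mutant_positive: int = 0
    total_droplets: int = 0


def poisson_concentration(k: int, n: int, droplet_volume: float) -> float:
    """Poisson-corrected template concentration in copies/µL.

    ``-ln(1 - k/n) / droplet_volume`` for ``k`` positive of ``n`` droplets.

    Raises
    ------
    SaturationError
        If every droplet is positive (concentration unbounded).
    ValueError
        If ``k`` or ``n`` are out of range or ``droplet_volume <= 0``.
    """
    if n <= 0:
        raise ValueError("total droplet count must be positive")
    if k < 0 or k > n:
        raise ValueError("positive-droplet count must lie in [0, n]")
    if droplet_volume <= 0:
        raise ValueError("droplet_volume must be positive")
    if k == n:
        raise SaturationError(
            f"all {n} droplets positive: concentration is unbounded"
        )
    return -math.log1p(-k / n) / droplet_volume


def merge_wells(wells: Sequence[WellDropletCount]) -> WellDropletCount:
    """Pool replicate wells of one sample by summing droplet counts.

    Summing before the Poisson correction is the standard merged-well
    treatment and has lower variance than averaging per-well concentrations.
    """
    if not wells:
        raise ValueError("cannot merge an empty list of wells")
    first = wells[0]
    for w in wells[1:]:
        if w.patient_id != first.patient_id or w.timepoint != first.timepoint:
            raise ValueError(
                "merge_wells requires a single patient_id and timepoint; got "
                f"({first.patient_id}, {first.timepoint}) and "
                f"({w.patient_id}, {w.timepoint})"
            )
    return WellDropletCount(
        patient_id=first.patient_id,
        timepoint=first.timepoint,
        mutant_positive=sum(w.mutant_positive for w in wells),
        wildtype_positive=sum(w.wildtype_positive for w in wells),
        total_droplets=sum(w.total_droplets for w in wells),
    )


def copies_per_ml_plasma(conc_rxn: float, constants: AssayConstants) -> float:
    """Back-calculate reaction concentration to mutant copies per mL plasma.

    ``conc_rxn * V_rxn * (V_elu / V_in) / V_pl``: total copies in the
    reaction, scaled up to the whole eluate, divided by the plasma volume.
    """
    if conc_rxn < 0:
        raise ValueError("conc_rxn must be non-negative")
    c = constants
    return (
        conc_rxn
        * c.reaction_volume
        * (c.eluate_volume / c.eluate_in_reaction)
        / c.plasma_volume
    )


def variant_allele_frequency(conc_mut: float, conc_wt: float) -> float | None:
    """Mutant fraction ``conc_mut / (conc_mut + conc_wt)``.

    Returns ``None`` when neither channel detected template (undefined).
    """
    if conc_mut < 0 or conc_wt < 0:
        raise ValueError("concentrations must be non-negative")
    total = conc_mut + conc_wt
    if total == 0:
        return None
    return conc_mut / total


def call_sample_status(mutant_positive: int, informative_droplets: int) -> str:
    """Apply the positivity/negativity rules to merged-sample counts.

    positive: >= 3 mutant droplets; negative: < 3 mutant droplets with
    >= 330 informative droplets; invalid otherwise.
    """
    if mutant_positive < 0 or informative_droplets < 0:
        raise ValueError("counts must be non-negative")
    if mutant_positive > informative_droplets:
        raise ValueError("mutant_positive cannot exceed informative_droplets")
    if mutant_positive >= MIN_MUTANT_DROPLETS:
        return "positive"
    if informative_droplets >= MIN_INFORMATIVE_DROPLETS:
        return "negative"
    return "invalid"


def limit_of_detection(
    min_positive_droplets: int = MIN_MUTANT_DROPLETS,
    informative_droplets: int = MIN_INFORMATIVE_DROPLETS,
) -> float:
    """Smallest callable mutant fraction given the droplet-count thresholds.

    The Poisson-corrected occupancy ``-ln(1 - k/n)`` of the informative
    pool when exactly ``k = min_positive_droplets`` of ``n`` informative
    droplets are mutant-positive. At the default 3/330 this is ~0.0091,
    i.e. an analytical sensitivity below 1%. Decreases monotonically as the
    informative count grows.
    """
    if min_positive_droplets <= 0 or informative_droplets <= 0:
        raise ValueError("droplet counts must be positive")
    if min_positive_droplets > informative_droplets:
        raise ValueError("min_positive_droplets cannot exceed informative count")
    if min_positive_droplets == informative_droplets:
        raise SaturationError("every informative droplet mutant: fraction unbounded")
    return -math.log1p(-min_positive_droplets / informative_droplets)


def quantify_sample(
    wells: Sequence[WellDropletCount],
    constants: AssayConstants | None = None,
    validate: bool = False,
) -> QuantResult:
    """Quantify one sample: merge wells, Poisson-correct both channels,
    back-calculate copies/mL plasma, and call the sample status."""
    constants = constants or AssayConstants()
    merged = merge_wells(wells)
    if validate:
        for w in wells:
            w.validate_droplet_range()

    lam_mut = -math.log1p(-merged.mutant_positive / merged.total_droplets)
    conc_mut = poisson_concentration(
        merged.mutant_positive, merged.total_droplets, constants.droplet_volume
    )
    conc_wt = poisson_concentration(
        merged.wildtype_positive, merged.total_droplets, constants.droplet_volume
    )
    return QuantResult(
        patient_id=merged.patient_id,
        timepoint=merged.timepoint,
        lambda_mut=lam_mut,
        conc_mut=conc_mut,
        conc_wt=conc_wt,
        copies_per_ml=copies_per_ml_plasma(conc_mut, constants),
        vaf=variant_allele_frequency(conc_mut, conc_wt),
        informative_droplets=merged.informative_droplets,
        status=call_sample_status(
            merged.mutant_positive, merged.informative_droplets
        ),
        mutant_positive=merged.mutant_positive,
        total_droplets=merged.total_droplets,
    )


def quantify_table(
    droplets: pd.DataFrame,
    constants: AssayConstants | None = None,
    validate: bool = False,
) -> pd.DataFrame:
    """Quantify a droplet-count table: one output row per patient x timepoint.

    Expects columns ``patient_id, timepoint, mutant_positive,
    wildtype_positive, total_droplets`` (a ``well_id`` column is tolerated;
    replicate wells are pooled).
    """
    required = {
        "patient_id",
        "timepoint",
        "mutant_positive",
        "wildtype_positive",
        "total_droplets",
    }
    missing = required - set(droplets.columns)
    if missing:
        raise ValueError(f"droplet table missing columns: {sorted(missing)}")

    rows = []
    for (pid, tp), grp in droplets.groupby(["patient_id", "timepoint"], sort=True):
        wells = [
            WellDropletCount(
                patient_id=str(pid),
                timepoint=str(tp),
                mutant_positive=int(r.mutant_positive),
                wildtype_positive=int(r.wildtype_positive),
                total_droplets=int(r.total_droplets),
            )
            for r in grp.itertuples()
        ]
        q = quantify_sample(wells, constants, validate=validate)
        rows.append(
            {
                "patient_id": q.patient_id,
                "timepoint": q.timepoint,
                "mutant_positive": q.mutant_positive,
                "informative_droplets": q.informative_droplets,
                "conc_mut": q.conc_mut,
                "conc_wt": q.conc_wt,
                "copies_per_ml": q.copies_per_ml,
                "vaf": q.vaf,
                "status": q.status,
            }
        )
    return pd.DataFrame(rows)
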