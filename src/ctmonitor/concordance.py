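"""Cross-platform agreement for paired ctDNA quantifications.

Two read-outs of the same plasma samples (e.g. a droplet digital PCR assay
and an automated qPCR cartridge assay) are compared on two levels: the
squared Pearson correlation of mutant copies/mL, optionally after dropping
very-high-level samples that dominate the fit, and Cohen's kappa on the
categorical dynamics calls derived from each platform.
"""

from __future__ import annotations

from collections import Counter
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = ["pearson_r2", "cohens_kappa", "concordance_summary"]


def pearson_r2(
    values_a: Sequence[float],
    values_b: Sequence[float],
    exclude_above: float | None = None,
) -> tuple[float, int, list[int]]:
    """Squared Pearson correlation of paired quantifications.

    ``exclude_above`` drops pairs where either platform exceeds the given
    copies/mL cutoff before recomputing (the with/without-high-level-cases
    view). Returns ``(r2, n_used, excluded_indices)``.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired value vectors must have equal length")
    keep = np.ones(a.size, dtype=bool)
    if exclude_above is not None:
        keep = (a <= exclude_above) & (b <= exclude_above)
    excluded = [int(i) for i in np.nonzero(~keep)[0]]
    a, b = a[keep], b[keep]
    if a.size < 3:
        raise ValueError("need at least 3 pairs after exclusion")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("zero variance on one platform: r2 undefined")
    r, _ = stats.pearsonr(a, b)
    return float(r**2), int(a.size), excluded


def cohens_kappa(calls_a: Sequence, calls_b: Sequence) -> float:
    """Chance-corrected categorical agreement between two raters.

    ``kappa = (p_o - p_e) / (1 - p_e)`` with expected agreement ``p_e``
    from the product of the raters' marginal label frequencies; any number
    of categories. When both raters are constant and identical
    (``p_e = 1``) agreement is perfect by convention and 1.0 is returned.
    """
    a = list(calls_a)
    b = list(calls_b)
    if len(a) != len(b):
        raise ValueError("call vectors must have equal length")
    if len(a) < 2:
        raise ValueError("need at least 2 paired calls")
    n = len(a)
    p_o = sum(x == y for x, y in zip(a, b)) / n
    freq_a = Counter(a)
    freq_b = Counter(b)
    p_e = sum(freq_a[l] * freq_b.get(l, 0) for l in freq_a) / n**2
    if p_e == 1.0:
        return 1.0  # both raters constant and equal
    return (p_o - p_e) / (1.0 - p_e)


def concordance_summary(
    values_a: Sequence[float],
    values_b: Sequence[float],
    calls_a: Sequence | None = None,
    calls_b: Sequence | None = None,
    high_level_cutoff: float | None = None,
) -> dict:
    """Joint agreement report: r2 (all pairs and below-cutoff pairs) and,
    when categorical calls are supplied, Cohen's kappa."""
    r2_all, n_all, _ = pearson_r2(values_a, values_b)
    out = {"r2_all": r2_all, "n_pairs": n_all, "excluded_ids": []}
    if high_level_cutoff is not None:
        r2_f, n_f, excl = pearson_r2(
            values_a, values_b, exclude_above=high_level_cutoff
        )
        out.update(r2_filtered=r2_f, n_filtered=n_f, excluded_ids=excl)
    if calls_a is not None and calls_b is not None:
        out["kappa"] = cohens_kappa(calls_a, calls_b)
        out["n_calls"] = len(list(calls_a))
    return out
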