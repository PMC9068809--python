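"""Lineage-age arithmetic from substitution rates.

A lineage's age follows from its mean within-lineage pairwise substitution
rate (substitutions per site), a per-generation mutation rate, and the
number of generations per year:

    age_years = rate / (mu * gens_per_year * branch_divisor)

``branch_divisor`` defaults to 1, treating the pairwise rate as if it
accrued along a single branch — the convention the printed worked examples
follow.  Since pairwise divergence actually accrues along both branches
from the founder, the population-genetics-standard choice is 2 (which
halves every age); it is available and documented, not default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .counting import PairwiseCounts

#: nuclear per-site per-generation base-substitution rate (mutation-
#: accumulation estimate for Daphnia pulex)
MU_NUCLEAR = 7.17e-9
#: mitochondrial per-site per-generation rate for asexual Daphnia pulex
MU_MTDNA = 4.3e-8
#: growing-season generations per calendar year
GENS_PER_YEAR = 5.0


@dataclass
class AgeModel:
    """Clock parameters for converting substitution rates to ages."""

    mu: float = MU_NUCLEAR
    gens_per_year: float = GENS_PER_YEAR
    branch_divisor: float = 1.0

    def __post_init__(self) -> None:
        if self.mu <= 0:
            raise ValueError("mu must be positive")
        if self.gens_per_year <= 0:
            raise ValueError("gens_per_year must be positive")
        if self.branch_divisor not in (1, 2, 1.0, 2.0):
            raise ValueError("branch_divisor must be 1 or 2")


@dataclass
class AgeEstimate:
    """A lineage age, raw and rounded to the nearest year."""

    years_raw: float
    years: int


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def lineage_age_years(pairwise_rate: float, model: AgeModel) -> AgeEstimate:
    """Age of a lineage from its mean pairwise substitution rate.

    ``pairwise_rate`` is the mean within-lineage pairwise substitution count
    per site.  Rounding is to the nearest year, half away from zero; the
    unrounded value is always retained.
    """
    if pairwise_rate < 0:
        raise ValueError("pairwise_rate must be non-negative")
    raw = pairwise_rate / (model.mu * model.gens_per_year * model.branch_divisor)
    return AgeEstimate(years_raw=raw, years=_round_half_away(raw))


def mean_pairwise_rate(
    pairs: Sequence[PairwiseCounts], sites: int | None = None
) -> tuple[float, float]:
    """Mean and SD of per-pair substitution rates within a lineage.

    Each pair's rate is its total substitution count (dn-C + dS + dN)
    divided by ``sites`` (or the pair's own ``sites_compared`` when
    ``sites`` is None).  SD is the sample standard deviation (0 for a
    single pair).
    """
    if len(pairs) == 0:
        raise ValueError("empty pairwise matrix")
    rates = []
    for p in pairs:
        denom = sites if sites is not None else p.sites_compared
        if denom <= 0:
            raise ValueError("sites compared must be positive")
        rates.append(p.total / denom)
    rates = np.asarray(rates)
    sd = float(np.std(rates, ddof=1)) if rates.size > 1 else 0.0
    return float(rates.mean()), sd
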