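"""Cohort-level derived statistics.

Three small computations used when reporting phage-resistance dynamics:
the percent of resistant isolates in a cohort (with an exact Clopper–Pearson
95% interval — the underlying cohorts are small, typically n = 20, so the
point estimate alone would overstate precision), the spontaneous resistance
frequency per cell challenged (with a rule-of-three upper bound when no
resistant colony is observed), and the fold reduction in bacterial load
between control and treated groups.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from scipy.stats import beta

from .errors import InputError


@dataclass(frozen=True)
class CohortCount:
    """Resistant / total isolate counts at one time point."""

    label: str
    resistant: int
    total: int

    def __post_init__(self) -> None:
        if self.total <= 0:
            raise InputError("total isolate count must be positive")
        if not (0 <= self.resistant <= self.total):
            raise InputError("resistant count must lie in [0, total]")


@dataclass(frozen=True)
class PercentResistant:
    percent: float
    ci_low: float  # exact binomial 95% interval, percent scale
    ci_high: float


def _clopper_pearson(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    alpha = 1.0 - level
    lo = 0.0 if k == 0 else float(beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


def percent_resistant(c: CohortCount) -> PercentResistant:
    """100 × resistant/total with an exact binomial 95% interval."""
    lo, hi = _clopper_pearson(c.resistant, c.total)
    return PercentResistant(100.0 * c.resistant / c.total, 100.0 * lo, 100.0 * hi)


@dataclass(frozen=True)
class FrequencyObservation:
    """Resistant colonies observed per cells challenged."""

    colonies: int
    cfu: float

    def __post_init__(self) -> None:
        if self.colonies < 0:
            raise InputError("colony count must be non-negative")
        if self.cfu <= 0:
            raise InputError("CFU challenged must be positive")


@dataclass(frozen=True)
class ResistanceFrequency:
    frequency: float
    upper_bound: Optional[float] = None  # rule-of-three bound when frequency is 0


def resistance_frequency(obs: FrequencyObservation) -> ResistanceFrequency:
    """Resistant colonies per CFU; zero counts report the 3/n upper bound."""
    if obs.colonies == 0:
        return ResistanceFrequency(0.0, upper_bound=3.0 / obs.cfu)
    return ResistanceFrequency(obs.colonies / obs.cfu)


@dataclass(frozen=True)
class FoldChange:
    fold: float
    infinite: bool = False


def fold_reduction(control_load: float, treated_load: float) -> FoldChange:
    """control/treated; a zero treated load is reported as infinite."""
    if control_load < 0 or treated_load < 0:
        raise InputError("loads must be non-negative")
    if treated_load == 0:
        return FoldChange(math.inf, infinite=True)
    return FoldChange(control_load / treated_load)
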