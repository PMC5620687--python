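"""Apparent mortality and competing-risks marginal attack rates.

Apparent mortality is the raw proportion of hosts a factor killed in a sample.
When several mortality sources act on a cohort at the same time they compete
for the same individuals, so the apparent mortality of each factor understates
what that factor would kill acting alone.  The *marginal attack rate* corrects
for this under the standard contemporaneous-mortality (constant competing
hazards) model:

    m_i = 1 - (1 - d) ** (d_i / d)

where ``d_i`` is the factor's apparent mortality and ``d`` the total apparent
mortality of the cohort.  The correction is exact when each factor is a
constant hazard over the interval; then ``prod_i (1 - m_i)`` equals total
survival, and ``m_i >= d_i`` always (equality only when the factor caused
nothing or caused everything).
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

__all__ = [
    "LifeTableCohort",
    "apparent_mortality",
    "marginal_attack_rate",
    "marginal_rates_from_life_table",
    "load_life_table",
]


@dataclass(frozen=True)
class LifeTableCohort:
    """A cohort exposed to several contemporaneous mortality factors.

    ``survivors + sum(deaths_by_factor.values())`` must equal ``cohort_size``.
    """

    cohort_size: int
    deaths_by_factor: Mapping[str, int]
    survivors: int

    def __post_init__(self) -> None:
        if self.cohort_size <= 0:
            raise ValueError(f"cohort_size must be positive, got {self.cohort_size}")
        if self.survivors < 0:
            raise ValueError("survivors must be non-negative")
        if any(d < 0 for d in self.deaths_by_factor.values()):
            raise ValueError("deaths must be non-negative")
        total = self.survivors + sum(self.deaths_by_factor.values())
        if total != self.cohort_size:
            raise ValueError(
                f"survivors ({self.survivors}) + deaths "
                f"({sum(self.deaths_by_factor.values())}) != cohort_size ({self.cohort_size})"
            )

    @property
    def total_mortality(self) -> float:
        return 1.0 - self.survivors / self.cohort_size


def apparent_mortality(deaths: int, cohort_size: int) -> float:
    """Proportion of the cohort killed: ``deaths / cohort_size``."""
    if cohort_size <= 0:
        raise ValueError(f"cohort_size must be positive, got {cohort_size}")
    if deaths < 0 or deaths > cohort_size:
        raise ValueError(f"deaths ({deaths}) must lie in [0, cohort_size={cohort_size}]")
    return deaths / cohort_size


def marginal_attack_rate(d_factor: float, d_total: float) -> float:
    """Marginal (stand-alone) mortality of one factor among competing factors.

    Parameters
    ----------
    d_factor
        The factor's apparent mortality, in ``[0, d_total]``.
    d_total
        Total apparent mortality of the cohort, in ``[0, 1)`` (``1`` only in
        the degenerate single-factor case ``d_factor == d_total == 1``).
    """
    if not (0.0 <= d_factor <= 1.0) or not (0.0 <= d_total <= 1.0):
        raise ValueError("mortalities must lie in [0, 1]")
    if d_factor > d_total:
        raise ValueError(f"d_factor ({d_factor}) exceeds d_total ({d_total})")
    if d_factor == 0.0:
        return 0.0
    if d_total == 1.0:
        if d_factor == 1.0:
            # sole factor wiped out the cohort; marginal = apparent = 1
            return 1.0
        raise ValueError(
            "total mortality is 1 with a partial factor: correction undefined "
            "(no survivors to anchor the survival split); censor the cohort instead"
        )
    return 1.0 - (1.0 - d_total) ** (d_factor / d_total)


def marginal_rates_from_life_table(cohort: LifeTableCohort) -> dict[str, float]:
    """Per-factor marginal attack rates for a multi-factor cohort.

    Raises if no individual survived (the correction is undefined at total
    mortality 1; the caller must censor such cohorts).
    The returned rates satisfy ``prod(1 - m_i) == survivors / cohort_size``
    to floating-point accuracy.
    """
    if cohort.survivors == 0:
        raise ValueError("no survivors: marginal rates undefined at total mortality 1")
    # integer-sum form keeps d_i <= d_total exact in floating point
    d_total = sum(cohort.deaths_by_factor.values()) / cohort.cohort_size
    return {
        factor: marginal_attack_rate(deaths / cohort.cohort_size, d_total)
        for factor, deaths in cohort.deaths_by_factor.items()
    }


def load_life_table(path: str | Path) -> LifeTableCohort:
    """Read a life-table CSV: ``factor,deaths`` rows plus one ``cohort_size`` row.

    Example::

        factor,deaths
        cohort_size,100
        parasitoid_a,20
        parasitoid_b,30

    Survivors are inferred as ``cohort_size - sum(deaths)``.
    """
    path = Path(path)
    cohort_size: int | None = None
    deaths: dict[str, int] = {}
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [c.strip() for c in header[:2]] != ["factor", "deaths"]:
            raise ValueError(f"{path.name}: expected header 'factor,deaths'")
        for row in reader:
            if not row or not row[0].strip():
                continue
            name, value = row[0].strip(), int(row[1])
            if name == "cohort_size":
                cohort_size = value
            else:
                deaths[name] = value
    if cohort_size is None:
        raise ValueError(f"{path.name}: missing 'cohort_size' row")
    survivors = cohort_size - sum(deaths.values())
    if survivors < 0:
        raise ValueError(f"{path.name}: deaths exceed cohort_size")
    return LifeTableCohort(cohort_size=cohort_size, deaths_by_factor=deaths, survivors=survivors)
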