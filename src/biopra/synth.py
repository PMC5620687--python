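"""Synthetic parasitism surveys and life-table cohorts.

Every stage of the pipeline can be exercised without field data by generating
inputs with the statistical structure the analysis assumes:

* Stratified parasitism surveys — per elevation stratum, a true parasitism
  rate is drawn per site from a beta distribution (optionally zero-inflated
  to mimic non-detection at sites the agent never reached), and the observed
  rate is a binomial count over the hosts sampled at that site divided by the
  sample size.  This is the sampling model under which a beta fit to observed
  rates is sensible.
* Multi-factor cohort life tables — individuals are exposed simultaneously to
  all mortality factors as constant competing hazards over one interval, with
  each factor's hazard calibrated so its stand-alone (marginal) mortality
  equals the requested value.  Under this generative model the
  contemporaneous-mortality correction in :mod:`biopra.mortality` is exact,
  so generated cohorts round-trip to their input marginal rates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .datasets import STRATA, MortalityRecord, SurveyDataset
from .mortality import LifeTableCohort

__all__ = [
    "StratumSpec",
    "SurveyGeneratorConfig",
    "generate_parasitism_survey",
    "generate_cohort_life_table",
]


@dataclass(frozen=True)
class StratumSpec:
    """Beta parameters and zero-inflation for one elevation stratum."""

    name: str
    true_alpha: float
    true_beta: float
    zero_inflation: float = 0.0

    def __post_init__(self) -> None:
        if self.name not in STRATA:
            raise ValueError(f"stratum name {self.name!r} not in {sorted(STRATA)}")
        if self.true_alpha <= 0 or self.true_beta <= 0:
            raise ValueError("beta shape parameters must be positive")
        if not (0.0 <= self.zero_inflation <= 1.0):
            raise ValueError("zero_inflation must be a probability")


@dataclass(frozen=True)
class SurveyGeneratorConfig:
    """Configuration of a stratified parasitism survey."""

    strata: tuple[StratumSpec, ...]
    n_sites_per_stratum: int
    hosts_per_site: int
    seed: int = 0
    agent_id: str = "synthetic_agent"

    def __post_init__(self) -> None:
        if not self.strata:
            raise ValueError("at least one stratum is required")
        if self.n_sites_per_stratum <= 0:
            raise ValueError("n_sites_per_stratum must be positive")
        if self.hosts_per_site <= 0:
            raise ValueError("hosts_per_site must be positive")

    @classmethod
    def from_dict(cls, cfg: dict) -> "SurveyGeneratorConfig":
        strata = tuple(
            StratumSpec(
                name=s["name"],
                true_alpha=s["true_alpha"],
                true_beta=s["true_beta"],
                zero_inflation=s.get("zero_inflation", 0.0),
            )
            for s in cfg["strata"]
        )
        return cls(
            strata=strata,
            n_sites_per_stratum=cfg["n_sites_per_stratum"],
            hosts_per_site=cfg["hosts_per_site"],
            seed=cfg.get("seed", 0),
            agent_id=cfg.get("agent_id", "synthetic_agent"),
        )


def generate_parasitism_survey(config: SurveyGeneratorConfig) -> SurveyDataset:
    """Simulate a stratified apparent-mortality survey (deterministic per seed)."""
    rng = np.random.default_rng(config.seed)
    records: list[MortalityRecord] = []
    datum = 1
    for stratum in config.strata:
        for _ in range(config.n_sites_per_stratum):
            if rng.random() < stratum.zero_inflation:
                true_rate = 0.0
            else:
                true_rate = rng.beta(stratum.true_alpha, stratum.true_beta)
            observed = rng.binomial(config.hosts_per_site, true_rate) / config.hosts_per_site
            records.append(
                MortalityRecord(
                    agent_id=config.agent_id,
                    datum_index=datum,
                    rate=float(observed),
                    mortality_type="apparent",
                    stratum=stratum.name,
                )
            )
            datum += 1
    return SurveyDataset(
        records=records,
        metadata={"source": "synthetic", "seed": str(config.seed)},
    )


def generate_cohort_life_table(
    marginal_rates: Sequence[float],
    cohort_size: int,
    seed: int = 0,
    factor_names: Sequence[str] | None = None,
) -> LifeTableCohort:
    """Simulate a cohort under competing constant hazards with given marginals.

    Each factor i acts as a constant hazard ``lambda_i = -log(1 - m_i)`` over
    one interval.  An individual survives with probability
    ``exp(-sum(lambda))``; deaths are attributed to factors in proportion to
    their hazards (the cause of a death is the factor whose event time came
    first, which for constant hazards is hazard-proportional).
    """
    rates = [float(m) for m in marginal_rates]
    if not rates:
        raise ValueError("at least one factor is required")
    if any(not (0.0 <= m < 1.0) for m in rates):
        raise ValueError("marginal rates must lie in [0, 1)")
    if cohort_size <= 0:
        raise ValueError("cohort_size must be positive")
    names = list(factor_names) if factor_names is not None else [
        f"factor_{i + 1}" for i in range(len(rates))
    ]
    if len(names) != len(rates):
        raise ValueError("factor_names length must match marginal_rates")

    rng = np.random.default_rng(seed)
    hazards = np.array([-math.log(1.0 - m) for m in rates])
    total_hazard = float(hazards.sum())
    if total_hazard == 0.0:
        return LifeTableCohort(
            cohort_size=cohort_size,
            deaths_by_factor={name: 0 for name in names},
            survivors=cohort_size,
        )
    p_death = 1.0 - math.exp(-total_hazard)
    n_dead = int(rng.binomial(cohort_size, p_death))
    cause_counts = rng.multinomial(n_dead, hazards / total_hazard)
    return LifeTableCohort(
        cohort_size=cohort_size,
        deaths_by_factor={name: int(c) for name, c in zip(names, cause_counts)},
        survivors=cohort_size - n_dead,
    )
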