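"""The precision tree: conditional contingencies multiplied along a branch.

A risk scenario chains three contingencies — spatial overlap between the agent
and the non-target habitat (probability P1), temporal overlap with susceptible
host stages (P2), and the effects distribution of parasitism rates given
contact (P3).  The overall non-target parasitism outcome is the product along
the branch.  Extra multiplicative contingencies (e.g. host-stage
susceptibility, or split dispersal routes) can be appended as an ordered list
of named probabilities.

Two gating semantics are offered for Monte Carlo propagation.  Under
``bernoulli`` gating (the default) each contingency is realized per trial as
an indicator — the agent either reaches the habitat or it does not — so the
outcome of a trial is ``I1 * I2 * r`` with ``r`` drawn from P3.  Under
``multiplier`` gating the branch probabilities scale the drawn rate directly,
``p1 * p2 * r``, reproducing pure branch-product arithmetic.  The two coincide
in expectation, and both give point_risk = p1 * p2 * E[P3].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datasets import builtin_dataset, SurveyDataset
from .distributions import FittedRateDistribution, fit_rate_distribution

__all__ = ["Scenario", "RiskForecast", "point_risk", "simulate_forecast", "build_scenario", "PRESETS"]

GATINGS = ("bernoulli", "multiplier")

#: Named scenario presets: worst case assumes full spatial and temporal
#: overlap; the average-outcome case keeps temporal overlap certain but takes
#: the published habitat records at face value (no spatial overlap).
PRESETS: dict[str, dict[str, float]] = {
    "worst_case": {"p_spatial": 1.0, "p_temporal": 1.0},
    "average_outcome": {"p_spatial": 0.0, "p_temporal": 1.0},
}


def _check_prob(name: str, p: float) -> float:
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"{name} must lie in [0, 1], got {p}")
    return float(p)


@dataclass(frozen=True)
class Scenario:
    """One parameterization of the precision tree."""

    name: str
    p_spatial: float
    p_temporal: float
    effects: FittedRateDistribution
    gating: str = "bernoulli"
    extra_contingencies: tuple[tuple[str, float], ...] = ()

    def __post_init__(self) -> None:
        _check_prob("p_spatial", self.p_spatial)
        _check_prob("p_temporal", self.p_temporal)
        for cname, p in self.extra_contingencies:
            _check_prob(f"contingency {cname!r}", p)
        if self.gating not in GATINGS:
            raise ValueError(f"gating must be one of {GATINGS}, got {self.gating!r}")

    @property
    def branch_probability(self) -> float:
        """Product of all contingency probabilities upstream of the effects node."""
        p = self.p_spatial * self.p_temporal
        for _, pc in self.extra_contingencies:
            p *= pc
        return p


@dataclass(frozen=True)
class RiskForecast:
    """Simulated overall non-target parasitism outcomes for one scenario."""

    outcomes: np.ndarray
    n_trials: int
    seed: int
    scenario_name: str

    def __post_init__(self) -> None:
        if len(self.outcomes) != self.n_trials:
            raise ValueError("length of outcomes must equal n_trials")
        if self.n_trials > 0 and (self.outcomes.min() < 0.0 or self.outcomes.max() > 1.0):
            raise ValueError("outcomes must lie in [0, 1]")


def point_risk(scenario: Scenario) -> float:
    """Expected overall parasitism: the branch product p1 * p2 * E[effects]."""
    return scenario.branch_probability * scenario.effects.mean()


def simulate_forecast(scenario: Scenario, n_trials: int = 2000, seed: int = 0) -> RiskForecast:
    """Monte Carlo propagation of the scenario through the tree.

    Deterministic given (scenario, n_trials, seed).  The default trial count
    is 2000, the setting used for the study forecasts.
    """
    if n_trials <= 0:
        raise ValueError(f"n_trials must be positive, got {n_trials}")
    rng = np.random.default_rng(seed)
    draws = scenario.effects.sample(n_trials, rng)
    probs = [scenario.p_spatial, scenario.p_temporal] + [p for _, p in scenario.extra_contingencies]
    if scenario.gating == "bernoulli":
        gate = np.ones(n_trials)
        for p in probs:
            # p in {0,1} short-circuits so zero branches are exactly zero
            gate *= 1.0 if p == 1.0 else (0.0 if p == 0.0 else rng.binomial(1, p, size=n_trials))
        outcomes = gate * draws
    else:
        mult = 1.0
        for p in probs:
            mult *= p
        outcomes = mult * draws
    return RiskForecast(outcomes=outcomes, n_trials=n_trials, seed=seed, scenario_name=scenario.name)


def _effects_from_config(effects: dict | FittedRateDistribution) -> FittedRateDistribution:
    if isinstance(effects, FittedRateDistribution):
        return effects
    family = effects.get("family", "beta")
    if "parameters" in effects:
        params = dict(effects["parameters"])
        # explicit parameters bypass fitting entirely
        if family == "degenerate":
            sample = (params["value"],)
        else:
            sample = ()
        return FittedRateDistribution(
            family=family, parameters=params, source_sample=sample, gof=float("nan")
        )
    if "values" in effects:
        return fit_rate_distribution(effects["values"], family)
    if "fixture" in effects:
        ds = builtin_dataset(effects["fixture"])
        if not isinstance(ds, SurveyDataset):
            raise ValueError(f"fixture {effects['fixture']!r} is not a mortality table")
        agent = effects.get("agent")
        values = ds.rates(agent)
        if not values:
            raise KeyError(f"no rates for agent {agent!r} in fixture {effects['fixture']!r}")
        return fit_rate_distribution(values, family)
    raise ValueError("effects config needs one of: parameters, values, fixture")


def build_scenario(config: dict) -> Scenario:
    """Validate a scenario config record and return a Scenario.

    Recognized keys: ``name``, ``preset`` ("worst_case" | "average_outcome"),
    ``p_spatial``, ``p_temporal``, ``gating``, ``extra_contingencies`` (list of
    [name, probability]) and ``effects``.  ``effects`` is either a fitted
    distribution or a mapping with a ``family`` plus one of ``parameters``
    (explicit), ``values`` (fit to a list) or ``fixture``/``agent`` (fit to a
    packaged table column).  Explicit probabilities override the preset.
    """
    cfg = dict(config)
    probs: dict[str, float] = {}
    preset = cfg.get("preset")
    if preset is not None:
        if preset not in PRESETS:
            raise KeyError(f"unknown preset {preset!r}; valid presets: {sorted(PRESETS)}")
        probs.update(PRESETS[preset])
    for key in ("p_spatial", "p_temporal"):
        if key in cfg:
            probs[key] = cfg[key]
        if key not in probs:
            raise ValueError(f"scenario config missing {key!r} (and no preset supplies it)")
    if "effects" not in cfg:
        raise ValueError("scenario config missing 'effects'")
    return Scenario(
        name=cfg.get("name", preset or "scenario"),
        p_spatial=probs["p_spatial"],
        p_temporal=probs["p_temporal"],
        effects=_effects_from_config(cfg["effects"]),
        gating=cfg.get("gating", "bernoulli"),
        extra_contingencies=tuple(
            (str(n), float(p)) for n, p in cfg.get("extra_contingencies", [])
        ),
    )
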