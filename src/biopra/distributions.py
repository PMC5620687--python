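"""Probability distributions for parasitism rates on [0, 1].

The effects input of the risk tree (P3) is a distribution of plausible
parasitism rates, built from a sample of observed proportions.  Four families
are supported:

``beta``
    Maximum-likelihood beta fit (the default: proportions live on [0, 1] and
    the forecast histograms are beta-shaped).  Values at the boundaries are
    nudged inward by ``BOUNDARY_EPS`` before fitting because the beta
    likelihood diverges there.
``truncated_normal``
    Normal restricted to [0, 1], fitted by direct MLE over (mu, sigma).
``empirical``
    Bootstrap resampling of the observed values; fit-free.
``degenerate``
    A point mass; returned automatically when the sample has no spread.

Goodness of fit is the Kolmogorov–Smirnov distance between the sample ECDF and
the fitted CDF.  All sampling goes through an explicitly seeded
``numpy.random.Generator`` — there is no global RNG state anywhere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "BOUNDARY_EPS",
    "FAMILIES",
    "FittedRateDistribution",
    "RateSample",
    "fit_rate_distribution",
    "select_best_fit",
    "draw_samples",
    "exceedance_probability",
    "summarize",
    "export_histogram",
]

BOUNDARY_EPS = 1e-4
FAMILIES = ("beta", "truncated_normal", "empirical", "degenerate")

_FAMILY_PRECEDENCE = {"beta": 0, "truncated_normal": 1, "empirical": 2, "degenerate": 3}


@dataclass(frozen=True)
class FittedRateDistribution:
    """A fitted distribution on [0, 1] for a parasitism rate."""

    family: str
    parameters: dict[str, float]
    source_sample: tuple[float, ...]
    gof: float
    degenerate_fallback: bool = False  # parametric fit requested but sample had no spread

    def mean(self) -> float:
        """Analytic mean of the fitted distribution (sample mean for empirical)."""
        p = self.parameters
        if self.family == "beta":
            return p["alpha"] / (p["alpha"] + p["beta"])
        if self.family == "truncated_normal":
            a = (0.0 - p["mu"]) / p["sigma"]
            b = (1.0 - p["mu"]) / p["sigma"]
            return float(stats.truncnorm.mean(a, b, loc=p["mu"], scale=p["sigma"]))
        if self.family == "empirical":
            return float(np.mean(self.source_sample))
        if self.family == "degenerate":
            return p["value"]
        raise ValueError(f"unknown family {self.family!r}")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``n`` values in [0, 1] using the caller's generator."""
        if n <= 0:
            raise ValueError(f"n must be positive, got {n}")
        p = self.parameters
        if self.family == "beta":
            return rng.beta(p["alpha"], p["beta"], size=n)
        if self.family == "truncated_normal":
            a = (0.0 - p["mu"]) / p["sigma"]
            b = (1.0 - p["mu"]) / p["sigma"]
            return stats.truncnorm.rvs(
                a, b, loc=p["mu"], scale=p["sigma"], size=n, random_state=rng
            )
        if self.family == "empirical":
            return rng.choice(np.asarray(self.source_sample), size=n, replace=True)
        if self.family == "degenerate":
            return np.full(n, p["value"])
        raise ValueError(f"unknown family {self.family!r}")

    def cdf(self, x: np.ndarray | float) -> np.ndarray | float:
        p = self.parameters
        if self.family == "beta":
            return stats.beta.cdf(x, p["alpha"], p["beta"])
        if self.family == "truncated_normal":
            a = (0.0 - p["mu"]) / p["sigma"]
            b = (1.0 - p["mu"]) / p["sigma"]
            return stats.truncnorm.cdf(x, a, b, loc=p["mu"], scale=p["sigma"])
        if self.family == "empirical":
            src = np.sort(np.asarray(self.source_sample))
            return np.searchsorted(src, x, side="right") / len(src)
        if self.family == "degenerate":
            return np.where(np.asarray(x, dtype=float) >= p["value"], 1.0, 0.0)
        raise ValueError(f"unknown family {self.family!r}")


@dataclass(frozen=True)
class RateSample:
    """A Monte Carlo sample of rates with its provenance (n, seed)."""

    values: np.ndarray
    n: int
    seed: int

    def __post_init__(self) -> None:
        if len(self.values) != self.n:
            raise ValueError("length of values must equal n")
        if self.n > 0 and (self.values.min() < 0.0 or self.values.max() > 1.0):
            raise ValueError("sample values must lie in [0, 1]")


def _validate_sample(sample: Sequence[float]) -> np.ndarray:
    arr = np.asarray(sample, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError("sample must be a non-empty 1-d sequence")
    if arr.min() < 0.0 or arr.max() > 1.0:
        raise ValueError("sample values must lie in [0, 1]")
    return arr


def _ks_distance(sample: np.ndarray, dist: FittedRateDistribution) -> float:
    if dist.family in ("empirical", "degenerate"):
        return 0.0
    return float(stats.kstest(sample, dist.cdf).statistic)


def _fit_beta(adj: np.ndarray) -> dict[str, float]:
    alpha, beta_, _, _ = stats.beta.fit(adj, floc=0.0, fscale=1.0)
    return {"alpha": float(alpha), "beta": float(beta_)}


def _fit_truncnorm(adj: np.ndarray) -> dict[str, float]:
    # direct 2-parameter MLE; (mu, log sigma) keeps sigma positive
    def nll(theta: np.ndarray) -> float:
        mu, log_sigma = theta
        sigma = math.exp(log_sigma)
        a, b = (0.0 - mu) / sigma, (1.0 - mu) / sigma
        return float(-np.sum(stats.truncnorm.logpdf(adj, a, b, loc=mu, scale=sigma)))

    x0 = np.array([float(np.mean(adj)), math.log(max(float(np.std(adj)), 1e-3))])
    res = optimize.minimize(nll, x0, method="Nelder-Mead", options={"xatol": 1e-8, "fatol": 1e-8})
    mu, sigma = float(res.x[0]), float(math.exp(res.x[1]))
    return {"mu": mu, "sigma": sigma}


def fit_rate_distribution(sample: Sequence[float], family: str = "beta") -> FittedRateDistribution:
    """Fit a distribution of the given family to a sample of proportions.

    A sample with fewer than two distinct values cannot support a parametric
    fit; a degenerate point mass is returned instead with
    ``degenerate_fallback=True``.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}; choose from {FAMILIES}")
    arr = _validate_sample(sample)
    src = tuple(float(v) for v in arr)

    n_distinct = len(np.unique(arr))
    if family == "degenerate" or n_distinct < 2:
        value = float(arr[0]) if n_distinct == 1 else float(np.mean(arr))
        dist = FittedRateDistribution(
            family="degenerate",
            parameters={"value": value},
            source_sample=src,
            gof=0.0,
            degenerate_fallback=(family not in ("degenerate",) and n_distinct < 2),
        )
        return dist

    if family == "empirical":
        return FittedRateDistribution(
            family="empirical", parameters={}, source_sample=src, gof=0.0
        )

    adj = np.clip(arr, BOUNDARY_EPS, 1.0 - BOUNDARY_EPS)
    params = _fit_beta(adj) if family == "beta" else _fit_truncnorm(adj)
    dist = FittedRateDistribution(family=family, parameters=params, source_sample=src, gof=0.0)
    gof = _ks_distance(arr, dist)
    return FittedRateDistribution(family=family, parameters=params, source_sample=src, gof=gof)


def select_best_fit(
    sample: Sequence[float], candidates: Sequence[str] = ("beta", "truncated_normal", "empirical")
) -> FittedRateDistribution:
    """Fit every candidate family and return the one with smallest KS distance.

    Ties break by fixed precedence beta > truncated_normal > empirical >
    degenerate.  A zero-variance sample yields a degenerate fit regardless of
    the candidate list.
    """
    if not candidates:
        raise ValueError("candidate family list is empty")
    fits: list[FittedRateDistribution] = []
    errors: list[str] = []
    for fam in candidates:
        try:
            fits.append(fit_rate_distribution(sample, fam))
        except Exception as exc:  # noqa: BLE001 - aggregate per-family failures
            errors.append(f"{fam}: {exc}")
    if not fits:
        raise ValueError("all candidate fits failed: " + "; ".join(errors))
    return min(fits, key=lambda d: (d.gof, _FAMILY_PRECEDENCE[d.family]))


def draw_samples(dist: FittedRateDistribution, n: int, seed: int) -> RateSample:
    """Draw a reproducible Monte Carlo sample from a fitted distribution."""
    if n <= 0:
        raise ValueError(f"n must be positive, got {n}")
    rng = np.random.default_rng(seed)
    values = dist.sample(n, rng)
    return RateSample(values=values, n=n, seed=seed)


def exceedance_probability(sample: RateSample | Sequence[float], threshold: float) -> float:
    """Fraction of sampled rates strictly above the threshold."""
    if not (0.0 <= threshold <= 1.0):
        raise ValueError(f"threshold {threshold} outside [0, 1]")
    values = sample.values if isinstance(sample, RateSample) else np.asarray(sample, dtype=float)
    if len(values) == 0:
        raise ValueError("sample is empty")
    return float(np.mean(values > threshold))


def summarize(sample: RateSample | Sequence[float]) -> dict[str, float]:
    """Descriptive summary: mean, sd, min, max and the 2.5/50/97.5 percentiles.

    Percentiles use linear interpolation between order statistics; the sd is
    the sample standard deviation (ddof=1; 0 for a singleton).
    """
    values = sample.values if isinstance(sample, RateSample) else np.asarray(sample, dtype=float)
    if len(values) == 0:
        raise ValueError("sample is empty")
    q = np.percentile(values, [2.5, 50.0, 97.5])
    return {
        "mean": float(np.mean(values)),
        "sd": float(np.std(values, ddof=1)) if len(values) > 1 else 0.0,
        "min": float(np.min(values)),
        "max": float(np.max(values)),
        "p2.5": float(q[0]),
        "p50": float(q[1]),
        "p97.5": float(q[2]),
    }


def export_histogram(
    sample: RateSample | Sequence[float],
    csv_path: str | Path | None = None,
    png_path: str | Path | None = None,
    bins: int = 40,
    title: str | None = None,
) -> dict[str, np.ndarray]:
    """Export frequency-chart bin counts (CSV) and optionally a PNG histogram."""
    values = sample.values if isinstance(sample, RateSample) else np.asarray(sample, dtype=float)
    counts, edges = np.histogram(values, bins=bins, range=(0.0, 1.0))
    if csv_path is not None:
        import csv as _csv

        with Path(csv_path).open("w", newline="", encoding="utf-8") as fh:
            w = _csv.writer(fh)
            w.writerow(["bin_left", "bin_right", "count"])
            for left, right, c in zip(edges[:-1], edges[1:], counts):
                w.writerow([f"{left:.6f}", f"{right:.6f}", int(c)])
    if png_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 4))
        ax.bar(edges[:-1], counts, width=np.diff(edges), align="edge", edgecolor="white")
        ax.set_xlabel("parasitism rate (proportion)")
        ax.set_ylabel("frequency")
        if title:
            ax.set_title(title)
        fig.tight_layout()
        fig.savefig(png_path, dpi=120)
        plt.close(fig)
    return {"counts": counts, "edges": edges}
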