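"""Convert mutational/genetic quantities to calendar time under tiered,
time-dependent mitochondrial substitution rates.

Expansion ages follow T = tau / (2 * mu * k) with tau in mutational units,
mu in substitutions/site/year and k the number of sites; the generation-time
form t = tau / (2 * u * k) with u = mu * g is equivalent and g is carried as
metadata only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd
import yaml

from .errors import DomainError, RateCoverageError
from .mismatch import ExpansionFit

DEFAULT_K = 16038  # mitogenome alignment length after gap-column removal

# rates the expansion-time table reports by default, in subs/site/year
REPORTING_RATES = (0.9e-7, 1.1e-7, 2.0e-7, 4.0e-7)


@dataclass(frozen=True)
class RateTier:
    locus: str
    label: str
    rate: float  # substitutions/site/year
    window: tuple[float, float]  # applicability (min_age, max_age] in years
    alternative: bool = False  # never auto-selected by rate_for_age
    source: str = ""

    def covers(self, age: float) -> bool:
        lo, hi = self.window
        return lo <= age <= hi


@dataclass(frozen=True)
class RatePolicy:
    tiers: tuple[RateTier, ...]

    def __post_init__(self):
        for t in self.tiers:
            if t.rate <= 0:
                raise DomainError(f"non-positive rate in tier {t.label!r}")

    def for_locus(self, locus: str) -> list[RateTier]:
        return [t for t in self.tiers if t.locus == locus]

    @classmethod
    def default(cls) -> "RatePolicy":
        inf = math.inf
        return cls(
            tiers=(
                RateTier("cytb", "ancient", 3.0e-8, (1e5, inf)),
                RateTier("cytb", "intermediate", 4.7e-8, (5e4, 6e4)),
                RateTier("cytb", "recent", 1.1e-7, (0.0, 2e4)),
                RateTier("mitogenome", "ancient", 2.4e-8, (1e5, inf),
                         source="80% of cytb ancient"),
                RateTier("mitogenome", "intermediate", 4.7e-8, (5e4, 6e4)),
                RateTier("mitogenome", "recent", 1.1e-7, (0.0, 2e4)),
                RateTier("mitogenome", "recent-scaled", 0.9e-7, (0.0, 2e4),
                         alternative=True, source="80% of recent"),
                RateTier("mitogenome", "high-alt-2.0", 2.0e-7, (0.0, 2e4),
                         alternative=True),
                RateTier("mitogenome", "high-alt-4.0", 4.0e-7, (0.0, 2e4),
                         alternative=True),
            )
        )

    @classmethod
    def from_yaml(cls, path) -> "RatePolicy":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        tiers = []
        for entry in data["tiers"]:
            lo = float(entry.get("min_age", 0.0))
            hi = float(entry["max_age"]) if entry.get("max_age") is not None else math.inf
            tiers.append(
                RateTier(
                    locus=entry["locus"],
                    label=entry["label"],
                    rate=float(entry["rate"]),
                    window=(lo, hi),
                    alternative=bool(entry.get("alternative", False)),
                    source=entry.get("source", ""),
                )
            )
        return cls(tiers=tuple(tiers))

    def to_yaml(self, path) -> None:
        data = {
            "tiers": [
                {
                    "locus": t.locus,
                    "label": t.label,
                    "rate": t.rate,
                    "min_age": t.window[0],
                    "max_age": None if math.isinf(t.window[1]) else t.window[1],
                    "alternative": t.alternative,
                    "source": t.source,
                }
                for t in self.tiers
            ]
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


def expansion_time(tau: float, mu: float, k: float) -> float:
    """T = tau / (2 * mu * k), in years (unrounded)."""
    if tau < 0:
        raise DomainError("tau must be non-negative")
    if mu <= 0 or k <= 0:
        raise DomainError("mu and k must be positive")
    return tau / (2.0 * mu * k)


def divergence_time(d: float, mu: float) -> float:
    """Strict-clock dating of a per-site distance between two clades: T = d/(2*mu)."""
    if d < 0:
        raise DomainError("distance must be non-negative")
    if mu <= 0:
        raise DomainError("mu must be positive")
    return d / (2.0 * mu)


def calibrate_locus_rate(base_rate: float, dist_ratio: float) -> float:
    """Scale a reference-locus rate by the observed distance ratio locusA/locusB."""
    if base_rate <= 0:
        raise DomainError("base_rate must be positive")
    if not (0.0 < dist_ratio <= 2.0):
        raise DomainError("dist_ratio must lie in (0, 2]")
    return base_rate * dist_ratio


def distance_ratio(mean_dist_a: float, mean_dist_b: float) -> float:
    """Helper: mean pairwise distance of locus A over locus B on the same samples."""
    if mean_dist_a < 0 or mean_dist_b <= 0:
        raise DomainError("distances must be positive")
    return mean_dist_a / mean_dist_b


def rate_for_age(age_years: float, policy: RatePolicy | None = None,
                 locus: str = "mitogenome") -> float:
    """Rate of the non-alternative tier whose window contains the age.

    Ties between overlapping windows break toward the younger tier (the one
    with the smaller window minimum). Ages in a coverage gap raise an error
    listing the declared windows rather than interpolating.
    """
    if age_years < 0:
        raise DomainError("age must be non-negative")
    policy = policy or RatePolicy.default()
    tiers = [t for t in policy.for_locus(locus) if not t.alternative]
    if not tiers:
        raise RateCoverageError(f"no rate tiers declared for locus {locus!r}")
    covering = [t for t in tiers if t.covers(age_years)]
    if not covering:
        windows = ", ".join(
            f"{t.label}: [{t.window[0]:g}, {t.window[1]:g}]" for t in tiers
        )
        raise RateCoverageError(
            f"no rate tier covers age {age_years:g} y for {locus!r}; windows: {windows}"
        )
    covering.sort(key=lambda t: t.window[0])
    return covering[0].rate


@dataclass(frozen=True)
class ExpansionTimeTable:
    """Per-rate expansion times (years, rounded) for one fitted group."""

    tau: float
    k: float
    times: dict[float, int]  # mu -> T years
    ci_times: dict[float, tuple[int, int]] | None = None


def expansion_time_table(
    fit: ExpansionFit, k: float = DEFAULT_K, rates=REPORTING_RATES
) -> ExpansionTimeTable:
    """One T per reporting rate; CI endpoints (when present) converted identically."""
    times = {mu: round(expansion_time(fit.tau, mu, k)) for mu in rates}
    ci_times = None
    if fit.tau_CI is not None:
        lo, hi = fit.tau_CI
        ci_times = {
            mu: (round(expansion_time(lo, mu, k)), round(expansion_time(hi, mu, k)))
            for mu in rates
        }
    return ExpansionTimeTable(tau=fit.tau, k=k, times=times, ci_times=ci_times)


def expansion_time_frame(tables: dict[str, ExpansionTimeTable]) -> pd.DataFrame:
    """Wide table: one row per group, one T column per reporting rate."""
    rows = []
    for group, t in tables.items():
        row = {"group": group, "tau": t.tau, "k": t.k}
        for mu, T in t.times.items():
            row[f"T_years_at_{mu * 1e7:g}e-7"] = T
        rows.append(row)
    return pd.DataFrame(rows)
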