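"""Tajima's D and Fu's Fs with coalescent-null significance.

Fu's Fs uses the Ewens sampling distribution of the number of alleles given
theta-hat = K (the mean pairwise difference), evaluated with unsigned
Stirling numbers of the first kind in log space so that sample sizes in the
hundreds remain finite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Literal

import numpy as np
from scipy.special import gammaln

from .alignment import Alignment, MissingPolicy, collapse_haplotypes, pairwise_differences
from .diversity import segregating_sites
from .errors import InsufficientSampleError, UndefinedStatisticError
from .simulate import SimConfig, simulate_alignment


@dataclass(frozen=True)
class NeutralityResult:
    D: float
    Fs: float
    p_D: float
    p_Fs: float
    reps: int
    seed: int
    tail: str
    significant_05: tuple[bool, bool]
    significant_01: tuple[bool, bool]


def tajimas_d(a: Alignment, missing_policy: MissingPolicy = "pairwise-deletion") -> float:
    """Tajima (1989) normalized difference between K and S/a1."""
    n = a.n
    if n < 4:
        raise InsufficientSampleError("Tajima's D needs n >= 4")
    S = segregating_sites(a)
    if S == 0:
        raise UndefinedStatisticError("Tajima's D undefined with no segregating sites")
    K = float(np.mean(pairwise_differences(a, missing_policy).pair_values()))
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a2 + a1**2)
    var = e1 * S + e2 * S * (S - 1)
    return (K - S / a1) / math.sqrt(var)


@lru_cache(maxsize=256)
def _log_stirling_first(n: int) -> tuple[float, ...]:
    """log |S(n, k)| for k = 0..n (unsigned Stirling numbers, first kind)."""
    log_s = np.full(n + 1, -np.inf)
    log_s[0] = 0.0  # |S(0,0)| = 1
    for m in range(1, n + 1):
        nxt = np.full(n + 1, -np.inf)
        # |S(m,k)| = |S(m-1,k-1)| + (m-1) |S(m-1,k)|
        nxt[1:] = log_s[:-1]
        if m > 1:
            with np.errstate(invalid="ignore"):
                nxt = np.logaddexp(nxt, log_s + math.log(m - 1))
        log_s = nxt
    return tuple(float(v) for v in log_s)


def ewens_allele_pmf(n: int, theta: float) -> np.ndarray:
    """P(number of alleles = h) for h = 0..n under the Ewens sampling formula."""
    if theta <= 0:
        raise UndefinedStatisticError("Ewens pmf needs theta > 0")
    log_s = np.asarray(_log_stirling_first(n))
    h = np.arange(n + 1)
    log_rising = float(gammaln(theta + n) - gammaln(theta))
    logp = log_s + h * math.log(theta) - log_rising
    p = np.exp(logp)
    p[0] = 0.0
    return p


def fu_fs(a: Alignment, missing_policy: MissingPolicy = "pairwise-deletion") -> float:
    """Fu (1997) Fs = ln(S' / (1 - S')), S' = P(alleles >= H_obs | theta=K)."""
    if a.n < 2:
        raise InsufficientSampleError("Fu's Fs needs n >= 2")
    K = float(np.mean(pairwise_differences(a, missing_policy).pair_values()))
    if K == 0.0:
        raise UndefinedStatisticError("Fu's Fs undefined for a monomorphic sample")
    H_obs = collapse_haplotypes(a).H
    pmf = ewens_allele_pmf(a.n, K)
    s_prime = float(pmf[H_obs:].sum())
    s_prime = min(max(s_prime, 1e-300), 1.0 - 1e-16)
    return math.log(s_prime / (1.0 - s_prime))


def neutrality_significance(
    a: Alignment,
    reps: int = 1000,
    seed: int = 0,
    tail: Literal["lower", "two-sided"] = "lower",
    missing_policy: MissingPolicy = "pairwise-deletion",
    fu_02_rule: bool = False,
) -> NeutralityResult:
    """Simulation p-values against a constant-size coalescent null with theta = K.

    Lower-tail by default (the expansion-detection direction): p is the
    fraction of null replicates whose statistic is <= the observed one.
    With `fu_02_rule`, Fs is flagged at the 0.05 level when p_Fs < 0.02.
    """
    if reps < 100:
        raise ValueError("need reps >= 100 for a stable p-value")
    D_obs = tajimas_d(a, missing_policy)
    Fs_obs = fu_fs(a, missing_policy)
    K = float(np.mean(pairwise_differences(a, missing_policy).pair_values()))
    rng = np.random.default_rng(seed)
    cfg = SimConfig.constant(n=a.n, theta=K, L=a.L)
    d_null, fs_null = [], []
    for _ in range(reps):
        sim, _truth = simulate_alignment(cfg, rng=rng)
        try:
            d_null.append(tajimas_d(sim))
        except UndefinedStatisticError:
            pass
        try:
            fs_null.append(fu_fs(sim))
        except UndefinedStatisticError:
            pass
    d_null = np.asarray(d_null)
    fs_null = np.asarray(fs_null)

    def _p(null: np.ndarray, obs: float) -> float:
        if null.size == 0:
            return float("nan")
        lower = float(np.mean(null <= obs))
        if tail == "lower":
            return lower
        return float(min(1.0, 2.0 * min(lower, np.mean(null >= obs))))

    p_D = _p(d_null, D_obs)
    p_Fs = _p(fs_null, Fs_obs)
    fs_05 = p_Fs < (0.02 if fu_02_rule else 0.05)
    return NeutralityResult(
        D=D_obs,
        Fs=Fs_obs,
        p_D=p_D,
        p_Fs=p_Fs,
        reps=reps,
        seed=seed,
        tail=tail,
        significant_05=(p_D < 0.05, fs_05),
        significant_01=(p_D < 0.01, p_Fs < 0.01),
    )
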