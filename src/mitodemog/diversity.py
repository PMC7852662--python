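"""Per-group diversity summary: n, H, Hd, S, Pi (%), K."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alignment import (
    Alignment,
    MissingPolicy,
    collapse_haplotypes,
    pairwise_differences,
)
from .errors import InsufficientSampleError


@dataclass(frozen=True)
class DiversitySummary:
    n: int
    H: int
    Hd: float
    S: int
    Pi_percent: float
    K: float


def segregating_sites(a: Alignment) -> int:
    """Columns carrying at least two distinct called (A/C/G/T) bases."""
    m = a.matrix()
    counts = np.zeros((4, a.L), dtype=np.int64)
    for b in range(4):
        counts[b] = (m == b).sum(axis=0)
    return int(((counts > 0).sum(axis=0) >= 2).sum())


def haplotype_diversity(a: Alignment) -> tuple[int, float]:
    """(H, Hd) with the sample-size-corrected estimator n/(n-1) * (1 - sum p_i^2)."""
    hs = collapse_haplotypes(a)
    n = hs.n
    if n < 2:
        raise InsufficientSampleError("haplotype diversity needs n >= 2")
    p = np.asarray(hs.multiplicities, dtype=float) / n
    hd = n / (n - 1) * (1.0 - float(np.sum(p * p)))
    return hs.H, hd


def summarize_diversity(
    a: Alignment, missing_policy: MissingPolicy = "pairwise-deletion"
) -> DiversitySummary:
    """Compute the standard per-group summary row.

    K is the mean pairwise difference count over all n(n-1)/2 pairs;
    Pi is 100 x the mean per-pair per-site difference fraction (so under
    complete-deletion Pi == 100*K/L exactly).
    """
    if a.n < 2:
        raise InsufficientSampleError("diversity summary needs n >= 2")
    H, Hd = haplotype_diversity(a)
    S = segregating_sites(a)
    pd_ = pairwise_differences(a, missing_policy)
    K = float(np.mean(pd_.pair_values()))
    Pi = 100.0 * float(np.mean(pd_.pair_fractions()))
    return DiversitySummary(n=a.n, H=H, Hd=Hd, S=S, Pi_percent=Pi, K=K)


def diversity_report(rows: dict[str, DiversitySummary]) -> pd.DataFrame:
    """One row per group: group, n, H, Hd, S, Pi_percent, K."""
    return pd.DataFrame(
        [
            {
                "group": name,
                "n": s.n,
                "H": s.H,
                "Hd": s.Hd,
                "S": s.S,
                "Pi_percent": s.Pi_percent,
                "K": s.K,
            }
            for name, s in rows.items()
        ]
    )
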