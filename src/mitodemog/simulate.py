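"""Coalescent simulator for constant-size and two-epoch sudden-expansion histories.

Time is measured in mutational units: a pair of lineages whose common
ancestor lies at time s carries s expected differences. Under this
convention theta equals the expected pairwise difference count at
equilibrium and tau is directly the crest location of the mismatch wave,
matching the analytic sudden-expansion model. Mutations fall as a Poisson
process of rate 1/2 per unit on each branch and are placed on distinct
uniformly drawn sites of an all-'A' ancestor (infinite-sites onto L
positions; collisions are redrawn).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .alignment import Alignment, write_fasta_alignment
from .errors import DomainError, SaturationError

_BASES = "ACGT"


@dataclass(frozen=True)
class SimConfig:
    """Two-epoch demography: size theta1 since time tau ago, theta0 before.

    tau == 0 collapses to a constant-size history at theta1.
    """

    n: int
    theta1: float
    theta0: float | None = None
    tau: float = 0.0
    L: int = 16038
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n < 2:
            raise DomainError("need n >= 2 samples")
        if self.theta1 <= 0 or (self.theta0 is not None and self.theta0 <= 0):
            raise DomainError("theta values must be positive")
        if self.tau < 0:
            raise DomainError("tau must be non-negative")
        if self.L < 1:
            raise DomainError("L must be >= 1")
        if self.tau > 0 and self.theta0 is None:
            raise DomainError("two-epoch history needs theta0")

    @classmethod
    def constant(cls, n: int, theta: float, L: int = 16038, seed=None) -> "SimConfig":
        return cls(n=n, theta1=theta, tau=0.0, L=L, seed=seed)


@dataclass
class SimTruth:
    """Bookkeeping record: realized genealogy and mutation load."""

    config: SimConfig
    coalescence_times: list[float]
    n_mutations: int

    @property
    def tmrca(self) -> float:
        return self.coalescence_times[-1]


def _simulate_tree(cfg: SimConfig, rng: np.random.Generator):
    """Hudson-style coalescent; returns (parent, branch_length, coal_times).

    Nodes 0..n-1 are tips; n..2n-2 internal in coalescence order. Coalescence
    rate with i active lineages is i(i-1)/(2*theta(t)), theta(t) = theta1 for
    t < tau and theta0 deeper than tau.
    """
    n = cfg.n
    n_nodes = 2 * n - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    node_time = np.zeros(n_nodes)
    active = list(range(n))
    t = 0.0
    next_node = n
    coal_times = []
    while len(active) > 1:
        i = len(active)
        theta = cfg.theta1 if (cfg.tau == 0.0 or t < cfg.tau) else cfg.theta0
        rate = i * (i - 1) / (2.0 * theta)
        dt = rng.exponential(1.0 / rate)
        if cfg.tau > 0.0 and t < cfg.tau and t + dt > cfg.tau:
            t = cfg.tau  # epoch boundary: redraw under the ancestral size
            continue
        t += dt
        a, b = rng.choice(i, size=2, replace=False)
        a, b = active[a], active[b]
        node_time[next_node] = t
        parent[a] = parent[b] = next_node
        active.remove(a)
        active.remove(b)
        active.append(next_node)
        coal_times.append(t)
        next_node += 1
    blen = np.zeros(n_nodes)
    has_parent = parent >= 0
    blen[has_parent] = node_time[parent[has_parent]] - node_time[has_parent]
    return parent, blen, coal_times


def _tips_below(parent: np.ndarray, n: int) -> list[np.ndarray]:
    """For each node, boolean mask over tips in its subtree."""
    n_nodes = parent.size
    below = [np.zeros(n, dtype=bool) for _ in range(n_nodes)]
    for tip in range(n):
        below[tip][tip] = True
        node = tip
        while parent[node] >= 0:
            node = parent[node]
            below[node][tip] = True
    return below


def simulate_alignment(cfg: SimConfig, rng=None) -> tuple[Alignment, SimTruth]:
    """Simulate one alignment plus its truth record. Reproducible from cfg.seed."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    parent, blen, coal_times = _simulate_tree(cfg, rng)
    n = cfg.n
    n_mut_per_branch = rng.poisson(blen / 2.0)
    total_mut = int(n_mut_per_branch.sum())
    if total_mut > cfg.L:
        raise SaturationError(
            f"{total_mut} mutations exceed {cfg.L} available sites"
        )
    below = _tips_below(parent, n)
    seqs = np.zeros((n, cfg.L), dtype=np.int8)  # all-'A' ancestor
    used: set[int] = set()
    for node in np.nonzero(n_mut_per_branch)[0]:
        mask = below[node]
        for _ in range(int(n_mut_per_branch[node])):
            site = int(rng.integers(cfg.L))
            while site in used:  # infinite sites: at most one hit per site
                site = int(rng.integers(cfg.L))
            used.add(site)
            alt = 1 + int(rng.integers(3))
            seqs[mask, site] = alt
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    ascii_rows = lut[seqs]
    rows = [ascii_rows[i].tobytes().decode("ascii") for i in range(n)]
    aln = Alignment(
        ids=tuple(f"sim{k:04d}" for k in range(n)), seqs=tuple(rows)
    )
    truth = SimTruth(
        config=cfg, coalescence_times=[float(t) for t in coal_times],
        n_mutations=total_mut,
    )
    return aln, truth


DEFAULT_SCENARIOS = {
    # sizes mirror the published per-haplogroup sample counts (13, 24, 11)
    "M1a7-3J-like": SimConfig(n=13, tau=9.5, theta0=0.5, theta1=1e4),
    "C1a1-like": SimConfig(n=24, tau=14.0, theta0=1.0, theta1=1e4),
    "C1a1-5-like": SimConfig(n=11, tau=3.0, theta0=2.0, theta1=50.0),
}


def make_fixture_panel(
    out_dir, scenarios: dict[str, SimConfig] | None = None, seed: int = 0
) -> list[Path]:
    """Write FASTA + metadata TSV + truth JSON per scenario; returns directories."""
    if scenarios is None:
        scenarios = DEFAULT_SCENARIOS
    root = Path(out_dir)
    root.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    written = []
    for name, cfg in scenarios.items():
        d = root / name
        d.mkdir(exist_ok=True)
        aln, truth = simulate_alignment(cfg, rng=rng)
        write_fasta_alignment(aln, d / "alignment.fasta")
        pd.DataFrame(
            {"sample_id": aln.ids, "group": name, "locality": "simulated"}
        ).to_csv(d / "metadata.tsv", sep="\t", index=False)
        payload = asdict(truth)
        payload["scenario"] = name
        payload["seed"] = seed
        (d / "truth.json").write_text(json.dumps(payload, indent=2))
        written.append(d)
    return written
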