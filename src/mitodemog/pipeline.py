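"""End-to-end orchestration: per-group diversity, neutrality, mismatch
expansion fitting with bootstrap, expansion-time tables and MJ networks."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .alignment import (
    GroupTable,
    clean_columns,
    collapse_haplotypes,
    pairwise_differences,
    read_fasta_alignment,
    subset_by_group,
    write_retained_columns,
)
from .chronology import (
    REPORTING_RATES,
    RatePolicy,
    expansion_time,
    expansion_time_table,
)
from .diversity import diversity_report, summarize_diversity
from .errors import MitodemogError
from .mismatch import bootstrap_expansion_test, fit_sudden_expansion, observed_mismatch
from .network import build_mj_network, network_summary, write_edge_tsv, write_graphml, write_nexus
from .neutrality import neutrality_significance

log = logging.getLogger("mitodemog")


@dataclass
class AnalysisConfig:
    alignment: str
    metadata: str
    out_dir: str
    group_column: str = "group"
    missing_policy: str = "pairwise-deletion"
    clean_policy: str = "drop-gap-columns"
    reps: int = 1000
    seed: int = 0
    k: float | None = None  # defaults to cleaned alignment length
    rates: tuple[float, ...] = REPORTING_RATES
    epsilon: int = 0
    network_groups: tuple[str, ...] | None = None  # None -> all eligible
    rate_ledger: str | None = None  # YAML path; None -> built-in default

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh)
        if "rates" in data:
            data["rates"] = tuple(float(r) for r in data["rates"])
        if data.get("network_groups") is not None:
            data["network_groups"] = tuple(data["network_groups"])
        return cls(**data)


@dataclass
class ReportBundle:
    diversity: pd.DataFrame
    demography: pd.DataFrame
    network_summaries: dict[str, object]
    skipped: dict[str, str]
    manifest: dict

    def diversity_path(self, out_dir) -> Path:
        return Path(out_dir) / "diversity.tsv"


def _file_hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_analysis(cfg: AnalysisConfig) -> ReportBundle:
    """Run every stage for every group; groups failing a precondition are
    skipped with a logged reason, never silently dropped."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if cfg.reps < 100:
        log.warning("reps=%d is below the recommended minimum of 100", cfg.reps)
    aln = read_fasta_alignment(cfg.alignment)
    groups = GroupTable.read_tsv(cfg.metadata, cfg.group_column)
    aln, kept = clean_columns(aln, cfg.clean_policy)
    write_retained_columns(kept, out / "retained_columns.tsv")
    k = cfg.k if cfg.k is not None else aln.L
    policy = (
        RatePolicy.from_yaml(cfg.rate_ledger)
        if cfg.rate_ledger
        else RatePolicy.default()
    )

    diversity_rows = {}
    demo_rows = []
    skipped: dict[str, str] = {}
    net_summaries = {}
    sample_groups = dict(
        zip(groups.table["sample_id"], groups.table[groups.group_column])
    )
    for label in groups.labels():
        try:
            sub = subset_by_group(aln, groups, label)
        except MitodemogError as exc:
            skipped[label] = f"no-sequences: {exc}"
            log.warning("group %s skipped: %s", label, exc)
            continue
        if sub.n < 2:
            skipped[label] = "insufficient-sample"
            log.warning("group %s skipped: insufficient-sample (n=%d)", label, sub.n)
            continue
        div = summarize_diversity(sub, cfg.missing_policy)
        diversity_rows[label] = div
        row = {
            "group": label,
            "n": div.n,
            "Pi_percent": div.Pi_percent,
            "D": None,
            "p_D": None,
            "Fs": None,
            "p_Fs": None,
            "tau": None,
            "tau_CI_low": None,
            "tau_CI_high": None,
            "SSD": None,
            "p_SSD": None,
            "r": None,
            "p_r": None,
        }
        try:
            neut = neutrality_significance(
                sub, reps=max(cfg.reps, 100), seed=cfg.seed,
                missing_policy=cfg.missing_policy,
            )
            row.update(D=neut.D, p_D=neut.p_D, Fs=neut.Fs, p_Fs=neut.p_Fs)
        except MitodemogError as exc:
            log.warning("group %s: neutrality skipped (%s)", label, exc)
        try:
            m = observed_mismatch(pairwise_differences(sub, cfg.missing_policy))
            fit = fit_sudden_expansion(m)
            fit = bootstrap_expansion_test(
                sub, fit, reps=max(cfg.reps, 100), seed=cfg.seed
            )
            row.update(
                tau=fit.tau,
                tau_CI_low=fit.tau_CI[0],
                tau_CI_high=fit.tau_CI[1],
                SSD=fit.SSD,
                p_SSD=fit.p_SSD,
                r=fit.r,
                p_r=fit.p_r,
            )
            tt = expansion_time_table(fit, k=k, rates=cfg.rates)
            for mu, T in tt.times.items():
                # internal consistency: printed T must equal tau/(2 mu k)
                assert T == round(expansion_time(fit.tau, mu, k))
                row[f"T_years_at_{mu * 1e7:g}e-7"] = T
        except MitodemogError as exc:
            log.warning("group %s: mismatch stage skipped (%s)", label, exc)
        demo_rows.append(row)

        wanted = cfg.network_groups is None or label in cfg.network_groups
        if wanted:
            hs = collapse_haplotypes(sub)
            if hs.H < 2:
                log.warning("group %s: network skipped (single haplotype)", label)
            else:
                net = build_mj_network(hs, epsilon=cfg.epsilon, groups=sample_groups)
                net_summaries[label] = network_summary(net)
                write_graphml(net, out / f"network_{label}.graphml")
                write_nexus(net, out / f"network_{label}.nex")
                write_edge_tsv(net, out / f"network_{label}_edges.tsv")

    if not diversity_rows:
        raise MitodemogError("all groups failed preconditions")
    div_df = diversity_report(diversity_rows)
    demo_df = pd.DataFrame(demo_rows)
    div_df.to_csv(out / "diversity.tsv", sep="\t", index=False)
    demo_df.to_csv(out / "demography.tsv", sep="\t", index=False)
    manifest = {
        "package_version": __version__,
        "seed": cfg.seed,
        "reps": cfg.reps,
        "k": k,
        "missing_policy": cfg.missing_policy,
        "clean_policy": cfg.clean_policy,
        "rates": list(cfg.rates),
        "epsilon": cfg.epsilon,
        "alignment": str(cfg.alignment),
        "alignment_sha256_16": _file_hash(Path(cfg.alignment)),
        "metadata": str(cfg.metadata),
        "rate_ledger": [
            {
                "locus": t.locus,
                "label": t.label,
                "rate": t.rate,
                "window": [t.window[0], t.window[1]],
                "alternative": t.alternative,
            }
            for t in policy.tiers
        ],
        "skipped_groups": skipped,
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return ReportBundle(
        diversity=div_df,
        demography=demo_df,
        network_summaries=net_summaries,
        skipped=skipped,
        manifest=manifest,
    )
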