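"""Alignment I/O, column cleaning, haplotype collapsing and pairwise differences.

Sequences are haploid DNA rows over {A, C, G, T, -, N, IUPAC ambiguity}.
Only A/C/G/T count as called bases; gaps, N and ambiguity codes are treated
as missing for all difference counting (conservative, matches common
population-genetics tooling).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import (
    DegenerateOutputError,
    InputError,
    InsufficientSampleError,
    RaggedAlignmentError,
)

IUPAC_SYMBOLS = frozenset("ACGTRYSWKMBDHVN-")
_BASES = "ACGT"

# byte-code lookup: A,C,G,T -> 0..3, everything else missing (-1)
_CODE_TABLE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(_BASES):
    _CODE_TABLE[ord(_b)] = _i

MissingPolicy = Literal["complete-deletion", "pairwise-deletion"]
CleanPolicy = Literal["drop-gap-columns", "drop-gap-or-ambiguous-columns"]


@dataclass
class Alignment:
    """Rectangular set of aligned sequences with unique ids."""

    ids: tuple[str, ...]
    seqs: tuple[str, ...]

    def __post_init__(self) -> None:
        self.ids = tuple(self.ids)
        self.seqs = tuple(self.seqs)
        if len(self.ids) != len(self.seqs):
            raise InputError("ids and seqs must have the same length")
        if len(self.ids) == 0:
            raise InputError("alignment must contain at least one sequence")
        if len(set(self.ids)) != len(self.ids):
            raise InputError("duplicate sequence ids in alignment")
        lengths = {len(s) for s in self.seqs}
        if len(lengths) > 1:
            raise RaggedAlignmentError(
                f"ragged alignment: row lengths {sorted(lengths)}"
            )
        self._matrix: np.ndarray | None = None

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def L(self) -> int:
        return len(self.seqs[0])

    def matrix(self) -> np.ndarray:
        """Integer-coded (n, L) matrix: A,C,G,T -> 0..3, missing -> -1."""
        if self._matrix is None:
            raw = np.frombuffer(
                "".join(self.seqs).encode("ascii"), dtype=np.uint8
            ).reshape(self.n, self.L)
            self._matrix = _CODE_TABLE[raw]
        return self._matrix

    def subset(self, indices: Sequence[int]) -> "Alignment":
        return Alignment(
            ids=tuple(self.ids[i] for i in indices),
            seqs=tuple(self.seqs[i] for i in indices),
        )


@dataclass(frozen=True)
class HaplotypeSet:
    """Unique sequences with multiplicities, in first-occurrence order."""

    haplotypes: tuple[str, ...]
    multiplicities: tuple[int, ...]
    members: tuple[tuple[str, ...], ...]

    @property
    def H(self) -> int:
        return len(self.haplotypes)

    @property
    def n(self) -> int:
        return sum(self.multiplicities)


@dataclass(frozen=True)
class PairwiseDiffs:
    """Symmetric matrices of per-pair difference counts and effective sites."""

    diffs: np.ndarray
    effective_sites: np.ndarray

    @property
    def n(self) -> int:
        return self.diffs.shape[0]

    def pair_values(self) -> np.ndarray:
        """Difference counts of the n(n-1)/2 unordered pairs."""
        iu = np.triu_indices(self.n, k=1)
        return self.diffs[iu]

    def pair_fractions(self) -> np.ndarray:
        """Per-pair differences / effective sites (per-site distances)."""
        iu = np.triu_indices(self.n, k=1)
        eff = self.effective_sites[iu].astype(float)
        if np.any(eff == 0):
            raise DegenerateOutputError("a sequence pair shares no called sites")
        return self.diffs[iu] / eff


class GroupTable:
    """Mapping sample id -> group label, with optional extra metadata columns."""

    def __init__(self, table: pd.DataFrame, group_column: str = "group"):
        if "sample_id" not in table.columns:
            raise InputError("metadata table must have a 'sample_id' column")
        if group_column not in table.columns:
            raise InputError(f"metadata table must have a {group_column!r} column")
        if table["sample_id"].duplicated().any():
            dup = table.loc[table["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise InputError(f"duplicate sample_id in metadata: {dup!r}")
        self.table = table.reset_index(drop=True)
        self.group_column = group_column

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, str]) -> "GroupTable":
        return cls(
            pd.DataFrame(
                {"sample_id": list(mapping), "group": list(mapping.values())}
            )
        )

    @classmethod
    def read_tsv(cls, path, group_column: str = "group") -> "GroupTable":
        return cls(pd.read_csv(path, sep="\t", dtype=str), group_column)

    def group_of(self, sample_id: str) -> str:
        row = self.table.loc[self.table["sample_id"] == sample_id]
        if row.empty:
            raise KeyError(sample_id)
        return row[self.group_column].iloc[0]

    def labels(self) -> list[str]:
        """Distinct group labels in order of first appearance."""
        return list(dict.fromkeys(self.table[self.group_column]))

    def members_of(self, label: str) -> list[str]:
        sel = self.table[self.group_column] == label
        if not sel.any():
            raise KeyError(label)
        return list(self.table.loc[sel, "sample_id"])


def read_fasta_alignment(path) -> Alignment:
    """Read a FASTA alignment; uppercase residues, map U to T, validate symbols."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise InputError(f"no FASTA records found in {path}")
    ids, seqs = [], []
    for rec in records:
        seq = str(rec.seq).upper().replace("U", "T")
        for pos, ch in enumerate(seq):
            if ch not in IUPAC_SYMBOLS:
                raise InputError(
                    f"non-IUPAC symbol {ch!r} in record {rec.id!r} at column {pos + 1}"
                )
        ids.append(rec.id)
        seqs.append(seq)
    return Alignment(ids=tuple(ids), seqs=tuple(seqs))


def write_fasta_alignment(a: Alignment, path) -> None:
    records = [
        SeqRecord(Seq(s), id=i, description="") for i, s in zip(a.ids, a.seqs)
    ]
    SeqIO.write(records, str(path), "fasta")


def clean_columns(
    a: Alignment, policy: CleanPolicy = "drop-gap-columns"
) -> tuple[Alignment, list[int]]:
    """Drop alignment columns containing gaps (optionally also N/ambiguity).

    Returns the cleaned alignment and the 0-based indices of retained columns.
    """
    if policy not in ("drop-gap-columns", "drop-gap-or-ambiguous-columns"):
        raise InputError(f"unknown cleaning policy {policy!r}")
    raw = np.frombuffer(
        "".join(a.seqs).encode("ascii"), dtype=np.uint8
    ).reshape(a.n, a.L)
    has_gap = (raw == ord("-")).any(axis=0)
    if policy == "drop-gap-columns":
        drop = has_gap
    else:
        called = _CODE_TABLE[raw] >= 0
        drop = has_gap | (~called).any(axis=0)
    kept = np.nonzero(~drop)[0]
    if kept.size == 0:
        raise DegenerateOutputError("column cleaning removed every column")
    if kept.size == a.L:
        return a, list(range(a.L))
    seqs = tuple("".join(s[j] for j in kept) for s in a.seqs)
    return Alignment(ids=a.ids, seqs=seqs), [int(j) for j in kept]


def write_retained_columns(kept: Iterable[int], path) -> None:
    """Retained-column report, 1-based coordinates."""
    pd.DataFrame({"column_1based": [j + 1 for j in kept]}).to_csv(
        path, sep="\t", index=False
    )


def collapse_haplotypes(a: Alignment) -> HaplotypeSet:
    """Exact-match collapse in first-occurrence order."""
    order: dict[str, list[str]] = {}
    for sid, seq in zip(a.ids, a.seqs):
        order.setdefault(seq, []).append(sid)
    return HaplotypeSet(
        haplotypes=tuple(order),
        multiplicities=tuple(len(v) for v in order.values()),
        members=tuple(tuple(v) for v in order.values()),
    )


def pairwise_differences(
    a: Alignment, missing_policy: MissingPolicy = "pairwise-deletion"
) -> PairwiseDiffs:
    """Count per-pair nucleotide differences over called (A/C/G/T) sites.

    Under complete-deletion, any column with a missing symbol in any row is
    excluded for every pair; under pairwise-deletion, columns are excluded
    per pair only when one member of that pair is missing there.
    """
    if a.n < 2:
        raise InsufficientSampleError("need at least 2 sequences")
    m = a.matrix()
    called = m >= 0
    if missing_policy == "complete-deletion":
        keep = called.all(axis=0)
        m = m[:, keep]
        called = called[:, keep]
    elif missing_policy != "pairwise-deletion":
        raise InputError(f"unknown missing policy {missing_policy!r}")
    n = a.n
    diffs = np.zeros((n, n), dtype=np.int64)
    eff = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        both = called[i] & called[i + 1 :]
        neq = (m[i] != m[i + 1 :]) & both
        diffs[i, i + 1 :] = neq.sum(axis=1)
        eff[i, i + 1 :] = both.sum(axis=1)
    diffs += diffs.T
    eff += eff.T
    np.fill_diagonal(eff, int(called[0].sum()) if n else 0)
    np.fill_diagonal(diffs, 0)
    return PairwiseDiffs(diffs=diffs, effective_sites=eff)


def subset_by_group(a: Alignment, g: GroupTable, label: str) -> Alignment:
    """Rows restricted to samples carrying `label`, original order preserved."""
    wanted = set(g.members_of(label))  # raises KeyError if label absent
    indices = [i for i, sid in enumerate(a.ids) if sid in wanted]
    if not indices:
        raise DegenerateOutputError(
            f"no aligned sequence carries group label {label!r}"
        )
    return a.subset(indices)
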