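import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitodemog.alignment import (
    Alignment,
    GroupTable,
    clean_columns,
    collapse_haplotypes,
    pairwise_differences,
    read_fasta_alignment,
    subset_by_group,
    write_fasta_alignment,
)
from mitodemog.errors import (
    DegenerateOutputError,
    InputError,
    InsufficientSampleError,
    RaggedAlignmentError,
)

from .conftest import make_aln


class TestReadFasta:
    def test_two_records(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">a\nACGT\n>b\nACGA\n")
        a = read_fasta_alignment(p)
        assert a.n == 2 and a.L == 4
        assert a.seqs == ("ACGT", "ACGA")

    def test_ragged_alignment_rejected(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">a\nACGT\n>b\nACG\n")
        with pytest.raises(RaggedAlignmentError, match="ragged"):
            read_fasta_alignment(p)

    def test_empty_file(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text("")
        with pytest.raises(InputError):
            read_fasta_alignment(p)

    def test_non_iupac_symbol_names_position(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">a\nACXT\n")
        with pytest.raises(InputError, match="column 3"):
            read_fasta_alignment(p)

    def test_lowercase_and_u_normalized(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">a\nacgu\n")
        assert read_fasta_alignment(p).seqs == ("ACGT",)

    def test_study_scale_shape_contract(self, tmp_path, rng):
        # 98 records x 16,038 columns, mirroring the study alignment
        bases = np.frombuffer(b"ACGT", dtype=np.uint8)
        mat = bases[rng.integers(0, 4, size=(98, 16038))]
        p = tmp_path / "big.fasta"
        with open(p, "w") as fh:
            for i in range(98):
                fh.write(f">s{i}\n{mat[i].tobytes().decode()}\n")
        a = read_fasta_alignment(p)
        assert (a.n, a.L) == (98, 16038)

    def test_roundtrip(self, tmp_path):
        a = make_aln("ACGT", "ACGA")
        p = tmp_path / "out.fasta"
        write_fasta_alignment(a, p)
        assert read_fasta_alignment(p).seqs == a.seqs


class TestCleanColumns:
    def test_drop_gap(self):
        a, kept = clean_columns(make_aln("A-G", "AAG"), "drop-gap-columns")
        assert a.seqs == ("AG", "AG")
        assert kept == [0, 2]

    def test_ambiguity_policies(self):
        a = make_aln("ANG", "AAG")
        cleaned, _ = clean_columns(a, "drop-gap-columns")
        assert cleaned.L == 3
        strict, kept = clean_columns(a, "drop-gap-or-ambiguous-columns")
        assert strict.L == 2 and kept == [0, 2]

    def test_gap_free_identity(self):
        a = make_aln("ACG", "ACT")
        cleaned, kept = clean_columns(a)
        assert cleaned.seqs == a.seqs and kept == [0, 1, 2]

    def test_all_columns_removed(self):
        with pytest.raises(DegenerateOutputError):
            clean_columns(make_aln("-A", "A-"))

    def test_idempotent(self):
        a = make_aln("A-GN", "AAG-", "AAGA")
        once, _ = clean_columns(a, "drop-gap-or-ambiguous-columns")
        twice, _ = clean_columns(once, "drop-gap-or-ambiguous-columns")
        assert twice.seqs == once.seqs
        assert once.L <= a.L


class TestCollapseHaplotypes:
    def test_basic(self):
        hs = collapse_haplotypes(make_aln("AAA", "AAA", "AAT"))
        assert hs.H == 2
        assert hs.multiplicities == (2, 1)

    def test_all_identical(self):
        assert collapse_haplotypes(make_aln(*["AA"] * 5)).H == 1

    def test_all_distinct(self):
        assert collapse_haplotypes(make_aln("AA", "AT", "TA", "TT")).H == 4

    @given(
        st.lists(
            st.text(alphabet="ACGT", min_size=5, max_size=5),
            min_size=1,
            max_size=12,
        )
    )
    def test_multiplicities_conserved(self, seqs):
        a = Alignment(
            ids=tuple(f"s{i}" for i in range(len(seqs))), seqs=tuple(seqs)
        )
        hs = collapse_haplotypes(a)
        assert sum(hs.multiplicities) == a.n
        assert len(set(hs.haplotypes)) == hs.H <= a.n


def _naive_pairwise(seqs, policy):
    n = len(seqs)
    d = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            for x, y in zip(seqs[i], seqs[j]):
                if x in "ACGT" and y in "ACGT" and x != y:
                    d[i, j] += 1
    if policy == "complete-deletion":
        d = np.zeros((n, n), dtype=int)
        cols = [
            c
            for c in range(len(seqs[0]))
            if all(s[c] in "ACGT" for s in seqs)
        ]
        for i in range(n):
            for j in range(n):
                d[i, j] = sum(seqs[i][c] != seqs[j][c] for c in cols) if i != j else 0
    return d


class TestPairwiseDifferences:
    def test_simple(self):
        pd_ = pairwise_differences(make_aln("AAA", "AAT"))
        assert pd_.diffs[0, 1] == 1

    def test_pairwise_deletion_effective_sites(self):
        pd_ = pairwise_differences(make_aln("AAN", "AAT"), "pairwise-deletion")
        assert pd_.diffs[0, 1] == 0
        assert pd_.effective_sites[0, 1] == 2

    def test_three_sequences(self):
        pd_ = pairwise_differences(make_aln("AAAA", "AATT", "ATTT"))
        assert pd_.diffs[0, 1] == 2
        assert pd_.diffs[0, 2] == 3
        assert pd_.diffs[1, 2] == 1

    def test_insufficient_sample(self):
        with pytest.raises(InsufficientSampleError):
            pairwise_differences(make_aln("AAA"))

    @settings(max_examples=40, deadline=None)
    @given(
        st.lists(
            st.text(alphabet="ACGTN-", min_size=8, max_size=8),
            min_size=2,
            max_size=6,
        ),
        st.sampled_from(["pairwise-deletion", "complete-deletion"]),
        st.randoms(use_true_random=False),
    )
    def test_matches_naive_oracle_and_permutation_invariant(self, seqs, policy, rnd):
        a = Alignment(
            ids=tuple(f"s{i}" for i in range(len(seqs))), seqs=tuple(seqs)
        )
        got = pairwise_differences(a, policy).diffs
        expect = _naive_pairwise(seqs, policy)
        assert np.array_equal(got, expect)
        perm = list(range(a.n))
        rnd.shuffle(perm)
        permuted = pairwise_differences(a.subset(perm), policy).diffs
        assert np.array_equal(permuted, got[np.ix_(perm, perm)])

    def test_symmetric_zero_diagonal(self):
        pd_ = pairwise_differences(make_aln("ACGT", "ACGA", "TCGA"))
        assert np.array_equal(pd_.diffs, pd_.diffs.T)
        assert np.all(np.diag(pd_.diffs) == 0)


class TestSubsetByGroup:
    def _table(self):
        return GroupTable.from_mapping(
            {"s0": "MUS", "s1": "MUS", "s2": "MUS", "s3": "CAS", "s4": "CAS"}
        )

    def test_subset(self):
        a = make_aln("AA", "AC", "AG", "AT", "CC")
        sub = subset_by_group(a, self._table(), "MUS")
        assert sub.n == 3 and sub.ids == ("s0", "s1", "s2")

    def test_absent_label(self):
        a = make_aln("AA", "AC", "AG", "AT", "CC")
        with pytest.raises(KeyError):
            subset_by_group(a, self._table(), "X")

    def test_identity_when_all_one_label(self):
        a = make_aln("AA", "AC")
        g = GroupTable.from_mapping({"s0": "G", "s1": "G"})
        assert subset_by_group(a, g, "G").seqs == a.seqs
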