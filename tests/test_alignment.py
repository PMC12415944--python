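import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from delimscale.alignment import (
    Alignment,
    AlignmentFormatError,
    GenePartition,
    concatenate,
    deduplicate_haplotypes,
    read_fasta_alignment,
    size_ladder,
    split_by_partitions,
    subset_prefix,
    write_fasta,
)


def make(ids, rows, parts=()):
    return Alignment.from_strings(ids, rows, parts)


class TestFastaIO:
    def test_round_trip_uppercases(self, tmp_path):
        p = tmp_path / "g.fasta"
        p.write_text(">s1 some description\nacgtacgtacgt\n>s2\nACGTACGTACGA\n")
        aln = read_fasta_alignment(p)
        assert aln.sample_ids == ["s1", "s2"]
        assert aln.n_columns == 12
        assert aln.rows()[0] == "ACGTACGTACGT"
        out = tmp_path / "out.fasta"
        write_fasta(aln, out)
        again = read_fasta_alignment(out, name="g")
        assert again.rows() == aln.rows()
        assert again.sample_ids == aln.sample_ids

    def test_ragged_alignment_is_an_error(self, tmp_path):
        p = tmp_path / "bad.fasta"
        p.write_text(">a\nACGTACGTACGT\n>b\nACGTACGTACGTA\n")
        with pytest.raises(AlignmentFormatError, match="ragged"):
            read_fasta_alignment(p)

    def test_duplicate_id_is_an_error(self, tmp_path):
        p = tmp_path / "dup.fasta"
        p.write_text(">a\nACGT\n>a\nACGT\n")
        with pytest.raises(AlignmentFormatError, match="duplicate"):
            read_fasta_alignment(p)


class TestConcatenate:
    def test_bookkeeping(self):
        g1 = make(["a", "b"], ["ACGTACGTAC", "ACGTACGTAA"], [GenePartition("g1", 0, 10)])
        g2 = make(["a", "b"], ["C" * 20, "G" * 20], [GenePartition("g2", 0, 20)])
        cat = concatenate([g1, g2])
        assert cat.n_columns == 30
        assert [(p.name, p.start, p.end) for p in cat.partitions] == [
            ("g1", 0, 10),
            ("g2", 10, 30),
        ]

    def test_random_order_is_seeded(self):
        genes = [
            make(["a"], ["A" * (i + 1)], [GenePartition(f"g{i}", 0, i + 1)])
            for i in range(8)
        ]
        c1 = concatenate(genes, order="random", seed=5)
        c2 = concatenate(genes, order="random", seed=5)
        c3 = concatenate(genes, order="random", seed=6)
        assert [p.name for p in c1.partitions] == [p.name for p in c2.partitions]
        assert [p.name for p in c1.partitions] != [p.name for p in c3.partitions]

    def test_split_round_trip(self):
        g1 = make(["a", "b"], ["ACGTACGTAC", "ACGTACGTAA"], [GenePartition("g1", 0, 10)])
        g2 = make(["a", "b"], ["CCCCC", "GGGGG"], [GenePartition("g2", 0, 5)])
        back = split_by_partitions(concatenate([g1, g2]))
        assert back[0].rows() == g1.rows()
        assert back[1].rows() == g2.rows()

    def test_missing_samples_padded_with_gaps(self):
        g1 = make(["a", "b"], ["ACGT", "ACGA"], [GenePartition("g1", 0, 4)])
        g2 = make(["a"], ["CC"], [GenePartition("g2", 0, 2)])
        cat = concatenate([g1, g2])
        assert cat.row("b") == "ACGA--"

    def test_empty_gene_list_is_an_error(self):
        with pytest.raises(ValueError):
            concatenate([])


class TestDeduplicate:
    def test_first_occurrence_rule(self):
        aln = make(["s1", "s2", "s3"], ["ACGT", "ACGA", "ACGT"])
        uniq, hmap = deduplicate_haplotypes(aln)
        assert uniq.sample_ids == ["s1", "s2"]
        assert hmap == {"s1": ["s3"], "s2": []}

    def test_idempotent_and_content_preserving(self):
        aln = make(["a", "b", "c"], ["AC-T", "AC-T", "ACTT"])
        once, _ = deduplicate_haplotypes(aln)
        twice, m2 = deduplicate_haplotypes(once)
        assert twice.rows() == once.rows()
        assert all(not v for v in m2.values())
        # no column content was altered
        assert set(once.rows()) <= set(aln.rows())

    def test_all_distinct_unchanged(self):
        aln = make(["a", "b"], ["ACGT", "ACGA"])
        uniq, hmap = deduplicate_haplotypes(aln)
        assert uniq.rows() == aln.rows()
        assert hmap == {"a": [], "b": []}


class TestSizeLadder:
    def test_default_ladder_endpoints_and_rungs(self):
        ladder = size_ladder()
        assert len(ladder) == 11
        assert ladder[0] == 316
        assert ladder[1] == 562  # round(10**2.75)
        assert ladder[-1] == 100000
        assert all(b > a for a, b in zip(ladder, ladder[1:]))

    def test_invalid_ladder(self):
        with pytest.raises(ValueError):
            size_ladder(5.0, 2.5)
        with pytest.raises(ValueError):
            size_ladder(step=0)


class TestSubsetPrefix:
    def test_clipping_and_partition_window(self):
        aln = make(
            ["a"], ["A" * 30], [GenePartition("g1", 0, 10), GenePartition("g2", 10, 30)]
        )
        sub = subset_prefix(aln, 10)
        assert sub.n_columns == 10
        assert [(p.name, p.start, p.end) for p in sub.partitions] == [("g1", 0, 10)]

    def test_longer_than_width_returns_full(self):
        aln = make(["a"], ["ACGT"])
        assert subset_prefix(aln, 99).rows() == aln.rows()

    def test_prefixes_are_nested(self):
        rng = np.random.default_rng(0)
        row = "".join(rng.choice(list("ACGT"), size=1000))
        aln = make(["a"], [row])
        small = subset_prefix(aln, 316)
        large = subset_prefix(aln, 700)
        assert large.rows()[0][:316] == small.rows()[0]

    def test_bad_length(self):
        with pytest.raises(ValueError):
            subset_prefix(make(["a"], ["ACGT"]), 0)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.lists(st.sampled_from("ACGT-N"), min_size=4, max_size=40))
def test_dedup_never_alters_columns(chars):
    row = "".join(chars)
    aln = make(["a", "b", "c"], [row, row, row[::-1]])
    uniq, hmap = deduplicate_haplotypes(aln)
    reps = set(uniq.sample_ids)
    collapsed = {x for v in hmap.values() for x in v}
    assert reps | collapsed == set(aln.sample_ids)
    assert reps & collapsed == set()


class TestAmbiguityAwareDedup:
    def test_wildcard_positions_collapse(self):
        aln = make(["a", "b", "c"], ["ACGT", "ACGN", "ACCA"])
        uniq, hmap = deduplicate_haplotypes(aln, ambiguity_aware=True)
        assert uniq.sample_ids == ["a", "c"]
        assert hmap == {"a": ["b"], "c": []}

    def test_default_remains_exact(self):
        aln = make(["a", "b"], ["ACGT", "ACGN"])
        uniq, _ = deduplicate_haplotypes(aln)
        assert uniq.n_samples == 2
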