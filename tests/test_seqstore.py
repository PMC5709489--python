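"""Distance primitives, FASTA I/O, locus filtering/ranking/panel selection."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from multibarcode.seqstore import (
    AlignmentError,
    BarcodeError,
    FastaParseError,
    Individual,
    LocusAlignment,
    MultilocusDataset,
    UndefinedDistanceError,
    concat_distance,
    filter_by_missing,
    load_dataset,
    p_distance,
    rank_loci_by_divergence,
    read_locus_fasta,
    sample_loci,
    select_panel,
    write_dataset,
)
from conftest import ind, make_dataset, random_seq


def brute_force_pdist(a: str, b: str) -> tuple[int, int]:
    """Independent per-site tally (pure Python, pairwise deletion)."""
    mism = valid = 0
    for x, y in zip(a, b):
        if x in "ACGT" and y in "ACGT":
            valid += 1
            if x != y:
                mism += 1
    return mism, valid


class TestPDistance:
    @pytest.mark.parametrize(
        "a,b,value,valid",
        [
            ("ACGT", "ACGA", 0.25, 4),
            ("AC-T", "ACGT", 0.0, 3),   # gap excluded pairwise
            ("ANGT", "ACGT", 0.0, 3),   # N excluded pairwise
            ("ACGT", "ACGT", 0.0, 4),
        ],
    )
    def test_examples(self, a, b, value, valid):
        d = p_distance(a, b)
        assert d.value == pytest.approx(value)
        assert d.valid_sites == valid

    def test_length_mismatch_raises(self):
        with pytest.raises(AlignmentError):
            p_distance("ACG", "ACGT")

    def test_all_sites_invalid_raises(self):
        with pytest.raises(UndefinedDistanceError):
            p_distance("NN--", "AC-N")

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(
        st.integers(0, 2**32 - 1),
        st.integers(10, 300),
    )
    def test_matches_per_site_oracle_and_symmetry(self, seed, length):
        rng = np.random.default_rng(seed)
        a = random_seq(rng, length, alphabet="ACGTN-")
        b = random_seq(rng, length, alphabet="ACGTN-")
        mism, valid = brute_force_pdist(a, b)
        if valid == 0:
            with pytest.raises(UndefinedDistanceError):
                p_distance(a, b)
            return
        d = p_distance(a, b)
        assert d.valid_sites == valid
        assert d.value == pytest.approx(mism / valid)
        d_rev = p_distance(b, a)
        assert d_rev.value == d.value and d_rev.valid_sites == d.valid_sites


class TestConcatDistance:
    def test_additivity_over_loci(self):
        a, b = ind("A", "x"), ind("B", "y")
        # locus 1: 1 mismatch / 4 valid; locus 2: 3 mismatches / 4 valid
        l1 = LocusAlignment("l1", {a: "ACGT", b: "CCGT"})
        l2 = LocusAlignment("l2", {a: "ACGT", b: "CGGA"})
        ds = MultilocusDataset([l1, l2])
        d = concat_distance(ds, ["l1", "l2"], a, b)
        assert d.value == pytest.approx(4 / 8)
        assert d.valid_sites == 8

    def test_single_locus_reduces_to_p_distance(self):
        a, b = ind("A", "x"), ind("B", "y")
        l1 = LocusAlignment("l1", {a: "ACGTTT", b: "ACATTA"})
        ds = MultilocusDataset([l1])
        assert concat_distance(ds, ["l1"], a, b) == p_distance("ACGTTT", "ACATTA")

    def test_equals_literal_concatenation_oracle(self):
        rng = np.random.default_rng(5)
        inds = [ind("A", "x"), ind("B", "y")]
        ds = make_dataset(10, inds, length=40, seed=5)
        lids = ds.locus_ids
        concat_a = "".join(ds.locus(l).sequences[inds[0]] for l in lids)
        concat_b = "".join(ds.locus(l).sequences[inds[1]] for l in lids)
        expected = p_distance(concat_a, concat_b)
        got = concat_distance(ds, lids, *inds)
        assert got.value == pytest.approx(expected.value)
        assert got.valid_sites == expected.valid_sites

    def test_no_shared_locus_raises(self):
        a, b = ind("A", "x"), ind("B", "y")
        l1 = LocusAlignment("l1", {a: "ACGT"})
        l2 = LocusAlignment("l2", {b: "ACGT"})
        ds = MultilocusDataset([l1, l2])
        with pytest.raises(UndefinedDistanceError):
            concat_distance(ds, ["l1", "l2"], a, b)


class TestFastaIO:
    def test_round_trip(self, tmp_path):
        inds = [ind("A", "a0"), ind("A", "a1"), ind("B", "b0")]
        ds = make_dataset(3, inds, length=30, seed=2)
        write_dataset(ds, tmp_path)
        back = load_dataset(tmp_path)
        assert back.locus_ids == ds.locus_ids
        assert back.individuals == ds.individuals
        for lid in ds.locus_ids:
            assert back.locus(lid).sequences == ds.locus(lid).sequences

    def test_parse_two_records(self, tmp_path):
        p = tmp_path / "locA.fasta"
        p.write_text(">spX|i1\nACGT\n>spY|i2\nACGA\n")
        aln = read_locus_fasta(p)
        assert aln.locus_id == "locA"
        assert len(aln.sequences) == 2
        assert aln.length == 4

    def test_ragged_alignment_rejected(self, tmp_path):
        p = tmp_path / "bad.fasta"
        p.write_text(">spX|i1\n" + "A" * 300 + "\n>spY|i2\n" + "A" * 299 + "\n")
        with pytest.raises(AlignmentError):
            read_locus_fasta(p)

    def test_header_without_separator_names_record(self, tmp_path):
        p = tmp_path / "bad2.fasta"
        p.write_text(">justonename\nACGT\n")
        with pytest.raises(FastaParseError, match="justonename"):
            read_locus_fasta(p)

    def test_empty_directory_rejected(self, tmp_path):
        with pytest.raises(BarcodeError):
            load_dataset(tmp_path)

    def test_duplicate_locus_id_rejected(self):
        a = ind("A", "x")
        l1 = LocusAlignment("same", {a: "ACGT"})
        l2 = LocusAlignment("same", {a: "AGGT"})
        with pytest.raises(BarcodeError, match="duplicate"):
            MultilocusDataset([l1, l2])


class TestMissingMask:
    def test_union_of_individuals_and_mask(self):
        inds = [ind("A", "a0"), ind("A", "a1"), ind("B", "b0"), ind("B", "b1")]
        missing = {("loc001", inds[2])}
        ds = make_dataset(3, inds, seed=3, missing=missing)
        assert ds.individuals == sorted(inds)
        assert not ds.is_present("loc001", inds[2])
        assert ds.is_present("loc000", inds[2])

    def test_filter_by_missing_keeps_complete_loci(self):
        inds = [ind("A", "a0"), ind("A", "a1"), ind("B", "b0")]
        missing = {("loc002", inds[1])}
        ds = make_dataset(5, inds, seed=4, missing=missing)
        kept = filter_by_missing(ds, inds)
        assert kept.locus_ids == ["loc000", "loc001", "loc003", "loc004"]

    def test_filter_matches_brute_force_on_random_mask(self):
        rng = np.random.default_rng(9)
        inds = [ind("A", f"a{i}") for i in range(4)]
        missing = {
            (f"loc{k:03d}", i)
            for k in range(12)
            for i in inds
            if rng.random() < 0.3
        }
        ds = make_dataset(12, inds, seed=9, missing=missing)
        subset = inds[:3]
        expected = [
            f"loc{k:03d}"
            for k in range(12)
            if all((f"loc{k:03d}", i) not in missing for i in subset)
        ]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert filter_by_missing(ds, subset).locus_ids == expected

    def test_no_complete_locus_warns_and_returns_empty(self):
        inds = [ind("A", "a0"), ind("A", "a1")]
        missing = {(f"loc{k:03d}", inds[k % 2]) for k in range(3)}
        ds = make_dataset(3, inds, seed=6, missing=missing)
        with pytest.warns(UserWarning, match="no locus"):
            out = filter_by_missing(ds, inds)
        assert len(out) == 0


class TestRankingAndPanel:
    def _toy(self):
        a, b = ind("A", "x"), ind("B", "y")
        # mean p-distances: hi=0.5, mid=0.25, zero=0.0
        loci = [
            LocusAlignment("mid", {a: "ACGT", b: "ACTT"}),
            LocusAlignment("zero", {a: "ACGT", b: "ACGT"}),
            LocusAlignment("hi", {a: "ACGT", b: "AGCT"}),
        ]
        return MultilocusDataset(loci)

    def test_hand_computed_order(self):
        ranking = rank_loci_by_divergence(self._toy())
        assert [lid for lid, _ in ranking] == ["hi", "mid", "zero"]
        assert ranking[0][1] == pytest.approx(0.5)
        assert ranking[-1][1] == pytest.approx(0.0)

    def test_identical_sequences_rank_last(self):
        ranking = rank_loci_by_divergence(self._toy())
        assert ranking[-1] == ("zero", 0.0)

    def test_order_invariant_to_input_permutation(self):
        ds = self._toy()
        perm = MultilocusDataset([ds.loci[2], ds.loci[0], ds.loci[1]])
        assert rank_loci_by_divergence(ds) == rank_loci_by_divergence(perm)

    def test_locus_with_single_individual_excluded_with_warning(self):
        a, b = ind("A", "x"), ind("B", "y")
        loci = [
            LocusAlignment("ok", {a: "ACGT", b: "ACTT"}),
            LocusAlignment("lonely", {a: "ACGT"}),
        ]
        ds = MultilocusDataset(loci)
        with pytest.warns(UserWarning, match="lonely"):
            ranking = rank_loci_by_divergence(ds)
        assert [lid for lid, _ in ranking] == ["ok"]

    def test_panel_selection_matches_brute_force(self):
        rng = np.random.default_rng(21)
        inds = [ind("A", f"a{i}") for i in range(3)] + [
            ind("B", f"b{i}") for i in range(3)
        ]
        missing = {
            (f"loc{k:03d}", i)
            for k in range(10)
            for i in inds
            if rng.random() < 0.25
        }
        ds = make_dataset(10, inds, seed=21, missing=missing, length=40)
        panel = select_panel(ds, n_low_missing=6, n_panel=3)
        # brute-force oracle: independent sort on (missing, -mean, id)
        from multibarcode.seqstore import locus_mean_distances

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            means = locus_mean_distances(ds)
        nmiss = ds.missing_counts()
        step1 = sorted(
            ds.locus_ids,
            key=lambda l: (nmiss[l], -means.get(l, float("-inf")), l),
        )[:6]
        step2 = sorted(
            step1, key=lambda l: (-means.get(l, float("-inf")), l)
        )[:3]
        assert panel == step2

    def test_panel_invariant_to_locus_order(self):
        inds = [ind("A", "x"), ind("B", "y")]
        ds = make_dataset(8, inds, seed=22, length=40)
        rev = MultilocusDataset(list(reversed(ds.loci)))
        assert select_panel(ds, 6, 4) == select_panel(rev, 6, 4)

    def test_insufficient_loci_error_names_counts(self):
        inds = [ind("A", "x"), ind("B", "y")]
        ds = make_dataset(4, inds, seed=23)
        with pytest.raises(BarcodeError, match="4 loci"):
            select_panel(ds, n_low_missing=6, n_panel=5)


class TestSampleLoci:
    def test_full_sample_and_seed_reproducibility(self):
        inds = [ind("A", "x"), ind("B", "y")]
        ds = make_dataset(6, inds, seed=1)
        assert sorted(sample_loci(ds, 6, seed=0)) == ds.locus_ids
        assert sample_loci(ds, 3, seed=42) == sample_loci(ds, 3, seed=42)
        with pytest.raises(BarcodeError):
            sample_loci(ds, 7, seed=0)

    def test_single_draw_frequencies_uniform(self):
        from scipy.stats import chisquare

        inds = [ind("A", "x"), ind("B", "y")]
        ds = make_dataset(8, inds, seed=2)
        counts = {lid: 0 for lid in ds.locus_ids}
        for s in range(10_000):
            counts[sample_loci(ds, 1, seed=s)[0]] += 1
        stat, p = chisquare(list(counts.values()))
        assert p > 1e-3
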