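"""Homogeneity statistics: chi-square, Z-tests, BH, letter groups."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportions_ztest

from spherical.align import AlignmentHit
from spherical.errors import SphericalError
from spherical.taxprofile import (
    UNCLASSIFIED,
    ProfileTable,
    bh_adjust,
    chi2_homogeneity,
    compare_iterations,
    contig_taxa_from_truth,
    profile_from_labels,
    two_prop_ztest,
)


def make_table(rows, index=None, columns=None):
    arr = np.asarray(rows)
    return ProfileTable(
        pd.DataFrame(
            arr,
            index=index or [f"it{i + 1}" for i in range(arr.shape[0])],
            columns=columns or [f"T{j}" for j in range(arr.shape[1])],
        )
    )


def hit(read_id, contig_id):
    return AlignmentHit(read_id=read_id, contig_id=contig_id, pos=0,
                        strand="+", mismatches=0, read_length=50)


class TestProfileConstruction:
    def test_empty_hits_give_zero_table(self):
        table = profile_from_labels({1: [], 2: []}, {})
        assert table.counts.values.sum() == 0

    def test_single_taxon_single_column(self):
        hits = {1: [hit("r1", "c1"), hit("r2", "c1")], 2: [hit("r3", "c2")]}
        table = profile_from_labels(hits, {"c1": "Firmicutes", "c2": "Firmicutes"})
        assert table.taxa == ["Firmicutes"]
        assert table.counts["Firmicutes"].tolist() == [2, 1]

    def test_unlabelled_contigs_are_unclassified(self):
        table = profile_from_labels({1: [hit("r1", "cX")]}, {})
        assert table.taxa == [UNCLASSIFIED]

    def test_row_sums_equal_hit_counts(self):
        hits = {
            1: [hit(f"r{i}", f"c{i % 3}") for i in range(30)],
            2: [hit(f"s{i}", f"c{i % 2}") for i in range(20)],
        }
        taxa = {"c0": "A", "c1": "B", "c2": "C"}
        table = profile_from_labels(hits, taxa)
        assert table.counts.sum(axis=1).tolist() == [30, 20]


class TestContigLabelling:
    def test_majority_vote(self):
        hits = [hit(f"r{i}", "c1") for i in range(10)]
        labels = {f"r{i}": ("A" if i < 9 else "B") for i in range(10)}
        assert contig_taxa_from_truth(hits, labels) == {"c1": "A"}

    def test_tie_breaks_lexicographically(self):
        hits = [hit(f"r{i}", "c1") for i in range(10)]
        labels = {f"r{i}": ("B" if i < 5 else "A") for i in range(10)}
        assert contig_taxa_from_truth(hits, labels) == {"c1": "A"}

    def test_contig_without_hits_absent(self):
        assert contig_taxa_from_truth([], {}) == {}

    def test_profile_matches_truth_tally_for_pure_contigs(self, small_truth):
        # contigs assembled from a labelled community are taxon-pure, so
        # the profile equals a direct read-truth tally
        from spherical.align import AlignParams, partition_reads
        from spherical.assemble import AssemblerParams, assemble

        reads = small_truth.reads[:8000]
        asm = assemble(reads, AssemblerParams(k=21, min_kmer_cov=2)).tag_iteration(1)
        hits, _ = partition_reads(reads, asm.contigs, AlignParams())
        truth = {r.id: r.taxon for r in reads}
        contig_taxa = contig_taxa_from_truth(hits, truth)
        table = profile_from_labels({1: hits}, contig_taxa)
        direct = {}
        for h in hits:
            direct[truth[h.read_id]] = direct.get(truth[h.read_id], 0) + 1
        profile_counts = table.counts.iloc[0].to_dict()
        # purity: at least 99% of reads land in their own genome's column
        agree = sum(min(direct.get(t, 0), c) for t, c in profile_counts.items())
        assert agree >= 0.99 * len(hits)


class TestChi2:
    def test_closed_form_example(self):
        res = chi2_homogeneity(make_table([[10, 20], [20, 10]]))
        assert res.statistic == pytest.approx(20 / 3, abs=1e-4)
        assert res.df == 1
        assert res.p_value == pytest.approx(0.00982, abs=1e-4)

    def test_identical_rows_statistic_zero(self):
        res = chi2_homogeneity(make_table([[5, 15, 30], [5, 15, 30]]))
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_matches_reference_on_random_tables(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            shape = (int(rng.integers(2, 6)), int(rng.integers(2, 6)))
            obs = rng.integers(1, 60, size=shape)
            mine = chi2_homogeneity(make_table(obs))
            ref = sps.chi2_contingency(obs, correction=False)
            assert mine.statistic == pytest.approx(ref.statistic, abs=1e-6)
            assert mine.p_value == pytest.approx(ref.pvalue, abs=1e-6)
            assert mine.df == ref.dof

    def test_zero_rows_dropped_then_degenerate_is_error(self):
        with pytest.raises(SphericalError):
            chi2_homogeneity(make_table([[0, 0], [1, 2]]))


class TestZTest:
    def test_closed_form_example(self):
        res = two_prop_ztest(30, 100, 10, 100)
        assert res.statistic == pytest.approx(3.5355, abs=1e-4)
        assert res.p_value == pytest.approx(4.07e-4, abs=1e-5)

    def test_equal_proportions_z_zero(self):
        res = two_prop_ztest(10, 100, 10, 100)
        assert res.statistic == 0.0 and res.p_value == pytest.approx(1.0)

    def test_sign_antisymmetry(self):
        a = two_prop_ztest(30, 100, 10, 100)
        b = two_prop_ztest(10, 100, 30, 100)
        assert a.statistic == pytest.approx(-b.statistic)
        assert a.p_value == pytest.approx(b.p_value)

    def test_degenerate_pooled_proportion(self):
        res = two_prop_ztest(0, 50, 0, 60)
        assert res.p_value == 1.0 and res.flag == "degenerate"

    def test_matches_reference_on_random_inputs(self):
        rng = np.random.default_rng(6)
        for _ in range(100):
            n1, n2 = int(rng.integers(10, 200)), int(rng.integers(10, 200))
            x1, x2 = int(rng.integers(1, n1)), int(rng.integers(1, n2))
            mine = two_prop_ztest(x1, n1, x2, n2)
            z, p = proportions_ztest([x1, x2], [n1, n2])
            assert mine.statistic == pytest.approx(z, abs=1e-6)
            assert mine.p_value == pytest.approx(p, abs=1e-6)


class TestBH:
    def test_stepup_example(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.3]).tolist() == [0.3]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=40))
    def test_matches_statsmodels_and_dominates_p(self, ps):
        q = bh_adjust(ps)
        ref = multipletests(ps, method="fdr_bh")[1]
        assert np.allclose(q, ref)
        assert (q >= np.asarray(ps) - 1e-12).all()

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(7)
        p = rng.random(25)
        perm = rng.permutation(25)
        assert np.allclose(bh_adjust(p)[perm], bh_adjust(p[perm]))


class TestCompareIterations:
    def test_homogeneous_single_letter_no_ztests(self):
        res = compare_iterations(make_table([[50, 50], [50, 50], [50, 50]]))
        assert set(res.letters.values()) == {"a"}
        assert len(res.ztests) == 0

    def test_shifted_taxon_detected_after_bh(self):
        res = compare_iterations(make_table([[100, 900], [300, 700]]))
        assert res.letters["it1"] != res.letters["it2"]
        sig = res.ztests[res.ztests.q < 0.05]
        assert "T0" in set(sig.taxon)

    def test_letter_grouping_relabel_invariance(self):
        rows = [[100, 900], [110, 890], [300, 700]]
        res1 = compare_iterations(make_table(rows, index=["a1", "a2", "a3"]))
        res2 = compare_iterations(make_table(rows, index=["b1", "b2", "b3"]))
        assert list(res1.letters.values()) == list(res2.letters.values())

    def test_tsv_roundtrip(self, tmp_path):
        table = make_table([[1, 2], [3, 4]])
        p = tmp_path / "prof.tsv"
        table.to_tsv(p)
        back = ProfileTable.from_tsv(p)
        assert (back.counts.values == table.counts.values).all()


def test_type_one_error_calibration():
    """Homogeneous multinomial draws: the chi-square homogeneity test
    rejects at alpha=0.05 in ~5% of replicates."""
    rng = np.random.default_rng(12345)
    probs = np.array([0.4, 0.25, 0.15, 0.1, 0.1])
    rejections = 0
    n_rep = 1000
    for _ in range(n_rep):
        rows = rng.multinomial(500, probs, size=4)
        res = chi2_homogeneity(make_table(rows))
        if res.p_value < 0.05:
            rejections += 1
    assert abs(rejections / n_rep - 0.05) <= 0.02
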