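import numpy as np
import pytest

from hapblup import (
    assign_diplotypes,
    em_haplotype_frequencies,
    filter_haplotypes_by_frequency,
)
from hapblup.datatypes import LDSubset, SubsetCatalog
from hapblup.errors import ValidationError
from hapblup.phasing import _compatible_pairs, haplotype_count_table, phase_subsets

from oracles import genotype_loglik, ml_haplotype_freqs


def catalog_from(haps, freqs, subset=None):
    haps = np.asarray(haps, np.int8)
    freqs = np.asarray(freqs, float)
    return SubsetCatalog(
        subset=subset, haplotypes=haps, frequencies=freqs,
        retained=np.ones(freqs.size, bool), loglik_trace=np.array([]),
        converged=True, n_iter=0,
    )


class TestEM:
    def test_unambiguous_homozygotes_give_count_frequencies(self):
        # 6 individuals, all homozygous at both SNPs: phase is certain
        g = np.array([[0, 0]] * 3 + [[2, 2]] * 2 + [[0, 2]] * 1)
        cat = em_haplotype_frequencies(g)
        freqs = dict(zip(cat.labels(), cat.frequencies))
        assert freqs == pytest.approx({"00": 6 / 12, "11": 4 / 12, "01": 2 / 12})

    def test_skewed_two_snp_case_matches_direct_ml(self):
        g = np.array([[0, 0]] * 9 + [[1, 1]] * 1)
        cat = em_haplotype_frequencies(g)
        haps, f_oracle, ll_oracle = ml_haplotype_freqs(g, seed=1)
        labels = {tuple(h): f for h, f in zip(haps, f_oracle)}
        for h, f in zip(cat.haplotypes, cat.frequencies):
            assert f == pytest.approx(labels[tuple(h)], abs=1e-3)
        ll_em = genotype_loglik(cat.frequencies, g, cat.haplotypes)
        assert ll_em == pytest.approx(ll_oracle, abs=1e-6)

    def test_all_double_heterozygotes_symmetric_fixed_point(self):
        """With only double heterozygotes the symmetric allele-product start
        (all four haplotypes at 0.25) is an EM stationary point: one E+M
        step reproduces it exactly."""
        g = np.array([[1, 1]] * 8)
        cat = em_haplotype_frequencies(g, init=np.full(4, 0.25), max_iter=1)
        assert np.allclose(cat.frequencies, 0.25)
        cat2 = em_haplotype_frequencies(g, init=np.full(4, 0.25))
        assert np.allclose(cat2.frequencies, 0.25)

    def test_loglik_trace_nondecreasing(self, rng):
        for _ in range(10):
            g = rng.integers(0, 3, size=(30, 3))
            cat = em_haplotype_frequencies(g)
            assert np.all(np.diff(cat.loglik_trace) >= -1e-8)

    def test_frequencies_sum_to_one(self, rng):
        for _ in range(10):
            g = rng.integers(0, 3, size=(25, 4))
            cat = em_haplotype_frequencies(g)
            assert cat.frequencies.sum() == pytest.approx(1.0, abs=1e-10)

    def test_subset_size_cap_enforced(self, rng):
        with pytest.raises(ValidationError, match="cap"):
            em_haplotype_frequencies(rng.integers(0, 3, size=(5, 13)))

    def test_bad_dosage_rejected(self):
        with pytest.raises(ValidationError):
            em_haplotype_frequencies(np.array([[0, 3]]))


class TestDiplotypes:
    def test_homozygote_gets_single_pair_posterior_one(self):
        cat = catalog_from([[0, 0], [1, 1]], [0.6, 0.4])
        out = assign_diplotypes(np.array([[0, 0], [2, 2]]), cat)
        assert out.pairs.tolist() == [[0, 0], [1, 1]]
        assert np.allclose(out.posterior, 1.0)
        assert not out.flagged.any()

    def test_double_heterozygote_posterior_arithmetic(self):
        # catalog order is lexicographic: 00, 01, 10, 11
        cat = catalog_from([[0, 0], [0, 1], [1, 0], [1, 1]], [0.4, 0.1, 0.1, 0.4])
        out = assign_diplotypes(np.array([[1, 1]]), cat)
        assert cat.labels()[out.pairs[0, 0]] == "00"
        assert cat.labels()[out.pairs[0, 1]] == "11"
        assert out.posterior[0] == pytest.approx(2 * 0.16 / (2 * 0.16 + 2 * 0.01))

    def test_exact_tie_broken_lexicographically(self):
        cat = catalog_from([[0, 0], [0, 1], [1, 0], [1, 1]], [0.25, 0.25, 0.25, 0.25])
        out = assign_diplotypes(np.array([[1, 1]]), cat)
        # (00,11) and (01,10) tie; lexicographically smallest pair wins
        assert (cat.labels()[out.pairs[0, 0]], cat.labels()[out.pairs[0, 1]]) == ("00", "11")

    def test_zero_mass_fallback_is_uniform_and_flagged(self):
        cat = catalog_from([[0, 0], [0, 1], [1, 0], [1, 1]], [0.5, 0.0, 0.0, 0.5])
        out = assign_diplotypes(np.array([[1, 0]]), cat)  # needs 00 with 10
        assert out.flagged[0]
        assert out.posterior[0] == pytest.approx(1.0)  # single compatible pair

    def test_assigned_pairs_reproduce_dosages(self, small_result):
        for cat, assign in zip(small_result.catalogs, small_result.assignments):
            g = small_result.dataset.dosages[:, cat.subset.members]
            recon = cat.haplotypes[assign.pairs[:, 0]] + cat.haplotypes[assign.pairs[:, 1]]
            assert np.array_equal(recon, g)

    def test_phase_recovery_on_simulated_truth(self, small_result):
        """High-posterior diplotype calls match the generator's true phase
        (as unordered allele-string pairs) in >95% of cases."""
        truth = small_result.truth
        total = matched = 0
        for cat, assign in zip(small_result.catalogs, small_result.assignments):
            members = cat.subset.members
            true_pairs = truth.haplotypes[:, :, members]
            called = cat.haplotypes[assign.pairs]
            confident = assign.posterior > 0.9
            for i in np.flatnonzero(confident):
                t = {true_pairs[i, 0].tobytes(), true_pairs[i, 1].tobytes()}
                c = {called[i, 0].tobytes(), called[i, 1].tobytes()}
                total += 1
                matched += t == c
        assert total > 100
        assert matched / total > 0.95


class TestFrequencyFilter:
    def test_threshold_boundary_and_flags(self):
        cat = catalog_from([[0, 0], [0, 1], [1, 1]], [0.009, 0.012, 0.979],
                           subset=LDSubset(chrom="1", members=np.array([0, 1])))
        filter_haplotypes_by_frequency([cat], 0.01)
        assert cat.retained.tolist() == [False, True, True]

    def test_zero_threshold_keeps_everything(self):
        cat = catalog_from([[0, 0], [1, 1]], [0.001, 0.999],
                           subset=LDSubset(chrom="1", members=np.array([0, 1])))
        filter_haplotypes_by_frequency([cat], 0.0)
        assert cat.retained.all()

    def test_count_table_layout(self):
        cats = [
            catalog_from([[0, 0], [1, 1]], [0.5, 0.5],
                         subset=LDSubset(chrom="1", members=np.array([0, 1]))),
            catalog_from([[0, 0, 0], [1, 1, 1]], [0.995, 0.005],
                         subset=LDSubset(chrom="2", members=np.array([2, 3, 4]))),
        ]
        table = filter_haplotypes_by_frequency(cats, 0.01)
        row1 = table[(table["chrom"] == "1") & (table["length"] == 2)].iloc[0]
        row2 = table[(table["chrom"] == "2") & (table["length"] == 3)].iloc[0]
        assert (row1["n_haplotypes"], row1["n_retained"]) == (2, 2)
        assert (row2["n_haplotypes"], row2["n_retained"]) == (2, 1)

    def test_empty_catalog_list_gives_empty_table(self):
        assert len(haplotype_count_table([])) == 0

    def test_planted_rare_haplotype_dropped_in_most_replicates(self):
        """A haplotype at true frequency 0.005 in n=2000 falls below the 1%
        filter in at least 95% of seeded replicates."""
        true_haps = np.array([[0, 0], [1, 1], [0, 1]], np.int8)
        true_freqs = np.array([0.795, 0.2, 0.005])
        dropped = 0
        n_rep = 100
        for rep in range(n_rep):
            rng = np.random.default_rng(900 + rep)
            draws = rng.choice(3, size=(2000, 2), p=true_freqs)
            genotypes = true_haps[draws[:, 0]] + true_haps[draws[:, 1]]
            cat = em_haplotype_frequencies(genotypes)
            filter_haplotypes_by_frequency([cat], 0.01)
            labels = cat.labels()
            dropped += ("01" not in labels) or (not cat.retained[labels.index("01")])
        assert dropped >= 95


def test_phase_subsets_runs_all_groups(small_result):
    assert len(small_result.catalogs) == len(small_result.subsets)
    for cat in small_result.catalogs:
        assert cat.converged
        # planted copy/complement blocks segregate exactly 2 haplotypes
        assert cat.n_haplotypes >= 2
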