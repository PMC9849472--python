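"""Diversity indices and neutrality tests against independent oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sympy.functions.combinatorial.numbers import stirling

from mtpopgen import coalsim, diversity
from mtpopgen.core import (
    PopulationDataset,
    RegionSet,
    VariantProfile,
    collapse_haplotypes,
)

RS = RegionSet(((1, 2450),))


def _ds(variant_sets, pop="p"):
    profiles = [
        VariantProfile(f"s{i}", frozenset(vs)) for i, vs in enumerate(variant_sets)
    ]
    return PopulationDataset(profiles, {p.sample_id: pop for p in profiles}, RS)


class TestGeneDiversity:
    def test_two_equal_haplotype_classes(self):
        H, se = diversity.gene_diversity([2, 2])
        assert H == pytest.approx(4 / 3 * 0.5)
        assert se > 0

    def test_single_haplotype_zero(self):
        H, _ = diversity.gene_diversity([5])
        assert H == 0.0

    def test_all_distinct_is_one(self):
        H, _ = diversity.gene_diversity([1] * 7)
        assert H == pytest.approx(1.0)

    def test_relabeling_invariance(self):
        assert diversity.gene_diversity([3, 1, 2]) == diversity.gene_diversity([1, 2, 3])

    def test_needs_two_samples(self):
        with pytest.raises(ValueError):
            diversity.gene_diversity([1])

    def test_variance_matches_brute_force_formula(self):
        counts = [4, 3, 2, 1]
        n = sum(counts)
        p = np.array(counts) / n
        s2, s3 = (p**2).sum(), (p**3).sum()
        V = 2 / (n * (n - 1)) * (2 * (n - 2) * (s3 - s2**2) + s2 - s2**2)
        _, se = diversity.gene_diversity(counts)
        assert se == pytest.approx(math.sqrt(V))


class TestNucleotideDiversity:
    def test_two_sequences_three_diffs(self):
        ds = _ds([set(), {(1, "T"), (2, "T"), (3, "T")}])
        pi, mnpd = diversity.nucleotide_diversity(ds)
        assert mnpd == pytest.approx(3.0)
        assert pi == pytest.approx(3 / 2450)

    def test_identical_sequences(self):
        ds = _ds([{(1, "T")}, {(1, "T")}])
        assert diversity.nucleotide_diversity(ds) == (0.0, 0.0)

    def test_three_sequences_hand_sum(self):
        # pairwise diffs {1, 2, 3} -> MNPd = 6/3 = 2
        ds = _ds([set(), {(1, "T")}, {(2, "T"), (3, "T")}])
        _, mnpd = diversity.nucleotide_diversity(ds)
        assert mnpd == pytest.approx(2.0)


class TestTajimasD:
    def test_derived_constants_example(self):
        assert diversity.tajimas_d(4, 3, 1.5) == pytest.approx(-0.7544510776, abs=1e-6)

    def test_zero_numerator(self):
        n, S = 10, 7
        a1 = sum(1 / i for i in range(1, n))
        assert diversity.tajimas_d(n, S, S / a1) == pytest.approx(0.0, abs=1e-12)

    def test_no_segregating_sites_is_na(self):
        assert math.isnan(diversity.tajimas_d(10, 0, 0.0))

    def test_sample_order_invariance_through_dataset(self, constant_dataset):
        ds = constant_dataset
        rev = PopulationDataset(
            list(reversed(ds.profiles)), ds.pop_of, ds.region_set
        )
        a = diversity.diversity_summary(ds, "pop1")
        b = diversity.diversity_summary(rev, "pop1")
        assert a.tajima_D == pytest.approx(b.tajima_D)
        assert a.fu_Fs == pytest.approx(b.fu_Fs)


class TestFusFs:
    def test_two_samples_theta_one(self):
        # P(K=2 | theta) = theta/(1+theta) = 0.5 -> Fs = 0
        assert diversity.fus_fs(2, 2, 1.0) == pytest.approx(0.0, abs=1e-12)

    def test_three_samples_ewens_hand_value(self):
        # S' = theta^3/(theta)_3 = 8/24 -> Fs = ln(1/2)
        assert diversity.fus_fs(3, 3, 2.0) == pytest.approx(math.log(0.5), abs=1e-12)

    def test_theta_zero_is_na(self):
        assert math.isnan(diversity.fus_fs(5, 1, 0.0))

    @pytest.mark.parametrize("n,k,theta", [(5, 3, 1.5), (6, 2, 0.7), (8, 5, 3.0)])
    def test_stirling_terms_match_sympy_exact(self, n, k, theta):
        rising = 1.0
        for i in range(n):
            rising *= theta + i
        sp = sum(
            int(stirling(n, j, kind=1, signed=False)) * theta**j for j in range(k, n + 1)
        ) / rising
        expected = math.log(sp / (1 - sp))
        assert diversity.fus_fs(n, k, theta) == pytest.approx(expected, rel=1e-9)

    def test_large_n_is_finite_and_stable(self):
        # up to the largest study-group size without overflow
        val = diversity.fus_fs(664, 375, 12.12)
        assert math.isfinite(val)

    @pytest.mark.parametrize("n,theta", [(5, 1.0), (6, 2.5)])
    def test_ewens_probability_vs_crp_simulation(self, n, theta, rng):
        """S' = P(K >= k) must match the empirical Ewens (Chinese-restaurant)
        distribution of the number of alleles within 3 Monte-Carlo SE."""
        reps = 100_000
        counts = np.zeros(n + 1)
        u = rng.random((reps, n - 1))
        k_draws = np.ones(reps, dtype=int)
        for i in range(1, n):
            new = u[:, i - 1] < theta / (theta + i)
            k_draws += new
        for k in range(1, n + 1):
            counts[k] = np.mean(k_draws >= k)
        for k in range(2, n + 1):
            fs = diversity.fus_fs(n, k, theta)
            sp = 1.0 / (1.0 + math.exp(-fs))
            p_emp = counts[k]
            se = math.sqrt(max(p_emp * (1 - p_emp), 1e-12) / reps)
            assert abs(sp - p_emp) < 3 * se + 1e-9


class TestNeutralitySigns:
    def test_constant_model_mean_D_near_zero(self):
        rng = np.random.Generator(np.random.PCG64(5150))
        model = coalsim.DemographicModel.constant(5.0)
        rs = RegionSet(((1, 2000),))
        ds_stats = []
        for _ in range(300):
            tree = coalsim.simulate_genealogy(50, model, rng)
            profiles = coalsim.drop_mutations(tree, rs, [1.0], rng)
            ds = PopulationDataset(
                profiles, {p.sample_id: "p" for p in profiles}, rs
            )
            _, mnpd = diversity.nucleotide_diversity(ds)
            S = diversity.polymorphic_sites(ds)
            D = diversity.tajimas_d(ds.n, S, mnpd)
            if math.isfinite(D):
                ds_stats.append(D)
        assert abs(np.mean(ds_stats)) < 0.15

    def test_expansion_pushes_D_and_Fs_negative(self):
        rng = np.random.Generator(np.random.PCG64(99))
        model = coalsim.DemographicModel.expansion(tau=8.0, theta0=0.5, theta1=500.0)
        rs = RegionSet(((1, 2000),))
        Ds, Fss = [], []
        for _ in range(80):
            tree = coalsim.simulate_genealogy(40, model, rng)
            profiles = coalsim.drop_mutations(tree, rs, [1.0], rng)
            ds = PopulationDataset(
                profiles, {p.sample_id: "p" for p in profiles}, rs
            )
            _, mnpd = diversity.nucleotide_diversity(ds)
            S = diversity.polymorphic_sites(ds)
            Ds.append(diversity.tajimas_d(ds.n, S, mnpd))
            k = len(collapse_haplotypes(ds))
            Fss.append(diversity.fus_fs(ds.n, k, mnpd))
        assert np.nanmean(Ds) < -0.5
        assert np.nanmean(Fss) < -2.0


class TestNeutralityPvalues:
    def test_extreme_observed_gives_small_p(self):
        # strongly expanded data against the constant-size null
        cfg = coalsim.SimConfig(
            n=40, seed=31,
            model=coalsim.DemographicModel.expansion(8.0, 0.2, 800.0),
        )
        ds, _ = coalsim.simulate_dataset(cfg)
        p_D, p_Fs = diversity.neutrality_pvalues(ds, reps=150, seed=1)
        assert p_Fs <= 0.05
        assert p_D <= 0.25  # D is the less powerful of the two

    def test_reps_floor_enforced(self, constant_dataset):
        with pytest.raises(ValueError):
            diversity.neutrality_pvalues(constant_dataset, reps=10, seed=0)


class TestSummaryTable:
    def test_table_shape_and_report_columns(self, three_pop_dataset):
        table = diversity.diversity_table(three_pop_dataset)
        assert set(table.index) == set(three_pop_dataset.populations)
        for col in ("n", "k", "k_over_n", "S", "H", "H_se", "pi", "MNPd",
                    "tajima_D", "fu_Fs"):
            assert col in table.columns
        assert (table["k"] <= table["n"]).all()
        assert ((table["H"] >= 0) & (table["H"] <= 1)).all()

    def test_all_distinct_group_has_k_over_n_one(self):
        ds = _ds([{(i + 1, "T")} for i in range(23)])
        s = diversity.diversity_summary(ds, "p")
        assert s.k == 23 and s.n == 23
        assert s.k / s.n == pytest.approx(1.0)

    def test_pi_equals_mnpd_over_length_without_missing(self, constant_dataset):
        s = diversity.diversity_summary(constant_dataset, "pop1")
        L = constant_dataset.region_set.total_length
        assert s.pi == pytest.approx(s.MNPd / L, rel=1e-9)
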