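"""AMOVA variance components, Rst, and permutation significance."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ystrpop as y
from ystrpop.haplotypes import Haplotype

from conftest import build_panel


# ---------------------------------------------------------------------------
# independent first-principles oracle
# ---------------------------------------------------------------------------

def bruteforce_rst(pop_alleles):
    """Variance components from explicit loops over per-sample allele lists.

    ``pop_alleles`` is a list of populations, each a list of samples, each a
    flat list of repeat values (copies expanded, ascending within locus).
    Implements the two-level AMOVA definitions directly, independently of
    the package's matrix code.
    """
    def d2(a, b):
        return sum((x - y) ** 2 for x, y in zip(a, b))

    all_samples = [s for pop in pop_alleles for s in pop]
    n_total = len(all_samples)
    n_pops = len(pop_alleles)
    ssd_total = 0.0
    for i in range(n_total):
        for j in range(i + 1, n_total):
            ssd_total += d2(all_samples[i], all_samples[j])
    ssd_total /= n_total
    ssd_within = 0.0
    for pop in pop_alleles:
        acc = 0.0
        for i in range(len(pop)):
            for j in range(i + 1, len(pop)):
                acc += d2(pop[i], pop[j])
        ssd_within += acc / len(pop)
    ssd_among = ssd_total - ssd_within
    ms_among = ssd_among / (n_pops - 1)
    ms_within = ssd_within / (n_total - n_pops)
    sizes = [len(p) for p in pop_alleles]
    n_c = (n_total - sum(s * s for s in sizes) / n_total) / (n_pops - 1)
    sigma_a = (ms_among - ms_within) / n_c
    sigma_w = ms_within
    if sigma_a + sigma_w == 0:
        return sigma_a, sigma_w, 0.0
    return sigma_a, sigma_w, sigma_a / (sigma_a + sigma_w)


def panel_from_alleles(pop_alleles, n_loci):
    loci = [y.LocusSpec(f"L{i}") for i in range(n_loci)]
    rows = []
    for p, pop in enumerate(pop_alleles):
        for s, vals in enumerate(pop):
            rows.append((
                f"P{p}S{s}", f"P{p}",
                {f"L{i}": (float(v),) for i, v in enumerate(vals)},
            ))
    return build_panel(loci, rows), [f"P{p}" for p in range(len(pop_alleles))]


# ---------------------------------------------------------------------------
# molecular distance
# ---------------------------------------------------------------------------

class TestSquaredDistance:
    def test_identical_haplotypes_zero(self):
        h = Haplotype({"DYS19": (14.0,), "DYS385": (13.0, 14.0)})
        loci = [y.LocusSpec("DYS19"), y.LocusSpec("DYS385", copy_number=2)]
        assert y.haplotype_squared_distance(h, h, loci) == 0.0

    def test_two_single_copy_loci(self):
        loci = [y.LocusSpec("DYS19"), y.LocusSpec("DYS390")]
        h1 = Haplotype({"DYS19": (14.0,), "DYS390": (24.0,)})
        h2 = Haplotype({"DYS19": (15.0,), "DYS390": (22.0,)})
        assert y.haplotype_squared_distance(h1, h2, loci) == 5.0

    def test_multicopy_sorted_pairing(self):
        loci = [y.LocusSpec("DYS385", copy_number=2)]
        h1 = Haplotype({"DYS385": (17.0, 13.0)})  # stored sorted
        h2 = Haplotype({"DYS385": (18.0, 14.0)})
        assert y.haplotype_squared_distance(h1, h2, loci) == 2.0

    def test_copy_count_mismatch_skips_locus(self):
        loci = [y.LocusSpec("DYF387S1", copy_number=2, variable_copy=True),
                y.LocusSpec("DYS19")]
        h1 = Haplotype({"DYF387S1": (36.0, 38.0, 39.0), "DYS19": (14.0,)})
        h2 = Haplotype({"DYF387S1": (36.0, 38.0), "DYS19": (16.0,)})
        skipped = []
        assert y.haplotype_squared_distance(h1, h2, loci, skipped) == 4.0
        assert skipped == ["DYF387S1"]

    def test_microvariants_use_literal_values(self):
        loci = [y.LocusSpec("DYS458")]
        h1 = Haplotype({"DYS458": (17.2,)})
        h2 = Haplotype({"DYS458": (17.0,)})
        assert y.haplotype_squared_distance(h1, h2, loci) == pytest.approx(0.04)


# ---------------------------------------------------------------------------
# variance components
# ---------------------------------------------------------------------------

class TestAmovaPair:
    def test_worked_four_sample_instance(self):
        panel, pops = panel_from_alleles([[[10], [10]], [[12], [14]]], 1)
        res = y.amova_pair(panel, *pops, "all")
        assert res.sigma_a == pytest.approx(4.0, abs=1e-12)
        assert res.sigma_w == pytest.approx(1.0, abs=1e-12)
        assert res.rst == pytest.approx(0.8, abs=1e-12)

    def test_identical_population_multisets_clamp_to_zero(self):
        panel, pops = panel_from_alleles(
            [[[10], [12], [13]], [[10], [12], [13]]], 1
        )
        res = y.amova_pair(panel, *pops, "all")
        assert res.sigma_a <= 0
        assert res.rst_clamped == 0.0

    def test_monomorphic_distinct_populations_rst_one(self):
        panel, pops = panel_from_alleles([[[10], [10]], [[14], [14]]], 1)
        res = y.amova_pair(panel, *pops, "all")
        assert res.rst == pytest.approx(1.0)

    def test_no_variation_is_degenerate_zero(self):
        panel, pops = panel_from_alleles([[[10], [10]], [[10], [10]]], 1)
        res = y.amova_pair(panel, *pops, "all")
        assert res.degenerate and res.rst == 0.0

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_pops = int(rng.integers(2, 4))
        n_loci = int(rng.integers(1, 5))
        sizes = rng.integers(2, 5, n_pops)
        while sizes.sum() > 12:
            sizes = rng.integers(2, 5, n_pops)
        pops = [
            [list(rng.integers(8, 17, n_loci)) for _ in range(s)]
            for s in sizes
        ]
        panel, labels = panel_from_alleles(pops, n_loci)
        res = y.amova(panel, labels, "all")
        sa, sw, rst = bruteforce_rst(pops)
        assert res.sigma_a == pytest.approx(sa, abs=1e-9)
        assert res.sigma_w == pytest.approx(sw, abs=1e-9)
        assert res.rst == pytest.approx(rst, abs=1e-9)

    @given(shift=st.integers(min_value=-5, max_value=9))
    @settings(derandomize=True, max_examples=15)
    def test_rst_invariant_under_allele_translation(self, shift):
        base = [[[10, 20], [11, 22], [12, 21]], [[14, 25], [15, 24], [13, 23]]]
        shifted = [
            [[v + shift for v in s] for s in pop] for pop in base
        ]
        p1, l1 = panel_from_alleles(base, 2)
        p2, l2 = panel_from_alleles(shifted, 2)
        r1 = y.amova(p1, l1, "all")
        r2 = y.amova(p2, l2, "all")
        assert r1.rst == pytest.approx(r2.rst, abs=1e-12)

    def test_requires_two_samples_per_population(self):
        panel, pops = panel_from_alleles([[[10]], [[12], [14]]], 1)
        with pytest.raises(ValueError, match="at least 2"):
            y.amova_pair(panel, *pops, "all")


class TestPairwiseMatrix:
    def test_identical_populations_all_zero(self):
        base = [[[10], [12], [14]]] * 3
        panel, _ = panel_from_alleles(base, 1)
        dm, details = y.pairwise_rst_matrix(panel, "all")
        assert np.allclose(dm.values, 0.0)
        assert (dm.raw <= 1e-12).all()

    def test_symmetric_zero_diagonal_on_simulated_panel(self):
        panel = y.simulate_panel(
            y.SimConfig(n_pops=3, pop_size=40, sample_size=15,
                        split_generations=80, seed=9)
        )
        dm, _ = y.pairwise_rst_matrix(panel)
        assert np.allclose(dm.values, dm.values.T)
        assert np.allclose(np.diag(dm.values), 0.0)
        assert (dm.values >= 0).all()

    def test_default_subset_restricts_loci(self):
        panel = y.simulate_panel(
            y.SimConfig(n_pops=2, pop_size=20, sample_size=8,
                        split_generations=20, seed=4)
        )
        res = y.amova_pair(panel, "P1", "P2")  # default: yfiler_plus
        assert set(res.loci_used) <= y.YFILER_PLUS_LOCI
        assert "DYS645" not in res.loci_used
        res_single = y.amova_pair(panel, "P1", "P2", include_multicopy=False)
        assert "DYS385" not in res_single.loci_used


class TestPermutation:
    def test_monomorphic_distinct_pops_minimum_p(self):
        pops = [[[10]] * 10, [[14]] * 10]
        panel, labels = panel_from_alleles(pops, 1)
        p = y.rst_permutation_pvalue(panel, *labels, "all", n_perm=999, seed=1)
        assert p == pytest.approx(1 / 1000)

    def test_fixed_seed_reproducible(self):
        panel = y.simulate_panel(
            y.SimConfig(n_pops=2, pop_size=30, sample_size=12,
                        split_generations=30, seed=2)
        )
        p1 = y.rst_permutation_pvalue(panel, "P1", "P2", n_perm=99, seed=42)
        p2 = y.rst_permutation_pvalue(panel, "P1", "P2", n_perm=99, seed=42)
        assert p1 == p2

    def test_null_pvalues_approximately_uniform(self):
        """KS distance of permutation p-values from uniform under random
        label splits of one population stays below 0.1."""
        from scipy import stats

        rng = np.random.default_rng(0)
        loci = [y.LocusSpec(f"L{i}") for i in range(4)]
        keys = y.distinct_haplotype_keys(20, loci)
        pvals = []
        for _ in range(200):
            counts = {k: int(c) for k, c in
                      zip(keys, rng.integers(1, 6, len(keys)))}
            spec = y.FrequencySpectrum("haplotype", counts)
            panel = y.sample_from_spectra(
                {"A": spec}, loci, mode="multinomial", sample_size=24,
                seed=int(rng.integers(2**31)),
            )
            # random relabel of one population into two groups of 12
            order = rng.permutation(24)
            for pos, s_idx in enumerate(order):
                panel.samples[s_idx].population = "G1" if pos < 12 else "G2"
            pvals.append(
                y.rst_permutation_pvalue(panel, "G1", "G2", "all",
                                         n_perm=199,
                                         seed=int(rng.integers(2**31)))
            )
        ks = stats.kstest(pvals, "uniform").statistic
        assert ks < 0.1
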