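"""Forward-simulation module: rescaling, meiosis, drift, pruning."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats

from qtlcross.genome import (
    GenomeSpec,
    InvalidPlanError,
    InvalidScalingError,
    pig_demography_plan,
    rescale_plan,
)
from qtlcross.popgen import breed_fst
from qtlcross.simulate import (
    HaplotypePopulation,
    gamete_from_haplotypes,
    prune_fixed_sites,
    run_demography,
    wright_fisher_generation,
)

from conftest import make_synthetic_breed, toy_plan


class TestRescaling:
    def test_identity_at_lambda_one(self):
        plan = pig_demography_plan()
        assert rescale_plan(plan, 1.0) is plan

    def test_lambda_ten_arithmetic(self):
        plan = rescale_plan(pig_demography_plan(), 10.0)
        anc = plan.epochs["ANC"][0]
        assert (anc.start, anc.end, anc.ne) == (0, 640, 350)
        spec = GenomeSpec().rescaled(10.0)
        assert spec.mutations_per_chrom_per_meiosis == pytest.approx(20.0)
        # drift intensity of the ancestral epoch preserved up to rounding
        full = pig_demography_plan().epochs["ANC"][0]
        assert (anc.end - anc.start) / (2 * anc.ne) == pytest.approx(
            (full.end - full.start) / (2 * full.ne), rel=0.02)

    def test_collapsing_scale_rejected(self):
        with pytest.raises(InvalidScalingError):
            rescale_plan(pig_demography_plan(), 1e5)
        with pytest.raises(InvalidScalingError):
            rescale_plan(pig_demography_plan(), -1.0)

    def test_fst_distribution_invariant_to_rescaling(self):
        """Population-genetic rescaling preserves the F_ST distribution."""
        spec1 = GenomeSpec(n_chromosomes=2, mutations_per_chrom_per_meiosis=1.0)
        plan1 = toy_plan()
        plan2 = rescale_plan(plan1, 2.0)
        spec2 = spec1.rescaled(2.0)
        vals1, vals2 = [], []
        for s in range(10):
            p1 = run_demography(plan1, spec1, seed=1000 + s)
            p2 = run_demography(plan2, spec2, seed=2000 + s)
            r = np.random.default_rng(s)
            vals1.append(breed_fst(p1["EU1"], p1["EU2"], rng=r))
            vals2.append(breed_fst(p2["EU1"], p2["EU2"], rng=r))
        stat = stats.mannwhitneyu(vals1, vals2)
        assert stat.pvalue > 0.01


class TestMeiosis:
    @pytest.mark.parametrize("d", [0.01, 0.1, 0.5])
    def test_haldane_recombination_fraction(self, d):
        """Empirical two-locus recombination matches 0.5 (1 - exp(-2d))."""
        spec = GenomeSpec(n_chromosomes=1,
                          mutations_per_chrom_per_meiosis=0.0)
        pos = [np.array([0.2, 0.2 + d])]
        ha = [np.array([1, 1], dtype=np.uint8)]
        hb = [np.array([0, 0], dtype=np.uint8)]
        rng = np.random.default_rng(5)
        n = 100_000
        rec = 0
        for _ in range(n):
            g, _m = gamete_from_haplotypes(pos, ha, hb, spec, rng)
            if g[0][0] != g[0][1]:
                rec += 1
        expect = 0.5 * (1.0 - np.exp(-2.0 * d))
        se = np.sqrt(expect * (1 - expect) / n)
        assert abs(rec / n - expect) < 3 * se

    def test_mean_new_mutations_per_gamete(self):
        """About two mutations per chromosome (20 per genome) per meiosis."""
        spec = GenomeSpec()  # 10 chromosomes, rate 2 per chromosome
        pos = [np.empty(0) for _ in range(10)]
        h0 = [np.empty(0, dtype=np.uint8) for _ in range(10)]
        rng = np.random.default_rng(6)
        n = 10_000
        total = 0
        for _ in range(n):
            _g, muts = gamete_from_haplotypes(pos, h0, h0, spec, rng)
            total += sum(len(m) for m in muts)
        mean = total / n
        se = np.sqrt(20.0 / n)  # Poisson(20) variance
        assert abs(mean - 20.0) < 3 * se

    def test_zero_length_chromosome_rejected(self):
        with pytest.raises(ValueError):
            GenomeSpec(chrom_length=0.0)


class TestWrightFisher:
    def test_drift_preserves_expected_frequency(self, rng):
        """The derived-allele frequency is a martingale under pure drift."""
        spec = GenomeSpec(n_chromosomes=1,
                          mutations_per_chrom_per_meiosis=0.0)
        n, f0, reps = 20, 0.3, 2000
        freqs = []
        base = HaplotypePopulation.from_haplotypes(
            [np.array([0.5])],
            [np.array([[1]] * int(2 * n * f0) + [[0]] * int(2 * n * (1 - f0)),
                      dtype=np.uint8)])
        for _ in range(reps):
            nxt = wright_fisher_generation(base, n, spec, rng)
            cnt = (nxt.derived_counts(0).sum() if nxt.n_variants else
                   (2 * n if len(nxt.fixed[0]) else 0))
            freqs.append(cnt / (2 * n))
        se = np.std(freqs, ddof=1) / np.sqrt(reps)
        assert abs(np.mean(freqs) - f0) < 3 * se

    def test_fixation_is_absorbing(self, rng):
        spec = GenomeSpec(n_chromosomes=1,
                          mutations_per_chrom_per_meiosis=0.0)
        pop = HaplotypePopulation.from_haplotypes(
            [np.array([0.3])], [np.ones((20, 1), dtype=np.uint8)])
        nxt = wright_fisher_generation(pop, 10, spec, rng)
        assert nxt.n_variants == 0
        assert list(nxt.fixed[0]) == [0.3]
        nxt2 = wright_fisher_generation(nxt, 10, spec, rng)
        assert list(nxt2.fixed[0]) == [0.3]

    def test_heterozygosity_decay(self, rng):
        """E[H_t] = H_0 (1 - 1/(2N))^t under drift without mutation."""
        spec = GenomeSpec(n_chromosomes=1,
                          mutations_per_chrom_per_meiosis=0.0)
        n, t, reps, m = 20, 10, 300, 30
        pos = np.sort(rng.random(m))
        h0 = (rng.random((2 * n, m)) < 0.5).astype(np.uint8)
        base = HaplotypePopulation.from_haplotypes([pos], [h0])
        f = base.allele_frequencies(0)
        h_start = float(np.mean(2 * f * (1 - f)))
        hs = []
        for _ in range(reps):
            pop = base
            for _g in range(t):
                pop = wright_fisher_generation(pop, n, spec, rng)
            if pop.n_variants:
                f = pop.allele_frequencies(0)
                het = 2 * f * (1 - f)
                # lost/fixed sites contribute zero heterozygosity
                hs.append(het.sum() / m)
            else:
                hs.append(0.0)
        expect = h_start * (1 - 1 / (2 * n)) ** t
        se = np.std(hs, ddof=1) / np.sqrt(reps)
        assert abs(np.mean(hs) - expect) < 3 * se

    def test_invalid_next_size(self, rng):
        spec = GenomeSpec(n_chromosomes=1)
        pop = HaplotypePopulation.from_haplotypes(
            [np.array([0.5])], [np.eye(8, 1, dtype=np.uint8) * 0 + 1])
        pop.haplotypes[0][2:] = 0
        with pytest.raises(ValueError):
            wright_fisher_generation(pop, 1, spec, rng)


class TestPrune:
    def test_identity_when_all_segregating(self, rng):
        pop = make_synthetic_breed(rng, lineage="X", n=10, n_chrom=2,
                                   m_per_chrom=15)
        out = prune_fixed_sites(pop)
        assert out.n_variants == pop.n_variants
        for c in range(2):
            np.testing.assert_array_equal(out.positions[c], pop.positions[c])
            np.testing.assert_array_equal(out.haplotype_matrix(c),
                                          pop.haplotype_matrix(c))

    def test_fixed_and_lost_removed(self):
        pos = [np.array([0.1, 0.2, 0.3])]
        h = np.zeros((6, 3), dtype=np.uint8)
        h[:, 0] = 1          # fixed
        h[0, 2] = 1          # segregating
        out = prune_fixed_sites(
            HaplotypePopulation.from_haplotypes(pos, [h]))
        assert out.n_variants == 1
        assert out.positions[0][0] == pytest.approx(0.3)
        assert list(out.fixed[0]) == [pytest.approx(0.1)]

    def test_frequencies_unchanged_for_survivors(self, rng):
        pop = make_synthetic_breed(rng, lineage="X", n=12, n_chrom=1,
                                   m_per_chrom=40)
        before = dict(zip(pop.positions[0], pop.allele_frequencies(0)))
        out = prune_fixed_sites(pop)
        after = dict(zip(out.positions[0], out.allele_frequencies(0)))
        for p, f in after.items():
            assert before[p] == pytest.approx(f)


class TestDemography:
    def test_monomorphic_without_mutation(self):
        spec = GenomeSpec(n_chromosomes=2,
                          mutations_per_chrom_per_meiosis=0.0)
        pops = run_demography(toy_plan(), spec, seed=4)
        for pop in pops.values():
            assert pop.n_variants == 0

    def test_terminal_sizes_and_generation(self):
        spec = GenomeSpec(n_chromosomes=2,
                          mutations_per_chrom_per_meiosis=0.5)
        pops = run_demography(toy_plan(), spec, seed=4)
        assert set(pops) == {"EU1", "EU2", "AS"}
        assert pops["EU1"].n_individuals == 20
        assert pops["AS"].n_individuals == 30
        assert all(p.generation == 80 for p in pops.values())

    def test_determinism(self):
        spec = GenomeSpec(n_chromosomes=2,
                          mutations_per_chrom_per_meiosis=1.0)
        a = run_demography(toy_plan(), spec, seed=9)
        b = run_demography(toy_plan(), spec, seed=9)
        for k in a:
            for c in range(2):
                np.testing.assert_array_equal(a[k].positions[c],
                                              b[k].positions[c])
                np.testing.assert_array_equal(a[k].haplotypes[c],
                                              b[k].haplotypes[c])

    def test_infinite_sites_positions_unique(self):
        spec = GenomeSpec(n_chromosomes=2,
                          mutations_per_chrom_per_meiosis=1.0)
        pops = run_demography(toy_plan(), spec, seed=12)
        for pop in pops.values():
            for c in range(2):
                allp = np.concatenate([pop.positions[c], pop.fixed[c]])
                assert len(np.unique(allp)) == len(allp)

    def test_close_split_low_differentiation(self):
        """Breeds split near the final generation barely differentiate,
        in contrast to the deep Asian/European split."""
        spec = GenomeSpec(n_chromosomes=2,
                          mutations_per_chrom_per_meiosis=1.0)
        rng = np.random.default_rng(3)
        close, far = [], []
        for s in range(5):
            pops = run_demography(toy_plan(), spec, seed=100 + s)
            close.append(breed_fst(pops["EU1"], pops["EU2"], rng=rng))
            far.append(breed_fst(pops["AS"], pops["EU2"], rng=rng))
        assert np.mean(close) < np.mean(far)
        assert all(c < f for c, f in zip(close, far))
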