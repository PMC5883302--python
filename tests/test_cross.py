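"""F2 cross construction: founder sampling, F1/F2 structure, pooling."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats

from qtlcross.cross import (
    CrossDesign,
    DesignViolationError,
    IncompatibleDatasetsError,
    InsufficientFoundersError,
    make_f1,
    make_f2,
    make_purebred,
    pool_crosses,
    sample_founders,
)

from conftest import DIVERGENT_SITE, make_synthetic_breed


class TestDesign:
    def test_f2_count(self):
        d = CrossDesign("EU1", "EU2", 2, 10)
        assert d.n_f2 == 500

    def test_inconsistent_f1_quota_rejected(self):
        with pytest.raises(DesignViolationError):
            CrossDesign("EU1", "EU2", 2, 10, n_f1_males=10, n_f1_females=40)


class TestFounders:
    def test_small_and_large_counts(self, synth_breeds, rng):
        sire, dam = synth_breeds
        for n_s, n_d in ((2, 10), (10, 50)):
            f0 = sample_founders(sire, dam,
                                 CrossDesign("EU1", "EU2", n_s, n_d), rng)
            assert len(f0.sire_ids) == n_s and len(f0.dam_ids) == n_d
            assert len(np.unique(f0.sire_indices)) == n_s
            assert len(np.unique(f0.dam_indices)) == n_d

    def test_insufficient_founders(self, synth_breeds, rng):
        sire, dam = synth_breeds
        with pytest.raises(InsufficientFoundersError):
            sample_founders(sire, dam, CrossDesign("EU1", "EU2", 200, 10), rng)

    def test_divergently_fixed_site_in_frame(self, synth_breeds, rng):
        sire, dam = synth_breeds
        f0 = sample_founders(sire, dam, CrossDesign("EU1", "EU2", 2, 10), rng)
        c, p = DIVERGENT_SITE
        j = np.searchsorted(f0.positions[c], p)
        assert f0.positions[c][j] == p
        col = f0.haplotypes[c][:, j]
        assert col[: 2 * 2].all() and not col[2 * 2:].any()


class TestF1:
    def test_composition_and_pedigree(self, synth_breeds, small_spec, rng):
        sire, dam = synth_breeds
        f0 = sample_founders(sire, dam, CrossDesign("EU1", "EU2", 2, 10), rng)
        f1 = make_f1(f0, small_spec, rng)
        assert len(f1.male_ids) == 10 and len(f1.female_ids) == 50
        ped = f1.pedigree.set_index("id")
        for fid in f1.male_ids + f1.female_ids:
            assert ped.loc[fid, "sire"] in f0.sire_ids
            assert ped.loc[fid, "dam"] in f0.dam_ids

    def test_all_heterozygous_at_divergent_site(self, synth_breeds,
                                                small_spec, rng):
        sire, dam = synth_breeds
        f0 = sample_founders(sire, dam, CrossDesign("EU1", "EU2", 2, 10), rng)
        f1 = make_f1(f0, small_spec, rng)
        c, p = DIVERGENT_SITE
        j = np.searchsorted(f1.positions[c], p)
        h = f1.haplotypes[c]
        genotypes = h[0::2, j] + h[1::2, j]
        assert (genotypes == 1).all()


class TestF2:
    def test_family_structure(self, synth_cross):
        ds = synth_cross
        assert ds.n_individuals == 500
        f2 = ds.pedigree[ds.pedigree.generation == "F2"]
        fam = f2.groupby(["sire", "dam"]).size()
        assert len(fam) == 50 and (fam == 10).all()
        half = f2.groupby("sire").size()
        assert len(half) == 10 and (half == 50).all()
        # each dam mated to exactly one sire
        assert (f2.groupby("dam")["sire"].nunique() == 1).all()

    def test_one_to_two_to_one_at_divergent_site(self, synth_cross):
        c, p = DIVERGENT_SITE
        doses = synth_cross.dose_at(c, p)
        counts = np.bincount(doses, minlength=3)
        chi = stats.chisquare(counts, f_exp=[125, 250, 125])
        assert chi.pvalue > 0.01

    def test_doses_valid(self, synth_cross):
        assert set(np.unique(synth_cross.genotypes)) <= {0, 1, 2}

    def test_wrong_f1_composition_rejected(self, synth_breeds, small_spec,
                                           rng):
        sire, dam = synth_breeds
        f0 = sample_founders(sire, dam, CrossDesign("EU1", "EU2", 2, 10), rng)
        f1 = make_f1(f0, small_spec, rng)
        f1.male_ids = f1.male_ids[:-1]
        with pytest.raises(DesignViolationError):
            make_f2(f1, small_spec, rng)


class TestPurebred:
    def test_sizes_and_pedigree(self, synth_breeds, small_spec, rng):
        _, dam = synth_breeds
        ds = make_purebred(dam, 200, small_spec, rng)
        assert ds.n_individuals == 200
        gens = ds.pedigree.generation.value_counts()
        assert gens["P1"] == 200 and gens["P2"] == 200

    def test_allele_frequencies_preserved(self, synth_breeds, small_spec,
                                          rng):
        """Two generations of drift leave frequencies regressing on the
        breed frequencies with slope about one."""
        _, dam = synth_breeds
        ds = make_purebred(dam, 300, small_spec, rng)
        breed_f = {}
        for c in range(dam.n_chromosomes):
            for p, f in zip(dam.positions[c], dam.allele_frequencies(c)):
                breed_f[(c, p)] = f
        pairs = [(breed_f[(c, p)],
                  ds.genotypes[:, j].mean() / 2)
                 for j, (c, p) in enumerate(zip(ds.chrom, ds.pos))
                 if (c, p) in breed_f]
        x, y = np.array(pairs).T
        slope = np.polyfit(x, y, 1)[0]
        assert slope == pytest.approx(1.0, abs=0.1)

    def test_zero_size_rejected(self, synth_breeds, small_spec, rng):
        _, dam = synth_breeds
        with pytest.raises(ValueError):
            make_purebred(dam, 0, small_spec, rng)


class TestPooling:
    def test_pooled_composition(self, synth_breeds, small_spec, rng):
        sire, dam = synth_breeds
        from qtlcross.cross import build_cross
        a = build_cross(sire, dam, CrossDesign("EU1", "EU2", 2, 10, name="a"),
                        small_spec, rng, replicate_key="k")
        b = build_cross(sire, dam, CrossDesign("EU1", "EU2", 2, 10, name="b"),
                        small_spec, rng, replicate_key="k")
        pooled = pool_crosses(a, b)
        assert pooled.n_individuals == 1000
        assert set(pooled.cross_labels) == {"a", "b"}

    def test_self_pool_rejected(self, synth_cross):
        with pytest.raises(IncompatibleDatasetsError):
            pool_crosses(synth_cross, synth_cross)

    def test_replicate_mismatch_rejected(self, synth_breeds, small_spec,
                                         rng):
        sire, dam = synth_breeds
        from qtlcross.cross import build_cross
        a = build_cross(sire, dam, CrossDesign("EU1", "EU2", 2, 10, name="a"),
                        small_spec, rng, replicate_key="k1")
        b = build_cross(sire, dam, CrossDesign("EU1", "EU2", 2, 10, name="b"),
                        small_spec, rng, replicate_key="k2")
        with pytest.raises(IncompatibleDatasetsError):
            pool_crosses(a, b)

    def test_private_variant_constant_in_other_cross(self, synth_breeds,
                                                     small_spec, rng):
        sire, dam = synth_breeds
        from qtlcross.cross import build_cross
        a = build_cross(sire, dam, CrossDesign("EU1", "EU2", 2, 10, name="a"),
                        small_spec, rng, replicate_key="k")
        b = build_cross(sire, dam, CrossDesign("EU1", "EU2", 2, 10, name="b"),
                        small_spec, rng, replicate_key="k")
        pooled = pool_crosses(a, b)
        b_sites = set(zip(b.chrom, b.pos))
        rows_a = np.isin(pooled.ids, a.ids)
        checked = 0
        for j, (c, p) in enumerate(zip(pooled.chrom, pooled.pos)):
            if (c, p) in b_sites and (int(c), float(p)) not in set(
                    zip(a.chrom, a.pos)):
                col = pooled.genotypes[rows_a, j]
                assert len(np.unique(col)) == 1 and col[0] in (0, 2)
                checked += 1
        assert checked > 0
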