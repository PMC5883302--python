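"""Shared fixtures: synthetic founder breeds, a reference F2 cross, and a
toy demography small enough for repeated end-to-end runs."""

from __future__ import annotations

import numpy as np
import pytest

from qtlcross.cross import CrossDesign, build_cross
from qtlcross.genome import DemographyPlan, Epoch, GenomeSpec, Split
from qtlcross.simulate import HaplotypePopulation


def make_synthetic_breed(rng, *, lineage, n=60, n_chrom=3, m_per_chrom=40,
                         fixed=None):
    """A random Hardy-Weinberg breed population with optional fixed sites.

    Synthetic stand-in for a simulated breed: positions uniform, derived
    allele frequencies uniform on (0.05, 0.95), haplotypes independent.
    """
    positions, haps = [], []
    for c in range(n_chrom):
        pos = np.sort(rng.random(m_per_chrom))
        freq = rng.uniform(0.05, 0.95, m_per_chrom)
        h = (rng.random((2 * n, m_per_chrom)) < freq).astype(np.uint8)
        # keep every site segregating
        h[0] = 1
        h[1] = 0
        positions.append(pos)
        haps.append(h)
    pop = HaplotypePopulation.from_haplotypes(positions, haps,
                                              lineage=lineage)
    if fixed:
        pop.fixed = [np.asarray(fixed.get(c, []), dtype=np.float64)
                     for c in range(n_chrom)]
    return pop


DIVERGENT_SITE = (0, 0.5)  # fixed-derived in the sire breed, absent in dams


@pytest.fixture(scope="session")
def synth_breeds():
    rng = np.random.default_rng(11)
    sire = make_synthetic_breed(rng, lineage="EU1",
                                fixed={0: [DIVERGENT_SITE[1]]})
    dam = make_synthetic_breed(rng, lineage="EU2", fixed={1: [0.77]})
    return sire, dam


@pytest.fixture(scope="session")
def small_spec():
    return GenomeSpec(n_chromosomes=3, chrom_length=1.0,
                      mutations_per_chrom_per_meiosis=0.2)


@pytest.fixture(scope="session")
def synth_cross(synth_breeds, small_spec):
    sire, dam = synth_breeds
    rng = np.random.default_rng(42)
    design = CrossDesign("EU1", "EU2", 2, 10, name="EU1xEU2_small")
    return build_cross(sire, dam, design, small_spec, rng,
                       replicate_key="synth")


def toy_plan() -> DemographyPlan:
    """Miniature three-breed history with the reference lineage names."""
    return DemographyPlan(
        epochs={
            "ANC": (Epoch(0, 40, 40),),
            "EUR": (Epoch(40, 70, 30),),
            "AS": (Epoch(40, 80, 30),),
            "EU1": (Epoch(70, 80, 20),),
            "EU2": (Epoch(70, 80, 20),),
        },
        splits=(Split(40, "ANC", ("EUR", "AS")),
                Split(70, "EUR", ("EU1", "EU2"))),
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
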