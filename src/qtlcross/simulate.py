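"""Forward simulation of the breed history: populations, meiosis, drift.

The central container is :class:`HaplotypePopulation`: ``2N`` haplotypes of
``N`` diploid individuals over a shared per-chromosome variant table.
Variant positions are continuous genetic positions in Morgans
(infinite-sites model); the derived allele is coded 1, the ancestral 0.
Variants fixed for the derived allele within the population's lineage are
kept in a separate ``fixed`` position list per chromosome: they are not
variable within the lineage but may be variable between lineages (the
divergently fixed variants that matter for crosses between breeds).

Recombination follows the Haldane mapping function: crossover counts are
Poisson with mean equal to the chromosome length in Morgans, crossover
positions are uniform, and there is no interference.  New mutations arise
at Poisson(``mutations_per_chrom_per_meiosis``) uniform positions per
chromosome per transmitted gamete.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _engine
from .genome import DemographyPlan, GenomeSpec, InvalidPlanError


@dataclass
class HaplotypePopulation:
    """A diploid population as packed haplotypes over a variant table."""

    lineage: str
    generation: int
    n_individuals: int
    positions: list[np.ndarray]  # per chromosome, sorted, Morgans
    haplotypes: list[np.ndarray]  # per chromosome, packed uint64 (2N, words)
    fixed: list[np.ndarray]  # per chromosome, derived-fixed positions

    # -- construction ------------------------------------------------------
    @classmethod
    def from_haplotypes(cls, positions, haplotype_matrices, *, lineage="pop",
                        generation=0, fixed=None):
        """Build from per-chromosome 0/1 haplotype matrices (2N x M)."""
        n_hap = haplotype_matrices[0].shape[0]
        if n_hap % 2 != 0:
            raise ValueError("haplotype count must be 2 x N")
        pos_out, mat_out = [], []
        for p, h in zip(positions, haplotype_matrices):
            p = np.asarray(p, dtype=np.float64)
            h = np.asarray(h, dtype=np.uint8)
            if h.shape != (n_hap, len(p)):
                raise ValueError("haplotype matrix shape mismatch")
            order = np.argsort(p, kind="stable")
            pos_out.append(p[order])
            mat_out.append(_engine.pack_bits(h[:, order]))
        if fixed is None:
            fixed = [np.empty(0, dtype=np.float64) for _ in positions]
        return cls(lineage, generation, n_hap // 2, pos_out, mat_out,
                   [np.asarray(f, dtype=np.float64) for f in fixed])

    @classmethod
    def _from_state(cls, state: _engine.PopState, lineage: str):
        return cls(
            lineage=lineage,
            generation=state.generation,
            n_individuals=state.n,
            positions=[ch.pos for ch in state.chroms],
            haplotypes=[ch.mat for ch in state.chroms],
            fixed=[ch.fixed for ch in state.chroms],
        )

    def _to_state(self) -> _engine.PopState:
        n_hap = 2 * self.n_individuals
        chroms = []
        for p, m, f in zip(self.positions, self.haplotypes, self.fixed):
            chroms.append(
                _engine.ChromState(
                    pos=p,
                    mat=m,
                    yflat=np.empty(0, dtype=np.float64),
                    yindptr=np.zeros(n_hap + 1, dtype=np.int64),
                    fixed=f,
                )
            )
        return _engine.PopState(n=self.n_individuals,
                                generation=self.generation, chroms=chroms)

    # -- accessors ---------------------------------------------------------
    @property
    def n_chromosomes(self) -> int:
        return len(self.positions)

    @property
    def n_variants(self) -> int:
        return int(sum(len(p) for p in self.positions))

    def haplotype_matrix(self, chrom: int, rows=None) -> np.ndarray:
        """Unpacked 0/1 haplotype matrix of one chromosome."""
        return _engine.unpack_bits(self.haplotypes[chrom],
                                   len(self.positions[chrom]), rows)

    def derived_counts(self, chrom: int) -> np.ndarray:
        return self.haplotype_matrix(chrom).sum(axis=0, dtype=np.int64)

    def allele_frequencies(self, chrom: int) -> np.ndarray:
        return self.derived_counts(chrom) / (2 * self.n_individuals)

    def variant_table(self) -> pd.DataFrame:
        chrom = np.repeat(np.arange(self.n_chromosomes),
                          [len(p) for p in self.positions])
        return pd.DataFrame({
            "chrom": chrom,
            "pos": np.concatenate(self.positions) if self.n_variants else
                   np.empty(0, dtype=np.float64),
        })

    def sample_individuals(self, indices) -> "HaplotypePopulation":
        """Subset of individuals over the same variant table (no pruning)."""
        indices = np.asarray(indices, dtype=np.int64)
        rows = np.empty(2 * len(indices), dtype=np.int64)
        rows[0::2] = 2 * indices
        rows[1::2] = 2 * indices + 1
        return HaplotypePopulation(
            lineage=self.lineage,
            generation=self.generation,
            n_individuals=len(indices),
            positions=[p.copy() for p in self.positions],
            haplotypes=[m[rows] for m in self.haplotypes],
            fixed=[f.copy() for f in self.fixed],
        )


# ---------------------------------------------------------------------------
# meiosis (reference, single gamete)
# ---------------------------------------------------------------------------

def gamete_from_haplotypes(positions, hap_a, hap_b, spec: GenomeSpec, rng):
    """Form one gamete from a pair of haplotypes (reference implementation).

    ``positions``/``hap_a``/``hap_b`` are per-chromosome lists (positions
    sorted; haplotypes 0/1 arrays).  Returns ``(gamete, new_mutations)``:
    the gamete's alleles at the existing variant positions and the
    positions of its new mutations, per chromosome.

    Crossovers: Poisson(chromosome length) uniform positions (Haldane, no
    interference); the gamete alternates parental segments starting from a
    randomly chosen haplotype.  New mutations: Poisson(mutation rate)
    uniform positions, derived allele carried by the gamete only.
    """
    out, muts = [], []
    for pos, ha, hb in zip(positions, hap_a, hap_b):
        n_xo = rng.poisson(spec.chrom_length)
        xo = np.sort(rng.random(n_xo) * spec.chrom_length)
        first, second = (ha, hb) if rng.integers(0, 2) == 0 else (hb, ha)
        g = np.array(first, dtype=np.uint8, copy=True)
        cols = np.searchsorted(pos, xo)
        for t in range(0, n_xo, 2):
            lo = cols[t]
            hi = cols[t + 1] if t + 1 < n_xo else len(pos)
            g[lo:hi] = second[lo:hi]
        n_mut = rng.poisson(spec.mutations_per_chrom_per_meiosis)
        muts.append(np.sort(rng.random(n_mut) * spec.chrom_length))
        out.append(g)
    return out, muts


def meiosis(pop: HaplotypePopulation, individual: int, spec: GenomeSpec, rng):
    """One meiosis of ``individual`` of ``pop`` (see gamete_from_haplotypes)."""
    hap_a = [pop.haplotype_matrix(c, [2 * individual])[0]
             for c in range(pop.n_chromosomes)]
    hap_b = [pop.haplotype_matrix(c, [2 * individual + 1])[0]
             for c in range(pop.n_chromosomes)]
    return gamete_from_haplotypes(pop.positions, hap_a, hap_b, spec, rng)


# ---------------------------------------------------------------------------
# population-level operations
# ---------------------------------------------------------------------------

def wright_fisher_generation(pop: HaplotypePopulation, next_ne: int,
                             spec: GenomeSpec, rng, *,
                             allow_selfing: bool = True) -> HaplotypePopulation:
    """One Wright-Fisher generation of ``next_ne`` diploid offspring.

    Each offspring's two parents are drawn uniformly with replacement from
    the current generation (monoecious random mating; selfing allowed by
    default and switchable); each parent contributes one recombinant,
    mutated gamete.  The returned population is consolidated: all variant
    columns segregating, fixed variants moved to the ``fixed`` lists.
    """
    if next_ne < 2:
        raise ValueError("next_Ne must be >= 2")
    if pop.n_individuals < 2:
        raise ValueError("population must have >= 2 individuals")
    state = pop._to_state()
    state = _engine.advance(state, next_ne, spec, rng,
                            allow_selfing=allow_selfing)
    _engine.consolidate(state)
    return HaplotypePopulation._from_state(state, pop.lineage)


def prune_fixed_sites(pop: HaplotypePopulation) -> HaplotypePopulation:
    """Remove variants with derived count 0 or 2N from the variant table.

    Fixed (count 2N) positions are appended to the population's ``fixed``
    lists; lost positions are dropped.  Genotype content at the surviving
    (segregating) sites is unchanged.
    """
    state = pop._to_state()
    _engine.consolidate(state)
    out = HaplotypePopulation._from_state(state, pop.lineage)
    out.generation = pop.generation
    return out


def run_demography(plan: DemographyPlan, spec: GenomeSpec, seed, *,
                   allow_selfing: bool = True,
                   consolidate_every: int = 50) -> dict[str, HaplotypePopulation]:
    """Simulate the full demographic plan from a monomorphic root.

    Returns the terminal-lineage populations at the final generation of the
    plan.  At each split the child lineages are initialised by independent
    Wright-Fisher sampling from the parent's last generation and evolve
    independently afterwards, each on its own random stream (so lineage
    simulation order cannot change the result).  Fixed and lost variants
    are pruned every ``consolidate_every`` generations.
    """
    root_ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    names = sorted(plan.epochs)
    streams = dict(zip(names, root_ss.spawn(len(names))))
    final = plan.final_generation
    out: dict[str, HaplotypePopulation] = {}

    def ne_next(lineage: str, g_next: int) -> int:
        # size of the generation produced at g_next within this lineage;
        # the state at the plan's final generation uses the last epoch's Ne
        if g_next < plan.epochs[lineage][-1].end:
            return plan.ne_at(lineage, g_next)
        return plan.epochs[lineage][-1].ne

    def simulate(lineage: str, state: _engine.PopState, rng) -> None:
        split = plan.split_of(lineage)
        # a parent lineage stops one generation before its split: the split
        # generation itself is produced independently by each child
        stop = split.generation - 1 if split is not None else final
        while state.generation < stop:
            g_next = state.generation + 1
            state = _engine.advance(state, ne_next(lineage, g_next),
                                    spec, rng, allow_selfing=allow_selfing)
            if state.gens_since_consolidation >= consolidate_every:
                _engine.consolidate(state)
        if split is None:
            _engine.consolidate(state)
            out[lineage] = HaplotypePopulation._from_state(state, lineage)
            return
        for child in split.children:
            child_rng = np.random.Generator(np.random.PCG64(streams[child]))
            child_state = _engine.advance(
                state, plan.ne_at(child, split.generation), spec, child_rng,
                allow_selfing=allow_selfing)
            simulate(child, child_state, child_rng)

    root = plan.root
    first_ne = plan.epochs[root][0].ne
    simulate(root, _engine.PopState.monomorphic(first_ne, spec.n_chromosomes),
             np.random.Generator(np.random.PCG64(streams[root])))
    missing = set(plan.terminal_lineages) - set(out)
    if missing:
        raise InvalidPlanError(f"lineages not simulated: {sorted(missing)}")
    return out
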