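"""Population-genetic statistics: allele frequencies, MAF filters,
Weir-Cockerham F_ST and genomic relationship matrices (with LOCO support).

All functions operate on derived-allele dose matrices (individuals x
variants, values 0/1/2) unless stated otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class UndefinedFstError(ValueError):
    """No polymorphic variant available for the F_ST estimator."""


class EmptyGrmError(ValueError):
    """All variants excluded from the GRM."""


def allele_frequencies(doses: np.ndarray) -> np.ndarray:
    """Derived-allele frequency per variant: sum(doses) / 2n."""
    doses = np.asarray(doses)
    if doses.shape[0] == 0:
        raise ValueError("empty dataset")
    return doses.sum(axis=0, dtype=np.float64) / (2.0 * doses.shape[0])


def maf_filter(freqs: np.ndarray, threshold: float = 0.05, *,
               strict: bool = False) -> np.ndarray:
    """Boolean mask of variants passing a minor-allele-frequency filter.

    The default keeps variants with ``min(f, 1-f) >= threshold`` (variants
    with MAF *below* the threshold are removed); ``strict=True`` demands
    ``MAF > threshold``.
    """
    if not 0.0 <= threshold <= 0.5:
        raise ValueError("threshold must be in [0, 0.5]")
    maf = np.minimum(freqs, 1.0 - freqs)
    return maf > threshold if strict else maf >= threshold


# ---------------------------------------------------------------------------
# Weir-Cockerham F_ST (two populations)
# ---------------------------------------------------------------------------

def _wc_components(doses1: np.ndarray, doses2: np.ndarray):
    """Per-locus variance components (a, b, c) of the Weir-Cockerham
    theta estimator for two populations, from genotype dose matrices."""
    n1, n2 = doses1.shape[0], doses2.shape[0]
    if n1 < 2 or n2 < 2:
        raise ValueError("both samples need >= 2 individuals")
    r = 2.0
    p1 = doses1.sum(axis=0, dtype=np.float64) / (2 * n1)
    p2 = doses2.sum(axis=0, dtype=np.float64) / (2 * n2)
    h1 = (doses1 == 1).mean(axis=0)
    h2 = (doses2 == 1).mean(axis=0)
    n_bar = (n1 + n2) / r
    n_c = (r * n_bar - (n1 * n1 + n2 * n2) / (r * n_bar)) / (r - 1.0)
    p_bar = (n1 * p1 + n2 * p2) / (r * n_bar)
    s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1.0) * n_bar)
    h_bar = (n1 * h1 + n2 * h2) / (r * n_bar)
    a = (n_bar / n_c) * (
        s2 - (p_bar * (1 - p_bar) - s2 * (r - 1.0) / r - h_bar / 4.0)
        / (n_bar - 1.0)
    )
    b = (n_bar / (n_bar - 1.0)) * (
        p_bar * (1 - p_bar) - s2 * (r - 1.0) / r
        - h_bar * (2.0 * n_bar - 1.0) / (4.0 * n_bar)
    )
    c = h_bar / 2.0
    return a, b, c


def weir_cockerham_fst(doses1: np.ndarray, doses2: np.ndarray,
                       subset=None) -> float:
    """Multi-locus Weir-Cockerham theta between two samples.

    Loci are combined as the ratio of summed variance components (ratio of
    averages): ``theta = sum(a) / sum(a + b + c)``.  ``subset`` optionally
    restricts the columns used.  Raises :class:`UndefinedFstError` when no
    locus is polymorphic in either sample.
    """
    doses1 = np.asarray(doses1)
    doses2 = np.asarray(doses2)
    if subset is not None:
        doses1 = doses1[:, subset]
        doses2 = doses2[:, subset]
    a, b, c = _wc_components(doses1, doses2)
    denom = (a + b + c).sum()
    if denom == 0.0:
        raise UndefinedFstError("no polymorphic variant in either sample")
    return float(a.sum() / denom)


def union_segregating(pops) -> list[np.ndarray]:
    """Per-chromosome positions segregating in the union of populations.

    A position qualifies if its derived count over all haplotypes of all
    populations is strictly between 0 and the total: this includes
    variants fixed within one lineage but not in all of them (the
    divergently fixed variants that segregate in crosses between breeds).
    """
    pops = list(pops)
    out = []
    for c in range(pops[0].n_chromosomes):
        all_sites = np.unique(np.concatenate(
            [np.concatenate([p.positions[c], p.fixed[c]]) for p in pops]))
        fixed_everywhere = pops[0].fixed[c]
        for p in pops[1:]:
            fixed_everywhere = np.intersect1d(fixed_everywhere, p.fixed[c])
        out.append(np.setdiff1d(all_sites, fixed_everywhere))
    return out


def breed_pair_doses(pop1, pop2):
    """Joint dose matrices of two breed populations over their variant union.

    The union per chromosome covers segregating and lineage-fixed derived
    positions of both populations, excluding positions fixed in *both*
    (monomorphic across the pair).  A position absent from a population's
    tables carries the ancestral allele there (dose 0); a lineage-fixed
    position carries dose 2 for every individual of that population.
    """
    blocks1, blocks2 = [], []
    for c in range(pop1.n_chromosomes):
        fixed_both = np.intersect1d(pop1.fixed[c], pop2.fixed[c])
        union = np.union1d(
            np.union1d(pop1.positions[c], pop1.fixed[c]),
            np.union1d(pop2.positions[c], pop2.fixed[c]),
        )
        union = np.setdiff1d(union, fixed_both)
        for pop, blocks in ((pop1, blocks1), (pop2, blocks2)):
            d = np.zeros((pop.n_individuals, len(union)), dtype=np.int8)
            seg = pop.positions[c]
            idx = np.searchsorted(union, seg)
            present = (idx < len(union))
            present[present] &= union[idx[present]] == seg[present]
            if present.any():
                h = pop.haplotype_matrix(c)[:, present]
                d[:, idx[present]] = (h[0::2] + h[1::2]).astype(np.int8)
            fidx = np.searchsorted(union, pop.fixed[c])
            fpresent = (fidx < len(union))
            fpresent[fpresent] &= union[fidx[fpresent]] == pop.fixed[c][fpresent]
            d[:, fidx[fpresent]] = 2
            blocks.append(d)
    return np.concatenate(blocks1, axis=1), np.concatenate(blocks2, axis=1)


def breed_fst(pop1, pop2, *, n_sample: int = 100, rng=None) -> float:
    """Weir-Cockerham F_ST between two breeds from sampled individuals.

    ``n_sample`` individuals per breed (or the whole breed if smaller) are
    drawn at the final generation; all variants of the pair's union table
    enter the estimator.
    """
    if rng is None:
        rng = np.random.default_rng()
    s1 = pop1
    if pop1.n_individuals > n_sample:
        s1 = pop1.sample_individuals(
            rng.choice(pop1.n_individuals, n_sample, replace=False))
    s2 = pop2
    if pop2.n_individuals > n_sample:
        s2 = pop2.sample_individuals(
            rng.choice(pop2.n_individuals, n_sample, replace=False))
    d1, d2 = breed_pair_doses(s1, s2)
    return weir_cockerham_fst(d1, d2)


# ---------------------------------------------------------------------------
# genomic relationship matrices
# ---------------------------------------------------------------------------

@dataclass
class GrmMatrix:
    """Standardised-dose genomic relationship matrix.

    ``values = Z Z' / m`` with ``z_ik = (x_ik - 2 p_k) / sqrt(2 p_k (1 - p_k))``,
    allele frequencies taken from the analysed dataset itself.
    """

    values: np.ndarray
    m: int  # number of variants used
    excluded_chromosomes: tuple[int, ...] = ()


def _standardize(doses: np.ndarray, dtype=np.float64) -> np.ndarray:
    """(x - 2p) / sqrt(2p(1-p)) per column; monomorphic columns become 0."""
    p = allele_frequencies(doses)
    scale = np.sqrt(2.0 * p * (1.0 - p))
    inv = np.where(scale > 0.0, 1.0 / np.where(scale > 0.0, scale, 1.0), 0.0)
    z = np.asarray(doses).astype(dtype, copy=True)
    z -= (2.0 * p).astype(dtype)
    z *= inv.astype(dtype)
    return z


def compute_grm(doses: np.ndarray, chrom: np.ndarray | None = None,
                excluded_chromosomes=()) -> GrmMatrix:
    """GRM from a dose matrix, optionally excluding whole chromosomes.

    ``chrom`` gives each variant's chromosome index (required when
    ``excluded_chromosomes`` is non-empty); monomorphic variants contribute
    zero.  Raises :class:`EmptyGrmError` if no variant remains.
    """
    excluded = tuple(excluded_chromosomes)
    doses = np.asarray(doses, dtype=np.float64)
    if excluded:
        if chrom is None:
            raise ValueError("chromosome labels required for exclusions")
        mask = ~np.isin(chrom, excluded)
        doses = doses[:, mask]
    m = doses.shape[1]
    if m == 0:
        raise EmptyGrmError("all variants excluded from the GRM")
    z = _standardize(doses)
    return GrmMatrix(values=z @ z.T / m, m=m, excluded_chromosomes=excluded)


class LocoGrmFamily:
    """All leave-one-chromosome-out GRMs of a dataset, computed via
    per-chromosome cross-product blocks (each chromosome's block is built
    once and subtracted from the genome-wide total)."""

    def __init__(self, doses: np.ndarray, chrom: np.ndarray):
        self.chromosomes = np.unique(chrom)
        z = _standardize(doses, dtype=np.float32)
        n = z.shape[0]
        self._blocks = {}
        self._m = {}
        total = np.zeros((n, n), dtype=np.float64)
        for c in self.chromosomes:
            zc = z[:, chrom == c]
            block = (zc @ zc.T).astype(np.float64)
            self._blocks[int(c)] = block
            self._m[int(c)] = zc.shape[1]
            total += block
        self._total = total
        self.m_total = int(doses.shape[1])

    def leave_out(self, c: int) -> GrmMatrix:
        m = self.m_total - self._m.get(int(c), 0)
        if m == 0:
            raise EmptyGrmError("all variants excluded from the GRM")
        vals = (self._total - self._blocks.get(int(c), 0.0)) / m
        return GrmMatrix(values=vals, m=m, excluded_chromosomes=(int(c),))

    def full(self) -> GrmMatrix:
        return GrmMatrix(values=self._total / self.m_total, m=self.m_total)
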