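"""Construction of F2 crosses and the purebred experimental population.

An F2 cross is built in three steps mirroring the experimental design:
``sample_founders`` draws F0 sires from the paternal breed and F0 dams
from the maternal breed; ``make_f1`` mates them to produce exactly 10 male
and 50 female F1; ``make_f2`` mates each F1 male to five exclusive F1
females with a litter size of ten, yielding 500 F2 individuals with a full
three-generation pedigree.  ``make_purebred`` instead applies two
generations of random mating within one breed (the within-breed comparison
population), and ``pool_crosses`` merges two crosses from the same
simulation replicate onto the union of their variant tables.

Genotypes of the analysed individuals are stored as derived-allele doses
(0/1/2).  Variants that are monomorphic-derived among a cross's founders
(e.g. fixed in both founder breeds) are not columns of the genotype matrix
but are recorded as ``constant_derived`` positions so that pooling can
reconstruct doses of 2 for them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import GenomeSpec
from .simulate import HaplotypePopulation, gamete_from_haplotypes
from . import _engine


class InsufficientFoundersError(ValueError):
    """A breed population is smaller than the requested founder count."""


class DesignViolationError(ValueError):
    """F1/F2 composition does not match the cross design."""


class IncompatibleDatasetsError(ValueError):
    """Datasets from different simulation replicates cannot be pooled."""


@dataclass(frozen=True)
class CrossDesign:
    """Mating design of one F2 cross.

    The defaults encode the common scheme: F0 sires x dams produce 10 male
    and 50 female F1; each F1 male is mated to five exclusive F1 females
    with litter size ten, i.e. 500 F2.
    """

    sire_breed: str
    dam_breed: str
    n_sires: int
    n_dams: int
    n_f1_males: int = 10
    n_f1_females: int = 50
    dams_per_f1_sire: int = 5
    litter_size: int = 10
    name: str = ""

    def __post_init__(self) -> None:
        if self.n_f1_males * self.dams_per_f1_sire != self.n_f1_females:
            raise DesignViolationError(
                "n_f1_males x dams_per_f1_sire must equal n_f1_females")
        if min(self.n_sires, self.n_dams, self.litter_size) < 1:
            raise DesignViolationError("counts must be positive")

    @property
    def n_f2(self) -> int:
        return self.n_f1_males * self.dams_per_f1_sire * self.litter_size

    @property
    def label(self) -> str:
        return self.name or f"{self.sire_breed}x{self.dam_breed}"


@dataclass
class FounderSet:
    """F0 founders over the variant union of the two founder breeds."""

    design: CrossDesign
    replicate_key: str
    positions: list[np.ndarray]          # per chromosome, sorted
    haplotypes: list[np.ndarray]         # per chromosome uint8 (2*(ns+nd), M)
    constant_derived: list[np.ndarray]   # per chromosome positions, dose 2
    sire_ids: list[str]
    dam_ids: list[str]
    sire_indices: np.ndarray = None      # chosen indices within the sire pool
    dam_indices: np.ndarray = None

    @property
    def n_founders(self) -> int:
        return len(self.sire_ids) + len(self.dam_ids)


@dataclass
class F1Set:
    design: CrossDesign
    replicate_key: str
    positions: list[np.ndarray]
    haplotypes: list[np.ndarray]         # (2*60, M) after new-mutation columns
    constant_derived: list[np.ndarray]
    male_ids: list[str]
    female_ids: list[str]
    pedigree: pd.DataFrame


@dataclass
class CrossDataset:
    """Genotypes + pedigree + cross labels of an experimental population."""

    name: str
    chrom: np.ndarray                    # int16 per variant
    pos: np.ndarray                      # float64 per variant (Morgans)
    genotypes: np.ndarray                # int8 (n_individuals, n_variants)
    ids: np.ndarray                      # str per individual
    cross_labels: np.ndarray             # str per individual
    pedigree: pd.DataFrame               # id, sire, dam, generation
    constant_derived: list[np.ndarray]
    replicate_key: str

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_variants(self) -> int:
        return self.genotypes.shape[1]

    def subset(self, indices) -> "CrossDataset":
        indices = np.asarray(indices)
        return CrossDataset(
            name=self.name,
            chrom=self.chrom,
            pos=self.pos,
            genotypes=self.genotypes[indices],
            ids=self.ids[indices],
            cross_labels=self.cross_labels[indices],
            pedigree=self.pedigree,
            constant_derived=self.constant_derived,
            replicate_key=self.replicate_key,
        )

    def doses_at(self, chrom: np.ndarray, pos: np.ndarray) -> np.ndarray:
        """Dose matrix (n_individuals x len(pos)) at arbitrary sites.

        Sites absent from the variant table are constant: dose 2 if listed
        in ``constant_derived`` for their chromosome, else dose 0.
        """
        chrom = np.asarray(chrom)
        pos = np.asarray(pos)
        out = np.zeros((self.n_individuals, len(pos)), dtype=np.int8)
        for c in np.unique(chrom):
            sel = np.flatnonzero(chrom == c)
            table_cols = np.flatnonzero(self.chrom == c)
            table_pos = self.pos[table_cols]
            idx = np.searchsorted(table_pos, pos[sel])
            hit = idx < len(table_pos)
            hit[hit] &= table_pos[idx[hit]] == pos[sel][hit]
            out[:, sel[hit]] = self.genotypes[:, table_cols[idx[hit]]]
            miss = sel[~hit]
            if len(miss):
                const = np.isin(pos[miss], self.constant_derived[int(c)])
                out[:, miss[const]] = 2
        return out

    def dose_at(self, chrom: int, pos: float) -> np.ndarray:
        """Dose vector at one site, honouring constant-derived positions."""
        j = np.searchsorted(self.pos[self.chrom == chrom], pos)
        cols = np.flatnonzero(self.chrom == chrom)
        if j < len(cols) and self.pos[cols[j]] == pos:
            return self.genotypes[:, cols[j]].astype(np.int8)
        if pos in self.constant_derived[chrom]:
            return np.full(self.n_individuals, 2, dtype=np.int8)
        return np.zeros(self.n_individuals, dtype=np.int8)


# ---------------------------------------------------------------------------
# founder sampling
# ---------------------------------------------------------------------------

def founder_pool(pop: HaplotypePopulation, min_size: int, spec: GenomeSpec,
                 rng) -> HaplotypePopulation:
    """Breed population to sample founders from, grown if necessary.

    If the breed's final generation holds fewer than ``min_size``
    individuals (a desk-scale situation), one additional generation of
    random mating of ``min_size`` offspring is appended; otherwise the
    population is returned unchanged.
    """
    if pop.n_individuals >= min_size:
        return pop
    from .simulate import wright_fisher_generation
    return wright_fisher_generation(pop, min_size, spec, rng,
                                    allow_selfing=False)


def _pair_union(sire_pop: HaplotypePopulation, dam_pop: HaplotypePopulation):
    """Per-chromosome variant union of two breeds, with per-breed roles.

    Positions fixed in both lineages are excluded (monomorphic across the
    pair); they are returned separately as constant-derived positions.
    """
    unions, constants = [], []
    for c in range(sire_pop.n_chromosomes):
        fixed_both = np.intersect1d(sire_pop.fixed[c], dam_pop.fixed[c])
        union = np.union1d(
            np.union1d(sire_pop.positions[c], sire_pop.fixed[c]),
            np.union1d(dam_pop.positions[c], dam_pop.fixed[c]),
        )
        unions.append(np.setdiff1d(union, fixed_both))
        constants.append(fixed_both)
    return unions, constants


def _fill_founder_haps(dest, rows, pop, chrom, union):
    """Write one breed's founder haplotypes into the union-frame matrix."""
    seg = pop.positions[chrom]
    idx = np.searchsorted(union, seg)
    present = idx < len(union)
    present[present] &= union[idx[present]] == seg[present]
    if present.any():
        h = pop.haplotype_matrix(chrom)[:, present]
        dest[np.ix_(rows, idx[present])] = h
    fidx = np.searchsorted(union, pop.fixed[chrom])
    fpresent = fidx < len(union)
    fpresent[fpresent] &= union[fidx[fpresent]] == pop.fixed[chrom][fpresent]
    dest[np.ix_(rows, fidx[fpresent])] = 1


def sample_founders(sire_pop: HaplotypePopulation,
                    dam_pop: HaplotypePopulation,
                    design: CrossDesign, rng, *,
                    replicate_key: str = "rep0",
                    sire_candidates=None, dam_candidates=None) -> FounderSet:
    """Randomly select F0 founders (without replacement) from the breeds.

    ``sire_candidates``/``dam_candidates`` optionally restrict the eligible
    individuals (used to keep the shared founder breed's animals disjoint
    between crosses).
    """
    sire_candidates = (np.arange(sire_pop.n_individuals)
                       if sire_candidates is None else np.asarray(sire_candidates))
    dam_candidates = (np.arange(dam_pop.n_individuals)
                      if dam_candidates is None else np.asarray(dam_candidates))
    if len(sire_candidates) < design.n_sires:
        raise InsufficientFoundersError(
            f"{design.sire_breed}: need {design.n_sires} sires, "
            f"have {len(sire_candidates)} candidates")
    if len(dam_candidates) < design.n_dams:
        raise InsufficientFoundersError(
            f"{design.dam_breed}: need {design.n_dams} dams, "
            f"have {len(dam_candidates)} candidates")
    sires = rng.choice(sire_candidates, design.n_sires, replace=False)
    dams = rng.choice(dam_candidates, design.n_dams, replace=False)

    sire_sub = sire_pop.sample_individuals(sires)
    dam_sub = dam_pop.sample_individuals(dams)
    unions, constants = _pair_union(sire_pop, dam_pop)
    n_hap = 2 * (design.n_sires + design.n_dams)
    positions, haps, const_out = [], [], []
    for c, union in enumerate(unions):
        mat = np.zeros((n_hap, len(union)), dtype=np.uint8)
        _fill_founder_haps(mat, range(2 * design.n_sires), sire_sub, c, union)
        _fill_founder_haps(mat, range(2 * design.n_sires, n_hap), dam_sub, c, union)
        # restrict to sites informative among these founders
        s = mat.sum(axis=0, dtype=np.int64)
        seg = (s > 0) & (s < n_hap)
        const_out.append(np.sort(np.concatenate([constants[c], union[s == n_hap]])))
        positions.append(union[seg])
        haps.append(np.ascontiguousarray(mat[:, seg]))
    label = design.label
    return FounderSet(
        design=design,
        replicate_key=replicate_key,
        positions=positions,
        haplotypes=haps,
        constant_derived=const_out,
        sire_ids=[f"{replicate_key}:{label}:F0-S{i}" for i in range(design.n_sires)],
        dam_ids=[f"{replicate_key}:{label}:F0-D{i}" for i in range(design.n_dams)],
        sire_indices=np.sort(sires),
        dam_indices=np.sort(dams),
    )


# ---------------------------------------------------------------------------
# F1 and F2
# ---------------------------------------------------------------------------

def _haps_of(haplotypes, row):
    return [h[row] for h in haplotypes]


def _append_new_mutation_columns(positions, haps, new_muts):
    """Insert new-mutation columns (one carrier haplotype each), resorted."""
    n_hap = haps[0].shape[0]
    out_pos, out_haps = [], []
    for c, (pos, mat) in enumerate(zip(positions, haps)):
        muts = new_muts[c]
        if not muts:
            out_pos.append(pos)
            out_haps.append(mat)
            continue
        mpos = np.array([m[0] for m in muts])
        rows = np.array([m[1] for m in muts])
        extra = np.zeros((n_hap, len(muts)), dtype=np.uint8)
        extra[rows, np.arange(len(muts))] = 1
        allp = np.concatenate([pos, mpos])
        allm = np.concatenate([mat, extra], axis=1)
        order = np.argsort(allp, kind="stable")
        out_pos.append(allp[order])
        out_haps.append(np.ascontiguousarray(allm[:, order]))
    return out_pos, out_haps


def make_f1(founders: FounderSet, spec: GenomeSpec, rng) -> F1Set:
    """Mate F0 to produce exactly 10 male and 50 female F1.

    Dams are partitioned evenly across sires; dams contribute offspring in
    round-robin order until the F1 quota is met, and F1 sexes are assigned
    deterministically (every ``n_f1 / n_f1_males``-th offspring is male) so
    the composition is exact and males descend from different dams.
    """
    d = founders.design
    n_f1 = d.n_f1_males + d.n_f1_females
    per_sire = d.n_dams // d.n_sires
    sire_of_dam = np.repeat(np.arange(d.n_sires), per_sire)
    if len(sire_of_dam) < d.n_dams:  # uneven split: spread the remainder
        extra = np.arange(d.n_dams - len(sire_of_dam)) % d.n_sires
        sire_of_dam = np.concatenate([sire_of_dam, extra])

    pairs = [(int(sire_of_dam[i % d.n_dams]), i % d.n_dams)
             for i in range(n_f1)]
    male_every = n_f1 // d.n_f1_males
    sexes = ["M" if (k % male_every == 0 and k // male_every < d.n_f1_males)
             else "F" for k in range(n_f1)]
    if sexes.count("M") != d.n_f1_males:  # top up if quota not yet exact
        for k in range(n_f1):
            if sexes.count("M") == d.n_f1_males:
                break
            if sexes[k] == "F":
                sexes[k] = "M"

    n_hap_out = 2 * n_f1
    haps = [np.zeros((n_hap_out, len(p)), dtype=np.uint8)
            for p in founders.positions]
    new_muts = [[] for _ in founders.positions]
    n_s = d.n_sires
    records = []
    male_ids, female_ids = [], []
    key, label = founders.replicate_key, d.label
    im = iw = 0
    for k, (s, dam) in enumerate(pairs):
        dam_row = n_s + dam
        for parent_row, hap_idx in ((s, 2 * k), (dam_row, 2 * k + 1)):
            g, muts = gamete_from_haplotypes(
                founders.positions,
                _haps_of(founders.haplotypes, 2 * parent_row),
                _haps_of(founders.haplotypes, 2 * parent_row + 1),
                spec, rng)
            for c in range(len(g)):
                haps[c][hap_idx] = g[c]
                for mp in muts[c]:
                    new_muts[c].append((mp, hap_idx))
        if sexes[k] == "M":
            fid = f"{key}:{label}:F1-M{im}"
            im += 1
            male_ids.append(fid)
        else:
            fid = f"{key}:{label}:F1-F{iw}"
            iw += 1
            female_ids.append(fid)
        records.append((fid, founders.sire_ids[s], founders.dam_ids[dam], "F1"))

    positions, haps = _append_new_mutation_columns(founders.positions, haps,
                                                   new_muts)
    ped = pd.DataFrame(
        [(i, "", "", "F0") for i in founders.sire_ids + founders.dam_ids]
        + records,
        columns=["id", "sire", "dam", "generation"])
    # order haplotype rows male-first for make_f2 (stable with id lists)
    order = ([k for k in range(n_f1) if sexes[k] == "M"]
             + [k for k in range(n_f1) if sexes[k] == "F"])
    rows = np.empty(2 * n_f1, dtype=np.int64)
    rows[0::2] = [2 * k for k in order]
    rows[1::2] = [2 * k + 1 for k in order]
    haps = [h[rows] for h in haps]
    return F1Set(
        design=d,
        replicate_key=key,
        positions=positions,
        haplotypes=haps,
        constant_derived=founders.constant_derived,
        male_ids=male_ids,
        female_ids=female_ids,
        pedigree=ped,
    )


def make_f2(f1: F1Set, spec: GenomeSpec, rng) -> CrossDataset:
    """Mate each F1 male to five exclusive F1 females, litter size ten.

    Yields the designed F2 population (500 individuals in the default
    design): ``n_f1_males`` paternal half-sib groups of
    ``dams_per_f1_sire x litter_size`` and one full-sib family of
    ``litter_size`` per mating pair.
    """
    d = f1.design
    if len(f1.male_ids) != d.n_f1_males or len(f1.female_ids) != d.n_f1_females:
        raise DesignViolationError("F1 composition does not match the design")
    n_f2 = d.n_f2
    n_m = d.n_f1_males
    doses = [np.zeros((n_f2, len(p)), dtype=np.int8) for p in f1.positions]
    new_muts = [[] for _ in f1.positions]
    ids = []
    records = []
    key, label = f1.replicate_key, d.label
    i = 0
    for m in range(n_m):
        for w in range(d.dams_per_f1_sire):
            female = m * d.dams_per_f1_sire + w  # exclusive allocation
            f_row = 2 * (n_m + female)
            m_row = 2 * m
            for _ in range(d.litter_size):
                gs, ms = gamete_from_haplotypes(
                    f1.positions, _haps_of(f1.haplotypes, m_row),
                    _haps_of(f1.haplotypes, m_row + 1), spec, rng)
                gd, md = gamete_from_haplotypes(
                    f1.positions, _haps_of(f1.haplotypes, f_row),
                    _haps_of(f1.haplotypes, f_row + 1), spec, rng)
                for c in range(len(gs)):
                    doses[c][i] = gs[c] + gd[c]
                    for mp in list(ms[c]) + list(md[c]):
                        new_muts[c].append((mp, i))
                fid = f"{key}:{label}:F2-{i}"
                ids.append(fid)
                records.append((fid, f1.male_ids[m], f1.female_ids[female], "F2"))
                i += 1

    # append F2 new-mutation columns (dose 1 for the carrier)
    pos_out, dose_out = [], []
    for c, (pos, mat) in enumerate(zip(f1.positions, doses)):
        muts = new_muts[c]
        if muts:
            mpos = np.array([m[0] for m in muts])
            rows = np.array([m[1] for m in muts])
            extra = np.zeros((n_f2, len(muts)), dtype=np.int8)
            extra[rows, np.arange(len(muts))] = 1
            pos_c = np.concatenate([pos, mpos])
            mat = np.concatenate([mat, extra], axis=1)
            order = np.argsort(pos_c, kind="stable")
            pos_out.append(pos_c[order])
            dose_out.append(np.ascontiguousarray(mat[:, order]))
        else:
            pos_out.append(pos)
            dose_out.append(mat)

    chrom = np.concatenate([np.full(len(p), c, dtype=np.int16)
                            for c, p in enumerate(pos_out)])
    ped = pd.concat([f1.pedigree,
                     pd.DataFrame(records,
                                  columns=["id", "sire", "dam", "generation"])],
                    ignore_index=True)
    return CrossDataset(
        name=label,
        chrom=chrom,
        pos=np.concatenate(pos_out),
        genotypes=np.concatenate(dose_out, axis=1),
        ids=np.array(ids),
        cross_labels=np.full(n_f2, label),
        pedigree=ped,
        constant_derived=f1.constant_derived,
        replicate_key=key,
    )


def build_cross(sire_pop, dam_pop, design: CrossDesign, spec: GenomeSpec,
                rng, *, replicate_key="rep0",
                sire_candidates=None, dam_candidates=None) -> CrossDataset:
    """Convenience: sample founders, make F1, make F2."""
    f0 = sample_founders(sire_pop, dam_pop, design, rng,
                         replicate_key=replicate_key,
                         sire_candidates=sire_candidates,
                         dam_candidates=dam_candidates)
    f1 = make_f1(f0, spec, rng)
    return make_f2(f1, spec, rng)


# ---------------------------------------------------------------------------
# purebred population and pooling
# ---------------------------------------------------------------------------

def make_purebred(breed_pop: HaplotypePopulation, n_final: int,
                  spec: GenomeSpec, rng, *,
                  replicate_key: str = "rep0") -> CrossDataset:
    """Two generations of random mating within one breed.

    The analysed individuals are the ``n_final`` second-generation
    offspring (1000 in the reference design); the intermediate generation
    also has ``n_final`` individuals.  Selfing is disallowed in these two
    experimental generations.
    """
    if n_final < 2:
        raise ValueError("n_final must be >= 2")
    state = breed_pop._to_state()
    state, par1 = _engine.advance(state, n_final, spec, rng,
                                  allow_selfing=False, record_parents=True)
    state, par2 = _engine.advance(state, n_final, spec, rng,
                                  allow_selfing=False, record_parents=True)
    _engine.consolidate(state)
    label = f"{breed_pop.lineage}-purebred"
    key = replicate_key
    base_ids = [f"{key}:{label}:P0-{i}" for i in range(breed_pop.n_individuals)]
    g1_ids = [f"{key}:{label}:P1-{i}" for i in range(n_final)]
    g2_ids = [f"{key}:{label}:P2-{i}" for i in range(n_final)]
    records = [(i, "", "", "P0") for i in base_ids]
    records += [(g1_ids[i], base_ids[par1[i, 0]], base_ids[par1[i, 1]], "P1")
                for i in range(n_final)]
    records += [(g2_ids[i], g1_ids[par2[i, 0]], g1_ids[par2[i, 1]], "P2")
                for i in range(n_final)]

    doses, positions = [], []
    for c, ch in enumerate(state.chroms):
        h = _engine.unpack_bits(ch.mat, len(ch.pos))
        doses.append((h[0::2] + h[1::2]).astype(np.int8))
        positions.append(ch.pos)
    chrom = np.concatenate([np.full(len(p), c, dtype=np.int16)
                            for c, p in enumerate(positions)])
    return CrossDataset(
        name=label,
        chrom=chrom,
        pos=np.concatenate(positions),
        genotypes=np.concatenate(doses, axis=1),
        ids=np.array(g2_ids),
        cross_labels=np.full(n_final, label),
        pedigree=pd.DataFrame(records,
                              columns=["id", "sire", "dam", "generation"]),
        constant_derived=[ch.fixed for ch in state.chroms],
        replicate_key=key,
    )


def pool_crosses(a: CrossDataset, b: CrossDataset) -> CrossDataset:
    """Union of individuals over the union of variant tables.

    Both datasets must come from the same simulation replicate (shared
    variant coordinate system).  A variant absent from one dataset's table
    gets the founder-breed constant dose there: 2 if the position is in
    that dataset's constant-derived list, else 0.
    """
    if a.replicate_key != b.replicate_key:
        raise IncompatibleDatasetsError(
            "datasets from different replicates share no coordinate system")
    if set(a.ids) & set(b.ids):
        raise IncompatibleDatasetsError("duplicate individual IDs in pool")

    n_chrom = len(a.constant_derived)
    chroms, poss, blocks_a, blocks_b, const_out = [], [], [], [], []
    for c in range(n_chrom):
        pa, pb = a.pos[a.chrom == c], b.pos[b.chrom == c]
        ca, cb = a.constant_derived[c], b.constant_derived[c]
        const_both = np.intersect1d(ca, cb)
        union = np.union1d(np.union1d(pa, pb),
                           np.setdiff1d(np.union1d(ca, cb), const_both))
        union = np.setdiff1d(union, const_both)
        const_out.append(const_both)
        for ds, pos_c, const_c, blocks in ((a, pa, ca, blocks_a),
                                           (b, pb, cb, blocks_b)):
            d = np.zeros((ds.n_individuals, len(union)), dtype=np.int8)
            gsub = ds.genotypes[:, ds.chrom == c]
            idx = np.searchsorted(union, pos_c)
            present = idx < len(union)
            present[present] &= union[idx[present]] == pos_c[present]
            d[:, idx[present]] = gsub[:, present]
            fidx = np.searchsorted(union, const_c)
            fpresent = fidx < len(union)
            fpresent[fpresent] &= union[fidx[fpresent]] == const_c[fpresent]
            d[:, fidx[fpresent]] = 2
            blocks.append(d)
        chroms.append(np.full(len(union), c, dtype=np.int16))
        poss.append(union)

    return CrossDataset(
        name=f"{a.name}+{b.name}",
        chrom=np.concatenate(chroms),
        pos=np.concatenate(poss),
        genotypes=np.concatenate(
            [np.concatenate(blocks_a, axis=1),
             np.concatenate(blocks_b, axis=1)], axis=0),
        ids=np.concatenate([a.ids, b.ids]),
        cross_labels=np.concatenate([a.cross_labels, b.cross_labels]),
        pedigree=pd.concat([a.pedigree, b.pedigree], ignore_index=True),
        constant_derived=const_out,
        replicate_key=a.replicate_key,
    )
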