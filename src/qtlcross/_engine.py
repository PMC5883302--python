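"""Forward Wright-Fisher engine on packed-bit haplotype matrices.

Internal module.  Haplotypes are rows of per-chromosome bit matrices
(``uint64`` words, column ``k`` lives in word ``k >> 6`` at bit ``k & 63``,
LSB first).  Columns are variant sites sorted by genetic position, so a
crossover maps to a contiguous column range and gamete formation is a
handful of word-range copies per chromosome.

Mutations younger than the consolidation interval are kept out of the
matrix, in per-haplotype sorted position lists ("young" mutations), because
most of them are lost within a few generations.  Every consolidation the
surviving young mutations are merged into the matrix as new columns, lost
columns are removed and columns fixed within the lineage are moved to the
lineage's ``fixed`` position list (they are no longer variable within the
lineage but may still be variable between lineages).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

_ALL_ONES = np.uint64(0xFFFFFFFFFFFFFFFF)
_ONE = np.uint64(1)


@njit(cache=True)
def _bsearch(a, lo, hi, x):
    """First index in ``a[lo:hi]`` whose value is >= x."""
    while lo < hi:
        mid = (lo + hi) >> 1
        if a[mid] < x:
            lo = mid + 1
        else:
            hi = mid
    return lo


@njit(cache=True, inline="always")
def _masked_copy(out, g, src, row, lo, hi):
    """Overwrite bit-columns [lo, hi) of out[g] with those of src[row]."""
    if hi <= lo:
        return
    lo_w = lo >> 6
    hi_w = (hi - 1) >> 6
    for w in range(lo_w, hi_w + 1):
        mask = _ALL_ONES
        if w == lo_w:
            mask = mask << np.uint64(lo & 63)
        if w == hi_w:
            r = hi - (w << 6)
            if r < 64:
                mask = mask & ((_ONE << np.uint64(r)) - _ONE)
        out[g, w] = (out[g, w] & ~mask) | (src[row, w] & mask)


@njit(cache=True)
def _transmit(
    mat,
    n_cols,
    yflat,
    yindptr,
    par_rows,
    start,
    xo_cols,
    xo_pos,
    xo_indptr,
    new_pos,
    new_indptr,
    out_mat,
    oyflat,
    oyindptr,
    ybuf,
):
    """Form one generation of gametes for a single chromosome.

    Gamete ``g`` is built from parental haplotype rows ``par_rows[g]``:
    mature columns by word-range copies switching source at each crossover
    column, young mutations by merging the segment-restricted parental
    young lists with the gamete's new mutations (all position-sorted).
    """
    n_gam = out_mat.shape[0]
    n_words = out_mat.shape[1]
    wp = 0
    oyindptr[0] = 0
    for g in range(n_gam):
        ra = par_rows[g, start[g]]
        rb = par_rows[g, 1 - start[g]]
        for w in range(n_words):
            out_mat[g, w] = mat[ra, w]
        s = xo_indptr[g]
        e = xo_indptr[g + 1]
        nxo = e - s
        t = 0
        while t < nxo:  # odd-numbered segments come from rb
            lo = xo_cols[s + t]
            hi = xo_cols[s + t + 1] if t + 1 < nxo else n_cols
            _masked_copy(out_mat, g, mat, rb, lo, hi)
            t += 2
        # young mutations inherited segment-wise
        nb = 0
        prev = -1.0
        for t in range(nxo + 1):
            seg_end = xo_pos[s + t] if t < nxo else np.inf
            row = ra if (t & 1) == 0 else rb
            ylo = _bsearch(yflat, yindptr[row], yindptr[row + 1], prev)
            yhi = _bsearch(yflat, yindptr[row], yindptr[row + 1], seg_end)
            for k in range(ylo, yhi):
                ybuf[nb] = yflat[k]
                nb += 1
            prev = seg_end
        # merge inherited young with this gamete's new mutations
        ns = new_indptr[g]
        ne = new_indptr[g + 1]
        i = 0
        j = ns
        while i < nb and j < ne:
            if ybuf[i] <= new_pos[j]:
                oyflat[wp] = ybuf[i]
                i += 1
            else:
                oyflat[wp] = new_pos[j]
                j += 1
            wp += 1
        while i < nb:
            oyflat[wp] = ybuf[i]
            i += 1
            wp += 1
        while j < ne:
            oyflat[wp] = new_pos[j]
            j += 1
            wp += 1
        oyindptr[g + 1] = wp


def pack_bits(rows: np.ndarray) -> np.ndarray:
    """Pack a (n_hap, n_cols) 0/1 matrix into uint64 words (LSB first)."""
    rows = np.ascontiguousarray(rows, dtype=np.uint8)
    n = rows.shape[0]
    packed = np.packbits(rows, axis=1, bitorder="little")
    n_words = (rows.shape[1] + 63) // 64
    out = np.zeros((n, n_words * 8), dtype=np.uint8)
    out[:, : packed.shape[1]] = packed
    return out.view(np.uint64)


def unpack_bits(mat: np.ndarray, n_cols: int, rows=None) -> np.ndarray:
    """Unpack uint64 rows back to a (n_hap, n_cols) uint8 matrix."""
    src = mat if rows is None else mat[rows]
    if n_cols == 0:
        return np.zeros((src.shape[0], 0), dtype=np.uint8)
    b = np.unpackbits(src.view(np.uint8), axis=1, bitorder="little")
    return b[:, :n_cols]


@dataclass
class ChromState:
    """Engine state of one chromosome of one population."""

    pos: np.ndarray  # float64 (n_cols,), sorted mature positions
    mat: np.ndarray  # uint64 (2N, n_words)
    yflat: np.ndarray  # float64, young positions, sorted per haplotype
    yindptr: np.ndarray  # int64 (2N+1,)
    fixed: np.ndarray  # float64, positions fixed (derived) in this lineage

    @classmethod
    def empty(cls, n_hap: int) -> "ChromState":
        return cls(
            pos=np.empty(0, dtype=np.float64),
            mat=np.zeros((n_hap, 0), dtype=np.uint64),
            yflat=np.empty(0, dtype=np.float64),
            yindptr=np.zeros(n_hap + 1, dtype=np.int64),
            fixed=np.empty(0, dtype=np.float64),
        )


@dataclass
class PopState:
    """Engine state of one population (all chromosomes)."""

    n: int  # diploid individuals
    generation: int
    chroms: list[ChromState]
    gens_since_consolidation: int = 0

    @classmethod
    def monomorphic(cls, n: int, n_chromosomes: int) -> "PopState":
        return cls(
            n=n,
            generation=0,
            chroms=[ChromState.empty(2 * n) for _ in range(n_chromosomes)],
        )


def _ragged_sorted_uniform(rng, counts: np.ndarray, scale: float):
    """Draw ``counts[g]`` uniforms on [0, scale) per cell, sorted within cells."""
    tot = int(counts.sum())
    indptr = np.zeros(len(counts) + 1, dtype=np.int64)
    np.cumsum(counts, out=indptr[1:])
    if tot == 0:
        return np.empty(0, dtype=np.float64), indptr
    owner = np.repeat(np.arange(len(counts)), counts)
    u = rng.random(tot)
    order = np.lexsort((u, owner))
    return u[order] * scale, indptr


def advance(state: PopState, n_next: int, spec, rng, *, allow_selfing=True,
            record_parents=False):
    """One Wright-Fisher generation: ``n_next`` offspring from ``state``.

    Each offspring draws two parents uniformly (with replacement) from the
    current generation and receives one recombinant, mutated gamete from
    each.  Returns the new :class:`PopState` (and the parent index array if
    ``record_parents``).
    """
    n = state.n
    if n < 1 or n_next < 1:
        raise ValueError("population sizes must be >= 1")
    n_gam = 2 * n_next
    parents = rng.integers(0, n, size=(n_next, 2))
    if not allow_selfing:
        if n < 2:
            raise ValueError("selfing-free mating needs >= 2 individuals")
        bad = parents[:, 0] == parents[:, 1]
        while bad.any():
            parents[bad, 1] = rng.integers(0, n, size=int(bad.sum()))
            bad = parents[:, 0] == parents[:, 1]
    # gamete g comes from parent individual parents[g >> 1, g & 1]
    par_ind = parents.reshape(-1)
    par_rows = np.empty((n_gam, 2), dtype=np.int64)
    par_rows[:, 0] = 2 * par_ind
    par_rows[:, 1] = 2 * par_ind + 1
    start = rng.integers(0, 2, size=n_gam).astype(np.uint8)

    new_chroms = []
    mu = spec.mutations_per_chrom_per_meiosis
    length = spec.chrom_length
    for ch in state.chroms:
        xo_counts = rng.poisson(length, n_gam)
        xo_pos, xo_indptr = _ragged_sorted_uniform(rng, xo_counts, length)
        new_counts = rng.poisson(mu, n_gam)
        new_pos, new_indptr = _ragged_sorted_uniform(rng, new_counts, length)
        xo_cols = np.searchsorted(ch.pos, xo_pos).astype(np.int64)

        out_mat = np.empty((n_gam, ch.mat.shape[1]), dtype=np.uint64)
        ylen = np.diff(ch.yindptr)
        bound = int(ylen[par_rows].sum() + new_counts.sum())
        oyflat = np.empty(bound, dtype=np.float64)
        oyindptr = np.empty(n_gam + 1, dtype=np.int64)
        pair_max = int((ylen[par_rows[:, 0]] + ylen[par_rows[:, 1]]).max()) if n_gam else 0
        ybuf = np.empty(max(pair_max, 1), dtype=np.float64)
        _transmit(
            ch.mat, len(ch.pos), ch.yflat, ch.yindptr, par_rows, start,
            xo_cols, xo_pos, xo_indptr, new_pos, new_indptr,
            out_mat, oyflat, oyindptr, ybuf,
        )
        new_chroms.append(
            ChromState(
                pos=ch.pos,
                mat=out_mat,
                yflat=oyflat[: oyindptr[-1]].copy(),
                yindptr=oyindptr,
                fixed=ch.fixed,
            )
        )
    out = PopState(
        n=n_next,
        generation=state.generation + 1,
        chroms=new_chroms,
        gens_since_consolidation=state.gens_since_consolidation + 1,
    )
    if record_parents:
        return out, parents
    return out


def consolidate(state: PopState) -> None:
    """Merge young mutations into the matrices; prune lost/fixed columns.

    In place.  After this, every matrix column is segregating within the
    population, ``fixed`` holds all derived positions shared by every
    haplotype of the lineage, and the young lists are empty.
    """
    n_hap = 2 * state.n
    for ch in state.chroms:
        n_cols = len(ch.pos)
        mat_b = unpack_bits(ch.mat, n_cols)
        cnt = mat_b.sum(axis=0, dtype=np.int64)
        keep = (cnt > 0) & (cnt < n_hap)
        newly_fixed = [ch.pos[cnt == n_hap]]

        if len(ch.yflat):
            owners = np.repeat(np.arange(n_hap), np.diff(ch.yindptr))
            upos, inv = np.unique(ch.yflat, return_inverse=True)
            ycnt = np.bincount(inv, minlength=len(upos))
            yfixed = ycnt == n_hap
            ykeep = ~yfixed
            newly_fixed.append(upos[yfixed])
            col_of = np.cumsum(ykeep) - 1
            ymat = np.zeros((n_hap, int(ykeep.sum())), dtype=np.uint8)
            sel = ykeep[inv]
            ymat[owners[sel], col_of[inv[sel]]] = 1
            all_pos = np.concatenate([ch.pos[keep], upos[ykeep]])
            all_b = np.concatenate([mat_b[:, keep], ymat], axis=1)
        else:
            all_pos = ch.pos[keep]
            all_b = mat_b[:, keep]

        order = np.argsort(all_pos, kind="stable")
        all_pos = all_pos[order]
        all_b = all_b[:, order]
        # infinite-sites guard: merge the vanishingly rare position clash
        if len(all_pos) > 1:
            dup = np.flatnonzero(np.diff(all_pos) == 0.0)
            if len(dup):
                all_b[:, dup] |= all_b[:, dup + 1]
                keep2 = np.ones(len(all_pos), dtype=bool)
                keep2[dup + 1] = False
                all_pos = all_pos[keep2]
                all_b = all_b[:, keep2]

        ch.pos = all_pos
        ch.mat = pack_bits(all_b)
        ch.yflat = np.empty(0, dtype=np.float64)
        ch.yindptr = np.zeros(n_hap + 1, dtype=np.int64)
        fixed = np.concatenate(newly_fixed + [ch.fixed])
        fixed.sort()
        ch.fixed = fixed
    state.gens_since_consolidation = 0
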