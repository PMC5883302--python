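"""Polygenic trait simulation: QTN selection, effects, breeding values.

A trait is controlled by 200 QTN (20 per chromosome, pairwise at least
2 cM apart within a chromosome) drawn from the variants segregating in the
union of the founder breeds.  Additive effects are i.i.d. draws from a
t-distribution with 4 degrees of freedom (heavy-tailed, variance 2).  The
breeding value of an individual with QTN doses x is

    BV(x) = sum_j (x_j - 2 p_j) a_j,

with p_j the derived-allele frequency in the reference dataset (the pooled
F2 data for cross analyses; the purebred population for the within-breed
analysis).  Phenotypes are y = BV + e with Gaussian residuals whose
variance is anchored so that the reference dataset has the target
heritability (0.5 by default): sigma_e^2 = sigma_A^2 (1 - h^2) / h^2 with
sigma_A^2 the empirical variance of the breeding values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class QtnSelectionError(RuntimeError):
    """Not enough spaced candidate variants for the requested QTN count."""


class DegenerateTraitError(ValueError):
    """Breeding values carry no variance; heritability undefined."""


@dataclass
class TraitArchitecture:
    """QTN identities and additive effects of one simulated trait."""

    chrom: np.ndarray    # int16 (n_qtn,)
    pos: np.ndarray      # float64 (n_qtn,)
    effects: np.ndarray  # float64 (n_qtn,), t(4) draws

    @property
    def n_qtn(self) -> int:
        return len(self.pos)


@dataclass
class PhenotypeSet:
    """Phenotypes y = BV + e of one dataset under one trait."""

    y: np.ndarray
    bv: np.ndarray
    residuals: np.ndarray
    sigma_a2: float      # variance of BV in the anchoring dataset
    sigma_e2: float
    h2_target: float

    @property
    def realized_h2(self) -> float:
        return float(np.var(self.bv) / np.var(self.y))


def select_qtn_positions(candidates: np.ndarray, n_qtn: int,
                         min_distance: float, rng, *,
                         max_restarts: int = 200) -> np.ndarray:
    """Uniformly sample ``n_qtn`` positions with pairwise spacing.

    Sequential rejection: candidates are visited in random order and
    accepted unless within ``min_distance`` of an already accepted
    position; if a pass ends short of the quota the selection restarts.
    This samples uniformly among spaced subsets reachable by the greedy
    pass and restarts guard against unlucky orders.
    """
    candidates = np.asarray(candidates)
    for _ in range(max_restarts):
        order = rng.permutation(len(candidates))
        chosen: list[float] = []
        for i in order:
            p = candidates[i]
            if all(abs(p - q) >= min_distance for q in chosen):
                chosen.append(float(p))
                if len(chosen) == n_qtn:
                    return np.sort(np.array(chosen))
    raise QtnSelectionError(
        f"could not place {n_qtn} QTN at spacing {min_distance} "
        f"among {len(candidates)} candidates")


def select_qtn(candidate_positions: list[np.ndarray], rng, *,
               qtn_per_chrom: int = 20,
               min_distance: float = 0.02) -> tuple[np.ndarray, np.ndarray]:
    """Select QTN per chromosome from candidate position lists.

    Returns (chrom, pos) arrays of the selected QTN (sorted by chromosome
    and position).  Raises :class:`QtnSelectionError` when a chromosome
    cannot host the quota at the required spacing.
    """
    chroms, poss = [], []
    for c, cand in enumerate(candidate_positions):
        sel = select_qtn_positions(cand, qtn_per_chrom, min_distance, rng)
        chroms.append(np.full(qtn_per_chrom, c, dtype=np.int16))
        poss.append(sel)
    return np.concatenate(chroms), np.concatenate(poss)


def sample_effects(n_qtn: int, rng) -> np.ndarray:
    """I.i.d. additive effects from a t-distribution with 4 df."""
    if n_qtn < 1:
        raise ValueError("n_qtn must be >= 1")
    return rng.standard_t(4, size=n_qtn)


def breeding_values(doses: np.ndarray, p: np.ndarray,
                    effects: np.ndarray) -> np.ndarray:
    """BV(x) = sum_j (x_j - 2 p_j) a_j for each individual (row of doses)."""
    doses = np.asarray(doses, dtype=np.float64)
    p = np.asarray(p, dtype=np.float64)
    effects = np.asarray(effects, dtype=np.float64)
    if doses.shape[1] != len(p) or len(p) != len(effects):
        raise ValueError("doses, frequencies and effects must align")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("allele frequencies must lie in [0, 1]")
    return (doses - 2.0 * p) @ effects


def add_residuals(bv: np.ndarray, h2: float, rng, *,
                  sigma_a2: float | None = None) -> PhenotypeSet:
    """Add Gaussian residuals targeting heritability ``h2``.

    ``sigma_a2`` defaults to the empirical variance of ``bv``; passing the
    pooled-dataset variance instead anchors the residual variance of a
    single-cross dataset to the pooled analysis (so the pooled data have
    exactly the target heritability at construction).
    """
    if not 0.0 < h2 < 1.0:
        raise ValueError("h2 must be in (0, 1)")
    bv = np.asarray(bv, dtype=np.float64)
    if len(bv) < 2:
        raise ValueError("need >= 2 individuals")
    if sigma_a2 is None:
        sigma_a2 = float(np.var(bv))
    if sigma_a2 <= 0.0:
        raise DegenerateTraitError("breeding values have zero variance")
    sigma_e2 = sigma_a2 * (1.0 - h2) / h2
    e = rng.normal(0.0, np.sqrt(sigma_e2), size=len(bv))
    return PhenotypeSet(y=bv + e, bv=bv, residuals=e,
                        sigma_a2=sigma_a2, sigma_e2=sigma_e2, h2_target=h2)
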