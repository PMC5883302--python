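"""Single-marker mixed-linear-model association with a LOCO polygenic term.

The model for individual i and tested variant j is

    y_i = mu_{k(i)} + b_j x_ij + g_i + e_i,

with one fixed mean per cross k, the variant's dose x_ij as fixed
regressor, a random polygenic effect g ~ N(0, G sigma_g^2) whose
covariance G is a genomic relationship matrix built while *leaving out the
tested variant's chromosome* (LOCO, so the variant is never fitted as both
fixed and random), and i.i.d. residuals e ~ N(0, I sigma_e^2).

Variance components are estimated once per LOCO GRM by REML (profile
likelihood on the variance ratio via the GRM's eigendecomposition) under
the null model (no variant effect), and each variant on the left-out
chromosome is then tested by generalized least squares with a Wald test
against the normal reference.  Multiple testing uses the Bonferroni rule
over the analysed variant set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .popgen import GrmMatrix, LocoGrmFamily, allele_frequencies


class ConvergenceError(RuntimeError):
    """REML optimisation failed."""


@dataclass
class SignificanceRule:
    """Bonferroni correction: per-test threshold alpha / n_tests."""

    alpha: float
    n_tests: int

    def __post_init__(self) -> None:
        if self.n_tests < 1:
            raise ValueError("n_tests must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")

    @property
    def threshold(self) -> float:
        return self.alpha / self.n_tests

    def is_significant(self, p) -> np.ndarray:
        return np.asarray(p) < self.threshold


def bonferroni(alpha: float, n_tests: int) -> SignificanceRule:
    """Genome-wide alpha to per-test threshold alpha / n_tests."""
    return SignificanceRule(alpha=alpha, n_tests=n_tests)


@dataclass
class MlmFit:
    """REML variance components of one (dataset, LOCO chromosome) null fit."""

    sigma_g2: float
    sigma_e2: float
    loglik: float           # restricted log-likelihood (up to a constant)
    excluded_chromosome: int | None
    n: int
    k: int                  # fixed-effect rank (number of cross means)

    @property
    def h2(self) -> float:
        return self.sigma_g2 / (self.sigma_g2 + self.sigma_e2)


@dataclass
class GwasResult:
    """Per-variant association results of one dataset x scenario analysis."""

    table: pd.DataFrame     # chrom, pos, beta, se, p
    dataset: str
    scenario: str
    rule: SignificanceRule
    fits: dict = field(default_factory=dict)

    @property
    def significant(self) -> np.ndarray:
        return self.rule.is_significant(self.table["p"].to_numpy())


def _design(cross_labels) -> np.ndarray:
    labels, inv = np.unique(np.asarray(cross_labels), return_inverse=True)
    X = np.zeros((len(inv), len(labels)))
    X[np.arange(len(inv)), inv] = 1.0
    return X


def _neg2_restricted_ll(delta, lam, uty, utx):
    w = 1.0 / (lam + delta)
    xtwx = (utx * w[:, None]).T @ utx
    xtwy = utx.T @ (w * uty)
    beta = np.linalg.solve(xtwx, xtwy)
    ypy = float((w * uty) @ uty - xtwy @ beta)
    n, k = len(lam), utx.shape[1]
    sign, logdet_xtwx = np.linalg.slogdet(xtwx)
    if sign <= 0 or ypy <= 0:
        return np.inf, 0.0
    val = ((n - k) * np.log(ypy / (n - k))
           + np.sum(np.log(lam + delta)) + logdet_xtwx)
    return val, ypy / (n - k)


def _profile_reml(lam, uty, utx, *, grid=None, tol=1e-6, max_iter=200):
    """Maximise the restricted likelihood over delta = sigma_e2 / sigma_g2.

    Grid search on log10(delta) followed by golden-section refinement of
    the bracketing interval; deterministic for fixed inputs.
    """
    if grid is None:
        grid = np.linspace(-6.0, 6.0, 121)
    vals = np.array([_neg2_restricted_ll(10.0 ** g, lam, uty, utx)[0]
                     for g in grid])
    if not np.isfinite(vals).any():
        raise ConvergenceError("restricted likelihood undefined on the grid")
    i = int(np.nanargmin(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    phi = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c = b - phi * (b - a)
    d = a + phi * (b - a)
    fc = _neg2_restricted_ll(10.0 ** c, lam, uty, utx)[0]
    fd = _neg2_restricted_ll(10.0 ** d, lam, uty, utx)[0]
    it = 0
    # stop when the h2 = 1/(1+delta) bracket is tighter than tol
    while abs(1.0 / (1.0 + 10.0 ** a) - 1.0 / (1.0 + 10.0 ** b)) > tol:
        it += 1
        if it > max_iter:
            raise ConvergenceError("golden-section refinement did not converge")
        if fc < fd:
            b, d, fd = d, c, fc
            c = b - phi * (b - a)
            fc = _neg2_restricted_ll(10.0 ** c, lam, uty, utx)[0]
        else:
            a, c, fc = c, d, fd
            d = a + phi * (b - a)
            fd = _neg2_restricted_ll(10.0 ** d, lam, uty, utx)[0]
    delta = 10.0 ** ((a + b) / 2.0)
    val, sigma_g2 = _neg2_restricted_ll(delta, lam, uty, utx)
    return delta, sigma_g2, -0.5 * val


def reml_fit(y, cross_labels, grm: GrmMatrix, *, tol: float = 1e-6) -> MlmFit:
    """REML variance components of y = X mu + g + e with Cov(g) = G sigma_g2.

    ``cross_labels`` define the fixed cross-mean design (one column per
    label).  Deterministic: eigendecomposition-based profile REML on the
    variance ratio.
    """
    y = np.asarray(y, dtype=np.float64)
    X = _design(cross_labels)
    if grm.values.shape != (len(y), len(y)):
        raise ValueError("GRM dimension does not match phenotypes")
    labels, counts = np.unique(np.asarray(cross_labels), return_counts=True)
    if (counts < 2).any():
        raise ValueError("each cross needs >= 2 individuals")
    lam, U = np.linalg.eigh(grm.values)
    lam = np.clip(lam, 0.0, None)
    delta, sigma_g2, ll = _profile_reml(lam, U.T @ y, U.T @ X, tol=tol)
    return MlmFit(
        sigma_g2=sigma_g2,
        sigma_e2=sigma_g2 * delta,
        loglik=ll,
        excluded_chromosome=(grm.excluded_chromosomes[0]
                             if grm.excluded_chromosomes else None),
        n=len(y),
        k=X.shape[1],
    )


def gls_single_marker(y, X, x, V) -> tuple[float, float]:
    """Direct GLS of one marker with known covariance V (reference path).

    Returns (beta_hat, se).  Used as the closed-form check for the
    whitened fast path on small instances.
    """
    Vi = np.linalg.inv(V)
    M = np.column_stack([X, x])
    coef = np.linalg.solve(M.T @ Vi @ M, M.T @ Vi @ y)
    cov = np.linalg.inv(M.T @ Vi @ M)
    return float(coef[-1]), float(np.sqrt(cov[-1, -1]))


def _scan_markers(lam, U, y, X, doses_cols, sigma_g2, sigma_e2):
    """Whitened GLS of each marker column with fixed variance components.

    The covariance is V = sigma_g2 * G + sigma_e2 * I with G = U lam U'.
    Returns (beta, se).  Small problems run in float64; large dose blocks
    use float32 for the rotation (the per-marker statistics are float64).
    """
    w = 1.0 / (sigma_g2 * lam + sigma_e2)
    sw = np.sqrt(w)
    ys = sw * (U.T @ y)
    Xs = sw[:, None] * (U.T @ X)
    Q, _ = np.linalg.qr(Xs)
    y_r = ys - Q @ (Q.T @ ys)
    if doses_cols.size <= 1_000_000:
        S = U.T @ np.asarray(doses_cols, dtype=np.float64)
    else:
        S = (U.T.astype(np.float32)
             @ np.ascontiguousarray(doses_cols, dtype=np.float32))
        S = S.astype(np.float64)
    S *= sw[:, None]
    S -= Q @ (Q.T @ S)
    denom = np.einsum("ij,ij->j", S, S)
    num = y_r @ S
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(denom > 0, num / denom, 0.0)
        se = np.where(denom > 0, np.sqrt(1.0 / np.where(denom > 0, denom, 1.0)),
                      np.inf)
    return beta, se


def marker_scan(y, cross_labels, doses, grm: GrmMatrix, fit: MlmFit):
    """GLS single-marker tests of all columns of ``doses`` under ``fit``.

    Equivalent to the direct GLS :func:`gls_single_marker` with
    V = sigma_g2 G + sigma_e2 I, computed via the GRM eigendecomposition.
    """
    y = np.asarray(y, dtype=np.float64)
    X = _design(cross_labels)
    lam, U = np.linalg.eigh(grm.values)
    lam = np.clip(lam, 0.0, None)
    return _scan_markers(lam, U, y, X, np.asarray(doses),
                         fit.sigma_g2, fit.sigma_e2)


def mlma_loco(doses, chrom, pos, y, cross_labels, *,
              alpha: float = 0.05, dataset: str = "", scenario: str = "",
              tol: float = 1e-6) -> GwasResult:
    """Mixed-model association of every variant, LOCO polygenic covariance.

    ``doses``: (n x m) dose matrix of the analysed variant set S (QTN are
    tested exactly like any other variant); ``chrom``/``pos`` give the
    variants' coordinates.  For each chromosome c a GRM excluding c is
    built from S, variance components are REML-estimated once under the
    null, and all variants on c are tested by whitened GLS with Wald
    p-values 2 Phi(-|b/se|).
    """
    doses = np.asarray(doses)
    y = np.asarray(y, dtype=np.float64)
    chrom = np.asarray(chrom)
    n, m = doses.shape
    if m == 0:
        raise ValueError("empty variant set")
    X = _design(cross_labels)
    family = LocoGrmFamily(doses, chrom)
    beta = np.empty(m)
    se = np.empty(m)
    fits: dict[int, MlmFit] = {}
    for c in family.chromosomes:
        grm = family.leave_out(int(c))
        lam, U = np.linalg.eigh(grm.values)
        lam = np.clip(lam, 0.0, None)
        uty = U.T @ y
        utx = U.T @ X
        delta, sigma_g2, ll = _profile_reml(lam, uty, utx, tol=tol)
        fit = MlmFit(sigma_g2=sigma_g2, sigma_e2=sigma_g2 * delta,
                     loglik=ll, excluded_chromosome=int(c), n=n, k=X.shape[1])
        fits[int(c)] = fit
        cols = np.flatnonzero(chrom == c)
        beta[cols], se[cols] = _scan_markers(
            lam, U, y, X, doses[:, cols], fit.sigma_g2, fit.sigma_e2)
    z = np.where(np.isfinite(se), beta / se, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    table = pd.DataFrame({
        "chrom": chrom, "pos": pos, "beta": beta, "se": se, "p": p,
    })
    return GwasResult(table=table, dataset=dataset, scenario=scenario,
                      rule=bonferroni(alpha, m), fits=fits)
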