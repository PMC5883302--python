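"""Mapping scenarios and the power/precision metrics.

Two analysis scenarios are supported.  In the *all segregating genes*
(ASG) scenario the analysed set S holds every variant passing the
within-dataset MAF filter.  In the *founder segregating genes* (FSG)
scenario, S is additionally restricted to variants segregating (MAF above
the threshold) in the common founder breed EU2 — the variants a breeder
of that breed could care about.  The QTN set Q is the intersection of the
simulated QTN with S, so Q_alpha (significant QTN) .. Q .. S are nested.

Metrics per dataset x scenario x replicate:

* QTN power  = #Q_alpha / #Q — the fraction of (analysable) causal
  variants that are themselves Bonferroni-significant.
* QTL power  = #W_alpha / #Q — the fraction of QTN whose centred 1 cM
  window contains at least one significant variant (the QTN counts as its
  own window member, so QTL power >= QTN power).
* QTN precision — for each *significant* QTN, one minus the proportion of
  significant window variants with a smaller p-value than the QTN,
  averaged over significant QTN.  Precision 1 means the causal variant is
  the top signal of its window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gwas import GwasResult, SignificanceRule
from .popgen import maf_filter


@dataclass(frozen=True)
class ScenarioConfig:
    """Settings shared by the scenario construction and the metrics."""

    scenario: str = "ASG"
    maf_threshold: float = 0.05
    founder_breed: str = "EU2"
    alpha: float = 0.05
    window: float = 0.01  # Morgans, QTN-centred
    maf_strict: bool = False      # within-dataset filter: keep MAF >= t
    founder_maf_strict: bool = True  # FSG founder filter: MAF > t
    precision_denominator: str = "significant"  # or "all"

    def __post_init__(self) -> None:
        if self.scenario not in ("ASG", "FSG"):
            raise ValueError("scenario must be ASG or FSG")
        if not self.window > 0:
            raise ValueError("window width must be > 0")
        if self.precision_denominator not in ("significant", "all"):
            raise ValueError("unknown precision denominator")


class FounderFrequencies:
    """Derived-allele frequency lookup in a founder breed population."""

    def __init__(self, pop):
        self._pos = [p.copy() for p in pop.positions]
        self._freq = [pop.allele_frequencies(c)
                      for c in range(pop.n_chromosomes)]
        self._fixed = [f.copy() for f in pop.fixed]

    def frequency(self, chrom: np.ndarray, pos: np.ndarray) -> np.ndarray:
        chrom = np.asarray(chrom)
        pos = np.asarray(pos)
        out = np.zeros(len(pos))
        for c in np.unique(chrom):
            sel = np.flatnonzero(chrom == c)
            idx = np.searchsorted(self._pos[int(c)], pos[sel])
            hit = idx < len(self._pos[int(c)])
            hit[hit] &= self._pos[int(c)][idx[hit]] == pos[sel][hit]
            out[sel[hit]] = self._freq[int(c)][idx[hit]]
            miss = sel[~hit]
            if len(miss):
                fixed = np.isin(pos[miss], self._fixed[int(c)])
                out[miss[fixed]] = 1.0
        return out

    def maf(self, chrom, pos) -> np.ndarray:
        f = self.frequency(chrom, pos)
        return np.minimum(f, 1.0 - f)


@dataclass
class ScenarioSets:
    """Variant set S and QTN set Q of one dataset x scenario."""

    scenario: str
    s_cols: np.ndarray  # dataset column indices in S (tested variants)
    q_rows: np.ndarray  # indices into s_cols that are QTN

    @property
    def n_s(self) -> int:
        return len(self.s_cols)

    @property
    def n_q(self) -> int:
        return len(self.q_rows)


def scenario_sets(dataset, qtn_chrom, qtn_pos, config: ScenarioConfig,
                  founder_freqs: FounderFrequencies | None = None) -> ScenarioSets:
    """Build (S, Q) for one dataset under one scenario.

    ASG keeps every variant passing the within-dataset MAF filter; FSG
    additionally requires segregation in the founder breed.  Q is the set
    of simulated QTN present in S (QTN are filtered exactly like SNPs).
    """
    from .popgen import allele_frequencies

    freqs = allele_frequencies(dataset.genotypes)
    keep = maf_filter(freqs, config.maf_threshold, strict=config.maf_strict)
    if config.scenario == "FSG":
        if founder_freqs is None:
            raise ValueError("FSG scenario needs founder breed frequencies")
        fm = founder_freqs.maf(dataset.chrom, dataset.pos)
        keep &= (fm > config.maf_threshold if config.founder_maf_strict
                 else fm >= config.maf_threshold)
    s_cols = np.flatnonzero(keep)
    if len(s_cols) == 0:
        raise ValueError("empty variant set S")
    # locate QTN among the S columns
    q_rows = []
    s_chrom = dataset.chrom[s_cols]
    s_pos = dataset.pos[s_cols]
    for qc, qp in zip(np.asarray(qtn_chrom), np.asarray(qtn_pos)):
        cand = np.flatnonzero((s_chrom == qc) & (s_pos == qp))
        if len(cand):
            q_rows.append(int(cand[0]))
    return ScenarioSets(scenario=config.scenario, s_cols=s_cols,
                        q_rows=np.array(sorted(q_rows), dtype=np.int64))


def qtn_power(result: GwasResult, q_rows, rule: SignificanceRule | None = None
              ) -> float:
    """#Q_alpha / #Q: fraction of QTN with Bonferroni-significant p."""
    q_rows = np.asarray(q_rows, dtype=np.int64)
    if len(q_rows) == 0:
        return np.nan
    rule = rule or result.rule
    p = result.table["p"].to_numpy()[q_rows]
    return float(rule.is_significant(p).mean())


def _window_members(chrom, pos, qc, qp, window):
    half = window / 2.0
    return np.flatnonzero((chrom == qc) & (np.abs(pos - qp) <= half))


def qtl_power(result: GwasResult, q_rows, config: ScenarioConfig,
              rule: SignificanceRule | None = None) -> float:
    """#W_alpha / #Q: QTN windows holding at least one significant variant."""
    q_rows = np.asarray(q_rows, dtype=np.int64)
    if len(q_rows) == 0:
        return np.nan
    rule = rule or result.rule
    chrom = result.table["chrom"].to_numpy()
    pos = result.table["pos"].to_numpy()
    sig = rule.is_significant(result.table["p"].to_numpy())
    hits = 0
    for q in q_rows:
        members = _window_members(chrom, pos, chrom[q], pos[q], config.window)
        if sig[members].any():
            hits += 1
    return hits / len(q_rows)


def qtn_precision(result: GwasResult, q_rows, config: ScenarioConfig,
                  rule: SignificanceRule | None = None) -> float:
    """Mean over significant QTN of 1 - (share of window variants beating
    the QTN).  With the default denominator, "window variants" are the
    significant ones; ``config.precision_denominator='all'`` divides by
    all window variants instead.  NaN when no QTN is significant.
    """
    q_rows = np.asarray(q_rows, dtype=np.int64)
    rule = rule or result.rule
    chrom = result.table["chrom"].to_numpy()
    pos = result.table["pos"].to_numpy()
    p = result.table["p"].to_numpy()
    sig = rule.is_significant(p)
    vals = []
    for q in q_rows:
        if not sig[q]:
            continue
        members = _window_members(chrom, pos, chrom[q], pos[q], config.window)
        beaters = int((p[members] < p[q]).sum())  # ties do not beat the QTN
        if config.precision_denominator == "significant":
            denom = int(sig[members].sum())
        else:
            denom = len(members)
        vals.append(1.0 - beaters / denom)
    return float(np.mean(vals)) if vals else np.nan


def replicate_metrics(result: GwasResult, sets: ScenarioSets,
                      config: ScenarioConfig, *, replicate=0) -> dict:
    """All metrics of one dataset x scenario x replicate as a record."""
    rule = result.rule
    p = result.table["p"].to_numpy()
    sig = rule.is_significant(p)
    q = sets.q_rows
    return {
        "dataset": result.dataset,
        "scenario": config.scenario,
        "replicate": replicate,
        "qtn_power": qtn_power(result, q, rule),
        "qtl_power": qtl_power(result, q, config, rule),
        "qtn_precision": qtn_precision(result, q, config, rule),
        "n_s": sets.n_s,
        "n_q": sets.n_q,
        "n_q_sig": int(sig[q].sum()) if len(q) else 0,
        "n_sig": int(sig.sum()),
    }


def aggregate(records: pd.DataFrame) -> pd.DataFrame:
    """Mean/SD of the metrics across replicates per dataset x scenario.

    Undefined replicate values (NaN) are excluded, with the number of
    valid replicates reported per metric; a single valid replicate gets
    SD 0 (flagged by n=1).
    """
    records = pd.DataFrame(records)
    if records.empty:
        raise ValueError("no replicate records to aggregate")
    rows = []
    for (ds, sc), grp in records.groupby(["dataset", "scenario"], sort=False):
        row: dict = {"dataset": ds, "scenario": sc,
                     "n_replicates": len(grp)}
        for metric in ("qtn_power", "qtl_power", "qtn_precision", "n_s", "n_q"):
            vals = grp[metric].to_numpy(dtype=float)
            vals = vals[~np.isnan(vals)]
            row[f"{metric}_mean"] = float(vals.mean()) if len(vals) else np.nan
            row[f"{metric}_sd"] = (float(vals.std(ddof=1)) if len(vals) > 1
                                   else 0.0 if len(vals) == 1 else np.nan)
            row[f"{metric}_n"] = len(vals)
        rows.append(row)
    return pd.DataFrame(rows)


def power_by_qtn_variance(result: GwasResult, sets: ScenarioSets,
                          qtn_doses: np.ndarray, effects: np.ndarray,
                          var_y: float, *, bins=None) -> pd.DataFrame:
    """QTN mapping power binned by the QTN's phenotypic-variance share.

    A QTN's contribution is 2 p (1 - p) a^2 / Var(y), with p its frequency
    in the analysed dataset.  ``qtn_doses``/``effects`` must align with
    ``sets.q_rows``.
    """
    if bins is None:
        bins = np.array([0.0, 1e-4, 3e-4, 1e-3, 3e-3, 1e-2, 3e-2, 1.0])
    p_freq = qtn_doses.mean(axis=0) / 2.0
    contrib = 2.0 * p_freq * (1.0 - p_freq) * effects ** 2 / var_y
    pvals = result.table["p"].to_numpy()[sets.q_rows]
    sig = result.rule.is_significant(pvals)
    which = np.digitize(contrib, bins) - 1
    rows = []
    for b in range(len(bins) - 1):
        m = which == b
        rows.append({
            "bin_low": bins[b], "bin_high": bins[b + 1],
            "n_qtn": int(m.sum()),
            "power": float(sig[m].mean()) if m.any() else np.nan,
        })
    return pd.DataFrame(rows)
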