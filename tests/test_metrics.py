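"""Scenario sets and the QTN/QTL power and precision metrics."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qtlcross.gwas import GwasResult, bonferroni
from qtlcross.metrics import (
    FounderFrequencies,
    ScenarioConfig,
    aggregate,
    qtl_power,
    qtn_power,
    qtn_precision,
    scenario_sets,
)

from conftest import make_synthetic_breed


def _result(chrom, pos, p, n_tests=None, alpha=0.05):
    table = pd.DataFrame({
        "chrom": np.asarray(chrom),
        "pos": np.asarray(pos, dtype=float),
        "beta": np.zeros(len(p)),
        "se": np.ones(len(p)),
        "p": np.asarray(p, dtype=float),
    })
    return GwasResult(table=table, dataset="toy", scenario="ASG",
                      rule=bonferroni(alpha, n_tests or len(p)))


CFG = ScenarioConfig()


class TestScenarioSets:
    def _toy_dataset(self, rng):
        from qtlcross.cross import CrossDataset

        n, m = 40, 30
        doses = rng.binomial(2, 0.5, (n, m)).astype(np.int8)
        doses[:, 5] = 2  # monomorphic: removed by the MAF filter
        pos = np.sort(rng.random(m))
        return CrossDataset(
            name="toy", chrom=np.zeros(m, dtype=np.int16), pos=pos,
            genotypes=doses, ids=np.array([f"i{i}" for i in range(n)]),
            cross_labels=np.full(n, "toy"), pedigree=pd.DataFrame(),
            constant_derived=[np.empty(0)], replicate_key="k")

    def test_asg_keeps_filtered_variants(self, rng):
        ds = self._toy_dataset(rng)
        qtn_c = np.zeros(3, dtype=np.int16)
        qtn_p = ds.pos[[1, 5, 10]]
        sets = scenario_sets(ds, qtn_c, qtn_p, CFG)
        assert 5 not in sets.s_cols        # monomorphic column dropped
        assert sets.n_q == 2               # QTN at column 5 filtered out

    def test_fsg_subsets_asg(self, rng):
        ds = self._toy_dataset(rng)
        founder = make_synthetic_breed(np.random.default_rng(1),
                                       lineage="EU2", n=20, n_chrom=1,
                                       m_per_chrom=10)
        ff = FounderFrequencies(founder)
        qtn_c = np.zeros(2, dtype=np.int16)
        qtn_p = ds.pos[[1, 10]]
        asg = scenario_sets(ds, qtn_c, qtn_p, CFG)
        fsg_cfg = ScenarioConfig(scenario="FSG")
        # no dataset position segregates in this founder: S would be empty
        with pytest.raises(ValueError):
            scenario_sets(ds, qtn_c, qtn_p, fsg_cfg, founder_freqs=ff)
        # founder sharing all positions: FSG = ASG here
        founder2 = make_synthetic_breed(np.random.default_rng(2),
                                        lineage="EU2", n=20, n_chrom=1,
                                        m_per_chrom=5)
        founder2.positions[0] = ds.pos[np.array([0, 1, 2, 3, 4])].copy()
        ff2 = FounderFrequencies(founder2)
        fsg = scenario_sets(ds, qtn_c, qtn_p, fsg_cfg, founder_freqs=ff2)
        assert fsg.n_s <= asg.n_s
        assert set(fsg.s_cols) <= set(asg.s_cols)

    def test_fsg_drops_qtn_fixed_in_founder(self, rng):
        ds = self._toy_dataset(rng)
        founder = make_synthetic_breed(np.random.default_rng(3),
                                       lineage="EU2", n=20, n_chrom=1,
                                       m_per_chrom=4)
        founder.positions[0] = ds.pos[np.array([0, 1, 2, 3])].copy()
        # QTN at ds.pos[10] is fixed (absent) in the founder
        ff = FounderFrequencies(founder)
        sets = scenario_sets(ds, np.zeros(2, dtype=np.int16),
                             ds.pos[[1, 10]], ScenarioConfig(scenario="FSG"),
                             founder_freqs=ff)
        s_pos = set(ds.pos[sets.s_cols])
        assert ds.pos[10] not in s_pos
        assert sets.n_q == 1


class TestQtnPower:
    def test_no_significant(self):
        res = _result([0] * 4, [0.1, 0.2, 0.3, 0.4], [0.5] * 4)
        assert qtn_power(res, [0, 1]) == 0.0

    def test_all_significant(self):
        res = _result([0] * 3, [0.1, 0.2, 0.3], [1e-12] * 3)
        assert qtn_power(res, [0, 1, 2]) == 1.0

    def test_three_of_ten(self):
        p = [1e-9] * 3 + [0.5] * 7
        res = _result([0] * 10, np.linspace(0.1, 0.9, 10), p,
                      n_tests=50_000)  # threshold 1e-6
        assert qtn_power(res, list(range(10))) == pytest.approx(0.3)

    def test_empty_q_undefined(self):
        res = _result([0], [0.5], [0.01])
        assert np.isnan(qtn_power(res, []))


class TestQtlPower:
    def test_significant_qtn_counts_its_window(self):
        res = _result([0, 0], [0.5, 0.9], [1e-12, 0.5])
        assert qtl_power(res, [0], CFG) == 1.0
        assert qtl_power(res, [0], CFG) >= qtn_power(res, [0])

    def test_nearby_significant_snp_counts(self):
        # SNP 0.4 cM from a non-significant QTN
        res = _result([0, 0], [0.5, 0.504], [0.5, 1e-12])
        assert qtl_power(res, [0], CFG) == 1.0

    def test_snp_outside_window_does_not_count(self):
        res = _result([0, 0], [0.5, 0.506], [0.5, 1e-12])
        assert qtl_power(res, [0], CFG) == 0.0

    def test_other_chromosome_does_not_count(self):
        res = _result([0, 1], [0.5, 0.5], [0.5, 1e-12])
        assert qtl_power(res, [0], CFG) == 0.0


class TestQtnPrecision:
    def test_top_qtn_gives_one(self):
        res = _result([0, 0, 0], [0.5, 0.501, 0.502], [1e-12, 1e-6, 0.5],
                      n_tests=100)
        assert qtn_precision(res, [0], CFG) == 1.0

    def test_half_of_significant_snps_beat_the_qtn(self):
        # window: QTN (1e-8) + significant SNPs {1e-9, 1e-10, 1e-7}:
        # 2 of the 4 significant window variants beat the QTN
        p = [1e-8, 1e-9, 1e-10, 1e-7]
        res = _result([0] * 4, [0.5, 0.501, 0.502, 0.503], p, n_tests=100)
        assert qtn_precision(res, [0], CFG) == pytest.approx(0.5)

    def test_spec_window_two_thirds(self):
        # QTN p = 1e-8; significant SNPs 1e-9 and 1e-7: one beater of three
        res = _result([0, 0, 0], [0.5, 0.501, 0.502], [1e-8, 1e-9, 1e-7],
                      n_tests=1000)
        assert qtn_precision(res, [0], CFG) == pytest.approx(2.0 / 3.0)

    def test_ties_do_not_beat(self):
        res = _result([0, 0], [0.5, 0.501], [1e-9, 1e-9], n_tests=100)
        assert qtn_precision(res, [0], CFG) == 1.0

    def test_all_denominator_variant(self):
        cfg = ScenarioConfig(precision_denominator="all")
        # window: QTN (1e-8), beater (1e-9), non-significant (0.4)
        res = _result([0, 0, 0], [0.5, 0.501, 0.502], [1e-8, 1e-9, 0.4],
                      n_tests=100)
        assert qtn_precision(res, [0], cfg) == pytest.approx(1.0 - 1.0 / 3.0)

    def test_undefined_without_significant_qtn(self):
        res = _result([0], [0.5], [0.9])
        assert np.isnan(qtn_precision(res, [0], CFG))


class TestAggregate:
    def test_single_replicate(self):
        df = pd.DataFrame([{"dataset": "d", "scenario": "ASG",
                            "replicate": 0, "qtn_power": 0.4,
                            "qtl_power": 0.5, "qtn_precision": np.nan,
                            "n_s": 10, "n_q": 5}])
        out = aggregate(df)
        assert out.qtn_power_mean.iloc[0] == pytest.approx(0.4)
        assert out.qtn_power_sd.iloc[0] == 0.0
        assert out.qtn_precision_n.iloc[0] == 0

    def test_mean_of_two(self):
        rows = [{"dataset": "d", "scenario": "ASG", "replicate": i,
                 "qtn_power": v, "qtl_power": v, "qtn_precision": v,
                 "n_s": 10, "n_q": 5} for i, v in enumerate((0.1, 0.3))]
        out = aggregate(pd.DataFrame(rows))
        assert out.qtn_power_mean.iloc[0] == pytest.approx(0.2)

    def test_constant_has_zero_sd(self):
        rows = [{"dataset": "d", "scenario": "ASG", "replicate": i,
                 "qtn_power": 0.25, "qtl_power": 0.25, "qtn_precision": 0.25,
                 "n_s": 10, "n_q": 5} for i in range(50)]
        out = aggregate(pd.DataFrame(rows))
        assert out.qtn_power_sd.iloc[0] == pytest.approx(0.0)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.lists(st.floats(min_value=1e-12, max_value=1.0), min_size=2,
                max_size=40),
       st.integers(min_value=1, max_value=5))
def test_qtl_power_dominates_qtn_power(pvals, n_qtn):
    """Set inclusion: a significant QTN always lights its own window."""
    m = len(pvals)
    n_qtn = min(n_qtn, m)
    pos = np.linspace(0.0, 0.9, m)
    res = _result([0] * m, pos, pvals, n_tests=max(m, 10))
    q = list(range(n_qtn))
    qp = qtn_power(res, q)
    lp = qtl_power(res, q, CFG)
    assert lp >= qp
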