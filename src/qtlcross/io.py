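"""Plain-text exports: VCF, PLINK ped/map, pedigrees, GRMs, result tables.

Genetic positions (Morgans) are mapped to base-pair coordinates by the
fixed convention 1 cM = 1 Mb, i.e. ``bp = round(pos_in_Morgans * 1e8) + 1``
(1-based).  The derived allele is written as ALT (alleles A=ancestral,
T=derived, chosen arbitrarily but consistently).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd


def _bp(pos_morgan: np.ndarray) -> np.ndarray:
    return (np.asarray(pos_morgan) * 1e8).round().astype(np.int64) + 1


def write_vcf(path, source, *, ids=None) -> None:
    """Write a population or dataset as an uncompressed VCF.

    ``source`` is either a :class:`~qtlcross.simulate.HaplotypePopulation`
    (phased haplotypes) or a :class:`~qtlcross.cross.CrossDataset`
    (unphased dose genotypes).
    """
    path = Path(path)
    from .cross import CrossDataset

    lines = ["##fileformat=VCFv4.2",
             "##FORMAT=<ID=GT,Number=1,Type=String,Description=\"Genotype\">"]
    if isinstance(source, CrossDataset):
        sample_ids = list(ids if ids is not None else source.ids)
        lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                     + "\t".join(sample_ids))
        gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
        bp = _bp(source.pos)
        for j in range(source.n_variants):
            row = "\t".join(gt_map[int(g)] for g in source.genotypes[:, j])
            lines.append(f"{int(source.chrom[j]) + 1}\t{bp[j]}\t"
                         f"v{int(source.chrom[j])}_{j}\tA\tT\t.\tPASS\t.\tGT\t"
                         + row)
    else:
        n = source.n_individuals
        sample_ids = list(ids if ids is not None else
                          (f"{source.lineage}_{i}" for i in range(n)))
        lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                     + "\t".join(sample_ids))
        for c in range(source.n_chromosomes):
            h = source.haplotype_matrix(c)
            bp = _bp(source.positions[c])
            for j in range(h.shape[1]):
                gts = "\t".join(f"{h[2 * i, j]}|{h[2 * i + 1, j]}"
                                for i in range(n))
                lines.append(f"{c + 1}\t{bp[j]}\tv{c}_{j}\tA\tT\t.\tPASS\t.\tGT\t"
                             + gts)
    path.write_text("\n".join(lines) + "\n")


def write_plink(prefix, dataset) -> None:
    """PLINK-style .ped/.map files for a dose dataset (unphased)."""
    prefix = Path(prefix)
    bp = _bp(dataset.pos)
    with open(prefix.with_suffix(".map"), "w") as fh:
        for j in range(dataset.n_variants):
            cm = dataset.pos[j] * 100.0
            fh.write(f"{int(dataset.chrom[j]) + 1}\tv{j}\t{cm:.6f}\t{bp[j]}\n")
    allele_pairs = {0: "A A", 1: "A T", 2: "T T"}
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for i in range(dataset.n_individuals):
            geno = " ".join(allele_pairs[int(g)] for g in dataset.genotypes[i])
            fh.write(f"FAM {dataset.ids[i]} 0 0 0 -9 {geno}\n")


def write_pedigree(path, dataset) -> None:
    dataset.pedigree.to_csv(path, sep="\t", index=False)


def write_grm_text(path, grm, ids) -> None:
    """Lower-triangular GRM as (id1, id2, m, value) rows."""
    with open(path, "w") as fh:
        fh.write("id1\tid2\tm\tvalue\n")
        v = grm.values
        for i in range(v.shape[0]):
            for j in range(i + 1):
                fh.write(f"{ids[i]}\t{ids[j]}\t{grm.m}\t{v[i, j]:.6g}\n")


def write_gwas_table(path, result, *, qtn_flags=None) -> None:
    tab = result.table.copy()
    tab["dataset"] = result.dataset
    tab["scenario"] = result.scenario
    tab["significant"] = result.significant
    if qtn_flags is not None:
        tab["is_qtn"] = qtn_flags
    tab.to_csv(path, sep="\t", index=False)


def export_experiment(result, outdir) -> None:
    """Write all aggregated outputs of an experiment to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.metrics.to_csv(outdir / "metrics_long.tsv", sep="\t", index=False)
    result.summary.to_csv(outdir / "metrics_summary.tsv", sep="\t", index=False)
    result.snp_counts.to_csv(outdir / "snp_counts.tsv", sep="\t", index=False)
    result.fst.to_csv(outdir / "fst.tsv", sep="\t", index=False)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump({"schema": 1, "replicates": result.manifests}, fh, indent=2)
    for (name, scenario), figs in result.figures.items():
        figs["manhattan"].to_csv(
            outdir / f"manhattan_{name}_{scenario}.tsv", sep="\t", index=False)
        figs["power_by_variance"].to_csv(
            outdir / f"power_by_qtn_variance_{name}_{scenario}.tsv",
            sep="\t", index=False)
        pd.DataFrame({"maf": figs["maf"]}).to_csv(
            outdir / f"maf_{name}_{scenario}.tsv", sep="\t", index=False)
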