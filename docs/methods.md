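# Methods

## The simulated system

`qtlcross` studies how well single-marker mixed-model GWAS on
whole-genome variant data maps causal variants (QTN) in experimental pig
F2 crosses.  Everything is simulated; no external data enter the
pipeline.

### Breed history

Three founder breeds descend from one ancestral diploid Fisher–Wright
population via `pig_demography_plan()`:

* ancestral population: 6400 generations at Ne 3500, starting
  monomorphic (mutation–drift build-up only; the ancestral population is
  deliberately *not* required to be at equilibrium, matching the stated
  protocol length);
* split into a European and an Asian lineage at generation 6400; both
  run at Ne 800 until generation 9915, then Ne 600;
* the Asian lineage continues at Ne 600 until 9975 (the schedule between
  9960 and 9975 is not stated by the protocol; we continue the preceding
  epoch) and finishes at Ne 300 at generation 10000, giving breed AS;
* the European lineage splits at generation 9960 into breeds EU1 and
  EU2, each at Ne 400 until 9975 and Ne 150 until generation 10000.

The genome is 10 chromosomes of 1 Morgan.  Recombination follows the
Haldane mapping function (Poisson crossover counts, uniform positions,
no interference).  Mutation is infinite-sites: Poisson(2) new mutations
per chromosome per transmitted gamete at continuous uniform positions,
so every SNP arises inside the simulation.  Mating is monoecious random
mating with selfing allowed in the breed-history phase (negligible at
these sizes; switchable via `allow_selfing`), and without selfing in the
experimental generations.

### Desk-scale rescaling

`rescale_plan(plan, lam)` divides every Ne and epoch length by `lam` and
`GenomeSpec.rescaled(lam)` multiplies the mutation rate by `lam`,
preserving drift intensities t/(2Ne) and the population-scaled diversity
4·Ne·µ up to integer rounding.  The shipped default is `lam = 10`
(minutes per demography run instead of hours).  `lam = 1` reproduces the
full-scale history.

A second, larger reduction is used for the test suite and the acceptance
script: the mutation rate is left at its base value
(`rescale_mutation=False`), i.e. roughly 10× fewer variants than the
θ-preserving desk run.  Under neutral infinite sites the frequency
trajectory of each variant is independent of the mutation rate, so
per-variant statistics — the allele-frequency spectra and Weir–Cockerham
F_ST — are unchanged (verified empirically: F_ST 0.085/0.778 at reduced
density vs 0.091/0.779 at full desk density); only variant *counts*
scale down.  Mapping-power levels rise with the milder Bonferroni
correction, but the orderings between datasets, which is what the
reduced runs are used to check, are preserved.  The methods' problem
sizes: 10 population replicates × 1 trait replicate each.

### Engine

Haplotypes are rows of per-chromosome packed-bit matrices with columns
sorted by position, so a crossover maps to a contiguous column range and
a gamete is a few word-range copies.  Mutations younger than the
consolidation interval (50 generations, also the fixed/lost pruning
interval; any interval gives identical segregating output) live in
per-haplotype sorted position lists, because most die within a few
generations.  Consolidation merges survivors into the matrix, drops lost
columns and moves columns fixed within a lineage to a per-lineage
`fixed` list — they are invariant within the lineage but still matter
between lineages (divergently fixed variants segregate in crosses and
dominate the AS×EU2 results).  Position collisions (probability ~2⁻⁵²
per pair) are merged as recurrent mutations.  All randomness flows from
one `SeedSequence` root, split per lineage, so lineage simulation order
cannot change results and runs are bit-reproducible.

### Experimental populations

Each F2 cross takes F0 sires from the paternal breed (2 or 10) and F0
dams from EU2 (10 or 50), produces exactly 10 male and 50 female F1
(dams partitioned evenly across sires, round-robin litters, sexes
assigned deterministically to hit the quota), and mates each F1 male to
five exclusive F1 females with litter size 10 → 500 F2.  The EU2
founder animals of the two crosses are disjoint.  The purebred
comparison population applies two generations of random mating within
EU2 (1000 offspring; the 500-animal dataset is a random subset).

At `lam = 10` the terminal breeds (15–30 diploids) are smaller than the
founder demand, so the pipeline appends one extra random-mating
generation sized to the total founder demand before sampling
(`founder_pool`).  At `lam = 1` the breeds are large enough and no
expansion occurs.

### Traits

Per trait replicate: 20 QTN per chromosome (200 total) drawn uniformly
from the variants segregating in the union of the three breeds — this
includes variants fixed in one breed but segregating in a cross — with
pairwise spacing ≥ 2 cM (greedy randomized selection with restarts).
Additive effects are i.i.d. t(4) (variance 2, heavy tails).  Breeding
values are BV(x) = Σ (x_j − 2p_j) a_j with p_j the pooled-F2 frequency
(cross analyses) or the purebred population frequency (EU2 analyses).
Residuals are Gaussian with σ²_E = σ²_A (1 − h²)/h², h² = 0.5, with
σ²_A the empirical BV variance of the anchoring dataset, so the pooled
data hit the target heritability exactly at construction and single
crosses reuse the same residual draw (one phenotype per individual).

### Association model

y_i = µ_{k(i)} + b_j x_ij + g_i + e_i, with one fixed mean per cross,
g ~ N(0, G σ²_g) and a standardized-dose GRM built from the analysed
variant set while leaving out the tested variant's chromosome (LOCO).
Variance components are profile-REML estimates on the variance ratio via
the GRM eigendecomposition (121-point log grid + golden-section
refinement to 10⁻⁶ on the heritability ratio; deterministic), computed
once per LOCO GRM under the null.  Each variant is then tested by
whitened GLS with a Wald normal p-value (t vs normal is immaterial at
n = 500–1000).  Marker blocks above 10⁶ entries are rotated in float32
for speed (double precision statistics thereafter); smaller problems run
entirely in float64 and match a textbook GLS to ≥ 10 significant
digits.  Multiple testing: Bonferroni over the analysed set.

### Scenarios and metrics

MAF filtering keeps variants with MAF ≥ 0.05 in the analysed dataset
(the removal rule "below 0.05"; a strict `>` variant is available).  FSG
additionally requires MAF > 0.05 in breed EU2.  QTN power, QTL power
(1 cM QTN-centred windows, closed boundaries, truncated at chromosome
ends) and QTN precision are defined in `metrics.py`; precision divides
by the *significant* window variants by default, with the
all-window-variants denominator available
(`precision_denominator="all"`) because the defining prose supports both
readings.  Ties at the QTN's p-value do not count as beating it.
Undefined replicate values (no analysable QTN, no significant QTN) are
excluded from aggregation with the valid-replicate count reported.

## Known limitations

* The Weir–Cockerham F_ST between the simulated breeds follows from the
  demographic plan: about 0.08–0.09 (EU1–EU2) and 0.78 (AS–EU2) — these
  match neutral-theory arithmetic for the stated epochs, and the
  EU1–EU2 ≪ AS–EU2 ordering holds in every run.  Published values for
  comparable real breed pairs are lower; see the README's reproduction
  notes.
* No selection, dominance, epistasis, sex chromosomes or
  genotype-by-environment effects; traits are neutral by construction.
* The synthetic breeds used in unit tests (`tests/conftest.py`) are
  Hardy–Weinberg draws without LD; they exercise Mendelian plumbing, not
  population structure.  Study-level properties are tested on the real
  simulator output.
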