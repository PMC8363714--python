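# Methods

`clonesel` infers which mode of selection governs a clonally evolving
blood cell population from the summary statistics of its somatic
variant-allele-frequency (VAF) spectrum.  The inference is
simulation-based: a forward clonal model generates populations under
known evolutionary parameters, a fixed 16-statistic summary reduces each
population (simulated or observed) to a feature vector, and an ensemble
of multi-task neural networks maps features to an evolutionary class
and parameter estimates with ensemble uncertainty.

## Forward clonal model

A haploid pool of `N` hematopoietic stem cells evolves by discrete
Wright–Fisher generations with no recombination.  Offspring counts per
clone are multinomial with weights `count × fitness`; clone fitness is
multiplicative over its mutations, `Π(1 + s_i)`, floored at 0.  Every
offspring cell acquires new mutations with genome-wide rate `μ·L`
(Poisson, infinite sites) over a region with a 1:2 ratio of synonymous
to nonsynonymous sites.  Synonymous mutations are neutral.  A
nonsynonymous mutation is beneficial with probability `p` (selection
coefficient `+Gamma(α_p, β_p)`), otherwise deleterious
(`−Gamma(α_n, β_n)`); a degenerate gamma (mean 0) yields `s = 0`.
Beneficial mutations arise in the driver-gene territory (a fixed
fraction of sites, default 10%); other mutations land there at the
background rate, so the driver-count statistic is informative but not a
class oracle.

Four parameters define a model — `μ`, `p`, and the two gamma means
`s_p = α_p/β_p`, `s_n = α_n/β_n` — and collapse deterministically into
four classes: **neutral** (`p = 0`, both means 0), **positive** (`p > 0`,
`s_p > 0`, `s_n = 0`), **negative** (`p = 0`, `s_n > 0`), and
**combination** (`p > 0`, both means > 0).  Tuples outside these four
cells (e.g. `p > 0` with `s_p = 0`) are rejected as ill-formed.

The state is clone-compressed as a mutation tree (each node one
mutation, a clone = a root path with a cell count), which is exact for
asexual populations and keeps memory proportional to the segregating
ancestry rather than to `N`.  The production path is a numba kernel;
a readable `CloneTable`/`step_generation` reference implementation of
the identical update rule is kept and cross-checked distributionally in
the tests.  Populations whose total fitness mass reaches zero raise a
degenerate-population error.

A simulation returns the segregating (non-fixed) mutations with
`vaf = cell fraction ≥ vaf_min` (default 0.1%, the resolution of a
5000× panel).  Cell fractions are reported directly as VAFs with no
diploid halving (observed blood VAF spectra extend above 0.8, which a
heterozygous-diploid read model would forbid).

### Scales

Parameters are quoted at a reference scale: `N_ref = 10,000` cells
(a classical estimate of the human HSC pool) over `L_ref = 1 Mb`.
Simulating that scale across a 4-class grid is expensive, so the
default **desk scale** uses `N = 1,000` cells over `L = 20 kb` for 500
generations.  Per-site mutation rates and selection coefficients are
multiplied by `N_ref/N`, holding the population-scaled quantities `N·μ`
(per site) and `N·s` invariant; overall diversity `θ ∝ N·μ·L` is
reduced by the shorter region (×1/50).  Consequences:

- class signatures that depend on `N·s` (sweep dynamics, purifying
  efficacy) are preserved;
- statistical precision of ratio statistics (pN/pS), which scales with
  the number of segregating sites, is roughly 7× lower than at full
  scale.  This is the binding constraint on class discrimination (see
  *Known limitations*).

Run length is 500 generations from a monomorphic start rather than the
long-run default of `10·N`: blood populations are not at neutral
equilibrium over a human lifetime, and near-equilibrium runs were found
to *reduce* positive-vs-combination separability by letting recurrent
sweeps dominate the spectrum.  `SimConfig.full_scale()` restores the
reference scale for users with the budget.

### Parameter grids

Per class, grid points are drawn as: `μ` log-uniform in
`[1e−7, 1e−5]` per site per generation; `p ~ U(0.05, 0.5)` plus a 15%
weight on `p = 1` (pure positive selection) for the positive class;
beneficial means log-uniform in `[0.005, 0.05]` with shapes
`U(0.5, 2)` — driver effects strong enough to sweep (`N·s ≥ 50`).
Deleterious means are class-specific: the negative-only grid is
concentrated in the nearly-neutral regime, log-uniform in
`[3e−5, 7e−4]` (`N·s ≈ 0.3–7`) with L-shaped gamma shapes
(log-uniform `[0.3, 2]`), reflecting passenger fitness costs hovering
at the drift barrier; combination models use the strong core
`[0.02, 0.05]` with shapes `U(1, 3)`, since only non-negligible
passenger costs interact dynamically with driver sweeps.  These ranges
are the package's scaled-down study conditions: they reproduce the
qualitative structure of the classification problem (selection-bearing
classes recovered best; neutral and negative mutually confusable) at a
tractable θ.  A separate *novel grid* shifts every shape and range for
generalization probes.

## Sequencing observation model

Deep targeted sequencing is emulated per variant as
`reads ~ Binomial(depth, vaf)` (default depth 5000×), split
`Binomial(reads, 1/2)` between strands.  A variant is retained only
with ≥ 5 supporting reads and ≥ 2 per strand — the duplex-panel
retention rule — and its observed VAF is `reads/depth`.  No sequencing
error, contamination, or consensus artifacts are modeled; the observation
model exists so that detection thresholds and read-support filtering
affect simulated and observed data identically.

## Summary statistics

The ordered 16-vector: total / silent / missense mutation counts;
silent and missense counts in low (< 0.1), intermediate ([0.1, 0.8]),
and high (> 0.8) VAF bins; overall and per-bin pN/pS (per-site missense
proportion over per-site silent proportion); Tajima's D; Fay & Wu's H;
and the driver-territory mutation count.  D and H are computed on an
unfolded pseudo-sample site-frequency spectrum obtained by rounding each
VAF to a derived count out of `n = 100` genomes, clipped to `[1, n−1]`
(detected ultra-rare variants stay singletons; fixed variants are
excluded).  `H = θ_π − θ_H` in its unnormalized form.  Undefined
statistics (no segregating sites; zero silent counts in a ratio) are
imputed as 0 and flagged; the count features disambiguate "no data"
from a true zero.  The layout carries a version tag stored in trained
models, which refuse mismatched extractors.

## Ensemble classifier

Each member is a multi-task MLP: 16 inputs, three ReLU hidden layers
(512 units at reference scale; 128 at desk scale), dropout 0.1 after
each hidden layer, a 4-unit softmax classification head, and four
1-unit linear regression heads for (`log10 μ`, `p`, `s_p`, `s_n`).
Loss is sparse categorical cross-entropy plus the sum of per-head MSEs
with equal weights; training is Adam (step size 1e−3, the optimizer
default) with batch 500 for 20 epochs.  The implementation is plain
numpy with explicit backpropagation, gradient-checked against finite
differences in the tests, and bit-reproducible for fixed seeds.

Simulations are split 90/10 by simulation; any test row whose feature
vector is bit-identical to a training row is removed from the test set
(leakage guard).  Each of the ensemble's members (10 at reference
scale; 3 at desk scale) trains on its own class-balanced bootstrap of
the training split — `size/4` rows per class drawn with replacement
(250,000 rows at reference scale; 20,000 at desk scale).

Numerical choices: count-valued features are `log1p`-transformed before
z-scoring with train-split statistics (counts span four orders of
magnitude under a log-uniform μ grid); regression targets are z-scored
during training and de-standardized at prediction (raw target scales
differ by orders of magnitude and would dominate the joint loss).  All
constants live in the HDF5 model artifact together with hyperparameters,
per-member seeds, and the feature-layout version.

Prediction reports the mean and standard error of each softmax
probability and each regression head across members; the class is the
argmax of the mean softmax, with ties broken by the fixed class order
(neutral < negative < positive < combination) and flagged.

## Cohort application

Per-subject variant tables (TSV or VCF) are annotated against a gene
panel (driver flags; unknown genes default to non-driver with a
warning), filtered by the read-support rule when strand counts are
present, featurized with the same extractor, and classified.  Downstream
summaries follow the study's definitions: class proportions per 10-year
age bin and case/control status with `SE = sqrt(p(1−p)/n)` and
chi-squared case-vs-control comparisons (scipy); mutation-rate
estimates rescaled across assumed HSC pool sizes by θ-invariance
(`μ_new = μ̂ · N_ref/N_new`, exact round-trip); the dominant clone
(highest-VAF variant, ties broken by CADD then first occurrence,
flagged) with width-10 CADD bins; driver-vs-passenger mean ± SEM CADD
per class with rank-sum comparisons; and the gene sets harboring
function-altering (CADD > 10) mutations per class with all exact
class-combination intersections.

## Synthetic cohorts

Because the real cohort is controlled-access, the fixtures module
generates fully synthetic cohorts: a 261-gene panel (driver flags on a
named AML driver subset; lognormal coding lengths), per-subject
class-conditional simulations passed through the sequencing model,
length-weighted gene assignment (beneficial mutations restricted to
driver genes, mirroring the simulator's territory convention),
metadata (ages uniform on 36–74.4; case follow-up 0.03–12.4 years,
control 3.36–14.9), and a ground-truth table.  Synthetic CADD scores
are baseline noise (N(5, 3) clipped at 0) plus a positive shift
(N(10, 3) clipped at 0) for mutations with nonzero selection
coefficients — a deliberately simple construction that gives
pathogenicity summaries the right *direction* of signal, not a model of
real CADD distributions.  Passing fixture-based tests therefore
demonstrates pipeline correctness and end-to-end class recovery, not
performance on real duplex-sequencing data.

## Known limitations

- At desk-scale θ, positive-vs-combination discrimination is
  information-limited at roughly 85–92% (a random-forest ceiling on the
  same features is ≈ 75–80%): detecting the purifying component of a
  combination model requires precise pN/pS contrasts that need more
  segregating sites than a 20 kb region provides.  The full-scale study
  this package scales down reports 97–99% for these classes at 50×
  larger θ.
- The neutral-vs-negative boundary is intentionally hard (nearly-neutral
  deleterious grid); per-class accuracies for those classes are
  sensitive to the training-corpus realization by a few points.
- No demography, cell hierarchy, recombination, or sequencing-error
  model; VAF noise is purely binomial.
- The pseudo-sample SFS mapping (`round(vaf·n)`, clipped to `[1, n−1]`)
  is deterministic, not a hypergeometric subsample: every detected rare
  variant becomes a sample singleton with certainty, so for `n ≪ N` the
  D and H features carry a structural singleton excess (negative D
  shift).  The shift is identical across classes and harmless as a
  classifier input, but it means the feature-space D is a
  detection-thresholded statistic, not an unbiased sample D.  The
  neutrality gate in the tests is therefore evaluated on the full
  population spectrum (`sample_n = N`), where the mapping is exact;
  the small residual negative expectation of whole-population D in a
  discrete Wright–Fisher genealogy there was cross-checked against an
  independent coalescent simulator (msprime, DTWF model) and matches.
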