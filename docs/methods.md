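# Methods

`pedlink` implements the computational chain by which a dominant disease
locus is mapped in multiplex families and its susceptibility gene
identified and characterized: parametric multipoint linkage, a
simulation-based genome-wide significance procedure, an exome
rare-variant filter cascade with subset sharing, founder-haplotype
analysis, and case-control association. This note records the models,
their assumptions, the numerical choices, and what the synthetic-data
generator does and does not emulate.

## Disease model

All parametric stages share one autosomal-dominant disease model: risk
allele frequency `q` (default 2×10⁻⁵), phenocopy rate `f = P(affected |
dd)` (default 10⁻⁶), and carrier penetrances `P(affected | Dd)` and
`P(affected | DD)` (default 1.0, configurable — studies of this kind
usually take penetrance from a prior segregation analysis rather than
estimating it). Affection is two-valued: *affected* or *unknown*. With
incomplete, age-dependent penetrance an unaffected relative is nearly
uninformative, so unaffecteds are scored as phenotype-unknown
("affected-only" analysis); phenotype-unknown members contribute a
likelihood factor of 1 wherever penetrance enters. An `unaffected` code
on input is accepted and coerced to unknown with a logged notice.

## Single-locus pedigree likelihood

`linkage.single_locus_likelihood` computes the exact joint likelihood of
one marker and the disease locus at recombination fraction θ. Each
individual carries two haplotype variables (paternal, maternal), each a
(disease allele, marker allele) pair; founders get the product prior
`P(d)·freq(a)`, transmission factors implement recombination
(`(1−θ)/2` for parental-phase-preserving gametes, `θ/2` otherwise), and
unary factors encode penetrance (affecteds only) and the observed
unordered marker genotype. The likelihood is evaluated by sum–product
variable elimination with a greedy smallest-factor order. Eliminating
haplotypes rather than whole genotypes bounds every factor by (2k)³ for
a k-allele marker. This is pedigree peeling in its graphical-model form;
because elimination handles cyclic factor graphs, consanguinity loops
need no explicit loop breakers (`loop_breakers` is accepted for API
compatibility but unused) — the cost simply grows with loop complexity.

Two-point LOD scores are `log10 L(θ) − log10 L(1/2)` summed over
families.

## Multipoint linkage (inheritance-vector HMM)

The multipoint engine follows the classic inheritance-vector
formulation. The hidden state at a locus is one bit per non-founder
meiosis recording which grandparental allele was transmitted (2·n bits
for n non-founders, full state space 2^B up to a configurable cap,
default 16 bits). Between adjacent loci each bit flips independently
with the Haldane recombination fraction θ(d) = (1 − e^(−2d/100))/2 of
the intervening distance; the transition operator therefore factorizes
per bit and is applied in O(B·2^B). Marker emissions sum all
founder-allele assignments consistent with the observed genotypes under
the descent pattern (computed by backtracking with pruning, deduplicated
over states that induce the same descent pattern on typed members); the
disease emission marginalizes founder disease alleles at frequency `q`
and applies penetrance to affecteds.

At a queried position x,

    LOD(x) = log10 [ Σ_v P(v_x = v | markers) · P(aff | v)
                     / ( 2^(−B) Σ_v P(aff | v) ) ],

summed over families; the denominator is the exact unlinked likelihood
of the affection pattern. Scaled forward–backward recursions give the
posterior at markers and between them. Forward–backward quantities are
computed once per family per chromosome and reused across disease
models, which makes the allele-frequency sensitivity sweep nearly free.

Design choices: the Haldane map function is used in both the simulator
and the likelihoods (memoryless recombination makes the HMM exact, and
generator/model consistency is required for parameter-recovery tests to
be meaningful); the full 2^B state space is used rather than a
founder-symmetry-reduced one — per-bit factorized transitions make the
full space fast at the package's scale, and the reduced space's
transition kernel is easy to get subtly wrong. LOD maxima report the
leftmost position on ties.

Haplotypes are reconstructed by the Viterbi path over the same HMM
(ties broken toward the lowest-index vector); alleles are imputed only
where the chosen path forces them, and a meiosis is flagged resolved
only when its posterior flip probability is beyond 0.95 (configurable) —
uninformative meioses are reported as unresolved, never guessed.

### Known sensitivity of the LOD to the assumed allele frequency

The LOD is nearly invariant to the assumed disease allele frequency while
`q` is small, because numerator and denominator are both dominated by
single-carrier founder configurations of weight ∝ 2q, which cancel. At
larger `q` (≈10⁻²) configurations with two carrier founders (weight ∝
(2q)²) start to matter, and they benefit the unlinked denominator more
than the peak: for the default synthetic families (ten members, four
founders, four to six affecteds) the maximum LOD drops by about 5% at
q = 0.01 while changing by <1% across 10⁻⁶–10⁻³. How flat the sweep is
at q = 0.01 is a property of the pedigree structure (specifically the
number of two-allele explanations of the affection pattern per
one-allele explanation); published claims of <1% invariance up to
q = 0.01 are data-dependent statements about the particular families
analyzed, and the corresponding check on the synthetic scenario fails at
the q = 0.01 point — deliberately left failing rather than reshaping the
generator around it.

## Genome-wide significance by gene dropping

The observed affection patterns are held fixed; marker genotypes are
re-dropped from founder allele frequencies down the same pedigrees,
unlinked to disease. Each replicate records the genome-wide maximum
multipoint LOD; the summary reports the median, the 2.5/97.5 empirical
percentiles of the maxima (a percentile interval of the null maxima, not
a CI of the median), and the overall maximum. The empirical p of an
observed peak is `(1 + #{max ≥ observed})/(n_reps + 1)` — never zero by
construction. On small pedigrees the maximum-LOD statistic has discrete
atoms (e.g. the all-meioses-nonrecombinant ceiling), so calibration
tests use the randomized probability integral transform (uniform
tie-breaking jitter), and uniformity is checked over independent
replicates, each with its own null table — p-values sharing one
reference table are jointly dependent and would over-reject any
goodness-of-fit test.

## Exome filter cascade

Per-case annotated variant tables pass through, in order: a strict
quality filter (depth > 8, consensus quality > 30, mapping quality > 20
— strict inequalities); a functional-class filter (missense, nonsense,
splice-site, indel); known-catalog exclusion; control-exome exclusion;
gene collapse (a gene counts for a case if any surviving variant of that
case hits it, tolerating allelic heterogeneity); k-of-n subset sharing
(with the full k-sweep reported, so the effect of assuming genetic
heterogeneity is visible); and intersection with the linkage locus
(1-based closed intervals, ≥1 bp overlap). Variant identity across cases
and catalogs is the left-normalized (chromosome, position, ref, alt)
key; indel normalization trims shared suffix then prefix (anchors of
pure indels remain representation-dependent without a reference genome,
so all inputs to one cascade must share an anchoring convention, as
caller outputs do). Per-case
counts are recorded at every stage; they are non-increasing by
construction through the variant-level stages, and the known/control
exclusion stages commute.

## Founder-haplotype analysis

Transmission phasing assigns child alleles to parental origin wherever
Mendelian logic forces a unique assignment (untyped parents are
wildcards); both-parents-and-child heterozygous stays unresolved. The
family's risk haplotype over the rare-variant panel carries a variant
when every typed affected member carries its rare allele — for variants
at ~1% control frequency, joint carriage across all affecteds identifies
the co-segregating haplotype content; ambiguous positions are scored
non-carrying (conservative) and logged. Identical presence/absence
vectors merge into haplotype classes (class 1 reserved for the
collective non-risk label; risk classes numbered by descending family
count). The core region is the intersection of the classes' carried
spans — the maximal interval on which every risk class retains the
founder alleles after historical recombination; an empty intersection is
a meaningful result, not an error.

The chance that an m-variant haplotype assembles from independent rare
alleles is `2^m · Π pᵢ` (each variant can arrive on either parental
chromosome). With the published rounded control frequencies (0.012,
0.014, 0.013, 0.022, 0.010) this is 1.5×10⁻⁸; with the exact count
fractions (9, 11, 10, 17, 8)/768 it is 1.6×10⁻⁸ — both are reported,
since the published figure derives from the rounded inputs.

Segregation checking asks whether every affected member of every family
carries ≥1 risk allele; unaffected carriers are reported as
reduced-penetrance evidence and never counted as failures.

## Case-control association

For each stratum and a pooled total: odds ratios `ad/(bc)` with Woolf
CIs `exp(ln OR ± 1.96·√(1/a+1/b+1/c+1/d))`; Pearson χ² (no continuity
correction) with the upper-tail p computed in log space via the scaled
complementary error function (`log p = log erfcx(z) − z²`, z = √(x/2)),
keeping −log₁₀ p exact far beyond float underflow (needed because
near-monogenic association signals reach p ≈ 10⁻¹²⁰); Hardy–Weinberg
goodness of fit (1 df, at the sample allele frequency); allele
frequencies; the Cochran–Armitage trend test (scores 0/1/2) and a
per-allele logistic odds ratio (damped Newton–Raphson on the aggregated
3×2 table, gradient tolerance 10⁻¹⁰, Wald CI) for the additive model.
Zero-cell tables get the Haldane–Anscombe +0.5 correction and are
flagged; logistic separation (including the underflow-masked variant
where the gradient vanishes at an absurd slope) falls back to the same
correction, flagged. Reports render ORs, CIs, MAFs and p-values at two
decimals with half-up rounding, the convention of the published tables
(135.625 prints as 135.63). No multiple-testing adjustment is applied —
model-wise values are reported raw, as in the source tables.

The dominant/recessive −log₁₀ p values and additive ORs printed in the
published association table do not match any standard formula that also
reproduces its allelic values and ORs (the logistic per-allele OR for
the Japanese stratum, for instance, is 265.5 against a printed 244.58);
those cells are therefore documented as engine-specific and not treated
as reference values. Likewise the published ">80%" power claim for
detecting a 2%-frequency allele in 70 chromosomes: the closed form
`1 − (1 − maf)^n` gives 75.7%, and both values are surfaced rather than
guessing the intended basis.

Population-attributable risk is `100·(K − y)/K` with K the case count
and y the non-carrier (phenocopy) cases.

## Synthetic-data generator

The generator produces every input the pipeline consumes, with known
ground truth:

* **Gene dropping.** Founder haplotypes are drawn per locus from the map
  allele frequencies; each meiosis recombines between adjacent loci with
  Haldane probability. A disease locus can be planted on the map; for
  ascertained multiplex families exactly one disease allele is planted
  on a chosen founder's haplotype (drawing carriers at 2×10⁻⁵ would
  essentially never produce one), affection is sampled from penetrance
  given dose, and families are rejection-sampled until a
  minimum-affected rule holds — mimicking multiplex-family collection.
  Defaults emulate a genome scan's stated design: eight three-generation
  families (founder couple, two married-in children, two grandchildren
  per couple), 22 autosomes with markers every 10 cM and equifrequent
  alleles (4 per marker — a compromise between microsatellite
  informativeness and state-space cost), disease allele frequency
  2×10⁻⁵, phenocopy 10⁻⁶, penetrance 1.0, at least four affecteds per
  family. Tests and the acceptance checks run the same families on
  down-sampled maps (one or two chromosomes) — stated here as the
  package's own problem-size choice.

* **Exome tables.** Catalog-known common sites form a shared pool
  (present in each case with probability 0.8); unknown background sites
  are private per case, with a stated fraction also placed in the
  control panel; qualities fall below the filter thresholds at a stated
  rate; one causal variant is planted in k of n cases, in a configurable
  gene inside the locus, always passing quality and absent from catalog
  and controls. Defaults (6,600 functional calls per case, 85%
  catalog-known, 40% of the rest control-shared, 5% quality failures,
  18,000 genes of which 21 in a 1.5-Mb locus) reproduce the magnitude of
  a typical early exome study's per-stage counts. Not emulated: linkage
  disequilibrium between background sites, shared rare variation between
  cases beyond the common pool, sequencing-read noise — so passing
  cascade tests demonstrates the filter semantics and the isolation
  power of k-of-n sharing plus locus intersection, not robustness to
  correlated real-exome structure.

* **Case-control counts.** Controls are multinomial under Hardy–Weinberg
  at the stated risk-allele frequency; cases follow a carrier-odds-ratio
  model (carrier odds multiplied by the planted OR; carriers split
  het/hom by the control conditional proportions). Defaults: 161 cases,
  384 controls, control allele frequency 0.014, carrier OR 100.

All generators are deterministic given their seed.

## Numerical and degenerate-input conventions

Forward–backward vectors are renormalized each step (scale-free, since
only posteriors are needed); zero-likelihood marker configurations raise
with a pointer to the Mendelian checker; a flat disease emission
(phenocopy = penetrance) yields LOD 0 rather than 0/0; monomorphic
samples give HWE p = 1; degenerate 2×2 margins give χ² = 0; empirical
percentiles warn below 100 replicates. Coordinates are 1-based closed
throughout; genotypes are unordered pairs with 0/half-missing coerced to
missing (logged).

## Limitations

X-linked and mitochondrial models, multi-locus disease models,
nonparametric (NPL) scoring, interference-aware map functions,
population-scale statistical phasing, and variant calling itself are out
of scope. Pedigrees are capped at 16 meiosis bits (configurable) —
larger sibships must be split. The additive-model engines of commercial
association suites are not reverse-engineered (see above). The
rare-variant panel's risk-haplotype rule assumes panel variants are rare
enough that joint carriage across affecteds implies co-transmission;
common variants would need true phase.
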