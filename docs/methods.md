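# Methods

This note records the models, estimators, numerical choices and known
limitations behind `snpld`, in the order the pipeline applies them.

## Genotype representation

Genotypes are allele-B dosages {0, 1, 2} in a samples × loci int8 matrix
with −1 for missing calls.  Allele orientation follows the PED reader's
rule: the first allele code observed at a locus is alleleA, and the dosage
counts copies of the other (alleleB).  PED/MAP text cannot encode which
allele is "B" when the first non-missing genotype is homozygous for it, so
panels are canonicalised (loci flipped so the first non-missing genotype
contains alleleA) by the generator and by `canonicalize_orientation()`;
after canonicalisation the write→read round trip is an exact identity on
the dosage matrix.  All LD magnitudes, MAF, call rate and the HWE test are
invariant under orientation flips; only D's sign depends on it, which is
why the sign is reported but not interpreted.

## Quality control

The cascade removes loci in three ordered stages — non-autosomal (X, Y,
MT), Hardy–Weinberg failure, then call rate or MAF — so each locus is
counted once and the stage counts partition the input.  Thresholds
(defaults: HWE p < 10⁻⁷, MAF < 0.05, call rate < 90%) are strict
inequalities; boundary loci are retained.  The call-rate and MAF filters
are merged into one reported stage because they are applied, and usually
reported, together.

The HWE test is the conditional exact test: given the observed allele
counts, the probability of every attainable heterozygote count is summed
over those no more probable than the observed one (two-sided by probability
mass, no mid-p).  The weights 2^h·C(n,h)·C(n−h,n_AA) are integers and share
a denominator, so the p-value is computed in exact rational arithmetic and
converted to float once — the test is exactly reproducible and is verified
against an independent factorial-form enumeration for every configuration
with n ≤ 50.  A chi-square variant (`hwe_method="chisq"`) is provided for
very large cohorts; at p < 10⁻⁷ the two flag nearly identical loci.

All QC statistics are computed on the panel pooled across populations, as
multi-breed studies do.  Pooling breeds with different allele frequencies
creates Wahlund heterozygote deficits, so loci strongly differentiated
between populations — including loci monomorphic in some populations — can
fail the pooled HWE test even though each population is internally in
equilibrium.  This is faithful to pooled-QC practice and is visible in the
synthetic study (the HWE stage removes slightly more loci than were
explicitly planted); per-population QC is deliberately not offered.

MAF spectra and monomorphic-marker sets are per-population and are assessed
on the QC-retained panel, where pooled filtering leaves each population
with its own monomorphic residue; the overlap statistic
|M_ref ∩ M_others| / |M_ref| measures shared ancestry signal in those sets.

## Haplotype-frequency EM

For two biallelic loci, the 3×3 unphased genotype table is a complete
sufficient statistic.  Every genotype except the double heterozygote
determines its two gametes; the double heterozygote is AB/ab or Ab/aB.  The
E-step splits it with weight p_AB·p_ab / (p_AB·p_ab + p_Ab·p_aB) and the
M-step counts gametes, which preserves the observed allele frequencies at
every iteration (verified to 10⁻¹²).  Convergence is declared when the
largest frequency change falls below 10⁻¹⁰ (cap 1000 iterations; the
converged flag is reported).  At that stopping rule the log-likelihood is
within ~2·10⁻⁹ of the continuous optimum, which sets the comparison slack
used when checking EM against a profile-likelihood grid.

The profile likelihood in p_AB can be bimodal (coupling vs repulsion
phase), and the linkage-equilibrium point can be a stationary stall.  The
EM therefore runs from three deterministic starts — D = 0 and D = ±Dmax/2 —
keeping the highest final likelihood and breaking ties (Δloglik < 10⁻⁸)
toward smaller |D|.  There is no randomness anywhere in the estimator.

A vectorised batch engine runs the same iteration over many pairs at once
(converged pairs are compacted out each sweep); the scalar API wraps a
batch of one, and tests assert scalar/batch agreement to 10⁻¹².

## LD statistics

D, D′, r² are computed from the fitted gamete frequencies with the standard
definitions (see README).  D′ is set to 0 when D = 0, since the Dmax branch
is undefined there.  Pairs are analysed with pairwise-complete deletion;
n in the r² correction is the pair-specific allele count 2 × (complete
individuals), since a panel-wide n would misstate the sampling noise of
pairs with missingness.  `correct_r2` floors at 0 by default because a
negative "squared correlation" has no interpretation; `floor=False` gives
the exact formula.  A pair is skipped (and counted, by reason) when fewer
than two complete individuals remain or either locus is monomorphic in the
complete subset.

One calibration fact worth knowing: for EM-based r̂² from unphased diploids,
the chance level at linkage equilibrium is ≈ 1/n_individuals, about twice
the 1/n_alleles that the correction subtracts (the classical 1/n law is for
gamete samples).  The corrected statistic therefore retains a small
positive bias at long distances, visible as a plateau of the decay curve's
tail; tests assert the corrected mean is at the chance-level scale, not
zero.

## Decay summaries

Distance classes default to 1–50 kb, 50–100 kb, 100–500 kb and 0.5–1 Mb,
half-open (lo, hi] with the first bin closed at 1 bp, so boundary pairs go
to the lower class and nothing is double-counted.  Summaries report mean,
population SD (divisor n) and pair count; empty classes report NaN.
"LD at 1/10/100 kb" point summaries use ±10% relative windows around each
focal distance (floored at the 1-bp minimum pair distance) — the window
width is a convention, exposed as a parameter.  Per-chromosome summaries
use all syntenic pairs within the 1-Mb ceiling; the adjacent-SNP summary is
a separate operation restricted to map-consecutive pairs, because the two
are both conventional "chromosome-level LD" figures and differ.  The
corrected r² is the default statistic for binned summaries; raw r² is used
for the focal-distance figures, and both appear in the per-pair tables.

## Synthetic data

Haplotypes come from a Gaussian copula: a latent stationary AR(1) process
along each chromosome with inter-locus correlation exp(−d/λ), thresholded
at each locus's target allele-frequency quantile.  λ (default 100 kb)
directly controls the distance–correlation map, which is the property the
decay analysis needs; the marginal at each locus is an exact Bernoulli draw
of the target frequency.  Diploids are random unions of two independent
haplotypes, so HWE holds except where violations are planted.  Default
study shape: 5 populations × 12 diploids, 2000 SNPs on 2 chromosomes of
15 Mb (≈15-kb spacing, chip-like density), allele-frequency spectrum
uniform on [0.05, 0.5] with a 20% low-MAF excess on [0.005, 0.05), and 2%
missing calls.

Planted defects are constructed, not sampled: HWE violations make every
sample heterozygous (exact-test p < 10⁻¹⁰ requires roughly ≥ 40 pooled
diploids; the generator refuses smaller cohorts), low-MAF loci carry a
single heterozygote (MAF = 1/2n, HWE p = 1), low-call-rate loci get 20% of
calls masked over a benign alternating genotype pattern, and per-population
monomorphic loci are forced to dosage 0 within the designated populations.
The truth record lists every planted index so stage counts can be asserted
exactly.  Duplicate samples perturb each non-missing call to a different
class with the given error rate (default 4%, chosen so the quality score of
a duplicate sits near 0.93, the reliability level typical of chip data).

What the generator does **not** emulate: coalescent genealogies and
recombination hotspots (LD structure is stationary AR(1), so long-range LD
is smoother than real data), ascertainment bias of chip SNP selection,
between-population frequency divergence beyond sampling (populations share
target frequencies), and per-sample artefacts (relatedness, sex errors).
Passing tests therefore certify the statistical machinery, not demographic
realism.

The two-locus Wright–Fisher simulator evolves the four gamete counts by
multinomial resampling of 2Ne gametes per generation, applying
recombination to the expected frequencies (Δ = −c·D), starting from linkage
equilibrium at allele frequencies 0.5.  Replicates where either locus fixes
in the population, or is monomorphic in the drawn sample, are dropped and
regenerated (r² is undefined there; the conditioning slightly enriches
intermediate frequencies, as in standard practice).  After 4Ne generations,
mean sampled r² at 4·Ne·c = 1 brackets Sved's 1/(1 + 4Nec) = 0.5 plus the
finite-sample inflation — the property-based acceptance check ties the
whole estimator chain to drift–recombination theory.

## Problem sizes used in checks

The acceptance-style checks run at desk scale, chosen to finish in minutes
while keeping each assertion statistically meaningful: 100 random tables of
20 individuals for EM-vs-grid; exhaustive HWE enumeration to n = 50; 200
frequency draws × 5000 diploids for parameter recovery (3·SE coverage with
binomial slack, mean |Δr²| ≤ 0.01 — the per-draw sampling SE of r̂² reaches
~0.008 at this n, so 0.01 is an aggregate guarantee); decay monotonicity on
2000 loci × 50 diploids at three seeds; 2000 Wright–Fisher replicates for
the Sved band.

## Known limitations

* Syntenic pairs only; inter-chromosomal LD and composite (Burrows) LD are
  out of scope, as are phased input and multiallelic sites.
* The HWE exact test's big-integer arithmetic is exact but O(n) per locus;
  for cohorts of many thousands use the chi-square option.
* The pooled-QC Wahlund caveat above: HWE removals conflate genotyping
  artefacts with population structure, by design of the emulated protocol.
* PED/MAP only (the era-appropriate interchange format); no BED/BIM/FAM or
  VCF.
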