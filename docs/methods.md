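# Methods

This note records the models behind `breedstruct`, the choices made
where the underlying procedures are conventionally under-specified, and
what the simulation-based validation does and does not establish.

## Pedigree model and metrics

A pedigree is a directed acyclic parent map with birth metadata.
Individuals without recorded parents are treated as *earliest
documented relatives* (EDRs) rather than true founders: in volunteer-
curated studbooks, missing parentage occurs both at breed formation and
whenever record keeping lapsed, so an EDR is any point where genetic
material enters the recorded population. An individual with exactly one
unknown parent contributes that unknown side as a distinct EDR.

**Validation and imputation.** `validate_pedigree` flags self-
parentage, ancestry cycles, sex-inconsistent parent roles and children
born before a parent; duplicate ids fail outright. Missing birth years
are imputed iteratively — full sibling's year, else parent's year + 2,
else offspring's year − 2 — using the 2-year standard generation
interval conventional for registry curation. Imputed records are
reported so downstream users can exclude them.

**Reference pedigree.** All metrics operate on a *reference pedigree*:
dogs born in a chosen window plus their complete ancestor closure.
Database members that neither fall in the window nor contribute to it
genetically are excluded, so the metrics describe the breed as it
currently exists.

**Completeness.** At generation *g* each dog has 2^g ancestor slots;
the proportion of filled slots, averaged over the reference population
and summed over generations, is the number of equivalent complete
generations g_e.

**Inbreeding.** F(x) is the kinship of x's parents under the
additive-relationship (tabular) recursion, memoized over the ancestor
closure; unknown parents enter as unrelated and non-inbred. Agreement
with Wright's path-counting formula Σ (1/2)^(n+n′+1)(1 + F_A) is exact
(≤ 1e−12 in tests). Depth-limited F treats any ancestor whose *minimum*
path distance from the individual exceeds the depth as unknown; because
truncation can only delete inbreeding loops, F(5) ≤ F(10) ≤ F(full)
individual by individual. Yearly mean F averages over all reference-
pedigree members born that year (ancestors included), which is what a
breed-history inbreeding timeline requires.

**Effective population size.** ΔF = (F̄_ref − F̄_par)/(1 − F̄_par)
compares the reference cohort with the set of their parents, and
N_e = 1/(2ΔF). When mean inbreeding has not increased the result is
reported as explicitly undefined rather than as a negative number.

**Gene-origin diversity.** Expected contributions are propagated down
the pedigree (each dog passes half its expectation per offspring path):

* EDR_e = 1/Σ p_i² over the proportional EDR contributions (Σ p_i = 1).
* EDR_a = 1/Σ p_k² over greedy marginal ancestor contributions: each
  round selects the candidate explaining the largest share of the
  reference gene pool not explained by previously selected ancestors.
  The marginal share is computed as upward gene flow with absorption at
  the selected set, times one minus the probability that the
  candidate's own genome is already explained; ties break by earliest
  birth year then id, and selection stops when the unexplained residual
  drops below 1e−6. This reproduces an independent path-enumeration
  oracle exactly on every pedigree tested.
* EDR_g = 1/Σ (p_i²/r_i), with r_i the mean fraction of EDR *i*'s
  uniquely labeled alleles surviving in the reference population over
  seeded Monte-Carlo gene drops of one unlinked locus (default 1,000
  replicates). An allele never observed surviving would make its term
  infinite; r̂ is floored at 1/(2·reps), which only affects entities
  whose p_i is already negligible.

**A limitation worth knowing.** EDR_g ≤ EDR_a ≤ EDR_e is the expected
ordering for deep closed populations, and it holds throughout the
simulation studies at realistic founder numbers. It is not, however, a
theorem: when drift makes EDR contributions very uneven while some
mid-pedigree ancestor offers a more balanced explaining set, the greedy
marginal decomposition can be slightly *more* even than the founder
decomposition, so EDR_a can exceed EDR_e by a small margin (observed at
the 0.1% level in roughly 1 in 200 simulated deep pedigrees, and
confirmed by exhaustive path enumeration — it is a property of the
estimator, not an implementation error). Shallow pedigrees (one or two
generations) violate EDR_g ≤ EDR_a routinely, because little allele
loss has accumulated; the ordering is meaningful only for studbooks
with many generations of depth.

## Homozygosity calling

Genotypes are coded hom-ref/het/hom-alt/missing against an ordered
marker map. Two rule sets reflect the two panel densities:

* **snp mode** (chip, ~14 kb spacing): a run of ≥ 5 consecutive
  homozygous calls is an RoH; heterozygous *and* missing calls break
  runs (the missingness tolerance below applies only to cohorts, where
  it is part of the stated procedure). An optional physical-span filter
  exists but is off by default, since with 14-kb spacing five SNPs are
  *expected* to span ≥ 70 kb.
* **wgs mode** (sequencing, ~300 bp): maximal segments with physical
  span ≥ min_length (10 kb–1 Mb grid) containing ≤ max_het heterozygous
  calls (0/1/5/10), found by a leftmost-maximal greedy scan; missing
  calls are non-informative. The scan provably equals "enumerate all
  rule-satisfying intervals, repeatedly keep the leftmost-longest,
  discard overlaps", and the test suite verifies equality with that
  brute-force oracle on every genotype string of length ≤ 12.

Interval coordinates run from first to last marker of the segment and
LnH = Σ(end − start); intervals are exported as 0-based half-open BED.
Because boundaries sit on markers, a true autozygous tract is observed
shortened by roughly one marker spacing per side — at 300 bp spacing a
70-kb tract is recovered with Jaccard ≈ 0.99, but a tract only barely
above the length threshold may be unobservable at marker resolution.

**Shared homozygosity** reduces a cohort to one pseudo-genotype per
marker: homozygous iff fewer than 20% (strict) of members are missing
and every non-missing call is homozygous (same-allele matching is
optional and off, since shared autozygosity of distinct haplotypes is
not distinguishable from genotypes alone); a marker with any
heterozygote codes het; otherwise missing. A cohort of one therefore
reproduces the individual call exactly. With missing-free data the
cohort-homozygous marker set only shrinks as the cohort grows, so
shared LnH is non-increasing; with missing data the <20% rule is
cohort-size dependent and can transiently re-admit a marker (e.g. one
miss among 4 dogs is 25% and excluded, among 6 dogs 16.7% and
tolerated). Both behaviors follow from the stated rules; the
monotonicity guarantee applies to complete data.

**Genotype inbreeding** is the method-of-moments estimator
F = (O_hom − E_hom)/(m_used − E_hom) with the small-sample correction
E_hom = Σ_j [1 − 2p_j(1−p_j)·n_j/(n_j−1)], frequencies taken from the
input matrix. With a per-breed input this measures inbreeding relative
to the breed's own gene pool (F_IS, near zero for drifted-but-random-
mating breeds); cross-breed comparisons require a pooled multi-breed
matrix, which is how the correlation analyses here are run. An input
with only monomorphic markers yields an explicitly undefined result.

**VIF pruning** slides a 50-SNP window in 5-SNP steps along each
chromosome; within a window the marker with the largest
VIF = 1/(1 − R²) (from the inverse correlation matrix of the window's
retained markers) is removed until all VIFs ≤ 2, i.e. R² ≤ 0.5.
Missing calls are mean-imputed per marker before the correlation matrix
is formed — a deliberate substitution for pairwise-complete statistics
that keeps the matrix positive semi-definite so the iterative inverse
is well defined. Singular windows (perfect collinearity) surface as
invalid inverse diagonals and are treated as infinite VIF, with the
later duplicate removed.

## Decay model and cohort size

For losses y_t = LnH_t − LnH_{t+1} (t = 1 is the loss caused by the
second dog, so y_1 = a and a 10-dog curve has 9 losses), the model
y_t = a·e^(−k(t−1)) is fitted by OLS on ln y_t vs (t−1) — free
intercept by default, optionally pinned at ln a. Zero losses (plateaus)
cannot enter the log fit and are excluded with a warning; fewer than
two positive losses is an explicit failure. Noiseless geometric curves
are recovered to machine precision, and the slope is invariant to
rescaling all losses.

The cohort needed to push the per-dog loss to y* solves
t* = 1 + ln(a/y*)/k; the reported cohort is the initial dog plus
⌈t*⌉ (whole-dog counts, conservative). y* is 1% of the first dog's LnH
or 1 bp. If y* ≥ a the threshold is met at the second dog and the
result is flagged. Because e^(−k) is the per-step multiplier, the
per-dog fractional decrease 1 − e^(−k) is reported alongside k (for
k ≈ 0.2 the two nearly coincide; for k ≈ 0.6 they diverge). A single
random addition order makes k̂ noisy, so `decay_over_orders` refits
over seeded permutations and reports the mean, spread and per-order
values; orders whose curve is entirely flat yield an undefined fit and
are kept as such, never silently dropped.

## Ne timelines and correlations

Externally estimated Ne-per-generation tables (e.g. from LD-based
estimators) are anchored to calendar years with a generation interval
of 3.76 years and linearly interpolated (the interpolation method is a
package choice; the sources do not state one). The recognition-year
slope analysis compares ΔNe per generation between generation 13 and
the recognition point against an equally long window further back;
slopes are signed with the older point first, so a shrinking population
has positive slope and "pre minus post" > 0 means faster shrinkage
before recognition.

Pearson correlations report r, t = r√((n−2)/(1−r²)) and the two-sided
p from Student's t with n−2 df, over pairwise-complete profile pairs.
Raw p-values are the primary output (matching how such tables are
conventionally presented); a Bonferroni column is emitted alongside for
transparency. Zero-variance inputs give explicitly undefined results.

## The simulator: what it emulates, what it does not

`pedsim` generates a closed studbook: founders in the start year
(alternating sexes so tiny configurations remain feasible), parentless
immigrants each year until registry closure, Poisson litter counts and
sizes, breeding ages 1–8 with a 10-year lifespan, and a popular-sire
mixture — with probability c/(1+c) a litter is sired by the
top-prestige eligible male, else by a uniform random male, giving the
measurable top-sire share π + (1−π)/M. An optional bottleneck year
removes each living dog independently with the stated probability.
Extinction after closure is an explicit error naming the year.

Genotypes come from dropping uniquely labeled founder haplotypes
through the pedigree with Haldane (no-interference) recombination at
1 cM/Mb; autozygosity truth is exact label identity, so planted-tract
recovery tests need no inference. Marker positions are Poisson-spaced
at 14 kb (chip) and 300 bp (sequencing) means, with ancestral allele
frequencies Uniform(0.05, 0.95) per marker; founder haplotypes are
Bernoulli draws against those frequencies. A shared `panel_seed` lets
several breeds share one marker map and frequency spectrum — the
multi-breed chip-study setting, where every breed is a drifted sample
from a common ancestral pool.

Deliberately absent: mutation, selection on phenotypes, sex
chromosomes, genotyping error, interference, and real genetic maps.
Consequences for interpretation: noise-free genotypes make tract
recovery cleaner than real data (no error-induced het breaks, hence
max_het = 0 suffices); uniform recombination misses hot/cold spots, so
real tract-length distributions are wider; and simulated allele
frequencies lack ascertainment bias, so chip-panel inflation of LnH is
if anything *under*-stated relative to a real chip designed for common
variants. Passing tests demonstrate correctness of the estimators and
the direction of panel-density and drift effects, not calibrated
magnitudes for any real breed.

## Problem sizes and numerics

Simulation studies run at desk scale, chosen to mirror the statistical
regime of real studbooks rather than their censuses: replicate breeds
use ~16 founders plus immigrants (≈28 EDRs), 40–50 years of records
(g_e ≈ 11–12, comparable to real reference pedigrees), populations of
300–1,600 dogs, and genomes of one 30–50 Mb chromosome (chip panels of
~2–4k markers, sequencing panels of ~100–170k). Gene dropping uses
1,000 replicates by default (Monte-Carlo s.e. on r_i ≈ 0.016), 500 in
the 200-replicate ordering study. Greedy ancestor selection stops at
residual < 1e−6; kinship recursion is exact rational arithmetic in
floating point with no tolerance beyond machine epsilon; decay fitting
and cohort prediction are closed-form. All stochastic entry points take
explicit seeds and are reproducible bit-for-bit.
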