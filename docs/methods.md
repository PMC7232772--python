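# Methods

`ciscopop` re-implements, as a tested library, the population-genomic
analysis used to study sympatric cisco (*Coregonus artedi* complex) forms:
SNP quality control, diversity and differentiation statistics, ancestry and
hybrid inference, leave-one-out assignment, LD-based effective population
size, a linkage-map genome scan, and a forward simulation study of
hybridization eroding differentiation. Raw RAD data are not required: a
synthetic-data module generates every input with known truth.

## The forward simulator

The simulator emulates an EASYPOP-style neutral Wright–Fisher model:
dioecious diploids, equal numbers of females and males per deme, random
mating (mother and father drawn uniformly with replacement within a deme;
selfing impossible, monogamy not enforced), non-overlapping generations,
K-allele mutation (a mutating gene copy switches to one of the other
allowed states uniformly; default 2 states, µ = 1e-8 per locus per
generation), and free recombination between loci.

It runs in two phases:

1. **Frequency-phase burn-in.** Because loci are unlinked and mating is
   random, the long low-migration burn-in (default 1,000 generations) is run
   as a per-locus allele-frequency recursion: deterministic migration mixing
   of deme frequencies, the 2-state mutation term, then binomial resampling
   of 2N gene copies per deme. Every locus starts at p = 0.5 in every deme
   (the maximal-diversity start for initially undifferentiated populations).
   This phase is restricted to biallelic loci. It makes 8,000-locus,
   1,000-generation scenarios run in seconds without changing expected
   differentiation dynamics; the engine's equilibrium matches the
   Crow–Aoki finite-island prediction (simulated GST 0.052 vs 0.0526 for
   3 demes of N = 2,000 at m = 0.001).
2. **Individual-based hybridization phase.** Individuals are instantiated
   from the burn-in frequencies (two Bernoulli(p) gene copies per locus:
   Hardy–Weinberg, linkage equilibrium), each tagged with a one-hot ancestry
   vector for its deme. Migration, mating and mutation then run explicitly;
   an offspring's ancestry vector is the average of its parents', so every
   sampled individual carries pedigree-true deme-of-origin fractions.

**Migration conventions.** `m` is the per-individual, per-generation
emigration probability. Island migrants choose a uniform other deme. The
1-D stepping stone is linear (non-circular): each individual attempts to
move left or right with probability m/2 each, and at the terminal demes the
outward attempt is dropped (the individual stays), so edge demes emigrate
at rate m/2. Within a generation the default order is *mate, then migrate*
(natal dispersal): a sample taken after G generations reflects G−1 rounds
of gene-flow mixing. Both choices are conventions for an external program
whose internals are not documented; the alternatives (migrate-then-mate via
`life_cycle="migrate_mate"`) are implemented, and the defaults are the pair
that reproduces the published simulated hybrid counts most closely. Deme
sizes and the 50/50 sex ratio are restored at each reproduction step, which
produces exactly N offspring per deme from its post-migration (or
pre-dispersal) adults.

**Two scales of "FST" for the same demography.** For d demes the
Weir–Cockerham estimator θ targets the among-deme variance with a d/(d−1)
(Bessel) factor relative to the plain mean-squared-deviation (Nei/GST)
scale. At the 3-deme burn-in conditions the GST scale sits near 0.05 while
multilocus θ sits near 0.076; for 2 demes the same engine gives θ ≈ 0.061,
0.118 and 0.195 at burn-in m = 0.001, 0.0005 and 0.0001. Reported burn-in
differentiation in this package is always multilocus θ unless stated
otherwise.

**Fixture generators.** `make_planted_island_genome` draws per-locus
two-population frequencies from a Balding–Nichols model at a background
FST, except inside a contiguous cM span on one linkage group, which is
drawn at an elevated FST. `make_paralog_depths` plants merged duplicate
loci: four gene copies determine the apparent genotype (heterozygous
whenever the copies disagree) and reads are drawn from all four copies at
double depth, producing the excess heterozygosity and skewed read ratios
that HDPlot screens for. `make_known_ne_population` drifts an isolated deme
of known size for 50 generations — ample for the inter-locus LD of unlinked
loci to reach its drift–recombination quasi-equilibrium (the LD decay
factor per generation is (1−c)² = 0.25) — from uniformly drawn starting
frequencies, then samples individuals and assigns loci round-robin to
linkage groups.

## QC filtering

Stages in order: locus call rate (keep ≥ 70% genotyped), individual
missingness (drop > 50% missing), minor allele count (keep MAC ≥ 3), HDPlot
(remove H > 0.55 or |D| > 5, with H the heterozygote proportion and
D = (A − n/2)/√(n/4) the z-score of the reference-read share A among the n
reads pooled over heterozygotes), and thinning to the single highest-MAF
SNP per RAD tag (ties to the smallest locus id). Boundary semantics mirror
the thresholds' phrasing: "fewer than 70%" and "count less than 3" keep the
boundary; "more than 50%" and "greater than 0.55/5" remove strictly beyond
it. Each stage sees the previous stage's output, so MAC is computed after
low-call-rate loci and high-missingness individuals are gone. Without a
depth matrix, HDPlot filters on H alone and logs a warning.

## Statistics

*Weir–Cockerham θ* uses the 1984 variance components a, b, c per allele per
locus; the multilocus estimate is the ratio of summed components over loci
and alleles (never a mean of ratios), negative per-locus values are
retained, multi-allelic loci are supported, per-locus sample sizes come
from non-missing calls, and loci monomorphic across the included groups or
with fewer than two genotyped individuals in any group are excluded.
The estimator was checked unbiased against independent Balding–Nichols
replicate demes (truth 0.05 → 0.0499 at 8,000 loci).

*Diversity*: Ho is the per-locus heterozygote proportion averaged over
loci; He is Nei's unbiased expected heterozygosity 2n/(2n−1)(1 − Σp²);
G_IS = 1 − mean(Ho)/mean(He) from the averaged components (a deliberate,
documented simplification of GenoDive's definition); A is the percentage of
all observed (locus, allele) combinations present in the group.

*G″ST* is Hedrick's standardized differentiation with the Meirmans–Hedrick
correction, k(H_T − H_S)/((kH_T − H_S)(1 − H_S)), using Nei–Chesser
unbiased H_S and H_T averaged over loci.

*Differentiation tests* replace Markov-chain exact tests with a label
permutation test on multilocus θ: p = (1 + #{θ_perm ≥ θ_obs})/(1 + n_perm).

## Ancestry, hybrids, assignment

The admixture model is the standard unsupervised allele-frequency mixture
(genotype ~ Binomial(2, Σ_k q_ik f_kl)), the same likelihood ADMIXTURE
maximises. It is fitted by EM with SQUAREM extrapolation; a step that fails
to improve the log-likelihood falls back to its plain EM updates, so
monotonicity holds. Plain random-start EM demonstrably stalls in soft local
optima on weakly differentiated data (lower log-likelihood, inflated
hybrid counts), so the first restart is seeded from k-means clusters on the
leading principal components, optionally one more from a-priori group
labels; these seeds only initialise the optimizer. Cluster allele
frequencies are clipped to [1e-6, 1 − 1e-6]. K is chosen by masked-entry
k-fold cross-validation (RMSE of predicted dosage 2Σq_ik f_kl over held-out
entries); only the argmin is meaningful, not the absolute error, which is
defined differently from ADMIXTURE's CV score. Label switching is resolved
by Hungarian assignment of clusters to majority field labels.

Hybrid calls: max-Q < 0.70 → hybrid, assigned to the two largest-Q
clusters (ties to the lower cluster index); max-Q ≥ 0.99 for a cluster
contradicting the field label → misidentified ("ancestry of essentially
100% elsewhere"); otherwise pure. The joint (Q, F) maximum-likelihood noise
floor matters when interpreting hybrid counts: with 1,000 loci at FST ≈ 0.1
and 50 individuals per deme, per-entry Q-RMSE for pure individuals is
about 0.07 (0.03 of it irreducible even with the true frequencies known).

Assignment computes the Paetkau home likelihood — the HWE probability of
the multilocus genotype under a group's allele frequencies, zero
frequencies floored at 0.005 and renormalized — with the focal individual
excluded from its own group's frequencies. Significance uses a parametric
Monte-Carlo null: genotypes simulated under HWE from the group frequencies,
flagging individuals below the α = 0.002 quantile over 1,000 replicates
(the original program's exact scheme is unspecified; this parametric null
is the package's documented choice).

## Effective size

Burrows composite r² per locus pair (Δ = cov(dosage_i, dosage_j)/2 with the
S/(S−1) correction; r² = Δ²/(p(1−p)q(1−q))), averaged over pairs of loci
on *different* linkage groups when a map is present (all pairs otherwise),
alleles rarer than p_crit excluded. The drift component subtracts the
random-mating sampling expectation E[r²] = 1/S + 3.19/S² (S ≥ 30; the
small-S variant is implemented but untested fixtures keep S ≥ 30) and
inverts Ne = (1/3 + √(1/9 − 2.76 r²'))/(2 r²'), infinite when r²' ≤ 0.
Confidence intervals are chi-square intervals on r²' whose degrees of
freedom come from a delete-one-individual jackknife (default — overlapping
locus pairs are far from independent, and the jackknife CI covers a truth
of Ne = 200 in 20/20 simulated replicates at S = 50), or parametrically
from the raw pair count (anti-conservative on dense SNP panels; provided
for comparison). Missing calls are mean-imputed before the pairwise
covariance; the simulated fixtures carry none.

## Genome scan

Per-locus FST is smoothed along each linkage group in 5-cM windows stepped
by 1 cM, Gaussian weights w = exp(−d²/2σ²) with σ = width/4 = 1.25 cM,
hard-truncated at ±width/2 (the weighting scheme is cited, not reprinted,
in the original description; σ is parameterized). Window significance keeps
the window's own positions and weights while redrawing statistic values
with replacement from the genome-wide pool of mapped loci (a
without-replacement flag exists): 1,000 replicates, escalated to 10,000
when the observed value exceeds the 90th percentile; significant = above
the 99th percentile of the escalated null with ≥ 2 loci in the window.
Significant windows whose centers are ≤ 1 step apart on the same linkage
group merge into segments. On exchangeable (null) statistics the rule
flags ≈ 0.5–1% of windows; a planted 10-cM island at FST 0.4 over a 0.05
background is recovered in 50/50 seeds at 1,000 loci.

The per-locus outlier test regresses scaled dosages on the first K
principal components, summarises the K z-scores by Mahalanobis distance,
divides by the genomic inflation factor (median distance over the
chi-square(K) median), and applies Benjamini–Hochberg FDR at α = 0.05.

## Problem sizes and reproducibility

The packaged study scenarios use the study's own conditions: demes of
2,000 diploids, 8,000 biallelic loci, 1,000 burn-in generations at
m = 0.001 (3-deme design) or 0.001/0.0005/0.0001 (2-deme erosion levels a,
b, c), hybridization at m ∈ {0.01, 0.05, 0.10}, 1,000 loci and 50
replicates for the erosion curves, and samples of 100 individuals per deme.
The test suite exercises the same designs; smaller demes and locus counts
appear only in unit tests of individual operations. All randomness flows
through `numpy.random.Generator` seeds; identical seeds give bit-identical
outputs.

## What the synthetic data do and do not show

The generators reproduce the *neutral, equilibrium-ish* features the
analyses rely on: HWE within demes, linkage equilibrium between (unlinked)
loci, drift-scaled allele-frequency divergence, pedigree-defined
admixture, Poisson read depths with symmetric heterozygote sampling. They
do not emulate selection, physical linkage within linkage groups (map
positions are labels, except where fixtures correlate loci deliberately),
allele dropout or genotyping-error structure of real RAD data, overlapping
generations, or multi-cohort Wahlund effects on Ne. Passing tests therefore
demonstrate correctness of the estimators and pipeline under the stated
models, not robustness to those real-data artefacts.

## Known limitations

- The frequency-phase burn-in supports two allelic states only; microsat
  style multi-allelic simulation must go through the individual-based phase.
- The admixture model is linkage-unaware and unsupervised only.
- BayeScan's multinomial-Dirichlet MCMC outlier test is out of scope; the
  package exposes the PCA-based test plus the window scan.
- EASYPOP's exact migration internals are undocumented; where its
  conventions were ambiguous the package picks one, implements the
  alternative behind a flag, and documents the choice here.
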