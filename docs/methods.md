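# Methods

This package reimplements, as one tested pipeline, the marker-based analyses
used to ask whether an oceanographic barrier has split a coastal fish into two
anciently isolated populations: mitochondrial control-region (CR) diversity
and distance-based AMOVA/Φ-statistics, microsatellite diversity and
F-statistics, neutrality tests and mismatch-distribution expansion inference,
median-joining haplotype networks, a drift-based power analysis, and the
mutation-scaled conversions used to express coalescent-sampler output in
natural units. A coalescent/drift generator produces data with the same
statistical structure, so every stage can be validated without external
downloads.

## Sequence statistics and site handling

mtDNA sequences are haploid, aligned, and may contain gaps (`-`) and
ambiguities (anything that is not A/C/G/T is stored as N). Site handling
follows the conventions of the standard AMOVA software so that counts are
auditable:

- **Haplotype collapsing** uses *complete deletion*: columns containing a gap
  or N in any analysed sequence are removed, and haplotypes are distinct rows
  of the remaining matrix. Haplotype ids (H1, H2, …) are ordered by
  decreasing frequency.
- **Distances and nucleotide diversity** use *pairwise deletion*: each pair
  of sequences is compared over its own gap-free sites.
- A site is **variable** when ≥ 2 plain bases are observed at it;
  **parsimony-informative** when ≥ 2 states are each carried by ≥ 2
  sequences; a **fixed difference** between two groups is a site whose
  observed state sets are disjoint.

Haplotype diversity is the unbiased gene diversity h = n/(n−1)(1 − Σp²);
nucleotide diversity π is the mean per-site pairwise difference. Distances
are plain difference counts, p-distances, or Kimura two-parameter (K80)
distances d = −½ln(1−2P−Q) − ¼ln(1−2Q) from per-pair transition (P) and
transversion (Q) proportions; saturated pairs (log arguments ≤ 0) are
flagged and reported as infinite.

## AMOVA and Φ-statistics

The analysis of molecular variance partitions squared inter-individual
distances hierarchically (among groups / among populations within groups /
within populations) with the Excoffier–Smouse–Quattro unbalanced-design
coefficients. Squared distances enter the sums of squares, so a K80 matrix is
squared element-wise first. Negative variance components are *not* truncated
before computing Φ (matching the reference software), and percentage
contributions use the raw total. Permutation schemes are level-appropriate:
individuals among populations for Φ_ST, whole populations among groups for
Φ_CT, individuals among populations within groups for Φ_SC. p-values use the
(1 + exceedances)/(1 + permutations) estimator and are therefore never
exactly zero; permutation streams are derived deterministically from one
master seed plus the test label, so pairwise matrices do not depend on
evaluation order. Default 10,000 permutations, reducible by flag.

With discrete, low-diversity data the permutation statistic can tie with its
null draws; ties are counted as exceedances, which keeps the test valid but
makes p conservative. The calibration test therefore simulates panmixia at
θ = 8, where ties are negligible and p is uniform to KS accuracy.

## Microsatellite statistics

Expected heterozygosity carries the unbiased 2n/(2n−1) correction. Allelic
richness uses hurlbert rarefaction over *genes actually scored*; the
rarefaction size is expressed in diploid individuals g (2g genes), default
the smallest per-locus per-population sample. F_IS per locus/population is
1 − H_O/H_E; the multilocus value is the ratio of sums (weighted), not the
mean of ratios. Weir–Cockerham θ sums the a, b, c variance components over
alleles and loci (θ = Σa / Σ(a+b+c)); its permutation unit is the
individual's multilocus genotype, preserving within-individual linkage.
Jost's D per locus uses the Nei–Chesser sample-size-corrected H_S and H_T
(harmonic-mean sample size Ñ): H_S′ = 2Ñ/(2Ñ−1)·H_S, H_T′ = H_T + H_S′/(2Ñk);
D = k/(k−1)·(H_T′−H_S′)/(1−H_S′) over k populations. The multilocus D is the
harmonic mean across loci with negative per-locus values clamped to zero
first — a zero-D locus therefore drives the multilocus harmonic mean to zero,
which is the convention of the original estimator software and is documented
here because it surprises users.

The Hardy–Weinberg test is a Monte-Carlo exact test shuffling the 2n scored
genes into random diploid genotypes; the statistic is the homozygote count
(heterozygote-deficiency direction, one-sided by default, since deficits are
the biologically expected alternative under null alleles or inbreeding; a
two-sided variant doubles the smaller tail). The linkage test permutes one
locus's genotypes between individuals and uses the G statistic of the
two-locus genotype table. Null-allele frequency is estimated by a
single-null-class EM under HWE: apparent homozygotes are a mixture of true
homozygotes and null heterozygotes; double-null individuals are assumed to
fail amplification and are excluded rather than modelled, which biases the
estimate slightly downward at high null frequency. This EM is a simplified
surrogate for the more elaborate estimator in dedicated null-allele software.

Holm's sequential (step-down) Bonferroni is provided for multiple testing.

## Power analysis

Statistical power to detect a target F_ST is estimated by the classic drift
simulation: t = ⌈ln(1−F_ST)/ln(1−1/(2Nₑ))⌉ generations of multinomial
resampling of 2Nₑ genes per population (each population drifts t generations
from the shared base frequencies), genotype samples of the study's sizes,
per-locus allele-count homogeneity tests (χ² default, Fisher exact for 2×2)
combined across loci by Fisher's method, and power = the fraction of
replicates significant at α. At target F_ST = 0 the procedure estimates the
type-I error and should return ≈ α.

## Neutrality tests and expansion inference

Tajima's D uses the standard a₁…e₂ constants; Fu's F_S is
ln(S′/(1−S′)) with S′ = P(K ≥ k_obs) under the Ewens sampling distribution at
θ = θ_π (the mean pairwise difference), evaluated in log space via the
unsigned-Stirling-number recurrence (exact to 1e−10 against rational
enumeration for n ≤ 12). k_obs is the number of distinct haplotypes.
Significance for both comes from neutral constant-size coalescent simulation
conditioned on θ̂ = θ_π (1,000 replicates by default): two-sided for D,
one-sided (lower tail) for F_S.

The mismatch distribution is fitted to the sudden-expansion model
F_j(τ, θ₀, θ₁) = F̂_j(θ₁) + e^{−τ(θ₁+1)/θ₁} Σ_{i≤j} τ^i/i!·[F̂_{j−i}(θ₀) −
F̂_{j−i}(θ₁)], F̂_j(θ) = θ^j/(1+θ)^{j+1}, by least squares (SSD), with a
coarse grid over (τ, θ₀, θ₁) followed by Nelder–Mead and the constraints
0 ≤ θ₀ ≤ θ₁, τ ≥ 0 enforced by rejection. The reference software's exact
optimisation scheme is unpublished; this seeded grid+simplex choice is the
package's own and is stable on the test problems. Goodness of fit uses a
parametric bootstrap: coalescent samples simulated under the fitted expansion
(in mutational time units, where the coalescence rate for k lineages is
k(k−1)/(2θ(t)) and branches mutate at rate ½), refitted, and compared by SSD.
The τ confidence interval is the percentile interval of the bootstrap
refits. A caveat established by the package's own recovery study: at small
sample sizes the least-squares fit tends to slide along the weakly
identified θ₀→0 ridge, absorbing θ₀ into τ̂ (upward bias) in a way the
parametric bootstrap — which re-simulates at the fitted θ̂₀ — cannot see, so
CI coverage degrades below nominal for n of a few tens; at n ≈ 100 (the
scale of the samples this pipeline targets) coverage is nominal. The basic
(pivot) interval was evaluated and covers worse here, because the bias is
parameter-dependent rather than translational.

Expansion time: τ = 2ut with u the whole-sequence per-lineage substitution
rate. The between-lineage divergence rate r (% per My; 3.6 for teleost CR)
gives u = (r/2)·L per site-My, so t is first computed in years, then also
expressed in generations (generation times: 2.2 y northern, 5 y southern).
Both scales are reported deliberately: published expansion times mix the two
conventions, and the conversion is linear in τ and inversely linear in r and
L, so the reader can rescale.

A net-divergence dating surrogate T = d_a/(r/100) with
d_a = d_xy − (d₁+d₂)/2 is provided for a rough split-time estimate; it is a
point surrogate only (no ancestral-polymorphism variance, no calibrated
prior) and is not equivalent to a Bayesian coalescent tmrca.

Coalescent-sampler output conversions: θ = xNₑμ gives Nₑ = θ/(xμ) with x = 1
for mtDNA and 4 for nuclear loci; M = m/μ gives m = Mμ; effective migrants
per generation are reported both as θM and xθM because both products are
used in the literature.

## Median-joining networks

Haplotypes (restricted to their variable sites) are joined by an ε-relaxed
minimum spanning network — an edge belongs iff its weight is within ε of the
bottleneck (minimax) MST path weight between its endpoints, which at ε = 0 is
the union of all MSTs with lexicographic tie-breaking for determinism. The
network is then augmented with quasi-median vectors: for triplets with at
least two linked pairs, the per-site majority consensus (sites with three
distinct states expand into all three alternatives, capped combinatorially);
a vector is accepted only if it strictly shortens the network, and inferred
vectors that stop helping are pruned each round, to a fixed point. On
tree-like data the result equals the MST with no medians. Haplogroups are
the connected components after removing edges of ≥ `min_steps` mutations;
the longest removed bridge is reported alongside the minimum inter-group
Hamming distance, because the two need not coincide. ε defaults to 0 with
equal site weights. No layout is computed; the graph exports to GraphML and
edge-list TSV.

## Synthetic data: what it emulates, and what it does not

The generator's defaults encode the study conditions the pipeline targets:

- **Two-population scenario**: a structured coalescent for two demes merging
  7×10⁵ generations ago (an ancient, Pliocene–Pleistocene-scale split at a
  2.2-year generation time) with optional symmetric migration; deme sizes
  63,000 and 100,000 gene copies and μ = 4×10⁻⁸ per site per generation give
  per-population π ≈ 0.005–0.008 on a 583-bp CR-like fragment, and the split
  depth fixes ≈ 25–30 differences between regions (Φ_ST ≈ 0.9). Samples are
  spread over six northern and two southern sites (20, 17, 20, 20, 20, 7 /
  20, 20 individuals) with no true within-region structure. Substitutions
  follow a two-parameter model with transition bias κ = 10; multiple hits are
  allowed (finite sites), consistent with analysing the output under K80.
- **Expansion scenario**: one population that grew from 26,600 to 157,000
  (≈ θ₀ = 1.24 → θ₁ = 7.3 in mutation units) 53,400 generations ago
  (τ ≈ 2.5), sampled at n = 104.
- **Microsatellites**: eight dinucleotide loci, base frequencies Dirichlet(1)
  over ten allele sizes, two-stage hierarchical drift at Nₑ = 500 (54
  region-level + 3 site-level generations, putting between-region pairwise
  F_ST near 0.055 and within-region F_ST near 0.006), stepwise mutation at
  10⁻⁴ per gene per generation, HWE genotype sampling, and an optional null
  allele whose homozygotes appear as missing data.

Not emulated: mutation-rate heterogeneity along the CR (so simulated
haplotype counts run lower than real CR data at matched π), selection,
recombination, more than two demes, allele-size constraints or genotyping
error. Passing tests therefore show the *estimators* behave correctly under
the model assumed by the analysis, not that real data meet those
assumptions.

## Numerical choices and degenerate inputs

- All randomness flows from one master seed through SHA-256-derived child
  streams labelled by stage and unit (`rng.derive_rng`), below 2³¹.
- Saturated K80 pairs → flagged infinite distances that propagate to AMOVA
  as errors rather than silently truncating.
- Monomorphic loci are excluded from θ (0/0 components) with a log note;
  loci with H_S = 1 are skipped for D_est.
- n < 2 diversity, S = 0 for Tajima's D, k_obs = 1 for F_S (F_S = +∞), and
  negative net divergence (T clamped to 0) are flagged, not silently
  dropped.
- The EM for null alleles stops at 10⁻⁹ parameter change or 1,000 iterations
  (non-convergence flagged).
- Problem sizes in the test suite and the acceptance script (e.g. 1,000
  permutations, 200 bootstraps, 50 recovery replicates, 200-replicate
  calibration runs) are chosen so the whole battery completes in minutes on
  one core while keeping Monte-Carlo error well inside the asserted
  tolerances.

## Known limitations

- The drift power simulation treats loci as independent and ignores
  mutation during the short drift phase (as the original procedure does).
- The null-allele EM is a single-null-class approximation (see above).
- The net-divergence date is a labelled surrogate, not a calibrated
  coalescent estimate.
- Bayesian clustering, skyline plots, and MCMC migration/tmrca samplers are
  out of scope; only their output-to-natural-units conversions are
  implemented.
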