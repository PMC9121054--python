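# Methods

This note documents the statistical model behind `gradientpop`, the
choices made where conventions diverge, and what the simulation-based
tests do and do not demonstrate.

## Input model and quality control

The unit of analysis is a species dataset: an aligned set of COI
barcode sequences, each labelled `north`, `baltic` or `transition`.
Transition-zone samples (Skagerrak–Kattegat–Belt Sea) sit inside the
cline itself and are removed before analysis by default.

QC operationalizes the usual manual curation of barcode alignments:

- Sequences are trimmed to the largest column window (0-based,
  half-open) covered by every retained sequence. If that window is
  shorter than 400 bp, fragments are dropped greedily — at each step
  the sequence whose removal widens the shared window most — until the
  window reaches 400 bp or no single removal helps. The greedy rule is
  a deterministic stand-in for by-eye trimming; an exhaustive search
  over drop subsets is used as the oracle in tests.
- Columns containing a gap in any retained sequence are removed. COI
  is protein-coding, so residual indels almost always indicate
  misalignment or pseudogenes rather than real variation.
- Datasets ending below 400 bp, or with fewer than 5 sequences in
  either analysed population, are flagged excluded (never a crash):
  short fragments underestimate diversity, and 5 sequences is the
  floor at which high- and low-diversity populations remain
  distinguishable.
- Sequences whose mean divergence from their own population exceeds
  5% are flagged as possible cryptic or misidentified lineages but
  never dropped automatically; the 5% threshold is a package
  convention, chosen near the classical barcode-gap scale, and is
  advisory only.

Ambiguity codes and N survive QC. They are treated as literal
characters when collapsing haplotypes (two sequences differing only at
an N are conservatively kept as distinct haplotypes, so unsequenced
sites never merge variants) but excluded pairwise when counting
differences, with the number of comparable sites tracked per pair
(pairwise deletion). Whether the diversity statistics in the original
R-package ecosystem use pairwise or complete deletion is not always
documented; pairwise deletion wastes the least data and is what we
state and test.

## Diversity statistics

For a population of n sequences:

- Haplotype diversity H = (n/(n−1))(1 − Σ pᵢ²), the bias-corrected
  probability that two random sequences carry different haplotypes.
- Mean pairwise differences k̂ = mean of d_ij over all n(n−1)/2 pairs,
  where d_ij counts sites at which both sequences carry unambiguous,
  different bases. Nucleotide diversity π is the per-site version,
  averaging d_ij / comparable_ij, so pairs with more missing data are
  not overweighted.
- Tajima's D = (k̂ − S/a₁) / √(e₁S + e₂S(S−1)) with the standard
  constants a₁, a₂, b₁, b₂, c₁, c₂, e₁, e₂ as functions of n. S counts
  sites with at least two distinct unambiguous alleles. With S = 0 the
  statistic is undefined and reported as NA — never coerced to 0,
  which would fabricate a neutral-equilibrium signal from a
  monomorphic sample. The primary p-value rescales D onto its
  theoretical range [D_min, D_max] and uses the beta approximation to
  the null; a two-sided normal p is also reported for comparison.

Haplotype networks are minimum spanning networks: Kruskal by weight
class, adding every edge whose endpoints lie in different components
before any edge of that weight is processed, so all edges that
participate in some minimum spanning tree are retained. This is
deterministic and, for the shallow star-like networks typical of
intraspecific COI variation, visually equivalent to statistical
parsimony, which we deliberately do not implement.

## Differentiation and permutation significance

Φ_ST comes from the AMOVA decomposition with pairwise difference
counts acting as squared molecular distances:
SSD_total = (1/N)Σ_{i<j} d_ij, SSD_within = Σ_p (1/n_p)Σ_{i<j∈p} d_ij,
σ²_w = SSD_within/(N−k), n_c = (N − Σn_p²/N)/(k−1),
σ²_a = (SSD_among/(k−1) − σ²_w)/n_c, Φ_ST = σ²_a/(σ²_a+σ²_w).
Negative estimates are reported as computed — clamping would make the
rarefaction distributions dishonest — with a clamped convenience field
for display. The all-identical 0/0 case is defined as 0.

Jost's D uses the two-population estimator with Nei–Chesser
bias-corrected heterozygosities: H_S_est = (ñ/(ñ−1))·H_S with ñ the
harmonic mean of n₁ and n₂, H_T_est = H_T + H_S_est/(2ñk), and
D = (k/(k−1))(H_T_est − H_S_est)/(1 − H_S_est). As H_S_est → 1 the
estimator diverges; within 1e−9 of 1 it is reported NA.

Hudson's Snn: each sequence's nearest-neighbor set contains every
other sequence at the minimal distance, ties and zero distances
included; x_i is the fraction of that set sharing i's label and Snn is
the mean x_i. The same pairwise-deletion distance matrix feeds Φ_ST
and Snn.

Significance for all three indices uses one shared stream of label
permutations (group sizes preserved), one-sided upper tail with the +1
correction: p = (1 + #{permuted ≥ observed})/(B + 1), B = 1000 by
default. The +1 correction keeps p in (0, 1] and is exact under
exchangeability; coupling the three indices to the same permutations
makes the joint report reproducible from a single seed. Note that
under panmixia the exact expectation of Snn is (n−1)/(N−1) (≈ 0.4975
for 100+100), marginally below the nominal 0.5.

## Diversity-difference testing

Comparing a single H (or π) value per population leaves nothing for a
classical one-way ANOVA to partition. The package instead tests
|measure(north) − measure(baltic)| against a null built by permuting
population labels, with the same +1-corrected p, and calls the
contrast `higher_north` / `higher_baltic` only when p < α (default
0.05). This preserves the scientific question — are the two
populations' diversities distinguishable given the sampling noise —
with a well-defined null. Cross-species structure is summarized by the
Pearson correlation between per-species baltic/north ratios of H and
of π, with a 95% Fisher-z interval.

## The coalescent generator

Synthetic species are drawn from a two-deme isolation-with-migration
structured coalescent. Backwards in time, j lineages in deme d
coalesce at rate j(j−1)/q_d and each lineage in deme d jumps to the
other deme at rate m_d (m₁₂ for the north deme, m₂₁ for the baltic —
backwards-in-time lineage movement, the IM-inference convention; the
forward interpretation swaps the indices). At scaled time t all
lineages merge into an ancestral deme of size q_A. Time is in expected
mutations per locus: mutations fall on branches as a Poisson process
at rate 1 per unit branch length, hit a uniform site and change the
base under Jukes–Cantor. Consequently E[k̂] = q and E[S] = a₁q for a
single panmictic deme, which the tests verify by simulation, and
divergence times convert to years as t/(r·L).

Jukes–Cantor is a deliberate simplification: every statistic in the
pipeline depends only on difference counts, for which transition/
transversion asymmetry (HKY-family models) is irrelevant at
intraspecific divergences; at the simulated depths multiple hits
deflate k̂ by well under 1%.

Default generator conditions mirror the study design the pipeline
targets: two populations, 5–220 sequences each (default 25 per deme,
the observed median), alignment length 423–675 bp (default 545), q of
order 1–5, t up to 10, asymmetric migration allowed. What the
generator does **not** emulate: selection, recombination (acceptable
for a non-recombining mitochondrial fragment), population growth
within demes, sequencing error, and the idiosyncratic sampling
heterogeneity of database-derived data. Passing simulation tests
therefore validates the estimators and their calibration under the IM
model, not the biological conclusions one would draw from any real
alignment.

The substitution-rate constant 1.22%/Myr is interpreted as a
per-lineage rate r = 1.22e−8 per site per year; if read as a pairwise
divergence rate instead, all reported years double — r is a config
knob precisely because the convention is ambiguous. Generation time
enters reporting only (years/generation_time); it never rescales the
years themselves.

## Rarefaction behaviour

Species with more than 20 sequences in both populations (strict) are
subsampled without replacement to 5, 10 and 15 per population, 100
times, and H, π, Tajima's D, Φ_ST, Jost's D and Snn recomputed each
time; 2.5/97.5 percentiles use linear interpolation, and undefined
replicate outcomes (a monomorphic subsample's Tajima's D) are dropped
and counted rather than silently imputed. Diversity statistics are
computed on the pooled subsample; differentiation on the labelled one.

Simulations reproduce the qualitative pattern expected of this design:
95% ranges shrink as the subsample grows, and are several-fold
narrower for strongly differentiated species than for weakly
differentiated ones — at high Φ_ST even five sequences per population
localize the estimate well. A small-sample upward bias of Φ_ST appears
when sampling is uneven and diversity asymmetric (a ratio-estimator
effect) and is asserted as a property test in that regime. The
analogous upward bias for Snn does not materialize under this
generator with the tie-inclusive Snn definition: subsampling dilutes
haplotype sharing, which pulls Snn down, and on constructed
migrant-archetype datasets the gain from excluding migrants cancels
against that dilution almost exactly. We therefore document the Snn
bias direction as negative-to-neutral under the IM model rather than
asserting a positive bias.

## Numerical and reproducibility choices

- All randomness flows through `numpy.random.Generator`; every
  stochastic stage (simulation, permutation, subsampling) is bitwise
  reproducible from its seed, and the multi-species pipeline derives
  per-species seeds from one root `SeedSequence`.
- Permutation p-values are exact rationals of the form k/(B+1)
  evaluated in floating point; ties count toward the tail.
- Percentiles use numpy's linear interpolation between order
  statistics.
- Degenerate inputs are mapped to NA (undefined Tajima's D, Jost's D
  at H_S_est→1, diversity with n<2) or to defined conventions stated
  above (Φ_ST 0/0 → 0); they are never silently clamped.

## Problem sizes used in validation

The simulation-based checks run at sizes chosen to keep the full suite
fast while leaving Monte-Carlo error well inside the asserted
tolerances: 500 replicates of 100+100 panmictic samples (B = 99
permutations each) for type-I error and the Snn null, 500 single-deme
replicates for the E[k̂] = q calibration, 40 replicates per grid point
for the Φ_ST monotonicity checks in t and m, and 100 rarefaction
replicates per size, matching the design's own replicate count.
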