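# gradientpop

Comparative population-genetic analysis of mitochondrial haplotype
alignments across the North Sea–Baltic Sea transition zone.

Many marine invertebrates occur on both sides of the steep salinity
gradient between the marine North Sea and the brackish Baltic Sea. A
recurring question is whether that transition acts as a barrier to
gene flow: do North and Baltic populations of a species exchange
migrants freely, or are they genetically differentiated? `gradientpop`
answers this per species from COI barcode alignments, for many species
in one comparative run, and ships a two-deme coalescent simulator so
the whole pipeline can be exercised and calibrated without any real
data.

## What it computes

For each species (a trimmed alignment plus `north`/`baltic` labels):

- **Per-population diversity** — haplotype diversity
  *H* = (n/(n−1))(1 − Σ pᵢ²) (Nei–Tajima), nucleotide diversity π
  (per site, pairwise deletion of ambiguous sites), mean pairwise
  differences k̂, segregating sites *S*, and Tajima's *D* with its
  beta-approximation test.
- **Differentiation** — Φ<sub>ST</sub> from the AMOVA sum-of-squares
  decomposition on pairwise-difference distances
  (Φ<sub>ST</sub> = σ²ₐ/(σ²ₐ+σ²_w)), Jost's *D* with Nei–Chesser
  bias-corrected heterozygosities and harmonic-mean sample size, and
  Hudson's nearest-neighbor statistic S<sub>nn</sub> (ties and
  zero-distance neighbors included). Significance for all three comes
  from one shared stream of label permutations
  (p = (1 + #{permuted ≥ observed}) / (B + 1), default B = 1000).
- **Robustness** — rarefaction to 5/10/15 sequences per population
  (100 replicates, 95% percentile ranges, bias vs the full-data
  estimate), equalized-sample-size re-analysis, a permutation test for
  North-vs-Baltic diversity differences, and the cross-species Pearson
  correlation of diversity ratios with a Fisher-z confidence interval.
- **Synthetic data** — a structured-coalescent isolation-with-migration
  simulator: two demes of mutation-scaled sizes q₁, q₂ splitting from
  an ancestor (q_A) at scaled time t, with backwards-in-time migration
  m₁₂/m₂₁ and Jukes–Cantor finite-sites mutation, so that
  E[k̂] = q for a single panmictic deme. Divergence times convert to
  years as t/(r·L) with r = 1.22 × 10⁻⁸ substitutions/site/year.

## Worked example

Simulate a species with a moderately deep split, asymmetric diversity
and a little migration, then analyse it:

```sh
gradientpop simulate --q1 5 --q2 1 --t 4 --m12 0.2 --m21 0.2 \
    -L 545 --n1 25 --n2 25 --seed 11 --out demo
gradientpop stats --fasta demo.fasta --popmap demo.popmap.tsv
gradientpop diff  --fasta demo.fasta --popmap demo.popmap.tsv \
    --permutations 1000 --seed 42
```

prints (tab-separated, shown abridged):

```
species  population  n   L    H     pi        k_hat  S   tajimas_D  tajima_p
demo     north       25  545  0.73  0.008281  4.513  18  -0.190     0.886
demo     baltic      25  545  0.63  0.001835  1.000   9  -1.883     0.038

species  n_north  n_baltic  phi_st  p_phi    josts_d  p_d      snn    p_snn
demo     25       25        0.300   0.00100  0.937    0.00100  0.954  0.00100
```

Reading this: the north population is more diverse (π four times
higher, H 0.73 vs 0.63); the baltic population's significantly
negative Tajima's *D* (−1.88, p = 0.038) is the signature of a recent
expansion or sweep. All three differentiation indices reject
panmixia at p = 1/1001 — the smallest value attainable with 1000
permutations — with Φ<sub>ST</sub> = 0.30 and a near-maximal
S<sub>nn</sub> of 0.95: the two basins exchange few migrants at this
locus. `gradientpop run-all --config config.yaml` runs the same
analysis over a whole species list and writes a comparative table.

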