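# isofrag

Isochromosome detection and chromatin-bridge fragmentation statistics from
allele-specific copy-number segments.

An isochromosome carries two mirror-imaged copies of one chromosome arm and
loses the complementary arm — i(8q) amplifying *MYC* and i(3q) deleting
*SETD2*/*BAP1* are recurrent examples across cancers.  In allele-specific
copy-number data (ASCAT-style integer major/minor copies per segment) an
isochromosome leaves a characteristic footprint: one arm with loss of
heterozygosity (LOH, minor copy 0) opposite a heterozygous arm whose
duplicated allele carries at least two copies.  When the fusion lies inside
an arm rather than at the centromere, the derivative is dicentric; it
bridges between daughter cells at anaphase and the bridged span shatters,
leaving heterozygous fragments embedded in the LOH arm whose sizes follow
the Mott law of dynamically fractured solids.

`isofrag` implements, as a reusable and tested pipeline:

- **Calling** (`isofrag.isocall`): the five-condition caller on
  length-weighted modal arm copy numbers — (1) LOH arm: modal minor = 0;
  (2) partner arm heterozygous: modal minor > 0; (3) LOH modal major ≤
  heterozygous modal total − 2; (4) the heterozygous-arm allele closest to
  the LOH modal major is the duplicated allele and must carry ≥ 2 copies;
  (5) the telomeric end of the LOH arm has minor copy 0.  Centricity is
  monocentric iff the LOH arm carries no heterozygous base pair.
- **Fragmentation statistics** (`isofrag.fragstats`): heterozygous-fragment
  counts (plus one for the centromere, minus a missing-data correction),
  fusion-site location (outer boundary of the farthest heterozygous
  fragment), OLS of fragment count on fusion distance (fragments/Mb),
  Mann–Whitney comparison of dicentric vs non-isochromosome fragmentation,
  and nonlinear least-squares fits of the Mott cumulative size law
  N(L) = N₀·exp(−μL^β) with mean fragment size μ^(−1/β)·Γ(1 + 1/β) and a
  constrained β = 1 (homogeneous Poisson-process) comparison fit.
- **Association** (`isofrag.assoc`): the two-proportion Wald statistic
  T = (p̂₁ − p̂₂)/√(p̂(1 − p̂)(1/N₁ + 1/N₂)) on per-chromosome isochromosome
  occurrence stratified by gene-LOH status, Benjamini–Hochberg FDR,
  per-locus scans (100 kb steps, 20-bin smoothed −log₁₀ p), Fisher's exact
  test for deleterious-mutation contrasts, occurrence-probability tables,
  cohort frequency arithmetic, and the bimodality index
  BI = √(π(1−π))·|m₁−m₂|/σ.
- **Break-point null** (`isofrag.breaksim`): telomere-anchored partial-arm
  deletions with one uniform break per patient in a region [a, b], plus the
  closed-form cohort mean E[CN](x) = [n_b(1 + F(x)) + n_f]/(n_b + n_f).
- **Co-dependency networks** (`isofrag.codependency`): gene graphs weighted
  by Pearson correlation of CRISPR gene-effect profiles (edge iff either
  gene is in the other's top-k co-dependency list), shortest paths over
  penalties 1 − r via Floyd–Warshall with tie-tolerant path counting, and
  min–max-normalised betweenness centrality for hub discovery.
- **Synthetic cohorts** (`isofrag.synthdata`): segment tables over a
  bundled synthetic genome with planted isochromosomes (monocentric and
  dicentric), Mott-distributed bridge fragments, marker-LOH coupling at a
  configurable odds ratio, and a factor-model gene-effect matrix with a
  planted hub — all with truth tables for oracle-equivalence testing.

## Worked example

```sh
isofrag synth --n-patients 50 --p-iso 0.3 --seed 3 --out-dir demo
isofrag call --segments demo/segments.tsv --centromeres demo/centromeres.bed \
             --chromosomes c1,c2,c3 --out demo/calls.tsv
isofrag fragstats --calls demo/calls.tsv --out demo/frag.json
isofrag breaksim --region chr3:52400000-90000000 --n-break 212 --n-full 126 \
                 --seed 7 --out demo/sim.tsv
isofrag codep --matrix demo/effect_matrix.csv --anchor HUB --out demo/centrality.tsv
```

prints

```
cohort of 50 patients -> demo/
46 isochromosome calls -> demo/calls.tsv
1 fragment every 11.26 Mb (24 dicentrics)
mean CN at region end: simulated 1.627, analytic 1.627
top hub: HUB (normalized betweenness 1.000)
```

The 50-patient cohort planted isochromosomes on 30% of eligible
chromosomes and the caller recovered all 46 of them; the 24 dicentric
calls regress to one new heterozygous fragment every ~11 Mb of fusion
distance (the generator plants 1/12 Mb; a 50-patient cohort estimates it
that precisely); the simulated break-point cohort of 212 break + 126
whole-arm-deletion patients reproduces the analytic mixture mean 1.627 at
the centromere-side end of the region; and the planted hub gene tops the
co-dependency betweenness ranking.

Each call row carries the sample, chromosome, LOH arm, duplicated allele
and its copy number, centricity, fusion site and distance, and the
heterozygous fragment count, e.g.

```
sample_id  chrom  loh_arm  retained_arm  iso_allele  iso_allele_cn  centricity  fusion_site  fusion_distance  n_het_fragments
S0000      c1     q        p             major       2              dicentric   118000934    18000934         3
```

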