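# Methods

## Data model and coordinate conventions

Segment tables are tab-delimited with columns `sample`, `chrom`, `start`,
`end`, `nMajor`, `nMinor`.  On disk coordinates are 1-based inclusive (the
dominant copy-number segment dialect); internally everything is 0-based
half-open, and emitted tables convert back.  Copy numbers are non-negative
integers with major ≥ minor; an `unordered` dialect switch swaps columns
where a row violates this, for sources that do not order the alleles.
Overlapping segments within a sample/chromosome are rejected with the
offending rows reported.  Subclonal (fractional) copy numbers are out of
scope.

Centromere annotations (UCSC-style table or BED3) may contain several rows
per chromosome; they are merged to the envelope [min(start), max(end)] and
the arm boundary is the floor of the envelope midpoint.  The p arm is
everything left of the midpoint, the q arm everything right of it, so the
two arms partition the chromosome.  Chromosomes 13, 14, 15, 21, 22 and Y
are excluded from calling by default (acrocentric short arms have no
reliable LOH status on arrays; Y is haploid); the set is overridable, and
X is included by default.

## Modal copy numbers and LOH status

All "modal" quantities are length-weighted: the mode of a track over an
arm is the value carried by the largest number of base pairs, which makes
every downstream decision invariant to how the segmentation happens to
split equal-copy runs (per-segment counting would not be).  The major,
minor and total tracks are tallied independently, so an arm's modal total
need not equal modal major + modal minor on mixed arms; the calling
conditions use the modal total exactly as defined.  Ties break to the
smaller copy number, deterministically.

A locus (gene) is in LOH for a sample when the length-weighted modal minor
copy over the covered part of the interval is zero; ties break toward
heterozygous, which is conservative for association testing.  No overlap
at all gives `no_data`, and such samples drop out of both groups.

## Isochromosome calling

For each sample × chromosome, with arm modes (p, q) and the minor copy of
the outermost covered segment of the candidate LOH arm:

1. LOH arm: modal minor = 0.
2. Partner arm heterozygous: modal minor > 0.  If both arms have modal
   minor 0 (whole-chromosome LOH), no call.
3. LOH modal major ≤ heterozygous modal total − 2 (the mirror-duplicated
   arm adds at least two copies relative to the lost arm).
4. If |LOH modal major − het modal minor| ≤ |LOH modal major − het modal
   major|, the major allele of the heterozygous arm is the duplicated one
   (ties prefer major); otherwise the minor allele.  The duplicated allele
   must carry ≥ 2 copies.
5. Telomeric minor copy of the LOH arm = 0 — this rejects partial-arm LOH
   mechanisms that retain a heterozygous telomere.

Segments are coalesced (adjacent equal-copy runs merged) before calling,
which also implements the rule that equal-copy fragments immediately
flanking the centromere act as one fragment.  If the terminal region of
the LOH arm is uncovered, the outermost covered segment is used; uncovered
arms skip the chromosome with a log message rather than guessing.

Centricity: a call is monocentric iff every covered base pair of the LOH
arm has minor copy 0; any heterozygous remnant implies an arm-internal
fusion that bridged, i.e. a dicentric.

## Fragmentation statistics

Heterozygous fragments are segments with minor copy > 0 entirely contained
in the LOH arm.  The fragment count adds 1 for the centromere region
itself and subtracts 1 when the centromere is not spanned by a single
segment but its flanking segments carry identical copy numbers — array
platforms have no centromeric probes, so such a boundary is a missing-data
artifact, not a fracture.  The count is floored at 1.

The fusion site is the telomere-facing boundary of the heterozygous
fragment farthest from the centromere midpoint (distance 0 with no
fragments, i.e. monocentric).  The fragment-count–vs–distance relation is
fitted by OLS with intercept; the slope is reported both per bp and as
Mb-per-new-fragment.  Designs with fewer than 3 calls or no spread in
distance are refused.  Dicentric vs non-isochromosome fragment counts are
compared with a two-sided Mann–Whitney U test (scipy, tie-corrected) plus
the ratio of group means.

### Mott fit

The cumulative count N(L) = #{fragments longer than L} of a dynamically
fractured solid follows N(L) = N₀·exp(−μL^β); β = 1 is the homogeneous
Poisson-process (exponential) case and β < 1 indicates heterogeneous
fracture propensity.  The fit minimises the squared error of
log N(L) = log N₀ − μL^β over the empirical counts evaluated at each
distinct observed length (no binning, avoiding bin-width sensitivity),
excluding the zero-count tail point.  Numerical choices:

- lengths are fitted in Mb (μ is per Mb^β); initialisation
  log N₀ = log n, μ = 1/mean length, with restarts at β₀ ∈ {0.5, 1, 1.5};
- points are weighted by N(L), the inverse of the approximate variance of
  log N(L), so the sparse far tail does not dominate — unweighted fits are
  noticeably noisier in μ;
- parameter standard errors use a sandwich estimator with the closed-form
  covariance of the empirical log-survival curve,
  Cov(log Nᵢ, log Nⱼ) ≈ 1/max(Nᵢ, Nⱼ) − 1/n, which accounts for the serial
  correlation of cumulative counts (the naive NLS covariance is far too
  small there);
- the β = 1 comparison fit shares the unconstrained fit's estimated mean
  fragment size μ^(−1/β)Γ(1 + 1/β) (so μ_exp = 1/mean), leaving only
  log N₀ free (closed-form weighted mean); both fits report the same
  weighted RSS objective.  Fits with < 10 fragments, non-positive or
  all-equal lengths are refused; non-convergence from all starts raises an
  error listing the initialisations tried.

## Association testing

With k isochromosome calls over c eligible chromosomes per patient
(defaults: c = 17 for a single-gene analysis excluding the gene's own
chromosome from the 18 screened non-acrocentrics, c = 16 for a double-LOH
analysis), per-chromosome probabilities are p̂₁ = k₁/(c·N₁) and
p̂₂ = k₂/(c·N₂), and

    T = (p̂₁ − p̂₂) / sqrt(p̂(1 − p̂)(1/N₁ + 1/N₂))

with the pooled p̂ and *patient* counts in the variance, evaluated against
a standard normal (two-sided), with odds ratio
[p̂₁/(1 − p̂₁)]/[p̂₂/(1 − p̂₂)].  With c > 1 this variance overstates the
per-chromosome sampling noise by a factor of c, making the test
conservative; the implementation reproduces this form deliberately and
exposes `variance="trials"` to substitute c·N.  Empty groups or degenerate
pooled proportions return flagged-undefined results rather than raising,
mirroring the exclusion of strata with no double-LOH patients.

BH q-values come from `scipy.stats.false_discovery_control` with the
significance threshold q < 0.01.  Fisher's exact test (two-sided, scipy)
covers mutation-status contrasts; the sample odds ratio ad/bc adds a
Haldane 0.5 to all cells only when the denominator vanishes, flagged.

The per-locus scan samples positions every 100 kb, partitions patients by
LOH status at each position, and computes T against per-patient call
counts that exclude the scanned chromosome.  Scan p-values are one-sided
upper-tail (the scan asks for *excess* occurrence in the LOH group);
global gene-level tests remain two-sided.  The −log₁₀ p track is smoothed
with a centred 20-bin running mean, truncated at the edges, with undefined
positions excluded from the window denominator.

The bimodality index fits an equal-variance two-component normal mixture
by EM (scikit-learn, tied covariance, 5 restarts) and reports
BI = √(π(1−π))·|m₁−m₂|/σ with the recommended cutoff 1.1.

## Break-point null model

Telomere-anchored partial-arm deletions are modelled as exactly one break
per patient in a region [a, b]; a single event of a homogeneous Poisson
process conditioned on one occurrence is uniform, which is the only
self-consistent reading of a "Poisson-distributed break point".  A break
patient has copy 1 below the break and 2 at or above it; whole-arm
patients have copy 1 throughout.  The cohort mean at x is
[n_b(1 + F(x)) + n_f]/(n_b + n_f) with F the uniform CDF, rising from 1.0
at the telomere-side bound to (2n_b + n_f)/(n_b + n_f) at the
centromere-side bound — 1.627 for the 212 + 126 configuration.  The
simulator emits the grid profile, the analytic curve, and the exact
standard error of the simulated mean, √(n_b F(1−F))/(n_b + n_f).
Deletion/amplification-conditioned mean profiles over real cohorts include
only patients carrying a sub-2 (or supra-2) total-copy segment on the arm
and average per grid position over covered patients.

## Co-dependency graphs and centrality

Edges connect genes u, v iff either appears in the other's top-k
co-dependency list (k = 100 by default; lists may be supplied or derived
by ranking pairwise correlations), weighted by the pairwise-complete
Pearson correlation of their effect vectors (edges with fewer than 10
complete pairs are skipped; constant vectors are excluded).  Edges with
r ≤ 0 are dropped by default, so penalties 1 − r are non-negative; a
switch admits them with penalty > 1.  Isolated vertices stay in the graph,
flagged.

All-pairs shortest paths use Floyd–Warshall over penalties with path
multiplicities counted under an absolute length tolerance of 1e−9 — with
real-valued weights exact ties are measure-zero, but a tolerance is needed
for reproducible counting.  Betweenness g(v) sums σ_st(v)/σ_st over
unordered pairs {s, t} within v's connected component (the ordered-pair
variant is exactly 2× and vanishes under the min–max normalisation
(g − min g)/(max g − min g), which pins the most central vertex to 1).
Components smaller than 3, or with flat scores, return all-zero normalised
values flagged degenerate.

## Synthetic cohorts

The generator emulates the statistical structure the pipeline assumes,
not any particular cancer-type composition.  The bundled genome has three
metacentric chromosomes (200, 160, 130 Mb) and one submetacentric marker
chromosome (120 Mb); background is diploid (1, 1).  Defaults, chosen once
as the study conditions: per-chromosome isochromosome probability 0.1,
monocentric fraction 0.4, fragmentation rate 1 fragment per 12 Mb of
fusion distance, fragment-size law Mott(μ = 0.9 Mb^−β, β = 0.7) giving a
mean fragment of ≈ 1.5 Mb so planted bridges fit inside the synthetic arms
while the LOH arm's modal minor stays 0, marker-LOH prevalence 0.3, and
coupling odds ratio 1 (no association) unless configured.

Monocentric plants put the whole LOH arm at (1, 0) opposite a retained arm
at (2, 1).  Dicentric plants draw a fusion distance uniformly on the arm
(10 Mb minimum, 5 Mb telomere margin), anchor one fragment's outer
boundary exactly at the fusion site, and add a Poisson(rate × distance)
number of further fragments at (1, 1) with positive gaps between them;
fragment sizes are inverse-survival Mott draws, resampled (never
re-counted) when they cannot fit, so the expected count stays linear in
distance and the OLS slope is an unbiased estimate of the planted rate.
The truth table records the planted arm, centricity, fusion site, fragment
count and marker status per patient × chromosome, and the caller recovers
it exactly on noise-free cohorts.  Marker-LOH patients carry a (1, 0)
segment over the marker interval (with ≤ 1 Mb random boundary jitter);
their per-chromosome isochromosome probability is the baseline shifted by
log(odds ratio).  At most one isochromosome is planted per chromosome.

The effect-matrix generator uses two latent factors, each driving half of
the spoke genes (loading 0.85); the hub loads hub_loading/√2 = 0.64 on
both, and idiosyncratic noise tops each gene up to unit variance, so with
zero measurement noise the population correlation of two genes is the
inner product of their loading rows.  Cross-cluster spokes are
uncorrelated, so shortest penalty paths between the clusters pass through
the hub, which therefore attains top betweenness.

What the generator does *not* emulate: segmentation noise and probe-level
artifacts, subclonality, multi-event chromosomes, real chromosome-arm
length distributions, cancer-type composition, and expression/survival
layers.  Passing oracle-equivalence tests therefore demonstrates the
correctness of the algorithms under their stated model, not robustness to
noisy real-world segmentations.

## Problem sizes in the test and acceptance runs

Oracle equivalence uses a 200-patient cohort; rate recovery uses a
3000-patient cohort (~2,300 dicentrics); Mott recovery uses 2,000 seeded
survival draws at (μ, β) = (0.05 Mb^−β, 0.7); Wald calibration uses 1,000
null replicates at N₁ = N₂ = 50 with one trial per patient (where the
printed variance form coincides with the standard two-proportion test and
calibrates near the nominal 5%; with 17 trials per patient the same
formula is conservative, which a separate test asserts); odds-ratio
recovery uses 200 replicates at a planted OR of 5; the graph oracle uses
50 random 8-vertex graphs against exhaustive simple-path enumeration and
100 planted-hub matrices.

## Known limitations

- Integer ASCAT-style input only; no subclonal copy numbers, no
  break-fusion-bridge cycle inference, no ISCN karyotype strings.
- The caller evaluates condition 3 against the heterozygous arm's modal
  *total* exactly as specified, which on mixed-segment arms can differ
  from modal major + modal minor.
- The Mott fit is descriptive: it characterises surviving heterozygous
  fragments under the assumption that they are a uniform sample of all
  fracture products (LOH gaps between them are unobserved losses).
- The scan's one-sided p-values and the global tests' two-sided p-values
  are deliberately asymmetric; mixing them in one FDR pass would be
  incoherent.
- `cohort_frequency` rounds half-up to one decimal, matching how such
  percentages are conventionally reported.
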