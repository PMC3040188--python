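# Methods

This note records the statistical model behind `poolscan`, the parameter
choices that matter, and the design decisions taken where the published
analysis it follows leaves details open.

## The pooled-GWAS measurement model

A pooled scan replaces individual genotypes with per-pool allele-frequency
estimates. Per probe and array, the Relative Allele Signal (RAS) is treated
as `f_pool` plus noise, where `f_pool` is the allele frequency among the
pooled individuals. Two error layers are distinguished, following the
variance-decomposition rationale of multi-replicate pooling designs:

- **pool-construction error** (`tau`, sd units of allele frequency), drawn
  once per pooling event, i.e. per (probe, pool, replicate) — repeated
  constitution of the same pool gives independent draws, so averaging the R
  replicate arrays of a pool divides this variance by R (R = 3 by default);
- **measurement error** (`sigma`), drawn once per array cell — averaging
  across all arrays divides this variance by the array count (24).

RAS values are clipped to [0, 1]. Gaussian additive noise is the simplest
law compatible with the variance decomposition; nothing downstream depends
on the noise law beyond its second moments, except the clipping at the
extremes (one reason extreme-frequency probes are removed by QC).

A third, often dominant, variance source is **cohort sampling**: a pool of
~33 individuals estimates the group frequency with binomial sd
`sqrt(p(1-p)/(2*33)) ~ 0.055`, and two groups of ~134 differ by
`sqrt(2 p q / 268) ~ 0.04` under the null. This is irreducible by array
replication and is modelled explicitly through individual genotype
simulation (below).

## The silhouette statistic

Per probe, the 24 arrays are scalar points; the two phenotype groups are
pre-assigned clusters. With Manhattan distance (absolute difference),
`a_i` is the mean distance of element i to the other members of its group
(self excluded; 0 for a singleton), `b_i` the mean distance to the other
group, `s_i = (b_i - a_i)/max(a_i, b_i)` (0 when the maximum is 0), and the
probe score is the mean of `s_i`. Scores lie in [-1, 1]; 1 means perfect
separation, 0 a constant probe.

Silhouette is used instead of an F statistic (RAS values near the [0, 1]
boundary are far from Gaussian) and instead of plain group differences
(which ignore within-group variability). An absolute-difference column is
still reported for description. Design choices:

- `a_i` excludes the element itself (the standard definition); an
  include-self variant is available for sensitivity analysis
  (`silhouette_include_self`).
- each array is one element (24 elements); replicate-averaged pools
  (8 elements) are available via `silhouette_elements="pools"`.
- missing cells drop that element for that probe; a probe with an empty
  group is recorded as unscored with a reason, not an error.

The implementation is vectorised but is verified in the test suite against
a brute-force double-loop oracle to 12 decimals, including missing-value
cases, and against a hand-computed example
({0.2, 0.3} vs {0.6, 0.8} → 0.653734).

## Selection, clustering, and the cluster-adapted threshold

The top `ceil(0.01 * n_scored)` probes by silhouette are selected (ties at
the cutoff included). Because a real association should be shared by
neighbouring markers in one LD block, selected probes are chained along
each chromosome: consecutive selected probes join when their gap is
strictly below 30 kb, and chains with fewer than 2 probes are dropped.

Significance is size-adapted: scores are permuted uniformly over all scored
probes (positions fixed), the selection and clustering are re-run, and
every permuted cluster's (size, average silhouette) is recorded over 100
permutations. The threshold `t_k` is the 95th percentile of permuted
averages at size k (`threshold_summary` also offers `mean` and `max`; the
quantile default gives a calibrated null rather than an uncontrolled
extreme). A real cluster is significant iff its average silhouette strictly
exceeds `t_k`. Cluster sizes never observed in the null inherit the
threshold of the largest smaller size with data and are flagged — a
conservative-coverage fallback, since larger clusters are rarer under the
null. Representative SNP: the member with the highest silhouette, ties
broken by smallest position, for determinism.

### Known limitation: exchangeability under LD

The reshuffle null treats scores as exchangeable across probes. Under LD,
probes in one block share genotypes, hence pool frequencies, hence nearly
identical silhouettes: a real cluster averages *correlated* scores, while a
permuted cluster averages independent draws (whose mean is less dispersed).
The 95th percentile of a k-draw mean sits below the 95th percentile of a
single draw, so block-coherent clusters exceed `t_k` at more than the
nominal rate. On null simulations with perfect within-block LD this
package measures an empirical exceedance of roughly 15% at the 95th
percentile (see `tests/test_acceptance.py::TestNullCalibration`). Users
should read the threshold as a strong *ranking* device, not an exact
type-I-error guarantee — consistent with its intended role of prioritising
candidates for individual-genotyping validation rather than declaring
genome-wide significance.

### Known limitation: detectable effect sizes

With two groups of ~134 individuals, the null between-group frequency
difference has sd ~0.04 per block; across ~12,000 independent blocks its
expected maximum is ~0.15. Planted differences of that order therefore sit
*inside* the null tail, and only a fraction of them can outrank it — the
recovery test over 20 seeds at Δ = 0.15 recovers a median of ~4/10 planted
blocks (`TestPlantedBlockRecovery`). This is a property of the cohort size,
not of the statistic: reliable recovery at this design needs planted
differences ≳ 0.25, which is the regime used in the fast unit tests. The
passing tests therefore demonstrate correctness of the machinery and
honest behaviour at realistic effect sizes, not that a 269-subject pooled
scan reliably pinpoints 0.15-frequency-difference loci.

## Synthetic cohorts

`SimulationConfig` defaults describe the study design the pipeline targets:

| parameter | default | meaning |
|---|---|---|
| `n_probes` | 50,000 | markers simulated (a desk-scale stand-in for a 500k array) |
| `mean_spacing_bp` | 6,400 | mean inter-marker gap (3.2 Gb / 500k markers), exponential spacing |
| `block_length_bp` | 20,000 | mean LD-block span (typical European block scale) |
| maf prior | 0.05 + 0.45·Beta(2, 2) | block allele frequency, one per block per group |
| `n_pools_per_group` / `n_replicates` | 4 / 3 | 24 arrays total |
| `pool_size_min..max` | 31–36 | individuals per pool, drawn uniformly |
| `effect_delta` | 0.15 | exact group frequency difference on effect blocks |
| `n_effect_blocks` | 10 | planted blocks, chosen among blocks with ≥ 2 probes |
| `tau`, `sigma` | 0.03, 0.03 | construction / measurement error sd |
| `ld_mixing` | 1.0 | within-block haplotype correlation (1 = perfect LD) |

Genotypes are drawn per individual as two Bernoulli(p) haplotype indicators
at block level and copied to every probe of the block (perfect LD;
`ld_mixing < 1` interpolates toward independent probes). Block membership
uses the memoryless property of exponential block lengths: a new block
starts after a gap g with probability `1 - exp(-g/block_length)`. Effect
blocks are planted only on blocks with ≥ 2 probes because a single-marker
block cannot satisfy the 2-probe cluster requirement — an indirect design
can only detect loci spanned by at least two markers.

What the generator does *not* emulate: realistic haplotype mosaics and
partial r² structure (blocks are all-or-nothing), allele-frequency
correlation between neighbouring blocks, array-specific intensity biases,
batch effects, and differential hybridisation of the two alleles. Passing
recovery tests therefore speak to the pipeline's statistics, not to
array-specific artefacts. With the chosen allele-frequency prior, the
default noise gives within-triplicate Pearson correlations around 0.87–0.90
(most between-probe variance is allele-frequency spread); tighter replicate
correlations (> 0.96) would correspond to `tau = sigma ≈ 0.015`.

## Quality control conventions

- Probe QC: strict inequalities, `0.1 < mean RAS < 0.9` and `AAD < 0.28`.
  AAD is the mean absolute deviation of per-array RAS from the probe mean;
  a pairwise mean-absolute-difference variant is available
  (`aad_method="pairwise"`) since the acronym admits both readings.
- Sample CV filter: keep iff `sd/mean ≤ 0.1` (sample sd, n−1). The filter
  exists to drop unreliable triplicate quantifications before equimolar
  pooling.
- Probes with fewer than two non-missing arrays fail with reason
  "insufficient data"; missing cells are excluded pairwise everywhere
  downstream.
- The PCA stratification check centres (but does not scale) the
  marker-restricted matrix, projects arrays onto PC1–PC2, and reports the
  silhouette of the group labels under Manhattan distance as a mixing
  score; |score| near 0 means no recognisable substructure, and an alarm
  threshold (default 0.5) flags separation. A zero-variance matrix is
  degenerate and scores 0 by convention.

## Association statistics

- HWE: conditional exact test (sum of heterozygote-count probabilities not
  exceeding the observed one, given allele counts), with a chi-squared
  variant. Verified against exact-rational enumeration for all tables with
  total ≤ 25.
- Fisher 2×2: two-sided exact p (hypergeometric tail summation); odds
  ratio as the sample cross-product with Woolf CI, Haldane 0.5 correction
  when a cell is zero (flagged); exact conditional MLE OR available.
  "Conditional OR" is read as the standard cross-product OR since no
  conditioning variable is defined; the exact conditional OR is the option.
- Genotypic tests: dominant/recessive collapse to 2×2 Fisher;
  2-df genotypic uses Freeman–Halton enumeration up to total 500 and a
  chi-squared fallback above (method reported in the result).
- Rate reconstruction: positives = round(n·pct/100), half away from zero;
  ratio form solves m/f = r with m + f = n. Reconstructed counts are
  returned as the table itself so provenance is visible.
- No multiple-testing correction is applied by default at the validation
  stage (raw p-values reported), mirroring common second-stage practice.

## Power model

`D' = (1 - theta)^G` with `theta` from the marker–disease distance at
1 cM/Mb (both the conversion and the 3.2 Gb genome length are
config-exposed, because the resulting minimum n depends on them).
Penetrances solve `K = f0[(1-p)^2 + grr_het·2p(1-p) + grr_hom·p^2]`;
infeasible combinations (f > 1) are rejected. Marker–disease haplotype
frequencies use `D = D'·Dmax` with
`Dmax = min(p_d(1-p_m), (1-p_d)p_m)`, oriented so the marker allele tags
the risk allele (the favourable case; "worst case" refers to the midway
distance only). Case/control marker frequencies follow by conditioning on
affection status under random mating; the 1-df allelic test's power uses
the noncentral chi-squared with
`ncp = n·(p_case - p_control)^2 / (p̄(1-p̄))` for equal groups, which is
exactly the Pearson statistic of the expected allele-count table. Minimum
sample size is found by doubling + integer bisection (power is monotone in
n). A Monte-Carlo rejection-rate cross-check (`monte_carlo_power`) guards
the analytic path in the tests. With all defaults the model yields
D′ ≈ 0.9841 and a minimum of 136 cases and 136 controls for 80% power at
α = 0.05.

## Numerical conventions

- Silhouette 0/0 cases → 0; singleton-group `a_i` → 0.
- Top-fraction selection: `k = ceil(fraction · n_scored)`, cutoff ties
  included and reported through the selection size.
- Clustering boundaries are strict: a 30,000 bp gap does **not** join at
  `cluster_gap_bp = 30,000`; threshold comparison is strictly greater.
- Exact-test tie handling adds a 1e-12 relative guard when summing
  configurations with probability equal to the observed one.
- All randomness flows through `numpy.random.Generator` objects seeded from
  explicit config fields; simulation and permutation streams are separate.

## Problem sizes used in the automated checks

Unit tests run on cohorts of 120–4,000 probes; the end-to-end calibration
and recovery checks use 20 simulations of 50,000 probes × 24 arrays with
100 permutations each, and the exact-test oracles enumerate all tables with
total ≤ 25. These sizes were chosen so the full suite exercises the same
code paths as a 500k-marker scan at a desk-friendly scale.
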