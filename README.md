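# poolscan

Candidate-SNP selection for **pooled-DNA genome-wide association scans**.

In a pooled GWAS, DNA from groups of individuals (e.g. asthmatic vs.
non-asthmatic allergic children) is combined into pools, and each pool is
hybridised to SNP arrays. Per probe, the Relative Allele Signal
(RAS ∈ [0, 1], the mean of sense and antisense strand signals) estimates the
pool's allele frequency. The design this package targets splits each of two
phenotype groups into 4 independent pools of 31–36 individuals, constitutes
every pool three times, and measures 24 arrays in total, so that replicate
averaging shrinks pool-construction error variance by 3 and measurement
error variance by the number of arrays.

`poolscan` implements a complete selection pipeline for that design, for
researchers prioritising SNPs for second-stage individual genotyping:

- **Quality control** — sample filtering by triplicate concentration CV;
  probe filtering by mean RAS band (0.1 < RAS < 0.9) and Average Absolute
  Difference (AAD < 0.28); replicate-correlation and variance-nesting
  diagnostics; a PCA stratification check on ancestry-informative markers.
- **Silhouette ranking.** For one probe with per-array values
  x₁,…,x₂₄ and two phenotype groups as pre-assigned clusters, each array
  gets, under Manhattan distance,

  aᵢ = mean distance to its own group (self excluded),
  bᵢ = mean distance to the other group,
  sᵢ = (bᵢ − aᵢ) / max(aᵢ, bᵢ),

  and the probe score s = mean(sᵢ) ∈ [−1, 1] quantifies how well the SNP
  separates the two groups relative to within-group variability. The top
  1% of scores are selected as candidates.
- **Physical-distance clustering with cluster-adapted thresholds.** Because
  a true signal is shared across an LD block, selected probes are chained
  along each chromosome (gap < 30 kb, clusters of ≥ 2 probes). Significance
  is assessed per cluster size k by reshuffling the silhouettes over all
  scored probes, repeating selection + clustering (100×), and comparing each
  real cluster's average silhouette with the null distribution of permuted
  cluster averages at the same size.
- **Synthetic pooled cohorts** — a generator with LD-block structure,
  Hardy–Weinberg individual genotypes, planted group frequency differences,
  and the two-layer pooling error model, so the whole pipeline is testable
  without array data.
- **Second-stage statistics** — exact Hardy–Weinberg test, two-sided Fisher
  allelic/genotypic tests, odds ratios with Woolf 95% CIs, and
  reconstruction of 2×2 tables from printed group sizes and rates.
- **Indirect-association power** — D′ attenuation over G generations,
  D′ = (1 − θ)^G, penetrances solved from prevalence and genotype relative
  risks, and the 1-df allelic-test power/minimum-n computation of the
  classical genetic power calculators.

## Worked example

Power for the default indirect-association model (risk allele frequency
0.15, prevalence 0.4, GRR 1.7 for both carrier genotypes, marker frequency
0.2, α = 0.05, 500 generations, ~500,000 markers on 3.2 Gb):

```text
$ poolscan power
D' after 500 generations: 0.9841
penetrances f0=0.3349 f1=0.5694 f2=0.5694
minimum n per group for power >= 0.8: 136 (achieved power 0.8020)
```

So a marker 3.2 kb from the disease locus retains D′ ≈ 0.98 of its original
association after 500 generations, and 136 cases + 136 controls give 80%
power for the allelic test.

Reconstructing a published 2×2 association from printed rates (group sizes
135/134, positive rates 39.3%/21.6%):

```text
$ poolscan table2x2 --n1 135 --n2 134 --pct1 39.3 --pct2 21.6
        positive  negative
group1        53        82
group2        29       105
fisher two-sided p = 0.002231; OR = 2.34 (95% CI 1.37-4.00)
```

End-to-end on a synthetic cohort — simulate 5,000 probes with four planted
blocks (Δfreq = 0.25, low noise), then run the full pipeline:

```text
$ poolscan simulate --config sim.toml --seed 11 --out demo/data
simulated 5000 probes with seed 11 -> demo/data
$ poolscan run --ras demo/data/ras.tsv --annot demo/data/probes.tsv \
    --design demo/data/design.tsv --config run.toml --seed 11 --out demo/out
seed=11 scored=4853 selected=49 clusters=8 significant=3
$ cut -f1-7 demo/out/significant.tsv
cluster_id  chromosome  start    end      size  average_silhouette  representative_probe
C1          chr2        3993203  4055743  13    0.825561            snp003126
C2          chr2        11917283 11938276 4     0.778279            snp004357
C3          chr2        6461294  6472677  4     0.776433            snp003518
```

4,853 of 5,000 probes pass QC, the top 1% (49 probes) are clustered, and the
three clusters exceeding their size-adapted reshuffle threshold all overlap
planted effect blocks (check against `demo/data/truth.tsv`). Each cluster is
summarised by its representative SNP — the member with the highest
silhouette. Outputs include BED files of cluster spans for genome browsers.

The library mirrors the CLI: see `poolscan.run_pipeline`,
`poolscan.simulate_dataset`, `poolscan.snp_silhouette`,
`poolscan.min_sample_size`, etc.

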