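"""Synthetic pooled-cohort generator.

Emulates the data-generating process a pooled GWAS assumes: diploid
individuals in two phenotype groups, genotypes drawn under Hardy-Weinberg
from block-level population allele frequencies (probes inside an LD block
share the ancestral haplotype, so their genotypes are correlated), pooled
allele frequencies measured on replicate arrays, and two additive Gaussian
error components:

* pool-construction error ``tau`` — drawn once per (probe, pool, replicate)
  pooling event, i.e. once per independently constituted pool;
* array measurement error ``sigma`` — drawn once per array cell.

Averaging the R replicate arrays of one pool therefore divides the
construction variance by R, and averaging across all arrays divides the
measurement variance by the array count, matching the rationale of the
multi-replicate pooling design.

The default shape is the study design this package targets: 2 groups x
4 pools x 3 replicates = 24 arrays, 31-36 individuals per pool, ~6.4 kb
mean marker spacing (a 500k-marker array on a 3.2 Gb genome).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .io import PoolDesign, RasMatrix, ValidationError

__all__ = [
    "SimulationConfig",
    "Cohort",
    "SimulatedDataset",
    "simulate_cohort",
    "pool_frequencies",
    "simulate_ras",
    "simulate_dataset",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic pooled cohort.

    Allele frequencies are drawn per LD block from
    ``0.05 + 0.45 * Beta(maf_alpha, maf_beta)``, i.e. supported on
    (0.05, 0.5).  ``effect_delta`` is the absolute group difference planted
    on every probe of an effect block; the direction (which group carries the
    higher frequency) is randomised per block.  ``ld_mixing`` interpolates
    between perfect within-block LD (1.0, probes copy the block haplotype)
    and independent probes (0.0).
    """

    n_probes: int = 50_000
    n_chromosomes: int = 4
    mean_spacing_bp: float = 6_400.0
    block_length_bp: float = 20_000.0
    maf_alpha: float = 2.0
    maf_beta: float = 2.0
    n_effect_blocks: int = 10
    effect_delta: float = 0.15
    n_pools_per_group: int = 4
    n_replicates: int = 3
    pool_size_min: int = 31
    pool_size_max: int = 36
    tau: float = 0.03
    sigma: float = 0.03
    ld_mixing: float = 1.0
    group_labels: tuple[str, str] = ("case", "control")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_probes < 1:
            raise ValidationError("n_probes must be >= 1")
        if not (0.0 <= self.effect_delta < 0.5):
            raise ValidationError("effect_delta must lie in [0, 0.5)")
        if self.tau < 0 or self.sigma < 0:
            raise ValidationError("tau and sigma must be >= 0")
        if not (0.0 <= self.ld_mixing <= 1.0):
            raise ValidationError("ld_mixing must lie in [0, 1]")
        if self.n_effect_blocks < 0:
            raise ValidationError("n_effect_blocks must be >= 0")
        if self.pool_size_min < 1 or self.pool_size_max < self.pool_size_min:
            raise ValidationError("need 1 <= pool_size_min <= pool_size_max")
        if len(set(self.group_labels)) != 2:
            raise ValidationError("group_labels must be two distinct labels")


@dataclass
class Cohort:
    """Ground-truth output of :func:`simulate_cohort`."""

    genotypes: dict[str, pd.DataFrame]  # group -> probes x individuals minor-allele counts
    individuals: pd.DataFrame  # individual_id, group, pool
    annotations: pd.DataFrame  # probe_id, chromosome, position
    truth: pd.DataFrame  # probe_id, block_id, is_effect, p_<group> per group
    design: PoolDesign
    config: SimulationConfig


@dataclass
class SimulatedDataset:
    """Cohort plus the pooled measurements derived from it."""

    ras: RasMatrix
    pool_freqs: pd.DataFrame
    cohort: Cohort

    @property
    def design(self) -> PoolDesign:
        return self.cohort.design

    @property
    def annotations(self) -> pd.DataFrame:
        return self.cohort.annotations

    @property
    def truth(self) -> pd.DataFrame:
        return self.cohort.truth


def _probe_map(config: SimulationConfig, rng: np.random.Generator):
    """Lay probes on chromosomes with exponential spacing and block breaks.

    Block membership uses the memoryless property of exponential block
    lengths: a new block starts after a gap g with probability
    1 - exp(-g / block_length_bp), plus forced breaks at chromosome starts.
    """
    n = config.n_probes
    per_chrom = np.full(config.n_chromosomes, n // config.n_chromosomes, dtype=int)
    per_chrom[: n % config.n_chromosomes] += 1
    per_chrom = per_chrom[per_chrom > 0]
    chroms: list[np.ndarray] = []
    positions: list[np.ndarray] = []
    new_block: list[np.ndarray] = []
    for c, nc in enumerate(per_chrom, start=1):
        gaps = np.maximum(1, np.round(rng.exponential(config.mean_spacing_bp, nc))).astype(np.int64)
        pos = np.cumsum(gaps)
        brk = rng.random(nc) < -np.expm1(-gaps / config.block_length_bp)
        brk[0] = True
        chroms.append(np.full(nc, c, dtype=np.int32))
        positions.append(pos)
        new_block.append(brk)
    chrom = np.concatenate(chroms)
    position = np.concatenate(positions)
    block_id = np.cumsum(np.concatenate(new_block)) - 1
    return chrom, position, block_id


def _build_design(config: SimulationConfig, rng: np.random.Generator) -> tuple[PoolDesign, dict]:
    rows = []
    pool_sizes: dict[tuple[str, int], int] = {}
    for group in config.group_labels:
        for pool in range(1, config.n_pools_per_group + 1):
            size = int(rng.integers(config.pool_size_min, config.pool_size_max + 1))
            pool_sizes[(group, pool)] = size
            for rep in range(1, config.n_replicates + 1):
                rows.append(
                    {
                        "array_id": f"{group}_p{pool}_r{rep}",
                        "group": group,
                        "pool": pool,
                        "replicate": rep,
                        "pool_size": size,
                    }
                )
    table = pd.DataFrame(rows).set_index("array_id")
    return PoolDesign(table), pool_sizes


def simulate_cohort(config: SimulationConfig, rng: np.random.Generator | None = None) -> Cohort:
    """Simulate individual genotypes with LD-block structure and planted effects.

    Effect blocks are chosen uniformly among blocks containing at least two
    probes (a single-marker block cannot support the two-probe clustering
    this pipeline requires, so planting there would test nothing).  On an
    effect block the two group frequencies differ by exactly
    ``effect_delta``; elsewhere they are identical.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    chrom, position, block_id = _probe_map(config, rng)
    n_blocks = int(block_id[-1]) + 1
    block_sizes = np.bincount(block_id, minlength=n_blocks)

    base = 0.05 + 0.45 * rng.beta(config.maf_alpha, config.maf_beta, n_blocks)
    g1, g2 = config.group_labels
    p_group = {g1: base.copy(), g2: base.copy()}
    is_effect_block = np.zeros(n_blocks, dtype=bool)
    if config.n_effect_blocks > 0 and config.effect_delta > 0:
        eligible = np.flatnonzero(block_sizes >= 2)
        if len(eligible) < config.n_effect_blocks:
            raise ValidationError(
                f"only {len(eligible)} blocks with >= 2 probes, "
                f"cannot plant {config.n_effect_blocks} effect blocks"
            )
        chosen = rng.choice(eligible, size=config.n_effect_blocks, replace=False)
        is_effect_block[chosen] = True
        up_in_g1 = rng.random(config.n_effect_blocks) < 0.5
        for b, up in zip(chosen, up_in_g1):
            raised = g1 if up else g2
            p_group[raised][b] = base[b] + config.effect_delta

    design, pool_sizes = _build_design(config, rng)

    individuals_rows = []
    genotypes: dict[str, pd.DataFrame] = {}
    probe_ids = np.array([f"snp{i:06d}" for i in range(config.n_probes)])
    for group in config.group_labels:
        ids = []
        pools = []
        for pool in range(1, config.n_pools_per_group + 1):
            size = pool_sizes[(group, pool)]
            ids.extend(f"{group}_i{pool}_{k:02d}" for k in range(size))
            pools.extend([pool] * size)
        n_ind = len(ids)
        p = p_group[group]
        # block-level haplotypes, copied to every probe of the block
        hap = rng.random((n_blocks, n_ind, 2)) < p[:, None, None]
        geno_block = hap.sum(axis=2).astype(np.int8)
        geno = geno_block[block_id, :]
        if config.ld_mixing < 1.0:
            hap_probe = rng.random((config.n_probes, n_ind, 2)) < p[block_id, None, None]
            keep_block = rng.random((config.n_probes, n_ind, 2)) < config.ld_mixing
            hap_mixed = np.where(keep_block, hap[block_id], hap_probe)
            geno = hap_mixed.sum(axis=2).astype(np.int8)
        genotypes[group] = pd.DataFrame(geno, index=probe_ids, columns=ids)
        individuals_rows.append(
            pd.DataFrame({"individual_id": ids, "group": group, "pool": pools})
        )
    individuals = pd.concat(individuals_rows, ignore_index=True)

    annotations = pd.DataFrame(
        {
            "probe_id": probe_ids,
            "chromosome": [f"chr{c}" for c in chrom],
            "position": position,
        }
    )
    truth = pd.DataFrame(
        {
            "probe_id": probe_ids,
            "block_id": block_id,
            "is_effect": is_effect_block[block_id],
            f"p_{g1}": p_group[g1][block_id],
            f"p_{g2}": p_group[g2][block_id],
        }
    )
    return Cohort(genotypes, individuals, annotations, truth, design, config)


def pool_frequencies(
    genotypes: dict[str, pd.DataFrame], individuals: pd.DataFrame
) -> pd.DataFrame:
    """Per-(probe, group, pool) sample allele frequency.

    ``frequency = minor allele count / (2 * pool size)``.  Pool memberships
    must partition each group's genotyped individuals.
    """
    cols = {}
    for (group, pool), members in individuals.groupby(["group", "pool"], sort=True):
        if group not in genotypes:
            raise ValidationError(f"no genotype table for group {group!r}")
        table = genotypes[group]
        ids = members["individual_id"].tolist()
        missing = [i for i in ids if i not in table.columns]
        if missing:
            raise ValidationError(
                f"pool members absent from genotype table: {missing[:5]}"
            )
        counts = table[ids].to_numpy().sum(axis=1)
        cols[(group, int(pool))] = counts / (2.0 * len(ids))
    out = pd.DataFrame(cols, index=next(iter(genotypes.values())).index)
    out.columns = pd.MultiIndex.from_tuples(out.columns, names=["group", "pool"])
    return out


def simulate_ras(
    pool_freqs: pd.DataFrame,
    design: PoolDesign,
    tau: float,
    sigma: float,
    rng: np.random.Generator | None = None,
) -> RasMatrix:
    """Measure pooled frequencies on replicate arrays with two error layers.

    ``RAS = clip(f_pool + e_construction + e_measurement, 0, 1)`` where
    ``e_construction ~ N(0, tau^2)`` per pooling event (probe, pool,
    replicate) and ``e_measurement ~ N(0, sigma^2)`` per array cell.
    """
    if tau < 0 or sigma < 0:
        raise ValidationError("tau and sigma must be >= 0")
    rng = np.random.default_rng(0) if rng is None else rng
    n_probes = len(pool_freqs)
    data = {}
    for array_id, row in design.table.iterrows():
        key = (row["group"], int(row["pool"]))
        if key not in pool_freqs.columns:
            raise ValidationError(f"pool {key} absent from pool frequencies")
        f = pool_freqs[key].to_numpy()
        construction = rng.normal(0.0, tau, n_probes) if tau > 0 else 0.0
        measurement = rng.normal(0.0, sigma, n_probes) if sigma > 0 else 0.0
        data[array_id] = np.clip(f + construction + measurement, 0.0, 1.0)
    values = pd.DataFrame(data, index=pool_freqs.index)
    return RasMatrix(values)


def simulate_dataset(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> SimulatedDataset:
    """One-stop simulation: cohort genotypes -> pool frequencies -> RAS arrays."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    cohort = simulate_cohort(config, rng)
    freqs = pool_frequencies(cohort.genotypes, cohort.individuals)
    ras = simulate_ras(freqs, cohort.design, config.tau, config.sigma, rng)
    return SimulatedDataset(ras, freqs, cohort)


def write_dataset(dataset: SimulatedDataset, out_dir: str | Path) -> None:
    """Write ras.tsv, probes.tsv, design.tsv and truth.tsv for a simulation."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dataset.ras.to_file(out / "ras.tsv")
    dataset.annotations.to_csv(out / "probes.tsv", sep="\t", index=False, lineterminator="\n")
    dataset.design.to_file(out / "design.tsv")
    dataset.truth.to_csv(out / "truth.tsv", sep="\t", index=False, lineterminator="\n")
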