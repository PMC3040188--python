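"""Genomic clustering of top-scoring SNPs and cluster-adapted thresholds.

A true association signal is expected to be shared by several markers inside
one LD block, so instead of thresholding single probes, the top-scoring
probes are chained along each chromosome: two consecutive selected probes
join the same cluster when their distance is strictly below ``gap_bp``
(default 30 kb), and only clusters of at least ``min_cluster_size`` probes
(default 2) are kept.

Significance is assessed per cluster size by score reshuffling: silhouette
scores are permuted uniformly over all scored probes (genomic positions
fixed), the whole selection + clustering procedure is repeated, and the
permuted clusters' average silhouettes at each size form the null against
which real cluster averages are compared.  A cluster is called significant
when its average silhouette strictly exceeds the size-adapted threshold.
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import PipelineConfig, PoolDesign, RasMatrix, ValidationError
from .silhouette import select_top_count, select_top_fraction, silhouette_scan

__all__ = [
    "GenomicCluster",
    "ClusterThresholds",
    "cluster_by_distance",
    "reshuffle_thresholds",
    "call_significant",
    "robustness_sweep",
]


@dataclass(frozen=True)
class GenomicCluster:
    """A maximal chain of selected probes with inter-probe gaps below threshold."""

    cluster_id: str
    chromosome: str
    members: tuple[str, ...]  # sorted by position
    positions: tuple[int, ...]
    silhouettes: tuple[float, ...]
    average_silhouette: float
    representative: str  # member with maximum silhouette (ties: smallest position)

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def span(self) -> tuple[int, int]:
        return (self.positions[0], self.positions[-1])


@dataclass
class ClusterThresholds:
    """Size-adapted null thresholds t_k from score reshuffling."""

    thresholds: dict[int, float]
    n_permutations: int
    summary: str
    quantile: float
    null_counts: dict[int, int]  # permuted clusters observed per size
    inherited: frozenset[int] = field(default_factory=frozenset)

    def for_size(self, size: int) -> float:
        if size not in self.thresholds:
            raise ValidationError(f"no threshold available for cluster size {size}")
        return self.thresholds[size]


# ---------------------------------------------------------------------------
# genome-order helpers shared by the real pass and the permutation null


def _genome_arrays(scores, annotations: pd.DataFrame):
    """Scored probes in genomic order: (probe_ids, chrom_labels, positions, scores)."""
    if isinstance(scores, pd.DataFrame):
        scores = scores["s"]
    scored = pd.Series(scores).dropna()
    ann = annotations.set_index("probe_id")
    missing = scored.index.difference(ann.index)
    if len(missing):
        raise ValidationError(
            f"scored probes without annotation: {list(missing[:10])}"
        )
    sub = ann.loc[scored.index, ["chromosome", "position"]].copy()
    sub["s"] = scored
    sub = sub.sort_values(["chromosome", "position"], kind="mergesort")
    return (
        sub.index.to_numpy(),
        sub["chromosome"].to_numpy(),
        sub["position"].to_numpy(dtype=np.int64),
        sub["s"].to_numpy(dtype=float),
    )


def _chain(sel: np.ndarray, chrom: np.ndarray, pos: np.ndarray, gap_bp: int):
    """Split genome-ordered selected indices into chains (strict < gap_bp joins)."""
    if len(sel) == 0:
        return np.array([], dtype=np.int64), 0
    joined = (chrom[sel[1:]] == chrom[sel[:-1]]) & (
        pos[sel[1:]] - pos[sel[:-1]] < gap_bp
    )
    starts = np.flatnonzero(np.concatenate(([True], ~joined)))
    return starts, len(sel)


def _top_mask(values: np.ndarray, k: int) -> np.ndarray:
    cutoff = np.partition(values, len(values) - k)[len(values) - k]
    return values >= cutoff


def cluster_by_distance(
    selected,
    annotations: pd.DataFrame,
    scores,
    gap_bp: int = 30_000,
    min_size: int = 2,
) -> list[GenomicCluster]:
    """Single-linkage chaining of selected probes along each chromosome.

    Consecutive selected probes on one chromosome join when their gap is
    strictly below ``gap_bp``; chains shorter than ``min_size`` are
    discarded.  Cluster ids C1, C2, ... are assigned by descending average
    silhouette.
    """
    if isinstance(scores, pd.DataFrame):
        scores = scores["s"]
    scores = pd.Series(scores)
    selected = pd.Index(selected)
    ann = annotations.set_index("probe_id")
    missing = selected.difference(ann.index)
    if len(missing):
        raise ValidationError(f"selected probes without annotation: {list(missing[:10])}")
    missing_scores = selected.difference(scores.dropna().index)
    if len(missing_scores):
        raise ValidationError(
            f"selected probes without silhouette score: {list(missing_scores[:10])}"
        )
    sub = ann.loc[selected, ["chromosome", "position"]].copy()
    sub["s"] = scores.loc[selected]
    sub = sub.sort_values(["chromosome", "position"], kind="mergesort")
    probe_ids = sub.index.to_numpy()
    chrom = sub["chromosome"].to_numpy()
    pos = sub["position"].to_numpy(dtype=np.int64)
    s = sub["s"].to_numpy(dtype=float)

    sel = np.arange(len(sub))
    starts, n_sel = _chain(sel, chrom, pos, gap_bp)
    bounds = list(starts) + [n_sel]
    raw: list[GenomicCluster] = []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        if hi - lo < min_size:
            continue
        idx = sel[lo:hi]
        sils = s[idx]
        best = idx[np.argmax(sils)]  # argmax -> first max -> smallest position
        raw.append(
            GenomicCluster(
                cluster_id="",
                chromosome=str(chrom[idx[0]]),
                members=tuple(probe_ids[idx]),
                positions=tuple(int(p) for p in pos[idx]),
                silhouettes=tuple(float(v) for v in sils),
                average_silhouette=float(np.mean(sils)),
                representative=str(probe_ids[best]),
            )
        )
    raw.sort(key=lambda c: (-c.average_silhouette, c.chromosome, c.span[0]))
    return [
        GenomicCluster(
            cluster_id=f"C{i}",
            chromosome=c.chromosome,
            members=c.members,
            positions=c.positions,
            silhouettes=c.silhouettes,
            average_silhouette=c.average_silhouette,
            representative=c.representative,
        )
        for i, c in enumerate(raw, start=1)
    ]


def reshuffle_thresholds(
    scores,
    annotations: pd.DataFrame,
    config: PipelineConfig | None = None,
    rng: np.random.Generator | None = None,
    ensure_sizes=(),
) -> ClusterThresholds:
    """Cluster-adapted null thresholds by silhouette reshuffling.

    Each permutation assigns the calculated silhouettes uniformly at random
    to all scored probes (positions fixed), repeats top-fraction selection
    and distance clustering, and records every permuted cluster's (size,
    average silhouette).  ``t_k`` summarises the permuted averages at size k
    (default: 95th percentile).  Sizes in ``ensure_sizes`` never observed in
    the null inherit the threshold of the largest smaller size with data
    (else the smallest larger) and are flagged in ``inherited``.
    """
    config = config or PipelineConfig()
    rng = np.random.default_rng(config.rng_seed) if rng is None else rng
    _, chrom, pos, s = _genome_arrays(scores, annotations)
    n = len(s)
    if n == 0:
        raise ValidationError("no scored probes")
    k = max(1, math.ceil(config.top_fraction * n))
    by_size: dict[int, list[float]] = {}
    for _ in range(config.n_permutations):
        perm = s[rng.permutation(n)]
        sel = np.flatnonzero(_top_mask(perm, k))
        starts, n_sel = _chain(sel, chrom, pos, config.cluster_gap_bp)
        if n_sel == 0:
            continue
        sums = np.add.reduceat(perm[sel], starts)
        bounds = np.append(starts, n_sel)
        sizes = np.diff(bounds)
        keep = sizes >= config.min_cluster_size
        for size, total in zip(sizes[keep], sums[keep]):
            by_size.setdefault(int(size), []).append(float(total / size))

    thresholds: dict[int, float] = {}
    for size, vals in by_size.items():
        arr = np.asarray(vals)
        if config.threshold_summary == "mean":
            thresholds[size] = float(arr.mean())
        elif config.threshold_summary == "max":
            thresholds[size] = float(arr.max())
        else:
            thresholds[size] = float(np.quantile(arr, config.threshold_quantile))

    inherited = set()
    available = sorted(thresholds)
    for size in ensure_sizes:
        size = int(size)
        if size in thresholds or not available:
            continue
        smaller = [a for a in available if a < size]
        source = max(smaller) if smaller else min(a for a in available if a > size)
        thresholds[size] = thresholds[source]
        inherited.add(size)
    return ClusterThresholds(
        thresholds=thresholds,
        n_permutations=config.n_permutations,
        summary=config.threshold_summary,
        quantile=config.threshold_quantile,
        null_counts={size: len(v) for size, v in by_size.items()},
        inherited=frozenset(inherited),
    )


def call_significant(
    clusters: list[GenomicCluster], thresholds: ClusterThresholds
) -> list[GenomicCluster]:
    """Clusters whose average silhouette strictly exceeds their size threshold."""
    out = [c for c in clusters if c.average_silhouette > thresholds.for_size(c.size)]
    out.sort(key=lambda c: (-c.average_silhouette, c.chromosome, c.span[0]))
    return out


def robustness_sweep(
    ras: RasMatrix,
    design: PoolDesign,
    annotations: pd.DataFrame,
    config: PipelineConfig | None = None,
    top_settings=None,
    gaps_bp=(20_000, 25_000, 30_000, 35_000),
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Concordance of significant-cluster representatives across settings.

    Runs the full selection over a grid of starting datasets (top fraction
    or fixed top counts) x clustering gaps and reports the pairwise Jaccard
    overlap of the representative-SNP sets.  Cells whose significant set is
    empty are flagged as low-support in the details.
    """
    from .qc import probe_qc  # local import to avoid a cycle at module load

    config = config or PipelineConfig()
    rng = np.random.default_rng(config.rng_seed) if rng is None else rng
    qc = probe_qc(ras, config)
    scores = silhouette_scan(ras, design, qc_pass=qc.index[qc["pass_flag"]], config=config)
    n_scored = int(scores["s"].notna().sum())
    if top_settings is None:
        top_settings = [
            ("fraction", config.top_fraction),
            ("count", min(5000, n_scored)),
            ("count", min(7000, n_scored)),
        ]
    reps: dict[str, set] = {}
    details: dict[str, dict] = {}
    for (kind, value), gap in itertools.product(top_settings, gaps_bp):
        label = (
            f"top{value:g}" if kind == "fraction" else f"top{int(value)}probes"
        ) + f"|gap{gap // 1000}kb"
        if kind == "fraction":
            selected = select_top_fraction(scores, value)
        else:
            selected = select_top_count(scores, int(value))
        cell_cfg = config.with_updates(
            cluster_gap_bp=gap,
            top_fraction=(value if kind == "fraction" else min(0.999999, value / n_scored)),
        )
        clusters = cluster_by_distance(
            selected, annotations, scores, gap_bp=gap, min_size=config.min_cluster_size
        )
        thresholds = reshuffle_thresholds(
            scores,
            annotations,
            cell_cfg,
            rng=rng,
            ensure_sizes={c.size for c in clusters},
        )
        significant = call_significant(clusters, thresholds)
        reps[label] = {c.representative for c in significant}
        details[label] = {
            "n_selected": len(selected),
            "n_clusters": len(clusters),
            "n_significant": len(significant),
            "low_support": len(significant) == 0,
        }
    labels = list(reps)
    mat = pd.DataFrame(np.ones((len(labels), len(labels))), index=labels, columns=labels)
    for a, b in itertools.combinations(labels, 2):
        union = reps[a] | reps[b]
        jac = len(reps[a] & reps[b]) / len(union) if union else 1.0
        mat.loc[a, b] = mat.loc[b, a] = jac
    return mat, details
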