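"""End-to-end candidate-SNP selection pipeline.

Chains probe QC -> silhouette scan -> top-fraction selection -> physical
distance clustering -> reshuffle thresholds -> significant-cluster calls,
all driven by one :class:`~poolscan.io.PipelineConfig` and one seeded RNG.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .clustering import (
    ClusterThresholds,
    GenomicCluster,
    call_significant,
    cluster_by_distance,
    reshuffle_thresholds,
)
from .io import PipelineConfig, PoolDesign, RasMatrix, validate_probe_annotation
from .qc import probe_qc
from .silhouette import select_top_fraction, silhouette_scan

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    qc: pd.DataFrame
    scores: pd.DataFrame
    selected: pd.Index
    clusters: list[GenomicCluster]
    thresholds: ClusterThresholds
    significant: list[GenomicCluster]
    config: PipelineConfig

    @property
    def representatives(self) -> list[str]:
        return [c.representative for c in self.significant]


def run_pipeline(
    ras: RasMatrix,
    design: PoolDesign,
    annotations: pd.DataFrame,
    config: PipelineConfig | None = None,
    rng: np.random.Generator | None = None,
) -> PipelineResult:
    config = config or PipelineConfig()
    rng = np.random.default_rng(config.rng_seed) if rng is None else rng
    annotations = validate_probe_annotation(annotations)
    qc = probe_qc(ras, config)
    scores = silhouette_scan(ras, design, qc_pass=qc.index[qc["pass_flag"]], config=config)
    selected = select_top_fraction(scores, config.top_fraction)
    clusters = cluster_by_distance(
        selected,
        annotations,
        scores,
        gap_bp=config.cluster_gap_bp,
        min_size=config.min_cluster_size,
    )
    thresholds = reshuffle_thresholds(
        scores,
        annotations,
        config,
        rng=rng,
        ensure_sizes={c.size for c in clusters},
    )
    significant = call_significant(clusters, thresholds)
    return PipelineResult(qc, scores, selected, clusters, thresholds, significant, config)
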