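import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from poolscan import (
    PipelineConfig,
    ValidationError,
    call_significant,
    cluster_by_distance,
    reshuffle_thresholds,
    robustness_sweep,
    run_pipeline,
)
from poolscan.clustering import ClusterThresholds
from poolscan.simulate import SimulationConfig, simulate_dataset


def ann_frame(rows):
    return pd.DataFrame(rows, columns=["probe_id", "chromosome", "position"])


class TestClusterByDistance:
    def test_hand_chaining(self):
        ann = ann_frame(
            [["a", "chr1", 1000], ["b", "chr1", 25000], ["c", "chr1", 60000]]
        )
        scores = pd.Series({"a": 0.5, "b": 0.6, "c": 0.7})
        clusters = cluster_by_distance(["a", "b", "c"], ann, scores, gap_bp=30000)
        assert len(clusters) == 1
        assert clusters[0].members == ("a", "b")
        assert clusters[0].average_silhouette == pytest.approx(0.55)

    def test_exact_gap_not_joined(self):
        ann = ann_frame([["a", "chr1", 1000], ["b", "chr1", 31000]])
        scores = pd.Series({"a": 0.5, "b": 0.6})
        assert cluster_by_distance(["a", "b"], ann, scores, gap_bp=30000) == []
        joined = cluster_by_distance(["a", "b"], ann, scores, gap_bp=30001)
        assert len(joined) == 1

    def test_chromosome_barrier(self):
        ann = ann_frame([["a", "chr1", 1000], ["b", "chr2", 1000]])
        scores = pd.Series({"a": 0.5, "b": 0.6})
        assert cluster_by_distance(["a", "b"], ann, scores, gap_bp=10**9) == []

    def test_representative_max_silhouette_tie_smallest_position(self):
        ann = ann_frame(
            [["a", "chr1", 100], ["b", "chr1", 200], ["c", "chr1", 300]]
        )
        scores = pd.Series({"a": 0.4, "b": 0.7, "c": 0.7})
        clusters = cluster_by_distance(["a", "b", "c"], ann, scores, gap_bp=30000)
        assert clusters[0].representative == "b"

    def test_unannotated_probe_listed(self):
        ann = ann_frame([["a", "chr1", 100]])
        with pytest.raises(ValidationError, match="ghost"):
            cluster_by_distance(["a", "ghost"], ann, pd.Series({"a": 0.5, "ghost": 0.1}))

    @given(
        positions=st.lists(
            st.integers(1, 500_000), min_size=2, max_size=60, unique=True
        ),
        seed=st.integers(0, 10_000),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_partition_properties(self, positions, seed):
        rng = np.random.default_rng(seed)
        n = len(positions)
        ids = [f"p{i}" for i in range(n)]
        chroms = rng.choice(["chr1", "chr2"], n)
        ann = ann_frame(list(zip(ids, chroms, positions)))
        scores = pd.Series(rng.random(n), index=ids)
        order = rng.permutation(ids)
        clusters = cluster_by_distance(order, ann, scores, gap_bp=40_000)
        seen = []
        for c in clusters:
            assert c.size >= 2
            assert set(c.members) <= set(ids)
            assert all(np.diff(c.positions) < 40_000)
            seen.extend(c.members)
        assert len(seen) == len(set(seen))  # no probe in two clusters
        # spans on a chromosome never overlap
        by_chrom = {}
        for c in clusters:
            by_chrom.setdefault(c.chromosome, []).append(c.span)
        for spans in by_chrom.values():
            spans.sort()
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                assert e1 < s2
        # invariant to probe input order
        again = cluster_by_distance(sorted(order), ann, scores, gap_bp=40_000)
        assert {c.members for c in again} == {c.members for c in clusters}


class TestReshuffleThresholds:
    def _setup(self, n=3000, seed=0):
        rng = np.random.default_rng(seed)
        ids = [f"p{i}" for i in range(n)]
        ann = ann_frame(
            list(zip(ids, ["chr1"] * n, np.cumsum(rng.integers(1000, 12000, n))))
        )
        scores = pd.Series(rng.normal(0.1, 0.05, n), index=ids)
        return ann, scores

    def test_single_permutation_deterministic(self):
        ann, scores = self._setup()
        cfg = PipelineConfig(n_permutations=1, rng_seed=5)
        a = reshuffle_thresholds(scores, ann, cfg)
        b = reshuffle_thresholds(scores, ann, cfg)
        assert a.thresholds == b.thresholds
        assert a.null_counts == b.null_counts

    def test_unseen_sizes_inherit_and_flag(self):
        ann, scores = self._setup()
        cfg = PipelineConfig(n_permutations=3, rng_seed=1)
        thr = reshuffle_thresholds(scores, ann, cfg, ensure_sizes=[50])
        assert 50 in thr.thresholds and 50 in thr.inherited
        source = max(k for k in thr.null_counts if k < 50)
        assert thr.thresholds[50] == thr.thresholds[source]

    def test_summary_options_ordered(self):
        ann, scores = self._setup()
        base = dict(n_permutations=20, rng_seed=2)
        means = reshuffle_thresholds(
            scores, ann, PipelineConfig(threshold_summary="mean", **base)
        )
        maxes = reshuffle_thresholds(
            scores, ann, PipelineConfig(threshold_summary="max", **base)
        )
        quant = reshuffle_thresholds(scores, ann, PipelineConfig(**base))
        for size in means.thresholds:
            assert means.thresholds[size] <= maxes.thresholds[size] + 1e-12
            if size in quant.thresholds:
                assert quant.thresholds[size] <= maxes.thresholds[size] + 1e-12


class TestCallSignificant:
    def _cluster(self, avg, size=2):
        from poolscan.clustering import GenomicCluster

        return GenomicCluster(
            cluster_id="C1",
            chromosome="chr1",
            members=tuple(f"m{i}" for i in range(size)),
            positions=tuple(range(100, 100 + size)),
            silhouettes=(avg,) * size,
            average_silhouette=avg,
            representative="m0",
        )

    def _thr(self, value):
        return ClusterThresholds(
            thresholds={2: value}, n_permutations=1, summary="quantile",
            quantile=0.95, null_counts={2: 1},
        )

    def test_strictly_above_threshold_called(self):
        assert call_significant([self._cluster(0.577)], self._thr(0.40))
        assert not call_significant([self._cluster(0.40)], self._thr(0.40))

    def test_infinite_threshold_blocks_everything(self):
        assert call_significant([self._cluster(0.99)], self._thr(np.inf)) == []

    def test_missing_size_threshold_raises(self):
        from poolscan.clustering import GenomicCluster

        c = self._cluster(0.5, size=3)
        with pytest.raises(ValidationError, match="size 3"):
            call_significant([c], self._thr(0.1))


class TestEndToEnd:
    def test_planted_blocks_dominate_small_scan(self, small_dataset):
        ds = small_dataset
        cfg = PipelineConfig(top_fraction=0.05, n_permutations=30, rng_seed=9)
        res = run_pipeline(ds.ras, ds.design, ds.annotations, cfg)
        truth = ds.truth.set_index("probe_id")
        assert res.clusters, "expected at least one cluster"
        top = res.clusters[0]
        assert truth.loc[list(top.members), "is_effect"].any()

    def test_robustness_sweep_contract(self, small_dataset):
        ds = small_dataset
        cfg = PipelineConfig(top_fraction=0.05, n_permutations=10, rng_seed=3)
        mat, details = robustness_sweep(
            ds.ras,
            ds.design,
            ds.annotations,
            cfg,
            top_settings=[("fraction", 0.05), ("count", 40)],
            gaps_bp=(20_000, 30_000),
        )
        assert mat.shape == (4, 4)
        assert np.allclose(np.diag(mat), 1.0)
        assert ((mat.to_numpy() >= 0) & (mat.to_numpy() <= 1.0 + 1e-12)).all()
        assert set(details) == set(mat.index)

    def test_robustness_high_overlap_for_strong_signal(self):
        # strong, low-noise planted effects should be selected regardless of
        # the exact top-k and gap settings
        ds = simulate_dataset(
            SimulationConfig(
                n_probes=4000, n_chromosomes=2, n_effect_blocks=4,
                effect_delta=0.3, tau=0.015, sigma=0.015, seed=21,
            )
        )
        cfg = PipelineConfig(n_permutations=20, rng_seed=4)
        mat, details = robustness_sweep(
            ds.ras,
            ds.design,
            ds.annotations,
            cfg,
            top_settings=[("fraction", 0.01), ("count", 60)],
            gaps_bp=(20_000, 35_000),
        )
        off_diag = mat.to_numpy()[~np.eye(len(mat), dtype=bool)]
        assert off_diag.min() >= 0.5
        assert np.median(off_diag) >= 0.8
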