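"""Per-SNP silhouette statistic and top-quantile candidate selection.

For one probe, every array contributes one scalar RAS value and the two
phenotype groups play the role of two pre-assigned clusters.  With
Manhattan distance on scalars (|x_i - x_j|), each element i gets

    a_i = mean distance to the other members of its own group
          (self excluded; 0 for a singleton group),
    b_i = mean distance to the members of the other group,
    s_i = (b_i - a_i) / max(a_i, b_i)   (0 when max(a_i, b_i) = 0),

and the probe's silhouette is the mean of s_i over all elements.  Scores
range from -1 (bad separation) to 1 (the two groups are perfectly split),
and 0 for a constant probe.  Silhouette rewards a between-group frequency
shift that is large relative to the within-group spread, which is why it is
preferred here over plain absolute differences (blind to variability) and
F-statistics (RAS values near the [0, 1] edges are far from Gaussian).
"""
from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .io import PipelineConfig, PoolDesign, RasMatrix, ValidationError

__all__ = ["snp_silhouette", "silhouette_scan", "select_top_fraction", "select_top_count"]

_CHUNK = 2048


def _scan_block(
    x: np.ndarray, in_g1: np.ndarray, include_self: bool
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised silhouette for a block of probes.

    ``x`` is (probes, elements) with NaN for missing; ``in_g1`` a boolean
    element mask.  Returns (scores, n_valid_elements); a probe whose groups
    are not both represented gets NaN.
    """
    same = in_g1[:, None] == in_g1[None, :]
    off_diag = ~np.eye(len(in_g1), dtype=bool)
    own = same if include_self else (same & off_diag)
    other = ~same

    d = np.abs(x[:, :, None] - x[:, None, :])
    valid = ~np.isnan(x)
    pair_ok = valid[:, :, None] & valid[:, None, :]
    dz = np.where(pair_ok, np.nan_to_num(d), 0.0)

    own_w = pair_ok & own
    other_w = pair_ok & other
    a_cnt = own_w.sum(axis=2)
    b_cnt = other_w.sum(axis=2)
    a = np.where(a_cnt > 0, (dz * own_w).sum(axis=2) / np.maximum(a_cnt, 1), 0.0)
    with np.errstate(invalid="ignore"):
        b = (dz * other_w).sum(axis=2) / np.maximum(b_cnt, 1)
    m = np.maximum(a, b)
    with np.errstate(invalid="ignore", divide="ignore"):
        s_i = np.where(m > 0, (b - a) / m, 0.0)
    n1 = (valid & in_g1[None, :]).sum(axis=1)
    n2 = (valid & ~in_g1[None, :]).sum(axis=1)
    n_valid = n1 + n2
    with np.errstate(invalid="ignore"):
        s = np.where(valid, s_i, 0.0).sum(axis=1) / np.maximum(n_valid, 1)
    s = np.where((n1 >= 1) & (n2 >= 1), s, np.nan)
    return s, n_valid


def snp_silhouette(
    values, labels, include_self: bool = False
) -> float:
    """Silhouette of one probe's per-array values under two group labels."""
    x = np.asarray(values, dtype=float)
    lab = np.asarray(labels)
    if x.shape != lab.shape or x.ndim != 1:
        raise ValidationError("values and labels must be 1-D and aligned")
    uniq = pd.unique(lab)
    if len(uniq) != 2:
        raise ValidationError(f"exactly 2 groups required, found {list(uniq)}")
    in_g1 = lab == uniq[0]
    valid = ~np.isnan(x)
    if not (valid & in_g1).any() or not (valid & ~in_g1).any():
        raise ValidationError("each group needs at least one non-missing value")
    s, _ = _scan_block(x[None, :], in_g1, include_self)
    return float(s[0])


def _pool_elements(
    ras: RasMatrix, design: PoolDesign
) -> tuple[np.ndarray, np.ndarray]:
    """Replicate-averaged (group, pool) elements: one column per pool."""
    cols = []
    labels = []
    for group, pool in design.pools():
        arrays = [a for a in design.arrays_of_pool(group, pool) if a in ras.array_ids]
        if not arrays:
            continue
        with np.errstate(invalid="ignore"):
            cols.append(np.nanmean(ras.values[arrays].to_numpy(dtype=float), axis=1))
        labels.append(group)
    return np.column_stack(cols), np.asarray(labels)


def silhouette_scan(
    ras: RasMatrix,
    design: PoolDesign,
    qc_pass=None,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Silhouette score for every probe (optionally restricted to a QC-pass set).

    Returns a frame indexed by probe id with columns ``s`` (NaN with a
    ``reason`` when undefined), ``abs_diff`` (absolute difference of group
    mean RAS, reported alongside as a descriptive column, not a ranking
    statistic) and ``n_elements``.
    """
    config = config or PipelineConfig()
    if qc_pass is not None:
        qc_index = pd.Index(qc_pass)
        missing = qc_index.difference(ras.probe_ids)
        if len(missing):
            raise ValidationError(f"qc_pass probes absent from RAS matrix: {list(missing[:5])}")
        sub = RasMatrix(ras.values.loc[qc_index])
    else:
        sub = ras
    if config.silhouette_elements == "pools":
        x_all, labels = _pool_elements(sub, design)
    else:
        x_all = sub.values.to_numpy(dtype=float)
        labels = design.labels_for(sub.array_ids)
    groups = sorted(pd.unique(labels))
    if len(groups) != 2:
        raise ValidationError(f"exactly 2 groups required, found {groups}")
    in_g1 = labels == groups[0]

    n = len(sub.probe_ids)
    s = np.empty(n)
    n_valid = np.empty(n, dtype=int)
    for lo in range(0, n, _CHUNK):
        s[lo : lo + _CHUNK], n_valid[lo : lo + _CHUNK] = _scan_block(
            x_all[lo : lo + _CHUNK], in_g1, config.silhouette_include_self
        )
    import warnings

    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean1 = np.nanmean(np.where(in_g1[None, :], x_all, np.nan), axis=1)
        mean2 = np.nanmean(np.where(~in_g1[None, :], x_all, np.nan), axis=1)
    abs_diff = np.abs(mean1 - mean2)
    reason = np.where(np.isnan(s), "group without data", "")
    return pd.DataFrame(
        {"s": s, "abs_diff": abs_diff, "n_elements": n_valid, "reason": reason},
        index=sub.probe_ids,
    )


def _scores_series(scores) -> pd.Series:
    if isinstance(scores, pd.DataFrame):
        scores = scores["s"]
    return pd.Series(scores).dropna()


def select_top_fraction(scores, fraction: float) -> pd.Index:
    """The ceil(fraction * n) highest-scoring probes, cutoff ties included.

    ``scores`` may be the frame from :func:`silhouette_scan` or a Series;
    NaN scores are excluded before ranking.  The returned index is ordered
    by descending score.
    """
    if not (0.0 < fraction < 1.0):
        raise ValidationError("fraction must lie in (0, 1)")
    scored = _scores_series(scores)
    if scored.empty:
        raise ValidationError("no scored probes to select from")
    k = math.ceil(fraction * len(scored))
    return select_top_count(scored, k)


def select_top_count(scores, k: int) -> pd.Index:
    """The k highest-scoring probes (ties at the cutoff value included)."""
    scored = _scores_series(scores)
    if scored.empty:
        raise ValidationError("no scored probes to select from")
    k = min(int(k), len(scored))
    if k < 1:
        raise ValidationError("k must be >= 1")
    ordered = scored.sort_values(ascending=False, kind="mergesort")
    cutoff = ordered.iloc[k - 1]
    return ordered.index[ordered.to_numpy() >= cutoff]
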