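"""Sample- and probe-level quality control and stratification diagnostics.

Probe QC keeps a probe when its overall mean RAS lies strictly inside
(ras_low, ras_high) — excluding low minor-allele-frequency probes — and its
AAD (Average Absolute Difference, the mean absolute deviation of per-array
RAS from the probe mean) is strictly below ``aad_max`` — excluding
high-variability probes.  Sample QC drops DNA samples whose triplicate
concentration measurements vary too much (CV above ``cv_max``), since a
noisy quantification corrupts the equimolar pooling.

The population-stratification check projects arrays onto the first two
principal components of a user-supplied ancestry-informative probe subset
and summarises group separation with a silhouette-based mixing score:
values near 0 mean the two phenotype groups are intermixed (no recognisable
substructure); values near 1 flag stratification.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score as _sk_silhouette_score

from .io import PipelineConfig, PoolDesign, RasMatrix, ValidationError

__all__ = [
    "filter_samples_by_cv",
    "probe_qc",
    "replicate_correlation",
    "VarianceProfile",
    "variance_profile",
    "StratificationResult",
    "pca_stratification_check",
]


def filter_samples_by_cv(
    concentrations: pd.DataFrame, cv_max: float = 0.1
) -> pd.DataFrame:
    """Keep samples whose triplicate concentration CV is at most ``cv_max``.

    ``concentrations`` is samples x 3 replicate measurements (all > 0).
    CV = sample standard deviation (n-1 denominator) / mean.  Returns a
    table with mean, sd, cv and a ``kept`` flag per sample.
    """
    conc = pd.DataFrame(concentrations).astype(float)
    if conc.shape[1] != 3:
        raise ValidationError(
            f"expected exactly 3 replicate measurements per sample, got {conc.shape[1]}"
        )
    if (conc <= 0).to_numpy().any():
        bad = conc.index[(conc <= 0).any(axis=1)].tolist()
        raise ValidationError(f"non-positive concentration for samples {bad[:5]}")
    mean = conc.mean(axis=1)
    sd = conc.std(axis=1, ddof=1)
    cv = sd / mean
    return pd.DataFrame(
        {"mean": mean, "sd": sd, "cv": cv, "kept": cv <= cv_max}
    )


def _pairwise_mean_abs_diff(x: np.ndarray) -> np.ndarray:
    """Mean |x_i - x_j| over distinct array pairs, NaN-aware, per probe row."""
    d = np.abs(x[:, :, None] - x[:, None, :])
    n = x.shape[1]
    off = ~np.eye(n, dtype=bool)
    valid = ~np.isnan(d) & off
    num = np.where(valid, d, 0.0).sum(axis=(1, 2))
    cnt = valid.sum(axis=(1, 2))
    with np.errstate(invalid="ignore"):
        return np.where(cnt > 0, num / np.maximum(cnt, 1), np.nan)


def probe_qc(ras: RasMatrix, config: PipelineConfig | None = None) -> pd.DataFrame:
    """Per-probe QC record: mean RAS, AAD, pass flag and failure reason.

    A probe passes iff ``ras_low < mean_ras < ras_high`` and
    ``aad < aad_max`` (strict inequalities).  Probes with fewer than two
    non-missing values fail with reason ``insufficient data``.
    """
    config = config or PipelineConfig()
    x = ras.values.to_numpy(dtype=float)
    n_obs = (~np.isnan(x)).sum(axis=1)
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(np.where(np.isnan(x), np.nan, x), axis=1)
        mean[n_obs == 0] = np.nan
    if config.aad_method == "overall":
        with np.errstate(invalid="ignore"):
            aad = np.nanmean(np.abs(x - mean[:, None]), axis=1)
        aad[n_obs == 0] = np.nan
    else:  # pairwise
        aad = np.zeros(len(x))
        chunk = 4096
        for lo in range(0, len(x), chunk):
            aad[lo : lo + chunk] = _pairwise_mean_abs_diff(x[lo : lo + chunk])
    enough = n_obs >= 2
    in_band = enough & (mean > config.ras_low) & (mean < config.ras_high)
    low_var = enough & (aad < config.aad_max)
    passed = in_band & low_var
    reason = np.full(len(x), "", dtype=object)
    reason[~enough] = "insufficient data"
    reason[enough & ~in_band] = "mean RAS outside band"
    reason[enough & in_band & ~low_var] = "AAD too high"
    return pd.DataFrame(
        {
            "mean_ras": mean,
            "aad": aad,
            "n_obs": n_obs,
            "pass_flag": passed,
            "reason": reason,
        },
        index=ras.probe_ids,
    )


def replicate_correlation(
    ras: RasMatrix, design: PoolDesign, warn_below: float = 0.96
) -> tuple[pd.DataFrame, dict]:
    """Array x array Pearson correlation over probes, pairwise-complete.

    The summary separates within-triplicate pairs (same group and pool) from
    between-pool pairs of the same group and between-group pairs, and sets a
    warning flag when any within-triplicate correlation is undefined or
    falls below ``warn_below`` (technical replicates of a well-behaved
    experiment correlate above 0.96).
    """
    design.labels_for(ras.array_ids)  # ensures arrays are covered
    corr = ras.values.corr(min_periods=2)
    t = design.table
    within, between_pool, between_group = [], [], []
    ids = list(ras.array_ids)
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            c = corr.loc[a, b]
            if t.loc[a, "group"] != t.loc[b, "group"]:
                between_group.append(c)
            elif t.loc[a, "pool"] == t.loc[b, "pool"]:
                within.append(c)
            else:
                between_pool.append(c)
    within_arr = np.asarray(within, dtype=float)
    n_undefined = int(np.isnan(corr.to_numpy()).sum() - np.isnan(np.diag(corr)).sum())
    summary = {
        "within_triplicate_min": float(np.nanmin(within_arr)) if len(within_arr) else np.nan,
        "within_triplicate_mean": float(np.nanmean(within_arr)) if len(within_arr) else np.nan,
        "between_pool_mean": float(np.nanmean(between_pool)) if between_pool else np.nan,
        "between_group_mean": float(np.nanmean(between_group)) if between_group else np.nan,
        "n_undefined_pairs": n_undefined,
        "warning": bool(
            len(within_arr) == 0
            or np.isnan(within_arr).any()
            or np.nanmin(within_arr) < warn_below
        ),
    }
    return corr, summary


@dataclass
class VarianceProfile:
    """Mean/dispersion of per-probe RAS variance at three nesting levels.

    ``replicate`` averages the variance within each technical triplicate,
    ``group`` the variance within each phenotype class, ``overall`` the
    variance across all arrays.  Homogeneous data shows the three means
    close together, ordered replicate <= group <= overall; a planted group
    difference widens the overall level only.
    """

    mu_replicate: float
    mu_group: float
    mu_overall: float
    sd_replicate: float
    sd_group: float
    sd_overall: float
    nesting_ok: bool

    def as_dict(self) -> dict:
        return {
            "mu_replicate": self.mu_replicate,
            "mu_group": self.mu_group,
            "mu_overall": self.mu_overall,
            "sd_replicate": self.sd_replicate,
            "sd_group": self.sd_group,
            "sd_overall": self.sd_overall,
            "nesting_ok": self.nesting_ok,
        }


def variance_profile(ras: RasMatrix, design: PoolDesign) -> VarianceProfile:
    vals = ras.values
    per_trip = []
    for group, pool in design.pools():
        arrays = design.arrays_of_pool(group, pool)
        per_trip.append(vals[arrays].var(axis=1, ddof=1))
    var_rep = pd.concat(per_trip, axis=1).mean(axis=1)
    per_group = []
    t = design.table
    for group in design.groups:
        arrays = t.index[t["group"] == group].tolist()
        per_group.append(vals[arrays].var(axis=1, ddof=1))
    var_group = pd.concat(per_group, axis=1).mean(axis=1)
    var_all = vals.var(axis=1, ddof=1)
    mu_a, mu_b, mu_c = (float(v.mean()) for v in (var_rep, var_group, var_all))
    return VarianceProfile(
        mu_replicate=mu_a,
        mu_group=mu_b,
        mu_overall=mu_c,
        sd_replicate=float(var_rep.std(ddof=1)),
        sd_group=float(var_group.std(ddof=1)),
        sd_overall=float(var_all.std(ddof=1)),
        nesting_ok=bool(mu_a <= mu_b + 1e-12 and mu_b <= mu_c + 1e-12),
    )


@dataclass
class StratificationResult:
    coordinates: pd.DataFrame  # array_id, PC1, PC2, group
    mixing_score: float
    degenerate: bool
    alarm: bool
    explained_variance_ratio: tuple[float, ...]


def pca_stratification_check(
    ras: RasMatrix,
    design: PoolDesign,
    marker_subset: list[str],
    alarm_threshold: float = 0.5,
) -> StratificationResult:
    """Project arrays onto PC1-PC2 of an ancestry-informative probe subset.

    The mixing score is the silhouette of the two phenotype labels in PC
    space under Manhattan distance: near 0 when groups are intermixed (no
    substructure), near 1 when arrays separate by group.  ``alarm`` is set
    when the score exceeds ``alarm_threshold``.  A zero-variance input is
    degenerate and scores 0 by convention.
    """
    if len(marker_subset) < 2:
        raise ValidationError("marker subset must contain at least 2 probes")
    missing = [p for p in marker_subset if p not in ras.probe_ids]
    if missing:
        raise ValidationError(f"marker probes absent from RAS matrix: {missing[:10]}")
    labels = design.labels_for(ras.array_ids)
    x = ras.values.loc[marker_subset].to_numpy(dtype=float).T  # arrays x probes
    col_mean = np.nanmean(np.where(np.isnan(x), np.nan, x), axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    inds = np.where(np.isnan(x))
    x[inds] = col_mean[inds[1]]
    centered = x - x.mean(axis=0)
    total_var = float((centered**2).sum())
    if total_var < 1e-24:
        coords = pd.DataFrame(
            {"PC1": np.zeros(len(labels)), "PC2": np.zeros(len(labels)), "group": labels},
            index=ras.array_ids,
        )
        return StratificationResult(coords, 0.0, True, False, (0.0, 0.0))
    n_comp = min(2, min(centered.shape) - 1) or 1
    pca = PCA(n_components=n_comp, svd_solver="full")
    pcs = pca.fit_transform(centered)
    if pcs.shape[1] < 2:
        pcs = np.column_stack([pcs, np.zeros(len(pcs))])
    coords = pd.DataFrame(
        {"PC1": pcs[:, 0], "PC2": pcs[:, 1], "group": labels}, index=ras.array_ids
    )
    score = float(
        _sk_silhouette_score(pcs[:, :2], labels, metric="manhattan")
    )
    evr = tuple(float(v) for v in pca.explained_variance_ratio_[:2])
    return StratificationResult(coords, score, False, score > alarm_threshold, evr)
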