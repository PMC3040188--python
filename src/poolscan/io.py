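"""File formats, domain containers and configuration for the pooled-array pipeline.

All tabular interchange uses one TSV dialect: tab-separated, UTF-8, Unix
newlines, with ``.`` or an empty cell denoting a missing value.  Probe
annotations carry 1-based genomic positions; BED output converts to the
0-based half-open convention expected by genome browsers.

The central containers are

``RasMatrix``
    probes x arrays of Relative Allele Signal (RAS) values in [0, 1].  A RAS
    value is the mean of the sense and antisense strand signals of a SNP
    probe quartet and serves as a quantitative index of the allele frequency
    in a DNA pool.
``PoolDesign``
    maps each array to a (phenotype group, pool, replicate) triple, mirroring
    the multi-pool design in which each of two phenotype groups is split into
    several independent pools and every pool is constituted and hybridised
    several times.
"""
from __future__ import annotations

import math
import tomllib
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MISSING_TOKENS = frozenset({"", ".", "NA", "NaN", "nan"})

__all__ = [
    "PoolscanError",
    "ParseError",
    "ValidationError",
    "RasMatrix",
    "PoolDesign",
    "PipelineConfig",
    "read_ras_table",
    "write_ras_table",
    "read_pool_design",
    "write_pool_design",
    "read_probe_annotation",
    "write_probe_annotation",
    "validate_probe_annotation",
    "write_cluster_report",
]


class PoolscanError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(PoolscanError):
    """A file could not be parsed into the expected tabular structure."""


class ValidationError(PoolscanError):
    """Parsed data violates a structural invariant."""


# ---------------------------------------------------------------------------
# RAS matrices


@dataclass
class RasMatrix:
    """Probes x arrays matrix of RAS values in [0, 1]; NaN marks missing cells."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.values
        if vals.index.duplicated().any():
            dup = vals.index[vals.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate probe ids: {dup[:5]}")
        if vals.columns.duplicated().any():
            dup = vals.columns[vals.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate array ids: {dup[:5]}")
        arr = vals.to_numpy(dtype=float)
        bad = (arr < 0.0) | (arr > 1.0)
        bad &= ~np.isnan(arr)
        if bad.any():
            i, j = map(int, np.argwhere(bad)[0])
            raise ValidationError(
                f"RAS value {arr[i, j]!r} outside [0, 1] "
                f"(probe {vals.index[i]!r}, array {vals.columns[j]!r})"
            )
        # normalise dtype once so downstream numerics never re-coerce
        self.values = vals.astype(float)

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def array_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_missing(self) -> int:
        return int(self.values.isna().to_numpy().sum())

    def to_file(self, path: str | Path) -> None:
        out = self.values.map(lambda v: "." if pd.isna(v) else f"{v:.6f}")
        out.to_csv(path, sep="\t", index_label="probe_id", lineterminator="\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "RasMatrix":
        return read_ras_table(path)


def read_ras_table(path: str | Path) -> RasMatrix:
    """Read a probes x arrays RAS table.

    The first column holds probe ids, the header row array ids; cells are
    numeric in [0, 1] or missing.  Malformed numeric cells raise
    :class:`ParseError` naming the offending probe and array.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    raw.index = raw.index.astype(str)
    missing = raw.isin(MISSING_TOKENS)
    num = raw.apply(pd.to_numeric, errors="coerce")
    unparsed = num.isna() & ~missing
    if unparsed.to_numpy().any():
        i, j = map(int, np.argwhere(unparsed.to_numpy())[0])
        raise ParseError(
            f"malformed numeric cell {raw.iat[i, j]!r} "
            f"(probe {raw.index[i]!r}, array {raw.columns[j]!r}) in {path}"
        )
    num = num.where(~missing, np.nan)
    return RasMatrix(num)


def write_ras_table(ras: RasMatrix, path: str | Path) -> None:
    ras.to_file(path)


# ---------------------------------------------------------------------------
# Pool design


DESIGN_COLUMNS = ("group", "pool", "replicate", "pool_size")


@dataclass
class PoolDesign:
    """Array-level description of the multi-pool design.

    ``table`` is indexed by array id with columns ``group`` (one of exactly
    two phenotype labels), ``pool`` (1..P within group), ``replicate``
    (1..R within pool) and ``pool_size`` (number of pooled individuals).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        for col in DESIGN_COLUMNS:
            if col not in t.columns:
                raise ValidationError(f"pool design lacks column {col!r}")
        if t.index.duplicated().any():
            raise ValidationError("duplicate array ids in pool design")
        t = t.copy()
        t["group"] = t["group"].astype(str)
        for col in ("pool", "replicate", "pool_size"):
            t[col] = t[col].astype(int)
        groups = sorted(t["group"].unique())
        if len(groups) != 2:
            raise ValidationError(f"expected exactly 2 groups, found {groups}")
        if (t["pool_size"] < 1).any():
            raise ValidationError("pool_size must be >= 1")
        if (t["pool"] < 1).any() or (t["replicate"] < 1).any():
            raise ValidationError("pool and replicate indices are 1-based")
        rep_counts = t.groupby(["group", "pool"])["replicate"].nunique()
        if rep_counts.nunique() != 1:
            raise ValidationError(
                "every (group, pool) must have the same replicate count; "
                f"found {sorted(rep_counts.unique())}"
            )
        if t.duplicated(subset=["group", "pool", "replicate"]).any():
            raise ValidationError("duplicate (group, pool, replicate) triple")
        sizes = t.groupby(["group", "pool"])["pool_size"].nunique()
        if (sizes != 1).any():
            raise ValidationError("pool_size differs between replicates of one pool")
        self.table = t

    @property
    def groups(self) -> tuple[str, str]:
        return tuple(sorted(self.table["group"].unique()))  # type: ignore[return-value]

    @property
    def array_ids(self) -> pd.Index:
        return self.table.index

    @property
    def n_replicates(self) -> int:
        return int(self.table.groupby(["group", "pool"])["replicate"].nunique().iloc[0])

    def pools(self) -> list[tuple[str, int]]:
        return sorted(
            set(zip(self.table["group"], self.table["pool"]))
        )

    def labels_for(self, array_ids: Sequence[str]) -> np.ndarray:
        missing = [a for a in array_ids if a not in self.table.index]
        if missing:
            raise ValidationError(f"arrays absent from pool design: {missing[:5]}")
        return self.table.loc[list(array_ids), "group"].to_numpy()

    def arrays_of_pool(self, group: str, pool: int) -> list[str]:
        t = self.table
        sel = (t["group"] == group) & (t["pool"] == pool)
        return t.index[sel].tolist()

    def to_file(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index_label="array_id", lineterminator="\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "PoolDesign":
        return read_pool_design(path)


def read_pool_design(path: str | Path) -> PoolDesign:
    t = pd.read_csv(path, sep="\t", dtype={"array_id": str, "group": str})
    if "array_id" not in t.columns:
        raise ParseError(f"pool design {path} lacks an 'array_id' column")
    return PoolDesign(t.set_index("array_id"))


def write_pool_design(design: PoolDesign, path: str | Path) -> None:
    design.to_file(path)


# ---------------------------------------------------------------------------
# Probe annotation


ANNOTATION_COLUMNS = ("probe_id", "chromosome", "position")


def validate_probe_annotation(annotations: pd.DataFrame) -> pd.DataFrame:
    """Validate and canonically sort a probe annotation table.

    Positions are 1-based; chromosome labels are opaque strings compared
    exactly.  Returns a copy sorted by (chromosome, position, probe_id).
    """
    for col in ANNOTATION_COLUMNS:
        if col not in annotations.columns:
            raise ValidationError(f"probe annotation lacks column {col!r}")
    ann = annotations.copy()
    ann["probe_id"] = ann["probe_id"].astype(str)
    ann["chromosome"] = ann["chromosome"].astype(str)
    try:
        ann["position"] = ann["position"].astype(int)
    except (TypeError, ValueError) as exc:
        raise ParseError(f"non-integer position in probe annotation: {exc}") from exc
    if (ann["position"] < 1).any():
        bad = ann.loc[ann["position"] < 1, "probe_id"].tolist()
        raise ValidationError(f"positions are 1-based; offending probes: {bad[:5]}")
    if ann["probe_id"].duplicated().any():
        dup = ann.loc[ann["probe_id"].duplicated(), "probe_id"].tolist()
        raise ValidationError(f"duplicate probe ids in annotation: {dup[:5]}")
    ann = ann.sort_values(["chromosome", "position", "probe_id"], kind="mergesort")
    return ann.reset_index(drop=True)


def read_probe_annotation(path: str | Path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return validate_probe_annotation(ann)


def write_probe_annotation(annotations: pd.DataFrame, path: str | Path) -> None:
    validate_probe_annotation(annotations).to_csv(
        path, sep="\t", index=False, lineterminator="\n"
    )


# ---------------------------------------------------------------------------
# Cluster reports


def write_cluster_report(clusters: Sequence, prefix: str | Path) -> tuple[Path, Path]:
    """Write clusters as ``<prefix>.bed`` and ``<prefix>.tsv``.

    The BED file carries one 0-based half-open span per cluster
    (start = min position - 1, end = max position).  The TSV report lists
    cluster id, size, average silhouette, representative probe and members,
    sorted by descending average silhouette.
    """
    prefix = Path(prefix)
    bed_path = prefix.with_suffix(".bed")
    tsv_path = prefix.with_suffix(".tsv")
    ordered = sorted(clusters, key=lambda c: (-c.average_silhouette, c.chromosome, c.span[0]))
    with open(bed_path, "w", encoding="utf-8", newline="\n") as fh:
        for c in ordered:
            start, end = c.span[0] - 1, c.span[1]
            fh.write(f"{c.chromosome}\t{start}\t{end}\t{c.cluster_id}\t{c.average_silhouette:.6f}\n")
    rows = [
        {
            "cluster_id": c.cluster_id,
            "chromosome": c.chromosome,
            "start": c.span[0],
            "end": c.span[1],
            "size": c.size,
            "average_silhouette": round(c.average_silhouette, 6),
            "representative_probe": c.representative,
            "member_probes": ",".join(c.members),
        }
        for c in ordered
    ]
    report = pd.DataFrame(
        rows,
        columns=[
            "cluster_id",
            "chromosome",
            "start",
            "end",
            "size",
            "average_silhouette",
            "representative_probe",
            "member_probes",
        ],
    )
    report.to_csv(tsv_path, sep="\t", index=False, lineterminator="\n")
    return bed_path, tsv_path


# ---------------------------------------------------------------------------
# Pipeline configuration


@dataclass
class PipelineConfig:
    """Tunable parameters of the selection pipeline.

    Defaults mirror the published analysis settings: probes kept when
    0.1 < mean RAS < 0.9 and AAD < 0.28, sample CV cutoff 0.1, top 1% of
    silhouette scores selected, 30 kb physical-distance clustering with
    minimum cluster size 2, and 100 score-reshuffling permutations for the
    cluster-adapted threshold.
    """

    ras_low: float = 0.1
    ras_high: float = 0.9
    aad_max: float = 0.28
    aad_method: str = "overall"  # or "pairwise"
    cv_max: float = 0.1
    top_fraction: float = 0.01
    cluster_gap_bp: int = 30_000
    min_cluster_size: int = 2
    n_permutations: int = 100
    threshold_summary: str = "quantile"  # or "mean" / "max"
    threshold_quantile: float = 0.95
    silhouette_elements: str = "arrays"  # or "pools"
    silhouette_include_self: bool = False
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.ras_low < self.ras_high <= 1.0):
            raise ValidationError("need 0 <= ras_low < ras_high <= 1")
        if not (0.0 < self.top_fraction < 1.0):
            raise ValidationError("top_fraction must lie in (0, 1)")
        if self.cluster_gap_bp <= 0:
            raise ValidationError("cluster_gap_bp must be positive")
        if self.n_permutations < 1:
            raise ValidationError("n_permutations must be >= 1")
        if self.min_cluster_size < 1:
            raise ValidationError("min_cluster_size must be >= 1")
        if self.aad_method not in ("overall", "pairwise"):
            raise ValidationError("aad_method must be 'overall' or 'pairwise'")
        if self.threshold_summary not in ("quantile", "mean", "max"):
            raise ValidationError("threshold_summary must be 'quantile', 'mean' or 'max'")
        if not (0.0 < self.threshold_quantile < 1.0):
            raise ValidationError("threshold_quantile must lie in (0, 1)")
        if self.silhouette_elements not in ("arrays", "pools"):
            raise ValidationError("silhouette_elements must be 'arrays' or 'pools'")

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def with_updates(self, **kwargs) -> "PipelineConfig":
        return replace(self, **kwargs)

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}
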