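"""Aligned LC-MS feature tables: strict I/O, filtering, pareto scaling.

The table is the output of an upstream peak-picking/alignment step
(XCMS-style), with one isotope flag per feature standing in for the
upstream isotope annotation. Filtering follows the untargeted-fungal-
metabolomics protocol: drop isotopic ions, drop features whose maximum
integrated area across samples is below 10,000 counts, and — for
mycelium-matrix tables only — drop features eluting after 25 min (the
column-wash tail of the gradient).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "FeatureTable",
    "read_feature_table",
    "write_feature_table",
    "filter_features",
    "pareto_scale",
    "split_by_matrix",
]

HOST_LEVELS = ("highbush", "wild")
MEDIUM_LEVELS = ("ML", "PDB")
MATRIX_LEVELS = ("filtrate", "mycelium")

FEATURE_COLUMNS = ("feature_id", "mz", "rt_min", "isotope_flag")
SAMPLE_COLUMNS = ("sample_id", "strain", "host", "medium", "matrix")

#: protocol defaults
AREA_MIN_DEFAULT = 10_000.0
MYCELIUM_RT_MAX_DEFAULT = 25.0


class SchemaError(ValueError):
    """Raised when a CSV does not conform to the documented schema."""


@dataclass(frozen=True)
class FeatureTable:
    """Features x samples abundance matrix plus attributes and metadata.

    ``features``: indexed by feature_id with columns mz, rt_min,
    isotope_flag. ``areas``: features x samples integrated areas.
    ``samples``: indexed by sample_id with columns strain, host, medium,
    matrix. ``log`` records applied processing steps (provenance).
    """

    features: pd.DataFrame
    areas: pd.DataFrame
    samples: pd.DataFrame
    log: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self):
        if not self.features.index.equals(self.areas.index):
            raise SchemaError("features and areas must share the same feature_id index")
        if list(self.areas.columns) != list(self.samples.index):
            raise SchemaError("area columns must match sample_id order")
        if (self.areas.to_numpy() < 0).any():
            raise SchemaError("areas must be non-negative")

    @property
    def n_features(self) -> int:
        return len(self.features)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def with_log(self, message: str) -> "FeatureTable":
        return replace(self, log=self.log + (message,))

    def subset_features(self, keep: pd.Index) -> "FeatureTable":
        return replace(self, features=self.features.loc[keep], areas=self.areas.loc[keep])

    def subset_samples(self, keep: list[str]) -> "FeatureTable":
        return replace(self, areas=self.areas[keep], samples=self.samples.loc[keep])

    def matrix(self) -> pd.DataFrame:
        """samples x features abundance matrix (modeling orientation)."""
        return self.areas.T


def _require_columns(df: pd.DataFrame, required: tuple[str, ...], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} CSV missing required column(s): {', '.join(missing)}")


def _check_levels(series: pd.Series, levels: tuple[str, ...], fieldname: str) -> None:
    bad = sorted(set(series) - set(levels))
    if bad:
        raise SchemaError(f"unknown {fieldname} level(s) {bad}; allowed: {list(levels)}")


def read_feature_table(features_csv: str | Path, metadata_csv: str | Path) -> FeatureTable:
    """Read and validate the two-CSV feature table representation.

    features CSV: feature_id, mz, rt_min, isotope_flag, then one area
    column per sample. metadata CSV: sample_id, strain, host, medium,
    matrix. Validation is strict and errors name the offending field.
    """
    fdf = pd.read_csv(features_csv, comment="#")
    mdf = pd.read_csv(metadata_csv, comment="#", dtype={"sample_id": str, "strain": str})
    _require_columns(fdf, FEATURE_COLUMNS, "features")
    _require_columns(mdf, SAMPLE_COLUMNS, "metadata")
    if fdf["feature_id"].duplicated().any():
        dup = fdf.loc[fdf["feature_id"].duplicated(), "feature_id"].iloc[0]
        raise SchemaError(f"duplicate feature_id: {dup!r}")
    if mdf["sample_id"].duplicated().any():
        dup = mdf.loc[mdf["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise SchemaError(f"duplicate sample_id: {dup!r}")
    _check_levels(mdf["host"], HOST_LEVELS, "host")
    _check_levels(mdf["medium"], MEDIUM_LEVELS, "medium")
    _check_levels(mdf["matrix"], MATRIX_LEVELS, "matrix")

    samples = mdf.set_index("sample_id")
    features = fdf.set_index("feature_id")[list(FEATURE_COLUMNS[1:])].copy()
    features["isotope_flag"] = features["isotope_flag"].astype(bool)
    if (features["mz"] <= 0).any():
        raise SchemaError("mz must be positive")
    if (features["rt_min"] < 0).any():
        raise SchemaError("rt_min must be non-negative")

    area_cols = [c for c in fdf.columns if c not in FEATURE_COLUMNS]
    missing = [s for s in samples.index if s not in area_cols]
    if missing:
        raise SchemaError(f"features CSV missing area column(s) for sample(s): {missing}")
    extra = [c for c in area_cols if c not in set(samples.index)]
    if extra:
        raise SchemaError(f"features CSV has area column(s) with no metadata row: {extra}")
    areas = fdf.set_index("feature_id")[list(samples.index)].astype(float)
    table = FeatureTable(features=features, areas=areas, samples=samples)
    return table.with_log(f"read: {table.n_features} features x {table.n_samples} samples")


def write_feature_table(
    table: FeatureTable,
    features_csv: str | Path,
    metadata_csv: str | Path,
    header_comment: str | None = None,
) -> None:
    prefix = ""
    if header_comment:
        prefix = "".join(f"# {line}\n" for line in header_comment.splitlines())
    fdf = pd.concat([table.features, table.areas], axis=1)
    fdf.insert(0, "feature_id", fdf.index)
    mdf = table.samples.copy()
    mdf.insert(0, "sample_id", mdf.index)
    for path, df in ((features_csv, fdf), (metadata_csv, mdf)):
        with open(path, "w", encoding="utf-8", newline="") as fh:
            fh.write(prefix)
            df.to_csv(fh, index=False)


def filter_features(
    table: FeatureTable,
    area_min: float = AREA_MIN_DEFAULT,
    mycelium_rt_max: float = MYCELIUM_RT_MAX_DEFAULT,
) -> FeatureTable:
    """Apply the protocol feature filters; idempotent.

    1. drop isotope-flagged features;
    2. drop features whose maximum area across samples is strictly
       below ``area_min`` (a max of exactly ``area_min`` is retained);
    3. when every sample in the table is mycelium-matrix, drop features
       with rt > ``mycelium_rt_max`` minutes. Mixed-matrix tables should
       be split with :func:`split_by_matrix` first; the RT rule is not
       applied to them.
    """
    if area_min <= 0 or mycelium_rt_max <= 0:
        raise ValueError("filter thresholds must be positive")
    keep = ~table.features["isotope_flag"]
    n_iso = int((~keep).sum())
    max_area = table.areas.max(axis=1)
    low = max_area < area_min
    n_low = int((low & keep).sum())
    keep &= ~low
    n_rt = 0
    all_mycelium = len(table.samples) > 0 and (table.samples["matrix"] == "mycelium").all()
    if all_mycelium:
        late = table.features["rt_min"] > mycelium_rt_max
        n_rt = int((late & keep).sum())
        keep &= ~late
    out = table.subset_features(table.features.index[keep])
    return out.with_log(
        f"filter: removed {n_iso} isotopic, {n_low} below area {area_min:g}, "
        f"{n_rt} after {mycelium_rt_max:g} min (mycelium rule "
        f"{'applied' if all_mycelium else 'not applicable'}); {int(keep.sum())} kept"
    )


def split_by_matrix(table: FeatureTable) -> dict[str, FeatureTable]:
    """Split a mixed-matrix table into per-matrix tables (filtrate/mycelium)."""
    out = {}
    for level in sorted(table.samples["matrix"].unique()):
        keep = list(table.samples.index[table.samples["matrix"] == level])
        out[level] = table.subset_samples(keep).with_log(f"split: matrix={level}")
    return out


def pareto_scale(X: pd.DataFrame | np.ndarray) -> tuple[pd.DataFrame | np.ndarray, np.ndarray]:
    """Pareto scaling: mean-center, divide by sqrt(standard deviation).

    Operates column-wise on a samples x features matrix; sd uses the
    n-1 denominator (SIMCA convention). Constant columns are centered
    only and flagged. Returns (scaled matrix, flags of constant columns).
    Not idempotent — record the application in provenance.
    """
    values = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, dtype=float)
    if values.ndim != 2 or values.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 samples (rows)")
    centered = values - values.mean(axis=0, keepdims=True)
    sd = values.std(axis=0, ddof=1)
    constant = sd == 0
    denom = np.sqrt(np.where(constant, 1.0, sd))
    scaled = centered / denom
    if isinstance(X, pd.DataFrame):
        scaled = pd.DataFrame(scaled, index=X.index, columns=X.columns)
    return scaled, constant
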