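"""Data model and TSV readers/writers for LC-MS feature tables and manifests.

A *metabolic feature* is a (m/z, retention time) peak from an LC-MS run.  The
central container is :class:`FeatureTable`: a (feature x injection) matrix of
peak areas together with per-feature metadata (m/z in Da/e, retention time in
seconds, ion mode) and a :class:`SampleManifest` describing each injection
(study, biological group or pooled-QC flag, injection order, ion mode).

Missing values are first-class: a peak that was not detected in an injection
is stored as NaN and written to disk as an empty cell, never as zero.  Any
zero-vs-NaN convention (for example zero-imputation before PCA) is an explicit
downstream transformation, not an I/O behaviour.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConsistencyError, FormatError

#: Biological group labels: non-diabetic / diabetic x untreated / TETA-treated,
#: plus the pooled quality-control sample injected throughout each run.
GROUPS = ("ND_UT", "ND_TETA", "DM_UT", "DM_TETA", "QC")
BIOLOGICAL_GROUPS = ("ND_UT", "ND_TETA", "DM_UT", "DM_TETA")
ION_MODES = ("positive", "negative")

MANIFEST_COLUMNS = ["sample_id", "study_id", "group", "injection_order", "ion_mode"]
FEATURE_META_COLUMNS = ["feature_id", "mz", "rt", "ion_mode"]

#: Tokens accepted as "missing" when reading intensity cells.
_NA_TOKENS = ["", "NA", "NaN", "nan"]


def _require(cond: bool, exc_type, msg: str) -> None:
    if not cond:
        raise exc_type(msg)


@dataclass
class SampleManifest:
    """Per-injection metadata, one row per sample_id.

    ``entries`` is indexed by sample_id with columns study_id, group,
    injection_order and ion_mode.  injection_order is 1-based and unique
    within each (study_id, ion_mode) analytical run.
    """

    entries: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.entries
        _require(df.index.is_unique, FormatError, "duplicate sample_id in manifest")
        bad_groups = set(df["group"]) - set(GROUPS)
        _require(not bad_groups, FormatError, f"unknown group labels: {sorted(bad_groups)}")
        bad_modes = set(df["ion_mode"]) - set(ION_MODES)
        _require(not bad_modes, FormatError, f"unknown ion modes: {sorted(bad_modes)}")
        _require(
            (df["injection_order"] >= 1).all(),
            FormatError,
            "injection_order must be a positive integer",
        )
        for (study, mode), run in df.groupby(["study_id", "ion_mode"], observed=True):
            _require(
                run["injection_order"].is_unique,
                FormatError,
                f"injection_order not unique within run (study {study}, {mode})",
            )
            _require(
                (run["group"] == "QC").any(),
                FormatError,
                f"run (study {study}, {mode}) has no QC injections",
            )

    @property
    def sample_ids(self) -> pd.Index:
        return self.entries.index

    def is_qc(self) -> pd.Series:
        return self.entries["group"] == "QC"

    def biological_ids(self) -> pd.Index:
        return self.entries.index[self.entries["group"] != "QC"]

    def group_ids(self, group: str) -> pd.Index:
        _require(group in GROUPS, ConsistencyError, f"unknown group label: {group!r}")
        return self.entries.index[self.entries["group"] == group]


@dataclass
class FeatureTable:
    """Peak areas for metabolic features across the ordered injections of runs.

    ``features``: DataFrame indexed by feature_id with columns mz, rt, ion_mode.
    ``intensities``: DataFrame (feature_id x sample_id) of non-negative peak
    areas with NaN marking missing (not detected).
    ``manifest``: the :class:`SampleManifest` describing the columns; columns
    are kept sorted by (study_id, ion_mode, injection_order).
    """

    features: pd.DataFrame
    intensities: pd.DataFrame
    manifest: SampleManifest = field(repr=False)

    def __post_init__(self) -> None:
        _require(self.features.index.is_unique, FormatError, "duplicate feature_id")
        _require((self.features["mz"] > 0).all(), FormatError, "mz must be positive")
        _require((self.features["rt"] >= 0).all(), FormatError, "rt must be non-negative")
        _require(
            self.intensities.index.equals(self.features.index),
            ConsistencyError,
            "intensity rows do not match feature metadata",
        )
        table_ids = set(self.intensities.columns)
        manifest_ids = set(self.manifest.sample_ids)
        if table_ids != manifest_ids:
            missing = sorted(manifest_ids - table_ids)[:5]
            extra = sorted(table_ids - manifest_ids)[:5]
            raise ConsistencyError(
                f"sample_id mismatch between table and manifest "
                f"(in manifest only: {missing}; in table only: {extra})"
            )
        vals = self.intensities.to_numpy(dtype=float)
        if np.nanmin(vals, initial=0.0) < 0:
            raise FormatError("negative intensity encountered")
        # canonical column order: by run, then injection order
        order = self.manifest.entries.sort_values(
            ["study_id", "ion_mode", "injection_order"]
        ).index
        self.intensities = self.intensities.loc[:, order]

    @property
    def n_features(self) -> int:
        return len(self.features)

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[1]

    def missing_mask(self) -> pd.DataFrame:
        return self.intensities.isna()

    def subset_features(self, feature_ids) -> "FeatureTable":
        return FeatureTable(
            self.features.loc[feature_ids].copy(),
            self.intensities.loc[feature_ids].copy(),
            self.manifest,
        )

    def subset_samples(self, sample_ids) -> "FeatureTable":
        keep = list(sample_ids)
        manifest = SampleManifest(self.manifest.entries.loc[keep].copy())
        return FeatureTable(self.features.copy(), self.intensities[keep].copy(), manifest)

    def group_values(self, feature_id: str, group: str) -> np.ndarray:
        """Non-missing intensities of one feature within one group."""
        vals = self.intensities.loc[feature_id, self.manifest.group_ids(group)]
        return vals.dropna().to_numpy(dtype=float)


def read_manifest(source) -> SampleManifest:
    df = pd.read_csv(source, sep="\t", dtype={"sample_id": str, "group": str, "ion_mode": str})
    missing_cols = set(MANIFEST_COLUMNS) - set(df.columns)
    _require(not missing_cols, FormatError, f"manifest missing columns: {sorted(missing_cols)}")
    df = df.set_index("sample_id")
    df["study_id"] = df["study_id"].astype(int)
    df["injection_order"] = df["injection_order"].astype(int)
    return SampleManifest(df)


def write_manifest(manifest: SampleManifest, destination) -> None:
    manifest.entries.to_csv(destination, sep="\t", index_label="sample_id")


def read_feature_table(table_source, manifest_source) -> FeatureTable:
    """Read a TSV feature table plus its manifest into a validated FeatureTable.

    The table has columns feature_id, mz, rt, ion_mode, then one intensity
    column per sample_id.  Empty cells (or NA/NaN tokens) are missing values
    and stay distinct from zero.
    """
    manifest = (
        manifest_source
        if isinstance(manifest_source, SampleManifest)
        else read_manifest(manifest_source)
    )
    df = pd.read_csv(
        table_source, sep="\t", dtype={"feature_id": str, "ion_mode": str},
        na_values=_NA_TOKENS, keep_default_na=False,
    )
    missing_cols = set(FEATURE_META_COLUMNS) - set(df.columns)
    _require(not missing_cols, FormatError, f"table missing columns: {sorted(missing_cols)}")
    _require(df["feature_id"].is_unique, FormatError, "duplicate feature_id in table")
    features = df.set_index("feature_id")[["mz", "rt", "ion_mode"]].copy()
    features["mz"] = features["mz"].astype(float)
    features["rt"] = features["rt"].astype(float)
    intensity_cols = [c for c in df.columns if c not in FEATURE_META_COLUMNS]
    intensities = df.set_index("feature_id")[intensity_cols].astype(float)
    return FeatureTable(features, intensities, manifest)


def write_feature_table(table: FeatureTable, destination) -> None:
    """Write the TSV format read by :func:`read_feature_table`.

    Missing intensities become empty cells; values are written with full
    ``repr`` precision so a write/read round trip is bit-identical.
    """
    out = pd.concat([table.features, table.intensities], axis=1)
    out.to_csv(destination, sep="\t", index_label="feature_id", na_rep="")


def table_to_string(table: FeatureTable) -> str:
    buf = _io.StringIO()
    write_feature_table(table, buf)
    return buf.getvalue()
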