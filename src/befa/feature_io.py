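"""Feature-table data model and delimited-text I/O.

A feature table holds post-peak-picking LC-HRMS features (rows) against
per-sample intensities (columns), plus a sample manifest mapping samples to
experimental groups.  Tables are dense: a missing intensity cell is an
ingest error, true zeros are kept.  Retention times are stored in seconds.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .chem_mass import ppm_window

__all__ = ["FeatureTable", "read_feature_table", "read_manifest", "write_feature_table"]

META_COLUMNS = ("mz", "rt", "ion_mode")
ION_MODES = ("neg", "pos")


class FeatureTableError(ValueError):
    """Raised for structurally invalid feature tables or manifests."""


@dataclass
class FeatureTable:
    """Features x samples with group manifest.

    Attributes
    ----------
    features : pd.DataFrame
        Indexed by unique ``feature_id``; columns ``mz`` (Th), ``rt``
        (seconds), ``ion_mode`` ("neg"/"pos").
    intensities : pd.DataFrame
        Same index; one non-negative column per sample.
    manifest : pd.DataFrame
        Indexed by ``sample_id``; columns ``group`` and optional
        ``experiment``.
    normalization : str
        "raw" or "normalized"; never ambiguous.
    excluded : frozenset[str]
        Feature ids flagged excluded-from-testing (e.g. the normalization
        reference and its isotopes/adducts).
    provenance : tuple[str, ...]
        Human-readable notes of applied operations.
    """

    features: pd.DataFrame
    intensities: pd.DataFrame
    manifest: pd.DataFrame
    normalization: str = "raw"
    excluded: frozenset = frozenset()
    provenance: Tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.features.index.name = "feature_id"
        self.intensities.index.name = "feature_id"
        self.manifest.index.name = "sample_id"
        self.validate()

    def validate(self) -> None:
        f, x, m = self.features, self.intensities, self.manifest
        for col in META_COLUMNS:
            if col not in f.columns:
                raise FeatureTableError(f"missing feature column {col!r}")
        if f.index.has_duplicates:
            dups = f.index[f.index.duplicated()].tolist()
            raise FeatureTableError(f"duplicate feature ids: {dups[:5]}")
        if not f.index.equals(x.index):
            raise FeatureTableError("feature metadata and intensity indices differ")
        if self.normalization not in ("raw", "normalized"):
            raise FeatureTableError(f"ambiguous normalization state {self.normalization!r}")
        bad_mode = set(f["ion_mode"]) - set(ION_MODES)
        if bad_mode:
            raise FeatureTableError(f"unknown ion mode(s): {sorted(bad_mode)}")
        if len(f) and (f["mz"] <= 0).any():
            rows = f.index[f["mz"] <= 0].tolist()
            raise FeatureTableError(f"non-positive m/z for features {rows[:5]}")
        if len(f) and (f["rt"] < 0).any():
            rows = f.index[f["rt"] < 0].tolist()
            raise FeatureTableError(f"negative rt for features {rows[:5]}")
        if x.isna().any().any():
            raise FeatureTableError("missing intensity cells (tables must be dense)")
        if len(x) and (x.to_numpy() < 0).any():
            raise FeatureTableError("negative intensities")
        if "group" not in m.columns:
            raise FeatureTableError("manifest lacks a 'group' column")
        if m["group"].astype(str).str.len().eq(0).any():
            raise FeatureTableError("empty group label in manifest")
        missing = [s for s in x.columns if s not in m.index]
        if missing:
            raise FeatureTableError(f"sample column(s) absent from manifest: {missing}")

    # -- convenience -------------------------------------------------------

    @property
    def n_features(self) -> int:
        return len(self.features)

    @property
    def sample_ids(self) -> List[str]:
        return list(self.intensities.columns)

    def samples_in_group(self, group: str) -> List[str]:
        ids = [s for s in self.sample_ids if self.manifest.loc[s, "group"] == group]
        return ids

    def group_means(self, group: str) -> pd.Series:
        samples = self.samples_in_group(group)
        if not samples:
            raise FeatureTableError(f"no samples in group {group!r}")
        return self.intensities[samples].mean(axis=1)

    def ion_modes(self) -> List[str]:
        return sorted(set(self.features["ion_mode"]))

    def subset(self, feature_ids: Iterable[str], note: str = "") -> "FeatureTable":
        ids = pd.Index(feature_ids)
        prov = self.provenance + ((note,) if note else ())
        return replace(
            self,
            features=self.features.loc[ids],
            intensities=self.intensities.loc[ids],
            excluded=frozenset(i for i in self.excluded if i in set(ids)),
            provenance=prov,
        )

    def query_mz(
        self,
        mz: float,
        tol_ppm: float,
        rt_range: Optional[Tuple[float, float]] = None,
    ) -> pd.DataFrame:
        """Features whose m/z falls in the ppm window (and rt in range).

        Returns feature metadata sorted by absolute ppm error; an EIC-like
        lookup on the feature table.
        """
        lo, hi = ppm_window(mz, tol_ppm)
        f = self.features
        mask = (f["mz"] >= lo) & (f["mz"] <= hi)
        if rt_range is not None:
            mask &= (f["rt"] >= rt_range[0]) & (f["rt"] <= rt_range[1])
        hits = f[mask].copy()
        hits["ppm_error"] = (hits["mz"] - mz) / mz * 1e6
        return hits.reindex(hits["ppm_error"].abs().sort_values(kind="stable").index)


def _sniff_sep(path: Path) -> str:
    sample = Path(path).read_text().splitlines()[0]
    try:
        return csv.Sniffer().sniff(sample, delimiters=",\t;").delimiter
    except csv.Error:
        return ","


def read_manifest(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"manifest file not found: {path}")
    df = pd.read_csv(path, sep=_sniff_sep(path))
    if "sample_id" not in df.columns or "group" not in df.columns:
        raise FeatureTableError(
            f"manifest {path} must have 'sample_id' and 'group' columns"
        )
    df["sample_id"] = df["sample_id"].astype(str)
    if df["sample_id"].duplicated().any():
        raise FeatureTableError("duplicate sample ids in manifest")
    return df.set_index("sample_id")


def read_feature_table(path, manifest_path, rt_in_minutes: bool = False) -> FeatureTable:
    """Load a delimited feature table plus sample manifest.

    Expected feature-table columns: ``feature_id, mz, rt, ion_mode`` then one
    column per sample.  Delimiter (comma/tab/semicolon) is sniffed.  Rows are
    validated with feature-id-level diagnostics; ``rt_in_minutes`` converts
    retention times to seconds on ingest.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"feature table file not found: {path}")
    manifest = read_manifest(manifest_path)
    df = pd.read_csv(path, sep=_sniff_sep(path))
    required = ("feature_id",) + META_COLUMNS
    for col in required:
        if col not in df.columns:
            raise FeatureTableError(f"{path}: missing column {col!r}")
    df["feature_id"] = df["feature_id"].astype(str)
    df = df.set_index("feature_id")
    sample_cols = [c for c in df.columns if c not in META_COLUMNS]
    if not sample_cols:
        raise FeatureTableError(f"{path}: no sample intensity columns")
    unknown = [c for c in sample_cols if c not in manifest.index]
    if unknown:
        raise FeatureTableError(
            f"{path}: sample column(s) not in manifest: {unknown}"
        )
    features = df[list(META_COLUMNS)].copy()
    if rt_in_minutes:
        features["rt"] = features["rt"] * 60.0
    intensities = df[sample_cols].astype(float)
    return FeatureTable(
        features=features,
        intensities=intensities,
        manifest=manifest,
        provenance=(f"read from {path.name}",),
    )


def write_feature_table(table: FeatureTable, path, manifest_path=None, sep: str = ",") -> None:
    """Write a table (and optionally its manifest) as delimited text.

    Numeric fields round-trip losslessly through `repr`-precision floats.
    """
    out = pd.concat([table.features, table.intensities], axis=1)
    out.index.name = "feature_id"
    out.to_csv(path, sep=sep)
    if manifest_path is not None:
        m = table.manifest.copy()
        m.index.name = "sample_id"
        m.to_csv(manifest_path, sep=sep)
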