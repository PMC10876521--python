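"""Comparative-metabolomics statistics for two-group feature tables.

The stages run in a fixed order mirroring standard untargeted workflows:

1. retention-time culling (default window 180-1080 s),
2. blank subtraction (keep features >= 5-fold over solvent blank),
3. mean-intensity filtering (default 10,000 AU over the pooled animal group),
4. normalization to an internal reference feature (ascr#3-style anchor),
5. per-feature Welch's unpaired two-sided t-test,
6. Benjamini-Hochberg step-up FDR (default q* = 0.15).

All thresholds are closed (>=) at their boundary.  The filter cascade is
monotone: each stage only removes features.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .feature_io import FeatureTable, FeatureTableError

__all__ = [
    "PipelineConfig",
    "DifferentialResult",
    "cull_by_rt",
    "blank_subtract",
    "intensity_filter",
    "normalize_to_reference",
    "welch_volcano",
    "bh_adjust",
    "run_differential",
]

#: exact mass of a 13C-for-12C substitution, Da — the default reference
#: isotope offset excluded around the normalization anchor.
C13_DELTA = 1.0033548378


@dataclass(frozen=True)
class PipelineConfig:
    """All thresholds of the differential workflow.

    Parameters
    ----------
    rt_window : closed retention-time window in seconds.
    blank_fold_threshold : minimum animal/blank mean-intensity ratio (> 1).
    min_group_mean_intensity : AU floor on the pooled animal-group mean.
    fdr_q : Benjamini-Hochberg target FDR in (0, 1).
    reference_feature_id : internal normalization anchor (None = skip
        normalization).
    reference_exclusion_deltas : m/z offsets (Da) of reference degenerates
        (isotopes/adducts) to flag excluded-from-testing, matched within
        ``ppm_tol`` and ``reference_rt_tol`` of the reference.
    log2fc_pseudo_intensity : AU floor added to group means before ratios.
    blank_pseudo_intensity : AU stand-in for a zero blank mean so features
        detected only in animals are kept.
    blank_group : manifest group holding solvent blanks.
    """

    rt_window: Tuple[float, float] = (180.0, 1080.0)
    blank_fold_threshold: float = 5.0
    min_group_mean_intensity: float = 10_000.0
    fdr_q: float = 0.15
    reference_feature_id: Optional[str] = None
    reference_exclusion_deltas: Tuple[float, ...] = (C13_DELTA,)
    reference_rt_tol: float = 5.0
    ppm_tol: float = 3.0
    log2fc_pseudo_intensity: float = 1.0
    blank_pseudo_intensity: float = 1.0
    blank_group: str = "blank"

    def __post_init__(self) -> None:
        if self.blank_fold_threshold <= 1:
            raise ValueError("blank_fold_threshold must exceed 1")
        if not 0 < self.fdr_q < 1:
            raise ValueError("fdr_q must lie in (0, 1)")
        if self.rt_window[0] >= self.rt_window[1]:
            raise ValueError("rt_window must be non-degenerate")
        if self.log2fc_pseudo_intensity <= 0 or self.blank_pseudo_intensity <= 0:
            raise ValueError("pseudo intensities must be positive")


@dataclass
class DifferentialResult:
    """Volcano-ready per-feature statistics plus per-stage survivor counts."""

    table: pd.DataFrame  # feature_id index; mz, rt, means, log2fc, t, p, q, significant
    stage_counts: Dict[str, int]
    group_a: str
    group_b: str
    config: PipelineConfig

    def significant(self) -> pd.DataFrame:
        return self.table[self.table["significant"]]


def _check_single_mode(table: FeatureTable) -> None:
    modes = table.ion_modes()
    if len(modes) > 1:
        raise FeatureTableError(
            f"cross-mode operation rejected; table mixes ion modes {modes}"
        )


def cull_by_rt(table: FeatureTable, config: PipelineConfig) -> FeatureTable:
    """Keep features whose retention time lies in the closed window."""
    lo, hi = config.rt_window
    keep = table.features.index[(table.features["rt"] >= lo) & (table.features["rt"] <= hi)]
    return table.subset(keep, note=f"rt cull [{lo},{hi}] s: {len(keep)} kept")


def blank_subtract(table: FeatureTable, config: PipelineConfig) -> FeatureTable:
    """Remove features < ``blank_fold_threshold``-fold over the solvent blank.

    Animal samples are pooled across genotypes (blank subtraction precedes
    genotype regrouping).  A zero blank mean is replaced by
    ``blank_pseudo_intensity`` so features detected only in animals survive.
    """
    groups = table.manifest["group"]
    if config.blank_group not in set(groups):
        raise FeatureTableError(f"manifest has no {config.blank_group!r} group")
    blank_samples = table.samples_in_group(config.blank_group)
    worm_samples = [s for s in table.sample_ids if s not in blank_samples]
    if not worm_samples:
        raise FeatureTableError("no non-blank samples to compare against blank")
    worm_mean = table.intensities[worm_samples].mean(axis=1)
    blank_mean = table.intensities[blank_samples].mean(axis=1)
    denom = blank_mean.where(blank_mean > 0, config.blank_pseudo_intensity)
    keep = table.features.index[worm_mean >= config.blank_fold_threshold * denom]
    return table.subset(
        keep, note=f"blank subtraction (fold {config.blank_fold_threshold}): {len(keep)} kept"
    )


def intensity_filter(table: FeatureTable, config: PipelineConfig, group: Optional[str] = None) -> FeatureTable:
    """Keep features with mean intensity >= threshold over the named group.

    ``group=None`` pools all non-blank samples (the animal group).
    """
    if group is None:
        samples = [s for s in table.sample_ids
                   if table.manifest.loc[s, "group"] != config.blank_group]
        label = "pooled non-blank"
    else:
        samples = table.samples_in_group(group)
        label = group
        if not samples:
            raise FeatureTableError(f"unknown or empty group {group!r}")
    if not samples:
        raise FeatureTableError("no samples for intensity filter")
    means = table.intensities[samples].mean(axis=1)
    keep = table.features.index[means >= config.min_group_mean_intensity]
    return table.subset(
        keep,
        note=f"intensity filter >= {config.min_group_mean_intensity} AU ({label}): {len(keep)} kept",
    )


def normalize_to_reference(table: FeatureTable, config: PipelineConfig) -> FeatureTable:
    """Scale each sample by its internal-reference response.

    Sample ``s`` is divided by ``ref_s / geomean(ref)``: anchoring to the
    geometric mean preserves the overall intensity scale, so AU thresholds
    stay meaningful.  The reference feature and any feature within
    ``ppm_tol`` of (reference m/z + delta) for each configured degenerate
    delta (13C isotope, adducts) and within ``reference_rt_tol`` seconds of
    the reference RT are flagged excluded-from-testing.
    """
    ref_id = config.reference_feature_id
    if ref_id is None:
        raise FeatureTableError("no reference_feature_id configured")
    if ref_id not in table.features.index:
        raise FeatureTableError(f"reference feature {ref_id!r} absent from table")
    ref = table.intensities.loc[ref_id]
    if (ref <= 0).any():
        bad = ref.index[ref <= 0].tolist()
        raise FeatureTableError(f"reference intensity non-positive in sample(s) {bad}")
    factors = ref / stats.gmean(ref.to_numpy())
    norm = table.intensities.div(factors, axis=1)

    ref_mz = float(table.features.loc[ref_id, "mz"])
    ref_rt = float(table.features.loc[ref_id, "rt"])
    excluded = {ref_id}
    for delta in config.reference_exclusion_deltas:
        target = ref_mz + delta
        tol = target * config.ppm_tol * 1e-6
        f = table.features
        hit = f.index[
            (f["mz"] - target).abs().le(tol)
            & (f["rt"] - ref_rt).abs().le(config.reference_rt_tol)
        ]
        excluded.update(hit)
    return replace(
        table,
        intensities=norm,
        normalization="normalized",
        excluded=table.excluded | frozenset(excluded),
        provenance=table.provenance
        + (f"normalized to {ref_id}; {len(excluded)} reference degenerates excluded",),
    )


def _welch_arrays(a: np.ndarray, b: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Vectorized Welch t and two-sided p for rows of a (group A) vs b (group B).

    Zero-variance edge cases: equal means -> t = 0, p = 1; unequal means with
    zero pooled variance -> t = +/-inf, p = 0.
    """
    na, nb = a.shape[1], b.shape[1]
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    va, vb = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    se2 = va / na + vb / nb
    diff = mb - ma
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(se2)
        df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
        p = 2.0 * stats.t.sf(np.abs(t), df)
    zero_se = se2 == 0
    t = np.where(zero_se & (diff == 0), 0.0, t)
    p = np.where(zero_se & (diff == 0), 1.0, p)
    t = np.where(zero_se & (diff != 0), np.where(diff > 0, np.inf, -np.inf), t)
    p = np.where(zero_se & (diff != 0), 0.0, p)
    return t, p


def welch_volcano(
    table: FeatureTable,
    group_a: str,
    group_b: str,
    config: PipelineConfig,
) -> pd.DataFrame:
    """Per-feature log2 fold change (B vs A) and Welch two-sided p.

    Features flagged excluded-from-testing are omitted.  Each group needs at
    least two samples.
    """
    _check_single_mode(table)
    sa = table.samples_in_group(group_a)
    sb = table.samples_in_group(group_b)
    if len(sa) < 2 or len(sb) < 2:
        raise FeatureTableError("each group needs >= 2 samples for Welch's t-test")
    tested = table.features.index.difference(pd.Index(table.excluded), sort=False)
    a = table.intensities.loc[tested, sa].to_numpy(float)
    b = table.intensities.loc[tested, sb].to_numpy(float)
    pseudo = config.log2fc_pseudo_intensity
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    log2fc = np.log2((mb + pseudo) / (ma + pseudo))
    t, p = _welch_arrays(a, b)
    out = table.features.loc[tested, ["mz", "rt"]].copy()
    out[f"mean_{group_a}"] = ma
    out[f"mean_{group_b}"] = mb
    out["log2fc"] = log2fc
    out["t"] = t
    out["p"] = p
    return out


def bh_adjust(pvalues: Sequence[float], fdr_q: float) -> Tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up q-values and significance flags.

    q_i = min_{j >= i} (m * p_(j) / j) clipped at 1; significant iff
    q <= ``fdr_q``.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size and ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    _, q, _, _ = multipletests(p, alpha=fdr_q, method="fdr_bh")
    return q, q <= fdr_q


def run_differential(
    table: FeatureTable,
    config: PipelineConfig,
    group_a: str,
    group_b: str,
) -> DifferentialResult:
    """Full cascade: RT cull -> blank subtract -> intensity filter ->
    normalize -> Welch -> BH.

    Normalization is skipped (with a provenance note) when no reference
    feature is configured.
    """
    _check_single_mode(table)
    counts: Dict[str, int] = {"input": table.n_features}
    t1 = cull_by_rt(table, config)
    counts["rt_cull"] = t1.n_features
    t2 = blank_subtract(t1, config)
    counts["blank_subtraction"] = t2.n_features
    t3 = intensity_filter(t2, config)
    counts["intensity_filter"] = t3.n_features
    if config.reference_feature_id is not None:
        t4 = normalize_to_reference(t3, config)
    else:
        t4 = replace(t3, provenance=t3.provenance + ("normalization skipped (no reference)",))
    counts["normalized"] = t4.n_features
    stats_df = welch_volcano(t4, group_a, group_b, config)
    counts["tested"] = len(stats_df)
    q, sig = bh_adjust(stats_df["p"].to_numpy(), config.fdr_q)
    stats_df["q"] = q
    stats_df["significant"] = sig
    counts["significant"] = int(sig.sum())
    return DifferentialResult(
        table=stats_df, stage_counts=counts, group_a=group_a, group_b=group_b, config=config
    )
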