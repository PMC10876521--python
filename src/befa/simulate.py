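"""Seeded generators of feature tables with known ground truth.

The differential generator emulates a two-genotype LC-HRMS experiment after
peak picking: per-feature log-normal intensities (multiplicative noise on
the log scale, the standard model for LC-MS responses), a blank-contaminated
stratum whose animal/blank ratio straddles the 5-fold rule, a low-variance
internal-reference feature, and differential features scaled by a known fold
change in one group.  The tracer generator plants deuterium-labeled
isotopologue partners at exact n x (m(2H)-m(1H)) offsets with Gaussian ppm
and retention-time jitter, intense only in the labeled condition.

Generators are pure functions of their arguments, seed included.  What they
do NOT emulate: correlated features (adducts/isotopes of one analyte),
retention-time drift, heteroscedastic noise floors, or missing cells.
"""

from __future__ import annotations

from typing import Dict, Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .chem_mass import deuterium_shift
from .feature_io import FeatureTable

__all__ = ["generate_differential_table", "generate_tracer_table"]

#: instrument scan range, Th
MZ_RANGE = (117.0, 1000.0)


def _manifest(groups: Dict[str, int]) -> pd.DataFrame:
    rows = []
    for g, k in groups.items():
        for r in range(1, k + 1):
            rows.append((f"{g}_{r}", g, r))
    m = pd.DataFrame(rows, columns=["sample_id", "group", "experiment"])
    return m.set_index("sample_id")


def generate_differential_table(
    n_features: int = 200,
    n_differential: int = 10,
    fold_change: float = 8.0,
    n_per_group: int = 6,
    noise_sigma: float = 0.2,
    seed: int = 0,
    group_names: Tuple[str, str] = ("WT", "mut"),
    n_blank: int = 2,
    blank_fraction: float = 0.1,
    base_log10_mean_range: Tuple[float, float] = (4.3, 5.8),
    rt_window: Tuple[float, float] = (180.0, 1080.0),
    include_reference: bool = True,
    reference_id: str = "ref_ascr3",
    ion_mode: str = "neg",
) -> Tuple[FeatureTable, pd.DataFrame]:
    """Two-group table with planted differential and blank-only features.

    Returns ``(table, truth)`` where ``truth`` is indexed by feature_id with
    columns ``class`` (null | differential | blank | reference),
    ``true_log2fc``, ``n_d`` (NaN here), and the generating ``seed``.

    Differential features have their group-B mean multiplied by
    ``fold_change`` (use 1.0 for a pure null table, in which case zero
    features are marked differential).  Blank-stratum features get a blank
    mean comparable to the animal mean (ratio drawn in [0.5, 3), below the
    5-fold keep rule).  Intensities are ``mean * exp(noise_sigma * Z)``.
    """
    if n_differential > n_features:
        raise ValueError("n_differential cannot exceed n_features")
    if fold_change <= 0:
        raise ValueError("fold_change must be positive")
    if n_per_group < 2:
        raise ValueError("need >= 2 samples per group")
    rng = np.random.default_rng(seed)
    ga, gb = group_names
    manifest = _manifest({ga: n_per_group, gb: n_per_group, "blank": n_blank})
    n_extra = 1 if include_reference else 0
    total = n_features + n_extra

    if fold_change == 1.0:
        n_differential = 0
    classes = np.array(["null"] * n_features, dtype=object)
    classes[:n_differential] = "differential"
    n_contam = int(round(blank_fraction * (n_features - n_differential)))
    classes[n_differential : n_differential + n_contam] = "blank"
    rng.shuffle(classes)

    base_mean = 10.0 ** rng.uniform(*base_log10_mean_range, size=n_features)
    mean_a = base_mean.copy()
    mean_b = np.where(classes == "differential", base_mean * fold_change, base_mean)
    blank_ratio = rng.uniform(0.5, 3.0, size=n_features)
    mean_blank = np.where(
        classes == "blank",
        base_mean * blank_ratio,
        base_mean * 1e-3,  # trace carryover, far below the 5-fold rule
    )

    def noisy(mean: np.ndarray, cols: int, sigma: float) -> np.ndarray:
        return mean[:, None] * np.exp(sigma * rng.standard_normal((mean.size, cols)))

    xa = noisy(mean_a, n_per_group, noise_sigma)
    xb = noisy(mean_b, n_per_group, noise_sigma)
    xblank = noisy(mean_blank, n_blank, noise_sigma)

    ids = [f"F{i:05d}" for i in range(n_features)]
    mz = rng.uniform(*MZ_RANGE, size=n_features)
    rt = rng.uniform(*rt_window, size=n_features)

    if include_reference:
        ids.append(reference_id)
        classes = np.append(classes, "reference")
        mz = np.append(mz, 301.2384)  # internal-reference anchor m/z
        rt = np.append(rt, float(np.mean(rt_window)))
        ref_mean = 1.0e6
        xa = np.vstack([xa, noisy(np.array([ref_mean]), n_per_group, 0.02)])
        xb = np.vstack([xb, noisy(np.array([ref_mean]), n_per_group, 0.02)])
        xblank = np.vstack([xblank, np.full((1, n_blank), 10.0)])
        mean_a = np.append(mean_a, ref_mean)
        mean_b = np.append(mean_b, ref_mean)

    features = pd.DataFrame(
        {"mz": mz, "rt": rt, "ion_mode": ion_mode}, index=pd.Index(ids, name="feature_id")
    )
    intensities = pd.DataFrame(
        np.hstack([xa, xb, xblank]), index=features.index, columns=manifest.index
    )
    table = FeatureTable(
        features=features,
        intensities=intensities,
        manifest=manifest,
        provenance=(f"synthetic differential table (seed={seed})",),
    )
    truth = pd.DataFrame(
        {
            "class": classes,
            "true_log2fc": np.where(
                classes == "differential", np.log2(fold_change), 0.0
            ),
            "n_d": np.nan,
            "seed": seed,
        },
        index=features.index,
    )
    return table, truth


def generate_tracer_table(
    base_table: FeatureTable,
    labeled_fraction: float = 0.2,
    n_d_values: Sequence[int] = (3,),
    ppm_jitter: float = 0.0,
    rt_shift: float = -2.0,
    seed: int = 0,
    labeled_group: str = "labeled",
    control_group: str = "control",
    partner_intensity_fraction: float = 0.4,
    base_truth: Optional[pd.DataFrame] = None,
) -> Tuple[FeatureTable, pd.DataFrame]:
    """Plant deuterium-labeled partners for a fraction of base features.

    For each selected feature, a partner is added at
    ``mz + deuterium_shift(n)`` (n cycled from ``n_d_values``) with Gaussian
    m/z jitter of sd ``ppm_jitter`` ppm and the stated retention-time shift,
    intense only in ``labeled_group`` samples.  Returns the augmented table
    and a truth frame with one row per planted partner
    (``parent_id, partner_id, n_d``).

    Jitter exceeding a downstream matching tolerance is allowed; recall is
    then expected to degrade.
    """
    if not 0 <= labeled_fraction <= 1:
        raise ValueError("labeled_fraction must lie in [0, 1]")
    if ppm_jitter < 0:
        raise ValueError("ppm_jitter must be non-negative")
    if not n_d_values:
        raise ValueError("n_d_values must be non-empty")
    rng = np.random.default_rng(seed)
    groups = base_table.manifest["group"]
    for g in (labeled_group, control_group):
        if g not in set(groups):
            raise ValueError(f"base table manifest lacks group {g!r}")
    labeled_samples = base_table.samples_in_group(labeled_group)
    eligible = [
        fid
        for fid in base_table.features.index
        if fid not in base_table.excluded
        and (base_truth is None or base_truth.loc[fid, "class"] in ("null", "differential"))
    ]
    k = int(round(labeled_fraction * len(eligible)))
    chosen = list(rng.choice(eligible, size=k, replace=False)) if k else []

    new_features = []
    new_rows = []
    truth_rows = []
    for idx, parent in enumerate(chosen):
        n_d = int(n_d_values[idx % len(n_d_values)])
        pmz = float(base_table.features.loc[parent, "mz"])
        prt = float(base_table.features.loc[parent, "rt"])
        mz = (pmz + deuterium_shift(n_d)) * (1.0 + rng.standard_normal() * ppm_jitter * 1e-6)
        rt = max(0.0, prt + rt_shift)
        partner_id = f"{parent}_D{n_d}"
        level = partner_intensity_fraction * base_table.intensities.loc[parent].mean()
        row = pd.Series(10.0, index=base_table.sample_ids)  # noise floor elsewhere
        row[labeled_samples] = level * np.exp(
            0.2 * rng.standard_normal(len(labeled_samples))
        )
        new_features.append(
            {"feature_id": partner_id, "mz": mz, "rt": rt,
             "ion_mode": base_table.features.loc[parent, "ion_mode"]}
        )
        new_rows.append(row.rename(partner_id))
        truth_rows.append({"parent_id": parent, "partner_id": partner_id, "n_d": n_d})

    if new_features:
        add_f = pd.DataFrame(new_features).set_index("feature_id")
        features = pd.concat([base_table.features, add_f])
        intensities = pd.concat([base_table.intensities, pd.DataFrame(new_rows)])
    else:
        features, intensities = base_table.features, base_table.intensities
    table = FeatureTable(
        features=features,
        intensities=intensities,
        manifest=base_table.manifest,
        normalization=base_table.normalization,
        excluded=base_table.excluded,
        provenance=base_table.provenance + (f"planted {len(chosen)} labeled partners (seed={seed})",),
    )
    truth = pd.DataFrame(truth_rows, columns=["parent_id", "partner_id", "n_d"])
    return table, truth
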