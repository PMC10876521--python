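"""Reporter quantification: GFP intensity normalization and delta-delta-Ct.

Two small, exact procedures used downstream of imaging and RT-qPCR:

* GFP: per independent experiment, background is the mean of the *minimum*
  intensities of all outlined animals; it is subtracted from each animal's
  mean intensity (floored at zero) and the result is normalized to the
  average of the untreated-control animals of the same experiment.
* ddCt: technical replicates are averaged first; dCt = Ct(target) -
  Ct(reference); ddCt subtracts the mean dCt of the control samples;
  relative expression is 2^(-ddCt).  No amplification-efficiency correction.
"""

from __future__ import annotations

import warnings
from typing import Optional

import numpy as np
import pandas as pd

__all__ = ["normalize_gfp", "ddct_expression"]


def normalize_gfp(measurements: pd.DataFrame, control_label: str) -> pd.DataFrame:
    """Background-correct and control-normalize per-animal GFP intensities.

    ``measurements`` needs columns ``animal_id, mean_intensity,
    min_intensity, treatment, experiment``.  Returns the frame with added
    ``background``, ``corrected`` and ``normalized`` columns.  Within each
    experiment the mean of the control animals' normalized values is exactly
    1.  Raises when an experiment has no control animals or their corrected
    mean is zero.
    """
    required = {"animal_id", "mean_intensity", "min_intensity", "treatment", "experiment"}
    missing = required - set(measurements.columns)
    if missing:
        raise ValueError(f"measurements missing column(s): {sorted(missing)}")
    if (measurements["min_intensity"] > measurements["mean_intensity"]).any():
        raise ValueError("min intensity exceeds mean intensity for some animal")
    if (measurements[["min_intensity", "mean_intensity"]] < 0).any().any():
        raise ValueError("negative intensities")

    out = []
    for exp, grp in measurements.groupby("experiment", sort=False):
        grp = grp.copy()
        background = grp["min_intensity"].mean()
        corrected = grp["mean_intensity"] - background
        if (corrected < 0).any():
            warnings.warn(
                f"experiment {exp!r}: {(corrected < 0).sum()} animal(s) dimmer than "
                "background; corrected intensity floored at 0",
                stacklevel=2,
            )
        corrected = corrected.clip(lower=0.0)
        controls = corrected[grp["treatment"] == control_label]
        if controls.empty:
            raise ValueError(f"experiment {exp!r} has no {control_label!r} animals")
        denom = controls.mean()
        if denom == 0:
            raise ValueError(f"experiment {exp!r}: control corrected mean is zero")
        grp["background"] = background
        grp["corrected"] = corrected
        grp["normalized"] = corrected / denom
        out.append(grp)
    return pd.concat(out, ignore_index=True)


def ddct_expression(
    records: pd.DataFrame,
    reference_gene: str,
    control_label: str,
) -> pd.DataFrame:
    """Relative expression by the delta-delta-Ct method.

    ``records`` needs columns ``sample_id, gene, treatment, ct``; technical
    replicates are separate rows and are averaged per (sample, gene) before
    any differences are taken.  Fold changes are normalized against the mean
    dCt of all control samples, per target gene.  Returns one row per
    (sample, target gene) with ``dct``, ``ddct`` and ``fold``.
    """
    required = {"sample_id", "gene", "treatment", "ct"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"records missing column(s): {sorted(missing)}")
    if not np.isfinite(records["ct"]).all():
        raise ValueError("non-finite Ct value")

    mean_ct = (
        records.groupby(["sample_id", "gene"], sort=False)
        .agg(ct=("ct", "mean"), treatment=("treatment", "first"))
        .reset_index()
    )
    ref = mean_ct[mean_ct["gene"] == reference_gene].set_index("sample_id")["ct"]
    targets = mean_ct[mean_ct["gene"] != reference_gene].copy()
    if targets.empty:
        raise ValueError("no target-gene measurements")
    missing_ref = sorted(set(targets["sample_id"]) - set(ref.index))
    if missing_ref:
        raise ValueError(
            f"sample(s) lack reference gene {reference_gene!r}: {missing_ref}"
        )
    targets["dct"] = targets["ct"] - targets["sample_id"].map(ref).to_numpy()

    out = []
    for gene, grp in targets.groupby("gene", sort=False):
        grp = grp.copy()
        control_dct = grp.loc[grp["treatment"] == control_label, "dct"]
        if control_dct.empty:
            raise ValueError(f"gene {gene!r}: no {control_label!r} control samples")
        grp["ddct"] = grp["dct"] - control_dct.mean()
        grp["fold"] = 2.0 ** (-grp["ddct"])
        out.append(grp)
    return pd.concat(out, ignore_index=True)[
        ["sample_id", "gene", "treatment", "ct", "dct", "ddct", "fold"]
    ]
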