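"""Canned transformation routes from vaccenic acid to the C11 endpoints.

The two parallel pathways share the skeleton-building step (+CH2 on the cis
double bond) and four beta-oxidation rounds:

* methylation route: methyl transfer -> 4x beta-oxidation -> bemeth#1, the
  beta-methyl decenoic acid; further alpha-hydroxylation gives bemeth#2 and
  additional distal (omega/omega-1) hydroxylation gives bemeth#3;
* cyclopropanation route: ring closure (lactobacillic-acid topology) ->
  4x beta-oxidation -> becyp#1, the beta-cyclopropyl isomer.

Which distal carbon bemeth#3 is hydroxylated at is not structurally fixed
here; the deuterium count is the same for any deuterated distal carbon, so
the position is a parameter (default omega-1).
"""

from __future__ import annotations

from typing import List, Optional, Union

from .biosynth import (
    LabeledChain,
    apply_beta_oxidation_round,
    apply_cyclopropanation,
    apply_hydroxylation,
    apply_methyl_transfer,
    make_vaccenic,
    predict_metabolite,
)
from .chem_mass import Adduct, M_MINUS_H

__all__ = ["run_route", "standard_predictions"]


def run_route(
    label: Optional[str] = None,
    route: str = "methylation",
    beta_rounds: int = 4,
    alpha_hydroxyl: bool = False,
    distal_hydroxyl: Optional[Union[int, str]] = None,
) -> LabeledChain:
    """Compose a transformation route starting from (optionally d13) vaccenate."""
    chain = make_vaccenic(label)
    if route == "methylation":
        chain = apply_methyl_transfer(chain)
    elif route == "cyclopropanation":
        chain = apply_cyclopropanation(chain)
    else:
        raise ValueError(f"unknown route {route!r}")
    for _ in range(beta_rounds):
        chain = apply_beta_oxidation_round(chain)
    if alpha_hydroxyl:
        chain = apply_hydroxylation(chain, 2)
    if distal_hydroxyl is not None:
        chain = apply_hydroxylation(chain, distal_hydroxyl)
    return chain


def standard_predictions(label: Optional[str] = None, adduct: Adduct = M_MINUS_H):
    """The named C11 endpoints of both routes for a given precursor label.

    Both +CH2 enzymes are cis-specific, so a d13_trans precursor yields no
    predictions — the negative control of the labeling design.
    """
    from .biosynth import NotASubstrateError

    preds = []
    labels = {"none": None}.get(label, label)
    try:
        bemeth1 = run_route(labels, "methylation", 4)
        preds.append(predict_metabolite(bemeth1, adduct, name=_tag("bemeth#1", bemeth1)))
        bemeth2 = apply_hydroxylation(bemeth1, 2)
        preds.append(predict_metabolite(bemeth2, adduct, name=_tag("bemeth#2", bemeth2)))
        bemeth3 = apply_hydroxylation(bemeth2, "omega-1")
        preds.append(predict_metabolite(bemeth3, adduct, name=_tag("bemeth#3", bemeth3)))
    except NotASubstrateError:
        pass  # trans-labeled precursor: not a methyltransferase substrate
    try:
        becyp1 = run_route(labels, "cyclopropanation", 4)
        preds.append(predict_metabolite(becyp1, adduct, name=_tag("becyp#1", becyp1)))
    except NotASubstrateError:
        pass  # cyclopropane synthase is cis-specific too
    return preds


def _tag(name: str, chain: LabeledChain) -> str:
    return f"D{chain.total_d}-{name}" if chain.total_d else name
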