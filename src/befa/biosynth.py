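"""Deterministic tracer-fate model of fatty-acid transformations.

Chains are tracked carbon by carbon (C1 = carboxyl carbon, IUPAC numbering;
"omega" is the highest index) with explicit protium/deuterium occupancy of
every hydrogen slot, so each transformation's effect on a deuterium label is
exact bookkeeping rather than heuristics:

* methyl transfer to a cis double bond (fatty-acid C-methyltransferase /
  cyclopropane-synthase chemistry): adds an unlabeled methyl branch at the
  proximal olefinic carbon, migrates the double bond one position distally
  with trans geometry, and abstracts one hydrogen (D preferred when present;
  kinetic isotope effects are ignored) from the carbon the bond migrates to;
* cyclopropanation: bridges a cis double bond with an unlabeled CH2;
* one beta-oxidation round: net removal of the two carboxyl-end carbons,
  the former C3 becoming the new carboxyl carbon and losing its hydrogens
  (the dehydrogenation/hydration/thiolysis intermediates collapse into this
  single rule); a branch or ring at C2/C3 blocks the round;
* alpha-oxidation: 2-hydroxylation followed by C1 removal, the former C2
  becoming the new carboxyl carbon;
* hydroxylation at any carbon, removing a D when the carbon carries one.

No operation ever increases the deuterium count.  The model is free-acid
only (CoA thioesters are out of scope) and stereochemistry-blind for mass
purposes; double-bond geometry is tracked because the methyltransferase is
cis-specific.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple, Union

from .chem_mass import Adduct, M_MINUS_H, MolecularFormula, mz_for_adduct

__all__ = [
    "Carbon",
    "LabeledChain",
    "PredictedMetabolite",
    "NotASubstrateError",
    "BetaBlockedError",
    "make_vaccenic",
    "apply_methyl_transfer",
    "apply_cyclopropanation",
    "apply_beta_oxidation_round",
    "apply_alpha_oxidation",
    "apply_hydroxylation",
    "predict_metabolite",
    "D13_LABEL_PATTERN",
]


class ChainError(ValueError):
    """Structurally impossible chain or operation."""


class NotASubstrateError(ChainError):
    """Chain lacks the cis double bond the enzyme requires."""


class BetaBlockedError(ChainError):
    """A beta-substituent (branch/ring at C2-C3) blocks the oxidation round."""


@dataclass(frozen=True)
class Carbon:
    """Hydrogen-slot occupancy of one carbon: protium and deuterium counts."""

    h: int = 0
    d: int = 0

    def __post_init__(self) -> None:
        if self.h < 0 or self.d < 0:
            raise ChainError("negative hydrogen occupancy")

    @property
    def total(self) -> int:
        return self.h + self.d

    def remove_one(self, prefer: str = "D") -> "Carbon":
        """Abstract one hydrogen; ``prefer`` ("D" or "H") is taken when present."""
        if self.total == 0:
            raise ChainError("no hydrogen to abstract")
        if prefer == "D":
            return Carbon(self.h, self.d - 1) if self.d else Carbon(self.h - 1, self.d)
        return Carbon(self.h - 1, self.d) if self.h else Carbon(self.h, self.d - 1)


DoubleBond = Tuple[int, int, str]  # (i, i+1, "cis"|"trans")

#: commercial d13 vaccenate labeling: C13-C17 doubly, terminal C18 triply deuterated
D13_LABEL_PATTERN: Dict[int, int] = {13: 2, 14: 2, 15: 2, 16: 2, 17: 2, 18: 3}


@dataclass(frozen=True)
class LabeledChain:
    """A fatty-acid carbon skeleton with per-carbon H/D bookkeeping.

    ``carbons[0]`` is C1, the carboxyl carbon (no C-H slots; its acidic OH
    hydrogen is added at formula assembly).  Branches, cyclopropane bridges,
    and hydroxyls are positioned by 1-based carbon index.
    """

    carbons: Tuple[Carbon, ...]
    double_bonds: Tuple[DoubleBond, ...] = ()
    branches: Tuple[Tuple[int, Carbon], ...] = ()  # (position, methyl CH3/CD3 slots)
    bridges: Tuple[Tuple[int, int, Carbon], ...] = ()  # (i, i+1, bridge CH2 slots)
    hydroxyls: Tuple[int, ...] = ()
    trace: Tuple[str, ...] = ()
    annotations: Tuple[str, ...] = ()  # e.g. stereochemistry notes; mass-blind

    def __post_init__(self) -> None:
        self._validate()

    # -- structural accounting --------------------------------------------

    @property
    def n(self) -> int:
        return len(self.carbons)

    def _bond_order(self, i: int) -> int:
        """Non-hydrogen bonds of chain carbon i (1-based)."""
        n = self.n
        bonds = 0
        if i > 1:
            bonds += 1  # bond to C(i-1)
        if i < n:
            bonds += 1  # bond to C(i+1)
        for a, b, _ in self.double_bonds:
            if i in (a, b):
                bonds += 1  # the pi bond
        for pos, _ in self.branches:
            if pos == i:
                bonds += 1
        for a, b, _ in self.bridges:
            if i in (a, b):
                bonds += 1
        if i == 1:
            bonds += 3  # carboxyl: C=O (2) + C-OH (1)
        if i in self.hydroxyls:
            bonds += 1
        return bonds

    def slots(self, i: int) -> int:
        """Hydrogen slots available on chain carbon i given its valence."""
        s = 4 - self._bond_order(i)
        if s < 0:
            raise ChainError(f"carbon {i} is over-bonded")
        return s

    def _validate(self) -> None:
        n = self.n
        if n < 2:
            raise ChainError("chain needs at least two carbons")
        seen_positions: set = set()
        for a, b, geom in self.double_bonds:
            if not (1 <= a < b <= n and b == a + 1):
                raise ChainError(f"double bond ({a},{b}) out of range")
            if geom not in ("cis", "trans"):
                raise ChainError(f"double-bond geometry must be cis/trans, got {geom!r}")
        for a, b, bridge in self.bridges:
            if not (1 <= a < b <= n and b == a + 1):
                raise ChainError(f"bridge ({a},{b}) out of range")
            if bridge.total != 2:
                raise ChainError("cyclopropane bridge CH2 must carry exactly 2 hydrogens")
            for x, y, _ in self.double_bonds:
                if {a, b} & {x, y}:
                    raise ChainError("double bond and bridge overlap")
        for pos, me in self.branches:
            if not 1 <= pos <= n:
                raise ChainError(f"branch position {pos} out of range")
            if me.total != 3:
                raise ChainError("methyl branch must carry exactly 3 hydrogens")
        for pos in self.hydroxyls:
            if not 1 <= pos <= n:
                raise ChainError(f"hydroxyl position {pos} out of range")
        for i, c in enumerate(self.carbons, start=1):
            s = self.slots(i)
            if c.total != s:
                raise ChainError(
                    f"carbon {i} carries {c.total} hydrogens but has {s} slots"
                )

    # -- composition --------------------------------------------------------

    @property
    def total_d(self) -> int:
        d = sum(c.d for c in self.carbons)
        d += sum(me.d for _, me in self.branches)
        d += sum(br.d for _, _, br in self.bridges)
        return d

    def formula(self) -> MolecularFormula:
        """Neutral free-acid molecular formula (D counted separately)."""
        n_c = self.n + len(self.branches) + len(self.bridges)
        h = sum(c.h for c in self.carbons)
        h += sum(me.h for _, me in self.branches)
        h += sum(br.h for _, _, br in self.bridges)
        h += 1  # carboxyl OH
        h += len(self.hydroxyls)  # each hydroxyl OH
        d = self.total_d
        counts = {"C": n_c, "H": h, "O": 2 + len(self.hydroxyls)}
        if d:
            counts["D"] = d
        return MolecularFormula(counts)

    def with_trace(self, step: str) -> "LabeledChain":
        return replace(self, trace=self.trace + (step,))


@dataclass(frozen=True)
class PredictedMetabolite:
    """A predicted chain endpoint: formula, deuterium count, and ion m/z."""

    name: str
    formula: MolecularFormula
    n_d: int
    adduct: Adduct
    mz: float
    trace: Tuple[str, ...]


def make_vaccenic(
    label: Optional[str] = None,
    label_pattern: Optional[Dict[int, int]] = None,
) -> LabeledChain:
    """Vaccenic acid: C18 with an 11,12 double bond (cis-11 18:1).

    ``label`` is None, "d13_cis" or "d13_trans"; the d13 variants place 13
    deuteriums at C13-C18 per ``label_pattern`` (default: 2 per carbon at
    C13-C17 plus 3 on terminal C18, the commercial pattern).
    """
    if label not in (None, "none", "d13_cis", "d13_trans"):
        raise ValueError(f"unknown label {label!r}")
    geometry = "trans" if label == "d13_trans" else "cis"
    pattern = dict(label_pattern or D13_LABEL_PATTERN) if label in ("d13_cis", "d13_trans") else {}
    n = 18
    carbons: List[Carbon] = []
    for i in range(1, n + 1):
        if i == 1:
            slots = 0
        elif i == n:
            slots = 3
        elif i in (11, 12):
            slots = 1
        else:
            slots = 2
        d = pattern.get(i, 0)
        if d > slots:
            raise ChainError(f"label pattern puts {d} D on carbon {i} with {slots} slots")
        carbons.append(Carbon(h=slots - d, d=d))
    tag = {None: "VA", "none": "VA", "d13_cis": "D13-cis-VA", "d13_trans": "D13-trans-VA"}[label]
    return LabeledChain(
        carbons=tuple(carbons),
        double_bonds=((11, 12, geometry),),
        trace=(tag,),
    )


def _single_cis_bond(chain: LabeledChain, what: str) -> DoubleBond:
    cis = [b for b in chain.double_bonds if b[2] == "cis"]
    if len(cis) != 1:
        raise NotASubstrateError(
            f"{what} requires exactly one cis double bond; "
            f"found {len(cis)} (bonds: {chain.double_bonds})"
        )
    return cis[0]


def apply_methyl_transfer(chain: LabeledChain) -> LabeledChain:
    """SAM-dependent C-methylation of the cis double bond.

    Adds an unlabeled CH3 at the proximal olefinic carbon i; the double bond
    migrates to (i+1, i+2) with trans geometry; one hydrogen is abstracted
    from carbon i+2 (a D if present).  Net formula change: +CH2.  Chains
    without a cis double bond are not substrates.
    """
    i, j, _ = _single_cis_bond(chain, "methyl transfer")
    if j + 1 > chain.n:
        raise NotASubstrateError("double bond too close to the chain end to migrate")
    k = j + 1
    if chain.carbons[k - 1].total < 1:
        raise NotASubstrateError(f"carbon {k} has no hydrogen to abstract")
    for pos, _ in chain.branches:
        if pos in (i, j, k):
            raise NotASubstrateError("branch already present at the reaction center")
    carbons = list(chain.carbons)
    carbons[k - 1] = carbons[k - 1].remove_one(prefer="D")
    bonds = tuple(b for b in chain.double_bonds if b[:2] != (i, j)) + ((j, k, "trans"),)
    branches = chain.branches + ((i, Carbon(h=3)),)
    return replace(
        chain,
        carbons=tuple(carbons),
        double_bonds=bonds,
        branches=branches,
    ).with_trace(f"methyl transfer at C{i}; bond migrated to {j},{k} trans; 1 H/D abstracted from C{k}")


def apply_cyclopropanation(chain: LabeledChain) -> LabeledChain:
    """Bridge the cis double bond with an unlabeled CH2 (cyclopropane ring).

    No hydrogens are abstracted from the former olefinic carbons; net
    formula change: +CH2, the same as methyl transfer (the two products are
    constitutional isomers).
    """
    i, j, _ = _single_cis_bond(chain, "cyclopropanation")
    bonds = tuple(b for b in chain.double_bonds if b[:2] != (i, j))
    bridges = chain.bridges + ((i, j, Carbon(h=2)),)
    return replace(chain, double_bonds=bonds, bridges=bridges).with_trace(
        f"cyclopropanation across C{i},C{j}"
    )


def apply_beta_oxidation_round(chain: LabeledChain) -> LabeledChain:
    """One net beta-oxidation round: remove C1 and C2; C3 becomes the new
    carboxyl carbon and loses all its hydrogens (and any deuterium on them).

    Raises :class:`BetaBlockedError` when a branch or cyclopropane ring sits
    at C2/C3 — the termination condition that makes beta-branched acids
    dead-end substrates for the canonical enzymes.
    """
    if chain.n < 4:
        raise ChainError(f"chain of {chain.n} carbons too short for beta-oxidation")
    for pos, _ in chain.branches:
        if pos in (2, 3):
            raise BetaBlockedError(f"methyl branch at C{pos} blocks beta-oxidation")
    for a, b, _ in chain.bridges:
        if {a, b} & {2, 3}:
            raise BetaBlockedError(f"cyclopropane ring at C{a},C{b} blocks beta-oxidation")
    for a, b, _ in chain.double_bonds:
        if a <= 3:
            raise ChainError(
                f"double bond at ({a},{b}) overlaps the cleaved/oxidized carbons; "
                "enoyl-isomerase chemistry is not modeled"
            )
    if 2 in chain.hydroxyls or 3 in chain.hydroxyls:
        raise ChainError("hydroxyl at C2/C3 not supported in beta-oxidation")
    carbons = list(chain.carbons[2:])
    carbons[0] = Carbon(h=0, d=0)  # new carboxyl carbon, stripped
    shift = lambda p: p - 2  # noqa: E731 — renumber old k to new k-2
    return replace(
        chain,
        carbons=tuple(carbons),
        double_bonds=tuple((shift(a), shift(b), g) for a, b, g in chain.double_bonds),
        branches=tuple((shift(p), me) for p, me in chain.branches),
        bridges=tuple((shift(a), shift(b), br) for a, b, br in chain.bridges),
        hydroxyls=tuple(shift(p) for p in chain.hydroxyls if p > 2),
    ).with_trace(f"beta-oxidation round -> C{chain.n - 2}")


def apply_alpha_oxidation(chain: LabeledChain) -> Tuple[LabeledChain, LabeledChain]:
    """Alpha-oxidation: returns (product, 2-hydroxy intermediate).

    Stage 1 replaces one hydrogen at C2 with a hydroxyl (an H is taken when
    present, a D only if C2 carries only D) — the shunt-metabolite
    intermediate.  Stage 2 removes C1; the former C2 becomes the new carboxyl
    carbon, losing its remaining hydrogens.  Net chain length -1.
    """
    if chain.n < 3:
        raise ChainError("chain too short for alpha-oxidation")
    c2 = chain.carbons[1]
    if c2.total < 1:
        raise ChainError("C2 is fully substituted; no hydrogen for 2-hydroxylation")
    carbons = list(chain.carbons)
    carbons[1] = c2.remove_one(prefer="H")
    intermediate = replace(
        chain,
        carbons=tuple(carbons),
        hydroxyls=tuple(sorted(chain.hydroxyls + (2,))),
    ).with_trace("2-hydroxylation at C2")

    for a, b, _ in intermediate.double_bonds + intermediate.bridges:
        if a <= 2:
            raise ChainError("unsaturation/ring at C1-C2 not supported in alpha-oxidation")
    for pos, _ in intermediate.branches:
        if pos <= 2:
            raise ChainError("branch at C1-C2 not supported in alpha-oxidation")
    new_carbons = list(intermediate.carbons[1:])
    new_carbons[0] = Carbon(h=0, d=0)  # former C2, now carboxyl
    shift = lambda p: p - 1  # noqa: E731
    product = replace(
        intermediate,
        carbons=tuple(new_carbons),
        double_bonds=tuple((shift(a), shift(b), g) for a, b, g in intermediate.double_bonds),
        branches=tuple((shift(p), me) for p, me in intermediate.branches),
        bridges=tuple((shift(a), shift(b), br) for a, b, br in intermediate.bridges),
        hydroxyls=tuple(shift(p) for p in intermediate.hydroxyls if p > 2),
    ).with_trace(f"alpha-oxidation: C1 removed -> C{chain.n - 1}")
    return product, intermediate


def apply_hydroxylation(
    chain: LabeledChain, position: Union[int, str]
) -> LabeledChain:
    """Replace one hydrogen at ``position`` with a hydroxyl (+O).

    ``position`` may be a 1-based carbon index, "omega" (terminal carbon) or
    "omega-1".  A deuterium is removed when the carbon carries one (isotope
    effects ignored), so distal oxidation of a labeled chain leaves a
    diagnostic deuterium count.
    """
    if position == "omega":
        pos = chain.n
    elif position == "omega-1":
        pos = chain.n - 1
    else:
        pos = int(position)
    if not 1 <= pos <= chain.n:
        raise ChainError(f"hydroxylation position {pos} out of range")
    c = chain.carbons[pos - 1]
    if c.total < 1:
        raise ChainError(f"carbon {pos} has no hydrogen to replace with OH")
    carbons = list(chain.carbons)
    carbons[pos - 1] = c.remove_one(prefer="D")
    return replace(
        chain,
        carbons=tuple(carbons),
        hydroxyls=tuple(sorted(chain.hydroxyls + (pos,))),
    ).with_trace(f"hydroxylation at C{pos}")


def predict_metabolite(
    chain: LabeledChain, adduct: Adduct = M_MINUS_H, name: str = ""
) -> PredictedMetabolite:
    """Assemble the chain's neutral formula, D count, and ion m/z."""
    f = chain.formula()
    return PredictedMetabolite(
        name=name or (chain.trace[-1] if chain.trace else ""),
        formula=f,
        n_d=chain.total_d,
        adduct=adduct,
        mz=mz_for_adduct(f, adduct),
        trace=chain.trace,
    )
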