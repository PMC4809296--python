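"""Nominal-mass checks for enzymatic product identification.

Negative-mode LC-MS of glycosylated phenolics reports unit-resolution
deprotonated ions [M−H]⁻, so product identity checks reduce to integer
arithmetic: the nominal mass of a molecular formula, the deprotonated
m/z (nominal mass − 1), and neutral-loss differences between parent and
fragment ions, annotated from a small table of sugar- and
galloyl-related losses (e.g. 162 = anhydrohexose for O-glucosides).

Example: β-glucogallin (1-O-galloyl-β-D-glucose, C13H16O10) gives
[M−H]⁻ at m/z 331 and loses 162 to the gallate fragment at m/z 169.

Nominal (integer) masses are the default because the instruments report
unit resolution; monoisotopic masses are available as an option.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping

__all__ = [
    "MolecularFormula",
    "NeutralLoss",
    "FormulaParseError",
    "parse_formula",
    "nominal_mass",
    "monoisotopic_mass",
    "deprotonated_mz",
    "neutral_loss",
    "NOMINAL_MASSES",
    "MONOISOTOPIC_MASSES",
    "NEUTRAL_LOSS_TABLE",
]

NOMINAL_MASSES = {"C": 12, "H": 1, "N": 14, "O": 16, "P": 31, "S": 32}
MONOISOTOPIC_MASSES = {
    "C": 12.0,
    "H": 1.00783,
    "N": 14.00307,
    "O": 15.99491,
    "P": 30.97376,
    "S": 31.97207,
}
PROTON_MASS = 1.00728

#: common neutral losses in glycoside / galloyl ester fragmentation
NEUTRAL_LOSS_TABLE = {
    162: "anhydrohexose (e.g. glucose, galactose)",
    146: "anhydrodeoxyhexose (e.g. rhamnose)",
    132: "anhydropentose",
    152: "galloyl",
    60: "C2H4O2 (hexose cross-ring cleavage)",
}

_TOKEN_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaParseError(ValueError):
    """Raised for element symbols outside C, H, N, O, P, S."""


@dataclass(frozen=True)
class MolecularFormula:
    """Element -> count mapping over C, H, N, O, P, S."""

    composition: Mapping[str, int]

    def __post_init__(self) -> None:
        comp = {}
        for elem, count in dict(self.composition).items():
            if elem not in NOMINAL_MASSES:
                raise FormulaParseError(f"unsupported element {elem!r}")
            count = int(count)
            if count < 0:
                raise ValueError(f"negative count for {elem}")
            if count:
                comp[elem] = count
        if not comp:
            raise ValueError("formula must contain at least one atom")
        object.__setattr__(self, "composition", comp)

    def __getitem__(self, elem: str) -> int:
        return self.composition.get(elem, 0)


def parse_formula(text: str) -> MolecularFormula:
    """Parse ``"C13H16O10"``-style formula strings (``C1`` == ``C``)."""
    pos = 0
    comp: dict[str, int] = {}
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if not m or m.start() != pos or not m.group(1):
            raise FormulaParseError(f"cannot parse formula {text!r} at offset {pos}")
        elem, digits = m.group(1), m.group(2)
        if elem not in NOMINAL_MASSES:
            raise FormulaParseError(f"unsupported element {elem!r} in {text!r}")
        comp[elem] = comp.get(elem, 0) + (int(digits) if digits else 1)
        pos = m.end()
    return MolecularFormula(comp)


def _coerce(formula) -> MolecularFormula:
    return formula if isinstance(formula, MolecularFormula) else parse_formula(formula)


def nominal_mass(formula) -> int:
    """Integer nominal mass (C=12, H=1, N=14, O=16, P=31, S=32)."""
    f = _coerce(formula)
    return sum(NOMINAL_MASSES[e] * n for e, n in f.composition.items())


def monoisotopic_mass(formula) -> float:
    """Monoisotopic mass in Da."""
    f = _coerce(formula)
    return sum(MONOISOTOPIC_MASSES[e] * n for e, n in f.composition.items())


def deprotonated_mz(formula, monoisotopic: bool = False):
    """[M−H]⁻ m/z: nominal mass − 1 (or monoisotopic mass − 1.00728).

    Requires at least one hydrogen to lose.
    """
    f = _coerce(formula)
    if f["H"] < 1:
        raise ValueError("deprotonation requires at least one hydrogen")
    if monoisotopic:
        return monoisotopic_mass(f) - PROTON_MASS
    return nominal_mass(f) - 1


@dataclass(frozen=True)
class NeutralLoss:
    """Parent − fragment mass difference with an annotation."""

    delta: int
    annotation: str


def neutral_loss(parent_mz: int, fragment_mz: int) -> NeutralLoss:
    """Annotated parent-minus-fragment difference.

    Differences absent from :data:`NEUTRAL_LOSS_TABLE` come back
    ``"unassigned"``; a fragment heavier than its parent is an error.
    """
    parent_mz, fragment_mz = int(parent_mz), int(fragment_mz)
    if parent_mz < fragment_mz:
        raise ValueError(
            f"fragment m/z {fragment_mz} exceeds parent m/z {parent_mz}"
        )
    delta = parent_mz - fragment_mz
    return NeutralLoss(delta=delta, annotation=NEUTRAL_LOSS_TABLE.get(delta, "unassigned"))
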