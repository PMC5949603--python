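"""Elemental formulas, monoisotopic masses and ESI adduct m/z for peptide graphs.

The formula of a peptide graph is assembled from residue formulas
(amino acid minus one water) plus one water for the free linear chain,
then adjusted per modification:

- C-terminal carboxamide: -O +N +H
- each lactam ring closure: -H2O
- chloroacetyl-cysteine thioether closure: net +2C +1O (chloroacetylation
  of the N-terminus followed by HCl loss on thioether formation; the two
  extra carbons belong to the closure bond, not to a residue)
- each backbone N-methylation: +CH2

Monoisotopic element masses are IUPAC values; cation masses for adducts
are electron-corrected (proton 1.007276 Da, Na+ 22.989218 Da,
K+ 38.963158 Da). Reported m/z values are rounded half-up to two
decimals, matching the journal convention for calc. values.
"""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Tuple

from bbpkit.notation import PeptideGraph, parse_bbp

__all__ = [
    "ElementalFormula",
    "AdductSpec",
    "ADDUCTS",
    "RESIDUE_FORMULAS",
    "formula_of",
    "monoisotopic_mass",
    "adduct_mz",
    "mz_report",
    "round_mz",
]

# IUPAC monoisotopic atomic masses (Da), most abundant isotope.
MONOISOTOPIC_MASS: Dict[str, float] = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "S": 31.97207100,
}

PROTON = 1.007276
SODIUM_CATION = 22.989218
POTASSIUM_CATION = 38.963158


class ElementalFormula(dict):
    """Element -> count mapping with closed addition/subtraction.

    Subtraction raising on underflow guards the modification bookkeeping:
    a lactam cannot remove a water that is not there.
    """

    def __init__(self, mapping: Mapping[str, int] | None = None, **kw: int):
        super().__init__()
        merged: Dict[str, int] = dict(mapping or {})
        merged.update(kw)
        for el, n in merged.items():
            if n < 0:
                raise ValueError(f"negative count for element {el}: {n}")
            if n:
                self[el] = int(n)

    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        out = dict(self)
        for el, n in other.items():
            out[el] = out.get(el, 0) + n
        return ElementalFormula(out)

    def __sub__(self, other: "ElementalFormula") -> "ElementalFormula":
        out = dict(self)
        for el, n in other.items():
            out[el] = out.get(el, 0) - n
            if out[el] < 0:
                raise ValueError(f"formula underflow on element {el}")
        return ElementalFormula(out)

    def __mul__(self, k: int) -> "ElementalFormula":
        return ElementalFormula({el: n * k for el, n in self.items()})

    __rmul__ = __mul__

    def hill(self) -> str:
        """Formula string in Hill order (C, H, then alphabetical)."""
        order = [el for el in ("C", "H") if el in self]
        order += sorted(el for el in self if el not in ("C", "H"))
        return "".join(f"{el}{self[el] if self[el] != 1 else ''}" for el in order)

    @classmethod
    def parse(cls, text: str) -> "ElementalFormula":
        """Parse a plain formula string like ``C36H52N8O8``."""
        import re

        out: Dict[str, int] = {}
        pos = 0
        for m in re.finditer(r"([A-Z][a-z]?)(\d*)", text):
            if not m.group(0):
                continue
            if m.start() != pos:
                raise ValueError(f"cannot parse formula {text!r}")
            pos = m.end()
            out[m.group(1)] = out.get(m.group(1), 0) + int(m.group(2) or 1)
        if pos != len(text):
            raise ValueError(f"cannot parse formula {text!r}")
        return cls(out)


def _f(**kw: int) -> ElementalFormula:
    return ElementalFormula(kw)


WATER = _f(C=0, H=2, O=1)

# Residue formulas = amino acid - H2O. Special residues:
#   z       gamma-thia-homoglutamate branching unit; contributes a cysteine
#           residue formula, the +C2O of the thioether lives on the bond
#   B       4-benzoyl-L-phenylalanine
#   K(biot) N-epsilon-biotinyl-lysine (Lys residue + biotinoyl - H2O)
RESIDUE_FORMULAS: Dict[str, ElementalFormula] = {
    "G": _f(C=2, H=3, N=1, O=1),
    "A": _f(C=3, H=5, N=1, O=1),
    "S": _f(C=3, H=5, N=1, O=2),
    "P": _f(C=5, H=7, N=1, O=1),
    "V": _f(C=5, H=9, N=1, O=1),
    "T": _f(C=4, H=7, N=1, O=2),
    "C": _f(C=3, H=5, N=1, O=1, S=1),
    "L": _f(C=6, H=11, N=1, O=1),
    "I": _f(C=6, H=11, N=1, O=1),
    "N": _f(C=4, H=6, N=2, O=2),
    "D": _f(C=4, H=5, N=1, O=3),
    "Q": _f(C=5, H=8, N=2, O=2),
    "K": _f(C=6, H=12, N=2, O=1),
    "E": _f(C=5, H=7, N=1, O=3),
    "M": _f(C=5, H=9, N=1, O=1, S=1),
    "H": _f(C=6, H=7, N=3, O=1),
    "F": _f(C=9, H=9, N=1, O=1),
    "R": _f(C=6, H=12, N=4, O=1),
    "Y": _f(C=9, H=9, N=1, O=2),
    "W": _f(C=11, H=10, N=2, O=1),
    "z": _f(C=3, H=5, N=1, O=1, S=1),
    "B": _f(C=16, H=13, N=1, O=2),
    "K(biot)": _f(C=16, H=26, N=4, O=3, S=1),
}

# Net formula deltas per modification.
AMIDE_C_TERM = {"add": _f(N=1, H=1), "sub": _f(O=1)}
LACTAM_DELTA = WATER  # subtracted once per lactam closure
THIOETHER_DELTA = _f(C=2, O=1)  # added once per thioether closure
N_METHYL_DELTA = _f(C=1, H=2)


@dataclass(frozen=True)
class AdductSpec:
    """Positive-mode ESI adduct: m/z = (M + sum of cation deltas) / z."""

    name: str
    delta: float  # total cation mass added, Da
    charge: int

    def mz(self, neutral_mass: float) -> float:
        if neutral_mass <= 0:
            raise ValueError("neutral mass must be positive")
        return (neutral_mass + self.delta) / self.charge


ADDUCTS: Dict[str, AdductSpec] = {
    "[M+H]+": AdductSpec("[M+H]+", PROTON, 1),
    "[M+Na]+": AdductSpec("[M+Na]+", SODIUM_CATION, 1),
    "[M+K]+": AdductSpec("[M+K]+", POTASSIUM_CATION, 1),
    "[M+2H]2+": AdductSpec("[M+2H]2+", 2 * PROTON, 2),
    "[M+Na+H]2+": AdductSpec("[M+Na+H]2+", SODIUM_CATION + PROTON, 2),
    "[M+K+H]2+": AdductSpec("[M+K+H]2+", POTASSIUM_CATION + PROTON, 2),
}


def formula_of(g: PeptideGraph) -> ElementalFormula:
    """Elemental formula of the (possibly cyclized, modified) peptide graph."""
    total = ElementalFormula()
    for res in g.residues:
        key = res.base_type
        if key not in RESIDUE_FORMULAS:
            raise KeyError(f"no formula for residue code {key!r}")
        total = total + RESIDUE_FORMULAS[key]
        if res.n_methylated:
            total = total + N_METHYL_DELTA
    total = total + WATER  # free linear peptide
    if g.c_terminus == "amide":
        total = (total + AMIDE_C_TERM["add"]) - AMIDE_C_TERM["sub"]
    for bond in g.bonds:
        if bond.bond_class == "sidechain_lactam":
            total = total - LACTAM_DELTA
        elif bond.bond_class == "thioether":
            total = total + THIOETHER_DELTA
    return total


def monoisotopic_mass(f: ElementalFormula) -> float:
    """Monoisotopic (most-abundant-isotope) mass in Da."""
    try:
        return sum(n * MONOISOTOPIC_MASS[el] for el, n in f.items())
    except KeyError as e:
        raise KeyError(f"unknown element {e.args[0]!r}") from None


def round_mz(x: float, ndigits: int = 2) -> float:
    """Round half-up, the convention used for printed calc. m/z values."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def adduct_mz(neutral_mass: float, adduct: str | AdductSpec) -> float:
    """Full-precision m/z of a named adduct (round with :func:`round_mz`)."""
    if isinstance(adduct, str):
        try:
            adduct = ADDUCTS[adduct]
        except KeyError:
            raise KeyError(f"unsupported adduct {adduct!r}") from None
    return adduct.mz(neutral_mass)


def mz_report(
    g: PeptideGraph | str, adducts: Iterable[str] = ("[M+H]+",)
) -> List[Tuple[str, float, float]]:
    """Table of (adduct name, m/z full precision, m/z rounded to 2 decimals).

    Accepts a parsed graph or a notation string (parsed with default flags).
    """
    if isinstance(g, str):
        g = parse_bbp(g)
    mass = monoisotopic_mass(formula_of(g))
    out = []
    for name in adducts:
        mz = adduct_mz(mass, name)
        out.append((name, mz, round_mz(mz)))
    return out
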