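"""Plain-text BBP sequence dialect and peptide-graph construction.

A sequence is written N->C as whitespace-separated residue tokens:

- one-letter code, upper case = L-residue, lower case = D-residue,
  glycine ``G`` achiral;
- special codes: ``z`` (branching D-gamma-thia-homoglutamate formed by
  chloroacetyl-cysteine thioether ligation), ``B`` (4-benzoyl-L-
  phenylalanine), ``K(biot)`` (N-epsilon-biotinyl-lysine);
- an optional ``Me`` prefix marks backbone N-methylation (``Mel1``);
- an optional digit suffix ``1`` or ``2`` marks the two residues joined
  by a ring closure (``l1 G k2 f P E1 a2``);
- per-sequence flags ``--amide`` (C-terminal carboxamide) and
  ``--thioether`` (force thioether chemistry for a head closure) may
  trail the tokens or be passed as keyword arguments.

Closure chemistry is resolved from residue identity:

- a label pairing ``z`` with the chain head is the chloroacetyl-cysteine
  thioether (the head's N-terminus is consumed by chloroacetylation);
- ``E``/``e`` paired with the chain head closes a lactam from the Glu
  side-chain carboxyl to the head alpha-amine;
- ``K``/``k`` paired with the chain tail closes a lactam from the
  C-terminal carboxyl to the Lys epsilon-amine;
- an ``E``/``e`` + ``K``/``k`` pair elsewhere closes a side-chain to
  side-chain lactam.

Chemically ambiguous pairings (e.g. two lysines sharing a label) raise
:class:`NotationError` rather than being guessed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import List, Literal, Optional, Tuple

import networkx as nx

from bbpkit.topology import Topology, classify_graph

__all__ = [
    "Residue",
    "BondRecord",
    "PeptideGraph",
    "NotationError",
    "parse_bbp",
    "serialize",
    "classify_topology",
]

_TOKEN_RE = re.compile(
    r"^(?P<me>Me)?(?P<code>K\(biot\)|[A-Za-z])(?P<label>[12])?$"
)

_KNOWN_CODES = set("ACDEFGHIKLMNPQRSTVWY") | {"z", "B", "K(biot)"}


class NotationError(ValueError):
    """Malformed sequence string or chemically invalid closure."""


@dataclass
class Residue:
    code: str  # token without Me prefix / label digit, case preserved
    chirality: Literal["L", "D", "achiral"]
    base_type: str  # formula lookup key: upper-case code, or z / B / K(biot)
    n_methylated: bool = False
    cyclization_label: Optional[int] = None
    position: int = 0  # 1-based, N->C


@dataclass
class BondRecord:
    from_residue: int  # acyl (C=O) donor position
    to_residue: int  # amine acceptor position
    bond_class: Literal["backbone_amide", "sidechain_lactam", "thioether"]


@dataclass
class PeptideGraph:
    residues: List[Residue]
    bonds: List[BondRecord]
    c_terminus: Literal["free_acid", "amide"] = "free_acid"
    n_terminus: Literal["free", "chloroacetylated"] = "free"
    flags: Tuple[str, ...] = field(default_factory=tuple)

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    @property
    def cyclomatic_number(self) -> int:
        return len(self.bonds) - len(self.residues) + 1

    def degree(self, position: int) -> int:
        return sum(
            1
            for b in self.bonds
            if b.from_residue == position or b.to_residue == position
        )

    def to_networkx(self) -> nx.MultiGraph:
        g = nx.MultiGraph()
        for r in self.residues:
            g.add_node(r.position, code=r.code)
        for b in self.bonds:
            g.add_edge(b.from_residue, b.to_residue, bond_class=b.bond_class)
        return g


def _parse_token(tok: str, position: int) -> Residue:
    m = _TOKEN_RE.match(tok)
    if not m:
        raise NotationError(f"cannot parse residue token {tok!r}")
    code = m.group("code")
    if code == "K(biot)":
        base, chir = "K(biot)", "L"
    elif code == "z":
        base, chir = "z", "D"
    elif code == "G":
        base, chir = "G", "achiral"
    else:
        base = code.upper()
        if base not in _KNOWN_CODES:
            raise NotationError(f"unknown residue code {code!r}")
        chir = "L" if code.isupper() else "D"
    label = int(m.group("label")) if m.group("label") else None
    return Residue(
        code=code,
        chirality=chir,
        base_type=base,
        n_methylated=bool(m.group("me")),
        cyclization_label=label,
        position=position,
    )


def _closure_bond(
    pair: Tuple[Residue, Residue], n: int, thioether_flag: bool
) -> Tuple[BondRecord, bool]:
    """Resolve closure chemistry for a label pair.

    Returns the bond and whether the N-terminus is consumed by
    chloroacetylation (thioether closure at the head).
    """
    a, b = pair
    types = {a.base_type, b.base_type}
    head = a if a.position == 1 else b if b.position == 1 else None
    tail = a if a.position == n else b if b.position == n else None
    other = lambda r: b if r is a else a  # noqa: E731

    if "z" in types:
        zres = a if a.base_type == "z" else b
        partner = other(zres)
        if partner.position != 1:
            raise NotationError(
                f"thioether closure requires the chain head; z{zres.position} "
                f"paired with position {partner.position}"
            )
        return (
            BondRecord(partner.position, zres.position, "thioether"),
            True,
        )
    if "E" in types and head is not None and head.base_type != "E":
        eres = a if a.base_type == "E" else b
        return BondRecord(eres.position, head.position, "sidechain_lactam"), False
    if "E" in types and "K" in types:
        eres = a if a.base_type == "E" else b
        kres = other(eres)
        return BondRecord(eres.position, kres.position, "sidechain_lactam"), False
    if "K" in types and tail is not None and tail.base_type != "K":
        kres = a if a.base_type == "K" else b
        return BondRecord(tail.position, kres.position, "sidechain_lactam"), False
    if thioether_flag and "C" in types and head is not None:
        cres = a if a.base_type == "C" else b
        return BondRecord(head.position, cres.position, "thioether"), True
    raise NotationError(
        f"cannot resolve closure chemistry for residues "
        f"{a.code}{a.position} / {b.code}{b.position}"
    )


def parse_bbp(
    text: str, *, amide: bool = False, thioether: bool = False
) -> PeptideGraph:
    """Parse a BBP notation string into a :class:`PeptideGraph`.

    >>> g = parse_bbp("l1 G k2 f P E1 a2")
    >>> g.n_residues, len(g.bonds), g.cyclomatic_number
    (7, 8, 2)
    """
    tokens = text.split()
    flags = []
    while tokens and tokens[-1].startswith("--"):
        flags.append(tokens.pop())
    for fl in reversed(flags):
        if fl == "--amide":
            amide = True
        elif fl == "--thioether":
            thioether = True
        else:
            raise NotationError(f"unknown flag {fl!r}")
    if not tokens:
        raise NotationError("empty sequence")

    residues = [_parse_token(tok, i + 1) for i, tok in enumerate(tokens)]
    n = len(residues)

    bonds = [
        BondRecord(i, i + 1, "backbone_amide") for i in range(1, n)
    ]

    by_label: dict[int, List[Residue]] = {}
    for r in residues:
        if r.cyclization_label is not None:
            by_label.setdefault(r.cyclization_label, []).append(r)
    n_terminus = "free"
    for label, members in sorted(by_label.items()):
        if len(members) != 2:
            raise NotationError(
                f"cyclization label {label} appears {len(members)} time(s); "
                "labels must come in pairs"
            )
        bond, chloroacetylated = _closure_bond(
            (members[0], members[1]), n, thioether
        )
        bonds.append(bond)
        if chloroacetylated:
            n_terminus = "chloroacetylated"

    g = PeptideGraph(
        residues=residues,
        bonds=bonds,
        c_terminus="amide" if amide else "free_acid",
        n_terminus=n_terminus,
        flags=tuple(sorted(set(flags))),
    )
    for r in residues:
        if g.degree(r.position) > 3:
            raise NotationError(
                f"residue {r.code}{r.position} would have degree "
                f"{g.degree(r.position)} > 3"
            )
    return g


def serialize(g: PeptideGraph, include_flags: bool = True) -> str:
    """Normalized notation string; left inverse of :func:`parse_bbp`."""
    toks = []
    for r in g.residues:
        tok = ("Me" if r.n_methylated else "") + r.code
        if r.cyclization_label is not None:
            tok += str(r.cyclization_label)
        toks.append(tok)
    out = " ".join(toks)
    if include_flags:
        if g.c_terminus == "amide":
            out += " --amide"
        if any(b.bond_class == "thioether" for b in g.bonds) and (
            "--thioether" in g.flags
        ):
            out += " --thioether"
    return out


def classify_topology(g: PeptideGraph) -> Topology:
    """Bridge decomposition of a bicyclic peptide graph.

    Requires cyclomatic number 2. Pendant (acyclic tail) residues are
    stripped before locating the two bridgehead nodes; their count is
    reported on the returned :class:`~bbpkit.topology.Topology`.
    """
    if g.cyclomatic_number != 2:
        raise ValueError(
            f"graph is not bicyclic (cyclomatic number {g.cyclomatic_number})"
        )
    return classify_graph(g.to_networkx())
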