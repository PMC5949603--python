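"""Backbone geometry: torsions, cis/trans amides, Ramachandran regions,
beta-turn typing, and intramolecular hydrogen-bond detection.

Conventions
-----------
Torsions follow the IUPAC sign convention and live in (-180, 180]:
phi(i) = C(i-1)-N(i)-CA(i)-C(i), psi(i) = N(i)-CA(i)-C(i)-N(i+1),
omega(i) = CA(i-1)-C(i-1)-N(i)-CA(i). A peptide bond is cis when
|omega| < 90 degrees.

Ramachandran regions are coarse convex polygon approximations of the
standard generic (non-Gly, non-Pro) preferred/allowed contours; for
D-residues the polygons are mirrored through (phi, psi) -> (-phi, -psi).

Beta turns are typed from (phi, psi) of the two central residues of an
i..i+3 window against the canonical Hutchinson-Thornton values, with the
community tolerance of +-30 degrees on each angle, one of the four
allowed to deviate up to +-45 degrees. Type VI requires a cis peptide
bond between i+1 and i+2. Windows failing every type are labeled IV.

Hydrogen bonds are detected on reconstructed amide protons (H placed in
the C(i-1)-N(i)-CA(i) plane, N-H 1.01 A, bisecting the exterior angle)
with cutoffs N...O <= 3.5 A and N-H...O >= 120 degrees, skipping the
donor's own and preceding residue.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Literal, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "BackboneResidue",
    "BackboneStructure",
    "DihedralSet",
    "TurnAssignment",
    "HBondRecord",
    "dihedral",
    "bond_angle",
    "omega_class",
    "ramachandran_region",
    "classify_turn",
    "detect_hbonds",
    "TURN_CANONICAL",
]


@dataclass
class BackboneResidue:
    name: str
    chirality: Literal["L", "D", "achiral"] = "L"
    atoms: Dict[str, np.ndarray] = field(default_factory=dict)

    def __getitem__(self, atom: str) -> np.ndarray:
        return self.atoms[atom]

    def __contains__(self, atom: str) -> bool:
        return atom in self.atoms


@dataclass
class BackboneStructure:
    """Ordered residues with N/CA/C/O (+ optional CB, H) coordinates in A."""

    residues: List[BackboneResidue]
    closure_bonds: List[Tuple[int, int]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.residues)

    def coords(self, atom: str) -> np.ndarray:
        return np.array([r[atom] for r in self.residues])

    def validate(self) -> List[str]:
        """Warnings for non-finite coordinates or unusual C-N distances."""
        warnings = []
        for i, r in enumerate(self.residues):
            for name, xyz in r.atoms.items():
                if not np.all(np.isfinite(xyz)):
                    warnings.append(f"residue {i + 1} atom {name}: non-finite")
        for i in range(len(self) - 1):
            if "C" in self.residues[i] and "N" in self.residues[i + 1]:
                d = float(
                    np.linalg.norm(self.residues[i]["C"] - self.residues[i + 1]["N"])
                )
                if not (1.2 <= d <= 1.5):
                    warnings.append(
                        f"C({i + 1})-N({i + 2}) distance {d:.2f} A outside 1.2-1.5"
                    )
        return warnings

    def torsions(self) -> "DihedralSet":
        """Recompute phi/psi/omega from coordinates (None at termini)."""
        n = len(self)
        phi: List[Optional[float]] = [None] * n
        psi: List[Optional[float]] = [None] * n
        omega: List[Optional[float]] = [None] * n
        for i in range(n):
            r = self.residues[i]
            if i > 0:
                prev = self.residues[i - 1]
                phi[i] = dihedral(prev["C"], r["N"], r["CA"], r["C"])
                omega[i] = dihedral(prev["CA"], prev["C"], r["N"], r["CA"])
            if i < n - 1:
                nxt = self.residues[i + 1]
                psi[i] = dihedral(r["N"], r["CA"], r["C"], nxt["N"])
        return DihedralSet(phi=phi, psi=psi, omega=omega)

    def mirrored(self) -> "BackboneStructure":
        """Coordinate inversion through the origin (chirality flip)."""
        flip = {"L": "D", "D": "L", "achiral": "achiral"}
        return BackboneStructure(
            residues=[
                BackboneResidue(
                    name=r.name,
                    chirality=flip[r.chirality],
                    atoms={a: -xyz for a, xyz in r.atoms.items()},
                )
                for r in self.residues
            ],
            closure_bonds=list(self.closure_bonds),
        )


@dataclass
class DihedralSet:
    """Per-residue phi/psi/omega in degrees; None where undefined."""

    phi: List[Optional[float]]
    psi: List[Optional[float]]
    omega: List[Optional[float]]

    def __len__(self) -> int:
        return len(self.phi)


def dihedral(p1, p2, p3, p4) -> float:
    """Signed torsion angle p1-p2-p3-p4 in degrees, IUPAC convention,
    range (-180, 180]."""
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    norm_b2 = np.linalg.norm(b2)
    if norm_b2 < 1e-12 or np.linalg.norm(n1) < 1e-9 or np.linalg.norm(n2) < 1e-9:
        raise ValueError("degenerate geometry: collinear points in torsion")
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2) / norm_b2)
    ang = math.degrees(math.atan2(y, x))
    if ang <= -180.0:
        ang += 360.0
    return ang


def bond_angle(p1, p2, p3) -> float:
    """Angle p1-p2-p3 in degrees."""
    p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p1, p2, p3))
    u = p1 - p2
    v = p3 - p2
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return math.degrees(math.acos(np.clip(cosang, -1.0, 1.0)))


def omega_class(omega: float) -> Literal["cis", "trans"]:
    """cis iff |omega| < 90 degrees."""
    return "cis" if abs(omega) < 90.0 else "trans"


# Coarse convex approximations of the generic Ramachandran contours for
# L-residues (phi, psi vertex lists). Exact published contour data can be
# substituted via the `polygons` argument.
_PREFERRED_L: List[List[Tuple[float, float]]] = [
    # right-handed alpha
    [(-105.0, -65.0), (-105.0, -10.0), (-45.0, -10.0), (-45.0, -65.0)],
    # beta / extended
    [(-170.0, 95.0), (-170.0, 180.0), (-55.0, 180.0), (-55.0, 95.0)],
]
_ALLOWED_L: List[List[Tuple[float, float]]] = [
    [(-180.0, -90.0), (-180.0, 40.0), (-20.0, 40.0), (-20.0, -90.0)],
    [(-180.0, 60.0), (-180.0, 180.0), (-20.0, 180.0), (-20.0, 60.0)],
    [(-180.0, -180.0), (-180.0, -160.0), (-20.0, -160.0), (-20.0, -180.0)],
    # left-handed alpha (allowed for L-residues)
    [(20.0, -20.0), (20.0, 90.0), (100.0, 90.0), (100.0, -20.0)],
]


def _in_convex(point: Tuple[float, float], poly: Sequence[Tuple[float, float]]) -> bool:
    x, y = point
    sign = 0
    npts = len(poly)
    for i in range(npts):
        x1, y1 = poly[i]
        x2, y2 = poly[(i + 1) % npts]
        cross = (x2 - x1) * (y - y1) - (y2 - y1) * (x - x1)
        if abs(cross) < 1e-12:
            continue
        s = 1 if cross > 0 else -1
        if sign == 0:
            sign = s
        elif s != sign:
            return False
    return True


def ramachandran_region(
    phi: float,
    psi: float,
    chirality: Literal["L", "D", "achiral"] = "L",
    polygons: Optional[
        Tuple[List[List[Tuple[float, float]]], List[List[Tuple[float, float]]]]
    ] = None,
) -> Literal["preferred", "allowed", "outlier"]:
    """Classify a (phi, psi) pair; D-residue regions are the mirror image
    of the L regions through (-phi, -psi)."""
    preferred, allowed = polygons if polygons is not None else (
        _PREFERRED_L,
        _ALLOWED_L,
    )
    if chirality == "D":
        phi, psi = -phi, -psi
    pt = (phi, psi)
    if any(_in_convex(pt, poly) for poly in preferred):
        return "preferred"
    if any(_in_convex(pt, poly) for poly in allowed):
        return "allowed"
    return "outlier"


# Canonical (phi_{i+1}, psi_{i+1}, phi_{i+2}, psi_{i+2}) per turn type,
# Hutchinson-Thornton convention. Type VI requires a cis i+1 -> i+2 bond.
TURN_CANONICAL: Dict[str, Tuple[float, float, float, float]] = {
    "I": (-60.0, -30.0, -90.0, 0.0),
    "I'": (60.0, 30.0, 90.0, 0.0),
    "II": (-60.0, 120.0, 80.0, 0.0),
    "II'": (60.0, -120.0, -80.0, 0.0),
    "VIII": (-60.0, -30.0, -120.0, 120.0),
    "VIa": (-60.0, 120.0, -90.0, 0.0),
    "VIb": (-135.0, 135.0, -75.0, 160.0),
}
_CIS_TYPES = {"VIa", "VIb"}
_MIRROR_TYPE = {"I": "I'", "I'": "I", "II": "II'", "II'": "II"}

TURN_TOLERANCE = 30.0
TURN_TOLERANCE_ONE = 45.0


@dataclass
class TurnAssignment:
    window: Tuple[int, int, int, int]  # residue indices i..i+3 (0-based)
    type_label: str  # one of TURN_CANONICAL keys or "IV"
    deviations: Dict[str, float] = field(default_factory=dict)
    ca_distance: Optional[float] = None


def _angdiff(a: float, b: float) -> float:
    d = (a - b + 180.0) % 360.0 - 180.0
    return abs(d)


def classify_turn(
    d: DihedralSet,
    i: int,
    cis_at_central_bond: Optional[bool] = None,
    ca_distance: Optional[float] = None,
) -> TurnAssignment:
    """Type the four-residue window starting at 0-based index ``i``.

    ``cis_at_central_bond`` is the omega class of the i+1 -> i+2 peptide
    bond; when None it is taken from ``d.omega[i+2]`` if defined, else
    assumed trans.
    """
    if i < 0 or i + 3 >= len(d):
        raise IndexError("turn window out of range")
    angles = (d.phi[i + 1], d.psi[i + 1], d.phi[i + 2], d.psi[i + 2])
    if any(a is None for a in angles):
        raise ValueError("undefined phi/psi in turn window")
    if cis_at_central_bond is None:
        om = d.omega[i + 2]
        cis_at_central_bond = om is not None and omega_class(om) == "cis"

    best_label = "IV"
    best_sum = math.inf
    best_devs: Dict[str, float] = {}
    for label, canon in TURN_CANONICAL.items():
        if (label in _CIS_TYPES) != cis_at_central_bond:
            continue
        devs = [_angdiff(a, c) for a, c in zip(angles, canon)]
        within = sum(1 for dv in devs if dv <= TURN_TOLERANCE)
        loose = sum(1 for dv in devs if dv <= TURN_TOLERANCE_ONE)
        if within >= 3 and loose == 4:
            s = sum(devs)
            if s < best_sum:
                best_sum = s
                best_label = label
                best_devs = dict(
                    zip(("phi_i1", "psi_i1", "phi_i2", "psi_i2"), devs)
                )
    return TurnAssignment(
        window=(i, i + 1, i + 2, i + 3),
        type_label=best_label,
        deviations=best_devs,
        ca_distance=ca_distance,
    )


def enumerate_turns(s: BackboneStructure) -> List[TurnAssignment]:
    """Classify every i..i+3 window along the written chain."""
    d = s.torsions()
    out = []
    for i in range(len(s) - 3):
        ca_d = float(
            np.linalg.norm(s.residues[i]["CA"] - s.residues[i + 3]["CA"])
        )
        out.append(classify_turn(d, i, ca_distance=ca_d))
    return out


@dataclass
class HBondRecord:
    donor: int  # residue index (0-based), backbone N-H
    acceptor: int  # residue index, carbonyl O
    distance: float  # N...O, A
    angle: float  # N-H...O, degrees


N_H_LENGTH = 1.01
HBOND_DIST_CUTOFF = 3.5
HBOND_ANGLE_CUTOFF = 120.0


def reconstruct_amide_h(s: BackboneStructure, i: int) -> Optional[np.ndarray]:
    """Amide H of residue i (needs the preceding residue's C)."""
    if i == 0:
        return None
    r = s.residues[i]
    prev = s.residues[i - 1]
    if "N" not in r or "CA" not in r or "C" not in prev:
        return None
    n = r["N"]
    u1 = prev["C"] - n
    u2 = r["CA"] - n
    u1 = u1 / np.linalg.norm(u1)
    u2 = u2 / np.linalg.norm(u2)
    h_dir = -(u1 + u2)
    norm = np.linalg.norm(h_dir)
    if norm < 1e-9:
        return None
    return n + N_H_LENGTH * h_dir / norm


def detect_hbonds(
    s: BackboneStructure,
    dist_cutoff: float = HBOND_DIST_CUTOFF,
    angle_cutoff: float = HBOND_ANGLE_CUTOFF,
) -> List[HBondRecord]:
    """Backbone N-H...O=C hydrogen bonds.

    Donors are backbone amide nitrogens with a reconstructed (or stored)
    H; acceptors are carbonyl oxygens. Pairs where the acceptor is the
    donor's own or preceding residue are trivial covalent contacts and
    skipped. Residues missing atoms are skipped, not fatal.
    """
    out: List[HBondRecord] = []
    for i, r in enumerate(s.residues):
        h = r.atoms.get("H")
        if h is None:
            h = reconstruct_amide_h(s, i)
        if h is None or "N" not in r:
            continue
        n = r["N"]
        for j, acc in enumerate(s.residues):
            if j in (i, i - 1) or "O" not in acc:
                continue
            o = acc["O"]
            dist = float(np.linalg.norm(n - o))
            if dist > dist_cutoff:
                continue
            ang = bond_angle(n, h, o)
            if ang >= angle_cutoff:
                out.append(HBondRecord(donor=i, acceptor=j, distance=dist, angle=ang))
    return out
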