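"""Alpha-helix mimicry: can a bicyclic scaffold present three side chains
the way a helix double turn does?

The analysis builds an ideal seven-residue alpha-helix (phi = -57,
psi = -47, omega = 180), enumerates all C(n,3) residue triplets on both
structures, optimally superposes each structure-triplet onto each
helix-triplet (least-squares rigid fit, proper rotations only), and
ranks the pairs by RMSD; a Gaussian atom-pair overlap score is reported
alongside. Atom modes: CA (3 points), CB (3 points, glycine triplets
skipped), or both (6 points).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import List, Literal, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial.transform import Rotation

from bbpkit.geometry import BackboneStructure
from bbpkit.synthetic import build_polyala

__all__ = [
    "TripletMatch",
    "build_ideal_helix",
    "enumerate_triplets",
    "superpose",
    "atom_pair_score",
    "rank_matches",
    "IDEAL_HELIX_PHI",
    "IDEAL_HELIX_PSI",
]

IDEAL_HELIX_PHI = -57.0
IDEAL_HELIX_PSI = -47.0


@dataclass
class TripletMatch:
    structure_triplet: Tuple[int, int, int]  # 0-based residue indices
    helix_triplet: Tuple[int, int, int]
    atom_mode: Literal["CA", "CB", "both"]
    rmsd: float
    overlap: float
    reversed_mapping: bool = False


def build_ideal_helix(n: int) -> BackboneStructure:
    """Ideal poly-alanine alpha-helix of n residues (n >= 2), all-trans,
    with tetrahedral CB atoms."""
    if n < 2:
        raise ValueError("helix needs at least 2 residues")
    return build_polyala(n, IDEAL_HELIX_PHI, IDEAL_HELIX_PSI, 180.0)


def enumerate_triplets(n: int) -> List[Tuple[int, int, int]]:
    """All C(n,3) ordered index triples i < j < k (0-based)."""
    if n < 3:
        raise ValueError("need at least 3 residues for a triplet")
    return list(itertools.combinations(range(n), 3))


def superpose(
    A: np.ndarray, B: np.ndarray
) -> Tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of B onto A.

    Returns (rotation matrix, translation, RMSD) such that
    ``B @ R.T + t`` best matches A in the least-squares sense. Only
    proper rotations are considered (no reflection), so superposing a
    chiral set onto its mirror image leaves a positive RMSD.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 3 or A.shape[0] < 3:
        raise ValueError("need two equal-shape (n>=3, 3) point sets")
    ca, cb = A.mean(axis=0), B.mean(axis=0)
    A0, B0 = A - ca, B - cb
    if np.linalg.matrix_rank(A0, tol=1e-9) < 2 or np.linalg.matrix_rank(B0, tol=1e-9) < 2:
        raise ValueError("degenerate (collinear) point set")
    rot, rssd = Rotation.align_vectors(A0, B0)
    R = rot.as_matrix()
    t = ca - cb @ R.T
    rmsd = rssd / math.sqrt(A.shape[0])
    return R, t, float(rmsd)


def atom_pair_score(A: np.ndarray, B: np.ndarray, sigma: float = 1.0) -> float:
    """Gaussian overlap of matched atom pairs after superposition.

    Mean over pairs of exp(-d^2 / (2 sigma^2)); 1.0 for perfect overlap,
    monotone decreasing in every pairwise distance.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    d2 = np.sum((A - B) ** 2, axis=1)
    return float(np.mean(np.exp(-d2 / (2.0 * sigma * sigma))))


def _triplet_points(
    s: BackboneStructure, triplet: Sequence[int], mode: str
) -> Optional[np.ndarray]:
    pts = []
    for idx in triplet:
        r = s.residues[idx]
        if mode in ("CA", "both"):
            if "CA" not in r:
                return None
            pts.append(r["CA"])
        if mode in ("CB", "both"):
            if "CB" not in r:
                return None  # glycine: no beta carbon
            pts.append(r["CB"])
    return np.array(pts)


def rank_matches(
    s: BackboneStructure,
    helix: Optional[BackboneStructure] = None,
    mode: Literal["CA", "CB", "both"] = "CA",
    sigma: float = 1.0,
    include_reversed: bool = False,
) -> List[TripletMatch]:
    """Evaluate every structure-triplet x helix-triplet pair and rank by
    ascending RMSD (ties by descending overlap score).

    Residues correspond in sequence order within a triplet (i->p, j->q,
    k->r); ``include_reversed`` also tries (i->r, j->q, k->p) and keeps
    the better fit. Triplets lacking a required atom (glycine in a CB
    mode) are skipped.
    """
    if helix is None:
        helix = build_ideal_helix(7)
    matches: List[TripletMatch] = []
    s_triplets = enumerate_triplets(len(s))
    h_triplets = enumerate_triplets(len(helix))
    for st in s_triplets:
        sp = _triplet_points(s, st, mode)
        if sp is None:
            continue
        for ht in h_triplets:
            hp = _triplet_points(helix, ht, mode)
            if hp is None:
                continue
            candidates = [(hp, False)]
            if include_reversed:
                npts = 2 if mode == "both" else 1
                rev = np.concatenate(
                    [hp[k * npts : (k + 1) * npts] for k in (2, 1, 0)]
                )
                candidates.append((rev, True))
            best = None
            for pts, is_rev in candidates:
                R, t, rmsd = superpose(sp, pts)
                overlap = atom_pair_score(sp, pts @ R.T + t, sigma)
                if best is None or rmsd < best[0]:
                    best = (rmsd, overlap, is_rev)
            matches.append(
                TripletMatch(
                    structure_triplet=st,
                    helix_triplet=ht,
                    atom_mode=mode,
                    rmsd=best[0],
                    overlap=best[1],
                    reversed_mapping=best[2],
                )
            )
    matches.sort(key=lambda m: (m.rmsd, -m.overlap))
    return matches
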