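"""Synthetic inputs: torsion-driven peptide backbones, coordinate noise,
simulated ITC/MST datasets, and packaged table fixtures.

The backbone builder places atoms sequentially from internal coordinates
(NeRF-style) with standard peptide geometry, so any list of per-residue
(phi, psi, omega) torsions can be turned into Cartesian coordinates and
round-tripped through :meth:`bbpkit.geometry.BackboneStructure.torsions`.
It is the desk-scale stand-in for experimentally refined coordinates.

Every generator is a pure function of its parameters and a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import List, Literal, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from bbpkit.geometry import BackboneResidue, BackboneStructure
from bbpkit.binding import ITCExperiment, Isotherm, MSTSeries, itc_model, mst_model

__all__ = [
    "TorsionSpec",
    "NoiseSpec",
    "GEOMETRY",
    "build_backbone",
    "build_polyala",
    "perturb",
    "gen_itc",
    "gen_mst",
    "load_fixtures",
    "paper_itc_design",
    "paper_mst_design",
]

# Standard peptide geometry (Engh-Huber-style values): bond lengths in A,
# angles in degrees.
GEOMETRY = {
    "N-CA": 1.458,
    "CA-C": 1.525,
    "C-N": 1.329,
    "C=O": 1.231,
    "CA-CB": 1.521,
    "N-CA-C": 111.2,
    "CA-C-N": 117.2,
    "C-N-CA": 121.7,
    "CA-C=O": 120.8,
    "N-CA-CB": 110.4,
    # improper torsion C-N-CA-CB placing CB; sign flips for D-residues
    "CB-improper": -122.55,
}


@dataclass
class TorsionSpec:
    """Per-residue (phi, psi, omega) in degrees plus identities.

    phi of the first residue and psi/omega entries at termini that have
    no geometric meaning are still carried (used e.g. to orient the
    C-terminal carbonyl) but are not recoverable from coordinates.
    """

    phi: Sequence[float]
    psi: Sequence[float]
    omega: Sequence[float]
    names: Optional[Sequence[str]] = None
    chirality: Optional[Sequence[str]] = None

    def __post_init__(self):
        n = len(self.phi)
        if len(self.psi) != n or len(self.omega) != n:
            raise ValueError("phi/psi/omega lengths disagree")
        if self.names is not None and len(self.names) != n:
            raise ValueError("names length disagrees")
        if self.chirality is not None and len(self.chirality) != n:
            raise ValueError("chirality length disagrees")

    def __len__(self) -> int:
        return len(self.phi)


@dataclass
class NoiseSpec:
    """Gaussian noise: sigma in A for coordinates, fraction-of-max for
    heats/signals. Identical seed => identical output."""

    sigma: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


def _place(a, b, c, length: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """NeRF: position of atom d bonded to c with angle b-c-d and torsion
    a-b-c-d."""
    angle = math.radians(angle_deg)
    torsion = math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -length * math.cos(angle),
            length * math.sin(angle) * math.cos(torsion),
            length * math.sin(angle) * math.sin(torsion),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_backbone(spec: TorsionSpec) -> BackboneStructure:
    """Cartesian backbone (N, CA, C, O, CB) from torsions.

    Glycine residues (name 'GLY' or chirality 'achiral') get no CB.
    D-residues get the mirrored CB improper torsion.
    """
    n_res = len(spec)
    names = list(spec.names) if spec.names is not None else ["ALA"] * n_res
    chir = list(spec.chirality) if spec.chirality is not None else ["L"] * n_res

    g = GEOMETRY
    residues: List[BackboneResidue] = []
    # first residue in the xy-plane
    N = np.array([0.0, 0.0, 0.0])
    CA = np.array([g["N-CA"], 0.0, 0.0])
    theta = math.radians(180.0 - g["N-CA-C"])
    C = CA + g["CA-C"] * np.array([math.cos(theta), math.sin(theta), 0.0])
    atoms_prev = (N, CA, C)
    for i in range(n_res):
        N, CA, C = atoms_prev
        res = BackboneResidue(name=names[i], chirality=chir[i], atoms={})
        res.atoms["N"], res.atoms["CA"], res.atoms["C"] = N, CA, C
        # carbonyl O anti to the next amide N: torsion N-CA-C-O = psi + 180
        res.atoms["O"] = _place(
            res.atoms["N"], res.atoms["CA"], res.atoms["C"],
            g["C=O"], g["CA-C=O"], spec.psi[i] + 180.0,
        )
        if chir[i] != "achiral" and names[i] != "GLY":
            tau = g["CB-improper"] if chir[i] == "L" else -g["CB-improper"]
            res.atoms["CB"] = _place(
                res.atoms["C"], res.atoms["N"], res.atoms["CA"],
                g["CA-CB"], g["N-CA-CB"], tau,
            )
        residues.append(res)
        if i + 1 < n_res:
            N_next = _place(N, CA, C, g["C-N"], g["CA-C-N"], spec.psi[i])
            CA_next = _place(CA, C, N_next, g["N-CA"], g["C-N-CA"], spec.omega[i + 1])
            C_next = _place(C, N_next, CA_next, g["CA-C"], g["N-CA-C"], spec.phi[i + 1])
            atoms_prev = (N_next, CA_next, C_next)
    return BackboneStructure(residues=residues)


def build_polyala(
    n: int, phi: float, psi: float, omega: float = 180.0
) -> BackboneStructure:
    """Uniform-torsion poly-L-alanine backbone (helix, strand, ...)."""
    spec = TorsionSpec(
        phi=[phi] * n, psi=[psi] * n, omega=[omega] * n,
        names=["ALA"] * n, chirality=["L"] * n,
    )
    return build_backbone(spec)


def perturb(s: BackboneStructure, noise: NoiseSpec) -> BackboneStructure:
    """i.i.d. Gaussian displacement of every coordinate; sigma = 0 is the
    identity, same seed gives identical output."""
    rng = np.random.default_rng(noise.seed)
    out = []
    for r in s.residues:
        atoms = {
            name: xyz + rng.normal(0.0, noise.sigma, size=3)
            for name, xyz in r.atoms.items()
        }
        out.append(BackboneResidue(name=r.name, chirality=r.chirality, atoms=atoms))
    return BackboneStructure(residues=out, closure_bonds=list(s.closure_bonds))


def paper_itc_design() -> ITCExperiment:
    """The published titration protocol: 15 x 2.5 uL injections of 0.7 mM
    peptide into 200 uL of 50 uM protein at 25 C."""
    return ITCExperiment(
        cell_volume_uL=200.0,
        injection_volumes_uL=(2.5,) * 15,
        syringe_conc_mM=0.7,
        cell_conc_uM=50.0,
        temperature_K=298.15,
    )


def paper_mst_design() -> MSTSeries:
    """The published dose-response design: 15-level 2-fold ligand series
    from 500 uM, mixed 1:1 with 20 nM labeled protein -> final ligand
    250 uM .. 15.3 nM at 10 nM protein. Signal filled by the generator."""
    from bbpkit.binding import dilution_series

    conc = dilution_series(500e-6, factor=2.0, levels=15, mix=True)
    return MSTSeries(
        ligand_conc_M=conc,
        protein_conc_M=10e-9,
        signal=np.full(len(conc), np.nan),
    )


def gen_itc(
    n: float,
    Ka: float,
    dH: float,
    experiment: ITCExperiment,
    noise: NoiseSpec = NoiseSpec(),
) -> Isotherm:
    """Forward one-set-of-sites isotherm plus additive Gaussian noise
    (sigma as a fraction of the largest |heat|)."""
    iso = itc_model(n, Ka, dH, experiment)
    if noise.sigma == 0:
        return iso
    rng = np.random.default_rng(noise.seed)
    scale = noise.sigma * float(np.max(np.abs(iso.heats_ucal)))
    heats = iso.heats_ucal + rng.normal(0.0, scale, size=len(iso.heats_ucal))
    return Isotherm(heats_ucal=heats, molar_ratio=iso.molar_ratio)


def gen_mst(
    KD: float,
    design: MSTSeries,
    noise: NoiseSpec = NoiseSpec(),
    s_free: float = 1.0,
    s_bound: float = 0.0,
) -> MSTSeries:
    """Forward 1:1 quadratic dose-response plus additive Gaussian noise
    (sigma as a fraction of the plateau-to-plateau amplitude)."""
    fb = np.array(
        [mst_model(L, design.protein_conc_M, KD) for L in design.ligand_conc_M]
    )
    signal = s_free + (s_bound - s_free) * fb
    if noise.sigma > 0:
        rng = np.random.default_rng(noise.seed)
        signal = signal + rng.normal(
            0.0, noise.sigma * abs(s_bound - s_free), size=len(signal)
        )
    return MSTSeries(
        ligand_conc_M=np.array(design.ligand_conc_M, dtype=float),
        protein_conc_M=design.protein_conc_M,
        signal=signal,
    )


_FIXTURE_FILES = {
    "sequences": "sequences.csv",
    "formulas_mz": "sequences.csv",
    "temp_coeffs": "temp_coeffs.csv",
    "nmethyl": "sequences.csv",
}


def load_fixtures(name: str) -> pd.DataFrame:
    """Packaged fixture tables.

    - ``sequences`` / ``formulas_mz``: every compound with its notation,
      flags, printed formula and printed calc. m/z values (plus
      consistency flags for the handful of printed-table typos).
    - ``nmethyl``: the N-methylated subseries.
    - ``temp_coeffs``: amide-proton temperature coefficients with the
      printed boldface (fully H-bonded) flags.
    - ``itc_design`` / ``mst_design``: the titration protocols as
      single-row tables.
    """
    if name in ("itc_design",):
        e = paper_itc_design()
        return pd.DataFrame(
            [
                {
                    "cell_volume_uL": e.cell_volume_uL,
                    "n_injections": len(e.injection_volumes_uL),
                    "injection_volume_uL": e.injection_volumes_uL[0],
                    "syringe_conc_mM": e.syringe_conc_mM,
                    "cell_conc_uM": e.cell_conc_uM,
                    "temperature_K": e.temperature_K,
                    "source": "published ITC protocol",
                }
            ]
        )
    if name in ("mst_design",):
        d = paper_mst_design()
        return pd.DataFrame(
            {
                "ligand_conc_M": d.ligand_conc_M,
                "protein_conc_M": d.protein_conc_M,
                "source": "published MST dilution scheme",
            }
        )
    if name not in _FIXTURE_FILES:
        raise KeyError(f"unknown fixture {name!r}")
    path = resources.files("bbpkit.data") / _FIXTURE_FILES[name]
    with path.open() as fh:
        df = pd.read_csv(fh, keep_default_na=False)
    for col in ("formula_consistent", "mz_consistent", "bold", "determined"):
        if col in df.columns and df[col].dtype == object:
            df[col] = df[col].map({"True": True, "False": False})
    if name == "nmethyl":
        df = df[df["source"] == "table4"].reset_index(drop=True)
    if name == "formulas_mz":
        df = df[df["printed_mz"] != ""].reset_index(drop=True)
    return df
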