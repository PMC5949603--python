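"""Torsion computation, Ramachandran classification, turn typing, H-bonds."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bbpkit.geometry import (
    TURN_CANONICAL,
    BackboneResidue,
    BackboneStructure,
    DihedralSet,
    classify_turn,
    detect_hbonds,
    dihedral,
    enumerate_turns,
    omega_class,
    ramachandran_region,
)
from bbpkit.synthetic import TorsionSpec, build_backbone, build_polyala

angles = st.floats(min_value=-179.99, max_value=180.0)


def _angdiff(a, b):
    return abs((a - b + 180.0) % 360.0 - 180.0)


class TestDihedral:
    def test_planar_cis_is_zero(self):
        p = [(1, 1, 0), (1, 0, 0), (-1, 0, 0), (-1, 1, 0)]
        assert dihedral(*p) == pytest.approx(0.0, abs=1e-12)

    def test_planar_anti_is_180(self):
        p = [(1, 1, 0), (1, 0, 0), (-1, 0, 0), (-1, -1, 0)]
        assert dihedral(*p) == pytest.approx(180.0, abs=1e-12)

    @pytest.mark.parametrize("target", [60.0, -60.0, 90.0, -135.0])
    def test_analytic_construction(self, target):
        # p4 rotated around the p2-p3 (x) axis by the target angle
        rad = math.radians(target)
        p1 = (1.0, 1.0, 0.0)
        p2 = (1.0, 0.0, 0.0)
        p3 = (-1.0, 0.0, 0.0)
        p4 = (-1.0, math.cos(rad), -math.sin(rad))
        assert dihedral(p1, p2, p3, p4) == pytest.approx(target, abs=1e-9)

    def test_collinear_degenerate(self):
        with pytest.raises(ValueError):
            dihedral((0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 1, 0))

    def test_range_is_half_open(self):
        p = [(1, 1, 0), (1, 0, 0), (-1, 0, 0), (-1, -1, 0)]
        assert dihedral(*p) == 180.0  # not -180


class TestOmegaClass:
    @pytest.mark.parametrize(
        "omega,expected",
        [(180.0, "trans"), (0.0, "cis"), (-95.0, "trans"), (89.9, "cis"), (90.0, "trans")],
    )
    def test_threshold(self, omega, expected):
        assert omega_class(omega) == expected


class TestRamachandran:
    def test_canonical_helix_point(self):
        assert ramachandran_region(-57.0, -47.0, "L") == "preferred"

    def test_d_residue_mirror_point(self):
        assert ramachandran_region(57.0, 47.0, "D") == "preferred"

    @given(phi=angles, psi=angles)
    @settings(deadline=None, max_examples=200)
    def test_mirror_symmetry_property(self, phi, psi):
        assert ramachandran_region(phi, psi, "L") == ramachandran_region(
            -phi, -psi, "D"
        )

    def test_outlier(self):
        assert ramachandran_region(100.0, -170.0, "L") == "outlier"


class TestClassifyTurn:
    @staticmethod
    def _dset(a1, a2, a3, a4, omega3=180.0):
        return DihedralSet(
            phi=[None, a1, a3, 10.0],
            psi=[10.0, a2, a4, None],
            omega=[None, 180.0, omega3, 180.0],
        )

    @pytest.mark.parametrize("label,canon", sorted(TURN_CANONICAL.items()))
    def test_canonical_identity(self, label, canon):
        omega3 = 0.0 if label in ("VIa", "VIb") else 180.0
        d = self._dset(*canon, omega3=omega3)
        assert classify_turn(d, 0).type_label == label

    def test_within_tolerance_keeps_type(self):
        d = self._dset(-40.0, 140.0, 100.0, 20.0)  # type II + 20 each
        assert classify_turn(d, 0).type_label == "II"

    def test_outside_tolerance_is_iv(self):
        d = self._dset(-10.0, 170.0, 130.0, 50.0)  # type II + 50 each
        assert classify_turn(d, 0).type_label == "IV"

    def test_one_angle_may_stretch_to_45(self):
        d = self._dset(-60.0, 120.0, 80.0 + 40.0, 0.0)
        assert classify_turn(d, 0).type_label == "II"
        d = self._dset(-60.0 - 40.0, 120.0, 80.0 + 40.0, 0.0)  # two loose angles
        assert classify_turn(d, 0).type_label == "IV"

    def test_cis_required_for_type_vi(self):
        canon = TURN_CANONICAL["VIa"]
        assert classify_turn(self._dset(*canon, omega3=0.0), 0).type_label == "VIa"
        # with a trans central bond the same angles are closest to II
        assert classify_turn(self._dset(*canon, omega3=180.0), 0).type_label != "VIa"

    def test_undefined_angles_rejected(self):
        d = DihedralSet(phi=[None] * 4, psi=[None] * 4, omega=[None] * 4)
        with pytest.raises(ValueError):
            classify_turn(d, 0)


class TestTorsionRoundTrip:
    @given(seed=st.integers(0, 10_000))
    @settings(deadline=None, max_examples=25)
    def test_build_then_recompute(self, seed):
        rng = np.random.default_rng(seed)
        n = 6
        spec = TorsionSpec(
            phi=rng.uniform(-179, 180, n),
            psi=rng.uniform(-179, 180, n),
            omega=rng.uniform(-179, 180, n),
        )
        t = build_backbone(spec).torsions()
        for i in range(n):
            if i > 0:
                assert _angdiff(t.phi[i], spec.phi[i]) < 1e-6
                assert _angdiff(t.omega[i], spec.omega[i]) < 1e-6
            if i < n - 1:
                assert _angdiff(t.psi[i], spec.psi[i]) < 1e-6

    def test_termini_undefined(self):
        t = build_polyala(4, -57.0, -47.0).torsions()
        assert t.phi[0] is None and t.omega[0] is None and t.psi[-1] is None


class TestMirrorProperty:
    def test_coordinate_inversion_negates_torsions_and_primes_turns(self):
        # type II turn embedded in a chain
        spec = TorsionSpec(
            phi=[-57.0, -60.0, 80.0, -57.0],
            psi=[-47.0, 120.0, 0.0, -47.0],
            omega=[180.0] * 4,
        )
        s = build_backbone(spec)
        m = s.mirrored()
        t, tm = s.torsions(), m.torsions()
        for i in range(4):
            if t.phi[i] is not None:
                assert _angdiff(tm.phi[i], -t.phi[i]) < 1e-9
            if t.psi[i] is not None:
                assert _angdiff(tm.psi[i], -t.psi[i]) < 1e-9
        assert classify_turn(t, 0).type_label == "II"
        assert classify_turn(tm, 0).type_label == "II'"


class TestHBonds:
    @staticmethod
    def _pair_structure(no_dist, angle_deg):
        """Donor N-H and acceptor C=O at a prescribed N...O distance and
        N-H...O angle (H on the x axis, O placed in the xy-plane)."""
        h = np.array([1.01, 0.0, 0.0])
        rad = math.radians(180.0 - angle_deg)
        # point O at distance no_dist from N, steered by the angle at H
        direction = np.array([math.cos(rad), math.sin(rad), 0.0])
        # find O along the ray from H such that |N-O| = no_dist
        # parameterize O = H + s*direction, solve |O| = no_dist
        b = 2 * float(h @ direction)
        c = float(h @ h) - no_dist**2
        s = (-b + math.sqrt(b * b - 4 * c)) / 2
        o = h + s * direction
        donor = BackboneResidue(
            name="ALA",
            atoms={
                "N": np.zeros(3),
                "H": h,
                "CA": np.array([-0.5, -1.3, 0.0]),
                "C": np.array([-2.0, -1.5, 0.0]),
                "O": np.array([-2.5, -2.5, 0.0]),
            },
        )
        spacer = BackboneResidue(name="GLY", atoms={"CA": np.array([5.0, 5.0, 5.0])})
        acceptor = BackboneResidue(
            name="ALA",
            atoms={"O": o, "C": o + np.array([0.0, 1.2, 0.0])},
        )
        return BackboneStructure(residues=[donor, spacer, acceptor])

    def test_inside_both_cutoffs_detected(self):
        s = self._pair_structure(2.9, 160.0)
        hits = detect_hbonds(s)
        assert [(h.donor, h.acceptor) for h in hits] == [(0, 2)]
        assert hits[0].distance == pytest.approx(2.9, abs=1e-9)
        assert hits[0].angle == pytest.approx(160.0, abs=1e-6)

    def test_long_distance_not_detected(self):
        assert detect_hbonds(self._pair_structure(4.0, 160.0)) == []

    def test_bent_geometry_not_detected(self):
        assert detect_hbonds(self._pair_structure(2.9, 100.0)) == []

    def test_ideal_helix_i4_to_i(self):
        from bbpkit.mimicry import build_ideal_helix

        s = build_ideal_helix(10)
        hits = detect_hbonds(s)
        pairs = {(h.donor, h.acceptor) for h in hits}
        expected = {(i + 4, i) for i in range(10 - 4)}
        assert expected <= pairs
        # nothing closer-range than i+3 sneaks in
        assert all(h.donor - h.acceptor >= 3 for h in hits)


class TestValidation:
    def test_broken_bond_distance_warns(self):
        s = build_polyala(3, -57.0, -47.0)
        s.residues[2].atoms["N"] = s.residues[2]["N"] + np.array([5.0, 0, 0])
        assert any("distance" in w for w in s.validate())

    def test_clean_structure_no_warnings(self):
        assert build_polyala(4, -57.0, -47.0).validate() == []

    def test_enumerate_turns_window_count(self):
        s = build_polyala(7, -57.0, -47.0)
        assert len(enumerate_turns(s)) == 4
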