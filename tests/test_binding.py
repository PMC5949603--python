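"""Temperature-coefficient classification and ITC/MST binding models."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bbpkit.binding import (
    ITCExperiment,
    Isotherm,
    MSTBindingModel,
    MSTSeries,
    OneSiteITCModel,
    R_GAS_KCAL,
    classify_temp_coeff,
    dilution_series,
    itc_model,
    mst_model,
    thermodynamics,
)
from bbpkit.synthetic import gen_mst, paper_itc_design, paper_mst_design


class TestTempCoeff:
    @pytest.mark.parametrize(
        "value,expected",
        [
            (1.7, "full"),
            (8.8, "none"),
            (4.0, "partial"),
            (7.0, "partial"),
            (3.999, "full"),
            (7.001, "none"),
            (-1.0, "full"),
        ],
    )
    def test_thresholds(self, value, expected):
        assert classify_temp_coeff(value) == expected

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            classify_temp_coeff(float("nan"))

    def test_published_bold_partition(self, temp_coeffs_df):
        """The fully-H-bonded class must coincide exactly with the
        boldface marking of the printed coefficient table."""
        det = temp_coeffs_df[temp_coeffs_df["determined"]]
        assert len(det) == 61
        for _, row in det.iterrows():
            cls = classify_temp_coeff(float(row["coefficient"]))
            assert (cls == "full") == bool(row["bold"]), (
                row["compound"],
                row["proton"],
            )


class TestThermodynamics:
    def test_unit_Ka_gives_zero_dG(self):
        dG, _ = thermodynamics(1.0, -5.0, 298.15)
        assert dG == 0.0

    def test_printed_example(self):
        # KD = 0.80 uM at 298.15 K
        dG, _ = thermodynamics(1.0 / 0.80e-6, -5.0, 298.15)
        assert dG == pytest.approx(-8.29, abs=0.01)

    @given(
        logKa=st.floats(-3, 12),
        dH=st.floats(-30, 30),
        T=st.floats(273.0, 330.0),
    )
    @settings(deadline=None)
    def test_gibbs_identity(self, logKa, dH, T):
        Ka = 10.0**logKa
        dG, dS = thermodynamics(Ka, dH, T)
        assert dG == pytest.approx(dH - T * dS, abs=1e-12)
        assert dG == pytest.approx(-R_GAS_KCAL * T * math.log(Ka), abs=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            thermodynamics(0.0, -5.0, 298.15)


class TestITCForwardModel:
    def test_stoichiometric_limit(self):
        # huge Ka: every injected mole binds until the cell saturates
        e = paper_itc_design()
        iso = itc_model(1.0, 1e12, -5.0, e)
        moles_per_inj = 2.5e-6 * 0.7e-3  # L * mol/L
        expected_ucal = -5.0 * moles_per_inj * 1e9
        assert iso.heats_ucal[0] == pytest.approx(expected_ucal, rel=5e-3)
        assert abs(iso.heats_ucal[-1]) < abs(expected_ucal) * 0.01

    def test_zero_affinity_limit(self):
        e = paper_itc_design()
        iso = itc_model(1.0, 1e-9, -5.0, e)
        assert np.all(np.abs(iso.heats_ucal) < 1e-6)

    def test_sigmoid_midpoint_near_n(self):
        # the half-height injection spans the interval ending at its molar
        # ratio, so the midpoint is the interval center
        e = paper_itc_design()
        for n in (0.8, 1.0, 1.3):
            iso = itc_model(n, 1e7, -5.0, e)
            half = 0.5 * iso.heats_ucal[0]
            idx = int(np.argmin(np.abs(iso.heats_ucal - half)))
            prev_ratio = iso.molar_ratio[idx - 1] if idx else 0.0
            center = 0.5 * (iso.molar_ratio[idx] + prev_ratio)
            assert center == pytest.approx(n, abs=0.1)

    def test_heat_sum_identity(self):
        """Injection heats minus displacement corrections telescope to the
        final cumulative binding heat."""
        e = paper_itc_design()
        n, Ka, dH = 1.0, 1.25e6, -5.0
        iso = itc_model(n, Ka, dH, e)
        V0 = e.cell_volume_uL * 1e-6
        inj = np.asarray(e.injection_volumes_uL) * 1e-6
        from bbpkit.binding import _bound_complex, _effective_concentrations

        Mt, Xt = _effective_concentrations(e, "displacement")
        Q = _bound_complex(n, Ka, Mt, Xt) * V0 * dH * 1e9
        Qprev = np.concatenate([[0.0], Q[:-1]])
        corrections = (inj / V0) * (Q + Qprev) / 2.0
        assert np.sum(iso.heats_ucal - corrections) == pytest.approx(
            Q[-1], rel=1e-9
        )

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            itc_model(1.0, -1.0, -5.0, paper_itc_design())
        with pytest.raises(ValueError):
            ITCExperiment(cell_volume_uL=-1.0)


class TestITCFit:
    def test_noiseless_self_recovery_at_printed_KD(self):
        e = paper_itc_design()
        iso = itc_model(1.0, 1.0 / 0.80e-6, -5.0, e)
        res = OneSiteITCModel(iso, e).fit()
        assert res.KD * 1e6 == pytest.approx(0.80, rel=1e-3)
        assert res.n == pytest.approx(1.0, rel=1e-3)
        assert res.dH == pytest.approx(-5.0, rel=1e-3)

    @pytest.mark.parametrize("KD_uM", [0.01, 0.1, 1.0, 10.0, 100.0])
    def test_recovery_across_affinity_grid(self, KD_uM):
        e = paper_itc_design()
        KD = KD_uM * 1e-6
        iso = itc_model(1.0, 1.0 / KD, -5.0, e)
        res = OneSiteITCModel(iso, e).fit()
        assert abs(res.KD - KD) / KD <= 1e-3

    def test_enthalpy_sign_symmetry(self):
        e = paper_itc_design()
        up = OneSiteITCModel(itc_model(1.0, 1.25e6, 5.0, e), e).fit()
        down = OneSiteITCModel(itc_model(1.0, 1.25e6, -5.0, e), e).fit()
        assert up.dH == pytest.approx(-down.dH, rel=1e-6)
        assert up.KD == pytest.approx(down.KD, rel=1e-6)

    def test_gibbs_identity_on_results(self):
        e = paper_itc_design()
        res = OneSiteITCModel(itc_model(1.0, 1.25e6, -5.0, e), e).fit()
        assert res.dG == pytest.approx(res.dH - res.temperature_K * res.dS, abs=1e-12)
        assert res.summary().startswith("One-set-of-sites ITC fit")

    def test_c_value_warning(self):
        e = paper_itc_design()
        iso = itc_model(1.0, 1e2, -5.0, e)  # c = 0.005
        res = OneSiteITCModel(iso, e).fit()
        assert any("c =" in w for w in res.warnings)

    def test_too_few_injections(self):
        e = ITCExperiment(injection_volumes_uL=(2.5,) * 3)
        iso = itc_model(1.0, 1e6, -5.0, e)
        with pytest.raises(ValueError):
            OneSiteITCModel(iso, e)


class TestMSTModel:
    def test_half_saturation_in_protein_free_limit(self):
        assert mst_model(4.5e-6, 0.0, 4.5e-6) == pytest.approx(0.5)

    def test_saturation(self):
        assert mst_model(1.0, 10e-9, 4.5e-6) == pytest.approx(1.0, abs=1e-4)

    def test_quadratic_matches_excess_ligand_limit(self):
        # at 10 nM protein the ligand is effectively in excess everywhere
        KD, P = 4.5e-6, 10e-9
        for L in dilution_series(500e-6, 2.0, 15, mix=True):
            exact = mst_model(L, P, KD)
            approx = L / (L + KD)
            assert abs(exact - approx) < 1e-3

    def test_invalid(self):
        with pytest.raises(ValueError):
            mst_model(1e-6, 1e-9, 0.0)


class TestDilutionSeries:
    def test_published_endpoints_pre_mix(self):
        series = dilution_series(500e-6, 2.0, 15)
        assert series[0] == pytest.approx(500e-6)
        assert series[-1] * 1e9 == pytest.approx(30.5, abs=0.05)

    def test_published_endpoints_after_mixing(self):
        series = dilution_series(500e-6, 2.0, 15, mix=True)
        assert series[0] == pytest.approx(250e-6)
        assert series[-1] * 1e9 == pytest.approx(15.3, abs=0.05)

    def test_single_level(self):
        assert list(dilution_series(1e-3, 2.0, 1)) == [1e-3]

    def test_strictly_decreasing_constant_factor(self):
        s = dilution_series(1e-3, 3.0, 8)
        ratios = s[:-1] / s[1:]
        assert np.allclose(ratios, 3.0)


class TestMSTFit:
    def test_noiseless_self_recovery_at_printed_KD(self):
        series = gen_mst(4.5e-6, paper_mst_design())
        res = MSTBindingModel(series).fit()
        assert res.KD * 1e6 == pytest.approx(4.5, rel=1e-3)
        assert res.reliable

    @pytest.mark.parametrize("KD_uM", [0.01, 0.1, 1.0, 10.0, 100.0])
    def test_recovery_across_affinity_grid(self, KD_uM):
        KD = KD_uM * 1e-6
        series = gen_mst(KD, paper_mst_design())
        res = MSTBindingModel(series).fit()
        assert abs(res.KD - KD) / KD <= 1e-3

    def test_flat_signal_flagged(self):
        d = paper_mst_design()
        series = MSTSeries(
            ligand_conc_M=d.ligand_conc_M,
            protein_conc_M=d.protein_conc_M,
            signal=np.ones_like(d.ligand_conc_M),
        )
        res = MSTBindingModel(series).fit()
        assert not res.reliable

    def test_transition_outside_range_flagged(self):
        series = gen_mst(0.05, paper_mst_design())  # KD = 50 mM, way above top
        res = MSTBindingModel(series).fit()
        assert any("outside" in w for w in res.warnings)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            MSTBindingModel(
                MSTSeries(np.ones(4), 1e-8, np.ones(4))
            )

    def test_summary_mentions_KD(self):
        res = MSTBindingModel(gen_mst(4.5e-6, paper_mst_design())).fit()
        assert "KD" in res.summary()
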