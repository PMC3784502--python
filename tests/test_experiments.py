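"""Virtual experiments: transfection patterns, dose responses, pulse-chase,
kinase inhibition, ablations, competition scans and sensitivity."""

import math

import numpy as np
import pytest

import dcx
from dcx import experiments as ex
from dcx.params import default_parameters


@pytest.fixture(scope="module")
def params():
    return default_parameters()


@pytest.fixture(scope="module")
def sw480_panel(params):
    return ex.run_transfection_panel("SW480", dose=100.0, params=params)


class TestTransfectionPanel:
    def test_sign_pattern(self, sw480_panel):
        """In SW480 cells at 100 nM dose: full-length-like constructs (A)
        and SAMP-bearing fragments (E) lower beta-catenin; more truncated
        APC (B) raises it; the isolated 20-aa fragment (D) and the empty
        fragment (F) change nothing; the 15-aa-only fragment (C) does not
        fall below the baseline."""
        base = sw480_panel["F"]           # F is inert, so it IS the baseline
        decreased = {c for c, v in sw480_panel.items() if v < base * 0.99}
        assert decreased == {"A", "E"}
        assert sw480_panel["B"] > base * 1.01
        assert sw480_panel["D"] == pytest.approx(base, rel=1e-4)
        assert sw480_panel["C"] >= base * 0.99

    def test_class_f_identical_to_untransfected(self, params, sw480_panel):
        untransfected = ex.total_bcat(
            dcx.make_cell_model("SW480", params=params)) / params.BCAT_tot
        assert sw480_panel["F"] == pytest.approx(untransfected, rel=1e-6)

    def test_class_d_inert_at_any_dose(self, params):
        base = ex.total_bcat(dcx.make_cell_model("SW480", params=params))
        for dose in (30.0, 300.0):
            v = ex.total_bcat(
                dcx.make_cell_model("SW480", [("D", dose)], params=params))
            assert v == pytest.approx(base, rel=1e-2)

    def test_negative_dose_rejected(self, params):
        with pytest.raises(ValueError):
            ex.run_transfection_panel("SW480", dose=-5.0, params=params)


class TestDoseScans:
    def test_normal_cell_apc_scan_monotone_nondecreasing(self, params):
        """Added full-length APC never lowers beta-catenin in normal
        cells (concentration-dependent positive effect)."""
        curve = ex.run_dose_scan("normal", "A", doses=[0.0, 0.1, 1.0, 3.0, 10.0],
                                 params=params)
        assert np.all(np.diff(curve.values) >= -1e-6)
        assert curve.values[-1] > curve.values[0]

    def test_sw480_full_length_scan_below_baseline(self, params):
        """Full-length APC depresses beta-catenin in SW480 cells over at
        least a decade of dose."""
        curve = ex.run_dose_scan("SW480", "A", doses=[0.0, 0.3, 1.0, 3.0],
                                 params=params)
        baseline = curve.values[0]
        assert np.all(curve.values[1:] < baseline)

    def test_sw480_truncated_scan_monotone_increasing(self, params):
        curve = ex.run_dose_scan("SW480", "B", doses=[0.0, 1.0, 10.0],
                                 params=params)
        assert np.all(np.diff(curve.values) > 0)
        # the elevation at 10x vs baseline is the "doubling" readout
        assert curve.meta.setdefault("elevation_10x",
                                     curve.values[-1] / curve.values[0]) > 1.5

    def test_dose_zero_equals_untransfected(self, params):
        curve = ex.run_dose_scan("SW480", "C", doses=[0.0], params=params)
        untrans = ex.total_bcat(dcx.make_cell_model("SW480", params=params))
        assert curve.values[0] == pytest.approx(untrans / params.BCAT_tot, rel=1e-9)

    def test_unsorted_doses_rejected(self):
        with pytest.raises(ValueError):
            ex.DoseResponseCurve(np.array([1.0, 0.5]), np.array([1.0, 1.0]),
                                 "BCAT_relative", "SW480")


class TestPulseChase:
    def test_uniform_degradation_gives_exact_exponential(self, params):
        """With kdeg_fast = kdeg_slow = k every molecule decays at k
        regardless of state, so the half-life is exactly ln2/k."""
        k = params.kdeg_slow
        p = params.replace(kdeg_fast=k)
        cell = dcx.make_cell_model("normal", params=p)
        res = ex.run_pulse_chase(cell)
        assert res.half_life_min * 60.0 == pytest.approx(math.log(2.0) / k,
                                                         rel=1e-4)

    def test_shutoff_and_cohort_protocols_agree(self, params):
        """The two pulse-chase readings differ only through background
        relaxation and should agree closely at steady state."""
        cell = dcx.make_cell_model("normal", params=params)
        shut = ex.run_pulse_chase(cell, "shutoff")
        coh = ex.run_pulse_chase(cell, "cohort")
        assert shut.half_life_min == pytest.approx(coh.half_life_min, rel=0.1)

    def test_decay_curve_monotone_nonincreasing(self, params):
        cell = dcx.make_cell_model("normal", params=params)
        res = ex.run_pulse_chase(cell)
        assert np.all(np.diff(res.level) <= 1e-9)
        assert res.level[0] == pytest.approx(1.0)

    def test_unknown_protocol_rejected(self, params):
        with pytest.raises(ValueError):
            ex.run_pulse_chase(dcx.make_cell_model("normal", params=params),
                               "chase-pulse")


class TestLiCl:
    def test_fold_one_is_flat(self, params):
        cell = dcx.make_cell_model("normal", params=params)
        res = ex.run_licl(cell, fold=1.0, t_end=1800.0, n_points=7)
        assert np.allclose(res["pS45_rel"], 1.0, atol=1e-5)
        assert np.allclose(res["pS33_37_rel"], 1.0, atol=1e-5)

    def test_normalized_to_one_at_time_zero(self, params):
        cell = dcx.make_cell_model("normal", params=params)
        res = ex.run_licl(cell, fold=20.0, t_end=3600.0, n_points=13)
        assert res["pS45_rel"][0] == pytest.approx(1.0)
        assert res["pS33_37_rel"][0] == pytest.approx(1.0)

    def test_stronger_inhibition_lowers_s33_37_pointwise(self, params):
        cell = dcx.make_cell_model("normal", params=params)
        r5 = ex.run_licl(cell, fold=5.0, t_end=3600.0, n_points=13)
        r20 = ex.run_licl(cell, fold=20.0, t_end=3600.0, n_points=13)
        assert np.all(r20["pS33_37_rel"][1:] < r5["pS33_37_rel"][1:])

    def test_infinite_inhibition_extinguishes_s33_37(self, params):
        """With the GSK-mediated rates effectively zero, the S33/37 pool
        has no production and decays toward zero."""
        cell = dcx.make_cell_model("normal", params=params)
        res = ex.run_licl(cell, fold=1e9, t_end=14400.0, n_points=13)
        assert res["pS33_37_rel"][-1] < 0.01

    def test_fold_below_one_rejected(self, params):
        with pytest.raises(ValueError):
            ex.run_licl(dcx.make_cell_model("normal", params=params), fold=0.5)


class TestAblation:
    def test_cyclic_core_is_dispensable(self, params):
        """Blocking the APC-BCAT (15-aa) or BCAT-Axin contact barely moves
        beta-catenin; only the APC-Axin (SAMP) interface matters."""
        results = {r.interface: r.relative_level
                   for r in ex.run_interface_ablation(params)}
        assert results["bcat_apc_15aa"] == pytest.approx(1.0, abs=0.05)
        assert results["bcat_axin"] == pytest.approx(1.0, abs=0.05)
        assert results["apc_axin"] > 1.5

    def test_no_ablation_is_unity_by_construction(self, params):
        ref = ex.total_bcat(dcx.make_cell_model("normal", params=params))
        assert ref / ref == 1.0


class TestPhosphoScan:
    def test_axin_association_decreases_with_phosphorylation(self, params):
        res = ex.run_apc_phospho_scan(ratios=(0.0, 1.0, 5.0), doses=[1.0],
                                      params=params)
        fr = [res["frac_axin_with_bcat"][r][0] for r in (0.0, 1.0, 5.0)]
        assert fr[0] > fr[1] > fr[2]

    def test_default_ratio_reproduces_unmodified_scan(self, params):
        res = ex.run_apc_phospho_scan(ratios=(1.0,), doses=[0.0], params=params)
        base = ex.total_bcat(dcx.make_cell_model("SW480", params=params))
        assert res["BCAT_relative"][1.0][0] == pytest.approx(
            base / params.BCAT_tot, rel=1e-6)

    def test_unphosphorylatable_apc_lowers_bcat(self, params):
        """With the 20-aa repeat never phosphorylated the truncated APC
        loses its stabilizing (sequestration) activity."""
        res = ex.run_apc_phospho_scan(ratios=(0.0, 1.0), doses=[0.0], params=params)
        assert res["BCAT_relative"][0.0][0] < res["BCAT_relative"][1.0][0]


class TestAxinAssociationScan:
    def test_scaffold_bell_in_normal_cells(self, params):
        """Axin-associated beta-catenin vs total APC has an interior
        maximum (the scaffold effect) in normal cells."""
        curves = ex.run_axin_association_scan(
            "normal", doses=np.logspace(-2, 1, 7), params=params)
        v = curves["frac_bcat_with_axin"].values
        k = int(np.argmax(v))
        assert 0 < k < len(v) - 1
        assert v[k] > v[0] and v[k] > v[-1]

    def test_monotone_sequestration_in_sw480(self, params):
        curves = ex.run_axin_association_scan(
            "SW480", doses=np.logspace(-2, 1, 7), params=params)
        v = curves["frac_bcat_with_axin"].values
        assert np.all(np.diff(v) < 0)

    def test_direct_apc_binding_rises_with_apc(self, params):
        curves = ex.run_axin_association_scan(
            "SW480", doses=np.array([0.01, 1.0, 10.0]), params=params)
        v = curves["bcat_direct_apc"].values
        assert v[-1] > v[0]


class TestSensitivity:
    def test_absent_parameter_has_zero_coefficient(self, params):
        """The truncated-APC affinity does not enter the normal-cell model."""
        table = ex.local_sensitivity(
            dcx.make_cell_model("normal", params=params),
            parameters=["KD2_bap_1338"])
        assert table.as_dict()["KD2_bap_1338"] == 0.0

    def test_synthesis_coefficient_is_one_in_first_order_limit(self, params):
        """With all binding off, steady state is ksyn/kdeg_slow, so the
        normalized sensitivity to the synthesis rate is exactly +1."""
        p = params.replace(kf=0.0)
        table = ex.local_sensitivity(
            dcx.make_cell_model("normal", params=p),
            parameters=["ksyn_molec"], delta=0.05)
        assert table.as_dict()["ksyn_molec"] == pytest.approx(1.0, abs=1e-3)

    def test_central_difference_convergence(self, params):
        """Halving delta shrinks the discretization error quadratically;
        compare successive Richardson differences."""
        cell = dcx.make_cell_model("normal", params=params)
        s1 = ex.local_sensitivity(cell, ["kdeg_fast"], delta=0.2).as_dict()["kdeg_fast"]
        s2 = ex.local_sensitivity(cell, ["kdeg_fast"], delta=0.1).as_dict()["kdeg_fast"]
        s3 = ex.local_sensitivity(cell, ["kdeg_fast"], delta=0.05).as_dict()["kdeg_fast"]
        assert abs(s3 - s2) < abs(s2 - s1) * 0.6 + 1e-9

    def test_invalid_delta_rejected(self, params):
        with pytest.raises(ValueError):
            ex.local_sensitivity(dcx.make_cell_model("normal", params=params),
                                 ["kf"], delta=1.5)
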