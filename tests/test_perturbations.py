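import math

import numpy as np
import pytest

import firesweep as fs
from firesweep.cable_solver import StimulusProtocol, run
from firesweep.perturbations import (
    PerturbationError,
    PerturbationSpec,
    StatisticUndefinedError,
    apply,
    initial_e_ca,
    load_scan_config,
    relative_difference_at_max_common,
    run_config,
    run_scenarios,
    scan,
)
from firesweep.protocols import FICurve


class TestPerturbationSpec:
    def test_conductance_factor_range_enforced(self):
        with pytest.raises(PerturbationError):
            PerturbationSpec(conductance_factors={"na_hh": 0.2})
        with pytest.raises(PerturbationError):
            PerturbationSpec(conductance_factors={"na_hh": 10.5})

    def test_reversal_shift_range_enforced(self):
        with pytest.raises(PerturbationError):
            PerturbationSpec(reversal_shifts={"na": 25.0})

    def test_unknown_region(self):
        with pytest.raises(PerturbationError):
            PerturbationSpec(cm_region="axon")

    def test_default_label(self):
        spec = PerturbationSpec(cm_factor=1.5, cm_region="sprx",
                                conductance_factors={"SK": 4.0})
        assert "cm1.5" in spec.label and "SK" in spec.label
        assert PerturbationSpec().label == "identity"


class TestApply:
    def test_identity_spec_compares_equal(self, oc_model):
        derived = apply(oc_model, PerturbationSpec())
        assert derived.equals(oc_model)

    def test_apply_is_pure(self, oc_model):
        cm_before = oc_model.cell.cm.copy()
        g_before = oc_model.placement("na_hh").gbar
        a = apply(oc_model, PerturbationSpec(cm_factor=1.5,
                                             conductance_factors={"na_hh": 2.0}))
        b = apply(oc_model, PerturbationSpec(cm_factor=1.5,
                                             conductance_factors={"na_hh": 2.0}))
        assert np.array_equal(oc_model.cell.cm, cm_before)
        assert oc_model.placement("na_hh").gbar == g_before
        assert a.equals(b)

    def test_oc_sprx_equals_all(self, oc_model):
        m_all = apply(oc_model, PerturbationSpec(cm_factor=1.5, cm_region="all"))
        m_sprx = apply(oc_model, PerturbationSpec(cm_factor=1.5, cm_region="sprx"))
        p = StimulusProtocol(amplitude=0.2, duration=100.0)
        assert np.array_equal(run(m_all, p).v, run(m_sprx, p).v)

    def test_sprx_and_all_diverge_for_bas(self, bas_model):
        m_all = apply(bas_model, PerturbationSpec(cm_factor=1.5, cm_region="all"))
        m_sprx = apply(bas_model, PerturbationSpec(cm_factor=1.5, cm_region="sprx"))
        p = StimulusProtocol(amplitude=0.2, duration=100.0)
        va, vs = run(m_all, p).v, run(m_sprx, p).v
        assert np.abs(va - vs).max() > 1.0

    def test_absent_mechanism_is_validation_error(self, oc_model):
        with pytest.raises(PerturbationError, match="SK"):
            apply(oc_model, PerturbationSpec(conductance_factors={"SK": 2.0}))

    def test_reversal_shift_hits_all_carriers_of_the_ion(self, small_fixture):
        model, _, _ = small_fixture
        shifted = apply(model, PerturbationSpec(reversal_shifts={"k": -10.0}))
        for pl, pl0 in zip(shifted.placements, model.placements):
            if pl.mech.ion == "k":
                assert pl.mech.erev == pl0.mech.erev - 10.0
            elif pl.mech.erev is not None:
                assert pl.mech.erev == pl0.mech.erev

    def test_leak_shift_hits_both_bas_leaks(self, bas_model):
        shifted = apply(bas_model, PerturbationSpec(reversal_shifts={"leak": 5.0}))
        assert shifted.placement("leak").mech.erev == -54.3 + 5.0
        assert shifted.placement("leak_dend").mech.erev == -65.0 + 5.0

    def test_na_shift_53_to_63(self, small_fixture):
        model, _, _ = small_fixture
        shifted = apply(model, PerturbationSpec(reversal_shifts={"na": 10.0}))
        assert shifted.placement("NaV").mech.erev == pytest.approx(63.0)

    def test_delta_e_ca_inversion_is_exact(self, small_fixture):
        model, _, _ = small_fixture
        e0 = initial_e_ca(model)
        for de in (-20.0, 10.0, 30.0):
            shifted = apply(model, PerturbationSpec(delta_e_ca=de))
            assert initial_e_ca(shifted) == pytest.approx(e0 + de, abs=1e-6)

    def test_plus_30mv_multiplies_ca_out_by_9p65(self, small_fixture):
        model, _, _ = small_fixture
        shifted = apply(model, PerturbationSpec(delta_e_ca=30.0))
        factor = shifted.ca.pool.ca_out / model.ca.pool.ca_out
        assert factor == pytest.approx(9.65, abs=0.01)

    def test_ca_out_factor_ten_gives_printed_161_53(self, small_fixture):
        model, _, _ = small_fixture
        assert initial_e_ca(model) == pytest.approx(131.06, abs=0.01)
        shifted = apply(model, PerturbationSpec(ca_out_factor=10.0))
        assert initial_e_ca(shifted) == pytest.approx(161.53, abs=0.01)

    def test_ca_in_never_perturbed(self, small_fixture):
        model, _, _ = small_fixture
        shifted = apply(model, PerturbationSpec(ca_out_factor=10.0))
        assert shifted.ca.pool.ca_rest == model.ca.pool.ca_rest

    def test_ca_shift_requires_calcium_model(self, oc_model):
        with pytest.raises(PerturbationError):
            apply(oc_model, PerturbationSpec(delta_e_ca=10.0))


class TestRelativeDifference:
    def _curve(self, freqs, di=0.01):
        n = len(freqs)
        return FICurve(currents=np.arange(n) * di, freqs=np.asarray(freqs, float), di=di)

    def test_identical_curves(self):
        a = self._curve([0, 10, 20, 30])
        assert relative_difference_at_max_common(a, a) == 0.0

    def test_scaled_by_0p62_gives_0p38(self):
        fa = np.array([0.0, 50.0, 80.0, 100.0])
        a = self._curve(fa)
        b = self._curve(fa * 0.62)
        assert relative_difference_at_max_common(a, b) == pytest.approx(0.38, abs=1e-12)

    def test_disjoint_ranges_error(self):
        a = self._curve([10.0, 20.0, 0.0, 0.0])
        b = self._curve([0.0, 0.0, 30.0, 40.0])
        # common grid points where both fire: none except index 1? a fires at
        # 0,1; b at 2,3 -> no overlap
        with pytest.raises(StatisticUndefinedError):
            relative_difference_at_max_common(a, b)

    def test_mismatched_grid_error(self):
        a = self._curve([0, 10], di=0.01)
        b = self._curve([0, 10], di=0.02)
        with pytest.raises(StatisticUndefinedError):
            relative_difference_at_max_common(a, b)

    def test_uses_largest_common_current(self):
        a = self._curve([0.0, 100.0, 100.0, 100.0])
        b = self._curve([0.0, 10.0, 50.0, 0.0])  # b blocks at the last point
        assert relative_difference_at_max_common(a, b) == pytest.approx(0.5)


class TestScan:
    def test_cm_scan_oc_threshold_invariant(self, oc_model):
        result = scan(oc_model, "cm", [1.0, 1.5], di=0.05, i_cap=0.1,
                      probes=(), threshold_resolution=0.001)
        th = [result.stats[lbl]["threshold_nA"] for lbl in result.stats]
        assert len(set(th)) == 1

    def test_out_of_range_factor_fails_fast(self, oc_model):
        with pytest.raises(PerturbationError):
            scan(oc_model, "conductance:na_hh", [0.2], di=0.05, i_cap=0.1, probes=())

    def test_reversal_scan_zero_shift_equals_baseline(self, oc_model):
        result = scan(oc_model, "reversal:na", [-20, -10, 0, 10, 20],
                      di=0.05, i_cap=0.1, probes=(), with_threshold=False)
        assert len(result.curves) == 5
        zero = [c for lbl, c in result.curves.items() if "+0mV" in lbl or "identity" in lbl]
        assert len(zero) == 1
        assert np.array_equal(zero[0].freqs, result.baseline.freqs)

    def test_tidy_output_schema(self, oc_model):
        result = scan(oc_model, "cm", [1.5], di=0.05, i_cap=0.1, probes=(),
                      with_threshold=False)
        df = result.tidy()
        assert set(df.columns) == {"model", "label", "axis", "value", "I_nA", "f_Hz"}
        assert (df["model"] == "OC").all()


class TestScenarios:
    def test_empty_scenario_list_baseline_only(self, oc_model):
        result = run_scenarios(oc_model, [], di=0.05, i_cap=0.1)
        assert result.curves == {}
        assert "baseline" in result.stats

    def test_fig6_config_parses_to_printed_values(self, small_fixture):
        model, _, _ = small_fixture
        cfg = load_scan_config("fig6")
        raw = cfg["scenarios"][0]
        assert raw["cm_factor"] == 1.5
        assert raw["reversals"]["na"] == 10
        from firesweep.perturbations import _spec_from_config

        spec = _spec_from_config(raw)
        shifted = apply(model, spec)
        assert shifted.placement("NaV").mech.erev == pytest.approx(63.0)
        ca_specs = [s for s in cfg["scenarios"] if "ca_out_factor" in s]
        assert ca_specs and all(s["ca_out_factor"] == 10.0 for s in ca_specs)
        assert initial_e_ca(apply(model, _spec_from_config(ca_specs[0]))) == pytest.approx(
            161.53, abs=0.01
        )

    def test_nested_depressive_scenarios_monotone(self, small_fixture):
        """Adding more depressive perturbations never decreases the relative
        firing-rate difference (nested scenario ordering on the fixture)."""
        model, _, _ = small_fixture
        specs = [
            PerturbationSpec(cm_factor=1.5, cm_region="sprx",
                             conductance_factors={"SK": 1.5}, label="weak"),
            PerturbationSpec(cm_factor=1.5, cm_region="sprx",
                             conductance_factors={"SK": 4.0, "Kv2like": 4.0},
                             label="strong"),
        ]
        result = run_scenarios(model, specs, di=0.1, i_cap=0.5)
        weak = result.stats["weak"]["rel_diff_vs_baseline"]
        strong = result.stats["strong"]["rel_diff_vs_baseline"]
        assert weak is not None and strong is not None
        assert strong >= weak


class TestConfigs:
    def test_all_bundled_configs_load(self):
        for name in ("fig2", "fig3", "fig4", "fig5", "fig6"):
            cfg = load_scan_config(name)
            assert cfg["name"] == name

    def test_unknown_config_field_rejected(self):
        with pytest.raises(PerturbationError):
            load_scan_config("name: x\nbogus_field: 1\n")

    def test_missing_config_file(self):
        with pytest.raises(FileNotFoundError):
            load_scan_config("no_such_config")

    def test_run_config_skips_inapplicable_axes(self, oc_model):
        cfg = load_scan_config("fig4")
        results = run_config(oc_model, cfg,
                             {"di": 0.05, "i_cap": 0.1, "probes": [],
                              "max_values_per_axis": 2, "disable_thresholds": True})
        gaps = [g for r in results for g in r.gaps]
        assert any("ca" in g for g in gaps)  # OC has no calcium reversal
        ran = [r for r in results if r.curves]
        assert len(ran) == 3  # na, k, leak axes
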