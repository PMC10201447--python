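"""Excluded volume, water activity, and condition composition."""

import math

import pytest

from crowdnn.crowding import (
    CrowdingError,
    Cosolute,
    SolutionCondition,
    compose_condition_parameters,
    delta_excluded_volume,
    ev_free_energy,
    excluded_volume_duplex,
    excluded_volume_generic,
    excluded_volume_per_nn,
    get_cosolute,
    m_cs_for,
    molality,
    peg_monomer_count,
    predict_in_condition,
    resolve_delta_aw,
    wa_contribution,
    water_activity_from_osmolality,
)
from crowdnn.sequences import DuplexSpec
from crowdnn.tables import FREE_PARAMETERS
from crowdnn.thermo import predict_duplex


class TestWaterActivity:
    def test_pure_water(self):
        assert water_activity_from_osmolality(0.0) == 1.0

    def test_one_osmolal_benchmark(self):
        aw = water_activity_from_osmolality(1000.0, 298.15)
        assert aw == pytest.approx(0.9820, abs=5e-4)
        # ideal-solution cross-check: a_w = exp(-0.018 * molality)
        assert aw == pytest.approx(math.exp(-0.018), abs=1e-3)

    def test_strictly_decreasing(self):
        vals = [water_activity_from_osmolality(o) for o in (0, 200, 500, 1500)]
        assert vals == sorted(vals, reverse=True)
        assert all(0 < v <= 1 for v in vals)

    def test_negative_rejected(self):
        with pytest.raises(CrowdingError):
            water_activity_from_osmolality(-1.0)


class TestMolality:
    def test_grams_per_100g_water_convention(self):
        assert molality(10, Cosolute("EG", 62.0)) == pytest.approx(1.613, abs=1e-3)
        assert molality(40, get_cosolute("PEG200")) == pytest.approx(2.0)
        assert molality(0, get_cosolute("PEG200")) == 0.0

    def test_peg_monomer_counts(self):
        assert peg_monomer_count(200.0) == 4
        assert get_cosolute("EG").n_monomers == 1
        assert get_cosolute("glycerol").n_monomers == 1


class TestExcludedVolume:
    def test_generic_unit_arithmetic(self):
        assert excluded_volume_generic(1, 1.0, 1.0) == pytest.approx(6.022e-4)

    def test_generic_linearity_in_k(self):
        v1 = excluded_volume_generic(3, 2.0, 1.5)
        assert excluded_volume_generic(3, 2.0, 3.0) == pytest.approx(2 * v1)

    def test_no_volume_change_no_effect(self):
        dv = delta_excluded_volume(2 * 0.7, 0.7)
        assert dv == 0.0
        assert ev_free_energy(dv, 2.0) == 0.0

    def test_printed_worked_example(self):
        # 11-mer in 10 wt% ethylene glycol
        C = molality(10, get_cosolute("EG"))
        assert excluded_volume_duplex(11, C, 1) == pytest.approx(-0.45, abs=0.005)

    def test_fig3_pipeline_inputs(self):
        C = molality(20, get_cosolute("EG"))
        assert excluded_volume_duplex(10, C, 1) == pytest.approx(-0.84, abs=0.005)

    def test_zero_concentration(self):
        assert excluded_volume_duplex(8, 0.0, 4) == 0.0

    def test_monotone_in_length_concentration_size(self):
        base = excluded_volume_duplex(8, 2.0, 4)
        assert excluded_volume_duplex(9, 2.0, 4) < base
        assert excluded_volume_duplex(8, 3.0, 4) < base
        assert excluded_volume_duplex(8, 2.0, 5) < base
        assert base < 0

    def test_warns_outside_fit_range(self):
        with pytest.warns(UserWarning, match="6-12"):
            excluded_volume_duplex(20, 2.0, 4)

    def test_per_nn_share(self):
        assert excluded_volume_per_nn(-0.45, 11) == pytest.approx(-0.0409, abs=5e-4)
        # length-averaged reference value for 40 wt% PEG200 (C*N = 8)
        shares = [
            excluded_volume_per_nn(excluded_volume_duplex(n, 2.0, 4), n)
            for n in range(6, 13)
        ]
        assert sum(shares) / len(shares) == pytest.approx(-0.22, abs=0.01)
        assert excluded_volume_per_nn(0.0, 9) == 0.0


class TestPrefactors:
    def test_wa_contribution_examples(self):
        assert wa_contribution(33.3, 0.0) == 0.0
        assert wa_contribution(33.3, 0.0489) == pytest.approx(1.63, abs=0.005)
        assert wa_contribution(13.7, 0.047) == pytest.approx(0.644, abs=0.001)

    def test_peg_class_uses_peg_column(self, decomp):
        m = m_cs_for(get_cosolute("PEG400"), decomp)
        assert m == decomp.m_peg_class

    def test_diol_class_scaled_by_slope_ratio(self, decomp):
        m = m_cs_for(get_cosolute("EG"), decomp)
        for q in FREE_PARAMETERS:
            assert m[q] == pytest.approx(0.411 * decomp.m_peg_class[q], abs=0.1)

    def test_custom_slope_ratio(self, decomp):
        cos = Cosolute("sorbitol", 182.0, 1, "custom", slope_ratio=0.5)
        m = m_cs_for(cos, decomp)
        assert m["initiation"] == pytest.approx(0.5 * 33.3)
        with pytest.raises(CrowdingError, match="slope_ratio"):
            m_cs_for(Cosolute("x", 100.0, 1, "custom"), decomp)

    def test_diol_destabilizes_less_than_peg(self, decomp):
        # equal delta_aw: diol-class wa terms are smaller in magnitude
        for q in FREE_PARAMETERS:
            m_peg = decomp.m_peg_class[q]
            m_diol = decomp.m_diol_class[q]
            assert abs(wa_contribution(m_diol, 0.05)) < abs(
                wa_contribution(m_peg, 0.05)
            )


class TestComposition:
    def test_reference_condition_reproduces_full_table(self, decomp, table1):
        """Bulk + cation(122) + ev + wa at 40 wt% PEG200 closes on Table 1."""
        sol = SolutionCondition(
            cosolute=get_cosolute("PEG200"), wt_pct=40, na_mM=122
        )
        for n_bp in range(6, 13):
            pset = compose_condition_parameters(decomp, sol, n_bp)
            for q in FREE_PARAMETERS:
                assert pset[q].dG37 == pytest.approx(
                    table1[q].dG37, abs=0.03
                ), (q, n_bp)

    def test_no_cosolute_is_bulk_plus_cation(self, decomp):
        sol = SolutionCondition(cosolute=None, na_mM=122)
        pset = compose_condition_parameters(decomp, sol, 8)
        for q in FREE_PARAMETERS:
            expected = decomp.dG_bulk[q] + decomp.dG_cation_122mM[q]
            assert pset[q].dG37 == pytest.approx(expected, abs=1e-12), q

    def test_bulk_only_at_10mM(self, decomp):
        sol = SolutionCondition(cosolute=None, na_mM=10)
        pset = compose_condition_parameters(decomp, sol, 8)
        assert pset["GC/CG"].dG37 == pytest.approx(decomp.dG_bulk["GC/CG"])

    def test_composed_set_is_dG_only(self, decomp):
        sol = SolutionCondition(cosolute=get_cosolute("EG"), wt_pct=20, delta_aw=0.047)
        pset = compose_condition_parameters(decomp, sol, 10)
        assert not pset.has_enthalpy
        t = predict_duplex(DuplexSpec("GGAUCGAUCC"), pset)
        assert not t.has_enthalpy

    def test_full_pipeline_self_complementary_ten_mer(self, decomp):
        """Composed prediction for GGAUCGAUCC in 122 mM Na+, 20 wt% EG."""
        sol = SolutionCondition(
            cosolute=get_cosolute("EG"), wt_pct=20, delta_aw=0.047, na_mM=122
        )
        t = predict_in_condition(DuplexSpec("GGAUCGAUCC"), sol, decomp)
        assert t.breakdown["symmetry"] == pytest.approx(0.43)
        assert t.dG37 == pytest.approx(-13.07, abs=0.02)

    def test_missing_delta_aw_is_error(self, decomp):
        sol = SolutionCondition(cosolute=get_cosolute("glycerol"), wt_pct=15)
        with pytest.raises(CrowdingError, match="delta_aw"):
            compose_condition_parameters(decomp, sol, 8)

    def test_bundled_lookup(self, decomp):
        sol = SolutionCondition(cosolute=get_cosolute("PEG200"), wt_pct=40)
        assert resolve_delta_aw(sol) == pytest.approx(0.0489)

    def test_unresolvable_cation_is_error(self, decomp):
        sol = SolutionCondition(cosolute=None, na_mM=55)
        with pytest.raises(Exception, match="refused|anchors"):
            compose_condition_parameters(decomp, sol, 8)
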