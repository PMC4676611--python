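"""Phenotype-switch probabilities and the per-step cell decision."""
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from myelosim.state import (CellAgent, CellType, CyclePhase, Grid,
                            ModelParameters, Phenotype)
from myelosim.intracellular import (LocalEnvironment, Outcome,
                                    advance_cell, apoptosis_probability,
                                    cell_cycle_gate, gc_apoptosis_rate,
                                    mm_apoptosis_rate,
                                    proliferation_probability)


class TestApoptosisProbability:
    def test_zero_hazard_gives_zero(self):
        assert apoptosis_probability(0.0, 2.0) == 0.0

    def test_huge_hazard_approaches_one(self):
        assert apoptosis_probability(1e6, 2.0) == pytest.approx(1.0)

    def test_closed_form_at_published_ob_rate(self):
        # hourly hazard 3.5e-2 over a 2 h step
        assert apoptosis_probability(3.5e-2, 2.0) == pytest.approx(
            1.0 - math.exp(-0.07), abs=1e-15)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            apoptosis_probability(-0.1, 2.0)


class TestDrugModulatedRates:
    def test_mm_rate_without_drug_is_basal_zero(self, table_params):
        assert mm_apoptosis_rate(0.0, table_params) == 0.0

    def test_mm_rate_half_saturates_at_threshold(self, table_params):
        expect = table_params.lambda0_mm + table_params.beta_mm_L / 2
        assert mm_apoptosis_rate(table_params.K_L_mm, table_params) == \
            pytest.approx(expect)

    def test_mm_rate_at_ten_thresholds(self, table_params):
        expect = table_params.beta_mm_L * 100.0 / 101.0
        assert mm_apoptosis_rate(10 * table_params.K_L_mm, table_params) == \
            pytest.approx(expect)

    def test_amplitude_binding_modes_swap_mm_amplitudes(self):
        sym = ModelParameters(beta_binding="symbols")
        lab = ModelParameters(beta_binding="labels")
        L = sym.K_L_mm
        assert mm_apoptosis_rate(L, sym) == pytest.approx(sym.beta_mm_L / 2)
        assert mm_apoptosis_rate(L, lab) == pytest.approx(lab.beta_mm_T / 2)

    def test_gc_rate_without_drug_is_basal(self, table_params):
        assert gc_apoptosis_rate(0.0, CellType.OB, table_params) == \
            pytest.approx(3.5e-2)

    def test_gc_rate_half_saturates_at_threshold(self, table_params):
        expect = table_params.lambda0_1 + table_params.beta1_GC / 2
        assert gc_apoptosis_rate(table_params.K_GC_1, CellType.OB,
                                 table_params) == pytest.approx(expect)

    def test_oc_gc_amplitude_zero_means_no_oc_kill(self, table_params):
        # the published OC amplitude is 0: glucocorticoids leave OCs alone
        for G in (0.0, 1.5e-6, 1.0, 1e3):
            assert gc_apoptosis_rate(G, CellType.OC, table_params) == 0.0

    def test_mm_target_rejected_for_gc(self, table_params):
        with pytest.raises(ValueError):
            gc_apoptosis_rate(1.0, CellType.MM, table_params)


class TestProliferation:
    def test_mm_basal_without_tnfa(self, table_params):
        env = LocalEnvironment()
        assert proliferation_probability(CellType.MM, env, table_params) == \
            pytest.approx(0.15)

    def test_oc_maximal_without_opg_rankl_inhibition(self, table_params):
        env = LocalEnvironment(o_rl=0.0)
        expect = table_params.P0_oc + table_params.P_pathway_oc
        assert proliferation_probability(CellType.OC, env, table_params) == \
            pytest.approx(expect)

    def test_ob_half_saturation_with_published_values(self, table_params):
        env = LocalEnvironment(ewnt=table_params.K_W)
        assert proliferation_probability(CellType.OB, env, table_params) == \
            pytest.approx(0.1 + 0.5)

    def test_result_clamped_to_unit_interval(self, table_params):
        # OB response saturates at 0.1 + 1.0 > 1 and must be clamped
        env = LocalEnvironment(ewnt=1e6)
        assert proliferation_probability(CellType.OB, env, table_params) == 1.0


class TestCellCycleGate:
    def test_certain_and_impossible_entry(self):
        assert cell_cycle_gate(1.0, 0.999999)
        assert not cell_cycle_gate(0.0, 0.0)

    def test_exhaustive_grid_fraction_matches_probability(self):
        grid = np.arange(0.0, 1.0, 0.01)
        frac = np.mean([cell_cycle_gate(0.6, u) for u in grid])
        assert frac == pytest.approx(0.60)

    def test_out_of_range_arguments_rejected(self):
        with pytest.raises(ValueError):
            cell_cycle_gate(1.2, 0.5)
        with pytest.raises(ValueError):
            cell_cycle_gate(0.5, 1.0)


@settings(max_examples=100, derandomize=True)
@given(conc=st.floats(0, 1e6, allow_nan=False),
       bump=st.floats(0, 1e6, allow_nan=False))
def test_hill_responses_are_monotone_bounded_probabilities(conc, bump):
    p = ModelParameters(beta_binding="symbols")
    # monotone non-decreasing in the stimulating ligand, bounded by
    # basal + amplitude
    assert mm_apoptosis_rate(conc, p) <= mm_apoptosis_rate(conc + bump, p) + 1e-12
    assert mm_apoptosis_rate(conc, p) <= p.lambda0_mm + p.beta_mm_L + 1e-12
    assert gc_apoptosis_rate(conc, CellType.OB, p) <= \
        gc_apoptosis_rate(conc + bump, CellType.OB, p) + 1e-12
    env_lo, env_hi = (LocalEnvironment(tnfa=conc, ewnt=conc, o_rl=conc),
                      LocalEnvironment(tnfa=conc + bump, ewnt=conc + bump,
                                       o_rl=conc + bump))
    for ct in (CellType.MM, CellType.OB):
        lo = proliferation_probability(ct, env_lo, p)
        hi = proliferation_probability(ct, env_hi, p)
        assert 0.0 <= lo <= 1.0 and lo <= hi + 1e-12
    # OC proliferation is non-increasing in the OPG:RANKL ratio
    assert proliferation_probability(CellType.OC, env_lo, p) >= \
        proliferation_probability(CellType.OC, env_hi, p) - 1e-12


def _lone_cell(cell_type=CellType.MM):
    g = Grid((5, 5, 5))
    cell = CellAgent(cell_type, (2, 2, 2))
    g.place(cell, (2, 2, 2))
    return g, cell


def _chooser_fixed(site):
    return lambda origin: site


class TestAdvanceCell:
    def test_apoptotic_cell_with_countdown_one_is_removed(self, rng,
                                                          table_params):
        _, cell = _lone_cell()
        cell.phenotype = Phenotype.APOPTOTIC
        cell.apoptosis_countdown = 1
        d = advance_cell(cell, LocalEnvironment(), table_params, rng,
                         _chooser_fixed(None))
        assert d.outcome == Outcome.APOPTOSE and d.remove

    def test_apoptosis_takes_ten_steps_from_entry(self, table_params):
        _, cell = _lone_cell()
        rng = np.random.default_rng(0)
        params = ModelParameters(beta_binding="symbols", lambda0_mm=1e9)
        d = advance_cell(cell, LocalEnvironment(), params, rng,
                         _chooser_fixed(None))
        assert d.outcome == Outcome.APOPTOSE and not d.remove
        removed_at = None
        for step_i in range(1, 12):
            d = advance_cell(cell, LocalEnvironment(), params, rng,
                             _chooser_fixed(None))
            if d.remove:
                removed_at = step_i
                break
        assert removed_at == 10

    def test_blocked_m_phase_cell_quiesces_and_retains_phase(self, rng,
                                                             table_params):
        _, cell = _lone_cell()
        cell.cycle_phase = CyclePhase.M
        cell.phenotype = Phenotype.PROLIFERATING
        params = ModelParameters(beta_binding="symbols", lambda0_mm=0.0)
        d = advance_cell(cell, LocalEnvironment(), params, rng,
                         _chooser_fixed(None))
        assert d.outcome == Outcome.QUIESCE
        assert cell.cycle_phase == CyclePhase.M

    def test_m_phase_cell_divides_into_offered_site(self, rng):
        _, cell = _lone_cell()
        cell.cycle_phase = CyclePhase.M
        params = ModelParameters(beta_binding="symbols")
        d = advance_cell(cell, LocalEnvironment(), params, rng,
                         _chooser_fixed((2, 2, 3)))
        assert d.outcome == Outcome.PROLIFERATE and d.site == (2, 2, 3)
        assert cell.cycle_phase == CyclePhase.G0G1  # parent re-enters

    def test_only_open_branch_is_migration(self, rng):
        params = ModelParameters(beta_binding="symbols", P0_mm=0.0,
                                 beta_mm_L=0.0, beta_mm_T=0.0)
        _, cell = _lone_cell()
        d = advance_cell(cell, LocalEnvironment(), params, rng,
                         _chooser_fixed((2, 2, 1)))
        assert d.outcome == Outcome.MIGRATE and d.site == (2, 2, 1)

    def test_interphase_clock_reaches_m_after_configured_steps(self):
        params = ModelParameters(beta_binding="symbols", P0_mm=1.0,
                                 cycle_steps_G0G1=2, cycle_steps_S=1,
                                 cycle_steps_G2=1)
        _, cell = _lone_cell()
        rng = np.random.default_rng(3)
        phases = []
        for _ in range(5):
            advance_cell(cell, LocalEnvironment(), params, rng,
                         _chooser_fixed(None))
            phases.append(cell.cycle_phase)
        # gate fires immediately (p=1); G0G1 x2, S, G2, then M
        assert phases == [CyclePhase.G0G1, CyclePhase.S, CyclePhase.G2,
                          CyclePhase.M, CyclePhase.M]

    def test_empirical_apoptosis_frequency_matches_hazard(self):
        params = ModelParameters(beta_binding="symbols", lambda0_mm=0.1)
        p_expect = 1.0 - math.exp(-0.1 * params.dt_hours)
        rng = np.random.default_rng(11)
        n, hits = 4000, 0
        for _ in range(n):
            _, cell = _lone_cell()
            d = advance_cell(cell, LocalEnvironment(), params, rng,
                             _chooser_fixed(None))
            hits += d.outcome == Outcome.APOPTOSE
        sigma = math.sqrt(p_expect * (1 - p_expect) / n)
        assert abs(hits / n - p_expect) < 3 * sigma
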