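"""Free-energy engine: standard values, reaction quotients, H2 analysis."""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from syntherm.thermo import (
    ACETATE_OXIDATION,
    ACETICLASTIC,
    HYDROGENOTROPHIC,
    SPECIES,
    ActivityError,
    CultureState,
    Reaction,
    ReactionMisuseError,
    SpeciesLookupError,
    delta_g,
    delta_g_standard,
    feasibility_window,
    ln_reaction_quotient,
    shift_h2,
    solve_h2_for_target,
)
from syntherm.units import ATM_PA, R_KJ

RT55 = R_KJ * 328.15


def independent_delta_g(reaction: Reaction, state: CultureState) -> float:
    """Term-by-term oracle sharing no code with the engine's Q routine.

    Evaluates sum nu_i * (dGf_i + R*T*ln a_i) directly, with activities
    written out explicitly per species.
    """
    activities = {
        "acetate": state.acetate,
        "bicarbonate": state.bicarbonate,
        "methane": state.p_ch4,
        "hydrogen": state.p_h2,
        "water": 1.0,
        "proton": 10.0 ** (7.0 - state.pH),
    }
    total = 0.0
    for name, coeff in reaction.stoichiometry.items():
        term = SPECIES[name].formation_energy
        if name != "water":  # water activity is 1; ln term vanishes
            term += R_KJ * state.temperature * math.log(activities[name])
        total += coeff * term
    return total


def random_states(n: int, seed: int) -> list[CultureState]:
    rng = np.random.default_rng(seed)
    return [
        CultureState(
            temperature=rng.uniform(290.0, 350.0),
            pH=rng.uniform(5.5, 8.5),
            acetate=rng.uniform(1e-4, 0.05),
            bicarbonate=rng.uniform(1e-4, 0.1),
            p_ch4=rng.uniform(1e-3, 1.0),
            p_h2=rng.uniform(1e-6, 1e-2),
        )
        for _ in range(n)
    ]


class TestStandardFreeEnergies:
    @pytest.mark.parametrize(
        "reaction, expected",
        [
            (ACETICLASTIC, -31.0),
            (ACETATE_OXIDATION, 104.6),
            (HYDROGENOTROPHIC, -135.6),
        ],
        ids=lambda r: getattr(r, "name", r),
    )
    def test_catabolic_reaction_dg0(self, reaction, expected):
        assert delta_g_standard(reaction) == pytest.approx(expected, abs=0.1)

    def test_syntrophic_sum_equals_aceticlastic(self):
        total = delta_g_standard(ACETATE_OXIDATION) + delta_g_standard(
            HYDROGENOTROPHIC
        )
        assert total == pytest.approx(delta_g_standard(ACETICLASTIC), abs=1e-9)

    def test_empty_reaction_is_zero(self):
        assert delta_g_standard(Reaction("noop", {})) == 0.0

    def test_missing_species_named_in_error(self):
        with pytest.raises(SpeciesLookupError, match="unobtainium"):
            Reaction("bad", {"unobtainium": 1})

    def test_unbalanced_reaction_rejected(self):
        with pytest.raises(ValueError, match="unbalanced"):
            Reaction("half", {"acetate": -1, "methane": 1})


class TestReactionQuotient:
    def test_standard_state_gives_zero(self):
        state = CultureState(
            acetate=1.0, bicarbonate=1.0, p_ch4=1.0, p_h2=1.0, pH=7.0
        )
        for rxn in (ACETICLASTIC, ACETATE_OXIDATION, HYDROGENOTROPHIC):
            assert ln_reaction_quotient(rxn, state) == pytest.approx(0.0, abs=1e-12)

    def test_aceticlastic_hand_value(self):
        state = CultureState(acetate=0.030, bicarbonate=0.001, p_ch4=0.1)
        # ln(0.001 * 0.1 / 0.030)
        assert ln_reaction_quotient(ACETICLASTIC, state) == pytest.approx(
            -5.704, abs=1e-3
        )

    def test_doubling_h2_adds_four_ln2_to_oxidation(self):
        state = CultureState(
            acetate=0.03, bicarbonate=0.01, p_ch4=0.1, p_h2=1e-4
        )
        doubled = replace(state, p_h2=2e-4)
        delta = ln_reaction_quotient(
            ACETATE_OXIDATION, doubled
        ) - ln_reaction_quotient(ACETATE_OXIDATION, state)
        assert delta == pytest.approx(4.0 * math.log(2.0), abs=1e-12)

    def test_zero_activity_names_species(self):
        state = CultureState(acetate=0.03, bicarbonate=0.01, p_ch4=0.1, p_h2=0.0)
        with pytest.raises(ActivityError, match="hydrogen"):
            ln_reaction_quotient(ACETATE_OXIDATION, state)

    def test_proton_term_tracks_ph(self):
        acidic = CultureState(
            acetate=0.03, bicarbonate=0.01, p_ch4=0.1, p_h2=1e-4, pH=6.0
        )
        neutral = replace(acidic, pH=7.0)
        delta = ln_reaction_quotient(
            ACETATE_OXIDATION, acidic
        ) - ln_reaction_quotient(ACETATE_OXIDATION, neutral)
        # one proton produced; activity convention 10**(7-pH)
        assert delta == pytest.approx(math.log(10.0), abs=1e-12)


class TestInSituDeltaG:
    def test_unit_activities_recover_dg0(self):
        state = CultureState(
            temperature=310.0, acetate=1.0, bicarbonate=1.0, p_ch4=1.0, p_h2=1.0
        )
        for rxn in (ACETICLASTIC, ACETATE_OXIDATION, HYDROGENOTROPHIC):
            assert delta_g(rxn, state).value == pytest.approx(
                delta_g_standard(rxn), abs=1e-9
            )

    def test_aceticlastic_worked_value(self):
        state = CultureState(acetate=0.030, bicarbonate=0.001, p_ch4=0.1)
        dg = delta_g(ACETICLASTIC, state)
        assert dg.value == pytest.approx(-46.6, abs=0.05)
        assert dg.feasible  # well below -20 kJ/mol

    def test_feasibility_flag_tracks_threshold(self):
        state = CultureState(acetate=0.030, bicarbonate=0.001, p_ch4=0.1)
        assert not delta_g(ACETICLASTIC, state, threshold=-50.0).feasible

    def test_additivity_identity_on_random_states(self):
        # SAOB + hydrogenotroph stoichiometries sum to the aceticlastic
        # reaction, so the free energies must too, state by state
        for state in random_states(1000, seed=42):
            lhs = (
                delta_g(ACETATE_OXIDATION, state).value
                + delta_g(HYDROGENOTROPHIC, state).value
            )
            rhs = delta_g(ACETICLASTIC, state).value
            assert abs(lhs - rhs) < 1e-9

    def test_matches_independent_term_by_term_oracle(self):
        for state in random_states(1000, seed=7):
            for rxn in (ACETICLASTIC, ACETATE_OXIDATION, HYDROGENOTROPHIC):
                assert delta_g(rxn, state).value == pytest.approx(
                    independent_delta_g(rxn, state), abs=1e-9
                )

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        h2_lo=st.floats(1e-6, 1e-3),
        factor=st.floats(1.1, 50.0),
        hco3_lo=st.floats(1e-4, 0.05),
    )
    def test_monotonicity_in_h2_and_bicarbonate(self, h2_lo, factor, hco3_lo):
        base = CultureState(
            acetate=0.03, bicarbonate=hco3_lo, p_ch4=0.1, p_h2=h2_lo
        )
        more_h2 = replace(base, p_h2=h2_lo * factor)
        more_hco3 = replace(base, bicarbonate=hco3_lo * factor)
        assert (
            delta_g(ACETATE_OXIDATION, more_h2).value
            > delta_g(ACETATE_OXIDATION, base).value
        )
        assert (
            delta_g(ACETATE_OXIDATION, more_hco3).value
            > delta_g(ACETATE_OXIDATION, base).value
        )
        assert (
            delta_g(HYDROGENOTROPHIC, more_h2).value
            < delta_g(HYDROGENOTROPHIC, base).value
        )
        assert delta_g(ACETICLASTIC, more_h2).value == pytest.approx(
            delta_g(ACETICLASTIC, base).value, abs=1e-12
        )


class TestH2Shift:
    def test_published_counterfactual(self):
        # -25.1 kJ/mol at 16.4 Pa shifted to 10 Pa at 55 degC
        shifted = shift_h2(-25.1, HYDROGENOTROPHIC, 16.4, 10.0, 328.15)
        assert shifted == pytest.approx(-19.7, abs=0.05)

    def test_identity_when_pressure_unchanged(self):
        assert shift_h2(-25.1, HYDROGENOTROPHIC, 16.4, 16.4, 328.15) == -25.1

    def test_round_trip(self):
        there = shift_h2(-25.1, ACETATE_OXIDATION, 16.4, 10.0, 328.15)
        back = shift_h2(there, ACETATE_OXIDATION, 10.0, 16.4, 328.15)
        assert back == pytest.approx(-25.1, abs=1e-12)

    def test_reaction_without_h2_rejected(self):
        with pytest.raises(ReactionMisuseError):
            shift_h2(-25.1, ACETICLASTIC, 16.4, 10.0, 328.15)


class TestSolveH2:
    @pytest.fixture()
    def state(self):
        return CultureState(
            acetate=0.02, bicarbonate=0.03, p_ch4=0.2, p_h2=2e-4
        )

    def test_round_trip_through_delta_g(self, state):
        for rxn in (ACETATE_OXIDATION, HYDROGENOTROPHIC):
            p_pa = solve_h2_for_target(rxn, state, -20.0)
            solved = replace(state, p_h2=p_pa / ATM_PA)
            assert delta_g(rxn, solved).value == pytest.approx(-20.0, abs=1e-9)

    def test_target_shift_doubles_pressure(self, state):
        p1 = solve_h2_for_target(ACETATE_OXIDATION, state, -20.0)
        p2 = solve_h2_for_target(
            ACETATE_OXIDATION, state, -20.0 + 4.0 * RT55 * math.log(2.0)
        )
        assert p2 / p1 == pytest.approx(2.0, rel=1e-12)

    def test_against_bisection_oracle(self, state):
        def oracle(target: float) -> float:
            lo, hi = 1e-3, 1e5  # Pa
            for _ in range(200):
                mid = math.sqrt(lo * hi)
                dg = delta_g(
                    HYDROGENOTROPHIC, replace(state, p_h2=mid / ATM_PA)
                ).value
                # hydrogenotrophic dG decreases with H2
                if dg > target:
                    lo = mid
                else:
                    hi = mid
            return math.sqrt(lo * hi)

        got = solve_h2_for_target(HYDROGENOTROPHIC, state, -20.0)
        assert got == pytest.approx(oracle(-20.0), rel=1e-9)

    def test_reaction_without_h2_rejected(self, state):
        with pytest.raises(ReactionMisuseError):
            solve_h2_for_target(ACETICLASTIC, state, -20.0)


class TestFeasibilityWindow:
    def test_endpoints_sit_on_threshold(self):
        state = CultureState(acetate=0.03, bicarbonate=0.005, p_ch4=0.05)
        w = feasibility_window(state, threshold=-20.0)
        for rxn, endpoint in (
            (HYDROGENOTROPHIC, w.h2_low),
            (ACETATE_OXIDATION, w.h2_high),
        ):
            at = replace(state, p_h2=endpoint / ATM_PA)
            assert delta_g(rxn, at).value == pytest.approx(-20.0, abs=1e-9)

    def test_bicarbonate_narrows_the_window(self):
        # HCO3- is a product of acetate oxidation (ceiling drops as
        # HCO3^-1/2) and a substrate of hydrogenotrophic methanogenesis
        # (floor drops more slowly, as HCO3^-1/4), so the log-width
        # shrinks as inorganic carbon accumulates
        lean = CultureState(acetate=0.03, bicarbonate=0.002, p_ch4=0.05)
        rich = replace(lean, bicarbonate=0.05)
        w_lean = feasibility_window(lean)
        w_rich = feasibility_window(rich)
        assert w_rich.h2_high < w_lean.h2_high
        assert w_rich.h2_low < w_lean.h2_low
        assert w_rich.log_width < w_lean.log_width
        ratio = w_rich.h2_high / w_lean.h2_high
        assert ratio == pytest.approx((0.002 / 0.05) ** 0.5, rel=1e-6)

    def test_high_co2_closes_window_while_aceticlastic_stays_feasible(self):
        # grid search over bicarbonate for a state where syntrophy is
        # infeasible but direct acetate cleavage still clears -20 kJ/mol:
        # the dominance-switch mechanism
        found = None
        for hco3 in np.logspace(-3, -0.5, 40):
            state = CultureState(
                acetate=0.03, bicarbonate=float(hco3), p_ch4=0.1, p_h2=2e-4
            )
            w = feasibility_window(state)
            if w.is_empty and delta_g(ACETICLASTIC, state).value < -20.0:
                found = state
                break
        assert found is not None
        assert feasibility_window(found).is_empty
        assert delta_g(ACETICLASTIC, found).feasible


class TestTemperatureCorrection:
    def test_correction_is_off_by_default_and_modest_when_on(self):
        state = CultureState(acetate=0.03, bicarbonate=0.01, p_ch4=0.1, p_h2=1e-4)
        plain = delta_g(ACETICLASTIC, state).value
        corrected = delta_g(ACETICLASTIC, state, temperature_correction=True).value
        assert plain != corrected
        # Gibbs-Helmholtz over a 30 K span moves dG0' by a few kJ at most
        assert abs(plain - corrected) < 10.0

    def test_correction_vanishes_at_reference_temperature(self):
        assert delta_g_standard(
            ACETICLASTIC, temperature=298.15
        ) == pytest.approx(delta_g_standard(ACETICLASTIC), abs=1e-12)
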