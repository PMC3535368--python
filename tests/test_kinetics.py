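"""Unit and property tests for the mass-action kinetic model."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ngbkin import kinetics
from ngbkin.errors import ConfigurationError, DomainError

from conftest import grid_scan_ligand_free


def _config(rates, total=1e-4, ligand=5e-4, duration=1000.0, n_out=11, **kw):
    iso = kinetics.IsomerSpec(label="A", total_conc=total, rates=rates, redox_tag="WT_ox")
    return kinetics.SimulationConfig(
        isomers=[iso], ligand_total=ligand, duration=duration,
        output_times=np.linspace(0.0, duration, n_out), **kw,
    )


class TestMassActionRHS:
    def test_all_hexa_with_closed_channel_is_stationary(self):
        """With k_minus_H = 0 and everything hexacoordinate, nothing moves."""
        rates = kinetics.RateConstants(k_H=5.0, k_minus_H=0.0, k_on_L=1.0, k_off_L=0.1)
        cfg = _config(rates)
        state = kinetics.SystemState(
            time=0.0,
            species={("WT_ox", "A"): kinetics.SpeciesConc(hexa=1e-4)},
            ligand_free=5e-4,
        )
        d = kinetics.mass_action_rhs(state, cfg)
        sc = d.species[("WT_ox", "A")]
        assert sc.hexa == sc.penta == sc.bound == 0.0
        assert d.ligand_free == 0.0

    def test_binding_term_is_mass_action(self):
        """d(bound)/dt = k_on * penta * L - k_off * bound."""
        rates = kinetics.RateConstants(k_H=2.0, k_minus_H=3.0, k_on_L=7.0, k_off_L=0.5)
        cfg = _config(rates)
        p, b, L = 3e-5, 2e-5, 4e-4
        state = kinetics.SystemState(
            time=0.0,
            species={("WT_ox", "A"): kinetics.SpeciesConc(hexa=5e-5, penta=p, bound=b)},
            ligand_free=L,
        )
        d = kinetics.mass_action_rhs(state, cfg)
        expected = rates.k_on_L * p * L - rates.k_off_L * b
        assert d.species[("WT_ox", "A")].bound == pytest.approx(expected, rel=1e-12)

    def test_conservation_by_construction(self):
        rates = kinetics.RateConstants(k_H=1.0, k_minus_H=2.0, k_on_L=5.0, k_off_L=0.3)
        cfg = _config(rates)
        state = kinetics.SystemState(
            time=0.0,
            species={("WT_ox", "A"): kinetics.SpeciesConc(hexa=4e-5, penta=1e-5, bound=5e-5)},
            ligand_free=3e-4,
        )
        d = kinetics.mass_action_rhs(state, cfg)
        sc = d.species[("WT_ox", "A")]
        assert sc.hexa + sc.penta + sc.bound == pytest.approx(0.0, abs=1e-18)
        assert d.ligand_free == pytest.approx(-sc.bound, rel=1e-12)

    def test_unknown_isomer_and_negative_concentration_errors(self):
        rates = kinetics.RateConstants(1.0, 1.0, 1.0)
        cfg = _config(rates)
        bad_key = kinetics.SystemState(
            time=0.0, species={("TM", "B"): kinetics.SpeciesConc(hexa=1e-5)}, ligand_free=0.0
        )
        with pytest.raises(ConfigurationError):
            kinetics.mass_action_rhs(bad_key, cfg)
        negative = kinetics.SystemState(
            time=0.0, species={("WT_ox", "A"): kinetics.SpeciesConc(hexa=-1e-9)}, ligand_free=0.0
        )
        with pytest.raises(DomainError):
            kinetics.mass_action_rhs(negative, cfg)


class TestEffectiveKobs:
    def test_no_histidine_trap_returns_kon(self):
        rates = kinetics.RateConstants(k_H=0.0, k_minus_H=4.0, k_on_L=3.3)
        assert kinetics.effective_kobs(rates) == pytest.approx(3.3)

    def test_arithmetic(self):
        rates = kinetics.RateConstants(k_H=2.0, k_minus_H=1.0, k_on_L=3.0)
        assert kinetics.effective_kobs(rates) == pytest.approx(1.0)

    def test_infinite_KH_is_domain_error(self):
        rates = kinetics.RateConstants(k_H=1.0, k_minus_H=0.0, k_on_L=3.0)
        with pytest.raises(DomainError):
            kinetics.effective_kobs(rates)

    @given(
        k_H=st.floats(0.01, 100.0),
        k_minus_H=st.floats(0.01, 100.0),
        k_on=st.floats(0.01, 100.0),
        bump=st.floats(0.01, 10.0),
    )
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_monotonicity(self, k_H, k_minus_H, k_on, bump):
        """k_obs strictly decreases in k_H and strictly increases in k_on_L."""
        base = kinetics.effective_kobs(kinetics.RateConstants(k_H, k_minus_H, k_on))
        more_trap = kinetics.effective_kobs(kinetics.RateConstants(k_H + bump, k_minus_H, k_on))
        faster_on = kinetics.effective_kobs(kinetics.RateConstants(k_H, k_minus_H, k_on + bump))
        assert more_trap < base < faster_on


class TestPseudoFirstOrder:
    def test_observed_time_constant_from_measured_rate(self):
        """k_obs = 1.75 M^-1 s^-1 at 500 uM ligand gives T near 19 min."""
        T_s = 1.0 / (1.75 * 500e-6)
        assert T_s == pytest.approx(1142.857, rel=1e-6)
        assert T_s / 60.0 == pytest.approx(19.05, abs=0.01)
        f = kinetics.pseudo_first_order_bound_fraction(1.75, 0.0, 500e-6, T_s, mode="paper")
        assert f == pytest.approx(1.0 - np.exp(-1.0), rel=1e-12)

    def test_zero_time_is_zero_in_both_modes(self):
        for mode in ("paper", "reversible"):
            assert kinetics.pseudo_first_order_bound_fraction(2.0, 0.1, 1e-3, 0.0, mode) == 0.0

    def test_reversible_reduces_to_paper_without_off_rate(self):
        t = np.linspace(0.0, 5000.0, 23)
        paper = kinetics.pseudo_first_order_bound_fraction(1.2, 0.0, 4e-4, t, "paper")
        rev = kinetics.pseudo_first_order_bound_fraction(1.2, 0.0, 4e-4, t, "reversible")
        np.testing.assert_allclose(rev, paper, rtol=1e-12)


class TestIntegrate:
    def test_matches_pseudo_first_order_in_rapid_preequilibrium(self, single_isomer_config):
        """Irreversible, excess ligand: ODE equals 1 - exp(-k_obs_eff*L*t) within 1%."""
        cfg = single_isomer_config
        iso = cfg.isomers[0]
        traj = kinetics.integrate(cfg, kinetics.initial_state(cfg))
        kobs = kinetics.effective_kobs(iso.rates)
        for state in traj[1:]:
            expected = kinetics.pseudo_first_order_bound_fraction(
                kobs, 0.0, cfg.ligand_total, state.time, mode="paper"
            )
            got = state.species[iso.key].bound / iso.total_conc
            assert got == pytest.approx(expected, rel=0.01, abs=1e-6)

    def test_zero_duration_returns_initial(self, single_isomer_config):
        cfg = single_isomer_config
        cfg = kinetics.SimulationConfig(
            isomers=cfg.isomers, ligand_total=cfg.ligand_total,
            duration=0.0, output_times=np.array([0.0]),
        )
        init = kinetics.initial_state(cfg)
        traj = kinetics.integrate(cfg, init)
        assert len(traj) == 1
        got = traj[0].species[cfg.isomers[0].key]
        want = init.species[cfg.isomers[0].key]
        assert (got.hexa, got.penta, got.bound) == (want.hexa, want.penta, want.bound)

    def test_long_time_state_matches_equilibrium_solver(self):
        """With k_off > 0 the trajectory relaxes to the coupled equilibrium."""
        r_a = kinetics.collapsed_rates(kobs=0.26, kd=153e-6, K_H=2.0)
        r_b = kinetics.collapsed_rates(kobs=0.12, kd=316e-6, K_H=2.0)
        isomers = [
            kinetics.IsomerSpec("A", 33.3e-6, r_a, "WT_red"),
            kinetics.IsomerSpec("B", 66.7e-6, r_b, "WT_red"),
        ]
        duration = 5e6  # ~ 60 days: far past the slowest relaxation
        cfg = kinetics.SimulationConfig(
            isomers=isomers, ligand_total=500e-6, duration=duration,
            output_times=np.array([0.0, duration]),
        )
        final = kinetics.integrate(cfg, kinetics.initial_state(cfg))[-1]
        eq = kinetics.solve_equilibrium(kinetics.induced_equilibrium_spec(cfg))
        assert final.ligand_free == pytest.approx(eq.ligand_free, rel=1e-3)
        for iso in isomers:
            assert final.species[iso.key].bound == pytest.approx(
                eq.bound["/".join(iso.key)], rel=1e-3
            )

    def test_conservation_along_trajectory(self):
        r = kinetics.collapsed_rates(kobs=1.75, kd=1e-4, K_H=9.0)
        cfg = _config(r, duration=20000.0, n_out=21)
        traj = kinetics.integrate(cfg, kinetics.initial_state(cfg))
        for state in traj:
            assert state.protein_total(("WT_ox", "A")) == pytest.approx(1e-4, rel=1e-8)
            assert state.ligand_total() == pytest.approx(5e-4, rel=1e-8)

    def test_deterministic(self, single_isomer_config):
        a = kinetics.integrate(single_isomer_config, kinetics.initial_state(single_isomer_config))
        b = kinetics.integrate(single_isomer_config, kinetics.initial_state(single_isomer_config))
        for sa, sb in zip(a, b):
            assert sa.ligand_free == sb.ligand_free
            for key in sa.species:
                assert sa.species[key].bound == sb.species[key].bound

    def test_reoxidation_transfers_between_redox_states(self):
        """Red-tagged protein drains into the matching ox species at 1/tau."""
        r = kinetics.RateConstants(k_H=0.0, k_minus_H=1.0, k_on_L=0.0, k_off_L=0.0)
        isomers = [
            kinetics.IsomerSpec("A", 1e-4, r, "WT_red"),
            kinetics.IsomerSpec("A", 1e-4, r, "WT_ox"),
        ]
        tau = 3600.0
        cfg = kinetics.SimulationConfig(
            isomers=isomers, ligand_total=0.0, duration=2 * tau,
            output_times=np.array([0.0, tau, 2 * tau]), reoxidation_tau=tau,
        )
        init = kinetics.initial_state(cfg, empty_keys=(("WT_ox", "A"),))
        traj = kinetics.integrate(cfg, init)
        red = traj[-1].protein_total(("WT_red", "A"))
        ox = traj[-1].protein_total(("WT_ox", "A"))
        assert red == pytest.approx(1e-4 * np.exp(-2.0), rel=1e-6)
        assert red + ox == pytest.approx(1e-4, rel=1e-8)

    def test_reoxidation_without_receiver_is_config_error(self):
        r = kinetics.RateConstants(0.0, 1.0, 0.0)
        with pytest.raises(ConfigurationError):
            kinetics.SimulationConfig(
                isomers=[kinetics.IsomerSpec("A", 1e-4, r, "WT_red")],
                ligand_total=0.0, duration=10.0, output_times=np.array([0.0, 10.0]),
                reoxidation_tau=3600.0,
            )


class TestSolveEquilibrium:
    def test_no_ligand_leaves_everything_free(self):
        spec = kinetics.EquilibriumSpec(species=[("x", 1e-4, 1e-5)], ligand_total=0.0)
        eq = kinetics.solve_equilibrium(spec)
        assert eq.ligand_free == 0.0
        assert eq.bound["x"] == 0.0

    def test_excess_ligand_isotherm(self):
        """Dilute protein in excess ligand follows L/(L+K_d)."""
        spec = kinetics.EquilibriumSpec(species=[("x", 1e-9, 2e-4)], ligand_total=5e-4)
        eq = kinetics.solve_equilibrium(spec)
        assert eq.bound["x"] / 1e-9 == pytest.approx(5e-4 / (5e-4 + 2e-4), rel=0.01)

    def test_against_dense_grid_scan(self):
        """Two competing isomers with ligand depletion: match the 10^6-point scan."""
        spec = kinetics.EquilibriumSpec(
            species=[("A", 33.3e-6, 153e-6), ("B", 66.7e-6, 316e-6)],
            ligand_total=500e-6,
        )
        eq = kinetics.solve_equilibrium(spec)
        oracle = grid_scan_ligand_free(spec, n_coarse=1_000_000, n_fine=10_000)
        assert eq.ligand_free == pytest.approx(oracle, rel=1e-4)
        # conservation closes
        total = eq.ligand_free + sum(eq.bound.values())
        assert total == pytest.approx(spec.ligand_total, rel=1e-9)

    @given(
        totals=st.lists(st.floats(1e-7, 1e-3), min_size=1, max_size=4),
        kds=st.lists(st.floats(1e-7, 1e-2), min_size=4, max_size=4),
        ligand=st.floats(1e-7, 1e-2),
    )
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_matches_grid_scan_property(self, totals, kds, ligand):
        species = [(f"s{i}", tot, kds[i]) for i, tot in enumerate(totals)]
        spec = kinetics.EquilibriumSpec(species=species, ligand_total=ligand)
        eq = kinetics.solve_equilibrium(spec)
        oracle = grid_scan_ligand_free(spec)
        assert eq.ligand_free == pytest.approx(oracle, rel=1e-4, abs=1e-12 * ligand)
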