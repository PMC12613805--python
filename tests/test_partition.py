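"""Competitive Langmuir-Freundlich partition: closed-form identities, the
2-D grid-refinement oracle, mass balance, and the self-consistent loop."""

import math

import numpy as np
import pytest

from lcdcc.nica import component_from_config
from lcdcc.partition import (PartitionError, SystemComposition, lf_isotherm,
                             self_consistent_solve, solve_binary_partition)

COMPS = {n: component_from_config(n) for n in ("HA", "FA")}


# ---------------------------------------------------------------------------
# single-component LF equation
# ---------------------------------------------------------------------------

def test_lf_langmuir_midpoint():
    assert lf_isotherm(1.0e4, 1.0, 1.0e-4) == pytest.approx(0.5)


def test_lf_zero_concentration():
    assert lf_isotherm(1.0e4, 0.5, 0.0) == 0.0


def test_lf_half_exponent():
    # (K phi)^q = 4^0.5 = 2 -> x/(1-x) = 2 -> x = 2/3
    assert lf_isotherm(4.0e4, 0.5, 1.0e-4) == pytest.approx(2.0 / 3.0)


def test_lf_validates_inputs():
    with pytest.raises(ValueError):
        lf_isotherm(-1.0, 0.5, 0.1)
    with pytest.raises(ValueError):
        lf_isotherm(1.0, 1.5, 0.1)
    with pytest.raises(ValueError):
        lf_isotherm(1.0, 0.5, 1.0)


# ---------------------------------------------------------------------------
# binary partition at fixed affinities (shared-denominator form)
# ---------------------------------------------------------------------------

def _grid_oracle(K, q, system, V, comps, n_rounds=11, n_grid=33):
    """Brute-force oracle over (phi_HA, phi_FA): nested 1-D grid
    refinements of the two LF residuals with mass balance substituted,
    independent of the solver's root-finding strategy."""
    S = system.surface_m2_m3
    cap = {n: min(system.total_kg_m3(n) / (S * V * comps[n].rho_p), 0.9999)
           for n in ("HA", "FA")}

    def lf_res(n, phi_n, phi_other):
        s = phi_n + phi_other
        if s >= 1.0:
            return np.inf
        C = system.total_kg_m3(n) - phi_n * V * comps[n].rho_p * S
        phi_sol = max(C, 0.0) / comps[n].rho_p
        rhs = (K[n] * phi_sol) ** q[n] if phi_sol > 0 else 0.0
        return phi_n / (1.0 - s) - rhs

    def refine_1d(fun, lo, hi):
        """Grid refinement of |fun| on [lo, hi]."""
        for _ in range(n_rounds):
            xs = np.linspace(lo, hi, n_grid)
            vals = [abs(fun(x)) for x in xs]
            i = int(np.argmin(vals))
            step = (hi - lo) / (n_grid - 1)
            lo = max(xs[i] - step, 0.0)
            hi = min(xs[i] + step, 0.9999)
        return 0.5 * (lo + hi)

    def phi_ha_given(phi_fa):
        return refine_1d(lambda x: lf_res("HA", x, phi_fa), 0.0, cap["HA"])

    phi_fa = refine_1d(lambda y: lf_res("FA", y, phi_ha_given(y)),
                       0.0, cap["FA"])
    return {"HA": phi_ha_given(phi_fa), "FA": phi_fa}


def test_degenerate_binary_equals_single_component():
    system = SystemComposition(HA_tot_mg_L=100.0, FA_tot_mg_L=0.0, pH=4.0)
    K = {"HA": 2.0e5, "FA": 1.0e5}
    q = {"HA": 0.1, "FA": 0.3}
    state = solve_binary_partition(K, q, system, 3e-9, COMPS)
    # same equation solved alone: x/(1-x) = (K phi_sol)^q with mass balance
    phi = state.phi_ads["HA"]
    rhs = (K["HA"] * state.phi_sol["HA"]) ** q["HA"]
    assert phi / (1 - phi) == pytest.approx(rhs, rel=1e-9)
    assert state.phi_ads["FA"] == 0.0


def test_symmetric_inputs_give_symmetric_state():
    comps = {"HA": COMPS["HA"], "FA": COMPS["HA"]}  # identical particles
    system = SystemComposition(HA_tot_mg_L=80.0, FA_tot_mg_L=80.0, pH=4.0)
    K = {"HA": 5.0e4, "FA": 5.0e4}
    q = {"HA": 0.4, "FA": 0.4}
    state = solve_binary_partition(K, q, system, 3e-9, comps)
    assert state.phi_ads["HA"] == pytest.approx(state.phi_ads["FA"], rel=1e-9)


def test_binary_agrees_with_grid_oracle_on_random_instances():
    """50 random instances against the 2-D grid-refinement oracle."""
    rng = np.random.default_rng(7)
    for _ in range(50):
        system = SystemComposition(
            HA_tot_mg_L=float(rng.uniform(10, 250)),
            FA_tot_mg_L=float(rng.uniform(10, 250)), pH=4.0)
        K = {"HA": float(10 ** rng.uniform(2, 6)),
             "FA": float(10 ** rng.uniform(2, 6))}
        q = {"HA": float(rng.uniform(0.1, 1.0)),
             "FA": float(rng.uniform(0.1, 1.0))}
        V = float(rng.uniform(0.8e-9, 3e-9))
        state = solve_binary_partition(K, q, system, V, COMPS)
        oracle = _grid_oracle(K, q, system, V, COMPS)
        for n in ("HA", "FA"):
            assert abs(state.phi_ads[n] - oracle[n]) < 1e-6


def test_q_one_reduces_to_competitive_langmuir():
    """q = 1 with abundant mass: phi_p = K_p c_p (1 - s) has the classical
    closed form phi_p = K_p c_p / (1 + sum K c)."""
    comps = {"HA": COMPS["HA"], "FA": COMPS["HA"]}  # equal V_i, rho
    system = SystemComposition(HA_tot_mg_L=4.0e5, FA_tot_mg_L=2.0e5, pH=4.0,
                               solid_g_L=1.0)
    # huge reservoirs: depletion negligible, phi_sol ~ total/rho
    K = {"HA": 800.0, "FA": 1500.0}
    q = {"HA": 1.0, "FA": 1.0}
    V = 3e-9
    state = solve_binary_partition(K, q, system, V, comps)
    x = {n: K[n] * system.total_kg_m3(n) / comps[n].rho_p for n in K}
    denom = 1.0 + x["HA"] + x["FA"]
    for n in ("HA", "FA"):
        assert state.phi_ads[n] == pytest.approx(x[n] / denom, rel=1e-3)


def test_mass_balance_exact_at_converged_states():
    system = SystemComposition(HA_tot_mg_L=120.0, FA_tot_mg_L=60.0, pH=4.0)
    K = {"HA": 1e5, "FA": 3e5}
    q = {"HA": 0.1, "FA": 0.3}
    state = solve_binary_partition(K, q, system, 2e-9, COMPS)
    S = system.surface_m2_m3
    for n in ("HA", "FA"):
        total = state.C[n] + state.Gamma[n] * S
        assert total == pytest.approx(system.total_kg_m3(n), rel=1e-12)


def test_infeasible_volume_raises():
    with pytest.raises(PartitionError):
        solve_binary_partition({"HA": 1.0, "FA": 1.0}, {"HA": 0.5, "FA": 0.5},
                               SystemComposition(HA_tot_mg_L=10.0, pH=4.0),
                               -1e-9, COMPS)


# ---------------------------------------------------------------------------
# self-consistent loop
# ---------------------------------------------------------------------------

def test_no_nom_reduces_to_bare_surface(calibrated_cfg):
    from lcdcc.goethite import default_sites, edl_from_config, \
        solve_surface_state

    state = self_consistent_solve(SystemComposition(pH=4.0), calibrated_cfg)
    bare = solve_surface_state(4.0, 0.01, None,
                               edl_from_config(calibrated_cfg),
                               default_sites(calibrated_cfg))
    for p in "012d":
        assert state.surface.psi[p] == pytest.approx(bare.psi[p], abs=1e-10)
    assert state.partition.Gamma == {"HA": 0.0, "FA": 0.0}


def test_single_fa_constant_volume_equals_variable(calibrated_cfg):
    sysc = SystemComposition(FA_tot_mg_L=100.0, pH=4.0)
    cfg_const = calibrated_cfg.updated({"V_constant_m3_m2": 0.8e-9})
    var = self_consistent_solve(sysc, calibrated_cfg, scenario="variable")
    const = self_consistent_solve(sysc, cfg_const, scenario="constant")
    assert var.partition.Gamma_mg_m2("FA") == pytest.approx(
        const.partition.Gamma_mg_m2("FA"), rel=1e-6)


def test_variable_volume_limits_ha_versus_constant(calibrated_cfg):
    """Space limitation: at a crowded binary point the variable-volume
    scenario predicts strictly less HA than the constant-volume one."""
    sysc = SystemComposition(HA_tot_mg_L=160.0, FA_tot_mg_L=200.0, pH=4.0)
    var = self_consistent_solve(sysc, calibrated_cfg, scenario="variable")
    const = self_consistent_solve(sysc, calibrated_cfg, scenario="constant")
    assert var.partition.Gamma_mg_m2("HA") < const.partition.Gamma_mg_m2("HA")


def test_warm_start_does_not_change_converged_state(calibrated_cfg):
    sysc = SystemComposition(HA_tot_mg_L=160.0, FA_tot_mg_L=100.0, pH=4.0)
    cold = self_consistent_solve(sysc, calibrated_cfg)
    other = self_consistent_solve(
        SystemComposition(HA_tot_mg_L=60.0, FA_tot_mg_L=40.0, pH=4.0),
        calibrated_cfg)
    warm = self_consistent_solve(sysc, calibrated_cfg, warm_state=other)
    for n in ("HA", "FA"):
        assert warm.partition.Gamma_mg_m2(n) == pytest.approx(
            cold.partition.Gamma_mg_m2(n), abs=5e-6)


def test_conditional_mode_pins_fixed_component(calibrated_cfg):
    sysc = SystemComposition(HA_tot_mg_L=160.0, FA_tot_mg_L=100.0, pH=4.0)
    state = self_consistent_solve(sysc, calibrated_cfg, mode="conditional",
                                  conditional_fixed={"FA": 0.6})
    assert state.partition.Gamma_mg_m2("FA") == pytest.approx(0.6, rel=1e-9)
    assert state.partition.Gamma_mg_m2("HA") > 0.0


def test_mass_conservation_through_full_solve(calibrated_cfg):
    sysc = SystemComposition(HA_tot_mg_L=160.0, FA_tot_mg_L=150.0, pH=6.0)
    state = self_consistent_solve(sysc, calibrated_cfg)
    S = sysc.surface_m2_m3
    for n in ("HA", "FA"):
        total = state.partition.C[n] + state.partition.Gamma[n] * S
        assert total == pytest.approx(sysc.total_kg_m3(n), rel=1e-12)
    assert abs(state.surface.electroneutrality()) < 1e-10


def test_adsorption_monotone_in_own_addition(calibrated_cfg):
    gammas = []
    warm = None
    for add in (40.0, 80.0, 120.0, 160.0):
        st = self_consistent_solve(
            SystemComposition(HA_tot_mg_L=add, FA_tot_mg_L=100.0, pH=4.0),
            calibrated_cfg, warm_state=warm)
        warm = st
        gammas.append(st.partition.Gamma_mg_m2("HA"))
    assert all(b >= a - 1e-9 for a, b in zip(gammas, gammas[1:]))


def test_adsorption_non_increasing_in_competitor_addition(calibrated_cfg):
    gammas = []
    warm = None
    for fa in (0.0, 60.0, 120.0, 200.0):
        st = self_consistent_solve(
            SystemComposition(HA_tot_mg_L=160.0, FA_tot_mg_L=fa, pH=4.0),
            calibrated_cfg, warm_state=warm)
        warm = st
        gammas.append(st.partition.Gamma_mg_m2("HA"))
    assert all(b <= a + 1e-9 for a, b in zip(gammas, gammas[1:]))
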