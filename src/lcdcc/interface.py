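"""Spatial distribution of adsorbed NOM over the Stern layers and the
d-plane, volume-fraction conversions, and the adsorption-volume rules for
the constant- and variable-volume scenarios.

An adsorbed component's functional groups are distributed over the first
Stern pair (fraction f_0+1), the second pair (f_1+2) and, for material in
excess of the Stern maximum, the d-plane (f_d).  The Stern occupation
maximum theta_s and the first-Stern share R respond to the potential
gradients in the compact layer through a pluggable regulator whose default
is a pair of logistic/sech functionals with a neutral point (theta_s = 1,
R = 1/2) at a flat potential profile.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

from .constants import FARADAY, GAS_R, T_DEFAULT
from .nica import NOMComponent


class InterfaceValidationError(ValueError):
    pass


class VolumeInfeasibleError(ValueError):
    """Adsorbed mass exceeds the available adsorption volume."""


@dataclass(frozen=True)
class InterfacialDistribution:
    f_0plus1: float
    f_1plus2: float
    f_d: float
    Gamma_tot: float = 0.0  # kg m-2
    Gamma_MST: float = 0.0  # kg m-2
    Gamma_MST_max: float = 0.0  # kg m-2, physical Stern maximum
    theta_s: float = 1.0
    R: float = 0.5

    def __post_init__(self) -> None:
        for name, f in (("f_0plus1", self.f_0plus1),
                        ("f_1plus2", self.f_1plus2), ("f_d", self.f_d)):
            if not -1e-12 <= f <= 1.0 + 1e-12:
                raise InterfaceValidationError(f"{name}={f} outside [0, 1]")
        if abs(self.f_0plus1 + self.f_1plus2 + self.f_d - 1.0) > 1e-9:
            raise InterfaceValidationError("distribution fractions must sum to 1")


@dataclass(frozen=True)
class AdsorptionVolume:
    V: float  # m3 m-2
    omega: dict  # relative adsorbed volume fraction per component
    V_i: dict  # per-component limiting volumes, m3 m-2
    scenario: str  # "constant" | "variable"


Regulator = Callable[[Mapping[str, float]], tuple[float, float]]


def excess_fraction(Gamma_tot: float, Gamma_MST: float) -> float:
    """Fraction of adsorbed material beyond the Stern maximum (d-plane).

    Piecewise: (Gamma_tot - Gamma_MST)/Gamma_tot above the maximum, zero
    below; continuous at the junction.
    """
    if Gamma_tot < 0 or Gamma_MST < 0:
        raise InterfaceValidationError("adsorbed amounts must be >= 0")
    if Gamma_tot <= Gamma_MST or Gamma_tot == 0.0:
        return 0.0
    return (Gamma_tot - Gamma_MST) / Gamma_tot


def mixing_volume(omega: Mapping[str, float] | Sequence[float],
                  V_i: Mapping[str, float] | Sequence[float]) -> float:
    """Adsorption volume of a mixed layer: V = sum_i omega_i V_i."""
    if isinstance(omega, Mapping):
        keys = list(omega)
        w = [omega[k] for k in keys]
        v = [V_i[k] for k in keys]
    else:
        w, v = list(omega), list(V_i)
    if abs(sum(w) - 1.0) > 1e-9:
        raise InterfaceValidationError(f"omega sums to {sum(w)}, not 1")
    return float(sum(wi * vi for wi, vi in zip(w, v)))


def volume_fraction_adsorbed(Gamma_p: float, V: float, rho_p: float,
                             tol: float = 1e-9) -> float:
    """phi_ads = Gamma / (V rho); 1 at complete filling of the layer."""
    if V <= 0 or rho_p <= 0:
        raise InterfaceValidationError("V and rho_p must be > 0")
    if Gamma_p < 0:
        raise InterfaceValidationError("Gamma must be >= 0")
    phi = Gamma_p / (V * rho_p)
    if phi > 1.0 + tol:
        raise VolumeInfeasibleError(
            f"adsorbed mass {Gamma_p} kg/m2 exceeds the available volume "
            f"(phi = {phi:.6g})"
        )
    return phi


def volume_fraction_solution(C_p: float, rho_p: float) -> float:
    """phi_sol = C / rho for a dissolved component (C in kg m-3)."""
    if rho_p <= 0:
        raise InterfaceValidationError("rho_p must be > 0")
    if C_p < 0:
        raise InterfaceValidationError("concentration must be >= 0")
    return C_p / rho_p


def default_regulator(alpha_R: float = 0.2, beta_theta: float = 0.05,
                      temperature: float = T_DEFAULT) -> Regulator:
    """Build the default conformation regulator.

    R follows a logistic in the first-Stern potential drop (psi0 - psi1),
    scaled by the thermal voltage, so an attractive gradient pulls the
    (negative) groups toward the surface; theta_s decays as a sech of the
    outer-Stern gradient.  Neutral point: flat profile -> (1, 1/2).
    """
    vt = GAS_R * temperature / FARADAY

    def regulator(psi: Mapping[str, float]) -> tuple[float, float]:
        d01 = (psi.get("0", 0.0) - psi.get("1", 0.0)) / vt
        d12 = (psi.get("1", 0.0) - psi.get("2", 0.0)) / vt
        # overflow-safe logistic and sech
        z = alpha_R * d01
        if z >= 0:
            R = 1.0 / (1.0 + math.exp(-min(z, 700.0)))
        else:
            ez = math.exp(max(z, -700.0))
            R = ez / (1.0 + ez)
        a = abs(beta_theta * d12)
        ea = math.exp(-min(a, 700.0))
        theta_s = 2.0 * ea / (1.0 + ea * ea)
        return theta_s, R

    return regulator


def regulate_distribution(plane_potentials: Mapping[str, float],
                          regulator: Regulator | None = None,
                          alpha_R: float = 0.2,
                          beta_theta: float = 0.05,
                          temperature: float = T_DEFAULT) -> tuple[float, float]:
    """(theta_s, R) for a potential profile; a pluggable override wins."""
    reg = regulator or default_regulator(alpha_R, beta_theta, temperature)
    theta_s, R = reg(plane_potentials)
    if not (0.0 <= theta_s <= 1.0 and 0.0 <= R <= 1.0):
        raise InterfaceValidationError(
            f"regulator returned out-of-range values ({theta_s}, {R})"
        )
    return theta_s, R


def electrolyte_layer_charge(psi_d: float, ionic_strength: float,
                             layer_thickness: float,
                             temperature: float = T_DEFAULT) -> float:
    """Electrolyte charge (C m-2) accumulated in the NOM-occupied region
    beyond the Stern layers, attributed to the d-plane.

    The region of thickness ``layer_thickness`` is assumed equilibrated
    with the bulk 1:1 electrolyte at the d-plane potential, so its net
    ion charge density is -2 F c sinh(F psi_d / RT); this countercharge
    screens the organic charge held outside the compact layer.
    """
    if layer_thickness <= 0.0:
        return 0.0
    RT = GAS_R * temperature
    x = min(max(FARADAY * psi_d / RT, -700.0), 700.0)
    c = ionic_strength * 1000.0  # mol m-3
    return -2.0 * FARADAY * c * layer_thickness * math.sinh(x)


def gamma_mst_max(component: NOMComponent, d_ST: float) -> float:
    """Physical Stern maximum (kg m-2): the component's limiting volume
    truncated at the Stern thickness, times its mass density."""
    return min(component.V_limit, d_ST) * component.rho_p


def build_distribution(
    Gamma_tot: float,
    component: NOMComponent,
    plane_potentials: Mapping[str, float],
    d_ST: float = 0.8e-9,
    regulator: Regulator | None = None,
    alpha_R: float = 0.2,
    beta_theta: float = 0.05,
    temperature: float = T_DEFAULT,
) -> InterfacialDistribution:
    """Distribution of one component at loading Gamma_tot (kg m-2)."""
    theta_s, R = regulate_distribution(plane_potentials, regulator,
                                       alpha_R, beta_theta, temperature)
    g_max = gamma_mst_max(component, d_ST)
    g_mst = theta_s * g_max
    fd = excess_fraction(Gamma_tot, g_mst)
    f01 = R * (1.0 - fd)
    f12 = (1.0 - R) * (1.0 - fd)
    return InterfacialDistribution(
        f_0plus1=f01, f_1plus2=f12, f_d=fd,
        Gamma_tot=Gamma_tot, Gamma_MST=min(Gamma_tot, g_mst),
        Gamma_MST_max=g_max, theta_s=theta_s, R=R,
    )


def build_joint_distributions(
    Gammas: Mapping[str, float],
    components: Mapping[str, NOMComponent],
    plane_potentials: Mapping[str, float],
    d_ST: float = 0.8e-9,
    regulator: Regulator | None = None,
    alpha_R: float = 0.2,
    beta_theta: float = 0.05,
    temperature: float = T_DEFAULT,
    size_preference: float = 1.0,
) -> dict[str, InterfacialDistribution]:
    """Distributions of co-adsorbed components sharing one Stern capacity.

    The Stern layers hold at most a volume theta_s * d_ST per unit area.
    When the combined demand of the adsorbed components exceeds that
    capacity, the space is allocated by weighted proportional sharing with
    weights (d_ST / V_limit)^size_preference: smaller particles sit closer
    to the surface and claim compact-layer space preferentially, crowding
    larger ones toward the d-plane.  size_preference = 0 recovers plain
    pro-rata sharing; large values approach strict small-first priority.
    With a single adsorbed component this reduces to the per-component
    distribution.
    """
    theta_s, R = regulate_distribution(plane_potentials, regulator,
                                       alpha_R, beta_theta, temperature)
    v_budget = theta_s * d_ST
    demand = {n: Gammas[n] / components[n].rho_p for n in Gammas}
    weight = {n: (d_ST / components[n].V_limit) ** size_preference
              for n in Gammas}
    # weighted water-filling: proportional claims, capped at demand, with
    # the surplus redistributed among still-hungry components
    alloc = {n: 0.0 for n in Gammas}
    remaining = v_budget
    hungry = [n for n in Gammas if demand[n] > 0.0]
    for _ in range(len(Gammas) + 1):
        if not hungry or remaining <= 0.0:
            break
        wsum = sum(weight[n] * demand[n] for n in hungry)
        if wsum <= 0.0:
            break
        filled = []
        for n in hungry:
            claim = remaining * weight[n] * demand[n] / wsum
            if claim >= demand[n] - alloc[n]:
                filled.append(n)
        if not filled:
            for n in hungry:
                alloc[n] += remaining * weight[n] * demand[n] / wsum
            remaining = 0.0
            break
        for n in filled:
            remaining -= demand[n] - alloc[n]
            alloc[n] = demand[n]
            hungry.remove(n)
    out: dict[str, InterfacialDistribution] = {}
    for name, g in Gammas.items():
        comp = components[name]
        v_cap = theta_s * min(comp.V_limit, d_ST)
        v_take = min(alloc[name], v_cap)
        g_mst = v_take * comp.rho_p
        fd = excess_fraction(g, g_mst)
        out[name] = InterfacialDistribution(
            f_0plus1=R * (1.0 - fd), f_1plus2=(1.0 - R) * (1.0 - fd),
            f_d=fd, Gamma_tot=g, Gamma_MST=min(g, g_mst),
            Gamma_MST_max=gamma_mst_max(comp, d_ST), theta_s=theta_s, R=R,
        )
    return out


def omega_shares(Gammas: Mapping[str, float], components: Mapping[str, NOMComponent],
                 mode: str = "volume") -> dict[str, float]:
    """Relative shares of the adsorbed phase per component.

    "volume" shares weight each component by its occupied volume
    Gamma_i / rho_i (the default, dimensionally consistent with the mixing
    rule); "mass" shares weight by Gamma_i directly.
    """
    if mode not in ("volume", "mass"):
        raise InterfaceValidationError(f"unknown omega share mode {mode!r}")
    weights = {}
    for name, g in Gammas.items():
        if g < 0:
            raise InterfaceValidationError("adsorbed amounts must be >= 0")
        weights[name] = g / components[name].rho_p if mode == "volume" else g
    total = sum(weights.values())
    if total <= 0.0:
        return {name: float("nan") for name in Gammas}
    return {name: w / total for name, w in weights.items()}


def adsorption_volume(
    Gammas: Mapping[str, float],
    components: Mapping[str, NOMComponent],
    scenario: str = "variable",
    V_constant: float = 3.0e-9,
    omega_mode: str = "volume",
) -> AdsorptionVolume:
    """Total adsorption volume under the chosen scenario.

    Scenario "constant" uses a fixed V; "variable" mixes the per-component
    limiting volumes with the current adsorbed shares.  With nothing
    adsorbed the variable volume defaults to the largest limiting volume
    (no constraint is active in an empty layer).
    """
    V_i = {name: c.V_limit for name, c in components.items()}
    if scenario == "constant":
        omega = omega_shares(Gammas, components, omega_mode)
        return AdsorptionVolume(V_constant, omega, V_i, scenario)
    if scenario != "variable":
        raise InterfaceValidationError(f"unknown scenario {scenario!r}")
    omega = omega_shares(Gammas, components, omega_mode)
    if any(math.isnan(w) for w in omega.values()):
        return AdsorptionVolume(max(V_i.values()), omega, V_i, scenario)
    V = mixing_volume(omega, V_i)
    return AdsorptionVolume(V, omega, V_i, scenario)
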