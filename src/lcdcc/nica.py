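"""Bimodal NICA proton binding of humic (HA) and fulvic (FA) acid
functional groups, with Boltzmann correction for groups residing at the
interfacial electrostatic planes.

Each component carries two continuous affinity distributions
(carboxylic-type and phenolic-type).  The proton occupancy of a
distribution with median affinity K and width exponent m at local proton
activity a is (K a)^m / (1 + (K a)^m); the net (negative) charge per unit
mass is the sum of the unprotonated site densities.  When a fraction of
the groups sits at an interfacial plane, its local proton activity is the
bulk activity times the Boltzmann factor exp(-F psi / RT).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

from .constants import FARADAY, GAS_R, T_DEFAULT
from .io_config import ModelConfig


class NICAValidationError(ValueError):
    """Invalid NICA input (non-positive activity, bad fractions, ...)."""


@dataclass(frozen=True)
class NICAParams:
    """Bimodal proton-binding parameters (mol kg-1, log10, widths in (0,1])."""

    Q1: float  # carboxylic-type site density, mol kg-1
    logK1: float
    m1: float
    Q2: float  # phenolic-type site density, mol kg-1
    logK2: float
    m2: float

    def __post_init__(self) -> None:
        if self.Q1 <= 0 or self.Q2 <= 0:
            raise NICAValidationError("site densities must be > 0")
        for m in (self.m1, self.m2):
            if not 0.0 < m <= 1.0:
                raise NICAValidationError(f"width exponent {m} outside (0, 1]")

    @property
    def Q_total(self) -> float:
        return self.Q1 + self.Q2


@dataclass(frozen=True)
class NOMComponent:
    """All component-specific parameters of one NOM class (HA or FA)."""

    name: str
    nica: NICAParams
    q: float  # particle-level heterogeneity exponent
    M_w_original: float  # kDa
    M_o: float  # kDa, most-preferred molar mass in adsorption
    k_fractionation: float  # kDa
    rho_p: float  # kg m-3
    V_limit: float  # m3 m-2, single-component limiting adsorption volume
    E_le: float = -500.0  # J per mol carboxylic group in the first Stern pair
    elec_coupling: float = 0.1  # plane-potential coupling of the particle charge
    E_rep: float = 0.0  # lateral repulsion, J kg-1 per mg m-2 total loading
    offset: float = 0.0  # calibrated particle free-energy offset, J mol-1

    def __post_init__(self) -> None:
        if not 0.0 < self.q <= 1.0:
            raise NICAValidationError(f"{self.name}: q={self.q} outside (0, 1]")
        if not 700.0 <= self.rho_p <= 1700.0:
            raise NICAValidationError(
                f"{self.name}: rho_p={self.rho_p} outside [700, 1700] kg m-3"
            )
        if self.V_limit <= 0:
            raise NICAValidationError(f"{self.name}: V_limit must be > 0")

    def with_offset(self, offset: float) -> "NOMComponent":
        return NOMComponent(self.name, self.nica, self.q, self.M_w_original,
                            self.M_o, self.k_fractionation, self.rho_p,
                            self.V_limit, self.E_le, self.elec_coupling,
                            self.E_rep, offset)


def component_from_config(name: str, config: ModelConfig | None = None) -> NOMComponent:
    cfg = config or ModelConfig()
    c = cfg["nom"][name]
    n = c["nica"]
    return NOMComponent(
        name=name,
        nica=NICAParams(n["Q1_mol_kg"], n["logK1"], n["m1"],
                        n["Q2_mol_kg"], n["logK2"], n["m2"]),
        q=c["q"],
        M_w_original=c["M_w_kDa"],
        M_o=c["M_o_kDa"],
        k_fractionation=c["k_kDa"],
        rho_p=c["rho_kg_m3"],
        V_limit=c["V_limit_m3_m2"],
        E_le=c["E_le_J_mol"],
        elec_coupling=c["elec_coupling"],
        E_rep=c["E_rep_J_kg_per_mg_m2"],
        offset=c["offset_J_mol"],
    )


def proton_occupancy(a_H_local: float, logK_tilde_H: float, m: float) -> float:
    """NICA proton occupancy of one distribution, in [0, 1]."""
    if a_H_local <= 0:
        raise NICAValidationError("proton activity must be > 0")
    if not 0.0 < m <= 1.0:
        raise NICAValidationError(f"width exponent {m} outside (0, 1]")
    lx = m * (logK_tilde_H * math.log(10.0) + math.log(a_H_local))
    if lx > 700.0:
        return 1.0
    x = math.exp(lx)
    return x / (1.0 + x)


def charge_at_activity(a_H_local: float, params: NICAParams) -> float:
    """Net charge (mol_c kg-1, negative) at a given local proton activity."""
    th1 = proton_occupancy(a_H_local, params.logK1, params.m1)
    th2 = proton_occupancy(a_H_local, params.logK2, params.m2)
    return -(params.Q1 * (1.0 - th1) + params.Q2 * (1.0 - th2))


def plane_weights(distribution, split_01: float = 0.5,
                  split_12: float = 0.5) -> dict[str, float]:
    """Fraction of the component's functional groups assigned to each plane.

    Groups in the 0+1 region split their charge between the 0- and 1-plane
    (share ``split_01`` on plane 0), groups in the 1+2 region between the
    1- and 2-plane, and the excess fraction sits wholly at the d-plane.
    """
    f01, f12, fd = distribution.f_0plus1, distribution.f_1plus2, distribution.f_d
    total = f01 + f12 + fd
    if abs(total - 1.0) > 1e-8:
        raise NICAValidationError(f"distribution fractions sum to {total}, not 1")
    return {
        "0": f01 * split_01,
        "1": f01 * (1.0 - split_01) + f12 * split_12,
        "2": f12 * (1.0 - split_12),
        "d": fd,
    }


def nom_charge_profile(
    pH: float,
    plane_potentials: Mapping[str, float],
    distribution,
    params: NOMComponent,
    split_01: float = 0.5,
    split_12: float = 0.5,
    temperature: float = T_DEFAULT,
) -> dict[str, float]:
    """Charge per plane (mol_c kg-1) for an adsorbed component.

    Each plane's share of the groups titrates against the local proton
    activity a_H * exp(-F psi_plane / RT).
    """
    a_H = 10.0 ** (-pH)
    RT = GAS_R * temperature
    w = plane_weights(distribution, split_01, split_12)
    out = {}
    for plane, weight in w.items():
        psi = float(plane_potentials.get(plane, 0.0))
        # clamp the Boltzmann exponent: root solvers probe extreme trial
        # potentials outside the physical range
        expo = min(max(-FARADAY * psi / RT, -700.0), 700.0)
        a_local = max(a_H * math.exp(expo), 1e-300)
        out[plane] = weight * charge_at_activity(a_local, params.nica)
    return out


def nom_charge_density(
    pH: float,
    plane_potentials: Mapping[str, float] | None,
    distribution,
    params: NOMComponent,
    split_01: float = 0.5,
    split_12: float = 0.5,
    temperature: float = T_DEFAULT,
) -> float:
    """Net charge of the component, mol_c kg-1 (negative).

    ``distribution="solution"`` (or None potentials) evaluates the
    dissolved component at the bulk proton activity.
    """
    if distribution == "solution" or distribution is None:
        return charge_at_activity(10.0 ** (-pH), params.nica)
    potentials = plane_potentials or {}
    profile = nom_charge_profile(pH, potentials, distribution, params,
                                 split_01, split_12, temperature)
    return sum(profile.values())
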