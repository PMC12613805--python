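"""CD-MUSIC surface speciation and multi-plane double-layer electrostatics
for goethite.

The surface is described with a 1-pK two-site model (singly coordinated
FeOH(-1/2) and triply coordinated Fe3O(-1/2) groups).  Protonation puts one
positive charge on the 0-plane; NaCl forms outer-sphere pairs whose ion
charge sits on the outermost Stern plane.  The compact layer is a chain of
parallel-plate capacitors:

    extended Stern:  0-plane --C1-- 1-plane --C2-- 2-plane --C3-- d-plane
    basic Stern:     0-plane --C1-- 1-plane --C3-- d-plane

followed by a Gouy-Chapman diffuse layer headed at the d-plane, so that
adsorbed organic-matter charge can be imposed on any of the four planes.
The equation system (mass action with Boltzmann factors, charge-potential
relations across the capacitors, diffuse-layer charge, global
electroneutrality) is solved for the plane potentials with a Powell-hybrid
root solver; every returned state is verified to satisfy electroneutrality
to better than 1e-10 C m-2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq, root

from .constants import EPS0, FARADAY, GAS_R
from .io_config import ModelConfig

PLANES = ("0", "1", "2", "d")

NomCharge = Mapping[str, float] | Callable[[dict[str, float]], Mapping[str, float]]


class SurfaceSolverError(RuntimeError):
    """Raised when the electrostatic solver does not converge.

    Carries the final residual vector (C m-2 per plane relation).
    """

    def __init__(self, message: str, residuals: np.ndarray | None = None):
        super().__init__(message)
        self.residuals = residuals


class ValidationError(ValueError):
    """Invalid physical input (non-positive capacitance, density, ...)."""


@dataclass(frozen=True)
class SurfaceSiteType:
    """A 1-pK surface hydroxyl type.

    Protonation S(-1/2) + H+ -> SH(+1/2) places +1 on the 0-plane; the
    electrolyte pairs SH...Cl and S...Na place -1/+1 on the outer Stern
    plane.  The plane charges of each reaction sum to its formal charge
    change by construction.
    """

    name: str
    density_nm2: float
    logK_H: float

    def __post_init__(self) -> None:
        if self.density_nm2 <= 0:
            raise ValidationError(f"site {self.name}: density must be > 0")


@dataclass(frozen=True)
class EDLConfig:
    """Compact-layer topology and solution-side parameters."""

    C1: float = 0.9  # F m-2, between 0- and 1-plane
    C2: float = 0.74  # F m-2, between 1- and 2-plane (extended Stern only)
    C3: float = 5.0  # F m-2, between outer Stern plane and d-plane
    stern: str = "extended"  # "extended" or "basic"
    d_ST: float = 0.8e-9  # m, Stern-layer thickness
    temperature: float = 295.15  # K
    specific_surface_area: float = 96.0  # m2 g-1
    eps_r: float = 78.54
    logK_Na: float = -1.0
    logK_Cl: float = -1.0

    def __post_init__(self) -> None:
        if min(self.C1, self.C2, self.C3) <= 0:
            raise ValidationError("Stern capacitances must be > 0")
        if self.d_ST <= 0:
            raise ValidationError("Stern thickness must be > 0")
        if self.stern not in ("extended", "basic"):
            raise ValidationError(f"unknown Stern topology {self.stern!r}")

    @property
    def plane_names(self) -> tuple[str, ...]:
        return ("0", "1", "2", "d") if self.stern == "extended" else ("0", "1", "d")

    @property
    def capacitances(self) -> tuple[float, ...]:
        if self.stern == "extended":
            return (self.C1, self.C2, self.C3)
        return (self.C1, self.C3)

    def plane_index(self, plane: str) -> int:
        """Map a logical plane label (0,1,2,d) to the topology's index.

        Under the basic-Stern topology the 2-plane coincides with the
        1-plane.
        """
        names = self.plane_names
        if plane in names:
            return names.index(plane)
        if plane == "2" and self.stern == "basic":
            return names.index("1")
        raise ValidationError(f"unknown plane {plane!r}")


def default_sites(config: ModelConfig | None = None) -> list[SurfaceSiteType]:
    cfg = config or ModelConfig()
    return [
        SurfaceSiteType(s["name"], s["density_nm2"], s["logK_H"])
        for s in cfg["surface"]["sites"]
    ]


def edl_from_config(config: ModelConfig | None = None) -> EDLConfig:
    cfg = config or ModelConfig()
    e, s = cfg["edl"], cfg["surface"]
    return EDLConfig(
        C1=e["C1_F_m2"], C2=e["C2_F_m2"], C3=e["C3_F_m2"], stern=e["stern"],
        d_ST=e["d_ST_m"], temperature=e["temperature_K"],
        specific_surface_area=e["area_m2_g"], eps_r=e["eps_r"],
        logK_Na=s["logK_Na"], logK_Cl=s["logK_Cl"],
    )


@dataclass
class SurfaceState:
    """Converged interfacial state of the oxide."""

    pH: float
    ionic_strength: float
    psi: dict[str, float]  # V per logical plane 0,1,2,d
    sigma: dict[str, float]  # C m-2 per plane, plus "dif" for the diffuse layer
    species_fractions: dict[str, dict[str, float]]
    residuals: np.ndarray
    converged: bool = True

    @property
    def net_surface_charge(self) -> float:
        """Charge inside the shear plane = -(diffuse charge), C m-2."""
        return -self.sigma["dif"]

    def electroneutrality(self) -> float:
        return sum(self.sigma.values())


# ---------------------------------------------------------------------------
# speciation and charge at given potentials
# ---------------------------------------------------------------------------

def _site_speciation(
    site: SurfaceSiteType,
    a_H: float,
    c_Na: float,
    c_Cl: float,
    psi0: float,
    psi_pair: float,
    edl: EDLConfig,
) -> dict[str, float]:
    """Equilibrium fractions of the four species of one site type."""
    RT = GAS_R * edl.temperature
    LN10 = math.log(10.0)

    def safe_exp(x: float) -> float:
        return math.exp(min(max(x, -700.0), 700.0))

    e0 = -FARADAY * psi0 / RT
    ep = -FARADAY * psi_pair / RT
    ln_aH = math.log(a_H)
    f_SH = safe_exp(site.logK_H * LN10 + ln_aH + e0)
    f_SHCl = safe_exp((site.logK_H + edl.logK_Cl) * LN10 + ln_aH
                      + math.log(c_Cl) + e0 - ep)
    f_SNa = safe_exp(edl.logK_Na * LN10 + math.log(c_Na) + ep)
    denom = 1.0 + f_SH + f_SHCl + f_SNa
    return {
        "S": 1.0 / denom,
        "SH": f_SH / denom,
        "SH.Cl": f_SHCl / denom,
        "S.Na": f_SNa / denom,
    }


def _surface_charges(
    sites: Sequence[SurfaceSiteType],
    a_H: float,
    ionic_strength: float,
    psi0: float,
    psi_pair: float,
    edl: EDLConfig,
) -> tuple[float, float, dict[str, dict[str, float]]]:
    """(sigma_0, sigma_pair_plane, fractions) from proton + pair speciation."""
    sigma0 = 0.0
    sigma_pair = 0.0
    fractions: dict[str, dict[str, float]] = {}
    for site in sites:
        th = _site_speciation(site, a_H, ionic_strength, ionic_strength,
                              psi0, psi_pair, edl)
        ns = site.density_nm2 * 1e18 / 6.02214076e23  # mol sites m-2
        # base charge -1/2 on the 0-plane; protonation adds +1 there
        sigma0 += ns * FARADAY * (-0.5 + th["SH"] + th["SH.Cl"])
        sigma_pair += ns * FARADAY * (th["S.Na"] - th["SH.Cl"])
        fractions[site.name] = th
    return sigma0, sigma_pair, fractions


def diffuse_charge(psi_d: float, ionic_strength: float, edl: EDLConfig) -> float:
    """Gouy-Chapman diffuse-layer charge for a 1:1 electrolyte, C m-2."""
    RT = GAS_R * edl.temperature
    pref = math.sqrt(8.0 * EPS0 * edl.eps_r * RT * ionic_strength * 1000.0)
    x = min(max(FARADAY * psi_d / (2.0 * RT), -700.0), 700.0)
    return -pref * math.sinh(x)


def _resolve_nom(nom: NomCharge | None, psi: dict[str, float]) -> dict[str, float]:
    if nom is None:
        return {p: 0.0 for p in PLANES}
    charges = nom(psi) if callable(nom) else nom
    out = {p: 0.0 for p in PLANES}
    for plane, value in charges.items():
        if plane not in PLANES:
            raise ValidationError(f"unknown NOM charge plane {plane!r}")
        out[plane] = float(value)
    return out


def _residuals(
    x: np.ndarray,
    pH: float,
    ionic_strength: float,
    nom: NomCharge | None,
    edl: EDLConfig,
    sites: Sequence[SurfaceSiteType],
) -> np.ndarray:
    names = edl.plane_names
    psi_logical = {p: x[edl.plane_index(p)] for p in PLANES}
    a_H = 10.0 ** (-pH)
    sig_nom = _resolve_nom(nom, psi_logical)

    psi_pair = psi_logical["2"]  # alias -> 1-plane under basic Stern
    sigma0_surf, sigma_pair, _ = _surface_charges(
        sites, a_H, ionic_strength, psi_logical["0"], psi_pair, edl
    )
    # charge per topological plane
    sigma = [0.0] * len(names)
    sigma[edl.plane_index("0")] += sigma0_surf + sig_nom["0"]
    sigma[edl.plane_index("1")] += sig_nom["1"]
    sigma[edl.plane_index("2")] += sigma_pair + sig_nom["2"]
    sigma[edl.plane_index("d")] += sig_nom["d"]

    caps = edl.capacitances
    res = np.empty(len(names))
    cum = 0.0
    for k in range(len(names) - 1):
        cum += sigma[k]
        res[k] = cum - caps[k] * (x[k] - x[k + 1])
    res[-1] = cum + sigma[-1] + diffuse_charge(x[-1], ionic_strength, edl)
    return res


def solve_surface_state(
    pH: float,
    ionic_strength: float,
    nom_plane_charges: NomCharge | None = None,
    edl: EDLConfig | None = None,
    sites: Sequence[SurfaceSiteType] | None = None,
    x0: np.ndarray | None = None,
    tol: float = 1e-12,
) -> SurfaceState:
    """Solve the full interfacial equation system at one solution condition.

    ``nom_plane_charges`` is either a fixed mapping plane -> C m-2 or a
    callable of the plane potentials returning such a mapping (used by the
    self-consistent loop so that the organic charge regulates with the
    potentials inside the solve).
    """
    if not (2.0 <= pH <= 12.0):
        raise ValidationError(f"pH {pH} outside the supported range [2, 12]")
    if ionic_strength <= 0:
        raise ValidationError("ionic strength must be > 0")
    edl = edl or EDLConfig()
    sites = list(sites) if sites is not None else default_sites()

    n = len(edl.plane_names)
    if x0 is None:
        mean_logK = float(np.mean([s.logK_H for s in sites]))
        psi_guess = max(-0.25, min(0.25, 0.0592 * (mean_logK - pH)))
        x0 = psi_guess * np.linspace(1.0, 0.3, n)
    x0 = np.asarray(x0, dtype=float)[:n]

    args = (pH, ionic_strength, nom_plane_charges, edl, sites)

    def attempt(guess: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        sol = root(_residuals, guess, args=args, method="hybr", tol=tol)
        xx = sol.x
        rr = _residuals(xx, *args)
        if np.max(np.abs(rr)) > 1e-10:
            sol = root(_residuals, xx, args=args, method="lm", tol=1e-14)
            xx = sol.x
            rr = _residuals(xx, *args)
        return xx, rr

    x, res = attempt(x0)
    if np.max(np.abs(res)) > 1e-10:
        for guess in (np.zeros(n), -0.1 * np.ones(n), 0.1 * np.ones(n)):
            x_try, res_try = attempt(guess)
            if np.max(np.abs(res_try)) <= 1e-10:
                x, res = x_try, res_try
                break
    if np.max(np.abs(res)) > 1e-10 and nom_plane_charges is not None:
        # homotopy: ramp the imposed organic charge up from the bare oxide
        def scaled(factor: float):
            if callable(nom_plane_charges):
                return lambda psi: {p: factor * c for p, c
                                    in nom_plane_charges(psi).items()}
            return {p: factor * c for p, c in nom_plane_charges.items()}

        xx, ok = x0, False
        for factor in (0.0, 0.2, 0.4, 0.6, 0.8, 0.9, 1.0):
            sub_args = (pH, ionic_strength, scaled(factor), edl, sites)
            sol = root(_residuals, xx, args=sub_args, method="hybr", tol=tol)
            xx = sol.x
            ok = np.max(np.abs(_residuals(xx, *sub_args))) <= 1e-9
        if ok:
            x, res = attempt(xx)
    if np.max(np.abs(res)) > 1e-10:
        raise SurfaceSolverError(
            f"surface solver did not converge at pH={pH}, I={ionic_strength}: "
            f"max residual {np.max(np.abs(res)):.3e} C m-2",
            residuals=res,
        )

    psi = {p: float(x[edl.plane_index(p)]) for p in PLANES}
    a_H = 10.0 ** (-pH)
    sig_nom = _resolve_nom(nom_plane_charges, psi)
    sigma0_surf, sigma_pair, fractions = _surface_charges(
        sites, a_H, ionic_strength, psi["0"], psi["2"], edl
    )
    sigma = {
        "0": sigma0_surf + sig_nom["0"],
        "1": sig_nom["1"],
        "2": sigma_pair + sig_nom["2"],
        "d": sig_nom["d"],
        "dif": diffuse_charge(psi["d"], ionic_strength, edl),
    }
    if edl.stern == "basic":
        # plane 2 is an alias of plane 1: report its charge on plane 1
        sigma["1"] += sigma.pop("2")
        sigma["2"] = 0.0
    return SurfaceState(pH, ionic_strength, psi, sigma, fractions, res)


def solve_surface_state_bisection(
    pH: float,
    ionic_strength: float,
    edl: EDLConfig | None = None,
    sites: Sequence[SurfaceSiteType] | None = None,
) -> SurfaceState:
    """Independent nested-bisection solution of the bare-oxide system.

    Used as an oracle: for a bare surface the capacitor chain propagates a
    trial psi_0 outward in closed form, leaving a single monotone residual
    (total charge + diffuse charge) that is bracketed and bisected.
    """
    edl = edl or EDLConfig()
    sites = list(sites) if sites is not None else default_sites()
    a_H = 10.0 ** (-pH)

    def chain(psi0: float) -> tuple[float, dict[str, float], dict[str, float]]:
        # The proton charge sigma0 depends on the pair-plane potential
        # through the SH.Cl species, so the inner unknown is the pair-plane
        # potential itself, located by bisection of the outer-Stern
        # capacitor relation (monotone increasing in that potential).
        if edl.stern == "extended":
            def inner(psi2: float) -> float:
                # second capacitor relation: sigma0 = C2 (psi1 - psi2),
                # with psi1 fixed by the first relation
                s0, _, _ = _surface_charges(sites, a_H, ionic_strength,
                                            psi0, psi2, edl)
                psi1 = psi0 - s0 / edl.C1
                return s0 - edl.C2 * (psi1 - psi2)
            lo_i, hi_i = psi0 - 2.0, psi0 + 2.0
            for _ in range(200):
                mid = 0.5 * (lo_i + hi_i)
                if inner(mid) > 0:
                    hi_i = mid
                else:
                    lo_i = mid
            psi2 = 0.5 * (lo_i + hi_i)
            sigma0, sigma_pair, frac = _surface_charges(
                sites, a_H, ionic_strength, psi0, psi2, edl
            )
            psi1 = psi0 - sigma0 / edl.C1
            psid = psi2 - (sigma0 + sigma_pair) / edl.C3
            psi = {"0": psi0, "1": psi1, "2": psi2, "d": psid}
        else:
            def inner_b(psi1: float) -> float:
                s0, _, _ = _surface_charges(sites, a_H, ionic_strength,
                                            psi0, psi1, edl)
                return s0 - edl.C1 * (psi0 - psi1)
            lo_i, hi_i = psi0 - 2.0, psi0 + 2.0
            for _ in range(200):
                mid = 0.5 * (lo_i + hi_i)
                if inner_b(mid) > 0:
                    hi_i = mid
                else:
                    lo_i = mid
            psi1 = 0.5 * (lo_i + hi_i)
            sigma0, sigma_pair, frac = _surface_charges(
                sites, a_H, ionic_strength, psi0, psi1, edl
            )
            psid = psi1 - (sigma0 + sigma_pair) / edl.C3
            psi = {"0": psi0, "1": psi1, "2": psi1, "d": psid}
        sigma = {"0": sigma0, "1": 0.0, "2": sigma_pair, "d": 0.0,
                 "dif": diffuse_charge(psi["d"], ionic_strength, edl)}
        return sigma0 + sigma_pair + sigma["dif"], psi, sigma

    lo, hi = -1.5, 1.5
    flo = chain(lo)[0]
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        fmid = chain(mid)[0]
        if (fmid > 0) == (flo > 0):
            lo, flo = mid, fmid
        else:
            hi = mid
    psi0 = 0.5 * (lo + hi)
    _, psi, sigma = chain(psi0)
    a_H = 10.0 ** (-pH)
    _, _, frac = _surface_charges(sites, a_H, ionic_strength, psi["0"], psi["2"], edl)
    return SurfaceState(pH, ionic_strength, psi, sigma, frac,
                        np.zeros(len(edl.plane_names)))


def compute_pzc(
    edl: EDLConfig | None = None,
    sites: Sequence[SurfaceSiteType] | None = None,
    ionic_strength: float = 0.01,
    pH_range: tuple[float, float] = (3.0, 12.0),
) -> float:
    """pH of zero net surface charge, by bracketed root finding."""
    edl = edl or EDLConfig()
    sites = list(sites) if sites is not None else default_sites()

    def net(pH: float) -> float:
        return solve_surface_state(pH, ionic_strength, None, edl, sites).net_surface_charge

    lo, hi = pH_range
    f_lo, f_hi = net(lo), net(hi)
    if f_lo * f_hi > 0:
        raise SurfaceSolverError(
            f"no zero-charge crossing between pH {lo} and {hi}"
        )
    return float(brentq(net, lo, hi, xtol=1e-10))


def charging_curve(
    pH_grid: Sequence[float],
    ionic_strength: float,
    edl: EDLConfig | None = None,
    sites: Sequence[SurfaceSiteType] | None = None,
) -> pd.DataFrame:
    """Charging curve over a monotone pH grid; one converged state per row."""
    grid = np.asarray(pH_grid, dtype=float)
    if grid.size > 1 and not (np.all(np.diff(grid) > 0) or np.all(np.diff(grid) < 0)):
        raise ValidationError("pH grid must be monotone")
    rows = []
    x0 = None
    for pH in grid:
        try:
            st = solve_surface_state(pH, ionic_strength, None, edl, sites, x0=x0)
        except SurfaceSolverError as exc:
            raise SurfaceSolverError(f"charging curve failed at pH {pH}: {exc}",
                                     residuals=exc.residuals) from exc
        x0 = np.array([st.psi[p] for p in (edl or EDLConfig()).plane_names])
        rows.append({
            "pH": pH,
            "sigma0": st.sigma["0"], "sigma1": st.sigma["1"],
            "sigma2": st.sigma["2"], "sigmad": st.sigma["dif"],
            "psi0": st.psi["0"], "psi1": st.psi["1"],
            "psi2": st.psi["2"], "psid": st.psi["d"],
        })
    return pd.DataFrame(rows)
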