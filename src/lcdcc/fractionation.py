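"""Adsorptive molecular fractionation.

Because high-affinity (low-molar-mass) humic particles adsorb
preferentially, the mean molar mass of the adsorbed HA pool depends on the
fraction of the added HA that remains in solution:

    M_w = M_o + k * (1 - rho_ssr * C_HA / HA_tot)            [kDa]

with M_o the molar mass of the most-preferred particles (1.6 kDa for this
HA), k the fractionation factor and rho_ssr the solution-to-solid ratio
(L g-1).  With everything adsorbed the pool carries the original mean
(M_o + k = 17 kDa); with nothing adsorbed the marginal adsorbate is the
most-preferred material.  Fulvic acid shows no measurable fractionation
(k ~ 0), so its adsorbed pool keeps the original 1.8 kDa.

For binary layers the mixture mean is mass-weighted,
M_w_mix = M_w_HA * phi_HA + M_w_FA * (1 - phi_HA), which is inverted to
recover the adsorbed-HA molar mass from a measured mixture mean.
"""

from __future__ import annotations

from dataclasses import dataclass


class FractionationError(ValueError):
    pass


@dataclass(frozen=True)
class FractionationParams:
    """Molar-mass bookkeeping constants (all kDa)."""

    M_o: float = 1.6
    k: float = 15.4
    M_w_FA: float = 1.8
    M_w_HA_original: float = 17.0

    def __post_init__(self) -> None:
        if self.M_o <= 0:
            raise FractionationError("M_o must be > 0")
        if self.k < 0:
            raise FractionationError("k must be >= 0")


def mw_adsorbed_ha(C_HA: float, HA_tot: float, ssr: float, params) -> float:
    """Mean molar mass (kDa) of the adsorbed HA pool.

    ``C_HA`` is the solution concentration (mg L-1), ``HA_tot`` the total
    addition on the solid basis (mg g-1), ``ssr`` the solution-to-solid
    ratio (L g-1).  ``params`` may be a :class:`FractionationParams` or any
    object with ``M_o`` and a fractionation factor (``k`` or
    ``k_fractionation``).  The result is clamped to [M_o, M_o + k].
    """
    if HA_tot <= 0:
        raise FractionationError("HA_tot must be > 0")
    if C_HA < 0:
        raise FractionationError("C_HA must be >= 0")
    if ssr * C_HA > HA_tot * (1.0 + 1e-9):
        raise FractionationError(
            "solution holds more HA than was added (negative adsorption)"
        )
    M_o = params.M_o
    k = getattr(params, "k", None)
    if k is None:
        k = params.k_fractionation
    mw = M_o + k * (1.0 - ssr * C_HA / HA_tot)
    return min(max(mw, M_o), M_o + k)


def mw_mixture(M_w_HA: float, M_w_FA: float, phi_frac_HA: float) -> float:
    """Mass-weighted mean molar mass of a mixed adsorbed layer (kDa)."""
    if not 0.0 <= phi_frac_HA <= 1.0:
        raise FractionationError("phi_frac_HA must be in [0, 1]")
    return M_w_HA * phi_frac_HA + M_w_FA * (1.0 - phi_frac_HA)


def invert_mw_ha(M_w_mix: float, phi_frac_HA: float, M_w_FA: float) -> float:
    """Adsorbed-HA molar mass from a measured mixture mean (exact inverse
    of :func:`mw_mixture`)."""
    if phi_frac_HA <= 0.0:
        raise FractionationError(
            "phi_frac_HA must be > 0 (HA molar mass is undetermined)"
        )
    if phi_frac_HA > 1.0:
        raise FractionationError("phi_frac_HA must be in (0, 1]")
    return (M_w_mix - M_w_FA * (1.0 - phi_frac_HA)) / phi_frac_HA
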