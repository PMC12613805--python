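"""Physical constants and unit helpers (strict SI internally)."""

FARADAY = 96485.33212  # C mol-1
GAS_R = 8.31446261815324  # J mol-1 K-1
EPS0 = 8.8541878128e-12  # F m-1
EPS_R_WATER = 78.54  # relative permittivity, dimensionless
AVOGADRO = 6.02214076e23  # mol-1

#: default temperature of the batch systems, K (22 degC)
T_DEFAULT = 295.15

# unit conversions at the I/O boundary
MG_L_TO_KG_M3 = 1e-3  # mg L-1 -> kg m-3
KG_M2_TO_MG_M2 = 1e6  # kg m-2 -> mg m-2
KDA_TO_KG_MOL = 1.0  # 1 kDa = 1 kg mol-1


def boltzmann_factor(psi_volt: float, temperature: float) -> float:
    """exp(-F psi / RT) for a unit positive charge at potential psi."""
    import math

    return math.exp(-FARADAY * psi_volt / (GAS_R * temperature))
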