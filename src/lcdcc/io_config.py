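"""Configuration schema, validation, table I/O and logging shared by all modules.

The configuration is a hierarchical YAML file.  Every physical quantity
carries its unit in the key name.  Unknown keys are rejected, missing keys
fall back to the documented defaults, and out-of-range values raise a
dedicated error class so callers can distinguish failure modes.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from .constants import T_DEFAULT

logger = logging.getLogger("lcdcc")


def setup_logging(verbose: bool = False) -> None:
    level = logging.DEBUG if verbose else logging.INFO
    logging.basicConfig(level=level, format="%(name)s %(levelname)s %(message)s")


# ---------------------------------------------------------------------------
# error classes
# ---------------------------------------------------------------------------

class ConfigError(Exception):
    """Base class for configuration problems."""


class ConfigFileError(ConfigError):
    """The configuration file cannot be read."""


class ConfigSyntaxError(ConfigError):
    """The configuration file is not valid YAML / not a mapping."""


class ConfigKeyError(ConfigError):
    """An unknown key was supplied."""


class ConfigRangeError(ConfigError):
    """A value is outside its physically admissible range."""


class TableFormatError(Exception):
    """A CSV table does not carry the documented header."""


# ---------------------------------------------------------------------------
# defaults
#
# Surface: two-site 1-pK CD-MUSIC goethite (singly and triply coordinated
# hydroxyls), logK_H equal to the pristine point of zero charge (9.3) so a
# symmetric electrolyte gives PZC = 9.3 by construction.  Specific surface
# area 96 m2/g.  Extended-Stern double layer with literature capacitances.
#
# NOM: generic bimodal NICA proton parameters for humic and fulvic acid
# (carboxylic- and phenolic-type distributions), particle-level
# heterogeneity exponents q_HA = 0.1 and q_FA = 0.3, mass density
# 1250 kg/m3, limiting adsorption volumes 3e-9 (HA) and 0.8e-9 (FA) m3/m2.
# ---------------------------------------------------------------------------

DEFAULT_CONFIG: dict[str, Any] = {
    "surface": {
        "sites": [
            {"name": "FeOH", "density_nm2": 3.45, "logK_H": 9.3},
            {"name": "Fe3O", "density_nm2": 2.7, "logK_H": 9.3},
        ],
        "logK_Na": -1.0,
        "logK_Cl": -1.0,
    },
    "edl": {
        "stern": "extended",  # "extended" (planes 0,1,2,d) or "basic" (0,1,d)
        "C1_F_m2": 0.9,
        "C2_F_m2": 0.74,
        "C3_F_m2": 5.0,  # between outer Stern plane and the d-plane (large: the d-plane sits at the Stern/diffuse boundary)
        "d_ST_m": 0.8e-9,
        "temperature_K": T_DEFAULT,
        "area_m2_g": 96.0,
        "eps_r": 78.54,
    },
    "nom": {
        "HA": {
            "nica": {
                "Q1_mol_kg": 3.15, "logK1": 2.93, "m1": 0.50,
                "Q2_mol_kg": 2.55, "logK2": 8.00, "m2": 0.26,
            },
            "q": 0.1,
            "M_w_kDa": 17.0,
            "M_o_kDa": 1.6,
            "k_kDa": 15.4,
            "rho_kg_m3": 1250.0,
            "V_limit_m3_m2": 3.0e-9,
            # fraction of the particle charge coupling to the plane
            # potentials in the transfer energy: most of a large humic
            # coil is screened by counterions inside the layer
            "elec_coupling": 0.05,
            "E_le_J_mol": -500.0,
            # lateral repulsion among adsorbed particles, J per kg per
            # mg m-2 of total surface loading
            "E_rep_J_kg_per_mg_m2": 500.0,
            "offset_J_mol": 0.0,
        },
        "FA": {
            "nica": {
                "Q1_mol_kg": 5.88, "logK1": 2.34, "m1": 0.38,
                "Q2_mol_kg": 1.86, "logK2": 8.60, "m2": 0.53,
            },
            "q": 0.3,
            "M_w_kDa": 1.8,
            "M_o_kDa": 1.8,
            "k_kDa": 0.0,
            "rho_kg_m3": 1250.0,
            "V_limit_m3_m2": 0.8e-9,
            # small fulvic particles sit within the compact layer and
            # couple strongly to the plane potentials
            "elec_coupling": 0.3,
            "E_le_J_mol": -500.0,
            # FA carries roughly twice the charge per mass of HA, hence a
            # much stronger lateral repulsion per unit mass
            "E_rep_J_kg_per_mg_m2": 12000.0,
            "offset_J_mol": 0.0,
        },
    },
    "regulator": {
        "alpha_R": 0.2,       # steepness of the first-Stern fraction response (per thermal volt)
        "beta_theta": 0.05,   # steepness of the Stern-occupation response (per thermal volt)
        "split_01": 0.5,      # share of the 0+1 group charge put on plane 0
        "split_12": 0.5,      # share of the 1+2 group charge put on plane 1
        # weight exponent for compact-layer space sharing between
        # co-adsorbed components (small particles claim space first)
        "size_preference": 2.0,
    },
    "solver": {
        "charge_tol_C_m2": 1e-10,
        "lf_tol": 1e-12,
        "outer_tol": 1e-9,
        "damping": 0.5,
        "max_outer": 400,
        "omega_share": "volume",  # "volume" or "mass" share for Eq of mixing
    },
    "scenario": "variable",  # "constant" or "variable" adsorption volume
    "V_constant_m3_m2": 3.0e-9,
    "calibration": {
        # single-component anchor states used by the default calibration:
        # at pH 4, 0.01 M, with C_sol pinned, the predicted loading must
        # equal the component's observed single-system maximum.
        "pH": 4.0,
        "ionic_strength_M": 0.01,
        "C_sol_mg_L": 100.0,
        "Gamma_target_HA_mg_m2": 2.0,
        "Gamma_target_FA_mg_m2": 0.95,
    },
}

# (path, low, high, low_open, high_open) range rules; None = unbounded
_RANGES: list[tuple[str, float | None, float | None, bool, bool]] = [
    ("edl.C1_F_m2", 0.0, None, True, False),
    ("edl.C2_F_m2", 0.0, None, True, False),
    ("edl.C3_F_m2", 0.0, None, True, False),
    ("edl.d_ST_m", 0.0, None, True, False),
    ("edl.temperature_K", 250.0, 350.0, False, False),
    ("edl.area_m2_g", 0.0, None, True, False),
    ("nom.HA.q", 0.0, 1.0, True, False),
    ("nom.FA.q", 0.0, 1.0, True, False),
    ("nom.HA.rho_kg_m3", 700.0, 1700.0, False, False),
    ("nom.FA.rho_kg_m3", 700.0, 1700.0, False, False),
    ("nom.HA.V_limit_m3_m2", 0.0, None, True, False),
    ("nom.FA.V_limit_m3_m2", 0.0, None, True, False),
    ("nom.HA.nica.m1", 0.0, 1.0, True, False),
    ("nom.HA.nica.m2", 0.0, 1.0, True, False),
    ("nom.FA.nica.m1", 0.0, 1.0, True, False),
    ("nom.FA.nica.m2", 0.0, 1.0, True, False),
    ("nom.HA.nica.Q1_mol_kg", 0.0, None, True, False),
    ("nom.HA.nica.Q2_mol_kg", 0.0, None, True, False),
    ("nom.FA.nica.Q1_mol_kg", 0.0, None, True, False),
    ("nom.FA.nica.Q2_mol_kg", 0.0, None, True, False),
    ("solver.damping", 0.0, 1.0, True, False),
    ("nom.HA.elec_coupling", 0.0, 1.0, True, False),
    ("nom.FA.elec_coupling", 0.0, 1.0, True, False),
    ("regulator.size_preference", 0.0, 100.0, False, False),
    ("V_constant_m3_m2", 0.0, None, True, False),
]

_CHOICES = {
    "scenario": {"constant", "variable"},
    "edl.stern": {"basic", "extended"},
    "solver.omega_share": {"volume", "mass"},
}


def _get_path(d: Mapping[str, Any], path: str) -> Any:
    cur: Any = d
    for part in path.split("."):
        cur = cur[part]
    return cur


def set_path(d: dict[str, Any], path: str, value: Any) -> None:
    """Set a dotted key path in a nested dict (used by sweeps/recovery)."""
    parts = path.split(".")
    cur = d
    for part in parts[:-1]:
        if part not in cur or not isinstance(cur[part], dict):
            raise ConfigKeyError(f"unknown configuration section {part!r} in {path!r}")
        cur = cur[part]
    if parts[-1] not in cur:
        raise ConfigKeyError(f"unknown configuration key {path!r}")
    cur[parts[-1]] = value


def _merge(defaults: Any, user: Any, path: str = "") -> Any:
    if isinstance(defaults, dict):
        if not isinstance(user, dict):
            raise ConfigSyntaxError(f"section {path or '<root>'} must be a mapping")
        out = {}
        for key, dval in defaults.items():
            sub = f"{path}.{key}" if path else key
            out[key] = _merge(dval, user[key], sub) if key in user else copy.deepcopy(dval)
        unknown = set(user) - set(defaults)
        if unknown:
            raise ConfigKeyError(
                f"unknown configuration key(s) {sorted(unknown)} in section {path or '<root>'}"
            )
        return out
    # "sites" is the only list-valued key: replace wholesale
    return copy.deepcopy(user)


def validate_config_dict(cfg: dict[str, Any]) -> None:
    for path, lo, hi, lo_open, hi_open in _RANGES:
        val = _get_path(cfg, path)
        if not isinstance(val, (int, float)):
            raise ConfigRangeError(f"{path} must be numeric, got {val!r}")
        if lo is not None and (val <= lo if lo_open else val < lo):
            raise ConfigRangeError(f"{path} = {val} below admissible range")
        if hi is not None and (val >= hi if hi_open else val > hi):
            raise ConfigRangeError(f"{path} = {val} above admissible range")
    for path, allowed in _CHOICES.items():
        val = _get_path(cfg, path)
        if val not in allowed:
            raise ConfigRangeError(f"{path} must be one of {sorted(allowed)}, got {val!r}")
    for site in cfg["surface"]["sites"]:
        extra = set(site) - {"name", "density_nm2", "logK_H"}
        if extra:
            raise ConfigKeyError(f"unknown site key(s) {sorted(extra)}")
        if site.get("density_nm2", 0) <= 0:
            raise ConfigRangeError(f"site {site.get('name')}: density must be > 0")


@dataclass
class ModelConfig:
    """Validated, fully defaulted model configuration (nested dict view)."""

    data: dict[str, Any] = field(default_factory=lambda: copy.deepcopy(DEFAULT_CONFIG))

    def __post_init__(self) -> None:
        validate_config_dict(self.data)

    def __getitem__(self, key: str) -> Any:
        return self.data[key]

    def get(self, path: str) -> Any:
        return _get_path(self.data, path)

    def updated(self, overrides: Mapping[str, Any]) -> "ModelConfig":
        """Return a copy with dotted-path overrides applied and revalidated."""
        new = copy.deepcopy(self.data)
        for path, value in overrides.items():
            set_path(new, path, value)
        return ModelConfig(new)


def load_config(path: str | Path | None = None) -> ModelConfig:
    """Load and validate a YAML configuration file.

    ``None`` or an empty file yields the full default configuration.
    """
    if path is None:
        return ModelConfig()
    p = Path(path)
    if not p.exists():
        raise ConfigFileError(f"configuration file not found: {p}")
    try:
        raw = yaml.safe_load(p.read_text(encoding="utf-8"))
    except yaml.YAMLError as exc:
        raise ConfigSyntaxError(f"malformed YAML in {p}: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigSyntaxError(f"top level of {p} must be a mapping")
    merged = _merge(DEFAULT_CONFIG, raw)
    return ModelConfig(merged)


def write_config(cfg: ModelConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.data, sort_keys=False), encoding="utf-8")


# ---------------------------------------------------------------------------
# isotherm tables
# ---------------------------------------------------------------------------

ISOTHERM_COLUMNS = [
    "design_id",
    "pH",
    "HA_added_mg_L",
    "FA_added_mg_L",
    "HA_ads_mg_m2",
    "FA_ads_mg_m2",
    "HA_sol_mg_L",
    "FA_sol_mg_L",
    "V_m3_m2",
    "scenario",
    "mode",
    "converged",
]

#: optional diagnostics appended by the fractionation module
MW_COLUMNS = ["M_w_HA_ads_kDa", "M_w_mix_kDa"]


def empty_table() -> pd.DataFrame:
    return pd.DataFrame(columns=ISOTHERM_COLUMNS)


def write_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write an isotherm table as CSV ('.' decimals, ',' separators, UTF-8)."""
    missing = [c for c in ISOTHERM_COLUMNS if c not in table.columns]
    if missing:
        raise TableFormatError(f"table is missing column(s): {missing}")
    table.to_csv(path, index=False, float_format="%.12g", encoding="utf-8")


def read_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, encoding="utf-8")
    missing = [c for c in ISOTHERM_COLUMNS if c not in df.columns]
    if missing:
        raise TableFormatError(f"CSV {path} is missing column(s): {missing}")
    return df
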