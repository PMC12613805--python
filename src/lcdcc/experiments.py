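"""In-silico batch experiment runner: the two standard competitive designs
(fixed FA with an HA series, and fixed HA with an FA series), exchange
ratios, scenario RMSE comparison and parameter sensitivity sweeps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .affinity import calibrate_plateau_offsets
from .constants import KG_M2_TO_MG_M2
from .io_config import ISOTHERM_COLUMNS, ModelConfig
from .partition import FullState, PartitionError, SystemComposition, \
    self_consistent_solve

logger = logging.getLogger("lcdcc")


class ExperimentError(ValueError):
    pass


@dataclass(frozen=True)
class ExperimentDesign:
    """A batch design: one component fixed, the other varied.

    The default factory designs follow the standard competitive layout:
    goethite 1 g/L in 0.01 M NaCl at pH 4 and 6; design I fixes FA at
    0/100 mg/L and varies HA 20-240 mg/L, design II fixes HA at 0/160 mg/L
    and varies FA 25-200 mg/L.  Fixed level 0 provides the
    single-component baselines.
    """

    design_id: str
    fixed_component: str  # "HA" | "FA"
    fixed_levels_mg_L: tuple[float, ...]
    varied_component: str
    varied_mg_L: tuple[float, ...]
    pH_values: tuple[float, ...] = (4.0, 6.0)
    solid_g_L: float = 1.0
    ionic_strength: float = 0.01

    def __post_init__(self) -> None:
        if self.fixed_component == self.varied_component:
            raise ExperimentError("fixed and varied components must differ")
        if min(self.varied_mg_L, default=0.0) < 0 or \
                min(self.fixed_levels_mg_L, default=0.0) < 0:
            raise ExperimentError("concentrations must be non-negative")


def design_exp1(pH_values: Sequence[float] = (4.0, 6.0),
                n_points: int = 8) -> ExperimentDesign:
    """HA series 20-240 mg/L at FA 0 or 100 mg/L."""
    return ExperimentDesign(
        "ExpI", fixed_component="FA", fixed_levels_mg_L=(0.0, 100.0),
        varied_component="HA",
        varied_mg_L=tuple(np.round(np.linspace(20.0, 240.0, n_points), 6)),
        pH_values=tuple(pH_values),
    )


def design_exp2(pH_values: Sequence[float] = (4.0, 6.0),
                n_points: int = 8) -> ExperimentDesign:
    """FA series 25-200 mg/L at HA 0 or 160 mg/L."""
    return ExperimentDesign(
        "ExpII", fixed_component="HA", fixed_levels_mg_L=(0.0, 160.0),
        varied_component="FA",
        varied_mg_L=tuple(np.round(np.linspace(25.0, 200.0, n_points), 6)),
        pH_values=tuple(pH_values),
    )


def calibrated_config(config: ModelConfig | None = None) -> ModelConfig:
    """Configuration with single-component plateau-calibrated offsets."""
    cfg, offsets = calibrate_plateau_offsets(config)
    logger.debug("calibrated offsets (J/mol): %s", offsets)
    return cfg


def _row(state: FullState, design_id: str, mode: str) -> dict:
    sysc = state.system
    return {
        "design_id": design_id,
        "pH": sysc.pH,
        "HA_added_mg_L": sysc.HA_tot_mg_L,
        "FA_added_mg_L": sysc.FA_tot_mg_L,
        "HA_ads_mg_m2": state.partition.Gamma_mg_m2("HA"),
        "FA_ads_mg_m2": state.partition.Gamma_mg_m2("FA"),
        "HA_sol_mg_L": state.partition.C_mg_L("HA"),
        "FA_sol_mg_L": state.partition.C_mg_L("FA"),
        "V_m3_m2": state.volume.V,
        "scenario": state.scenario,
        "mode": mode,
        "converged": state.converged,
        "M_w_HA_ads_kDa": state.M_w["HA"],
    }


def run_design(
    design: ExperimentDesign,
    config: ModelConfig | None = None,
    scenario: str | None = None,
    mode: str = "predictive",
    observed: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Simulate every (pH, fixed level, varied addition) combination.

    Includes the zero-competitor baselines (fixed level 0 and, for each
    fixed level, the varied = 0 point).  ``mode="conditional"`` pins the
    fixed component's adsorption to the matching value in ``observed``.
    Failed points are kept with ``converged=False`` and NaN adsorption.
    """
    cfg = config or ModelConfig()
    rows = []
    for pH in design.pH_values:
        for fixed_level in design.fixed_levels_mg_L:
            warm = None
            for varied in (0.0, *design.varied_mg_L):
                adds = {design.fixed_component: fixed_level,
                        design.varied_component: varied}
                if adds["HA"] == 0.0 and adds["FA"] == 0.0 and rows and \
                        any(r["pH"] == pH and r["HA_added_mg_L"] == 0.0
                            and r["FA_added_mg_L"] == 0.0 for r in rows):
                    continue  # duplicate blank
                sysc = SystemComposition(
                    HA_tot_mg_L=adds["HA"], FA_tot_mg_L=adds["FA"],
                    solid_g_L=design.solid_g_L, pH=pH,
                    ionic_strength=design.ionic_strength,
                    area_m2_g=cfg.get("edl.area_m2_g"),
                )
                conditional = None
                if mode == "conditional" and fixed_level > 0.0:
                    if observed is None:
                        raise ExperimentError(
                            "conditional mode needs an observed table"
                        )
                    match = observed[
                        (observed["pH"] == pH)
                        & (observed["HA_added_mg_L"] == adds["HA"])
                        & (observed["FA_added_mg_L"] == adds["FA"])
                    ]
                    if len(match) != 1:
                        raise ExperimentError(
                            f"no unique observed row for pH={pH}, "
                            f"adds={adds}"
                        )
                    col = f"{design.fixed_component}_ads_mg_m2"
                    conditional = {
                        design.fixed_component: float(match[col].iloc[0])
                    }
                try:
                    state = self_consistent_solve(
                        sysc, cfg, scenario=scenario,
                        mode=("conditional" if conditional else "predictive"),
                        conditional_fixed=conditional, warm_state=warm,
                    )
                    warm = state
                    rows.append(_row(state, design.design_id,
                                     mode if conditional else "predictive"))
                except PartitionError as exc:
                    logger.warning("point pH=%s adds=%s failed: %s",
                                   pH, adds, exc)
                    rows.append({
                        "design_id": design.design_id, "pH": pH,
                        "HA_added_mg_L": adds["HA"],
                        "FA_added_mg_L": adds["FA"],
                        "HA_ads_mg_m2": np.nan, "FA_ads_mg_m2": np.nan,
                        "HA_sol_mg_L": np.nan, "FA_sol_mg_L": np.nan,
                        "V_m3_m2": np.nan, "scenario": scenario
                        or cfg["scenario"], "mode": mode,
                        "converged": False, "M_w_HA_ads_kDa": np.nan,
                    })
    return pd.DataFrame(rows)


def predict_single_component(
    component: str,
    additions_mg_L: Sequence[float],
    pH_values: Sequence[float],
    config: ModelConfig | None = None,
    ionic_strength: float = 0.01,
    solid_g_L: float = 1.0,
    scenario: str = "variable",
) -> np.ndarray:
    """Adsorbed amounts (mg m-2) for single-component points (vectorised
    over matched addition/pH sequences); used by offset calibration."""
    cfg = config or ModelConfig()
    out = np.empty(len(additions_mg_L))
    warm = None
    for i, (add, pH) in enumerate(zip(additions_mg_L, pH_values)):
        adds = {"HA": 0.0, "FA": 0.0}
        adds[component] = float(add)
        sysc = SystemComposition(adds["HA"], adds["FA"], solid_g_L,
                                 float(pH), ionic_strength,
                                 cfg.get("edl.area_m2_g"))
        state = self_consistent_solve(sysc, cfg, scenario=scenario,
                                      warm_state=warm)
        warm = state
        out[i] = state.partition.Gamma_mg_m2(component)
    return out


def exchange_ratio(
    table: pd.DataFrame,
    displaced: str,
    pH: float | None = None,
    intercept: bool = True,
) -> tuple[float, float]:
    """Mass-exchange ratio: OLS slope of (baseline - current) adsorption of
    the displaced component versus the competitor's adsorption.

    The baseline is the zero-competitor row at the same pH and the same
    own-addition.  Returns (slope, standard error).  With
    ``intercept=False`` the regression is forced through the origin.
    """
    competitor = "FA" if displaced == "HA" else "HA"
    if displaced not in ("HA", "FA"):
        raise ExperimentError(f"unknown component {displaced!r}")
    tab = table[table["converged"] == True]  # noqa: E712
    if pH is not None:
        tab = tab[tab["pH"] == pH]
    xs, ys = [], []
    for ph_val in tab["pH"].unique():
        sub = tab[tab["pH"] == ph_val]
        mixed = sub[(sub[f"{competitor}_added_mg_L"] > 0)
                    & (sub[f"{displaced}_added_mg_L"] > 0)]
        for _, row in mixed.iterrows():
            base = sub[
                (sub[f"{competitor}_added_mg_L"] == 0.0)
                & (sub[f"{displaced}_added_mg_L"]
                   == row[f"{displaced}_added_mg_L"])
            ]
            if len(base) != 1:
                continue
            desorbed = float(base[f"{displaced}_ads_mg_m2"].iloc[0]
                             - row[f"{displaced}_ads_mg_m2"])
            adsorbed = float(row[f"{competitor}_ads_mg_m2"])
            if adsorbed > 0:
                xs.append(adsorbed)
                ys.append(desorbed)
    if len(xs) < 3:
        raise ExperimentError(
            f"need >= 3 points with positive competitor adsorption, "
            f"got {len(xs)}"
        )
    x = np.asarray(xs)
    X = sm.add_constant(x) if intercept else x[:, None]
    fit = sm.OLS(np.asarray(ys), X).fit()
    idx = 1 if intercept else 0
    return float(fit.params[idx]), float(fit.bse[idx])


def rmse(predicted: pd.DataFrame, observed: pd.DataFrame,
         component: str) -> float:
    """Root mean square error (mg m-2) between matched design points."""
    keys = ["design_id", "pH", "HA_added_mg_L", "FA_added_mg_L"]
    col = f"{component}_ads_mg_m2"
    merged = predicted.merge(observed, on=keys, suffixes=("_pred", "_obs"))
    if len(merged) != len(predicted) or len(merged) != len(observed):
        raise ExperimentError(
            f"row mismatch: {len(predicted)} predicted, {len(observed)} "
            f"observed, {len(merged)} matched"
        )
    diff = merged[f"{col}_pred"].to_numpy() - merged[f"{col}_obs"].to_numpy()
    return float(np.sqrt(np.mean(diff ** 2)))


def sensitivity_sweep(
    parameter: str,
    values: Sequence[float],
    design: ExperimentDesign,
    config: ModelConfig | None = None,
    scenario: str | None = None,
    output_metric: str = "max_ads",
    metric_component: str | None = None,
) -> pd.DataFrame:
    """Re-run a design for each value of one configuration key.

    ``output_metric``: "max_ads" (maximum adsorption of the metric
    component, mg m-2) or "total_C" (summed adsorbed mass over the design,
    mg m-2).  The parameter is a dotted configuration path, e.g.
    "nom.FA.q"; unknown paths raise.
    """
    cfg = config or ModelConfig()
    comp = metric_component or design.varied_component
    rows = []
    for value in values:
        sub_cfg = cfg.updated({parameter: float(value)})  # raises if unknown
        table = run_design(design, sub_cfg, scenario=scenario)
        ok = table[table["converged"] == True]  # noqa: E712
        if output_metric == "max_ads":
            metric = float(ok[f"{comp}_ads_mg_m2"].max())
        elif output_metric == "total_C":
            metric = float(ok["HA_ads_mg_m2"].sum() + ok["FA_ads_mg_m2"].sum())
        else:
            raise ExperimentError(f"unknown metric {output_metric!r}")
        rows.append({"parameter": parameter, "value": value,
                     "metric": output_metric, "result": metric})
    return pd.DataFrame(rows)
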