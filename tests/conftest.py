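"""Shared fixtures: the calibrated default configuration and the standard
competitive designs at pH 4, computed once per session."""

import pytest

from lcdcc import ModelConfig
from lcdcc.affinity import calibrate_plateau_offsets
from lcdcc.experiments import design_exp1, design_exp2, run_design


@pytest.fixture(scope="session")
def default_cfg():
    return ModelConfig()


@pytest.fixture(scope="session")
def calibrated_cfg():
    cfg, _ = calibrate_plateau_offsets()
    return cfg


@pytest.fixture(scope="session")
def exp1_ph4(calibrated_cfg):
    return run_design(design_exp1(pH_values=(4.0,)), calibrated_cfg)


@pytest.fixture(scope="session")
def exp2_ph4(calibrated_cfg):
    return run_design(design_exp2(pH_values=(4.0,)), calibrated_cfg)


@pytest.fixture(scope="session")
def exp1_ph6(calibrated_cfg):
    return run_design(design_exp1(pH_values=(6.0,)), calibrated_cfg)


@pytest.fixture(scope="session")
def exp2_ph6(calibrated_cfg):
    return run_design(design_exp2(pH_values=(6.0,)), calibrated_cfg)
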