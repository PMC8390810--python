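"""Run configuration: validated, hashable, YAML-loadable."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, model_validator

from .experiment import Scenario, gc_scenario, heat_scenario, thz_scenario

__all__ = ["BeamConfig", "ScenarioConfig", "RunConfig", "load_config", "config_hash", "build_scenario"]


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid")


class BeamConfig(_StrictModel):
    power_density_mw_cm2: float | None = None  # None: look up from the condition
    reflection_loss: float = 0.40
    absorption_coefficient_cm: float = 83.0
    pathlength_cm: float = 0.039


class ScenarioConfig(_StrictModel):
    kind: Literal["thz", "heat", "none"] = "thz"
    # thz parameters
    f_kop_up: float = 4.0
    f_kch_down: float = 0.1
    temp_offset_c: float | None = None  # None: 0.3 for THz_low, 5.0 for THz_high
    # heat parameters
    delta_t_c: float = 5.0
    f_kop_down: float = 0.1


class RunConfig(_StrictModel):
    """Everything one end-to-end run needs; unknown keys are rejected."""

    mode: Literal["simulate", "analyze"]
    out_dir: Path
    seed: int | None = None
    condition: Literal["TC", "THz_low", "THz_high"] = "THz_low"
    scenario: ScenarioConfig = ScenarioConfig()
    nominal_snr: float | None = 100.0
    storage_hours: float | None = None
    n_spectra: int = 3
    snr_min: float = 33.3
    floor_multiple: float = 3.0
    errdr_method: Literal["quadrature", "sum", "half_sum"] = "quadrature"
    pdb_path: Path | None = None
    chain: str = "A"
    # analyze mode: {"gc": {timepoint: path}, "pert": {timepoint: path}}
    tables: dict[str, dict[int, Path]] | None = None
    beam: BeamConfig | None = None

    @model_validator(mode="after")
    def _check_mode(self) -> "RunConfig":
        if self.mode == "simulate" and self.seed is None:
            raise ValueError("simulate mode requires a seed")
        if self.mode == "analyze" and not self.tables:
            raise ValueError("analyze mode requires input peak-table paths under 'tables'")
        if self.snr_min <= 0:
            raise ValueError("snr_min must be positive")
        return self


def load_config(path: str | Path) -> RunConfig:
    return RunConfig.model_validate(yaml.safe_load(Path(path).read_text(encoding="utf-8")))


def config_hash(config: RunConfig) -> str:
    payload = json.dumps(config.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(payload.encode("utf-8")).hexdigest()


def build_scenario(config: RunConfig) -> Scenario:
    """Instantiate the perturbation scenario the config describes."""
    sc = config.scenario
    if sc.kind == "none":
        return gc_scenario()
    if sc.kind == "heat":
        return heat_scenario(delta_t_c=sc.delta_t_c, f_kop_down=sc.f_kop_down)
    offset = sc.temp_offset_c
    if offset is None:
        offset = 5.0 if config.condition == "THz_high" else 0.3
    return thz_scenario(f_kop_up=sc.f_kop_up, f_kch_down=sc.f_kch_down, temp_offset_c=offset)
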