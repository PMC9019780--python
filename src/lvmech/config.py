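"""YAML configuration round-trip for the pipeline.

Every parameter of :class:`~lvmech.pipeline.PipelineConfig` (geometry,
passive/active material constants, circulation circuit, calibration targets
and search settings) can be written to and restored from a YAML file, so a
calibrated setup is reusable as an input.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import yaml

from .geometry import LVGeometrySpec
from .materials import ActiveParams, PassiveParams
from .circulation import CirculationParams, ElastanceWaveform
from .calibration import HemodynamicTargets
from .pipeline import PipelineConfig

__all__ = ["config_to_yaml", "config_from_yaml", "default_config"]


def default_config() -> PipelineConfig:
    return PipelineConfig()


def config_to_yaml(config: PipelineConfig, path) -> None:
    data = asdict(config)
    data["surface_v_span"] = list(config.surface_v_span)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def config_from_yaml(path) -> PipelineConfig:
    with open(Path(path)) as fh:
        data = yaml.safe_load(fh)
    kwargs = {}
    if "geometry" in data:
        kwargs["geometry"] = LVGeometrySpec(**data["geometry"])
    if "passive" in data:
        kwargs["passive"] = PassiveParams(**data["passive"])
    if "active" in data:
        kwargs["active"] = ActiveParams(**data["active"])
    if "circulation" in data:
        cp = dict(data["circulation"])
        for key in ("e_la", "e_rv"):
            if key in cp and isinstance(cp[key], dict):
                cp[key] = ElastanceWaveform(**cp[key])
        kwargs["circulation"] = CirculationParams(**cp)
    if "targets" in data:
        kwargs["targets"] = HemodynamicTargets(**data["targets"])
    for key in ("endo_angle", "epi_angle", "tolerance", "budget",
                "exchange_dt", "n_coupled_cycles", "surface_n_v",
                "correction_pass"):
        if key in data:
            kwargs[key] = data[key]
    if "surface_v_span" in data:
        kwargs["surface_v_span"] = tuple(data["surface_v_span"])
    return PipelineConfig(**kwargs)
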