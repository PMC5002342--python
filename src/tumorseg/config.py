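"""Pipeline configuration with the published defaults.

Every stage parameter is collected in one dataclass so a whole run is
reproducible from a single record.  The classifier/front-propagation defaults
(alpha = -3.5, beta = 8.0, K = 200, ridge lambda = 0.01, 3x3x3 window,
stop value 15) are fixed across cases; the remaining knobs (ROI margin,
diffusion settings, gradient scale, morphology radius) have documented
defaults and can be overridden from a YAML file or CLI flags.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, replace
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "load_config"]


@dataclass
class PipelineConfig:
    # ROI
    margin_mm: float = 20.0
    # anisotropic diffusion
    diffusion_steps: int = 5
    diffusion_time_step: float = 0.0625
    diffusion_conductance: float = 3.0
    # gradient / edge potential
    gradient_sigma_mm: float = 1.0
    sigmoid_alpha: float = -3.5
    sigmoid_beta: float = 8.0
    # fast marching
    stop_value: float = 15.0
    # ELM
    hidden_size: int = 200
    ridge: float = 0.01
    window: tuple[int, int, int] = (3, 3, 3)
    rng_seed: int = 0
    # patterns from the noise-reduced ROI (False: raw ROI)
    patterns_from_smoothed: bool = True
    # postprocessing
    component_connectivity: int = 26
    morphology_radius: int = 1

    def to_dict(self) -> dict:
        d = asdict(self)
        d["window"] = list(self.window)
        return d

    def override(self, **kwargs) -> "PipelineConfig":
        kwargs = {k: v for k, v in kwargs.items() if v is not None}
        if "window" in kwargs:
            kwargs["window"] = tuple(int(w) for w in kwargs["window"])
        return replace(self, **kwargs)


def load_config(path=None, **overrides) -> PipelineConfig:
    """Config from an optional YAML file, then keyword overrides on top."""
    cfg = PipelineConfig()
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cfg.to_dict())
        if unknown:
            raise ValueError(f"unknown config keys in {path}: {sorted(unknown)}")
        cfg = cfg.override(**raw)
    return cfg.override(**overrides)
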