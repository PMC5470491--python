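"""Flat, serializable pipeline configuration.

Every knob of the pipeline lives here with its default: the blackness-ratio
regularizer epsilon, the DoG competition constants, the SLIC parameters
(K, m, iterations), the superpixel-saliency reach delta, the FOA radius
fraction, the rejection-loop cap, and the Chan-Vese parameters.  Configs
round-trip losslessly through YAML.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from typing import IO

import yaml

from .chanvese import ChanVeseParams
from .io import ValidationError
from .saliency import NormalizeParams

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    epsilon: float = 1e-3
    norm_iterations: int = 3
    norm_ex_sigma_frac: float = 0.02
    norm_ex_weight: float = 0.5
    norm_inh_sigma_frac: float = 0.25
    norm_inh_weight: float = 1.5
    slic_k: int = 400
    slic_m: float = 40.0
    slic_iter: int = 10
    delta: float = 0.05
    radius_frac: float = 0.125
    max_attempts: int = 3
    post_processing: bool = True
    ior_mode: str = "mask"
    cv_mu: float = 0.2 * 255.0 ** 2
    cv_smooth_sigma: float = 1.5
    cv_max_iter: int = 500

    def norm_params(self) -> NormalizeParams:
        return NormalizeParams(
            iterations=self.norm_iterations,
            ex_sigma_frac=self.norm_ex_sigma_frac,
            ex_weight=self.norm_ex_weight,
            inh_sigma_frac=self.norm_inh_sigma_frac,
            inh_weight=self.norm_inh_weight,
        )

    def cv_params(self) -> ChanVeseParams:
        return ChanVeseParams(mu=self.cv_mu, smooth_sigma=self.cv_smooth_sigma,
                              max_iter=self.cv_max_iter)

    def localize_kwargs(self) -> dict:
        return dict(
            epsilon=self.epsilon, norm_params=self.norm_params(),
            slic_k=self.slic_k, slic_m=self.slic_m, slic_iter=self.slic_iter,
            delta=self.delta, radius_frac=self.radius_frac,
            max_attempts=self.max_attempts, post_processing=self.post_processing,
            ior_mode=self.ior_mode, cv_params=self.cv_params(),
        )

    def to_yaml(self, stream: IO | None = None) -> str | None:
        return yaml.safe_dump(asdict(self), stream, sort_keys=True)

    @classmethod
    def from_yaml(cls, stream: str | IO) -> "PipelineConfig":
        data = yaml.safe_load(stream) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
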