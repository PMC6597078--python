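"""Detector configuration with the published default parameter set.

Defaults: 45x45 training patches, 16-px descriptor grids every 2 px,
K = 400 visual words, M = 50 query / N = 200 background patches, scale
search 0.5-1.5 in steps of 0.1 (11 factors), voting-map threshold
gamma = 0.2, LLC base size C = 5, SVM C-grid 2^-8..2^8 with 5-fold CV,
NMS overlap threshold 0.5.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace

import numpy as np
import yaml

from .dsift import GridSpec
from .localization import ScaleSet


@dataclass(frozen=True)
class DetectorConfig:
    grid_size: int = 16
    grid_step: int = 2
    patch_w: int = 45
    patch_h: int = 45
    K: int = 400
    M: int = 50
    N: int = 200
    scale_min: float = 0.5
    scale_max: float = 1.5
    scale_step: float = 0.1
    gamma: float = 0.2
    llc_C: int = 5
    svm_c_min_pow: int = -8
    svm_c_max_pow: int = 8
    cv_folds: int = 5
    nms_threshold: float = 0.5
    nms_containment: float = 0.8
    seed: int = 0

    @property
    def grid_spec(self) -> GridSpec:
        return GridSpec(grid_size=self.grid_size, grid_step=self.grid_step)

    @property
    def scale_set(self) -> ScaleSet:
        n = int(round((self.scale_max - self.scale_min) / self.scale_step)) + 1
        return ScaleSet(
            tuple(np.round(self.scale_min + self.scale_step * np.arange(n), 10))
        )

    @property
    def svm_c_grid(self) -> tuple:
        return tuple(
            2.0**p for p in range(self.svm_c_min_pow, self.svm_c_max_pow + 1)
        )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "DetectorConfig":
        known = {k: v for k, v in d.items() if k in cls.__dataclass_fields__}
        return cls(**known)

    @classmethod
    def from_yaml(cls, path) -> "DetectorConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def with_overrides(self, **kwargs) -> "DetectorConfig":
        kwargs = {k: v for k, v in kwargs.items() if v is not None}
        return replace(self, **kwargs)
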