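"""Pipeline configuration: every tunable of every stage in one place.

The config serializes to/from JSON.  Unknown keys are rejected on load so a
typo in a config file fails loudly instead of silently running defaults.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

from .edge_enforcement import EnforceParams
from .errors import InvalidInputError
from .infection_classifier import KernelParams
from .skin_demarcation import PresenceParams, SkinRange
from .threshold_optimization import CandidateParams, OptimizedParams
from .wound_reconstruction import HoughParams

__all__ = ["PipelineConfig"]


@dataclass(frozen=True)
class PipelineConfig:
    """All tunables of the segmentation and assessment pipelines."""

    # edge detection / enforcement
    init_threshold: float = 20.0     # starting Canny high threshold (0-255)
    canny_sigma: float = 1.4
    enforce: EnforceParams = field(default_factory=EnforceParams)
    # skin demarcation
    skin_range: SkinRange = field(default_factory=SkinRange)
    presence: PresenceParams = field(default_factory=PresenceParams)
    close_radius: int = 5            # region realization (disk radius, px)
    support_erosion: int = 8         # conservative interior margin of the skin support
    # threshold search
    candidate: CandidateParams = field(default_factory=CandidateParams)
    optimized: OptimizedParams = field(default_factory=OptimizedParams)
    # wound reconstruction
    hough: HoughParams = field(default_factory=HoughParams)
    margin: int = 15                 # peri-wound skin retained around the coverage area
    # suture ROI detection
    linkage: str = "average"
    score_variant: str = "dispersion"
    roi_pad: int = 10
    # classification
    kernel: KernelParams = field(default_factory=KernelParams)
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        return cls(**_build(cls, data))

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))


_NESTED = {
    "enforce": EnforceParams,
    "skin_range": SkinRange,
    "presence": PresenceParams,
    "candidate": CandidateParams,
    "optimized": OptimizedParams,
    "hough": HoughParams,
    "kernel": KernelParams,
}


def _build(cls, data: dict) -> dict:
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise InvalidInputError(f"unknown config keys: {sorted(unknown)}")
    kwargs = {}
    for key, value in data.items():
        if key in _NESTED and isinstance(value, dict):
            sub_cls = _NESTED[key]
            sub_names = {f.name for f in dataclasses.fields(sub_cls)}
            bad = set(value) - sub_names
            if bad:
                raise InvalidInputError(f"unknown config keys under {key!r}: {sorted(bad)}")
            value = sub_cls(**{k: tuple(v) if isinstance(v, list) else v for k, v in value.items()})
        kwargs[key] = value
    return kwargs
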