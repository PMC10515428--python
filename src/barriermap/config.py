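"""Run configuration: every threshold of the analysis in one serializable object.

Defaults equal the published filter set: r2 > 0.6, Dyn > 5 %, 5 % TT/AOT
threshold, minimum cluster size 30 voxels.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

from .distributions import BinConfig
from .kinetics import FitConfig

__all__ = ["RunConfig"]


@dataclass(frozen=True)
class RunConfig:
    r2_min: float = 0.6
    dyn_min: float = 5.0  # percent
    min_cluster: int = 30  # voxels
    connectivity: int = 6  # 3D component connectivity: 6, 18 or 26
    fit: FitConfig = field(default_factory=FitConfig)
    bins: BinConfig = field(default_factory=BinConfig)
    registration: str = "identity"  # or "rigid"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.registration not in ("identity", "rigid"):
            raise ValueError(f"unknown registration mode {self.registration!r}")
        if self.min_cluster < 1:
            raise ValueError("min_cluster must be >= 1")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "fit" in d and isinstance(d["fit"], dict):
            d["fit"] = FitConfig(**d["fit"])
        if "bins" in d and isinstance(d["bins"], dict):
            d["bins"] = BinConfig(**d["bins"])
        return cls(**d)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    @property
    def digest(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]
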