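"""Run configuration: one declarative object covering every pipeline stage.

Defaults encode the standard published settings: RAP/PRx from 30
consecutive 10-s means updated every minute; validity bounds ICP in
(-15, 100) mmHg and MAP in (0, 200) mmHg; ARIMA order search over
p, q in [0, 10] under AIC with d = 1 via pre-differencing; detector
windows 100/50 at minute resolution and 50/25 at 10-min, order
tolerance 3.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .core import InvalidParameterError

log = logging.getLogger("rapkit")


@dataclass
class RunConfig:
    resolutions: tuple[str, ...] = ("1min", "10min", "30min", "60min")
    # derivation
    correlation_window_samples: int = 30
    correlation_update_seconds: float = 60.0
    icp_min: float = -15.0
    icp_max: float = 100.0
    map_min: float = 0.0
    map_max: float = 200.0
    # ARIMA search
    p_max: int = 10
    q_max: int = 10
    criterion: str = "aic"
    stationarity_alpha: float = 0.05
    # detectors
    detector_window_1min: int = 100
    detector_step_1min: int = 50
    detector_window_10min: int = 50
    detector_step_10min: int = 25
    order_tolerance: int = 3
    # clean/non-clean comparison resolution (the detectors operate at
    # minute level, so alignment defaults there too)
    alignment_resolution: str = "1min"

    def __post_init__(self) -> None:
        for r in self.resolutions:
            if r not in ("1min", "10min", "30min", "60min"):
                raise InvalidParameterError(f"unknown resolution {r!r}")
        if self.criterion not in ("aic", "bic", "loglik"):
            raise InvalidParameterError("criterion must be aic/bic/loglik")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "resolutions" in raw:
            raw["resolutions"] = tuple(raw["resolutions"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["resolutions"] = list(data["resolutions"])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)
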