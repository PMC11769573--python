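"""Shared containers for waveforms, derived index series, and artifact masks.

The pipeline distinguishes two sampling regimes: raw pulsatile recordings
(>= 50 Hz, holding ICP/ABP waveforms) and uniformly spaced derived index
series (10-s means and the minute-level and coarser resolutions built from
them).  Missing values are always explicit NaNs, never dropped samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: seconds per sample for each named temporal resolution
RESOLUTION_SECONDS: dict[str, float] = {
    "10s": 10.0,
    "1min": 60.0,
    "10min": 600.0,
    "30min": 1800.0,
    "60min": 3600.0,
}


class InvalidParameterError(ValueError):
    """Raised when a generator or pipeline parameter violates its contract."""


@dataclass
class PhysioRecording:
    """A multi-channel time-stamped physiological recording.

    Parameters
    ----------
    time
        Timestamps in seconds, strictly increasing.
    channels
        Mapping from channel name (e.g. ``"ICP"``, ``"ABP"``) to a value
        array of the same length as ``time``, in mmHg.  NaN marks missing.
    sample_rate
        Nominal sampling rate in Hz, or ``None`` for irregular sampling.
    """

    time: np.ndarray
    channels: dict[str, np.ndarray]
    sample_rate: float | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.channels = {k: np.asarray(v, dtype=float) for k, v in self.channels.items()}
        if self.time.ndim != 1:
            raise InvalidParameterError("time must be one-dimensional")
        if np.any(np.diff(self.time) <= 0):
            raise InvalidParameterError("timestamps must be strictly increasing")
        for name, values in self.channels.items():
            if values.shape != self.time.shape:
                raise InvalidParameterError(
                    f"channel {name!r} length {values.shape} != time length {self.time.shape}"
                )

    def __len__(self) -> int:
        return self.time.size

    @property
    def duration(self) -> float:
        """Recording span in seconds (first to last sample)."""
        if self.time.size == 0:
            return 0.0
        return float(self.time[-1] - self.time[0])

    def copy(self) -> "PhysioRecording":
        return PhysioRecording(
            time=self.time.copy(),
            channels={k: v.copy() for k, v in self.channels.items()},
            sample_rate=self.sample_rate,
        )


@dataclass
class IndexSeries:
    """A uniformly sampled derived series at a named temporal resolution.

    ``values`` uses NaN for missing samples; correlation indices (RAP, PRx)
    are bounded to [-1, 1] where present.
    """

    name: str
    time: np.ndarray
    values: np.ndarray
    resolution: str

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.time.shape != self.values.shape:
            raise InvalidParameterError("time and values must have equal length")
        if self.resolution not in RESOLUTION_SECONDS:
            raise InvalidParameterError(
                f"unknown resolution {self.resolution!r}; expected one of {sorted(RESOLUTION_SECONDS)}"
            )
        if self.time.size >= 2:
            # grid-aligned: spacing is a positive integer multiple of the
            # resolution step (gaps from removed rows are permitted; a clean
            # export with artifact rows deleted is still on the grid)
            step = RESOLUTION_SECONDS[self.resolution]
            dt = np.diff(self.time)
            multiples = dt / step
            if np.any(dt <= 0) or not np.allclose(multiples, np.round(multiples), atol=1e-6):
                raise InvalidParameterError(
                    f"timestamps of a {self.resolution} series must lie on a {step}-s grid"
                )

    def __len__(self) -> int:
        return self.time.size

    @property
    def step_seconds(self) -> float:
        return RESOLUTION_SECONDS[self.resolution]

    @property
    def valid(self) -> np.ndarray:
        """Boolean array, True where the sample is present (non-NaN)."""
        return ~np.isnan(self.values)

    def dropna(self) -> np.ndarray:
        """Non-missing values as a plain array."""
        return self.values[self.valid]

    def copy(self) -> "IndexSeries":
        return IndexSeries(self.name, self.time.copy(), self.values.copy(), self.resolution)


@dataclass
class ArtifactMask:
    """Boolean artifact labels aligned 1:1 with a recording or index series."""

    time: np.ndarray
    flags: np.ndarray
    provenance: str = "ground_truth"

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.flags = np.asarray(self.flags, dtype=bool)
        if self.time.shape != self.flags.shape:
            raise InvalidParameterError("mask flags must align 1:1 with the time base")
        if self.provenance not in ("ground_truth", "detected"):
            raise InvalidParameterError("provenance must be 'ground_truth' or 'detected'")

    def __len__(self) -> int:
        return self.flags.size

    @property
    def n_artifact(self) -> int:
        return int(self.flags.sum())

    def segments(self) -> list[tuple[int, int]]:
        """Maximal runs of True flags as half-open index ranges [start, stop)."""
        out: list[tuple[int, int]] = []
        flags = self.flags
        idx = np.flatnonzero(np.diff(np.concatenate(([False], flags, [False])).astype(int)))
        for start, stop in zip(idx[::2], idx[1::2]):
            out.append((int(start), int(stop)))
        return out
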