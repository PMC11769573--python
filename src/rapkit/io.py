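"""CSV I/O for recordings and index series, and clean/non-clean alignment.

The on-disk dialect follows bedside monitoring exports: comma-separated,
header row, a time column named ``DateTime`` (epoch seconds, full float
precision, or ISO-8601 on read), one column per channel, and masks as a
0/1 column.  Missing samples are empty fields, never dropped rows.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .core import RESOLUTION_SECONDS, ArtifactMask, IndexSeries, PhysioRecording

TIME_COLUMN = "DateTime"


def write_physio_csv(recording: PhysioRecording, path: str | Path,
                     mask: ArtifactMask | None = None) -> None:
    data = {TIME_COLUMN: recording.time}
    data.update(recording.channels)
    if mask is not None:
        data["artifact"] = mask.flags.astype(int)
    pd.DataFrame(data).to_csv(path, index=False)


def _parse_time(raw: pd.Series, path: str | Path) -> np.ndarray:
    time = pd.to_numeric(raw, errors="coerce")
    if time.isna().any():
        parsed = pd.to_datetime(raw, errors="coerce", format="ISO8601")
        if parsed.isna().any():
            bad = [int(i) + 2 for i in np.flatnonzero(parsed.isna().to_numpy())[:10]]
            raise ValueError(f"{path}: unparseable timestamps at line(s) {bad}")
        time = (parsed - pd.Timestamp("1970-01-01")) / pd.Timedelta(seconds=1)
    return time.to_numpy(dtype=float)


def read_physio_csv(
    path: str | Path,
    channel_map: dict[str, str] | None = None,
    sample_rate: float | None = None,
) -> PhysioRecording:
    """Read a recording, enforcing strictly increasing timestamps.

    ``channel_map`` renames file columns to canonical channel names
    (e.g. ``{"icp[mmHg]": "ICP"}``).  The nominal sample rate is inferred
    from the median timestamp spacing when not supplied.
    """
    df = pd.read_csv(path)
    if TIME_COLUMN not in df.columns:
        raise ValueError(f"{path}: missing {TIME_COLUMN!r} column")
    time = _parse_time(df[TIME_COLUMN], path)
    dt = np.diff(time)
    if np.any(dt <= 0):
        line = int(np.flatnonzero(dt <= 0)[0]) + 3  # +1 header, +1 next row, 1-based
        raise ValueError(f"{path}: non-monotone or duplicated timestamp at line {line}")
    if channel_map:
        df = df.rename(columns=channel_map)
    channels = {
        c: df[c].to_numpy(dtype=float)
        for c in df.columns
        if c not in (TIME_COLUMN, "artifact")
    }
    if sample_rate is None and time.size >= 2:
        sample_rate = float(1.0 / np.median(dt))
    return PhysioRecording(time=time, channels=channels, sample_rate=sample_rate)


def write_index_csv(series: IndexSeries, path: str | Path) -> None:
    pd.DataFrame({TIME_COLUMN: series.time, series.name: series.values}).to_csv(
        path, index=False
    )


def read_index_csv(path: str | Path, resolution: str, name: str | None = None) -> IndexSeries:
    df = pd.read_csv(path)
    time = _parse_time(df[TIME_COLUMN], path)
    value_col = name or [c for c in df.columns if c != TIME_COLUMN][0]
    return IndexSeries(
        name=value_col,
        time=time,
        values=df[value_col].to_numpy(dtype=float),
        resolution=resolution,
    )


def align_clean_nonclean(clean: IndexSeries, nonclean: IndexSeries,
                         tolerance: float | None = None) -> ArtifactMask:
    """Ground-truth mask from a clean/non-clean pair of exports.

    Expert cleaning removes artifact samples, so any timestamp present in
    the non-clean series but absent from the clean one is an artifact.
    Timestamps match when within half the nominal sampling interval
    (override with ``tolerance``).  Clean timestamps missing from the
    non-clean series indicate mismatched exports and raise.
    """
    if tolerance is None:
        tolerance = 0.5 * RESOLUTION_SECONDS[nonclean.resolution]
    ct = np.sort(clean.time)
    present = np.zeros(len(nonclean), dtype=bool)
    if ct.size:
        idx = np.searchsorted(ct, nonclean.time)
        for shift in (0, -1):
            j = np.clip(idx + shift, 0, ct.size - 1)
            present |= np.abs(ct[j] - nonclean.time) <= tolerance
    # every clean timestamp must exist in the non-clean export
    nt = np.sort(nonclean.time)
    idx = np.searchsorted(nt, ct)
    matched = np.zeros(ct.size, dtype=bool)
    for shift in (0, -1):
        j = np.clip(idx + shift, 0, max(nt.size - 1, 0))
        matched |= np.abs(nt[j] - ct) <= tolerance
    if not matched.all():
        raise ValueError(
            f"{int((~matched).sum())} clean timestamp(s) absent from the non-clean series"
        )
    return ArtifactMask(time=nonclean.time, flags=~present, provenance="ground_truth")


def export_artifact_segments(series: IndexSeries, mask: ArtifactMask,
                             out_dir: str | Path, prefix: str = "artifact") -> list[Path]:
    """Write each maximal artifact run to its own CSV; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for k, (start, stop) in enumerate(mask.segments()):
        p = out_dir / f"{prefix}_{series.name}_{k:03d}.csv"
        pd.DataFrame(
            {TIME_COLUMN: series.time[start:stop], series.name: series.values[start:stop]}
        ).to_csv(p, index=False)
        paths.append(p)
    return paths
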