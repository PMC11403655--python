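"""Readers and writers for window time series and window metadata.

Window series use the two-column xvg-style dialect produced by pull-coordinate
outputs: whitespace-separated `time_ps  value_nm` rows, with lines starting
with `#` or `@` treated as comments.  Window metadata is a TSV with header
`window  center_nm  k_kj_mol_nm2`.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd

from .geometry import TimeSeries

__all__ = [
    "WindowMeta",
    "ParseError",
    "read_window_series",
    "write_window_series",
    "read_window_metadata",
    "write_window_metadata",
]

METADATA_COLUMNS = ("window", "center_nm", "k_kj_mol_nm2")


def load_windows(windows_dir, metadata_path):
    """Read a metadata TSV plus one series file per window.

    Series files are looked up as `<windows_dir>/<window id>.xvg`.
    Returns a list of UmbrellaWindow in metadata order.
    """
    from .wham import UmbrellaWindow  # avoid import cycle at module load

    windows_dir = Path(windows_dir)
    records = read_window_metadata(metadata_path)
    windows = []
    for rec in records:
        series_path = windows_dir / f"{rec.window}.xvg"
        if not series_path.exists():
            raise FileNotFoundError(f"missing window series file {series_path}")
        series = read_window_series(series_path)
        windows.append(
            UmbrellaWindow(rec.window, rec.center_nm, rec.k_kj_mol_nm2, series)
        )
    return windows


class ParseError(ValueError):
    """Malformed input file; message carries the path and line number."""


@dataclass(frozen=True)
class WindowMeta:
    """One umbrella window: id, restraint center (nm), spring constant
    (kJ mol^-1 nm^-2)."""

    window: str
    center_nm: float
    k_kj_mol_nm2: float


def read_window_series(path: str | os.PathLike) -> TimeSeries:
    """Parse a two-column xvg-dialect file into a TimeSeries.

    `#` and `@` prefixed lines and blank lines are skipped.  Raises
    ParseError with the offending line number on non-numeric rows or
    non-monotone times.
    """
    path = Path(path)
    times: list[float] = []
    values: list[float] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped[0] in "#@":
                continue
            fields = stripped.split()
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: expected two columns, got {stripped!r}")
            try:
                t, v = float(fields[0]), float(fields[1])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric row {stripped!r}") from exc
            if times and t <= times[-1]:
                raise ParseError(
                    f"{path}:{lineno}: time {t} not after previous time {times[-1]}"
                )
            times.append(t)
            values.append(v)
    if not times:
        raise ParseError(f"{path}: no data rows")
    return TimeSeries(times, values)


def write_window_series(path: str | os.PathLike, series: TimeSeries,
                        comment: str | None = None) -> None:
    """Write a TimeSeries in the two-column dialect, full double precision."""
    path = Path(path)
    with path.open("w") as fh:
        if comment:
            for line in comment.splitlines():
                fh.write(f"# {line}\n")
        for t, v in zip(series.times, series.values):
            fh.write(f"{float(t)!r} {float(v)!r}\n")


def read_window_metadata(path: str | os.PathLike) -> list[WindowMeta]:
    """Read the window metadata TSV.

    Window ids must be unique; spring constants must be positive.  Duplicate
    centers are allowed (two windows may legitimately share a center).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    missing = set(METADATA_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    ids = df["window"].astype(str)
    if ids.duplicated().any():
        dupes = sorted(ids[ids.duplicated()].unique())
        raise ParseError(f"{path}: duplicate window ids {dupes}")
    if (df["k_kj_mol_nm2"] <= 0).any():
        bad = df.loc[df["k_kj_mol_nm2"] <= 0, "window"].tolist()
        raise ParseError(f"{path}: non-positive spring constant for windows {bad}")
    if df["center_nm"].isna().any() or df["k_kj_mol_nm2"].isna().any():
        raise ParseError(f"{path}: missing numeric values")
    return [
        WindowMeta(str(r.window), float(r.center_nm), float(r.k_kj_mol_nm2))
        for r in df.itertuples(index=False)
    ]


def write_window_metadata(path: str | os.PathLike,
                          records: Iterable[WindowMeta]) -> None:
    records = list(records)
    df = pd.DataFrame(
        {
            "window": [r.window for r in records],
            "center_nm": [r.center_nm for r in records],
            "k_kj_mol_nm2": [r.k_kj_mol_nm2 for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False)
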