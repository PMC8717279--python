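"""Reading and normalizing GPS telemetry.

Telemetry arrives as a CSV of timestamped fixes (Movebank-style column names
by default).  This module parses it into per-animal :class:`Track` objects on
a common "study day" scale: fractional days since a configurable epoch, by
default the earliest timestamp across the loaded file.  Rows with missing or
unparseable coordinates are dropped and counted; duplicate timestamps within
an animal are resolved by a configurable policy (position averaging by
default, which is deterministic and order-independent).

Timestamps are interpreted as UTC throughout; no local-time conversion is
attempted, which avoids daylight-saving ambiguities the data cannot resolve.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, EmptyInputError

#: Movebank export column names
DEFAULT_COLUMNS = {
    "time": "timestamp",
    "lon": "location-long",
    "lat": "location-lat",
    "id": "individual-local-identifier",
}


@dataclass(frozen=True)
class TelemetryConfig:
    """How to interpret a telemetry CSV.

    Parameters
    ----------
    columns
        Mapping with keys ``time``, ``lon``, ``lat``, ``id`` naming the CSV
        columns.  Defaults to Movebank export names.
    epoch
        Calendar instant mapped to study time 0 (interpreted at 00:00 UTC if
        a date).  ``None`` (default) uses the earliest parsed timestamp in
        the file, truncated to midnight.
    duplicate_policy
        ``"average"`` (default) averages coordinates of rows sharing a
        timestamp within one animal; ``"keep-first"`` keeps the first row.
    """

    columns: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_COLUMNS))
    epoch: "pd.Timestamp | str | None" = None
    duplicate_policy: str = "average"

    def __post_init__(self):
        if self.duplicate_policy not in ("average", "keep-first"):
            raise ConfigurationError(
                f"unknown duplicate policy {self.duplicate_policy!r}")


@dataclass
class Track:
    """One animal's telemetry on the study day-scale.

    ``times`` are strictly increasing fractional days since ``epoch``;
    ``lon``/``lat`` are decimal degrees (WGS84).
    """

    animal_id: str
    times: np.ndarray
    lon: np.ndarray
    lat: np.ndarray
    epoch: "pd.Timestamp | None" = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.lon = np.asarray(self.lon, dtype=float)
        self.lat = np.asarray(self.lat, dtype=float)
        if len(self.times) == 0:
            raise EmptyInputError(f"track {self.animal_id!r} has no records")
        if not (len(self.times) == len(self.lon) == len(self.lat)):
            raise ConfigurationError("times/lon/lat length mismatch")
        if np.any(np.diff(self.times) <= 0):
            raise ConfigurationError(
                f"track {self.animal_id!r} times not strictly increasing")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def domain(self) -> tuple[float, float]:
        return float(self.times[0]), float(self.times[-1])


@dataclass(frozen=True)
class MonitoringSummary:
    animal_id: str
    n_fixes: int
    first_time: float
    last_time: float

    @property
    def span_days(self) -> float:
        return self.last_time - self.first_time


@dataclass
class LoadReport:
    """Accounting of what happened to each input row."""

    rows_total: int = 0
    rows_kept: int = 0
    rows_rejected: int = 0
    duplicates_merged: int = 0
    negative_times: int = 0

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def to_study_days(timestamps, epoch) -> np.ndarray:
    """Convert calendar timestamps to fractional days since ``epoch`` 00:00.

    The map is affine and strictly order-preserving.  Timestamps before the
    epoch yield negative study days (the caller may flag them).
    """
    ts = pd.to_datetime(pd.Series(timestamps), utc=True, format="mixed",
                        errors="coerce")
    if ts.isna().any():
        bad = int(np.flatnonzero(ts.isna().to_numpy())[0])
        raise ConfigurationError(f"unparseable timestamp at row {bad}")
    ep = pd.Timestamp(epoch)
    if ep.tzinfo is None:
        ep = ep.tz_localize("UTC")
    ep = ep.normalize()
    return ((ts - ep) / pd.Timedelta(days=1)).to_numpy()


def read_telemetry(path, config: TelemetryConfig | None = None,
                   ) -> tuple[list[Track], LoadReport]:
    """Read a telemetry CSV into one :class:`Track` per individual.

    Returns the tracks (sorted by animal id) and a :class:`LoadReport`.
    Rows with missing/unparseable coordinates are dropped and counted;
    ``kept + rejected`` always equals the input row count.
    """
    config = config or TelemetryConfig()
    cols = {**DEFAULT_COLUMNS, **dict(config.columns)}
    df = pd.read_csv(path)
    report = LoadReport(rows_total=len(df))

    missing = [c for c in (cols["time"], cols["lon"], cols["lat"], cols["id"])
               if c not in df.columns]
    if missing:
        raise ConfigurationError(f"missing required column(s): {missing}")

    lon = pd.to_numeric(df[cols["lon"]], errors="coerce")
    lat = pd.to_numeric(df[cols["lat"]], errors="coerce")
    ts = pd.to_datetime(df[cols["time"]], utc=True, format="mixed",
                        errors="coerce")
    valid = lon.notna() & lat.notna() & ts.notna()
    valid &= lat.abs() <= 90.0
    valid &= lon.abs() <= 180.0
    report.rows_rejected = int((~valid).sum())
    report.rows_kept = int(valid.sum())
    if report.rows_kept == 0:
        raise EmptyInputError(f"no valid telemetry rows in {path}")

    sub = pd.DataFrame({
        "id": df.loc[valid, cols["id"]].astype(str),
        "ts": ts[valid],
        "lon": lon[valid],
        "lat": lat[valid],
    })

    if config.epoch is not None:
        epoch = pd.Timestamp(config.epoch)
        if epoch.tzinfo is None:
            epoch = epoch.tz_localize("UTC")
        epoch = epoch.normalize()
    else:
        epoch = sub["ts"].min().normalize()

    tracks: list[Track] = []
    for animal_id, grp in sub.groupby("id", sort=True):
        grp = grp.sort_values("ts", kind="stable")
        if config.duplicate_policy == "average":
            before = len(grp)
            grp = grp.groupby("ts", as_index=False).agg(
                lon=("lon", "mean"), lat=("lat", "mean"))
            report.duplicates_merged += before - len(grp)
        else:  # keep-first
            before = len(grp)
            grp = grp.drop_duplicates("ts", keep="first")
            report.duplicates_merged += before - len(grp)
        times = to_study_days(grp["ts"], epoch)
        report.negative_times += int((times < 0).sum())
        tracks.append(Track(str(animal_id), times, grp["lon"].to_numpy(),
                            grp["lat"].to_numpy(), epoch=epoch))
    return tracks, report


def write_telemetry(tracks: Iterable[Track], path,
                    config: TelemetryConfig | None = None) -> None:
    """Write tracks back to the same CSV dialect :func:`read_telemetry` reads."""
    config = config or TelemetryConfig()
    cols = {**DEFAULT_COLUMNS, **dict(config.columns)}
    frames = []
    for tr in tracks:
        epoch = tr.epoch if tr.epoch is not None else pd.Timestamp(
            "2014-01-01", tz="UTC")
        ts = epoch + pd.to_timedelta(tr.times, unit="D")
        frames.append(pd.DataFrame({
            cols["time"]: ts.strftime("%Y-%m-%d %H:%M:%S.%f"),
            cols["lon"]: tr.lon,
            cols["lat"]: tr.lat,
            cols["id"]: tr.animal_id,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False,
                                                float_format="%.12f")


def summarize_monitoring(track: Track) -> MonitoringSummary:
    """Fix count and monitoring window for one track."""
    first, last = track.domain
    return MonitoringSummary(track.animal_id, len(track), first, last)


def monitoring_table(tracks: Sequence[Track]) -> pd.DataFrame:
    """Per-animal monitoring statistics as a DataFrame (one row per animal)."""
    rows = [summarize_monitoring(t) for t in tracks]
    return pd.DataFrame({
        "animal_id": [r.animal_id for r in rows],
        "n_fixes": [r.n_fixes for r in rows],
        "first_time": [r.first_time for r in rows],
        "last_time": [r.last_time for r in rows],
        "span_days": [r.span_days for r in rows],
    })
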