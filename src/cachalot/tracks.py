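"""Telemetry track cleaning and movement summaries.

The cleaning pipeline applies, in fixed order: de-duplication of
timestamps, the 7 km/h forward-pass speed filter, the land filter, then
season assignment and the minimum-locations rule per (individual,
season). Summaries reproduce the per-track statistics reported for
satellite-tracked sperm whales: number of locations, tracking duration
in days, cumulative great-circle distance and mean horizontal speed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geo import haversine_km
from .grids import EnvStack

log = logging.getLogger(__name__)

WET = "Wet"
DRY = "Dry"


@dataclass
class SeasonSpec:
    """Monsoon season partition of the calendar months."""

    wet_months: frozenset[int] = frozenset({12, 1, 2, 3})
    dry_months: frozenset[int] = frozenset({4, 5, 6, 7, 8, 9, 10, 11})

    def __post_init__(self):
        if self.wet_months & self.dry_months:
            raise ValueError("wet and dry months overlap")
        if self.wet_months | self.dry_months != set(range(1, 13)):
            raise ValueError("seasons must partition months 1-12")


def assign_season(timestamps, spec: SeasonSpec | None = None):
    """Wet/dry label for each timestamp, by calendar month."""
    spec = spec or SeasonSpec()
    ts = pd.DatetimeIndex(np.atleast_1d(pd.to_datetime(timestamps)))
    wet = np.isin(ts.month, list(spec.wet_months))
    out = np.where(wet, WET, DRY)
    return out if out.size > 1 else out.item()


def _check_track_frame(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True)
    if np.any(np.abs(df["lon"]) > 180) or np.any(np.abs(df["lat"]) > 90):
        raise ValueError("coordinates outside valid range")
    return df.sort_values("timestamp", kind="stable").reset_index(drop=True)


def dedupe_fixes(df: pd.DataFrame) -> pd.DataFrame:
    """Drop later fixes sharing a timestamp with an earlier one."""
    df = _check_track_frame(df)
    dup = df["timestamp"].duplicated(keep="first")
    if dup.any():
        log.info("dropped %d duplicate-timestamp fixes", int(dup.sum()))
    return df.loc[~dup].reset_index(drop=True)


def speed_filter(df: pd.DataFrame, vmax_kmh: float = 7.0) -> pd.DataFrame:
    """Sequential forward-pass speed filter.

    Walks the time-ordered fixes of one individual keeping the first fix,
    then each subsequent fix only if the speed implied from the *last
    retained* fix is at most ``vmax_kmh``. Idempotent and order-preserving.
    """
    df = dedupe_fixes(df)
    if len(df) <= 1:
        return df
    t = df["timestamp"].astype("int64").to_numpy() / 3.6e12  # hours
    lon = df["lon"].to_numpy()
    lat = df["lat"].to_numpy()
    keep = [0]
    last = 0
    for i in range(1, len(df)):
        dt = t[i] - t[last]
        if dt <= 0:
            log.info("dropping fix %d with non-positive time step", i)
            continue
        dist = float(haversine_km(lon[last], lat[last], lon[i], lat[i]))
        if dist / dt <= vmax_kmh:
            keep.append(i)
            last = i
    return df.iloc[keep].reset_index(drop=True)


def land_filter(df: pd.DataFrame, stack: EnvStack,
                bathy_layer: str = "bathymetry",
                off_grid: str = "drop") -> pd.DataFrame:
    """Remove fixes whose nearest cell has elevation >= 0 (sea is negative).

    Off-grid fixes are dropped with a warning by default (``off_grid="keep"``
    retains them).
    """
    if df.empty:
        return df.reset_index(drop=True)
    rows, cols, valid = stack.nearest_index(df["lon"].to_numpy(), df["lat"].to_numpy())
    elev = stack[bathy_layer][rows, cols]
    on_sea = valid & (elev < 0)
    if (~valid).any():
        log.warning("%d fixes fall outside the bathymetry grid", int((~valid).sum()))
        if off_grid == "keep":
            on_sea = on_sea | ~valid
    return df.loc[on_sea].reset_index(drop=True)


def eligible_tracks(df: pd.DataFrame, min_locations: int = 10,
                    season_spec: SeasonSpec | None = None) -> pd.DataFrame:
    """Keep (individual, season) groups with at least ``min_locations`` fixes.

    Adds a ``season`` column if absent; groups with strictly fewer fixes
    than the minimum are discarded whole.
    """
    df = df.copy()
    if "season" not in df.columns:
        df["season"] = assign_season(df["timestamp"], season_spec)
    counts = df.groupby(["id", "season"])["timestamp"].transform("size")
    return df.loc[counts >= min_locations].reset_index(drop=True)


@dataclass
class TrackSummary:
    id: str
    season: str
    n_locations: int
    duration_days: float
    distance_km: float
    speed_kmh: float | None = None

    def as_dict(self):
        return {
            "id": self.id, "season": self.season, "n_locations": self.n_locations,
            "duration_days": self.duration_days, "distance_km": self.distance_km,
            "speed_kmh": self.speed_kmh,
        }


def summarize_track(df: pd.DataFrame, season: str,
                    speed_mode: str = "legwise") -> TrackSummary:
    """Movement summary of one individual's fixes within one season.

    distance = sum of consecutive great-circle legs; speed is the mean of
    legwise speeds by default (``speed_mode="overall"`` uses total
    distance over total duration instead). A single fix yields zero
    duration/distance and an undefined (None) speed.
    """
    df = _check_track_frame(df)
    ident = str(df["id"].iloc[0]) if "id" in df.columns else ""
    n = len(df)
    if n < 2:
        return TrackSummary(ident, season, n, 0.0, 0.0, None)
    legs = haversine_km(df["lon"].to_numpy()[:-1], df["lat"].to_numpy()[:-1],
                        df["lon"].to_numpy()[1:], df["lat"].to_numpy()[1:])
    dt_h = np.diff(df["timestamp"].astype("int64").to_numpy()) / 3.6e12
    duration_days = float((df["timestamp"].iloc[-1] - df["timestamp"].iloc[0])
                          / pd.Timedelta(days=1))
    distance = float(legs.sum())
    ok = dt_h > 0
    if speed_mode == "legwise":
        speed = float(np.mean(legs[ok] / dt_h[ok])) if ok.any() else 0.0
    elif speed_mode == "overall":
        speed = distance / (duration_days * 24.0) if duration_days > 0 else 0.0
    else:
        raise ValueError(f"unknown speed_mode {speed_mode!r}")
    return TrackSummary(ident, season, n, duration_days, distance, speed)


def summarize_all(df: pd.DataFrame, season_spec: SeasonSpec | None = None,
                  speed_mode: str = "legwise") -> pd.DataFrame:
    """Per-(individual, season) summaries as a tidy frame."""
    df = df.copy()
    if "season" not in df.columns:
        df["season"] = assign_season(df["timestamp"], season_spec)
    rows = [
        summarize_track(g, season, speed_mode).as_dict()
        for (ident, season), g in df.groupby(["id", "season"], sort=True)
    ]
    return pd.DataFrame(rows)


SUMMARY_COLUMNS = ["n_locations", "duration_days", "distance_km", "speed_kmh"]


def season_means(summaries: pd.DataFrame,
                 columns: list[str] | None = None) -> pd.DataFrame:
    """Per-season mean and sample SD of the summary columns.

    With a single summary in a season the SD is undefined and reported
    as NaN. Mirrors the means ± SD rows appended to per-whale movement
    tables.
    """
    columns = columns or SUMMARY_COLUMNS
    out = []
    for season, g in summaries.groupby("season", sort=True):
        row: dict = {"season": season, "n_tracks": len(g)}
        for c in columns:
            vals = g[c].astype(float).dropna()
            row[f"{c}_mean"] = float(vals.mean())
            row[f"{c}_sd"] = float(vals.std(ddof=1)) if len(vals) > 1 else np.nan
        out.append(row)
    return pd.DataFrame(out)


def distance_from_origin(df: pd.DataFrame, origin: tuple[float, float]) -> pd.DataFrame:
    """Time series of great-circle distance (km) from a tagging origin."""
    df = _check_track_frame(df)
    d = haversine_km(origin[0], origin[1], df["lon"].to_numpy(), df["lat"].to_numpy())
    return pd.DataFrame({"timestamp": df["timestamp"], "distance_km": d})


def departure_date(series: pd.DataFrame, threshold_km: float = 100.0,
                   sustain_days: float = 2.0):
    """First time the distance series exceeds a threshold and stays above it.

    The excursion must remain above ``threshold_km`` for at least
    ``sustain_days`` (all observed fixes in that window above threshold,
    and the window actually spanning the sustain duration or reaching the
    end of the series while above). Returns the timestamp or None.
    """
    if series.empty:
        raise ValueError("empty distance series")
    t = series["timestamp"].reset_index(drop=True)
    d = series["distance_km"].reset_index(drop=True)
    above = (d > threshold_km).to_numpy()
    n = len(d)
    i = 0
    while i < n:
        if not above[i]:
            i += 1
            continue
        j = i
        while j < n and above[j]:
            j += 1
        span_days = (t[j - 1] - t[i]) / pd.Timedelta(days=1)
        if span_days >= sustain_days or j == n:
            return t[i]
        i = j
    return None
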