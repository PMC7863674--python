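"""Binned dive-summary decoding and diel behaviour analysis.

Wildlife-Computers-style summary messages bin maximum dive depth at
100 m edges (14th bin open-ended above 1,300 m) and maximum duration at
5 min edges (open above 65 min). Each record is classified day or night
from the solar elevation at its time and position, and diel differences
in deep-dive depth (and duration) are tested with a rank-based
(Kruskal-Wallis) two-group test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import kruskal

from .solar import solar_elevation

DEPTH_EDGE_M = 100.0
DEPTH_TOP_BIN = 14          # > 1,300 m
DURATION_EDGE_MIN = 5.0
DURATION_TOP_BIN = 14       # > 65 min
#: plotting/mean proxies for the open-ended top bins
DEPTH_TOP_MID = 1400.0
DURATION_TOP_MID = 70.0


def decode_depth_bin(index: int) -> tuple[float, float]:
    """Half-open depth interval (lower, upper] in metres for bin 1-14.

    Bin labels are taken as upper edges (bin k < 14 covers
    ((k-1)*100, k*100]); bin 14 is the open interval (1300, inf).
    """
    if not 1 <= index <= DEPTH_TOP_BIN:
        raise ValueError(f"depth bin index {index} outside 1..{DEPTH_TOP_BIN}")
    if index == DEPTH_TOP_BIN:
        return ((DEPTH_TOP_BIN - 1) * DEPTH_EDGE_M, np.inf)
    return ((index - 1) * DEPTH_EDGE_M, index * DEPTH_EDGE_M)


def decode_duration_bin(index: int) -> tuple[float, float]:
    """Half-open duration interval (lower, upper] in minutes for bin 1-14."""
    if not 1 <= index <= DURATION_TOP_BIN:
        raise ValueError(f"duration bin index {index} outside 1..{DURATION_TOP_BIN}")
    if index == DURATION_TOP_BIN:
        return ((DURATION_TOP_BIN - 1) * DURATION_EDGE_MIN, np.inf)
    return ((index - 1) * DURATION_EDGE_MIN, index * DURATION_EDGE_MIN)


def encode_depth(depth_m) -> np.ndarray:
    """Bin index (1-14) containing each positive depth."""
    d = np.asarray(depth_m, dtype=float)
    if np.any(d <= 0):
        raise ValueError("depths must be positive")
    return np.minimum(np.ceil(d / DEPTH_EDGE_M).astype(int), DEPTH_TOP_BIN)


def encode_duration(duration_min) -> np.ndarray:
    """Bin index (1-14) containing each positive duration."""
    d = np.asarray(duration_min, dtype=float)
    if np.any(d <= 0):
        raise ValueError("durations must be positive")
    return np.minimum(np.ceil(d / DURATION_EDGE_MIN).astype(int), DURATION_TOP_BIN)


def bin_midpoint(index, kind: str = "depth") -> np.ndarray:
    """Bin midpoints; the open top bins use 1,400 m / 70 min proxies."""
    idx = np.asarray(index, dtype=int)
    if kind == "depth":
        mid = (idx - 0.5) * DEPTH_EDGE_M
        return np.where(idx >= DEPTH_TOP_BIN, DEPTH_TOP_MID, mid)
    mid = (idx - 0.5) * DURATION_EDGE_MIN
    return np.where(idx >= DURATION_TOP_BIN, DURATION_TOP_MID, mid)


def classify_day_night(times, lons, lats, twilight_elevation: float = 0.0):
    """"day" where solar elevation strictly exceeds the threshold.

    The default threshold 0° is sunrise/sunset (elevation exactly zero
    counts as night); pass -6 for a civil-twilight day definition.
    """
    elev = solar_elevation(times, lons, lats)
    out = np.where(elev > twilight_elevation, "day", "night")
    return out if out.size > 1 else out.item()


@dataclass
class DielSummary:
    """Per-phase dive statistics and the diel rank-test results."""

    n_day: int
    n_night: int
    depth_mean_day: float
    depth_mean_night: float
    depth_median_day: float
    depth_median_night: float
    depth_statistic: float
    depth_p_value: float
    duration_mean_day: float | None = None
    duration_mean_night: float | None = None
    duration_statistic: float | None = None
    duration_p_value: float | None = None
    prop_short: float | None = None
    prop_long: float | None = None
    deep_threshold_m: float | None = None


def _phase_column(records: pd.DataFrame, twilight_elevation: float) -> pd.Series:
    if "phase" in records.columns:
        return records["phase"]
    return pd.Series(
        classify_day_night(records["timestamp"], records["lon"].to_numpy(),
                           records["lat"].to_numpy(), twilight_elevation),
        index=records.index)


def diel_depth_test(records: pd.DataFrame, deep_threshold_m: float = 200.0,
                    twilight_elevation: float = 0.0,
                    duration_subset: str = "all") -> DielSummary:
    """Diel comparison of maximum dive depth (and duration).

    Depths are restricted to deep dives (> ``deep_threshold_m``) before
    the rank test; the duration test uses all dives by default
    (``duration_subset="deep"`` restricts it the same way). Requires at
    least 3 deep dives per phase.
    """
    rec = records.copy()
    rec["phase"] = _phase_column(rec, twilight_elevation)
    deep = rec.loc[rec["depth_m"] > deep_threshold_m]
    day = deep.loc[deep["phase"] == "day", "depth_m"].to_numpy()
    night = deep.loc[deep["phase"] == "night", "depth_m"].to_numpy()
    if len(day) < 3 or len(night) < 3:
        raise ValueError("need at least 3 deep dives in each diel phase")
    if len(day) == len(night) and np.allclose(np.sort(day), np.sort(night)):
        stat, p = 0.0, 1.0
    else:
        stat, p = kruskal(day, night)

    dur_rec = deep if duration_subset == "deep" else rec
    dday = dur_rec.loc[dur_rec["phase"] == "day", "duration_min"].dropna().to_numpy()
    dnight = dur_rec.loc[dur_rec["phase"] == "night", "duration_min"].dropna().to_numpy()
    if len(dday) >= 3 and len(dnight) >= 3:
        if len(dday) == len(dnight) and np.allclose(np.sort(dday), np.sort(dnight)):
            dstat, dp = 0.0, 1.0
        else:
            dstat, dp = kruskal(dday, dnight)
        dmd, dmn = float(dday.mean()), float(dnight.mean())
    else:
        dstat = dp = dmd = dmn = None

    return DielSummary(
        n_day=len(day), n_night=len(night),
        depth_mean_day=float(day.mean()), depth_mean_night=float(night.mean()),
        depth_median_day=float(np.median(day)),
        depth_median_night=float(np.median(night)),
        depth_statistic=float(stat), depth_p_value=float(p),
        duration_mean_day=dmd, duration_mean_night=dmn,
        duration_statistic=dstat, duration_p_value=dp,
        deep_threshold_m=deep_threshold_m,
    )


def dive_summary(records: pd.DataFrame, short_max_min: float = 10.0,
                 long_range_min: tuple[float, float] = (40.0, 60.0),
                 twilight_elevation: float = 0.0) -> dict:
    """Duration-profile proportions and per-phase means.

    ``prop_short`` is the fraction of dives shorter than 10 min;
    ``prop_long`` the fraction between 40 and 60 min inclusive. When only
    bin indices are available (column ``duration_bin``), bin midpoints
    stand in for values.
    """
    if records.empty:
        raise ValueError("no dive records")
    rec = records.copy()
    if "duration_min" not in rec.columns and "duration_bin" in rec.columns:
        rec["duration_min"] = bin_midpoint(rec["duration_bin"], "duration")
    if "depth_m" not in rec.columns and "depth_bin" in rec.columns:
        rec["depth_m"] = bin_midpoint(rec["depth_bin"], "depth")
    rec["phase"] = _phase_column(rec, twilight_elevation)
    dur = rec["duration_min"].dropna()
    lo, hi = long_range_min
    out = {
        "n": int(len(rec)),
        "prop_short": float((dur < short_max_min).mean()),
        "prop_long": float(((dur >= lo) & (dur <= hi)).mean()),
        "duration_mean": float(dur.mean()),
    }
    for phase in ("day", "night"):
        sub = rec.loc[rec["phase"] == phase]
        out[f"n_{phase}"] = int(len(sub))
        if len(sub):
            out[f"depth_mean_{phase}"] = float(sub["depth_m"].mean())
            out[f"duration_mean_{phase}"] = float(sub["duration_min"].mean())
    return out
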