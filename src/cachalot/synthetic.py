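"""Synthetic study system: environmental fields, a known suitability
surface, suitability-biased whale tracks and diel dive records.

Everything downstream (filtering, home ranges, pseudo-absence SDMs, diel
tests) is exercised against data from this module, where the truth is
known by construction:

* covariate layers are spatially autocorrelated Gaussian random fields
  (smoothed white noise) on a 0.08° grid around the Mascarene islands;
* habitat suitability is an explicit logistic function of 0-1 scaled
  layers, so parameter-recovery tests have an exact target;
* tracks are biased correlated random walks at sperm-whale travel speed
  (~2-4 km/h) with irregular sampling, isotropic location noise and
  occasional implausible jump outliers;
* dive records are two-component depth/duration mixtures with distinct
  day and night deep modes.

Every generator is deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.special import expit

from .envlayers import add_slope_layer
from .geo import KM_PER_DEGREE
from .grids import EnvStack
from .solar import solar_elevation

# defaults place the grid over the south-west Indian Ocean study region
DEFAULT_EXTENT = (55.0, 63.0, -24.0, -16.0)  # lon_min, lon_max, lat_min, lat_max

#: layer name -> (correlation length in cells, (low, high) value range)
DEFAULT_LAYERS: dict[str, tuple[float, tuple[float, float]]] = {
    "sst": (8.0, (22.0, 29.0)),            # °C
    "ssh": (10.0, (-0.3, 0.4)),            # m
    "u": (6.0, (-0.5, 0.5)),               # m/s eastward
    "v": (6.0, (-0.5, 0.5)),               # m/s northward
    "velocity": (6.0, (0.0, 0.7)),         # m/s
    "mld": (8.0, (10.0, 80.0)),            # m
    "bottom_temperature": (10.0, (1.0, 5.0)),  # °C
    "bathymetry": (6.0, (-4500.0, -200.0)),    # m, negative = depth
}


#: default loadings of layers on a shared large-scale latent field; SSH and
#: bottom temperature co-vary through thermocline/steric structure, which is
#: also what lets a 2-D PCA background capture the niche-defining gradient
DEFAULT_SHARED_LATENT = {"ssh": 0.8, "bottom_temperature": -0.8}


@dataclass
class EnvFieldSpec:
    """Recipe for one stack of co-registered random covariate fields."""

    extent: tuple[float, float, float, float] = DEFAULT_EXTENT
    cell_size: float = 0.08
    layers: dict[str, tuple[float, tuple[float, float]]] = field(
        default_factory=lambda: dict(DEFAULT_LAYERS))
    shared_latent: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SHARED_LATENT))
    latent_corr_length: float = 6.0
    n_islands: int = 2
    include_slope: bool = True
    season: str | None = None
    seed: int = 0

    def __post_init__(self):
        lon0, lon1, lat0, lat1 = self.extent
        if lon1 <= lon0 or lat1 <= lat0 or self.cell_size <= 0:
            raise ValueError("degenerate grid extent")
        if len(set(self.layers)) != len(self.layers):
            raise ValueError("layer names must be unique")
        for name, (corr, (lo, hi)) in self.layers.items():
            if corr <= 0:
                raise ValueError(f"correlation length must be positive ({name})")
            if hi <= lo:
                raise ValueError(f"empty value range for layer {name}")


@dataclass
class SuitabilitySpec:
    """Logistic truth surface: expit(intercept + sum(coef * scaled layer))."""

    intercept: float = 0.0
    coefficients: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.coefficients and not any(v != 0 for v in self.coefficients.values()):
            raise ValueError("at least one coefficient must be nonzero")


@dataclass
class TrackSimSpec:
    """Biased correlated random walk parameters for simulated whales."""

    n_individuals: int = 6
    fixes_per_day: int = 8
    mean_speed_kmh: float = 2.9       # wet-season travel speed scale
    speed_cv: float = 0.35            # dispersion of per-step speeds
    turning_kappa: float = 4.0        # von Mises concentration of turns
    bias_weight: float = 0.7          # 0 = pure CRW, 1 = pure gradient ascent
    noise_km: float = 0.5             # isotropic location error SD
    outlier_prob: float = 0.02
    outlier_km: float = 80.0          # implausible-jump magnitude
    start_date: str = "2018-12-01"
    duration_days: int = 30
    max_speed_kmh: float = 5.5        # truncation keeping honest fixes < 7 km/h
    seed: int = 0

    def __post_init__(self):
        if self.mean_speed_kmh <= 0:
            raise ValueError("mean speed must be positive")
        if not 0.0 <= self.outlier_prob <= 1.0:
            raise ValueError("outlier probability must be in [0, 1]")


@dataclass
class DiveSimSpec:
    """Two-component diel mixtures for maximum dive depth and duration.

    Deep-mode depth means default to the observed day/night means of
    1,146 m and 816 m; durations mix a short (<10 min) and a long mode
    so that about 20% of dives are short and the overall mean sits near
    34 min.
    """

    day_deep_mean: float = 1146.0
    day_deep_sd: float = 200.0
    night_deep_mean: float = 816.0
    night_deep_sd: float = 200.0
    day_shallow_mean: float = 80.0
    day_shallow_sd: float = 35.0
    night_shallow_mean: float = 70.0
    night_shallow_sd: float = 30.0
    prop_shallow: float = 0.45
    short_dur_mean: float = 7.0
    short_dur_sd: float = 2.0
    long_dur_mean: float = 41.0
    long_dur_sd: float = 8.0
    prop_short: float = 0.20
    lon: float = 57.5
    lat: float = -20.3
    start_date: str = "2016-05-01"
    duration_days: int = 60
    n_records: int = 500
    seed: int = 0

    def __post_init__(self):
        for v in (self.day_deep_mean, self.night_deep_mean,
                  self.day_shallow_mean, self.night_shallow_mean):
            if v <= 0:
                raise ValueError("depth means must be positive")
        for p in (self.prop_shallow, self.prop_short):
            if not 0.0 <= p <= 1.0:
                raise ValueError("proportions must be in [0, 1]")


# --------------------------------------------------------------------------
# environmental fields

def _unit_field(rng: np.random.Generator, shape, corr_cells: float) -> np.ndarray:
    """Smoothed white noise rescaled to unit pointwise variance.

    Smoothing unit white noise with a Gaussian of scale sigma leaves a
    pointwise standard deviation of 1/(2*sqrt(pi)*sigma) in 2-D.
    """
    smooth = gaussian_filter(rng.standard_normal(shape), sigma=corr_cells,
                             mode="reflect")
    return smooth * (2.0 * np.sqrt(np.pi) * corr_cells)


def _to_range(z: np.ndarray, corr_cells: float,
              value_range: tuple[float, float]) -> np.ndarray:
    """Map a unit-variance field into ``value_range``.

    The amplitude shrinks with the correlation length (tanh(z/sigma)), so
    longer correlation lengths yield smoother *and flatter* fields —
    variance goes to zero in the infinite-correlation limit — while the
    soft clip keeps every value inside the range.
    """
    lo, hi = value_range
    mid, half = 0.5 * (lo + hi), 0.5 * (hi - lo)
    return mid + half * np.tanh(z / corr_cells)


def generate_env_stack(spec: EnvFieldSpec) -> EnvStack:
    """Generate a stack of spatially autocorrelated covariate layers.

    The bathymetry layer gets island-like shallow features (Gaussian
    seamounts breaking the surface) so land filtering is exercisable.
    If requested, a slope layer is derived from the synthetic bathymetry
    exactly as it would be from a real grid.
    """
    lon0, lon1, lat0, lat1 = spec.extent
    lon = np.arange(lon0 + spec.cell_size / 2, lon1, spec.cell_size)
    lat = np.arange(lat0 + spec.cell_size / 2, lat1, spec.cell_size)
    if lon.size == 0 or lat.size == 0:
        raise ValueError("degenerate grid extent: zero cells")
    shape = (lat.size, lon.size)
    rng = np.random.default_rng(spec.seed)
    latent = _unit_field(rng, shape, spec.latent_corr_length)
    layers: dict[str, np.ndarray] = {}
    for name, (corr, vrange) in spec.layers.items():
        own = _unit_field(rng, shape, corr)
        rho = float(spec.shared_latent.get(name, 0.0))
        z = rho * latent + np.sqrt(1.0 - rho * rho) * own
        layers[name] = _to_range(z, corr, vrange)
    if "bathymetry" in layers and spec.n_islands > 0:
        bathy = layers["bathymetry"]
        rows, cols = np.indices(shape)
        for _ in range(spec.n_islands):
            r0 = rng.uniform(0.25, 0.75) * shape[0]
            c0 = rng.uniform(0.25, 0.75) * shape[1]
            sigma = rng.uniform(2.0, 4.0)
            bump = np.exp(-((rows - r0) ** 2 + (cols - c0) ** 2) / (2 * sigma**2))
            peak = 300.0 - bathy[int(r0), int(c0)]
            bathy += peak * bump
        layers["bathymetry"] = bathy
    stack = EnvStack(lon=lon, lat=lat, layers=layers, season=spec.season)
    if spec.include_slope and "bathymetry" in stack:
        add_slope_layer(stack)
    return stack


def true_suitability(stack: EnvStack, spec: SuitabilitySpec) -> np.ndarray:
    """Cellwise logistic suitability on 0-1 scaled layers.

    Each layer named in the coefficients is min-max scaled over the grid
    before entering the linear predictor, matching how the SDM design is
    scaled; the output is a probability grid in [0, 1].
    """
    eta = np.full(stack.shape, float(spec.intercept))
    for name, coef in spec.coefficients.items():
        if name not in stack:
            raise KeyError(f"suitability references unknown layer {name!r}")
        layer = stack[name]
        finite = layer[np.isfinite(layer)]
        lo, hi = finite.min(), finite.max()
        scaled = (layer - lo) / (hi - lo) if hi > lo else np.zeros_like(layer)
        eta = eta + coef * scaled
    return expit(eta)


# --------------------------------------------------------------------------
# tracks

@dataclass
class Track:
    """One individual's ordered telemetry fixes plus tag metadata."""

    id: str
    fixes: pd.DataFrame  # columns: timestamp, lon, lat (+ outlier flag here)
    sex: str = "Female"
    instrument: str = "SPLASH10"

    def __post_init__(self):
        if len(self.fixes) < 1:
            raise ValueError("a track needs at least one fix")


def _suitability_gradient(stack: EnvStack, suit: np.ndarray):
    """Per-cell gradient direction of suitability in the east/north frame."""
    dy_km = (stack.lat[1] - stack.lat[0]) * KM_PER_DEGREE if stack.lat.size > 1 else 1.0
    dx_km = (stack.lon[1] - stack.lon[0]) * KM_PER_DEGREE * np.cos(
        np.radians(stack.lat.mean()))
    gy, gx = np.gradient(suit, dy_km, dx_km)
    return gx, gy


def generate_tracks(stack: EnvStack, suit: np.ndarray, spec: TrackSimSpec,
                    start_lonlat: tuple[float, float] | None = None) -> list[Track]:
    """Simulate suitability-biased correlated random walks.

    Headings follow a wrapped (von Mises) turn process mixed toward the
    local suitability-gradient direction with weight ``bias_weight``.
    Recorded fixes carry isotropic Gaussian noise and, with probability
    ``outlier_prob``, an implausible jump of ``outlier_km``. Steps that
    would land on land (bathymetry >= 0) or off-grid are re-drawn.
    """
    if suit.shape != stack.shape:
        raise ValueError("suitability grid not co-registered with the stack")
    rng = np.random.default_rng(spec.seed)
    bathy = stack["bathymetry"] if "bathymetry" in stack else np.full(stack.shape, -1.0)
    ocean = bathy < 0
    gx, gy = _suitability_gradient(stack, suit)
    glon, glat = stack.cell_centres()
    # candidate starts: ocean cells in the upper suitability half
    cand = ocean & (suit >= np.median(suit[ocean]))
    cand_idx = np.flatnonzero(cand)
    if start_lonlat is not None:
        r, c, ok = stack.nearest_index([start_lonlat[0]], [start_lonlat[1]])
        if not ok[0] or bathy[r[0], c[0]] >= 0:
            raise ValueError("start position is on land or off-grid")

    dt_h = 24.0 / spec.fixes_per_day
    n_steps = int(spec.duration_days * spec.fixes_per_day)
    shape_k = 1.0 / spec.speed_cv**2
    start = pd.Timestamp(spec.start_date, tz="UTC")
    tracks: list[Track] = []
    for i in range(spec.n_individuals):
        if start_lonlat is None:
            j = cand_idx[rng.integers(cand_idx.size)]
            lon, lat = glon.ravel()[j], glat.ravel()[j]
        else:
            lon, lat = start_lonlat
        heading = rng.uniform(-np.pi, np.pi)
        # irregular sampling first, so each step spans its actual interval
        offsets = (np.arange(n_steps) + rng.uniform(-0.2, 0.2, n_steps)) * dt_h
        offsets[0] = 0.0
        offsets = np.sort(offsets)
        dts = np.diff(offsets)
        lons, lats = [lon], [lat]
        for k in range(n_steps - 1):
            speed = rng.gamma(shape_k, spec.mean_speed_kmh / shape_k)
            speed = float(np.clip(speed, 0.2, spec.max_speed_kmh))
            step_km = speed * dts[k]
            turn = rng.vonmises(0.0, spec.turning_kappa)
            crw = heading + turn
            r, c, ok = stack.nearest_index([lon], [lat])
            gvec = np.array([gx[r[0], c[0]], gy[r[0], c[0]]]) if ok[0] else np.zeros(2)
            if np.hypot(*gvec) > 0 and spec.bias_weight > 0:
                unit_crw = np.array([np.cos(crw), np.sin(crw)])
                unit_g = gvec / np.hypot(*gvec)
                mix = (1 - spec.bias_weight) * unit_crw + spec.bias_weight * unit_g
                new_heading = np.arctan2(mix[1], mix[0])
            else:
                new_heading = crw
            placed = False
            for attempt in range(12):
                h = new_heading if attempt == 0 else rng.uniform(-np.pi, np.pi)
                dlat = step_km * np.sin(h) / KM_PER_DEGREE
                dlon = step_km * np.cos(h) / (KM_PER_DEGREE * np.cos(np.radians(lat)))
                nlon, nlat = lon + dlon, lat + dlat
                r, c, ok = stack.nearest_index([nlon], [nlat])
                if ok[0] and bathy[r[0], c[0]] < 0:
                    lon, lat, heading = nlon, nlat, h
                    placed = True
                    break
            if not placed:
                pass  # stay put this step; next step re-tries
            lons.append(lon)
            lats.append(lat)

        lons = np.asarray(lons)
        lats = np.asarray(lats)
        times = start + pd.to_timedelta(offsets, unit="h")
        # recorded positions: truth + isotropic noise (+ rare huge jumps);
        # noise clipped at 2 SD so honest consecutive fixes stay below the
        # 7 km/h plausibility bound at the default sampling rate
        noise_deg = spec.noise_km / KM_PER_DEGREE
        nclip = 2.0 * noise_deg
        elon = np.clip(rng.normal(0, noise_deg, n_steps), -nclip, nclip)
        elat = np.clip(rng.normal(0, noise_deg, n_steps), -nclip, nclip)
        rec_lon = lons + elon / np.cos(np.radians(lats))
        rec_lat = lats + elat
        is_outlier = rng.random(n_steps) < spec.outlier_prob
        is_outlier[0] = False
        if is_outlier.any():
            ang = rng.uniform(-np.pi, np.pi, int(is_outlier.sum()))
            d_deg = spec.outlier_km / KM_PER_DEGREE
            rec_lon[is_outlier] += d_deg * np.cos(ang) / np.cos(np.radians(lats[is_outlier]))
            rec_lat[is_outlier] += d_deg * np.sin(ang)
        fixes = pd.DataFrame({
            "timestamp": times, "lon": rec_lon, "lat": rec_lat,
            "true_lon": lons, "true_lat": lats, "outlier": is_outlier,
        })
        tracks.append(Track(id=f"sim{i:02d}", fixes=fixes))
    return tracks


def tracks_to_frame(tracks: list[Track]) -> pd.DataFrame:
    """Stack tracks into one tidy fix table (id, timestamp, lon, lat)."""
    frames = []
    for t in tracks:
        df = t.fixes[["timestamp", "lon", "lat"]].copy()
        df.insert(0, "id", t.id)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def tracks_to_csv(tracks: list[Track], path) -> None:
    df = tracks_to_frame(tracks)
    df["timestamp"] = df["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%SZ")
    df.to_csv(path, index=False)


# --------------------------------------------------------------------------
# dives

def generate_dive_records(spec: DiveSimSpec) -> pd.DataFrame:
    """Draw diel-phase-dependent maximum dive depths and durations.

    Timestamps are uniform over the stated date range at the spec's
    (lon, lat); the phase of each record is determined by the actual
    solar elevation there, and the depth mixture's deep/shallow modes
    switch parameters with the phase. Durations share one mixture across
    phases (matching the absence of a diel duration difference).
    """
    if spec.n_records == 0:
        return pd.DataFrame(columns=["id", "timestamp", "lon", "lat",
                                     "depth_m", "duration_min"])
    rng = np.random.default_rng(spec.seed)
    start = pd.Timestamp(spec.start_date, tz="UTC")
    offs = np.sort(rng.uniform(0, spec.duration_days * 24.0, spec.n_records))
    times = start + pd.to_timedelta(offs, unit="h")
    lons = np.full(spec.n_records, spec.lon)
    lats = np.full(spec.n_records, spec.lat)
    is_day = solar_elevation(times, lons, lats) > 0.0

    shallow = rng.random(spec.n_records) < spec.prop_shallow
    depth = np.where(
        shallow,
        np.where(is_day,
                 rng.normal(spec.day_shallow_mean, spec.day_shallow_sd, spec.n_records),
                 rng.normal(spec.night_shallow_mean, spec.night_shallow_sd, spec.n_records)),
        np.where(is_day,
                 rng.normal(spec.day_deep_mean, spec.day_deep_sd, spec.n_records),
                 rng.normal(spec.night_deep_mean, spec.night_deep_sd, spec.n_records)),
    )
    depth = np.clip(depth, 5.0, None)

    short = rng.random(spec.n_records) < spec.prop_short
    duration = np.where(
        short,
        rng.normal(spec.short_dur_mean, spec.short_dur_sd, spec.n_records),
        rng.normal(spec.long_dur_mean, spec.long_dur_sd, spec.n_records),
    )
    duration = np.clip(duration, 1.0, None)

    return pd.DataFrame({
        "id": "simdive", "timestamp": times, "lon": lons, "lat": lats,
        "depth_m": depth, "duration_min": duration,
    })
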