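"""Gridded environmental covariate stacks.

An :class:`EnvStack` holds named 2-D layers on a shared regular lon/lat
grid (cell centres, ascending coordinates). It is deliberately a thin
container: xarray handles NetCDF round-trips, and plain CSV writers
cover text-only exchange.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class EnvStack:
    """Named co-registered covariate grids for one season.

    Attributes
    ----------
    lon, lat : 1-D arrays of cell-centre coordinates (degrees, ascending).
    layers : mapping of layer name to a (nlat, nlon) float array; NaN marks
        missing cells.
    season : optional season label ("wet" / "dry").
    scaling : per-layer (min, max) recorded when a layer has been 0-1
        scaled, so the identical transform can be replayed on a
        prediction grid.
    """

    lon: np.ndarray
    lat: np.ndarray
    layers: dict[str, np.ndarray]
    season: str | None = None
    scaling: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self):
        self.lon = np.asarray(self.lon, dtype=float)
        self.lat = np.asarray(self.lat, dtype=float)
        if self.lon.size == 0 or self.lat.size == 0:
            raise ValueError("degenerate grid extent: zero cells")
        shape = (self.lat.size, self.lon.size)
        for name, arr in self.layers.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != shape:
                raise ValueError(f"layer {name!r} shape {arr.shape} != grid {shape}")
            self.layers[name] = arr

    @property
    def shape(self) -> tuple[int, int]:
        return (self.lat.size, self.lon.size)

    @property
    def cell_size(self) -> float:
        if self.lon.size > 1:
            return float(self.lon[1] - self.lon[0])
        return float(self.lat[1] - self.lat[0])

    def __contains__(self, name: str) -> bool:
        return name in self.layers

    def __getitem__(self, name: str) -> np.ndarray:
        return self.layers[name]

    def nearest_index(self, lons, lats):
        """Row/column of the nearest cell for each point, with validity.

        Points beyond half a cell outside the grid edge are invalid.
        """
        lons = np.atleast_1d(np.asarray(lons, dtype=float))
        lats = np.atleast_1d(np.asarray(lats, dtype=float))
        half = self.cell_size / 2.0
        cols = np.clip(np.searchsorted(self.lon, lons) , 0, self.lon.size - 1)
        cols = np.where(
            (cols > 0)
            & (np.abs(lons - self.lon[np.maximum(cols - 1, 0)]) < np.abs(lons - self.lon[cols])),
            cols - 1,
            cols,
        )
        rows = np.clip(np.searchsorted(self.lat, lats), 0, self.lat.size - 1)
        rows = np.where(
            (rows > 0)
            & (np.abs(lats - self.lat[np.maximum(rows - 1, 0)]) < np.abs(lats - self.lat[rows])),
            rows - 1,
            rows,
        )
        valid = (
            (lons >= self.lon[0] - half) & (lons <= self.lon[-1] + half)
            & (lats >= self.lat[0] - half) & (lats <= self.lat[-1] + half)
        )
        return rows, cols, valid

    def cell_centres(self):
        """Meshgrid of cell-centre (lon, lat), each shaped (nlat, nlon)."""
        return np.meshgrid(self.lon, self.lat)

    # ---------------------------------------------------------------- I/O
    def to_dataset(self):
        import xarray as xr

        ds = xr.Dataset(
            {name: (("lat", "lon"), arr) for name, arr in self.layers.items()},
            coords={"lat": self.lat, "lon": self.lon},
        )
        if self.season:
            ds.attrs["season"] = self.season
        for name, (mn, mx) in self.scaling.items():
            ds[name].attrs.update(scale_min=mn, scale_max=mx)
        return ds

    def to_netcdf(self, path) -> None:
        self.to_dataset().to_netcdf(path)

    @classmethod
    def from_dataset(cls, ds) -> "EnvStack":
        layers = {str(k): np.asarray(ds[k].values, dtype=float) for k in ds.data_vars}
        scaling = {
            str(k): (float(ds[k].attrs["scale_min"]), float(ds[k].attrs["scale_max"]))
            for k in ds.data_vars
            if "scale_min" in ds[k].attrs
        }
        return cls(
            lon=np.asarray(ds["lon"].values, dtype=float),
            lat=np.asarray(ds["lat"].values, dtype=float),
            layers=layers,
            season=ds.attrs.get("season"),
            scaling=scaling,
        )

    @classmethod
    def from_netcdf(cls, path) -> "EnvStack":
        import xarray as xr

        with xr.open_dataset(path) as ds:
            return cls.from_dataset(ds.load())

    def to_csv(self, path) -> None:
        """Long-format text dump: one row per cell with all layer values."""
        glon, glat = self.cell_centres()
        df = pd.DataFrame({"lon": glon.ravel(), "lat": glat.ravel()})
        for name, arr in self.layers.items():
            df[name] = arr.ravel()
        df.to_csv(path, index=False)

    def table(self, variables: list[str] | None = None) -> pd.DataFrame:
        """Cell x variable table over the grid (row-major cell order)."""
        variables = variables or list(self.layers)
        glon, glat = self.cell_centres()
        out = {"lon": glon.ravel(), "lat": glat.ravel()}
        for name in variables:
            out[name] = self.layers[name].ravel()
        return pd.DataFrame(out)
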