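"""Preparation of environmental covariate layers.

Covers the standard raster chores that sit between raw monthly ocean
products and a model-ready design: seasonal averaging, seafloor slope
from bathymetry, 0-1 scaling with a replayable record, variance-inflation
collinearity screening, point extraction and polygon masking.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .geo import KM_PER_DEGREE
from .grids import EnvStack

WET_MONTHS = frozenset({12, 1, 2, 3})
DRY_MONTHS = frozenset({4, 5, 6, 7, 8, 9, 10, 11})


def seasonal_mean(monthly: dict[int, np.ndarray], months) -> np.ndarray:
    """Cellwise mean of the monthly grids belonging to one season.

    ``monthly`` maps month number (1-12) to a grid. Cells missing (NaN)
    in some months are averaged over the months where they are present;
    cells missing everywhere stay NaN.
    """
    months = [m for m in months if m in monthly]
    if not months:
        raise ValueError("no monthly grids available for the requested season")
    stack = np.stack([np.asarray(monthly[m], dtype=float) for m in months])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        return np.nanmean(stack, axis=0)


def metres_per_cell(cell_size_deg: float, lats: np.ndarray):
    """(dx, dy) in metres for each grid row at the given latitudes."""
    dy = cell_size_deg * KM_PER_DEGREE * 1000.0
    dx = dy * np.cos(np.radians(np.asarray(lats, dtype=float)))
    return dx, dy


def slope_from_bathymetry(bathy: np.ndarray, dx_m, dy_m) -> np.ndarray:
    """Seafloor slope in degrees from a bathymetry grid in metres.

    Horn's 8-neighbour finite-difference stencil; the grid is padded by
    odd reflection (linear extrapolation), so border cells reduce to
    one-sided differences. ``dx_m`` may be a scalar or a per-row array
    (metres per cell eastward, shrinking with latitude); ``dy_m`` is the
    northward cell size in metres.
    """
    z = np.pad(np.asarray(bathy, dtype=float), 1, mode="reflect",
               reflect_type="odd")
    # Horn stencil weights (1,2,1) across the three rows/columns
    gx = (
        (z[:-2, 2:] + 2 * z[1:-1, 2:] + z[2:, 2:])
        - (z[:-2, :-2] + 2 * z[1:-1, :-2] + z[2:, :-2])
    )
    gy = (
        (z[2:, :-2] + 2 * z[2:, 1:-1] + z[2:, 2:])
        - (z[:-2, :-2] + 2 * z[:-2, 1:-1] + z[:-2, 2:])
    )
    dx = np.asarray(dx_m, dtype=float)
    if dx.ndim == 1:
        dx = dx[:, None]
    dzdx = gx / (8.0 * dx)
    dzdy = gy / (8.0 * float(np.atleast_1d(dy_m)[0]))
    return np.degrees(np.arctan(np.hypot(dzdx, dzdy)))


def add_slope_layer(stack: EnvStack, bathy_layer: str = "bathymetry",
                    name: str = "slope") -> EnvStack:
    """Derive a slope layer from the stack's bathymetry, in place."""
    dx, dy = metres_per_cell(stack.cell_size, stack.lat)
    stack.layers[name] = slope_from_bathymetry(stack[bathy_layer], dx, dy)
    return stack


def scale_unit(layer: np.ndarray):
    """Scale a layer to [0, 1]; returns (scaled, (min, max)).

    The min/max are taken over finite cells and must be stored so the
    same affine transform can be replayed on a prediction grid.
    """
    layer = np.asarray(layer, dtype=float)
    finite = layer[np.isfinite(layer)]
    if finite.size < 2 or np.ptp(finite) == 0:
        raise ValueError("constant or empty layer cannot be 0-1 scaled")
    mn, mx = float(finite.min()), float(finite.max())
    return (layer - mn) / (mx - mn), (mn, mx)


def apply_scaling(layer: np.ndarray, bounds: tuple[float, float]) -> np.ndarray:
    mn, mx = bounds
    return (np.asarray(layer, dtype=float) - mn) / (mx - mn)


def unscale(scaled: np.ndarray, bounds: tuple[float, float]) -> np.ndarray:
    mn, mx = bounds
    return np.asarray(scaled, dtype=float) * (mx - mn) + mn


def scale_stack(stack: EnvStack, variables: list[str] | None = None) -> EnvStack:
    """Return a new stack with the named layers 0-1 scaled and the
    per-layer (min, max) recorded in ``scaling``."""
    variables = variables or list(stack.layers)
    layers, scaling = {}, {}
    for name in variables:
        layers[name], scaling[name] = scale_unit(stack[name])
    return EnvStack(lon=stack.lon.copy(), lat=stack.lat.copy(), layers=layers,
                    season=stack.season, scaling=scaling)


def vif_screen(design: pd.DataFrame, threshold: float = 4.0) -> pd.DataFrame:
    """Variance inflation factors, VIF_j = 1/(1 - R²_j).

    Each column is regressed (with intercept) on the remaining columns.
    Returns a frame with columns ``variable``, ``vif``, ``pass`` where
    ``pass`` is VIF < threshold. Perfectly collinear variables come back
    with infinite VIF.
    """
    if design.shape[1] < 2:
        raise ValueError("need at least two variables for VIF")
    if design.shape[0] <= design.shape[1]:
        raise ValueError("need more rows than variables for VIF")
    rows = []
    cols = list(design.columns)
    x = design.to_numpy(dtype=float)
    for j, name in enumerate(cols):
        others = sm.add_constant(np.delete(x, j, axis=1))
        r2 = sm.OLS(x[:, j], others).fit().rsquared
        vif = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
        rows.append({"variable": name, "vif": vif, "pass": bool(vif < threshold)})
    return pd.DataFrame(rows)


def extract_at_points(stack: EnvStack, lons, lats,
                      variables: list[str] | None = None) -> pd.DataFrame:
    """Nearest-cell covariate values at each point.

    Off-grid points, and points landing on a missing cell in any layer,
    are flagged ``valid=False`` but never dropped.
    """
    variables = variables or list(stack.layers)
    lons = np.atleast_1d(np.asarray(lons, dtype=float))
    lats = np.atleast_1d(np.asarray(lats, dtype=float))
    rows, cols, valid = stack.nearest_index(lons, lats)
    out = pd.DataFrame({"lon": lons, "lat": lats})
    for name in variables:
        vals = stack[name][rows, cols]
        vals = np.where(valid, vals, np.nan)
        out[name] = vals
        valid = valid & np.isfinite(vals)
    out["valid"] = valid
    return out


def mask_by_polygon(stack: EnvStack, polygon, layer: str) -> np.ndarray:
    """Values of cells whose centres fall inside the polygon.

    ``polygon`` is a shapely geometry in lon/lat degrees. Returns a 1-D
    array of the selected cell values (NaN cells included); warns when
    the intersection is empty.
    """
    import shapely

    glon, glat = stack.cell_centres()
    inside = shapely.contains_xy(polygon, glon.ravel(), glat.ravel())
    if not inside.any():
        warnings.warn("polygon does not intersect the grid", stacklevel=2)
    return stack[layer].ravel()[inside]
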