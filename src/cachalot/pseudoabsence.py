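"""Pseudo-absence generation outside an environmental envelope.

With tracking data only presences are observed. Following the
environmental-profiling family of techniques, a correlation PCA of the
covariate background (every valid grid cell) defines a 2-D environmental
space; the region of that space occupied by the presences — their convex
hull by default, a Mahalanobis quantile ellipse as an alternative — is
deemed favourable, and pseudo-absences are drawn uniformly without
replacement from the grid cells whose scores fall *outside* it, in equal
number to the presences. Replicate runs (default 10) with derived seeds
quantify sensitivity to this sampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler

from .envlayers import extract_at_points
from .grids import EnvStack


@dataclass
class EnvBackground:
    """Two-component PCA of the standardized cell x covariate table."""

    variables: list[str]
    scaler: StandardScaler
    pca: PCA
    cells: pd.DataFrame          # lon, lat, PC1, PC2 for every valid cell
    explained: np.ndarray        # variance fractions of PC1, PC2
    season: str | None = None

    def transform(self, values: pd.DataFrame) -> np.ndarray:
        """Scores of new covariate rows in the stored (PC1, PC2) basis."""
        z = self.scaler.transform(values[self.variables].to_numpy(dtype=float))
        return self.pca.transform(z)[:, :2]


@dataclass
class Envelope:
    """Favourable region of (PC1, PC2) space fitted on presence scores."""

    method: str                   # "convex-hull" | "mahalanobis"
    geometry: object | None = None    # shapely polygon (hull method)
    mean: np.ndarray | None = None    # ellipse parameters (mahalanobis)
    cov_inv: np.ndarray | None = None
    radius2: float | None = None
    inflate: float = 0.0

    def contains(self, scores: np.ndarray) -> np.ndarray:
        scores = np.atleast_2d(scores)
        if self.method == "convex-hull":
            import shapely

            # boundary counts as inside: presence vertices sit on the hull
            return shapely.intersects_xy(self.geometry, scores[:, 0], scores[:, 1])
        d = scores - self.mean
        m2 = np.einsum("ij,jk,ik->i", d, self.cov_inv, d)
        return m2 <= self.radius2

    @property
    def area(self) -> float:
        if self.method == "convex-hull":
            return float(self.geometry.area)
        cov = np.linalg.inv(self.cov_inv)
        return float(np.pi * self.radius2 * np.sqrt(np.linalg.det(cov)))

    def describe(self) -> dict:
        out = {"method": self.method, "inflate": self.inflate, "area": self.area}
        if self.method == "convex-hull":
            out["vertices"] = list(map(list, self.geometry.exterior.coords))
        else:
            out["mean"] = self.mean.tolist()
            out["radius2"] = self.radius2
        return out


@dataclass
class PseudoAbsenceRun:
    """One replicate's pseudo-absence cells with their PC scores."""

    run: int
    seed: int
    cells: pd.DataFrame          # lon, lat, PC1, PC2
    season: str | None = None
    envelope: dict = field(default_factory=dict)


def fit_background_pca(stack: EnvStack,
                       variables: list[str] | None = None,
                       exclude_land: bool = True) -> EnvBackground:
    """Correlation PCA over the study-area grid cells.

    Cells with any missing covariate are excluded; land cells
    (bathymetry >= 0) are excluded by default since whales cannot occur
    there. Variables are standardized (zero mean, unit variance) before
    the PCA, and the first two components are retained as the
    environmental background.
    """
    variables = variables or [n for n in stack.layers if n != "bathymetry"] or list(stack.layers)
    if len(variables) < 2:
        raise ValueError("need at least two variables for a 2-D background")
    table = stack.table(variables)
    mask = np.isfinite(table[variables].to_numpy(dtype=float)).all(axis=1)
    if exclude_land and "bathymetry" in stack:
        mask &= stack["bathymetry"].ravel() < 0
    table = table.loc[mask].reset_index(drop=True)
    if len(table) < 3:
        raise ValueError("fewer than 3 valid cells: cannot fit a background")
    scaler = StandardScaler().fit(table[variables].to_numpy(dtype=float))
    z = scaler.transform(table[variables].to_numpy(dtype=float))
    pca = PCA(n_components=2, svd_solver="full").fit(z)
    scores = pca.transform(z)
    cells = table[["lon", "lat"]].copy()
    cells["PC1"] = scores[:, 0]
    cells["PC2"] = scores[:, 1]
    return EnvBackground(variables=list(variables), scaler=scaler, pca=pca,
                         cells=cells, explained=pca.explained_variance_ratio_.copy(),
                         season=stack.season)


def presence_scores(background: EnvBackground, stack: EnvStack,
                    lons, lats, unique_cells: bool = True) -> np.ndarray:
    """PC scores of presence locations via their nearest grid cell.

    Presences are snapped to cells and (by default) thinned to unique
    cells before envelope fitting, so dense track segments do not warp
    the envelope. Invalid extractions are dropped.
    """
    ext = extract_at_points(stack, lons, lats, background.variables)
    ext = ext.loc[ext["valid"]].reset_index(drop=True)
    if unique_cells:
        rows, cols, _ = stack.nearest_index(ext["lon"].to_numpy(), ext["lat"].to_numpy())
        ext = ext.loc[~pd.DataFrame({"r": rows, "c": cols}).duplicated().to_numpy()]
    return background.transform(ext)


def presence_envelope(scores: np.ndarray, method: str = "convex-hull",
                      inflate: float = 0.0, quantile: float = 0.95) -> Envelope:
    """Favourable envelope of presence scores in (PC1, PC2).

    ``convex-hull`` (default): convex hull of the scores, optionally
    inflated by scaling the hull about its centroid by (1 + inflate).
    ``mahalanobis``: ellipse at the given chi-square quantile of the
    fitted mean/covariance. Collinear scores degrade the hull to a
    buffered segment (small fixed buffer), with a warning.
    """
    import warnings

    from shapely import affinity
    from shapely.geometry import MultiPoint

    scores = np.asarray(scores, dtype=float)
    if scores.shape[0] < 3:
        raise ValueError("need at least 3 presence scores")
    if method == "convex-hull":
        hull = MultiPoint(scores).convex_hull
        if hull.geom_type != "Polygon":
            warnings.warn("collinear presence scores: buffering the segment",
                          stacklevel=2)
            hull = hull.buffer(1e-6 + 0.01 * np.ptp(scores))
        if inflate:
            hull = affinity.scale(hull, 1.0 + inflate, 1.0 + inflate)
        return Envelope(method=method, geometry=hull, inflate=inflate)
    if method == "mahalanobis":
        mean = scores.mean(axis=0)
        cov = np.cov(scores.T)
        return Envelope(method=method, mean=mean, cov_inv=np.linalg.inv(cov),
                        radius2=float(chi2.ppf(quantile, df=2)), inflate=inflate)
    raise ValueError(f"unknown envelope method {method!r}")


def draw_pseudo_absences(background: EnvBackground, envelope: Envelope,
                         n: int, seed: int, run: int = 1) -> PseudoAbsenceRun:
    """Uniform sample of ``n`` grid cells outside the envelope.

    Sampling is without replacement over cells so the pseudo-absences
    inherit exact covariate values; raises if fewer than ``n`` candidate
    cells lie outside the envelope.
    """
    scores = background.cells[["PC1", "PC2"]].to_numpy()
    outside = ~envelope.contains(scores)
    candidates = background.cells.loc[outside]
    if len(candidates) < n:
        raise ValueError(
            f"only {len(candidates)} cells outside the envelope for {n} "
            "pseudo-absences; shrink the envelope or use fewer presences")
    rng = np.random.default_rng(seed)
    pick = rng.choice(len(candidates), size=n, replace=False)
    cells = candidates.iloc[np.sort(pick)].reset_index(drop=True)
    return PseudoAbsenceRun(run=run, seed=seed, cells=cells,
                            season=background.season, envelope=envelope.describe())


def build_runs(background: EnvBackground, envelope: Envelope, n: int,
               n_runs: int = 10, master_seed: int = 0) -> list[PseudoAbsenceRun]:
    """Replicate pseudo-absence draws with per-run derived seeds."""
    seeds = np.random.SeedSequence(master_seed).generate_state(n_runs) % (2**31)
    return [
        draw_pseudo_absences(background, envelope, n, int(seeds[k]), run=k + 1)
        for k in range(n_runs)
    ]
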