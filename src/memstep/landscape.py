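"""Synthetic landscapes: covariate raster stacks with seasonal availability.

A :class:`Landscape` is a stack of ``P`` named raster layers on a shared
planar grid (kilometre coordinates, row-major arrays, origin at the
lower-left cell corner).  Layers can represent spatially autocorrelated
habitat fields (berry probability, prey density), Euclidean
distance-to-feature surfaces (riparian corridors, human settlements,
cabins), or constants.  Each layer may carry a seasonal availability
window: outside its day-of-year interval the covariate is treated as 0,
emulating resources that are only worth selecting for during part of the
active season.  Layers without a window (the anthropogenic ones) are
temporally constant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .errors import OutOfDomainError

__all__ = [
    "SeasonalWindow",
    "Landscape",
    "DEFAULT_WINDOWS",
    "generate_random_landscape",
    "default_bear_landscape",
    "distance_to_features",
    "day_of_year",
]


@dataclass(frozen=True)
class SeasonalWindow:
    """Inclusive day-of-year interval during which a resource is available."""

    start_doy: int
    end_doy: int

    def __post_init__(self) -> None:
        if not (1 <= self.start_doy <= self.end_doy <= 366):
            raise ValueError(
                f"invalid seasonal window ({self.start_doy}, {self.end_doy}): "
                "need 1 <= start <= end <= 366"
            )

    def contains(self, doy) -> np.ndarray | bool:
        doy = np.asarray(doy)
        out = (doy >= self.start_doy) & (doy <= self.end_doy)
        return bool(out) if out.ndim == 0 else out


#: Availability windows for the six standard covariates.  Berries peak from
#: August 1 to the end of the active season (Nov 30); riparian food is
#: accessible while the river is ice-free (May 10 - Oct 16); ground squirrels
#: are easiest to hunt while dormant (Sep 11 - Nov 30); sweetvetch roots give
#: the best return in early spring (Apr 1 - Jun 15).  Distances from human
#: settlements and cabins are temporally constant.
DEFAULT_WINDOWS: dict[str, SeasonalWindow | None] = {
    "berries": SeasonalWindow(213, 334),      # Aug 1 - Nov 30
    "riparian": SeasonalWindow(130, 289),     # May 10 - Oct 16
    "squirrels": SeasonalWindow(254, 334),    # Sep 11 - Nov 30
    "sweetvetch": SeasonalWindow(91, 166),    # Apr 1 - Jun 15
    "settlements": None,
    "cabins": None,
}


def day_of_year(timestamps) -> np.ndarray:
    """Day of year with leap days mapped to 366.

    In leap years, Feb 29 maps to 366 and every later date keeps the
    day-of-year it would have in a common year, so calendar windows defined
    from dates (e.g. Aug 1 = 213) are year-invariant.
    """
    ts = np.asarray(timestamps, dtype="datetime64[s]")
    scalar = ts.ndim == 0
    ts = np.atleast_1d(ts)
    years = ts.astype("datetime64[Y]")
    doy = (ts.astype("datetime64[D]") - years.astype("datetime64[D]")).astype(int) + 1
    year_num = years.astype(int) + 1970
    leap = (year_num % 4 == 0) & ((year_num % 100 != 0) | (year_num % 400 == 0))
    months = (ts.astype("datetime64[M]") - years.astype("datetime64[M]")).astype(int) + 1
    days = (ts.astype("datetime64[D]") - ts.astype("datetime64[M]").astype("datetime64[D]")).astype(int) + 1
    feb29 = leap & (months == 2) & (days == 29)
    after = leap & (months > 2)
    doy = np.where(feb29, 366, doy - after.astype(int))
    return int(doy[0]) if scalar else doy


@dataclass
class Landscape:
    """Stack of covariate rasters on a common planar grid.

    Parameters
    ----------
    origin : (float, float)
        (x, y) of the lower-left corner of the grid, in km.
    cell_size : float
        Side length of the square cells, in km (0.03 km = 30 m default).
    layers : dict[str, ndarray]
        Named ``(n_rows, n_cols)`` rasters; row 0 is the southernmost row.
    feature_sets : dict[str, ndarray]
        Point locations (``(K, 2)`` arrays, km) behind distance layers.
    windows : dict[str, SeasonalWindow | None]
        Optional availability window per layer.
    """

    origin: tuple[float, float]
    cell_size: float
    layers: dict[str, np.ndarray]
    feature_sets: dict[str, np.ndarray] = field(default_factory=dict)
    windows: dict[str, "SeasonalWindow | None"] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        shapes = {lay.shape for lay in self.layers.values()}
        if len(shapes) > 1:
            raise ValueError(f"layers disagree on grid shape: {shapes}")
        for name, lay in self.layers.items():
            self.layers[name] = np.asarray(lay, dtype=float)

    # -- grid geometry -------------------------------------------------
    @property
    def n_rows(self) -> int:
        return next(iter(self.layers.values())).shape[0]

    @property
    def n_cols(self) -> int:
        return next(iter(self.layers.values())).shape[1]

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, xmax, ymin, ymax) in km."""
        x0, y0 = self.origin
        return (x0, x0 + self.n_cols * self.cell_size,
                y0, y0 + self.n_rows * self.cell_size)

    def center(self) -> np.ndarray:
        xmin, xmax, ymin, ymax = self.extent
        return np.array([(xmin + xmax) / 2, (ymin + ymax) / 2])

    def cell_index(self, points, clamp: bool = False) -> tuple[np.ndarray, np.ndarray]:
        """Map points to (row, col).  Cells are half-open: a point on a shared
        edge belongs to the cell with the larger index."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        x0, y0 = self.origin
        col = np.floor((pts[:, 0] - x0) / self.cell_size).astype(np.int64)
        row = np.floor((pts[:, 1] - y0) / self.cell_size).astype(np.int64)
        if clamp:
            col = np.clip(col, 0, self.n_cols - 1)
            row = np.clip(row, 0, self.n_rows - 1)
        else:
            bad = (col < 0) | (col >= self.n_cols) | (row < 0) | (row >= self.n_rows)
            if np.any(bad):
                i = int(np.flatnonzero(bad)[0])
                raise OutOfDomainError(
                    f"point {tuple(pts[i])} outside landscape extent {self.extent}"
                )
        return row, col

    def in_extent(self, points) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        xmin, xmax, ymin, ymax = self.extent
        return ((pts[:, 0] >= xmin) & (pts[:, 0] < xmax)
                & (pts[:, 1] >= ymin) & (pts[:, 1] < ymax))

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Meshgrid-style (X, Y) arrays of cell-centre coordinates."""
        x0, y0 = self.origin
        xs = x0 + (np.arange(self.n_cols) + 0.5) * self.cell_size
        ys = y0 + (np.arange(self.n_rows) + 0.5) * self.cell_size
        return np.meshgrid(xs, ys)

    # -- covariate lookup ----------------------------------------------
    def stack(self) -> np.ndarray:
        """Layers as a single (P, n_rows, n_cols) array, in `names` order."""
        return np.stack([self.layers[n] for n in self.names])

    def seasonal_mask(self, doy) -> np.ndarray:
        """(P,) or (n, P) 0/1 mask: 0 where a layer's window excludes `doy`."""
        doy = np.asarray(doy)
        cols = []
        for name in self.names:
            win = self.windows.get(name)
            if win is None:
                cols.append(np.ones(doy.shape if doy.ndim else (), dtype=float))
            else:
                cols.append(win.contains(doy) * 1.0)
        out = np.stack([np.asarray(c, dtype=float) for c in cols], axis=-1)
        return out

    def covariates_at(self, points, doy: int | None = None,
                      seasonal: bool = False, clamp: bool = False) -> np.ndarray:
        """Covariate vector(s) r_1..r_P at the cell(s) containing `points`.

        With ``seasonal=True`` layers whose window excludes `doy` return 0
        (values are zeroed, never rescaled).  Out-of-extent points raise
        :class:`OutOfDomainError` unless ``clamp=True`` (nearest-cell value,
        used only for candidate endpoints near range edges).
        """
        pts = np.asarray(points, dtype=float)
        single = pts.ndim == 1
        row, col = self.cell_index(pts, clamp=clamp)
        out = self.stack()[:, row, col].T  # (n, P)
        if seasonal:
            if doy is None:
                raise ValueError("seasonal=True requires day_of_year")
            out = out * self.seasonal_mask(doy)
        return out[0] if single else out


# ----------------------------------------------------------------------
# generators


def distance_to_features(grid: Landscape | tuple, features) -> np.ndarray:
    """Raster of Euclidean distances (km) from each cell centre to the
    nearest feature point.  Features may lie outside the extent."""
    features = np.atleast_2d(np.asarray(features, dtype=float))
    if features.size == 0:
        raise ValueError("at least one feature point is required")
    if isinstance(grid, Landscape):
        X, Y = grid.cell_centers()
    else:  # (origin, cell_size, n_rows, n_cols)
        origin, cell, n_rows, n_cols = grid
        xs = origin[0] + (np.arange(n_cols) + 0.5) * cell
        ys = origin[1] + (np.arange(n_rows) + 0.5) * cell
        X, Y = np.meshgrid(xs, ys)
    tree = cKDTree(features)
    d, _ = tree.query(np.column_stack([X.ravel(), Y.ravel()]))
    return d.reshape(X.shape)


def _smooth_field(rng: np.random.Generator, n_rows: int, n_cols: int,
                  smoothness: float) -> np.ndarray:
    """White noise convolved with an isotropic Gaussian kernel, then
    standardized to mean 0, sd 1."""
    z = rng.standard_normal((n_rows, n_cols))
    if smoothness > 0:
        z = ndimage.gaussian_filter(z, sigma=smoothness, mode="wrap")
    z = z - z.mean()
    sd = z.std()
    if sd > 0:
        z = z / sd
    return z


def generate_random_landscape(seed: int, n_rows: int, n_cols: int,
                              cell_size: float, layer_specs: list[dict],
                              origin: tuple[float, float] = (0.0, 0.0),
                              ) -> Landscape:
    """Deterministically generate a covariate stack from layer specs.

    Each spec is a dict with ``name`` and ``kind``:

    - ``smooth``: autocorrelated Gaussian field, ``smoothness`` in cell
      units (sd of the convolution kernel), standardized to mean 0 / sd 1;
    - ``distance``: Euclidean distance from ``n_features`` randomly placed
      points (or explicit ``features``);
    - ``interaction``: product of two independent smooth fields (emulating
      e.g. a slope x shrub interaction), standardized;
    - ``constant``: every cell equals ``value``.

    A spec may also carry ``window`` (a :class:`SeasonalWindow` or
    ``(start_doy, end_doy)`` tuple).
    """
    if n_rows < 4 or n_cols < 4:
        raise ValueError("need n_rows, n_cols >= 4")
    if cell_size <= 0:
        raise ValueError("cell_size must be positive")
    rng = np.random.default_rng(seed)
    geom = (origin, cell_size, n_rows, n_cols)
    extent_x = n_cols * cell_size
    extent_y = n_rows * cell_size
    layers: dict[str, np.ndarray] = {}
    feature_sets: dict[str, np.ndarray] = {}
    windows: dict[str, SeasonalWindow | None] = {}
    for spec in layer_specs:
        name, kind = spec["name"], spec["kind"]
        if kind == "smooth":
            sm = float(spec.get("smoothness", 0.0))
            if sm < 0:
                raise ValueError("smoothness must be >= 0")
            layers[name] = _smooth_field(rng, n_rows, n_cols, sm)
        elif kind == "distance":
            if "features" in spec:
                feats = np.atleast_2d(np.asarray(spec["features"], dtype=float))
            else:
                k = int(spec.get("n_features", 3))
                feats = np.column_stack([
                    origin[0] + rng.uniform(0, extent_x, k),
                    origin[1] + rng.uniform(0, extent_y, k),
                ])
            feature_sets[name] = feats
            layers[name] = distance_to_features(geom, feats)
        elif kind == "interaction":
            sm = float(spec.get("smoothness", 0.0))
            if sm < 0:
                raise ValueError("smoothness must be >= 0")
            prod = (_smooth_field(rng, n_rows, n_cols, sm)
                    * _smooth_field(rng, n_rows, n_cols, sm))
            prod = prod - prod.mean()
            sd = prod.std()
            layers[name] = prod / sd if sd > 0 else prod
        elif kind == "constant":
            layers[name] = np.full((n_rows, n_cols), float(spec.get("value", 0.0)))
        else:
            raise ValueError(f"unknown layer kind {kind!r}")
        win = spec.get("window")
        if win is not None and not isinstance(win, SeasonalWindow):
            win = SeasonalWindow(*win)
        windows[name] = win
    return Landscape(origin=origin, cell_size=cell_size, layers=layers,
                     feature_sets=feature_sets, windows=windows)


def default_bear_landscape(seed: int = 0, n_rows: int = 120, n_cols: int = 120,
                           cell_size: float = 0.25,
                           smoothness: float = 5.0) -> Landscape:
    """Six-covariate landscape emulating the standard study stack: two smooth
    habitat fields (berries, squirrels), one interaction field (sweetvetch),
    and three distance layers (riparian water, settlements, cabins), with the
    default seasonal windows attached."""
    specs = [
        {"name": "berries", "kind": "smooth", "smoothness": smoothness},
        {"name": "riparian", "kind": "distance", "n_features": 4},
        {"name": "squirrels", "kind": "smooth", "smoothness": smoothness},
        {"name": "sweetvetch", "kind": "interaction", "smoothness": smoothness},
        {"name": "settlements", "kind": "distance", "n_features": 2},
        {"name": "cabins", "kind": "distance", "n_features": 6},
    ]
    ls = generate_random_landscape(seed, n_rows, n_cols, cell_size, specs)
    ls.windows = dict(DEFAULT_WINDOWS)
    return ls
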