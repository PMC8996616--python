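"""File formats: track CSVs, raster grids, and run configuration.

Tracks travel as CSV with columns ``id, timestamp, x, y`` (ISO-8601 UTC
timestamps; planar kilometres - no geographic projection is performed).
Rasters are ESRI ASCII grids (``.asc``), plain CSV matrices, or plain
TIFF arrays; landscape metadata (layer names, windows, feature sets)
lives in a YAML/JSON config.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import TrackOrderError
from .landscape import Landscape, SeasonalWindow
from .track import Track

__all__ = ["read_tracks", "write_tracks", "read_raster", "write_raster",
           "read_landscape_config", "write_landscape", "read_landscape"]


def read_tracks(path, dt_hours: float = 4.0) -> dict[str, Track]:
    """Read per-animal tracks from a CSV of (id, timestamp, x, y).

    Timestamps must be strictly increasing per animal (duplicates are
    rejected); fixes are snapped to the declared interval grid when
    within +/-10% of it, larger gaps are recorded as gaps (never
    interpolated).  Training flags cover the first year from each
    animal's first fix; animals whose data do not extend past the
    training year get ``excluded=True``.
    """
    df = pd.read_csv(path)
    required = {"id", "timestamp", "x", "y"}
    if not required.issubset(df.columns):
        raise ValueError(f"track file needs columns {sorted(required)}, "
                         f"found {list(df.columns)}")
    try:
        df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True,
                                         format="ISO8601")
    except (ValueError, TypeError) as e:
        bad = pd.to_datetime(df["timestamp"], utc=True, format="ISO8601",
                             errors="coerce")
        line = int(np.flatnonzero(bad.isna().to_numpy())[0]) + 2
        raise ValueError(f"unparseable timestamp at line {line}: {e}") from e
    df["timestamp"] = df["timestamp"].dt.tz_localize(None)
    out: dict[str, Track] = {}
    for aid, g in df.groupby("id", sort=False):
        ts = g["timestamp"].to_numpy().astype("datetime64[s]")
        if np.any(np.diff(ts).astype(float) <= 0):
            raise TrackOrderError(
                f"animal {aid}: timestamps not strictly increasing")
        out[str(aid)] = Track(animal_id=str(aid), timestamps=ts,
                              xy=g[["x", "y"]].to_numpy(dtype=float),
                              dt_hours=dt_hours)
    return out


def write_tracks(tracks, path) -> None:
    """Write tracks to the CSV dialect read_tracks accepts (round-trips)."""
    if isinstance(tracks, Track):
        tracks = [tracks]
    if isinstance(tracks, dict):
        tracks = list(tracks.values())
    df = pd.concat([t.to_dataframe() for t in tracks], ignore_index=True)
    df["timestamp"] = df["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    df.to_csv(path, index=False)


# ----------------------------------------------------------------------
# rasters


def write_raster(path, array: np.ndarray, origin=(0.0, 0.0),
                 cell_size: float = 1.0) -> None:
    """Write an ESRI ASCII grid (row 0 of the array = southernmost row)."""
    path = Path(path)
    arr = np.asarray(array, dtype=float)
    header = (f"ncols {arr.shape[1]}\nnrows {arr.shape[0]}\n"
              f"xllcorner {origin[0]}\nyllcorner {origin[1]}\n"
              f"cellsize {cell_size}\nNODATA_value -9999\n")
    with open(path, "w") as fh:
        fh.write(header)
        # ESRI grids store the top (northern) row first
        np.savetxt(fh, arr[::-1], fmt="%.8g")


def read_raster(path):
    """Read a raster layer: .asc (with geometry), .csv matrix, or .tif
    array.  Returns (array, origin, cell_size); origin/cell_size are None
    for formats that do not carry geometry."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".asc":
        meta = {}
        with open(path) as fh:
            for _ in range(6):
                pos = fh.tell()
                parts = fh.readline().split()
                if len(parts) == 2 and parts[0][0].isalpha():
                    meta[parts[0].lower()] = float(parts[1])
                else:
                    fh.seek(pos)
                    break
            arr = np.loadtxt(fh)
        arr = arr[::-1]  # back to south-first rows
        return (arr, (meta.get("xllcorner", 0.0), meta.get("yllcorner", 0.0)),
                meta.get("cellsize", 1.0))
    if suffix == ".csv":
        return np.loadtxt(path, delimiter=","), None, None
    if suffix in (".tif", ".tiff"):
        import tifffile
        return np.asarray(tifffile.imread(path), dtype=float), None, None
    raise ValueError(f"unsupported raster format {suffix!r}")


# ----------------------------------------------------------------------
# landscape config


def write_landscape(landscape: Landscape, directory,
                    config_name: str = "landscape.yml") -> Path:
    """Write each layer as an .asc grid plus a YAML config tying the stack
    together (windows, feature sets, geometry)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    cfg: dict = {"origin": [float(landscape.origin[0]),
                            float(landscape.origin[1])],
                 "cell_size": float(landscape.cell_size),
                 "layers": []}
    for name in landscape.names:
        fname = f"{name}.asc"
        write_raster(directory / fname, landscape.layers[name],
                     landscape.origin, landscape.cell_size)
        entry: dict = {"name": name, "path": fname}
        win = landscape.windows.get(name)
        if win is not None:
            entry["window"] = [win.start_doy, win.end_doy]
        if name in landscape.feature_sets:
            entry["features"] = np.asarray(
                landscape.feature_sets[name]).tolist()
        cfg["layers"].append(entry)
    cfg_path = directory / config_name
    with open(cfg_path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
    return cfg_path


def read_landscape_config(path) -> dict:
    path = Path(path)
    with open(path) as fh:
        if path.suffix in (".json",):
            return json.load(fh)
        return yaml.safe_load(fh)


def read_landscape(config_path) -> Landscape:
    """Load a landscape from its config plus referenced raster files."""
    config_path = Path(config_path)
    cfg = read_landscape_config(config_path)
    missing = [k for k in ("origin", "cell_size", "layers") if k not in cfg]
    if missing:
        raise ValueError(f"landscape config missing keys: {missing}")
    origin = tuple(float(v) for v in cfg["origin"])
    cell = float(cfg["cell_size"])
    layers, windows, features = {}, {}, {}
    for entry in cfg["layers"]:
        arr, o, c = read_raster(config_path.parent / entry["path"])
        layers[entry["name"]] = arr
        windows[entry["name"]] = (SeasonalWindow(*entry["window"])
                                  if "window" in entry else None)
        if "features" in entry:
            features[entry["name"]] = np.asarray(entry["features"],
                                                 dtype=float)
    return Landscape(origin=origin, cell_size=cell, layers=layers,
                     feature_sets=features, windows=windows)
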