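"""GPS track container: fixes, derived steps, bursts and training flags.

A :class:`Track` holds one animal's relocations at a nominally regular fix
interval (4 h in the motivating study).  Fixes are snapped to the fix grid;
larger irregularities split the track into *bursts* (contiguous runs of
grid-adjacent fixes).  Steps are consecutive fix pairs within a burst; the
first step of a burst has no defined inbound heading.  The first year of
data is flagged as *training*: it seeds the cognitive map but its steps
contribute no likelihood terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cognitive import CognitiveMap
from .errors import TrackOrderError
from .landscape import day_of_year

__all__ = ["Track", "TRAINING_DAYS"]

#: Length of the training window, days from the first fix.
TRAINING_DAYS = 365.0

#: Steps shorter than this (km) are stationary-scale jitter: their
#: direction carries no heading information (3x the 30 m stationary mean).
HEADING_MIN_KM = 0.09


@dataclass
class Track:
    """Ordered GPS fixes for one animal.

    Parameters
    ----------
    animal_id : str
    timestamps : array of datetime64[s]
        Strictly increasing fix times.
    xy : (N, 2) float array
        Planar coordinates in km.
    dt_hours : float
        Nominal fix interval (hours).
    """

    animal_id: str
    timestamps: np.ndarray
    xy: np.ndarray
    dt_hours: float = 4.0
    training: np.ndarray | None = None
    excluded: bool = False

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype="datetime64[s]")
        self.xy = np.asarray(self.xy, dtype=float)
        if self.xy.shape != (len(self.timestamps), 2):
            raise ValueError("xy must be (N, 2) matching timestamps")
        dt_sec = np.diff(self.timestamps).astype("timedelta64[s]").astype(float)
        if np.any(dt_sec <= 0):
            raise TrackOrderError(
                f"track {self.animal_id}: timestamps not strictly increasing"
            )
        # hours since first fix, snapped to the fix grid where regular
        self.t_hours = np.concatenate([[0.0], np.cumsum(dt_sec)]) / 3600.0
        self.fix_index = np.rint(self.t_hours / self.dt_hours).astype(np.int64)
        resid = np.abs(self.t_hours - self.fix_index * self.dt_hours)
        self.on_grid = resid <= 0.1 * self.dt_hours
        if self.training is None:
            self.training = self.t_hours < TRAINING_DAYS * 24.0
        self.training = np.asarray(self.training, dtype=bool)
        # excluded unless data extend beyond the training window
        if not np.any(~self.training):
            self.excluded = True
        self.doy = day_of_year(self.timestamps)

    # -- basic views ---------------------------------------------------
    def __len__(self) -> int:
        return len(self.timestamps)

    @property
    def n_years(self) -> float:
        return float(self.t_hours[-1] / (24.0 * 365.0)) if len(self) > 1 else 0.0

    def steps(self) -> pd.DataFrame:
        """Derived steps: consecutive grid-adjacent fix pairs.

        Columns: from/to fix row indices, length (km), absolute direction
        and turning angle (radians; NaN when the inbound heading is
        undefined), dt (h), day-of-year of the destination fix, and flags
        ``heading_defined`` and ``training`` (step is training when its
        destination fix is).
        """
        i = np.arange(len(self) - 1)
        adjacent = (self.fix_index[i + 1] == self.fix_index[i] + 1) \
            & self.on_grid[i] & self.on_grid[i + 1]
        i = i[adjacent]
        d = self.xy[i + 1] - self.xy[i]
        length = np.hypot(d[:, 0], d[:, 1])
        direction = np.arctan2(d[:, 1], d[:, 0])
        # Inbound heading phi_{t-1} carries the direction of the last
        # heading-informative step: displacements below HEADING_MIN_KM are
        # stationary-scale jitter whose direction is noise, so they leave
        # the carried heading unchanged.  Gaps (burst breaks) reset it.
        heading_in = np.full(len(i), np.nan)
        last = np.nan
        for s in range(len(i)):
            if s > 0 and i[s] != i[s - 1] + 1:
                last = np.nan
            heading_in[s] = last
            if length[s] >= HEADING_MIN_KM:
                last = direction[s]
        has_prev = ~np.isnan(heading_in)
        turn = np.where(has_prev,
                        _wrap_angle(direction - np.nan_to_num(heading_in)),
                        np.nan)
        return pd.DataFrame({
            "from_idx": i, "to_idx": i + 1,
            "length": length, "direction": direction,
            "heading_in": heading_in, "turn": turn,
            "heading_defined": has_prev,
            "dt": np.full(len(i), self.dt_hours),
            "doy": self.doy[i + 1],
            "training": self.training[i + 1],
        })

    def cognitive_map(self, origin=(0.0, 0.0), cell_size=1.0) -> CognitiveMap:
        """Cognitive map built from every fix (training included: memory
        accrues from the first fix even though training steps carry no
        likelihood)."""
        cmap = CognitiveMap(origin=origin, cell_size=cell_size,
                            dt_fix=self.dt_hours)
        for t, p in zip(self.t_hours, self.xy):
            cmap.update(p, float(t))
        return cmap

    def indexed_path(self) -> tuple[np.ndarray, np.ndarray]:
        """Dense (positions, defined) arrays on the fix grid (index 0 at the
        first fix), for the fast likelihood kernels."""
        n = int(self.fix_index[-1]) + 1
        pos = np.zeros((n, 2))
        defined = np.zeros(n, dtype=bool)
        ok = self.on_grid
        pos[self.fix_index[ok]] = self.xy[ok]
        defined[self.fix_index[ok]] = True
        return pos, defined

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "id": self.animal_id,
            "timestamp": self.timestamps,
            "x": self.xy[:, 0],
            "y": self.xy[:, 1],
        })

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, animal_id: str | None = None,
                       dt_hours: float = 4.0) -> "Track":
        if animal_id is None:
            ids = df["id"].unique()
            if len(ids) != 1:
                raise ValueError("dataframe holds multiple animals; pass animal_id")
            animal_id = str(ids[0])
        else:
            df = df[df["id"].astype(str) == str(animal_id)]
        ts = pd.to_datetime(df["timestamp"]).to_numpy().astype("datetime64[s]")
        return cls(animal_id=str(animal_id), timestamps=ts,
                   xy=df[["x", "y"]].to_numpy(dtype=float), dt_hours=dt_hours)

    def plot(self, ax=None, color_period_days: float | None = None, **kw):
        """Plot the track, optionally coloring fixes by phase within a
        revisitation cycle of ``color_period_days``."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        if color_period_days:
            phase = (self.t_hours / 24.0) % color_period_days
            sc = ax.scatter(self.xy[:, 0], self.xy[:, 1], c=phase,
                            cmap="twilight", s=6, **kw)
            plt.colorbar(sc, ax=ax, label=f"days mod {color_period_days:g}")
        else:
            ax.plot(self.xy[:, 0], self.xy[:, 1], "-", lw=0.5, **kw)
        ax.set_xlabel("x (km)")
        ax.set_ylabel("y (km)")
        ax.set_aspect("equal")
        return ax


def _wrap_angle(a: np.ndarray) -> np.ndarray:
    """Wrap to (-pi, pi]."""
    out = np.mod(a + np.pi, 2 * np.pi) - np.pi
    return np.where(out == -np.pi, np.pi, out)
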