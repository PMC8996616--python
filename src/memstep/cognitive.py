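"""The cognitive map: where the animal has been, and when.

The map keeps two synchronized views of the movement history:

- ``path``: the time-indexed sequence of (time, location) fixes, which
  answers "where was the animal at time t - tau" by exact lag indexing on
  the regular fix grid (the form the memory weighting needs);
- ``cell_visits``: per grid cell, the ordered list of visit times, so a
  cell visited twice holds a two-element list.

Times are in hours.  Fixes sit on a regular grid of ``dt_fix`` hours;
missed fixes (collar gaps, denning) simply leave the corresponding lags
undefined, and lag lookups return ``None`` for them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["CognitiveMap"]


@dataclass
class CognitiveMap:
    """Visit history of one animal on a shared landscape grid.

    Parameters
    ----------
    origin, cell_size : grid geometry shared with the Landscape.
    dt_fix : float
        Nominal fix interval in hours (lag lookups index on this grid).
    """

    origin: tuple[float, float] = (0.0, 0.0)
    cell_size: float = 1.0
    dt_fix: float = 4.0
    times: list = field(default_factory=list)
    points: list = field(default_factory=list)
    cell_visits: dict = field(default_factory=dict)

    # -- updates -------------------------------------------------------
    def update(self, point, t: float) -> "CognitiveMap":
        """Record a fix at time ``t`` (hours).  Times must strictly increase."""
        if self.times and t <= self.times[-1]:
            raise ValueError(
                f"non-increasing fix time {t} (last recorded {self.times[-1]})"
            )
        point = (float(point[0]), float(point[1]))
        self.times.append(float(t))
        self.points.append(point)
        cell = self._cell(point)
        self.cell_visits.setdefault(cell, []).append(float(t))
        return self

    def _cell(self, point) -> tuple[int, int]:
        col = int(np.floor((point[0] - self.origin[0]) / self.cell_size))
        row = int(np.floor((point[1] - self.origin[1]) / self.cell_size))
        return (row, col)

    # -- queries -------------------------------------------------------
    def __len__(self) -> int:
        return len(self.times)

    @property
    def t_start(self) -> float | None:
        return self.times[0] if self.times else None

    def location_at(self, t: float):
        """Recorded location at exactly time ``t``, or None for gaps /
        times before the first fix (tolerance 1e-6 h)."""
        if not self.times:
            return None
        times = np.asarray(self.times)
        i = int(np.searchsorted(times, t - 1e-6))
        if i < len(times) and abs(times[i] - t) <= 1e-6:
            return np.asarray(self.points[i])
        return None

    def location_at_lag(self, t: float, tau: float):
        """Where the animal was at time ``t - tau`` (``tau`` > 0), or None."""
        if tau <= 0:
            raise ValueError("tau must be positive")
        return self.location_at(t - tau)

    def indexed_path(self) -> tuple[float, np.ndarray, np.ndarray]:
        """Dense path on the fix grid: ``(t0, positions, defined)`` where
        ``positions[i]`` is the location at ``t0 + i * dt_fix`` and
        ``defined[i]`` is False at gaps.  This is the array view the fast
        likelihood kernels consume."""
        if not self.times:
            return 0.0, np.zeros((0, 2)), np.zeros(0, dtype=bool)
        t0 = self.times[0]
        idx = np.rint((np.asarray(self.times) - t0) / self.dt_fix).astype(np.int64)
        n = int(idx[-1]) + 1
        pos = np.zeros((n, 2))
        defined = np.zeros(n, dtype=bool)
        pos[idx] = np.asarray(self.points)
        defined[idx] = True
        return t0, pos, defined

    # -- invariant helpers --------------------------------------------
    def rebuild_cell_visits(self) -> dict:
        """Recompute cell_visits from the path (round-trip identity check)."""
        out: dict = {}
        for t, p in zip(self.times, self.points):
            out.setdefault(self._cell(p), []).append(t)
        return out

    @classmethod
    def from_path(cls, times, points, origin=(0.0, 0.0), cell_size=1.0,
                  dt_fix=4.0) -> "CognitiveMap":
        cmap = cls(origin=origin, cell_size=cell_size, dt_fix=dt_fix)
        for t, p in zip(times, points):
            cmap.update(p, float(t))
        return cmap
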