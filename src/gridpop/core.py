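"""Core data containers shared across the analysis pipeline.

Coordinates are continuous centimeters with the origin at the environment
center.  Rate maps live on a 1-cm square grid covering the bounding square of
the environment; bin ``(iy, ix)`` of an array covers the half-open square
``[origin + i, origin + i + 1)`` in each dimension, so array row index maps to
y and column index to x.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Geometry",
    "GridParams",
    "Trajectory",
    "SpikeTrain",
    "RateMap",
    "LinearRateMap",
]


@dataclass(frozen=True)
class Geometry:
    """Circular environment: open arena or annular track.

    Parameters
    ----------
    kind : {"arena", "track"}
        An arena is a full disc (``inner_radius == 0``); a track is an
        annulus.
    outer_radius, inner_radius : float
        Radii in cm.  The default geometry of the experiments this package
        models is a 75-cm arena and a 15-cm-wide track obtained by removing
        the inner disc of radius 60 cm.
    center : tuple of float
        Environment center in cm.
    bin_size : float
        Spatial discretization, cm.
    """

    kind: str
    outer_radius: float
    inner_radius: float = 0.0
    center: tuple[float, float] = (0.0, 0.0)
    bin_size: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("arena", "track"):
            raise ValueError(f"kind must be 'arena' or 'track', got {self.kind!r}")
        if not (self.outer_radius > self.inner_radius >= 0):
            raise ValueError("need outer_radius > inner_radius >= 0")
        if self.kind == "arena" and self.inner_radius != 0:
            raise ValueError("an arena has inner_radius 0")
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")

    @property
    def n_bins(self) -> int:
        """Bins per side of the square grid covering the environment."""
        return int(round(2 * self.outer_radius / self.bin_size))

    @property
    def grid_origin(self) -> tuple[float, float]:
        """Center (cm) of bin (0, 0), i.e. the lower-left grid bin."""
        cx, cy = self.center
        r = self.outer_radius
        return (cx - r + self.bin_size / 2, cy - r + self.bin_size / 2)

    def bin_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Meshgrids ``(X, Y)`` of bin-center coordinates, shape (n, n)."""
        ox, oy = self.grid_origin
        n = self.n_bins
        xs = ox + self.bin_size * np.arange(n)
        ys = oy + self.bin_size * np.arange(n)
        return np.meshgrid(xs, ys)

    def mask(self) -> np.ndarray:
        """Boolean occupancy mask: bins whose center lies in the environment."""
        X, Y = self.bin_centers()
        r = np.hypot(X - self.center[0], Y - self.center[1])
        return (r >= self.inner_radius) & (r <= self.outer_radius)


def standard_arena(radius: float = 75.0) -> Geometry:
    return Geometry(kind="arena", outer_radius=radius)


def standard_track(outer_radius: float = 75.0, width: float = 15.0) -> Geometry:
    return Geometry(kind="track", outer_radius=outer_radius,
                    inner_radius=outer_radius - width)


@dataclass(frozen=True)
class GridParams:
    """Generative parameters of one idealized grid cell.

    ``spacing`` is the nearest-neighbor distance of the hexagonal firing
    lattice (cm), ``orientation`` the lattice angle in degrees (reduced mod
    60), ``phase`` a 2D offset (cm) of the lattice relative to the
    environment center, and ``peak_rate`` the firing rate at field centers
    (Hz).
    """

    spacing: float
    orientation: float
    phase: tuple[float, float] = (0.0, 0.0)
    peak_rate: float = 10.0

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if self.peak_rate <= 0:
            raise ValueError("peak_rate must be positive")
        object.__setattr__(self, "orientation", float(self.orientation) % 60.0)

    def lattice_vectors(self) -> np.ndarray:
        """Two primitive lattice vectors, shape (2, 2), rows are vectors."""
        th = np.deg2rad(self.orientation)
        a = self.spacing
        return np.array([
            [a * np.cos(th), a * np.sin(th)],
            [a * np.cos(th + np.pi / 3), a * np.sin(th + np.pi / 3)],
        ])


@dataclass(frozen=True)
class Trajectory:
    """Animal path: strictly increasing times (s) and 2D positions (cm)."""

    times: np.ndarray
    positions: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        p = np.asarray(self.positions, dtype=float)
        if p.ndim != 2 or p.shape[1] != 2:
            raise ValueError("positions must have shape (n, 2)")
        if len(t) != len(p):
            raise ValueError("times and positions must have equal length")
        if len(t) == 0:
            raise ValueError("trajectory is empty")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "positions", p)

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    @property
    def median_dt(self) -> float:
        if len(self.times) < 2:
            return 0.0
        return float(np.median(np.diff(self.times)))

    def position_at(self, t: np.ndarray) -> np.ndarray:
        """Linear interpolation of the path at times ``t``; shape (len(t), 2)."""
        t = np.asarray(t, dtype=float)
        x = np.interp(t, self.times, self.positions[:, 0])
        y = np.interp(t, self.times, self.positions[:, 1])
        return np.column_stack([x, y])


@dataclass(frozen=True)
class SpikeTrain:
    """Spike times (s) of one cell, nondecreasing."""

    spike_times: np.ndarray
    cell_id: str | None = None

    def __post_init__(self) -> None:
        s = np.asarray(self.spike_times, dtype=float)
        if s.ndim != 1:
            raise ValueError("spike_times must be 1-D")
        if len(s) > 1 and np.any(np.diff(s) < 0):
            raise ValueError("spike_times must be nondecreasing")
        object.__setattr__(self, "spike_times", s)

    def __len__(self) -> int:
        return len(self.spike_times)

    def check_within(self, traj: Trajectory) -> None:
        s = self.spike_times
        if len(s) and (s[0] < traj.times[0] or s[-1] > traj.times[-1]):
            raise ValueError("spike times fall outside the trajectory time range")


@dataclass
class RateMap:
    """Binned 2D firing-rate field (Hz) with a visited-bin mask.

    ``origin`` is the coordinate (cm) of the center of bin (0, 0); array rows
    index y, columns x.  Rates are 0 wherever ``visited_mask`` is False.
    """

    values: np.ndarray
    visited_mask: np.ndarray
    origin: tuple[float, float]
    bin_size: float = 1.0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        m = np.asarray(self.visited_mask, dtype=bool)
        if v.shape != m.shape or v.ndim != 2:
            raise ValueError("values and visited_mask must be equal-shape 2-D arrays")
        if np.any(v < 0):
            raise ValueError("rates must be nonnegative")
        v = np.where(m, v, 0.0)
        self.values = v
        self.visited_mask = m

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def bin_centers(self) -> tuple[np.ndarray, np.ndarray]:
        ox, oy = self.origin
        ny, nx = self.values.shape
        xs = ox + self.bin_size * np.arange(nx)
        ys = oy + self.bin_size * np.arange(ny)
        return np.meshgrid(xs, ys)

    def value_at(self, points: np.ndarray) -> np.ndarray:
        """Nearest-bin rate lookup at continuous positions (0 outside grid)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        ox, oy = self.origin
        ix = np.round((pts[:, 0] - ox) / self.bin_size).astype(int)
        iy = np.round((pts[:, 1] - oy) / self.bin_size).astype(int)
        ny, nx = self.values.shape
        ok = (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny)
        out = np.zeros(len(pts))
        out[ok] = self.values[iy[ok], ix[ok]]
        return out


@dataclass
class LinearRateMap:
    """1-cm-binned firing rate along the linearized (unwrapped) track.

    Positions are cumulative signed angular distance times the linearization
    radius, so lap-stable fields repeat with period ``circumference``.
    """

    bin_edges: np.ndarray
    rates: np.ndarray
    circumference: float
    visited: np.ndarray = field(default=None)  # type: ignore[assignment]
    total_distance: float = 0.0
    cell_id: str | None = None

    def __post_init__(self) -> None:
        e = np.asarray(self.bin_edges, dtype=float)
        r = np.asarray(self.rates, dtype=float)
        if len(e) != len(r) + 1:
            raise ValueError("bin_edges must have len(rates) + 1 entries")
        if np.any(np.diff(e) <= 0):
            raise ValueError("bin_edges must be increasing")
        if np.any(r < 0):
            raise ValueError("rates must be nonnegative")
        if self.circumference <= 0:
            raise ValueError("circumference must be positive")
        if self.visited is None:
            self.visited = r > 0
        self.bin_edges = e
        self.rates = r
        self.visited = np.asarray(self.visited, dtype=bool)

    @property
    def bin_size(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])
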