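"""Gridness scoring and hexagonal-lattice inference from a correlogram.

The analysis extracts the annulus containing the innermost peak ring
(excluding the central peak) from the radial profile M(r) — the mean
correlation on concentric circles — and scores sixfold symmetry by rotating
the annulus:

    gridness = min{r(60°), r(120°)} − max{r(30°), r(90°), r(150°)} ,

where r(φ) is the Pearson correlation between the annulus and its copy
rotated by φ.  Spacing is the mean radial distance of the three peaks found
in the upper half-annulus (peaks are found iteratively, excluding ±35°
sectors around each previous peak), and the three orientation angles are the
peak directions from the positive x-axis.

On a circular track the large central peak can obscure the innermost ring,
in which case the detected ring is the second hexagonal ring — radius √3·λ,
rotated 30° from the first.  The caller interprets which ring was found;
:func:`locate_ring` searches an explicit radial band for this purpose.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .correlograms import Correlogram2D

__all__ = [
    "AnnulusSpec",
    "LatticeFeatures",
    "radial_profile",
    "annulus_bounds",
    "rotational_autocorrelation",
    "rotational_profile",
    "gridness_score",
    "locate_peaks",
    "locate_ring",
    "infer_lattice",
    "second_ring_features",
]

FALLBACK_RMIN = 25.0
FALLBACK_RMAX = 40.0
EXCLUSION_HALF_ANGLE = 35.0  # degrees, around each located peak
_DEPTH_FRAC = 0.02  # required M(r_max)-M(r_min) depth relative to M(0)


@dataclass(frozen=True)
class AnnulusSpec:
    """Radial band of the correlogram containing one peak ring.

    ``inner_radius = r_min`` and ``outer_radius = r_max + (r_max − r_min)``,
    where r_min/r_max are the extrema of the radial profile.
    ``fallback_used`` flags the structureless-profile fallback (25, 40) cm.
    """

    r_min: float
    r_max: float
    fallback_used: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.r_min < self.r_max):
            raise ValueError("need 0 < r_min < r_max")

    @property
    def inner_radius(self) -> float:
        return self.r_min

    @property
    def outer_radius(self) -> float:
        return 2 * self.r_max - self.r_min


@dataclass
class LatticeFeatures:
    """Inferred lattice: spacing, orientations, gridness and the peaks."""

    spacing: float
    orientations: np.ndarray  # three angles, degrees in [0, 180)
    gridness: float
    peaks: np.ndarray         # (3, 2) lag coordinates (cm)
    annulus: AnnulusSpec | None = None

    def __post_init__(self) -> None:
        self.orientations = np.sort(np.asarray(self.orientations, dtype=float))
        self.peaks = np.asarray(self.peaks, dtype=float)
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if self.orientations.shape != (3,):
            raise ValueError("exactly three orientations expected")


def radial_profile(corr: Correlogram2D) -> tuple[np.ndarray, np.ndarray]:
    """Mean correlation M(r) on concentric rings of integer radius.

    Bins are assigned to the ring their center distance rounds to; invalid
    lags are excluded from the mean.  Returns ``(radii, M)`` with radii
    0..half-extent in bin-size steps.
    """
    LX, LY = corr.lag_grids()
    dist = np.hypot(LX, LY)
    r_idx = np.round(dist / corr.bin_size).astype(int)
    n_r = int(np.floor(corr.half_extent / corr.bin_size)) + 1
    ok = corr.valid & (r_idx < n_r)
    sums = np.bincount(r_idx[ok], weights=corr.values[ok], minlength=n_r)
    counts = np.bincount(r_idx[ok], minlength=n_r)
    with np.errstate(invalid="ignore"):
        m = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    radii = corr.bin_size * np.arange(n_r)
    return radii, m


def annulus_bounds(radii: np.ndarray, m: np.ndarray,
                   search_range: tuple[float, float] | None = None,
                   ) -> AnnulusSpec:
    """Annulus extrema from the radial profile, with structureless fallback.

    ``r_min`` is the first local minimum of M after the central descent
    (radius > 2 bins); ``r_max`` is the first local maximum of M beyond it —
    the center of the innermost peak ring, which M rises to after the
    trough.  (On a circular track the global maximum of M can instead sit on
    the ring the track geometry itself contributes near the track diameter,
    so the first local maximum is the right one.)  When no such
    minimum/maximum pair exists, or the max−min depth is below 2% of M(0),
    the profile is considered structureless and the fallback (25, 40) cm is
    used.  Ties resolve to the smallest radius.
    """
    radii = np.asarray(radii, dtype=float)
    m = np.asarray(m, dtype=float)
    if search_range is None:
        search_range = (0.0, radii[-1])
    lo, hi = search_range
    bin_size = radii[1] - radii[0] if len(radii) > 1 else 1.0

    def fallback() -> AnnulusSpec:
        return AnnulusSpec(r_min=FALLBACK_RMIN, r_max=FALLBACK_RMAX,
                           fallback_used=True)

    finite = np.isfinite(m)
    m0 = m[0] if finite[0] else np.nanmax(m)
    i_min = None
    for i in range(1, len(m) - 1):
        r = radii[i]
        if r <= 2 * bin_size or r < lo or r > hi:
            continue
        if not (finite[i - 1] and finite[i] and finite[i + 1]):
            continue
        if m[i] <= m[i - 1] and m[i] <= m[i + 1]:
            i_min = i
            break
    if i_min is None:
        return fallback()
    i_max = None
    for i in range(i_min + 1, len(m) - 1):
        if radii[i] > hi:
            break
        if not (finite[i - 1] and finite[i] and finite[i + 1]):
            continue
        if m[i] >= m[i - 1] and m[i] >= m[i + 1] and m[i] > m[i_min]:
            i_max = i
            break
    if i_max is None:
        return fallback()
    if not np.isfinite(m0) or (m[i_max] - m[i_min]) < _DEPTH_FRAC * abs(m0):
        return fallback()
    return AnnulusSpec(r_min=float(radii[i_min]), r_max=float(radii[i_max]),
                       fallback_used=False)


def _annulus_selection(corr: Correlogram2D, inner: float, outer: float):
    LX, LY = corr.lag_grids()
    dist = np.hypot(LX, LY)
    sel = (dist >= inner) & (dist <= outer)
    return LX, LY, dist, sel


def rotational_autocorrelation(corr: Correlogram2D, annulus: AnnulusSpec,
                               angle: float) -> float:
    """Pearson correlation of the annulus with itself rotated by ``angle``.

    Rotated values are bilinear interpolations of the correlogram at the
    back-rotated bin centers; bins whose rotated sample leaves the grid or
    touches an invalid lag are dropped pairwise.  Returns NaN when fewer
    than two valid pairs remain or the annulus is constant.
    """
    outer = min(annulus.outer_radius, corr.half_extent)
    LX, LY, dist, sel = _annulus_selection(corr, annulus.inner_radius, outer)
    if not sel.any():
        return np.nan
    a = corr.values[sel]
    x = LX[sel]
    y = LY[sel]
    th = np.deg2rad(angle)
    xr = np.cos(th) * x - np.sin(th) * y
    yr = np.sin(th) * x + np.cos(th) * y
    # grid coordinates: row = (lag_y - lags_y[0]) / bin, col likewise
    row = (yr - corr.lags_y[0]) / corr.bin_size
    col = (xr - corr.lags_x[0]) / corr.bin_size
    vals = np.where(corr.valid, corr.values, np.nan)
    b = ndimage.map_coordinates(vals, np.vstack([row, col]), order=1,
                                mode="constant", cval=np.nan)
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 2:
        return np.nan
    a, b = a[ok], b[ok]
    sa, sb = a.std(), b.std()
    if sa <= 1e-12 * max(abs(a).max(), 1.0) or \
       sb <= 1e-12 * max(abs(b).max(), 1.0):
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def rotational_profile(corr: Correlogram2D, annulus: AnnulusSpec,
                       step: float = 3.0) -> tuple[np.ndarray, np.ndarray]:
    """Diagnostic rotational-correlation curve r(φ) for φ in [0°, 180°]."""
    angles = np.arange(0.0, 180.0 + step / 2, step)
    vals = np.array([rotational_autocorrelation(corr, annulus, a)
                     for a in angles])
    return angles, vals


def gridness_score(corr: Correlogram2D,
                   annulus: AnnulusSpec | None = None) -> float:
    """Sixfold-symmetry score in [−2, 2]; NaN when undefined.

    Positive scores indicate hexagonal structure (high correlation at 60°
    and 120° rotations, low at 30°, 90°, 150°); a square lattice scores
    negative and a radially symmetric annulus scores 0.
    """
    if annulus is None:
        annulus = annulus_bounds(*radial_profile(corr))
    on = [rotational_autocorrelation(corr, annulus, a) for a in (60.0, 120.0)]
    off = [rotational_autocorrelation(corr, annulus, a)
           for a in (30.0, 90.0, 150.0)]
    if not (np.all(np.isfinite(on)) and np.all(np.isfinite(off))):
        return np.nan
    return float(min(on) - max(off))


def _upper_half_angles(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Angle in degrees in [0, 360) from the positive x-axis."""
    return np.rad2deg(np.arctan2(y, x)) % 360.0


def locate_ring(corr: Correlogram2D, inner: float, outer: float,
                n_peaks: int = 3) -> np.ndarray:
    """Iterative peak search on the upper half of a radial band.

    The maximum of the correlogram over the upper half-annulus (0°–180° from
    the positive x-axis) is located; a ±35° sector around it (mod 180°, via
    the correlogram's point symmetry) is excluded and the search repeats
    until ``n_peaks`` peaks are found.  Ties resolve to the lowest (row,
    column) index.  Returns peak lag coordinates, shape (n_peaks, 2).
    """
    outer = min(outer, corr.half_extent)
    if not (0 < inner < outer):
        raise ValueError("invalid radial band")
    LX, LY, dist, sel = _annulus_selection(corr, inner, outer)
    ang = _upper_half_angles(LX, LY)
    upper = sel & (ang >= 0.0) & (ang < 180.0) & corr.valid
    if not upper.any():
        raise ValueError("annulus contains no valid upper-half bins")
    vals = np.where(upper, corr.values, -np.inf)
    peaks = []
    available = upper.copy()
    for _ in range(n_peaks):
        masked = np.where(available, vals, -np.inf)
        if not np.isfinite(masked).any():
            raise ValueError(
                "annulus too narrow: peak-exclusion sectors exhausted it")
        flat = int(np.argmax(masked))  # row-major: lowest (row, col) wins ties
        iy, ix = np.unravel_index(flat, masked.shape)
        px, py = LX[iy, ix], LY[iy, ix]
        peaks.append((px, py))
        peak_ang = _upper_half_angles(np.array(px), np.array(py)) % 180.0
        d = np.abs((ang % 180.0) - peak_ang)
        d = np.minimum(d, 180.0 - d)  # point symmetry wraps 0°/180°
        available &= d >= EXCLUSION_HALF_ANGLE
    return np.asarray(peaks)


def locate_peaks(corr: Correlogram2D, annulus: AnnulusSpec) -> np.ndarray:
    """Three inner-ring peak coordinates from the extracted annulus."""
    return locate_ring(corr, annulus.inner_radius,
                       min(annulus.outer_radius, corr.half_extent))


def infer_lattice(corr: Correlogram2D,
                  annulus: AnnulusSpec | None = None) -> LatticeFeatures:
    """Spacing, orientations and gridness from a correlogram's peak ring.

    Spacing is the mean radial distance of the three peaks; orientations are
    their angles from the positive x-axis in [0°, 180°).  When the inner ring
    is obscured (track data) the detected ring may be the second ring at
    radius √3·λ rotated 30°; interpreting which ring was found is left to
    the caller (see :func:`second_ring_features`).
    """
    if annulus is None:
        annulus = annulus_bounds(*radial_profile(corr))
    peaks = locate_peaks(corr, annulus)
    radii = np.hypot(peaks[:, 0], peaks[:, 1])
    orient = _upper_half_angles(peaks[:, 0], peaks[:, 1]) % 180.0
    score = gridness_score(corr, annulus)
    return LatticeFeatures(spacing=float(radii.mean()), orientations=orient,
                           gridness=score, peaks=peaks, annulus=annulus)


def second_ring_features(corr: Correlogram2D,
                         first: LatticeFeatures | float,
                         band: tuple[float, float] = (1.37, 1.87),
                         ) -> LatticeFeatures:
    """Locate the second hexagonal ring given the first-ring spacing.

    ``first`` is the inferred first-ring features or the spacing λ itself.
    The search band defaults to (1.37, 1.87)·λ: the geometric midpoints
    between the consecutive hexagonal ring radii λ, √3·λ and 2λ, so the band
    brackets the second ring (√3 ≈ 1.73) while excluding the first and third.
    The same iterative three-peak procedure with ±35° exclusion applies.  For
    an ideal lattice the returned spacing is √3 times the first-ring spacing
    and the orientations are offset 30°.
    """
    spacing = first if isinstance(first, (int, float)) else first.spacing
    peaks = locate_ring(corr, band[0] * spacing, band[1] * spacing)
    radii = np.hypot(peaks[:, 0], peaks[:, 1])
    orient = _upper_half_angles(peaks[:, 0], peaks[:, 1]) % 180.0
    score = first.gridness if isinstance(first, LatticeFeatures) else np.nan
    annulus = first.annulus if isinstance(first, LatticeFeatures) else None
    return LatticeFeatures(spacing=float(radii.mean()), orientations=orient,
                           gridness=score, peaks=peaks, annulus=annulus)
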