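"""Field-shuffle surrogates, spike-time shuffles and permutation significance.

A field-shuffle control preserves everything about a rate map except the
spatial arrangement of its firing fields: connected suprathreshold components
are relocated uniformly at random in the same environment without overlap
(largest first), and the subthreshold pixel values are randomly reassigned to
the remaining environment bins.  If any field exceeds the per-environment
area cap (1000 cm² arena, 500 cm² track) or a placement fails, the detection
threshold is raised by 1% of the map maximum and the whole procedure
restarts.

Significance of a population gridness score is the fraction of field-shuffled
population replicates whose gridness is at least the observed one (a plain
fraction, so p may be exactly 0; this understates p by at most 1/n_controls).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import Geometry, RateMap, SpikeTrain
from .correlograms import autocorrelation_2d, population_autocorrelation
from .gridness import gridness_score

__all__ = [
    "Field",
    "ShuffleControl",
    "SignificanceResult",
    "detect_fields",
    "shuffle_fields",
    "shuffle_spikes_time",
    "gridness_significance",
    "joint_significance",
    "MAX_FIELD_AREA",
]

MAX_FIELD_AREA = {"arena": 1000.0, "track": 500.0}  # cm^2
_EIGHT_CONN = np.ones((3, 3), dtype=int)


@dataclass
class Field:
    """One connected firing field: pixel indices, values and area (cm²)."""

    rows: np.ndarray
    cols: np.ndarray
    values: np.ndarray
    area: float

    @property
    def n_pixels(self) -> int:
        return len(self.rows)


@dataclass
class ShuffleControl:
    """A field-shuffled surrogate map and the threshold that produced it."""

    control_map: RateMap
    final_threshold: float
    n_fields: int
    field_areas: list[float] = field(default_factory=list)


@dataclass
class SignificanceResult:
    observed: float
    control_scores: np.ndarray
    p_value: float

    @property
    def n_controls(self) -> int:
        return len(self.control_scores)


def detect_fields(rate_map: RateMap, threshold: float) -> list[Field]:
    """Connected components (8-neighbor) of bins above ``threshold·max``.

    ``threshold`` is a fraction in [0, 1) of the map maximum.  An all-zero
    map has no fields.
    """
    if not (0 <= threshold < 1):
        raise ValueError("threshold must be in [0, 1)")
    v = rate_map.values
    vmax = v.max()
    if vmax <= 0:
        return []
    labeled, n = ndimage.label(v > threshold * vmax, structure=_EIGHT_CONN)
    fields = []
    bin_area = rate_map.bin_size ** 2
    for lab, sl in enumerate(ndimage.find_objects(labeled), start=1):
        sub_r, sub_c = np.nonzero(labeled[sl] == lab)
        rows = sub_r + sl[0].start
        cols = sub_c + sl[1].start
        fields.append(Field(rows=rows, cols=cols, values=v[rows, cols],
                            area=len(rows) * bin_area))
    return fields


def _try_place(fields: list[Field], env_mask: np.ndarray,
               rng: np.random.Generator) -> np.ndarray | None:
    """Place fields uniformly at random without overlap; None when a field
    has no remaining position.

    Valid anchor positions for a field are enumerated exactly by cross-
    correlating the free-bin mask with the field footprint, so a placement
    is drawn uniformly over every position where the whole footprint lies on
    free environment bins, and failure means a placement is truly
    impossible (not merely unlucky).
    """
    from scipy.signal import fftconvolve

    control = np.zeros(env_mask.shape)
    free = env_mask.astype(float)
    ny, nx = env_mask.shape
    for f in fields:
        rel_r = f.rows - f.rows.min()
        rel_c = f.cols - f.cols.min()
        h = rel_r.max() + 1
        w = rel_c.max() + 1
        foot = np.zeros((h, w))
        foot[rel_r, rel_c] = 1.0
        # counts[rr, cc] = free bins covered when anchored at (rr, cc)
        counts = fftconvolve(free, foot[::-1, ::-1], mode="valid")
        ok_r, ok_c = np.nonzero(counts > f.n_pixels - 0.5)
        if len(ok_r) == 0:
            return None
        pick = rng.integers(0, len(ok_r))
        tr = rel_r + ok_r[pick]
        tc = rel_c + ok_c[pick]
        control[tr, tc] = f.values
        free[tr, tc] = 0.0
    return control


def shuffle_fields(rate_map: RateMap,
                   geometry: Geometry,
                   seed: int | np.random.SeedSequence | np.random.Generator = 0,
                   max_area: float | None = None,
                   threshold_step: float = 0.01) -> ShuffleControl:
    """Build one field-shuffled surrogate of a rate map.

    Starting from threshold 0, fields are detected and placed in decreasing
    area order; oversized fields or failed placements raise the threshold by
    ``threshold_step`` of the map maximum and restart the whole placement.
    Subthreshold pixel values are then randomly assigned to the control's
    remaining environment bins, so the value multiset over the environment
    is preserved exactly.
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    if max_area is None:
        max_area = MAX_FIELD_AREA[geometry.kind]
    env_mask = geometry.mask()
    if env_mask.shape != rate_map.shape:
        raise ValueError("geometry grid does not match the rate map")

    threshold = 0.0
    while threshold < 1.0:
        fields = detect_fields(rate_map, threshold)
        fields.sort(key=lambda f: -f.area)
        if fields and fields[0].area > max_area:
            threshold += threshold_step
            continue
        if sum(f.n_pixels for f in fields) > env_mask.sum():
            raise ValueError("environment too small for the total field area")
        control = _try_place(fields, env_mask, rng)
        if control is None:
            threshold += threshold_step
            continue
        # preserve the subthreshold value multiset on the leftover bins
        in_field = np.zeros(rate_map.shape, dtype=bool)
        for f in fields:
            in_field[f.rows, f.cols] = True
        sub_vals = rate_map.values[env_mask & ~in_field]
        # field pixels are strictly above threshold·max > 0, so the placed
        # bins are exactly the nonzero control bins at this point
        target = env_mask & ~(control > 0)
        slots = np.nonzero(target)
        if len(sub_vals) != len(slots[0]):
            raise RuntimeError("subthreshold slot count mismatch")
        perm = rng.permutation(len(sub_vals))
        control[slots] = sub_vals[perm]
        cm = RateMap(values=control, visited_mask=env_mask,
                     origin=rate_map.origin, bin_size=rate_map.bin_size)
        return ShuffleControl(control_map=cm, final_threshold=threshold,
                              n_fields=len(fields),
                              field_areas=[f.area for f in fields])
    raise ValueError("field shuffle failed: threshold escalated to 100%")


def shuffle_spikes_time(spikes: SpikeTrain,
                        session_bounds: tuple[float, float],
                        seed: int | np.random.SeedSequence = 0) -> SpikeTrain:
    """Shuffle all spikes uniformly across the session time window."""
    rng = np.random.default_rng(seed)
    t0, t1 = session_bounds
    times = np.sort(rng.uniform(t0, t1, size=len(spikes)))
    return SpikeTrain(spike_times=times, cell_id=spikes.cell_id)


def _population_gridness(maps: list[RateMap], mode: str,
                         support_mask: np.ndarray | None) -> float:
    corrs = [autocorrelation_2d(m, mode=mode, support_mask=support_mask)
             for m in maps]
    return gridness_score(population_autocorrelation(corrs))


def gridness_significance(observed_maps: list[RateMap],
                          geometry: Geometry,
                          n_controls: int = 1000,
                          seed: int | np.random.SeedSequence = 0,
                          mode: str = "zero_fill_pearson",
                          support_mask: np.ndarray | None = None,
                          max_redraws: int = 10,
                          ) -> SignificanceResult:
    """Permutation p-value for a population gridness score.

    Every control replicate field-shuffles each cell's map independently and
    scores the gridness of the resulting population autocorrelation;
    ``p = #{control ≥ observed} / n_controls`` (so p can be exactly 0).
    Replicates with undefined gridness are redrawn (with a warning).
    """
    if not observed_maps:
        raise ValueError("need at least one rate map")
    observed = _population_gridness(observed_maps, mode, support_mask)
    ss = np.random.SeedSequence(seed) \
        if not isinstance(seed, np.random.SeedSequence) else seed
    rng = np.random.default_rng(ss)
    scores = np.empty(n_controls)
    for k in range(n_controls):
        score = np.nan
        for attempt in range(max_redraws):
            shuffled = [shuffle_fields(m, geometry, seed=rng).control_map
                        for m in observed_maps]
            score = _population_gridness(shuffled, mode, support_mask)
            if np.isfinite(score):
                break
            warnings.warn(f"control replicate {k} had undefined gridness; "
                          "redrawing", stacklevel=2)
        scores[k] = score
    p = float(np.mean(scores >= observed))
    return SignificanceResult(observed=observed, control_scores=scores,
                              p_value=p)


def joint_significance(observed_pair: tuple[float, float],
                       control_pairs: np.ndarray) -> float:
    """Fraction of control pairs dominating the observed pair in both
    components (``>=`` is inclusive); a simultaneous-dominance joint test
    over matched shuffle replicates of two environments."""
    pairs = np.asarray(control_pairs, dtype=float)
    o1, o2 = observed_pair
    both = (pairs[:, 0] >= o1) & (pairs[:, 1] >= o2)
    return float(np.mean(both))
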