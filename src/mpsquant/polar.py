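"""Bullseye polar-map geometry, normalization, and the 17-segment model.

A polar map (bullseye plot) projects the left ventricle onto a disc with the
apex at the center and the base at the rim.  We sample it on a regular
``n_theta`` (angular) x ``n_r`` (radial) grid.  Arrays are stored with shape
``(n_r, n_theta)``: row 0 is the innermost (apical) ring, the last row is the
basal rim.  Angles are measured from the 3-o'clock position, counterclockwise;
cell centers sit at ``theta = (i + 0.5) * 360 / n_theta`` degrees and
``r = (j + 0.5) / n_r`` (fraction of the outer radius).

Each cell carries an area weight proportional to the annulus sector it covers
(polar Jacobian), so that "percent of left ventricle" computed from cell sums
is not biased toward the over-represented apex.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

PHASES = ("stress", "rest", "difference")


@dataclass(frozen=True)
class PolarGrid:
    """Sampling geometry of a bullseye polar map.

    Attributes
    ----------
    n_theta, n_r : int
        Number of angular and radial bins.
    area_weight : (n_r, n_theta) ndarray
        Fraction of the total disc area covered by each cell; sums to 1.
    """

    n_theta: int
    n_r: int
    area_weight: np.ndarray = field(repr=False)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_r, self.n_theta)

    @property
    def theta_centers_deg(self) -> np.ndarray:
        """Cell-center angles in degrees, 0 at 3 o'clock, counterclockwise."""
        return (np.arange(self.n_theta) + 0.5) * (360.0 / self.n_theta)

    @property
    def r_centers(self) -> np.ndarray:
        """Cell-center radii as fractions of the outer radius."""
        return (np.arange(self.n_r) + 0.5) / self.n_r


def make_polar_grid(n_theta: int, n_r: int) -> PolarGrid:
    """Build a :class:`PolarGrid` with Jacobian (annulus-sector) area weights.

    The annulus between radial edges ``r_j = j/n_r`` and ``r_{j+1}`` has area
    proportional to ``r_{j+1}^2 - r_j^2``; it is split evenly over the
    ``n_theta`` angular bins and the whole disc is normalized to total
    weight 1.
    """
    if n_theta < 4 or n_r < 2:
        raise ValueError(
            f"grid too small: need n_theta >= 4 and n_r >= 2, "
            f"got ({n_theta}, {n_r})"
        )
    edges = np.arange(n_r + 1) / n_r
    ring = edges[1:] ** 2 - edges[:-1] ** 2          # (n_r,)
    w = np.repeat(ring[:, None], n_theta, axis=1) / n_theta
    w /= w.sum()
    w.setflags(write=False)
    return PolarGrid(n_theta=n_theta, n_r=n_r, area_weight=w)


@dataclass(frozen=True)
class PolarMap:
    """Scalar uptake field on a :class:`PolarGrid`.

    ``values`` has shape ``(n_r, n_theta)``.  ``phase`` is one of
    ``"stress"``, ``"rest"`` or ``"difference"``; stress/rest values must be
    nonnegative (counts or percent), difference maps may be negative.
    ``normalized`` marks a map rescaled to percent-of-maximum (max = 100).
    """

    grid: PolarGrid
    values: np.ndarray = field(repr=False)
    phase: str = "stress"
    normalized: bool = False

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != self.grid.shape:
            raise ValueError(
                f"values shape {v.shape} does not match grid {self.grid.shape}"
            )
        if not np.all(np.isfinite(v)):
            raise ValueError("polar-map values must be finite")
        if self.phase not in PHASES:
            raise ValueError(f"phase must be one of {PHASES}, got {self.phase!r}")
        if self.phase in ("stress", "rest") and np.any(v < 0):
            raise ValueError(f"{self.phase} map has negative uptake values")
        v.setflags(write=False)
        object.__setattr__(self, "values", v)


def normalize_uptake(pmap: PolarMap) -> PolarMap:
    """Rescale a map to percent of its maximum (max cell -> 100).

    Idempotent and invariant to multiplying the input by a positive constant.
    Raises ``ValueError`` on an all-zero (or non-positive) map, for which
    percent-of-maximum is undefined.
    """
    vmax = float(np.max(pmap.values))
    if vmax <= 0:
        raise ValueError("cannot normalize a map with no positive uptake")
    return replace(pmap, values=100.0 * pmap.values / vmax, normalized=True)


def difference_map(stress: PolarMap, rest: PolarMap) -> PolarMap:
    """Per-cell rest - stress difference of two normalized maps.

    Positive where uptake recovers at rest, i.e. where the stress reduction is
    reversible.  Both inputs must share one grid and be normalized.
    """
    if stress.grid.shape != rest.grid.shape:
        raise ValueError(
            f"grid mismatch: stress {stress.grid.shape} vs rest {rest.grid.shape}"
        )
    if not (stress.normalized and rest.normalized):
        raise ValueError("difference_map requires normalized stress and rest maps")
    return PolarMap(
        grid=stress.grid,
        values=rest.values - stress.values,
        phase="difference",
        normalized=False,
    )


# --------------------------------------------------------------------------
# 17-segment model (AHA-style): 4 radial bands (apex / apical / mid / basal)
# with a 1 / 4 / 6 / 6 angular split.  The layout below is the package's
# documented convention: angles in degrees from 3 o'clock, counterclockwise,
# half-open intervals [start, stop).  Intervals wrapping 360 are split.
# --------------------------------------------------------------------------

#: radial band edges as fractions of the outer radius: apex, apical, mid, basal
RADIAL_BAND_EDGES = (0.0, 0.25, 0.5, 0.75, 1.0)

#: (segment id, label, angular interval(s) in degrees) per band, base->apex
SEGMENT_ANCHORS: dict[str, tuple[tuple[int, str, tuple[tuple[float, float], ...]], ...]] = {
    "basal": (
        (1, "basal anterior", ((60.0, 120.0),)),
        (2, "basal anteroseptal", ((120.0, 180.0),)),
        (3, "basal inferoseptal", ((180.0, 240.0),)),
        (4, "basal inferior", ((240.0, 300.0),)),
        (5, "basal inferolateral", ((300.0, 360.0),)),
        (6, "basal anterolateral", ((0.0, 60.0),)),
    ),
    "mid": (
        (7, "mid anterior", ((60.0, 120.0),)),
        (8, "mid anteroseptal", ((120.0, 180.0),)),
        (9, "mid inferoseptal", ((180.0, 240.0),)),
        (10, "mid inferior", ((240.0, 300.0),)),
        (11, "mid inferolateral", ((300.0, 360.0),)),
        (12, "mid anterolateral", ((0.0, 60.0),)),
    ),
    "apical": (
        (13, "apical anterior", ((45.0, 135.0),)),
        (14, "apical septal", ((135.0, 225.0),)),
        (15, "apical inferior", ((225.0, 315.0),)),
        (16, "apical lateral", ((315.0, 360.0), (0.0, 45.0))),
    ),
    "apex": ((17, "apex", ((0.0, 360.0),)),),
}

#: band name per radial index 0..3 (innermost first)
_BAND_BY_RADIAL_INDEX = ("apex", "apical", "mid", "basal")


@dataclass(frozen=True)
class SegmentModel17:
    """AHA-style 17-segment partition of the bullseye disc."""

    radial_edges: tuple[float, ...] = RADIAL_BAND_EDGES
    anchors: dict = field(default_factory=lambda: SEGMENT_ANCHORS)

    @property
    def labels(self) -> dict[int, str]:
        return {
            seg: name
            for band in self.anchors.values()
            for seg, name, _ in band
        }


def _band_of_radius(model: SegmentModel17, r: float) -> str:
    edges = model.radial_edges
    for b in range(4):
        if edges[b] <= r < edges[b + 1]:
            return _BAND_BY_RADIAL_INDEX[b]
    return _BAND_BY_RADIAL_INDEX[3]  # r == 1.0 edge case -> basal


def segment_of(
    grid: PolarGrid, cell: tuple[int, int], model: SegmentModel17 | None = None
) -> int:
    """Segment id (1..17) owning ``cell = (theta_index, radial_index)``."""
    if model is None:
        model = SegmentModel17()
    ti, ri = cell
    if not (0 <= ti < grid.n_theta and 0 <= ri < grid.n_r):
        raise IndexError(f"cell {cell} outside grid {grid.n_theta}x{grid.n_r}")
    theta = float(grid.theta_centers_deg[ti]) % 360.0
    r = float(grid.r_centers[ri])
    band = _band_of_radius(model, r)
    for seg, _name, intervals in model.anchors[band]:
        for lo, hi in intervals:
            if lo <= theta < hi:
                return seg
    raise AssertionError(f"no segment covers theta={theta} in band {band}")


def segment_map(grid: PolarGrid, model: SegmentModel17 | None = None) -> np.ndarray:
    """(n_r, n_theta) int array of segment ids; vectorized ``segment_of``."""
    if model is None:
        model = SegmentModel17()
    out = np.empty(grid.shape, dtype=np.int8)
    for ri in range(grid.n_r):
        for ti in range(grid.n_theta):
            out[ri, ti] = segment_of(grid, (ti, ri), model)
    return out
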