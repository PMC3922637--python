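"""Per-study quantities: defect extent (% of LV) and 17-segment scores.

Two independent routes to "percent ischemic myocardium":

* *extent*: area-weighted percentage of the left ventricle covered by the
  union of delineated reversible (difference-defect) masks;
* *SD%*: the summed difference score over the 17 AHA segments, each scored
  0 (normal) to 4 (absent uptake), expressed as a percentage of the maximum
  possible score 4 x 17 = 68.

The two routes are deliberately kept independent: SD% is driven by
segment-mean uptake, extent by delineated masks, so a study can have SD% > 0
with zero delineated extent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .delineation import DefectRegion
from .polar import PolarGrid, PolarMap, SegmentModel17, segment_map

#: maximum possible summed score: 17 segments x worst score 4
MAX_SUMMED_SCORE = 68

#: lower uptake bounds (percent of max) for scores 0..3; below the last -> 4.
#: Not from any published protocol; a transparent stand-in for the
#: normal-database scoring of commercial packages (see docs/methods.md).
DEFAULT_SCORE_BINS = (70.0, 55.0, 40.0, 25.0)


@dataclass(frozen=True)
class SegmentScores:
    """17-segment stress/rest scores and the derived summed scores."""

    stress_scores: tuple[int, ...]
    rest_scores: tuple[int, ...]

    def __post_init__(self):
        for name, scores in (("stress", self.stress_scores), ("rest", self.rest_scores)):
            if len(scores) != 17:
                raise ValueError(f"{name}_scores must have 17 entries, got {len(scores)}")
            if any((s < 0 or s > 4 or int(s) != s) for s in scores):
                raise ValueError(f"{name}_scores must be integers in 0..4: {scores}")
        object.__setattr__(self, "stress_scores", tuple(int(s) for s in self.stress_scores))
        object.__setattr__(self, "rest_scores", tuple(int(s) for s in self.rest_scores))

    @property
    def sss(self) -> int:
        """Summed stress score."""
        return sum(self.stress_scores)

    @property
    def srs(self) -> int:
        """Summed rest score."""
        return sum(self.rest_scores)

    @property
    def sds(self) -> int:
        """Summed difference score: per-segment positive part of stress-rest,
        so segments that look worse at rest do not reduce the total."""
        return sum(max(s - r, 0) for s, r in zip(self.stress_scores, self.rest_scores))


def extent_percent(regions: list[DefectRegion], grid: PolarGrid) -> float:
    """Area-weighted % of the LV covered by the union of region masks.

    The union prevents double counting where regions overlap; an empty list
    is a normal study with extent 0.
    """
    if not regions:
        return 0.0
    union = np.zeros(grid.shape, dtype=bool)
    for r in regions:
        if r.mask.shape != grid.shape:
            raise ValueError("region mask shape does not match grid")
        union |= r.mask
    return 100.0 * float(grid.area_weight[union].sum())


def per_region_extent(regions: list[DefectRegion], grid: PolarGrid) -> list[float]:
    """Extent of each region individually (overlaps not deduplicated)."""
    return [100.0 * float(grid.area_weight[r.mask].sum()) for r in regions]


def segment_scores(
    norm_map: PolarMap,
    model: SegmentModel17 | None = None,
    bins: tuple[float, float, float, float] = DEFAULT_SCORE_BINS,
) -> tuple[int, ...]:
    """Score each of the 17 segments 0..4 from area-weighted mean uptake.

    Mean uptake m (percent of max) maps to a score via the documented bins:
    m >= bins[0] -> 0, bins[1] <= m < bins[0] -> 1, ... , m < bins[3] -> 4.
    """
    if not norm_map.normalized:
        raise ValueError("segment_scores expects a normalized map")
    if model is None:
        model = SegmentModel17()
    if not all(bins[i] > bins[i + 1] for i in range(3)):
        raise ValueError(f"score bins must be strictly decreasing: {bins}")
    seg = segment_map(norm_map.grid, model)
    w = norm_map.grid.area_weight
    scores = []
    for s in range(1, 18):
        cells = seg == s
        mean_uptake = float(np.average(norm_map.values[cells], weights=w[cells]))
        score = 4
        for k, lower in enumerate(bins):
            if mean_uptake >= lower:
                score = k
                break
        scores.append(score)
    return tuple(scores)


def summed_scores(stress_scores, rest_scores) -> SegmentScores:
    """Bundle per-segment stress/rest scores; validates range and length."""
    return SegmentScores(tuple(stress_scores), tuple(rest_scores))


def sd_percent(scores: SegmentScores) -> float:
    """SDS as percent of the maximum possible score (4 x 17 = 68)."""
    return 100.0 * scores.sds / MAX_SUMMED_SCORE


@dataclass(frozen=True)
class ExtentResult:
    """Both per-study quantities plus per-region breakdown."""

    extent_percent: float
    sd_percent: float
    scores: SegmentScores
    per_region: tuple[float, ...]


def quantify_study(
    stress_norm: PolarMap,
    rest_norm: PolarMap,
    difference_defects: list[DefectRegion],
    model: SegmentModel17 | None = None,
    bins: tuple[float, float, float, float] = DEFAULT_SCORE_BINS,
) -> ExtentResult:
    """Extent (from difference-defect masks) and SD% (from segment scores)."""
    grid = stress_norm.grid
    sc = summed_scores(
        segment_scores(stress_norm, model, bins),
        segment_scores(rest_norm, model, bins),
    )
    return ExtentResult(
        extent_percent=extent_percent(difference_defects, grid),
        sd_percent=sd_percent(sc),
        scores=sc,
        per_region=tuple(per_region_extent(difference_defects, grid)),
    )
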