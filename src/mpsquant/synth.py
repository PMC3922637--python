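"""Synthetic stress/rest polar-map studies and multi-rater extent panels.

Real perfusion studies come with no ground truth, so the delineation and
agreement machinery is exercised on simulated data with known answers:

* :func:`simulate_study` builds a stress/rest polar-map pair containing
  parametric perfusion defects (location, angular/radial size, severity,
  reversibility) on a flat baseline of 100, with multiplicative Gaussian
  noise standing in for count noise after reconstruction, and returns the
  ground-truth defect masks and reversible extent.
* :func:`simulate_rater_panel` draws a patients x observers panel of extent
  values from the additive two-way random-effects model that the ICC
  estimator assumes, so the implied ICC is known in closed form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .agreement import RaterPanel
from .polar import PolarGrid, PolarMap


@dataclass(frozen=True)
class DefectSpec:
    """Parametric perfusion defect on the bullseye disc.

    ``center_theta`` (degrees) and ``center_r`` (fraction of outer radius)
    place the defect core; ``half_width_theta`` (degrees) and ``half_width_r``
    (radius fraction) give its half-sizes; ``severity`` is the fractional
    uptake reduction at the core; ``reversibility`` the fraction of the
    stress reduction recovered at rest; ``edge_softness`` the width of the
    raised-cosine edge transition, expressed as a radius fraction (the
    angular transition uses the same physical arc width at ``center_r``).
    """

    center_theta: float
    center_r: float
    half_width_theta: float
    half_width_r: float
    severity: float
    reversibility: float = 1.0
    edge_softness: float = 0.02

    def __post_init__(self):
        if not (0.0 <= self.severity <= 1.0):
            raise ValueError(f"severity must be in [0,1], got {self.severity}")
        if not (0.0 <= self.reversibility <= 1.0):
            raise ValueError(f"reversibility must be in [0,1], got {self.reversibility}")
        if not (0.0 <= self.center_r <= 1.0):
            raise ValueError(f"center_r must be in [0,1], got {self.center_r}")
        if self.half_width_theta <= 0 or self.half_width_r <= 0:
            raise ValueError("defect half-widths must be positive")
        if self.edge_softness <= 0:
            raise ValueError("edge_softness must be positive")
        if (self.center_r - self.half_width_r < -1e-9
                or self.center_r + self.half_width_r > 1.0 + 1e-9):
            raise ValueError(
                "defect radial band exceeds the disc: "
                f"center_r={self.center_r}, half_width_r={self.half_width_r}"
            )


@dataclass(frozen=True)
class GroundTruth:
    """True defect masks and reversible extent for a simulated study."""

    stress_defect_mask: np.ndarray  # bool (n_r, n_theta)
    reversible_mask: np.ndarray     # bool, subset of stress_defect_mask
    true_extent_percent: float      # area-weighted % of LV under reversible_mask


def _soft_window(d: np.ndarray, half_width: float, softness: float) -> np.ndarray:
    """1-D raised-cosine window: 1 inside, cosine rolloff of width ``softness``
    ending at ``half_width``, 0 beyond.  The half-height point sits at
    ``half_width - softness/2``."""
    w = np.zeros_like(d)
    inner = half_width - softness
    w[d <= inner] = 1.0
    trans = (d > inner) & (d < half_width)
    w[trans] = 0.5 * (1.0 + np.cos(np.pi * (d[trans] - inner) / softness))
    return w


def defect_profile(grid: PolarGrid, spec: DefectSpec) -> np.ndarray:
    """Separable angular x radial defect profile in [0, 1] on grid cells."""
    theta = grid.theta_centers_deg[None, :]
    r = grid.r_centers[:, None]
    d_theta = np.abs((theta - spec.center_theta + 180.0) % 360.0 - 180.0)
    d_r = np.abs(r - spec.center_r)
    # angular softness with the same arc width as the radial transition
    soft_theta = math.degrees(spec.edge_softness / max(spec.center_r, 1e-6))
    w_theta = _soft_window(
        np.broadcast_to(d_theta, grid.shape).copy(), spec.half_width_theta, soft_theta
    )
    w_r = _soft_window(
        np.broadcast_to(d_r, grid.shape).copy(), spec.half_width_r, spec.edge_softness
    )
    return w_theta * w_r


def simulate_study(
    grid: PolarGrid,
    defects: list[DefectSpec],
    noise_level: float = 0.0,
    seed: int = 0,
    baseline: float = 100.0,
) -> tuple[PolarMap, PolarMap, GroundTruth]:
    """Simulate a stress/rest polar-map pair with known defects.

    Uptake starts at a flat ``baseline``; each defect multiplies the stress
    map by ``1 - severity * profile`` and the rest map by
    ``1 - severity * (1 - reversibility) * profile`` (overlapping defects
    combine multiplicatively).  Multiplicative Gaussian noise of relative SD
    ``noise_level`` is then applied with the given ``seed``.

    Ground-truth masks use the full-width-half-maximum convention: a cell is
    in a defect's mask where its noise-free profile exceeds 0.5 (i.e. the
    stress reduction exceeds half the core severity); the reversible mask is
    the union over defects with ``reversibility > 0``.
    """
    if noise_level < 0:
        raise ValueError("noise_level must be nonnegative")
    stress = np.full(grid.shape, baseline, dtype=float)
    rest = np.full(grid.shape, baseline, dtype=float)
    stress_mask = np.zeros(grid.shape, dtype=bool)
    rev_mask = np.zeros(grid.shape, dtype=bool)
    for spec in defects:
        prof = defect_profile(grid, spec)
        stress *= 1.0 - spec.severity * prof
        rest *= 1.0 - spec.severity * (1.0 - spec.reversibility) * prof
        core = prof > 0.5
        if spec.severity > 0:
            stress_mask |= core
            if spec.reversibility > 0:
                rev_mask |= core
    if noise_level > 0:
        rng = np.random.default_rng(seed)
        stress = np.clip(stress * (1.0 + noise_level * rng.standard_normal(grid.shape)), 0, None)
        rest = np.clip(rest * (1.0 + noise_level * rng.standard_normal(grid.shape)), 0, None)
    truth = GroundTruth(
        stress_defect_mask=stress_mask,
        reversible_mask=rev_mask,
        true_extent_percent=100.0 * float(grid.area_weight[rev_mask].sum()),
    )
    return (
        PolarMap(grid=grid, values=stress, phase="stress"),
        PolarMap(grid=grid, values=rest, phase="rest"),
        truth,
    )


@dataclass(frozen=True)
class RaterPanelSpec:
    """Two-way random-effects generating model for a rater panel.

    ``value(i,j) = grand_mean + p_i + o_j + e_ij`` with independent zero-mean
    normal draws: ``p ~ N(0, patient_sd^2)`` (between-patient spread of true
    extent), ``o ~ N(0, rater_sd^2)`` (systematic rater bias) and
    ``e ~ N(0, error_sd^2)`` (residual).  All SDs in percentage points.
    """

    n_patients: int
    n_raters: int
    patient_sd: float
    rater_sd: float
    error_sd: float
    grand_mean: float = 20.0

    def __post_init__(self):
        if self.n_patients < 2 or self.n_raters < 2:
            raise ValueError("need at least 2 patients and 2 raters")
        if min(self.patient_sd, self.rater_sd, self.error_sd) < 0:
            raise ValueError("SDs must be nonnegative")

    @property
    def implied_icc(self) -> float:
        """Closed-form ICC of the generating model (before any clipping)."""
        num = self.patient_sd**2
        den = self.patient_sd**2 + self.rater_sd**2 + self.error_sd**2
        return num / den if den > 0 else 1.0


def simulate_rater_panel(
    spec: RaterPanelSpec, seed: int = 0
) -> tuple[RaterPanel, np.ndarray]:
    """Draw a patients x raters extent panel from the two-way model.

    Values are clipped into [0, 100] (extents are percentages); the number of
    clipped cells is reported on the returned panel rather than hidden,
    because clipping biases the ICC.  Also returns the patient effects
    ``p_i`` (the per-patient true deviations), which downstream experiments
    use as a noise-free reference reading.
    """
    rng = np.random.default_rng(seed)
    p = spec.patient_sd * rng.standard_normal(spec.n_patients)
    o = spec.rater_sd * rng.standard_normal(spec.n_raters)
    e = spec.error_sd * rng.standard_normal((spec.n_patients, spec.n_raters))
    raw = spec.grand_mean + p[:, None] + o[None, :] + e
    clipped = np.clip(raw, 0.0, 100.0)
    n_clipped = int(np.sum(raw != clipped))
    return RaterPanel(values=clipped, n_clipped=n_clipped), p
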