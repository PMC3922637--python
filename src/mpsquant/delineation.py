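"""Two-stage automatic delineation of reversible perfusion defects.

Stage 1 finds "stress defects": seed points are taken at local uptake minima
of the normalized stress map, and a closed deformable contour (snake) of
circular topology is grown from each seed and fit by greedy energy descent
using edge (gradient-magnitude) and intensity information.  Stage 2 extracts
the strictly reversible "difference defects": the rest-stress difference map
is Gaussian-smoothed and thresholded, and only connected components lying
inside stage-1 stress defects are kept.

The polar grid is treated as a Cartesian lattice that is periodic in the
angular direction; lattice coordinates are ``(x, y) = (theta_index,
radial_index)`` with cell centers at integers.  Contours that would need to
enclose the apex center (full-circle defects at r ~ 0) are outside this
parameterization and are a documented limitation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
from matplotlib.path import Path as MplPath
from scipy import ndimage

from .polar import PolarMap, difference_map, normalize_uptake


@dataclass(frozen=True)
class DelineationParams:
    """Tunable parameters of the two-stage delineation.

    None of these constants come from a published protocol; they are the
    package's documented defaults (see docs/methods.md) and all are
    overridable.
    """

    depth_threshold: float = 70.0   # seed cells must be darker than this % of max
    n_vertices: int = 32            # snake vertices (>= 8)
    alpha: float = 0.1              # membrane (spacing) weight
    beta: float = 0.05              # thin-plate (curvature) weight
    gamma_edge: float = 1.0         # gradient-magnitude attraction weight
    gamma_intensity: float = 1.0    # low-uptake attraction weight
    step: float = 1.0               # greedy move size, lattice cells
    max_iter: int = 500             # greedy sweeps
    tol: float = 1e-4               # energy-change stopping tolerance
    sigma: float = 2.0              # stage-2 Gaussian smoothing width, cells
    rev_threshold: float = 10.0     # stage-2 threshold on smoothed rest-stress, % points
    min_area_cells: int = 4         # discard regions smaller than this

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class Contour:
    """Closed snake in lattice coordinates of circular topology.

    ``vertices`` is an (M, 2) array of (theta_index, r_index) points; the
    theta coordinate is continuous and unwrapped (reduce mod n_theta to map
    onto the grid).  The polygon is star-shaped around ``seed`` by
    construction, hence closed and non-self-intersecting, with the seed in
    its interior.
    """

    vertices: np.ndarray = field(repr=False)
    seed: tuple[float, float] = (0.0, 0.0)
    energy_trace: tuple[float, ...] = ()
    converged: bool = True


@dataclass(frozen=True)
class DefectRegion:
    """A delineated defect: boolean cell mask plus optional contour."""

    mask: np.ndarray = field(repr=False)
    kind: str = "stress_defect"  # or "difference_defect"
    contour: Contour | None = None
    seeds: tuple = ()            # provenance: originating seed cells

    def __post_init__(self):
        if self.kind not in ("stress_defect", "difference_defect"):
            raise ValueError(f"unknown region kind {self.kind!r}")
        if not np.any(self.mask):
            raise ValueError("a DefectRegion mask must be nonempty")

    @property
    def n_cells(self) -> int:
        return int(self.mask.sum())


# --------------------------------------------------------------------------
# seeds
# --------------------------------------------------------------------------


def find_seeds(stress_norm: PolarMap, depth_threshold: float = 70.0) -> list[tuple[int, int]]:
    """Seed cells: strict local minima below ``depth_threshold`` % of max.

    A cell is a candidate if no 8-neighbor is lower (angular wrap-around;
    radial edges one-sided) and its value is below the threshold.  Equal-value
    plateau cells that jointly form a minimum collapse to the plateau's
    centroid cell.  Returns ``(theta_index, radial_index)`` tuples; an empty
    list is a normal result.
    """
    if not stress_norm.normalized:
        raise ValueError("find_seeds expects a normalized (percent-of-max) map")
    v = stress_norm.values
    n_r, n_theta = v.shape
    # min over the 3x3 neighborhood, wrapping theta, clamping r
    padded = np.pad(v, ((1, 1), (0, 0)), mode="edge")
    padded = np.pad(padded, ((0, 0), (1, 1)), mode="wrap")
    neigh_min = ndimage.minimum_filter(padded, size=3)[1:-1, 1:-1]
    cand = (v <= neigh_min) & (v < depth_threshold)
    if not np.any(cand):
        return []
    # group equal-valued candidate plateaus (8-connected, theta-periodic)
    labels, n_lab = _label_periodic(cand)
    seeds: list[tuple[int, int]] = []
    for lab in range(1, n_lab + 1):
        comp = labels == lab
        vals = v[comp]
        if not np.allclose(vals, vals.flat[0]):
            # mixed-value component: keep each strict minimum cell separately
            for rj, ti in zip(*np.nonzero(comp & (v == vals.min()))):
                seeds.append((int(ti), int(rj)))
            continue
        # strictness: every bordering non-plateau neighbor must be higher
        border = _dilate_periodic(comp) & ~comp
        if border.size and np.any(v[border] <= vals.flat[0]):
            continue
        rjs, tis = np.nonzero(comp)
        rj = int(round(rjs.mean()))
        # circular mean of theta indices
        ang = tis * (2 * np.pi / n_theta)
        ti = int(round(np.arctan2(np.sin(ang).mean(), np.cos(ang).mean())
                       / (2 * np.pi / n_theta))) % n_theta
        # snap to a cell inside the plateau (centroid may fall just outside)
        if not comp[rj, ti]:
            d2 = (rjs - rjs.mean()) ** 2 + (np.minimum((tis - ti) % n_theta,
                                                       (ti - tis) % n_theta)) ** 2
            k = int(np.argmin(d2))
            rj, ti = int(rjs[k]), int(tis[k])
        seeds.append((ti, rj))
    seeds.sort()
    return seeds


def _label_periodic(mask: np.ndarray) -> tuple[np.ndarray, int]:
    """8-connected labeling with wrap-around in the theta (column) axis."""
    structure = np.ones((3, 3), dtype=bool)
    labels, n = ndimage.label(mask, structure=structure)
    if n == 0 or mask.shape[1] < 2:
        return labels, n
    # merge labels touching across the theta seam (8-connectivity)
    parent = list(range(n + 1))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    left, right = labels[:, 0], labels[:, -1]
    n_r = mask.shape[0]
    for j in range(n_r):
        if left[j]:
            for dj in (-1, 0, 1):
                jj = j + dj
                if 0 <= jj < n_r and right[jj]:
                    union(left[j], right[jj])
    remap = {}
    out = np.zeros_like(labels)
    next_id = 0
    for lab in range(1, n + 1):
        root = find(lab)
        if root not in remap:
            next_id += 1
            remap[root] = next_id
    for lab in range(1, n + 1):
        out[labels == lab] = remap[find(lab)]
    return out, next_id


def _dilate_periodic(mask: np.ndarray) -> np.ndarray:
    padded = np.pad(mask, ((1, 1), (0, 0)), mode="constant")
    padded = np.pad(padded, ((0, 0), (1, 1)), mode="wrap")
    dil = ndimage.binary_dilation(padded, structure=np.ones((3, 3), bool))
    return dil[1:-1, 1:-1]


# --------------------------------------------------------------------------
# snake
# --------------------------------------------------------------------------


def _bilinear(arr: np.ndarray, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Bilinear sample at lattice coords (x=theta col, wraps; y=r row, clamps)."""
    n_r, n_theta = arr.shape
    y = np.clip(y, 0.0, n_r - 1.0)
    x0 = np.floor(x).astype(int)
    y0 = np.floor(np.clip(y, 0, n_r - 2)).astype(int)
    fx = x - x0
    fy = y - y0
    x0m = x0 % n_theta
    x1m = (x0 + 1) % n_theta
    y1 = y0 + 1
    v00 = arr[y0, x0m]
    v01 = arr[y0, x1m]
    v10 = arr[y1, x0m]
    v11 = arr[y1, x1m]
    return (v00 * (1 - fx) * (1 - fy) + v01 * fx * (1 - fy)
            + v10 * (1 - fx) * fy + v11 * fx * fy)


def _gradient_magnitude(values: np.ndarray) -> np.ndarray:
    """|grad I| by central differences, periodic in theta, one-sided in r."""
    gx = (np.roll(values, -1, axis=1) - np.roll(values, 1, axis=1)) / 2.0
    gy = np.gradient(values, axis=0)
    return np.hypot(gx, gy)


def _snake_energy(
    xs: np.ndarray, ys: np.ndarray, img: np.ndarray, grad: np.ndarray,
    p: DelineationParams,
) -> float:
    dx = np.diff(np.append(xs, xs[0]))
    dy = np.diff(np.append(ys, ys[0]))
    e_mem = float(np.sum(dx**2 + dy**2))
    cx = np.roll(xs, -1) - 2 * xs + np.roll(xs, 1)
    cy = np.roll(ys, -1) - 2 * ys + np.roll(ys, 1)
    e_curv = float(np.sum(cx**2 + cy**2))
    e_edge = float(np.sum(_bilinear(grad, xs, ys)))
    # intensity as fraction of max (0..1): keeps the edge term (percentage
    # points per cell) dominant at defect borders, so the contour settles on
    # the gradient ridge instead of being dragged into the dark interior
    e_int = float(np.sum(_bilinear(img, xs, ys))) / 100.0
    return (p.alpha * e_mem + p.beta * e_curv
            - p.gamma_edge * e_edge + p.gamma_intensity * e_int)


def _init_radii(
    img: np.ndarray, seed: tuple[float, float], phi: np.ndarray,
    n_r: int, seed_val: float,
) -> np.ndarray:
    """Per-ray initial radius: march outward to the half-height crossing
    between the seed value and the normal plateau (100 on a normalized map).

    The snake energy has no inflation term, so a small-circle start cannot
    cross the flat interior of a wide defect; starting each vertex at the
    half-rise point along its ray puts it near the defect edge, which the
    greedy descent then refines.
    """
    half = 0.5 * (seed_val + 100.0)
    sx, sy = seed
    max_rho = 1.5 * n_r  # rays leave the grid radially well before this
    rhos = np.empty(phi.shape)
    for k, a in enumerate(phi):
        ca, sa = math.cos(a), math.sin(a)
        rho = 0.75
        found = None
        while rho <= max_rho:
            y = sy + rho * sa
            if y < -0.5 or y > n_r - 0.5:
                break
            if _bilinear(img, np.array([sx + rho * ca]), np.array([y]))[0] >= half:
                found = rho
                break
            rho += 0.25
        if found is None:
            # no rise along this ray: stop at the grid edge (defect reaches
            # the rim/apex in this direction)
            found = rho
        rhos[k] = max(found, 0.75)
    return rhos


def fit_active_contour(
    stress_norm: PolarMap, seed: tuple[int, int],
    params: DelineationParams | None = None,
) -> Contour:
    """Fit a closed snake around a low-uptake seed by greedy energy descent.

    The energy is the classical combination

        E = alpha * sum |v_{k+1}-v_k|^2 + beta * sum |v_{k+1}-2 v_k+v_{k-1}|^2
            - gamma_edge * sum |grad I(v_k)| + gamma_int * sum I(v_k)

    with I the normalized uptake in percent (low uptake attracts the
    contour).  Vertices are parameterized by their radius along fixed,
    evenly-spaced ray directions from the seed, so the polygon is always
    star-shaped (closed, non-self-intersecting, seed inside).  Each greedy
    sweep moves every vertex radially by +/- ``step`` if that lowers E;
    iteration stops when the energy improvement falls below ``tol`` or after
    ``max_iter`` sweeps (the contour is then flagged, not rejected).
    """
    p = params or DelineationParams()
    if p.n_vertices < 8:
        raise ValueError("a contour needs at least 8 vertices")
    img = stress_norm.values
    n_r, n_theta = img.shape
    ti, rj = int(seed[0]) % n_theta, int(seed[1])
    if not (0 <= rj <= n_r - 2):
        raise ValueError(
            f"seed radial index {rj} is on or outside the disc boundary"
        )
    grad = _gradient_magnitude(img)
    phi = 2 * np.pi * np.arange(p.n_vertices) / p.n_vertices
    seed_xy = (float(ti), float(rj))
    seed_val = float(img[rj, ti])
    rhos = _init_radii(img, seed_xy, phi, n_r, seed_val)

    cos_phi, sin_phi = np.cos(phi), np.sin(phi)

    def positions(r):
        return seed_xy[0] + r * cos_phi, seed_xy[1] + r * sin_phi

    def rho_limits(k):
        # keep the vertex on the disc: y in [-0.49, n_r - 0.51]
        lo, hi = 0.5, 1.5 * n_r
        if sin_phi[k] > 1e-12:
            hi = min(hi, (n_r - 0.51 - seed_xy[1]) / sin_phi[k])
        elif sin_phi[k] < -1e-12:
            hi = min(hi, (-0.49 - seed_xy[1]) / sin_phi[k])
        return lo, max(hi, lo)

    for k in range(p.n_vertices):
        lo, hi = rho_limits(k)
        rhos[k] = min(max(rhos[k], lo), hi)

    xs, ys = positions(rhos)
    energy = _snake_energy(xs, ys, img, grad, p)
    trace = [energy]
    converged = False
    for _ in range(p.max_iter):
        improved = 0.0
        for k in range(p.n_vertices):
            lo, hi = rho_limits(k)
            best_rho, best_e = rhos[k], energy
            for delta in (-p.step, p.step):
                cand = rhos[k] + delta
                if cand < lo or cand > hi:
                    continue
                old = rhos[k]
                rhos[k] = cand
                xs, ys = positions(rhos)
                e = _snake_energy(xs, ys, img, grad, p)
                if e < best_e - 1e-12:
                    best_rho, best_e = cand, e
                rhos[k] = old
            if best_rho != rhos[k]:
                improved += energy - best_e
                rhos[k] = best_rho
                energy = best_e
        trace.append(energy)
        if improved < p.tol:
            converged = True
            break
    xs, ys = positions(rhos)
    verts = np.column_stack([xs, ys])
    return Contour(
        vertices=verts, seed=seed_xy, energy_trace=tuple(trace), converged=converged
    )


def rasterize_contour(contour: Contour, shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask of cells whose centers fall inside the contour polygon.

    Even-odd rule via matplotlib's path test; angular wrap-around is handled
    by testing each cell center at theta, theta +/- n_theta (the polygon is
    built unwrapped around its seed).
    """
    n_r, n_theta = shape
    path = MplPath(np.vstack([contour.vertices, contour.vertices[:1]]))
    yy, xx = np.mgrid[0:n_r, 0:n_theta]
    pts = np.column_stack([xx.ravel().astype(float), yy.ravel().astype(float)])
    inside = np.zeros(len(pts), dtype=bool)
    for shift in (-n_theta, 0, n_theta):
        q = pts.copy()
        q[:, 0] += shift
        inside |= path.contains_points(q)
    return inside.reshape(shape)


# --------------------------------------------------------------------------
# stage 1 / stage 2 / pipeline
# --------------------------------------------------------------------------


def delineate_stress_defects(
    stress_norm: PolarMap, params: DelineationParams | None = None
) -> list[DefectRegion]:
    """Stage 1: seeds -> snakes -> rasterized masks -> merge -> size filter.

    Masks overlapping by at least one cell are merged (union mask; the
    originating contours are kept as provenance on the first region of each
    merged group via ``seeds``).  Regions below ``min_area_cells`` cells are
    discarded.  Output masks are pairwise disjoint.
    """
    p = params or DelineationParams()
    seeds = find_seeds(stress_norm, p.depth_threshold)
    raw: list[tuple[np.ndarray, Contour, tuple[int, int]]] = []
    for s in seeds:
        c = fit_active_contour(stress_norm, s, p)
        m = rasterize_contour(c, stress_norm.grid.shape)
        m[s[1], s[0]] = True  # the seed cell itself always belongs
        raw.append((m, c, s))
    # merge overlapping masks with union-find
    n = len(raw)
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i in range(n):
        for j in range(i + 1, n):
            if np.any(raw[i][0] & raw[j][0]):
                ri, rjx = find(i), find(j)
                if ri != rjx:
                    parent[max(ri, rjx)] = min(ri, rjx)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    regions = []
    for members in groups.values():
        mask = np.zeros(stress_norm.grid.shape, dtype=bool)
        for i in members:
            mask |= raw[i][0]
        if mask.sum() < p.min_area_cells:
            continue
        regions.append(
            DefectRegion(
                mask=mask,
                kind="stress_defect",
                contour=raw[members[0]][1],
                seeds=tuple(raw[i][2] for i in members),
            )
        )
    regions.sort(key=lambda r: (-r.n_cells, r.seeds))
    return regions


def extract_reversible(
    stress_defects: list[DefectRegion],
    diff: PolarMap,
    sigma: float = 2.0,
    rev_threshold: float = 10.0,
    min_area_cells: int = 4,
) -> list[DefectRegion]:
    """Stage 2: smooth + threshold the difference map inside stress defects.

    The rest-stress difference is Gaussian-smoothed (angular wrap-around,
    radial edges clamped) and cells exceeding ``rev_threshold`` percentage
    points are selected, but only inside stage-1 stress-defect masks; the
    selection is split into connected components per parent defect, so every
    difference defect is contained in exactly one stress defect.
    """
    if diff.phase != "difference":
        raise ValueError("extract_reversible expects a difference map")
    if not stress_defects:
        return []
    if stress_defects[0].mask.shape != diff.grid.shape:
        raise ValueError("stress-defect masks and difference map are on different grids")
    if sigma > 0:
        smoothed = ndimage.gaussian_filter(diff.values, sigma, mode=("nearest", "wrap"))
    else:
        smoothed = diff.values
    hot = smoothed > rev_threshold
    out: list[DefectRegion] = []
    for parent in stress_defects:
        sel = hot & parent.mask
        if not np.any(sel):
            continue
        labels, n_lab = _label_periodic(sel)
        for lab in range(1, n_lab + 1):
            comp = labels == lab
            if comp.sum() < min_area_cells:
                continue
            out.append(DefectRegion(mask=comp, kind="difference_defect"))
    out.sort(key=lambda r: -r.n_cells)
    return out


def delineate(
    stress: PolarMap, rest: PolarMap, params: DelineationParams | None = None
) -> tuple[list[DefectRegion], list[DefectRegion]]:
    """Full two-stage pipeline on a raw stress/rest pair.

    Both maps are normalized to percent of maximum, stage 1 delineates stress
    defects on the stress map, and stage 2 extracts reversible difference
    defects from the smoothed, thresholded rest-stress difference inside
    them.  Returns ``(stress_defects, difference_defects)``; extent and SD%
    downstream are computed from the difference defects.
    """
    p = params or DelineationParams()
    if stress.grid.shape != rest.grid.shape:
        raise ValueError("stress and rest maps are on different grids")
    s_norm = normalize_uptake(stress)
    r_norm = normalize_uptake(rest)
    diff = difference_map(s_norm, r_norm)
    stress_defects = delineate_stress_defects(s_norm, p)
    difference_defects = extract_reversible(
        stress_defects, diff, p.sigma, p.rev_threshold, p.min_area_cells
    )
    return stress_defects, difference_defects
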