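"""File formats: polar-map CSV + JSON sidecar, regions JSON, panels, fixture.

Interchange convention for polar maps (there is no standard file format for
bullseye data): a dense numeric CSV with rows = radial bins from apex to
base and columns = angular bins (0 deg at 3 o'clock, counterclockwise), plus
a small JSON sidecar carrying ``n_theta``, ``n_r``, ``phase`` and the
``normalized`` flag.  Values round-trip at full float precision.

Defect regions are serialized as JSON with per-radial-row run-length encoded
masks (reviewable diffs) and the contour vertex list when present.
"""

from __future__ import annotations

import importlib.resources
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .agreement import RaterPanel
from .delineation import Contour, DefectRegion
from .polar import PolarMap, make_polar_grid


def _sidecar_path(path) -> Path:
    p = Path(path)
    return p.with_suffix(p.suffix + ".json") if p.suffix != ".csv" \
        else p.with_suffix(".json")


def write_polar_csv(pmap: PolarMap, path) -> None:
    """Write a polar map as dense CSV plus its JSON sidecar."""
    path = Path(path)
    np.savetxt(path, pmap.values, delimiter=",", fmt="%.17g")
    meta = {
        "n_theta": pmap.grid.n_theta,
        "n_r": pmap.grid.n_r,
        "phase": pmap.phase,
        "normalized": pmap.normalized,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1) + "\n")


def read_polar_csv(path, phase: str | None = None) -> PolarMap:
    """Read a polar-map CSV (+sidecar when present).

    Without a sidecar the grid dimensions are inferred from the matrix shape
    and ``phase`` must be supplied.  Ragged rows or non-numeric cells raise a
    parse error naming the offending row (1-based).
    """
    path = Path(path)
    rows: list[list[float]] = []
    width = None
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.split(",")
        if width is None:
            width = len(fields)
        elif len(fields) != width:
            raise ValueError(
                f"{path.name}: ragged CSV at row {lineno} "
                f"({len(fields)} fields, expected {width})"
            )
        try:
            rows.append([float(f) for f in fields])
        except ValueError as exc:
            raise ValueError(f"{path.name}: non-numeric cell at row {lineno}: {exc}")
    if not rows:
        raise ValueError(f"{path.name}: empty polar-map CSV")
    values = np.array(rows)
    sidecar = _sidecar_path(path)
    normalized = False
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        if (meta["n_r"], meta["n_theta"]) != values.shape:
            raise ValueError(
                f"{path.name}: sidecar dims ({meta['n_r']}, {meta['n_theta']}) "
                f"do not match CSV shape {values.shape}"
            )
        phase = phase or meta["phase"]
        normalized = bool(meta.get("normalized", False))
    if phase is None:
        raise ValueError(f"{path.name}: no sidecar found; pass phase explicitly")
    grid = make_polar_grid(values.shape[1], values.shape[0])
    return PolarMap(grid=grid, values=values, phase=phase, normalized=normalized)


# --------------------------------------------------------------------------
# regions JSON (run-length encoded masks)
# --------------------------------------------------------------------------


def _mask_to_rle(mask: np.ndarray) -> list[list]:
    out = []
    for j, row in enumerate(mask):
        runs = []
        start = None
        for i, v in enumerate(row):
            if v and start is None:
                start = i
            elif not v and start is not None:
                runs.append([start, i - start])
                start = None
        if start is not None:
            runs.append([start, len(row) - start])
        if runs:
            out.append([j, runs])
    return out


def _rle_to_mask(rle: list, shape: tuple[int, int]) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    for j, runs in rle:
        for start, length in runs:
            mask[j, start:start + length] = True
    return mask


def write_regions_json(
    regions: list[DefectRegion], shape: tuple[int, int], path
) -> None:
    items = []
    for r in regions:
        item = {
            "kind": r.kind,
            "rle": _mask_to_rle(r.mask),
            "contour": None if r.contour is None
            else np.asarray(r.contour.vertices).round(4).tolist(),
            "seeds": [list(s) for s in r.seeds],
        }
        items.append(item)
    Path(path).write_text(
        json.dumps({"shape": list(shape), "regions": items}, indent=1) + "\n"
    )


def read_regions_json(path) -> tuple[list[DefectRegion], tuple[int, int]]:
    doc = json.loads(Path(path).read_text())
    shape = tuple(doc["shape"])
    regions = []
    for item in doc["regions"]:
        contour = None
        if item.get("contour"):
            contour = Contour(vertices=np.asarray(item["contour"], dtype=float))
        regions.append(
            DefectRegion(
                mask=_rle_to_mask(item["rle"], shape),
                kind=item["kind"],
                contour=contour,
                seeds=tuple(tuple(s) for s in item.get("seeds", [])),
            )
        )
    return regions, shape


# --------------------------------------------------------------------------
# panels
# --------------------------------------------------------------------------


def write_panel_csv(panel: RaterPanel, path) -> None:
    panel.to_frame().to_csv(path, index_label="patient")


def read_panel_csv(path) -> RaterPanel:
    """Read a wide patients x observers CSV (first column = patient ids)."""
    df = pd.read_csv(path, index_col=0)
    return RaterPanel(
        values=df.to_numpy(dtype=float),
        patient_ids=tuple(str(i) for i in df.index),
        observer_ids=tuple(str(c) for c in df.columns),
    )


def load_reference_panel() -> pd.DataFrame:
    """Packaged per-patient reference table: extent and SD% reported by four
    commercial quantification programs plus the physicians' median (range)
    for 25 patients with reversible ischemia."""
    with importlib.resources.files("mpsquant.data").joinpath(
        "reference_extent_panel.csv"
    ).open() as fh:
        return pd.read_csv(fh, index_col="patient")


def write_polar_png(pmap: PolarMap, path, regions: list[DefectRegion] | None = None) -> None:
    """Render a bullseye view of a polar map (optional region overlay)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    grid = pmap.grid
    theta_edges = np.linspace(0, 2 * np.pi, grid.n_theta + 1)
    r_edges = np.linspace(0, 1, grid.n_r + 1)
    fig, ax = plt.subplots(subplot_kw={"projection": "polar"}, figsize=(4, 4))
    ax.set_theta_zero_location("E")
    ax.set_theta_direction(1)
    tt, rr = np.meshgrid(theta_edges, r_edges)
    pcm = ax.pcolormesh(tt, rr, pmap.values, cmap="inferno", shading="flat")
    if regions:
        overlay = np.zeros(grid.shape)
        for r in regions:
            overlay[r.mask] = 1.0
        ax.contour(
            (tt[:-1, :-1] + tt[1:, 1:]) / 2,
            (rr[:-1, :-1] + rr[1:, 1:]) / 2,
            overlay, levels=[0.5], colors="cyan", linewidths=1.2,
        )
    ax.set_yticklabels([])
    ax.set_xticklabels([])
    fig.colorbar(pcm, ax=ax, shrink=0.7)
    fig.savefig(path, dpi=110, bbox_inches="tight")
    plt.close(fig)
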