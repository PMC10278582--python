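"""Curvilinear cortical coordinate system from a Laplacian potential.

Given a labeled ribbon mask (pial boundary, gray/white boundary,
interior), a harmonic potential psi is solved between the two
boundaries (Dirichlet: psi = 0 at the pial surface, 1 at the gray/white
junction).  Streamlines of grad(psi) traced from 50 equally spaced pial
origins give "grid-lines" through the cortical depth; each is resampled
to 10 equidistant vertices so depth index d means relative depth d/9
regardless of local thickness.  Scalar maps are then sampled at the 500
vertices by bilinear interpolation, giving one 50 x 10 "metric sheet"
per subject per metric — the unit of all group statistics downstream.

All positions are world coordinates (mm); the mask's affine maps voxel
indices (row, col) of the analyzed 2D slice to world (x, y).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, sparse
from scipy.sparse.linalg import spsolve

from .io_core import ImageVolume

__all__ = [
    "LABEL_INTERIOR",
    "LABEL_PIAL",
    "LABEL_WM",
    "LaplaceField",
    "GridLine",
    "CorticalGrid",
    "MetricSheet",
    "TopologyError",
    "solve_laplace",
    "trace_gridlines",
    "resample_line",
    "build_grid",
    "sample_metric",
]

LABEL_INTERIOR = 1
LABEL_PIAL = 2
LABEL_WM = 3

N_LINES_DEFAULT = 50
N_DEPTHS = 10
STEP_MM_DEFAULT = 0.088


class TopologyError(ValueError):
    """Ribbon is not simply connected between the two boundaries."""


@dataclass
class LaplaceField:
    """Discrete harmonic potential on the ribbon.

    ``psi`` is NaN outside ribbon+boundaries, 0 on the pial label, 1 on
    the gray/white label, and strictly inside (0, 1) on the interior.
    """

    psi: np.ndarray
    labels: np.ndarray
    affine: np.ndarray
    voxel_size: tuple

    @property
    def interior(self) -> np.ndarray:
        return self.labels == LABEL_INTERIOR


@dataclass
class GridLine:
    """One cortical depth line: 10 ordered vertices in world mm."""

    vertices: np.ndarray  # (10, 2)
    tangents: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, float)
        if self.vertices.shape != (N_DEPTHS, 2):
            raise ValueError(f"grid-line needs {N_DEPTHS} 2D vertices")
        if self.tangents is None:
            self.tangents = _vertex_tangents(self.vertices)

    @property
    def arc_length(self) -> float:
        return float(
            np.sum(np.linalg.norm(np.diff(self.vertices, axis=0), axis=1))
        )

    @property
    def segments(self) -> np.ndarray:
        """9 unit tangent vectors between consecutive vertices."""
        d = np.diff(self.vertices, axis=0)
        return d / np.linalg.norm(d, axis=1, keepdims=True)


@dataclass
class CorticalGrid:
    """50 grid-lines ordered along the pial boundary."""

    lines: list
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.lines = list(self.lines)

    @property
    def n_lines(self) -> int:
        return len(self.lines)

    def vertices(self) -> np.ndarray:
        """(n_lines, 10, 2) vertex array."""
        return np.stack([ln.vertices for ln in self.lines])

    def tangents(self) -> np.ndarray:
        return np.stack([ln.tangents for ln in self.lines])

    def to_table(self) -> pd.DataFrame:
        rows = []
        for li, ln in enumerate(self.lines):
            for di in range(N_DEPTHS):
                rows.append(
                    dict(
                        line_index=li,
                        depth_index=di,
                        x_mm=ln.vertices[di, 0],
                        y_mm=ln.vertices[di, 1],
                        tangent_x=ln.tangents[di, 0],
                        tangent_y=ln.tangents[di, 1],
                    )
                )
        return pd.DataFrame(rows)

    @classmethod
    def from_table(cls, df: pd.DataFrame, subject_id: str = "") -> "CorticalGrid":
        lines = []
        for _, grp in df.groupby("line_index", sort=True):
            grp = grp.sort_values("depth_index")
            lines.append(
                GridLine(
                    grp[["x_mm", "y_mm"]].to_numpy(),
                    grp[["tangent_x", "tangent_y"]].to_numpy(),
                )
            )
        return cls(lines, subject_id)


@dataclass
class MetricSheet:
    """(n_lines x 10) sheet of one scalar metric on the cortical grid."""

    values: np.ndarray
    metric_name: str
    missing: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if self.values.ndim != 2 or self.values.shape[1] != N_DEPTHS:
            raise ValueError(f"sheet must be (n_lines, {N_DEPTHS})")
        if self.missing is None:
            self.missing = ~np.isfinite(self.values)
        self.missing = np.asarray(self.missing, bool)
        self.values = np.where(self.missing, np.nan, self.values)

    @property
    def shape(self) -> tuple:
        return self.values.shape

    def to_csv(self, path) -> None:
        pd.DataFrame(self.values).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, metric_name: str = "") -> "MetricSheet":
        return cls(pd.read_csv(path).to_numpy(), metric_name)


def _vertex_tangents(vertices: np.ndarray) -> np.ndarray:
    """Per-vertex unit tangents (central / one-sided differences)."""
    t = np.empty_like(vertices)
    t[0] = vertices[1] - vertices[0]
    t[-1] = vertices[-1] - vertices[-2]
    t[1:-1] = vertices[2:] - vertices[:-2]
    return t / np.linalg.norm(t, axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# Laplace solve


def solve_laplace(mask: ImageVolume, tol: float = 1e-6) -> LaplaceField:
    """Solve the discrete Laplace equation between the two boundaries.

    The 5-point stencil with Dirichlet boundaries (pial = 0, gray/white
    = 1) is assembled as a sparse system and solved directly; the
    residual of the direct solve is far below any practical ``tol``.
    """
    labels = np.asarray(mask.data)
    if labels.ndim != 2:
        raise ValueError("mask must be a 2D labeled slice")
    pial = labels == LABEL_PIAL
    wm = labels == LABEL_WM
    interior = labels == LABEL_INTERIOR
    if not pial.any() or not wm.any():
        raise ValueError("both boundary labels (2: pial, 3: gray/white) required")
    ribbon = pial | wm | interior
    # every connected piece of ribbon must touch both boundaries
    comp, n_comp = ndimage.label(ribbon, structure=[[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    for c in range(1, n_comp + 1):
        inside = comp == c
        if interior[inside].any() and not (
            pial[inside].any() and wm[inside].any()
        ):
            raise TopologyError(
                "ribbon component has no path to both boundaries"
            )

    psi = np.full(labels.shape, np.nan)
    psi[pial] = 0.0
    psi[wm] = 1.0
    idx = -np.ones(labels.shape, dtype=int)
    ii, jj = np.nonzero(interior)
    idx[ii, jj] = np.arange(len(ii))
    n = len(ii)
    if n:
        rows, cols, vals = [], [], []
        rhs = np.zeros(n)
        for k in range(n):
            rows.append(k)
            cols.append(k)
            vals.append(4.0)
        for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            ni, nj = ii + di, jj + dj
            ok = (
                (ni >= 0) & (ni < labels.shape[0])
                & (nj >= 0) & (nj < labels.shape[1])
            )
            lab = np.zeros(n, dtype=int)
            lab[ok] = labels[ni[ok], nj[ok]]
            isint = ok & (lab == LABEL_INTERIOR)
            rows.extend(np.flatnonzero(isint))
            cols.extend(idx[ni[isint], nj[isint]])
            vals.extend([-1.0] * int(isint.sum()))
            isb = ok & ((lab == LABEL_PIAL) | (lab == LABEL_WM))
            rhs[isb] += np.where(lab[isb] == LABEL_WM, 1.0, 0.0)
            # neighbors outside the ribbon: homogeneous Neumann (drop term)
            out = ~ok | (lab == 0)
            kidx = np.flatnonzero(out)
            for k in kidx:
                rows.append(k)
                cols.append(k)
                vals.append(-1.0)
        A = sparse.csr_matrix((vals, (rows, cols)), shape=(n, n))
        psi[ii, jj] = spsolve(A, rhs)
    return LaplaceField(psi, labels, mask.affine, mask.voxel_size)


# ---------------------------------------------------------------------------
# boundary ordering, streamline tracing


def _order_boundary(pixels: np.ndarray) -> np.ndarray:
    """Order boundary pixel coordinates along the curve.

    Greedy nearest-neighbor chaining from an extremal pixel; adequate
    for the simple open boundary curves of a cortical ribbon slice.
    """
    pts = pixels.astype(float)
    n = len(pts)
    if n == 1:
        return np.array([0])
    # start from the pixel farthest from the centroid (an endpoint)
    d0 = np.linalg.norm(pts - pts.mean(axis=0), axis=1)
    start = int(np.argmax(d0))
    order = [start]
    used = np.zeros(n, bool)
    used[start] = True
    cur = start
    for _ in range(n - 1):
        d = np.linalg.norm(pts - pts[cur], axis=1)
        d[used] = np.inf
        nxt = int(np.argmin(d))
        order.append(nxt)
        used[nxt] = True
        cur = nxt
    return np.array(order)


def _fill_for_gradient(psi: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Extend psi outside the ribbon so central differences are usable.

    Background pixels get the value of the nearest ribbon pixel pushed
    slightly past its Dirichlet value, keeping grad(psi) pointing
    inward at the pial edge and outward at the gray/white edge.
    """
    valid = np.isfinite(psi)
    _, (inds_i, inds_j) = ndimage.distance_transform_edt(
        ~valid, return_indices=True
    )
    filled = psi[inds_i, inds_j]
    outside = ~valid
    src_lab = labels[inds_i, inds_j]
    filled = np.where(outside & (src_lab == LABEL_PIAL), -0.05, filled)
    filled = np.where(outside & (src_lab == LABEL_WM), 1.05, filled)
    filled[valid] = psi[valid]
    return filled


def _bilinear(arr: np.ndarray, pts: np.ndarray) -> np.ndarray:
    """Bilinear interpolation of ``arr`` at float (row, col) points."""
    r = np.clip(pts[:, 0], 0.0, arr.shape[0] - 1.0)
    c = np.clip(pts[:, 1], 0.0, arr.shape[1] - 1.0)
    r0 = np.clip(np.floor(r).astype(int), 0, arr.shape[0] - 2)
    c0 = np.clip(np.floor(c).astype(int), 0, arr.shape[1] - 2)
    fr, fc = r - r0, c - c0
    return (
        arr[r0, c0] * (1 - fr) * (1 - fc)
        + arr[r0 + 1, c0] * fr * (1 - fc)
        + arr[r0, c0 + 1] * (1 - fr) * fc
        + arr[r0 + 1, c0 + 1] * fr * fc
    )


def trace_gridlines(
    field: LaplaceField,
    n_lines: int = N_LINES_DEFAULT,
    step_mm: float = STEP_MM_DEFAULT,
    max_steps: int | None = None,
):
    """Trace streamlines of grad(psi) from equally spaced pial origins.

    Fixed-step Euler integration along the normalized gradient of psi
    (direction of increasing psi, i.e. toward the gray/white junction),
    with the gradient bilinearly interpolated from central differences.
    Returns a list of (k_i, 2) world-coordinate polylines; a line that
    exceeds the step budget is returned as None (flagged missing).
    """
    labels = field.labels
    px = float(field.voxel_size[0])
    py = float(field.voxel_size[1])
    filled = _fill_for_gradient(field.psi, labels)
    gr, gc = np.gradient(filled)  # d/d(row), d/d(col), in psi per pixel
    gr = gr / px
    gc = gc / py

    pial_pix = np.argwhere(labels == LABEL_PIAL)
    if len(pial_pix) < 1:
        raise ValueError("no pial boundary pixels")
    order = _order_boundary(pial_pix)
    chain = pial_pix[order].astype(float)
    seg = np.diff(chain, axis=0) * [px, py]
    arc = np.concatenate([[0.0], np.cumsum(np.linalg.norm(seg, axis=1))])
    total = arc[-1]
    if n_lines == 1:
        targets = np.array([total / 2.0])
    else:
        targets = np.linspace(0.0, total, n_lines)
    origins = np.column_stack(
        [np.interp(targets, arc, chain[:, 0]), np.interp(targets, arc, chain[:, 1])]
    )

    ribbon = labels > 0
    thickness_mm = _ribbon_thickness_mm(field)
    if max_steps is None:
        max_steps = max(int(10 * thickness_mm / step_mm), 50)

    lines = []
    for o in origins:
        p = o.copy()
        psi_prev = float(_bilinear(filled, p[None])[0])
        pts = [p.copy()]
        ok = False
        for _ in range(max_steps):
            g = np.array(
                [_bilinear(gr, p[None])[0], _bilinear(gc, p[None])[0]]
            )
            nrm = np.linalg.norm(g)
            if nrm < 1e-12:
                break
            # step in mm, then back to pixel units per axis
            d = g / nrm
            p_new = p + step_mm * d / [px, py]
            psi_new = float(_bilinear(filled, p_new[None])[0])
            if psi_new >= 1.0:
                # clip the endpoint to the psi = 1 level crossing so the
                # traced length is independent of the integration step
                t = (1.0 - psi_prev) / max(psi_new - psi_prev, 1e-12)
                end = p + np.clip(t, 0.0, 1.0) * (p_new - p)
                # psi saturates at exactly 1.0 on the array edge; keep
                # the endpoint on the grid
                end[0] = np.clip(end[0], 0.0, labels.shape[0] - 1.0)
                end[1] = np.clip(end[1], 0.0, labels.shape[1] - 1.0)
                pts.append(end)
                ok = True
                break
            p, psi_prev = p_new, psi_new
            pts.append(p.copy())
            ri, ci = int(round(p[0])), int(round(p[1]))
            inside = (
                0 <= ri < labels.shape[0] and 0 <= ci < labels.shape[1]
            )
            if not inside or not ribbon[ri, ci]:
                ok = True  # left the ribbon sideways of the gradient field
                break
        if not ok or len(pts) < 2:
            lines.append(None)
            continue
        pix = np.array(pts)
        world = _pixels_to_world(pix, field.affine)
        lines.append(world)
    return lines


def _ribbon_thickness_mm(field: LaplaceField) -> float:
    interior = field.labels > 0
    px = float(field.voxel_size[0])
    rows = interior.sum(axis=0).max()
    cols = interior.sum(axis=1).max()
    return float(min(rows, cols)) * px


def _pixels_to_world(pix: np.ndarray, affine: np.ndarray) -> np.ndarray:
    """(k, 2) pixel (row, col) -> world (x, y) via the slice affine."""
    homo = np.column_stack(
        [pix, np.zeros(len(pix)), np.ones(len(pix))]
    )
    return (homo @ affine.T)[:, :2]


def _world_to_pixels(world: np.ndarray, affine: np.ndarray) -> np.ndarray:
    inv = np.linalg.inv(affine)
    homo = np.column_stack(
        [world, np.zeros(len(world)), np.ones(len(world))]
    )
    return (homo @ inv.T)[:, :2]


def resample_line(streamline: np.ndarray) -> GridLine:
    """Resample a polyline to 10 vertices at equal arc-length spacing."""
    pts = np.asarray(streamline, float)
    if pts.ndim != 2 or len(pts) < 2:
        raise ValueError("streamline needs >= 2 points")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    if arc[-1] <= 0:
        raise ValueError("zero-length streamline")
    t = np.linspace(0.0, arc[-1], N_DEPTHS)
    verts = np.column_stack(
        [np.interp(t, arc, pts[:, 0]), np.interp(t, arc, pts[:, 1])]
    )
    return GridLine(verts)


def build_grid(
    field: LaplaceField,
    n_lines: int = N_LINES_DEFAULT,
    step_mm: float = STEP_MM_DEFAULT,
    subject_id: str = "",
) -> CorticalGrid:
    """Trace and resample the full grid (missing lines are dropped)."""
    raw = trace_gridlines(field, n_lines=n_lines, step_mm=step_mm)
    lines = [resample_line(s) for s in raw if s is not None]
    return CorticalGrid(lines, subject_id)


def sample_metric(metric_map: ImageVolume, grid: CorticalGrid) -> MetricSheet:
    """Sample a 2D scalar map at all grid vertices (bilinear).

    Vertices outside the map, or whose four interpolation neighbors
    include non-finite data, are flagged missing.
    """
    arr = np.asarray(metric_map.data, float)
    if arr.ndim != 2:
        raise ValueError("metric map must be 2D")
    verts = grid.vertices()  # (L, 10, 2) world
    flat = verts.reshape(-1, 2)
    pix = _world_to_pixels(flat, metric_map.affine)
    eps = 1e-6  # endpoints can sit on the map edge plus float round-off
    inb = (
        (pix[:, 0] >= -eps)
        & (pix[:, 0] <= arr.shape[0] - 1 + eps)
        & (pix[:, 1] >= -eps)
        & (pix[:, 1] <= arr.shape[1] - 1 + eps)
    )
    vals = np.full(len(flat), np.nan)
    if inb.any():
        finite = np.isfinite(arr)
        support = _bilinear(finite.astype(float), pix[inb])
        v = _bilinear(np.nan_to_num(arr), pix[inb])
        v[support < 1.0 - 1e-9] = np.nan
        vals[inb] = v
    sheet = vals.reshape(verts.shape[0], N_DEPTHS)
    return MetricSheet(sheet, metric_map_name(metric_map))


def metric_map_name(metric_map: ImageVolume) -> str:
    return getattr(metric_map, "name", "")
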