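"""Parallel / perpendicular labeling of tensor compartments.

At every grid vertex the fitted compartments ("fixels") are scored by
the absolute inner product between their normalized principal axis and
the local grid-line tangent.  The compartment with the highest score is
the *parallel* fixel, the one with the lowest the *perpendicular*
fixel; with three compartments the intermediate one enters neither
class.  The absolute value makes the labeling antipodally symmetric —
fiber orientations are axial, so sign cannot carry information.  A
through-plane component of the axis lowers the score (it contributes
nothing to the in-plane inner product), so strongly out-of-plane
compartments naturally fall into the perpendicular class; no
compartment is excluded for being out-of-plane.

A voxel with a single compartment is assigned to the parallel class if
its score is at least cos(45 deg), else to the perpendicular class; the
other class is missing at that vertex.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cortical_grid import CorticalGrid, MetricSheet, N_DEPTHS
from .tensor_models import MultiTensorFit, TensorCompartment

__all__ = ["LabeledFixels", "label_fixels", "label_grid", "build_sheets"]

_SINGLE_SPLIT = np.cos(np.deg2rad(45.0))


@dataclass
class LabeledFixels:
    """Labeling outcome at one grid vertex."""

    parallel: TensorCompartment | None
    perpendicular: TensorCompartment | None
    score_parallel: float = np.nan
    score_perpendicular: float = np.nan


def _scores(fit: MultiTensorFit, tangent: np.ndarray) -> np.ndarray:
    t = np.asarray(tangent, float)
    if t.size == 2:
        t = np.array([t[0], t[1], 0.0])
    n = np.linalg.norm(t)
    if n < 1e-12:
        raise ValueError("zero tangent vector")
    t = t / n
    return np.array(
        [abs(float(c.principal_axis @ t)) for c in fit.compartments]
    )


def label_fixels(fit: MultiTensorFit, tangent: np.ndarray) -> LabeledFixels:
    """Assign parallel/perpendicular fixels for one vertex.

    Ties in score are broken toward the larger signal fraction, then by
    storage order, so the outcome is deterministic and independent of
    how the compartments happen to be ordered.
    """
    s = _scores(fit, tangent)
    comps = fit.compartments
    if len(comps) == 1:
        if s[0] >= _SINGLE_SPLIT:
            return LabeledFixels(comps[0], None, s[0], np.nan)
        return LabeledFixels(None, comps[0], np.nan, s[0])
    # sort by (score, fraction, -index): highest wins parallel
    order = sorted(
        range(len(comps)),
        key=lambda i: (s[i], comps[i].fraction, -i),
    )
    i_perp, i_par = order[0], order[-1]
    return LabeledFixels(comps[i_par], comps[i_perp], s[i_par], s[i_perp])


def label_grid(fits_at_vertices, grid: CorticalGrid):
    """Label fixels at every vertex of the grid.

    ``fits_at_vertices`` is a (n_lines, 10) nested sequence of
    :class:`MultiTensorFit` or None (missing fit).  Returns the same
    layout of :class:`LabeledFixels` / None.
    """
    tangents = grid.tangents()
    out = []
    for li in range(grid.n_lines):
        row = []
        for di in range(N_DEPTHS):
            fit = fits_at_vertices[li][di]
            row.append(
                None if fit is None else label_fixels(fit, tangents[li, di])
            )
        out.append(row)
    return out


def build_sheets(labeled, metrics=("FA", "MD")) -> dict:
    """Build the orientation-resolved metric sheets.

    From the (n_lines x 10) labeled-fixel layout, returns a dict of
    :class:`MetricSheet` keyed ``FA_par``, ``FA_perp``, ``MD_par``,
    ``MD_perp`` (for the default metrics).  Vertices whose class is
    missing stay missing — they are never zero-filled.
    """
    n_lines = len(labeled)
    sheets = {}
    for metric in metrics:
        for cls in ("par", "perp"):
            vals = np.full((n_lines, N_DEPTHS), np.nan)
            for li in range(n_lines):
                for di in range(N_DEPTHS):
                    lf = labeled[li][di]
                    if lf is None:
                        continue
                    comp = lf.parallel if cls == "par" else lf.perpendicular
                    if comp is None:
                        continue
                    vals[li, di] = getattr(comp, metric.lower())
            sheets[f"{metric}_{cls}"] = MetricSheet(vals, f"{metric}_{cls}")
    return sheets
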