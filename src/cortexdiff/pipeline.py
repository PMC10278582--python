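"""End-to-end orchestration: signals -> fits -> grid -> sheets -> stats.

One subject's processing chain is: DTI and multi-tensor fits over the
ribbon voxels; the Laplacian grid from the labeled mask; DTI FA/MD maps
sampled bilinearly at the 500 grid vertices; multi-tensor compartments
labeled parallel/perpendicular against the vertex tangent (each vertex
uses the fit of the voxel that contains it — fixels are discrete
per-voxel objects and cannot be interpolated across voxels the way
scalar maps can).  Group studies stack the resulting sheets and run the
permutation machinery.
"""

from __future__ import annotations

import numpy as np

from .cortical_grid import (
    CorticalGrid,
    MetricSheet,
    build_grid,
    sample_metric,
    solve_laplace,
    _world_to_pixels,
)
from .fixel_labeling import build_sheets, label_grid
from .group_stats import ClusterResult, GroupStudy, cluster_inference
from .io_core import AcquisitionScheme, ImageVolume
from .synthetic_data import StudyData
from .tensor_models import fa as fa_of, fit_dti_batch, fit_multi_tensor_batch

__all__ = [
    "fit_slice",
    "subject_sheets",
    "study_sheets",
    "run_group_analysis",
]

MT_METRICS = ("FA_par", "FA_perp", "MD_par", "MD_perp")
DTI_METRICS = ("FA", "MD")
ALL_METRICS = DTI_METRICS + MT_METRICS


def fit_slice(
    signal: np.ndarray,
    labels: ImageVolume,
    scheme: AcquisitionScheme,
    max_tensors: int = 3,
    merge_angle_deg: float = 20.0,
):
    """Fit DTI and the multi-tensor model at every ribbon voxel.

    Returns (fa_map, md_map, fits) where the maps are 2D ImageVolumes
    (NaN outside the ribbon) and ``fits`` is an (H, W) object array of
    MultiTensorFit / None.
    """
    lab = np.asarray(labels.data)
    ribbon = lab > 0
    Y = np.asarray(signal, float)[ribbon]
    evals, _, _ = fit_dti_batch(Y, scheme)
    fa_map = np.full(lab.shape, np.nan)
    md_map = np.full(lab.shape, np.nan)
    fa_map[ribbon] = fa_of(evals[:, 0], evals[:, 1], evals[:, 2])
    md_map[ribbon] = evals.mean(axis=1)
    mt = fit_multi_tensor_batch(
        Y, scheme, max_tensors=max_tensors, merge_angle_deg=merge_angle_deg
    )
    fits = np.full(lab.shape, None, dtype=object)
    fits[ribbon] = mt
    mk = lambda d, name: _named_volume(d, labels, name)  # noqa: E731
    return mk(fa_map, "FA"), mk(md_map, "MD"), fits


def _named_volume(data, like: ImageVolume, name: str) -> ImageVolume:
    vol = ImageVolume(data, like.voxel_size, like.affine)
    vol.name = name
    return vol


def fits_at_vertices(fits: np.ndarray, grid: CorticalGrid, affine: np.ndarray):
    """Nearest-voxel multi-tensor fit for every grid vertex."""
    verts = grid.vertices()
    out = []
    H, W = fits.shape
    for li in range(grid.n_lines):
        row = []
        pix = _world_to_pixels(verts[li], affine)
        for di in range(verts.shape[1]):
            r, c = int(round(pix[di, 0])), int(round(pix[di, 1]))
            r, c = min(max(r, 0), H - 1), min(max(c, 0), W - 1)
            row.append(fits[r, c])
        out.append(row)
    return out


def subject_sheets(
    signal: np.ndarray,
    labels: ImageVolume,
    scheme: AcquisitionScheme,
    grid: CorticalGrid | None = None,
    max_tensors: int = 3,
    merge_angle_deg: float = 20.0,
) -> dict:
    """All metric sheets (FA, MD, FA_par, FA_perp, MD_par, MD_perp)."""
    if grid is None:
        grid = build_grid(solve_laplace(labels))
    fa_map, md_map, fits = fit_slice(
        signal, labels, scheme, max_tensors, merge_angle_deg
    )
    sheets = {
        "FA": sample_metric(fa_map, grid),
        "MD": sample_metric(md_map, grid),
    }
    labeled = label_grid(fits_at_vertices(fits, grid, labels.affine), grid)
    sheets.update(build_sheets(labeled))
    for name, sh in sheets.items():
        sh.metric_name = name
    return sheets


def study_sheets(
    study: StudyData,
    metrics=ALL_METRICS,
    max_tensors: int = 3,
    merge_angle_deg: float = 20.0,
) -> dict:
    """Per-metric GroupStudy objects for a simulated two-group study.

    The phantom geometry (and hence the grid) is shared by all
    subjects, so the Laplace solve and tracing run once.
    """
    labels = study.truth_a.labels
    grid = build_grid(solve_laplace(labels))
    scheme = study.spec.scheme

    def sheets_for(group):
        per_subject = []
        for sig in group:
            sh = subject_sheets(
                sig, labels, scheme, grid, max_tensors, merge_angle_deg
            )
            per_subject.append(sh)
        return per_subject

    sh_a = sheets_for(study.group_a)
    sh_b = sheets_for(study.group_b)
    out = {}
    for m in metrics:
        out[m] = GroupStudy(
            [s[m] for s in sh_a], [s[m] for s in sh_b], metric_name=m
        )
    return out


def fits_to_stack(fits: np.ndarray, max_tensors: int = 3):
    """Serialize an (H, W) fit array to a channel stack + count map.

    Channels per compartment: lambda_par, lambda_perp, axis x/y/z,
    fraction (6 x max_tensors channels); unused compartments are NaN.
    """
    H, W = fits.shape
    stack = np.full((H, W, 6 * max_tensors), np.nan)
    nsel = np.zeros((H, W), dtype=np.int16)
    for r in range(H):
        for c in range(W):
            f = fits[r, c]
            if f is None:
                continue
            nsel[r, c] = f.n_selected
            for k, comp in enumerate(f.compartments):
                o = 6 * k
                stack[r, c, o + 0] = comp.eigenvalues[0]
                stack[r, c, o + 1] = comp.rd
                stack[r, c, o + 2 : o + 5] = comp.principal_axis
                stack[r, c, o + 5] = comp.fraction
    return stack, nsel


def stack_to_fits(stack: np.ndarray, nsel: np.ndarray) -> np.ndarray:
    """Inverse of :func:`fits_to_stack` (s0 and residuals are not kept)."""
    from .tensor_models import MultiTensorFit, TensorCompartment

    H, W = nsel.shape
    fits = np.full((H, W), None, dtype=object)
    for r in range(H):
        for c in range(W):
            n = int(nsel[r, c])
            if n < 1:
                continue
            comps = []
            for k in range(n):
                o = 6 * k
                lp, lq = stack[r, c, o], stack[r, c, o + 1]
                comps.append(
                    TensorCompartment(
                        (lp, lq, lq), stack[r, c, o + 2 : o + 5],
                        float(stack[r, c, o + 5]),
                    )
                )
            total = sum(cm.fraction for cm in comps)
            for cm in comps:
                cm.fraction /= total
            fits[r, c] = MultiTensorFit(comps, 1.0, 0.0)
    return fits


def run_group_analysis(
    group_study: GroupStudy,
    n_perm: int = 5000,
    alpha_form: float = 0.05,
    connectivity: int = 4,
    seed: int = 0,
) -> ClusterResult:
    """Cluster-wise permutation inference for one metric."""
    return cluster_inference(
        group_study,
        alpha_form=alpha_form,
        n_perm=n_perm,
        seed=seed,
        connectivity=connectivity,
    )
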