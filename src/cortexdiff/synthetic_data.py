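"""Synthetic cortical-ribbon phantoms and two-group dMRI studies.

No animal data accompany the study design this package implements, so
every end-to-end exercise runs on phantoms that emulate it: a curved or
straight cortical ribbon at 0.175 mm in-plane resolution, populated
with radial (depth-running) and tangential (surface-running) fiber
populations; a 3-shell (b = 670 / 1,270 / 2,010 s/mm^2), 90-direction
plus 15-b0 acquisition; Rician magnitude noise; and group studies where
the experimental group carries an injected "lesion" — a multiplicative
eigenvalue change of one fiber population within a bounded block of the
cortical grid, mimicking the focal reduction of anisotropy a cortical
malformation produces.

Default population eigenvalues (mm^2/s): radial lambda_par 1.7e-3,
lambda_perp 0.3e-3 (FA ~ 0.80); tangential 1.2e-3 / 0.4e-3 (FA ~ 0.60)
— plausible in-vivo values for coherent intracortical fibers.  Between-
subject biology is emulated by a multiplicative eigenvalue jitter with
5% coefficient of variation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .io_core import AcquisitionScheme, ImageVolume
from .cortical_grid import LABEL_INTERIOR, LABEL_PIAL, LABEL_WM
from ._sphere import fibonacci_directions

__all__ = [
    "FiberPopulation",
    "PhantomSpec",
    "LesionSpec",
    "PhantomTruth",
    "default_scheme",
    "make_phantom",
    "simulate_signal",
    "make_study",
]

PIXEL_SIZE_DEFAULT = 0.175  # mm in-plane
SLICE_THICKNESS = 1.0  # mm
LAMBDA_FLOOR, LAMBDA_CEIL = 1e-5, 4e-3


def default_scheme(
    n_directions: int = 90,
    shells=(670.0, 1270.0, 2010.0),
    n_b0: int = 15,
) -> AcquisitionScheme:
    """The emulated acquisition: 90 directions x 3 shells + 15 b0.

    Directions follow a spherical Fibonacci spiral (deterministic,
    near-uniform); the three shells share the direction set.
    """
    dirs = fibonacci_directions(n_directions)
    bvals = np.concatenate(
        [np.zeros(n_b0), np.repeat(shells, n_directions)]
    )
    bvecs = np.concatenate(
        [np.zeros((n_b0, 3))] + [dirs for _ in shells]
    )
    return AcquisitionScheme(bvals, bvecs)


@dataclass(frozen=True)
class FiberPopulation:
    """One fiber population: orientation field + diffusivities + fraction."""

    axis_field: str  # 'radial' | 'tangential' | 'through_plane'
    lambda_par: float = 1.7e-3
    lambda_perp: float = 0.3e-3
    fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.axis_field not in ("radial", "tangential", "through_plane"):
            raise ValueError(f"unknown axis field {self.axis_field!r}")


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry + fiber content + acquisition of one phantom subject."""

    geometry: str = "slab"  # 'slab' | 'quarter_annulus'
    length_mm: float = 8.75  # slab extent along the pial surface
    thickness_mm: float = 1.75  # cortical depth
    inner_radius_mm: float = 3.5  # quarter_annulus only
    pixel_size: float = PIXEL_SIZE_DEFAULT
    populations: tuple = (
        FiberPopulation("radial", 1.7e-3, 0.3e-3, 0.5),
        FiberPopulation("tangential", 1.2e-3, 0.4e-3, 0.5),
    )
    s0: float = 1.0
    snr_b0: float = 30.0  # Rician SNR at b=0; inf -> noiseless
    scheme: AcquisitionScheme = field(default_factory=default_scheme)

    def __post_init__(self) -> None:
        fsum = sum(p.fraction for p in self.populations)
        if abs(fsum - 1.0) > 1e-9:
            raise ValueError(f"population fractions sum to {fsum:g}")
        if self.geometry not in ("slab", "quarter_annulus"):
            raise ValueError(f"unknown geometry {self.geometry!r}")
        if self.thickness_mm < 3 * self.pixel_size:
            raise ValueError("ribbon thinner than 3 pixels")


@dataclass(frozen=True)
class LesionSpec:
    """A bounded multiplicative eigenvalue change of one population.

    The region is expressed in cortical-grid coordinates (line index
    range x depth index range, half-open) and mapped geometrically onto
    voxels: line fraction along the pial surface, depth fraction across
    the ribbon.
    """

    line_range: tuple = (20, 30)
    depth_range: tuple = (3, 7)
    target: str = "radial"
    lambda_par_factor: float = 0.7
    lambda_perp_factor: float = 1.0
    n_lines: int = 50
    n_depths: int = 10


@dataclass
class PhantomTruth:
    """Ground truth of one phantom: per-voxel axes/eigenvalues/fractions."""

    labels: ImageVolume  # 0 bg, 1 interior, 2 pial, 3 gray/white
    axes: np.ndarray  # (H, W, P, 3) unit axes per population
    lambda_par: np.ndarray  # (H, W, P)
    lambda_perp: np.ndarray  # (H, W, P)
    fractions: np.ndarray  # (H, W, P)
    s0: float
    scheme: AcquisitionScheme
    # geometric coordinates used for lesion placement
    line_frac: np.ndarray  # (H, W) position along the surface, [0, 1]
    depth_frac: np.ndarray  # (H, W) relative cortical depth, [0, 1]

    @property
    def ribbon(self) -> np.ndarray:
        return self.labels.data > 0


def _slab_geometry(spec: PhantomSpec):
    px = spec.pixel_size
    n_depth = int(round(spec.thickness_mm / px))
    n_len = int(round(spec.length_mm / px))
    H, W = n_depth + 2, n_len  # one boundary row each side
    labels = np.zeros((H, W), int)
    labels[0, :] = LABEL_PIAL
    labels[-1, :] = LABEL_WM
    labels[1:-1, :] = LABEL_INTERIOR
    rows = np.arange(H)[:, None] * np.ones((1, W))
    cols = np.ones((H, 1)) * np.arange(W)[None, :]
    depth_frac = rows / (H - 1)
    line_frac = cols / max(W - 1, 1)
    radial = np.zeros((H, W, 3))
    radial[..., 0] = 1.0  # along rows = increasing depth
    tangential = np.zeros((H, W, 3))
    tangential[..., 1] = 1.0  # along columns = along the surface
    return labels, radial, tangential, line_frac, depth_frac


def _annulus_geometry(spec: PhantomSpec):
    px = spec.pixel_size
    r_in = spec.inner_radius_mm / px
    r_out = (spec.inner_radius_mm + spec.thickness_mm) / px
    N = int(np.ceil(r_out)) + 3
    yy, xx = np.meshgrid(np.arange(N), np.arange(N), indexing="ij")
    r = np.hypot(xx, yy)
    ribbon = (r >= r_in - 0.5) & (r <= r_out + 0.5)
    labels = np.zeros((N, N), int)
    labels[ribbon] = LABEL_INTERIOR
    labels[ribbon & (r < r_in + 0.5)] = LABEL_PIAL
    labels[ribbon & (r > r_out - 0.5)] = LABEL_WM
    with np.errstate(invalid="ignore", divide="ignore"):
        ur_row = np.where(r > 0, yy / np.maximum(r, 1e-12), 1.0)
        ur_col = np.where(r > 0, xx / np.maximum(r, 1e-12), 0.0)
    radial = np.zeros((N, N, 3))
    radial[..., 0] = ur_row
    radial[..., 1] = ur_col
    tangential = np.zeros((N, N, 3))
    tangential[..., 0] = -ur_col
    tangential[..., 1] = ur_row
    theta = np.arctan2(yy, xx)  # 0 .. pi/2 on the quarter
    line_frac = theta / (np.pi / 2)
    depth_frac = np.clip((r - r_in) / (r_out - r_in), 0.0, 1.0)
    return labels, radial, tangential, line_frac, depth_frac


def make_phantom(spec: PhantomSpec, seed: int = 0) -> PhantomTruth:
    """Build the labeled ribbon and its per-voxel fiber ground truth.

    Deterministic given (spec, seed); the seed only matters for specs
    that request randomized features (none of the built-in fields are
    random, so identical specs always yield identical truth).
    """
    if spec.geometry == "slab":
        labels, radial, tangential, line_frac, depth_frac = _slab_geometry(spec)
    else:
        labels, radial, tangential, line_frac, depth_frac = _annulus_geometry(spec)
    H, W = labels.shape
    P = len(spec.populations)
    axes = np.zeros((H, W, P, 3))
    lpar = np.zeros((H, W, P))
    lperp = np.zeros((H, W, P))
    frac = np.zeros((H, W, P))
    through = np.zeros((H, W, 3))
    through[..., 2] = 1.0
    fields = dict(radial=radial, tangential=tangential, through_plane=through)
    for k, pop in enumerate(spec.populations):
        axes[:, :, k, :] = fields[pop.axis_field]
        lpar[:, :, k] = pop.lambda_par
        lperp[:, :, k] = pop.lambda_perp
        frac[:, :, k] = pop.fraction
    vol = ImageVolume(
        labels,
        (spec.pixel_size, spec.pixel_size, SLICE_THICKNESS),
    )
    return PhantomTruth(
        vol, axes, lpar, lperp, frac, spec.s0, spec.scheme,
        line_frac, depth_frac,
    )


def apply_lesion(truth: PhantomTruth, spec: PhantomSpec, lesion: LesionSpec) -> PhantomTruth:
    """Return a copy of the truth with the lesion's eigenvalue change."""
    l0 = lesion.line_range[0] / lesion.n_lines
    l1 = lesion.line_range[1] / lesion.n_lines
    d0 = lesion.depth_range[0] / lesion.n_depths
    d1 = lesion.depth_range[1] / lesion.n_depths
    region = (
        (truth.line_frac >= l0) & (truth.line_frac < l1)
        & (truth.depth_frac >= d0) & (truth.depth_frac < d1)
        & truth.ribbon
    )
    if not region.any():
        raise ValueError("lesion region maps to no ribbon voxels")
    pop_idx = [
        k for k, p in enumerate(spec.populations) if p.axis_field == lesion.target
    ]
    if not pop_idx:
        raise ValueError(f"no {lesion.target!r} population in the phantom")
    lpar = truth.lambda_par.copy()
    lperp = truth.lambda_perp.copy()
    for k in pop_idx:
        lpar[region, k] = np.clip(
            lpar[region, k] * lesion.lambda_par_factor, LAMBDA_FLOOR, LAMBDA_CEIL
        )
        lperp[region, k] = np.clip(
            lperp[region, k] * lesion.lambda_perp_factor, LAMBDA_FLOOR, LAMBDA_CEIL
        )
    out = PhantomTruth(
        truth.labels, truth.axes, lpar, lperp, truth.fractions,
        truth.s0, truth.scheme, truth.line_frac, truth.depth_frac,
    )
    return out


def noiseless_signal(truth: PhantomTruth) -> np.ndarray:
    """(H, W, M) mixture signal S0 * sum_i f_i exp(-b g^T D_i g)."""
    scheme = truth.scheme
    b, g = scheme.bvals, scheme.bvecs
    H, W, P, _ = truth.axes.shape
    ribbon = truth.ribbon
    S = np.zeros((H, W, len(b)))
    ax = truth.axes[ribbon]  # (V, P, 3)
    lp = truth.lambda_par[ribbon]
    lq = truth.lambda_perp[ribbon]
    fr = truth.fractions[ribbon]
    c = np.einsum("vpk,mk->vpm", ax, g)  # (V, P, M)
    att = np.exp(
        -b[None, None, :] * (lq[:, :, None] + (lp - lq)[:, :, None] * c**2)
    )
    S[ribbon] = truth.s0 * np.sum(fr[:, :, None] * att, axis=1)
    return S


def add_rician_noise(
    S: np.ndarray, s0: float, snr_b0: float, rng: np.random.Generator
) -> np.ndarray:
    """Magnitude (Rician) noise: sqrt((S + e1)^2 + e2^2), e ~ N(0, s0/SNR)."""
    if not np.isfinite(snr_b0):
        return S.copy()
    sigma = s0 / snr_b0
    e1 = rng.normal(0.0, sigma, S.shape)
    e2 = rng.normal(0.0, sigma, S.shape)
    return np.sqrt((S + e1) ** 2 + e2**2)


def simulate_signal(
    truth: PhantomTruth,
    snr_b0: float | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Simulate the 4D series (H, W, M) for one subject."""
    scheme = truth.scheme
    weighted = ~scheme.is_b0
    norms = np.linalg.norm(scheme.bvecs[weighted], axis=1)
    if np.any(np.abs(norms - 1.0) > 1e-6):
        raise ValueError("non-unit gradient on a weighted volume")
    S = noiseless_signal(truth)
    if snr_b0 is None:
        snr_b0 = np.inf
    rng = np.random.default_rng(seed)
    noisy = add_rician_noise(S, truth.s0, snr_b0, rng)
    noisy[~truth.ribbon] = 0.0
    return noisy


def _jitter_truth(
    truth: PhantomTruth, cv: float, rng: np.random.Generator
) -> PhantomTruth:
    """Subject-level eigenvalue jitter: one multiplicative factor per
    population per subject (between-subject biological variance)."""
    if cv <= 0:
        return truth
    P = truth.lambda_par.shape[-1]
    fac_par = rng.normal(1.0, cv, P)
    fac_perp = rng.normal(1.0, cv, P)
    lpar = np.clip(truth.lambda_par * fac_par, LAMBDA_FLOOR, LAMBDA_CEIL)
    lperp = np.clip(truth.lambda_perp * fac_perp, LAMBDA_FLOOR, LAMBDA_CEIL)
    lperp = np.minimum(lperp, lpar)  # keep populations prolate
    return PhantomTruth(
        truth.labels, truth.axes, lpar, lperp, truth.fractions,
        truth.s0, truth.scheme, truth.line_frac, truth.depth_frac,
    )


def make_null_sheet_study(
    n_a: int = 19,
    n_b: int = 18,
    shape: tuple = (50, 10),
    seed: int = 0,
):
    """Two groups of iid standard-normal metric sheets (exchangeable null).

    Bypasses the imaging chain: the sheets themselves are the simulated
    quantity.  Used for calibration of the permutation machinery, where
    hundreds of replicate studies are needed.
    """
    rng = np.random.default_rng(seed)
    a = rng.normal(size=(n_a,) + tuple(shape))
    b = rng.normal(size=(n_b,) + tuple(shape))
    return a, b


@dataclass
class StudyData:
    """Simulated two-group study: per-subject 4D series plus truths."""

    group_a: list  # control subjects, (H, W, M) arrays
    group_b: list  # experimental subjects
    truth_a: PhantomTruth
    truth_b: PhantomTruth
    spec: PhantomSpec
    lesion: LesionSpec | None


def make_study(
    spec: PhantomSpec,
    lesion: LesionSpec | None = None,
    n_a: int = 19,
    n_b: int = 18,
    subject_cv: float = 0.05,
    seed: int = 0,
) -> StudyData:
    """Simulate a control group and a lesioned experimental group.

    Group sizes default to the emulated study design (19 control vs 18
    experimental).  Each subject gets independent eigenvalue jitter and
    independent Rician noise; the study is fully reproducible from
    (spec, lesion, seed).
    """
    base = make_phantom(spec, seed=seed)
    lesioned = apply_lesion(base, spec, lesion) if lesion is not None else base
    rng = np.random.default_rng(seed)
    group_a, group_b = [], []
    for _ in range(n_a):
        subj = _jitter_truth(base, subject_cv, rng)
        group_a.append(
            add_rician_noise(
                noiseless_signal(subj), spec.s0, spec.snr_b0, rng
            )
            * subj.ribbon[:, :, None]
        )
    for _ in range(n_b):
        subj = _jitter_truth(lesioned, subject_cv, rng)
        group_b.append(
            add_rician_noise(
                noiseless_signal(subj), spec.s0, spec.snr_b0, rng
            )
            * subj.ribbon[:, :, None]
        )
    return StudyData(group_a, group_b, base, lesioned, spec, lesion)
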