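"""Single- and multi-tensor representations of the diffusion signal.

The diffusion-weighted signal in gray matter is modeled as a mixture of
non-exchanging Gaussian compartments,

    S(b, g) = S0 * sum_i f_i * exp(-b * g^T D_i g),

one tensor per fiber population, each with its own eigenvalues, signal
fraction and orientation.  A single-tensor (DTI) fit is kept as the
baseline.  Multi-tensor compartments are axially symmetric (lambda_2 =
lambda_3 = lambda_perp): at three shells and 90 directions, full 6-dof
tensors per compartment are not identifiable for three crossings.

Fitting strategy per voxel:

1. weighted linear least squares DTI fit on the log-signal;
2. per candidate count N = 1..3, a discrete search over subdivided
   icosahedral axis grids (coarse 321, fine 1,281 axes per hemisphere)
   picks seed orientations, with fractions from a linear solve against
   the axis dictionary;
3. batched Levenberg-Marquardt refinement of all parameters on signal
   amplitudes (Gaussian-noise least squares);
4. compartments whose principal axes lie closer than the merge angle
   (default 20 degrees) are merged and the fit re-optimized;
5. the number of tensors kept is decided by a nested F-test between
   successive candidate counts at alpha = 0.05.

All voxels of a slice are fit simultaneously: residuals, Jacobians and
normal equations are evaluated as stacked arrays, which is what makes
whole-phantom studies tractable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io_core import AcquisitionScheme
from ._sphere import icosphere_hemisphere

__all__ = [
    "TensorCompartment",
    "MultiTensorFit",
    "FitError",
    "ConditioningError",
    "fa",
    "md",
    "fit_dti",
    "fit_dti_batch",
    "fit_multi_tensor",
    "fit_multi_tensor_batch",
]

# eigenvalue search bounds, mm^2/s
LAMBDA_MIN = 1e-5
LAMBDA_MAX = 4e-3
# compartments below this signal fraction are discarded as spurious
MIN_FRACTION = 0.01
# angular slack (degrees) so a separation numerically *at* the merge
# angle counts as two distinct populations, not one
_MERGE_EPS_DEG = 1e-3


class FitError(ValueError):
    """Signal cannot be fit (non-positive, degenerate, ...)."""


class ConditioningError(FitError):
    """The acquisition scheme under-determines the model."""


# ---------------------------------------------------------------------------
# scalar metrics


def fa(l1, l2, l3):
    """Fractional anisotropy of eigenvalues (vectorized).

    FA = sqrt(3/2) * ||lambda - MD|| / ||lambda||, defined as 0 when all
    eigenvalues vanish.  Negative eigenvalues are a domain error.
    """
    l1, l2, l3 = np.broadcast_arrays(*(np.asarray(x, float) for x in (l1, l2, l3)))
    if np.any(l1 < 0) or np.any(l2 < 0) or np.any(l3 < 0):
        raise ValueError("eigenvalues must be non-negative")
    m = (l1 + l2 + l3) / 3.0
    num = (l1 - m) ** 2 + (l2 - m) ** 2 + (l3 - m) ** 2
    den = l1**2 + l2**2 + l3**2
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.sqrt(1.5) * np.sqrt(num / np.where(den > 0, den, 1.0))
    out = np.where(den > 0, out, 0.0)
    return float(out) if out.ndim == 0 else out


def md(l1, l2, l3):
    """Mean diffusivity (lambda_1 + lambda_2 + lambda_3) / 3."""
    l1, l2, l3 = (np.asarray(x, float) for x in (l1, l2, l3))
    if np.any(l1 < 0) or np.any(l2 < 0) or np.any(l3 < 0):
        raise ValueError("eigenvalues must be non-negative")
    out = (l1 + l2 + l3) / 3.0
    return float(out) if np.ndim(out) == 0 else out


# ---------------------------------------------------------------------------
# domain types


@dataclass
class TensorCompartment:
    """One Gaussian diffusion compartment.

    eigenvalues are sorted descending (mm^2/s); ``principal_axis`` is the
    unit eigenvector of the largest eigenvalue; ``fraction`` is the
    compartment's share of the b=0 signal.
    """

    eigenvalues: np.ndarray
    principal_axis: np.ndarray
    fraction: float = 1.0

    def __post_init__(self) -> None:
        ev = np.sort(np.asarray(self.eigenvalues, float))[::-1]
        if ev[-1] < -1e-12:
            raise ValueError(f"negative eigenvalue {ev[-1]:g}")
        self.eigenvalues = np.clip(ev, 0.0, None)
        ax = np.asarray(self.principal_axis, float)
        n = np.linalg.norm(ax)
        if not np.isfinite(n) or n < 1e-12:
            raise ValueError("principal axis must be a nonzero vector")
        self.principal_axis = ax / n
        if not 0.0 <= self.fraction <= 1.0 + 1e-9:
            raise ValueError(f"fraction {self.fraction:g} outside [0, 1]")
        self.fraction = float(min(self.fraction, 1.0))

    @property
    def ad(self) -> float:
        return float(self.eigenvalues[0])

    @property
    def rd(self) -> float:
        return float((self.eigenvalues[1] + self.eigenvalues[2]) / 2.0)

    @property
    def fa(self) -> float:
        return float(fa(*self.eigenvalues))

    @property
    def md(self) -> float:
        return float(md(*self.eigenvalues))


@dataclass
class MultiTensorFit:
    """Multi-tensor representation of one voxel."""

    compartments: list
    s0: float
    residual_sse: float
    converged: bool = True
    n_selected: int = field(init=False)

    def __post_init__(self) -> None:
        if not 1 <= len(self.compartments) <= 3:
            raise ValueError("1-3 compartments required")
        self.n_selected = len(self.compartments)
        fsum = sum(c.fraction for c in self.compartments)
        if abs(fsum - 1.0) > 1e-6:
            raise ValueError(f"fractions sum to {fsum:g}, not 1")


# ---------------------------------------------------------------------------
# DTI (weighted linear least squares on the log signal)


def _dti_design(scheme: AcquisitionScheme) -> np.ndarray:
    b = scheme.bvals
    g = scheme.bvecs
    return np.column_stack(
        [
            np.ones_like(b),
            -b * g[:, 0] ** 2,
            -b * g[:, 1] ** 2,
            -b * g[:, 2] ** 2,
            -2 * b * g[:, 0] * g[:, 1],
            -2 * b * g[:, 0] * g[:, 2],
            -2 * b * g[:, 1] * g[:, 2],
        ]
    )


def _tensor_from_coeffs(coef: np.ndarray) -> np.ndarray:
    dxx, dyy, dzz, dxy, dxz, dyz = coef
    return np.array([[dxx, dxy, dxz], [dxy, dyy, dyz], [dxz, dyz, dzz]])


def fit_dti_batch(signals: np.ndarray, scheme: AcquisitionScheme):
    """Weighted linear least squares DTI fit for a stack of voxels.

    Parameters
    ----------
    signals : (V, M) array of positive amplitudes.

    Returns
    -------
    evals : (V, 3) descending eigenvalues (clamped at 0)
    evecs : (V, 3, 3) eigenvectors as columns, matching ``evals``
    s0 : (V,) fitted b=0 amplitude
    """
    Y = np.atleast_2d(np.asarray(signals, float))
    if Y.shape[1] != scheme.n_volumes:
        raise FitError(
            f"signal has {Y.shape[1]} volumes, scheme has {scheme.n_volumes}"
        )
    if scheme.n_volumes < 7 or scheme.n_b0 < 1:
        raise FitError("DTI needs >= 7 volumes including a b=0")
    if np.any(~np.isfinite(Y)) or np.any(Y <= 0):
        raise FitError("signal must be positive and finite")
    X = _dti_design(scheme)
    if np.linalg.matrix_rank(X) < 7:
        raise ConditioningError("gradient directions do not span the tensor space")
    logY = np.log(Y)
    beta = np.linalg.lstsq(X, logY.T, rcond=None)[0].T  # (V, 7)
    # one reweighting pass: weights = predicted signal squared
    W = np.exp(X @ beta.T).T ** 2  # (V, M)
    XtWX = np.einsum("vm,mp,mq->vpq", W, X, X)
    XtWy = np.einsum("vm,mp,vm->vp", W, X, logY)
    beta = np.linalg.solve(XtWX, XtWy[:, :, None])[:, :, 0]
    s0 = np.exp(beta[:, 0])
    D = np.empty((Y.shape[0], 3, 3))
    D[:, 0, 0], D[:, 1, 1], D[:, 2, 2] = beta[:, 1], beta[:, 2], beta[:, 3]
    D[:, 0, 1] = D[:, 1, 0] = beta[:, 4]
    D[:, 0, 2] = D[:, 2, 0] = beta[:, 5]
    D[:, 1, 2] = D[:, 2, 1] = beta[:, 6]
    w, v = np.linalg.eigh(D)  # ascending
    evals = np.clip(w[:, ::-1], 0.0, None)
    evecs = v[:, :, ::-1]
    return evals, evecs, s0


def fit_dti(signal: np.ndarray, scheme: AcquisitionScheme):
    """DTI fit of one voxel; returns (TensorCompartment, s0)."""
    evals, evecs, s0 = fit_dti_batch(np.atleast_2d(signal), scheme)
    comp = TensorCompartment(evals[0], evecs[0][:, 0], 1.0)
    return comp, float(s0[0])


# ---------------------------------------------------------------------------
# multi-tensor machinery


def _axes_from_angles(theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
    st, ct = np.sin(theta), np.cos(theta)
    return np.stack([st * np.cos(phi), st * np.sin(phi), ct], axis=-1)


def _model_and_jac(x, b, g, n_comp, want_jac=True):
    """Signal model and Jacobian, batched over voxels.

    x : (V, 5N) packed as [theta, phi, lpar, lperp, w] per compartment.
    Returns S (V, M) and J (V, M, 5N) or None.
    """
    V = x.shape[0]
    M = b.shape[0]
    S = np.zeros((V, M))
    J = np.zeros((V, M, 5 * n_comp)) if want_jac else None
    for i in range(n_comp):
        th, ph, lpar, lperp, w = (x[:, 5 * i + k][:, None] for k in range(5))
        st, ct = np.sin(th), np.cos(th)
        sp, cp = np.sin(ph), np.cos(ph)
        u = np.concatenate([st * cp, st * sp, ct], axis=1)  # (V, 3)
        c = u @ g.T  # (V, M)
        dl = lpar - lperp
        E = np.exp(-b[None, :] * (lperp + dl * c**2))
        wE = w * E
        S += wE
        if not want_jac:
            continue
        # axis derivatives through c = g . u(theta, phi)
        du_dth = np.concatenate([ct * cp, ct * sp, -st], axis=1)
        du_dph = np.concatenate([-st * sp, st * cp, np.zeros_like(st)], axis=1)
        dc_dth = du_dth @ g.T
        dc_dph = du_dph @ g.T
        base = -b[None, :] * wE
        J[:, :, 5 * i + 0] = base * dl * 2 * c * dc_dth
        J[:, :, 5 * i + 1] = base * dl * 2 * c * dc_dph
        J[:, :, 5 * i + 2] = base * c**2
        J[:, :, 5 * i + 3] = base * (1 - c**2)
        J[:, :, 5 * i + 4] = E
    return S, J


def _clip_params(x: np.ndarray, n_comp: int, w_max: np.ndarray) -> np.ndarray:
    for i in range(n_comp):
        x[:, 5 * i + 2] = np.clip(x[:, 5 * i + 2], LAMBDA_MIN, LAMBDA_MAX)
        x[:, 5 * i + 3] = np.clip(x[:, 5 * i + 3], LAMBDA_MIN, LAMBDA_MAX)
        x[:, 5 * i + 4] = np.clip(x[:, 5 * i + 4], 0.0, w_max)
    return x


def _lm_refine(Y, b, g, x0, n_comp, max_iter=60, ftol=1e-12):
    """Batched projected Levenberg-Marquardt on signal amplitudes."""
    x = x0.copy()
    V = x.shape[0]
    w_max = 2.0 * Y.max(axis=1)
    S, _ = _model_and_jac(x, b, g, n_comp, want_jac=False)
    cost = np.sum((S - Y) ** 2, axis=1)
    mu = np.full(V, 1e-3)
    active = np.ones(V, dtype=bool)
    n_iter = np.zeros(V, dtype=int)
    P = 5 * n_comp
    eye = np.eye(P)
    for _ in range(max_iter):
        if not active.any():
            break
        idx = np.flatnonzero(active)
        xa = x[idx]
        Sa, Ja = _model_and_jac(xa, b, g, n_comp)
        r = Sa - Y[idx]
        Jt = Ja.transpose(0, 2, 1)
        JtJ = Jt @ Ja
        gvec = (Jt @ r[:, :, None])[:, :, 0]
        diag = np.einsum("vpp->vp", JtJ)
        A = JtJ + mu[idx, None, None] * (
            diag[:, :, None] * eye[None] + 1e-12 * eye[None]
        )
        try:
            delta = np.linalg.solve(A, -gvec[:, :, None])[:, :, 0]
        except np.linalg.LinAlgError:
            A += 1e-8 * eye[None]
            delta = np.linalg.solve(A, -gvec[:, :, None])[:, :, 0]
        x_try = _clip_params(xa + delta, n_comp, w_max[idx])
        S_try, _ = _model_and_jac(x_try, b, g, n_comp, want_jac=False)
        cost_try = np.sum((S_try - Y[idx]) ** 2, axis=1)
        better = cost_try < cost[idx]
        rel_drop = (cost[idx] - cost_try) / np.maximum(cost[idx], 1e-300)
        x[idx[better]] = x_try[better]
        cost[idx[better]] = cost_try[better]
        mu[idx[better]] = np.maximum(mu[idx[better]] / 3.0, 1e-12)
        mu[idx[~better]] = np.minimum(mu[idx[~better]] * 4.0, 1e8)
        # converged: accepted step barely moved the cost
        done = better & (rel_drop < ftol)
        stuck = ~better & (mu[idx] >= 1e8)
        active[idx[done | stuck]] = False
        n_iter[idx] += 1
    converged = ~active | (n_iter < max_iter)
    return x, cost, converged


def _pair_angle_deg(u: np.ndarray, v: np.ndarray) -> float:
    d = abs(float(np.dot(u, v)))
    return float(np.degrees(np.arccos(min(d, 1.0))))


class _Dictionaries:
    """Shared discrete-search state for one (scheme, lambda-seed) pair."""

    def __init__(self, scheme, lpar, lperp, n_fine_neighbors=8):
        self.coarse = icosphere_hemisphere(3)  # 321 axes
        self.fine = icosphere_hemisphere(4)  # 1281 axes
        b, g = scheme.bvals, scheme.bvecs
        dl = lpar - lperp

        def basis(axes):
            c = g @ axes.T  # (M, K)
            return np.exp(-b[:, None] * (lperp + dl * c**2))

        self.A_c = basis(self.coarse)
        self.A_f = basis(self.fine)
        self.G_c = self.A_c.T @ self.A_c
        self.G_f = self.A_f.T @ self.A_f
        # coarse axis -> nearest fine axes (for local refinement)
        dots = np.abs(self.coarse @ self.fine.T)
        order = np.argsort(-dots, axis=1)
        self.fine_neighbors = order[:, :n_fine_neighbors]
        self.coarse_to_fine = order[:, 0]
        self._fine_nb_of_fine = None


_DICT_CACHE: dict = {}


def _get_dictionaries(scheme, lpar, lperp) -> "_Dictionaries":
    # quantize the seed diffusivities so repeated batches reuse the basis
    key = (id(scheme), round(lpar * 1e4), round(lperp * 1e4))
    if key not in _DICT_CACHE:
        if len(_DICT_CACHE) > 16:
            _DICT_CACHE.clear()
        _DICT_CACHE[key] = _Dictionaries(
            scheme, round(lpar * 1e4) / 1e4, round(lperp * 1e4) / 1e4
        )
    return _DICT_CACHE[key]


def _coarse_pair_search(B, yty, G, top_k=48):
    """Best axis pair per voxel by closed-form 2x2 least squares.

    B : (V, K) projections of signals on the dictionary; G : (K, K) Gram.
    To keep the search linear in voxels, pairs are drawn from the
    ``top_k`` axes with the largest single-axis projection per voxel —
    both lobes of a crossing project strongly, so their neighborhoods
    survive the cut.  Returns (i, j) index arrays of shape (V,).
    """
    V, K = B.shape
    top_k = min(top_k, K)
    cand = np.argpartition(-B, top_k - 1, axis=1)[:, :top_k]  # (V, top_k)
    iu, ju = np.triu_indices(top_k, k=1)
    ci, cj = cand[:, iu], cand[:, ju]  # (V, P) per-voxel axis indices
    gii, gjj, gij = G[ci, ci], G[cj, cj], G[ci, cj]
    det = gii * gjj - gij**2
    det = np.where(np.abs(det) < 1e-30, 1e-30, det)
    Bi = np.take_along_axis(B, ci, axis=1)
    Bj = np.take_along_axis(B, cj, axis=1)
    w1 = (gjj * Bi - gij * Bj) / det
    w2 = (gii * Bj - gij * Bi) / det
    sse = yty[:, None] - (w1 * Bi + w2 * Bj)
    # discourage sign-flipped (negative-weight) solutions when seeding
    sse = np.where((w1 < 0) | (w2 < 0), np.inf, sse)
    k = np.argmin(sse, axis=1)
    rows = np.arange(V)
    return ci[rows, k], cj[rows, k]


def _solve_weights(G, B, idx):
    """Least-squares weights for the axes in ``idx`` per voxel.

    idx : (V, n) fine-dictionary indices.  Returns (V, n) weights and
    (V,) explained sum of squares.
    """
    V, n = idx.shape
    Gs = G[idx[:, :, None], idx[:, None, :]] + 1e-12 * np.eye(n)[None]
    Bs = np.take_along_axis(B, idx, axis=1)
    w = np.linalg.solve(Gs, Bs[:, :, None])[:, :, 0]
    return w, np.sum(w * Bs, axis=1)


def _refine_axes_fine(idx, B_f, G_f, neighbors):
    """One coordinate-descent pass of local fine-grid axis refinement."""
    V, n = idx.shape
    idx = idx.copy()
    for slot in range(n):
        cand_sets = neighbors[idx[:, slot]]  # needs coarse->fine mapping upstream
        best_expl = np.full(V, -np.inf)
        best_idx = idx[:, slot].copy()
        for c in range(cand_sets.shape[1]):
            trial = idx.copy()
            trial[:, slot] = cand_sets[:, c]
            # skip degenerate duplicates
            dup = np.zeros(V, dtype=bool)
            for other in range(n):
                if other != slot:
                    dup |= trial[:, other] == trial[:, slot]
            _, expl = _solve_weights(G_f, B_f, trial)
            expl = np.where(dup, -np.inf, expl)
            upd = expl > best_expl
            best_expl[upd] = expl[upd]
            best_idx[upd] = trial[upd, slot]
        idx[:, slot] = best_idx
    return idx


def _pack_seeds(axes, lpar, lperp, w):
    """axes (V, n, 3), lpar/lperp/w (V, n) -> packed (V, 5n)."""
    V, n, _ = axes.shape
    x = np.empty((V, 5 * n))
    uz = np.clip(axes[:, :, 2], -1.0, 1.0)
    x[:, 0::5] = np.arccos(uz)
    x[:, 1::5] = np.arctan2(axes[:, :, 1], axes[:, :, 0])
    x[:, 2::5] = np.clip(lpar, LAMBDA_MIN, LAMBDA_MAX)
    x[:, 3::5] = np.clip(lperp, LAMBDA_MIN, LAMBDA_MAX)
    x[:, 4::5] = np.clip(w, 0.0, None)
    return x


def _unpack(x, n_comp):
    """Packed params -> (axes (V,n,3), lpar, lperp, w)."""
    th, ph = x[:, 0::5], x[:, 1::5]
    st = np.sin(th)
    axes = np.stack(
        [st * np.cos(ph), st * np.sin(ph), np.cos(th)], axis=-1
    )
    return axes, x[:, 2::5], x[:, 3::5], x[:, 4::5]


def _reduce_voxel(axes, lpar, lperp, w, merge_angle_deg):
    """Merge near-parallel compartments / drop negligible ones (one voxel).

    Returns (axes, lpar, lperp, w, changed).  Merging is greedy from the
    closest pair; the merged axis is the fraction-weighted mean axis.
    """
    changed = False
    comps = [
        dict(u=axes[i], lpar=lpar[i], lperp=lperp[i], w=w[i])
        for i in range(len(w))
    ]
    # drop spurious compartments first
    wsum = sum(c["w"] for c in comps)
    if wsum <= 0:
        keep = [max(comps, key=lambda c: c["w"])]
        return _comps_to_arrays(keep) + (True,)
    kept = [c for c in comps if c["w"] / wsum >= MIN_FRACTION]
    if not kept:
        kept = [max(comps, key=lambda c: c["w"])]
    if len(kept) != len(comps):
        changed = True
    comps = kept
    while len(comps) > 1:
        angles = [
            (_pair_angle_deg(comps[i]["u"], comps[j]["u"]), i, j)
            for i in range(len(comps))
            for j in range(i + 1, len(comps))
        ]
        ang, i, j = min(angles)
        if ang >= merge_angle_deg - _MERGE_EPS_DEG:
            break
        a, bq = comps[i], comps[j]
        sgn = 1.0 if np.dot(a["u"], bq["u"]) >= 0 else -1.0
        u = a["w"] * a["u"] + sgn * bq["w"] * bq["u"]
        nrm = np.linalg.norm(u)
        u = u / nrm if nrm > 1e-12 else a["u"]
        wtot = a["w"] + bq["w"]
        merged = dict(
            u=u,
            lpar=(a["w"] * a["lpar"] + bq["w"] * bq["lpar"]) / wtot,
            lperp=(a["w"] * a["lperp"] + bq["w"] * bq["lperp"]) / wtot,
            w=wtot,
        )
        comps = [c for k, c in enumerate(comps) if k not in (i, j)] + [merged]
        changed = True
    return _comps_to_arrays(comps) + (changed,)


def _comps_to_arrays(comps):
    axes = np.array([c["u"] for c in comps])
    return (
        axes,
        np.array([c["lpar"] for c in comps]),
        np.array([c["lperp"] for c in comps]),
        np.array([c["w"] for c in comps]),
    )


def _fit_candidate(Y, b, g, seeds_by_n, merge_angle_deg, max_iter=60):
    """LM-refine seeds (grouped by compartment count), then merge+refit.

    seeds_by_n is (n, x0, vox_idx) where x0 is one packed seed array or
    a list of alternative seed arrays (the best LM outcome per voxel is
    kept); all voxels here share the same count n.  Returns per-voxel
    dicts with axes, lambdas, weights, sse, converged.
    """
    n, x0, vox_idx = seeds_by_n
    seed_sets = x0 if isinstance(x0, (list, tuple)) else [x0]
    x, sse, conv = _lm_refine(Y[vox_idx], b, g, seed_sets[0], n, max_iter=max_iter)
    for alt in seed_sets[1:]:
        x2, sse2, conv2 = _lm_refine(Y[vox_idx], b, g, alt, n, max_iter=max_iter)
        better = sse2 < sse
        x[better], sse[better], conv[better] = x2[better], sse2[better], conv2[better]
    axes, lpar, lperp, w = _unpack(x, n)
    out = {}
    refit: dict[int, list] = {}
    for k, v in enumerate(vox_idx):
        a2, p2, q2, w2, changed = _reduce_voxel(
            axes[k], lpar[k], lperp[k], w[k], merge_angle_deg
        )
        if changed and len(w2) >= 1:
            refit.setdefault(len(w2), []).append((v, a2, p2, q2, w2))
        else:
            out[v] = dict(
                axes=axes[k], lpar=lpar[k], lperp=lperp[k], w=w[k],
                sse=sse[k], converged=bool(conv[k]),
            )
    for n2, items in refit.items():
        vi = np.array([it[0] for it in items])
        x0r = _pack_seeds(
            np.stack([it[1] for it in items]),
            np.stack([it[2] for it in items]),
            np.stack([it[3] for it in items]),
            np.stack([it[4] for it in items]),
        )
        xr, sser, convr = _lm_refine(Y[vi], b, g, x0r, n2, max_iter=max_iter)
        axr, lpr, lqr, wr = _unpack(xr, n2)
        for k, v in enumerate(vi):
            # a refit may itself need reduction; one more pass, no refit
            a3, p3, q3, w3, _ = _reduce_voxel(
                axr[k], lpr[k], lqr[k], wr[k], merge_angle_deg
            )
            if len(w3) != n2:
                S3, _ = _model_and_jac(
                    _pack_seeds(a3[None], p3[None], q3[None], w3[None]),
                    b, g, len(w3), want_jac=False,
                )
                sse3 = float(np.sum((S3[0] - Y[v]) ** 2))
                out[v] = dict(axes=a3, lpar=p3, lperp=q3, w=w3,
                              sse=sse3, converged=bool(convr[k]))
            else:
                out[v] = dict(axes=axr[k], lpar=lpr[k], lperp=lqr[k], w=wr[k],
                              sse=sser[k], converged=bool(convr[k]))
    return out


def _select_n(cands, n_volumes, yty, alpha=0.05, perfect_tol=1e-16):
    """Nested F-test over candidate compartment counts (one voxel).

    cands: dict N -> candidate fit dict.  Accept N+1 over N when the
    SSE drop is F-significant at ``alpha``; stop as soon as a richer
    candidate is rejected or adds no effective compartments.
    """
    order = sorted(cands)
    chosen = order[0]
    for N, N1 in zip(order, order[1:]):
        a, bnd = cands[N], cands[N1]
        eff_a, eff_b = len(a["w"]), len(bnd["w"])
        if eff_b <= eff_a:
            break
        if a["sse"] <= perfect_tol * yty:  # already explains the data
            break
        d_sse = a["sse"] - bnd["sse"]
        df1 = 5 * (eff_b - eff_a)
        df2 = n_volumes - 5 * eff_b
        if df2 <= 0 or d_sse <= 0:
            break
        with np.errstate(divide="ignore", invalid="ignore"):
            if bnd["sse"] <= 0:
                p = 0.0
            else:
                F = (d_sse / df1) / (bnd["sse"] / df2)
                p = float(stats.f.sf(F, df1, df2))
        if p < alpha:
            chosen = N1
        else:
            break
    return chosen


def _to_fit(cand, converged_ok=True) -> MultiTensorFit:
    w = np.clip(cand["w"], 0.0, None)
    s0 = float(w.sum())
    if s0 <= 0:
        raise FitError("all compartment weights collapsed to zero")
    fr = w / s0
    comps = []
    for i in range(len(w)):
        lp, lq = float(cand["lpar"][i]), float(cand["lperp"][i])
        if lp >= lq:
            ev = (lp, lq, lq)
            axis = cand["axes"][i]
        else:  # oblate solution: principal axis is any vector in the plane
            ev = (lq, lq, lp)
            u = cand["axes"][i]
            ref = np.array([1.0, 0.0, 0.0])
            if abs(np.dot(ref, u)) > 0.9:
                ref = np.array([0.0, 1.0, 0.0])
            axis = np.cross(u, ref)
        comps.append(TensorCompartment(ev, axis, float(fr[i])))
    return MultiTensorFit(
        comps, s0, float(cand["sse"]), converged=bool(cand["converged"])
    )


def fit_multi_tensor_batch(
    signals: np.ndarray,
    scheme: AcquisitionScheme,
    max_tensors: int = 3,
    merge_angle_deg: float = 20.0,
    alpha: float = 0.05,
    max_iter: int = 60,
):
    """Fit the multi-tensor model to a stack of voxels at once.

    Returns a list of :class:`MultiTensorFit`, one per row of
    ``signals``.  See the module docstring for the algorithm.
    """
    Y = np.atleast_2d(np.asarray(signals, float))
    V, M = Y.shape
    if len(scheme.shells) < 2:
        raise ConditioningError("multi-tensor fitting needs >= 2 nonzero shells")
    if M - 5 * 1 <= 0 or M < 7:
        raise ConditioningError("too few volumes for even one compartment")
    b, g = scheme.bvals, scheme.bvecs

    evals, evecs, s0 = fit_dti_batch(Y, scheme)
    ad = np.clip(evals[:, 0], LAMBDA_MIN, LAMBDA_MAX)
    rd = np.clip((evals[:, 1] + evals[:, 2]) / 2.0, LAMBDA_MIN, LAMBDA_MAX)
    e1 = evecs[:, :, 0]

    lpar_seed = float(np.median(ad))
    lperp_seed = float(np.median(rd))
    if lpar_seed - lperp_seed < 1e-5:
        lpar_seed, lperp_seed = 1.7e-3, 0.3e-3  # isotropic batch: generic seed
    dicts = _get_dictionaries(scheme, lpar_seed, lperp_seed)
    B_f = Y @ dicts.A_f
    B_c = Y @ dicts.A_c
    yty = np.sum(Y**2, axis=1)

    candidates: dict[int, dict] = {}

    # --- N = 1: DTI-seeded
    x1 = _pack_seeds(e1[:, None, :], ad[:, None], rd[:, None], s0[:, None])
    candidates[1] = _fit_candidate(
        Y, b, g, (1, x1, np.arange(V)), merge_angle_deg, max_iter
    )

    if max_tensors >= 2:
        i_c, j_c = _coarse_pair_search(B_c, yty, dicts.G_c)
        idx2 = np.stack(
            [dicts.coarse_to_fine[i_c], dicts.coarse_to_fine[j_c]], axis=1
        )
        # local fine refinement with per-fine-axis neighbor sets
        fine_nb_of_fine = _fine_neighbor_table(dicts)
        idx2 = _refine_axes_fine(idx2, B_f, dicts.G_f, fine_nb_of_fine)
        w2, _ = _solve_weights(dicts.G_f, B_f, idx2)
        w2 = np.clip(w2, 0.05 * s0[:, None], None)
        axes2 = dicts.fine[idx2]
        x2 = _pack_seeds(
            axes2,
            np.repeat(ad[:, None], 2, axis=1),
            np.repeat(rd[:, None], 2, axis=1),
            w2,
        )
        # alternative geometric seed: split the DTI principal axis by
        # +/-12 deg in the e1/e2 plane — recovers shallow crossings that
        # the dictionary pair search can miss
        e2 = evecs[:, :, 1]
        split = np.deg2rad(12.0)
        u_plus = np.cos(split) * e1 + np.sin(split) * e2
        u_minus = np.cos(split) * e1 - np.sin(split) * e2
        axes_split = np.stack([u_plus, u_minus], axis=1)
        axes_split /= np.linalg.norm(axes_split, axis=2, keepdims=True)
        x2b = _pack_seeds(
            axes_split,
            np.repeat(ad[:, None] * 1.15, 2, axis=1),
            np.repeat(rd[:, None] * 0.85, 2, axis=1),
            np.repeat(0.5 * s0[:, None], 2, axis=1),
        )
        candidates[2] = _fit_candidate(
            Y, b, g, (2, [x2, x2b], np.arange(V)), merge_angle_deg, max_iter
        )

    if max_tensors >= 3:
        # only voxels where the 2-tensor candidate is a genuine, still
        # imperfect 2-compartment fit can be promoted to 3 by the F-test
        need3 = np.array(
            [
                len(candidates[2][v]["w"]) == 2
                and candidates[2][v]["sse"] > 1e-16 * yty[v]
                for v in range(V)
            ]
        )
        v3 = np.flatnonzero(need3)
        if len(v3):
            pair_fine = idx2[v3]
            _, k3 = _greedy_third(B_c[v3], B_f[v3], dicts, pair_fine)
            idx3 = np.concatenate(
                [pair_fine, dicts.coarse_to_fine[k3][:, None]], axis=1
            )
            idx3 = _refine_axes_fine(idx3, B_f[v3], dicts.G_f, fine_nb_of_fine)
            w3, _ = _solve_weights(dicts.G_f, B_f[v3], idx3)
            w3 = np.clip(w3, 0.03 * s0[v3, None], None)
            x3 = _pack_seeds(
                dicts.fine[idx3],
                np.repeat(ad[v3, None], 3, axis=1),
                np.repeat(rd[v3, None], 3, axis=1),
                w3,
            )
            candidates[3] = _fit_candidate(
                Y, b, g, (3, x3, v3), merge_angle_deg, max_iter
            )

    fits = []
    for v in range(V):
        cands_v = {N: candidates[N][v] for N in candidates if v in candidates[N]}
        Nsel = _select_n(cands_v, M, yty[v], alpha=alpha)
        fits.append(_to_fit(cands_v[Nsel]))
    return fits


def _fine_neighbor_table(dicts: _Dictionaries, n_neighbors: int = 8):
    if dicts._fine_nb_of_fine is None:
        dots = np.abs(dicts.fine @ dicts.fine.T)
        dicts._fine_nb_of_fine = np.argsort(-dots, axis=1)[:, :n_neighbors]
    return dicts._fine_nb_of_fine


def _greedy_third(B_c, B_f, dicts, pair_fine):
    """Pick the coarse axis that best complements the fixed fine pair."""
    V = pair_fine.shape[0]
    Kc = dicts.coarse.shape[0]
    # cross-Gram between fine and coarse dictionaries
    Gfc = dicts.A_f.T @ dicts.A_c  # (Kf, Kc)
    G_f = dicts.G_f
    i, j = pair_fine[:, 0], pair_fine[:, 1]
    g11, g22, g12 = G_f[i, i], G_f[j, j], G_f[i, j]
    b1, b2 = B_f[np.arange(V), i], B_f[np.arange(V), j]
    g13 = Gfc[i]  # (V, Kc)
    g23 = Gfc[j]
    g33 = np.diag(dicts.G_c)[None, :]
    b3 = B_c
    best_expl = np.full(V, -np.inf)
    best_k = np.zeros(V, dtype=int)
    chunk = 64
    for s in range(0, Kc, chunk):
        sl = slice(s, s + chunk)
        n = g33[:, sl].shape[1]
        Gs = np.empty((V, n, 3, 3))
        Gs[..., 0, 0] = g11[:, None]
        Gs[..., 1, 1] = g22[:, None]
        Gs[..., 2, 2] = g33[:, sl]
        Gs[..., 0, 1] = Gs[..., 1, 0] = g12[:, None]
        Gs[..., 0, 2] = Gs[..., 2, 0] = g13[:, sl]
        Gs[..., 1, 2] = Gs[..., 2, 1] = g23[:, sl]
        Bs = np.stack(
            [np.broadcast_to(b1[:, None], (V, n)),
             np.broadcast_to(b2[:, None], (V, n)),
             b3[:, sl]], axis=-1
        )
        Gs = Gs + 1e-12 * np.eye(3)[None, None]
        w = np.linalg.solve(Gs, Bs[..., None])[..., 0]
        expl = np.sum(w * Bs, axis=-1)
        expl = np.where(np.any(w < 0, axis=-1), -np.inf, expl)
        k = np.argmax(expl, axis=1)
        e = expl[np.arange(V), k]
        upd = e > best_expl
        best_expl[upd] = e[upd]
        best_k[upd] = (s + k)[upd]
    return best_expl, best_k


def fit_multi_tensor(
    signal: np.ndarray,
    scheme: AcquisitionScheme,
    max_tensors: int = 3,
    merge_angle_deg: float = 20.0,
    alpha: float = 0.05,
) -> MultiTensorFit:
    """Fit the multi-tensor model to a single voxel's signal."""
    return fit_multi_tensor_batch(
        np.atleast_2d(signal), scheme, max_tensors, merge_angle_deg, alpha
    )[0]
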