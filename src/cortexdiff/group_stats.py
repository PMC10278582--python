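"""Permutation tests and cluster-wise inference on metric sheets.

Point-wise: at each of the 50 x 10 grid points the statistic is the
difference of group means (control minus experimental).  Significance
comes from random relabelings of the pooled subjects — the same
relabeling sequence at every point — with the add-one estimator

    p = (1 + #{permuted |T| >= observed |T|}) / (n_perm + 1),

which is valid (super-uniform under the null) at any finite number of
permutations.

Cluster-wise: observed clusters are 4-connected components of points
with p below the cluster-forming threshold (default 0.05); their
familywise-corrected p compares each cluster's size against the
empirical null distribution of the *maximum* cluster size per permuted
grid.  Each permuted dataset's point-wise p-values are computed against
the same shared permutation ensemble (rank of its |T| among all
ensemble rows), so one ensemble serves both levels at once.

Effect sizes are Cohen's d with the pooled standard deviation, signed
control minus experimental.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .cortical_grid import MetricSheet

__all__ = [
    "GroupStudy",
    "ClusterResult",
    "pointwise_perm_test",
    "cluster_inference",
    "cohens_d",
]

logger = logging.getLogger(__name__)

_STRUCTURE_4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
_STRUCTURE_8 = np.ones((3, 3), int)


@dataclass
class GroupStudy:
    """Stacked metric sheets for a two-group comparison."""

    sheets_a: np.ndarray  # (n_A, L, D) control
    sheets_b: np.ndarray  # (n_B, L, D) experimental
    metric_name: str = ""

    def __post_init__(self) -> None:
        self.sheets_a = _stack(self.sheets_a)
        self.sheets_b = _stack(self.sheets_b)
        if self.sheets_a.shape[1:] != self.sheets_b.shape[1:]:
            raise ValueError("group sheets have different grid shapes")
        if len(self.sheets_a) < 2 or len(self.sheets_b) < 2:
            raise ValueError("each group needs >= 2 subjects")

    @property
    def n_a(self) -> int:
        return len(self.sheets_a)

    @property
    def n_b(self) -> int:
        return len(self.sheets_b)

    @property
    def grid_shape(self) -> tuple:
        return self.sheets_a.shape[1:]

    def pooled(self) -> np.ndarray:
        return np.concatenate([self.sheets_a, self.sheets_b], axis=0)


def _stack(sheets) -> np.ndarray:
    if isinstance(sheets, np.ndarray) and sheets.ndim == 3:
        return np.asarray(sheets, float)
    arrs = [
        s.values if isinstance(s, MetricSheet) else np.asarray(s, float)
        for s in sheets
    ]
    return np.stack(arrs).astype(float)


def _relabelings(n_total, n_a, n_perm, seed) -> np.ndarray:
    """(n_perm, n_total) permutation matrix of subject indices."""
    rng = np.random.default_rng(seed)
    return np.array([rng.permutation(n_total) for _ in range(n_perm)])


def _group_stats_for_perms(data, n_a, perms, min_subjects):
    """Mean-difference statistic for each relabeling.

    data : (n, P) pooled subject-by-point values (NaN = missing).
    Returns (R, P) statistics; points with fewer than ``min_subjects``
    valid subjects in either group under a relabeling get NaN.
    """
    perms = np.asarray(perms)
    finite = np.isfinite(data)
    if finite.all():
        # complete data: the statistic is a fixed linear weighting of
        # subjects, so all relabelings reduce to one matrix product
        n = data.shape[0]
        n_a_f, n_b_f = float(n_a), float(n - n_a)
        W = np.full(perms.shape, -1.0 / n_b_f)
        W[:, :n_a] = 1.0 / n_a_f
        Wfull = np.zeros((len(perms), n))
        np.put_along_axis(Wfull, perms, W, axis=1)
        if min(n_a, n - n_a) < min_subjects:
            return np.full((len(perms), data.shape[1]), np.nan)
        return Wfull @ data
    dataz = np.where(finite, data, 0.0)
    stats = np.empty((len(perms), data.shape[1]))
    for r, perm in enumerate(perms):
        ia, ib = perm[:n_a], perm[n_a:]
        ca = finite[ia].sum(axis=0)
        cb = finite[ib].sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            ma = dataz[ia].sum(axis=0) / ca
            mb = dataz[ib].sum(axis=0) / cb
        t = ma - mb
        t[(ca < min_subjects) | (cb < min_subjects)] = np.nan
        stats[r] = t
    return stats


def pointwise_perm_test(
    study: GroupStudy,
    n_perm: int = 5000,
    seed: int = 0,
    min_subjects: int = 5,
) -> np.ndarray:
    """Two-sided point-wise permutation p-values (add-one estimator)."""
    if n_perm < 100:
        logger.warning("n_perm=%d is very low; p-values will be coarse", n_perm)
    data = study.pooled().reshape(study.n_a + study.n_b, -1)
    obs = _group_stats_for_perms(
        data, study.n_a, [np.arange(data.shape[0])], min_subjects
    )[0]
    perms = _relabelings(data.shape[0], study.n_a, n_perm, seed)
    stats = _group_stats_for_perms(data, study.n_a, perms, min_subjects)
    # ties at the observed value count as exceedances (tolerance keeps
    # exact ties broken only by float round-off counted as ties)
    tol = 1e-12 * float(np.nanmax(np.abs(data), initial=1.0))
    with np.errstate(invalid="ignore"):
        exceed = np.nansum(
            np.abs(stats) >= np.abs(obs)[None, :] - tol, axis=0
        )
    p = (1.0 + exceed) / (n_perm + 1.0)
    p[~np.isfinite(obs)] = np.nan
    return p.reshape(study.grid_shape)


def cohens_d(study: GroupStudy) -> np.ndarray:
    """Cohen's d map (control minus experimental, pooled SD).

    Zero pooled variance gives d = 0 for equal means and +/-inf for
    unequal means.
    """
    a, b = study.sheets_a, study.sheets_b
    na = np.isfinite(a).sum(axis=0).astype(float)
    nb = np.isfinite(b).sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        ma, mb = np.nanmean(a, axis=0), np.nanmean(b, axis=0)
        va = np.nanvar(a, axis=0, ddof=1)
        vb = np.nanvar(b, axis=0, ddof=1)
        sp = np.sqrt(((na - 1) * va + (nb - 1) * vb) / (na + nb - 2))
        d = (ma - mb) / sp
    diff = ma - mb
    zero_sp = sp == 0
    d = np.where(zero_sp & (diff == 0), 0.0, d)
    d = np.where(zero_sp & (diff != 0), np.sign(diff) * np.inf, d)
    d[(na < 2) | (nb < 2)] = np.nan
    return d


@dataclass
class ClusterResult:
    """Cluster-wise inference output on the grid."""

    p_point: np.ndarray
    d_map: np.ndarray
    cluster_labels: np.ndarray
    cluster_sizes: np.ndarray
    p_cluster: np.ndarray
    null_max_sizes: np.ndarray
    alpha_form: float

    @property
    def significant(self) -> np.ndarray:
        """Boolean mask of grid points in clusters with p_cluster < alpha."""
        sig = np.zeros(self.p_point.shape, bool)
        for lab, p in enumerate(self.p_cluster, start=1):
            if p < self.alpha_form:
                sig |= self.cluster_labels == lab
        return sig


def _label_clusters(mask: np.ndarray, connectivity: int):
    structure = _STRUCTURE_4 if connectivity == 4 else _STRUCTURE_8
    labels, n = ndimage.label(mask, structure=structure)
    sizes = (
        np.bincount(labels.ravel(), minlength=n + 1)[1:]
        if n
        else np.zeros(0, int)
    )
    return labels, sizes


def cluster_inference(
    study: GroupStudy,
    alpha_form: float = 0.05,
    n_perm: int = 5000,
    seed: int = 0,
    connectivity: int = 4,
    min_subjects: int = 5,
    null_statistic: str = "max",
) -> ClusterResult:
    """Cluster-wise permutation inference with a shared ensemble.

    ``null_statistic='max'`` (default) controls the familywise error by
    tallying the maximum cluster size per permuted grid;
    ``'pooled'`` instead pools every cluster size from every permuted
    grid into one null distribution.
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    data = study.pooled().reshape(study.n_a + study.n_b, -1)
    n_total = data.shape[0]
    perms = _relabelings(n_total, study.n_a, n_perm, seed)
    all_perms = np.concatenate([np.arange(n_total)[None, :], perms], axis=0)
    stats = _group_stats_for_perms(data, study.n_a, all_perms, min_subjects)
    absT = np.abs(stats)  # row 0 = observed
    # each row's point-wise p against the shared ensemble (rows 1..R),
    # via a per-point sorted search (memory stays O(R * P))
    P = absT.shape[1]
    tol = 1e-12 * float(np.nanmax(np.abs(data), initial=1.0))
    exceed = np.zeros((n_perm + 1, P))
    for j in range(P):
        ens = absT[1:, j]
        fin = ens[np.isfinite(ens)]
        fin.sort()
        col = absT[:, j]
        pos = np.searchsorted(fin, col - tol, side="left")
        exceed[:, j] = len(fin) - pos
    # a null row always finds itself in the ensemble; remove that self
    # count so null and observed p share the add-one estimator form
    exceed[1:] = np.maximum(exceed[1:] - 1.0, 0.0)
    p_all = (1.0 + exceed) / (n_perm + 1.0)
    p_all = np.where(np.isfinite(absT), p_all, np.nan)

    shape = study.grid_shape
    p_obs = p_all[0].reshape(shape)
    obs_mask = np.isfinite(p_obs) & (p_obs < alpha_form)
    labels, sizes = _label_clusters(obs_mask, connectivity)

    null_sizes = []
    for r in range(1, n_perm + 1):
        pr = p_all[r].reshape(shape)
        m = np.isfinite(pr) & (pr < alpha_form)
        _, sz = _label_clusters(m, connectivity)
        if null_statistic == "max":
            null_sizes.append(int(sz.max()) if len(sz) else 0)
        else:
            null_sizes.extend(int(s) for s in sz) if len(sz) else null_sizes.append(0)
    null_sizes = np.asarray(null_sizes)

    denom = len(null_sizes) + 1.0
    p_cluster = np.array(
        [(1.0 + np.count_nonzero(null_sizes >= s)) / denom for s in sizes]
    )
    return ClusterResult(
        p_point=p_obs,
        d_map=cohens_d(study),
        cluster_labels=labels,
        cluster_sizes=sizes,
        p_cluster=p_cluster,
        null_max_sizes=null_sizes,
        alpha_form=alpha_form,
    )
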