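"""Multivariate (PLS) and mass-univariate cluster statistics on source maps.

``task_pls`` is mean-centered task PLS: the group-by-element matrix of
condition means is column-centered and decomposed by SVD; latent-vector
significance comes from permuting subjects' group assignments, and element
stability from bootstrap resampling of subjects within groups.

``cluster_permutation`` is a standard cluster-mass permutation test on the
voxel grid: voxelwise statistics (two-sample t, or Fisher r-to-z difference
of within-group correlations), a two-sided cluster-forming threshold,
face-connected (6-neighbor) components scored by the sum of |t|, and a null
distribution of the maximum cluster mass under label permutation;
``p_cluster = (r + 1) / (n_perm + 1)``.

``sphere_cluster`` converts a significant map into regional features the way
the prediction stage consumes them: spheres of a fixed voxel radius centered
on local |t| maxima, restricted to significant voxels, averaged per sphere
and then across spheres sharing an anatomical label.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .exceptions import DesignError
from .synthgen import SourceMapSet

FACE_CONNECTIVITY = ndimage.generate_binary_structure(3, 1)


# ---------------------------------------------------------------------------
# PLS


@dataclass
class PLSResult:
    singular_values: np.ndarray
    design_saliences: np.ndarray  # (n_groups, n_lv)
    element_saliences: np.ndarray  # (n_elements, n_lv)
    subject_scores: np.ndarray  # (n_subjects, n_lv)
    perm_p: np.ndarray
    bootstrap_ratios: np.ndarray | None
    group_order: list


def _crossblock_means(X, groups, levels):
    M = np.stack([X[groups == g].mean(axis=0) for g in levels])
    return M - M.mean(axis=0, keepdims=True)


def _crossblock_corr(X, y, groups, levels):
    rows = []
    for g in levels:
        sel = groups == g
        Xg = X[sel]
        yg = y[sel]
        Xc = Xg - Xg.mean(axis=0)
        yc = yg - yg.mean()
        denom = np.sqrt((Xc**2).sum(axis=0) * (yc**2).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(denom > 0, Xc.T @ yc / np.where(denom > 0, denom, 1.0), 0.0)
        rows.append(r)
    return np.stack(rows)


def _pls_core(M):
    U, S, Vt = np.linalg.svd(M, full_matrices=False)
    return U, S, Vt.T


def _pls(
    X,
    groups,
    *,
    behavior=None,
    n_perm=500,
    n_boot=200,
    seed=0,
):
    X = np.asarray(X, dtype=float)
    groups = np.asarray(groups)
    levels = list(pd.unique(groups))
    n = len(groups)
    if behavior is None and len(levels) < 2:
        raise DesignError("task PLS needs at least 2 groups/conditions")
    for g in levels:
        if (groups == g).sum() < 2:
            raise DesignError(f"group {g!r} has fewer than 2 subjects")
    if X.shape[0] != n:
        raise DesignError("data and group label lengths differ")
    if not np.all(np.isfinite(X)):
        raise DesignError("non-finite elements in the data block")

    rng = np.random.default_rng(seed)

    def crossblock(Xp, gp, yp):
        if behavior is None:
            return _crossblock_means(Xp, gp, levels)
        return _crossblock_corr(Xp, yp, gp, levels)

    y = None if behavior is None else np.asarray(behavior, dtype=float)
    M = crossblock(X, groups, y)
    U, S, V = _pls_core(M)

    # permutation: reassign group labels (task) or shuffle behavior (behavioral)
    exceed = np.zeros_like(S)
    for _ in range(n_perm):
        if behavior is None:
            gp = groups[rng.permutation(n)]
            Sp = np.linalg.svd(crossblock(X, gp, None), compute_uv=False)
        else:
            yp = y[rng.permutation(n)]
            Sp = np.linalg.svd(crossblock(X, groups, yp), compute_uv=False)
        k = min(len(Sp), len(S))
        exceed[:k] += Sp[:k] >= S[:k]
    perm_p = (exceed + 1.0) / (n_perm + 1.0)

    ratios = None
    if n_boot:
        boots = np.empty((n_boot,) + V.shape)
        idx_by_group = {g: np.flatnonzero(groups == g) for g in levels}
        for b in range(n_boot):
            take = np.concatenate(
                [rng.choice(idx, size=len(idx), replace=True) for idx in idx_by_group.values()]
            )
            Mb = crossblock(X[take], groups[take], None if y is None else y[take])
            _, _, Vb = _pls_core(Mb)
            k = min(Vb.shape[1], V.shape[1])
            # align sign of each latent vector with the observed solution
            signs = np.sign(np.einsum("ij,ij->j", Vb[:, :k], V[:, :k]))
            signs[signs == 0] = 1.0
            boots[b, :, :k] = Vb[:, :k] * signs
            boots[b, :, k:] = np.nan
        se = np.nanstd(boots, axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            ratios = np.where(se > 0, V / se, np.inf * np.sign(V))

    scores = (X - X.mean(axis=0)) @ V
    return PLSResult(
        singular_values=S,
        design_saliences=U,
        element_saliences=V,
        subject_scores=scores,
        perm_p=perm_p,
        bootstrap_ratios=ratios,
        group_order=levels,
    )


def task_pls(X, groups, n_perm=500, n_boot=200, seed=0) -> PLSResult:
    """Mean-centered task PLS of a subjects x elements block against group membership."""
    return _pls(X, groups, behavior=None, n_perm=n_perm, n_boot=n_boot, seed=seed)


def behavior_pls(X, behavior, groups=None, n_perm=500, n_boot=200, seed=0) -> PLSResult:
    """Behavioral PLS: SVD of within-group element-behavior correlations."""
    if groups is None:
        groups = np.zeros(len(np.asarray(behavior)), dtype=int)
    return _pls(X, groups, behavior=behavior, n_perm=n_perm, n_boot=n_boot, seed=seed)


# ---------------------------------------------------------------------------
# cluster-mass permutation


@dataclass
class Cluster:
    voxels: np.ndarray  # (k, 3) integer indices
    mass: float
    p_cluster: float
    sign: int


@dataclass
class SourceStatMap:
    t_values: np.ndarray
    threshold: float
    sig_mask: np.ndarray
    clusters: list
    atlas: object
    band: str | None = None
    task: str | None = None


def _two_sample_t(a, b):
    # a, b: (n, voxels); Welch-free pooled-variance two-sample t
    na, nb = a.shape[0], b.shape[0]
    ma, mb = a.mean(axis=0), b.mean(axis=0)
    va = a.var(axis=0, ddof=1)
    vb = b.var(axis=0, ddof=1)
    sp = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    denom = np.sqrt(sp * (1.0 / na + 1.0 / nb))
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom > 0, (ma - mb) / np.where(denom > 0, denom, 1.0), 0.0)


def _corr_rows(a, y):
    ac = a - a.mean(axis=0)
    yc = y - y.mean()
    denom = np.sqrt((ac**2).sum(axis=0) * (yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom > 0, ac.T @ yc / np.where(denom > 0, denom, 1.0), 0.0)


def _corr_diff_z(a, ya, b, yb):
    na, nb = a.shape[0], b.shape[0]
    ra = np.clip(_corr_rows(a, ya), -0.999999, 0.999999)
    rb = np.clip(_corr_rows(b, yb), -0.999999, 0.999999)
    se = np.sqrt(1.0 / (na - 3) + 1.0 / (nb - 3))
    return (np.arctanh(ra) - np.arctanh(rb)) / se


def _cluster_masses(stat_map, threshold):
    """Face-connected suprathreshold clusters of each sign, scored by sum |t|."""
    out = []
    for sign in (1, -1):
        mask = stat_map * sign >= threshold
        labels, n = ndimage.label(mask, structure=FACE_CONNECTIVITY)
        for lab in range(1, n + 1):
            vox = np.argwhere(labels == lab)
            mass = float(np.abs(stat_map[labels == lab]).sum())
            out.append((vox, mass, sign))
    return out


def cluster_permutation(
    maps_a: SourceMapSet | np.ndarray,
    maps_b: np.ndarray | None = None,
    *,
    group_a: str | None = None,
    group_b: str | None = None,
    behavior=None,
    mode: str = "group",
    threshold_p: float = 0.05,
    n_perm: int = 500,
    seed: int = 0,
) -> SourceStatMap:
    """Cluster-mass permutation test between two groups of source maps.

    ``mode="group"``: voxelwise two-sample t between the groups.
    ``mode="correlation_difference"``: voxelwise Fisher r-to-z difference of
    within-group correlations of ERD with ``behavior`` (a, b vectors).
    """
    atlas = None
    if isinstance(maps_a, SourceMapSet):
        mapset = maps_a
        atlas = mapset.atlas
        if group_a is None or group_b is None:
            raise DesignError("group_a/group_b required with a SourceMapSet input")
        sel_a = mapset.groups == group_a
        sel_b = mapset.groups == group_b
        grid_shape = mapset.grid_shape
        A = mapset.values[sel_a].reshape(sel_a.sum(), -1)
        B = mapset.values[sel_b].reshape(sel_b.sum(), -1)
        if behavior is not None:
            behavior = (np.asarray(behavior)[sel_a], np.asarray(behavior)[sel_b])
        band, task = mapset.band, mapset.task
    else:
        A = np.asarray(maps_a, dtype=float)
        B = np.asarray(maps_b, dtype=float)
        grid_shape = A.shape[1:]
        A = A.reshape(A.shape[0], -1)
        B = B.reshape(B.shape[0], -1)
        band = task = None
    na, nb = A.shape[0], B.shape[0]
    if min(na, nb) < 3:
        raise DesignError("cluster_permutation needs at least 3 subjects per group")

    rng = np.random.default_rng(seed)
    if mode == "group":
        stat = _two_sample_t(A, B).reshape(grid_shape)
        threshold = float(stats.t.ppf(1.0 - threshold_p / 2.0, df=na + nb - 2))
    elif mode == "correlation_difference":
        ya, yb = (np.asarray(v, dtype=float) for v in behavior)
        stat = _corr_diff_z(A, ya, B, yb).reshape(grid_shape)
        threshold = float(stats.norm.ppf(1.0 - threshold_p / 2.0))
    else:
        raise ValueError(f"unknown mode {mode!r}")

    observed = _cluster_masses(stat, threshold)
    pooled = np.vstack([A, B])
    if mode == "correlation_difference":
        pooled_y = np.concatenate([ya, yb])
    null_max = np.zeros(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(na + nb)
        ia, ib = perm[:na], perm[na:]
        if mode == "group":
            s = _two_sample_t(pooled[ia], pooled[ib]).reshape(grid_shape)
        else:
            s = _corr_diff_z(pooled[ia], pooled_y[ia], pooled[ib], pooled_y[ib]).reshape(grid_shape)
        masses = [m for _, m, _ in _cluster_masses(s, threshold)]
        null_max[i] = max(masses) if masses else 0.0

    clusters = []
    for vox, mass, sign in observed:
        p = (np.sum(null_max >= mass) + 1.0) / (n_perm + 1.0)
        clusters.append(Cluster(voxels=vox, mass=mass, p_cluster=float(p), sign=sign))
    clusters.sort(key=lambda c: c.p_cluster)

    sig_mask = np.zeros(grid_shape, dtype=bool)
    for c in clusters:
        if c.p_cluster <= 0.05:
            sig_mask[tuple(c.voxels.T)] = True
    return SourceStatMap(
        t_values=stat,
        threshold=threshold,
        sig_mask=sig_mask,
        clusters=clusters,
        atlas=atlas,
        band=band,
        task=task,
    )


# ---------------------------------------------------------------------------
# sphere features


@dataclass
class SphereFeature:
    center: tuple
    members: np.ndarray  # (k, 3)
    region_label: str


def sphere_cluster(
    stat: SourceStatMap,
    values: SourceMapSet | np.ndarray,
    radius_voxels: float = 3.0,
) -> tuple[pd.DataFrame, list]:
    """Regional sphere-averaged features from a significant statistic map.

    Sphere centers are the local maxima of |t| within the significance mask
    (a significant voxel with no strictly larger |t| within the radius; ties
    break to the smallest linear index).  Members are the *significant*
    voxels within the Euclidean radius of the center; non-significant voxels
    inside the radius are excluded.  Per-subject sphere means carrying the
    same anatomical label are averaged into one named feature.
    """
    if isinstance(values, SourceMapSet):
        subj_values = values.values
        ids = values.subject_ids
        atlas = values.atlas
    else:
        subj_values = np.asarray(values, dtype=float)
        ids = np.arange(subj_values.shape[0])
        atlas = stat.atlas
    n_subj = subj_values.shape[0]
    coords = np.argwhere(stat.sig_mask)
    if coords.size == 0:
        return pd.DataFrame(index=pd.Index(ids, name="subject_id")), []

    absmap = np.abs(stat.t_values)
    lin = np.ravel_multi_index(coords.T, stat.sig_mask.shape)
    tvals = absmap[tuple(coords.T)]
    d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2)
    within = d2 <= radius_voxels**2

    centers = []
    for i in range(len(coords)):
        neigh = np.flatnonzero(within[i])
        best = tvals[neigh].max()
        if tvals[i] < best:
            continue
        ties = neigh[tvals[neigh] == best]
        if lin[i] == lin[ties].min():
            centers.append(i)

    spheres = []
    per_region_means: dict[str, list] = {}
    for i in centers:
        members = coords[within[i]]
        # majority label over members; ties resolved by the center's own label
        member_labels = atlas.label_volume[tuple(members.T)]
        lab_ids, counts = np.unique(member_labels, return_counts=True)
        best = lab_ids[counts == counts.max()]
        center_label = int(atlas.label_volume[tuple(coords[i])])
        region = atlas.names[center_label if center_label in best else int(best[0])]
        spheres.append(SphereFeature(center=tuple(coords[i]), members=members, region_label=region))
        vals = subj_values[:, members[:, 0], members[:, 1], members[:, 2]].mean(axis=1)
        per_region_means.setdefault(region, []).append(vals)

    feat = {
        region: np.mean(np.stack(v), axis=0) for region, v in per_region_means.items()
    }
    table = pd.DataFrame(feat, index=pd.Index(ids, name="subject_id"))
    return table, spheres
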