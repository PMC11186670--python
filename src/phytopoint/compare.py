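"""Registration and change detection between point clouds.

Point-to-plane ICP (optionally restricted to a rigid region mask, e.g.
the beet body while leaves deform), M3C2 signed surface distances,
deformation summaries, and the sensor completeness/precision scores used
to benchmark 3D phenotyping platforms against a reference scan.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .core import PointCloud, RigidTransform, require_nonempty
from .errors import DegenerateGeometryError, EmptyInputError, ParameterError, RegistrationError
from .preprocess import estimate_normals, voxel_downsample

__all__ = [
    "ICPConfig",
    "M3C2Config",
    "M3C2Result",
    "CompletenessReport",
    "register_icp",
    "m3c2",
    "deformation_summary",
    "completeness_score",
    "sensor_report",
]

log = logging.getLogger(__name__)


@dataclass
class ICPConfig:
    """Point-to-plane ICP settings.

    mask_moving / mask_fixed restrict correspondence search to a rigid
    region (the estimated transform is still meant for the whole cloud).
    """

    max_iterations: int = 50
    max_correspondence_mm: float = 10.0
    convergence_tol: float = 1e-8     # relative RMSE change
    normal_radius_mm: float = 5.0
    mask_moving: np.ndarray | None = None
    mask_fixed: np.ndarray | None = None

    def __post_init__(self) -> None:
        if (self.max_iterations <= 0 or self.max_correspondence_mm <= 0
                or self.convergence_tol <= 0):
            raise ParameterError("ICPConfig values must be positive")


@dataclass
class M3C2Config:
    """M3C2 scales (mm). ``normal_scale_mm`` is the diameter D of the
    neighborhood used to estimate/orient normals at the core points;
    ``projection_radius_mm`` is the search-cylinder radius d/2 and
    ``max_depth_mm`` its half-length."""

    normal_scale_mm: float = 10.0
    projection_radius_mm: float = 5.0
    max_depth_mm: float = 50.0
    min_points: int = 4
    core_spacing_mm: float | None = None   # None → every reference point

    def __post_init__(self) -> None:
        if (self.normal_scale_mm <= 0 or self.projection_radius_mm <= 0
                or self.max_depth_mm <= 0 or self.min_points < 1):
            raise ParameterError("M3C2Config values must be positive")


@dataclass
class M3C2Result:
    """Signed per-core-point surface distances.

    Positive distances point along the oriented (upward) normal, so
    negative values read as movement with gravity. Invalid core points
    (too few neighbors in either cloud) carry NaN, never zero.
    """

    core_points: np.ndarray
    normals: np.ndarray
    distances_mm: np.ndarray
    valid: np.ndarray

    @property
    def mean_mm(self) -> float:
        return float(np.mean(self.distances_mm[self.valid]))

    @property
    def std_mm(self) -> float:
        return float(np.std(self.distances_mm[self.valid]))


@dataclass
class CompletenessReport:
    """Voxel-count completeness (occlusion) score against a reference."""

    voxel_size_mm: float
    n_reference: int
    n_test: int

    @property
    def percent_difference(self) -> float:
        return (self.n_test - self.n_reference) / self.n_reference * 100.0


def _solve_point_to_plane(src, dst, nrm):
    """One linearized point-to-plane Gauss-Newton step -> RigidTransform."""
    c = np.cross(src, nrm)
    A = np.hstack([c, nrm])
    b = np.einsum("ij,ij->i", dst - src, nrm)
    x, *_ = np.linalg.lstsq(A, b, rcond=None)
    alpha, beta, gamma = x[:3]
    ca, sa = np.cos(alpha), np.sin(alpha)
    cb, sb = np.cos(beta), np.sin(beta)
    cg, sg = np.cos(gamma), np.sin(gamma)
    Rx = np.array([[1, 0, 0], [0, ca, -sa], [0, sa, ca]])
    Ry = np.array([[cb, 0, sb], [0, 1, 0], [-sb, 0, cb]])
    Rz = np.array([[cg, -sg, 0], [sg, cg, 0], [0, 0, 1]])
    return RigidTransform(Rz @ Ry @ Rx, x[3:])


def register_icp(moving: PointCloud, fixed: PointCloud,
                 config: ICPConfig | None = None,
                 initial: RigidTransform | None = None
                 ) -> tuple[RigidTransform, float]:
    """Point-to-plane ICP: minimize Σ((T·p − q)·n_q)² over correspondences.

    Parameters
    ----------
    moving, fixed : PointCloud
        ``fixed`` needs normals; they are estimated if absent.
    config : ICPConfig
        Iteration limits, correspondence gate, optional region masks.
    initial : RigidTransform
        Rough pre-alignment (identity by default).

    Returns
    -------
    (RigidTransform, float)
        Transform mapping ``moving`` into the fixed frame, and the final
        RMSE (mm) of the point-to-plane residuals on the used region.
    """
    config = config or ICPConfig()
    require_nonempty(moving, "moving cloud")
    require_nonempty(fixed, "fixed cloud")
    if not fixed.has_normals:
        fixed = estimate_normals(fixed, config.normal_radius_mm)
    fpts, fnrm = fixed.points, fixed.normals
    if config.mask_fixed is not None:
        fpts, fnrm = fpts[config.mask_fixed], fnrm[config.mask_fixed]
    ok = ~np.isnan(fnrm[:, 0])
    fpts, fnrm = fpts[ok], fnrm[ok]
    if len(fpts) < 6:
        raise RegistrationError("fewer than 6 fixed points with normals")
    mpts = moving.points
    if config.mask_moving is not None:
        mpts = mpts[config.mask_moving]
    tree = cKDTree(fpts)
    transform = initial or RigidTransform.identity()
    prev_rmse = np.inf
    rmse = np.inf
    for it in range(config.max_iterations):
        cur = transform.apply(mpts)
        dist, idx = tree.query(cur, distance_upper_bound=config.max_correspondence_mm)
        good = np.isfinite(dist)
        if np.sum(good) < 6:
            raise RegistrationError(
                f"only {int(np.sum(good))} correspondences inside "
                f"{config.max_correspondence_mm} mm (iteration {it})")
        src = cur[good]
        dst = fpts[idx[good]]
        nrm = fnrm[idx[good]]
        residual = np.einsum("ij,ij->i", src - dst, nrm)
        rmse = float(np.sqrt(np.mean(residual ** 2)))
        if abs(prev_rmse - rmse) <= config.convergence_tol * max(rmse, 1e-12):
            break
        prev_rmse = rmse
        step = _solve_point_to_plane(src, dst, nrm)
        transform = step.compose(transform)
    return transform, rmse


def m3c2(reference: PointCloud, compared: PointCloud,
         config: M3C2Config | None = None) -> M3C2Result:
    """M3C2 signed distance from ``reference`` to ``compared``.

    For each core point (every reference point, or a voxel-spaced subset)
    a normal is estimated from reference points within normal_scale/2 and
    oriented upward. Points of each cloud inside the search cylinder
    (radius ``projection_radius_mm``, half-depth ``max_depth_mm``) are
    projected onto the normal; the distance is the difference of the mean
    projections (compared − reference). A core point is valid only when
    both clouds contribute at least ``min_points``.
    """
    config = config or M3C2Config()
    require_nonempty(reference, "reference")
    require_nonempty(compared, "compared")
    if config.core_spacing_mm is not None:
        core = voxel_downsample(reference, config.core_spacing_mm).points
    else:
        core = reference.points
    ref_tree = cKDTree(reference.points)
    cmp_tree = cKDTree(compared.points)

    # normals at core points from the reference cloud, oriented up
    nbrs = ref_tree.query_ball_point(core, r=config.normal_scale_mm / 2.0)
    normals = np.full((len(core), 3), np.nan)
    for i, idx in enumerate(nbrs):
        if len(idx) < 3:
            continue
        local = reference.points[idx] - reference.points[idx].mean(axis=0)
        _, vecs = np.linalg.eigh(local.T @ local)
        n = vecs[:, 0]
        normals[i] = n if n[2] >= 0 else -n

    search_r = np.sqrt(config.projection_radius_mm ** 2 + config.max_depth_mm ** 2)
    distances = np.full(len(core), np.nan)
    valid = np.zeros(len(core), dtype=bool)
    for i, (p, n) in enumerate(zip(core, normals)):
        if np.isnan(n[0]):
            continue
        means = []
        ok = True
        for cloud_pts, tree in ((reference.points, ref_tree),
                                (compared.points, cmp_tree)):
            idx = tree.query_ball_point(p, r=search_r)
            if len(idx) < config.min_points:
                ok = False
                break
            rel = cloud_pts[idx] - p
            axial = rel @ n
            radial2 = np.einsum("ij,ij->i", rel, rel) - axial ** 2
            inside = (np.abs(axial) <= config.max_depth_mm) & \
                     (radial2 <= config.projection_radius_mm ** 2 + 1e-12)
            if np.sum(inside) < config.min_points:
                ok = False
                break
            means.append(axial[inside].mean())
        if ok:
            distances[i] = means[1] - means[0]
            valid[i] = True
    if not valid.any():
        log.warning("m3c2: no valid core points")
    return M3C2Result(core, normals, distances, valid)


def deformation_summary(result: M3C2Result,
                        labels: np.ndarray | None = None) -> dict:
    """Per-label and global statistics of the valid M3C2 distances.

    Returns a dict: ``{"global": {...}, "per_label": {label: {...}}}``
    with mean/std/min/max in mm and the count of valid core points.
    """
    if not result.valid.any():
        raise EmptyInputError("M3C2 result has no valid distances")

    def stats(d):
        return {"mean_mm": float(np.mean(d)), "std_mm": float(np.std(d)),
                "min_mm": float(np.min(d)), "max_mm": float(np.max(d)),
                "n": int(len(d))}

    out = {"global": stats(result.distances_mm[result.valid])}
    if labels is not None:
        labels = np.asarray(labels)
        if labels.shape != result.valid.shape:
            raise ParameterError("labels length must match core points")
        per = {}
        for lab in np.unique(labels):
            sel = result.valid & (labels == lab)
            if sel.any():
                per[int(lab)] = stats(result.distances_mm[sel])
        out["per_label"] = per
    return out


def completeness_score(reference: PointCloud, test: PointCloud,
                       voxel_size_mm: float = 5.0,
                       anchor=None) -> CompletenessReport:
    """Occlusion/completeness score: voxel-count difference vs reference.

    Both clouds are subsampled on one shared voxel grid (anchored at the
    reference minimum corner unless given) and the signed percentage
    difference of the point counts is reported.
    """
    require_nonempty(reference, "reference")
    require_nonempty(test, "test cloud")
    if anchor is None:
        anchor = reference.points.min(axis=0)
    n_ref = len(voxel_downsample(reference, voxel_size_mm, anchor))
    n_test = len(voxel_downsample(test, voxel_size_mm, anchor))
    return CompletenessReport(voxel_size_mm, n_ref, n_test)


def sensor_report(per_leaf: list) -> dict:
    """Tabulate per-leaf sensor precision and completeness.

    Parameters
    ----------
    per_leaf : list of (label, sigma_mm, percent_difference) or
        (label, M3C2Result, CompletenessReport) tuples.

    Returns
    -------
    dict with ``rows`` (label, sigma to 2 decimals, signed percent to 1
    decimal) and a ``mean`` row: arithmetic mean of the sigmas and of the
    *absolute* percentages (a sensor that over- and under-samples in
    different leaves should not score as complete).
    """
    if not per_leaf:
        raise EmptyInputError("sensor_report needs at least one leaf entry")
    rows = []
    for label, sigma, pct in per_leaf:
        if isinstance(sigma, M3C2Result):
            sigma = sigma.std_mm
        if isinstance(pct, CompletenessReport):
            pct = pct.percent_difference
        rows.append({"label": label,
                     "sigma_mm": round(float(sigma), 2),
                     "percent": round(float(pct), 1)})
    sigmas = np.array([r["sigma_mm"] for r in rows])
    pcts = np.array([r["percent"] for r in rows])
    return {
        "rows": rows,
        "mean": {
            "sigma_mm": round(float(sigmas.mean()), 2),
            "abs_percent": round(float(np.abs(pcts).mean()), 2),
        },
    }
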