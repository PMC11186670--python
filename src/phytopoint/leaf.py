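"""Single-leaf trait extraction.

Pipeline: align the leaf's longitudinal axis with +x (rotation about z
only, so the vertical is preserved) → petiole base (lowest x) → width
profile in 1.0-mm slabs → blade base (the first segment whose width
exceeds 2.5 × the running interquartile mean of all widths so far) →
blade tip (geodesic farthest point from the petiole base; that distance
is the leaf length) → blade length, blade width (max per-slab geodesic
across the blade), blade area (meshed blade), inclination angle.

Measured clouds are internally denoised by local-plane projection before
any surface-path computation; silhouettes are unaffected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import trim_mean

from .core import PointCloud, RigidTransform, require_min_points
from .errors import (
    DegenerateGeometryError,
    EmptyInputError,
    NoBladeBaseError,
    ParameterError,
    StageError,
)
from .surface import (
    GeodesicField,
    GeodesicSolver,
    MeshingConfig,
    farthest_point,
    graph_geodesic_distances,
    mesh_area,
    mesh_surface,
    triangulate_cloud,
)

__all__ = [
    "LeafKeypoints",
    "LeafBaseConfig",
    "LeafTraits",
    "WidthSegment",
    "align_leaf",
    "detect_petiole_base",
    "detect_blade_tip",
    "width_profile",
    "detect_blade_base",
    "blade_width",
    "blade_area",
    "inclination_angle",
    "extract_leaf_traits",
]

log = logging.getLogger(__name__)


@dataclass
class LeafKeypoints:
    """The three measurement points, in the aligned frame (mm)."""

    petiole_base: np.ndarray
    blade_base: np.ndarray
    blade_tip: np.ndarray
    blade_base_segment_index: int = -1


@dataclass
class LeafBaseConfig:
    """Parameters of the width-profile / blade-base procedure.

    segment_length_mm
        Slab thickness along the longitudinal axis (1.0 mm).
    width_factor
        A segment marks the blade base when its width exceeds this factor
        times the running mean (2.5 correlates best with 2D reference
        measurements of sugar beet).
    poly_degree
        Degree of the polynomial fitted to a slab's top surface.
    trim_fraction
        Central fraction of all widths kept by the running mean (0.5 =
        interquartile mean).
    warmup_segments
        Segments skipped before the trigger may fire (no baseline yet).
    """

    segment_length_mm: float = 1.0
    width_factor: float = 2.5
    poly_degree: int = 3
    trim_fraction: float = 0.5
    warmup_segments: int = 5

    def __post_init__(self) -> None:
        if self.segment_length_mm <= 0:
            raise ParameterError("segment_length_mm must be positive")
        if self.width_factor <= 1:
            raise ParameterError("width_factor must exceed 1")
        if not 0 < self.trim_fraction <= 1:
            raise ParameterError("trim_fraction must be in (0, 1]")
        if self.poly_degree < 1 or self.warmup_segments < 1:
            raise ParameterError("poly_degree and warmup_segments must be >= 1")


@dataclass
class WidthSegment:
    """One 1-mm slab of the width profile."""

    start_x_mm: float
    width_mm: float
    fallback: bool = False   # y-extent used (too few bins for the fit)


@dataclass
class LeafTraits:
    """Extracted single-leaf parameters (mm / mm² / degrees)."""

    leaf_length_mm: float = np.nan
    blade_length_mm: float = np.nan
    blade_width_mm: float = np.nan
    blade_area_mm2: float = np.nan
    inclination_deg: float = np.nan
    keypoints: LeafKeypoints | None = None
    alignment: RigidTransform | None = None   # input frame → aligned frame
    status: dict = field(default_factory=dict)

    def as_cm_row(self) -> dict:
        """Leaf-scale report row: cm / degrees, 1 decimal."""
        return {
            "leaf_length_cm": round(self.leaf_length_mm / 10.0, 1),
            "blade_length_cm": round(self.blade_length_mm / 10.0, 1),
            "blade_width_cm": round(self.blade_width_mm / 10.0, 1),
            "leaf_angle_deg": round(self.inclination_deg, 1),
            "leaf_area_cm2": round(self.blade_area_mm2 / 100.0, 1),
        }


def align_leaf(leaf: PointCloud) -> tuple[PointCloud, RigidTransform]:
    """Rotate about z so the longitudinal axis runs along +x.

    The longitudinal axis is the first principal component of the xy
    spread; z is preserved (it is the vertical against which inclination
    is measured). The petiole end — identified as the narrower end — is
    placed at lower x. The returned transform maps input to output.
    """
    require_min_points(leaf, 10, "align_leaf")
    pts = leaf.points
    centroid = pts.mean(axis=0)
    xy = pts[:, :2] - centroid[:2]
    cov = xy.T @ xy
    evals, evecs = np.linalg.eigh(cov)
    if evals[1] < 1e-12:
        raise DegenerateGeometryError(
            "leaf orientation is ambiguous (degenerate xy spread); supply "
            "a manual alignment transform")
    axis = evecs[:, 1]   # largest eigenvalue
    if evals[0] / evals[1] > 0.6:
        # near-isotropic footprint (steep, wide leaf): the xy principal
        # axis is unreliable, so take the 3D principal axis (the midrib
        # direction) and use its horizontal projection instead
        centered = pts - centroid
        evals3, evecs3 = np.linalg.eigh(centered.T @ centered)
        pc1 = evecs3[:, 2]
        if (evals3[1] / evals3[2] > 0.95
                or np.linalg.norm(pc1[:2]) < 0.05):
            raise DegenerateGeometryError(
                "leaf orientation is ambiguous (isotropic spread); supply "
                "a manual alignment transform")
        axis = pc1[:2] / np.linalg.norm(pc1[:2])
    angle = -np.degrees(np.arctan2(axis[1], axis[0]))
    tfm = RigidTransform.about_z(angle)
    tfm = RigidTransform(tfm.rotation, -tfm.rotation @ centroid)
    aligned = leaf.transformed(tfm)
    # petiole at lower x: the blade carries most of the surface (hence
    # most points), so the point mass must sit tip-ward of the extent
    # midpoint; if it does not, the leaf is facing the wrong way
    x = aligned.points[:, 0]
    if np.median(x) < 0.5 * (x.min() + x.max()):
        flip = RigidTransform.about_z(180.0)
        tfm = flip.compose(tfm)
        aligned = leaf.transformed(tfm)
    return aligned, tfm


def detect_petiole_base(aligned_leaf: PointCloud) -> int:
    """Index of the point with the lowest x (ties → lowest index)."""
    require_min_points(aligned_leaf, 1, "detect_petiole_base")
    return int(np.argmin(aligned_leaf.points[:, 0]))


def detect_blade_tip(aligned_leaf: PointCloud, petiole_base: int,
                     solver: GeodesicSolver | None = None,
                     field_out: list | None = None) -> tuple[int, float]:
    """Blade tip = geodesic farthest point from the petiole base.

    Returns (tip index, leaf length in mm — the geodesic distance).
    """
    if solver is None:
        faces = triangulate_cloud(aligned_leaf.points)
        solver = GeodesicSolver(aligned_leaf.points, faces)
    dist = solver.distances(petiole_base)
    fld = GeodesicField(petiole_base, dist)
    if field_out is not None:
        field_out.append(fld)
    return farthest_point(fld)


def width_profile(aligned_leaf: PointCloud,
                  config: LeafBaseConfig | None = None) -> list[WidthSegment]:
    """Per-slab top-surface widths along the longitudinal axis.

    Within each ``segment_length_mm`` x-slab, points are binned by y (bin
    width = half the segment length) and the highest point of each bin is
    taken as the slab's top surface. A polynomial z = p(y) is fitted to
    those crest points and the width is the arc length of p over the
    occupied y range — a chord would undercount curled sections. Slabs
    with fewer than poly_degree+1 occupied bins fall back to the plain
    y extent and are flagged.
    """
    config = config or LeafBaseConfig()
    pts = aligned_leaf.points
    require_min_points(aligned_leaf, config.poly_degree + 2, "width_profile")
    seg = config.segment_length_mm
    x0 = pts[:, 0].min()
    n_seg = int(np.ceil((pts[:, 0].max() - x0) / seg))
    slab_of = np.floor((pts[:, 0] - x0) / seg).astype(int)
    slab_of = np.clip(slab_of, 0, n_seg - 1)
    out: list[WidthSegment] = []
    for i in range(n_seg):
        sel = slab_of == i
        if not np.any(sel):
            continue   # gap recorded implicitly by the missing start_x
        y, z = pts[sel, 1], pts[sel, 2].copy()
        start_x = x0 + i * seg
        # remove the longitudinal slope within the slab: on a steeply
        # rising petiole the z spread across the slab otherwise leaks
        # into the transverse curve and inflates its arc length
        xs = pts[sel, 0]
        if np.ptp(xs) > 1e-9 and len(xs) >= 4:
            slope = np.polyfit(xs - xs.mean(), z, 1)[0]
            z = z - slope * (xs - xs.mean())
        bin_w = seg / 2.0
        bins = np.floor((y - y.min()) / bin_w).astype(int)
        order = np.lexsort((z, bins))
        last = np.concatenate([bins[order][1:] != bins[order][:-1], [True]])
        top_idx = order[last]          # per-bin max-z representative
        yb, zb = y[top_idx], z[top_idx]
        if len(yb) < config.poly_degree + 1:
            out.append(WidthSegment(start_x, float(y.max() - y.min()), True))
            continue
        dom = [yb.min(), yb.max()]
        p = np.polynomial.Polynomial.fit(yb, zb, config.poly_degree,
                                         domain=dom)
        dp = p.deriv()
        ys = np.linspace(yb.min(), yb.max(), 64)
        width = float(np.trapezoid(np.sqrt(1.0 + dp(ys) ** 2), ys))
        out.append(WidthSegment(start_x, width, False))
    return out


def running_trimmed_mean(widths: np.ndarray, trim_fraction: float) -> float:
    """Mean of the central ``trim_fraction`` of the values seen so far."""
    cut = (1.0 - trim_fraction) / 2.0
    return float(trim_mean(widths, proportiontocut=cut))


def detect_blade_base(profile: list[WidthSegment],
                      config: LeafBaseConfig | None = None) -> tuple[int, float]:
    """Locate the petiole/blade junction on a width profile.

    Walking tip-ward, a running mean of all widths seen so far is kept as
    the mean of their central 50% (interquartile mean — robust, so single
    noisy spikes and the first blade segments are trimmed away). The
    first segment, after the warm-up, whose width exceeds ``width_factor``
    times the running mean marks the blade base; its slab midpoint x is
    returned with the segment index.
    """
    config = config or LeafBaseConfig()
    if len(profile) < config.warmup_segments:
        raise NoBladeBaseError(
            f"profile has {len(profile)} segments, fewer than the "
            f"{config.warmup_segments}-segment warm-up")
    widths = np.array([s.width_mm for s in profile])
    for i in range(config.warmup_segments, len(profile)):
        baseline = running_trimmed_mean(widths[:i], config.trim_fraction)
        if widths[i] > config.width_factor * baseline:
            mid_x = profile[i].start_x_mm + config.segment_length_mm / 2.0
            return i, float(mid_x)
    raise NoBladeBaseError(
        "no segment exceeded the width-jump threshold (factor "
        f"{config.width_factor}); is this a constant-width object?")


def _blade_base_point(aligned_leaf: PointCloud, profile: list[WidthSegment],
                      seg_index: int, mid_x: float,
                      config: LeafBaseConfig) -> np.ndarray:
    """3D blade-base keypoint: slab midpoint in x, top-curve midpoint in y/z."""
    pts = aligned_leaf.points
    seg = config.segment_length_mm
    sel = np.abs(pts[:, 0] - mid_x) <= seg
    if not np.any(sel):
        raise StageError("blade_base", "no points near the detected junction")
    y, z = pts[sel, 1], pts[sel, 2]
    y_mid = 0.5 * (y.min() + y.max())
    band = np.abs(y - y_mid) <= max(seg, (y.max() - y.min()) / 8.0)
    z_mid = z[band].max() if np.any(band) else z.max()
    return np.array([mid_x, y_mid, z_mid])


def blade_width(aligned_blade: PointCloud,
                config: LeafBaseConfig | None = None,
                window_mm: float = 6.0) -> float:
    """Greatest per-slab geodesic width of the blade.

    For each 1-mm slab the surface distance between its two extreme-y
    boundary points is computed over the blade surface (so a curled
    cross-section is measured along its arc, not its chord); the maximum
    over slabs is the blade width. Each slab query runs on a submesh
    within ``window_mm`` of the slab, which contains the cross-section
    geodesic for any realistically curled blade.
    """
    config = config or LeafBaseConfig()
    require_min_points(aligned_blade, 8, "blade_width")
    pts = aligned_blade.points
    seg = config.segment_length_mm
    x0 = pts[:, 0].min()
    n_seg = int(np.ceil((pts[:, 0].max() - x0) / seg))
    slab_of = np.clip(np.floor((pts[:, 0] - x0) / seg).astype(int), 0, n_seg - 1)
    try:
        all_faces = triangulate_cloud(pts, k=min(12, len(pts) - 1))
    except DegenerateGeometryError:
        all_faces = None
    face_x = None if all_faces is None else pts[all_faces, 0]
    best = 0.0
    for i in range(n_seg):
        sel = slab_of == i
        if np.sum(sel) < 2:
            continue
        center = x0 + (i + 0.5) * seg
        sub_sel = np.abs(pts[:, 0] - center) <= window_mm
        n_sub = int(np.sum(sub_sel))
        if n_sub < 4:
            continue
        remap = np.full(len(pts), -1, dtype=np.int64)
        remap[sub_sel] = np.arange(n_sub)
        sub = pts[sub_sel]
        slab_local = remap[sel & sub_sel]
        ys = sub[slab_local, 1]
        src = int(slab_local[np.argmin(ys)])
        tgt = int(slab_local[np.argmax(ys)])
        if src == tgt:
            continue
        d = np.inf
        if all_faces is not None:
            in_win = np.all(np.abs(face_x - center) <= window_mm, axis=1)
            sub_faces = remap[all_faces[in_win]]
            if len(sub_faces):
                try:
                    d = GeodesicSolver(sub, sub_faces).distances(src)[tgt]
                except DegenerateGeometryError:
                    pass
        if not np.isfinite(d):
            d = graph_geodesic_distances(sub, src)[tgt]
        if np.isfinite(d):
            best = max(best, float(d))
    if best == 0.0:
        raise DegenerateGeometryError("no slab yielded a finite width")
    return best


def blade_area(aligned_leaf: PointCloud, keypoints: LeafKeypoints,
               meshing: MeshingConfig | None = None) -> float:
    """Blade surface area: mesh the points tip-ward of the blade base.

    The blade is detached orthogonally to the longitudinal axis at the
    blade base x, meshed, and the triangle areas are summed.
    """
    pts = aligned_leaf.points
    sel = pts[:, 0] >= keypoints.blade_base[0]
    if np.sum(sel) < 3:
        raise StageError("blade_area", "fewer than 3 points tip-ward of the blade base")
    mesh = mesh_surface(PointCloud(pts[sel]), meshing)
    if len(mesh.faces) == 0:
        raise StageError("blade_area", "meshing produced no triangles")
    return mesh_area(mesh)


def inclination_angle(keypoints: LeafKeypoints) -> float:
    """Angle (degrees, [0, 180]) between the vertical (+z) and the blade
    base → tip line; > 90° means the tip droops below the base."""
    v = keypoints.blade_tip - keypoints.blade_base
    n = np.linalg.norm(v)
    if n < 1e-9:
        raise DegenerateGeometryError("blade base and tip coincide")
    return float(np.degrees(np.arccos(np.clip(v[2] / n, -1.0, 1.0))))


def extract_leaf_traits(leaf: PointCloud,
                        config: LeafBaseConfig | None = None,
                        meshing: MeshingConfig | None = None,
                        denoise: bool = True) -> LeafTraits:
    """Run the full single-leaf pipeline; failures are staged and partial.

    A constant-width object (no blade-base trigger) still reports leaf
    length; blade-dependent traits stay NaN with the stage noted.
    """
    from .preprocess import project_to_local_planes

    config = config or LeafBaseConfig()
    traits = LeafTraits()
    aligned, tfm = align_leaf(leaf)
    traits.alignment = tfm
    traits.status["align"] = "ok"
    work = project_to_local_planes(aligned) if denoise else aligned
    base_idx = detect_petiole_base(work)
    traits.status["petiole_base"] = "ok"

    try:
        faces = triangulate_cloud(work.points)
        solver = GeodesicSolver(work.points, faces)
    except DegenerateGeometryError as exc:
        raise StageError("triangulation", str(exc)) from exc

    tip_idx, leaf_len = detect_blade_tip(work, base_idx, solver)
    traits.leaf_length_mm = leaf_len
    traits.status["leaf_length"] = "ok"

    petiole_base_pt = work.points[base_idx]
    tip_pt = work.points[tip_idx]
    keypoints = LeafKeypoints(petiole_base_pt, tip_pt.copy(), tip_pt)
    traits.keypoints = keypoints

    try:
        profile = width_profile(work, config)
        seg_idx, mid_x = detect_blade_base(profile, config)
        keypoints.blade_base_segment_index = seg_idx
        keypoints.blade_base = _blade_base_point(work, profile, seg_idx,
                                                 mid_x, config)
        traits.status["blade_base"] = "ok"
    except NoBladeBaseError as exc:
        traits.status["blade_base"] = f"NoBladeBaseError: {exc}"
        log.warning("extract_leaf_traits: %s", exc)
        return traits

    # blade length: geodesic from the point nearest the blade-base keypoint
    # to the tip, measured over the same surface
    snap = int(np.argmin(np.linalg.norm(work.points - keypoints.blade_base,
                                        axis=1)))
    tip_field = solver.distances(tip_idx)
    traits.blade_length_mm = float(min(tip_field[snap], traits.leaf_length_mm))
    traits.status["blade_length"] = "ok"

    blade_pts = work.points[work.points[:, 0] >= keypoints.blade_base[0]]
    try:
        traits.blade_width_mm = blade_width(PointCloud(blade_pts), config)
        traits.status["blade_width"] = "ok"
    except (DegenerateGeometryError, EmptyInputError) as exc:
        traits.status["blade_width"] = f"{type(exc).__name__}: {exc}"
    try:
        traits.blade_area_mm2 = blade_area(work, keypoints, meshing)
        traits.status["blade_area"] = "ok"
    except StageError as exc:
        traits.status["blade_area"] = str(exc)
    traits.inclination_deg = inclination_angle(keypoints)
    traits.status["inclination"] = "ok"
    return traits
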