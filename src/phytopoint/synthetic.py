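"""Synthetic rosette-plant fixtures with analytic ground truth.

A parametric sugar-beet-like leaf is a curved petiole strip joined to a
lofted blade. The midrib lives in the vertical plane of the leaf azimuth:
its tangent tilts from a near-vertical take-off angle down to ``droop_deg``
along the petiole, then continues straight through the blade, so the leaf
inclination (blade base → tip line vs the vertical) equals ``droop_deg``
by construction. The blade cross-section is a circular arc of arc-width
w(s) — the curled-leaf width that a geodesic measurement should recover —
whose width law along the blade is

    w(u) = blade_max_width · sin(π u)^k,   u ∈ [0, 1].

Sugar beet blades reach nearly their full width within a few millimetres
of the petiole junction (the cordate "shoulder"); the small default
exponent k reproduces that abrupt widening.

A plant is a spheroidal beet body with leaves attached at the crown at
their azimuths. All ground-truth quantities are obtained by fine
numerical integration of the same parametrization the sampler uses; a
fixed seed makes every cloud reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .core import PointCloud
from .errors import ParameterError

__all__ = [
    "LeafSpec",
    "SamplingSpec",
    "OcclusionSpec",
    "GroundTruth",
    "PlantGroundTruth",
    "make_leaf",
    "make_plant",
    "degrade",
    "random_leaf_spec",
]

_TRUTH_STEP_MM = 0.1


@dataclass
class LeafSpec:
    """Geometry of one parametric leaf (lengths in mm, angles in degrees)."""

    petiole_length_mm: float = 100.0
    petiole_width_mm: float = 8.0
    blade_length_mm: float = 150.0
    blade_max_width_mm: float = 70.0
    width_profile_exponent: float = 0.08
    droop_deg: float = 45.0
    azimuth_deg: float = 0.0
    cross_curvature: float = 0.3   # fraction of π subtended by the curl
    takeoff_deg: float = 12.0      # petiole tangent at the base, from vertical

    def __post_init__(self) -> None:
        if min(self.petiole_length_mm, self.petiole_width_mm,
               self.blade_length_mm, self.blade_max_width_mm) <= 0:
            raise ParameterError("all lengths must be positive")
        if self.blade_max_width_mm <= self.petiole_width_mm:
            raise ParameterError("blade_max_width must exceed petiole_width")
        if not 0.0 <= self.cross_curvature < 1.0:
            raise ParameterError("cross_curvature must be in [0, 1)")

    @property
    def total_length_mm(self) -> float:
        return self.petiole_length_mm + self.blade_length_mm


@dataclass
class OcclusionSpec:
    """Occlusion model: hidden-point removal or contiguous patch dropout."""

    mode: str = "hpr"                 # "hpr" | "patch"
    viewpoint: tuple = (0.0, 0.0, 1000.0)
    dropout_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in ("hpr", "patch"):
            raise ParameterError("occlusion mode must be 'hpr' or 'patch'")
        if not 0.0 <= self.dropout_fraction <= 1.0:
            raise ParameterError("dropout_fraction must be in [0, 1]")


@dataclass
class SamplingSpec:
    """How a parametric surface is turned into a measured cloud."""

    point_density_per_mm2: float = 1.0
    noise_sigma_mm: float = 0.3
    seed: int = 0
    occlusion: OcclusionSpec | None = None

    def __post_init__(self) -> None:
        if self.point_density_per_mm2 <= 0:
            raise ParameterError("density must be positive")
        if self.noise_sigma_mm < 0:
            raise ParameterError("noise sigma must be >= 0")


@dataclass
class GroundTruth:
    """Analytic morphology of one synthetic leaf."""

    leaf_length_mm: float
    blade_length_mm: float
    blade_max_width_mm: float
    blade_area_mm2: float
    inclination_deg: float
    petiole_base: np.ndarray = field(default_factory=lambda: np.zeros(3))
    blade_base: np.ndarray = field(default_factory=lambda: np.zeros(3))
    blade_tip: np.ndarray = field(default_factory=lambda: np.zeros(3))
    width_ratio: float = 0.0


@dataclass
class PlantGroundTruth:
    """Plant-level truth plus the per-leaf truths."""

    height_mm: float
    width_mm: float
    leaf_truths: list


def _midrib(spec: LeafSpec, step: float):
    """Midrib polyline in the azimuth=0 frame; returns (s, positions)."""
    n = max(2, int(np.ceil(spec.total_length_mm / step)) + 1)
    s = np.linspace(0.0, spec.total_length_mm, n)
    phi = np.empty_like(s)
    in_pet = s <= spec.petiole_length_mm
    t0, t1 = np.deg2rad(spec.takeoff_deg), np.deg2rad(spec.droop_deg)
    phi[in_pet] = t0 + (t1 - t0) * s[in_pet] / spec.petiole_length_mm
    phi[~in_pet] = t1
    # tangent (sin φ, 0, cos φ); integrate with the trapezoid rule
    tx, tz = np.sin(phi), np.cos(phi)
    ds = np.diff(s)
    x = np.concatenate([[0.0], np.cumsum(0.5 * (tx[1:] + tx[:-1]) * ds)])
    z = np.concatenate([[0.0], np.cumsum(0.5 * (tz[1:] + tz[:-1]) * ds)])
    pos = np.column_stack([x, np.zeros_like(x), z])
    return s, pos, phi


def _width_law(spec: LeafSpec, s: np.ndarray) -> np.ndarray:
    w = np.full_like(s, float(spec.petiole_width_mm))
    blade = s > spec.petiole_length_mm
    u = (s[blade] - spec.petiole_length_mm) / spec.blade_length_mm
    wb = spec.blade_max_width_mm * np.sin(np.pi * np.clip(u, 0, 1)) ** spec.width_profile_exponent
    w[blade] = np.maximum(wb, 1e-3)
    return w


def _surface_points(spec: LeafSpec, s: np.ndarray, pos: np.ndarray,
                    phi: np.ndarray, v: np.ndarray):
    """Loft the cross-section arcs: grid of shape (len(s), len(v), 3)."""
    # frame: tangent in the x-z plane, side = +y, "up" = side × tangent
    w = _width_law(spec, s)
    tx, tz = np.sin(phi), np.cos(phi)
    up = np.stack([-tz, np.zeros_like(tz), tx], axis=1)   # S × T
    side = np.array([0.0, 1.0, 0.0])
    psi = spec.cross_curvature * np.pi
    grid = np.empty((len(s), len(v), 3))
    is_blade = s > spec.petiole_length_mm
    for i in range(len(s)):
        wi = w[i]
        if psi < 1e-9 or not is_blade[i]:   # petiole stays a flat strip
            off = np.outer(v * wi, side)
        else:
            R = wi / psi
            theta = v * psi
            off = (R * np.sin(theta))[:, None] * side \
                + (R * (1.0 - np.cos(theta)))[:, None] * up[i]
        grid[i] = pos[i] + off
    return grid


def _rotate_z(points: np.ndarray, azimuth_deg: float) -> np.ndarray:
    a = np.deg2rad(azimuth_deg)
    c, s = np.cos(a), np.sin(a)
    R = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    return points @ R.T


def _grid_triangles(ns: int, nv: int) -> np.ndarray:
    idx = np.arange(ns * nv).reshape(ns, nv)
    a = idx[:-1, :-1].ravel()
    b = idx[1:, :-1].ravel()
    c = idx[1:, 1:].ravel()
    d = idx[:-1, 1:].ravel()
    return np.vstack([np.column_stack([a, b, c]),
                      np.column_stack([a, c, d])])


def _sample_on_grid(grid: np.ndarray, density: float,
                    rng: np.random.Generator) -> np.ndarray:
    ns, nv, _ = grid.shape
    V = grid.reshape(-1, 3)
    F = _grid_triangles(ns, nv)
    p0, p1, p2 = V[F[:, 0]], V[F[:, 1]], V[F[:, 2]]
    areas = 0.5 * np.linalg.norm(np.cross(p1 - p0, p2 - p0), axis=1)
    total = areas.sum()
    n_points = max(8, int(round(total * density)))
    choice = rng.choice(len(F), size=n_points, p=areas / total)
    r1 = np.sqrt(rng.random(n_points))
    r2 = rng.random(n_points)
    bary = np.column_stack([1 - r1, r1 * (1 - r2), r1 * r2])
    return (bary[:, 0, None] * p0[choice]
            + bary[:, 1, None] * p1[choice]
            + bary[:, 2, None] * p2[choice])


def _leaf_truth(spec: LeafSpec) -> GroundTruth:
    s, pos, phi = _midrib(spec, _TRUTH_STEP_MM)
    i_base = int(np.searchsorted(s, spec.petiole_length_mm))
    blade_base = pos[i_base]
    tip = pos[-1]
    vec = tip - blade_base
    incl = np.degrees(np.arccos(np.clip(vec[2] / np.linalg.norm(vec), -1, 1)))
    # blade area by fine parametric integration
    sb = s[s >= spec.petiole_length_mm]
    posb = pos[s >= spec.petiole_length_mm]
    phib = phi[s >= spec.petiole_length_mm]
    v = np.linspace(-0.5, 0.5, 101)
    grid = _surface_points(spec, sb, posb, phib, v)
    V = grid.reshape(-1, 3)
    F = _grid_triangles(grid.shape[0], grid.shape[1])
    p0, p1, p2 = V[F[:, 0]], V[F[:, 1]], V[F[:, 2]]
    area = float(0.5 * np.linalg.norm(np.cross(p1 - p0, p2 - p0), axis=1).sum())
    return GroundTruth(
        leaf_length_mm=spec.total_length_mm,
        blade_length_mm=spec.blade_length_mm,
        blade_max_width_mm=spec.blade_max_width_mm,
        blade_area_mm2=area,
        inclination_deg=float(incl),
        petiole_base=pos[0].copy(),
        blade_base=blade_base.copy(),
        blade_tip=tip.copy(),
        width_ratio=spec.blade_max_width_mm / spec.petiole_width_mm,
    )


def _leaf_noiseless_points(spec: LeafSpec, density: float,
                           rng: np.random.Generator) -> np.ndarray:
    step = 1.2
    s, pos, phi = _midrib(spec, step)
    nv = max(9, int(np.ceil(spec.blade_max_width_mm / step)) | 1)
    v = np.linspace(-0.5, 0.5, nv)
    grid = _surface_points(spec, s, pos, phi, v)
    return _sample_on_grid(grid, density, rng)


def make_leaf(spec: LeafSpec, sampling: SamplingSpec | None = None
              ) -> tuple[PointCloud, GroundTruth]:
    """Sample one leaf to a noisy point cloud; return it with its truth.

    Points are drawn uniformly by area on the triangulated parametric
    surface (petiole strip + lofted blade), then perturbed by isotropic
    Gaussian noise. The same seed always yields the same cloud.
    """
    sampling = sampling or SamplingSpec()
    rng = np.random.default_rng(sampling.seed)
    pts = _leaf_noiseless_points(spec, sampling.point_density_per_mm2, rng)
    if sampling.noise_sigma_mm > 0:
        pts = pts + rng.normal(0.0, sampling.noise_sigma_mm, pts.shape)
    pts = _rotate_z(pts, spec.azimuth_deg)
    truth = _leaf_truth(spec)
    for attr in ("petiole_base", "blade_base", "blade_tip"):
        setattr(truth, attr, _rotate_z(getattr(truth, attr)[None, :],
                                       spec.azimuth_deg)[0])
    cloud = PointCloud(pts)
    if sampling.occlusion is not None:
        cloud = degrade(cloud, sampling)
    return cloud, truth


def _body_points(radius_mm: float, density: float,
                 rng: np.random.Generator) -> np.ndarray:
    """Spheroidal beet body: semi-axes (a, a, 0.7a), kept above z = -0.3a."""
    a = radius_mm
    c = 0.7 * a
    area_est = 4.0 * np.pi * ((a * a + 2 * a * c) / 3.0)
    n = max(16, int(area_est * density))
    u = rng.normal(size=(n, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    pts = u * np.array([a, a, c])
    return pts[pts[:, 2] >= -0.3 * a]


def make_plant(leaf_specs: list[LeafSpec], body_radius_mm: float = 60.0,
               sampling: SamplingSpec | None = None
               ) -> tuple[PointCloud, PlantGroundTruth]:
    """Assemble a labeled rosette plant: body (label 0) + leaves (1..N).

    Each leaf's petiole base is attached at the body crown on its azimuth;
    plant height/width ground truth is computed from a dense noiseless
    sampling of the union surface.
    """
    if not leaf_specs:
        raise ParameterError("need at least one leaf")
    sampling = sampling or SamplingSpec()
    rng = np.random.default_rng(sampling.seed)
    a = body_radius_mm
    crown_r = 0.45 * a
    crown_z = 0.65 * a if a > 0 else 0.0

    all_pts, all_labels = [], []
    dense_pts = []
    leaf_truths = []
    if a > 0:
        body = _body_points(a, sampling.point_density_per_mm2, rng)
        all_pts.append(body)
        all_labels.append(np.zeros(len(body), dtype=np.int64))
        dense_pts.append(_body_points(a, max(2.0, sampling.point_density_per_mm2), rng))
    for li, spec in enumerate(leaf_specs, start=1):
        az = np.deg2rad(spec.azimuth_deg)
        attach = np.array([crown_r * np.cos(az), crown_r * np.sin(az), crown_z])
        pts = _leaf_noiseless_points(spec, sampling.point_density_per_mm2, rng)
        dense = _leaf_noiseless_points(spec, max(2.0, sampling.point_density_per_mm2), rng)
        if sampling.noise_sigma_mm > 0:
            pts = pts + rng.normal(0.0, sampling.noise_sigma_mm, pts.shape)
        pts = _rotate_z(pts, spec.azimuth_deg) + attach
        dense = _rotate_z(dense, spec.azimuth_deg) + attach
        truth = _leaf_truth(spec)
        for attr in ("petiole_base", "blade_base", "blade_tip"):
            setattr(truth, attr,
                    _rotate_z(getattr(truth, attr)[None, :], spec.azimuth_deg)[0] + attach)
        leaf_truths.append(truth)
        all_pts.append(pts)
        all_labels.append(np.full(len(pts), li, dtype=np.int64))
        dense_pts.append(dense)

    points = np.vstack(all_pts)
    labels = np.concatenate(all_labels)
    dense = np.vstack(dense_pts)
    height = float(dense[:, 2].max() - dense[:, 2].min())
    uv = dense[:, :2]
    try:
        hull = ConvexHull(uv)
        cand = uv[hull.vertices]
        diff = cand[:, None, :] - cand[None, :, :]
        width = float(np.sqrt((diff ** 2).sum(axis=2)).max())
    except QhullError:
        # (near-)collinear projection: diameter along the principal axis
        centered = uv - uv.mean(axis=0)
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        proj = centered @ vt[0]
        width = float(proj.max() - proj.min())
    cloud = PointCloud(points, labels=labels)
    if sampling.occlusion is not None:
        cloud = degrade(cloud, sampling)
    return cloud, PlantGroundTruth(height, width, leaf_truths)


def degrade(cloud: PointCloud, sampling: SamplingSpec) -> PointCloud:
    """Apply the occlusion model; output points are a subset of the input.

    ``hpr``: hidden-point removal by the spherical-flip criterion — points
    visible from the viewpoint are those whose flipped images lie on the
    convex hull of the flipped cloud plus the viewpoint.
    ``patch``: remove one contiguous patch (the ``dropout_fraction``·N
    nearest neighbors of a randomly chosen center).
    """
    occ = sampling.occlusion
    if occ is None:
        raise ParameterError("SamplingSpec.occlusion is not set")
    rng = np.random.default_rng(sampling.seed + 77003)
    pts = cloud.points
    if occ.mode == "patch":
        n_drop = int(round(occ.dropout_fraction * len(pts)))
        if n_drop == 0:
            return cloud.select(np.arange(len(pts)))
        center = pts[rng.integers(len(pts))]
        order = np.argsort(np.linalg.norm(pts - center, axis=1))
        keep = np.ones(len(pts), dtype=bool)
        keep[order[:n_drop]] = False
        return cloud.select(keep)
    # spherical flip HPR (Katz, Tal & Basri)
    vp = np.asarray(occ.viewpoint, dtype=np.float64)
    rel = pts - vp
    dist = np.linalg.norm(rel, axis=1)
    radius = dist.max() * 100.0
    flipped = pts + 2.0 * (radius - dist)[:, None] * (-rel) / np.maximum(dist, 1e-12)[:, None]
    hull = ConvexHull(np.vstack([flipped, vp[None, :]]))
    visible = np.unique(hull.vertices)
    visible = visible[visible < len(pts)]
    keep = np.zeros(len(pts), dtype=bool)
    keep[visible] = True
    return cloud.select(keep)


def random_leaf_spec(rng: np.random.Generator) -> LeafSpec:
    """Draw a leaf within the reference model's plausible trait ranges
    (leaf lengths ~140–320 mm, blade widths ~25–100 mm)."""
    petiole = rng.uniform(50.0, 130.0)
    blade = rng.uniform(70.0, 220.0)
    width = rng.uniform(28.0, min(100.0, 0.8 * blade))
    return LeafSpec(
        petiole_length_mm=petiole,
        petiole_width_mm=rng.uniform(5.0, min(9.0, width / 3.5)),
        blade_length_mm=blade,
        blade_max_width_mm=width,
        width_profile_exponent=rng.uniform(0.05, 0.12),
        droop_deg=rng.uniform(25.0, 110.0),
        azimuth_deg=rng.uniform(0.0, 360.0),
        cross_curvature=rng.uniform(0.0, 0.5),
    )
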