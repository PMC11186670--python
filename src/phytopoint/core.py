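"""Core containers: point clouds, triangle meshes, rigid transforms.

All coordinates are millimetres in a z-up frame (gravity along −z).
Reporting layers convert to cm / cm² / cm³.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateGeometryError, EmptyInputError, ParameterError

__all__ = [
    "PointCloud",
    "TriangleMesh",
    "RigidTransform",
    "PreprocessConfig",
]

_NORMAL_TOL = 1e-6


@dataclass
class PointCloud:
    """N points (mm, z-up) with optional unit normals and leaf labels.

    Parameters
    ----------
    points : (N, 3) float array
        Coordinates in millimetres. Must be finite.
    normals : (N, 3) float array, optional
        Unit normals, one per point. Rows may be NaN where a normal could
        not be estimated (isolated points); all non-NaN rows must have
        unit length within 1e-6.
    labels : (N,) int array, optional
        Per-point leaf id; 0 means beet body / unassigned.
    """

    points: np.ndarray
    normals: np.ndarray | None = None
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ParameterError(
                f"points must be (N, 3), got {self.points.shape}"
            )
        if not np.all(np.isfinite(self.points)):
            raise ParameterError("points contain non-finite coordinates")
        if self.normals is not None:
            self.normals = np.asarray(self.normals, dtype=np.float64)
            if self.normals.shape != self.points.shape:
                raise ParameterError("normals shape must match points")
            norms = np.linalg.norm(self.normals, axis=1)
            valid = ~np.isnan(norms)
            if np.any(np.abs(norms[valid] - 1.0) > _NORMAL_TOL):
                raise ParameterError("normals must be unit length")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.int64)
            if self.labels.shape != (len(self.points),):
                raise ParameterError("labels length must match point count")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def has_normals(self) -> bool:
        return self.normals is not None

    def select(self, index: np.ndarray) -> "PointCloud":
        """Subset cloud by boolean mask or integer index, keeping order."""
        return PointCloud(
            self.points[index],
            None if self.normals is None else self.normals[index],
            None if self.labels is None else self.labels[index],
        )

    def transformed(self, transform: "RigidTransform") -> "PointCloud":
        pts = transform.apply(self.points)
        nrm = None
        if self.normals is not None:
            nrm = self.normals @ transform.rotation.T
        return PointCloud(pts, nrm, None if self.labels is None else self.labels.copy())


@dataclass
class TriangleMesh:
    """Triangle surface: (V, 3) vertices in mm, (F, 3) int vertex indices."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.faces.size == 0:
            self.faces = self.faces.reshape(0, 3)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ParameterError("vertices must be (V, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ParameterError("faces must be (F, 3)")
        if len(self.faces):
            if self.faces.min() < 0 or self.faces.max() >= len(self.vertices):
                raise ParameterError("face index out of range")
            a, b, c = self.faces.T
            if np.any((a == b) | (b == c) | (a == c)):
                raise ParameterError("face references the same vertex twice")

    def __len__(self) -> int:
        return len(self.faces)


@dataclass
class RigidTransform:
    """Proper rigid motion x ↦ R x + t (R orthonormal, det +1)."""

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    _TOL = 1e-8

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=np.float64)
        self.translation = np.asarray(self.translation, dtype=np.float64).reshape(3)
        R = self.rotation
        if R.shape != (3, 3):
            raise ParameterError("rotation must be 3x3")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-7):
            raise ParameterError("rotation is not orthonormal")
        if np.linalg.det(R) < 0:
            raise ParameterError("rotation has determinant -1 (reflection)")

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return self ∘ other (apply ``other`` first)."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform()

    @staticmethod
    def about_z(angle_deg: float, translation=(0.0, 0.0, 0.0)) -> "RigidTransform":
        a = np.deg2rad(angle_deg)
        c, s = np.cos(a), np.sin(a)
        R = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
        return RigidTransform(R, np.asarray(translation, dtype=np.float64))

    @staticmethod
    def random_small(rng: np.random.Generator, max_angle_deg: float = 10.0,
                     max_translation_mm: float = 20.0) -> "RigidTransform":
        """Random rotation (axis uniform, angle ≤ max) + bounded translation."""
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        angle = np.deg2rad(rng.uniform(0.0, max_angle_deg))
        K = np.array([
            [0, -axis[2], axis[1]],
            [axis[2], 0, -axis[0]],
            [-axis[1], axis[0], 0],
        ])
        R = np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)
        t = rng.uniform(-max_translation_mm, max_translation_mm, size=3)
        return RigidTransform(R, t)


@dataclass
class PreprocessConfig:
    """Defaults for the standard cleanup chain.

    voxel_size_mm
        Grid pitch of the voxel filter (the sensor-evaluation protocol
        subsamples to 5 mm).
    outlier_neighbors, outlier_std_ratio
        k and σ-ratio of the statistical outlier filter.
    normal_radius_mm
        Neighborhood radius for PCA normal estimation.
    """

    voxel_size_mm: float = 5.0
    outlier_neighbors: int = 20
    outlier_std_ratio: float = 2.0
    normal_radius_mm: float = 5.0

    def __post_init__(self) -> None:
        if (
            self.voxel_size_mm <= 0
            or self.outlier_neighbors <= 0
            or self.outlier_std_ratio <= 0
            or self.normal_radius_mm <= 0
        ):
            raise ParameterError("all PreprocessConfig fields must be positive")


def require_nonempty(cloud: PointCloud, what: str = "cloud") -> None:
    if len(cloud) == 0:
        raise EmptyInputError(f"{what} is empty")


def require_min_points(cloud: PointCloud, n: int, what: str = "operation") -> None:
    if len(cloud) < n:
        raise DegenerateGeometryError(f"{what} needs at least {n} points, got {len(cloud)}")
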