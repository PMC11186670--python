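"""Plant-scale morphological traits.

Height (z-extent), width (largest xy-projected pairwise distance), convex
hull volume/area, projected canopy area, and — when a leaf segmentation is
available — total leaf area and leaf count. Internally mm; the report
layer converts to the cm scale of field practice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .core import PointCloud, require_nonempty
from .errors import EmptyInputError
from .surface import convex_hull, projected_area

__all__ = ["PlantTraits", "plant_height", "plant_width", "extract_plant_traits"]


@dataclass
class PlantTraits:
    """Plant-scale parameters (mm / mm² / mm³).

    ``status`` maps field name → "ok" or an error string for fields that
    could not be computed (partial results are allowed).
    """

    height_mm: float = np.nan
    width_mm: float = np.nan
    hull_volume_mm3: float = np.nan
    hull_area_mm2: float = np.nan
    projected_area_mm2: float = np.nan
    total_leaf_area_mm2: float | None = None
    leaf_count: int | None = None
    status: dict = field(default_factory=dict)

    def as_cm_dict(self) -> dict:
        """Report in cm / cm² / cm³, rounded to 1 decimal (table scale)."""
        out = {
            "height_cm": round(self.height_mm / 10.0, 1),
            "width_cm": round(self.width_mm / 10.0, 1),
            "hull_volume_cm3": round(self.hull_volume_mm3 / 1000.0, 1),
            "hull_area_cm2": round(self.hull_area_mm2 / 100.0, 1),
            "projected_area_cm2": round(self.projected_area_mm2 / 100.0, 1),
        }
        if self.total_leaf_area_mm2 is not None:
            out["total_leaf_area_cm2"] = round(self.total_leaf_area_mm2 / 100.0, 1)
        if self.leaf_count is not None:
            out["leaf_count"] = self.leaf_count
        return out


def plant_height(cloud: PointCloud) -> float:
    """Height (mm): difference between highest and lowest point (z-extent)."""
    require_nonempty(cloud)
    z = cloud.points[:, 2]
    return float(z.max() - z.min())


def plant_width(cloud: PointCloud) -> float:
    """Width (mm): largest pairwise Euclidean distance of the xy-projection.

    Computed exactly via the 2D convex hull (the diameter is attained at
    hull vertices) followed by a pairwise scan over the hull vertices, so
    the result equals the brute-force O(N²) answer.
    """
    require_nonempty(cloud)
    if len(cloud) == 1:
        import logging
        logging.getLogger(__name__).warning("plant_width of a single point is 0")
        return 0.0
    uv = cloud.points[:, :2]
    try:
        hull = ConvexHull(uv)
        cand = uv[hull.vertices]
    except QhullError:
        # collinear projection: the diameter lies along the principal axis
        centered = uv - uv.mean(axis=0)
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        proj = centered @ vt[0]
        return float(proj.max() - proj.min())
    diff = cand[:, None, :] - cand[None, :, :]
    return float(np.sqrt((diff ** 2).sum(axis=2)).max())


def extract_plant_traits(cloud: PointCloud,
                         leaf_clouds: list[PointCloud] | None = None,
                         alpha_mm: float | None = None,
                         leaf_config=None,
                         meshing=None) -> PlantTraits:
    """Assemble all plant-scale traits; per-field failures are recorded.

    Parameters
    ----------
    cloud : PointCloud
        Whole-plant cloud.
    leaf_clouds : list of PointCloud, optional
        Pre-segmented single leaves. When given, total_leaf_area_mm2 is
        the sum of per-leaf blade areas (see :mod:`phytopoint.leaf`) and
        leaf_count is their number. Segmentation is manual upstream, as
        in reference-model practice.
    alpha_mm : float, optional
        Alpha-shape scale for the projected area.
    """
    require_nonempty(cloud)
    traits = PlantTraits()

    def attempt(name, fn):
        try:
            value = fn()
            traits.status[name] = "ok"
            return value
        except Exception as exc:   # record, keep going
            traits.status[name] = f"{type(exc).__name__}: {exc}"
            return np.nan

    traits.height_mm = attempt("height_mm", lambda: plant_height(cloud))
    traits.width_mm = attempt("width_mm", lambda: plant_width(cloud))

    def hull_metrics():
        h = convex_hull(cloud)
        return h

    h = attempt("hull", hull_metrics)
    if traits.status["hull"] == "ok":
        traits.hull_volume_mm3 = h.volume_mm3
        traits.hull_area_mm2 = h.area_mm2
        traits.status["hull_volume_mm3"] = traits.status["hull_area_mm2"] = "ok"
    traits.projected_area_mm2 = attempt(
        "projected_area_mm2", lambda: projected_area(cloud, alpha_mm))

    if leaf_clouds is not None:
        from .leaf import extract_leaf_traits

        traits.leaf_count = len(leaf_clouds)
        total = 0.0
        ok = True
        for i, leaf in enumerate(leaf_clouds):
            try:
                lt = extract_leaf_traits(leaf, config=leaf_config, meshing=meshing)
                if lt.blade_area_mm2 is None or np.isnan(lt.blade_area_mm2):
                    raise EmptyInputError("no blade area")
                total += lt.blade_area_mm2
            except Exception as exc:
                traits.status[f"leaf_{i}_area"] = f"{type(exc).__name__}: {exc}"
                ok = False
        traits.total_leaf_area_mm2 = total if ok else (total or None)
        traits.status["total_leaf_area_mm2"] = "ok" if ok else "partial"
    return traits
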