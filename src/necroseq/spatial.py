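"""Spatial quantification of tissue annotations and detections.

Mirrors a digital-pathology workflow: GeoJSON scenes carry a tumor-border
polygon, necrotic-zone polygons, and point detections (e.g. RNA in-situ
hybridization spots) in a shared Cartesian frame in micrometres (y-down
image convention). The module computes detection distances to the nearest
necrotic interface and tumor border, perinecrotic enrichment profiles with
a permutation test, necrosis area fractions with a high/low rule, and
vessel morphometrics from label masks.
"""
from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from scipy.ndimage import distance_transform_edt
from shapely.geometry import Point, Polygon, mapping, shape
from skimage.measure import regionprops

logger = logging.getLogger(__name__)

NO_INTERFACE = math.nan  # sentinel distance when a scene has no necrotic zones
NECROSIS_HIGH_CUTOFF = 15.0  # percent of tumor area; strictly above is "high"


# ---------------------------------------------------------------------------
# scene container


@dataclass
class AnnotationScene:
    """Tumor border + necrotic zones + point detections, all in um."""

    tumor_border: Polygon
    necrotic_zones: list[Polygon]
    detections: pd.DataFrame  # columns x, y, cls
    pixel_size: float = 2.0

    def __post_init__(self) -> None:
        if not self.tumor_border.is_valid:
            raise ValueError("tumor border polygon is not simple")
        for z in self.necrotic_zones:
            if not z.is_valid:
                raise ValueError("necrotic polygon is not simple")
            if not self.tumor_border.covers(z):
                raise ValueError("necrotic zone not contained in tumor border")
        xy = self.detections[["x", "y"]].to_numpy(float)
        if xy.size and not np.isfinite(xy).all():
            raise ValueError("detection coordinates must be finite")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def necrosis_union(self):
        return shapely.union_all(self.necrotic_zones) if self.necrotic_zones else None

    def viable_region(self):
        u = self.necrosis_union
        return self.tumor_border if u is None else self.tumor_border.difference(u)

    # -- GeoJSON interchange (QuPath-compatible polygons/points) ------------

    def to_geojson(self, path: str | Path) -> None:
        features = [
            {
                "type": "Feature",
                "geometry": mapping(self.tumor_border),
                "properties": {"role": "tumor_border"},
            }
        ]
        for z in self.necrotic_zones:
            features.append(
                {"type": "Feature", "geometry": mapping(z), "properties": {"role": "necrosis"}}
            )
        for _, row in self.detections.iterrows():
            features.append(
                {
                    "type": "Feature",
                    "geometry": mapping(Point(row["x"], row["y"])),
                    "properties": {"class": row["cls"]},
                }
            )
        doc = {
            "type": "FeatureCollection",
            "features": features,
            "properties": {"pixel_size_um": self.pixel_size},
        }
        Path(path).write_text(json.dumps(doc, indent=1))

    @classmethod
    def from_geojson(cls, path: str | Path) -> "AnnotationScene":
        doc = json.loads(Path(path).read_text())
        tumor = None
        zones: list[Polygon] = []
        pts: list[tuple[float, float, str]] = []
        for feat in doc["features"]:
            geom = shape(feat["geometry"])
            props = feat.get("properties", {}) or {}
            if props.get("role") == "tumor_border":
                tumor = geom
            elif props.get("role") == "necrosis":
                zones.append(geom)
            elif geom.geom_type == "Point":
                pts.append((geom.x, geom.y, props.get("class", "detection")))
        if tumor is None:
            raise ValueError(f"{path}: no polygon tagged role=tumor_border")
        detections = pd.DataFrame(pts, columns=["x", "y", "cls"])
        return cls(tumor, zones, detections, float(doc.get("properties", {}).get("pixel_size_um", 2.0)))

    # -- rasterization -------------------------------------------------------

    def rasterize(self, pixel_size: float | None = None) -> dict:
        """Label the tumor bounding box on a pixel grid.

        Returns origin, pixel centers and boolean masks for tumor, necrosis
        and viable (tumor minus necrosis) tissue, plus the distance (um) of
        each pixel center to the necrotic interface (Euclidean distance
        transform; NaN-free zero array when there is no necrosis).
        """
        px = self.pixel_size if pixel_size is None else pixel_size
        minx, miny, maxx, maxy = self.tumor_border.bounds
        xs = np.arange(minx + px / 2, maxx, px)
        ys = np.arange(miny + px / 2, maxy, px)
        gx, gy = np.meshgrid(xs, ys)
        tumor_mask = shapely.contains_xy(self.tumor_border, gx.ravel(), gy.ravel()).reshape(gx.shape)
        u = self.necrosis_union
        if u is None:
            necrotic_mask = np.zeros_like(tumor_mask)
            dist = np.full(tumor_mask.shape, np.nan)
        else:
            necrotic_mask = shapely.contains_xy(u, gx.ravel(), gy.ravel()).reshape(gx.shape)
            necrotic_mask &= tumor_mask
            if necrotic_mask.any():
                dist = distance_transform_edt(~necrotic_mask) * px
            else:
                dist = np.full(tumor_mask.shape, np.nan)
        return {
            "pixel_size": px,
            "x": xs,
            "y": ys,
            "tumor_mask": tumor_mask,
            "necrotic_mask": necrotic_mask,
            "viable_mask": tumor_mask & ~necrotic_mask,
            "distance_to_necrosis": dist,
        }


# ---------------------------------------------------------------------------
# distances and annotation


def distance_to_boundary(point, polygon_set) -> float:
    """Unsigned minimum Euclidean distance from a point to any polygon
    boundary in the set. An empty set yields the ``NO_INTERFACE`` sentinel
    (NaN), never 0; inside/outside is reported separately by
    :func:`annotate_detections`.
    """
    polys = list(polygon_set)
    if not polys:
        return NO_INTERFACE
    p = Point(point)
    return min(poly.boundary.distance(p) for poly in polys)


def annotate_detections(scene: AnnotationScene) -> pd.DataFrame:
    """One row per detection with distances to the necrotic interface and
    tumor border and a region label (necrotic / viable / outside).

    Points exactly on a boundary count as inside (deterministic tie rule).
    """
    det = scene.detections
    pts = shapely.points(det[["x", "y"]].to_numpy(float)) if len(det) else np.array([], dtype=object)
    u = scene.necrosis_union
    if len(det) == 0:
        return det.assign(d_necrosis=[], d_tumor_border=[], region=[])
    d_border = shapely.distance(pts, scene.tumor_border.boundary)
    if u is None:
        d_necrosis = np.full(len(det), NO_INTERFACE)
        in_necrosis = np.zeros(len(det), dtype=bool)
    else:
        d_necrosis = shapely.distance(pts, u.boundary)
        in_necrosis = shapely.covers(u, pts)
    in_tumor = shapely.covers(scene.tumor_border, pts)
    region = np.where(in_necrosis, "necrotic", np.where(in_tumor, "viable", "outside"))
    return det.assign(d_necrosis=d_necrosis, d_tumor_border=d_border, region=region)


# ---------------------------------------------------------------------------
# perinecrotic profile


@dataclass
class DistanceProfile:
    """Detection density in distance bands from the necrotic interface."""

    bin_edges: np.ndarray  # um, len = n_bins + 1
    counts: np.ndarray  # detections per band
    areas: np.ndarray  # viable area per band, um^2
    densities: np.ndarray  # counts / areas
    enrichment: float  # density(first band) / overall density
    p_value: float | None  # permutation p (uniform null over viable area)
    n_viable_detections: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_start_um": self.bin_edges[:-1],
                "bin_end_um": self.bin_edges[1:],
                "count": self.counts,
                "viable_area_um2": self.areas,
                "density_per_um2": self.densities,
            }
        )


def perinecrotic_profile(
    annotated: pd.DataFrame,
    scene: AnnotationScene,
    bin_width_um: float = 100.0,
    n_permutations: int = 999,
    seed: int = 0,
    pixel_size: float | None = None,
) -> DistanceProfile:
    """Distance-banded detection density relative to the necrotic interface.

    Band viable areas come from rasterization at ``pixel_size``; the
    enrichment statistic is the first-band density over the overall viable
    density, and its p-value compares against ``n_permutations`` uniform
    resamplings of detection locations over the viable area (one-sided,
    add-one smoothed).
    """
    if not scene.necrotic_zones:
        raise ValueError("perinecrotic profile requires at least one necrotic zone")
    viable = annotated[annotated["region"] == "viable"]
    if len(viable) < 20:
        raise ValueError(
            f"need >= 20 viable detections for a stable profile, got {len(viable)}"
        )
    raster = scene.rasterize(pixel_size)
    px2 = raster["pixel_size"] ** 2
    pix_d = raster["distance_to_necrosis"][raster["viable_mask"]]
    if pix_d.size == 0:
        raise ValueError("viable area rasterized to zero pixels; decrease pixel_size")
    d_obs = viable["d_necrosis"].to_numpy(float)
    dmax = max(float(d_obs.max()), float(pix_d.max()))
    n_bins = max(1, int(math.ceil(dmax / bin_width_um)))
    edges = np.linspace(0.0, n_bins * bin_width_um, n_bins + 1)
    counts, _ = np.histogram(np.clip(d_obs, 0, edges[-1] - 1e-9), bins=edges)
    pix_counts, _ = np.histogram(np.clip(pix_d, 0, edges[-1] - 1e-9), bins=edges)
    areas = pix_counts * px2
    with np.errstate(divide="ignore", invalid="ignore"):
        densities = np.where(areas > 0, counts / areas, np.nan)
    total_area = areas.sum()
    n = len(viable)
    overall = n / total_area
    enrichment = float(densities[0] / overall)
    p_value: float | None = None
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        first_band = pix_d < bin_width_um
        # uniform over viable area == uniform over viable pixels
        draws = rng.choice(first_band.astype(np.int8), size=(n_permutations, n), replace=True)
        c0 = draws.sum(axis=1)
        stat = (c0 / areas[0]) / overall
        p_value = float((1 + int((stat >= enrichment).sum())) / (n_permutations + 1))
    return DistanceProfile(edges, counts, areas, densities, enrichment, p_value, n)


# ---------------------------------------------------------------------------
# necrosis area and vessels


def necrosis_area_fraction(scene: AnnotationScene) -> float:
    """Percent of the tumor cross-section occupied by necrotic zones."""
    area_t = scene.tumor_border.area
    if area_t <= 0:
        raise ValueError("degenerate tumor polygon (zero area)")
    u = scene.necrosis_union
    return 0.0 if u is None else 100.0 * u.area / area_t


def necrosis_area_fraction_from_mask(
    label_mask: np.ndarray, viable_label: int = 1, necrotic_label: int = 2
) -> float:
    """Mask route: percent of labeled tumor pixels that are necrotic."""
    n_viable = int((label_mask == viable_label).sum())
    n_necrotic = int((label_mask == necrotic_label).sum())
    total = n_viable + n_necrotic
    if total == 0:
        raise ValueError("mask contains no tumor pixels")
    return 100.0 * n_necrotic / total


def classify_necrosis_level(percent: float) -> str:
    """High/low necrosis rule: strictly more than 15% by area is high."""
    if not 0.0 <= percent <= 100.0:
        raise ValueError(f"necrosis percent {percent} outside [0, 100]")
    return "high" if percent > NECROSIS_HIGH_CUTOFF else "low"


@dataclass
class VesselStats:
    n_total: int
    n_dilated: int
    dilated_density_per_mm2: float
    diameters_um: np.ndarray = field(default_factory=lambda: np.array([]))


def vessel_morphometrics(
    label_mask: np.ndarray,
    pixel_size: float,
    dilated_diameter_threshold_um: float = 50.0,
    viable_area_um2: float | None = None,
) -> VesselStats:
    """Per-vessel equivalent diameters from a label mask.

    Equivalent diameter = 2*sqrt(area/pi); a vessel is dilated iff its
    diameter is at least the threshold. Density is dilated vessels per mm^2
    of viable area when that area is supplied.
    """
    if dilated_diameter_threshold_um <= 0:
        raise ValueError("dilated diameter threshold must be positive")
    mask = np.asarray(label_mask)
    if mask.min() < 0:
        raise ValueError("labels must be positive integers")
    props = regionprops(mask.astype(int))
    if not props:
        warnings.warn("empty vessel mask; returning zero counts", stacklevel=2)
        return VesselStats(0, 0, 0.0 if viable_area_um2 else math.nan)
    areas = np.array([p.area for p in props], float) * pixel_size**2
    diameters = 2.0 * np.sqrt(areas / math.pi)
    n_dilated = int((diameters >= dilated_diameter_threshold_um).sum())
    if viable_area_um2:
        density = n_dilated / (viable_area_um2 / 1e6)
    else:
        density = math.nan
    return VesselStats(len(props), n_dilated, density, diameters)
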