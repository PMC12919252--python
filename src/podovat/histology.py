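"""Glomerular tuft and podocyte-nucleus annotation handling.

Reads polygon annotations (GeoJSON FeatureCollection dialect, as
exported by common digital-pathology viewers), converts pixel
coordinates to μm, assigns WT1-positive nucleus detections to the
nonsclerotic tuft containing their centroid, and aggregates everything
into a per-subject :class:`SlideMorphometry` that feeds the
stereological formulas.

Annotation conventions
----------------------
Each feature is a GeoJSON ``Polygon`` whose ``properties`` carry a
``classification`` of ``"tuft"``, ``"tuft_sclerotic"`` or ``"nucleus"``
(either a bare string or the QuPath-style ``{"name": ...}`` mapping).
Coordinates are 0-based pixel centers; they are converted to μm once at
load time by multiplying with ``pixel_size``.

Sclerotic tufts are counted for the sclerosis percentage but excluded
from all area statistics and from nucleus assignment; the apparent
nuclear caliper diameter is the equivalent-area circular diameter of the
nucleus polygon.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from shapely.geometry import Polygon
from shapely.strtree import STRtree

logger = logging.getLogger(__name__)

__all__ = [
    "GlomerulusProfile",
    "NucleusDetection",
    "SlideMorphometry",
    "UnusableSlideError",
    "load_annotations",
    "write_annotations",
    "polygon_area",
    "equivalent_diameter",
    "assign_nuclei",
    "summarize_slide",
]

CLASS_TUFT = "tuft"
CLASS_TUFT_SCLEROTIC = "tuft_sclerotic"
CLASS_NUCLEUS = "nucleus"


class UnusableSlideError(ValueError):
    """Raised when a slide has no usable (nonsclerotic) glomeruli."""


@dataclass(frozen=True)
class GlomerulusProfile:
    """A glomerular tuft profile: closed ring in μm plus a sclerosis flag."""

    polygon: Polygon
    sclerotic: bool = False

    @property
    def area(self) -> float:
        """Shoelace (unsigned) profile area in μm²."""
        return self.polygon.area


@dataclass(frozen=True)
class NucleusDetection:
    """A WT1-positive nucleus polygon in μm coordinates.

    ``host_glomerulus`` is the index of the containing nonsclerotic
    tuft (set by :func:`assign_nuclei`) or ``None`` if unassigned.
    """

    polygon: Polygon
    host_glomerulus: Optional[int] = None

    @property
    def area(self) -> float:
        return self.polygon.area

    @property
    def apparent_d(self) -> float:
        """Equivalent-area circular diameter, ``2*sqrt(area/pi)`` (μm)."""
        return equivalent_diameter(self.polygon.area)


@dataclass(frozen=True)
class SlideMorphometry:
    """Per-subject slide summary consumed by the stereology module."""

    subject_id: str
    n_glomeruli_nonsclerotic: int
    n_glomeruli_sclerotic: int
    percent_sclerotic: float
    mean_profile_area: float  # μm²
    total_tuft_area: float  # μm²
    n_nuclei: int
    mean_apparent_d: float  # μm


def polygon_area(ring: Sequence[Sequence[float]]) -> float:
    """Unsigned shoelace area of a closed planar ring (μm²).

    Orientation-independent; raises on rings with fewer than three
    distinct vertices.
    """
    coords = np.asarray(ring, dtype=float)
    if coords.ndim != 2 or coords.shape[0] < 3 or coords.shape[1] != 2:
        raise ValueError("ring must contain at least 3 (x, y) vertices")
    return Polygon(coords).area


def equivalent_diameter(area: float) -> float:
    """Diameter of the circle with the given area: ``2*sqrt(area/pi)``."""
    if area < 0:
        raise ValueError(f"area must be >= 0, got {area}")
    return 2.0 * math.sqrt(area / math.pi)


def _classification_name(props: dict) -> Optional[str]:
    cls = (props or {}).get("classification")
    if isinstance(cls, dict):
        cls = cls.get("name")
    return cls


def load_annotations(
    path: str | Path, pixel_size: float
) -> tuple[list[GlomerulusProfile], list[NucleusDetection]]:
    """Load tuft and nucleus polygons from a GeoJSON annotation file.

    Parameters
    ----------
    path:
        GeoJSON FeatureCollection with Polygon features classified as
        ``tuft``, ``tuft_sclerotic`` or ``nucleus``.
    pixel_size:
        μm per pixel; coordinates are scaled to μm at load.

    Raises
    ------
    ValueError
        On unparseable files, missing/unknown classification labels or
        non-simple rings, naming the offending feature index.
    """
    if not pixel_size > 0:
        raise ValueError(f"pixel_size must be > 0, got {pixel_size}")
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"{path} is not valid annotation JSON: {exc}") from exc
    features = payload.get("features")
    if payload.get("type") != "FeatureCollection" or features is None:
        raise ValueError(f"{path} is not a FeatureCollection")

    profiles: list[GlomerulusProfile] = []
    nuclei: list[NucleusDetection] = []
    for i, feature in enumerate(features):
        geometry = feature.get("geometry") or {}
        if geometry.get("type") != "Polygon":
            raise ValueError(f"feature {i}: unsupported geometry {geometry.get('type')!r}")
        cls = _classification_name(feature.get("properties"))
        if cls is None:
            raise ValueError(f"feature {i}: missing classification label")
        exterior = np.asarray(geometry["coordinates"][0], dtype=float) * pixel_size
        poly = Polygon(exterior)
        if not poly.is_valid or poly.area == 0:
            raise ValueError(f"feature {i}: ring is not simple")
        if cls in (CLASS_TUFT, CLASS_TUFT_SCLEROTIC):
            profiles.append(GlomerulusProfile(poly, sclerotic=cls == CLASS_TUFT_SCLEROTIC))
        elif cls == CLASS_NUCLEUS:
            nuclei.append(NucleusDetection(poly))
        else:
            raise ValueError(f"feature {i}: unknown classification {cls!r}")
    return profiles, nuclei


def write_annotations(
    path: str | Path,
    profiles: Sequence[GlomerulusProfile],
    nuclei: Sequence[NucleusDetection],
    pixel_size: float,
) -> None:
    """Write tufts and nuclei back to a GeoJSON FeatureCollection.

    Coordinates are converted from μm back to pixels (μm / pixel_size);
    round-trips with :func:`load_annotations` preserve areas.
    """
    if not pixel_size > 0:
        raise ValueError(f"pixel_size must be > 0, got {pixel_size}")

    def feature(poly: Polygon, cls: str) -> dict:
        ring = [[x / pixel_size, y / pixel_size] for x, y in poly.exterior.coords]
        return {
            "type": "Feature",
            "geometry": {"type": "Polygon", "coordinates": [ring]},
            "properties": {"classification": cls},
        }

    features = [
        feature(p.polygon, CLASS_TUFT_SCLEROTIC if p.sclerotic else CLASS_TUFT)
        for p in profiles
    ]
    features += [feature(n.polygon, CLASS_NUCLEUS) for n in nuclei]
    Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": features}))


def assign_nuclei(
    profiles: Sequence[GlomerulusProfile], nuclei: Sequence[NucleusDetection]
) -> list[NucleusDetection]:
    """Assign each nucleus to the nonsclerotic tuft covering its centroid.

    A centroid on a tuft boundary counts as inside.  When overlapping
    tufts both cover a centroid, the largest-area tuft wins (logged).
    Nuclei outside all nonsclerotic tufts stay unassigned and are
    excluded from downstream counts.
    """
    candidates = [(i, p) for i, p in enumerate(profiles) if not p.sclerotic]
    if not candidates:
        return [replace(n, host_glomerulus=None) for n in nuclei]
    tree = STRtree([p.polygon for _, p in candidates])
    assigned: list[NucleusDetection] = []
    for nucleus in nuclei:
        centroid = nucleus.polygon.centroid
        hits = [
            candidates[j]
            for j in tree.query(centroid)
            if candidates[j][1].polygon.covers(centroid)
        ]
        if not hits:
            assigned.append(replace(nucleus, host_glomerulus=None))
            continue
        if len(hits) > 1:
            logger.warning(
                "nucleus centroid covered by %d tufts; keeping largest", len(hits)
            )
            hits.sort(key=lambda item: item[1].area, reverse=True)
        assigned.append(replace(nucleus, host_glomerulus=hits[0][0]))
    return assigned


def summarize_slide(
    profiles: Sequence[GlomerulusProfile],
    nuclei: Sequence[NucleusDetection],
    subject_id: str,
) -> SlideMorphometry:
    """Aggregate profiles and assigned nuclei into a slide summary.

    Sclerotic tufts enter only the sclerosis percentage; area statistics
    and the nucleus count use nonsclerotic tufts and assigned nuclei.
    Raises :class:`UnusableSlideError` when no nonsclerotic tuft exists.
    """
    non = [p for p in profiles if not p.sclerotic]
    n_scl = len(profiles) - len(non)
    if not non:
        raise UnusableSlideError(
            f"subject {subject_id}: no nonsclerotic glomeruli on slide"
        )
    areas = np.array([p.area for p in non])
    assigned = [n for n in nuclei if n.host_glomerulus is not None]
    mean_d = float(np.mean([n.apparent_d for n in assigned])) if assigned else 0.0
    return SlideMorphometry(
        subject_id=subject_id,
        n_glomeruli_nonsclerotic=len(non),
        n_glomeruli_sclerotic=n_scl,
        percent_sclerotic=100.0 * n_scl / len(profiles),
        mean_profile_area=float(areas.mean()),
        total_tuft_area=float(areas.sum()),
        n_nuclei=len(assigned),
        mean_apparent_d=mean_d,
    )
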