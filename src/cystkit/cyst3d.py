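"""3D cyst quantification from per-well image stacks.

Primary human ADPKD cyst cultures grown in Matrigel are imaged as a series of
focal planes per well (by default 28 planes, 150 µm apart).  Each plane is
segmented independently; detected objects are described by circular-shape
statistics (mean centroid-to-boundary radius, its coefficient of variation,
and moment-ellipse eccentricity), filtered to remove non-cyst objects, and
linked across consecutive planes so that a cyst spanning several planes is
counted once.  Assuming cysts are spherical, each linked cyst's volume is
4/3·π·r³ with r the mean radius of its largest cross-section.

The whole pipeline is deterministic: no random number generation anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage import filters, measure

__all__ = [
    "ImageStack",
    "SegmentedObject",
    "SegmentationConfig",
    "ObjectFilterConfig",
    "LinkConfig",
    "CystTrack",
    "WellSummary",
    "segment_slice",
    "filter_objects",
    "link_stack",
    "measure_cyst",
    "quantify_well",
    "cyst_index",
    "sphere_volume",
]


def sphere_volume(radius: float) -> float:
    """Volume of a sphere, 4/3·π·r³."""
    return 4.0 / 3.0 * np.pi * float(radius) ** 3


@dataclass
class ImageStack:
    """Ordered series of 2D grayscale focal planes from one well.

    Parameters
    ----------
    slices : (depth, height, width) float array
        Focal planes in ascending acquisition order.
    pixel_size_um : float, optional
        In-plane pixel edge length; volumes are reported in µm³ when given,
        otherwise in px³.
    slice_spacing_um : float
        Axial distance between consecutive planes (default 150).
    """

    slices: np.ndarray
    pixel_size_um: Optional[float] = None
    slice_spacing_um: float = 150.0

    def __post_init__(self) -> None:
        self.slices = np.asarray(self.slices, dtype=float)
        if self.slices.ndim != 3 or self.slices.shape[0] < 1:
            raise ValueError("stack must be a (depth, height, width) array with >= 1 slice")

    @property
    def depth(self) -> int:
        return self.slices.shape[0]

    @property
    def image_shape(self) -> tuple[int, int]:
        return self.slices.shape[1], self.slices.shape[2]


@dataclass
class SegmentedObject:
    """One labeled connected component in one focal plane.

    ``radius_mean_px``/``radius_cv`` are computed over the distances from the
    centroid to the 8-connected object border; ``eccentricity`` is that of the
    second-central-moment ellipse, sqrt(1 − (b/a)²), 0 for a perfect circle.
    """

    slice_index: int
    label: int
    centroid: tuple[float, float]  # (row, col), 0-based
    radius_mean_px: float
    radius_cv: float
    eccentricity: float
    area_px: int
    touches_border: bool = False

    def __post_init__(self) -> None:
        if self.radius_mean_px <= 0:
            raise ValueError("radius_mean_px must be > 0")
        if self.radius_cv < 0:
            raise ValueError("radius_cv must be >= 0")
        if not 0.0 <= self.eccentricity <= 1.0:
            raise ValueError("eccentricity must lie in [0, 1]")


@dataclass
class SegmentationConfig:
    """Parameters of the per-slice segmentation operator.

    The operator is Gaussian smoothing -> local mean threshold (window
    ``block_size``, raised by ``offset_frac`` of the slice's dynamic range)
    -> hole filling -> connected-component labeling.  Expressing the offset
    as a fraction of the dynamic range makes segmentation invariant to
    rescaling the image contrast.
    """

    sigma: float = 2.0
    block_size: int = 101
    offset_frac: float = 0.1
    min_area_px: int = 50

    def __post_init__(self) -> None:
        if self.block_size % 2 == 0:
            raise ValueError("block_size must be odd")


@dataclass
class ObjectFilterConfig:
    """Shape-based filter removing noise and non-cyst objects.

    Defaults: keep objects with mean radius in [15, 200] px, radius CV
    <= 0.2 and eccentricity <= 0.75.
    """

    radius_min_px: float = 15.0
    radius_max_px: float = 200.0
    radius_cv_max: float = 0.2
    eccentricity_max: float = 0.75

    def __post_init__(self) -> None:
        if not 0 < self.radius_min_px < self.radius_max_px:
            raise ValueError("require 0 < radius_min_px < radius_max_px")

    def violations(self, obj: SegmentedObject) -> tuple[str, ...]:
        reasons = []
        if obj.radius_mean_px < self.radius_min_px:
            reasons.append("radius_min")
        if obj.radius_mean_px > self.radius_max_px:
            reasons.append("radius_max")
        if obj.radius_cv > self.radius_cv_max:
            reasons.append("radius_cv")
        if obj.eccentricity > self.eccentricity_max:
            reasons.append("eccentricity")
        return tuple(reasons)


@dataclass
class LinkConfig:
    """Across-slice linking: two objects in consecutive slices belong to the
    same cyst iff their centroid distance is at most ``center_dist_factor``
    times the sum of their mean radii.  ``max_gap`` allows a cyst to miss
    detection in that many intermediate slices (default none).
    """

    center_dist_factor: float = 0.5
    max_gap: int = 0


@dataclass
class CystTrack:
    """A cyst: one object per slice over a run of consecutive slices."""

    objects: list[SegmentedObject]

    def __post_init__(self) -> None:
        if not self.objects:
            raise ValueError("track must contain at least one object")

    @property
    def slice_span(self) -> tuple[int, int]:
        idx = [o.slice_index for o in self.objects]
        return min(idx), max(idx)

    @property
    def max_radius_px(self) -> float:
        return max(o.radius_mean_px for o in self.objects)

    def volume(self, pixel_size_um: Optional[float] = None) -> float:
        return measure_cyst(self, pixel_size_um)


@dataclass
class WellSummary:
    """Per-well cyst count and volumes (px³, or µm³ if pixel size known)."""

    cyst_count: int
    volumes: list[float]
    total_volume: float
    mean_volume: float
    tracks: list[CystTrack] = field(default_factory=list, repr=False)


def segment_slice(
    image: np.ndarray, config: SegmentationConfig | None = None
) -> list[SegmentedObject]:
    """Segment one grayscale focal plane into labeled objects.

    A blank image yields an empty list.  Shape statistics: the border is the
    set of object pixels with at least one 8-connected neighbour outside the
    object; radii are centroid-to-border distances.
    """
    config = config or SegmentationConfig()
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("segment_slice expects a 2D grayscale image")

    smoothed = ndi.gaussian_filter(image, sigma=config.sigma)
    rng_span = float(smoothed.max() - smoothed.min())
    if rng_span == 0.0:
        return []
    # threshold_local subtracts `offset` from the local mean; a negative
    # offset therefore *raises* the threshold above the local mean.
    thresh = filters.threshold_local(
        smoothed,
        block_size=config.block_size,
        method="mean",
        offset=-config.offset_frac * rng_span,
    )
    mask = smoothed > thresh
    mask = ndi.binary_fill_holes(mask)
    labels, _ = ndi.label(mask)

    out: list[SegmentedObject] = []
    h, w = image.shape
    for region in measure.regionprops(labels):
        if region.area < config.min_area_px:
            continue
        rmean, rcv = _boundary_radius_stats(region.image, region.centroid_local)
        if rmean <= 0:
            continue
        minr, minc, maxr, maxc = region.bbox
        out.append(
            SegmentedObject(
                slice_index=0,
                label=int(region.label),
                centroid=(float(region.centroid[0]), float(region.centroid[1])),
                radius_mean_px=rmean,
                radius_cv=rcv,
                eccentricity=float(region.eccentricity),
                area_px=int(region.area),
                touches_border=minr == 0 or minc == 0 or maxr == h or maxc == w,
            )
        )
    return out


def _boundary_radius_stats(
    region_mask: np.ndarray, centroid_local: tuple[float, float]
) -> tuple[float, float]:
    """Mean and CV of centroid-to-border distances (8-connected inner border)."""
    eroded = ndi.binary_erosion(region_mask, structure=np.ones((3, 3)), border_value=0)
    border = region_mask & ~eroded
    rr, cc = np.nonzero(border)
    if rr.size == 0:
        return 0.0, 0.0
    d = np.hypot(rr - centroid_local[0], cc - centroid_local[1])
    mean = float(d.mean())
    if mean == 0.0:
        return 0.0, 0.0
    return mean, float(d.std() / mean)


def filter_objects(
    objects: Sequence[SegmentedObject], config: ObjectFilterConfig | None = None
) -> tuple[list[SegmentedObject], list[tuple[SegmentedObject, tuple[str, ...]]]]:
    """Partition objects into (kept, removed-with-reasons).

    Pure predicate: every input object lands in exactly one of the two lists
    and the decision depends only on that object's statistics.
    """
    config = config or ObjectFilterConfig()
    kept: list[SegmentedObject] = []
    removed: list[tuple[SegmentedObject, tuple[str, ...]]] = []
    for obj in objects:
        reasons = config.violations(obj)
        if reasons:
            removed.append((obj, reasons))
        else:
            kept.append(obj)
    return kept, removed


def link_stack(
    per_slice_objects: Sequence[Sequence[SegmentedObject]],
    config: LinkConfig | None = None,
) -> list[CystTrack]:
    """Link filtered objects across consecutive slices into cyst tracks.

    Greedy matching: candidate (track, object) pairs within each slice are
    considered in ascending centroid-distance order; a pair links iff the
    distance is <= factor × (r_track + r_object).  Unmatched objects start
    new tracks; every input object ends up in exactly one track.
    """
    config = config or LinkConfig()
    tracks: list[list[SegmentedObject]] = []
    last_slice: list[int] = []  # per track, slice index of its last object

    for i, slice_objs in enumerate(per_slice_objects):
        open_tracks = [
            t for t in range(len(tracks)) if 0 < i - last_slice[t] <= 1 + config.max_gap
        ]
        pairs = []
        for t in open_tracks:
            tail = tracks[t][-1]
            for j, obj in enumerate(slice_objs):
                d = float(np.hypot(tail.centroid[0] - obj.centroid[0],
                                   tail.centroid[1] - obj.centroid[1]))
                if d <= config.center_dist_factor * (tail.radius_mean_px + obj.radius_mean_px):
                    pairs.append((d, t, j))
        pairs.sort(key=lambda p: p[0])
        used_tracks: set[int] = set()
        used_objs: set[int] = set()
        for d, t, j in pairs:
            if t in used_tracks or j in used_objs:
                continue
            tracks[t].append(slice_objs[j])
            last_slice[t] = i
            used_tracks.add(t)
            used_objs.add(j)
        for j, obj in enumerate(slice_objs):
            if j not in used_objs:
                tracks.append([obj])
                last_slice.append(i)

    return [CystTrack(objects=t) for t in tracks]


def measure_cyst(track: CystTrack, pixel_size_um: Optional[float] = None) -> float:
    """Spherical volume from a track's largest cross-section.

    r is the mean radius of the largest member object; volume = 4/3·π·r³ in
    px³, multiplied by pixel_size_um³ when a pixel size is supplied.
    """
    if not track.objects:
        raise ValueError("cannot measure an empty track")
    vol = sphere_volume(track.max_radius_px)
    if pixel_size_um is not None:
        vol *= float(pixel_size_um) ** 3
    return vol


def quantify_well(
    stack: ImageStack,
    seg_config: SegmentationConfig | None = None,
    filter_config: ObjectFilterConfig | None = None,
    link_config: LinkConfig | None = None,
) -> WellSummary:
    """Full per-well pipeline: segment → filter → link → measure.

    Deterministic for fixed input and configuration.
    """
    per_slice: list[list[SegmentedObject]] = []
    for i in range(stack.depth):
        objs = segment_slice(stack.slices[i], seg_config)
        for o in objs:
            o.slice_index = i
        kept, _ = filter_objects(objs, filter_config)
        per_slice.append(kept)
    tracks = link_stack(per_slice, link_config)
    volumes = [measure_cyst(t, stack.pixel_size_um) for t in tracks]
    return WellSummary(
        cyst_count=len(tracks),
        volumes=volumes,
        total_volume=float(np.sum(volumes)) if volumes else 0.0,
        mean_volume=float(np.mean(volumes)) if volumes else 0.0,
        tracks=tracks,
    )


def cyst_index(cyst_mask: np.ndarray, tissue_mask: np.ndarray) -> float:
    """2D cyst index: cystic area / total tissue section area.

    Both arguments are binary masks of the same shape with the cystic region
    contained in the tissue region.
    """
    cyst_mask = np.asarray(cyst_mask, dtype=bool)
    tissue_mask = np.asarray(tissue_mask, dtype=bool)
    if cyst_mask.shape != tissue_mask.shape:
        raise ValueError("masks must have the same shape")
    tissue_area = int(tissue_mask.sum())
    if tissue_area == 0:
        raise ValueError("tissue mask is empty")
    if np.any(cyst_mask & ~tissue_mask):
        raise ValueError("cystic region must be contained in the tissue region")
    return float(cyst_mask.sum()) / tissue_area
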