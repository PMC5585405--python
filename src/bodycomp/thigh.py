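"""Per-thigh segmentation of muscle, SAT, SFAT and IMAT.

The two thighs are separated as distinct body components and every later
step runs on one thigh at a time.  Muscle and adipose tissue come from
HU thresholding with cortical bone (and the marrow it encloses) removed;
SAT is the adipose tissue outside the ILT inside-mask; the remaining
inner adipose tissue is split into subfascial (SFAT, the rim just under
the fascia lata) and intermuscular (IMAT) by either of two methods: a
second, stricter ILT pass, or a morphological erosion of the muscle
compartment by a fixed physical depth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import CTSlice, DEFAULT_BANDS, HUBands, area_cm2, warn
from .errors import SegmentationError
from .ilt import ILTParams, ilt_response, inside_mask
from .liver import fit_gaussian_center

__all__ = [
    "ThighSideResult",
    "separate_thighs",
    "segment_muscle_at",
    "thigh_sat",
    "sfat_imat_ilt",
    "sfat_imat_morph",
    "muscle_attenuation",
    "segment_thigh_slice",
]


@dataclass
class ThighSideResult:
    """Depot masks, areas (cm^2) and muscle attenuation for one thigh."""

    side: str
    muscle: np.ndarray
    sat: np.ndarray
    sfat: np.ndarray
    imat: np.ndarray
    bone: np.ndarray
    muscle_area: float
    sat_area: float
    sfat_area: float
    imat_area: float
    muscle_attenuation: float
    method: str


def _label_components(mask: np.ndarray):
    labels, n = ndimage.label(mask, structure=ndimage.generate_binary_structure(2, 2))
    return labels, n


def separate_thighs(
    ct: CTSlice, bands: HUBands = DEFAULT_BANDS, table_row_fraction: float = 0.8
) -> tuple[np.ndarray, np.ndarray]:
    """Segment and separate the two thighs (left/right in image coordinates).

    The two largest non-table body components are returned, holes filled.
    If the legs touch and form a single component, one binary opening is
    attempted before giving up.
    """
    if ct.station != "thigh":
        raise ValueError("slice station must be 'thigh'")
    thresholded = bands.body(ct.pixels)
    if not thresholded.any():
        raise SegmentationError("no pixels above the body threshold", stage="body")
    labels, n = _label_components(thresholded)
    areas = np.bincount(labels.ravel())[1:]
    centroids = ndimage.center_of_mass(thresholded, labels, index=np.arange(1, n + 1))
    keep = [i for i in range(n) if centroids[i][0] < table_row_fraction * ct.shape[0]]
    if not keep:
        raise SegmentationError("all components classified as table", stage="body")
    keep.sort(key=lambda i: areas[i], reverse=True)
    masks = [labels == i + 1 for i in keep[:2]]
    if len(masks) < 2 or areas[keep[1]] < 0.05 * areas[keep[0]]:
        # legs probably touching: try one opening on the dominant component
        opened = ndimage.binary_opening(
            masks[0], structure=ndimage.generate_binary_structure(2, 1)
        )
        labels2, n2 = _label_components(opened)
        if n2 < 2:
            raise SegmentationError("could not separate two thighs", stage="separate")
        areas2 = np.bincount(labels2.ravel())[1:]
        top2 = np.argsort(areas2)[::-1][:2]
        masks = [labels2 == i + 1 for i in top2]
    masks = [ndimage.binary_fill_holes(m) for m in masks]
    cols = [np.nonzero(m)[1].mean() for m in masks]
    left, right = (masks[0], masks[1]) if cols[0] < cols[1] else (masks[1], masks[0])
    return left, right


def segment_muscle_at(
    thigh: np.ndarray, ct: CTSlice, bands: HUBands = DEFAULT_BANDS
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Muscle, adipose and bone masks of one thigh.

    Bone is the cortical threshold plus the marrow it encloses (hole
    filling inside the cortical ring); marrow HU falls inside the adipose
    band but is not an adipose depot, so adipose and muscle both exclude
    bone.
    """
    thigh = np.asarray(thigh, bool)
    if not thigh.any():
        raise ValueError("empty thigh mask")
    cortical = bands.bone_mask(ct.pixels) & thigh
    bone = ndimage.binary_fill_holes(cortical) if cortical.any() else cortical
    adipose = bands.adipose_mask(ct.pixels) & thigh & ~bone
    muscle = bands.lean_mask(ct.pixels) & thigh & ~bone
    return muscle, adipose, bone


def thigh_sat(
    adipose: np.ndarray,
    ct: CTSlice,
    ilt: ILTParams,
    thigh: np.ndarray | None = None,
) -> np.ndarray:
    """SAT of one thigh: adipose tissue outside the ILT inside-mask.

    ``thigh`` confines the lean-probability support and the evaluation to
    one leg so rays ignore the contralateral thigh and the table.
    """
    support = thigh if thigh is not None else None
    response = ilt_response(ct, ilt, roi=support, support=support)
    inside = inside_mask(response, ilt.pm_threshold, largest_component=True, fill_holes=True)
    if not inside.any():
        warn("ILT inside mask empty; labelling all adipose tissue as SAT")
        return np.asarray(adipose, bool).copy()
    return np.asarray(adipose, bool) & ~inside


def sfat_imat_ilt(
    adipose_inner: np.ndarray,
    ct: CTSlice,
    ilt2: ILTParams,
    thigh: np.ndarray | None = None,
    response: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Method 1: split inner adipose tissue into SFAT and IMAT with a
    second, stricter ILT pass.

    The higher threshold keeps only the region deep inside muscle; inner
    adipose tissue within it is IMAT, the remainder (the rim just beneath
    the fascia lata) is SFAT.  A precomputed ``response`` may be passed to
    reuse the first pass when only the threshold differs.
    """
    adipose_inner = np.asarray(adipose_inner, bool)
    if not adipose_inner.any():
        empty = np.zeros_like(adipose_inner)
        return empty, empty.copy()
    if response is None:
        support = thigh if thigh is not None else None
        response = ilt_response(ct, ilt2, roi=support, support=support)
    deep = inside_mask(response, ilt2.pm_threshold, largest_component=True, fill_holes=True)
    imat = adipose_inner & deep
    sfat = adipose_inner & ~deep
    return sfat, imat


def _disk(radius_px: float) -> np.ndarray:
    r = int(np.ceil(radius_px))
    yy, xx = np.ogrid[-r : r + 1, -r : r + 1]
    return yy * yy + xx * xx <= radius_px * radius_px


def sfat_imat_morph(
    adipose_inner: np.ndarray,
    muscle: np.ndarray,
    depth_mm: float,
    spacing: tuple[float, float],
    closing_mm: float = 6.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Method 2: split inner adipose tissue into SFAT and IMAT morphologically.

    The muscle compartment (muscle plus inner adipose tissue, closed and
    hole-filled) is eroded by ``depth_mm`` — implemented spacing-aware as
    a Euclidean-distance threshold — leaving a deep zone; inner adipose
    tissue inside it is IMAT, the rim of thickness ~``depth_mm`` under the
    fascia is SFAT.  The distance threshold carries a quarter-pixel offset
    compensating the lattice gap between the raster region boundary and
    the background pixel centres the EDT measures to; this makes the
    eroded area agree with the continuous erosion to well under a percent
    at 1 mm pixels.
    """
    if depth_mm <= 0:
        raise ValueError("depth_mm must be positive")
    adipose_inner = np.asarray(adipose_inner, bool)
    if not adipose_inner.any():
        empty = np.zeros_like(adipose_inner)
        return empty, empty.copy()
    region = adipose_inner | np.asarray(muscle, bool)
    close_px = closing_mm / min(spacing)
    if close_px >= 1:
        region = ndimage.binary_closing(region, structure=_disk(close_px))
    region = ndimage.binary_fill_holes(region)
    dist = ndimage.distance_transform_edt(region, sampling=spacing)
    deep = dist >= depth_mm + 0.25 * min(spacing)
    if not deep.any():
        warn("erosion depth annihilates the muscle compartment; all inner adipose -> SFAT")
        return adipose_inner.copy(), np.zeros_like(adipose_inner)
    imat = adipose_inner & deep
    sfat = adipose_inner & ~deep
    return sfat, imat


def muscle_attenuation(ct: CTSlice, muscle: np.ndarray, stat: str = "mean") -> float:
    """Mean HU over the muscle mask (or the Gaussian-fit centre, for symmetry
    with the liver measurement)."""
    muscle = np.asarray(muscle, bool)
    if not muscle.any():
        raise ValueError("empty muscle mask")
    values = ct.pixels[muscle]
    if stat == "mean":
        return float(values.mean())
    if stat == "gaussian":
        return fit_gaussian_center(values)
    raise ValueError("stat must be 'mean' or 'gaussian'")


def segment_thigh_slice(
    ct: CTSlice,
    bands: HUBands = DEFAULT_BANDS,
    ilt_sat: ILTParams | None = None,
    ilt_deep: ILTParams | None = None,
    method: str = "ilt",
    depth_mm: float = 5.0,
) -> dict[str, ThighSideResult]:
    """Full thigh pipeline: both legs, all depots, muscle attenuation."""
    from .config import THIGH_DEEP_ILT, THIGH_SAT_ILT

    if method not in ("ilt", "morph"):
        raise ValueError("method must be 'ilt' or 'morph'")
    ilt_sat = ilt_sat or THIGH_SAT_ILT
    ilt_deep = ilt_deep or THIGH_DEEP_ILT
    left, right = separate_thighs(ct, bands)
    results = {}
    for side, mask in (("left", left), ("right", right)):
        muscle, adipose, bone = segment_muscle_at(mask, ct, bands)
        sat = thigh_sat(adipose, ct, ilt_sat, thigh=mask)
        inner = adipose & ~sat
        if method == "ilt":
            sfat, imat = sfat_imat_ilt(inner, ct, ilt_deep, thigh=mask)
        else:
            sfat, imat = sfat_imat_morph(inner, muscle, depth_mm, ct.spacing)
        results[side] = ThighSideResult(
            side=side,
            muscle=muscle,
            sat=sat,
            sfat=sfat,
            imat=imat,
            bone=bone,
            muscle_area=area_cm2(muscle, ct.spacing),
            sat_area=area_cm2(sat, ct.spacing),
            sfat_area=area_cm2(sfat, ct.spacing),
            imat_area=area_cm2(imat, ct.spacing),
            muscle_attenuation=muscle_attenuation(ct, muscle),
            method=method,
        )
    return results
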