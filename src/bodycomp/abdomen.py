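"""Abdominal VAT/SAT segmentation at the L4 level.

Adipose tissue is thresholded, the ILT filter locates the abdominal
cavity (the region enclosed by the muscle wall), and paraspinal adipose
tissue — which counts as neither VAT nor SAT — is removed with an
alignable back-probability atlas (P_back).  Also provides the geometric
helpers used when manually splitting SAT by Scarpa's fascia and VAT by
the retroperitoneal contour.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely

from .atlas import Frame, ShapeAtlas, align_atlas, build_shape_atlas, mask_bbox
from .core import CTSlice, DEFAULT_BANDS, HUBands, area_cm2, body_mask, warn
from .errors import GeometryError, SegmentationError
from .ilt import ILTParams, ilt_response, inside_mask

__all__ = [
    "AbdomenResult",
    "segment_vat_sat",
    "build_back_atlas",
    "split_sat_by_fascia",
    "split_vat_by_contour",
]


@dataclass
class AbdomenResult:
    """Masks and areas from the automated VAT/SAT segmentation.

    ``vat``, ``sat`` and ``excluded_back_at`` partition the adipose
    pixels inside the body; ``tat_area = vat_area + sat_area`` (back AT
    counts toward neither).
    """

    vat: np.ndarray
    sat: np.ndarray
    excluded_back_at: np.ndarray
    vat_area: float
    sat_area: float
    tat_area: float
    cavity: np.ndarray | None = None
    cavity_frame: Frame | None = None
    body: np.ndarray | None = None


def build_back_atlas(
    reference_back_masks: list[np.ndarray],
    cavity_boxes: list[Frame],
    grid_size: int | tuple[int, int] = 128,
) -> ShapeAtlas:
    """P_back: mean of reference back-AT masks aligned by their cavity boxes."""
    return build_shape_atlas(reference_back_masks, cavity_boxes, grid_size=grid_size)


def segment_vat_sat(
    ct: CTSlice,
    ilt: ILTParams,
    back_atlas: ShapeAtlas,
    bands: HUBands = DEFAULT_BANDS,
    back_threshold: float = 0.5,
) -> AbdomenResult:
    """Automated VAT/SAT segmentation of an L4 slice.

    VAT is adipose inside the ILT cavity (minus back AT); SAT is adipose
    outside it (minus back AT); back AT is adipose where the aligned
    P_back is at least ``back_threshold``.  The three masks partition the
    adipose pixels of the body by construction.
    """
    if ct.station != "abdomen":
        raise ValueError("slice station must be 'abdomen'")
    body = body_mask(ct, bands, n_components=1)
    adipose = bands.adipose_mask(ct.pixels) & body

    response = ilt_response(ct, ilt, roi=body, support=body)
    cavity = inside_mask(response, ilt.pm_threshold, largest_component=True, fill_holes=True)
    if not cavity.any():
        raise SegmentationError("ILT cavity is empty", stage="cavity")
    frame = mask_bbox(cavity)
    p_back = align_atlas(back_atlas, frame, ct.shape)

    if not adipose.any():
        warn("no adipose-band pixels in body; all areas zero")
    back = adipose & (p_back >= back_threshold)
    vat = adipose & cavity & ~back
    sat = adipose & ~cavity & ~back

    vat_area = area_cm2(vat, ct.spacing)
    sat_area = area_cm2(sat, ct.spacing)
    return AbdomenResult(
        vat=vat,
        sat=sat,
        excluded_back_at=back,
        vat_area=vat_area,
        sat_area=sat_area,
        tat_area=vat_area + sat_area,
        cavity=cavity,
        cavity_frame=frame,
        body=body,
    )


# ---------------------------------------------------------------------------
# Geometric helpers for the manually delineated sub-depots
# ---------------------------------------------------------------------------


def _resample_polyline(vertices: np.ndarray, step: float = 0.25) -> np.ndarray:
    """Densify a polyline so every segment is sampled at least every ``step`` px."""
    pts = [vertices[0]]
    for a, b in zip(vertices[:-1], vertices[1:]):
        seg = np.linalg.norm(b - a)
        n = max(int(np.ceil(seg / step)), 1)
        for t in np.linspace(0, 1, n + 1)[1:]:
            pts.append(a + t * (b - a))
    return np.asarray(pts)


def split_sat_by_fascia(
    sat: np.ndarray,
    fascia: np.ndarray,
    body_centroid_row: float,
) -> tuple[np.ndarray, np.ndarray, dict[str, bool]]:
    """Split SAT into deep (DSAT) and superficial (SSAT) along a traced fascia.

    The fascia polyline (vertices as (row, col)) is interpreted in polar
    coordinates around the SAT centroid: SAT pixels radially inside the
    fascia (toward the body) are deep, outside superficial.  The
    anterior/posterior halves are delimited by ``body_centroid_row`` (the
    centre of gravity of the segmented abdomen; anterior = smaller row
    indices, the supine convention) and a half is reported as valid only
    if the fascia's angular span covers essentially all (>= 98%) of that
    half's SAT pixels.
    """
    sat = np.asarray(sat, bool)
    fascia = np.asarray(fascia, dtype=np.float64)
    if fascia.ndim != 2 or fascia.shape[1] != 2 or fascia.shape[0] < 2:
        raise GeometryError("fascia must be an (N, 2) polyline with N >= 2")
    if not sat.any():
        raise GeometryError("SAT mask is empty")

    rows, cols = np.nonzero(sat)
    center = (body_centroid_row, cols.mean())

    # fascia must lie within (a 1-px dilation of) the SAT annulus
    from scipy import ndimage as ndi

    sat_dilated = ndi.binary_dilation(sat, ndi.generate_binary_structure(2, 2), iterations=2)
    pts = _resample_polyline(fascia)
    ri = np.clip(np.round(pts[:, 0]).astype(int), 0, sat.shape[0] - 1)
    ci = np.clip(np.round(pts[:, 1]).astype(int), 0, sat.shape[1] - 1)
    if not sat_dilated[ri, ci].all():
        raise GeometryError("fascia polyline leaves the SAT region")

    theta_f = np.arctan2(pts[:, 0] - center[0], pts[:, 1] - center[1])
    rho_f = np.hypot(pts[:, 0] - center[0], pts[:, 1] - center[1])
    order = np.argsort(theta_f)
    theta_f, rho_f = theta_f[order], rho_f[order]
    # wrap-around padding so interpolation works across the -pi/pi seam when
    # the polyline is (nearly) closed
    closed = (2 * np.pi - (theta_f[-1] - theta_f[0])) < np.deg2rad(10)
    if closed:
        theta_pad = np.concatenate([theta_f - 2 * np.pi, theta_f, theta_f + 2 * np.pi])
        rho_pad = np.concatenate([rho_f, rho_f, rho_f])
    else:
        theta_pad, rho_pad = theta_f, rho_f

    theta_p = np.arctan2(rows - center[0], cols - center[1])
    rho_p = np.hypot(rows - center[0], cols - center[1])
    covered = (
        np.ones_like(theta_p, bool)
        if closed
        else (theta_p >= theta_f.min()) & (theta_p <= theta_f.max())
    )
    rho_at_pixel = np.interp(theta_p, theta_pad, rho_pad)
    deep = covered & (rho_p < rho_at_pixel)
    superficial = covered & (rho_p >= rho_at_pixel)

    anterior_p = rows < body_centroid_row
    flags = {}
    for half, sel in (("anterior", anterior_p), ("posterior", ~anterior_p)):
        flags[half] = bool(sel.any()) and float(covered[sel].mean()) >= 0.98

    dsat = np.zeros_like(sat)
    ssat = np.zeros_like(sat)
    for half, sel in (("anterior", anterior_p), ("posterior", ~anterior_p)):
        if flags[half]:
            dsat[rows[sel & deep], cols[sel & deep]] = True
            ssat[rows[sel & superficial], cols[sel & superficial]] = True
    return dsat, ssat, flags


def split_vat_by_contour(
    vat: np.ndarray, rpat_contour: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Split VAT into intra- (IPAT) and retroperitoneal (RPAT) by a closed contour.

    VAT pixels whose centres fall inside the traced contour become RPAT,
    the remainder IPAT; the two partition VAT exactly.
    """
    vat = np.asarray(vat, bool)
    contour = np.asarray(rpat_contour, dtype=np.float64)
    if contour.ndim != 2 or contour.shape[1] != 2 or contour.shape[0] < 3:
        raise GeometryError("contour must be an (N, 2) closed polyline with N >= 3")
    ring = shapely.LinearRing(contour[:, ::-1])  # shapely wants (x, y) = (col, row)
    if not ring.is_simple or not ring.is_valid:
        raise GeometryError("contour is self-intersecting")
    poly = shapely.Polygon(ring)
    rows, cols = np.nonzero(vat)
    inside = shapely.contains_xy(poly, cols.astype(float), rows.astype(float))
    rpat = np.zeros_like(vat)
    rpat[rows[inside], cols[inside]] = True
    ipat = vat & ~rpat
    return ipat, rpat
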