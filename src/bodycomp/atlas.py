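"""Shape probability atlases aligned via the abdominal-cavity span.

Reference segmentations are mapped into a canonical unit square by an
anisotropic affine rescaling of each image's cavity bounding box; the
per-pixel mean of the aligned masks is the shape probability map
(P_liver, P_back).  At application time the canonical map is rescaled
onto the target image's cavity span, located automatically with the ILT
filter.  No rotation is modelled (subjects are supine).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import CTSlice, DEFAULT_BANDS, HUBands, body_mask
from .errors import SegmentationError
from .ilt import ILTParams, ilt_response, inside_mask

__all__ = [
    "Frame",
    "ShapeAtlas",
    "mask_bbox",
    "cavity_span",
    "build_shape_atlas",
    "align_atlas",
    "save_atlas",
    "load_atlas",
]


@dataclass(frozen=True)
class Frame:
    """A reference rectangle in image index units (row0, col0, height, width)."""

    row0: float
    col0: float
    height: float
    width: float

    def __post_init__(self):
        if self.height <= 0 or self.width <= 0:
            raise ValueError("frame must have positive height and width")

    def shifted(self, drow: float, dcol: float) -> "Frame":
        return Frame(self.row0 + drow, self.col0 + dcol, self.height, self.width)


@dataclass
class ShapeAtlas:
    """A probability map on a canonical grid spanning the unit cavity rectangle."""

    prob: np.ndarray

    def __post_init__(self):
        self.prob = np.asarray(self.prob, dtype=np.float64)
        if self.prob.ndim != 2:
            raise ValueError("atlas probability map must be 2D")
        if self.prob.min() < 0.0 or self.prob.max() > 1.0:
            raise ValueError("atlas values must lie in [0, 1]")

    @property
    def grid_size(self) -> tuple[int, int]:
        return self.prob.shape


def mask_bbox(mask: np.ndarray) -> Frame:
    """Bounding rectangle of the true pixels of a mask."""
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise SegmentationError("cannot take the bounding box of an empty mask")
    height = float(rows.max() - rows.min())
    width = float(cols.max() - cols.min())
    if height == 0 or width == 0:
        raise SegmentationError("mask is degenerate (zero extent)")
    return Frame(float(rows.min()), float(cols.min()), height, width)


def cavity_span(
    ct: CTSlice,
    ilt: ILTParams,
    bands: HUBands = DEFAULT_BANDS,
) -> Frame:
    """Bounding rectangle of the ILT-detected abdominal cavity (inside SAT)."""
    body = body_mask(ct, bands, n_components=1)
    response = ilt_response(ct, ilt, roi=body, support=body)
    cavity = inside_mask(response, ilt.pm_threshold, largest_component=True, fill_holes=True)
    if not cavity.any():
        raise SegmentationError("ILT inside mask is empty", stage="cavity")
    return mask_bbox(cavity)


def _canonical_coords(frame: Frame, grid_size: tuple[int, int]) -> list[np.ndarray]:
    gr, gc = grid_size
    v = np.linspace(0.0, 1.0, gr)
    u = np.linspace(0.0, 1.0, gc)
    rows = frame.row0 + v[:, None] * frame.height + np.zeros((1, gc))
    cols = frame.col0 + u[None, :] * frame.width + np.zeros((gr, 1))
    return [rows.ravel(), cols.ravel()]


def build_shape_atlas(
    reference_masks: list[np.ndarray],
    frames: list[Frame],
    grid_size: int | tuple[int, int] = 128,
) -> ShapeAtlas:
    """Average reference masks after aligning their frames onto the unit rectangle.

    Each mask is sampled (bilinearly) at the canonical grid points mapped
    into its frame; the atlas value is the per-pixel mean over masks.
    """
    if len(reference_masks) != len(frames):
        raise ValueError("reference_masks and frames must have equal length")
    if len(reference_masks) < 1:
        raise ValueError("at least one reference mask is required")
    if isinstance(grid_size, int):
        grid_size = (grid_size, grid_size)
    acc = np.zeros(grid_size, dtype=np.float64)
    for mask, frame in zip(reference_masks, frames):
        coords = _canonical_coords(frame, grid_size)
        sampled = ndimage.map_coordinates(
            np.asarray(mask, dtype=np.float64), coords, order=1, mode="constant", cval=0.0
        ).reshape(grid_size)
        acc += sampled
    return ShapeAtlas(np.clip(acc / len(reference_masks), 0.0, 1.0))


def align_atlas(atlas: ShapeAtlas, frame: Frame, shape: tuple[int, int]) -> np.ndarray:
    """Resample the canonical atlas onto a target image given its cavity frame.

    Pixels mapping outside the canonical grid get probability 0.
    """
    gr, gc = atlas.grid_size
    rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]].astype(np.float64)
    v = (rows - frame.row0) / frame.height * (gr - 1)
    u = (cols - frame.col0) / frame.width * (gc - 1)
    out = ndimage.map_coordinates(
        atlas.prob, [v.ravel(), u.ravel()], order=1, mode="constant", cval=0.0
    ).reshape(shape)
    outside = (v < 0) | (v > gr - 1) | (u < 0) | (u > gc - 1)
    out[outside] = 0.0
    return out


def save_atlas(atlas: ShapeAtlas, nifti_path, descriptor_path=None) -> None:
    """Serialise an atlas as a NIfTI probability map plus a JSON descriptor."""
    import nibabel as nib

    img = nib.Nifti1Image(atlas.prob.astype(np.float32), np.eye(4))
    nib.save(img, str(nifti_path))
    if descriptor_path is not None:
        with open(descriptor_path, "w") as fh:
            json.dump({"grid_size": list(atlas.grid_size), "frame": "unit cavity rectangle"}, fh)


def load_atlas(nifti_path) -> ShapeAtlas:
    import nibabel as nib

    data = np.asanyarray(nib.load(str(nifti_path)).dataobj).astype(np.float64)
    if data.ndim == 3 and data.shape[2] == 1:
        data = data[:, :, 0]
    return ShapeAtlas(np.clip(data, 0.0, 1.0))
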