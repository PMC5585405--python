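"""Image data model, HU band definitions, I/O and mask utilities.

A CT slice is a 2D raster of attenuation values in Hounsfield units (HU)
together with its pixel spacing in mm.  Binary masks are plain boolean
numpy arrays of the same shape; probability maps are float arrays in
[0, 1].  All coordinates are row-major ``(row, col)``, 0-based.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import FormatError, MetadataError, SegmentationError

STATIONS = ("liver", "abdomen", "thigh")

HU_MIN = -1024.0
HU_MAX = 3071.0


@dataclass
class CTSlice:
    """A single axial CT slice in Hounsfield units.

    Parameters
    ----------
    pixels : ndarray, shape (rows, cols)
        Attenuation in HU.  Must be finite and within the 12-bit CT range
        [-1024, 3071].
    spacing : (float, float)
        (row_mm, col_mm) pixel spacing, strictly positive.
    station : {"liver", "abdomen", "thigh"}
        Anatomical level of the slice.
    """

    pixels: np.ndarray
    spacing: tuple[float, float]
    station: str

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2D array")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixels must be finite")
        if self.pixels.min() < HU_MIN or self.pixels.max() > HU_MAX:
            raise ValueError(
                f"HU values outside the plausible CT range [{HU_MIN}, {HU_MAX}]"
            )
        self.spacing = (float(self.spacing[0]), float(self.spacing[1]))
        if self.spacing[0] <= 0 or self.spacing[1] <= 0:
            raise ValueError("spacing components must be strictly positive")
        if self.station not in STATIONS:
            raise ValueError(f"station must be one of {STATIONS}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def pixel_area_mm2(self) -> float:
        return self.spacing[0] * self.spacing[1]


@dataclass(frozen=True)
class HUBands:
    """Global HU thresholds used throughout the pipelines.

    The adipose band is closed on both ends, [adipose_lo, adipose_hi];
    the lean band is half-open, (lean_lo, lean_hi], so that the two bands
    partition a contiguous HU interval without double counting (the
    integer conventions -190..-30 for adipose and -29..+151 for lean).
    Body is everything above ``body_min``; cortical bone everything above
    ``cortical_bone_min``.
    """

    body_min: float = -300.0
    adipose: tuple[float, float] = (-190.0, -30.0)
    lean: tuple[float, float] = (-30.0, 151.0)
    cortical_bone_min: float = 400.0

    def __post_init__(self):
        if not self.adipose[0] <= self.adipose[1]:
            raise ValueError("adipose band inverted")
        if not self.lean[0] < self.lean[1]:
            raise ValueError("lean band inverted")
        if self.adipose[1] > self.lean[0]:
            raise ValueError("adipose band must not extend above lean band start")
        if self.lean[1] >= self.cortical_bone_min:
            raise ValueError("lean band must end below the cortical bone threshold")
        if self.body_min > self.adipose[0]:
            raise ValueError("body_min must not exceed the adipose band start")

    def body(self, hu: np.ndarray) -> np.ndarray:
        return hu > self.body_min

    def adipose_mask(self, hu: np.ndarray) -> np.ndarray:
        lo, hi = self.adipose
        return (hu >= lo) & (hu <= hi)

    def lean_mask(self, hu: np.ndarray) -> np.ndarray:
        lo, hi = self.lean
        return (hu > lo) & (hu <= hi)

    def bone_mask(self, hu: np.ndarray) -> np.ndarray:
        return hu > self.cortical_bone_min


DEFAULT_BANDS = HUBands()


def _as_hu(image) -> np.ndarray:
    return image.pixels if isinstance(image, CTSlice) else np.asarray(image, float)


def threshold_band(image, lo: float, hi: float) -> np.ndarray:
    """Binary mask of pixels with lo <= HU <= hi (closed on both ends)."""
    if lo > hi:
        raise ValueError(f"band inverted: lo={lo} > hi={hi}")
    hu = _as_hu(image)
    return (hu >= lo) & (hu <= hi)


def _structure(connectivity: int) -> np.ndarray:
    if connectivity not in (1, 2):
        raise ValueError("connectivity must be 1 (4-neighbour) or 2 (8-neighbour)")
    return ndimage.generate_binary_structure(2, connectivity)


def body_mask(
    ct: CTSlice,
    bands: HUBands = DEFAULT_BANDS,
    n_components: int | None = None,
    table_row_fraction: float = 0.8,
    connectivity: int = 2,
    fill_connectivity: int = 1,
) -> np.ndarray:
    """Segment the subject body, excluding air and the patient table.

    Connected components of (HU > body_min) are computed (8-connectivity by
    default); components whose centroid lies in the bottom
    ``1 - table_row_fraction`` of image rows are treated as the patient
    table and discarded.  The ``n_components`` largest remaining components
    are kept (default 1, or 2 for the thigh station where each leg is a
    separate component) and internal holes (bowel gas, marrow, ...) are
    filled with 4-connectivity.
    """
    thresholded = bands.body(ct.pixels)
    if not thresholded.any():
        raise SegmentationError("no pixels above the body threshold", stage="body")
    if n_components is None:
        n_components = 2 if ct.station == "thigh" else 1
    labels, n = ndimage.label(thresholded, structure=_structure(connectivity))
    areas = np.bincount(labels.ravel())[1:]
    rows = np.arange(ct.shape[0], dtype=float)
    # mean row index per component
    row_sum = ndimage.sum_labels(rows[:, None] * np.ones(ct.shape), labels, index=np.arange(1, n + 1))
    centroid_rows = row_sum / areas
    keep = np.flatnonzero(centroid_rows < table_row_fraction * ct.shape[0])
    if keep.size == 0:
        raise SegmentationError("all components classified as table", stage="body")
    chosen = keep[np.argsort(areas[keep])[::-1][:n_components]] + 1
    mask = np.isin(labels, chosen)
    return ndimage.binary_fill_holes(mask, structure=_structure(fill_connectivity))


def area_cm2(mask: np.ndarray, spacing: tuple[float, float]) -> float:
    """Area of a binary mask in cm^2: pixel count x row_mm x col_mm / 100."""
    if spacing[0] <= 0 or spacing[1] <= 0:
        raise ValueError("spacing must be positive")
    return int(np.count_nonzero(mask)) * spacing[0] * spacing[1] / 100.0


def mask_mean_hu(ct: CTSlice, mask: np.ndarray) -> float:
    if not mask.any():
        raise ValueError("empty mask")
    return float(ct.pixels[mask].mean())


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------
#
# Fixture format (".cts"): a plain-text container making tests download-free
# and bit-exact.  Line 1 is a JSON header {"format": "cts-v1", "station": ...,
# "spacing": [row_mm, col_mm], "shape": [rows, cols]}; the remaining ``rows``
# lines hold ``cols`` space-separated HU values (repr precision).

_CTS_FORMAT = "cts-v1"


def write_slice(path, ct: CTSlice) -> None:
    """Write a CTSlice in the textual fixture format."""
    header = {
        "format": _CTS_FORMAT,
        "station": ct.station,
        "spacing": list(ct.spacing),
        "shape": list(ct.shape),
    }
    with open(path, "w") as fh:
        fh.write(json.dumps(header) + "\n")
        for row in ct.pixels:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def _read_cts(path, station):
    with open(path) as fh:
        try:
            header = json.loads(fh.readline())
        except json.JSONDecodeError as exc:
            raise FormatError(f"{path}: bad fixture header") from exc
        if header.get("format") != _CTS_FORMAT:
            raise FormatError(f"{path}: not a {_CTS_FORMAT} file")
        if "spacing" not in header:
            raise MetadataError(f"{path}: fixture header lacks spacing")
        pixels = np.loadtxt(fh, dtype=np.float64, ndmin=2)
    if list(pixels.shape) != header["shape"]:
        raise FormatError(f"{path}: array shape does not match header")
    return CTSlice(pixels, tuple(header["spacing"]), station or header["station"])


def _read_dicom(path, station):
    import pydicom

    try:
        ds = pydicom.dcmread(path)
        arr = ds.pixel_array.astype(np.float64)
    except Exception as exc:  # pydicom raises a zoo of types
        raise FormatError(f"{path}: unreadable DICOM") from exc
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    hu = arr * slope + intercept
    if not hasattr(ds, "PixelSpacing"):
        raise MetadataError(f"{path}: DICOM lacks PixelSpacing")
    spacing = (float(ds.PixelSpacing[0]), float(ds.PixelSpacing[1]))
    if station is None:
        raise MetadataError("station must be given for DICOM input")
    return CTSlice(hu, spacing, station)


def _read_nifti(path, station, slice_index):
    import nibabel as nib

    try:
        img = nib.load(str(path))
    except Exception as exc:
        raise FormatError(f"{path}: unreadable NIfTI") from exc
    data = np.asanyarray(img.dataobj).astype(np.float64)
    zooms = img.header.get_zooms()
    if data.ndim == 3:
        if data.shape[2] == 1:
            slice_index = 0
        if slice_index is None:
            raise MetadataError(f"{path}: 3D volume requires slice_index")
        data = data[:, :, slice_index]
    elif data.ndim != 2:
        raise FormatError(f"{path}: expected a 2D or 3D NIfTI")
    spacing = (float(zooms[0]), float(zooms[1]))
    if spacing[0] <= 0 or spacing[1] <= 0:
        raise MetadataError(f"{path}: non-positive voxel spacing")
    if station is None:
        raise MetadataError("station must be given for NIfTI input")
    return CTSlice(data, spacing, station)


def read_slice(path, station: str | None = None, slice_index: int | None = None) -> CTSlice:
    """Read a CT slice from DICOM, NIfTI or the ``.cts`` fixture format.

    The format is chosen by file extension (``.dcm``, ``.nii``/``.nii.gz``,
    ``.cts``).  Rescale slope/intercept are applied to DICOM stored values
    so the returned pixels are HU.
    """
    p = str(path)
    if p.endswith(".cts"):
        return _read_cts(path, station)
    if p.endswith(".dcm") or p.endswith(".ima"):
        return _read_dicom(path, station)
    if p.endswith(".nii") or p.endswith(".nii.gz"):
        return _read_nifti(path, station, slice_index)
    raise FormatError(f"{path}: unrecognised extension (want .cts, .dcm, .nii[.gz])")


def save_labels_nifti(labels: np.ndarray, spacing: tuple[float, float], path) -> None:
    """Write an integer label map as NIfTI-1 with the pixel spacing in the affine."""
    import nibabel as nib

    affine = np.diag([spacing[0], spacing[1], 1.0, 1.0])
    img = nib.Nifti1Image(np.asarray(labels, dtype=np.int16), affine)
    img.header.set_zooms((spacing[0], spacing[1]))
    nib.save(img, str(path))


def masks_to_labels(masks: dict[str, np.ndarray]) -> tuple[np.ndarray, dict[str, int]]:
    """Flatten named binary masks into one integer label map (later wins overlaps)."""
    names = list(masks)
    if not names:
        raise ValueError("no masks given")
    labels = np.zeros(next(iter(masks.values())).shape, dtype=np.int16)
    legend = {}
    for i, name in enumerate(names, start=1):
        labels[masks[name]] = i
        legend[name] = i
    return labels, legend


def save_overlay_png(ct: CTSlice, masks: dict[str, np.ndarray], path, dpi: int = 120) -> None:
    """Save a PNG of the slice with coloured, semi-transparent mask overlays."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    ax.imshow(ct.pixels, cmap="gray", vmin=-200, vmax=250)
    cmap = plt.get_cmap("tab10")
    for i, (name, mask) in enumerate(masks.items()):
        overlay = np.zeros((*mask.shape, 4))
        overlay[mask] = (*cmap(i % 10)[:3], 0.45)
        ax.imshow(overlay)
        ax.plot([], [], color=cmap(i % 10), label=name)
    ax.legend(loc="lower right", fontsize=8)
    ax.set_axis_off()
    fig.savefig(str(path), dpi=dpi, bbox_inches="tight")
    plt.close(fig)


def results_to_csv(rows: list[dict], path) -> None:
    import pandas as pd

    pd.DataFrame(rows).to_csv(str(path), index=False)


def warn(msg: str) -> None:
    warnings.warn(msg, stacklevel=2)
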