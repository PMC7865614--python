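"""Reading, standardization and skull-stripping of 2D brain-slice images.

Images travel through the pipeline as :class:`GrayImage`: a single-channel
raster of real-valued intensities on the 8-bit scale [0, 255].  MRI slices are
intrinsically scalar, so RGB inputs are collapsed to one plane by channel
averaging and 16-bit inputs are rescaled linearly onto [0, 255].

Coordinates are 0-based ``(row, column)``.  For an even width ``W`` the
vertical mirror axis lies between columns ``W/2 - 1`` and ``W/2``.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Optional, Union

import numpy as np
from PIL import Image
from scipy import ndimage


class EmptyBrainMaskError(ValueError):
    """Raised when skull stripping leaves no pixel inside the threshold band."""


@dataclasses.dataclass
class GrayImage:
    """A 2D grayscale intensity raster with 8-bit value semantics.

    Parameters
    ----------
    pixels
        ``H x W`` array of intensities in ``[0, 255]``.  Stored as float64 so
        that interpolation does not quantize; serialized as 8-bit PNG.
    source_id
        Identifier carried through the pipeline (usually the file stem).
    """

    pixels: np.ndarray
    source_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError(f"GrayImage requires a 2D raster, got shape {self.pixels.shape}")
        if self.pixels.size and (self.pixels.min() < 0 or self.pixels.max() > 255):
            raise ValueError("GrayImage intensities must lie in [0, 255]")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclasses.dataclass(frozen=True)
class ThresholdBand:
    """Closed intensity interval [lower, upper] used for skull stripping."""

    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError(f"threshold band requires lower < upper, got [{self.lower}, {self.upper}]")


def as_pixels(img: Union[GrayImage, np.ndarray]) -> np.ndarray:
    """Return the float64 pixel array of a GrayImage or a bare array."""
    if isinstance(img, GrayImage):
        return img.pixels
    return np.asarray(img, dtype=np.float64)


def load_image(
    path: Union[str, Path],
    slice_index: Optional[int] = None,
    slice_axis: int = 2,
) -> GrayImage:
    """Load a PNG/JPEG/TIFF image or one slice of a NIfTI volume as grayscale.

    RGB(A) inputs are collapsed by averaging the color channels; integer
    inputs deeper than 8 bits are rescaled linearly so the dtype maximum maps
    to 255.  NIfTI volumes require ``slice_index`` (and optionally
    ``slice_axis``); the extracted slice is min-max rescaled to [0, 255].
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"cannot read image: no such file {path}")

    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        if slice_index is None:
            raise ValueError(f"NIfTI input {path} requires a slice index (config key slice_index)")
        import nibabel as nib

        vol = np.asanyarray(nib.load(str(path)).dataobj, dtype=np.float64)
        sl = np.take(vol, slice_index, axis=slice_axis)
        lo, hi = sl.min(), sl.max()
        arr = np.zeros_like(sl) if hi <= lo else (sl - lo) * (255.0 / (hi - lo))
        return GrayImage(arr, source_id=path.stem.replace(".nii", ""))

    try:
        with Image.open(path) as im:
            arr = np.asarray(im)
    except Exception as exc:  # noqa: BLE001 - re-raise with path context
        raise IOError(f"cannot read image {path}: {exc}") from exc

    arr = arr.astype(np.float64)
    if arr.ndim == 3:  # RGB(A): average the color channels
        arr = arr[..., :3].mean(axis=2)
    if arr.max(initial=0.0) > 255.0:
        # deeper-than-8-bit integer input: map the dtype range onto [0, 255]
        with Image.open(path) as im:
            dtype = np.asarray(im).dtype
        scale = float(np.iinfo(dtype).max) if np.issubdtype(dtype, np.integer) else arr.max()
        arr = arr * (255.0 / scale)
    return GrayImage(arr, source_id=path.stem)


def write_image(img: Union[GrayImage, np.ndarray], path: Union[str, Path]) -> None:
    """Write an image as 8-bit PNG (intensities rounded to nearest integer)."""
    arr = np.clip(np.rint(as_pixels(img)), 0, 255).astype(np.uint8)
    Image.fromarray(arr).save(str(path))


def _bilinear_resize(arr: np.ndarray, out_h: int, out_w: int) -> np.ndarray:
    """Bilinear resampling with pixel-center alignment and edge clamping.

    Output pixel ``i`` samples input coordinate ``(i + 0.5) * H_in / H_out - 0.5``,
    the convention shared by OpenCV and scikit-image.
    """
    in_h, in_w = arr.shape
    rows = (np.arange(out_h) + 0.5) * (in_h / out_h) - 0.5
    cols = (np.arange(out_w) + 0.5) * (in_w / out_w) - 0.5
    grid = np.meshgrid(rows, cols, indexing="ij")
    return ndimage.map_coordinates(arr, grid, order=1, mode="nearest")


def normalize_resize(img: Union[GrayImage, np.ndarray], size: int = 256) -> GrayImage:
    """Standardize an image: bilinear resize to ``size x size``, then min-max
    rescale intensities to span [0, 255] (a constant image maps to all zeros)."""
    arr = as_pixels(img)
    if arr.size == 0:
        raise ValueError("cannot standardize an empty image")
    if arr.shape != (size, size):
        arr = _bilinear_resize(arr, size, size)
    lo, hi = arr.min(), arr.max()
    if hi <= lo:
        arr = np.zeros_like(arr)
    else:
        arr = np.clip((arr - lo) * (255.0 / (hi - lo)), 0.0, 255.0)
    sid = img.source_id if isinstance(img, GrayImage) else ""
    return GrayImage(arr, source_id=sid)


def skull_strip(img: Union[GrayImage, np.ndarray], band: ThresholdBand) -> GrayImage:
    """Remove non-brain tissue by intensity-band thresholding.

    Pixels with intensity inside ``[band.lower, band.upper]`` are retained;
    everything else (background, bright skull/scalp) is zeroed.  Of the
    retained pixels only the largest 8-connected component survives, which
    discards residual skull arcs and small islands.  This is an automated
    stand-in for interactive threshold segmentation and can be swapped for a
    dedicated brain-extraction tool upstream of the pipeline.
    """
    arr = as_pixels(img)
    in_band = (arr >= band.lower) & (arr <= band.upper)
    if not in_band.any():
        raise EmptyBrainMaskError(
            f"empty brain mask: no pixel inside threshold band [{band.lower}, {band.upper}]"
        )
    labels, n = ndimage.label(in_band, structure=np.ones((3, 3), dtype=int))
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        keep = int(np.argmax(sizes)) + 1
        in_band = labels == keep
    out = np.where(in_band, arr, 0.0)
    sid = img.source_id if isinstance(img, GrayImage) else ""
    return GrayImage(out, source_id=sid)
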