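"""Midline alignment and mirror-difference asymmetry extraction.

A brain slice is assumed to carry an axis of reflective symmetry through its
center.  The alignment stage places that axis on the image's vertical
midline in three steps: binarize the slice, translate its centroid to the
geometric image center, then grid-search the in-plane rotation that
minimizes the mean squared difference between the image and its vertical
mirror.  The asymmetry map is then the pixelwise two-way saturating
subtraction of the aligned image and its mirror,

    D = (L - R)_+ + (R - L)_+  =  |I - mirror(I)|,

which is exactly zero wherever the hemispheres match and carries the gray
level of the mismatch elsewhere.  The two clipped half-differences are kept
explicit because the subtraction is defined on 8-bit semantics (negative
differences floor at zero); their sum coincides with the absolute
difference on the full grid.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Tuple, Union

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .image_io import GrayImage, as_pixels


class BlankImageError(ValueError):
    """Raised when an operation requiring brain content receives an all-zero image."""


@dataclasses.dataclass
class BinaryMask:
    """H x W raster of {0, 1} produced by thresholding, plus the threshold used."""

    pixels: np.ndarray
    threshold_used: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        vals = np.unique(self.pixels)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("BinaryMask values must be exactly 0 or 1")
        self.pixels = self.pixels.astype(np.uint8)


@dataclasses.dataclass(frozen=True)
class AlignmentResult:
    """Pose placing the brain's reflective axis on the vertical midline.

    ``shift_row/shift_col`` are the translation applied to the input;
    ``angle_deg`` the rotation applied afterwards (counter-clockwise
    positive, about the geometric image center); ``symmetry_score`` the mean
    squared mirror difference at the optimum (lower = more symmetric).
    """

    centroid_row: float
    centroid_col: float
    shift_row: float
    shift_col: float
    angle_deg: float
    symmetry_score: float


@dataclasses.dataclass
class AsymmetryMap:
    """Mirror-difference image: 0 where hemispheres match, |L - R| elsewhere."""

    pixels: np.ndarray
    parent_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.min(initial=0.0) < 0 or self.pixels.max(initial=0.0) > 255:
            raise ValueError("AsymmetryMap values must lie in [0, 255]")


def binarize(img: Union[GrayImage, np.ndarray], threshold: Union[float, str] = "auto") -> BinaryMask:
    """Threshold a grayscale image to {0, 1}; pixels strictly above the
    threshold become 1.  ``"auto"`` picks Otsu's threshold computed on the
    histogram of nonzero pixels (the zero background would otherwise dominate
    a skull-stripped slice)."""
    arr = as_pixels(img)
    if not (arr > 0).any():
        raise BlankImageError("cannot binarize an all-zero image")
    if threshold == "auto":
        nz = arr[arr > 0]
        thr = float(threshold_otsu(nz)) if np.unique(nz).size > 1 else 0.0
    else:
        thr = float(threshold)
    return BinaryMask((arr > thr).astype(np.uint8), threshold_used=thr)


def centroid(
    mask: BinaryMask, weights: Optional[Union[GrayImage, np.ndarray]] = None
) -> Tuple[float, float]:
    """Centroid of a binary mask, or the intensity-weighted center of mass.

    Unweighted: mean (row, col) of the nonzero mask pixels.  Weighted: the
    intensity-weighted mean position over all pixels of ``weights``.
    """
    if weights is not None:
        w = as_pixels(weights)
        total = w.sum()
        if total <= 0:
            raise BlankImageError("weighted centroid of an all-zero image is undefined")
        rows, cols = np.mgrid[0 : w.shape[0], 0 : w.shape[1]]
        return float((rows * w).sum() / total), float((cols * w).sum() / total)
    rr, cc = np.nonzero(mask.pixels)
    if rr.size == 0:
        raise BlankImageError("centroid of an empty mask is undefined")
    return float(rr.mean()), float(cc.mean())


def translate_to_center(img: Union[GrayImage, np.ndarray], c: Tuple[float, float]) -> GrayImage:
    """Shift the image so point ``c`` lands on the geometric center
    ``((H-1)/2, (W-1)/2)``.  Subpixel shifts use bilinear interpolation;
    vacated pixels are zero-filled."""
    arr = as_pixels(img)
    h, w = arr.shape
    dr = (h - 1) / 2.0 - c[0]
    dc = (w - 1) / 2.0 - c[1]
    if abs(dr) > h or abs(dc) > w:
        raise ValueError(f"shift ({dr:.1f}, {dc:.1f}) exceeds image size {arr.shape}")
    out = ndimage.shift(arr, (dr, dc), order=1, mode="constant", cval=0.0)
    out = np.clip(out, 0.0, 255.0)
    sid = img.source_id if isinstance(img, GrayImage) else ""
    return GrayImage(out, source_id=sid)


def symmetry_objective(img: Union[GrayImage, np.ndarray]) -> float:
    """Mean squared difference between an image and its vertical mirror,
    averaged over the union support (pixels where either image is nonzero).
    Zero iff the image is perfectly mirror-symmetric on that support."""
    arr = as_pixels(img)
    mir = arr[:, ::-1]
    support = (arr > 0) | (mir > 0)
    if not support.any():
        raise BlankImageError("symmetry objective of a blank image is undefined")
    diff = arr - mir
    return float((diff[support] ** 2).mean())


def rotate_about_center(img: Union[GrayImage, np.ndarray], angle_deg: float) -> GrayImage:
    """Rotate counter-clockwise about the geometric image center, bilinear
    interpolation, zero fill, frame size preserved."""
    arr = as_pixels(img)
    out = ndimage.rotate(arr, angle_deg, reshape=False, order=1, mode="constant", cval=0.0)
    out = np.clip(out, 0.0, 255.0)
    sid = img.source_id if isinstance(img, GrayImage) else ""
    return GrayImage(out, source_id=sid)


def find_symmetry_rotation(
    img: Union[GrayImage, np.ndarray],
    range_deg: float = 15.0,
    step_deg: float = 0.5,
    centroid_rc: Optional[Tuple[float, float]] = None,
    shift_rc: Tuple[float, float] = (0.0, 0.0),
) -> AlignmentResult:
    """Grid-search the rotation maximizing mirror symmetry.

    Evaluates ``symmetry_objective`` after rotating the (centroid-centered)
    image by every angle in ``[-range_deg, +range_deg]`` at ``step_deg``
    spacing and returns the minimizer.  Ties are broken toward the smallest
    ``|angle|``, then toward the negative angle.  The exhaustive grid is
    deliberate: the objective is non-convex in the presence of lesions and a
    deterministic search keeps the stage reproducible.
    """
    arr = as_pixels(img)
    if not (arr > 0).any():
        raise BlankImageError("cannot search rotations of a blank image")
    n = int(round(range_deg / step_deg))
    angles = np.arange(-n, n + 1) * step_deg
    best_angle, best_score = 0.0, np.inf
    for ang in angles:
        score = symmetry_objective(rotate_about_center(arr, float(ang)))
        better = score < best_score - 1e-12
        tie = abs(score - best_score) <= 1e-12 and (
            abs(ang) < abs(best_angle) - 1e-12
            or (abs(abs(ang) - abs(best_angle)) <= 1e-12 and ang < best_angle)
        )
        if better or tie:
            best_angle, best_score = float(ang), float(score)
    cr, cc = centroid_rc if centroid_rc is not None else (float("nan"), float("nan"))
    return AlignmentResult(
        centroid_row=cr,
        centroid_col=cc,
        shift_row=float(shift_rc[0]),
        shift_col=float(shift_rc[1]),
        angle_deg=best_angle,
        symmetry_score=best_score,
    )


def mirror_vertical(img: Union[GrayImage, np.ndarray]) -> GrayImage:
    """Mirror across the vertical axis (reverse column order); an involution."""
    arr = as_pixels(img)
    sid = img.source_id if isinstance(img, GrayImage) else ""
    return GrayImage(arr[:, ::-1].copy(), source_id=sid)


def asymmetry_map(img: Union[GrayImage, np.ndarray]) -> AsymmetryMap:
    """Two-way saturating hemispheric subtraction of an aligned slice.

    With ``M`` the vertical mirror, computes ``clip0(I - M) + clip0(M - I)``
    — the 8-bit reading of subtracting each hemisphere from the other, equal
    to ``|I - M|`` elementwise.  Bilaterally symmetric pixels come out
    exactly 0.
    """
    arr = as_pixels(img)
    mir = arr[:, ::-1]
    d = np.maximum(arr - mir, 0.0) + np.maximum(mir - arr, 0.0)
    sid = img.source_id if isinstance(img, GrayImage) else ""
    return AsymmetryMap(d, parent_id=sid)


def align_and_extract(
    img: Union[GrayImage, np.ndarray],
    threshold: Union[float, str] = "auto",
    angle_range: float = 15.0,
    angle_step: float = 0.5,
    weighted_centroid: bool = False,
) -> Tuple[GrayImage, AsymmetryMap, AlignmentResult]:
    """Full alignment chain on a skull-stripped slice.

    binarize -> centroid -> translate to center -> rotation search -> rotate
    -> asymmetry map.  Returns the aligned image, its asymmetry map, and the
    recovered pose.  Stage failures propagate with the stage named.
    """
    arr = as_pixels(img)
    sid = img.source_id if isinstance(img, GrayImage) else ""
    h, w = arr.shape
    try:
        mask = binarize(arr, threshold)
        c = centroid(mask, weights=arr if weighted_centroid else None)
    except BlankImageError as exc:
        raise BlankImageError(f"alignment failed at stage 'centroid': {exc}") from exc
    shift_rc = ((h - 1) / 2.0 - c[0], (w - 1) / 2.0 - c[1])
    centered = translate_to_center(arr, c)
    try:
        pose = find_symmetry_rotation(
            centered, range_deg=angle_range, step_deg=angle_step, centroid_rc=c, shift_rc=shift_rc
        )
    except BlankImageError as exc:
        raise BlankImageError(f"alignment failed at stage 'rotation-search': {exc}") from exc
    aligned = rotate_about_center(centered, pose.angle_deg)
    aligned.source_id = sid
    amap = asymmetry_map(aligned)
    amap.parent_id = sid
    return aligned, amap, pose
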