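"""Labelled brain-slice phantoms with controlled bilateral asymmetry.

The study's real data (clinical T1 MRI) are access-controlled, so every
pipeline stage is validated against phantoms whose ground truth is known by
construction.  A phantom is a mirror-symmetric base slice — elliptical
"skull" ring, a dark CSF gap, an inner tissue ellipse with smooth symmetric
texture, and a dark medial ventricle pair — on which purely unilateral
Gaussian lesions are painted.  Because the base is symmetric to machine
precision, the phantom's true asymmetry is exactly its lesion content; the
class label controls the lesion amplitude.

Class amplitude defaults encode the clinical ordering the pipeline is meant
to detect: early mild cognitive impairment presents *more* symmetric than
normal aging (asymmetry dips early), while Alzheimer's disease presents
markedly less symmetric, so EMCI < NC < AD.

After the symmetric render the phantom is rotated and shifted (the pose the
alignment stage must recover) and Gaussian noise is added last, so that
alignment has to cope with noisy mirror residuals — as it would on real
scans.  Everything is a pure function of the spec's seed.
"""

from __future__ import annotations

import dataclasses
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy import ndimage

from .image_io import GrayImage
from .symmetry import BinaryMask

LABELS = ("NC", "EMCI", "AD")

#: Default unilateral lesion amplitude (intensity units) per diagnostic class.
CLASS_AMPLITUDES: Dict[str, float] = {"EMCI": 2.0, "NC": 6.0, "AD": 14.0}

# Base-slice geometry (256 x 256 frame), intensities chosen so that tissue
# stays inside a [60, 200] skull-strip band while skull (240), CSF gap (25)
# and background (0) fall outside it.
_SIZE = 256
_SKULL_OUT = (112.0, 88.0)  # (row, col) semi-axes
_SKULL_IN = (104.0, 80.0)
_TISSUE = (96.0, 72.0)
_SKULL_LEVEL = 240.0
_GAP_LEVEL = 25.0
_TISSUE_LEVEL = 130.0
_TEXTURE_AMP = 22.0
_VENT_LEVEL = 70.0
_VENT_OFFSET = 22.0  # ventricle center distance from the midline (columns)
_VENT_AXES = (30.0, 9.0)


@dataclasses.dataclass
class PhantomSpec:
    """Parameters of one phantom; fully determines the rendered image."""

    label: str
    seed: int
    asymmetry_amplitude: Optional[float] = None  # default: class amplitude
    n_lesions: int = 3
    lesion_radius: float = 8.0
    rotation_deg: float = 0.0
    shift: Tuple[float, float] = (0.0, 0.0)
    noise_sigma: float = 0.0
    skull: bool = True

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")
        if self.asymmetry_amplitude is None:
            self.asymmetry_amplitude = CLASS_AMPLITUDES[self.label]
        if self.asymmetry_amplitude < 0 or self.noise_sigma < 0 or self.n_lesions < 0:
            raise ValueError("amplitude, noise_sigma and n_lesions must be non-negative")


@dataclasses.dataclass
class PhantomBundle:
    """Rendered phantom plus its ground truth (pre-noise, in the posed frame)."""

    image: GrayImage
    truth_mask_tissue: BinaryMask
    truth_lesions: List[Tuple[float, float, float, float]]  # (row, col, radius, amplitude)
    truth_pose: Tuple[float, Tuple[float, float]]  # (rotation_deg, (shift_r, shift_c))
    spec: PhantomSpec


def _ellipse_mask(shape: Tuple[int, int], center: Tuple[float, float], axes: Tuple[float, float]) -> np.ndarray:
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    return ((rr - center[0]) / axes[0]) ** 2 + ((cc - center[1]) / axes[1]) ** 2 <= 1.0


def _symmetric_texture(rng: np.random.Generator, shape: Tuple[int, int]) -> np.ndarray:
    """Smooth random field, symmetrized by averaging with its own mirror."""
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    field = np.zeros(shape)
    for _ in range(8):
        r0 = rng.uniform(40, shape[0] - 40)
        c0 = rng.uniform(40, shape[1] - 40)
        amp = rng.uniform(-1.0, 1.0)
        sig = rng.uniform(12, 28)
        field += amp * np.exp(-((rr - r0) ** 2 + (cc - c0) ** 2) / (2 * sig**2))
    field = 0.5 * (field + field[:, ::-1])
    peak = np.abs(field).max()
    return field * (_TEXTURE_AMP / peak) if peak > 0 else field


def _place_lesions(
    rng: np.random.Generator, spec: PhantomSpec, tissue: np.ndarray
) -> List[Tuple[float, float, float, float]]:
    h, w = tissue.shape
    cr, cc = (h - 1) / 2.0, (w - 1) / 2.0
    sigma = spec.lesion_radius / 2.0
    reach = 3.0 * sigma  # truncation radius of the painted blob
    lesions = []
    for _ in range(spec.n_lesions):
        for attempt in range(100):
            side = rng.integers(0, 2)  # 0 = left hemisphere, 1 = right
            r_lo, r_hi = cr - _TISSUE[0] + reach, cr + _TISSUE[0] - reach
            lo, hi = (reach + 2, cc - reach - 2) if side == 0 else (cc + reach + 2, w - reach - 2)
            if r_lo >= r_hi or lo >= hi:  # footprint cannot fit at all
                continue
            r0 = rng.uniform(r_lo, r_hi)
            c0 = rng.uniform(lo, hi)
            # whole footprint inside tissue, clear of the midline
            inside = ((r0 - cr) / (_TISSUE[0] - reach)) ** 2 + ((c0 - cc) / (_TISSUE[1] - reach)) ** 2 <= 1.0
            if inside and abs(c0 - cc) > reach + 1:
                lesions.append((r0, c0, spec.lesion_radius, float(spec.asymmetry_amplitude)))
                break
        else:
            raise RuntimeError("could not place a lesion inside tissue after 100 tries")
    return lesions


def _paint_lesion(img: np.ndarray, r0: float, c0: float, radius: float, amp: float) -> None:
    sigma = radius / 2.0
    reach = int(np.ceil(3.0 * sigma))
    r_lo, r_hi = int(np.floor(r0)) - reach, int(np.floor(r0)) + reach + 1
    c_lo, c_hi = int(np.floor(c0)) - reach, int(np.floor(c0)) + reach + 1
    rr, cc = np.mgrid[r_lo:r_hi, c_lo:c_hi]
    d2 = (rr - r0) ** 2 + (cc - c0) ** 2
    blob = amp * np.exp(-d2 / (2 * sigma**2))
    blob[d2 > (3.0 * sigma) ** 2] = 0.0  # hard truncation: finite footprint
    img[r_lo:r_hi, c_lo:c_hi] += blob


def generate_phantom(spec: PhantomSpec) -> PhantomBundle:
    """Render one phantom: symmetric base + unilateral lesions + pose + noise."""
    rng = np.random.default_rng(spec.seed)
    shape = (_SIZE, _SIZE)
    center = ((_SIZE - 1) / 2.0, (_SIZE - 1) / 2.0)

    img = np.zeros(shape)
    if spec.skull:
        ring = _ellipse_mask(shape, center, _SKULL_OUT) & ~_ellipse_mask(shape, center, _SKULL_IN)
        img[ring] = _SKULL_LEVEL
        gap = _ellipse_mask(shape, center, _SKULL_IN) & ~_ellipse_mask(shape, center, _TISSUE)
        img[gap] = _GAP_LEVEL
    tissue = _ellipse_mask(shape, center, _TISSUE)
    img[tissue] = _TISSUE_LEVEL
    img[tissue] += _symmetric_texture(rng, shape)[tissue]
    for dc in (-_VENT_OFFSET, _VENT_OFFSET):
        vent = _ellipse_mask(shape, (center[0], center[1] + dc), _VENT_AXES)
        img[vent & tissue] = _VENT_LEVEL

    lesions = _place_lesions(rng, spec, tissue) if spec.n_lesions else []
    for r0, c0, radius, amp in lesions:
        _paint_lesion(img, r0, c0, radius, amp)

    truth = tissue.astype(np.float64)
    if spec.rotation_deg != 0.0:
        img = ndimage.rotate(img, spec.rotation_deg, reshape=False, order=1, mode="constant", cval=0.0)
        truth = ndimage.rotate(truth, spec.rotation_deg, reshape=False, order=0, mode="constant", cval=0.0)
    if spec.shift != (0.0, 0.0):
        img = ndimage.shift(img, spec.shift, order=1, mode="constant", cval=0.0)
        truth = ndimage.shift(truth, spec.shift, order=0, mode="constant", cval=0.0)
    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, size=shape)
    img = np.clip(img, 0.0, 255.0)

    sid = f"phantom_{spec.label}_{spec.seed}"
    return PhantomBundle(
        image=GrayImage(img, source_id=sid),
        truth_mask_tissue=BinaryMask(truth > 0.5, threshold_used=0.5),
        truth_lesions=lesions,
        truth_pose=(spec.rotation_deg, spec.shift),
        spec=spec,
    )


def generate_cohort(
    n_per_class: int,
    class_params: Optional[Dict[str, float]] = None,
    seed: int = 0,
    n_lesions: int = 3,
    lesion_radius: float = 8.0,
    max_rotation_deg: float = 8.0,
    max_shift_px: float = 8.0,
    noise_sigma: float = 2.0,
) -> List[PhantomBundle]:
    """Balanced labelled cohort with randomized pose and noise.

    ``class_params`` maps label -> lesion amplitude; defaults reproduce the
    EMCI < NC < AD asymmetry ordering.  Per-image seeds are derived from the
    master seed, so the cohort is reproducible bit-for-bit.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    amplitudes = dict(CLASS_AMPLITUDES)
    if class_params:
        amplitudes.update(class_params)
    master = np.random.default_rng(seed)
    bundles = []
    for label in LABELS:
        for _ in range(n_per_class):
            child_seed = int(master.integers(0, 2**31 - 1))
            pose_rng = np.random.default_rng(child_seed + 1)
            spec = PhantomSpec(
                label=label,
                seed=child_seed,
                asymmetry_amplitude=amplitudes[label],
                n_lesions=n_lesions,
                lesion_radius=lesion_radius,
                rotation_deg=float(pose_rng.uniform(-max_rotation_deg, max_rotation_deg)),
                shift=(
                    float(pose_rng.uniform(-max_shift_px, max_shift_px)),
                    float(pose_rng.uniform(-max_shift_px, max_shift_px)),
                ),
                noise_sigma=noise_sigma,
            )
            bundles.append(generate_phantom(spec))
    return bundles
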