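"""Asymmetry-map descriptors: wavelet texture statistics and bag-of-features.

Each asymmetry map is summarized by a fixed, ordered 10-statistic vector
(MSE, Mean, Std, Entropy, RMS, Variance, Smoothness, Kurtosis, Skewness,
IDM).  The MSE is the one statistic computed *without* a wavelet transform:
it is the mean squared difference between the aligned slice and its mirror,
i.e. the global magnitude of hemispheric asymmetry.  The remaining nine are
texture statistics of the approximation subband of a 2D discrete wavelet
transform of the map (Haar, one level, by default): moments, Shannon
entropy of the 256-bin subband histogram, smoothness 1 - 1/(1 + sigma^2) on
unit-scaled values, and the inverse difference moment of a normalized
symmetric gray-level co-occurrence matrix.

Moment conventions: population (biased) estimators throughout; kurtosis is
non-excess (a Gaussian scores 3).  These choices make the internal
identities Variance = Std^2 and RMS^2 = Mean^2 + Variance hold exactly.

The bag-of-features channel mimics the classical SURF + K-Means recipe:
blob-like interest points from a Determinant-of-Hessian detector, 64-dim
gradient descriptors (4x4 subregions x (sum dx, sum |dx|, sum dy, sum |dy|)
over a window scaled to the keypoint), a K-Means codebook, and an
L1-normalized occurrence histogram per image.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import pywt
from scipy import ndimage, stats
from skimage.feature import blob_doh, graycomatrix
from sklearn.cluster import KMeans

from .image_io import GrayImage, as_pixels
from .symmetry import AsymmetryMap

STAT_NAMES = ("mse", "mean", "std", "entropy", "rms", "variance",
              "smoothness", "kurtosis", "skewness", "idm")


@dataclasses.dataclass(frozen=True)
class StatFeatureVector:
    """The ordered 10-statistic descriptor of one asymmetry map."""

    mse: float
    mean: float
    std: float
    entropy: float
    rms: float
    variance: float
    smoothness: float
    kurtosis: float
    skewness: float
    idm: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in STAT_NAMES], dtype=np.float64)

    @classmethod
    def from_array(cls, arr: Sequence[float]) -> "StatFeatureVector":
        arr = np.asarray(arr, dtype=np.float64)
        if arr.shape != (len(STAT_NAMES),):
            raise ValueError(f"expected {len(STAT_NAMES)} statistics, got shape {arr.shape}")
        return cls(*map(float, arr))


@dataclasses.dataclass
class Codebook:
    """K-Means visual vocabulary over local descriptors."""

    centers: np.ndarray
    k: int
    descriptor_dim: int
    seed: int

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=np.float64)
        if self.k < 2:
            raise ValueError("codebook size k must be >= 2")
        if self.centers.shape != (self.k, self.descriptor_dim):
            raise ValueError("centers shape inconsistent with (k, descriptor_dim)")


@dataclasses.dataclass
class FeatureRecord:
    """All features of one image: statistics, BOF histogram, class label."""

    source_id: str
    stats: StatFeatureVector
    label: str
    bof_hist: Optional[np.ndarray] = None


# ---------------------------------------------------------------------------
# statistical features
# ---------------------------------------------------------------------------

def mirror_mse(original: Union[GrayImage, np.ndarray], mirrored: Union[GrayImage, np.ndarray]) -> float:
    """Mean over all pixels of the squared difference between an image and
    its mirrored counterpart — the scalar magnitude of hemispheric asymmetry."""
    a, b = as_pixels(original), as_pixels(mirrored)
    if a.shape != b.shape:
        raise ValueError(f"dimension mismatch: {a.shape} vs {b.shape}")
    return float(((a - b) ** 2).mean())


def dwt_approx(
    amap: Union[AsymmetryMap, GrayImage, np.ndarray], wavelet: str = "db1", level: int = 1
) -> np.ndarray:
    """Approximation (low-pass) subband of a 2D separable DWT at ``level``.

    With the default Haar filter each decomposition level halves both
    dimensions and scales a constant image by 2 (1D low-pass gain sqrt(2),
    applied along rows and columns).
    """
    arr = amap.pixels if isinstance(amap, (AsymmetryMap, GrayImage)) else np.asarray(amap, np.float64)
    if arr.size == 0:
        raise ValueError("cannot transform an empty map")
    if level < 1:
        raise ValueError("decomposition level must be >= 1")
    wav = pywt.Wavelet(wavelet)
    if min(arr.shape) < wav.dec_len:
        raise ValueError(f"image {arr.shape} smaller than the {wavelet} filter support")
    coeffs = pywt.wavedec2(arr, wav, level=level)
    return np.asarray(coeffs[0], dtype=np.float64)


def _shannon_entropy_bits(values: np.ndarray) -> float:
    """Shannon entropy (base 2) of the 256-bin histogram of values min-max
    rescaled to [0, 255]; a constant input has entropy 0."""
    lo, hi = values.min(), values.max()
    scaled = np.zeros_like(values) if hi <= lo else (values - lo) * (255.0 / (hi - lo))
    counts, _ = np.histogram(scaled, bins=256, range=(0.0, 256.0))
    p = counts[counts > 0] / values.size
    return float(-(p * np.log2(p)).sum())


def _quantize_256(values: np.ndarray) -> np.ndarray:
    lo, hi = values.min(), values.max()
    if hi <= lo:
        return np.zeros(values.shape, dtype=np.uint8)
    return np.clip(np.rint((values - lo) * (255.0 / (hi - lo))), 0, 255).astype(np.uint8)


def inverse_difference_moment(values: np.ndarray, normalized: bool = True) -> float:
    """IDM (homogeneity) of the gray-level co-occurrence matrix.

    GLCM with offset (0, 1), 256 levels, symmetric; ``normalized`` divides by
    the number of co-occurrences so IDM lies in (0, 1] (1 for a constant
    image).  The unnormalized variant is kept as a compatibility option for
    workflows that report raw co-occurrence counts.
    """
    q = _quantize_256(values)
    glcm = graycomatrix(q, distances=[1], angles=[0], levels=256,
                        symmetric=True, normed=normalized)[:, :, 0, 0].astype(np.float64)
    i, j = np.ogrid[0:256, 0:256]
    return float((glcm / (1.0 + (i - j) ** 2)).sum())


def stat_features(
    amap: Union[AsymmetryMap, np.ndarray],
    original: Union[GrayImage, np.ndarray],
    wavelet: str = "db1",
    level: int = 1,
    idm_normalized: bool = True,
) -> StatFeatureVector:
    """Compute the ordered 10-statistic vector for one asymmetry map.

    ``original`` is the aligned slice from which the map was derived; the MSE
    statistic compares it against its own vertical mirror.  All other
    statistics are computed on the DWT approximation subband of the map.  For
    an all-zero (perfectly symmetric) map kurtosis and skewness are
    undefined; they are reported as 0 with a warning.
    """
    orig = as_pixels(original)
    mse = mirror_mse(orig, orig[:, ::-1])
    sub = dwt_approx(amap, wavelet=wavelet, level=level).ravel()

    mean = float(sub.mean())
    var = float(sub.var())  # population convention
    std = float(np.sqrt(var))
    rms = float(np.sqrt((sub**2).mean()))
    entropy = _shannon_entropy_bits(sub)

    lo, hi = sub.min(), sub.max()
    unit = np.zeros_like(sub) if hi <= lo else (sub - lo) / (hi - lo)
    smoothness = float(1.0 - 1.0 / (1.0 + unit.var()))

    if std == 0.0:
        warnings.warn("kurtosis/skewness undefined for a constant subband; reporting 0",
                      RuntimeWarning, stacklevel=2)
        kurt, skew = 0.0, 0.0
    else:
        kurt = float(stats.kurtosis(sub, fisher=False, bias=True))
        skew = float(stats.skew(sub, bias=True))

    idm = inverse_difference_moment(sub.reshape(dwt_approx(amap, wavelet, level).shape),
                                    normalized=idm_normalized)
    return StatFeatureVector(mse, mean, std, entropy, rms, var, smoothness, kurt, skew, idm)


# ---------------------------------------------------------------------------
# dataset-level summaries
# ---------------------------------------------------------------------------

def stats_matrix(records: Sequence[FeatureRecord]) -> np.ndarray:
    return np.stack([r.stats.as_array() for r in records])


def normalize_features(
    records: Sequence[FeatureRecord], return_bounds: bool = False
):
    """Min-max scale every statistic to [0, 1] across the dataset.

    A constant column maps to all zeros.  With ``return_bounds`` the
    per-feature (min, max) pair is returned too, which inverts the scaling.
    """
    if len(records) < 2:
        raise ValueError("normalization needs at least 2 records")
    X = stats_matrix(records)
    lo, hi = X.min(axis=0), X.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    Xn = np.where(hi > lo, (X - lo) / span, 0.0)
    out = [
        dataclasses.replace(r, stats=StatFeatureVector.from_array(row))
        for r, row in zip(records, Xn)
    ]
    return (out, (lo, hi)) if return_bounds else out


def class_feature_means(records: Sequence[FeatureRecord]) -> pd.DataFrame:
    """Per-class arithmetic mean of each statistic (rows: class, cols: feature)."""
    if not records:
        raise ValueError("no records")
    df = pd.DataFrame(stats_matrix(records), columns=list(STAT_NAMES))
    df["label"] = [r.label for r in records]
    return df.groupby("label").mean()


def mse_pareto(records: Sequence[FeatureRecord]) -> pd.DataFrame:
    """Pareto ordering of per-class MSE totals.

    Returns classes sorted by descending total mirror-MSE with each class's
    cumulative percentage of the grand total — the chart that ranks disease
    stages by how much hemispheric asymmetry they contribute.
    """
    if not records:
        raise ValueError("no records")
    totals: Dict[str, float] = {}
    for r in records:
        totals[r.label] = totals.get(r.label, 0.0) + r.stats.mse
    df = pd.DataFrame(
        sorted(totals.items(), key=lambda kv: -kv[1]), columns=["label", "total_mse"]
    ).set_index("label")
    df["cumulative_pct"] = 100.0 * df["total_mse"].cumsum() / df["total_mse"].sum()
    return df


# ---------------------------------------------------------------------------
# bag of features
# ---------------------------------------------------------------------------

DESCRIPTOR_DIM = 64
_PATCH_SAMPLES = 16  # descriptor window resampled to 16x16 before pooling


def detect_keypoints(
    arr: np.ndarray,
    min_sigma: float = 2.0,
    max_sigma: float = 12.0,
    threshold: float = 0.001,
    dense_fallback: bool = True,
    min_keypoints: int = 8,
) -> np.ndarray:
    """Blob-like interest points as rows of (row, col, sigma).

    Uses a Determinant-of-Hessian detector; if it yields fewer than
    ``min_keypoints`` (flat or nearly symmetric maps), falls back to a dense
    grid of keypoints at a fixed scale so every image remains encodable.
    """
    blobs = blob_doh(arr / 255.0, min_sigma=min_sigma, max_sigma=max_sigma,
                     num_sigma=8, threshold=threshold)
    if len(blobs) < min_keypoints and dense_fallback:
        step = 16
        rr, cc = np.mgrid[step // 2 : arr.shape[0] : step, step // 2 : arr.shape[1] : step]
        blobs = np.column_stack([rr.ravel(), cc.ravel(), np.full(rr.size, 3.0)])
    return np.asarray(blobs, dtype=np.float64)


def _descriptors_at(arr: np.ndarray, keypoints: np.ndarray) -> np.ndarray:
    """64-dim gradient descriptors at the given (row, col, sigma) keypoints.

    The window of half-size 10*sigma around a keypoint is resampled to a
    fixed 16x16 grid of Gaussian-smoothed gradient samples (edge-clamped),
    split into 4x4 subregions, and each subregion pooled into
    (sum dx, sum |dx|, sum dy, sum |dy|); the 64-vector is L2-normalized.
    """
    out = np.zeros((len(keypoints), DESCRIPTOR_DIM))
    smooth_cache: Dict[float, Tuple[np.ndarray, np.ndarray]] = {}
    for idx, (r0, c0, sigma) in enumerate(keypoints):
        sigma = max(float(sigma), 1.0)
        if sigma not in smooth_cache:
            sm = ndimage.gaussian_filter(arr, sigma)
            gy, gx = np.gradient(sm)
            smooth_cache[sigma] = (gy, gx)
        gy, gx = smooth_cache[sigma]
        half = 10.0 * sigma
        lin = np.linspace(-half, half, _PATCH_SAMPLES)
        rows = np.clip(r0 + lin, 0, arr.shape[0] - 1)
        cols = np.clip(c0 + lin, 0, arr.shape[1] - 1)
        grid = np.meshgrid(rows, cols, indexing="ij")
        dx = ndimage.map_coordinates(gx, grid, order=1, mode="nearest")
        dy = ndimage.map_coordinates(gy, grid, order=1, mode="nearest")
        vec = []
        q = _PATCH_SAMPLES // 4
        for bi in range(4):
            for bj in range(4):
                sx = dx[bi * q : (bi + 1) * q, bj * q : (bj + 1) * q]
                sy = dy[bi * q : (bi + 1) * q, bj * q : (bj + 1) * q]
                vec.extend([sx.sum(), np.abs(sx).sum(), sy.sum(), np.abs(sy).sum()])
        v = np.asarray(vec)
        norm = np.linalg.norm(v)
        out[idx] = v / norm if norm > 0 else v
    return out


def extract_descriptors(
    amap: Union[AsymmetryMap, GrayImage, np.ndarray], retain_fraction: float = 0.8
) -> np.ndarray:
    """Detect keypoints and describe them; keep the strongest ``retain_fraction``
    by blob response (Laplacian magnitude at the keypoint's scale)."""
    arr = amap.pixels if isinstance(amap, (AsymmetryMap, GrayImage)) else np.asarray(amap, np.float64)
    kps = detect_keypoints(arr)
    if len(kps) == 0:
        return np.zeros((0, DESCRIPTOR_DIM))
    if 0 < retain_fraction < 1 and len(kps) > 4:
        log_cache: Dict[float, np.ndarray] = {}
        strengths = np.empty(len(kps))
        for i, (r0, c0, sigma) in enumerate(kps):
            sigma = max(float(sigma), 1.0)
            if sigma not in log_cache:
                log_cache[sigma] = ndimage.gaussian_laplace(arr, sigma)
            strengths[i] = sigma**2 * abs(log_cache[sigma][int(round(r0)), int(round(c0))])
        keep = np.argsort(-strengths, kind="stable")[: max(4, int(np.ceil(retain_fraction * len(kps))))]
        kps = kps[np.sort(keep)]
    return _descriptors_at(arr, kps)


def bof_fit_descriptors(descriptor_sets: Sequence[np.ndarray], k: int, seed: int) -> Codebook:
    """Fit the K-Means codebook on pre-extracted per-image descriptor sets."""
    desc = [d for ds in descriptor_sets for d in np.asarray(ds)]
    if len(desc) < k:
        raise ValueError(
            f"only {len(desc)} descriptors extracted across the corpus but k={k}; "
            "reduce k or enable the dense-grid fallback on more images"
        )
    X = np.stack(desc)
    km = KMeans(n_clusters=k, init="k-means++", n_init=10, random_state=seed % (2**31))
    km.fit(X)
    centers = km.cluster_centers_
    # a vocabulary with coincident words cannot disambiguate assignments
    if len(np.unique(np.round(centers, 12), axis=0)) < k:
        raise ValueError("K-Means produced duplicate centers (degenerate corpus); reduce k")
    return Codebook(centers=centers, k=k, descriptor_dim=X.shape[1], seed=seed)


def bof_fit(
    maps: Sequence[Union[AsymmetryMap, np.ndarray]],
    k: int = 500,
    seed: int = 0,
    retain_fraction: float = 0.8,
) -> Codebook:
    """Build the visual vocabulary over a corpus of maps: pooled descriptors
    quantized by K-Means (k-means++ init, fixed seed, deterministic)."""
    return bof_fit_descriptors([extract_descriptors(m, retain_fraction) for m in maps], k, seed)


def encode_descriptors(desc: np.ndarray, cb: Codebook) -> np.ndarray:
    """Nearest-center occurrence histogram of a descriptor set, L1-normalized.
    An empty descriptor set encodes as the uniform histogram (with a warning)."""
    desc = np.asarray(desc, dtype=np.float64)
    if desc.size and desc.shape[1] != cb.descriptor_dim:
        raise ValueError(f"descriptor dim {desc.shape[1]} != codebook dim {cb.descriptor_dim}")
    if len(desc) == 0:
        warnings.warn("no descriptors found; encoding as uniform histogram", RuntimeWarning)
        return np.full(cb.k, 1.0 / cb.k)
    d2 = ((desc[:, None, :] - cb.centers[None, :, :]) ** 2).sum(axis=2)
    nearest = d2.argmin(axis=1)
    hist = np.bincount(nearest, minlength=cb.k).astype(np.float64)
    return hist / hist.sum()


def bof_encode(
    amap: Union[AsymmetryMap, np.ndarray], cb: Codebook, retain_fraction: float = 0.8
) -> np.ndarray:
    """Encode one asymmetry map against a fitted codebook."""
    return encode_descriptors(extract_descriptors(amap, retain_fraction), cb)


# ---------------------------------------------------------------------------
# tabular interchange
# ---------------------------------------------------------------------------

def records_to_frame(records: Sequence[FeatureRecord]) -> pd.DataFrame:
    """Flatten records into the features table: source_id, label, the 10
    named statistics in fixed order, then bof_000... columns if present."""
    rows = []
    for r in records:
        row: Dict[str, object] = {"source_id": r.source_id, "label": r.label}
        row.update(dict(zip(STAT_NAMES, r.stats.as_array())))
        if r.bof_hist is not None:
            row.update({f"bof_{i:03d}": v for i, v in enumerate(r.bof_hist)})
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_records(df: pd.DataFrame) -> List[FeatureRecord]:
    bof_cols = sorted(c for c in df.columns if c.startswith("bof_"))
    records = []
    for _, row in df.iterrows():
        records.append(
            FeatureRecord(
                source_id=str(row["source_id"]),
                label=str(row["label"]),
                stats=StatFeatureVector.from_array([row[n] for n in STAT_NAMES]),
                bof_hist=row[bof_cols].to_numpy(dtype=np.float64) if bof_cols else None,
            )
        )
    return records
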