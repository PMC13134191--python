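"""Hand-crafted radiomics features over a binary lesion mask.

Implements the feature families used by the classification ensemble —
first-order statistics, 3D shape descriptors, and the three texture
matrices GLSZM (zone-based), GLDM (dependence-based) and NGTDM
(neighborhood-based) — computed on the original image, a logarithm-filtered
image, and the eight sub-bands of a single-level undecimated 3D wavelet
transform.

Conventions follow the common fixed-bin-width radiomics toolkit practice:

* discretization is min-anchored with a fixed bin width (default 25), so
  every feature is invariant to adding a constant to all intensities;
* texture zones/dependencies use 26-connected 3D neighborhoods;
* feature names follow ``<image_filter>_<class>_<Feature>`` (e.g.
  ``wavelet-HHH_glszm_LargeAreaEmphasis``, ``original_shape_Elongation``).

Degenerate inputs (single-voxel ROI, zero-variance ROI) yield a documented
sentinel value of 0.0 with a logged warning, never a crash — the
downstream variance filter removes such columns naturally.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError

from .imaging_core import VolumeGrid, MultiLabelMask, binarize

logger = logging.getLogger(__name__)

_EPS = np.spacing(1.0)


@dataclass(frozen=True)
class FeatureExtractionConfig:
    """Extraction settings (all exposed; defaults follow common toolkit use)."""

    bin_width: float = 25.0
    wavelet: str = "coif1"
    connectivity: int = 26
    gldm_alpha: float = 0.0
    filters: tuple[str, ...] = ("original", "logarithm", "wavelet")


@dataclass(frozen=True)
class DiscretizedRoi:
    """Gray-level lattice over a ROI: integer levels 1..Ng inside, 0 outside."""

    levels: np.ndarray       # 3D int array, 0 outside ROI
    mask: np.ndarray         # 3D bool array
    ng: int                  # number of gray levels
    np_: int                 # number of ROI voxels
    voxel_volume: float      # mm^3
    bin_width: float


def discretize(volume: np.ndarray, roi_mask: np.ndarray, bin_width: float,
               voxel_volume: float = 1.0) -> DiscretizedRoi:
    """Fixed-bin-width discretization: level = floor((x - min_roi)/w) + 1."""
    volume = np.asarray(volume, dtype=float)
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if not roi_mask.any():
        raise ValueError("empty ROI")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    vals = volume[roi_mask]
    lo = vals.min()
    levels = np.zeros(volume.shape, dtype=np.int64)
    levels[roi_mask] = np.floor((volume[roi_mask] - lo) / bin_width).astype(np.int64) + 1
    ng = int(levels.max())
    return DiscretizedRoi(levels=levels, mask=roi_mask, ng=ng,
                          np_=int(roi_mask.sum()), voxel_volume=voxel_volume,
                          bin_width=float(bin_width))


# --------------------------------------------------------------------------
# Image filters
# --------------------------------------------------------------------------

def wavelet_subbands(volume: np.ndarray, wavelet: str = "coif1") -> dict[str, np.ndarray]:
    """Single-level undecimated separable 3D wavelet transform.

    Returns 8 shape-preserving sub-bands keyed 'LLL'..'HHH'; the k-th letter
    is the filter (L=low-pass, H=high-pass) applied along axis k.  Periodic
    boundary handling keeps the orthogonal filter bank energy-conserving.
    """
    volume = np.asarray(volume, dtype=float)
    if volume.ndim != 3:
        raise ValueError("expected a 3D volume")
    w = pywt.Wavelet(wavelet)
    # 1/sqrt(2) per axis: the undecimated analysis bank then conserves energy
    # (|L|^2 + |H|^2 = 1 at every frequency for an orthogonal pair)
    filters = {"L": np.asarray(w.dec_lo) / np.sqrt(2.0),
               "H": np.asarray(w.dec_hi) / np.sqrt(2.0)}
    flen = len(w.dec_lo)
    if min(volume.shape) < flen:
        raise ValueError(
            f"every dimension must be >= filter length {flen}, got {volume.shape}"
        )
    out: dict[str, np.ndarray] = {}
    # precompute the two 1D convolutions per axis, then combine
    partial = {"": volume}
    for axis in range(3):
        nxt = {}
        for key, arr in partial.items():
            for letter, filt in filters.items():
                nxt[key + letter] = ndimage.convolve1d(arr, filt, axis=axis,
                                                       mode="wrap")
        partial = nxt
    for key, arr in partial.items():
        out[key] = arr
    return out


def logarithm_filter(volume: np.ndarray) -> np.ndarray:
    """Logarithm image filter: log(1 + x - min(x)), rescaled to the input range.

    Compresses bright outliers while preserving the intensity range, so
    min-anchored discretization behaves comparably across filters.
    """
    volume = np.asarray(volume, dtype=float)
    shifted = volume - volume.min()
    logged = np.log1p(shifted)
    rng = shifted.max()
    if logged.max() > 0 and rng > 0:
        logged = logged * (rng / logged.max())
    return logged + volume.min()


# --------------------------------------------------------------------------
# First-order features
# --------------------------------------------------------------------------

FIRSTORDER_NAMES = (
    "Energy", "TotalEnergy", "Entropy", "Minimum", "10Percentile",
    "90Percentile", "Maximum", "Mean", "Median", "InterquartileRange",
    "Range", "MeanAbsoluteDeviation", "RobustMeanAbsoluteDeviation",
    "RootMeanSquared", "StandardDeviation", "Skewness", "Kurtosis",
    "Variance", "Uniformity",
)


def first_order_features(values: np.ndarray, voxel_volume: float,
                         bin_width: float = 25.0) -> dict[str, float]:
    """19 first-order statistics of the ROI intensity distribution.

    Kurtosis is non-excess (Gaussian -> 3); Variance is population-style
    (divide by N).  Entropy/Uniformity use the fixed-bin-width histogram.
    Zero-variance ROIs report Skewness/Kurtosis as sentinel 0 (logged).
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty ROI")
    n = x.size
    mean = float(x.mean())
    var = float(x.var())  # population
    m2 = var
    if m2 > 0 and n >= 2:
        m3 = float(((x - mean) ** 3).mean())
        m4 = float(((x - mean) ** 4).mean())
        skew = m3 / m2 ** 1.5
        kurt = m4 / m2 ** 2
    else:
        logger.debug("zero-variance ROI: Skewness/Kurtosis sentinel 0")
        skew = kurt = 0.0
    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    inner = x[(x >= p10) & (x <= p90)]
    rmad = float(np.abs(inner - inner.mean()).mean()) if inner.size else 0.0
    # histogram probabilities at the same bin width as texture discretization
    nbins = max(1, int(np.floor((x.max() - x.min()) / bin_width)) + 1)
    counts = np.bincount(
        np.floor((x - x.min()) / bin_width).astype(int), minlength=nbins
    ).astype(float)
    p = counts[counts > 0] / n
    return {
        "Energy": float((x ** 2).sum()),
        "TotalEnergy": float(voxel_volume * (x ** 2).sum()),
        "Entropy": float(-(p * np.log2(p)).sum()),
        "Minimum": float(x.min()),
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Maximum": float(x.max()),
        "Mean": mean,
        "Median": float(p50),
        "InterquartileRange": float(p75 - p25),
        "Range": float(x.max() - x.min()),
        "MeanAbsoluteDeviation": float(np.abs(x - mean).mean()),
        "RobustMeanAbsoluteDeviation": rmad,
        "RootMeanSquared": float(np.sqrt((x ** 2).mean())),
        "StandardDeviation": float(np.sqrt(var)),
        "Skewness": float(skew),
        "Kurtosis": float(kurt),
        "Variance": var,
        "Uniformity": float((p ** 2).sum()),
    }


# --------------------------------------------------------------------------
# Shape features
# --------------------------------------------------------------------------

SHAPE_NAMES = (
    "VoxelVolume", "SurfaceArea", "SurfaceVolumeRatio", "Sphericity",
    "Compactness", "Maximum3DDiameter", "Maximum2DDiameterSlice",
    "Maximum2DDiameterColumn", "Maximum2DDiameterRow", "MajorAxisLength",
    "MinorAxisLength", "LeastAxisLength", "Elongation", "Flatness",
)


def _voxel_surface_area(binary: np.ndarray, spacing) -> float:
    """Total area of exposed voxel faces (voxelized surface approximation)."""
    sx, sy, sz = spacing
    face = {0: sy * sz, 1: sx * sz, 2: sx * sy}
    area = 0.0
    for axis in range(3):
        for shift in (1, -1):
            shifted = np.roll(binary, shift, axis=axis)
            # rolled-in border voxels are outside the volume -> background
            sl = [slice(None)] * 3
            sl[axis] = 0 if shift == 1 else -1
            shifted[tuple(sl)] = False
            area += face[axis] * np.count_nonzero(binary & ~shifted)
    return float(area)


def _max_pairwise(points: np.ndarray) -> float:
    """Largest pairwise Euclidean distance; uses hull vertices when possible."""
    if len(points) < 2:
        return 0.0
    pts = points
    if len(points) > 50:
        try:
            hull = ConvexHull(points)
            pts = points[hull.vertices]
        except QhullError:
            pass
    d = pts[:, None, :] - pts[None, :, :]
    return float(np.sqrt((d ** 2).sum(-1)).max())


def shape_features(binary: np.ndarray,
                   spacing: tuple[float, float, float]) -> dict[str, float]:
    """3D shape descriptors from physical voxel-center coordinates.

    Elongation = sqrt(λ2/λ1), Flatness = sqrt(λ3/λ1) with λ1 >= λ2 >= λ3 the
    covariance eigenvalues (value 1 = isotropic in the leading plane).
    Degenerate covariance gives Elongation/Flatness 0 with a warning.
    """
    binary = np.asarray(binary, dtype=bool)
    np_vox = int(binary.sum())
    if np_vox < 1:
        raise ValueError("empty mask")
    sp = np.asarray(spacing, dtype=float)
    voxel_volume = float(np.prod(sp))
    coords = np.argwhere(binary) * sp
    volume = np_vox * voxel_volume
    area = _voxel_surface_area(binary, spacing)
    sentinel = dict.fromkeys(SHAPE_NAMES, 0.0)
    sentinel["VoxelVolume"] = volume
    sentinel["SurfaceArea"] = area
    if np_vox < 4:
        logger.warning("mask with <4 voxels: shape sentinels")
        return sentinel
    cov = np.cov(coords.T)
    eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
    eig = np.clip(eig, 0.0, None)
    if eig[0] <= 0:
        logger.warning("degenerate covariance: Elongation/Flatness sentinel 0")
        elong = flat = 0.0
        major = minor = least = 0.0
    else:
        elong = math.sqrt(eig[1] / eig[0])
        flat = math.sqrt(eig[2] / eig[0])
        major, minor, least = (4.0 * math.sqrt(max(v, 0.0)) for v in eig)
    surf = np.argwhere(binary) * sp  # all voxel centers; hull trims internally
    max3d = _max_pairwise(surf)
    def max2d(drop_axis: int) -> float:
        best = 0.0
        keep = [a for a in range(3) if a != drop_axis]
        idx = np.argwhere(binary)
        for plane in np.unique(idx[:, drop_axis]):
            pts = idx[idx[:, drop_axis] == plane][:, keep] * sp[keep]
            best = max(best, _max_pairwise(pts))
        return best
    sphericity = (36.0 * math.pi * volume ** 2) ** (1.0 / 3.0) / area if area else 0.0
    compact = volume / (math.sqrt(math.pi) * area ** 1.5) if area else 0.0
    return {
        "VoxelVolume": volume,
        "SurfaceArea": area,
        "SurfaceVolumeRatio": area / volume,
        "Sphericity": sphericity,
        "Compactness": compact,
        "Maximum3DDiameter": max3d,
        "Maximum2DDiameterSlice": max2d(2),   # in-plane (x, y)
        "Maximum2DDiameterColumn": max2d(1),  # (x, z)
        "Maximum2DDiameterRow": max2d(0),     # (y, z)
        "MajorAxisLength": major,
        "MinorAxisLength": minor,
        "LeastAxisLength": least,
        "Elongation": elong,
        "Flatness": flat,
    }


# --------------------------------------------------------------------------
# Texture matrices
# --------------------------------------------------------------------------

_OFFSETS_26 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
]

GLSZM_NAMES = (
    "SmallAreaEmphasis", "LargeAreaEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized", "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized", "ZonePercentage", "GrayLevelVariance",
    "ZoneVariance", "ZoneEntropy", "LowGrayLevelZoneEmphasis",
    "HighGrayLevelZoneEmphasis", "SmallAreaLowGrayLevelEmphasis",
    "SmallAreaHighGrayLevelEmphasis", "LargeAreaLowGrayLevelEmphasis",
    "LargeAreaHighGrayLevelEmphasis",
)

GLDM_NAMES = (
    "SmallDependenceEmphasis", "LargeDependenceEmphasis",
    "GrayLevelNonUniformity", "DependenceNonUniformity",
    "DependenceNonUniformityNormalized", "GrayLevelVariance",
    "DependenceVariance", "DependenceEntropy", "LowGrayLevelEmphasis",
    "HighGrayLevelEmphasis", "SmallDependenceLowGrayLevelEmphasis",
    "SmallDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis",
    "LargeDependenceHighGrayLevelEmphasis",
)

NGTDM_NAMES = ("Coarseness", "Contrast", "Busyness", "Complexity", "Strength")


def glszm_zones(roi: DiscretizedRoi, connectivity: int = 26) -> np.ndarray:
    """(level, size) per 26-connected equal-level zone, as an (Nz, 2) array."""
    structure = ndimage.generate_binary_structure(3, {6: 1, 18: 2, 26: 3}[connectivity])
    zones = []
    for lvl in np.unique(roi.levels[roi.mask]):
        lbl, n = ndimage.label(roi.levels == lvl, structure=structure)
        sizes = np.bincount(lbl.ravel())[1:]
        zones.extend((int(lvl), int(s)) for s in sizes)
    return np.asarray(zones, dtype=np.int64)


def glszm_features(roi: DiscretizedRoi, connectivity: int = 26) -> dict[str, float]:
    """Gray Level Size Zone Matrix features (zones = 26-connected regions)."""
    zones = glszm_zones(roi, connectivity)
    i = zones[:, 0].astype(float)
    j = zones[:, 1].astype(float)
    nz = float(len(zones))
    npx = float(roi.np_)
    mu_i = (i / nz).sum()
    mu_j = (j / nz).sum()
    # P(i,j) probabilities for entropy: aggregate duplicate (i, j) pairs
    _, counts = np.unique(zones, axis=0, return_counts=True)
    pz = counts / nz
    gl_sums = np.bincount(zones[:, 0])  # per-level zone counts
    sz_sums = np.bincount(zones[:, 1])
    return {
        "SmallAreaEmphasis": float((1.0 / j ** 2).sum() / nz),
        "LargeAreaEmphasis": float((j ** 2).sum() / nz),
        "GrayLevelNonUniformity": float((gl_sums.astype(float) ** 2).sum() / nz),
        "GrayLevelNonUniformityNormalized": float((gl_sums.astype(float) ** 2).sum() / nz ** 2),
        "SizeZoneNonUniformity": float((sz_sums.astype(float) ** 2).sum() / nz),
        "SizeZoneNonUniformityNormalized": float((sz_sums.astype(float) ** 2).sum() / nz ** 2),
        "ZonePercentage": float(nz / npx),
        "GrayLevelVariance": float(((i - mu_i) ** 2).sum() / nz),
        "ZoneVariance": float(((j - mu_j) ** 2).sum() / nz),
        "ZoneEntropy": float(-(pz * np.log2(pz + _EPS)).sum()),
        "LowGrayLevelZoneEmphasis": float((1.0 / i ** 2).sum() / nz),
        "HighGrayLevelZoneEmphasis": float((i ** 2).sum() / nz),
        "SmallAreaLowGrayLevelEmphasis": float((1.0 / (i ** 2 * j ** 2)).sum() / nz),
        "SmallAreaHighGrayLevelEmphasis": float((i ** 2 / j ** 2).sum() / nz),
        "LargeAreaLowGrayLevelEmphasis": float((j ** 2 / i ** 2).sum() / nz),
        "LargeAreaHighGrayLevelEmphasis": float((i ** 2 * j ** 2).sum() / nz),
    }


def gldm_matrix(roi: DiscretizedRoi, alpha: float = 0.0) -> np.ndarray:
    """(level, dependence) per ROI voxel; dependence = 1 + #26-neighbors in
    the ROI with |level difference| <= alpha."""
    lv = roi.levels
    mask = roi.mask
    dep = np.ones(lv.shape, dtype=np.int64)
    for off in _OFFSETS_26:
        shifted_lv = _shift(lv, off)
        shifted_mask = _shift(mask, off)
        ok = mask & shifted_mask & (np.abs(lv - shifted_lv) <= alpha)
        dep[ok] += 1
    return np.stack([lv[mask], dep[mask]], axis=1)


def _shift(arr: np.ndarray, off) -> np.ndarray:
    """Shift with zero/False fill (out-of-bounds neighbors vanish)."""
    out = np.zeros_like(arr)
    src = [slice(None)] * 3
    dst = [slice(None)] * 3
    for ax, o in enumerate(off):
        if o > 0:
            dst[ax] = slice(o, None)
            src[ax] = slice(None, -o)
        elif o < 0:
            dst[ax] = slice(None, o)
            src[ax] = slice(-o, None)
    out[tuple(dst)] = arr[tuple(src)]
    return out


def gldm_features(roi: DiscretizedRoi, alpha: float = 0.0) -> dict[str, float]:
    """Gray Level Dependence Matrix features; sum of matrix entries = Np."""
    entries = gldm_matrix(roi, alpha)
    i = entries[:, 0].astype(float)
    j = entries[:, 1].astype(float)
    nz = float(len(entries))  # == Np: every voxel contributes one entry
    mu_i = i.mean()
    mu_j = j.mean()
    _, counts = np.unique(entries, axis=0, return_counts=True)
    pz = counts / nz
    gl_sums = np.bincount(entries[:, 0])
    dp_sums = np.bincount(entries[:, 1])
    return {
        "SmallDependenceEmphasis": float((1.0 / j ** 2).mean()),
        "LargeDependenceEmphasis": float((j ** 2).mean()),
        "GrayLevelNonUniformity": float((gl_sums.astype(float) ** 2).sum() / nz),
        "DependenceNonUniformity": float((dp_sums.astype(float) ** 2).sum() / nz),
        "DependenceNonUniformityNormalized": float((dp_sums.astype(float) ** 2).sum() / nz ** 2),
        "GrayLevelVariance": float(((i - mu_i) ** 2).mean()),
        "DependenceVariance": float(((j - mu_j) ** 2).mean()),
        "DependenceEntropy": float(-(pz * np.log2(pz + _EPS)).sum()),
        "LowGrayLevelEmphasis": float((1.0 / i ** 2).mean()),
        "HighGrayLevelEmphasis": float((i ** 2).mean()),
        "SmallDependenceLowGrayLevelEmphasis": float((1.0 / (i ** 2 * j ** 2)).mean()),
        "SmallDependenceHighGrayLevelEmphasis": float((i ** 2 / j ** 2).mean()),
        "LargeDependenceLowGrayLevelEmphasis": float((j ** 2 / i ** 2).mean()),
        "LargeDependenceHighGrayLevelEmphasis": float((i ** 2 * j ** 2).mean()),
    }


def ngtdm_table(roi: DiscretizedRoi) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Per-level (n_i, p_i, s_i) over voxels with >= 1 in-ROI 26-neighbor.

    s_i sums |level - neighborhood mean| over the contributing voxels; the
    neighborhood mean uses only in-ROI neighbors (center excluded).
    Returns (n, p, s) indexed 0..Ng and the count of valid voxels.
    """
    lv = roi.levels.astype(float)
    mask = roi.mask
    kernel = np.ones((3, 3, 3))
    kernel[1, 1, 1] = 0.0
    sums = ndimage.correlate(lv * mask, kernel, mode="constant", cval=0.0)
    counts = ndimage.correlate(mask.astype(float), kernel, mode="constant", cval=0.0)
    valid = mask & (counts > 0)
    nvp = int(valid.sum())
    ng = roi.ng
    n = np.zeros(ng + 1)
    s = np.zeros(ng + 1)
    if nvp:
        levels_v = roi.levels[valid]
        a = sums[valid] / counts[valid]
        dev = np.abs(levels_v - a)
        n = np.bincount(levels_v, minlength=ng + 1).astype(float)
        s = np.bincount(levels_v, weights=dev, minlength=ng + 1)
    p = n / nvp if nvp else n
    return n, p, s, nvp


def ngtdm_features(roi: DiscretizedRoi) -> dict[str, float]:
    """Neighboring Gray Tone Difference Matrix features.

    A constant ROI has all s_i = 0; Busyness/Complexity/Strength then report
    the documented sentinel 0 and Coarseness the standard large-value cap.
    """
    n, p, s, nvp = ngtdm_table(roi)
    ng_present = int((n > 0).sum())
    i_all = np.arange(len(n), dtype=float)
    present = n > 0
    ip = i_all[present]
    pp = p[present]
    sp_ = s[present]
    sum_ps = float((pp * sp_).sum())
    coarseness = 1.0 / sum_ps if sum_ps > 0 else 1e6  # standard cap
    if ng_present > 1 and nvp > 0:
        pi, pj = np.meshgrid(pp, pp, indexing="ij")
        ii, jj = np.meshgrid(ip, ip, indexing="ij")
        contrast = float((pi * pj * (ii - jj) ** 2).sum()) \
            / (ng_present * (ng_present - 1)) * float(s.sum()) / nvp
        busy_den = float(np.abs(ii * pi - jj * pj).sum())
        busyness = sum_ps / busy_den if busy_den > 0 else 0.0
        si, sj = np.meshgrid(sp_, sp_, indexing="ij")
        complexity = float((np.abs(ii - jj) * (pi * si + pj * sj)
                            / (pi + pj)).sum()) / nvp
        s_total = float(s.sum())
        strength = (float(((pi + pj) * (ii - jj) ** 2).sum()) / s_total
                    if s_total > 0 else 0.0)
    else:
        contrast = busyness = complexity = strength = 0.0
    return {
        "Coarseness": coarseness,
        "Contrast": contrast,
        "Busyness": busyness,
        "Complexity": complexity,
        "Strength": strength,
    }


# --------------------------------------------------------------------------
# Full extraction
# --------------------------------------------------------------------------

TEXTURE_CLASSES = {
    "firstorder": FIRSTORDER_NAMES,
    "glszm": GLSZM_NAMES,
    "gldm": GLDM_NAMES,
    "ngtdm": NGTDM_NAMES,
}

WAVELET_BANDS = ("LLL", "LLH", "LHL", "LHH", "HLL", "HLH", "HHL", "HHH")


def feature_registry(config: FeatureExtractionConfig | None = None) -> list[str]:
    """The fixed, ordered name set of every feature extract_all emits."""
    config = config or FeatureExtractionConfig()
    image_filters = []
    for f in config.filters:
        if f == "wavelet":
            image_filters.extend(f"wavelet-{b}" for b in WAVELET_BANDS)
        else:
            image_filters.append(f)
    names = [f"original_shape_{n}" for n in SHAPE_NAMES]
    for img in image_filters:
        for cls, feats in TEXTURE_CLASSES.items():
            names.extend(f"{img}_{cls}_{n}" for n in feats)
    return names


def _sentinel_record(config: FeatureExtractionConfig) -> dict[str, float]:
    return dict.fromkeys(feature_registry(config), 0.0)


def extract_all(volume: VolumeGrid, mask: MultiLabelMask | np.ndarray,
                config: FeatureExtractionConfig | None = None) -> dict[str, float]:
    """Extract every registered feature for one case.

    The lesion is processed inside its padded bounding box; the padding is
    wide enough that wavelet coefficients within the ROI match a whole-volume
    computation except for lesions touching the volume edge.
    """
    config = config or FeatureExtractionConfig()
    binary = binarize(mask) if isinstance(mask, MultiLabelMask) else np.asarray(mask, bool)
    if binary.shape != volume.shape:
        raise ValueError("mask grid does not match volume grid")
    if not binary.any():
        raise ValueError("empty mask: no ROI to extract features from")
    voxel_volume = volume.voxel_volume

    record: dict[str, float] = {}
    n_fore = int(binary.sum())
    if n_fore < 2:
        logger.warning("single-voxel ROI: sentinel feature record")
        rec = _sentinel_record(config)
        rec.update({f"original_shape_{k}": v
                    for k, v in shape_features(binary, volume.spacing).items()})
        return rec

    for k, v in shape_features(binary, volume.spacing).items():
        record[f"original_shape_{k}"] = float(v)

    # padded bounding box: wavelet filter support on each side
    pad = len(pywt.Wavelet(config.wavelet).dec_lo) + 1
    idx = np.argwhere(binary)
    lo = np.maximum(idx.min(axis=0) - pad, 0)
    hi = np.minimum(idx.max(axis=0) + pad + 1, binary.shape)
    sl = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
    sub = volume.data[sl]
    sub_mask = binary[sl]

    images: dict[str, np.ndarray] = {}
    for f in config.filters:
        if f == "original":
            images["original"] = sub
        elif f == "logarithm":
            images["logarithm"] = logarithm_filter(sub)
        elif f == "wavelet":
            if min(sub.shape) >= len(pywt.Wavelet(config.wavelet).dec_lo):
                bands = wavelet_subbands(sub, config.wavelet)
            else:  # tiny ROI near a thin volume: pad the subvolume further
                padded = np.pad(sub, pad, mode="reflect")
                bands = {k: v[pad:-pad, pad:-pad, pad:-pad]
                         for k, v in wavelet_subbands(padded, config.wavelet).items()}
            for b in WAVELET_BANDS:
                images[f"wavelet-{b}"] = bands[b]
        else:
            raise ValueError(f"unknown image filter {f!r}")

    for img_name, img in images.items():
        vals = img[sub_mask]
        record.update({
            f"{img_name}_firstorder_{k}": float(v)
            for k, v in first_order_features(vals, voxel_volume, config.bin_width).items()
        })
        roi = discretize(img, sub_mask, config.bin_width, voxel_volume)
        record.update({f"{img_name}_glszm_{k}": float(v)
                       for k, v in glszm_features(roi, config.connectivity).items()})
        record.update({f"{img_name}_gldm_{k}": float(v)
                       for k, v in gldm_features(roi, config.gldm_alpha).items()})
        record.update({f"{img_name}_ngtdm_{k}": float(v)
                       for k, v in ngtdm_features(roi).items()})
    # keep the registry order and guarantee finiteness
    registry = feature_registry(config)
    out = {}
    for name in registry:
        v = record.get(name, 0.0)
        if not np.isfinite(v):
            logger.warning("non-finite feature %s -> sentinel 0", name)
            v = 0.0
        out[name] = float(v)
    return out
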