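"""ROI radiomics: preprocessing, wavelet sub-bands, and first-order /
GLRLM / GLCM / shape features.

Volumes are resampled to a common voxel grid, intensity-normalized
within the ROI, decomposed into the eight sub-bands of a single-level
3D separable discrete wavelet transform (labelled LLL…HHH, one L/H
letter per axis), and summarized by named scalar features. Texture
features come from the gray-level run-length matrix (GLRLM) and the
gray-level co-occurrence matrix (GLCM), computed over the 13 unique 3D
directions and averaged per feature (direction averaging, not matrix
merging — the two differ numerically).

Feature names follow ``<band>_<transform>_<feature>`` where ``band`` is
a wavelet sub-band label or ``none`` and ``transform`` names an
optional pre-transform hook (``none`` = identity). The hook slot exists
so externally defined intensity transforms (e.g. a SIFT-style filter)
can be plugged in without changing the naming scheme.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pywt
from scipy import ndimage, stats

#: 13 unique direction vectors of the 3D 26-neighbourhood (one per +/- pair).
DIRECTIONS_13: tuple[tuple[int, int, int], ...] = tuple(
    d for d in (
        (1, 0, 0), (0, 1, 0), (0, 0, 1),
        (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1),
        (0, 1, 1), (0, 1, -1),
        (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
    )
)

BAND_LABELS = ("LLL", "LLH", "LHL", "LHH", "HLL", "HLH", "HHL", "HHH")

FIRST_ORDER_NAMES = (
    "Energy", "Entropy", "Maximum", "Mean", "Mean absolute deviation",
    "Median", "Range", "Root mean square", "Skewness", "Standard deviation",
    "Third quartile", "Uniformity", "Variance",
)

GLRLM_NAMES = (
    "SRE", "LRE", "GLN", "RLN", "RP", "LGRE", "HGRE",
    "SRLGLE", "SRHGLE", "LRLGLE", "LRHGLE",
)
#: The run-length features the trained models draw on.
GLRLM_MODEL_NAMES = ("SRE", "SRLGLE", "SRHGLE", "LRHGLE")

GLCM_NAMES = ("IMC1",)
SHAPE_NAMES = ("Volume", "Surface area", "Sphericity")


@dataclass
class ImageVolume:
    """A 3D scalar volume with physical voxel spacing."""

    voxels: np.ndarray
    spacing_mm: tuple[float, float, float]
    modality: str = "T1C"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 3:
            raise ValueError("volume must be 3D")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("volume contains non-finite voxels")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing must be positive")
        if self.modality not in ("T1C", "ADC"):
            raise ValueError(f"unknown modality {self.modality!r}")


@dataclass
class RadiomicFeatureVector:
    """Named scalar features for one (sample, modality)."""

    features: dict[str, float]

    def __post_init__(self) -> None:
        bad = [k for k, v in self.features.items() if not np.isfinite(v)]
        if bad:
            raise ValueError(f"non-finite feature values: {bad[:5]}")

    def __getitem__(self, name: str) -> float:
        return self.features[name]

    def __len__(self) -> int:
        return len(self.features)


@dataclass
class ExtractionConfig:
    """Knobs of the extraction pipeline.

    n_bins: gray-level quantization bins within the ROI.
    wavelet: PyWavelets family for the sub-band decomposition.
    bands_enabled: compute features on the eight sub-bands as well.
    directions: 3D direction vectors for GLRLM/GLCM aggregation.
    pre_transforms: named intensity pre-transforms; ``None`` = identity.
    """

    n_bins: int = 32
    wavelet: str = "haar"
    bands_enabled: bool = True
    directions: tuple = DIRECTIONS_13
    pre_transforms: Mapping[str, Callable | None] = field(
        default_factory=lambda: {"none": None}
    )
    include_shape: bool = True


# ---------------------------------------------------------------- preprocess

def resample(volume: ImageVolume,
             target_spacing: tuple[float, float, float] = (0.75, 0.75, 3.0),
             is_mask: bool = False) -> ImageVolume:
    """Resample to the target grid (trilinear; nearest for masks)."""
    if any(s <= 0 for s in target_spacing):
        raise ValueError("target spacing must be positive")
    factors = tuple(s / t for s, t in zip(volume.spacing_mm, target_spacing))
    if all(abs(f - 1.0) < 1e-12 for f in factors):
        return ImageVolume(volume.voxels.copy(), tuple(target_spacing),
                           volume.modality)
    out = ndimage.zoom(volume.voxels, factors, order=0 if is_mask else 1,
                       mode="nearest", grid_mode=True)
    return ImageVolume(out, tuple(target_spacing), volume.modality)


def normalize_intensity(volume: ImageVolume, mask: np.ndarray) -> ImageVolume:
    """ROI z-score, clipped at +/-3 SD, mapped linearly onto [0, 1]."""
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("empty mask")
    roi = volume.voxels[mask]
    sd = roi.std()
    if sd == 0:
        raise ValueError("zero in-mask variance")
    z = np.clip((volume.voxels - roi.mean()) / sd, -3.0, 3.0)
    return ImageVolume((z + 3.0) / 6.0, volume.spacing_mm, volume.modality)


def wavelet_bands(volume: np.ndarray, wavelet: str = "haar") -> dict[str, np.ndarray]:
    """Single-level 3D DWT; eight sub-bands keyed LLL…HHH (axis order x,y,z)."""
    arr = np.asarray(volume, float)
    if arr.ndim != 3 or min(arr.shape) < 2:
        raise ValueError("need a 3D volume with every dimension >= 2")
    coeffs = pywt.dwtn(arr, wavelet, axes=(0, 1, 2))
    out = {}
    for key, band in coeffs.items():
        label = "".join("L" if c == "a" else "H" for c in key)
        out[label] = band
    return {label: out[label] for label in BAND_LABELS}


def quantize(values: np.ndarray, mask: np.ndarray, n_bins: int = 32) -> np.ndarray:
    """Equal-width gray-level quantization within the ROI; levels 1..n_bins.

    Voxels outside the mask get level 0 (ignored by texture code).
    """
    mask = np.asarray(mask, bool)
    roi = values[mask]
    lo, hi = roi.min(), roi.max()
    lv = np.zeros(values.shape, dtype=np.int32)
    if hi == lo:
        lv[mask] = 1
        return lv
    q = np.floor((values - lo) / (hi - lo) * n_bins).astype(np.int32)
    lv[mask] = np.clip(q[mask], 0, n_bins - 1) + 1
    return lv


# --------------------------------------------------------------- first order

def first_order(values: np.ndarray, n_bins: int = 32) -> dict[str, float]:
    """The 13 named first-order statistics of the in-ROI intensities."""
    x = np.asarray(values, float).ravel()
    if x.size < 2:
        raise ValueError("need at least 2 in-ROI voxels")
    hist, _ = np.histogram(x, bins=n_bins)
    p = hist / hist.sum()
    p = p[p > 0]
    mean = x.mean()
    sd = x.std()
    skew = 0.0 if sd == 0 else float(stats.skew(x))
    return {
        "Energy": float(np.sum(x ** 2)),
        "Entropy": float(-(p * np.log2(p)).sum()),
        "Maximum": float(x.max()),
        "Mean": float(mean),
        "Mean absolute deviation": float(np.abs(x - mean).mean()),
        "Median": float(np.median(x)),
        "Range": float(x.max() - x.min()),
        "Root mean square": float(np.sqrt(np.mean(x ** 2))),
        "Skewness": skew,
        "Standard deviation": float(sd),
        "Third quartile": float(np.percentile(x, 75)),
        "Uniformity": float(np.sum(p ** 2)),
        "Variance": float(x.var()),
    }


# -------------------------------------------------------------------- GLRLM

_RUN_GEOMETRY_CACHE: dict[tuple, tuple[np.ndarray, np.ndarray]] = {}


def _run_geometry(shape: tuple[int, int, int],
                  direction: tuple[int, int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Sorted traversal order grouping voxels into lines along a direction.

    Returns (order, chain): ``order`` flattens the volume so each line's
    voxels are contiguous and in step order; ``chain[i]`` is True when
    sorted voxel i is the immediate geometric successor of i-1 on the
    same line. Cached per (shape, direction) — the dominant cost is
    shape-only, so repeat extractions are cheap.
    """
    key = (shape, direction)
    cached = _RUN_GEOMETRY_CACHE.get(key)
    if cached is not None:
        return cached
    dx, dy, dz = direction
    xs, ys, zs = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    x, y, z = xs.ravel(), ys.ravel(), zs.ravel()
    # Step index along the direction: one voxel step advances t by 1.
    # Any nonzero component serves, since components are in {-1, 0, 1}.
    coords = (x, y, z)
    k = next(i for i, c in enumerate((dx, dy, dz)) if c != 0)
    t = coords[k] * (dx, dy, dz)[k]
    # Line id: the line's anchor point (constant along the line).
    l1, l2, l3 = x - t * dx, y - t * dy, z - t * dz
    order = np.lexsort((t, l3, l2, l1))
    ts, a1, a2, a3 = t[order], l1[order], l2[order], l3[order]
    chain = np.zeros(len(order), dtype=bool)
    chain[1:] = ((np.diff(ts) == 1) & (np.diff(a1) == 0)
                 & (np.diff(a2) == 0) & (np.diff(a3) == 0))
    _RUN_GEOMETRY_CACHE[key] = (order, chain)
    return order, chain


def _runs_along(levels: np.ndarray, mask: np.ndarray,
                direction: tuple[int, int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Maximal same-level runs of in-mask voxels along one direction.

    Returns (gray_levels, run_lengths), one entry per run.
    """
    order, chain = _run_geometry(levels.shape, tuple(direction))
    lv = levels.ravel()[order]
    valid = mask.ravel()[order]
    pos = np.flatnonzero(valid)
    if pos.size == 0:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    lvs = lv[pos]
    cont = (np.diff(pos) == 1) & chain[pos[1:]] & (lvs[1:] == lvs[:-1])
    starts = np.concatenate(([0], np.flatnonzero(~cont) + 1))
    lengths = np.diff(np.append(starts, pos.size))
    return lvs[starts].astype(np.int64), lengths.astype(np.int64)


def glrlm_features(levels: np.ndarray, mask: np.ndarray,
                   directions=DIRECTIONS_13) -> dict[str, float]:
    """Run-length features averaged over directions.

    ``levels`` is a quantized volume (1-based gray levels, 0 outside the
    ROI); runs break at ROI boundaries and at gray-level changes.
    """
    mask = np.asarray(mask, bool)
    n_vox = int(mask.sum())
    if n_vox == 0:
        raise ValueError("empty ROI")
    acc = {name: 0.0 for name in GLRLM_NAMES}
    for direction in directions:
        i, j = _runs_along(levels, mask, direction)
        nr = len(i)
        i = i.astype(float)
        j = j.astype(float)
        gln = np.bincount(np.int64(i))
        rln = np.bincount(np.int64(j))
        acc["SRE"] += np.sum(1.0 / j ** 2) / nr
        acc["LRE"] += np.sum(j ** 2) / nr
        acc["GLN"] += np.sum(gln.astype(float) ** 2) / nr
        acc["RLN"] += np.sum(rln.astype(float) ** 2) / nr
        acc["RP"] += nr / n_vox
        acc["LGRE"] += np.sum(1.0 / i ** 2) / nr
        acc["HGRE"] += np.sum(i ** 2) / nr
        acc["SRLGLE"] += np.sum(1.0 / (i ** 2 * j ** 2)) / nr
        acc["SRHGLE"] += np.sum(i ** 2 / j ** 2) / nr
        acc["LRLGLE"] += np.sum(j ** 2 / i ** 2) / nr
        acc["LRHGLE"] += np.sum(i ** 2 * j ** 2) / nr
    return {name: val / len(directions) for name, val in acc.items()}


# --------------------------------------------------------------------- GLCM

def _glcm_for_direction(levels: np.ndarray, mask: np.ndarray,
                        direction: tuple[int, int, int],
                        n_levels: int) -> np.ndarray | None:
    """Symmetric normalized co-occurrence matrix at distance 1, or None."""
    src = [slice(None)] * 3
    dst = [slice(None)] * 3
    for ax, d in enumerate(direction):
        if d == 1:
            src[ax], dst[ax] = slice(0, -1), slice(1, None)
        elif d == -1:
            src[ax], dst[ax] = slice(1, None), slice(0, -1)
    a = levels[tuple(src)].ravel()
    b = levels[tuple(dst)].ravel()
    ok = (mask[tuple(src)].ravel()) & (mask[tuple(dst)].ravel())
    if not ok.any():
        return None
    a, b = a[ok] - 1, b[ok] - 1
    m = np.bincount(a * n_levels + b,
                    minlength=n_levels * n_levels).reshape(n_levels, n_levels)
    m = m + m.T  # symmetric pairs
    return m / m.sum()


def _imc1(p: np.ndarray) -> float:
    """Informational measure of correlation 1 (entropies in bits)."""
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    hx = float(-np.sum(px[px > 0] * np.log2(px[px > 0])))
    hy = float(-np.sum(py[py > 0] * np.log2(py[py > 0])))
    denom = max(hx, hy)
    if denom == 0:
        warnings.warn("degenerate GLCM (single gray level); IMC1 set to 0")
        return 0.0
    nz = p > 0
    hxy = float(-np.sum(p[nz] * np.log2(p[nz])))
    outer = np.outer(px, py)
    hxy1 = float(-np.sum(p[nz] * np.log2(outer[nz])))
    return (hxy - hxy1) / denom


def glcm_imc1(levels: np.ndarray, mask: np.ndarray,
              directions=DIRECTIONS_13) -> float:
    """IMC1 averaged over the co-occurrence directions (distance 1)."""
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("empty ROI")
    n_levels = int(levels.max())
    vals = []
    for direction in directions:
        p = _glcm_for_direction(levels, mask, direction, n_levels)
        if p is not None:
            vals.append(_imc1(p))
    if not vals:
        warnings.warn("no co-occurring voxel pairs; IMC1 set to 0")
        return 0.0
    return float(np.mean(vals))


# -------------------------------------------------------------------- shape

def shape_features(mask: np.ndarray,
                   spacing_mm: tuple[float, float, float]) -> dict[str, float]:
    """Voxel-count volume, exposed-face surface area, and sphericity."""
    mask = np.asarray(mask, bool)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("empty mask")
    sx, sy, sz = spacing_mm
    volume = n * sx * sy * sz
    face_areas = (sy * sz, sx * sz, sx * sy)
    area = 0.0
    padded = np.pad(mask, 1)
    for ax, fa in enumerate(face_areas):
        diff = np.diff(padded.astype(np.int8), axis=ax)
        area += np.abs(diff).sum() * fa
    sphericity = (np.pi ** (1 / 3)) * (6.0 * volume) ** (2 / 3) / area
    return {"Volume": float(volume), "Surface area": float(area),
            "Sphericity": float(sphericity)}


# ------------------------------------------------------------------ extract

def _band_mask(mask: np.ndarray, band_shape: tuple[int, ...]) -> np.ndarray:
    dec = mask[::2, ::2, ::2]
    if dec.shape == band_shape:
        return dec
    factors = tuple(b / m for b, m in zip(band_shape, mask.shape))
    out = ndimage.zoom(mask.astype(np.int8), factors, order=0, mode="nearest",
                       grid_mode=True)
    return out.astype(bool)


def _texture_block(values: np.ndarray, mask: np.ndarray,
                   config: ExtractionConfig) -> dict[str, float]:
    out = dict(first_order(values[mask], n_bins=config.n_bins))
    lv = quantize(values, mask, n_bins=config.n_bins)
    rl = glrlm_features(lv, mask, directions=config.directions)
    out.update({k: rl[k] for k in GLRLM_MODEL_NAMES})
    out["IMC1"] = glcm_imc1(lv, mask, directions=config.directions)
    return out


def extract_all(volume: ImageVolume, mask: np.ndarray,
                config: ExtractionConfig | None = None) -> RadiomicFeatureVector:
    """Full named feature vector for one ROI-masked volume.

    First-order + GLRLM + GLCM features on the original volume and (if
    enabled) each wavelet sub-band, for every configured pre-transform;
    shape features once per ROI.
    """
    config = config or ExtractionConfig()
    mask = np.asarray(mask, bool)
    if volume.voxels.shape != mask.shape:
        raise ValueError("volume and mask shapes differ")
    if not mask.any():
        raise ValueError("empty mask")
    feats: dict[str, float] = {}
    for tname, tfun in config.pre_transforms.items():
        base = volume.voxels if tfun is None else np.asarray(tfun(volume.voxels), float)
        for name, value in _texture_block(base, mask, config).items():
            feats[f"none_{tname}_{name}"] = value
        if config.bands_enabled:
            for label, band in wavelet_bands(base, config.wavelet).items():
                bmask = _band_mask(mask, band.shape)
                if bmask.sum() < 2:
                    warnings.warn(f"band {label}: ROI too small, skipped")
                    continue
                for name, value in _texture_block(band, bmask, config).items():
                    feats[f"{label}_{tname}_{name}"] = value
    if config.include_shape:
        for name, value in shape_features(mask, volume.spacing_mm).items():
            feats[f"none_none_{name}"] = value
    return RadiomicFeatureVector(feats)


def feature_class_of(name: str) -> str:
    """Feature class (first_order / glrlm / glcm / shape) from a name."""
    base = name.split("_", 2)[-1]
    if base in SHAPE_NAMES:
        return "shape"
    if base in GLRLM_NAMES:
        return "glrlm"
    if base in GLCM_NAMES:
        return "glcm"
    if base in FIRST_ORDER_NAMES:
        return "first_order"
    raise ValueError(f"unrecognized feature name {name!r}")


def class_proportions(names) -> dict[str, float]:
    """Percentage of features per class; sums to 100."""
    names = list(names)
    counts: dict[str, int] = {}
    for n in names:
        c = feature_class_of(n)
        counts[c] = counts.get(c, 0) + 1
    return {c: 100.0 * k / len(names) for c, k in counts.items()}
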