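"""Texture-matrix construction and the 730-feature extractor.

First-order histogram statistics, gray-level co-occurrence (GLCM) and
gray-level run-length (GLRLM) matrices are computed on the normalized
ROI and on the four subbands of a single-level 2-D discrete wavelet
transform.  All statistics respect the ROI mask: co-occurrence pairs
require both endpoints inside the mask, runs break at masked-out pixels,
first-order statistics pool masked pixels only.

Degenerate statistics (e.g. GLCM correlation of a constant patch)
return 0 and are flagged rather than raising, so constant ROIs survive
the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt

from .imaging import MASKED_OUT, QuantizedPatch, RoiPatch, quantize
from .registry import (
    DEFAULT_REGISTRY,
    FIRST_ORDER_STATS,
    GLCM_STATS,
    GLRLM_STATS,
    FeatureRegistry,
)

__all__ = [
    "Glcm",
    "Glrlm",
    "WaveletSubbands",
    "FeatureVector",
    "first_order_features",
    "compute_glcm",
    "glcm_features",
    "compute_glrlm",
    "glrlm_features",
    "wavelet_decompose",
    "extract_all_features",
]

# pixel offsets (drow, dcol) for angles measured counter-clockwise from
# the positive column axis, rows increasing downward
_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}

_HIST_BINS = 32  # histogram depth for first-order entropy/uniformity
_EPS = np.finfo(float).tiny


@dataclass(frozen=True)
class Glcm:
    """Symmetric, normalized gray-level co-occurrence matrix."""

    matrix: np.ndarray  # G x G, sums to 1 (or all zero if degenerate)
    levels: int
    distance: int
    angle: int
    degenerate: bool = False  # no valid pixel pair for this offset


@dataclass(frozen=True)
class Glrlm:
    """Gray-level run-length matrix r(i, j): runs of level i, length j."""

    matrix: np.ndarray  # G x R counts
    levels: int
    angle: int
    n_runs: int
    n_pixels: int


@dataclass(frozen=True)
class WaveletSubbands:
    """Single-level 2-D DWT of a patch with block-downsampled mask."""

    LL: np.ndarray
    LH: np.ndarray
    HL: np.ndarray
    HH: np.ndarray
    mask: np.ndarray  # subband-resolution mask (2x2 block-any)
    wavelet: str

    def as_patches(self) -> dict[str, RoiPatch]:
        return {
            name: RoiPatch(getattr(self, name), self.mask, normalized=True)
            for name in ("LL", "LH", "HL", "HH")
        }


@dataclass(frozen=True)
class FeatureVector:
    """Ordered 730-feature measurement for one patient."""

    patient_id: str
    values: np.ndarray
    names: tuple[str, ...]
    degenerate_flags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if len(self.values) != len(self.names):
            raise ValueError("value/name length mismatch")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.values))

    def __len__(self) -> int:
        return len(self.values)


def first_order_features(patch: RoiPatch) -> dict[str, float]:
    """Fourteen histogram statistics over the masked pixels.

    Entropy (bits) and uniformity use a 32-bin equal-width histogram of
    the masked intensities; variance and its derivatives are population
    moments.  Skewness/kurtosis of a constant patch are reported as 0.
    """
    x = patch.masked_values
    if x.size < 2:
        raise ValueError("need at least 2 masked pixels")
    mu = x.mean()
    var = x.var()
    sd = np.sqrt(var)
    if sd > 0:
        skew = np.mean((x - mu) ** 3) / sd**3
        kurt = np.mean((x - mu) ** 4) / var**2  # Pearson (normal -> 3)
    else:
        skew = 0.0
        kurt = 0.0
    if x.max() > x.min():
        counts, _ = np.histogram(x, bins=_HIST_BINS)
        p = counts / counts.sum()
        p = p[p > 0]
    else:
        p = np.array([1.0])
    return {
        "mean": float(mu),
        "variance": float(var),
        "std": float(sd),
        "skewness": float(skew),
        "kurtosis": float(kurt),
        "energy": float(np.sum(x**2)),
        "entropy": float(-np.sum(p * np.log2(p))),
        "minimum": float(x.min()),
        "maximum": float(x.max()),
        "median": float(np.median(x)),
        "range": float(x.max() - x.min()),
        "rms": float(np.sqrt(np.mean(x**2))),
        "mad": float(np.mean(np.abs(x - mu))),
        "uniformity": float(np.sum(p**2)),
    }


def compute_glcm(q: QuantizedPatch, distance: int = 1, angle: int = 0) -> Glcm:
    """Count symmetric co-occurrences at the given offset.

    A pair contributes only if both endpoints lie inside the mask; the
    offset and its negation are accumulated (symmetric convention) and
    the matrix normalized to unit sum.
    """
    if distance < 1:
        raise ValueError("distance must be >= 1")
    if angle not in _OFFSETS:
        raise ValueError(f"angle must be one of {sorted(_OFFSETS)}")
    dr, dc = _OFFSETS[angle]
    dr, dc = dr * distance, dc * distance
    G = q.levels
    h, w = q.pixels.shape
    counts = np.zeros((G, G), dtype=float)

    r0, r1 = max(0, -dr), min(h, h - dr)
    c0, c1 = max(0, -dc), min(w, w - dc)
    if r0 < r1 and c0 < c1:
        a = q.pixels[r0:r1, c0:c1]
        b = q.pixels[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        valid = (a != MASKED_OUT) & (b != MASKED_OUT)
        if valid.any():
            ai, bi = a[valid] - 1, b[valid] - 1
            np.add.at(counts, (ai, bi), 1.0)
            np.add.at(counts, (bi, ai), 1.0)
    total = counts.sum()
    if total == 0:
        return Glcm(counts, G, distance, angle, degenerate=True)
    return Glcm(counts / total, G, distance, angle)


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-np.sum(p * np.log2(p)))


def glcm_features(m: Glcm) -> dict[str, float]:
    """The 22 second-order statistics of a normalized GLCM.

    Haralick-style definitions on 1-based gray levels; the symmetric
    matrix makes the row and column marginals identical.  Degenerate
    cases (zero marginal variance, empty matrix) yield 0.
    """
    P = m.matrix
    G = m.levels
    if m.degenerate:
        return {name: 0.0 for name in _GLCM_NAMES}
    if abs(P.sum() - 1.0) > 1e-9:
        raise ValueError("GLCM must be normalized to unit sum")
    i = np.arange(1, G + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = P.sum(axis=1)  # row marginal (= column marginal, symmetric)
    mu = float(np.sum(i * px))
    var = float(np.sum((i - mu) ** 2 * px))

    diff = np.abs(ii - jj)
    # distributions of i+j (k = 2..2G) and |i-j| (k = 0..G-1)
    p_sum = np.zeros(2 * G + 1)
    np.add.at(p_sum, (ii + jj).ravel(), P.ravel())
    p_diff = np.zeros(G)
    np.add.at(p_diff, diff.ravel(), P.ravel())
    ks = np.arange(2 * G + 1)
    kd = np.arange(G)

    sum_avg = float(np.sum(ks * p_sum))
    sum_var = float(np.sum((ks - sum_avg) ** 2 * p_sum))
    diff_avg = float(np.sum(kd * p_diff))
    diff_var = float(np.sum((kd - diff_avg) ** 2 * p_diff))

    contrast = float(np.sum(diff**2 * P))
    if var > 0:
        correlation = float((np.sum(ii * jj * P) - mu * mu) / var)
    else:
        correlation = 0.0

    hxy = _entropy(P.ravel())
    hx = _entropy(px)
    # joint entropies against the independence surrogate px*py
    outer = np.outer(px, px)
    nz = (P > 0) | (outer > 0)
    hxy1 = float(-np.sum(P[nz] * np.log2(outer[nz] + _EPS)))
    hxy2 = float(-np.sum(outer[nz] * np.log2(outer[nz] + _EPS)))
    imc1 = (hxy - hxy1) / hx if hx > 0 else 0.0
    arg = 1.0 - np.exp(-2.0 * (hxy2 - hxy))
    imc2 = float(np.sqrt(arg)) if arg > 0 else 0.0

    return {
        "autocorrelation": float(np.sum(ii * jj * P)),
        "contrast": contrast,
        "correlation": correlation,
        "cluster_prominence": float(np.sum((ii + jj - 2 * mu) ** 4 * P)),
        "cluster_shade": float(np.sum((ii + jj - 2 * mu) ** 3 * P)),
        "dissimilarity": float(np.sum(diff * P)),
        "energy": float(np.sum(P**2)),
        "entropy": hxy,
        "homogeneity": float(np.sum(P / (1.0 + diff))),
        "idm": float(np.sum(P / (1.0 + diff**2))),
        "max_probability": float(P.max()),
        "sum_of_squares": float(np.sum((ii - mu) ** 2 * P)),
        "sum_average": sum_avg,
        "sum_variance": sum_var,
        "sum_entropy": _entropy(p_sum),
        "difference_variance": diff_var,
        "difference_entropy": _entropy(p_diff),
        "imc1": float(imc1),
        "imc2": imc2,
        "idn": float(np.sum(P / (1.0 + diff / G))),
        "idmn": float(np.sum(P / (1.0 + diff**2 / G**2))),
        "marginal_mean": mu,
    }


_GLCM_NAMES = GLCM_STATS


def compute_glrlm(q: QuantizedPatch, angle: int = 0) -> Glrlm:
    """Count maximal same-level pixel runs along a direction.

    Runs break at masked-out pixels and patch edges; pixel counts are
    conserved: sum_ij j * r(i, j) equals the number of masked pixels.
    """
    if angle not in _OFFSETS:
        raise ValueError(f"angle must be one of {sorted(_OFFSETS)}")
    G = q.levels
    arr = q.pixels
    h, w = arr.shape

    if angle == 0:
        lines = [arr[r, :] for r in range(h)]
    elif angle == 90:
        lines = [arr[:, c] for c in range(w)]
    elif angle == 45:
        f = np.fliplr(arr)
        lines = [f.diagonal(k) for k in range(-(h - 1), w)]
    else:  # 135
        lines = [arr.diagonal(k) for k in range(-(h - 1), w)]

    # concatenate all lines with sentinel separators, then one RLE pass
    sep = np.full(1, MASKED_OUT, dtype=arr.dtype)
    seq = np.concatenate([np.concatenate([ln, sep]) for ln in lines])
    change = np.flatnonzero(np.diff(seq)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [len(seq)]])
    levels_run = seq[starts]
    lengths = ends - starts
    keep = levels_run != MASKED_OUT
    levels_run, lengths = levels_run[keep], lengths[keep]

    R = int(lengths.max()) if lengths.size else 1
    mat = np.zeros((G, R), dtype=np.int64)
    if lengths.size:
        np.add.at(mat, (levels_run - 1, lengths - 1), 1)
    return Glrlm(mat, G, angle, n_runs=int(lengths.size), n_pixels=int(q.mask.sum()))


def glrlm_features(m: Glrlm) -> dict[str, float]:
    """Eleven run-emphasis statistics with the standard definitions."""
    if m.n_runs < 1:
        raise ValueError("run-length matrix has zero runs")
    r = m.matrix.astype(float)
    nr = float(m.n_runs)
    i = np.arange(1, r.shape[0] + 1)[:, None].astype(float)
    j = np.arange(1, r.shape[1] + 1)[None, :].astype(float)
    level_marginal = r.sum(axis=1)
    length_marginal = r.sum(axis=0)
    return {
        "sre": float(np.sum(r / j**2) / nr),
        "lre": float(np.sum(r * j**2) / nr),
        "gln": float(np.sum(level_marginal**2) / nr),
        "rln": float(np.sum(length_marginal**2) / nr),
        "rp": float(nr / m.n_pixels),
        "lgre": float(np.sum(r / i**2) / nr),
        "hgre": float(np.sum(r * i**2) / nr),
        "srlge": float(np.sum(r / (i**2 * j**2)) / nr),
        "srhge": float(np.sum(r * i**2 / j**2) / nr),
        "lrlge": float(np.sum(r * j**2 / i**2) / nr),
        "lrhge": float(np.sum(r * i**2 * j**2) / nr),
    }


def wavelet_decompose(patch: RoiPatch, wavelet: str = "haar") -> WaveletSubbands:
    """Single-level separable 2-D DWT with symmetric padding.

    The four subbands sit at half resolution; the ROI mask is
    downsampled by a 2x2 block-any rule so a subband coefficient is
    kept if any of the underlying pixels was inside the ROI.  Pixels
    outside the ROI are replaced by the masked-pixel mean (zero for a
    normalized patch) before the transform, so values outside the mask
    can never leak into subband statistics; the perfect-reconstruction
    contract therefore applies to this mean-filled patch.
    """
    if patch.pixels.shape[0] < 2 or patch.pixels.shape[1] < 2:
        raise ValueError("patch too small for wavelet decomposition")
    filled = np.where(patch.mask, patch.pixels, patch.masked_values.mean())
    LL, (LH, HL, HH) = pywt.dwt2(filled, wavelet, mode="symmetric")
    h, w = patch.mask.shape
    hp, wp = 2 * ((h + 1) // 2), 2 * ((w + 1) // 2)
    mp = np.zeros((hp, wp), dtype=bool)
    mp[:h, :w] = patch.mask
    small = mp.reshape(hp // 2, 2, wp // 2, 2).any(axis=(1, 3))
    # for longer filters pywt subbands exceed ceil(n/2); pad the mask edge
    sh, sw = LL.shape
    sub_mask = np.zeros((sh, sw), dtype=bool)
    sub_mask[: small.shape[0], : small.shape[1]] = small
    return WaveletSubbands(LL, LH, HL, HH, sub_mask, wavelet)


def _texture_block(
    patch: RoiPatch,
    levels: int,
    clip: tuple[float, float] | None,
    distance: int,
    angles: tuple[int, ...],
) -> list[float]:
    """GLCM (22 x angles) then GLRLM (11 x angles) values, stat-major order."""
    q = quantize(patch, levels=levels, clip=clip)
    glcm_by_angle = [glcm_features(compute_glcm(q, distance, a)) for a in angles]
    glrlm_by_angle = []
    for a in angles:
        m = compute_glrlm(q, a)
        if m.n_runs == 0:
            glrlm_by_angle.append({name: 0.0 for name in _GLRLM_NAMES})
        else:
            glrlm_by_angle.append(glrlm_features(m))
    values: list[float] = []
    for name in _GLCM_NAMES:
        values.extend(d[name] for d in glcm_by_angle)
    for name in _GLRLM_NAMES:
        values.extend(d[name] for d in glrlm_by_angle)
    return values


_GLRLM_NAMES = GLRLM_STATS
_FO_NAMES = FIRST_ORDER_STATS


def extract_all_features(
    patch: RoiPatch,
    registry: FeatureRegistry = DEFAULT_REGISTRY,
    *,
    patient_id: str = "",
    levels: int = 32,
    clip: tuple[float, float] | None = (1.0, 99.0),
    distance: int = 1,
    wavelet: str = "haar",
) -> FeatureVector:
    """Compute the full feature panel for one normalized ROI patch.

    Applies the 14 first-order statistics, 22 GLCM statistics per angle
    and 11 GLRLM statistics per angle to the original patch and to each
    wavelet subband (each subband re-quantized independently with the
    same depth and clipping).  Non-finite values are replaced by 0 and
    recorded in ``degenerate_flags``.
    """
    if not patch.normalized:
        raise ValueError("extract_all_features expects a normalized patch")
    subbands = wavelet_decompose(patch, wavelet=wavelet)
    channels = {"orig": patch, **subbands.as_patches()}
    angles = registry.angles

    values: list[float] = []
    for ch in registry.channels:
        p = channels[ch]
        fo = first_order_features(p)
        values.extend(fo[name] for name in _FO_NAMES)
        values.extend(_texture_block(p, levels, clip, distance, angles))

    arr = np.asarray(values, dtype=float)
    bad = ~np.isfinite(arr)
    flags = frozenset(np.asarray(registry.names)[bad].tolist())
    arr[bad] = 0.0
    return FeatureVector(patient_id, arr, registry.names, flags)
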