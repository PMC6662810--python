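"""Gray-level co-occurrence and run-length texture statistics.

Trabecular micro-architecture shows up in low-magnification micrographs as a
fine anisotropic texture.  This module quantizes 8-bit grayscale images and
computes the two classical second-order texture summaries used for bone
texture analysis:

* the gray-level co-occurrence matrix (GLCM) and eleven Haralick-style
  parameters derived from it, and
* the gray-level run-length matrix (GLRLM) and its four run statistics.

Both are evaluated in the four canonical raster directions (0deg, 45deg,
90deg, 135deg); an optional binary region-of-interest mask restricts the
pixel pairs and breaks runs at its boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "DIRECTIONS",
    "GLCM_FEATURE_NAMES",
    "GLRLM_FEATURE_NAMES",
    "TEXTURE_FEATURE_NAMES",
    "QuantizedImage",
    "CooccurrenceMatrix",
    "RunLengthMatrix",
    "quantize",
    "compute_glcm",
    "glcm_features",
    "compute_glrlm",
    "glrlm_features",
    "directional_table",
]

#: Direction tags in degrees.  Offsets use (row, col) with row 0 at the top,
#: so 45deg points up-right in the displayed image.
DIRECTIONS = (0, 45, 90, 135)

_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}

GLCM_FEATURE_NAMES = (
    "angular_second_moment",
    "contrast",
    "correlation",
    "variance",
    "sum_of_variance",
    "mean_sum",
    "entropy",
    "sum_entropy",
    "entropy_difference",
    "residual_variance",
    "inverse_difference_moment",
)

GLRLM_FEATURE_NAMES = (
    "run_length_nonuniformity",
    "grey_level_nonuniformity",
    "short_run_emphasis",
    "long_run_emphasis",
)

TEXTURE_FEATURE_NAMES = GLCM_FEATURE_NAMES + GLRLM_FEATURE_NAMES


class DegenerateInputError(ValueError):
    """Raised when an image/mask combination leaves nothing to measure."""


@dataclass(frozen=True)
class QuantizedImage:
    """A gray-level-reduced image with an optional ROI mask.

    Parameters
    ----------
    pixels
        2-D integer array with values in ``[0, levels)``.
    levels
        Number of gray levels G after quantization.
    mask
        Optional boolean array of the same shape; ``True`` marks pixels
        inside the region of interest.
    """

    pixels: np.ndarray
    levels: int
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("pixels must be a nonempty 2-D array")
        if self.levels < 2:
            raise ValueError("levels must be >= 2")
        if px.min() < 0 or px.max() >= self.levels:
            raise ValueError("pixel values must lie in [0, levels)")
        object.__setattr__(self, "pixels", px.astype(np.intp))
        if self.mask is not None:
            m = np.asarray(self.mask, dtype=bool)
            if m.shape != px.shape:
                raise ValueError("mask shape must match pixel grid")
            object.__setattr__(self, "mask", m)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class CooccurrenceMatrix:
    """Symmetric, normalized GLCM for one (direction, distance) offset."""

    counts: np.ndarray  # G x G, sums to 1
    direction: int
    distance: int
    levels: int


@dataclass(frozen=True)
class RunLengthMatrix:
    """Run counts by (gray level, run length) for one direction."""

    counts: np.ndarray  # G x R integer counts
    direction: int
    levels: int

    @property
    def n_runs(self) -> int:
        return int(self.counts.sum())


def quantize(image: np.ndarray, levels: int = 64,
             mask: np.ndarray | None = None) -> QuantizedImage:
    """Uniformly bin an 8-bit grayscale image into ``levels`` gray levels.

    The full dynamic range [0, 255] is split into ``levels`` equal bins, so
    the mapping is monotone and does not depend on the image content.
    """
    if levels < 2:
        raise ValueError("levels must be >= 2")
    img = np.asarray(image)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("image must be a nonempty 2-D grayscale array")
    img = np.clip(img, 0, 255)
    q = (img.astype(np.int64) * levels) // 256
    return QuantizedImage(pixels=q, levels=levels, mask=mask)


def _pair_indices(qimage: QuantizedImage, distance: int, direction: int):
    """Gray levels of the valid co-occurring pixel pairs for one offset."""
    dr, dc = _OFFSETS[direction]
    dr, dc = dr * distance, dc * distance
    px = qimage.pixels
    nrow, ncol = px.shape

    r0 = slice(max(0, -dr), min(nrow, nrow - dr))
    c0 = slice(max(0, -dc), min(ncol, ncol - dc))
    r1 = slice(max(0, dr), min(nrow, nrow + dr))
    c1 = slice(max(0, dc), min(ncol, ncol + dc))

    a = px[r0, c0]
    b = px[r1, c1]
    if qimage.mask is not None:
        valid = qimage.mask[r0, c0] & qimage.mask[r1, c1]
        a, b = a[valid], b[valid]
    return a.ravel(), b.ravel()


def compute_glcm(qimage: QuantizedImage, distance: int = 3,
                 direction: int = 0) -> CooccurrenceMatrix:
    """Count co-occurring gray-level pairs at one offset.

    Pairs are counted in both orders (symmetric matrix) and normalized to
    sum to one.  Pairs with either pixel outside the mask are dropped.
    """
    if direction not in _OFFSETS:
        raise ValueError(f"direction must be one of {DIRECTIONS}")
    if distance < 1:
        raise ValueError("distance must be >= 1")
    if min(qimage.shape) <= distance:
        raise ValueError("image dimensions must exceed the distance")
    a, b = _pair_indices(qimage, distance, direction)
    if a.size == 0:
        raise DegenerateInputError(
            f"no valid pixel pairs at distance {distance}, direction {direction}")
    G = qimage.levels
    counts = np.bincount(a * G + b, minlength=G * G).reshape(G, G).astype(float)
    counts = counts + counts.T
    counts /= counts.sum()
    return CooccurrenceMatrix(counts=counts, direction=direction,
                              distance=distance, levels=G)


def _xlogx(p: np.ndarray) -> np.ndarray:
    # natural log with the 0*log(0) = 0 convention
    out = np.zeros_like(p)
    nz = p > 0
    out[nz] = p[nz] * np.log(p[nz])
    return out


def glcm_features(glcm: CooccurrenceMatrix) -> dict[str, float]:
    """The eleven GLCM parameters used for trabecular texture.

    Definitions follow the Haralick set as implemented in the MaZda texture
    package: ``variance`` is the sum-of-squares variance, ``mean_sum`` the
    sum average, ``sum_of_variance`` the sum variance, ``residual_variance``
    the difference variance and ``entropy_difference`` the difference
    entropy.  All entropies use the natural logarithm.  ``correlation`` is
    undefined on a zero-variance (constant) image and is reported as NaN
    with a warning rather than coerced to a number.
    """
    P = glcm.counts
    G = glcm.levels
    if not np.isclose(P.sum(), 1.0, atol=1e-9):
        raise ValueError("GLCM must be normalized")
    i = np.arange(G, dtype=float)
    px = P.sum(axis=1)  # marginal (symmetric, so px == py)
    mu = float(i @ px)
    sigma2 = float(((i - mu) ** 2) @ px)

    ii, jj = np.meshgrid(i, i, indexing="ij")
    diff = np.abs(ii - jj).astype(np.intp)
    summ = (ii + jj).astype(np.intp)
    p_diff = np.bincount(diff.ravel(), weights=P.ravel(), minlength=G)
    p_sum = np.bincount(summ.ravel(), weights=P.ravel(), minlength=2 * G - 1)
    k_diff = np.arange(G, dtype=float)
    k_sum = np.arange(2 * G - 1, dtype=float)

    asm = float((P ** 2).sum())
    contrast = float((k_diff ** 2) @ p_diff)
    if sigma2 <= 0:
        warnings.warn("correlation undefined for zero-variance image; "
                      "reporting NaN", RuntimeWarning, stacklevel=2)
        correlation = float("nan")
    else:
        correlation = float(((ii * jj * P).sum() - mu * mu) / sigma2)
    variance = float((((ii - mu) ** 2) * P).sum())
    mean_sum = float(k_sum @ p_sum)
    sum_of_variance = float(((k_sum - mean_sum) ** 2) @ p_sum)
    entropy = float(-_xlogx(P).sum())
    sum_entropy = float(-_xlogx(p_sum).sum())
    entropy_difference = float(-_xlogx(p_diff).sum())
    mu_diff = float(k_diff @ p_diff)
    residual_variance = float(((k_diff - mu_diff) ** 2) @ p_diff)
    idm = float((P / (1.0 + (ii - jj) ** 2)).sum())

    return {
        "angular_second_moment": asm,
        "contrast": contrast,
        "correlation": correlation,
        "variance": variance,
        "sum_of_variance": sum_of_variance,
        "mean_sum": mean_sum,
        "entropy": entropy,
        "sum_entropy": sum_entropy,
        "entropy_difference": entropy_difference,
        "residual_variance": residual_variance,
        "inverse_difference_moment": idm,
    }


def _encode_runs(lines) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized run-length encoding of a list of (values, valid) lines.

    Lines are concatenated with a -1 separator so runs never straddle line
    boundaries; invalid (masked-out) pixels become separators too, which
    breaks runs at the mask edge.  Returns (gray levels, run lengths).
    """
    parts = []
    sep = np.array([-1], dtype=np.int64)
    for line, valid in lines:
        vals = np.where(np.asarray(valid), np.asarray(line, dtype=np.int64),
                        -1)
        parts.append(vals)
        parts.append(sep)
    flat = np.concatenate(parts)
    change = np.flatnonzero(np.diff(flat) != 0) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [flat.size]])
    levels = flat[starts]
    keep = levels >= 0
    return levels[keep], (ends - starts)[keep]


def _diagonals(arr: np.ndarray, anti: bool):
    a = arr[:, ::-1] if anti else arr
    nrow, ncol = a.shape
    for off in range(-(nrow - 1), ncol):
        yield np.diagonal(a, offset=off)


def compute_glrlm(qimage: QuantizedImage, direction: int = 0) -> RunLengthMatrix:
    """Gray-level run-length matrix along one direction.

    A run is a maximal sequence of pixels with the same quantized level
    along unit steps of the direction; every in-mask pixel belongs to
    exactly one run per direction.
    """
    if direction not in _OFFSETS:
        raise ValueError(f"direction must be one of {DIRECTIONS}")
    px = qimage.pixels
    mask = qimage.mask if qimage.mask is not None else np.ones(px.shape, bool)
    if not mask.any():
        raise DegenerateInputError("empty mask: no pixels to run-length encode")

    if direction == 0:
        lines = [(px[r], mask[r]) for r in range(px.shape[0])]
    elif direction == 90:
        lines = [(px[:, c], mask[:, c]) for c in range(px.shape[1])]
    elif direction == 45:
        # 45deg runs step up-right: anti-diagonals
        lines = list(zip(_diagonals(px, anti=True), _diagonals(mask, anti=True)))
    else:  # 135deg: main diagonals
        lines = list(zip(_diagonals(px, anti=False), _diagonals(mask, anti=False)))

    levels, lengths = _encode_runs(lines)
    max_len = int(lengths.max())
    counts = np.zeros((qimage.levels, max_len), dtype=np.int64)
    np.add.at(counts, (levels, lengths - 1), 1)
    return RunLengthMatrix(counts=counts, direction=direction,
                           levels=qimage.levels)


def glrlm_features(rlm: RunLengthMatrix) -> dict[str, float]:
    """Short/long run emphasis and the two non-uniformity statistics."""
    R = rlm.counts.astype(float)
    n_runs = R.sum()
    if n_runs <= 0:
        raise DegenerateInputError("run-length matrix holds no runs")
    r = np.arange(1, R.shape[1] + 1, dtype=float)
    sre = float((R / r ** 2).sum() / n_runs)
    lre = float((R * r ** 2).sum() / n_runs)
    gln = float((R.sum(axis=1) ** 2).sum() / n_runs)
    rln = float((R.sum(axis=0) ** 2).sum() / n_runs)
    return {
        "run_length_nonuniformity": rln,
        "grey_level_nonuniformity": gln,
        "short_run_emphasis": sre,
        "long_run_emphasis": lre,
    }


def directional_table(qimage: QuantizedImage, distance: int = 3
                      ) -> dict[str, dict[int, float]]:
    """All fifteen texture parameters in each of the four directions.

    Returns a mapping ``{parameter name -> {direction -> value}}``.  GLCM
    parameters are computed at the given distance; GLRLM parameters are
    distance-free.
    """
    table: dict[str, dict[int, float]] = {n: {} for n in TEXTURE_FEATURE_NAMES}
    for d in DIRECTIONS:
        g = glcm_features(compute_glcm(qimage, distance=distance, direction=d))
        r = glrlm_features(compute_glrlm(qimage, direction=d))
        for name, val in {**g, **r}.items():
            table[name][d] = val
    return table
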