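"""Synthetic two-class trabecular images and labeled feature matrices.

Real low-magnification micrographs of rat tibial slices are not
redistributable, so the package ships a generator that emulates their two
study groups:

* **SHAM** (sham-operated controls) — fine, dense trabecular network:
  short spatial correlation length and high bone-area fraction, hence
  rich, complex texture;
* **OVX** (ovariectomized, the estrogen-deficient osteoporosis model) —
  coarser, sparser struts: longer correlation length and lower fill
  fraction, the direction in which real osteoporotic images differ.

Images are thresholded Gaussian random fields: seeded white noise is
smoothed with a kernel of scale ``correlation_length``, thresholded at the
``fill_fraction`` quantile to produce a trabecular mask, rendered with soft
edges, optically blurred (``blur_sigma``) and corrupted with pixel noise
(``noise_sd``).  A mild vertical anisotropy is applied so that the
directional texture machinery has signal to weigh.  Everything is a pure
function of (parameters, seed).

A second generator produces labeled feature matrices with known
informative, redundant and pure-noise columns for exercising the feature
selector; the redundant columns mimic the strong inter-feature
correlations of real texture tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "ImageClassParams",
    "MatrixGenParams",
    "SHAM_PARAMS",
    "OVX_PARAMS",
    "gen_trabecular_image",
    "gen_dataset",
    "gen_feature_matrix",
]


@dataclass(frozen=True)
class ImageClassParams:
    """Texture statistics of one image class."""

    correlation_length: float  # pixels; scale of the smoothing kernel
    fill_fraction: float       # bone-area fraction in (0, 1)
    blur_sigma: float = 2.0    # optical blur of the low-power lens, pixels
    noise_sd: float = 6.0      # additive pixel noise, gray levels
    image_size: int = 512      # square image side
    anisotropy: float = 1.6    # vertical/horizontal kernel-scale ratio

    def __post_init__(self) -> None:
        if not 0 < self.fill_fraction < 1:
            raise ValueError("fill_fraction must lie strictly in (0, 1)")
        if self.correlation_length < 1:
            raise ValueError("correlation_length must be >= 1")


#: defaults emulating the two study groups (SHAM finer and denser than OVX)
SHAM_PARAMS = ImageClassParams(correlation_length=3.0, fill_fraction=0.45)
OVX_PARAMS = ImageClassParams(correlation_length=6.0, fill_fraction=0.28)


@dataclass(frozen=True)
class MatrixGenParams:
    """Layout of a synthetic labeled feature matrix."""

    n1: int = 34               # class +1 samples
    n2: int = 18               # class -1 samples
    p_informative: int = 8
    p_redundant: int = 6
    p_noise: int = 14
    effect_size: float = 2.0   # class-mean separation of informative columns
    redundancy_noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.p_informative < 1:
            raise ValueError("need at least one informative column")
        if min(self.n1, self.n2, self.p_redundant, self.p_noise) < 0:
            raise ValueError("counts must be nonnegative")
        if self.effect_size < 0:
            raise ValueError("effect size must be nonnegative")


def gen_trabecular_image(params: ImageClassParams, seed: int):
    """One synthetic micrograph; returns ``(image uint8, mask bool)``.

    The mask is the thresholded random field (the trabecular silhouette);
    the image renders bone bright on a dark marrow background.
    """
    rng = np.random.default_rng(seed)
    size = params.image_size
    field = rng.standard_normal((size, size))
    sig = params.correlation_length
    field = ndimage.gaussian_filter(field, sigma=(sig * params.anisotropy, sig),
                                    mode="wrap")
    thr = np.quantile(field, 1.0 - params.fill_fraction)
    mask = field >= thr
    if not mask.any() or mask.all():
        raise ValueError("parameters yield a degenerate (empty/full) mask")

    soft = ndimage.gaussian_filter(mask.astype(float), sigma=1.0)
    img = 55.0 + 150.0 * soft
    img = ndimage.gaussian_filter(img, sigma=params.blur_sigma)
    img += rng.normal(0.0, params.noise_sd, img.shape)
    return np.clip(img, 0, 255).astype(np.uint8), mask


def gen_dataset(n_sham: int = 34, n_ovx: int = 18,
                sham_params: ImageClassParams = SHAM_PARAMS,
                ovx_params: ImageClassParams = OVX_PARAMS,
                seed: int = 0):
    """A labeled image collection mirroring the 34 SHAM + 18 OVX design.

    Returns ``(images, masks, labels)`` with per-image seeds derived from
    the master seed via a seed sequence, so disjoint master seeds give
    disjoint datasets and the whole collection is reproducible.
    """
    if min(n_sham, n_ovx) < 1:
        raise ValueError("need at least one image per class")
    children = np.random.SeedSequence(seed).spawn(n_sham + n_ovx)
    images, masks, labels = [], [], []
    for k, child in enumerate(children):
        is_sham = k < n_sham
        params = sham_params if is_sham else ovx_params
        sub_seed = int(child.generate_state(1)[0] % (2 ** 31))
        img, mask = gen_trabecular_image(params, sub_seed)
        images.append(img)
        masks.append(mask)
        labels.append("SHAM" if is_sham else "OVX")
    return images, masks, labels


def gen_feature_matrix(params: MatrixGenParams):
    """Labeled feature matrix with known ground-truth support.

    Informative columns are Normal(+d/2, 1) in class +1 and Normal(-d/2, 1)
    in class -1 with d the effect size; redundant columns copy a random
    informative column plus Normal(0, redundancy_noise_sd); noise columns
    are standard normal, independent of the label.  Returns
    ``(A, Y, true_support)`` with Y in {-1, +1} and ``true_support`` the
    indices of the informative columns (they come first, then redundant,
    then noise).
    """
    rng = np.random.default_rng(params.seed)
    n = params.n1 + params.n2
    y = np.concatenate([np.ones(params.n1, int), -np.ones(params.n2, int)])
    half = params.effect_size / 2.0

    info = rng.standard_normal((n, params.p_informative)) + y[:, None] * half
    sources = rng.integers(0, params.p_informative, params.p_redundant)
    redundant = info[:, sources] + rng.normal(
        0.0, params.redundancy_noise_sd, (n, params.p_redundant))
    noise = rng.standard_normal((n, params.p_noise))

    A = np.hstack([info, redundant, noise])
    true_support = np.arange(params.p_informative)
    return A, y, true_support
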