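"""End-to-end feature extraction: images + masks -> 28-column tables.

Glue between the texture, weighting and shape stages.  Texture is computed
over the whole grayscale image (the low-power field of view is the unit of
analysis); shape comes from the binary ROI mask.  Each image yields

* 15 direction-weighted texture values (and, separately, their plain
  direction averages for the unweighted pipeline variants), and
* 13 shape values (6 ratios + 7 Hu moments),

in the fixed column order 15 texture then 13 shape.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .shape import SHAPE_FEATURE_NAMES, aggregate_shape
from .texture import TEXTURE_FEATURE_NAMES, directional_table, quantize
from .weighting import simple_average_table, weigh_table

__all__ = [
    "FEATURE_COLUMNS",
    "extract_image_features",
    "extract_tables",
]

#: fixed 28-column order of the fused feature table
FEATURE_COLUMNS = TEXTURE_FEATURE_NAMES + SHAPE_FEATURE_NAMES


def extract_image_features(image: np.ndarray, mask: np.ndarray,
                           config: PipelineConfig | None = None):
    """One image -> (simple texture, weighted texture, shape) dicts."""
    config = config or PipelineConfig()
    q = quantize(image, levels=config.levels)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        table = directional_table(q, distance=config.glcm_distance)
        simple = simple_average_table(table)
        weighted = weigh_table(table, sentinels=config.sentinels)
    shape = aggregate_shape(mask, min_area=config.min_component_area,
                            mode=config.shape_aggregation).values
    return simple, weighted, shape


def extract_tables(images, masks, config: PipelineConfig | None = None,
                   ids=None):
    """Image collection -> three aligned DataFrames.

    Returns ``(texture_simple, texture_weighted, shape)`` indexed by image
    id.  A failing image is skipped with a warning naming it; the
    remaining rows are still produced.
    """
    config = config or PipelineConfig()
    if ids is None:
        ids = [f"img{k:03d}" for k in range(len(images))]
    rows_s, rows_w, rows_h, kept = [], [], [], []
    for img_id, image, mask in zip(ids, images, masks):
        try:
            simple, weighted, shape = extract_image_features(image, mask,
                                                             config)
        except Exception as exc:  # error isolation: one bad file, not the run
            warnings.warn(f"skipping {img_id}: {exc}", RuntimeWarning,
                          stacklevel=2)
            continue
        rows_s.append(simple)
        rows_w.append(weighted)
        rows_h.append(shape)
        kept.append(img_id)
    if not kept:
        raise ValueError("feature extraction failed for every image")
    tex_s = pd.DataFrame(rows_s, index=kept)[list(TEXTURE_FEATURE_NAMES)]
    tex_w = pd.DataFrame(rows_w, index=kept)[list(TEXTURE_FEATURE_NAMES)]
    shp = pd.DataFrame(rows_h, index=kept)[list(SHAPE_FEATURE_NAMES)]
    return tex_s, tex_w, shp
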