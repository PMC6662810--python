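"""Reproducible study harnesses built on the synthetic generators.

Two canned experiments summarize what the pipeline delivers end to end:

* :func:`variant_accuracy_study` — generate many two-class image datasets
  (34 SHAM + 18 OVX each, the canonical design), run all six pipeline
  variants with LOOCV, and tabulate accuracies;
* :func:`support_recovery_study` — generate labeled feature matrices with
  known informative columns and score how reliably the dispersion selector
  recovers them.

Both are pure functions of their parameters and a master seed.
"""

from __future__ import annotations

import warnings
from dataclasses import replace

import numpy as np
import pandas as pd

from .evaluation import VARIANTS, run_all_variants
from .pipeline import extract_tables
from .selection import DispersionLasso
from .synthetic import (OVX_PARAMS, SHAM_PARAMS, MatrixGenParams, gen_dataset,
                        gen_feature_matrix)

__all__ = ["variant_accuracy_study", "support_recovery_study"]


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(c.generate_state(1)[0] % (2 ** 31)) for c in ss.spawn(n)]


def variant_accuracy_study(n_datasets: int = 20, image_size: int = 192,
                           n_sham: int = 34, n_ovx: int = 18,
                           seed: int = 0) -> pd.DataFrame:
    """LOOCV accuracy of every variant on independently generated datasets.

    Returns a DataFrame with one row per dataset and one column per
    variant tag.  ``image_size`` trades fidelity for runtime; the class
    contrast of the generator does not depend on it.
    """
    rows = []
    for ds_seed in _child_seeds(seed, n_datasets):
        images, masks, labels = gen_dataset(
            n_sham, n_ovx,
            sham_params=replace(SHAM_PARAMS, image_size=image_size),
            ovx_params=replace(OVX_PARAMS, image_size=image_size),
            seed=ds_seed)
        tex_s, tex_w, shp = extract_tables(images, masks)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            report = run_all_variants(tex_s, tex_w, shp, np.array(labels))
        rows.append({tag: report[tag]["ACC"] for tag in VARIANTS})
    return pd.DataFrame(rows)


def support_recovery_study(n_seeds: int = 100, n1: int = 30, n2: int = 30,
                           p_informative: int = 8, p_noise: int = 20,
                           effect_size: float = 2.0,
                           seed: int = 0) -> pd.DataFrame:
    """Selection quality of the dispersion model on known ground truth.

    Each row records, for one generated matrix, how many informative and
    how many non-informative columns the selector retained at the default
    (extended-BIC) penalty, plus whether the run counts as a recovery
    (at least ``p_informative - 1`` informative kept and at most 2
    spurious columns).
    """
    rows = []
    for mat_seed in _child_seeds(seed, n_seeds):
        params = MatrixGenParams(n1=n1, n2=n2, p_informative=p_informative,
                                 p_redundant=0, p_noise=p_noise,
                                 effect_size=effect_size, seed=mat_seed)
        A, y, true_support = gen_feature_matrix(params)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            result = DispersionLasso(A, y).fit()
        selected = set(result.support.tolist())
        truth = set(true_support.tolist())
        n_info = len(selected & truth)
        n_spurious = len(selected - truth)
        rows.append({"informative_kept": n_info,
                     "spurious_kept": n_spurious,
                     "recovered": (n_info >= p_informative - 1
                                   and n_spurious <= 2)})
    return pd.DataFrame(rows)
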