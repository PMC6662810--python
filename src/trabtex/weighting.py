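"""Variation-coefficient weighting of directional texture parameters.

At low magnification the four raster directions of a texture matrix can
disagree substantially, and plain averaging discards that anisotropy.  The
weighting implemented here uses the most direction-sensitive parameter of
each matrix family as a sentinel: per sample, the sentinel's four direction
values x(i,1..4) give

    mean        x_bar_i = (1/4) sum_j x(i,j)
    variation   v(i,j)  = |x(i,j) - x_bar_i| / x_bar_i
    weight      w(i,j)  = v(i,j) / sum_j v(i,j)

and every parameter p of that family is collapsed to the weighted average
p_bar_i = sum_j w(i,j) p(i,j).  Directions in which the sentinel deviates
most from its mean therefore contribute most.

Defaults follow the bone-texture use case: the GLCM family is weighted by
the correlation parameter (computed at pixel distance 3) and the GLRLM
family by the long run emphasis.
"""

from __future__ import annotations

import warnings

import numpy as np

from .texture import (DIRECTIONS, GLCM_FEATURE_NAMES, GLRLM_FEATURE_NAMES,
                      TEXTURE_FEATURE_NAMES)

__all__ = [
    "direction_mean",
    "variation_coefficients",
    "direction_weights",
    "weighted_value",
    "weigh_table",
    "simple_average_table",
    "rank_direction_sensitivity",
    "distance_stability",
    "SENTINELS",
]

#: sentinel (most direction-sensitive) parameter per matrix family
SENTINELS = {"glcm": "correlation", "glrlm": "long_run_emphasis"}

UNIFORM = np.full(4, 0.25)


class DegenerateMeanError(ValueError):
    """Sentinel mean is zero; the variation coefficient is undefined."""


def _as4(x) -> np.ndarray:
    a = np.asarray(x, dtype=float).ravel()
    if a.size != 4:
        raise ValueError("expected exactly 4 direction values")
    if not np.all(np.isfinite(a)):
        raise ValueError("direction values must be finite")
    return a


def direction_mean(x) -> float:
    """Arithmetic mean of the four direction values."""
    return float(_as4(x).mean())


def variation_coefficients(x) -> np.ndarray:
    """Per-direction relative deviation |x_j - x_bar| / x_bar."""
    a = _as4(x)
    m = a.mean()
    if m == 0:
        raise DegenerateMeanError("sentinel mean is zero")
    return np.abs(a - m) / m


def direction_weights(v) -> np.ndarray:
    """Normalize variation coefficients to weights summing to one.

    An isotropic sentinel gives all-zero coefficients; the weights then
    fall back to uniform 1/4 (plain averaging), with a warning.
    """
    a = np.asarray(v, dtype=float).ravel()
    if a.size != 4:
        raise ValueError("expected 4 variation coefficients")
    if np.any(a < 0):
        raise ValueError("variation coefficients must be nonnegative")
    s = a.sum()
    if s == 0:
        warnings.warn("all variation coefficients are zero; falling back to "
                      "uniform weights", RuntimeWarning, stacklevel=2)
        return UNIFORM.copy()
    return a / s


def weighted_value(w, p) -> float:
    """Convex combination sum_j w_j p_j of the four direction values."""
    wa = _as4(w)
    if not np.isclose(wa.sum(), 1.0, atol=1e-9):
        raise ValueError("weights must sum to 1")
    return float(wa @ _as4(p))


def _sentinel_weights(table: dict[str, dict[int, float]],
                      sentinel: str) -> np.ndarray:
    x = np.array([table[sentinel][d] for d in DIRECTIONS], dtype=float)
    if not np.all(np.isfinite(x)) or x.mean() == 0:
        warnings.warn(f"sentinel '{sentinel}' undefined or zero-mean; using "
                      "uniform weights", RuntimeWarning, stacklevel=3)
        return UNIFORM.copy()
    v = variation_coefficients(x)
    if v.sum() == 0:
        warnings.warn(f"sentinel '{sentinel}' is isotropic; using uniform "
                      "weights", RuntimeWarning, stacklevel=3)
        return UNIFORM.copy()
    return direction_weights(v)


def weigh_table(table: dict[str, dict[int, float]],
                sentinels: dict[str, str] = SENTINELS) -> dict[str, float]:
    """Collapse a 15-parameter x 4-direction table to 15 weighted scalars.

    One weight vector is derived per matrix family from that family's
    sentinel parameter and applied to every parameter of the family.  An
    undefined sentinel (e.g. correlation on a constant image) falls back to
    uniform weights.
    """
    w_glcm = _sentinel_weights(table, sentinels["glcm"])
    w_glrlm = _sentinel_weights(table, sentinels["glrlm"])
    out: dict[str, float] = {}
    for name in TEXTURE_FEATURE_NAMES:
        w = w_glcm if name in GLCM_FEATURE_NAMES else w_glrlm
        p = np.array([table[name][d] for d in DIRECTIONS], dtype=float)
        out[name] = float(w @ p)
    return out


def simple_average_table(table: dict[str, dict[int, float]]) -> dict[str, float]:
    """Plain (unweighted) mean over the four directions, per parameter."""
    return {name: float(np.mean([table[name][d] for d in DIRECTIONS]))
            for name in TEXTURE_FEATURE_NAMES}


def rank_direction_sensitivity(tables) -> dict[str, list[tuple[str, float]]]:
    """Rank parameters by direction sensitivity, per matrix family.

    The sensitivity score of a parameter is the coefficient of variation
    across the four directions (population std / |mean|), averaged over
    samples.  Parameters whose directional mean is zero in any sample are
    excluded with a warning.  Returns descending ``(name, score)`` lists
    under the keys ``"glcm"`` and ``"glrlm"``.
    """
    tables = list(tables)
    if not tables:
        raise ValueError("need at least one sample table")
    scores: dict[str, float] = {}
    for name in TEXTURE_FEATURE_NAMES:
        cvs = []
        ok = True
        for t in tables:
            x = np.array([t[name][d] for d in DIRECTIONS], dtype=float)
            m = x.mean()
            if m == 0 or not np.all(np.isfinite(x)):
                ok = False
                break
            cvs.append(x.std() / abs(m))
        if not ok:
            warnings.warn(f"parameter '{name}' has zero or undefined "
                          "directional mean; excluded from ranking",
                          RuntimeWarning, stacklevel=2)
            continue
        scores[name] = float(np.mean(cvs))
    out = {}
    for family, names in (("glcm", GLCM_FEATURE_NAMES),
                          ("glrlm", GLRLM_FEATURE_NAMES)):
        fam = [(n, scores[n]) for n in names if n in scores]
        fam.sort(key=lambda kv: -kv[1])
        out[family] = fam
    return out


def distance_stability(qimages, distances=(1, 2, 3, 4, 5),
                       parameters=("contrast", "correlation", "entropy",
                                   "inverse_difference_moment"),
                       threshold: float = 0.05):
    """Scan GLCM distances and recommend the smallest stable one.

    For each candidate distance the monitored GLCM parameters are averaged
    over all images and directions.  The recommended distance is the
    smallest ``d`` from which on the relative change of every monitored
    parameter between consecutive distances stays below ``threshold``
    (default 5%).  If no distance qualifies, the distance entering the step
    of minimal total relative change is returned with a warning.

    Returns ``(profiles, recommended)`` where ``profiles`` maps parameter
    name -> mean value per distance.
    """
    from .texture import compute_glcm, glcm_features

    distances = list(distances)
    if len(distances) < 2:
        raise ValueError("need at least 2 distances to assess stability")
    if sorted(distances) != distances:
        raise ValueError("distances must be sorted ascending")

    qimages = list(qimages)
    profiles = {p: [] for p in parameters}
    for d in distances:
        acc = {p: [] for p in parameters}
        for q in qimages:
            for direction in DIRECTIONS:
                feats = glcm_features(compute_glcm(q, distance=d,
                                                   direction=direction))
                for p in parameters:
                    acc[p].append(feats[p])
        for p in parameters:
            profiles[p].append(float(np.mean(acc[p])))

    rec = _recommend_distance(profiles, distances, threshold)
    return profiles, rec


def _recommend_distance(profiles: dict[str, list[float]], distances,
                        threshold: float) -> int:
    """Stability rule shared by ``distance_stability`` and its tests."""
    n = len(distances)
    rel = np.zeros((len(profiles), n - 1))
    for k, vals in enumerate(profiles.values()):
        v = np.asarray(vals, dtype=float)
        denom = np.where(np.abs(v[:-1]) > 0, np.abs(v[:-1]), 1.0)
        rel[k] = np.abs(np.diff(v)) / denom
    step_ok = (rel < threshold).all(axis=0)
    for i in range(n - 1):
        if step_ok[i:].all():
            return distances[i]
    warnings.warn("no distance reaches the stability threshold; returning "
                  "the distance with minimal total change", RuntimeWarning,
                  stacklevel=3)
    totals = rel.sum(axis=0)
    best = len(totals) - 1 - int(np.argmin(totals[::-1]))  # ties -> largest d
    return distances[best]
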