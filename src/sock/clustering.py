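"""Adaptive, deterministic k-means labeling of component features.

Two labelings are produced without any training data:

* **Smoothness** — a two-stage nested 2-means on the ratio curves.  Stage
  one splits all curves into two clusters; the higher-mean cluster is
  *Smooth*.  Stage two splits the remaining cluster again; the higher-mean
  subcluster is *Subsmooth*, the lower *Unsmooth*.
* **Binary High/Low** — a scalar 2-means on edge activities or TFN values;
  the larger-centroid cluster is *High*.

Degenerate inputs (too few components, zero variance) fall back to the
non-rejecting label (Smooth / Low) with a warning, so degeneracy can never
cause a component to be discarded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from sock.features import RatioCurveSet
from sock.ica_io import SockInputError

SMOOTH, SUBSMOOTH, UNSMOOTH = "Smooth", "Subsmooth", "Unsmooth"
HIGH, LOW = "High", "Low"

#: Nested binary splits need at least this many curves.
MIN_N_SMOOTHNESS = 6
#: A scalar 2-means needs at least this many values.
MIN_N_BINARY = 4

_N_RESTARTS = 10


@dataclass
class SmoothnessLabels:
    labels: np.ndarray  # dtype=object over {Smooth, Subsmooth, Unsmooth}


@dataclass
class BinaryLabels:
    labels: np.ndarray  # dtype=object over {High, Low}
    feature_name: str


def _curve_features(curves: np.ndarray) -> np.ndarray:
    """log10 + per-radius z-scoring.

    The log compresses the huge dynamic range of the ratios (capped values
    reach 1e12); standardizing each radius stops any single radius from
    dominating the Euclidean metric.  Zero-variance radii map to 0.
    """
    logged = np.log10(np.maximum(curves, 1e-30))
    std = logged.std(axis=0)
    std[std == 0] = 1.0
    return (logged - logged.mean(axis=0)) / std


def _kmeans2(points: np.ndarray, seed: int) -> np.ndarray:
    km = KMeans(n_clusters=2, n_init=_N_RESTARTS, random_state=seed)
    return km.fit_predict(points)


def cluster_smoothness(curves: RatioCurveSet, seed: int = 0) -> SmoothnessLabels:
    """Three-way Smooth / Subsmooth / Unsmooth labeling of ratio curves.

    Each curve is one point in an R-dimensional Euclidean space (after the
    log/standardize transform); cluster ordering uses the mean transformed
    curve value, highest mean first.  Deterministic given ``seed``.
    """
    n = curves.n_components
    labels = np.empty(n, dtype=object)
    if n < MIN_N_SMOOTHNESS:
        warnings.warn(
            f"only {n} components (< {MIN_N_SMOOTHNESS}); smoothness clustering "
            "skipped, all components labeled Smooth"
        )
        labels[:] = SMOOTH
        return SmoothnessLabels(labels=labels)

    feats = _curve_features(curves.curves)
    heights = feats.mean(axis=1)  # per-curve mean, orders the clusters
    if np.allclose(feats, feats[0]):
        warnings.warn("all ratio curves identical; all components labeled Smooth")
        labels[:] = SMOOTH
        return SmoothnessLabels(labels=labels)

    assign1 = _kmeans2(feats, seed)
    means1 = [heights[assign1 == c].mean() for c in (0, 1)]
    smooth_c = int(np.argmax(means1))
    labels[assign1 == smooth_c] = SMOOTH

    lower_idx = np.flatnonzero(assign1 != smooth_c)
    lower = feats[lower_idx]
    if len(lower_idx) < 2 or np.allclose(lower, lower[0]):
        warnings.warn(
            "lower smoothness cluster cannot be split further; "
            "its components are labeled Subsmooth"
        )
        labels[lower_idx] = SUBSMOOTH
        return SmoothnessLabels(labels=labels)

    assign2 = _kmeans2(lower, seed)
    means2 = [heights[lower_idx[assign2 == c]].mean() for c in (0, 1)]
    sub_c = int(np.argmax(means2))
    labels[lower_idx[assign2 == sub_c]] = SUBSMOOTH
    labels[lower_idx[assign2 != sub_c]] = UNSMOOTH
    return SmoothnessLabels(labels=labels)


def _best_contiguous_split(values: np.ndarray) -> np.ndarray:
    """Exact 1-D 2-means: the global optimum is a contiguous split of the
    sorted values, so scan all n-1 splits for minimum within-cluster SSE.
    Returns a boolean array, True = upper (High) cluster."""
    order = np.argsort(values, kind="stable")
    v = values[order]
    n = len(v)
    prefix = np.concatenate([[0.0], np.cumsum(v)])
    prefix2 = np.concatenate([[0.0], np.cumsum(v**2)])

    def sse(lo: int, hi: int) -> float:  # half-open [lo, hi)
        s, s2, m = prefix[hi] - prefix[lo], prefix2[hi] - prefix2[lo], hi - lo
        return s2 - s * s / m

    costs = [sse(0, k) + sse(k, n) for k in range(1, n)]
    k_best = int(np.argmin(costs)) + 1  # lowest split index on ties
    upper = np.zeros(n, dtype=bool)
    upper[order[k_best:]] = True
    return upper


def cluster_binary(values: np.ndarray, feature_name: str, seed: int = 0) -> BinaryLabels:
    """High/Low labeling of scalar feature values by exact 1-D 2-means.

    The returned partition minimizes within-cluster sum of squares (the
    k-means objective, solved exactly in one dimension); the cluster with
    the larger centroid is High.  ``seed`` is accepted for interface
    symmetry — the exact solver is deterministic without it.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    labels = np.empty(n, dtype=object)
    if n < MIN_N_BINARY:
        warnings.warn(
            f"only {n} values for {feature_name} (< {MIN_N_BINARY}); "
            "clustering skipped, all labeled Low"
        )
        labels[:] = LOW
        return BinaryLabels(labels=labels, feature_name=feature_name)
    if np.ptp(values) == 0:
        warnings.warn(f"all {feature_name} values equal; all labeled Low")
        labels[:] = LOW
        return BinaryLabels(labels=labels, feature_name=feature_name)

    upper = _best_contiguous_split(values)
    labels[upper] = HIGH
    labels[~upper] = LOW
    return BinaryLabels(labels=labels, feature_name=feature_name)
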