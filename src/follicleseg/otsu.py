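"""Multilevel Otsu thresholding.

Otsu's criterion picks thresholds minimizing the total within-class intensity
variance (equivalently maximizing the between-class variance) of the gray
histogram.  With thresholds t1 < t2 < ... < tk the gray range splits into
half-open classes

    class 0 = [0, t1),  class 1 = [t1, t2),  ...,  class k = [tk, 256),

lower-inclusive / upper-exclusive.  The solver is exact: cumulative zeroth,
first and second moments give each interval's squared-deviation sum in O(1),
and a dynamic program over the class count finds the global optimum.  Ties are
broken toward the lexicographically smallest threshold tuple.

Follicles are hypoechoic, so the darkest class (class 0) is the default
foreground when the thresholded image is turned into a binary seed mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["DegenerateHistogramError", "ThresholdSet", "histogram", "multilevel_otsu", "otsu_mask"]


class DegenerateHistogramError(ValueError):
    """Histogram has too few occupied bins for the requested class count."""


@dataclass(frozen=True)
class ThresholdSet:
    """Ordered Otsu thresholds and the attained objective.

    ``thresholds`` are strictly increasing integers in [1, 255];
    ``within_class_variance`` is the minimized total within-class variance
    (weighted by class probability) on the source histogram.
    """

    thresholds: tuple[int, ...]
    within_class_variance: float

    @property
    def k(self) -> int:
        return len(self.thresholds)

    def __iter__(self):
        return iter(self.thresholds)

    def class_index(self, values: np.ndarray) -> np.ndarray:
        """Class of each gray value under the half-open partition."""
        return np.searchsorted(np.asarray(self.thresholds), values, side="right")


def histogram(img: np.ndarray) -> np.ndarray:
    """256-bin gray-level histogram (integer counts)."""
    img = np.asarray(img)
    if img.dtype != np.uint8:
        raise ValueError(f"histogram: expected uint8 image, got {img.dtype}")
    return np.bincount(img.ravel(), minlength=256)


def _interval_sse(counts: np.ndarray) -> np.ndarray:
    """Matrix S[i, j] = squared-deviation sum of bins [i, j), via prefix moments."""
    v = np.arange(256, dtype=np.float64)
    c = counts.astype(np.float64)
    p0 = np.concatenate(([0.0], np.cumsum(c)))
    p1 = np.concatenate(([0.0], np.cumsum(c * v)))
    p2 = np.concatenate(([0.0], np.cumsum(c * v * v)))
    n = p0[None, :] - p0[:, None]  # pixels in [i, j)
    s1 = p1[None, :] - p1[:, None]
    s2 = p2[None, :] - p2[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        sse = s2 - np.where(n > 0, s1 * s1 / np.where(n > 0, n, 1.0), 0.0)
    sse[n <= 0] = 0.0
    return sse


def multilevel_otsu(hist: np.ndarray, k: int = 4) -> ThresholdSet:
    """Exact k-threshold Otsu partition of a 256-bin histogram.

    Minimizes the total within-class variance over all strictly increasing
    threshold tuples; among cost ties the lexicographically smallest tuple is
    returned.  Requires at least k + 1 occupied bins.
    """
    hist = np.asarray(hist)
    if hist.ndim != 1 or len(hist) != 256 or (hist < 0).any():
        raise ValueError("multilevel_otsu: hist must be 256 non-negative counts")
    total = int(hist.sum())
    if total <= 0:
        raise DegenerateHistogramError("multilevel_otsu: empty histogram")
    if k < 1:
        raise ValueError(f"multilevel_otsu: k must be >= 1, got {k}")
    occupied = int(np.count_nonzero(hist))
    if occupied < k + 1:
        raise DegenerateHistogramError(
            f"multilevel_otsu: need at least {k + 1} occupied bins for k={k}, "
            f"histogram has {occupied}"
        )

    sse = _interval_sse(hist)

    # g[m][i] = minimal summed SSE partitioning bins [i, 256) into m classes.
    # Suffix DP so the reconstruction below can pick thresholds greedily from
    # the left, which yields the lexicographically smallest optimal tuple.
    g = np.empty((k + 2, 257))
    g[1, :] = sse[:, 256]
    idx = np.arange(257)
    for m in range(2, k + 2):
        # cand[i, t] = sse[i, t] + g[m-1, t], valid for i < t <= 255
        cand = sse[:, :256] + g[m - 1, :256][None, :]
        cand[idx[:, None] >= idx[None, :256]] = np.inf
        cand[:, 0] = np.inf  # thresholds live in [1, 255]
        g[m, :] = cand.min(axis=1)

    thresholds: list[int] = []
    i = 0
    for m in range(k + 1, 1, -1):
        costs = sse[i, 1:256] + g[m - 1, 1:256]
        valid = np.arange(1, 256) > i
        costs = np.where(valid, costs, np.inf)
        # smallest t attaining g[m, i]; equality is exact because g[m, i] was
        # computed as the minimum of these same float expressions
        t = int(np.argmin(costs)) + 1
        thresholds.append(t)
        i = t

    return ThresholdSet(tuple(thresholds), float(g[k + 1, 0] / total))


def otsu_mask(
    img: np.ndarray, ts: ThresholdSet, fg_classes: tuple[int, ...] = (0,)
) -> np.ndarray:
    """Binary seed mask: True where a pixel's Otsu class is in ``fg_classes``.

    Class 0 (darkest) is the default foreground, matching hypoechoic follicles.
    """
    img = np.asarray(img)
    if img.dtype != np.uint8:
        raise ValueError(f"otsu_mask: expected uint8 image, got {img.dtype}")
    n_classes = ts.k + 1
    fg = tuple(fg_classes)
    if any(c < 0 or c >= n_classes for c in fg):
        raise IndexError(f"otsu_mask: fg_classes {fg} outside [0, {n_classes})")
    return np.isin(ts.class_index(img), fg)
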