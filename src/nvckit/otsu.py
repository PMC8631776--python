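"""Histogram thresholding by between-class-variance maximization (Otsu).

The threshold returned is the *upper edge* of the last bin assigned to the
lower class, so that classifying with ``x > threshold`` realizes exactly the
partition that maximized the between-class variance.  A bin-center
convention would misclassify any histogram spike falling in the split bin
itself — precisely the situation at the partial-intensity rim of a smoothed
vessel, where a whole population of edge pixels shares one value.
"""

from __future__ import annotations

import numpy as np

__all__ = ["otsu_threshold", "between_class_variance"]


def otsu_threshold(values: np.ndarray, nbins: int = 256) -> float:
    """Threshold maximizing between-class variance on an ``nbins`` histogram.

    Parameters
    ----------
    values
        Sample values (any shape; flattened).
    nbins
        Histogram resolution; candidate thresholds are the interior bin
        edges.

    Returns
    -------
    float
        The bin edge separating the two classes (first optimum on ties).

    Raises
    ------
    ValueError
        If the values have no spread (the histogram is a single spike).
    """
    x = np.asarray(values, dtype=float).ravel()
    hist, edges = np.histogram(x, bins=nbins)
    w = hist.astype(float)
    if np.count_nonzero(w) < 2:
        raise ValueError("between-class variance undefined for constant input")
    centers = (edges[:-1] + edges[1:]) / 2.0
    # split after bin i: lower class = bins [0, i], upper = bins (i, nbins)
    w0 = np.cumsum(w)[:-1]
    w1 = w.sum() - w0
    s0 = np.cumsum(w * centers)[:-1]
    s1 = (w * centers).sum() - s0
    valid = (w0 > 0) & (w1 > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        var = w0 * w1 * (s0 / w0 - s1 / w1) ** 2
    var[~valid] = -np.inf
    idx = int(np.argmax(var))
    return float(edges[idx + 1])


def between_class_variance(values: np.ndarray, threshold: float) -> float:
    """Between-class variance of the split ``values > threshold`` (data level)."""
    x = np.asarray(values, dtype=float).ravel()
    lo = x[x <= threshold]
    hi = x[x > threshold]
    if lo.size == 0 or hi.size == 0:
        return 0.0
    w0 = lo.size / x.size
    w1 = hi.size / x.size
    return float(w0 * w1 * (lo.mean() - hi.mean()) ** 2)
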