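"""Pairwise comparison of fold-change vectors.

Each panel compares two per-gene logFC vectors (muscle vs muscle for the
same contrast, or age-contrast vs drug-contrast within a muscle). The
summary line drawn through the cloud is the direction of highest variance:
the leading eigenvector of the 2x2 covariance matrix (orthogonal /
total-least-squares fit), passing through the centroid. Pearson r and an
ordinary least-squares slope are reported alongside for reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class PairwiseFit:
    slope: float
    intercept: float
    r: float
    n: int
    ols_slope: float
    ols_intercept: float
    vertical: bool = False  # leading eigenvector parallel to the y axis

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.slope * np.asarray(x) + self.intercept


def tls_slope_closed_form(vxx: float, vyy: float, vxy: float) -> float:
    """Leading-eigenvector slope of [[vxx, vxy], [vxy, vyy]] for vxy != 0."""
    if vxy == 0:
        raise ValueError("closed form requires a nonzero covariance")
    return (vyy - vxx + np.sqrt((vyy - vxx) ** 2 + 4 * vxy**2)) / (2 * vxy)


def tls_fit(x, y) -> PairwiseFit:
    """Orthogonal-regression (PC1-direction) fit of paired logFC vectors.

    The slope follows the leading eigenvector of the 2x2 covariance of
    (x, y); the line passes through the centroid. Unlike ordinary least
    squares, swapping x and y maps the slope to its reciprocal. A vertical
    leading direction is reported as an infinite slope with a flag.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and paired")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 genes")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values")
    cov = np.cov(x, y, ddof=1)
    vxx, vyy, vxy = cov[0, 0], cov[1, 1], cov[0, 1]
    if vxx == 0 and vyy == 0:
        raise ValueError("zero variance in both coordinates; fit undefined")
    evals, evecs = np.linalg.eigh(cov)
    lead = evecs[:, np.argmax(evals)]
    xbar, ybar = x.mean(), y.mean()
    if lead[0] == 0:
        slope, intercept, vertical = np.inf, np.nan, True
    else:
        slope = lead[1] / lead[0]
        intercept = ybar - slope * xbar
        vertical = False
    if vxx > 0 and vyy > 0:
        r = vxy / np.sqrt(vxx * vyy)
    else:
        r = 0.0
    ols_slope = vxy / vxx if vxx > 0 else np.inf
    ols_intercept = ybar - ols_slope * xbar if np.isfinite(ols_slope) else np.nan
    return PairwiseFit(float(slope), float(intercept), float(r), n, float(ols_slope), float(ols_intercept), vertical)


def density_grid(x, y, bins: int = 50):
    """2-D histogram over an equal-width grid spanning the data range.

    Returns (counts, x_edges, y_edges); counts sum to n.
    """
    if bins < 2:
        raise ValueError("need at least 2 bins")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    counts, xe, ye = np.histogram2d(x, y, bins=bins)
    return counts, xe, ye
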