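"""Costes automatic thresholding and Manders colocalization.

The Costes procedure fits an orthogonal (total least squares) line
ch2 = a*ch1 + b through the ROI pixels, then walks the channel-1
threshold down over the distinct observed intensities with the
channel-2 threshold slaved to the line, stopping at the first pair for
which the below-threshold pixels are uncorrelated (Pearson r <= 0 or
undefined).  Manders coefficients are then intensity fractions above
the partner threshold:

    M1 = sum(ch1 where ch2 > t2) / sum(ch1)
    M2 = sum(ch2 where ch1 > t1) / sum(ch2)

Region effects (e.g. soma vs neuropil) are compared by one-way ANOVA
with eta^2 as the effect size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .effects import one_way_anova

__all__ = [
    "ImagePair",
    "subtract_background",
    "costes_threshold",
    "manders",
    "compare_regions",
]


@dataclass
class ImagePair:
    """Two registered single-channel images plus optional named ROI masks."""

    ch1: np.ndarray
    ch2: np.ndarray
    roi_masks: dict[str, np.ndarray] = field(default_factory=dict)
    background_subtracted: bool = False

    def __post_init__(self) -> None:
        self.ch1 = np.asarray(self.ch1, dtype=float)
        self.ch2 = np.asarray(self.ch2, dtype=float)
        if self.ch1.shape != self.ch2.shape:
            raise ValueError("channel shapes differ")
        if (self.ch1 < 0).any() or (self.ch2 < 0).any():
            raise ValueError("intensities must be non-negative")
        for name, mask in self.roi_masks.items():
            mask = np.asarray(mask, dtype=bool)
            if mask.shape != self.ch1.shape:
                raise ValueError(f"ROI mask {name!r} does not match image bounds")
            self.roi_masks[name] = mask

    def roi(self, name: str | None) -> np.ndarray:
        if name is None:
            return np.ones(self.ch1.shape, dtype=bool)
        return self.roi_masks[name]


def subtract_background(image: np.ndarray, scalar_mean: float) -> np.ndarray:
    """Subtract a scalar background estimate, clipping at zero."""
    if scalar_mean < 0:
        raise ValueError("background mean must be >= 0")
    return np.clip(np.asarray(image, dtype=float) - scalar_mean, 0.0, None)


def _tls_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Orthogonal-regression slope and intercept of y on x."""
    mx, my = x.mean(), y.mean()
    u, v = x - mx, y - my
    sxx, syy, sxy = (u * u).mean(), (v * v).mean(), (u * v).mean()
    if sxy == 0 and sxx >= syy:
        slope = 0.0
    else:
        # major-axis slope of the 2x2 covariance matrix
        d = syy - sxx
        slope = (d + np.hypot(d, 2 * sxy)) / (2 * sxy) if sxy != 0 else np.inf
    intercept = my - slope * mx
    return float(slope), float(intercept)


def _pearson_prefix(sums: dict, n: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        cov = sums["xy"] - sums["x"] * sums["y"] / n
        vx = sums["xx"] - sums["x"] ** 2 / n
        vy = sums["yy"] - sums["y"] ** 2 / n
        r = cov / np.sqrt(vx * vy)
    r[(n < 2) | ~np.isfinite(r)] = np.nan
    return r


def costes_threshold(
    pair: ImagePair, roi: str | np.ndarray | None = None
) -> tuple[float, float, float, float]:
    """Costes automatic threshold pair for an ROI.

    Returns (t1, t2, slope, intercept).  The scan descends over the
    sorted distinct channel-1 intensities from the maximum, with
    t2 = slope*t1 + intercept; it stops at the first candidate whose
    strictly-below-threshold pixel set has Pearson correlation <= 0 or
    undefined (fewer than two pixels, or constant).  If no candidate
    stops the scan, the channel minima are returned.
    """
    mask = pair.roi(roi) if isinstance(roi, (str, type(None))) else np.asarray(roi, bool)
    x = pair.ch1[mask].ravel()
    y = pair.ch2[mask].ravel()
    if x.size < 2 or np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("both channels need nonzero variance within the ROI")
    a, b = _tls_line(x, y)
    cand = np.unique(x)[::-1]  # distinct intensities, descending

    if np.isfinite(a) and a > 0:
        # below-set membership is monotone in t1: pixel in-set iff
        # t1 > max(x, (y - b) / a); prefix sums over exit thresholds.
        exit_t = np.maximum(x, (y - b) / a)
        order = np.argsort(exit_t, kind="stable")
        xs, ys = x[order], y[order]
        exits = exit_t[order]
        cum = {
            "x": np.concatenate(([0.0], np.cumsum(xs))),
            "y": np.concatenate(([0.0], np.cumsum(ys))),
            "xx": np.concatenate(([0.0], np.cumsum(xs * xs))),
            "yy": np.concatenate(([0.0], np.cumsum(ys * ys))),
            "xy": np.concatenate(([0.0], np.cumsum(xs * ys))),
        }
        n_in = np.searchsorted(exits, cand, side="left").astype(float)
        sums = {k: v[n_in.astype(int)] for k, v in cum.items()}
        r = _pearson_prefix(sums, n_in)
        stop = np.isnan(r) | (r <= 0)
        if stop.any():
            t1 = float(cand[np.argmax(stop)])
            return t1, float(a * t1 + b), a, b
    else:
        for t1 in cand:
            t2 = a * t1 + b
            below = (x < t1) & (y < t2)
            n = int(below.sum())
            if n < 2:
                return float(t1), float(t2), a, b
            bx, by = x[below], y[below]
            if np.ptp(bx) == 0 or np.ptp(by) == 0:
                return float(t1), float(t2), a, b
            r = np.corrcoef(bx, by)[0, 1]
            if not np.isfinite(r) or r <= 0:
                return float(t1), float(t2), a, b
    return float(x.min()), float(y.min()), a, b


def manders(
    pair: ImagePair,
    t1: float,
    t2: float,
    roi: str | np.ndarray | None = None,
) -> tuple[float, float]:
    """Manders coefficients (M1, M2) at thresholds (t1, t2) within an ROI.

    M1 is the fraction of channel-1 intensity on pixels where channel 2
    exceeds t2; M2 swaps the channels.  A zero-intensity denominator
    channel yields NaN for that coefficient.
    """
    mask = pair.roi(roi) if isinstance(roi, (str, type(None))) else np.asarray(roi, bool)
    x = pair.ch1[mask].ravel()
    y = pair.ch2[mask].ravel()
    sum1, sum2 = x.sum(), y.sum()
    m1 = float(x[y > t2].sum() / sum1) if sum1 > 0 else float("nan")
    m2 = float(y[x > t1].sum() / sum2) if sum2 > 0 else float("nan")
    return m1, m2


def compare_regions(values_by_region: dict[str, np.ndarray]) -> dict:
    """One-way ANOVA of per-image coefficients grouped by region.

    Returns F, df, p, and eta^2 = SS_between / SS_total.
    """
    return one_way_anova(values_by_region)
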