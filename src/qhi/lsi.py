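"""Laser speckle imaging: spatial contrast, flow index, beta correction.

A raw speckle frame is reduced to a spatial contrast map ``K = sigma/mean``
over a sliding window (default 5x5), converted to a speckle flow index
``SFI = 1/(2 T K^2)`` and normalized by the instrument factor ``beta``
estimated from a static phantom.

Estimator conventions, held fixed so the brute-force oracle matches:
``sigma`` is the sample standard deviation (N-1 denominator); pixels whose
window exits the frame are flagged invalid rather than padded, because
padding biases K near edges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "ContrastMap",
    "FlowMap",
    "BetaFactor",
    "speckle_contrast",
    "sfi",
    "estimate_beta",
    "beta_correct",
    "roi_timecourse",
]


@dataclass
class ContrastMap:
    """Speckle contrast image with its exposure and window size."""

    k: np.ndarray
    exposure: float
    window: int
    invalid: np.ndarray


@dataclass
class FlowMap:
    """Per-pixel flow map: SFI (1/s) or Db (mm^2/s)."""

    values: np.ndarray
    units: str
    invalid: np.ndarray


@dataclass(frozen=True)
class BetaFactor:
    """Instrument normalization factor, squared static-phantom contrast."""

    beta: float
    source: str = ""

    def __post_init__(self):
        if not (0.0 < self.beta <= 1.0):
            raise ValueError(f"beta must be in (0, 1], got {self.beta}")


def speckle_contrast(frame: np.ndarray, window: int = 5,
                     exposure: float = 0.010) -> ContrastMap:
    """Sliding-window spatial speckle contrast ``K = sigma(I)/<I>``.

    The center pixel of each full window is assigned the ratio of the
    window's sample standard deviation to its mean.  A border of
    ``window//2`` pixels, and any window with non-positive mean, is flagged
    invalid.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 1, got {window}")
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2:
        raise ValueError("frame must be 2-D")
    if np.any(frame < 0):
        raise ValueError("frame intensities must be non-negative")
    h, w = frame.shape
    r = window // 2
    k = np.full((h, w), np.nan)
    invalid = np.ones((h, w), dtype=bool)
    if h >= window and w >= window:
        win = sliding_window_view(frame, (window, window))
        mean = win.mean(axis=(-2, -1))
        sd = win.std(axis=(-2, -1), ddof=1)
        ok = mean > 0
        inner_k = np.full(mean.shape, np.nan)
        np.divide(sd, mean, out=inner_k, where=ok)
        k[r:h - r, r:w - r] = inner_k
        invalid[r:h - r, r:w - r] = ~ok
    return ContrastMap(k=k, exposure=exposure, window=window, invalid=invalid)


def sfi(c: ContrastMap) -> FlowMap:
    """Speckle flow index ``SFI = 1/(2 T K^2)`` (1/s).

    Pixels with ``K = 0`` (infinite flow index) are flagged invalid along
    with pixels already invalid in the contrast map.
    """
    if not c.exposure > 0:
        raise ValueError(f"exposure must be > 0, got {c.exposure}")
    invalid = c.invalid | ~np.isfinite(c.k) | (c.k <= 0)
    values = np.full_like(c.k, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        np.divide(1.0, 2.0 * c.exposure * c.k**2, out=values, where=~invalid)
    return FlowMap(values=values, units="1/s", invalid=invalid)


def estimate_beta(static_phantom_contrast: ContrastMap,
                  roi: np.ndarray | None = None,
                  source: str = "static-phantom") -> BetaFactor:
    """Beta from a static phantom: ``beta = (median K in ROI)^2``.

    The median (rather than mean) makes the estimate robust to <50%
    contamination of the ROI by outliers (dust, specular pixels).  Invalid
    contrast pixels are excluded.  Values marginally above 1 from sampling
    noise are clipped to 1.
    """
    k = static_phantom_contrast.k
    if roi is None:
        roi = np.ones_like(k, dtype=bool)
    sel = roi & ~static_phantom_contrast.invalid & np.isfinite(k)
    if not np.any(sel):
        raise ValueError("ROI contains no valid contrast pixels")
    beta = float(np.median(k[sel]) ** 2)
    return BetaFactor(beta=min(beta, 1.0), source=source)


def beta_correct(f: FlowMap, b: BetaFactor) -> FlowMap:
    """Pixelwise beta normalization: ``SFI_corrected = beta * SFI``."""
    return FlowMap(values=f.values * b.beta, units=f.units,
                   invalid=f.invalid.copy())


def roi_timecourse(maps, roi: np.ndarray, filter_len: int = 1) -> np.ndarray:
    """ROI-median time course with a centered moving-average filter.

    For each map in the sequence the median over valid ROI pixels is taken;
    the resulting series is smoothed with a flat moving average of length
    ``filter_len`` (boxcar, 'valid' mode, so the output has
    ``n - filter_len + 1`` samples).  ``filter_len = 1`` returns the raw
    median series.

    ``maps`` may contain :class:`FlowMap` / :class:`ContrastMap` objects or
    bare 2-D arrays (NaNs treated as invalid).
    """
    series = []
    for m in maps:
        if hasattr(m, "values"):
            arr, inv = m.values, m.invalid
        elif hasattr(m, "k"):
            arr, inv = m.k, m.invalid
        else:
            arr, inv = np.asarray(m, float), None
        sel = roi & np.isfinite(arr)
        if inv is not None:
            sel &= ~inv
        if not np.any(sel):
            raise ValueError("ROI contains no valid pixels in one frame")
        series.append(float(np.median(arr[sel])))
    series = np.asarray(series)
    if filter_len < 1:
        raise ValueError(f"filter_len must be >= 1, got {filter_len}")
    if filter_len > series.size:
        raise ValueError(f"filter_len {filter_len} exceeds series length "
                         f"{series.size}")
    if filter_len == 1:
        return series
    kernel = np.full(filter_len, 1.0 / filter_len)
    return np.convolve(series, kernel, mode="valid")
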