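"""Abundance-threshold estimation from the k-mer multiplicity histogram.

A shotgun read pool produces a characteristic bimodal histogram: k-mers
carrying sequencing errors pile up at very low multiplicity, while k-mers
from the unique fraction of the genome form a Poisson-like peak near the
k-mer coverage. K-mers occurring more than once genome-wide sit in the
right tail beyond that peak.

The estimator locates the first local minimum (error/genomic boundary) and
the unique peak beyond it, fits an ordinary least-squares line to the
descending flank of the peak on the linear scale, and takes the point
where the line crosses the x-axis as the upper edge of the unique
component. That value is doubled (the safety factor) to guard against
unique k-mers leaking into the abundant set; k-mers with multiplicity
strictly above the doubled value T are classified as abundant.

The exact endpoints of the fitted flank are a concrete choice of this
implementation: from the peak down to the first bin below
``fit_floor_frac`` of the peak height, or to the first upturn, whichever
comes first. When that plain rule degenerates — shot noise around a flat
peak top can truncate the flank after a bin or two — minimum, peak and
flank extent are re-detected on a lightly smoothed copy of the histogram
(centred moving average, default window 3); the least-squares fit always
uses the raw bin counts. The estimate object records the segment used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ParameterError, ThresholdEstimationError
from .kmer import KmerSpectrum, SpectrumHistogram


@dataclass(frozen=True)
class ThresholdEstimate:
    """All intermediates of the threshold fit, for audit.

    v_errmin
        First local minimum of the histogram: boundary between the
        sequencing-error component and genomic k-mers.
    v_peak
        Mode of the unique-genome component, searched above v_errmin.
    slope, intercept
        OLS line fitted to (m, bins[m]) on the descending flank.
    x_intercept
        Where the fitted line crosses zero: predicted upper edge of the
        unique component.
    T
        Final abundance threshold, ``ceil(safety_factor * x_intercept)``;
        k-mers with multiplicity > T are abundant.
    segment
        Inclusive multiplicity range (lo, hi) of the fitted flank.
    """

    v_errmin: int
    v_peak: int
    slope: float
    intercept: float
    x_intercept: float
    T: int
    safety_factor: float
    segment: tuple[int, int]

    def as_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "v_errmin", "v_peak", "slope", "intercept", "x_intercept",
            "T", "safety_factor")}
        d["segment"] = list(self.segment)
        return d


def _smooth(dense: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average; index 0 stays unused."""
    if window <= 1:
        return dense.astype(float)
    kernel = np.ones(window)
    out = dense.astype(float).copy()
    norm = np.convolve(np.ones(len(dense) - 1), kernel, mode="same")
    out[1:] = np.convolve(dense[1:], kernel, mode="same") / norm
    return out


def _try_estimate(
    dense: np.ndarray,
    fit_floor_frac: float,
    safety_factor: float,
    window: int,
) -> ThresholdEstimate:
    """One estimation attempt; shape detection on a window-smoothed copy
    (window=1 means the plain rule), the OLS fit always on raw bins."""
    m_max = len(dense) - 2
    sm = _smooth(dense, window)

    # First local minimum: smallest m with bins[m] <= bins[m+1]. In an
    # error-free pool the histogram rises from m=1, so v_errmin = 1.
    v_errmin = None
    for m in range(1, m_max):
        if sm[m] <= sm[m + 1]:
            v_errmin = m
            break
    if v_errmin is None:
        raise ThresholdEstimationError(
            "histogram is monotone decreasing: no error/genomic minimum found; "
            "supply a manual threshold"
        )

    tail = sm[v_errmin + 1 : m_max + 1]
    if tail.size == 0 or tail.max() == 0:
        raise ThresholdEstimationError(
            "no unique-genome peak above the error minimum; supply a manual threshold"
        )
    v_peak = v_errmin + 1 + int(np.argmax(tail))

    # descending flank: peak down to the floor or the first upturn
    floor = fit_floor_frac * sm[v_peak]
    hi = v_peak
    while hi + 1 <= m_max and sm[hi + 1] >= floor and sm[hi + 1] <= sm[hi]:
        hi += 1
    seg_m = np.arange(v_peak, hi + 1, dtype=float)
    seg_n = dense[v_peak : hi + 1].astype(float)
    if seg_m.size < 3:
        raise ThresholdEstimationError(
            f"descending flank has only {seg_m.size} point(s); "
            "supply a manual threshold"
        )

    slope, intercept = np.polyfit(seg_m, seg_n, 1)
    if slope >= 0:
        raise ThresholdEstimationError(
            "fitted flank slope is non-negative; supply a manual threshold"
        )
    x_intercept = -intercept / slope
    if x_intercept <= v_peak:
        raise ThresholdEstimationError(
            "fitted line crosses zero left of the peak; supply a manual threshold"
        )
    # round before ceil so an analytically integer product is not bumped
    # up by floating-point residue
    T = math.ceil(round(safety_factor * x_intercept, 6))
    return ThresholdEstimate(
        v_errmin=v_errmin,
        v_peak=v_peak,
        slope=float(slope),
        intercept=float(intercept),
        x_intercept=float(x_intercept),
        T=T,
        safety_factor=safety_factor,
        segment=(v_peak, hi),
    )


def estimate_threshold(
    hist: SpectrumHistogram,
    fit_floor_frac: float = 0.05,
    safety_factor: float = 2.0,
    smooth_window: int = 3,
) -> ThresholdEstimate:
    """Estimate the abundance threshold T from a multiplicity histogram.

    The plain peak/flank rule is tried first; when it degenerates (no
    minimum, no peak, a flank shorter than 3 bins, or a non-descending
    fit — typical of flat-topped low-coverage histograms where shot noise
    produces an immediate upturn) the shape detection is retried on a
    moving-average-smoothed copy of the histogram. Raises
    :class:`ThresholdEstimationError` when both attempts fail; the caller
    may then supply a manual threshold instead.
    """
    if safety_factor <= 0:
        raise ParameterError("safety_factor must be > 0")
    if not 0 < fit_floor_frac < 1:
        raise ParameterError("fit_floor_frac must be in (0, 1)")
    if smooth_window < 1:
        raise ParameterError("smooth_window must be >= 1")

    dense = hist.as_dense()  # dense[m] = n distinct k-mers at multiplicity m
    try:
        return _try_estimate(dense, fit_floor_frac, safety_factor, 1)
    except ThresholdEstimationError:
        if smooth_window <= 1:
            raise
    return _try_estimate(dense, fit_floor_frac, safety_factor, smooth_window)


def extract_abundant(spectrum: KmerSpectrum, T: int) -> list[str]:
    """Canonical k-mers with multiplicity strictly above T, sorted.

    The strict inequality mirrors the "frequency above this threshold"
    classification; an empty result is valid.
    """
    if T < 1:
        raise ParameterError(f"T must be >= 1, got {T}")
    return sorted(k for k, c in spectrum.counts.items() if c > T)
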