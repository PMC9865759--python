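"""Extracted-ion chromatograms and chromatographic peak detection on MS1 data.

The precursor-presence criterion of the screening engine rests on this
module: a compound's precursor is "present" when its extracted-ion
chromatogram (XIC) within a +-5 ppm window contains at least one
chromatographic peak whose signal-to-noise ratio reaches the configured
threshold (default 10).

Noise is estimated robustly as 1.4826 x the median absolute deviation of the
XIC after excluding candidate peak regions; S/N is peak height over that
estimate.  Area is a plain trapezoid over the raw points of the peak region
(no smoothing), which keeps results deterministic and unit-transparent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
from scipy.signal import find_peaks

from .chem import ppm_window
from .spectra_io import AcquiredRun, POSITIVE

__all__ = ["Chromatogram", "ChromPeak", "build_xic", "detect_peaks"]


@dataclass
class Chromatogram:
    rt: np.ndarray  # seconds, strictly increasing
    intensity: np.ndarray
    target_mz: float
    tol_ppm: float
    mz_weighted: Optional[np.ndarray] = None  # per-scan intensity-weighted m/z (nan if empty)

    def __post_init__(self) -> None:
        self.rt = np.asarray(self.rt, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.rt.shape != self.intensity.shape:
            raise ValueError("rt and intensity must have equal length")
        if self.rt.size > 1 and np.any(np.diff(self.rt) <= 0):
            raise ValueError("rt must be strictly increasing")
        if self.mz_weighted is not None:
            self.mz_weighted = np.asarray(self.mz_weighted, dtype=float)
            if self.mz_weighted.shape != self.rt.shape:
                raise ValueError("mz_weighted must match rt length")


@dataclass
class ChromPeak:
    rt_apex: float
    area: float
    height: float
    snr: float
    mz_observed: float  # intensity-weighted m/z over the peak region (nan if unknown)
    rt_start: float
    rt_end: float

    def __post_init__(self) -> None:
        if self.area <= 0 or self.height <= 0:
            raise ValueError("peak area and height must be positive")
        if self.snr < 0:
            raise ValueError("snr must be non-negative")


def build_xic(
    run: AcquiredRun,
    target_mz: float,
    tol_ppm: float = 5.0,
    polarity: str = POSITIVE,
) -> Chromatogram:
    """Per-MS1-scan summed intensity inside the ppm window around ``target_mz``.

    Scans with no peak in the window contribute zero.  Raises if the run has
    no MS1 scans of the requested polarity.
    """
    scans = run.ms1_scans(polarity)
    if not scans:
        raise ValueError(f"run {run.sample_id!r} has no MS1 scans of polarity {polarity!r}")
    lo, hi = ppm_window(target_mz, tol_ppm)
    rts = np.empty(len(scans))
    intens = np.zeros(len(scans))
    wmz = np.full(len(scans), np.nan)
    for k, s in enumerate(scans):
        rts[k] = s.rt
        i, j = np.searchsorted(s.mz, [lo, hi])
        if j > i:
            seg_i = s.intensity[i:j]
            intens[k] = seg_i.sum()
            if intens[k] > 0:
                wmz[k] = float(np.average(s.mz[i:j], weights=seg_i))
    return Chromatogram(rts, intens, target_mz, tol_ppm, wmz)


def _mad_noise(x: np.ndarray) -> float:
    if x.size == 0:
        return 0.0
    med = np.median(x)
    return float(1.4826 * np.median(np.abs(x - med)))


def detect_peaks(
    c: Chromatogram,
    snr_min: float = 10.0,
    min_points: int = 3,
) -> List[ChromPeak]:
    """Detect chromatographic peaks with S/N at or above ``snr_min``.

    Candidate local maxima are grown into contiguous regions above
    ``baseline + 2 x noise``; regions of fewer than ``min_points`` samples are
    discarded.  Noise and baseline are then re-estimated from the off-peak
    samples and each surviving region is scored as
    ``snr = (apex - baseline) / noise``.
    """
    y = c.intensity
    if y.size < 5:
        raise ValueError("chromatogram must contain at least 5 points")
    if not np.any(y > 0):
        return []

    baseline = float(np.median(y))
    noise = _mad_noise(y)
    thr = baseline + 2.0 * noise
    idx, _ = find_peaks(y, height=max(thr, np.finfo(float).tiny))

    # grow candidate regions, then refine baseline/noise on the remainder
    regions = []
    for i in idx:
        a = i
        while a > 0 and y[a - 1] > thr:
            a -= 1
        b = i
        while b < y.size - 1 and y[b + 1] > thr:
            b += 1
        regions.append((a, b, i))
    off_peak = np.ones(y.size, dtype=bool)
    for a, b, _ in regions:
        off_peak[a: b + 1] = False
    if off_peak.any():
        baseline = float(np.median(y[off_peak]))
        noise = _mad_noise(y[off_peak])
        if noise == 0.0:
            # zero-inflated trace (intensities clipped at 0): estimate the
            # noise scale from the non-zero off-peak samples instead
            nz = y[off_peak & (y > 0)]
            if nz.size >= 5:
                noise = _mad_noise(nz)

    peaks: List[ChromPeak] = []
    consumed = np.zeros(y.size, dtype=bool)
    for a, b, i in regions:
        if b - a + 1 < min_points or consumed[i]:
            continue
        apex = int(a + np.argmax(y[a: b + 1]))
        height = float(y[apex] - baseline)
        if height <= 0:
            continue
        snr = float(height / noise) if noise > 0 else float("inf")
        if snr < snr_min:
            continue
        consumed[a: b + 1] = True
        area = float(np.trapezoid(y[a: b + 1], c.rt[a: b + 1]))
        if area <= 0:  # single-sided region at trace edge
            continue
        if c.mz_weighted is not None:
            seg = c.mz_weighted[a: b + 1]
            w = y[a: b + 1]
            ok = ~np.isnan(seg)
            mz_obs = float(np.average(seg[ok], weights=w[ok])) if ok.any() else float("nan")
        else:
            mz_obs = float("nan")
        peaks.append(
            ChromPeak(
                rt_apex=float(c.rt[apex]),
                area=area,
                height=height,
                snr=snr,
                mz_observed=mz_obs,
                rt_start=float(c.rt[a]),
                rt_end=float(c.rt[b]),
            )
        )
    peaks.sort(key=lambda p: p.rt_apex)
    return peaks
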