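"""Pan-Tompkins QRS detection and ultra-short-term time-domain HRV.

The detector follows the canonical 1985 pipeline: band-pass (~5-15 Hz),
five-point derivative, squaring, 150-ms moving-window integration, adaptive
signal/noise thresholds with RR-based search-back and a 200-ms refractory
period.  Fiducial marks are refined to the local ECG maximum within
+/-50 ms so reported peak times sit on the R wave itself.

HRV statistics are the four classic time-domain measures over one 25-s
segment: SDNN, RMSSD, pNN50 and mean heart rate.  RR intervals are in
milliseconds, peak times in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .config import AnalysisConfig, DEFAULT_CONFIG, PanTompkinsConfig
from .errors import InsufficientBeatsError, ValidationError
from .io_formats import EcgRecord


@dataclass
class RrSeries:
    """R-peak times (s) and the successive RR intervals (ms)."""

    peak_times_s: np.ndarray
    rr_ms: np.ndarray

    def __post_init__(self) -> None:
        self.peak_times_s = np.asarray(self.peak_times_s, dtype=float)
        self.rr_ms = np.asarray(self.rr_ms, dtype=float)
        if len(self.rr_ms) != max(0, len(self.peak_times_s) - 1):
            raise ValidationError("rr_ms length must be n_peaks - 1")
        if np.any(np.diff(self.peak_times_s) <= 0):
            raise ValidationError("peak times must be strictly increasing")
        if np.any(self.rr_ms <= 0):
            raise ValidationError("RR intervals must be positive")

    @classmethod
    def from_peaks(cls, peak_times_s) -> "RrSeries":
        peaks = np.asarray(peak_times_s, dtype=float)
        return cls(peaks, np.diff(peaks) * 1000.0)

    @property
    def n_peaks(self) -> int:
        return len(self.peak_times_s)


@dataclass
class HrvMetrics:
    sdnn_ms: float
    rmssd_ms: float
    pnn50_pct: float
    hr_bpm: float
    n_beats: int


# ---------------------------------------------------------------------------
# Pan-Tompkins
# ---------------------------------------------------------------------------

def pan_tompkins(ecg: EcgRecord, config: AnalysisConfig = DEFAULT_CONFIG) -> np.ndarray:
    """Detect R peaks; returns peak times in seconds (possibly empty)."""
    pt = config.pan_tompkins
    fs = ecg.fs
    if fs < 100:
        raise ValidationError("Pan-Tompkins requires fs >= 100 Hz")
    if ecg.duration_s < 2.0:
        raise ValidationError("recording too short for QRS detection (< 2 s)")
    x = ecg.samples - np.mean(ecg.samples)
    if np.ptp(x) == 0:
        return np.empty(0)

    mwi, filtered = _preprocess(x, fs, pt)
    fiducials = _adaptive_detect(mwi, fs, pt)
    if fiducials.size == 0:
        return np.empty(0)
    peaks = _refine_peaks(filtered, fiducials, fs, pt)
    return peaks / fs


def _preprocess(x: np.ndarray, fs: float, pt: PanTompkinsConfig):
    nyq = fs / 2.0
    b, a = sps.butter(pt.filter_order,
                      [pt.band_low_hz / nyq, pt.band_high_hz / nyq],
                      btype="band")
    filtered = sps.filtfilt(b, a, x)
    # five-point derivative, gain-normalised
    kernel = np.array([1, 2, 0, -2, -1]) * fs / 8.0
    deriv = np.convolve(filtered, kernel, mode="same")
    squared = deriv ** 2
    win = max(1, int(round(pt.integration_window_s * fs)))
    mwi = np.convolve(squared, np.ones(win) / win, mode="same")
    return mwi, filtered


def _adaptive_detect(mwi: np.ndarray, fs: float, pt: PanTompkinsConfig) -> np.ndarray:
    refractory = int(round(pt.refractory_s * fs))
    cand, _ = sps.find_peaks(mwi, distance=refractory)
    if cand.size == 0:
        return np.empty(0, dtype=int)

    # initial estimates from the first two seconds of integrator output
    head = mwi[: int(2 * fs)] if len(mwi) > int(2 * fs) else mwi
    spki = 0.25 * float(np.max(head))
    npki = 0.5 * float(np.mean(head))
    thr1 = npki + 0.25 * (spki - npki)

    accepted: list[int] = []
    rr_avg: list[float] = []
    c = pt.peak_update
    i = 0
    while i < len(cand):
        idx = cand[i]
        peak = mwi[idx]
        if peak > thr1:
            accepted.append(idx)
            spki = c * peak + (1 - c) * spki
            if len(accepted) >= 2:
                rr_avg.append(accepted[-1] - accepted[-2])
                rr_avg = rr_avg[-8:]
        else:
            npki = c * peak + (1 - c) * npki
            # search-back: if too long since the last beat, retry this
            # candidate against the halved threshold
            if accepted and rr_avg:
                mean_rr = float(np.mean(rr_avg))
                if idx - accepted[-1] > pt.searchback_factor * mean_rr and peak > thr1 / 2:
                    accepted.append(idx)
                    spki = c * 0.25 * peak + (1 - c * 0.25) * spki
                    rr_avg.append(accepted[-1] - accepted[-2])
                    rr_avg = rr_avg[-8:]
        thr1 = npki + 0.25 * (spki - npki)
        i += 1
    return np.asarray(accepted, dtype=int)


def _refine_peaks(filtered: np.ndarray, fiducials: np.ndarray, fs: float,
                  pt: PanTompkinsConfig) -> np.ndarray:
    """Move each integrator fiducial to the local band-passed maximum."""
    half = int(round(pt.refine_window_s * fs))
    refined = []
    for idx in fiducials:
        lo = max(0, idx - half)
        hi = min(len(filtered), idx + half + 1)
        refined.append(lo + int(np.argmax(filtered[lo:hi])))
    refined = np.unique(refined)
    # enforce the refractory period after refinement
    refractory = pt.refractory_s * fs
    keep = [refined[0]]
    for idx in refined[1:]:
        if idx - keep[-1] >= refractory:
            keep.append(idx)
    return np.asarray(keep, dtype=float)


# ---------------------------------------------------------------------------
# Segment RR extraction and exclusion rules
# ---------------------------------------------------------------------------

def extract_segment_rr(peak_times_s, window,
                       config: AnalysisConfig = DEFAULT_CONFIG) -> RrSeries:
    """RR series for peaks inside the half-open window ``(start, end)``.

    No RR interval spans a window edge: intervals are formed only between
    consecutive peaks that both fall inside the window.
    """
    start, end = window
    peaks = np.asarray(peak_times_s, dtype=float)
    inside = peaks[(peaks >= start) & (peaks < end)]
    if len(inside) < config.min_peaks_per_segment:
        raise InsufficientBeatsError(
            f"{len(inside)} peaks in [{start}, {end}); "
            f"need >= {config.min_peaks_per_segment}"
        )
    return RrSeries.from_peaks(inside)


def has_abnormal_rr(triplet_rr, config: AnalysisConfig = DEFAULT_CONFIG) -> bool:
    """True iff any RR in any of the three segments is < 400 or > 2000 ms.

    A True result excludes the whole arousal event from analysis.
    """
    for rr in triplet_rr:
        if np.any((rr.rr_ms < config.rr_min_ms) | (rr.rr_ms > config.rr_max_ms)):
            return True
    return False


# ---------------------------------------------------------------------------
# Time-domain HRV
# ---------------------------------------------------------------------------

def compute_hrv(rr: RrSeries, config: AnalysisConfig = DEFAULT_CONFIG) -> HrvMetrics:
    """SDNN, RMSSD, pNN50 and heart rate for one segment.

    SDNN is the sample standard deviation of the RR intervals (ddof=1).
    RMSSD is the root mean of the squared successive differences; the
    ``rmssd_denominator`` config flag switches the divisor from the number
    of differences (default) to the number of intervals.  pNN50 counts
    successive differences strictly greater than 50 ms.  HR = 60000 / mean RR.
    """
    rr_ms = rr.rr_ms
    if len(rr_ms) < 2:
        raise InsufficientBeatsError(
            f"need >= 3 peaks (2 intervals), got {rr.n_peaks} peaks"
        )
    diffs = np.diff(rr_ms)
    sdnn = float(np.std(rr_ms, ddof=1))
    denom = len(diffs) if config.rmssd_denominator == "diffs" else len(rr_ms)
    rmssd = float(np.sqrt(np.sum(diffs ** 2) / denom))
    pnn50 = float(np.count_nonzero(np.abs(diffs) > 50.0) / len(diffs) * 100.0)
    hr = 60000.0 / float(np.mean(rr_ms))
    return HrvMetrics(sdnn_ms=sdnn, rmssd_ms=rmssd, pnn50_pct=pnn50,
                      hr_bpm=hr, n_beats=rr.n_peaks)
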