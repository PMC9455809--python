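"""Heuristic per-beat fiducial delineation given annotated R peaks.

Q and S are the signal minima in +-60 ms windows flanking the R peak; P is
the maximum of a 200..60 ms window before R, accepted only when it rises at
least 0.05 mV above the local baseline (window median).  QRS onset/offset
are found by moving outward from Q (resp. S) until the smoothed absolute
slope (10 ms moving average of |first difference|) falls below 12.5% of the
maximum absolute slope inside the QRS region, capped at +-100 ms from R.
All windows and thresholds are configurable; the defaults are standard
delineation heuristics for a 150 Hz working rate.

Absent points (e.g. no P wave) are represented explicitly as None, never
fabricated.
"""
from __future__ import annotations

import dataclasses

import numpy as np

from .io import ECGRecord


@dataclasses.dataclass
class FiducialConfig:
    """Search windows (seconds) and thresholds for delineation."""

    qs_window_s: float = 0.060
    p_window_s: tuple = (0.200, 0.060)  # before R: [R-200ms, R-60ms)
    slope_frac: float = 0.125
    slope_smooth_s: float = 0.010
    onoff_cap_s: float = 0.100
    p_min_amp_mv: float = 0.05


@dataclasses.dataclass
class FiducialPoints:
    """Per-beat landmark sample indices (record coordinates).

    Invariant when all present: qrs_onset <= q_peak <= r_peak <= s_peak <=
    qrs_offset, and p_peak < qrs_onset.
    """

    r_peak: int
    p_peak: int | None
    q_peak: int
    s_peak: int
    qrs_onset: int
    qrs_offset: int


def _moving_avg(x: np.ndarray, k: int) -> np.ndarray:
    if k <= 1:
        return x
    kernel = np.ones(k) / k
    return np.convolve(x, kernel, mode="same")


def detect_fiducials(rec: ECGRecord, beat_index: int,
                     cfg: FiducialConfig | None = None,
                     lead: int = 0) -> FiducialPoints:
    """Delineate one beat of a record (expected at the 150 Hz working rate)."""
    cfg = cfg or FiducialConfig()
    sig = rec.lead(lead)
    n = len(sig)
    fs = rec.fs
    r = int(rec.r_peaks[beat_index])

    w = max(1, int(round(cfg.qs_window_s * fs)))
    cap = max(w, int(round(cfg.onoff_cap_s * fs)))
    lo = max(0, r - w)
    q = lo + int(np.argmin(sig[lo:r])) if r > lo else r
    hi = min(n, r + w + 1)
    s = r + 1 + int(np.argmin(sig[r + 1 : hi])) if hi > r + 1 else r

    # slope field around the beat
    a = max(0, r - cap - 2)
    b = min(n, r + cap + 3)
    k = max(1, int(round(cfg.slope_smooth_s * fs)))
    slope = np.abs(np.diff(sig[a:b]))
    slope = _moving_avg(slope, k)

    def sl(i: int) -> float:
        # smoothed |slope| at sample i (slope[j] sits between samples j, j+1)
        j = np.clip(i - a, 0, len(slope) - 1)
        return float(slope[j])

    qrs_lo, qrs_hi = max(0, r - cap), min(n - 1, r + cap)
    max_slope = max((sl(i) for i in range(qrs_lo, qrs_hi)), default=0.0)
    thr = cfg.slope_frac * max_slope

    onset = qrs_lo
    for i in range(q, qrs_lo - 1, -1):
        if sl(max(0, i - 1)) < thr:
            onset = i
            break
    offset = qrs_hi
    for i in range(s, qrs_hi + 1):
        if sl(i) < thr:
            offset = i
            break
    onset = min(onset, q)
    offset = max(offset, s)

    p_far = int(round(cfg.p_window_s[0] * fs))
    p_near = int(round(cfg.p_window_s[1] * fs))
    p_lo, p_hi = max(0, r - p_far), max(0, r - p_near)
    p_peak: int | None = None
    if p_hi > p_lo:
        win = sig[p_lo:p_hi]
        cand = p_lo + int(np.argmax(win))
        baseline = float(np.median(win))
        # a true P is an interior local peak; a monotone tail of the previous
        # beat's T wave peaks at the window edge and is rejected
        interior = p_lo < cand < p_hi - 1
        if interior and sig[cand] - baseline >= cfg.p_min_amp_mv and cand < onset:
            p_peak = cand
    return FiducialPoints(r_peak=r, p_peak=p_peak, q_peak=q, s_peak=s,
                          qrs_onset=onset, qrs_offset=offset)


def detect_all_fiducials(rec: ECGRecord, cfg: FiducialConfig | None = None,
                         lead: int = 0) -> list[FiducialPoints]:
    cfg = cfg or FiducialConfig()
    return [detect_fiducials(rec, i, cfg, lead) for i in range(rec.n_beats)]


def _crossing_width(w: np.ndarray, level: float, fs: float) -> float:
    """Width (ms) of the span where ``w`` exceeds ``level``, with linear
    interpolation at the two crossings."""
    above = np.nonzero(w >= level)[0]
    if len(above) == 0:
        return 0.0
    i, j = int(above[0]), int(above[-1])
    t_left = float(i)
    if i > 0 and w[i] != w[i - 1]:
        t_left = (i - 1) + (level - w[i - 1]) / (w[i] - w[i - 1])
    t_right = float(j)
    if j < len(w) - 1 and w[j] != w[j + 1]:
        t_right = j + (w[j] - level) / (w[j] - w[j + 1])
    return max(0.0, (t_right - t_left) * 1000.0 / fs)


def qrs_widths(rec_or_signal, fp: FiducialPoints,
               fs: float | None = None, lead: int = 0):
    """QRS width and its half/quarter-level widths, in ms.

    ``QRSw`` is offset-onset; ``QRSw2``/``QRSw4`` are the widths of the span
    where the QRS-window signal exceeds min + 50% (resp. 25%) of the QRS
    range, measured with linear interpolation at the crossings.  A zero
    range (flat window) yields all-zero widths.
    """
    if isinstance(rec_or_signal, ECGRecord):
        sig = rec_or_signal.lead(lead)
        fs = rec_or_signal.fs
    else:
        sig = np.asarray(rec_or_signal, dtype=float)
        if fs is None:
            raise ValueError("fs required when passing a bare signal")
    on, off = int(fp.qrs_onset), int(fp.qrs_offset)
    if off <= on:
        return 0.0, 0.0, 0.0
    w = sig[on : off + 1]
    rng = float(np.max(w) - np.min(w))
    if rng <= 0:
        return 0.0, 0.0, 0.0
    qrsw = (off - on) * 1000.0 / fs
    lvl2 = float(np.min(w)) + 0.5 * rng
    lvl4 = float(np.min(w)) + 0.25 * rng
    return qrsw, _crossing_width(w, lvl2, fs), _crossing_width(w, lvl4, fs)
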