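"""Per-beat feature vector (79 named features) and MI-based selection.

Families
--------
RR (6): ``rr``, ``pre_rr``, ``post_rr`` in samples at the 150 Hz working
rate, the ratios ``pre_rr_over_rr`` and ``post_rr_over_rr``, and ``t_rr``,
the t-statistic of the current RR against the trailing window of up to 32
RR values (including the current one).

Medical morphology (12 + 13 normalized): P/Q/R/S amplitudes (mV), the P-Q,
Q-R and R-S amplitude differences, the P-peak-to-QRS-onset and Q-to-S
distances (ms), and the QRS width at full, half and quarter level (ms).
Each has a locally normalized twin (``..._norm``, division by the trailing
32-beat mean), and ``rr`` is normalized the same way (``rr_norm``).

Mathematical morphology (48): excess kurtosis and skewness of five equal
parts of the 75-sample beat window (10), a level-3 db2 DWT of the window
zero-padded to 24 coefficients, and 14 Hermite-basis-function coefficients
(``hbf_1..14``) fitted by least squares with the width parameter sigma
chosen from a small grid by reconstruction error.

Degenerate values (empty windows, zero variance, zero mean) map to 0 by
rule, never to NaN.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
import pywt
from scipy import stats

from .fiducial import FiducialConfig, FiducialPoints, detect_all_fiducials, qrs_widths
from .io import WORKING_FS, BeatWindow, ECGRecord, extract_beat_windows, resample_record

RR_WINDOW = 32
NORM_WINDOW = 32
N_STAT_PARTS = 5
N_DWT = 24
N_HERMITE = 14
SIGMA_GRID_MS = (10.0, 15.0, 20.0, 25.0, 30.0)

RR_NAMES = ["rr", "pre_rr", "post_rr", "pre_rr_over_rr", "post_rr_over_rr", "t_rr"]
MEDICAL_NAMES = ["amp_P", "amp_Q", "amp_R", "amp_S", "diff_PQ", "diff_QR",
                 "diff_RS", "dist_P_QRSon", "dist_QS", "QRSw", "QRSw2", "QRSw4"]
NORM_NAMES = [f"{n}_norm" for n in MEDICAL_NAMES] + ["rr_norm"]
MATH_NAMES = ([f"kurt_{i}" for i in range(1, N_STAT_PARTS + 1)]
              + [f"skew_{i}" for i in range(1, N_STAT_PARTS + 1)]
              + [f"dwt_{i}" for i in range(1, N_DWT + 1)]
              + [f"hbf_{i}" for i in range(1, N_HERMITE + 1)])
FEATURE_NAMES = RR_NAMES + MEDICAL_NAMES + NORM_NAMES + MATH_NAMES  # 79


def rr_features(r_peaks: np.ndarray, i: int,
                window: int = RR_WINDOW) -> dict:
    """RR-interval features for beat ``i`` (units: samples of ``r_peaks``).

    Missing neighbours at the record edges are substituted with the record
    median RR; ``t_rr`` uses the trailing up-to-``window`` RR values ending
    at the current beat (sample s.d., zero s.d. or fewer than two values
    give 0).
    """
    r = np.asarray(r_peaks, dtype=float)
    if len(r) < 2:
        raise ValueError("rr features require at least 2 beats")
    d = np.diff(r)  # d[j] = RR ending at beat j+1
    med = float(np.median(d))

    def rr_of(j: int) -> float:
        # RR interval ending at beat j; j<1 has no interval -> median
        return float(d[j - 1]) if j >= 1 else med

    rr = rr_of(i)
    pre = rr_of(i - 1)
    post = float(d[i]) if i + 1 < len(r) else med
    series = np.array([rr_of(j) for j in range(max(0, i - window + 1), i + 1)])
    t_rr = 0.0
    if len(series) >= 2:
        sd = float(np.std(series, ddof=1))
        if sd > 0:
            t_rr = (rr - float(np.mean(series))) / (sd / np.sqrt(len(series)))
    return {
        "rr": rr, "pre_rr": pre, "post_rr": post,
        "pre_rr_over_rr": pre / rr if rr else 0.0,
        "post_rr_over_rr": post / rr if rr else 0.0,
        "t_rr": t_rr,
    }


def medical_features(rec: ECGRecord, fp: FiducialPoints, lead: int = 0) -> dict:
    """Amplitude/distance/width features from one beat's fiducials.

    Absent P maps to zero amplitude and zero P-onset distance (so
    ``diff_PQ`` equals ``-amp_Q`` there), per the documented absence rule.
    """
    sig = rec.lead(lead)
    fs = rec.fs
    amp_p = float(sig[fp.p_peak]) if fp.p_peak is not None else 0.0
    amp_q = float(sig[fp.q_peak])
    amp_r = float(sig[fp.r_peak])
    amp_s = float(sig[fp.s_peak])
    dist_p_on = ((fp.qrs_onset - fp.p_peak) * 1000.0 / fs
                 if fp.p_peak is not None else 0.0)
    dist_qs = (fp.s_peak - fp.q_peak) * 1000.0 / fs
    qrsw, qrsw2, qrsw4 = qrs_widths(rec, fp, lead=lead)
    return {
        "amp_P": amp_p, "amp_Q": amp_q, "amp_R": amp_r, "amp_S": amp_s,
        "diff_PQ": amp_p - amp_q, "diff_QR": amp_q - amp_r,
        "diff_RS": amp_r - amp_s, "dist_P_QRSon": dist_p_on,
        "dist_QS": dist_qs, "QRSw": qrsw, "QRSw2": qrsw2, "QRSw4": qrsw4,
    }


def local_normalize(values: np.ndarray, window: int = NORM_WINDOW) -> np.ndarray:
    """Divide each value by the trailing up-to-``window`` mean (incl. itself).

    Scale invariant (degree-0 homogeneous); a zero trailing mean maps to 0.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    x = np.asarray(values, dtype=float)
    out = np.zeros_like(x)
    c = np.concatenate([[0.0], np.cumsum(x)])
    for i in range(len(x)):
        lo = max(0, i - window + 1)
        m = (c[i + 1] - c[lo]) / (i + 1 - lo)
        out[i] = x[i] / m if m != 0 else 0.0
    return out


def segment_stats(beat: BeatWindow | np.ndarray) -> dict:
    """Excess kurtosis and skewness of five equal parts of the beat window.

    Population (biased) moment formulas; zero-variance parts give 0 for both.
    """
    x = beat.samples if isinstance(beat, BeatWindow) else np.asarray(beat, float)
    parts = np.array_split(x, N_STAT_PARTS)
    out = {}
    for i, p in enumerate(parts, start=1):
        if len(p) == 0 or float(np.var(p)) == 0.0:
            out[f"kurt_{i}"] = 0.0
            out[f"skew_{i}"] = 0.0
        else:
            out[f"kurt_{i}"] = float(stats.kurtosis(p, fisher=True, bias=True))
            out[f"skew_{i}"] = float(stats.skew(p, bias=True))
    return out


def dwt_features(beat: BeatWindow | np.ndarray) -> dict:
    """Level-3 db2 DWT (symmetric padding): level-3 approximation then
    level-3 detail coefficients, truncated/zero-padded to 24 values."""
    x = beat.samples if isinstance(beat, BeatWindow) else np.asarray(beat, float)
    coeffs = pywt.wavedec(x, "db2", mode="symmetric", level=3)
    vec = np.concatenate([coeffs[0], coeffs[1]])
    if len(vec) >= N_DWT:
        vec = vec[:N_DWT]
    else:
        vec = np.concatenate([vec, np.zeros(N_DWT - len(vec))])
    return {f"dwt_{i+1}": float(v) for i, v in enumerate(vec)}


def hermite_basis(n_samples: int, r_index: int, fs: float, sigma_ms: float,
                  n_basis: int = N_HERMITE) -> np.ndarray:
    """Sampled orthonormal Hermite basis functions, shape (n_samples, n_basis).

    phi_n(t; sigma) = psi_n(t/sigma)/sqrt(sigma) with psi_n the orthonormal
    Hermite functions (stable two-term recurrence), t in ms centered at R.
    """
    t_ms = (np.arange(n_samples) - r_index) * 1000.0 / fs
    u = t_ms / sigma_ms
    psi = np.empty((n_samples, n_basis))
    psi[:, 0] = np.pi ** -0.25 * np.exp(-0.5 * u**2)
    if n_basis > 1:
        psi[:, 1] = np.sqrt(2.0) * u * psi[:, 0]
    for k in range(2, n_basis):
        psi[:, k] = (np.sqrt(2.0 / k) * u * psi[:, k - 1]
                     - np.sqrt((k - 1) / k) * psi[:, k - 2])
    return psi / np.sqrt(sigma_ms)


def hermite_features(beat: BeatWindow, sigma_grid=SIGMA_GRID_MS,
                     n_basis: int = N_HERMITE) -> dict:
    """Least-squares Hermite expansion of the beat window.

    For each sigma in the grid the window is projected onto the first
    ``n_basis`` orthonormal Hermite basis functions; the coefficients of the
    sigma with the smallest reconstruction SSE are returned (``hbf_i``,
    1-based).  A zero beat yields all-zero coefficients.
    """
    x = beat.samples
    best = None
    for sigma in sigma_grid:
        basis = hermite_basis(len(x), beat.r_index_local, beat.fs, sigma, n_basis)
        coef, _, _, _ = np.linalg.lstsq(basis, x, rcond=None)
        sse = float(np.sum((x - basis @ coef) ** 2))
        if best is None or sse < best[0]:
            best = (sse, coef)
    return {f"hbf_{i+1}": float(c) for i, c in enumerate(best[1])}


def extract_features(rec: ECGRecord,
                     fiducial_cfg: FiducialConfig | None = None,
                     lead: int = 0,
                     norm_window: int = NORM_WINDOW) -> pd.DataFrame:
    """Full 79-feature frame for every beat of a working-rate record.

    ``rec`` must already be at the 150 Hz working rate (see
    :func:`beat_feature_frame` for the resampling front end).  The output has
    one row per beat, columns :data:`FEATURE_NAMES` plus ``symbol`` and
    ``padded`` (boundary-window flag); all feature values are finite.
    """
    fps = detect_all_fiducials(rec, fiducial_cfg, lead)
    windows = extract_beat_windows(rec, lead)
    rows = []
    for i in range(rec.n_beats):
        row: dict = {}
        row.update(rr_features(rec.r_peaks, i))
        row.update(medical_features(rec, fps[i], lead))
        row.update(segment_stats(windows[i]))
        row.update(dwt_features(windows[i]))
        row.update(hermite_features(windows[i]))
        rows.append(row)
    df = pd.DataFrame(rows)
    for name in MEDICAL_NAMES:
        df[f"{name}_norm"] = local_normalize(df[name].to_numpy(), norm_window)
    df["rr_norm"] = local_normalize(df["rr"].to_numpy(), norm_window)
    df = df[FEATURE_NAMES]
    df = df.replace([np.inf, -np.inf], 0.0).fillna(0.0)
    df["symbol"] = rec.beat_symbols
    df["padded"] = [w.padded for w in windows]
    return df


def beat_feature_frame(rec: ECGRecord, working_fs: float = WORKING_FS,
                       **kwargs) -> pd.DataFrame:
    """Resample to the working rate and extract the full feature frame."""
    return extract_features(resample_record(rec, working_fs), **kwargs)


def mi_rank(features: pd.DataFrame, labels, seed: int = 0,
            n_neighbors: int = 3) -> list[tuple[str, float]]:
    """Rank features by mutual information with the class label.

    kNN MI estimator (k=3) with seeded neighbor tie-breaking; descending
    score, ties broken by feature name.  Requires at least two classes.
    """
    from sklearn.feature_selection import mutual_info_classif

    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("mi_rank requires at least 2 classes")
    X = features.drop(columns=["symbol", "padded"], errors="ignore")
    X = X.select_dtypes(include=[np.number])
    scores = mutual_info_classif(X.to_numpy(), y, n_neighbors=n_neighbors,
                                 random_state=seed)
    ranked = sorted(zip(X.columns, scores), key=lambda kv: (-kv[1], kv[0]))
    return [(str(n), float(s)) for n, s in ranked]


def select_top(ranked, n_f: int = 6) -> list[str]:
    """First ``n_f`` feature names of a ranking."""
    if n_f > len(ranked):
        raise ValueError(f"n_f={n_f} exceeds {len(ranked)} ranked features")
    return [name for name, _ in ranked[:n_f]]
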