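"""ECG record / annotation I/O and the shared record data model.

A record is a sampled voltage trace (mV) on one or two leads together with
per-beat R-peak sample indices and one-character beat symbols (MIT-BIH
alphabet).  Two on-disk dialects are supported:

``csv``
    ``<id>.signal.csv`` — a ``# fs=<rate>`` comment line, a header naming the
    leads, then one row per sample; and ``<id>.beats.csv`` with columns
    ``r_peak_sample,symbol``.  Lossless (samples written with ``%.17g``).

``wfdb``
    The standard ``.hea``/``.dat``/``.atr`` triple.  A minimal reader/writer
    covering signal formats 212 and 16 and MIT annotation files is built in;
    amplitudes are converted to mV via the header gain/baseline.

Beat analysis downstream runs at a fixed working rate of 150 Hz; beat windows
span -250..+250 ms around the annotated R peak (75 samples, R at index 37).
"""
from __future__ import annotations

import dataclasses
import struct
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy.signal import resample_poly

#: working sampling rate (Hz) for per-beat analysis
WORKING_FS = 150.0
#: half-span of a beat window in seconds (window is 2*half+1 samples, closed)
BEAT_HALF_SPAN_S = 0.25


class DataError(ValueError):
    """Malformed or inconsistent ECG data."""


@dataclasses.dataclass
class ECGRecord:
    """A sampled ECG with beat annotations.

    Parameters
    ----------
    record_id : str
        Identifier, used for file naming and seeding.
    signal : ndarray, shape (n_samples, n_leads)
        Voltage in mV; a 1-D array is promoted to a single lead.
    fs : float
        Sampling rate in Hz, > 0.
    r_peaks : ndarray of int
        Strictly increasing R-peak sample indices (0-based), within the record.
    beat_symbols : ndarray of str
        One-character annotation symbol per beat.
    """

    record_id: str
    signal: np.ndarray
    fs: float
    r_peaks: np.ndarray
    beat_symbols: np.ndarray

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim == 1:
            self.signal = self.signal[:, None]
        if self.signal.ndim != 2:
            raise DataError("signal must be 1-D or 2-D (samples x leads)")
        if not self.fs > 0:
            raise DataError(f"fs must be positive, got {self.fs}")
        self.r_peaks = np.asarray(self.r_peaks, dtype=np.int64)
        self.beat_symbols = np.asarray(list(self.beat_symbols), dtype="<U1")
        if len(self.r_peaks) != len(self.beat_symbols):
            raise DataError(
                f"{len(self.r_peaks)} R peaks but {len(self.beat_symbols)} symbols"
            )
        d = np.diff(self.r_peaks)
        if np.any(d <= 0):
            i = int(np.argmax(d <= 0))
            raise DataError(
                f"r_peaks not strictly increasing at index {i + 1}: "
                f"{self.r_peaks[i]} -> {self.r_peaks[i + 1]}"
            )
        if len(self.r_peaks) and (
            self.r_peaks[0] < 0 or self.r_peaks[-1] >= self.n_samples
        ):
            raise DataError("r_peaks outside [0, n_samples)")

    @property
    def n_samples(self) -> int:
        return self.signal.shape[0]

    @property
    def n_leads(self) -> int:
        return self.signal.shape[1]

    @property
    def n_beats(self) -> int:
        return len(self.r_peaks)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def lead(self, index: int = 0) -> np.ndarray:
        return self.signal[:, index]


@dataclasses.dataclass
class BeatWindow:
    """A fixed-length slice of one lead centered on an R peak."""

    samples: np.ndarray
    r_index_local: int
    fs: float
    padded: bool = False


# ---------------------------------------------------------------- csv dialect

def _csv_paths(path: str | Path) -> tuple[Path, Path]:
    p = Path(path)
    name = p.name
    for suffix in (".signal.csv", ".beats.csv"):
        if name.endswith(suffix):
            name = name[: -len(suffix)]
    base = p.with_name(name)
    return base.with_name(base.name + ".signal.csv"), base.with_name(
        base.name + ".beats.csv"
    )


def _read_csv_record(path: str | Path) -> ECGRecord:
    sig_path, beats_path = _csv_paths(path)
    if not sig_path.exists():
        raise DataError(f"missing signal file {sig_path}")
    if not beats_path.exists():
        raise DataError(f"missing annotation file {beats_path}")
    with open(sig_path) as fh:
        first = fh.readline().strip()
        if not first.startswith("# fs="):
            raise DataError(f"{sig_path}: expected '# fs=<rate>' header line")
        fs = float(first[len("# fs=") :])
        header = fh.readline()  # lead names; content unused
        n_leads = max(1, len(header.strip().split(",")))
        data = np.loadtxt(fh, delimiter=",", ndmin=2)
    if data.size == 0:
        data = data.reshape(0, n_leads)
    peaks: list[int] = []
    symbols: list[str] = []
    with open(beats_path) as fh:
        fh.readline()  # header
        for line in fh:
            line = line.strip()
            if not line:
                continue
            s, sym = line.split(",")
            peaks.append(int(s))
            symbols.append(sym)
    record_id = sig_path.name[: -len(".signal.csv")]
    return ECGRecord(record_id, data, fs, np.array(peaks, dtype=np.int64),
                     np.array(symbols))


def _write_csv_record(rec: ECGRecord, directory: str | Path) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    sig_path = directory / f"{rec.record_id}.signal.csv"
    beats_path = directory / f"{rec.record_id}.beats.csv"
    with open(sig_path, "w") as fh:
        fh.write(f"# fs={rec.fs!r}\n")
        fh.write(",".join(f"lead{i}" for i in range(rec.n_leads)) + "\n")
        np.savetxt(fh, rec.signal, delimiter=",", fmt="%.17g")
    with open(beats_path, "w") as fh:
        fh.write("r_peak_sample,symbol\n")
        for r, s in zip(rec.r_peaks, rec.beat_symbols):
            fh.write(f"{int(r)},{s}\n")
    return sig_path.with_name(rec.record_id)


# --------------------------------------------------------------- wfdb dialect
#
# Minimal support for the PhysioNet WFDB file layout: a text .hea header, a
# binary .dat in format 212 (two 12-bit two's-complement samples per 3 bytes)
# or 16 (little-endian int16), and a MIT-format .atr annotation file.

_ANN_CODE_TO_SYMBOL = {
    1: "N", 2: "L", 3: "R", 4: "a", 5: "V", 6: "F", 7: "J", 8: "A", 9: "S",
    10: "E", 11: "j", 12: "/", 13: "Q", 34: "e", 38: "f",
}
_SYMBOL_TO_ANN_CODE = {v: k for k, v in _ANN_CODE_TO_SYMBOL.items()}
# non-beat codes whose occurrences are skipped when reading
_ANN_SKIP = 59
_ANN_NUM = 60
_ANN_SUB = 61
_ANN_CHN = 62
_ANN_AUX = 63


def _read_wfdb_header(hea_path: Path):
    lines = [
        ln.strip()
        for ln in hea_path.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    head = lines[0].split()
    name = head[0].split("/")[0]
    n_sig = int(head[1])
    fs = float(head[2].split("/")[0]) if len(head) > 2 else 250.0
    n_samples = int(head[3]) if len(head) > 3 else 0
    signals = []
    for ln in lines[1 : 1 + n_sig]:
        parts = ln.split()
        fname = parts[0]
        fmt = int(parts[1].split("x")[0].split(":")[0].split("+")[0])
        gain, baseline = 200.0, 0
        if len(parts) > 2:
            g = parts[2].split("/")[0]
            if "(" in g:
                g, b = g.split("(")
                baseline = int(b.rstrip(")"))
                gain = float(g)
            else:
                gain = float(g)
            if gain == 0:
                gain = 200.0
        adc_zero = int(parts[4]) if len(parts) > 4 else 0
        if "(" not in (parts[2].split("/")[0] if len(parts) > 2 else ""):
            baseline = adc_zero
        signals.append({"file": fname, "fmt": fmt, "gain": gain,
                        "baseline": baseline})
    return name, n_sig, fs, n_samples, signals


def _read_dat(dat_path: Path, fmt: int, n_sig: int, n_samples: int) -> np.ndarray:
    raw = dat_path.read_bytes()
    if fmt == 16:
        adc = np.frombuffer(raw, dtype="<i2")
        adc = adc[: n_sig * (len(adc) // n_sig)].reshape(-1, n_sig)
    elif fmt == 212:
        b = np.frombuffer(raw, dtype=np.uint8)
        b = b[: 3 * (len(b) // 3)].reshape(-1, 3)
        s0 = (b[:, 0].astype(np.int32) | ((b[:, 1].astype(np.int32) & 0x0F) << 8))
        s1 = (b[:, 2].astype(np.int32) | ((b[:, 1].astype(np.int32) & 0xF0) << 4))
        s0[s0 > 2047] -= 4096
        s1[s1 > 2047] -= 4096
        flat = np.empty(2 * len(b), dtype=np.int32)
        flat[0::2], flat[1::2] = s0, s1
        adc = flat[: n_sig * (len(flat) // n_sig)].reshape(-1, n_sig)
    else:
        raise DataError(f"unsupported WFDB signal format {fmt}")
    if n_samples:
        adc = adc[:n_samples]
    return adc


def _read_atr(atr_path: Path):
    raw = atr_path.read_bytes()
    samples: list[int] = []
    symbols: list[str] = []
    t = 0
    i = 0
    while i + 1 < len(raw):
        word = struct.unpack_from("<H", raw, i)[0]
        i += 2
        code = word >> 10
        delta = word & 0x3FF
        if code == 0 and delta == 0:
            break
        if code == _ANN_SKIP:
            # long interval stored high word first
            hi = struct.unpack_from("<h", raw, i)[0]
            lo = struct.unpack_from("<H", raw, i + 2)[0]
            long_delta = (hi << 16) | lo
            i += 4
            t += long_delta
            continue
        if code in (_ANN_NUM, _ANN_SUB, _ANN_CHN):
            continue
        if code == _ANN_AUX:
            i += delta + (delta & 1)
            continue
        t += delta
        if code in _ANN_CODE_TO_SYMBOL:
            samples.append(t)
            symbols.append(_ANN_CODE_TO_SYMBOL[code])
        # other annotation types (rhythm changes, noise marks) are skipped
    return np.array(samples, dtype=np.int64), np.array(symbols)


def _read_wfdb_record(path: str | Path) -> ECGRecord:
    p = Path(path)
    hea_path = p if p.suffix == ".hea" else p.with_suffix(".hea")
    if not hea_path.exists():
        raise DataError(f"missing header file {hea_path}")
    name, n_sig, fs, n_samples, signals = _read_wfdb_header(hea_path)
    dat_path = hea_path.with_name(signals[0]["file"])
    if not dat_path.exists():
        raise DataError(f"missing signal file {dat_path}")
    adc = _read_dat(dat_path, signals[0]["fmt"], n_sig, n_samples)
    sig = np.empty(adc.shape, dtype=float)
    for j, meta in enumerate(signals):
        sig[:, j] = (adc[:, j] - meta["baseline"]) / meta["gain"]
    atr_path = hea_path.with_suffix(".atr")
    if not atr_path.exists():
        raise DataError(f"missing annotation file {atr_path}")
    peaks, symbols = _read_atr(atr_path)
    return ECGRecord(name, sig, fs, peaks, symbols)


def write_wfdb(rec: ECGRecord, directory: str | Path, fmt: int = 212,
               gain: float = 200.0) -> Path:
    """Write a record as a .hea/.dat/.atr triple (formats 212 or 16)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    name = rec.record_id
    adc = np.rint(rec.signal * gain).astype(np.int32)
    if fmt == 212:
        adc = np.clip(adc, -2048, 2047)
    lines = [f"{name} {rec.n_leads} {rec.fs:g} {rec.n_samples}"]
    for j in range(rec.n_leads):
        lines.append(f"{name}.dat {fmt} {gain:g}(0)/mV 12 0 0 0 0 lead{j}")
    (directory / f"{name}.hea").write_text("\n".join(lines) + "\n")
    flat = adc.reshape(-1)
    if fmt == 16:
        data = flat.astype("<i2").tobytes()
    elif fmt == 212:
        if len(flat) % 2:
            flat = np.append(flat, 0)
        s0 = flat[0::2].astype(np.int32) & 0xFFF
        s1 = flat[1::2].astype(np.int32) & 0xFFF
        out = np.empty((len(s0), 3), dtype=np.uint8)
        out[:, 0] = s0 & 0xFF
        out[:, 1] = ((s0 >> 8) & 0x0F) | (((s1 >> 8) & 0x0F) << 4)
        out[:, 2] = s1 & 0xFF
        data = out.tobytes()
    else:
        raise DataError(f"unsupported WFDB signal format {fmt}")
    (directory / f"{name}.dat").write_bytes(data)
    buf = bytearray()
    t_prev = 0
    for r, s in zip(rec.r_peaks, rec.beat_symbols):
        code = _SYMBOL_TO_ANN_CODE.get(str(s))
        if code is None:
            raise DataError(f"symbol {s!r} has no MIT annotation code")
        delta = int(r) - t_prev
        if delta >= 1024:
            buf += struct.pack("<H", _ANN_SKIP << 10)
            buf += struct.pack("<h", delta >> 16)
            buf += struct.pack("<H", delta & 0xFFFF)
            delta = 0
        buf += struct.pack("<H", (code << 10) | delta)
        t_prev = int(r)
    buf += struct.pack("<H", 0)
    (directory / f"{name}.atr").write_bytes(bytes(buf))
    return directory / name


# ------------------------------------------------------------- public surface

def read_record(path: str | Path, dialect: str = "csv") -> ECGRecord:
    """Read an annotated ECG record.

    ``path`` may be the record prefix or any of the dialect's file names.
    R peaks come from the annotation stream; they are never re-detected.
    """
    if dialect == "csv":
        return _read_csv_record(path)
    if dialect == "wfdb":
        return _read_wfdb_record(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_record(rec: ECGRecord, directory: str | Path,
                 dialect: str = "csv") -> Path:
    """Write a record; returns the record prefix path."""
    if dialect == "csv":
        return _write_csv_record(rec, directory)
    if dialect == "wfdb":
        return write_wfdb(rec, directory)
    raise ValueError(f"unknown dialect {dialect!r}")


def resample_record(rec: ECGRecord, fs_out: float) -> ECGRecord:
    """Resample to ``fs_out`` Hz, rescaling R-peak indices to nearest sample.

    Polyphase resampling with the rational ratio fs_out/fs; the beat count is
    preserved and the operation is the identity when fs_out == fs.
    """
    if not fs_out > 0:
        raise ValueError("fs_out must be positive")
    if fs_out == rec.fs:
        return ECGRecord(rec.record_id, rec.signal.copy(), rec.fs,
                         rec.r_peaks.copy(), rec.beat_symbols.copy())
    ratio = Fraction(fs_out / rec.fs).limit_denominator(10_000)
    sig = resample_poly(rec.signal, ratio.numerator, ratio.denominator, axis=0)
    n_out = sig.shape[0]
    peaks = np.rint(rec.r_peaks * (fs_out / rec.fs)).astype(np.int64)
    peaks = np.clip(peaks, 0, n_out - 1)
    return ECGRecord(rec.record_id, sig, fs_out, peaks, rec.beat_symbols.copy())


def beat_window_half_span(fs: float) -> int:
    # floor: 75 samples at 150 Hz (+-37 samples around R), 181 at 360 Hz
    return int(BEAT_HALF_SPAN_S * fs)


def extract_beat_windows(rec: ECGRecord, lead: int = 0) -> list[BeatWindow]:
    """Slice one window per R peak (closed interval R-250ms .. R+250ms).

    Windows crossing a record boundary are zero-padded on the missing side
    and flagged via :attr:`BeatWindow.padded`, so beat and feature counts
    stay aligned with the annotation stream.
    """
    half = beat_window_half_span(rec.fs)
    length = 2 * half + 1
    sig = rec.lead(lead)
    n = rec.n_samples
    out = []
    for r in rec.r_peaks:
        lo, hi = int(r) - half, int(r) + half + 1
        w = np.zeros(length)
        src_lo, src_hi = max(lo, 0), min(hi, n)
        w[src_lo - lo : src_hi - lo] = sig[src_lo:src_hi]
        out.append(BeatWindow(w, half, rec.fs, padded=(lo < 0 or hi > n)))
    return out
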