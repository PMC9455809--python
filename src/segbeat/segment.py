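"""Rhythm-context segment labels: segmentation, classification, encoding.

The record is divided into fixed-length segments (optionally with half
overlap); a segment classifier predicts a rhythm class per segment, and
every beat inherits the label(s) of the segment(s) containing its R peak.
The per-beat encoding is a single categorical label ID without overlap, or
a multi-hot bit vector (one bit per rhythm class) with half overlap — an
interior beat is covered by at most two segments, so at most two bits are
set.

Two classifier providers are built in: an oracle that reads the generating
rhythm blocks of a synthetic record (optionally corrupted at a configured
error rate, to study how segment-label quality affects the downstream beat
classifier), and a trainable 1-D CNN (:class:`EcgRecordingCNN`) operating
on 60 s single-lead segments.
"""
from __future__ import annotations

import dataclasses
import json
import zlib
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from . import cnn as _cnn
from .io import ECGRecord, resample_record
from .synth import SynthTruth

SEGMENT_FEATURE_PREFIX = "seg_"


class LabelSet:
    """An ordered, unique set of rhythm-class names.

    Order is semantic: it defines the categorical label ID and the bit
    positions of the multi-hot encoding.
    """

    def __init__(self, names):
        names = [str(n) for n in names]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate label names in {names}")
        self.names = tuple(names)

    def __len__(self) -> int:
        return len(self.names)

    def __iter__(self):
        return iter(self.names)

    def __eq__(self, other) -> bool:
        return isinstance(other, LabelSet) and self.names == other.names

    def id(self, name: str) -> int:
        return self.names.index(name)

    def name(self, label_id: int) -> str:
        return self.names[label_id]


@dataclasses.dataclass
class Segment:
    start: int  # sample index, inclusive
    end: int  # sample index, exclusive
    probs: np.ndarray | None = None
    label: str | None = None


def segment_record(n_samples: int, fs: float, length_s: float = 60.0,
                   overlap: str = "none") -> list[tuple[int, int]]:
    """Segment boundaries (half-open sample intervals) for one record.

    ``overlap='none'`` partitions the record into consecutive windows, the
    last one possibly partial.  ``overlap='half'`` strides by half the
    window; windows stop once the record end is covered, and a trailing
    partial window is added only when needed for full coverage (so every
    beat falls in at least one segment).
    """
    if length_s <= 0:
        raise ValueError("length_s must be positive")
    if overlap not in ("none", "half"):
        raise ValueError(f"overlap must be 'none' or 'half', got {overlap!r}")
    L = int(round(length_s * fs))
    stride = L if overlap == "none" else max(1, L // 2)
    bounds = []
    start = 0
    while True:
        end = min(start + L, n_samples)
        bounds.append((start, end))
        if end >= n_samples:
            break
        start += stride
    return bounds


def preprocess_segment(x: np.ndarray, fs: float, target_fs: float = 360.0,
                       length_s: float = 60.0,
                       record_abs_max: float | None = None) -> np.ndarray:
    """Standardize one single-lead segment for the CNN classifier.

    Baseline removal by two consecutive median filters (200 ms then 600 ms
    kernels), amplitude normalization by the record's max |value| (pass
    ``record_abs_max``; defaults to the segment's own, zero-safe), polyphase
    resampling to ``target_fs``, and cut/zero-pad to ``length_s`` seconds
    (21600 samples at the 360 Hz default).
    """
    x = np.asarray(x, dtype=float)
    k1 = max(1, int(round(0.2 * fs)) | 1)
    k2 = max(1, int(round(0.6 * fs)) | 1)
    baseline = median_filter(median_filter(x, size=k1, mode="nearest"),
                             size=k2, mode="nearest")
    y = x - baseline
    scale = record_abs_max if record_abs_max is not None else float(
        np.max(np.abs(y))) if len(y) else 0.0
    if scale and scale > 0:
        y = y / scale
    if fs != target_fs:
        rec = ECGRecord("_seg", y, fs, np.array([], dtype=np.int64),
                        np.array([], dtype="<U1"))
        y = resample_record(rec, target_fs).lead(0)
    n_target = int(round(length_s * target_fs))
    if len(y) >= n_target:
        return y[:n_target]
    return np.concatenate([y, np.zeros(n_target - len(y))])


@dataclasses.dataclass
class SegmentLabeling:
    """Per-segment predictions and the encoded per-beat context feature."""

    label_set: LabelSet
    overlap: str
    segments: list
    beat_ids: np.ndarray | None = None  # (n_beats,), overlap == 'none'
    beat_bits: np.ndarray | None = None  # (n_beats, |labels|), overlap == 'half'

    def feature_frame(self) -> pd.DataFrame:
        """Encode per-beat context as ``seg_<label>`` indicator columns.

        Without overlap this is the one-hot expansion of the categorical
        label ID; with half overlap it is the multi-hot bit vector directly.
        Either way the frame has |label_set| columns of 0/1 integers.
        """
        cols = [f"{SEGMENT_FEATURE_PREFIX}{n}" for n in self.label_set]
        if self.overlap == "none":
            bits = np.zeros((len(self.beat_ids), len(self.label_set)), dtype=int)
            bits[np.arange(len(self.beat_ids)), self.beat_ids] = 1
        else:
            bits = self.beat_bits.astype(int)
        return pd.DataFrame(bits, columns=cols)

    def beat_labels(self) -> list:
        """Decode the encoding back to label names (one or a set per beat)."""
        if self.overlap == "none":
            return [self.label_set.name(i) for i in self.beat_ids]
        return [{self.label_set.name(j) for j in np.nonzero(row)[0]}
                for row in self.beat_bits]


class SegmentClassifier:
    """Interface: a rhythm classifier operating on record segments.

    Concrete providers define :attr:`label_set`, :attr:`segment_length_s`,
    :attr:`input_fs` and implement :meth:`predict_segment`, returning a
    probability vector over the label set for the samples
    ``rec[start:end]``.
    """

    label_set: LabelSet
    segment_length_s: float = 60.0
    input_fs: float = 360.0

    def predict_segment(self, rec: ECGRecord, start: int, end: int,
                        lead: int = 0) -> np.ndarray:
        raise NotImplementedError


class OracleSegmentClassifier(SegmentClassifier):
    """Test double that reads the true rhythm block of a synthetic record.

    Predicts the label of the block with the largest overlap with the
    segment, with probability 1.  With ``error_rate`` > 0 the prediction is
    replaced, with that probability, by a uniformly chosen *wrong* label;
    corruption is seeded per (record, segment) so repeated queries agree.
    """

    def __init__(self, truths: dict[str, SynthTruth] | SynthTruth,
                 label_set: LabelSet | None = None, error_rate: float = 0.0,
                 seed: int = 0, segment_length_s: float = 60.0):
        if isinstance(truths, SynthTruth):
            truths = {"": truths}
        self.truths = truths
        self.label_set = label_set or LabelSet(
            sorted({lbl for t in truths.values() for lbl, _, _ in t.blocks}))
        if not 0.0 <= error_rate <= 1.0:
            raise ValueError("error_rate must be in [0, 1]")
        self.error_rate = error_rate
        self.seed = seed
        self.segment_length_s = segment_length_s

    def _truth_for(self, rec: ECGRecord) -> SynthTruth:
        t = self.truths.get(rec.record_id) or self.truths.get("")
        if t is None:
            raise KeyError(f"no truth for record {rec.record_id!r}")
        if t.fs != rec.fs:
            t = t.rescale(rec.fs)
        return t

    def predict_segment(self, rec, start, end, lead=0):
        truth = self._truth_for(rec)
        overlaps = {}
        for lbl, lo, hi in truth.blocks:
            overlaps[lbl] = overlaps.get(lbl, 0) + max(
                0, min(end, hi) - max(start, lo))
        label = max(sorted(overlaps), key=lambda k: overlaps[k])
        if self.error_rate > 0:
            rng = np.random.default_rng(np.random.SeedSequence(
                [self.seed, zlib.crc32(rec.record_id.encode()), int(start)]))
            if rng.random() < self.error_rate:
                wrong = [n for n in self.label_set if n != label]
                label = str(rng.choice(wrong))
        probs = np.zeros(len(self.label_set))
        probs[self.label_set.id(label)] = 1.0
        return probs


def assign_segment_labels(rec: ECGRecord, clf: SegmentClassifier,
                          overlap: str = "none",
                          length_s: float | None = None,
                          lead: int = 0) -> SegmentLabeling:
    """Predict per-segment rhythm labels and encode them per beat.

    Every beat (by its R sample) receives the label of the segment
    containing it (categorical ID, no overlap) or one bit per label over
    the up-to-two covering segments (half overlap).  Partial trailing
    segments are classified like any other (the preprocessing zero-pads),
    so no beat is left unlabeled.
    """
    length_s = length_s if length_s is not None else clf.segment_length_s
    bounds = segment_record(rec.n_samples, rec.fs, length_s, overlap)
    label_set = clf.label_set
    segments = []
    for start, end in bounds:
        probs = np.asarray(clf.predict_segment(rec, start, end, lead), float)
        if len(probs) != len(label_set):
            raise ValueError("classifier output length != |label_set|")
        segments.append(Segment(start, end, probs,
                                label_set.name(int(np.argmax(probs)))))
    n_beats = rec.n_beats
    if overlap == "none":
        ids = np.full(n_beats, -1, dtype=int)
        for seg in segments:
            inside = (rec.r_peaks >= seg.start) & (rec.r_peaks < seg.end)
            ids[inside] = label_set.id(seg.label)
        if np.any(ids < 0):
            raise RuntimeError("internal error: beat outside all segments")
        return SegmentLabeling(label_set, overlap, segments, beat_ids=ids)
    bits = np.zeros((n_beats, len(label_set)), dtype=int)
    covered = np.zeros(n_beats, dtype=bool)
    for seg in segments:
        inside = (rec.r_peaks >= seg.start) & (rec.r_peaks < seg.end)
        bits[inside, label_set.id(seg.label)] = 1
        covered |= inside
    if not covered.all():
        raise RuntimeError("internal error: beat outside all segments")
    return SegmentLabeling(label_set, overlap, segments, beat_bits=bits)


class EcgRecordingCNN(SegmentClassifier, ClassifierMixin, BaseEstimator):
    """Trainable 1-D CNN rhythm classifier for fixed-length ECG segments.

    The default architecture is 7 ConvUnits — each a same-padded 1-D
    convolution (128 filters, kernel 3) + ReLU, max pooling (size 2) and
    dropout (rate 0.5) — followed by three fully connected layers, each with
    batch normalization (ReLU on the first two), and a final per-label
    sigmoid.  Sigmoid rather than softmax because rhythm annotations can be
    multi-label.  Trained with binary cross-entropy and Adam (lr 0.001).

    ``fit`` expects preprocessed segments (see :func:`preprocess_segment`)
    as a (n_segments, input_len) array and label names (or multi-hot rows)
    aligned with ``labels``.  The prediction rule is the label with the
    highest score.
    """

    def __init__(self, labels=("NSR", "AFIB_LIKE"), segment_length_s: float = 60.0,
                 input_fs: float = 360.0, n_conv_units: int = 7,
                 filters: int = 128, kernel_size: int = 3, pool_size: int = 2,
                 dropout: float = 0.5, fc_sizes=(256, 64), lr: float = 1e-3,
                 epochs: int = 35, batch_size: int = 16, seed: int = 0):
        self.labels = tuple(labels)
        self.segment_length_s = segment_length_s
        self.input_fs = input_fs
        self.n_conv_units = n_conv_units
        self.filters = filters
        self.kernel_size = kernel_size
        self.pool_size = pool_size
        self.dropout = dropout
        self.fc_sizes = tuple(fc_sizes)
        self.lr = lr
        self.epochs = epochs
        self.batch_size = batch_size
        self.seed = seed

    @property
    def label_set(self) -> LabelSet:
        return LabelSet(self.labels)

    @property
    def input_len(self) -> int:
        return int(round(self.segment_length_s * self.input_fs))

    def _build(self, rng: np.random.Generator) -> _cnn.Network:
        layers: list[_cnn.Layer] = []
        ch = 1
        length = self.input_len
        for _ in range(self.n_conv_units):
            layers += [_cnn.Conv1D(ch, self.filters, self.kernel_size, rng),
                       _cnn.ReLU(), _cnn.MaxPool1D(self.pool_size),
                       _cnn.Dropout(self.dropout, rng)]
            ch = self.filters
            length //= self.pool_size
        if length < 1:
            raise ValueError("input too short for the conv stack")
        layers.append(_cnn.Flatten())
        n_in = length * ch
        widths = list(self.fc_sizes) + [len(self.labels)]
        for i, n_out in enumerate(widths):
            layers.append(_cnn.Dense(n_in, n_out, rng))
            layers.append(_cnn.BatchNorm(n_out))
            if i < len(widths) - 1:
                layers.append(_cnn.ReLU())
            n_in = n_out
        return _cnn.Network(layers)

    def build_network(self) -> _cnn.Network:
        """Construct the (untrained) network with seeded initialization."""
        return self._build(np.random.default_rng(self.seed))

    def _as_multihot(self, y) -> np.ndarray:
        y = np.asarray(y)
        if y.ndim == 2:
            return y.astype(float)
        out = np.zeros((len(y), len(self.labels)))
        for i, name in enumerate(y):
            out[i, self.labels.index(str(name))] = 1.0
        return out

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.input_len:
            raise ValueError(
                f"X must be (n, {self.input_len}) preprocessed segments")
        T = self._as_multihot(y)
        rng = np.random.default_rng(self.seed)
        net = self._build(rng)
        opt = _cnn.Adam(net, lr=self.lr)
        n = len(X)
        self.loss_curve_ = []
        for _ in range(self.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for lo in range(0, n, self.batch_size):
                idx = order[lo : lo + self.batch_size]
                xb = X[idx][:, :, None]
                logits = net.forward(xb, train=True)
                loss, grad = _cnn.bce_loss(logits, T[idx])
                net.backward(grad)
                opt.step()
                epoch_loss += loss * len(idx)
            self.loss_curve_.append(epoch_loss / n)
        self.net_ = net
        self.classes_ = np.array(self.labels)
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "net_")
        X = np.asarray(X, dtype=float)
        out = []
        for lo in range(0, len(X), max(1, self.batch_size)):
            logits = self.net_.forward(X[lo : lo + self.batch_size][:, :, None],
                                       train=False)
            out.append(_cnn.sigmoid(logits))
        return np.vstack(out)

    def predict(self, X) -> np.ndarray:
        probs = self.predict_proba(X)
        return self.classes_[np.argmax(probs, axis=1)]

    def score(self, X, y) -> float:
        y = np.asarray(y)
        if y.ndim == 2:
            y = self.classes_[np.argmax(y, axis=1)]
        return float(np.mean(self.predict(X) == y.astype(str)))

    # ---- SegmentClassifier interface -------------------------------------
    def predict_segment(self, rec: ECGRecord, start: int, end: int,
                        lead: int = 0) -> np.ndarray:
        check_is_fitted(self, "net_")
        raw = rec.lead(lead)[start:end]
        record_abs_max = float(np.max(np.abs(rec.lead(lead)))) or None
        x = preprocess_segment(raw, rec.fs, self.input_fs,
                               self.segment_length_s, record_abs_max)
        return self.predict_proba(x[None, :])[0]

    # ---- serialization ---------------------------------------------------
    def save(self, path: str | Path) -> None:
        check_is_fitted(self, "net_")
        path = Path(path)
        arrays = {f"a{i}": a for i, a in enumerate(self.net_.state())}
        np.savez(path.with_suffix(".npz"), **arrays)
        meta = self.get_params()
        meta["labels"] = list(self.labels)
        meta["fc_sizes"] = list(self.fc_sizes)
        path.with_suffix(".json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, path: str | Path) -> "EcgRecordingCNN":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        est = cls(**meta)
        net = est.build_network()
        with np.load(path.with_suffix(".npz")) as z:
            net.load_state([z[f"a{i}"] for i in range(len(z.files))])
        est.net_ = net
        est.classes_ = np.array(est.labels)
        return est
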