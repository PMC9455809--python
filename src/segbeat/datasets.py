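"""Programmatic datasets for training and testing the rhythm classifiers.

Everything here is synthetic and generated at call time; nothing is read
from disk.
"""
from __future__ import annotations

import dataclasses

import numpy as np

from .segment import EcgRecordingCNN, preprocess_segment
from .synth import AFIB_LIKE, NSR, SynthConfig, generate_record


def synthetic_segment_set(n_segments: int, clf: EcgRecordingCNN,
                          seed: int = 0, record_fs: float = 120.0):
    """Single-rhythm segments, preprocessed for ``clf``, with labels.

    Each segment is one fresh synthetic record whose whole duration is a
    single rhythm block drawn (seeded) from the classifier's label set; the
    record is baseline-filtered, normalized, resampled and cut/padded to the
    classifier's input shape.  Returns ``(X, y)`` with X of shape
    ``(n_segments, input_len)``.
    """
    rng = np.random.default_rng(seed)
    labels = list(clf.labels)
    X = np.empty((n_segments, clf.input_len))
    y = []
    for i in range(n_segments):
        label = labels[int(rng.integers(len(labels)))]
        cfg = SynthConfig(seed=seed, fs=record_fs,
                          rhythm_blocks=((label, clf.segment_length_s),))
        rec, _ = generate_record(cfg, record_id=f"seg-{seed}-{i:05d}")
        X[i] = preprocess_segment(rec.lead(0), rec.fs, clf.input_fs,
                                  clf.segment_length_s)
        y.append(label)
    return X, np.array(y)


def scaled_cnn(seed: int = 0, epochs: int = 50) -> EcgRecordingCNN:
    """A reduced-size rhythm CNN configuration for desk-scale training runs.

    Same architecture family as the default (7 ConvUnits, 3 FC layers,
    sigmoid head) with a 36 Hz input rate and 16 filters, so a few hundred
    60 s segments train in minutes on one CPU.  The dropout rate shrinks
    with the filter count (0.05 at 16 filters): dropping half of 16 channels
    seven times destroys the signal that half of 128 channels would keep.
    """
    return EcgRecordingCNN(labels=(NSR, AFIB_LIKE), input_fs=36.0,
                           filters=16, fc_sizes=(64, 32), dropout=0.05,
                           epochs=epochs, batch_size=16, seed=seed)
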