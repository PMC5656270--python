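"""Fixed-length epoch segmentation and the 50% ground-truth labeling rule.

The fully automatic pipeline classifies the signal in non-overlapping 5-s
epochs.  Five seconds captures most chewing sequences (mean annotated
sequence length 7.35 +/- 5.16 s) while still containing several chew cycles
even at the slowest chewing frequency (0.94 Hz).  An epoch is labeled food
intake (+1) when at least half of its samples fall inside annotated intake
intervals, otherwise non-intake (-1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np

from .core_io import ChewSegment, SensorSignal

DEFAULT_EPOCH_S = 5.0

INTAKE_LABEL = 1
NON_INTAKE_LABEL = -1


@dataclass
class Epoch:
    """One fixed-length window of a visit recording."""

    index: int
    start_s: float
    duration_s: float
    samples: np.ndarray
    label: Optional[int] = None
    predicted: Optional[int] = None

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("epoch duration must be positive")
        for value in (self.label, self.predicted):
            if value is not None and value not in (INTAKE_LABEL, NON_INTAKE_LABEL):
                raise ValueError("labels must be +1 or -1")

    @property
    def end_s(self) -> float:
        return self.start_s + self.duration_s


def segment_epochs(signal: SensorSignal, epoch_s: float = DEFAULT_EPOCH_S) -> List[Epoch]:
    """Split a signal into floor(duration / epoch_s) non-overlapping epochs.

    The grid starts at t = 0 of the recording; a trailing partial epoch is
    discarded.
    """
    if epoch_s <= 0:
        raise ValueError("epoch_s must be positive")
    samples_per_epoch = int(round(epoch_s * signal.fs))
    n_epochs = len(signal.samples) // samples_per_epoch
    epochs = []
    for i in range(n_epochs):
        sl = signal.samples[i * samples_per_epoch : (i + 1) * samples_per_epoch]
        epochs.append(Epoch(index=i, start_s=i * epoch_s, duration_s=epoch_s, samples=sl))
    return epochs


def intake_overlap_fraction(
    start_s: float, end_s: float, segments: Sequence[ChewSegment]
) -> float:
    """Fraction of [start_s, end_s) covered by intake intervals.

    Annotations of one visit are non-overlapping, so plain summation of the
    per-segment overlaps is exact.
    """
    total = 0.0
    for seg in segments:
        if not seg.is_intake:
            continue
        lo = max(start_s, seg.start_s)
        hi = min(end_s, seg.end_s)
        if hi > lo:
            total += hi - lo
    return total / (end_s - start_s)


def label_epoch(epoch: Epoch, segments: Sequence[ChewSegment]) -> int:
    """+1 iff at least half of the epoch lies inside intake intervals."""
    frac = intake_overlap_fraction(epoch.start_s, epoch.end_s, segments)
    return INTAKE_LABEL if frac >= 0.5 else NON_INTAKE_LABEL


def label_epochs(epochs: Sequence[Epoch], segments: Sequence[ChewSegment]) -> np.ndarray:
    """Label all epochs in place and return the label vector."""
    labels = np.empty(len(epochs), dtype=int)
    for i, epoch in enumerate(epochs):
        epoch.label = label_epoch(epoch, segments)
        labels[i] = epoch.label
    return labels
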