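"""Signal conditioning ahead of peak detection.

Chewing occupies roughly 0.94–2 Hz, so the conditioning chain is: subtract
the mean amplitude (offset drift of the piezo film), then low-pass at 3 Hz
to strip speech, motion bursts and wideband noise.  The filter family is a
4th-order Butterworth applied forward-backward: maximally flat passband and
zero phase, so peak positions — and therefore counts — are not shifted.

A centered moving average with shrink-to-valid edges is used later in the
counting pipeline to smooth the thresholded signal; it lives here because it
is a generic conditioning primitive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .core_io import SensorSignal


@dataclass
class FilterSpec:
    """Low-pass filter configuration.

    cutoff_hz must stay below the Nyquist frequency of the signal it is
    applied to.  ``zero_phase`` selects forward-backward application.
    """

    cutoff_hz: float = 3.0
    order: int = 4
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if self.cutoff_hz <= 0:
            raise ValueError("cutoff must be positive")
        if self.order < 1:
            raise ValueError("order must be >= 1")


def demean(signal: SensorSignal) -> SensorSignal:
    """Subtract the mean amplitude from the signal."""
    if len(signal.samples) == 0:
        raise ValueError("cannot demean an empty signal")
    return signal.replace_samples(signal.samples - signal.samples.mean())


def lowpass(signal: SensorSignal, spec: FilterSpec | None = None) -> SensorSignal:
    """Low-pass filter the signal (default 3 Hz, order 4, zero phase)."""
    spec = spec or FilterSpec()
    nyq = signal.fs / 2.0
    if spec.cutoff_hz >= nyq:
        raise ValueError(
            f"cutoff {spec.cutoff_hz} Hz must be below Nyquist {nyq} Hz"
        )
    sos = sps.butter(spec.order, spec.cutoff_hz, btype="low", fs=signal.fs, output="sos")
    if spec.zero_phase:
        filtered = sps.sosfiltfilt(sos, signal.samples)
    else:
        filtered = sps.sosfilt(sos, signal.samples)
    return signal.replace_samples(filtered)


def moving_average(samples: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average; edge windows shrink to the available samples.

    Output length equals input length and a constant input is returned
    unchanged (no artificial boundary peaks).
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    x = np.asarray(samples, dtype=float)
    if window == 1 or len(x) == 0:
        return x.copy()
    kernel = np.ones(min(window, len(x)))
    sums = np.convolve(x, kernel, mode="same")
    counts = np.convolve(np.ones_like(x), kernel, mode="same")
    return sums / counts


def preprocess(signal: SensorSignal, spec: FilterSpec | None = None) -> SensorSignal:
    """Standard conditioning chain: demean then low-pass."""
    return lowpass(demean(signal), spec)


def decimate(signal: SensorSignal, factor: int) -> SensorSignal:
    """Anti-aliased decimation by an integer factor (optional speed stage)."""
    if factor < 1:
        raise ValueError("decimation factor must be >= 1")
    if factor == 1:
        return signal.replace_samples(signal.samples.copy())
    out = sps.decimate(signal.samples, factor, zero_phase=True)
    return SensorSignal(out, signal.fs / factor, signal.subject_id, signal.visit_id)
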