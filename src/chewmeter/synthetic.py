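"""Ground-truth jaw-sensor signal generator.

The study's recordings are not publicly deposited, so every stage of the
pipeline is exercised on synthetic signals that emulate the statistical
structure of the real data:

* chewing bouts are trains of raised-cosine strain pulses — one pulse per
  jaw close, at a per-bout chewing frequency drawn from 0.94–2.0 Hz, with
  bout durations around 7.35 +/- 5.16 s (truncated at 1.5 s);
* a meal is rest, then alternating bouts and short pauses, then rest,
  mirroring the laboratory protocol (relaxed sitting before and after
  unrestricted eating);
* degradations: additive Gaussian noise, slow sinusoidal baseline drift,
  and transient artifacts (low-frequency biphasic "motion" spikes and
  100–400 Hz "speech" bursts) anywhere in the record;
* subjects differ by a random log-uniform gain (x0.3–x3), emulating the
  large amplitude differences caused by adiposity and sensor placement.

Each pulse occupies ~30% of its chew period, so the amplitude histogram is
peak-dominated the way the real sensor's is and the upper-percentile
threshold lands below the weakest true pulse peak.

All randomness flows from a single master seed through
``numpy.random.SeedSequence`` spawning (one child stream per meal).

A separate deterministic construction, :func:`generate_alpha_probe_cohort`,
builds visits whose |error|-versus-alpha curve has its common minimum
exactly at alpha = 0.90: every chew period carries a sub-threshold
distractor bump just below the 0.90-quantile (double-counted once the
threshold drops below it) and one in five true pulses is a weak pulse just
above it (missed once the threshold rises).  The two amplitudes are placed
by a fixed-point iteration on the conditioned signal's own quantiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .core_io import ChewSegment, SensorSignal
from .epochs import label_epochs, segment_epochs
from .features import feature_matrix
from .preprocess import demean, preprocess

#: Fraction of each chew period occupied by the strain pulse.
PULSE_DUTY = 0.30


@dataclass
class CohortSpec:
    """Statistical description of a synthetic cohort.

    Durations are seconds, amplitudes volts.  ``noise_sd`` defaults to the
    value giving 10 dB bout SNR at unit pulse amplitude.
    """

    n_subjects: int = 10
    visits_per_subject: int = 3
    bout_duration_mean: float = 7.35
    bout_duration_sd: float = 5.16
    bout_duration_min: float = 1.5
    chew_freq_range: Tuple[float, float] = (0.94, 2.0)
    bouts_per_meal: Tuple[int, int] = (8, 12)
    pause_duration: Tuple[float, float] = (1.0, 5.0)
    rest_duration: Tuple[float, float] = (20.0, 40.0)
    amplitude: float = 1.0
    amp_jitter: float = 0.2
    noise_sd: float = field(default=None)  # type: ignore[assignment]
    artifact_rate: float = 2.0  # events per minute
    drift_amplitude: float = 0.05
    subject_gain_range: Tuple[float, float] = (0.3, 3.0)
    fs: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd is None:
            self.noise_sd = noise_sd_for_snr(10.0, self.amplitude)
        lo, hi = self.chew_freq_range
        if not 0.5 <= lo <= hi <= 2.5:
            raise ValueError("chew_freq_range must lie within [0.5, 2.5] Hz")
        if self.fs <= 2 * 400.0:
            # speech-band artifacts extend to 400 Hz
            raise ValueError("fs must exceed twice the 400 Hz artifact band")
        if self.n_subjects < 1 or self.visits_per_subject < 1:
            raise ValueError("cohort must contain at least one subject and visit")


def noise_sd_for_snr(snr_db: float, amplitude: float = 1.0, duty: float = PULSE_DUTY) -> float:
    """Noise sd giving the requested in-bout SNR for a raised-cosine train.

    The mean square of a raised-cosine pulse of peak A is 3/8 A^2 over the
    pulse, times the duty cycle over the bout.
    """
    signal_power = duty * 0.375 * amplitude**2
    return float(np.sqrt(signal_power / 10 ** (snr_db / 10.0)))


def _raised_cosine(n: int) -> np.ndarray:
    """Unit-peak raised-cosine pulse of n samples (half-period Hann bump)."""
    t = np.arange(n)
    return 0.5 * (1.0 - np.cos(2.0 * np.pi * (t + 0.5) / n))


def generate_bout(
    n_chews: int,
    freq: float,
    fs: float,
    amp_jitter: float = 0.0,
    seed: int = 0,
    amplitude: float = 1.0,
    duty: float = PULSE_DUTY,
) -> Tuple[np.ndarray, int]:
    """One chewing bout: ``n_chews`` raised-cosine pulses at ``freq`` Hz.

    Each pulse sits at the start of its 1/freq period and occupies ``duty``
    of it; per-pulse peak amplitude is jittered uniformly by
    ``+/- amp_jitter`` (fraction).  Returns (samples, true chew count);
    the bout duration is exactly n_chews / freq seconds of samples.
    """
    if n_chews < 1:
        raise ValueError("n_chews must be >= 1")
    if not 0.5 <= freq <= 2.5:
        raise ValueError("chew frequency must lie in [0.5, 2.5] Hz")
    rng = np.random.default_rng(seed)
    period_n = int(round(fs / freq))
    pulse_n = max(3, int(round(duty * period_n)))
    pulse = _raised_cosine(pulse_n)
    total_n = int(round(n_chews * fs / freq))
    out = np.zeros(total_n)
    for k in range(n_chews):
        a = amplitude * (1.0 + amp_jitter * rng.uniform(-1.0, 1.0))
        start = k * period_n
        end = min(start + pulse_n, total_n)
        out[start:end] += a * pulse[: end - start]
    return out, n_chews


@dataclass
class Meal:
    """One generated visit with its ground truth."""

    signal: SensorSignal
    segments: List[ChewSegment]
    intake_mask: np.ndarray
    acnt: int
    subject_id: str = ""
    visit_id: str = ""
    meal_type: str = ""
    gain: float = 1.0


def _add_artifacts(samples: np.ndarray, fs: float, rate_per_min: float, amplitude: float, rng) -> None:
    """Transient biphasic spikes and speech-band bursts, in place."""
    duration_min = len(samples) / fs / 60.0
    n_events = rng.poisson(rate_per_min * duration_min)
    for _ in range(n_events):
        kind = rng.uniform()
        if kind < 0.5:  # motion-like biphasic spike, ~5 Hz, 0.2 s
            width = int(0.2 * fs)
            t = np.arange(width) / fs
            shape = np.sin(2 * np.pi * 5.0 * t) * np.hanning(width)
            amp = amplitude * rng.uniform(0.5, 1.5)
        else:  # speech-like burst, 100-400 Hz carrier, 0.3 s
            width = int(0.3 * fs)
            t = np.arange(width) / fs
            carrier = rng.uniform(100.0, 400.0)
            shape = np.sin(2 * np.pi * carrier * t) * np.hanning(width)
            amp = amplitude * rng.uniform(0.1, 0.4)
        start = rng.integers(0, max(1, len(samples) - width))
        samples[start : start + width] += amp * shape


def generate_meal(
    spec: CohortSpec,
    seed: int = 0,
    subject_id: str = "s0",
    visit_id: str = "v0",
    gain: float = 1.0,
    n_bouts: int | None = None,
    chew_counts: Sequence[int] | None = None,
) -> Meal:
    """One meal: rest – (bout, pause)* – rest, with noise, drift, artifacts.

    Bout durations are Gaussian (truncated from below), chew frequencies
    uniform in the configured range; the per-bout true count is recorded in
    the returned annotations.  ``gain`` scales the whole recording.
    ``chew_counts`` pins the per-bout counts (overrides ``n_bouts`` and the
    duration draw) for constructions that need exact ground truth.
    """
    rng = np.random.default_rng(seed)
    fs = spec.fs
    if chew_counts is not None:
        n_bouts = len(chew_counts)
    elif n_bouts is None:
        n_bouts = int(rng.integers(spec.bouts_per_meal[0], spec.bouts_per_meal[1] + 1))

    pieces: List[np.ndarray] = []
    segments: List[ChewSegment] = []
    t = 0.0

    rest1 = rng.uniform(*spec.rest_duration)
    pieces.append(np.zeros(int(round(rest1 * fs))))
    t += len(pieces[-1]) / fs

    acnt = 0
    for b in range(n_bouts):
        freq = rng.uniform(*spec.chew_freq_range)
        if chew_counts is not None:
            n_chews = int(chew_counts[b])
        else:
            duration = max(
                spec.bout_duration_min,
                rng.normal(spec.bout_duration_mean, spec.bout_duration_sd),
            )
            n_chews = max(2, int(round(duration * freq)))
        bout, truth = generate_bout(
            n_chews,
            freq,
            fs,
            amp_jitter=spec.amp_jitter,
            seed=int(rng.integers(2**31)),
            amplitude=spec.amplitude,
        )
        start = t
        pieces.append(bout)
        t += len(bout) / fs
        segments.append(ChewSegment(start_s=start, end_s=t, label="intake", chew_count=truth))
        acnt += truth
        if b < n_bouts - 1:
            pause = rng.uniform(*spec.pause_duration)
            pieces.append(np.zeros(int(round(pause * fs))))
            t += len(pieces[-1]) / fs

    rest2 = rng.uniform(*spec.rest_duration)
    pieces.append(np.zeros(int(round(rest2 * fs))))

    samples = np.concatenate(pieces)
    n = len(samples)
    time = np.arange(n) / fs

    if spec.drift_amplitude > 0:
        period = rng.uniform(20.0, 60.0)
        phase = rng.uniform(0, 2 * np.pi)
        samples = samples + spec.drift_amplitude * np.sin(2 * np.pi * time / period + phase)
    if spec.artifact_rate > 0:
        _add_artifacts(samples, fs, spec.artifact_rate, spec.amplitude, rng)
    if spec.noise_sd > 0:
        samples = samples + rng.normal(0.0, spec.noise_sd, size=n)

    samples = gain * samples

    mask = np.zeros(n, dtype=bool)
    for seg in segments:
        i0 = int(np.ceil(seg.start_s * fs - 1e-9))
        i1 = int(np.ceil(seg.end_s * fs - 1e-9))
        mask[i0:i1] = True

    return Meal(
        signal=SensorSignal(samples, fs, subject_id, visit_id),
        segments=segments,
        intake_mask=mask,
        acnt=acnt,
        subject_id=subject_id,
        visit_id=visit_id,
        gain=gain,
    )


def generate_cohort(spec: CohortSpec) -> List[Meal]:
    """Subjects x visits meals with per-subject amplitude gains.

    Reproducible from ``spec.seed``: one spawned seed stream per meal plus
    one for the per-subject gains.
    """
    ss = np.random.SeedSequence(spec.seed)
    n_meals = spec.n_subjects * spec.visits_per_subject
    children = ss.spawn(n_meals + 1)
    gain_rng = np.random.default_rng(children[0])
    lo, hi = spec.subject_gain_range
    gains = np.exp(gain_rng.uniform(np.log(lo), np.log(hi), size=spec.n_subjects))

    meal_types = ["breakfast", "lunch", "dinner"]
    meals: List[Meal] = []
    idx = 1
    for s in range(spec.n_subjects):
        for v in range(spec.visits_per_subject):
            meal = generate_meal(
                spec,
                seed=int(children[idx].generate_state(1)[0] % (2**31)),
                subject_id=f"s{s:02d}",
                visit_id=f"s{s:02d}_v{v}",
                gain=float(gains[s]),
            )
            meal.meal_type = meal_types[v % len(meal_types)]
            meals.append(meal)
            idx += 1
    return meals


def build_epoch_dataset(
    meals: Sequence[Meal], epoch_s: float = 5.0
) -> Dict[str, Tuple[np.ndarray, np.ndarray]]:
    """Per-subject (features, true labels) for classifier training.

    Epochs are cut from the demeaned raw signal on the t=0 grid and labeled
    with the 50% rule against the ground-truth intake segments.
    """
    per_subject: Dict[str, List[Tuple[np.ndarray, np.ndarray]]] = {}
    for meal in meals:
        raw = demean(meal.signal)
        grid = segment_epochs(raw, epoch_s)
        labels = label_epochs(grid, meal.segments)
        feats = feature_matrix([e.samples for e in grid], meal.signal.fs)
        per_subject.setdefault(meal.subject_id, []).append((feats, labels))
    return {
        s: (np.vstack([f for f, _ in parts]), np.concatenate([l for _, l in parts]))
        for s, parts in per_subject.items()
    }


# ---------------------------------------------------------------------------
# alpha-calibration probe cohort
# ---------------------------------------------------------------------------

_PROBE_PERIOD_S = 1.0
_PROBE_PULSE_W_S = 0.30
_PROBE_MAIN_OFFSET_S = 0.10
_PROBE_DIST_OFFSET_S = 0.55
_PROBE_WEAK_EVERY = 5  # every 5th main pulse is weak


def _build_probe(n_periods: int, fs: float, a_weak: float, a_dist: float) -> np.ndarray:
    period_n = int(round(_PROBE_PERIOD_S * fs))
    pulse_n = int(round(_PROBE_PULSE_W_S * fs))
    pulse = _raised_cosine(pulse_n)
    x = np.zeros(n_periods * period_n)
    for k in range(n_periods):
        base = k * period_n
        main_amp = a_weak if (k % _PROBE_WEAK_EVERY) == _PROBE_WEAK_EVERY - 1 else 1.0
        i = base + int(round(_PROBE_MAIN_OFFSET_S * fs))
        x[i : i + pulse_n] += main_amp * pulse
        j = base + int(round(_PROBE_DIST_OFFSET_S * fs))
        x[j : j + pulse_n] += a_dist * pulse
    return x


def _probe_peaks(y: np.ndarray, n_periods: int, fs: float) -> Tuple[float, float, float]:
    """(min weak-main peak, min strong-main peak, max distractor peak)."""
    period_n = int(round(_PROBE_PERIOD_S * fs))
    w = int(round(_PROBE_PULSE_W_S * fs))
    weak, strong, dist = [], [], []
    for k in range(n_periods):
        base = k * period_n
        i = base + int(round(_PROBE_MAIN_OFFSET_S * fs))
        j = base + int(round(_PROBE_DIST_OFFSET_S * fs))
        peak = y[i : i + w].max()
        (weak if (k % _PROBE_WEAK_EVERY) == _PROBE_WEAK_EVERY - 1 else strong).append(peak)
        dist.append(y[j : j + w].max())
    return min(weak), min(strong), max(dist)


def generate_alpha_probe_visit(
    n_periods: int = 30, fs: float = 1000.0, target_alpha: float = 0.90
) -> Tuple[SensorSignal, List[ChewSegment]]:
    """One deterministic visit whose |error|(alpha) curve dips at ``target_alpha``.

    The weak-pulse and distractor amplitudes are placed by fixed-point
    iteration so that, on the conditioned signal, every distractor peak
    falls between the (alpha-0.01)- and alpha-quantiles and every weak main
    peak between the alpha- and (alpha+0.01)-quantiles.  At the target
    alpha the count is exact; one grid step lower every distractor is
    double-counted, one step higher every weak pulse is lost.
    """
    a_weak, a_dist = 0.75, 0.55
    q_lo, q_mid, q_hi = (target_alpha - 0.01) * 100, target_alpha * 100, (target_alpha + 0.01) * 100
    for _ in range(60):
        x = _build_probe(n_periods, fs, a_weak, a_dist)
        y = preprocess(SensorSignal(x, fs)).samples
        t_lo, t_mid, t_hi = np.percentile(y, [q_lo, q_mid, q_hi])
        p_weak, p_strong, p_dist = _probe_peaks(y, n_periods, fs)
        floor = np.percentile(y, 20)  # between-pulse baseline
        target_d = 0.5 * (t_lo + t_mid)
        target_w = 0.5 * (t_mid + t_hi)
        err_d = target_d - p_dist
        err_w = target_w - p_weak
        tol = 0.05 * (t_mid - t_lo)
        if abs(err_d) < tol and abs(err_w) < tol:
            break
        a_dist *= 1.0 + 0.7 * err_d / max(p_dist - floor, 1e-6)
        a_weak *= 1.0 + 0.7 * err_w / max(p_weak - floor, 1e-6)

    x = _build_probe(n_periods, fs, a_weak, a_dist)
    y = preprocess(SensorSignal(x, fs)).samples
    t_lo, t_mid, t_hi = np.percentile(y, [q_lo, q_mid, q_hi])
    p_weak, p_strong, p_dist = _probe_peaks(y, n_periods, fs)
    if not (t_lo < p_dist < t_mid < p_weak < t_hi < p_strong):
        raise RuntimeError("alpha-probe construction failed to separate amplitudes")

    signal = SensorSignal(x, fs)
    segments = [
        ChewSegment(start_s=0.0, end_s=len(x) / fs, label="intake", chew_count=n_periods)
    ]
    return signal, segments


def generate_alpha_probe_cohort(
    n_visits: int = 20, fs: float = 1000.0, target_alpha: float = 0.90
) -> List[Tuple[SensorSignal, List[ChewSegment]]]:
    """Deterministic calibration cohort; visits differ in length only."""
    return [
        generate_alpha_probe_visit(n_periods=25 + i, fs=fs, target_alpha=target_alpha)
        for i in range(n_visits)
    ]
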