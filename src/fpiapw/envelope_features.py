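"""Rate-of-change envelope, peak detection, epoch averaging, minima catalog.

The interference intensity of a moving cavity is I(t) ~ cos(phi(t)), so
|dI/dt| ~ |sin(phi)| * |phi'|: the Hilbert envelope of the intensity's
rate of change tracks the instantaneous phase velocity, i.e. how fast the
membrane moves.  Envelope peaks mark the systolic upstroke (one per
heartbeat); envelope minima mark candidate phase-direction reversals
(systole start, systolic peak, dicrotic notch, rebound peak) and feed the
breakpoint proposal of the annotation stage.

Epoch averaging: every detected envelope peak is an event onset; the
envelope segments around all onsets are averaged into a mean cycle with a
95% confidence band, minima of that mean cycle are found by inverted peak
detection and mapped back to absolute time at every onset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "EnvelopeResult",
    "EpochAverage",
    "MinimaCatalog",
    "compute_envelope",
    "detect_envelope_peaks",
    "epoch_average",
    "detect_epoch_minima",
]


@dataclass(frozen=True)
class EnvelopeResult:
    """Gradient, Hilbert envelope and its smoothed version on a trimmed axis."""

    time_s: np.ndarray
    rate_of_change: np.ndarray
    envelope: np.ndarray          # |analytic signal| of rate_of_change, max = 1
    smoothed_envelope: np.ndarray

    @property
    def dt(self) -> float:
        return float(self.time_s[1] - self.time_s[0])

    @property
    def sampling_rate_hz(self) -> float:
        return 1.0 / self.dt


@dataclass(frozen=True)
class EpochAverage:
    """Pointwise mean of peak-aligned epochs with a 95% confidence band."""

    epoch_time_s: np.ndarray
    mean_signal: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    epoch_count: int
    dropped_count: int = 0


@dataclass(frozen=True)
class MinimaCatalog:
    """Absolute-time minima records feeding breakpoint proposal."""

    absolute_time_s: np.ndarray
    amplitude: np.ndarray
    epoch_relative_time_s: np.ndarray  # provenance: epoch-relative origin

    def __len__(self) -> int:
        return self.absolute_time_s.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"absolute_time": self.absolute_time_s, "amplitude": self.amplitude}
        )

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "MinimaCatalog":
        t = df["absolute_time"].to_numpy(float)
        return cls(
            absolute_time_s=t,
            amplitude=df["amplitude"].to_numpy(float),
            epoch_relative_time_s=np.full_like(t, np.nan),
        )


def compute_envelope(
    time_s: np.ndarray,
    processed: np.ndarray,
    trim_s: float = 0.5,
    band: tuple[float, float] = (0.5, 10.0),
    filter_order: int = 4,
) -> EnvelopeResult:
    """Rate of change, Hilbert envelope and zero-phase band-passed envelope.

    ``trim_s`` seconds are discarded at both ends to mitigate filter and
    Hilbert edge effects.  The envelope is normalized to a maximum of 1
    before smoothing.
    """
    t = np.asarray(time_s, float)
    x = np.asarray(processed, float)
    dt = t[1] - t[0]
    fs = 1.0 / dt
    if trim_s < 0:
        raise ValueError("trim_s must be >= 0")
    if 2.0 * trim_s >= t[-1] - t[0]:
        raise ValueError("trim_s too large: nothing left after trimming")
    lo, hi = band
    if not 0.0 < lo < hi < fs / 2.0:
        raise ValueError(f"band {band} must satisfy 0 < low < high < Nyquist")

    n_trim = int(round(trim_s * fs))
    sl = slice(n_trim, t.size - n_trim if n_trim else None)
    t, x = t[sl], x[sl]

    rate = np.gradient(x, dt)          # central differences, one-sided at ends
    env = np.abs(signal.hilbert(rate))
    peak = env.max()
    if peak > 0:
        env = env / peak
    sos = signal.butter(filter_order, (lo, hi), btype="bandpass", fs=fs,
                        output="sos")
    smoothed = signal.sosfiltfilt(sos, env)
    return EnvelopeResult(
        time_s=t, rate_of_change=rate, envelope=env, smoothed_envelope=smoothed
    )


def detect_envelope_peaks(
    env: EnvelopeResult,
    min_height: float = 0.3,
    min_distance_s: float = 0.5,
) -> np.ndarray:
    """Times of smoothed-envelope peaks above ``min_height``.

    Peaks closer than ``min_distance_s`` are resolved greedily by
    descending height (the scipy distance rule).  Returns an empty array
    when nothing qualifies.
    """
    if min_distance_s <= 0:
        raise ValueError("min_distance_s must be > 0")
    distance = max(1, int(round(min_distance_s * env.sampling_rate_hz)))
    idx, _ = signal.find_peaks(env.smoothed_envelope, height=min_height,
                               distance=distance)
    return env.time_s[idx]


def epoch_average(
    time_s: np.ndarray,
    values: np.ndarray,
    peak_times: np.ndarray,
    window: tuple[float, float] = (-0.2, 1.0),
) -> EpochAverage:
    """Average peak-aligned epochs of a signal; 95% CI = mean +/- 1.96 SE.

    Peaks whose window would exceed the signal bounds are dropped and
    counted in ``dropped_count``.  Raises if no usable epoch remains.
    """
    t = np.asarray(time_s, float)
    x = np.asarray(values, float)
    pre_s, post_s = window
    if post_s <= pre_s:
        raise ValueError("epoch window must have post > pre")
    dt = t[1] - t[0]
    fs = 1.0 / dt
    i_pre = int(round(pre_s * fs))
    i_post = int(round(post_s * fs))
    rel_idx = np.arange(i_pre, i_post + 1)

    epochs = []
    dropped = 0
    for pt in np.asarray(peak_times, float):
        center = int(round((pt - t[0]) * fs))
        lo, hi = center + i_pre, center + i_post
        if lo < 0 or hi >= t.size:
            dropped += 1
            continue
        epochs.append(x[lo:hi + 1])
    if not epochs:
        raise ValueError("no epoch fits inside the signal bounds")

    stack = np.vstack(epochs)
    k = stack.shape[0]
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1) if k > 1 else np.zeros_like(mean)
    half = 1.96 * sd / np.sqrt(k)
    return EpochAverage(
        epoch_time_s=rel_idx * dt,
        mean_signal=mean,
        ci_lower=mean - half,
        ci_upper=mean + half,
        epoch_count=k,
        dropped_count=dropped,
    )


def detect_epoch_minima(
    avg: EpochAverage,
    peak_times: np.ndarray,
    min_distance_s: float = 0.1,
    prominence_fraction: float = 0.05,
    smooth_cutoff_hz: float | None = None,
    drop_first: int = 0,
    drop_last: int = 0,
    out_path=None,
) -> MinimaCatalog:
    """Minima of the mean epoch, mapped to absolute time at every peak.

    Minima are peaks of the negated mean signal (same height/distance
    machinery as peak detection), with prominence at least
    ``prominence_fraction`` of the mean signal's range.  When
    ``smooth_cutoff_hz`` is given the mean epoch is first smoothed by a
    zero-phase low-pass — epoch averaging suppresses noise across beats,
    the low-pass suppresses what ripple remains within the beat without
    blurring brief dips the way trace-level band-passing would.  Each
    epoch-relative minimum time ``t_rel`` is emitted at ``peak_time +
    t_rel`` for every peak.  ``drop_first``/``drop_last`` remove
    leading/trailing catalog entries (the manual-cleanup knob for minima
    with no interferometric counterpart in slow diastolic regions).
    """
    mean = avg.mean_signal
    dt = avg.epoch_time_s[1] - avg.epoch_time_s[0]
    if smooth_cutoff_hz is not None and mean.size > 100:
        sos = signal.butter(4, smooth_cutoff_hz, btype="lowpass", fs=1.0 / dt,
                            output="sos")
        mean = signal.sosfiltfilt(sos, mean)
    rng_ = float(mean.max() - mean.min())
    distance = max(1, int(round(min_distance_s / dt)))
    idx, _ = signal.find_peaks(
        -mean, distance=distance,
        prominence=prominence_fraction * rng_ if rng_ > 0 else None,
    )
    rel_times = avg.epoch_time_s[idx]
    rel_amps = mean[idx]

    abs_t, amps, provenance = [], [], []
    for pt in np.asarray(peak_times, float):
        abs_t.extend(pt + rel_times)
        amps.extend(rel_amps)
        provenance.extend(rel_times)
    order = np.argsort(abs_t)
    abs_t = np.asarray(abs_t, float)[order]
    amps = np.asarray(amps, float)[order]
    provenance = np.asarray(provenance, float)[order]

    # Adjacent windows overlap (window spans more than one cycle), so the
    # same physical minimum can be emitted twice; merge near-duplicates.
    if abs_t.size:
        keep = np.concatenate([[True], np.diff(abs_t) > min_distance_s])
        abs_t, amps, provenance = abs_t[keep], amps[keep], provenance[keep]

    sl = slice(drop_first, abs_t.size - drop_last if drop_last else None)
    catalog = MinimaCatalog(
        absolute_time_s=abs_t[sl],
        amplitude=amps[sl],
        epoch_relative_time_s=provenance[sl],
    )
    if out_path is not None:
        catalog.write_csv(out_path)
    return catalog
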