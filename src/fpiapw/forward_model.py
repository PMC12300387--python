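"""Synthetic arterial pulse waveforms and their interferometric rendering.

This module is the ground-truth generator for the whole pipeline.  It
produces (a) a quasi-periodic arterial pulse displacement profile dz(t)
with the four named morphological events of a radial-artery pulse
(systole start, systolic peak, dicrotic notch, diastole end) and (b) the
interference intensity that a low-finesse Fabry-Perot sensor would record
for that displacement, via the two-beam cosine law.

The per-cycle displacement shape is a piecewise C1 analytic form built
from raised-cosine segments:

* systolic upstroke  (0 -> peak)          sin^2 rise,
* systolic decline   (peak -> notch)      cos^2 fall,
* dicrotic rebound   (notch -> 2nd peak)  sin^2 rise scaled by notch depth,
* diastolic decay    (2nd peak -> 0)      Gaussian-damped cos^2 fall.

Every cycle starts and ends exactly at baseline displacement 0 with zero
slope, so concatenated cycles are C1.  Beat-to-beat variability is
emulated by Gaussian jitter of the individual cycle durations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .optics import OpticalConfig
from .preprocess import InterferogramTrace

__all__ = [
    "APWTemplate",
    "DisplacementProfile",
    "SyntheticRecording",
    "make_apw",
    "render_interferogram",
    "synthesize_recording",
]

# Fixed morphology constants of the template (fractions of normalized height
# / cycle length).  These shape the waveform between the named events and are
# not exposed as template parameters.
_NOTCH_BASE_LEVEL = 0.45       # level entering the notch, at zero depth
_NOTCH_LEVEL_DROP = 0.15       # how much a full-depth notch lowers that level
_REBOUND_GAIN = 0.35           # rebound height per unit notch depth
_REBOUND_WIDTH_FRACTION = 0.15  # notch -> rebound-peak duration / cycle


@dataclass(frozen=True)
class APWTemplate:
    """Parametric ground-truth arterial pulse displacement profile.

    Parameters
    ----------
    heart_rate_hz:
        Mean beat frequency [Hz].
    peak_amplitude_um:
        Systolic peak displacement [um]; radial-artery recordings show
        15-20 um, default 17.5.
    systolic_fraction:
        Time of the systolic peak as a fraction of the cycle, in (0, 1).
    dicrotic_notch_depth:
        Relative prominence of the dicrotic notch in [0, 1); 0 removes the
        notch (monotone decline after the systolic peak).
    dicrotic_notch_time_fraction:
        Time of the notch as a fraction of the cycle, in (0, 1).
    diastolic_decay_rate:
        Gaussian decay rate of the diastolic tail [1/s].
    cycle_jitter_sd_s:
        Standard deviation of beat-to-beat cycle-length jitter [s].
    n_cycles:
        Number of cardiac cycles to generate.
    """

    heart_rate_hz: float = 1.0
    peak_amplitude_um: float = 17.5
    systolic_fraction: float = 0.15
    dicrotic_notch_depth: float = 0.5
    dicrotic_notch_time_fraction: float = 0.40
    diastolic_decay_rate: float = 2.0
    cycle_jitter_sd_s: float = 0.02
    n_cycles: int = 10

    def __post_init__(self) -> None:
        if self.heart_rate_hz <= 0:
            raise ValueError("heart_rate_hz must be > 0")
        if self.peak_amplitude_um <= 0:
            raise ValueError("peak_amplitude_um must be > 0")
        if not 0.0 < self.systolic_fraction < 1.0:
            raise ValueError("systolic_fraction must be in (0, 1)")
        if not 0.0 <= self.dicrotic_notch_depth < 1.0:
            raise ValueError("dicrotic_notch_depth must be in [0, 1)")
        if not 0.0 < self.dicrotic_notch_time_fraction < 1.0:
            raise ValueError("dicrotic_notch_time_fraction must be in (0, 1)")
        if self.diastolic_decay_rate <= 0:
            raise ValueError("diastolic_decay_rate must be > 0")
        if self.cycle_jitter_sd_s < 0:
            raise ValueError("cycle_jitter_sd_s must be >= 0")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        rebound_end = self.dicrotic_notch_time_fraction + _REBOUND_WIDTH_FRACTION
        if not self.systolic_fraction < self.dicrotic_notch_time_fraction:
            raise ValueError("systolic peak must precede the dicrotic notch")
        if rebound_end >= 1.0:
            raise ValueError(
                "dicrotic_notch_time_fraction too late: rebound would spill "
                "past the end of the cycle"
            )

    # -- per-cycle shape ---------------------------------------------------
    def cycle_shape(self, tau: np.ndarray, cycle_duration_s: float) -> np.ndarray:
        """Normalized displacement (0..1) at cycle phase ``tau`` in [0, 1]."""
        tau = np.asarray(tau, dtype=float)
        tp = self.systolic_fraction
        tn = self.dicrotic_notch_time_fraction
        tr = tn + _REBOUND_WIDTH_FRACTION
        d = self.dicrotic_notch_depth
        v_n = _NOTCH_BASE_LEVEL - _NOTCH_LEVEL_DROP * d
        v_r = v_n + _REBOUND_GAIN * d

        out = np.zeros_like(tau)

        m1 = tau < tp
        out[m1] = np.sin(np.pi * tau[m1] / (2.0 * tp)) ** 2

        m2 = (tau >= tp) & (tau < tn)
        u = (tau[m2] - tp) / (tn - tp)
        out[m2] = v_n + (1.0 - v_n) * np.cos(np.pi * u / 2.0) ** 2

        m3 = (tau >= tn) & (tau < tr)
        u = (tau[m3] - tn) / (tr - tn)
        out[m3] = v_n + (v_r - v_n) * np.sin(np.pi * u / 2.0) ** 2

        m4 = tau >= tr
        u = tau[m4] - tr
        damp = np.exp(
            -self.diastolic_decay_rate * cycle_duration_s * u**2 / (1.0 - tr)
        )
        out[m4] = v_r * damp * np.cos(np.pi * u / (2.0 * (1.0 - tr))) ** 2
        return out

    def max_slope_nm_per_s(self) -> float:
        """Upper bound on |d dz/dt| [nm/s], used for the Nyquist check."""
        amp_nm = self.peak_amplitude_um * 1e3
        period = 1.0 / self.heart_rate_hz
        tp = self.systolic_fraction
        tn = self.dicrotic_notch_time_fraction
        v_n = _NOTCH_BASE_LEVEL - _NOTCH_LEVEL_DROP * self.dicrotic_notch_depth
        up = np.pi / (2.0 * tp)                     # upstroke, full height
        down = (1.0 - v_n) * np.pi / (2.0 * (tn - tp))
        return amp_nm * max(up, down) / period


@dataclass(frozen=True)
class DisplacementProfile:
    """Uniformly sampled cavity-length change dz(t) [nm]."""

    time_s: np.ndarray
    delta_z_nm: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.time_s, dtype=float)
        z = np.asarray(self.delta_z_nm, dtype=float)
        if t.ndim != 1 or t.shape != z.shape or t.size < 2:
            raise ValueError("time_s and delta_z_nm must be equal-length 1-D arrays")
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise ValueError("time_s must be strictly increasing")
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=0.0):
            raise ValueError("time_s must be uniformly spaced")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(z))):
            raise ValueError("profile contains non-finite values")
        object.__setattr__(self, "time_s", t)
        object.__setattr__(self, "delta_z_nm", z)

    @property
    def sampling_rate_hz(self) -> float:
        return 1.0 / (self.time_s[1] - self.time_s[0])


@dataclass(frozen=True)
class SyntheticRecording:
    """Rendered interferogram together with its ground truth."""

    trace: InterferogramTrace
    ground_truth: DisplacementProfile
    truth_events: list = field(default_factory=list)  # (time_s, label)
    noise_sd: float = 0.0
    seed: int = 0

    def events(self, label: str) -> np.ndarray:
        """Times of all ground-truth events with the given label."""
        return np.array([t for t, lab in self.truth_events if lab == label])


def make_apw(
    template: APWTemplate,
    sampling_rate_hz: float,
    seed: int = 0,
) -> tuple[DisplacementProfile, list]:
    """Generate a ground-truth displacement profile and its event list.

    Returns the profile and a list of ``(time_s, label)`` tuples with labels
    ``systole_start``, ``systolic_peak``, ``dicrotic_notch``, ``diastole_end``.
    A notch event is emitted only when ``dicrotic_notch_depth > 0``.
    """
    if sampling_rate_hz < 100:
        raise ValueError("sampling_rate_hz must be >= 100 to resolve fringes")
    # Fringe-resolution guard: the fastest expected interference carrier is
    # max|d dz/dt| / (2 * halfwave quantum); it must stay below Nyquist.
    quantum = OpticalConfig().halfwave_quantum_nm
    carrier_hz = template.max_slope_nm_per_s() / (2.0 * quantum)
    if carrier_hz >= sampling_rate_hz / 2.0:
        raise ValueError(
            f"sampling rate {sampling_rate_hz} Hz too low: expected fringe "
            f"carrier {carrier_hz:.0f} Hz exceeds Nyquist"
        )

    rng = np.random.default_rng(seed)
    period = 1.0 / template.heart_rate_hz
    durations = period + rng.normal(0.0, template.cycle_jitter_sd_s, template.n_cycles)
    durations = np.clip(durations, 0.5 * period, 1.5 * period)
    if template.cycle_jitter_sd_s == 0.0:
        durations = np.full(template.n_cycles, period)
    starts = np.concatenate([[0.0], np.cumsum(durations)])
    total = starts[-1]

    n = int(round(total * sampling_rate_hz))
    t = np.arange(n) / sampling_rate_hz
    # Assign each sample to its cycle, then evaluate the per-cycle shape.
    cycle_idx = np.clip(np.searchsorted(starts, t, side="right") - 1, 0,
                        template.n_cycles - 1)
    dz = np.empty(n)
    amp_nm = template.peak_amplitude_um * 1e3
    for k in range(template.n_cycles):
        sel = cycle_idx == k
        tau = (t[sel] - starts[k]) / durations[k]
        dz[sel] = amp_nm * template.cycle_shape(np.clip(tau, 0.0, 1.0),
                                                durations[k])

    events: list = []
    for k in range(template.n_cycles):
        t0, dur = starts[k], durations[k]
        events.append((t0, "systole_start"))
        events.append((t0 + template.systolic_fraction * dur, "systolic_peak"))
        if template.dicrotic_notch_depth > 0:
            events.append(
                (t0 + template.dicrotic_notch_time_fraction * dur, "dicrotic_notch")
            )
        events.append((t0 + dur, "diastole_end"))
    events.sort(key=lambda e: e[0])

    return DisplacementProfile(time_s=t, delta_z_nm=dz), events


def render_interferogram(
    profile: DisplacementProfile,
    optics: OpticalConfig | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    sign: int = -1,
    truth_events: list | None = None,
) -> SyntheticRecording:
    """Render a displacement profile into interference intensity.

    Implements the two-beam law
    ``I(t) = I1 + I2 + 2 sqrt(I1 I2) cos(4 pi n / lambda (z + sign*dz) + pi)``
    with additive white Gaussian noise of standard deviation ``noise_sd``.
    ``sign = -1`` (default) encodes that systole shortens the cavity.
    """
    optics = optics or OpticalConfig()
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if sign not in (-1, 1):
        raise ValueError("sign must be +1 or -1")
    carrier_hz = np.max(np.abs(np.gradient(profile.delta_z_nm, profile.time_s))) / (
        2.0 * optics.halfwave_quantum_nm
    )
    if carrier_hz >= profile.sampling_rate_hz / 2.0:
        raise ValueError(
            f"fringe carrier {carrier_hz:.0f} Hz exceeds Nyquist for this profile"
        )

    i1 = optics.intensity_fiber
    i2 = optics.intensity_membrane
    phase = (
        4.0 * np.pi * optics.refractive_index / optics.wavelength_nm
    ) * (optics.static_cavity_length_nm + sign * profile.delta_z_nm) + np.pi
    intensity = i1 + i2 + optics.fringe_amplitude * np.cos(phase)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        intensity = intensity + rng.normal(0.0, noise_sd, intensity.size)

    trace = InterferogramTrace(time_s=profile.time_s.copy(), intensity=intensity)
    return SyntheticRecording(
        trace=trace,
        ground_truth=profile,
        truth_events=list(truth_events or []),
        noise_sd=noise_sd,
        seed=seed,
    )


def synthesize_recording(
    template: APWTemplate,
    optics: OpticalConfig | None = None,
    sampling_rate_hz: float = 10_000.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    sign: int = -1,
) -> SyntheticRecording:
    """Convenience: ``make_apw`` followed by ``render_interferogram``.

    The same seed drives both the cycle-length jitter and the sensor noise,
    so identical arguments give bit-identical recordings.
    """
    profile, events = make_apw(template, sampling_rate_hz, seed=seed)
    return render_interferogram(
        profile, optics, noise_sd=noise_sd, seed=seed, sign=sign,
        truth_events=events,
    )


# -- CSV output ------------------------------------------------------------

def write_recording_csv(rec: SyntheticRecording, path, truth_path=None,
                        events_path=None) -> None:
    """Write ``time,intensity`` (and optionally ground truth / events) CSVs."""
    pd.DataFrame(
        {"time": rec.trace.time_s, "intensity": rec.trace.intensity}
    ).to_csv(path, index=False)
    if truth_path is not None:
        pd.DataFrame(
            {"time": rec.ground_truth.time_s,
             "delta_z_nm": rec.ground_truth.delta_z_nm}
        ).to_csv(truth_path, index=False)
    if events_path is not None:
        pd.DataFrame(rec.truth_events, columns=["time", "label"]).to_csv(
            events_path, index=False
        )
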