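"""Raw-recording validation, outlier repair, drift removal, normalization.

The preprocessing stage turns a raw two-column (time, intensity) recording
into a drift-free trace normalized segment-wise to [0, 1]:

1. structural validation (numeric data, uniform time step),
2. z-score outlier repair by linear interpolation with edge fill,
3. zero-phase fourth-order Butterworth high-pass (0.5 Hz default),
4. per-segment (1 s default) min-max normalization.

Zero-phase (forward-backward) filtering is used throughout the package:
the downstream timing claims are at the millisecond level, which rules out
the group delay of a single-pass recursive filter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "InterferogramTrace",
    "PreprocessConfig",
    "PreprocessedTrace",
    "validate_input",
    "repair_outliers",
    "highpass_filter",
    "segment_normalize",
    "run_preprocess",
]

_DT_RTOL = 1e-6  # relative tolerance on time-step uniformity


@dataclass(frozen=True)
class InterferogramTrace:
    """Uniformly sampled (time, intensity) series."""

    time_s: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.time_s, dtype=float)
        x = np.asarray(self.intensity, dtype=float)
        if t.ndim != 1 or t.shape != x.shape or t.size < 2:
            raise ValueError("time_s and intensity must be equal-length 1-D "
                             "arrays with at least 2 samples")
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise ValueError("time_s must be strictly increasing")
        bad = np.flatnonzero(np.abs(dt - dt[0]) > _DT_RTOL * abs(dt[0]))
        if bad.size:
            raise ValueError(
                f"non-uniform time step: first offending index {bad[0] + 1}"
            )
        object.__setattr__(self, "time_s", t)
        object.__setattr__(self, "intensity", x)

    @property
    def dt(self) -> float:
        return float(self.time_s[1] - self.time_s[0])

    @property
    def sampling_rate_hz(self) -> float:
        return 1.0 / self.dt

    @property
    def duration_s(self) -> float:
        return float(self.time_s[-1] - self.time_s[0])

    def replace(self, intensity: np.ndarray) -> "InterferogramTrace":
        return InterferogramTrace(time_s=self.time_s, intensity=intensity)


@dataclass(frozen=True)
class PreprocessConfig:
    """Parameters of the preprocessing stage."""

    zscore_threshold: float = 3.0
    highpass_cutoff_hz: float = 0.5
    filter_order: int = 4
    segment_length_s: float = 1.0

    def __post_init__(self) -> None:
        if self.zscore_threshold <= 0:
            raise ValueError("zscore_threshold must be > 0")
        if self.highpass_cutoff_hz <= 0:
            raise ValueError("highpass_cutoff_hz must be > 0")
        if self.filter_order < 1:
            raise ValueError("filter_order must be >= 1")
        if self.segment_length_s <= 0:
            raise ValueError("segment_length_s must be > 0")


@dataclass(frozen=True)
class PreprocessedTrace:
    """Raw trace alongside its fully processed version (shared time axis)."""

    time_s: np.ndarray
    raw: np.ndarray
    processed: np.ndarray
    outlier_indices: np.ndarray
    config: PreprocessConfig

    @property
    def dt(self) -> float:
        return float(self.time_s[1] - self.time_s[0])

    @property
    def sampling_rate_hz(self) -> float:
        return 1.0 / self.dt

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.time_s, "raw": self.raw, "processed": self.processed}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame,
                   config: PreprocessConfig | None = None) -> "PreprocessedTrace":
        return cls(
            time_s=df["time"].to_numpy(float),
            raw=df["raw"].to_numpy(float),
            processed=df["processed"].to_numpy(float),
            outlier_indices=np.array([], dtype=int),
            config=config or PreprocessConfig(),
        )


def validate_input(raw_table) -> InterferogramTrace:
    """Validate a raw two-column table and return a verified trace.

    Accepts anything ``pandas.DataFrame`` accepts (a DataFrame, a dict of
    columns, a 2-D array); the first column is time [s], the second
    intensity [a.u.].  Raises ``ValueError`` naming the offending row on
    non-numeric cells or a broken time grid.
    """
    df = pd.DataFrame(raw_table)
    if df.shape[0] == 0:
        raise ValueError("input table is empty")
    if df.shape[1] < 2:
        raise ValueError("input table needs at least 2 columns (time, intensity)")
    cols = df.iloc[:, :2]
    numeric = cols.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & ~cols.isna()
    if bad.to_numpy().any():
        row = int(np.flatnonzero(bad.any(axis=1).to_numpy())[0])
        raise ValueError(f"non-numeric value in row {row}")
    if numeric.isna().to_numpy().any():
        row = int(np.flatnonzero(numeric.isna().any(axis=1).to_numpy())[0])
        raise ValueError(f"missing value in row {row}")
    return InterferogramTrace(
        time_s=numeric.iloc[:, 0].to_numpy(float),
        intensity=numeric.iloc[:, 1].to_numpy(float),
    )


def repair_outliers(
    trace: InterferogramTrace, zscore_threshold: float = 3.0
) -> tuple[InterferogramTrace, np.ndarray]:
    """Replace z-score outliers by interpolation between valid neighbors.

    Samples with ``|x - mean| / sd > threshold`` (global mean/sd) are
    replaced by linear interpolation between the nearest non-outlier
    samples; leading/trailing outliers take the nearest valid value.
    A constant trace (sd = 0) has no outliers by convention.
    """
    x = trace.intensity
    sd = float(np.std(x))
    if sd == 0.0:
        return trace, np.array([], dtype=int)
    z = np.abs(x - np.mean(x)) / sd
    out = z > zscore_threshold
    idx = np.flatnonzero(out)
    if idx.size == 0:
        return trace, idx
    if idx.size == x.size:
        raise ValueError("all samples flagged as outliers; signal unusable")
    good = ~out
    repaired = x.copy()
    repaired[out] = np.interp(
        trace.time_s[out], trace.time_s[good], x[good]
    )  # np.interp clamps at the ends -> forward/backward fill behavior
    return trace.replace(repaired), idx


def highpass_filter(
    trace: InterferogramTrace, cutoff_hz: float = 0.5, order: int = 4
) -> InterferogramTrace:
    """Zero-phase Butterworth high-pass (applied forward and backward)."""
    nyq = trace.sampling_rate_hz / 2.0
    if not 0 < cutoff_hz < nyq:
        raise ValueError(
            f"cutoff {cutoff_hz} Hz must lie in (0, Nyquist={nyq:.6g} Hz)"
        )
    sos = signal.butter(order, cutoff_hz, btype="highpass",
                        fs=trace.sampling_rate_hz, output="sos")
    return trace.replace(signal.sosfiltfilt(sos, trace.intensity))


def segment_normalize(
    trace: InterferogramTrace, segment_length_s: float = 1.0
) -> InterferogramTrace:
    """Per-segment min-max normalization to [0, 1].

    Segments are half-open intervals ``[k*L, (k+1)*L)`` from the start of
    the trace; the final partial segment is normalized over its own extent.
    A degenerate (constant) segment maps to 0.5.
    """
    if segment_length_s <= 0:
        raise ValueError("segment_length_s must be > 0")
    x = trace.intensity.copy()
    seg_len = max(1, int(round(segment_length_s * trace.sampling_rate_hz)))
    for start in range(0, x.size, seg_len):
        seg = x[start:start + seg_len]
        lo, hi = seg.min(), seg.max()
        if hi > lo:
            x[start:start + seg_len] = (seg - lo) / (hi - lo)
        else:
            x[start:start + seg_len] = 0.5
    return trace.replace(x)


def run_preprocess(
    raw_table, config: PreprocessConfig | None = None, out_path=None
) -> PreprocessedTrace:
    """Full preprocessing chain; optionally writes ``preprocessed.csv``.

    Output CSV columns: ``time, raw, processed`` with processed in [0, 1].
    """
    config = config or PreprocessConfig()
    trace = validate_input(raw_table)
    repaired, outlier_idx = repair_outliers(trace, config.zscore_threshold)
    filtered = highpass_filter(repaired, config.highpass_cutoff_hz,
                               config.filter_order)
    normalized = segment_normalize(filtered, config.segment_length_s)
    result = PreprocessedTrace(
        time_s=trace.time_s,
        raw=trace.intensity,
        processed=normalized.intensity,
        outlier_indices=outlier_idx,
        config=config,
    )
    if out_path is not None:
        result.to_frame().to_csv(out_path, index=False)
    return result
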