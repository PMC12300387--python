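"""Halfwave counting and cubic-spline displacement reconstruction.

Between successive interference extrema the cavity length changes by one
halfwave quantum lambda/(4n) (~386.7 nm for a 1551.3 nm laser in air with
n = 1.003).  Given an annotated fringe sequence, the integer halfwave
number m starts at 1 at the first extremum after the first breakpoint
(systole onset), increases by 1 per extremum until a breakpoint is
reached, then decreases by 1 until the next breakpoint, and so on.  Each
extremum therefore anchors the displacement at dz = m * lambda/(4n); a
cubic spline through the anchors gives the smooth arterial pulse
displacement curve, and breakpoint displacements are read off the spline
(a reversal sits between two grid levels and carries no integer quantum of
its own).

The absolute sign and offset of dz are not recoverable from a
single-wavelength interferogram; the reconstruction reports displacement
magnitude from the diastolic baseline, systole up.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .annotation import AnnotationSet
from .optics import OpticalConfig
from .preprocess import PreprocessedTrace

__all__ = [
    "HalfwaveAssignment",
    "DisplacementTrace",
    "halfwave_quantum",
    "assign_halfwave",
    "delta_z_at_anchors",
    "reconstruct_displacement",
    "demodulate",
]


@dataclass(frozen=True)
class HalfwaveAssignment:
    """Integer halfwave number per labeled point (breakpoints carry none)."""

    anchor_times_s: np.ndarray    # extrema after the first BP
    anchor_m: np.ndarray          # integer halfwave numbers, m >= 0
    anchor_status: list           # 'MAX'/'MIN' per anchor
    breakpoint_times_s: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.anchor_m)
        if m.size and np.any(np.abs(np.diff(m)) != 1):
            raise ValueError("consecutive anchors must differ by exactly 1")


@dataclass(frozen=True)
class DisplacementTrace:
    """Reconstructed arterial pulse displacement on the trace time grid."""

    time_s: np.ndarray
    m: np.ndarray                 # piecewise-constant halfwave number
    delta_z_nm: np.ndarray        # spline displacement [nm]
    intensity: np.ndarray         # processed intensity (I2_t column)
    anchor_times_s: np.ndarray
    anchor_delta_z_nm: np.ndarray
    breakpoint_times_s: np.ndarray
    breakpoint_delta_z_nm: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.time_s, "m": self.m, "delta_z": self.delta_z_nm,
             "I2_t": self.intensity}
        )

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def halfwave_quantum(optics: OpticalConfig) -> float:
    """Cavity-length change between successive extrema, lambda/(4n) [nm]."""
    return optics.halfwave_quantum_nm


def assign_halfwave(annotations: AnnotationSet) -> HalfwaveAssignment:
    """Assign integer halfwave numbers to the extrema after the first BP.

    The first extremum after the first breakpoint gets m = 1; each
    subsequent extremum gets the previous m plus the current direction;
    the direction starts at +1 and negates at every breakpoint.  Points
    before the first breakpoint are excluded.

    m = 0 is legitimate only for the last fringe crossing before a
    breakpoint: the displacement touches the diastolic baseline (dz = 0)
    right before the motion reverses at the start of the next systole.
    m reaching 0 anywhere else — or going negative — indicates a missed
    or spurious breakpoint and raises ``ValueError``.
    """
    statuses = annotations.statuses()
    if "BP" not in statuses:
        raise ValueError("annotation set contains no breakpoint")
    first_bp = statuses.index("BP")
    pts = annotations.points[first_bp:]

    times, ms, stats, bp_times = [], [], [], []
    direction = 1
    m = 0
    for k, p in enumerate(pts):
        if p.status == "BP":
            bp_times.append(p.time_s)
            if times:  # direction flips at every BP after the first
                direction = -direction
            continue
        m += direction
        next_is_bp = k + 1 < len(pts) and pts[k + 1].status == "BP"
        if m < 0 or (m == 0 and not next_is_bp):
            raise ValueError(
                f"halfwave number reached {m} at t={p.time_s:.4f} s away "
                "from a baseline breakpoint: inconsistent annotation "
                "(missed or spurious breakpoint)"
            )
        times.append(p.time_s)
        ms.append(m)
        stats.append(p.status)
    return HalfwaveAssignment(
        anchor_times_s=np.asarray(times, float),
        anchor_m=np.asarray(ms, int),
        anchor_status=stats,
        breakpoint_times_s=np.asarray(bp_times, float),
    )


def delta_z_at_anchors(
    assignment: HalfwaveAssignment, optics: OpticalConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Anchor displacements dz = m * lambda/(4n) [nm]."""
    return (
        assignment.anchor_times_s,
        assignment.anchor_m * halfwave_quantum(optics),
    )


def reconstruct_displacement(
    anchor_times_s: np.ndarray,
    anchor_delta_z_nm: np.ndarray,
    breakpoint_times_s: np.ndarray,
    time_grid_s: np.ndarray,
    anchor_m: np.ndarray | None = None,
    intensity: np.ndarray | None = None,
) -> DisplacementTrace:
    """Cubic spline through the anchors, evaluated on the time grid.

    Breakpoint displacements are the spline values at the breakpoint
    times.  Grid points outside the anchored span are excluded (no
    extrapolation).  Requires at least 4 strictly time-increasing anchors.
    """
    t_a = np.asarray(anchor_times_s, float)
    z_a = np.asarray(anchor_delta_z_nm, float)
    if t_a.size < 4:
        raise ValueError(f"need at least 4 anchors for a cubic spline, got {t_a.size}")
    if np.any(np.diff(t_a) <= 0):
        raise ValueError("anchor times must be strictly increasing")

    spline = CubicSpline(t_a, z_a, bc_type="not-a-knot")
    grid = np.asarray(time_grid_s, float)
    inside = (grid >= t_a[0]) & (grid <= t_a[-1])
    t = grid[inside]
    dz = spline(t)

    bp_t = np.asarray(breakpoint_times_s, float)
    bp_in = bp_t[(bp_t >= t_a[0]) & (bp_t <= t_a[-1])]
    bp_z = spline(bp_in)

    if anchor_m is None:
        anchor_m = np.arange(1, t_a.size + 1)
    # per-sample m: the last anchor's halfwave number (piecewise constant)
    pos = np.clip(np.searchsorted(t_a, t, side="right") - 1, 0, t_a.size - 1)
    m_grid = np.asarray(anchor_m)[pos]

    if intensity is None:
        intensity_in = np.full(t.size, np.nan)
    else:
        intensity_in = np.asarray(intensity, float)[inside]

    return DisplacementTrace(
        time_s=t,
        m=m_grid,
        delta_z_nm=dz,
        intensity=intensity_in,
        anchor_times_s=t_a,
        anchor_delta_z_nm=z_a,
        breakpoint_times_s=bp_in,
        breakpoint_delta_z_nm=bp_z,
    )


def demodulate(
    preprocessed: PreprocessedTrace,
    annotations: AnnotationSet,
    optics: OpticalConfig | None = None,
    out_path=None,
) -> DisplacementTrace:
    """Full demodulation: halfwave assignment -> anchors -> spline curve.

    The ``I2_t`` output column carries the processed intensity sample.
    Annotation times must lie on the preprocessed trace's time axis.
    """
    optics = optics or OpticalConfig()
    t = preprocessed.time_s
    for p in annotations.points:
        i = int(np.argmin(np.abs(t - p.time_s)))
        if abs(t[i] - p.time_s) > 0.5 * preprocessed.dt:
            raise ValueError(
                f"annotation at t={p.time_s} does not lie on the trace time axis"
            )
    assignment = assign_halfwave(annotations)
    t_a, z_a = delta_z_at_anchors(assignment, optics)
    result = reconstruct_displacement(
        t_a, z_a, assignment.breakpoint_times_s, t,
        anchor_m=assignment.anchor_m, intensity=preprocessed.processed,
    )
    if out_path is not None:
        result.write_csv(out_path)
    return result
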