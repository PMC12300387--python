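"""Fringe extrema detection, breakpoint proposal, edits, validation.

Every local extremum of the interference intensity is either a *fringe
crossing* (the phase passed a multiple of pi, i.e. the cavity length
crossed a lambda/(4n) grid level) or a *breakpoint* (BP): a point where
the membrane motion reverses and the phase progression flips sign.  A
reversal is itself a critical point of I(t), so breakpoints are
constrained to coincide with detected extrema; free-floating BP times are
disallowed.

Labeling rules enforced here (and why):

* Consecutive extrema must alternate MAX/MIN; same-type neighbors are a
  detection artifact and the less prominent one is dropped.
* A breakpoint is chosen among the extrema near an envelope-minimum time,
  preferring a *shallow* extremum (value away from the 0/1 fringe rails):
  the reversal extremum generically stops short of the fringe envelope,
  while crossings touch it.
* After BP placement, if the two extrema flanking a BP share a type, the
  post-BP one is removed.  A reversal re-crosses the last grid level it
  passed, producing a redundant extremum at the same cavity length; with
  it removed, the halfwave counting rule (+1 per extremum, direction flip
  at each BP, BP itself uncounted) assigns the physically correct quantum
  to every anchor.

Physiological sanity rules (checked by ``validate_annotations``): each
analysis period begins with an extremum followed by a breakpoint, and
every cardiac cycle contains an even number of breakpoints.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "LabeledPoint",
    "AnnotationSet",
    "ValidationReport",
    "detect_extrema",
    "propose_breakpoints",
    "build_annotations",
    "apply_edits",
    "validate_annotations",
    "read_annotations_csv",
]

STATUSES = ("MAX", "MIN", "BP")


@dataclass(frozen=True)
class LabeledPoint:
    sample_index: int
    time_s: float
    value: float
    status: str
    prominence: float = float("nan")

    def __post_init__(self) -> None:
        if self.status not in STATUSES:
            raise ValueError(f"status must be one of {STATUSES}, got {self.status!r}")
        if self.sample_index < 0:
            raise ValueError("sample_index must be >= 0")


@dataclass(frozen=True)
class AnnotationSet:
    """Ordered labeled points on a trace, restricted to an analysis window."""

    points: tuple
    analysis_window: tuple
    audit_log: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        pts = tuple(sorted(self.points, key=lambda p: p.time_s))
        times = [p.time_s for p in pts]
        if len(set(times)) != len(times):
            raise ValueError("annotation times must be strictly increasing")
        lo, hi = self.analysis_window
        for p in pts:
            if not lo <= p.time_s <= hi:
                raise ValueError(
                    f"point at t={p.time_s} outside analysis window [{lo}, {hi}]"
                )
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return len(self.points)

    def statuses(self) -> list:
        return [p.status for p in self.points]

    def times(self, status: str | None = None) -> np.ndarray:
        return np.array(
            [p.time_s for p in self.points if status is None or p.status == status]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "index": [p.sample_index for p in self.points],
                "time": [p.time_s for p in self.points],
                "value": [p.value for p in self.points],
                "Status": [p.status for p in self.points],
            }
        )

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def read_annotations_csv(path, analysis_window=None) -> AnnotationSet:
    df = pd.read_csv(path, float_precision="round_trip")
    pts = [
        LabeledPoint(
            sample_index=int(r["index"]), time_s=float(r["time"]),
            value=float(r["value"]), status=str(r["Status"]),
        )
        for _, r in df.iterrows()
    ]
    if analysis_window is None:
        analysis_window = (df["time"].min(), df["time"].max())
    return AnnotationSet(points=tuple(pts), analysis_window=tuple(analysis_window))


# -- detection -------------------------------------------------------------

def _estimate_noise_floor(values: np.ndarray, window: int = 1000) -> float:
    """Additive-noise amplitude estimate from slow regions of the trace.

    The first difference suppresses the slowly varying displacement signal;
    in windows where the interference carrier is slow (near reversals) the
    residual difference is essentially the sensor noise.  The 10th
    percentile of windowed difference SDs, rescaled by sqrt(2), is a
    robust noise-floor estimate that is ~0 for clean signals.
    """
    d = np.diff(np.asarray(values, float))
    n_win = max(1, d.size // window)
    wsd = [np.std(d[k * window:(k + 1) * window]) for k in range(n_win)]
    return float(np.percentile(wsd, 10)) / np.sqrt(2.0)


def _turning_point_filter(pts: list, hysteresis: float) -> list:
    """Keep only turning points whose swing exceeds the hysteresis band.

    Standard robust fringe-counting device: an opposite-type extremum is
    accepted only if the signal moved at least ``hysteresis`` since the
    last accepted one; a same-type candidate replaces the last accepted
    point when it is more extreme.  Small noise wiggles are removed while
    full fringe swings survive.
    """
    if not pts:
        return pts
    kept = [pts[0]]
    for p in pts[1:]:
        last = kept[-1]
        if p.status == last.status:
            more_extreme = (
                p.value > last.value if p.status == "MAX" else p.value < last.value
            )
            if more_extreme:
                kept[-1] = p
        elif abs(p.value - last.value) >= hysteresis:
            kept.append(p)
    return kept


def detect_extrema(
    time_s: np.ndarray,
    values: np.ndarray,
    window: tuple | None = None,
    prominence: float = 0.05,
    hysteresis: float | None = None,
) -> list:
    """Detect alternating MAX/MIN fringe extrema within a time window.

    Detection runs ``scipy.signal.find_peaks`` on the signal and its
    negation with a prominence floor, then applies three consistency
    passes:

    1. opposite-type pairs closer than ~2.5 samples are dropped (step
       artifacts at segment-normalization boundaries);
    2. a hysteresis turning-point filter removes wiggles smaller than
       ``hysteresis`` (auto-estimated from the trace's noise floor when
       not given);
    3. alternation repair: of two same-type neighbors the more prominent
       one is kept.

    Raises ``ValueError`` when fewer than 2 extrema are found (no fringes).
    """
    t = np.asarray(time_s, float)
    x = np.asarray(values, float)
    if window is None:
        window = (t[0], t[-1])
    lo, hi = window
    sel = (t >= lo) & (t <= hi)
    offset = int(np.flatnonzero(sel)[0]) if sel.any() else 0
    tw, xw = t[sel], x[sel]
    if tw.size < 3:
        raise ValueError("analysis window too short for extrema detection")
    dt = tw[1] - tw[0]

    imax, pmax = signal.find_peaks(xw, prominence=prominence)
    imin, pmin = signal.find_peaks(-xw, prominence=prominence)
    pts = [
        LabeledPoint(offset + int(i), float(tw[i]), float(xw[i]), "MAX",
                     float(p))
        for i, p in zip(imax, pmax["prominences"])
    ] + [
        LabeledPoint(offset + int(i), float(tw[i]), float(xw[i]), "MIN",
                     float(p))
        for i, p in zip(imin, pmin["prominences"])
    ]
    pts.sort(key=lambda p: p.time_s)

    # (1) drop sample-adjacent opposite-type pairs (normalization steps)
    changed = True
    while changed:
        changed = False
        for i in range(len(pts) - 1):
            close = pts[i + 1].time_s - pts[i].time_s <= 2.5 * dt
            if close and pts[i].status != pts[i + 1].status:
                del pts[i:i + 2]
                changed = True
                break

    # (2) hysteresis turning-point filter
    if hysteresis is None:
        hysteresis = min(6.0 * _estimate_noise_floor(xw), 0.45)
    if hysteresis > 0:
        pts = _turning_point_filter(pts, hysteresis)

    # (3) alternation repair
    pts = _alternation_repair(pts)

    if len(pts) < 2:
        raise ValueError("fewer than 2 fringe extrema found in window")
    return pts


def _alternation_repair(pts: list) -> list:
    """Of two same-type neighbors keep the more prominent one."""
    pts = list(pts)
    changed = True
    while changed:
        changed = False
        for i in range(len(pts) - 1):
            if pts[i].status == pts[i + 1].status:
                drop = i if pts[i].prominence < pts[i + 1].prominence else i + 1
                del pts[drop]
                changed = True
                break
    return pts


def _shallowness(extrema: list, n_neighbors: int = 5) -> np.ndarray:
    """Per-extremum deviation from the local fringe rails, as a fraction.

    For each extremum, the local MAX and MIN rails are the medians of the
    values of the nearest ``n_neighbors`` same-type extrema on each side.
    A fringe crossing rides its rail; a reversal extremum stops short of
    it.  Returns |value - own rail| / local fringe range.
    """
    values = np.array([p.value for p in extrema])
    is_max = np.array([p.status == "MAX" for p in extrema])
    rails = np.empty(2, dtype=object)
    rail_of = np.empty(values.size)
    rng = np.empty(values.size)
    for kind in (True, False):
        idx = np.flatnonzero(is_max == kind)
        med = np.empty(idx.size)
        for j, i in enumerate(idx):
            lo = max(0, j - n_neighbors)
            window = np.delete(values[idx[lo:j + n_neighbors + 1]],
                               j - lo)
            med[j] = np.median(window) if window.size else values[i]
        rails[int(kind)] = dict(zip(idx, med))
    for i in range(values.size):
        rail_of[i] = rails[int(is_max[i])][i]
    # local range: distance between the two rails near each extremum
    max_rail = np.interp(
        np.arange(values.size),
        np.flatnonzero(is_max), [rails[1][i] for i in np.flatnonzero(is_max)],
    ) if is_max.any() else np.ones(values.size)
    min_rail = np.interp(
        np.arange(values.size),
        np.flatnonzero(~is_max), [rails[0][i] for i in np.flatnonzero(~is_max)],
    ) if (~is_max).any() else np.zeros(values.size)
    rng = np.maximum(max_rail - min_rail, 1e-12)
    return np.abs(values - rail_of) / rng


def propose_breakpoints(
    extrema: list,
    minima_catalog,
    search_radius_s: float = 0.15,
    shallow_fraction: float = 0.1,
) -> tuple[list, list]:
    """Select the extrema to relabel as breakpoints.

    For each catalog minimum the nearest fringe extremum within
    ``search_radius_s`` becomes a BP; among candidates, *shallow* extrema
    — those stopping short of the local fringe rails by more than
    ``shallow_fraction`` of the local fringe range, the signature of a
    motion-reversal extremum — take precedence over strictly nearer
    rail-touching crossings.  Catalog minima with no extremum in radius
    are skipped and returned as warnings.

    Returns ``(bp_points, warnings)`` where ``bp_points`` are the chosen
    extrema relabeled to status BP.
    """
    if search_radius_s < 0:
        raise ValueError("search_radius_s must be >= 0")
    times = np.array([p.time_s for p in extrema])
    depth = _shallowness(extrema)
    chosen: dict[int, LabeledPoint] = {}
    warnings: list = []
    for tmin in np.asarray(minima_catalog.absolute_time_s, float):
        dist = np.abs(times - tmin)
        in_radius = np.flatnonzero(dist <= search_radius_s)
        in_radius = np.array([i for i in in_radius if i not in chosen], dtype=int)
        if in_radius.size == 0:
            warnings.append(
                f"no fringe extremum within {search_radius_s} s of catalog "
                f"minimum at t={tmin:.4f} s; skipped"
            )
            continue
        shallow = [i for i in in_radius if depth[i] > shallow_fraction]
        pool = shallow if shallow else list(in_radius)
        best = min(pool, key=lambda i: dist[i])
        chosen[best] = replace(extrema[best], status="BP")
    bps = [chosen[i] for i in sorted(chosen)]
    return bps, warnings


def _merge_redundant_crossings(points: list) -> list:
    """Drop the post-BP flank extremum when both BP flanks share a type."""
    pts = list(points)
    changed = True
    while changed:
        changed = False
        for i, p in enumerate(pts):
            if p.status != "BP":
                continue
            prev_ext = next(
                (q for q in reversed(pts[:i]) if q.status != "BP"), None
            )
            nxt_pos = next(
                (j for j in range(i + 1, len(pts)) if pts[j].status != "BP"),
                None,
            )
            if prev_ext is None or nxt_pos is None:
                continue
            if prev_ext.status == pts[nxt_pos].status:
                del pts[nxt_pos]
                changed = True
                break
    return pts


def build_annotations(
    time_s: np.ndarray,
    values: np.ndarray,
    minima_catalog,
    window: tuple | None = None,
    prominence: float = 0.05,
    search_radius_s: float = 0.15,
    shallow_fraction: float = 0.1,
    artifact_shallow_threshold: float = 0.35,
    cycle_anchor_times: np.ndarray | None = None,
) -> tuple["AnnotationSet", list]:
    """Detect extrema, place breakpoints, and assemble a consistent set.

    The leading points are trimmed so the set starts with the extremum
    immediately preceding the starting breakpoint (each analysis period
    begins with an extremum followed by a breakpoint).  When
    ``cycle_anchor_times`` (typically the envelope-peak times, one per
    systolic upstroke) are given, the starting breakpoint is the one
    immediately preceding an upstroke — a systole-onset reversal, which is
    what the halfwave counting rule downstream assumes the first
    breakpoint to be.  Returns the set and any placement warnings.
    """
    t = np.asarray(time_s, float)
    if window is None:
        window = (float(t[0]), float(t[-1]))
    extrema = detect_extrema(t, values, window, prominence)
    if len(minima_catalog) == 0:
        raise ValueError("minima catalog is empty; cannot place breakpoints")

    # A markedly shallow extremum can only be a motion reversal, and
    # reversals occur only near envelope minima: shallow extrema far from
    # every catalog minimum are noise artifacts and are removed (together
    # with their now-redundant same-type neighbor via alternation repair).
    # The exemption radius is deliberately tighter than the breakpoint
    # search radius: wrongly removing a true reversal extremum merely
    # collapses its fringe trio into the merged-crossing case (handled
    # downstream), while keeping a noise pair corrupts the halfwave count.
    depth = _shallowness(extrema)
    cat_t = np.asarray(minima_catalog.absolute_time_s, float)
    keep = [
        p for p, d in zip(extrema, depth)
        if d <= artifact_shallow_threshold
        or np.min(np.abs(cat_t - p.time_s)) <= 0.5 * search_radius_s
    ]
    if len(keep) >= 2:
        extrema = _alternation_repair(keep)

    bps, warnings = propose_breakpoints(
        extrema, minima_catalog, search_radius_s, shallow_fraction
    )
    bp_times = {p.time_s for p in bps}
    merged = [p for p in extrema if p.time_s not in bp_times] + bps
    merged.sort(key=lambda p: p.time_s)
    merged = _merge_redundant_crossings(merged)

    start_bp = None
    if cycle_anchor_times is not None:
        bp_ts = np.array([p.time_s for p in merged if p.status == "BP"])
        for anchor in np.sort(np.asarray(cycle_anchor_times, float)):
            before = bp_ts[(bp_ts < anchor) & (bp_ts > anchor - 0.35)]
            if before.size:
                t_start = before.max()
                start_bp = next(
                    i for i, p in enumerate(merged)
                    if p.status == "BP" and p.time_s == t_start
                )
                break
    if start_bp is None:
        start_bp = next(
            (i for i, p in enumerate(merged) if p.status == "BP"), None
        )
    if start_bp is None:
        raise ValueError("no breakpoint could be placed")

    # trim so that points[0] is the extremum right before the starting BP
    merged = merged[start_bp - 1 if start_bp > 0 else start_bp:]
    while merged and merged[0].status == "BP":
        merged = merged[1:]
        if not any(p.status == "BP" for p in merged):
            raise ValueError("no breakpoint with a preceding extremum")
    return AnnotationSet(points=tuple(merged), analysis_window=window), warnings


# -- edits -----------------------------------------------------------------

def apply_edits(
    annotations: AnnotationSet,
    edits: list,
    time_s: np.ndarray | None = None,
    values: np.ndarray | None = None,
) -> AnnotationSet:
    """Apply a list of scriptable edit commands; returns a new set.

    Commands are dicts with an ``op`` key:

    * ``{"op": "add", "time": t, "status": s[, "value": v]}`` — value and
      sample index are resolved from the trace when given, else ``value``
      is required;
    * ``{"op": "remove", "index": k}`` — k-th point of the current set;
    * ``{"op": "relabel", "index": k, "status": s}``;
    * ``{"op": "move", "index": k, "time": t}``.

    Every command is recorded in the returned set's ``audit_log``.  This is
    the reproducible replacement for interactive (mouse/keyboard) editing.
    """
    pts = list(annotations.points)
    lo, hi = annotations.analysis_window
    log = list(annotations.audit_log)
    for cmd in edits:
        op = cmd.get("op")
        if op == "add":
            t_new = float(cmd["time"])
            if not lo <= t_new <= hi:
                raise ValueError(f"add at t={t_new} outside analysis window: {cmd}")
            if time_s is not None:
                idx = int(np.argmin(np.abs(np.asarray(time_s) - t_new)))
                val = float(values[idx]) if values is not None else float("nan")
            else:
                if "value" not in cmd:
                    raise ValueError(f"add without trace requires 'value': {cmd}")
                idx, val = 0, float(cmd["value"])
                idx = cmd.get("index", 0)
            pts.append(LabeledPoint(idx, t_new, val, cmd["status"]))
        elif op in ("remove", "relabel", "move"):
            k = cmd.get("index")
            if k is None or not 0 <= k < len(pts):
                raise ValueError(f"command references nonexistent point: {cmd}")
            if op == "remove":
                del pts[k]
            elif op == "relabel":
                pts[k] = replace(pts[k], status=cmd["status"])
            else:
                t_new = float(cmd["time"])
                if not lo <= t_new <= hi:
                    raise ValueError(
                        f"move to t={t_new} outside analysis window: {cmd}"
                    )
                pts[k] = replace(pts[k], time_s=t_new)
        else:
            raise ValueError(f"unknown edit op: {cmd}")
        log.append(dict(cmd))
        pts.sort(key=lambda p: p.time_s)
    return AnnotationSet(
        points=tuple(pts), analysis_window=annotations.analysis_window,
        audit_log=tuple(log),
    )


def load_edits(path) -> list:
    with open(path) as fh:
        return json.load(fh)


# -- validation ------------------------------------------------------------

@dataclass(frozen=True)
class ValidationReport:
    ordering_ok: bool
    cycles: list  # (start_s, end_s, bp_count, parity_ok)
    passed: bool

    def summary(self) -> str:
        lines = [f"ordering (extremum then BP): {'PASS' if self.ordering_ok else 'FAIL'}"]
        for start, end, nbp, ok in self.cycles:
            lines.append(
                f"cycle [{start:.3f}, {end:.3f}] s: {nbp} BPs, parity "
                f"{'PASS' if ok else 'FAIL'}"
            )
        lines.append(f"overall: {'PASS' if self.passed else 'FAIL'}")
        return "\n".join(lines)


def validate_annotations(
    annotations: AnnotationSet, cycle_bounds: np.ndarray
) -> ValidationReport:
    """Check the ordering rule and per-cycle breakpoint parity.

    ``cycle_bounds`` is a sorted list of cycle boundary times (one cycle
    per consecutive pair).  Parity rule: an even number of breakpoints
    strictly inside each cycle.  Ordering rule: the set starts with an
    extremum (MAX/MIN) immediately followed by a BP.
    """
    st = annotations.statuses()
    ordering_ok = (
        len(st) >= 2 and st[0] in ("MAX", "MIN") and st[1] == "BP"
    )
    bp_times = annotations.times("BP")
    bounds = np.asarray(cycle_bounds, float)
    cycles = []
    all_ok = ordering_ok
    for a, b in zip(bounds[:-1], bounds[1:]):
        nbp = int(np.sum((bp_times > a) & (bp_times < b)))
        ok = nbp % 2 == 0
        all_ok = all_ok and ok
        cycles.append((float(a), float(b), nbp, ok))
    return ValidationReport(ordering_ok=ordering_ok, cycles=cycles, passed=all_ok)
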