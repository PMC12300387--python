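# Methods

## Signal model

A low-finesse (two-beam) Fabry–Perot cavity is formed between a cleaved
fiber end and an elastic membrane applanating a superficial artery.  The
reflected intensity is

I(t) = I1 + I2 + 2√(I1·I2)·cos(4πn/λ·(z + s·Δz(t)) + π),

with I1, I2 the two partial reflections (I2 treated as constant — its
variation only modulates the fringe amplitude weakly), n the refractive
index of the air-filled cavity, λ the laser wavelength, z the static
cavity length, and Δz(t) the pulse-induced cavity-length change.  The
sign s is −1 by default (systole shortens the cavity) and configurable.
Consecutive intensity extrema are separated by a phase change of π,
i.e. by one *halfwave quantum* of displacement, q = λ/(4n) = 386.7 nm at
λ = 1551.3 nm, n = 1.003.  This quantum is both the anchor spacing of
the reconstruction and its displacement resolution.

Two properties of the model drive the whole design:

* the intensity extrema are of two physical kinds — *crossings* of the
  quantized grid levels (the phase passes a multiple of π) and
  *reversals* of the membrane motion (Δφ′ = 0), and both appear as local
  extrema of I(t);
* the Hilbert envelope of dI/dt is proportional to |Δφ′(t)|, so envelope
  minima locate the reversals and envelope peaks locate the systolic
  upstroke, one per heartbeat.

## Synthetic pulse generator

The generator is the ground truth for all quantitative claims.  Each
cardiac cycle is a C1 piecewise raised-cosine profile with four named
events: a sin² systolic upstroke from baseline 0 to the peak at
`systolic_fraction` of the cycle (default 0.15), a cos² decline to the
dicrotic notch at `dicrotic_notch_time_fraction` (default 0.40), a sin²
dicrotic rebound over the following 15% of the cycle, and a
Gaussian-damped cos² diastolic decay (rate `diastolic_decay_rate`,
default 2.0 s⁻¹) back to exactly 0 at the cycle end.  Notch level and
rebound height scale with `dicrotic_notch_depth` (default 0.5, in
[0, 1)); at depth 0 the notch vanishes and no notch event is emitted.
Defaults: heart rate 1 Hz, peak amplitude 17.5 μm (the middle of the
15–20 μm range seen at the radial artery), 10 cycles, cycle-length
jitter SD 20 ms (resting-state beat-to-beat variability), sampling
10 kHz so the ≲250 Hz fringe carrier of the systolic upstroke is
oversampled ~20×.  White Gaussian noise is added to the rendered
intensity; both jitter and noise derive from one seed, so identical
arguments give bit-identical recordings.

What the generator does *not* emulate: motion artifacts, contact-pressure
drift, respiratory baseline wander, heteroscedastic sensor noise, and
amplitude variation of I2(t).  Passing tests therefore demonstrate the
correctness and noise robustness of the demodulation logic, not
performance on artifact-laden clinical recordings (which the stage-wise
design addresses with the scriptable edit API instead).

## Pipeline stages and numerical choices

**Preprocess.** Global z-score outlier repair (threshold 3.0) by linear
interpolation with edge fill; fourth-order Butterworth high-pass at
0.5 Hz applied forward–backward (zero phase — millisecond-level timing
claims rule out the group delay of a single pass); min–max normalization
per 1-second half-open segment, constant segments mapping to 0.5.
Uniform-grid validation uses a relative dt tolerance of 1e-6.

**Envelope.** np.gradient (central differences) → Hilbert magnitude →
max-normalization → zero-phase band-pass 0.5–10 Hz for peak detection
(peaks: height ≥ 0.3, spacing ≥ 0.5 s, i.e. ≤ 120 bpm).  0.5 s is
trimmed at both ends against filter/Hilbert edge effects.  Epoch
averaging uses the window (−0.2 s, +1.0 s) around each envelope peak and
the *unsmoothed* envelope; the averaged cycle is then low-passed at
20 Hz before inverted peak detection (prominence ≥ 5% of range, spacing
≥ 0.1 s).  Averaging across beats plus within-beat low-passing preserves
the brief notch dip that trace-level band-passing blurs away.  The 95%
confidence band is the normal approximation mean ± 1.96·SD/√k.

**Annotation.** Fringe extrema come from prominence-thresholded peak
detection (default 0.05 in normalized units) with three consistency
passes: (1) opposite-type pairs closer than 2.5 samples are
normalization-boundary step artifacts and are dropped; (2) a hysteresis
turning-point filter removes swings smaller than 6× the estimated noise
floor (10th percentile of windowed first-difference SDs — ~0 for clean
traces, so the filter is inert there); (3) same-type neighbors keep the
more prominent member.  Shallow extrema — those stopping short of the
local fringe rails by >35% of the local fringe range — can only be
motion reversals, so any found far from every envelope-minimum time are
removed as noise.  Rails are medians over the five nearest same-type
extremum values, which keeps the shallowness measure valid when
segment-wise normalization leaves fringes short of [0, 1].

Breakpoint placement: for each catalog minimum, the nearest extremum
within 0.15 s wins, except that a shallow candidate (>10% off its rail)
beats a nearer rail-touching crossing — the reversal extremum generically
stops short of the fringe envelope.  After placement, if the two extrema
flanking a breakpoint share a type, the post-breakpoint one is removed:
a reversal re-crosses the last grid level it passed, and that redundant
re-crossing must not consume a halfwave count.  This single rule is what
makes the counting below assign the physically correct quantum whether
the reversal extremum was detected separately or merged into its
neighboring crossing.  The first breakpoint of the analysis is the one
immediately preceding an envelope peak — a systole-onset reversal — and
the set is trimmed to start with the extremum right before it.

**Demodulation.** After the first breakpoint, m = 1 at the first
extremum, +1 per extremum, direction negated at every breakpoint,
breakpoints themselves uncounted.  m = 0 is legal exactly at the last
crossing before a breakpoint (the diastolic baseline touch, Δz = 0);
anywhere else it indicates a missed or spurious breakpoint and raises an
error rather than clamping.  Anchors at Δz = m·q feed a not-a-knot cubic
spline (anchors are exact samples of the true displacement up to a
constant, so spline error is dominated by the anchor gaps around
reversals, bounded by ~1 quantum); breakpoint displacements are the
spline values at the breakpoint times; no extrapolation beyond the
anchored span.  The per-sample `m` column is piecewise constant (last
anchor); `I2_t` carries the processed intensity.

**Evaluation.** SNR uses an 8 Hz zero-phase low-pass/residual split of
the reconstructed displacement (the pulse and its relevant harmonics sit
below ~8 Hz at 1 Hz heart rate).  Feature timing matches reconstructed
systolic peaks to ground-truth peak events greedily by increasing |Δt|
within a 50 ms radius.  A reconstructed systolic peak is reported at its
breakpoint time: the displacement maximum *is* a motion-reversal
breakpoint whose time is read off the fringe pattern at sample
resolution, whereas the spline apex between asymmetrically spaced
anchors is biased by several milliseconds.  Because a single-wavelength
interferogram determines Δz only up to sign and an additive constant
(< q, from the unknown static phase), displacement-error metrics remove
the least-squares constant offset; the sign convention is systole-up.

## Design choices where the design was open

* Which signal is epoched: the unsmoothed envelope (see above).
* Breakpoint Δz: spline evaluation at the breakpoint time, rather than
  re-estimating the sub-quantum overshoot from the breakpoint's
  intensity value — the latter would be a phase-interpolation extension
  beyond fringe counting.
* Cycle bounds for the parity check: envelope-peak-to-peak intervals,
  giving four interior breakpoints per beat (systole start, systolic
  peak, notch, rebound peak) — an even count, as required.
* Interactive editing is replaced by a JSON command file applied through
  `apply_edits`, with an audit log; detection functions stay pure.
* Spline boundary condition: not-a-knot.

## Problem sizes

The test suite and the acceptance script run the full pipeline on
10-cycle, 10 kHz recordings (10⁵ samples) over five seeds — the scale at
which every stage including epoch averaging is exercised — and verify
fringe-count laws on ramps of 5–20 quanta against a dense-grid
brute-force oracle.

## Known limitations

* Fully automated breakpoint detection is reliable up to ~1% additive
  noise (relative to the fringe amplitude) under the default morphology;
  at 5% occasional missed/misplaced breakpoints can mirror or offset
  individual strokes, and timing error grows accordingly.  The scriptable
  edit API is the intended remedy, mirroring manual practice.
* The direction sign and absolute offset of Δz are unrecoverable by
  design (single wavelength, no quadrature); outputs are displacement
  magnitudes from the diastolic baseline.
* Amplitude accuracy at reversals is bounded by one quantum: the true
  extremum lies up to q beyond the last anchored grid level.
* The first trim_s of recording plus the first partial cycle are not
  reconstructed (edge trimming and the first-breakpoint convention).
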