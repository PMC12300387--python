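# fpiapw — arterial pulse waveforms from Fabry–Perot interferograms

A low-finesse Fabry–Perot sensor pressed on an arterial pulse point
(applanation tonometry) does not record the arterial pulse waveform (APW)
directly.  It records an interference intensity

```
I(t) = I1 + I2 + 2·√(I1·I2) · cos( 4πn/λ · (z ± Δz(t)) + π )
```

whose phase tracks the cavity-length change Δz(t) caused by the pulsating
artery.  Because the pulse displacement (15–20 μm at the radial artery)
spans many wavelengths, the recording is a frequency-modulated fringe
pattern, and the waveform must be recovered by phase demodulation.
`fpiapw` implements that demodulation for researchers building optical
pulse sensors, together with the forward model needed to validate it:

1. **preprocess** — z-score outlier repair, zero-phase fourth-order
   Butterworth high-pass (0.5 Hz), per-second min–max normalization;
2. **envelope** — the Hilbert envelope of the signal's rate of change
   tracks the instantaneous phase velocity |Δφ′(t)|; envelope peaks mark
   systolic upstrokes, epoch-averaged envelope minima mark candidate
   motion reversals;
3. **annotate** — fringe extrema are labeled MAX/MIN and reversal extrema
   are relabeled BP (*breakpoints*); each cardiac cycle must contain an
   even number of breakpoints and each analysis period starts with an
   extremum followed by a breakpoint;
4. **demodulate** — between breakpoints the integer halfwave number *m*
   increments by one per extremum and flips direction at each breakpoint;
   each extremum anchors the displacement at Δz = m·λ/(4n) ≈ m·386.7 nm,
   and a cubic spline through the anchors yields the smooth waveform;
5. **evaluate** — SNR(dB) = 20·log₁₀(RMS_signal/RMS_noise) and
   feature-timing error against synthetic ground truth.

The quantity λ/(4n) — the cavity-length change between successive
intensity extrema — is the native displacement resolution of the method:
386.7 nm for a 1551.3 nm laser in air (n = 1.003).

## Worked example

```python
import numpy as np
from fpiapw import APWTemplate, OpticalConfig, run_auto_pipeline, synthesize_recording

template = APWTemplate()            # 1 Hz, 17.5 um peak, 10 cycles
optics = OpticalConfig()            # 1551.3 nm laser, n = 1.003
rec = synthesize_recording(template, optics,
                           noise_sd=0.01 * optics.fringe_amplitude, seed=1)
result = run_auto_pipeline(rec.trace, optics)
disp = result.displacement

truth = np.interp(disp.time_s, rec.ground_truth.time_s, rec.ground_truth.delta_z_nm)
err = disp.delta_z_nm - truth
err -= err.mean()                   # absolute offset is unobservable
print(disp.delta_z_nm.max() / 1e3, np.sqrt(np.mean(err**2)))
```

Running this (it is `examples/simulate_and_demodulate.py`) prints:

```
recording: 100450 samples at 10000 Hz, noise sd 0.0089 a.u.
envelope peaks (cycles found): 9
labeled points: 928 (36 breakpoints)
reconstructed span: 1.03-9.53 s, peak displacement 17.43 um
RMSE vs ground truth: 86 nm (halfwave quantum 386.7 nm)
```

The pipeline found 9 analyzable cycles (the first is consumed by filter
edge trimming), placed 4 breakpoints per cycle (systole start, systolic
peak, dicrotic notch, dicrotic-rebound peak), and reconstructed the
17.5 μm pulse with an RMS error of 86 nm — well below one halfwave
quantum, i.e. sub-fringe accuracy.  `examples/validate_timing.py` scores
feature timing: at noise up to 1% of the fringe amplitude the mean
systolic-peak timing error is ~0.5 ms (bounded by 3 ms), growing
monotonically with noise.

## Command line

Every stage is also a subcommand of the `fpiapw` CLI:

```sh
fpiapw simulate --cycles 10 --noise-sd 0.009 --seed 1 --out rec.csv
fpiapw run --config pipeline.yaml        # preprocessed/minima/annotations/displacement.csv + manifest
fpiapw validate --cycles 10 --noise-pct 1 --seed 7 --report report.json
```

Interactive breakpoint editing is replaced by a scriptable edit file
(`--edits edits.json` on `fpiapw annotate`) so that every run is
reproducible; each edit command is recorded in an audit log.

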