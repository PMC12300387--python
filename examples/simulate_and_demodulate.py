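"""Simulate an arterial pulse recording and demodulate it end to end.

Builds a 10-cycle radial-artery pulse (1 Hz, 17.5 um peak), renders it
through the Fabry-Perot interference law with 1% white noise, runs the
automated pipeline, and compares the reconstructed displacement with the
known ground truth.
"""

import numpy as np

from fpiapw import (
    APWTemplate,
    OpticalConfig,
    run_auto_pipeline,
    synthesize_recording,
)

template = APWTemplate()  # 1 Hz, 17.5 um, 10 cycles, physiologic morphology
optics = OpticalConfig()  # 1551.3 nm laser, air-filled cavity (n = 1.003)
noise_sd = 0.01 * optics.fringe_amplitude

rec = synthesize_recording(template, optics, noise_sd=noise_sd, seed=1)
print(f"recording: {rec.trace.time_s.size} samples at "
      f"{rec.trace.sampling_rate_hz:.0f} Hz, noise sd {noise_sd:.4f} a.u.")

result = run_auto_pipeline(rec.trace, optics)
disp = result.displacement
st = result.annotations.statuses()
print(f"envelope peaks (cycles found): {result.peak_times.size}")
print(f"labeled points: {len(st)} ({st.count('BP')} breakpoints)")
print(f"reconstructed span: {disp.time_s[0]:.2f}-{disp.time_s[-1]:.2f} s, "
      f"peak displacement {disp.delta_z_nm.max() / 1e3:.2f} um")

truth = np.interp(disp.time_s, rec.ground_truth.time_s,
                  rec.ground_truth.delta_z_nm)
err = disp.delta_z_nm - truth
err -= err.mean()  # absolute offset is unobservable (unknown static phase)
print(f"RMSE vs ground truth: {np.sqrt(np.mean(err**2)):.0f} nm "
      f"(halfwave quantum {optics.halfwave_quantum_nm:.1f} nm)")
# The RMSE sits well below one halfwave quantum: fringe counting plus
# spline reconstruction recovers the pulse waveform at sub-quantum accuracy.
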