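"""Simulate a ventilation recording that drifts from normal breathing into
severe Cheyne-Stokes respiration, and inspect its ground truth.

The schedule reproduces the canonical demonstration scenario: two minutes
of normal breathing, nine minutes of early CSR (modulation index h = 0.5),
then four minutes of severe over-modulated CSR (h = 1.5) whose clipped
envelope produces a central apnea once per modulation cycle.
"""

import numpy as np

import csrdemod as cd

schedule = cd.fig1_schedule(f_m=0.01)
rec = cd.build_recording(
    schedule, fs=25.0, noise_sd=0.05, breath_jitter=0.1, seed=7,
    carrier="breath",
)

print("schedule:")
for seg in schedule:
    print(
        f"  {seg.start_s:6.0f}-{seg.end_s:6.0f} s  h={seg.params.h:3.1f}  "
        f"f_m={seg.params.f_m * 1000:.0f} mHz"
    )
delta = cd.apnea_duration(1.5, 0.01)
print(f"\npredicted apnea duration at h=1.5, f_m=10 mHz: {delta:.1f} s")
print(f"breaths present in the signal: {len(rec.breath_peaks)}")
print(f"per-minute truth: {' '.join('O' if m == 'oscillating' else '.' for m in rec.truth_minutes)}")
print(f"peak signal amplitude: {np.max(np.abs(rec.signal.values)):.2f} "
      f"(noiseless envelope bound A_c(1+h) = 2.50, plus additive noise)")

cd.simulator.write_signal_csv(rec.signal, "fig1_recording.csv")
print("\nwrote fig1_recording.csv  (O = minute with pathological oscillation)")
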