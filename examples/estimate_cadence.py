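"""Estimate running cadence from a head-motion trace, window by window.

Generates a trace whose oscillation is pre-distorted with the inverse of
the bias-correction model (so the raw FFT estimate overestimates, as on
real recordings), then runs the full estimation pipeline: centered
128-frame window, radix-2 FFT with the first five bins discarded,
dominant-bin cadence, and the linear correction. Also shows the streaming
schedule (one estimate per ~4.27 s) and the peak-counting baseline.
"""

from facecadence import (
    TraceSpec,
    apply_correction,
    default_correction_model,
    estimate_cadence_peaks,
    estimate_cadence_raw,
    extract_analysis_window,
    generate_trace,
    stream_estimates,
)

model = default_correction_model()
true_cadence = 158.0
trace = generate_trace(
    TraceSpec(true_cadence=true_cadence, bias_mode="inverse_correction", seed=3),
    model=model,
)

window = extract_analysis_window(trace, skip=10.0, length=128)
est = estimate_cadence_raw(window)
corrected = apply_correction(est.raw_spm, model)
print(f"true cadence      : {true_cadence:.1f} steps/min")
print(f"dominant bin      : {est.dominant_bin} ({est.dominant_frequency:.3f} Hz)")
print(f"raw FFT estimate  : {est.raw_spm:.2f} steps/min  (systematic overestimate)")
print(f"corrected estimate: {corrected:.2f} steps/min  (0.83*raw + 13.70)")
print(f"peaks baseline    : {estimate_cadence_peaks(window):.2f} steps/min")
# The corrected value should sit within ~6 steps/min of the truth (half a
# frequency bin scaled by the correction slope); the raw value overshoots.

print("\nstreaming, one non-overlapping window per ~4.27 s:")
for e in stream_estimates(trace, model, hop=128):
    print(f"  frames {e.origin[1]:4d}..{e.origin[1]+127}: {e.corrected_spm:7.2f} steps/min")
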