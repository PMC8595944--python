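"""Synthesize a short EEG recording with planted spectral structure.

A 10-minute, 4-channel recording is generated with known band-power
fractions and a slow-oscillation-like 0.75 Hz peak, then the planted
fractions are read back from the normalized spectrum.
"""

from somnospec import EEGSynthesisSpec, TILING_BANDS, epoch_psd, relative_power, synthesize_eeg

spec = EEGSynthesisSpec(
    duration=600.0,
    n_channels=4,
    peak_frequency=0.75,  # Hz, typical slow-oscillation frequency
    peak_relative_amplitude=0.08,  # 8% of total power in the peak
    seed=1,
)
rec = synthesize_eeg(spec)
print(f"recording: {rec.n_channels} channels x {rec.duration:.0f} s "
      f"at {rec.sampling_rate:.0f} Hz, RMS {rec.samples.std():.1f} uV")

spectrum = epoch_psd(rec)  # 30-s epochs, averaged, unit-sum over 0.1-70 Hz
print(f"{'band':8s} {'planted':>8s} {'recovered':>10s}")
for band in TILING_BANDS:
    planted = spec.band_power_fractions[band.name] * (1 - spec.peak_relative_amplitude)
    recovered = relative_power(spectrum, band).mean()
    print(f"{band.name:8s} {planted:8.3f} {recovered:10.3f}")
print("recovered relative power tracks the planted per-band fractions;")
print("the small delta1 excess is the planted 0.75 Hz peak.")
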