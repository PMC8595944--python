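"""Run the whole pipeline on a small synthetic study.

Synthesizes 12 subjects of 2-minute EEG, preprocesses, extracts features,
builds the six bootstrap correlation networks (2 measures x 3 severity
groups) and writes the cohort report -- all into ./example_run/.
"""

import json
from pathlib import Path

from somnospec.pipeline import (
    NetworkConfig,
    PreprocessConfig,
    RunConfig,
    SynthConfig,
    run_pipeline,
)

config = RunConfig(
    out_dir="example_run",
    seed=11,
    synth=SynthConfig(group_sizes=(6, 4, 2), duration_s=120.0),
    preprocess=PreprocessConfig(trim_minutes=0.5),
    network=NetworkConfig(n_boot=200),
)
manifest = run_pipeline(config)
print(json.dumps(manifest["stages"], indent=1))

peaks = json.loads(Path("example_run/spectra/so_peaks.json").read_text())
for group, peak in peaks.items():
    print(f"{group}: slow-oscillation peak at {peak['frequency_hz']:.3f} Hz")
print("peak frequency decreases and amplitude increases with severity,")
print("matching the planted regime; outputs are under example_run/.")
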