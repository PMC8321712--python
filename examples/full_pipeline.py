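"""Run the complete simulated study end to end.

Simulates a healthy and a GAD cohort from the published targets, renders
every subject's dynamic volume, extracts cerebellum-normalized SUVmax
curves, computes the three uptake metrics, and writes the comparison tables,
dynamics labels and TAC figure to an output directory.
"""

import warnings

from petloop import pipeline

cfg = pipeline.PipelineConfig(seed=11, n_subjects=20, grid_dims=(32, 32, 32))
with warnings.catch_warnings():
    warnings.simplefilter("ignore")  # printed rates imply clipped endpoints
    artifacts = pipeline.run_pipeline(cfg, "pipeline_output")

print(f"config hash: {cfg.hash()}")
for name, path in sorted(artifacts.items()):
    print(f"{name:>15}: {path}")
print(
    "\nEach CSV is stamped with the config hash and seed; rerunning with the "
    "same config reproduces the tables byte for byte."
)
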