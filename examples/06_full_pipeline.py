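"""Run the full synthetic pipeline and print the report.

Simulates paired control/treated eyes, measures and grades every 250 um
region, fits the density model, quantifies markers, simulates and analyses
per-electrode cortical responses, and runs the group statistics
(Kruskal-Wallis with Holm-adjusted Dunn post hocs) and retina-cortex
correlations.  The same call is available from the shell as
`orrquant run --seed 7 --out pipeline_out`.
"""

from orrquant import PipelineConfig, run_pipeline

cfg = PipelineConfig(output_dir="scratch/example_pipeline", seed=7,
                     n_control_eyes=1, n_treated_eyes=1,
                     section_length_um=2000.0)
result = run_pipeline(cfg)

print(result.paths["report"].read_text())
print("Bundle files:")
for name, path in result.paths.items():
    print(f"  {name}: {path}")
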