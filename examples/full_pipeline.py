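"""Run the whole pipeline (simulate -> extract -> cutpoints -> survive).

Writes every CSV artifact into ./example_run and prints the per-filter
stepwise Cox table.  Re-running reproduces identical files.
"""

from texturesurv import RunConfig, SyntheticConfig, render_reports, run_pipeline

config = RunConfig(
    outdir="example_run",
    seed=42,
    synthetic=SyntheticConfig(n_patients=60),
    sigmas=(0.0, 1.0, 1.5, 2.0, 2.5),
    loocv=True,
)
result = run_pipeline(config)
render_reports(result)

print("artifacts:", sorted(p.name for p in result.outdir.iterdir()))
print("\nPer-filter stepwise Cox models:")
print(result.table4.round(3).to_string(index=False))
# Each filter block is its own model; `nodal` plus a low-average /
# homogeneous-texture indicator (HR < 1) is the expected signature.
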