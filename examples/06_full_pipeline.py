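"""The whole analysis in one call: synthesize -> modules -> centrality
-> hubs -> NBS sweep -> ANCOVA at every level, with all reports written
to an output directory and summarised as text."""

from connstats import PipelineConfig, make_report, run_pipeline

config = PipelineConfig(
    out_dir="scratch/pipeline_demo",
    seed=42,
    synthetic=True,
    n_per_group=(12, 12, 12),  # reduced for a quick demo
    n_perm=200,
    consensus_runs=20,
    k_per_group=12,
    nbs_thresholds=(2.1, 2.3, 2.5),
)

bundle = run_pipeline(config)
print(make_report(bundle))
print(f"\nreports written to {config.out_dir}/")
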