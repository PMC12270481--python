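"""One-call pipeline: simulate -> AE -> screen -> classify -> curate.

Writes every stage table plus a resolved config echo under `outdir` and
returns a summary dict.  The same entry point runs on real inputs by
setting counts_path / genotype_vcfs / genes_path instead of `simulate`.
"""

from xciase.pipeline import PipelineConfig, run_pipeline

config = PipelineConfig(
    outdir="scratch/example_run",
    seed=7,
    simulate=dict(n_donors=8, n_nmxci=3, tissues=8, screen_tissue_mix=False,
                  n_genes=150),
)
summary = run_pipeline(config)

for key, value in summary.items():
    print(f"{key}: {value}")
# n_nmxci donors found by the screen are confirmed across tissues, their
# genes classified and curated; variable_fraction_percent is the share of
# genes with tissue- or donor-dependent escape among all classified genes.
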