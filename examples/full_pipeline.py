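"""Run every pipeline stage end to end from one seeded configuration.

Writes all artifacts (TSV/FASTA/FASTQ/PDB/JSON) into a run directory and
prints the aggregated summary. Identical config and seed reproduce the
summary byte for byte.
"""

from designscreen.pipeline import RunConfig, report, run

config = RunConfig(
    seed=1,
    out_dir="scratch/example_run",
    n_per_strategy=1000,
    k_per_strategy=150,
    depth=30_000,
    n_surrogate_models=15,
    n_trees=40,
    nnk_n_sequences=5_000,
    nnk_replicates=3,
)
run_dir = run(config)
print(report(run_dir))
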