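"""Run the complete analysis end to end and write all artifacts.

simulate -> segment cores -> split VLp into Vim -> build the probabilistic
target -> warp to patient spaces -> metrics -> outcome statistics.
Artifacts (NIfTI volumes, TSV tables, summary JSON) land in ./pipeline_run.
"""

import json

from vimtarget import PipelineConfig, run_all

config = PipelineConfig(
    n_patients=14,
    rng_seed=0,
    dims=(96, 96, 96),
    outdir="pipeline_run",
)
result, outdir = run_all(config)

print(json.dumps(result.summary, indent=2, sort_keys=True))
print(f"\nartifacts written to {outdir}/")
print("  cores/<id>_core.nii.gz       segmented ablation cores")
print("  vims/<id>_vim.nii.gz         per-patient Vim (ventral VLp)")
print("  probabilistic_target.nii.gz  cohort consensus target")
print("  ablation_count_map.nii.gz    per-voxel ablation coverage count")
print("  metrics.tsv / correlations.tsv / summary.json")

# Re-running with the same configuration reproduces every file bit for bit;
# the summary records the seed, parameters and configuration hash.
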