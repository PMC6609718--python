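"""Run the whole study end to end on a simulated herd.

simulate -> raw records -> six traits -> REML per trait -> DGE/SGE
pseudo-phenotypes -> genotype QC -> single- and multi-locus scans -> region
reports.  Writes all tables to ./pipeline_demo and prints the manifest
summary.  Takes a minute or two.
"""

import json

from sociogwas.pipeline import PipelineConfig, run_pipeline
from sociogwas.simulate import SimulationConfig

cfg = PipelineConfig(
    outdir="pipeline_demo",
    seed=1,
    simulation=SimulationConfig(n_animals=260, n_founders=60, n_snps=400, seed=1),
)
manifest = run_pipeline(cfg)

print(json.dumps({k: manifest[k] for k in
                  ("seed", "config_hash", "n_phenotyped",
                   "n_snps_input", "n_snps_pass")}, indent=2))
print(f"\n{len(manifest['outputs'])} files in pipeline_demo/: "
      "per-trait variance components (Table-1-style), 24 scan tables "
      "(6 traits x dge/sge x single/multi), QC report, region report.")
print("Every file header carries the seed and config hash; re-running with "
      "the same seed reproduces each file byte for byte.")
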