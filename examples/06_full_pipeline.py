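"""Run the whole study workflow from one configuration.

Simulation -> batch residualization -> five DE contrasts -> subtype
concordance -> three RFS screens -> enrichment -> summary JSON, written to
./pipeline_out (re-running with the same seed is byte-identical).
"""

import json

from serialdex import PipelineConfig, SimConfig, run_all

cfg = PipelineConfig(sim=SimConfig(seed=1), n_perm=2000, seed=1)
summary = run_all(cfg, out_dir="pipeline_out")

for name, block in summary["contrasts"].items():
    print(f"{name:14s} {block['n_significant']:4d} significant "
          f"({block['n_up']} up / {block['n_down']} down)  [{block['threshold_rule']}]")
for pair, block in summary["concordance"].items():
    print(f"concordance {pair}: {block['rate_percent']} % over {block['n_pairs']} pairs")
for mode, block in summary["rfs_screens"].items():
    print(f"rfs {mode:9s} {block['n_significant']:4d} significant of {block['n_features']}")
print("truth eval:", json.dumps(summary["truth_eval"]))
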