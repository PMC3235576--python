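"""Run the whole pipeline on simulated data and inspect the run report.

Five genes are simulated, meta-analysed per SNP, graded, ranked, and the
run report summarises counts; with a fixed seed the outputs are
byte-identical across runs.
"""

import json
from pathlib import Path

from metacred import RunConfig, run_pipeline

config = RunConfig(
    outdir="scratch/demo_run",
    seed=7,
    n_genes=5,
    simulate={"true_or": 1.5, "tau2": 0.0},
)
report = run_pipeline(config)

print(f"config hash: {report['config_hash']}")
print(f"counts: {json.dumps(report['counts'])}")
print((Path(config.outdir) / "top_list.tsv").read_text())
# Each simulated gene is well powered, so all five typically reach the
# top list with quality "AAA"; re-running with the same seed reproduces
# the identical report_hash.
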