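"""Run the whole pipeline from files, the way the CLI does it.

Writes a synthetic dataset to disk, builds a RunConfig, and executes
quantify -> decay -> classify -> enrich, producing TSVs, a markdown
report with the filter-attrition funnel, and a MANIFEST.
"""

import tempfile
from pathlib import Path

from mrnafate import RunConfig, SimConfig, run_all, simulate_dataset, write_dataset

tmp = Path(tempfile.mkdtemp(prefix="mrnafate_"))
sim = simulate_dataset(SimConfig(seed=17, n_genes=120, depth=5e5, chase_depth=5e5))
paths = write_dataset(sim, tmp / "data")

config = RunConfig(
    annotation=paths["annotation"],
    steady_counts=paths["steady_counts"],
    steady_samples=paths["steady_samples"],
    chase_counts=paths["chase_counts"],
    chase_samples=paths["chase_samples"],
    gene_sets=paths["gene_sets"],
    out_dir=str(tmp / "results"),
)
manifest = run_all(config)

print(f"pipeline complete: {manifest['complete']}")
print("outputs:")
for name in manifest["outputs"]:
    print(f"  {name}")
print(f"\nattrition funnel (from {tmp/'results'/'attrition.tsv'}):")
print(Path(manifest["outputs"]["attrition"]).read_text())
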