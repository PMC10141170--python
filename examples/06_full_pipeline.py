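"""Run the complete pipeline on a simulated two-treatment study.

Generates all inputs (hit table, taxonomy, copy numbers, genome
annotations, counts, metadata), then executes assignment -> collapse ->
renormalization -> diversity/ordination -> modulation + tests -> CPI ->
f-scores, writing one TSV per stage plus a manifest.
"""

import json
import tempfile
from pathlib import Path

import pandas as pd

from glycomod.pipeline import RunConfig, run_pipeline
from glycomod.simulate import build_world, generate_experiment, write_world

workdir = Path(tempfile.mkdtemp(prefix="glycomod_demo_"))
world = build_world(n_species=80, n_genera=20,
                    conditions=("apple pectin", "inulin"), seed=42)
write_world(world, generate_experiment(world), workdir / "inputs")

rundir = run_pipeline(RunConfig.from_dir(workdir / "inputs",
                                         workdir / "run", seed=42))
manifest = json.loads((rundir / "manifest.json").read_text())
print("stages:", ", ".join(sorted(manifest["stages"])))

diversity = pd.read_csv(rundir / "diversity.tsv", sep="\t", index_col=0)
print("\nmean Shannon diversity by condition:")
print(diversity.groupby(diversity.index.str.rsplit("_", n=1).str[0]).mean())

stats = pd.read_csv(rundir / "modulation_stats.tsv", sep="\t")
altered = stats[stats["call"] != "unchanged"].groupby("treatment").size()
print("\naltered phylotypes per treatment:")
print(altered.to_string())

fscores = pd.read_csv(rundir / "fscore_long.tsv", sep="\t")
print("\npairwise f-scores:")
print(fscores.to_string(index=False))
print("\nEach treatment plants 15 ten-fold responders drawn independently")
print("from the same pool of detectable mid-abundance taxa, so the pair")
print("overlaps by chance at roughly the hypergeometric expectation.")
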