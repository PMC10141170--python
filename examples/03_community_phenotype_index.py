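"""Predict community metabolic potential from genome content.

Genome annotations are binarized into a binary phenotype matrix (BPM);
each phylotype's value is the mean over its genomes, and the community
phenotype index (CPI) weights those values by relative abundance.
"""

import pandas as pd

from glycomod import build_bpm, community_phenotype_index, default_vocabulary
from glycomod.phenotype import GenomeAnnotation, phylotype_values
from glycomod.taxonomy import Lineage

vocab = default_vocabulary(n_gh=5, n_pl=2)
lin = {
    name: Lineage(domain="Bacteria", genus=name.split()[0], species=name)
    for name in ("Bacteroides fragilis", "Bifidobacterium longum",
                 "Escherichia coli")
}
annotations = [
    GenomeAnnotation("g1", lin["Bacteroides fragilis"],
                     {"GH2": 14, "PL1": 3}, {"propionate": 1, "acetate": 1}),
    GenomeAnnotation("g2", lin["Bifidobacterium longum"],
                     {"GH2": 6}, {"L-lactate": 1, "acetate": 1}),
    GenomeAnnotation("g3", lin["Escherichia coli"],
                     {"GH1": 1}, {"ethanol": 1, "formate": 1, "acetate": 1}),
]
bpm = build_bpm(annotations, vocab)
genome_map = {l: [f"g{i + 1}"] for i, l in enumerate(lin.values())}
values, unmapped = phylotype_values(
    {name: [l] for name, l in lin.items()}, bpm, genome_map
)

rel = pd.Series({"Bacteroides fragilis": 0.5,
                 "Bifidobacterium longum": 0.3,
                 "Escherichia coli": 0.2})
cpi = community_phenotype_index(rel, values)
print(cpi[["acetate", "propionate", "L-lactate", "GH2", "PL1"]])
print()
print("CPI is the abundance share of organisms carrying each trait: every")
print("taxon makes acetate (CPI 1.0), only the 50% Bacteroides fraction")
print("makes propionate or encodes PL1 (CPI 0.5), and 80% of the community")
print("carries a GH2 glycosidase.")
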