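"""Correct phylotype abundances for 16S rRNA gene copy number.

A taxon with 4 rRNA operons contributes 4x the amplicons per cell, so raw
counts are divided by a per-taxon copy-number estimate (species-level mean
if indexed, walking up the ranks otherwise) before renormalizing.
"""

import pandas as pd

from glycomod import build_copy_number_index, estimate_copy_number, \
    renormalize_abundances
from glycomod.taxonomy import Lineage

ecoli = Lineage(domain="Bacteria", family="Enterobacteriaceae",
                genus="Escherichia", species="Escherichia coli")
bfra = Lineage(domain="Bacteria", family="Bacteroidaceae",
               genus="Bacteroides", species="Bacteroides fragilis")
bnovel = Lineage(domain="Bacteria", family="Bacteroidaceae",
                 genus="Bacteroides", species="Bacteroides novel")

index = build_copy_number_index([(ecoli, 7), (bfra, 6), (bfra, 4)])
print("E. coli estimate (species entry)  :", estimate_copy_number(ecoli, index))
print("B. novel estimate (genus fallback):", estimate_copy_number(bnovel, index))

counts = pd.DataFrame({"sample1": [700, 500]},
                      index=["Escherichia coli", "Bacteroides fragilis"])
rel = renormalize_abundances(counts, {"Escherichia coli": 7.0,
                                      "Bacteroides fragilis": 5.0})
print()
print(rel)
print()
print("Equal cell numbers hide behind unequal read counts: after dividing")
print("700 reads by 7 copies and 500 by 5, both taxa are 50% of the")
print("community instead of the raw 58%/42%.")
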