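"""16S rRNA gene copy-number correction.

Bacterial genomes carry between 1 and ~15 copies of the 16S rRNA gene, so
raw amplicon counts overrepresent high-copy taxa.  The correction here
follows the rrnDB-style usage: build per-rank average copy numbers from a
reference table, look up each phylotype at the most specific rank with an
entry (species first, walking up to domain, then a global mean), and divide
counts by the estimate before renormalizing to relative abundance.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import IO, Mapping, Sequence

import pandas as pd

from .taxonomy import RANKS, Lineage, MTAssignment

__all__ = [
    "CopyNumberIndex",
    "build_copy_number_index",
    "read_copy_number_table",
    "estimate_copy_number",
    "renormalize_abundances",
]


@dataclass(frozen=True)
class CopyNumberIndex:
    """Per-rank mean 16S copy numbers plus a global fallback mean."""

    per_rank: Mapping[str, Mapping[str, float]]
    global_mean: float


def build_copy_number_index(
    records: Sequence[tuple[Lineage, float]],
) -> CopyNumberIndex:
    """Average copy numbers at each taxonomic level.

    For every rank and label, the mean over all records carrying that label;
    the global mean averages all records and backstops lineages unknown at
    every rank.
    """
    if not records:
        raise ValueError("cannot build a copy-number index from zero records")
    for lineage, cn in records:
        if cn < 1:
            raise ValueError(f"copy number {cn} < 1 for {lineage.to_string()}")
    per_rank: dict[str, dict[str, float]] = {}
    for rank in RANKS:
        groups: dict[str, list[float]] = {}
        for lineage, cn in records:
            label = lineage.label_at(rank)
            if label:
                groups.setdefault(label, []).append(float(cn))
        per_rank[rank] = {
            label: sum(vals) / len(vals) for label, vals in groups.items()
        }
    global_mean = sum(float(cn) for _, cn in records) / len(records)
    return CopyNumberIndex(per_rank=per_rank, global_mean=global_mean)


def read_copy_number_table(source: str | Path | IO[str]) -> CopyNumberIndex:
    """Read ``lineage<TAB>copy_number`` rows and build the index."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            return read_copy_number_table(fh)
    records: list[tuple[Lineage, float]] = []
    for lineno, line in enumerate(source, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ValueError(f"line {lineno}: expected 'lineage<TAB>copy_number'")
        records.append((Lineage.from_string(parts[0]), float(parts[1])))
    return build_copy_number_index(records)


def _estimate_single(lineage: Lineage, index: CopyNumberIndex) -> float:
    # Most specific rank first (species -> domain), then global fallback.
    for rank in reversed(RANKS):
        label = lineage.label_at(rank)
        if label and label in index.per_rank.get(rank, {}):
            return index.per_rank[rank][label]
    return index.global_mean


def estimate_copy_number(
    taxon: MTAssignment | Lineage, index: CopyNumberIndex
) -> float:
    """Estimated 16S copy number for a lineage or multi-taxon assignment.

    A single lineage uses the mean at its most specific indexed rank; a
    multi-taxon assignment averages its members' estimates (members are
    equally plausible under the multi-taxonomy rule).
    """
    if isinstance(taxon, Lineage):
        return _estimate_single(taxon, index)
    if not taxon.members:
        return index.global_mean
    estimates = [_estimate_single(m, index) for m in taxon.members]
    return sum(estimates) / len(estimates)


def renormalize_abundances(
    counts: pd.DataFrame, copy_numbers: Mapping[str, float] | pd.Series
) -> pd.DataFrame:
    """Copy-number-correct a phylotype x sample count table.

    Per sample: ``a_i = (c_i / cn_i) / sum_j (c_j / cn_j)``.  Output columns
    sum to 1; zero counts stay zero; all copy numbers must be positive and
    every sample must have nonzero total counts.
    """
    cn = pd.Series(copy_numbers, dtype=float).reindex(counts.index)
    missing = cn.index[cn.isna()].tolist()
    if missing:
        raise KeyError(f"no copy-number estimate for phylotypes: {missing}")
    if (cn <= 0).any():
        bad = cn.index[cn <= 0].tolist()
        raise ValueError(f"non-positive copy numbers for: {bad}")
    weighted = counts.div(cn, axis=0)
    totals = weighted.sum(axis=0)
    dead = totals.index[totals <= 0].tolist()
    if dead:
        raise ValueError(f"samples with all-zero counts: {dead}")
    return weighted.div(totals, axis=1)
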