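"""Genome-content-based community phenotype prediction.

Each reference genome is annotated with pathway phenotype calls
(fermentation end-products, vitamin/cofactor biosynthesis) and CAZyme
family counts (glycosyl hydrolase GH and polysaccharide lyase PL families).
Family counts are binarized — a genome scores 1 for a family if it encodes
at least one member enzyme — and stacked into a binary phenotype matrix
(BPM).  A phylotype's phenotype value is the unweighted mean of the BPM
rows of every genome mapped to any of its member taxa, so strain-variable
traits take fractional values.  The community phenotype index (CPI) of a
sample is then the relative-abundance-weighted mean of taxon values: the
expected probability that a randomly drawn (copy-number-corrected) 16S read
comes from an organism carrying the phenotype.  Unmapped phylotypes are
dropped and abundance renormalized over mapped mass rather than silently
counted as phenotype-negative.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .taxonomy import Lineage

__all__ = [
    "FERMENTATION_PRODUCTS",
    "VITAMINS",
    "PhenotypeVocabulary",
    "default_vocabulary",
    "GenomeAnnotation",
    "binarize_families",
    "build_bpm",
    "taxon_phenotype_value",
    "phylotype_values",
    "community_phenotype_index",
    "cpi_table",
    "phenotype_percent_change",
    "net_family_shift",
    "read_annotation_table",
    "write_annotation_table",
]

#: Anaerobic fermentation end-products tracked as producer phenotypes.
FERMENTATION_PRODUCTS = (
    "acetate",
    "propionate",
    "butyrate",
    "D-lactate",
    "L-lactate",
    "ethanol",
    "formate",
)

#: Vitamin / cofactor biosynthesis phenotypes.
VITAMINS = (
    "B1",
    "B2",
    "B3",
    "B5",
    "B6",
    "B7",
    "B9",
    "B12",
    "K",
    "queuosine",
    "lipoate",
)


@dataclass(frozen=True)
class PhenotypeVocabulary:
    """Declared phenotype label sets; labels are unique across categories."""

    fermentation: tuple[str, ...] = FERMENTATION_PRODUCTS
    vitamins: tuple[str, ...] = VITAMINS
    gh_families: tuple[str, ...] = ()
    pl_families: tuple[str, ...] = ()
    version: str = "1"

    def __post_init__(self) -> None:
        labels = self.all_labels
        if len(labels) != len(set(labels)):
            seen: set[str] = set()
            dups = sorted({l for l in labels if l in seen or seen.add(l)})
            raise ValueError(f"duplicate phenotype labels: {dups}")

    @property
    def families(self) -> tuple[str, ...]:
        return self.gh_families + self.pl_families

    @property
    def pathways(self) -> tuple[str, ...]:
        return self.fermentation + self.vitamins

    @property
    def all_labels(self) -> tuple[str, ...]:
        return self.pathways + self.families

    def to_json(self, path: str | Path) -> None:
        payload = {
            "version": self.version,
            "fermentation": list(self.fermentation),
            "vitamins": list(self.vitamins),
            "gh_families": list(self.gh_families),
            "pl_families": list(self.pl_families),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "PhenotypeVocabulary":
        payload = json.loads(Path(path).read_text())
        return cls(
            fermentation=tuple(payload["fermentation"]),
            vitamins=tuple(payload["vitamins"]),
            gh_families=tuple(payload["gh_families"]),
            pl_families=tuple(payload["pl_families"]),
            version=str(payload.get("version", "1")),
        )


def default_vocabulary(n_gh: int = 170, n_pl: int = 33) -> PhenotypeVocabulary:
    """Standard vocabulary: 7 fermentation products, 11 vitamins/cofactors,
    and GH1..GH{n_gh} plus PL1..PL{n_pl} CAZyme families."""
    return PhenotypeVocabulary(
        gh_families=tuple(f"GH{i}" for i in range(1, n_gh + 1)),
        pl_families=tuple(f"PL{i}" for i in range(1, n_pl + 1)),
    )


@dataclass(frozen=True)
class GenomeAnnotation:
    """One reference genome: lineage, CAZyme family counts, pathway calls."""

    genome_id: str
    lineage: Lineage
    family_counts: Mapping[str, int] = field(default_factory=dict)
    pathway_calls: Mapping[str, int] = field(default_factory=dict)


def binarize_families(
    family_counts: Mapping[str, int], vocabulary: PhenotypeVocabulary
) -> dict[str, int]:
    """Binarize CAZyme family counts: 1 iff the genome has >= 1 enzyme.

    Returns a full 0/1 vector over the vocabulary's families (absent labels
    default to 0).  Unknown family labels are a hard error.
    """
    known = set(vocabulary.families)
    unknown = sorted(set(family_counts) - known)
    if unknown:
        raise KeyError(f"family labels not in vocabulary: {unknown}")
    for label, count in family_counts.items():
        if count < 0:
            raise ValueError(f"negative count for family {label}: {count}")
    return {
        label: int(family_counts.get(label, 0) >= 1) for label in vocabulary.families
    }


def build_bpm(
    annotations: Sequence[GenomeAnnotation], vocabulary: PhenotypeVocabulary
) -> pd.DataFrame:
    """Stack annotations into the genome x phenotype binary matrix (BPM)."""
    if not annotations:
        raise ValueError("build_bpm requires at least one annotation")
    ids = [a.genome_id for a in annotations]
    if len(ids) != len(set(ids)):
        seen: set[str] = set()
        dups = sorted({g for g in ids if g in seen or seen.add(g)})
        raise ValueError(f"duplicate genome ids: {dups}")
    known_pathways = set(vocabulary.pathways)
    rows = []
    for ann in annotations:
        unknown = sorted(set(ann.pathway_calls) - known_pathways)
        if unknown:
            raise KeyError(
                f"{ann.genome_id}: pathway labels not in vocabulary: {unknown}"
            )
        row = {p: int(bool(ann.pathway_calls.get(p, 0))) for p in vocabulary.pathways}
        row.update(binarize_families(ann.family_counts, vocabulary))
        rows.append(row)
    bpm = pd.DataFrame(rows, index=pd.Index(ids, name="genome_id"))
    return bpm[list(vocabulary.all_labels)]


def taxon_phenotype_value(
    members: Iterable[Lineage],
    bpm: pd.DataFrame,
    genome_map: Mapping[Lineage, Sequence[str]],
) -> pd.Series | None:
    """Phenotype values of one phylotype: mean BPM over all member genomes.

    Genomes of all members are pooled unweighted.  Returns None when no
    member maps to any genome (the phylotype is unmapped).
    """
    genomes: list[str] = []
    for member in members:
        genomes.extend(genome_map.get(member, ()))
    if not genomes:
        return None
    return bpm.loc[genomes].mean(axis=0)


def phylotype_values(
    memberships: Mapping[str, Iterable[Lineage]],
    bpm: pd.DataFrame,
    genome_map: Mapping[Lineage, Sequence[str]],
) -> tuple[pd.DataFrame, list[str]]:
    """Per-phylotype phenotype values; unmapped phylotypes are excluded.

    Returns (phylotype x phenotype DataFrame, list of unmapped phylotypes).
    """
    values: dict[str, pd.Series] = {}
    unmapped: list[str] = []
    for name, members in memberships.items():
        v = taxon_phenotype_value(members, bpm, genome_map)
        if v is None:
            unmapped.append(name)
        else:
            values[name] = v
    frame = pd.DataFrame(values).T
    frame.index.name = "phylotype"
    return frame, unmapped


def community_phenotype_index(
    rel_abundance: pd.Series, taxon_values: pd.DataFrame
) -> pd.Series:
    """CPI for one sample: abundance-weighted mean of taxon phenotype values.

    Abundance is renormalized over mapped phylotypes (rows of
    ``taxon_values``) before the dot product, so CPI stays in [0, 1].
    """
    mapped = taxon_values.index.intersection(rel_abundance.index)
    a = rel_abundance.loc[mapped]
    total = float(a.sum())
    if total <= 0:
        raise ValueError("no mapped phylotypes with positive abundance")
    return taxon_values.loc[mapped].mul(a / total, axis=0).sum(axis=0)


def cpi_table(
    rel_abundance: pd.DataFrame, taxon_values: pd.DataFrame
) -> tuple[pd.DataFrame, pd.Series]:
    """CPI for every sample of a phylotype x sample relative-abundance table.

    Returns (sample x phenotype CPI table, per-sample mapped abundance
    fraction).  The mapped fraction reports how much community mass the
    genome mapping covered before renormalization.
    """
    mapped = taxon_values.index.intersection(rel_abundance.index)
    mapped_fraction = rel_abundance.loc[mapped].sum(axis=0)
    cpi = pd.DataFrame(
        {
            sample: community_phenotype_index(rel_abundance[sample], taxon_values)
            for sample in rel_abundance.columns
        }
    ).T
    cpi.index.name = "sample"
    return cpi, mapped_fraction


def phenotype_percent_change(
    cpi_treatment: Sequence[float], cpi_control: Sequence[float]
) -> float:
    """Signed percent change of mean CPI in treatment vs control replicates:
    ``100 * (mean_T - mean_C) / mean_C``."""
    t = np.asarray(cpi_treatment, dtype=float)
    c = np.asarray(cpi_control, dtype=float)
    if t.size == 0 or c.size == 0:
        raise ValueError("need at least one replicate per group")
    mean_c = float(c.mean())
    if mean_c == 0.0:
        raise ZeroDivisionError("control mean CPI is zero; percent change undefined")
    return 100.0 * (float(t.mean()) - mean_c) / mean_c


def net_family_shift(
    percent_changes: Mapping[str, float],
    p_values: Mapping[str, float] | None = None,
    alpha: float = 0.05,
    only_significant: bool = False,
) -> float:
    """Community-wide signed sum of per-family percent changes.

    With ``only_significant``, restrict to families whose test p-value
    (e.g. Mann-Whitney) is below ``alpha``.
    """
    if only_significant:
        if p_values is None:
            raise ValueError("only_significant requires p_values")
        return float(
            sum(
                v
                for fam, v in percent_changes.items()
                if p_values.get(fam, 1.0) < alpha
            )
        )
    return float(sum(percent_changes.values()))


def write_annotation_table(
    annotations: Sequence[GenomeAnnotation],
    vocabulary: PhenotypeVocabulary,
    path: str | Path,
) -> None:
    """Write genome annotations as a TSV: genome_id, lineage, one column per
    pathway (0/1) and family (raw count)."""
    rows = []
    for ann in annotations:
        row: dict[str, object] = {
            "genome_id": ann.genome_id,
            "lineage": ann.lineage.to_string(),
        }
        for p in vocabulary.pathways:
            row[p] = int(bool(ann.pathway_calls.get(p, 0)))
        for f in vocabulary.families:
            row[f] = int(ann.family_counts.get(f, 0))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_annotation_table(
    path: str | Path, vocabulary: PhenotypeVocabulary
) -> list[GenomeAnnotation]:
    """Read the TSV written by :func:`write_annotation_table`."""
    frame = pd.read_csv(path, sep="\t", dtype={"genome_id": str})
    annotations = []
    for _, row in frame.iterrows():
        annotations.append(
            GenomeAnnotation(
                genome_id=row["genome_id"],
                lineage=Lineage.from_string(row["lineage"]),
                family_counts={
                    f: int(row[f]) for f in vocabulary.families if f in frame.columns
                },
                pathway_calls={
                    p: int(row[p]) for p in vocabulary.pathways if p in frame.columns
                },
            )
        )
    return annotations
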