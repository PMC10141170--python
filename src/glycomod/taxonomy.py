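"""Multi-taxonomy ASV assignment and phylotype collapse.

Short 16S rRNA amplicons (e.g. the V3-V4 region) frequently match several
reference sequences at nearly indistinguishable percent identity, so forcing
each amplicon sequence variant (ASV) onto a single species overstates the
resolution of the data.  The multi-taxonomy approach (MTA) implemented here
instead admits *every* reference taxon whose alignment identity exceeds an
adaptive threshold ``t = M - (1 - M) / 4``, where ``M`` is the ASV's best
identity.  The window ``(t, M]`` widens as the best match degrades and
collapses to a point at ``M = 1``, so a perfect match is never diluted while
a mediocre one honestly reports its ambiguity.  The resulting assignment is
displayed as a "/"-joined multi-name (e.g.
``Bacteroides faecis/Bacteroides thetaiotaomicron``) and that multi-name —
the *phylotype* — is the downstream analysis unit; counts are never
fractionally split across member taxa.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "RANKS",
    "Lineage",
    "AlignmentHit",
    "MTAssignment",
    "PhylotypeCounts",
    "parse_hit_table",
    "read_taxonomy_table",
    "mta_threshold",
    "assign_asv",
    "assign_all",
    "phylotype_label",
    "collapse_to_phylotypes",
    "count_phylotypes",
    "write_assignment_report",
]

#: Fixed rank order, most inclusive first.
RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")

_RANK_INDEX = {r: i for i, r in enumerate(RANKS)}

# QIIME-style single-letter prefixes accepted (and stripped) in lineage strings.
_PREFIXES = {
    "d": "domain",
    "k": "domain",  # some taxonomies say kingdom
    "p": "phylum",
    "c": "class",
    "o": "order",
    "f": "family",
    "g": "genus",
    "s": "species",
}

#: Phylotype name used for ASVs without any alignment hit.
UNCLASSIFIED = "unclassified"


@dataclass(frozen=True, order=True)
class Lineage:
    """Ranked taxonomic lineage; labels may be absent below some rank.

    Labels must not contain the reserved ``/`` (multi-name separator) or
    ``;`` (lineage-string delimiter) characters.
    """

    domain: str | None = None
    phylum: str | None = None
    klass: str | None = None
    order: str | None = None
    family: str | None = None
    genus: str | None = None
    species: str | None = None

    def __post_init__(self) -> None:
        for label in self.labels():
            if label is not None and ("/" in label or ";" in label):
                raise ValueError(
                    f"taxon label {label!r} contains a reserved character ('/' or ';')"
                )

    def labels(self) -> tuple[str | None, ...]:
        return (
            self.domain,
            self.phylum,
            self.klass,
            self.order,
            self.family,
            self.genus,
            self.species,
        )

    def label_at(self, rank: str) -> str | None:
        if rank not in _RANK_INDEX:
            raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
        return self.labels()[_RANK_INDEX[rank]]

    def most_specific_label(self) -> str | None:
        """The deepest non-empty label (species first), or None."""
        for label in reversed(self.labels()):
            if label:
                return label
        return None

    @classmethod
    def from_string(cls, text: str) -> "Lineage":
        """Parse a semicolon-delimited lineage string.

        Accepts QIIME-style prefixes (``d__Bacteria;p__Bacteroidota;...``)
        or bare labels in fixed rank order.
        """
        fields: dict[str, str] = {}
        parts = [p.strip() for p in text.strip().split(";")]
        for i, part in enumerate(parts):
            if not part:
                continue
            if len(part) >= 3 and part[1:3] == "__" and part[0].lower() in _PREFIXES:
                rank = _PREFIXES[part[0].lower()]
                label = part[3:].strip()
            else:
                if i >= len(RANKS):
                    raise ValueError(f"lineage string has too many fields: {text!r}")
                rank = RANKS[i]
                label = part
            if label:
                fields[rank] = label
        return cls(
            domain=fields.get("domain"),
            phylum=fields.get("phylum"),
            klass=fields.get("class"),
            order=fields.get("order"),
            family=fields.get("family"),
            genus=fields.get("genus"),
            species=fields.get("species"),
        )

    def to_string(self) -> str:
        """QIIME-style prefixed semicolon-delimited representation."""
        prefixes = ("d", "p", "c", "o", "f", "g", "s")
        return ";".join(
            f"{p}__{label or ''}" for p, label in zip(prefixes, self.labels())
        )


@dataclass(frozen=True)
class AlignmentHit:
    """One ASV-vs-reference alignment; identity is a fraction in (0, 1]."""

    asv_id: str
    ref_id: str
    identity: float

    def __post_init__(self) -> None:
        if not 0.0 < self.identity <= 1.0:
            raise ValueError(
                f"identity must be in (0, 1], got {self.identity!r} "
                f"for {self.asv_id} vs {self.ref_id}"
            )


@dataclass(frozen=True)
class MTAssignment:
    """Multi-taxonomy assignment for one ASV.

    ``members`` holds every admissible lineage (identity strictly above the
    threshold, plus the best hit itself); ``display_name`` is the sorted,
    de-duplicated "/"-joined member species names.
    """

    asv_id: str
    max_identity: float
    threshold: float
    members: frozenset[Lineage]
    display_name: str


def parse_hit_table(
    source: str | Path | IO[str], dialect: str = "blast12"
) -> list[AlignmentHit]:
    """Parse a BLAST-style tabular alignment hit file.

    Only the first three columns are consumed: query id, subject id and
    percent identity (0-100, stored as a fraction).  Rows must have at least
    three columns; a malformed identity is a hard error naming the line.
    """
    if dialect != "blast12":
        raise ValueError(f"unknown hit-table dialect {dialect!r}")
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            return parse_hit_table(fh, dialect=dialect)

    hits: list[AlignmentHit] = []
    for lineno, line in enumerate(source, start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) < 3:
            raise ValueError(
                f"line {lineno}: expected >= 3 columns (qseqid, sseqid, pident), "
                f"got {len(parts)}"
            )
        try:
            pident = float(parts[2])
        except ValueError:
            raise ValueError(
                f"line {lineno}: percent identity {parts[2]!r} is not a number"
            ) from None
        if not 0.0 <= pident <= 100.0:
            raise ValueError(
                f"line {lineno}: percent identity {pident} outside [0, 100]"
            )
        hits.append(AlignmentHit(parts[0], parts[1], pident / 100.0))
    if not hits:
        warnings.warn("hit table contained no rows", stacklevel=2)
    return hits


def read_taxonomy_table(source: str | Path | IO[str]) -> dict[str, Lineage]:
    """Read a two-column TSV ``ref_id<TAB>lineage string`` into a mapping."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            return read_taxonomy_table(fh)
    taxonomy: dict[str, Lineage] = {}
    for lineno, line in enumerate(source, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ValueError(f"line {lineno}: expected 'ref_id<TAB>lineage'")
        taxonomy[parts[0]] = Lineage.from_string(parts[1])
    return taxonomy


def mta_threshold(m: float) -> float:
    """Adaptive identity threshold ``t = M - (1 - M) / 4``.

    ``t`` equals ``M`` only at ``M = 1``; the admission window ``(t, M]``
    has width ``(1 - M) / 4``.
    """
    if not 0.0 < m <= 1.0:
        raise ValueError(f"M must be in (0, 1], got {m!r}")
    return m - (1.0 - m) / 4.0


def _species_label(lineage: Lineage) -> str:
    return lineage.species or lineage.most_specific_label() or UNCLASSIFIED


def _display_name(members: Iterable[Lineage]) -> str:
    return "/".join(sorted({_species_label(m) for m in members}))


def assign_asv(
    hits: Sequence[AlignmentHit],
    taxonomy: Mapping[str, Lineage],
    decimals: int = 6,
) -> MTAssignment:
    """Assign a multi-taxonomy to one ASV from its alignment hits.

    Members are the lineages of hits with identity strictly greater than
    ``mta_threshold(M)``, plus (always) the lineage(s) achieving the maximum
    identity ``M``; members are de-duplicated by full lineage.  Identities
    are compared after rounding to ``decimals`` places so float noise cannot
    split ties carried with 2-3 decimals in tabular input.
    """
    if not hits:
        raise ValueError("assign_asv requires at least one hit")
    asv_ids = {h.asv_id for h in hits}
    if len(asv_ids) != 1:
        raise ValueError(f"hits span multiple ASVs: {sorted(asv_ids)}")
    missing = sorted({h.ref_id for h in hits} - set(taxonomy))
    if missing:
        raise KeyError(f"reference ids missing from taxonomy: {missing}")

    idents = [round(h.identity, decimals) for h in hits]
    m = max(idents)
    t = round(mta_threshold(m), decimals)
    members = {
        taxonomy[h.ref_id]
        for h, ident in zip(hits, idents)
        if ident > t or ident == m
    }
    return MTAssignment(
        asv_id=hits[0].asv_id,
        max_identity=m,
        threshold=t,
        members=frozenset(members),
        display_name=_display_name(members),
    )


def assign_all(
    hits: Iterable[AlignmentHit],
    taxonomy: Mapping[str, Lineage],
    decimals: int = 6,
) -> dict[str, MTAssignment]:
    """Group hits by ASV (input order preserved) and assign each one."""
    by_asv: dict[str, list[AlignmentHit]] = {}
    for hit in hits:
        by_asv.setdefault(hit.asv_id, []).append(hit)
    return {
        asv: assign_asv(asv_hits, taxonomy, decimals=decimals)
        for asv, asv_hits in by_asv.items()
    }


def phylotype_label(assignment: MTAssignment | None, rank: str) -> str:
    """Collapse an assignment's members to a label at ``rank``.

    If all members agree at the rank the common label is returned; otherwise
    the sorted "/"-joined multi-name of the per-member labels.  ``None``
    (no-hit ASV) maps to :data:`UNCLASSIFIED`.
    """
    if rank not in _RANK_INDEX:
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
    if assignment is None or not assignment.members:
        return UNCLASSIFIED
    labels = set()
    for member in assignment.members:
        label = member.label_at(rank)
        if rank == "species":
            label = label or _species_label(member)
        labels.add(label or member.most_specific_label() or UNCLASSIFIED)
    return "/".join(sorted(labels))


def collapse_to_phylotypes(
    asv_counts: pd.DataFrame,
    assignments: Mapping[str, MTAssignment | None],
    rank: str = "species",
) -> pd.DataFrame:
    """Collapse an ASV x sample count table to phylotypes at ``rank``.

    Each ASV's counts are added whole and undivided to exactly one
    phylotype, so column sums are conserved exactly.  ASVs missing from
    ``assignments`` collapse into :data:`UNCLASSIFIED`.  The returned
    table carries ``attrs['rank']`` and ``attrs['provenance']``
    (phylotype -> contributing ASV ids).
    """
    labels = {
        asv: phylotype_label(assignments.get(asv), rank) for asv in asv_counts.index
    }
    collapsed = asv_counts.groupby(pd.Series(labels), sort=True).sum()
    collapsed.index.name = "phylotype"
    provenance: dict[str, list[str]] = {}
    for asv, label in labels.items():
        provenance.setdefault(label, []).append(asv)
    collapsed.attrs["rank"] = rank
    collapsed.attrs["provenance"] = provenance
    return collapsed


@dataclass(frozen=True)
class PhylotypeCounts:
    """Summary of phylotype presence across culture conditions."""

    total_unique: int
    per_condition: dict[str, int]
    mean_per_condition: float


def count_phylotypes(
    tables: Mapping[str, pd.DataFrame], presence_floor: float = 1.0
) -> PhylotypeCounts:
    """Count unique and per-condition phylotypes.

    A phylotype is present in a condition if any replicate's abundance is
    at least ``presence_floor`` (default one count).  Totals de-duplicate
    by phylotype name across conditions.
    """
    per_condition: dict[str, int] = {}
    all_names: set[str] = set()
    for condition, table in tables.items():
        present = table.index[(table >= presence_floor).any(axis=1)]
        per_condition[condition] = len(present)
        all_names.update(present)
    mean = sum(per_condition.values()) / len(per_condition) if per_condition else 0.0
    return PhylotypeCounts(
        total_unique=len(all_names),
        per_condition=per_condition,
        mean_per_condition=mean,
    )


def write_assignment_report(
    assignments: Mapping[str, MTAssignment], path: str | Path
) -> None:
    """Write a per-ASV assignment report TSV."""
    rows = [
        {
            "asv_id": a.asv_id,
            "max_identity": a.max_identity,
            "threshold": a.threshold,
            "n_members": len(a.members),
            "display_name": a.display_name,
        }
        for a in assignments.values()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
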