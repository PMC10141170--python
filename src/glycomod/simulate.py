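"""Synthetic inputs with planted ground truth.

Generates every artifact the pipeline consumes — reference lineages with
integer 16S copy numbers (1-15) and genus-correlated phenotype content,
BLAST-style alignment hit tables exercising the multi-taxonomy admission
window, and replicated count tables for control and supplemented culture
conditions — so every stage is testable end-to-end without downloads.

The study design emulated: a pooled fecal inoculum grown in defined medium
with or without a glycan supplement, 6 technical replicates per condition
(the experimental range is 4-6), ~1e5 16S reads per replicate.  Baseline
relative abundances are log-normal (sigma = 1.5), mimicking skewed
communities dominated by a few families; technical replicates share one
underlying composition and differ only by multinomial sampling noise
(Dirichlet overdispersion is available but off by default).  Condition
effects are planted as per-taxon fold changes; responders default to taxa
with baseline relative abundance in [1e-3, 5e-3] — abundant enough to be
detectable at the stated depth, rare enough that a 10-fold expansion does
not drown the rest of the community through compositional dilution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .phenotype import (
    GenomeAnnotation,
    PhenotypeVocabulary,
    default_vocabulary,
    write_annotation_table,
)
from .taxonomy import AlignmentHit, Lineage

__all__ = [
    "ReferenceRecord",
    "SyntheticWorld",
    "Experiment",
    "DEFAULT_PREVALENCE",
    "generate_reference_database",
    "generate_hit_table",
    "choose_responder_taxa",
    "plant_overlapping_responders",
    "build_world",
    "generate_experiment",
    "write_world",
]


def _default_prevalence(vocabulary: PhenotypeVocabulary) -> dict[str, float]:
    base = {
        "acetate": 0.80,
        "propionate": 0.35,
        "butyrate": 0.30,
        "D-lactate": 0.30,
        "L-lactate": 0.45,
        "ethanol": 0.50,
        "formate": 0.60,
        "B1": 0.60,
        "B2": 0.65,
        "B3": 0.55,
        "B5": 0.50,
        "B6": 0.50,
        "B7": 0.35,
        "B9": 0.55,
        "B12": 0.35,
        "K": 0.45,
        "queuosine": 0.40,
        "lipoate": 0.30,
    }
    for gh in vocabulary.gh_families:
        base[gh] = 0.30
    for pl in vocabulary.pl_families:
        base[pl] = 0.12
    return base


#: Default per-phenotype carriage prevalences (fraction of genomes positive).
DEFAULT_PREVALENCE = _default_prevalence(default_vocabulary())


@dataclass(frozen=True)
class ReferenceRecord:
    """One reference organism: 16S record, copy number and genome content."""

    ref_id: str
    lineage: Lineage
    copy_number: int
    annotation: GenomeAnnotation


def generate_reference_database(
    n_species: int = 120,
    n_genera: int = 30,
    phenotype_prevalence: Mapping[str, float] | None = None,
    vocabulary: PhenotypeVocabulary | None = None,
    seed: int = 0,
    genus_concentration: float = 8.0,
) -> list[ReferenceRecord]:
    """Ranked reference lineages with genus-correlated phenotype draws.

    Each phenotype label has a target prevalence p; every genus draws a
    carriage probability from Beta(c*p, c*(1-p)) (c = ``genus_concentration``)
    and its species draw Bernoulli from that, so related species share
    traits while the marginal prevalence matches the target.  Positive
    CAZyme families get 1 + Poisson(2) enzyme copies; 16S copy numbers are
    integers in [1, 15].
    """
    if not 1 <= n_genera <= n_species:
        raise ValueError("need n_species >= n_genera >= 1")
    vocabulary = vocabulary or default_vocabulary()
    prevalence = dict(_default_prevalence(vocabulary))
    if phenotype_prevalence:
        unknown = sorted(set(phenotype_prevalence) - set(vocabulary.all_labels))
        if unknown:
            raise KeyError(f"prevalence given for unknown labels: {unknown}")
        prevalence.update(phenotype_prevalence)
    for label, p in prevalence.items():
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"prevalence for {label} outside [0, 1]: {p}")

    rng = np.random.default_rng(seed)
    labels = list(vocabulary.all_labels)
    targets = np.array([prevalence[l] for l in labels])

    # Genus-level carriage probabilities, clipped Beta around the target.
    c = genus_concentration
    genus_theta = np.empty((n_genera, len(labels)))
    for j, p in enumerate(targets):
        if p <= 0.0 or p >= 1.0:
            genus_theta[:, j] = p
        else:
            genus_theta[:, j] = rng.beta(c * p, c * (1.0 - p), size=n_genera)

    genus_of_species = np.sort(rng.integers(0, n_genera, size=n_species))
    # Guarantee every genus appears at least once when possible.
    genus_of_species[:n_genera] = np.arange(n_genera)
    genus_of_species = np.sort(genus_of_species)[:n_species]

    records: list[ReferenceRecord] = []
    per_genus_counter: dict[int, int] = {}
    for i in range(n_species):
        g = int(genus_of_species[i])
        per_genus_counter[g] = per_genus_counter.get(g, 0) + 1
        genus_name = f"Genus{g + 1:02d}"
        species_name = f"{genus_name} sp{per_genus_counter[g]:03d}"
        lineage = Lineage(
            domain="Bacteria",
            phylum=f"Phylum{g // 16 + 1:02d}",
            klass=f"Class{g // 8 + 1:02d}",
            order=f"Order{g // 4 + 1:02d}",
            family=f"Family{g // 2 + 1:02d}",
            genus=genus_name,
            species=species_name,
        )
        calls = (rng.random(len(labels)) < genus_theta[g]).astype(int)
        family_counts: dict[str, int] = {}
        pathway_calls: dict[str, int] = {}
        for label, call in zip(labels, calls):
            if label in vocabulary.families:
                family_counts[label] = int((1 + rng.poisson(2.0)) * call)
            else:
                pathway_calls[label] = int(call)
        ref_id = f"ref{i:04d}"
        records.append(
            ReferenceRecord(
                ref_id=ref_id,
                lineage=lineage,
                copy_number=int(rng.integers(1, 16)),
                annotation=GenomeAnnotation(
                    genome_id=f"gen{i:04d}",
                    lineage=lineage,
                    family_counts=family_counts,
                    pathway_calls=pathway_calls,
                ),
            )
        )
    return records


def generate_hit_table(
    references: Sequence[ReferenceRecord],
    ambiguity_rate: float = 0.2,
    seed: int = 0,
) -> tuple[list[AlignmentHit], dict[str, frozenset[str]], dict[str, str]]:
    """One ASV per reference with a controlled admission window.

    The top hit has identity M ~ Uniform(0.95, 1.0) (3 decimals).  With
    probability ``ambiguity_rate`` — and whenever the 3-decimal grid has
    room strictly inside (t, M) with t = M - (1-M)/4 — 1-3 decoy hits are
    planted inside the window (these become members) plus decoys strictly
    below t (which must not).  Identities are placed by integer
    milli-arithmetic so strict inequalities survive rounding exactly.

    Returns (hits, truth: asv_id -> member ref ids, sources:
    asv_id -> generating ref id).
    """
    if not 0.0 <= ambiguity_rate <= 1.0:
        raise ValueError("ambiguity_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    by_genus: dict[str, list[int]] = {}
    for i, rec in enumerate(references):
        by_genus.setdefault(rec.lineage.genus or "", []).append(i)

    hits: list[AlignmentHit] = []
    truth: dict[str, frozenset[str]] = {}
    sources: dict[str, str] = {}
    for i, rec in enumerate(references):
        asv_id = f"asv{i:04d}"
        sources[asv_id] = rec.ref_id
        m_milli = int(rng.integers(950, 1001))  # M in [0.950, 1.000]
        m = m_milli / 1000.0
        hits.append(AlignmentHit(asv_id, rec.ref_id, m))
        members = {rec.ref_id}

        # Integer bounds: k/1000 > t  <=>  4k > 5*m_milli - 1000.
        num = 5 * m_milli - 1000
        k_min = num // 4 + 1
        k_max = m_milli - 1
        other = [j for j in range(len(references)) if j != i]
        if other and k_min <= k_max and rng.random() < ambiguity_rate:
            same_genus = [j for j in by_genus[rec.lineage.genus or ""] if j != i]
            pool = same_genus if same_genus else other
            n_decoys = int(rng.integers(1, 4))
            picks = rng.choice(pool, size=min(n_decoys, len(pool)), replace=False)
            for j in picks:
                k = int(rng.integers(k_min, k_max + 1))
                hits.append(AlignmentHit(asv_id, references[j].ref_id, k / 1000.0))
                members.add(references[j].ref_id)

        # Below-threshold decoys: k/1000 < t  <=>  4k < 5*m_milli - 1000.
        k_below_max = (num - 1) // 4
        if other and k_below_max >= 750:
            n_below = int(rng.integers(1, 3))
            picks = rng.choice(other, size=min(n_below, len(other)), replace=False)
            for j in picks:
                k = int(rng.integers(750, k_below_max + 1))
                hits.append(AlignmentHit(asv_id, references[j].ref_id, k / 1000.0))
        truth[asv_id] = frozenset(members)
    return hits, truth, sources


def choose_responder_taxa(
    baseline: pd.Series,
    n: int,
    rng: np.random.Generator,
    band: tuple[float, float] = (1e-3, 5e-3),
    exclude: Sequence[str] = (),
) -> list[str]:
    """Pick ``n`` taxa to carry a planted effect, preferring the abundance
    band where effects are detectable yet compositionally mild.

    If the band holds fewer than ``n`` eligible taxa, the remainder is
    filled with the taxa nearest the band's geometric center.
    """
    eligible = baseline.drop(index=list(exclude), errors="ignore")
    in_band = eligible[(eligible >= band[0]) & (eligible <= band[1])]
    if len(in_band) >= n:
        return list(rng.choice(in_band.index, size=n, replace=False))
    center = np.sqrt(band[0] * band[1])
    ranked = (np.log(eligible) - np.log(center)).abs().sort_values()
    return list(ranked.index[:n])


def plant_overlapping_responders(
    baseline: pd.Series,
    rng: np.random.Generator,
    set_size: int = 16,
    overlap_fraction: float = 0.5,
    fold: float = 10.0,
    band: tuple[float, float] = (1e-3, 5e-3),
) -> tuple[dict[str, float], dict[str, float], frozenset[str], frozenset[str]]:
    """Two fold-change maps whose responder sets overlap by a known fraction.

    Both sets have ``set_size`` taxa and share ``round(q * set_size)`` of
    them, so the asymptotic pairwise f-score is 50 * q.
    Returns (folds_a, folds_b, taxa_a, taxa_b).
    """
    if not 0.0 <= overlap_fraction <= 1.0:
        raise ValueError("overlap_fraction must be in [0, 1]")
    n_shared = int(round(overlap_fraction * set_size))
    n_total = 2 * set_size - n_shared
    taxa = choose_responder_taxa(baseline, n_total, rng, band=band)
    shared = taxa[:n_shared]
    only_a = taxa[n_shared : set_size]
    only_b = taxa[set_size :]
    set_a = frozenset(shared + only_a)
    set_b = frozenset(shared + only_b)
    return (
        {t: fold for t in set_a},
        {t: fold for t in set_b},
        set_a,
        set_b,
    )


@dataclass
class SyntheticWorld:
    """A fully specified in-silico study: references, ASV registry,
    baseline composition, planted effects, and design constants."""

    references: list[ReferenceRecord]
    hits: list[AlignmentHit]
    hit_truth: dict[str, frozenset[str]]
    asv_sources: dict[str, str]
    baseline: pd.Series  # asv_id -> baseline relative abundance (sums to 1)
    effect_map: dict[str, dict[str, float]]  # condition -> asv_id -> fold
    conditions: list[str]  # includes the control
    control: str = "control"
    replicates: int = 6
    depth: int = 100_000
    seed: int = 0
    vocabulary: PhenotypeVocabulary = field(default_factory=default_vocabulary)

    def __post_init__(self) -> None:
        if not 4 <= self.replicates <= 6:
            raise ValueError("replicates must be in the experimental range 4-6")
        if self.control not in self.conditions:
            raise ValueError(f"control {self.control!r} missing from conditions")
        for condition, folds in self.effect_map.items():
            bad = [a for a, f in folds.items() if f <= 0]
            if bad:
                raise ValueError(f"{condition}: non-positive fold changes for {bad}")
        if self.effect_map.get(self.control):
            raise ValueError("control condition must have no planted effects")

    def display_name(self, asv_id: str) -> str:
        """Expected multi-taxonomy display name of an ASV (from planted truth)."""
        by_ref = {r.ref_id: r for r in self.references}
        labels = {
            by_ref[ref].lineage.species or by_ref[ref].lineage.most_specific_label()
            for ref in self.hit_truth[asv_id]
        }
        return "/".join(sorted(l for l in labels if l))


@dataclass
class Experiment:
    """Sampled count tables plus metadata and the planted ground truth."""

    counts: pd.DataFrame  # ASV x sample
    metadata: pd.DataFrame  # indexed by sample: condition, replicate
    ground_truth: dict[str, dict[str, list[str]]]


def build_world(
    n_species: int = 120,
    n_genera: int = 30,
    conditions: Sequence[str] = ("treatment",),
    n_responders: int = 15,
    fold: float = 10.0,
    replicates: int = 6,
    depth: int = 100_000,
    sigma: float = 1.5,
    ambiguity_rate: float = 0.2,
    seed: int = 0,
    effect_map: Mapping[str, Mapping[str, float]] | None = None,
    vocabulary: PhenotypeVocabulary | None = None,
    responder_band: tuple[float, float] = (1e-3, 5e-3),
    control: str = "control",
) -> SyntheticWorld:
    """Assemble a complete synthetic study.

    Unless an explicit ``effect_map`` is given, each non-control condition
    gets ``n_responders`` planted ``fold``-fold increases on taxa drawn
    from ``responder_band``.  Everything derives from ``seed``; the same
    seed yields byte-identical worlds.
    """
    vocabulary = vocabulary or default_vocabulary()
    references = generate_reference_database(
        n_species=n_species, n_genera=n_genera, vocabulary=vocabulary, seed=seed
    )
    hits, truth, sources = generate_hit_table(
        references, ambiguity_rate=ambiguity_rate, seed=seed + 1
    )
    rng = np.random.default_rng(seed + 2)
    raw = rng.lognormal(mean=0.0, sigma=sigma, size=n_species)
    baseline = pd.Series(raw / raw.sum(), index=sorted(sources))

    all_conditions = [control] + [c for c in conditions if c != control]
    if effect_map is not None:
        effects = {c: dict(effect_map.get(c, {})) for c in all_conditions}
    else:
        effects = {control: {}}
        for condition in all_conditions:
            if condition == control:
                continue
            chosen = choose_responder_taxa(
                baseline, n_responders, rng, band=responder_band
            )
            effects[condition] = {asv: fold for asv in chosen}
    return SyntheticWorld(
        references=references,
        hits=hits,
        hit_truth=truth,
        asv_sources=sources,
        baseline=baseline,
        effect_map=effects,
        conditions=all_conditions,
        control=control,
        replicates=replicates,
        depth=depth,
        seed=seed,
        vocabulary=vocabulary,
    )


def generate_experiment(
    world: SyntheticWorld,
    dirichlet_concentration: float | None = None,
) -> Experiment:
    """Sample replicate count tables from a world.

    Per condition the baseline is multiplied by the planted fold changes and
    renormalized; each technical replicate is an independent multinomial of
    ``world.depth`` reads from that shared composition.  Setting
    ``dirichlet_concentration`` adds between-replicate Dirichlet
    overdispersion (smaller = noisier); the default None keeps pure
    technical (multinomial) noise.
    """
    rng = np.random.default_rng([world.seed, 3])
    asvs = list(world.baseline.index)
    columns: dict[str, np.ndarray] = {}
    meta_rows = []
    ground_truth: dict[str, dict[str, list[str]]] = {}
    for condition in world.conditions:
        folds = world.effect_map.get(condition, {})
        weights = world.baseline.copy()
        for asv, f in folds.items():
            weights.loc[asv] *= f
        p = (weights / weights.sum()).to_numpy()
        for rep in range(1, world.replicates + 1):
            sample = f"{condition}_r{rep}"
            p_rep = p
            if dirichlet_concentration is not None:
                p_rep = rng.dirichlet(p * dirichlet_concentration)
            columns[sample] = rng.multinomial(world.depth, p_rep)
            meta_rows.append(
                {"sample": sample, "condition": condition, "replicate": rep}
            )
        ground_truth[condition] = {
            "increased": sorted(
                world.display_name(a) for a, f in folds.items() if f > 1
            ),
            "decreased": sorted(
                world.display_name(a) for a, f in folds.items() if f < 1
            ),
        }
    counts = pd.DataFrame(columns, index=pd.Index(asvs, name="asv_id"))
    metadata = pd.DataFrame(meta_rows).set_index("sample")
    return Experiment(counts=counts, metadata=metadata, ground_truth=ground_truth)


def write_world(
    world: SyntheticWorld, experiment: Experiment, outdir: str | Path
) -> dict[str, Path]:
    """Emit every pipeline input format plus the ground-truth report.

    Writes hits.tsv (12-column alignment tabular), taxonomy.tsv,
    copy_numbers.tsv, annotations.tsv, counts.tsv, metadata.tsv,
    vocabulary.json and ground_truth.json; returns the path of each.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["hits"] = outdir / "hits.tsv"
    with open(paths["hits"], "w") as fh:
        for h in world.hits:
            pident = f"{h.identity * 100.0:.3f}"
            # qseqid sseqid pident length mismatch gapopen qstart qend
            # sstart send evalue bitscore — alignment geometry is not
            # consumed downstream, placeholders keep the 12-column shape.
            fh.write(
                f"{h.asv_id}\t{h.ref_id}\t{pident}\t250\t0\t0\t1\t250\t1\t250"
                f"\t0.0\t500\n"
            )

    paths["taxonomy"] = outdir / "taxonomy.tsv"
    with open(paths["taxonomy"], "w") as fh:
        for rec in world.references:
            fh.write(f"{rec.ref_id}\t{rec.lineage.to_string()}\n")

    paths["copy_numbers"] = outdir / "copy_numbers.tsv"
    with open(paths["copy_numbers"], "w") as fh:
        for rec in world.references:
            fh.write(f"{rec.lineage.to_string()}\t{rec.copy_number}\n")

    paths["annotations"] = outdir / "annotations.tsv"
    write_annotation_table(
        [rec.annotation for rec in world.references],
        world.vocabulary,
        paths["annotations"],
    )

    paths["counts"] = outdir / "counts.tsv"
    experiment.counts.to_csv(paths["counts"], sep="\t")

    paths["metadata"] = outdir / "metadata.tsv"
    experiment.metadata.to_csv(paths["metadata"], sep="\t")

    paths["vocabulary"] = outdir / "vocabulary.json"
    world.vocabulary.to_json(paths["vocabulary"])

    paths["ground_truth"] = outdir / "ground_truth.json"
    truth = {
        "effect_map": {
            c: {a: f for a, f in folds.items()}
            for c, folds in world.effect_map.items()
        },
        "responders": experiment.ground_truth,
        "seed": world.seed,
        "depth": world.depth,
        "replicates": world.replicates,
    }
    paths["ground_truth"].write_text(json.dumps(truth, indent=1, sort_keys=True))
    return paths
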