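"""Config-driven orchestration of the full analysis.

Stage order: parse & assign (MTA) -> collapse to phylotypes -> copy-number
renormalization -> diversity & ordination -> five-fold modulation +
Mann-Whitney tests -> community phenotype indices & phenotype shifts ->
pairwise f-scores.  Every run writes its outputs plus a manifest recording
the configuration, package version and input checksums, so reruns are
byte-comparable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .copy_number import estimate_copy_number, read_copy_number_table
from .fscore import pairwise_f_matrix, responder_set
from .phenotype import (
    PhenotypeVocabulary,
    build_bpm,
    cpi_table,
    default_vocabulary,
    net_family_shift,
    phenotype_percent_change,
    phylotype_values,
    read_annotation_table,
)
from .stats import (
    apply_pseudocount,
    bray_curtis_matrix,
    mann_whitney_exact,
    pcoa,
    shannon_diversity,
    treatment_vs_control,
)
from .taxonomy import (
    assign_all,
    collapse_to_phylotypes,
    parse_hit_table,
    read_taxonomy_table,
    write_assignment_report,
)

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger("glycomod")


@dataclass
class RunConfig:
    """All knobs of one pipeline run."""

    hits: str
    taxonomy: str
    copy_numbers: str
    annotations: str
    counts: str
    metadata: str
    outdir: str
    control: str = "control"
    vocabulary: str | None = None  # JSON path; None -> default vocabulary
    alpha: float = 0.05
    fold_cutoff: float = 5.0
    pseudo: float = 0.5
    shannon_base: float | None = None  # None -> natural log
    rank: str = "species"
    mta_decimals: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.fold_cutoff <= 1.0:
            raise ValueError(f"fold cutoff must exceed 1, got {self.fold_cutoff}")
        if self.pseudo <= 0.0:
            raise ValueError(f"pseudo must be positive, got {self.pseudo}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        payload.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**payload)

    @classmethod
    def from_dir(cls, input_dir: str | Path, outdir: str | Path,
                 **overrides) -> "RunConfig":
        """Convenience constructor for a directory of standard-named inputs
        (as written by :func:`glycomod.simulate.write_world`)."""
        d = Path(input_dir)
        vocab = d / "vocabulary.json"
        return cls(
            hits=str(d / "hits.tsv"),
            taxonomy=str(d / "taxonomy.tsv"),
            copy_numbers=str(d / "copy_numbers.tsv"),
            annotations=str(d / "annotations.tsv"),
            counts=str(d / "counts.tsv"),
            metadata=str(d / "metadata.tsv"),
            vocabulary=str(vocab) if vocab.exists() else None,
            outdir=str(outdir),
            **overrides,
        )


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Execute every stage and return the run directory.

    Any stage failure aborts with the stage name attached to the raised
    exception.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}
    stage = "validate-config"
    try:
        # --- load inputs -------------------------------------------------
        stage = "load-inputs"
        hits = parse_hit_table(config.hits)
        taxonomy = read_taxonomy_table(config.taxonomy)
        cn_index = read_copy_number_table(config.copy_numbers)
        vocabulary = (
            PhenotypeVocabulary.from_json(config.vocabulary)
            if config.vocabulary
            else default_vocabulary()
        )
        annotations = read_annotation_table(config.annotations, vocabulary)
        counts = pd.read_csv(config.counts, sep="\t", index_col=0)
        metadata = pd.read_csv(config.metadata, sep="\t", index_col=0)
        if config.control not in set(metadata["condition"]):
            raise ValueError(
                f"control condition {config.control!r} absent from metadata"
            )
        missing = [s for s in counts.columns if s not in metadata.index]
        if missing:
            raise ValueError(f"samples without metadata: {missing}")

        # --- stage 1: multi-taxonomy assignment --------------------------
        stage = "assign"
        assignments = assign_all(hits, taxonomy, decimals=config.mta_decimals)
        write_assignment_report(assignments, outdir / "assignment_report.tsv")
        outputs["assign"] = "assignment_report.tsv"

        # --- stage 2: collapse to phylotypes -----------------------------
        stage = "collapse"
        phylotypes = collapse_to_phylotypes(counts, assignments, rank=config.rank)
        phylotypes.to_csv(outdir / "phylotypes.tsv", sep="\t")
        outputs["collapse"] = "phylotypes.tsv"

        # --- stage 3: copy-number renormalization ------------------------
        stage = "renormalize"
        provenance = phylotypes.attrs["provenance"]
        cn = pd.Series(
            {
                name: sum(
                    estimate_copy_number(assignments[a], cn_index)
                    if a in assignments
                    else cn_index.global_mean
                    for a in asvs
                )
                / len(asvs)
                for name, asvs in provenance.items()
            }
        )
        padded = apply_pseudocount(phylotypes, config.pseudo)
        weighted = padded.div(cn, axis=0)
        rel = weighted.div(weighted.sum(axis=0), axis=1)
        rel.to_csv(outdir / "relative_abundance.tsv", sep="\t")
        outputs["renormalize"] = "relative_abundance.tsv"

        # --- stage 4: diversity and ordination ---------------------------
        stage = "diversity"
        diversity = pd.DataFrame(
            {
                "shannon": {
                    s: shannon_diversity(rel[s], base=config.shannon_base)
                    for s in rel.columns
                }
            }
        )
        diversity.index.name = "sample"
        diversity.to_csv(outdir / "diversity.tsv", sep="\t")
        distances = bray_curtis_matrix(rel)
        ordination = pcoa(distances)
        coords = ordination.coordinates.copy()
        coords.columns = [f"PCo{i + 1}" for i in range(coords.shape[1])]
        coords.to_csv(outdir / "pcoa_coordinates.tsv", sep="\t")
        outputs["diversity"] = "diversity.tsv"

        # --- stage 5: modulation calls and tests -------------------------
        stage = "modulation"
        conditions = [
            c for c in metadata["condition"].unique() if c != config.control
        ]
        pseudo_mask = phylotypes == 0
        stats_frames = []
        for condition in conditions:
            frame = treatment_vs_control(
                weighted,
                metadata,
                treatment=condition,
                control=config.control,
                pseudo=config.pseudo,
                cutoff=config.fold_cutoff,
                run_t_test=True,
            )
            frame["used_pseudo"] = pseudo_mask.loc[frame.index].any(axis=1)
            stats_frames.append(frame.reset_index())
        stats_long = pd.concat(stats_frames, ignore_index=True)
        stats_long.to_csv(outdir / "modulation_stats.tsv", sep="\t", index=False)
        outputs["modulation"] = "modulation_stats.tsv"

        # --- stage 6: community phenotype indices ------------------------
        stage = "cpi"
        bpm = build_bpm(annotations, vocabulary)
        genome_map: dict = {}
        for ann in annotations:
            genome_map.setdefault(ann.lineage, []).append(ann.genome_id)
        memberships = {}
        for name, asvs in provenance.items():
            members = set()
            for a in asvs:
                if a in assignments:
                    members.update(assignments[a].members)
            memberships[name] = members
        taxon_values, unmapped = phylotype_values(memberships, bpm, genome_map)
        if unmapped:
            log.info("unmapped phylotypes excluded from CPI: %s", unmapped)
        cpi, mapped_fraction = cpi_table(rel, taxon_values)
        cpi.to_csv(outdir / "cpi.tsv", sep="\t")
        mapped_fraction.rename("mapped_fraction").to_csv(
            outdir / "mapped_fraction.tsv", sep="\t"
        )
        change_rows = []
        control_samples = metadata.index[metadata["condition"] == config.control]
        for condition in conditions:
            t_samples = metadata.index[metadata["condition"] == condition]
            for phenotype in cpi.columns:
                tv = cpi.loc[t_samples, phenotype].to_numpy()
                cv = cpi.loc[control_samples, phenotype].to_numpy()
                pct = (
                    phenotype_percent_change(tv, cv)
                    if cv.mean() > 0
                    else float("nan")
                )
                change_rows.append(
                    {
                        "treatment": condition,
                        "phenotype": phenotype,
                        "percent_change": pct,
                        "p_mw": mann_whitney_exact(tv, cv).p_value,
                    }
                )
        changes = pd.DataFrame(change_rows)
        changes.to_csv(outdir / "phenotype_changes.tsv", sep="\t", index=False)
        family_set = set(vocabulary.families)
        shift_rows = []
        for condition in conditions:
            block = changes[
                (changes["treatment"] == condition)
                & changes["phenotype"].isin(family_set)
            ]
            pct = dict(zip(block["phenotype"], block["percent_change"]))
            pvals = dict(zip(block["phenotype"], block["p_mw"]))
            shift_rows.append(
                {
                    "treatment": condition,
                    "net_family_shift": net_family_shift(pct),
                    "net_family_shift_significant": net_family_shift(
                        pct, pvals, alpha=config.alpha, only_significant=True
                    ),
                }
            )
        pd.DataFrame(shift_rows).to_csv(
            outdir / "net_family_shift.tsv", sep="\t", index=False
        )
        outputs["cpi"] = "cpi.tsv"

        # --- stage 7: pairwise f-scores ----------------------------------
        stage = "fscore"
        if len(conditions) >= 2:
            sets = [
                responder_set(
                    stats_long[stats_long["treatment"] == c].set_index("phylotype"),
                    treatment=c,
                    alpha=config.alpha,
                )
                for c in conditions
            ]
            matrix = pairwise_f_matrix(sets)
            matrix.to_long().to_csv(
                outdir / "fscore_long.tsv", sep="\t", index=False
            )
            matrix.to_square().to_csv(outdir / "fscore_matrix.tsv", sep="\t")
            outputs["fscore"] = "fscore_long.tsv"
        else:
            outputs["fscore"] = ""
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "version": __version__,
        "config": dataclasses.asdict(config),
        "input_checksums": {
            name: _sha256(getattr(config, name))
            for name in (
                "hits",
                "taxonomy",
                "copy_numbers",
                "annotations",
                "counts",
                "metadata",
            )
        },
        "stages": outputs,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                     sort_keys=True))
    return outdir
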