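"""Responder-overlap (f-score) analysis and response-instance accounting.

For each pair of treatments, count the taxa significantly increased by both
(the overlap ``o``) and the sum of taxa significantly increased by each
alone (``s = |A| + |B|``); the pair's f-score is ``f% = 100 * o / s``,
bounded above by 50 (reached only for identical non-empty responder sets).
Cross-class prebiotic-herb profiles flag pairs with f above a threshold
(default 10), which reads as shared substrate accessibility between a
defined glycan and an undefined herb polysaccharide pool.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ResponderSet",
    "FScore",
    "FScoreMatrix",
    "responder_set",
    "f_score",
    "pairwise_f_matrix",
    "prebiotic_herb_profile",
    "load_treatment_metadata",
    "tabulate_response_instances",
]


@dataclass(frozen=True)
class ResponderSet:
    """Taxa significantly modulated in one direction by one treatment."""

    treatment: str
    taxa: frozenset[str]
    alpha: float = 0.05
    direction: str = "increased"


@dataclass(frozen=True)
class FScore:
    """Overlap statistic of one treatment pair."""

    treatment_a: str
    treatment_b: str
    o: int  # |A ∩ B|
    s: int  # |A| + |B|
    f: float | None  # 100 * o / s, undefined (None) when s == 0


def responder_set(
    stats: pd.DataFrame,
    treatment: str | None = None,
    alpha: float = 0.05,
    direction: str = "increased",
    p_column: str = "p_mw",
) -> ResponderSet:
    """Extract the responder set from a per-phylotype stats table.

    ``stats`` is the output of
    :func:`glycomod.stats.treatment_vs_control` (indexed by phylotype, with
    ``p_mw``, ``mean_treatment``, ``mean_control`` columns).  Responders
    have p < alpha and, for the default increased direction, a treatment
    mean strictly above the control mean.
    """
    if direction not in ("increased", "decreased"):
        raise ValueError("direction must be 'increased' or 'decreased'")
    if treatment is None:
        treatments = stats["treatment"].unique()
        if len(treatments) != 1:
            raise ValueError("stats table spans multiple treatments; pass one")
        treatment = str(treatments[0])
    significant = stats[p_column] < alpha
    if direction == "increased":
        moved = stats["mean_treatment"] > stats["mean_control"]
    else:
        moved = stats["mean_treatment"] < stats["mean_control"]
    taxa = frozenset(str(t) for t in stats.index[significant & moved])
    return ResponderSet(treatment=treatment, taxa=taxa, alpha=alpha,
                        direction=direction)


def f_score(a: ResponderSet | Iterable[str], b: ResponderSet | Iterable[str]
            ) -> FScore:
    """Overlap o, sum s and f% = 100*o/s for two responder sets.

    f is undefined (None) when both sets are empty — "no responders" is
    distinct from "no overlap".
    """
    name_a = a.treatment if isinstance(a, ResponderSet) else "A"
    name_b = b.treatment if isinstance(b, ResponderSet) else "B"
    set_a = set(a.taxa if isinstance(a, ResponderSet) else a)
    set_b = set(b.taxa if isinstance(b, ResponderSet) else b)
    o = len(set_a & set_b)
    s = len(set_a) + len(set_b)
    f = 100.0 * o / s if s > 0 else None
    return FScore(name_a, name_b, o, s, f)


class FScoreMatrix:
    """Symmetric collection of pairwise f-scores over treatments."""

    def __init__(self, scores: Sequence[FScore], treatments: Sequence[str]):
        self.treatments = list(treatments)
        self._scores: dict[frozenset[str], FScore] = {}
        for score in scores:
            key = frozenset((score.treatment_a, score.treatment_b))
            self._scores[key] = score

    def __getitem__(self, pair: tuple[str, str]) -> FScore:
        return self._scores[frozenset(pair)]

    def __len__(self) -> int:
        return len(self._scores)

    def to_long(self) -> pd.DataFrame:
        rows = [
            {
                "treatment_a": s.treatment_a,
                "treatment_b": s.treatment_b,
                "o": s.o,
                "s": s.s,
                "f": np.nan if s.f is None else s.f,
            }
            for s in self._scores.values()
        ]
        return pd.DataFrame(rows)

    def to_square(self) -> pd.DataFrame:
        n = len(self.treatments)
        square = pd.DataFrame(
            np.full((n, n), np.nan), index=self.treatments, columns=self.treatments
        )
        for score in self._scores.values():
            value = np.nan if score.f is None else score.f
            square.loc[score.treatment_a, score.treatment_b] = value
            square.loc[score.treatment_b, score.treatment_a] = value
        return square


def pairwise_f_matrix(sets: Sequence[ResponderSet]) -> FScoreMatrix:
    """All unordered treatment pairs (12 treatments -> 66 pairs)."""
    if len(sets) < 2:
        raise ValueError("need at least two responder sets")
    names = [s.treatment for s in sets]
    if len(names) != len(set(names)):
        seen: set[str] = set()
        dups = sorted({n for n in names if n in seen or seen.add(n)})
        raise ValueError(f"duplicate treatment names: {dups}")
    scores = [f_score(a, b) for a, b in itertools.combinations(sets, 2)]
    return FScoreMatrix(scores, names)


def prebiotic_herb_profile(
    matrix: FScoreMatrix,
    metadata: pd.DataFrame,
    threshold: float = 10.0,
) -> pd.DataFrame:
    """Per-prebiotic summary of herb pairs with f strictly above threshold.

    ``metadata`` is indexed by treatment with a ``class`` column
    (prebiotic / herb / mucin / control); mucin is profiled alongside the
    prebiotics.  Returns one row per prebiotic: the herbs above threshold,
    their count, and the mean / min / max of those f values.
    """
    classes = metadata["class"]
    left = [t for t in matrix.treatments if classes.get(t) in ("prebiotic", "mucin")]
    herbs = [t for t in matrix.treatments if classes.get(t) == "herb"]
    rows = []
    for prebiotic in left:
        hits: list[tuple[str, float]] = []
        for herb in herbs:
            score = matrix[(prebiotic, herb)]
            if score.f is not None and score.f > threshold:
                hits.append((herb, score.f))
        values = [f for _, f in hits]
        rows.append(
            {
                "prebiotic": prebiotic,
                "n_herbs": len(hits),
                "herbs": ",".join(h for h, _ in sorted(hits)),
                "mean_f": float(np.mean(values)) if values else np.nan,
                "min_f": min(values) if values else np.nan,
                "max_f": max(values) if values else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("prebiotic")


def load_treatment_metadata() -> pd.DataFrame:
    """Packaged treatment roster: 11 prebiotic fibers, mucin and 17 herbs
    with group / sugar / linkage descriptors, indexed by treatment."""
    with resources.files("glycomod.data").joinpath("treatments.tsv").open() as fh:
        frame = pd.read_csv(fh, sep="\t", dtype=str, keep_default_na=False)
    return frame.set_index("treatment")


def tabulate_response_instances(
    calls: pd.DataFrame,
    taxon_col: str = "taxon",
    treatment_col: str = "treatment",
    class_col: str = "class",
    change_col: str = "change",
) -> dict[str, object]:
    """Instance accounting of a taxon x treatment response grid.

    ``calls`` holds one row per (taxon, treatment) combination with the
    treatment class and a change label in {"increased", "decreased", "ns"}.
    Returns totals and percentages: every (taxon, treatment) combination is
    an *instance*; the percent significant is over all combinations, and
    per-class increased/decreased percentages are over that class's
    (taxa x class-treatments) instances.
    """
    taxa = calls[taxon_col].unique()
    treatments = calls[treatment_col].unique()
    n_taxa, n_treatments = len(taxa), len(treatments)
    n_combinations = n_taxa * n_treatments
    if len(calls) != n_combinations:
        raise ValueError(
            f"expected a complete grid of {n_combinations} rows, got {len(calls)}"
        )
    significant = calls[change_col] != "ns"
    summary: dict[str, object] = {
        "n_taxa": n_taxa,
        "n_treatments": n_treatments,
        "n_combinations": n_combinations,
        "n_significant": int(significant.sum()),
        "pct_significant": 100.0 * float(significant.mean()),
        "per_class": {},
    }
    class_of = calls.groupby(treatment_col)[class_col].first()
    for cls in class_of.unique():
        cls_treatments = class_of.index[class_of == cls]
        block = calls[calls[treatment_col].isin(cls_treatments)]
        denom = n_taxa * len(cls_treatments)
        increased = int((block[change_col] == "increased").sum())
        decreased = int((block[change_col] == "decreased").sum())
        summary["per_class"][cls] = {
            "n_treatments": len(cls_treatments),
            "n_instances": denom,
            "n_increased": increased,
            "pct_increased": 100.0 * increased / denom,
            "n_decreased": decreased,
            "pct_decreased": 100.0 * decreased / denom,
        }
    return summary
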