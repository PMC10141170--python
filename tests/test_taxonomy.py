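"""Multi-taxonomy assignment, threshold arithmetic and phylotype collapse."""

import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from glycomod.taxonomy import (
    AlignmentHit,
    Lineage,
    assign_asv,
    collapse_to_phylotypes,
    count_phylotypes,
    mta_threshold,
    parse_hit_table,
    phylotype_label,
    read_taxonomy_table,
)

from conftest import make_lineage


class TestParseHitTable:
    def test_percent_identity_converted_to_fraction(self):
        hits = parse_hit_table(io.StringIO("asv1\trefA\t98.0\t250\t5\t0\n"))
        assert hits == [AlignmentHit("asv1", "refA", 0.98)]

    def test_full_identity_row(self):
        hits = parse_hit_table(io.StringIO("asv1 refA 100.000"))
        assert hits[0].identity == 1.0

    def test_empty_input_warns_and_returns_empty(self):
        with pytest.warns(UserWarning, match="no rows"):
            assert parse_hit_table(io.StringIO("")) == []

    def test_identity_out_of_range_names_line(self):
        stream = io.StringIO("asv1\trefA\t98.0\nasv2\trefB\t101.0\n")
        with pytest.raises(ValueError, match="line 2"):
            parse_hit_table(stream)

    def test_too_few_columns_rejected(self):
        with pytest.raises(ValueError, match="3 columns"):
            parse_hit_table(io.StringIO("asv1\trefA\n"))


class TestMtaThreshold:
    @pytest.mark.parametrize(
        "m,expected", [(1.0, 1.0), (0.96, 0.95), (0.90, 0.875)]
    )
    def test_formula(self, m, expected):
        assert mta_threshold(m) == pytest.approx(expected)

    @pytest.mark.parametrize("m", [0.0, -0.1, 1.2])
    def test_domain_enforced(self, m):
        with pytest.raises(ValueError):
            mta_threshold(m)

    @given(
        st.floats(min_value=0.01, max_value=1.0),
        st.floats(min_value=0.01, max_value=1.0),
    )
    def test_monotone_and_window_shrinks(self, m1, m2):
        if m1 > m2:
            assert mta_threshold(m1) > mta_threshold(m2)
        assert m1 - mta_threshold(m1) == pytest.approx((1 - m1) / 4)


class TestAssignAsv:
    def test_window_admits_near_ties_only(self, bacteroides_taxonomy):
        # M = 0.98 -> t = 0.975; 0.976 in, 0.970 out.
        hits = [
            AlignmentHit("asv1", "refA", 0.98),
            AlignmentHit("asv1", "refB", 0.976),
            AlignmentHit("asv1", "refC", 0.970),
        ]
        a = assign_asv(hits, bacteroides_taxonomy)
        assert a.members == frozenset(
            {bacteroides_taxonomy["refA"], bacteroides_taxonomy["refB"]}
        )
        assert a.display_name == (
            "Bacteroides faecis/Bacteroides thetaiotaomicron"
        )

    def test_single_hit(self, bacteroides_taxonomy):
        a = assign_asv([AlignmentHit("x", "refA", 0.99)], bacteroides_taxonomy)
        assert a.members == frozenset({bacteroides_taxonomy["refA"]})
        assert a.display_name == "Bacteroides faecis"

    def test_identical_lineages_deduplicated(self, bacteroides_taxonomy):
        taxonomy = dict(bacteroides_taxonomy)
        taxonomy["refA2"] = taxonomy["refA"]
        hits = [
            AlignmentHit("x", "refA", 0.97),
            AlignmentHit("x", "refA2", 0.97),
        ]
        assert len(assign_asv(hits, taxonomy).members) == 1

    def test_missing_reference_listed(self, bacteroides_taxonomy):
        with pytest.raises(KeyError, match="refZ"):
            assign_asv([AlignmentHit("x", "refZ", 0.99)], bacteroides_taxonomy)

    def test_top_hit_always_member_random_hit_sets(self, bacteroides_taxonomy):
        """Agreement with an exhaustive filter-and-dedupe oracle."""
        rng = np.random.default_rng(42)
        refs = list(bacteroides_taxonomy)
        for _ in range(200):
            n = rng.integers(1, 21)
            hits = [
                AlignmentHit("x", refs[rng.integers(len(refs))],
                             round(float(rng.uniform(0.9, 1.0)), 3))
                for _ in range(n)
            ]
            a = assign_asv(hits, bacteroides_taxonomy)
            m = max(round(h.identity, 6) for h in hits)
            t = m - (1 - m) / 4
            oracle = {
                bacteroides_taxonomy[h.ref_id]
                for h in hits
                if round(h.identity, 6) > round(t, 6)
                or round(h.identity, 6) == m
            }
            assert a.members == oracle
            best = {bacteroides_taxonomy[h.ref_id] for h in hits
                    if round(h.identity, 6) == m}
            assert best <= a.members


class TestCollapse:
    def _assignments(self, taxonomy):
        return {
            "asv1": assign_asv([AlignmentHit("asv1", "refA", 0.99)], taxonomy),
            "asv2": assign_asv([AlignmentHit("asv2", "refA", 0.98)], taxonomy),
            "asv3": assign_asv(
                [AlignmentHit("asv3", "refA", 0.98),
                 AlignmentHit("asv3", "refB", 0.979)],
                taxonomy,
            ),
        }

    def test_counts_conserved_and_summed(self, bacteroides_taxonomy):
        counts = pd.DataFrame(
            {"s1": [10, 5, 3], "s2": [0, 2, 7]},
            index=["asv1", "asv2", "asv3"],
        )
        table = collapse_to_phylotypes(
            counts, self._assignments(bacteroides_taxonomy), "species"
        )
        assert table.loc["Bacteroides faecis", "s1"] == 15
        assert (table.sum() == counts.sum()).all()

    def test_multi_name_species_group(self, bacteroides_taxonomy):
        counts = pd.DataFrame({"s1": [4]}, index=["asv3"])
        table = collapse_to_phylotypes(
            counts, self._assignments(bacteroides_taxonomy), "species"
        )
        assert list(table.index) == [
            "Bacteroides faecis/Bacteroides thetaiotaomicron"
        ]

    def test_family_agreement_gives_single_name(self, bacteroides_taxonomy):
        counts = pd.DataFrame({"s1": [4]}, index=["asv3"])
        table = collapse_to_phylotypes(
            counts, self._assignments(bacteroides_taxonomy), "family"
        )
        assert list(table.index) == ["Bacteroidaceae"]

    def test_higher_rank_never_more_phylotypes(self, bacteroides_taxonomy):
        counts = pd.DataFrame(
            {"s1": [1, 2, 3]}, index=["asv1", "asv2", "asv3"]
        )
        assignments = self._assignments(bacteroides_taxonomy)
        n_by_rank = [
            len(collapse_to_phylotypes(counts, assignments, r))
            for r in ("species", "genus", "family", "domain")
        ]
        assert n_by_rank == sorted(n_by_rank, reverse=True)

    def test_unknown_rank_rejected(self, bacteroides_taxonomy):
        with pytest.raises(ValueError, match="rank"):
            phylotype_label(None, "strain")

    def test_unassigned_asv_goes_to_unclassified(self, bacteroides_taxonomy):
        counts = pd.DataFrame({"s1": [9]}, index=["asvX"])
        table = collapse_to_phylotypes(counts, {}, "species")
        assert table.loc["unclassified", "s1"] == 9


class TestCountPhylotypes:
    def test_identical_sets(self):
        t = pd.DataFrame(np.ones((50, 2)), index=[f"p{i}" for i in range(50)])
        result = count_phylotypes({"a": t, "b": t})
        assert result.total_unique == 50
        assert result.mean_per_condition == 50

    def test_disjoint_sets(self):
        a = pd.DataFrame(np.ones((30, 1)), index=[f"p{i}" for i in range(30)])
        b = pd.DataFrame(np.ones((20, 1)), index=[f"q{i}" for i in range(20)])
        result = count_phylotypes({"a": a, "b": b})
        assert result.total_unique == 50
        assert result.mean_per_condition == 25

    def test_matches_brute_force_set_arithmetic(self):
        rng = np.random.default_rng(3)
        names = [f"p{i}" for i in range(40)]
        tables = {
            c: pd.DataFrame(
                rng.integers(0, 3, size=(40, 4)), index=names
            )
            for c in ("x", "y", "z")
        }
        result = count_phylotypes(tables, presence_floor=1)
        present = {
            c: {n for n in names if (t.loc[n] >= 1).any()}
            for c, t in tables.items()
        }
        assert result.total_unique == len(set().union(*present.values()))
        assert result.per_condition == {c: len(s) for c, s in present.items()}
        assert result.mean_per_condition == pytest.approx(
            np.mean([len(s) for s in present.values()])
        )


class TestLineageParsing:
    def test_qiime_prefixes_stripped(self):
        lin = Lineage.from_string(
            "d__Bacteria;p__Bacteroidota;c__;o__;f__Bacteroidaceae;"
            "g__Bacteroides;s__Bacteroides faecis"
        )
        assert lin.genus == "Bacteroides"
        assert lin.klass is None
        assert Lineage.from_string(lin.to_string()) == lin

    def test_reserved_characters_rejected(self):
        with pytest.raises(ValueError, match="reserved"):
            make_lineage("Bacteroides", "a/b")

    def test_taxonomy_table_roundtrip(self, bacteroides_taxonomy):
        text = "\n".join(
            f"{ref}\t{lin.to_string()}" for ref, lin in bacteroides_taxonomy.items()
        )
        assert read_taxonomy_table(io.StringIO(text)) == bacteroides_taxonomy
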