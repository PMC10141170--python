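"""Diversity, ordination, modulation scoring and small-sample tests."""

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given
from hypothesis import strategies as st

from glycomod.stats import (
    ModulationCall,
    apply_pseudocount,
    bray_curtis,
    bray_curtis_matrix,
    chi_squared,
    classify_modulation,
    count_altered,
    mann_whitney_exact,
    pcoa,
    shannon_diversity,
    t_test,
    treatment_vs_control,
)


class TestShannon:
    def test_single_taxon_zero(self):
        assert shannon_diversity([42]) == 0.0

    def test_uniform_is_log_k(self):
        assert shannon_diversity([3] * 8) == pytest.approx(np.log(8))
        assert shannon_diversity([3] * 8, base=2) == pytest.approx(3.0)

    def test_hand_computed_value(self):
        assert shannon_diversity([1, 1, 2]) == pytest.approx(1.0397, abs=1e-4)

    def test_order_invariant_and_uniform_maximal(self):
        rng = np.random.default_rng(0)
        x = rng.integers(1, 50, size=10).astype(float)
        assert shannon_diversity(x) == pytest.approx(
            shannon_diversity(x[::-1])
        )
        assert shannon_diversity(x) <= np.log(10) + 1e-12

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            shannon_diversity([0, 0, 0])


class TestBrayCurtis:
    def test_identical_zero(self):
        assert bray_curtis([1, 2, 3], [1, 2, 3]) == 0.0

    def test_disjoint_one(self):
        assert bray_curtis([5, 0, 0], [0, 3, 2]) == 1.0

    def test_hand_computed(self):
        assert bray_curtis([2, 0], [1, 1]) == pytest.approx(0.5)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            bray_curtis([1, 2], [1, 2, 3])

    @given(st.integers(0, 2**31 - 1))
    def test_symmetric_bounded_rescale_invariant(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.random(6) + 1e-9
        y = rng.random(6) + 1e-9
        d = bray_curtis(x, y)
        assert 0.0 <= d <= 1.0
        assert d == pytest.approx(bray_curtis(y, x))
        assert bray_curtis(3.7 * x, 3.7 * y) == pytest.approx(d)


class TestPcoa:
    def test_two_points(self):
        res = pcoa(np.array([[0.0, 3.0], [3.0, 0.0]]))
        assert res.coordinates.shape[1] == 1
        assert sorted(res.coordinates.iloc[:, 0]) == pytest.approx([-1.5, 1.5])

    def test_euclidean_round_trip(self):
        rng = np.random.default_rng(21)
        points = rng.normal(size=(7, 3))
        d = np.linalg.norm(points[:, None] - points[None, :], axis=-1)
        res = pcoa(d)
        coords = res.coordinates.to_numpy()
        recon = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
        assert np.allclose(recon, d, atol=1e-8)
        assert np.all(np.diff(res.eigenvalues) <= 1e-12)

    def test_equilateral_triangle_degenerate_eigenvalues(self):
        d = np.array([[0.0, 1, 1], [1, 0, 1], [1, 1, 0]])
        res = pcoa(d)
        assert res.eigenvalues[0] == pytest.approx(res.eigenvalues[1])

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            pcoa(np.array([[0.0, 1.0], [2.0, 0.0]]))


class TestPseudocount:
    def test_only_zeros_replaced(self):
        t = pd.DataFrame({"s": [0, 10]}, index=["a", "b"])
        out = apply_pseudocount(t, 0.5)
        assert out["s"].tolist() == [0.5, 10]

    def test_no_zeros_unchanged(self):
        t = pd.DataFrame({"s": [1, 10]}, index=["a", "b"])
        assert apply_pseudocount(t).equals(t.astype(float).mask(t == 0, 0.5))

    def test_ratio_with_pseudo_matches_manual(self):
        t = pd.DataFrame({"c": [0, 100], "t": [40, 60]}, index=["a", "b"])
        out = apply_pseudocount(t, 0.5)
        assert out.loc["a", "t"] / out.loc["a", "c"] == pytest.approx(40 / 0.5)


class TestModulation:
    @pytest.mark.parametrize(
        "ratio,call",
        [(6.0, "increased"), (1.0, "unchanged"), (0.1, "reduced"),
         (5.0, "increased"), (0.2, "reduced"), (4.99, "unchanged")],
    )
    def test_five_fold_cutoff(self, ratio, call):
        assert classify_modulation(ratio, 1.0).call == call

    @given(
        st.floats(min_value=1e-6, max_value=1e6),
        st.floats(min_value=1e-6, max_value=1e6),
    )
    def test_antisymmetric(self, a, b):
        forward = classify_modulation(a, b).call
        backward = classify_modulation(b, a).call
        flip = {"increased": "reduced", "reduced": "increased",
                "unchanged": "unchanged"}
        assert backward == flip[forward]

    def test_count_altered(self):
        assert count_altered(["unchanged"] * 4) == 0
        calls = [ModulationCall(9.0, "increased")] * 3 + [
            ModulationCall(0.1, "reduced")
        ] * 2
        assert count_altered(calls) == 5


def brute_force_mw_p(x, y):
    """Independent oracle: U by direct pair counting over every assignment."""
    pooled = np.concatenate([x, y])
    n1 = len(x)

    def u_stat(a, b):
        return sum(
            (ai > bi) + 0.5 * (ai == bi) for ai in a for bi in b
        )

    u_obs = u_stat(x, y)
    le = ge = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        mask = np.zeros(len(pooled), dtype=bool)
        mask[list(idx)] = True
        u = u_stat(pooled[mask], pooled[~mask])
        total += 1
        le += u <= u_obs + 1e-9
        ge += u >= u_obs - 1e-9
    return min(1.0, 2.0 * min(le / total, ge / total))


class TestMannWhitney:
    def test_resolution_floor_six_vs_six(self):
        r = mann_whitney_exact([1, 2, 3, 4, 5, 6], [7, 8, 9, 10, 11, 12])
        assert r.p_value == pytest.approx(2 / 924)
        assert round(r.p_value, 3) == 0.002
        assert r.method == "mann_whitney_exact"

    def test_resolution_floor_five_vs_five(self):
        r = mann_whitney_exact([1, 2, 3, 4, 5], [6, 7, 8, 9, 10])
        assert r.p_value == pytest.approx(2 / 252)
        assert round(r.p_value, 3) == 0.008

    def test_identical_constants_give_p_one(self):
        r = mann_whitney_exact([2.0, 2.0, 2.0], [2.0, 2.0, 2.0])
        assert r.p_value == 1.0

    def test_direction_sign(self):
        assert mann_whitney_exact([5, 6, 7], [1, 2, 3]).direction == 1
        assert mann_whitney_exact([1, 2, 3], [5, 6, 7]).direction == -1

    def test_matches_scipy_exact_without_ties(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            x = rng.normal(size=5)
            y = rng.normal(size=6)
            ours = mann_whitney_exact(x, y).p_value
            _, theirs = scipy.stats.mannwhitneyu(
                x, y, alternative="two-sided", method="exact"
            )
            assert ours == pytest.approx(theirs, abs=1e-12)

    def test_matches_brute_force_with_ties(self):
        rng = np.random.default_rng(29)
        for n1, n2 in [(2, 3), (4, 4), (3, 6), (5, 5), (6, 6)]:
            x = rng.integers(0, 4, size=n1).astype(float)
            y = rng.integers(0, 4, size=n2).astype(float)
            assert mann_whitney_exact(x, y).p_value == pytest.approx(
                brute_force_mw_p(x, y)
            )

    def test_large_groups_fall_back_with_notice(self):
        rng = np.random.default_rng(1)
        with pytest.warns(UserWarning, match="normal approximation"):
            r = mann_whitney_exact(rng.normal(size=12), rng.normal(size=12))
        assert r.method == "mann_whitney_normal"

    def test_tiny_groups_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_exact([1.0], [2.0, 3.0])


class TestTAndChi:
    def test_identical_groups_t(self):
        r = t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.statistic == pytest.approx(0.0)
        assert r.p_value == pytest.approx(1.0)

    def test_perfect_separation_chi2(self):
        r = chi_squared([[10, 0], [0, 10]])
        assert r.statistic == pytest.approx(20.0)
        assert r.p_value < 0.001

    def test_equal_proportions_chi2(self):
        r = chi_squared([[5, 5], [5, 5]])
        assert r.statistic == pytest.approx(0.0)
        assert r.p_value == pytest.approx(1.0)

    def test_zero_expected_rejected(self):
        with pytest.raises(ValueError):
            chi_squared([[0, 5], [0, 5]])


class TestTreatmentVsControl:
    def test_planted_shift_called_and_tested(self):
        rng = np.random.default_rng(33)
        base = np.array([1000, 500, 200, 50], dtype=float)
        samples = {}
        meta = []
        for rep in range(1, 7):
            samples[f"control_r{rep}"] = rng.poisson(base)
            meta.append((f"control_r{rep}", "control", rep))
        shifted = base.copy()
        shifted[3] *= 10  # planted 10-fold increase of the rare taxon p3
        for rep in range(1, 7):
            samples[f"trt_r{rep}"] = rng.poisson(shifted)
            meta.append((f"trt_r{rep}", "trt", rep))
        counts = pd.DataFrame(samples, index=[f"p{i}" for i in range(4)])
        metadata = pd.DataFrame(
            meta, columns=["sample", "condition", "replicate"]
        ).set_index("sample")
        stats = treatment_vs_control(counts, metadata, "trt", "control")
        assert stats.loc["p3", "call"] == "increased"
        assert stats.loc["p3", "p_mw"] == pytest.approx(2 / 924)
        assert (stats.drop("p3")["call"] == "unchanged").all()

    def test_bh_adjustment_is_optional_and_monotone(self):
        rng = np.random.default_rng(44)
        counts = pd.DataFrame(
            rng.poisson(200, size=(10, 8)).astype(float),
            index=[f"p{i}" for i in range(10)],
            columns=[f"s{i}" for i in range(8)],
        )
        metadata = pd.DataFrame(
            {"condition": ["control"] * 4 + ["trt"] * 4},
            index=counts.columns,
        )
        plain = treatment_vs_control(counts, metadata, "trt", "control")
        assert "p_mw_bh" not in plain.columns
        adjusted = treatment_vs_control(
            counts, metadata, "trt", "control", bh_adjust=True
        )
        assert (adjusted["p_mw_bh"] >= adjusted["p_mw"] - 1e-12).all()

    def test_bray_curtis_matrix_is_symmetric_zero_diagonal(self):
        rng = np.random.default_rng(4)
        table = pd.DataFrame(rng.random((8, 4)) + 0.01)
        d = bray_curtis_matrix(table)
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0.0)
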