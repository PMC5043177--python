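"""Community statistics: Bray-Curtis, Shannon, rarefaction, chi-square,
size bins, coverage."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import braycurtis as scipy_braycurtis
from scipy.stats import chisquare as scipy_chisquare

from codetect import community
from codetect.errors import UndefinedMetricError

abund = st.dictionaries(
    st.sampled_from(list("abcdefgh")),
    st.floats(0, 1e4, allow_nan=False, allow_infinity=False),
    min_size=1,
    max_size=8,
)


class TestBrayCurtis:
    def test_hand_computed_value(self):
        s = community.bray_curtis_similarity({"x": 1, "y": 2}, {"x": 2, "y": 0})
        assert s == pytest.approx(1 - (1 + 2) / (3 + 2))

    def test_identity_and_disjoint(self):
        assert community.bray_curtis_similarity({"a": 3, "b": 1}, {"a": 3, "b": 1}) == 1.0
        assert community.bray_curtis_similarity({"a": 3}, {"b": 5}) == 0.0

    def test_both_empty_is_undefined(self):
        with pytest.raises(UndefinedMetricError):
            community.bray_curtis_similarity({"a": 0.0}, {"b": 0.0})

    def test_matches_scipy_on_aligned_vectors(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            a = rng.integers(0, 20, 6).astype(float)
            b = rng.integers(0, 20, 6).astype(float)
            if a.sum() + b.sum() == 0:
                continue
            units = [f"u{i}" for i in range(6)]
            ours = community.bray_curtis_similarity(dict(zip(units, a)), dict(zip(units, b)))
            assert ours == pytest.approx(1 - scipy_braycurtis(a, b))

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(a=abund, b=abund, scale=st.floats(0.01, 100))
    def test_symmetric_bounded_scale_invariant(self, a, b, scale):
        try:
            s_ab = community.bray_curtis_similarity(a, b)
        except UndefinedMetricError:
            return
        s_ba = community.bray_curtis_similarity(b, a)
        assert s_ab == pytest.approx(s_ba)
        assert -1e-12 <= s_ab <= 1 + 1e-12
        scaled = community.bray_curtis_similarity(
            {k: v * scale for k, v in a.items()}, {k: v * scale for k, v in b.items()}
        )
        assert scaled == pytest.approx(s_ab, abs=1e-9)

    def test_similarity_matrix_symmetric_unit_diagonal(self):
        vecs = {
            "jan": {"a": 3.0, "b": 1.0},
            "feb": {"b": 2.0, "c": 5.0},
            "mar": {},
        }
        mat = community.similarity_matrix(vecs)
        assert (np.diag(mat) == 1).all()
        assert mat.loc["jan", "feb"] == mat.loc["feb", "jan"]
        assert np.isnan(mat.loc["feb", "mar"]) or mat.loc["feb", "mar"] == 0.0


class TestShannon:
    def test_single_individual_is_zero(self):
        assert community.shannon_diversity({"a": 7}) == 0.0

    def test_uniform_equals_log_richness(self):
        for n in (2, 5, 11):
            h = community.shannon_diversity({f"i{k}": 3.0 for k in range(n)})
            assert h == pytest.approx(math.log(n))

    def test_hand_computed_value(self):
        h = community.shannon_diversity({"a": 1, "b": 1, "c": 2})
        expected = -(0.25 * math.log(0.25) * 2 + 0.5 * math.log(0.5))
        assert h == pytest.approx(expected)
        assert h == pytest.approx(1.0397, abs=1e-4)

    def test_all_zero_is_undefined(self):
        with pytest.raises(UndefinedMetricError):
            community.shannon_diversity({"a": 0.0, "b": 0.0})

    def test_base_conversion(self):
        h2 = community.shannon_diversity({"a": 1, "b": 1}, base=2)
        assert h2 == pytest.approx(1.0)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(v=st.lists(st.floats(0.01, 1e3), min_size=1, max_size=12))
    def test_bounded_by_log_richness(self, v):
        h = community.shannon_diversity(v)
        assert -1e-9 <= h <= math.log(len(v)) + 1e-9

    def test_matches_skbio(self):
        pytest.importorskip("skbio")
        from skbio.diversity.alpha import shannon

        counts = np.array([4, 1, 9, 2])
        ours = community.shannon_diversity(counts)
        assert ours == pytest.approx(float(shannon(counts, base=math.e)))


class TestRarefaction:
    def test_identical_sets_flat_curve(self):
        sets = [{"a", "b", "c"}] * 5
        curve = community.rarefaction_curve(sets, method="exact")
        assert (curve["mean"] == 3).all()
        assert (curve["sd"] == 0).all()

    def test_disjoint_equal_sets_exact_line(self):
        sets = [{f"s{i}a", f"s{i}b"} for i in range(4)]
        curve = community.rarefaction_curve(sets, method="exact")
        assert list(curve["mean"]) == [2, 4, 6, 8]
        assert (curve["sd"] == 0).all()

    def test_exact_matches_independent_enumeration(self):
        rng = np.random.default_rng(11)
        pool = [f"x{i}" for i in range(9)]
        sets = [set(rng.choice(pool, rng.integers(1, 6), replace=False)) for _ in range(4)]
        curve = community.rarefaction_curve(sets, method="exact")
        # brute-force enumeration of all 4! orderings
        acc = np.zeros((24, 4))
        for r, order in enumerate(itertools.permutations(range(4))):
            seen = set()
            for m, i in enumerate(order):
                seen |= sets[i]
                acc[r, m] = len(seen)
        assert np.allclose(curve["mean"], acc.mean(axis=0))
        assert np.allclose(curve["sd"], acc.std(axis=0))

    def test_random_mode_agrees_with_exact_within_mc_error(self):
        rng = np.random.default_rng(5)
        pool = [f"x{i}" for i in range(12)]
        sets = [set(rng.choice(pool, rng.integers(2, 8), replace=False)) for _ in range(5)]
        exact = community.rarefaction_curve(sets, method="exact")
        rand = community.rarefaction_curve(sets, method="random", n_perm=3000, seed=1)
        assert np.allclose(rand["mean"], exact["mean"], atol=0.15)

    def test_mean_nondecreasing_and_final_equals_total(self):
        rng = np.random.default_rng(3)
        pool = [f"x{i}" for i in range(20)]
        sets = [set(rng.choice(pool, rng.integers(1, 10), replace=False)) for _ in range(6)]
        curve = community.rarefaction_curve(sets, method="random", n_perm=50, seed=2)
        assert (np.diff(curve["mean"]) >= -1e-12).all()
        assert curve["mean"].iloc[-1] == len(set().union(*sets))

    def test_matches_vegan_specaccum(self, tmp_path):
        """The exact-permutation curve agrees with R vegan's specaccum
        (method='random' at large nperm) on a small incidence matrix."""
        import subprocess

        sets = [{"a", "b"}, {"b", "c", "d"}, {"a", "e"}, {"d"}]
        units = sorted(set().union(*sets))
        mat = pd.DataFrame(
            [[1 if u in s else 0 for u in units] for s in sets], columns=units
        )
        f = tmp_path / "incidence.csv"
        mat.to_csv(f, index=False)
        script = (
            'x <- read.csv("%s"); library(vegan); '
            "set.seed(1); s <- specaccum(x, method='random', permutations=20000); "
            'cat(s$richness, sep=",")' % f
        )
        res = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        )
        vegan_mean = np.array([float(v) for v in res.stdout.strip().split(",")])
        ours = community.rarefaction_curve(sets, method="exact")
        assert np.allclose(ours["mean"], vegan_mean, atol=0.05)


class TestCompositionChisq:
    def test_null_proportional_counts(self):
        res = community.composition_chisq([10, 10], [0.5, 0.5], monte_carlo=False)
        assert res.statistic == 0.0
        assert res.p_value == 1.0
        res_mc = community.composition_chisq(
            [10, 10], [0.5, 0.5], monte_carlo=True, n_sim=500, seed=0
        )
        assert res_mc.p_value == 1.0

    def test_hand_computed_statistic(self):
        res = community.composition_chisq([10, 20], [0.5, 0.5], monte_carlo=False)
        assert res.statistic == pytest.approx(10 / 3)
        assert res.df == 1

    def test_matches_scipy_asymptotic(self):
        obs = [12, 30, 18, 40]
        props = [0.1, 0.3, 0.2, 0.4]
        ours = community.composition_chisq(obs, props, monte_carlo=False)
        ref = scipy_chisquare(obs, np.asarray(props) * sum(obs))
        assert ours.statistic == pytest.approx(ref.statistic)
        assert ours.p_value == pytest.approx(ref.pvalue)

    def test_auto_switches_to_monte_carlo_on_small_expected(self):
        res = community.composition_chisq([8, 1, 1], [0.8, 0.1, 0.1], seed=0)
        assert res.method == "monte_carlo"  # expected counts 1 < 5
        res2 = community.composition_chisq([80, 10, 10], [0.8, 0.1, 0.1], seed=0)
        assert res2.method == "asymptotic"

    def test_monte_carlo_p_never_zero(self):
        res = community.composition_chisq(
            [100, 0], [0.5, 0.5], monte_carlo=True, n_sim=200, seed=0
        )
        assert res.p_value == pytest.approx(1 / 201)

    def test_expected_sums_to_observed_total(self):
        res = community.composition_chisq([7, 9, 4], [0.2, 0.5, 0.3], seed=1)
        assert res.expected.sum() == pytest.approx(res.observed.sum())

    def test_zero_probability_with_counts_is_error(self):
        with pytest.raises(ValueError):
            community.composition_chisq([5, 5], [1.0, 0.0])

    def test_props_must_sum_to_one(self):
        with pytest.raises(ValueError):
            community.composition_chisq([5, 5], [0.6, 0.6])


class TestSizeBinning:
    @pytest.mark.parametrize(
        "fl,expected",
        [
            (194, "200"),       # focal sharks' class: nearest multiple of 25
            (198, "200"),
            (187.5, "200"),     # tie rounds up
            (187.4, "175"),
            (246, "225+"),      # large females pool into the open top bin
            (237.5, "225+"),
            (237.4, "225"),
            (75, "75"),
            (62.5, "75"),
            (62.4, community.OUT_OF_RANGE),
        ],
    )
    def test_bin_assignment(self, fl, expected):
        assert community.size_binning(fl) == expected

    def test_non_positive_length_is_error(self):
        with pytest.raises(ValueError):
            community.size_binning(0)
        with pytest.raises(ValueError):
            community.size_binning(-10)

    def test_labels_ordered(self):
        labels = community.size_bin_labels()
        assert labels[0] == "75" and labels[-1] == "225+"
        assert len(labels) == 7


class TestCoverage:
    def test_study_coverage_values(self):
        assert community.coverage_percent(170, 325) == 52.3
        assert community.coverage_percent(200, 325) == 61.5

    def test_bounds(self):
        assert community.coverage_percent(0, 10) == 0.0
        assert community.coverage_percent(10, 10) == 100.0
        with pytest.raises(ValueError):
            community.coverage_percent(11, 10)
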