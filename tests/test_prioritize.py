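"""Permutation test, analytic oracle, BH correction, and the pair model."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tcmlink.prioritize import (
    CompoundDiseaseModel,
    UniverseSpec,
    as_universe,
    bh_adjust,
    hypergeometric_oracle,
    overlap_count,
    permutation_test,
    prioritize_all,
    z_score,
)


def brute_force_null(N, K, n):
    """Enumerate every n-subset of an N-universe against the first K elements."""
    overlaps = [
        sum(1 for x in subset if x < K)
        for subset in itertools.combinations(range(N), n)
    ]
    return np.array(overlaps)


class TestOverlapCount:
    def test_direct_counts(self):
        universe = {"A", "B", "C", "D", "E"}
        assert overlap_count({"A", "B", "C"}, {"B", "C", "D"}, universe) == 2
        assert overlap_count({"A"}, {"B"}, universe) == 0
        assert overlap_count({"A", "B"}, {"A", "B"}, universe) == 2

    def test_genes_outside_universe_ignored(self):
        assert overlap_count({"A", "X"}, {"A", "X"}, {"A", "B"}) == 1


class TestHypergeometricOracle:
    def test_matches_exhaustive_enumeration(self):
        """All 120 subsets for N=10, K=4, n=3: tail(2)=1/30, mean 1.2, sd 0.7483."""
        overlaps = brute_force_null(10, 4, 3)
        tail, mean, sd = hypergeometric_oracle(4, 3, 2, 10)
        assert tail == pytest.approx((overlaps > 2).mean())  # == 1/30
        assert mean == pytest.approx(overlaps.mean())  # == 1.2
        assert sd == pytest.approx(overlaps.std(ddof=0))  # == sqrt(0.56)
        assert tail == pytest.approx(1 / 30)

    def test_support_bound_tail_is_zero(self):
        tail, _, _ = hypergeometric_oracle(4, 3, 3, 10)
        assert tail == 0.0

    def test_empty_target_set(self):
        assert hypergeometric_oracle(0, 3, 0, 10) == (0.0, 0.0, 0.0)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            hypergeometric_oracle(11, 3, 1, 10)


class TestPermutationTest:
    def test_within_monte_carlo_error_of_exact_tail(self):
        null = permutation_test(4, 3, 2, 10, n_perm=100_000, seed=1)
        tail, mean, sd = hypergeometric_oracle(4, 3, 2, 10)
        se = np.sqrt(tail * (1 - tail) / null.n_permutations)
        assert abs(null.p_value - tail) <= 3 * se
        assert null.mu == pytest.approx(mean, rel=0.02)
        assert null.sigma == pytest.approx(sd, rel=0.02)

    def test_subset_sampler_agrees_with_count_sampler(self):
        """The literal draw-n-genes permutation matches the fast count sampler."""
        kwargs = dict(K=12, n=8, g_obs=3, universe=60, n_perm=4_000)
        fast = permutation_test(**kwargs, seed=3, method="counts")
        slow = permutation_test(**kwargs, seed=3, method="subsets")
        tail, mean, sd = hypergeometric_oracle(12, 8, 3, 60)
        se = np.sqrt(tail * (1 - tail) / 4_000)
        for null in (fast, slow):
            assert abs(null.p_value - tail) <= 4 * se
            assert null.mu == pytest.approx(mean, rel=0.1)
            assert null.sigma == pytest.approx(sd, rel=0.1)

    def test_degenerate_everything_targeted(self):
        """K = N: every permuted overlap equals n, strict exceedance never fires."""
        null = permutation_test(10, 3, 3, 10, n_perm=1_000, seed=0)
        assert null.p_value == 0.0
        assert null.sigma == 0.0
        assert np.isnan(null.z)

    def test_p_non_increasing_in_observed_overlap(self):
        ps = [
            permutation_test(8, 5, g, 40, n_perm=5_000, seed=9).p_value
            for g in range(6)
        ]
        assert ps == sorted(ps, reverse=True)

    def test_seed_reproducibility(self):
        a = permutation_test(4, 3, 1, 10, n_perm=1_000, seed=5)
        b = permutation_test(4, 3, 1, 10, n_perm=1_000, seed=5)
        assert a == b

    def test_pseudocount_p_is_never_zero(self):
        null = permutation_test(10, 3, 3, 10, n_perm=100, seed=0)
        assert null.p_value == 0.0
        assert null.p_pseudocount == pytest.approx(1 / 101)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            permutation_test(11, 3, 1, 10)
        with pytest.raises(ValueError):
            permutation_test(4, 3, 5, 10)
        with pytest.raises(ValueError):
            permutation_test(4, 3, 1, 10, n_perm=0)


class TestZScore:
    def test_arithmetic(self):
        assert z_score(1.2, 1.2, 0.7483) == 0.0
        assert z_score(2, 1.2, 0.7483314773547883) == pytest.approx(1.0690, abs=1e-4)

    def test_sigma_zero_is_undefined(self):
        assert np.isnan(z_score(3, 3.0, 0.0))

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            z_score(1, 0.0, -1.0)


class TestBHAdjust:
    def test_hand_computed_step_up(self):
        q = bh_adjust([0.01, 0.04, 0.03, 0.002])
        assert q == pytest.approx([0.02, 0.04, 0.04, 0.008])

    def test_all_equal_p(self):
        assert bh_adjust([0.05, 0.05, 0.05]) == pytest.approx([0.05, 0.05, 0.05])

    def test_single_p_passes_through(self):
        assert bh_adjust([0.3]) == pytest.approx([0.3])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0, allow_nan=False), min_size=1,
                 max_size=50)
    )
    @settings(max_examples=200, deadline=None)
    def test_q_dominates_p_and_is_monotone_in_p_order(self, p_values):
        q = bh_adjust(p_values)
        assert np.all(q >= np.asarray(p_values) - 1e-12)
        assert np.all(q <= 1.0)
        order = np.argsort(p_values, kind="mergesort")
        assert np.all(np.diff(q[order]) >= -1e-12)


class TestUniverseSpec:
    def test_coercions(self):
        assert as_universe(100).size == 100
        spec = as_universe({"A", "B"})
        assert spec.size == 2 and spec.genes == {"A", "B"}
        assert as_universe(spec) is spec

    def test_invalid_sizes(self):
        with pytest.raises(ValueError):
            UniverseSpec(size=0)
        with pytest.raises(ValueError):
            UniverseSpec(size=3, genes=frozenset({"A"}))


class TestCompoundDiseaseModel:
    @pytest.fixture
    def toy_model(self):
        signatures = {
            "drugA": {"G1", "G2", "G3"},
            "drugB": {"G4", "G5"},
        }
        diseases = {
            "C01.100.100": {"G1", "G2", "G9"},
            "C02.100.100": {"G7", "G8"},
        }
        universe = {f"G{i}" for i in range(1, 11)}
        return CompoundDiseaseModel(signatures, diseases, universe=universe)

    def test_fit_is_deterministic_and_order_independent(self, toy_model):
        first = toy_model.fit(n_perm=2_000, seed=4).frame
        second = toy_model.fit(n_perm=2_000, seed=4).frame
        assert first.equals(second)
        # reversed insertion order of the inputs gives the identical table
        reordered = CompoundDiseaseModel(
            dict(reversed(list(toy_model.targets.items()))),
            dict(reversed(list(toy_model.disease_sets.items()))),
            universe=toy_model.universe,
        ).fit(n_perm=2_000, seed=4).frame
        assert first.equals(reordered)

    def test_all_pairs_tested_and_bh_joint(self, toy_model):
        results = toy_model.fit(n_perm=1_000, seed=0)
        assert results.n_tested == 4
        frame = results.frame
        assert np.all(frame["q"].to_numpy() >= frame["p"].to_numpy() - 1e-12)

    def test_empty_signatures_give_zero_overlap(self):
        model = CompoundDiseaseModel(
            {"drugA": set()}, {"C01.100.100": {"G1"}}, universe={"G1", "G2"}
        )
        frame = model.fit(n_perm=500, seed=0).frame
        assert (frame["overlap"] == 0).all()
        assert not frame["significant"].any()

    def test_min_overlap_prefilter(self, toy_model):
        toy_model.min_overlap = 1
        results = toy_model.fit(n_perm=500, seed=0)
        assert results.n_tested == 1  # only drugA x C01 overlaps at all
        assert results.frame.iloc[0]["overlap"] == 2

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            CompoundDiseaseModel({}, {"C01.100.100": {"G1"}}, universe={"G1"})

    def test_prioritize_all_wrapper_matches_model(self, toy_model):
        results = toy_model.fit(n_perm=1_000, seed=2)
        pairs = prioritize_all(
            toy_model.targets, toy_model.disease_sets,
            universe=toy_model.universe, n_perm=1_000, seed=2,
        )
        assert [(p.compound, p.disease_id) for p in pairs] == list(
            zip(results.frame["compound"], results.frame["disease_id"])
        )
        assert [p.p for p in pairs] == list(results.frame["p"])

    def test_heatmap_matrix_cells_match_frame(self, toy_model):
        results = toy_model.fit(n_perm=1_000, seed=2)
        matrix = results.heatmap_matrix()
        for row in results.frame.itertuples(index=False):
            cell = matrix.loc[row.compound, row.disease_id]
            assert (np.isnan(cell) and np.isnan(row.z)) or cell == row.z

    def test_summary_text_counts(self, toy_model):
        results = toy_model.fit(n_perm=500, seed=0)
        text = results.summary()
        assert "pairs tested:           4" in text
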