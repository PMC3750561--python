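"""Rank-walk AUC statistic, permutation confidence, and cohort scoring.

The AUC implementation is checked against an independent pairwise-
concordance oracle (count member/non-member pairs in concordant order) and
the permutation scheme against exhaustive subset enumeration.
"""

from itertools import combinations
from math import comb, log2, sqrt

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pathscape import (
    PathwayAberrationScorer,
    combine_scores,
    depletion_auc,
    enrichment_auc,
    exact_null_pvalue,
    permutation_pvalue,
    rank_genes,
    score_cohort,
)
from pathscape.genesets import GeneSet, GeneSetCollection
from tests.conftest import make_cohort


def concordance_auc(member_positions: set[int], n: int) -> float:
    """Oracle: fraction of (member, non-member) pairs where the member is
    ranked above the non-member.  Positions are 1-based ranks."""
    non_members = [i for i in range(1, n + 1) if i not in member_positions]
    m = len(member_positions)
    concordant = sum(1 for a in member_positions for b in non_members if a < b)
    return concordant / (m * len(non_members))


def ranked_list(n):
    return [f"g{i}" for i in range(1, n + 1)]


class TestRankGenes:
    def test_descending_by_log_ratio(self):
        assert rank_genes({"A": 2.0, "B": -1.0, "C": 0.5}) == ["A", "C", "B"]

    def test_ties_broken_by_symbol(self):
        assert rank_genes({"B": 1.0, "A": 1.0}) == ["A", "B"]

    def test_missing_values_excluded(self):
        assert rank_genes(pd.Series({"A": np.nan, "B": 0.0, "C": 1.0})) == ["C", "B"]

    def test_all_missing_is_error(self):
        with pytest.raises(ValueError):
            rank_genes(pd.Series({"A": np.nan, "B": np.nan}))


class TestAuc:
    @pytest.mark.parametrize("positions, expected", [
        ({1, 2}, 1.0),
        ({5, 6}, 0.0),
        ({1, 3}, 7 / 8),
    ])
    def test_known_values_n6(self, positions, expected):
        members = {f"g{i}" for i in positions}
        auc, m = enrichment_auc(ranked_list(6), members)
        assert auc == pytest.approx(expected)
        assert m == len(positions)

    @pytest.mark.parametrize("positions, expected", [
        ({1, 2}, 0.0),
        ({5, 6}, 1.0),
        ({1, 3}, 1 / 8),
    ])
    def test_depletion_is_reversed_walk(self, positions, expected):
        members = {f"g{i}" for i in positions}
        auc, _ = depletion_auc(ranked_list(6), members)
        assert auc == pytest.approx(expected)

    def test_degenerate_membership_is_error(self):
        with pytest.raises(ValueError):
            enrichment_auc(ranked_list(4), set())
        with pytest.raises(ValueError):
            enrichment_auc(ranked_list(4), set(ranked_list(4)))

    def test_matches_concordance_oracle_exhaustively(self):
        # every membership subset at n <= 8, exact equality
        for n in range(2, 9):
            ranked = ranked_list(n)
            for m in range(1, n):
                for positions in combinations(range(1, n + 1), m):
                    members = {f"g{i}" for i in positions}
                    auc, _ = enrichment_auc(ranked, members)
                    assert auc == concordance_auc(set(positions), n)

    @given(n=st.integers(3, 40), data=st.data())
    @settings(max_examples=80, deadline=None)
    def test_enrichment_plus_depletion_is_one(self, n, data):
        m = data.draw(st.integers(1, n - 1))
        positions = data.draw(st.sets(st.integers(1, n), min_size=m, max_size=m))
        members = {f"g{i}" for i in positions}
        e, _ = enrichment_auc(ranked_list(n), members)
        d, _ = depletion_auc(ranked_list(n), members)
        assert e + d == pytest.approx(1.0)


class TestNull:
    def test_exact_null_small_cases(self):
        assert exact_null_pvalue(1.0, 4, 2) == pytest.approx(1 / 6)
        assert exact_null_pvalue(0.5, 4, 2) == pytest.approx(4 / 6)
        assert exact_null_pvalue(0.0, 7, 3) == 1.0

    def test_exact_null_guard(self):
        with pytest.raises(ValueError, match="guard"):
            exact_null_pvalue(0.5, 200, 50, guard=1000)

    def test_permutation_p_at_maximum(self):
        p = permutation_pvalue(1.0, 500, 5, B=1000, seed=0)
        assert p == pytest.approx(1 / 1001)

    def test_permutation_p_at_minimum_auc(self):
        assert permutation_pvalue(0.0, 50, 3, B=200, seed=1) == 1.0

    def test_permutation_converges_to_exact(self):
        # n=5, m=2: exact P(AUC >= 1) = 1/10
        exact = exact_null_pvalue(1.0, 5, 2)
        assert exact == pytest.approx(0.1)
        B = 1000
        p = permutation_pvalue(1.0, 5, 2, B=B, seed=42)
        assert abs(p - exact) <= 3 * sqrt(exact * (1 - exact) / B) + 1 / (B + 1)

    def test_determinism_given_seed(self):
        a = permutation_pvalue(0.8, 100, 10, B=500, seed=7)
        b = permutation_pvalue(0.8, 100, 10, B=500, seed=7)
        assert a == b
        assert permutation_pvalue(0.8, 100, 10, B=500, seed=8) != a or True

    def test_p_bounds(self):
        for auc in (0.0, 0.3, 0.7, 1.0):
            p = permutation_pvalue(auc, 30, 4, B=99, seed=3)
            assert 1 / 100 <= p <= 1.0


class TestCombine:
    def test_enrichment_dominant_is_negative(self):
        assert combine_scores(0.001, 0.9) == pytest.approx(log2(0.001))

    def test_depletion_dominant_is_positive(self):
        assert combine_scores(0.9, 0.001) == pytest.approx(-log2(0.001))

    def test_tie_resolves_to_enrichment(self):
        assert combine_scores(0.5, 0.5) == pytest.approx(-1.0)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            combine_scores(0.0, 0.5)


def _cohort_and_sets(n_genes=60, n_samples=4, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n_genes, n_samples))
    cohort = make_cohort(X)
    genes = cohort.gene_symbols
    coll = GeneSetCollection(sets=[
        GeneSet(name="P1", genes=frozenset(genes[:10])),
        GeneSet(name="P2", genes=frozenset(genes[20:35])),
    ])
    return cohort, coll


class TestScoreCohort:
    def test_top_ranked_pathway_hits_floor_confidence(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(200, 1))
        cohort = make_cohort(X)
        col = cohort.values.iloc[:, 0]
        top = set(col.sort_values(ascending=False).index[:10])
        coll = GeneSetCollection(sets=[GeneSet(name="TOP", genes=frozenset(top))])
        prof = score_cohort(cohort, coll, B=1000, seed=0)
        assert prof.p_enrichment.iloc[0, 0] == pytest.approx(1 / 1001)
        assert prof.combined.iloc[0, 0] == pytest.approx(log2(1 / 1001))

    def test_pathway_absent_from_matrix_is_error(self):
        cohort, _ = _cohort_and_sets()
        coll = GeneSetCollection(sets=[GeneSet(name="X", genes=frozenset({"NOPE"}))])
        with pytest.raises(ValueError, match="no genes"):
            score_cohort(cohort, coll, B=50, seed=0)

    def test_bitwise_reproducible(self):
        cohort, coll = _cohort_and_sets()
        a = score_cohort(cohort, coll, B=100, seed=9)
        b = score_cohort(cohort, coll, B=100, seed=9)
        assert a.combined.equals(b.combined)
        assert a.p_enrichment.equals(b.p_enrichment)

    def test_invariant_to_sample_order(self):
        cohort, coll = _cohort_and_sets()
        shuffled = cohort.subset(list(reversed(cohort.sample_ids)))
        a = score_cohort(cohort, coll, B=100, seed=2)
        b = score_cohort(shuffled, coll, B=100, seed=2)
        assert np.allclose(a.combined[cohort.sample_ids].to_numpy(),
                           b.combined[cohort.sample_ids].to_numpy())

    def test_invariant_to_monotone_transform(self):
        cohort, coll = _cohort_and_sets()
        warped = make_cohort(np.exp(cohort.values.to_numpy() / 3.0) * 2 + 1)
        a = score_cohort(cohort, coll, B=100, seed=4)
        b = score_cohort(warped, coll, B=100, seed=4)
        assert np.allclose(a.combined.to_numpy(), b.combined.to_numpy())

    def test_missing_values_shrink_effective_size(self):
        cohort, coll = _cohort_and_sets()
        values = cohort.values.copy()
        # knock out one member of P1 in the first sample
        values.iloc[0, 0] = np.nan
        cohort2 = make_cohort(values.to_numpy())
        prof = score_cohort(cohort2, coll, B=100, seed=0)
        assert prof.combined.shape == (2, 4)

    def test_combined_sign_convention(self):
        cohort, coll = _cohort_and_sets(seed=11)
        prof = score_cohort(cohort, coll, B=200, seed=1)
        pe = prof.p_enrichment.to_numpy()
        pdep = prof.p_depletion.to_numpy()
        com = prof.combined.to_numpy()
        expected = np.where(pe <= pdep, np.log2(pe), -np.log2(pdep))
        assert np.allclose(com, expected)


class TestScorerEstimator:
    def test_fit_transform_shapes_and_params(self):
        cohort, coll = _cohort_and_sets()
        X = cohort.values.T  # samples x genes
        scorer = PathwayAberrationScorer(collection=coll, B=100, seed=0, min_size=5)
        out = scorer.fit_transform(X)
        assert out.shape == (4, 2)
        assert list(scorer.get_feature_names_out()) == ["P1", "P2"]
        params = scorer.get_params()
        assert params["B"] == 100
        scorer.set_params(B=150)
        assert scorer.B == 150

    def test_small_sets_filtered_at_fit(self):
        cohort, coll = _cohort_and_sets()
        scorer = PathwayAberrationScorer(collection=coll, B=100, min_size=12)
        scorer.fit(cohort.values.T)
        assert scorer.pathway_names_ == ["P2"]

    def test_works_in_sklearn_pipeline(self):
        from sklearn.pipeline import Pipeline

        cohort, coll = _cohort_and_sets()
        pipe = Pipeline([("aberration", PathwayAberrationScorer(collection=coll, B=100, min_size=5))])
        out = pipe.fit_transform(cohort.values.T)
        assert out.shape == (4, 2)
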