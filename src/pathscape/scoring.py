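"""Rank-walk AUC aberration scoring with permutation confidence.

For one sample, all measured genes are rank-ordered from most up- to most
down-regulated.  Walking down the list and labelling pathway members 1 and
non-members 0 traces a step curve of fraction-of-1's against
fraction-of-0's; its area (AUC) is the normalized Mann-Whitney concordance
between members and non-members:

    AUC = (1 / (m (n - m))) * sum over members of #(non-members ranked below)

AUC = 1 when every member precedes every non-member (maximal enrichment);
walking the reversed list gives the depletion AUC, and with a strict total
order AUC_enrichment + AUC_depletion = 1.

Significance is empirical: the null re-draws the member positions uniformly
(equivalent to permuting the ranked gene list) B times, and

    p = (1 + #{null AUC >= observed AUC}) / (B + 1)

so p lies in [1/(B+1), 1] and log2 p is always defined.  The enrichment and
depletion confidences are combined by taking the smaller and mapping it to
log2 space for enrichment and -log2 space for depletion (ties go to
enrichment), yielding one signed value per (sample, pathway): strongly
negative = enriched, strongly positive = depleted.  No multiple-testing
correction is applied anywhere in scoring -- an intentional choice for an
exploratory profile.

Internally AUC comparisons are exact: an AUC on n genes with m members is
determined by the integer sum of member ranks, and observed-vs-null
comparisons are done on those integer rank sums.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from itertools import combinations
from math import comb, log2
from sklearn.base import BaseEstimator, TransformerMixin

from .expression import ExpressionCohort
from .genesets import GeneSetCollection


# ---------------------------------------------------------------------------
# ranked lists and the AUC statistic


def rank_genes(sample_values: Mapping[str, float] | pd.Series) -> list[str]:
    """Order genes from most up- to most down-regulated.

    Exact ties are broken by ascending gene symbol so the order is total and
    deterministic; genes with missing values are excluded.
    """
    if isinstance(sample_values, pd.Series):
        items = [(g, v) for g, v in sample_values.items() if not pd.isna(v)]
    else:
        items = [(g, v) for g, v in sample_values.items() if v is not None and not np.isnan(v)]
    if len(items) < 2:
        raise ValueError("need >= 2 genes with non-missing values to rank")
    items.sort(key=lambda gv: (-gv[1], gv[0]))
    return [g for g, _ in items]


def _member_ranks(ranked: list[str], members: Iterable[str]) -> np.ndarray:
    pos = {g: i + 1 for i, g in enumerate(ranked)}  # 1-based ranks
    ranks = sorted(pos[g] for g in members if g in pos)
    return np.asarray(ranks, dtype=np.int64)


def _auc_from_rank_sum(rank_sum: int, n: int, m: int) -> float:
    # concordant pairs = m*n - rank_sum - m(m-1)/2
    return (m * n - rank_sum - m * (m - 1) // 2) / (m * (n - m))


def enrichment_auc(ranked: list[str], members: Iterable[str]) -> tuple[float, int]:
    """AUC of the member/non-member rank walk from the top of the list.

    Returns (auc, m) where m is the effective pathway size (members present
    in the ranked list).  Undefined when m = 0 or m = n.
    """
    n = len(ranked)
    ranks = _member_ranks(ranked, members)
    m = len(ranks)
    if m == 0 or m == n:
        raise ValueError(f"AUC undefined for m={m} of n={n}")
    return _auc_from_rank_sum(int(ranks.sum()), n, m), m


def depletion_auc(ranked: list[str], members: Iterable[str]) -> tuple[float, int]:
    """Enrichment AUC of the reversed list (most down-regulated first)."""
    return enrichment_auc(list(reversed(ranked)), members)


# ---------------------------------------------------------------------------
# null distributions


def _null_rank_sums(n: int, m: int, B: int, rng: np.random.Generator) -> np.ndarray:
    """Rank sums of B uniformly random m-subsets of {1..n}, sorted ascending."""
    # Gumbel-free top-m trick: argpartition of uniform noise = random subset
    u = rng.random((B, n))
    idx = np.argpartition(u, m - 1, axis=1)[:, :m]
    sums = idx.sum(axis=1, dtype=np.int64) + m  # 0-based -> 1-based ranks
    sums.sort()
    return sums


def _null_seed(seed: int, n: int, m: int) -> np.random.Generator:
    # stable stream per (n, m): the null depends on nothing else
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed, spawn_key=(n, m))))


def permutation_pvalue(auc_obs: float, n: int, m: int, B: int = 1000, seed: int = 0) -> float:
    """One-sided empirical confidence of an observed AUC.

    p = (1 + #{null AUC >= auc_obs}) / (B + 1) over B uniformly random
    m-subsets of n ranks; deterministic given seed; p in [1/(B+1), 1].
    """
    if not (1 <= m < n):
        raise ValueError(f"need 1 <= m < n, got n={n}, m={m}")
    if B < 1:
        raise ValueError("B must be >= 1")
    sums = _null_rank_sums(n, m, B, _null_seed(seed, n, m))
    # AUC >= auc_obs  <=>  rank_sum <= threshold; round to nearest half-integer
    # grid point so support values compare exactly
    thresh = m * n - m * (m - 1) // 2 - auc_obs * m * (n - m)
    count = int(np.searchsorted(sums, np.floor(thresh + 1e-9), side="right"))
    return (1 + count) / (B + 1)


def exact_null_pvalue(auc_obs: float, n: int, m: int, guard: int = 10**6) -> float:
    """Exact null tail P(AUC >= auc_obs) by exhaustive subset enumeration.

    Serves as an independent oracle for the permutation scheme; refuses
    instances with more than ``guard`` subsets.
    """
    if not (1 <= m < n):
        raise ValueError(f"need 1 <= m < n, got n={n}, m={m}")
    total = comb(n, m)
    if total > guard:
        raise ValueError(f"C({n},{m})={total} exceeds guard; use permutation_pvalue")
    hits = 0
    for subset in combinations(range(1, n + 1), m):
        if _auc_from_rank_sum(sum(subset), n, m) >= auc_obs - 1e-12:
            hits += 1
    return hits / total


def combine_scores(p_enrichment: float, p_depletion: float) -> float:
    """Signed combination: log2 of the smaller confidence, negative for
    enrichment, positive for depletion; ties resolve toward enrichment."""
    if p_enrichment <= 0 or p_depletion <= 0:
        raise ValueError("confidence scores must be in (0, 1]")
    if p_enrichment <= p_depletion:
        return log2(p_enrichment)
    return -log2(p_depletion)


# ---------------------------------------------------------------------------
# cohort scoring


@dataclass
class AberrationProfiles:
    """Pathways x samples aberration profile matrices.

    ``combined`` holds the signed log2 values; ``p_enrichment`` and
    ``p_depletion`` the underlying empirical confidences.  B and seed make
    the result reproducible bit-for-bit.
    """

    combined: pd.DataFrame
    p_enrichment: pd.DataFrame
    p_depletion: pd.DataFrame
    B: int
    seed: int

    @property
    def pathway_names(self) -> list[str]:
        return self.combined.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.combined.columns.tolist()

    def manifest(self) -> dict:
        return {
            "B": self.B,
            "seed": self.seed,
            "n_pathways": len(self.pathway_names),
            "n_samples": len(self.sample_ids),
        }


def _collection_member_indices(
    collection: GeneSetCollection, gene_index: pd.Index
) -> dict[str, np.ndarray]:
    lookup = {g: i for i, g in enumerate(gene_index)}
    out = {}
    for s in collection.sets:
        idx = np.asarray(sorted(lookup[g] for g in s.genes if g in lookup), dtype=np.int64)
        out[s.name] = idx
    return out


def score_cohort(
    cohort: ExpressionCohort,
    collection: GeneSetCollection,
    B: int = 1000,
    seed: int = 0,
) -> AberrationProfiles:
    """Score every (sample, pathway) pair of a cohort.

    Each sample is ranked internally (so any strictly monotone per-sample
    transform of the values leaves the result unchanged), the enrichment and
    depletion AUCs are computed from integer member-rank sums, and empirical
    confidences are read off a per-(n, m) permutation null shared across
    samples -- the null distribution depends only on the number of ranked
    genes n and the effective set size m, so sharing is distributionally
    identical to redrawing and keeps the output invariant to sample order.
    """
    if cohort.n_samples == 0 or cohort.n_genes == 0:
        raise ValueError("empty expression matrix")
    if len(collection) == 0:
        raise ValueError("empty gene set collection")
    for s in collection.sets:
        if not (s.genes & set(cohort.gene_symbols)):
            raise ValueError(f"pathway {s.name!r} has no genes in the expression matrix")

    X = cohort.values.to_numpy(dtype=float)
    n_genes, n_samples = X.shape
    genes = cohort.values.index
    member_idx = _collection_member_indices(collection, genes)
    pathway_names = collection.names

    P_enr = np.empty((len(pathway_names), n_samples))
    P_dep = np.empty((len(pathway_names), n_samples))
    combined = np.empty((len(pathway_names), n_samples))

    null_cache: dict[tuple[int, int], np.ndarray] = {}

    # deterministic tie-break: sort by (-value, symbol); missing excluded
    sym_order = np.argsort(genes.to_numpy())  # ascending symbol
    for j in range(n_samples):
        col = X[:, j]
        mask = ~np.isnan(col)
        n = int(mask.sum())
        if n < 2:
            raise ValueError(f"sample {cohort.sample_ids[j]!r} has < 2 measured genes")
        # ranks[i] = 1-based rank of gene i in this sample (0 where missing)
        present = sym_order[mask[sym_order]]
        order = present[np.argsort(-col[present], kind="stable")]
        ranks = np.zeros(n_genes, dtype=np.int64)
        ranks[order] = np.arange(1, n + 1)

        for i, name in enumerate(pathway_names):
            idx = member_idx[name]
            mranks = ranks[idx]
            mranks = mranks[mranks > 0]
            m = int(mranks.size)
            if m == 0 or m == n:
                raise ValueError(
                    f"pathway {name!r} has degenerate effective size m={m} in sample "
                    f"{cohort.sample_ids[j]!r}"
                )
            key = (n, m)
            null = null_cache.get(key)
            if null is None:
                null = _null_rank_sums(n, m, B, _null_seed(seed, n, m))
                null_cache[key] = null
            s_enr = int(mranks.sum())
            s_dep = m * (n + 1) - s_enr  # rank sum in the reversed list
            # AUC >= observed  <=>  null rank sum <= observed rank sum
            p_enr = (1 + int(np.searchsorted(null, s_enr, side="right"))) / (B + 1)
            p_dep = (1 + int(np.searchsorted(null, s_dep, side="right"))) / (B + 1)
            P_enr[i, j] = p_enr
            P_dep[i, j] = p_dep
            combined[i, j] = log2(p_enr) if p_enr <= p_dep else -log2(p_dep)

    cols = cohort.sample_ids
    return AberrationProfiles(
        combined=pd.DataFrame(combined, index=pathway_names, columns=cols),
        p_enrichment=pd.DataFrame(P_enr, index=pathway_names, columns=cols),
        p_depletion=pd.DataFrame(P_dep, index=pathway_names, columns=cols),
        B=B,
        seed=seed,
    )


class PathwayAberrationScorer(BaseEstimator, TransformerMixin):
    """Transform expression profiles into signed pathway aberration profiles.

    scikit-learn style transformer: X is samples x genes (one row per
    sample).  ``fit`` records the gene universe and restricts the gene-set
    collection to it; ``transform`` returns a samples x pathways array of
    combined signed scores (negative = enriched, positive = depleted).

    Parameters
    ----------
    collection : GeneSetCollection
        Gene sets to score; restricted to measured genes at fit time.
    B : int, default 1000
        Number of permutations for the empirical null.
    seed : int, default 0
        Base seed for the permutation streams.
    min_size, max_size : int
        Effective set-size bounds applied after restriction to the
        measured-gene universe.
    """

    def __init__(self, collection: GeneSetCollection | None = None, B: int = 1000,
                 seed: int = 0, min_size: int = 10, max_size: int = 1000):
        self.collection = collection
        self.B = B
        self.seed = seed
        self.min_size = min_size
        self.max_size = max_size

    def fit(self, X, y=None):
        from .genesets import filter_sets

        X = self._validate(X)
        if self.collection is None or len(self.collection) == 0:
            raise ValueError("a non-empty GeneSetCollection is required")
        universe = list(X.columns)
        self.collection_, self.removed_sets_ = filter_sets(
            self.collection, universe=universe,
            min_size=self.min_size, max_size=self.max_size)
        if len(self.collection_) == 0:
            raise ValueError("no gene set survives the universe/size filter")
        self.gene_symbols_ = universe
        self.pathway_names_ = self.collection_.names
        self.n_features_in_ = len(universe)
        return self

    def transform(self, X) -> np.ndarray:
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "collection_")
        X = self._validate(X)
        missing = [g for g in self.gene_symbols_ if g not in X.columns]
        if missing:
            raise ValueError(f"X lacks {len(missing)} fitted genes (e.g. {missing[:3]})")
        values = X[self.gene_symbols_].T  # genes x samples
        meta = pd.DataFrame({"patient_id": values.columns}, index=values.columns)
        cohort = ExpressionCohort(values, meta)
        self.profiles_ = score_cohort(cohort, self.collection_, B=self.B, seed=self.seed)
        return self.profiles_.combined.to_numpy().T

    @staticmethod
    def _validate(X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            return X
        arr = np.asarray(X, dtype=float)
        if arr.ndim != 2:
            raise ValueError("X must be 2-D (samples x genes)")
        return pd.DataFrame(
            arr,
            index=[f"S{i}" for i in range(arr.shape[0])],
            columns=[f"G{i}" for i in range(arr.shape[1])],
        )

    def get_feature_names_out(self, input_features=None):
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "pathway_names_")
        return np.asarray(self.pathway_names_, dtype=object)


def collection_hash(collection: GeneSetCollection) -> str:
    """Stable content hash of a collection for run manifests."""
    h = hashlib.sha256()
    for s in collection.sets:
        h.update(s.name.encode())
        for g in sorted(s.genes):
            h.update(b"|" + g.encode())
        h.update(b"\n")
    return h.hexdigest()
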