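"""Clinical association testing for discovered subgroups.

Survival differences are assessed with Kaplan-Meier estimators and the
two-group Mantel-Cox (log-rank) test, subgroup vs. the rest of its cohort.
Categorical label enrichment (e.g. prior molecular subtype) uses Fisher's
exact test on the 2x2 in/out-of-subgroup by label table.  Differential
expression between sample groups uses the two-sided Wilcoxon rank-sum test
per gene.  Scans are reported uncorrected (the exploratory convention this
pipeline follows throughout); a Benjamini-Hochberg column is appended as a
supplementary aid only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .expression import ExpressionCohort
from .subgroups import SubgroupAssignment


@dataclass
class AssociationResult:
    subgroup: str
    test: str
    statistic: float
    p_value: float
    direction: str
    n_group: int
    n_rest: int

    def __post_init__(self) -> None:
        if not (0 <= self.p_value <= 1):
            raise ValueError("p_value must lie in [0, 1]")


def _km_table(kmf: KaplanMeierFitter) -> pd.DataFrame:
    ev = kmf.event_table
    surv = kmf.survival_function_.iloc[:, 0]
    return pd.DataFrame({
        "time": ev.index.to_numpy(dtype=float),
        "at_risk": ev["at_risk"].to_numpy(dtype=float),
        "observed": ev["observed"].to_numpy(dtype=float),
        "survival": surv.reindex(ev.index).to_numpy(dtype=float),
    })


def km_logrank(
    group_a: pd.DataFrame, group_b: pd.DataFrame, label_a: str = "a", label_b: str = "b"
) -> tuple[AssociationResult, pd.DataFrame, pd.DataFrame]:
    """Two-group Mantel-Cox log-rank test with Kaplan-Meier estimators.

    Each group is a DataFrame with columns ``time`` (days > 0) and ``event``
    (True = death observed, False = right-censored).  Returns the test
    result and the two product-limit step tables (time, at-risk, observed,
    survival).
    """
    for name, g in ((label_a, group_a), (label_b, group_b)):
        if len(g) == 0:
            raise ValueError(f"group {name!r} is empty")
        if (np.asarray(g["time"], dtype=float) <= 0).any():
            raise ValueError(f"group {name!r} has non-positive survival times")
    ev_a = np.asarray(group_a["event"], dtype=bool)
    ev_b = np.asarray(group_b["event"], dtype=bool)
    if not (ev_a.any() or ev_b.any()):
        raise ValueError("log-rank test undefined with zero events in both groups")

    res = logrank_test(
        group_a["time"], group_b["time"], event_observed_A=ev_a, event_observed_B=ev_b
    )
    kmf_a, kmf_b = KaplanMeierFitter(), KaplanMeierFitter()
    kmf_a.fit(group_a["time"], ev_a, label=label_a)
    kmf_b.fit(group_b["time"], ev_b, label=label_b)
    med_a, med_b = kmf_a.median_survival_time_, kmf_b.median_survival_time_
    direction = "worse" if med_a < med_b else ("better" if med_a > med_b else "similar")
    result = AssociationResult(
        subgroup=label_a,
        test="logrank",
        statistic=float(res.test_statistic),
        p_value=float(res.p_value),
        direction=direction,
        n_group=len(group_a),
        n_rest=len(group_b),
    )
    return result, _km_table(kmf_a), _km_table(kmf_b)


def survival_scan(
    assignment: SubgroupAssignment,
    survival: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Log-rank scan of every subgroup against the rest of its cohort.

    ``survival``: DataFrame indexed by sample_id with columns time, event.
    Subgroups with fewer than 2 surviving records are skipped with a
    warning row.  Output columns: subgroup, n_group, n_rest, statistic,
    p_value, direction, significant (p < alpha, uncorrected), p_bh
    (supplementary Benjamini-Hochberg adjusted values).
    """
    rows = []
    ids = assignment.labels.index
    surv = survival.loc[survival.index.intersection(ids)]
    for sg in sorted(assignment.labels.unique()):
        in_ids = [s for s in assignment.members(sg) if s in surv.index]
        out_ids = [s for s in ids if s in surv.index and assignment.labels[s] != sg]
        if len(in_ids) < 2 or len(out_ids) < 2:
            rows.append({"subgroup": sg, "n_group": len(in_ids), "n_rest": len(out_ids),
                         "statistic": np.nan, "p_value": np.nan, "direction": "skipped",
                         "significant": False})
            continue
        res, _, _ = km_logrank(surv.loc[in_ids], surv.loc[out_ids],
                               label_a=str(sg), label_b="rest")
        rows.append({"subgroup": sg, "n_group": res.n_group, "n_rest": res.n_rest,
                     "statistic": res.statistic, "p_value": res.p_value,
                     "direction": res.direction, "significant": res.p_value < alpha})
    out = pd.DataFrame(rows)
    mask = out["p_value"].notna()
    out["p_bh"] = np.nan
    if mask.any():
        out.loc[mask, "p_bh"] = multipletests(out.loc[mask, "p_value"], method="fdr_bh")[1]
    return out


def fisher_association(
    assignment: SubgroupAssignment, labels: pd.Series, alpha: float = 0.05
) -> pd.DataFrame:
    """Fisher's exact association of each subgroup with a binary label.

    ``labels``: sample_id -> truthy/falsy label; unlabeled samples (NaN) are
    excluded.  The two-sided p sums the probabilities of all 2x2 tables
    with the observed margins that are at most as likely as the observed
    table.  Degenerate margins yield p = 1.
    """
    lab = labels.dropna()
    lab = lab.loc[lab.index.intersection(assignment.labels.index)].astype(bool)
    rows = []
    for sg in sorted(assignment.labels.unique()):
        in_sg = pd.Index(assignment.members(sg)).intersection(lab.index)
        out_sg = lab.index.difference(in_sg)
        a = int(lab.loc[in_sg].sum())
        b = len(in_sg) - a
        c = int(lab.loc[out_sg].sum())
        d = len(out_sg) - c
        if min(a + c, b + d) == 0 or min(a + b, c + d) == 0:
            odds, p = np.nan, 1.0
        else:
            odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        direction = "enriched" if (a * d - b * c) > 0 else ("depleted" if (a * d - b * c) < 0 else "balanced")
        rows.append({"subgroup": sg, "table": (a, b, c, d), "odds_ratio": odds,
                     "p_value": float(p), "direction": direction,
                     "significant": p < alpha})
    return pd.DataFrame(rows)


def wilcoxon_de(
    cohort: ExpressionCohort,
    group_a: list[str],
    group_b: list[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-gene two-sided Wilcoxon rank-sum differential expression.

    Exact p when both groups have <= 12 non-missing values and no ties;
    normal approximation with tie correction otherwise.  Genes with fewer
    than 2 usable values in either group are skipped.  Direction is the
    sign of the median difference (a vs b).
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("both groups need >= 2 samples")
    A = cohort.values[group_a].to_numpy(dtype=float)
    B = cohort.values[group_b].to_numpy(dtype=float)
    rows = []
    for i, gene in enumerate(cohort.gene_symbols):
        xa = A[i][~np.isnan(A[i])]
        xb = B[i][~np.isnan(B[i])]
        if xa.size < 2 or xb.size < 2:
            continue
        pooled = np.concatenate([xa, xb])
        if np.all(pooled == pooled[0]):
            stat, p = float(xa.size * xb.size) / 2.0, 1.0
        else:
            has_ties = np.unique(pooled).size < pooled.size
            method = "exact" if (xa.size <= 12 and xb.size <= 12 and not has_ties) else "asymptotic"
            res = stats.mannwhitneyu(xa, xb, alternative="two-sided", method=method,
                                     use_continuity=False)
            stat, p = float(res.statistic), float(res.pvalue)
        diff = float(np.median(xa) - np.median(xb))
        rows.append({"gene": gene, "statistic": stat, "p_value": p,
                     "direction": "up" if diff > 0 else ("down" if diff < 0 else "equal"),
                     "median_diff": diff, "significant": p < alpha})
    out = pd.DataFrame(rows)
    if len(out):
        out["p_bh"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out
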