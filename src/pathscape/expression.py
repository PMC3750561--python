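"""Expression matrix I/O and quality control.

The cohort container holds a genes x samples matrix of log2 expression
ratios against a common reference, plus per-sample metadata (patient id,
cancer label, optional survival).  QC covers quantile normalization (used
only for PCA screening -- the scoring engine ranks each sample internally,
so cross-sample normalization cannot change scores), PCA embedding, and
duplicate-sample removal so each sample represents a unique case.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

logger = logging.getLogger(__name__)

METADATA_COLUMNS = ["sample_id", "patient_id", "cancer_label", "survival_days", "event", "prior_subtype"]


@dataclass
class ExpressionCohort:
    """Genes x samples log-ratio matrix joined with sample metadata.

    ``values``: DataFrame indexed by unique gene symbol, columns = unique
    sample ids; NaN marks missing measurements.  ``metadata``: DataFrame
    indexed by sample_id with columns patient_id, cancer_label,
    survival_days, event, prior_subtype.
    """

    values: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene symbols: {dupes[:5]}")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample ids in matrix")
        if not self.values.columns.equals(self.metadata.index):
            raise ValueError("matrix columns and metadata index must match")
        st = self.metadata.get("survival_days")
        ev = self.metadata.get("event")
        if st is not None and ev is not None and not (st.isna() == ev.isna()).all():
            raise ValueError("survival_days must be present iff event is present")

    @property
    def gene_symbols(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.values.columns.tolist()

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset(self, sample_ids: Sequence[str]) -> "ExpressionCohort":
        ids = list(sample_ids)
        return ExpressionCohort(self.values[ids], self.metadata.loc[ids])


def load_expression(
    path: str | Path,
    metadata_path: str | Path,
    missing_token: str = "NA",
) -> ExpressionCohort:
    """Load a TSV matrix (genes in rows, sample-id header) and metadata TSV.

    Samples missing from the metadata table are dropped with a warning;
    metadata rows without a matrix column are ignored.  Duplicate gene rows
    and non-numeric cells (other than the missing token) are errors.
    """
    values = pd.read_csv(path, sep="\t", index_col=0, na_values=[missing_token],
                         keep_default_na=False, dtype=str)
    try:
        values = values.astype(float)
    except ValueError as exc:
        raise ValueError(f"non-numeric expression cell in {path}: {exc}") from exc
    values.index = values.index.astype(str)
    if values.index.has_duplicates:
        dupes = values.index[values.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene symbol rows in {path}: {dupes[:5]}")

    meta = pd.read_csv(metadata_path, sep="\t", dtype={"sample_id": str, "patient_id": str})
    if meta["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in metadata")
    meta = meta.set_index("sample_id")
    for col in ("patient_id", "cancer_label", "survival_days", "event", "prior_subtype"):
        if col not in meta.columns:
            meta[col] = np.nan
    if meta["event"].notna().any():
        meta["event"] = meta["event"].map(
            lambda v: v if pd.isna(v) else bool(int(v)) if str(v) in {"0", "1"} else bool(v)
        )

    shared = [s for s in values.columns if s in meta.index]
    dropped = values.shape[1] - len(shared)
    if dropped:
        warnings.warn(f"dropping {dropped} sample(s) lacking metadata", stacklevel=2)
        logger.warning("dropped %d samples without metadata", dropped)
    return ExpressionCohort(values[shared], meta.loc[shared])


def save_expression(cohort: ExpressionCohort, path: str | Path, metadata_path: str | Path,
                    missing_token: str = "NA") -> None:
    cohort.values.to_csv(path, sep="\t", na_rep=missing_token, index_label="gene")
    cohort.metadata.to_csv(metadata_path, sep="\t", index_label="sample_id", na_rep="")


def _map_to_reference(column: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Replace a column's values by reference order statistics at their ranks.

    Tied values receive the mean of the reference values at their tied rank
    positions, so the output preserves ties as well as rank order.
    """
    order = np.argsort(column, kind="mergesort")
    out = np.empty_like(reference, dtype=float)
    sorted_vals = column[order]
    i = 0
    n = len(column)
    while i < n:
        j = i
        while j + 1 < n and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        out[order[i : j + 1]] = reference[i : j + 1].mean()
        i = j + 1
    return out


def quantile_normalize(cohort: ExpressionCohort) -> ExpressionCohort:
    """Force every sample onto the mean-of-order-statistics distribution.

    After normalization each column's sorted values equal the across-column
    mean of order statistics; within-column rank order (including ties) is
    preserved.  Columns with missing values are normalized against the
    reference linearly interpolated to their non-missing length.
    """
    if cohort.n_samples < 2:
        raise ValueError("quantile normalization requires >= 2 samples")
    X = cohort.values.to_numpy(dtype=float)
    n_genes, n_samples = X.shape
    complete = not np.isnan(X).any()

    if complete:
        reference = np.sort(X, axis=0).mean(axis=1)
        out = np.column_stack([_map_to_reference(X[:, j], reference) for j in range(n_samples)])
    else:
        # pool a common reference over a fixed grid, then map each column's
        # non-missing values through a length-matched interpolated reference
        grid = np.linspace(0, 1, n_genes)
        interp_cols = []
        for j in range(n_samples):
            col = np.sort(X[~np.isnan(X[:, j]), j])
            if col.size == 0:
                raise ValueError(f"sample {cohort.sample_ids[j]!r} has no measured genes")
            interp_cols.append(np.interp(grid, np.linspace(0, 1, col.size), col))
        reference = np.mean(interp_cols, axis=0)
        out = np.full_like(X, np.nan)
        for j in range(n_samples):
            mask = ~np.isnan(X[:, j])
            k = int(mask.sum())
            ref_j = np.interp(np.linspace(0, 1, k), grid, reference)
            out[mask, j] = _map_to_reference(X[mask, j], ref_j)

    values = pd.DataFrame(out, index=cohort.values.index, columns=cohort.values.columns)
    return ExpressionCohort(values, cohort.metadata)


def pca_embed(cohort: ExpressionCohort, k: int) -> tuple[pd.DataFrame, np.ndarray]:
    """Project samples onto the top-k principal axes of gene space.

    Missing values are mean-imputed per gene (PCA only; scoring never sees
    imputed values).  Returns (samples x k coordinates, explained-variance
    fractions, non-increasing).
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if k > min(cohort.n_genes, cohort.n_samples):
        raise ValueError("k exceeds min(genes, samples)")
    X = cohort.values.to_numpy(dtype=float).T  # samples x genes
    if np.isnan(X).any():
        gene_means = np.nanmean(X, axis=0)
        gene_means = np.where(np.isnan(gene_means), 0.0, gene_means)
        idx = np.where(np.isnan(X))
        X = X.copy()
        X[idx] = np.take(gene_means, idx[1])
    pca = PCA(n_components=k, svd_solver="full" if min(X.shape) < 500 else "auto")
    coords = pca.fit_transform(X)
    evr = np.nan_to_num(pca.explained_variance_ratio_)  # zero-variance data -> 0, not NaN
    frame = pd.DataFrame(coords, index=cohort.sample_ids,
                         columns=[f"PC{i+1}" for i in range(k)])
    return frame, evr


def detect_duplicates(
    cohort: ExpressionCohort,
    corr_threshold: float = 0.99,
    blacklist: Iterable[str] | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Flag duplicate samples and return the retained unique-case list.

    Three rules: (i) samples sharing a patient_id keep only the
    lexicographically first sample_id; (ii) cross-patient pairs whose
    Pearson correlation reaches ``corr_threshold`` are reported for manual
    review (not auto-removed); (iii) blacklisted patient_ids are removed
    unconditionally.

    Returns (report DataFrame with columns sample_id, patient_id, flag,
    detail; retained sample_id list).
    """
    if not (0 < corr_threshold <= 1):
        raise ValueError("corr_threshold must be in (0, 1]")
    black = {str(p) for p in (blacklist or ())}
    meta = cohort.metadata
    rows: list[dict] = []
    retained: list[str] = []

    for sid in sorted(cohort.sample_ids):
        pid = str(meta.loc[sid, "patient_id"])
        if pid in black:
            rows.append({"sample_id": sid, "patient_id": pid, "flag": "blacklisted",
                         "detail": "patient on blacklist"})
    removed = {r["sample_id"] for r in rows}

    by_patient: dict[str, list[str]] = {}
    for sid in sorted(cohort.sample_ids):
        if sid in removed:
            continue
        by_patient.setdefault(str(meta.loc[sid, "patient_id"]), []).append(sid)
    for pid, sids in by_patient.items():
        retained.append(sids[0])
        for extra in sids[1:]:
            rows.append({"sample_id": extra, "patient_id": pid, "flag": "duplicate-patient",
                         "detail": f"kept {sids[0]}"})

    # cross-patient near-duplicates: reported only
    retained_in_order = [s for s in cohort.sample_ids if s in set(retained)]
    if len(retained_in_order) >= 2:
        sub = cohort.values[retained_in_order]
        corr = np.corrcoef(sub.to_numpy(dtype=float), rowvar=False)
        pids = [str(meta.loc[s, "patient_id"]) for s in retained_in_order]
        for i in range(len(retained_in_order)):
            for j in range(i + 1, len(retained_in_order)):
                if pids[i] != pids[j] and corr[i, j] >= corr_threshold:
                    rows.append({
                        "sample_id": retained_in_order[j],
                        "patient_id": pids[j],
                        "flag": "high-correlation",
                        "detail": f"r={corr[i, j]:.4f} with {retained_in_order[i]}",
                    })
    report = pd.DataFrame(rows, columns=["sample_id", "patient_id", "flag", "detail"])
    return report, retained_in_order
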