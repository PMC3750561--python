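"""End-to-end orchestration: load/QC -> gene sets -> scoring -> calls ->
frequencies -> subgrouping -> clinical associations -> cross-cohort
comparison, with a checksummed run manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from ._version import __version__
from .clinical import fisher_association, survival_scan
from .expression import ExpressionCohort, load_expression, quantile_normalize, pca_embed, detect_duplicates
from .genesets import read_gmt, harmonize_symbols, filter_sets, write_gmt
from .scoring import score_cohort, collection_hash
from .subgroups import (
    aberration_frequencies,
    call_aberrations,
    cross_group_features,
    extract_subgroups,
    hierarchical_cluster,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run (YAML-mappable field for field)."""

    expression: str
    metadata: str
    gmt: str
    out_dir: str
    alias_map: str | None = None
    blacklist: str | None = None
    B: int = 1000
    seed: int = 0
    alpha: float = 0.05
    min_set_size: int = 10
    max_set_size: int = 1000
    subgroup_min: int = 20
    subgroup_max: int = 30
    k_override: dict = field(default_factory=dict)  # cohort label -> k
    corr_threshold: float = 0.99
    missing_token: str = "NA"

    def __post_init__(self) -> None:
        if self.B < 100:
            raise ValueError("B must be >= 100")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def validate_paths(self) -> None:
        for name in ("expression", "metadata", "gmt", "alias_map", "blacklist"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"config path {name!r} does not exist: {p}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage in order and return the run manifest.

    Each stage's outputs are written under ``config.out_dir`` and
    checksummed; a failing stage aborts with earlier outputs intact.
    """
    config.validate_paths()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": asdict(config),
        "stages": [],
        "outputs": {},
    }

    def finish_stage(name: str, t0: float, files: list[Path], **info) -> None:
        for f in files:
            manifest["outputs"][f.name] = _sha256(f)
        manifest["stages"].append({"name": name, "seconds": round(time.time() - t0, 3), **info})
        logger.info("stage %s done in %.1fs %s", name, time.time() - t0, info)

    # --- load & QC -----------------------------------------------------
    t0 = time.time()
    cohort = load_expression(config.expression, config.metadata, missing_token=config.missing_token)
    blacklist = None
    if config.blacklist:
        blacklist = [l.strip() for l in Path(config.blacklist).read_text().splitlines() if l.strip()]
    qc_report, retained = detect_duplicates(cohort, corr_threshold=config.corr_threshold,
                                            blacklist=blacklist)
    cohort = cohort.subset(retained)
    normed = quantile_normalize(cohort)
    coords, evr = pca_embed(normed, k=min(2, cohort.n_samples - 1, cohort.n_genes))
    qc_path = out / "qc_flagged_samples.tsv"
    qc_report.to_csv(qc_path, sep="\t", index=False)
    pca_path = out / "pca_coordinates.tsv"
    coords.assign().to_csv(pca_path, sep="\t", index_label="sample_id")
    finish_stage("load_qc", t0, [qc_path, pca_path],
                 n_genes=cohort.n_genes, n_samples=cohort.n_samples,
                 explained_variance=[float(v) for v in evr])

    # --- gene sets -----------------------------------------------------
    t0 = time.time()
    collection = read_gmt(config.gmt)
    if config.alias_map:
        alias = dict(pd.read_csv(config.alias_map, sep="\t", header=None).itertuples(index=False, name=None))
        collection = harmonize_symbols(collection, alias)
    collection, removal = filter_sets(collection, universe=cohort.gene_symbols,
                                      min_size=config.min_set_size, max_size=config.max_set_size)
    if len(collection) == 0:
        raise RuntimeError("gene set preparation: no set survives filtering")
    gmt_path = out / "genesets_filtered.gmt"
    write_gmt(collection, gmt_path)
    rem_path = out / "genesets_removed.tsv"
    removal.to_csv(rem_path, sep="\t", index=False)
    finish_stage("genesets", t0, [gmt_path, rem_path], n_sets=len(collection),
                 n_removed=len(removal))

    # --- scoring (un-normalized log ratios: ranking is per-sample) ----
    t0 = time.time()
    profiles = score_cohort(cohort, collection, B=config.B, seed=config.seed)
    score_files = []
    for name, frame in (("combined", profiles.combined),
                        ("p_enrichment", profiles.p_enrichment),
                        ("p_depletion", profiles.p_depletion)):
        p = out / f"scores_{name}.tsv"
        frame.to_csv(p, sep="\t", index_label="pathway")
        score_files.append(p)
    run_info = {"B": config.B, "seed": config.seed, "collection_sha256": collection_hash(collection),
                "min_set_size": config.min_set_size, "max_set_size": config.max_set_size,
                "version": __version__}
    info_path = out / "scoring_manifest.json"
    info_path.write_text(json.dumps(run_info, indent=2))
    finish_stage("scoring", t0, score_files + [info_path])

    # --- calls & per-cohort frequencies -------------------------------
    t0 = time.time()
    calls = call_aberrations(profiles, alpha=config.alpha)
    calls_path = out / "aberration_calls.tsv"
    calls.to_csv(calls_path, sep="\t", index_label="pathway")
    cancer_of = cohort.metadata["cancer_label"].astype(str)
    freqs = aberration_frequencies(calls, cancer_of)
    freq_path = out / "cohort_frequencies.tsv"
    freqs.to_csv(freq_path, sep="\t", index=False)
    finish_stage("calls_frequencies", t0, [calls_path, freq_path])

    # --- per-cohort subgrouping ---------------------------------------
    t0 = time.time()
    assignments = {}
    rows = []
    for label in sorted(cancer_of.unique()):
        ids = cancer_of.index[cancer_of == label].tolist()
        if len(ids) < 2:
            logger.warning("cohort %s has < 2 samples; skipping subgrouping", label)
            continue
        feats = profiles.combined[ids].T  # samples x pathways
        tree = hierarchical_cluster(feats)
        assignment = extract_subgroups(
            tree, cohort=label, min_size=min(config.subgroup_min, len(ids)),
            max_size=config.subgroup_max,
            k_override=config.k_override.get(label), features=feats)
        assignments[label] = assignment
        (out / f"dendrogram_{label}.nwk").write_text(assignment.tree.to_newick() + "\n")
        for sid, sg in assignment.labels.items():
            rows.append({"sample_id": sid, "cohort": label, "subgroup": int(sg)})
    sg_path = out / "subgroups.tsv"
    pd.DataFrame(rows).to_csv(sg_path, sep="\t", index=False)
    finish_stage("subgrouping", t0, [sg_path],
                 n_subgroups={k: a.n_subgroups for k, a in assignments.items()})

    # --- clinical associations ----------------------------------------
    t0 = time.time()
    clin_files = []
    meta = cohort.metadata
    have_survival = meta["survival_days"].notna() & meta["event"].notna()
    for label, assignment in assignments.items():
        ids = assignment.labels.index
        surv_ids = [s for s in ids if have_survival.get(s, False)]
        if len(surv_ids) >= 4:
            surv = pd.DataFrame({
                "time": meta.loc[surv_ids, "survival_days"].astype(float),
                "event": meta.loc[surv_ids, "event"].astype(bool),
            })
            scan = survival_scan(assignment, surv, alpha=config.alpha)
            p = out / f"survival_scan_{label}.tsv"
            scan.to_csv(p, sep="\t", index=False)
            clin_files.append(p)
        subtype = meta.loc[ids, "prior_subtype"]
        if subtype.notna().any():
            assoc_rows = []
            for value in sorted(subtype.dropna().astype(str).unique()):
                binary = subtype.astype(str) == value
                assoc = fisher_association(assignment, binary, alpha=config.alpha)
                assoc["label"] = value
                assoc_rows.append(assoc)
            p = out / f"label_associations_{label}.tsv"
            pd.concat(assoc_rows, ignore_index=True).to_csv(p, sep="\t", index=False)
            clin_files.append(p)
    finish_stage("clinical", t0, clin_files)

    # --- cross-cohort subgroup comparison -----------------------------
    t0 = time.time()
    cross_files = []
    if assignments:
        tables = []
        for label, assignment in assignments.items():
            mapping = {sid: f"{label}/{int(sg)}" for sid, sg in assignment.labels.items()}
            tables.append(aberration_frequencies(calls[list(mapping)], mapping))
        feats = cross_group_features(tables)
        if len(feats) >= 2:
            tree = hierarchical_cluster(feats)
            p = out / "cross_cohort_dendrogram.nwk"
            p.write_text(tree.to_newick() + "\n")
            cross_files.append(p)
        p = out / "subgroup_frequency_features.tsv"
        feats.to_csv(p, sep="\t", index_label="subgroup")
        cross_files.append(p)
    finish_stage("cross_cohort", t0, cross_files)

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
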