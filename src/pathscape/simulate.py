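"""Synthetic cohort generator with known ground truth.

Emulates the statistical structure of multi-cancer log-ratio expression
data measured against a common reference: each cancer type has its own
sparse baseline shift (so cancers separate in PCA), planted subgroups shift
designated pathways' member genes coherently up (enrichment, +delta) or
down (depletion, -delta) on top of Gaussian noise, near-duplicate samples
sharing a patient id exercise QC, and exponential survival times with
subgroup-dependent hazards exercise the survival scan.  Every generator is
bit-reproducible given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import ExpressionCohort
from .genesets import GeneSet, GeneSetCollection


@dataclass
class SubgroupSpec:
    """One planted subgroup: its size and the pathways it aberrates."""

    size: int
    aberrations: dict[str, str]  # pathway name -> "ENRICHED" | "DEPLETED"
    hazard_multiplier: float = 1.0

    def __post_init__(self) -> None:
        for state in self.aberrations.values():
            if state not in ("ENRICHED", "DEPLETED"):
                raise ValueError(f"unknown aberration state {state!r}")
        if self.size < 1:
            raise ValueError("subgroup size must be >= 1")
        if self.hazard_multiplier <= 0:
            raise ValueError("hazard multiplier must be positive")


@dataclass
class CancerSpec:
    label: str
    subgroups: list[SubgroupSpec]

    @property
    def n_samples(self) -> int:
        return sum(sg.size for sg in self.subgroups)


@dataclass
class CohortDesign:
    """Full specification of a synthetic multi-cancer cohort."""

    n_genes: int
    cancers: list[CancerSpec]
    effect_size: float = 1.0  # delta: planted per-gene log-ratio shift
    noise_sd: float = 1.0  # sigma of Gaussian noise on the log-ratio scale
    baseline_fraction: float = 0.10  # fraction of genes shifted per cancer baseline
    baseline_magnitude: float = 1.0
    n_duplicates: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.effect_size <= 0:
            raise ValueError("effect_size must be > 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        labels = [c.label for c in self.cancers]
        if len(labels) != len(set(labels)):
            raise ValueError("cancer labels must be unique")

    @property
    def n_samples(self) -> int:
        return sum(c.n_samples for c in self.cancers)


@dataclass
class GroundTruth:
    """What the generator planted, for end-to-end validation."""

    subgroup: pd.Series  # sample_id -> "<cancer>/<subgroup index>"
    aberrations: dict[tuple[str, str], str]  # (sample_id, pathway) -> state
    hazard_multiplier: pd.Series  # sample_id -> multiplier
    duplicate_pairs: list[tuple[str, str]] = field(default_factory=list)


def generate_genesets(
    n_sets: int,
    size_range: tuple[int, int],
    universe_size: int,
    overlap_fraction: float = 0.0,
    seed: int = 0,
    sentinels: bool = True,
) -> GeneSetCollection:
    """Random gene-set collection over a synthetic universe G0001..G<N>.

    Set sizes are uniform in ``size_range``; ``overlap_fraction`` of each
    set's genes is shared with the previous set.  When ``sentinels`` is on
    and the universe permits, extra sets of size 9 and 1001 are appended to
    straddle the standard 10/1000 size-filter bounds.
    """
    low, high = size_range
    if not (1 <= low <= high <= universe_size):
        raise ValueError("infeasible size range for the universe")
    if not (0 <= overlap_fraction < 1):
        raise ValueError("overlap_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    width = len(str(universe_size))
    universe = np.array([f"G{i + 1:0{width}d}" for i in range(universe_size)])

    sets: list[GeneSet] = []
    prev: np.ndarray | None = None
    cursor = 0  # rolling pointer so overlap_fraction=0 gives disjoint sets while room lasts
    for i in range(n_sets):
        size = int(rng.integers(low, high + 1))
        n_shared = int(np.floor(overlap_fraction * size)) if prev is not None else 0
        n_shared = min(n_shared, len(prev) if prev is not None else 0)
        shared = rng.choice(prev, size=n_shared, replace=False) if n_shared else np.array([], dtype=universe.dtype)
        n_fresh = size - n_shared
        if cursor + n_fresh <= universe_size:
            fresh = universe[cursor : cursor + n_fresh]
            cursor += n_fresh
        else:  # universe exhausted: draw the remainder at random, avoiding the shared part
            pool = np.setdiff1d(universe, shared, assume_unique=False)
            fresh = rng.choice(pool, size=n_fresh, replace=False)
        genes = frozenset(np.concatenate([shared, fresh]).tolist())
        sets.append(GeneSet(name=f"SET{i + 1:04d}", genes=genes, source="USER",
                            description=f"synthetic set {i + 1}"))
        prev = np.asarray(sorted(genes))

    if sentinels:
        if universe_size >= 9:
            genes = frozenset(rng.choice(universe, size=9, replace=False).tolist())
            sets.append(GeneSet(name="SENTINEL_SMALL", genes=genes, source="USER",
                                description="size-9 sentinel (below the size-10 filter)"))
        if universe_size >= 1001:
            genes = frozenset(rng.choice(universe, size=1001, replace=False).tolist())
            sets.append(GeneSet(name="SENTINEL_LARGE", genes=genes, source="USER",
                                description="size-1001 sentinel (above the size-1000 filter)"))
    return GeneSetCollection(sets=sets, universe=frozenset(universe.tolist()))


def generate_cohort(
    design: CohortDesign, collection: GeneSetCollection
) -> tuple[ExpressionCohort, GroundTruth]:
    """Simulate the expression matrix, metadata and ground truth of a design.

    entry = cancer baseline + planted shift (+/-delta for member genes of
    the sample's subgroup pathways) + N(0, sigma).  Duplicates are injected
    as near-copies (noise sd sigma/10) sharing the source patient_id.
    """
    rng = np.random.default_rng(design.seed)
    for cancer in design.cancers:
        for sg in cancer.subgroups:
            for pw in sg.aberrations:
                if pw not in collection.names:
                    raise ValueError(f"planted pathway {pw!r} not in the collection")

    n_genes = design.n_genes
    width = len(str(n_genes))
    genes = [f"G{i + 1:0{width}d}" for i in range(n_genes)]
    gene_pos = {g: i for i, g in enumerate(genes)}
    member_rows = {
        s.name: np.array(sorted(gene_pos[g] for g in s.genes if g in gene_pos), dtype=int)
        for s in collection.sets
    }

    cols, meta_rows = [], []
    truth_subgroup, truth_hazard = {}, {}
    truth_aber: dict[tuple[str, str], str] = {}
    values = np.empty((n_genes, design.n_samples))

    j = 0
    for cancer in design.cancers:
        baseline = np.zeros(n_genes)
        n_shift = int(round(design.baseline_fraction * n_genes))
        if n_shift:
            idx = rng.choice(n_genes, size=n_shift, replace=False)
            baseline[idx] = rng.choice([-design.baseline_magnitude, design.baseline_magnitude],
                                       size=n_shift)
        for gi, sg in enumerate(cancer.subgroups, start=1):
            shift = np.zeros(n_genes)
            for pw, state in sg.aberrations.items():
                rows = member_rows[pw]
                shift[rows] += design.effect_size if state == "ENRICHED" else -design.effect_size
            for _ in range(sg.size):
                sid = f"{cancer.label}-{j + 1:04d}"
                values[:, j] = baseline + shift + rng.normal(0.0, design.noise_sd, n_genes)
                cols.append(sid)
                meta_rows.append({"sample_id": sid, "patient_id": f"P{j + 1:04d}",
                                  "cancer_label": cancer.label,
                                  "prior_subtype": f"{cancer.label}/sg{gi}"})
                truth_subgroup[sid] = f"{cancer.label}/sg{gi}"
                truth_hazard[sid] = sg.hazard_multiplier
                for pw, state in sg.aberrations.items():
                    truth_aber[(sid, pw)] = state
                j += 1

    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    frame = pd.DataFrame(values, index=genes, columns=cols)

    duplicate_pairs: list[tuple[str, str]] = []
    if design.n_duplicates:
        src = rng.choice(design.n_samples, size=design.n_duplicates, replace=False)
        dup_cols, dup_meta = [], []
        for k, s in enumerate(sorted(int(x) for x in src)):
            sid = cols[s]
            dup_id = f"{sid}-DUP{k + 1}"
            dup = frame[sid].to_numpy() + rng.normal(0.0, design.noise_sd / 10.0, n_genes)
            dup_cols.append(pd.Series(dup, index=genes, name=dup_id))
            row = meta.loc[sid].copy()
            row.name = dup_id
            dup_meta.append(row)
            duplicate_pairs.append((sid, dup_id))
            truth_subgroup[dup_id] = truth_subgroup[sid]
            truth_hazard[dup_id] = truth_hazard[sid]
        frame = pd.concat([frame, pd.concat(dup_cols, axis=1)], axis=1)
        meta = pd.concat([meta, pd.DataFrame(dup_meta)])

    meta["survival_days"] = np.nan
    meta["event"] = np.nan
    cohort = ExpressionCohort(frame, meta)
    truth = GroundTruth(
        subgroup=pd.Series(truth_subgroup, name="subgroup"),
        aberrations=truth_aber,
        hazard_multiplier=pd.Series(truth_hazard, name="hazard_multiplier"),
        duplicate_pairs=duplicate_pairs,
    )
    return cohort, truth


def _calibrate_censoring(rates: np.ndarray, target: float) -> float:
    """Upper bound c of Uniform(0, c) censoring achieving the target
    expected censored fraction for a mixture of exponential event times."""
    from scipy.optimize import brentq

    def censored_fraction(c: float) -> float:
        return float(np.mean((1.0 - np.exp(-rates * c)) / (rates * c)))

    # censored_fraction decreases from 1 (c->0) to 0 (c->inf)
    lo, hi = 1e-9, 1.0
    while censored_fraction(hi) > target:
        hi *= 2.0
        if hi > 1e12:
            raise RuntimeError("censoring calibration failed")
    return float(brentq(lambda c: censored_fraction(c) - target, lo, hi))


def generate_survival(
    truth: GroundTruth,
    base_rate: float = 1.0 / 365.0,
    censoring_fraction: float = 0.2,
    seed: int = 0,
) -> pd.DataFrame:
    """Exponential survival with subgroup-dependent hazards.

    Event time ~ Exp(base_rate x hazard multiplier); independent
    Uniform(0, c) censoring with c calibrated so the expected censored
    fraction equals ``censoring_fraction``.  Returns a DataFrame indexed by
    sample_id with columns time, event.
    """
    if base_rate <= 0:
        raise ValueError("base_rate must be > 0")
    if not (0 <= censoring_fraction < 1):
        raise ValueError("censoring_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    ids = truth.hazard_multiplier.index.tolist()
    rates = base_rate * truth.hazard_multiplier.to_numpy(dtype=float)
    event_times = rng.exponential(1.0 / rates)
    if censoring_fraction == 0:
        times, events = event_times, np.ones(len(ids), dtype=bool)
    else:
        c = _calibrate_censoring(rates, censoring_fraction)
        censor_times = rng.uniform(0.0, c, size=len(ids))
        events = event_times <= censor_times
        times = np.where(events, event_times, censor_times)
    times = np.maximum(times, 1e-9)  # keep strictly positive
    return pd.DataFrame({"time": times, "event": events}, index=pd.Index(ids, name="sample_id"))


def default_design(seed: int = 0, collection: GeneSetCollection | None = None
                   ) -> tuple[CohortDesign, GeneSetCollection]:
    """The canonical synthetic study: 3 cancers x 100 samples, 2000 genes,
    200 gene sets of 20-100 genes, 3 subgroups per cancer (34/33/33) each
    planting 8 pathway aberrations at delta = 1.0 over noise sd 1.0, two
    injected duplicates, and one hazard-ratio-3 subgroup per cancer."""
    if collection is None:
        collection = generate_genesets(200, (20, 100), universe_size=2000,
                                       overlap_fraction=0.0, seed=seed, sentinels=False)
    names = collection.names
    cancers = []
    for ci, label in enumerate(("CAN1", "CAN2", "CAN3")):
        subgroups = []
        for gi, size in enumerate((34, 33, 33)):
            start = (ci * 3 + gi) * 8
            planted = {names[(start + k) % len(names)]: ("ENRICHED" if k % 2 == 0 else "DEPLETED")
                       for k in range(8)}
            subgroups.append(SubgroupSpec(size=size, aberrations=planted,
                                          hazard_multiplier=3.0 if gi == 0 else 1.0))
        cancers.append(CancerSpec(label=label, subgroups=subgroups))
    design = CohortDesign(n_genes=2000, cancers=cancers, effect_size=1.0, noise_sd=1.0,
                          n_duplicates=2, seed=seed)
    return design, collection
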