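"""Synthetic case-control cohorts with a batch effect confounded with case status.

This module simulates the data structure of a two-cohort (discovery /
validation) ovarian-cancer study combining two serum proteins (CA125, HE4)
with chromosome-arm copy-number scores from cell-free DNA.  The defining
pathology it reproduces is a *perfectly confounded batch effect*: one block
of early library batches contains only cancer and benign samples from a
single sample-ID prefix, and a subset of copy-number features carries an
additive technical offset in exactly those batches.  A classifier trained on
such a cohort can learn the technical offset as if it were cancer signal,
inflating cross-validation performance relative to an unconfounded
validation cohort.

Distributional model
--------------------
* Protein log-concentrations are bivariate normal on the zlog scale: healthy
  samples are standard normal (by construction of the zlog transform), and
  benign/cancer conditions add condition-specific location shifts, with a
  configurable inter-protein correlation.  Concentrations are obtained by
  inverting the zlog transform, hence are log-normal and strictly positive.
* Copy-number scores are standard normal, plus an additive cancer effect on
  a designated feature subset and an additive batch offset (in SD units) on
  a possibly different subset for affected-batch samples.
* Fragmentation principal components, when requested, are standard normal
  noise (no signal), mirroring their nuisance role in the audit.

All randomness flows from one :class:`numpy.random.Generator` seeded from a
single integer, so a (spec, seed) pair reproduces tables bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

COHORTS = ("discovery", "validation")
CONDITIONS = ("healthy", "benign", "cancer")
GROUPS = ("affected", "unaffected")

CATEGORY_PROTEIN_CONC = "protein_concentration"
CATEGORY_PROTEIN_ZLOG = "protein_zlog"
CATEGORY_COPY_NUMBER = "copy_number"
CATEGORY_FRAGMENTATION = "fragmentation_pc"

PROTEINS = ("CA125", "HE4")

# Chromosome arms with meaningful cfDNA coverage: 22 autosomes minus the five
# acrocentric short arms (13p, 14p, 15p, 21p, 22p) -> 39 arm-level features.
_ACROCENTRIC_P = {"13p", "14p", "15p", "21p", "22p"}
ARM_NAMES: Tuple[str, ...] = tuple(
    f"cn_{chrom}{arm}"
    for chrom in range(1, 23)
    for arm in ("p", "q")
    if f"{chrom}{arm}" not in _ACROCENTRIC_P
)

# Default identity of the batch-affected copy-number features (17 of 39).
# The three arms known to separate prefixes almost perfectly (11p, 18p, 19q)
# are included; the remaining 14 are an illustrative, fixed choice.
DEFAULT_BATCH_AFFECTED: Tuple[str, ...] = (
    "cn_11p", "cn_18p", "cn_19q",
    "cn_1p", "cn_2q", "cn_3p", "cn_4p", "cn_5p", "cn_6p", "cn_7q",
    "cn_9p", "cn_10q", "cn_12p", "cn_14q", "cn_16p", "cn_20q", "cn_22q",
)

# Arms with a (weak) genuine cancer shift; chosen among arms recurrently
# altered in high-grade serous ovarian cancer.
DEFAULT_CANCER_AFFECTED: Tuple[str, ...] = (
    "cn_3q", "cn_8q", "cn_17p", "cn_17q", "cn_4q", "cn_5q",
)


def copy_number_feature_names(n: int) -> Tuple[str, ...]:
    """First ``n`` copy-number feature names (chromosome arms, then generic)."""
    if n <= len(ARM_NAMES):
        return ARM_NAMES[:n]
    extra = tuple(f"cn_x{i}" for i in range(len(ARM_NAMES) + 1, n + 1))
    return ARM_NAMES + extra


@dataclass(frozen=True)
class SampleMetadata:
    """Per-sample study metadata."""

    sample_id: str
    prefix: str
    batch: int
    cohort: str
    condition: str

    def __post_init__(self) -> None:
        if not self.sample_id.startswith(self.prefix):
            raise ValueError(f"prefix {self.prefix!r} is not a leading substring of {self.sample_id!r}")
        if self.cohort not in COHORTS:
            raise ValueError(f"unknown cohort {self.cohort!r}; expected one of {COHORTS}")
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}; expected one of {CONDITIONS}")


def metadata_frame(metadata: Sequence[SampleMetadata]) -> pd.DataFrame:
    """Metadata records as a DataFrame (columns sample_id, prefix, batch, cohort, condition)."""
    frame = pd.DataFrame(
        [(m.sample_id, m.prefix, m.batch, m.cohort, m.condition) for m in metadata],
        columns=["sample_id", "prefix", "batch", "cohort", "condition"],
    )
    if frame["sample_id"].duplicated().any():
        dupes = frame.loc[frame["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample IDs: {dupes}")
    return frame


def infer_category(feature_name: str) -> str:
    if feature_name.startswith("zlog_"):
        return CATEGORY_PROTEIN_ZLOG
    if feature_name.startswith("cn_"):
        return CATEGORY_COPY_NUMBER
    if feature_name.startswith("pc_"):
        return CATEGORY_FRAGMENTATION
    return CATEGORY_PROTEIN_CONC


@dataclass
class FeatureTable:
    """Samples x features numeric matrix with per-feature category tags.

    ``raw_scale`` marks tables holding measurements on their original scale,
    for which protein concentrations must be strictly positive; derived
    tables (z-scores and the like) set it to False.
    """

    values: pd.DataFrame
    categories: pd.Series = None  # type: ignore[assignment]
    raw_scale: bool = True

    def __post_init__(self) -> None:
        if self.categories is None:
            self.categories = pd.Series(
                {name: infer_category(name) for name in self.values.columns}
            )
        self.categories = self.categories.reindex(self.values.columns)
        if self.categories.isna().any():
            missing = list(self.categories.index[self.categories.isna()])
            raise ValueError(f"features without a category tag: {missing}")
        if self.values.isna().any().any():
            raise ValueError("feature table contains missing values")
        conc = [f for f in self.values.columns if self.categories[f] == CATEGORY_PROTEIN_CONC]
        if self.raw_scale and conc and (self.values[conc] <= 0).any().any():
            raise ValueError("protein concentrations must be strictly positive")
        if self.values.index.duplicated().any():
            raise ValueError("duplicate sample IDs in feature table")

    @property
    def sample_ids(self) -> List[str]:
        return list(self.values.index)

    @property
    def feature_names(self) -> List[str]:
        return list(self.values.columns)

    def features_of(self, category: str) -> List[str]:
        return [f for f in self.values.columns if self.categories[f] == category]

    def subset_samples(self, sample_ids: Sequence[str]) -> "FeatureTable":
        return FeatureTable(self.values.loc[list(sample_ids)].copy(), self.categories.copy(), self.raw_scale)

    def subset_features(self, names: Sequence[str]) -> "FeatureTable":
        missing = [n for n in names if n not in self.values.columns]
        if missing:
            raise KeyError(f"unknown features: {missing}")
        return FeatureTable(self.values[list(names)].copy(), self.categories[list(names)].copy(), self.raw_scale)


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic confounded cohort.

    ``counts`` maps (cohort, condition, group) to a sample count, where group
    is ``"affected"`` (samples in the early, confounded batches, carrying the
    affected prefix) or ``"unaffected"``.  Protein shifts are per-condition
    location shifts on the zlog scale (units of healthy-population SD).
    ``copy_number_batch_offset`` is the additive technical shift, in SD
    units, applied to ``batch_affected_features`` for affected-group samples;
    ``copy_number_cancer_effect`` is the additive biological shift on
    ``cancer_affected_features`` for cancer samples of either group.
    """

    counts: Mapping[Tuple[str, str, str], int] = field(default_factory=dict)
    n_copy_number_features: int = 39
    n_fragmentation_pcs: int = 0
    affected_batch_ids: Tuple[int, ...] = tuple(range(1, 17))
    unaffected_batch_ids: Tuple[int, ...] = tuple(range(17, 39))
    affected_prefix: str = "PGDX"
    unaffected_prefix: str = "CGPL"
    protein_shifts: Mapping[str, Tuple[float, float]] = field(
        default_factory=lambda: {
            "healthy": (0.0, 0.0),
            "benign": (1.1, 0.3),
            "cancer": (2.2, 2.1),
        }
    )
    protein_log_correlation: float = 0.57
    batch_affected_features: Tuple[str, ...] = DEFAULT_BATCH_AFFECTED
    copy_number_batch_offset: float = -3.0
    cancer_affected_features: Tuple[str, ...] = DEFAULT_CANCER_AFFECTED
    copy_number_cancer_effect: float = 0.3
    copy_number_correlation: float = 0.0
    leakage_mode: bool = True
    mixed_batch_id: int | None = None
    enforce_paper_structure: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for key, n in self.counts.items():
            cohort, condition, group = key
            if cohort not in COHORTS or condition not in CONDITIONS or group not in GROUPS:
                raise ValueError(f"malformed count key {key!r}")
            if n < 0:
                raise ValueError(f"negative sample count {n} for {key!r}")
        if set(self.affected_batch_ids) & set(self.unaffected_batch_ids):
            raise ValueError("affected and unaffected batch ID sets must be disjoint")
        cn_names = set(copy_number_feature_names(self.n_copy_number_features))
        for label, subset in (
            ("batch_affected_features", self.batch_affected_features),
            ("cancer_affected_features", self.cancer_affected_features),
        ):
            unknown = set(subset) - cn_names
            if unknown:
                raise ValueError(f"{label} not among copy-number features: {sorted(unknown)}")
        if self.enforce_paper_structure:
            for (cohort, condition, group), n in self.counts.items():
                if group == "affected" and n > 0 and (condition == "healthy" or cohort == "validation"):
                    raise ValueError(
                        "affected batches must contain no healthy and no validation "
                        f"samples, got {n} for {(cohort, condition, group)}"
                    )
        if not -1 < self.protein_log_correlation < 1:
            raise ValueError("protein_log_correlation must be in (-1, 1)")
        if not 0 <= self.copy_number_correlation < 1:
            raise ValueError("copy_number_correlation must be in [0, 1)")

    def with_(self, **kwargs) -> "CohortSpec":
        return replace(self, **kwargs)

    def total(self, group: str | None = None) -> int:
        return sum(n for (c, cond, g), n in self.counts.items() if group is None or g == group)


def paper_default_spec(**overrides) -> CohortSpec:
    """Spec whose marginals match the printed study structure.

    85 affected ("PGDX") samples, all discovery, none healthy; 394 unaffected
    ("CGPL") samples; 182 discovery healthy; 94 discovery cancer split
    42 affected / 52 unaffected.  Benign and validation counts are not
    printed in the study and are documented package defaults.
    """
    counts = {
        ("discovery", "healthy", "unaffected"): 182,
        ("discovery", "benign", "unaffected"): 60,
        ("discovery", "cancer", "unaffected"): 52,
        ("discovery", "benign", "affected"): 43,
        ("discovery", "cancer", "affected"): 42,
        ("validation", "healthy", "unaffected"): 40,
        ("validation", "benign", "unaffected"): 30,
        ("validation", "cancer", "unaffected"): 30,
    }
    return CohortSpec(counts=counts, **overrides)


def _assign_affected_batches(
    spec: CohortSpec, condition_counts: Dict[str, int], rng: np.random.Generator
) -> Dict[str, List[int]]:
    """Assign affected samples to batches, largely homogeneous by condition.

    The affected batch list is split into contiguous per-condition blocks
    proportional to the condition counts; samples round-robin within their
    block.  If ``mixed_batch_id`` is set, one cancer and one benign sample
    are moved into that batch so it holds both conditions.
    """
    batches = list(spec.affected_batch_ids)
    conditions = [c for c in CONDITIONS if condition_counts.get(c, 0) > 0]
    total = sum(condition_counts[c] for c in conditions)
    assignment: Dict[str, List[int]] = {}
    start = 0
    for i, cond in enumerate(conditions):
        n = condition_counts[cond]
        if i == len(conditions) - 1:
            block = batches[start:]
        else:
            width = max(1, round(len(batches) * n / total))
            width = min(width, len(batches) - start - (len(conditions) - 1 - i))
            block = batches[start : start + width]
            start += width
        assignment[cond] = [block[j % len(block)] for j in range(n)]
    if spec.mixed_batch_id is not None and spec.mixed_batch_id in batches:
        for cond in ("cancer", "benign"):
            if assignment.get(cond):
                assignment[cond][0] = spec.mixed_batch_id
    return assignment


def generate_cohort(
    spec: CohortSpec, seed: int | None = None
) -> Tuple[FeatureTable, List[SampleMetadata]]:
    """Generate a synthetic cohort matching ``spec``.

    Returns a :class:`FeatureTable` with protein-concentration and
    copy-number (and optional fragmentation-PC) columns, plus the per-sample
    metadata.  Identical (spec, seed) pairs reproduce identical output.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed if seed is None else seed)

    cn_names = copy_number_feature_names(spec.n_copy_number_features)
    pc_names = tuple(f"pc_{i}" for i in range(1, spec.n_fragmentation_pcs + 1))

    # Deterministic sample ordering: sorted count keys, counter per prefix.
    keys = sorted(spec.counts)
    records: List[Tuple[str, str, str, str]] = []  # (group, cohort, condition, sample_id)
    id_counter = {"affected": 0, "unaffected": 0}
    for cohort, condition, group in keys:
        prefix = spec.affected_prefix if group == "affected" else spec.unaffected_prefix
        for _ in range(spec.counts[(cohort, condition, group)]):
            id_counter[group] += 1
            records.append((group, cohort, condition, f"{prefix}{id_counter[group]:04d}"))

    # Batch assignment.
    affected_cond_counts: Dict[str, int] = {}
    for group, cohort, condition, _ in records:
        if group == "affected":
            affected_cond_counts[condition] = affected_cond_counts.get(condition, 0) + 1
    affected_batches = _assign_affected_batches(spec, affected_cond_counts, rng)
    affected_used = {c: 0 for c in affected_cond_counts}

    unaff_batches = list(spec.unaffected_batch_ids)
    if spec.leakage_mode:
        pools = {"discovery": unaff_batches, "validation": unaff_batches}
    else:
        half = max(1, len(unaff_batches) // 2)
        pools = {"discovery": unaff_batches[:half], "validation": unaff_batches[half:]}
    unaff_used = {"discovery": 0, "validation": 0}

    metadata: List[SampleMetadata] = []
    for group, cohort, condition, sample_id in records:
        if group == "affected":
            batch = affected_batches[condition][affected_used[condition]]
            affected_used[condition] += 1
            prefix = spec.affected_prefix
        else:
            pool = pools[cohort]
            batch = pool[unaff_used[cohort] % len(pool)]
            unaff_used[cohort] += 1
            prefix = spec.unaffected_prefix
        metadata.append(SampleMetadata(sample_id, prefix, batch, cohort, condition))

    n = len(records)
    # Proteins: correlated shifts on the zlog scale, inverted to concentration.
    from .zlog import CA125_RANGE, HE4_RANGE, inverse_zlog

    rho = spec.protein_log_correlation
    cov = np.array([[1.0, rho], [rho, 1.0]])
    chol = np.linalg.cholesky(cov)
    z = rng.standard_normal((n, 2)) @ chol.T
    shifts = np.array([spec.protein_shifts[condition] for _, _, condition, _ in records])
    z += shifts
    ca125 = inverse_zlog(z[:, 0], CA125_RANGE)
    he4 = inverse_zlog(z[:, 1], HE4_RANGE)

    # Copy-number scores: equicorrelated N(0,1) baseline (a shared per-sample
    # factor emulates genome-wide coverage variation) + cancer effect + batch
    # offset.  Marginals stay standard normal.
    rho = spec.copy_number_correlation
    shared = rng.standard_normal((n, 1))
    cn = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * rng.standard_normal((n, len(cn_names)))
    cn_index = {name: j for j, name in enumerate(cn_names)}
    cancer_cols = [cn_index[f] for f in spec.cancer_affected_features]
    batch_cols = [cn_index[f] for f in spec.batch_affected_features]
    for i, (group, _, condition, _) in enumerate(records):
        if condition == "cancer" and cancer_cols:
            cn[i, cancer_cols] += spec.copy_number_cancer_effect
        if group == "affected" and batch_cols:
            cn[i, batch_cols] += spec.copy_number_batch_offset

    columns: Dict[str, np.ndarray] = {"CA125": ca125, "HE4": he4}
    for j, name in enumerate(cn_names):
        columns[name] = cn[:, j]
    if pc_names:
        pcs = rng.standard_normal((n, len(pc_names)))
        for j, name in enumerate(pc_names):
            columns[name] = pcs[:, j]

    values = pd.DataFrame(columns, index=pd.Index([r[3] for r in records], name="sample_id"))
    return FeatureTable(values), metadata


def add_zlog_features(table: FeatureTable, ranges: Mapping[str, "object"] | None = None) -> FeatureTable:
    """Append zlog-transformed columns for each protein-concentration feature.

    ``ranges`` maps analyte name to a :class:`~confaudit.zlog.ReferenceRange`;
    defaults to the CA125/HE4 ranges.  New columns are named ``zlog_<name>``.
    """
    from .zlog import CA125_RANGE, HE4_RANGE, zlog as _zlog

    if ranges is None:
        ranges = {"CA125": CA125_RANGE, "HE4": HE4_RANGE}
    values = table.values.copy()
    cats = table.categories.copy()
    for name in table.features_of(CATEGORY_PROTEIN_CONC):
        if name not in ranges:
            raise KeyError(f"no reference range supplied for analyte {name!r}")
        col = f"zlog_{name}"
        values[col] = _zlog(values[name].to_numpy(), ranges[name])
        cats[col] = CATEGORY_PROTEIN_ZLOG
    return FeatureTable(values, cats)
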