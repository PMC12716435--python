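"""Batch-effect audit: orientation-free single-feature AUCs, ANOVA feature
ordering, standardized matrices, and batch-composition / leakage checks.

A single feature's discriminative value is summarized by the Mann-Whitney
AUC computed with midranks, reported as max(a, 1 - a) so that features
anti-correlated with the target are not hidden (0.5 becomes the minimum
reportable value).  Features with reported AUC above 0.75 are flagged as
"important".  Three screens use this statistic:

* ``condition_auc_screen`` — cancer prediction within one prefix group, in a
  screening (healthy vs cancer) or diagnostic (benign vs cancer) context;
* ``prefix_confounding_screen`` — prefix prediction among discovery-cohort
  cancer samples only: a feature that predicts which *batch era* a cancer
  sample came from is carrying technical, not biological, signal.

The ANOVA ordering (one-way F-test across prefix groups within cancer
samples) sorts features so the most batch-affected appear first, and the
standardized matrix makes the offsets visible on a common scale.  Finally,
``batch_composition`` tabulates conditions and cohorts per library batch and
flags two structural pathologies: batches mixing discovery and validation
samples (data leakage) and batches holding a single condition (perfect
confounding of batch with case status).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

from .synthetic_cohort import FeatureTable

IMPORTANCE_AUC_THRESHOLD = 0.75


@dataclass
class AuditReport:
    """Bundle of audit outputs (see module docstring)."""

    feature_auc: pd.DataFrame
    anova: pd.DataFrame
    standardized: pd.DataFrame
    batch_composition: pd.DataFrame
    flags: pd.DataFrame


def single_feature_auc(values: Sequence[float], labels: Sequence[bool]) -> float:
    """Orientation-free AUC of one feature: max(a, 1-a), a from midranks."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present to compute an AUC")
    a = roc_auc_score(labels, values)
    return max(a, 1.0 - a)


def _auc_table(values: pd.DataFrame, labels: np.ndarray, context: str) -> pd.DataFrame:
    rows = []
    for name in values.columns:
        auc = single_feature_auc(values[name].to_numpy(), labels)
        rows.append((name, context, auc, auc > IMPORTANCE_AUC_THRESHOLD))
    return pd.DataFrame(rows, columns=["feature", "context", "auc", "important"])


def prefix_confounding_screen(table: FeatureTable, metadata: pd.DataFrame) -> pd.DataFrame:
    """Per-feature AUC for predicting sample prefix among discovery cancers.

    Restricted to cancer samples of the discovery cohort; the label is
    membership in the lexicographically last prefix (with exactly two
    prefixes the orientation is irrelevant under the max rule).
    """
    meta = metadata.set_index("sample_id")
    meta = meta.loc[table.sample_ids]
    mask = (meta["condition"] == "cancer") & (meta["cohort"] == "discovery")
    sub = meta[mask]
    prefixes = sorted(sub["prefix"].unique())
    if len(prefixes) < 2:
        raise ValueError(f"need >= 2 prefixes among discovery cancer samples, got {prefixes}")
    labels = (sub["prefix"] == prefixes[-1]).to_numpy()
    values = table.subset_samples(list(sub.index)).values
    return _auc_table(values, labels, "prefix")


def condition_auc_screen(
    table: FeatureTable,
    metadata: pd.DataFrame,
    context: str,
    prefix_filter: str | None = None,
    cohort: str = "discovery",
) -> pd.DataFrame:
    """Per-feature cancer-prediction AUC within one prefix group and cohort."""
    from .lr_models import CONTEXT_CONDITIONS

    if context not in CONTEXT_CONDITIONS:
        raise ValueError(f"unknown context {context!r}")
    negative, positive = CONTEXT_CONDITIONS[context]
    meta = metadata.set_index("sample_id").loc[table.sample_ids]
    mask = meta["condition"].isin([negative, positive]) & (meta["cohort"] == cohort)
    if prefix_filter is not None:
        mask &= meta["prefix"] == prefix_filter
    sub = meta[mask]
    if sub.empty or sub["condition"].nunique() < 2:
        raise ValueError(
            f"no usable samples for context={context!r}, prefix={prefix_filter!r}, cohort={cohort!r}"
        )
    labels = (sub["condition"] == positive).to_numpy()
    values = table.subset_samples(list(sub.index)).values
    return _auc_table(values, labels, context)


def anova_order(
    table: FeatureTable,
    metadata: pd.DataFrame,
    group_by: str = "prefix",
    within_condition: str | None = "cancer",
) -> pd.DataFrame:
    """One-way ANOVA per feature across ``group_by`` groups, ascending p.

    By default runs within cancer samples grouped by prefix, so the features
    most affected by the prefix-associated batch offset sort first.  With
    two groups the F statistic equals the square of the pooled-variance t
    statistic.
    """
    meta = metadata.set_index("sample_id").loc[table.sample_ids]
    if within_condition is not None:
        meta = meta[meta["condition"] == within_condition]
    groups = meta.groupby(group_by).groups
    if len(groups) < 2:
        raise ValueError(f"ANOVA needs >= 2 groups by {group_by!r}, got {len(groups)}")
    for g, ids in groups.items():
        if len(ids) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
    values = table.values.loc[meta.index]
    rows = []
    for name in values.columns:
        samples = [values.loc[ids, name].to_numpy() for ids in groups.values()]
        if np.ptp(values[name].to_numpy()) == 0:
            f_stat, p = 0.0, 1.0  # identical across groups: no evidence
        else:
            f_stat, p = stats.f_oneway(*samples)
        rows.append((name, float(f_stat), float(p)))
    out = pd.DataFrame(rows, columns=["feature", "F", "p"])
    return out.sort_values(["p", "feature"], kind="mergesort").reset_index(drop=True)


def standardize_features(table: FeatureTable, ddof: int = 1) -> FeatureTable:
    """Z-score every feature column (mean 0, SD 1).

    ``ddof=1`` gives the sample-SD convention; pass ``ddof=0`` for the
    population SD.  A zero-variance feature is an error naming the feature.
    """
    values = table.values
    sds = values.std(axis=0, ddof=ddof)
    zero = sds[sds == 0]
    if not zero.empty:
        raise ValueError(f"zero-variance features cannot be standardized: {list(zero.index)}")
    z = (values - values.mean(axis=0)) / sds
    return FeatureTable(z, table.categories.copy(), raw_scale=False)


def batch_composition(metadata: pd.DataFrame) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Per-batch condition x cohort counts plus leakage/homogeneity flags.

    A batch is flagged for *leakage* when it holds both discovery and
    validation samples, and for *homogeneity* when it holds exactly one
    condition (so any technical offset in that batch is perfectly
    confounded with the condition).
    """
    counts = (
        metadata.groupby(["batch", "cohort", "condition"])
        .size()
        .rename("n")
        .reset_index()
        .sort_values(["batch", "cohort", "condition"])
        .reset_index(drop=True)
    )
    flags = []
    for batch, sub in metadata.groupby("batch"):
        flags.append(
            (
                batch,
                sub["cohort"].nunique() > 1,
                sub["condition"].nunique() == 1,
                len(sub),
            )
        )
    flag_frame = pd.DataFrame(flags, columns=["batch", "leakage", "homogeneous", "n_samples"])
    return counts, flag_frame


def run_audit(
    table: FeatureTable,
    metadata: pd.DataFrame,
    prefix_filter: str | None = None,
    contexts: Sequence[str] = ("screening", "diagnostic"),
) -> AuditReport:
    """Full audit: AUC screens, ANOVA ordering, standardized matrix, flags."""
    auc_parts = [prefix_confounding_screen(table, metadata)]
    for context in contexts:
        auc_parts.append(condition_auc_screen(table, metadata, context, prefix_filter))
    feature_auc = pd.concat(auc_parts, ignore_index=True)
    anova = anova_order(table, metadata)
    standardized = standardize_features(table).values
    counts, flags = batch_composition(metadata)
    return AuditReport(feature_auc, anova, standardized, counts, flags)
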