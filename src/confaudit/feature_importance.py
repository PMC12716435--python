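"""Scaled coefficients and normalized feature importances for linear models.

A raw logistic-regression coefficient depends on its feature's units; to
compare coefficients across features they are rescaled by the feature's
training-set standard deviation.  The primary mode divides the coefficient
by the SD (the convention this package adopts); an explicitly labeled
alternative multiplies by the SD (the textbook standardized coefficient,
equivalent to the coefficient the model would have after z-scoring the
feature).  The two modes must never be mixed within one comparison.

A feature's importance is |scaled| / sum(|scaled|), so importances are
nonnegative and sum to one; category importances sum member fractions.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .lr_models import FittedLinearModel

SCALING_MODES = ("divide_by_sd", "multiply_by_sd")


def scaled_coefficients(model: FittedLinearModel, mode: str = "divide_by_sd") -> pd.Series:
    """Per-feature scaled coefficients, indexed by feature name."""
    if mode not in SCALING_MODES:
        raise ValueError(f"mode must be one of {SCALING_MODES}, got {mode!r}")
    coef = model.coefficients
    sds = model.training_sds
    bad = (sds == 0) & (coef != 0)
    if mode == "divide_by_sd" and bad.any():
        names = [model.feature_names[i] for i in np.flatnonzero(bad)]
        raise ValueError(f"zero training SD with nonzero coefficient: {names}")
    if mode == "divide_by_sd":
        scaled = np.where(coef == 0, 0.0, coef / np.where(sds == 0, 1.0, sds))
    else:
        scaled = coef * sds
    return pd.Series(scaled, index=list(model.feature_names), name="scaled")


def importances(
    scaled: pd.Series, categories: Mapping[str, str] | pd.Series
) -> pd.DataFrame:
    """Importance table from scaled coefficients and per-feature categories.

    Columns: scaled, importance, category.  Importance fractions sum to 1;
    zero-coefficient features have importance exactly 0.
    """
    total = scaled.abs().sum()
    if total == 0:
        raise ValueError("all scaled coefficients are zero; importances undefined")
    cats = pd.Series(dict(categories) if not isinstance(categories, pd.Series) else categories)
    missing = [f for f in scaled.index if f not in cats.index]
    if missing:
        raise KeyError(f"features without category tags: {missing}")
    out = pd.DataFrame(
        {
            "scaled": scaled,
            "importance": scaled.abs() / total,
            "category": cats.reindex(scaled.index),
        }
    )
    out.index.name = "feature"
    return out


def category_importances(table: pd.DataFrame) -> pd.Series:
    """Summed importance fraction per feature category."""
    return table.groupby("category")["importance"].sum().sort_values(ascending=False)


def importance_table(model: FittedLinearModel, categories, mode: str = "divide_by_sd") -> pd.DataFrame:
    """Convenience: raw + scaled coefficients + importances in one frame."""
    scaled = scaled_coefficients(model, mode)
    out = importances(scaled, categories)
    out.insert(0, "coefficient", pd.Series(model.coefficients, index=list(model.feature_names)))
    return out


def compare_models(table_a: pd.DataFrame, table_b: pd.DataFrame) -> pd.DataFrame:
    """Aligned per-feature importance deltas between two importance tables.

    Features absent from one table are treated as zero-coefficient there;
    features zero in both are omitted.  ``delta = importance_b -
    importance_a``.
    """
    union = table_a.index.union(table_b.index)
    imp_a = table_a["importance"].reindex(union, fill_value=0.0)
    imp_b = table_b["importance"].reindex(union, fill_value=0.0)
    cats = table_a["category"].reindex(union).fillna(table_b["category"].reindex(union))
    out = pd.DataFrame(
        {
            "category": cats,
            "importance_a": imp_a,
            "importance_b": imp_b,
            "delta": imp_b - imp_a,
        }
    )
    out = out[(out["importance_a"] != 0) | (out["importance_b"] != 0)]
    out.index.name = "feature"
    return out.sort_values("delta")


def compare_categories(comparison: pd.DataFrame) -> pd.DataFrame:
    """Category-level importance deltas from a per-feature comparison."""
    grouped = comparison.groupby("category")[["importance_a", "importance_b"]].sum()
    grouped["delta"] = grouped["importance_b"] - grouped["importance_a"]
    return grouped.sort_values("delta")
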