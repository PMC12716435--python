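"""File formats, run configuration, and the end-to-end analysis pipeline.

The full analysis reproduces a batch-confounding audit of a multi-analyte
cancer classifier: simulate (or load) a two-cohort dataset, zlog-transform
the protein concentrations, cross-validate models on the discovery cohort,
refit on the full discovery data and score the external validation cohort,
audit the features for prefix-associated batch effects, retrain after
excluding the affected prefix, compare feature importances, and report
clinically relevant operating points.  All outputs are plain text (TSV /
JSON / YAML) and depend only on the configuration and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml
from sklearn.metrics import roc_auc_score

from . import batch_audit, clinical_metrics, feature_importance, lr_models
from .synthetic_cohort import (
    CATEGORY_COPY_NUMBER,
    CATEGORY_FRAGMENTATION,
    CATEGORY_PROTEIN_ZLOG,
    COHORTS,
    CONDITIONS,
    CohortSpec,
    FeatureTable,
    SampleMetadata,
    add_zlog_features,
    generate_cohort,
    metadata_frame,
    paper_default_spec,
)
from .zlog import CA125_RANGE, HE4_RANGE, ReferenceRange

logger = logging.getLogger("confaudit")

#: Accepted spellings for condition labels in input metadata.
CONDITION_ALIASES = {
    "healthy": "healthy",
    "no known lesions": "healthy",
    "no_known_lesions": "healthy",
    "benign": "benign",
    "benign adnexal mass": "benign",
    "cancer": "cancer",
    "ovarian cancer": "cancer",
}

METADATA_COLUMNS = ["sample_id", "prefix", "batch", "cohort", "condition"]


# ---------------------------------------------------------------- file I/O


def write_feature_table(table: FeatureTable, path) -> None:
    # %.17g keeps the float64 round trip exact
    table.values.to_csv(path, sep="\t", index_label="sample_id", float_format="%.17g")


def read_feature_table(path) -> FeatureTable:
    values = pd.read_csv(path, sep="\t", index_col="sample_id", float_precision="round_trip")
    if values.index.duplicated().any():
        dupes = list(values.index[values.index.duplicated()])
        raise ValueError(f"duplicate sample IDs in feature table: {dupes}")
    return FeatureTable(values)


def write_metadata(metadata: pd.DataFrame, path) -> None:
    metadata[METADATA_COLUMNS].to_csv(path, sep="\t", index=False)


def read_metadata(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t" if str(path).endswith((".tsv", ".txt")) else None, engine="python")
    missing = [c for c in METADATA_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"metadata missing required columns: {missing}")
    frame = frame[METADATA_COLUMNS].copy()
    if frame["sample_id"].duplicated().any():
        dupes = frame.loc[frame["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample IDs in metadata: {dupes}")
    frame["condition"] = frame["condition"].map(
        lambda c: CONDITION_ALIASES.get(str(c).strip().lower())
    )
    if frame["condition"].isna().any():
        raise ValueError(
            f"unknown condition labels; accepted: {sorted(set(CONDITION_ALIASES))}"
        )
    frame["cohort"] = frame["cohort"].str.strip().str.lower()
    if not frame["cohort"].isin(COHORTS).all():
        bad = sorted(set(frame["cohort"]) - set(COHORTS))
        raise ValueError(f"unknown cohort labels {bad}; expected {COHORTS}")
    # re-validate through the record type
    for rec in frame.itertuples(index=False):
        SampleMetadata(rec.sample_id, rec.prefix, int(rec.batch), rec.cohort, rec.condition)
    return frame


def check_alignment(table: FeatureTable, metadata: pd.DataFrame) -> None:
    """Table and metadata must describe exactly the same samples."""
    t, m = set(table.sample_ids), set(metadata["sample_id"])
    if t != m:
        only_t, only_m = sorted(t - m), sorted(m - t)
        raise ValueError(
            f"feature table / metadata mismatch: only in table {only_t[:5]}, "
            f"only in metadata {only_m[:5]}"
        )


# ----------------------------------------------------------- configuration


@dataclass
class RunConfig:
    """Configuration of one end-to-end analysis run.

    Exactly one of (``feature_path`` + ``metadata_path``) or ``spec`` is
    used; with neither supplied the paper-structure default synthetic spec
    is generated.
    """

    feature_path: str | None = None
    metadata_path: str | None = None
    spec: CohortSpec | None = None
    contexts: Tuple[str, ...] = ("screening",)
    excluded_prefix: str = "PGDX"
    reference_ranges: Mapping[str, ReferenceRange] = field(
        default_factory=lambda: {"CA125": CA125_RANGE, "HE4": HE4_RANGE}
    )
    cv_folds: int = 5
    cv_repeats: int = 10
    C: float = 1.0
    include_copy_number: bool = True
    specificity_floor: float = 0.99
    prevalence: float = clinical_metrics.DEFAULT_PREVALENCE
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.feature_path is None) != (self.metadata_path is None):
            raise ValueError("feature_path and metadata_path must be supplied together")
        if self.feature_path is not None and self.spec is not None:
            raise ValueError("supply either input paths or a simulation spec, not both")

    def to_dict(self) -> dict:
        d = {
            "feature_path": self.feature_path,
            "metadata_path": self.metadata_path,
            "spec": spec_to_dict(self.spec) if self.spec is not None else None,
            "contexts": list(self.contexts),
            "excluded_prefix": self.excluded_prefix,
            "reference_ranges": {
                k: {"lower": r.lower, "upper": r.upper, "analyte": r.analyte, "units": r.units}
                for k, r in self.reference_ranges.items()
            },
            "cv_folds": self.cv_folds,
            "cv_repeats": self.cv_repeats,
            "C": self.C,
            "include_copy_number": self.include_copy_number,
            "specificity_floor": self.specificity_floor,
            "prevalence": self.prevalence,
            "seed": self.seed,
        }
        return d


def spec_to_dict(spec: CohortSpec) -> dict:
    d = asdict(spec)
    d["counts"] = {"|".join(k): v for k, v in spec.counts.items()}
    d["protein_shifts"] = {k: list(v) for k, v in spec.protein_shifts.items()}
    for key in ("affected_batch_ids", "unaffected_batch_ids", "batch_affected_features", "cancer_affected_features"):
        d[key] = list(d[key])
    return d


def spec_from_dict(d: Mapping) -> CohortSpec:
    d = dict(d)
    d["counts"] = {tuple(k.split("|")): int(v) for k, v in d.get("counts", {}).items()}
    if "protein_shifts" in d:
        d["protein_shifts"] = {k: tuple(v) for k, v in d["protein_shifts"].items()}
    for key in ("affected_batch_ids", "unaffected_batch_ids"):
        if key in d:
            d[key] = tuple(int(x) for x in d[key])
    for key in ("batch_affected_features", "cancer_affected_features"):
        if key in d:
            d[key] = tuple(d[key])
    return CohortSpec(**d)


def write_spec_yaml(spec: CohortSpec, path) -> None:
    Path(path).write_text(yaml.safe_dump(spec_to_dict(spec), sort_keys=True))


def read_spec_yaml(path) -> CohortSpec:
    return spec_from_dict(yaml.safe_load(Path(path).read_text()))


def config_hash(config: RunConfig) -> str:
    canonical = json.dumps(config.to_dict(), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


# ------------------------------------------------------------ the pipeline


def _model_feature_sets(table: FeatureTable, include_copy_number: bool) -> Dict[str, List[str]]:
    zlogs = table.features_of(CATEGORY_PROTEIN_ZLOG)
    sets = {"two_protein": zlogs}
    ca125 = [f for f in zlogs if "CA125" in f]
    if ca125:
        sets["ca125_only"] = ca125
    if include_copy_number:
        cn = table.features_of(CATEGORY_COPY_NUMBER)
        pcs = table.features_of(CATEGORY_FRAGMENTATION)
        if cn:
            sets["full_panel"] = zlogs + cn + pcs
    return sets


def _write_tsv(frame: pd.DataFrame, path: Path, index: bool = False) -> None:
    frame.to_csv(path, sep="\t", index=index, float_format="%.10g")


def run_full_analysis(config: RunConfig, out_dir) -> Dict[str, dict]:
    """Execute the whole analysis and write a report directory.

    Returns a nested summary dict (also written as ``summary.json``) keyed
    by context and model name.  Rerunning with an identical config
    reproduces every output byte for byte.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config_hash(config)
    logger.info("run start: seed=%d config_hash=%s", config.seed, chash)

    # Stage 1: obtain data.
    if config.feature_path is not None:
        table = read_feature_table(config.feature_path)
        metadata = read_metadata(config.metadata_path)
        check_alignment(table, metadata)
    else:
        spec = config.spec if config.spec is not None else paper_default_spec()
        table, meta_records = generate_cohort(spec, seed=config.seed)
        metadata = metadata_frame(meta_records)
        write_feature_table(table, out / "features.tsv")
        write_metadata(metadata, out / "metadata.tsv")
        write_spec_yaml(spec, out / "cohort_spec.yaml")
    logger.info("data: %d samples x %d features", len(table.sample_ids), len(table.feature_names))

    # Stage 2: zlog transform of protein concentrations.
    table = add_zlog_features(table, config.reference_ranges)

    meta_idx = metadata.set_index("sample_id")
    disc_ids = [s for s in table.sample_ids if meta_idx.loc[s, "cohort"] == "discovery"]
    val_ids = [s for s in table.sample_ids if meta_idx.loc[s, "cohort"] == "validation"]
    discovery, validation = table.subset_samples(disc_ids), None
    if val_ids:
        validation = table.subset_samples(val_ids)

    summary: Dict[str, dict] = {}
    threshold_rows = []
    for context in config.contexts:
        summary[context] = {}
        feature_sets = _model_feature_sets(table, config.include_copy_number)
        for name, feats in feature_sets.items():
            mc = lr_models.ModelConfig(
                context=context,
                features=tuple(feats),
                C=config.C,
                cv_folds=config.cv_folds,
                cv_repeats=config.cv_repeats,
                seed=config.seed,
            )
            variants = {"": mc}
            if name == "full_panel":
                variants["restricted_"] = mc  # same config, restricted data
            for tag, model_config in variants.items():
                label = f"{tag}{name}_{context}"
                if tag == "restricted_":
                    model, cv = lr_models.restrict_and_refit(
                        discovery, metadata, config.excluded_prefix, model_config
                    )
                else:
                    model, cv = lr_models.train_context_model(discovery, metadata, model_config)
                (out / f"model_{label}.json").write_text(model.to_json())
                _write_tsv(cv.to_frame(), out / f"cv_scores_{label}.tsv")
                cv_auc = float(roc_auc_score(cv.labels, cv.mean_scores))
                entry = {"cv_auc": cv_auc, "n_train": len(cv.labels)}

                if validation is not None:
                    vsub, vlabels = lr_models.select_context(validation, metadata, context)
                    vscores = lr_models.score_external(model, vsub.values)
                    _write_tsv(
                        pd.DataFrame(
                            {"sample_id": vsub.sample_ids, "label": vlabels.astype(int), "score": vscores.to_numpy()}
                        ),
                        out / f"validation_scores_{label}.tsv",
                    )
                    entry["validation_auc"] = float(roc_auc_score(vlabels, vscores))

                report = clinical_metrics.threshold_at_specificity(
                    cv.mean_scores, cv.labels, config.specificity_floor
                )
                report.ppv = clinical_metrics.ppv(
                    report.sensitivity, report.specificity, config.prevalence
                )
                entry.update(
                    threshold=report.threshold,
                    specificity=report.specificity,
                    sensitivity=report.sensitivity,
                    ppv=report.ppv,
                )
                row = {
                    "model": label,
                    "floor": report.floor,
                    "threshold": report.threshold,
                    "spec_k": report.spec_k,
                    "spec_n": report.spec_n,
                    "sensitivity": report.sensitivity,
                    "ppv": report.ppv,
                    "zlog": "",
                    "concentration": "",
                }
                if len([w for w in model.coefficients if w != 0]) == 1 and name == "ca125_only":
                    z, conc = clinical_metrics.threshold_to_concentration(
                        report.threshold, model, config.reference_ranges["CA125"]
                    )
                    row["zlog"], row["concentration"] = z, conc
                    entry["threshold_zlog"], entry["threshold_concentration"] = z, conc
                threshold_rows.append(row)
                summary[context][label] = entry
                logger.info("model %s: %s", label, entry)

        # Importance comparison for the confounded vs restricted full panel.
        if "full_panel" in feature_sets:
            cats = table.categories
            full = lr_models.FittedLinearModel.from_json(
                (out / f"model_full_panel_{context}.json").read_text()
            )
            restricted = lr_models.FittedLinearModel.from_json(
                (out / f"model_restricted_full_panel_{context}.json").read_text()
            )
            # One comparison per scaling mode; modes are never mixed in a file.
            for tag, mode in (("", "divide_by_sd"), ("standardized_", "multiply_by_sd")):
                tab_full = feature_importance.importance_table(full, cats, mode)
                tab_res = feature_importance.importance_table(restricted, cats, mode)
                comparison = feature_importance.compare_models(tab_full, tab_res)
                _write_tsv(tab_full, out / f"{tag}importance_full_panel_{context}.tsv", index=True)
                _write_tsv(tab_res, out / f"{tag}importance_restricted_full_panel_{context}.tsv", index=True)
                _write_tsv(comparison, out / f"{tag}importance_comparison_{context}.tsv", index=True)
                _write_tsv(
                    feature_importance.compare_categories(comparison),
                    out / f"{tag}category_importance_comparison_{context}.tsv",
                    index=True,
                )

    # Stage: audit on the discovery cohort (zlog proteins + copy number).
    audit_feats = (
        discovery.features_of(CATEGORY_PROTEIN_ZLOG)
        + discovery.features_of(CATEGORY_COPY_NUMBER)
    )
    audit_table = discovery.subset_features(audit_feats)
    unaffected_prefix = (
        metadata.loc[metadata["prefix"] != config.excluded_prefix, "prefix"].iloc[0]
        if (metadata["prefix"] != config.excluded_prefix).any()
        else None
    )
    audit_dir = out / "audit"
    audit_dir.mkdir(exist_ok=True)
    contexts = [c for c in config.contexts]
    report = batch_audit.run_audit(audit_table, metadata, prefix_filter=unaffected_prefix, contexts=contexts)
    _write_tsv(report.feature_auc, audit_dir / "feature_auc.tsv")
    _write_tsv(report.anova, audit_dir / "anova_order.tsv")
    _write_tsv(
        report.standardized[list(report.anova["feature"])],
        audit_dir / "standardized_matrix.tsv",
        index=True,
    )
    _write_tsv(report.batch_composition, audit_dir / "batch_composition.tsv")
    _write_tsv(report.flags, audit_dir / "flags.tsv")

    _write_tsv(pd.DataFrame(threshold_rows), out / "thresholds.tsv")
    run_info = {"seed": config.seed, "config_hash": chash, "config": config.to_dict()}
    (out / "run_config.yaml").write_text(yaml.safe_dump(run_info, sort_keys=True))
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    logger.info("run complete: %s", out)
    return summary
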