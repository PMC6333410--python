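"""End-to-end pipeline: records -> flux features -> encoding -> stack -> report.

The pipeline freezes everything fit-dependent on the training split:
encoder imputation medians, standardisation statistics, the PCA basis and
all learners. Test rows only ever pass through frozen transforms and the
final scoring, and a :class:`~cellfactory.preprocess.LeakageAudit` collects
the ids each stage consumed so the guarantee is verifiable per run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd
import yaml

from .ensemble import (EvaluationReport, RegressorSpec, StackedTRYRegressor,
                       default_specs, evaluate)
from .flux import MetabolicModel, flux_feature_frame
from .preprocess import (AugmentationParams, FrozenTransform, LeakageAudit,
                         split_ids)
from .schema import (DesignRecord, FeatureMatrix, StrainDesignEncoder,
                     derive_metrics, targets_frame)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "FittedPipeline", "PipelineResult", "run_pipeline",
           "load_config"]

DEFAULT_TARGETS = ("titer", "rate", "yield_1")


@dataclass
class PipelineConfig:
    """Run configuration (YAML-loadable via :func:`load_config`)."""

    targets: tuple[str, ...] = DEFAULT_TARGETS
    test_fraction: float = 0.1
    n_folds: int = 5
    n_components: int = 40
    seed: int = 0
    use_cobra: bool = True
    augmentation: AugmentationParams | None = field(
        default_factory=lambda: AugmentationParams(n=3, t=0.1))
    nn_epochs: int = 60
    default_uptake: float = 10.0
    per_product_scaling: bool = False
    # product identity enters through its numeric descriptors (formula, mw,
    # precursor, enzyme steps); name indicators would crowd the 40-component
    # budget with redundant one-hots
    product_name_indicators: bool = False
    # supervise and score on reported metrics only: values back-filled by
    # derive_metrics are provenance-flagged estimates of a related quantity
    # (e.g. average vs maximum productivity), not ground truth
    reported_targets_only: bool = True


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    aug = raw.pop("augmentation", None)
    cfg = PipelineConfig(**{k: v for k, v in raw.items()
                            if k in PipelineConfig.__dataclass_fields__})
    if aug is not None:
        cfg.augmentation = AugmentationParams(**aug)
    if "targets" in raw:
        cfg.targets = tuple(raw["targets"])
    return cfg


@dataclass
class FittedPipeline:
    """Frozen preprocessing + one stacked model per target."""

    encoder: StrainDesignEncoder
    transform: FrozenTransform
    models: dict[str, StackedTRYRegressor]
    config: PipelineConfig
    cobra_columns: tuple[str, ...] = ()
    flux_context: tuple | None = None  # (model, carbon_exchange_map)

    def predict(self, records: Sequence[DesignRecord],
                target: str) -> pd.Series:
        """Predict a production metric for new records (never reads targets)."""
        if len(records) == 0:
            return pd.Series(dtype=float)
        records = [derive_metrics(r) for r in records]
        fm = self.encoder.transform(records)
        if self.cobra_columns and self.flux_context is not None:
            model, cmap = self.flux_context
            fm = fm.with_cobra(flux_feature_frame(records, model, cmap,
                                                  self.config.default_uptake))
        Z = self.transform.transform(fm.frame)
        return pd.Series(self.models[target].predict(Z), index=fm.frame.index)


@dataclass
class PipelineResult:
    pipeline: FittedPipeline
    reports: dict[str, EvaluationReport]
    split: object
    audit: LeakageAudit
    features: FeatureMatrix

    def summary(self) -> pd.DataFrame:
        rows = []
        for target, rep in self.reports.items():
            rows.append({"target": target, "n_test": rep.n_test, "test_r2": rep.r2,
                         "test_pearson_r": rep.pearson_r,
                         "cv_r2_mean": rep.cv_r2_mean, "cv_r2_sd": rep.cv_r2_sd})
        return pd.DataFrame(rows)


def build_feature_matrix(records: Sequence[DesignRecord],
                         encoder: StrainDesignEncoder,
                         model: MetabolicModel | None,
                         carbon_exchange_map: Mapping[str, str] | None,
                         use_cobra: bool,
                         default_uptake: float) -> FeatureMatrix:
    fm = encoder.transform(records)
    if use_cobra:
        if model is None or carbon_exchange_map is None:
            raise ValueError("flux features requested but no metabolic model given")
        fm = fm.with_cobra(flux_feature_frame(records, model, carbon_exchange_map,
                                              default_uptake))
    return fm


def run_pipeline(records: Sequence[DesignRecord],
                 model: MetabolicModel | None = None,
                 carbon_exchange_map: Mapping[str, str] | None = None,
                 config: PipelineConfig | None = None,
                 specs: Sequence[RegressorSpec] | None = None) -> PipelineResult:
    """Train and evaluate stacked TRY models on a record set.

    Steps: derive missing metrics; split by record id; fit the encoder
    (imputation medians) and the standardise+PCA transform on training rows
    only; append flux features; fit one stacked regressor per target with
    fold-internal augmentation; evaluate on the untouched test rows.
    """
    cfg = config or PipelineConfig()
    audit = LeakageAudit()
    records = [derive_metrics(r) for r in records]
    split = split_ids([r.record_id for r in records], cfg.test_fraction,
                      cfg.n_folds, cfg.seed)
    by_id = {r.record_id: r for r in records}
    train_records = [by_id[i] for i in split.train_ids]
    test_records = [by_id[i] for i in split.test_ids]

    encoder = StrainDesignEncoder(include_product_name=cfg.product_name_indicators).fit(train_records)
    audit.record("encoder_fit", split.train_ids)
    fm_train = build_feature_matrix(train_records, encoder, model,
                                    carbon_exchange_map, cfg.use_cobra,
                                    cfg.default_uptake)
    fm_test = build_feature_matrix(test_records, encoder, model,
                                   carbon_exchange_map, cfg.use_cobra,
                                   cfg.default_uptake)

    transform = FrozenTransform(cfg.n_components).fit(fm_train.frame)
    audit.record("transform_fit", split.train_ids)
    Xtr = transform.transform(fm_train.frame)
    Xte = transform.transform(fm_test.frame)
    ytr = targets_frame(train_records)
    yte = targets_frame(test_records)

    if specs is None:
        specs = default_specs(cfg.seed, nn_epochs=cfg.nn_epochs)
    aug = cfg.augmentation
    if aug is not None:
        aug = AugmentationParams(n=aug.n, t=aug.t, seed=cfg.seed)
        audit.record("augmentation", split.train_ids)

    models: dict[str, StackedTRYRegressor] = {}
    reports: dict[str, EvaluationReport] = {}
    for target in cfg.targets:
        logger.info("fitting stacked model for %s", target)
        y_tr, y_te = ytr[target], yte[target]
        if cfg.reported_targets_only:
            y_tr = y_tr.where(~ytr[f"{target}_estimated"])
            y_te = y_te.where(~yte[f"{target}_estimated"])
        stack = StackedTRYRegressor(specs=specs, n_folds=cfg.n_folds,
                                    augmentation=aug, random_state=cfg.seed,
                                    audit=audit)
        stack.fit(Xtr, y_tr)
        models[target] = stack
        reports[target] = evaluate(
            stack, Xte, y_te, target=target,
            products=yte["prod_name"] if cfg.per_product_scaling else None,
            per_product_scaling=cfg.per_product_scaling)
    audit.assert_clean(split.test_ids)

    pipeline = FittedPipeline(
        encoder=encoder, transform=transform, models=models, config=cfg,
        cobra_columns=tuple(fm_train.cobra_columns),
        flux_context=(model, dict(carbon_exchange_map)) if cfg.use_cobra else None)
    full_fm = FeatureMatrix(pd.concat([fm_train.frame, fm_test.frame]),
                            dict(fm_train.roles))
    return PipelineResult(pipeline=pipeline, reports=reports, split=split,
                          audit=audit, features=full_fm)
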