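"""Cohort-level experiment orchestration.

Two evaluation scenarios over a cohort of subjects:

* **Stratified k-fold cross-validation** -- test folds partition the cohort
  with per-site proportions preserved to within one subject; within each
  fold, 20% of the non-test subjects (rounded to nearest) form the
  validation set used for early stopping and threshold selection, the rest
  train the model.  One model is trained from scratch per fold with a
  fold-specific seed derived from the master seed.
* **Cross-site train/test split** -- train on one site's cohort (keeping a
  20% validation subset) and evaluate on a disjoint cohort from another
  site.

At the reference cohort size (90 subjects, 54 + 36 across two sites,
k = 6) each fold has 15 test, 60 training and 15 validation subjects, and a
20% split of the 54-subject site keeps 11 validation cases.
"""

from __future__ import annotations

import dataclasses
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, KFold, train_test_split

from .evaluation import MetricsReport, evaluate_case
from .inference import predict_volume, select_threshold
from .network import UNetMinusSpec, build_model
from .training import TrainConfig, train
from .volumes_io import SubjectCase, zscore_normalize


@dataclasses.dataclass
class FoldPlan:
    """Train/validation/test subject ids per fold plus stratification labels."""

    k: int
    folds: List[Dict[str, List[str]]]
    sites: Dict[str, str]

    def test_ids(self) -> List[str]:
        out: List[str] = []
        for fold in self.folds:
            out.extend(fold["test"])
        return out


def validation_count(n_pool: int, val_fraction: float = 0.20) -> int:
    """Validation-set size: the fraction of the pool, rounded to nearest."""
    return int(round(n_pool * val_fraction))


def make_folds(subject_ids: Sequence[str], sites: Sequence[str], k: int = 6,
               val_fraction: float = 0.20, seed: int = 0) -> FoldPlan:
    """Build a site-stratified k-fold plan. Deterministic given ``seed``.

    Test folds are disjoint and cover the cohort; per-site proportions in
    each test fold match the cohort within one subject.  If some site has
    fewer subjects than ``k``, a warning is issued and plain (unstratified)
    folding is used best-effort.
    """
    ids = list(subject_ids)
    site_list = list(sites)
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(ids) < k:
        raise ValueError(f"cohort of {len(ids)} cannot be split into {k} folds")
    if len(ids) != len(site_list):
        raise ValueError("subject_ids and sites must align")
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate subject ids")

    X = np.zeros((len(ids), 1))
    y = np.asarray(site_list)
    counts = pd.Series(site_list).value_counts()
    if (counts < k).any():
        import warnings
        warnings.warn(f"site(s) {list(counts[counts < k].index)} have fewer than "
                      f"{k} subjects; falling back to unstratified folds", stacklevel=2)
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
        split_iter = splitter.split(X)
    else:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        split_iter = splitter.split(X, y)

    folds = []
    for fold_idx, (pool_idx, test_idx) in enumerate(split_iter):
        pool_ids = [ids[i] for i in pool_idx]
        pool_sites = [site_list[i] for i in pool_idx]
        n_val = validation_count(len(pool_ids), val_fraction)
        if n_val < 1:
            raise ValueError("validation fraction yields an empty validation set")
        try:
            train_ids, val_ids = train_test_split(
                pool_ids, test_size=n_val, stratify=pool_sites,
                random_state=seed + 1000 + fold_idx)
        except ValueError:
            train_ids, val_ids = train_test_split(
                pool_ids, test_size=n_val, random_state=seed + 1000 + fold_idx)
        folds.append({"train": sorted(train_ids), "val": sorted(val_ids),
                      "test": sorted(ids[i] for i in test_idx)})
    return FoldPlan(k=k, folds=folds, sites=dict(zip(ids, site_list)))


def _normalized(case: SubjectCase) -> SubjectCase:
    return SubjectCase(subject_id=case.subject_id,
                       flair=zscore_normalize(case.flair),
                       mp2rage=zscore_normalize(case.mp2rage),
                       gt=case.gt, site=case.site)


def _fit_and_score(train_cases, val_cases, test_cases, train_config, arch_spec,
                   fold_seed, min_size, connectivity, inference_side):
    """Train one model, pick its threshold on validation, score the test set."""
    config = dataclasses.replace(train_config, seed=fold_seed)
    model = build_model(arch_spec, init_seed=fold_seed)
    result = train(model, train_cases, val_cases, config)

    val_norm = [_normalized(c) for c in val_cases]
    probs = [predict_volume(model, c, input_side=inference_side)[1] for c in val_norm]
    gts = [c.gt for c in val_cases]
    threshold = select_threshold(probs, gts, min_size=min_size, connectivity=connectivity)

    rows = {}
    for case in test_cases:
        mask, _prob = predict_volume(model, _normalized(case), threshold=threshold,
                                     input_side=inference_side)
        row = evaluate_case(mask, case.gt, min_size=min_size, connectivity=connectivity)
        row["site"] = case.site
        row["threshold"] = threshold
        rows[case.subject_id] = row
    return MetricsReport.from_rows(rows), result, threshold


@dataclasses.dataclass
class CrossValidationResult:
    fold_reports: List[MetricsReport]
    pooled: MetricsReport
    thresholds: List[float]

    def pooled_summary(self) -> pd.DataFrame:
        return self.pooled.cohort_summary()


def run_cross_validation(cohort: Sequence[SubjectCase], fold_plan: FoldPlan,
                         train_config: TrainConfig, arch_spec: UNetMinusSpec,
                         min_size: int = 3, connectivity: int = 18,
                         inference_side: Optional[int] = None) -> CrossValidationResult:
    """Train/evaluate one model per fold; pool the per-subject test rows."""
    by_id = {c.subject_id: c for c in cohort}
    master = np.random.SeedSequence(train_config.seed)
    fold_seeds = [int(s.generate_state(1)[0] % (2 ** 31 - 1)) for s in master.spawn(fold_plan.k)]
    fold_reports, thresholds = [], []
    for fold, fold_seed in zip(fold_plan.folds, fold_seeds):
        report, _result, threshold = _fit_and_score(
            [by_id[i] for i in fold["train"]],
            [by_id[i] for i in fold["val"]],
            [by_id[i] for i in fold["test"]],
            train_config, arch_spec, fold_seed, min_size, connectivity, inference_side)
        fold_reports.append(report)
        thresholds.append(threshold)
    pooled = MetricsReport(per_subject=pd.concat([r.per_subject for r in fold_reports]))
    return CrossValidationResult(fold_reports=fold_reports, pooled=pooled,
                                 thresholds=thresholds)


def run_split_experiment(train_cohort: Sequence[SubjectCase],
                         test_cohort: Sequence[SubjectCase],
                         train_config: TrainConfig, arch_spec: UNetMinusSpec,
                         val_fraction: float = 0.20, min_size: int = 3,
                         connectivity: int = 18,
                         inference_side: Optional[int] = None) -> MetricsReport:
    """Single cross-site pass: train on one cohort, test on a disjoint one."""
    train_ids = {c.subject_id for c in train_cohort}
    overlap = train_ids & {c.subject_id for c in test_cohort}
    if overlap:
        raise ValueError(f"cohorts overlap: {sorted(overlap)}")
    n_val = validation_count(len(train_cohort), val_fraction)
    if n_val < 1 or n_val >= len(train_cohort):
        raise ValueError("validation split infeasible for this cohort size")
    ids = sorted(train_ids)
    sites = [next(c.site for c in train_cohort if c.subject_id == i) for i in ids]
    try:
        fit_ids, val_ids = train_test_split(ids, test_size=n_val, stratify=sites,
                                            random_state=train_config.seed)
    except ValueError:
        fit_ids, val_ids = train_test_split(ids, test_size=n_val,
                                            random_state=train_config.seed)
    by_id = {c.subject_id: c for c in train_cohort}
    report, _result, _threshold = _fit_and_score(
        [by_id[i] for i in sorted(fit_ids)], [by_id[i] for i in sorted(val_ids)],
        list(test_cohort), train_config, arch_spec, train_config.seed,
        min_size, connectivity, inference_side)
    return report
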