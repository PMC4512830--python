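"""Monte Carlo cross-validated random-forest ranking of pathway pairs.

The selection protocol repeatedly (default 50 bootstraps) splits samples
into stratified 60/40 train/test partitions.  Within each bootstrap every
pathway pair is scored by the 10-fold cross-validated AUC of a random
forest trained on that pair's Discriminating Score alone (a single
feature, so mtry = sqrt(1) = 1); the ten best-ranked pairs are then
re-fitted on the whole training partition and validated on the held-out
test partition.  Pairs are finally aggregated by the frequency with which
they entered a bootstrap's top ten.

In full-pipeline mode a ``feature_builder`` callback recomputes the
DEA -> PEA -> DS stages on the training samples of each bootstrap, so
feature construction never sees test data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .dea import TUMOR

logger = logging.getLogger(__name__)

#: builder(train_ids, test_ids, seed) -> (ds_train, ds_test) with aligned columns
FeatureBuilder = Callable[[list[str], list[str], int], tuple[pd.DataFrame, pd.DataFrame]]


@dataclass
class BootstrapResult:
    bootstrap_id: int
    train_samples: list[str]
    test_samples: list[str]
    train_auc: dict[str, float]
    top10: list[str]
    test_auc: dict[str, float] = field(default_factory=dict)


def mccv_split(samples, labels: pd.Series, train_frac: float = 0.6,
               seed: int = 0) -> tuple[list[str], list[str]]:
    """Stratified train/test split of sample ids, deterministic under seed."""
    if not 0.0 < train_frac < 1.0:
        raise ValueError(f"train_frac must be in (0, 1), got {train_frac}")
    samples = list(samples)
    rng = np.random.default_rng(seed)
    train, test = [], []
    for cls in sorted(set(labels.loc[samples])):
        members = [s for s in samples if labels.loc[s] == cls]
        if len(members) < 2:
            raise ValueError(f"class {cls!r} has <2 samples")
        n_train = int(round(train_frac * len(members)))
        n_train = min(max(n_train, 1), len(members) - 1)
        perm = rng.permutation(len(members))
        train.extend(members[i] for i in perm[:n_train])
        test.extend(members[i] for i in perm[n_train:])
    return sorted(train), sorted(test)


def _binary_y(labels: pd.Series, samples) -> np.ndarray:
    return (labels.loc[list(samples)] == TUMOR).to_numpy(dtype=int)


def pair_auc(feature_column, labels: pd.Series, k: int = 10, ntree: int = 500,
             seed: int = 0) -> float:
    """Mean out-of-fold AUC of a single-feature random forest.

    Stratified k-fold CV; k is reduced (with a warning) when a class has
    fewer than k samples.  A constant feature is uninformative and returns
    AUC 0.5.
    """
    x = np.asarray(feature_column, dtype=float).reshape(-1, 1)
    y = _binary_y(labels, feature_column.index) if isinstance(
        feature_column, pd.Series) else np.asarray(labels, dtype=int)
    if np.ptp(x) == 0:
        logger.warning("pair_auc: constant feature, returning 0.5")
        return 0.5
    n_min = int(np.bincount(y, minlength=2).min())
    if n_min < 2:
        raise ValueError("pair_auc: both classes need >=2 samples")
    if n_min < k:
        logger.warning("pair_auc: reducing k from %d to %d", k, n_min)
        k = n_min
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    aucs = []
    for i, (tr, te) in enumerate(skf.split(x, y)):
        clf = RandomForestClassifier(n_estimators=ntree, max_features=1,
                                     random_state=seed + i)
        clf.fit(x[tr], y[tr])
        prob = clf.predict_proba(x[te])[:, list(clf.classes_).index(1)]
        aucs.append(roc_auc_score(y[te], prob))
    return float(np.mean(aucs))


def _holdout_auc(x_train, y_train, x_test, y_test, ntree: int, seed: int) -> float:
    if np.ptp(x_train) == 0:
        return 0.5
    clf = RandomForestClassifier(n_estimators=ntree, max_features=1,
                                 random_state=seed)
    clf.fit(x_train.reshape(-1, 1), y_train)
    prob = clf.predict_proba(x_test.reshape(-1, 1))[:, list(clf.classes_).index(1)]
    return float(roc_auc_score(y_test, prob))


def run_mccv(ds_matrix: pd.DataFrame | None, labels: pd.Series,
             n_bootstraps: int = 50, train_frac: float = 0.6, k: int = 10,
             ntree: int = 500, top_n: int = 10, seed: int = 0,
             feature_builder: FeatureBuilder | None = None,
             samples: list[str] | None = None,
             ) -> tuple[list[BootstrapResult], pd.DataFrame]:
    """Run the bootstrap selection protocol and aggregate top-``top_n`` lists.

    Fixed-feature mode (``feature_builder`` None) slices a precomputed DS
    matrix (samples x pairs); full-pipeline mode calls ``feature_builder``
    per bootstrap to rebuild features from the training samples only.
    Ranking ties are broken lexicographically by pair name.

    Returns the per-bootstrap results and an aggregate table (pair,
    frequency, mean_train_auc, mean_test_auc) sorted by decreasing
    frequency.
    """
    if n_bootstraps <= 0:
        logger.warning("run_mccv: n_bootstraps=%d, nothing to do", n_bootstraps)
        return [], pd.DataFrame(
            columns=["pair", "frequency", "mean_train_auc", "mean_test_auc"])
    if samples is None:
        samples = list(ds_matrix.index) if ds_matrix is not None else list(labels.index)

    children = np.random.SeedSequence(seed).spawn(n_bootstraps)
    results: list[BootstrapResult] = []
    for b, child in enumerate(children):
        s_split, s_auc, s_val = (int(x) for x in
                                 child.generate_state(3, dtype=np.uint32) >> 1)
        train, test = mccv_split(samples, labels, train_frac, seed=s_split)
        if feature_builder is not None:
            ds_train, ds_test = feature_builder(train, test, s_split)
        else:
            ds_train, ds_test = ds_matrix.loc[train], ds_matrix.loc[test]

        train_auc = {
            pair: pair_auc(ds_train[pair], labels, k=k, ntree=ntree, seed=s_auc)
            for pair in ds_train.columns
        }
        ranked = sorted(train_auc, key=lambda p: (-train_auc[p], p))
        top = ranked[:min(top_n, len(ranked))]

        y_tr, y_te = _binary_y(labels, train), _binary_y(labels, test)
        test_auc = {
            pair: _holdout_auc(ds_train[pair].to_numpy(), y_tr,
                               ds_test[pair].to_numpy(), y_te, ntree, s_val)
            for pair in top
        }
        results.append(BootstrapResult(b, train, test, train_auc, top, test_auc))
        logger.info("bootstrap %d: best pair %s (train AUC %.3f)",
                    b, top[0] if top else "-", train_auc[top[0]] if top else np.nan)

    agg = aggregate_ranking(results)
    return results, agg


def aggregate_ranking(results: list[BootstrapResult]) -> pd.DataFrame:
    """Frequency-in-top-10 aggregation across bootstraps."""
    rows: dict[str, dict] = {}
    for res in results:
        for pair in res.top10:
            row = rows.setdefault(pair, {"frequency": 0, "train": [], "test": []})
            row["frequency"] += 1
            row["train"].append(res.train_auc[pair])
            row["test"].append(res.test_auc[pair])
    out = pd.DataFrame([
        {"pair": pair, "frequency": row["frequency"],
         "mean_train_auc": float(np.mean(row["train"])),
         "mean_test_auc": float(np.mean(row["test"]))}
        for pair, row in rows.items()
    ], columns=["pair", "frequency", "mean_train_auc", "mean_test_auc"])
    if len(out):
        out = out.sort_values(["frequency", "mean_test_auc", "pair"],
                              ascending=[False, False, True], kind="mergesort",
                              ignore_index=True)
    return out


def baseline_classifier(expr_subset: pd.DataFrame, labels: pd.Series,
                        k: int = 10, ntree: int = 500, n_bootstraps: int = 50,
                        train_frac: float = 0.6, top_n: int = 10, seed: int = 0,
                        ) -> tuple[list[BootstrapResult], pd.DataFrame]:
    """Selection baseline on raw expression features (e.g. TFs or DE miRNAs).

    Applies the same MCCV/RF protocol as the pathway-pair selection but
    with each individual feature's expression as the classifier input,
    mirroring the TF- and miRNA-expression comparators.
    """
    if expr_subset.shape[0] == 0:
        raise ValueError("baseline_classifier: empty feature subset")
    return run_mccv(expr_subset.T, labels, n_bootstraps=n_bootstraps,
                    train_frac=train_frac, k=k, ntree=ntree, top_n=top_n,
                    seed=seed)
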