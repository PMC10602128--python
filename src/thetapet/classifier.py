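"""Tau-positivity classifier: stratified splitting and a bagged stack ensemble.

The model predicts the visual tau rating from the 41 regional SUVRs.  The
architecture is a two-layer stack: the first layer is a portfolio of
gradient-boosted tree models fitted with repeated k-fold bagging (k models
per repeat, each trained on a fold-complement), the second a regularized
logistic combiner fitted on strictly out-of-fold first-layer predictions.
At scoring time the k fold-models of each repeat are averaged into one
probability column per repeat, and the combiner maps those columns to the
final probability.

Splitting is a semi-random iterative stratified scheme over the joint
(visual status × concordance group) strata: each stratum contributes a test
share within one participant of the requested fraction; singleton strata go
to the training set; remainders are assigned largest-fraction-first with
seeded tie-breaking.
"""

from __future__ import annotations

import pickle
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from lightgbm import LGBMClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import KFold

from .atlas import AtlasConfig
from .cohort import CohortTable, RegionSUVRPanel
from .errors import ConfigError, FeatureMismatchError, TrainingError

DEFAULT_K = 5
DEFAULT_REPEATS = 2

# lightgbm's sklearn wrapper emits this even for pure-ndarray fit/predict
warnings.filterwarnings(
    "ignore", message="X does not have valid feature names", category=UserWarning
)


@dataclass(frozen=True)
class SplitSpec:
    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    test_fraction: float
    seed: int
    #: participant_id -> joint stratum label
    strata: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.train_ids) & set(self.test_ids):
            raise ConfigError("train and test sets must be disjoint")


def stratified_split(
    cohort: CohortTable,
    concordance: Optional[Mapping[str, str]] = None,
    test_fraction: float = 0.20,
    seed: int = 0,
) -> SplitSpec:
    """Deterministic stratified train/test split.

    Strata are the joint (visual status, concordance label); when no
    concordance labels are given, visual status alone defines the strata.
    """
    if not 0 < test_fraction < 1:
        raise ConfigError(f"test_fraction must lie in (0, 1), got {test_fraction}")
    strata: dict[str, str] = {}
    for rec, _ in cohort.records:
        if rec.visual_rating is None:
            raise ConfigError(
                f"participant {rec.participant_id} has no visual rating; "
                "stratified splitting requires complete labels"
            )
        vis = "pos" if rec.visual_rating else "neg"
        grp = concordance.get(rec.participant_id, "na") if concordance else "na"
        strata[rec.participant_id] = f"{vis}|{grp}"

    rng = np.random.default_rng(seed)
    by_stratum: dict[str, list[str]] = {}
    for pid in cohort.participant_ids:
        by_stratum.setdefault(strata[pid], []).append(pid)

    n_total = len(cohort)
    target_total = int(round(n_total * test_fraction))
    floors: dict[str, int] = {}
    fractional: list[tuple[float, float, str]] = []
    for label in sorted(by_stratum):
        members = by_stratum[label]
        if len(members) == 1:
            floors[label] = 0  # singleton strata stay in train
            continue
        ideal = len(members) * test_fraction
        floors[label] = int(np.floor(ideal))
        fractional.append((ideal - floors[label], rng.random(), label))
    remaining = target_total - sum(floors.values())
    # largest fractional part first, seeded tie-break; never exceed ceil(ideal)
    for _, _, label in sorted(fractional, reverse=True):
        if remaining <= 0:
            break
        if floors[label] + 1 <= len(by_stratum[label]) - 1:
            floors[label] += 1
            remaining -= 1

    test_ids: list[str] = []
    train_ids: list[str] = []
    for label in sorted(by_stratum):
        members = sorted(by_stratum[label])
        perm = rng.permutation(len(members))
        chosen = {members[j] for j in perm[: floors[label]]}
        test_ids.extend(sorted(chosen))
        train_ids.extend(m for m in members if m not in chosen)
    return SplitSpec(
        train_ids=tuple(sorted(train_ids)),
        test_ids=tuple(sorted(test_ids)),
        test_fraction=test_fraction,
        seed=seed,
        strata=strata,
    )


def _make_base_learner(seed: int) -> LGBMClassifier:
    return LGBMClassifier(
        n_estimators=60,
        num_leaves=15,
        learning_rate=0.1,
        min_child_samples=10,
        # random-subspace bagging: with 41 strongly correlated regional
        # features, per-tree feature subsampling spreads split mass across
        # correlated regions instead of collapsing onto one proxy
        feature_fraction=0.5,
        deterministic=True,
        force_row_wise=True,
        n_jobs=1,
        random_state=seed,
        verbose=-1,
    )


@dataclass
class TrainedClassifier:
    """Fitted two-layer stack; scores panels in the atlas feature order."""

    base_learners: list[list]  # [repeat][fold]
    stacker: LogisticRegression
    feature_order: tuple[str, ...]
    training_prevalence: float
    fit_metadata: dict

    def predict_proba_matrix(self, X: np.ndarray) -> np.ndarray:
        """Positive-class probability for each row of an n × m SUVR matrix."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != len(self.feature_order):
            raise FeatureMismatchError(
                f"expected {len(self.feature_order)} features, got {X.shape}"
            )
        cols = [
            np.mean([mdl.predict_proba(X)[:, 1] for mdl in fold_models], axis=0)
            for fold_models in self.base_learners
        ]
        Z = np.column_stack(cols)
        return self.stacker.predict_proba(Z)[:, 1]

    def predict_fn(self):
        """The bare ``X -> probability`` callable used for attribution."""
        return self.predict_proba_matrix


def train_ensemble(
    cohort: CohortTable,
    split: SplitSpec,
    k: int = DEFAULT_K,
    repeats: int = DEFAULT_REPEATS,
    seed: int = 0,
    atlas: Optional[AtlasConfig] = None,
) -> TrainedClassifier:
    """Fit the repeated k-fold bagged stack on the training side of ``split``.

    k × repeats base learners are fitted on rotating fold-complements; the
    logistic combiner sees only out-of-fold base predictions (one averaged
    column per repeat).  Row-index bookkeeping for the out-of-fold
    discipline is kept in ``fit_metadata``.
    """
    if k < 2 or repeats < 1:
        raise ConfigError("need k >= 2 folds and repeats >= 1")
    feature_order = (
        tuple(atlas.region_names) if atlas is not None else cohort.region_names
    )
    train = cohort.subset(split.train_ids)
    X = train.suvr_matrix(feature_order)
    y = train.visual_ratings()
    if np.isnan(y).any():
        raise TrainingError("training rows with missing visual rating")
    y = y.astype(int)
    if len(np.unique(y)) < 2:
        raise TrainingError("training set contains a single class")

    n = len(y)
    oof = np.zeros((n, repeats))
    base_learners: list[list] = []
    fit_rows: list[list[np.ndarray]] = []
    oof_rows: list[list[np.ndarray]] = []
    for r in range(repeats):
        kf = KFold(n_splits=k, shuffle=True, random_state=seed + r)
        fold_models, fold_fit_rows, fold_oof_rows = [], [], []
        for j, (fit_idx, heldout_idx) in enumerate(kf.split(X)):
            mdl = _make_base_learner(seed * 1000 + r * 100 + j)
            mdl.fit(X[fit_idx], y[fit_idx])
            oof[heldout_idx, r] = mdl.predict_proba(X[heldout_idx])[:, 1]
            fold_models.append(mdl)
            fold_fit_rows.append(fit_idx)
            fold_oof_rows.append(heldout_idx)
        base_learners.append(fold_models)
        fit_rows.append(fold_fit_rows)
        oof_rows.append(fold_oof_rows)

    stacker = LogisticRegression(C=1.0, max_iter=1000, random_state=seed)
    stacker.fit(oof, y)
    metadata = {
        "seed": seed,
        "k": k,
        "repeats": repeats,
        "n_base_learners": k * repeats,
        "train_ids": tuple(train.participant_ids),
        "fit_rows": fit_rows,
        "oof_rows": oof_rows,
    }
    return TrainedClassifier(
        base_learners=base_learners,
        stacker=stacker,
        feature_order=feature_order,
        training_prevalence=float(np.mean(y)),
        fit_metadata=metadata,
    )


def _panel_vector(model: TrainedClassifier, panel: RegionSUVRPanel) -> np.ndarray:
    have = set(panel.region_values)
    want = set(model.feature_order)
    if have != want:
        raise FeatureMismatchError(
            f"panel regions differ from model features; "
            f"missing={sorted(want - have)}, unexpected={sorted(have - want)}"
        )
    return panel.values_in_order(model.feature_order)


def predict_proba(model: TrainedClassifier, panel: RegionSUVRPanel) -> float:
    """p(tau-positive) for one panel, in the model's canonical region order."""
    x = _panel_vector(model, panel)
    return float(model.predict_proba_matrix(x[None, :])[0])


def predict_status(
    model: TrainedClassifier, panel: RegionSUVRPanel, threshold: float = 0.5
) -> bool:
    """Positive iff the stacked probability strictly exceeds ``threshold``."""
    return predict_proba(model, panel) > threshold


def repeated_runs(
    cohort: CohortTable,
    concordance: Optional[Mapping[str, str]],
    n_runs: int,
    base_seed: int,
    test_fraction: float = 0.20,
    k: int = DEFAULT_K,
    repeats: int = DEFAULT_REPEATS,
    atlas: Optional[AtlasConfig] = None,
):
    """Re-split and refit ``n_runs`` times (seed = base_seed + run index).

    Returns ``[(TrainedClassifier, MetricsReport), ...]``, one per run, each
    report computed on that run's held-out test set.
    """
    from .stats import classification_metrics  # local import avoids a cycle

    if n_runs < 2:
        raise ConfigError("repeated_runs requires n_runs >= 2")
    out = []
    for i in range(n_runs):
        run_seed = base_seed + i
        split = stratified_split(cohort, concordance, test_fraction, seed=run_seed)
        model = train_ensemble(cohort, split, k=k, repeats=repeats, seed=run_seed, atlas=atlas)
        test = cohort.subset(split.test_ids)
        proba = model.predict_proba_matrix(test.suvr_matrix(model.feature_order))
        y = test.visual_ratings().astype(int)
        report = classification_metrics(y, (proba > 0.5).astype(int), proba)
        out.append((model, report))
    return out


def save_model(model: TrainedClassifier, path, config_hash: str = "") -> None:
    """Persist a fitted ensemble; predictions round-trip bit-identically."""
    with open(path, "wb") as fh:
        pickle.dump({"config_hash": config_hash, "model": model}, fh)


def load_model(path) -> tuple[TrainedClassifier, str]:
    with open(path, "rb") as fh:
        blob = pickle.load(fh)
    return blob["model"], blob.get("config_hash", "")
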