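"""Tree-ensemble models under subject-grouped repeated cross-validation.

Three variants estimate cognitive targets from the typing feature vector:

* ``independent`` — one gradient-boosted decision-tree regressor with
  gradient-based one-side sampling (GOSS, LightGBM) per target; 100
  estimators, squared-error loss, library defaults otherwise.  Missing
  features are routed natively by the trees; subjects missing a target are
  dropped from that target's training set only, so every subject with a
  valid target contributes.
* ``joint`` — one extremely-randomized-trees multi-output regressor
  (scikit-learn ExtraTreesRegressor, 100 trees, squared-error criterion)
  over all targets at once, exploiting their correlation.  The library does
  not support missing values, so features are mean-imputed with
  training-fold means and subjects with any missing target are dropped
  (complete-case on targets).
* ``single`` — the independent architecture applied to one scalar target
  (e.g. the MoCA total).

All variants are trained and tested with R repetitions of a K-fold
cross-validation (default 10 × 3) grouped by subject: each repetition
randomly permutes the subjects into K near-equal folds and no subject ever
appears on both sides of a split.  No feature scaling is performed — trees
are insensitive to it.  No hyperparameter search is performed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lightgbm import LGBMRegressor
from sklearn.ensemble import ExtraTreesRegressor

VARIANTS = ("independent", "joint", "single")

DEFAULT_REPETITIONS = 10
DEFAULT_FOLDS = 3
N_ESTIMATORS = 100


class ModelingError(ValueError):
    pass


class LeakageError(AssertionError):
    """A subject appeared in both the training and the testing fold."""


@dataclass(frozen=True)
class ModelSpec:
    """Which variant to train and on which targets."""

    variant: str = "independent"
    targets: tuple[str, ...] = ()
    n_estimators: int = N_ESTIMATORS

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ModelingError(f"unknown variant {self.variant!r}")
        if self.variant == "single" and len(self.targets) != 1:
            raise ModelingError("single variant takes exactly one target")

    @property
    def missing_policy(self) -> str:
        # trees handle NaN natively for the boosted variants; the joint
        # extra-trees variant requires mean imputation
        return "mean_impute" if self.variant == "joint" else "native"


@dataclass(frozen=True)
class FoldAssignment:
    """Subject → fold map for one repetition; folds partition the subjects
    into k groups whose sizes differ by at most one."""

    repetition: int
    k: int
    fold_of: Mapping[str, int]

    def test_subjects(self, fold: int) -> list[str]:
        return [s for s, f in self.fold_of.items() if f == fold]

    def train_subjects(self, fold: int) -> list[str]:
        return [s for s, f in self.fold_of.items() if f != fold]


def assign_folds(
    subject_ids: Sequence[str],
    repetitions: int = DEFAULT_REPETITIONS,
    k: int = DEFAULT_FOLDS,
    seed: int = 0,
) -> list[FoldAssignment]:
    """Randomized subject-grouped fold assignments, one per repetition."""
    subject_ids = list(subject_ids)
    if len(set(subject_ids)) != len(subject_ids):
        raise ModelingError("duplicate subject ids")
    if len(subject_ids) < k:
        raise ModelingError(f"need at least k={k} subjects, got {len(subject_ids)}")
    out: list[FoldAssignment] = []
    for rep in range(1, repetitions + 1):
        rng = np.random.default_rng(np.random.SeedSequence((seed, rep)))
        perm = rng.permutation(len(subject_ids))
        fold_of: dict[str, int] = {}
        for fold, chunk in enumerate(np.array_split(perm, k), start=1):
            for idx in chunk:
                fold_of[subject_ids[int(idx)]] = fold
        out.append(FoldAssignment(repetition=rep, k=k, fold_of=fold_of))
    return out


def _model_seed(base_seed: int, variant: str, target: str, rep: int, fold: int) -> int:
    key = f"{variant}|{target}|{rep}|{fold}".encode()
    return (int(base_seed) * 0x9E3779B1 + zlib.crc32(key)) % (2**31 - 1)


def make_goss_regressor(seed: int, n_estimators: int = N_ESTIMATORS) -> LGBMRegressor:
    """Gradient-boosted trees with GOSS row sampling, squared-error loss,
    library defaults otherwise (pinned here for stability)."""
    return LGBMRegressor(
        boosting_type="gbdt",
        data_sample_strategy="goss",
        objective="regression",
        n_estimators=n_estimators,
        random_state=seed,
        deterministic=True,
        force_row_wise=True,
        verbose=-1,
    )


def fit_independent(
    features: pd.DataFrame, target: pd.Series, seed: int = 0,
    n_estimators: int = N_ESTIMATORS,
) -> LGBMRegressor:
    """Fit one GOSS boosted model on the rows with a non-missing target."""
    mask = target.notna()
    if int(mask.sum()) < 10:
        raise ModelingError(
            f"need ≥ 10 training subjects with a non-missing target, got {int(mask.sum())}"
        )
    model = make_goss_regressor(seed, n_estimators)
    model.fit(features.loc[mask], target.loc[mask].to_numpy())
    return model


@dataclass
class JointModel:
    """ExtraTrees multi-output model plus its training-fold imputation means."""

    model: ExtraTreesRegressor
    impute_means: pd.Series
    target_names: tuple[str, ...]

    def predict(self, features: pd.DataFrame) -> pd.DataFrame:
        x = features.fillna(self.impute_means).to_numpy()
        pred = self.model.predict(x)
        pred = np.atleast_2d(pred)
        if pred.shape[0] != len(features):
            pred = pred.T
        return pd.DataFrame(pred, index=features.index, columns=list(self.target_names))


def fit_joint(
    features: pd.DataFrame, targets: pd.DataFrame, seed: int = 0,
    n_estimators: int = N_ESTIMATORS,
) -> JointModel:
    """Fit the multi-output extra-trees model on complete-target rows,
    mean-imputing features with training-fold means."""
    complete = targets.notna().all(axis=1)
    if int(complete.sum()) < 10:
        raise ModelingError(
            f"need ≥ 10 training subjects with complete targets, got {int(complete.sum())}"
        )
    x_train = features.loc[complete]
    impute_means = x_train.mean(axis=0, skipna=True).fillna(0.0)
    model = ExtraTreesRegressor(
        n_estimators=n_estimators,
        criterion="squared_error",
        random_state=seed,
    )
    y_train = targets.loc[complete].to_numpy()
    if y_train.shape[1] == 1:
        y_train = y_train.ravel()
    model.fit(x_train.fillna(impute_means).to_numpy(), y_train)
    return JointModel(model=model, impute_means=impute_means,
                      target_names=tuple(targets.columns))


def fit_single(
    features: pd.DataFrame, target: pd.Series, seed: int = 0,
    n_estimators: int = N_ESTIMATORS,
) -> LGBMRegressor:
    """Single-output reference model; identical architecture to
    :func:`fit_independent`."""
    return fit_independent(features, target, seed, n_estimators)


@dataclass(frozen=True)
class FoldModel:
    """A fitted per-fold model kept for attribution analysis."""

    repetition: int
    fold: int
    target: str | None  # None for the joint variant (all targets at once)
    model: object
    test_subjects: tuple[str, ...]


@dataclass
class CVResult:
    """Out-of-fold predictions (the substrate of all evaluation) plus the
    per-fold fitted models."""

    predictions: pd.DataFrame  # columns: subject_id, target, repetition, prediction
    spec: ModelSpec
    models: list[FoldModel] = field(default_factory=list)

    def aggregated(self) -> pd.DataFrame:
        """Per-subject mean of the out-of-fold predictions over repetitions;
        wide frame (subjects × targets)."""
        return self.predictions.pivot_table(
            index="subject_id", columns="target", values="prediction", aggfunc="mean"
        )


def cross_validate(
    features: pd.DataFrame,
    targets: pd.DataFrame,
    spec: ModelSpec,
    folds: Sequence[FoldAssignment],
    base_seed: int = 0,
    keep_models: bool = False,
) -> CVResult:
    """Train and test the requested variant over all fold assignments.

    ``features`` and ``targets`` are subject-indexed frames over the same
    subjects.  Every subject is predicted exactly once per repetition by a
    model trained without any of its data; a violation raises
    :class:`LeakageError` rather than silently continuing.
    """
    target_names = list(spec.targets) if spec.targets else list(targets.columns)
    missing_t = [t for t in target_names if t not in targets.columns]
    if missing_t:
        raise ModelingError(f"targets not in frame: {missing_t}")
    subjects = set(features.index)
    rows: list[tuple[str, str, int, float]] = []
    kept: list[FoldModel] = []
    for fa in folds:
        if set(fa.fold_of) - subjects:
            raise ModelingError("fold assignment covers unknown subjects")
        for fold in range(1, fa.k + 1):
            train_ids = fa.train_subjects(fold)
            test_ids = fa.test_subjects(fold)
            if set(train_ids) & set(test_ids):
                raise LeakageError(
                    f"rep {fa.repetition} fold {fold}: subject overlap between folds"
                )
            x_train = features.loc[train_ids]
            x_test = features.loc[test_ids]
            if spec.variant == "joint":
                jm = fit_joint(
                    x_train,
                    targets.loc[train_ids, target_names],
                    seed=_model_seed(base_seed, "joint", "*", fa.repetition, fold),
                    n_estimators=spec.n_estimators,
                )
                pred = jm.predict(x_test)
                for sid in test_ids:
                    for t in target_names:
                        rows.append((sid, t, fa.repetition, float(pred.at[sid, t])))
                if keep_models:
                    kept.append(FoldModel(fa.repetition, fold, None, jm, tuple(test_ids)))
            else:
                for t in target_names:
                    m = fit_independent(
                        x_train,
                        targets.loc[train_ids, t],
                        seed=_model_seed(base_seed, spec.variant, t, fa.repetition, fold),
                        n_estimators=spec.n_estimators,
                    )
                    yhat = m.predict(x_test)
                    for sid, v in zip(test_ids, yhat):
                        rows.append((sid, t, fa.repetition, float(v)))
                    if keep_models:
                        kept.append(FoldModel(fa.repetition, fold, t, m, tuple(test_ids)))
    predictions = pd.DataFrame(
        rows, columns=["subject_id", "target", "repetition", "prediction"]
    )
    dup = predictions.duplicated(["subject_id", "target", "repetition"])
    if dup.any():
        raise LeakageError("duplicate (subject, target, repetition) prediction")
    return CVResult(predictions=predictions, spec=spec, models=kept)
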