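"""Tremor-type discrimination protocol.

Stratified 3:1 split, repeated-LASSO stability selection (penalty chosen by
10-fold CV per repeat, nonzero-coefficient features counted over repeats),
five learners tuned by inner 10-fold CV, and bootstrap-resampled AUC on the
held-out test set.  Feature selection sees only the training split.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LassoCV
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import GridSearchCV, KFold, StratifiedKFold, train_test_split
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .core import SCORE_NAMES, MorphometryDataset
from .errors import ConfigurationError, EvaluationError, UsageError, ValidationError

FEATURE_SETS = ("morphology", "clinical", "combined")
LEARNERS = ("RF", "SVM-linear", "SVM-poly", "SVM-rbf", "SVM-sigmoid")
POSITIVE_LABEL = "TD"

#: small documented hyperparameter grids (cost over 4 decades; RF at a
#: fixed forest size with depth as the only knob)
SVM_GRID = {"C": [0.01, 0.1, 1.0, 10.0]}
RF_GRID = {"max_depth": [None, 4], "max_features": ["sqrt", None]}
RF_N_TREES = 500


@dataclass
class FeatureTable:
    """Subjects x features matrix with binary TD/ET labels."""

    X: pd.DataFrame
    labels: np.ndarray
    feature_set: str = "morphology"

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.X.shape[0] != self.labels.size:
            raise ValidationError("label count differs from row count")
        if not set(np.unique(self.labels)) <= {"TD", "ET"}:
            raise ValidationError("labels must be TD or ET")
        if self.X.isna().any().any():
            raise ValidationError("feature table contains missing values; impute first")

    @property
    def y(self) -> np.ndarray:
        """Labels as 0/1 with TD positive."""
        return (self.labels == POSITIVE_LABEL).astype(int)

    @property
    def feature_names(self) -> list[str]:
        return list(self.X.columns)

    def restrict(self, features: Sequence[str]) -> "FeatureTable":
        return FeatureTable(
            X=self.X[list(features)], labels=self.labels, feature_set=self.feature_set
        )


@dataclass
class SelectionProfile:
    """Per-feature selection counts from repeated LASSO."""

    counts: pd.Series
    n_repeats: int
    threshold: int
    mode: str
    selected: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"count": self.counts, "selected": self.counts.index.isin(self.selected)}
        )


@dataclass
class ModelEval:
    """Bootstrap AUC distribution for one learner."""

    model: str
    auc_samples: np.ndarray
    mean_auc: float
    ci_low: float
    ci_high: float

    def __post_init__(self):
        if np.any((self.auc_samples < 0) | (self.auc_samples > 1)):
            raise ValidationError("AUC samples outside [0, 1]")


# ---------------------------------------------------------------------------
# feature assembly
# ---------------------------------------------------------------------------

_CLINICAL_COLUMNS = ("age", "sex", "education") + SCORE_NAMES


def build_feature_table(dataset: MorphometryDataset, feature_set: str = "combined") -> FeatureTable:
    """Patient-only feature table: region mean thickness + subcortical
    volumes ("morphology"), demographics + clinical scores ("clinical"),
    or both ("combined").  Missing clinical scores are mean-imputed later,
    inside the training split."""
    if feature_set not in FEATURE_SETS:
        raise UsageError(f"unknown feature set {feature_set!r}")
    patients = dataset.subset(dataset.group_mask("TD", "ET"))
    blocks = []
    if feature_set in ("morphology", "combined"):
        blocks.append(patients.region_means())
        blocks.append(patients.volumes)
    if feature_set in ("clinical", "combined"):
        clin = pd.DataFrame(index=pd.Index(patients.subject_ids))
        clin["age"] = patients.ages
        clin["sex"] = patients.sexes
        clin["education"] = [s.education for s in patients.subjects]
        for name in SCORE_NAMES:
            clin[name] = [s.scores.get(name) for s in patients.subjects]
        blocks.append(clin)
    X = pd.concat(blocks, axis=1)
    X = X.fillna(X.mean())  # cohort-level fallback; split-level imputation below
    return FeatureTable(X=X, labels=patients.groups, feature_set=feature_set)


def impute_train_test(train: FeatureTable, test: FeatureTable) -> tuple[FeatureTable, FeatureTable]:
    """Mean-impute both splits using training means only (leakage-safe)."""
    means = train.X.mean()
    return (
        FeatureTable(train.X.fillna(means), train.labels, train.feature_set),
        FeatureTable(test.X.fillna(means), test.labels, test.feature_set),
    )


# ---------------------------------------------------------------------------
# split
# ---------------------------------------------------------------------------

def split_train_test(
    table: FeatureTable,
    test_fraction: float = 0.25,
    stratified: bool = True,
    seed: Optional[int] = None,
) -> tuple[FeatureTable, FeatureTable]:
    """Stratified 3:1 split (class proportions preserved within 1 subject)."""
    if table.X.shape[0] < 8:
        raise UsageError(f"need >= 8 subjects to split, got {table.X.shape[0]}")
    classes = np.unique(table.labels)
    if classes.size < 2:
        raise UsageError("cannot stratify a single-class table")
    idx = np.arange(table.X.shape[0])
    tr, te = train_test_split(
        idx,
        test_size=test_fraction,
        stratify=table.labels if stratified else None,
        random_state=None if seed is None else int(seed),
    )
    tr, te = np.sort(tr), np.sort(te)
    return (
        FeatureTable(table.X.iloc[tr], table.labels[tr], table.feature_set),
        FeatureTable(table.X.iloc[te], table.labels[te], table.feature_set),
    )


# ---------------------------------------------------------------------------
# LASSO stability selection
# ---------------------------------------------------------------------------

def lasso_stability_select(
    train: FeatureTable,
    n_repeats: int = 1000,
    cv_folds: int = 10,
    threshold: int = 500,
    mode: str = "count_threshold",
    seed: Optional[int] = None,
    subsample: float = 0.8,
) -> SelectionProfile:
    """Repeated-LASSO stability selection.

    Each repeat draws a stratified row subsample (fraction ``subsample``
    without replacement — resampling the data is what makes selection
    counts informative), reshuffles the CV folds, picks the penalty by
    ``cv_folds``-fold cross-validation, and records the features with
    nonzero coefficients.  Selection keeps features chosen in strictly more
    than ``threshold`` repeats, or the top 30% by count in ``top_30pct``
    mode."""
    if mode not in ("count_threshold", "top_30pct"):
        raise UsageError(f"unknown selection mode {mode!r}")
    y = train.y
    for cls in (0, 1):
        if np.count_nonzero(y == cls) < cv_folds:
            raise UsageError(
                f"need >= {cv_folds} subjects per class for {cv_folds}-fold CV"
            )
    X = train.X.copy()
    dead = [c for c in X.columns if X[c].std() == 0]
    if dead:
        warnings.warn(f"dropping constant features before LASSO: {dead}", stacklevel=2)
        X = X.drop(columns=dead)
    names = list(X.columns)
    Xs = StandardScaler().fit_transform(X.to_numpy(dtype=float))
    if not 0.1 <= subsample <= 1.0:
        raise UsageError(f"subsample fraction must be in [0.1, 1], got {subsample}")
    rng = np.random.default_rng(seed)
    counts = np.zeros(len(names), dtype=int)
    idx_by_class = [np.flatnonzero(y == c) for c in (0, 1)]
    for _ in range(n_repeats):
        take = []
        for idx in idx_by_class:
            k = max(cv_folds, int(round(subsample * idx.size)))
            take.append(rng.choice(idx, size=min(k, idx.size), replace=False))
        rows = np.sort(np.concatenate(take))
        cv = KFold(n_splits=cv_folds, shuffle=True,
                   random_state=int(rng.integers(0, 2**31 - 1)))
        model = LassoCV(cv=cv, alphas=50, max_iter=5000)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(Xs[rows], y[rows].astype(float))
        counts += model.coef_ != 0
    series = pd.Series(counts, index=names).sort_values(ascending=False)
    if mode == "count_threshold":
        selected = [f for f in names if series[f] > threshold]
    else:
        k = max(1, int(np.ceil(0.30 * len(names))))
        selected = list(series.index[:k])
    selected = [f for f in series.index if f in selected]  # count-ordered
    return SelectionProfile(
        counts=series, n_repeats=n_repeats, threshold=threshold, mode=mode,
        selected=selected,
    )


# ---------------------------------------------------------------------------
# model training and evaluation
# ---------------------------------------------------------------------------

def _make_estimator(name: str, seed: int):
    if name == "RF":
        return RandomForestClassifier(n_estimators=RF_N_TREES, random_state=seed), dict(RF_GRID)
    kernel = name.split("-", 1)[1]
    est = Pipeline([
        ("scale", StandardScaler()),
        ("clf", SVC(kernel=kernel, probability=True, random_state=seed)),
    ])
    grid = {f"clf__{k}": v for k, v in SVM_GRID.items()}
    return est, grid


def train_models(
    train: FeatureTable,
    selected_features: Sequence[str],
    learners: Sequence[str] = LEARNERS,
    inner_cv: int = 10,
    seed: Optional[int] = None,
) -> dict:
    """Tune each learner by inner stratified 10-fold CV (ROC-AUC scoring).

    Returns a bundle: fitted best estimator + tuned settings per learner,
    plus the feature list every estimator consumes.
    """
    selected_features = list(selected_features)
    if not selected_features:
        raise ConfigurationError(
            "empty feature selection; rerun with mode='top_30pct' or selection off"
        )
    unknown = [f for f in selected_features if f not in train.X.columns]
    if unknown:
        raise UsageError(f"selected features missing from table: {unknown}")
    for name in learners:
        if name not in LEARNERS:
            raise UsageError(f"unknown learner {name!r}; choose from {LEARNERS}")
    X = train.X[selected_features].to_numpy(dtype=float)
    y = train.y
    rng = np.random.default_rng(seed)
    bundle = {"features": selected_features, "models": {}, "cv_auc": {}, "params": {}}
    for name in learners:
        est_seed = int(rng.integers(0, 2**31 - 1))
        est, grid = _make_estimator(name, est_seed)
        cv = StratifiedKFold(n_splits=inner_cv, shuffle=True, random_state=est_seed)
        search = GridSearchCV(est, grid, cv=cv, scoring="roc_auc", n_jobs=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            search.fit(X, y)
        bundle["models"][name] = search.best_estimator_
        bundle["cv_auc"][name] = float(search.best_score_)
        bundle["params"][name] = dict(search.best_params_)
    return bundle


def evaluate_resampled_auc(
    bundle: dict,
    test: FeatureTable,
    n_resamples: int = 1000,
    seed: Optional[int] = None,
) -> dict[str, ModelEval]:
    """Bootstrap the test subjects ``n_resamples`` times and collect the AUC
    of each learner's predicted probabilities; single-class resamples are
    redrawn (at most 10x attempts each)."""
    if test.X.shape[0] == 0:
        raise UsageError("empty test set")
    y = test.y
    if np.unique(y).size < 2:
        raise UsageError("test set must contain both classes")
    X = test.X[bundle["features"]].to_numpy(dtype=float)
    probs = {
        name: model.predict_proba(X)[:, 1] for name, model in bundle["models"].items()
    }
    rng = np.random.default_rng(seed)
    n = y.size
    boot = np.empty((n_resamples, n), dtype=int)
    for b in range(n_resamples):
        for attempt in range(10):
            idx = rng.integers(0, n, size=n)
            if np.unique(y[idx]).size == 2:
                break
        else:
            raise EvaluationError("could not draw a two-class resample in 10 attempts")
        boot[b] = idx
    out = {}
    for name, prob in probs.items():
        aucs = np.array([roc_auc_score(y[idx], prob[idx]) for idx in boot])
        out[name] = ModelEval(
            model=name,
            auc_samples=aucs,
            mean_auc=float(aucs.mean()),
            ci_low=float(np.percentile(aucs, 2.5)),
            ci_high=float(np.percentile(aucs, 97.5)),
        )
    return out


def evaluation_table(evals: Mapping[str, ModelEval]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"model": e.model, "mean_auc": e.mean_auc,
             "ci_low": e.ci_low, "ci_high": e.ci_high}
            for e in evals.values()
        ]
    ).set_index("model")
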