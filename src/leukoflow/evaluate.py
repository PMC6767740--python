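"""Model selection and validation protocol.

Implements the evaluation scheme the workflow is built around:

* subject-wise cross-validation — one fold per blood donor, so the
  classifier never sees any cell of the held-out donor during training
  (all preprocessing included: undersampling and standardization are fit
  on training donors only);
* its deliberately flawed counterpart, row-level shuffle-and-split, kept
  for demonstrating the optimistic bias donor batch effects induce;
* repeated random undersampling (default 10 runs) with per-run winners and
  a majority vote for the overall best classifier;
* two-stage classification — four WBC main types first, then B vs T within
  lymphocytes — scored by per-fold macro F1 averaged over folds;
* feature-importance top-10 unions across undersampling runs.

The default classifier set is AdaBoost, gradient-boosted trees, k-nearest
neighbors, random forest and an RBF support-vector machine, each with
library-default hyperparameters; scale-sensitive models (KNN, SVM) are
wrapped in a per-fold standardization pipeline.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.metrics import f1_score
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import LabelEncoder, StandardScaler
from sklearn.svm import SVC

__all__ = [
    "META_COLUMNS",
    "DEFAULT_CLASSIFIERS",
    "macro_f1",
    "make_classifier",
    "random_undersample",
    "subject_wise_cv",
    "shuffle_split_cv",
    "select_best_classifier",
    "two_stage_fit_predict",
    "importance_union",
    "CVResult",
    "EvaluationReport",
    "TwoStagePredictions",
]

META_COLUMNS = ["event_id", "donor_id", "truth_stage1", "truth_stage2"]

DEFAULT_CLASSIFIERS = (
    "adaboost",
    "gradient_boosting",
    "knn",
    "random_forest",
    "svm",
)


def feature_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in META_COLUMNS]


class GradientBoostedTrees(BaseEstimator, ClassifierMixin):
    """Gradient-boosted decision trees (XGBoost backend, default settings).

    Thin adapter handling string class labels and exposing
    ``feature_importances_`` for importance unions.
    """

    def __init__(self, random_state: int = 0):
        self.random_state = random_state

    def fit(self, X, y):
        from xgboost import XGBClassifier

        self._encoder = LabelEncoder().fit(y)
        self.classes_ = self._encoder.classes_
        self._model = XGBClassifier(
            random_state=self.random_state, n_jobs=1, verbosity=0
        )
        self._model.fit(np.asarray(X), self._encoder.transform(y))
        return self

    def predict(self, X):
        return self._encoder.inverse_transform(self._model.predict(np.asarray(X)))

    @property
    def feature_importances_(self) -> np.ndarray:
        return self._model.feature_importances_


def make_classifier(spec: str, random_state: int | None = 0):
    """Instantiate a named classifier with library-default hyperparameters."""
    if spec == "adaboost":
        return AdaBoostClassifier(random_state=random_state)
    if spec == "gradient_boosting":
        return GradientBoostedTrees(random_state=random_state or 0)
    if spec == "knn":
        return Pipeline([("scale", StandardScaler()), ("knn", KNeighborsClassifier())])
    if spec == "svm":
        return Pipeline(
            [("scale", StandardScaler()), ("svm", SVC(random_state=random_state))]
        )
    if spec == "random_forest":
        return RandomForestClassifier(random_state=random_state)
    raise ValueError(f"unknown classifier spec {spec!r}")


def macro_f1(y_true, y_pred, average: str = "macro") -> float:
    """Mean per-class F1 over the classes present in the truth.

    Classes predicted but absent from the truth do not contribute; empty
    precision/recall denominators score 0 for that class.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0:
        raise ValueError("macro_f1 requires non-empty label sequences")
    if y_true.shape != y_pred.shape:
        raise ValueError("label sequences must have equal length")
    labels = np.unique(y_true)
    return float(
        f1_score(y_true, y_pred, labels=labels, average=average, zero_division=0)
    )


def random_undersample(labels, seed) -> np.ndarray:
    """Positional indices of a class-balanced subsample (minority count each).

    Sampling is without replacement within each class; the same seed always
    selects the same rows.
    """
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("random undersampling requires at least 2 classes")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_min = int(counts.min())
    keep = [
        rng.choice(np.flatnonzero(labels == cls), size=n_min, replace=False)
        for cls in classes
    ]
    return np.sort(np.concatenate(keep))


@dataclass
class FoldResult:
    donor_id: str
    f1: float
    n_test: int
    flagged: bool = False  # training set lacked a class; excluded from mean


@dataclass
class CVResult:
    classifier: str
    folds: list[FoldResult]
    mean_f1: float

    @property
    def fold_f1(self) -> list[float]:
        return [f.f1 for f in self.folds if not f.flagged]


def _check_table(table: pd.DataFrame, label_col: str) -> None:
    if table["donor_id"].nunique() < 2:
        raise ValueError("subject-wise evaluation needs at least 2 donors")
    cols = feature_columns(table)
    if table[cols].isna().any().any():
        raise ValueError("feature table contains missing values")
    if table[label_col].isna().any():
        raise ValueError(f"missing labels in {label_col!r}")


def subject_wise_cv(
    table: pd.DataFrame,
    classifier_spec: str,
    seed: int = 0,
    *,
    label_col: str = "truth_stage1",
    undersample: bool = False,
    average: str = "macro",
) -> CVResult:
    """Leave-one-donor-out cross-validation (one fold per donor).

    The model is refit per fold; undersampling (when enabled) and any
    scaler inside the classifier pipeline are fit on the training donors
    only — no information crosses the donor split. Folds whose training set
    lacks one of the table's classes are flagged and excluded from the
    mean with a warning.
    """
    _check_table(table, label_col)
    cols = feature_columns(table)
    donors = sorted(table["donor_id"].unique())
    all_classes = set(table[label_col].unique())
    rng = np.random.default_rng(seed)

    folds: list[FoldResult] = []
    for donor in donors:
        test = table["donor_id"] == donor
        train_tab = table.loc[~test]
        test_tab = table.loc[test]
        if undersample:
            idx = random_undersample(train_tab[label_col].to_numpy(), rng)
            train_tab = train_tab.iloc[idx]
        if set(train_tab[label_col].unique()) != all_classes:
            warnings.warn(
                f"fold {donor}: training set lacks a class; fold excluded",
                stacklevel=2,
            )
            folds.append(FoldResult(donor, np.nan, int(test.sum()), flagged=True))
            continue
        model = clone(
            make_classifier(classifier_spec, random_state=int(rng.integers(2**31)))
        )
        model.fit(train_tab[cols].to_numpy(), train_tab[label_col].to_numpy())
        pred = model.predict(test_tab[cols].to_numpy())
        folds.append(
            FoldResult(
                donor,
                macro_f1(test_tab[label_col].to_numpy(), pred, average=average),
                int(test.sum()),
            )
        )
    usable = [f.f1 for f in folds if not f.flagged]
    mean = float(np.mean(usable)) if usable else float("nan")
    return CVResult(classifier=classifier_spec, folds=folds, mean_f1=mean)


def shuffle_split_cv(
    table: pd.DataFrame,
    classifier_spec: str,
    test_fraction: float = 0.25,
    seed: int = 0,
    *,
    label_col: str = "truth_stage1",
    undersample: bool = False,
    average: str = "macro",
) -> float:
    """Row-level random split ignoring donor identity (the flawed protocol).

    Cells of one donor end up on both sides of the split, so donor-specific
    signal leaks into training; kept for quantifying that optimism against
    :func:`subject_wise_cv`.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must lie strictly between 0 and 1")
    _check_table(table, label_col)
    cols = feature_columns(table)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(table))
    n_test = max(1, int(round(test_fraction * len(table))))
    train_tab = table.iloc[perm[n_test:]]
    test_tab = table.iloc[perm[:n_test]]
    if undersample:
        idx = random_undersample(train_tab[label_col].to_numpy(), rng)
        train_tab = train_tab.iloc[idx]
    model = clone(
        make_classifier(classifier_spec, random_state=int(rng.integers(2**31)))
    )
    model.fit(train_tab[cols].to_numpy(), train_tab[label_col].to_numpy())
    pred = model.predict(test_tab[cols].to_numpy())
    return macro_f1(test_tab[label_col].to_numpy(), pred, average=average)


@dataclass
class EvaluationReport:
    """Outcome of repeated-undersampling classifier selection."""

    avg_f1: pd.DataFrame  # index: run, columns: classifier, values: mean fold F1
    fold_f1: pd.DataFrame  # long form: run, classifier, donor_id, f1, flagged
    per_run_winners: list[str]
    winner: str  # majority vote over runs (balanced data)
    imbalanced_avg_f1: dict[str, float] = field(default_factory=dict)
    imbalanced_winner: str | None = None
    importance_models: dict[int, object] = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        out = self.avg_f1.mean(axis=0).to_frame("mean_f1_balanced")
        out["wins"] = pd.Series(Counter(self.per_run_winners))
        out["wins"] = out["wins"].fillna(0).astype(int)
        if self.imbalanced_avg_f1:
            out["mean_f1_imbalanced"] = pd.Series(self.imbalanced_avg_f1)
        return out.sort_values("mean_f1_balanced", ascending=False)


def _vote(per_run_winners: list[str], mean_f1: pd.Series) -> str:
    counts = Counter(per_run_winners)
    top = max(counts.values())
    tied = [c for c, n in counts.items() if n == top]
    if len(tied) == 1:
        return tied[0]
    best = mean_f1.loc[tied]  # tie-break: mean F1 across runs, then name
    return sorted(best.index[best == best.max()])[0]


def select_best_classifier(
    table: pd.DataFrame,
    classifier_specs=DEFAULT_CLASSIFIERS,
    n_runs: int = 10,
    seed: int = 0,
    *,
    label_col: str = "truth_stage1",
    compare_imbalanced: bool = True,
    fit_importance_models: bool = True,
    importance_spec: str = "gradient_boosting",
    average: str = "macro",
) -> EvaluationReport:
    """Repeated-undersampling selection with majority voting.

    For each of ``n_runs`` undersampling seeds every classifier is scored
    by subject-wise CV (undersampling applied within each fold's training
    portion); the per-run winner is the classifier with the highest mean
    fold F1, and the overall winner the mode of per-run winners (ties:
    higher mean F1 across runs, then lexicographic). With
    ``compare_imbalanced``, the same CV without undersampling is also
    scored once per classifier so the balanced and imbalanced champions
    can be compared. Per run, an ``importance_spec`` model is additionally
    fit on an undersampled copy of the full table to support
    feature-importance unions.
    """
    specs = list(classifier_specs)
    if len(specs) < 2:
        raise ValueError("need at least 2 classifier specs to select among")
    root = np.random.SeedSequence(seed)
    run_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(n_runs)]

    rows = {}
    fold_rows = []
    importance_models: dict[int, object] = {}
    for run, run_seed in enumerate(run_seeds):
        for spec in specs:
            cv = subject_wise_cv(
                table,
                spec,
                seed=run_seed,
                label_col=label_col,
                undersample=True,
                average=average,
            )
            rows[(run, spec)] = cv.mean_f1
            for f in cv.folds:
                fold_rows.append(
                    {
                        "run": run,
                        "classifier": spec,
                        "donor_id": f.donor_id,
                        "f1": f.f1,
                        "flagged": f.flagged,
                    }
                )
        if fit_importance_models:
            rng = np.random.default_rng(run_seed)
            idx = random_undersample(table[label_col].to_numpy(), rng)
            sub = table.iloc[idx]
            model = clone(make_classifier(importance_spec, random_state=run_seed))
            model.fit(sub[feature_columns(table)].to_numpy(), sub[label_col].to_numpy())
            importance_models[run] = model

    avg = pd.Series(rows).unstack()
    avg.index.name = "run"
    overall_mean = avg.mean(axis=0)
    per_run_winners = []
    for run in avg.index:
        row = avg.loc[run]
        per_run_winners.append(sorted(row.index[row == row.max()])[0])
    winner = _vote(per_run_winners, overall_mean)

    imbalanced: dict[str, float] = {}
    imbalanced_winner = None
    if compare_imbalanced:
        for spec in specs:
            cv = subject_wise_cv(
                table,
                spec,
                seed=seed,
                label_col=label_col,
                undersample=False,
                average=average,
            )
            imbalanced[spec] = cv.mean_f1
        imbalanced_winner = max(sorted(imbalanced), key=lambda s: imbalanced[s])

    return EvaluationReport(
        avg_f1=avg,
        fold_f1=pd.DataFrame(fold_rows),
        per_run_winners=per_run_winners,
        winner=winner,
        imbalanced_avg_f1=imbalanced,
        imbalanced_winner=imbalanced_winner,
        importance_models=importance_models,
    )


@dataclass
class TwoStagePredictions:
    """Stage-1 predictions plus B/T calls under both gating conventions."""

    stage1: pd.Series  # per event_id: 4-class prediction
    stage2_predicted_gate: pd.Series  # B/T for cells *predicted* lymphocyte
    stage2_truth_gate: pd.Series  # B/T for cells *labeled* lymphocyte


def two_stage_fit_predict(
    train_table: pd.DataFrame,
    test_table: pd.DataFrame,
    winner_spec: str,
    seed: int = 0,
    *,
    undersample: bool = True,
) -> TwoStagePredictions:
    """Fit the two-stage classifier and predict on held-out cells.

    Stage 1 is a four-class model over the WBC main types; stage 2 is a
    binary B/T model trained only on ground-truth lymphocytes. At predict
    time stage 2 is applied both to the cells stage 1 calls lymphocytes
    (the deployment convention) and to the cells whose ground truth says
    lymphocyte (the evaluation convention, which restricts training *and*
    evaluation to labeled lymphocytes); both are reported.
    """
    cols = feature_columns(train_table)
    rng = np.random.default_rng(seed)

    s1_train = train_table
    if undersample:
        idx = random_undersample(s1_train["truth_stage1"].to_numpy(), rng)
        s1_train = s1_train.iloc[idx]
    stage1_model = clone(make_classifier(winner_spec, random_state=seed))
    stage1_model.fit(s1_train[cols].to_numpy(), s1_train["truth_stage1"].to_numpy())
    stage1_pred = pd.Series(
        stage1_model.predict(test_table[cols].to_numpy()),
        index=test_table["event_id"].to_numpy(),
        name="stage1",
    )

    lymph_train = train_table[train_table["truth_stage1"] == "lymphocyte"]
    if lymph_train.empty:
        raise ValueError("no ground-truth lymphocytes in the training table")
    if undersample and lymph_train["truth_stage2"].nunique() > 1:
        idx = random_undersample(lymph_train["truth_stage2"].to_numpy(), rng)
        lymph_train = lymph_train.iloc[idx]
    stage2_model = clone(make_classifier(winner_spec, random_state=(seed + 1) % 2**31))
    stage2_model.fit(lymph_train[cols].to_numpy(), lymph_train["truth_stage2"].to_numpy())

    def _stage2(selector: np.ndarray) -> pd.Series:
        sub = test_table.loc[selector]
        if sub.empty:
            return pd.Series(dtype=object, name="stage2")
        return pd.Series(
            stage2_model.predict(sub[cols].to_numpy()),
            index=sub["event_id"].to_numpy(),
            name="stage2",
        )

    predicted_gate = _stage2(stage1_pred.to_numpy() == "lymphocyte")
    truth_gate = _stage2((test_table["truth_stage1"] == "lymphocyte").to_numpy())
    return TwoStagePredictions(
        stage1=stage1_pred,
        stage2_predicted_gate=predicted_gate,
        stage2_truth_gate=truth_gate,
    )


def importance_union(
    fitted_models_per_run,
    feature_names: list[str],
    top_k: int = 10,
) -> pd.DataFrame:
    """Union of per-run top-``top_k`` features, sorted by frequency.

    Each model must expose ``feature_importances_`` (models without, such
    as k-nearest neighbors, are skipped with a warning). The result lists
    one row per union feature: its name, channel, the number of runs in
    which it reached the top ``top_k`` (``frequency``, descending sort
    key) and its mean rank among those runs (ascending tie-break).
    """
    models = list(
        fitted_models_per_run.values()
        if isinstance(fitted_models_per_run, dict)
        else fitted_models_per_run
    )
    ranks: dict[str, list[int]] = {}
    n_used = 0
    for model in models:
        importances = getattr(model, "feature_importances_", None)
        if importances is None:
            warnings.warn(
                f"{type(model).__name__} exposes no feature importances; skipped",
                stacklevel=2,
            )
            continue
        n_used += 1
        order = np.argsort(importances)[::-1][:top_k]
        for rank, j in enumerate(order, start=1):
            ranks.setdefault(feature_names[j], []).append(rank)
    if n_used == 0:
        raise ValueError("no model with feature importances was supplied")
    rows = [
        {
            "feature": name,
            "channel": name.split("_", 1)[0],
            "frequency": len(r),
            "mean_rank": float(np.mean(r)),
        }
        for name, r in ranks.items()
    ]
    out = pd.DataFrame(rows).sort_values(
        ["frequency", "mean_rank", "feature"], ascending=[False, True, True]
    )
    return out.reset_index(drop=True)
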