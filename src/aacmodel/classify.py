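"""Stacked ensemble diagnostic classifier with nested cross-validation.

Three base learners - elastic-net logistic regression (ENET), k-nearest
neighbors (KNN), and bagged AdaBoost decision trees (ADABAG) - are tuned on
an inner 80/20 train/validation split of each outer training fold, with the
minority class up-sampled with replacement inside training portions only.
Hyperparameter candidates are seeded uniform draws over declared ranges
(alpha in [0,1], log10 lambda in [-4,1], k in 1..25, mfinal in 10..150,
maxdepth in 1..5), crossed into a grid per learner.  Validation AUCs both
select hyperparameters and set the stacking weights,
w_a proportional to max(AUC_a - 0.5, 1e-6), so below-chance learners receive
essentially zero weight.  The stacked probability is the weighted linear
combination of base-learner probabilities; performance (rank AUC, sensitivity,
specificity, balanced accuracy = their mean) is averaged over outer folds and
over repeated runs.  Variable importance is the stack-weighted combination of
|standardized ENET coefficients| and permutation importances (KNN, ADABAG) on
the validation split, min-max scaled to 0-100.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import AdaBoostClassifier, BaggingClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.tree import DecisionTreeClassifier

ALGORITHMS = ("enet", "knn", "adabag")

#: Feature columns for the five nested predictor sets.
PREDICTOR_SETS = {
    1: ["age", "sex"],
    2: ["ec_baseline", "ec_followup", "du_baseline", "du_followup"],
    3: ["ec_baseline", "ec_followup", "du_baseline", "du_followup",
        "age", "sex"],
    4: ["ec_baseline", "ec_followup", "du_baseline", "du_followup",
        "entropy_rt_r"],
    5: ["ec_baseline", "ec_followup", "du_baseline", "du_followup",
        "entropy_rt_r", "age", "sex"],
}

#: Declared hyperparameter ranges for the seeded random starting values.
HYPER_RANGES = {
    "alpha": (0.0, 1.0),          # ENET l1 ratio
    "log_lambda": (-4.0, 1.0),    # ENET penalty strength, log10
    "k": (1, 25),                 # KNN neighbors
    "mfinal": (10, 150),          # ADABAG boosting iterations
    "maxdepth": (1, 5),           # ADABAG tree depth
}


@dataclass
class FeatureTable:
    """Assembled classifier input: numeric features X and binary labels y."""

    X: pd.DataFrame
    y: np.ndarray
    predictor_set: int
    n_excluded: int = 0

    def __post_init__(self) -> None:
        if self.X.isna().any().any():
            raise ValueError("feature table contains missing cells")
        if len(np.unique(self.y)) != 2:
            raise ValueError("labels must contain both classes")


def build_feature_table(
    features: pd.DataFrame,
    predictor_set: int = 5,
    label_col: str = "label",
) -> FeatureTable:
    """Select and encode the columns of one predictor set.

    ``features`` is a wide per-subject frame containing the label column plus
    whichever of age, sex, ec/du at baseline and follow-up, and the
    entropy-RT r each predictor set needs.  Sex is sum-coded (female = -1,
    male = +1), age is centered, rows with any missing required value are
    excluded (counted, not silently dropped).
    """
    if predictor_set not in PREDICTOR_SETS:
        raise ValueError(f"predictor_set must be in 1..5, got {predictor_set}")
    cols = PREDICTOR_SETS[predictor_set]
    missing_cols = [c for c in cols if c not in features.columns]
    if missing_cols:
        raise ValueError(f"feature frame lacks columns: {missing_cols}")
    table = features[cols + [label_col]].copy()
    if "sex" in cols and table["sex"].dtype == object:
        table["sex"] = table["sex"].map({"female": -1.0, "male": 1.0})
    keep = table.notna().all(axis=1)
    n_excluded = int((~keep).sum())
    table = table[keep]
    for c in cols:
        if features[c].isna().all():
            raise ValueError(f"column {c} is entirely missing")
    X = table[cols].astype(float).reset_index(drop=True)
    if "age" in cols:
        X["age"] = X["age"] - X["age"].mean()
    y = table[label_col].to_numpy()
    if y.dtype == object:
        classes = np.unique(y)
        if len(classes) != 2:
            raise ValueError("labels must contain exactly two classes")
        y = (y == classes[1]).astype(int)
    return FeatureTable(X=X, y=np.asarray(y, dtype=int),
                        predictor_set=predictor_set, n_excluded=n_excluded)


def _upsample(X: np.ndarray, y: np.ndarray, rng: np.random.Generator):
    """Balance classes by duplicating minority rows with replacement.

    Returns the augmented arrays plus the indices (into X) of the appended
    duplicates, for leakage auditing.
    """
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2 or counts[0] == counts[1]:
        return X, y, np.array([], dtype=int)
    minority = classes[np.argmin(counts)]
    idx_min = np.flatnonzero(y == minority)
    n_extra = counts.max() - counts.min()
    extra = rng.choice(idx_min, size=n_extra, replace=True)
    return (
        np.vstack([X, X[extra]]),
        np.concatenate([y, y[extra]]),
        extra,
    )


def _make_learner(algo: str, hp: dict, seed: int, n_bags: int):
    if algo == "enet":
        return make_pipeline(
            StandardScaler(),
            LogisticRegression(
                solver="saga",
                l1_ratio=hp["alpha"],
                C=1.0 / (10.0 ** hp["log_lambda"]),
                max_iter=2000,
                random_state=seed,
            ),
        )
    if algo == "knn":
        return make_pipeline(
            StandardScaler(), KNeighborsClassifier(n_neighbors=hp["k"])
        )
    if algo == "adabag":
        return BaggingClassifier(
            estimator=AdaBoostClassifier(
                estimator=DecisionTreeClassifier(
                    max_depth=hp["maxdepth"], random_state=seed
                ),
                n_estimators=hp["mfinal"],
                random_state=seed,
            ),
            n_estimators=n_bags,
            random_state=seed,
        )
    raise ValueError(f"unknown algorithm {algo!r}")


def _hyper_grid(algo: str, rng: np.random.Generator, n_starts: int) -> list[dict]:
    """Seeded random starting values per hyperparameter, crossed into a grid."""
    if algo == "enet":
        alphas = rng.uniform(*HYPER_RANGES["alpha"], n_starts)
        lams = rng.uniform(*HYPER_RANGES["log_lambda"], n_starts)
        return [{"alpha": float(a), "log_lambda": float(l)}
                for a in alphas for l in lams]
    if algo == "knn":
        lo, hi = HYPER_RANGES["k"]
        ks = np.unique(rng.integers(lo, hi + 1, n_starts))
        return [{"k": int(k)} for k in ks]
    if algo == "adabag":
        lo_m, hi_m = HYPER_RANGES["mfinal"]
        lo_d, hi_d = HYPER_RANGES["maxdepth"]
        mfinals = np.unique(rng.integers(lo_m, hi_m + 1, n_starts))
        depths = np.unique(rng.integers(lo_d, hi_d + 1, n_starts))
        return [{"mfinal": int(m), "maxdepth": int(d)}
                for m in mfinals for d in depths]
    raise ValueError(algo)


def _safe_auc(y_true: np.ndarray, probs: np.ndarray) -> float:
    if len(np.unique(y_true)) < 2:
        return np.nan
    return float(roc_auc_score(y_true, probs))


class StackedEnsembleClassifier(BaseEstimator, ClassifierMixin):
    """AUC-weighted linear stack of tuned ENET, KNN and ADABAG learners.

    ``fit`` performs the inner 80/20 split, per-learner hyperparameter search
    and within-training up-sampling, then refits each tuned learner on the
    full (up-sampled) training data.  ``predict_proba`` returns the weighted
    combination of base-learner probabilities.

    Parameters
    ----------
    n_hyper_starts : int
        Random starting values drawn per hyperparameter (default 7).
    val_fraction : float
        Validation share of the inner split (default 0.2).
    n_bags : int
        Bagging rounds wrapped around each AdaBoost learner.
    upsample : bool
        Up-sample the minority class inside training portions.
    random_state : int or None
        Seeds the inner split, hyperparameter draws and learners.
    """

    def __init__(
        self,
        n_hyper_starts: int = 7,
        val_fraction: float = 0.2,
        n_bags: int = 5,
        upsample: bool = True,
        random_state: int | None = None,
    ):
        self.n_hyper_starts = n_hyper_starts
        self.val_fraction = val_fraction
        self.n_bags = n_bags
        self.upsample = upsample
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("binary classification only")
        y01 = (y == self.classes_[1]).astype(int)
        rng = np.random.default_rng(self.random_state)
        seed = int(rng.integers(2**31))

        # inner split: training (80%) / validation (20%), stratified
        idx = np.arange(len(y01))
        tr_idx, val_idx = train_test_split(
            idx, test_size=self.val_fraction, stratify=y01, random_state=seed
        )
        X_tr, y_tr = X[tr_idx], y01[tr_idx]
        X_val, y_val = X[val_idx], y01[val_idx]
        if self.upsample:
            X_tr_up, y_tr_up, _ = _upsample(X_tr, y_tr, rng)
        else:
            X_tr_up, y_tr_up = X_tr, y_tr

        self.best_hyperparams_ = {}
        self.validation_auc_ = {}
        self.models_ = {}
        for algo in ALGORITHMS:
            best_auc, best_hp = -np.inf, None
            for hp in _hyper_grid(algo, rng, self.n_hyper_starts):
                model = _make_learner(algo, hp, seed, self.n_bags)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    model.fit(X_tr_up, y_tr_up)
                auc = _safe_auc(y_val, model.predict_proba(X_val)[:, 1])
                if np.isnan(auc):
                    auc = 0.5
                if auc > best_auc:
                    best_auc, best_hp = auc, hp
            self.best_hyperparams_[algo] = best_hp
            self.validation_auc_[algo] = best_auc

        # refit tuned learners on the full training data (up-sampled)
        if self.upsample:
            X_up, y_up, extra = _upsample(X, y01, rng)
        else:
            X_up, y_up, extra = X, y01, np.array([], dtype=int)
        self.upsample_indices_ = extra
        for algo in ALGORITHMS:
            model = _make_learner(
                algo, self.best_hyperparams_[algo], seed, self.n_bags
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model.fit(X_up, y_up)
            self.models_[algo] = model

        raw_w = np.array(
            [max(self.validation_auc_[a] - 0.5, 1e-6) for a in ALGORITHMS]
        )
        self.stack_weights_ = raw_w / raw_w.sum()
        self.validation_data_ = (X_val, y_val)
        return self

    def predict_proba_by_algorithm(self, X) -> dict[str, np.ndarray]:
        X = np.asarray(X, dtype=float)
        return {a: self.models_[a].predict_proba(X)[:, 1] for a in ALGORITHMS}

    def predict_proba(self, X) -> np.ndarray:
        per_algo = self.predict_proba_by_algorithm(X)
        p1 = sum(
            w * per_algo[a] for w, a in zip(self.stack_weights_, ALGORITHMS)
        )
        return np.column_stack([1 - p1, p1])

    def predict(self, X) -> np.ndarray:
        # ties at 0.5 resolve toward the positive class
        p1 = self.predict_proba(X)[:, 1]
        return self.classes_[(p1 >= 0.5).astype(int)]


def evaluate_predictions(
    probabilities, labels, threshold: float = 0.5
) -> dict[str, float]:
    """Rank AUC, sensitivity, specificity, balanced accuracy and confusion.

    Predictions at or above the threshold count as positive.  AUC is NaN if
    only one class is present.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=int)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("probabilities must be in [0, 1]")
    pred = (p >= threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    sens = tp / (tp + fn) if (tp + fn) else np.nan
    spec = tn / (tn + fp) if (tn + fp) else np.nan
    return {
        "auc": _safe_auc(y, p),
        "sensitivity": sens,
        "specificity": spec,
        "balanced_accuracy": (sens + spec) / 2,
        "tp": tp, "fn": fn, "tn": tn, "fp": fp,
    }


def _permutation_importance(
    model, X_val: np.ndarray, y_val: np.ndarray,
    rng: np.random.Generator, n_repeats: int = 5,
) -> np.ndarray:
    """Mean validation-AUC drop per permuted feature, clipped at zero."""
    base = _safe_auc(y_val, model.predict_proba(X_val)[:, 1])
    if np.isnan(base):
        return np.zeros(X_val.shape[1])
    imp = np.zeros(X_val.shape[1])
    for j in range(X_val.shape[1]):
        drops = []
        for _ in range(n_repeats):
            Xp = X_val.copy()
            Xp[:, j] = rng.permutation(Xp[:, j])
            drops.append(base - _safe_auc(y_val, model.predict_proba(Xp)[:, 1]))
        imp[j] = np.mean(drops)
    return np.clip(imp, 0.0, None)


def _fold_importance(
    clf: StackedEnsembleClassifier, rng: np.random.Generator
) -> np.ndarray:
    """Stack-weighted per-feature importance for one fitted classifier."""
    X_val, y_val = clf.validation_data_
    per_algo = {}
    lr = clf.models_["enet"].named_steps["logisticregression"]
    per_algo["enet"] = np.abs(lr.coef_.ravel())
    for algo in ("knn", "adabag"):
        per_algo[algo] = _permutation_importance(
            clf.models_[algo], X_val, y_val, rng
        )
    combined = np.zeros(X_val.shape[1])
    for w, algo in zip(clf.stack_weights_, ALGORITHMS):
        v = per_algo[algo]
        if v.max() > 0:
            v = v / v.max()
        combined += w * v
    return combined


@dataclass
class StackReport:
    """Nested-CV performance of the base learners and the stack."""

    per_algorithm: dict[str, dict[str, float]]
    stacked: dict[str, float]
    stack_weights: dict[str, float]
    confusion: dict[str, int]
    variable_importance: dict[str, float]
    fold_metrics: pd.DataFrame
    fold_indices: list[dict] = field(default_factory=list)
    n_rows: int = 0

    def to_json(self) -> str:
        payload = {
            "per_algorithm": self.per_algorithm,
            "stacked": self.stacked,
            "stack_weights": self.stack_weights,
            "confusion": self.confusion,
            "variable_importance": self.variable_importance,
            "n_rows": self.n_rows,
        }
        return json.dumps(payload, indent=2, default=float)


def stacked_classify(
    table: FeatureTable,
    seed: int = 0,
    folds: int = 5,
    repeats: int = 5,
    n_hyper_starts: int = 7,
    n_bags: int = 5,
    upsample: bool = True,
) -> StackReport:
    """Outer k-fold CV (repeated) around the stacked ensemble.

    Metrics are computed on each held-out fold for every base learner and the
    stack, then averaged across folds and repeats.  Variable importance is
    averaged the same way and min-max scaled to 0-100.
    """
    X = table.X.to_numpy(dtype=float)
    y = table.y
    feat_names = list(table.X.columns)
    if len(y) < 20 or min(np.bincount(y)) < 5:
        raise ValueError("need >= 20 rows with >= 5 per class")
    ss = np.random.SeedSequence(seed)
    rep_seeds = ss.generate_state(repeats)
    rows = []
    vi_folds = []
    weight_folds = []
    confusion = {"tp": 0, "fn": 0, "tn": 0, "fp": 0}
    fold_indices = []
    for rep, rep_seed in enumerate(rep_seeds):
        skf = StratifiedKFold(n_splits=folds, shuffle=True,
                              random_state=int(rep_seed % 2**31))
        for fold, (tr, te) in enumerate(skf.split(X, y)):
            fold_seed = int((rep_seed + fold) % 2**31)
            clf = StackedEnsembleClassifier(
                n_hyper_starts=n_hyper_starts,
                n_bags=n_bags,
                upsample=upsample,
                random_state=fold_seed,
            ).fit(X[tr], y[tr])
            per_algo = clf.predict_proba_by_algorithm(X[te])
            stacked_p = clf.predict_proba(X[te])[:, 1]
            for algo in ALGORITHMS:
                m = evaluate_predictions(per_algo[algo], y[te])
                rows.append({"repeat": rep, "fold": fold, "model": algo, **m})
            m = evaluate_predictions(stacked_p, y[te])
            rows.append({"repeat": rep, "fold": fold, "model": "stack", **m})
            for key in confusion:
                confusion[key] += m[key]
            rng = np.random.default_rng(fold_seed)
            vi_folds.append(_fold_importance(clf, rng))
            weight_folds.append(clf.stack_weights_)
            fold_indices.append(
                {
                    "repeat": rep,
                    "fold": fold,
                    "train_index": tr,
                    "test_index": te,
                    "upsampled_train_index": tr[clf.upsample_indices_]
                    if len(clf.upsample_indices_)
                    else np.array([], dtype=int),
                }
            )
    fold_df = pd.DataFrame(rows)
    metric_cols = ["auc", "sensitivity", "specificity", "balanced_accuracy"]
    means = fold_df.groupby("model")[metric_cols].mean()
    vi = np.mean(vi_folds, axis=0)
    if vi.max() > vi.min():
        vi_scaled = 100.0 * (vi - vi.min()) / (vi.max() - vi.min())
    elif vi.max() > 0:
        vi_scaled = np.full_like(vi, 100.0)
    else:
        warnings.warn("all variable importances are zero")
        vi_scaled = np.zeros_like(vi)
    mean_w = np.mean(weight_folds, axis=0)
    return StackReport(
        per_algorithm={a: means.loc[a].to_dict() for a in ALGORITHMS},
        stacked=means.loc["stack"].to_dict(),
        stack_weights={a: float(w) for a, w in zip(ALGORITHMS, mean_w)},
        confusion=confusion,
        variable_importance={
            f: float(v) for f, v in zip(feat_names, vi_scaled)
        },
        fold_metrics=fold_df,
        fold_indices=fold_indices,
        n_rows=len(y),
    )
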