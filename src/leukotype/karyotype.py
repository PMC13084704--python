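"""Five-class virtual-karyotype ensemble classifier.

Distinguishes near-haploid (23-29 chromosomes), low-hypodiploid (33-39),
high-hyperdiploid (52-67), iAMP21/chr21-amplification and non-aneuploid
("other") B-ALL from the 186 chromosome-level dosage/MAF features.  The
model is a soft-voting ensemble of a random forest, a k-nearest-neighbours
classifier and gradient-boosted trees: class probabilities are the
unweighted mean of the three base learners' probability vectors, the label
the argmax (alphabetical tie-break).

Training balances classes with SMOTE (synthetic minority points as convex
combinations of a minority point and one of its k = min(5, class size - 1)
nearest minority neighbours) and standardizes features with a per-feature
z-score; both are refit inside every cross-validation training fold so no
information from a held-out sample leaks into its own prediction.
Evaluation follows leave-one-out cross-validation with pooled accuracy,
class-frequency-weighted F1, one-vs-rest per-class sensitivity/specificity
and a Wilson 95% interval on accuracy.
"""
from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import joblib
import numpy as np
import pandas as pd
from scipy.stats import loguniform, randint
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix, f1_score
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier, NearestNeighbors
from sklearn.preprocessing import StandardScaler
from statsmodels.stats.proportion import proportion_confint
from xgboost import XGBClassifier

logger = logging.getLogger(__name__)

MODEL_FORMAT_VERSION = "leukotype-karyotype-model-1"

KARYOTYPE_CLASSES = ("high_hyperdiploid", "iamp21_chr21amp",
                     "low_hypodiploid", "near_haploid", "other")

DEFAULT_HYPERPARAMS: dict[str, dict] = {
    "rf": {"n_estimators": 200, "max_depth": None, "min_samples_leaf": 1},
    "knn": {"n_neighbors": 5, "weights": "distance"},
    "xgb": {"n_estimators": 150, "max_depth": 4, "learning_rate": 0.1,
            "subsample": 0.9},
}

#: randomized-search space (documented configuration)
SEARCH_SPACE = {
    "rf__n_estimators": randint(100, 501),
    "rf__max_depth": randint(3, 13),
    "knn__n_neighbors": (3, 5, 7, 9),
    "xgb__n_estimators": randint(100, 501),
    "xgb__max_depth": randint(3, 13),
    "xgb__learning_rate": loguniform(0.01, 0.3),
}


class ModelError(ValueError):
    """Invalid model input/artifact."""


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def _child_seed(seed: int, i: int) -> int:
    return int((int(seed) * 1_000_003 + i) % (2**31 - 1))


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------
@dataclass
class KaryotypeCall:
    """One karyotype class with its ensemble class probabilities."""

    label: str
    probabilities: dict[str, float]

    def __post_init__(self) -> None:
        total = sum(self.probabilities.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"probabilities sum to {total}, not 1")
        best = min(sorted(self.probabilities),
                   key=lambda c: (-self.probabilities[c], c))
        if self.label != best:
            raise ValueError(f"label {self.label!r} is not the argmax {best!r}")

    @classmethod
    def from_probabilities(cls, probabilities: Mapping[str, float]) -> "KaryotypeCall":
        label = min(sorted(probabilities),
                    key=lambda c: (-probabilities[c], c))
        return cls(label=label, probabilities=dict(probabilities))

    @classmethod
    def certain(cls, label: str) -> "KaryotypeCall":
        """Degenerate call with probability 1 on ``label`` (ground truth)."""
        probs = {c: 0.0 for c in KARYOTYPE_CLASSES}
        probs[label] = 1.0
        return cls(label=label, probabilities=probs)


@dataclass
class EnsembleModel:
    scaler: StandardScaler
    learners: dict
    classes: tuple[str, ...]
    manifest: tuple[str, ...]
    manifest_hash: str
    hyperparams: dict
    seed: int
    version: str = MODEL_FORMAT_VERSION


@dataclass
class EvaluationReport:
    accuracy: float
    weighted_f1: float
    per_class: pd.DataFrame  # sensitivity/specificity per class
    confusion: pd.DataFrame  # true x predicted counts
    accuracy_ci: tuple[float, float]
    n: int


# --------------------------------------------------------------------------
# SMOTE class balancing
# --------------------------------------------------------------------------
def balance_classes(features: np.ndarray, labels: Sequence[str],
                    rng) -> tuple[np.ndarray, np.ndarray]:
    """SMOTE-balance all classes up to the majority-class count.

    Synthetic minority points are convex combinations x_i + u (x_j - x_i)
    with u ~ U(0, 1), where x_j is one of x_i's k = min(5, class size - 1)
    nearest same-class neighbours.  Classes of size 1 are duplicated.
    Original rows are returned first, synthetic rows appended.
    """
    rng = _as_rng(rng)
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ModelError("class balancing requires at least 2 classes")
    target = int(counts.max())
    new_X, new_y = [X], [y]
    for cls, count in zip(classes, counts):
        need = target - int(count)
        if need == 0:
            continue
        Xc = X[y == cls]
        if len(Xc) == 1:
            new_X.append(np.repeat(Xc, need, axis=0))
        else:
            k = min(5, len(Xc) - 1)
            nn = NearestNeighbors(n_neighbors=k + 1).fit(Xc)
            _, nbr = nn.kneighbors(Xc)  # column 0 is the point itself
            i = rng.integers(0, len(Xc), size=need)
            j = nbr[i, rng.integers(1, k + 1, size=need)]
            u = rng.random(need)[:, None]
            new_X.append(Xc[i] + u * (Xc[j] - Xc[i]))
        new_y.append(np.repeat(cls, need))
    return np.concatenate(new_X), np.concatenate(new_y)


# --------------------------------------------------------------------------
# ensemble training and prediction
# --------------------------------------------------------------------------
def _build_learners(hyperparams: dict, seed: int,
                    n_samples: int | None = None) -> dict:
    hp = {k: {**DEFAULT_HYPERPARAMS[k], **hyperparams.get(k, {})}
          for k in DEFAULT_HYPERPARAMS}
    if n_samples is not None:  # tiny training sets: k cannot exceed n
        hp["knn"]["n_neighbors"] = min(hp["knn"]["n_neighbors"], n_samples)
    return {
        "rf": RandomForestClassifier(random_state=seed, n_jobs=1, **hp["rf"]),
        "knn": KNeighborsClassifier(**hp["knn"]),
        "xgb": XGBClassifier(random_state=seed, n_jobs=1, tree_method="hist",
                             verbosity=0, **hp["xgb"]),
    }


def _coerce_matrix(features) -> tuple[np.ndarray, tuple[str, ...]]:
    if isinstance(features, pd.DataFrame):
        return features.to_numpy(dtype=float), tuple(features.columns)
    X = np.asarray(features, dtype=float)
    return X, tuple(f"f{i}" for i in range(X.shape[1]))


def train_ensemble(features, labels, hyperparams: dict | None = None,
                   seed: int = 0) -> EnsembleModel:
    """SMOTE-balance, standardize and fit the three base learners."""
    X, manifest = _coerce_matrix(features)
    y = np.asarray(labels)
    if not np.isfinite(X).all():
        j = int(np.argwhere(~np.isfinite(X))[0, 1])
        raise ModelError(f"non-finite values in feature {manifest[j]!r}")
    rng = np.random.default_rng(seed)
    Xb, yb = balance_classes(X, y, rng)
    scaler = StandardScaler().fit(Xb)
    Xs = scaler.transform(Xb)
    classes = tuple(sorted(np.unique(y)))
    code = {c: i for i, c in enumerate(classes)}
    yb_enc = np.array([code[c] for c in yb])
    learners = _build_learners(hyperparams or {}, seed, n_samples=len(Xs))
    for learner in learners.values():
        learner.fit(Xs, yb_enc)
    manifest_hash = hashlib.sha256("\n".join(manifest).encode()).hexdigest()
    return EnsembleModel(scaler=scaler, learners=learners, classes=classes,
                         manifest=manifest, manifest_hash=manifest_hash,
                         hyperparams=hyperparams or {}, seed=seed)


def _check_manifest(model: EnsembleModel, features) -> np.ndarray:
    if isinstance(features, pd.Series):
        features = features.to_frame().T
    if isinstance(features, pd.DataFrame):
        if tuple(features.columns) != model.manifest:
            raise ModelError("feature manifest mismatch between model and input")
        return features.to_numpy(dtype=float)
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != len(model.manifest):
        raise ModelError("feature manifest mismatch between model and input")
    return X


def predict_proba(model: EnsembleModel, features) -> pd.DataFrame:
    """Soft-vote probabilities: unweighted mean of the base learners."""
    X = model.scaler.transform(_check_manifest(model, features))
    base = []
    for learner in model.learners.values():
        p = learner.predict_proba(X).astype(float)
        p /= p.sum(axis=1, keepdims=True)  # counter float32 rounding (XGB)
        base.append(p)
    return pd.DataFrame(np.mean(base, axis=0), columns=list(model.classes))


def predict(model: EnsembleModel, features):
    """KaryotypeCall(s) for one feature vector or a matrix of vectors."""
    single = isinstance(features, pd.Series) or (
        not isinstance(features, pd.DataFrame)
        and np.asarray(features).ndim == 1)
    probs = predict_proba(model, features)
    calls = [KaryotypeCall.from_probabilities(row.to_dict())
             for _, row in probs.iterrows()]
    return calls[0] if single else calls


def save_model(model: EnsembleModel, path: str | Path) -> None:
    joblib.dump({"format_version": MODEL_FORMAT_VERSION,
                 "manifest": model.manifest,
                 "manifest_hash": model.manifest_hash,
                 "model": model}, path)


def load_model(path: str | Path,
               expected_manifest: Sequence[str] | None = None) -> EnsembleModel:
    """Load a model artifact; refuse on version or manifest mismatch."""
    blob = joblib.load(path)
    if blob.get("format_version") != MODEL_FORMAT_VERSION:
        raise ModelError(f"unsupported model format {blob.get('format_version')!r}")
    model: EnsembleModel = blob["model"]
    stored_hash = hashlib.sha256("\n".join(model.manifest).encode()).hexdigest()
    if stored_hash != blob["manifest_hash"]:
        raise ModelError("corrupt model artifact: manifest hash mismatch")
    if (expected_manifest is not None
            and tuple(expected_manifest) != model.manifest):
        raise ModelError("model manifest does not match expected features")
    return model


# --------------------------------------------------------------------------
# evaluation
# --------------------------------------------------------------------------
def loocv_single(features, labels, i: int, hyperparams: dict | None = None,
                 seed: int = 0) -> str:
    """Predicted label for sample i from a model trained on all others.

    The held-out sample's label never enters training, balancing or
    standardization, so corrupting it cannot change this fold's prediction.
    """
    X, manifest = _coerce_matrix(features)
    y = np.asarray(labels)
    mask = np.ones(len(y), dtype=bool)
    mask[i] = False
    model = train_ensemble(pd.DataFrame(X[mask], columns=list(manifest)),
                           y[mask], hyperparams, seed=_child_seed(seed, i))
    return predict(model, pd.Series(X[i], index=list(manifest))).label


def loocv_predictions(features, labels, hyperparams: dict | None = None,
                      seed: int = 0) -> np.ndarray:
    X, _ = _coerce_matrix(features)
    return np.array([loocv_single(features, labels, i, hyperparams, seed)
                     for i in range(len(X))])


def loocv_evaluate(features, labels, hyperparams: dict | None = None,
                   seed: int = 0) -> EvaluationReport:
    """Leave-one-out evaluation with pooled held-out predictions."""
    y = np.asarray(labels)
    if len(y) < 10:
        raise ModelError("LOOCV evaluation requires at least 10 samples")
    pred = loocv_predictions(features, labels, hyperparams, seed)
    classes = sorted(np.unique(y))
    cm = pd.DataFrame(confusion_matrix(y, pred, labels=classes),
                      index=classes, columns=classes)
    correct = int((pred == y).sum())
    accuracy = correct / len(y)
    wf1 = float(f1_score(y, pred, labels=classes, average="weighted",
                         zero_division=0))
    lo, hi = proportion_confint(correct, len(y), alpha=0.05, method="wilson")
    lo, hi = min(float(lo), accuracy), max(float(hi), accuracy)  # fp guard
    return EvaluationReport(accuracy=accuracy, weighted_f1=wf1,
                            per_class=per_class_metrics(cm),
                            confusion=cm, accuracy_ci=(float(lo), float(hi)),
                            n=len(y))


def per_class_metrics(confusion) -> pd.DataFrame:
    """One-vs-rest sensitivity and specificity per class, plus macro row.

    A class absent from the truth (empty confusion row) gets NaN sensitivity
    rather than 0; macro averages skip NaN.
    """
    cm = confusion.to_numpy() if isinstance(confusion, pd.DataFrame) else np.asarray(confusion)
    classes = (list(confusion.index) if isinstance(confusion, pd.DataFrame)
               else [str(i) for i in range(cm.shape[0])])
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise ValueError("confusion matrix must be square")
    if (cm < 0).any() or not np.issubdtype(cm.dtype, np.number):
        raise ValueError("confusion matrix must be non-negative counts")
    total = cm.sum()
    rows = {}
    for k, cls in enumerate(classes):
        tp = cm[k, k]
        fn = cm[k, :].sum() - tp
        fp = cm[:, k].sum() - tp
        tn = total - tp - fn - fp
        sens = tp / (tp + fn) if (tp + fn) > 0 else np.nan
        spec = tn / (tn + fp) if (tn + fp) > 0 else np.nan
        rows[cls] = {"sensitivity": sens, "specificity": spec}
    df = pd.DataFrame(rows).T
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        df.loc["macro"] = [np.nanmean(df["sensitivity"]),
                           np.nanmean(df["specificity"])]
    return df


# --------------------------------------------------------------------------
# hyperparameter search
# --------------------------------------------------------------------------
def _sample_config(rng: np.random.Generator) -> dict:
    def draw(spec):
        if isinstance(spec, tuple):
            return spec[rng.integers(len(spec))]
        return spec.rvs(random_state=rng)

    flat = {k: draw(v) for k, v in SEARCH_SPACE.items()}
    out: dict[str, dict] = {}
    for key, value in flat.items():
        learner, param = key.split("__")
        if isinstance(value, np.generic):
            value = value.item()
        out.setdefault(learner, {})[param] = value
    return out


def tune_hyperparameters(features, labels, n_iter: int = 50,
                         seed: int = 0, n_splits: int = 5) -> dict:
    """Randomized search maximizing mean weighted F1 over stratified folds.

    Balancing and standardization are refit inside each training fold.  If
    the smallest class has fewer than ``n_splits`` members the fold count is
    lowered to that size (with a warning).
    """
    X, manifest = _coerce_matrix(features)
    y = np.asarray(labels)
    rng = np.random.default_rng(seed)
    min_class = int(np.unique(y, return_counts=True)[1].min())
    if min_class < n_splits:
        logger.warning("smallest class has %d samples; lowering folds "
                       "from %d to %d", min_class, n_splits, min_class)
        n_splits = max(2, min_class)
    best_config, best_score = None, -np.inf
    for it in range(n_iter):
        config = _sample_config(rng)
        skf = StratifiedKFold(n_splits=n_splits, shuffle=True,
                              random_state=_child_seed(seed, it))
        scores = []
        for fold, (tr, va) in enumerate(skf.split(X, y)):
            model = train_ensemble(
                pd.DataFrame(X[tr], columns=list(manifest)), y[tr], config,
                seed=_child_seed(seed, 1000 * it + fold))
            pred = [c.label for c in
                    predict(model, pd.DataFrame(X[va], columns=list(manifest)))]
            scores.append(f1_score(y[va], pred, average="weighted",
                                   zero_division=0))
        mean = float(np.mean(scores))
        if mean > best_score:
            best_config, best_score = config, mean
    logger.info("selected configuration with CV weighted F1 %.3f", best_score)
    return best_config
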