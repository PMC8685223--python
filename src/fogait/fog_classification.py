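"""Motion-phase FoG labeling, classifier training and leave-one-patient-out evaluation.

Classifier variants: ``C0`` (features of the phase itself), ``C210`` (the
phase plus its two predecessors) for detection, and ``C21`` (predecessors
only) for prediction. Models: RBF-kernel SVM on all 10 features (SVM_10),
SVM on the five most important features (SVM_5), and AdaBoost over
depth-limited decision trees. The positive class is FoG throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import AdaBoostClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .data_io import AnnotatedEpisode, FogaitError
from .feature_extraction import (
    FEATURE_NAMES,
    VARIANT_LAGS,
    build_design_matrix,
    rank_features,
)

__all__ = [
    "ClassifierSpec",
    "EvalResult",
    "FIXED_TOP5_FEATURES",
    "default_spec",
    "label_motion_phases",
    "rater_agreement",
    "train_classifier",
    "tune_hyperparameters",
    "evaluate_metrics",
    "auc_score",
    "lopo_cross_validate",
    "compare_models_ttest",
    "select_best_foot",
    "preakinesia_fraction",
]

#: Shipped per-(variant, model) hyperparameter defaults.
_SVM_DEFAULTS = {
    ("C0", "SVM_10"): {"kernel": "rbf", "C": 5.9, "gamma": 0.005},
    ("C0", "SVM_5"): {"kernel": "rbf", "C": 0.032, "gamma": 0.33},
    ("C210", "SVM_10"): {"kernel": "rbf", "C": 2.37, "gamma": 0.026},
    ("C210", "SVM_5"): {"kernel": "rbf", "C": 10.0, "gamma": 0.006},
    ("C21", "SVM_10"): {"kernel": "rbf", "C": 10.0, "gamma": 0.006},
    ("C21", "SVM_5"): {"kernel": "rbf", "C": 10.0, "gamma": 0.081},
}
_ADABOOST_DEFAULTS = {
    ("C0", "AdaBoost"): {"criterion": "entropy", "max_depth": 3,
                         "n_estimators": 20, "learning_rate": 0.318},
    ("C210", "AdaBoost"): {"criterion": "gini", "max_depth": 2,
                           "n_estimators": 20, "learning_rate": 0.447},
    ("C21", "AdaBoost"): {"criterion": "entropy", "max_depth": 5,
                          "n_estimators": 20, "learning_rate": 0.01},
}

#: Fixed top-5 subset (global chi-square ranking) selectable instead of the
#: leakage-free per-fold ranking.
FIXED_TOP5_FEATURES = (
    "max_velocity",
    "step_duration",
    "stride_length",
    "max_pitch",
    "min_pitch",
)

MODELS = ("SVM_10", "SVM_5", "AdaBoost")


@dataclass(frozen=True)
class ClassifierSpec:
    """Variant + model + hyperparameters of one classifier configuration."""

    variant: str = "C0"
    model: str = "SVM_10"
    hyperparams: dict = field(default_factory=dict)
    feature_subset: tuple | None = None  # fixed subset for SVM_5; None = per-fold ranking

    def __post_init__(self) -> None:
        if self.variant not in VARIANT_LAGS:
            raise FogaitError(f"unknown variant {self.variant!r}")
        if self.model not in MODELS:
            raise FogaitError(f"unknown model {self.model!r}")
        hp = self.hyperparams
        if "C" in hp and hp["C"] <= 0:
            raise FogaitError("C must be positive")
        if "gamma" in hp and hp["gamma"] <= 0:
            raise FogaitError("gamma must be positive")
        if "n_estimators" in hp and hp["n_estimators"] < 1:
            raise FogaitError("n_estimators must be >= 1")

    def with_hyperparams(self, **hp) -> "ClassifierSpec":
        merged = dict(self.hyperparams)
        merged.update(hp)
        return replace(self, hyperparams=merged)


def default_spec(variant: str, model: str) -> ClassifierSpec:
    """The shipped hyperparameter defaults for a (variant, model) pair."""
    if model == "AdaBoost":
        hp = _ADABOOST_DEFAULTS[(variant, model)]
    else:
        hp = _SVM_DEFAULTS[(variant, model)]
    return ClassifierSpec(variant=variant, model=model, hyperparams=dict(hp))


# ---------------------------------------------------------------------------
# Labels
# ---------------------------------------------------------------------------

def label_motion_phases(phases, episodes, combination: str = "OR") -> np.ndarray:
    """Binary FoG labels for motion phases from expert episode annotations.

    A phase is FoG when its end time lies inside an episode (half-open
    ``[start, end)``) of any rater (``OR``) or of every rater (``AND``).
    ``phases`` may be MotionPhase objects or plain end times.
    """
    if combination not in ("OR", "AND"):
        raise FogaitError("combination must be 'OR' or 'AND'")
    end_times = [getattr(p, "t_end", p) for p in phases]
    raters = sorted({e.rater for e in episodes})
    if not raters:
        return np.zeros(len(end_times), dtype=int)
    per_rater = []
    for rater in raters:
        eps = [e for e in episodes if e.rater == rater]
        per_rater.append(
            np.array([any(e.contains(t) for e in eps) for t in end_times], dtype=bool)
        )
    stacked = np.vstack(per_rater)
    combined = stacked.any(axis=0) if combination == "OR" else stacked.all(axis=0)
    return combined.astype(int)


def rater_agreement(labels_e1: np.ndarray, labels_e2: np.ndarray) -> float:
    """|AND-FoG| / |OR-FoG| over the same phase set; 1.0 when the OR set is empty."""
    a = np.asarray(labels_e1, dtype=bool)
    b = np.asarray(labels_e2, dtype=bool)
    if a.shape != b.shape:
        raise FogaitError("label vectors must have equal length")
    n_or = int(np.sum(a | b))
    if n_or == 0:
        return 1.0
    return float(np.sum(a & b)) / n_or


# ---------------------------------------------------------------------------
# Models
# ---------------------------------------------------------------------------

def _build_estimator(spec: ClassifierSpec, seed: int | None):
    hp = {**(_ADABOOST_DEFAULTS if spec.model == "AdaBoost" else _SVM_DEFAULTS).get(
        (spec.variant, spec.model), {}), **spec.hyperparams}
    if spec.model == "AdaBoost":
        base = DecisionTreeClassifier(
            criterion=hp.get("criterion", "gini"),
            max_depth=hp.get("max_depth", 3),
            random_state=seed,
        )
        clf = AdaBoostClassifier(
            estimator=base,
            n_estimators=hp.get("n_estimators", 20),
            learning_rate=hp.get("learning_rate", 1.0),
            random_state=seed,
        )
    else:
        clf = SVC(kernel=hp.get("kernel", "rbf"), C=hp.get("C", 1.0),
                  gamma=hp.get("gamma", "scale"), random_state=seed)
    return Pipeline([("scale", StandardScaler()), ("clf", clf)])


def train_classifier(X: np.ndarray, y: np.ndarray, spec: ClassifierSpec,
                     seed: int | None = 0):
    """Fit the configured model; features are z-scored inside the pipeline.

    The returned pipeline exposes ``decision_function`` as a continuous
    score with the natural operating point at 0.
    """
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise FogaitError("training labels contain a single class")
    model = _build_estimator(spec, seed)
    model.fit(np.asarray(X, dtype=float), y)
    return model


def tune_hyperparameters(X, y, spec: ClassifierSpec, budget: int = 25,
                         seed: int = 0) -> dict:
    """Budgeted random search over a log-uniform grid, scored by inner-CV AUC.

    Deterministic for a fixed seed. Shipped defaults remain the recommended
    configuration; tuning is optional.
    """
    from sklearn.model_selection import StratifiedKFold

    if budget < 1:
        raise FogaitError("budget must be >= 1")
    rng = np.random.default_rng(seed)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    splitter = StratifiedKFold(n_splits=3, shuffle=True, random_state=seed)
    best_score, best_hp = -np.inf, None
    for _ in range(budget):
        if spec.model == "AdaBoost":
            hp = {
                "criterion": str(rng.choice(["gini", "entropy"])),
                "max_depth": int(rng.integers(1, 6)),
                "n_estimators": int(rng.choice([10, 20, 50])),
                "learning_rate": float(10 ** rng.uniform(-2, 0)),
            }
        else:
            hp = {
                "kernel": "rbf",
                "C": float(10 ** rng.uniform(-2, 2)),
                "gamma": float(10 ** rng.uniform(-3, 1)),
            }
        scores = []
        for train_idx, test_idx in splitter.split(X, y):
            if len(np.unique(y[train_idx])) < 2 or len(np.unique(y[test_idx])) < 2:
                continue
            model = train_classifier(X[train_idx], y[train_idx],
                                     spec.with_hyperparams(**hp), seed)
            scores.append(auc_score(model.decision_function(X[test_idx]), y[test_idx]))
        score = float(np.mean(scores)) if scores else -np.inf
        if score > best_score:
            best_score, best_hp = score, hp
    return best_hp


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def auc_score(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the Mann-Whitney statistic (ties count one half) via ranking."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    ranks = stats.rankdata(scores)
    rank_sum_pos = float(np.sum(ranks[labels == 1]))
    return (rank_sum_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def evaluate_metrics(scores: np.ndarray, labels: np.ndarray,
                     threshold: float = 0.0) -> dict:
    """Sensitivity, specificity, accuracy at the natural threshold, plus AUC."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pred = (scores > threshold).astype(int)
    tp = int(np.sum((pred == 1) & (labels == 1)))
    tn = int(np.sum((pred == 0) & (labels == 0)))
    fp = int(np.sum((pred == 1) & (labels == 0)))
    fn = int(np.sum((pred == 0) & (labels == 1)))
    sens = tp / (tp + fn) if (tp + fn) else float("nan")
    spec = tn / (tn + fp) if (tn + fp) else float("nan")
    acc = (tp + tn) / labels.size if labels.size else float("nan")
    return {
        "sensitivity": sens,
        "specificity": spec,
        "accuracy": acc,
        "auc": auc_score(scores, labels),
        "n_fog": tp + fn,
        "n_normal": tn + fp,
    }


# ---------------------------------------------------------------------------
# Leave-one-patient-out cross-validation
# ---------------------------------------------------------------------------

@dataclass
class EvalResult:
    """Per-(subject, foot) metrics of one classifier configuration."""

    spec: ClassifierSpec
    frame: pd.DataFrame  # columns: subject_id, foot, sensitivity, ..., auc, n_fog, n_normal
    skipped: list = field(default_factory=list)

    def mean(self, metric: str = "auc") -> float:
        return float(self.frame[metric].mean())

    def std(self, metric: str = "auc") -> float:
        return float(self.frame[metric].std(ddof=1))

    def per_subject(self, metric: str = "auc") -> pd.Series:
        """Metric averaged over feet, indexed by subject (for paired tests)."""
        return self.frame.groupby("subject_id")[metric].mean()

    def to_dict(self) -> dict:
        return {
            "variant": self.spec.variant,
            "model": self.spec.model,
            "mean": {m: self.mean(m) for m in ("sensitivity", "specificity", "accuracy", "auc")},
            "std": {m: self.std(m) for m in ("sensitivity", "specificity", "accuracy", "auc")},
            "per_foot": self.frame.to_dict(orient="records"),
            "skipped": list(self.skipped),
        }


def _select_columns(spec: ClassifierSpec, train_frame: pd.DataFrame,
                    y_train: np.ndarray) -> list[int] | None:
    """Column indices for SVM_5: top-5 base features at every lag of the variant."""
    if spec.model != "SVM_5":
        return None
    if spec.feature_subset is not None:
        top5 = list(spec.feature_subset)
    else:
        ranking = rank_features(train_frame, y_train)
        top5 = ranking["feature"].head(5).tolist()
    lags = VARIANT_LAGS[spec.variant]
    base_idx = [FEATURE_NAMES.index(name) for name in top5]
    n = len(FEATURE_NAMES)
    return [j * n + i for j in range(len(lags)) for i in sorted(base_idx)]


def lopo_cross_validate(frame: pd.DataFrame, spec: ClassifierSpec,
                        seed: int = 0) -> EvalResult:
    """Leave-one-patient-out evaluation of one classifier configuration.

    ``frame`` holds one row per motion phase with the base feature columns,
    ``subject_id``, ``foot``, ``label`` and ``t_end``. For each held-out
    subject the model trains on all other subjects (both feet) and is
    evaluated on each foot of the held-out subject separately. Feature
    standardization and SVM_5 subset selection are fitted per fold on
    training data only.
    """
    subjects = sorted(frame["subject_id"].unique())
    if len(subjects) < 2:
        raise FogaitError("leave-one-patient-out requires at least 2 subjects")
    X_all, y_all, meta = build_design_matrix(frame, spec.variant)
    results, skipped = [], []
    for subject in subjects:
        train_mask = (meta["subject_id"] != subject).to_numpy()
        y_train = y_all[train_mask]
        if len(np.unique(y_train)) < 2:
            skipped.append(subject)
            warnings.warn(f"fold {subject}: single-class training data; skipped")
            continue
        cols = _select_columns(spec, frame[frame["subject_id"] != subject], None
                               if spec.feature_subset is not None else
                               frame.loc[frame["subject_id"] != subject, "label"].to_numpy())
        X_train = X_all[train_mask]
        if cols is not None:
            X_train = X_train[:, cols]
        model = train_classifier(X_train, y_train, spec, seed)
        for foot in sorted(meta.loc[~train_mask, "foot"].unique()):
            test_mask = ((meta["subject_id"] == subject) & (meta["foot"] == foot)).to_numpy()
            if not np.any(test_mask):
                continue
            X_test = X_all[test_mask]
            if cols is not None:
                X_test = X_test[:, cols]
            metrics = evaluate_metrics(model.decision_function(X_test), y_all[test_mask])
            results.append({"subject_id": subject, "foot": foot, **metrics})
    return EvalResult(spec=spec, frame=pd.DataFrame(results), skipped=skipped)


def compare_models_ttest(aucs_a, aucs_b) -> float:
    """Two-sided paired t-test on per-subject AUC vectors.

    Identical vectors give p = 1; a constant non-zero difference (zero
    variance) degenerates to p = 0 with a warning.
    """
    a = np.asarray(aucs_a, dtype=float)
    b = np.asarray(aucs_b, dtype=float)
    if a.shape != b.shape:
        raise FogaitError("AUC vectors must have equal length")
    diff = a - b
    if np.allclose(diff, 0.0):
        return 1.0
    if np.isclose(np.std(diff), 0.0):
        warnings.warn("zero-variance non-zero difference; p-value degenerates to 0")
        return 0.0
    return float(stats.ttest_rel(a, b).pvalue)


def select_best_foot(result: EvalResult) -> dict:
    """Per subject, the foot with the higher AUC; ties resolve to left."""
    best = {}
    for subject, group in result.frame.groupby("subject_id"):
        group = group.set_index("foot")["auc"].dropna()
        if group.empty:
            group = result.frame[result.frame["subject_id"] == subject].set_index("foot")["auc"]
        if "left" in group.index and "right" in group.index:
            best[subject] = "left" if group["left"] >= group["right"] else "right"
        else:
            best[subject] = group.index[0]
    return best


def preakinesia_fraction(
    labels: np.ndarray,
    phases,
    episodes: list[AnnotatedEpisode],
    horizon_s: float = 3.0,
) -> float | None:
    """Fraction of motion phases shortly before akinesia labeled FoG of another subtype.

    A phase qualifies when its end time falls in ``[start - horizon_s, start)``
    of any akinesia episode; it counts when its end time also lies inside a
    non-akinesia episode of any rater. Returns None when the annotations
    contain no akinesia or no phase qualifies.
    """
    akinesia = [e for e in episodes if e.subtype == "akinesia"]
    if not akinesia:
        return None
    others = [e for e in episodes if e.subtype != "akinesia"]
    end_times = np.array([getattr(p, "t_end", p) for p in phases], dtype=float)
    qualifying = np.zeros(end_times.size, dtype=bool)
    for e in akinesia:
        qualifying |= (end_times >= e.start - horizon_s) & (end_times < e.start)
    if not np.any(qualifying):
        return None
    labeled = np.array(
        [any(e.contains(t) for e in others) for t in end_times], dtype=bool
    )
    labels = np.asarray(labels, dtype=bool)
    hits = labeled[qualifying] & labels[qualifying]
    return float(np.sum(hits)) / float(np.sum(qualifying))
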