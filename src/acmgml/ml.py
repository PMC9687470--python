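"""Two-tier serial classification of BRCA1/2 variants from evidence vectors.

The three interpretation classes (P/LP, VUS, B/LB) are learned as a cascade
of two binary classifiers over the 17-bit ACMG-AMP evidence vector: tier 1
separates VUS from everything else, tier 2 separates P/LP from B/LB among
the non-VUS variants.  Eight standard algorithms are compared per tier with
repeated stratified cross-validation; a flat three-class baseline uses the
same protocol.

Each tier is split, trained and tested on its own dataset (tier 1 on all
variants, tier 2 on the P/LP and B/LB subset); the cascade
(:func:`predict_serial`) is how new variants are classified, not how the
per-tier test metrics are produced.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from decimal import Decimal, ROUND_HALF_UP
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata, spearmanr
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.naive_bayes import BernoulliNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .io_annotation import CRITERIA_ORDER, CLASS_LABELS, LabeledDataset
from .shapley import shapley_values

log = logging.getLogger(__name__)

N_FEATURES = len(CRITERIA_ORDER)

TIER1_POSITIVE = "VUS"
TIER1_NEGATIVE = "other"
TIER2_POSITIVE = "P/LP"
TIER2_NEGATIVE = "B/LB"

ALGORITHMS = ("LR", "LDA", "KNN", "CART", "BernoulliNB", "SVM", "RF", "MLP")


@dataclass(frozen=True)
class MLConfig:
    train_fraction: float = 0.8
    cv_folds: int = 3
    cv_repeats: int = 20
    split_stratified: bool = True
    seed: int = 0
    collinearity_threshold: float = 0.85
    shap_drop_threshold: float = 0.01

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0,1)")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


@dataclass(frozen=True)
class ModelSpec:
    """Algorithm identity plus every hyperparameter that will be fitted.

    Unspecified settings are frozen to explicit values (recorded verbatim
    in run reports) so results cannot drift silently with library defaults.
    """

    algorithm: str
    hyperparameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")

    def build(self, seed: int = 0):
        hp = dict(self.hyperparameters)
        if self.algorithm == "LR":
            return LogisticRegression(**hp)
        if self.algorithm == "LDA":
            return LinearDiscriminantAnalysis(**hp)
        if self.algorithm == "KNN":
            return KNeighborsClassifier(**hp)
        if self.algorithm == "CART":
            return DecisionTreeClassifier(random_state=seed, **hp)
        if self.algorithm == "BernoulliNB":
            return BernoulliNB(**hp)
        if self.algorithm == "SVM":
            return SVC(random_state=seed, **hp)
        if self.algorithm == "RF":
            return RandomForestClassifier(random_state=seed, **hp)
        if self.algorithm == "MLP":
            return MLPClassifier(random_state=seed, **hp)
        raise AssertionError(self.algorithm)


def default_specs(n_features: int = N_FEATURES) -> dict[str, ModelSpec]:
    """The eight compared algorithms with their tuned hyperparameters.

    Tuned values: LR newton-cg solver; BernoulliNB without fitted class
    priors; linear-kernel SVM; RF with 200 trees considering 11 features
    per split; MLP with one 11-unit hidden layer, LBFGS, 400 iterations.
    Everything else is pinned to an explicit value.
    """
    max_features = min(11, n_features)
    return {
        "LR": ModelSpec("LR", {"solver": "newton-cg", "C": 1.0, "max_iter": 100}),
        "LDA": ModelSpec("LDA", {"solver": "svd"}),
        "KNN": ModelSpec("KNN", {"n_neighbors": 5, "weights": "uniform"}),
        "CART": ModelSpec("CART", {"criterion": "gini"}),
        "BernoulliNB": ModelSpec("BernoulliNB", {"alpha": 1.0, "fit_prior": False}),
        "SVM": ModelSpec("SVM", {"kernel": "linear", "C": 1.0}),
        "RF": ModelSpec("RF", {"n_estimators": 200, "max_features": max_features,
                               "criterion": "gini"}),
        "MLP": ModelSpec("MLP", {"hidden_layer_sizes": (11,), "solver": "lbfgs",
                                 "max_iter": 400}),
    }


# ---------------------------------------------------------------------------
# labels and splits

def relabel_for_tier(labels: Sequence[str], tier: int) -> np.ndarray:
    """Map three-class labels onto a tier's binary problem.

    Tier 1 keeps VUS as the positive class and pools P/LP with B/LB as
    "other"; tier 2 expects only P/LP and B/LB rows (positive = P/LP).
    """
    labels = np.asarray(labels, dtype=object)
    bad = set(labels) - set(CLASS_LABELS)
    if bad:
        raise ValueError(f"unknown label(s) {sorted(bad)}")
    if tier == 1:
        return np.where(labels == "VUS", TIER1_POSITIVE, TIER1_NEGATIVE)
    if tier == 2:
        if (labels == "VUS").any():
            raise ValueError("tier 2 received VUS rows")
        return labels.copy()
    raise ValueError(f"tier must be 1 or 2, got {tier}")


def split_train_test(X: np.ndarray, y: Sequence[str],
                     cfg: MLConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Stratified 80/20 split; deterministic given the config seed.

    The test partition takes ceil((1 - train_fraction) * n) rows, which
    reproduces test supports of 100 for n=497 and 74 for n=367.
    """
    y = np.asarray(y, dtype=object)
    if len(y) == 0:
        raise ValueError("empty dataset")
    _, counts = np.unique(y, return_counts=True)
    if cfg.split_stratified and counts.min() < 2:
        raise ValueError("a class has fewer than 2 members; cannot stratify")
    return train_test_split(
        np.asarray(X), y, test_size=1.0 - cfg.train_fraction,
        stratify=y if cfg.split_stratified else None,
        random_state=cfg.seed, shuffle=True)


def cross_validate(spec: ModelSpec, X: np.ndarray, y: Sequence[str],
                   cfg: MLConfig) -> dict:
    """Repeated stratified k-fold CV accuracy (mean +/- sd over all folds).

    Default protocol: 3 folds re-shuffled independently 20 times.
    """
    X = np.asarray(X)
    y = np.asarray(y, dtype=object)
    scores: list[float] = []
    for rep in range(cfg.cv_repeats):
        skf = StratifiedKFold(n_splits=cfg.cv_folds, shuffle=True,
                              random_state=cfg.seed + rep)
        for k, (tr, te) in enumerate(skf.split(X, y)):
            if len(np.unique(y[tr])) < 2:
                raise ValueError(f"fold {k} of repeat {rep} lacks both classes")
            model = spec.build(seed=cfg.seed)
            model.fit(X[tr], y[tr])
            scores.append(float(np.mean(model.predict(X[te]) == y[te])))
    arr = np.array(scores)
    return {"algorithm": spec.algorithm, "n_folds": len(scores),
            "mean_accuracy": float(arr.mean()), "sd_accuracy": float(arr.std(ddof=1))}


# ---------------------------------------------------------------------------
# tier models

@dataclass
class TierModel:
    tier: int
    spec: ModelSpec
    estimator: object
    positive_class: str
    seed: int

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X)
        if X.shape[0] == 0:
            return np.array([], dtype=object)
        return self.estimator.predict(X).astype(object)

    def score_positive(self, X: np.ndarray) -> np.ndarray:
        """Ranking score for the positive class (for ROC analysis)."""
        est = self.estimator
        classes = list(est.classes_)
        pos = classes.index(self.positive_class)
        if hasattr(est, "predict_proba"):
            return est.predict_proba(X)[:, pos]
        score = est.decision_function(X)
        return score if pos == 1 else -score


def fit_tier(spec: ModelSpec, X: np.ndarray, y: Sequence[str],
             tier: int, seed: int = 0) -> TierModel:
    """Fit one tier's binary classifier on already-relabeled data."""
    X = np.asarray(X)
    if X.shape[1] != N_FEATURES:
        raise ValueError(f"expected {N_FEATURES} features, got {X.shape[1]}")
    y = np.asarray(y, dtype=object)
    if len(np.unique(y)) < 2:
        raise ValueError("degenerate single-class training set")
    est = spec.build(seed=seed)
    est.fit(X, y)
    positive = TIER1_POSITIVE if tier == 1 else TIER2_POSITIVE
    return TierModel(tier=tier, spec=spec, estimator=est,
                     positive_class=positive, seed=seed)


def predict_serial(m1: TierModel, m2: TierModel, X: np.ndarray) -> np.ndarray:
    """Cascade prediction: tier 1 routes VUS, tier 2 settles the rest."""
    if m1.tier != 1 or m2.tier != 2:
        raise ValueError("predict_serial needs a tier-1 and a tier-2 model")
    X = np.asarray(X)
    if X.shape[0] == 0:
        return np.array([], dtype=object)
    if X.shape[1] != N_FEATURES:
        raise ValueError(f"expected {N_FEATURES} features, got {X.shape[1]}")
    out = m1.predict(X)
    rest = out != TIER1_POSITIVE
    if rest.any():
        out[rest] = m2.predict(X[rest])
    return out


# ---------------------------------------------------------------------------
# metrics

def round2(x: float) -> float:
    """Half-up rounding to 2 decimals, the display convention for reports."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"),
                                                  rounding=ROUND_HALF_UP))


@dataclass
class EvaluationReport:
    class_order: list[str]
    confusion: np.ndarray               # rows = truth, cols = prediction
    per_class: pd.DataFrame             # precision/recall/specificity/f1/support
    weighted: dict[str, float]
    accuracy: float
    auroc: Optional[float] = None
    cv_mean: Optional[float] = None
    cv_sd: Optional[float] = None

    def rounded(self) -> dict:
        d = {
            "class_order": self.class_order,
            "confusion": self.confusion.tolist(),
            "accuracy": round2(self.accuracy),
            "per_class": {
                cls: {m: round2(row[m]) for m in
                      ("precision", "recall", "specificity", "f1")} | {
                          "support": int(row["support"])}
                for cls, row in self.per_class.iterrows()},
            "weighted": {k: round2(v) for k, v in self.weighted.items()},
        }
        if self.auroc is not None:
            d["auroc"] = round2(self.auroc)
        if self.cv_mean is not None:
            d["cv_mean"] = round2(self.cv_mean)
            d["cv_sd"] = round2(self.cv_sd)
        return d


def confusion_and_metrics(pred: Sequence[str], truth: Sequence[str],
                          class_order: Sequence[str]) -> EvaluationReport:
    """Confusion matrix plus per-class and support-weighted metrics.

    Per-class precision, recall, specificity and F1 follow the one-vs-rest
    convention; weighted averages weight each class by its true support
    (making weighted recall identical to accuracy).  Because the
    support-weighting of specificity is ambiguous in parts of the
    literature, a negatives-weighted variant is reported alongside.
    """
    pred = np.asarray(pred, dtype=object)
    truth = np.asarray(truth, dtype=object)
    if len(pred) != len(truth):
        raise ValueError("prediction/truth length mismatch")
    extra = (set(pred) | set(truth)) - set(class_order)
    if extra:
        raise ValueError(f"labels outside class order: {sorted(extra)}")
    cm = _sk_confusion(truth, pred, labels=list(class_order))
    total = cm.sum()
    rows = {}
    for i, cls in enumerate(class_order):
        tp = cm[i, i]
        fn = cm[i].sum() - tp
        fp = cm[:, i].sum() - tp
        tn = total - tp - fn - fp
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn) if tp + fn else 0.0
        specificity = tn / (tn + fp) if tn + fp else 0.0
        f1 = (2 * precision * recall / (precision + recall)
              if precision + recall else 0.0)
        rows[cls] = {"precision": precision, "recall": recall,
                     "specificity": specificity, "f1": f1,
                     "support": int(tp + fn)}
    per_class = pd.DataFrame.from_dict(rows, orient="index")
    support = per_class["support"].to_numpy(dtype=float)
    negatives = total - support
    weighted = {
        m: float(np.average(per_class[m], weights=support))
        for m in ("precision", "recall", "specificity", "f1")}
    weighted["specificity_negatives_weighted"] = (
        float(np.average(per_class["specificity"], weights=negatives))
        if negatives.sum() > 0 else float(per_class["specificity"].mean()))
    accuracy = float(np.trace(cm) / total) if total else 0.0
    return EvaluationReport(class_order=list(class_order), confusion=cm,
                            per_class=per_class, weighted=weighted,
                            accuracy=accuracy)


def roc_auc(scores: Sequence[float], truth: Sequence[int]) -> tuple[float, pd.DataFrame]:
    """AUROC via the Mann-Whitney U statistic (ties counted 0.5).

    Returns the area and the ROC curve points (fpr, tpr, threshold) for
    plotting.
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth).astype(int)
    n_pos = int(truth.sum())
    n_neg = len(truth) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs both classes in the truth vector")
    ranks = rankdata(scores)
    u = ranks[truth == 1].sum() - n_pos * (n_pos + 1) / 2
    auc = float(u / (n_pos * n_neg))
    fpr, tpr, thr = _sk_roc_curve(truth, scores)
    curve = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
    return auc, curve


def spearman_collinearity(F: np.ndarray, cfg: MLConfig,
                          feature_names: Sequence[str] = CRITERIA_ORDER
                          ) -> tuple[pd.DataFrame, list[tuple[str, str, float]]]:
    """Spearman rank correlation among features, flagging collinear pairs.

    Constant columns have undefined correlation (reported as NaN, never
    flagged).  Pairs at |rho| >= the collinearity threshold are returned.
    """
    F = np.asarray(F, dtype=float)
    if F.shape[0] < 2:
        raise ValueError("need at least 2 rows")
    p = F.shape[1]
    names = list(feature_names)
    corr = np.full((p, p), np.nan)
    constant = F.min(axis=0) == F.max(axis=0)
    live = np.where(~constant)[0]
    if len(live) >= 2:
        rho = np.asarray(spearmanr(F[:, live]).statistic)
        if rho.ndim == 0:   # scipy returns a scalar for exactly two columns
            rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
        for a, i in enumerate(live):
            for b, j in enumerate(live):
                corr[i, j] = rho[a, b]
    for i in live:
        corr[i, i] = 1.0
    flagged = []
    for a in range(p):
        for b in range(a + 1, p):
            if not np.isnan(corr[a, b]) and abs(corr[a, b]) >= cfg.collinearity_threshold:
                flagged.append((names[a], names[b], float(corr[a, b])))
    matrix = pd.DataFrame(corr, index=names, columns=names)
    return matrix, flagged


def feature_importance(model: TierModel, X_train: np.ndarray, cfg: MLConfig,
                       feature_names: Sequence[str] = CRITERIA_ORDER,
                       max_eval_rows: int = 60, max_background: int = 20
                       ) -> pd.DataFrame:
    """Mean absolute Shapley attribution per feature over the training rows.

    Rows and background are deduplicated to their unique evidence patterns
    (weighted by multiplicity), since binary features make repeats exact.
    Features at or below the drop threshold are flagged droppable; constant
    features attribute exactly zero.
    """
    X_train = np.asarray(X_train)
    uniq, counts = np.unique(X_train, axis=0, return_counts=True)
    rng = np.random.default_rng(cfg.seed)
    if uniq.shape[0] > max_eval_rows:
        sel = rng.choice(uniq.shape[0], size=max_eval_rows, replace=False,
                         p=counts / counts.sum())
        eval_rows, eval_w = uniq[sel], counts[sel].astype(float)
    else:
        eval_rows, eval_w = uniq, counts.astype(float)
    n_bg = min(max_background, uniq.shape[0])
    bg_idx = rng.choice(uniq.shape[0], size=n_bg, replace=False,
                        p=counts / counts.sum()) if uniq.shape[0] > n_bg \
        else np.arange(uniq.shape[0])
    background = uniq[bg_idx]

    result = shapley_values(model.score_positive, eval_rows, background,
                            feature_names=feature_names, seed=cfg.seed)
    mean_abs = np.average(np.abs(result.values), axis=0, weights=eval_w)
    df = pd.DataFrame({
        "feature": list(feature_names),
        "mean_abs_shap": mean_abs,
        "droppable": mean_abs <= cfg.shap_drop_threshold,
    }).sort_values("mean_abs_shap", ascending=False, kind="stable")
    df.attrs["method"] = result.method
    return df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# experiment drivers

def evaluate_tier(dataset: LabeledDataset, tier: int, cfg: MLConfig,
                  specs: Optional[dict[str, ModelSpec]] = None) -> dict:
    """Full per-tier protocol: restrict/relabel, split, CV-compare, test.

    Returns a report dict with one entry per algorithm (CV mean/sd, test
    confusion matrix, per-class and weighted metrics, AUROC).
    """
    specs = specs or default_specs()
    X = dataset.feature_matrix()
    labels = np.asarray(dataset.labels, dtype=object)
    if tier == 2:
        keep = labels != "VUS"
        X, labels = X[keep], labels[keep]
    y = relabel_for_tier(labels, tier)
    class_order = ([TIER1_NEGATIVE, TIER1_POSITIVE] if tier == 1
                   else [TIER2_NEGATIVE, TIER2_POSITIVE])
    X_tr, X_te, y_tr, y_te = split_train_test(X, y, cfg)
    out: dict = {"tier": tier, "n_train": int(len(y_tr)), "n_test": int(len(y_te)),
                 "class_order": class_order, "algorithms": {}}
    positive = class_order[1]
    for name, spec in specs.items():
        cv = cross_validate(spec, X_tr, y_tr, cfg)
        model = fit_tier(spec, X_tr, y_tr, tier, seed=cfg.seed)
        pred = model.predict(X_te)
        report = confusion_and_metrics(pred, y_te, class_order)
        report.cv_mean, report.cv_sd = cv["mean_accuracy"], cv["sd_accuracy"]
        auc, _ = roc_auc(model.score_positive(X_te),
                         (y_te == positive).astype(int))
        report.auroc = auc
        out["algorithms"][name] = {
            "hyperparameters": dict(spec.hyperparameters),
            "cv_mean_accuracy": cv["mean_accuracy"],
            "cv_sd_accuracy": cv["sd_accuracy"],
            "test": report.rounded(),
            "test_accuracy": report.accuracy,
        }
    best = max(out["algorithms"], key=lambda k: out["algorithms"][k]["test_accuracy"])
    out["best_algorithm"] = best
    out["best_test_accuracy"] = out["algorithms"][best]["test_accuracy"]
    return out


def evaluate_flat_three_class(spec: ModelSpec, dataset: LabeledDataset,
                              cfg: MLConfig) -> EvaluationReport:
    """Flat three-class baseline under the same split/CV protocol."""
    X = dataset.feature_matrix()
    y = np.asarray(dataset.labels, dtype=object)
    X_tr, X_te, y_tr, y_te = split_train_test(X, y, cfg)
    cv = cross_validate(spec, X_tr, y_tr, cfg)
    est = spec.build(seed=cfg.seed)
    est.fit(X_tr, y_tr)
    pred = est.predict(X_te).astype(object)
    report = confusion_and_metrics(pred, y_te, list(CLASS_LABELS))
    report.cv_mean, report.cv_sd = cv["mean_accuracy"], cv["sd_accuracy"]
    return report


def run_model_comparison(dataset: LabeledDataset, cfg: MLConfig,
                         include_flat: bool = False) -> dict:
    """Train/compare all algorithms on both tiers; JSON-serializable report."""
    report = {
        "config": asdict(cfg),
        "class_counts": dataset.class_counts(),
        "tier1": evaluate_tier(dataset, 1, cfg),
        "tier2": evaluate_tier(dataset, 2, cfg),
    }
    matrix, flagged = spearman_collinearity(dataset.feature_matrix(), cfg)
    report["collinearity"] = {
        "threshold": cfg.collinearity_threshold,
        "flagged_pairs": [list(t) for t in flagged],
    }
    if include_flat:
        flat = {}
        for name, spec in default_specs().items():
            rep = evaluate_flat_three_class(spec, dataset, cfg)
            flat[name] = rep.rounded()
        report["flat_three_class"] = flat
    return report
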