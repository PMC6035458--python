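"""SMOTE-balanced SVM with sequential forward selection under repeated
stratified cross-validation, plus ROC metrics and DeLong comparison.

Leakage discipline: within every outer fold, z-scoring statistics and SMOTE
are computed from the training portion only; validation instances are never
synthesized over or rescaled with their own statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn import metrics as skm
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CVConfig:
    k_folds: int = 5
    repeats: int = 100
    smote_k: int = 5
    seed: int = 0
    kernel: str = "rbf"
    C: float = 1.0
    gamma: str | float = "scale"
    sfs_tol: float = 1e-4
    sfs_max_features: int | None = 10
    inner_folds: int = 5

    def __post_init__(self) -> None:
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")


@dataclass
class ConfusionMetrics:
    ACC: float
    SEN: float
    SPE: float


@dataclass
class PredictionResult:
    acc: np.ndarray  # per repeat
    sen: np.ndarray
    spe: np.ndarray
    auc: np.ndarray
    scores: list[np.ndarray]  # pooled validation scores per repeat
    labels: list[np.ndarray]
    config: CVConfig

    @property
    def mean_acc(self) -> float:
        return float(np.mean(self.acc))

    @property
    def mean_sen(self) -> float:
        return float(np.mean(self.sen))

    @property
    def mean_spe(self) -> float:
        return float(np.mean(self.spe))

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.auc))

    @property
    def auc_ci(self) -> tuple[float, float]:
        lo, hi = np.percentile(self.auc, [2.5, 97.5])
        return float(lo), float(hi)

    def summary(self) -> dict:
        lo, hi = self.auc_ci
        return {"ACC": self.mean_acc, "SEN": self.mean_sen,
                "SPE": self.mean_spe, "AUC": self.mean_auc,
                "AUC_CI": [lo, hi]}


@dataclass
class FeatureRanking:
    frequency: pd.Series  # selection frequency in [0, 1], sorted descending

    def top(self, n: int) -> list[str]:
        return list(self.frequency.index[:n])


# ---------------------------------------------------------------------------
# building blocks


def smote(minority: np.ndarray, k: int, n_synthetic: int,
          rng: np.random.Generator | int) -> np.ndarray:
    """Synthetic minority samples on segments to k-nearest minority
    neighbors: x + u * (x_nn - x), u ~ U(0, 1)."""
    rng = np.random.default_rng(rng)
    X = np.asarray(minority, dtype=float)
    if len(X) < 2:
        raise ValueError("SMOTE needs at least 2 minority samples")
    if k >= len(X):
        raise ValueError("k must be < number of minority samples")
    if n_synthetic <= 0:
        return np.empty((0, X.shape[1]))
    d2 = ((X[:, None, :] - X[None, :, :]) ** 2).sum(-1)
    np.fill_diagonal(d2, np.inf)
    nn = np.argsort(d2, axis=1)[:, :k]
    base = rng.integers(0, len(X), size=n_synthetic)
    pick = rng.integers(0, k, size=n_synthetic)
    u = rng.uniform(size=n_synthetic)[:, None]
    x = X[base]
    return x + u * (X[nn[base, pick]] - x)


def balance_with_smote(X: np.ndarray, y: np.ndarray, k: int,
                       rng: np.random.Generator) -> tuple[np.ndarray,
                                                          np.ndarray]:
    """Equalize class counts by SMOTE-augmenting the minority class."""
    y = np.asarray(y).astype(int)
    n1, n0 = int((y == 1).sum()), int((y == 0).sum())
    if n1 == n0:
        return X, y
    minority = 1 if n1 < n0 else 0
    deficit = abs(n0 - n1)
    Xm = X[y == minority]
    k_eff = min(k, len(Xm) - 1)
    if k_eff < k:
        log.debug("SMOTE k reduced to %d (minority size %d)", k_eff, len(Xm))
    synth = smote(Xm, k_eff, deficit, rng)
    return (np.vstack([X, synth]),
            np.concatenate([y, np.full(deficit, minority, dtype=int)]))


def confusion_metrics(TP: int, TN: int, FP: int, FN: int) -> ConfusionMetrics:
    """ACC = (TP+TN)/all, SEN = TP/(TP+FN), SPE = TN/(TN+FP)."""
    if min(TP, TN, FP, FN) < 0:
        raise ValueError("negative count")
    total = TP + TN + FP + FN
    acc = (TP + TN) / total if total else float("nan")
    sen = TP / (TP + FN) if TP + FN else float("nan")
    spe = TN / (TN + FP) if TN + FP else float("nan")
    return ConfusionMetrics(acc, sen, spe)


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the normalized Mann-Whitney statistic; ties count one half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n1, n0 = int((labels == 1).sum()), int((labels == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC needs both classes")
    ranks = stats.rankdata(scores)
    return float((ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0)
                 / (n1 * n0))


def roc_curve(scores: np.ndarray, labels: np.ndarray):
    """(fpr, tpr, thresholds); trapezoidal area equals :func:`auc`."""
    fpr, tpr, thr = skm.roc_curve(labels, scores)
    return fpr, tpr, thr


def _svm(config: CVConfig) -> SVC:
    return SVC(kernel=config.kernel, C=config.C, gamma=config.gamma)


def _inner_cv_auc(X: np.ndarray, y: np.ndarray, cols: list[int],
                  config: CVConfig, seed: int) -> float:
    skf = StratifiedKFold(n_splits=min(config.inner_folds,
                                       int(np.bincount(y).min())),
                          shuffle=True, random_state=seed)
    scores = np.empty(len(y))
    for tr, va in skf.split(X, y):
        clf = _svm(config)
        clf.fit(X[np.ix_(tr, cols)], y[tr])
        scores[va] = clf.decision_function(X[np.ix_(va, cols)])
    return auc(scores, y)


def svm_sfs(train_features: np.ndarray, train_labels: np.ndarray,
            config: CVConfig, seed: int = 0) -> tuple[list[int], SVC]:
    """Greedy sequential forward selection maximizing inner-CV AUC.

    Starts empty; each step adds the feature (lowest index wins ties) whose
    addition maximizes the inner 5-fold cross-validated AUC of the SVM;
    stops when the best improvement is <= ``sfs_tol`` or the feature budget
    is exhausted. Returns selected column indices and the classifier
    refitted on the full training data restricted to them.
    """
    X = np.asarray(train_features, dtype=float)
    y = np.asarray(train_labels).astype(int)
    if X.ndim != 2 or X.shape[1] < 1:
        raise ValueError("need a 2D feature matrix")
    if len(set(y)) < 2:
        raise ValueError("both classes required")
    n_feat = X.shape[1]
    budget = config.sfs_max_features or n_feat
    selected: list[int] = []
    trace: list[float] = []  # criterion after each accepted step
    best_score = -np.inf
    remaining = list(range(n_feat))
    while remaining and len(selected) < budget:
        cand_scores = np.array([
            _inner_cv_auc(X, y, selected + [c], config, seed)
            for c in remaining
        ])
        best_i = int(np.argmax(cand_scores))
        improvement = cand_scores[best_i] - (best_score
                                             if np.isfinite(best_score)
                                             else 0.0)
        if selected and improvement <= config.sfs_tol:
            break
        best_score = float(cand_scores[best_i])
        selected.append(remaining.pop(best_i))
        trace.append(best_score)
    clf = _svm(config)
    clf.fit(X[:, selected], y)
    clf.sfs_trace_ = trace
    return selected, clf


def _stratified_split(y: np.ndarray, k: int, seed: int):
    """Stratified folds; redrawn (new seed) if a fold misses a class."""
    for attempt in range(20):
        skf = StratifiedKFold(n_splits=k, shuffle=True,
                              random_state=seed + attempt)
        folds = list(skf.split(np.zeros(len(y)), y))
        if all(len(set(y[va])) == 2 for _, va in folds):
            if attempt:
                log.warning("redrew stratified split %d time(s)", attempt)
            return folds
    raise ValueError("cannot build stratified folds with both classes")


def repeated_cv(table: pd.DataFrame, labels: np.ndarray,
                config: CVConfig = CVConfig()) -> tuple[PredictionResult,
                                                        FeatureRanking]:
    """Repeated stratified k-fold CV of the SMOTE + SVM-SFS pipeline.

    Per fold: z-score with training statistics, SMOTE-balance the training
    portion only, run SFS, then score the untouched validation fold.
    ACC/SEN/SPE use the decision-function zero threshold; AUC pools each
    repeat's validation scores. Selection frequencies are accumulated over
    all repeats x folds.
    """
    y = np.asarray(labels).astype(int)
    X = table.values.astype(float)
    names = list(table.columns)
    ss = np.random.SeedSequence(config.seed)
    repeat_seeds = ss.spawn(config.repeats)
    counts = np.zeros(len(names))
    accs, sens, spes, aucs, all_scores, all_labels = [], [], [], [], [], []
    for r in range(config.repeats):
        rng = np.random.default_rng(repeat_seeds[r])
        split_seed = int(rng.integers(0, 2 ** 31 - 1))
        folds = _stratified_split(y, config.k_folds, split_seed)
        TP = TN = FP = FN = 0
        rep_scores = np.empty(len(y))
        for tr, va in folds:
            mu = X[tr].mean(axis=0)
            sd = X[tr].std(axis=0)
            sd[sd == 0] = 1.0
            Xtr = (X[tr] - mu) / sd
            Xva = (X[va] - mu) / sd
            Xb, yb = balance_with_smote(Xtr, y[tr], config.smote_k, rng)
            sfs_seed = int(rng.integers(0, 2 ** 31 - 1))
            cols, clf = svm_sfs(Xb, yb, config, seed=sfs_seed)
            counts[cols] += 1
            s = clf.decision_function(Xva[:, cols])
            rep_scores[va] = s
            pred = (s > 0).astype(int)
            TP += int(((pred == 1) & (y[va] == 1)).sum())
            TN += int(((pred == 0) & (y[va] == 0)).sum())
            FP += int(((pred == 1) & (y[va] == 0)).sum())
            FN += int(((pred == 0) & (y[va] == 1)).sum())
        cm = confusion_metrics(TP, TN, FP, FN)
        accs.append(cm.ACC)
        sens.append(cm.SEN)
        spes.append(cm.SPE)
        aucs.append(auc(rep_scores, y))
        all_scores.append(rep_scores)
        all_labels.append(y.copy())
    freq = pd.Series(counts / (config.repeats * config.k_folds), index=names)
    freq = freq.sort_values(ascending=False, kind="stable")
    result = PredictionResult(np.asarray(accs), np.asarray(sens),
                              np.asarray(spes), np.asarray(aucs),
                              all_scores, all_labels, config)
    return result, FeatureRanking(freq)


# ---------------------------------------------------------------------------
# ROC comparison


def _delong_placements(scores: np.ndarray, labels: np.ndarray):
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    cmp_mat = (pos[:, None] > neg[None, :]).astype(float) \
        + 0.5 * (pos[:, None] == neg[None, :])
    v10 = cmp_mat.mean(axis=1)  # per positive
    v01 = cmp_mat.mean(axis=0)  # per negative
    return v10, v01, cmp_mat.mean()


def delong_test(scores_a: np.ndarray, scores_b: np.ndarray,
                labels: np.ndarray) -> tuple[float, float]:
    """Paired DeLong z-test for the difference of two AUCs measured on the
    same instances. Returns (z, two-sided p)."""
    labels = np.asarray(labels).astype(int)
    va10, va01, auc_a = _delong_placements(np.asarray(scores_a), labels)
    vb10, vb01, auc_b = _delong_placements(np.asarray(scores_b), labels)
    m, n = len(va10), len(va01)
    s10 = np.cov(np.vstack([va10, vb10])) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([va01, vb01])) if n > 1 else np.zeros((2, 2))
    S = s10 / m + s01 / n
    var = S[0, 0] + S[1, 1] - 2.0 * S[0, 1]
    diff = auc_a - auc_b
    if var <= 1e-15:
        return (0.0, 1.0) if abs(diff) < 1e-15 else (np.inf * np.sign(diff),
                                                     0.0)
    z = diff / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def compare_rocs(result_a: PredictionResult,
                 result_b: PredictionResult) -> tuple[float, float]:
    """DeLong comparison of two cross-validated models, pooling all
    repeats' validation scores. Both results must come from the same
    splits of the same instances."""
    la = np.concatenate(result_a.labels)
    lb = np.concatenate(result_b.labels)
    if len(la) != len(lb) or np.any(la != lb):
        raise ValueError("results are not paired on the same instances")
    return delong_test(np.concatenate(result_a.scores),
                       np.concatenate(result_b.scores), la)


def bonferroni(p_values, m: int | None = None) -> np.ndarray:
    """p_adj = min(1, m * p)."""
    p = np.asarray(p_values, dtype=float)
    m = m if m is not None else len(p)
    return np.minimum(1.0, m * p)
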