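"""Epoch classification and apnea-hypopnea index estimation.

The classifier is trained on class-balanced epochs: the minority RE class
is oversampled to parity by synthetic interpolation between nearest
neighbours (SMOTE) and the result is cleaned with the edited
nearest-neighbours rule to remove noisy synthetic points. Candidate
models are linear classifiers (elastic-net logistic regression trained by
stochastic gradient descent, a Huber-type linear model, and linear and
quadratic discriminant analysis) graded by inner cross-validated
precision-recall AUC.

The AHI is a calibrated multiple of the detected RE-epoch fraction:

    AHI_pred = beta * (# detected RE epochs) / (# analysable epochs),

where beta is the Theil-Sen slope (median of pairwise slopes) regressing
the reference AHI on the true RE-epoch fraction of the training
recordings; the robust slope resists recordings whose long events inflate
the epoch count. The RE-probability threshold is chosen on the training
recordings by maximising Cohen's kappa between estimated and reference
severity classes (normal/mild/moderate/severe at 5/15/30 events/h).
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.discriminant_analysis import (LinearDiscriminantAnalysis,
                                           QuadraticDiscriminantAnalysis)
from sklearn.linear_model import SGDClassifier
from sklearn.metrics import average_precision_score
from sklearn.neighbors import NearestNeighbors

from .evaluation import cohens_kappa

MODEL_KINDS = ("logistic_elastic_net", "huber_linear", "lda", "qda")

SEVERITY_ORDER = ("normal", "mild", "moderate", "severe")
SEVERITY_EDGES = (5.0, 15.0, 30.0)  # inclusive lower bounds of mild+

DEFAULT_SGD = dict(alpha=1e-4, l1_ratio=0.15, max_iter=1000, tol=1e-3)

THRESHOLD_GRID = np.round(np.arange(0.01, 1.00, 0.01), 2)


def severity_from_ahi(ahi: float) -> str:
    """Canonical severity class; lower edges inclusive (AHI >= 5 is mild)."""
    if ahi < SEVERITY_EDGES[0]:
        return "normal"
    if ahi < SEVERITY_EDGES[1]:
        return "mild"
    if ahi < SEVERITY_EDGES[2]:
        return "moderate"
    return "severe"


@dataclass
class AHIEstimate:
    record_id: str
    n_analysable_epochs: int
    n_detected_re_epochs: int
    ahi_pred: float
    severity: str


@dataclass
class TrainedEstimator:
    """A fully fitted epoch classifier with its calibration.

    ``chains`` maps feature name to the transformation chain learned on
    the training set; ``column_means``/``column_stds`` standardise the
    transformed, imputed feature matrix; ``fallback_medians`` impute a
    column when a recording has no finite value of its own for it.
    """

    model_kind: str
    model: object
    probability_threshold: float
    beta: float
    feature_names: list
    chains: dict = field(default_factory=dict)
    column_means: Optional[np.ndarray] = None
    column_stds: Optional[np.ndarray] = None
    fallback_medians: Optional[np.ndarray] = None

    def save(self, path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @staticmethod
    def load(path) -> "TrainedEstimator":
        with open(path, "rb") as fh:
            return pickle.load(fh)


# ---------------------------------------------------------------------------
# Class balancing: SMOTE oversampling + edited nearest-neighbour cleaning
# ---------------------------------------------------------------------------

def smote_oversample(X: np.ndarray, y: np.ndarray, k: int = 5,
                     seed: int = 0):
    """Oversample the minority class to parity by neighbour interpolation."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=bool)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == n_neg:
        return X, y
    minority = y if n_pos < n_neg else ~y
    X_min = X[minority]
    n_new = abs(n_neg - n_pos)
    if X_min.shape[0] < k + 1:
        raise ValueError(
            f"minority class has {X_min.shape[0]} samples; SMOTE with k={k} "
            "needs at least k+1 — reduce k or provide more data")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X_min)
    _, idx = nn.kneighbors(X_min)
    rng = np.random.default_rng(seed)
    base = rng.integers(0, X_min.shape[0], size=n_new)
    pick = rng.integers(1, k + 1, size=n_new)  # skip self at column 0
    gap = rng.random(size=(n_new, 1))
    neigh = X_min[idx[base, pick]]
    synth = X_min[base] + gap * (neigh - X_min[base])
    X_out = np.vstack([X, synth])
    y_out = np.concatenate([y, np.full(n_new, bool(n_pos < n_neg))])
    return X_out, y_out


def enn_clean(X: np.ndarray, y: np.ndarray, k: int = 3):
    """Edited nearest neighbours: drop samples contradicted by the
    majority vote of their k nearest neighbours."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=bool)
    if X.shape[0] <= k + 1:
        return X, y
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
    _, idx = nn.kneighbors(X)
    votes = y[idx[:, 1:]].mean(axis=1)
    keep = (votes >= 0.5) == y
    if not np.any(keep):
        return X, y
    return X[keep], y[keep]


def balance_epochs(X: np.ndarray, y: np.ndarray, k_smote: int = 5,
                   k_enn: int = 3, seed: int = 0):
    """SMOTE to class parity followed by ENN cleaning."""
    X2, y2 = smote_oversample(X, y, k=k_smote, seed=seed)
    return enn_clean(X2, y2, k=k_enn)


# ---------------------------------------------------------------------------
# Candidate models and selection
# ---------------------------------------------------------------------------

def _make_model(model_kind: str, seed: int, **hyper):
    params = {**DEFAULT_SGD, **hyper}
    if model_kind == "logistic_elastic_net":
        return SGDClassifier(loss="log_loss", penalty="elasticnet",
                             random_state=seed, **params)
    if model_kind == "huber_linear":
        return SGDClassifier(loss="modified_huber", penalty="elasticnet",
                             random_state=seed, **params)
    if model_kind == "lda":
        return LinearDiscriminantAnalysis()
    if model_kind == "qda":
        return QuadraticDiscriminantAnalysis(reg_param=1e-3)
    raise ValueError(f"unknown model kind {model_kind!r}")


def select_model(folds, seed: int = 0, **hyper) -> str:
    """Pick the candidate with the best mean inner-CV precision-recall AUC.

    ``folds`` is a sequence of ``((X_train, y_train), (X_val, y_val))``
    pairs with participant-disjoint sides. Folds whose validation side is
    single-class are skipped with a warning. Ties break toward the
    earliest candidate (logistic first).
    """
    import warnings
    scores = {}
    for kind in MODEL_KINDS:
        aucs = []
        for (X_tr, y_tr), (X_va, y_va) in folds:
            if len(set(np.asarray(y_va, bool))) < 2 or len(set(np.asarray(y_tr, bool))) < 2:
                warnings.warn("single-class fold skipped in model selection",
                              stacklevel=2)
                continue
            model = _make_model(kind, seed, **hyper)
            model.fit(X_tr, np.asarray(y_tr, int))
            prob = model.predict_proba(X_va)[:, 1]
            aucs.append(average_precision_score(np.asarray(y_va, int), prob))
        scores[kind] = float(np.mean(aucs)) if aucs else -np.inf
    best = MODEL_KINDS[0]
    for kind in MODEL_KINDS:
        if scores[kind] > scores[best]:
            best = kind
    return best


def train_classifier(X: np.ndarray, y: np.ndarray,
                     model_kind: str = "logistic_elastic_net",
                     seed: int = 0, **hyper):
    """Fit the chosen epoch classifier; reproducible given the seed."""
    X = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(X)):
        bad = np.where(~np.isfinite(X).all(axis=0))[0]
        raise ValueError(f"non-finite inputs in feature columns {bad.tolist()}")
    model = _make_model(model_kind, seed, **hyper)
    model.fit(X, np.asarray(y, int))
    return model


# ---------------------------------------------------------------------------
# Theil-Sen calibration and AHI estimation
# ---------------------------------------------------------------------------

def theil_sen_slope(x, y) -> float:
    """Median of all pairwise slopes; pairs with equal x are skipped."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two points")
    dx = x[:, None] - x[None, :]
    dy = y[:, None] - y[None, :]
    iu = np.triu_indices(x.size, k=1)
    dx, dy = dx[iu], dy[iu]
    defined = dx != 0
    if not np.any(defined):
        raise ValueError("all x values equal: slope undefined")
    return float(np.median(dy[defined] / dx[defined]))


def estimate_beta(reference_ahis, true_epoch_labels, analysable_masks) -> float:
    """Theil-Sen slope from true RE-epoch fractions to reference AHI.

    For each training recording the predictor is the fraction of
    analysable (sleep) epochs whose true class is RE; the response is the
    reference AHI.
    """
    x = []
    for labels, mask in zip(true_epoch_labels, analysable_masks):
        labels = np.asarray(labels, bool)
        mask = np.asarray(mask, bool)
        n = int(mask.sum())
        if n == 0:
            raise ValueError("recording without analysable epochs")
        x.append(labels[mask].sum() / n)
    return theil_sen_slope(np.asarray(x), np.asarray(reference_ahis, float))


def select_probability_threshold(probabilities_per_recording,
                                 reference_severities, beta: float) -> float:
    """Severity-kappa-maximising RE-probability threshold.

    Probabilities must already be restricted to sleep epochs. The grid is
    0.01..0.99 in steps of 0.01 and ties resolve toward the highest
    threshold (favouring specificity).
    """
    reference = list(reference_severities)
    best_thr, best_kappa = THRESHOLD_GRID[0], -np.inf
    for thr in THRESHOLD_GRID:
        est = []
        for probs in probabilities_per_recording:
            probs = np.asarray(probs, float)
            frac = np.mean(probs >= thr) if probs.size else 0.0
            est.append(severity_from_ahi(beta * frac))
        kappa = cohens_kappa(reference, est)
        if kappa >= best_kappa:
            best_thr, best_kappa = float(thr), kappa
    return best_thr


def estimate_ahi(probabilities, estimator: TrainedEstimator,
                 analysable_mask, record_id: str = "record") -> AHIEstimate:
    """AHI and severity from per-epoch RE probabilities.

    Only analysable (sleep) epochs count; detection is probability >=
    threshold.
    """
    probs = np.asarray(probabilities, float)
    mask = np.asarray(analysable_mask, bool)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("no analysable epochs: AHI undefined")
    detected = int(np.sum(probs[mask] >= estimator.probability_threshold))
    ahi = estimator.beta * detected / n
    return AHIEstimate(record_id=record_id, n_analysable_epochs=n,
                       n_detected_re_epochs=detected, ahi_pred=ahi,
                       severity=severity_from_ahi(ahi))
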