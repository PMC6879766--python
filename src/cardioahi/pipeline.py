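"""End-to-end training and prediction over prepared recordings.

Gluing the stages together: epoch labelling -> feature extraction ->
per-feature transformation chains (learned on the training set) ->
per-recording median imputation and training-set standardisation ->
SMOTE+ENN balancing -> classifier -> Theil-Sen beta and severity-kappa
probability threshold.

Classifier training uses all epochs (wake included); the probability
threshold and beta are chosen on sleep epochs only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .epoch_labelling import (EpochLabelSet, apply_sleep_mask,
                              characterise_epochs, label_re_epochs)
from .feature_extraction import (FeatureMatrix, FeatureRegistry,
                                 extract_feature_matrix)
from .feature_optimisation import (TransformationChain, apply_chain,
                                   optimise_feature)
from .io_formats import harmonise_hypopneas
from .modelling import (TrainedEstimator, balance_epochs, estimate_ahi,
                        estimate_beta, select_model,
                        select_probability_threshold, severity_from_ahi,
                        train_classifier)


@dataclass
class PreparedRecording:
    """Feature matrix plus epoch labels for one recording."""

    record_id: str
    features: FeatureMatrix
    labels: EpochLabelSet
    reference_ahi: Optional[float] = None


def prepare_recording(ibis, events, stages, n_epochs: int,
                      registry: Optional[FeatureRegistry] = None,
                      ecg=None, reference_ahi: Optional[float] = None,
                      harmonise: bool = True) -> PreparedRecording:
    """Label epochs and extract features for one recording."""
    if harmonise:
        events = harmonise_hypopneas(events)
    labels = label_re_epochs(events, n_epochs)
    labels = characterise_epochs(events, labels)
    labels = apply_sleep_mask(labels, stages)
    features = extract_feature_matrix(ibis, ecg, n_epochs, registry)
    return PreparedRecording(record_id=ibis.record_id, features=features,
                             labels=labels, reference_ahi=reference_ahi)


def _transform_matrix(rec: PreparedRecording, chains: dict,
                      feature_names) -> np.ndarray:
    cols = []
    frame = rec.features.to_frame()
    for name in feature_names:
        x = frame[name].to_numpy(dtype=float)
        chain = chains.get(name)
        if chain is not None and len(chain):
            x = apply_chain(x, chain)
        cols.append(x)
    return np.column_stack(cols)


def _impute(X: np.ndarray, fallback: np.ndarray) -> np.ndarray:
    """Per-recording median imputation with training fallback."""
    X = X.copy()
    for j in range(X.shape[1]):
        col = X[:, j]
        bad = ~np.isfinite(col)
        if bad.all():
            X[bad, j] = fallback[j]
        elif bad.any():
            X[bad, j] = np.nanmedian(col)
    return X


def train_pipeline(recordings: Sequence[PreparedRecording], seed: int = 0,
                   model_kind: Optional[str] = "logistic_elastic_net",
                   max_chain_depth: int = 5,
                   optimise: bool = True, cv_threshold: bool = True,
                   **hyper) -> TrainedEstimator:
    """Fit the full estimator on training recordings.

    ``model_kind=None`` selects the classifier by 4-fold inner
    cross-validated precision-recall AUC; the default skips selection and
    trains the elastic-net logistic model directly.

    With ``cv_threshold`` (default) the severity-kappa probability
    threshold is chosen on out-of-fold probabilities from an inner 4-fold
    participant-level split: in-sample probabilities are optimistically
    sharp, which drags the threshold too low and overestimates the AHI of
    severe recordings at validation time.
    """
    if any(r.reference_ahi is None for r in recordings):
        raise ValueError("training recordings need reference_ahi")
    feature_names = recordings[0].features.names

    series = {name: [] for name in feature_names}
    labels_per_rec = []
    for r in recordings:
        frame = r.features.to_frame()
        for name in feature_names:
            series[name].append(frame[name].to_numpy(dtype=float))
        labels_per_rec.append(r.labels.re_class)

    chains = {}
    for name in feature_names:
        if optimise:
            chains[name] = optimise_feature(series[name], labels_per_rec,
                                            feature_name=name,
                                            max_depth=max_chain_depth)
        else:
            chains[name] = TransformationChain(name, [], 0.0)

    raw_mats = [_transform_matrix(r, chains, feature_names)
                for r in recordings]
    stacked = np.vstack(raw_mats)
    fallback = np.nanmedian(stacked, axis=0)
    fallback[~np.isfinite(fallback)] = 0.0
    mats = [_impute(m, fallback) for m in raw_mats]
    stacked = np.vstack(mats)
    means = stacked.mean(axis=0)
    stds = stacked.std(axis=0)
    stds[stds == 0] = 1.0
    mats = [(m - means) / stds for m in mats]

    X = np.vstack(mats)
    y = np.concatenate([r.labels.re_class for r in recordings])

    if model_kind is None:
        model_kind = _inner_select(mats, recordings, seed, **hyper)

    Xb, yb = balance_epochs(X, y, seed=seed)
    model = train_classifier(Xb, yb, model_kind=model_kind, seed=seed,
                             **hyper)

    beta = estimate_beta(
        [r.reference_ahi for r in recordings],
        [r.labels.re_class for r in recordings],
        [r.labels.analysable for r in recordings])

    if cv_threshold and len(recordings) >= 8:
        probs_sleep = _out_of_fold_probabilities(mats, recordings, model_kind,
                                                 seed, **hyper)
    else:
        probs_sleep = [model.predict_proba(m)[:, 1][r.labels.analysable]
                       for m, r in zip(mats, recordings)]
    ref_sev = [severity_from_ahi(r.reference_ahi) for r in recordings]
    threshold = select_probability_threshold(probs_sleep, ref_sev, beta)

    return TrainedEstimator(model_kind=model_kind, model=model,
                            probability_threshold=threshold, beta=beta,
                            feature_names=list(feature_names), chains=chains,
                            column_means=means, column_stds=stds,
                            fallback_medians=fallback)


def _out_of_fold_probabilities(mats, recordings, model_kind, seed, **hyper):
    """Sleep-epoch probabilities predicted by 4-fold inner models.

    Folds are participant-level; each recording's probabilities come from
    a classifier that never saw it, mirroring how the estimator is
    applied to validation recordings.
    """
    from .cross_validation import build_folds
    meta = [{"record_id": r.record_id, "ahi": r.reference_ahi}
            for r in recordings]
    plan = build_folds(meta, k=4, seed=seed)
    index = {r.record_id: i for i, r in enumerate(recordings)}
    probs = [None] * len(recordings)
    for i in range(plan.k):
        tr_ids, va_ids = plan.fold(i)
        X_tr = np.vstack([mats[index[rid]] for rid in tr_ids])
        y_tr = np.concatenate([recordings[index[rid]].labels.re_class
                               for rid in tr_ids])
        Xb, yb = balance_epochs(X_tr, y_tr, seed=seed)
        fold_model = train_classifier(Xb, yb, model_kind=model_kind,
                                      seed=seed, **hyper)
        for rid in va_ids:
            j = index[rid]
            p = fold_model.predict_proba(mats[j])[:, 1]
            probs[j] = p[recordings[j].labels.analysable]
    return probs


def _inner_select(mats, recordings, seed, **hyper):
    from .cross_validation import build_folds
    meta = [{"record_id": r.record_id, "ahi": r.reference_ahi}
            for r in recordings]
    plan = build_folds(meta, k=4, seed=seed)
    by_id = {r.record_id: (m, r.labels.re_class)
             for m, r in zip(mats, recordings)}
    folds = []
    for i in range(plan.k):
        tr_ids, va_ids = plan.fold(i)
        X_tr = np.vstack([by_id[rid][0] for rid in tr_ids])
        y_tr = np.concatenate([by_id[rid][1] for rid in tr_ids])
        X_va = np.vstack([by_id[rid][0] for rid in va_ids])
        y_va = np.concatenate([by_id[rid][1] for rid in va_ids])
        folds.append(((X_tr, y_tr), (X_va, y_va)))
    return select_model(folds, seed=seed, **hyper)


def predict_probabilities(rec: PreparedRecording,
                          estimator: TrainedEstimator) -> np.ndarray:
    """Per-epoch RE probabilities for one recording."""
    X = _transform_matrix(rec, estimator.chains, estimator.feature_names)
    X = _impute(X, estimator.fallback_medians)
    X = (X - estimator.column_means) / estimator.column_stds
    return estimator.model.predict_proba(X)[:, 1]


def predict_recording(rec: PreparedRecording, estimator: TrainedEstimator):
    """(probabilities, AHIEstimate) for one recording."""
    probs = predict_probabilities(rec, estimator)
    est = estimate_ahi(probs, estimator, rec.labels.analysable,
                       record_id=rec.record_id)
    return probs, est
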