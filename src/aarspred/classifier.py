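"""Soft-margin kernel SVM training, scoring and the two-stage cascade.

The default kernel is the radial basis function; linear and polynomial
kernels are also exposed. Stage 1 scores a protein as aaRS (positive)
versus non-aaRS; sequences passing stage 1 are forwarded to stage 2, where
class-1 is the positive label and class-2 the negative. Decision values
are signed distances to the margin; the prediction threshold defaults to
0 and can be swept.
"""

from __future__ import annotations

import datetime
import hashlib
import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import joblib
import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from aarspred.composition import FeatureSpec, FeatureVector
from aarspred.domains import DomainAnnotation
from aarspred.errors import ComputationError, InputError, SpecMismatchError
from aarspred.evaluation import confusion, metrics
from aarspred.sequence_io import ProteinSequence

Kernel = str  # linear | polynomial | rbf

#: Regularization grid explored by :func:`grid_search`.
DEFAULT_C_GRID: tuple[float, ...] = (0.1, 1.0, 10.0, 100.0)
#: RBF width grid: powers of two from 2^-7 to 2^3.
DEFAULT_GAMMA_GRID: tuple[float, ...] = tuple(2.0 ** e for e in range(-7, 4))


@dataclass
class SVMModel:
    """A fitted kernel SVM bound to a fixed, named feature order."""

    kernel: Kernel
    C: float
    gamma: float | None
    degree: int | None
    feature_spec: FeatureSpec
    svc: SVC
    metadata: dict = field(default_factory=dict)

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        """Signed decision values for a (n_samples, n_features) matrix."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != len(self.feature_spec):
            raise SpecMismatchError(
                f"matrix has {X.shape[1] if X.ndim == 2 else '?'} columns, "
                f"model expects {len(self.feature_spec)}"
            )
        return np.asarray(self.svc.decision_function(X))


def _as_sklearn_kernel(kernel: Kernel) -> str:
    mapping = {"linear": "linear", "polynomial": "poly", "rbf": "rbf"}
    if kernel not in mapping:
        raise InputError(
            f"unknown kernel {kernel!r}; expected one of {sorted(mapping)}"
        )
    return mapping[kernel]


def train(
    X: np.ndarray,
    y: Sequence[int],
    kernel: Kernel = "rbf",
    C: float = 10.0,
    gamma: float = 0.05,
    degree: int = 3,
    seed: int = 0,
    feature_spec: FeatureSpec | None = None,
) -> SVMModel:
    """Fit a soft-margin SVM; reproducible for fixed inputs and seed.

    ``feature_spec`` names and orders the columns of X; scoring later
    refuses vectors whose spec differs. Raises on single-class or
    non-finite input.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.ndim != 2:
        raise InputError("X must be 2-dimensional")
    if not np.isfinite(X).all():
        raise InputError("feature matrix contains NaN or infinite values")
    if len(np.unique(y)) < 2:
        raise InputError("training requires both classes present")
    if feature_spec is None:
        feature_spec = FeatureSpec(tuple(f"f{i}" for i in range(X.shape[1])))
    if len(feature_spec) != X.shape[1]:
        raise InputError(
            f"feature_spec has {len(feature_spec)} names for "
            f"{X.shape[1]} columns"
        )
    svc = SVC(
        kernel=_as_sklearn_kernel(kernel),
        C=C,
        gamma=gamma if kernel != "linear" else "scale",
        degree=degree if degree is not None else 3,
        random_state=seed,
    )
    svc.fit(X, y)
    meta = {
        "seed": seed,
        "date": datetime.date.today().isoformat(),
        "dataset_hash": hashlib.sha256(
            X.tobytes() + y.tobytes()
        ).hexdigest()[:16],
        "n_samples": int(len(y)),
    }
    return SVMModel(
        kernel=kernel,
        C=C,
        gamma=None if kernel == "linear" else gamma,
        degree=degree if kernel == "polynomial" else None,
        feature_spec=feature_spec,
        svc=svc,
        metadata=meta,
    )


def _check_spec(m: SVMModel, v: FeatureVector) -> None:
    if v.spec != m.feature_spec:
        have, want = set(v.spec.names), set(m.feature_spec.names)
        extra, missing = sorted(have - want), sorted(want - have)
        if extra or missing:
            detail = f"unexpected {extra[:5]}, missing {missing[:5]}"
        else:
            detail = "same names, different order"
        raise SpecMismatchError(f"feature spec mismatch: {detail}")


def decision_value(m: SVMModel, v: FeatureVector) -> float:
    """Signed score of one feature vector; positive side = positive class."""
    _check_spec(m, v)
    return float(m.decision_function(v.values[None, :])[0])


def decision_values(m: SVMModel, vs: Sequence[FeatureVector]) -> np.ndarray:
    """Vectorized :func:`decision_value` over same-spec vectors."""
    for v in vs:
        _check_spec(m, v)
    X = np.stack([v.values for v in vs])
    return m.decision_function(X)


def predict_label(m: SVMModel, v: FeatureVector, threshold: float = 0.0) -> int:
    """1 iff the decision value is at or above the threshold."""
    return int(decision_value(m, v) >= threshold)


def grid_search(
    X: np.ndarray,
    y: Sequence[int],
    kernel: Kernel = "rbf",
    C_grid: Sequence[float] = DEFAULT_C_GRID,
    gamma_grid: Sequence[float] = DEFAULT_GAMMA_GRID,
    k: int = 5,
    seed: int = 0,
    feature_spec: FeatureSpec | None = None,
) -> tuple[SVMModel, dict]:
    """Pick (C, gamma) by mean k-fold CV accuracy, MCC as tie-breaker.

    Returns the model refit on all data with the winning parameters plus a
    record of the search. Deterministic for a fixed seed.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y))
    gammas = gamma_grid if kernel != "linear" else (0.0,)
    best: tuple[float, float, float, float] | None = None  # acc, mcc, -C, -gamma
    best_params: tuple[float, float] | None = None
    trace = []
    for C, gamma in itertools.product(C_grid, gammas):
        accs, mccs = [], []
        for train_idx, test_idx in splits:
            model = train(
                X[train_idx], y[train_idx], kernel=kernel, C=C,
                gamma=gamma or 1.0, seed=seed,
            )
            preds = (model.decision_function(X[test_idx]) >= 0.0).astype(int)
            rep = metrics(confusion(list(y[test_idx]), list(preds)))
            accs.append(rep.accuracy)
            mccs.append(rep.mcc)
        key = (float(np.mean(accs)), float(np.mean(mccs)), -C, -gamma)
        trace.append({"C": C, "gamma": gamma, "cv_accuracy": key[0], "cv_mcc": key[1]})
        if best is None or key > best:
            best, best_params = key, (C, gamma)
    assert best_params is not None
    C, gamma = best_params
    model = train(
        X, y, kernel=kernel, C=C, gamma=gamma or 1.0, seed=seed,
        feature_spec=feature_spec,
    )
    search = {
        "best_C": C, "best_gamma": gamma,
        "cv_accuracy": best[0], "cv_mcc": best[1], "trace": trace,
    }
    return model, search


def save_model(m: SVMModel, path: str | Path) -> None:
    """Persist a model (feature spec, kernel, hyperparameters, metadata)."""
    joblib.dump(m, path)


def load_model(path: str | Path) -> SVMModel:
    obj = joblib.load(path)
    if not isinstance(obj, SVMModel):
        raise InputError(f"{path}: not a saved SVM model")
    return obj


@dataclass(frozen=True)
class TwoStagePrediction:
    """Cascade outcome: stage-2 fields are populated only for aaRS calls."""

    stage1_score: float
    stage1_label: str  # "aaRS" | "non-aaRS"
    stage2_score: float | None
    final_label: str  # "non-aaRS" | "class-1" | "class-2"


def two_stage_predict(
    seq: ProteinSequence,
    stage1_model: SVMModel,
    stage1_featurize: Callable[[ProteinSequence, DomainAnnotation], FeatureVector],
    stage2_model: SVMModel,
    stage2_featurize: Callable[[ProteinSequence, DomainAnnotation], FeatureVector],
    ann: DomainAnnotation,
    thresholds: tuple[float, float] = (0.0, 0.0),
) -> TwoStagePrediction:
    """Predict aaRS vs non-aaRS, then class-1 vs class-2 for positives.

    Stage 2 runs only on stage-1 positives; its positive label is class-1.
    """
    s1 = decision_value(stage1_model, stage1_featurize(seq, ann))
    if s1 < thresholds[0]:
        return TwoStagePrediction(s1, "non-aaRS", None, "non-aaRS")
    s2 = decision_value(stage2_model, stage2_featurize(seq, ann))
    final = "class-1" if s2 >= thresholds[1] else "class-2"
    return TwoStagePrediction(s1, "aaRS", s2, final)
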