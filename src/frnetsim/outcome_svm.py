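"""RBF-SVM classification of post-operative seizure freedom.

The classifier consumes the four FR factors (FR resection ratio, spatial
FRnet, temporal FRnet-A, temporal FRnet-B) and a seizure-free label per
patient.  Hyperparameters follow the clinical protocol: z-score
normalization fitted on the training rows, RBF kernel with C = 1 and a
kernel coefficient of 1/(number of factors) = 0.25 for four factors.

:class:`FROutcomeClassifier` is a scikit-learn estimator (fit/predict,
``get_params``/``set_params``, trailing-underscore fitted attributes) and
composes with sklearn model selection; the module-level :func:`train`,
:func:`predict` and :func:`loocv_accuracy` are thin wrappers.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from .fr_network import FEATURE_NAMES, FRFeatureVector

__all__ = ["FROutcomeClassifier", "train", "predict", "loocv_accuracy"]


class FROutcomeClassifier(BaseEstimator, ClassifierMixin):
    """Seizure-freedom SVM over the four FR factors.

    Parameters
    ----------
    C : float
        SVM penalty (protocol value 1.0).
    kernel_scale : {"fixed", "auto"}
        ``"fixed"`` sets the RBF coefficient to 1/n_features on the
        z-scored features (the protocol's 1/number-of-factors rule);
        ``"auto"`` delegates to sklearn's ``gamma="scale"``.

    Attributes
    ----------
    feature_means_ : ndarray
        Training-column means, used both for z-scoring and to impute
        unavailable (NaN) components at z-score 0.
    gamma_ : float
        The kernel coefficient actually used.
    classes_ : ndarray of [False, True]
        ``True`` = seizure free.

    Notes
    -----
    A decision value of exactly 0 is labelled *not* seizure free — the
    conservative convention that keeps a virtual resection growing.
    """

    def __init__(self, C: float = 1.0, kernel_scale: str = "fixed"):
        self.C = C
        self.kernel_scale = kernel_scale

    # -- helpers -----------------------------------------------------------
    def _impute(self, X: np.ndarray) -> np.ndarray:
        X = np.array(X, dtype=float, copy=True)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (n_samples, n_features)")
        nan = np.isnan(X)
        if nan.any():
            X[nan] = np.take(self.feature_means_, np.where(nan)[1])
        return X

    # -- sklearn API -------------------------------------------------------
    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=bool)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X and y have incompatible shapes")
        if len(np.unique(y)) < 2:
            raise ValueError("training set contains a single outcome label")
        self.n_features_in_ = X.shape[1]
        self.feature_means_ = np.nanmean(X, axis=0)
        Ximp = self._impute(X)
        sds = Ximp.std(axis=0)
        if np.any(sds == 0):
            names = (FEATURE_NAMES if X.shape[1] == len(FEATURE_NAMES)
                     else [f"feature_{i}" for i in range(X.shape[1])])
            bad = [names[i] for i in np.flatnonzero(sds == 0)]
            raise ValueError(f"constant feature(s): {bad}")
        self.scaler_ = StandardScaler().fit(Ximp)
        if self.kernel_scale == "fixed":
            gamma = 1.0 / self.n_features_in_
        elif self.kernel_scale == "auto":
            gamma = "scale"
        else:
            raise ValueError(f"unknown kernel_scale {self.kernel_scale!r}")
        Z = self.scaler_.transform(Ximp)
        self.svc_ = SVC(C=self.C, kernel="rbf", gamma=gamma)
        self.svc_.fit(Z, y)
        if self.kernel_scale == "fixed":
            self.gamma_ = 1.0 / self.n_features_in_
        else:
            self.gamma_ = 1.0 / (self.n_features_in_ * Z.var())
        self.classes_ = np.array([False, True])
        self._train_X = np.asarray(X, dtype=float)
        self._train_y = y
        return self

    def decision_function(self, X):
        check_is_fitted(self, "svc_")
        Z = self.scaler_.transform(self._impute(np.asarray(X, dtype=float)))
        return self.svc_.decision_function(Z)

    def predict(self, X):
        return self.decision_function(X) > 0.0

    def predict_feature_vector(self, fv: FRFeatureVector) -> bool:
        """Label a single :class:`FRFeatureVector` (NaN components imputed)."""
        return bool(self.predict(fv.as_array()[None, :])[0])

    # -- persistence -------------------------------------------------------
    def to_json(self, path) -> None:
        """Serialize for reproducible reload (training data + params).

        Refitting on reload is exact: the SVM solver is deterministic for
        fixed inputs.
        """
        check_is_fitted(self, "svc_")
        payload = {
            "C": self.C,
            "kernel_scale": self.kernel_scale,
            "gamma": self.gamma_,
            "feature_means": self.feature_means_.tolist(),
            "scaler_mean": self.scaler_.mean_.tolist(),
            "scaler_scale": self.scaler_.scale_.tolist(),
            "train_X": np.where(np.isnan(self._train_X), None,
                                self._train_X).tolist(),
            "train_y": self._train_y.astype(int).tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")

    @classmethod
    def from_json(cls, path) -> "FROutcomeClassifier":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        model = cls(C=payload["C"], kernel_scale=payload["kernel_scale"])
        X = np.array(
            [[np.nan if v is None else float(v) for v in row]
             for row in payload["train_X"]]
        )
        y = np.array(payload["train_y"], dtype=bool)
        return model.fit(X, y)


def train(features, labels, C: float = 1.0,
          kernel_scale: str = "fixed") -> FROutcomeClassifier:
    """Fit the outcome SVM on an (n, 4) factor matrix; requires n >= 4."""
    X = np.asarray(features, dtype=float)
    if X.shape[0] < 4:
        raise ValueError("need at least 4 training patients")
    return FROutcomeClassifier(C=C, kernel_scale=kernel_scale).fit(X, labels)


def predict(model: FROutcomeClassifier, fv: FRFeatureVector) -> bool:
    """Deterministic seizure-free label for one feature vector."""
    return model.predict_feature_vector(fv)


def loocv_accuracy(features, labels, C: float = 1.0,
                   kernel_scale: str = "fixed") -> float:
    """Leave-one-out cross-validated accuracy (1 - misclassification).

    Each fold refits normalization and SVM on the remaining rows.  A
    fold whose training rows cannot support a fit (single label, or
    constant features) predicts the fold's majority label instead (with
    a warning); a within-fold tie falls back to the whole cohort's
    majority.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=bool)
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least 3 rows for leave-one-out")

    def majority(labels_: np.ndarray) -> bool:
        pos = int(labels_.sum())
        neg = labels_.size - pos
        if pos != neg:
            return pos > neg
        return bool(y.sum() * 2 > n)

    correct = 0
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        yi = y[mask]
        try:
            model = FROutcomeClassifier(C=C, kernel_scale=kernel_scale)
            model.fit(X[mask], yi)
            pred = bool(model.predict(X[i][None, :])[0])
        except ValueError as exc:
            warnings.warn(
                f"fold {i}: {exc}; predicting majority label", stacklevel=2
            )
            pred = majority(yi)
        correct += int(pred == bool(y[i]))
    return correct / n


def cohort_features(patients, resections=None, graphs=None, rates=None):
    """Factor matrix and label vector for a cohort.

    Parameters
    ----------
    patients : sequence of PatientRecord
    resections : sequence of contact sets, optional
        Defaults to each patient's actual resected set.
    graphs, rates : optional pre-computed per-patient MI graphs / rate
        tables (sequences aligned with ``patients``).

    Returns
    -------
    X : (n, 4) float array (NaN for unavailable components)
    y : (n,) bool array of seizure-free labels
    """
    from . import fr_network

    X, y = [], []
    for k, p in enumerate(patients):
        res = resections[k] if resections is not None else p.resected_set
        fv = fr_network.feature_vector(
            p, res,
            graph=None if graphs is None else graphs[k],
            rates=None if rates is None else rates[k],
        )
        if p.seizure_free is None:
            raise ValueError(f"patient {p.patient_id} has no outcome label")
        X.append(fv.as_array())
        y.append(p.seizure_free)
    return np.array(X), np.array(y, dtype=bool)
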