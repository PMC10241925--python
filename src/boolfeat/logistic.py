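"""Balanced-loss logistic layer on derived features.

The classifier is ``logit P(y=1|x) = beta . Phi(x) + b0`` where Phi is the
evaluated representation.  Fitting minimizes the class-balanced logistic loss
(inverse-prevalence weights ``N / (2 N_c)``) plus a small ridge penalty by
damped Newton iteration.  The ridge term stabilizes the frequent case of a
Boolean derived feature that perfectly separates a small training fold.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import expressions as ex
from .datasets import Dataset
from .exceptions import DegenerateDataError, SchemaError

PROB_EPS = 1e-12


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def class_weights(labels: np.ndarray) -> np.ndarray:
    """Per-sample weights N / (2 N_c): each class contributes equal total weight."""
    labels = np.asarray(labels)
    n = labels.size
    n1 = int(np.sum(labels == 1))
    n0 = n - n1
    if n0 == 0 or n1 == 0:
        raise DegenerateDataError("class weights need both classes present")
    w = np.where(labels == 1, n / (2.0 * n1), n / (2.0 * n0))
    return w


def balanced_log_loss(
    labels: np.ndarray,
    probabilities: np.ndarray,
    sample_weight: np.ndarray | None = None,
) -> tuple[float, np.ndarray]:
    """Weight-normalized cross-entropy; returns (aggregate, per-case losses)."""
    y = np.asarray(labels, dtype=float)
    p = np.clip(np.asarray(probabilities, dtype=float), PROB_EPS, 1 - PROB_EPS)
    if y.shape != p.shape:
        raise ValueError("labels and probabilities must have the same length")
    w = np.ones_like(y) if sample_weight is None else np.asarray(sample_weight, dtype=float)
    if w.shape != y.shape:
        raise ValueError("sample_weight must match labels in length")
    per_case = -w * (y * np.log(p) + (1 - y) * np.log(1 - p))
    return float(per_case.sum() / w.sum()), per_case


def fit_logistic(
    Phi: np.ndarray,
    labels: np.ndarray,
    sample_weight: np.ndarray | None = None,
    ridge: float = 1e-6,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> tuple[np.ndarray, float]:
    """Damped-Newton fit of weighted ridge-penalized logistic regression.

    Returns ``(beta, intercept)``.  The intercept is not penalized.  The fit is
    deterministic: no randomness, fixed initialization at zero.
    """
    Phi = np.asarray(Phi, dtype=float)
    if Phi.ndim != 2:
        raise ValueError("Phi must be 2-D")
    if not np.isfinite(Phi).all():
        raise ValueError("Phi contains non-finite entries")
    y = np.asarray(labels, dtype=float)
    n, p = Phi.shape
    if n <= p:
        warnings.warn(f"fitting {p} coefficients on only {n} samples", stacklevel=2)
    if np.any(np.ptp(Phi, axis=0) == 0):
        warnings.warn("constant derived-feature column; its coefficient is ridge-shrunk",
                      stacklevel=2)
    w = np.ones(n) if sample_weight is None else np.asarray(sample_weight, dtype=float)
    wsum = w.sum()

    Xa = np.column_stack([Phi, np.ones(n)])
    theta = np.zeros(p + 1)
    pen = np.full(p + 1, ridge)
    pen[-1] = 0.0  # intercept unpenalized

    def loss(th: np.ndarray) -> float:
        pr = sigmoid(Xa @ th)
        base, _ = balanced_log_loss(y, pr, w)
        return base + 0.5 * float(pen @ (th**2))

    prev = loss(theta)
    for _ in range(max_iter):
        pr = sigmoid(Xa @ theta)
        grad = Xa.T @ (w * (pr - y)) / wsum + pen * theta
        curv = w * pr * (1 - pr)
        H = (Xa.T * curv) @ Xa / wsum + np.diag(pen)
        H[np.diag_indices_from(H)] += 1e-10
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = grad
        # damping: halve until the loss does not increase
        t = 1.0
        new = theta - step
        cur = loss(new)
        for _ in range(30):
            if cur <= prev + 1e-15:
                break
            t /= 2.0
            new = theta - t * step
            cur = loss(new)
        theta = new
        if abs(prev - cur) < tol:
            prev = cur
            break
        prev = cur
    return theta[:p].copy(), float(theta[p])


@dataclass
class FitnessRecord:
    """Losses and size metrics for one candidate representation."""

    per_case_losses: np.ndarray
    balanced_loss: float
    complexity: float
    size: int

    def __post_init__(self) -> None:
        self.per_case_losses = np.asarray(self.per_case_losses, dtype=float)


@dataclass
class Model:
    """A representation plus its logistic layer and decision threshold."""

    representation: ex.Representation
    beta: np.ndarray
    intercept: float
    decision_threshold: float = 0.5
    feature_names: list[str] | None = None
    training_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        if self.beta.shape != (self.representation.p,):
            raise ValueError("beta length must equal representation dimensionality")
        if not (0 < self.decision_threshold < 1):
            raise ValueError("decision_threshold must lie in (0, 1)")

    # -- scoring ------------------------------------------------------------
    def _resolve_matrix(self, data) -> np.ndarray:
        if isinstance(data, Dataset):
            if self.feature_names is not None and data.feature_names != self.feature_names:
                missing = [n for n in self.feature_names if n not in data.feature_names]
                if missing:
                    raise SchemaError(f"scoring data lacks model features: {missing}")
                order = [data.feature_names.index(n) for n in self.feature_names]
                return data.X[:, order]
            return data.X
        return np.asarray(data, dtype=float)

    def decision_function(self, data) -> np.ndarray:
        X = self._resolve_matrix(data)
        Phi = ex.evaluate(self.representation, X)
        return Phi @ self.beta + self.intercept

    def predict_proba(self, data) -> np.ndarray:
        return sigmoid(self.decision_function(data))

    def predict(self, data) -> np.ndarray:
        return (self.predict_proba(data) >= self.decision_threshold).astype(int)

    @property
    def size(self) -> int:
        return ex.size(self.representation)

    def complexity(self, weights: dict[str, float] | None = None) -> float:
        return ex.complexity(self.representation, weights)

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "representation": ex.rep_to_dict(self.representation, self.feature_names),
            "feature_names": self.feature_names,
            "beta": self.beta.tolist(),
            "intercept": self.intercept,
            "decision_threshold": self.decision_threshold,
            "training_meta": self.training_meta,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Model":
        return cls(
            representation=ex.rep_from_dict(d["representation"]),
            beta=np.array(d["beta"], dtype=float),
            intercept=float(d["intercept"]),
            decision_threshold=float(d["decision_threshold"]),
            feature_names=d.get("feature_names"),
            training_meta=d.get("training_meta", {}),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "Model":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def fit_model(
    rep: ex.Representation,
    X: np.ndarray,
    y: np.ndarray,
    sample_weight: np.ndarray | None = None,
    ridge: float = 1e-6,
    operator_weights: dict[str, float] | None = None,
    feature_names: Sequence[str] | None = None,
) -> tuple[Model, FitnessRecord]:
    """Fit the logistic layer for one representation and score it on ``(X, y)``."""
    if sample_weight is None:
        sample_weight = class_weights(y)
    Phi = ex.evaluate(rep, X)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        beta, intercept = fit_logistic(Phi, y, sample_weight, ridge=ridge)
    probs = sigmoid(Phi @ beta + intercept)
    agg, per_case = balanced_log_loss(y, probs, sample_weight)
    record = FitnessRecord(
        per_case_losses=per_case,
        balanced_loss=agg,
        complexity=ex.complexity(rep, operator_weights),
        size=ex.size(rep),
    )
    model = Model(
        representation=rep,
        beta=beta,
        intercept=intercept,
        feature_names=list(feature_names) if feature_names is not None else None,
    )
    return model, record
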