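"""Final-model choice, multi-restart robust selection, and threshold calibration.

The search returns an archive of Pareto-efficient models; the deployed model
is the archive member with the lowest balanced log-loss on the internal
validation split.  Because the search is stochastic, a robust variant reruns
it several times, drops runs in the lowest quartile of validation average
precision, and keeps the smallest surviving model.  The decision threshold is
then calibrated so the positive-predictive value, re-weighted to an assumed
deployment prevalence, meets a clinical target.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .datasets import Dataset
from .exceptions import ConfigError, DegenerateDataError
from .logistic import Model, balanced_log_loss, class_weights


def validation_loss(model: Model, validation: Dataset) -> float:
    """Balanced log-loss of a model on a labeled validation set."""
    probs = model.predict_proba(validation)
    agg, _ = balanced_log_loss(validation.y, probs, class_weights(validation.y))
    return agg


def select_final(archive, validation: Dataset) -> Model:
    """Lowest validation balanced log-loss; ties broken by size, then
    complexity, then archive order."""
    members = list(archive.members) if hasattr(archive, "members") else list(archive)
    if not members:
        raise DegenerateDataError("cannot select from an empty archive")
    best, best_key = None, None
    for k, (model, record) in enumerate(members):
        key = (validation_loss(model, validation), record.size, record.complexity, k)
        if best_key is None or key < best_key:
            best, best_key = model, key
    return best


def robust_select(runs: list[tuple[Model, float]]) -> Model:
    """Pick among restart winners: drop the lowest validation-AUPRC quartile,
    then take the smallest model (ties: higher AUPRC, then first-run order).

    ``runs`` is a list of ``(model, validation AUPRC)`` pairs, one per restart.
    """
    if len(runs) < 2:
        raise ValueError("robust selection needs at least two runs")
    auprcs = np.array([a for _, a in runs], dtype=float)
    q25 = float(np.percentile(auprcs, 25))  # linear interpolation
    survivors = [(k, m, a) for k, (m, a) in enumerate(runs) if a >= q25]
    best = min(survivors, key=lambda t: (t[1].size, -t[2], t[0]))
    return best[1]


@dataclass
class ThresholdReport:
    threshold: float
    sensitivity: float
    specificity: float
    adjusted_ppv: float
    target_met: bool


def adjusted_ppv(sensitivity: float, specificity: float, prevalence: float) -> float:
    """PPV re-weighted to a deployment prevalence rho:
    se*rho / (se*rho + (1-sp)*(1-rho))."""
    num = sensitivity * prevalence
    den = num + (1.0 - specificity) * (1.0 - prevalence)
    return num / den if den > 0 else 0.0


def choose_threshold(
    scores: np.ndarray,
    labels: np.ndarray,
    target_ppv: float = 0.70,
    deployment_prevalence: float = 0.075,
) -> ThresholdReport:
    """Lowest score cut-point whose prevalence-adjusted PPV meets the target.

    Scanning cut-points from low to high trades specificity for sensitivity;
    taking the lowest qualifying threshold maximizes sensitivity subject to
    the PPV constraint.  If no cut-point qualifies, the threshold of maximal
    adjusted PPV is returned with a warning.
    """
    if not (0 < deployment_prevalence < 1):
        raise ConfigError("deployment_prevalence must lie in (0, 1)")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n1 = int(np.sum(labels == 1))
    n0 = int(np.sum(labels == 0))
    if n1 == 0 or n0 == 0:
        raise DegenerateDataError("threshold choice needs both classes present")

    cuts = np.unique(scores)
    best_fallback, best_fallback_ppv = None, -1.0
    for cut in cuts:
        pred = scores >= cut
        se = float(np.sum(pred & (labels == 1)) / n1)
        sp = float(np.sum(~pred & (labels == 0)) / n0)
        ppv = adjusted_ppv(se, sp, deployment_prevalence)
        if ppv >= target_ppv:
            return ThresholdReport(float(cut), se, sp, ppv, True)
        if ppv > best_fallback_ppv:
            best_fallback_ppv = ppv
            best_fallback = ThresholdReport(float(cut), se, sp, ppv, False)
    warnings.warn(
        f"no threshold reaches adjusted PPV {target_ppv}; "
        f"returning the maximizer ({best_fallback_ppv:.3f})",
        stacklevel=2,
    )
    return best_fallback
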