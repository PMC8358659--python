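"""Test-time coding and class assignment, plus evaluation helpers.

A new target-domain sample ``y`` is projected by the target block ``Mt``
(the stacked projection acts on concatenated-domain coordinates, so a
single target sample can only see its own block), ridge-coded against the
shared dictionary,

    alpha = (D^T D + mu I)^{-1} D^T Mt y,

and assigned to the class whose atoms reconstruct it best per coefficient
mass:

    label(y) = argmin_i ||Mt y - D phi_i(alpha)||^2 / ||phi_i(alpha)||^2,

where ``phi_i`` keeps only class-``i`` coefficients. Classes with zero
coefficient mass score +inf; ties go to the smallest class index.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
from scipy.linalg import solve

from .core import DASRCModel
from .domain import LabeledDomain
from .errors import InputError, UnclassifiableError

__all__ = [
    "Prediction",
    "code_sample",
    "classify",
    "classify_domain",
    "evaluate",
    "repeated_evaluate",
]


@dataclass
class Prediction:
    """One classified sample: label, per-class residual scores, code."""

    label: int
    per_class_score: np.ndarray
    code: np.ndarray


def _project_target(y: np.ndarray, model: DASRCModel) -> np.ndarray:
    y = np.asarray(y, dtype=float).ravel()
    Mt = model.projections.Mt
    if y.shape[0] != Mt.shape[1]:
        raise InputError(
            f"sample dimension {y.shape[0]} does not match the target-domain "
            f"dimension {Mt.shape[1]} the model was trained with"
        )
    return Mt @ y


def code_sample(y: np.ndarray, model: DASRCModel) -> np.ndarray:
    """Ridge code of one target-domain sample against the dictionary."""
    z = _project_target(y, model)
    D = model.dictionary.atoms
    mu = model.mu_test
    return solve(D.T @ D + mu * np.eye(model.dictionary.K), D.T @ z, assume_a="pos")


def classify(y: np.ndarray, model: DASRCModel) -> Prediction:
    """Assign one target-domain sample to the class with the smallest
    coefficient-normalized reconstruction residual."""
    z = _project_target(y, model)
    alpha = code_sample(y, model)
    D = model.dictionary.atoms
    atom_class = model.dictionary.atom_class
    scores = np.empty(model.C)
    for i, c in enumerate(model.classes):
        phi = np.where(atom_class == c, alpha, 0.0)
        mass = float(phi @ phi)
        if mass == 0.0:
            scores[i] = np.inf
        else:
            r = z - D @ phi
            scores[i] = float(r @ r) / mass
    if not np.any(np.isfinite(scores)):
        raise UnclassifiableError(
            "all class scores are +inf (zero coefficient mass in every class)"
        )
    # ties -> smallest class index (argmin returns the first minimum)
    return Prediction(int(model.classes[int(np.argmin(scores))]), scores, alpha)


def classify_domain(domain: LabeledDomain, model: DASRCModel) -> np.ndarray:
    """Predicted labels for every column of a feature matrix."""
    return np.array([classify(domain.X[:, j], model).label for j in range(domain.n)])


def evaluate(
    predictions: np.ndarray, truth: np.ndarray
) -> Tuple[float, dict, np.ndarray]:
    """Accuracy, per-class accuracy and confusion table.

    The confusion table is ``C x C`` over the sorted classes present in
    the truth labels, rows = truth, columns = prediction.
    """
    predictions = np.asarray(predictions, dtype=int).ravel()
    truth = np.asarray(truth, dtype=int).ravel()
    if predictions.size == 0 or predictions.size != truth.size:
        raise InputError("predictions and truth must be equal-length and nonempty")
    accuracy = float(np.mean(predictions == truth))
    classes = np.unique(truth)
    per_class = {
        int(c): float(np.mean(predictions[truth == c] == c)) for c in classes
    }
    lut = {int(c): i for i, c in enumerate(classes)}
    confusion = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(truth, predictions):
        if int(p) in lut:
            confusion[lut[int(t)], lut[int(p)]] += 1
    return accuracy, per_class, confusion


def repeated_evaluate(run_accuracies: Sequence[float]) -> Tuple[float, float]:
    """Mean and population-style std over repeated-run accuracies."""
    accs = np.asarray(list(run_accuracies), dtype=float)
    if accs.size == 0:
        raise InputError("no runs given")
    return float(accs.mean()), float(accs.std(ddof=0))
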