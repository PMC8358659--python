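"""Labeled feature-matrix container shared by every pipeline stage.

The in-memory convention is *samples as columns*: a domain with ``n``
samples of dimension ``d`` is a ``d x n`` matrix ``X`` plus a length-``n``
integer label vector. On disk (see :mod:`dasrc.io`) the transposed
row-sample layout is used, which is the ubiquitous interchange dialect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InputError

__all__ = ["LabeledDomain"]


@dataclass
class LabeledDomain:
    """A feature matrix (``d x n``, samples as columns) with integer labels.

    Parameters
    ----------
    X
        Real feature matrix of shape ``(d, n)``.
    labels
        Integer class labels of shape ``(n,)``.
    """

    X: np.ndarray
    labels: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise InputError(f"feature matrix must be 2-D, got shape {self.X.shape}")
        if not np.all(np.isfinite(self.X)):
            raise InputError("feature matrix contains non-finite values")
        if self.labels is None:
            raise InputError("labels are required")
        self.labels = np.asarray(self.labels, dtype=int).ravel()
        if self.labels.shape[0] != self.X.shape[1]:
            raise InputError(
                f"label count {self.labels.shape[0]} does not match "
                f"sample count {self.X.shape[1]}"
            )
        if self.labels.size == 0:
            raise InputError("domain has no samples")

    @property
    def d(self) -> int:
        """Feature dimension (rows)."""
        return self.X.shape[0]

    @property
    def n(self) -> int:
        """Sample count (columns)."""
        return self.X.shape[1]

    @property
    def classes(self) -> np.ndarray:
        """Sorted unique class labels present in this domain."""
        return np.unique(self.labels)

    def class_columns(self, c: int) -> np.ndarray:
        """Columns of ``X`` belonging to class ``c`` (``d x n_c``)."""
        return self.X[:, self.labels == c]
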