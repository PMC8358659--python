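"""Source-only baseline: same dictionary machinery, no adaptation.

Trains the PCA projection and per-class KSVD dictionary on the source
domain alone and applies them directly to target samples (which therefore
must share the source's feature dimension). Serves as the no-adaptation
reference the adapted model is compared against.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import solve

from .core import (
    ClassDictionary,
    HyperParams,
    ProjectionPair,
    _ksvd,
    _clip_atoms,
    pca_basis,
)
from .domain import LabeledDomain
from .errors import InputError

__all__ = ["source_only_src"]


def source_only_src(
    Ys: LabeledDomain, target: LabeledDomain, hp: HyperParams
) -> np.ndarray:
    """Predicted labels for ``target`` from a source-only ridge-SRC model.

    The projection is the source's top-``hp.p`` principal axes; the
    dictionary is a per-class KSVD fit of the projected source samples;
    classification uses the same ridge coding and residual-ratio rule as
    the adapted model.
    """
    if target.d != Ys.d:
        raise InputError(
            f"source-only baseline needs matching dimensions, got "
            f"d_s={Ys.d}, d_t={target.d}"
        )
    M = pca_basis(Ys.X, hp.p)
    classes = Ys.classes
    K_c = hp.K_c if hp.K_c is not None else max(1, round(80 / len(classes)))
    rng = np.random.default_rng(hp.seed)
    P = M @ Ys.X
    atoms, atom_class = [], []
    for c in classes:
        Xc = P[:, Ys.labels == c]
        Dc = _ksvd(Xc, K_c, hp.l0, hp.ksvd_iters, rng)
        atoms.append(Dc)
        atom_class.extend([c] * K_c)
    D = _clip_atoms(ClassDictionary(np.hstack(atoms), np.array(atom_class)))
    G = D.atoms.T @ D.atoms + hp.mu * np.eye(D.K)
    A = solve(G, D.atoms.T @ (M @ target.X), assume_a="pos")
    preds = np.empty(target.n, dtype=int)
    for j in range(target.n):
        z = M @ target.X[:, j]
        scores = []
        for c in classes:
            phi = np.where(D.atom_class == c, A[:, j], 0.0)
            mass = float(phi @ phi)
            if mass == 0:
                scores.append(np.inf)
            else:
                r = z - D.atoms @ phi
                scores.append(float(r @ r) / mass)
        preds[j] = classes[int(np.argmin(scores))]
    return preds
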