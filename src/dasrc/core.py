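"""Joint subspace + shared-dictionary learning for domain adaptation.

The model learns one projection per domain (``Ms``: p x d_s, ``Mt``:
p x d_t, stacked as ``M = [Ms, Mt]`` with orthonormal rows) and one
class-partitioned dictionary ``D`` (p x K) living in the shared
p-dimensional subspace, by minimizing

    ||M Y - D Theta||_F^2 / ||M Y - D Delta||_F^2
        + Tr( M Y (L - alpha I) Y^T M^T ),        s.t.  M M^T = I,

where ``Y`` is the block-diagonal stack of both domains' samples, ``L``
the block-diagonal graph Laplacian (k-NN graph on the source, same-class
graph on the target), ``Theta``/``Delta`` the same-class / other-class
selector splits of the ridge sparse codes, and ``alpha`` weighs the PCA
(variance-preserving) criterion against locality. The ratio is a Fisher
criterion on reconstruction errors: same-class atoms should reconstruct a
sample well, other-class atoms badly.

Optimization alternates closed-form updates of the Lagrangian

    F(M, D, beta, gamma) = ||M Y - D Theta||^2 + Tr(M Y (L - alpha I) Y^T M^T)
                           - beta ||M Y - D Delta||^2 - gamma (Tr(M M^T) - p)

with multiplier updates for ``beta`` (Dinkelbach rule by default) and
``gamma``, followed by an SVD retraction of ``M`` onto the orthonormal-row
manifold. See :func:`fit`.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from typing import List, Optional, Tuple

import numpy as np
from scipy.linalg import block_diag, solve
from sklearn.linear_model import orthogonal_mp

from .domain import LabeledDomain
from .errors import (
    ConfigError,
    DegenerateStateError,
    InputError,
    OptimizationError,
)
from .graphs import AUTO, knn_source_graph, laplacian, target_label_graph

__all__ = [
    "HyperParams",
    "ProjectionPair",
    "ClassDictionary",
    "SparseCodes",
    "TrainLog",
    "DASRCModel",
    "FitState",
    "pca_basis",
    "retract_rows",
    "init_projections",
    "init_dictionary",
    "sparse_code",
    "build_selectors",
    "objective",
    "lagrangian_value",
    "solve_projection",
    "solve_dictionary",
    "beta_upper_bound",
    "update_projection",
    "update_dictionary",
    "update_beta",
    "update_gamma",
    "fit",
]

_COND_LIMIT = 1e12
_JITTER = 1e-8


# --------------------------------------------------------------------------
# containers


@dataclass
class HyperParams:
    """Hyperparameters of the model and its optimizer.

    Parameters
    ----------
    p
        Shared subspace dimension. The paper-scale suggestion is 60; it
        must not exceed ``min(d_s, d_t, n_s - 1)``.
    K_c
        Atoms per class. ``None`` derives ``round(80 / C)`` so the total
        dictionary size is near the paper-scale suggestion of 80.
    k_nn, sigma
        Source-graph neighbour count and Gaussian bandwidth
        (``"auto"`` = median of pairwise squared distances).
    alpha
        Weight of the variance-preserving (PCA) criterion inside the
        trace term.
    mu
        Ridge penalty of the sparse-coding rule, shared between training
        and test coding unless ``mu_test`` is set.
    beta0, gamma0, lambda_beta, lambda_gamma
        Initial multipliers and their step sizes. With the default SVD
        retraction the orthogonality violation is ~1e-15, so ``gamma``
        stays at ``gamma0`` and acts as a small ridge in the projection
        update.
    beta_rule
        ``"dinkelbach"`` (beta = current Fisher ratio; default) or
        ``"paper"`` (first-order multiplier step).
    coding
        ``"ridge"`` (closed form, default) or ``"omp"`` (l0-greedy).
    ortho
        ``"joint"`` retracts the stacked ``[Ms, Mt]`` to orthonormal rows
        (the constraint the simplified objective carries); ``"block"``
        retracts each domain block separately.
    """

    p: int = 60
    K_c: Optional[int] = None
    k_nn: int = 5
    sigma: float | str = AUTO
    alpha: float = 1.0
    mu: float = 0.01
    mu_test: Optional[float] = None
    beta0: float = 0.0
    gamma0: float = 1e-3
    lambda_beta: float = 0.1
    lambda_gamma: float = 0.0
    beta_rule: str = "dinkelbach"
    coding: str = "ridge"
    ortho: str = "joint"
    l0: int = 5
    ksvd_iters: int = 10
    max_iter: int = 40
    tol: float = 1e-5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.p < 1:
            raise ConfigError("p must be >= 1")
        if self.alpha < 0:
            raise ConfigError("alpha must be >= 0")
        if self.mu <= 0:
            raise ConfigError("mu must be > 0")
        if self.max_iter < 1:
            raise ConfigError("max_iter must be >= 1")
        if self.beta_rule not in ("dinkelbach", "paper"):
            raise ConfigError(f"unknown beta_rule {self.beta_rule!r}")
        if self.coding not in ("ridge", "omp"):
            raise ConfigError(f"unknown coding {self.coding!r}")
        if self.ortho not in ("joint", "block"):
            raise ConfigError(f"unknown ortho {self.ortho!r}")


def benchmark_hyperparams(**overrides) -> HyperParams:
    """Preset for the default synthetic benchmark (ambient dimension 20),
    selected by the same small grid search over subspace dimension and
    atoms per class that the method prescribes at paper scale:
    p = 12, 4 atoms per class, alpha = 2, mu = 0.01 with a slightly
    stronger test-time ridge (0.1)."""
    kw = dict(p=12, K_c=4, alpha=2.0, mu=0.01, mu_test=0.1)
    kw.update(overrides)
    return HyperParams(**kw)


@dataclass
class ProjectionPair:
    """Per-domain projections ``Ms`` (p x d_s) and ``Mt`` (p x d_t)."""

    Ms: np.ndarray
    Mt: np.ndarray

    @property
    def p(self) -> int:
        return self.Ms.shape[0]

    @property
    def M(self) -> np.ndarray:
        """The stacked projection ``[Ms, Mt]`` of shape (p, d_s + d_t)."""
        return np.hstack([self.Ms, self.Mt])

    def orthogonality_violation(self) -> float:
        M = self.M
        return float(np.linalg.norm(M @ M.T - np.eye(self.p)))


@dataclass
class ClassDictionary:
    """Shared dictionary: atoms (p x K) with an atom -> class map."""

    atoms: np.ndarray
    atom_class: np.ndarray

    def __post_init__(self) -> None:
        self.atoms = np.asarray(self.atoms, dtype=float)
        self.atom_class = np.asarray(self.atom_class, dtype=int).ravel()
        if self.atoms.shape[1] != self.atom_class.shape[0]:
            raise InputError("atom_class length must match atom count")

    @property
    def K(self) -> int:
        return self.atoms.shape[1]

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.atom_class)

    def class_atoms(self, c: int) -> np.ndarray:
        return self.atoms[:, self.atom_class == c]

    def max_atom_norm(self) -> float:
        return float(np.max(np.linalg.norm(self.atoms, axis=0)))


@dataclass
class SparseCodes:
    """Coefficient matrix A (K x n) with its selector split."""

    A: np.ndarray
    Theta: np.ndarray
    Delta: np.ndarray


@dataclass
class IterationRecord:
    iteration: int
    objective: float
    fisher_num: float
    fisher_den: float
    trace_term: float
    beta: float
    gamma: float
    ortho_violation: float
    max_atom_norm: float
    accepted: bool = True


@dataclass
class TrainLog:
    records: List[IterationRecord] = field(default_factory=list)

    def objectives(self) -> np.ndarray:
        return np.array([r.objective for r in self.records])

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class DASRCModel:
    """A trained model: projections + dictionary + settings + log."""

    projections: ProjectionPair
    dictionary: ClassDictionary
    hyper: HyperParams
    log: TrainLog
    classes: np.ndarray

    @property
    def C(self) -> int:
        return len(self.classes)

    @property
    def mu_test(self) -> float:
        return self.hyper.mu if self.hyper.mu_test is None else self.hyper.mu_test


# --------------------------------------------------------------------------
# initialization


def pca_basis(X: np.ndarray, p: int) -> np.ndarray:
    """Top-``p`` principal axes of the columns of ``X`` as rows (p x d).

    Axes are eigenvectors of the mean-centered covariance, ordered by
    decreasing variance; the sign of each axis is fixed so its largest
    component is positive. When ``p`` exceeds the data rank, the trailing
    axes are an (orthonormal, deterministic) completion of the basis.
    """
    X = np.asarray(X, dtype=float)
    d, n = X.shape
    if p > d:
        raise InputError(f"p={p} exceeds the feature dimension d={d}")
    Xc = X - X.mean(axis=1, keepdims=True)
    U, _, _ = np.linalg.svd(Xc, full_matrices=True)
    B = U[:, :p].T
    flip = np.sign(B[np.arange(p), np.argmax(np.abs(B), axis=1)])
    flip[flip == 0] = 1.0
    return B * flip[:, None]


def retract_rows(M: np.ndarray) -> np.ndarray:
    """Nearest matrix with orthonormal rows (polar/SVD retraction)."""
    U, _, Vt = np.linalg.svd(M, full_matrices=False)
    return U @ Vt


def init_projections(Ys: LabeledDomain, Yt: LabeledDomain, p: int) -> ProjectionPair:
    """PCA initialization of both projections, then joint retraction.

    Each block starts as the domain's top-``p`` principal axes (row
    orthonormal); the stacked ``[Ms, Mt]`` is then retracted so the joint
    constraint ``M M^T = I`` holds (which rescales the blocks by 1/sqrt(2)).
    """
    limits = {"d_s": Ys.d, "d_t": Yt.d, "n_s - 1": Ys.n - 1}
    for name, lim in limits.items():
        if p > lim:
            raise InputError(f"p={p} exceeds {name}={lim}")
    M = retract_rows(np.hstack([pca_basis(Ys.X, p), pca_basis(Yt.X, p)]))
    return ProjectionPair(M[:, : Ys.d], M[:, Ys.d :])


def _ksvd(X: np.ndarray, K: int, l0: int, n_iter: int, rng: np.random.Generator) -> np.ndarray:
    """Small KSVD run (OMP coding + rank-1 atom updates) returning p x K atoms."""
    p, n = X.shape
    idx = rng.choice(n, size=K, replace=n < K)
    D = X[:, idx].astype(float).copy()
    for k in range(K):
        nrm = np.linalg.norm(D[:, k])
        if nrm < 1e-12:
            D[:, k] = rng.standard_normal(p)
            nrm = np.linalg.norm(D[:, k])
        D[:, k] /= nrm
    n_nonzero = max(1, min(l0, K))
    for _ in range(n_iter):
        with warnings.catch_warnings():
            # small same-class blocks are often linearly dependent; OMP
            # stopping early there is expected, not actionable
            warnings.simplefilter("ignore", RuntimeWarning)
            A = np.atleast_2d(orthogonal_mp(D, X, n_nonzero_coefs=n_nonzero))
        if A.shape != (K, n):
            A = A.reshape(K, n)
        for k in range(K):
            users = np.flatnonzero(A[k, :])
            if users.size == 0:
                # dead atom: replace by the worst-represented sample
                resid = X - D @ A
                j = int(np.argmax(np.sum(resid**2, axis=0)))
                nrm = np.linalg.norm(X[:, j])
                D[:, k] = X[:, j] / nrm if nrm > 1e-12 else rng.standard_normal(p)
                D[:, k] /= np.linalg.norm(D[:, k])
                continue
            E = X[:, users] - D @ A[:, users] + np.outer(D[:, k], A[k, users])
            U, s, Vt = np.linalg.svd(E, full_matrices=False)
            D[:, k] = U[:, 0]
            A[k, users] = s[0] * Vt[0, :]
    return D


def init_dictionary(
    Ys: LabeledDomain,
    Yt: LabeledDomain,
    proj: ProjectionPair,
    K_c: int,
    seed: int = 0,
    l0: int = 5,
    n_iter: int = 10,
) -> ClassDictionary:
    """Per-class KSVD initialization of the shared dictionary.

    For each class, ``K_c`` atoms are fitted to that class's projected
    samples pooled across both domains. Classes with fewer than ``K_c``
    samples are padded with perturbed duplicates (warned). Atom signs are
    fixed so each atom correlates nonnegatively with its class mean, and
    norms are clipped to <= 1.
    """
    if K_c < 1:
        raise InputError("K_c must be >= 1")
    rng = np.random.default_rng(seed)
    P = np.hstack([proj.Ms @ Ys.X, proj.Mt @ Yt.X])
    labels = np.concatenate([Ys.labels, Yt.labels])
    classes = np.unique(labels)
    atoms, atom_class = [], []
    for c in classes:
        Xc = P[:, labels == c]
        if Xc.shape[1] == 0:
            raise InputError(f"class {c} has no samples")
        if Xc.shape[1] < K_c:
            warnings.warn(
                f"class {c} has {Xc.shape[1]} samples < K_c={K_c}; padding "
                "with perturbed duplicates",
                RuntimeWarning,
                stacklevel=2,
            )
            reps = -(-K_c // Xc.shape[1])
            Xc = np.tile(Xc, reps)[:, :K_c]
            Xc = Xc + 1e-6 * rng.standard_normal(Xc.shape)
        Dc = _ksvd(Xc, K_c, l0, n_iter, rng)
        mean_c = Xc.mean(axis=1)
        sign = np.sign(Dc.T @ mean_c)
        sign[sign == 0] = 1.0
        Dc = Dc * sign[None, :]
        atoms.append(Dc)
        atom_class.extend([c] * K_c)
    return _clip_atoms(ClassDictionary(np.hstack(atoms), np.array(atom_class)))


def _clip_atoms(D: ClassDictionary) -> ClassDictionary:
    norms = np.linalg.norm(D.atoms, axis=0)
    over = norms > 1.0
    if np.any(over):
        D.atoms[:, over] /= norms[over]
    return D


# --------------------------------------------------------------------------
# coding, selectors, objective


def sparse_code(X_proj: np.ndarray, D: ClassDictionary, mu: float) -> np.ndarray:
    """Ridge codes ``A = (D^T D + mu I)^{-1} D^T X`` (K x n), columnwise."""
    if mu <= 0:
        raise ConfigError("mu must be > 0")
    At = D.atoms
    G = At.T @ At + mu * np.eye(D.K)
    return solve(G, At.T @ np.atleast_2d(X_proj), assume_a="pos")


def omp_code(X_proj: np.ndarray, D: ClassDictionary, l0: int) -> np.ndarray:
    """Greedy l0 codes via orthogonal matching pursuit (K x n)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        A = np.atleast_2d(
            orthogonal_mp(
                D.atoms, np.atleast_2d(X_proj), n_nonzero_coefs=max(1, min(l0, D.K))
            )
        )
    n = np.atleast_2d(X_proj).shape[1]
    return A.reshape(D.K, n)


def build_selectors(
    A: np.ndarray, labels: np.ndarray, atom_class: np.ndarray
) -> Tuple[np.ndarray, np.ndarray]:
    """Split codes into same-class (Theta) and other-class (Delta) parts.

    Column ``j`` of Theta keeps the entries of ``A[:, j]`` at atoms of
    the sample's class and zeros elsewhere; Delta keeps the complement,
    so ``Theta + Delta == A`` exactly.
    """
    A = np.atleast_2d(A)
    labels = np.asarray(labels, dtype=int).ravel()
    atom_class = np.asarray(atom_class, dtype=int).ravel()
    if labels.shape[0] != A.shape[1]:
        raise InputError("labels must align with code columns")
    missing = set(labels) - set(atom_class)
    if missing:
        raise InputError(f"labels {sorted(missing)} own no dictionary atoms")
    mask = atom_class[:, None] == labels[None, :]
    Theta = np.where(mask, A, 0.0)
    Delta = np.where(mask, 0.0, A)
    return Theta, Delta


def objective(
    M: np.ndarray,
    D: np.ndarray,
    Theta: np.ndarray,
    Delta: np.ndarray,
    Ytil: np.ndarray,
    Ltil: np.ndarray,
    alpha: float,
) -> Tuple[float, float, float, float]:
    """Evaluate the ratio-plus-trace objective.

    Returns ``(total, fisher_num, fisher_den, trace_term)`` where
    ``total = fisher_num / fisher_den + trace_term`` and the trace term is
    ``Tr(M Y (L - alpha I) Y^T M^T)``.
    """
    PY = M @ Ytil
    num = float(np.sum((PY - D @ Theta) ** 2))
    den = float(np.sum((PY - D @ Delta) ** 2))
    if den <= 0:
        raise DegenerateStateError("Fisher denominator is zero")
    trace_term = float(np.sum((PY @ Ltil) * PY) - alpha * np.sum(PY**2))
    return num / den + trace_term, num, den, trace_term


def lagrangian_value(
    M: np.ndarray,
    D: np.ndarray,
    Theta: np.ndarray,
    Delta: np.ndarray,
    Ytil: np.ndarray,
    Ltil: np.ndarray,
    alpha: float,
    beta: float,
    gamma: float,
) -> float:
    """The scalar Lagrangian: num + trace - beta*den - gamma*(Tr(MM^T) - p)."""
    PY = M @ Ytil
    num = float(np.sum((PY - D @ Theta) ** 2))
    den = float(np.sum((PY - D @ Delta) ** 2))
    trace_term = float(np.sum((PY @ Ltil) * PY) - alpha * np.sum(PY**2))
    ortho = float(np.trace(M @ M.T) - M.shape[0])
    return num + trace_term - beta * den - gamma * ortho


def _solve_regularized(S: np.ndarray, R: np.ndarray, what: str) -> np.ndarray:
    """Solve X S = R for X with diagonal jitter past condition 1e12."""
    S = (S + S.T) / 2.0
    if np.linalg.cond(S) > _COND_LIMIT:
        warnings.warn(
            f"{what} system condition number exceeds {_COND_LIMIT:.0e}; "
            f"adding {_JITTER:.0e} diagonal jitter",
            RuntimeWarning,
            stacklevel=3,
        )
        S = S + _JITTER * np.eye(S.shape[0])
    try:
        return solve(S, R.T, assume_a="sym").T
    except np.linalg.LinAlgError as exc:  # pragma: no cover - pathological
        raise OptimizationError(f"singular {what} system after regularization") from exc


def solve_projection(
    D: np.ndarray,
    Theta: np.ndarray,
    Delta: np.ndarray,
    Ytil: np.ndarray,
    Ltil: np.ndarray,
    alpha: float,
    beta: float,
    gamma: float,
) -> Optional[np.ndarray]:
    """Closed-form (pre-retraction) stationary point of the Lagrangian in M:

        M = D (Theta - beta Delta) Y^T
            (Y Y^T + Y (L - alpha I) Y^T - beta Y Y^T - gamma I)^{-1}.

    Returns ``None`` when the numerator vanishes (e.g. D = 0, beta = 0), in
    which case the caller keeps the previous projection.
    """
    n = Ytil.shape[1]
    N = D @ (Theta - beta * Delta) @ Ytil.T
    if not np.any(N):
        return None
    YYt = Ytil @ Ytil.T
    S = (1.0 - beta) * YYt + Ytil @ (Ltil - alpha * np.eye(n)) @ Ytil.T
    S = S - gamma * np.eye(S.shape[0])
    return _solve_regularized(S, N, "projection update")


def solve_dictionary(
    M: np.ndarray,
    Ytil: np.ndarray,
    Theta: np.ndarray,
    Delta: np.ndarray,
    beta: float,
) -> np.ndarray:
    """Closed-form stationary point of the Lagrangian in D:

        D = M Y (Theta - beta Delta)^T (Theta Theta^T - beta Delta Delta^T)^{-1}.

    With beta = 0 this is the ordinary least-squares reconstruction
    dictionary ``M Y Theta^T (Theta Theta^T)^{-1}``. Atom-norm clipping is
    applied by :func:`update_dictionary`, not here.
    """
    B = Theta @ Theta.T - beta * Delta @ Delta.T
    R = M @ Ytil @ (Theta - beta * Delta).T
    return _solve_regularized(B, R, "dictionary update")


def beta_upper_bound(Theta: np.ndarray, Delta: np.ndarray) -> float:
    """Largest beta keeping ``Theta Theta^T - beta Delta Delta^T`` positive
    definite, with a 1% safety margin: 0.99 * lam_min / lam_max."""
    lam_min = max(float(np.linalg.eigvalsh(Theta @ Theta.T)[0]), 0.0)
    lam_max = float(np.linalg.eigvalsh(Delta @ Delta.T)[-1])
    if lam_max <= 0:
        return np.inf
    return 0.99 * lam_min / lam_max


# --------------------------------------------------------------------------
# alternating optimization


@dataclass
class FitState:
    """Mutable optimization state threaded through the block updates."""

    Ytil: np.ndarray
    Ltil: np.ndarray
    labels: np.ndarray
    atom_class: np.ndarray
    d_s: int
    M: np.ndarray
    D: np.ndarray
    codes: Optional[SparseCodes]
    beta: float
    gamma: float
    hp: HyperParams

    def split_projection(self) -> ProjectionPair:
        return ProjectionPair(self.M[:, : self.d_s], self.M[:, self.d_s :])

    def dictionary(self) -> ClassDictionary:
        return ClassDictionary(self.D.copy(), self.atom_class.copy())

    def refresh_codes(self) -> SparseCodes:
        """(Re)code all samples against the current M and D."""
        Xp = self.M @ self.Ytil
        D = ClassDictionary(self.D, self.atom_class)
        if self.hp.coding == "omp":
            A = omp_code(Xp, D, self.hp.l0)
        else:
            A = sparse_code(Xp, D, self.hp.mu)
        Theta, Delta = build_selectors(A, self.labels, self.atom_class)
        self.codes = SparseCodes(A, Theta, Delta)
        return self.codes

    def objective(self) -> Tuple[float, float, float, float]:
        c = self.codes
        return objective(
            self.M, self.D, c.Theta, c.Delta, self.Ytil, self.Ltil, self.hp.alpha
        )


def _retract_state(M: np.ndarray, d_s: int, mode: str) -> np.ndarray:
    if mode == "block":
        return np.hstack([retract_rows(M[:, :d_s]), retract_rows(M[:, d_s:])])
    return retract_rows(M)


def update_projection(state: FitState) -> ProjectionPair:
    """Closed-form projection update followed by orthonormal retraction."""
    c = state.codes
    M_pre = solve_projection(
        state.D, c.Theta, c.Delta, state.Ytil, state.Ltil,
        state.hp.alpha, state.beta, state.gamma,
    )
    if M_pre is None:
        warnings.warn(
            "projection update numerator is zero; keeping previous projection",
            RuntimeWarning,
            stacklevel=2,
        )
        return state.split_projection()
    state.M = _retract_state(M_pre, state.d_s, state.hp.ortho)
    return state.split_projection()


def update_dictionary(state: FitState) -> ClassDictionary:
    """Closed-form dictionary update with atom-norm clipping.

    If the quadratic system is indefinite (the difference objective would
    be unbounded), beta is clamped to its positive-definite bound and the
    solve retried once.
    """
    c = state.codes
    B = c.Theta @ c.Theta.T - state.beta * c.Delta @ c.Delta.T
    if np.linalg.eigvalsh((B + B.T) / 2.0)[0] <= 0:
        bound = beta_upper_bound(c.Theta, c.Delta)
        clamped = float(np.clip(state.beta, 0.0, bound))
        warnings.warn(
            f"indefinite dictionary system; clamping beta {state.beta:.3g} -> "
            f"{clamped:.3g}",
            RuntimeWarning,
            stacklevel=2,
        )
        state.beta = clamped
        B = c.Theta @ c.Theta.T - state.beta * c.Delta @ c.Delta.T
        if np.linalg.eigvalsh((B + B.T) / 2.0)[0] <= -_JITTER:
            raise OptimizationError("dictionary system indefinite even after beta clamp")
    D_new = solve_dictionary(state.M, state.Ytil, c.Theta, c.Delta, state.beta)
    norms = np.linalg.norm(D_new, axis=0)
    over = norms > 1.0
    if np.any(over):
        D_new[:, over] /= norms[over]
    state.D = D_new
    return state.dictionary()


def update_beta(state: FitState) -> float:
    """Multiplier update for the Fisher ratio.

    ``dinkelbach``: beta <- num/den (the fixed point of fractional
    programming). ``paper``: beta <- beta + lambda_beta * F / F'(beta)
    with ``F'(beta) = -den``. Either way the result is clamped to keep
    the dictionary system positive definite.
    """
    c = state.codes
    _, num, den, _ = state.objective()
    if state.hp.beta_rule == "dinkelbach":
        beta = num / den
    else:
        F = lagrangian_value(
            state.M, state.D, c.Theta, c.Delta, state.Ytil, state.Ltil,
            state.hp.alpha, state.beta, state.gamma,
        )
        beta = state.beta + state.hp.lambda_beta * F / (-den)
    state.beta = float(np.clip(beta, 0.0, beta_upper_bound(c.Theta, c.Delta)))
    return state.beta


def update_gamma(state: FitState) -> float:
    """Scalar surrogate of the orthogonality-multiplier step.

    The printed update divides by the matrix ``I - M M^T``; the surrogate
    uses its trace, and is skipped when the violation is below 1e-10 —
    which after the SVD retraction it always is, leaving gamma as a fixed
    small ridge.
    """
    viol = float(state.M.shape[0] - np.sum(state.M**2))
    if abs(viol) <= 1e-10 or state.hp.lambda_gamma == 0.0:
        return state.gamma
    c = state.codes
    F = lagrangian_value(
        state.M, state.D, c.Theta, c.Delta, state.Ytil, state.Ltil,
        state.hp.alpha, state.beta, state.gamma,
    )
    state.gamma = float(state.gamma + state.hp.lambda_gamma * F / viol)
    return state.gamma


def _build_state(Ys: LabeledDomain, Yt: LabeledDomain, hp: HyperParams) -> FitState:
    classes = np.unique(np.concatenate([Ys.labels, Yt.labels]))
    C = len(classes)
    K_c = hp.K_c if hp.K_c is not None else max(1, round(80 / C))
    Ls = laplacian(knn_source_graph(Ys, hp.k_nn, hp.sigma))
    Lt = laplacian(target_label_graph(Yt.labels))
    Ytil = block_diag(Ys.X, Yt.X)
    Ltil = block_diag(Ls.matrix, Lt.matrix)
    proj = init_projections(Ys, Yt, hp.p)
    D0 = init_dictionary(Ys, Yt, proj, K_c, seed=hp.seed, l0=hp.l0, n_iter=hp.ksvd_iters)
    state = FitState(
        Ytil=Ytil,
        Ltil=Ltil,
        labels=np.concatenate([Ys.labels, Yt.labels]),
        atom_class=D0.atom_class,
        d_s=Ys.d,
        M=proj.M,
        D=D0.atoms,
        codes=None,
        beta=hp.beta0,
        gamma=hp.gamma0,
        hp=hp,
    )
    state.refresh_codes()
    return state


def fit(Ys: LabeledDomain, Yt: LabeledDomain, hp: Optional[HyperParams] = None) -> DASRCModel:
    """Alternating optimization of projections and dictionary.

    Each iteration codes all samples against the current dictionary,
    splits the codes with the class selectors, then applies the
    closed-form updates of M (with retraction), D (with atom clipping),
    beta and gamma. The run stops when the relative objective change
    drops below ``hp.tol``, when ``hp.max_iter`` is reached, or when an
    iteration fails to improve the objective (that iteration is rolled
    back — a monotonicity safeguard, since the closed forms optimize the
    Lagrangian rather than the ratio objective directly). Fully
    deterministic given ``hp.seed``.
    """
    hp = hp if hp is not None else HyperParams()
    state = _build_state(Ys, Yt, hp)
    log = TrainLog()
    obj_prev = state.objective()[0]
    for it in range(1, hp.max_iter + 1):
        M_old, D_old = state.M.copy(), state.D.copy()
        beta_old, gamma_old = state.beta, state.gamma
        state.refresh_codes()
        update_projection(state)
        update_dictionary(state)
        update_beta(state)
        update_gamma(state)
        state.refresh_codes()
        total, num, den, tr = state.objective()
        if not np.isfinite(total):
            raise OptimizationError(
                f"objective became non-finite at iteration {it}: "
                f"num={num}, den={den}, trace={tr}"
            )
        accepted = total <= obj_prev + 1e-9
        if not accepted:
            state.M, state.D = M_old, D_old
            state.beta, state.gamma = beta_old, gamma_old
            state.refresh_codes()
            total, num, den, tr = state.objective()
        viol = float(np.linalg.norm(state.M @ state.M.T - np.eye(hp.p)))
        atom_norm = float(np.max(np.linalg.norm(state.D, axis=0)))
        log.records.append(
            IterationRecord(
                it, total, num, den, tr, state.beta, state.gamma, viol, atom_norm, accepted
            )
        )
        if not accepted:
            break
        if abs(obj_prev - total) <= hp.tol * max(1.0, abs(obj_prev)):
            break
        obj_prev = total
    return DASRCModel(
        projections=state.split_projection(),
        dictionary=state.dictionary(),
        hyper=hp,
        log=log,
        classes=np.unique(np.concatenate([Ys.labels, Yt.labels])),
    )
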