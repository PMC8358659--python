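"""Shared builders for optimization-state tests."""

import numpy as np
from scipy.linalg import block_diag

from dasrc import LabeledDomain, knn_source_graph, laplacian, target_label_graph
from dasrc.core import FitState, HyperParams, retract_rows, sparse_code, ClassDictionary


def make_random_state(
    seed: int,
    p: int = 4,
    d: int = 8,
    n: int = 30,
    C: int = 3,
    K_c: int = 2,
    beta: float | None = None,
    alpha: float = 0.5,
    gamma: float = 1e-3,
    mu: float = 0.01,
) -> FitState:
    """A random but internally consistent optimization state.

    Both domains get ``n`` samples of dimension ``d`` with balanced labels
    1..C; M has orthonormal rows, atoms have norm <= 1, codes are fresh
    ridge codes. ``beta=None`` picks a small value safely inside the
    positive-definiteness bound of the dictionary system.
    """
    rng = np.random.default_rng(seed)
    labels = np.tile(np.arange(1, C + 1), n // C + 1)[:n]
    Ys = LabeledDomain(rng.standard_normal((d, n)) + labels[None, :], labels)
    Yt = LabeledDomain(rng.standard_normal((d, n)) - labels[None, :], labels)
    Ls = laplacian(knn_source_graph(Ys, k=3, sigma=1.0)).matrix
    Lt = laplacian(target_label_graph(Yt.labels)).matrix
    Ytil = block_diag(Ys.X, Yt.X)
    Ltil = block_diag(Ls, Lt)
    M = retract_rows(rng.standard_normal((p, 2 * d)))
    K = C * K_c
    D = rng.standard_normal((p, K))
    D /= np.maximum(np.linalg.norm(D, axis=0), 1.0)
    atom_class = np.repeat(np.arange(1, C + 1), K_c)
    hp = HyperParams(p=p, K_c=K_c, alpha=alpha, mu=mu, seed=seed)
    state = FitState(
        Ytil=Ytil,
        Ltil=Ltil,
        labels=np.concatenate([Ys.labels, Yt.labels]),
        atom_class=atom_class,
        d_s=d,
        M=M,
        D=D,
        codes=None,
        beta=0.0,
        gamma=gamma,
        hp=hp,
    )
    state.refresh_codes()
    if beta is None:
        from dasrc.core import beta_upper_bound

        bound = beta_upper_bound(state.codes.Theta, state.codes.Delta)
        beta = 0.5 * bound if np.isfinite(bound) else 0.1
    state.beta = float(beta)
    return state


def numerical_gradient(f, X: np.ndarray, h: float = 1e-4) -> np.ndarray:
    """Central-difference gradient of a scalar function of a matrix."""
    G = np.zeros_like(X)
    it = np.nditer(X, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        Xp, Xm = X.copy(), X.copy()
        Xp[idx] += h
        Xm[idx] -= h
        G[idx] = (f(Xp) - f(Xm)) / (2 * h)
    return G
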