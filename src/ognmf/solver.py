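"""Masked non-negative matrix factorization with an orthogonality-promoting step.

The model approximates a non-negative target matrix ``X`` (patients x
features) by a low-rank product ``U V`` with ``U >= 0`` (patients x k) and
``V >= 0`` (k x features), minimizing the masked Frobenius objective

    f(U, V) = 1/2 * sum_{ij : M_ij = 1} (X_ij - (U V)_ij)^2 ,

so that unobserved cells (``M_ij = 0``) contribute nothing and the fitted
product imputes them.  The solver runs masked Lee-Seung multiplicative
updates, with the gradient of an orthogonality penalty
``lambda/2 * ||U'U - I||_F^2`` on the patient factors folded into the
U-update denominator; at ``lambda = 0`` it reduces to plain masked NMF, for
which each update step never increases the objective.  Iterations stop once
the relative objective change (the *step error*) drops below the
convergence tolerance ``epsilon``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SolverConfig",
    "TraceLog",
    "Factorization",
    "masked_objective",
    "update_step",
    "step_error",
    "fit_ognmf",
    "impute",
]

#: Guard for divisions and relative changes.
DELTA = 1e-12


@dataclass(frozen=True)
class SolverConfig:
    """Solver hyper-parameters.

    k
        Latent rank; default 4, one dimension per risk level.
    epsilon
        Convergence tolerance on the relative objective change.
    max_iter
        Iteration cap; hitting it flags non-convergence but is not fatal.
    ortho_weight
        Weight ``lambda`` of the orthogonality penalty on U; 0 disables it.
    init
        ``"random"`` (seeded half-normal) or ``"nndsvd"``.
    store_factors
        Keep a per-iteration snapshot of (U, V) in the trace; needed for
        accuracy-versus-iteration diagnostics, off by default.
    """

    k: int = 4
    epsilon: float = 1e-5
    max_iter: int = 500
    ortho_weight: float = 0.1
    seed: int = 0
    init: str = "random"
    store_factors: bool = False

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("rank k must be >= 1")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.ortho_weight < 0:
            raise ValueError("ortho_weight must be >= 0")
        if self.init not in ("random", "nndsvd"):
            raise ValueError(f"unknown init scheme {self.init!r}")


@dataclass
class TraceLog:
    """Per-iteration objective values and step errors."""

    objective: list[float] = field(default_factory=list)
    step: list[float] = field(default_factory=list)
    snapshots: list[tuple[np.ndarray, np.ndarray]] | None = None

    @property
    def n_iter(self) -> int:
        return len(self.objective)


@dataclass
class Factorization:
    """Fitted non-negative factors plus the solver trace."""

    U: np.ndarray
    V: np.ndarray
    k: int
    trace: TraceLog
    converged: bool

    def reconstruction(self) -> np.ndarray:
        return self.U @ self.V


def _check_shapes(X, M, U, V) -> None:
    if X.shape != M.shape:
        raise ValueError(f"X shape {X.shape} != mask shape {M.shape}")
    n, p = X.shape
    if U.shape[0] != n or V.shape[1] != p or U.shape[1] != V.shape[0]:
        raise ValueError(
            f"factor shapes {U.shape} x {V.shape} inconsistent with X {X.shape}"
        )


def masked_objective(
    X: np.ndarray, M: np.ndarray, U: np.ndarray, V: np.ndarray
) -> float:
    """Half the squared Frobenius residual over observed cells only."""
    X, M, U, V = map(np.asarray, (X, M, U, V))
    _check_shapes(X, M, U, V)
    R = M * (X - U @ V)
    return 0.5 * float(np.sum(R * R))


def update_step(
    X: np.ndarray,
    M: np.ndarray,
    U: np.ndarray,
    V: np.ndarray,
    config: SolverConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """One masked multiplicative update of U then V.

    U-update denominator carries the orthogonality-penalty gradient
    ``lambda * U (U'U - I)``; denominators are floored at ``DELTA`` and the
    factors clipped at 0, so non-negativity is preserved exactly.
    """
    X, M, U, V = map(lambda a: np.asarray(a, dtype=float), (X, M, U, V))
    _check_shapes(X, M, U, V)
    for a in (X, M, U, V):
        if not np.all(np.isfinite(a)):
            raise ValueError("non-finite entries in solver input")
    lam = config.ortho_weight
    MX = M * X

    num_u = MX @ V.T
    den_u = (M * (U @ V)) @ V.T
    if lam > 0:
        k = U.shape[1]
        den_u = den_u + lam * U @ (U.T @ U - np.eye(k))
    U_new = np.maximum(U * num_u / np.maximum(den_u, DELTA), 0.0)

    num_v = U_new.T @ MX
    den_v = U_new.T @ (M * (U_new @ V))
    V_new = np.maximum(V * num_v / np.maximum(den_v, DELTA), 0.0)
    return U_new, V_new


def step_error(f_t: float, f_prev: float) -> float:
    """Relative objective change ``|f_t - f_prev| / max(f_prev, DELTA)``."""
    return abs(f_t - f_prev) / max(f_prev, DELTA)


def _init_factors(
    X: np.ndarray, M: np.ndarray, config: SolverConfig
) -> tuple[np.ndarray, np.ndarray]:
    n, p = X.shape
    k = config.k
    if config.init == "nndsvd":
        # NNDSVD: SVD of X, non-negative parts of the leading singular pairs.
        W, s, H = np.linalg.svd(X, full_matrices=False)
        U = np.zeros((n, k))
        V = np.zeros((k, p))
        U[:, 0] = np.sqrt(s[0]) * np.abs(W[:, 0])
        V[0, :] = np.sqrt(s[0]) * np.abs(H[0, :])
        for j in range(1, min(k, len(s))):
            u, v = W[:, j], H[j, :]
            up, un = np.maximum(u, 0), np.maximum(-u, 0)
            vp, vn = np.maximum(v, 0), np.maximum(-v, 0)
            if np.linalg.norm(up) * np.linalg.norm(vp) >= np.linalg.norm(un) * np.linalg.norm(vn):
                a, b = up, vp
            else:
                a, b = un, vn
            na, nb = np.linalg.norm(a), np.linalg.norm(b)
            if na * nb > 0:
                scale = np.sqrt(s[j] * na * nb)
                U[:, j] = scale * a / na
                V[j, :] = scale * b / nb
        # mean-filled variant: zeros stall multiplicative updates, so they
        # are replaced by the matrix mean
        fill = X[M > 0].mean()
        U[U < 1e-12] = fill
        V[V < 1e-12] = fill
        return U, V
    rng = np.random.default_rng(config.seed)
    scale = X[M > 0].mean() / k
    U = np.abs(rng.standard_normal((n, k))) * scale
    V = np.abs(rng.standard_normal((k, p))) * scale
    return U, V


def fit_ognmf(
    X: np.ndarray, M: np.ndarray, config: SolverConfig | None = None
) -> Factorization:
    """Fit the masked factorization from a seeded non-negative start.

    Runs :func:`update_step` until the step error drops below
    ``config.epsilon`` or ``config.max_iter`` is reached; the returned
    :class:`Factorization` carries the full objective / step-error trace and
    a ``converged`` flag (non-convergence is reported, never raised).

    Every row and column of the mask must contain at least one observed
    cell, otherwise the corresponding factor slice is unidentifiable.
    """
    config = config or SolverConfig()
    X = np.asarray(X, dtype=float)
    M = np.asarray(M, dtype=float)
    if X.shape != M.shape:
        raise ValueError(f"X shape {X.shape} != mask shape {M.shape}")
    if not np.all((M == 0) | (M == 1)):
        raise ValueError("mask must be binary")
    if np.any(X < 0):
        raise ValueError("X must be non-negative")
    if np.any(M.sum(axis=1) == 0):
        raise ValueError("every row of the mask needs >= 1 observed cell")
    if np.any(M.sum(axis=0) == 0):
        raise ValueError("every column of the mask needs >= 1 observed cell")

    U, V = _init_factors(X, M, config)
    trace = TraceLog(snapshots=[] if config.store_factors else None)
    f_prev = masked_objective(X, M, U, V)
    converged = False
    for _ in range(config.max_iter):
        U, V = update_step(X, M, U, V, config)
        f = masked_objective(X, M, U, V)
        e = step_error(f, f_prev)
        trace.objective.append(f)
        trace.step.append(e)
        if trace.snapshots is not None:
            trace.snapshots.append((U.copy(), V.copy()))
        f_prev = f
        if e < config.epsilon:
            converged = True
            break
    return Factorization(U=U, V=V, k=config.k, trace=trace, converged=converged)


def impute(
    fact: Factorization,
    fm,
    cells: list[tuple[int, int]] | list[tuple[int, str]],
) -> np.ndarray:
    """Read the reconstruction at the given cells, in clinical units.

    ``cells`` are ``(row, column)`` pairs where the column may be an index
    into ``fm.columns`` or a feature name; each column must be continuous so
    the stored affine scaling can be inverted.
    """
    from .cohort_io import decode_column

    Xhat = fact.reconstruction()
    n, p = fm.X.shape
    if Xhat.shape != (n, p):
        raise ValueError("factorization shape does not match feature matrix")
    out = np.empty(len(cells))
    for idx, (i, col) in enumerate(cells):
        name = fm.columns[col] if isinstance(col, (int, np.integer)) else col
        j = fm.column_index(name)
        if not (0 <= i < n):
            raise IndexError(f"cell row {i} outside matrix with {n} rows")
        out[idx] = decode_column(fm, Xhat, name)[i]
    return out
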