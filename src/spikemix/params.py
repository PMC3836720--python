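"""Parameter containers and forward evaluation for the four model families.

All families share the same observation model: the spike probability in a
bin is ``sigma(f(x, s))`` where ``sigma`` is the logistic function and
``f`` is a family-specific predictor of the stimulus features ``x`` and the
one-hot spike-history vector ``s``:

* linear (GLM):        ``f = w'x + h's + b``
* quadratic:           ``f = 1/2 x'Ax + w'x + h's + b``
* STM:                 ``f = log sum_k exp(1/2 x'A_k x + w_k'x + a_k) + h's``
* factored STM:        ``f = log sum_k exp(sum_m b_km (u_m'x)^2 + w_k'x + a_k) + h's``

The STM's log-sum-exp is a soft maximum over per-component quadratic
responses; with K = 1 it reduces exactly to the quadratic model, and with
A = 0 the quadratic model reduces to the GLM.  The shared history filter
``h`` acting on a one-hot ``s`` is equivalent to an additive log-ratio of
interspike-interval distributions (naive-Bayes history term).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, logsumexp as _scipy_logsumexp


def sigmoid(z):
    """Logistic function ``1 / (1 + exp(-z))``, stable for large ``|z|``."""
    return expit(z)


def log_sum_exp(q, axis=None):
    """Numerically stable ``log(sum(exp(q)))`` (soft maximum).

    Implemented with max-subtraction; errors on empty input.
    """
    q = np.asarray(q, dtype=float)
    if q.size == 0:
        raise ValueError("log_sum_exp of an empty vector is undefined")
    return _scipy_logsumexp(q, axis=axis)


def _symmetrize(A):
    A = np.asarray(A, dtype=float)
    return (A + A.T) / 2.0


def _as_2d(x, name, dim):
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X = np.atleast_2d(x)
    if X.shape[1] != dim:
        raise ValueError(
            f"{name} has dimension {X.shape[1]}, expected {dim}"
        )
    return X, single


@dataclass
class GLMParams:
    """Linear-nonlinear-Bernoulli parameters: stimulus filter, history
    filter and bias."""

    w: np.ndarray
    h: np.ndarray
    b: float

    def __post_init__(self):
        self.w = np.asarray(self.w, dtype=float).ravel()
        self.h = np.asarray(self.h, dtype=float).ravel()
        self.b = float(self.b)
        if not (np.isfinite(self.w).all() and np.isfinite(self.h).all()
                and np.isfinite(self.b)):
            raise ValueError("GLM parameters must be finite")

    @property
    def dim(self):
        return self.w.size

    @property
    def history_dim(self):
        return self.h.size

    def copy(self):
        return GLMParams(self.w.copy(), self.h.copy(), self.b)


@dataclass
class QuadraticParams:
    """Quadratic-form parameters; ``A`` is stored symmetric (symmetrized on
    ingestion)."""

    A: np.ndarray
    w: np.ndarray
    h: np.ndarray
    b: float

    def __post_init__(self):
        self.A = _symmetrize(self.A)
        self.w = np.asarray(self.w, dtype=float).ravel()
        self.h = np.asarray(self.h, dtype=float).ravel()
        self.b = float(self.b)
        if self.A.shape != (self.w.size, self.w.size):
            raise ValueError("A must be D x D with D = len(w)")

    @property
    def dim(self):
        return self.w.size

    @property
    def history_dim(self):
        return self.h.size

    def copy(self):
        return QuadraticParams(self.A.copy(), self.w.copy(), self.h.copy(), self.b)


@dataclass
class STMParams:
    """Spike-triggered mixture model parameters.

    Per component k: symmetric quadratic matrix ``A[k]``, linear filter
    ``W[k]`` and bias ``a[k]``; the history filter ``h`` is shared across
    components.  There is no separate global bias (it is absorbed into the
    per-component ``a_k``).
    """

    A: np.ndarray  # (K, D, D)
    W: np.ndarray  # (K, D)
    a: np.ndarray  # (K,)
    h: np.ndarray  # (H,)

    def __post_init__(self):
        self.A = np.asarray(self.A, dtype=float)
        if self.A.ndim == 2:
            self.A = self.A[None]
        self.A = (self.A + np.transpose(self.A, (0, 2, 1))) / 2.0
        self.W = np.atleast_2d(np.asarray(self.W, dtype=float))
        self.a = np.asarray(self.a, dtype=float).ravel()
        self.h = np.asarray(self.h, dtype=float).ravel()
        K, D = self.W.shape
        if K < 1:
            raise ValueError("STM needs at least one component")
        if self.A.shape != (K, D, D) or self.a.shape != (K,):
            raise ValueError("inconsistent STM component shapes")

    @property
    def n_components(self):
        return self.W.shape[0]

    @property
    def dim(self):
        return self.W.shape[1]

    @property
    def history_dim(self):
        return self.h.size

    def copy(self):
        return STMParams(self.A.copy(), self.W.copy(), self.a.copy(), self.h.copy())


@dataclass
class FactoredSTMParams:
    """Low-rank STM with shared quadratic features.

    The quadratic response of component k is ``sum_m B[k, m] * (U[:, m]'x)^2``:
    the feature directions ``U`` (D x M) are shared, only the coefficients
    ``B`` (K x M) differ per component, so the parameter count grows
    linearly in the stimulus dimension.  Setting
    ``A_k = U diag(2 B[k]) U'`` recovers the dense STM component.
    """

    U: np.ndarray  # (D, M)
    B: np.ndarray  # (K, M)
    W: np.ndarray  # (K, D)
    a: np.ndarray  # (K,)
    h: np.ndarray  # (H,)

    def __post_init__(self):
        self.W = np.atleast_2d(np.asarray(self.W, dtype=float))
        K, D = self.W.shape
        self.U = np.asarray(self.U, dtype=float).reshape(D, -1)
        M = self.U.shape[1]
        self.B = np.asarray(self.B, dtype=float).reshape(K, M)
        self.a = np.asarray(self.a, dtype=float).ravel()
        self.h = np.asarray(self.h, dtype=float).ravel()
        if K < 1:
            raise ValueError("factored STM needs at least one component")
        if self.a.shape != (K,):
            raise ValueError("inconsistent factored STM shapes")

    @property
    def n_components(self):
        return self.W.shape[0]

    @property
    def n_features(self):
        return self.U.shape[1]

    @property
    def dim(self):
        return self.W.shape[1]

    @property
    def history_dim(self):
        return self.h.size

    def copy(self):
        return FactoredSTMParams(self.U.copy(), self.B.copy(), self.W.copy(),
                                 self.a.copy(), self.h.copy())

    def to_stm(self) -> STMParams:
        """Equivalent dense STM: ``A_k = U diag(2 B_k) U'``."""
        A = np.einsum("dm,km,em->kde", self.U, 2.0 * self.B, self.U)
        return STMParams(A, self.W.copy(), self.a.copy(), self.h.copy())


ParamsLike = GLMParams | QuadraticParams | STMParams | FactoredSTMParams

FAMILY_NAMES = {
    GLMParams: "glm",
    QuadraticParams: "quadratic",
    STMParams: "stm",
    FactoredSTMParams: "fstm",
}


def family_of(params) -> str:
    for cls, name in FAMILY_NAMES.items():
        if isinstance(params, cls):
            return name
    raise TypeError(f"unknown parameter family: {type(params).__name__}")


def history_term(s, h):
    """History contribution ``h's``: 0 for all-zero ``s``, ``h_j`` for a
    one-hot at ``j``.  Vectorized over rows of ``s``."""
    s = np.asarray(s, dtype=float)
    h = np.asarray(h, dtype=float).ravel()
    if s.shape[-1] != h.size:
        raise ValueError(
            f"history vector has dimension {s.shape[-1]}, filter expects {h.size}"
        )
    return s @ h


def component_responses(params, x):
    """Per-component quadratic responses ``q_k(x)`` of an (factored) STM.

    Returns an array of shape (T, K) for 2-d input, (K,) for a single x.
    """
    if isinstance(params, STMParams):
        X, single = _as_2d(x, "x", params.dim)
        # q[t, k] = 1/2 x' A_k x + w_k' x + a_k
        quad = 0.5 * np.einsum("td,kde,te->tk", X, params.A, X, optimize=True)
        Q = quad + X @ params.W.T + params.a
    elif isinstance(params, FactoredSTMParams):
        X, single = _as_2d(x, "x", params.dim)
        Z = X @ params.U  # (T, M)
        Q = (Z ** 2) @ params.B.T + X @ params.W.T + params.a
    else:
        raise TypeError("component responses only defined for STM families")
    return Q[0] if single else Q


def predictor(params, x, s):
    """Predictor value ``f(x, s)`` feeding the sigmoid; vectorized over bins.

    ``x`` may be a single length-D vector or a (T, D) matrix (``s``
    likewise); raises on dimension mismatch, naming the offending input.
    """
    if isinstance(params, GLMParams):
        X, single = _as_2d(x, "x", params.dim)
        f = X @ params.w + params.b
    elif isinstance(params, QuadraticParams):
        X, single = _as_2d(x, "x", params.dim)
        f = 0.5 * np.einsum("td,de,te->t", X, params.A, X) + X @ params.w + params.b
    elif isinstance(params, (STMParams, FactoredSTMParams)):
        Q = component_responses(params, np.atleast_2d(np.asarray(x, dtype=float)))
        single = np.asarray(x).ndim == 1
        f = _scipy_logsumexp(Q, axis=1)
    else:
        raise TypeError(f"unknown parameter family: {type(params).__name__}")
    S, s_single = _as_2d(s, "s", params.history_dim)
    if S.shape[0] != len(np.atleast_1d(f)):
        if S.shape[0] == 1 or len(np.atleast_1d(f)) == 1:
            pass  # broadcasting a single row is fine
        else:
            raise ValueError(
                f"x has {len(np.atleast_1d(f))} rows but s has {S.shape[0]}"
            )
    f = f + S @ params.h
    return float(f[0]) if (single and s_single) else f


def firing_prob(params, x, s):
    """Spike probability ``sigma(f(x, s))``; strictly inside (0, 1) for
    finite parameters."""
    return sigmoid(predictor(params, x, s))


def count_parameters(family: str, D: int, H: int, K: int = 1, M: int = 0) -> int:
    """Number of free parameters of a model family.

    * glm:       D + H + 1
    * quadratic: D(D+1)/2 + D + H + 1
    * stm:       K (D(D+1)/2 + D + 1) + H
    * fstm:      M D + K M + K D + K + H
    """
    if D < 0 or H < 0 or M < 0:
        raise ValueError("dimensions must be non-negative")
    family = family.lower()
    if family == "glm":
        return D + H + 1
    if family in ("quadratic", "quad"):
        return D * (D + 1) // 2 + D + H + 1
    if K < 1:
        raise ValueError("STM families need K >= 1")
    if family == "stm":
        return K * (D * (D + 1) // 2 + D + 1) + H
    if family in ("fstm", "factored", "factored_stm"):
        return M * D + K * M + K * D + K + H
    raise ValueError(f"unknown model family: {family!r}")
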