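"""LKJ correlation-matrix machinery.

A J x J correlation matrix is parameterized by its J(J-1)/2 canonical
partial correlations (cpcs) w in (-1, 1), mapped to the Cholesky
factor L of R row by row:

    L[i, j] = w[i, j] * sqrt(1 - sum_{k<j} L[i, k]^2)   (j < i)
    L[i, i] = sqrt(1 - sum_{k<i} L[i, k]^2)

Under LKJ(eta) the cpcs are independent with (w+1)/2 ~ Beta(b, b),
b = eta + (J - 2 - j)/2 for 0-indexed column j.  For unconstrained
sampling the cpcs are in turn written as w = tanh(y); the combined
log density of y (Beta density times tanh Jacobian) is
sum b * log(1 - w^2) up to a constant, with gradient -2 b w — the
same construction gradient-based samplers for these models use.
"""

from __future__ import annotations

import numpy as np
from scipy.special import betaln

_EPS = 1e-12


def n_cpc(J: int) -> int:
    return J * (J - 1) // 2


def tril_indices(J: int) -> tuple[np.ndarray, np.ndarray]:
    """Row-major strictly-lower-triangular indices pairing the flat
    cpc vector with matrix positions."""
    return np.tril_indices(J, k=-1)


def cpc_beta_shapes(J: int, eta: float = 1.0) -> np.ndarray:
    """Beta shape b for each cpc, flat in row-major tril order."""
    rows, cols = tril_indices(J)
    return eta + (J - 2 - cols) / 2.0


def chol_from_cpc(w_flat: np.ndarray, J: int) -> np.ndarray:
    """Cholesky factor of the correlation matrix from flat cpcs."""
    rows, cols = tril_indices(J)
    W = np.zeros((J, J))
    W[rows, cols] = w_flat
    L = np.zeros((J, J))
    L[0, 0] = 1.0
    for i in range(1, J):
        s = 1.0
        for j in range(i):
            L[i, j] = W[i, j] * np.sqrt(max(s, _EPS))
            s -= L[i, j] ** 2
        L[i, i] = np.sqrt(max(s, _EPS))
    return L


def chol_from_cpc_with_grad(w_flat: np.ndarray, J: int):
    """Forward construction plus a reverse-mode pullback.

    Returns (L, backward) where backward(gL) maps a gradient with
    respect to L onto the flat cpc vector.
    """
    rows, cols = tril_indices(J)
    W = np.zeros((J, J))
    W[rows, cols] = w_flat
    L = np.zeros((J, J))
    S = np.zeros((J, J + 1))  # S[i, j] = remaining squared mass before column j
    L[0, 0] = 1.0
    for i in range(1, J):
        S[i, 0] = 1.0
        for j in range(i):
            L[i, j] = W[i, j] * np.sqrt(max(S[i, j], _EPS))
            S[i, j + 1] = S[i, j] - L[i, j] ** 2
        L[i, i] = np.sqrt(max(S[i, i], _EPS))

    def backward(gL: np.ndarray) -> np.ndarray:
        gW = np.zeros((J, J))
        for i in range(1, J):
            gs = gL[i, i] * 0.5 / np.sqrt(max(S[i, i], _EPS))
            for j in range(i - 1, -1, -1):
                g_lij = gL[i, j] - gs * 2.0 * L[i, j]
                root = np.sqrt(max(S[i, j], _EPS))
                gW[i, j] = g_lij * root
                gs = gs + g_lij * W[i, j] * 0.5 / root
        return gW[rows, cols]

    return L, backward


def corr_from_cpc(w_flat: np.ndarray, J: int) -> np.ndarray:
    L = chol_from_cpc(w_flat, J)
    R = L @ L.T
    np.fill_diagonal(R, 1.0)
    return 0.5 * (R + R.T)


def sample_lkj(J: int, eta: float = 1.0, rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw a correlation matrix from LKJ(eta) via the cpc-Beta
    construction (exact, no MCMC)."""
    rng = rng or np.random.default_rng()
    b = cpc_beta_shapes(J, eta)
    w = 2.0 * rng.beta(b, b) - 1.0
    return corr_from_cpc(w, J)


def lkj_logpdf_cpc(w_flat: np.ndarray, J: int, eta: float = 1.0) -> float:
    """Log density of the flat cpc vector under LKJ(eta), including
    the Beta normalization constants (a proper density on (-1,1)^m)."""
    b = cpc_beta_shapes(J, eta)
    w = np.asarray(w_flat, dtype=float)
    if np.any(np.abs(w) >= 1.0):
        return -np.inf
    return float(
        np.sum((b - 1.0) * np.log1p(-(w**2)) - betaln(b, b) - (2.0 * b - 1.0) * np.log(2.0))
    )


def lkj_logpdf_unconstrained(y_flat: np.ndarray, J: int, eta: float = 1.0):
    """Log density and gradient of unconstrained y (w = tanh(y)).

    Adds the tanh Jacobian sum log(1 - w^2) to the cpc-Beta density;
    the variable part collapses to sum b * log(1 - w^2).
    """
    b = cpc_beta_shapes(J, eta)
    w = np.tanh(np.asarray(y_flat, dtype=float))
    const = float(np.sum(-betaln(b, b) - (2.0 * b - 1.0) * np.log(2.0)))
    with np.errstate(divide="ignore"):  # |w| -> 1 gives -inf, a rejection
        logp = const + float(np.sum(b * np.log1p(-(w**2))))
    grad = -2.0 * b * w
    return logp, grad
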