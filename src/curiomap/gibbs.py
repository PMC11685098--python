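"""Blocked Gibbs sampler for Gaussian (multivariate) linear mixed models.

Model, for observation ``i`` in group ``g(i)``::

    y_i = B' x_i + U_{g(i)}' z_i + e_i,      e_i ~ N_d(0, Sigma)

with ``y_i`` a ``d``-vector of outcomes, ``x_i`` the fixed-effect design
(``p``-vector), ``z_i`` the random-effect design (``q``-vector, typically an
intercept plus within-person predictors) and ``U_g`` the ``q x d`` matrix of
group (participant) effects.

Priors are conjugate throughout:

* ``vec(B) ~ N(0, diag(prior_sd**2))`` — independent zero-centred normals on
  every fixed effect (weakly informative; scale per predictor),
* ``vec(U_g) ~ N(0, T)`` with ``T ~ InvWishart(nu_t, s_t * I)`` — correlated
  participant intercepts/slopes across outcomes,
* ``Sigma ~ InvWishart(nu_sigma, s_sigma * I)`` — residual covariance, whose
  off-diagonal carries the residual correlation of a bivariate fit.

The fixed effects are updated with the group effects integrated out
(a partially collapsed step using the Woodbury identity), followed by the
group effects' exact conditional — i.e. one joint draw of ``(B, U)`` given
``(T, Sigma)``.  This removes the notoriously slow mixing between a global
intercept and group intercepts.  ``vec`` is column-major throughout: the
first ``p`` (or ``q``) entries belong to outcome 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_triangular

__all__ = ["GibbsDraws", "sample_mlmm"]


@dataclass
class GibbsDraws:
    """Post-warm-up draws from one chain."""

    B: np.ndarray  # (n_draws, p, d)
    Sigma: np.ndarray  # (n_draws, d, d)
    T: np.ndarray  # (n_draws, q*d, q*d)


def _sample_mvn_canonical(A: np.ndarray, b: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draw from N(A^-1 b, A^-1) given precision ``A`` and linear term ``b``."""
    A = 0.5 * (A + A.T)
    L = np.linalg.cholesky(A)
    w = solve_triangular(L, b, lower=True)
    mean_t = solve_triangular(L.T, w, lower=False)
    z = rng.standard_normal(b.shape[0])
    return mean_t + solve_triangular(L.T, z, lower=False)


def _inv_wishart(df: float, S: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draw from InvWishart(df, S) via the Bartlett decomposition."""
    m = S.shape[0]
    P = np.linalg.inv(0.5 * (S + S.T))
    L = np.linalg.cholesky(0.5 * (P + P.T))
    A = np.zeros((m, m))
    for i in range(m):
        A[i, i] = np.sqrt(rng.chisquare(df - i))
    idx = np.tril_indices(m, -1)
    A[idx] = rng.standard_normal(len(idx[0]))
    LA = L @ A
    W = LA @ LA.T
    return np.linalg.inv(W + 1e-12 * np.eye(m))


def sample_mlmm(
    Y: np.ndarray,
    X: np.ndarray,
    Z: np.ndarray,
    groups: np.ndarray,
    *,
    prior_sd: np.ndarray,
    n_iter: int,
    warmup: int,
    rng: np.random.Generator,
    s_t: float = 1e-4,
    s_sigma: float = 1e-4,
) -> GibbsDraws:
    """Run one Gibbs chain; returns draws after discarding ``warmup``.

    Parameters
    ----------
    Y : (n, d) outcomes; X : (n, p) fixed design; Z : (n, q) random design.
    groups : (n,) integer group labels.
    prior_sd : (p,) prior SD of each fixed effect (shared across outcomes).
    s_t, s_sigma : scale of the inverse-Wishart prior matrices (times
        identity); degrees of freedom are ``dim + 2`` so the priors are proper
        but weak next to tens of groups / hundreds of trials.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, d = Y.shape
    X = np.asarray(X, dtype=float)
    Z = np.asarray(Z, dtype=float)
    p, q = X.shape[1], Z.shape[1]
    _, gidx = np.unique(np.asarray(groups), return_inverse=True)
    G = gidx.max() + 1
    qd, pd_ = q * d, p * d

    if warmup >= n_iter:
        raise ValueError("warmup must be smaller than n_iter")
    prior_sd = np.asarray(prior_sd, dtype=float)
    if prior_sd.shape != (p,) or np.any(prior_sd <= 0):
        raise ValueError("prior_sd must be positive with one entry per fixed effect")

    rows = [np.nonzero(gidx == g)[0] for g in range(G)]
    Zg = [Z[r] for r in rows]
    ZtZ = [z.T @ z for z in Zg]
    XtZ = [X[r].T @ Zg[g] for g, r in enumerate(rows)]
    ZtY = [Zg[g].T @ Y[r] for g, r in enumerate(rows)]
    XtX = X.T @ X
    XtY = X.T @ Y

    prior_prec = np.tile(1.0 / prior_sd**2, d)
    nu_t = qd + 2
    nu_sigma = d + 2
    S_t0 = s_t * np.eye(qd)
    S_sigma0 = s_sigma * np.eye(d)

    # initial values: least squares for B, residual covariance for Sigma
    B = np.linalg.lstsq(X, Y, rcond=None)[0]
    resid = Y - X @ B
    Sigma = np.atleast_2d(np.cov(resid.T)) + 1e-8 * np.eye(d)
    T = 1e-4 * np.eye(qd)
    U = np.zeros((G, q, d))
    random_part = np.zeros((n, d))

    n_keep = n_iter - warmup
    out_B = np.empty((n_keep, p, d))
    out_Sigma = np.empty((n_keep, d, d))
    out_T = np.empty((n_keep, qd, qd))

    for it in range(n_iter):
        Sinv = np.linalg.inv(Sigma)
        Tinv = np.linalg.inv(T + 1e-12 * np.eye(qd))

        # --- fixed effects B | T, Sigma with U integrated out (Woodbury)
        A = np.kron(Sinv, XtX) + np.diag(prior_prec)
        b = (XtY @ Sinv).flatten(order="F")
        Minv = []
        for g in range(G):
            Mg = Tinv + np.kron(Sinv, ZtZ[g])
            Mg_inv = np.linalg.inv(0.5 * (Mg + Mg.T))
            Minv.append(Mg_inv)
            Cg = np.kron(Sinv, XtZ[g])  # (p*d, q*d)
            rg = (ZtY[g] @ Sinv).flatten(order="F")
            CM = Cg @ Mg_inv
            A -= CM @ Cg.T
            b -= CM @ rg
        B = _sample_mvn_canonical(A, b, rng).reshape(p, d, order="F")

        # --- group effects U_g | B, T, Sigma (exact conditional)
        E = Y - X @ B
        S_u = S_t0.copy()
        for g in range(G):
            lin = (Zg[g].T @ E[rows[g]] @ Sinv).flatten(order="F")
            cov = Minv[g]
            mean = cov @ lin
            Lc = np.linalg.cholesky(0.5 * (cov + cov.T) + 1e-14 * np.eye(qd))
            u_vec = mean + Lc @ rng.standard_normal(qd)
            U[g] = u_vec.reshape(q, d, order="F")
            random_part[rows[g]] = Zg[g] @ U[g]
            S_u += np.outer(u_vec, u_vec)

        # --- random-effect covariance T | U
        T = _inv_wishart(nu_t + G, S_u, rng)

        # --- residual covariance Sigma | B, U
        E2 = E - random_part
        Sigma = _inv_wishart(nu_sigma + n, S_sigma0 + E2.T @ E2, rng)

        if it >= warmup:
            j = it - warmup
            out_B[j] = B
            out_Sigma[j] = Sigma
            out_T[j] = T

    return GibbsDraws(out_B, out_Sigma, out_T)
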