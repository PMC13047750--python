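"""Fast profiled maximum-likelihood engine for two-level growth models.

Fits y_ij = x_ij' beta + z_ij' b_i + e_ij with b_i ~ N(0, Psi),
e_ij ~ N(0, sigma^2), where z_ij is (1,) or (1, age_ij).  The relative
covariance D = Psi / sigma^2 is parameterized through its Cholesky factor
(log-diagonal), so the search space is unconstrained; beta and sigma^2 are
profiled out in closed form via the Woodbury identity, leaving an
optimization over at most three scalars.  This is the same ML criterion a
general mixed-model package maximizes, specialized to the (1, age) random
structure for speed, so thousands of replication fits stay cheap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.optimize import minimize

STRUCTURES = ("full", "diagonal", "intercept")


@njit(cache=False)
def _profile_pieces(y, X, age, starts, D00, D01, D11, use_slope):
    """Accumulate GLS pieces for V_i = I + Z_i D Z_i' (relative scale).

    Returns (XtViX, XtViy, ytViy, sum_logdet).
    """
    k = X.shape[1]
    A = np.zeros((k, k))
    bvec = np.zeros(k)
    yy = 0.0
    logdet = 0.0
    n_sub = starts.shape[0] - 1
    for s in range(n_sub):
        i0, i1 = starts[s], starts[s + 1]
        ni = i1 - i0
        # Z'Z, Z'y, Z'X for Z = [1, age] (or [1])
        if use_slope:
            s1 = float(ni)
            sa = 0.0
            saa = 0.0
            for i in range(i0, i1):
                sa += age[i]
                saa += age[i] * age[i]
            # M = I2 + (Z'Z) D
            zz00, zz01, zz11 = s1, sa, saa
            m00 = 1.0 + zz00 * D00 + zz01 * D01
            m01 = zz00 * D01 + zz01 * D11
            m10 = zz01 * D00 + zz11 * D01
            m11 = 1.0 + zz01 * D01 + zz11 * D11
            det = m00 * m11 - m01 * m10
            logdet += np.log(det)
            # C = D (I2 + Z'Z D)^{-1}  (2x2)
            im00, im01, im10, im11 = m11 / det, -m01 / det, -m10 / det, m00 / det
            c00 = D00 * im00 + D01 * im10
            c01 = D00 * im01 + D01 * im11
            c10 = D01 * im00 + D11 * im10
            c11 = D01 * im01 + D11 * im11
            # u = Z'y (2,), W = Z'X (2,k)
            u0 = 0.0
            u1 = 0.0
            W = np.zeros((2, k))
            for i in range(i0, i1):
                u0 += y[i]
                u1 += age[i] * y[i]
                for j in range(k):
                    W[0, j] += X[i, j]
                    W[1, j] += age[i] * X[i, j]
            # V^{-1} = I - Z C Z'  =>  x'V^{-1}y = x'y - (Z'x)' C (Z'y)
            cu0 = c00 * u0 + c01 * u1
            cu1 = c10 * u0 + c11 * u1
            for i in range(i0, i1):
                yy += y[i] * y[i]
                for j in range(k):
                    A_ij = X[i, j]
                    bvec[j] += A_ij * y[i]
                    for l in range(j, k):
                        A[j, l] += A_ij * X[i, l]
            yy -= u0 * cu0 + u1 * cu1
            for j in range(k):
                bvec[j] -= W[0, j] * cu0 + W[1, j] * cu1
                cw0 = c00 * W[0, j] + c01 * W[1, j]
                cw1 = c10 * W[0, j] + c11 * W[1, j]
                for l in range(j, k):
                    A[j, l] -= W[0, l] * cw0 + W[1, l] * cw1
        else:
            s1 = float(ni)
            det = 1.0 + s1 * D00
            logdet += np.log(det)
            c = D00 / det
            u0 = 0.0
            W = np.zeros(k)
            for i in range(i0, i1):
                u0 += y[i]
                for j in range(k):
                    W[j] += X[i, j]
            for i in range(i0, i1):
                yy += y[i] * y[i]
                for j in range(k):
                    bvec[j] += X[i, j] * y[i]
                    for l in range(j, k):
                        A[j, l] += X[i, j] * X[i, l]
            yy -= c * u0 * u0
            for j in range(k):
                bvec[j] -= c * W[j] * u0
                for l in range(j, k):
                    A[j, l] -= c * W[j] * W[l]
    for j in range(k):
        for l in range(j):
            A[j, l] = A[l, j]
    return A, bvec, yy, logdet


def _nll_profiled(dpar, y, X, age, starts, structure):
    D00, D01, D11, use_slope = _unpack(dpar, structure)
    A, b, yy, logdet = _profile_pieces(y, X, age, starts, D00, D01, D11,
                                       use_slope)
    try:
        beta = np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        return 1e10
    rss = yy - b @ beta
    n = y.shape[0]
    if rss <= 0:
        return 1e10
    sigma2 = rss / n
    return 0.5 * (n * np.log(2.0 * np.pi * sigma2) + logdet + n)


def _unpack(dpar, structure):
    """Cholesky-parameterized relative covariance D."""
    if structure == "full":
        l00 = np.exp(dpar[0])
        l10 = dpar[1]
        l11 = np.exp(dpar[2])
        return l00 * l00, l00 * l10, l10 * l10 + l11 * l11, True
    if structure == "diagonal":
        l00 = np.exp(dpar[0])
        l11 = np.exp(dpar[1])
        return l00 * l00, 0.0, l11 * l11, True
    l00 = np.exp(dpar[0])
    return l00 * l00, 0.0, 0.0, False


@dataclass
class LMMResult:
    beta: np.ndarray
    bse: np.ndarray
    sigma2: float
    psi: np.ndarray  # random-effect covariance on the data scale (2x2 or 1x1)
    llf: float
    converged: bool
    fitted: np.ndarray  # including empirical-Bayes random effects
    structure: str
    dpar: np.ndarray | None = None  # optimized covariance parameters


def fit_lmm(y, X, age, groups, structure: str = "full",
            extra_start: np.ndarray | None = None) -> LMMResult:
    """ML fit of the two-level model; ``groups`` need not be presorted.

    ``extra_start`` adds a warm start for the covariance parameters (e.g.
    the optimum of a nested model with the same random structure), which
    keeps likelihood-ratio chains monotone.
    """
    if structure not in STRUCTURES:
        raise ValueError(f"unknown structure {structure!r}")
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    age = np.asarray(age, dtype=float)
    codes, _ = pd_factorize(groups)
    order = np.argsort(codes, kind="stable")
    y, X, age, codes = y[order], X[order], age[order], codes[order]
    change = np.flatnonzero(np.diff(codes)) + 1
    starts = np.concatenate(([0], change, [len(y)])).astype(np.int64)

    n_par = {"full": 3, "diagonal": 2, "intercept": 1}[structure]
    x0s = [np.full(n_par, -1.0), np.full(n_par, 0.5), np.full(n_par, -3.0)]
    if structure == "full":
        for x0 in x0s:
            x0[1] = 0.0
    if extra_start is not None and len(extra_start) == n_par:
        x0s.insert(0, np.asarray(extra_start, dtype=float))
    bounds = {"full": [(-8, 4), (-8, 8), (-8, 4)],
              "diagonal": [(-8, 4), (-8, 4)],
              "intercept": [(-8, 4)]}[structure]
    best = None
    for x0 in x0s:
        res = minimize(_nll_profiled, x0, args=(y, X, age, starts, structure),
                       method="L-BFGS-B", bounds=bounds,
                       options={"maxiter": 200, "ftol": 1e-11})
        if best is None or res.fun < best.fun:
            best = res
    D00, D01, D11, use_slope = _unpack(best.x, structure)
    A, b, yy, logdet = _profile_pieces(y, X, age, starts, D00, D01, D11,
                                       use_slope)
    beta = np.linalg.solve(A, b)
    n = len(y)
    sigma2 = float(max(yy - b @ beta, 1e-300) / n)
    cov_beta = sigma2 * np.linalg.inv(A)
    bse = np.sqrt(np.clip(np.diag(cov_beta), 0.0, None))
    llf = -_nll_profiled(best.x, y, X, age, starts, structure)

    # empirical-Bayes random effects for conditional fitted values
    fitted = X @ beta
    resid = y - fitted
    D = np.array([[D00, D01], [D01, D11]])
    for s in range(len(starts) - 1):
        i0, i1 = starts[s], starts[s + 1]
        Z = np.column_stack((np.ones(i1 - i0), age[i0:i1])) if use_slope \
            else np.ones((i1 - i0, 1))
        Dz = D[:Z.shape[1], :Z.shape[1]]
        M = np.eye(Z.shape[1]) + Z.T @ Z @ Dz
        b_i = Dz @ np.linalg.solve(M, Z.T @ resid[i0:i1])
        fitted[i0:i1] += Z @ b_i
    # undo the sort for caller-aligned fitted values
    fitted_out = np.empty_like(fitted)
    fitted_out[order] = fitted
    psi_dim = 2 if use_slope else 1
    psi = sigma2 * D[:psi_dim, :psi_dim]
    return LMMResult(beta, bse, sigma2, psi, float(llf),
                     bool(best.success), fitted_out, structure, best.x)


def pd_factorize(groups):
    import pandas as pd

    return pd.factorize(groups)
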