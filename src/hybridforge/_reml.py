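"""Restricted-maximum-likelihood machinery for the single-GRM mixed model

    y = X beta + u + e,   u ~ N(0, K sigma_u^2),   e ~ N(0, I sigma_e^2).

One eigendecomposition of K reduces the model to independent weighted
regressions; the REML criterion is profiled down to a one-dimensional
optimization over the log variance ratio lambda = sigma_u^2 / sigma_e^2,
which is solved deterministically by a grid bracket plus Brent
refinement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

_LOG_LAMBDA_LO, _LOG_LAMBDA_HI = -10.0, 10.0
_GRID_POINTS = 41
_PSD_TOL = 1e-8


@dataclass
class SpectralREML:
    """Fitted variance components and the cached rotation of (y, X).

    Attributes
    ----------
    lam : float
        sigma_u^2 / sigma_e^2.
    sigma_u2, sigma_e2 : float
    beta : ndarray
        GLS fixed-effect estimates at the REML optimum.
    beta_se : ndarray
    llf : float
        Restricted log-likelihood at the optimum.
    U, s : ndarray
        Eigenvectors/eigenvalues of K.
    y_rot, X_rot : ndarray
        U.T @ y and U.T @ X, reused by per-variant scans.
    """

    lam: float
    sigma_u2: float
    sigma_e2: float
    beta: np.ndarray
    beta_se: np.ndarray
    llf: float
    U: np.ndarray
    s: np.ndarray
    y_rot: np.ndarray
    X_rot: np.ndarray

    @property
    def heritability(self) -> float:
        """sigma_u^2 / (sigma_u^2 + sigma_e^2) ("genomic heritability")."""
        tot = self.sigma_u2 + self.sigma_e2
        return self.sigma_u2 / tot if tot > 0 else 0.0

    @property
    def weights(self) -> np.ndarray:
        """1 / (lam * s_i + 1): inverse rotated covariance up to sigma_e^2."""
        return 1.0 / (self.lam * self.s + 1.0)

    def residual_rot(self) -> np.ndarray:
        return self.y_rot - self.X_rot @ self.beta

    def blup_u(self) -> np.ndarray:
        """BLUPs of the random effects for the fitted samples."""
        r = self.residual_rot()
        return self.U @ (self.lam * self.s * self.weights * r)


def _check_psd(s: np.ndarray) -> np.ndarray:
    if s.min() < -_PSD_TOL * max(1.0, s.max()):
        raise ValueError(
            f"kinship matrix is not PSD (min eigenvalue {s.min():.3g})"
        )
    return np.clip(s, 0.0, None)


def _check_full_rank(X: np.ndarray, names=None) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the first column that adds no rank
        for j in range(1, X.shape[1] + 1):
            if np.linalg.matrix_rank(X[:, :j]) < j:
                label = names[j - 1] if names is not None else f"column {j - 1}"
                raise ValueError(f"covariate matrix rank-deficient at {label}")


def fit_reml(
    y: np.ndarray,
    X: np.ndarray,
    K: np.ndarray,
    covariate_names=None,
) -> SpectralREML:
    """Fit the one-GRM mixed model by profiled spectral REML."""
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.size:
        X = X.T
    n, c = X.shape
    if y.size != n or K.shape != (n, n):
        raise ValueError("y, X and K dimensions disagree")
    if n - c < 2:
        raise ValueError("too few residual degrees of freedom for REML")
    _check_full_rank(X, covariate_names)

    s, U = np.linalg.eigh((K + K.T) / 2.0)
    s = _check_psd(s)
    y_rot = U.T @ y
    X_rot = U.T @ X

    def neg_restricted_ll(log_lam: float) -> float:
        return -_restricted_ll(log_lam, y_rot, X_rot, s)[0]

    grid = np.linspace(_LOG_LAMBDA_LO, _LOG_LAMBDA_HI, _GRID_POINTS)
    vals = np.array([neg_restricted_ll(g) for g in grid])
    # flat profiles (e.g. K proportional to I) are unidentifiable: break
    # the tie deterministically toward the smallest variance ratio
    tol = 1e-9 * max(1.0, abs(float(vals.min())))
    k = int(np.flatnonzero(vals <= vals.min() + tol)[0])
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, len(grid) - 1)]
    if k in (0, len(grid) - 1):
        log_lam = grid[k]
    else:
        res = minimize_scalar(
            neg_restricted_ll, bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-8},
        )
        log_lam = float(res.x)
        if neg_restricted_ll(log_lam) > vals[k]:
            log_lam = grid[k]

    llf, lam, sigma_e2, beta, beta_cov = _solve_at(
        log_lam, y_rot, X_rot, s
    )
    return SpectralREML(
        lam=lam,
        sigma_u2=lam * sigma_e2,
        sigma_e2=sigma_e2,
        beta=beta,
        beta_se=np.sqrt(np.diag(beta_cov)),
        llf=llf,
        U=U,
        s=s,
        y_rot=y_rot,
        X_rot=X_rot,
    )


def _restricted_ll(log_lam, y_rot, X_rot, s):
    lam = np.exp(log_lam)
    n, c = X_rot.shape
    d = lam * s + 1.0
    w = 1.0 / d
    XtWX = X_rot.T @ (w[:, None] * X_rot)
    XtWy = X_rot.T @ (w * y_rot)
    beta = np.linalg.solve(XtWX, XtWy)
    r = y_rot - X_rot @ beta
    rss = float(r @ (w * r))
    df = n - c
    sigma_e2 = rss / df
    sign, logdet_XtWX = np.linalg.slogdet(XtWX)
    llf = -0.5 * (
        df * (np.log(2.0 * np.pi * sigma_e2) + 1.0)
        + np.log(d).sum()
        + logdet_XtWX
    )
    return llf, lam, sigma_e2, beta, XtWX


def _solve_at(log_lam, y_rot, X_rot, s):
    llf, lam, sigma_e2, beta, XtWX = _restricted_ll(log_lam, y_rot, X_rot, s)
    beta_cov = sigma_e2 * np.linalg.inv(XtWX)
    return llf, lam, sigma_e2, beta, beta_cov
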