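"""Sparse generalized PLS for a binary response, with a clinical offset variant.

The sparse direction comes from the univariate closed form of the
elastic-net-constrained surrogate problem: with

    H = X' W ytilde / ||X' W ytilde||,

the thresholded surrogate weight vector is

    c_hat = (|H| - delta * max_j |H_j|)_+ * sign(H),   0 < delta < 1,

so the support of c_hat is {j : |H_j| > delta * max|H|}.  The classifier
iterates IRLS-style updates of (eta, pi, W, ytilde), re-solves the sparse
direction, accumulates an active set A = {j: c_hat_j != 0} u {j: beta_j != 0},
fits PLS on the active columns X^A, and maps the PLS coefficients back into
beta, until the coefficient change falls below ``eps``.

SGPLSOffClin replaces the IRLS-style update with the offset version (the
fitted clinical predictor eta_clin enters eta but not the pseudo-response)
and the PLS step with weighted PLS, as in the RPLS offset variant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .glm import LogisticFit, binomial_loglik, fit_logistic
from .pls import PLSFit, fit_pls

__all__ = [
    "SparseWeightSolution",
    "SGPLSFit",
    "solve_sparse_weight",
    "fit_sgpls",
    "predict_sgpls",
]

_PI_CLIP = 1e-5
_W_FLOOR = 1e-10


@dataclass
class SparseWeightSolution:
    """Thresholded surrogate weight vector and its direction."""

    c_hat: np.ndarray
    H: np.ndarray
    delta: float
    kappa: float = 0.5

    @property
    def support(self) -> np.ndarray:
        return np.flatnonzero(self.c_hat)


def solve_sparse_weight(
    X: np.ndarray,
    w_diag: np.ndarray,
    y_tilde: np.ndarray,
    delta: float,
    kappa: float = 0.5,
) -> SparseWeightSolution:
    """Closed-form univariate sparse weight: soft-threshold H at delta*max|H|.

    ``kappa`` is accepted for interface fidelity but does not enter the
    univariate closed form.  ``delta = 1`` (boundary) yields c_hat == 0.
    """
    if not (0.0 < delta <= 1.0):
        raise ValueError(f"delta must be in (0, 1], got {delta}")
    X = np.asarray(X, dtype=float)
    w = np.asarray(w_diag, dtype=float).ravel()
    yt = np.asarray(y_tilde, dtype=float).ravel()
    v = X.T @ (w * yt)
    norm = np.linalg.norm(v)
    if norm <= 0.0:
        raise ValueError("X' W ytilde is zero: no sparse direction exists")
    H = v / norm
    thr = delta * np.max(np.abs(H))
    c_hat = np.maximum(np.abs(H) - thr, 0.0) * np.sign(H)
    return SparseWeightSolution(c_hat=c_hat, H=H, delta=float(delta), kappa=float(kappa))


@dataclass
class SGPLSFit:
    """Fitted SGPLS / SGPLSOffClin classifier."""

    beta_hat: np.ndarray  # (p,), nonzero only on the active set
    intercept: float
    active_set: np.ndarray
    r: int
    delta: float
    kappa: float
    clinical: LogisticFit | None
    n_outer_iterations: int
    converged: bool
    final_delta_beta: float
    pls: PLSFit | None = None

    def linear_predictor(
        self, X_new: np.ndarray, Z_new: np.ndarray | None = None
    ) -> np.ndarray:
        X_new = np.asarray(X_new, dtype=float)
        if X_new.shape[1] != self.beta_hat.size:
            raise ValueError(
                f"X has {X_new.shape[1]} columns, fit expects {self.beta_hat.size}"
            )
        eta = self.intercept + X_new @ self.beta_hat
        if self.clinical is not None:
            if Z_new is None:
                raise ValueError("fit has a clinical offset part; Z_new is required")
            eta = eta + self.clinical.predict_linear(Z_new)
        return eta

    def to_table(self, names: list[str] | None = None):
        """(feature, selected, beta_hat) table."""
        import pandas as pd

        p = self.beta_hat.size
        if names is None:
            names = [f"m{j + 1}" for j in range(p)]
        selected = np.zeros(p, dtype=bool)
        selected[self.active_set] = True
        return pd.DataFrame(
            {"feature": names, "selected": selected, "beta_hat": self.beta_hat}
        )


def fit_sgpls(
    X: np.ndarray,
    y_binary: np.ndarray,
    delta: float,
    r: int,
    kappa: float = 0.5,
    clinical_design: np.ndarray | None = None,
    *,
    eps: float = 1e-5,
    max_iter: int = 100,
) -> SGPLSFit:
    """Fit SGPLS (clinical_design=None) or SGPLSOffClin.

    Outer loop: IRLS-style update of (eta, pi, W, ytilde) at the current
    beta; sparse weight via :func:`solve_sparse_weight`; active-set union;
    PLS (weighted PLS in the offset variant) of ytilde on the active
    columns; beta updated from the PLS coefficients.  Stops when the
    max-absolute coefficient change drops below ``eps`` or at ``max_iter``
    (flagged).

    Two safeguards handle p >> n quasi-separation, where the binomial MLE
    does not exist and raw IRLS iterates diverge: pi is clipped to
    [1e-5, 1-1e-5] so the pseudo-response stays bounded, and the training
    log-likelihood is monitored across outer iterations — an update that
    decreases it is rejected, the previous iterate is kept, and iteration
    stops (flagged as not converged).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y_binary, dtype=float).ravel()
    n, p = X.shape
    if y.size != n:
        raise ValueError("X and y have different numbers of rows")
    if np.unique(y).size < 2:
        raise ValueError("y must contain both classes")
    if not (0.0 < delta < 1.0):
        raise ValueError(f"delta must be in (0, 1), got {delta}")
    if r < 1:
        raise ValueError(f"r must be >= 1, got {r}")

    clinical = None
    eta_clin = np.zeros(n)
    if clinical_design is not None:
        clinical = fit_logistic(clinical_design, y)
        eta_clin = clinical.linear_predictor

    beta = np.zeros(p)
    b0 = 0.0
    active = np.zeros(p, dtype=bool)
    converged = False
    delta_beta = np.inf
    pls_fit: PLSFit | None = None
    ll_prev = -np.inf
    prev_state = (beta, b0)
    it = 0
    for it in range(1, max_iter + 1):
        eta_x = b0 + X @ beta
        ll = binomial_loglik(y, eta_clin + eta_x)
        if not np.isfinite(ll) or ll < ll_prev - 1e-8:
            beta, b0 = prev_state  # likelihood dropped: keep previous iterate
            break
        prev_state = (beta, b0)
        ll_prev = ll
        pi = np.clip(expit(eta_clin + eta_x), _PI_CLIP, 1.0 - _PI_CLIP)
        w = np.clip(pi * (1.0 - pi), _W_FLOOR, None)
        ytilde = eta_x + (y - pi) / w  # offset excluded from pseudo-response
        sol = solve_sparse_weight(X, w, ytilde, delta, kappa)
        active |= (sol.c_hat != 0.0) | (beta != 0.0)
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break  # thresholding removed everything: keep the current fit
        XA = X[:, idx]
        r_eff = min(r, idx.size, n - 1)
        if clinical is None:
            pls_fit = fit_pls(XA, ytilde, r_eff)
        else:
            pls_fit = fit_pls(XA, ytilde, r_eff, weight_diag=w)
        beta_new = np.zeros(p)
        beta_new[idx] = pls_fit.beta
        b0_new = pls_fit.intercept
        if not (np.all(np.isfinite(beta_new)) and np.isfinite(b0_new)):
            break  # diverged: keep the last finite iterate, flagged
        delta_beta = max(
            float(np.max(np.abs(beta_new - beta))), abs(b0_new - b0)
        )
        beta, b0 = beta_new, b0_new
        if delta_beta < eps:
            converged = True
            break
    return SGPLSFit(
        beta_hat=beta,
        intercept=float(b0),
        active_set=np.flatnonzero(active),
        r=r,
        delta=float(delta),
        kappa=float(kappa),
        clinical=clinical,
        n_outer_iterations=it,
        converged=converged,
        final_delta_beta=float(delta_beta),
        pls=pls_fit,
    )


def predict_sgpls(
    fit: SGPLSFit, X_new: np.ndarray, Z_new: np.ndarray | None = None
) -> np.ndarray:
    """Class-1 probabilities from a fitted SGPLS / SGPLSOffClin model."""
    return expit(fit.linear_predictor(X_new, Z_new))
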