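"""(Weighted) partial least squares, ridge PLS, and the clinical-offset variant.

PLS components t_h = X w_h maximize cov^2(t_h, y) under ||w_h|| = 1 with
mutually orthogonal scores; weighted PLS (WPLS) maximizes
cov^2(W^{1/2} t_h, W^{1/2} y).  Extraction is NIPALS-style on the
square-root-weight transformed, weighted-mean-centered data, with
X-deflation; this reproduces the stated objective and orthogonality
constraints and, for the unweighted case, coincides with standard PLS1.

RPLS chains ridge-IRLS and WPLS: ridge-IRLS supplies the converged
pseudo-response ytilde* and weight diagonal W*, and WPLS regresses ytilde*
on X with those weights, giving a linear classifier for the binary response.
RPLSOffClin first fits the clinical logistic model, feeds its linear
predictor eta_clin into ridge-IRLS as an offset, and runs WPLS on the
offset-adjusted pseudo-response; predictions add eta_clin back.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .glm import LogisticFit, PseudoResponse, fit_logistic, ridge_irls

__all__ = ["PLSFit", "RPLSFit", "fit_pls", "fit_rpls", "predict_rpls"]


@dataclass
class PLSFit:
    """A fitted (weighted) PLS1 regression."""

    weights: np.ndarray  # (p, r) unit-norm direction vectors w_h
    x_scores: np.ndarray  # (n, r) scores on the transformed data
    x_loadings: np.ndarray  # (p, r)
    y_loadings: np.ndarray  # (r,) response loadings c_h
    beta: np.ndarray  # (p,) composite coefficients
    intercept: float
    x_mean: np.ndarray
    y_mean: float
    r: int
    weight_diag: np.ndarray | None = None

    def predict(self, X_new: np.ndarray) -> np.ndarray:
        X_new = np.asarray(X_new, dtype=float)
        if X_new.shape[1] != self.beta.size:
            raise ValueError(
                f"X has {X_new.shape[1]} columns, fit expects {self.beta.size}"
            )
        return self.intercept + X_new @ self.beta

    def coef_path(self) -> tuple[np.ndarray, np.ndarray]:
        """Composite coefficients and intercepts for every leading-k submodel.

        Returns ``(betas, intercepts)`` with ``betas[k-1]`` the coefficient
        vector of the k-component model; useful for evaluating nested
        component counts from a single extraction.
        """
        betas = np.zeros((self.r, self.beta.size))
        intercepts = np.zeros(self.r)
        for k in range(1, self.r + 1):
            W = self.weights[:, :k]
            P = self.x_loadings[:, :k]
            c = self.y_loadings[:k]
            beta = W @ np.linalg.solve(P.T @ W, c)
            betas[k - 1] = beta
            intercepts[k - 1] = self.y_mean - self.x_mean @ beta
        return betas, intercepts

    def to_table(self, names: list[str] | None = None):
        import pandas as pd

        if names is None:
            names = [f"m{j + 1}" for j in range(self.beta.size)]
        return pd.DataFrame({"feature": names, "beta_pls": self.beta})


def fit_pls(
    X: np.ndarray,
    y_continuous: np.ndarray,
    r: int,
    weight_diag: np.ndarray | None = None,
) -> PLSFit:
    """Extract ``r`` (weighted) PLS components of a continuous response.

    With weights W, centering uses W-weighted means and the problem is
    mapped to plain PLS on (W^{1/2} X_c, W^{1/2} y_c); Euclidean score
    orthogonality there is W-orthogonality of the original-scale scores.
    Extraction stops early (r reduced) if X is deflated to numerical zero.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y_continuous, dtype=float).ravel()
    n, p = X.shape
    if y.size != n:
        raise ValueError("X and y have different numbers of rows")
    if not 1 <= r <= min(n - 1, p):
        raise ValueError(f"r must be in [1, min(n-1, p)] = [1, {min(n - 1, p)}], got {r}")
    if weight_diag is not None:
        w = np.asarray(weight_diag, dtype=float).ravel()
        if w.size != n:
            raise ValueError("weight_diag must have one entry per sample")
        if np.any(w <= 0):
            raise ValueError("weights must be strictly positive")
    else:
        w = np.ones(n)
    wn = w / w.sum()
    x_mean = wn @ X
    y_mean = float(wn @ y)
    if np.allclose(y, y_mean):
        raise ValueError("y has zero variance; PLS direction undefined")
    sw = np.sqrt(w)
    Xt = sw[:, None] * (X - x_mean)
    yt = sw * (y - y_mean)

    Wmat = np.zeros((p, r))
    T = np.zeros((n, r))
    P = np.zeros((p, r))
    c = np.zeros(r)
    r_eff = 0
    for h in range(r):
        wvec = Xt.T @ yt
        norm = np.linalg.norm(wvec)
        if norm < 1e-12:
            break  # X deflated to zero: no further components
        omega = wvec / norm
        t = Xt @ omega
        tt = float(t @ t)
        if tt < 1e-24:
            break
        ch = float(t @ yt) / tt
        pload = Xt.T @ t / tt
        Xt = Xt - np.outer(t, pload)
        Wmat[:, h] = omega
        T[:, h] = t
        P[:, h] = pload
        c[h] = ch
        r_eff = h + 1
    if r_eff == 0:
        raise ValueError("no PLS direction: X'Wy is numerically zero")
    Wmat, T, P, c = Wmat[:, :r_eff], T[:, :r_eff], P[:, :r_eff], c[:r_eff]
    beta = Wmat @ np.linalg.solve(P.T @ Wmat, c)
    intercept = y_mean - x_mean @ beta
    return PLSFit(
        weights=Wmat,
        x_scores=T,
        x_loadings=P,
        y_loadings=c,
        beta=beta,
        intercept=float(intercept),
        x_mean=x_mean,
        y_mean=y_mean,
        r=r_eff,
        weight_diag=None if weight_diag is None else w,
    )


@dataclass
class RPLSFit:
    """RPLS or RPLSOffClin fitted state."""

    pls: PLSFit
    pseudo: PseudoResponse
    clinical: LogisticFit | None
    lam: float
    r: int

    @property
    def beta_pls(self) -> np.ndarray:
        return self.pls.beta

    def linear_predictor(
        self, X_new: np.ndarray, Z_new: np.ndarray | None = None
    ) -> np.ndarray:
        eta = self.pls.predict(X_new)
        if self.clinical is not None:
            if Z_new is None:
                raise ValueError(
                    "fit has a clinical offset part; Z_new is required"
                )
            eta = eta + self.clinical.predict_linear(Z_new)
        return eta


def fit_rpls(
    X: np.ndarray,
    y_binary: np.ndarray,
    lam: float,
    r: int,
    clinical_design: np.ndarray | None = None,
    *,
    sigma2: np.ndarray | None = None,
    irls_tol: float = 1e-6,
    irls_max_iter: int = 100,
) -> RPLSFit:
    """Fit RPLS (clinical_design=None) or RPLSOffClin.

    Plain RPLS: ridge-IRLS with zero offset, then WPLS of ytilde* on X with
    weights W*.  RPLSOffClin: (1) logistic regression on the clinical block
    gives eta_clin, (2) ridge-IRLS with offset eta_clin, (3) WPLS of the
    offset-adjusted pseudo-response on X with weights W*.
    """
    clinical = None
    offset = None
    if clinical_design is not None:
        clinical = fit_logistic(clinical_design, y_binary)
        offset = clinical.linear_predictor
    pseudo = ridge_irls(
        X,
        y_binary,
        lam,
        sigma2=sigma2,
        offset=offset,
        tol=irls_tol,
        max_iter=irls_max_iter,
    )
    pls = fit_pls(X, pseudo.y_tilde_star, r, weight_diag=pseudo.w_star)
    return RPLSFit(pls=pls, pseudo=pseudo, clinical=clinical, lam=float(lam), r=pls.r)


def predict_rpls(
    fit: RPLSFit, X_new: np.ndarray, Z_new: np.ndarray | None = None
) -> np.ndarray:
    """Class-1 probabilities from a fitted RPLS / RPLSOffClin model."""
    return expit(fit.linear_predictor(X_new, Z_new))
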