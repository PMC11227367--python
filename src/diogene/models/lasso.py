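"""L1-penalized linear regression with per-variable penalty factors.

The model solves

    min_beta  (1 / 2n) ||y - X beta||^2 + lambda * sum_j pf_j |beta_j|

where pf_j >= 0 is the penalty factor of variable j. A finite pf is handled
by the standard rescaling trick (divide column j by pf_j, fit a plain
LASSO, divide the coefficient back); an infinite pf removes the variable
from the design. The global lambda is selected by k-fold cross-validation
over a log-spaced path anchored at the smallest lambda that zeroes every
coefficient, the same construction glmnet uses.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.linear_model import lasso_path
from sklearn.model_selection import KFold
from sklearn.utils.validation import check_is_fitted

__all__ = ["WeightedLasso"]


class WeightedLasso(RegressorMixin, BaseEstimator):
    """LASSO with per-variable penalty factors and internal lambda CV.

    Parameters
    ----------
    penalty_factor : array-like of shape (n_features,) or None
        Nonnegative multipliers of the L1 penalty per variable; ``None``
        means all ones (plain LASSO). ``numpy.inf`` excludes a variable.
    n_lambdas : int, default 100
        Length of the log-spaced regularization path.
    lambda_min_ratio : float, default 1e-3
        Smallest lambda as a fraction of lambda_max.
    cv : int, default 5
        Number of cross-validation folds for lambda selection.
    random_state : int, numpy SeedSequence, or None
        Seeds the CV partitioning.

    Attributes
    ----------
    coef_ : ndarray of shape (n_features,)
        Coefficients on the original (unscaled) design; exactly 0 for
        excluded variables.
    intercept_ : float
    lambda_ : float
        Selected regularization strength.
    lambdas_ : ndarray
        The full path, decreasing.
    cv_mse_path_ : ndarray of shape (n_lambdas,)
        Mean validation MSE along the path.
    """

    def __init__(
        self,
        penalty_factor=None,
        n_lambdas: int = 100,
        lambda_min_ratio: float = 1e-3,
        cv: int = 5,
        max_iter: int = 5000,
        random_state=None,
    ):
        self.penalty_factor = penalty_factor
        self.n_lambdas = n_lambdas
        self.lambda_min_ratio = lambda_min_ratio
        self.cv = cv
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        n, p = X.shape
        self.n_features_in_ = p
        if n < self.cv:
            raise ValueError(f"need at least cv={self.cv} samples, got {n}")
        if self.penalty_factor is None:
            pf = np.ones(p)
        else:
            pf = np.asarray(self.penalty_factor, dtype=float)
            if pf.shape != (p,):
                raise ValueError("penalty_factor length must match n_features")
            if (pf <= 0).any():
                raise ValueError("penalty factors must be positive (inf to exclude)")
        active = np.isfinite(pf)
        if not active.any():
            raise ValueError("no admissible regulator: every variable is excluded")
        self.active_ = active

        Xs = X[:, active] / pf[active]

        # glmnet-style path: lambda_max is the smallest lambda with all-zero
        # coefficients on the centered design
        xm, ym = Xs.mean(axis=0), y.mean()
        Xc, yc = Xs - xm, y - ym
        lam_max = float(np.max(np.abs(Xc.T @ yc)) / n)
        if lam_max <= 0:
            lam_max = 1e-3
        self.lambdas_ = np.logspace(
            np.log10(lam_max), np.log10(lam_max * self.lambda_min_ratio), self.n_lambdas
        )

        if isinstance(self.random_state, np.random.SeedSequence):
            seed = int(self.random_state.generate_state(1)[0])
        else:
            seed = self.random_state
        kf = KFold(n_splits=self.cv, shuffle=True, random_state=seed)
        cv_err = np.zeros((self.cv, self.n_lambdas))
        for f, (tr, va) in enumerate(kf.split(Xs)):
            xm_f, ym_f = Xs[tr].mean(axis=0), y[tr].mean()
            _, coefs, _ = lasso_path(
                Xs[tr] - xm_f, y[tr] - ym_f, alphas=self.lambdas_, max_iter=self.max_iter
            )
            pred = (Xs[va] - xm_f) @ coefs + ym_f  # (n_va, n_lambdas)
            cv_err[f] = np.mean((y[va][:, None] - pred) ** 2, axis=0)
        self.cv_mse_path_ = cv_err.mean(axis=0)
        # ties resolved toward the larger lambda (sparser model): the path
        # is decreasing and argmin takes the first minimum
        best = int(np.argmin(self.cv_mse_path_))
        self.lambda_ = float(self.lambdas_[best])

        _, coefs, _ = lasso_path(Xc, yc, alphas=self.lambdas_, max_iter=self.max_iter)
        beta_scaled = coefs[:, best]
        coef = np.zeros(p)
        coef[active] = beta_scaled / pf[active]
        self.coef_ = coef
        self.intercept_ = float(ym - xm @ beta_scaled)
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        X = np.asarray(X, dtype=float)
        return X @ self.coef_ + self.intercept_

    def coef_path(self, X, y):
        """Full coefficient path on the (centered) data, original scale.

        Returns ``(lambdas, coefs)`` with ``coefs`` of shape
        (n_features, n_lambdas); useful for boundary-equivalence checks.
        """
        check_is_fitted(self, "coef_")
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        pf = (
            np.ones(self.n_features_in_)
            if self.penalty_factor is None
            else np.asarray(self.penalty_factor, dtype=float)
        )
        Xs = X[:, self.active_] / pf[self.active_]
        Xc, yc = Xs - Xs.mean(axis=0), y - y.mean()
        _, coefs, _ = lasso_path(Xc, yc, alphas=self.lambdas_, max_iter=self.max_iter)
        out = np.zeros((self.n_features_in_, self.n_lambdas))
        out[self.active_] = coefs / pf[self.active_][:, None]
        return self.lambdas_, out
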