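"""Modified partial least squares (MPLS) regression.

MPLS is the PLS1 variant used by near-infrared calibration software in
which, after each latent factor has been extracted and deflated, the
X-residual at every wavelength is standardized (divided by the standard
deviation of the residuals at that wavelength) before the next factor is
computed. The stored per-factor scale vectors are back-accumulated so that
prediction remains a single affine map of the pretreated spectrum,

    y_hat = beta0 + sum_j beta_j * x_{lambda_j},

whose wavelength-domain coefficients ``beta`` localise the spectral regions
driving each analyte.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["MPLSRegression", "MPLSResults", "cross_validate", "CrossValidation"]


class MPLSRegression:
    """Modified PLS1 model of a single analyte on pretreated spectra.

    Parameters
    ----------
    endog : ndarray, shape (n,)
        Reference concentrations.
    exog : ndarray, shape (n, p)
        Pretreated spectra.
    wavelengths : ndarray, optional
        Effective wavelength grid (for the beta-coefficient profile).
    standardize_residuals : bool
        If False the residual scaling step is skipped and the model reduces
        to ordinary PLS1 (useful as a cross-check).
    """

    def __init__(self, endog, exog, wavelengths=None, standardize_residuals=True):
        self.endog = np.asarray(endog, dtype=float).ravel()
        self.exog = np.asarray(exog, dtype=float)
        if self.exog.ndim != 2 or self.exog.shape[0] != self.endog.size:
            raise ValueError("exog must be (n, p) aligned with endog")
        if wavelengths is None:
            wavelengths = np.arange(self.exog.shape[1], dtype=float)
        self.wavelengths = np.asarray(wavelengths, dtype=float)
        if self.wavelengths.size != self.exog.shape[1]:
            raise ValueError("wavelengths must match the number of spectral variables")
        self.standardize_residuals = standardize_residuals

    @property
    def nobs(self) -> int:
        return self.endog.size

    def fit(self, n_factors: int) -> "MPLSResults":
        n, p = self.exog.shape
        if n_factors < 0 or n_factors > min(n - 1, p):
            raise ValueError(f"n_factors must be in [0, {min(n - 1, p)}]")
        y = self.endog
        if n_factors > 0 and np.std(y) == 0:
            raise ValueError("zero-variance target: nothing to regress on")
        x_mean = self.exog.mean(axis=0)
        y_mean = float(y.mean())
        X = self.exog - x_mean
        r = y - y_mean
        W = np.zeros((n_factors, p))
        P = np.zeros((n_factors, p))
        S = np.ones((n_factors, p))
        q = np.zeros(n_factors)
        for k in range(n_factors):
            w = X.T @ r
            norm = np.linalg.norm(w)
            if norm <= 1e-14:
                # Residual target orthogonal to X: stop with a null factor.
                W, P, S, q = W[:k], P[:k], S[:k], q[:k]
                break
            w /= norm
            t = X @ w
            tt = float(t @ t)
            pk = X.T @ t / tt
            qk = float(r @ t) / tt
            X = X - np.outer(t, pk)
            r = r - qk * t
            W[k], P[k], q[k] = w, pk, qk
            if self.standardize_residuals:
                s = X.std(axis=0, ddof=1)
                s[s <= 1e-14] = 1.0
                S[k] = s
                X = X / s
        res = MPLSResults(
            model=self,
            x_mean=x_mean,
            y_mean=y_mean,
            weights=W,
            loadings=P,
            scales=S,
            q=q,
        )
        res._finalize()
        return res


@dataclass
class MPLSResults:
    """Fitted MPLS model: factors, residual scales and beta coefficients."""

    model: MPLSRegression
    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray   # (k, p) factor weights, in the scaled space of each step
    loadings: np.ndarray  # (k, p)
    scales: np.ndarray    # (k, p) residual SDs applied after each factor
    q: np.ndarray         # (k,) y-loadings
    beta0: float = 0.0
    beta: np.ndarray = field(default=None)
    fittedvalues: np.ndarray = field(default=None)

    @property
    def n_factors(self) -> int:
        return len(self.q)

    @property
    def wavelengths(self) -> np.ndarray:
        return self.model.wavelengths

    def _finalize(self) -> None:
        p = self.x_mean.size
        # The prediction recursion is affine in the input spectrum; recover
        # beta by propagating the identity matrix through it.
        basis = np.eye(p)
        zero = np.zeros((1, p))
        f_basis = self._predict_centered(basis)
        f_zero = self._predict_centered(zero)[0]
        self.beta = f_basis - f_zero
        self.beta0 = float(self.y_mean + f_zero - self.beta @ self.x_mean)
        self.fittedvalues = self.predict(self.model.exog)

    def _predict_centered(self, Z: np.ndarray) -> np.ndarray:
        """Accumulated factor contributions for already-centered spectra."""
        Z = Z.copy()
        yhat = np.zeros(Z.shape[0])
        for k in range(self.n_factors):
            t = Z @ self.weights[k]
            yhat += self.q[k] * t
            Z = (Z - np.outer(t, self.loadings[k])) / self.scales[k]
        return yhat

    def predict(self, exog: np.ndarray, n_factors: int | None = None) -> np.ndarray:
        """Predict concentrations; optionally truncate to fewer factors."""
        X = np.asarray(exog, dtype=float)
        squeeze = X.ndim == 1
        X = np.atleast_2d(X)
        if X.shape[1] != self.x_mean.size:
            raise ValueError("spectrum length does not match the model grid")
        if n_factors is None or n_factors >= self.n_factors:
            out = self.beta0 + X @ self.beta
        else:
            Z = X - self.x_mean
            yhat = np.full(X.shape[0], self.y_mean)
            for k in range(n_factors):
                t = Z @ self.weights[k]
                yhat += self.q[k] * t
                Z = (Z - np.outer(t, self.loadings[k])) / self.scales[k]
            out = yhat
        return out[0] if squeeze else out

    def predict_path(self, exog: np.ndarray) -> np.ndarray:
        """(n, k+1) predictions using 0, 1, ..., k factors (for SECV curves)."""
        X = np.atleast_2d(np.asarray(exog, dtype=float))
        Z = X - self.x_mean
        path = np.empty((X.shape[0], self.n_factors + 1))
        yhat = np.full(X.shape[0], self.y_mean)
        path[:, 0] = yhat
        for k in range(self.n_factors):
            t = Z @ self.weights[k]
            yhat = yhat + self.q[k] * t
            Z = (Z - np.outer(t, self.loadings[k])) / self.scales[k]
            path[:, k + 1] = yhat
        return path

    @property
    def resid(self) -> np.ndarray:
        return self.model.endog - self.fittedvalues

    def beta_profile(self) -> tuple[np.ndarray, np.ndarray]:
        """(wavelength, beta) pairs on the effective grid."""
        return self.wavelengths, self.beta

    def beta_peaks(self, n_peaks: int = 5) -> np.ndarray:
        """Wavelengths of the largest |beta| local maxima, ranked."""
        b = np.abs(self.beta)
        interior = (b[1:-1] >= b[:-2]) & (b[1:-1] >= b[2:])
        idx = np.flatnonzero(interior) + 1
        if idx.size == 0:
            idx = np.array([int(np.argmax(b))])
        order = np.argsort(b[idx])[::-1]
        return self.wavelengths[idx[order][:n_peaks]]

    def plot_beta(self, ax=None):  # pragma: no cover - thin plotting helper
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.wavelengths, self.beta, lw=0.8)
        ax.set_xlabel("wavelength (nm)")
        ax.set_ylabel("beta coefficient")
        return ax

    def summary(self) -> str:
        e = self.resid
        lines = [
            "MPLS regression results",
            f"  n obs:            {self.model.nobs}",
            f"  n factors:        {self.n_factors}",
            f"  intercept beta0:  {self.beta0:.6g}",
            f"  |beta| max:       {np.abs(self.beta).max():.6g}",
            f"  RMS residual:     {np.sqrt(np.mean(e ** 2)):.6g}",
        ]
        return "\n".join(lines)


@dataclass
class CrossValidation:
    """Cross-validation SECV curve and the chosen factor count."""

    secv_by_factors: np.ndarray  # index k -> SECV with k factors (index 0 = mean model)
    n_factors: int
    folds: list
    cv_predictions: np.ndarray   # held-out predictions at the chosen factor count

    @property
    def secv(self) -> float:
        return float(self.secv_by_factors[self.n_factors])


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    n_groups: int = 4,
    max_factors: int = 16,
    seed: int = 0,
) -> CrossValidation:
    """Grouped cross-validation of the MPLS factor count.

    The calibration set is shuffled with the given seed and cut into
    ``n_groups`` contiguous groups; each group is predicted from a model
    built on the others. SECV(k) = sqrt(mean of all held-out squared errors
    with k factors); the chosen factor count minimises SECV, ties broken
    toward fewer factors.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if n_groups < 2:
        raise ValueError("need at least 2 cross-validation groups")
    if max_factors < 1:
        raise ValueError("max_factors must be >= 1")
    if n // n_groups < 2:
        raise ValueError("cross-validation groups would have fewer than 2 samples")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = [np.sort(f) for f in np.array_split(order, n_groups)]
    kmax = min(max_factors, min(n - len(f) for f in folds) - 1, X.shape[1])
    press = np.zeros(kmax + 1)
    cv_path = np.empty((n, kmax + 1))
    for f in folds:
        train = np.setdiff1d(np.arange(n), f)
        res = MPLSRegression(y[train], X[train]).fit(kmax)
        path = res.predict_path(X[f])[:, : kmax + 1]
        if path.shape[1] < kmax + 1:  # early stop in degenerate fits
            path = np.pad(path, ((0, 0), (0, kmax + 1 - path.shape[1])), mode="edge")
        cv_path[f] = path
        press += ((path - y[f, None]) ** 2).sum(axis=0)
    secv = np.sqrt(press / n)
    # argmin over k >= 1, ties toward fewer factors.
    best = 1 + int(np.argmin(secv[1:]))
    return CrossValidation(
        secv_by_factors=secv,
        n_factors=best,
        folds=folds,
        cv_predictions=cv_path[:, best],
    )
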