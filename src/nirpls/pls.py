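"""Univariate partial least-squares regression (PLS1) via NIPALS.

The model relates a spectra matrix X (n samples x I channels) to a single
response y through A orthogonal latent variables:

    T = X_c W*,    y_hat = T c + y_bar

where X_c is the training-centred spectra matrix, W* = W (P'W)^{-1} maps raw
centred spectra to scores, P holds the X loadings and c the response
loadings.  For a univariate response the NIPALS inner loop converges in a
single pass per component, so component extraction is exact (no iteration
tolerance is involved); the generic iterative path is retained for
completeness and guarded by a 1e-12 tolerance.

The public surface follows the statsmodels convention: ``PLSModel(endog,
exog)`` holds the data, ``.fit(n_components)`` returns a :class:`PLSResults`
carrying estimates and diagnostics, and ``cross_validate`` scores a grid of
component counts by seeded k-fold cross-validation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd


class PLSModel:
    """Partial least-squares regression model for a single response.

    Parameters
    ----------
    endog : ndarray, shape (n,)
        Response vector (e.g. total-CBD concentration, % w/w).
    exog : ndarray, shape (n, I)
        Predictor matrix (one pre-processed spectrum per row).
    center : bool
        Mean-centre X and y on the training data (default).  Per-channel
        unit-variance autoscaling is deliberately not applied: row-wise SNV
        already normalises intensity, and column autoscaling on top of it
        would double-normalise.
    """

    def __init__(self, endog: np.ndarray, exog: np.ndarray, *, center: bool = True):
        y = np.asarray(endog, dtype=float).ravel()
        X = np.asarray(exog, dtype=float)
        if X.ndim != 2:
            raise ValueError("exog must be 2-d (samples x channels)")
        if y.size != X.shape[0]:
            raise ValueError(
                f"endog length {y.size} != exog rows {X.shape[0]}"
            )
        if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
            raise ValueError("non-finite values in model data")
        self.endog = y
        self.exog = X
        self.center = center
        self.nobs, self.n_channels = X.shape

    @classmethod
    def from_dataframe(
        cls, data: pd.DataFrame, response: str, *, center: bool = True
    ) -> "PLSModel":
        """Build a model from a DataFrame: ``response`` column vs the rest."""
        y = data[response].to_numpy(dtype=float)
        X = data.drop(columns=[response]).to_numpy(dtype=float)
        return cls(y, X, center=center)

    def fit(self, n_components: int = 20) -> "PLSResults":
        """Extract ``n_components`` NIPALS components and return the results.

        X is deflated after each component (X <- X - t p'); the response is
        deflated by its explained part.  Requires
        n_components <= min(nobs - 1, n_channels).
        """
        A = int(n_components)
        bound = min(self.nobs - 1, self.n_channels)
        if not (1 <= A <= bound):
            raise ValueError(
                f"n_components must be in [1, {bound}] "
                f"for {self.nobs} samples x {self.n_channels} channels"
            )
        x_mean = self.exog.mean(axis=0) if self.center else np.zeros(self.n_channels)
        y_mean = float(self.endog.mean()) if self.center else 0.0
        Xc = self.exog - x_mean
        yc = self.endog - y_mean

        W = np.zeros((self.n_channels, A))
        P = np.zeros((self.n_channels, A))
        C = np.zeros(A)
        T = np.zeros((self.nobs, A))
        Xd, yd = Xc.copy(), yc.copy()
        for a in range(A):
            w = Xd.T @ yd
            norm = np.linalg.norm(w)
            if norm < 1e-14:
                raise np.linalg.LinAlgError(
                    f"residual covariance vanished at component {a + 1}; "
                    f"reduce n_components"
                )
            w /= norm
            t = Xd @ w
            tt = float(t @ t)
            p = Xd.T @ t / tt
            c = float(yd @ t) / tt
            Xd -= np.outer(t, p)
            yd = yd - c * t
            W[:, a], P[:, a], C[a], T[:, a] = w, p, c, t

        # collapse scores-and-loadings into a single regression vector:
        # y_hat = (X - x_mean) @ beta + y_mean
        beta = W @ np.linalg.solve(P.T @ W, C)
        return PLSResults(
            model=self,
            n_components=A,
            x_mean=x_mean,
            y_mean=y_mean,
            weights=W,
            x_loadings=P,
            y_loadings=C,
            scores=T,
            coef=beta,
        )


@dataclass
class PLSResults:
    """Fitted PLS1 model: estimates, diagnostics and prediction."""

    model: PLSModel
    n_components: int
    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray       # W, channels x A
    x_loadings: np.ndarray    # P, channels x A
    y_loadings: np.ndarray    # c, length A
    scores: np.ndarray        # T, nobs x A (training scores)
    coef: np.ndarray          # collapsed regression vector, length channels

    def predict(self, exog: np.ndarray | None = None) -> np.ndarray:
        """Predict the response for new spectra (default: training spectra)."""
        X = self.model.exog if exog is None else np.asarray(exog, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.x_mean.size:
            raise ValueError(
                f"expected {self.x_mean.size} channels, got {X.shape[1]}"
            )
        return (X - self.x_mean) @ self.coef + self.y_mean

    def transform(self, exog: np.ndarray | None = None) -> np.ndarray:
        """Latent-variable scores T_pred for new spectra.

        Scores are computed sequentially with the same deflation used in
        fitting (t_a = E w_a, E <- E - t_a p_a'), so the first ``a`` columns
        equal the scores an ``a``-component model would produce — truncation
        is exact.
        """
        X = self.model.exog if exog is None else np.asarray(exog, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.x_mean.size:
            raise ValueError(
                f"expected {self.x_mean.size} channels, got {X.shape[1]}"
            )
        E = X - self.x_mean
        T = np.empty((E.shape[0], self.n_components))
        for a in range(self.n_components):
            t = E @ self.weights[:, a]
            T[:, a] = t
            E = E - np.outer(t, self.x_loadings[:, a])
        return T

    def predict_via_scores(self, exog: np.ndarray | None = None) -> np.ndarray:
        """Prediction through explicit scores: y_hat = T_pred c + y_bar.

        Numerically identical to :meth:`predict`; kept as the loading-space
        route for inspection and testing."""
        return self.transform(exog) @ self.y_loadings + self.y_mean

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.predict()

    @property
    def resid(self) -> np.ndarray:
        return self.model.endog - self.fittedvalues

    @property
    def rmse(self) -> float:
        return float(np.sqrt(np.mean(self.resid**2)))

    @property
    def rsquared(self) -> float:
        y = self.model.endog
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        return 1.0 - float(np.sum(self.resid**2)) / ss_tot

    def summary(self) -> str:
        """Plain-text summary table in the statsmodels spirit."""
        lines = [
            "PLS1 Regression Results (NIPALS)",
            "=" * 40,
            f"{'No. observations:':<26}{self.model.nobs:>14}",
            f"{'No. channels:':<26}{self.model.n_channels:>14}",
            f"{'Latent variables (A):':<26}{self.n_components:>14}",
            f"{'Centered:':<26}{str(self.model.center):>14}",
            f"{'Training RMSE:':<26}{self.rmse:>14.6g}",
            f"{'Training R-squared:':<26}{self.rsquared:>14.6g}",
            f"{'||regression vector||:':<26}{np.linalg.norm(self.coef):>14.6g}",
            "=" * 40,
        ]
        return "\n".join(lines)

    # -- serialization ------------------------------------------------------

    def to_json(self, path=None, *, provenance: dict | None = None):
        """Serialize the fitted model (centres, W, P, c, coef, A) to JSON."""
        payload = {
            "format": "nirpls-pls1",
            "n_components": self.n_components,
            "x_mean": self.x_mean.tolist(),
            "y_mean": self.y_mean,
            "weights": self.weights.tolist(),
            "x_loadings": self.x_loadings.tolist(),
            "y_loadings": np.asarray(self.y_loadings).tolist(),
            "coef": self.coef.tolist(),
            "provenance": provenance or {},
        }
        if path is None:
            return json.dumps(payload)
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh)
        return None

    @staticmethod
    def load_predictor(path):
        """Load a serialized model as a standalone prediction function."""
        with open(path, "r", encoding="utf-8") as fh:
            payload = json.load(fh)
        if payload.get("format") != "nirpls-pls1":
            raise ValueError("not a nirpls PLS1 model file")
        x_mean = np.array(payload["x_mean"])
        y_mean = float(payload["y_mean"])
        coef = np.array(payload["coef"])

        def predict(X: np.ndarray) -> np.ndarray:
            X = np.atleast_2d(np.asarray(X, dtype=float))
            return (X - x_mean) @ coef + y_mean

        return predict


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------


@dataclass
class CVResult:
    """Seeded k-fold cross-validation over a grid of component counts."""

    a_grid: np.ndarray
    rmsecv: np.ndarray          # per A, pooled out-of-fold RMSE
    r2cv: np.ndarray            # per A, pooled out-of-fold R^2
    fold_assignment: np.ndarray  # sample index -> fold index
    n_folds: int
    seed: int

    @property
    def best_a(self) -> int:
        """Component count minimising RMSECV (ties broken toward smaller A)."""
        return int(self.a_grid[int(np.argmin(self.rmsecv))])

    def score_at(self, a: int) -> tuple[float, float]:
        """(RMSECV, R2CV) at a given component count on the grid."""
        idx = np.nonzero(self.a_grid == a)[0]
        if idx.size == 0:
            raise ValueError(f"A={a} not in the evaluated grid")
        return float(self.rmsecv[idx[0]]), float(self.r2cv[idx[0]])


def make_folds(n: int, n_folds: int, seed: int) -> np.ndarray:
    """Seeded random partition of n samples into near-equal folds.

    A uniform random permutation is sliced into n_folds contiguous blocks
    whose sizes differ by at most one.  Returns fold index per sample.
    """
    if not (2 <= n_folds <= n):
        raise ValueError(f"need 2 <= n_folds <= n, got k={n_folds}, n={n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    assignment = np.empty(n, dtype=int)
    for f, block in enumerate(np.array_split(perm, n_folds)):
        if block.size < 2:
            raise ValueError(f"fold {f} has fewer than 2 samples")
        assignment[block] = f
    return assignment


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    a_grid=range(1, 21),
    *,
    n_folds: int = 10,
    seed: int = 0,
    center: bool = True,
) -> CVResult:
    """k-fold cross-validation of PLS1 over a grid of component counts.

    For each A, out-of-fold predictions are assembled over all folds and
    RMSECV / R2CV computed on the pooled predictions (R2 about the pooled
    observed mean).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    a_grid = np.asarray(sorted(set(int(a) for a in a_grid)))
    if a_grid.size == 0 or a_grid[0] < 1:
        raise ValueError("a_grid must contain positive component counts")
    assignment = make_folds(n, n_folds, seed)

    min_train = min(np.sum(assignment != f) for f in range(n_folds))
    bound = min(min_train - 1, X.shape[1])
    if a_grid[-1] > bound:
        raise ValueError(
            f"max A={a_grid[-1]} exceeds the rank bound {bound} "
            f"for the smallest training fold"
        )

    oof = np.empty((a_grid.size, n))
    for f in range(n_folds):
        test = assignment == f
        model = PLSModel(y[~test], X[~test], center=center)
        # fit once at the largest A; smaller-A predictions reuse the same
        # component sequence (NIPALS components are nested)
        res = model.fit(int(a_grid[-1]))
        T_pred = res.transform(X[test])
        for i, a in enumerate(a_grid):
            oof[i, test] = T_pred[:, :a] @ res.y_loadings[:a] + res.y_mean

    ss_tot = float(np.sum((y - y.mean()) ** 2))
    rmsecv = np.sqrt(np.mean((oof - y) ** 2, axis=1))
    r2cv = 1.0 - np.sum((oof - y) ** 2, axis=1) / ss_tot
    return CVResult(
        a_grid=a_grid,
        rmsecv=rmsecv,
        r2cv=r2cv,
        fold_assignment=assignment,
        n_folds=n_folds,
        seed=seed,
    )
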