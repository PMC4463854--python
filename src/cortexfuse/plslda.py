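"""Partial least squares latent-variable extraction plus linear discriminant
analysis — the classifier at the heart of the toolkit.

PLS finds orthogonal linear combinations (latent components) of the feature
matrix X that maximize covariance with the 0/1 class coding y; the number of
components K is chosen by the prediction residual sum of squares (PRESS),
the leave-one-out criterion.  LDA is then fit on the K-dimensional training
scores with per-class means and a pooled within-class covariance, and a new
observation is assigned to the class whose mean is nearer in Mahalanobis
distance.

Notes on the discriminant rule: the literature sometimes prints the rule
with an argmax over the Mahalanobis quadratic form, which would assign the
*farther* class; standard LDA (and this implementation) uses argmin, which
is the rule that maximally separates the groups.

Features are mean-centered only by default; optional autoscaling (unit
variance) is available because regional features mix units (mm and uptake
ratios) and scaling materially affects PLS.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PlsModel",
    "LdaModel",
    "PlsLdaModel",
    "fit_pls",
    "select_components_press",
    "fit_lda",
    "fit_plslda",
    "predict",
]

_RANK_TOL = 1e-10
_RIDGE_COND = 1e8
_RIDGE_SCALE = 1e-8


@dataclass
class PlsModel:
    """A fitted PLS1 (univariate-response NIPALS) model.

    Stores the centering vectors, per-component weights ``W`` (d x A),
    X-loadings ``P`` (d x A), y-loadings ``q`` (A,), inner regression
    coefficients ``beta`` (A,) relating the y-scores to the X-scores
    (u_a = beta_a t_a), the training score matrix ``T`` (N x A), and the
    optional autoscaling vector.
    """

    x_mean: np.ndarray
    y_mean: float
    x_scale: np.ndarray
    W: np.ndarray
    P: np.ndarray
    q: np.ndarray
    beta: np.ndarray
    T: np.ndarray
    A: int

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Latent scores for new observations (N x A)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != len(self.x_mean):
            raise ValueError(
                f"expected {len(self.x_mean)} features, got {X.shape[1]}"
            )
        Xc = (X - self.x_mean) / self.x_scale
        T = np.empty((X.shape[0], self.A))
        for a in range(self.A):
            t = Xc @ self.W[:, a]
            T[:, a] = t
            Xc = Xc - np.outer(t, self.P[:, a])
        return T

    def predict_y(self, X: np.ndarray, n_components: int | None = None
                  ) -> np.ndarray:
        """PLS-regression prediction of the (centered-coded) response."""
        A = self.A if n_components is None else n_components
        T = self.transform(X)[:, :A]
        return self.y_mean + T[:, :A] @ (self.beta[:A] * self.q[:A])


@dataclass
class LdaModel:
    """Gaussian LDA in latent space: class means, pooled covariance, priors."""

    means: np.ndarray  # (2, K)
    cov: np.ndarray  # (K, K) pooled within-class
    priors: np.ndarray  # (2,)
    _cov_inv: np.ndarray | None = field(default=None, repr=False)

    def cov_inv(self) -> np.ndarray:
        if self._cov_inv is None:
            self._cov_inv = np.linalg.inv(self.cov)
        return self._cov_inv


@dataclass
class PlsLdaModel:
    """Composed classifier: PLS projection followed by LDA in latent space."""

    pls: PlsModel
    lda: LdaModel
    n_components: int

    def __post_init__(self) -> None:
        if self.n_components != self.pls.A:
            raise ValueError("selected component count must match the PLS model")

    # -- serialization ----------------------------------------------------
    def to_json(self) -> str:
        def arr(a):
            return np.asarray(a).tolist()

        payload = {
            "pls": {
                "x_mean": arr(self.pls.x_mean),
                "y_mean": self.pls.y_mean,
                "x_scale": arr(self.pls.x_scale),
                "W": arr(self.pls.W),
                "P": arr(self.pls.P),
                "q": arr(self.pls.q),
                "beta": arr(self.pls.beta),
                "T": arr(self.pls.T),
                "A": self.pls.A,
            },
            "lda": {
                "means": arr(self.lda.means),
                "cov": arr(self.lda.cov),
                "priors": arr(self.lda.priors),
            },
            "n_components": self.n_components,
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "PlsLdaModel":
        d = json.loads(text)
        pls = PlsModel(
            x_mean=np.array(d["pls"]["x_mean"]),
            y_mean=float(d["pls"]["y_mean"]),
            x_scale=np.array(d["pls"]["x_scale"]),
            W=np.array(d["pls"]["W"]),
            P=np.array(d["pls"]["P"]),
            q=np.array(d["pls"]["q"]),
            beta=np.array(d["pls"]["beta"]),
            T=np.array(d["pls"]["T"]),
            A=int(d["pls"]["A"]),
        )
        lda = LdaModel(
            means=np.array(d["lda"]["means"]),
            cov=np.array(d["lda"]["cov"]),
            priors=np.array(d["lda"]["priors"]),
        )
        return cls(pls=pls, lda=lda, n_components=int(d["n_components"]))


def _validate_xy(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != len(y):
        raise ValueError("X and y must have the same number of rows")
    if X.shape[0] < 3:
        raise ValueError("at least 3 observations are required")
    classes = np.unique(y)
    if not np.isin(classes, (0.0, 1.0)).all():
        raise ValueError("y must be coded 0/1")
    if len(classes) < 2:
        raise ValueError("both classes must be present in y")
    return X, y


def fit_pls(
    X: np.ndarray, y: np.ndarray, A: int, autoscale: bool = False
) -> PlsModel:
    """Sequential NIPALS extraction of A latent components for a 0/1 response.

    X is mean-centered (and optionally scaled to unit variance); per
    component the weight vector is w_a = X^T y / ||X^T y||, the score
    t_a = X w_a, and X is deflated by its rank-one reconstruction
    t_a p_a^T.  The inner relation u_a = beta_a t_a is stored per component.
    Components beyond the numerical rank of X are dropped with a warning.
    """
    X, y = _validate_xy(X, y)
    N, d = X.shape
    if not 1 <= A <= min(d, N - 1):
        raise ValueError(
            f"component count must be in [1, min(d, N-1)] = "
            f"[1, {min(d, N - 1)}]; got {A}"
        )
    x_mean = X.mean(axis=0)
    if autoscale:
        sd = X.std(axis=0, ddof=1)
        x_scale = np.where(sd > 0, sd, 1.0)
    else:
        x_scale = np.ones(d)
    y_mean = float(y.mean())
    Xc = (X - x_mean) / x_scale
    yc = y - y_mean
    total = float(np.abs(Xc.T @ yc).max()) or 1.0

    W = np.zeros((d, A))
    P = np.zeros((d, A))
    q = np.zeros(A)
    beta = np.zeros(A)
    T = np.zeros((N, A))
    kept = 0
    for a in range(A):
        cov = Xc.T @ yc
        norm = np.linalg.norm(cov)
        if norm <= _RANK_TOL * total:
            warnings.warn(
                f"X exhausted after {kept} components; requested {A}",
                stacklevel=2,
            )
            break
        w = cov / norm
        t = Xc @ w
        tt = float(t @ t)
        if tt <= _RANK_TOL:
            warnings.warn(
                f"X exhausted after {kept} components; requested {A}",
                stacklevel=2,
            )
            break
        p = Xc.T @ t / tt
        q_a = float(yc @ t) / tt
        # inner relation u_a = beta_a t_a: with a univariate response the
        # y-block score u_a is the current y residual (y-loading normalized
        # to 1), so the inner least-squares coefficient is q_a itself.
        W[:, a], P[:, a], T[:, a] = w, p, t
        q[a] = 1.0
        beta[a] = q_a
        Xc = Xc - np.outer(t, p)
        yc = yc - q_a * t
        kept += 1
    if kept == 0:
        raise ValueError("no usable covariance between X and y")
    return PlsModel(
        x_mean=x_mean,
        y_mean=y_mean,
        x_scale=x_scale,
        W=W[:, :kept],
        P=P[:, :kept],
        q=q[:kept],
        beta=beta[:kept],
        T=T[:, :kept],
        A=kept,
    )


def select_components_press(
    X: np.ndarray, y: np.ndarray, A_max: int, autoscale: bool = False
) -> int:
    """Choose the PLS component count by minimum leave-one-out PRESS.

    For every A in 1..A_max the prediction residual sum of squares
    ``sum_i (y_i - yhat_{-i, A})^2`` is computed by exact leave-one-out
    refitting (one PLS fit per left-out observation provides all A nested
    truncations).  Ties break to the smallest A.
    """
    X, y = _validate_xy(X, y)
    N, d = X.shape
    A_cap = min(d, N - 2)  # each LOO fold has N-1 rows
    if A_max < 1:
        raise ValueError("A_max must be at least 1")
    A_max = min(A_max, A_cap)
    press = np.zeros(A_max)
    for i in range(N):
        keep = np.ones(N, dtype=bool)
        keep[i] = False
        yi = y[keep]
        if len(np.unique(yi)) < 2:
            raise ValueError(
                f"leaving out observation {i} removes a class; "
                "cannot run PRESS"
            )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = fit_pls(X[keep], yi, A_max, autoscale=autoscale)
        # nested truncations: one transform yields predictions for every A
        t_i = model.transform(X[i])[0]
        preds = model.y_mean + np.cumsum(t_i * model.beta * model.q)
        resid2 = (y[i] - preds) ** 2
        if model.A < A_max:  # rank-exhausted folds reuse the last prediction
            resid2 = np.r_[resid2, np.full(A_max - model.A, resid2[-1])]
        press += resid2
    return int(np.argmin(press)) + 1  # argmin takes the first (smallest A)


def fit_lda(T: np.ndarray, y: np.ndarray, priors: str = "equal") -> LdaModel:
    """LDA on latent scores: class means and pooled within-class covariance.

    A ridge floor of ``1e-8 * trace / K`` is added when the pooled covariance
    is ill-conditioned (condition number above 1e8).  Priors are equal by
    default; ``priors="empirical"`` uses class frequencies.
    """
    T = np.atleast_2d(np.asarray(T, dtype=float))
    if T.ndim == 2 and T.shape[0] == 1 and len(np.asarray(y).ravel()) > 1:
        T = T.T
    y = np.asarray(y, dtype=float).ravel()
    K = T.shape[1]
    means = np.zeros((2, K))
    scatter = np.zeros((K, K))
    n = np.zeros(2)
    for g in (0, 1):
        Tg = T[y == g]
        if len(Tg) < 2:
            raise ValueError(f"class {g} needs at least 2 samples; has {len(Tg)}")
        means[g] = Tg.mean(axis=0)
        dev = Tg - means[g]
        scatter += dev.T @ dev
        n[g] = len(Tg)
    cov = scatter / (n.sum() - 2)
    tr = np.trace(cov)
    if tr <= 0:
        cov = cov + np.eye(K) * max(tr, 1.0) * _RIDGE_SCALE
    cond = np.linalg.cond(cov)
    if not np.isfinite(cond) or cond > _RIDGE_COND:
        cov = cov + np.eye(K) * _RIDGE_SCALE * max(np.trace(cov), 1e-30) / K
    cond = np.linalg.cond(cov)
    if not np.isfinite(cond) or cond > 1e14:
        raise ValueError("pooled covariance is singular even after the ridge floor")
    if priors == "equal":
        pri = np.array([0.5, 0.5])
    elif priors == "empirical":
        pri = n / n.sum()
    else:
        raise ValueError(f"unknown priors option {priors!r}")
    return LdaModel(means=means, cov=cov, priors=pri)


def _discriminant_scores(lda: LdaModel, T: np.ndarray) -> np.ndarray:
    """Signed score D(class 0) - D(class 1); positive favors class 1.

    D is the squared Mahalanobis distance to the class mean minus
    2 log prior.
    """
    T = np.atleast_2d(np.asarray(T, dtype=float))
    inv = lda.cov_inv()
    D = np.empty((T.shape[0], 2))
    for g in (0, 1):
        dev = T - lda.means[g]
        D[:, g] = np.einsum("ij,jk,ik->i", dev, inv, dev) - 2.0 * np.log(
            lda.priors[g]
        )
    return D[:, 0] - D[:, 1]


def predict(
    model: PlsLdaModel, X_new: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Classify new observations.

    Each row of ``X_new`` is centered by the training means, projected onto
    the latent components, and assigned to the class with the *smaller*
    Mahalanobis distance to its mean under the pooled covariance.  Returns
    ``(classes, scores)`` where the score is D(class 0) - D(class 1)
    (positive favors class 1); exact ties go to class 0.  A single 1-D input
    returns scalars.
    """
    X = np.asarray(X_new, dtype=float)
    single = X.ndim == 1
    T = model.pls.transform(np.atleast_2d(X))[:, : model.n_components]
    scores = _discriminant_scores(model.lda, T)
    classes = (scores > 0).astype(int)  # ties (score == 0) -> class 0
    if single:
        return int(classes[0]), float(scores[0])
    return classes, scores


def fit_plslda(
    X: np.ndarray,
    y: np.ndarray,
    A_max: int = 10,
    autoscale: bool = False,
    priors: str = "equal",
) -> PlsLdaModel:
    """Fit the full classifier: PRESS component selection, PLS, then LDA."""
    X, y = _validate_xy(X, y)
    K = select_components_press(X, y, A_max, autoscale=autoscale)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pls = fit_pls(X, y, K, autoscale=autoscale)
    lda = fit_lda(pls.T, y, priors=priors)
    return PlsLdaModel(pls=pls, lda=lda, n_components=pls.A)
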