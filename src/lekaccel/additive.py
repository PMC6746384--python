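"""Penalized additive mixed models (binomial / gaussian) on numpy.

Model: g(E[y]) = beta0 + sum_j f_j(x_j) + u_{bird}, with each f_j a cubic
B-spline of basis dimension k (default 4) under a sum-to-zero constraint and
a second-order difference penalty, and the random intercept implemented as a
ridge-penalized group-indicator block (the standard Gaussian random-effect
equivalence).  Fitting is penalized IRLS; smoothing parameters are chosen by
minimizing the GCV score n*D / (n - edf)^2 over log-lambdas.

Confidence statements use the Bayesian posterior covariance
(X'WX + S)^{-1} * phi.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.interpolate import BSpline
from scipy.special import expit
from scipy.stats import chi2 as chi2_dist
from scipy.stats import f as f_dist

__all__ = [
    "AdditiveModelFit",
    "NonConvergenceError",
    "SplineBasis",
    "fit_additive_model",
]

_MAX_PIRLS = 100
_PIRLS_TOL = 1e-9


class NonConvergenceError(RuntimeError):
    """PIRLS failed to converge; carries iteration diagnostics."""


@dataclass(frozen=True)
class SplineBasis:
    """Cubic (degree = min(3, k-1)) B-spline basis of dimension k on
    [xmin, xmax], with a sum-to-zero constraint transform Z fitted to the
    training column means."""

    name: str
    k: int
    degree: int
    knots: np.ndarray
    xmin: float
    xmax: float
    Z: np.ndarray          # (k, k-1) constraint null-space basis
    penalty: np.ndarray    # (k-1, k-1) constrained difference penalty

    @classmethod
    def build(cls, name: str, x: np.ndarray, k: int = 4) -> "SplineBasis":
        if k < 2:
            raise ValueError(f"smooth basis dimension must be >= 2, got k={k}")
        x = np.asarray(x, dtype=float)
        xmin, xmax = float(x.min()), float(x.max())
        if xmax <= xmin:
            raise ValueError(f"covariate {name!r} is degenerate (constant)")
        degree = min(3, k - 1)
        n_interior = k - degree - 1
        if n_interior > 0:
            qs = np.linspace(0, 1, n_interior + 2)[1:-1]
            interior = np.quantile(x, qs)
        else:
            interior = np.array([])
        knots = np.concatenate([
            np.full(degree + 1, xmin), interior, np.full(degree + 1, xmax)])
        raw = cls._design(knots, degree, x, xmin, xmax)
        # sum-to-zero over the data: C beta = 0 with C = column means
        c = raw.mean(axis=0, keepdims=True)
        _, _, vt = np.linalg.svd(c)
        Z = vt[1:].T                                       # (k, k-1)
        D = np.diff(np.eye(k), n=2, axis=0)                # second differences
        penalty = Z.T @ (D.T @ D) @ Z
        return cls(name=name, k=k, degree=degree, knots=knots,
                   xmin=xmin, xmax=xmax, Z=Z, penalty=penalty)

    @staticmethod
    def _design(knots: np.ndarray, degree: int, x: np.ndarray,
                xmin: float, xmax: float) -> np.ndarray:
        xc = np.clip(x, xmin, xmax)
        return BSpline.design_matrix(xc, knots, degree).toarray()

    def design(self, x: np.ndarray, *, extrapolation: str = "clamp") -> np.ndarray:
        """Constrained design matrix at new covariate values.

        ``clamp`` extends the smooth flat beyond the training range;
        ``linear`` extends it linearly using the boundary derivative.
        """
        x = np.asarray(x, dtype=float)
        B = self._design(self.knots, self.degree, x, self.xmin, self.xmax)
        if extrapolation == "linear":
            for bound, side in ((self.xmin, -1.0), (self.xmax, 1.0)):
                out = (x - bound) * side > 0
                if np.any(out):
                    Bb = self._design(self.knots, self.degree,
                                      np.array([bound]), self.xmin, self.xmax)
                    dB = self._deriv_row(bound)
                    B[out] = Bb + np.outer(x[out] - bound, dB)
        elif extrapolation != "clamp":
            raise ValueError("extrapolation must be 'clamp' or 'linear'")
        return B @ self.Z

    def _deriv_row(self, x0: float) -> np.ndarray:
        rows = np.zeros(self.k)
        for j in range(self.k):
            coef = np.zeros(self.k)
            coef[j] = 1.0
            rows[j] = BSpline(self.knots, coef, self.degree, extrapolate=True
                              ).derivative()(np.clip(x0, self.xmin, self.xmax))
        return rows


@dataclass
class TermInfo:
    name: str
    kind: str                  # "smooth" | "random"
    cols: np.ndarray           # column indices into the model matrix
    basis: SplineBasis | None = None
    levels: np.ndarray | None = None
    lambda_: float = np.nan
    edf: float = np.nan
    statistic: float = np.nan
    statistic_name: str = ""
    p_value: float = np.nan


@dataclass
class AdditiveModelFit:
    """Fitted penalized additive mixed model."""

    family: str
    response: str
    beta: np.ndarray
    cov: np.ndarray            # Bayesian posterior covariance of beta
    terms: list[TermInfo]
    scale: float               # dispersion phi (1 for binomial)
    deviance: float
    null_deviance: float
    edf_total: float
    n: int
    gcv: float
    fitted: np.ndarray
    converged: bool
    extrapolation: str = "clamp"
    random_intercept_var: float = np.nan
    y: np.ndarray | None = None

    def term(self, name: str) -> TermInfo:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(f"unknown term {name!r}; have {[t.name for t in self.terms]}")

    @property
    def smooth_terms(self) -> list[TermInfo]:
        return [t for t in self.terms if t.kind == "smooth"]

    def _model_matrix(self, data: Mapping, *, include_random: bool = True) -> np.ndarray:
        n = len(data) if isinstance(data, pd.DataFrame) else len(next(iter(data.values())))
        X = np.zeros((n, len(self.beta)))
        X[:, 0] = 1.0
        for t in self.terms:
            if t.kind == "smooth":
                X[:, t.cols] = t.basis.design(np.asarray(data[t.name], dtype=float),
                                              extrapolation=self.extrapolation)
            elif include_random:
                groups = np.asarray(data[t.name])
                for i, lev in enumerate(t.levels):
                    X[groups == lev, t.cols[i]] = 1.0
        return X

    def linear_predictor(self, data: Mapping, *, include_random: bool = True,
                         return_se: bool = False):
        X = self._model_matrix(data, include_random=include_random)
        eta = X @ self.beta
        if not return_se:
            return eta
        se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", X, self.cov, X), 0.0))
        return eta, se

    def predict(self, data: Mapping, *, include_random: bool = True) -> np.ndarray:
        eta = self.linear_predictor(data, include_random=include_random)
        return expit(eta) if self.family == "binomial" else eta

    def term_effect(self, name: str, grid: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Centered smooth-term curve and pointwise se on the linear-predictor
        scale."""
        t = self.term(name)
        if t.kind != "smooth":
            raise KeyError(f"term {name!r} is not a smooth")
        Xg = t.basis.design(np.asarray(grid, dtype=float),
                            extrapolation=self.extrapolation)
        effect = Xg @ self.beta[t.cols]
        V = self.cov[np.ix_(t.cols, t.cols)]
        se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", Xg, V, Xg), 0.0))
        return effect, se

    def report(self) -> dict:
        """JSON-able fit summary (interface parity with published GAMM tables)."""
        return {
            "family": self.family,
            "response": self.response,
            "n": int(self.n),
            "deviance": float(self.deviance),
            "null_deviance": float(self.null_deviance),
            "scale": float(self.scale),
            "edf_total": float(self.edf_total),
            "gcv": float(self.gcv),
            "converged": bool(self.converged),
            "random_intercept_var": float(self.random_intercept_var),
            "terms": [
                {
                    "name": t.name, "kind": t.kind, "edf": float(t.edf),
                    "lambda": float(t.lambda_),
                    "statistic": float(t.statistic),
                    "statistic_name": t.statistic_name,
                    "p_value": float(t.p_value),
                }
                for t in self.terms
            ],
        }


def _binomial_deviance(y: np.ndarray, mu: np.ndarray) -> float:
    mu = np.clip(mu, 1e-12, 1 - 1e-12)
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = y * np.log(mu) + (1 - y) * np.log(1 - mu)
    return float(-2.0 * ll.sum())


def _pirls(X: np.ndarray, y: np.ndarray, S: np.ndarray, family: str):
    """Penalized IRLS; returns beta, XWX, deviance, mu."""
    n, p = X.shape
    if family == "gaussian":
        XWX = X.T @ X
        beta = np.linalg.solve(XWX + S, X.T @ y)
        mu = X @ beta
        return beta, XWX, float(((y - mu) ** 2).sum()), mu
    # binomial
    mu = np.clip((y + 0.5) / 2.0, 0.01, 0.99)
    eta = np.log(mu / (1 - mu))
    dev = _binomial_deviance(y, mu)
    beta = np.zeros(p)
    for _ in range(_MAX_PIRLS):
        w = np.clip(mu * (1 - mu), 1e-10, None)
        z = eta + (y - mu) / w
        Xw = X * w[:, None]
        XWX = X.T @ Xw
        beta_new = np.linalg.solve(XWX + S, Xw.T @ z)
        eta = X @ beta_new
        mu = expit(eta)
        dev_new = _binomial_deviance(y, mu)
        beta = beta_new
        if abs(dev_new - dev) < _PIRLS_TOL * (abs(dev_new) + 0.1):
            w = np.clip(mu * (1 - mu), 1e-10, None)
            XWX = X.T @ (X * w[:, None])
            return beta, XWX, dev_new, mu
        dev = dev_new
    raise NonConvergenceError(
        f"PIRLS did not converge in {_MAX_PIRLS} iterations (deviance {dev:.4g})")


def fit_additive_model(data: pd.DataFrame, response: str,
                       smooth_terms: Sequence[str], family: str,
                       random_intercept: str | None = None, *,
                       k: int = 4, lambdas: Sequence[float] | None = None,
                       extrapolation: str = "clamp",
                       optimizer_restarts: int = 2) -> AdditiveModelFit:
    """Fit the additive mixed model.

    ``lambdas`` fixes the smoothing parameters (one per smooth, plus one for
    the random intercept if present); otherwise they are selected by GCV.
    """
    if family not in ("binomial", "gaussian"):
        raise ValueError(f"family must be binomial or gaussian, got {family!r}")
    y = np.asarray(data[response], dtype=float)
    n = len(y)
    if family == "binomial" and not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("binomial response must be 0/1")

    terms: list[TermInfo] = []
    blocks = [np.ones((n, 1))]
    col = 1
    for name in smooth_terms:
        basis = SplineBasis.build(name, data[name].to_numpy(), k=k)
        Xj = basis.design(data[name].to_numpy(), extrapolation="clamp")
        cols = np.arange(col, col + Xj.shape[1])
        terms.append(TermInfo(name=name, kind="smooth", cols=cols, basis=basis))
        blocks.append(Xj)
        col += Xj.shape[1]

    if random_intercept is not None:
        levels = np.array(sorted(pd.unique(data[random_intercept])))
        if len(levels) < 2:
            import warnings
            warnings.warn(f"single level in {random_intercept!r}; "
                          "random intercept dropped", stacklevel=2)
            random_intercept = None
        else:
            Zre = (data[random_intercept].to_numpy()[:, None] == levels[None, :]
                   ).astype(float)
            cols = np.arange(col, col + len(levels))
            terms.append(TermInfo(name=random_intercept, kind="random",
                                  cols=cols, levels=levels))
            blocks.append(Zre)
            col += len(levels)

    X = np.hstack(blocks)
    p = X.shape[1]
    pen_blocks = []
    for t in terms:
        P = np.zeros((p, p))
        if t.kind == "smooth":
            P[np.ix_(t.cols, t.cols)] = t.basis.penalty
        else:
            P[np.ix_(t.cols, t.cols)] = np.eye(len(t.cols))
        pen_blocks.append(P)

    _LOG_LAM_BOUND = 25.0  # lambda in [e^-25, e^25]; beyond is numerically inert

    def assemble(log_lam: np.ndarray) -> np.ndarray:
        S = np.zeros((p, p))
        for ll, P in zip(np.clip(log_lam, -_LOG_LAM_BOUND, _LOG_LAM_BOUND),
                         pen_blocks):
            S += np.exp(ll) * P
        return S

    def fit_at(log_lam: np.ndarray):
        S = assemble(log_lam)
        beta, XWX, dev, mu = _pirls(X, y, S, family)
        A = np.linalg.solve(XWX + S, XWX)
        edf = float(np.trace(A))
        gcv = n * dev / max(n - edf, 1e-6) ** 2
        return beta, XWX, S, dev, mu, A, edf, gcv

    n_pen = len(pen_blocks)
    if lambdas is not None:
        if len(lambdas) != n_pen:
            raise ValueError(f"need {n_pen} lambdas, got {len(lambdas)}")
        best_log = np.log(np.asarray(lambdas, dtype=float))
    elif n_pen == 0:
        best_log = np.zeros(0)
    else:
        def objective(ll: np.ndarray) -> float:
            try:
                return fit_at(ll)[-1]
            except (NonConvergenceError, np.linalg.LinAlgError):
                return np.inf

        starts = [np.zeros(n_pen), np.full(n_pen, 3.0), np.full(n_pen, -3.0)]
        best_log, best_val = None, np.inf
        for x0 in starts[: 1 + optimizer_restarts]:
            res = optimize.minimize(
                objective, x0, method="Nelder-Mead",
                options={"maxiter": 120 * n_pen, "xatol": 1e-2, "fatol": 1e-6})
            if np.isfinite(res.fun) and res.fun < best_val:
                best_val, best_log = res.fun, np.clip(
                    res.x, -_LOG_LAM_BOUND, _LOG_LAM_BOUND)
        if best_log is None:
            raise NonConvergenceError("smoothing-parameter search failed from all starts")

    beta, XWX, S, dev, mu, A, edf_total, gcv = fit_at(best_log)

    if family == "gaussian":
        scale = dev / max(n - edf_total, 1e-6)
    else:
        scale = 1.0
    Vb = np.linalg.solve(XWX + S, np.eye(p)) * scale

    # null deviance
    if family == "binomial":
        null_dev = _binomial_deviance(y, np.full(n, y.mean()))
    else:
        null_dev = float(((y - y.mean()) ** 2).sum())

    edf_diag = np.diag(A)
    re_var = np.nan
    for i, t in enumerate(terms):
        t.lambda_ = float(np.exp(best_log[i])) if n_pen else np.nan
        t.edf = float(edf_diag[t.cols].sum())
        bj = beta[t.cols]
        Vj = Vb[np.ix_(t.cols, t.cols)]
        stat = float(bj @ np.linalg.pinv(Vj, rcond=1e-10) @ bj)
        df = max(t.edf, 0.5)
        if family == "binomial":
            t.statistic, t.statistic_name = stat, "chi2"
            t.p_value = float(chi2_dist.sf(stat, df))
        else:
            t.statistic, t.statistic_name = stat / df, "F"
            t.p_value = float(f_dist.sf(stat / df, df, max(n - edf_total, 1.0)))
        if t.kind == "random":
            # implied Gaussian random-intercept variance phi / lambda
            re_var = scale / t.lambda_ if t.lambda_ > 0 else np.inf

    return AdditiveModelFit(
        family=family, response=response, beta=beta, cov=Vb, terms=terms,
        scale=float(scale), deviance=float(dev), null_deviance=null_dev,
        edf_total=edf_total, n=n, gcv=float(gcv),
        fitted=mu if family == "binomial" else X @ beta,
        converged=True, extrapolation=extrapolation,
        random_intercept_var=float(re_var), y=y,
    )
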