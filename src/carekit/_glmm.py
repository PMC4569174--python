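"""Poisson log-link mixed model fit by Laplace-approximated ML.

Random structure: independent scalar variance components (random intercepts
and random slopes without slope-intercept correlations).  Parametrization
follows the usual relative-scale trick: b = theta * u with u ~ N(0, I), so
the inner problem maximizes the jointly concave penalized log-likelihood
over (beta, u) and the outer problem optimizes the Laplace deviance over the
non-negative theta vector.  theta -> 0 collapses exactly onto a plain
Poisson GLM, which is what the limit tests exercise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, special, stats

__all__ = ["RandomTerm", "GlmmFit", "PoissonGLMM", "ConvergenceError"]


class ConvergenceError(RuntimeError):
    pass


@dataclass(frozen=True)
class RandomTerm:
    """One variance component: a grouping factor, optionally times a covariate."""

    name: str
    codes: np.ndarray  # integer level index per observation
    n_levels: int
    covariate: Optional[np.ndarray] = None  # None -> random intercept

    def design(self) -> np.ndarray:
        n = len(self.codes)
        z = np.zeros((n, self.n_levels))
        z[np.arange(n), self.codes] = 1.0
        if self.covariate is not None:
            z *= self.covariate[:, None]
        return z

    @staticmethod
    def from_labels(
        name: str, labels: Sequence, covariate: Optional[np.ndarray] = None
    ) -> "RandomTerm":
        levels, codes = np.unique(np.asarray(labels), return_inverse=True)
        return RandomTerm(name, codes, len(levels), covariate)


@dataclass
class GlmmFit:
    beta: np.ndarray
    se: np.ndarray
    theta: np.ndarray  # random-effect SDs, one per term
    loglik: float
    mu: np.ndarray
    u: np.ndarray
    fixed_names: list[str]
    term_names: list[str]
    converged: bool
    n: int

    @property
    def z_values(self) -> np.ndarray:
        return self.beta / self.se

    @property
    def p_values(self) -> np.ndarray:
        return 2.0 * stats.norm.sf(np.abs(self.z_values))


class PoissonGLMM:
    def __init__(
        self,
        y: np.ndarray,
        X: np.ndarray,
        terms: Sequence[RandomTerm] = (),
        fixed_names: Optional[Sequence[str]] = None,
    ):
        self.y = np.asarray(y, dtype=float)
        self.X = np.asarray(X, dtype=float)
        self.terms = list(terms)
        self.n, self.p = self.X.shape
        if len(self.y) != self.n:
            raise ValueError("y and X disagree on n")
        self.fixed_names = list(
            fixed_names if fixed_names is not None else
            [f"x{j}" for j in range(self.p)]
        )
        self.Z = (
            np.hstack([t.design() for t in self.terms])
            if self.terms
            else np.zeros((self.n, 0))
        )
        self.q = self.Z.shape[1]
        # column slice per term, for scaling by theta
        self._slices = []
        start = 0
        for t in self.terms:
            self._slices.append(slice(start, start + t.n_levels))
            start += t.n_levels
        self._loggamma = float(special.gammaln(self.y + 1.0).sum())

    # -- inner problem -----------------------------------------------------

    def _scaled_z(self, theta: np.ndarray) -> np.ndarray:
        zl = self.Z.copy()
        for s, th in zip(self._slices, theta):
            zl[:, s] *= th
        return zl

    def _inner(
        self, theta: np.ndarray, start: Optional[np.ndarray] = None
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
        """Newton maximization of the penalized log-likelihood over (beta, u)."""
        zl = self._scaled_z(theta)
        M = np.hstack([self.X, zl])
        pen = np.concatenate([np.zeros(self.p), np.ones(self.q)])
        gamma = start if start is not None else np.zeros(self.p + self.q)
        # keep the initial eta in a sane range
        obj_prev = -np.inf
        for _ in range(100):
            eta = M @ gamma
            mu = np.exp(np.clip(eta, -30, 30))
            grad = M.T @ (self.y - mu) - pen * gamma
            H = (M * mu[:, None]).T @ M
            H[np.arange(self.p + self.q), np.arange(self.p + self.q)] += pen
            try:
                step = np.linalg.solve(H, grad)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(H, grad, rcond=None)[0]
            # line search with step halving on the penalized objective
            obj = self._pen_obj(M, pen, gamma)
            t = 1.0
            for _ in range(30):
                cand = gamma + t * step
                if self._pen_obj(M, pen, cand) >= obj:
                    break
                t *= 0.5
            gamma = gamma + t * step
            obj_new = self._pen_obj(M, pen, gamma)
            if abs(obj_new - obj_prev) < 1e-10 * (1 + abs(obj_new)):
                break
            obj_prev = obj_new
        eta = M @ gamma
        mu = np.exp(np.clip(eta, -30, 30))
        return gamma[: self.p], gamma[self.p:], mu, self._pen_obj(M, pen, gamma)

    def _pen_obj(self, M, pen, gamma) -> float:
        eta = np.clip(M @ gamma, -30, 30)
        return float(self.y @ eta - np.exp(eta).sum() - 0.5 * (pen * gamma**2).sum())

    # -- Laplace log-likelihood -------------------------------------------

    def _laplace_loglik(
        self, theta: np.ndarray, start: Optional[np.ndarray] = None
    ) -> tuple[float, np.ndarray]:
        beta, u, mu, pen_obj = self._inner(theta, start)
        ll = pen_obj - self._loggamma
        if self.q:
            zl = self._scaled_z(theta)
            A = (zl * mu[:, None]).T @ zl
            A[np.arange(self.q), np.arange(self.q)] += 1.0
            sign, logdet = np.linalg.slogdet(A)
            if sign <= 0:
                return -np.inf, np.concatenate([beta, u])
            ll -= 0.5 * logdet
        return ll, np.concatenate([beta, u])

    # -- public fit --------------------------------------------------------

    def fit(self, theta0: Optional[np.ndarray] = None) -> GlmmFit:
        n_terms = len(self.terms)
        warm = {"gamma": None}

        def negll(theta: np.ndarray) -> float:
            ll, gamma = self._laplace_loglik(np.abs(theta), warm["gamma"])
            warm["gamma"] = gamma
            return -ll

        if n_terms:
            x0 = np.full(n_terms, 0.3) if theta0 is None else np.asarray(theta0, float)
            res = optimize.minimize(
                negll,
                x0,
                method="L-BFGS-B",
                bounds=[(0.0, None)] * n_terms,
                options={"maxiter": 200, "ftol": 1e-11},
            )
            theta = np.abs(res.x)
            converged = bool(res.success)
        else:
            theta = np.zeros(0)
            converged = True
        ll, _ = self._laplace_loglik(theta, warm["gamma"])
        beta, u, mu, _ = self._inner(theta, warm["gamma"])
        se = self._fixed_se(theta, mu)
        if not np.isfinite(ll):
            raise ConvergenceError("Laplace log-likelihood not finite at optimum")
        return GlmmFit(
            beta=beta,
            se=se,
            theta=theta,
            loglik=float(ll),
            mu=mu,
            u=u,
            fixed_names=self.fixed_names,
            term_names=[t.name for t in self.terms],
            converged=converged,
            n=self.n,
        )

    def _fixed_se(self, theta: np.ndarray, mu: np.ndarray) -> np.ndarray:
        """SEs from the Schur complement of the joint penalized Hessian."""
        Hbb = (self.X * mu[:, None]).T @ self.X
        if self.q:
            zl = self._scaled_z(theta)
            Hbu = (self.X * mu[:, None]).T @ zl
            Huu = (zl * mu[:, None]).T @ zl
            Huu[np.arange(self.q), np.arange(self.q)] += 1.0
            Hbb = Hbb - Hbu @ np.linalg.solve(Huu, Hbu.T)
        cov = np.linalg.inv(Hbb)
        return np.sqrt(np.diag(cov))
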