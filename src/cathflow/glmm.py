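"""Random-intercept GLMMs fitted by adaptive Gauss-Hermite quadrature.

Supports Poisson (log link) and Bernoulli (logit link) responses with a
single Gaussian random intercept per cluster — the structure needed for a
two-period crossover, where the cluster is the participant.  The marginal
log-likelihood integrates the random intercept out of each cluster's
contribution; the integral is approximated with Gauss-Hermite quadrature
recentred and rescaled at each cluster's posterior mode (adaptive
quadrature, 15 nodes by default), which keeps the approximation accurate
even for clusters with few observations.

The mode search is a damped Newton iteration run simultaneously on all
clusters with vectorised array operations, so one likelihood evaluation
costs a handful of numpy passes regardless of the number of clusters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial.hermite import hermgauss
from scipy.optimize import minimize
from scipy.special import gammaln, logsumexp

from .errors import DataError

_LOG_SIGMA_MIN = -10.0  # sigma ~ 4.5e-5: numerically the fixed-effects limit
_LOG_SIGMA_MAX = 3.0


def _check_family(family: str) -> None:
    if family not in ("poisson", "binomial"):
        raise DataError(f"unsupported GLMM family {family!r}")


@dataclass
class GLMMResult:
    """Maximum-likelihood fit of a random-intercept GLMM."""

    params: np.ndarray        # fixed-effect coefficients
    sigma: float              # random-intercept SD
    cov_params: np.ndarray    # Wald covariance of the fixed effects
    loglike: float
    converged: bool
    n_obs: int
    n_groups: int
    family: str

    def bse(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.cov_params), 0.0, None))


class RandomInterceptGLMM:
    """Poisson or binomial GLMM with one Gaussian random intercept.

    Parameters
    ----------
    y, X : response vector and fixed-effects design matrix.
    groups : integer cluster labels (any hashable values; factorised).
    family : "poisson" or "binomial".
    n_quad : number of adaptive Gauss-Hermite nodes.
    """

    def __init__(self, y, X, groups, family: str = "poisson", n_quad: int = 15):
        _check_family(family)
        self.y = np.asarray(y, dtype=float)
        self.X = np.asarray(X, dtype=float)
        if self.X.ndim != 2 or len(self.y) != self.X.shape[0]:
            raise DataError("X must be 2-D with one row per observation")
        self.groups = np.unique(np.asarray(groups), return_inverse=True)[1]
        self.n_groups = int(self.groups.max()) + 1
        self.n_obs = len(self.y)
        self.family = family
        nodes, weights = hermgauss(n_quad)
        self.nodes = nodes
        self.log_weights = np.log(weights)
        if family == "poisson":
            self._y_const = -gammaln(self.y + 1.0)
        else:
            if not np.isin(self.y, (0.0, 1.0)).all():
                raise DataError("binomial responses must be 0/1")
            self._y_const = np.zeros_like(self.y)

    # -- per-observation log densities and derivatives -------------------

    def _obs_loglike(self, eta: np.ndarray) -> np.ndarray:
        if self.family == "poisson":
            return self.y * eta - np.exp(eta) + self._y_const
        return self.y * eta - np.logaddexp(0.0, eta)

    def _mean(self, eta: np.ndarray) -> np.ndarray:
        if self.family == "poisson":
            return np.exp(eta)
        return 1.0 / (1.0 + np.exp(-eta))

    def _variance(self, eta: np.ndarray) -> np.ndarray:
        mu = self._mean(eta)
        if self.family == "poisson":
            return mu
        return mu * (1.0 - mu)

    # -- marginal likelihood ---------------------------------------------

    def _cluster_modes(self, eta_fix: np.ndarray, sigma: float):
        """Posterior mode and curvature of the random intercept per cluster."""
        g = self.groups
        b = np.zeros(self.n_groups)
        for _ in range(50):
            eta = eta_fix + b[g]
            score = np.bincount(
                g, weights=self.y - self._mean(eta), minlength=self.n_groups
            ) - b / sigma**2
            info = np.bincount(
                g, weights=self._variance(eta), minlength=self.n_groups
            ) + 1.0 / sigma**2
            step = score / info
            step = np.clip(step, -2.0, 2.0)  # damp early oversized steps
            b = b + step
            if np.max(np.abs(step)) < 1e-9:
                break
        eta = eta_fix + b[g]
        curv = np.bincount(
            g, weights=self._variance(eta), minlength=self.n_groups
        ) + 1.0 / sigma**2
        return b, curv

    def loglike(self, beta: np.ndarray, log_sigma: float) -> float:
        sigma = float(np.exp(log_sigma))
        eta_fix = self.X @ beta
        b_hat, curv = self._cluster_modes(eta_fix, sigma)
        tau = 1.0 / np.sqrt(curv)  # Laplace scale per cluster
        # nodes: (G, K) random-intercept values
        bk = b_hat[:, None] + np.sqrt(2.0) * tau[:, None] * self.nodes[None, :]
        # integrand per cluster and node
        h = -0.5 * bk**2 / sigma**2 - 0.5 * np.log(2.0 * np.pi * sigma**2)
        for k in range(bk.shape[1]):
            eta = eta_fix + bk[self.groups, k]
            h[:, k] += np.bincount(
                self.groups, weights=self._obs_loglike(eta), minlength=self.n_groups
            )
        log_int = logsumexp(
            self.log_weights[None, :] + self.nodes[None, :] ** 2 + h, axis=1
        ) + 0.5 * np.log(2.0) + np.log(tau)
        return float(np.sum(log_int))

    # -- fitting -----------------------------------------------------------

    def _start_beta(self) -> np.ndarray:
        import statsmodels.api as sm

        import warnings

        fam = sm.families.Poisson() if self.family == "poisson" else sm.families.Binomial()
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.GLM(self.y, self.X, family=fam).fit()
            beta = np.asarray(res.params, dtype=float)
            beta[~np.isfinite(beta)] = 0.0
            return np.clip(beta, -10.0, 10.0)
        except Exception:
            return np.zeros(self.X.shape[1])

    def fit(
        self,
        start_params: np.ndarray | None = None,
        fixed_sigma: float | None = None,
        penalty: float = 0.0,
    ) -> GLMMResult:
        """Maximise the marginal likelihood.

        ``fixed_sigma`` pins the random-intercept SD (0 or near-0 forces the
        fixed-effects limit).  ``penalty`` adds a ridge term 0.5*penalty*
        sum(beta^2) on non-intercept coefficients, used as a fallback under
        separation.
        """
        p = self.X.shape[1]
        beta0 = np.asarray(start_params, float) if start_params is not None else self._start_beta()
        ridge_mask = np.ones(p)
        ridge_mask[0] = 0.0  # never penalise the intercept

        if fixed_sigma is not None:
            log_sig = np.log(max(fixed_sigma, np.exp(_LOG_SIGMA_MIN)))

            def nll(th):
                pen = 0.5 * penalty * np.sum(ridge_mask * th**2)
                return -self.loglike(th, log_sig) + pen

            res = minimize(nll, beta0, method="BFGS",
                           options={"gtol": 1e-7, "maxiter": 500})
            full = np.concatenate([res.x, [log_sig]])
        else:
            th0 = np.concatenate([beta0, [np.log(0.5)]])

            def nll(th):
                ls = np.clip(th[-1], _LOG_SIGMA_MIN, _LOG_SIGMA_MAX)
                pen = 0.5 * penalty * np.sum(ridge_mask * th[:p] ** 2)
                return -self.loglike(th[:p], ls) + pen

            res = minimize(
                nll, th0, method="L-BFGS-B",
                bounds=[(None, None)] * p + [(_LOG_SIGMA_MIN, _LOG_SIGMA_MAX)],
                options={"ftol": 1e-11, "gtol": 1e-7, "maxiter": 500},
            )
            full = np.concatenate([res.x[:p], [np.clip(res.x[-1], _LOG_SIGMA_MIN, _LOG_SIGMA_MAX)]])

        beta = full[:p]
        sigma = float(np.exp(full[-1]))
        cov = self._wald_cov(beta, full[-1], fixed_sigma is not None)
        return GLMMResult(
            params=beta,
            sigma=sigma,
            cov_params=cov,
            loglike=self.loglike(beta, full[-1]),
            converged=bool(res.success),
            n_obs=self.n_obs,
            n_groups=self.n_groups,
            family=self.family,
        )

    def _wald_cov(self, beta: np.ndarray, log_sigma: float, sigma_fixed: bool) -> np.ndarray:
        from statsmodels.tools.numdiff import approx_hess

        p = len(beta)
        if sigma_fixed:
            def f(th):
                return -self.loglike(th, log_sigma)
            hess = approx_hess(beta, f)
        else:
            def f(th):
                return -self.loglike(th[:p], np.clip(th[-1], _LOG_SIGMA_MIN, _LOG_SIGMA_MAX))
            hess = approx_hess(np.concatenate([beta, [log_sigma]]), f)
        try:
            cov_all = np.linalg.inv(hess)
        except np.linalg.LinAlgError:
            cov_all = np.linalg.pinv(hess)
        return cov_all[:p, :p]

    # -- profile-likelihood CI ---------------------------------------------

    def profile_ci(
        self, index: int, level: float = 0.95, fit: GLMMResult | None = None
    ) -> tuple[float, float]:
        """Profile-likelihood CI for one fixed-effect coefficient.

        Falls back to wide search bounds; returns -inf/inf when the deviance
        never reaches the chi-square cutoff (e.g. an all-zero arm).
        """
        from scipy.optimize import brentq
        from scipy.stats import chi2

        fit = fit or self.fit()
        target = fit.loglike - chi2.ppf(level, 1) / 2.0
        p = self.X.shape[1]
        free_idx = [j for j in range(p) if j != index]

        def prof_ll(val: float) -> float:
            def nll(free_and_ls):
                beta = np.empty(p)
                beta[free_idx] = free_and_ls[:-1]
                beta[index] = val
                return -self.loglike(beta, np.clip(free_and_ls[-1], _LOG_SIGMA_MIN, _LOG_SIGMA_MAX))

            x0 = np.concatenate([fit.params[free_idx], [np.log(max(fit.sigma, 1e-4))]])
            res = minimize(nll, x0, method="Nelder-Mead",
                           options={"xatol": 1e-5, "fatol": 1e-7, "maxiter": 2000})
            return -res.fun

        mle = fit.params[index]
        se = max(fit.bse()[index], 0.5)
        if not np.isfinite(se):
            se = 2.0
        se = min(se, 5.0)  # step size for the bracket search only

        def g(val):
            ll = prof_ll(val)
            if not np.isfinite(ll):
                return -1.0  # off the likelihood surface: outside the interval
            return ll - target

        lo, hi = -np.inf, np.inf
        # search outward for a bracketing point on each side
        for sign, store in ((-1, "lo"), (1, "hi")):
            bound = None
            for mult in (1, 2, 4, 8, 16, 32):
                cand = mle + sign * mult * se
                if g(cand) < 0:
                    bound = cand
                    break
            if bound is not None:
                val = brentq(g, min(mle, bound), max(mle, bound), xtol=1e-4)
                if store == "lo":
                    lo = val
                else:
                    hi = val
        return lo, hi
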