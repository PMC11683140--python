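"""Restricted maximum likelihood (REML) estimation for linear mixed models.

Fits models of the form

    y = X b + sum_i Z_i u_i + e,   u_i ~ N(0, K_i s2_i),   e ~ N(0, I s2_e)

with independent variance components, by average-information (AI) REML with
EM-REML warm-up and fallback.  All computations run on Henderson's mixed-model
equations (MME), so the per-iteration cost scales with the total number of
random-effect levels rather than the number of records.  This supports crossed
design factors (environment, row, column, genotype, genotype-by-environment)
as well as dense genomic covariance structures (G, D, Gaussian kernels).

BLUPs of every random effect are obtained as a by-product of the converged
MME solve.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

logger = logging.getLogger(__name__)

__all__ = ["RandomEffect", "MixedModel", "MixedModelResults", "NotPositiveDefiniteError"]


class NotPositiveDefiniteError(np.linalg.LinAlgError):
    """A covariance structure is not positive definite after stabilization."""


@dataclass
class RandomEffect:
    """One random term: incidence matrix ``Z`` and optional covariance ``K``.

    ``K=None`` means independent levels (identity covariance).  ``levels``
    carries the label of each column of ``Z`` so BLUPs can be reported by name.
    """

    name: str
    Z: np.ndarray
    K: np.ndarray | None = None
    levels: list | None = None

    @property
    def n_levels(self) -> int:
        return self.Z.shape[1]


@dataclass
class MixedModelResults:
    """Converged (or best-effort) REML fit."""

    variance_components: dict[str, float]
    beta: np.ndarray
    random_effects: dict[str, np.ndarray]
    effect_levels: dict[str, list]
    loglik: float
    converged: bool
    n_iterations: int
    fitted_values: np.ndarray
    residuals: np.ndarray
    n_obs: int
    ai_matrix: np.ndarray | None = None
    se_components: dict[str, float] = field(default_factory=dict)

    def blup(self, name: str):
        """BLUPs of one random term as a dict level -> value."""
        levels = self.effect_levels[name]
        values = self.random_effects[name]
        return dict(zip(levels, values))

    def summary(self) -> str:
        lines = ["Mixed model (REML) results", "-" * 40]
        lines.append(f"n obs: {self.n_obs}   iterations: {self.n_iterations}   "
                     f"converged: {self.converged}")
        lines.append(f"REML log-likelihood: {self.loglik:.4f}")
        lines.append("Variance components:")
        for k, v in self.variance_components.items():
            se = self.se_components.get(k)
            se_txt = f"  (SE {se:.4g})" if se is not None else ""
            lines.append(f"  {k:<12s} {v:.6g}{se_txt}")
        return "\n".join(lines)


class MixedModel:
    """Linear mixed model with independent variance components, REML-fitted.

    Parameters
    ----------
    y : array
        Response vector (n,).
    X : array
        Fixed-effect design (n, p), full column rank expected.
    random_effects : list of RandomEffect
        The random terms. A residual term is always present implicitly.
    """

    def __init__(self, y, X, random_effects: list[RandomEffect]):
        self.y = np.asarray(y, dtype=float).ravel()
        n = self.y.size
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if X.shape[0] != n:
            raise ValueError("X and y have incompatible shapes")
        self.X = X
        if not random_effects:
            raise ValueError("at least one random effect is required")
        for re in random_effects:
            if re.Z.shape[0] != n:
                raise ValueError(f"Z for '{re.name}' has {re.Z.shape[0]} rows, expected {n}")
            if re.K is not None and re.K.shape != (re.Z.shape[1], re.Z.shape[1]):
                raise ValueError(f"K for '{re.name}' has wrong shape")
            if re.levels is None:
                re.levels = list(range(re.Z.shape[1]))
        self.random_effects = random_effects

    # -- internal helpers -------------------------------------------------

    def _prepare(self):
        X, res = self.X, self.random_effects
        self._p = X.shape[1]
        self._q = [re.n_levels for re in res]
        self._offsets = np.concatenate([[self._p], self._p + np.cumsum(self._q)])
        W = np.hstack([X] + [re.Z for re in res])
        self._WtW = W.T @ W
        self._Wty = W.T @ self.y
        self._W = W
        self._yty = float(self.y @ self.y)
        # inverses / log-dets of the K structures, computed once
        self._Kinv, self._logdetK = [], []
        for re in res:
            if re.K is None:
                self._Kinv.append(None)
                self._logdetK.append(0.0)
            else:
                K = np.asarray(re.K, dtype=float)
                try:
                    c = linalg.cho_factor(K, lower=True)
                except np.linalg.LinAlgError as exc:
                    raise NotPositiveDefiniteError(
                        f"covariance for '{re.name}' is not positive definite; "
                        "apply a diagonal ridge before fitting") from exc
                self._Kinv.append(linalg.cho_solve(c, np.eye(K.shape[0])))
                self._logdetK.append(2.0 * float(np.sum(np.log(np.diag(c[0])))))

    def _assemble(self, s2: np.ndarray, s2e: float):
        """Build the natural-unit MME coefficient matrix and RHS."""
        C = self._WtW / s2e
        for i, re in enumerate(self.random_effects):
            a, b = self._offsets[i], self._offsets[i + 1]
            if self._Kinv[i] is None:
                C[a:b, a:b] += np.eye(b - a) / s2[i]
            else:
                C[a:b, a:b] += self._Kinv[i] / s2[i]
        rhs = self._Wty / s2e
        return C, rhs

    def _loglik(self, s2, s2e, sol, logdetC):
        """-2 restricted log-likelihood up to an additive constant, negated to
        a conventional log-likelihood (higher is better)."""
        n, p = self.y.size, self._p
        ypy = (self._yty - sol @ self._Wty) / s2e
        val = n * np.log(s2e) + logdetC + ypy
        for i, qi in enumerate(self._q):
            val += qi * np.log(s2[i]) + self._logdetK[i]
        return -0.5 * val

    # -- fitting ----------------------------------------------------------

    def fit(self, max_iter: int = 200, tol: float = 1e-8, n_em: int = 3,
            start: dict[str, float] | None = None,
            verbose: bool = False) -> MixedModelResults:
        """Estimate variance components by REML.

        Models with a single random term are solved exactly by profiling the
        restricted likelihood over the variance ratio on the eigenbasis of
        Z K Z'.  Multi-component models use AI-REML: ``n_em`` EM iterations
        stabilize the start; afterwards AI updates are used with
        step-halving, falling back to an EM step whenever the AI step leaves
        the parameter space or decreases the restricted likelihood.
        Components are bounded below at a small fraction of the phenotypic
        variance.
        """
        if len(self.random_effects) == 1 and np.var(self.y) > 0:
            return self._fit_single_kernel()
        self._prepare()
        y = self.y
        n, p = y.size, self._p
        c = len(self.random_effects)
        vary = float(np.var(y))
        if vary == 0.0:
            return self._degenerate_fit()
        lower = 1e-8 * vary
        upper = 1e6 * vary  # keeps the MME numerically nonsingular

        names = [re.name for re in self.random_effects]
        theta = np.full(c + 1, vary / (c + 1))  # [s2_1..s2_c, s2_e]
        if start:
            for i, nm in enumerate(names):
                if nm in start:
                    theta[i] = max(start[nm], lower)
            if "residual" in start:
                theta[-1] = max(start["residual"], lower)

        prev_ll = -np.inf
        converged = False
        it = 0
        ai_mat = None
        for it in range(1, max_iter + 1):
            state = self._iteration_state(theta)
            ll = state["loglik"]
            if verbose:
                logger.info("iter %d  loglik %.6f  theta %s", it, ll, theta)
            if it > 1 and abs(ll - prev_ll) / (abs(prev_ll) + 1.0) < tol:
                converged = True
                break
            prev_ll = ll

            em_theta = self._em_update(theta, state)
            if it <= n_em:
                theta = np.minimum(np.maximum(em_theta, lower), upper)
                continue

            score, AI = self._score_and_ai(theta, state)
            ai_mat = AI
            try:
                step = np.linalg.solve(AI, score)
                # active-set move: clamp components the raw step would push
                # below bound, re-solve the Newton system for the rest
                neg = theta + step < lower
                if neg.any() and not neg.all():
                    free = ~neg
                    sub = np.linalg.solve(AI[np.ix_(free, free)], score[free])
                    step = np.where(neg, lower - theta, 0.0)
                    step[free] = sub
            except np.linalg.LinAlgError:
                theta = np.maximum(em_theta, lower)
                continue
            accepted = False
            for _ in range(8):  # step-halving
                cand = theta + step
                if np.all(cand >= lower) and np.all(cand <= upper):
                    try:
                        cand_ll = self._iteration_state(cand, light=True)["loglik"]
                    except np.linalg.LinAlgError:
                        cand_ll = -np.inf
                    if cand_ll >= ll - 1e-10:
                        theta = cand
                        accepted = True
                        break
                step *= 0.5
            if not accepted:
                theta = np.minimum(np.maximum(em_theta, lower), upper)

        if not converged:
            # boundary-hugging components can stall EM/AI; polish with a
            # derivative-free search on the log scale
            from scipy.optimize import minimize

            def neg_ll(log_theta):
                t = np.clip(np.exp(log_theta), lower, upper)
                try:
                    return -self._iteration_state(t, light=True)["loglik"]
                except np.linalg.LinAlgError:
                    return np.inf

            nm = minimize(neg_ll, np.log(theta), method="Nelder-Mead",
                          options={"xatol": 1e-10, "fatol": 1e-10,
                                   "maxfev": 400 * (c + 1)})
            if -nm.fun >= prev_ll:
                theta = np.clip(np.exp(nm.x), lower, upper)
                converged = bool(nm.success)
            if not converged:
                warnings.warn("REML did not converge within max_iter", RuntimeWarning)

        state = self._iteration_state(theta)
        return self._build_results(theta, state, converged, it, ai_mat)

    def _fit_single_kernel(self) -> MixedModelResults:
        """Exact REML for one random term via the eigenbasis of Z K Z'.

        Profiles the restricted likelihood over log(lambda) with
        lambda = s2_u / s2_e, which reduces to a 1-D bounded minimization;
        BLUPs follow from u_hat = s2_u K Z' Vinv (y - X beta)."""
        from scipy.optimize import minimize_scalar

        re = self.random_effects[0]
        y, X = self.y, self.X
        n, p = y.size, X.shape[1]
        ZKZ = re.Z @ re.Z.T if re.K is None else re.Z @ re.K @ re.Z.T
        d, U = np.linalg.eigh(0.5 * (ZKZ + ZKZ.T))
        d = np.clip(d, 0.0, None)
        yt, Xt = U.T @ y, U.T @ X

        def neg2ll(log_lam):
            lam = np.exp(log_lam)
            w = 1.0 / (lam * d + 1.0)  # V = s2e * diag(1/w)
            XtWX = Xt.T @ (w[:, None] * Xt)
            beta = np.linalg.solve(XtWX, Xt.T @ (w * yt))
            r = yt - Xt @ beta
            rss = float(r @ (w * r))
            s2e = rss / (n - p)
            # -2L = log|V| + log|X'VinvX| + y'Py with the profile s2e:
            #   log|V| = n log s2e - sum log w ;  log|X'VinvX| = log|XtWX| - p log s2e
            sign, ld_x = np.linalg.slogdet(XtWX)
            return ((n - p) * np.log(s2e) - float(np.sum(np.log(w)))
                    + ld_x + (n - p))

        def score(log_lam):
            # d(-2L)/d(log lam), analytic (envelope theorem for beta and s2e)
            lam = np.exp(log_lam)
            w = 1.0 / (lam * d + 1.0)
            XtWX = Xt.T @ (w[:, None] * Xt)
            beta = np.linalg.solve(XtWX, Xt.T @ (w * yt))
            r = yt - Xt @ beta
            s2e = float(r @ (w * r)) / (n - p)
            dw = -d * w * w
            ds2e = float(r @ (dw * r)) / (n - p)
            dld_x = float(np.trace(np.linalg.solve(XtWX, Xt.T @ (dw[:, None] * Xt))))
            return lam * ((n - p) * ds2e / s2e - float(np.sum(dw / w)) + dld_x)

        opt = minimize_scalar(neg2ll, bounds=(-30.0, 30.0), method="bounded",
                              options={"xatol": 1e-10})
        x_star = float(opt.x)
        # polish with a sign-change root find on the analytic score: the
        # quadratic flatness of -2L limits Brent to ~1e-6 in log(lambda)
        if -29.0 < x_star < 29.0:
            from scipy.optimize import brentq
            lo, hi = x_star - 0.05, x_star + 0.05
            if score(lo) * score(hi) < 0:
                x_star = brentq(score, lo, hi, xtol=1e-13)
        lam = float(np.exp(x_star))
        w = 1.0 / (lam * d + 1.0)
        XtWX = Xt.T @ (w[:, None] * Xt)
        beta = np.linalg.solve(XtWX, Xt.T @ (w * yt))
        r = yt - Xt @ beta
        s2e = float(r @ (w * r)) / (n - p)
        s2u = lam * s2e
        # BLUPs: u_hat = s2u K Z' Vinv (y - X beta); Vinv = U diag(w/s2e) U'
        vinv_r = U @ (w * r) / s2e
        KZt = re.Z.T if re.K is None else re.K @ re.Z.T
        u_hat = s2u * (KZt @ vinv_r)
        fitted = X @ beta + re.Z @ u_hat
        loglik = -0.5 * float(opt.fun)
        return MixedModelResults(
            variance_components={re.name: s2u, "residual": s2e},
            beta=beta, random_effects={re.name: u_hat},
            effect_levels={re.name: re.levels if re.levels is not None
                           else list(range(re.n_levels))},
            loglik=loglik, converged=True, n_iterations=int(opt.nfev),
            fitted_values=fitted, residuals=y - fitted, n_obs=n)

    # -- per-iteration quantities -----------------------------------------

    def _iteration_state(self, theta, light=False):
        s2, s2e = theta[:-1], theta[-1]
        C, rhs = self._assemble(s2, s2e)
        cf = linalg.cho_factor(C, lower=True)
        sol = linalg.cho_solve(cf, rhs)
        logdetC = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
        out = {"sol": sol, "cf": cf,
               "loglik": self._loglik(s2, s2e, sol, logdetC)}
        if light:
            return out
        Cinv = linalg.cho_solve(cf, np.eye(C.shape[0]))
        out["Cinv"] = Cinv
        resid = self.y - self._W @ sol  # e-hat = y - Xb - Zu
        out["resid"] = resid
        out["Py"] = resid / s2e
        return out

    def _em_update(self, theta, state):
        s2, s2e = theta[:-1], theta[-1]
        sol, Cinv = state["sol"], state["Cinv"]
        new = np.empty_like(theta)
        for i in range(len(self.random_effects)):
            a, b = self._offsets[i], self._offsets[i + 1]
            u = sol[a:b]
            Cii = Cinv[a:b, a:b]
            Ki = self._Kinv[i]
            if Ki is None:
                quad = float(u @ u)
                tr = float(np.trace(Cii))
            else:
                quad = float(u @ Ki @ u)
                tr = float(np.sum(Ki * Cii))  # tr(Kinv @ Cii), both symmetric
            new[i] = (quad + tr) / self._q[i]
        n, p = self.y.size, self._p
        new[-1] = float(self.y @ state["resid"]) / (n - p)
        return new

    def _trace_p_terms(self, theta, state):
        """tr(P A_i) for every random term and tr(P)."""
        s2, s2e = theta[:-1], theta[-1]
        Cinv = state["Cinv"]
        n, p = self.y.size, self._p
        traces = np.empty(len(self.random_effects))
        for i in range(len(self.random_effects)):
            a, b = self._offsets[i], self._offsets[i + 1]
            Cii = Cinv[a:b, a:b]
            Ki = self._Kinv[i]
            tr_kc = float(np.trace(Cii)) if Ki is None else float(np.sum(Ki * Cii))
            traces[i] = (self._q[i] - tr_kc / s2[i]) / s2[i]
        tr_p = (n - p - float(np.sum(s2 * traces))) / s2e
        return traces, tr_p

    def _score_and_ai(self, theta, state):
        s2, s2e = theta[:-1], theta[-1]
        sol, Py = state["sol"], state["Py"]
        c = len(self.random_effects)
        # working vectors w_i = A_i P y = Z_i u_hat_i / s2_i ; w_e = P y
        Ws = []
        for i, re in enumerate(self.random_effects):
            a, b = self._offsets[i], self._offsets[i + 1]
            Ws.append(re.Z @ (sol[a:b] / s2[i]))
        Ws.append(Py)
        traces, tr_p = self._trace_p_terms(theta, state)
        score = np.empty(c + 1)
        for i in range(c):
            score[i] = -0.5 * (traces[i] - float(Ws[i] @ Py))
        score[-1] = -0.5 * (tr_p - float(Py @ Py))
        # AI_ij = 0.5 w_i' P w_j ;  P w = (w - W sol_w) / s2e with sol_w from MME
        Pw = np.empty((self.y.size, c + 1))
        for j, w in enumerate(Ws):
            rhs = (self._W.T @ w) / s2e
            sol_w = linalg.cho_solve(state["cf"], rhs)
            Pw[:, j] = (w - self._W @ sol_w) / s2e
        Wmat = np.column_stack(Ws)
        AI = 0.5 * (Wmat.T @ Pw)
        AI = 0.5 * (AI + AI.T)
        return score, AI

    # -- results ----------------------------------------------------------

    def _degenerate_fit(self) -> MixedModelResults:
        names = [re.name for re in self.random_effects]
        vc = {nm: 0.0 for nm in names}
        vc["residual"] = 0.0
        beta, *_ = np.linalg.lstsq(self.X, self.y, rcond=None)
        fitted = self.X @ beta
        return MixedModelResults(
            variance_components=vc, beta=beta,
            random_effects={re.name: np.zeros(re.n_levels) for re in self.random_effects},
            effect_levels={re.name: re.levels for re in self.random_effects},
            loglik=0.0, converged=True, n_iterations=0,
            fitted_values=fitted, residuals=self.y - fitted, n_obs=self.y.size)

    def _build_results(self, theta, state, converged, n_iter, ai_mat) -> MixedModelResults:
        s2, s2e = theta[:-1], theta[-1]
        sol = state["sol"]
        vc = {re.name: float(s2[i]) for i, re in enumerate(self.random_effects)}
        vc["residual"] = float(s2e)
        ranef, levels = {}, {}
        for i, re in enumerate(self.random_effects):
            a, b = self._offsets[i], self._offsets[i + 1]
            ranef[re.name] = sol[a:b].copy()
            levels[re.name] = re.levels
        beta = sol[: self._p].copy()
        fitted = self._W @ sol
        se = {}
        if ai_mat is not None:
            try:
                cov = np.linalg.inv(ai_mat)
                names = list(vc.keys())
                for i, nm in enumerate(names):
                    if cov[i, i] > 0:
                        se[nm] = float(np.sqrt(cov[i, i]))
            except np.linalg.LinAlgError:
                pass
        return MixedModelResults(
            variance_components=vc, beta=beta, random_effects=ranef,
            effect_levels=levels, loglik=float(state["loglik"]),
            converged=converged, n_iterations=n_iter,
            fitted_values=fitted, residuals=self.y - fitted,
            n_obs=self.y.size, ai_matrix=ai_mat, se_components=se)
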