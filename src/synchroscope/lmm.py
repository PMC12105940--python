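"""Restricted-maximum-likelihood solver for LMMs with crossed random intercepts.

Model: y = X beta + sum_k Z_k u_k + e, with u_k ~ N(0, sigma_k^2 I) for each
grouping factor k (species, pair id, optionally family) and e ~ N(0,
sigma^2 I). The factors are crossed, not nested, so the marginal covariance
is V = sigma^2 (I + sum_k lambda_k Z_k Z_k') with lambda_k = sigma_k^2 /
sigma^2.

The solver profiles out beta and sigma^2 and minimises the REML criterion
over the log variance ratios. All linear algebra runs on the q x q
cross-product of the random-effect design (Woodbury identity), where q is the
total number of random-effect levels, so a fit costs O(q^3) per criterion
evaluation after a single O(n (p + q)^2) pass over the data. Permutation
tests exploit this: replacing one predictor column only touches O(n) entries
of the sufficient statistics, making a full REML refit per permutation cheap.

Wald F statistics per fixed-effect term are computed from the estimated
coefficient covariance (marginal, not sequential); denominator degrees of
freedom are never needed because inference is by permutation, so only
within-analysis consistency of the statistic matters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize

#: a variance ratio below this is treated as a boundary (singular) estimate
SINGULAR_TOL = 1e-5


class RankDeficientError(ValueError):
    """Fixed-effect design is rank deficient; carries the aliased columns."""


class ConvergenceError(RuntimeError):
    """REML optimisation failed; carries optimizer diagnostics."""


@dataclass
class LMMFit:
    """A fitted crossed-random-intercept model."""

    beta: np.ndarray
    se: np.ndarray
    cov_beta: np.ndarray
    sigma2: float
    lambdas: dict[str, float]  # variance ratios sigma_k^2 / sigma^2
    reml_criterion: float
    n: int
    p: int
    singular: dict[str, bool] = field(default_factory=dict)
    colnames: list[str] = field(default_factory=list)

    @property
    def variance_components(self) -> dict[str, float]:
        out = {k: self.sigma2 * lam for k, lam in self.lambdas.items()}
        out["residual"] = self.sigma2
        return out

    def wald_F(self, cols: list[int] | np.ndarray) -> float:
        """Wald F for the joint null that the listed coefficients are zero."""
        cols = np.asarray(cols, int)
        b = self.beta[cols]
        c = self.cov_beta[np.ix_(cols, cols)]
        try:
            stat = float(b @ np.linalg.solve(c, b)) / len(cols)
        except np.linalg.LinAlgError:
            stat = float(b @ np.linalg.pinv(c) @ b) / len(cols)
        return max(stat, 0.0)


class LMMData:
    """Sufficient statistics for repeated REML fits on a fixed row set.

    Holds cross-products (X'X, Z'X, Z'Z, ...) and supports cheap in-place
    replacement of individual X columns, which is all a permutation needs.
    """

    def __init__(
        self,
        y: np.ndarray,
        X: np.ndarray,
        factors: dict[str, np.ndarray],
        colnames: list[str] | None = None,
    ) -> None:
        y = np.asarray(y, float)
        X = np.asarray(X, float)
        self.n, self.p = X.shape
        if self.n != len(y):
            raise ValueError("X and y row counts differ")
        self.y = y
        self.X = X.copy()
        self.colnames = colnames or [f"x{j}" for j in range(self.p)]
        self.factor_names = list(factors)
        self.codes: list[np.ndarray] = []
        self.q_per: list[int] = []
        for name in self.factor_names:
            codes = np.asarray(factors[name])
            if codes.dtype.kind not in "iu":
                _, codes = np.unique(codes, return_inverse=True)
            qk = int(codes.max()) + 1 if len(codes) else 0
            if qk < 2:
                raise ValueError(f"random factor '{name}' needs >= 2 levels")
            self.codes.append(codes.astype(np.intp))
            self.q_per.append(qk)
        self.q = int(sum(self.q_per))
        self.offsets = np.concatenate([[0], np.cumsum(self.q_per)])[:-1]
        # which lambda applies to each of the q random-effect columns
        self.col_factor = np.concatenate(
            [np.full(qk, k) for k, qk in enumerate(self.q_per)]
        ).astype(np.intp) if self.q else np.empty(0, np.intp)

        self._build_crossproducts()

        r = np.linalg.matrix_rank(self.XtX)
        if r < self.p:
            # identify aliased columns by pivoted QR of X'X
            diag = np.abs(np.diag(np.linalg.qr(self.XtX, mode="r")))
            bad = [self.colnames[j] for j in np.where(diag < 1e-8 * diag.max())[0]]
            raise RankDeficientError(f"rank-deficient fixed effects; aliased: {bad}")

    # -- construction -------------------------------------------------------

    def _zt(self, v: np.ndarray) -> np.ndarray:
        """Z' v for a length-n vector, stacked over factors."""
        out = np.empty(self.q)
        for k, codes in enumerate(self.codes):
            o = self.offsets[k]
            out[o : o + self.q_per[k]] = np.bincount(codes, weights=v, minlength=self.q_per[k])
        return out

    def _build_crossproducts(self) -> None:
        X, y = self.X, self.y
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)
        self.ZtX = np.empty((self.q, self.p))
        for j in range(self.p):
            self.ZtX[:, j] = self._zt(X[:, j])
        self.Zty = self._zt(y)
        self.ZtZ = np.zeros((self.q, self.q))
        for k, ck in enumerate(self.codes):
            ok = self.offsets[k]
            for l, cl in enumerate(self.codes):
                ol = self.offsets[l]
                if k == l:
                    counts = np.bincount(ck, minlength=self.q_per[k])
                    self.ZtZ[ok : ok + self.q_per[k], ol : ol + self.q_per[l]] += np.diag(
                        counts.astype(float)
                    )
                elif k < l:
                    block = np.zeros((self.q_per[k], self.q_per[l]))
                    np.add.at(block, (ck, cl), 1.0)
                    self.ZtZ[ok : ok + self.q_per[k], ol : ol + self.q_per[l]] = block
                    self.ZtZ[ol : ol + self.q_per[l], ok : ok + self.q_per[k]] = block.T

    # -- column replacement (permutations) ----------------------------------

    def set_column(self, j: int, values: np.ndarray) -> None:
        """Replace fixed-effect column j, updating every cross-product in O(n p)."""
        v = np.asarray(values, float)
        self.X[:, j] = v
        col = self.X.T @ v
        self.XtX[j, :] = col
        self.XtX[:, j] = col
        self.Xty[j] = float(v @ self.y)
        self.ZtX[:, j] = self._zt(v)

    # -- REML ----------------------------------------------------------------

    def _profile(self, lambdas: np.ndarray) -> tuple[float, dict]:
        """Profiled REML criterion and the quantities needed for the fit."""
        s = np.sqrt(lambdas[self.col_factor])  # per random-effect column
        SZtX = s[:, None] * self.ZtX
        SZty = s * self.Zty
        M = np.eye(self.q) + (s[:, None] * self.ZtZ) * s[None, :]
        cf = cho_factor(M, lower=True)
        logdetH = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
        MiZtX = cho_solve(cf, SZtX)
        MiZty = cho_solve(cf, SZty)
        XtHiX = self.XtX - SZtX.T @ MiZtX
        XtHiy = self.Xty - SZtX.T @ MiZty
        ytHiy = self.yty - float(SZty @ MiZty)
        try:
            cfx = cho_factor(XtHiX, lower=True)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded by rank check
            raise ConvergenceError(f"X'H^-1 X not positive definite: {exc}") from exc
        beta = cho_solve(cfx, XtHiy)
        rss = max(ytHiy - float(beta @ XtHiy), 1e-300)
        dof = self.n - self.p
        sigma2 = rss / dof
        logdetXtHiX = 2.0 * float(np.sum(np.log(np.diag(cfx[0]))))
        crit = dof * np.log(sigma2) + logdetH + logdetXtHiX
        return crit, {
            "beta": beta,
            "sigma2": sigma2,
            "XtHiX": XtHiX,
            "cfx": cfx,
        }

    def fit(self, start_lambdas: np.ndarray | None = None) -> LMMFit:
        """Minimise the REML criterion over the log variance ratios."""
        k = len(self.factor_names)
        x0 = np.log(np.full(k, 0.5)) if start_lambdas is None else np.log(
            np.clip(start_lambdas, 1e-8, None)
        )

        def objective(theta: np.ndarray) -> float:
            lam = np.exp(np.clip(theta, -30.0, 30.0))
            try:
                crit, _ = self._profile(lam)
            except (np.linalg.LinAlgError, ConvergenceError):
                return 1e12
            return crit

        # warm-started refits (permutations) can afford a looser stop rule:
        # the Wald F is flat in the variance ratios near the optimum
        opts = (
            {"xatol": 2e-3, "fatol": 1e-5, "maxiter": 200}
            if start_lambdas is not None
            else {"xatol": 1e-4, "fatol": 1e-8, "maxiter": 400}
        )
        res = minimize(objective, x0, method="Nelder-Mead", options=opts)
        if not np.isfinite(res.fun) or res.fun >= 1e12:
            raise ConvergenceError(f"REML optimisation failed: {res.message}")
        lam = np.exp(np.clip(res.x, -30.0, 30.0))
        crit, parts = self._profile(lam)
        cov_beta = parts["sigma2"] * cho_solve(parts["cfx"], np.eye(self.p))
        cov_beta = (cov_beta + cov_beta.T) / 2.0
        se = np.sqrt(np.clip(np.diag(cov_beta), 0.0, None))
        singular = {
            name: bool(lam[i] < SINGULAR_TOL) for i, name in enumerate(self.factor_names)
        }
        return LMMFit(
            beta=parts["beta"],
            se=se,
            cov_beta=cov_beta,
            sigma2=parts["sigma2"],
            lambdas=dict(zip(self.factor_names, lam)),
            reml_criterion=crit,
            n=self.n,
            p=self.p,
            singular=singular,
            colnames=list(self.colnames),
        )
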