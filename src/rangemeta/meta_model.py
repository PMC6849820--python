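"""Multilevel random-effects meta-regression for log response ratios.

The model for effect size :math:`y_i` is

.. math::

    y_i = x_i^\\top \\beta + u_{exp(i)} + u_{pub(i)} + u_{meth(i)} + e_i

with independent mean-zero random effects for experiment, publication nested
within experiment, and (where a response was measured by more than one
method) measurement method, each with its own variance component, plus a
residual.  Two weighting conventions are supported:

``unweighted``
    The reported sampling variances are ignored and the residual variance is
    estimated freely.  This is the appropriate default when many sampling
    variances were imputed from p-value ranges and are not trustworthy as
    weights.
``inverse_variance``
    The marginal covariance additionally carries the known per-observation
    sampling variances on its diagonal, as in a conventional multivariate
    meta-analysis.

Estimation maximises the restricted (REML) or full (ML) Gaussian likelihood
over the variance components on the log scale (bounded quasi-Newton with
analytic gradients and dispersed restarts); the fixed effects follow by
generalised least squares at the optimum.  REML is used for reported
coefficients of a single model; ML whenever models with different fixed
effects are compared or averaged by AIC, since restricted likelihoods are
not comparable across fixed-effect structures.

The entry points mirror the statsmodels idiom: build a
:class:`MetaRegression` from data, call :meth:`~MetaRegression.fit`, and
read estimates off the returned :class:`MetaRegressionResults`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "ModeratorTransform",
    "ModeratorSpec",
    "RandomEffectsSpec",
    "MetaRegression",
    "MetaRegressionResults",
    "ConvergenceError",
    "transform_moderators",
    "build_design",
    "fit_meta_model",
    "wald_ci",
    "report_overall_effect",
]

_SIGMA_FLOOR = 1e-12  # variance floor used inside the linear algebra
_SIGMA_TRUNC = 1e-10  # components below this are reported as exactly 0


class ConvergenceError(RuntimeError):
    """Raised when no optimizer start converges; carries the trace."""

    def __init__(self, message: str, trace=None):
        super().__init__(message)
        self.trace = trace


# ---------------------------------------------------------------------------
# moderator transformation


@dataclass
class ModeratorTransform:
    """log -> center -> scale transform for continuous moderators.

    The per-term mean and sample SD of the *log-scale* values are captured at
    fit time and reused verbatim for every subsequent transform — notably for
    scenario prediction, which must never re-standardise on scenario values.
    """

    stats: dict[str, tuple[float, float]] = field(default_factory=dict)

    def fit(self, data: pd.DataFrame, terms: Sequence[str]) -> "ModeratorTransform":
        for term in terms:
            values = np.asarray(data[term], dtype=float)
            if np.any(~np.isfinite(values)) or np.any(values <= 0):
                bad = np.where(~(values > 0))[0]
                raise ValueError(
                    f"moderator {term!r} must be strictly positive to "
                    f"log-transform; offending rows {bad[:5].tolist()}"
                )
            logs = np.log(values)
            mu = float(np.mean(logs))
            sd = float(np.std(logs, ddof=1)) if len(logs) > 1 else 0.0
            if sd == 0.0:
                raise ValueError(f"moderator {term!r} is constant (zero SD) on the log scale")
            self.stats[term] = (mu, sd)
        return self

    def transform(self, data: pd.DataFrame | Mapping[str, float]) -> pd.DataFrame:
        if isinstance(data, Mapping):
            data = pd.DataFrame({k: [v] for k, v in data.items()})
        out = data.copy()
        for term, (mu, sd) in self.stats.items():
            if term not in out:
                continue
            values = np.asarray(out[term], dtype=float)
            if np.any(~(values > 0)):
                raise ValueError(f"moderator {term!r} must be strictly positive")
            out[term] = (np.log(values) - mu) / sd
        return out


def transform_moderators(
    data: pd.DataFrame, terms: Sequence[str]
) -> tuple[pd.DataFrame, ModeratorTransform]:
    """Standardise continuous moderators; returns the data and fitted stats."""
    tr = ModeratorTransform().fit(data, terms)
    return tr.transform(data), tr


@dataclass
class ModeratorSpec:
    """Which moderators enter a model and how.

    ``continuous`` terms are log-transformed, centered and scaled;
    ``categorical`` currently means the climate dummy (dryland=0,
    mediterranean=1, never effect-coded); ``covariate_only`` terms (soil
    sample depth) may never appear in interactions.
    """

    continuous: tuple[str, ...] = ("days_since_application", "amount_applied", "amendment_n")
    categorical: tuple[str, ...] = ("climate_zone",)
    covariate_only: tuple[str, ...] = ("soil_depth",)

    def main_terms(self, include_climate: bool = True, include_depth: bool = False):
        terms = list(self.continuous)
        if include_climate:
            terms += list(self.categorical)
        if include_depth:
            terms += list(self.covariate_only)
        return tuple(terms)


@dataclass
class RandomEffectsSpec:
    """Grouping factors: experiment, publication-in-experiment, optional method."""

    experiment: str = "experiment_id"
    publication: str = "publication_id"
    method: str | None = None  # column name, e.g. "method_subtype"

    def factors(self, data: pd.DataFrame) -> dict[str, np.ndarray]:
        """Integer group codes per factor; publication codes are nested."""
        out: dict[str, np.ndarray] = {}
        exp = data[self.experiment].astype(str)
        out["experiment"] = pd.factorize(exp)[0]
        # composite key makes publication labels unique within experiment
        pub = exp.str.cat(data[self.publication].astype(str), sep="//")
        out["publication"] = pd.factorize(pub)[0]
        if self.method is not None and self.method in data:
            meth = data[self.method].astype(str)
            if meth.nunique() > 1:
                out["method"] = pd.factorize(meth)[0]
        return out


_CLIMATE_CODES = {"dryland": 0.0, "mediterranean": 1.0}


def _climate_column(values: pd.Series) -> np.ndarray:
    """Dummy-code the climate zone column (dryland=0, mediterranean=1)."""
    if values.dtype.kind in "fiu":
        return np.asarray(values, dtype=float)
    try:
        return np.array([_CLIMATE_CODES[str(v).lower()] for v in values])
    except KeyError as err:  # pragma: no cover - schema guard
        raise ValueError(f"unknown climate zone {err.args[0]!r}") from None


def build_design(
    data: pd.DataFrame, terms: Sequence
) -> tuple[np.ndarray, list[str]]:
    """Design matrix (intercept first) from standardised data and a term set.

    A term is a column name or an (a, b) pair denoting the product
    interaction ``a:b`` of the two (already standardised / dummy) columns.
    """
    n = len(data)
    cols = [np.ones(n)]
    names = ["intercept"]
    for term in terms:
        if isinstance(term, tuple):
            a, b = term
            cols.append(_term_column(data, a) * _term_column(data, b))
            names.append(f"{a}:{b}")
        else:
            cols.append(_term_column(data, term))
            names.append(str(term))
    X = np.column_stack(cols)
    return X, names


def _term_column(data: pd.DataFrame, term: str) -> np.ndarray:
    if term == "climate_zone":
        return _climate_column(data[term])
    return np.asarray(data[term], dtype=float)


# ---------------------------------------------------------------------------
# likelihood engine


class _MarginalLikelihood:
    """REML/ML objective for V = sum_k s2_k Z_k Z_k' + s2_e I (+ diag(v))."""

    def __init__(self, y, X, group_codes: Sequence[np.ndarray], v=None, reml=True):
        self.y = np.asarray(y, dtype=float)
        self.X = np.asarray(X, dtype=float)
        self.n, self.p = self.X.shape
        self.reml = reml
        self.v = None if v is None else np.asarray(v, dtype=float)
        # indicator cross-products A_k = Z_k Z_k' as dense boolean masks
        self.A = [
            (np.asarray(codes)[:, None] == np.asarray(codes)[None, :]).astype(float)
            for codes in group_codes
        ]
        self.k_var = len(self.A) + 1  # + residual

    def _V(self, sigma2: np.ndarray) -> np.ndarray:
        V = np.diag(np.full(self.n, max(sigma2[-1], _SIGMA_FLOOR)))
        if self.v is not None:
            V[np.diag_indices(self.n)] += self.v
        for s2, A in zip(sigma2[:-1], self.A):
            if s2 > 0:
                V += s2 * A
        return V

    def loglik(self, sigma2: np.ndarray):
        """Log-likelihood, GLS beta, its covariance, and reusable solves."""
        V = self._V(sigma2)
        try:
            L = np.linalg.cholesky(V)
        except np.linalg.LinAlgError:
            return None
        logdetV = 2.0 * np.sum(np.log(np.diag(L)))
        # solves against V
        Vi_y = _chol_solve(L, self.y)
        Vi_X = _chol_solve(L, self.X)
        XtViX = self.X.T @ Vi_X
        XtViy = self.X.T @ Vi_y
        try:
            cov_beta = np.linalg.inv(XtViX)
        except np.linalg.LinAlgError:
            return None
        beta = cov_beta @ XtViy
        r = self.y - self.X @ beta
        Vi_r = Vi_y - Vi_X @ beta
        quad = float(r @ Vi_r)
        if self.reml:
            sign, logdetXtViX = np.linalg.slogdet(XtViX)
            if sign <= 0:
                return None
            ll = -0.5 * (
                (self.n - self.p) * math.log(2 * math.pi)
                + logdetV + logdetXtViX + quad
            )
        else:
            ll = -0.5 * (self.n * math.log(2 * math.pi) + logdetV + quad)
        return ll, beta, cov_beta, L, Vi_X, Vi_r

    def neg_loglik_grad(self, theta: np.ndarray):
        """Negative log-likelihood and gradient w.r.t. theta = log sigma2."""
        sigma2 = np.exp(theta)
        out = self.loglik(sigma2)
        if out is None:
            return np.inf, np.zeros_like(theta)
        ll, beta, cov_beta, L, Vi_X, Vi_r = out
        n = self.n
        Vi = _chol_solve(L, np.eye(n))
        if self.reml:
            # P = Vi - Vi X (X'ViX)^-1 X'Vi ; note Vi_r = P y at the GLS beta
            P = Vi - Vi_X @ cov_beta @ Vi_X.T
        else:
            P = Vi
        grad = np.empty_like(theta)
        for k, A in enumerate(self.A):
            dl = -0.5 * float(np.sum(P * A)) + 0.5 * float(Vi_r @ A @ Vi_r)
            grad[k] = dl * sigma2[k]
        dl_res = -0.5 * float(np.trace(P)) + 0.5 * float(Vi_r @ Vi_r)
        grad[-1] = dl_res * sigma2[-1]
        return -ll, -grad


def _chol_solve(L: np.ndarray, b: np.ndarray) -> np.ndarray:
    from scipy.linalg import solve_triangular

    z = solve_triangular(L, b, lower=True, check_finite=False)
    return solve_triangular(L.T, z, lower=False, check_finite=False)


# ---------------------------------------------------------------------------
# model / results


class MetaRegression:
    """Multilevel random-effects meta-regression model.

    Parameters
    ----------
    endog : array-like
        Effect sizes (log response ratios).
    exog : ndarray
        Design matrix, intercept column first.
    groups : mapping factor name -> integer/label codes per observation.
    sampling_var : array-like, optional
        Known per-observation sampling variances (used only in
        ``inverse_variance`` weighting).
    exog_names : sequence of str, optional.
    """

    def __init__(self, endog, exog, groups: Mapping[str, np.ndarray],
                 sampling_var=None, exog_names=None, transform: ModeratorTransform | None = None,
                 terms: tuple | None = None):
        y = np.asarray(endog, dtype=float)
        X = np.atleast_2d(np.asarray(exog, dtype=float))
        if X.shape[0] != y.shape[0]:
            raise ValueError("endog and exog lengths differ")
        self.exog_names = list(exog_names) if exog_names is not None else [
            f"x{j}" for j in range(X.shape[1])
        ]
        group_items = list(groups.items())
        codes = [pd.factorize(np.asarray(c))[0] for _, c in group_items]
        for name, c in zip([g[0] for g in group_items], codes):
            if len(np.unique(c)) < 2:
                raise ValueError(f"random factor {name!r} has fewer than 2 levels")
        v = None if sampling_var is None else np.asarray(sampling_var, dtype=float)
        # canonical row order -> estimates invariant to input permutations
        order = np.lexsort(tuple(X.T[::-1]) + tuple(codes[::-1]) + (y,))
        self.endog = y[order]
        self.exog = X[order]
        self.group_names = [g[0] for g in group_items]
        self.group_codes = [c[order] for c in codes]
        self.sampling_var = None if v is None else v[order]
        self.transform = transform
        self.terms = terms
        if np.linalg.matrix_rank(self.exog) < self.exog.shape[1]:
            raise ValueError(
                f"design matrix is rank deficient; collinear terms among {self.exog_names}"
            )

    @classmethod
    def from_effects(
        cls,
        effects: pd.DataFrame,
        terms: Sequence = (),
        re_spec: RandomEffectsSpec | None = None,
        transform: ModeratorTransform | None = None,
    ) -> "MetaRegression":
        """Build the model from an effect-size table.

        ``terms`` are moderator names / interaction pairs; continuous terms
        are standardised with ``transform`` (fitted on this data if not
        supplied).  An empty term set gives the intercept-only overall-effect
        model.
        """
        re_spec = re_spec or RandomEffectsSpec()
        continuous = sorted(
            {t for t in _flatten(terms) if t not in ("climate_zone",)}
        )
        if transform is None and continuous:
            transform = ModeratorTransform().fit(effects, continuous)
        data = transform.transform(effects) if transform else effects
        X, names = build_design(data, terms)
        groups = {k: v for k, v in re_spec.factors(effects).items()}
        return cls(
            effects["lnrr"], X, groups,
            sampling_var=effects["variance"] if "variance" in effects else None,
            exog_names=names, transform=transform, terms=tuple(terms),
        )

    def fit(
        self,
        method: str = "REML",
        weighting: str = "unweighted",
        n_restarts: int = 5,
        tol: float = 1e-10,
        seed: int = 0,
    ) -> "MetaRegressionResults":
        """Maximise the (restricted) likelihood over the variance components.

        Optimisation runs on the log-variance scale with L-BFGS-B from one
        moment-based start plus dispersed random restarts; restarts stop
        early once two starts agree on the optimum.  Components below 1e-10
        are truncated to exactly zero in the report.
        """
        if method not in ("REML", "ML"):
            raise ValueError("method must be 'REML' or 'ML'")
        if weighting not in ("unweighted", "inverse_variance"):
            raise ValueError("weighting must be 'unweighted' or 'inverse_variance'")
        v = self.sampling_var if weighting == "inverse_variance" else None
        lik = _MarginalLikelihood(
            self.endog, self.exog, self.group_codes, v=v, reml=(method == "REML")
        )
        k = lik.k_var
        var_y = max(float(np.var(self.endog, ddof=1)), 1e-8)
        lo, hi = math.log(1e-12), math.log(1e3 * var_y)
        bounds = [(lo, hi)] * k
        base = np.full(k, math.log(var_y / k))
        rng = np.random.default_rng(seed)
        starts = [base] + [
            np.clip(base + rng.uniform(-4.0, 4.0, size=k), lo, hi)
            for _ in range(max(0, n_restarts - 1))
        ]
        best, trace, agree = None, [], 0
        for x0 in starts:
            res = optimize.minimize(
                lik.neg_loglik_grad, x0, jac=True, method="L-BFGS-B",
                bounds=bounds, options={"ftol": 1e-14, "gtol": 1e-10, "maxiter": 500},
            )
            trace.append(res)
            if not np.isfinite(res.fun):
                continue
            if best is None or res.fun < best.fun - 1e-9:
                best, agree = res, 0
            elif abs(res.fun - best.fun) <= 1e-7:
                agree += 1
                if agree >= 1:
                    break
        if best is None:
            raise ConvergenceError("no optimizer start converged", trace=trace)
        sigma2 = np.exp(best.x)
        sigma2[sigma2 < _SIGMA_TRUNC] = 0.0
        out = lik.loglik(np.maximum(sigma2, 0.0))
        if out is None:  # pragma: no cover - safety net
            raise ConvergenceError("likelihood undefined at optimum", trace=trace)
        ll, beta, cov_beta, *_ = out
        names = self.group_names + ["residual"]
        k_params = self.exog.shape[1] + k
        return MetaRegressionResults(
            model=self,
            params=pd.Series(beta, index=self.exog_names),
            cov_params=pd.DataFrame(cov_beta, index=self.exog_names, columns=self.exog_names),
            sigma2=dict(zip(names, sigma2)),
            llf=float(ll),
            method=method,
            weighting=weighting,
            k_params=k_params,
            nobs=len(self.endog),
            converged=bool(best.success),
        )


def _flatten(terms):
    for t in terms:
        if isinstance(t, tuple):
            yield from t
        else:
            yield t


@dataclass
class MetaRegressionResults:
    """Fitted multilevel meta-regression: coefficients, components, fit stats."""

    model: MetaRegression
    params: pd.Series
    cov_params: pd.DataFrame
    sigma2: dict[str, float]
    llf: float
    method: str
    weighting: str
    k_params: int
    nobs: int
    converged: bool

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov_params)), index=self.params.index)

    @property
    def aic(self) -> float:
        return -2.0 * self.llf + 2.0 * self.k_params

    def conf_int(self, level: float = 0.95) -> pd.DataFrame:
        if not (0 < level < 1):
            raise ValueError("level must lie in (0, 1)")
        z = stats.norm.ppf(1 - (1 - level) / 2)
        lo = self.params - z * self.bse
        hi = self.params + z * self.bse
        return pd.DataFrame({"lower": lo, "upper": hi})

    def wald_ci(self, name: str, level: float = 0.95) -> tuple[float, float]:
        if name not in self.params.index:
            raise KeyError(f"unknown coefficient {name!r}")
        ci = self.conf_int(level)
        return float(ci.loc[name, "lower"]), float(ci.loc[name, "upper"])

    def predict(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Fixed-effects predictions and their standard errors at rows of X."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        pred = X @ self.params.to_numpy()
        se = np.sqrt(np.einsum("ij,jk,ik->i", X, self.cov_params.to_numpy(), X))
        return pred, se

    def summary(self) -> str:
        ci = self.conf_int()
        lines = [
            "Multilevel random-effects meta-regression",
            f"  method: {self.method}   weighting: {self.weighting}   n: {self.nobs}",
            f"  loglik: {self.llf:.4f}   AIC: {self.aic:.4f}   k: {self.k_params}",
            "  Fixed effects:",
        ]
        for name in self.params.index:
            lines.append(
                f"    {name:<34s} {self.params[name]:>10.4f}  "
                f"(SE {self.bse[name]:.4f}, 95% CI {ci.loc[name,'lower']:.4f} "
                f"to {ci.loc[name,'upper']:.4f})"
            )
        lines.append("  Variance components:")
        for name, s2 in self.sigma2.items():
            lines.append(f"    sigma2[{name}] = {s2:.6f}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# spec-surface functional wrappers


def fit_meta_model(
    effects: pd.DataFrame,
    terms: Sequence = (),
    re_spec: RandomEffectsSpec | None = None,
    method: str = "REML",
    weighting: str = "unweighted",
    transform: ModeratorTransform | None = None,
    **kwargs,
) -> MetaRegressionResults:
    """Convenience wrapper: build and fit in one call."""
    model = MetaRegression.from_effects(effects, terms, re_spec, transform)
    return model.fit(method=method, weighting=weighting, **kwargs)


def wald_ci(fit: MetaRegressionResults, coefficient: str = "intercept",
            level: float = 0.95) -> tuple[float, float]:
    return fit.wald_ci(coefficient, level)


def report_overall_effect(fit: MetaRegressionResults, level: float = 0.95) -> dict:
    """Overall effect on the log and response-ratio scales with its CI."""
    est = float(fit.params["intercept"])
    lo, hi = fit.wald_ci("intercept", level)
    return {
        "lnrr": est,
        "lnrr_ci": (lo, hi),
        "ratio": math.exp(est),
        "ratio_ci": (math.exp(lo), math.exp(hi)),
    }
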