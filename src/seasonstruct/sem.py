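"""Structural equation models with latent variables.

A small covariance-structure (LISREL/RAM) estimator: measurement equations
``Latent =~ ind1 + ind2 + ...`` and structural regressions ``y ~ x + ...``
are parsed from a lavaan-like model string, arranged in the RAM form

    Sigma(theta) = F (I - A)^-1 S (I - A)^-T F^T,

where A holds loadings and regression paths, S variances and covariances,
and F selects observed variables.  Parameters are estimated by maximum
likelihood on the sample covariance of standardized variables,

    F_ML = log|Sigma| + tr(S_n Sigma^-1) - log|S_n| - p,

minimized with scipy; standard errors come from the numerical Hessian.
The default model used in this package regresses seasonal structural
stability (SS) on latent Diversity and Variability factors and the net
biodiversity effect (NBE) on all three.

Usage follows the statsmodels convention::

    res = SemModel(df, MODEL_SPEC).fit()
    res.summary()
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

DEFAULT_SEM_SPEC = """
Diversity =~ richness + pd + fd
Variability =~ var_phylo + var_taxo + var_func
ss ~ Diversity + Variability
nbe ~ ss + Diversity + Variability
"""


class SemIdentificationError(ValueError):
    """Raised when the model cannot be identified from the data
    (e.g. perfectly collinear indicators)."""


class SemConvergenceError(RuntimeError):
    """Raised when the optimizer fails; carries the scipy result."""

    def __init__(self, message: str, opt_result) -> None:
        super().__init__(message)
        self.opt_result = opt_result


@dataclass(frozen=True)
class _Param:
    kind: str   # "loading" | "path" | "var" | "cov"
    lhs: str
    rhs: str


def parse_model(spec: str) -> tuple[dict[str, list[str]], list[tuple[str, str]]]:
    """Parse ``=~`` measurement and ``~`` regression lines.

    Returns (loadings: latent -> indicator list, paths: list of (lhs, rhs)).
    """
    loadings: dict[str, list[str]] = {}
    paths: list[tuple[str, str]] = []
    for raw in spec.strip().splitlines():
        line = raw.split("#")[0].strip()
        if not line:
            continue
        if "=~" in line:
            lhs, rhs = line.split("=~")
            loadings[lhs.strip()] = [t.strip() for t in re.split(r"\+", rhs) if t.strip()]
        elif "~" in line:
            lhs, rhs = line.split("~", 1)
            for term in re.split(r"\+", rhs):
                if term.strip():
                    paths.append((lhs.strip(), term.strip()))
        else:
            raise ValueError(f"cannot parse model line: {raw!r}")
    return loadings, paths


class SemModel:
    """Latent-variable SEM built from a DataFrame and a model string.

    Variables are standardized (z-scored) before fitting; rows with missing
    values are dropped listwise.
    """

    def __init__(self, data: pd.DataFrame, spec: str = DEFAULT_SEM_SPEC) -> None:
        self.loadings_spec, self.paths_spec = parse_model(spec)
        self.latents = list(self.loadings_spec)
        observed: list[str] = []
        for inds in self.loadings_spec.values():
            observed.extend(inds)
        for lhs, rhs in self.paths_spec:
            for v in (lhs, rhs):
                if v not in self.latents and v not in observed:
                    observed.append(v)
        self.observed = observed
        self.names = self.observed + self.latents

        df = data[self.observed].dropna()
        self.nobs = len(df)
        if self.nobs <= len(self.observed):
            raise ValueError(f"too few complete rows ({self.nobs}) for SEM")
        z = (df - df.mean()) / df.std(ddof=1)
        self.sample_cov = np.cov(z.to_numpy(), rowvar=False, ddof=1)
        eig = np.linalg.eigvalsh(self.sample_cov)
        if eig.min() < 1e-10:
            raise SemIdentificationError(
                "sample covariance is singular (collinear indicators?)"
            )
        self._build_parameters()

    # -- parameter bookkeeping ------------------------------------------------
    def _build_parameters(self) -> None:
        idx = {v: i for i, v in enumerate(self.names)}
        self._idx = idx
        m = len(self.names)
        self._fixed_A = np.zeros((m, m))
        params: list[_Param] = []
        endogenous = set()
        for lat, inds in self.loadings_spec.items():
            self._fixed_A[idx[inds[0]], idx[lat]] = 1.0  # scale anchor
            endogenous.update(inds)
            for ind in inds[1:]:
                params.append(_Param("loading", ind, lat))
        regressed = set()
        for lhs, rhs in self.paths_spec:
            params.append(_Param("path", lhs, rhs))
            regressed.add(lhs)
            endogenous.add(lhs)
        # residual variances for all observed; variances for latents
        for v in self.observed:
            params.append(_Param("var", v, v))
        exog_lat = [l for l in self.latents if l not in regressed]
        for l in self.latents:
            params.append(_Param("var", l, l))
        for i, a in enumerate(exog_lat):
            for b in exog_lat[i + 1:]:
                params.append(_Param("cov", a, b))
        self.param_index = params
        self.k_params = len(params)

    def _matrices(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        m = len(self.names)
        A = self._fixed_A.copy()
        S = np.zeros((m, m))
        idx = self._idx
        for val, p in zip(theta, self.param_index):
            i, j = idx[p.lhs], idx[p.rhs]
            if p.kind in ("loading", "path"):
                A[i, j] = val
            elif p.kind == "var":
                S[i, i] = val
            else:
                S[i, j] = S[j, i] = val
        return A, S

    def implied_cov(self, theta: np.ndarray) -> np.ndarray:
        A, S = self._matrices(theta)
        m = len(self.names)
        inv = np.linalg.inv(np.eye(m) - A)
        total = inv @ S @ inv.T
        p = len(self.observed)
        return total[:p, :p], total

    def _objective(self, theta: np.ndarray) -> float:
        sigma, _ = self.implied_cov(theta)
        try:
            chol = np.linalg.cholesky(sigma)  # also certifies pd
        except np.linalg.LinAlgError:
            return 1e10
        logdet = 2.0 * np.log(np.diag(chol)).sum()
        inv = np.linalg.inv(sigma)
        s = self.sample_cov
        _, logdet_s = np.linalg.slogdet(s)
        return float(logdet + np.trace(s @ inv) - logdet_s - len(self.observed))

    def _start(self) -> np.ndarray:
        theta = np.empty(self.k_params)
        for i, p in enumerate(self.param_index):
            if p.kind == "loading":
                theta[i] = 0.8
            elif p.kind == "path":
                theta[i] = 0.1
            elif p.kind == "var":
                theta[i] = 0.5
            else:
                theta[i] = 0.1
        return theta

    def fit(self, maxiter: int = 2000) -> "SemResults":
        bounds = [
            (1e-6, None) if p.kind == "var" else (None, None)
            for p in self.param_index
        ]
        res = optimize.minimize(
            self._objective, self._start(), method="L-BFGS-B", bounds=bounds,
            options={"maxiter": maxiter, "ftol": 1e-11, "gtol": 1e-8},
        )
        if not res.success or res.fun >= 1e9:
            raise SemConvergenceError(
                f"SEM did not converge: {res.message} (F_ML={res.fun:.4g}, "
                f"nit={res.nit})", res
            )
        return SemResults(self, res.x, float(res.fun), res)


def _numerical_hessian(f, x: np.ndarray, eps: float = 1e-5) -> np.ndarray:
    n = x.size
    h = np.zeros((n, n))
    f0 = f(x)
    for i in range(n):
        for j in range(i, n):
            xpp = x.copy(); xpp[i] += eps; xpp[j] += eps
            xpm = x.copy(); xpm[i] += eps; xpm[j] -= eps
            xmp = x.copy(); xmp[i] -= eps; xmp[j] += eps
            xmm = x.copy(); xmm[i] -= eps; xmm[j] -= eps
            h[i, j] = h[j, i] = (f(xpp) - f(xpm) - f(xmp) + f(xmm)) / (4 * eps * eps)
    return h, f0


class SemResults:
    """Estimates, standard errors, standardized solution and R^2."""

    def __init__(self, model: SemModel, theta: np.ndarray, fmin: float, opt) -> None:
        self.model = model
        self.theta = theta
        self.fmin = fmin
        self.opt_result = opt
        self._compute()

    def _compute(self) -> None:
        model = self.model
        n = model.nobs
        hess, _ = _numerical_hessian(model._objective, self.theta)
        # cov(theta) = 2/(n-1) * H^-1 for the F_ML discrepancy
        try:
            hinv = np.linalg.pinv(hess)
        except np.linalg.LinAlgError:
            hinv = np.full((model.k_params, model.k_params), np.nan)
        pcov = 2.0 / (n - 1) * hinv
        se = np.sqrt(np.clip(np.diag(pcov), 0, None))
        zval = np.divide(self.theta, se, out=np.full_like(se, np.nan), where=se > 0)
        pval = 2 * stats.norm.sf(np.abs(zval))

        _, total = model.implied_cov(self.theta)
        sd = np.sqrt(np.clip(np.diag(total), 1e-12, None))
        idx = model._idx
        A, S = model._matrices(self.theta)

        # latent sign canonicalization: a latent is only identified up to
        # sign; orient each so its mean standardized loading is positive
        sign = {name: 1.0 for name in model.names}
        for lat, inds in model.loadings_spec.items():
            li = [idx[i] for i in inds]
            ri = idx[lat]
            mean_loading = np.mean([A[i, ri] * sd[ri] / sd[i] for i in li])
            if mean_loading < 0:
                sign[lat] = -1.0

        rows = []
        for i, p in enumerate(model.param_index):
            li, ri = idx[p.lhs], idx[p.rhs]
            flip = sign[p.lhs] * sign[p.rhs]
            if p.kind in ("loading", "path"):
                std = A[li, ri] * sd[ri] / sd[li] * flip
            elif p.kind == "var":
                std = S[li, li] / total[li, li]
            else:
                std = S[li, ri] / (sd[li] * sd[ri]) * flip
            rows.append(
                {
                    "kind": p.kind, "lhs": p.lhs, "rhs": p.rhs,
                    "estimate": self.theta[i], "se": se[i],
                    "z": zval[i], "pvalue": pval[i], "std_estimate": std,
                }
            )
        # anchor loadings (fixed to 1) reported too, standardized
        for lat, inds in model.loadings_spec.items():
            li, ri = idx[inds[0]], idx[lat]
            rows.append(
                {
                    "kind": "loading", "lhs": inds[0], "rhs": lat,
                    "estimate": 1.0, "se": np.nan, "z": np.nan, "pvalue": np.nan,
                    "std_estimate": A[li, ri] * sd[ri] / sd[li] * sign[lat],
                }
            )
        self.estimates = pd.DataFrame(rows)

        endog = sorted({lhs for lhs, _ in model.paths_spec})
        self.rsquared = {
            v: float(1.0 - S[idx[v], idx[v]] / total[idx[v], idx[v]]) for v in endog
        }

    @property
    def paths(self) -> pd.DataFrame:
        return self.estimates[self.estimates["kind"] == "path"].reset_index(drop=True)

    @property
    def loadings(self) -> pd.DataFrame:
        return self.estimates[self.estimates["kind"] == "loading"].reset_index(drop=True)

    def path_coefficient(self, lhs: str, rhs: str, standardized: bool = True) -> float:
        sel = self.paths[(self.paths["lhs"] == lhs) & (self.paths["rhs"] == rhs)]
        if sel.empty:
            raise KeyError(f"no path {lhs} ~ {rhs}")
        return float(sel["std_estimate" if standardized else "estimate"].iloc[0])

    def summary(self) -> str:
        lines = [
            "Structural equation model (ML on standardized variables)",
            f"n = {self.model.nobs}, F_ML = {self.fmin:.6f}, "
            f"free parameters = {self.model.k_params}",
            "",
            self.estimates.to_string(
                index=False, float_format=lambda v: f"{v: .4f}"
            ),
            "",
        ]
        for v, r2 in self.rsquared.items():
            lines.append(f"R^2({v}) = {r2:.3f}")
        return "\n".join(lines)
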