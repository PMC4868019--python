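"""Binomial logistic mixed models with random intercepts.

Model: for row j in group i, successes k_j ~ Binomial(n_j, p_j) with
logit(p_j) = x_j' beta + b_{i(j)}, b_i ~ N(0, sigma_a^2); the nested variant
adds independent intercepts for an outer grouping (field within transect).
Estimation maximises the Laplace approximation to the marginal likelihood;
for single-grouping models an adaptive Gauss-Hermite quadrature evaluation
is available as a verification mode. The module also carries the
model-comparison toolkit used around such fits: small-sample AIC (AICc),
Nakagawa-Schielzeth marginal/conditional R2 on the latent scale, predictor
standardisation (centred, divided by two standard deviations), the design
condition number kappa, and single-term-deletion likelihood-ratio tests.

Model formulas use the familiar text syntax, e.g.::

    n_land/n_forage_points ~ stage + cloud + temp + sunrise_prox + (1|individual_id)
    present ~ veg_height + obs_period + (1|transect_id/field_id)
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from scipy.special import expit, gammaln

LATENT_LOGISTIC_VAR = math.pi ** 2 / 3.0

_MAX_ETA = 30.0  # logit clamp; expit saturates well before this


class SpecificationError(ValueError):
    """Formula/design problem (aliased columns, unknown terms, ...)."""


# ---------------------------------------------------------------------------
# formula handling
# ---------------------------------------------------------------------------

@dataclass
class GlmmSpec:
    """Parsed model specification.

    ``response`` is the successes column (or a 0/1 column when ``trials`` is
    None, giving a Bernoulli model); ``fixed`` lists main-effect and ``a:b``
    interaction terms in declaration order; ``random`` holds the grouping
    columns — one for a single random intercept, two ``(outer, inner)`` for
    nested intercepts.
    """

    response: str
    trials: str | None
    fixed: list[str]
    random: tuple[str, ...]

    @property
    def formula(self) -> str:
        resp = self.response if self.trials is None else f"{self.response}/{self.trials}"
        rnd = "/".join(self.random)
        rhs = " + ".join(self.fixed) if self.fixed else "1"
        tail = f" + (1|{rnd})" if self.random else ""
        return f"{resp} ~ {rhs}{tail}"


def parse_formula(formula: str) -> GlmmSpec:
    """Parse ``response[/trials] ~ terms + (1|group[/subgroup])``."""
    if "~" not in formula:
        raise SpecificationError(f"no '~' in formula: {formula!r}")
    lhs, rhs = (s.strip() for s in formula.split("~", 1))
    if "/" in lhs:
        response, trials = (s.strip() for s in lhs.split("/", 1))
    else:
        response, trials = lhs, None

    random: tuple[str, ...] = ()
    m = re.search(r"\(\s*1\s*\|\s*([^)]+)\)", rhs)
    if m:
        random = tuple(s.strip() for s in m.group(1).split("/"))
        if len(random) > 2:
            raise SpecificationError("at most two nested grouping levels supported")
        rhs = (rhs[:m.start()] + rhs[m.end():])

    fixed: list[str] = []
    for tok in (t.strip() for t in rhs.split("+")):
        if not tok or tok == "1":
            continue
        if "*" in tok:
            a, b = (s.strip() for s in tok.split("*", 1))
            for t in (a, b, f"{a}:{b}"):
                if t not in fixed:
                    fixed.append(t)
        else:
            if tok not in fixed:
                fixed.append(tok)
    for t in fixed:
        if ":" in t:
            a, b = t.split(":")
            if a not in fixed or b not in fixed:
                raise SpecificationError(
                    f"interaction {t} requires both main effects in the model")
    return GlmmSpec(response, trials, fixed, random)


def _levels(col: pd.Series) -> list:
    if isinstance(col.dtype, pd.CategoricalDtype):
        return [lv for lv in col.cat.categories if (col == lv).any()]
    return sorted(pd.unique(col.dropna()))


def _is_categorical(col: pd.Series) -> bool:
    return (isinstance(col.dtype, pd.CategoricalDtype)
            or col.dtype == object or col.dtype == bool)


def _encode_main(df: pd.DataFrame, term: str) -> tuple[np.ndarray, list[str]]:
    col = df[term]
    if _is_categorical(col):
        levels = _levels(col)
        # first level (declaration order for ordered categoricals) = reference
        cols = [(col == lv).to_numpy(float) for lv in levels[1:]]
        names = [f"{term}[{lv}]" for lv in levels[1:]]
        if not cols:
            raise SpecificationError(f"categorical {term} has a single level")
        return np.column_stack(cols), names
    return col.to_numpy(float)[:, None], [term]


def build_design(df: pd.DataFrame, fixed: list[str]) -> tuple[np.ndarray, list[str]]:
    """Dense fixed-effects design matrix with leading intercept column."""
    blocks = [np.ones((len(df), 1))]
    names = ["(Intercept)"]
    encoded: dict[str, tuple[np.ndarray, list[str]]] = {}
    for term in fixed:
        if ":" in term:
            a, b = term.split(":")
            Xa, na = encoded[a]
            Xb, nb = encoded[b]
            cols, cnames = [], []
            for i, an in enumerate(na):
                for j, bn in enumerate(nb):
                    cols.append(Xa[:, i] * Xb[:, j])
                    cnames.append(f"{an}:{bn}")
            blocks.append(np.column_stack(cols))
            names.extend(cnames)
        else:
            if term not in df.columns:
                raise SpecificationError(f"unknown predictor: {term}")
            X, n = _encode_main(df, term)
            encoded[term] = (X, n)
            blocks.append(X)
            names.extend(n)
    X = np.column_stack(blocks)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # name the aliased columns via QR pivoting
        _, R = np.linalg.qr(X)
        bad = [names[i] for i in range(X.shape[1]) if abs(R[i, i]) < 1e-10]
        raise SpecificationError(f"rank-deficient design; aliased: {bad}")
    return X, names


# ---------------------------------------------------------------------------
# likelihood machinery
# ---------------------------------------------------------------------------

def _binom_const(k: np.ndarray, n: np.ndarray) -> float:
    return float(np.sum(gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)))


def _binom_ll(eta: np.ndarray, k: np.ndarray, n: np.ndarray) -> float:
    eta = np.clip(eta, -_MAX_ETA, _MAX_ETA)
    # k*eta - n*log(1+e^eta), stable
    return float(np.sum(k * eta - n * np.logaddexp(0.0, eta)))


class _SingleGroupModel:
    """Laplace machinery for one random-intercept grouping (vectorised)."""

    def __init__(self, X: np.ndarray, k: np.ndarray, n: np.ndarray,
                 gidx: np.ndarray, n_groups: int):
        self.X, self.k, self.n = X, k, n
        self.gidx, self.n_groups = gidx, n_groups
        self.const = _binom_const(k, n)
        self.p = X.shape[1]
        self.n_vc = 1
        self._b = np.zeros(n_groups)  # warm start across evaluations
        self.k_by_g = np.bincount(gidx, weights=k, minlength=n_groups)

    def _solve_modes(self, eta0: np.ndarray, sigma2: float) -> np.ndarray:
        b = self._b.copy()
        gidx, k, n = self.gidx, self.k, self.n
        for _ in range(100):
            p = expit(np.clip(eta0 + b[gidx], -_MAX_ETA, _MAX_ETA))
            g = self.k_by_g - np.bincount(gidx, weights=n * p,
                                          minlength=self.n_groups) - b / sigma2
            W = np.bincount(gidx, weights=n * p * (1 - p),
                            minlength=self.n_groups) + 1.0 / sigma2
            step = np.clip(g / W, -8.0, 8.0)
            b += step
            if np.max(np.abs(step)) < 1e-10:
                break
        self._b = b
        return b

    def loglik(self, params: np.ndarray) -> float:
        beta, log_sigma = params[:-1], params[-1]
        sigma2 = math.exp(2.0 * log_sigma)
        eta0 = self.X @ beta
        b = self._solve_modes(eta0, sigma2)
        eta = eta0 + b[self.gidx]
        W = np.bincount(self.gidx, weights=self.n * expit(eta) * (1 - expit(eta)),
                        minlength=self.n_groups)
        return (_binom_ll(eta, self.k, self.n) + self.const
                - 0.5 * float(np.sum(b * b)) / sigma2
                - 0.5 * float(np.sum(np.log1p(sigma2 * W))))

    def loglik_agq(self, params: np.ndarray, n_nodes: int = 15) -> float:
        """Adaptive Gauss-Hermite marginal log-likelihood (verification)."""
        beta, log_sigma = params[:-1], params[-1]
        sigma = math.exp(log_sigma)
        sigma2 = sigma * sigma
        eta0 = self.X @ beta
        b = self._solve_modes(eta0, sigma2)
        p = expit(np.clip(eta0 + b[self.gidx], -_MAX_ETA, _MAX_ETA))
        W = np.bincount(self.gidx, weights=self.n * p * (1 - p),
                        minlength=self.n_groups) + 1.0 / sigma2
        scale = 1.0 / np.sqrt(W)  # mode curvature sets the node spread
        x, w = np.polynomial.hermite.hermgauss(n_nodes)
        total = 0.0
        for g in range(self.n_groups):
            rows = self.gidx == g
            kg, ng, e0 = self.k[rows], self.n[rows], eta0[rows]
            bv = b[g] + math.sqrt(2.0) * scale[g] * x          # (n_nodes,)
            eta = np.clip(e0[None, :] + bv[:, None], -_MAX_ETA, _MAX_ETA)
            ll = np.sum(kg * eta - ng * np.logaddexp(0.0, eta), axis=1)
            log_int = (np.log(w) + x * x + ll
                       - 0.5 * bv * bv / sigma2
                       - 0.5 * math.log(2 * math.pi * sigma2)
                       + math.log(math.sqrt(2.0) * scale[g]))
            total += special.logsumexp(log_int)
        return float(total + self.const)

    def ranef(self, params: np.ndarray) -> np.ndarray:
        beta, log_sigma = params[:-1], params[-1]
        return self._solve_modes(self.X @ beta, math.exp(2.0 * log_sigma))


class _NestedGroupModel:
    """Laplace machinery for inner-within-outer nested intercepts (dense)."""

    def __init__(self, X, k, n, outer_idx, inner_idx, n_outer, n_inner):
        self.X, self.k, self.n = X, k, n
        self.const = _binom_const(k, n)
        self.p = X.shape[1]
        self.n_vc = 2
        self.q = n_outer + n_inner
        self.n_outer, self.n_inner = n_outer, n_inner
        Z = np.zeros((len(k), self.q))
        Z[np.arange(len(k)), outer_idx] = 1.0
        Z[np.arange(len(k)), n_outer + inner_idx] = 1.0
        self.Z = Z
        self._u = np.zeros(self.q)

    def _dinv(self, params) -> np.ndarray:
        s2_out = math.exp(2.0 * params[-2])
        s2_in = math.exp(2.0 * params[-1])
        return np.concatenate([np.full(self.n_outer, 1.0 / s2_out),
                               np.full(self.n_inner, 1.0 / s2_in)])

    def _solve_modes(self, eta0: np.ndarray, dinv: np.ndarray) -> np.ndarray:
        u = self._u.copy()
        Z, k, n = self.Z, self.k, self.n
        for _ in range(100):
            eta = np.clip(eta0 + Z @ u, -_MAX_ETA, _MAX_ETA)
            p = expit(eta)
            g = Z.T @ (k - n * p) - dinv * u
            H = (Z.T * (n * p * (1 - p))) @ Z
            H[np.diag_indices_from(H)] += dinv
            step = np.linalg.solve(H, g)
            nrm = np.max(np.abs(step))
            if nrm > 8.0:
                step *= 8.0 / nrm
            u += step
            if nrm < 1e-10:
                break
        self._u = u
        return u

    def loglik(self, params: np.ndarray) -> float:
        beta = params[:-2]
        dinv = self._dinv(params)
        eta0 = self.X @ beta
        u = self._solve_modes(eta0, dinv)
        eta = np.clip(eta0 + self.Z @ u, -_MAX_ETA, _MAX_ETA)
        p = expit(eta)
        H = (self.Z.T * (self.n * p * (1 - p))) @ self.Z
        H[np.diag_indices_from(H)] += dinv
        sign, logdet_H = np.linalg.slogdet(H)
        logdet_D = -float(np.sum(np.log(dinv)))
        return (_binom_ll(eta, self.k, self.n) + self.const
                - 0.5 * float(np.sum(dinv * u * u))
                - 0.5 * (logdet_H + logdet_D))

    def ranef(self, params: np.ndarray) -> np.ndarray:
        return self._solve_modes(self.X @ params[:-2], self._dinv(params))


class _FixedOnlyModel:
    """Plain binomial GLM (degenerate case: all variances fixed at zero)."""

    def __init__(self, X, k, n):
        self.X, self.k, self.n = X, k, n
        self.const = _binom_const(k, n)
        self.p = X.shape[1]
        self.n_vc = 0

    def loglik(self, params: np.ndarray) -> float:
        return _binom_ll(self.X @ params, self.k, self.n) + self.const


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass
class GlmmFit:
    """A fitted binomial mixed model and its comparison statistics."""

    spec: GlmmSpec
    beta: pd.Series
    var_components: dict[str, float]
    loglik: float
    n_obs: int
    k_params: int
    aicc: float
    r2_marginal: float
    r2_conditional: float
    kappa: float
    converged: bool
    coef_names: list[str] = field(repr=False, default_factory=list)
    _model: object = field(repr=False, default=None)
    _params: np.ndarray = field(repr=False, default=None)
    _group_levels: dict = field(repr=False, default_factory=dict)

    def loglik_agq(self, n_nodes: int = 15) -> float:
        """Adaptive-quadrature marginal log-likelihood at the fitted params."""
        if not isinstance(self._model, _SingleGroupModel):
            raise SpecificationError("AGQ verification needs a single grouping")
        return self._model.loglik_agq(self._params, n_nodes)

    def wald_se(self) -> pd.Series:
        """Wald standard errors of beta from the numerical Hessian."""
        H = _numerical_hessian(lambda t: -self._model.loglik(t), self._params)
        p = len(self.beta)
        cov = np.linalg.inv(H)
        se = np.sqrt(np.clip(np.diag(cov)[:p], 0.0, None))
        return pd.Series(se, index=self.beta.index)

    def ranef(self) -> np.ndarray:
        return self._model.ranef(self._params)


def _numerical_hessian(f, x: np.ndarray, h: float = 1e-4) -> np.ndarray:
    d = len(x)
    H = np.zeros((d, d))
    f0 = f(x)
    steps = h * np.maximum(1.0, np.abs(x))
    for i in range(d):
        for j in range(i, d):
            ei = np.zeros(d); ei[i] = steps[i]
            ej = np.zeros(d); ej[j] = steps[j]
            val = (f(x + ei + ej) - f(x + ei - ej)
                   - f(x - ei + ej) + f(x - ei - ej)) / (4 * steps[i] * steps[j])
            H[i, j] = H[j, i] = val
    return H


def _irls_glm(X: np.ndarray, k: np.ndarray, n: np.ndarray,
              maxiter: int = 60) -> np.ndarray:
    """Binomial IRLS for starting values (and the no-random-effect fit)."""
    beta = np.zeros(X.shape[1])
    # initialise intercept at the pooled empirical logit
    ybar = (k.sum() + 0.5) / (n.sum() + 1.0)
    beta[0] = math.log(ybar / (1.0 - ybar))
    for _ in range(maxiter):
        eta = np.clip(X @ beta, -_MAX_ETA, _MAX_ETA)
        p = expit(eta)
        w = np.maximum(n * p * (1 - p), 1e-10)
        z = eta + (k - n * p) / w
        XtW = X.T * w
        new = np.linalg.solve(XtW @ X + 1e-10 * np.eye(X.shape[1]), XtW @ z)
        if np.max(np.abs(new - beta)) < 1e-10:
            beta = new
            break
        beta = new
    return beta


def _extract_response(data: pd.DataFrame, spec: GlmmSpec):
    k = data[spec.response].to_numpy(float)
    if spec.trials is not None:
        n = data[spec.trials].to_numpy(float)
    else:
        n = np.ones_like(k)
    if np.any(n < 1):
        raise SpecificationError("all rows need trials >= 1 "
                                 "(drop unclassified trips first)")
    if np.any((k < 0) | (k > n)):
        raise SpecificationError("successes must lie in [0, trials]")
    return k, n


def fit_glmm(data: pd.DataFrame, spec: GlmmSpec | str,
             x0: np.ndarray | None = None) -> GlmmFit:
    """Maximum-likelihood fit via the Laplace approximation.

    Categorical predictors are dummy-encoded against their first level.
    ``x0`` optionally warm-starts the optimiser (used by the permutation and
    bootstrap loops) as ``(beta, log sigma ...)``.
    """
    if isinstance(spec, str):
        spec = parse_formula(spec)
    data = data.reset_index(drop=True)
    k, n = _extract_response(data, spec)
    X, names = build_design(data, spec.fixed)

    group_levels: dict = {}
    if len(spec.random) == 0:
        model = _FixedOnlyModel(X, k, n)
        x_start = _irls_glm(X, k, n) if x0 is None else np.asarray(x0, float)
    elif len(spec.random) == 1:
        gcol = spec.random[0]
        codes, levels = pd.factorize(data[gcol], sort=True)
        if len(levels) < 2:
            raise SpecificationError(f"random term {gcol} needs >= 2 levels")
        group_levels[gcol] = list(levels)
        model = _SingleGroupModel(X, k, n, codes.astype(np.intp), len(levels))
        if x0 is None:
            x_start = np.append(_irls_glm(X, k, n), 0.0)
        else:
            x_start = np.asarray(x0, float)
    else:
        ocol, icol = spec.random
        ocodes, olev = pd.factorize(data[ocol], sort=True)
        inner_key = data[ocol].astype(str) + "/" + data[icol].astype(str)
        icodes, ilev = pd.factorize(inner_key, sort=True)
        if len(olev) < 2 or len(ilev) < 2:
            raise SpecificationError("nested random terms need >= 2 levels each")
        group_levels[ocol] = list(olev)
        group_levels[icol] = list(ilev)
        model = _NestedGroupModel(X, k, n, ocodes.astype(np.intp),
                                  icodes.astype(np.intp), len(olev), len(ilev))
        if x0 is None:
            x_start = np.concatenate([_irls_glm(X, k, n), [0.0, 0.0]])
        else:
            x_start = np.asarray(x0, float)

    if model.n_vc == 0:
        params = x_start
        ll = model.loglik(params)
        converged = True
    else:
        bounds = ([(None, None)] * model.p
                  + [(-7.0, 4.0)] * model.n_vc)
        res = optimize.minimize(lambda t: -model.loglik(t), x_start,
                                method="L-BFGS-B", bounds=bounds,
                                options={"maxiter": 400, "ftol": 1e-12,
                                         "gtol": 1e-7})
        params = res.x
        ll = -res.fun
        converged = bool(res.success)

    beta = pd.Series(params[:model.p], index=names)
    if model.n_vc == 0:
        var_components = {}
    elif model.n_vc == 1:
        var_components = {spec.random[0]: math.exp(2.0 * params[-1])}
    else:
        var_components = {spec.random[0]: math.exp(2.0 * params[-2]),
                          spec.random[1]: math.exp(2.0 * params[-1])}

    n_obs = len(data)
    k_params = model.p + model.n_vc
    sigma_f2 = float(np.var(X @ beta.to_numpy()))  # population variance
    sigma_r2 = float(sum(var_components.values()))
    denom = sigma_f2 + sigma_r2 + LATENT_LOGISTIC_VAR
    try:
        aicc_val = aicc(float(ll), k_params, n_obs)
    except ValueError:  # n <= k+1: AICc undefined for this fit
        aicc_val = float("nan")
    fit = GlmmFit(
        spec=spec, beta=beta, var_components=var_components,
        loglik=float(ll), n_obs=n_obs, k_params=k_params,
        aicc=aicc_val,
        r2_marginal=sigma_f2 / denom,
        r2_conditional=(sigma_f2 + sigma_r2) / denom,
        kappa=float(np.linalg.cond(X)),
        converged=converged, coef_names=names,
        _model=model, _params=params, _group_levels=group_levels,
    )
    return fit


# ---------------------------------------------------------------------------
# comparison toolkit
# ---------------------------------------------------------------------------

def aicc(loglik: float, k: int, n: int) -> float:
    """AICc = -2 loglik + 2k + 2k(k+1)/(n-k-1); k counts fixed coefficients
    plus variance components."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined: n={n} <= k+1={k + 1}")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def rank_models(fits: dict[str, GlmmFit] | list[GlmmFit]) -> pd.DataFrame:
    """AICc ranking table (ascending) with deltas against the best model."""
    if isinstance(fits, dict):
        items = list(fits.items())
    else:
        items = [(f.spec.formula, f) for f in fits]
    rows = [{"model": name, "df": f.k_params, "AICc": f.aicc,
             "R2m": f.r2_marginal, "R2c": f.r2_conditional,
             "converged": f.converged} for name, f in items]
    tab = pd.DataFrame(rows).sort_values(["AICc", "model"],
                                         kind="mergesort").reset_index(drop=True)
    tab.insert(3, "dAICc", tab["AICc"] - tab["AICc"].min())
    return tab


def r2_nakagawa(fit: GlmmFit) -> tuple[float, float]:
    """Latent-scale marginal and conditional R2 for logit-link fits."""
    return fit.r2_marginal, fit.r2_conditional


def standardize(data: pd.DataFrame, spec: GlmmSpec | str,
                ) -> tuple[pd.DataFrame, dict[str, tuple[float, float]]]:
    """Centre numeric predictors and divide by two standard deviations.

    Binary (two-valued) numeric predictors are centred only; categoricals
    are left to the dummy encoding against their reference level. Returns
    the transformed table and a ``column -> (center, scale)`` mapping for
    back-transforming coefficients (original = standardised / scale).
    """
    if isinstance(spec, str):
        spec = parse_formula(spec)
    out = data.copy()
    mapping: dict[str, tuple[float, float]] = {}
    cols = {t for term in spec.fixed for t in term.split(":")}
    for col in sorted(cols):
        s = out[col]
        if _is_categorical(s):
            continue
        vals = s.to_numpy(float)
        uniq = np.unique(vals)
        if len(uniq) < 2:
            raise SpecificationError(f"zero-variance predictor: {col}")
        center = float(vals.mean())
        if len(uniq) == 2:
            scale = 1.0
        else:
            sd = float(vals.std(ddof=1))
            if sd == 0.0:
                raise SpecificationError(f"zero-variance predictor: {col}")
            scale = 2.0 * sd
        out[col] = (vals - center) / scale
        mapping[col] = (center, scale)
    return out, mapping


def kappa_collinearity(fit: GlmmFit) -> float:
    """Exact 2-norm condition number of the fitted fixed-effects design."""
    return fit.kappa


def drop_term_lrt(fit: GlmmFit, data: pd.DataFrame) -> pd.DataFrame:
    """Single-term deletions against the full model.

    Main effects participating in a retained interaction are not dropped
    (marginality). For each droppable term the model is refit without it;
    chi2 = 2 (l_full - l_reduced) with df = number of coefficients removed.
    """
    spec = fit.spec
    in_interaction = {t for term in spec.fixed if ":" in term
                      for t in term.split(":")}
    rows = []
    for term in spec.fixed:
        if ":" not in term and term in in_interaction:
            continue
        reduced_terms = [t for t in spec.fixed if t != term]
        rspec = GlmmSpec(spec.response, spec.trials, reduced_terms, spec.random)
        rfit = fit_glmm(data, rspec)
        n_removed = len(fit.beta) - len(rfit.beta)
        chi2 = max(0.0, 2.0 * (fit.loglik - rfit.loglik))
        row = {"term": term, "df": n_removed, "chi2": chi2,
               "p": float(stats.chi2.sf(chi2, n_removed)),
               "converged": rfit.converged}
        if not rfit.converged:
            row["p"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)
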