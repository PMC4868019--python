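"""Individual repeatability of terrestrial-foraging propensity.

Adjusted repeatability on the latent (logit) scale:
r = sigma_a^2 / (sigma_a^2 + pi^2/3), the between-individual share of
latent variance once the model's fixed effects are accounted for. The
significance test permutes individual labels across trips and refits
(plus-one-corrected p), and the confidence interval is a percentile
parametric bootstrap: responses re-simulated from the fitted model at the
observed trial counts, refit, and the repeatability recomputed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .glmm import LATENT_LOGISTIC_VAR, GlmmFit, GlmmSpec, fit_glmm, parse_formula


@dataclass
class RepeatabilityResult:
    r: float
    p_randomization: float | None
    ci_low: float | None
    ci_high: float | None
    n_iterations: int

    def to_dict(self) -> dict:
        return {"r": self.r, "p_randomization": self.p_randomization,
                "ci_low": self.ci_low, "ci_high": self.ci_high,
                "n_iterations": self.n_iterations}


def repeatability_point(fit: GlmmFit) -> float:
    """Latent-scale adjusted repeatability from a single-grouping fit."""
    if len(fit.spec.random) != 1:
        raise ValueError("repeatability needs exactly one random intercept")
    s2 = fit.var_components[fit.spec.random[0]]
    return s2 / (s2 + LATENT_LOGISTIC_VAR)


def randomization_p(data: pd.DataFrame, spec: GlmmSpec | str,
                    n_iter: int = 1000, seed: int = 0,
                    observed_fit: GlmmFit | None = None) -> float:
    """Permutation p-value for r: shuffle individual labels across trips.

    p = (1 + #{r_perm >= r_obs}) / (n_ok + 1); iterations whose refit does
    not converge are dropped from both counts (warned above 5 %).
    """
    if isinstance(spec, str):
        spec = parse_formula(spec)
    fit = observed_fit if observed_fit is not None else fit_glmm(data, spec)
    r_obs = repeatability_point(fit)
    gcol = spec.random[0]
    rng = np.random.default_rng(seed)
    n_ge, n_ok, n_fail = 0, 0, 0
    labels = data[gcol].to_numpy()
    for _ in range(n_iter):
        shuffled = data.copy()
        shuffled[gcol] = rng.permutation(labels)
        pfit = fit_glmm(shuffled, spec)
        if not pfit.converged:
            n_fail += 1
            continue
        n_ok += 1
        if repeatability_point(pfit) >= r_obs - 1e-12:
            n_ge += 1
    if n_fail > 0.05 * n_iter:
        import warnings
        warnings.warn(f"{n_fail}/{n_iter} permutation refits failed to converge")
    return (1 + n_ge) / (n_ok + 1)


def bootstrap_ci(fit: GlmmFit, data: pd.DataFrame, n_iter: int = 1000,
                 seed: int = 0, level: float = 0.95) -> tuple[float, float]:
    """Percentile parametric-bootstrap CI for r.

    Each iteration draws fresh individual intercepts from N(0, sigma_a^2),
    simulates binomial responses at the observed trial counts under the
    fitted fixed effects, refits, and recomputes r.
    """
    spec = fit.spec
    if len(spec.random) != 1:
        raise ValueError("bootstrap_ci needs exactly one random intercept")
    gcol = spec.random[0]
    if data[gcol].nunique() < 2:
        raise ValueError("parametric bootstrap needs >= 2 individuals")
    rng = np.random.default_rng(seed)
    from .glmm import build_design
    data = data.reset_index(drop=True)
    X, _ = build_design(data, spec.fixed)
    eta_fixed = X @ fit.beta.to_numpy()
    sigma = float(np.sqrt(fit.var_components[gcol]))
    codes, levels = pd.factorize(data[gcol], sort=True)
    if spec.trials is not None:
        trials = data[spec.trials].to_numpy(int)
    else:
        trials = np.ones(len(data), dtype=int)
    rs = []
    for _ in range(n_iter):
        b = rng.normal(0.0, sigma, size=len(levels))
        p = expit(eta_fixed + b[codes])
        k = rng.binomial(trials, p)
        sim = data.copy()
        sim[spec.response] = k
        bfit = fit_glmm(sim, spec)
        if bfit.converged:
            rs.append(repeatability_point(bfit))
    if not rs:
        raise RuntimeError("no bootstrap refit converged")
    alpha = 1.0 - level
    lo, hi = np.quantile(rs, [alpha / 2.0, 1.0 - alpha / 2.0])
    return float(lo), float(hi)


def repeatability_analysis(data: pd.DataFrame, spec: GlmmSpec | str,
                           n_iter: int = 1000, seed: int = 0,
                           level: float = 0.95,
                           with_randomization: bool = True,
                           with_bootstrap: bool = True) -> RepeatabilityResult:
    """Point estimate plus (optionally) permutation p and bootstrap CI."""
    if isinstance(spec, str):
        spec = parse_formula(spec)
    fit = fit_glmm(data, spec)
    r = repeatability_point(fit)
    p = ci = None
    if with_randomization:
        p = randomization_p(data, spec, n_iter=n_iter, seed=seed,
                            observed_fit=fit)
    if with_bootstrap:
        ci = bootstrap_ci(fit, data, n_iter=n_iter, seed=seed + 1, level=level)
    return RepeatabilityResult(
        r=r, p_randomization=p,
        ci_low=None if ci is None else ci[0],
        ci_high=None if ci is None else ci[1],
        n_iterations=n_iter)
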