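"""Injury-risk models: random-intercept logistic regression and its harnesses.

The central model is a mixed-effects ("repeated measures") logistic regression

    logit P(injured_ij = 1) = beta0 + beta1 * x_ij + u_i,   u_i ~ N(0, sigma_u^2)

with one fixed effect at a time and a per-athlete random intercept absorbing
the within-athlete correlation induced by replicating the athlete-level
outcome across trials.  The marginal likelihood integrates u_i by adaptive
Gauss-Hermite quadrature (modes and curvatures found per athlete by Newton's
method).  Around it: likelihood-ratio tests against the intercept-only null,
Bonferroni adjustment, Nakagawa-Schielzeth marginal R^2, leave-one-out
refitting over injured athletes, and Monte-Carlo observed power.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy import optimize
from scipy.special import expit, logsumexp
from scipy.stats import chi2

_BETA_BOUND = 15.0
_SEPARATION_BOUND = 14.5
_LOG_SIGMA_BOUNDS = (-6.0, 3.5)


class NonIdentifiableError(ValueError):
    """The fixed-effect column has no variance (or no second athlete)."""


@dataclass
class GlmmFit:
    """A fitted single-predictor random-intercept logistic regression."""

    fixed: str | None
    beta0: float
    beta1: float | None
    sigma_u: float
    loglik: float
    se_beta1: float | None
    converged: bool
    separation: bool
    n_obs: int
    n_groups: int
    n_quad: int
    p_lrt: float | None = None
    p_adjusted: float | None = None
    r2_marginal: float | None = None

    @property
    def or_hat(self) -> float | None:
        return None if self.beta1 is None else float(np.exp(self.beta1))

    @property
    def ci95(self) -> tuple[float, float] | None:
        if self.beta1 is None or self.se_beta1 is None or not np.isfinite(self.se_beta1):
            return None
        lo = math.exp(self.beta1 - 1.959963984540054 * self.se_beta1)
        hi = math.exp(self.beta1 + 1.959963984540054 * self.se_beta1)
        return (lo, hi)


@dataclass
class PowerEstimate:
    power: float
    ci95: tuple[float, float]
    n_sims: int
    alpha: float
    p_values: np.ndarray | None = None


@dataclass
class LooResult:
    """Leave-one-injured-athlete-out refits of the single-predictor model."""

    entries: pd.DataFrame  # athlete_id, or_hat, p_lrt, converged
    or_range: tuple[float, float]
    p_range: tuple[float, float]

    @property
    def n_refits(self) -> int:
        return len(self.entries)


# ---------------------------------------------------------------------------
# marginal likelihood by adaptive Gauss-Hermite quadrature
# ---------------------------------------------------------------------------

@dataclass
class _Design:
    g: np.ndarray  # group code per (collapsed) row, sorted ascending
    x: np.ndarray | None
    y: np.ndarray
    w: np.ndarray  # row multiplicities
    starts: np.ndarray  # reduceat boundaries per group
    m: int  # number of groups
    n_obs: int
    group_ids: np.ndarray


def _build_design(table: pd.DataFrame, fixed: str | None, outcome: str, group: str) -> _Design:
    cols = [group, outcome] + ([fixed] if fixed else [])
    df = table[cols].copy()
    codes, group_ids = pd.factorize(df[group], sort=True)
    y = df[outcome].to_numpy(dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("outcome must be binary 0/1")
    x = df[fixed].to_numpy(dtype=float) if fixed else None
    if fixed is not None and np.ptp(x) == 0.0:
        raise NonIdentifiableError(f"fixed column {fixed!r} is constant")
    if len(np.unique(codes)) < 2:
        raise NonIdentifiableError("need at least 2 athletes")

    # collapse identical (group, x, y) rows to weighted rows; a big win for
    # binary predictors (<= 4 rows per athlete), harmless for continuous ones
    key = np.column_stack([codes, y] + ([x] if fixed else []))
    uniq, counts = np.unique(key, axis=0, return_counts=True)
    g = uniq[:, 0].astype(np.intp)
    yy = uniq[:, 1]
    xx = uniq[:, 2] if fixed else None
    starts = np.flatnonzero(np.r_[True, np.diff(g) > 0])
    return _Design(
        g=g, x=xx, y=yy, w=counts.astype(float), starts=starts,
        m=len(np.unique(g)), n_obs=len(df), group_ids=np.asarray(group_ids),
    )


def _eta0(d: _Design, beta0: float, beta1: float) -> np.ndarray:
    return beta0 + (beta1 * d.x if d.x is not None else np.zeros_like(d.y))


def _plain_loglik(d: _Design, beta0: float, beta1: float) -> float:
    eta = _eta0(d, beta0, beta1)
    return float(np.sum(d.w * (d.y * eta - np.logaddexp(0.0, eta))))


def _agq_loglik(
    d: _Design, beta0: float, beta1: float, sigma: float, nodes, weights,
    u_warm: np.ndarray | None = None,
) -> float:
    """Marginal log-likelihood with per-group adaptive quadrature."""
    eta0 = _eta0(d, beta0, beta1)
    s2 = sigma * sigma

    # Newton iterations (vectorised over groups) for the joint-density mode;
    # warm-starting from the previous outer evaluation cuts the iteration
    # count without changing the solution (the solve runs to tolerance)
    u = np.zeros(d.m) if u_warm is None else u_warm.copy()
    for _ in range(100):
        eta = eta0 + u[d.g]
        p = expit(eta)
        grad = np.bincount(d.g, weights=d.w * (d.y - p), minlength=d.m) - u / s2
        hess = -(np.bincount(d.g, weights=d.w * p * (1.0 - p), minlength=d.m) + 1.0 / s2)
        step = grad / hess
        u = u - np.clip(step, -4.0, 4.0)
        if np.max(np.abs(step)) < 1e-11:
            break
    eta = eta0 + u[d.g]
    p = expit(eta)
    hess = -(np.bincount(d.g, weights=d.w * p * (1.0 - p), minlength=d.m) + 1.0 / s2)
    tau = 1.0 / np.sqrt(-hess)

    U = u[:, None] + math.sqrt(2.0) * tau[:, None] * nodes[None, :]
    eta_nk = eta0[:, None] + U[d.g, :]
    ll_rows = d.w[:, None] * (d.y[:, None] * eta_nk - np.logaddexp(0.0, eta_nk))
    G = np.add.reduceat(ll_rows, d.starts, axis=0)
    H = G - 0.5 * math.log(2.0 * math.pi * s2) - U * U / (2.0 * s2)
    ll_i = np.log(math.sqrt(2.0) * tau) + logsumexp(
        H + nodes[None, :] ** 2 + np.log(weights)[None, :], axis=1
    )
    if u_warm is not None:
        u_warm[:] = u
    return float(ll_i.sum())


def fit_glmm_logistic(
    table: pd.DataFrame,
    fixed: str | None,
    *,
    outcome: str = "injured",
    group: str = "athlete_id",
    n_quad: int = 25,
    fix_sigma: float | None = None,
) -> GlmmFit:
    """Maximum-likelihood fit of the random-intercept logistic regression.

    ``fixed=None`` fits the intercept-only null model (random intercept kept).
    ``fix_sigma=0.0`` constrains the random-intercept SD to zero, reducing the
    model to ordinary logistic regression (used for validation).
    """
    d = _build_design(table, fixed, outcome, group)
    nodes, weights = hermgauss(n_quad)
    has_slope = fixed is not None
    free_sigma = fix_sigma is None

    ybar = float(np.clip(np.average(d.y, weights=d.w), 1e-4, 1 - 1e-4))
    l0 = math.log(ybar / (1 - ybar))
    beta_bounds = [(-30.0, 30.0)] + ([(-_BETA_BOUND, _BETA_BOUND)] if has_slope else [])
    beta_start = [l0] + ([0.0] if has_slope else [])
    bounds = beta_bounds + ([_LOG_SIGMA_BOUNDS] if free_sigma else [])

    def unpack(theta):
        b0 = theta[0]
        b1 = theta[1] if has_slope else 0.0
        if free_sigma:
            sigma = math.exp(theta[-1])
        else:
            sigma = fix_sigma
        return b0, b1, sigma

    u_warm = np.zeros(d.m)

    def nll(theta):
        b0, b1, sigma = unpack(theta)
        if sigma is not None and sigma > 1e-4:
            return -_agq_loglik(d, b0, b1, sigma, nodes, weights, u_warm=u_warm)
        return -_plain_loglik(d, b0, b1)

    # the marginal likelihood can be multimodal in sigma at strong effects
    # (a conditional-effect basin vs a large-sigma mixture basin), so the
    # betas are first profiled on a coarse log-sigma grid and the joint
    # optimisation started from the best grid point
    if free_sigma:
        best = None
        for ls in (-1.0, 0.0, 1.0, 2.0, 3.0, _LOG_SIGMA_BOUNDS[1]):
            prof = optimize.minimize(
                lambda th: nll(np.r_[th, ls]),
                np.array(beta_start),
                method="L-BFGS-B",
                bounds=beta_bounds,
                options={"maxiter": 60, "ftol": 1e-6},  # initialiser only
            )
            if best is None or prof.fun < best[0]:
                best = (prof.fun, np.r_[prof.x, ls])
        theta0 = best[1]
    else:
        theta0 = np.array(beta_start)

    res = optimize.minimize(
        nll, theta0, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": 500, "ftol": 1e-11, "gtol": 1e-8},
    )
    if not res.success:
        # rare line-search failures: polish with a derivative-free pass
        res2 = optimize.minimize(
            nll, res.x, method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 4000},
        )
        if res2.fun <= res.fun:
            res2.x = np.clip(res2.x, [b[0] for b in bounds], [b[1] for b in bounds])
            res = res2
    b0, b1, sigma = unpack(res.x)
    loglik = -float(res.fun)
    separation = has_slope and abs(b1) >= _SEPARATION_BOUND
    if separation:
        import warnings

        warnings.warn(
            f"possible separation in fixed effect {fixed!r}: |beta1| at cap", stacklevel=2
        )

    se_b1 = None
    if has_slope:
        se_b1 = _wald_se(nll, res.x, index=1)

    return GlmmFit(
        fixed=fixed,
        beta0=float(b0),
        beta1=float(b1) if has_slope else None,
        sigma_u=float(sigma if sigma is not None else 0.0),
        loglik=loglik,
        se_beta1=se_b1,
        converged=bool(res.success),
        separation=separation,
        n_obs=d.n_obs,
        n_groups=d.m,
        n_quad=n_quad,
    )


# separation is reported as a warning flag with a capped estimate; the fit
# itself still counts as converged for downstream likelihood-ratio tests


def _wald_se(nll, theta_hat: np.ndarray, index: int) -> float | None:
    """SE from the observed information (central-difference Hessian)."""
    k = len(theta_hat)
    h = 1e-4 * np.maximum(1.0, np.abs(theta_hat))
    hess = np.zeros((k, k))
    f0 = nll(theta_hat)
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = h[i]
            ej = np.zeros(k); ej[j] = h[j]
            if i == j:
                f1 = nll(theta_hat + ei)
                f2 = nll(theta_hat - ei)
                hess[i, i] = (f1 - 2.0 * f0 + f2) / (h[i] ** 2)
            else:
                fpp = nll(theta_hat + ei + ej)
                fpm = nll(theta_hat + ei - ej)
                fmp = nll(theta_hat - ei + ej)
                fmm = nll(theta_hat - ei - ej)
                hess[i, j] = hess[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * h[i] * h[j])
    try:
        cov = np.linalg.inv(hess)
        var = cov[index, index]
        if var <= 0:
            cov = np.linalg.pinv(hess)
            var = cov[index, index]
        return float(np.sqrt(var)) if var > 0 else None
    except np.linalg.LinAlgError:
        return None


# ---------------------------------------------------------------------------
# inference helpers
# ---------------------------------------------------------------------------

def lrt_pvalue(full: GlmmFit, null: GlmmFit) -> float:
    """Likelihood-ratio test of the fixed effect: chi-square with 1 df."""
    if not (full.converged and null.converged):
        raise ValueError("both fits must have converged for a likelihood-ratio test")
    dev = 2.0 * (full.loglik - null.loglik)
    if dev < 0.0:
        dev = 0.0
    return float(chi2.sf(dev, df=1))


def bonferroni(p: float, family_size: int = 3) -> float:
    """Bonferroni adjustment: multiply by family size, cap at 1."""
    if not (0.0 <= p <= 1.0):
        raise ValueError("p must lie in [0, 1]")
    if family_size < 1:
        raise ValueError("family_size must be >= 1")
    return min(1.0, family_size * p)


def marginal_r2(fit: GlmmFit, x: np.ndarray) -> float:
    """Nakagawa-Schielzeth marginal R^2 for a logit-link mixed model.

    var(beta1 * x) / (var(beta1 * x) + sigma_u^2 + pi^2 / 3); the last term is
    the variance of the standard-logistic residual distribution.
    """
    if fit.beta1 is None:
        return 0.0
    vf = float(np.var(fit.beta1 * np.asarray(x, dtype=float)))
    return vf / (vf + fit.sigma_u**2 + math.pi**2 / 3.0)


def loo_cross_validation(
    table: pd.DataFrame,
    fixed: str,
    *,
    outcome: str = "injured",
    group: str = "athlete_id",
    n_quad: int = 25,
) -> LooResult:
    """One refit per injured athlete with all of that athlete's trials removed."""
    injured_ids = sorted(table.loc[table[outcome] == 1, group].unique())
    if len(injured_ids) < 2:
        raise ValueError("need at least 2 injured athletes for leave-one-out")
    rows = []
    for aid in injured_ids:
        sub = table[table[group] != aid]
        try:
            full = fit_glmm_logistic(sub, fixed, outcome=outcome, group=group, n_quad=n_quad)
            null = fit_glmm_logistic(sub, None, outcome=outcome, group=group, n_quad=n_quad)
            p = lrt_pvalue(full, null)
            rows.append({"athlete_id": aid, "or_hat": full.or_hat, "p_lrt": p,
                         "converged": full.converged})
        except (ValueError, NonIdentifiableError):
            rows.append({"athlete_id": aid, "or_hat": np.nan, "p_lrt": np.nan,
                         "converged": False})
    entries = pd.DataFrame(rows)
    ok = entries[entries["converged"]]
    if ok.empty:
        or_range = p_range = (float("nan"), float("nan"))
    else:
        or_range = (float(ok["or_hat"].min()), float(ok["or_hat"].max()))
        p_range = (float(ok["p_lrt"].min()), float(ok["p_lrt"].max()))
    return LooResult(entries=entries, or_range=or_range, p_range=p_range)


# ---------------------------------------------------------------------------
# Monte-Carlo observed power
# ---------------------------------------------------------------------------

def observed_power(
    model,
    n_sims: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
    *,
    table: pd.DataFrame | None = None,
    fixed: str = "true_early_peak",
    outcome: str = "injured",
    group: str = "athlete_id",
    n_quad: int = 25,
) -> PowerEstimate:
    """Monte-Carlo observed power of the likelihood-ratio test.

    Two generating models are supported:

    * a ``GeneratorConfig``: each replicate draws a fresh feature-level cohort
      from the generator and tests the ``fixed`` truth column against injury;
    * a ``GlmmFit`` plus the ``table`` it was fitted to: each replicate keeps
      the design fixed and simulates trial-level outcomes from the fitted
      model (new random intercepts and Bernoulli draws), the approach used by
      simulation-based power packages for mixed models.

    The 95% CI is the normal approximation p +/- 1.96 * sqrt(p(1-p)/n_sims).
    """
    from kamrisk.config import GeneratorConfig
    from kamrisk.synthetic import sample_cohort_features

    if n_sims < 100:
        import warnings

        warnings.warn("n_sims < 100: the power CI is unreliable", stacklevel=2)
    ss = np.random.SeedSequence(seed)
    pvals = np.empty(n_sims)

    if isinstance(model, GeneratorConfig):
        child_seeds = ss.generate_state(n_sims) % (2**31 - 1)
        for i in range(n_sims):
            cfg = copy.deepcopy(model)
            cfg.seed = int(child_seeds[i])
            trials, _ = sample_cohort_features(cfg)
            tab = trials[["athlete_id", fixed, "leg_injured"]].copy()
            tab[outcome] = tab["leg_injured"].astype(int)
            pvals[i] = _lrt_p_once(tab, fixed, outcome, group, n_quad)
    elif isinstance(model, GlmmFit):
        if table is None:
            raise ValueError("a fitted-model power run needs the design table")
        rng = np.random.default_rng(ss)
        x = table[model.fixed].to_numpy(dtype=float)
        codes, _ = pd.factorize(table[group], sort=True)
        eta_fix = model.beta0 + model.beta1 * x
        m = codes.max() + 1
        tab = table[[group, model.fixed]].copy()
        for i in range(n_sims):
            u = rng.normal(0.0, model.sigma_u, m)
            y = (rng.random(len(x)) < expit(eta_fix + u[codes])).astype(int)
            tab[outcome] = y
            if y.min() == y.max():  # degenerate replicate: never significant
                pvals[i] = 1.0
                continue
            pvals[i] = _lrt_p_once(tab, model.fixed, outcome, group, n_quad)
    else:
        raise TypeError("model must be a GeneratorConfig or a GlmmFit")

    power = float(np.mean(pvals < alpha))
    half = 1.959963984540054 * math.sqrt(max(power * (1.0 - power), 1e-12) / n_sims)
    ci = (max(0.0, power - half), min(1.0, power + half))
    return PowerEstimate(power=power, ci95=ci, n_sims=n_sims, alpha=alpha, p_values=pvals)


def _lrt_p_once(tab, fixed, outcome, group, n_quad) -> float:
    try:
        full = fit_glmm_logistic(tab, fixed, outcome=outcome, group=group, n_quad=n_quad)
        null = fit_glmm_logistic(tab, None, outcome=outcome, group=group, n_quad=n_quad)
        return lrt_pvalue(full, null)
    except (ValueError, NonIdentifiableError):
        return 1.0


# ---------------------------------------------------------------------------
# single-predictor regressions for every discrete feature
# ---------------------------------------------------------------------------

#: report rows and Bonferroni families: kinematics (angles + trunk-foot
#: offset) and kinetics (discrete moments + vGRF), three variables each
FEATURE_FAMILIES = {
    "knee_abd_angle_ic": "kinematics",
    "knee_flex_angle_ic": "kinematics",
    "trunk_foot_ml_ic": "kinematics",
    "vgrf_max_100ms": "kinetics",
    "early_kam_max": "kinetics",
    "highest_kam_stance": "kinetics",
}


def build_feature_regressions(
    table: pd.DataFrame,
    *,
    outcome: str = "injured",
    group: str = "athlete_id",
    n_quad: int = 25,
    family_size: int = 3,
    variables: dict[str, str] | None = None,
) -> pd.DataFrame:
    """One single-fixed-effect mixed logistic regression per discrete variable.

    Returns a report with OR (per unit change), Wald 95% CI, raw and
    Bonferroni-adjusted LRT p-values and marginal R^2 for each variable.
    """
    fams = variables or FEATURE_FAMILIES
    null = fit_glmm_logistic(table, None, outcome=outcome, group=group, n_quad=n_quad)
    rows = []
    for var, family in fams.items():
        fit = fit_glmm_logistic(table, var, outcome=outcome, group=group, n_quad=n_quad)
        p = lrt_pvalue(fit, null)
        ci = fit.ci95 or (np.nan, np.nan)
        rows.append(
            {
                "variable": var,
                "family": family,
                "or_hat": fit.or_hat,
                "ci_lower": ci[0],
                "ci_upper": ci[1],
                "p_lrt": p,
                "p_adjusted": bonferroni(p, family_size),
                "r2_marginal": marginal_r2(fit, table[var].to_numpy()),
                "sigma_u": fit.sigma_u,
                "converged": fit.converged,
            }
        )
    return pd.DataFrame(rows)
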