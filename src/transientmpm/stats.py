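"""Comparative hierarchical models.

Three model families over the per-population summaries:

* contribution models — logit-transformed proportion responses (r2_asym,
  r2_trans, prop_abs_trans) regressed on growth form (one intercept per
  form, no reference level) and matrix dimension, with a species random
  intercept and Gaussian residual;
* boom test — intercept-only model with species random effect on mean log
  reactivity (the null expectation is an intercept of zero: populations
  equally likely to boom as to bust);
* association test — mixed regression of a growth response on mean log
  reactivity with a species random effect, plus a likelihood-ratio test
  against the no-slope null.

A fixed effect is called *important* exactly when its 95% interval excludes
zero.  Two interchangeable backends honour that interval contract: a
maximum-likelihood linear mixed model (Wald intervals; fast, default) and a
conjugate Gibbs sampler with diffuse priors (zero-mean normal with variance
1e10 on fixed effects, inverse-gamma with unit scale and a 0.001 degree
parameter on variance components) run with long chains, a fractional
burn-in and heavy thinning.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import ValidationError

LOGIT_EPS = 1e-6

PROPORTION_RESPONSES = ("r2_asym", "r2_trans", "prop_abs_trans")


@dataclass(frozen=True)
class McmcConfig:
    """Inference settings.

    Defaults follow the long-chain MCMC protocol (500000 iterations, 10%
    burn-in, thinning 250 -> ~1800 retained draws).  ``backend`` selects
    ``"mixedlm"`` (ML mixed model with Wald intervals) or ``"gibbs"``.
    """

    iterations: int = 500_000
    burn_in_fraction: float = 0.10
    thinning: int = 250
    fixed_effect_variance: float = 1e10
    vc_scale: float = 1.0
    vc_nu: float = 0.001
    seed: int = 0
    backend: str = "mixedlm"

    def __post_init__(self):
        if not 0 <= self.burn_in_fraction < 1:
            raise ValidationError("burn_in_fraction must be in [0, 1)")
        if self.thinning < 1 or self.iterations < 1:
            raise ValidationError("iterations and thinning must be >= 1")
        if self.backend not in ("mixedlm", "gibbs"):
            raise ValidationError(f"unknown backend {self.backend!r}")


@dataclass
class FitResult:
    """Point estimates, 95% intervals and diagnostics for one fitted model.

    ``params`` has one row per parameter with columns ``mean``, ``lower95``,
    ``upper95`` and ``important`` (interval excludes zero).  ``pmcmc`` is the
    two-sided posterior tail probability of the focal parameter (for the ML
    backend, the analogous two-sided Wald probability).
    """

    params: pd.DataFrame
    variance_components: dict = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)
    pmcmc: float | None = None
    lrt_stat: float | None = None
    lrt_p: float | None = None

    def to_csv(self, path) -> None:
        out = self.params.copy()
        out.index.name = "parameter"
        out.to_csv(path)


def logit_transform(p, eps: float = LOGIT_EPS):
    """logit with clamping: log(p'/(1-p')), p' = clip(p, eps, 1-eps).

    Accepts scalars or arrays; raises on values outside [0, 1].
    """
    arr = np.asarray(p, dtype=float)
    if np.any((arr < 0) | (arr > 1)) or not np.all(np.isfinite(arr)):
        raise ValidationError("proportions must lie in [0, 1]")
    clipped = np.clip(arr, eps, 1.0 - eps)
    out = np.log(clipped / (1.0 - clipped))
    return float(out) if np.isscalar(p) or arr.ndim == 0 else out


def _require_columns(summaries: pd.DataFrame, cols) -> None:
    missing = [c for c in cols if c not in summaries.columns]
    if missing:
        raise ValidationError(f"summaries are missing column(s) {missing}")


def _contribution_design(summaries: pd.DataFrame):
    """Design for the contribution models.

    The model is fitted with ordinary treatment coding (global intercept,
    form contrasts, dimension slope) for numerical stability, but reported
    as one intercept per growth form plus the shared dimension slope.  The
    returned matrix ``L`` maps fitted coefficients to reported parameters.
    Drops the form effects (with a warning) if only one form is present.
    """
    forms = sorted(summaries["growth_form"].unique())
    dim = summaries["matrix_dimension"].to_numpy(dtype=float)
    n = len(summaries)
    if len(forms) == 1:
        warnings.warn(
            f"single growth form {forms[0]!r}: dropping growth-form effects",
            stacklevel=3,
        )
        X = np.column_stack([np.ones(n), dim])
        return X, np.eye(2), ["intercept", "matrix_dimension"]
    k = len(forms)
    contrasts = np.column_stack(
        [(summaries["growth_form"] == f).to_numpy(dtype=float) for f in forms[1:]]
    )
    X = np.column_stack([np.ones(n), contrasts, dim])
    # reported parameter j (form intercept) = beta0 (+ beta_j); slope last
    L = np.zeros((k + 1, k + 1))
    L[:k, 0] = 1.0
    for j in range(1, k):
        L[j, j] = 1.0
    L[k, k] = 1.0
    names = [f"form:{f}" for f in forms] + ["matrix_dimension"]
    return X, L, names


def _interval_frame(names, means, lowers, uppers) -> pd.DataFrame:
    frame = pd.DataFrame(
        {"mean": means, "lower95": lowers, "upper95": uppers},
        index=pd.Index(names, name="parameter"),
    )
    frame["important"] = (frame["lower95"] > 0) | (frame["upper95"] < 0)
    return frame


def _degenerate_fit(y: np.ndarray, names) -> FitResult:
    """Exact fit for a response with (numerically) zero variance."""
    mu = float(y.mean())
    # slope-type rows get exactly 0; intercept rows the common value
    means = [0.0 if n in ("matrix_dimension", "slope") else mu for n in names]
    frame = _interval_frame(names, means, means, means)
    return FitResult(
        params=frame,
        variance_components={"species": 0.0, "residual": 0.0},
        diagnostics={"backend": "degenerate", "converged": True},
        pmcmc=1.0,
    )


def _mixedlm_solve(model, reml: bool):
    """Fit a MixedLM, falling back through optimizers on numerical failure."""
    last = None
    for method in (None, "powell", "nm"):
        try:
            kwargs = {} if method is None else {"method": method}
            return model.fit(reml=reml, **kwargs)
        except (np.linalg.LinAlgError, ValueError) as exc:
            last = exc
    raise last


def _fit_mixedlm(y, X, L, names, groups, focal: str):
    import statsmodels.api as sm

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        model = sm.MixedLM(y, X, groups=np.asarray(groups))
        res = _mixedlm_solve(model, reml=True)
    p = X.shape[1]
    beta = np.asarray(res.fe_params)[:p]
    cov_fe = np.asarray(res.cov_params())[:p, :p]
    means = L @ beta
    ses = np.sqrt(np.clip(np.diag(L @ cov_fe @ L.T), 0.0, None))
    z = sps.norm.ppf(0.975)
    frame = _interval_frame(names, means, means - z * ses, means + z * ses)
    i = names.index(focal)
    zstat = means[i] / ses[i] if ses[i] > 0 else np.inf
    pm = float(2.0 * sps.norm.sf(abs(zstat)))
    converged = bool(getattr(res, "converged", True))
    return FitResult(
        params=frame,
        variance_components={
            "species": float(np.asarray(res.cov_re)[0, 0]),
            "residual": float(res.scale),
        },
        diagnostics={
            "backend": "mixedlm",
            "converged": converged,
            "n_obs": int(len(y)),
            "warnings": sorted({str(w.message) for w in caught})[:5],
        },
        pmcmc=pm,
    ), res


def _ess(x: np.ndarray) -> float:
    """Effective sample size from the initial-positive autocorrelation sum."""
    n = x.size
    if n < 4 or x.std() == 0:
        return float(n)
    xc = x - x.mean()
    acf = np.correlate(xc, xc, mode="full")[n - 1 :] / (xc @ xc)
    total = 0.0
    for k in range(1, n // 2):
        if acf[k] <= 0:
            break
        total += acf[k]
    return float(n / (1.0 + 2.0 * total))


def _fit_gibbs(y, X, L, names, groups, focal: str, cfg: McmcConfig):
    """Conjugate Gibbs sampler for y = X b + Z u + e with one random
    intercept; diffuse normal prior on b, inverse-gamma on both variances."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x91BB5]))
    n, p = X.shape
    labels, z_idx = np.unique(np.asarray(groups), return_inverse=True)
    q = labels.size
    nu, V = cfg.vc_nu, cfg.vc_scale
    a0, b0 = nu / 2.0, nu * V / 2.0
    prior_prec = 1.0 / cfg.fixed_effect_variance

    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    sig_e = max(float(resid.var()), 1e-8)
    sig_u = max(sig_e / 2.0, 1e-8)
    u = np.zeros(q)
    counts = np.bincount(z_idx, minlength=q).astype(float)

    n_burn = int(cfg.iterations * cfg.burn_in_fraction)
    keep_iters = range(n_burn, cfg.iterations, cfg.thinning)
    n_keep = len(keep_iters)
    draws_beta = np.empty((n_keep, p))
    draws_su = np.empty(n_keep)
    draws_se = np.empty(n_keep)
    keep_set = iter(keep_iters)
    next_keep = next(keep_set, None)
    XtX = X.T @ X

    k = 0
    for it in range(cfg.iterations):
        # fixed effects | u, sig_e
        prec = XtX / sig_e + prior_prec * np.eye(p)
        cov = np.linalg.inv(prec)
        mean = cov @ (X.T @ (y - u[z_idx])) / sig_e
        beta = rng.multivariate_normal(mean, cov, method="cholesky")
        # random intercepts | beta, variances
        r = y - X @ beta
        sums = np.bincount(z_idx, weights=r, minlength=q)
        post_prec = counts / sig_e + 1.0 / sig_u
        u = sums / sig_e / post_prec + rng.standard_normal(q) / np.sqrt(post_prec)
        # variance components
        sig_u = 1.0 / rng.gamma(a0 + q / 2.0, 1.0 / (b0 + 0.5 * (u @ u)))
        e = r - u[z_idx]
        sig_e = 1.0 / rng.gamma(a0 + n / 2.0, 1.0 / (b0 + 0.5 * (e @ e)))
        if it == next_keep:
            draws_beta[k] = beta
            draws_su[k] = sig_u
            draws_se[k] = sig_e
            k += 1
            next_keep = next(keep_set, None)

    report = draws_beta @ L.T
    means = report.mean(axis=0)
    lowers = np.percentile(report, 2.5, axis=0)
    uppers = np.percentile(report, 97.5, axis=0)
    frame = _interval_frame(names, means, lowers, uppers)
    i = names.index(focal)
    chain = report[:, i]
    tail = min((chain > 0).mean(), (chain < 0).mean())
    pm = float(min(1.0, 2.0 * max(tail, 1.0 / chain.size)))
    lag1 = float(np.corrcoef(chain[:-1], chain[1:])[0, 1]) if chain.size > 2 else 0.0
    return FitResult(
        params=frame,
        variance_components={
            "species": float(draws_su.mean()),
            "residual": float(draws_se.mean()),
        },
        diagnostics={
            "backend": "gibbs",
            "n_obs": int(n),
            "n_draws": int(n_keep),
            "ess": {nm: _ess(report[:, j]) for j, nm in enumerate(names)},
            "max_lag1_autocorr": abs(lag1),
            "converged": abs(lag1) < 0.1,
        },
        pmcmc=pm,
    )


def _fit(y, X, names, groups, focal, cfg: McmcConfig, L=None):
    if L is None:
        L = np.eye(X.shape[1])
    if float(np.std(y)) < 1e-12:
        return _degenerate_fit(np.asarray(y), names)
    if cfg.backend == "gibbs":
        return _fit_gibbs(y, X, L, names, groups, focal, cfg)
    fit, _ = _fit_mixedlm(y, X, L, names, groups, focal)
    return fit


def fit_contribution_model(
    summaries: pd.DataFrame,
    response: str,
    cfg: McmcConfig | None = None,
) -> FitResult:
    """Hierarchical regression of a logit proportion on growth form and
    matrix dimension with a species random intercept.

    ``response`` is one of ``r2_asym``, ``r2_trans``, ``prop_abs_trans``.
    """
    if response not in PROPORTION_RESPONSES:
        raise ValidationError(
            f"response must be one of {PROPORTION_RESPONSES}, got {response!r}"
        )
    cfg = cfg or McmcConfig()
    _require_columns(
        summaries, [response, "growth_form", "matrix_dimension", "species_id"]
    )
    if summaries["species_id"].nunique() < 2:
        raise ValidationError("need at least 2 species")
    if summaries["matrix_dimension"].nunique() < 2:
        raise ValidationError("need at least 2 distinct matrix dimensions")
    y = logit_transform(summaries[response].to_numpy())
    X, L, names = _contribution_design(summaries)
    return _fit(y, X, names, summaries["species_id"], "matrix_dimension", cfg, L=L)


def boom_test(
    summaries: pd.DataFrame,
    response: str = "mean_log_reactivity",
    cfg: McmcConfig | None = None,
) -> FitResult:
    """Intercept-only model with species random effect on a growth response.

    The returned ``pmcmc`` is the two-sided posterior tail probability that
    the intercept's sign differs from its posterior mean's sign (ML backend:
    the analogous two-sided Wald probability).
    """
    cfg = cfg or McmcConfig()
    _require_columns(summaries, [response, "species_id"])
    if summaries["species_id"].nunique() < 2:
        raise ValidationError("need at least 2 species")
    y = summaries[response].to_numpy(dtype=float)
    X = np.ones((len(y), 1))
    return _fit(y, X, ["intercept"], summaries["species_id"], "intercept", cfg)


def association_test(
    summaries: pd.DataFrame,
    predictor: str = "mean_log_reactivity",
    response: str = "mean_log_lambda_obs",
    cfg: McmcConfig | None = None,
) -> FitResult:
    """Mixed regression of ``response`` on ``predictor`` with a species
    random intercept, plus a likelihood-ratio test against the no-slope null.

    The LRT refits both models by maximum likelihood regardless of backend;
    its statistic is 2 * (llf_full - llf_null), chi-squared with 1 df.
    """
    import statsmodels.api as sm

    cfg = cfg or McmcConfig()
    _require_columns(summaries, [predictor, response, "species_id"])
    if len(summaries) < 3:
        raise ValidationError("need at least 3 populations")
    y = summaries[response].to_numpy(dtype=float)
    x = summaries[predictor].to_numpy(dtype=float)
    groups = summaries["species_id"].to_numpy()
    X = np.column_stack([np.ones_like(x), x])
    names = ["intercept", "slope"]
    fit = _fit(y, X, names, groups, "slope", cfg)

    if float(np.std(y)) >= 1e-12 and float(np.std(x)) >= 1e-12:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            full = _mixedlm_solve(sm.MixedLM(y, X, groups=groups), reml=False)
            null = _mixedlm_solve(sm.MixedLM(y, X[:, :1], groups=groups), reml=False)
        stat = max(0.0, 2.0 * (full.llf - null.llf))
        fit.lrt_stat = float(stat)
        fit.lrt_p = float(sps.chi2.sf(stat, df=1))
    return fit
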