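"""Poisson and negative-binomial (NB2) regression of distal-site counts.

Models the number of binding sites in a gene's distal promoter region as
a log-link function of the plus-strand site count, the motif similarity
covariate, and optionally the receptor group with a (plus-count x group)
interaction. The NB2 family parameterizes the variance as mu + mu^2/theta,
so theta is the dispersion ("size") parameter reported by the study:
smaller theta means more overdispersion, and theta -> infinity recovers
the Poisson model. Companion diagnostics: the residual-deviance
overdispersion test, exponentiated effect tables (rate ratios and percent
changes with Wald intervals), AIC/BIC, the Vuong non-nested comparison,
and delta-method prediction intervals on the mean scale.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.special import gammaln


@dataclass
class ModelSpec:
    response: str = "distal_count"
    predictors: list[str] = field(default_factory=lambda: ["plus_count",
                                                           "similarity"])
    family: str = "negbin"  # "poisson" | "negbin"
    interaction: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.family not in ("poisson", "negbin"):
            raise ValueError("family must be 'poisson' or 'negbin'")


@dataclass
class GLMFit:
    spec: ModelSpec
    names: list[str]
    beta: np.ndarray
    covariance: np.ndarray
    loglik: float
    null_deviance: float
    residual_deviance: float
    df_residual: int
    aic: float
    bic: float
    theta: float | None
    converged: bool
    n_iter: int
    n_obs: int
    loglik_obs: np.ndarray
    X: np.ndarray
    y: np.ndarray

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.covariance))

    @property
    def fitted(self) -> np.ndarray:
        return np.exp(self.X @ self.beta)

    def wald_pvalues(self) -> np.ndarray:
        z = self.beta / self.se
        return 2 * stats.norm.sf(np.abs(z))

    def conf_int(self, level: float = 0.95) -> np.ndarray:
        z = stats.norm.ppf(0.5 + level / 2)
        return np.column_stack([self.beta - z * self.se, self.beta + z * self.se])


@dataclass
class OverdispersionResult:
    ratio: float
    statistic: float
    df: int
    p_value: float
    overdispersed: bool  # verdict at alpha = 0.05


@dataclass
class VuongResult:
    statistic: float
    p_value: float
    preferred: str


def _design(data: pd.DataFrame, spec: ModelSpec,
            check_rank: bool = True) -> tuple[np.ndarray, np.ndarray,
                                              list[str]]:
    y = data[spec.response].to_numpy()
    if not np.allclose(y, np.round(y)) or (y < 0).any():
        raise ValueError("response must be non-negative integer counts")
    y = np.round(y).astype(float)
    cols, names = [np.ones(len(data))], ["(Intercept)"]
    for p in spec.predictors:
        v = data[p]
        if v.dtype == object or str(v.dtype) == "category":
            levels = sorted(v.unique())
            if len(levels) < 2:
                raise ValueError(f"predictor {p!r} has a single level")
            for lev in levels[1:]:
                cols.append((v == lev).to_numpy(float))
                names.append(f"{p}[{lev}]")
        else:
            cols.append(v.to_numpy(float))
            names.append(p)
    for a, b in spec.interaction:
        va = data[a].to_numpy(float)
        vb = data[b]
        if vb.dtype == object or str(vb.dtype) == "category":
            levels = sorted(vb.unique())
            if len(levels) < 2:
                raise ValueError(f"interaction factor {b!r} has a single level")
            for lev in levels[1:]:
                cols.append(va * (vb == lev).to_numpy(float))
                names.append(f"{a}:{b}[{lev}]")
        else:
            cols.append(va * vb.to_numpy(float))
            names.append(f"{a}:{b}")
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X) if check_rank else X.shape[1]
    if rank < X.shape[1]:
        raise ValueError(
            f"rank-deficient design ({rank} < {X.shape[1]}); "
            f"check collinearity among {names}"
        )
    return X, y, names


def _poisson_loglik_obs(y: np.ndarray, mu: np.ndarray) -> np.ndarray:
    return y * np.log(mu) - mu - gammaln(y + 1)


def _nb2_loglik_obs(y: np.ndarray, mu: np.ndarray, theta: float) -> np.ndarray:
    return (gammaln(y + theta) - gammaln(theta) - gammaln(y + 1)
            + theta * np.log(theta / (theta + mu))
            + y * np.log(mu / (theta + mu)))


def _poisson_deviance(y: np.ndarray, mu: np.ndarray) -> float:
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(y / mu), 0.0)
    return float(2 * (term - (y - mu)).sum())


def _nb2_deviance(y: np.ndarray, mu: np.ndarray, theta: float) -> float:
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(y / mu), 0.0)
    return float(
        2 * (term - (y + theta) * np.log((y + theta) / (mu + theta))).sum()
    )


def fit_poisson(data: pd.DataFrame, spec: ModelSpec | None = None) -> GLMFit:
    """Log-link Poisson regression fitted by IRLS."""
    spec = spec or ModelSpec(family="poisson")
    X, y, names = _design(data, spec)
    model = sm.GLM(y, X, family=sm.families.Poisson())
    try:
        res = model.fit(tol=1e-10)
    except ValueError as exc:  # e.g. all-zero response drives mu to 0
        raise RuntimeError(f"Poisson IRLS diverged: {exc}") from exc
    mu = res.fittedvalues
    if not res.converged or not np.all(np.isfinite(res.params)):
        raise RuntimeError("Poisson IRLS did not converge (degenerate response?)")
    if (y.sum() == 0) and spec.predictors == []:
        raise RuntimeError("all-zero response: intercept diverges to -inf")
    k = X.shape[1]
    ll = float(res.llf)
    return GLMFit(
        spec=spec, names=names, beta=np.asarray(res.params),
        covariance=np.asarray(res.cov_params()),
        loglik=ll,
        null_deviance=float(res.null_deviance),
        residual_deviance=float(res.deviance),
        df_residual=int(res.df_resid),
        aic=-2 * ll + 2 * k,
        bic=-2 * ll + np.log(len(y)) * k,
        theta=None,
        converged=bool(res.converged),
        n_iter=int(getattr(res, "fit_history", {}).get("iteration", 0) or 0),
        n_obs=len(y),
        loglik_obs=_poisson_loglik_obs(y, mu),
        X=X, y=y,
    )


def fit_negbin(data: pd.DataFrame, spec: ModelSpec | None = None,
               theta_cap: float = 1e6) -> GLMFit:
    """NB2 regression: variance mu + mu^2/theta, joint ML in (beta, theta).

    The dispersion is estimated by full maximum likelihood (statsmodels'
    NB2 likelihood, alpha = 1/theta); a theta diverging past ``theta_cap``
    is reported with a Poisson-equivalence warning.
    """
    spec = spec or ModelSpec(family="negbin")
    X, y, names = _design(data, spec)
    start = sm.GLM(y, X, family=sm.families.Poisson()).fit().params
    model = sm.NegativeBinomial(y, X, loglike_method="nb2")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(start_params=np.append(start, 0.5), disp=0,
                        maxiter=200, method="bfgs", gtol=1e-8)
        if not res.mle_retvals.get("converged", False):
            res = model.fit(start_params=np.append(start, 0.5), disp=0,
                            maxiter=500, method="nm", xtol=1e-8, ftol=1e-8)
    if not (res.mle_retvals.get("converged", False)
            or np.all(np.isfinite(res.params))):
        raise RuntimeError("NB2 maximum-likelihood fit did not converge")
    alpha = float(res.params[-1])
    theta = 1.0 / alpha if alpha > 1.0 / theta_cap else theta_cap
    if theta >= theta_cap:
        # at the alpha=0 boundary the NB Hessian is singular; the model is
        # the Poisson limit, so take beta and its covariance from there
        warnings.warn("theta at cap: data are Poisson-equivalent")
        pois = sm.GLM(y, X, family=sm.families.Poisson()).fit(tol=1e-10)
        beta = np.asarray(pois.params)
        cov = np.asarray(pois.cov_params())
    else:
        beta = np.asarray(res.params[:-1])
        cov = np.asarray(res.cov_params())[:-1, :-1]
    mu = np.exp(X @ beta)
    k = X.shape[1] + 1  # theta counts as a parameter
    ll = float(res.llf)
    mu0 = np.full_like(y, y.mean(), dtype=float)
    return GLMFit(
        spec=spec, names=names, beta=beta, covariance=cov,
        loglik=ll,
        null_deviance=_nb2_deviance(y, mu0, theta),
        residual_deviance=_nb2_deviance(y, mu, theta),
        df_residual=len(y) - X.shape[1],
        aic=-2 * ll + 2 * k,
        bic=-2 * ll + np.log(len(y)) * k,
        theta=theta,
        converged=bool(res.mle_retvals.get("converged", True)),
        n_iter=int(res.mle_retvals.get("iterations", 0) or 0),
        n_obs=len(y),
        loglik_obs=_nb2_loglik_obs(y, mu, theta),
        X=X, y=y,
    )


def fit_model(data: pd.DataFrame, spec: ModelSpec) -> GLMFit:
    return fit_poisson(data, spec) if spec.family == "poisson" else \
        fit_negbin(data, spec)


def overdispersion_test(fit: GLMFit) -> OverdispersionResult:
    """Residual-deviance chi-square test of the Poisson mean-variance
    assumption: ratio = residual deviance / residual df, p-value from the
    upper tail of chi-square(df) at the residual deviance."""
    if fit.df_residual <= 0:
        raise ValueError("need positive residual degrees of freedom")
    ratio = fit.residual_deviance / fit.df_residual
    p = float(stats.chi2.sf(fit.residual_deviance, fit.df_residual))
    return OverdispersionResult(
        ratio=float(ratio),
        statistic=float(fit.residual_deviance),
        df=fit.df_residual,
        p_value=p,
        overdispersed=p < 0.05,
    )


def dispersion_auxiliary_test(fit: GLMFit) -> OverdispersionResult:
    """Cameron-Trivedi auxiliary OLS test of overdispersion (one-sided)."""
    mu = fit.fitted
    z = ((fit.y - mu) ** 2 - fit.y) / mu
    t = sm.OLS(z, mu).fit()
    stat = float(t.tvalues[0])
    p = float(stats.norm.sf(stat))
    return OverdispersionResult(
        ratio=fit.residual_deviance / fit.df_residual,
        statistic=stat, df=fit.df_residual, p_value=p, overdispersed=p < 0.05,
    )


def effects_table(fit: GLMFit, level: float = 0.95) -> pd.DataFrame:
    """Exponentiated coefficients: rate ratios, percent changes, Wald CIs."""
    ci = fit.conf_int(level)
    return pd.DataFrame(
        {
            "term": fit.names,
            "estimate": fit.beta,
            "rate_ratio": np.exp(fit.beta),
            "rr_low": np.exp(ci[:, 0]),
            "rr_high": np.exp(ci[:, 1]),
            "percent_change": 100 * (np.exp(fit.beta) - 1),
            "ci_low": ci[:, 0],
            "ci_high": ci[:, 1],
            "p_value": fit.wald_pvalues(),
        }
    )


def percent_change(beta: float) -> float:
    """100*(exp(beta)-1) displayed to one decimal place.

    Display values are truncated toward zero rather than rounded, the
    convention the study's worked examples follow.
    """
    return math.trunc(1000 * (math.exp(beta) - 1)) / 10


def rate_ratio(beta: float) -> float:
    """exp(beta) displayed to two decimal places (truncated, see above)."""
    return math.trunc(100 * math.exp(beta)) / 100


def vuong_test(fit_a: GLMFit, fit_b: GLMFit) -> VuongResult:
    """Vuong closeness test for (possibly non-nested) count models fitted
    to the same response; positive statistic favors the first model."""
    if fit_a.n_obs != fit_b.n_obs or not np.array_equal(fit_a.y, fit_b.y):
        raise ValueError("models must be fitted to the identical response")
    m = fit_a.loglik_obs - fit_b.loglik_obs
    n = len(m)
    sd = m.std(ddof=0)
    if sd == 0:
        return VuongResult(statistic=0.0, p_value=1.0,
                           preferred="indistinguishable")
    z = float(np.sqrt(n) * m.mean() / sd)
    p = float(2 * stats.norm.sf(abs(z)))
    if p >= 0.05:
        preferred = "indistinguishable"
    else:
        preferred = "model_a" if z > 0 else "model_b"
    return VuongResult(statistic=z, p_value=p, preferred=preferred)


def fit_group_interaction(data: pd.DataFrame, spec: ModelSpec,
                          group: str = "group",
                          interacting: str | None = None) -> GLMFit:
    """Extend the design with a group indicator and a (count x group)
    interaction, keeping the requested family."""
    levels = data[group].unique()
    if len(levels) < 2:
        raise ValueError(f"group column {group!r} has a single level")
    interacting = interacting or spec.predictors[0]
    ext = ModelSpec(
        response=spec.response,
        predictors=spec.predictors + [group],
        family=spec.family,
        interaction=[(interacting, group)],
    )
    return fit_model(data, ext)


def predict_expected(fit: GLMFit, newdata: pd.DataFrame,
                     level: float = 0.95) -> pd.DataFrame:
    """Expected counts exp(x'beta) with delta-method CIs on the mean scale."""
    spec = fit.spec
    X, _, names = _design(
        newdata.assign(**{spec.response: 0}), spec, check_rank=False
    )
    if names != fit.names:
        raise ValueError(f"prediction grid columns mismatch: {names} vs {fit.names}")
    eta = X @ fit.beta
    se_eta = np.sqrt(np.einsum("ij,jk,ik->i", X, fit.covariance, X))
    z = stats.norm.ppf(0.5 + level / 2)
    out = newdata.copy()
    out["expected"] = np.exp(eta)
    out["ci_low"] = np.exp(eta - z * se_eta)
    out["ci_high"] = np.exp(eta + z * se_eta)
    return out
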