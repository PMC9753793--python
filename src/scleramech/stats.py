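"""Paired-eye statistical analysis.

Outcomes that are strictly positive (moduli, conductivities, ratios) are
analysed on the log scale with an animal-level random intercept, the mixed
linear model standing in for a Gamma/log-link GLMM with the identical mean
structure: fixed effects for eye (treated vs contralateral), treatment arm,
their interaction and the applied-strain deviation, exponentiated contrasts
giving percent interocular differences.  Estimated marginal means are
evaluated at zero strain deviation; because the deviation enters additively
on the log scale, the eye contrast coefficient is itself the corrected
log-ratio.  A fixed-effects Gamma GLM (log link, animal as blocks) is
provided as a cross-check mode.  Refractive error, which can be negative,
uses an identity-link Gaussian paired analysis.

Significance of fixed effects is by likelihood-ratio test between the full
model and null models each lacking one term; families of contrasts are
adjusted with the multivariate-t (max-|t|) method by seeded Monte Carlo.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import (
    EstimabilityError,
    InvalidInputError,
    NestingError,
)

__all__ = [
    "PairedModelFit",
    "EffectEstimate",
    "fit_paired_log_model",
    "emm_percent_iod",
    "likelihood_ratio_test",
    "adjust_multivariate_t",
    "concordance_correlation",
    "paired_gaussian_iod",
]


@dataclass(frozen=True)
class EffectEstimate:
    """A single exponentiated contrast reported as percent change."""

    label: str
    percent_change: float
    ci_low: float
    ci_high: float
    p_raw: float
    p_adjusted: float | None = None
    estimate_log: float = float("nan")
    se_log: float = float("nan")


@dataclass(frozen=True)
class PairedModelFit:
    """Wrapper around a fitted paired-eye model."""

    result: object
    formula: str
    method: str
    outcome: str
    nobs: int

    @property
    def llf(self) -> float:
        return float(self.result.llf)

    @property
    def params(self) -> pd.Series:
        return self.result.params

    def cov_params(self) -> pd.DataFrame:
        return self.result.cov_params()

    @property
    def fixed_names(self) -> list:
        names = list(self.result.fe_params.index) if hasattr(self.result, "fe_params") \
            else list(self.result.params.index)
        return names


def _default_formula(table: pd.DataFrame, outcome_expr: str) -> str:
    terms = []
    if "eye" in table:
        eye = "C(eye, Treatment(reference='contralateral'))"
        if "arm" in table and table["arm"].nunique() > 1:
            terms.append(f"{eye} * C(arm)")
        else:
            terms.append(eye)
    if "step" in table and table["step"].nunique() > 1:
        terms.append("C(step)")
    if "strain_deviation" in table:
        terms.append("strain_deviation")
    if not terms:
        terms = ["1"]
    return f"{outcome_expr} ~ " + " + ".join(terms)


def fit_paired_log_model(
    table: pd.DataFrame,
    formula: str | None = None,
    outcome: str = "value",
    groups: str = "animal_id",
    eye_vc: bool = True,
    method: str = "lmm",
) -> PairedModelFit:
    """Fit the paired log-link model.

    ``method='lmm'`` (default): linear mixed model on log(outcome) with an
    animal random intercept (plus an eye-level variance component when
    repeated steps per eye are present), maximum likelihood.
    ``method='gamma_glm'``: fixed-effects Gamma GLM with log link and animal
    blocks, as a cross-check of the mean structure.

    Deterministic given the data; duplicating every animal's rows leaves the
    point estimates unchanged.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = table.copy()
    if outcome not in df:
        raise InvalidInputError(f"outcome column {outcome!r} missing")
    y = pd.to_numeric(df[outcome])
    if (y <= 0).any() or not np.isfinite(y).all():
        raise InvalidInputError(
            f"outcome {outcome!r} must be strictly positive and finite for the "
            "log-scale family"
        )
    if groups in df and df[groups].nunique() < 2:
        raise InvalidInputError("need at least 2 animals")
    df["_log_y"] = np.log(y)

    if method == "gamma_glm":
        rhs = (formula or _default_formula(df, "_log_y")).split("~", 1)[1].strip()
        glm_formula = f"{outcome} ~ {rhs} + C({groups})"
        model = smf.glm(glm_formula, data=df,
                        family=sm.families.Gamma(link=sm.families.links.Log()))
        res = model.fit()
        return PairedModelFit(result=res, formula=glm_formula, method=method,
                              outcome=outcome, nobs=int(res.nobs))

    if method != "lmm":
        raise InvalidInputError(f"unknown method {method!r}")
    formula = formula or _default_formula(df, "_log_y")
    vc = None
    if eye_vc and "eye_id" in df:
        per_eye_rows = df.groupby("eye_id").size()
        if (per_eye_rows > 1).any():
            vc = {"eye": "0 + C(eye_id)"}
    model = smf.mixedlm(formula, data=df, groups=df[groups], vc_formula=vc)
    res = None
    last_err = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for optimizer in ("lbfgs", "bfgs", "cg", "powell"):
            try:
                candidate = model.fit(reml=False, method=optimizer, maxiter=500)
            except (np.linalg.LinAlgError, ValueError) as err:
                last_err = err
                continue
            res = candidate
            if getattr(res, "converged", True):
                break
    if res is None:
        raise InvalidInputError(f"mixed model fit failed: {last_err}")
    _check_rank(res)
    return PairedModelFit(result=res, formula=formula, method="lmm",
                          outcome=outcome, nobs=int(res.nobs))


def _check_rank(res) -> None:
    fe = res.fe_params if hasattr(res, "fe_params") else res.params
    if not np.all(np.isfinite(np.asarray(fe))):
        bad = [n for n, v in fe.items() if not np.isfinite(v)]
        raise InvalidInputError(f"singular design: aliased terms {bad}")


def _find_param(fit: PairedModelFit, contrast: str) -> str:
    names = fit.fixed_names
    if contrast in names:
        return contrast
    matches = [n for n in names if contrast in n]
    if len(matches) != 1:
        raise EstimabilityError(
            f"contrast {contrast!r} not uniquely estimable; fixed effects: {names}"
        )
    return matches[0]


def emm_percent_iod(fit: PairedModelFit, contrast: str = "eye") -> EffectEstimate:
    """Percent interocular difference from an exponentiated model contrast.

    ``percent = 100*(exp(beta) - 1)`` evaluated at zero strain deviation,
    with a delta-method (log-scale Wald) confidence interval.
    """
    name = _find_param(fit, contrast)
    b = float(fit.params[name])
    se = float(np.sqrt(fit.cov_params().loc[name, name]))
    z = sps.norm.ppf(0.975)
    pct = 100.0 * np.expm1(b)
    lo = 100.0 * np.expm1(b - z * se)
    hi = 100.0 * np.expm1(b + z * se)
    p = 2.0 * sps.norm.sf(abs(b) / se) if se > 0 else float(b == 0.0)
    return EffectEstimate(label=name, percent_change=pct, ci_low=lo, ci_high=hi,
                          p_raw=float(p), estimate_log=b, se_log=se)


def likelihood_ratio_test(full: PairedModelFit, null: PairedModelFit):
    """LRT between a full model and a nested null lacking fixed-effect terms.

    Returns ``(statistic, df, p)`` with the statistic ``2*(llf_full -
    llf_null)`` (clipped at 0 within tolerance) referred to chi-square with
    df equal to the fixed-effect parameter difference.
    """
    if full.nobs != null.nobs:
        raise NestingError("models fitted to different numbers of observations")
    full_names, null_names = set(full.fixed_names), set(null.fixed_names)
    if not null_names <= full_names:
        extra = sorted(null_names - full_names)
        raise NestingError(f"null model is not nested in full: extra terms {extra}")
    df = len(full_names) - len(null_names)
    stat = 2.0 * (full.llf - null.llf)
    if stat < -1e-6:
        raise NestingError(
            f"negative LRT statistic ({stat:.3g}): null fits better than full; "
            "models are not nested on the same data"
        )
    stat = max(stat, 0.0)
    p = 1.0 if df == 0 else float(sps.chi2.sf(stat, df))
    return stat, df, p


def adjust_multivariate_t(
    estimates,
    covariance,
    df: float,
    n_draws: int = 100_000,
    seed: int = 0,
):
    """Max-|t| (multivariate t) multiplicity adjustment of Wald contrasts.

    ``adjusted p_i = Pr(max_j |T_j| >= |t_i|)`` under the joint multivariate
    t distribution with the estimated contrast correlation, computed by
    seeded Monte Carlo.  A single contrast (or perfectly correlated family)
    is returned at its raw p-value; adjusted p-values never fall below raw.
    Returns ``(p_raw, p_adjusted)`` arrays.
    """
    est = np.atleast_1d(np.asarray(estimates, dtype=float))
    cov = np.atleast_2d(np.asarray(covariance, dtype=float))
    m = est.size
    if cov.shape != (m, m):
        raise InvalidInputError(f"covariance shape {cov.shape} != ({m},{m})")
    eig = np.linalg.eigvalsh((cov + cov.T) / 2.0)
    if eig.min() < -1e-8 * max(eig.max(), 1.0):
        raise InvalidInputError("covariance is not positive semi-definite")
    se = np.sqrt(np.diag(cov))
    if np.any(se <= 0):
        raise InvalidInputError("zero-variance contrast")
    t_obs = est / se
    use_t = np.isfinite(df)
    p_raw = (2.0 * sps.t.sf(np.abs(t_obs), df) if use_t
             else 2.0 * sps.norm.sf(np.abs(t_obs)))
    corr = cov / np.outer(se, se)
    if m == 1 or np.all(np.abs(corr - corr[0, 0]) < 1e-12):
        return p_raw, p_raw.copy()
    rng = np.random.default_rng(seed)
    # sample T = Z / sqrt(W/df), Z ~ N(0, R): one shared chi-square per draw,
    # as in the single-step max-t adjustment
    z = rng.multivariate_normal(np.zeros(m), corr, size=n_draws,
                                method="eigh")
    if use_t:
        w = rng.chisquare(df, size=n_draws) / df
        z = z / np.sqrt(w)[:, None]
    maxabs = np.max(np.abs(z), axis=1)
    p_adj = np.array([np.mean(maxabs >= abs(t)) for t in t_obs])
    return p_raw, np.maximum(p_raw, p_adj)


def concordance_correlation(x, y) -> float:
    """Lin's concordance correlation coefficient (population 1/n moments).

    rho_c = 2 s_xy / (s_x^2 + s_y^2 + (mean_x - mean_y)^2); penalises both
    poor correlation and location/scale shift, so |rho_c| <= |Pearson r|.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise InvalidInputError("x and y must be equal-length vectors with n >= 2")
    mx, my = x.mean(), y.mean()
    sx2 = np.mean((x - mx) ** 2)
    sy2 = np.mean((y - my) ** 2)
    sxy = np.mean((x - mx) * (y - my))
    denom = sx2 + sy2 + (mx - my) ** 2
    if denom == 0.0:
        raise InvalidInputError(
            "concordance undefined: both inputs constant with equal means"
        )
    return float(2.0 * sxy / denom)


def paired_gaussian_iod(iods) -> dict:
    """Identity-link Gaussian paired analysis for signed outcomes (e.g. RE).

    Returns the mean interocular difference with a t-based CI and two-sided
    p-value against zero.
    """
    d = np.asarray(iods, dtype=float)
    d = d[np.isfinite(d)]
    if d.size < 2:
        raise InvalidInputError("need >= 2 paired differences")
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    se = sd / np.sqrt(d.size)
    tcrit = sps.t.ppf(0.975, d.size - 1)
    if se > 0:
        p = float(2.0 * sps.t.sf(abs(mean) / se, d.size - 1))
    else:
        p = 1.0 if mean == 0 else 0.0
    return {
        "mean_iod": mean,
        "sd": sd,
        "se": float(se),
        "ci_low": mean - tcrit * se,
        "ci_high": mean + tcrit * se,
        "p": p,
        "n": int(d.size),
    }
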