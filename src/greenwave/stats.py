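"""Mixed-model inference on CIRG: transforms, screening, selection, effects.

The response is each animal's cumulative IRG over the growing season;
candidate predictors are landscape and biological covariates of the
summer home range.  Models are Gaussian linear mixed models with a
random intercept for collar-year, fit by maximum likelihood so that
AICc is comparable across fixed-effect structures; all subsets of the
global fixed effects (interactions only with both parents present) are
ranked by AICc, models within dAIC < 2 form the competitive set, and
variance explained is reported as marginal/conditional R^2 following
Nakagawa & Schielzeth.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# transforms

@dataclass
class TransformSpec:
    """Per-covariate transform plan plus fitted standardization constants.

    ``transforms`` maps column name to one of ``log`` (natural log,
    positive values), ``asin_sqrt`` (arcsine square root, proportions) or
    ``none``.  ``standardize`` lists columns to center and scale after
    transforming.  Means and sds are stored at fit time so effects can be
    mapped back to the original scale.
    """

    transforms: dict[str, str]
    standardize: tuple[str, ...] = ()
    means: dict[str, float] = field(default_factory=dict)
    sds: dict[str, float] = field(default_factory=dict)


def apply_transforms(table: pd.DataFrame, spec: TransformSpec) -> pd.DataFrame:
    """Transform and (optionally) standardize covariate columns.

    Returns a copy of the table; fitted centering/scaling constants are
    stored on ``spec`` for inverse mapping.
    """
    out = table.copy()
    for col, kind in spec.transforms.items():
        vals = out[col].to_numpy(dtype=float)
        finite = np.isfinite(vals)
        if kind == "log":
            if np.any(vals[finite] <= 0):
                i = table.index[finite][vals[finite] <= 0][0]
                raise ValueError(f"log transform of non-positive value in row {i!r} ({col})")
            out[col] = np.where(finite, np.log(np.where(finite, vals, 1.0)), np.nan)
        elif kind == "asin_sqrt":
            if np.any((vals[finite] < 0) | (vals[finite] > 1)):
                bad = (vals < 0) | (vals > 1)
                i = table.index[finite & bad][0]
                raise ValueError(f"proportion outside [0, 1] in row {i!r} ({col})")
            out[col] = np.arcsin(np.sqrt(np.clip(vals, 0.0, 1.0)))
        elif kind != "none":
            raise ValueError(f"unknown transform {kind!r} for {col}")
    for col in spec.standardize:
        vals = out[col].to_numpy(dtype=float)
        m = float(np.nanmean(vals))
        s = float(np.nanstd(vals, ddof=1))
        if s == 0:
            raise ValueError(f"cannot standardize constant column {col}")
        spec.means[col] = m
        spec.sds[col] = s
        out[col] = (vals - m) / s
    return out


# ---------------------------------------------------------------------------
# collinearity screen

def correlation_screen(table: pd.DataFrame, covariates: list[str],
                       relevance: list[str], threshold: float = 0.6):
    """Drop the less relevant member of each highly correlated pair.

    Pairwise Pearson correlations are computed on the (transformed)
    covariates; while any retained pair exceeds ``|r| > threshold``, the
    pair with the largest |r| is resolved by dropping the covariate
    ranked lower in ``relevance`` (a most-to-least-relevant ordering).
    Returns (retained, exclusion log).
    """
    missing = [c for c in covariates if c not in relevance]
    if missing:
        raise ValueError(f"relevance ranking missing covariates: {missing}")
    retained = list(covariates)
    exclusions: list[dict] = []
    while True:
        corr = table[retained].corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        corr = corr.fillna(0.0)  # constant columns carry no correlation signal
        r_max = float(corr.values.max()) if len(retained) > 1 else 0.0
        if r_max <= threshold:
            break
        i, j = np.unravel_index(int(np.argmax(corr.values)), corr.shape)
        a, b = retained[i], retained[j]
        drop = a if relevance.index(a) > relevance.index(b) else b
        keep = b if drop == a else a
        retained.remove(drop)
        exclusions.append({"dropped": drop, "kept": keep, "r": r_max})
        logger.info("correlation screen: dropped %s (|r|=%.2f with %s)", drop, r_max, keep)
    return retained, exclusions


# ---------------------------------------------------------------------------
# information criteria

def aicc(loglik: float, df: int, n: int) -> float:
    """Small-sample Akaike information criterion.

    AICc = -2 loglik + 2 df + 2 df (df + 1)/(n - df - 1), where ``df``
    counts all estimated parameters (fixed effects plus variance
    components).
    """
    if n <= df + 1:
        raise ValueError(f"AICc undefined for n={n} <= df+1={df + 1}")
    return -2.0 * loglik + 2.0 * df + 2.0 * df * (df + 1) / (n - df - 1)


# ---------------------------------------------------------------------------
# mixed model fit

@dataclass
class ModelFitResult:
    """One candidate mixed model: estimates, variances, AICc and R^2."""

    terms: tuple[str, ...]
    estimates: pd.Series
    se: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    year_sd: float
    resid_sd: float
    loglik: float
    aicc: float
    df: int
    n: int
    r2_marginal: float
    r2_conditional: float
    boundary_flag: bool = False
    converged: bool = True
    reml: bool = False


def _formula(response: str, terms) -> str:
    rhs = " + ".join(terms) if terms else "1"
    return f"{response} ~ {rhs}"


def fit_lmm(table: pd.DataFrame, response: str, terms,
            group: str = "year", reml: bool = False) -> ModelFitResult:
    """Fit a Gaussian random-intercept mixed model.

    ``terms`` are fixed-effect formula terms (numeric columns or ``a:b``
    interactions).  ML estimation is the default so that AICc is valid
    for comparing fixed-effect structures; pass ``reml=True`` only for
    final coefficient reporting.  A near-zero year variance is retained
    with ``boundary_flag`` set.
    """
    terms = tuple(terms)
    used = {response, group}
    for term in terms:
        used.update(term.split(":"))
    data = table[list(used)]
    if data.isna().any().any():
        raise ValueError("missing values in modeling columns; filter the table first")
    if table[group].nunique() < 2:
        raise ValueError("random intercept requires >= 2 group levels")

    formula = _formula(response, terms)

    # Boundary candidate: with the year variance profiled to zero the ML
    # solution is ordinary least squares (sigma^2 = RSS/n).  MixedLM cannot
    # represent this point stably (singular random-effects covariance), so
    # it is computed directly and kept when the interior fit fails or does
    # not beat it.
    ols = smf.ols(formula, data=table).fit()
    boundary_fit = {
        "fe": ols.params,
        "se": ols.bse,
        "var_year": 0.0,
        "var_resid": float(np.mean(ols.resid ** 2)),
        "llf": float(ols.llf),
        "exog": ols.model.exog,
        "boundary": True,
        "converged": True,
    }

    chosen = boundary_fit
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = smf.mixedlm(formula, data=table, groups=table[group])
            fit = model.fit(reml=reml, method=["powell", "cg"])
            llf = float(fit.llf)
            var_year = float(np.asarray(fit.cov_re)[0, 0])
            if np.isfinite(llf) and llf >= boundary_fit["llf"] - 1e-8:
                chosen = {
                    "fe": fit.fe_params,
                    "se": fit.bse_fe,
                    "var_year": var_year,
                    "var_resid": float(fit.scale),
                    "llf": llf,
                    "exog": fit.model.exog,
                    "boundary": var_year < 1e-6 * max(float(fit.scale), 1e-12),
                    "converged": bool(getattr(fit, "converged", True)),
                }
        except Exception:
            logger.info("mixed fit fell back to the zero-variance boundary: %s", terms)

    fe = chosen["fe"]
    var_year = chosen["var_year"]
    var_resid = chosen["var_resid"]
    boundary = chosen["boundary"]
    converged = chosen["converged"]
    n = len(table)
    df = len(fe) + 2
    ll = chosen["llf"]

    var_fixed = float(np.var(chosen["exog"] @ fe.to_numpy()))
    denom = var_fixed + var_year + var_resid
    r2m = var_fixed / denom if denom > 0 else 0.0
    r2c = (var_fixed + var_year) / denom if denom > 0 else 0.0

    from scipy.stats import norm

    tvals = fe / chosen["se"]
    pvals = pd.Series(2 * norm.sf(np.abs(tvals.to_numpy())), index=fe.index)
    return ModelFitResult(
        terms=terms,
        estimates=fe,
        se=chosen["se"],
        tvalues=tvals,
        pvalues=pvals,
        year_sd=float(np.sqrt(var_year)),
        resid_sd=float(np.sqrt(var_resid)),
        loglik=ll,
        aicc=aicc(ll, df, n),
        df=df,
        n=n,
        r2_marginal=r2m,
        r2_conditional=r2c,
        boundary_flag=boundary,
        converged=converged,
        reml=reml,
    )


def r2_nakagawa(fit: ModelFitResult) -> tuple[float, float]:
    """Marginal and conditional R^2 of a fitted mixed model."""
    return fit.r2_marginal, fit.r2_conditional


# ---------------------------------------------------------------------------
# all-subsets selection

@dataclass
class SelectionResult:
    """Ranked all-subsets AICc model comparison."""

    table: pd.DataFrame  # one row per candidate: terms, df, loglik, aicc, delta, weight
    fits: list[ModelFitResult]
    competitive: list[ModelFitResult]
    preferred: ModelFitResult


def all_subsets_selection(table: pd.DataFrame, response: str,
                          main_terms: list[str],
                          interactions: list[tuple[str, str]] = (),
                          group: str = "year",
                          delta_competitive: float = 2.0) -> SelectionResult:
    """Fit every admissible subset of the global fixed effects.

    All subsets of ``main_terms`` are considered; each interaction
    ``(a, b)`` may enter only alongside both of its parents
    (marginality).  Candidates are ranked by AICc; the preferred model is
    the lowest-AICc one, ties broken toward fewer covariates.
    Non-converging candidates are logged and ranked last.
    """
    candidates: list[tuple[str, ...]] = []
    for k in range(len(main_terms) + 1):
        for mains in itertools.combinations(main_terms, k):
            eligible = [f"{a}:{b}" for a, b in interactions if a in mains and b in mains]
            for j in range(len(eligible) + 1):
                for inters in itertools.combinations(eligible, j):
                    candidates.append(tuple(mains) + inters)

    fits: list[ModelFitResult] = []
    rows = []
    for terms in candidates:
        try:
            fit = fit_lmm(table, response, terms, group=group)
        except Exception as err:  # pragma: no cover - rare optimizer failures
            logger.warning("subset %s failed: %s", terms, err)
            continue
        if not fit.converged:
            logger.info("subset %s did not converge; ranked last", terms)
            fit.aicc = np.inf
        fits.append(fit)
        rows.append({
            "terms": " + ".join(terms) if terms else "(intercept)",
            "n_terms": len(terms),
            "df": fit.df,
            "loglik": fit.loglik,
            "aicc": fit.aicc,
        })

    tab = pd.DataFrame(rows)
    tab["delta_aic"] = tab["aicc"] - tab["aicc"].min()
    finite = np.isfinite(tab["delta_aic"].to_numpy())
    w = np.exp(-0.5 * np.where(finite, tab["delta_aic"].to_numpy(), np.inf))
    tab["weight"] = w / w.sum()
    order = tab.sort_values(["aicc", "n_terms"]).index.to_numpy()
    tab = tab.loc[order].reset_index(drop=True)
    fits = [fits[i] for i in order]
    competitive = [f for f, d in zip(fits, tab["delta_aic"]) if d < delta_competitive]
    return SelectionResult(table=tab, fits=fits, competitive=competitive,
                           preferred=fits[0])


# ---------------------------------------------------------------------------
# effect sizes on the original proportion scale

def effect_size_proportion(fit: ModelFitResult, covariate: str,
                           table: pd.DataFrame, spec: TransformSpec,
                           delta: float = 0.10) -> dict:
    """Back-transformed CIRG change for a ``delta`` increase in a proportion.

    For each animal with raw proportion p <= 1 - delta, the model-implied
    change is beta_raw [asin(sqrt(p + delta)) - asin(sqrt(p))], where
    beta_raw undoes any standardization of the arcsine-sqrt covariate.
    Returns the mean and min-max range of |change| over animals, the
    effect sign, and the count of excluded rows.
    """
    if spec.transforms.get(covariate) != "asin_sqrt":
        raise ValueError(f"{covariate} is not an arcsine-sqrt proportion covariate")
    beta = float(fit.estimates[covariate])
    if covariate in spec.sds:
        beta = beta / spec.sds[covariate]
    p = table[covariate].to_numpy(dtype=float)
    ok = np.isfinite(p) & (p <= 1.0 - delta)
    n_excluded = int((~ok).sum())
    change = beta * (np.arcsin(np.sqrt(p[ok] + delta)) - np.arcsin(np.sqrt(p[ok])))
    mags = np.abs(change)
    return {
        "mean": float(mags.mean()) if mags.size else 0.0,
        "min": float(mags.min()) if mags.size else 0.0,
        "max": float(mags.max()) if mags.size else 0.0,
        "sign": float(np.sign(beta)),
        "n_excluded": n_excluded,
    }
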