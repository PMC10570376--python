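"""Regression layer: how (Δ)MPD varies with latitude, climate and human
landscape modification, and how a species' naturalization probability
varies with its distance to the resident natives.

Region-level models
    * simple / weighted linear regressions of MPD or ΔMPD on latitude
      (inverse-null-variance weights for ΔMPD),
    * latitude × human-modification interaction models,
    * variance-weighted linear mixed models on the two climate axes with
      a continent random intercept.

Species-level model
    * a binomial GLMM with complementary log-log link,
      naturalized ~ MPD × |latitude|, with species and region random
      intercepts and (optionally) species random slopes, fitted through R
      lme4; a plain cloglog GLM is the documented fallback when R is not
      available.

All mixed-model inference is Wald-based.  Standardized effect sizes are
obtained by refitting on unit-variance-scaled predictors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
import statsmodels.api as sm

from . import _lme4

__all__ = [
    "ModelFit",
    "fit_weighted_linear",
    "fit_interaction_model",
    "fit_lmm_climate",
    "fit_glmm_naturalization",
    "partial_predictions",
    "completeness_weighted_refit",
]


@dataclass
class ModelFit:
    """A fitted model: coefficient table plus enough state to predict.

    ``coef`` is indexed by term with columns estimate, se, stat, pvalue
    (stat is a t or Wald z statistic depending on ``method``) and, for
    models fitted with ``standardize=True``, std_estimate / std_se from a
    refit on unit-variance predictors.
    """

    formula: str
    method: str
    coef: pd.DataFrame
    adj_r2: float | None = None
    re_var: dict | None = None
    converged: bool = True
    notes: list[str] = field(default_factory=list)
    data: pd.DataFrame | None = None
    predictors: list[str] = field(default_factory=list)
    _predict: Callable[[pd.DataFrame], np.ndarray] | None = None

    def predict(self, newdata: pd.DataFrame) -> np.ndarray:
        if self._predict is None:
            raise ValueError("this fit does not support prediction")
        return self._predict(newdata)


# ---------------------------------------------------------------------
# small design-matrix helper (terms are names or 'a:b' products)
# ---------------------------------------------------------------------


def _term_column(df: pd.DataFrame, term: str) -> np.ndarray:
    if ":" in term:
        a, b = term.split(":")
        return df[a].to_numpy(float) * df[b].to_numpy(float)
    return df[term].to_numpy(float)


def _design(df: pd.DataFrame, terms: list[str]) -> np.ndarray:
    cols = [np.ones(len(df))] + [_term_column(df, t) for t in terms]
    return np.column_stack(cols)


def _check_full_rank(X: np.ndarray, terms: list[str]) -> None:
    from scipy.linalg import qr

    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, _, piv = qr(X, mode="economic", pivoting=True)
        aliased = sorted(
            (["Intercept"] + terms)[j] for j in piv[rank:]
        )
        raise ValueError(f"rank-deficient design; aliased terms: {aliased}")


def _wls(
    df: pd.DataFrame,
    response: str,
    terms: list[str],
    weights: np.ndarray | None,
) -> sm.regression.linear_model.RegressionResultsWrapper:
    X = _design(df, terms)
    _check_full_rank(X, terms)
    y = df[response].to_numpy(float)
    w = np.ones(len(df)) if weights is None else np.asarray(weights, float)
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    return sm.WLS(y, X, weights=w).fit()


def _coef_frame(terms, est, se, stat, pval) -> pd.DataFrame:
    return pd.DataFrame(
        {"estimate": est, "se": se, "stat": stat, "pvalue": pval},
        index=pd.Index(["Intercept"] + list(terms), name="term"),
    )


def _standardized_refit(df, response, terms, weights, fitter) -> pd.DataFrame:
    """Refit on z-scored predictors; returns std_estimate/std_se."""
    zdf = df.copy()
    base_vars = sorted({v for t in terms for v in t.split(":")})
    for v in base_vars:
        x = zdf[v].to_numpy(float)
        sd = x.std(ddof=1)
        zdf[v] = (x - x.mean()) / (sd if sd > 0 else 1.0)
    refit = fitter(zdf, response, terms, weights)
    return refit.coef[["estimate", "se"]].rename(
        columns={"estimate": "std_estimate", "se": "std_se"}
    )


# ---------------------------------------------------------------------
# region-level linear models
# ---------------------------------------------------------------------


def fit_weighted_linear(
    response,
    predictors: dict | pd.DataFrame,
    weights=None,
    response_name: str = "y",
    standardize: bool = False,
) -> ModelFit:
    """(Weighted) least-squares regression with two-sided t tests.

    ``predictors`` maps names to vectors; weights, when given, are
    positive (for ΔMPD models: inverse null variances).
    """
    pred = pd.DataFrame(dict(predictors))
    df = pred.copy()
    df[response_name] = np.asarray(response, float)
    terms = list(pred.columns)
    res = _wls(df, response_name, terms, weights)
    fit = ModelFit(
        formula=f"{response_name} ~ " + " + ".join(terms),
        method="wls" if weights is not None else "ols",
        coef=_coef_frame(
            terms, res.params, res.bse, res.tvalues, res.pvalues
        ),
        adj_r2=float(res.rsquared_adj),
        data=df,
        predictors=terms,
        _predict=lambda nd, t=terms, p=np.asarray(res.params): (
            _design(nd, t) @ p
        ),
    )
    if standardize:
        std = _standardized_refit(
            df, response_name, terms, weights,
            lambda d, r, t, w: fit_weighted_linear(
                d[r], d[t], w, response_name=r
            ),
        )
        fit.coef = fit.coef.join(std)
    return fit


def fit_interaction_model(
    response, latitude, hm, weights=None, standardize: bool = False
) -> ModelFit:
    """response ~ latitude + hm + latitude×hm (optionally weighted)."""
    df = pd.DataFrame(
        {
            "latitude": np.asarray(latitude, float),
            "hm": np.asarray(hm, float),
            "y": np.asarray(response, float),
        }
    )
    terms = ["latitude", "hm", "latitude:hm"]
    res = _wls(df, "y", terms, weights)
    fit = ModelFit(
        formula="y ~ latitude * hm",
        method="wls" if weights is not None else "ols",
        coef=_coef_frame(
            terms, res.params, res.bse, res.tvalues, res.pvalues
        ),
        adj_r2=float(res.rsquared_adj),
        data=df,
        predictors=["latitude", "hm"],
        _predict=lambda nd, t=terms, p=np.asarray(res.params): (
            _design(nd, t) @ p
        ),
    )
    if standardize:
        std = _standardized_refit(
            df, "y", terms, weights,
            lambda d, r, t, w: _fit_terms(d, r, t, w),
        )
        fit.coef = fit.coef.join(std)
    return fit


def _fit_terms(df, response, terms, weights) -> ModelFit:
    res = _wls(df, response, terms, weights)
    return ModelFit(
        formula=f"{response} ~ " + " + ".join(terms),
        method="wls" if weights is not None else "ols",
        coef=_coef_frame(
            terms, res.params, res.bse, res.tvalues, res.pvalues
        ),
        adj_r2=float(res.rsquared_adj),
    )


# ---------------------------------------------------------------------
# climate LMM with continent random intercept and variance weights
# ---------------------------------------------------------------------


def fit_lmm_climate(
    response,
    pc_temp,
    pc_prec,
    hm,
    continent,
    weights=None,
    standardize: bool = True,
) -> ModelFit:
    """response ~ PC_Temp×HM + PC_Prec×HM + (1 | continent), weighted.

    Residual weights enter exactly: with Var(e_i) = σ²/w_i, the model is
    premultiplied by √w_i and the random-intercept design column becomes
    √w_i, which statsmodels MixedLM accepts as ``exog_re``.  Weights are
    rescaled internally to unit mean (inference is invariant to their
    overall scale).  A single continent degenerates to the weighted
    linear fit; non-convergence falls back likewise, flagged on the
    result.
    """
    df = pd.DataFrame(
        {
            "pc_temp": np.asarray(pc_temp, float),
            "pc_prec": np.asarray(pc_prec, float),
            "hm": np.asarray(hm, float),
            "continent": np.asarray(continent),
            "y": np.asarray(response, float),
        }
    )
    terms = ["pc_temp", "pc_prec", "hm", "pc_temp:hm", "pc_prec:hm"]
    w = np.ones(len(df)) if weights is None else np.asarray(weights, float)
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    w = w / w.mean()
    groups = df["continent"].to_numpy()
    formula = "y ~ pc_temp*hm + pc_prec*hm + (1|continent)"

    def _fallback(note: str) -> ModelFit:
        fit = _fit_with_predict(df, "y", terms, w, formula)
        fit.converged = "single group" in note
        fit.notes.append(note)
        if standardize:
            fit.coef = fit.coef.join(
                _standardized_refit(
                    df, "y", terms, w,
                    lambda d, r, t, ww: _fit_terms(d, r, t, ww),
                )
            )
        return fit

    if len(np.unique(groups)) < 2:
        return _fallback("single group: reduces to the weighted linear fit")

    X = _design(df, terms)
    _check_full_rank(X, terms)
    sw = np.sqrt(w)
    try:
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.MixedLM(
                endog=df["y"].to_numpy() * sw,
                exog=X * sw[:, None],
                groups=groups,
                exog_re=sw[:, None],
            )
            res = model.fit(reml=True, method=["lbfgs", "powell"])
        if not res.converged or not np.all(np.isfinite(res.bse_fe)):
            raise RuntimeError("mixed model did not converge")
    except Exception as exc:
        return _fallback(f"LMM fell back to weighted linear fit: {exc}")

    k = X.shape[1]
    params = np.asarray(res.params[:k])
    fit = ModelFit(
        formula=formula,
        method="lmm",
        coef=_coef_frame(
            terms,
            params,
            np.asarray(res.bse[:k]),
            np.asarray(res.tvalues[:k]),
            np.asarray(res.pvalues[:k]),
        ),
        re_var={
            "continent_intercept_var": float(np.asarray(res.cov_re)[0, 0]),
            "residual_var": float(res.scale),
        },
        converged=True,
        data=df,
        predictors=["pc_temp", "pc_prec", "hm"],
        _predict=lambda nd, t=terms, p=params: _design(nd, t) @ p,
    )
    if standardize:

        def _std_fitter(d, r, t, ww):
            sub = fit_lmm_climate(
                d[r], d["pc_temp"], d["pc_prec"], d["hm"], d["continent"],
                weights=ww, standardize=False,
            )
            return sub

        fit.coef = fit.coef.join(
            _standardized_refit(df, "y", terms, w, _std_fitter)
        )
    return fit


def _fit_with_predict(df, response, terms, weights, formula) -> ModelFit:
    res = _wls(df, response, terms, weights)
    base = sorted({v for t in terms for v in t.split(":")})
    return ModelFit(
        formula=formula,
        method="wls",
        coef=_coef_frame(
            terms, res.params, res.bse, res.tvalues, res.pvalues
        ),
        adj_r2=float(res.rsquared_adj),
        data=df,
        predictors=base,
        _predict=lambda nd, t=terms, p=np.asarray(res.params): (
            _design(nd, t) @ p
        ),
    )


# ---------------------------------------------------------------------
# species-level cloglog GLMM
# ---------------------------------------------------------------------

_GLMM_FORMULAS = {
    "full": (
        "naturalized ~ z_mpd * z_lat + (1 + z_mpd * z_lat | species)"
        " + (1 | region_id)"
    ),
    "intercepts_only": (
        "naturalized ~ z_mpd * z_lat + (1 | species) + (1 | region_id)"
    ),
}

_TERM_MAP = {
    "(Intercept)": "Intercept",
    "z_mpd": "mpd",
    "z_lat": "abs_latitude",
    "z_mpd:z_lat": "mpd:abs_latitude",
}


def _cloglog_inv(eta: np.ndarray) -> np.ndarray:
    return 1.0 - np.exp(-np.exp(eta))


def fit_glmm_naturalization(
    table: pd.DataFrame,
    random_structure: str = "full",
    backend: str = "auto",
) -> ModelFit:
    """Binomial cloglog mixed model of naturalization success.

    ``table`` holds one row per (species, region) with the species not
    native there: columns species, region_id, mpd_to_natives,
    abs_latitude, naturalized (0/1).  MPD and latitude are z-standardized
    internally.  The full random structure has species random slopes for
    MPD × latitude plus a region random intercept; non-convergence (or a
    singular fit) triggers an automatic refit with random intercepts
    only.  ``backend='glm'`` (or an unusable R) drops the random effects
    entirely — a plain cloglog GLM — and says so in the notes.
    """
    if random_structure not in _GLMM_FORMULAS:
        raise ValueError(
            "random_structure must be 'full' or 'intercepts_only'"
        )
    req = {"species", "region_id", "mpd_to_natives", "abs_latitude",
           "naturalized"}
    missing = req - set(table.columns)
    if missing:
        raise ValueError(f"table is missing columns: {sorted(missing)}")
    y = table["naturalized"].to_numpy(float)
    if not (np.any(y == 1) and np.any(y == 0)):
        raise ValueError("both outcome classes must be present")

    mpd = table["mpd_to_natives"].to_numpy(float)
    lat = table["abs_latitude"].to_numpy(float)
    scal = {
        "mpd_mean": mpd.mean(), "mpd_sd": mpd.std(ddof=1) or 1.0,
        "lat_mean": lat.mean(), "lat_sd": lat.std(ddof=1) or 1.0,
    }
    df = pd.DataFrame(
        {
            "species": table["species"].astype(str),
            "region_id": table["region_id"].astype(str),
            "z_mpd": (mpd - scal["mpd_mean"]) / scal["mpd_sd"],
            "z_lat": (lat - scal["lat_mean"]) / scal["lat_sd"],
            "naturalized": y.astype(int),
        }
    )
    notes: list[str] = []

    if backend == "auto":
        backend = "lme4" if _lme4.lme4_available() else "glm"
        if backend == "glm":
            notes.append(
                "R/lme4 unavailable; fell back to a cloglog GLM without "
                "random effects"
            )

    if backend == "lme4":
        structure = random_structure
        while True:
            try:
                res = _lme4.fit_glmer(df, _GLMM_FORMULAS[structure])
            except RuntimeError as exc:
                if structure == "full":
                    notes.append(
                        f"full random structure failed ({exc}); refitting "
                        "with random intercepts only"
                    )
                    structure = "intercepts_only"
                    continue
                notes.append(
                    f"glmer failed ({exc}); fell back to a cloglog GLM"
                )
                backend = "glm"
                break
            bad = bool(res["messages"]) or bool(res["singular"])
            if bad and structure == "full":
                notes.append(
                    "full random structure did not converge cleanly "
                    f"({res['messages'] or 'singular fit'}); refitting "
                    "with random intercepts only"
                )
                structure = "intercepts_only"
                continue
            terms = [_TERM_MAP.get(t, t) for t in res["terms"]]
            coef = pd.DataFrame(
                {
                    "estimate": res["estimate"],
                    "se": res["se"],
                    "stat": res["z"],
                    "pvalue": res["p"],
                },
                index=pd.Index(terms, name="term"),
            )
            re_var = {
                f"{g}:{t}" if t else f"{g}:Intercept": float(sd) ** 2
                for g, t, sd in zip(
                    res["vc_group"], res["vc_term"], res["vc_sd"]
                )
                if g != "Residual"
            }
            params = coef["estimate"].to_numpy()
            return ModelFit(
                formula=_GLMM_FORMULAS[structure],
                method=f"glmm-cloglog-lme4[{structure}]",
                coef=coef,
                re_var=re_var,
                converged=not bad,
                notes=notes + (
                    ["singular random-effect fit"] if res["singular"] else []
                ),
                data=table.copy(),
                predictors=["mpd_to_natives", "abs_latitude"],
                _predict=_make_glmm_predict(scal, params),
            )

    # plain cloglog GLM fallback / explicit backend
    if backend != "glm":
        raise ValueError("backend must be 'auto', 'lme4' or 'glm'")
    X = _design(df.rename(columns={}), ["z_mpd", "z_lat", "z_mpd:z_lat"])
    glm = sm.GLM(
        df["naturalized"].to_numpy(),
        X,
        family=sm.families.Binomial(link=sm.families.links.CLogLog()),
    ).fit()
    coef = _coef_frame(
        ["mpd", "abs_latitude", "mpd:abs_latitude"],
        glm.params, glm.bse, glm.tvalues, glm.pvalues,
    )
    return ModelFit(
        formula="naturalized ~ z_mpd * z_lat (no random effects)",
        method="glm-cloglog",
        coef=coef,
        converged=True,
        notes=notes,
        data=table.copy(),
        predictors=["mpd_to_natives", "abs_latitude"],
        _predict=_make_glmm_predict(scal, coef["estimate"].to_numpy()),
    )


def _make_glmm_predict(scal: dict, params: np.ndarray):
    def _predict(nd: pd.DataFrame) -> np.ndarray:
        zm = (
            nd["mpd_to_natives"].to_numpy(float) - scal["mpd_mean"]
        ) / scal["mpd_sd"]
        zl = (
            nd["abs_latitude"].to_numpy(float) - scal["lat_mean"]
        ) / scal["lat_sd"]
        eta = (
            params[0] + params[1] * zm + params[2] * zl
            + params[3] * zm * zl
        )
        return _cloglog_inv(eta)

    return _predict


# ---------------------------------------------------------------------
# partial predictions and sensitivity refits
# ---------------------------------------------------------------------


def partial_predictions(
    fit: ModelFit,
    focal: str,
    fix: dict[str, float] | None = None,
    fix_values: dict[str, float] | None = None,
    grid: int = 50,
) -> pd.DataFrame:
    """Predicted response along one predictor, others held fixed.

    ``fix`` maps predictor names to sample *quantiles* (e.g. HM at 0.1 /
    0.5 / 0.9); ``fix_values`` fixes on the raw scale (e.g. latitude at
    chosen values for the species-level model).  Unmentioned predictors
    sit at their sample mean.
    """
    if fit.data is None:
        raise ValueError("fit carries no training data")
    if focal not in fit.predictors:
        raise KeyError(
            f"unknown focal predictor {focal!r}; have {fit.predictors}"
        )
    fix = fix or {}
    fix_values = fix_values or {}
    for name in list(fix) + list(fix_values):
        if name not in fit.predictors:
            raise KeyError(f"unknown predictor {name!r}")
    x = np.linspace(
        fit.data[focal].min(), fit.data[focal].max(), grid
    )
    nd = pd.DataFrame({focal: x})
    for name in fit.predictors:
        if name == focal:
            continue
        if name in fix_values:
            nd[name] = fix_values[name]
        elif name in fix:
            nd[name] = float(fit.data[name].quantile(fix[name]))
        else:
            nd[name] = float(fit.data[name].mean())
    nd["prediction"] = fit.predict(nd)
    nd.insert(0, "focal", focal)
    return nd


def completeness_weighted_refit(
    response,
    predictors: dict | pd.DataFrame,
    completeness,
    min_completeness: float = 0.5,
    weights=None,
) -> tuple[ModelFit, ModelFit]:
    """Inventory-completeness sensitivity: subset fit and weighted fit.

    (a) refit on regions with completeness > ``min_completeness``;
    (b) refit on all regions with completeness as (additional) weights.
    """
    comp = np.asarray(completeness, float)
    if np.any((comp < 0) | (comp > 1)):
        raise ValueError("completeness must lie in [0, 1]")
    pred = pd.DataFrame(dict(predictors))
    y = np.asarray(response, float)
    base_w = np.ones(len(y)) if weights is None else np.asarray(weights)

    keep = comp > min_completeness
    if not keep.any():
        raise ValueError("completeness subset is empty")
    subset_fit = fit_weighted_linear(
        y[keep], pred[keep].reset_index(drop=True),
        weights=base_w[keep] if weights is not None else None,
    )
    if np.any(comp <= 0):
        raise ValueError("weighted refit needs positive completeness")
    weighted_fit = fit_weighted_linear(y, pred, weights=base_w * comp)
    return subset_fit, weighted_fit
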