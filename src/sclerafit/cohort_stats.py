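"""Group-comparison layer: gamma log-link GLMs, LRTs, marginal means,
multivariate-t multiplicity adjustment and percent differences.

Random-intercept structure is handled without re-implementing REML:
one-value-per-animal designs (eye-averaged biometry) are fit as plain
fixed-effects GLMs, which coincide with the mixed model in balanced
cases; repeated measures within a sample (three strain steps) use a
cluster-robust covariance as the documented stand-in.

Likelihood-ratio tests use profile log-likelihoods: the gamma shape
(and the gaussian variance) is maximized out at the fitted means in
both the full and null models, so twice the log-likelihood difference
is asymptotically chi-square with df equal to the parameter difference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import patsy
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import optimize, special, stats

__all__ = [
    "ModelSpec",
    "FittedModel",
    "ContrastResult",
    "fit_model",
    "likelihood_ratio_test",
    "emm_at",
    "adjust_multiplicity",
    "percent_difference",
]


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one outcome model.

    ``covariate`` is the numeric regressor interacting with treatment
    (strain in percent, or a numeric timepoint code); extra additive
    covariates (e.g. centered age deviation) go in ``extra_terms``.
    """

    outcome: str = "value"
    family: str = "gamma"  # "gamma" (log link) | "gaussian" (identity)
    treatment: str | None = "treatment"  # None -> intercept-only null model
    covariate: str | None = None
    interaction: bool = True
    extra_terms: tuple[str, ...] = ()
    cluster: str | None = None

    def __post_init__(self) -> None:
        if self.family not in ("gamma", "gaussian"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.interaction and self.covariate is None and self.covariate != "":
            # interaction without a covariate degenerates to the main effect
            pass

    def formula(self) -> str:
        if self.treatment is None:
            rhs = ["1"] if not self.covariate else [self.covariate]
        else:
            rhs = [f"C({self.treatment})"]
            if self.covariate:
                if self.interaction:
                    rhs = [f"C({self.treatment}) * {self.covariate}"]
                else:
                    rhs.append(self.covariate)
        rhs = rhs + list(self.extra_terms)
        return f"{self.outcome} ~ " + " + ".join(rhs)


@dataclass
class FittedModel:
    """A fitted GLM plus the profile log-likelihood used for LRTs."""

    result: object
    spec: ModelSpec
    formula: str
    llf: float
    n_params: int
    data: pd.DataFrame

    @property
    def params(self) -> pd.Series:
        return self.result.params

    @property
    def cov_params(self) -> pd.DataFrame:
        return self.result.cov_params()

    @property
    def df_resid(self) -> float:
        return self.result.df_resid


@dataclass
class ContrastResult:
    name: str
    estimate: float
    se: float
    statistic: float
    p_raw: float
    p_adjusted: float | None = None
    method: str = ""

    def __post_init__(self) -> None:
        if self.p_adjusted is not None and self.p_adjusted < self.p_raw - 1e-12:
            raise ValueError("adjusted p must be >= raw p")


def _gamma_profile_llf(y: np.ndarray, mu: np.ndarray) -> float:
    """Gamma log-likelihood with the shape parameter maximized out."""
    y = np.asarray(y, float)
    mu = np.asarray(mu, float)

    def nll(log_a: float) -> float:
        a = math.exp(log_a)
        return -np.sum(
            a * log_a
            - a * np.log(mu)
            + (a - 1.0) * np.log(y)
            - a * y / mu
            - special.gammaln(a)
        )

    res = optimize.minimize_scalar(nll, bounds=(-10, 15), method="bounded")
    return -res.fun


def _gaussian_profile_llf(y: np.ndarray, mu: np.ndarray) -> float:
    resid = np.asarray(y, float) - np.asarray(mu, float)
    n = len(resid)
    s2 = float(np.mean(resid**2))
    return -0.5 * n * (math.log(2.0 * math.pi * s2) + 1.0)


def fit_model(data: pd.DataFrame, spec: ModelSpec) -> FittedModel:
    """Fit the GLM described by ``spec`` to a long-format table.

    Gamma family requires strictly positive outcomes; offending rows
    are named in the error.  With ``spec.cluster`` set, the covariance
    is cluster-robust (repeated measures within sample).
    """
    if (
        spec.treatment is not None
        and spec.treatment in data.columns
        and data[spec.treatment].nunique() < 2
    ):
        raise ValueError("treatment must have at least 2 levels")
    y = data[spec.outcome]
    if spec.family == "gamma":
        bad = data.index[y <= 0].tolist()
        if bad:
            raise ValueError(
                f"gamma family requires positive outcomes; offending rows: {bad[:10]}"
            )
        family = sm.families.Gamma(link=sm.families.links.Log())
    else:
        family = sm.families.Gaussian()
    formula = spec.formula()
    model = smf.glm(formula, data=data, family=family)
    fit_kwds: dict = {}
    if spec.cluster:
        fit_kwds = {"cov_type": "cluster", "cov_kwds": {"groups": data[spec.cluster]}}
    try:
        result = model.fit(**fit_kwds)
    except ValueError:
        # zero-deviance boundary (e.g. constant response): seed IRLS with
        # the least-squares solution on the link scale
        endog = y.to_numpy(dtype=float)
        target = np.log(endog) if spec.family == "gamma" else endog
        start, *_ = np.linalg.lstsq(model.exog, target, rcond=None)
        import warnings as _warnings

        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            result = model.fit(start_params=start, **fit_kwds)
    if not np.all(np.isfinite(result.params)):
        raise ValueError("singular or separated design: non-finite coefficients")
    mu = result.fittedvalues.to_numpy()
    if spec.family == "gamma":
        llf = _gamma_profile_llf(y.to_numpy(), mu)
    else:
        llf = _gaussian_profile_llf(y.to_numpy(), mu)
    return FittedModel(
        result=result,
        spec=spec,
        formula=formula,
        llf=llf,
        n_params=len(result.params),
        data=data,
    )


def _is_nested(null: FittedModel, full: FittedModel) -> bool:
    """Column space of the null design contained in the full design."""
    xf = np.asarray(full.result.model.exog)
    xn = np.asarray(null.result.model.exog)
    if xn.shape[0] != xf.shape[0]:
        return False
    proj = xf @ np.linalg.lstsq(xf, xn, rcond=None)[0]
    return bool(np.allclose(proj, xn, atol=1e-8 * max(1.0, np.abs(xn).max())))


def likelihood_ratio_test(full: FittedModel, null: FittedModel) -> ContrastResult:
    """LRT of nested GLMs: 2*(llf_full - llf_null) ~ chi-square(df diff)."""
    if null.n_params > full.n_params or not _is_nested(null, full):
        raise ValueError("null model is not nested in the full model")
    df = full.n_params - null.n_params
    stat = max(2.0 * (full.llf - null.llf), 0.0)
    if df == 0:
        p = 1.0
    else:
        p = float(stats.chi2.sf(stat, df))
    return ContrastResult(
        name=f"LRT df={df}", estimate=stat, se=math.nan, statistic=stat, p_raw=p,
        method="likelihood ratio",
    )


def _prediction_matrix(fitted: FittedModel, points: pd.DataFrame) -> np.ndarray:
    design_info = fitted.result.model.data.design_info
    (X,) = patsy.build_design_matrices([design_info], points)
    return np.asarray(X)


def emm_at(
    fitted: FittedModel,
    covariate_values,
    *,
    extra_values: dict | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """Estimated marginal means at exact covariate values, per treatment.

    Returns ``(emms, contrasts, contrast_cov)``: response-scale group
    means with delta-method SEs, the treated-minus-control contrasts at
    each covariate value, and the joint covariance of those contrasts
    (for multiplicity adjustment).  Covariate values outside the
    observed range are flagged as extrapolations.
    """
    spec = fitted.spec
    if spec.covariate is None:
        raise ValueError("model has no numeric covariate to adjust")
    if spec.covariate not in fitted.data.columns:
        raise ValueError(f"covariate {spec.covariate!r} absent from model data")
    levels = sorted(fitted.data[spec.treatment].unique())
    obs = fitted.data[spec.covariate]
    lo, hi = obs.min(), obs.max()

    rows = []
    for v in covariate_values:
        for g in levels:
            row = {spec.treatment: g, spec.covariate: v}
            for term in spec.extra_terms:
                row[term] = 0.0
            if extra_values:
                row.update(extra_values)
            rows.append(row)
    points = pd.DataFrame(rows)
    X = _prediction_matrix(fitted, points)
    beta = fitted.params.to_numpy()
    V = np.asarray(fitted.cov_params)
    eta = X @ beta
    var_eta = np.einsum("ij,jk,ik->i", X, V, X)
    if spec.family == "gamma":
        mean = np.exp(eta)
        grad = mean[:, None] * X  # d(exp eta)/d(beta)
    else:
        mean = eta
        grad = X
    se_mean = np.sqrt(np.einsum("ij,jk,ik->i", grad, V, grad))

    emms = points.copy()
    emms["emm"] = mean
    emms["se"] = se_mean
    emms["extrapolated"] = (points[spec.covariate] < lo) | (
        points[spec.covariate] > hi
    )

    # treated-minus-control contrasts on the response scale at each value
    ctrl, others = levels[0], levels[1:]
    contrasts = []
    grads = []
    df = fitted.df_resid
    for v in covariate_values:
        sub = emms[emms[spec.covariate] == v]
        i_c = sub.index[sub[spec.treatment] == ctrl][0]
        for g in others:
            i_t = sub.index[sub[spec.treatment] == g][0]
            gvec = grad[i_t] - grad[i_c]
            est = mean[i_t] - mean[i_c]
            se = math.sqrt(float(gvec @ V @ gvec))
            tstat = est / se if se > 0 else math.nan
            p = 2.0 * float(stats.t.sf(abs(tstat), df))
            contrasts.append(
                {
                    "covariate_value": v,
                    "contrast": f"{g} - {ctrl}",
                    "estimate": est,
                    "se": se,
                    "statistic": tstat,
                    "p_raw": p,
                    "extrapolated": bool(v < lo or v > hi),
                }
            )
            grads.append(gvec)
    G = np.asarray(grads)
    contrast_cov = G @ V @ G.T
    return emms, pd.DataFrame(contrasts), contrast_cov


def adjust_multiplicity(
    contrasts: list[ContrastResult],
    cov: np.ndarray,
    df: float,
    method: str = "mvt",
    *,
    seed: int = 0,
    n_draws: int = 100_000,
) -> list[ContrastResult]:
    """Family-wise adjusted p-values via the max-|t| distribution.

    Draws from the joint multivariate t implied by the contrast
    covariance (Monte Carlo, fixed seed).  Falls back to Bonferroni with
    a warning flag when the covariance is singular beyond repair.
    """
    k = len(contrasts)
    if k == 0:
        return []
    if k == 1:
        c = contrasts[0]
        return [replace(c, p_adjusted=c.p_raw, method="single contrast")]
    cov = np.asarray(cov, dtype=float)
    sd = np.sqrt(np.diag(cov))
    tstats = np.array([c.statistic for c in contrasts])

    if method == "bonferroni":
        return [
            replace(c, p_adjusted=min(1.0, c.p_raw * k), method="bonferroni")
            for c in contrasts
        ]
    if method != "mvt":
        raise ValueError(f"unknown adjustment method {method!r}")

    corr = cov / np.outer(sd, sd)
    corr = np.clip(corr, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    try:
        # tiny jitter keeps perfectly-correlated families factorizable
        chol = np.linalg.cholesky(corr + 1e-10 * np.eye(k))
    except np.linalg.LinAlgError:
        return [
            replace(
                c,
                p_adjusted=min(1.0, c.p_raw * k),
                method="bonferroni (singular covariance fallback)",
            )
            for c in contrasts
        ]
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_draws, k)) @ chol.T
    if np.isfinite(df) and df > 0:
        s = np.sqrt(rng.chisquare(df, size=n_draws) / df)
        t_draws = z / s[:, None]
    else:
        t_draws = z
    max_abs = np.max(np.abs(t_draws), axis=1)
    out = []
    for c, t in zip(contrasts, tstats):
        p_mc = float(np.mean(max_abs >= abs(t)))
        out.append(
            replace(c, p_adjusted=min(1.0, max(p_mc, c.p_raw)), method="multivariate t")
        )
    return out


def percent_difference(
    table: pd.DataFrame,
    *,
    value: str = "value",
    treatment: str = "treatment",
    stratum: str | None = None,
    reference: str = "Ctrl",
) -> pd.DataFrame:
    """Per-sample percent difference from the control mean of the same stratum.

    Returns the non-reference rows with a ``pct_diff`` column; summary
    (mean +- SD per stratum) is in ``result.attrs["summary"]``.
    """
    strata = [stratum] if stratum else []
    ref_rows = table[table[treatment] == reference]
    if ref_rows.empty:
        raise ValueError(f"reference group {reference!r} is empty")
    if strata:
        ref_mean = ref_rows.groupby(strata)[value].mean()
        missing = set(table[stratum].unique()) - set(ref_mean.index)
        if missing:
            raise ValueError(f"empty reference stratum: {sorted(missing)}")
        ref = table[stratum].map(ref_mean)
    else:
        ref = pd.Series(ref_rows[value].mean(), index=table.index)
    if (ref == 0).any():
        raise ValueError("reference mean is zero")
    out = table.copy()
    out["pct_diff"] = 100.0 * (out[value] - ref) / ref
    out = out[out[treatment] != reference]
    if strata:
        summary = out.groupby(strata)["pct_diff"].agg(["mean", "std"])
    else:
        summary = out["pct_diff"].agg(["mean", "std"]).to_frame().T
    out.attrs["summary"] = summary
    return out
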