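"""Regressions of network properties on environmental gradients.

Each site contributes one row: its network metrics as responses and its
environmental covariates (elevation, absolute latitude, forest cover,
human footprint) as predictors.  Error families follow the nature of each
response: Gamma GLMs (log link) for the strictly positive mean richness
per flock and network CV; Gaussian GLMs for modularity and for
log-transformed connectance (bounded but heavily right-skewed); Beta
regressions (logit mean link, constant precision) for normalized average
degree and clustering, which live in (0, 1).

Predictors are z-scored before fitting, so coefficients are per-standard-
deviation effects; an elevation x |latitude| interaction is fitted first
and retained only when its Wald p-value is below 0.05.  Collinearity is
screened with pairwise Pearson correlations (|r| >= 0.5 flags) and
variance inflation factors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.othermod.betareg import BetaModel

from .metrics import MetricSet
from .io import SiteCovariates
from .robustness import RcomResult

logger = logging.getLogger(__name__)

PREDICTORS = ("elevation", "abs_latitude", "forest_cover", "human_footprint")
INTERACTION = "elevation:abs_latitude"

#: response -> (family, transform) as dictated by each metric's support
MODEL_SPECS: dict[str, tuple[str, str]] = {
    "mean_richness_per_flock": ("gamma", "none"),
    "cv": ("gamma", "none"),
    "modularity_q": ("gaussian", "none"),
    "connectance": ("gaussian", "log"),
    "avg_degree_norm": ("beta", "none"),
    "clustering": ("beta", "none"),
}


@dataclass(frozen=True)
class ModelSpec:
    response: str
    family: str
    transform: str
    predictors: tuple[str, ...] = PREDICTORS
    interaction: bool = True

    def __post_init__(self) -> None:
        if self.response in MODEL_SPECS:
            fam, tr = MODEL_SPECS[self.response]
            if (self.family, self.transform) != (fam, tr):
                raise ValueError(
                    f"{self.response} must use family={fam}, transform={tr}")


@dataclass(frozen=True)
class GradientFit:
    spec: ModelSpec
    n_sites: int
    coefficients: pd.DataFrame = field(repr=False)  # term, estimate, se, pvalue
    interaction_retained: bool = False
    vifs: dict[str, float] = field(default_factory=dict)
    convergence: bool = True
    loglik: float = float("nan")

    def __post_init__(self) -> None:
        if self.interaction_retained and \
                INTERACTION not in set(self.coefficients["term"]):
            raise ValueError("interaction flagged retained but term absent")

    def coef(self, term: str) -> tuple[float, float, float]:
        row = self.coefficients.set_index("term").loc[term]
        return float(row["estimate"]), float(row["se"]), float(row["pvalue"])


def _as_fit(spec: ModelSpec, res, terms: list[str],
            vifs: dict[str, float] | None = None,
            converged: bool = True) -> GradientFit:
    coefs = pd.DataFrame({
        "term": terms,
        "estimate": np.asarray(res.params, dtype=float),
        "se": np.asarray(res.bse, dtype=float),
        "pvalue": np.asarray(res.pvalues, dtype=float),
    })
    return GradientFit(spec=spec, n_sites=int(res.nobs), coefficients=coefs,
                       interaction_retained=INTERACTION in terms,
                       vifs=vifs or {}, convergence=converged,
                       loglik=float(res.llf))


def _check_design(X: np.ndarray) -> None:
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")


def fit_gamma_glm(y: np.ndarray, X: np.ndarray, terms: list[str] | None = None,
                  spec: ModelSpec | None = None) -> GradientFit:
    """Gamma GLM with log link (ML via IRLS); Wald inference.

    The log link is used rather than the canonical inverse link: it keeps
    the mean positive for any linear predictor and is far better behaved on
    small positive responses.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if (y <= 0).any():
        raise ValueError("Gamma response must be strictly positive")
    _check_design(X)
    terms = terms or [f"x{i}" for i in range(X.shape[1])]
    spec = spec or ModelSpec("y_gamma", "gamma", "none")
    model = sm.GLM(y, X, family=sm.families.Gamma(link=sm.families.links.Log()))
    res = model.fit()
    return _as_fit(spec, res, terms, converged=bool(res.converged))


def fit_gaussian_glm(y: np.ndarray, X: np.ndarray, terms: list[str] | None = None,
                     spec: ModelSpec | None = None) -> GradientFit:
    """Ordinary least squares (Gaussian GLM with identity link)."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    _check_design(X)
    terms = terms or [f"x{i}" for i in range(X.shape[1])]
    spec = spec or ModelSpec("y_gaussian", "gaussian", "none")
    res = sm.OLS(y, X).fit()
    return _as_fit(spec, res, terms)


def compress_unit_interval(y: np.ndarray, n: int | None = None) -> np.ndarray:
    """Smithson-Verkuilen boundary compression y' = (y (n-1) + 0.5) / n.

    Keeps responses strictly inside (0, 1) so the Beta likelihood is
    defined when observed proportions touch the boundary.
    """
    y = np.asarray(y, dtype=float)
    n = n if n is not None else len(y)
    return (y * (n - 1) + 0.5) / n


def fit_beta_regression(y: np.ndarray, X: np.ndarray,
                        terms: list[str] | None = None,
                        spec: ModelSpec | None = None) -> GradientFit:
    """Maximum-likelihood Beta regression, logit mean link, constant precision.

    Responses on [0, 1] are allowed: exact 0/1 values trigger boundary
    compression of the whole response vector (logged); values outside
    [0, 1] are a domain error.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if (y < -1e-9).any() or (y > 1 + 1e-9).any():
        raise ValueError("Beta response must lie in [0, 1]")
    y = np.clip(y, 0.0, 1.0)  # forgive floating-point overshoot only
    _check_design(X)
    if (y <= 0).any() or (y >= 1).any():
        logger.warning("boundary response values: applying (y(n-1)+0.5)/n "
                       "compression before Beta fit")
        y = compress_unit_interval(y)
    terms = terms or [f"x{i}" for i in range(X.shape[1])]
    spec = spec or ModelSpec("y_beta", "beta", "none")
    model = BetaModel(y, X)
    res = model.fit(disp=False)
    converged = bool(getattr(res, "mle_retvals", {}).get("converged", True))
    # last parameter is the precision; report mean-model terms only
    coefs = pd.DataFrame({
        "term": terms,
        "estimate": np.asarray(res.params[:len(terms)], dtype=float),
        "se": np.asarray(res.bse[:len(terms)], dtype=float),
        "pvalue": np.asarray(res.pvalues[:len(terms)], dtype=float),
    })
    return GradientFit(spec=spec, n_sites=int(res.nobs), coefficients=coefs,
                       interaction_retained=INTERACTION in terms,
                       convergence=converged, loglik=float(res.llf))


def vif(X: np.ndarray, terms: list[str] | None = None) -> dict[str, float]:
    """Variance inflation factors: VIF_j = 1 / (1 - R2_j).

    Each predictor is regressed (with intercept) on the others; perfectly
    collinear predictors report infinity.  ``X`` holds predictors only (no
    intercept column).
    """
    X = np.asarray(X, dtype=float)
    if X.shape[1] < 2:
        raise ValueError("VIF needs at least two predictors")
    if (X.std(axis=0) == 0).any():
        raise ValueError("constant predictor column")
    terms = terms or [f"x{i}" for i in range(X.shape[1])]
    out = {}
    for j in range(X.shape[1]):
        others = sm.add_constant(np.delete(X, j, axis=1))
        r2 = sm.OLS(X[:, j], others).fit().rsquared
        out[terms[j]] = float("inf") if r2 >= 1 - 1e-12 else float(1 / (1 - r2))
    return out


def screen_predictors(covars: list[SiteCovariates] | pd.DataFrame,
                      n_species: dict[str, int] | None = None,
                      flag_threshold: float = 0.5) -> tuple[pd.DataFrame, list]:
    """Pairwise Pearson correlations among predictors (and effort columns).

    Returns the correlation matrix and a list of flagged pairs with
    |r| >= ``flag_threshold``.  Constant columns yield NaN correlations,
    reported as missing and never flagged.
    """
    if isinstance(covars, pd.DataFrame):
        df = covars.copy()
    else:
        df = pd.DataFrame([{
            "elevation": c.elevation, "abs_latitude": abs(c.latitude),
            "forest_cover": c.forest_cover, "human_footprint": c.human_footprint,
            "n_flocks": c.n_flocks, "site_id": c.site_id} for c in covars])
        if n_species:
            df["n_species"] = df["site_id"].map(n_species)
        df = df.drop(columns="site_id")
    if len(df) < 2:
        raise ValueError("need at least two sites to screen predictors")
    corr = df.corr(method="pearson")
    flags = []
    cols = list(corr.columns)
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            r = corr.loc[a, b]
            if np.isfinite(r) and abs(r) >= flag_threshold:
                flags.append((a, b, float(r)))
    return corr, flags


def build_model_table(metrics: list[MetricSet],
                      covars: list[SiteCovariates]) -> pd.DataFrame:
    """Join per-site metrics and covariates into one modelling table."""
    mi = {m.site_id: m for m in metrics}
    ci = {c.site_id: c for c in covars}
    if set(mi) - set(ci):
        raise ValueError(f"sites without covariates: {sorted(set(mi) - set(ci))}")
    rows = []
    for sid, m in mi.items():
        c = ci[sid]
        rows.append({
            "site_id": sid, "n_flocks": m.n_flocks, "n_species": m.n_species,
            "mean_richness_per_flock": m.mean_richness_per_flock,
            "cv": m.cv, "avg_degree_norm": m.avg_degree_norm,
            "connectance": m.connectance, "modularity_q": m.modularity_q,
            "clustering": m.clustering,
            "elevation": c.elevation, "abs_latitude": abs(c.latitude),
            "forest_cover": c.forest_cover, "human_footprint": c.human_footprint,
        })
    return pd.DataFrame(rows).sort_values("site_id").reset_index(drop=True)


def _design(df: pd.DataFrame, interaction: bool) -> tuple[np.ndarray, list[str]]:
    z = {}
    for p in PREDICTORS:
        col = df[p].to_numpy(dtype=float)
        sd = col.std(ddof=0)
        if sd == 0:
            raise ValueError(f"constant predictor {p}")
        z[p] = (col - col.mean()) / sd
    cols = [np.ones(len(df))] + [z[p] for p in PREDICTORS]
    terms = ["intercept", *PREDICTORS]
    if interaction:
        cols.append(z["elevation"] * z["abs_latitude"])
        terms.append(INTERACTION)
    return np.column_stack(cols), terms


def fit_metric_model(df: pd.DataFrame, response: str,
                     interaction_alpha: float = 0.05) -> GradientFit:
    """Fit one response with its prescribed family and the retention rule.

    The model is fitted with the elevation x |latitude| interaction; the
    interaction is retained iff its Wald p < ``interaction_alpha``,
    otherwise the model is refitted without it.  VIFs are attached for the
    four main-effect predictors.
    """
    family, transform = MODEL_SPECS[response]
    sub = df.dropna(subset=[response])
    if len(sub) < len(df):
        logger.warning("%s: dropped %d site(s) with undefined response",
                       response, len(df) - len(sub))
    y = sub[response].to_numpy(dtype=float)
    if transform == "log":
        if (y <= 0).any():
            raise ValueError(f"{response}: log transform needs positive values")
        y = np.log(y)

    def fit_once(interaction: bool) -> GradientFit:
        X, terms = _design(sub, interaction)
        spec = ModelSpec(response, family, transform,
                         interaction=interaction)
        if family == "gamma":
            return fit_gamma_glm(y, X, terms, spec)
        if family == "gaussian":
            return fit_gaussian_glm(y, X, terms, spec)
        return fit_beta_regression(y, X, terms, spec)

    full = fit_once(True)
    _, _, p_int = full.coef(INTERACTION)
    if np.isfinite(p_int) and p_int < interaction_alpha:
        chosen = full
    else:
        chosen = fit_once(False)
    X_main, _ = _design(sub, False)
    vifs = vif(X_main[:, 1:], list(PREDICTORS))
    return GradientFit(spec=chosen.spec, n_sites=chosen.n_sites,
                       coefficients=chosen.coefficients,
                       interaction_retained=chosen.interaction_retained,
                       vifs=vifs, convergence=chosen.convergence,
                       loglik=chosen.loglik)


def run_gradient_analysis(metrics: list[MetricSet],
                          covars: list[SiteCovariates],
                          subset: str = "all",
                          rcom_results: list[RcomResult] | None = None,
                          rcom_threshold: float = 0.4,
                          min_flocks: int = 20,
                          exclude: list[str] | None = None,
                          ) -> dict[str, GradientFit]:
    """Fit all six metric models on a chosen subset of sites.

    Subsets: ``all`` (every analysed site), ``min20`` (sites with at least
    ``min_flocks`` flocks), ``rcom04`` (modularity model only, sites with
    r_com strictly above ``rcom_threshold``), ``exclude_list`` (drop the
    sites named in ``exclude``).
    """
    df = build_model_table(metrics, covars)
    if subset == "all":
        pass
    elif subset == "min20":
        df = df[df["n_flocks"] >= min_flocks]
    elif subset == "rcom04":
        if rcom_results is None:
            raise ValueError("subset rcom04 needs rcom_results")
        keep = {r.site_id for r in rcom_results
                if r.r_com > rcom_threshold and not r.degenerate}
        df = df[df["site_id"].isin(keep)]
    elif subset == "exclude_list":
        df = df[~df["site_id"].isin(set(exclude or []))]
    else:
        raise ValueError(f"unknown subset {subset!r}")
    if df.empty:
        raise ValueError(f"subset {subset!r} retained no sites")
    responses = (["modularity_q"] if subset == "rcom04"
                 else list(MODEL_SPECS))
    return {r: fit_metric_model(df, r) for r in responses}
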