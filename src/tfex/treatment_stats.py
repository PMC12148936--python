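"""Treatment comparisons: transform rules, mixed models, regressions.

The central question is whether a measured hydraulic variable differs
between the droughted (TFE) and control plots once tree size and taxonomy
are accounted for.  The canonical model is a linear mixed model on the
transformed response with plot and diameter as fixed effects and individual
nested within genus as random effects; reduced models (dropping genus
and/or diameter) are fitted alongside and the module reports whether the
conclusions converge (same sign, same significance verdict at alpha=0.05).

Transform rules:

* log for most responses (improves residual normality),
* square root for the "reduction from annual maximum" percentages,
* absolute value before log for (negative) water potentials,
* none as an explicit opt-out.

Fixed-effect p-values are Wald tests on the mixed-model estimates; the
random-effects backend is statsmodels MixedLM, with individual-level
variation entering as a variance component inside genus groups.  Singular
fits fall back to a reduced random structure (then to OLS) with a logged
warning.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

logger = logging.getLogger(__name__)

ALPHA = 0.05

TRANSFORMS = ("log", "sqrt", "abs_then_log", "none")


def apply_transform(values, transform: str):
    """Apply a named transform; domain violations raise rather than NaN."""
    x = np.asarray(values, dtype=float)
    if transform == "log":
        if np.any(x <= 0):
            raise ValueError("log transform requires positive values")
        return np.log(x)
    if transform == "sqrt":
        if np.any(x < 0):
            raise ValueError("sqrt transform requires non-negative values")
        return np.sqrt(x)
    if transform == "abs_then_log":
        a = np.abs(x)
        if np.any(a <= 0):
            raise ValueError("abs_then_log requires non-zero values")
        return np.log(a)
    if transform == "none":
        return x
    raise ValueError(f"unknown transform {transform!r}")


def transform_for_response(response: str) -> str:
    """Default transform rule for a response variable, by naming convention.

    Reduction-from-annual-max percentages -> sqrt; water potentials (which
    are negative tensions) -> absolute value then log; everything else ->
    log.  The registry is total: every response name maps to exactly one
    rule.
    """
    name = response.lower()
    if "reduction" in name:
        return "sqrt"
    if "wp" in name or "water_potential" in name or "psi" in name:
        return "abs_then_log"
    return "log"


@dataclass(frozen=True)
class ComparisonSpec:
    """Specification of one plot comparison."""

    response: str
    transform: Optional[str] = None          # None = registry default
    fixed_effects: Tuple[str, ...] = ("plot", "diameter")
    random_structure: str = "individual_in_genus"  # or "genus", "none"
    subset: Optional[str] = None             # pandas query string

    def resolved_transform(self) -> str:
        t = self.transform or transform_for_response(self.response)
        if t not in TRANSFORMS:
            raise ValueError(f"unknown transform {t!r}")
        return t


@dataclass
class ModelResult:
    """Fitted-model summary: estimates, Wald p-values, bookkeeping."""

    params: Dict[str, float]
    bse: Dict[str, float]
    pvalues: Dict[str, float]
    n_obs: int
    method: str                       # "mixedlm", "ols"
    converged: bool
    plot_term: Optional[str] = None
    variance_components: Dict[str, float] = field(default_factory=dict)
    conclusions_converge: Optional[bool] = None
    notes: str = ""

    @property
    def plot_estimate(self) -> Optional[float]:
        return self.params.get(self.plot_term) if self.plot_term else None

    @property
    def plot_pvalue(self) -> Optional[float]:
        return self.pvalues.get(self.plot_term) if self.plot_term else None


def _result_from_fit(res, method: str, plot_term: Optional[str],
                     vc: Optional[Dict[str, float]] = None,
                     notes: str = "") -> ModelResult:
    params = {k: float(v) for k, v in res.params.items()}
    bse = {k: float(v) for k, v in res.bse.items()}
    pvalues = {k: float(v) for k, v in res.pvalues.items()}
    converged = bool(getattr(res, "converged", True))
    return ModelResult(params=params, bse=bse, pvalues=pvalues,
                       n_obs=int(res.nobs), method=method,
                       converged=converged, plot_term=plot_term,
                       variance_components=vc or {}, notes=notes)


def _find_term(params: Iterable[str], stem: str) -> Optional[str]:
    for name in params:
        if stem in name:
            return name
    return None


def _has_replicates(df: pd.DataFrame) -> bool:
    return "tree_id" in df.columns and df["tree_id"].duplicated().any()


def _aggregate_replicates(df: pd.DataFrame) -> pd.DataFrame:
    """One row per tree: numeric columns averaged, labels carried through."""
    numeric = df.select_dtypes("number").columns
    agg = {c: "mean" for c in numeric}
    for c in ("plot", "genus"):
        if c in df.columns:
            agg[c] = "first"
    return df.groupby("tree_id", observed=True).agg(agg).reset_index()


def _fixed_pvalues_ok(res, fixed_terms: Iterable[str]) -> bool:
    """Wald p-values for the fixed effects must be finite (a boundary or
    singular random-effects fit produces NaNs)."""
    for name in fixed_terms:
        if name in res.pvalues.index and not np.isfinite(res.pvalues[name]):
            return False
    return True


def _fit_mixed(df: pd.DataFrame, fixed_formula: str,
               random_structure: str) -> ModelResult:
    """Fit a mixed model, degrading the random structure if it is singular."""
    fixed_terms = [t.strip() for t in
                   fixed_formula.split("~")[1].split("+")]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if random_structure == "individual_in_genus":
            try:
                model = smf.mixedlm(fixed_formula, df, groups=df["genus"],
                                    re_formula="1",
                                    vc_formula={"individual": "0 + C(tree_id)"})
                res = model.fit(reml=True)
                if res.converged and _fixed_pvalues_ok(
                        res, [_find_term(res.params.index, t) or t
                              for t in fixed_terms]):
                    vc = {"genus": float(res.cov_re.iloc[0, 0]),
                          "individual": float(res.vcomp[0]),
                          "residual": float(res.scale)}
                    return _result_from_fit(res, "mixedlm",
                                            _find_term(res.params.index, "plot"),
                                            vc)
                logger.warning("nested mixed fit singular; reducing random "
                               "structure to genus")
            except Exception as exc:  # numerical failure
                logger.warning("nested mixed fit failed (%s); reducing random "
                               "structure to genus", exc)
            random_structure = "genus"
        if random_structure == "genus":
            try:
                model = smf.mixedlm(fixed_formula, df, groups=df["genus"])
                res = model.fit(reml=True)
                if res.converged and _fixed_pvalues_ok(
                        res, [_find_term(res.params.index, t) or t
                              for t in fixed_terms]):
                    vc = {"genus": float(res.cov_re.iloc[0, 0]),
                          "residual": float(res.scale)}
                    return _result_from_fit(
                        res, "mixedlm", _find_term(res.params.index, "plot"),
                        vc, notes="random structure: genus intercept only")
                logger.warning("genus mixed fit singular; falling back to OLS")
            except Exception as exc:
                logger.warning("genus mixed fit failed (%s); falling back to "
                               "OLS", exc)
    res = smf.ols(fixed_formula, df).fit()
    return _result_from_fit(res, "ols", _find_term(res.params.index, "plot"),
                            notes="fell back to OLS (singular random structure)")


def compare_plots(data: pd.DataFrame, spec: ComparisonSpec) -> ModelResult:
    """Mixed-model comparison of a response between plots.

    ``data`` needs columns ``plot`` (two levels), the response, and as
    applicable ``diameter``, ``genus``, ``tree_id``.  The full model per
    ``spec`` is fitted, plus a reduced model excluding genus and diameter
    (plain OLS of response on plot); the result's
    ``conclusions_converge`` records whether both give the same plot-effect
    sign and the same significance verdict at alpha = 0.05.
    """
    df = data.copy()
    if spec.subset:
        df = df.query(spec.subset)
    df = df.dropna(subset=[spec.response]).reset_index(drop=True)
    if df.empty:
        raise ValueError(f"no observations for response {spec.response!r}")
    transform = spec.resolved_transform()
    df["_y"] = apply_transform(df[spec.response], transform)

    terms = []
    if "plot" in spec.fixed_effects:
        terms.append("C(plot)")
    if "diameter" in spec.fixed_effects and "diameter" in df.columns:
        terms.append("diameter")
    fixed_formula = "_y ~ " + (" + ".join(terms) if terms else "1")

    use_random = (spec.random_structure != "none"
                  and "genus" in df.columns
                  and df["genus"].nunique() >= 2)
    if use_random:
        full = _fit_mixed(df, fixed_formula, spec.random_structure)
        if full.method == "ols" and _has_replicates(df):
            # a raw-row OLS on repeated measures is pseudo-replicated;
            # aggregate to one mean per tree before the fallback fit
            agg = _aggregate_replicates(df)
            res = smf.ols(fixed_formula, agg).fit()
            full = _result_from_fit(
                res, "ols", _find_term(res.params.index, "plot"),
                notes="fell back to per-tree OLS (singular random structure)")
    else:
        fit_df = _aggregate_replicates(df) if _has_replicates(df) else df
        res = smf.ols(fixed_formula, fit_df).fit()
        full = _result_from_fit(res, "ols", _find_term(res.params.index, "plot"))

    # Reduced model: plot only — genus and diameter dropped, but the
    # individual random intercept kept (repeated measures per tree).
    reduced_res = None
    if "tree_id" in df.columns and df["tree_id"].nunique() >= 2:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                reduced_res = smf.mixedlm("_y ~ C(plot)", df,
                                          groups=df["tree_id"]).fit(reml=True)
                if not reduced_res.converged:
                    reduced_res = None
        except Exception:
            reduced_res = None
    if reduced_res is None:
        reduced_res = smf.ols("_y ~ C(plot)", df).fit()
    reduced_term = _find_term(reduced_res.params.index, "C(plot)")
    if full.plot_term is not None and reduced_term is not None:
        full_sig = full.plot_pvalue < ALPHA
        red_sig = float(reduced_res.pvalues[reduced_term]) < ALPHA
        same_sign = (np.sign(full.plot_estimate)
                     == np.sign(float(reduced_res.params[reduced_term])))
        full.conclusions_converge = bool((full_sig == red_sig)
                                         and (same_sign or
                                              (not full_sig and not red_sig)))
    return full


def variance_explained(data: pd.DataFrame, response: str,
                       factors: Sequence[str] = ("genus", "diameter"),
                       transform: Optional[str] = None) -> Dict[str, float]:
    """R^2 of the (transformed) response explained by each factor separately.

    One plain linear model per factor: categorical for genus, linear for
    diameter.  Returns ``{factor: r_squared}``.
    """
    df = data.dropna(subset=[response]).copy()
    t = transform or transform_for_response(response)
    df["_y"] = apply_transform(df[response], t)
    out = {}
    for factor in factors:
        if factor == "genus":
            formula = "_y ~ C(genus)"
        else:
            formula = f"_y ~ {factor}"
        res = smf.ols(formula, df).fit()
        out[factor] = float(res.rsquared)
    return out


def _simple_regression(df: pd.DataFrame, response: str, predictor: str,
                       with_year: bool) -> ModelResult:
    """OLS of response on predictor, optionally with year as a covariate.

    A constant predictor yields a flagged NA-slope result instead of a
    crash; when year is included, the result notes whether the predictor's
    significance verdict matches the year-free fit.
    """
    df = df.dropna(subset=[response, predictor]).reset_index(drop=True)
    if df.empty or len(df) < 3:
        raise ValueError("too few observations for regression")
    if np.isclose(df[predictor].std(ddof=0), 0.0):
        return ModelResult(params={predictor: np.nan}, bse={}, pvalues={},
                           n_obs=len(df), method="ols", converged=False,
                           notes=f"degenerate: {predictor} is constant")
    base = smf.ols(f"{response} ~ {predictor}", df).fit()
    result_res = base
    notes = ""
    if with_year:
        full = smf.ols(f"{response} ~ {predictor} + year", df).fit()
        base_sig = float(base.pvalues[predictor]) < ALPHA
        full_sig = float(full.pvalues[predictor]) < ALPHA
        notes = ("significance robust to year covariate" if base_sig == full_sig
                 else "significance changes with year covariate")
        result_res = full
    out = _result_from_fit(result_res, "ols", None, notes=notes)
    return out


DENSITY_COLUMNS = {"total": "n_trees", "topcanopy": "n_topcanopy",
                   "subcanopy": "n_subcanopy"}


def density_biomass_model(series: pd.DataFrame, density_class: str = "total",
                          with_year: bool = False,
                          biomass_col: str = "agb_mean") -> ModelResult:
    """Annual plot biomass regressed on tree density.

    ``density_class`` selects total, top-canopy/emergent, or subcanopy
    density (columns n_trees / n_topcanopy / n_subcanopy of the plot
    biomass series); ``with_year`` adds calendar year to absorb temporal
    autocorrelation and notes whether the density term's verdict changes.
    """
    try:
        density_col = DENSITY_COLUMNS[density_class]
    except KeyError:
        raise ValueError(f"density_class must be one of {set(DENSITY_COLUMNS)}")
    if series["year"].nunique() < 5:
        raise ValueError("need at least 5 years of biomass data")
    return _simple_regression(series, biomass_col, density_col, with_year)


def growth_water_model(growth: pd.DataFrame, rwa: pd.DataFrame,
                       with_year: bool = False,
                       growth_col: str = "mean_growth") -> ModelResult:
    """Class mean growth regressed on biomass-relative water availability.

    ``growth`` has ``year`` and the growth column (cm yr^-1, one canopy
    class, one plot); ``rwa`` has ``year`` and ``rwa_mean``.  Years are
    paired by inner join.
    """
    merged = growth.merge(rwa[["year", "rwa_mean"]], on="year", how="inner")
    return _simple_regression(merged, growth_col, "rwa_mean", with_year)
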