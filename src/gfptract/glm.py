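"""Overdispersed GLM inference for occupancy and paternity experiments.

The analysis chain mirrors standard practice for factorial insect
sperm-competition data:

* proportion responses (percentage cover, paternity share) are fitted
  with logit-linked quasi-binomial GLMs — a binomial likelihood whose
  dispersion ``phi`` is estimated post hoc from Pearson residuals and
  scales the standard errors and likelihood-ratio statistics;
* continuous responses (mean pixel intensity) use identity-linked
  Gaussian GLMs (equivalent to OLS);
* each term is judged by a drop1 likelihood-ratio test — an F test for
  continuous responses, a scaled-deviance chi-squared test for bounded
  proportions;
* two-way interactions are entered initially and pruned (least
  significant first) while main design factors are always retained;
* post-hoc Wald contrasts (z for quasi-binomial, t for Gaussian) and
  response-scale percent changes summarise treatment effects;
* explained deviance (pseudo-R^2) summarises model fit.

Model fitting itself is delegated to :mod:`statsmodels`.

No multiple-testing correction is applied anywhere in this module.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .imaging import SITE_SPERMATHECA, SITE_TOTAL_TRACT

REFERENCE_LEVELS = {
    "thermal": "control",
    "female_status": "virgin",
    "time": "30min",
    "male_treatment": "control",
}


class GLMError(ValueError):
    pass


class AliasingError(GLMError):
    pass


class ConvergenceError(GLMError):
    pass


class MarginalityError(GLMError):
    """Attempt to drop a main effect still involved in an interaction."""


@dataclass(frozen=True)
class GLMSpec:
    """What to fit.

    ``response`` is a column name for Gaussian models; for
    quasi-binomial models it is either ``(column, denominator)`` — e.g.
    ``("cover_percent", 100)`` for percentage cover entered as
    cbind(percent, 100 - percent), non-integer values permitted — or a
    ``(success_column, failure_column)`` pair of count columns.
    """

    family: str  # "gaussian" | "quasibinomial"
    response: str | tuple
    terms: tuple[str, ...]

    def __post_init__(self):
        if self.family not in ("gaussian", "quasibinomial"):
            raise GLMError(f"unknown family '{self.family}'")
        object.__setattr__(self, "terms", tuple(self.terms))


def _design_matrix(df: pd.DataFrame, terms: Sequence[str],
                   reference: Mapping[str, str] = REFERENCE_LEVELS):
    """Treatment-coded design matrix with explicit reference levels."""
    n = len(df)
    names = ["Intercept"]
    cols = [np.ones(n)]
    cache: dict[str, list[tuple[str, np.ndarray]]] = {}

    def factor_dummies(f: str):
        if f not in cache:
            if f not in df.columns:
                raise GLMError(f"factor '{f}' not in records")
            levels = sorted(map(str, pd.unique(df[f].astype(str))))
            ref = reference.get(f, levels[0])
            if ref not in levels:
                ref = levels[0]
            cache[f] = [
                (f"{f}[{lv}]", (df[f].astype(str) == lv).to_numpy(float))
                for lv in levels if lv != ref
            ]
        return cache[f]

    for term in terms:
        parts = term.split(":")
        for combo in itertools.product(*[factor_dummies(p) for p in parts]):
            names.append(":".join(c[0] for c in combo))
            cols.append(np.prod(np.stack([c[1] for c in combo]), axis=0))
    return np.column_stack(cols), names


def _build_endog(df: pd.DataFrame, spec: GLMSpec):
    if spec.family == "gaussian":
        if not isinstance(spec.response, str):
            raise GLMError("gaussian response must be a single column name")
        return df[spec.response].to_numpy(float)
    col, other = spec.response
    if isinstance(other, (int, float)):
        success = df[col].to_numpy(float)
        fail = float(other) - success
    else:
        success = df[col].to_numpy(float)
        fail = df[other].to_numpy(float)
    if (success < 0).any() or (fail < 0).any():
        raise GLMError("negative success/failure counts")
    return np.column_stack([success, fail])


@dataclass
class GLMFit:
    """A fitted GLM plus everything needed to refit reduced models."""

    spec: GLMSpec
    data: pd.DataFrame
    result: object  # statsmodels GLMResults
    exog_names: list[str]

    @property
    def params(self) -> pd.Series:
        return pd.Series(self.result.params, index=self.exog_names)

    @property
    def bse(self) -> pd.Series:
        """Standard errors; for quasi-binomial fits the binomial SEs are
        inflated by sqrt(phi) with phi the Pearson dispersion."""
        se = np.asarray(self.result.bse, dtype=float)
        if self.spec.family == "quasibinomial":
            se = se * np.sqrt(pearson_dispersion(self))
        return pd.Series(se, index=self.exog_names)

    @property
    def deviance(self) -> float:
        # numerically perfect fits leave float junk (~1e-29) that would
        # otherwise masquerade as signal in deviance differences
        d = float(self.result.deviance)
        floor = 1e-10 * max(float(self.result.null_deviance), 1e-12)
        return 0.0 if d <= floor else d

    @property
    def null_deviance(self) -> float:
        return float(self.result.null_deviance)

    @property
    def df_resid(self) -> int:
        return int(self.result.df_resid)

    @property
    def n_obs(self) -> int:
        return int(self.result.nobs)

    @property
    def dispersion_phi(self) -> float:
        return pearson_dispersion(self)

    def term_columns(self, term: str) -> list[str]:
        parts = term.split(":")
        out = []
        for name in self.exog_names[1:]:
            bits = [b.split("[")[0] for b in name.split(":")]
            if sorted(bits) == sorted(parts):
                out.append(name)
        return out

    def wald_ci(self, column: str, level: float = 0.95) -> tuple[float, float]:
        """Wald confidence interval for one coefficient (z for
        quasi-binomial, t for Gaussian)."""
        b = self.params[column]
        se = self.bse[column]
        alpha = 1 - level
        if self.spec.family == "gaussian":
            q = sps.t.ppf(1 - alpha / 2, self.df_resid)
        else:
            q = sps.norm.ppf(1 - alpha / 2)
        return (b - q * se, b + q * se)


@dataclass(frozen=True)
class TermTest:
    """drop1 likelihood-ratio test for one model term."""

    term: str
    statistic_kind: str  # "F" | "chi_squared"
    statistic: float
    df: int
    p_value: float


@dataclass(frozen=True)
class EffectSummary:
    """Post-hoc Wald contrast of a treatment level against its reference."""

    factor: str
    contrast: str
    percent_change: float        # model-adjusted, non-focal factors balanced
    percent_change_raw: float    # raw group-mean ratio
    statistic_kind: str          # "z" | "t"
    statistic: float
    p_value: float
    group_means: dict[str, tuple[float, float, int]]  # level -> (mean, se, n)


class _GaussianOLSResult:
    """Identity-link Gaussian GLM realized as OLS (same estimator),
    presenting the subset of the GLM results interface used here."""

    def __init__(self, ols_result):
        self._res = ols_result
        self.params = np.asarray(ols_result.params)
        self.bse = np.asarray(ols_result.bse)
        self.deviance = float(ols_result.ssr)
        self.null_deviance = float(ols_result.centered_tss)
        self.pearson_chi2 = float(ols_result.ssr)
        self.df_resid = int(ols_result.df_resid)
        self.nobs = int(ols_result.nobs)
        self.converged = True

    def predict(self, exog):
        return self._res.predict(exog)


def fit_glm(records: pd.DataFrame, spec: GLMSpec) -> GLMFit:
    """Fit a Gaussian or quasi-binomial GLM.

    The identity-link Gaussian model is fitted as ordinary least squares
    (to which Gaussian IRLS reduces exactly). The quasi-binomial model
    maximises the binomial likelihood by IRLS; its dispersion is
    estimated afterwards from Pearson residuals and only rescales
    standard errors, never the coefficients.
    """
    df = records.reset_index(drop=True)
    X, names = _design_matrix(df, spec.terms)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise AliasingError("design matrix is rank deficient (aliased terms)")
    y = _build_endog(df, spec)
    try:
        if spec.family == "gaussian":
            result = _GaussianOLSResult(sm.OLS(y, X).fit())
        else:
            # dispersion never enters the IRLS iterations; it is estimated
            # afterwards and only rescales standard errors
            result = sm.GLM(y, X, family=sm.families.Binomial()).fit(
                maxiter=100, tol=1e-8)
    except Exception as exc:  # separation shows up as a numerical failure
        raise ConvergenceError(f"GLM fit failed: {exc}") from exc
    if not getattr(result, "converged", True):
        raise ConvergenceError("IRLS did not converge within 100 iterations")
    if not np.all(np.isfinite(result.params)):
        raise ConvergenceError("non-finite coefficients (possible separation)")
    return GLMFit(spec=spec, data=df, result=result, exog_names=names)


def pearson_dispersion(fit: GLMFit) -> float:
    """Overdispersion statistic phi = sum(Pearson residual^2) / df_resid."""
    if fit.df_resid <= 0:
        raise GLMError("no residual degrees of freedom")
    return float(fit.result.pearson_chi2 / fit.df_resid)


def drop1_llrt(fit: GLMFit, term: str) -> TermTest:
    """Likelihood-ratio test of one term by refitting without it.

    Continuous responses use F = (dDeviance/ddf) / phi with phi from the
    larger model; bounded-proportion responses use the scaled deviance
    dDeviance / phi against a chi-squared distribution.
    """
    if term not in fit.spec.terms:
        raise GLMError(f"term '{term}' not in the fitted model")
    for other in fit.spec.terms:
        if other != term and ":" in other and term in other.split(":"):
            raise MarginalityError(
                f"cannot drop '{term}' while '{other}' is in the model"
            )
    reduced = fit_glm(fit.data, replace(fit.spec,
                                        terms=tuple(t for t in fit.spec.terms
                                                    if t != term)))
    ddf = reduced.df_resid - fit.df_resid
    if ddf == 0:
        raise GLMError(f"dropping '{term}' does not change model df")
    ddev = max(reduced.deviance - fit.deviance, 0.0)
    if ddev == 0.0:
        kind = "F" if fit.spec.family == "gaussian" else "chi_squared"
        return TermTest(term, kind, 0.0, ddf, 1.0)
    phi = pearson_dispersion(fit)
    if fit.spec.family == "gaussian":
        stat = (ddev / ddf) / phi
        p = float(sps.f.sf(stat, ddf, fit.df_resid))
        return TermTest(term, "F", float(stat), ddf, p)
    stat = ddev / phi
    p = float(sps.chi2.sf(stat, ddf))
    return TermTest(term, "chi_squared", float(stat), ddf, p)


def reduce_model(fit: GLMFit, alpha: float = 0.05) -> GLMFit:
    """Prune non-significant two-way interactions, one at a time.

    The least significant interaction with p >= alpha is dropped and the
    model refitted, until every remaining interaction is significant.
    Main design factors are never dropped.
    """
    while True:
        interactions = [t for t in fit.spec.terms if ":" in t]
        if not interactions:
            return fit
        tests = [drop1_llrt(fit, t) for t in interactions]
        worst = max(tests, key=lambda t: t.p_value)
        if worst.p_value < alpha:
            return fit
        fit = fit_glm(fit.data, replace(
            fit.spec, terms=tuple(t for t in fit.spec.terms if t != worst.term)))


def _response_scale_values(df: pd.DataFrame, spec: GLMSpec) -> np.ndarray:
    if spec.family == "gaussian":
        return df[spec.response].to_numpy(float)
    col, other = spec.response
    if isinstance(other, (int, float)):
        return df[col].to_numpy(float) / float(other)
    tot = df[col].to_numpy(float) + df[other].to_numpy(float)
    with np.errstate(invalid="ignore"):
        return np.where(tot > 0, df[col].to_numpy(float) / tot, np.nan)


def _adjusted_means(fit: GLMFit, factor: str) -> dict[str, float]:
    """Model-predicted response-scale means per level of ``factor``,
    with every other factor balanced equally across its levels."""
    main_factors = sorted({p for t in fit.spec.terms for p in t.split(":")})
    levels = {f: sorted(map(str, pd.unique(fit.data[f].astype(str))))
              for f in main_factors}
    out = {}
    for lv in levels[factor]:
        others = [f for f in main_factors if f != factor]
        combos = list(itertools.product(*[levels[f] for f in others])) or [()]
        grid = pd.DataFrame(
            [{factor: lv, **dict(zip(others, combo))} for combo in combos]
        )
        Xg, _ = _design_matrix(pd.concat([fit.data[main_factors], grid])
                               .reset_index(drop=True), fit.spec.terms)
        Xg = Xg[-len(grid):]
        out[lv] = float(np.mean(fit.result.predict(Xg)))
    return out


def posthoc_contrasts(fit: GLMFit) -> list[EffectSummary]:
    """Wald contrasts of each factor's non-reference levels vs reference.

    The Wald statistic is coefficient / standard error (z for
    quasi-binomial, t for Gaussian). ``percent_change`` compares
    model-predicted response-scale means with the non-focal factors
    balanced equally across their levels; ``percent_change_raw`` uses
    raw group means.
    """
    obs = _response_scale_values(fit.data, fit.spec)
    summaries = []
    main_factors = [t for t in fit.spec.terms if ":" not in t]
    for factor in main_factors:
        ref = REFERENCE_LEVELS.get(
            factor, sorted(map(str, pd.unique(fit.data[factor].astype(str))))[0])
        adj = _adjusted_means(fit, factor)
        gm = {}
        for lv, grp in pd.DataFrame(
                {"lv": fit.data[factor].astype(str), "y": obs}).groupby("lv"):
            vals = grp["y"].dropna()
            n = len(vals)
            se = float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
            gm[lv] = (float(vals.mean()), se, n)
        for col in fit.term_columns(factor):
            level = col.split("[")[1].rstrip("]")
            b = float(fit.params[col])
            se = float(fit.bse[col])
            stat = b / se if se > 0 else np.inf * np.sign(b) if b else 0.0
            if fit.spec.family == "gaussian":
                kind = "t"
                p = float(2 * sps.t.sf(abs(stat), fit.df_resid))
            else:
                kind = "z"
                p = float(2 * sps.norm.sf(abs(stat)))
            pc = 100.0 * (adj[level] - adj[ref]) / adj[ref]
            pc_raw = (100.0 * (gm[level][0] - gm[ref][0]) / gm[ref][0]
                      if gm.get(ref, (0,))[0] else np.nan)
            summaries.append(EffectSummary(
                factor=factor, contrast=f"{level} vs {ref}",
                percent_change=float(pc), percent_change_raw=float(pc_raw),
                statistic_kind=kind, statistic=float(stat), p_value=p,
                group_means=gm,
            ))
    return summaries


def pseudo_r2(fit: GLMFit) -> float:
    """Explained deviance: 1 - residual deviance / null deviance."""
    if fit.null_deviance == 0:
        raise GLMError("null deviance is zero; pseudo-R^2 undefined")
    return 1.0 - fit.deviance / fit.null_deviance


def spearman_correlation(x, y) -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties.

    Returns (rho, S) where S is the sum of squared rank differences, the
    statistic R reports alongside rho for this test.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise GLMError("need equal-length 1-D vectors with >= 3 entries")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise GLMError("zero variance in one of the vectors")
    rho = float(sps.spearmanr(x, y).statistic)
    rx = sps.rankdata(x, method="average")
    ry = sps.rankdata(y, method="average")
    return rho, float(np.sum((rx - ry) ** 2))


def describe_by(records: pd.DataFrame, grouping: Sequence[str] | str,
                values: Sequence[str] | str) -> pd.DataFrame:
    """Mean +/- s.e. (and n) per group for each value column.

    Groups of size one get s.e. 0 with n = 1 left visible as the flag.
    """
    if isinstance(grouping, str):
        grouping = [grouping]
    if isinstance(values, str):
        values = [values]
    if len(records) == 0:
        raise GLMError("no records")
    rows = []
    for key, grp in records.groupby(list(grouping)):
        if not isinstance(key, tuple):
            key = (key,)
        for v in values:
            vals = grp[v].astype(float)
            n = len(vals)
            rows.append({
                **dict(zip(grouping, key)), "variable": v, "n": n,
                "mean": float(vals.mean()),
                "se": float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0,
            })
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Experiment-level drivers
# --------------------------------------------------------------------------

OCCUPANCY_TERMS = (
    "thermal", "female_status", "time",
    "thermal:female_status", "thermal:time", "female_status:time",
)

FAMILY_LABEL = {
    "quasibinomial": "GLM Q-bin (logit)",
    "gaussian": "GLM Gaus (ID)",
}


@dataclass
class ModelReport:
    """One fitted response: reduced model, term tests, contrasts."""

    experiment: str
    site: str
    response: str
    family: str
    n_obs: int
    df_resid: int
    dispersion_phi: float
    pseudo_r2: float
    retained_interactions: list[str]
    term_tests: list[TermTest]
    contrasts: list[EffectSummary]
    coefficients: dict[str, float]
    std_errors: dict[str, float]

    def to_dict(self) -> dict:
        return {
            "experiment": self.experiment,
            "site": self.site,
            "response": self.response,
            "family": self.family,
            "n_obs": self.n_obs,
            "df_resid": self.df_resid,
            "dispersion_phi": self.dispersion_phi,
            "pseudo_r2": self.pseudo_r2,
            "retained_interactions": self.retained_interactions,
            "term_tests": [vars(t) for t in self.term_tests],
            "contrasts": [
                {**{k: v for k, v in vars(c).items() if k != "group_means"},
                 "group_means": {lv: {"mean": m, "se": s, "n": n}
                                 for lv, (m, s, n) in c.group_means.items()}}
                for c in self.contrasts
            ],
            "coefficients": self.coefficients,
            "std_errors": self.std_errors,
        }


def _report_model(experiment: str, site: str, response: str,
                  fit: GLMFit) -> ModelReport:
    reduced = reduce_model(fit)
    retained = [t for t in reduced.spec.terms if ":" in t]
    blocked = {p for t in retained for p in t.split(":")}
    tests = []
    for term in reduced.spec.terms:
        if ":" not in term and term in blocked:
            # marginal to a retained interaction: type-II style test
            # against the model stripped of interactions containing it
            base_terms = tuple(
                t for t in reduced.spec.terms
                if not (":" in t and term in t.split(":"))
            )
            base = fit_glm(reduced.data, replace(reduced.spec, terms=base_terms))
            tests.append(drop1_llrt(base, term))
            continue
        tests.append(drop1_llrt(reduced, term))
    return ModelReport(
        experiment=experiment, site=site, response=response,
        family=FAMILY_LABEL[reduced.spec.family],
        n_obs=reduced.n_obs, df_resid=reduced.df_resid,
        dispersion_phi=pearson_dispersion(reduced),
        pseudo_r2=(pseudo_r2(reduced) if reduced.null_deviance > 0
                   else float("nan")),
        retained_interactions=retained,
        term_tests=tests,
        contrasts=posthoc_contrasts(reduced),
        coefficients={k: float(v) for k, v in reduced.params.items()},
        std_errors={k: float(v) for k, v in reduced.bse.items()},
    )


@dataclass
class OccupancyResults:
    """Model reports for the four response x site combinations."""

    reports: dict[tuple[str, str], ModelReport]
    errors: dict[tuple[str, str], str] = field(default_factory=dict)

    def to_table(self) -> pd.DataFrame:
        """Flat summary table: one row per fixed factor plus a residual row."""
        rows = []
        for (site, response), rep in self.reports.items():
            for t in rep.term_tests:
                rows.append({
                    "experiment": rep.experiment, "fixed_factor": t.term,
                    "df": t.df, "statistic_kind": t.statistic_kind,
                    "statistic": t.statistic, "p_value": t.p_value,
                    "model": rep.family,
                    "pseudo_r2": rep.pseudo_r2,
                })
            rows.append({
                "experiment": rep.experiment, "fixed_factor": "residual",
                "df": rep.df_resid, "statistic_kind": "", "statistic": np.nan,
                "p_value": np.nan, "model": rep.family,
                "pseudo_r2": rep.pseudo_r2,
            })
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "models": {f"{site}:{resp}": rep.to_dict()
                       for (site, resp), rep in self.reports.items()},
            "errors": {f"{site}:{resp}": msg
                       for (site, resp), msg in self.errors.items()},
        }


def analyze_occupancy(records: pd.DataFrame) -> OccupancyResults:
    """Fit and reduce the four occupancy models (site x response).

    Percentage cover is analysed as a logit-linked quasi-binomial GLM on
    cbind(percent, 100 - percent); mean intensity as an identity-linked
    Gaussian GLM. Fitting errors for one response are recorded and the
    others continue.
    """
    needed = {"thermal", "female_status", "time", "site",
              "cover_percent", "mean_intensity"}
    missing = needed - set(records.columns)
    if missing:
        raise GLMError(f"records lack columns: {sorted(missing)}")
    specs = {
        "cover": GLMSpec("quasibinomial", ("cover_percent", 100),
                         OCCUPANCY_TERMS),
        "intensity": GLMSpec("gaussian", "mean_intensity", OCCUPANCY_TERMS),
    }
    names = {
        (SITE_TOTAL_TRACT, "cover"):
            "female tract sperm distribution percentage cover",
        (SITE_TOTAL_TRACT, "intensity"):
            "female tract sperm distribution mean intensity",
        (SITE_SPERMATHECA, "cover"):
            "female spermatheca sperm distribution percentage cover",
        (SITE_SPERMATHECA, "intensity"):
            "female spermatheca sperm distribution mean intensity",
    }
    results = OccupancyResults(reports={})
    for site in (SITE_TOTAL_TRACT, SITE_SPERMATHECA):
        sub = records[records["site"] == site]
        for response, spec in specs.items():
            key = (site, response)
            try:
                fit = fit_glm(sub, spec)
                results.reports[key] = _report_model(
                    names[key], site, response, fit)
            except GLMError as exc:
                results.errors[key] = str(exc)
    return results


def analyze_paternity(records: pd.DataFrame) -> ModelReport:
    """Quasi-binomial GLM of (filiform, clubbed) offspring counts on the
    focal male's thermal treatment."""
    total = records["n_filiform"] + records["n_clubbed"]
    if (total <= 0).all():
        raise GLMError("all broods are empty")
    usable = records[total > 0].reset_index(drop=True)
    if usable["male_treatment"].nunique() < 2:
        raise GLMError("need both treatment arms")
    spec = GLMSpec("quasibinomial", ("n_filiform", "n_clubbed"),
                   ("male_treatment",))
    fit = fit_glm(usable, spec)
    return _report_model("GFP male P2 paternity proportion", "paternity",
                         "p2", fit)


def metric_correlations(records: pd.DataFrame) -> pd.DataFrame:
    """Spearman correlations among occupancy metrics, per site:
    presence ~ percentage cover and median ~ mean intensity."""
    rows = []
    for site, grp in records.groupby("site"):
        for a, b in (("presence", "cover_percent"),
                     ("median_intensity", "mean_intensity")):
            rho, s = spearman_correlation(
                grp[a].astype(float), grp[b].astype(float))
            rows.append({"site": site, "pair": f"{a}~{b}",
                         "n": len(grp), "rho": rho, "S": s})
    return pd.DataFrame(rows)
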